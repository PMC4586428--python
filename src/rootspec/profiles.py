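"""Parametric peak models for root spectra of the eight study species.

Each species is described by a :class:`SpeciesProfile`: a baseline level plus
Gaussian peaks. Three bands are common to all dried/ground root material —
the O-H stretch near 3330 cm^-1, the C-H stretch near 2921 cm^-1 and the
dominant polysaccharide (cellulose/hemicellulose) band near 1030 cm^-1 —
while the 1800-800 cm^-1 fingerprint region carries family- and
species-specific bands. Peak positions for the named species follow the
absorbance maxima reported for dried/ground roots (maize 1572, barnyard
grass 1637, barley 1510 and 815, wheat 1510 and 1420, sugar beet 1621 and
1416, common lambsquarters 1516 and 1240 cm^-1); amplitudes are set so the
qualitative relative-height relations hold: 1030 cm^-1 is the tallest band
everywhere, grass (Poaceae) and goosefoot (Chenopodiaceae) species share
family templates so that within-family spectra are mutually closer than
cross-family ones, blackgrass is elevated over wheat in 1800-1200 cm^-1,
and barley/wild oat share peak positions and differ only in peak height
(the hardest pair).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import ContractError, UnknownSpeciesError

__all__ = [
    "Peak",
    "SpeciesProfile",
    "NoiseModel",
    "MixtureSample",
    "STUDY_SPECIES",
    "CROP_WEED_PAIRS",
    "COMMON_PEAK_CENTERS",
    "builtin_profile",
    "builtin_profiles",
]

#: Band roles: common to all plant roots, shared within a family, or
#: species-specific. Fresh-mode masking and the tip-convergence option act
#: on the non-common roles only.
PEAK_TAGS = ("common", "family", "specific", "water")

COMMON_PEAK_CENTERS = (3330.0, 2921.0, 1030.0)

STUDY_SPECIES = (
    "maize",
    "barnyard_grass",
    "barley",
    "wild_oat",
    "wheat",
    "blackgrass",
    "sugar_beet",
    "common_lambsquarters",
)

#: The four crop/weed pairs of the discrimination experiment.
CROP_WEED_PAIRS = (
    ("maize", "barnyard_grass"),
    ("barley", "wild_oat"),
    ("wheat", "blackgrass"),
    ("sugar_beet", "common_lambsquarters"),
)

FAMILY = {
    "maize": "Poaceae",
    "barnyard_grass": "Poaceae",
    "barley": "Poaceae",
    "wild_oat": "Poaceae",
    "wheat": "Poaceae",
    "blackgrass": "Poaceae",
    "sugar_beet": "Chenopodiaceae",
    "common_lambsquarters": "Chenopodiaceae",
}


@dataclass(frozen=True)
class Peak:
    """One Gaussian absorption band."""

    center: float  # cm^-1
    width: float  # Gaussian standard deviation, cm^-1
    amplitude: float  # absorbance units at the peak maximum
    tag: str = "specific"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ContractError("peak width must be positive")
        if self.amplitude < 0:
            raise ContractError("peak amplitude must be nonnegative")
        if not 0 <= self.center <= 10000:
            raise ContractError("peak center outside the working range")
        if self.tag not in PEAK_TAGS:
            raise ContractError(f"peak tag must be one of {PEAK_TAGS}")


@dataclass(frozen=True)
class SpeciesProfile:
    """Peak model plus baseline for one species' root material."""

    species: str
    peaks: tuple[Peak, ...]
    baseline_level: float = 0.02

    def __init__(self, species: str, peaks: Iterable[Peak], baseline_level: float = 0.02):
        object.__setattr__(self, "species", species)
        object.__setattr__(self, "peaks", tuple(peaks))
        object.__setattr__(self, "baseline_level", float(baseline_level))
        if not species:
            raise ContractError("species must be non-empty")

    def max_amplitude(self) -> float:
        return max(p.amplitude for p in self.peaks)

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "baseline_level": self.baseline_level,
            "peaks": [
                {"center": p.center, "width": p.width, "amplitude": p.amplitude, "tag": p.tag}
                for p in self.peaks
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SpeciesProfile":
        return cls(
            species=data["species"],
            peaks=[Peak(**p) for p in data["peaks"]],
            baseline_level=data.get("baseline_level", 0.02),
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SpeciesProfile":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic measurement model for simulated spectra.

    additive_sd
        white detector noise, absorbance units.
    amplitude_cv
        relative per-peak amplitude jitter between replicate samples; the
        main carrier of within-species biological variation.
    baseline_drift_sd
        scale of the random baseline offset and tilt, absorbance units.
    scale_sd
        relative global intensity variation (sample thickness / crystal
        contact); removed by vector normalization.
    seed
        fixes the full random stream; identical seeds give identical spectra.
    """

    additive_sd: float = 0.002
    amplitude_cv: float = 0.05
    baseline_drift_sd: float = 0.01
    scale_sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("additive_sd", "amplitude_cv", "baseline_drift_sd", "scale_sd"):
            if getattr(self, name) < 0:
                raise ContractError(f"{name} must be nonnegative")

    @classmethod
    def silent(cls, seed: int = 0) -> "NoiseModel":
        """All noise sources off; generation is then fully deterministic."""
        return cls(0.0, 0.0, 0.0, 0.0, seed)

    @classmethod
    def dried(cls, seed: int = 0) -> "NoiseModel":
        """Default noise for dried root segments."""
        return cls(additive_sd=0.002, amplitude_cv=0.05, baseline_drift_sd=0.01,
                   scale_sd=0.10, seed=seed)

    @classmethod
    def ground(cls, seed: int = 0) -> "NoiseModel":
        """Default noise for ground (homogenized) roots: lower amplitude
        jitter because milling averages out local tissue composition."""
        return cls(additive_sd=0.002, amplitude_cv=0.02, baseline_drift_sd=0.01,
                   scale_sd=0.10, seed=seed)


@dataclass(frozen=True)
class MixtureSample:
    """Mass fractions of the species in one artificial root mixture."""

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        for sp, f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ContractError(f"fraction of {sp} = {f} outside [0, 1]")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ContractError(f"fractions sum to {total}, expected 1")

    def species(self) -> tuple[str, ...]:
        return tuple(self.fractions)


def _poaceae_template() -> list[Peak]:
    return [
        Peak(1160.0, 25.0, 0.35, "family"),
        Peak(1370.0, 25.0, 0.20, "family"),
        Peak(898.0, 15.0, 0.15, "family"),
    ]


def _chenopodiaceae_template() -> list[Peak]:
    return [
        Peak(1100.0, 30.0, 0.30, "family"),
        Peak(1320.0, 25.0, 0.18, "family"),
        Peak(1740.0, 20.0, 0.22, "family"),
    ]


def _common_peaks(poly_amp: float = 1.0) -> list[Peak]:
    # 1030 cm^-1 polysaccharide band carries the largest amplitude of any peak
    return [
        Peak(3330.0, 120.0, 0.45, "common"),
        Peak(2921.0, 35.0, 0.30, "common"),
        Peak(1030.0, 45.0, poly_amp, "common"),
    ]


_SPECIFIC: dict[str, tuple[float, list[Peak]]] = {
    # species: (polysaccharide amplitude, fingerprint peaks)
    # weeds, especially grasses, show the tallest 1030 cm^-1 band
    "maize": (0.95, [Peak(1572.0, 18.0, 0.30, "specific")]),
    "barnyard_grass": (1.10, [Peak(1637.0, 18.0, 0.30, "specific")]),
    "barley": (0.95, [Peak(1510.0, 15.0, 0.25, "specific"),
                      Peak(815.0, 12.0, 0.18, "specific")]),
    # wild oat: same peak positions as barley, different heights only
    "wild_oat": (1.10, [Peak(1510.0, 15.0, 0.12, "specific"),
                        Peak(815.0, 12.0, 0.08, "specific")]),
    "wheat": (0.95, [Peak(1510.0, 15.0, 0.25, "specific"),
                     Peak(1420.0, 15.0, 0.22, "specific")]),
    # blackgrass: elevated absorbance over wheat throughout 1800-1200 cm^-1
    "blackgrass": (1.10, [Peak(1515.0, 15.0, 0.35, "specific"),
                          Peak(1420.0, 15.0, 0.30, "specific"),
                          Peak(1650.0, 25.0, 0.25, "specific")]),
    "sugar_beet": (0.90, [Peak(1621.0, 20.0, 0.40, "specific"),
                          Peak(1416.0, 18.0, 0.35, "specific")]),
    "common_lambsquarters": (1.00, [Peak(1516.0, 18.0, 0.38, "specific"),
                                    Peak(1240.0, 18.0, 0.30, "specific")]),
}


def builtin_profile(species: str) -> SpeciesProfile:
    """Peak model for one of the eight study species.

    Raises :class:`UnknownSpeciesError` (listing valid names) otherwise.
    """
    if species not in _SPECIFIC:
        raise UnknownSpeciesError(species, STUDY_SPECIES)
    poly_amp, specific = _SPECIFIC[species]
    family = (
        _poaceae_template() if FAMILY[species] == "Poaceae" else _chenopodiaceae_template()
    )
    return SpeciesProfile(
        species=species,
        peaks=_common_peaks(poly_amp) + family + specific,
    )


def builtin_profiles(species: Iterable[str] | None = None) -> dict[str, SpeciesProfile]:
    """Profiles for the requested species (default: all eight)."""
    names = tuple(species) if species is not None else STUDY_SPECIES
    return {name: builtin_profile(name) for name in names}
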