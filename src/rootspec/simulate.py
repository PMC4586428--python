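"""Synthetic root-spectrum generation.

Spectra are rendered as a baseline plus a sum of Gaussian bands, with four
stochastic components (see :class:`~rootspec.profiles.NoiseModel`): per-peak
amplitude jitter, a random baseline offset/tilt, a global intensity scale
and additive white noise. Preparation states map onto the generator as
follows:

``dried_segment``
    the peak model as given, default amplitude jitter.
``ground``
    homogenized material — the same peak model with lower amplitude jitter.
``fresh_segment``
    moist tissue — broad water bands (O-H stretch near 3300 cm^-1 and the
    H-O-H bend near 1640 cm^-1) are superimposed at >= 5x the tallest dry
    band, and the family/species-specific fingerprint bands are attenuated,
    emulating how the water signal conceals the weaker compositional bands.

Mixture spectra follow Beer-Lambert additivity: the noise-free part is the
mass-fraction-weighted sum of the pure-species spectra, with measurement
noise applied to the mixed spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, SamplingError
from .profiles import (
    MixtureSample,
    NoiseModel,
    SpeciesProfile,
    builtin_profiles,
)
from .spectra import SampleMeta, Spectrum, WavenumberGrid, default_grid

__all__ = [
    "WATER_BANDS",
    "MixtureDesign",
    "simulate_spectrum",
    "simulate_mixture_spectrum",
    "simulate_species_set",
    "simulate_mixture_set",
    "design_2species",
    "design_3species",
    "DEFAULT_3SPECIES_BOUNDS",
]

#: Fresh-tissue water bands: (center cm^-1, width cm^-1, amplitude multiple
#: of the profile's tallest peak). O-H stretch and H-O-H bend.
WATER_BANDS = ((3300.0, 150.0, 6.0), (1640.0, 40.0, 5.0))

#: Attenuation applied to family/species-specific bands in fresh mode: the
#: water signal overlaps and conceals the compositional fingerprint.
FRESH_FINGERPRINT_SCALE = 0.3


@dataclass(frozen=True)
class MixtureDesign:
    """Ordered list of mixture compositions over a fixed species set."""

    species: tuple[str, ...]
    samples: tuple[MixtureSample, ...]

    def __len__(self) -> int:
        return len(self.samples)

    def fractions_percent(self) -> pd.DataFrame:
        """Compositions as a (n_samples x n_species) table in percent."""
        rows = [
            {sp: 100.0 * s.fractions.get(sp, 0.0) for sp in self.species}
            for s in self.samples
        ]
        frame = pd.DataFrame(rows, columns=list(self.species))
        frame.insert(0, "sample_id", [f"mix{i:02d}" for i in range(len(rows))])
        return frame

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.fractions_percent().to_csv(path, index=False)
        return path


def _gaussian(wn: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wn - center) / width) ** 2)


def _effective_peaks(
    profile: SpeciesProfile,
    prep: str,
    segment: str,
    segment_scale: Mapping[str, float] | None,
    tip_specific_shrink: float,
) -> list[tuple[float, float, float]]:
    """Resolve prep/segment modifiers into (center, width, amplitude) triples."""
    seg_mult = 1.0 if segment_scale is None else float(segment_scale.get(segment, 1.0))
    triples = []
    for p in profile.peaks:
        amp = p.amplitude * seg_mult
        if prep == "fresh_segment" and p.tag in ("family", "specific"):
            amp *= FRESH_FINGERPRINT_SCALE
        if segment == "tip" and p.tag == "specific":
            amp *= tip_specific_shrink
        triples.append((p.center, p.width, amp))
    if prep == "fresh_segment":
        top = profile.max_amplitude()
        for center, width, mult in WATER_BANDS:
            triples.append((center, width, mult * top))
    return triples


def _render_peaks(
    triples: Sequence[tuple[float, float, float]],
    grid: WavenumberGrid,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sum of Gaussian bands with per-peak multiplicative amplitude jitter."""
    wn = grid.values
    eps = rng.normal(1.0, noise.amplitude_cv, size=len(triples)) if noise.amplitude_cv > 0 \
        else np.ones(len(triples))
    eps = np.clip(eps, 0.0, None)
    y = np.zeros_like(wn)
    for (center, width, amp), e in zip(triples, eps):
        y += amp * e * _gaussian(wn, center, width)
    return y


def _finish(
    y: np.ndarray, grid: WavenumberGrid, noise: NoiseModel, rng: np.random.Generator
) -> np.ndarray:
    """Apply global scale, baseline drift and additive noise, in that order."""
    scale = rng.normal(1.0, noise.scale_sd) if noise.scale_sd > 0 else 1.0
    y = max(scale, 0.0) * y
    if noise.baseline_drift_sd > 0:
        offset = rng.normal(0.0, noise.baseline_drift_sd)
        tilt = rng.normal(0.0, noise.baseline_drift_sd)
        ramp = np.linspace(-1.0, 1.0, len(grid))
        y = y + offset + tilt * ramp
    if noise.additive_sd > 0:
        y = y + rng.normal(0.0, noise.additive_sd, size=len(grid))
    return y


def simulate_spectrum(
    profile: SpeciesProfile,
    prep: str = "dried_segment",
    segment: str = "none",
    noise: NoiseModel | None = None,
    grid: WavenumberGrid | None = None,
    rng: np.random.Generator | None = None,
    sample_id: str | None = None,
    replicate: int = 1,
    segment_scale: Mapping[str, float] | None = None,
    tip_specific_shrink: float = 1.0,
) -> Spectrum:
    """Simulate one root spectrum for a species profile.

    With an all-zero noise model the output is deterministic; with a fixed
    ``noise.seed`` two calls produce bit-identical spectra. An explicit
    ``rng`` overrides the seed (used when drawing many replicates from one
    stream). ``tip_specific_shrink`` < 1 enables tip convergence: the
    species-specific bands shrink at root tips, where surface chemistry is
    most alike across species.
    """
    noise = noise or NoiseModel.silent()
    grid = grid or default_grid()
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    triples = _effective_peaks(profile, prep, segment, segment_scale, tip_specific_shrink)
    y = profile.baseline_level + _render_peaks(triples, grid, noise, rng)
    y = _finish(y, grid, noise, rng)
    meta = SampleMeta(
        sample_id=sample_id or f"{profile.species}_{prep}_{segment}_{replicate}",
        species=profile.species,
        prep_state=prep,
        segment="none" if prep == "ground" else segment,
        replicate=replicate,
        pot_type="synthetic",
    )
    return Spectrum(grid, y, meta)


def simulate_mixture_spectrum(
    profiles: Mapping[str, SpeciesProfile],
    sample: MixtureSample,
    noise: NoiseModel | None = None,
    grid: WavenumberGrid | None = None,
    rng: np.random.Generator | None = None,
    sample_id: str = "mixture",
    replicate: int = 1,
) -> Spectrum:
    """Simulate a spectrum of ground roots mixed at given mass fractions.

    The noise-free part is the fraction-weighted sum of the pure-species
    spectra (Beer-Lambert additivity); scale, drift and additive noise are
    applied to the mixed spectrum. A single-species "mixture" at the same
    seed reproduces :func:`simulate_spectrum` exactly.
    """
    noise = noise or NoiseModel.silent()
    grid = grid or default_grid()
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    missing = [sp for sp in sample.fractions if sp not in profiles]
    if missing:
        raise KeyError(f"no profile for species: {', '.join(missing)}")
    y = np.zeros(len(grid))
    for sp, frac in sample.fractions.items():
        profile = profiles[sp]
        triples = _effective_peaks(profile, "ground", "none", None, 1.0)
        pure = profile.baseline_level + _render_peaks(triples, grid, noise, rng)
        y += frac * pure
    y = _finish(y, grid, noise, rng)
    species_label = "+".join(
        f"{sp}:{frac:g}" for sp, frac in sample.fractions.items()
    )
    meta = SampleMeta(
        sample_id=sample_id,
        species=species_label,
        prep_state="ground",
        segment="none",
        replicate=replicate,
        pot_type="synthetic",
    )
    return Spectrum(grid, y, meta)


def simulate_species_set(
    species: Sequence[str],
    n_replicates: int,
    prep: str = "ground",
    noise: NoiseModel | None = None,
    grid: WavenumberGrid | None = None,
    segments: Sequence[str] = ("none",),
    profiles: Mapping[str, SpeciesProfile] | None = None,
    **kwargs,
) -> list[Spectrum]:
    """Replicate spectra for several species from one seeded stream.

    One spectrum per (species, segment, replicate), generated in that order
    from a single generator seeded with ``noise.seed`` so the whole set is
    reproducible.
    """
    noise = noise or NoiseModel.silent()
    grid = grid or default_grid()
    profiles = profiles or builtin_profiles(species)
    rng = np.random.default_rng(noise.seed)
    out = []
    for sp in species:
        for seg in segments:
            for rep in range(1, n_replicates + 1):
                out.append(
                    simulate_spectrum(
                        profiles[sp], prep=prep, segment=seg, noise=noise,
                        grid=grid, rng=rng, replicate=rep,
                        sample_id=f"{sp}_{prep}_{seg}_r{rep}", **kwargs,
                    )
                )
    return out


def simulate_mixture_set(
    design: MixtureDesign,
    n_replicates: int = 3,
    noise: NoiseModel | None = None,
    grid: WavenumberGrid | None = None,
    profiles: Mapping[str, SpeciesProfile] | None = None,
) -> tuple[list[Spectrum], pd.DataFrame]:
    """Replicate spectra for every mixture in a design.

    Returns the spectra and the aligned composition table in percent (one
    row per spectrum, columns = design species), ready for calibration.
    """
    noise = noise or NoiseModel.silent()
    grid = grid or default_grid()
    profiles = profiles or builtin_profiles(design.species)
    rng = np.random.default_rng(noise.seed)
    spectra: list[Spectrum] = []
    rows = []
    for i, sample in enumerate(design.samples):
        for rep in range(1, n_replicates + 1):
            sid = f"mix{i:02d}_r{rep}"
            spectra.append(
                simulate_mixture_spectrum(
                    profiles, sample, noise=noise, grid=grid, rng=rng,
                    sample_id=sid, replicate=rep,
                )
            )
            rows.append(
                {"sample_id": sid,
                 **{sp: 100.0 * sample.fractions.get(sp, 0.0) for sp in design.species}}
            )
    frame = pd.DataFrame(rows).set_index("sample_id")
    return spectra, frame


def design_2species(
    step_percent: float = 5.0, species: tuple[str, str] = ("maize", "wild_oat")
) -> MixtureDesign:
    """Two-species dilution series: (k*step, 100 - k*step) for k = 0..100/step.

    The default 5% step over maize/wild oat gives the 21-composition
    calibration series.
    """
    n_steps = 100.0 / step_percent
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ContractError(f"step {step_percent}% does not divide 100 exactly")
    k = int(round(n_steps))
    a, b = species
    samples = tuple(
        MixtureSample({a: i * step_percent / 100.0, b: 1.0 - i * step_percent / 100.0})
        for i in range(k + 1)
    )
    return MixtureDesign(species=species, samples=samples)


#: Composition ranges of the three-species design: dominant crop, wide-range
#: first weed, minor second weed (percent of total root mass).
DEFAULT_3SPECIES_BOUNDS = {
    "maize": (15.0, 80.0),
    "wild_oat": (1.5, 79.0),
    "barnyard_grass": (0.5, 20.0),
}


def design_3species(
    n: int = 21,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    max_tries: int = 1_000_000,
) -> MixtureDesign:
    """Random three-species design on the simplex, constrained per species.

    Compositions are drawn uniformly on the simplex (flat Dirichlet) and
    rejected until all per-species percent bounds hold; the seed makes the
    design reproducible.
    """
    bounds = dict(bounds or DEFAULT_3SPECIES_BOUNDS)
    species = tuple(bounds)
    lows = np.array([bounds[sp][0] for sp in species])
    highs = np.array([bounds[sp][1] for sp in species])
    if np.any(lows > highs):
        raise ContractError("each low bound must not exceed its high bound")
    if lows.sum() > 100.0 + 1e-9 or highs.sum() < 100.0 - 1e-9:
        raise ContractError(
            f"infeasible bounds: lows sum to {lows.sum()}%, highs to {highs.sum()}%"
        )
    rng = np.random.default_rng(seed)
    samples: list[MixtureSample] = []
    tries = 0
    while len(samples) < n:
        if tries >= max_tries:
            raise SamplingError(
                f"rejection budget ({max_tries}) exhausted after {len(samples)}/{n} samples"
            )
        tries += 1
        x = rng.dirichlet(np.ones(len(species))) * 100.0
        if np.all(x >= lows) and np.all(x <= highs):
            fracs = x / x.sum()
            samples.append(MixtureSample(dict(zip(species, fracs))))
    return MixtureDesign(species=species, samples=tuple(samples))
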