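"""Spectrum data model, tabular I/O, resampling and spectral-window extraction.

A :class:`Spectrum` is a vector of absorbance values on a
:class:`WavenumberGrid` (reciprocal centimetres) plus per-sample metadata.
Wavenumbers are stored ascending internally; mid-infrared convention plots
them descending, which is left to presentation code. Spectra move between
memory and disk as plain delimited tables: the wavenumber axis in the first
column, one sample per remaining column, with an optional companion table
carrying the sample metadata.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ContractError,
    EmptySelectionError,
    ExtrapolationError,
    SpectraFormatError,
    SpectraParseError,
)

__all__ = [
    "WavenumberGrid",
    "SampleMeta",
    "Spectrum",
    "SpectralWindows",
    "DEFAULT_WINDOWS",
    "default_grid",
    "read_spectra_table",
    "write_spectra_table",
    "read_metadata_table",
    "write_metadata_table",
    "resample",
    "extract_windows",
]

PREP_STATES = ("fresh_segment", "dried_segment", "ground")
SEGMENTS = ("basis", "middle", "tip", "taproot", "none")
POT_TYPES = ("single", "mixture", "synthetic")


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly increasing wavenumber axis in cm^-1."""

    values: np.ndarray
    spacing: float = field(init=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ContractError("grid needs at least two wavenumbers")
        if np.any(np.diff(values) <= 0):
            # accept descending input; normalize to ascending storage
            if np.all(np.diff(values) < 0):
                values = values[::-1]
            else:
                raise ContractError("wavenumbers must be strictly monotonic")
        if values[0] < 0 or values[-1] > 10000:
            raise ContractError("wavenumbers must lie within [0, 10000] cm^-1")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", float(np.median(np.diff(values))))

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and np.array_equal(
            self.values, other.values
        )

    def __hash__(self) -> int:
        return hash((self.values.size, float(self.values[0]), float(self.values[-1])))

    @property
    def span(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        steps = np.diff(self.values)
        return bool(np.allclose(steps, steps[0], rtol=rtol))


def default_grid(low: float = 400.0, high: float = 4000.0, spacing: float = 2.0) -> WavenumberGrid:
    """Working grid: 4000-400 cm^-1 digitized at 2 cm^-1 (1801 points).

    2 cm^-1 point spacing is the conventional digitization for a 4 cm^-1
    optical resolution; both bounds and the spacing are configurable.
    """
    n = int(round((high - low) / spacing)) + 1
    return WavenumberGrid(low + spacing * np.arange(n))


@dataclass(frozen=True)
class SampleMeta:
    """Identity and preparation state of one measured sample."""

    sample_id: str
    species: str
    prep_state: str = "dried_segment"
    segment: str = "none"
    replicate: int = 1
    pot_type: str = "single"

    def __post_init__(self) -> None:
        if not self.species:
            raise ContractError("species must be non-empty")
        if self.prep_state not in PREP_STATES:
            raise ContractError(f"prep_state must be one of {PREP_STATES}")
        if self.segment not in SEGMENTS:
            raise ContractError(f"segment must be one of {SEGMENTS}")
        if self.pot_type not in POT_TYPES:
            raise ContractError(f"pot_type must be one of {POT_TYPES}")
        if self.prep_state == "ground" and self.segment != "none":
            raise ContractError("ground samples carry no segment position")


@dataclass(frozen=True)
class Spectrum:
    """Absorbance values on a wavenumber grid plus sample metadata."""

    grid: WavenumberGrid
    absorbance: np.ndarray
    meta: SampleMeta

    def __post_init__(self) -> None:
        absorbance = np.asarray(self.absorbance, dtype=float)
        if absorbance.shape != (len(self.grid),):
            raise ContractError(
                f"absorbance length {absorbance.size} != grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(absorbance)):
            raise ContractError("absorbance must be finite")
        object.__setattr__(self, "absorbance", absorbance)

    def with_absorbance(self, values: np.ndarray) -> "Spectrum":
        return Spectrum(self.grid, values, self.meta)

    def with_meta(self, **changes) -> "Spectrum":
        return Spectrum(self.grid, self.absorbance, dataclasses.replace(self.meta, **changes))


@dataclass(frozen=True)
class SpectralWindows:
    """Inclusive wavenumber intervals selecting sub-ranges of a spectrum."""

    windows: tuple[tuple[float, float], ...]

    def __init__(self, windows: Iterable[Sequence[float]]):
        pairs = tuple((float(lo), float(hi)) for lo, hi in windows)
        if not pairs:
            raise ContractError("at least one window required")
        for lo, hi in pairs:
            if lo >= hi:
                raise ContractError(f"window ({lo}, {hi}) must satisfy low < high")
        ordered = sorted(pairs)
        for (_, hi_a), (lo_b, _) in zip(ordered, ordered[1:]):
            if lo_b <= hi_a:
                raise ContractError("windows must not overlap")
        object.__setattr__(self, "windows", pairs)

    def descending(self) -> tuple[tuple[float, float], ...]:
        """Windows ordered high-wavenumber first (spectroscopy reading order)."""
        return tuple(sorted(self.windows, key=lambda w: -w[1]))


#: The two discriminative ranges used throughout: the C-H/O-H stretch region
#: and the fingerprint region, skipping the uninformative 2749-1800 gap.
DEFAULT_WINDOWS = SpectralWindows([(2749.0, 3751.0), (599.0, 1800.0)])


def _shared_grid(spectra: Sequence[Spectrum]) -> WavenumberGrid:
    if not spectra:
        raise ContractError("empty spectrum set")
    grid = spectra[0].grid
    for s in spectra[1:]:
        if s.grid != grid:
            raise ContractError(
                "spectra are on mixed grids; resample onto a common grid first"
            )
    return grid


def write_spectra_table(
    spectra: Sequence[Spectrum], path: str | Path, sep: str = ","
) -> Path:
    """Write spectra as a delimited table, wavenumber first column.

    All spectra must share one grid. Round-trips with
    :func:`read_spectra_table` to 1e-9.
    """
    grid = _shared_grid(spectra)
    frame = pd.DataFrame({"wavenumber": grid.values})
    for s in spectra:
        frame[s.meta.sample_id] = s.absorbance
    path = Path(path)
    frame.to_csv(path, sep=sep, index=False, float_format="%.10g")
    return path


def write_metadata_table(spectra: Sequence[Spectrum], path: str | Path, sep: str = ",") -> Path:
    rows = [
        {
            "sample_id": s.meta.sample_id,
            "species": s.meta.species,
            "prep_state": s.meta.prep_state,
            "segment": s.meta.segment,
            "replicate": s.meta.replicate,
            "pot_type": s.meta.pot_type,
        }
        for s in spectra
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
    return path


def read_metadata_table(path: str | Path, sep: str = ",") -> dict[str, SampleMeta]:
    frame = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "species": str})
    metas: dict[str, SampleMeta] = {}
    for row in frame.itertuples(index=False):
        metas[str(row.sample_id)] = SampleMeta(
            sample_id=str(row.sample_id),
            species=str(row.species),
            prep_state=str(row.prep_state),
            segment=str(row.segment),
            replicate=int(row.replicate),
            pot_type=str(row.pot_type),
        )
    return metas


def read_spectra_table(
    path: str | Path,
    sep: str = ",",
    metadata: dict[str, SampleMeta] | None = None,
    default_species: str = "unknown",
) -> list[Spectrum]:
    """Read a delimited spectra table into a list of spectra on one grid.

    First column is the wavenumber axis; each remaining column is one sample,
    its header the sample id. Metadata can be supplied from a companion table
    (see :func:`read_metadata_table`); otherwise minimal metadata is built
    from the column header.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=sep)
    if frame.shape[1] < 2:
        raise SpectraFormatError(f"{path}: need wavenumber column plus >=1 sample column")
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise SpectraParseError(
                f"{path}: non-numeric value in column {col!r}, row {row}"
            )
        frame[col] = coerced
    wn = frame.iloc[:, 0].to_numpy(dtype=float)
    diffs = np.diff(wn)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise SpectraFormatError(f"{path}: wavenumber column is not strictly monotonic")
    grid = WavenumberGrid(wn)
    ascending = wn[1] > wn[0]
    spectra = []
    for col in frame.columns[1:]:
        values = frame[col].to_numpy(dtype=float)
        if not ascending:
            values = values[::-1]
        sid = str(col)
        meta = (metadata or {}).get(sid) or SampleMeta(sample_id=sid, species=default_species)
        spectra.append(Spectrum(grid, values, meta))
    return spectra


def resample(spectrum: Spectrum, target: WavenumberGrid) -> Spectrum:
    """Linearly interpolate a spectrum onto a target grid.

    The target must lie within the span of the source grid; extrapolation is
    refused because absorbance outside the recorded range is unknown.
    """
    lo, hi = spectrum.grid.span
    tlo, thi = target.span
    if tlo < lo - 1e-12 or thi > hi + 1e-12:
        raise ExtrapolationError(
            f"target span ({tlo}, {thi}) exceeds source span ({lo}, {hi})"
        )
    values = np.interp(target.values, spectrum.grid.values, spectrum.absorbance)
    return Spectrum(target, values, spectrum.meta)


def extract_windows(
    spectrum: Spectrum, windows: SpectralWindows
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate the absorbance values falling inside each window.

    Windows are processed in descending-wavenumber order (high-frequency
    region first, as spectra are conventionally read); within a window the
    points keep the internal ascending order. Bounds are inclusive. Returns
    the feature vector and the retained wavenumbers, aligned elementwise.
    """
    wn = spectrum.grid.values
    parts_y: list[np.ndarray] = []
    parts_w: list[np.ndarray] = []
    for lo, hi in windows.descending():
        mask = (wn >= lo) & (wn <= hi)
        if mask.any():
            parts_y.append(spectrum.absorbance[mask])
            parts_w.append(wn[mask])
    if not parts_y:
        raise EmptySelectionError(
            f"no grid point falls inside any window {windows.windows}"
        )
    return np.concatenate(parts_y), np.concatenate(parts_w)
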