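"""Spectral preprocessing operators and their composition.

Three operators are provided, the standard pre-treatments for ATR absorbance
spectra ahead of clustering or calibration:

``first_derivative``
    Savitzky-Golay smoothed first derivative with respect to wavenumber.
    Emphasizes steep peak edges and removes constant/slow baselines.
``vector_normalize``
    subtract the mean intensity, then divide by the Euclidean norm of the
    centered spectrum; removes sample-thickness and crystal-contact scaling.
``offset_correct``
    shift so the minimum absorbance is exactly zero.

:func:`apply_pipeline` composes an ordered subset of these and then extracts
the configured spectral windows, producing the sample x feature matrix used
downstream. Normalization runs over the full recorded range and windowing
happens last, so the window choice does not alter the normalization
(``window_first=True`` flips this for sensitivity analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .errors import ContractError, DegenerateSpectrumError
from .spectra import DEFAULT_WINDOWS, SpectralWindows, Spectrum, extract_windows

__all__ = [
    "PreprocessSpec",
    "first_derivative",
    "vector_normalize",
    "offset_correct",
    "apply_pipeline",
    "STEP_NAMES",
]

STEP_NAMES = ("first_derivative", "vector_normalize", "offset_correct")


@dataclass(frozen=True)
class PreprocessSpec:
    """Ordered preprocessing steps plus the windows applied afterwards.

    ``steps=()`` means raw spectra (windowing only). The default spec —
    first derivative then vector normalization over the stretch and
    fingerprint windows — is the treatment applied before every cluster
    analysis here.
    """

    steps: tuple[str, ...] = ("first_derivative", "vector_normalize")
    derivative_window: int = 9
    derivative_polyorder: int = 2
    windows: SpectralWindows = field(default_factory=lambda: DEFAULT_WINDOWS)
    window_first: bool = False

    def __post_init__(self) -> None:
        for step in self.steps:
            if step not in STEP_NAMES:
                raise ContractError(f"unknown step {step!r}; valid: {STEP_NAMES}")
        if self.derivative_window % 2 == 0:
            raise ContractError("derivative_window must be odd")
        if self.derivative_window <= self.derivative_polyorder:
            raise ContractError("derivative_window must exceed derivative_polyorder")

    def describe(self) -> dict:
        return {
            "steps": list(self.steps),
            "derivative_window": self.derivative_window,
            "derivative_polyorder": self.derivative_polyorder,
            "windows": [list(w) for w in self.windows.windows],
            "window_first": self.window_first,
        }

    @classmethod
    def raw(cls, windows: SpectralWindows | None = None) -> "PreprocessSpec":
        return cls(steps=(), windows=windows or DEFAULT_WINDOWS)


def first_derivative(spectrum: Spectrum, window: int = 9, polyorder: int = 2) -> Spectrum:
    """Savitzky-Golay first derivative, in absorbance per cm^-1.

    A polynomial of ``polyorder`` is fit over a sliding ``window`` of points
    and differentiated analytically; edges are handled by fitting the edge
    window's polynomial rather than padding, so no artificial edge features
    appear. Requires a uniform grid.
    """
    if window % 2 == 0 or window <= polyorder:
        raise ContractError("window must be odd and exceed polyorder")
    if len(spectrum.grid) < window:
        raise ContractError(
            f"spectrum has {len(spectrum.grid)} points, fewer than window {window}"
        )
    if not spectrum.grid.is_uniform():
        raise ContractError("first_derivative requires a uniform wavenumber grid")
    deriv = savgol_filter(
        spectrum.absorbance,
        window_length=window,
        polyorder=polyorder,
        deriv=1,
        delta=spectrum.grid.spacing,
        mode="interp",
    )
    return spectrum.with_absorbance(deriv)


def vector_normalize(spectrum: Spectrum) -> Spectrum:
    """Center at zero mean, then scale to unit Euclidean norm.

    The average intensity is subtracted from the spectrum, the sum of the
    squared intensities of the centered spectrum is computed, and the
    spectrum is divided by its square root. Constant spectra have zero norm
    after centering and are rejected.
    """
    centered = spectrum.absorbance - spectrum.absorbance.mean()
    norm = float(np.sqrt(np.sum(centered**2)))
    if norm == 0.0:
        raise DegenerateSpectrumError(
            f"{spectrum.meta.sample_id}: constant spectrum cannot be vector-normalized"
        )
    return spectrum.with_absorbance(centered / norm)


def offset_correct(spectrum: Spectrum) -> Spectrum:
    """Shift the spectrum so its minimum is exactly zero."""
    return spectrum.with_absorbance(spectrum.absorbance - spectrum.absorbance.min())


_OPERATORS = {
    "vector_normalize": lambda s, spec: vector_normalize(s),
    "offset_correct": lambda s, spec: offset_correct(s),
    "first_derivative": lambda s, spec: first_derivative(
        s, spec.derivative_window, spec.derivative_polyorder
    ),
}


def _transform_one(spectrum: Spectrum, spec: PreprocessSpec) -> Spectrum:
    for step in spec.steps:
        try:
            spectrum = _OPERATORS[step](spectrum, spec)
        except ContractError as err:
            raise type(err)(f"{spectrum.meta.sample_id}: {step}: {err}") from err
    return spectrum


def apply_pipeline(
    spectra: Sequence[Spectrum], spec: PreprocessSpec
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Transform a spectrum set into a feature matrix.

    Returns ``(X, wavenumbers, provenance)``: one row per input spectrum in
    input order, columns the retained wavenumbers, and a provenance record
    of the applied steps suitable for embedding in result files.
    """
    if not spectra:
        raise ContractError("empty spectrum set")
    grid = spectra[0].grid
    for s in spectra[1:]:
        if s.grid != grid:
            raise ContractError("spectra are on mixed grids; resample first")
    rows = []
    retained: np.ndarray | None = None
    for s in spectra:
        if spec.window_first:
            values, wn = extract_windows(s, spec.windows)
            sub = Spectrum(
                grid=type(s.grid)(wn), absorbance=values, meta=s.meta
            )
            transformed = _transform_one(sub, spec)
            vec, wn = transformed.absorbance, transformed.grid.values
        else:
            transformed = _transform_one(s, spec)
            vec, wn = extract_windows(transformed, spec.windows)
        if retained is None:
            retained = wn
        rows.append(vec)
    provenance = {"preprocess": spec.describe(), "n_samples": len(rows),
                  "n_features": int(retained.size)}
    return np.vstack(rows), retained, provenance
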