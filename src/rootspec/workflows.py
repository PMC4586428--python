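"""High-level experiment workflows.

These tie the simulator, preprocessing, clustering and quantification
modules into the two headline analyses: crop/weed pair discrimination from
ground-root spectra, and PLS quantification of the two-species mixture
series. Both are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cluster import cut_and_purity, pairwise_distances, ward_linkage
from .preprocess import PreprocessSpec, apply_pipeline
from .profiles import CROP_WEED_PAIRS, NoiseModel
from .quant import LoocvResult, loocv
from .simulate import design_2species, simulate_mixture_set, simulate_species_set
from .spectra import WavenumberGrid

__all__ = [
    "PairSeparation",
    "pair_discrimination",
    "two_species_quantification",
]


@dataclass(frozen=True)
class PairSeparation:
    """Separation results for crop/weed pairs clustered at k=2."""

    per_pair: dict[tuple[str, str], float]
    pooled_percent: float  # pooled over all leaves of all pairs
    n_samples: int


def pair_discrimination(
    seed: int,
    prep: str = "ground",
    n_replicates: int = 6,
    pairs: tuple[tuple[str, str], ...] = CROP_WEED_PAIRS,
    grid: WavenumberGrid | None = None,
    spec: PreprocessSpec | None = None,
) -> PairSeparation:
    """Cluster each crop/weed pair and score species separation at k=2.

    For every pair, ``n_replicates`` spectra per species are simulated in
    the given preparation mode with its default noise model, preprocessed
    (default: first derivative + vector normalization over the stretch and
    fingerprint windows), Ward-clustered and cut into two clusters. The
    pooled percentage counts species-pure assignments over all leaves of
    all pairs.
    """
    spec = spec or PreprocessSpec()
    noise = NoiseModel.ground(seed) if prep == "ground" else NoiseModel.dried(seed)
    segments = ("none",) if prep == "ground" else ("basis",)
    per_pair: dict[tuple[str, str], float] = {}
    good = total = 0
    for pair in pairs:
        spectra = simulate_species_set(
            list(pair), n_replicates, prep=prep, noise=noise, grid=grid,
            segments=segments,
        )
        X, _, _ = apply_pipeline(spectra, spec)
        tree = ward_linkage(pairwise_distances(X), [s.meta.sample_id for s in spectra])
        labels = [s.meta.species for s in spectra]
        sep, _ = cut_and_purity(tree, 2, labels)
        per_pair[pair] = sep
        good += sep / 100.0 * len(labels)
        total += len(labels)
    return PairSeparation(
        per_pair=per_pair, pooled_percent=100.0 * good / total, n_samples=total
    )


def two_species_quantification(
    seed: int,
    step_percent: float = 5.0,
    n_replicates: int = 3,
    max_components: int = 10,
    grid: WavenumberGrid | None = None,
    spec: PreprocessSpec | None = None,
) -> tuple[LoocvResult, "np.ndarray"]:
    """Calibrate and leave-one-out-validate the two-species mixture model.

    Simulates the 5%-step maize/wild-oat dilution series (21 compositions by
    default) with ``n_replicates`` replicate spectra per mixture under the
    dried-material noise model, preprocesses, and runs leave-one-out
    cross-validation with component-count selection. Returns the LOOCV
    result and the true composition matrix in percent.
    """
    spec = spec or PreprocessSpec()
    design = design_2species(step_percent)
    spectra, Y = simulate_mixture_set(
        design, n_replicates, noise=NoiseModel.dried(seed), grid=grid
    )
    X, _, _ = apply_pipeline(spectra, spec)
    result = loocv(X, Y.to_numpy(), max_components, species=list(Y.columns))
    return result, Y.to_numpy()
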