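"""PLS calibration of species mass fractions from mixture spectra.

Mixture composition is regressed on preprocessed spectra with partial least
squares (PLS, NIPALS with mean centering and no variance scaling — spectra
entering the model are already vector-normalized). All species are fitted
jointly in one multivariate model, which preserves the closure of the
response: when calibration compositions sum to 100%, so do the predictions,
and for a two-species model the per-species errors mirror each other (equal
RMSE, opposite bias).

Model quality is summarized with the chemometric metric suite:

* RMSEE — root mean square error of estimation (calibration residuals);
* RMSECV — of cross-validation (leave-one-out held-out residuals);
* RMSEP — of prediction (external test set);
* bias — mean signed error;
* RPD — residual predictive deviation, SD(reference) / RMSE, classified as
  insufficient (<= 3), sufficient (> 3), good (> 5) or excellent (> 10);
* R^2 and the Pearson correlation r.

RMSE uses the plain 1/n mean; the reference SD entering RPD uses the n-1
sample variance.

Predictions are reported as-is, not clipped to [0, 100] nor renormalized to
the simplex — over- and under-estimation at the range ends is diagnostic
information (``clip=True``/``renormalize=True`` opt in).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from .errors import ContractError
from .preprocess import PreprocessSpec, apply_pipeline
from .spectra import Spectrum

__all__ = [
    "PLSModel",
    "QuantMetrics",
    "fit_pls",
    "predict",
    "loocv",
    "compute_metrics",
    "metrics_table",
    "optimize_model",
    "external_validation",
    "rpd_class",
]

RPD_THRESHOLDS = ((10.0, "excellent"), (5.0, "good"), (3.0, "sufficient"))


def rpd_class(rpd: float) -> str:
    """Classify a residual predictive deviation value.

    > 3 sufficient, > 5 good, > 10 excellent; at or below 3 the model is
    insufficient for quantitative prediction.
    """
    for threshold, name in RPD_THRESHOLDS:
        if rpd > threshold:
            return name
    return "insufficient"


@dataclass(frozen=True)
class PLSModel:
    """Fitted multivariate PLS calibration.

    Prediction is affine: ``y_hat = y_center + (x - x_center) @ coef``.
    """

    n_components: int
    species: tuple[str, ...]
    x_center: np.ndarray
    y_center: np.ndarray
    coef: np.ndarray  # (n_features, n_species)
    preprocess: PreprocessSpec | None = None
    wavenumbers: np.ndarray | None = None

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "n_components": self.n_components,
            "species": list(self.species),
            "x_center": self.x_center.tolist(),
            "y_center": self.y_center.tolist(),
            "coef": self.coef.tolist(),
            "preprocess": self.preprocess.describe() if self.preprocess else None,
            "wavenumbers": self.wavenumbers.tolist() if self.wavenumbers is not None else None,
        }
        path = Path(path)
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PLSModel":
        data = json.loads(Path(path).read_text())
        return cls(
            n_components=data["n_components"],
            species=tuple(data["species"]),
            x_center=np.asarray(data["x_center"]),
            y_center=np.asarray(data["y_center"]),
            coef=np.asarray(data["coef"]),
            preprocess=None,
            wavenumbers=np.asarray(data["wavenumbers"]) if data["wavenumbers"] else None,
        )


def _validate_xy(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ContractError("X and Y must be 2-D with aligned rows")
    return X, Y


def fit_pls(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    species: Sequence[str] | None = None,
    preprocess: PreprocessSpec | None = None,
    wavenumbers: np.ndarray | None = None,
) -> PLSModel:
    """Fit a centered multivariate PLS model of composition (percent) on spectra."""
    X, Y = _validate_xy(X, Y)
    n, p = X.shape
    max_rank = min(n - 1, p)
    if not 1 <= n_components <= max_rank:
        raise ContractError(
            f"n_components = {n_components} outside [1, min(n-1, p) = {max_rank}]"
        )
    pls = PLSRegression(n_components=n_components, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # y residual may be constant at high ranks
        pls.fit(X, Y)
    names = tuple(species) if species is not None else tuple(
        f"component{i}" for i in range(Y.shape[1])
    )
    # centered PLS predicts the calibration mean response at the mean spectrum
    return PLSModel(
        n_components=n_components,
        species=names,
        x_center=X.mean(axis=0),
        y_center=Y.mean(axis=0),
        coef=pls.coef_.T.copy(),
        preprocess=preprocess,
        wavenumbers=None if wavenumbers is None else np.asarray(wavenumbers),
    )


def predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Predicted compositions in percent, unclipped."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.x_center.size:
        raise ContractError(
            f"feature count {X.shape[1]} does not match model ({model.x_center.size})"
        )
    return model.y_center + (X - model.x_center) @ model.coef


@dataclass(frozen=True)
class QuantMetrics:
    """Error metrics for one species in one validation context."""

    context: str  # calibration | cross_validation | prediction
    n: int
    r2: float
    rmse: float
    bias: float
    rpd: float
    rpd_class: str
    r: float
    unstable: bool = False  # fewer than 3 samples: r and line ill-determined

    @property
    def rmse_name(self) -> str:
        return {"calibration": "RMSEE", "cross_validation": "RMSECV",
                "prediction": "RMSEP"}[self.context]

    def to_dict(self) -> dict:
        return {
            "context": self.context, "n": self.n, "r2": self.r2,
            self.rmse_name: self.rmse, "bias": self.bias,
            "rpd": self.rpd, "rpd_class": self.rpd_class, "r": self.r,
        }


def compute_metrics(
    true: np.ndarray, predicted: np.ndarray, context: str = "prediction"
) -> QuantMetrics:
    """Metric suite for one species' true vs. predicted percent values."""
    if context not in ("calibration", "cross_validation", "prediction"):
        raise ContractError(f"unknown context {context!r}")
    y = np.asarray(true, dtype=float).ravel()
    yhat = np.asarray(predicted, dtype=float).ravel()
    if y.size == 0 or y.size != yhat.size:
        raise ContractError("true and predicted must be non-empty and aligned")
    err = yhat - y
    rmse = float(np.sqrt(np.mean(err**2)))
    bias = float(np.mean(err))
    sd = float(np.std(y, ddof=1)) if y.size > 1 else 0.0
    if sd == 0.0:
        raise ContractError("SD of reference values is zero; RPD undefined")
    rpd = sd / rmse if rmse > 0 else float("inf")
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(err**2)) / sst
    if y.size >= 2 and np.std(yhat) > 0:
        r = float(stats.pearsonr(y, yhat)[0])
    else:
        r = float("nan")
    return QuantMetrics(
        context=context, n=int(y.size), r2=r2, rmse=rmse, bias=bias,
        rpd=rpd, rpd_class=rpd_class(rpd), r=r, unstable=y.size < 3,
    )


def metrics_table(
    true: np.ndarray,
    predicted: np.ndarray,
    species: Sequence[str],
    context: str,
) -> dict[str, QuantMetrics]:
    """Per-species metrics for aligned (n x k) true/predicted matrices."""
    true = np.atleast_2d(np.asarray(true, dtype=float))
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float))
    return {
        sp: compute_metrics(true[:, j], predicted[:, j], context)
        for j, sp in enumerate(species)
    }


@dataclass(frozen=True)
class LoocvResult:
    """Leave-one-out cross-validation over a grid of component counts."""

    table: pd.DataFrame  # index n_components, columns rmsecv_<sp>, rmsecv_mean
    selected: int
    predictions: np.ndarray  # LOO predictions at the selected count
    metrics: dict[str, QuantMetrics]  # at the selected count


def _loo_predictions(X: np.ndarray, Y: np.ndarray, n_components: int) -> np.ndarray:
    n = X.shape[0]
    out = np.empty_like(Y)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = fit_pls(X[mask], Y[mask], n_components)
        out[i] = predict(model, X[i])
    return out


def loocv(
    X: np.ndarray,
    Y: np.ndarray,
    max_components: int,
    species: Sequence[str] | None = None,
) -> LoocvResult:
    """Leave-one-out cross-validation, selecting the component count.

    Every sample is held out once; the model is refit on the remainder and
    the held-out sample predicted. The selected component count minimizes
    the mean RMSECV over species, ties resolved toward the smaller (more
    parsimonious) model. An infeasible ``max_components`` is reduced to the
    largest count every fold supports, with a warning.
    """
    X, Y = _validate_xy(X, Y)
    n, p = X.shape
    if n < 3:
        raise ContractError("leave-one-out cross-validation needs at least 3 samples")
    names = tuple(species) if species is not None else tuple(
        f"component{i}" for i in range(Y.shape[1])
    )
    feasible = min(n - 2, p)  # each fold trains on n-1 rows
    if max_components > feasible:
        warnings.warn(
            f"max_components reduced from {max_components} to {feasible} "
            f"(n = {n} samples, {p} features)", stacklevel=2,
        )
        max_components = feasible
    rows = []
    preds_by_c = {}
    for c in range(1, max_components + 1):
        try:
            preds = _loo_predictions(X, Y, c)
        except (np.linalg.LinAlgError, ValueError):
            preds = np.full_like(Y, np.nan)  # rank exhausted in some fold
        preds_by_c[c] = preds
        row = {"n_components": c}
        if np.all(np.isfinite(preds)):
            for j, sp in enumerate(names):
                row[f"rmsecv_{sp}"] = float(np.sqrt(np.mean((preds[:, j] - Y[:, j]) ** 2)))
            row["rmsecv_mean"] = float(
                np.mean([row[f"rmsecv_{sp}"] for sp in names])
            )
        else:
            # count exceeds the effective rank of some training fold
            for sp in names:
                row[f"rmsecv_{sp}"] = float("inf")
            row["rmsecv_mean"] = float("inf")
        rows.append(row)
    table = pd.DataFrame(rows).set_index("n_components")
    selected = int(table["rmsecv_mean"].idxmin())  # idxmin takes first = fewest
    preds = preds_by_c[selected]
    metrics = metrics_table(Y, preds, names, "cross_validation")
    return LoocvResult(table=table, selected=selected, predictions=preds, metrics=metrics)


@dataclass(frozen=True)
class OptimizationResult:
    best_spec: PreprocessSpec
    best_spec_index: int
    best_n_components: int
    leaderboard: pd.DataFrame  # spec_index, n_components, rmsecv_mean


def optimize_model(
    spectra: Sequence[Spectrum],
    Y: np.ndarray,
    candidate_specs: Sequence[PreprocessSpec],
    max_components: int,
    species: Sequence[str] | None = None,
) -> OptimizationResult:
    """Grid search over preprocessing specs and component counts.

    Every (spec, component count) pair is scored by leave-one-out RMSECV
    averaged over species; the leaderboard is sorted by (RMSECV ascending,
    spec index ascending) so the result is deterministic.
    """
    if not candidate_specs:
        raise ContractError("at least one candidate preprocessing spec required")
    entries = []
    errors = []
    for idx, spec in enumerate(candidate_specs):
        try:
            X, _, _ = apply_pipeline(spectra, spec)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = loocv(X, Y, max_components, species)
        except Exception as err:  # noqa: BLE001 - aggregate per-candidate failures
            errors.append(f"spec {idx}: {err}")
            continue
        for c, row in result.table.iterrows():
            entries.append(
                {"spec_index": idx, "n_components": int(c),
                 "rmsecv_mean": float(row["rmsecv_mean"])}
            )
    if not entries:
        raise ContractError("all candidate specs failed: " + "; ".join(errors))
    leaderboard = pd.DataFrame(entries).sort_values(
        ["rmsecv_mean", "spec_index", "n_components"], kind="stable"
    ).reset_index(drop=True)
    top = leaderboard.iloc[0]
    return OptimizationResult(
        best_spec=candidate_specs[int(top.spec_index)],
        best_spec_index=int(top.spec_index),
        best_n_components=int(top.n_components),
        leaderboard=leaderboard,
    )


@dataclass(frozen=True)
class ValidationReport:
    """External test-set validation: metrics plus predicted-vs-true lines."""

    metrics: dict[str, QuantMetrics]
    lines: dict[str, tuple[float, float]]  # species -> (slope, intercept)
    predictions: np.ndarray

    def to_dict(self) -> dict:
        return {
            "metrics": {sp: m.to_dict() for sp, m in self.metrics.items()},
            "lines": {sp: {"slope": s, "intercept": i} for sp, (s, i) in self.lines.items()},
        }


def external_validation(
    model: PLSModel, X_test: np.ndarray, Y_test: np.ndarray
) -> ValidationReport:
    """Validate a calibration on an independent test set.

    Reports RMSEP-context metrics per species and the least-squares line of
    predicted on true composition (slope 1, intercept 0 is the ideal). The
    caller is responsible for test samples being disjoint from calibration.
    With fewer than 3 test samples the correlation and line are flagged
    unstable but still computed.
    """
    X_test, Y_test = _validate_xy(X_test, Y_test)
    preds = predict(model, X_test)
    metrics = metrics_table(Y_test, preds, model.species, "prediction")
    lines = {}
    for j, sp in enumerate(model.species):
        y, yhat = Y_test[:, j], preds[:, j]
        if np.std(y) > 0 and y.size >= 2:
            slope, intercept = np.polyfit(y, yhat, 1)
        else:
            slope, intercept = float("nan"), float("nan")
        lines[sp] = (float(slope), float(intercept))
    return ValidationReport(metrics=metrics, lines=lines, predictions=preds)
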