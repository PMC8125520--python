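"""Fold management and cross-validated scoring.

All engines (GPR, PLSR, vegetation indices) share one FoldAssignment so
their calibration/validation splits are identical: the samples are randomly
and evenly divided into k subsets; each model is calibrated on k-1 subsets
and validated on the held-out one; the k per-fold R² and RMSE values are
averaged.

R² is the squared Pearson correlation of measured vs predicted (identical
to the R² of the least-squares line through the scatter); RMSE is computed
on raw residuals about the 1:1 relationship. The 95%-confidence linear fit
of predicted on measured is returned alongside for scatter annotation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import gpr, plsr
from .spectra import SpectralDataset, transform_dataset


@dataclass(frozen=True)
class FoldAssignment:
    """Per-sample fold labels in 1..k; sizes differ by at most one."""

    labels: np.ndarray
    k: int
    seed: int

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        counts = np.bincount(labels, minlength=self.k + 1)[1:]
        if counts.max() - counts.min() > 1:
            raise ValueError("fold sizes differ by more than one")
        if labels.min() < 1 or labels.max() > self.k:
            raise ValueError("labels must lie in 1..k")

    @property
    def n(self) -> int:
        return self.labels.size

    def split(self, g: int):
        """(train_mask, test_mask) for held-out group g."""
        te = self.labels == g
        return ~te, te

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"k": self.k, "seed": self.seed,
                       "labels": self.labels.tolist()}, fh)

    @classmethod
    def from_json(cls, path) -> "FoldAssignment":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.array(d["labels"]), d["k"], d["seed"])


def make_folds(n: int, k: int, seed: int) -> FoldAssignment:
    """Randomly, evenly divide n samples into k folds (sizes n//k or n//k+1)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    start = 0
    for g, size in enumerate(sizes, start=1):
        labels[perm[start:start + size]] = g
        start += size
    return FoldAssignment(labels, k, seed)


@dataclass(frozen=True)
class ScoreResult:
    r2: float
    rmse: float
    slope: float
    intercept: float
    slope_ci: tuple
    intercept_ci: tuple


def score_predictions(measured, predicted, confidence: float = 0.95) -> ScoreResult:
    """R² (squared Pearson r), raw-residual RMSE, and the annotated linear fit."""
    measured = np.asarray(measured, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if measured.size != predicted.size:
        raise ValueError("length mismatch")
    if measured.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(measured) == 0:
        raise ValueError("measured values are constant")

    rmse = float(np.sqrt(np.mean((predicted - measured) ** 2)))
    if np.ptp(predicted) == 0:
        return ScoreResult(0.0, rmse, 0.0, float(predicted[0]),
                           (0.0, 0.0), (float(predicted[0]),) * 2)
    fit = stats.linregress(measured, predicted)
    tcrit = stats.t.ppf(0.5 + confidence / 2, measured.size - 2)
    return ScoreResult(
        r2=float(fit.rvalue**2),
        rmse=rmse,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_ci=(float(fit.slope - tcrit * fit.stderr),
                  float(fit.slope + tcrit * fit.stderr)),
        intercept_ci=(float(fit.intercept - tcrit * fit.intercept_stderr),
                      float(fit.intercept + tcrit * fit.intercept_stderr)),
    )


@dataclass(frozen=True)
class CVResult:
    cal_r2: np.ndarray
    val_r2: np.ndarray
    cal_rmse: np.ndarray
    val_rmse: np.ndarray
    measured: np.ndarray       # pooled held-out truths, one entry per sample
    predicted: np.ndarray      # pooled held-out predictions
    predicted_sd: np.ndarray | None = None   # GPR only

    @property
    def mean_cal_r2(self) -> float:
        return float(np.mean(self.cal_r2))

    @property
    def mean_val_r2(self) -> float:
        return float(np.mean(self.val_r2))

    @property
    def mean_cal_rmse(self) -> float:
        return float(np.mean(self.cal_rmse))

    @property
    def mean_val_rmse(self) -> float:
        return float(np.mean(self.val_rmse))

    def summary(self) -> dict:
        return {
            "cal_r2": self.mean_cal_r2, "val_r2": self.mean_val_r2,
            "cal_rmse": self.mean_cal_rmse, "val_rmse": self.mean_val_rmse,
        }


@dataclass(frozen=True)
class ModelSpec:
    """Names an engine, the wavelengths it uses, and the spectral transform."""

    engine: str                      # "gpr" or "plsr"
    wavelengths: tuple
    transform: str = "log1r"         # "log1r" or "reflectance"
    n_components: int | str = "auto"  # PLSR: fixed count or PRESS/SS rule
    n_restarts: int = 4              # GPR restarts
    seed: int = 0


class _LabelFolds:
    """Bare fold labels, for leave-one-group-out over a training block."""

    def __init__(self, labels):
        self.labels = np.asarray(labels, dtype=int)


def _fit_predict(spec: ModelSpec, Xtr, ytr, Xte, fold_seed: int,
                 inner_labels=None):
    """Fit one engine on the training block; predict train and test."""
    if spec.engine == "plsr":
        if spec.n_components == "auto":
            if inner_labels is None:
                inner = make_folds(len(ytr), min(10, len(ytr)), fold_seed)
            else:
                inner = _LabelFolds(inner_labels)
            a = plsr.select_components(Xtr, ytr, inner)
        else:
            a = int(spec.n_components)
        m = plsr.fit_plsr(Xtr, ytr, a)
        return plsr.predict_plsr(m, Xtr), plsr.predict_plsr(m, Xte), None
    if spec.engine == "gpr":
        m = gpr.fit_gpr(Xtr, ytr, n_restarts=spec.n_restarts, seed=fold_seed)
        pr_tr = gpr.predict_gpr(m, Xtr)
        pr_te = gpr.predict_gpr(m, Xte)
        return pr_tr.mean, pr_te.mean, pr_te.sd
    raise ValueError(f"unknown engine {spec.engine!r}")


def cross_validate(ds: SpectralDataset, spec: ModelSpec,
                   folds: FoldAssignment) -> CVResult:
    """k-fold calibration/validation of one model specification."""
    if folds.n != len(ds):
        raise ValueError("fold assignment does not match dataset size")
    work = transform_dataset(ds, spec.transform)
    X = work.design_matrix(spec.wavelengths)
    y = work.contents("anth")

    cal_r2, val_r2, cal_rmse, val_rmse = [], [], [], []
    pred = np.full(folds.n, np.nan)
    pred_sd = np.full(folds.n, np.nan)
    has_sd = False
    for g in range(1, folds.k + 1):
        tr, te = folds.split(g)
        try:
            yhat_tr, yhat_te, sd_te = _fit_predict(
                spec, X[tr], y[tr], X[te], spec.seed * 1000 + g,
                inner_labels=folds.labels[tr])
        except Exception as exc:
            raise RuntimeError(f"engine failure in fold {g}: {exc}") from exc
        cal = score_predictions(y[tr], yhat_tr)
        val = score_predictions(y[te], yhat_te)
        cal_r2.append(cal.r2); val_r2.append(val.r2)
        cal_rmse.append(cal.rmse); val_rmse.append(val.rmse)
        pred[te] = yhat_te
        if sd_te is not None:
            pred_sd[te] = sd_te
            has_sd = True
    return CVResult(
        np.array(cal_r2), np.array(val_r2),
        np.array(cal_rmse), np.array(val_rmse),
        y.copy(), pred, pred_sd if has_sd else None)


def correlation_spectrum(ds: SpectralDataset, transform: str = "log1r",
                         pigment: str = "anth"):
    """Per-wavelength Pearson r between spectral values and pigment content.

    Returns (wavelengths, r, constant_flags); constant channels get r = 0
    with their flag set.
    """
    work = transform_dataset(ds, transform)
    X = work.design_matrix()
    y = work.contents(pigment)
    if len(work) < 3:
        raise ValueError("need at least 3 samples")
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc**2, axis=0))
    sy = np.sqrt(np.sum(yc**2))
    constant = sx < 1e-300
    r = np.zeros(X.shape[1])
    ok = ~constant
    r[ok] = (xc[:, ok].T @ yc) / (sx[ok] * sy)
    return work.grid.wavelengths.copy(), r, constant


def absorbance_difference_feature(ds: SpectralDataset,
                                  green_nm: float = 550.0,
                                  red_edge_nm: float = 708.0) -> np.ndarray:
    """log10(1/R_green) - log10(1/R_red_edge) per sample.

    With chlorophyll the dominant absorber at the red edge and both pigments
    absorbing in the green, this difference estimates the anthocyanin
    absorption at the green wavelength.
    """
    if ds.representation != "reflectance":
        raise ValueError("feature is defined on reflectance data")
    R = ds.design_matrix([green_nm, red_edge_nm])
    if np.any(R <= 0):
        raise ValueError("non-positive reflectance")
    A = np.log10(1.0 / R)
    return A[:, 0] - A[:, 1]


def prediction_intervals(m: gpr.GPRModel, queries) -> tuple:
    """(posterior mean, posterior SD) per query, for error-bar plots."""
    pred = gpr.predict_gpr(m, queries)
    return pred.mean, pred.sd
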