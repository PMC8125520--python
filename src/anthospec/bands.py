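"""Wavelength selection.

Sequential backward band removal (SBBR): with the surviving wavelengths,
ten models are calibrated (one per held-out fold); each calibration records
a per-wavelength importance indicator — the ARD length scale sigma_m for
GPR (large sigma_m = unimportant) or |beta| for PLSR (large |beta| =
important) — and the within-fold importance ranking (rank 1 = most
important, ties averaged). Indicator and rank sums over the ten folds drive
the removal of the least important wavelength; the loop repeats until one
wavelength is left. Fold-averaged calibration/validation R²/RMSE are logged
at every iteration.

Final model wavelengths are picked by walking the removal order backward
from the last survivor, keeping wavelengths more than a minimum distance
(default 10 nm, the coarsest resolution a hyperspectral instrument should
offer) from every already-picked one.

The exhaustive two-wavelength search pairs one green-peak channel with one
red-edge channel and cross-validates a GPR model for every pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import gpr, plsr
from .evaluate import CVResult, FoldAssignment, ModelSpec, cross_validate, \
    score_predictions
from .spectra import SpectralDataset


class EngineFailure(RuntimeError):
    """Engine fit failed mid-elimination; the partial trace is attached."""

    def __init__(self, msg, trace):
        super().__init__(msg)
        self.trace = trace


@dataclass(frozen=True)
class ImportanceRecord:
    """Fold-summed importance for the surviving wavelengths of one iteration."""

    wavelengths: np.ndarray
    indicator_sum: np.ndarray   # sum over folds of sigma_m (GPR) or |beta| (PLSR)
    rank_sum: np.ndarray        # sum over folds of within-fold ranks (1 = best)


@dataclass(frozen=True)
class RemovalStep:
    iteration: int
    removed_nm: float
    surviving_nm: tuple         # after this removal
    cal_r2: float
    val_r2: float
    cal_rmse: float
    val_rmse: float
    importance: ImportanceRecord


@dataclass(frozen=True)
class RemovalTrace:
    steps: tuple
    engine: str
    strategy: str

    def __len__(self):
        return len(self.steps)

    @property
    def final_wavelength(self) -> float:
        return self.steps[-1].surviving_nm[0]

    def removal_order(self) -> list:
        return [s.removed_nm for s in self.steps]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"iteration": s.iteration, "removed_nm": s.removed_nm,
             "n_surviving": len(s.surviving_nm),
             "cal_r2": s.cal_r2, "val_r2": s.val_r2,
             "cal_rmse": s.cal_rmse, "val_rmse": s.val_rmse,
             "surviving_nm": list(s.surviving_nm)}
            for s in self.steps
        ])


def _fold_fit(engine, X, y, tr, te, seed, warm=None, n_restarts=4,
              n_components=None):
    """One fold's calibration: returns (indicator, cal pred, val pred, hyper)."""
    if engine == "plsr":
        a = n_components
        if a is None:
            cap = np.linalg.matrix_rank(X[tr] - X[tr].mean(axis=0))
            a = int(min(2, cap))
        m = plsr.fit_plsr(X[tr], y[tr], max(a, 1))
        return (np.abs(m.beta), plsr.predict_plsr(m, X[tr]),
                plsr.predict_plsr(m, X[te]), None)
    if engine == "gpr":
        m = gpr.fit_gpr(X[tr], y[tr], init=warm, n_restarts=n_restarts,
                        seed=seed)
        return (m.hyper.length_scales.copy(),
                gpr.predict_gpr(m, X[tr]).mean,
                gpr.predict_gpr(m, X[te]).mean, m.hyper)
    raise ValueError(f"unknown engine {engine!r}")


def sbbr(ds: SpectralDataset, engine: str, strategy: str,
         folds: FoldAssignment, seed: int = 0, n_restarts: int = 2,
         plsr_components: int | None = None) -> RemovalTrace:
    """Sequential backward band removal down to a single wavelength.

    ``ds`` must already carry the representation to model (reflectance or
    log(1/R)); ``strategy`` is ``sum_indicator`` or ``sum_rankings``.
    GPR fits are warm-started per fold from the previous iteration's
    optimum (with fresh restarts) to cut runtime.
    """
    if strategy not in ("sum_indicator", "sum_rankings"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if len(ds.grid) < 2:
        raise ValueError("need at least 2 channels")
    if folds.n != len(ds):
        raise ValueError("fold assignment does not match dataset size")

    X_full = ds.spectra
    y = ds.contents("anth")
    surviving = list(range(len(ds.grid)))
    wl = ds.grid.wavelengths
    warm = {g: None for g in range(1, folds.k + 1)}
    steps = []
    iteration = 0
    while len(surviving) > 1:
        iteration += 1
        X = X_full[:, surviving]
        nch = len(surviving)
        ind_sum = np.zeros(nch)
        rank_sum = np.zeros(nch)
        cal_r2 = np.empty(folds.k); val_r2 = np.empty(folds.k)
        cal_rmse = np.empty(folds.k); val_rmse = np.empty(folds.k)
        for g in range(1, folds.k + 1):
            tr, te = folds.split(g)
            try:
                indicator, yhat_tr, yhat_te, hyper = _fold_fit(
                    engine, X, y, tr, te, seed * 1000 + g,
                    warm=warm[g], n_restarts=n_restarts,
                    n_components=plsr_components)
            except Exception as exc:
                raise EngineFailure(
                    f"{engine} fit failed at iteration {iteration}, fold {g}: {exc}",
                    RemovalTrace(tuple(steps), engine, strategy)) from exc
            ind_sum += indicator
            # rank 1 = most important: smallest sigma_m (GPR), largest |beta| (PLSR)
            key = indicator if engine == "gpr" else -indicator
            rank_sum += rankdata(key, method="average")
            cal = score_predictions(y[tr], yhat_tr)
            val = score_predictions(y[te], yhat_te)
            cal_r2[g - 1], val_r2[g - 1] = cal.r2, val.r2
            cal_rmse[g - 1], val_rmse[g - 1] = cal.rmse, val.rmse
            if hyper is not None:
                warm[g] = hyper

        if strategy == "sum_indicator":
            # least important: largest summed sigma_m, or smallest summed |beta|
            key = ind_sum if engine == "gpr" else -ind_sum
        else:
            key = rank_sum  # least important = worst (largest) summed rank
        worst = np.flatnonzero(np.isclose(key, key.max()))
        # ties: remove the longest wavelength first
        drop_pos = worst[np.argmax(wl[[surviving[i] for i in worst]])]

        fitted_wl = np.array([wl[i] for i in surviving])
        removed = surviving.pop(drop_pos)
        for g in warm:
            if warm[g] is not None:
                ls = np.delete(warm[g].length_scales, drop_pos)
                warm[g] = gpr.GPRHyper(warm[g].sigma_f, ls, warm[g].sigma_n)
        steps.append(RemovalStep(
            iteration=iteration,
            removed_nm=float(wl[removed]),
            surviving_nm=tuple(float(wl[i]) for i in surviving),
            cal_r2=float(cal_r2.mean()), val_r2=float(val_r2.mean()),
            cal_rmse=float(cal_rmse.mean()), val_rmse=float(val_rmse.mean()),
            importance=ImportanceRecord(fitted_wl, ind_sum.copy(),
                                        rank_sum.copy()),
        ))
    return RemovalTrace(tuple(steps), engine, strategy)


def pick_final_wavelengths(trace: RemovalTrace, min_distance: float = 10.0,
                           max_count: int | None = None) -> list:
    """Walk the removal order backward, keeping mutually distant wavelengths.

    Starts from the last survivor; a wavelength removed at an earlier
    iteration is added iff it lies more than ``min_distance`` nm from every
    wavelength already picked. Returned in pick order (survivor first).
    """
    if len(trace) == 0:
        raise ValueError("empty removal trace")
    if min_distance < 0:
        raise ValueError("min_distance must be >= 0")
    picked = [trace.final_wavelength]
    for step in reversed(trace.steps):
        if max_count is not None and len(picked) >= max_count:
            break
        w = step.removed_nm
        if all(abs(w - p) > min_distance for p in picked):
            picked.append(w)
    return picked


def two_wavelength_search(ds: SpectralDataset, range_a: tuple,
                          range_b: tuple, folds: FoldAssignment,
                          transform: str = "log1r", step_nm: float = 1.0,
                          n_restarts: int = 1, seed: int = 0) -> pd.DataFrame:
    """Cross-validate a two-channel GPR model for every (green, red-edge) pair.

    ``range_a`` and ``range_b`` are inclusive (lo, hi) nm intervals on the
    grid; ``step_nm`` coarsens the search lattice. Returns one row per pair
    with fold-averaged metrics.
    """
    wl = ds.grid.wavelengths

    def channels(lo, hi):
        sel = wl[(wl >= lo) & (wl <= hi)]
        if sel.size == 0:
            raise ValueError(f"range ({lo}, {hi}) nm is off the grid")
        keep = np.isclose((sel - sel[0]) % step_nm, 0) | np.isclose(
            (sel - sel[0]) % step_nm, step_nm)
        return sel[keep]

    if not (range_a[1] < range_b[0] or range_b[1] < range_a[0]):
        raise ValueError("search ranges must be disjoint")
    rows = []
    for la in channels(*range_a):
        for lb in channels(*range_b):
            spec = ModelSpec("gpr", (float(la), float(lb)),
                             transform=transform, n_restarts=n_restarts,
                             seed=seed)
            cv = cross_validate(ds, spec, folds)
            rows.append({"lambda_a": float(la), "lambda_b": float(lb),
                         **cv.summary()})
    return pd.DataFrame(rows)


def fraction_above(results: pd.DataFrame, threshold: float,
                   column: str = "val_r2") -> float:
    """Fraction of searched pairs whose score exceeds the threshold."""
    return float(np.mean(results[column].to_numpy() > threshold))
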