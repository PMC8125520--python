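"""Anthocyanin vegetation indices and their linear calibration.

Implemented indices (R_x = reflectance at x nm):

* red_green_1: R675 / R550
* red_green_2: sum(R, 600-699 nm) / sum(R, 500-599 nm) (inclusive bounds)
* ari:         1/R550 - 1/R700
* mari:        (1/R_l1 - 1/R_l2) * R_l3, with l1 in the green (530-570 nm),
               l2 near the red edge (690-710 nm), l3 in the NIR (760-780 nm);
               the bands can be optimized against measured content
* maci:        R780 / R550

The -1/R term near 705 nm in ARI/mARI cancels chlorophyll interference with
the green-region anthocyanin absorption. Index values are calibrated to
content by per-fold least-squares lines inside the shared 10-fold scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluate import CVResult, FoldAssignment, score_predictions
from .spectra import LeafSample, SpectralDataset, SpectralGrid

_DEFAULT_BANDS = {
    "red_green_1": {"red": 675.0, "green": 550.0},
    "red_green_2": {"red_range": (600.0, 699.0), "green_range": (500.0, 599.0)},
    "ari": {"green": 550.0, "red_edge": 700.0},
    "mari": {"green": 549.0, "red_edge": 699.0, "nir": 760.0},
    "maci": {"nir": 780.0, "green": 550.0},
}


@dataclass(frozen=True)
class IndexSpec:
    name: str
    bands: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in _DEFAULT_BANDS:
            raise ValueError(f"unknown index {self.name!r}")
        merged = {**_DEFAULT_BANDS[self.name], **self.bands}
        object.__setattr__(self, "bands", merged)
        for key, val in merged.items():
            if key.endswith("_range") and val[0] > val[1]:
                raise ValueError(f"interval bounds out of order for {key}: {val}")


def _channel(sample: LeafSample, grid: SpectralGrid, nm: float) -> float:
    v = float(sample.spectrum[grid.index_of(nm)])
    if v == 0:
        raise ValueError(f"zero reflectance at {nm:g} nm")
    return v


def _band_sum(sample: LeafSample, grid: SpectralGrid, lo: float, hi: float) -> float:
    mask = (grid.wavelengths >= lo) & (grid.wavelengths <= hi)
    if not mask.any():
        raise ValueError(f"range {lo:g}-{hi:g} nm is off the grid")
    return float(sample.spectrum[mask].sum())


def compute_index(sample: LeafSample, grid: SpectralGrid, spec: IndexSpec) -> float:
    """Evaluate one index on one reflectance spectrum."""
    b = spec.bands
    if spec.name == "red_green_1":
        return _channel(sample, grid, b["red"]) / _channel(sample, grid, b["green"])
    if spec.name == "red_green_2":
        return (_band_sum(sample, grid, *b["red_range"])
                / _band_sum(sample, grid, *b["green_range"]))
    if spec.name == "ari":
        return (1.0 / _channel(sample, grid, b["green"])
                - 1.0 / _channel(sample, grid, b["red_edge"]))
    if spec.name == "mari":
        return ((1.0 / _channel(sample, grid, b["green"])
                 - 1.0 / _channel(sample, grid, b["red_edge"]))
                * _channel(sample, grid, b["nir"]))
    if spec.name == "maci":
        return _channel(sample, grid, b["nir"]) / _channel(sample, grid, b["green"])
    raise AssertionError(spec.name)


def compute_index_dataset(ds: SpectralDataset, spec: IndexSpec) -> np.ndarray:
    if ds.representation != "reflectance":
        raise ValueError("indices are defined on reflectance spectra")
    return np.array([compute_index(s, ds.grid, spec) for s in ds.samples])


def optimize_mari_bands(ds: SpectralDataset, responses=None,
                        green_range=(530.0, 570.0),
                        red_edge_range=(690.0, 710.0),
                        nir_range=(760.0, 780.0)) -> tuple:
    """Band optimization for the modified anthocyanin reflectance index.

    The green band l1 maximizes |corr(1/R_l, content)| — 1/R is the index's
    own absorption proxy. With l1 fixed, (l2, l3) exhaustively maximize the
    R² of the least-squares line of the index against content. Deterministic;
    ties resolve to the shortest wavelength.
    """
    if ds.representation != "reflectance":
        raise ValueError("band optimization requires reflectance data")
    if len(ds) < 10:
        raise ValueError("need at least 10 samples")
    y = ds.contents("anth") if responses is None else np.asarray(responses, float)
    if np.ptp(y) == 0:
        raise ValueError("content vector is constant")
    wl = ds.grid.wavelengths
    R = ds.spectra

    def in_range(rng):
        idx = np.flatnonzero((wl >= rng[0]) & (wl <= rng[1]))
        if idx.size == 0:
            raise ValueError(f"range {rng} nm is off the grid")
        return idx

    green = in_range(green_range)
    inv = 1.0 / R[:, green]
    yc = y - y.mean()
    xc = inv - inv.mean(axis=0)
    denom = np.sqrt(np.sum(xc**2, axis=0)) * np.sqrt(np.sum(yc**2))
    corr = np.abs(xc.T @ yc) / np.where(denom > 0, denom, np.inf)
    l1 = float(wl[green[int(np.argmax(corr))]])

    inv_l1 = 1.0 / R[:, ds.grid.index_of(l1)]
    best = (-np.inf, None, None)
    for j2 in in_range(red_edge_range):
        diff = inv_l1 - 1.0 / R[:, j2]
        for j3 in in_range(nir_range):
            index = diff * R[:, j3]
            if np.ptp(index) == 0:
                continue
            r = np.corrcoef(index, y)[0, 1] ** 2
            if r > best[0] + 1e-15:
                best = (r, float(wl[j2]), float(wl[j3]))
    if best[1] is None:
        raise ValueError("no usable band pair found")
    return l1, best[1], best[2]


def calibrate_index(ds: SpectralDataset, spec: IndexSpec,
                    folds: FoldAssignment) -> tuple[CVResult, tuple]:
    """Per-fold linear calibration content ~ index; returns (CVResult,
    (slope, intercept) of the all-data line)."""
    x = compute_index_dataset(ds, spec)
    y = ds.contents("anth")
    if folds.n != len(ds):
        raise ValueError("fold assignment does not match dataset size")

    cal_r2, val_r2, cal_rmse, val_rmse = [], [], [], []
    pred = np.full(folds.n, np.nan)
    for g in range(1, folds.k + 1):
        tr, te = folds.split(g)
        slope, intercept = np.polyfit(x[tr], y[tr], 1)
        yhat_tr = intercept + slope * x[tr]
        yhat_te = intercept + slope * x[te]
        cal = score_predictions(y[tr], yhat_tr)
        val = score_predictions(y[te], yhat_te)
        cal_r2.append(cal.r2); val_r2.append(val.r2)
        cal_rmse.append(cal.rmse); val_rmse.append(val.rmse)
        pred[te] = yhat_te
    slope, intercept = np.polyfit(x, y, 1)
    cv = CVResult(np.array(cal_r2), np.array(val_r2),
                  np.array(cal_rmse), np.array(val_rmse), y.copy(), pred)
    return cv, (float(slope), float(intercept))
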