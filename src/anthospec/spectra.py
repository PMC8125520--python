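"""Spectral data model and I/O.

A dataset is a wide table: one row per leaf, pigment contents in nmol/cm²,
and per-wavelength reflectance (fraction in (0, 1]) on a uniform nm grid.
The absorbance proxy used throughout is log10(1/R).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Pigment content columns, in canonical order.
PIGMENT_COLUMNS = ("chl", "car", "anth")

#: Pigments that must be present for a sample to be usable downstream.
REQUIRED_PIGMENTS = ("chl", "anth")


class SpectraFormatError(ValueError):
    """Malformed table: missing/duplicate columns, unparsable headers."""


class GridError(ValueError):
    """Wavelength grid is not strictly increasing with a uniform step."""


class RepresentationError(ValueError):
    """Operation applied to the wrong representation (reflectance/absorbance)."""


@dataclass(frozen=True)
class SpectralGrid:
    """Uniform wavelength grid, channel centers in nm, inclusive endpoints."""

    wavelengths: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        if wl.ndim != 1 or wl.size < 1:
            raise GridError("grid must be a non-empty 1-D array of nm values")
        if wl.min() < 350 or wl.max() > 1100:
            raise GridError(
                f"wavelengths outside the supported 350-1100 nm window: "
                f"[{wl.min():g}, {wl.max():g}]"
            )
        if wl.size > 1:
            steps = np.diff(wl)
            if np.any(steps <= 0):
                raise GridError("wavelengths must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
                raise GridError("wavelength step is not uniform")

    @classmethod
    def from_range(cls, start: float, stop: float, step: float = 1.0) -> "SpectralGrid":
        n = int(round((stop - start) / step)) + 1
        return cls(start + step * np.arange(n))

    @property
    def step(self) -> float:
        wl = self.wavelengths
        return float(wl[1] - wl[0]) if wl.size > 1 else 1.0

    def __len__(self) -> int:
        return self.wavelengths.size

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpectralGrid):
            return NotImplemented
        return (
            self.wavelengths.shape == other.wavelengths.shape
            and bool(np.allclose(self.wavelengths, other.wavelengths, rtol=0, atol=1e-9))
        )

    def index_of(self, nm: float) -> int:
        """Index of the channel at ``nm``; raises if off-grid."""
        idx = np.flatnonzero(np.isclose(self.wavelengths, nm, rtol=0, atol=1e-6))
        if idx.size == 0:
            raise GridError(f"wavelength {nm:g} nm is not on the grid")
        return int(idx[0])

    def indices_of(self, nms) -> np.ndarray:
        return np.array([self.index_of(w) for w in nms], dtype=int)


@dataclass(frozen=True)
class PigmentProfile:
    """Per-leaf pigment contents in nmol/cm²; carotenoids may be unmeasured."""

    chlorophylls: float
    anthocyanins: float
    carotenoids: float | None = None

    def __post_init__(self):
        for name in ("chlorophylls", "anthocyanins"):
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                object.__setattr__(self, name, None)
                continue
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.carotenoids is not None:
            if math.isnan(self.carotenoids):
                object.__setattr__(self, "carotenoids", None)
            elif self.carotenoids < 0:
                raise ValueError(f"carotenoids must be >= 0, got {self.carotenoids}")

    def get(self, pigment: str):
        return {
            "chl": self.chlorophylls,
            "car": self.carotenoids,
            "anth": self.anthocyanins,
        }[pigment]

    @property
    def complete(self) -> bool:
        """True when every required content (chl, anth) is recorded."""
        return all(self.get(p) is not None for p in REQUIRED_PIGMENTS)


@dataclass(frozen=True)
class LeafSample:
    id: str
    profile: PigmentProfile
    spectrum: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "spectrum", np.asarray(self.spectrum, dtype=float))


@dataclass(frozen=True)
class SpectralDataset:
    """An ordered collection of leaf samples sharing one wavelength grid.

    ``representation`` is ``"reflectance"`` (values in (0, 1]) or
    ``"absorbance"`` (log10(1/R), values >= 0 for R <= 1).
    """

    grid: SpectralGrid
    samples: tuple[LeafSample, ...]
    representation: str = "reflectance"

    def __post_init__(self):
        if self.representation not in ("reflectance", "absorbance"):
            raise RepresentationError(
                f"unknown representation {self.representation!r}"
            )
        object.__setattr__(self, "samples", tuple(self.samples))
        n = len(self.grid)
        for s in self.samples:
            if s.spectrum.size != n:
                raise ValueError(
                    f"sample {s.id!r}: spectrum length {s.spectrum.size} != grid length {n}"
                )

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def spectra(self) -> np.ndarray:
        """(n_samples, n_channels) matrix of spectral values."""
        return np.array([s.spectrum for s in self.samples])

    def contents(self, pigment: str = "anth") -> np.ndarray:
        """Content vector for one pigment; unmeasured entries become NaN."""
        vals = [s.profile.get(pigment) for s in self.samples]
        return np.array([np.nan if v is None else v for v in vals], dtype=float)

    def design_matrix(self, wavelengths=None) -> np.ndarray:
        """Spectral matrix restricted to the given wavelengths (nm)."""
        X = self.spectra
        if wavelengths is None:
            return X
        return X[:, self.grid.indices_of(wavelengths)]

    def subset(self, index) -> "SpectralDataset":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(self, samples=tuple(self.samples[int(i)] for i in idx))

    def restrict_channels(self, channel_index) -> "SpectralDataset":
        """Keep only the listed channel positions (grid must stay uniform)."""
        idx = np.asarray(channel_index, dtype=int)
        grid = SpectralGrid(self.grid.wavelengths[idx])
        samples = tuple(
            replace(s, spectrum=s.spectrum[idx]) for s in self.samples
        )
        return SpectralDataset(grid, samples, self.representation)

    def coarsen(self, step_nm: float) -> "SpectralDataset":
        """Subsample the grid to a coarser uniform step (e.g. 5 nm)."""
        factor = int(round(step_nm / self.grid.step))
        if factor < 1 or abs(factor * self.grid.step - step_nm) > 1e-9:
            raise GridError(
                f"coarse step {step_nm} nm is not a multiple of {self.grid.step} nm"
            )
        return self.restrict_channels(np.arange(0, len(self.grid), factor))


def to_absorbance(ds: SpectralDataset) -> SpectralDataset:
    """Apply the log10(1/R) absorbance transform channel-wise."""
    if ds.representation != "reflectance":
        raise RepresentationError("dataset is already in absorbance representation")
    X = ds.spectra
    if np.any(X <= 0):
        bad = int(np.sum(X <= 0))
        raise ValueError(f"{bad} non-positive reflectance value(s); cannot take log")
    samples = tuple(
        replace(s, spectrum=np.log10(1.0 / s.spectrum)) for s in ds.samples
    )
    return SpectralDataset(ds.grid, samples, "absorbance")


def transform_dataset(ds: SpectralDataset, transform: str) -> SpectralDataset:
    """Dispatch on the named transform: ``reflectance`` or ``log1r``."""
    if transform in ("reflectance", "R"):
        return ds
    if transform in ("log1r", "absorbance"):
        return to_absorbance(ds)
    raise ValueError(f"unknown transform {transform!r}")


def _wavelength_columns(columns) -> dict[str, float]:
    out = {}
    for c in columns:
        if c in PIGMENT_COLUMNS or c == "sample_id":
            continue
        try:
            out[c] = float(c)
        except ValueError:
            raise SpectraFormatError(f"unrecognized column {c!r}") from None
    return out


def read_dataset(path) -> SpectralDataset:
    """Read a wide-format CSV: sample_id, chl, car, anth, then nm columns."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise SpectraFormatError("missing required column 'sample_id'")
    for col in ("chl", "anth"):
        if col not in df.columns:
            raise SpectraFormatError(f"missing required content column {col!r}")
    dupes = df.columns[df.columns.duplicated()].tolist()
    if dupes:
        raise SpectraFormatError(f"duplicate columns: {dupes}")

    wl_map = _wavelength_columns(df.columns)
    if not wl_map:
        raise SpectraFormatError("no wavelength columns found")
    wl_cols = sorted(wl_map, key=wl_map.get)
    grid = SpectralGrid(np.array([wl_map[c] for c in wl_cols]))

    X = df[wl_cols].to_numpy(dtype=float)
    bad = np.argwhere(~((X > 0) & (X <= 1)))
    if bad.size:
        cells = [
            f"(row {int(i)}, {wl_cols[int(j)]} nm: {X[i, j]!r})" for i, j in bad[:10]
        ]
        raise ValueError(
            f"{len(bad)} reflectance value(s) outside (0, 1]: {', '.join(cells)}"
        )

    has_car = "car" in df.columns
    samples = []
    for i, row in enumerate(df.itertuples(index=False)):
        car = getattr(row, "car") if has_car else None
        if car is not None and isinstance(car, float) and math.isnan(car):
            car = None
        profile = PigmentProfile(
            chlorophylls=float(row.chl),
            anthocyanins=float(row.anth),
            carotenoids=None if car is None else float(car),
        )
        samples.append(LeafSample(str(row.sample_id), profile, X[i]))
    return SpectralDataset(grid, tuple(samples), "reflectance")


def write_dataset(ds: SpectralDataset, path) -> None:
    """Write the wide-format CSV read back by :func:`read_dataset`."""
    if ds.representation != "reflectance":
        raise RepresentationError("only reflectance datasets are written to CSV")
    cols = {"sample_id": [s.id for s in ds.samples]}
    for pig, attr in (("chl", "chlorophylls"), ("car", "carotenoids"),
                      ("anth", "anthocyanins")):
        cols[pig] = [getattr(s.profile, attr) for s in ds.samples]
    df = pd.DataFrame(cols)
    X = ds.spectra
    wl_names = [f"{w:g}" for w in ds.grid.wavelengths]
    df = pd.concat([df, pd.DataFrame(X, columns=wl_names)], axis=1)
    df.to_csv(path, index=False)


def pool_datasets(dss) -> SpectralDataset:
    """Pool several reflectance datasets onto their common wavelength range.

    Samples missing a required pigment content are dropped (count logged),
    mirroring how incomplete leaf records are excluded when multi-source
    tables are merged.
    """
    dss = list(dss)
    if not dss:
        raise ValueError("no datasets to pool")
    for ds in dss:
        if ds.representation != "reflectance":
            raise RepresentationError("pooling requires reflectance datasets")
    step = dss[0].grid.step
    if any(abs(ds.grid.step - step) > 1e-9 for ds in dss):
        raise GridError("datasets do not share a grid step")

    lo = max(ds.grid.wavelengths[0] for ds in dss)
    hi = min(ds.grid.wavelengths[-1] for ds in dss)
    if lo > hi:
        raise GridError("wavelength ranges have empty intersection")
    grid = SpectralGrid.from_range(lo, hi, step)

    samples = []
    dropped = 0
    for ds in dss:
        idx = ds.grid.indices_of(grid.wavelengths)
        for s in ds.samples:
            if not s.profile.complete:
                dropped += 1
                continue
            samples.append(replace(s, spectrum=s.spectrum[idx]))
    if dropped:
        logger.info("pool_datasets: dropped %d sample(s) with missing content", dropped)
    return SpectralDataset(grid, tuple(samples), "reflectance")
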