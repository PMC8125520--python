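"""Synthetic leaf-spectrum generator.

Emulates the statistical structure of pooled multi-species leaf datasets used
in anthocyanin retrieval work: pigment contents drawn from correlated
truncated normals (strong chlorophyll-carotenoid coupling, weak
anthocyanin-chlorophyll coupling), and reflectance built from a Beer-Lambert
absorbance model whose per-pigment response saturates at high content, so
that absorbance is linear in content only at low content.

The absorbance at wavelength lambda for a leaf with pigment contents c_p is

    A(lambda) = baseline + sum_p shape_p(lambda) * kappa * c_p / (kappa + c_p) + eps

with eps ~ N(0, noise_sd^2) i.i.d. per channel, and reflectance
R = 10^(-A) clipped to (1e-6, 1]. The Michaelis-Menten-form response
kappa*c/(kappa+c) is linear in c for c << kappa and approaches the asymptote
kappa for c >> kappa; its half-saturation point sits at c = kappa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .spectra import LeafSample, PigmentProfile, SpectralDataset, SpectralGrid

PIGMENTS = ("chl", "car", "anth")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class PigmentPrior:
    """Marginal targets and latent correlation for the pigment contents.

    ``means``/``sds`` are the target mean and SD of the *truncated*
    distributions on ``ranges`` (nmol/cm²); sampling moment-matches the
    underlying normals so empirical statistics land on these targets.
    ``correlation`` is the 3x3 latent Gaussian-copula correlation over
    (chl, car, anth).
    """

    means: dict = field(default_factory=lambda: {"chl": 13.88, "car": 4.23, "anth": 8.88})
    sds: dict = field(default_factory=lambda: {"chl": 12.71, "car": 2.85, "anth": 8.05})
    ranges: dict = field(default_factory=lambda: {
        "chl": (0.07, 53.76), "car": (0.15, 12.27), "anth": (0.00, 30.23)})
    correlation: np.ndarray = field(default_factory=lambda: np.array([
        [1.00, 0.85, 0.20],
        [0.85, 1.00, 0.15],
        [0.20, 0.15, 1.00],
    ]))

    def __post_init__(self):
        C = np.asarray(self.correlation, dtype=float)
        object.__setattr__(self, "correlation", C)
        if C.shape != (3, 3) or not np.allclose(C, C.T):
            raise ConfigurationError("correlation must be a symmetric 3x3 matrix")
        if not np.allclose(np.diag(C), 1.0):
            raise ConfigurationError("correlation diagonal must be 1")
        if np.linalg.eigvalsh(C).min() <= 0:
            raise ConfigurationError("correlation matrix is not positive-definite")
        for p in PIGMENTS:
            lo, hi = self.ranges[p]
            if lo < 0 or hi < lo:
                raise ConfigurationError(f"invalid range for {p}: ({lo}, {hi})")
            if self.sds[p] < 0:
                raise ConfigurationError(f"negative SD for {p}")


from functools import lru_cache


@lru_cache(maxsize=64)
def _match_truncnorm(mean: float, sd: float, lo: float, hi: float):
    """Find (loc, scale) of an untruncated normal whose [lo, hi]-truncation
    comes as close as the family allows to the requested mean and SD.

    Wide targets (SD comparable to the range) sit on the boundary of the
    truncated-normal family; the bounded solve then returns the nearest
    attainable moments (within a few percent for the default prior).
    """
    if sd == 0:
        return mean, 0.0
    width = hi - lo

    def resid(params):
        loc, log_scale = params
        scale = np.exp(log_scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    lb = (lo - 2 * width, np.log(sd / 10))
    ub = (hi, np.log(4 * width))
    best = None
    for loc0 in (mean, lo, (lo + hi) / 2):
        for s0 in (sd, 2 * sd):
            x0 = [np.clip(loc0, lb[0], ub[0]),
                  np.clip(np.log(s0), lb[1], ub[1])]
            sol = optimize.least_squares(resid, x0, bounds=(lb, ub))
            err = float(np.abs(sol.fun).max())
            if best is None or err < best[0]:
                best = (err, sol.x)
            if best[0] < 1e-10:
                break
        if best[0] < 1e-10:
            break
    loc, log_scale = best[1]
    return float(loc), float(np.exp(log_scale))


def sample_pigments(prior: PigmentPrior, n: int, seed: int):
    """Draw n correlated pigment profiles via a Gaussian copula over
    moment-matched truncated-normal margins."""
    if n < 2:
        raise ValueError("need n >= 2 samples")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(prior.correlation)
    latent = rng.standard_normal((n, 3)) @ L.T
    u = stats.norm.cdf(latent)

    values = {}
    for j, p in enumerate(PIGMENTS):
        lo, hi = prior.ranges[p]
        loc, scale = _match_truncnorm(prior.means[p], prior.sds[p], lo, hi)
        if scale == 0:
            values[p] = np.full(n, loc)
            continue
        a, b = (lo - loc) / scale, (hi - loc) / scale
        values[p] = stats.truncnorm.ppf(u[:, j], a, b, loc=loc, scale=scale)

    return [
        PigmentProfile(
            chlorophylls=float(values["chl"][i]),
            carotenoids=float(values["car"][i]),
            anthocyanins=float(values["anth"][i]),
        )
        for i in range(n)
    ]


@dataclass(frozen=True)
class AbsorptionShape:
    """Specific-absorption spectrum as a sum of Gaussian peaks.

    Each peak is (center nm, width nm, amplitude in absorbance per
    saturated nmol/cm²).
    """

    peaks: tuple

    def __call__(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        out = np.zeros_like(wl)
        for center, width, amp in self.peaks:
            out += amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
        return out


def default_shapes() -> dict:
    """Default per-pigment shapes.

    Anthocyanin absorbs most strongly in the green (peak 545 nm);
    chlorophyll has blue and red peaks, a red-edge shoulder, and a broad
    green tail scaled so chlorophyll absorbs about equally at 550 nm and at
    the red-edge band near 708 nm — the cancellation property the
    green/red-edge index pairs rely on; carotenoid absorbs in the blue.
    """
    return {
        "anth": AbsorptionShape(((545.0, 35.0, 0.060),)),
        "chl": AbsorptionShape((
            (430.0, 30.0, 0.055),
            (680.0, 25.0, 0.060),
            (700.0, 15.0, 0.022),
            (550.0, 60.0, 0.050),
        )),
        "car": AbsorptionShape(((470.0, 25.0, 0.045),)),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    n: int = 210
    seed: int = 0
    prior: PigmentPrior = field(default_factory=PigmentPrior)
    shapes: dict = field(default_factory=default_shapes)
    baseline_absorbance: float = 0.15
    kappa: float = 18.0            # half-saturation content, nmol/cm²
    noise_sd: float = 0.01         # absorbance units
    grid: SpectralGrid = field(
        default_factory=lambda: SpectralGrid.from_range(436, 780, 1.0))

    def __post_init__(self):
        if self.n < 2:
            raise ConfigurationError("n must be >= 2")
        if self.kappa <= 0:
            raise ConfigurationError("kappa must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise SD must be >= 0")
        wl = self.grid.wavelengths
        anth = self.shapes["anth"](wl)
        mask = (wl >= 530) & (wl <= 560)
        if mask.any() and anth.max() > 0 and anth[mask].max() < anth.max() * (1 - 1e-9):
            raise ConfigurationError(
                "anthocyanin shape must peak within 530-560 nm")
        edge = (wl >= 690) & (wl <= 720)
        if edge.any():
            chl = self.shapes["chl"](wl)
            if np.any(chl[edge] <= anth[edge]):
                raise ConfigurationError(
                    "chlorophyll shape must dominate anthocyanin in 690-720 nm")


def saturating_response(c: float, kappa: float) -> float:
    """kappa*c/(kappa+c): linear at c << kappa, half the asymptote at c = kappa."""
    return kappa * c / (kappa + c)


def compose_reflectance(profile: PigmentProfile, cfg: GeneratorConfig,
                        seed: int, sample_id: str = "leaf") -> LeafSample:
    """Build one leaf spectrum from a pigment profile."""
    wl = cfg.grid.wavelengths
    A = np.full(wl.shape, cfg.baseline_absorbance, dtype=float)
    for p in PIGMENTS:
        c = profile.get(p)
        if c is None:
            continue
        A += cfg.shapes[p](wl) * saturating_response(c, cfg.kappa)
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(seed)
        A += rng.normal(0.0, cfg.noise_sd, size=wl.shape)
    R = np.clip(10.0 ** (-A), 1e-6, 1.0)
    return LeafSample(sample_id, profile, R)


def generate_dataset(cfg: GeneratorConfig) -> SpectralDataset:
    """Generate a full dataset; one master seed expands to per-stage streams."""
    ss = np.random.SeedSequence(cfg.seed)
    pigment_seed, noise_seed = ss.spawn(2)
    profiles = sample_pigments(
        cfg.prior, cfg.n, np.random.default_rng(pigment_seed).integers(2**31))
    noise_seeds = np.random.default_rng(noise_seed).integers(2**31, size=cfg.n)
    samples = tuple(
        compose_reflectance(p, cfg, int(noise_seeds[i]), f"leaf-{i:04d}")
        for i, p in enumerate(profiles)
    )
    return SpectralDataset(cfg.grid, samples, "reflectance")
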