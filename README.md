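# anthospec

Retrieval of leaf anthocyanin content (nmol/cm²) from hyperspectral leaf
reflectance on the 436–780 nm window, for plant-pigment and remote-sensing
researchers comparing calibration strategies at the leaf scale.

Anthocyanins absorb most strongly around the green reflectance peak
(~550 nm), where chlorophyll also absorbs; wavelengths on the red edge
(~700–730 nm), where chlorophyll dominates, let a model cancel that
interference. `anthospec` implements and compares, under one shared
10-fold cross-validation scheme:

- **Gaussian-process regression** with the ARD squared-exponential kernel
  k(s,s') = σ_f² exp(−½ Σ_m (s_m−s'_m)²/σ_m²), trained by maximizing the
  log marginal likelihood
  log p(z|S) = −½ z'K_y⁻¹z − ½ log|K_y| − (n/2) log 2π with analytic
  gradients (K_y = K + σ_n²I). Per-channel length scales σ_m double as
  wavelength-importance indicators (small σ_m = informative), and the
  posterior variance gives per-leaf error bars.
- **NIPALS partial least squares** (X = TP′ + E, y = Uq′ + f, inner
  relations u_h = b_h t_h) with the PRESS/SS admission rule: component a
  enters iff PRESS_a/SS_{a−1} < 0.95².
- **Sequential backward band removal**: drop the least important
  wavelength (summed σ_m, |β|, or their fold rankings) until one survives,
  then pick mutually distant (>10 nm) wavelengths walking the removal
  order backward.
- **Anthocyanin vegetation indices** — ARI = 1/R₅₅₀ − 1/R₇₀₀,
  band-optimized mARI = (1/R_λ1 − 1/R_λ2)·R_λ3, red/green ratios, mACI —
  calibrated linearly against content.
- **A synthetic leaf-spectrum generator** (correlated truncated-normal
  pigment contents; Beer–Lambert absorbance with saturating per-pigment
  response) so the whole pipeline is testable end to end without data
  downloads.

## Worked example

```python
import anthospec as asp

ds = asp.generate_dataset(asp.GeneratorConfig(n=210, seed=1))
folds = asp.make_folds(len(ds), k=10, seed=1)

# two-wavelength GPR on the log(1/R) absorbance proxy
gpr_cv = asp.cross_validate(
    ds, asp.ModelSpec("gpr", (555.0, 705.0), transform="log1r",
                      n_restarts=1, seed=1), folds)
print(gpr_cv.summary())

# four-wavelength PLSR with PRESS-selected components
plsr_cv = asp.cross_validate(
    ds, asp.ModelSpec("plsr", (566.0, 709.0, 723.0, 755.0),
                      n_components="auto", seed=1), folds)
print(plsr_cv.summary())
```

prints (floats abbreviated):

```
{'cal_r2': 0.993, 'val_r2': 0.992, 'cal_rmse': 0.578, 'val_rmse': 0.612}
{'cal_r2': 0.929, 'val_r2': 0.938, 'cal_rmse': 1.850, 'val_rmse': 1.843}
```

The nonlinear GPR at one green-peak and one red-edge wavelength validates
at R² ≈ 0.99 with RMSE ≈ 0.6 nmol/cm², clearly ahead of the linear
four-wavelength PLSR model (R² ≈ 0.94, RMSE ≈ 1.8 nmol/cm²): absorbance
saturates at high pigment content, so the linear model systematically
underestimates leaves above ~18 nmol/cm² while the GP keeps tracking.

The same workflow is available from the shell:

```bash
anthospec simulate --n 210 --seed 1 --out leaves.csv
anthospec gpr-fit --data leaves.csv --wavelengths 555,705 --out gpr.json
anthospec evaluate --data leaves.csv --model gpr.json --out cv.json
anthospec select-bands --data leaves.csv --engine gpr --coarsen 5 --out trace.json
anthospec indices --data leaves.csv --which ari,mari --out indices.json
```

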