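# Methods

## Problem

Leaf anthocyanin content (nmol/cm²) is retrieved from visible/near-infrared
reflectance spectra on the 436–780 nm window at 1 nm resolution
(345 channels). Two calibration engines are compared — linear partial least
squares regression (PLSR) and nonlinear Gaussian-process regression (GPR) —
together with closed-form vegetation indices, under one shared 10-fold
cross-validation scheme. Wavelength subsets are chosen by sequential
backward band removal so that final models use only a handful of channels
around the green peak (~550–566 nm, where anthocyanin absorbs most
strongly) and the red edge (~700–730 nm, where chlorophyll dominates and
can be cancelled out).

Spectra are modeled either as reflectance R or as the absorbance proxy
log10(1/R). The base of the logarithm is fixed at 10 (the spectroscopic
absorbance convention); both engines are invariant to the positive scale
factor a base change introduces, so this cannot affect model rankings and
is not configurable.

## PLSR (`anthospec.plsr`)

Single-response NIPALS with mean centering and no variance scaling:
reflectance channels share units, and autoscaling would inflate noise
channels. Per component h: w_h ∝ X'y (normalized), t_h = X w_h,
p_h = X't_h/t_h't_h, q_h = y't_h/t_h't_h, then X and y are deflated. The
composite coefficients β = W(P'W)⁻¹q reproduce the score-path predictions
to 1e-10; both code paths are kept and compared in tests. If the response
residual vanishes before the requested component count (exact fit),
extraction stops early and the model is truncated.

The component count is selected by the PRESS/SS rule: component a is
admitted iff PRESS_a/SS_{a−1} < 0.95² = 0.9025, where PRESS_a sums
held-out squared errors over leave-one-group-out refits on the shared fold
assignment and SS_{a−1} is the all-data residual sum of squares with a−1
components (SS₀ = total centered sum of squares). Selection stops at the
first rejection. The floor is one component: the rule may reject even the
first, but a zero-component model is useless downstream.

## GPR (`anthospec.gpr`)

Exact zero-mean GP on the centered response with the ARD squared-
exponential kernel k(s,s') = σ_f² exp(−½ Σ_m (s_m−s'_m)²/σ_m²) plus
i.i.d. Gaussian noise σ_n². Inputs are standardized per channel before
kernel evaluation (parameters stored on the model) — ARD length-scale
initialization is only meaningful on a common scale. Hyperparameters are
trained by maximizing the log marginal likelihood with analytic gradients
on the log scale, L-BFGS-B from σ_f = SD(z), σ_m = 1, σ_n = 0.1·SD(z),
plus seeded random restarts perturbed log-uniformly by ±1 (default 4; the
cross-validated searches use 1 for speed). Log-hyperparameters are bounded
in ±18 to avoid overflow. Cholesky factorization uses a jitter ladder
(0, 1e-10, 1e-8, 1e-6 of the mean diagonal) before declaring a
conditioning failure. Predictive variances are the diagonal of the
posterior covariance; interval coverage checks add σ_n² because held-out
observations include noise.

A small σ_m marks an informative channel; σ_m is the per-channel
importance indicator used in band elimination.

## Band elimination (`anthospec.bands`)

At each iteration, ten models are calibrated (one per held-out fold) on
the surviving channels; per-fold indicators (σ_m or |β|) and within-fold
ranks (rank 1 = most important, ties averaged) are summed across folds.
The least important channel — largest summed σ_m / smallest summed |β|
under `sum_indicator`, or largest summed rank under `sum_rankings` — is
removed; ties remove the longer wavelength first (deterministic). Fold-
averaged calibration/validation R²/RMSE are logged every iteration, and
the loop runs to a single survivor. Validation responses never influence
the removal order. GPR fits warm-start per fold from the previous
iteration's optimum (with fresh restarts), an implementation choice that
cuts runtime without changing determinism.

Final wavelengths are picked by walking the removal order backward from
the survivor, accepting a wavelength only if it is more than 10 nm (the
coarsest resolution a hyperspectral instrument should offer) from every
already-picked one.

The two-wavelength search cross-validates a two-channel GPR model for
every (green-peak, red-edge) pair on a configurable lattice. The default
test runs use a 10-nm lattice and the acceptance script a 5-nm lattice:
evaluating a subset of pairs can only understate the best achievable
score, so lower bounds derived from it remain conservative.

## Vegetation indices (`anthospec.indices`)

Red/Green-1 = R₆₇₅/R₅₅₀; Red/Green-2 = ΣR(600–699)/ΣR(500–599) with
inclusive integer bounds; ARI = 1/R₅₅₀ − 1/R₇₀₀;
mARI = (1/R_λ1 − 1/R_λ2)·R_λ3; mACI = R₇₈₀/R₅₅₀. For mARI, λ1 maximizes
|corr(1/R_λ, content)| over 530–570 nm — 1/R is the index's own absorption
proxy, an interpretation documented here because the correlation target
(content vs. absorbance vs. an extinction template) is genuinely open —
then (λ2, λ3) exhaustively maximize the linear-calibration R² over
690–710 × 760–780 nm. Indices are calibrated to content by per-fold
least-squares lines in the shared fold scheme.

## Evaluation (`anthospec.evaluate`)

Folds: a seeded permutation chunked into k near-equal groups (sizes differ
by at most one); serialized to JSON so every engine shares the assignment.
R² is the squared Pearson correlation of measured vs. predicted, identical
to the R² of the least-squares line through the scatter. RMSE is computed
on raw residuals about the 1:1 relationship — the standard retrieval
metric, zero iff prediction is perfect — not about the fitted line; the
95%-confidence line fit is returned for scatter annotation only. Negative
predicted contents are not clipped in metrics.

## Synthetic data (`anthospec.simulate`)

The generator emulates the statistical structure of pooled multi-species
leaf datasets so every stage is testable without a download:

- **Contents.** A Gaussian copula over per-pigment truncated normals,
  moment-matched so the truncated distributions hit the target means/SDs:
  chlorophylls 13.88 ± 12.71 on [0.07, 53.76], carotenoids 4.23 ± 2.85 on
  [0.15, 12.27], anthocyanins 8.88 ± 8.05 on [0.00, 30.23] nmol/cm². The
  chlorophyll and anthocyanin targets lie just outside the moments any
  truncated normal on those ranges can produce; the solver returns the
  closest attainable parameters (≤ 9% deviation). Latent correlations
  (chl–car 0.85, chl–anth 0.20, car–anth 0.15) encode the strong
  chlorophyll–carotenoid and weak anthocyanin–chlorophyll coupling; these
  are design targets, not measured values.
- **Spectra.** Absorbance A(λ) = baseline + Σ_p shape_p(λ)·κc_p/(κ+c_p) + ε,
  reflectance R = 10^(−A) clipped to (1e-6, 1]. The Michaelis–Menten-form
  response with κ = 18 nmol/cm² is linear at low content and saturates at
  high content — the Beer–Lambert breakdown that makes linear calibration
  underestimate contents above ~18 nmol/cm² while a nonlinear model keeps
  tracking. Per-pigment shapes are Gaussian-peak sums: anthocyanin peaks at
  545 nm (σ 35); chlorophyll at 430 and 680 nm with a 700 nm red-edge
  shoulder and a broad green tail whose amplitude makes chlorophyll absorb
  about equally at 550 nm and 708 nm — the cancellation property the
  green/red-edge index pairs and the log(1/R₅₅₀)−log(1/R₇₀₈) feature
  exploit; carotenoid at 470 nm. Noise is i.i.d. N(0, 0.01²) absorbance
  per channel. One master seed expands into per-stage substreams.

What the generator does **not** emulate: leaf-structure scattering and
specular effects, species-specific spectral signatures, wavelength-
correlated instrument noise, and any radiative-transfer physics. Passing
tests therefore demonstrate that the pipeline recovers the qualitative
regularities it assumes (green-peak signal, red-edge cancellation,
saturation-driven nonlinearity) — not that it would reach any particular
accuracy on real leaves.

## Problem sizes and numerical choices

Test and script workloads are sized for a single desktop core: elimination
tests use 3-channel, 30-sample sets; pipeline replicates use the full
n = 210, 345-channel dataset with two-wavelength searches on 10-nm (tests)
or 5-nm (script) lattices; the uncertainty-coverage check trains on 120 and
tests on 200 GP-drawn points. Degenerate inputs are rejected loudly:
constant responses, non-positive reflectances under the log transform,
off-grid wavelengths, non-uniform grids, infeasible correlation matrices.

## Known limitations

- PLSR fits inside the elimination loop use a fixed two-component model
  (rank-capped) rather than re-running PRESS selection at every
  iteration × fold; PRESS selection is available (`n_components="auto"`)
  for final models.
- The exact GP scales as O(n³); the package targets leaf-scale datasets
  (hundreds of samples), not imagery.
- Index formulas assume reflectance as a fraction in (0, 1]; percent data
  must be converted on ingest.
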