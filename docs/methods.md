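# Methods

## Model

The observation model is a two-level Normal hierarchy on an annual panel of
areal concentrations `y_it` (μg/m³), unit `i = 1..n`, year `t = 1..T`:

```
y_it  ~ Normal(mu_it, sigma0^2)
mu_it ~ Normal(theta_it, sigma1^2)
ln(theta_it) = alpha + S_i + (b0 t* + v_t) + b1_i t* + eps_it
```

with centered time `t* = year − mean(year)` (for 17 consecutive years t* runs
−8..+8). The first layer captures global observation variability (`sigma0`),
the second the dispersion of local means around the structural surface
(`sigma1`). `exp(S_i)` is the unit's multiplicative magnitude relative to the
overall level `exp(alpha)`; `b1_i` its additive departure from the common
log-trend `b0`; `v_t` yearly shocks around the linear trend; `eps_it` an
optional over-dispersion term.

### Priors

* `alpha`, `b0`: flat improper priors (constants in the log target).
* `S_i` and `b1_i`: BYM convolution — an intrinsic CAR (ICAR) structured
  component on the Queen contiguity graph plus an iid Normal unstructured
  component. The ICAR has improper joint kernel
  `−(n−c)·ln τ − (1/2τ²) Σ_{i<j} w_ij (x_i − x_j)²` (`c` = number of
  connected graph components, `w_ij ∈ {0,1}`), equivalently full conditionals
  `x_i | x_−i ~ Normal(mean of neighbors, τ²/m_i)`. The structured :
  unstructured variance split is not fixed a priori; both sds are estimated.
* Every standard deviation (`sigma0`, `sigma1`, `sigma_eps`, `tau_S`,
  `sd_S_unstruct`, `tau_b1`, `sd_b1_unstruct`, `sd_v`): half-normal, default
  scale 10 on the sd scale — weakly informative for data on the scale of tens
  of μg/m³, configurable per field. `sigma_eps` defaults to a tight scale
  (0.05) because the over-dispersion layer is only weakly separable from
  `sigma1`; `PriorSpec(overdispersion=False)` removes the layer entirely, and
  recovery experiments run with it off.

A CAR conditional written as `Normal(μ_i + Σ_j w_ij (S_j − μ_j), σ_i²)` with
zero-centered fields and row-standardized weights reduces to exactly the ICAR
conditional above (neighbor mean, variance τ²/m_i); that is the form
implemented, matching what WinBUGS's `car.normal` and standard BYM disease
mapping use. Isolated units (no neighbors) are excluded from the ICAR terms;
their spatial effect is carried by the unstructured component alone.

## Sampler

Metropolis-within-Gibbs, one sweep =

1. conjugate Gibbs draw of every latent `mu_it` (Normal–Normal given `y` and
   `theta`);
2. random-walk Metropolis for `alpha` and `b0` (likelihood-only targets);
3. the ICAR fields updated single-site but *vectorized over graph-coloring
   classes*: units in one color class share no edges, so they are
   conditionally independent given the rest of the field and can be
   accepted/rejected simultaneously. Acceptance uses the exact local
   difference of the joint (row likelihood + CAR neighbor terms), which is
   tested against full joint-density differences;
4. simultaneous independent RW updates of the unstructured fields, `v_t`
   (columns are conditionally independent), and `eps_it` (elementwise);
5. log-scale RW updates of all standard deviations (half-normal prior and
   Jacobian in the target);
6. identifiability recentering: the means of the structured fields are folded
   into `alpha`/`b0`, and `v` is residualized against `(1, t*)` with the
   fitted line folded into `(alpha, b0)`. The structured-field shift leaves
   both eta and the ICAR kernels invariant; the `v` sweep is the standard
   constraint that makes the (flat-prior) trend identifiable.

Step sizes adapt by Robbins–Monro toward 0.44 acceptance during burn-in only
and are frozen afterwards, preserving detailed balance in the sampling phase.
Chains are seeded independently by `SeedSequence(seed).spawn(...)` and run
sequentially; identical inputs give bit-identical draws. Standard deviations
are floored at 1e-10 to survive degenerate (noise-free) data. A NaN in the
state aborts with the offending sweep reported.

Convergence is assessed with the classic Gelman–Rubin statistic
`R̂ = sqrt(((n−1)/n · W + B/n) / W)`; values below 1 (possible when the
between-chain variance is ~0) are reported as 1.0. The default operating
criterion is R̂ ≤ 1.1 for `alpha` and `b0`.

## Decision outputs

* **Magnitude**: per-unit posterior median of `exp(S_i)` (exp applied per
  draw; the median commutes for this monotone transform). Mapped to six
  classes by a geometric-interval rule anchored at parity: three classes
  below 1.0 and three above, breaks forming a geometric progression between
  each side's extreme and the anchor. If all magnitudes fall on one side of
  1.0 the classifier falls back to a one-sided six-class geometric
  progression between min and max. This anchored progression reproduces the
  semantics of GIS "geometric interval" legends (whose exact algorithm is
  proprietary) with a documented, reproducible rule.
* **Trend class**: `faster` iff median(`b1_i`) > 0 and
  `p(b1_i > 0 | data) > 0.8`; `decreasing` iff median < 0 and `p < 0.2`;
  otherwise `stable`, with both boundaries (p exactly 0.8/0.2) stable.
  `p` counts strictly positive draws.

## Preprocessing conventions

* **Raster format**: ESRI-ASCII-style plain text (header `ncols`, `nrows`,
  optional corner coordinates, `cellsize`, `NODATA_value`; then row-major
  values, row 0 = north).
* **Focal-mean imputation**: missing cells are filled by the mean of observed
  cells in a 6×6 sliding window, iterated until none remain. An even window
  has no central cell; the convention here anchors the window for cell
  (r, c) at rows r−2..r+3 and columns c−2..c+3 (0-based, inclusive),
  truncated at edges. Passes are Jacobi-style — every fill in a pass uses the
  previous pass's surface — making the result independent of cell order.
  Filled values are means of observed values, hence bounded by the observed
  range, and the operation is idempotent.
* **Grades**: left-closed right-open bands; defaults (−∞,15), [15,25),
  [25,35), [35,70), [70,∞) μg/m³ from the WHO guideline/interim targets plus
  the 70 μg/m³ severe bound; fully configurable.
* **Aggregation**: unit value = unweighted arithmetic mean of member cells
  (cells treated as equal-area); area shares are cell-count shares.
* **Quantiles**: linear interpolation of order statistics (numpy default,
  "type 7").
* **Exposure**: strict inequality (population in cells with concentration
  *greater than* the threshold), as boundary mass is negligible for
  continuous surfaces.

## Synthetic-data generator

The generator draws every model component exactly as specified above, so the
fit's target distribution is correctly specified on generated data:

* `S` and `b1`: ICAR draw (spectral construction — eigendecomposition of the
  graph Laplacian `D − W` restricted to its non-null eigenspace, which
  imposes the per-component sum-to-zero constraint exactly) + iid Normal
  component + planted hotspot bumps (Gaussian falloff or flat disc on the
  unit lattice).
* Centering: after planting, field means (and `v`'s fitted line) are removed
  and folded into `alpha`/`b0`, so the stored truth equals the identified
  quantities a fit should recover.
* Observation layers: `mu ~ N(exp(eta), sigma1²)`, `y ~ N(mu, sigma0²)`.
  Negative `y` is possible when the sds are large relative to `exp(eta)`;
  at the default noise levels (≤5% of the level) it effectively never occurs.
* Cell-level rasters take the unit's `theta_it` plus cell noise, clipped at
  zero, with configurable random missingness for exercising imputation; the
  population surface is log-linear in `S` (density ∝ `exp(coef · S_i)`),
  normalized to a fixed national total.

Default scenario: 17 annual surfaces (1998–2014), overall level
`exp(alpha) = 30` μg/m³ (national annual means in such panels run roughly
26–34 μg/m³), common trend 0.01/yr on the log scale (~+0.3 μg/m³/yr at that
level), three contiguous hotspot clusters pushing `exp(S)` up to about 2,
yearly shocks sd 0.03, observation sds 1.5 and 1.0 μg/m³, over-dispersion
off. Recovery experiments use 60 units (6×10 Queen lattice) with trend
0.02/yr; the coverage experiment scales down to 20 units × 9 years × 2,000
sweeps × 20 replicates, and the trend-classification experiment plants
+0.03/yr on a contiguous ~20% of units with the BYM trend noise switched
off. These problem sizes keep a full test-and-reproduction cycle to a few
minutes on a single CPU while leaving all posterior checks well-powered.

What the generator does *not* emulate: the spatial geometry of any real
country, satellite retrieval/AOD error structure, spatially correlated
observation noise, or population dynamics. Passing recovery tests therefore
demonstrate correctness of the inference machinery under the model's own
assumptions, not robustness to real-data misspecification.

## Numerical choices and limitations

* ICAR rank in the log target is `n − c` with isolated units counting as
  singleton components.
* Even-sample posterior medians are interpolated (numpy convention), so
  median/exp commutation is exact only up to interpolation.
* The half-normal prior scale is configurable per sd; analyses of data on a
  very different scale should set it accordingly.
* The three noise layers (`sigma0`, `sigma1`, `eps`) are retained for
  fidelity to the hierarchy but are weakly mutually separable; the
  over-dispersion switch exists precisely because fits with all three layers
  free identify their sum far better than the split.
* The spectral ICAR sampler is dense (O(n³) eigendecomposition) — fine for
  desk-scale lattices (≤ ~2,000 units), not for pixel-level national grids.
* The pipeline's manifest hashes every output file; determinism holds for
  fixed numpy/scipy versions on one platform.
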