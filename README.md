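# stbhm — space-time Bayesian hierarchical analysis of gridded pollution panels

`stbhm` is a reusable pipeline for analysing annual concentration surfaces
(e.g. satellite-derived PM2.5 at 0.1° resolution) observed over a lattice of
areal units across many years. It answers two questions environmental
epidemiologists routinely ask of such panels: *where* is pollution persistently
high relative to the national level (hotspot detection), and *which* units are
trending faster or slower than the common trend (local-trend clustering) — plus
the classical companions: OLS trends of annual summaries, grade-area shares,
and the percent of population exposed above concentration thresholds.

## The model

For unit *i* and year *t*, observed concentration *y<sub>it</sub>* follows a
two-level Normal hierarchy with a log-link linear predictor:

```
y_it  ~ Normal(mu_it, sigma0^2)
mu_it ~ Normal(theta_it, sigma1^2)
ln(theta_it) = alpha + S_i + (b0 t* + v_t) + b1_i t* + eps_it
```

* `alpha` — overall log concentration level; `exp(alpha)` is the national level.
* `S_i` — unit *i*'s persistent log departure; `exp(S_i)` is its **local
  magnitude** relative to the national level (>1 = more polluted).
* `b0 t* + v_t` — common linear trend on centered time `t* = t − t̄` with
  yearly random departures `v_t`.
* `b1_i` — unit *i*'s **local trend** departure from `b0`; positive means the
  unit deteriorates faster than the country as a whole.
* `eps_it` — optional over-dispersion.

`S_i` and `b1_i` carry Besag–York–Mollié (BYM) priors: an intrinsic CAR field
on the first-order Queen contiguity graph plus an iid Normal component.
`alpha` and `b0` get flat priors; every standard deviation a half-normal
prior. Inference is an adaptive Metropolis-within-Gibbs sampler with
graph-coloring-vectorized CAR updates; convergence is monitored with the
Gelman–Rubin statistic.

Decision rules on the posterior: units are classed **faster** when the
posterior median of `b1_i` is positive and `p(b1_i > 0 | data) > 0.8`,
**decreasing** when the median is negative and `p < 0.2`, **stable**
otherwise; magnitudes `exp(S_i)` are mapped to six classes by a geometric
interval progression anchored at 1.0 (three classes below parity, three
above).

## Worked example

Simulate a 40-unit, 17-year panel with two planted hotspot clusters and a
common upward trend of 0.02/yr on the log scale, fit the hierarchy, and
summarize:

```python
import math
from stbhm import (queen_lattice, make_truth, simulate_panel, run_mcmc,
                   PriorSpec, MCMCConfig, summarize_units,
                   overall_level_and_trend, gelman_rubin)
from stbhm.synthetic import TruthConfig, HotspotSpec

adj = queen_lattice(5, 8)                      # 40 county-like units
truth = make_truth(
    adj,
    TruthConfig(
        alpha=math.log(30.0), b0=0.02,
        s_hotspots=(HotspotSpec(center=(1, 2), radius=2.0, amplitude=0.7),
                    HotspotSpec(center=(3, 6), radius=1.5, amplitude=0.5)),
        sigma_eps=0.0,
    ),
    seed=42, lattice_shape=(5, 8),
)
panel = simulate_panel(truth, seed=7)          # 40 x 17 annual panel
draws = run_mcmc(panel, adj, PriorSpec(overdispersion=False),
                 MCMCConfig(n_chains=3, n_iter=3000, n_burnin=1500, thin=3, seed=1))

overall = overall_level_and_trend(draws)
units = summarize_units(draws)
```

This prints (medians with 95% credible intervals):

```
overall level exp(alpha): 45.17 (44.86-45.43) ug/m3
common trend b0: 0.0193 (0.0184-0.0201) per year  [truth 0.0195]
R-hat: alpha 1.034, b0 1.000
 unit_id  magnitude  magnitude_class  b1_median  prob_positive trend_class
      19   1.358841                6   0.000773       0.739333      stable
      11   1.355319                6   0.000564       0.691333      stable
      30   1.237637                6  -0.000145       0.444667      stable
```

The recovered common trend brackets the planted truth, the hottest units sit
in the top magnitude class, and no spurious "faster" trend is declared where
none was planted. (The overall level exceeds 30 μg/m³ because the planted
hotspot mass raises the identified mean level; the generator folds that shift
into the stored truth, so recovery is judged against the identified value.)

A full file-based run — rasters with missing cells, focal-mean imputation,
zonal aggregation, fit, summaries, trends, exposure — goes through the CLI:

```
stbhm all --seed 1 --out-dir runs/demo          # or: stbhm simulate / fit / ...
```

which writes text rasters, a panel CSV, a GAL neighbor list, per-chain draw
CSVs, unit summaries, trend fits, an exposure table, and a deterministic
`manifest.json` with content hashes of every output.

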