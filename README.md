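# tickabund

Joint Bayesian modelling of monthly lone-star-tick counts across the three
questing life stages (larvae, nymphs, adults), with negative-binomial (NB) and
zero-inflated negative-binomial (ZINB) observation layers.

## The scientific problem

Field surveillance programmes drag for ticks along fixed transects and record,
per site, habitat and month, how many larvae, nymphs and adults were caught.
These counts are hard to model:

- **Severe overdispersion.** Larval counts in particular arrive in clumps
  (egg masses hatch at a point in space), so variances exceed means by factors
  of hundreds to thousands.
- **Excess zeros.** Most winter records are zero, and many summer records are
  zero too. Are these "true" zeros from an NB with tiny size parameter, or
  *structural* zeros from months/sites where ticks were not available to be
  caught at all (the ZINB view)?
- **Cross-stage dependence.** This year's larvae become next seasons' nymphs
  and adults, sites differ persistently in suitability for all stages at
  once, and all stages share year-to-year environmental forcing.

`tickabund` fits the three stages *jointly*: stage-specific annual harmonics
(one sine/cosine pair), shared habitat effects, lagged log-abundance coupling
between successive stages, a shared sum-to-zero year random effect (RW1 or
iid), and one correlated trivariate location effect per site with a shared
3×3 covariance. The observation layer is NB, optionally zero-inflated with a
stage-specific structural-zero probability. Both model families can be fitted
and compared by WAIC/DIC and randomized-PIT calibration; no model is
auto-selected. See [docs/methods.md](docs/methods.md) for the full model and
the inference algorithm (nested Laplace with adaptive importance resampling).

## Worked example

There is no public dataset bundled, so the example uses the package's own
synthetic generator, whose defaults mimic a mid-Atlantic surveillance
programme (6 locations × up to 3 habitats, monthly sampling May 2009 –
December 2018, ~30% of site-months unsampled).

```python
import tickabund as ta
from tickabund.descriptives import describe_counts

panel, latents = ta.simulate_panel(ta.default_config(seed=7))
print(describe_counts(panel).round(3))
```

```text
           mean      variance        vmr  prop_zero  expected_zero_poisson
larvae  457.399  1.297387e+07  28364.445      0.712                    0.0
nymphs   19.683  5.642015e+03    286.638      0.532                    0.0
adults   72.191  1.606349e+05   2225.146      0.515                    0.0
```

Variance-to-mean ratios in the hundreds to tens of thousands and zero
fractions far above the Poisson prediction: the classic motivation for
NB/ZINB modelling. Fit the joint NB model:

```python
res = ta.fit(panel, ta.ModelSpec(family="nb", draws=1000, seed=0))
print(res.summarize().round(3).head(10))
```

```text
             mean     sd  ci_low  ci_high
parameter
beta_sin_L -5.270  0.183  -5.648   -4.927
beta_cos_L -2.538  0.159  -2.857   -2.216
beta_sin_N -0.535  0.106  -0.735   -0.330
beta_cos_N -3.614  0.114  -3.836   -3.390
beta_sin_A  1.243  0.086   1.076    1.413
beta_cos_A -5.392  0.132  -5.658   -5.123
beta_grass -1.317  0.096  -1.506   -1.127
beta_woods  0.570  0.094   0.391    0.758
beta_lagL   0.170  0.031   0.109    0.229
beta_lagN   0.096  0.035   0.030    0.165
```

(The generating values — e.g. `beta_grass = -1.298`, `beta_woods = 0.496`,
`beta_lagL = 0.212` — sit inside the intervals.) Derived phenology and
diagnostics:

```python
from tickabund.effects import seasonal_curves_from_result, peak_ordering
from tickabund.diagnostics import fit_criteria, pit_from_result

print(peak_ordering(seasonal_curves_from_result(res)).table.round(2))
crit = fit_criteria(res)
print(f"WAIC {crit.waic:.1f}  DIC {crit.dic:.1f}")
print(f"PIT KS p = {pit_from_result(res, seed=0).ks_p:.3f}")
```

```text
 stage  peak_month  peak_month_continuous  amplitude
nymphs           6                   6.28       3.65
adults           6                   5.57       5.53
larvae           8                   8.14       5.85
WAIC 13727.1  DIC 13727.1
PIT KS p = 0.719
```

Adults and nymphs peak in early summer, larvae strictly later in August, and
the model is predictively calibrated on its own data (PIT indistinguishable
from uniform).

### sklearn-style estimator

```python
from tickabund import MultistageAbundanceModel

est = MultistageAbundanceModel(family="zinb", draws=1000, seed=0).fit(panel)
mu_hat = est.predict(panel)        # (n_obs, 3) expected counts
est.summary_                       # posterior summary table
```

### Command line

```bash
tickabund simulate --seed 7 --output panel.csv
tickabund fit --panel panel.csv --family nb --draws 1000 --output post.npz
tickabund diagnose --posterior post.npz --panel panel.csv --out diag/
tickabund effects  --posterior post.npz --panel panel.csv --out effects/
tickabund run --config pipeline.yaml        # full pipeline with manifest
```

`tickabund prepare` aggregates raw visit-level CSV records into the monthly
panel; `tickabund sensitivity` refits under three prior sets and flags
parameters whose credible-interval width blows up (≥3× the narrowest set).

## Reproduction

All headline numbers are recomputed from scratch by:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which writes analytic descriptive targets (`t1`–`t3`), likelihood and
information-criteria oracle errors, the 20-replicate parameter-recovery
battery, the 2×10-replicate NB/ZINB model-selection battery, and the
10-replicate PIT calibration battery (≈15 minutes on one CPU). The test suite
(`python -m pytest -q tests/`) runs the same checks as assertions. One known
honest failure: on NB-generated data the fitted larval zero-inflation
posterior mean is ~0.06–0.15 rather than <0.1, and exact brute-force oracles
confirm the true posterior behaves the same way — see
`docs/methods.md` (limitations) for the identifiability analysis.
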