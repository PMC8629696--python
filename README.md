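# emanet

Multilevel VAR(1) network analysis of daily diary data.

Intensive longitudinal (diary / EMA) studies prompt the same people every
day with a battery of symptom and context items. A central question is how
the pieces of a depressive state push each other around *within* a person —
which is not answerable from cross-sectional correlations, because
within-person dynamics and between-person differences can diverge and even
oppose each other (Simpson's paradox). `emanet` implements the standard
dynamic-network decomposition for such panels, for researchers in clinical
psychology, psychiatric epidemiology and psychometrics.

## Model

For person *p* with item vector *x_t* on day *t*:

```
x_t = B_p (x_{t−1} − μ_p) + μ_p + ε_t,    ε_t ~ N(0, Σ_w)
μ_p ~ N(μ_0, Σ_b),    B_p = B + U_p,    U_p[j,k] ~ N(0, τ[j,k]²)
```

Estimated by two-step node-wise multilevel regression with orthogonal
(mutually uncorrelated) random effects, yielding three networks:

- **temporal** — directed lag-1 fixed effects `B` (Granger-causal,
  controlling for all other nodes; diagonal = autoregressive carry-over);
- **contemporaneous** — partial correlations of same-day residuals,
  the graphical model of `Σ_w⁻¹` (dynamics faster than one day);
- **between-subjects** — partial correlations of person means, the
  graphical model of `Σ_b⁻¹` (trait-like risk-factor structure).

Around the estimator: completion filtering, linear + weekend detrending,
within-person centering, item-redundancy screening (Hittner dependent-
correlation test, goldbricker pairwise search), raw strength centrality
with radar-chart visualization, a split-half replicability protocol, period
trend models, and a synthetic diary generator with known ground truth so
everything is testable by parameter recovery. See `docs/methods.md` for
assumptions, defaults and known limitations (including the Nickell bias of
the autoregressive diagonal under sample-mean centering).

## Worked example

Simulate a discretized 6-item diary panel with day-level missingness, run
the full pipeline, and compare against the generating truth:

```python
import numpy as np
from emanet import *

params = sample_generative_params(6, edge_density=0.3, effect_scale=0.15,
                                  seed=1, tau_scale=0.1)
params.missing_model = (8.0, 2.0)   # per-person completion ~ Beta(8, 2)
params.discretize = True            # 1-5 response scale
panel, truth = simulate_panel(params, 120, 40)

kept, rep = filter_min_completion(panel, 30)
print(f"retained {rep.n_retained}/{rep.n_total} persons "
      f"({rep.retention_percent:.2f}%)")
centered = within_person_center(detrend(kept, fit_trends(kept)))
net = fit_mlvar(centered)
cent = compute_centrality(net)
```

Output:

```
retained 91/120 persons (75.83%)
strongest temporal edge:        0.121
strongest contemporaneous edge: 0.201
strongest between edge:         0.438
top outstrength: ['V1', 'V3', 'V2']
recovery r (temporal):          0.958
recovery r (contemporaneous):   0.985
```

Reading: at the 30-of-40 completion cutoff, 91 of 120 simulated persons
remain. The fitted networks reproduce the usual ordering — temporal edges
smallest, between-subjects edges largest — and correlate > .95 with the
generating truth. `write_network_set(net, "nets/")` saves the three labeled
matrices plus metadata; `average_layout` / `render_network` /
`render_radar` reproduce the standard display conventions (minimum .04,
cut .05, maximum .4, averaged Fruchterman–Reingold layout).

The same pipeline is available from the shell:

```
emanet simulate --out panel.csv --truth truth.json --n-items 6 --seed 1
emanet screen   --in panel.csv --report redundancy.csv
emanet fit      --in panel.csv --out nets/ --min-days 30
emanet viz      --networks nets/ --out figs/
emanet replicate --in panel.csv --out replication.json
emanet trends   --in panel.csv --out trends.csv
```

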