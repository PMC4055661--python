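# florisk

Extinction-risk projection and reserve prioritization for threatened floras
censused on ordinal abundance scales.

National plant censuses carried out by volunteer botanists typically record
each population's size only as an ordinal class (1–9, 10–99, …, ≥1000) at a
coarse grid resolution, at two points in time. `florisk` turns such data into
quantitative conservation outputs:

1. **Population viability analysis (PVA).** Each taxon × cell population is
   projected in decadal steps, `N(t+1) = N(t)·r(t)`, with initial sizes drawn
   log-uniformly within the recorded class and rates of change drawn from
   frequency-weighted pools of observed change entities — either the taxon's
   own records across all cells ("what happened here may happen there", with
   probability `p_pool1`) or all taxa's records within the cell ("what
   happened here will happen here again"). A taxon is extinct when every cell
   falls below one individual; Monte Carlo replication yields a cumulative
   extinction CDF per decade, a species-loss curve, and the set of
   *threatened* taxa (P(extinct within 100 y) ≥ 10 %).
2. **Protected-area effectiveness.** Each record with change information is
   labelled declined / not declined and regressed on the cell's
   protected-area coverage by logistic regression (AIC-compared with the
   null). The fitted curve yields the *conservation effectiveness* — the
   fraction of would-decline populations saved at full coverage,
   `E = [P_nd(1) − P_nd(0)]/[1 − P_nd(0)]` — plus a literal probability
   ratio, and per-pressure tallies of declining populations.
3. **SPERS prioritization.** Greedy selection of cells to maximize the
   reduction of extinction risk, `RER = (1/S) Σ_s (1 − T_s/T_{s−p})`, where
   T are expected waiting times to extinction without/with protection.
   Precomputed per-(taxon, cell) local extinction databases (unprotected and
   protected at a given effectiveness, where each drawn rate r < 1 is
   cancelled with probability E) make taxon risk a product of per-cell CDFs,
   so the greedy search never re-runs the PVA. Complementarity, hotspot and
   random selectors are included as comparators.

Because such census databases are rarely public, the package ships a
synthetic census generator with known ground truth (heavy-tailed range
sizes, the census's record-completeness mixture, cell-severity
heterogeneity, a protection effect with an exactly recoverable
effectiveness) so every stage is testable end to end. See
`docs/methods.md` for the models, assumptions and design choices.

## Worked example

```python
import numpy as np
from florisk import ExtinctionRiskModel, ScenarioConfig, make_worked_fixture

records, cells = make_worked_fixture()   # five taxa with enumerable pools
cfg = ScenarioConfig(p_pool1=1.0, n_replications=1000, seed=42)
res = ExtinctionRiskModel(records, config=cfg).fit()
print(res.summary())
```

```
Population viability analysis (Monte Carlo)
=============================================
taxa simulated      : 5
taxa unsimulatable  : 0
replications        : 1000
p_pool1             : 1.0
horizon             : 100 years
expected losses     : 4.0 taxa
threatened (P>=0.10) : 4 taxa
```

The fixture's `coinflip` taxon has a pool of one guaranteed-survival and one
forced-extinction entity — a per-decade hazard of exactly 1/2 — and its
estimated CDF tracks the geometric law `1 − 0.5**t`:

```python
print(res.trajectories["coinflip"].cum_prob)
# [0.493 0.73  0.88  0.937 0.97  0.984 0.99  0.992 0.996 0.997]
```

Fitting the effectiveness model on 10 000 synthetic decline observations
generated with a true protection success of 0.6:

```python
from florisk import DeclineLogit
from florisk.synthetic import sample_decline_observations

obs = sample_decline_observations(10_000, baseline_decline_prob=0.6,
                                  protection_effect=0.6, seed=1)
print(DeclineLogit(obs["declined"], obs["pa_proportion"]).fit().summary())
```

```
Decline ~ protected-area coverage (logistic regression)
========================================================
observations            : 10000
intercept               :  0.4316
slope (coverage)        : -1.5039  (SE 0.0653)
AIC (model / null)      : 13294.9 / 13857.3
delta AIC (null-model)  : 562.4
P(decline) at 0% / 100% : 0.606 / 0.255
effectiveness (saved)   : 0.579
effectiveness (literal) : 1.229
```

The negative coverage slope is decisively supported (ΔAIC ≈ 562) and the
saved-fraction effectiveness recovers the generating value 0.6 to within
sampling error.

A full pipeline — loss curves across pooling scenarios, effectiveness for
total-PA and core-zone coverage, prioritization curves per method,
remaining-threatened curves per effectiveness, pressure tallies — runs from
a YAML config:

```sh
florisk all --config config.yaml --out out/
```

or stage by stage (`florisk synth / run / effectiveness / prioritize`); each
output directory contains a manifest sufficient to reproduce its numbers.

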