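# Methods

This note documents the models implemented in `florisk`, the choices made
where the design was genuinely open, and what the synthetic data generator
does and does not emulate.

## 1. The projection model

Census data arrive as one record per taxon × ~100-km² map cell, with
population size recorded on ordinal scales that differ between the two
censuses (first: 1–9, 10–99, 100–999, ≥1000; second: extinct, 1–9, 10–49,
50–99, 100–999, 1000–9999, ≥10 000), optionally accompanied by an ordinal
decline score (<1/100, 1/100–1/10, 1/10–1/2, 1/2–1, >1) describing the
fraction of individuals surviving the previous decade.

Each cell population is projected by

    N_i(t+1) = N_i(t) · r_i(t),

in decadal steps over a century. Both the initial size and every decadal
rate are drawn stochastically to propagate the interval-censoring of the
ordinal classes:

* **Initial size.** Log-uniform within the recorded class, so the expected
  draw equals the geometric mean of the class bounds. The open-ended classes
  contribute their point values (1000 and 10 000) exactly.
* **Rates.** Each record carrying change information contributes one *change
  entity* to frequency-weighted pools: a pair of census size classes (a
  quantitative record in both censuses; the pair is pooled as a single
  unit), a forced extinction (second census recorded extinct; rate fixed at
  1/10 000 so any population is removed in one step), or a decline score.
  A class pair yields `r = LU(second) / LU(first)` with independent
  log-uniform draws; a decline score yields a log-uniform draw within its
  bounds. The open rate classes take a floor of 1/10 000 (the forced rate)
  and a ceiling of 2 (reciprocal symmetry with the 1/2–1 class); both are
  configurable.
* **Pooling.** At every step of every replication the rate is drawn from
  the taxon's pool across all its cells ("what happened here may happen
  there") with probability `p_pool1`, otherwise from the cell's pool across
  all taxa ("what happened here will happen here again"). An empty chosen
  pool falls back to the other pool, then to the global pool — the rule
  covering taxa with size information but no computable rate of their own.

A cell is locally extinct once N < 1 (local extinction is absorbing); the
taxon is extinct when all its cells are. The cumulative extinction
probability per decade is estimated over (by default) 1000 replications.
Populations sized at the second census run ten steps; cells with only a
first-census size start one decade earlier and run eleven so that all
populations end at the same time; cells recorded extinct at the second
census are treated as deterministically gone before the common clock (the
forced rate removes any first-census class in one step); cells with no
usable starting size are ignored, and taxa with no simulatable cell at all
are excluded with a warning. A taxon is *threatened* when its probability
of extinction within the century is ≥ 0.10.

Populations are continuous positive reals and are never rounded: integer
flooring would make the forced-extinction rate exact only by accident for
populations below 10 000.

## 2. Expected waiting time to extinction

The prioritization objective needs a scalar waiting time T per taxon. We use
the restricted mean time to extinction: with survival S(t) = 1 − CDF(t) at
decade t,

    T = 10 · Σ_{t≥0} S(t),   truncated at a horizon (default 500 years).

Replications surviving the simulated century are extrapolated with a
geometric tail whose per-decade hazard is the *average* hazard of the
simulated window, h = 1 − (1 − c_n)^(1/n), floored at 10⁻⁴ so T stays
finite. The average-hazard tail (rather than the final-decade hazard) was
chosen deliberately: it is the only simple tail that keeps T monotone
decreasing under any pointwise increase of the CDF — with a final-decade
tail, raising the risk at decade n−1 alone can *lengthen* the extrapolated
wait. For constant-hazard CDFs the two rules coincide. An identically-zero
CDF returns the horizon. The horizon, the floor and the tail are
configuration knobs; RER values depend on the horizon and should only be
compared across runs sharing it.

## 3. Protected-area effectiveness

Every record with change information is labelled declined (1) or not (0):
observed extinctions are declines; decline scores below 1 (including 1/2–1)
are declines and the increase score is not; class pairs are compared by the
geometric midpoints of the two classes, with equal midpoints counted as
constant (the ordinal data do not define "decrease" for overlapping classes;
the midpoint rule is deterministic, symmetric and ordinal-faithful). The
binary outcome is regressed on the cell's protected-area proportion (or
core-zone proportion) by maximum-likelihood logistic regression with no
other covariates, and compared with the intercept-only null by AIC.

Two effectiveness summaries are reported, with P_nd(x) the fitted
probability of non-decline at coverage x:

* **saved fraction** (default): E = [P_nd(1) − P_nd(0)] / [1 − P_nd(0)] —
  of the populations that would decline without protection, the share saved
  at full coverage. This matches the simulation semantics of protection
  (cancelling an otherwise-declining rate with probability E) and is bounded
  in [0, 1].
* **literal ratio**: E′ = P_nd(1) / P_d(0), the probability of avoided
  decline under full protection divided by the probability of decline with
  none. It is reported alongside for comparability but can exceed 1 and does
  not equal a protection-success probability.

Perfect separation falls back to a lightly L2-penalized fit, flagged in the
results. Pressure tallies count declining (taxon, cell) records per pressure
label, over all cells or the subsets with >20 % PA or core coverage.

## 4. SPERS: prioritization by reduction of extinction risk

Re-running the PVA for every candidate cell at every greedy step is
infeasible, so the prioritizer precomputes, per (taxon, cell), two
per-decade local extinction CDFs: unprotected, and protected at a given
effectiveness E, where each drawn rate r < 1 is replaced by 1 with
probability E independently per draw. Both vectors are estimated from the
same underlying draws (common random numbers), which makes
protected ≤ unprotected hold exactly, pointwise, and makes the protected
CDFs monotone in E when several effectiveness values are built together.
Cells recorded extinct at the second census stay extinct in both variants:
prospective protection cannot undo a decline that happened between the
censuses.

The databases are built under `p_pool1 = 1.0`, which makes cells
conditionally independent; the taxon CDF under any protected set is then the
product of the chosen per-cell CDFs. The objective is

    RER = (1/S) Σ_s (1 − T_s / T_{s−p}),

with T from Section 2 applied to the unprotected and protected taxon CDFs.
It is 0 for the empty set and each term lies in [0, 1). An unnormalized
variant Σ (T_{s−p} − T_s) is selectable; the dominance properties asserted
by the tests hold under the default. Selection is greedy — each step adds
the cell with the largest RER gain, ties to the lowest cell id — which is
not guaranteed optimal but is the standard, well-behaved approximation for
this class of objective. Comparators: complementarity (greedy set cover on
species representation, then deepening the representation level), hotspot
(ranking by distinct-species richness), and ensembles of uniform random
orderings (mean/min/max curves).

## 5. The synthetic census generator

The original census database is not public, so the pipeline is exercised on
generated data with known ground truth. The generator emulates:

* **Range-size skew** — cells-per-taxon follows a discretized lognormal
  (default μ = 1.445, σ = 1.518 on the log scale, truncated at the number of
  cells), under which ~18 % of taxa are single-cell and ~68 % occupy fewer
  than ten cells. A pure (even exponentially cut) power law cannot match
  these quantiles simultaneously.
* **Record completeness** — the four information types (both censuses / one
  census + decline / one census only / decline only) are drawn with weights
  9115 : 4755 : 9600 : 1413, the relative frequencies reported for the
  national census.
* **Cell-severity heterogeneity and protection** — a population "would
  decline" with probability sigmoid(logit(p₀) + σ_c·z_cell), where z_cell is
  a per-cell habitat-quality effect (default σ_c = 1.5, p₀ = 0.6); if it
  would, protection rescues it with probability E_true · pa. Under this
  mechanism the saved-fraction effectiveness equals E_true exactly, giving
  the recoverable ground truth for the regression stage. Declining
  populations draw a latent decadal rate from the declining rate classes
  (weights 0.05/0.20/0.40/0.35 — free parameters; the census reports no
  empirical class distribution), others from the increase class; census
  classes are then read off a latent abundance trajectory, so observed
  extinctions and class pairs arise mechanically.
* **Pressures** — declining populations carry 1–2 labels whose composition
  shifts with coverage (development-type pressures recede inside PAs).

It does **not** emulate spatial autocorrelation of ranges or protected
areas, real geography, taxon-level correlation of trends beyond what the
cell effect induces, or observer error in class assignment. Passing tests
therefore demonstrate the correctness and the qualitative behaviour of the
machinery under the assumed structure, not quantitative national estimates.

A hand-written five-taxon fixture with enumerable pools (certain extinction;
certain survival; a per-decade hazard of exactly 1/2 whose CDF follows
1 − 0.5^t; two declining taxa sharing a cell and pressure labels) anchors
the oracle tests throughout.

### A note on the pooling-scenario ordering

Drawing all rates taxon-wise (`p_pool1 = 1`) removes within-taxon refuges
(mild cells receive the taxon's severe rates), and on datasets with
heterogeneous cell severity the century-end species loss under `p_pool1 = 1`
exceeds the cell-wise scenario — by ~1–6 taxa out of 40 on the default test
scenario, with no reversal in 60 generator seeds (rare marginal reversals
within Monte Carlo noise can occur on unlucky datasets). The finer contrast
between `p_pool1 = 0.8` and `1.0` is *not* resolvable on synthetic data of
this size: taxa whose own pool is mild keep losing risk as the mixing weight
rises while already-doomed taxa cannot gain more, so the two top scenarios
are statistically indistinguishable. Tests assert the robust pairwise form.

## 6. Numerical and reproducibility choices

* Problem sizes in the test-suite and acceptance runs are scaled-down study
  conditions chosen as the package's defaults for desk-scale verification:
  worked fixtures at 1000 replications; scenario comparisons at 40 taxa ×
  25 cells × 300–500 replications × 20 generator seeds; prioritization at
  30 taxa × 15 cells with budget 8.
* Every stochastic stage takes an explicit integer seed; per-taxon (and
  per-taxon-per-cell) streams are derived via `SeedSequence` with a CRC32 of
  the identifier, so results are bit-reproducible and stable under record
  reordering.
* Monte Carlo oracle comparisons use 3 binomial standard errors (floored at
  a small absolute tolerance near CDF endpoints).
* Class labels are Unicode-normalized (en-dash → hyphen, ≥ → >=) so field
  dialects parse identically; tables are written in a canonical ASCII CSV
  dialect that round-trips byte-identically.
* Ties in all selectors break to the lowest cell id, for determinism.

## 7. Known limitations

* No demographic structure, density dependence, dispersal or rescue between
  cells; rates are i.i.d. across decades (no temporal autocorrelation), the
  most literal reading of the census procedure.
* The product-form taxon CDF in the prioritizer is exact only under
  taxon-wise pooling; it is not valid for mixed pooling scenarios.
* The restricted-mean waiting time depends on the extrapolation horizon;
  RER magnitudes are comparable only within a fixed horizon.
* The effectiveness regression deliberately excludes covariates other than
  coverage, so it estimates an association, not a causal effect adjusted for
  siting bias.
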