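# Methods

## Discrete-day demography

Worms are inspected once per adult day, so observation is interval-censored on
a unit grid: a death in `(x−1, x]` is scored on day `x` (the ceiling of the
continuous death time). For integer days this makes the empirical survival at
day `x` an unbiased estimate of the continuous `S(x)`, which is why the
Gompertz–Makeham model can be fitted to Kaplan–Meier values at integer ages
without a half-interval correction.

Lifetables tally, per day, the number entering the interval (`N_x`), deaths
(`d_x`) and censored individuals (`c_x`), with `q_x = d_x/N_x` and
`m_x = −ln(1−q_x)`. Censored worms count in `N_x` on their final day and leave
the risk set afterwards. Days with `q_x = 1` give `m_x = +∞`; they are carried
in the table (and logged) but excluded from any regression on log-mortality.
Mean lifespan is the restricted mean survival time — the area under the KM
step curve up to the last observed day — the standard censoring-consistent
mean; without censoring it equals the arithmetic mean of death days.

## Gompertz–Makeham fitting

Hazard `M(x) = M0·e^{G·x} + M∞`; survival
`S(x) = exp[(M0/G)(1−e^{G·x}) − M∞·x]`, with the analytic limit
`exp[−(M0+M∞)x]` at `G = 0`. The fit minimises the unweighted sum of squared
differences between `S(x)` and the KM estimate at each observed day (KM
already accounts for censoring), using `scipy.optimize.least_squares` with the
trust-region-reflective method, bounds `M0 ∈ [10⁻⁸, 1]`, `G ∈ [0, 2]`,
`M∞ ∈ [0, 1]` per day (generous envelopes for daily worm mortality), and
objective tolerance 10⁻¹⁰. Points after the day KM first reaches zero are
dropped — the model never reaches exactly zero and a run of exact zeros would
overweight the tail. Initialisation exploits Gompertz log-linearity: ordinary
least squares of `ln m_x` on `x` over days with `0 < q_x < 1` supplies starting
`(ln M0, G)` with `M∞ = 0`; two deterministically jittered restarts are run and
the lowest-RSS solution kept. Non-convergence sets a flag rather than raising;
a curve that never falls below 0.9 raises a non-identifiability error.

Derived lifespans come from the fitted parameters by monotone root-finding
(median at `S = 0.5`; "maximum lifespan" defined as the age at 1% estimated
survival, `S = 0.01`) and adaptive quadrature of `S` for the mean, integrating
to the 10⁻¹² survival quantile (the neglected tail is below 10⁻¹² per day).

**A known small-sample property**: with `M∞` free, the early-age hazard is
only weakly split between `M0` and `M∞` (both act additively before `e^{G·x}`
grows), so on cohorts of a few hundred worms roughly half the fits assign some
baseline hazard to `M∞` and compensate `M0` downward. At n = 300 with
`M0 = 0.002/d`, `G = 0.25/d`, `M∞ = 0` this produces a median relative bias of
about −13% in fitted `M0` (fixing `M∞ = 0` removes it entirely, but that would
be a model choice the fit deliberately does not make); `G` is estimated with
median relative bias ≈ 2%. Both biases shrink as cohorts grow. Per-parameter
comparisons between conditions are unaffected to first order because both arms
carry the same fitting behaviour.

## Statistical comparisons

Two-group survival comparison is the standard log-rank chi-square (1 df) on
the shared day grid, with the tie-corrected hypergeometric variance; its
per-day observed-minus-expected contributions are exposed for diagnostics.
Families of gene-versus-control comparisons are adjusted with the Holm
(sequentially rejective Bonferroni step-down) procedure, applied across all
genes in a pipeline run. Scalar phenotypes use Student's two-sample t-test;
the degenerate zero-variance/equal-means case returns p = 1.

Demographic classification calls an IMR or RoA effect when the two-sample
t-test across per-replicate fitted parameters is significant at α (default
0.05) *and* the mean difference has a consistent sign. The lifespan effect is
tested on the per-replicate restricted mean lifespans, again by t-test. The
log-rank test is deliberately *not* used here: the group definitions concern
the mean lifespan, while log-rank tests equality of the whole survival
distribution — a gene that lowers IMR and raises RoA so as to leave the mean
unchanged (the Group 3 pattern) still reshapes the curve, and at pooled sizes
of ~900 worms per arm log-rank rejects such scenarios essentially always,
making Group 3 uncallable. The pipeline still reports the log-rank comparison
per gene (it is the appropriate test of survival difference); only the group
call consumes the mean-lifespan t-test. Patterns outside the four observed
groups (e.g. IMR up) return `"unclassified"` rather than being forced into a
group.

Classifying against three α = 0.05 tests means a truly null gene is called
Group 4 with probability at most ≈ 0.95³ ≈ 0.86 (less when estimates
correlate); this family-wise false-positive compounding is inherent to the
rule, not an implementation artefact.

## Reproductive screen

Self-fertilizing RLS is `last nonzero day − first nonzero day + 1` — interior
zero-progeny days do not end the span, since worms are only declared
post-reproductive after progeny stop appearing for good. Mated assays use the
absolute last day of live progeny production as the event day for
reproductive-survival KM/log-rank analysis. A hit requires pooled mean RLS
extension above the threshold (default 25%) and a significant increase in
every replicate experiment (the "positive three times" rule); the all-replicate
conjunction drives the null hit rate far below single-test α (< 1% empirically
over 500 null genes). Note the pooled >25% gate also binds under a true
effect: with per-replicate power 0.9 and n = 10/arm the joint hit probability
is ≈ 0.63, not 0.9³ ≈ 0.73, because the pooled extension only clears 25% in
≈ 84% of runs.

Epistasis classification is a pure truth table over the three wet-lab flags
(extension in *daf-2*, *daf-16*, *sma-2* mutants): extension in both *daf-2*
and *daf-16* means IIS-independence; crossing that with the *sma-2* flag gives
the four pathway classes. The flags are inputs, not inferences.

## Synthetic cohorts

The generator emulates the assay structure: Gompertz–Makeham lifetimes by
inverse-transform sampling (closed form for `M∞ = 0`; otherwise bracketed
bisection/Brent on the strictly increasing cumulative hazard, tolerance 10⁻¹⁰
days), ceiling discretization to the daily grid, independent per-day geometric
censoring (a declared stand-in for worms lost at transfer — the real loss
mechanism is unobserved), administrative censoring at the observation horizon,
and Poisson daily progeny counts up to a per-individual cessation day drawn
from a configurable distribution. Default cohort structure follows the assay
design: ~100 worms per replicate, three independent replicates. One integer
seed expands via `SeedSequence.spawn` into independent substreams for
lifetimes, censoring and progeny.

What the generator does *not* emulate: between-plate environmental
heterogeneity, day-to-day scoring error, non-independent censoring (e.g.
matricide correlated with reproduction), or any developmental-timing
variation. Passing tests therefore demonstrate correctness of the estimators
and decision rules under the assumed sampling model, not robustness to those
real-data complications.

## Problem sizes and numerical choices

Validation runs use 200 simulated cohorts per condition for parameter
recovery (n ∈ {75, 150, 300}), 1000 null pairs (n = 100/arm) for log-rank
calibration, 100 runs per classification scenario (3 replicates × 300 worms
per arm), and 300 runs for screen operating characteristics — sizes at which
the Monte-Carlo error on the reported rates is a few percent. Classification
scenarios are built from the effect sizes the demographic analysis is meant to
resolve: a 48% RoA reduction (Group 1), a five-fold IMR reduction (Group 2),
and a 91% IMR reduction with RoA raised to exactly preserve the model mean
lifespan (Group 3, solved once by root-finding on the mean). Quadrature
tolerances are 10⁻¹³ absolute for hazard–survival equivalence checks;
root-finding tolerances 10⁻¹⁰–10⁻¹² days. Ties in the lowest-RSS restart
selection keep the first (unjittered) start, making fits deterministic.
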