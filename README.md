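# wormdemog

Demographic and reproductive-senescence analysis for *C. elegans* RNAi
screens: lifetables and Kaplan–Meier survival on a daily scoring grid,
Gompertz–Makeham mortality fitting with IMR/RoA decomposition, log-rank and
t-test comparisons with Holm (Bonferroni step-down) adjustment, reproductive
lifespan scoring with screen hit-calling, and insulin/IGF-1–TGF-β pathway
epistasis classification. A synthetic-cohort generator produces per-worm event
tables and daily progeny schedules with the statistical structure these assays
yield, so the whole pipeline can be exercised and validated end to end without
any external data.

## Who this is for

Worm labs (or anyone doing organismal demography on a discrete inspection
grid) who score survival by daily prodding and progeny by daily transfer, and
want the standard downstream analysis — mortality decomposition, survival
comparisons, screen hit calls — as tested, scriptable functions rather than a
spreadsheet.

## The model

Survival is scored once per day of adulthood (adult day 1 is the first day of
adulthood; a death in `(x−1, x]` is recorded on day `x`). From the counts
entering (`N_x`), dying (`d_x`) and censored (`c_x`) in each interval, the
lifetable gives the probability of death `q_x = d_x / N_x`, the force of
mortality `m_x = −ln(1 − q_x)`, and the Kaplan–Meier product-limit survival.

Age-specific mortality follows the Gompertz–Makeham hazard

```
M(x) = M0 · exp(G·x) + M∞
```

whose survival function (the exponential of minus the cumulative hazard) is

```
S(x) = exp[ (M0/G)·(1 − e^{G·x}) − M∞·x ]
```

`M0` is the **initial mortality rate (IMR)** — the intercept of the
log-mortality trajectory, a measure of baseline frailty at young adulthood —
and `G` is the **demographic rate of aging (RoA)**, its slope. The model is
fitted to the Kaplan–Meier survival estimate by bounded trust-region-reflective
nonlinear least squares, per replicate experiment; derived summaries include
the fitted median lifespan (`S(x) = 0.5`), mean lifespan (`∫ S`), and maximum
lifespan defined as the age at 1% estimated survival (`S(x) = 0.01`).

Gene inactivations are classified by how they reshape the mortality
trajectory: Group 1 lowers RoA (slower aging) and extends mean lifespan;
Group 2 lowers IMR with unchanged RoA and extends mean lifespan; Group 3
lowers IMR but raises RoA, leaving mean lifespan unchanged; Group 4 changes
nothing.

Reproductive lifespan (RLS) runs from the first day of reproduction
(indexed 1) to the last day progeny are scored, tolerating interior zero-count
days. A screen hit must extend pooled mean RLS by more than 25% *and* be
significant (Student t-test, α = 0.05) in every replicate experiment.
Epistasis classification maps, for each gene, whether its inactivation still
delays reproductive senescence in *daf-2*, *daf-16* and *sma-2* mutants onto
its relationship with insulin/IGF-1 and TGF-β signaling.

## Worked example

```python
import pandas as pd
import wormdemog as w

# three replicate plates of 100 worms each, scored daily, 1%/day losses
control = w.simulate_cohort(
    w.CohortSpec(100, 3, w.GMParams(m0=0.004, g=0.25), 0.01, 60, seed=1), "control")
slow = w.simulate_cohort(
    w.CohortSpec(100, 3, w.GMParams(m0=0.004, g=0.13), 0.01, 60, seed=2), "daf-2i")
events = pd.concat([control, slow], ignore_index=True)

fits = {g: w.summarize_replicates(
            [w.fit_gm(w.km_survival(events, g, r)) for r in ("r1", "r2", "r3")])
        for g in ("control", "daf-2i")}
imr_pct, roa_pct = w.percent_change_params(fits["daf-2i"], fits["control"])
life = w.mean_lifespan_comparison(events, "daf-2i", "control")
call = w.classify_demographic_group(fits["daf-2i"], fits["control"], life)
print(f"IMR reduction: {imr_pct:.0f}%   RoA reduction: {roa_pct:.0f}%")
print(f"mean lifespan change: {life.percent_change:+.0f}% (p = {life.p_raw:.2g})")
print(f"demographic group: {call.group}")
```

prints

```
IMR reduction: 43%   RoA reduction: 37%
mean lifespan change: +55% (p = 7.5e-06)
demographic group: 1
```

The simulated inactivation halves the rate of aging: RoA drops significantly
(0.258 → 0.162 per day across replicates), the apparent IMR change is not
significant against the replicate scatter (sd ≈ 0.001/day), and mean lifespan
rises 55% — the Group 1 pattern of slowed demographic aging.

The same stages are available from the shell:

```sh
wormdemog simulate --m0 0.004 --g 0.25 --n 100 --replicates 3 --seed 1 \
    --group control --out control.csv
wormdemog lifetable control.csv --group control --out lifetable.csv
wormdemog fit control.csv --group control --out fits.csv
wormdemog run config.yaml            # full pipeline from a YAML config
```

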