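# imorsens

Sensitivity analysis for two-arm randomized controlled trials whose single
binary outcome is incomplete — the common situation in smoking-, alcohol-
and substance-cessation trials, where participants lost to follow-up are
conventionally counted as still smoking/drinking/using ("missing = event",
the Russell Standard) or handled by last observation carried forward
(LOCF).  Rather than committing to one such convention, `imorsens` embeds
them all in one pattern-mixture model and lets the analyst sweep over the
assumptions, showing exactly how much the estimated intervention effect
depends on them.

It is written for trial statisticians: input is either participant-level
records or per-cell counts, output is intervention-effect estimates with
delta-method standard errors and Wald intervals, as Python objects or CSV
from a small command-line tool.

## The model

Participants are stratified by randomized arm `Z ∈ {0, 1}` and, optionally,
a binary baseline covariate `X ∈ {0, 1}` (typically the outcome state at
baseline).  `R` indicates whether the outcome `Y ∈ {0, 1}` was observed.
Within each `(X, Z)` cell:

    logit P(Y = 1 | X, Z, R = 1) = θ_xz            (identifiable)
    logit P(Y = 1 | X, Z, R = 0) = θ_xz + δ_xz     (δ_xz analyst-supplied)

`θ_xz` is estimated as the empirical log-odds among the cell's responders.
`δ_xz` is the log **informatively missing odds ratio** (IMOR): the log
odds ratio of the event comparing non-responders with responders in that
cell.  The data carry no information about `δ`; it encodes the missing-data
assumption and is varied in a sensitivity analysis:

| δ assignment                        | assumption                      |
|-------------------------------------|---------------------------------|
| `0` everywhere                       | MAR given `(X, Z)`              |
| `+∞` everywhere                      | missing = event (Russell Standard) |
| `−∞` for `X=0`, `+∞` for `X=1`       | LOCF                            |

Infinities are handled symbolically, so the `±∞` analyses agree *exactly*
(point estimate and standard error) with deterministic single imputation,
and the no-covariate MAR analysis agrees exactly with the complete-case
2×2 analysis.

Arm event probabilities combine the cells by the law of total probability
with the observed cell sizes as weights, and the intervention effect is
`g(p₁) − g(p₀)` with `g` the logit (log odds ratio), identity (risk
difference) or log (log relative risk).  Standard errors propagate the
multinomial sampling variability of each arm's cell counts by the delta
method; the `δ` values are treated as fixed constants.

## Worked example

The treatment arm of the iQuit internet-based cessation trial (877
participants; event = smoking at follow-up): among those not smoking at
baseline, 65 of 131 reported an outcome, 41 of them smoking; among those
smoking at baseline, 286 of 746 reported, 230 of them smoking.

```python
import imorsens as im
from imorsens.examples import iquit_treatment_arm
from imorsens.sensitivity_model import estimate_observed_log_odds

table = iquit_treatment_arm()
est = estimate_observed_log_odds(table.cells[(0, 1)], cell_id=(0, 1))
print(round(est.log_odds, 3))                                   # 0.536
print(round(100 * im.cell_probability(est.log_odds, 1.0, observed=False)))  # 82

ests = {k: estimate_observed_log_odds(c, cell_id=k)
        for k, c in table.cells.items() if c.n_obs > 0}
params = im.SensitivityParameters.with_x(1, 1, 0, 0)
print(round(100 * im.arm_probability(table, 1, ests, params)))  # 85
```

With a log IMOR of 1 in both treatment-arm cells, the estimated smoking
probability among the 66 non-responders not smoking at baseline is 82%
(observed responders: 63%), among the 460 smoking at baseline 92%
(observed: 80%), and the law of total probability gives an overall
treatment-arm smoking probability of 85%.

A full sensitivity grid over the standard assumptions, from the command
line (here on a table that adds a control arm to the counts above):

```
$ imorsens grid --counts counts.csv --table5-presets
          assumption  estimate   se  display_estimate  display_ci_lower  display_ci_upper
    MAR (ignoring x)      0.57 0.17              1.77              1.27              2.47
                 MAR      0.60 0.17              1.81              1.30              2.53
                LOCF      0.41 0.13              1.51              1.18              1.94
     Missing = event      0.74 0.15              2.10              1.55              2.84
            MAR/LOCF      0.06 0.16              1.06              0.78              1.44
 ...
```

`estimate` is the log odds ratio of the event (treatment vs control) under
each assumption, `display_estimate` the odds ratio with its 95% interval;
mixed labels read treatment/control.  `imorsens fit` runs one assumption
(`--preset`, explicit per-cell values with `inf`/`-inf` tokens, or the
paired `--x0/--x1` mode that applies the same assumption in both arms),
and `imorsens simulate` generates synthetic trials from the same model.

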