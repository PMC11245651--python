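# driftwatch

Label-free drift surveillance for deployed clinical risk models.

A risk model running inside a hospital's EHR pipeline rarely has ground-truth
outcomes arriving alongside its predictions, yet its accuracy silently depends
on the incoming data continuing to look like the training data. Lab codes get
remapped, databases stall overnight, upstream schemas change, and patient
populations drift. `driftwatch` is a monitoring toolkit for the data-science
team responsible for such a model: it compares every production day against
the frozen training baseline, flags level/scale drift, missingness creep, and
call-volume anomalies, and turns the findings into a staged
blue/green/yellow/red communication protocol with retraining advice.

## What it computes

For each feature $X_j$ (and for the predicted probabilities themselves),
pooling the trailing 14-day window against the training sample:

- **Standardized difference**
  $d = (\bar{x}_1 - \bar{x}_2)\,/\,\sqrt{(s_1^2 + s_2^2)/2}$ — the scale-free
  covariate-balance measure (Bernoulli variances for binary features);
- **Two-sample tests** — Kolmogorov–Smirnov for continuous features,
  Pearson $\chi^2$ on the 2×2 presence table for binary ones;
- **Phase-I rank control charts** over the full post-deployment history:
  per-day studentized midrank means (level) and Mood-type squared centered
  ranks (scale), with the maximum daily statistic calibrated by permutation
  so the family-wise false-alarm probability across all charted days is
  controlled at a configured FAP. Rank statistics keep the charts honest on
  the heavily skewed, heavily tied features typical of clinical labs;
- **Missingness charts** — the same machinery applied to per-call 0/1
  missingness indicators, the signature of unmapped-code incidents;
- **Call-volume monitoring** — zero-call and absent days, plus a robust
  median ± 5·MAD anomaly band;
- **Long-run trend** — OLS of daily mean predicted probability on days since
  deployment, catching slow score inflation a two-week window cannot see;
- **Triage policy** — findings are classified into four error categories
  (technical infrastructure / explained shift / unexplained shift /
  performance loss) and mapped onto a four-stage protocol: 1 blue (normal
  operation), 2 green (minor interface change), 3 yellow (possible
  degradation — use with discretion), 4 red (unusable — suspend use, nonzero
  exit code for scriptable alerting), plus fix-upstream-first retraining
  advice.

The statistical core is exposed as sklearn-style estimators
(`WindowDriftTest`, `RankControlChart`: `fit` the reference, evaluate new
data) and a synthetic stream generator replays documented failure modes
(code changes, missingness ramps, outages, score inflation, concept shift)
for testing the whole stack without any real patient data.

## Worked example

Simulate the classic silent lab-code migration — from day 30 a new troponin
lab code is not mapped to the model's input, so the feature goes fully
missing — then monitor the stream:

```bash
$ driftwatch simulate troponin_code_change --out sim --seed 0
wrote scenario 'troponin_code_change' to sim

$ driftwatch monitor --reference sim/reference.csv --catalogue sim/catalogue.csv \
      --stream sim/stream.csv --out run --seed 0
[STAGE 4 / RED] Significant error: model output is not usable
(probability_shift; covariate_shift (lab_02); covariate_shift (lab_11);
missingness_shift (troponin); missingness_shift (troponin);
missingness_shift (lab_05); missingness_shift (lab_05)). Do not use the tool
until a fix is implemented; the monitoring team has been alerted.
$ echo $?
2
```

The troponin collapse also shows up downstream of the feature itself: the
score distribution shifts (troponin feeds the risk model, and its missing
values are mean-imputed), which is the `probability_shift` finding in the
banner; the remaining findings are chance per-feature reds that do not
escalate. The run directory holds the dashboard as data: `tabs/features.csv`
(one comparison row per feature, sorted by model importance),
`tabs/historical_missingness.csv` (the green/red chart grid — troponin's
level chart is red with permutation p = 0.0005, the smallest value 2000
permutations can resolve), `findings.json` (each finding with its error
category; the troponin finding is marked *blocking* because the covariate is
wholly absent from the trailing window, which is what forces stage 4 and the
exit code 2), `trend.json`, `advice.json` (`retrain: false` — the shift is a
pipeline problem, not grounds for retraining), and a self-contained
`report.html`. The fix itself is declarative:
add the new lab code to the `aliases` column of `catalogue.csv` and the
loader maps it back onto the troponin feature.

An in-control stream (`driftwatch simulate null ...`) monitored the same way
prints the stage-1 blue banner and exits 0; a handful of per-feature table
rows may sit below α = 0.05 (about `α × n_features` is expected by chance)
but none survives the family-wise escalation threshold, so the protocol
stage does not move.

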