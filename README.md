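# hdpsmatch

Propensity-score (PS) and high-dimensional propensity-score (hdPS) matching
for confounding by indication in medico-administrative claims data, with a
synthetic claims generator that provides known ground truth.

Observational drug-safety studies are prone to confounding by indication:
sicker patients are preferentially started on more intensive therapy, so
crude treatment-outcome contrasts are biased. The motivating setting is a
new-user cohort of statin initiators (high- vs lower-potency index
dispensation) followed two years for incident diabetes. Two adjustment
strategies are compared head to head:

- **Traditional PS** — logistic regression of treatment on an
  investigator-specified covariate list (demographics, poverty status,
  entry year, one-year utilization, drug-dispensation and comorbidity
  flags), e(x) = P(T=1 | X=x).
- **hdPS** — the same estimator on machine-selected covariates: the
  one-year lookback is structured into six data dimensions (outpatient
  drugs, claim procedures, claim diagnoses, physician specialty, inpatient
  procedures, inpatient diagnoses); the 200 most prevalent codes per
  dimension are expanded into recurrence indicators (≥ once, ≥ median,
  ≥ 75th percentile count) and ranked by the absolute log of the Bross
  bias multiplier

  bias(c) = (PC₁·(RR−1) + 1) / (PC₀·(RR−1) + 1),

  where PC₁/PC₀ are the candidate's prevalences among exposed/unexposed
  and RR ≥ 1 its crude outcome risk ratio; the top 500 candidates plus a
  small forced set (sex, age, poverty, entry year, utilization) form the
  hdPS model.

For either score, patients outside the common support are trimmed, then
high-potency patients are greedily 1:1 matched without replacement to the
nearest lower-potency patient on the logit of the score within a caliper
of 0.2 × SD(logit score). Performance is read off two surfaces: absolute
standardized differences (ASDD = |Δ| / pooled SD; < 0.1 means balance) over
18 prespecified characteristics, and the unadjusted odds ratio of the
outcome with a Wald 95% CI.

## Worked example

```python
from hdpsmatch import SimulationConfig, run_pipeline

cfg = SimulationConfig(n_patients=20_000, seed=42,
                       n_codes_per_dimension={d: 20 for d in range(1, 7)})
res = run_pipeline(cfg)            # true conditional OR = 1.0 by default
```

prints (via `res.flowchart`, `res.summary_*`, `res.effects`):

```
       stage  high  lower
    entering  6931  13069
  trimmed_ps    14      0
  matched_ps  6557   6557
trimmed_hdps    15      5
matched_hdps  6527   6527
full:         mean ASDD 0.137 (range 0.061-0.284), 11/18 above 0.1
ps_matched:   mean ASDD 0.010 (range 0.001-0.039),  0/18 above 0.1
hdps_matched: mean ASDD 0.018 (range 0.000-0.062),  0/18 above 0.1
full:         OR 1.219 (95% CI 1.045-1.422)
ps_matched:   OR 1.038 (95% CI 0.868-1.240)
hdps_matched: OR 1.017 (95% CI 0.849-1.219)
```

The generator's default confounding makes the crude OR ~1.22 even though
the true conditional OR is 1.0; matching on either score restores balance
(mean ASDD ≤ 0.02) and moves the estimate back to the null. The same
pipeline is available from the shell:

```bash
hdpsmatch run-all --n 20000 --seed 42 --out out/
hdpsmatch simulate --n 50000 --seed 7 --out claims/
hdpsmatch build-cohort --in claims/ --out cohort.csv
hdpsmatch fit-ps --cohort cohort.csv --out ps_scores.csv
hdpsmatch fit-hdps --cohort cohort.csv --claims claims/ --out hdps_scores.csv
```

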