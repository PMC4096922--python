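# ihcmark

Quantitative immunohistochemistry (IHC) biomarker analysis for small
oncology cohorts, built for the question: *can the expression of a
DNA-repair protein, measured on a pre-treatment biopsy, predict which
head-and-neck cancer patients respond to induction chemotherapy, and who
survives longer?*

The package implements the full analysis chain such a study runs:

* **Scoring** — pathologist grades: quantity Q ∈ {0..4} from the percent
  of positive tumor cells (0% → 0; 1–9% → 1; 10–39% → 2; 40–69% → 3;
  70–100% → 4), intensity I ∈ {0..3}, composite IxQ = Q·I; machine
  scoring: intensity-bin fractions (f₀, f₁, f₂, f₃) over the 0/1+/2+/3+
  bins and the H-score `H = 100·(f₁ + 2f₂ + 3f₃) ∈ [0, 300]`; Pearson
  concordance between the two strategies.
* **Response discrimination** — patients dichotomized into responders
  (CR/PR) and non-responders (SD/PD); per marker, a ROC curve with SD/PD
  as the positive class (sensitivity = fraction of SD/PD called SD/PD,
  1−specificity = fraction of CR/PR called SD/PD), its AUC
  (= Mann-Whitney concordant-pair fraction), the percent of responders
  correctly classified when every SD/PD patient is captured, the
  rank-sum p-value, and the apparent-error-rate-optimal threshold with
  sensitivity/specificity/PPV/NPV/RR/OR.
* **Survival** — Kaplan-Meier estimation, the two-group log-rank test and
  univariate Cox proportional-hazards regression (Newton-Raphson on the
  partial likelihood, Efron ties), all written from first principles; the
  minimum-p-value cutpoint search that dichotomizes a marker at the
  threshold minimizing the log-rank p, excluding splits that leave fewer
  than 10% of patients on one side; an opt-in permutation adjustment for
  the multiplicity that search induces.
* **Synthetic cohorts** — a seeded generator with planted response
  (log-odds per SD of marker score) and survival (log hazard ratio per SD)
  effects, so the whole chain is testable end to end without patient data.

## Worked example

The numbered scripts under `analysis/` run the study end to end on a
synthetic 37-patient cohort with a planted response effect on XPF and a
planted survival effect on nuclear pMK2 (all other markers null):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_scoring_concordance.py
python analysis/03_response_discrimination.py
python analysis/04_survival_cutpoints.py
```

The response stage prints (abridged):

```
  marker   auc  pct_correct_at_full_capture  rank_p  threshold   aer orientation
     XPF 0.760                        0.000   0.010    250.322 0.243        high
  FANCD2 0.593                        8.333   0.356    104.835 0.351         low
  ...
best discriminator: XPF (AUC 0.760, rank-sum p 0.00997)
```

XPF — the only marker with a planted response effect — tops the AUC
column; the null markers sit near 0.5. The survival stage prints:

```
  marker  threshold  n_low  n_high  logrank_p  cox_hr     cox_p
    pMK2      145.8     17      20  3.771e-05   2.611 0.0001752
     PAR      58.46      4      33  0.0001198  0.8755    0.5323
  ...
smallest survival p: pMK2 at threshold 145.8 (raw log-rank p 3.771e-05,
permutation-adjusted p 0.008)
```

pMK2 — the planted survival marker — attains the minimum p; its Cox
hazard ratio of 2.6 per standard deviation of score recovers the planted
effect (e^0.8 ≈ 2.2 plus sampling noise at n = 37). The permutation-
adjusted p shows how much of the raw minimum p is an artifact of
searching over thresholds. Output tables land in `results/`.

The same pipeline runs from a shell on any cohort table:

```sh
ihcmark simulate --seed 7 --out cohort.csv
ihcmark analyze --cohort cohort.csv --out results/
ihcmark report --out results/
```

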