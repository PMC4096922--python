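# Methods

## Scoring model

Pathologist scoring grades each marker × compartment as a quantity bin
Q ∈ {0..4} from the percentage of positively stained tumor cells and an
intensity grade I ∈ {0..3}; the composite is IxQ = Q·I ∈ {0..12}. The
quantity rule is anchored on integers (0%; 1–9%; 10–39%; 40–69%;
70–100%); fractional percentages are resolved by reading the intervals as
half-open — [0,1), [1,10), [10,40), [40,70), [70,100] — which preserves
every integer anchor. Machine scoring consumes the fractions of tumor
nuclei in the 0/1+/2+/3+ intensity bins and computes the standard H-score
`H = 100·(f₁ + 2f₂ + 3f₃)` on [0, 300]. Bin fractions must sum to 1
within 1e-6 and are renormalized below that tolerance, so rounded inputs
pass without bias. Concordance between the two strategies is Pearson's r;
both r and r² are returned because the literature quotes either.

## Response discrimination

The positive class is the non-responder (SD/PD) group. The ROC curve
sweeps every unique score as a threshold; AUC is the trapezoidal area,
which is algebraically the Mann-Whitney concordant-pair fraction with
ties counted ½ (the tests assert this equivalence against brute-force
pair counting). Orientation is a per-marker choice: "high" means high
score predicts SD/PD; "auto" evaluates both directions and keeps the one
with AUC ≥ 0.5, recording which was used. The full-capture statistic
places the threshold at the extreme SD/PD score so that no non-responder
is missed and reports the percentage of responders still classified
correctly — the clinically relevant question when missing a non-responder
is the costly error.

The group-difference p-value uses the two-sided Wilcoxon rank-sum test:
scores are ordinal/bounded, so a rank test is the defensible default.
Exact enumeration is used for combined n ≤ 20 without ties, the normal
approximation with tie correction otherwise; constant scores return p = 1.

The optimal threshold minimizes the apparent (in-sample) error rate over
candidate thresholds: midpoints of consecutive unique scores plus the two
degenerate thresholds that assign everyone to one class. Including the
degenerate candidates guarantees the optimum never loses to the majority
rule (AER ≤ min(prevalence, 1−prevalence)). Ties are broken by maximal
Youden index, then the lower threshold, so output is deterministic. For
2×2 statistics, empty margins yield NaN rather than errors; zero cells
trigger the Haldane-Anscombe +0.5 correction (flagged) for RR/OR only, so
the proportions stay uncorrected. No cross-validation is applied: the
reported statistics are apparent, in-sample quantities by design.

## Survival analysis

All estimators are written from first principles (an established survival
library serves only as a test oracle):

* **Kaplan-Meier**: product-limit estimator; at tied times events precede
  censorings (a patient censored at *t* is in the risk set of events
  at *t*).
* **Log-rank**: one-degree-of-freedom statistic from observed minus
  hypergeometric-expected events per distinct event time, with the usual
  variance term dropped when only one patient remains at risk.
* **Cox**: Newton-Raphson on the scalar partial likelihood, Efron tie
  handling by default, Breslow available (Breslow at β = 0 gives the
  score test that analytically equals the log-rank chi-square on tie-free
  binary data — asserted to 1e-8). Convergence requires a Newton step
  below 1e-10 and gradient below 1e-7; steps are clipped to ±5 to tame
  early iterations. A monotone likelihood (perfect separation) is flagged
  non-converged with the drift direction instead of returning a spurious
  estimate. Standard error is the inverse root of the observed
  information; the p-value is the two-sided normal Wald test.

The cutpoint search sweeps midpoints of consecutive unique scores,
splits the cohort at score > t versus ≤ t, and keeps the admissible split
with the smallest log-rank p. Splits whose smaller group holds less than
10% of patients (by default) are excluded as unreliable; the reported
`passes_constraint` flag always evaluates the 10% rule even when the
search itself ran unconstrained. The search is invariant to strictly
monotone transforms of the scores. Its minimum p is biased low by
construction; `minp_permutation_adjust` re-runs the search under
permutations of the score-to-patient assignment and reports
`(1 + #{permuted min-p ≤ observed}) / (n_perm + 1)`. It is off by
default so the headline tables mirror the uncorrected convention of the
study design this pipeline emulates; the fourth analysis script prints
both.

## Synthetic cohort generator

The generator emulates the table such a study would assemble, not the
slides. Each marker has a latent expression score on the 0–300 H-score
scale (default uniform over the full range, configurable
location/scale/normal). From the latent score:

* machine bin fractions are a Gaussian-kernel softmax over the bin
  centers of latent/100 with width 0.6, so the derived H-score is a
  smooth, slightly compressed monotone image of the latent score;
* pathologist grades rederive from the bin fractions (percent positive →
  Q by the binning rule; intensity = rounded mean stained-bin intensity),
  with optional additive jitter emulating inter-observer noise (off by
  default);
* non-response follows a logistic model whose intercept matches the
  configured marginal SD(+PD) probability and whose log-odds shift by
  `response_effect · z` per marker, z the population-standardized latent
  score;
* event times are exponential with hazard
  `baseline_hazard · exp(Σ log_hazard_ratio · z)`; censoring is an
  independent exponential — the simplest mechanism satisfying the random
  censoring KM and the log-rank assume.

Defaults are the study conditions the pipeline targets: n = 37,
response marginals 11/19/7 CR/PR/SD, eight DNA-repair markers with pMK2
scored in both compartments, baseline hazard 0.02 events/month (median
survival ≈ 35 months, typical of locoregionally-advanced head-and-neck
cancer), censoring 0.01/month, a planted response effect of 1.2 log-odds
per SD on XPF and a planted hazard effect of 0.8 log-HR per SD on nuclear
pMK2. One seeded generator drives all draws in fixed order, so a config
plus seed reproduces the table byte for byte.

What the generator does *not* model: pixel-level image analysis,
inter-marker correlation, non-proportional hazards, informative
censoring, and pathologist disagreement beyond additive jitter. Passing
tests therefore demonstrate correctness of the statistical machinery and
recoverability of planted effects under the model's assumptions — not
robustness to the messier failure modes of real IHC data.

## Numerical and design choices

* Problem sizes in the validation suites — 50 oracle fixtures at n ≤ 200,
  200 AUC instances at n ≤ 30, 1000 null replicates at n = 200, 100
  recovery replicates at n = 500 — keep Monte-Carlo error comfortably
  below the asserted tolerances while the full suite runs in well under a
  minute of simulation time.
* The latent score is kept as a column of the generated table; effect-
  recovery tests condition on it directly, since the H-score is a
  compressed transform whose attenuation is a property of the measurement,
  not of the estimators under test.
* p-values are written to the output tables at 4 significant figures;
  in-memory values are unrounded.
* Missing marker values: a marker missing in more than half the patients
  yields an undefined (NaN) row, not an error; rows missing survival time
  are dropped from the survival stage only.

## Known limitations

Single-marker analyses only (no multivariate Cox, no multi-marker
classifier, no competing risks); the apparent error rate is optimistic by
construction; the raw minimum-p cutpoint p-value is anti-conservative
unless the permutation adjustment is enabled.
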