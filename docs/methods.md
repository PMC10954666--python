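# Methods

## Scope and data model

One row per patient. Variables are declared by kind — continuous, binary,
categorical, time, event indicator — in a schema that also names the
endpoints: CR (binary), EFS and OS (time + event pairs). Missing values are
NaN in memory, an empty CSV cell on disk, and the reserved category label
`na` wherever a categorical view is needed (binned records, generator
marginals). Two invariants are enforced everywhere: times are non-negative,
and EFS ≤ OS whenever both are observed. Times are written in months at one
decimal.

## Fixture simulator (the study conditions)

The simulator produces cohorts shaped like a pooled intensive-chemotherapy
AML trial population, with every generating parameter retained for
parameter-recovery testing.

- **Covariates.** A latent multivariate normal of dimension 56 (4 blood/age
  marginals + sex + disease-onset status + 50 alterations) is thresholded
  and transformed per variable. Age is truncated normal (mean 55 y, SD 14,
  range 18–90); WBC, Hb and PLT are log-normal with medians 19.5 GPt/l,
  5.9 mmol/l and 50 GPt/l and log-scale spreads matched to wide clinical
  interquartile ranges. The 50 alteration frequencies are fixed at
  field-typical values between 0.5% and 34% (NPM1 30%, DNMT3A 26%,
  FLT3-ITD 22%, down to rare spliceosome hits), and the latent correlation
  encodes the known co-occurrence skeleton (NPM1 with FLT3-ITD/DNMT3A and
  normal karyotype, TP53 with complex karyotype and chromosomal losses,
  ASXL1/SRSF2/RUNX1 with age, negative NPM1–RUNX1 and
  karyotype-exclusivity entries), repaired to the nearest positive-definite
  correlation.
- **Response.** CR ~ Bernoulli(logistic(x)) with an intercept of 1.15 and
  adverse weights on age, TP53, complex karyotype, RUNX1, ASXL1, −7,
  FLT3-ITD and favorable weights on NPM1, t(8;21), inv(16); this yields a
  ~71% CR rate.
- **Survival.** OS follows a Weibull proportional-hazards model (shape 0.9,
  scale 19 months) with a covariate linear predictor, mixed with a 20%
  long-survivor ("cure") fraction that never has an event — a plain
  Weibull cannot produce the late plateau seen in real OS curves. The
  population (uncensored) median OS, ~17.5 months, is computed by seeded
  200k-draw quadrature and stored as ground truth. EFS is OS minus a
  non-negative gap Δ (zero with probability 0.35 — death without a prior
  event — else gamma(1.5, 6) months), clipped at zero.
- **Censoring.** One administrative draw per patient: entry uniform on
  0–84 months before a 132-month horizon, censoring both endpoints jointly
  (EFS censored at min(censor time, EFS)). This gives a reverse
  Kaplan-Meier median follow-up near 90 months and makes an EFS follow-up
  longer than the OS follow-up structurally impossible.
- **Missingness.** MCAR per variable, applied last: 3% on blood counts, 2%
  per alteration, 1.1% on disease-onset status, 0 on endpoints by default;
  all rates are user-configurable. MCAR is chosen deliberately — it keeps
  parameter-recovery tests interpretable, at the cost of not exercising
  informative-missingness behavior.

What the fixtures do *not* emulate: real trial cohorts have informative
censoring patterns, measurement batch effects, genuinely non-Gaussian
dependence (e.g. strict mutual exclusivity rather than negative latent
correlation), and protocol-driven missingness. Tests passing on fixtures
therefore demonstrate correctness of the estimators and pipeline under a
known truth, not performance claims about any real data set.

## Copula generator

Fitting: each variable gets an empirical marginal — the sorted non-missing
values for continuous/time kinds, (optionally Laplace-smoothed) category
proportions otherwise — plus its missingness probability. Dependence is
estimated on the latent normal scale, pairwise-complete: Pearson
correlation of van der Waerden scores for continuous pairs; a polyserial
moment estimator for continuous–categorical pairs (exact for a latent
bivariate normal, since E[z₁ | z₂ ∈ I] = ρ·E[z₂ | z₂ ∈ I]); tetrachoric
maximum likelihood for categorical pairs, solved by vectorized bisection on
a Gauss-Legendre evaluation of the bivariate normal CDF, with K-level
variables handled by averaging the tetrachorics of all cumulative 2×2
collapses (collapsing at thresholds preserves the latent ρ). Undefined
entries (fewer than 3 complete pairs, degenerate margins) are set to 0 and
the matrix is repaired by eigenvalue clipping at 1e−8 with rescaling to
unit diagonal — idempotent on PD inputs.

Missingness is realized as one extra latent mask dimension per affected
variable, for all kinds. Putting `na` into the cumulative ordering of the
value dimension itself would mechanically correlate missingness with
extreme values; a separate mask dimension keeps the value distribution and
the missingness process distinct while still letting masks correlate with
anything else through the copula.

The survival block drops the EFS time from the copula and models the gap
Δ = OS − EFS (computed on rows where both are observed) as a continuous
variable alongside OS time and the two event indicators. Sampling inverts
each marginal at the Gaussian-copula uniforms — continuous values by
empirical-quantile interpolation, hence bounded to the observed training
range (a deliberate, documented fidelity limitation: genuine outliers
beyond the training support are never produced) — and reconstructs
EFS = max(0, OS − max(0, Δ)), so EFS ≤ OS holds in 100% of sampled rows by
construction rather than by filtering.

Hyperparameters (latent shrinkage toward identity, continuous jitter
bandwidth, category smoothing) default to 0 and can be tuned by seeded
random search whose objective averages three holdout scores chosen for
clinical relevance: support coverage of CR, Kaplan-Meier divergence of OS,
and moment agreement of the Δ distribution, equally weighted (a declared
choice; nothing in the problem fixes the weighting). Trial t depends only
on (seed, t), so the best objective is non-decreasing in the budget.

## Evaluation metrics

All scores are normalized to [0, 1], equal 1.0 on an exact self-comparison,
and are emitted with per-variable breakdowns so alternative aggregations
can be recomputed.

- **Regularized Support Coverage.** Per variable, categories are the
  declared levels plus `na` (continuous variables enter through their
  10-bin decile quantization on the real cohort's edges);
  S_v = mean over categories of min(1, p̃_syn/p̃_real) with Laplace-smoothed
  proportions p̃ = (count + 1)/(N + K); overall = mean over variables.
  Smoothing keeps a missed rare category from zeroing the score.
- **Basic Statistical Measure.** Continuous/time variables are min-max
  normalized by the real cohort; per statistic s ∈ {mean, median, SD}:
  clip(1 − |s_real − s_syn|, 0, 1), averaged over statistics and variables.
  Variables with < 2 non-missing values on either side are excluded with a
  warning.
- **Log-Transformed Correlation Score.** 1 minus the mean absolute
  difference of the two association matrices over defined off-diagonal
  pairs. Associations are |Pearson r| on log1p-transformed pairwise-complete
  values (continuous×continuous), Cramér's V (categorical×categorical) and
  the correlation ratio η (mixed); `na` is excluded — a modeled missing
  state must not masquerade as a numeric level in correlations.
- **Survival fidelity.** On the union grid of both step curves, carried
  forward flat beyond their last observation and integrated over the real
  cohort's follow-up window T: KM divergence = 1 − (1/T)∫|S_real − S_syn|;
  optimism reports the signed area (1/T)∫(S_syn − S_real) next to
  1 − |signed|; short-sightedness = 1 − max(0, (T_real − T_syn)/T_real),
  with no penalty for a synthetic horizon overshooting the real one. The
  grid convention is recorded in the report metadata.
- **Privacy.** All variables are binned to 10 empirical deciles of the
  original cohort (equal-width bins would collapse the heavy-tailed blood
  counts into one bin), missing → `na`, and minimum Hamming distances are
  computed record-wise. The training side aggregates as the mean over four
  test-set-sized training subsets rather than over their union — the
  subsetting exists to compare at equal reference sizes, and a pooled
  reference would mechanically shrink minima. Leakage coefficient =
  (syn→test)/(syn→train) − 1, breach above 0.05; a syn→train of exactly 0
  (verbatim copies) forces the breach flag with an explanatory note. A
  context-only baseline column evaluates test→subset and subset→test
  distances; its orientation is a declared convention. Exact matches are
  counted on raw records with missing-equals-missing.

## Statistical analysis conventions

Quartiles use linear interpolation (recorded in summary metadata).
Percentages are reported over total n with missing counts alongside;
two-sample tests use non-missing denominators. Two-sample continuous
comparisons gate on Shapiro-Wilk at α = 0.05 (subsampled to 5000 with a
fixed seed, inside the test's validity range): both normal → unpaired
t-test, else Wilcoxon rank-sum with tie-corrected normal approximation and
continuity correction, and the chosen test is reported. Categorical
comparisons use two-sided Fisher's exact tests, per level vs rest for
multi-level variables. Cox models use Breslow tie handling (switchable to
Efron); Kaplan-Meier ties resolve events before censorings. The reverse
Kaplan-Meier follow-up CI uses the log(−log) transform with Greenwood
variance. α = 0.05 two-sided throughout, no multiplicity correction
(matching univariable exploratory practice); Benjamini-Hochberg is
available behind a flag for users who want it. Concordance cells classify
each marker-endpoint pair from the signs of the log effects and the two
significance flags; "inverse" requires opposite directions with at least
one significant effect — two non-significant estimates straddling 1 carry
no evidence of disagreement.

## Numerical and design notes

- Tetrachoric bisection: 60 iterations on ρ ∈ [−0.999, 0.999] with a
  32-node Gauss-Legendre path integral; saturated tables clamp at ±0.999,
  degenerate margins return 0.
- The privacy subset partition sizes at min(test_n, ⌊n_train/k⌋); surplus
  rows are left unassigned with a warning (1606 → 1284/322 split → four
  subsets of 321, surplus 0, matching the balanced design).
- Pipeline seeds fan out from one global seed via `SeedSequence.spawn`, all
  reduced below 2³¹; rerunning a serialized config reproduces every number
  exactly (tested byte-for-byte on the JSON bundle).
- Problem sizes: the default pipeline and examples run at the study size
  n = 1606; Monte-Carlo recovery tests use 20 000-row fixtures, where
  alteration frequencies recover within ±0.01, latent correlations within
  ±0.05 and planted hazard ratios within ±0.05.

## Known limitations

The generator cannot extrapolate beyond observed continuous supports, does
not model informative missingness or time-varying effects, and its Gaussian
dependence cannot express strict mutual exclusivity. The univariable HR of
a marker under a cure mixture is attenuated relative to the conditional
log-hazard used in simulation (proportional hazards does not hold
marginally), so direction/significance concordance — not HR equality — is
the right acceptance notion for risk-marker preservation. External
synthetic cohorts plug into the same evaluation path via CSV + schema
sidecar, without running the bundled generator.
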