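# Methods

## Quotient panel

All concentrations are normalised to mg/L at ingestion; the CSV loader
accepts a per-column units declaration (`g_per_L` columns are scaled
×1000), since laboratories commonly report serum albumin and IgG in g/L.
Quotients are dimensionless only under consistent units, which is why the
conversion lives in the loader rather than the arithmetic.

Hyperbolic reference curves have the form a·√(Qalb² + b) − c with a > 0,
strictly increasing in Qalb with asymptotic slope a. For IgG the
constants are fixed (0.93, 6·10⁻⁶, 1.7·10⁻³). For KFLC they are a
configuration input: the upper discrimination line defaults to
(3.27, 33·10⁻⁶, 8.2·10⁻³), the widely used KFLC hyperbolic function from
the quotient-diagram literature. The `mean` and `low` curves shipped
alongside are visual-band aids for diagram export obtained by scaling the
upper line; they enter no computed statistic, and users with
laboratory-specific constants should supply their own triples.

The KFLC intrathecal fraction (1 − Qlim/Qκ)·100 % is returned raw:
negative values mean the measured quotient sits below the reference line.
Positivity is strict (IF > 0). An opt-in clamp-at-zero mode exists
because some laboratories report censored-at-zero fractions, but it is
off by default so that distributional summaries remain honest.

CSF KFLC below the 0.3 mg/L detection limit (or recorded as
unmeasurable) is imputed at half the limit — 0.15 mg/L — with a
censoring flag preserved through CSV round-trips (an empty cell encodes
"unmeasurable"). Note the imputation itself can produce kappa indices in
the 5–8 range when serum KFLC and Qalb are both low; this is a property
of the rule, not a bug, and it measurably adds false positives near the
5.8 cut-off.

## Diagnostic accuracy

- Proportion CIs are exact Clopper–Pearson intervals
  (`statsmodels.proportion_confint(method="beta")`). The tabular display
  convention rounds point percentages half away from zero, and CI bounds
  through a one-decimal intermediate (91.49 → 91.5 → 92), which is how
  clinical tables transcribed from one-decimal software output behave.
- ROC curves are empirical over all distinct thresholds (markers are
  higher-is-positive); the AUC is the rank/concordance statistic with
  ties counting one half. Curve points come from scikit-learn; the AUC
  variance and the paired equality-of-AUC test use the DeLong structural
  components (verified to 12 digits against R `pROC::roc.test` on a
  fixed instance). For a dichotomised marker the AUC reduces to
  (sensitivity + specificity)/2 and its CI uses the same DeLong variance
  computed from the 2×2 counts.
- Youden optimisation scans midpoints between adjacent distinct observed
  values plus one candidate beyond each extreme. Ties on J break toward
  the higher specificity, then the larger cut-off — deterministic and
  conservative toward false positives. Reported cut-offs are rounded to
  display precision (one decimal for the kappa index, whole per cent for
  KFLC IF); the comparison operator (≥ vs >) is a per-marker parameter
  because fixed conventions differ (kappa index ≥ 5.8, KFLC IF > 0).
- Metrics with a zero denominator are reported as NaN and flagged
  undefined, never silently zero.

## Synthetic cohort generator

The generator exists so every pipeline stage can be exercised without
patient data. It emulates a 540-patient mixed neurological cohort with
eleven diagnosis groups sized 84 (MS) / 28 / 23 / 42 / 50 / 28 / 62 / 25
/ 61 / 63 / 74; the first five groups form the CNS
inflammatory/infectious (CNSID) outcome. The published per-group counts
sum to 537 against a stated total of 540; the three unaccounted patients
are assigned to the catch-all miscellaneous group.

Group-conditional distributions are lognormal, parameterised by target
arithmetic mean ± SD through exact moment matching
(σ² = ln(1 + (SD/mean)²)). Lognormality is an assumption, chosen because
concentrations are positive and right-skewed with SD/mean ratios above
one; its known cost is a light left tail — an MS kappa-index lognormal
matched to mean 78.6, SD 105.8 puts only ~2% of mass below 5.8, so
synthetic MS sensitivity at that cut-off runs near 96% where a real
mixed cohort shows ~89%. The generator draws the kappa index, IgG index
and Qalb directly (these carry the published moments) and back-computes
CSF concentrations, e.g. CSF KFLC = kappa index × Qalb × serum KFLC.
The MS group uses the published MS moments; the ten non-MS group
parameterisations are package choices constrained to reproduce the
non-MS aggregate (kappa ≥ 5.8 in ~16% of non-MS patients, OCB in ~11%,
inflammatory non-MS groups near 30% for both).

IEF patterns are drawn per group from base probabilities (MS:
2/4/6/1/54/17/0 over the seven categories). OCB positivity is linked to
the patient's within-group kappa-index quantile u by a logistic model:
log-odds = b₀ + ln(D)·(2u − 1), where D is `ocb_kappa_dependence` and b₀
is solved (64-point Gauss–Legendre quadrature + bisection, fully
deterministic) so the group's marginal OCB rate equals its base rate.
The quantile uses the post-imputation kappa index, so detection-limit
artifacts stay coupled to the pattern. The default D = 2·10⁴ makes the
pattern nearly threshold-determined by the latent synthesis level —
appropriate, since OCB and the kappa index are two readouts of the same
intrathecal process — and was calibrated by simulation so cohort-level
OCB/kappa concordance centres near 0.90 (all of 30 seeds inside
[0.85, 0.95]; smaller multipliers centre it at 0.80–0.87).

Randomness: a single integer seed drives a `numpy` `SeedSequence` with
one spawned substream per diagnosis group in fixed enum order, so editing
one group's parameters leaves the other groups' draws untouched. Group
sizes are apportioned from weights by largest remainder, deterministic.

What passing tests on synthetic cohorts do **not** show: the generator
matches first/second moments, pattern frequencies and one dependence
structure, not per-patient joint distributions, age/sex structure, or
assay noise; conclusions about real cohorts need real cohorts.

## Study pipeline

`run_study` derives the panel, then produces descriptive MS vs non-MS
summaries, the kappa/OCB concordance with a per-diagnosis discordance
breakdown, accuracy tables for the MS and CNSID outcomes over six
markers (OCB; OCB or single CSF band; kappa index at the fixed and at
the Youden-optimal cut-off; KFLC IF > 0 and at its Youden optimum), and
the single-band subcohort reclassification. The MS outcome counts MS
only (CIS is a negative). An outcome lacking two records in either class
is skipped with a recorded warning rather than fabricated; the run fails
only if both outcomes are unusable. The pipeline is deterministic:
identical records and config give bit-identical reports.

Problem sizes used by the shipped checks: synthetic cohorts of n = 540
(default configuration) and n = 5000 (boundary-recovery configuration),
300 replicates at n = 120 for the DeLong null calibration and 200 at
n = 500 for its power check — all chosen to keep Monte-Carlo error well
below the asserted margins.

## Known limitations

- The KFLC mean/low diagram curves are package-chosen visual aids, not
  published constants.
- Lognormal marginals understate the left tail of the MS kappa-index
  distribution (above).
- The DeLong comparison assumes paired markers on the same subjects;
  unpaired designs are out of scope, as are multi-class or
  covariate-adjusted ROC.
- IEF patterns are input categories; no band counting or gel image
  analysis is attempted.
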