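# Methods

## The measurement model

Every measure is compared at farm level. For one measure, the paired
values of the two observers over the n visits form a complete n×2 table
modelled by the two-way layout

    x_ij = μ + α_i + β_j + ε_ij ,

with visit (object) effects α_i, observer effects β_j, and residual
ε_ij. With a single observation per cell the observer-by-object
interaction cannot be separated from the residual and is absorbed into
ε. The variance components are method-of-moments estimates from the
mean squares:

    σ²_obj = (MS_rows − MS_err)/k ,   σ²_observers = (MS_cols − MS_err)/n ,
    σ²_residual = MS_err ,            k = 2 observers.

Negative estimates are truncated to zero before any derived statistic,
which keeps the agreement-form ICC

    ICC = σ²_obj / (σ²_obj + σ²_observers + σ²_residual)

inside [0, 1]. A table with all components zero (every cell identical)
carries no reliability information; the ICC is reported as *not
computable* rather than 0, which would wrongly assert total
unreliability.

Two observer pairs (A–B and A–C) are analysed as one comparison: the
partner columns are concatenated into a single "BC" column, each paired
visit contributing exactly one row. This treats B and C as
interchangeable raters relative to A, which is the standard pooling when
the two pairwise comparisons behave alike; it understates observer
variance if B and C have opposite biases.

### The four statistics

- **RS** (Spearman) is the Pearson correlation of midranks — pure rank
  agreement, insensitive to monotone recalibration between observers.
  It is undefined for a constant column (all ranks tie) and raised as an
  error rather than returned as 0 or NaN silently.
- **ICC** (agreement form) penalises observer bias and residual noise
  alike. Both RS and ICC grow with between-farm spread: a homogeneous
  farm sample can make them small even when observers agree closely.
- **SDC** = 1.96·√2·SEM with SEM = √(σ²_observers + σ²_residual): the
  smallest change in a farm's score distinguishable from measurement
  error, in the measure's own units. Some sources print the formula
  without the square root, i.e. applying 1.96·√2 to the variance itself;
  that form is dimensionally inconsistent (variance, not measure units)
  and is provided only behind `sdc(..., literal_formula=True)` for
  comparison with such sources.
- **LoA** is computed directly from the observed differences d = A − BC
  as mean(d) ± 1.96·sd(d) (sample sd), the Bland–Altman standard, rather
  than through the variance components. On a balanced table with no mean
  observer shift the two routes agree: for k = 2, sd(d)² = 2·MS_err
  exactly, and the observer component only absorbs the squared mean
  difference (σ²_observers ≈ d̄²/2 for large n). The property test
  asserts the half-widths agree within 2 % on zero-bias tables; with a
  real bias the components route is wider by construction.

### Acceptability labels

RS/ICC: ≥ 0.7 good, ≥ 0.4 acceptable (inclusive), else not acceptable.
SDC ≤ 0.1 and LoA ⊆ [−0.1, 0.1] are acceptable *on the fraction scale*:
prevalences and behaviour fractions are thresholded directly; the QBA
score is first divided by its theoretical range (derived from the
weights and the 125 mm scale, or supplied as `score_range` in the YAML
config), and raw adjective differences by the 125 mm scale. Cough and
sneeze rates are thresholded in their own units (per-pig rates of
magnitude ~1–10 would need a study-specific bound; the default mirrors
the fraction convention).

### Rare-measure exclusion

A score category whose mean prevalence over both observers and all
visits is ≤ 0.5 % (configurable) is excluded before analysis, with the
reason recorded: at 29 visits with tens of animals each, a 0.05 %
category rests on one or two animals and any reliability estimate for it
would be noise. Non-prevalence measures are never excluded.

## Scoring conventions

- **QBA**: score = intercept + Σ w_k·N_k with intercept −4.5367 and one
  0–125 mm mark per adjective per visit. The published weights live in
  the protocol document and are deliberately not embedded here;
  `synthetic_qba_weights()` provides a labelled synthetic stand-in
  (valence-signed, theoretical range width ≈ 24.2 score units) for
  simulation and testing only.
- **Behaviour fractions**: counts are pooled over all scans and
  viewpoints *before* division — the fraction is then the fraction of
  all observed active pigs, with each scan weighted by how many active
  pigs it saw. Per-viewpoint averaging would instead weight viewpoints
  equally; with similar pen sizes the two differ little, and the pooled
  convention is the natural reading of "percent of total active
  behaviour".
- **Prevalences**: ternary parameters are reported as three separate
  per-category prevalences treated as independent measures downstream,
  even though they sum to one by construction.
- All fractions are stored in [0, 1] and rendered as percentages only at
  report time.

## The synthetic-data generator

The generator emulates the paired-observer study design — 29 visits on
24 farms, observer A paired with B on 19 visits and with C on 10, both
rating the same animals independently — with known ground truth:

- **Continuous measures** are drawn from the two-way model itself:
  object effects ~ N(0, σ²_obj), observer effects fixed at configured
  biases, residuals ~ N(0, σ²_res). For two observers with fixed biases
  the implied observer component is (b_A − b_BC)²/2, so the true ICC is
  known in closed form. Values are clipped (not resampled) to the legal
  range and the clipping fraction reported; above ~5 % clipped,
  normal-theory recovery checks are no longer meaningful.
- **Animal scores**: farm-level true prevalences are Dirichlet-drawn
  around a configured base vector (concentration 40 by default, giving a
  realistic between-farm spread); each animal's true category follows
  the farm's prevalence, and each observer's recorded category passes
  through a row-stochastic misclassification matrix independently given
  the truth. The default matrix confuses adjacent categories with total
  probability 0.08 — trained observers mostly disagree by one scale
  step. An identity matrix gives error-free observers; a uniform matrix
  destroys all reliability (ICC → 0).
- **QBA and scans**: adjective marks are truncated normal on [0, 125]
  around a farm-level latent intensity (farm sd 18 mm, observer sd 9 mm
  by default); scan counts are multinomial over the six behaviour
  categories with farm-level Dirichlet probabilities, drawn
  independently per observer. Cough/sneeze counts are gamma-Poisson with
  shared farm-level intensity.

Defaults: 60 animals per visit, 3 viewpoints × 5 scans × 50 pigs, ~50 %
resting. The seed contract is strict: identical configuration (including
seed) reproduces bit-identical datasets.

What the generator does **not** emulate: spatial pen structure,
time-of-day and seasonal effects, observer drift over the study, and
correlated misclassification (e.g. both observers misled by the same
soiled legs — the mechanism that can make a parameter like bursitis
unreliable in the field). Passing recovery tests therefore show the
statistics are computed correctly under the stated model, not that any
field instrument is reliable.

## Problem sizes in the tests

The recovery property is checked at the study's own size: replicated
29-visit studies for true ICC ∈ {0.2, 0.5, 0.8} (200 replicates in the
acceptance suite, 60 in the unit suite) recover the mean ICC within
±0.1 and the mean SDC within 15 % relative error; LoA coverage is
checked at 5000 pairs against the nominal ≈95 %. Recovery runs use an
unbounded value range so boundary clipping cannot bias the check.

## Numerical choices

- Mean-squares ANOVA on float64; SS_err is clamped at 0 against
  cancellation on exact-agreement tables.
- Spearman ties take midranks; no permutation p-values are computed.
- sd in the LoA uses ddof=1 (sample standard deviation).
- Report values are rounded to 2 decimals for display; a parallel
  full-precision CSV is always written.
- Data-file validation is fail-open (all violations collected with file
  and row); configuration validation is fail-fast.

## Known limitations

- Confidence intervals for the ICC and hypothesis tests are out of
  scope, as are weighted kappa and other agreement statistics.
- The A-vs-BC pooling assumes the partner observers are exchangeable;
  a per-pair analysis would need to re-run the engine on subset tables
  (supported, but not a built-in report).
- Aggregation of measures into welfare criteria/principle scores
  (I-splines, Choquet integrals) and resource-based measures are not
  implemented; comparison stops at parameter level.
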