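# Methods

## The instrument

The Awake Bruxism Identification Tool (ABIT) screens children aged 8–12 for
awake bruxism (AB) — masticatory muscle activity during wakefulness:
repetitive or sustained tooth contact and/or bracing or thrusting of the
mandible. Rather than a present/absent diagnosis it places a child on an
"AB Spectrum" built from six components:

| component | what it is | raw range | positivity cut-off |
|---|---|---|---|
| R1 | parents' report, 3 Likert questions | 0–12 | ≥ 1, subject to the null rule |
| SR | child self-report, same 3 questions | 0–12 | ≥ 1, subject to the null rule |
| R2 | parents' report after 7 days of guided observation | 0–12 | ≥ 1, subject to the null rule |
| ICA | intraoral exam: linea-alba hyperkeratosis, labial hyperkeratosis, labial/tongue/buccal indentation | 0–6 declared | ≥ 1, valid only with ECA ≥ 1 |
| ECA | extraoral exam: masseter and temporal hypertrophy | 0–2 | ≥ 1, valid only with ICA ≥ 1 |
| EMA | analog diary: 7 days × 6 emoji slots, painted per perceived event | 0–42 | ≥ 4 days with paintings |

Each Likert question scores never=0, almost never=1, sometimes=2, most of
the time=3, always=4; "don't know" (DK) carries no score and is excluded
from sums. The per-tooth wear grades (five-point ordinal scale, 0–4) are
recorded as complementary data and never scored. The anamnesis
sleep-bruxism flag is metadata only.

### Null rules

Two results are *null* — non-positive despite a nonzero raw sum:

* a triplet whose only nonzero scored answer is a single "almost never"
  (score 1). DK answers are ignored entirely, so (DK, almost never, DK)
  is null and an all-DK triplet is zero (flagged with a validation
  warning). Two answers at score 1 are positive, not null — the rule
  speaks of *one* behavior among the three.
* an EMA diary painted on 1–3 days (below the 4-day cut-off).

Null components contribute 0 points to the spectrum total: null is grouped
with zero under "Not AB", and accumulating null points could give a
"Not AB" child a nonzero spectrum.

### Categories

Any positive triplet gives report/self-report evidence (`AB based on
R/SR`); report evidence together with a positive EMA upgrades to the
combined category (`AB based on R/SR and EMA`, replacing the bare report
category); a positive EMA alone is `AB based on EMA`; the clinical category
(`AB based on CA`) requires at least one finding on *both* the intraoral
and extraoral side and combines with any other. A record with no category
is `Not AB`.

Two deliberate readings where the published description is silent or
ambiguous:

* an isolated one-sided clinical finding (e.g. ICA = 1, ECA = 0) assigns no
  category — isolated clinical markers lack predictive power — but its
  points still enter the spectrum total, since the instrument sums both
  clinical scores into the spectrum regardless of the conjunction;
* a positive self-report alone (parents report all "never") does qualify
  for `AB based on R/SR`: the category is defined over all three of
  R1/SR/R2.

Event counting (the perceived-events table) tallies any answer scoring
above 0, including answers inside null triplets: it describes perceived
events, while the null rule governs component positivity.

### The declared 0–96 range

The published instrument describes the AB Spectrum as ranging 0–96, but the
declared per-component maxima sum to 3×12 + 6 + 2 + 42 = 86. No assignment
of the named findings yields the missing 10 points (relatedly, the declared
ICA maximum is 6 while only five intraoral findings are named; the
definition keeps 6 and permits a sixth configurable finding slot, shipped
disabled). This package treats the component maxima as authoritative —
every scoring rule derives from them — so `max_spectrum()` reports the
attainable 86 and the headline 96 is regarded as a publication erratum.
One acceptance test asserts the published 96 verbatim and is expected to
fail for exactly this reason.

## Reliability statistics

Temporal stability of the instrument is assessed on matched test/retest
cohorts (15-day interval in the original pilot):

* **Cronbach's alpha**, `α = k/(k−1)·(1 − Σᵢ s²ᵢ / s²_total)` with n−1
  sample variances, computed per administration over the three questions
  (k = 3, subjects = participants): R1 from the test stage, R2 from the
  retest stage.
* **Single-measures ICC** from the two-way subjects × administrations
  ANOVA, in the McGraw–Wong forms ICC(C,1) (consistency,
  `(MS_R − MS_E)/(MS_R + (k−1)MS_E)`) and ICC(A,1) (absolute agreement,
  adding `(k/n)(MS_C − MS_E)` to the denominator). The two forms coincide
  exactly when MS_C = MS_E; agreement ≤ consistency whenever
  MS_C ≥ MS_E *and* MS_R ≥ MS_E (a negative ICC flips the ordering).
* **Lin's concordance correlation coefficient**,
  `ρc = 2s_xy / (s²_x + s²_y + (x̄−ȳ)²)` with n-denominator moments, with a
  95% CI from the Fisher z-transform using Lin's (1989) variance estimator.
  The variance is evaluated in terms of the bias-correction factor
  C_b = ρc/r, which removes the spurious 0/0 at r = 0 (the limit is
  C_b²/(n−2)); for |ρc| = 1 or a one-sided zero variance the interval
  collapses onto the point estimate. A closed-form CI was preferred over a
  bootstrap so results are reproducible at pilot sizes (n = 5).

Because the published protocol does not state which score the ICC/CCC were
computed over, the report computes them over paired spectrum totals *and*
over paired report sums (R1+SR+R2), labelled separately. Degenerate inputs
(zero total variance, constant matrices) raise `UndefinedStatisticError`
rather than returning NaN.

The pilot's printed coefficients (alpha 0.462/0.827, ICC 0.880 consistency
/ 0.831 agreement, CCC 0.997 with CI 0.979–0.999) are documentation
examples only: the participant-level data behind them are not published, so
they cannot be recomputed and are not asserted anywhere.

## Synthetic cohorts

The generator emulates the data structure the instrument assumes, so
scoring, classification and reliability are testable without any data
download. Each child has a scalar latent propensity θ — the mean number of
AB events per day — drawn log-normally (σ = 0.5, mean preserved) around
`theta_active` (default 1.5/day) or `theta_inactive` (0.05/day) according
to `prevalence` (0.4). The three behaviors share θ through fixed
multipliers (0.5, 1.0, 0.9): clenching is the most perceived event,
followed by bracing/thrusting, then grinding, matching the ordering the
pilot observed. Defaults describe a pilot-scale clinic sample of 10
children; they are conditions, not tuning knobs.

* **Diary**: daily events ~ Poisson(θ) truncated at the 6 slots the sheet
  offers; each event is painted with probability `adherence` (0.8);
  painted slots are placed in a per-day random order. The generator can
  never emit more than 6 painted slots per day.
* **Likert answers**: the behavior rate θ·mult maps to a base category
  through fixed thresholds (0.05, 0.35, 1.0, 2.5 events/day — constants
  documented here, not fitted: no calibration data exist), then moves one
  category up or down with probability `report_noise` (0.1).
* **Clinical findings**: independent Bernoulli per finding with probability
  `clinical_prob_active` (0.15) or `clinical_prob_inactive` (0.03); drawn
  once per child since physical signs are stable over a 15-day interval.
  Tooth wear on eight FDI index teeth uses the same probabilities (grade 2
  half as likely as grade 1).
* **Test–retest coupling**: θ is paired across stages through a Gaussian
  copula with correlation `retest_rho` (0.9) — the simplest one-parameter
  correlation structure — and all count/finding draws use common random
  numbers: one uniform stream per child, shared across stages and consumed
  through inverse CDFs. Only the report-noise draws are stage-specific.
  Consequently `retest_rho = 1` with `report_noise = 0` reproduces the test
  records exactly at retest, and test-retest dependence decays smoothly as
  `retest_rho` drops.

What the generator does **not** emulate: dropout, school/home context
effects, the behavioral-change (awareness) effect of repeated
self-monitoring, DK answers, and any systematic disagreement between
parent and child perception beyond independent noise. Passing tests
therefore show that the scoring engine implements the instrument's rules
and that the reliability statistics recover known parameters under the
stated model — not that the instrument is valid on real children.

## Numerical choices and problem sizes

Identity-line statistics are computed in float64 throughout; oracle
comparisons in the tests are at 1e-10 (closed forms) and Monte-Carlo checks
at 3 standard errors. The test suite enumerates all 5³ triplet patterns,
all 2⁷ clinical finding combinations and all 3⁶ component-status
combinations exhaustively. Simulation-based checks use cohorts of 150–400
children and 10⁴ random diaries; the CCC parameter-recovery check uses 100
replicates of 200 matched-moment Gaussian pairs at latent correlation 0.9.
The acceptance script simulates 200 paired children. These sizes give
Monte-Carlo errors well below the asserted tolerances while keeping the
whole suite under a minute on one CPU.

## Known limitations

* The engine implements the instrument as published; it cannot validate
  the instrument itself (no electromyography ground truth exists here).
* The CCC confidence interval assumes approximate normality of the paired
  scores; spectrum totals are discrete and skewed at pilot sizes, so the
  interval is indicative rather than exact for n ≈ 5–10.
* Null EMA diaries ("some paintings, fewer than 4 days") are treated as a
  single status; the underlying slot counts are preserved in the scores
  table for finer analysis but play no role in classification.
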