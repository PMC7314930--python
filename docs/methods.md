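# Methods

This note documents the statistical procedures implemented in
`methpanel`, the choices made where the underlying assay description left
the design open, and what the synthetic-data tests do and do not
demonstrate.

## 1. Calling model

**Validity.** Every sample carries an *ACTB* triplicate as an internal
amplification control; a sample is invalid when its ACTB Ct is greater
than 41.0 cycles (strictly — Ct = 41.0 passes). The assay description
does not say how a *triplicate* ACTB is reduced to "the" ACTB Ct. The
default here is the **minimum over detected replicates**: the control
exists to prove that amplifiable DNA is present, and one passing well
proves it. A sample with no ACTB amplification at all is invalid.
`mean` and `all` aggregations are available
(`validate_sample(..., aggregation=...)`); the choice only matters for
samples whose ACTB wells straddle the limit. Invalid samples are excluded
from numerators and denominators of every downstream rate — the only
treatment consistent with using the control to avoid false negatives.

**Detection and k-of-3 calls.** A well detects its target when Ct is
*strictly* below the marker's detection limit (45.0 cycles for mSEPT9,
50.0 for mSDC2; 50 is the maximal number of cycles run). A marker is
positive under the k/3 algorithm when at least k of 3 wells detect.
A rule may add a mean-Ct requirement, applied as *mean of the detected
wells strictly below the cut-off*. Aggregating over detected wells only
is a choice: under the operative 3/3 rule all three wells are detected,
so the choice is invisible in every case the operative rule exercises and
matters only for exploratory 1/3 and 2/3 rules with mean cut-offs.

**Panel.** The panel call is the OR of the marker calls. Monotonicity
properties follow directly and are enforced by property tests: raising k
or lowering a mean-Ct cut-off never creates a positive, and the OR never
has a lower positive rate than either arm.

**Censored score.** For ROC analysis each marker's continuous score is
its mean detected Ct, with samples that never amplified assigned exactly
50.0; the panel score is the **minimum** of the two marker scores, the
continuous analogue of the OR rule (`combine="mean"` is available). The
score therefore has a large point mass at 50.0 in controls; ROC and AUC
code treat ties explicitly (half weight), and the trapezoidal AUC equals
the exhaustive pairwise rank statistic, which the tests verify against a
brute-force oracle.

## 2. Diagnostic statistics

* **Proportion CIs**: Wilson score with continuity correction, two-sided,
  clamped to [0, 1]. This method was identified by inversion: it
  reproduces all 25 of the assay's reported intervals to the printed
  decimal (e.g. 4/6 → 24.1–94.0%), which plain Wilson and
  Clopper–Pearson do not. The alternatives remain available behind
  `proportion_ci(..., method=...)` and delegate to statsmodels.
* **Youden index**: J = sensitivity + specificity − 1, identically the
  case rate minus the control rate; both phrasings are asserted equal.
* **AUC CI**: DeLong's asymptotic variance (the standard for diagnostic
  AUCs); verified against a 2,000-resample bootstrap percentile interval
  on a fixture (agreement within 0.03).
* **Subgroup comparisons**: two-sided Welch t-test on the 0/1 positivity
  indicators by default, since the assay's analysis reports t-tests on
  positivity. A pooled Student t and a chi-square (no continuity
  correction) are provided; on the reported male/female mSEPT9 split
  (46/53 vs 29/41) Welch gives p = 0.066, Student p = 0.055 and
  chi-square p = 0.054, so the chi-square variant is the one that matches
  the reported figure. No multiplicity correction is applied.
* **Rounding**: tables print percentages to one decimal, half-up;
  computation is at full precision throughout.

## 3. Two-step cut-off search

Step one tabulates each marker under 1/3, 2/3, 3/3. Step two crosses the
mSEPT9 3/3 arm with mean-Ct requirements {none, <40, <39, <38} against
mSDC2 {2/3, 3/3} — eight combinations — evaluates each on the training
cohort, and ranks them lexicographically by configurable keys, default
`(youden_crc, youden_aa, specificity)`; exact ties fall to the earliest
(loosest) rule in grid order. The fitted rule is then **frozen** and the
validation cohort only ever scored with it.

A structural fact worth recording: on any dataset realising the reported
single-marker counts, tightening mSDC2 from 2/3 to 3/3 trades at most
5.4 percentage points of CRC sensitivity for 6.2 points of specificity,
so the mSDC2 3/3 variants always dominate on CRC Youden alone and the
pure `youden_crc` maximiser is *not* the operative 2/3 rule. The
operative rule is preferred when advanced-adenoma performance enters the
ranking — which is why the ranking is exposed as a parameter rather than
hard-coded, and why `youden_all` (AA and CRC pooled as cases) is offered.

## 4. Synthetic cohorts

**Latent-state generator.** Per group and marker, a sample carries a
methylated state with probability `q`; wells detect independently with
probability `r` given the state and `b` (background) without it; detected
wells draw Ct from a normal distribution truncated to (20, detection
limit), so a "detected" Ct can never reach the limit. The three-parameter
mixture is the minimal model that reproduces the reported k-of-3 rate
triples: the reported data show strong within-sample replicate
correlation (3/3 rates close to 1/3 rates in CRC), ruling out independent
wells, while a two-parameter (q, r) state model still misses the CRC
mSDC2 triple by 3.6 points; with the background term every reported
triple fits within 1 point. `calibrate_from_rates` inverts the closed-form
k-of-3 tail probabilities by multi-start least squares.

**Default (calibrated) parameters.** Detection parameters are fitted at
call time to the reported training-set triples. Ct locations are not
reported per sample, so they were fixed once on assay-typical grounds:
CRC mSEPT9 ~ N(33, 2.5²), control mSEPT9 ~ N(39.5, 2.5²) (control
positives are weak, near-limit signals — the structure the mean-Ct
tightening exploits), CRC mSDC2 ~ N(36, 3²), control mSDC2 ~ N(43, 3²),
AA intermediate, ACTB ~ N(26, 1.5²); invalid rate 0 (no invalid samples
are reported). Group sizes default to the training design (65/6/55).

**Rule-planted parameters.** For studying whether the grid search can
*recover* a known optimum at realistic sample sizes, a second parameter
set plants the operative rule as the generating truth: CRC mSDC2 wells
detect independently at 76.2% per well (2/3 rate at the reported 83.6%,
3/3 rate only 44% — tightening to 3/3 costs real sensitivity), control
mSDC2 positives are sample-level with nearly equal 2/3 and 3/3 rates
(tightening buys nothing), and control mSEPT9 mean Cts straddle the 38–40
window. Under these conditions the operative rule maximises CRC Youden in
expectation with 4–5 point margins over every competitor, and the search
recovers it in ≈95% of 100 cohorts of the published size. The planted
design is necessary because, per the structural fact in §3, no generator
matching *all* reported marginal rates can make the operative rule the
CRC-Youden optimum.

**Reference cohorts.** `simulate.reference_cohort("training"/"validation")`
expands hand-solved per-sample pattern tables into deterministic cohorts
whose single-marker counts, operative-rule counts, per-stage counts and
sex distributions equal the reported tables exactly. The reported
combination table is internally inconsistent in a few cells (they differ
by one sample from any jointly realisable dataset, e.g. a control union
count exceeding the sum of its feasible parts); where that happens the
pattern tables match the realisable value and the discrepancy is at most
one sample in rows the operative analysis does not use.

**What the synthetic tests do not show.** The generator targets
call-level statistics only: no stool DNA degradation, bisulfite
conversion efficiency, PCR kinetics, or covariate–marker dependence
(tumor size/location effects are not simulated), and the two markers are
drawn independently within a sample, whereas real methylation burdens are
correlated — which is why the calibrated generator's OR-combined
sensitivity runs above the reported panel sensitivity even though each
arm matches. Passing recovery tests demonstrate the pipeline's
correctness under the stated model, not the assay's field performance.

## 5. Numerical and degenerate-input conventions

* Empty Ct cells in CSVs mean "no amplification" and become NaN; missing
  covariates use explicit `unknown`/`NA` tokens, never empty cells.
* Rates with zero denominators raise (single groups) or report n = 0 with
  undefined rate (report tables); an all-negative control column gives a
  CI lower bound of exactly 0.
* ROC requires both classes; DeLong requires ≥ 2 per class; two identical
  degenerate arms compare with p = 1 by convention.
* Tumor size bins are [0, 3), [3, 6], (6, ∞) cm; stage dichotomy 0–II vs
  III–IV with unknown shown but excluded from tests; unknowns are never
  dropped from tables.
* Problem sizes in the stochastic tests: 10,000 samples/group for
  rate-recovery (3-binomial-SE tolerance), 100 replicates of 126-sample
  cohorts for rule recovery, 50,000 samples for the closed-form binomial
  check — all chosen to make Monte-Carlo error small relative to the
  asserted tolerances while keeping the suite fast.
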