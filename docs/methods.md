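# Methods

`chemovote` implements a preference-weighted association analysis linking
patient strain preference (survey votes) to strain chemotype (lot-level
cannabinoid and terpene assays), together with a generative model of the
whole study that plants known effects so the analysis can be validated end
to end.

## The analysis

### Vote tallies and rankings

Respondents name the strain(s) they found most and least effective
(multi-select allowed). For category *c*, the vote count of strain *s* is
the number of respondents whose selection set contains *s*; the category
denominator *n_c* is the number of respondents with a non-empty selection.
Rankings sort by votes descending with alphabetical tie-break (the data
has no principled tie order, and a deterministic rule is required for
reproducibility); reported shares are 100·V_s/n_c. Because of
multi-select, shares need not sum to 100.

The 0–10 effectiveness ratings are summarized over rated respondents only:
sample mean and SD (n−1 denominator), median (mean of central pair for even
n), and a Student-t 95% CI for the mean — t rather than normal because n is
finite and the cost at large n is nil. Side-effect percentages use a
configurable denominator (default: respondents reporting at least one side
effect) since multi-select response tables are often published against an
ambiguous base.

### Vote-weighted group profiles

For the top-k strains of each category (default k = 4), every lot
measurement of an analyte enters the group average weighted by its
strain's full vote count V_s:

    WA = Σ_lots x_lot · V_s(lot) / Σ_lots V_s(lot)

With integer votes this is exactly the mean of the expanded sample in which
each lot value appears V_s times, and the weighted SD is defined as the
population SD of that expanded sample:

    SD_w = √( Σ w (x − WA)² / Σ w )

That frequency-weight reading makes both quantities testable against a
brute-force oracle (`np.repeat` expansion) and invariant to rescaling all
weights. The reported standard error is SD_w/√n where **n is the number of
lot measurements** contributing to that analyte (12 when complete: 4
strains × 3 lots). Votes are preference weights, not independent
measurements; dividing by √Σw would understate the SE by an order of
magnitude.

Missing data carries two distinct states everywhere: *measured zero* (below
detection; contributes 0.0 with full weight, and group averages of exactly
0 are meaningful) and *not tested* (the lab's panel did not cover the
analyte for that lot; the value and its weight are dropped from that
analyte's average only). A `missing_mode="as_zero"` option exists purely
for sensitivity comparison. An analyte not tested in any contributing lot
is reported absent, never zero.

### The association coefficient

Per analyte, with group averages a (most effective) and b (least
effective):

    cc = (a − b) / (a + b) ∈ [−1, 1]

Positive values mean enrichment in the preferred group. cc = +1 exactly
when the constituent is absent from the least-effective group (b = 0 < a),
−1 in the mirror case, and cc is undefined (NA, never 0) when both
averages are zero. The coefficient is computed at full precision and
rounded to 3 decimals only for reporting. A delta-method SE is attached
(∂cc/∂a = 2b/(a+b)², ∂cc/∂b = −2a/(a+b)²).

### Significance

The difference of group means is tested with a two-sided Welch t-test from
summary statistics with Satterthwaite degrees of freedom — the safe default
when group variances differ, which they visibly do for bimodal
constituents such as CBD. Degenerate inputs are defined rather than
undefined: both SDs zero with equal means gives t = 0, p = 1; with unequal
means, p = 0 plus a degenerate-variance flag.

One numerical subtlety matters. The descriptive weighted SD uses the
population (Σw) denominator, which is the oracle-exact convention but a
biased estimate of the sampling SD at n = 12. Feeding it into the t-test
unchanged puts the test's true null level near 0.06 rather than 0.05
(confirmed by direct simulation, 200k draws). The association stage
therefore multiplies each SD by √(n/(n−1)) before testing. Descriptive
outputs (weighted SD, weighted SE) keep the population convention.

Flags: `significant` for p < α (default 0.05) and `marginal` for
α ≤ p < 0.10, mirroring common reporting practice for this design. No
multiple-testing correction is applied to the flags — the panel is treated
as descriptive screening — but a Benjamini–Hochberg adjusted column is
emitted alongside as a clearly supplementary extension.

Terpenes are partitioned into *major* (> 0.05 % w/w in either group
average — the conventional threshold above which a volatile terpene is
considered pharmacologically interesting) and *minor*; cannabinoids and
the total-terpenes aggregate are excluded from the partition.

## The generative model

### Chemotypes and lot assays

Four built-in archetypes span the chemotype families a single producer's
menu typically covers: THC-dominant *kush* profiles rich in
trans-nerolidol/β-caryophyllene, myrcene-dominant THC profiles, a
terpinolene-dominant profile carrying the co-occurring minor monoterpenes
(α-phellandrene, 3-carene, α/γ-terpinene), and a mixed THC:CBD (type II)
profile. Magnitudes are % w/w in the ranges commercial dried-flower assays
report (THC 7–20, individual terpenes 0–0.6).

A lot assay draws each analyte as archetype mean × lognormal noise with
mean 1 and coefficient of variation `lot_cv` (σ² = ln(1+cv²), μ = −σ²/2;
default cv = 0.2, a typical lot-to-lot reproducibility for flower
production). Multiplicative lognormal noise keeps concentrations positive
and right-skewed, and `lot_cv = 0` reproduces the archetype exactly. Lab
coverage masks mark configured (lot, analyte) cells not-tested — the
default study-shaped config masks four GC-MS terpenes on two lots,
mimicking a second lab with a narrower method. The total-terpenes
aggregate is the sum of the lot's measured terpenes.

### The voting model

Respondent r's latent utility for tried strain s is

    u_rs = Σ_analyte w_analyte · mean_s(analyte) + ε_rs,  ε_rs ~ N(0, σ_r)

a linear function of the strain's *archetype mean* concentrations (the
stable chemotype, not one lot's noise) plus independent respondent noise.
Each respondent tries a uniform random subset of 2–6 strains, votes every
tried strain within `vote_margin` utility of the maximum "most effective"
(multi-select arises naturally; default margin 0 gives singleton votes),
and symmetrically for "least effective", with overlap resolved in favour
of "most". Complete ties fall back to a deterministic alphabetical rule
(first strain most, last least). Because the tie-break is label-dependent,
exact label-permutation equivariance holds in the tie-free regime
(σ_r > 0, almost surely no ties), which is the regime every experiment
uses.

The 0–10 rating is round(7.9 + 0.05·u_best + N(0, 1.7)) clamped to the
scale; category and rating items are each answered with configured
probabilities (defaults 0.50, 0.43, 0.59). With the default seven-strain
config these choices produce cohorts whose shape matches the observed
study: ~220/190 category respondents, top-strain votes in the tens, rating
mean ≈ 8.2, SD ≈ 1.5, ~85% rating ≥ 7.

The simulator allows cross-respondent disagreement (the same strain can
lead both aggregate rankings) but not within-respondent contradiction: one
respondent never votes a strain both most and least effective.

### Parameter recovery and calibration

`run_recovery_experiment` replays simulate → tally → profile → associate
over many replicates (seeds spawned from one master seed) and scores:

* **sign recovery** — fraction of (replicate, planted analyte) pairs whose
  coefficient carries the planted sign;
* **false-positive rate** — fraction of null-analyte tests rejected at α,
  with per-replicate rates retained so Monte-Carlo standard errors respect
  the within-replicate correlation of the 30-odd analyte tests.

Replicates with an empty vote category are flagged invalid, excluded from
both rates, and counted. The total-terpenes aggregate is only treated as
null when no individual terpene carries a planted weight.

Two structural facts shape the calibration design:

1. **Group overlap.** With seven strains the top-4 most and top-4 least
   groups necessarily share at least one strain, so the same lot
   measurements sit in both samples of the two-sample test, which makes it
   strongly conservative (measured FPR ≈ 0.01 at nominal 0.05). This is a
   property of the method at study scale worth knowing when reading its
   p-values. Calibration of the test's nominal level therefore uses a
   25-strain menu (a realistic producer catalogue) and the
   `require_disjoint_groups` option, which excludes (and counts)
   replicates whose groups overlap — the regime where the test's
   independence assumption actually holds.
2. **Exchangeability.** A meaningful false-positive rate needs the null to
   be true: all strains share one archetype, so vote-defined groups differ
   only through lot noise. With distinct archetypes and zero planted
   weights, randomly voted groups genuinely differ in composition and the
   test's rejections are not false positives (the `recover` CLI labels
   this accordingly).

Under that design the measured FPR sits within 3 Monte-Carlo SEs of 0.05
(≈ 0.051 over 600+ disjoint replicates), and recovery behaves as expected:
a strong planted weight at low noise recovers its sign in every replicate,
and recovery degrades monotonically toward chance as respondent noise
grows.

## Problem sizes

The test suite's stochastic experiments use 1300 replicates (≥ 500
disjoint) at 200 respondents for null calibration, 100 replicates for
strong-signal recovery, and 80 replicates per noise level for the
degradation curve — sizes at which the Monte-Carlo error is far below the
effects being checked while the whole suite stays fast.

## What the synthetic data does not capture

Real survey cohorts carry recall and selection bias, correlated
strain-exposure histories, dose and set-and-setting effects, and
cross-producer chemotype drift for same-named strains; lot assays carry
inter-lab calibration offsets beyond simple panel coverage. None of these
are modelled. Passing recovery tests therefore shows the *pipeline*
recovers planted linear-utility effects under its own assumptions — it is
not evidence about real-world anxiolytic activity. The biphasic
dose-response of the major cannabinoids is deliberately out of scope.

## Known limitations

* The coefficient conflates effect size with presence/absence: any
  constituent absent from one group hits ±1 regardless of concentration,
  so low-abundance chemotype markers can out-rank abundant constituents.
* The Welch test treats the 12 lot values per group as independent;
  lots cluster within strains, and when chemotypes genuinely differ
  between strains the effective sample size is closer to the number of
  strains than the number of lots.
* Printed report values are rounded to 3 decimals; coefficients computed
  from *rounded* group averages can differ from full-precision ones near
  zero denominators (the package always computes at full precision and
  rounds last).
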