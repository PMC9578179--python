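# Methods

## The problem

In acute respiratory distress syndrome (ARDS), mechanical ventilation itself
injures the lung (ventilator-induced lung injury, VILI). Protective
conventions cap the driving pressure (DP, the inspiratory pressure applied
above PEEP) at a fixed 14–15 cmH2O, but lungs differ: treating the lung as
an elastic material, pressure applied beyond its *elastic limit* no longer
produces recoverable distension — it breaks elastic fibres. This package
implements and evaluates, on synthetic cohorts, a titration method that
reads the elastic limit off a quasi-static pressure–volume (P–V) maneuver
and sets DP to the pressure rise from baseline to that limit, individually
per subject.

## Lung model

A single compartment with two regimes in quasi-static inflation. With PEEP
`P0` (cmH2O), elastic-zone elastance `E1` (cmH2O/mL), elastic-limit volume
`V_el` (mL) and plastic stiffening rate `α` (1/mL):

    P(V) = P0 + E1·V                                        V ≤ V_el
    P(V) = P0 + E1·V_el + (E1/α)·(exp(α·(V − V_el)) − 1)    V > V_el

The regimes join with a continuous first derivative (the slope at `V_el+`
is `E1`), the slope is non-decreasing everywhere, and `α → 0` degenerates
to a straight-line extension. The true individualized DP of a simulated
lung is `E1·V_el`, the pressure rise from zero injected volume to the
elastic limit.

The deflation limb uses the same family anchored at the same zero-volume
pressure with elastic elastance `E1/h`, `h ≥ 1` a hysteresis factor, so the
deflation curve lies at or below the inflation curve at every volume. Its
hinge pressure `P0 + (E1/h)·V_el` is the ground truth for expiratory PEEP
selection. This limb is an explicit stand-in: real deflation limbs are
sigmoid with a derecruitment knee at low volume, and no measured expiratory
protocol was available to calibrate one, so the PEEP recommendation should
be read as a consistency device rather than a validated estimator.

Maneuvers follow the super-syringe protocol: volumes 0, 1, …, 14 mL, with
i.i.d. Gaussian read-off noise (sd 0.3 cmH2O, configurable) on every
pressure sample including the baseline. 0.3 cmH2O is an instrument-scale
guess for a neonatal-range anesthesia machine's mean-pressure display; the
true per-step noise of such maneuvers is unknown.

### Default parameter ranges

Per-animal parameters are drawn uniformly: elastic-limit DP 8–14 cmH2O
(drawn directly and converted to `E1 = DP/V_el`, so the cohort's DP span is
explicit), `V_el` 5–10 mL, hysteresis 1.2–1.8, PEEP from {9, 10, 11, 12}
cmH2O weighted toward 12 (the typical individualized PEEP in a severe
lavage-ARDS rodent model). The plastic rate is parameterized through the
total stiffening exponent `γ = α·(V_max − V_el)` over the observable
plastic range, default 1.5–2.8: end-of-maneuver elastance 4.5–16× the
elastic value and end pressures ≈ 25–55 cmH2O wherever the limit falls. A
raw `α` range would instead produce end pressures of hundreds of cmH2O
whenever the elastic limit comes early, which no airway sustains.

## Elastic-point detection

`fit_two_segment` fits a continuous two-segment piecewise-linear (hinge)
model by least squares, with the knot restricted to the measured volume
grid: every interior grid volume leaving ≥ 3 points per segment is tried,
and the knot minimizing the total SSE wins (ties to the lower volume — the
conservative, smaller-DP choice). The basis is `[1, V, max(0, V − V_k)]`,
so the hinge is continuous by construction; the two segment elastances are
`E1̂ = b1` and `E2̂ = b1 + b2`. The individualized DP is the fitted hinge
pressure minus the fitted zero-volume pressure — both from the fit, which
denoises the baseline reading. A fit whose upper slope does not exceed the
lower one is flagged "no plastic transition" and callers fall back to
standard settings. Grid resolution bounds knot precision at ±1 step; no
sub-grid knot search is attempted.

`max_acceleration` is the raw curvature alternative: the grid point with
the greatest increase in local slope (second finite difference), ties to
the lower volume. It is unsmoothed and noise-sensitive, and is kept as a
cross-check, not the default.

### Known estimator bias on smooth curves

On maneuvers with a genuine slope discontinuity (two line segments), the
hinge fit recovers knot volume, knot pressure and both elastances exactly
(zero SSE) — this is verified in the test suite and is the regime the
method's exactness claims live in.

On the smooth generator law above, however, the elastic limit produces no
local kink (the join is C1), and detectability comes only from accumulated
exponential curvature. The SSE criterion then systematically places the
knot *past* the true limit: the convex tail's large residuals dominate the
objective, and absorbing early plastic points into the "elastic" segment is
cheap. The resulting DP estimate overshoots `E1·V_el` by several cmH2O
(median ≈ +5 cmH2O under default ranges; see
`analysis/04_detector_benchmark.py`, which profiles the bias against the
stiffening exponent). No choice of physically sensible generator defaults
removes this: weak stiffening hides the transition entirely, strong
stiffening inflates the tail that causes the bias. DP estimates from
smooth, strongly stiffening curves should therefore be read as upper
bounds, and the benchmark table shipped with the analysis quantifies the
margin. A detector robust to this geometry (e.g. fitting on a compliance
scale, or robust loss) is out of scope here, where the plain hinge fit is
the method under study.

## Recommendations

DP recommendations are rounded to 0.5 cmH2O (ventilator granularity,
half-up). Warnings flag: recommended DP ≥ 15 cmH2O (the conventional
protective ceiling), elastic-limit volume above 6 mL/kg of body weight
(tidal-volume safety), and non-positive DP (degenerate curve). The PEEP
recommendation applies the same hinge fit to the deflation limb and returns
its hinge pressure (the pressure below which expiratory compliance falls);
absent a transition it returns the 5 cmH2O pre-titration default with a
warning.

## Outcomes

* **P/F ratio**: PaO2/FiO2 in mmHg.
* **Berlin class**: severe ≤ 100 < moderate ≤ 200 < mild ≤ 300 < none,
  inclusive on the upper edge of each class; classification requires PEEP ≥
  5 cmH2O.
* **ALI histology score**: four items (alveolar capillary congestion,
  hemorrhage, neutrophil infiltration / wall thickness, hyaline membranes),
  each rated 0–4 per rater; the per-item score is the unrounded mean across
  raters (any number ≥ 1, two by default) and the global score their sum
  (0–16).

## Synthetic cohort

Each arm's outcome variables are drawn from distributions calibrated to a
configured median and IQR:

* **lognormal** (cytokines, gases, lactate): `μ = ln(median)`, `σ` from the
  upper-quartile relation `p75 = exp(μ + σ·z₀.₇₅)`. The lower quartile is
  then implied (`median²/p75`); a two-parameter lognormal cannot match a
  median plus two log-asymmetric quartiles, so when the configured IQR is
  asymmetric in log space the implied p25 deviates from the configured one.
  Medians and upper quartiles are reproduced to within 2% and 5%
  respectively at 10⁵ draws (tested).
* **normal** (cell fractions): mean = median, sd = IQR/1.349. The three
  fractions (lymphocytes, monocytes, polymorphonuclears) are clipped at 0
  and renormalized per animal to sum to 100%.
* **ordinal 0–4** (ALI items): a latent normal with the same calibration,
  shared between raters through a latent correlation (default 0.8),
  rounded and clipped to the 0–4 scale per rater.

Default calibrations encode the post-ventilation contrasts of the severe
lavage-ARDS experiment this generator emulates (IL-6 270 vs 155 pg/mL,
TNF-α 292 vs 139 pg/mL, IL-1β 563 vs 331 pg/mL, ALI items, cell fractions,
gases). What the generator does *not* emulate: any mechanistic coupling
between the applied DP and the outcomes (arms differ by construction, not
through simulated biology), longitudinal kinetics, pre-ARDS baselines, and
correlations between outcome variables. Passing pipeline tests therefore
demonstrate that the *analysis* machinery is calibrated and faithful, not
that the biological effect would reproduce.

All randomness descends from one seed through spawned `SeedSequence`
substreams (per animal: one for parameters and outcomes, one per maneuver
limb), so equal configurations reproduce cohorts bit for bit and adding
stages never perturbs earlier draws.

## Statistics

Quantitative variables are routed by a composite-normality test —
Lilliefors-corrected Kolmogorov–Smirnov with the Dallal–Wilkinson p-value
approximation (statsmodels), α = 0.05; samples with n < 5 or zero range are
routed non-normal with a flag. Both arms normal: Student t (pooled
variance; Welch behind a flag) with mean [95% t-CI] summaries. Otherwise:
two-sided Mann–Whitney — exact null distribution when combined n ≤ 20
without ties, else normal approximation with tie and continuity corrections
— with median [p25, p75] summaries (quartiles by linear interpolation
between order statistics, the inclusive method). Qualitative 2×2 contrasts:
chi-square without continuity correction when all expected counts ≥ 5,
otherwise Fisher's exact test, two-sided by the point-probability method. A
zero margin is degenerate and excluded with a note. No multiplicity
adjustment by default (a Holm option exists), α fixed at 0.05. The routed
pipeline's type-I error at n = 10 per arm is verified to sit in
[0.035, 0.065] under both normal and lognormal nulls (2000 replicates).

The exact tests are delegated to scipy; the test suite cross-checks them
against independent brute-force enumerations (all rank assignments for
Mann–Whitney up to 6 per arm; hypergeometric point-probability sums for
every 2×2 table with total ≤ 30), and the change-point fit against an
independent refit-at-every-knot implementation in a different
parameterization.

## Pipeline and problem sizes

`run_pipeline` chains simulate → titrate → arm policy (standard arm: fixed
14 cmH2O; individualized arm: the rounded recommendation, falling back to
14 when no transition is detectable) → study report, and writes all
artifacts plus a manifest (config hash, seed, version, row counts). Report
serialization is deterministic: stable column order, floats at 4
significant digits; repeated runs with one (config, seed) pair are byte
identical apart from manifest timestamps.

Simulation studies use 10 animals per arm (the emulated design), 500
replicates for detector recovery, 2000 replicates for null calibration and
10⁵ draws for generator calibration — sizes at which the Monte-Carlo error
is comfortably below every asserted tolerance.

## Degenerate inputs and tie-breaks

Duplicate volumes are rejected at the container; maneuvers need ≥ 5 points
(≥ 6 for fitting). Equal-SSE knots and equal second differences resolve to
the lower volume. A degenerate outcome spec (p25 = median = p75) collapses
to a point mass at the median. Constant samples route non-normal and
summarize with zero-width intervals. Berlin classification below 5 cmH2O
PEEP returns "not classifiable" rather than a severity.
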