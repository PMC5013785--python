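# Methods

## Model

Responses are binary (an ant shows or does not show the maxilla-labium
extension response to a test odour), aggregated to percentages per test
odour within a training group. The perceptual dimension is aldehyde
carbon-chain length; each odour is its integer carbon count (6–9 for
hexanal through nonanal). Two latent gradients are posited:

- an **excitatory gradient** G_σ(x) = exp(−(x − c₊)²/(2σ²)), the
  probability of being excited to respond, centred on the rewarded CS+;
- an **inhibitory gradient** G_σ′(x), the probability of being inhibited
  from responding, centred on the punished CS−.

Both have amplitude fixed at 100%: the absolute-conditioning groups respond
essentially universally to their own CS+ in the test, and the CS− is taken
to inhibit fully at its own position. Centres are pinned to the CS+ and
CS− (maximal excitation/inhibition at the trained stimuli). The only free
parameters are the widths σ and σ′, in carbon units.

Under the **multiplicative interaction**, responding requires being excited
and not inhibited, treated as independent events:
R(x) = 100·G_σ(x)·(1 − G_σ′(x)). Structural consequences, all
property-tested: 0 ≤ R ≤ 100·G_σ everywhere; R(c₋) = 0 exactly; the peak of
R lies strictly on the side of c₊ opposite c₋ whenever σ, σ′ > 0 (peak
shift), and returns to c₊ as σ′ → 0.

Two **additive variants** reconstruct the classical superposition account
for comparison: clip(100·G_σ − A′·G_σ′, 0, 100) with the inhibitory
amplitude A′ either fixed at 100 (2 parameters) or free in [0, 100]
(3 parameters). The exact functional form used historically for additive
gradient interaction is not uniquely determined, so both reconstructions
are reported side by side rather than choosing one.

## Fitting

Per experiment, (σ, σ′) minimise the unweighted sum of squared residuals on
the percentage scale over eight points: four absolute-conditioning
percentages against 100·G_σ and, simultaneously, four
differential-conditioning percentages against R(x). Percentages are fitted
raw — no binomial weighting — to match the least-mean-squares convention of
the reference analysis; a `sample_weight` option exists on the estimator
but is off by default.

Numerics: `scipy.optimize.least_squares` (trust-region reflective) with
bounds (0.05, 10] carbons on both widths, convergence tolerance 1e−10, and
a 4×4 multi-start grid over {0.5, 1.0, 1.5, 2.5}² keeping the lowest
objective, which makes the result initialisation-independent (verified
against exhaustive 0.01-resolution grid search). When a parameter is
unidentifiable the objective has a flat valley touching a bound (e.g. σ′
when the differential data show no inhibition away from the CS−); the fit
then snaps the parameter to the bound whenever that costs less than 1e−8
in objective, and sets `boundary_flag_`, so degenerate inputs yield a
deterministic, flagged solution instead of an arbitrary point in the
valley.

Residual error is summarised under three conventions — sum of absolute
residuals (the default "RE"; RE divided by the number of fitted points is
the typical per-point deviation in percentage points), sum of squares, and
RMS — because a headline residual-error number does not identify its own
convention. Reports always emit all three, per experiment and aggregated.

Model comparison fits every interaction variant to the same eight points
and ranks by objective and by small-sample AICc with k = 1–3 free
parameters against n = 8 points. Uncertainty is by parametric bootstrap:
responder counts resampled as Binomial(n_tested, observed proportion),
refit per replicate (warm-started from the point estimate — the multi-start
is for the unknown-data case, not for perturbations of a known optimum),
percentile intervals. Deterministic given the seed.

## Shift descriptors

`peak_location` maximises R on [c₊ − 4, c₊ + 4] by dense grid search (step
0.001 carbons) with bounded local refinement; plateaus are broken toward
the CS+ and flagged. `area_shift` is the sum of responses at test positions
on the side of the CS+ opposite the CS− minus the sum on the CS− side,
excluding the CS+ itself; positive values indicate the area shift. It is
undefined (by construction) when the CS+ sits at an end of the tested
range, as in two of the four study designs; the pipeline reports null
there. An observed-data variant uses measured percentages under the same
contract.

## Test statistics

Within-group differences across the four test odours use Cochran's Q with
k − 1 degrees of freedom; subjects with incomplete test batteries are
excluded listwise and counted. When every subject responds identically
across odours both the numerator and denominator of Q vanish; the statistic
is then reported as 0 (p = 1) with an `undefined` flag. Pairwise follow-ups
use McNemar's χ² on discordant pairs — continuity correction off by
default, available by flag, and always named in the report, since the
original variant is not identifiable from published ranges — with
sequential-Bonferroni correction implemented as Holm's step-down (the
standard referent of that phrase; plain Bonferroni available). Between-group
comparisons use two-sided Fisher's exact tests. Fisher and Holm delegate to
scipy/statsmodels; Q and McNemar are computed from their closed forms and
cross-checked against statsmodels in the test suite.

## Synthetic data

The generator reproduces the study conditions: four odours at positions
6–9; a CS+ with, in differential groups, a CS− two carbons away; group
sizes 29/38, 30/40, 30/41, 28/41 (absolute/differential per experiment);
twelve training trials (six CS+ interleaved with six blank or CS− trials in
the fixed pseudo-random order ABBABAABABBA); and a test of all four odours.
Test responses are i.i.d. Bernoulli draws per ant with p(x) given by the
gradient model — G_σ for absolute groups, G_σ·(1 − G_σ′) for differential —
using the published fitted widths as generating truth in the
`make_paper_fixture` preset. Acquisition curves follow
p(t) = asymptote·(1 − (1 − r)^t) with r = 0.5 by default and asymptotes
1.0 (absolute CS+), 0.74 (differential CS+) and 0.03 (CS−), matching the
late-trial response levels observed behaviourally.

What the generator deliberately does not emulate: ant-level heterogeneity
(an optional Beta-distributed response scale exists for robustness checks
but is off by default), lapse responding (the model forces p(CS−) = 0
exactly; an `epsilon` floor, default 0, settable to ≈0.03, mixes
p ← ε + (1 − ε)p to mimic the low but nonzero CS− responding of real ants),
trial-order effects, and any neural mechanism. Passing tests on this data
therefore demonstrate correctness of the estimator and statistics under the
model's own assumptions — binomial sampling noise at realistic group sizes —
not robustness to the dependence structure or drift of real behavioural
records. Blank trials are represented as events at the lapse floor, a
simplification of the actual unreinforced-trial procedure.

## Problem sizes and determinism

All simulations are seeded (`numpy.random.default_rng`) and bit-stable;
the end-to-end pipeline's JSON report is byte-identical across reruns of
one configuration. The optimiser–oracle equivalence check uses a
0.01-carbon exhaustive grid (the 0.001 grid is reserved for the peak
search, where it is one-dimensional); the parameter-recovery study uses 100
replicate experiments at n = 40 per group; bootstrap coverage is assessed
with 20 outer replications of 99 bootstrap draws. These sizes give stable
medians and coverage proportions while keeping the full suite fast.

## Known limitations

- With only eight points and two parameters, σ and σ′ are well identified
  only when responding actually declines across the tested range; saturated
  or empty response profiles drive widths to the bounds (flagged).
- The additive variants are reconstructions; conclusions about the additive
  model family are conditional on these functional forms.
- Area shift is undefined for designs whose CS+ is at the edge of the
  tested range — a property of the design, not of the implementation.
- Aggregate-only data support fitting and shift descriptors but not the
  within-subject statistics, which need per-ant records.
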