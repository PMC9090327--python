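# Methods

This note documents the models, conventions and numerical choices behind
`oneshotshapes`, in the order the pipeline uses them.

## Contour representation and conventions

A drawing is a simple closed polygon in screen coordinates (y axis down),
stored as an ordered circular point list with the first point not
repeated. Orientation is normalized at construction to clockwise on
screen, i.e. the signed shoelace area of the stored order (computed with
the mathematical y-up formula) is negative; all traversal-order analyses
("clockwise from the left-most point") rely on this. The left-most point
is the minimum-x point, ties broken by minimum y, then lowest index.

All cross-shape analyses operate on contours resampled to a standard
count of **360 points equally spaced in arc length** (starting at the
original point 0). 360 gives one point per degree on a circular blob and
makes point counts directly interchangeable with perimeter fractions.
Resampling is exact in arc position along the source polyline; note that
re-resampling an already-resampled jagged polygon is only approximately
idempotent, because chords near corners are shorter than the arcs they
replace.

Straightness ("fraction of the perimeter drawn with straight lines") has
two estimators. When stroke metadata is present (the drawing interface
recorded freehand vs straight-line mode per segment), the fraction is the
arc length of straight-mode segments over the perimeter, and this takes
precedence. Otherwise a geometric classifier is used: a vertex is
*straight* when the total absolute turning angle over a ±k window stays
below 1°/vertex. The default window is k = 1: at the standard 360-point
resolution a circle turns exactly 1°/vertex, so any window threshold at
1°/vertex sits on the decision boundary; a 0.1° guard band (windows
fluctuate by ~0.02° after resampling) puts constant-curvature contours
robustly on the curved side, and the narrow window keeps the per-corner
cost small enough that a resampled square still scores ≥ 0.95. Both k
and the threshold are configurable. Which estimator a given study used
is generally unknowable from the data, so neither is asserted as "the"
definition; the generator sets stroke metadata and analyses prefer it.

Chord cuts (`cut_part`) accept a part pick only when the open chord
between the two clicked points lies strictly inside the polygon —
mirroring a picking interface that refuses lines crossing the shape —
and return the two complementary half-open circular segments (lengths
summing to n). Geometry predicates (simplicity, containment, polygon
unions) are delegated to shapely.

## Synthetic exemplars and variations

Exemplars emulate hand-crafted stimuli built from **a main body with
0–5 attached parts**. The body is either a 6-corner polygon with
radius jitter (polygonal class) or a low-frequency radial Fourier blob,
r(θ) = R·(1 + Σₖ aₖ cos(kθ+φₖ)), k = 2…4, aₖ ∈ [0.02, 0.07] (curved
class); R = 150 drawing units around centre (250, 250). Parts occupy
disjoint angular windows (26–38°) centred on six fixed slots 60° apart:
spikes or blocks on polygonal bodies, raised-cosine bumps on curved
ones, positive (protrusion) or negative (indentation), with amplitudes
0.22–0.45 R (positive) or 0.15–0.28 R (negative) so the shape stays
star-shaped and simple. Every part carries a ground-truth
distinctiveness weight in [0, 1]; one "signature" part per exemplar has
weight 1. The eight default categories follow the 0–5 parts range with
alternating curvature classes, and category 2's single part is a
negative indentation.

Variations are re-realizations of the exemplar's parametric recipe:

- **warp** (magnitude m ∈ [0, 1]): body corner radii / Fourier
  coefficients and part amplitudes, widths and slot positions are
  jittered with standard deviations proportional to m, preserving point
  order and curvature class;
- **shuffle**: parts are permuted among slots. With three parts every
  cyclic arrangement is a rotation or a reflection of the original, so
  a genuine "shuffled" order needs ≥ 4 parts; the generator records the
  *induced* cyclic order class (identical / reversed / shuffled)
  computed from the realized spans, never the requested strategy;
- **reversal**: a geometric mirror of the whole shape, so parts *and*
  the body stretches between them reverse together;
- **omission / addition / substitution** of single parts, recorded as
  ground truth.

Drawer *d* of 17 has characteristic warp magnitude spaced evenly over
[0.08, 0.6], and the part-edit probabilities scale with that magnitude
(creative drawers also edit structure more), which yields a stable
ground-truth creativity ordering. The ground-truth deviation magnitude
of a variation is the mean point displacement from the exemplar after
centroid alignment, normalized by R, plus 0.15 per part change and 0.1
for a changed order — monotone in the warp and simple to reason about.

Identity variations (magnitude 0, no strategies) reproduce the exemplar
bit-exactly. All generation is deterministic given the seed; the cohort
fan-outs per-stage seeds through `numpy.random.SeedSequence`.

## Simulated raters

*Similarity*: rater-specific axis origin and scale (the analysis must be
affine-invariant), placement = origin + scale·(deviation + Gaussian
noise, σ = 0.04 by default).

*Classification*: correct with probability 1 − confusability
(default 0.12), otherwise uniform over the other seven categories.

*Correspondence*: the noiseless rater pairs every retained part by
ground truth and pairs the body stretches between consecutive retained
parts; stretches are matched across the two shapes by their unordered
anchor-part pair (with the closest-length candidate winning when both
directed stretches share one pair, which happens with exactly two
anchors and keeps mirrored variations consistent). Non-retained spans
(omitted parts on the exemplar; added or substituted-in parts on the
variation) stay unpicked, which is precisely what makes the gap analysis
recover omissions, additions and substitutions. Pick chords prefer
interior chords (widening the span stepwise); where no interior chord
exists the exact endpoints are used — the simulated rater idealizes the
interface rather than fragmenting a region. A bundling probability
(default 0.35 in the pipeline) merges a part pick with its following
stretch pick, emulating observers aggregating adjacent elements and
driving trials below the >2-correspondence threshold needed for order
analysis. Cross-category trials produce at most one small body pick.

*Paintings*: each rater paints tier 1 on the top-weight ground-truth
span (endpoints jittered, σ = 1.5 points), optionally tiers 2/3 on the
next-ranked spans (probabilities 0.7 / 0.4). Shapes without parts fall
back to the window of maximal smoothed curvature — distinctiveness read
as a geometric outlier — so every category remains eligible for swap
synthesis.

*Copy discrimination (2-AFC)*: copies deviate by |N(0, 0.02)|; the
rater picks the true copy with probability Φ((dev_variation −
dev_copy)/0.05).

*Swap classification*: an evidence model keyed on ground truth. The
base category contributes 1.0 (body) plus 1.6 when its distinctive part
is intact; the swapped-in donor part contributes 1.6 (distinctive) or
0.9 (indistinctive); choices are softmax at temperature 0.55 over the
eight categories. The unswapped > indistinctive-swap > distinctive-swap
accuracy ordering is a structural consequence, not an assignment.

## Analyses

**Similarity space.** Per rater × category, placements are rescaled by
|x − x_exemplar| / max distance, so the exemplar maps to 0 and the
rater's most distant shape to 1 (per full session, not per trial).
Aggregation is the across-rater mean with unbiased variance. The
spanning subset divides [0, 1] into n equal-width bins (20 or 40), picks
the minimum-variance shape per bin, and fills empty bins from
neighbouring bins in the order +1, −1, +2, −2, … with a not-yet-used
shape — the neighbour order is an implementation decision.

**Part circles.** Scanning clockwise from the left-most point, each
point contributes its pick label or a gap marker; runs are merged
circularly. Rest-of-shape picks enter area computations (a trial with a
rest pick corresponds fully) but are excluded from circles — a catch-all
pick carries no order information. Order comparison removes gaps and
non-shared labels and tests the variation's cycle against all rotations
of the exemplar's (identical) and of its reversal (reversed); with ≤ 2
shared labels the relation is undefined ([A,B] equals [B,A] cyclically).
Gap changes are classified per interval between consecutive shared
labels *in the exemplar's cyclic order*, reading the variation clockwise
from the first label to the second — "the same spot" is operationalized
as "the same inter-label interval". Note one consequence: an added and
an omitted part falling in the same interval are measured as one
substitution; the exact-recovery tests therefore use single-edit trials.

**Area fractions.** Pick polygons (segment plus closing chord) are
unioned per trial × rater, clipped to the exemplar, divided by its
area, then averaged over raters within trials and over trials
(rater-then-trial order is a choice; trials without correspondence
enter as 0).

**Distinctiveness.** Point score = Σ(3·tier1 + 2·tier2 + 1·tier3),
normalized to 0–100 by the *highest possible* score 3 × n_raters (a
literal reading of "highest possible", not the observed maximum), so
100 is attained iff every rater paints tier 1 there. High-score regions
use a strict > 75 threshold. The headline perimeter fraction uses the
largest consecutive region per shape by default (a `total` mode exists).
The randomized null resamples, per category and tier, the empirical
usage frequency, number of painted areas and run lengths, places runs
uniformly at random, forbids within-rater tier overlap
(rejection-resampled with fresh lengths), and always includes tier 1.
Human-vs-null comparison is a two-sample KS test on per-shape fractions
(exact p for n ≤ 25, asymptotic otherwise).

**Swap synthesis.** The distinctive part is the largest all-above-75
run (ties: higher mean, then lower start); a shape with no point above
75 is ineligible — an explicit error, never a fallback. The
indistinctive part is the same-length non-overlapping window of minimum
mean score. Transplantation maps the donor part's endpoints exactly onto
the points adjacent to the removed run by the unique proper similarity
transform (complex form z ↦ az + b); of the two mirror solutions the one
whose interior lies outside the remaining body is kept (outward
orientation), the contour is re-closed and resampled to 360. Exact
endpoint mapping is an interpretation of "fit the gap as best as
possible"; a least-squares non-endpoint fit would be an alternative.
Since points are equally spaced, same point count implies same perimeter
length for removed and inserted indistinctive segments. Screening
(simple polygon + minimum clearance between non-neighbouring points)
replaces manual curation, and candidates are drawn in seeded order per
design cell until the cell fills — both are deliberate, documented
departures from hand-picking.

**Statistics.** Binomial tests are exact one-sided (upper tail
P(X ≥ k)); multiple testing uses Bonferroni division only. The
confusion matrix tests each cell against chance 1/8, upper tail for
cells at or above chance and lower tail below, at α = 0.05/8 = 0.00625.
(The α = 0.05/8 value and a differently printed "0.015 for eight
outcomes" both circulate for this design; `confusion_analysis` exposes
`family_alpha`/`adjust_m` so either convention can be configured, and
neither is silently corrected.) The binomial sample-size calculator
reports the normal-approximation n = ⌈((z₁₋α√(p₀q₀) + z₁₋β√(p₁q₁))/(p₁−p₀))²⌉
— which reproduces the planning value 3197 for p₀ = 0.125, p₁ = 0.15,
α = 0.00625, power 0.95 — alongside an exact-binomial search (3246 for
the same parameters; the exact test's sawtooth power at the
approximation's n is ~0.945). The t-test calculator iterates
noncentral-t power over equal group sizes; d = 0.2, α = 0.05, power
0.95, one-sided gives 542 per group, total 1084 — the total is the
quantity consistent with a two-sample reading. OLS, t, Pearson and KS
wrappers delegate to statsmodels/scipy.

## What the synthetic data does and does not show

The generator reproduces the study *structure* — counts, responses
formats, monotonicities, ground-truth recoverability — not human
behaviour. Passing tests show that the analysis code measures what it
claims to measure on data with known truth: order relations are
recovered exactly on noiseless picks, the null model matches its corpus
statistics, swap accuracy ordering follows from evidence content, and
so on. They do not show that human percentages (similarity spreads,
77/7/17 order splits, 19 % high-score coverage, 86 %→69 %→32 %
accuracy) would be reproduced; those depend on real drawings and
raters. Geometric realism is also limited: bodies are star-shaped,
parts sit on a fixed slot grid, and noise models are Gaussian or
categorical with fixed parameters.

## Problem sizes used by the test and acceptance runs

Default cohort 17 × 12 × 8 = 1632 drawings; similarity 12 raters;
classification 15 raters over 40-bin subsets; correspondence 15 raters
over 8 × (10 + 10) = 160 trials per participant; paintings 10 raters
over 8 shapes per category plus exemplars; null model 10 randomized
raters per shape; swap design 8 × 7 × 2 × 5 = 560. The part-order
recovery check runs 500 noiseless trials; Monte-Carlo power checks use
10,000 replicates; the null-generator distribution check draws 10,000
paintings. Unit tests use smaller cohorts (e.g. 4 × 6 × 8) where a full
cohort adds nothing to the property under test.
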