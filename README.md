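# oneshotshapes

Analysis tools for **generative one-shot categorization** studies of 2D
shape: experiments in which people see a *single* exemplar of a novel,
abstract closed-contour object, draw new members of its category, and
other observers then rate, sort, segment and annotate those drawings.
The package turns the raw materials of such a study — closed contours,
similarity placements, 8-way classification choices, part-correspondence
picks and tiered "distinctiveness" paintings — into the quantities the
paradigm is built around:

- a **perceived-similarity space** per category (placements normalized to
  [0, 1] per rater, averaged across raters), with a per-drawer
  *creativity index* and within-session order trends;
- **category-membership statistics**: confusion matrices with cell-wise
  one-sided exact binomial tests against chance 1/8 under Bonferroni
  adjustment;
- **part correspondence and part order**: per-point correspondence fields
  (modal exemplar target and support per variation point),
  corresponding-area fractions, and cyclic **part circles** whose
  comparison classifies each variation's part order as *identical*,
  *reversed* or *shuffled* and its gaps as part *omission*, *addition*
  or *substitution*;
- **distinctiveness fields**: tiered paintings aggregated with weights
  3/2/1 and normalized to 0–100 by the highest possible score
  (3 × raters), high-score regions (> 75 at every point), and a
  placement-randomized null that preserves each tier's usage frequency,
  run-length and area-count distributions;
- **distinctive-part-swap synthesis**: replacing a shape's most (or an
  equally long least) distinctive part with a donor exemplar's part via
  the endpoint-fitting similarity transform (rotation + uniform scale),
  screening artefacts, and enumerating the full
  8 × 7 × 2 × 5 = 560-stimulus design, with Cohen's
  *h* = 2·arcsin√p₁ − 2·arcsin√p₂ for the resulting accuracy drops;
- the **a-priori sample-size calculators** used to plan such studies
  (normal-approximation binomial and noncentral-*t*).

Because the original drawings and ratings come from human participants,
the package ships a first-class **synthetic-data generator**: exemplars
built from a main body with 0–5 attached parts (polygonal or curved
class), drawer cohorts (17 drawers × 12 variations × 8 exemplars = 1632
drawings by default) whose variations warp, shuffle, mirror, omit, add
or substitute parts with full ground truth recorded, and simulated rater
responses for every experiment with controllable noise. Every analysis
stage can therefore be exercised and verified end to end.

## Worked example

`examples/06_swap_stimuli.py` runs the whole chain — cohort simulation,
similarity space, painting aggregation, swap-stimulus synthesis and
categorization of the swapped shapes:

```
$ python examples/06_swap_stimuli.py
stimuli built: 560 (8 x 7 x 2 x 5 = 560)
correct categorization: unswapped 96%  indistinctive swap 91%  distinctive swap 21%
Cohen's h vs unswapped: indistinctive 0.20, distinctive 1.78
```

Reading: of the 560 synthesized swap stimuli, shapes whose *distinctive*
part (the largest contour run scoring above 75 in the aggregated
distinctiveness field) was replaced by another category's part are
categorized correctly far less often (21 %) than shapes that lost an
equally long *indistinctive* stretch (91 %) or unmodified shapes (96 %):
the distinctive part carries most of the category signal even though it
is a small fraction of the contour. The other examples
(`examples/01_…` to `examples/07_…`) each demonstrate one capability and
print a line explaining their numbers.

A thin command-line front-end mirrors the pipeline for shell use:

```bash
oneshot simulate --seed 1 --out dataset/     # write a synthetic dataset
oneshot analyze-similarity --bins 20         # Experiment-2-style analysis
oneshot report --seed 1 --out results/       # all experiments end to end
oneshot validate dataset/                    # structural dataset checks
```

## Layout

```
src/oneshotshapes/
  contour.py          geometry kernel: contours, resampling, chord cuts
  synthetic.py        exemplar/variation generator + simulated raters
  similarity.py       placement normalization, creativity, subsets
  correspondence.py   part picks, part circles, order & gap analysis
  distinctiveness.py  painting aggregation, high-score regions, null model
  swap.py             distinctive-part swap synthesis and screening
  stats.py            binomial/t tests, Cohen's h, sample sizes, wrappers
  pipeline.py         experiment orchestration and reports
  io.py               contour JSON, SVG, response CSV tables
  cli.py              thin argparse front-end (`oneshot`)
```

See `docs/methods.md` for the models, conventions and design decisions.
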