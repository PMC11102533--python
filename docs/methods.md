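# Methods

## The staging procedure

A single Humphrey-style perimetry result is staged from three inputs: the
mean deviation (MD, dB), the four central global-plot sensitivities (the
points at |x| = |y| = 3°), and the per-locus pattern-deviation
probability categories (not significant, or depressed at P < 5%, < 2%,
< 1%, < 0.5%). Each of four criteria grades the field independently on
`none < mild < moderate < severe`; the overall stage is the maximum.

* **MD bands** — `none` for MD ≥ −1 dB, `mild` ≥ −6 dB, `moderate`
  ≥ −12 dB, `severe` below; all floors inclusive, so MD = −6.0 dB is
  mild. The bands are exhaustive and mutually exclusive.
* **Central points** — a point is *depressed* iff strictly below 15 dB
  (a reading of exactly 15 dB is healthy). Depression confined to one
  hemifield (split at the horizontal meridian) is moderate; depression
  in both hemifields, or any point at ≤ 0 dB, is severe. The ≤ 0 rather
  than = 0 comparison is defensive: sub-zero sensitivities are not
  printed but must not slip through. This criterion has no mild band.
* **Pattern-deviation proportions** — at P < 5%-or-worse: 0 loci is
  none, up to 25% (inclusive) mild, up to 50% (inclusive) moderate,
  above severe. At P < 1%-or-worse the reference counts are out of 76:
  below 10/76 mild, from 10/76 up to (excluding) 20/76 moderate, from
  20/76 severe. Proportions are compared as exact rationals
  (`fractions.Fraction`), never floats, so boundaries are bit-stable:
  on a 54-locus 24-2, 7/54 < 10/76 grades mild while 8/54 grades
  moderate, decided by integer cross-multiplication.

All thresholds live in `HpaThresholds` and are configurable, so variant
criteria can be expressed without touching the engine; reports echo the
thresholds used.

### Canonical locus layouts

The 24-2 pattern is the 6°-spaced grid offset 3° from both meridians
with row extents |x| ≤ 9 at |y| = 21, ≤ 15 at 15, ≤ 21 at 9 and 3, plus
one nasal point at |x| = 27 on each |y| = 3 row — 54 loci. The 30-2
extends to |y| = 27 with extents 9/15/21/27/27 — 76 loci. Loci are
stored in right-eye convention (x positive temporal, nasal points at
x = −27); left-eye charts are the x-mirror. The denominator for
proportion criteria is the full displayed locus count, including the
blind-spot-adjacent loci.

## The plot-image parser

Parsing is deliberately rule-based and one-dimensional, so every
decision can be audited from the diagnostics JSON.

1. **Binarisation** — colour is reduced to luminance; a global Otsu
   threshold separates ink from paper (printouts are near-bilevel, so no
   per-image tuning is needed). A blank or near-blank image raises a
   "no plot found" error.
2. **Panel detection** — the preferred route finds the panel's
   rectangular frame: a large connected component whose bounding-box
   border is fully inked but whose interior is mostly empty. The frame
   band is stripped per edge and the interior mapped linearly onto the
   pattern's known degree extent (outermost locus centers plus a 3°
   half-cell pad on each side). Two or more frame-like candidates raise
   an ambiguity error listing them. For frameless crops, connected-
   component centroids are clustered into grid columns and rows (gaps
   above half the inter-locus pitch split clusters); the outermost
   cluster means mark the outermost locus centers. Clustering matters
   because stippled glyphs are several components each; glyphs are
   drawn symmetric, so sub-component centroids average back to the
   locus center.
3. **Grid superposition** — one sampling window per canonical locus,
   0.8× the 6° pitch on a side, so neighbouring windows never overlap.
   Windows that would fall outside the image raise a geometry error.
4. **Symbol classification** — the feature is mean *darkness* in the
   window, normalised between the background level (image median) and
   full ink. Unlike a binary pixel count, mean darkness is approximately
   conserved by resampling, which is what makes classification robust to
   uniform rescaling (tested over 0.75–1.5×). The measured density is
   matched to the nearest reference density; references are measured
   from the glyph alphabets themselves, rendered at a large calibration
   cell (96 px) where pixel quantisation is negligible. Exact ties
   resolve toward the *less* significant category, and near-ties (the
   best and runner-up distances within 20% of each other) are flagged as
   low-confidence warnings rather than silently decided — conservative
   against false severity inflation. A legend strip, when available, can
   replace the built-in references (`calibration_from_legend`).

Numeric values (MD, central sensitivities) are never extracted from
images: there is no OCR, mirroring a three-input design in which the
user supplies the numbers and the image only carries the probability
map.

## The synthetic generator

The generator stands in for a clinical validation set; its defaults are
the study conditions under which the pipeline is certified.

* **Records** — `sample_field` draws per-criterion grades at or below a
  target overall grade (forcing at least one criterion to the target),
  realises MD inside the matching band, central sensitivities to one
  decimal place, and pattern-deviation counts uniformly inside the
  matching count bands (P < 1% count never exceeding the P < 5% count),
  then verifies the overall grade with the rule engine itself and
  rejects on mismatch. Ground truth is therefore the engine's own
  verdict on the numeric record, by construction.
* **Rendering** — a bordered panel (3 px frame, meridian cross) on
  white paper, one glyph per locus at 32 px per 6° cell, with ±1 px
  placement jitter. Two glyph families — "block" (squares/stipple) and
  "round" (dots/discs) — share the same five-step ink-density ladder
  (≈ 0.02 / 0.08 / 0.20 / 0.40 / 0.80 of the sampling window) and
  exercise the parser's style tolerance. Element sizes are quantised
  from the diameter once, independent of sub-pixel position, so a
  glyph's ink area does not flicker with grid phase. Optional dark
  speckle noise exists for robustness experiments and is off by
  default. Rendering is byte-deterministic in (matrix, eye, style,
  seed).
* **Validation sets** — `make_validation_set(n, class_mix, seed, style)`
  apportions `n` records over the four grades by largest remainder and
  shuffles them. The default mixture is 0/0.4/0.3/0.3 over
  none/mild/moderate/severe: a glaucoma-clinic skew in which every
  recorded field shows some defect. That choice deliberately reproduces
  the undefined-specificity situation (no true negatives for "any
  defect"); mixtures with defect-free fields avoid it. The default
  validation size is 168 fields, parsed and scored in a few seconds on
  one CPU.

What the generator does **not** emulate: spatially correlated scotomata
(arcuate bundles, nasal steps), reliability indices, grayscale maps, or
whole printout pages. Passing the round-trip and end-to-end suites
therefore demonstrates correctness of the rules and of the parsing
mechanism under controlled rendering variation — not robustness to
scanner artefacts, skew, or unfamiliar printer fonts, which would need
real scanned printouts to assess.

## Validation statistics

Agreement is summarised by the truth-vs-predicted confusion matrix,
unweighted Cohen's κ = (p_o − p_e)/(1 − p_e), and positive-vs-rest
collapses ("any defect" = mild or worse; "severe") scored as
sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy, and
F1 = 2TP/(2TP+FP+FN). Any metric with a zero denominator is reported as
the first-class value `UNDEFINED` — distinct from 0 and from an error —
because a defect-only dataset genuinely cannot estimate any-defect
specificity, and that fact belongs in the report. κ is likewise
`UNDEFINED` when the margins make chance agreement 1. Unweighted κ is
used throughout; no bootstrap intervals are computed.

Appraisal-duration comparisons are computed from per-method summary
statistics. Welch's unequal-variance form is the primary test — the two
methods' spreads differ by an order of magnitude in realistic timing
data, and automation compresses variance — with Welch–Satterthwaite
degrees of freedom; the pooled form is also exposed. With equal group
sizes the two t statistics coincide exactly (only the degrees of
freedom differ), which the suite checks against an independent
implementation (`scipy.stats.ttest_ind_from_stats`).

## Numerical and design choices

* Proportion comparisons: exact rationals; no float equality anywhere
  near a band boundary.
* Severity and significance scales are `IntEnum`s; ordering is the
  integer order, and most-severe-wins is literally `max`.
* Grade names serialise lowercase; `"early"` is accepted as an input
  alias for `"mild"`.
* The classifier's tie direction (toward less significant) trades a
  possible one-step under-grade, flagged with a warning, against silent
  severity inflation.
* Batch validation continues past per-record parse failures and reports
  them; dataset *integrity* problems (missing or inconsistent truth
  files) abort, naming the record.
* All randomness in generation flows from a single seed; derived
  per-record seeds stay below 2³¹.

## Known limitations

* The parser assumes a single cropped pattern-deviation panel; it does
  not segment full single-field-analysis printouts.
* Symbol classification assumes the five-glyph alphabet is ordered in
  ink density, which holds for standard printouts and both built-in
  families but not for arbitrary custom symbologies — supply a legend
  calibration in that case.
* Non-uniform scaling (different x/y factors) is handled by the
  geometry but glyph density references assume near-isotropic pixels.
* The undefined-specificity convention means downstream consumers must
  handle `"undefined"` in report JSON.
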