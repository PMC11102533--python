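# hpagrade

Automatic staging of glaucomatous visual-field defects from Humphrey
perimetry results, by the Hodapp-Parrish-Anderson (HPA) criteria — with a
rule-based computer-vision parser for pattern-deviation probability plot
images, a synthetic printout renderer for validation with exact ground
truth, and the agreement statistics used to certify the pipeline.

## Who this is for

Clinicians and vision researchers who need reproducible, objective HPA
staging of single visual fields: glaucoma severity grading is an input to
risk stratification, progression baselines and (in some jurisdictions)
sight-impairment certification, yet manual application of the criteria is
labour-intensive and inter-rater agreement on free-form reading is poor.
`hpagrade` encodes the criteria exactly, and is explicitly *not* a
machine-learning black box: every decision — band thresholds, hemifield
logic, symbol classification — is explicit, inspectable code with
per-locus diagnostics.

## The model

A field is staged on the ordinal scale `none < mild < moderate < severe`
from three inputs, each criterion graded independently, with the **most
severe verdict winning**:

| Criterion | none | mild | moderate | severe |
|---|---|---|---|---|
| Mean deviation (MD) | ≥ −1 dB | ≥ −6 dB | ≥ −12 dB | < −12 dB |
| Central 5° points (4 values) | all ≥ 15 dB | — | point(s) < 15 dB in one hemifield | points < 15 dB in both hemifields, or any point ≤ 0 dB |
| Pattern deviation, P < 5% | 0% | ≤ 25% | ≤ 50% | > 50% |
| Pattern deviation, P < 1% | 0 | < 10/76 | < 20/76 | ≥ 20/76 |

Pattern-deviation criteria are proportions of the displayed loci, so the
same rules apply to 24-2 (54 loci) and 30-2 (76 loci) patterns;
comparisons are computed in exact rational arithmetic (e.g. 19/76 is
*exactly* the 25% boundary and grades mild).

The image parser locates the plot panel (rectangular frame, or symbol
extent for frameless crops), superimposes the canonical 6°-spaced locus
grid (mirrored for left eyes), and classifies each locus's probability
symbol by its ink density against glyph-derived references — a
one-dimensional, auditable feature that is conserved under image
rescaling.

## Worked example

Grade one left eye from its mean deviation, four central sensitivities
(order: upper-nasal, upper-temporal, lower-nasal, lower-temporal) and a
cropped pattern-deviation plot image:

```
$ hpagrade grade --md 1.1 --central 17.5,13.8,32.7,23.2 \
      --image plot.png --eye left --overlay overlay.png
{
 "schema": "hpagrade.grading_report.v1",
 "grade_md": "none",
 "grade_central": "moderate",
 "grade_pd5": "mild",
 "grade_pd1": "mild",
 "overall": "moderate",
 "counts": {"p5": 13, "p1": 5, "total": 54},
 ...
}
```

Reading the report: MD of +1.1 dB is normal; one central point (13.8 dB,
upper hemifield) is depressed below 15 dB, which alone makes the field
*moderate*; the parser found 13 of 54 loci depressed at P < 5% (mild
band, 24%) and 5 at P < 1% (mild band); most-severe-wins gives
**moderate** overall. `overlay.png` shows the detected panel and the
classified sampling window at every locus.

Other commands: `hpagrade synth` writes a synthetic validation dataset
(plots + numeric records + truth + manifest), `hpagrade validate` runs
the full image→grade pipeline over such a dataset and scores it
(confusion matrix, Cohen's κ, severe-vs-rest metrics), and
`hpagrade report` computes the same statistics from a prepared
truth/predicted CSV, optionally with appraisal-duration comparisons
(Welch *t* from per-record timings). Library use mirrors the CLI:
`hpagrade.grade_field`, `hpagrade.parse_pattern_plot`,
`hpagrade.make_validation_set`, `hpagrade.validation_report`.

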