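# dvhscore

Dose-volume-histogram metrics and **piecewise-linear dosimetric scorecards**
for radiotherapy plan-quality assessment, built around hippocampal-avoidance
whole-brain radiotherapy (HA-WBRT).

A protocol's pass/variation/fail dose constraints under-specify clinical
intent: many plans satisfy all of them while trading target coverage against
organ-at-risk sparing very differently. A dosimetric scorecard articulates
one intent precisely: an ordered set of DVH metrics, each mapped to points by
a piecewise-linear function spanning from a failing value (0 points, a
protocol violation) through a steep "variation acceptable" segment to a
shallow aspirational (ALARA) segment ending at the metric's maximum points.
The total, as a share of the card maximum, is a single objective measure of
how well a plan realizes that intent.

`dvhscore` is a library (plus a thin `dvhscore` CLI) that provides:

- **DVH engine** — cumulative DVHs from 3-D dose grids and structure masks;
  D_x% / D_xcc, V_d (absolute or percent-of-prescription levels), mean/max/min
  dose, homogeneity index `HI = (D1% − D99%) / Rx`, and the van't Riet
  conformation number `CN = (TV_D/TV)·(TV_D/V_D)`.
- **Structure algebra** — boolean combinations and exact Euclidean margin
  expansion (e.g. the hippocampal avoidance region = hippocampi + 5 mm), with
  a serializable recipe language for derived evaluation structures such as
  `_Brain&BODY` and `_Eyes&BODY`.
- **Scorecard model** — a metric-text grammar (`"Dose at 0.03CC [Gy]"`,
  `"Volume at 105% [%]"`, …), piecewise-linear score functions, a JSON/CSV
  file format, and the three built-in HA-WBRT cards: `HLS-EC-WB` (limited
  sparing, enhanced coverage, 20 Gy/5 fx, 158.5 points), `HMS-EC-WB`
  (moderate sparing, enhanced coverage, 30 Gy/10 fx scalable, 158.5 points)
  and `HSWBv2` (aggressive sparing, 30 Gy/10 fx scalable, 142 points). The
  published knot coordinates are not public; shipped knots are clearly
  labelled reconstructions anchored on the published protocol thresholds.
- **Scoring engine** — plan scoring, prescription (Rx) scaling, and the
  *normalize-to-max-score* search: the global dose rescaling factor `r*`
  maximizing the total score `S(r)`, found exactly by enumerating the
  breakpoints of the piecewise-smooth objective.
- **Synthetic phantom** — a seeded cranial phantom (64³ × 2 mm by default)
  with parametric dose fields covering the coverage-vs-sparing trade-off,
  so everything is testable end to end with zero downloads.
- **Batch I/O** — NRRD plan bundles, TPS-style cumulative-DVH CSV import,
  batch scoring with comparison tables and CSV reports, and an optional
  DICOM-RT (RTDOSE/RTSTRUCT) adapter.

## Worked example

```python
from dvhscore import builtin_scorecard, score_plan, study_plan

plan = study_plan("limited_sparing", seed=7)   # synthetic 20 Gy HA-WBRT plan
card = builtin_scorecard("HLS-EC-WB")
res = score_plan(plan, card)
print(f"{res.total_points:.2f} / {res.max_points:g} ({res.percent_of_max:.2f}%)")
```

prints

```
124.01 / 158.5 (78.24%)
```

i.e. the plan earns 124.01 of 158.5 possible points on the limited-sparing
card. Per-metric rows (`res.per_metric`) show where points are lost — here
mostly on near-maximum doses to structures inside the treated brain — and
`examples/02_score_a_plan.py` prints the full table. Batch-scoring the three
intent archetypes on all three cards (`examples/04_batch_comparison.py`)
reproduces the study's headline pattern: each plan's largest percent-of-max
sits in its own card's column:

```
            plan  HLS-EC-WB %  HMS-EC-WB %  HSWBv2 %
    deep_sparing        76.85        79.65     82.16
moderate_sparing        69.67        70.24     68.44
 limited_sparing        78.24        71.92     72.47
```

The other examples cover raw DVH metrics (`01`), normalize-to-max (`03`),
and DVH-only scoring plus 20 → 30 Gy prescription scaling (`05`). The same
workflows are scriptable from the shell:

```bash
dvhscore phantom --preset limited_sparing --seed 3 --out bundle/
dvhscore score bundle/ --card HLS-EC-WB --normalize max --out report.csv
```

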