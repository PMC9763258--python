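# gevrisk

Desk-scale tooling for endoscopic **gastroesophageal-varix (GEV) bleeding-risk
assessment**: the model-free analytic chain that sits between a lesion
segmenter and the clinical risk call, plus a seeded synthetic scene generator
so every stage is testable without clinical images.

Cirrhotic patients are screened by endoscopy for esophageal (EV) and gastric
(GV) varices; the findings that drive prophylaxis are the varix grade (1-3 for
EV, big/small at 5 mm for GV), the red color signs (RC) on the variceal wall,
and the Child-Pugh class. This package is for researchers building or
evaluating quantitative varix-assessment pipelines who need the
post-segmentation logic — thresholding, instance extraction, RC clustering,
grade rules, temporal smoothing, risk rules, evaluation statistics — as
reusable, tested components. Trained segmentation/classification networks are
out of scope: any callable mapping a frame to a probability map satisfies the
segmenter contract, and classical stand-ins are included.

## What it computes

- **Segmentation post-processing** — probability maps are binarized at the
  varix cut-off 0.4 and the RC cut-off 0.5 (inclusive, `p >= cutoff`);
  connected components become per-varix instances.
- **RC grading by density clustering** — RC blob centroids are clustered with
  from-scratch DBSCAN using minPts = 1 and the frame-scaled radius
  `eps = sqrt(w*h/6.5)` px; grade RC0-RC3 follows cluster count K and the
  angular span of the spots around the lumen (RC1: K <= 2 and span <= 90 deg;
  RC3: K >= 6 or span >= 270 deg; RC2 between; GV use binary RC0/RC1).
- **Grade/size from geometry** — medial-axis widths give grade 1 (< 3 mm,
  flat profile), grade 2 (3-5 mm or beady), grade 3 (>= 5 mm or nodular), and
  the GV big/small split at 5 mm diameter.
- **Exam videos** — quality filters (blur, dye, forceps, water, inflation,
  off-site) drop unusable frames; labels are majority-smoothed over windows of
  5 consecutive qualified frames (a label wins with >= 3 occurrences) and
  accumulated per region and over time into one final label per family.
- **Risk stratification** — high risk iff grade >= 2, or grade 1 with RC or
  Child-Pugh C (presets for the narrower variant without the RC trigger); the
  GV rule mirrors this on the size split.
- **Evaluation statistics** — pixel precision/recall/IoU, mIoU with threshold
  fractions, per-varix and per-image sensitivity, diagnostic tables with 95%
  CIs (Agresti-Coull default, exact Clopper-Pearson available), McNemar's
  paired test, and system-vs-reader improvement deltas.
- **Synthetic scenes** — seeded phantoms with grade-dependent varix geometry,
  controllable RC count/angular spread, probability-map noise, exam-video
  scripts with unqualified-frame contamination, and patient cohorts with known
  risk labels. At zero noise the pipeline recovers every generated label
  exactly; that parameter recovery is the package's main correctness surface.

## Worked example

```
$ python examples/02_rc_grading.py
true RC1: 2 spots -> 1 cluster(s) at eps=217.4 px, angular span 59 deg -> graded RC1
true RC2: 4 spots -> 1 cluster(s) at eps=217.4 px, angular span 179 deg -> graded RC2
true RC3: 8 spots -> 1 cluster(s) at eps=217.4 px, angular span 298 deg -> graded RC3
```

On a 640x480 frame the DBSCAN radius is `sqrt(640*480/6.5) = 217.4` px, so
nearby spots merge into one cluster and the angular span does the grading
work: 59 deg is localized (RC1), 298 deg is circumferential (RC3).

```
$ python examples/05_risk_tables.py
system: accuracy 97.69% (95% CI 93.14-99.51%), sensitivity 99.10%, specificity 89.47%
endoscopists: accuracy 85.38% (95% CI 78.22-90.52%), sensitivity 93.69%, specificity 36.84%
delta correct: 16/130 = 12.31% more patients correctly stratified
delta low-risk: 10/19 = 52.63% more low-risk patients spared
McNemar (b=19, c=3): p = 0.0009 (exact)
```

Here the inputs are two gold-by-called patient-count tables (system and
endoscopists on the same 130 patients); the deltas say how many more patients
the system stratifies correctly overall and how many more gold-low-risk
patients it spares from unnecessary treatment.

The other examples generate a scene and segment it back (`01`), run a full
exam video with quality filtering and smoothing (`03`), and stratify a
synthetic cohort end to end (`04`).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the headline risk-stratification statistics (accuracies of the two
2x2 risk tables, the GV table, and both improvement deltas) by running the
package's diagnostic-table machinery on the published patient counts, runs a
seeded synthetic cohort end to end as a self-check, and writes the values to
the given JSON path.

See `docs/methods.md` for the model assumptions, parameter defaults and known
limitations, and `docs/FORMATS.md` for file conventions.
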