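# Methods

## Scope and design

`gevrisk` implements the analytic (model-free) half of a varix-screening
pipeline. The trained networks that produce lesion probability maps and the
CNN grade classifiers of a deployed clinical system are deliberately out of
scope; they are replaced by two contracts:

- **Segmenter contract** — any callable `(frame, target) -> ProbabilityMap`
  with `target in {"varix", "rc"}`. Shipped implementations:
  `PhantomSegmenter` (renders maps from synthetic ground truth with
  configurable degradation) and `BaselineSegmenter` (classical
  darkness-contrast / red-dominance scoring of rendered RGB frames).
- **Classifier contract** — grade/size labels are derived from measurable
  instance geometry (`measure_varix_geometry` -> `classify_ev_grade` /
  `classify_gv_size`); an external predictor producing the same label +
  geometry JSON can be substituted.

All free parameters live in one frozen `RunConfig` whose hash is embedded in
every report.

## Fixed constants

| Parameter | Default | Meaning |
|---|---|---|
| `cutoff_varix` | 0.4 | probability cut-off delineating varices (inclusive) |
| `cutoff_rc` | 0.5 | probability cut-off delineating red color signs |
| DBSCAN `min_pts` | 1 | every RC point is a core point; no outliers |
| DBSCAN `eps` | `sqrt(w*h/6.5)` px | frame-scaled neighbourhood radius |
| smoothing | 3 of 5 | window of consecutive qualified frames / quorum |
| risk rule | `intro` | high iff grade >= 2 or grade 1 with (RC or Child C) |

The first five are fixed constants of the emulated system; the risk rule has
a second preset (`methods`) that omits the RC trigger, matching the narrower
prophylaxis-indication wording that also circulates; the wider variant is the
default because risk stratification is explicitly described as using RC.

## RC grading

RC are graded by density and distribution. Because `eps` scales with the
frame (217 px at 640x480), clustering raw RC *pixels* would merge everything;
the package clusters **blob centroids** (one point per 8-connected RC
component, components under `min_rc_area` = 10 px discarded as thresholding
noise). This is the main interpretive choice in the package and is
configurable. DBSCAN itself is authored here (queue expansion over epsilon
neighbourhoods) and is cross-checked in the tests against a brute-force
epsilon-graph oracle and scikit-learn.

"Localized" vs "circumferential" is operationalized as the minimal circular
arc around the lumen centre covering the clustered points (360 minus the
largest angular gap); the per-cluster column-span fraction is reported as a
secondary distribution measure. Grade mapping defaults: RC1 iff K <= 2 and
span <= 90 deg; RC3 iff K >= 6 or span >= 270 deg; RC2 otherwise; RC0 iff no
clusters. The numeric thresholds are stand-in defaults for qualitative
criteria, surfaced in `RCThresholds`.

## Varix geometry

Widths are twice the Euclidean distance transform sampled along the skeleton
path between the two geodesically farthest skeleton endpoints (double-sweep
Dijkstra; exact on tree skeletons). Statistics are computed on the path
trimmed by half the maximal width at each end, because skeletons of discrete
shapes grow 45-degree end spurs that otherwise bias tortuosity by ~8% on a
plain rectangle. Nodularity counts local width-profile maxima above 1.5x the
mean width after a 5-sample moving average. Blob-like instances whose
skeleton collapses (GV mounds) fall back to width = 2 * max(EDT), with
degenerate shape statistics. Instances under 10 px are flagged unmeasurable
and skipped by the pipeline.

Grade thresholds: grade 1 iff max width < 3 mm, width CV < 0.15 and no
nodules; grade 3 iff max width >= 5 mm or >= 2 nodules; grade 2 otherwise.
The 3/5 mm cut points align the grade-2/3 boundary with the
"medium-to-large" treatment language and the 5 mm GV rule — the only numeric
size anchor available.

## Temporal smoothing and accumulation

Only qualified frames enter the label streams. Each family (EV grade, EV RC,
GV size, GV RC) is smoothed independently: a window of 5 consecutive
qualified labels emits the label occurring >= 3 times; when no label reaches
quorum the highest-severity label among the most frequent ones is emitted
(the cost of missing a high-risk varix — rupture ~15%/year — outweighs a
false alarm). Streams shorter than the window collapse to their modal label
and the report is flagged `unsmoothed`.

The final per-exam label per family is the **highest-severity label whose
smoothed occurrence fraction reaches `aggregation_floor`** (default 5%), not
the plain majority: a short grade-3 segment of a long varix must not be
outvoted by grade-1 frames, while the floor suppresses single-window flicker.
Cumulative per-label fraction series and per-region tallies (window assigned
to its centre frame's region) are kept for interface-style displays.

## Risk stratification

Child-Pugh classes use the standard clinical banding (A 5-6, B 7-9,
C 10-15 points over five 1-3-point components); the banding is not restated
in the emulated system's description and is taken from standard practice.
The GV rule is nowhere stated explicitly; the shipped default mirrors the EV
rule (high iff big, or small with RC or Child C) and is declared a package
default, not a fidelity claim. Cohort stratification excludes patients
without varices of a family from that family's confusion table and skips
patients with missing Child-Pugh data (logged).

## Evaluation statistics

IoU is computed on region masks, not literal bounding boxes (the emulated
system displays freeform delineations); `boxes=True` gives the literal
bounding-box reading. A gold instance counts as detected at >= 50% predicted
coverage (configurable; "any overlap" is degenerate). Empty-vs-empty pairs
score 1.0 and are flagged `degenerate`. mIoU CIs use a seeded 2000-resample
percentile bootstrap over images.

Diagnostic-table CIs default to **Agresti-Coull**: it reproduces exactly the
reference intervals for 127/130 (93.14-99.51%), 111/130 (78.22-90.52%) and
113/118 (90.21-98.43%), whereas exact Clopper-Pearson gives 93.40-99.52% for
127/130. Clopper-Pearson remains available (`ci_method="clopper-pearson"`)
and is property-tested against exhaustive binomial tail inversion. McNemar's
test is exact-binomial for b + c < 25 and continuity-corrected chi-square
otherwise.

## Synthetic data: what it emulates, and what it does not

Scenes model an axial endoscopic view: EV as an annular arc band (332 deg
span, radius 140 px) around the lumen centre whose width profile encodes the
grade — constant 2.0 mm (grade 1), 3.6 +/- 0.4 mm sinusoidal beading
(grade 2), 6.0 mm with three ~2 mm Gaussian bulges (grade 3); GV as disk
mounds of 3.5 mm (small) / 7.0 mm (big) diameter. RC are 5-px-radius disks on
varix pixels, evenly spread (with jitter) over an angular window of 60 deg
(RC1, 2 spots), 180 deg (RC2, 4), 300 deg (RC3, 8) — tied to the grading
thresholds so that zero-noise phantoms grade back exactly. Default frame
640x480 at 0.05 mm/px; probability-map degradation is Gaussian blur plus
clipped additive Gaussian noise ("moderate noise" in the tests: blur sigma
2 px, additive sigma 0.1).

Cohort defaults: Child class A/B/C = 0.45/0.45/0.10 (the prospective-cohort
case mix); EV grade absent/1/2/3 = 0.20/0.35/0.30/0.15, EV RC 0/1/2/3 =
0.40/0.25/0.20/0.15, GV absent/small/big = 0.50/0.30/0.20, GV RC 0/1 =
0.60/0.40 — a plausible screening mix, chosen once and not calibrated to any
dataset. Exams default to 7 fps metadata and caller-set frame counts.

A green recovery test therefore establishes that the analytic chain is
self-consistent — thresholds, clustering, geometry, smoothing and rules
invert the generator exactly — not that it would reproduce a clinical
system's accuracy on real endoscopy: phantoms have no specular highlights,
peristalsis, insufflation dynamics, erosions (the dominant real-world RC
confounder) or appearance variation, and the per-varix geometry is idealized.
Dataset-dependent headline numbers (mIoU ~0.81-0.89, RC accuracy ~94%) are
not reproducible at desk scale and are not targets of this package.

## Numerical choices and edge cases

- Threshold comparison is inclusive (`>=`); instance labels are assigned in
  raster-scan order of each component's first pixel; coordinates are 0-based
  (row, col) with half-open bounding boxes; default connectivity 8.
- DBSCAN cluster ids follow first-core-point input order; the partition is
  input-order invariant (tested under permutation).
- Angular span of < 2 points is 0; the lumen centre falls back to the image
  centre when unset.
- Tortuosity is 1.0 when the trimmed chord is under 1 px (degenerate blobs).
- An all-unqualified exam yields an empty report flagged `empty` with
  absent/0 labels; per-frame analysis failures become skipped frames with
  reason `error`, never aborting the exam.
- At zero noise the exam runner caches one analysis per (scene, site family),
  which is exact because the rendered map is then deterministic per scene.

## Known limitations

- The RC point representation (centroids, not pixels) and the numeric RC/
  grade thresholds are declared stand-ins for qualitative criteria; real
  systems may differ.
- The baseline segmenter is a contrast heuristic for rendered phantoms; it is
  a contract demonstration, not a usable clinical segmenter.
- GV risk stratification uses a mirrored, unvalidated rule (explicitly
  configuration-replaceable).
- The "disappears on insufflation" criterion for minimal venous dilation is
  temporal/physiological and has no single-frame analog here.
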