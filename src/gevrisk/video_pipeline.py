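"""Per-exam orchestration: quality filtering, temporal smoothing, and
per-region/time accumulation of frame-level varix assessments.

An exam video is analyzed frame by frame: quality filters drop unusable
frames (blur, dye, forceps, flushing water, inadequate inflation,
off-site); each qualified frame runs the full chain (segment ->
threshold -> instances -> RC clustering/grading -> grade/size); the
resulting per-frame label streams are majority-smoothed over windows of
five consecutive qualified frames (a label wins with three or more
occurrences); and the smoothed streams are accumulated per region and
over time into an exam report with one final label per family.

The final per-family exam label is the highest-severity label whose
smoothed occurrence fraction reaches ``aggregation_floor`` (default 5%):
a short grade-3 segment of a long varix must not be outvoted by grade-1
frames, while the floor filters single-window flicker.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage

from .config import RunConfig, DEFAULT_CONFIG
from .grade_classify import (
    UnmeasurableInstanceError,
    classify_ev_grade,
    classify_gv_size,
    measure_varix_geometry,
)
from .rc_grading import (
    dbscan,
    epsilon_for_image,
    grade_rc_ev,
    grade_rc_gv,
    rc_points_from_mask,
)
from .segmentation import (
    ProbabilityMap,
    RasterMask,
    baseline_segment,
    extract_instances,
    threshold_probability_map,
)
from .synthdata import (
    ESOPHAGEAL_SITES,
    RETAINED_SITES,
    ExamScript,
    Frame,
    NoiseParams,
    render_frame,
    render_probability_map,
)

GV_SIZE_SEVERITY = {"absent": 0, "small": 1, "big": 2}
FAMILIES = ("ev_grade", "rc_ev", "gv_size", "rc_gv")


def _severity(family: str, label) -> float:
    return GV_SIZE_SEVERITY[label] if family == "gv_size" else float(label)


# ---------------------------------------------------------------------------
# quality filtering


def laplacian_sharpness(frame: np.ndarray) -> float:
    """Variance of the discrete Laplacian of the gray image (blur score:
    lower is blurrier)."""
    gray = np.asarray(frame, float)
    if gray.ndim == 3:
        gray = gray.mean(axis=2)
    lap = ndimage.laplace(gray)
    return float(lap.var())


def quality_filter(
    frame: np.ndarray | None,
    metadata: dict,
    sharpness_threshold: float = 25.0,
) -> tuple[bool, str | None]:
    """Decide whether a frame enters the analysis, with a reason code.

    Metadata verdicts are honored first (``qualified``/``reason`` flags
    from upstream quality and inflation models), then the anatomical-site
    vocabulary check, then the image-based sharpness test when pixel data
    is provided.  Reasons: blur, chromo, forceps, water, inflation,
    off-site.
    """
    if metadata.get("qualified") is False:
        return False, metadata.get("reason", "blur")
    if metadata.get("inflation") is True:
        return False, "inflation"
    region = metadata.get("region")
    if region is not None and region not in RETAINED_SITES:
        return False, "off-site"
    if frame is not None and laplacian_sharpness(frame) < sharpness_threshold:
        return False, "blur"
    return True, None


# ---------------------------------------------------------------------------
# smoothing


@dataclass
class SmoothedStream:
    labels: list
    unsmoothed: bool = False  # True when the stream was shorter than the window


def smooth_stream(
    labels: list,
    window: int = 5,
    quorum: int = 3,
    severity: Callable = float,
) -> SmoothedStream:
    """Majority-smooth a stream of qualified-frame labels.

    Slides a window of ``window`` consecutive labels; emits the label
    occurring at least ``quorum`` times, else the highest-severity label
    among the most frequent ones (clinical cost asymmetry: err toward the
    severe call).  Output has length ``len(labels) - window + 1``; streams
    shorter than the window collapse to their modal label, flagged
    ``unsmoothed``.
    """
    if not (window >= quorum >= 1):
        raise ValueError("need window >= quorum >= 1")
    if not labels:
        return SmoothedStream([], unsmoothed=True)

    def vote(chunk) -> object:
        counts = Counter(chunk)
        top = max(counts.values())
        modal = [lab for lab, c in counts.items() if c == top]
        return max(modal, key=severity)

    if len(labels) < window:
        return SmoothedStream([vote(labels)], unsmoothed=True)
    out = [vote(labels[i: i + window]) for i in range(len(labels) - window + 1)]
    return SmoothedStream(out)


# ---------------------------------------------------------------------------
# frame assessment and accumulation


@dataclass
class FrameAssessment:
    frame_index: int
    region: str
    qualified: bool
    reason: str | None = None
    ev_grade: int | None = None  # 0 = absent
    rc_ev: int | None = None
    gv_present: bool | None = None
    gv_size: str | None = None
    rc_gv: int | None = None

    def label(self, family: str):
        return getattr(self, family)


@dataclass
class ExamReport:
    final_labels: dict = field(default_factory=dict)
    final_risk_basis: dict = field(default_factory=dict)
    region_tallies: dict = field(default_factory=dict)  # region -> family -> Counter
    cumulative: dict = field(default_factory=dict)  # family -> label -> fraction series
    filtered_counts: dict = field(default_factory=dict)  # reason -> n
    n_frames: int = 0
    n_qualified: int = 0
    empty: bool = False
    unsmoothed: bool = False
    config: dict = field(default_factory=dict)
    config_hash: str = ""


def _empty_labels() -> dict:
    return {"ev_grade": 0, "rc_ev": 0, "gv_size": "absent", "rc_gv": 0}


def accumulate(
    assessments: list[FrameAssessment],
    config: RunConfig = DEFAULT_CONFIG,
) -> ExamReport:
    """Smooth the qualified-frame label streams and fold them into an
    exam report (per-region tallies, cumulative fractions, final labels)."""
    report = ExamReport(config=config.to_dict(), config_hash=config.config_hash)
    report.n_frames = len(assessments)
    report.filtered_counts = dict(
        Counter(a.reason for a in assessments if not a.qualified)
    )
    qualified = [a for a in assessments if a.qualified]
    report.n_qualified = len(qualified)
    if not qualified:
        report.empty = True
        report.final_labels = _empty_labels()
        return report

    sm = config.smoothing
    for family in FAMILIES:
        stream = [a.label(family) for a in qualified]
        smoothed = smooth_stream(
            stream, window=sm.window, quorum=sm.quorum,
            severity=lambda lab, f=family: _severity(f, lab),
        )
        report.unsmoothed = report.unsmoothed or smoothed.unsmoothed
        n = len(smoothed.labels)
        # region of a smoothed window = region of its centre frame
        offset = 0 if smoothed.unsmoothed else sm.window // 2
        for i, lab in enumerate(smoothed.labels):
            region = qualified[min(i + offset, len(qualified) - 1)].region
            report.region_tallies.setdefault(region, {}).setdefault(
                family, Counter()
            )[lab] += 1
        counts = Counter(smoothed.labels)
        # cumulative fraction of each observed label over the smoothed stream
        series = {}
        for lab in counts:
            hits = np.cumsum([lab == s for s in smoothed.labels])
            series[lab] = hits / np.arange(1, n + 1)
        report.cumulative[family] = series
        floor = config.aggregation_floor
        eligible = [lab for lab, c in counts.items() if c / n >= floor]
        report.final_labels[family] = max(
            eligible, key=lambda lab: _severity(family, lab)
        )
    return report


# ---------------------------------------------------------------------------
# segmenter contracts


class PhantomSegmenter:
    """Segmenter contract implementation backed by phantom ground truth.

    Stands in for the trained segmentation networks: renders a probability
    map from the frame's scene with configurable blur/additive noise.
    With zero noise the map is deterministic per scene, which the exam
    runner exploits to cache per-scene analyses.
    """

    def __init__(self, noise: NoiseParams = NoiseParams(), seed: int = 0):
        self.noise = noise
        self.seed = seed

    @property
    def per_scene_deterministic(self) -> bool:
        return self.noise.blur == 0 and self.noise.additive == 0

    def __call__(self, frame: Frame, target: str) -> ProbabilityMap:
        frame_seed = (self.seed * 1_000_003 + frame.index) % (2**31)
        return render_probability_map(frame.scene, target, self.noise, seed=frame_seed)


class BaselineSegmenter:
    """Classical image-based segmenter over rendered RGB frames."""

    per_scene_deterministic = False

    def __init__(self, seed: int = 0):
        self.seed = seed

    def __call__(self, frame: Frame, target: str) -> ProbabilityMap:
        img = render_frame(frame.scene, seed=(self.seed * 31 + frame.index) % (2**31))
        if target == "rc":
            return baseline_segment(img, "rc")
        cls = "ev_varix" if frame.region in ESOPHAGEAL_SITES else "gv_varix"
        return baseline_segment(img, cls)


# ---------------------------------------------------------------------------
# exam runner


def _analyze_frame(frame: Frame, segmenter, config: RunConfig) -> dict:
    """Full per-frame chain; returns the lesion labels for one frame."""
    scene = frame.scene
    mmpp = scene.mm_per_pixel
    pmap = segmenter(frame, "varix")
    varix_mask = threshold_probability_map(pmap, config.cutoff_varix)
    instances = [
        inst
        for inst in extract_instances(varix_mask, config.connectivity)
        if inst.area >= config.min_instance_area
    ]
    labels = {"ev_grade": 0, "rc_ev": 0, "gv_present": False,
              "gv_size": "absent", "rc_gv": 0}
    if not instances:
        return labels
    geometries = []
    for inst in instances:
        try:
            geometries.append(measure_varix_geometry(inst, mmpp))
        except UnmeasurableInstanceError:
            continue
    if not geometries:
        return labels
    varix_fg = np.zeros(varix_mask.shape, bool)
    for inst in instances:
        varix_fg[inst.pixels[:, 0], inst.pixels[:, 1]] = True

    rc_pmap = segmenter(frame, "rc")
    rc_all = threshold_probability_map(rc_pmap, config.cutoff_rc)
    rc_mask = RasterMask.from_bool(rc_all.as_bool() & varix_fg)

    if frame.region in ESOPHAGEAL_SITES:
        labels["ev_grade"] = max(
            classify_ev_grade(g, config.grade_thresholds) for g in geometries
        )
        points = rc_points_from_mask(
            rc_mask, lumen_center=scene.lumen_center, min_area=config.min_rc_area
        )
        if config.dbscan.eps_mode == "formula":
            eps = epsilon_for_image(scene.width, scene.height)
        else:
            eps = float(config.dbscan.eps_value)
        clustering = dbscan(points, eps=eps, min_pts=config.dbscan.min_pts)
        labels["rc_ev"] = grade_rc_ev(clustering, config.rc_thresholds)
    else:
        sizes = [classify_gv_size(g, config.grade_thresholds) for g in geometries]
        labels["gv_present"] = True
        labels["gv_size"] = "big" if "big" in sizes else "small"
        labels["rc_gv"] = grade_rc_gv(rc_mask, min_area=config.min_rc_area)
    return labels


def run_exam(
    script: ExamScript,
    segmenter=None,
    config: RunConfig = DEFAULT_CONFIG,
) -> ExamReport:
    """Run the full chain over an exam script and accumulate the report.

    Per-frame failures are recorded as skipped frames (reason ``error``),
    never aborting the exam.  Deterministic given the segmenter's seeds
    and the config.
    """
    segmenter = segmenter if segmenter is not None else PhantomSegmenter()
    cache: dict = {}
    assessments: list[FrameAssessment] = []
    for frame in script.frames:
        ok, reason = quality_filter(None, {"qualified": frame.qualified,
                                           "reason": frame.reason,
                                           "region": frame.region})
        if not ok:
            assessments.append(
                FrameAssessment(frame.index, frame.region, False, reason)
            )
            continue
        key = (id(frame.scene), frame.region in ESOPHAGEAL_SITES)
        cacheable = getattr(segmenter, "per_scene_deterministic", False)
        try:
            if cacheable and key in cache:
                labels = cache[key]
            else:
                labels = _analyze_frame(frame, segmenter, config)
                if cacheable:
                    cache[key] = labels
        except Exception:  # pragma: no cover - defensive per-frame guard
            assessments.append(
                FrameAssessment(frame.index, frame.region, False, "error")
            )
            continue
        assessments.append(
            FrameAssessment(frame.index, frame.region, True, None, **labels)
        )
    return accumulate(assessments, config)
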