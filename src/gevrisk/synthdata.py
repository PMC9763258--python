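"""Seeded synthetic endoscopic scenes, exam videos and patient cohorts.

The generator emulates, at desk scale, the inputs of a varix-screening
endoscopy viewed axially down the lumen: esophageal varices (EV) appear as
annular arc bands around the lumen centre whose width profile encodes the
grade — grade 1 a straight constant-caliber tube under 3 mm, grade 2 a
beady (sinusoidally modulated) tube of 3-5 mm, grade 3 a markedly enlarged
band over 5 mm with nodular bulges; gastric varices (GV) are disk mounds
dichotomized at 5 mm diameter.  Red color signs (RC) are small disks
placed on varix pixels with a controllable count and angular spread, from
localized (RC1) to circumferential (RC3).

Everything is deterministic given (params, seed): identical calls yield
bit-identical phantoms.  True labels are attached at generation time and
are recoverable by the analysis pipeline at zero noise; that parameter
recovery is the package's main acceptance surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from . import riskstrat
from .segmentation import ProbabilityMap, RasterMask

RETAINED_SITES = (
    "esophagus",
    "squamocolumnar_junction",
    "fundus_lesser_curvature",
    "fundus_anterior_wall",
    "fundus_greater_curvature",
    "fundus_posterior_wall",
)
ESOPHAGEAL_SITES = ("esophagus", "squamocolumnar_junction")
UNQUALIFIED_REASONS = ("blur", "chromo", "forceps", "water", "inflation")

# default RC placement per EV RC grade: (n_spots, angular spread in degrees);
# tied to the grading thresholds n1=2/a1=90, n3=6/a3=270 so that zero-noise
# phantoms grade back to their true RC grade.
RC_DEFAULTS = {1: (2, 60.0), 2: (4, 180.0), 3: (8, 300.0)}

BACKGROUND_RGB = (200, 160, 155)
VARIX_RGB = (120, 80, 120)
RC_RGB = (150, 30, 40)


# ---------------------------------------------------------------------------
# scene types


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one esophageal-varix scene.

    ``grade`` 0 means no varix; ``rc_grade`` 0 means no red color signs.
    ``n_rc_spots``/``angular_spread_deg`` default per RC grade
    (see ``RC_DEFAULTS``).
    """

    grade: int = 0
    rc_grade: int = 0
    n_rc_spots: int | None = None
    angular_spread_deg: float | None = None
    width: int = 640
    height: int = 480
    mm_per_pixel: float = 0.05
    arc_radius_px: float = 140.0
    arc_span_deg: float = 332.0
    rc_spot_radius_px: float = 5.0
    # grade geometry (mm): base widths and modulations
    grade1_width_mm: float = 2.0
    grade2_width_mm: float = 3.6
    grade2_bead_amp_mm: float = 0.4
    grade3_width_mm: float = 6.0
    grade3_bulge_amp_mm: float = 2.0


@dataclass(frozen=True)
class GVSceneParams:
    """Parameters of one gastric-varix scene (disk mound)."""

    size: str = "absent"  # absent | small | big
    rc_present: bool = False
    width: int = 640
    height: int = 480
    mm_per_pixel: float = 0.05
    small_diameter_mm: float = 3.5
    big_diameter_mm: float = 7.0
    rc_spot_radius_px: float = 5.0


@dataclass(frozen=True)
class NoiseParams:
    """Probability-map degradation: Gaussian blur then clipped additive noise."""

    blur: float = 0.0
    additive: float = 0.0

    def __post_init__(self):
        if self.blur < 0 or self.additive < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass
class ScenePhantom:
    width: int
    height: int
    lumen_center: tuple[float, float]
    varix_masks: list[RasterMask]
    rc_mask: RasterMask
    true_ev_grade: int = 0  # 0 = absent
    true_gv_size: str = "absent"
    true_rc_grade: int = 0
    mm_per_pixel: float = 0.05
    site: str = "esophagus"

    def varix_union(self) -> np.ndarray:
        out = np.zeros((self.height, self.width), bool)
        for m in self.varix_masks:
            out |= m.as_bool()
        return out

    def validate(self) -> None:
        union = self.varix_union()
        if (self.rc_mask.as_bool() & ~union).any():
            raise ValueError("RC pixels must lie on varix pixels")
        if (self.true_rc_grade == 0) != (not self.rc_mask.as_bool().any()):
            raise ValueError("true_rc_grade must be 0 iff the RC mask is empty")
        overlap = np.zeros((self.height, self.width), np.int32)
        for m in self.varix_masks:
            overlap += m.as_bool()
        if (overlap > 1).any():
            raise ValueError("varix instance masks must be pairwise disjoint")


@dataclass
class PatientRecord:
    patient_id: str
    child_components: tuple[int, int, int, int, int]
    child_class: str
    true_ev_grade: int = 0
    true_rc_ev: int = 0
    true_gv_size: str = "absent"
    true_rc_gv: int = 0
    true_ev_risk: str = "none"  # high | low | none
    true_gv_risk: str = "none"


@dataclass
class Frame:
    index: int
    region: str
    qualified: bool
    reason: str | None
    scene: ScenePhantom


@dataclass
class ExamScript:
    frames: list[Frame]
    fps: float
    patient: PatientRecord | None = None

    def __post_init__(self):
        for f in self.frames:
            if f.region not in RETAINED_SITES:
                raise ValueError(f"unknown region label {f.region!r}")
        idx = [f.index for f in self.frames]
        if idx != sorted(idx):
            raise ValueError("frames must be ordered by timestamp index")


# ---------------------------------------------------------------------------
# scene generation


def _polar_grids(width: int, height: int, center: tuple[float, float]):
    yy, xx = np.mgrid[0:height, 0:width]
    dx = xx - center[0]
    dy = yy - center[1]
    radius = np.hypot(dx, dy)
    angle = np.mod(np.degrees(np.arctan2(dy, dx)), 360.0)
    return radius, angle


def _halfwidth_profile_mm(params: SceneParams, angle_from_start: np.ndarray, rng) -> np.ndarray:
    """Full-width profile (mm) of the varix band as a function of arc angle."""
    g = params.grade
    if g == 1:
        w = np.full_like(angle_from_start, params.grade1_width_mm)
    elif g == 2:
        w = params.grade2_width_mm + params.grade2_bead_amp_mm * np.sin(
            np.radians(angle_from_start) * 6.0
        )
    else:  # grade 3: nodular bulges at three fixed arc positions (jittered)
        w = np.full_like(angle_from_start, params.grade3_width_mm)
        centers = np.array([0.25, 0.5, 0.75]) * params.arc_span_deg
        centers = centers + rng.uniform(-10, 10, size=3)
        for c in centers:
            w = w + params.grade3_bulge_amp_mm * np.exp(-(((angle_from_start - c) / 12.0) ** 2))
    return w


def generate_varix_scene(params: SceneParams, seed: int) -> ScenePhantom:
    """Generate one esophageal scene with known ground truth.

    Deterministic per (params, seed).  ``rc_grade > 0`` without a varix is
    rejected (RC sit on varices by definition).
    """
    if params.grade not in (0, 1, 2, 3):
        raise ValueError("grade must be 0 (absent), 1, 2 or 3")
    if params.rc_grade not in (0, 1, 2, 3):
        raise ValueError("rc_grade must be in 0..3")
    if params.rc_grade > 0 and params.grade == 0:
        raise ValueError("rc_grade > 0 requires a varix (grade >= 1)")
    rng = np.random.default_rng(seed)
    w, h = params.width, params.height
    center = (w / 2.0, h / 2.0)
    empty = RasterMask(np.zeros((h, w), np.int32))
    if params.grade == 0:
        return ScenePhantom(
            width=w, height=h, lumen_center=center, varix_masks=[], rc_mask=empty,
            mm_per_pixel=params.mm_per_pixel, site="esophagus",
        )

    px_per_mm = 1.0 / params.mm_per_pixel
    radius, angle = _polar_grids(w, h, center)
    arc_start = float(rng.uniform(0.0, 360.0))
    rel = np.mod(angle - arc_start, 360.0)
    halfwidth_px = _halfwidth_profile_mm(params, rel, rng) * px_per_mm / 2.0
    in_arc = rel <= params.arc_span_deg
    varix = in_arc & (np.abs(radius - params.arc_radius_px) <= halfwidth_px)
    varix_mask = RasterMask.from_bool(varix)

    rc = np.zeros((h, w), bool)
    if params.rc_grade > 0:
        n_default, spread_default = RC_DEFAULTS[params.rc_grade]
        n = params.n_rc_spots if params.n_rc_spots is not None else n_default
        spread = (
            params.angular_spread_deg
            if params.angular_spread_deg is not None
            else spread_default
        )
        margin = 6.0
        spread = min(spread, params.arc_span_deg - 2 * margin)
        start_lo = margin
        start_hi = params.arc_span_deg - margin - spread
        window_start = float(rng.uniform(start_lo, max(start_lo, start_hi)))
        if n == 1:
            spot_angles = np.array([window_start + spread / 2.0])
        else:
            spot_angles = window_start + np.linspace(0.0, spread, n)
            jitter_amp = min(2.0, spread / (4.0 * max(n - 1, 1)))
            jitter = rng.uniform(-jitter_amp, jitter_amp, size=n)
            jitter[0] = abs(jitter[0])      # keep the end spots pinned inside
            jitter[-1] = -abs(jitter[-1])   # the window so the span is stable
            spot_angles = spot_angles + jitter
        radial_jitter = rng.uniform(-4.0, 4.0, size=n)
        yy, xx = np.mgrid[0:h, 0:w]
        for a, dr in zip(spot_angles, radial_jitter):
            theta = np.radians(arc_start + a)
            r = params.arc_radius_px + dr
            cx = center[0] + r * np.cos(theta)
            cy = center[1] + r * np.sin(theta)
            rc |= np.hypot(xx - cx, yy - cy) <= params.rc_spot_radius_px
        rc &= varix  # guarantee containment at the boundary
    scene = ScenePhantom(
        width=w, height=h, lumen_center=center,
        varix_masks=[varix_mask], rc_mask=RasterMask.from_bool(rc),
        true_ev_grade=params.grade, true_rc_grade=params.rc_grade,
        mm_per_pixel=params.mm_per_pixel, site="esophagus",
    )
    scene.validate()
    return scene


def generate_gv_scene(params: GVSceneParams, seed: int) -> ScenePhantom:
    """Generate one gastric (fundus) scene: a disk mound with optional RC."""
    if params.size not in ("absent", "small", "big"):
        raise ValueError("size must be absent, small or big")
    if params.rc_present and params.size == "absent":
        raise ValueError("RC requires a varix")
    rng = np.random.default_rng(seed)
    w, h = params.width, params.height
    center = (w / 2.0, h / 2.0)
    empty = RasterMask(np.zeros((h, w), np.int32))
    if params.size == "absent":
        return ScenePhantom(
            width=w, height=h, lumen_center=center, varix_masks=[], rc_mask=empty,
            mm_per_pixel=params.mm_per_pixel, site="fundus_greater_curvature",
        )
    diameter_mm = params.small_diameter_mm if params.size == "small" else params.big_diameter_mm
    r_px = diameter_mm / params.mm_per_pixel / 2.0
    offset = rng.uniform(-40.0, 40.0, size=2)
    cx, cy = center[0] + offset[0], center[1] + offset[1]
    yy, xx = np.mgrid[0:h, 0:w]
    mound = np.hypot(xx - cx, yy - cy) <= r_px
    rc = np.zeros((h, w), bool)
    if params.rc_present:
        jit = rng.uniform(-0.3, 0.3, size=2) * r_px
        rc = np.hypot(xx - (cx + jit[0]), yy - (cy + jit[1])) <= params.rc_spot_radius_px
        rc &= mound
    scene = ScenePhantom(
        width=w, height=h, lumen_center=center,
        varix_masks=[RasterMask.from_bool(mound)], rc_mask=RasterMask.from_bool(rc),
        true_gv_size=params.size, true_rc_grade=int(params.rc_present),
        mm_per_pixel=params.mm_per_pixel, site="fundus_greater_curvature",
    )
    scene.validate()
    return scene


# ---------------------------------------------------------------------------
# rendering


def render_probability_map(
    scene: ScenePhantom,
    target: str,
    noise: NoiseParams = NoiseParams(),
    seed: int = 0,
) -> ProbabilityMap:
    """Render the stand-in of a segmentation network's probability map.

    With zero noise the map is exactly 1 on ground-truth pixels and 0
    elsewhere; otherwise it is Gaussian-blurred and perturbed with clipped
    additive Gaussian noise.
    """
    if target not in ("varix", "rc"):
        raise ValueError("target must be 'varix' or 'rc'")
    truth = scene.rc_mask.as_bool() if target == "rc" else scene.varix_union()
    values = truth.astype(float)
    if noise.blur > 0:
        values = ndimage.gaussian_filter(values, noise.blur)
    if noise.additive > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise.additive, size=values.shape)
    values = np.clip(values, 0.0, 1.0)
    if target == "rc":
        target_class = "rc"
    else:
        target_class = "ev_varix" if scene.site in ESOPHAGEAL_SITES else "gv_varix"
    return ProbabilityMap(values, target_class=target_class, source="phantom")


def render_frame(scene: ScenePhantom, seed: int = 0, texture_sigma: float = 3.0) -> np.ndarray:
    """Render the scene to an RGB uint8 frame (for the baseline segmenter
    and the image-based quality filters)."""
    h, w = scene.height, scene.width
    img = np.empty((h, w, 3), float)
    img[:] = BACKGROUND_RGB
    varix = scene.varix_union()
    img[varix] = VARIX_RGB
    img[scene.rc_mask.as_bool()] = RC_RGB
    if texture_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, texture_sigma, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# exams and cohorts


def default_trajectory(patient: PatientRecord | None = None) -> list[str]:
    """Esophagus -> squamocolumnar junction -> fundus walls."""
    return [
        "esophagus",
        "squamocolumnar_junction",
        "fundus_greater_curvature",
        "fundus_posterior_wall",
    ]


def generate_exam_video(
    patient: PatientRecord,
    n_frames: int,
    unqualified_rate: float = 0.0,
    trajectory: Sequence[str] | None = None,
    fps: float = 7.0,
    seed: int = 0,
    scene_params: SceneParams = SceneParams(),
    gv_scene_params: GVSceneParams = GVSceneParams(),
) -> ExamScript:
    """Script an exam video for one patient.

    Frames are split into contiguous per-region blocks along the
    trajectory; esophageal regions show the patient's EV scene, fundus
    regions the GV scene.  Each frame is independently unqualified with
    probability ``unqualified_rate`` (random reason).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not (0.0 <= unqualified_rate < 1.0):
        raise ValueError("unqualified_rate must lie in [0, 1)")
    trajectory = list(trajectory if trajectory is not None else default_trajectory(patient))
    if not trajectory:
        raise ValueError("trajectory must be non-empty")
    rng = np.random.default_rng(seed)
    ev_scene = generate_varix_scene(
        replace(scene_params, grade=patient.true_ev_grade, rc_grade=patient.true_rc_ev),
        seed=int(rng.integers(2**31)),
    )
    gv_scene = generate_gv_scene(
        replace(gv_scene_params, size=patient.true_gv_size, rc_present=bool(patient.true_rc_gv)),
        seed=int(rng.integers(2**31)),
    )
    bounds = np.linspace(0, n_frames, len(trajectory) + 1).astype(int)
    frames: list[Frame] = []
    for k, region in enumerate(trajectory):
        scene = ev_scene if region in ESOPHAGEAL_SITES else gv_scene
        for i in range(bounds[k], bounds[k + 1]):
            unqualified = rng.random() < unqualified_rate
            reason = str(rng.choice(UNQUALIFIED_REASONS)) if unqualified else None
            frames.append(Frame(index=i, region=region, qualified=not unqualified,
                                reason=reason, scene=scene))
    return ExamScript(frames=frames, fps=fps, patient=patient)


@dataclass(frozen=True)
class CohortPrevalences:
    """Marginal label prevalences of a synthetic cohort.

    Child-class defaults follow the prospective-cohort case mix (45/45/10%
    A/B/C); varix-label defaults are a plausible screening mix.  Each dict
    must sum to 1.
    """

    ev_grade: dict = field(
        default_factory=lambda: {0: 0.20, 1: 0.35, 2: 0.30, 3: 0.15}
    )
    rc_ev: dict = field(
        default_factory=lambda: {0: 0.40, 1: 0.25, 2: 0.20, 3: 0.15}
    )
    gv_size: dict = field(
        default_factory=lambda: {"absent": 0.50, "small": 0.30, "big": 0.20}
    )
    rc_gv: dict = field(default_factory=lambda: {0: 0.60, 1: 0.40})
    child_class: dict = field(
        default_factory=lambda: {"A": 0.45, "B": 0.45, "C": 0.10}
    )

    def validate(self) -> None:
        for name in ("ev_grade", "rc_ev", "gv_size", "rc_gv", "child_class"):
            d = getattr(self, name)
            if abs(sum(d.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} prevalences must sum to 1")


def _sample(rng, dist: dict):
    keys = list(dist.keys())
    probs = np.array([dist[k] for k in keys], float)
    return keys[int(rng.choice(len(keys), p=probs))]


def _child_components(rng, cls: str) -> tuple[int, ...]:
    lo, hi = {"A": (5, 6), "B": (7, 9), "C": (10, 15)}[cls]
    total = int(rng.integers(lo, hi + 1))
    comps = [1] * 5
    for _ in range(total - 5):
        open_idx = [i for i, c in enumerate(comps) if c < 3]
        comps[int(rng.choice(open_idx))] += 1
    return tuple(comps)


def generate_patient(
    rng: np.random.Generator,
    patient_id: str,
    prevalences: CohortPrevalences,
    risk_rule: str = "intro",
) -> PatientRecord:
    ev_grade = _sample(rng, prevalences.ev_grade)
    rc_ev = _sample(rng, prevalences.rc_ev) if ev_grade > 0 else 0
    gv_size = _sample(rng, prevalences.gv_size)
    rc_gv = _sample(rng, prevalences.rc_gv) if gv_size != "absent" else 0
    cls = _sample(rng, prevalences.child_class)
    comps = _child_components(rng, cls)
    ev_risk = (
        riskstrat.stratify_ev(ev_grade, rc_ev, cls, rule=risk_rule).risk
        if ev_grade > 0 else "none"
    )
    gv_risk = (
        riskstrat.stratify_gv(gv_size, rc_gv, cls).risk if gv_size != "absent" else "none"
    )
    return PatientRecord(
        patient_id=patient_id, child_components=comps, child_class=cls,
        true_ev_grade=ev_grade, true_rc_ev=rc_ev,
        true_gv_size=gv_size, true_rc_gv=rc_gv,
        true_ev_risk=ev_risk, true_gv_risk=gv_risk,
    )


def generate_cohort(
    n_patients: int,
    prevalences: CohortPrevalences | None = None,
    seed: int = 0,
    n_frames: int = 20,
    unqualified_rate: float = 0.0,
    fps: float = 7.0,
    risk_rule: str = "intro",
    scene_params: SceneParams = SceneParams(),
    gv_scene_params: GVSceneParams = GVSceneParams(),
) -> list[tuple[PatientRecord, ExamScript]]:
    """Generate a cohort of patients with exam scripts and true risk labels."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    prevalences = prevalences or CohortPrevalences()
    prevalences.validate()
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_patients):
        patient = generate_patient(rng, f"P{i:04d}", prevalences, risk_rule=risk_rule)
        script = generate_exam_video(
            patient, n_frames=n_frames, unqualified_rate=unqualified_rate,
            fps=fps, seed=int(rng.integers(2**31)),
            scene_params=scene_params, gv_scene_params=gv_scene_params,
        )
        cohort.append((patient, script))
    return cohort
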