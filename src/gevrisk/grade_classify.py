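"""Geometric stand-in classifiers for varix grade and size.

Endoscopic grading distinguishes grade 1 (straight, small-caliber),
grade 2 (moderately enlarged, beady) and grade 3 (markedly enlarged,
nodular or tumor-shaped) esophageal varices; gastric varices are
dichotomized at a 5 mm diameter.  In the deployed clinical system these
labels come from trained CNN classifiers; here they are derived from
measurable geometry — medial-axis widths, tortuosity, nodularity — behind
the same classifier contract, so an external predictor honoring the
contract can be substituted.

Width is measured as twice the Euclidean distance transform along the
skeleton path between the two geodesically farthest skeleton endpoints.
Statistics (mean width, width CV, nodularity, tortuosity) are taken on the
path trimmed by half the maximal width at each end: skeletons of discrete
shapes grow 45-degree spurs at blunt ends which would otherwise bias
tortuosity and the width profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.morphology import skeletonize

from .config import GradeThresholds
from .segmentation import VarixInstance

MIN_MEASURABLE_AREA = 10


class UnmeasurableInstanceError(ValueError):
    """Raised for degenerate instances (< 10 px) with no usable geometry."""


@dataclass
class VarixGeometry:
    max_width_mm: float
    mean_width_mm: float
    width_cv: float
    tortuosity: float
    nodularity: int

    def to_dict(self) -> dict:
        return {
            "max_width_mm": self.max_width_mm,
            "mean_width_mm": self.mean_width_mm,
            "width_cv": self.width_cv,
            "tortuosity": self.tortuosity,
            "nodularity": self.nodularity,
        }


def _skeleton_path(skel: np.ndarray) -> tuple[np.ndarray, float] | None:
    """Longest geodesic path through a skeleton.

    Returns (path pixel indices into the skeleton point list as (k,2)
    row/col coordinates, geodesic length) or None when the skeleton is too
    small to carry a path.  Uses the double-sweep heuristic (farthest point
    from an arbitrary start, then farthest from that), exact on trees and
    adequate on near-tree skeletons.
    """
    rows, cols = np.nonzero(skel)
    n = len(rows)
    if n < 2:
        return None
    index = {(r, c): i for i, (r, c) in enumerate(zip(rows, cols))}
    src, dst, wts = [], [], []
    for i, (r, c) in enumerate(zip(rows, cols)):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None and j > i:
                    w = np.hypot(dr, dc)
                    src.append(i)
                    dst.append(j)
                    wts.append(w)
    if not src:
        return None
    graph = coo_matrix((wts + wts, (src + dst, dst + src)), shape=(n, n)).tocsr()

    def farthest(start: int):
        dist = dijkstra(graph, indices=start, directed=False)
        dist[np.isinf(dist)] = -1
        end = int(np.argmax(dist))
        return end, dist[end]

    a, _ = farthest(0)
    b, length = farthest(a)
    dist, pred = dijkstra(graph, indices=a, directed=False, return_predecessors=True)
    path = [b]
    while path[-1] != a and pred[path[-1]] >= 0:
        path.append(int(pred[path[-1]]))
    path = path[::-1]
    coords = np.column_stack([rows[path], cols[path]])
    return coords, float(length)


def measure_varix_geometry(instance: VarixInstance, mm_per_pixel: float) -> VarixGeometry:
    """Measure width/shape descriptors of one varix instance.

    Deterministic; raises :class:`UnmeasurableInstanceError` below 10 px.
    For blob-like instances whose skeleton collapses to a point (e.g.
    gastric variceal mounds) the width falls back to twice the maximal
    distance-transform value and the shape statistics are degenerate
    (cv = 0, tortuosity = 1, nodularity = 0).
    """
    if mm_per_pixel <= 0:
        raise ValueError("mm_per_pixel must be positive")
    if instance.area < MIN_MEASURABLE_AREA:
        raise UnmeasurableInstanceError(
            f"instance of {instance.area} px is below the {MIN_MEASURABLE_AREA} px floor"
        )
    r0, r1, c0, c1 = instance.bbox
    local = np.zeros((r1 - r0 + 2, c1 - c0 + 2), bool)
    local[instance.pixels[:, 0] - r0 + 1, instance.pixels[:, 1] - c0 + 1] = True
    edt = ndimage.distance_transform_edt(local)
    fallback_width = 2.0 * float(edt.max()) * mm_per_pixel

    skel = skeletonize(local)
    path = _skeleton_path(skel)
    if path is None:
        return VarixGeometry(fallback_width, fallback_width, 0.0, 1.0, 0)
    coords, _ = path
    widths_px = 2.0 * edt[coords[:, 0], coords[:, 1]]

    # trim half the maximal width off both ends (end-cap taper + spurs)
    steps = np.hypot(*np.diff(coords, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    trim = widths_px.max() / 2.0
    keep = (cum >= trim) & (cum <= cum[-1] - trim)
    if keep.sum() < 3:
        keep = np.ones(len(coords), bool)
    coords_t, widths_t, cum_t = coords[keep], widths_px[keep], cum[keep]

    path_len = cum_t[-1] - cum_t[0]
    chord = float(np.hypot(*(coords_t[-1] - coords_t[0]).astype(float)))
    tortuosity = path_len / chord if chord > 1.0 else 1.0

    mean_w = float(widths_t.mean())
    cv = float(widths_t.std() / mean_w) if mean_w > 0 else 0.0
    # nodularity: local width maxima exceeding 1.5x the mean width, on a
    # lightly smoothed profile so pixel jitter does not spawn peaks
    profile = ndimage.uniform_filter1d(widths_t, size=min(5, len(widths_t)))
    peaks, _ = signal.find_peaks(profile, height=1.5 * mean_w)
    return VarixGeometry(
        max_width_mm=float(widths_t.max()) * mm_per_pixel,
        mean_width_mm=mean_w * mm_per_pixel,
        width_cv=cv,
        tortuosity=max(1.0, float(tortuosity)),
        nodularity=int(len(peaks)),
    )


def classify_ev_grade(geometry: VarixGeometry, thresholds: GradeThresholds | None = None) -> int:
    """Esophageal varix grade 1-3 from geometry.

    Grade 1: max width below ``w12`` with a flat width profile and no
    nodules.  Grade 3: max width at or above ``w23`` or ``nodularity_3``
    or more nodular bulges.  Grade 2 otherwise (moderately enlarged or
    beady).
    """
    t = thresholds or GradeThresholds()
    if geometry.max_width_mm >= t.w23 or geometry.nodularity >= t.nodularity_3:
        return 3
    if geometry.max_width_mm < t.w12 and geometry.width_cv < t.cv and geometry.nodularity == 0:
        return 1
    return 2


def classify_gv_size(geometry: VarixGeometry, thresholds: GradeThresholds | None = None) -> str:
    """Gastric varix size: 'big' iff maximal diameter >= 5 mm (inclusive)."""
    t = thresholds or GradeThresholds()
    return "big" if geometry.max_width_mm >= t.gv_big_mm else "small"
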