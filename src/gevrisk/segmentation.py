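"""Probability-map thresholding and per-varix instance extraction.

A segmenter is any callable mapping a frame to a :class:`ProbabilityMap`
(the segmenter contract); this module supplies the downstream, model-free
half of the chain — cut-off thresholding (0.4 for varices, 0.5 for red
color signs), connected-component instance extraction — plus a classical
baseline segmenter usable on rendered synthetic frames.

Conventions used package-wide: pixel coordinates are 0-based (row, col);
bounding boxes are half-open ``[r0, r1) x [c0, c1)``; threshold comparison
is inclusive (``p >= cutoff`` is foreground).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage


# ---------------------------------------------------------------------------
# containers


@dataclass
class ProbabilityMap:
    """Per-pixel lesion likelihood in [0, 1] for one target class."""

    values: np.ndarray
    target_class: Literal["ev_varix", "gv_varix", "rc"] = "ev_varix"
    source: str = "unknown"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("probability map must be a 2-D grid")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("probability values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class RasterMask:
    """Binary or instance-labeled pixel grid.

    Binary mode holds {0, 1}; instance mode holds consecutive labels
    ``1..N`` on background 0.
    """

    values: np.ndarray
    mode: Literal["binary", "instance"] = "binary"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("mask must be a 2-D grid")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.all(self.values == np.round(self.values)):
                raise ValueError("mask values must be integers")
            self.values = self.values.astype(np.int32)
        if self.values.size and self.values.min() < 0:
            raise ValueError("mask labels must be non-negative")
        labels = np.unique(self.values)
        labels = labels[labels > 0]
        if self.mode == "binary":
            if labels.size and not np.array_equal(labels, [1]):
                raise ValueError("binary mask may only contain {0, 1}")
        else:
            n = labels.size
            if labels.size and not np.array_equal(labels, np.arange(1, n + 1)):
                raise ValueError("instance labels must be consecutive 1..N")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_instances(self) -> int:
        return int(self.values.max()) if self.values.size else 0

    def as_bool(self) -> np.ndarray:
        return self.values > 0

    @classmethod
    def from_bool(cls, arr: np.ndarray) -> "RasterMask":
        return cls(np.asarray(arr, bool).astype(np.int32), mode="binary")


@dataclass
class VarixInstance:
    """One connected varix component (the unit of per-varix sensitivity)."""

    pixels: np.ndarray  # (k, 2) array of (row, col)
    bbox: tuple[int, int, int, int]  # half-open (r0, r1, c0, c1)
    area: int = field(init=False)
    label: int = 0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        self.area = len(self.pixels)

    def to_mask(self, shape: tuple[int, int]) -> RasterMask:
        out = np.zeros(shape, np.int32)
        out[self.pixels[:, 0], self.pixels[:, 1]] = 1
        return RasterMask(out, mode="binary")


# ---------------------------------------------------------------------------
# operations


def threshold_probability_map(pmap: ProbabilityMap, cutoff: float) -> RasterMask:
    """Binarize a probability map at ``cutoff`` (inclusive: p >= cutoff).

    Default cut-offs in :class:`~gevrisk.config.RunConfig` are 0.4 for
    varix targets and 0.5 for red color signs.
    """
    if not (0.0 < cutoff < 1.0):
        raise ValueError(f"cutoff must lie in (0, 1), got {cutoff}")
    return RasterMask.from_bool(pmap.values >= cutoff)


def extract_instances(mask: RasterMask, connectivity: int = 8) -> list[VarixInstance]:
    """Split a binary mask into connected components.

    Components are labeled deterministically in raster-scan order of each
    component's first pixel.  Returns a (possibly empty) list of
    :class:`VarixInstance`.
    """
    if mask.mode != "binary":
        raise ValueError("extract_instances expects a binary mask")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    labeled, n = ndimage.label(mask.as_bool(), structure=structure)
    # scipy labels in raster-scan order of first pixels already; rely on it
    # but keep the guarantee explicit by sorting on each component's first
    # flattened index.
    out: list[VarixInstance] = []
    objects = ndimage.find_objects(labeled)
    order = []
    for lab in range(1, n + 1):
        sl = objects[lab - 1]
        rows, cols = np.nonzero(labeled[sl] == lab)
        rows = rows + sl[0].start
        cols = cols + sl[1].start
        first = rows[0] * labeled.shape[1] + cols[0]
        order.append((first, rows, cols, sl))
    order.sort(key=lambda t: t[0])
    for i, (_, rows, cols, sl) in enumerate(order, start=1):
        out.append(
            VarixInstance(
                pixels=np.column_stack([rows, cols]),
                bbox=(sl[0].start, sl[0].stop, sl[1].start, sl[1].stop),
                label=i,
            )
        )
    return out


def instances_to_mask(instances: list[VarixInstance], shape: tuple[int, int]) -> RasterMask:
    """Paint instances 1..N back into an instance-mode mask."""
    out = np.zeros(shape, np.int32)
    for i, inst in enumerate(instances, start=1):
        out[inst.pixels[:, 0], inst.pixels[:, 1]] = i
    return RasterMask(out, mode="instance" if instances else "binary")


def baseline_segment(
    frame: np.ndarray,
    target: Literal["ev_varix", "gv_varix", "rc"] = "ev_varix",
    *,
    contrast_span: float = 60.0,
    redness_offset: float = 60.0,
    redness_span: float = 60.0,
) -> ProbabilityMap:
    """Classical stand-in segmenter over an RGB frame.

    Varix targets score each pixel by its rectified darkness contrast
    against the frame's median intensity (varices image darker than the
    surrounding mucosa, which dominates the frame).  The RC target scores
    red-channel dominance ``R - max(G, B)``.  Scores are clipped to
    [0, 1]; a featureless frame maps to an all-zero map.
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError("baseline_segment expects an RGB frame (H, W, 3)")
    f = frame.astype(float)
    if target == "rc":
        dominance = f[..., 0] - np.maximum(f[..., 1], f[..., 2])
        score = (dominance - redness_offset) / redness_span
    else:
        gray = f.mean(axis=2)
        score = (np.median(gray) - gray) / contrast_span
    return ProbabilityMap(np.clip(score, 0.0, 1.0), target_class=target, source="baseline")
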