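"""Evaluation statistics for segmentation and diagnostic tables.

Pixel-level precision/recall/IoU on region masks, per-image mIoU summaries
with threshold fractions, per-varix and per-image detection sensitivity,
k x k diagnostic tables with exact (Clopper-Pearson) 95% confidence
intervals, McNemar's paired test, and the paired-table deltas used to
compare a system against readers on the same patients.

Conventions: a gold varix instance counts as detected when the predicted
foreground covers at least ``coverage_threshold`` (default 0.5) of its
pixels; an image counts as detected when any of its gold instances is;
empty-vs-empty mask pairs score 1.0 on all overlap metrics (flagged via
``degenerate``).  IoU is computed on the region masks themselves;
``boxes=True`` switches to literal bounding-box overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .segmentation import RasterMask, extract_instances


# ---------------------------------------------------------------------------
# confidence intervals


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial CI: [Beta(a/2; k, n-k+1), Beta(1-a/2; k+1, n-k)]."""
    if not (0 <= k <= n) or n <= 0:
        raise ValueError("need 0 <= k <= n with n > 0")
    lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def agresti_coull(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Agresti-Coull adjusted-Wald binomial CI (default for diagnostic
    tables: it reproduces the interval style of standard clinical
    statistics packages)."""
    if not (0 <= k <= n) or n <= 0:
        raise ValueError("need 0 <= k <= n with n > 0")
    z = stats.norm.ppf(1 - alpha / 2)
    n_adj = n + z * z
    p_adj = (k + z * z / 2) / n_adj
    half = z * np.sqrt(p_adj * (1 - p_adj) / n_adj)
    return float(max(0.0, p_adj - half)), float(min(1.0, p_adj + half))


_CI_METHODS = {"clopper-pearson": clopper_pearson, "agresti-coull": agresti_coull}


def proportion_ci(k: int, n: int, method: str = "agresti-coull") -> tuple[float, float]:
    return _CI_METHODS[method](k, n)


def _bootstrap_ci(values: np.ndarray, seed: int, n_boot: int = 2000) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean over images."""
    rng = np.random.default_rng(seed)
    values = np.asarray(values, float)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    means = values[idx].mean(axis=1)
    return float(np.percentile(means, 2.5)), float(np.percentile(means, 97.5))


# ---------------------------------------------------------------------------
# pixel overlap


@dataclass(frozen=True)
class PixelOverlap:
    tp_area: int
    fp_area: int
    fn_area: int
    precision: float
    recall: float
    iou: float
    degenerate: bool = False  # both masks empty


def _bbox_mask(mask: np.ndarray) -> np.ndarray:
    if not mask.any():
        return np.zeros_like(mask)
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    out = np.zeros_like(mask)
    out[rows[0]: rows[-1] + 1, cols[0]: cols[-1] + 1] = True
    return out


def pixel_metrics(pred: RasterMask, gt: RasterMask, boxes: bool = False) -> PixelOverlap:
    """Area-based precision, recall and IoU of two binary masks."""
    if pred.shape != gt.shape:
        raise ValueError("mask dimensions must match")
    p, g = pred.as_bool(), gt.as_bool()
    if boxes:
        p, g = _bbox_mask(p), _bbox_mask(g)
    tp = int((p & g).sum())
    fp = int((p & ~g).sum())
    fn = int((~p & g).sum())
    if tp + fp + fn == 0:
        return PixelOverlap(0, 0, 0, 1.0, 1.0, 1.0, degenerate=True)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    iou = tp / (tp + fp + fn)
    return PixelOverlap(tp, fp, fn, precision, recall, iou)


# ---------------------------------------------------------------------------
# segmentation report


@dataclass
class SegmentationReport:
    n_images: int
    n_varices: int
    miou: float
    miou_ci: tuple[float, float]
    frac_iou_gt_05: float
    frac_iou_gt_05_ci: tuple[float, float]
    frac_iou_gt_06: float
    frac_iou_gt_06_ci: tuple[float, float]
    sens_per_varix: float
    sens_per_varix_ci: tuple[float, float]
    sens_per_image: float
    sens_per_image_ci: tuple[float, float]
    precision: float
    recall: float
    per_image_iou: list[float] = field(default_factory=list)


def segmentation_report(
    pairs: list[tuple[RasterMask, RasterMask]],
    coverage_threshold: float = 0.5,
    seed: int = 0,
    ci_method: str = "agresti-coull",
) -> SegmentationReport:
    """Summarize segmentation quality over (pred, gt) mask pairs.

    ``gt`` may be binary or instance-labeled; binary gold masks are split
    into 8-connected instances for the per-varix count.  Per-image
    sensitivity is computed over images with non-empty gold only.
    """
    if not pairs:
        raise ValueError("need at least one (pred, gt) pair")
    ious, tps, fps, fns = [], 0, 0, 0
    varices_total = varices_hit = 0
    images_total = images_hit = 0
    for pred, gt in pairs:
        gt_bin = RasterMask.from_bool(gt.as_bool())
        ov = pixel_metrics(pred, gt_bin)
        ious.append(ov.iou)
        tps, fps, fns = tps + ov.tp_area, fps + ov.fp_area, fns + ov.fn_area
        if gt.mode == "instance":
            instances = [gt.values == lab for lab in range(1, gt.n_instances + 1)]
        else:
            instances = [inst.to_mask(gt.shape).as_bool() for inst in extract_instances(gt_bin)]
        pred_fg = pred.as_bool()
        hits = [
            (pred_fg & inst).sum() >= coverage_threshold * inst.sum() for inst in instances
        ]
        varices_total += len(instances)
        varices_hit += sum(hits)
        if instances:
            images_total += 1
            images_hit += any(hits)
    ious_arr = np.array(ious)
    gt05 = int((ious_arr > 0.5).sum())
    gt06 = int((ious_arr > 0.6).sum())
    n = len(ious)

    def prop_ci(k, m):
        return proportion_ci(k, m, ci_method) if m else (0.0, 1.0)

    return SegmentationReport(
        n_images=n,
        n_varices=varices_total,
        miou=float(ious_arr.mean()),
        miou_ci=_bootstrap_ci(ious_arr, seed) if n > 1 else (ious_arr[0], ious_arr[0]),
        frac_iou_gt_05=gt05 / n,
        frac_iou_gt_05_ci=prop_ci(gt05, n),
        frac_iou_gt_06=gt06 / n,
        frac_iou_gt_06_ci=prop_ci(gt06, n),
        sens_per_varix=varices_hit / varices_total if varices_total else 0.0,
        sens_per_varix_ci=prop_ci(varices_hit, varices_total),
        sens_per_image=images_hit / images_total if images_total else 0.0,
        sens_per_image_ci=prop_ci(images_hit, images_total),
        precision=tps / (tps + fps) if tps + fps else 0.0,
        recall=tps / (tps + fns) if tps + fns else 0.0,
        per_image_iou=[float(v) for v in ious],
    )


# ---------------------------------------------------------------------------
# diagnostic tables


@dataclass
class DiagnosticTable:
    counts: np.ndarray  # gold rows x predicted cols
    accuracy: float
    accuracy_ci: tuple[float, float]
    sensitivity: float | None = None
    sensitivity_ci: tuple[float, float] | None = None
    specificity: float | None = None
    specificity_ci: tuple[float, float] | None = None
    ppv: float | None = None
    ppv_ci: tuple[float, float] | None = None
    npv: float | None = None
    npv_ci: tuple[float, float] | None = None


def diagnostic_report(counts, ci_method: str = "agresti-coull") -> DiagnosticTable:
    """Accuracy (and, for 2x2 tables with gold-positive row 0 /
    predicted-positive column 0: sensitivity, specificity, PPV, NPV) with
    95% CIs (``agresti-coull`` default, ``clopper-pearson`` available)."""
    m = np.asarray(counts, dtype=int)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("counts must be a square gold x predicted table")
    if (m < 0).any():
        raise ValueError("counts must be non-negative")
    total = int(m.sum())
    if total == 0:
        raise ValueError("table total must be positive")
    correct = int(np.trace(m))
    out = DiagnosticTable(
        counts=m, accuracy=correct / total,
        accuracy_ci=proportion_ci(correct, total, ci_method),
    )
    if m.shape == (2, 2):
        tp, fn, fp, tn = int(m[0, 0]), int(m[0, 1]), int(m[1, 0]), int(m[1, 1])

        def rate(k, n):
            return (k / n, proportion_ci(k, n, ci_method)) if n else (None, None)

        out.sensitivity, out.sensitivity_ci = rate(tp, tp + fn)
        out.specificity, out.specificity_ci = rate(tn, tn + fp)
        out.ppv, out.ppv_ci = rate(tp, tp + fp)
        out.npv, out.npv_ci = rate(tn, tn + fn)
    return out


def mcnemar_test(discordant_b: int, discordant_c: int, total_pairs: int | None = None) -> dict:
    """Two-sided McNemar test on the discordant pair counts.

    Exact binomial when b + c < 25, chi-square with continuity correction
    ((|b-c|-1)^2/(b+c)) otherwise.
    """
    b, c = int(discordant_b), int(discordant_c)
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    if total_pairs is not None and b + c > total_pairs:
        raise ValueError("discordant counts exceed total pairs")
    n = b + c
    if n == 0:
        return {"statistic": 0.0, "p": 1.0, "method": "exact"}
    if n < 25:
        k = min(b, c)
        p = 2.0 * float(stats.binom.cdf(k, n, 0.5))
        return {"statistic": float(k), "p": min(1.0, p), "method": "exact"}
    statistic = (abs(b - c) - 1) ** 2 / n
    p = float(stats.chi2.sf(statistic, df=1))
    return {"statistic": float(statistic), "p": p, "method": "chi2-cc"}


def table3_deltas(system, readers) -> dict:
    """Improvement of a system over readers on the same 2x2 risk tables.

    ``delta_correct_pct``: extra correctly stratified patients as a
    percentage of all patients.  ``delta_lowrisk_pct``: extra correctly
    called gold-low-risk patients as a percentage of gold-low patients
    (patients spared unnecessary treatment).
    """
    s = np.asarray(system, int)
    e = np.asarray(readers, int)
    if s.shape != (2, 2) or e.shape != (2, 2):
        raise ValueError("expected 2x2 gold x predicted tables")
    if s.sum() != e.sum():
        raise ValueError("tables must cover the same patients")
    total = int(s.sum())
    gold_low = int(s[1].sum())
    if e[1].sum() != gold_low:
        raise ValueError("gold margins must agree between tables")
    delta_correct = int(np.trace(s) - np.trace(e))
    delta_lowrisk = int(s[1, 1] - e[1, 1])
    return {
        "delta_correct": delta_correct,
        "delta_correct_pct": 100.0 * delta_correct / total,
        "delta_lowrisk": delta_lowrisk,
        "delta_lowrisk_pct": 100.0 * delta_lowrisk / gold_low if gold_low else 0.0,
        "total": total,
        "gold_low_total": gold_low,
    }
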