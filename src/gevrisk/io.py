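"""File conventions: PNG masks, probability maps, scene/exam manifests.

Byte-level conventions
----------------------
* Binary masks: 8-bit grayscale PNG with values {0, 255}; normalized to
  {0, 1} on load.
* Instance masks: 16-bit grayscale PNG, background 0, instances 1..N
  (consecutive; gaps are rejected on load).
* Probability maps: either 16-bit grayscale PNG scaled by 65535 (lossy at
  ~1.5e-5) or a lossless ``.npy`` single-array file.
* Scenes: ``image.png`` (RGB), ``varix_mask.png`` (16-bit instance),
  ``rc_mask.png`` (8-bit binary), ``labels.json``.
* Exam scripts: a JSON manifest listing frame entries in time order, with
  a schema version and the patient record.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .config import SCHEMA_VERSION
from .segmentation import ProbabilityMap, RasterMask
from .synthdata import ExamScript, Frame, PatientRecord, ScenePhantom, render_frame


# ---------------------------------------------------------------------------
# masks


def save_mask(mask: RasterMask, path: str | Path) -> None:
    path = Path(path)
    if mask.mode == "binary":
        iio.imwrite(path, (mask.values * 255).astype(np.uint8))
    else:
        iio.imwrite(path, mask.values.astype(np.uint16))


def load_mask(path: str | Path, mode: str = "binary") -> RasterMask:
    """Load a PNG mask; binary {0,255} normalizes to {0,1}; instance
    labels must be consecutive 1..N."""
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim != 2:
        raise ValueError("mask PNG must be single-channel")
    if arr.size == 0 or 0 in arr.shape:
        raise ValueError("mask has a zero dimension")
    if mode == "binary":
        values = np.unique(arr)
        if not set(values.tolist()) <= {0, 255} and not set(values.tolist()) <= {0, 1}:
            raise ValueError("binary mask PNG must contain only {0, 255}")
        return RasterMask((arr > 0).astype(np.int32), mode="binary")
    return RasterMask(arr.astype(np.int32), mode="instance")


# ---------------------------------------------------------------------------
# probability maps


def save_probability_map(pmap: ProbabilityMap, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, pmap.values)
    else:
        iio.imwrite(path, np.round(pmap.values * 65535).astype(np.uint16))


def load_probability_map(path: str | Path, target_class: str = "ev_varix") -> ProbabilityMap:
    path = Path(path)
    if path.suffix == ".npy":
        values = np.load(path)
    else:
        values = np.asarray(iio.imread(path)).astype(float) / 65535.0
    return ProbabilityMap(values, target_class=target_class, source=str(path))


# ---------------------------------------------------------------------------
# scenes and exam manifests


def save_scene(scene: ScenePhantom, out_dir: str | Path, render_seed: int = 0) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out_dir / "image.png", render_frame(scene, seed=render_seed))
    instance = np.zeros((scene.height, scene.width), np.uint16)
    for i, m in enumerate(scene.varix_masks, start=1):
        instance[m.as_bool()] = i
    iio.imwrite(out_dir / "varix_mask.png", instance)
    save_mask(scene.rc_mask, out_dir / "rc_mask.png")
    labels = {
        "schema_version": SCHEMA_VERSION,
        "grade": scene.true_ev_grade,
        "rc_grade": scene.true_rc_grade,
        "gv_size": scene.true_gv_size,
        "region": scene.site,
        "mm_per_pixel": scene.mm_per_pixel,
        "lumen_center": list(scene.lumen_center),
    }
    (out_dir / "labels.json").write_text(json.dumps(labels, indent=2, sort_keys=True))
    return out_dir


def load_scene(scene_dir: str | Path) -> ScenePhantom:
    scene_dir = Path(scene_dir)
    labels = json.loads((scene_dir / "labels.json").read_text())
    instance = np.asarray(iio.imread(scene_dir / "varix_mask.png")).astype(np.int32)
    n = int(instance.max())
    varix_masks = [RasterMask.from_bool(instance == i) for i in range(1, n + 1)]
    rc = load_mask(scene_dir / "rc_mask.png", mode="binary")
    scene = ScenePhantom(
        width=instance.shape[1], height=instance.shape[0],
        lumen_center=tuple(labels["lumen_center"]),
        varix_masks=varix_masks, rc_mask=rc,
        true_ev_grade=labels["grade"], true_gv_size=labels["gv_size"],
        true_rc_grade=labels["rc_grade"], mm_per_pixel=labels["mm_per_pixel"],
        site=labels["region"],
    )
    scene.validate()
    return scene


def save_exam_script(script: ExamScript, out_dir: str | Path) -> Path:
    """Write an exam as scene directories plus a JSON manifest in frame order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scene_dirs: dict[int, str] = {}
    for frame in script.frames:
        if id(frame.scene) not in scene_dirs:
            name = f"scene_{len(scene_dirs):03d}"
            save_scene(frame.scene, out_dir / name)
            scene_dirs[id(frame.scene)] = name
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "fps": script.fps,
        "patient": vars(script.patient) if script.patient else None,
        "frames": [
            {
                "index": f.index,
                "region": f.region,
                "qualified": f.qualified,
                "reason": f.reason,
                "scene": scene_dirs[id(f.scene)],
            }
            for f in script.frames
        ],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir


def load_exam_script(exam_dir: str | Path) -> ExamScript:
    exam_dir = Path(exam_dir)
    manifest = json.loads((exam_dir / "manifest.json").read_text())
    if manifest.get("schema_version") != SCHEMA_VERSION:
        raise ValueError("unsupported manifest schema version")
    scenes: dict[str, ScenePhantom] = {}
    frames = []
    for entry in manifest["frames"]:
        name = entry["scene"]
        if name not in scenes:
            scenes[name] = load_scene(exam_dir / name)
        frames.append(
            Frame(index=entry["index"], region=entry["region"],
                  qualified=entry["qualified"], reason=entry["reason"],
                  scene=scenes[name])
        )
    patient = manifest.get("patient")
    if patient:
        patient["child_components"] = tuple(patient["child_components"])
        patient = PatientRecord(**patient)
    return ExamScript(frames=frames, fps=manifest["fps"], patient=patient)


def save_report(report, path: str | Path) -> None:
    """Serialize an ExamReport to JSON (cumulative series as lists)."""
    d = {
        "schema_version": SCHEMA_VERSION,
        "config_hash": report.config_hash,
        "config": report.config,
        "final_labels": report.final_labels,
        "n_frames": report.n_frames,
        "n_qualified": report.n_qualified,
        "empty": report.empty,
        "unsmoothed": report.unsmoothed,
        "filtered_counts": report.filtered_counts,
        "region_tallies": {
            r: {f: {str(k): v for k, v in c.items()} for f, c in fam.items()}
            for r, fam in report.region_tallies.items()
        },
        "cumulative": {
            f: {str(k): np.asarray(v).tolist() for k, v in series.items()}
            for f, series in report.cumulative.items()
        },
    }
    Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))
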