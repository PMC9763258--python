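# File conventions

All artifacts are plain text or PNG; every JSON artifact carries
`schema_version` and reports embed the `config_hash` of the producing
`RunConfig`.

## Masks (PNG)

- **Binary masks** — 8-bit grayscale, values {0, 255}; normalized to {0, 1}
  on load. Any other value is rejected.
- **Instance masks** — 16-bit grayscale, background 0, instances labeled
  consecutively 1..N; gaps in the label set are rejected on load.

## Probability maps

- **`.png`** — 16-bit grayscale, value = `round(p * 65535)` (quantization
  error <= 1/131070).
- **`.npy`** — lossless float64 single-array file.

## Scenes

One directory per scene:

```
scene_000/
  image.png        RGB rendering (uint8)
  varix_mask.png   16-bit instance mask
  rc_mask.png      8-bit binary mask
  labels.json      {schema_version, grade, rc_grade, gv_size, region,
                    mm_per_pixel, lumen_center}
```

`grade` is 0 (absent) to 3; `gv_size` is `absent|small|big`.

## Exam manifests

`manifest.json` at the exam root:

```
{
  "schema_version": "1",
  "fps": 7.0,
  "patient": {patient_id, child_components, child_class, true_* labels},
  "frames": [
    {"index": 0, "region": "esophagus", "qualified": true,
     "reason": null, "scene": "scene_000"},
    ...
  ]
}
```

Frames are listed in non-decreasing `index` order; `region` is drawn from
the retained-site vocabulary (`esophagus`, `squamocolumnar_junction`, four
fundus walls); `reason` for unqualified frames is one of
`blur|chromo|forceps|water|inflation|off-site`.

## Exam reports

`save_report` writes JSON with `final_labels`, `n_frames`/`n_qualified`,
`filtered_counts` by reason, per-region tallies, cumulative per-label
fraction series, the full config echo and its hash.
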