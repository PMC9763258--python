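import itertools

import numpy as np
import pytest

from gevrisk.config import RunConfig
from gevrisk.synthdata import (
    CohortPrevalences,
    NoiseParams,
    generate_cohort,
    generate_exam_video,
    generate_patient,
    generate_varix_scene,
    render_frame,
    SceneParams,
)
from gevrisk.video_pipeline import (
    FrameAssessment,
    PhantomSegmenter,
    accumulate,
    laplacian_sharpness,
    quality_filter,
    run_exam,
    smooth_stream,
)


class TestQualityFilter:
    def test_metadata_passthrough(self):
        assert quality_filter(None, {"qualified": False, "reason": "forceps"}) == (
            False,
            "forceps",
        )

    def test_off_site_region(self):
        assert quality_filter(None, {"region": "duodenum"}) == (False, "off-site")

    def test_retained_region_accepted(self):
        assert quality_filter(None, {"region": "esophagus"}) == (True, None)

    def test_inflation_flag(self):
        assert quality_filter(None, {"inflation": True}) == (False, "inflation")

    def test_blur_ordering_on_rendered_pair(self):
        scene = generate_varix_scene(SceneParams(grade=2, rc_grade=1), seed=4)
        sharp = render_frame(scene, seed=1)
        from scipy import ndimage

        blurred = ndimage.gaussian_filter(sharp.astype(float), (8, 8, 0))
        assert laplacian_sharpness(sharp) > laplacian_sharpness(blurred)
        assert quality_filter(sharp, {"region": "esophagus"})[0]
        assert quality_filter(blurred, {"region": "esophagus"}) == (False, "blur")


class TestSmoothStream:
    def test_three_of_five_majority(self):
        out = smooth_stream([2, 2, 2, 1, 1])
        assert out.labels == [2] and not out.unsmoothed

    def test_unanimity(self):
        assert smooth_stream([1, 1, 1, 1, 1]).labels == [1]

    def test_tie_break_highest_severity_among_modal(self):
        # modal set {1, 2} at count 2; no label reaches quorum 3
        assert smooth_stream([1, 1, 2, 2, 3]).labels == [2]

    def test_short_stream_flagged_unsmoothed(self):
        out = smooth_stream([1, 2, 2])
        assert out.labels == [2] and out.unsmoothed

    def test_sliding_window_length(self):
        out = smooth_stream([1, 1, 1, 2, 2, 2, 2])
        assert len(out.labels) == 3

    def test_quorum_always_wins_exhaustively(self):
        # any label with count >= 3 in a window of 5 must be emitted
        for window in itertools.product((1, 2, 3), repeat=5):
            out = smooth_stream(list(window))
            counts = {lab: window.count(lab) for lab in set(window)}
            winners = [lab for lab, c in counts.items() if c >= 3]
            if winners:
                assert out.labels == [winners[0]]
            else:
                assert out.labels[0] in counts  # emitted label from window set

    def test_idempotent_on_constant_streams(self):
        out = smooth_stream([3] * 10)
        assert out.labels == [3] * 6

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_stream([1, 2], window=2, quorum=3)


def _assessments(labels, region="esophagus", qualified=True):
    out = []
    for i, g in enumerate(labels):
        out.append(
            FrameAssessment(
                frame_index=i, region=region, qualified=qualified,
                ev_grade=g if qualified else None,
                rc_ev=0 if qualified else None,
                gv_size="absent" if qualified else None,
                rc_gv=0 if qualified else None,
            )
        )
    return out


class TestAccumulate:
    def test_constant_stream(self):
        report = accumulate(_assessments([2] * 8))
        assert report.final_labels["ev_grade"] == 2
        series = report.cumulative["ev_grade"][2]
        assert np.allclose(series, 1.0)

    def test_zero_qualified_frames_flagged_empty(self):
        report = accumulate(_assessments([None] * 4, qualified=False))
        assert report.empty
        assert report.final_labels["ev_grade"] == 0

    def test_max_severity_above_floor(self):
        # 70 grade-1 / 30 grade-2 smoothed labels: grade 2 exceeds the 5% floor
        labels = [1] * 70 + [2] * 34  # smoothing keeps 30 windows at grade 2
        report = accumulate(_assessments(labels))
        assert report.final_labels["ev_grade"] == 2

    def test_floor_filters_flicker(self):
        labels = [1] * 100 + [3] * 4  # a 4% grade-3 tail stays below the floor
        report = accumulate(_assessments(labels), RunConfig(aggregation_floor=0.10))
        assert report.final_labels["ev_grade"] == 1

    def test_cumulative_fractions_sum_to_one(self):
        labels = [1] * 10 + [2] * 10 + [1] * 10
        report = accumulate(_assessments(labels))
        series = report.cumulative["ev_grade"]
        total = sum(np.asarray(s) for s in series.values())
        assert np.allclose(total, 1.0)

    def test_cumulative_recomputable_from_scratch(self):
        labels = [1, 1, 2, 2, 2, 1, 3, 3, 3, 3]
        report = accumulate(_assessments(labels))
        smoothed = smooth_stream(labels).labels
        for lab, series in report.cumulative["ev_grade"].items():
            for t in range(len(smoothed)):
                want = np.mean([s == lab for s in smoothed[: t + 1]])
                assert series[t] == pytest.approx(want)

    def test_region_tallies(self):
        report = accumulate(_assessments([2] * 8, region="esophagus"))
        assert report.region_tallies["esophagus"]["ev_grade"][2] == 4

    def test_filtered_reason_counts(self):
        frames = _assessments([1] * 6) + [
            FrameAssessment(9, "esophagus", False, "water"),
            FrameAssessment(10, "esophagus", False, "water"),
        ]
        report = accumulate(frames)
        assert report.filtered_counts == {"water": 2}


class TestRunExam:
    def _patient(self, **kw):
        from gevrisk.synthdata import PatientRecord

        defaults = dict(
            patient_id="T0", child_components=(1, 1, 1, 1, 1), child_class="A",
            true_ev_grade=2, true_rc_ev=0, true_gv_size="absent", true_rc_gv=0,
            true_ev_risk="high", true_gv_risk="none",
        )
        defaults.update(kw)
        return PatientRecord(**defaults)

    def test_recovers_grade2_rc0_phantom(self):
        script = generate_exam_video(self._patient(), n_frames=12, seed=6)
        report = run_exam(script, PhantomSegmenter())
        assert report.final_labels["ev_grade"] == 2
        assert report.final_labels["rc_ev"] == 0
        assert report.final_labels["gv_size"] == "absent"

    def test_recovers_gv_labels(self):
        patient = self._patient(
            true_ev_grade=0, true_ev_risk="none",
            true_gv_size="big", true_rc_gv=1, true_gv_risk="high",
        )
        script = generate_exam_video(patient, n_frames=12, seed=6)
        report = run_exam(script, PhantomSegmenter())
        assert report.final_labels["gv_size"] == "big"
        assert report.final_labels["rc_gv"] == 1
        assert report.final_labels["ev_grade"] == 0

    def test_empty_script_flagged(self):
        patient = self._patient()
        script = generate_exam_video(patient, n_frames=6, seed=2)
        for f in script.frames:
            f.qualified, f.reason = False, "blur"
        report = run_exam(script, PhantomSegmenter())
        assert report.empty

    def test_deterministic_across_runs(self):
        script = generate_exam_video(self._patient(true_rc_ev=2), n_frames=10, seed=8)
        seg = PhantomSegmenter(NoiseParams(blur=1.0, additive=0.05), seed=3)
        a = run_exam(script, seg)
        b = run_exam(script, seg)
        assert a.final_labels == b.final_labels
        assert a.config_hash == b.config_hash

    def test_unqualified_frames_counted(self):
        script = generate_exam_video(
            self._patient(), n_frames=40, unqualified_rate=0.4, seed=9
        )
        report = run_exam(script, PhantomSegmenter())
        assert report.n_frames == 40
        assert report.n_qualified == sum(f.qualified for f in script.frames)
        assert sum(report.filtered_counts.values()) == 40 - report.n_qualified
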