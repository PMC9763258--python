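"""Run the full per-frame chain over one synthetic exam video.

A grade-3 EV + big-GV patient is examined over 24 frames (30% unusable:
blur, dye, forceps, water, inflation).  Qualified frames are segmented,
graded and majority-smoothed (3 of 5 consecutive); the report shows the
per-region tallies and the final per-exam labels the smoothed stream
supports.
"""

from gevrisk import PatientRecord, PhantomSegmenter, generate_exam_video, run_exam

patient = PatientRecord(
    patient_id="demo", child_components=(1, 2, 2, 1, 1), child_class="B",
    true_ev_grade=3, true_rc_ev=2, true_gv_size="big", true_rc_gv=1,
    true_ev_risk="high", true_gv_risk="high",
)
script = generate_exam_video(patient, n_frames=24, unqualified_rate=0.3, seed=11)
report = run_exam(script, PhantomSegmenter())

print(f"frames: {report.n_frames} total, {report.n_qualified} qualified, "
      f"filtered: {report.filtered_counts}")
for region, families in report.region_tallies.items():
    print(f"  {region}: ev_grade tallies {dict(families['ev_grade'])}, "
          f"gv_size tallies {dict(families['gv_size'])}")
print(f"final labels: {report.final_labels}  (true: grade {patient.true_ev_grade}, "
      f"RC{patient.true_rc_ev}, GV {patient.true_gv_size}, RC-GV {patient.true_rc_gv})")
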