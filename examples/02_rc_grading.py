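"""Cluster red color signs with DBSCAN and grade their distribution.

RC blobs are reduced to centroids and clustered with minPts = 1 and the
frame-scaled radius eps = sqrt(w*h/6.5).  The grade follows cluster count
and angular span around the lumen: few/localized -> RC1, numerous or
circumferential -> RC3.
"""

from gevrisk import (
    SceneParams,
    dbscan,
    epsilon_for_image,
    generate_varix_scene,
    grade_rc_ev,
    rc_points_from_mask,
)

for true_rc in (1, 2, 3):
    scene = generate_varix_scene(SceneParams(grade=2, rc_grade=true_rc), seed=5)
    points = rc_points_from_mask(scene.rc_mask, lumen_center=scene.lumen_center)
    eps = epsilon_for_image(scene.width, scene.height)
    clustering = dbscan(points, eps=eps, min_pts=1)
    grade = grade_rc_ev(clustering)
    print(f"true RC{true_rc}: {len(points)} spots -> {clustering.n_clusters} cluster(s) "
          f"at eps={eps:.1f} px, angular span {clustering.overall_extent_deg:.0f} deg "
          f"-> graded RC{grade}")
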