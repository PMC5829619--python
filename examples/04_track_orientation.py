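"""Track each leaf across a day and measure its orientation change.

Three epochs (07:00, 12:30, 18:00) of a moving plant are segmented and the
leaves matched across epochs by least-squares 3D surface matching.  For
every tracked leaf the change of its PCA normal is expressed as spherical
azimuth (aspect) and elevation (hyponasty) angles of the difference
vector, per interval.
"""

import numpy as np

import leafmotion as lm
from leafmotion.orientation import orientation_change

scene = lm.default_scene(seed=1, n_epochs=3, sampling=0.004)

segmentations = []
for cloud in scene.clouds:
    filtered, _, _ = lm.remove_outliers(cloud)
    canopy = filtered.select(np.flatnonzero(filtered.points[:, 2] > 0.11))
    segmentations.append(lm.segment_cloud(canopy))

tracks = lm.track_epochs(segmentations)
full = [t for t in tracks if len(t.segments) == 3]
print(f"{len(full)}/{scene.n_leaves} leaves tracked across all 3 epochs\n")
print(f"{'leaf':>4} {'interval':>16} {'az. change':>12} {'elev. change':>13}")
for track in full:
    for ch in orientation_change(track, epoch_order=list(scene.epochs)):
        if ch.cumulative or ch.theta is None:
            continue
        print(f"{track.leaf_id:>4} {ch.interval[0]:>7}->{ch.interval[1]:<8}"
              f"{ch.theta:>10.1f} deg {ch.phi:>10.1f} deg")
# Azimuth/elevation angles of the normal-difference vector: positive
# elevation change means the leaf rose (hyponasty), the azimuth says in
# which horizontal direction the blade reoriented.
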