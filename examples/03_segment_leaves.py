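"""Segment a plant scan into individual leaves and score the result.

Octree split-and-merge on point-normal homogeneity: normals are estimated
per point, the cloud is subdivided while cell normals vary, high-variation
cells (edges, stem) are removed, and flat seed cells grow into leaf
segments.  The generator's ground-truth labels provide the confusion
matrix and global accuracy.
"""

import numpy as np

import leafmotion as lm

scene = lm.make_plant(seed=1, sampling=0.003)
cloud, labels = scene.clouds[0], scene.labels[0]

filtered, removed, _ = lm.remove_outliers(cloud)
labels = np.delete(labels, removed)
keep = np.flatnonzero(filtered.points[:, 2] > 0.11)  # crop to the canopy
canopy, labels = filtered.select(keep), labels[keep]

segments = lm.segment_cloud(canopy)
auto = lm.labels_from_segments(segments, len(canopy))
confusion, accuracy = lm.evaluate_segmentation(auto, labels)

print(f"{len(segments)} leaves found in {len(canopy)} canopy points "
      f"(true count: {scene.n_leaves})")
for seg in segments:
    theta, phi = lm.spherical_angles(seg.pca_normal)
    print(f"  leaf {seg.leaf_id}: {len(seg):5d} points, "
          f"normal azimuth {theta:7.1f} deg, elevation {phi:5.1f} deg")
print(f"global accuracy vs ground truth: {accuracy:.2f}%")
# Each segment is one leaf; its PCA normal (third eigenvector of the point
# covariance) summarizes the blade's orientation.
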