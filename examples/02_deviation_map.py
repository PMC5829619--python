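"""Quantify overnight leaf movement with a cloud-to-cloud deviation map.

Builds two epochs of a plant in which a single leaf tilts by 35 degrees,
computes chamfer and quadric-refined deviation maps from the later scan to
the earlier one, and summarizes displacement per leaf.
"""

import numpy as np

import leafmotion as lm
from leafmotion.synthetic import evolve_epoch, make_plant

scene = make_plant(seed=8, sampling=0.004, outlier_frac=0.0)
motions = [None] * scene.n_leaves
motions[2] = (0.0, -35.0)  # leaf 3 folds 35 degrees toward the stem
evolve_epoch(scene, motions)

reference, compared = scene.clouds
dev = lm.quadric_refined_deviation(compared, reference)
summary = lm.deviation_summary(dev, scene.labels[1])

print(f"deviation map ({dev.method}): mean {summary['mean'] * 100:.2f} cm, "
      f"max {summary['max'] * 100:.2f} cm over {summary['n']} points")
for leaf, s in sorted(summary["per_label"].items()):
    if leaf <= 0:
        continue
    print(f"  leaf {leaf}: mean {s['mean'] * 100:5.2f} cm   "
          f"max {s['max'] * 100:5.2f} cm")
# The moved leaf dominates both the mean and the maximum displacement;
# static leaves sit at the 2 mm range-noise floor.
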