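# leafmotion

Quantifying diel (day-course) leaf movement of a potted plant from
multi-temporal terrestrial-LiDAR point clouds.

Rosette plants such as *Calathea* reorient their leaves over the day —
opening toward the light, closing at night. A terrestrial laser scanner
parked in front of the plant captures its surface as a point cloud every few
hours, independent of ambient light. `leafmotion` turns such a series of
scans into movement numbers:

- **Outlier filtering** — interference returns are removed by the
  distance-statistics rule: with `d̄` and `σ_d` the mean and standard
  deviation of per-point mean neighbor distances (neighborhood: a 1.6 cm
  sphere), points whose mean neighbor distance exceeds
  `L_d = d̄ + p·σ_d` are discarded.
- **Registration check & deviation maps** — epochs are verified rigid-body
  aligned (point-to-point ICP), cropped to a common bounding box, and
  compared by cloud-to-cloud deviation maps: a k-d-tree chamfer pass,
  optionally refined by fitting a local least-squares quadric
  `z = a₀ + a₁x + a₂y + a₃x² + a₄xy + a₅y²` to the reference surface around
  each compared point.
- **Leaf segmentation** — per-point normals (k-neighborhood plane fit or
  local Delaunay facet averaging) drive an octree split-and-merge: cells are
  subdivided while their normals' angular spread exceeds a tolerance,
  high-variation cells (leaf edges, stem) are removed, and flat seed cells
  grow into individual-leaf segments over face-adjacent, surface-connected
  cells.
- **Leaf tracking** — segments are matched across epochs by rigid
  least-squares 3D surface matching (point-to-plane Gauss–Markov iteration),
  accepted below an RMS-residual threshold.
- **Orientation change** — each leaf's orientation is its PCA normal (the
  eigenvector of the segment covariance Σ with smallest eigenvalue); movement
  between epochs is the difference of normals, reported as spherical azimuth
  θ = atan2(y, x) (aspect) and elevation Φ = arctan(z/√(x²+y²)) (hyponasty)
  of the difference vector, in degrees.
- **Canopy volume** — the backside a single viewpoint cannot see is
  recovered by mirroring across an estimated vertical symmetry plane; the
  canopy's enveloped space is the convex-hull volume in dm³, and its signed
  per-interval differences track whole-plant opening and closing.

Because no scan data ships with the method, the package includes a
first-class synthetic-scene generator (`leafmotion.synthetic`): multi-epoch
rosette plants with per-point leaf labels, analytic per-leaf normals, exact
rigid leaf motions, millimeter range noise, interference outliers and
single-viewpoint occlusion. Every pipeline stage is validated against this
ground truth.

## Worked example

```bash
python examples/03_segment_leaves.py
```

```
9 leaves found in 5277 canopy points (true count: 9)
  leaf 1:   539 points, normal azimuth   -34.6 deg, elevation  69.1 deg
  leaf 2:   507 points, normal azimuth    91.2 deg, elevation  70.4 deg
  ...
global accuracy vs ground truth: 100.00%
```

Nine leaf segments are recovered from a 9-leaf synthetic scan; each line
gives a leaf's size and the spherical angles of its PCA normal (elevation
near 90° = a flat, horizontal blade). The global accuracy is the trace of
the point-wise confusion matrix against the generator's labels.

The other examples each demonstrate one capability end to end — outlier
filtering (`01`), deviation maps (`02`), day-course orientation tracking
(`04`), one-sided-scan volume recovery (`05`) and the file-to-report
pipeline (`06`). A thin CLI wraps the same functions:

```bash
leafmotion simulate --seed 1 --out-dir scans/
leafmotion filter scans/scan_0700.ply filtered.ply
leafmotion segment filtered.ply --out labels.csv
leafmotion run config.yaml
```

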