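"""Shared fixtures: coarse synthetic scenes reused across the suite.

Scenes are sampled at 4 mm (instead of the 1 mm production default) so the
whole suite runs in minutes; the geometry, noise level and motion
magnitudes are the study conditions of the generator defaults.
"""

from __future__ import annotations

import numpy as np
import pytest

import leafmotion as lm

#: canopy floor used when cropping scenes to the plant (pot top + margin)
CANOPY_FLOOR = 0.11


def circular_diff(a: float, b: float) -> float:
    """Absolute difference of two angles in degrees, on the circle."""
    return abs((a - b + 180.0) % 360.0 - 180.0)


def canopy_view(cloud, labels):
    """Filter outliers and crop to the canopy; labels carried along."""
    filtered, removed, _ = lm.remove_outliers(cloud)
    kept_labels = np.delete(labels, removed)
    keep = np.flatnonzero(filtered.points[:, 2] > CANOPY_FLOOR)
    return filtered.select(keep), kept_labels[keep]


@pytest.fixture(scope="session")
def scene3():
    """A 3-epoch moving 9-leaf plant at 4 mm sampling, fixed seed."""
    return lm.default_scene(seed=1, n_epochs=3, sampling=0.004)


@pytest.fixture(scope="session")
def segmented3(scene3):
    """Per-epoch (cloud, reference labels, segments) for ``scene3``."""
    out = []
    for cloud, labels in zip(scene3.clouds, scene3.labels):
        cropped, ref = canopy_view(cloud, labels)
        out.append((cropped, ref, lm.segment_cloud(cropped)))
    return out


@pytest.fixture(scope="session")
def sphere_points():
    """40k points uniform on a 0.1 m-radius sphere surface (fixed seed)."""
    rng = np.random.default_rng(7)
    u = rng.uniform(-1.0, 1.0, 40000)
    phi = rng.uniform(0.0, 2.0 * np.pi, 40000)
    r = np.sqrt(1.0 - u**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), u]) * 0.1
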