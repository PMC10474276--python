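"""Shared fixtures: analytic prism phantoms built voxel-by-voxel.

The prism builders construct label volumes with exact axis-aligned integer
geometry so every metric has a closed-form expected value, independently of
the package's own phantom generator.
"""

from __future__ import annotations

import numpy as np
import pytest

from rcmorph import LabelVolume, RoiSchema
from rcmorph.schema import MUSCLES


@pytest.fixture(scope="session")
def schema() -> RoiSchema:
    return RoiSchema.default()


def make_prism_volume(
    schema: RoiSchema,
    n_slices: int = 50,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    scapula_area_vox: tuple[int, int] = (10, 10),
    muscle_areas_vox: dict[str, tuple[int, int]] | None = None,
    fat_every: dict[str, int] | None = None,
    shape_rc: tuple[int, int] = (96, 96),
) -> LabelVolume:
    """Coextensive uniform prisms: scapula plus four muscle boxes.

    Each ROI spans all ``n_slices`` with a constant rectangular
    cross-section, so cumulative volumes are exactly linear in depth.
    ``fat_every[m] = k`` relabels every k-th in-plane column stripe of
    muscle m as fat, giving an exact fat fraction of 1/k per slice.
    """
    rows, cols = shape_rc
    vox = np.zeros((n_slices, rows, cols), dtype=np.int16)
    h, w = scapula_area_vox
    r0, c0 = rows // 2 - h // 2, cols // 2 - w // 2
    vox[:, r0 : r0 + h, c0 : c0 + w] = schema.label("scapula")

    anchors = {
        "supraspinatus": (8, cols // 2 - 10),
        "infraspinatus": (rows - 24, 8),
        "teres_minor": (rows - 24, cols - 28),
        "subscapularis": (8, 8),
    }
    if muscle_areas_vox is None:
        muscle_areas_vox = {m: (10, 20) for m in MUSCLES}
    for m, (mh, mw) in muscle_areas_vox.items():
        ar, ac = anchors[m]
        block = vox[:, ar : ar + mh, ac : ac + mw]
        assert block.shape[1:] == (mh, mw), f"{m} prism does not fit the grid"
        assert not block.any(), f"{m} prism overlaps another ROI"
        block[:] = schema.label(m)
        k = (fat_every or {}).get(m)
        if k:
            vox[:, ar : ar + mh, ac : ac + mw : k] = schema.label(schema.fat_roi(m))
    return LabelVolume(voxels=vox, spacing=spacing, schema=schema)


@pytest.fixture
def prism_volume(schema) -> LabelVolume:
    """Scapula 10×10 mm², four 200 mm² fat-free muscles, 50 slices at 1 mm."""
    return make_prism_volume(schema)


def make_blob_volume(
    schema: RoiSchema,
    seed: int,
    n_slices: int = 25,
    shape_rc: tuple[int, int] = (40, 40),
    spacing: tuple[float, float, float] = (2.0, 1.5, 1.5),
) -> LabelVolume:
    """Random disjoint blobs: every ROI drawn i.i.d. over the grid.

    The scapula is forced nonempty in the first and last slice so the
    captured extent spans the whole grid.
    """
    rng = np.random.default_rng(seed)
    labels = [0, *schema.labels.values()]
    probs = np.array([0.6] + [0.4 / len(schema.labels)] * len(schema.labels))
    vox = rng.choice(labels, size=(n_slices, *shape_rc), p=probs).astype(np.int16)
    scap = schema.label("scapula")
    vox[0, 0, 0] = scap
    vox[-1, 0, 0] = scap
    return LabelVolume(voxels=vox, spacing=spacing, schema=schema)
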