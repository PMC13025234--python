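"""3D segmentation and volumetrics against closed forms and ground truth."""

import math

import numpy as np
import pytest

from nucarch.errors import GeometryError
from nucarch.geometry import ImageGeometry
from nucarch.morphometry2d import SegmentationParams
from nucarch.morphometry3d import LabeledObjects3D, measure_3d, segment_3d
from nucarch.synthdata.shapes import prolate_sphericity


def _ball_mask(n, radius, center=None, spacing=(1.0, 1.0, 1.0)):
    center = center or ((n - 1) / 2.0,) * 3
    zz, yy, xx = np.mgrid[:n, :n, :n].astype(float)
    zz *= spacing[0] / spacing[0]  # indices; distances scaled below
    d2 = (
        ((zz - center[0]) * spacing[0]) ** 2
        + ((yy - center[1]) * spacing[1]) ** 2
        + ((xx - center[2]) * spacing[2]) ** 2
    )
    return (d2 <= radius**2).astype(np.int32)


def test_ball_matches_closed_form():
    geom = ImageGeometry((50, 50, 50), (0.1, 0.1, 0.1))
    mask = _ball_mask(50, 20.0)  # radius 20 voxels = 2 um
    m = measure_3d(LabeledObjects3D(mask, geom))
    assert m.volume_um3[0] == pytest.approx(4 / 3 * math.pi * 2.0**3, rel=0.02)
    assert m.sphericity[0] == pytest.approx(1.0, abs=0.02)


def test_cube_matches_closed_form():
    geom = ImageGeometry((60, 60, 60), (0.1, 0.1, 0.1))
    mask = np.zeros((60, 60, 60), np.int32)
    mask[5:55, 5:55, 5:55] = 1
    m = measure_3d(LabeledObjects3D(mask, geom))
    assert m.sphericity[0] == pytest.approx((math.pi / 6) ** (1 / 3), abs=0.03)


def test_blank_stack_segments_to_zero_objects(geom3d):
    out = segment_3d(np.zeros(geom3d.shape, np.uint16), geom3d,
                     SegmentationParams())
    assert out.n_objects == 0


def test_2d_input_rejected(geom2d):
    with pytest.raises(GeometryError):
        segment_3d(np.zeros(geom2d.shape), geom2d, SegmentationParams())


def test_segmentation_recovers_truth_volumes(image3d_noiseless):
    img = image3d_noiseless
    out = segment_3d(img.channels["dna"], img.geometry,
                     SegmentationParams(smoothing_sigma=0.0, min_size=20.0),
                     "dna")
    truth = img.truth_metrics[img.truth_metrics.channel == "dna"]
    assert out.n_objects == len(truth) == 8
    measured = measure_3d(out)
    # match objects by centroid proximity, then compare volumes within 5 %
    for _, t in truth.iterrows():
        d = np.hypot(
            np.hypot(measured.centroid_z_um - t.centroid_z_um,
                     measured.centroid_y_um - t.centroid_y_um),
            measured.centroid_x_um - t.centroid_x_um,
        )
        m = measured.iloc[int(np.argmin(d))]
        assert m.volume_um3 == pytest.approx(t.volume_um3, rel=0.05)


def test_anisotropic_and_isotropic_volumes_agree():
    radius = 2.0  # um
    iso = ImageGeometry((60, 60, 60), (0.1, 0.1, 0.1))
    m_iso = measure_3d(LabeledObjects3D(_ball_mask(60, radius, spacing=iso.spacing), iso))
    aniso = ImageGeometry((20, 60, 60), (0.3, 0.1, 0.1))
    zz, yy, xx = np.mgrid[:20, :60, :60].astype(float)
    d2 = (((zz - 9.5) * 0.3) ** 2 + ((yy - 29.5) * 0.1) ** 2
          + ((xx - 29.5) * 0.1) ** 2)
    m_aniso = measure_3d(LabeledObjects3D((d2 <= radius**2).astype(np.int32), aniso))
    assert m_aniso.volume_um3[0] == pytest.approx(m_iso.volume_um3[0], rel=0.05)


def test_voxelization_error_shrinks_with_radius():
    errors = []
    for r in (5, 10, 20, 40):
        n = 2 * r + 10
        geom = ImageGeometry((n, n, n), (0.1, 0.1, 0.1))
        m = measure_3d(LabeledObjects3D(_ball_mask(n, float(r)), geom))
        true = 4 / 3 * math.pi * (r * 0.1) ** 3
        errors.append(abs(m.volume_um3[0] / true - 1.0))
    assert all(a > b for a, b in zip(errors, errors[1:]))


def test_sphericity_scale_invariant_under_uniform_spacing():
    mask = _ball_mask(50, 20.0)
    a = measure_3d(LabeledObjects3D(mask, ImageGeometry((50, 50, 50), (0.1,) * 3)))
    b = measure_3d(LabeledObjects3D(mask, ImageGeometry((50, 50, 50), (0.2,) * 3)))
    assert abs(a.sphericity[0] - b.sphericity[0]) < 0.01


def test_ball_attains_highest_sphericity():
    geom = ImageGeometry((60, 60, 60), (0.1, 0.1, 0.1))
    ball = measure_3d(LabeledObjects3D(_ball_mask(60, 20.0), geom)).sphericity[0]
    cube = np.zeros((60, 60, 60), np.int32)
    cube[14:46, 14:46, 14:46] = 1
    zz, yy, xx = np.mgrid[:60, :60, :60].astype(float)
    ell = ((((zz - 29.5) / 25) ** 2 + ((yy - 29.5) / 13) ** 2
            + ((xx - 29.5) / 13) ** 2) <= 1).astype(np.int32)
    for other in (cube, ell):
        assert measure_3d(LabeledObjects3D(other, geom)).sphericity[0] < ball


def test_generated_prolate_ellipsoids_match_analytic_sphericity(rng):
    """Axis-ratio 2:1:1 ellipsoids at random sizes: mean measured
    sphericity within 0.02 of the closed-form prolate value."""
    expected = prolate_sphericity(2.0)
    vals = []
    for _ in range(100):
        a = rng.uniform(8.0, 12.0)  # equatorial semi-axis, voxels
        c = 2.0 * a
        nz, nxy = int(2 * c + 8), int(2 * a + 8)
        geom = ImageGeometry((max(nz, 16), max(nxy, 16), max(nxy, 16)),
                             (0.1, 0.1, 0.1))
        zz, yy, xx = np.mgrid[: geom.shape[0], : geom.shape[1], : geom.shape[2]]
        cz, cy, cx = [(s - 1) / 2.0 for s in geom.shape]
        mask = ((((zz - cz) / c) ** 2 + ((yy - cy) / a) ** 2
                 + ((xx - cx) / a) ** 2) <= 1).astype(np.int32)
        vals.append(measure_3d(LabeledObjects3D(mask, geom)).sphericity[0])
    assert abs(np.mean(vals) - expected) < 0.02


def test_single_voxel_object_skipped_with_warning():
    geom = ImageGeometry((16, 16, 16), (0.1, 0.1, 0.1))
    mask = np.zeros((16, 16, 16), np.int32)
    mask[4:10, 4:10, 4:10] = 1
    mask[14, 14, 14] = 2
    with pytest.warns(UserWarning, match="single voxel"):
        m = measure_3d(LabeledObjects3D(mask, geom))
    assert list(m.label) == [1]


def test_z_border_objects_excluded_by_default():
    geom = ImageGeometry((24, 96, 96), (0.2, 0.2, 0.2))
    img = np.zeros((24, 96, 96))
    zz, yy, xx = np.mgrid[:24, :96, :96].astype(float)
    # one ball fully inside, one crossing the first z-plane
    img[((zz - 12) ** 2 + (yy - 30) ** 2 + (xx - 30) ** 2) <= 64] = 1000.0
    img[((zz - 1) ** 2 + (yy - 70) ** 2 + (xx - 70) ** 2) <= 64] = 1000.0
    params = SegmentationParams(smoothing_sigma=0.0, threshold=500.0,
                                exclude_border=False)
    assert segment_3d(img, geom, params).n_objects == 1
    assert segment_3d(img, geom, params, exclude_z_border=False).n_objects == 2
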