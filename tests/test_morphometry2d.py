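"""2D segmentation and morphometry against closed forms and ground truth."""

import math

import numpy as np
import pytest
from skimage.draw import disk

from nucarch.errors import GeometryError
from nucarch.geometry import ImageGeometry
from nucarch.morphometry2d import (
    LabeledObjects2D,
    SegmentationParams,
    assign_compartments,
    freeze_threshold,
    measure_2d,
    segment_2d,
)
from nucarch.synthdata import NoiseSpec, NuclearPhenotypeSpec
from nucarch.synthdata.imaging import rasterize_boundary_2d
from nucarch.synthdata.shapes import build_boundary_2d


def _disc_mask(shape, center, radius):
    mask = np.zeros(shape, dtype=np.int32)
    rr, cc = disk(center, radius)
    mask[rr, cc] = 1
    return mask


def test_disc_matches_closed_form():
    geom = ImageGeometry((128, 128), (0.1, 0.1))
    m = measure_2d(LabeledObjects2D(_disc_mask((128, 128), (64, 64), 50), geom))
    assert m.area_um2[0] == pytest.approx(math.pi * 5.0**2, rel=0.01)
    assert m.circularity[0] == pytest.approx(1.0, abs=0.02)


def test_square_matches_closed_form():
    geom = ImageGeometry((400, 400), (0.1, 0.1))
    mask = np.zeros((400, 400), dtype=np.int32)
    mask[50:350, 50:350] = 1
    m = measure_2d(LabeledObjects2D(mask, geom))
    assert m.circularity[0] == pytest.approx(math.pi / 4.0, abs=0.03)


def test_circularity_never_exceeds_one_on_large_discs():
    geom = ImageGeometry((360, 360), (0.1, 0.1))
    for r in (50, 80, 120):
        m = measure_2d(LabeledObjects2D(_disc_mask((360, 360), (180, 180), r), geom))
        assert m.circularity[0] <= 1.0
        # pre-clip overshoot is bounded: 4*pi*A/P^2 stays within 2 % of 1
        overshoot = 4 * math.pi * m.area_um2[0] / m.perimeter_um[0] ** 2
        assert overshoot < 1.02


def test_circularity_is_scale_invariant():
    mask = _disc_mask((256, 256), (128, 128), 100)
    fine = measure_2d(LabeledObjects2D(mask, ImageGeometry((256, 256), (0.1, 0.1))))
    coarse = measure_2d(LabeledObjects2D(mask, ImageGeometry((256, 256), (0.2, 0.2))))
    assert coarse.area_um2[0] == pytest.approx(4 * fine.area_um2[0], rel=1e-6)
    assert abs(coarse.circularity[0] - fine.circularity[0]) < 0.01


def test_blank_image_segments_to_zero_objects(geom2d):
    out = segment_2d(np.zeros(geom2d.shape, dtype=np.uint16), geom2d,
                     SegmentationParams())
    assert out.n_objects == 0
    # constant non-zero image under Otsu is the same empty case
    out = segment_2d(np.full(geom2d.shape, 500, dtype=np.uint16), geom2d,
                     SegmentationParams())
    assert out.n_objects == 0


def test_shape_mismatch_raises(geom2d):
    with pytest.raises(GeometryError):
        segment_2d(np.zeros((10, 10)), geom2d, SegmentationParams())


def test_segmentation_recovers_ground_truth_nuclei(image2d_noiseless):
    img = image2d_noiseless
    out = segment_2d(img.channels["dna"], img.geometry,
                     SegmentationParams(smoothing_sigma=0.0, min_size=20.0),
                     "dna")
    truth = img.truth_masks["dna"]
    assert out.n_objects == int(truth.max()) == 12
    # each segmented label overlaps exactly one truth object with high Jaccard
    for lbl in range(1, out.n_objects + 1):
        seg = out.label_mask == lbl
        hit = np.unique(truth[seg])
        hit = hit[hit > 0]
        assert len(hit) == 1
        tru = truth == hit[0]
        jacc = (seg & tru).sum() / (seg | tru).sum()
        assert jacc > 0.9


def test_exclude_border_removes_edge_objects():
    geom = ImageGeometry((200, 200), (0.1, 0.1))
    img = np.zeros((200, 200))
    for center in ((50, 50), (140, 140), (5, 100)):  # last touches the border
        rr, cc = disk(center, 20, shape=(200, 200))
        img[rr, cc] = 1000.0
    keep = segment_2d(img, geom, SegmentationParams(
        smoothing_sigma=0.0, threshold=500.0, exclude_border=False))
    drop = segment_2d(img, geom, SegmentationParams(
        smoothing_sigma=0.0, threshold=500.0, exclude_border=True))
    assert keep.n_objects == 3
    assert drop.n_objects == 2


def test_measured_circularity_tracks_generator_truth(rng):
    """200 perturbed nuclei: measured cohort mean within 0.02 of the
    analytic truth mean."""
    geom = ImageGeometry((200, 200), (0.1, 0.1))
    truths, measured = [], []
    for _ in range(200):
        b = build_boundary_2d(rng, area=120.0, n_harmonics=4,
                              target_circularity=0.84)
        truths.append(b.metrics()[2])
        mask = rasterize_boundary_2d(b, geom, (10.0, 10.0)).astype(np.int32)
        measured.append(measure_2d(LabeledObjects2D(mask, geom)).circularity[0])
    assert abs(np.mean(measured) - np.mean(truths)) < 0.02


def test_circularity_decreases_with_boundary_perturbation(rng):
    """Strictly monotone decrease of mean measured circularity with the
    generator's irregularity amplitude."""
    geom = ImageGeometry((200, 200), (0.1, 0.1))
    means = []
    for amp in (0.0, 0.06, 0.12, 0.2):
        vals = []
        for _ in range(50):
            b = build_boundary_2d(rng, area=120.0, n_harmonics=4, amplitude=amp)
            mask = rasterize_boundary_2d(b, geom, (10.0, 10.0)).astype(np.int32)
            vals.append(measure_2d(LabeledObjects2D(mask, geom)).circularity[0])
        means.append(np.mean(vals))
    assert all(a > b for a, b in zip(means, means[1:]))


def test_anisotropic_2d_pixels_rejected():
    geom = ImageGeometry((64, 64), (0.1, 0.2))
    with pytest.raises(GeometryError):
        measure_2d(LabeledObjects2D(np.ones((64, 64), np.int32), geom))


def test_frozen_threshold_reused_across_images(geom2d):
    spec = NuclearPhenotypeSpec(n_cells=4, mean_size=120.0, size_cv=0.1)
    from nucarch.synthdata import generate_image

    base = generate_image(spec, [], NoiseSpec(), geom2d, seed=1)
    params = SegmentationParams(smoothing_sigma=0.2, min_size=20.0)
    t = freeze_threshold([base.channels["dna"]], geom2d, params)
    frozen = params.with_threshold(t)
    assert frozen.threshold == t
    later = generate_image(spec, [], NoiseSpec(), geom2d, seed=2)
    out = segment_2d(later.channels["dna"], geom2d, frozen, "dna")
    assert out.n_objects == 4


class TestAssignCompartments:
    geom = ImageGeometry((64, 64), (0.1, 0.1))

    def _objs(self, mask):
        return LabeledObjects2D(np.asarray(mask, np.int32), self.geom)

    def test_child_inside_single_parent(self):
        parent = np.zeros((64, 64)); parent[10:40, 10:40] = 1
        child = np.zeros((64, 64)); child[20:25, 20:25] = 1
        out = assign_compartments(self._objs(parent), self._objs(child))
        assert out.mapping == {1: 1}
        assert out.orphans == []

    def test_child_in_background_is_orphan(self):
        parent = np.zeros((64, 64)); parent[10:20, 10:20] = 1
        child = np.zeros((64, 64)); child[40:45, 40:45] = 1
        out = assign_compartments(self._objs(parent), self._objs(child))
        assert out.mapping == {}
        assert out.orphans == [1]

    def test_exact_tie_goes_to_lower_parent_label(self):
        parent = np.zeros((64, 64)); parent[:, :32] = 1; parent[:, 32:] = 2
        child = np.zeros((64, 64)); child[10:20, 28:36] = 1  # 50/50 split
        out = assign_compartments(self._objs(parent), self._objs(child))
        assert out.mapping == {1: 1}

    def test_geometry_mismatch_raises(self):
        other = LabeledObjects2D(
            np.zeros((64, 64), np.int32), ImageGeometry((64, 64), (0.2, 0.2)))
        with pytest.raises(GeometryError):
            assign_compartments(self._objs(np.zeros((64, 64))), other)

    def test_generated_compartments_have_no_orphans(self, image2d_noiseless):
        img = image2d_noiseless
        parents = LabeledObjects2D(img.truth_masks["dna"], img.geometry)
        children = LabeledObjects2D(img.truth_masks["nucleolin"], img.geometry)
        out = assign_compartments(parents, children)
        assert out.orphans == []
        assert len(out.mapping) == int(img.truth_masks["nucleolin"].max())
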