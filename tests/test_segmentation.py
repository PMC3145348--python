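"""Segmentation, compartment construction and speckle detection, each
checked against small brute-force oracles where geometry permits."""

import numpy as np
import pytest

from assayscreen.segmentation import (
    SegmentationParams,
    assign_parents,
    detect_speckles,
    dilate_objects,
    geodesic_costs_dijkstra,
    propagate_cells,
    segment_nuclei,
    subtract_compartment,
    tophat_enhance,
)
from conftest import disk_labels, render_disk


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def nearest_object_brute(objects, distance):
    """Per-pixel nearest-object assignment by exhaustive distance scan."""
    h, w = objects.shape
    coords = {
        lab: np.argwhere(objects == lab) for lab in np.unique(objects) if lab > 0
    }
    out = np.zeros_like(objects)
    for r in range(h):
        for c in range(w):
            best, best_lab = np.inf, 0
            for lab in sorted(coords):
                d = np.sqrt(((coords[lab] - (r, c)) ** 2).sum(axis=1)).min()
                if d < best:
                    best, best_lab = d, lab
            if best <= distance:
                out[r, c] = best_lab
    return out


def opening_brute(img, radius):
    """Morphological opening = erosion then dilation with a disk, by loops."""
    h, w = img.shape
    offs = [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    ]
    big = np.inf
    eroded = np.empty_like(img)
    for r in range(h):
        for c in range(w):
            m = big
            for dy, dx in offs:
                rr, cc = r + dy, c + dx
                v = img[rr, cc] if 0 <= rr < h and 0 <= cc < w else big
                m = min(m, v)
            eroded[r, c] = m
    opened = np.empty_like(img)
    for r in range(h):
        for c in range(w):
            m = -big
            for dy, dx in offs:
                rr, cc = r + dy, c + dx
                if 0 <= rr < h and 0 <= cc < w:
                    m = max(m, eroded[rr, cc])
            opened[r, c] = m
    return opened


# ---------------------------------------------------------------------------
# segment_nuclei
# ---------------------------------------------------------------------------

class TestSegmentNuclei:
    def test_blank_raster(self):
        assert segment_nuclei(np.zeros((64, 64))).max() == 0

    def test_nonfinite_rejected(self):
        img = np.zeros((16, 16))
        img[3, 3] = np.nan
        with pytest.raises(ValueError):
            segment_nuclei(img)

    def test_single_disk(self):
        img = render_disk((96, 96), (48, 48), 12, value=0.8, background=0.05)
        labels = segment_nuclei(img, SegmentationParams(min_area=100, max_area=2000))
        assert labels.max() == 1
        area = (labels == 1).sum()
        assert abs(area - np.pi * 12**2) < 0.1 * np.pi * 12**2

    def test_labels_consecutive(self):
        img = np.full((96, 96), 0.05)
        for c in [(20, 20), (20, 70), (70, 45)]:
            img = np.maximum(img, render_disk((96, 96), c, 8, 0.9, 0.0))
        labels = segment_nuclei(img, SegmentationParams(min_area=50, max_area=1000))
        assert sorted(np.unique(labels)) == [0, 1, 2, 3]

    def test_border_objects_removed(self):
        img = render_disk((64, 64), (0, 32), 10, 0.9, 0.05)
        labels = segment_nuclei(img, SegmentationParams(min_area=20, max_area=2000))
        assert labels.max() == 0

    def test_declump_touching_disks(self):
        truth_centers = [(40, 30), (40, 52)]
        img = np.full((80, 80), 0.05)
        for c in truth_centers:
            img = np.maximum(img, render_disk((80, 80), c, 12, 0.9, 0.0))
        labels = segment_nuclei(
            img, SegmentationParams(min_area=100, max_area=2000, declump=True)
        )
        assert labels.max() == 2
        for lab in (1, 2):
            cy, cx = np.argwhere(labels == lab).mean(axis=0)
            d = min(np.hypot(cy - a, cx - b) for a, b in truth_centers)
            assert d < 3

    def test_no_declump_merges_touching_disks(self):
        img = np.full((80, 80), 0.05)
        for c in [(40, 30), (40, 52)]:
            img = np.maximum(img, render_disk((80, 80), c, 12, 0.9, 0.0))
        labels = segment_nuclei(
            img, SegmentationParams(min_area=100, max_area=2000, declump=False)
        )
        assert labels.max() == 1


# ---------------------------------------------------------------------------
# dilate / subtract
# ---------------------------------------------------------------------------

class TestDilate:
    def test_zero_distance_identity(self):
        labels = disk_labels((40, 40), [(20, 20)], 6)
        assert np.array_equal(dilate_objects(labels, 0), labels)

    def test_disk_area_growth(self):
        labels = disk_labels((80, 80), [(40, 40)], 10)
        out = dilate_objects(labels, 8)
        area = (out == 1).sum()
        assert abs(area - np.pi * 18**2) < 0.1 * np.pi * 18**2

    def test_matches_brute_force_nearest(self):
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[8:12, 6:10] = 1
        labels[20:25, 18:23] = 2
        labels[5:8, 24:28] = 3
        for d in (0, 3, 10):
            assert np.array_equal(
                dilate_objects(labels, d), nearest_object_brute(labels, d)
            )

    def test_equidistant_boundary_between_two_objects(self):
        labels = disk_labels((48, 64), [(24, 20), (24, 42)], 8)  # 6 px gap
        out = dilate_objects(labels, 10)
        brute = nearest_object_brute(labels, 10)
        assert np.array_equal(out, brute)
        assert (out == 1).any() and (out == 2).any()
        # objects never merge: original pixels keep their labels
        assert np.array_equal(out[labels > 0], labels[labels > 0])

    def test_negative_distance(self):
        with pytest.raises(ValueError):
            dilate_objects(np.zeros((4, 4), dtype=int), -1)


class TestSubtract:
    def test_equal_compartments_give_empty_rings(self):
        labels = disk_labels((40, 40), [(20, 20)], 6)
        out = subtract_compartment(labels, labels)
        assert out.max() == 0

    def test_ring_geometry(self):
        inner = disk_labels((64, 64), [(32, 32)], 10)
        outer = disk_labels((64, 64), [(32, 32)], 15)
        ring = subtract_compartment(outer, inner)
        expected = np.pi * (15**2 - 10**2)
        assert abs((ring == 1).sum() - expected) < 0.1 * expected

    def test_exact_pixel_counts_per_label(self):
        inner = disk_labels((64, 96), [(32, 24), (32, 70)], 7)
        outer = dilate_objects(inner, 6)
        ring = subtract_compartment(outer, inner)
        for lab in (1, 2):
            assert (ring == lab).sum() == (outer == lab).sum() - (inner == lab).sum()
            assert not ((ring == lab) & (inner == lab)).any()

    def test_containment_violation(self):
        inner = disk_labels((32, 32), [(16, 16)], 6)
        outer = disk_labels((32, 32), [(10, 10)], 6)
        with pytest.raises(ValueError, match="containment"):
            subtract_compartment(outer, inner)


# ---------------------------------------------------------------------------
# propagate_cells
# ---------------------------------------------------------------------------

class TestPropagate:
    def test_threshold_above_max_collapses_to_seeds(self):
        seeds = disk_labels((32, 32), [(16, 16)], 4)
        green = np.full((32, 32), 0.3)
        out = propagate_cells(seeds, green, threshold=0.9)
        assert np.array_equal(out, seeds)

    def test_uniform_foreground_single_seed_fills_component(self):
        seeds = disk_labels((48, 48), [(24, 24)], 3)
        green = render_disk((48, 48), (24, 24), 18, value=0.5)
        out = propagate_cells(seeds, green, threshold=0.4)
        assert np.array_equal(out > 0, green >= 0.4)
        assert set(np.unique(out)) == {0, 1}

    def test_unreachable_foreground_stays_background(self):
        seeds = disk_labels((40, 40), [(10, 10)], 3)
        green = np.zeros((40, 40))
        green[5:16, 5:16] = 0.5
        green[30:38, 30:38] = 0.5  # disconnected island, no seed
        out = propagate_cells(seeds, green, threshold=0.4)
        assert out[32, 32] == 0
        assert out[10, 10] == 1

    def test_two_seeds_uniform_intensity_boundary_equidistant(self):
        seeds = disk_labels((40, 60), [(20, 15), (20, 45)], 2)
        green = np.full((40, 60), 0.5)
        out = propagate_cells(seeds, green, threshold=0.1, regularization=1.0)
        # everything left of the midline belongs to seed 1, right to seed 2
        assert (out[:, :28] != 2).all()
        assert (out[:, 33:] != 1).all()

    def test_matches_dijkstra_oracle(self, rng):
        shape = (24, 24)
        green = rng.uniform(0.2, 0.8, shape)
        seeds = np.zeros(shape, dtype=np.int32)
        seeds[4, 4] = 1
        seeds[20, 19] = 2
        out = propagate_cells(seeds, green, threshold=0.0, regularization=0.05)
        gy, gx = np.gradient(green)
        cost = np.sqrt(0.05 + gy**2 + gx**2)
        d1 = geodesic_costs_dijkstra(cost, [(4, 4)])
        d2 = geodesic_costs_dijkstra(cost, [(20, 19)])
        margin = np.abs(d1 - d2)
        agree = (out == np.where(d1 <= d2, 1, 2)) | (margin < 1e-6)
        assert agree.all()

    def test_large_regularization_equals_nearest_seed(self):
        seeds = disk_labels((40, 40), [(12, 12), (28, 30)], 2)
        green = np.full((40, 40), 0.5)
        out = propagate_cells(seeds, green, threshold=0.0, regularization=1e6)
        nearest = dilate_objects(seeds, 1e9)
        # away from exact ties the two assignments agree
        disagree = (out != nearest).mean()
        assert disagree < 0.02

    def test_no_seeds_rejected(self):
        with pytest.raises(ValueError, match="seed"):
            propagate_cells(np.zeros((8, 8), dtype=int), np.ones((8, 8)) * 0.5, 0.1)


# ---------------------------------------------------------------------------
# top-hat + speckles
# ---------------------------------------------------------------------------

class TestTophat:
    def test_constant_raster_gives_zero(self):
        out = tophat_enhance(np.full((32, 32), 0.7), 3)
        assert np.allclose(out, 0)

    def test_single_bright_pixel_preserved(self):
        img = np.zeros((32, 32))
        img[16, 16] = 0.9
        out = tophat_enhance(img, 3)
        assert out[16, 16] == pytest.approx(0.9)
        out[16, 16] = 0
        assert np.allclose(out, 0)

    def test_element_size_selects_feature_scale(self):
        img = render_disk((64, 64), (32, 32), 10, value=0.8)
        inside = img > 0
        small_elem = tophat_enhance(img, 5)    # disk survives opening -> ~0
        large_elem = tophat_enhance(img, 15)   # disk removed -> full response
        # discrete-disk openings leave a few boundary pixels, so compare
        # the bulk response over the disk
        assert small_elem[inside].mean() < 0.05
        assert large_elem[inside].mean() > 0.7

    def test_matches_brute_force_opening(self, rng):
        img = rng.uniform(0, 1, (20, 20))
        for radius in (1, 2, 3):
            expected = np.maximum(img - opening_brute(img, radius), 0)
            assert np.allclose(tophat_enhance(img, radius), expected, atol=1e-12)

    def test_radius_below_one_rejected(self):
        with pytest.raises(ValueError):
            tophat_enhance(np.zeros((8, 8)), 0)


class TestSpeckles:
    def plant_spots(self, parents, spots, value=0.8):
        img = np.zeros(parents.shape)
        for (r, c) in spots:
            img[r - 1 : r + 2, c - 1 : c + 2] = value
        return img

    def test_zero_enhanced_gives_zero_speckles(self):
        parents = disk_labels((64, 64), [(32, 32)], 20)
        labels, pmap = detect_speckles(np.zeros((64, 64)), parents)
        assert labels.max() == 0 and pmap == {}

    def test_planted_spots_recovered_with_parents(self):
        parents = disk_labels((80, 80), [(25, 25), (55, 55)], 18)
        spots = {(20, 20): 1, (30, 28): 1, (25, 33): 1, (55, 50): 2, (60, 60): 2}
        enhanced = self.plant_spots(parents, list(spots))
        labels, pmap = detect_speckles(enhanced, parents, min_area=2, max_area=50)
        assert labels.max() == 5
        recovered = sorted(pmap.values())
        assert recovered == sorted(spots.values())

    def test_size_filter_drops_large_blob(self):
        parents = disk_labels((80, 80), [(40, 40)], 30)
        enhanced = self.plant_spots(parents, [(30, 30), (40, 50), (50, 32)])
        enhanced[36:48, 36:46] = 0.8  # 120 px blob > max_area
        labels, pmap = detect_speckles(enhanced, parents, min_area=2, max_area=50)
        assert labels.max() == 3

    def test_per_object_threshold_beats_global_on_uneven_background(self):
        # dim spots in one cell, bright background in the other
        parents = disk_labels((80, 160), [(40, 40), (40, 120)], 25)
        enhanced = np.zeros((80, 160))
        enhanced[parents == 2] = 0.5          # uniformly bright cell, no spots
        enhanced[30:32, 35:37] = 0.2          # dim spot in cell 1
        enhanced[48:50, 44:46] = 0.2
        labels_po, pmap_po = detect_speckles(
            enhanced, parents, min_area=2, max_area=50, per_object=True
        )
        assert sorted(pmap_po.values()) == [1, 1]

    def test_empty_parents_with_per_object_rejected(self):
        with pytest.raises(ValueError):
            detect_speckles(np.zeros((8, 8)), np.zeros((8, 8), dtype=int))


class TestAssignParents:
    def test_child_inside_parent(self):
        parents = disk_labels((40, 40), [(10, 10), (30, 30)], 8)
        children = disk_labels((40, 40), [(30, 30)], 2)
        assert assign_parents(children, parents) == {1: 2}

    def test_majority_overlap_wins(self):
        parents = np.zeros((10, 10), dtype=np.int32)
        parents[:, :6] = 1
        parents[:, 6:] = 2
        children = np.zeros((10, 10), dtype=np.int32)
        children[4, 3:8] = 1  # 3 px on parent 1, 2 px on parent 2
        assert assign_parents(children, parents) == {1: 1}

    def test_tie_goes_to_lower_parent(self):
        parents = np.zeros((10, 10), dtype=np.int32)
        parents[:, :5] = 2
        parents[:, 5:] = 1
        children = np.zeros((10, 10), dtype=np.int32)
        children[4, 3:7] = 1  # 2 px on each parent
        assert assign_parents(children, parents) == {1: 1}

    def test_background_only_child_maps_to_zero(self):
        parents = np.zeros((10, 10), dtype=np.int32)
        parents[0:2, 0:2] = 1
        children = np.zeros((10, 10), dtype=np.int32)
        children[7:9, 7:9] = 1
        assert assign_parents(children, parents) == {1: 0}

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            assign_parents(np.zeros((4, 4), dtype=int), np.zeros((5, 4), dtype=int))


class TestNestingInvariants:
    def test_compartment_nesting_and_label_preservation(self):
        nuclei = disk_labels((96, 96), [(30, 30), (60, 66)], 7)
        dilated = dilate_objects(nuclei, 6)
        ring = subtract_compartment(dilated, nuclei)
        for lab in (1, 2):
            nuc, dil, rg = nuclei == lab, dilated == lab, ring == lab
            assert (nuc & ~dil).sum() == 0          # nucleus inside dilation
            assert (rg & nuc).sum() == 0            # ring disjoint from nucleus
            assert np.array_equal(rg, dil & ~nuc)   # ring is the set difference
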