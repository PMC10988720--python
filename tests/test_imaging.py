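"""Imaging-chain tests: projection, segmentation, compartments, features."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from plomcon import generate_scene
from plomcon.imaging import (
    aggregate_median,
    compute_confluency,
    derive_compartments,
    detect_nuclei,
    filter_fields,
    max_intensity_projection,
    measure_features,
    segment_cells,
)


def _disk_labels(shape, centers, radii):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    lab = np.zeros(shape, dtype=np.int32)
    for i, ((r0, c0), r) in enumerate(zip(centers, radii), start=1):
        lab[(rr - r0) ** 2 + (cc - c0) ** 2 <= r**2] = i
    return lab


class TestMIP:
    def test_single_plane_is_identity(self):
        img = np.arange(12.0).reshape(1, 3, 4)
        np.testing.assert_array_equal(max_intensity_projection(img), img[0])

    def test_elementwise_max_by_hand(self):
        stack = np.array([[[0, 1], [2, 0]], [[3, 0], [0, 4]]], dtype=float)
        np.testing.assert_array_equal(
            max_intensity_projection(stack), [[3, 1], [2, 4]]
        )

    def test_all_zero_stack(self):
        assert max_intensity_projection(np.zeros((3, 4, 4))).sum() == 0

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            max_intensity_projection(np.zeros((0, 4, 4)))

    @given(arrays(np.float64, (3, 6, 6), elements=st.floats(0, 1e3)),
           st.permutations(range(3)))
    def test_invariant_to_plane_order(self, stack, perm):
        np.testing.assert_array_equal(
            max_intensity_projection(stack), max_intensity_projection(stack[list(perm)])
        )


class TestDetectNuclei:
    def test_blank_image_yields_no_nuclei(self):
        assert detect_nuclei(np.zeros((64, 64))).max() == 0

    def test_two_synthetic_nuclei_match_ground_truth(self):
        stacks, truth = generate_scene(2, (128, 128), seed=5)
        labels = detect_nuclei(max_intensity_projection(stacks["nuclear_marker"]))
        assert labels.max() == 2
        # each detected nucleus overlaps its true mask with IoU >= 0.7
        for cid in (1, 2):
            true = truth.nucleus_labels == cid
            best = max(
                ((labels == d) & true).sum() / ((labels == d) | true).sum()
                for d in (1, 2)
            )
            assert best >= 0.7

    def test_nucleus_below_min_area_removed(self):
        # no smoothing so the bright region is exactly 9 px
        img = np.zeros((64, 64))
        img[30:33, 30:33] = 100.0
        assert detect_nuclei(img, min_area=10, smooth_sigma=0).max() == 0
        assert detect_nuclei(img, min_area=9, smooth_sigma=0).max() == 1


class TestSegmentCells:
    def test_two_separated_cells_counted(self):
        stacks, truth = generate_scene(2, (128, 128), seed=6)
        nuclei = detect_nuclei(max_intensity_projection(stacks["nuclear_marker"]))
        cells = segment_cells(max_intensity_projection(stacks["cyto_marker"]), nuclei)
        assert len(np.unique(cells)) - 1 == 2

    def test_zero_seeds_gives_all_background(self):
        cells = segment_cells(np.random.default_rng(0).poisson(50, (32, 32)).astype(float),
                              np.zeros((32, 32), dtype=np.int32))
        assert cells.max() == 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            segment_cells(np.zeros((10, 10)), np.zeros((8, 8), dtype=np.int32))

    def test_touching_cells_split_between_their_nuclei(self):
        # two cells closer than two radii: watershed must keep one nucleus per cell
        from scipy import ndimage as ndi

        shape = (96, 96)
        centers = [(48, 34), (48, 60)]
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        cyto = np.zeros(shape)
        nuc = np.zeros(shape)
        for (r0, c0) in centers:
            cyto[(rr - r0) ** 2 + (cc - c0) ** 2 <= 16**2] += 120.0
            nuc[(rr - r0) ** 2 + (cc - c0) ** 2 <= 6**2] += 200.0
        cyto = ndi.gaussian_filter(cyto, 2)
        nuclei = detect_nuclei(nuc)
        assert nuclei.max() == 2
        cells = segment_cells(cyto, nuclei)
        assert set(np.unique(cells)) == {0, 1, 2}
        for cid in (1, 2):
            owners = np.unique(nuclei[cells == cid])
            assert set(owners[owners > 0]) == {cid}


class TestCompartments:
    def test_disk_cell_cytoplasm_area_close_to_annulus(self):
        cell = _disk_labels((64, 64), [(32, 32)], [10])
        nuc = _disk_labels((64, 64), [(32, 32)], [4])
        cmap = derive_compartments(cell, nuc)
        cmap.validate()
        area = (cmap.cytoplasm_labels == 1).sum()
        assert area == pytest.approx(math.pi * (100 - 16), rel=0.10)

    def test_nucleus_equal_to_cell_gives_empty_cytoplasm(self):
        cell = _disk_labels((64, 64), [(32, 32)], [8])
        cmap = derive_compartments(cell, cell.copy())
        assert (cmap.cytoplasm_labels == 1).sum() == 0

    def test_membrane_ring_width_one_close_to_perimeter(self):
        cell = _disk_labels((64, 64), [(32, 32)], [10])
        nuc = _disk_labels((64, 64), [(32, 32)], [4])
        cmap = derive_compartments(cell, nuc, membrane_width=1)
        ring = (cmap.plasma_membrane_labels == 1).sum()
        perimeter = 2 * math.pi * 10
        assert perimeter / 2 <= ring <= perimeter * 2

    def test_cell_without_nucleus_dropped(self, caplog):
        cell = _disk_labels((64, 64), [(20, 20), (44, 44)], [8, 8])
        nuc = _disk_labels((64, 64), [(20, 20)], [3])  # cell 2 has no nucleus
        cmap = derive_compartments(cell, nuc)
        assert list(cmap.cell_ids) == [1]


class TestConfluencyGate:
    def test_confluency_fractions(self):
        assert compute_confluency(np.zeros((10, 10))) == 0.0
        half = np.zeros((10, 10), dtype=int)
        half[:5] = 1
        assert compute_confluency(half) == 0.5

    def test_generated_scene_confluency_matches_truth(self):
        stacks, truth = generate_scene(6, (192, 192), seed=8)
        nuclei = detect_nuclei(max_intensity_projection(stacks["nuclear_marker"]))
        cells = segment_cells(max_intensity_projection(stacks["cyto_marker"]), nuclei)
        assert compute_confluency(cells) == pytest.approx(truth.confluency, rel=0.10)

    def test_gate_boundaries_inclusive(self):
        fields = ["a", "b", "c", "d", "e"]
        conf = [0.10, 0.20, 0.40, 0.65, 0.70]
        assert filter_fields(fields, conf) == ["b", "c", "d"]

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            filter_fields(["a"], [0.5], low=0.7, high=0.2)


class TestMeasureFeatures:
    def _simple_map(self):
        cell = _disk_labels((64, 64), [(32, 32)], [10])
        nuc = _disk_labels((64, 64), [(32, 32)], [4])
        return derive_compartments(cell, nuc)

    def test_uniform_image_gives_constant_means_and_unit_ratio(self):
        cmap = self._simple_map()
        df = measure_features(np.full((64, 64), 7.0), cmap, "X")
        assert set(df["compartment"]) == {
            "nucleus", "cytoplasm", "plasma_membrane", "nuclear_membrane",
            "nucleus/cytoplasm",
        }
        for comp in ("nucleus", "cytoplasm"):
            assert df.loc[df.compartment == comp, "value"].item() == 7.0
        assert df.loc[df.compartment == "nucleus/cytoplasm", "value"].item() == 1.0

    def test_nuclear_to_cytoplasmic_ratio(self):
        cmap = self._simple_map()
        img = np.full((64, 64), 2.0)
        img[cmap.nucleus_labels == 1] = 10.0
        df = measure_features(img, cmap, "X")
        assert df.loc[df.compartment == "nucleus/cytoplasm", "value"].item() == pytest.approx(5.0)

    def test_empty_cytoplasm_yields_no_cytoplasm_or_ratio_record(self):
        cell = _disk_labels((64, 64), [(32, 32)], [8])
        cmap = derive_compartments(cell, cell.copy())
        df = measure_features(np.full((64, 64), 3.0), cmap, "X")
        assert "cytoplasm" not in set(df["compartment"])
        assert "nucleus/cytoplasm" not in set(df["compartment"])


class TestAggregateMedian:
    def _records(self, values, time_h=1.0):
        return pd.DataFrame({
            "protein": "X", "compartment": "nucleus",
            "time_h": time_h, "value": values,
        })

    def test_median_definition_odd_and_even(self):
        t = aggregate_median(self._records([1.0, 2.0, 100.0]), "control")
        assert t.values[0, 0] == 2.0
        t = aggregate_median(self._records([3.0, 5.0]), "control")
        assert t.values[0, 0] == 4.0

    def test_matches_sort_based_oracle(self, rng):
        values = rng.gamma(5.0, 10.0, size=50)
        t = aggregate_median(self._records(values), "control")
        s = np.sort(values)
        oracle = 0.5 * (s[24] + s[25])
        assert t.values[0, 0] == oracle

    @given(st.permutations(range(9)))
    def test_invariant_to_record_permutation(self, perm):
        values = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0])
        base = aggregate_median(self._records(values), "c")
        shuf = aggregate_median(self._records(values[list(perm)]), "c")
        np.testing.assert_array_equal(base.values, shuf.values)

    def test_incomplete_feature_excluded(self, caplog):
        df = pd.DataFrame({
            "protein": ["X", "X", "Y"],
            "compartment": ["nucleus"] * 3,
            "time_h": [1.0, 2.0, 1.0],  # Y missing at t=2
            "value": [1.0, 2.0, 3.0],
        })
        t = aggregate_median(df, "control")
        assert t.features == (("X", "nucleus"),)


class TestEndToEnd:
    def test_well_separated_scenes_recover_exact_cell_count(self):
        hits = 0
        for seed in range(20):
            stacks, truth = generate_scene(8, (256, 256), seed=seed)
            nuclei = detect_nuclei(max_intensity_projection(stacks["nuclear_marker"]))
            cells = segment_cells(max_intensity_projection(stacks["cyto_marker"]), nuclei)
            cmap = derive_compartments(cells, nuclei)
            cmap.validate()
            hits += cmap.cell_ids.size == len(truth.cell_centers)
        assert hits >= 19
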