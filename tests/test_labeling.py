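"""Spectral-angle math, SAM selection, label assignment, dataset extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import hsibrain as hb
from hsibrain.errors import InvalidClassError, UndefinedAngleError
from hsibrain.labeling import assign_selection, sam_angle, sam_select


class TestSamAngle:
    def test_identity_orthogonality_scale(self):
        x = np.array([0.3, 0.5, 0.2])
        assert sam_angle(x, x) == pytest.approx(0.0, abs=1e-6)
        assert sam_angle([1, 0], [0, 1]) == pytest.approx(90.0)
        assert sam_angle(x, 5 * x) == pytest.approx(0.0, abs=1e-6)

    def test_zero_vector_rejected(self):
        with pytest.raises(UndefinedAngleError):
            sam_angle([0, 0], [1, 1])

    @settings(deadline=None, derandomize=True)
    @given(hnp.arrays(np.float64, 4, elements=st.floats(0.01, 10)),
           hnp.arrays(np.float64, 4, elements=st.floats(0.01, 10)))
    def test_symmetry_and_range(self, a, b):
        ang = sam_angle(a, b)
        assert ang == pytest.approx(sam_angle(b, a))
        assert 0 <= ang <= 90  # positive spectra stay in the first orthant

    @settings(deadline=None, derandomize=True)
    @given(hnp.arrays(np.float64, 5, elements=st.floats(0.01, 10)),
           hnp.arrays(np.float64, 5, elements=st.floats(0.01, 10)),
           st.floats(0.0, 1.0))
    def test_angle_to_convex_combination_bounded(self, a, b, t):
        mix = t * a + (1 - t) * b
        assert sam_angle(a, mix) <= sam_angle(a, b) + 1e-6


class TestSamSelect:
    def _cube_two_regions(self):
        """Left half proportional to spectrum A, right half to spectrum B."""
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([4.0, 3.0, 2.0, 1.0])
        data = np.empty((6, 8, 4))
        rng = np.random.default_rng(0)
        scale = 0.5 + rng.random((6, 8, 1))  # brightness varies, shape fixed
        data[:, :4] = a
        data[:, 4:] = b
        return hb.HSCube(data * scale, np.arange(4, dtype=float) + 400.0,
                         stage="normalized"), a, b

    def test_recovers_spectral_region_exactly(self):
        cube, a, b = self._cube_two_regions()
        # threshold strictly between within-region (0) and cross-region angle
        thr = sam_angle(a, b) / 2
        sel = sam_select(cube, (0, 0), thr)
        expected = np.zeros((6, 8), dtype=bool)
        expected[:, :4] = True
        np.testing.assert_array_equal(sel.mask, expected)

    def test_vacuous_and_zero_thresholds(self):
        cube, _, _ = self._cube_two_regions()
        assert sam_select(cube, (0, 0), 180.0).mask.all()
        # proportional pixels sit at angle ~0 up to float rounding (<1e-3 deg)
        exact = sam_select(cube, (0, 0), 1e-3).mask
        assert exact[:, :4].all() and not exact[:, 4:].any()

    def test_monotone_in_threshold(self):
        cube, a, b = self._cube_two_regions()
        prev = np.zeros((6, 8), dtype=bool)
        for thr in (0.001, 1.0, 30.0, 90.0, 180.0):
            mask = sam_select(cube, (2, 2), thr).mask
            assert np.all(prev <= mask)
            prev = mask

    def test_radian_unit_switch(self):
        cube, _, _ = self._cube_two_regions()
        deg = sam_select(cube, (0, 0), 45.0, unit="deg").mask
        rad = sam_select(cube, (0, 0), np.pi / 4, unit="rad").mask
        np.testing.assert_array_equal(deg, rad)

    def test_out_of_bounds_reference(self):
        cube, _, _ = self._cube_two_regions()
        with pytest.raises(IndexError):
            sam_select(cube, (99, 0), 1.0)


class TestAssignAndExtract:
    def _selection(self, mask):
        return hb.labeling.SamSelection((0, 0), 1.0, mask)

    def test_assign_counts_and_keep_first(self):
        lmap = hb.LabelMap(np.zeros((4, 4), dtype=int))
        m1 = np.zeros((4, 4), dtype=bool)
        m1[:2] = True
        lmap, conflicts = assign_selection(lmap, self._selection(m1), 2)
        assert conflicts == 0
        assert lmap.counts() == {2: 8}
        m2 = np.zeros((4, 4), dtype=bool)
        m2[1:3] = True  # overlaps row 1 (8 already-tumor pixels -> 4 conflicts)
        lmap2, conflicts = assign_selection(lmap, self._selection(m2), 1)
        assert conflicts == 4
        assert lmap2.counts() == {1: 4, 2: 8}
        np.testing.assert_array_equal(lmap2.labels[1], 2)  # first labels kept

    def test_overwrite_and_invalid_class(self):
        lmap = hb.LabelMap(np.full((2, 2), 1))
        sel = self._selection(np.ones((2, 2), dtype=bool))
        out, _ = assign_selection(lmap, sel, 3, policy="overwrite")
        assert out.counts() == {3: 4}
        with pytest.raises(InvalidClassError):
            assign_selection(lmap, sel, 0)

    def test_extract_counts_match_construction(self):
        labels = np.zeros((5, 5), dtype=int)
        labels[0, :] = 2   # 5 tumor
        labels[1, :3] = 1  # 3 normal
        cube = hb.HSCube(np.random.default_rng(0).random((5, 5, 6)),
                         np.arange(6, dtype=float))
        ds = hb.extract_dataset([(cube, hb.LabelMap(labels))])
        assert len(ds) == 8
        ids, counts = np.unique(ds.class_ids, return_counts=True)
        assert dict(zip(ids, counts)) == {1: 3, 2: 5}
        # spectra are the cube pixels at labeled positions
        np.testing.assert_array_equal(ds.spectra[:5], cube.data[0, :5])

    def test_extract_empty_map(self):
        cube = hb.HSCube(np.ones((3, 3, 4)), np.arange(4, dtype=float))
        ds = hb.extract_dataset([(cube, hb.LabelMap(np.zeros((3, 3), dtype=int)))])
        assert len(ds) == 0
        assert ds.summary().loc["Total", "Total"] == 0

    def test_summary_matches_brute_force_counts(self, small_phantom, small_chain):
        """Dataset summary equals per-class mask popcounts on the phantom."""
        _, _, truth = small_phantom
        reduced, _ = small_chain
        sparse = hb.sample_gold_standard(truth, 0.2, seed=3)
        ds = hb.extract_dataset([(reduced, sparse)], patient_ids=["P1"])
        table = ds.summary()
        for name, cid in hb.CLASS_IDS.items():
            assert table.loc["P1", name] == int(np.sum(sparse.labels == cid))
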