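"""MAE, dice of isodose volumes, DVH statistics."""

import numpy as np
import pytest

from accudose import (
    DoseGrid,
    GeometryError,
    GridGeometry,
    InsufficientVolumeError,
    InvalidStructureError,
    cumulative_dvh,
    dose_at_volume_cc,
    dsc,
    isodose_dsc_profile,
    mae_in_mask,
    volume_at_dose,
)


class TestMAE:
    def test_identical_grids_give_zero(self, uniform_dose, geom):
        mask = np.ones(geom.shape, dtype=bool)
        assert mae_in_mask(uniform_dose(60.0), uniform_dose(60.0), mask) == 0.0

    def test_constant_offset(self, uniform_dose, geom):
        mask = np.zeros(geom.shape, dtype=bool)
        mask[2:5] = True
        assert mae_in_mask(uniform_dose(62.0), uniform_dose(60.0), mask) == pytest.approx(2.0)

    def test_matches_exhaustive_loop(self):
        rng = np.random.default_rng(21)
        geom = GridGeometry(shape=(8, 8, 8), spacing=(1, 1, 1))
        a = DoseGrid(values=rng.uniform(0, 80, geom.shape), geometry=geom)
        b = DoseGrid(values=rng.uniform(0, 80, geom.shape), geometry=geom)
        mask = rng.random(geom.shape) < 0.5
        total, n = 0.0, 0
        for idx in np.ndindex(*geom.shape):
            if mask[idx]:
                total += abs(a.values[idx] - b.values[idx])
                n += 1
        assert mae_in_mask(a, b, mask) == pytest.approx(total / n)

    def test_empty_mask_rejected(self, uniform_dose, geom):
        with pytest.raises(InvalidStructureError):
            mae_in_mask(uniform_dose(1.0), uniform_dose(1.0), np.zeros(geom.shape, bool))


class TestDSC:
    def test_identical_and_disjoint(self, geom):
        a = np.zeros(geom.shape, dtype=bool)
        a[0:3] = True
        b = np.zeros(geom.shape, dtype=bool)
        b[4:6] = True
        assert dsc(a, a) == 1.0
        assert dsc(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros(200, dtype=bool)
        b = np.zeros(200, dtype=bool)
        a[:100], b[50:150] = True, True
        assert dsc(a, b) == pytest.approx(0.5)  # 2*50 / (100+100)

    def test_both_empty_is_perfect_agreement(self, geom):
        empty = np.zeros(geom.shape, dtype=bool)
        assert dsc(empty, empty) == 1.0

    def test_symmetry_and_range(self, geom):
        rng = np.random.default_rng(22)
        for _ in range(10):
            a = rng.random(geom.shape) < 0.4
            b = rng.random(geom.shape) < 0.4
            d = dsc(a, b)
            assert d == dsc(b, a)
            assert 0.0 <= d <= 1.0


class TestIsodoseProfile:
    def test_self_comparison_is_one_at_all_16_levels(self, phantom_case):
        d = phantom_case.truth_dose
        profile = isodose_dsc_profile(d, d)
        assert len(profile) == 16
        assert list(profile["level_gy"]) == [float(g) for g in range(10, 170, 10)]
        assert (profile["dsc"] == 1.0).all()

    def test_shifted_ramp_matches_closed_form(self, ramp_dose):
        # actual: dose = x; pred: dose = x + 5.  At level L the isodose
        # half-lines start at L (pred: L-5), so the dice of the two
        # suffixes of a 0..100 ramp is 2*(100-L) / ((100-L) + (105-L)).
        actual = ramp_dose(shape=(100, 2, 2), spacing=(1.0, 1.0, 1.0))
        pred = DoseGrid(values=actual.values + 5.0, geometry=actual.geometry)
        profile = isodose_dsc_profile(pred, actual, levels=[30.0, 60.0, 90.0])
        for level, got in zip(profile["level_gy"], profile["dsc"]):
            n_actual = np.sum(actual.values[:, 0, 0] >= level)
            n_pred = np.sum(pred.values[:, 0, 0] >= level)
            expected = 2.0 * n_actual / (n_actual + n_pred)
            assert got == pytest.approx(expected)


class TestDVH:
    def test_zero_edge_is_full_volume(self, phantom_case):
        st = phantom_case.structures
        dvh = cumulative_dvh(phantom_case.truth_dose, st["bladder"], bin_width_gy=0.5)
        assert dvh.relative_volume[0] == 1.0
        assert np.all(np.diff(dvh.relative_volume) <= 0)

    def test_uniform_organ_is_step_function(self, uniform_dose, geom):
        mask = np.ones(geom.shape, dtype=bool)
        dvh = cumulative_dvh(uniform_dose(60.0), mask, bin_width_gy=1.0)
        edges, rel = dvh.bin_edges_gy, dvh.relative_volume
        assert np.all(rel[edges <= 60.0] == 1.0)
        assert np.all(rel[edges > 60.0] == 0.0)

    def test_two_level_organ_half_volume_at_midpoint(self, geom):
        vals = np.full(geom.shape, 30.0)
        vals[: geom.shape[0] // 2] = 70.0
        dose = DoseGrid(values=vals, geometry=geom)
        dvh = cumulative_dvh(dose, np.ones(geom.shape, bool), bin_width_gy=1.0)
        idx = np.searchsorted(dvh.bin_edges_gy, 50.0)
        assert dvh.relative_volume[idx] == pytest.approx(0.5)

    def test_cross_consistency_with_volume_at_dose(self, phantom_case):
        d = phantom_case.truth_dose
        mask = phantom_case.structures["rectum"]
        dvh = cumulative_dvh(d, mask, bin_width_gy=0.5)
        for i in range(0, len(dvh.bin_edges_gy), 17):
            edge = dvh.bin_edges_gy[i]
            assert dvh.relative_volume[i] * 100.0 == pytest.approx(
                volume_at_dose(d, mask, edge)
            )

    def test_volume_cc_matches_geometry(self, uniform_dose, geom):
        mask = np.zeros(geom.shape, dtype=bool)
        mask[:2] = True  # 2*8*4 voxels of 4*4*5 mm^3
        dvh = cumulative_dvh(uniform_dose(10.0), mask)
        assert dvh.volume_cc == pytest.approx(64 * 80e-3)


class TestVolumeAtDose:
    def test_uniform_above_and_below(self, uniform_dose, geom):
        mask = np.ones(geom.shape, dtype=bool)
        assert volume_at_dose(uniform_dose(60.0), mask, 50.0) == 100.0
        assert volume_at_dose(uniform_dose(40.0), mask, 50.0) == 0.0

    def test_half_above_threshold(self, geom):
        vals = np.full(geom.shape, 30.0)
        vals[: geom.shape[0] // 2] = 70.0
        assert volume_at_dose(DoseGrid(values=vals, geometry=geom),
                              np.ones(geom.shape, bool), 50.0) == 50.0

    def test_non_increasing_in_threshold(self, phantom_case):
        d = phantom_case.truth_dose
        mask = phantom_case.structures["bladder"]
        vols = [volume_at_dose(d, mask, t) for t in np.linspace(0, 120, 25)]
        assert np.all(np.diff(vols) <= 0)


class TestDoseAtVolume:
    def test_uniform_organ_any_volume(self, uniform_dose, geom):
        mask = np.ones(geom.shape, dtype=bool)
        assert dose_at_volume_cc(uniform_dose(84.0), mask, 2.0) == 84.0

    def test_discrete_sorting_rule(self):
        # 30 voxels of 0.1 cm^3 with doses 1..30 Gy: the hottest 2 cm^3 are
        # the top 20 voxels, whose minimum dose is 11 Gy
        geom = GridGeometry(shape=(30, 1, 1), spacing=(5.0, 5.0, 4.0))
        dose = DoseGrid(values=np.arange(1.0, 31.0).reshape(30, 1, 1), geometry=geom)
        assert geom.voxel_volume_cc == pytest.approx(0.1)
        assert dose_at_volume_cc(dose, np.ones(geom.shape, bool), 2.0) == 11.0

    def test_request_exceeding_volume_rejected(self, uniform_dose, geom):
        mask = np.zeros(geom.shape, dtype=bool)
        mask[0, 0, 0] = True
        with pytest.raises(InsufficientVolumeError):
            dose_at_volume_cc(uniform_dose(10.0), mask, 2.0)

    def test_non_increasing_in_volume(self, phantom_case):
        d = phantom_case.truth_dose
        mask = phantom_case.structures["rectum"]
        doses = [dose_at_volume_cc(d, mask, v) for v in (0.5, 1.0, 2.0, 5.0)]
        assert np.all(np.diff(doses) <= 0)


def test_profile_geometry_mismatch_rejected(uniform_dose, geom):
    other = GridGeometry(shape=(4, 4, 4), spacing=(1, 1, 1))
    with pytest.raises(GeometryError):
        isodose_dsc_profile(uniform_dose(10.0), uniform_dose(10.0, other))
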