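"""Structure label maps, distance-to-target maps, CT override, isodose tools."""

import numpy as np
import pytest

from accudose import (
    GeometryError,
    GridGeometry,
    InvalidParameterError,
    InvalidStructureError,
    LabelCollisionError,
    StructureSet,
    build_structure_label_map,
    compute_dtt_map,
    decode_label,
    default_label_table,
    isodose_volume,
    overlap_contour,
    override_ct_numbers,
)


def random_structures(rng, geom, names=("ptv", "bladder", "rectum")) -> StructureSet:
    masks = {"body": np.ones(geom.shape, dtype=bool)}
    for name in names:
        masks[name] = rng.random(geom.shape) < 0.3
    return StructureSet(geometry=geom, masks=masks)


class TestLabelMap:
    def test_background_and_overlap_labels(self, small_structures):
        lm = build_structure_label_map(small_structures)
        assert lm.assignment == {"ptv": 2, "bladder": 4}
        body_only = small_structures["body"] & ~small_structures["ptv"] & ~small_structures["bladder"]
        assert np.all(lm.values[body_only] == 1)
        assert np.all(lm.values[small_structures["ptv"]] == 2)

    def test_overlapping_structures_sum(self, geom):
        a = np.zeros(geom.shape, dtype=bool)
        b = np.zeros(geom.shape, dtype=bool)
        a[2:5], b[3:6] = True, True
        ss = StructureSet(geometry=geom,
                          masks={"body": np.ones(geom.shape, bool), "ptv": a, "bladder": b})
        lm = build_structure_label_map(ss)
        assert np.all(lm.values[3:5] == 6)  # 2 (ptv) + 4 (bladder)

    def test_exterior_is_zero(self, geom):
        body = np.zeros(geom.shape, dtype=bool)
        body[2:6] = True
        ptv = np.zeros(geom.shape, dtype=bool)
        ptv[3:4] = True
        lm = build_structure_label_map(StructureSet(geometry=geom, masks={"body": body, "ptv": ptv}))
        assert np.all(lm.values[~body] == 0)

    def test_round_trip_decoding(self, geom):
        rng = np.random.default_rng(11)
        for _ in range(5):
            ss = random_structures(rng, geom)
            lm = build_structure_label_map(ss)
            for value in np.unique(lm.values):
                members = decode_label(int(value), lm.assignment)
                expected = frozenset(
                    name for name in lm.assignment
                    if np.any(ss[name] & (lm.values == value))
                )
                assert members == expected

    def test_colliding_custom_labels_rejected(self, geom):
        a = np.zeros(geom.shape, dtype=bool)
        b = np.zeros(geom.shape, dtype=bool)
        c = np.zeros(geom.shape, dtype=bool)
        a[0:2], b[1:3], c[4:6] = True, True, True
        ss = StructureSet(geometry=geom, masks={"body": np.ones(geom.shape, bool),
                                                "ptv": a, "bladder": b, "rectum": c})
        # ptv+bladder overlap (2+3=5) collides with rectum alone (5)
        with pytest.raises(LabelCollisionError):
            build_structure_label_map(ss, {"ptv": 2, "bladder": 3, "rectum": 5})

    def test_default_table_is_powers_of_two(self, small_structures):
        table = default_label_table(small_structures)
        labels = sorted(table.values())
        assert labels == [2, 4]


def brute_force_dtt(structures: StructureSet) -> np.ndarray:
    """Exhaustive minimum distance to any PTV voxel center."""
    geom = structures.geometry
    cx, cy, cz = geom.voxel_centers_mm()
    pts = np.stack(np.meshgrid(cx, cy, cz, indexing="ij"), axis=-1).reshape(-1, 3)
    ptv_pts = pts[structures["ptv"].ravel()]
    out = np.zeros(len(pts))
    for i, p in enumerate(pts):
        out[i] = np.sqrt(((ptv_pts - p) ** 2).sum(axis=1)).min()
    out = out.reshape(geom.shape)
    out[structures["ptv"]] = 0.0
    out[~structures["body"]] = 0.0
    return out


class TestDTT:
    def test_zero_inside_ptv_and_outside_body(self, phantom_case):
        dtt = compute_dtt_map(phantom_case.structures)
        assert np.all(dtt.values[phantom_case.structures["ptv"]] == 0.0)
        assert np.all(dtt.values[~phantom_case.structures["body"]] == 0.0)

    def test_face_adjacent_voxel_at_unit_spacing(self):
        geom = GridGeometry(shape=(5, 5, 5), spacing=(1.0, 1.0, 1.0))
        body = np.ones(geom.shape, dtype=bool)
        ptv = np.zeros(geom.shape, dtype=bool)
        ptv[2, 2, 2] = True
        dtt = compute_dtt_map(StructureSet(geometry=geom, masks={"body": body, "ptv": ptv}))
        assert dtt.values[3, 2, 2] == pytest.approx(1.0)
        assert dtt.values[3, 3, 2] == pytest.approx(np.sqrt(2.0))

    def test_matches_exhaustive_oracle_anisotropic(self):
        rng = np.random.default_rng(12)
        geom = GridGeometry(shape=(12, 10, 8), spacing=(1.0, 2.0, 3.5))
        body = rng.random(geom.shape) < 0.9
        ptv = (rng.random(geom.shape) < 0.08) & body
        ptv[5, 5, 4] = body[5, 5, 4] = True  # ensure non-empty
        ss = StructureSet(geometry=geom, masks={"body": body, "ptv": ptv})
        dtt = compute_dtt_map(ss)
        np.testing.assert_allclose(dtt.values, brute_force_dtt(ss), atol=1e-9)

    def test_lipschitz_in_physical_distance(self, phantom_case):
        dtt = compute_dtt_map(phantom_case.structures).values
        st = phantom_case.structures
        free = st["body"] & ~st["ptv"]
        spacing = phantom_case.geometry.spacing
        for axis, step in enumerate(spacing):
            shifted = np.roll(dtt, 1, axis=axis)
            both = free & np.roll(free, 1, axis=axis)
            # drop wrapped boundary plane
            sl = [slice(None)] * 3
            sl[axis] = slice(1, None)
            diffs = np.abs(dtt - shifted)[tuple(sl)][both[tuple(sl)]]
            assert np.all(diffs <= step + 1e-9)

    def test_empty_ptv_rejected(self, geom):
        ss = StructureSet(geometry=geom, masks={"body": np.ones(geom.shape, bool),
                                                "ptv": np.zeros(geom.shape, bool)})
        with pytest.raises(InvalidStructureError):
            compute_dtt_map(ss)


class TestOverrideCT:
    def test_empty_table_is_identity(self, small_structures, geom):
        img = np.full(geom.shape, 50.0)
        np.testing.assert_array_equal(override_ct_numbers(img, small_structures, {}), img)

    def test_single_mask_override(self, small_structures, geom):
        img = np.full(geom.shape, 50.0)
        out = override_ct_numbers(img, small_structures, {"bladder": 0.0})
        assert np.all(out[small_structures["bladder"]] == 0.0)
        assert np.all(out[~small_structures["bladder"]] == 50.0)

    def test_overlap_last_listed_wins(self, geom):
        a = np.zeros(geom.shape, dtype=bool)
        b = np.zeros(geom.shape, dtype=bool)
        a[2:5], b[3:6] = True, True
        ss = StructureSet(geometry=geom,
                          masks={"body": np.ones(geom.shape, bool), "ptv": a, "bladder": b})
        out = override_ct_numbers(np.zeros(geom.shape), ss, {"ptv": 100.0, "bladder": 200.0})
        assert np.all(out[3:5] == 200.0)
        assert np.all(out[2] == 100.0)

    def test_unknown_structure_rejected(self, small_structures, geom):
        with pytest.raises(InvalidStructureError):
            override_ct_numbers(np.zeros(geom.shape), small_structures, {"sigmoid": 0.0})


class TestIsodose:
    def test_uniform_above_level_fills_grid(self, uniform_dose):
        mask = isodose_volume(uniform_dose(76.25), 70.0)
        assert mask.all()

    def test_level_above_max_is_empty(self, uniform_dose):
        assert not isodose_volume(uniform_dose(40.0), 70.0).any()

    def test_ramp_count_matches_analytic(self, ramp_dose):
        d = ramp_dose(shape=(100, 2, 2), spacing=(1.0, 1.0, 1.0))
        mask = isodose_volume(d, 50.0)
        # centers at 0.5..99.5 mm; those >= 50 are 50.5..99.5 -> 50 planes
        assert mask.sum() == 50 * 4
        assert np.all(mask[50:])

    def test_monotone_in_level(self, phantom_case):
        d = phantom_case.truth_dose
        for lo, hi in [(10, 20), (40, 70), (70, 160)]:
            assert not (isodose_volume(d, hi) & ~isodose_volume(d, lo)).any()

    def test_nonpositive_level_rejected(self, uniform_dose):
        with pytest.raises(InvalidParameterError):
            isodose_volume(uniform_dose(10.0), 0.0)


class TestOverlapContour:
    def test_oar_below_level_gives_empty(self, uniform_dose, geom):
        oar = np.ones(geom.shape, dtype=bool)
        assert not overlap_contour(uniform_dose(40.0), 70.0, oar).any()

    def test_oar_inside_isodose_returns_oar(self, uniform_dose, geom):
        oar = np.zeros(geom.shape, dtype=bool)
        oar[1:4] = True
        out = overlap_contour(uniform_dose(80.0), 70.0, oar)
        np.testing.assert_array_equal(out, oar)

    def test_matches_elementwise_and_oracle(self, phantom_case):
        st = phantom_case.structures
        pred = phantom_case.truth_dose
        out = overlap_contour(pred, 70.0, st["rectum"])
        oracle = np.zeros(pred.geometry.shape, dtype=bool)
        for idx in np.ndindex(*pred.geometry.shape):
            oracle[idx] = pred.values[idx] >= 70.0 and st["rectum"][idx]
        np.testing.assert_array_equal(out, oracle)
        assert out.any()  # BT hotspot abuts the rectum by construction

    def test_geometry_mismatch_rejected(self, uniform_dose):
        with pytest.raises(GeometryError):
            overlap_contour(uniform_dose(80.0), 70.0, np.ones((2, 2, 2), dtype=bool))
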