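"""Hausdorff expansion distance, point features and variance decomposition."""

import numpy as np
import pytest

import eudgate as eg
from eudgate.geometry import extract_features

from conftest import brute_force_directed_hausdorff, random_blob_mask


def cube_mask(spec, lo, hi):
    m = np.zeros(spec.shape, bool)
    m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return eg.StructureMask(spec, m)


class TestHausdorffExpansion:
    def test_identical_masks_give_zero(self, small_spec):
        rng = np.random.default_rng(0)
        m = random_blob_mask(small_spec, rng)
        hdd, _ = eg.hausdorff_expansion(m, m)
        assert hdd == 0.0

    def test_contained_mask_gives_zero(self, small_spec):
        outer = cube_mask(small_spec, (2, 2, 2), (20, 20, 20))
        inner = cube_mask(small_spec, (6, 6, 6), (15, 15, 15))
        assert eg.hausdorff_expansion(outer, inner)[0] == 0.0

    def test_shifted_cube_three_voxels(self):
        spec = eg.GridSpec((20, 20, 20), (2.0, 2.0, 2.0))
        a = cube_mask(spec, (3, 3, 3), (13, 13, 13))
        b = cube_mask(spec, (6, 3, 3), (16, 13, 13))  # +3 voxels along z
        hdd, hdp = eg.hausdorff_expansion(a, b)
        assert hdd == pytest.approx(6.0)
        ref, _ = brute_force_directed_hausdorff(a, b)
        assert hdd == pytest.approx(ref)

    def test_matches_brute_force_on_random_blobs(self):
        rng = np.random.default_rng(5)
        spec = eg.GridSpec((12, 12, 12), (2.0, 2.0, 2.0))
        for _ in range(25):
            a = random_blob_mask(spec, rng, threshold=rng.uniform(40, 70))
            b = random_blob_mask(spec, rng, threshold=rng.uniform(40, 70))
            hdd, hdp = eg.hausdorff_expansion(a, b)
            ref, ref_p = brute_force_directed_hausdorff(a, b)
            assert hdd == pytest.approx(ref, abs=1e-9)
            assert np.allclose(hdp, ref_p)

    def test_translation_changes_hdd_by_at_most_shift(self):
        spec = eg.GridSpec((24, 24, 24), (2.0, 2.0, 2.0))
        a = cube_mask(spec, (4, 4, 4), (14, 14, 14))
        base, _ = eg.hausdorff_expansion(a, cube_mask(spec, (6, 4, 4), (16, 14, 14)))
        for extra in (1, 2):
            shifted = cube_mask(spec, (6 + extra, 4, 4), (16 + extra, 14, 14))
            hdd, _ = eg.hausdorff_expansion(a, shifted)
            assert abs(hdd - base) <= extra * 2.0 + 1e-9

    def test_empty_mask_raises(self, small_spec):
        empty = eg.StructureMask(small_spec, np.zeros(small_spec.shape, bool))
        full = cube_mask(small_spec, (2, 2, 2), (8, 8, 8))
        with pytest.raises(ValueError):
            eg.hausdorff_expansion(full, empty)


class TestHDPWorst:
    def test_argmax_fraction(self):
        pts = [np.array([0.0, 0, i]) for i in range(3)]
        idx, p = eg.hdp_worst(list(zip([3.0, 7.0, 5.0], pts)))
        assert idx == 1 and np.allclose(p, pts[1])

    def test_tie_goes_to_earliest(self):
        pts = [np.array([0.0, 0, i]) for i in range(3)]
        idx, p = eg.hdp_worst(list(zip([4.0, 4.0, 4.0], pts)))
        assert idx == 0

    def test_matches_linear_scan(self):
        rng = np.random.default_rng(1)
        hdds = rng.uniform(0, 10, 30)
        pts = [rng.normal(size=3) for _ in range(30)]
        idx, _ = eg.hdp_worst(list(zip(hdds, pts)))
        assert idx == int(np.argmax(hdds))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            eg.hdp_worst([])


def constant_field(spec, vec):
    vals = np.broadcast_to(np.asarray(vec, float), spec.shape + (3,)).copy()
    return eg.DisplacementField(spec, vals)


class TestPDMinGlobal:
    def test_zero_fields_keep_argmin(self, small_spec):
        zero = constant_field(small_spec, (0, 0, 0))
        pts = [np.array([10.0, 12.0, 14.0]), np.array([8.0, 8.0, 8.0])]
        x, q = eg.pd_min_global([40.0, 55.0], pts, [zero, zero])
        assert x == 0 and np.allclose(q, pts[0])

    def test_single_fraction(self, small_spec):
        zero = constant_field(small_spec, (0, 0, 0))
        x, q = eg.pd_min_global([33.0], [np.array([6.0, 6.0, 6.0])], [zero])
        assert x == 0 and np.allclose(q, [6.0, 6.0, 6.0])

    def test_constant_translation_inverts_analytically(self, small_spec):
        t = np.array([4.0, -2.0, 6.0])
        fld = constant_field(small_spec, t)
        p = np.array([20.0, 22.0, 18.0])
        x, q = eg.pd_min_global([30.0], [p], [fld])
        assert np.allclose(q, p - t, atol=1e-6)

    def test_ties_go_to_earliest_fraction(self, small_spec):
        zero = constant_field(small_spec, (0, 0, 0))
        pts = [np.array([1.0, 1, 1]), np.array([2.0, 2, 2])]
        x, _ = eg.pd_min_global([50.0, 50.0], pts, [zero, zero])
        assert x == 0


class TestPropagateAndScalar:
    def test_zero_field_identity(self, small_spec):
        dose = eg.DoseGrid(small_spec, np.full(small_spec.shape, 60.0))
        zero = constant_field(small_spec, (0, 0, 0))
        p = np.array([20.0, 20.0, 20.0])
        moved, d = eg.propagate_point(p, zero, dose)
        assert np.allclose(moved, p) and d == 60.0

    def test_translation_through_linear_ramp(self):
        # 3 %/mm ramp along z; a 4 mm z-shift drops the dose by 12 points
        spec = eg.GridSpec((30, 10, 10), (2.0, 2.0, 2.0))
        zmm = np.arange(30)[:, None, None] * 2.0
        dose = eg.DoseGrid(spec, np.broadcast_to(100.0 - 3.0 * zmm, spec.shape).copy())
        fld = constant_field(spec, (4.0, 0.0, 0.0))
        p = np.array([20.0, 10.0, 10.0])
        moved, d = eg.propagate_point(p, fld, dose)
        assert np.allclose(moved, [24.0, 10.0, 10.0])
        assert d == pytest.approx(100.0 - 3.0 * 24.0)

    def test_interpolation_stays_within_neighbour_range(self, small_spec):
        rng = np.random.default_rng(2)
        dose = eg.DoseGrid(small_spec, rng.uniform(0, 70, small_spec.shape))
        zero = constant_field(small_spec, (0, 0, 0))
        p = np.array([11.3, 15.8, 9.1])
        _, d = eg.propagate_point(p, zero, dose)
        i0 = np.floor(p / 2.0).astype(int)
        block = dose.values[i0[0]:i0[0] + 2, i0[1]:i0[1] + 2, i0[2]:i0[2] + 2]
        assert block.min() - 1e-9 <= d <= block.max() + 1e-9

    def test_scalar_projection_examples(self, small_spec):
        p = np.array([20.0, 20.0, 20.0])
        f_x = constant_field(small_spec, (6.0, 8.0, 0.0))
        assert eg.scalar_pdmin(p, f_x, f_x) == pytest.approx(10.0)
        f_perp = constant_field(small_spec, (0.0, 0.0, 5.0))
        assert eg.scalar_pdmin(p, f_perp, f_x) == pytest.approx(0.0)
        f_i = constant_field(small_spec, (3.0, 0.0, 0.0))
        assert eg.scalar_pdmin(p, f_i, f_x) == pytest.approx(1.8)

    def test_scalar_degenerate_reference_warns_and_returns_zero(self, small_spec):
        p = np.array([20.0, 20.0, 20.0])
        zero = constant_field(small_spec, (0, 0, 0))
        with pytest.warns(UserWarning, match="degenerate"):
            assert eg.scalar_pdmin(p, zero, zero) == 0.0

    def test_scalar_never_exceeds_vector_length(self, small_spec):
        rng = np.random.default_rng(4)
        p = np.array([20.0, 20.0, 20.0])
        for _ in range(20):
            vi, vx = rng.normal(size=3), rng.normal(size=3)
            s = eg.scalar_pdmin(p, constant_field(small_spec, vi),
                                constant_field(small_spec, vx))
            assert abs(s) <= np.linalg.norm(vi) + 1e-9

    def test_delta_l_examples(self, small_spec):
        p = np.array([20.0, 20.0, 20.0])
        zero = constant_field(small_spec, (0, 0, 0))
        assert eg.delta_l_hdp_worst(p, zero) == 0.0
        f = constant_field(small_spec, (2.3, 3.0, 1.7))
        assert eg.delta_l_hdp_worst(p, f) == pytest.approx(4.1449, abs=1e-3)
        # norm is invariant under axis permutation of the vector
        g = constant_field(small_spec, (1.7, 2.3, 3.0))
        assert eg.delta_l_hdp_worst(p, g) == pytest.approx(4.1449, abs=1e-3)


class TestVarianceDecomposition:
    def test_identical_vectors_give_zero(self):
        samples = [np.tile([1.0, 2.0, 3.0], (5, 1))] * 3
        syst, rand = eg.deformation_variance_decomposition(samples)
        assert np.allclose(syst, 0) and np.allclose(rand, 0)

    def test_constant_per_patient_offsets(self):
        a = np.tile([2.0, 0.0, 0.0], (4, 1))
        b = np.tile([6.0, 0.0, 0.0], (4, 1))
        syst, rand = eg.deformation_variance_decomposition([a, b])
        assert np.allclose(rand, 0)
        # SD (ddof=1) of the two patient means {2, 6}
        assert syst[0] == pytest.approx(np.std([2.0, 6.0], ddof=1))

    def test_single_fraction_or_patient_raises(self):
        with pytest.raises(ValueError, match="2 fractions"):
            eg.deformation_variance_decomposition(
                [np.zeros((1, 3)), np.zeros((4, 3))]
            )
        with pytest.raises(ValueError, match="two patients"):
            eg.deformation_variance_decomposition([np.zeros((4, 3))])

    def test_pure_random_recovery(self):
        rng = np.random.default_rng(8)
        sd = np.array([3.0, 2.0, 1.0])
        samples = [rng.normal(0, sd, size=(200, 3)) for _ in range(6)]
        syst, rand = eg.deformation_variance_decomposition(samples)
        assert np.allclose(rand, sd, rtol=0.1)


def test_zero_deformation_cohort_features(mini_cohort):
    """With zero fields every geometric feature collapses: HDD = dL =
    Scalar = 0 and the dose at the propagated global-minimum point equals
    the minimum CTV dose."""
    cfg, _ = mini_cohort
    import dataclasses

    zero_cfg = dataclasses.replace(
        cfg, systematic_sd=(0, 0, 0), random_sd=(0, 0, 0), large_excursion_prob=0.0
    )
    cohort = eg.generate_cohort(zero_cfg)
    feats = extract_features(cohort[0])
    assert (feats["HDD_mm"] == 0).all()
    assert (feats["dL_HDPworst_mm"] == 0).all()
    assert (feats["Scalar_PDmin_mm"] == 0).all()
    assert np.allclose(feats["D_PDmin_global"], feats["D_min"], atol=1e-9)
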