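"""Dipole physics, lead fields, single-dipole fitting, eLORETA, line test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vepsource.errors import (DegenerateInputError, GeometryError,
                              SingularityError)
from vepsource.localize import (Dipole, PhysicalConstants, TargetRegion,
                                accuracy_weights, build_lead_field,
                                dipole_field, dipole_field_polar,
                                eloreta_inverse, fit_single_dipole,
                                line_region_test, moment_from_field,
                                scalp_potentials, transfer_matrix,
                                transfer_matrix_inverse)
from vepsource.montage import region_codes
from vepsource.simulate import ground_truth_dipole


def _random_unit(rng):
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


class TestTransferMatrix:
    def test_z_axis_closed_form(self):
        M = transfer_matrix(np.array([0.0, 0.0, 1.0]))
        np.testing.assert_allclose(M, np.diag([-1.0, -1.0, 2.0]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_eigenvalues_are_2_minus1_minus1(self, seed):
        e = _random_unit(np.random.default_rng(seed))
        vals = np.sort(np.linalg.eigvalsh(transfer_matrix(e)))
        np.testing.assert_allclose(vals, [-1.0, -1.0, 2.0], atol=1e-12)

    def test_closed_form_inverse(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            e = _random_unit(rng)
            M = transfer_matrix(e)
            np.testing.assert_allclose(M @ transfer_matrix_inverse(e),
                                       np.eye(3), atol=1e-12)

    def test_non_unit_vector_rejected(self):
        with pytest.raises(ValueError):
            transfer_matrix(np.array([0.0, 0.0, 2.0]))


class TestDipoleField:
    def test_matrix_form_equals_polar_form(self):
        """The transfer-matrix field and the polar 2cos/sin field agree to
        1e-10 relative over random moments and observation points."""
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(10_000):
            p0 = rng.standard_normal(3) * 1e-8
            r = rng.standard_normal(3)
            E = dipole_field(p0, r)
            dist = np.linalg.norm(r)
            e_r = r / dist
            cos_t = np.dot(p0, e_r) / np.linalg.norm(p0)
            radial, tangential = dipole_field_polar(
                np.linalg.norm(p0), dist, np.arccos(np.clip(cos_t, -1, 1)))
            mag_polar = np.hypot(radial, tangential)
            worst = max(worst, abs(np.linalg.norm(E) - mag_polar)
                        / mag_polar)
        assert worst < 1e-10

    def test_parallel_and_perpendicular_magnitudes(self):
        c = PhysicalConstants()
        p0 = np.array([0.0, 0.0, 2e-8])
        k = 2e-8 / (4 * np.pi * c.epsilon0 * 0.1 ** 3)
        E_par = dipole_field(p0, np.array([0.0, 0.0, 0.1]))
        assert np.linalg.norm(E_par) == pytest.approx(2 * k, rel=1e-12)
        E_perp = dipole_field(p0, np.array([0.1, 0.0, 0.0]))
        assert np.linalg.norm(E_perp) == pytest.approx(k, rel=1e-12)

    def test_inverse_cube_falloff(self):
        p0 = np.array([1e-8, 2e-8, -1e-8])
        r = np.array([0.03, 0.01, 0.05])
        near = np.linalg.norm(dipole_field(p0, r))
        far = np.linalg.norm(dipole_field(p0, 2 * r))
        assert far == pytest.approx(near / 8.0, rel=1e-12)

    def test_observation_at_source_rejected(self):
        with pytest.raises(SingularityError):
            dipole_field(np.array([0, 0, 1e-8]), np.zeros(3))


class TestMomentInversion:
    def test_round_trip_over_random_dipoles(self):
        rng = np.random.default_rng(11)
        worst = 0.0
        for _ in range(500):
            p0 = rng.standard_normal(3) * 1e-8
            r0 = rng.standard_normal(3) * 0.02
            r = r0 + _random_unit(rng) * rng.uniform(0.02, 0.1)
            E = dipole_field(p0, r, r0=r0)
            back = moment_from_field(E, r, r0)
            worst = max(worst, np.linalg.norm(back - p0)
                        / np.linalg.norm(p0))
        assert worst < 1e-10

    def test_zero_field_zero_moment(self):
        p = moment_from_field(np.zeros(3), np.array([0.1, 0, 0]), np.zeros(3))
        np.testing.assert_array_equal(p, np.zeros(3))

    def test_two_observation_points_agree(self):
        rng = np.random.default_rng(13)
        p0 = rng.standard_normal(3) * 1e-8
        r0 = np.array([0.01, -0.02, 0.01])
        estimates = []
        for _ in range(5):
            r = r0 + _random_unit(rng) * 0.07
            estimates.append(moment_from_field(
                dipole_field(p0, r, r0=r0), r, r0))
        for est in estimates[1:]:
            np.testing.assert_allclose(est, estimates[0], rtol=1e-9)


class TestScalpPotentials:
    def test_posterior_dipole_peaks_posterior(self, montage):
        v = scalp_potentials(ground_truth_dipole(5e-8), montage)
        best = int(np.argmax(np.abs(v))) + 1
        assert best in region_codes(montage, "posterior_v1")

    def test_linearity_in_moment(self, montage):
        d1 = ground_truth_dipole(3e-8)
        d2 = ground_truth_dipole(6e-8)
        np.testing.assert_allclose(scalp_potentials(d2, montage),
                                   2 * scalp_potentials(d1, montage),
                                   rtol=1e-12)

    def test_average_reference_sums_to_zero(self, montage):
        v = scalp_potentials(ground_truth_dipole(5e-8), montage)
        assert abs(v.sum()) < 1e-18

    def test_outside_sphere_rejected(self, montage):
        with pytest.raises(GeometryError):
            scalp_potentials(Dipole(r0=np.array([0, 0.1, 0]),
                                    p=np.array([0, 0, 1e-8])), montage)


class TestLeadField:
    def test_grid_count_matches_brute_force(self, montage, lead_field):
        spacing, frac = 0.012, 0.85
        rmax = frac * montage.sphere_radius
        ax = np.arange(-rmax, rmax + spacing / 2, spacing)
        ax = ax - (ax[0] + ax[-1]) / 2.0
        count = sum(1 for x in ax for y in ax for z in ax
                    if np.sqrt(x * x + y * y + z * z) <= rmax)
        assert lead_field.n_grid == count
        assert lead_field.A.shape == (59, 3 * count)

    def test_columns_reproduce_forward_model(self, montage, lead_field):
        idx = lead_field.n_grid // 2
        r0 = lead_field.grid[idx]
        for axis in range(3):
            p = np.zeros(3)
            p[axis] = 1.0
            expected = scalp_potentials(Dipole(r0=r0, p=p), montage)
            np.testing.assert_allclose(
                lead_field.A[:, 3 * idx + axis], expected, rtol=1e-12)

    def test_average_reference_columns(self, lead_field):
        sums = lead_field.A.sum(axis=0)
        scale = np.abs(lead_field.A).max(axis=0)
        assert np.all(np.abs(sums) <= 1e-12 * np.maximum(scale, 1.0))

    def test_empty_grid_rejected(self, montage):
        with pytest.raises(ValueError):
            build_lead_field(montage, spacing=-1.0)


class TestSingleDipoleFit:
    def test_noise_free_recovery(self, montage):
        rng = np.random.default_rng(23)
        for _ in range(5):
            r0 = _random_unit(rng) * rng.uniform(0.02, 0.06)
            p = _random_unit(rng) * 5e-8
            truth = Dipole(r0=r0, p=p)
            y = scalp_potentials(truth, montage)
            fit, resid = fit_single_dipole(y, montage)
            assert np.linalg.norm(fit.r0 - r0) <= 1e-3
            cos = np.dot(fit.p, p) / (np.linalg.norm(fit.p)
                                      * np.linalg.norm(p))
            assert np.degrees(np.arccos(np.clip(abs(cos), 0, 1))) <= 1.0
            assert resid < 1e-6

    def test_scaling_moves_moment_not_position(self, montage):
        truth = ground_truth_dipole(5e-8)
        y = scalp_potentials(truth, montage)
        fit1, _ = fit_single_dipole(y, montage)
        fit2, _ = fit_single_dipole(3.0 * y, montage)
        np.testing.assert_allclose(fit2.r0, fit1.r0, atol=1e-6)
        np.testing.assert_allclose(fit2.p, 3.0 * fit1.p, rtol=1e-6,
                                   atol=1e-12 * np.linalg.norm(fit1.p))

    def test_masked_sensors_still_recover(self, montage):
        rng = np.random.default_rng(29)
        truth = Dipole(r0=np.array([0.01, -0.04, 0.02]),
                       p=np.array([2e-8, -1e-8, 3e-8]))
        y = scalp_potentials(truth, montage)
        w = np.ones(59)
        w[rng.choice(59, 20, replace=False)] = 0.0
        fit, _ = fit_single_dipole(y, montage, weights=w)
        assert np.linalg.norm(fit.r0 - truth.r0) <= 2e-3

    def test_zero_data_rejected(self, montage):
        with pytest.raises(DegenerateInputError):
            fit_single_dipole(np.zeros(59), montage)


class TestAccuracyWeights:
    def test_chance_map_falls_back_to_uniform(self):
        w, flag = accuracy_weights(np.full(59, 0.5))
        assert flag
        np.testing.assert_allclose(w, 1.0 / 59)

    def test_single_informative_channel_takes_all(self):
        acc = np.full(59, 0.5)
        acc[10] = 1.0
        w, flag = accuracy_weights(acc)
        assert not flag
        assert w[10] == 1.0 and w.sum() == pytest.approx(1.0)

    def test_normalization_property(self):
        rng = np.random.default_rng(31)
        acc = rng.uniform(0.5, 0.9, 59)
        w, _ = accuracy_weights(acc)
        w_shift, _ = accuracy_weights(acc + 0.05)
        assert w.sum() == pytest.approx(1.0)
        assert w_shift.sum() == pytest.approx(1.0)
        # shifting accuracies changes relative weights unless renormalized
        assert not np.allclose(w, w_shift)


class TestEloreta:
    def test_node_sources_recovered_exactly(self, lead_field):
        rng = np.random.default_rng(37)
        for node in rng.choice(lead_field.n_grid, 5, replace=False):
            mom = _random_unit(rng)
            y = lead_field.A[:, 3 * node:3 * node + 3] @ mom
            est = eloreta_inverse(y, lead_field, alpha=0.0)
            assert int(np.argmax(est.magnitude)) == node

    def test_zero_data_zero_estimate(self, lead_field):
        est = eloreta_inverse(np.zeros(59), lead_field, alpha=1e-6)
        np.testing.assert_allclose(est.magnitude, 0.0, atol=1e-30)

    def test_linearity_in_data(self, lead_field):
        rng = np.random.default_rng(41)
        node = 17
        y = lead_field.A[:, 3 * node:3 * node + 3] @ _random_unit(rng)
        a = eloreta_inverse(y, lead_field, alpha=1e-8)
        b = eloreta_inverse(3.0 * y, lead_field, alpha=1e-8)
        np.testing.assert_allclose(b.magnitude, 3.0 * a.magnitude,
                                   rtol=1e-8)


class TestLineRegionTest:
    def test_line_through_center_hits(self):
        region = TargetRegion(center=np.array([0.0, -0.065, 0.0]))
        d = Dipole(r0=np.array([0.0, -0.065, 0.05]),
                   p=np.array([0.0, 0.0, 1e-8]))
        hit, dist = line_region_test(d, region)
        assert hit and dist == pytest.approx(0.0, abs=1e-15)

    def test_parallel_offset_line_misses(self):
        region = TargetRegion(center=np.array([0.0, -0.065, 0.0]),
                              radius=0.01)
        d = Dipole(r0=np.array([0.02, -0.065, 0.05]),
                   p=np.array([0.0, 0.0, 1e-8]))
        hit, dist = line_region_test(d, region)
        assert not hit
        assert dist == pytest.approx(0.02, abs=1e-12)

    def test_zero_moment_rejected(self):
        with pytest.raises(DegenerateInputError):
            line_region_test(Dipole(r0=np.zeros(3), p=np.zeros(3)),
                             TargetRegion())

    def test_ground_truth_dipole_hits_calcarine(self):
        hit, dist = line_region_test(ground_truth_dipole(5e-8),
                                     TargetRegion())
        assert hit
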