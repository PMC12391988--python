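"""Network-diffusion models: spot values, monotonicity, inversion, mesh fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import geldiff as g
from geldiff.exceptions import OutsideModelRangeError, ValidationError


class TestVolumeFraction:
    @pytest.mark.parametrize(
        "w, rho_p, rho_s, expected, tol",
        [
            (0.0206, 1.3, 0.997, 0.016, 5e-4),   # collagen gel composition -> 0.016 at 3 dp
            (0.0, 1.3, 0.997, 0.0, 0.0),          # no polymer
            (0.37, 1.1, 1.1, 0.37, 1e-12),        # equal densities: volume == mass fraction
        ],
    )
    def test_values(self, w, rho_p, rho_s, expected, tol):
        phi = g.volume_fraction(g.GelComposition(w, rho_p, rho_s))
        assert phi == pytest.approx(expected, abs=tol)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            g.GelComposition(1.2, 1.3, 0.997)
        with pytest.raises(ValidationError):
            g.GelComposition(0.02, -1.0, 0.997)
        with pytest.raises(ValidationError):
            g.GelComposition(float("nan"), 1.3, 0.997)


class TestMeshRadius:
    @pytest.mark.parametrize("rf, phi, expected_nm", [(1.0, 0.016, 14), (10.0, 0.016, 140)])
    def test_collagen_mesh_sizes(self, rf, phi, expected_nm):
        assert round(g.mesh_radius(rf, phi)) == expected_nm

    def test_algebraic_identity(self):
        # sqrt(pi / (pi/4)) = 2 exactly
        assert g.mesh_radius(3.0, math.pi / 4) == pytest.approx(6.0, rel=1e-14)

    @given(rf=st.floats(0.1, 100), phi1=st.floats(1e-4, 0.5), phi2=st.floats(1e-4, 0.5))
    @settings(derandomize=True, max_examples=50)
    def test_monotone_in_fiber_radius_and_phi(self, rf, phi1, phi2):
        assert g.mesh_radius(2 * rf, phi1) > g.mesh_radius(rf, phi1)
        lo, hi = sorted((phi1, phi2))
        if lo < hi:
            assert g.mesh_radius(rf, lo) > g.mesh_radius(rf, hi)

    def test_rejects_bad_phi(self):
        with pytest.raises(ValidationError):
            g.mesh_radius(1.0, 0.0)
        with pytest.raises(ValidationError):
            g.mesh_radius(1.0, 1.0)


class TestStokesEinstein:
    @pytest.mark.parametrize("r_nm, expected", [(3.0, 102.12), (7.95, 38.535)])
    def test_hand_values(self, r_nm, expected, medium):
        assert g.stokes_einstein_d0(r_nm, medium) == pytest.approx(expected, rel=1e-3)

    def test_inverse_proportional_to_radius(self, medium):
        assert g.stokes_einstein_d0(4.0, medium) == pytest.approx(
            0.5 * g.stokes_einstein_d0(2.0, medium), rel=1e-12)

    def test_rejects_nonpositive_radius(self, medium):
        with pytest.raises(ValidationError):
            g.stokes_einstein_d0(-1.0, medium)


class TestObstructionRatios:
    def test_ogston_amsden_at_mesh_radius(self, thin_fiber_network):
        # R_h = r̄ makes the exponent argument exactly (pi/4)
        val = g.ogston_amsden_ratio(thin_fiber_network.mesh_radius_nm, thin_fiber_network)
        assert val == pytest.approx(math.exp(-math.pi / 4), rel=1e-12)
        assert val == pytest.approx(0.45594, abs=1e-5)

    def test_ogston_amsden_spot_values(self):
        net = g.GelNetwork(10.0, 0.016, 140.0)
        assert g.ogston_amsden_ratio(3.0, net) == pytest.approx(0.99412, abs=1e-5)
        net_thin = g.GelNetwork(1.0, 0.016, 14.0)
        small = g.ogston_amsden_ratio(1e-9, net_thin)
        assert small == pytest.approx(math.exp(-(math.pi / 4) * (1 / 15) ** 2), rel=1e-6)
        assert small == pytest.approx(0.99652, abs=1e-5)

    def test_clague_phillips_spot_value(self):
        net = g.GelNetwork(10.0, 0.016, 140.0)
        # independent scripted evaluation of the hindered-diffusion formula
        phi, rf, rs = 0.016, 10.0, 3.0
        alpha = phi * ((rs + rf) / rf) ** 2
        expected = math.exp(-math.pi * phi ** (0.174 * math.log(59.6 * rf / rs))) / (1 + 2 * alpha / 3)
        assert alpha == pytest.approx(0.02704, abs=1e-5)
        got = g.clague_phillips_ratio(rs, net)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.9161, abs=1e-4)

    def test_clague_phillips_dilute_limit(self):
        net = g.GelNetwork(10.0, 1e-12, 140.0)
        assert g.clague_phillips_ratio(3.0, net) == pytest.approx(1.0, abs=1e-6)

    def test_clague_phillips_warns_outside_validity(self):
        net = g.GelNetwork(1.0, 0.016, 14.0)
        with pytest.warns(RuntimeWarning):
            g.clague_phillips_ratio(60.0, net)  # R_s >= 59.6 * R_f

    @given(r1=st.floats(0.2, 400), r2=st.floats(0.2, 400))
    @settings(derandomize=True, max_examples=60)
    def test_both_ratios_bounded_and_decreasing(self, r1, r2, thick_fiber_network):
        lo, hi = sorted((r1, r2))
        for ratio in (g.ogston_amsden_ratio, g.clague_phillips_ratio):
            a, b = ratio(lo, thick_fiber_network), ratio(hi, thick_fiber_network)
            assert 0.0 < b <= a <= 1.0
            if hi > lo:
                assert b < a

    def test_ogston_amsden_open_mesh_limit(self):
        wide = g.GelNetwork(1.0, 0.016, 1e9)
        assert g.ogston_amsden_ratio(10.0, wide) == pytest.approx(1.0, abs=1e-9)


class TestModelCurve:
    def test_single_point_composition(self, thin_fiber_network, medium):
        r = thin_fiber_network.mesh_radius_nm
        curve = g.model_curve("ogston_amsden", thin_fiber_network, medium, [r])
        expected = g.stokes_einstein_d0(r, medium) * math.exp(-math.pi / 4)
        assert curve.dg_um2_s[0] == pytest.approx(expected, rel=1e-12)

    def test_pointwise_against_scripted_evaluation(self, medium):
        net = g.GelNetwork(10.0, 0.016, 140.0)
        radii = np.array([0.7, 3.0, 7.95])
        curve = g.model_curve("ogston_amsden", net, medium, radii)
        kb, t, eta = 1.380649e-23, 307.0, 7.34e-4
        for i, r in enumerate(radii):
            d0 = kb * t / (6 * math.pi * eta * r * 1e-9) * 1e12
            expect = d0 * math.exp(-(math.pi / 4) * ((r + 10) / 150) ** 2)
            assert curve.dg_um2_s[i] == pytest.approx(expect, rel=1e-10)

    def test_curve_decreasing_and_below_free_diffusion(self, thick_fiber_network, medium):
        curve = g.model_curve("ogston_amsden", thick_fiber_network, medium)
        assert np.all(np.diff(curve.dg_um2_s) < 0)
        d0 = g.stokes_einstein_d0(curve.radius_grid_nm, medium)
        assert np.all(curve.dg_um2_s <= d0)

    def test_empty_grid_rejected(self, thin_fiber_network, medium):
        with pytest.raises(ValidationError):
            g.model_curve("ogston_amsden", thin_fiber_network, medium, [])


class TestInvertRadius:
    @pytest.mark.parametrize("model", ["ogston_amsden", "clague_phillips"])
    def test_round_trip(self, model, thick_fiber_network, medium):
        forward = g.model_curve(model, thick_fiber_network, medium, [5.0]).dg_um2_s[0]
        assert g.invert_radius(forward, model, thick_fiber_network, medium) == pytest.approx(
            5.0, rel=1e-6)

    def test_matches_dense_grid_scan(self, medium):
        # brute-force oracle: locate 2.5 um^2/s on a dense curve by interpolation
        net = g.GelNetwork(10.0, 0.016, 140.0)
        grid = np.geomspace(0.1, 1e4, 400_000)
        dg = g.stokes_einstein_d0(grid, medium) * g.ogston_amsden_ratio(grid, net)
        idx = np.argmin(np.abs(dg - 2.5))
        scan_root = grid[idx]
        root = g.invert_radius(2.5, "ogston_amsden", net, medium)
        assert root == pytest.approx(scan_root, rel=1e-4)
        assert root == pytest.approx(88.0, abs=1.0)

    def test_unattainable_target_errors(self, thick_fiber_network, medium):
        with pytest.raises(OutsideModelRangeError):
            g.invert_radius(1e6, "ogston_amsden", thick_fiber_network, medium)


class TestMeshEstimation:
    def test_noiseless_round_trip(self, medium):
        net = g.GelNetwork(1.0, 0.016, 14.0)
        probes = [
            g.ProbeSpec(f"p{i}", r, d_gel_um2_s=g.stokes_einstein_d0(r, medium)
                        * g.ogston_amsden_ratio(r, net))
            for i, r in enumerate([0.7, 3.0, 7.95])
        ]
        fit = g.estimate_mesh_from_probes(probes, fiber_radius_nm=1.0, medium=medium)
        assert fit.network.mesh_radius_nm == pytest.approx(14.0, rel=1e-6)
        assert not fit.poor_fit

    def test_single_probe_matches_closed_form(self, medium):
        net = g.GelNetwork(1.0, 0.016, 14.0)
        r = 3.0
        dg = g.stokes_einstein_d0(r, medium) * g.ogston_amsden_ratio(r, net)
        fit = g.estimate_mesh_from_probes([g.ProbeSpec("only", r, d_gel_um2_s=dg)],
                                          fiber_radius_nm=1.0, medium=medium)
        ratio = dg / g.stokes_einstein_d0(r, medium)
        closed = (r + 1.0) / math.sqrt(-4 * math.log(ratio) / math.pi) - 1.0
        assert fit.network.mesh_radius_nm == pytest.approx(closed, rel=1e-9)

    def test_noisy_recovery_within_calibrated_tolerance(self):
        # 3 probes, 5% multiplicative noise, 200 seeds: median |mesh error| <= 15%
        errors = []
        for seed in range(200):
            probes, truth = g.generate_probe_dataset(
                g.ProbeSimConfig(seed=seed, noise_cv=0.05))
            fit = g.estimate_mesh_from_probes(probes, fiber_radius_nm=1.0)
            errors.append(abs(fit.network.mesh_radius_nm - truth["mesh_radius_nm"])
                          / truth["mesh_radius_nm"])
        assert np.median(errors) <= 0.15

    def test_requires_a_measured_probe(self):
        with pytest.raises(ValidationError):
            g.estimate_mesh_from_probes([g.ProbeSpec("dry", 3.0)], fiber_radius_nm=1.0)
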