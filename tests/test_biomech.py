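"""Indentation analysis: Hayes factor, segment extraction, moduli."""

import dataclasses

import numpy as np
import pytest

from cartispec._hayes import kappa_exact
from cartispec.biomech import (analyze_test, dynamic_modulus_phase,
                               equilibrium_modulus, hayes_kappa,
                               instantaneous_modulus, mean_thickness,
                               prestress_offset)
from cartispec.records import SegmentMarkers
from cartispec.synthdata import ProtocolConfig, generate_mechanical_test


def _moduli(E_eq=1.29, E_inst=19.12, E_dyn=9.42, phase=5.37):
    return {"E_eq_MPa": E_eq, "E_inst_MPa": E_inst, "E_dyn_MPa": E_dyn,
            "phase_deg": phase}


class TestHayesKappa:
    def test_halfspace_limit(self):
        # kappa - 1 ~ 0.9..1.1 a/h to first order, so the half-space value
        # is approached linearly: 0.5 % agreement inside a/h <= 0.004.
        assert hayes_kappa(0.0, 0.3) == pytest.approx(1.0, abs=1e-9)
        for nu in (0.3, 0.5):
            assert hayes_kappa(0.004, nu) == pytest.approx(1.0, rel=0.005)

    def test_monotone_in_aspect_ratio_and_nu(self):
        for nu in (0.3, 0.5):
            k = [hayes_kappa(a, nu) for a in (0.25, 0.5, 1.0)]
            assert k[0] < k[1] < k[2]
            assert all(v > 1.0 for v in k)
        assert hayes_kappa(0.5, 0.5) > hayes_kappa(0.5, 0.3)

    @pytest.mark.parametrize("aoh", [0.137, 0.61, 1.23])
    @pytest.mark.parametrize("nu", [0.3, 0.5])
    def test_interpolant_matches_direct_solution(self, aoh, nu):
        # off-grid cross-check against the Fredholm solver
        assert hayes_kappa(aoh, nu) == pytest.approx(kappa_exact(aoh, nu),
                                                     rel=2e-3)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            hayes_kappa(2.5, 0.3)
        with pytest.raises(ValueError):
            hayes_kappa(0.5, 0.6)


class TestThickness:
    def test_mean(self):
        assert mean_thickness([2.0, 2.2, 2.4]) == pytest.approx(2.2)
        assert mean_thickness([1.7, 1.7, 1.7]) == pytest.approx(1.7)

    def test_bounds_and_errors(self):
        pts = [1.9, 2.3, 2.6]
        assert min(pts) <= mean_thickness(pts) <= max(pts)
        with pytest.raises(ValueError):
            mean_thickness([2.0, -0.1, 2.4])
        with pytest.raises(ValueError):
            mean_thickness([2.0, 2.1])


class TestRoundTrip:
    def test_reported_group_means_recovered(self, group_means):
        for params in group_means.values():
            test = generate_mechanical_test(
                {k: v for k, v in params.items() if k != "thickness_mm"},
                params["thickness_mm"])
            res = analyze_test(test)
            assert res.E_eq_MPa == pytest.approx(params["E_eq_MPa"], rel=0.01)
            assert res.E_inst_MPa == pytest.approx(params["E_inst_MPa"], rel=0.01)
            assert res.E_dyn_MPa == pytest.approx(params["E_dyn_MPa"], rel=0.01)
            assert res.phase_deg == pytest.approx(params["phase_deg"], abs=0.1)

    @pytest.mark.parametrize("e_eq,thick", [(0.05, 1.2), (1.0, 2.5), (30.0, 3.5)])
    def test_broad_modulus_grid(self, e_eq, thick):
        m = _moduli(E_eq=e_eq, E_inst=3 * e_eq, E_dyn=2 * e_eq, phase=4.0)
        res = analyze_test(generate_mechanical_test(m, thick))
        assert res.E_eq_MPa == pytest.approx(e_eq, rel=0.01)
        assert res.E_inst_MPa == pytest.approx(3 * e_eq, rel=0.01)
        assert res.E_dyn_MPa == pytest.approx(2 * e_eq, rel=0.01)
        assert res.phase_deg == pytest.approx(4.0, abs=0.1)

    def test_force_scaling_linearity(self):
        test = generate_mechanical_test(_moduli(), 2.37)
        doubled = dataclasses.replace(test, force=2 * test.force)
        assert equilibrium_modulus(doubled) == pytest.approx(
            2 * equilibrium_modulus(test), rel=1e-9)

    def test_purely_elastic_limit(self):
        m = _moduli(E_eq=1.0, E_inst=1.0)
        test = generate_mechanical_test(m, 2.0)
        assert instantaneous_modulus(test) == pytest.approx(
            equilibrium_modulus(test), rel=0.01)

    def test_zero_relaxation_time_peaks_coincide_with_plateaus(self):
        proto = ProtocolConfig(tau_s=0.0)
        test = generate_mechanical_test(_moduli(), 2.37, protocol=proto)
        f = test.force_N
        for i0, i1 in test.markers.steps:
            seg = f[i0:i1]
            assert seg.max() == pytest.approx(seg[-1], rel=1e-9)

    def test_noise_robustness(self):
        # ~1% bias budget at force SNR ~100 on the dynamic amplitude
        truth = _moduli()
        e_dyns, phases = [], []
        for s in range(20):
            test = generate_mechanical_test(
                truth, 2.37, force_noise_sd=2e-3,
                rng=np.random.default_rng(s))
            e, p = dynamic_modulus_phase(test)
            e_dyns.append(e)
            phases.append(p)
        assert np.mean(e_dyns) == pytest.approx(truth["E_dyn_MPa"], rel=0.01)
        assert np.mean(phases) == pytest.approx(truth["phase_deg"], abs=0.1)


class TestSegments:
    def test_zero_phase(self):
        test = generate_mechanical_test(_moduli(phase=0.0), 2.37)
        _, phase = dynamic_modulus_phase(test)
        assert abs(phase) <= 0.05

    def test_phase_invariant_to_force_offset(self):
        test = generate_mechanical_test(_moduli(), 2.37)
        shifted = dataclasses.replace(test, force=test.force + 0.5)
        assert dynamic_modulus_phase(shifted)[1] == pytest.approx(
            dynamic_modulus_phase(test)[1], abs=1e-6)

    def test_step_selection_near_ten_percent_strain(self):
        test = generate_mechanical_test(_moduli(), 2.37)
        u0, _ = prestress_offset(test)
        strains = []
        for i0, i1 in test.markers.steps:
            j = i0 + int(np.argmax(test.force_N[i0:i1]))
            strains.append((test.displacement_mm[j] - u0) / test.thickness_mm)
        expect = [1 - 0.95**k for k in range(1, 5)]
        assert strains == pytest.approx(expect, rel=1e-6)
        assert int(np.argmin(np.abs(np.array(strains) - 0.10))) == 1

    def test_prestress_origin_matches_truth(self):
        test = generate_mechanical_test(_moduli(), 2.37)
        u0, f0 = prestress_offset(test)
        assert u0 == pytest.approx(test.truth["u_origin_mm"], abs=1e-9)
        assert f0 == pytest.approx(test.truth["F_pre_N"], rel=1e-9)

    def test_missing_prestress_segment_falls_back_with_warning(self):
        test = generate_mechanical_test(_moduli(), 2.37)
        test = dataclasses.replace(
            test, markers=SegmentMarkers(None, test.markers.steps,
                                         test.markers.dynamic))
        with pytest.warns(UserWarning):
            u0, _ = prestress_offset(test)
        assert u0 == test.displacement_mm[0]

    def test_unit_conversion(self):
        test = generate_mechanical_test(_moduli(), 2.37)
        scaled = dataclasses.replace(
            test, force=test.force * 1e3, force_unit="mN",
            displacement=test.displacement * 1e3, displacement_unit="um")
        a, b = analyze_test(test), analyze_test(scaled)
        assert b.E_eq_MPa == pytest.approx(a.E_eq_MPa, rel=1e-9)
        assert b.E_dyn_MPa == pytest.approx(a.E_dyn_MPa, rel=1e-9)

    def test_incremental_equals_per_step_inversion_for_linear_material(self):
        from cartispec.biomech import _step_plateaus
        test = generate_mechanical_test(_moduli(), 2.37)
        u0, f0 = prestress_offset(test)
        a_m = 0.5 * test.indenter_diameter_mm * 1e-3
        h_m = test.thickness_mm * 1e-3
        kappa = hayes_kappa(a_m / h_m, 0.3)
        u_eq, f_eq = _step_plateaus(test, 60.0)
        per_step = (f_eq - f0) * (1 - 0.3**2) / (
            2 * a_m * (u_eq - u0) * 1e-3 * kappa) / 1e6
        assert np.mean(per_step) == pytest.approx(equilibrium_modulus(test),
                                                  rel=1e-6)
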