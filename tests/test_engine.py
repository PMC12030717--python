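import numpy as np
import pytest
import scipy.linalg

import tcbpbpk as tp
from tcbpbpk.engine import SystemLayout, assemble_system, pk_metrics, simulate

from conftest import STUDY_DOSE_NMOL, reduced_body_scenario


class TestAssembly:
    def test_state_count_matches_hand_counted_layout(self, scenario):
        layout = SystemLayout(scenario)
        # 2 blood + 12 tissue organs: 4 species x (2 + 24) sub-compartments,
        # 3 extra tumor species, 14 catabolized pools, 1 + 24 T-cell states
        assert layout.n == 4 * 26 + 3 + 14 + 25
        assert layout.n == layout.expected_size()

    def test_unknown_state_raises_named_error(self, scenario):
        layout = SystemLayout(scenario)
        with pytest.raises(Exception, match="no state"):
            layout.idx("pancreas", "vascular", "tcb")

    def test_zero_dose_holds_equilibrium(self, scenario):
        """Receptors, HER2 and T-cells start at homeostasis and stay there."""
        res = simulate(scenario, "HER2-CD3L", dose_nmol=0.0)
        y0 = res.system.y_steady
        scale = np.maximum(np.abs(y0), np.abs(y0).max() * 1e-12)
        drift = np.abs(res.y - y0[None, :]) / scale[None, :]
        assert drift.max() < 1e-6
        assert res.tcb_mass_balance_error() == 0.0

    def test_tcell_baseline_recorded_on_organs(self, scenario):
        assemble_system(scenario, "gD")
        spleen = scenario.organ("spleen")
        assert spleen.tcell_baseline > 0


class TestSimulate:
    def test_mass_balance_study_dose(self, variant_results):
        res = variant_results["HER2-CD3L"]
        assert res.tcb_mass_balance_error() < 1e-6

    def test_deterministic_repeat(self, scenario):
        r1 = simulate(scenario, "gD", dose_nmol=0.01, rtol=1e-6)
        r2 = simulate(scenario, "gD", dose_nmol=0.01, rtol=1e-6)
        assert np.array_equal(r1.y, r2.y)

    def test_tolerance_refinement_converged(self, scenario):
        """Halving the solver tolerance moves reported Cmax by <0.1%."""
        cmaxes = []
        for rtol in (1e-6, 5e-7):
            res = simulate(scenario, "HER2-CD3L", dose_nmol=STUDY_DOSE_NMOL, rtol=rtol)
            cmaxes.append(pk_metrics(res.t, res.conc_nM("tumor", "interstitial", "synapse")).cmax)
        assert abs(cmaxes[1] - cmaxes[0]) / cmaxes[0] < 1e-3

    def test_gd_blood_pk_is_biexponential_multiday(self, variant_results):
        """The non-binding control declines biexponentially with a multi-day
        terminal half-life, as expected for an IgG in the mouse."""
        res = variant_results["gD"]
        c = res.blood_conc_nM("tcb")
        m = pk_metrics(res.t, c)
        t_half = np.log(2) / m.lambda_z
        assert 48.0 < t_half < 400.0
        # early decline is faster than the terminal phase (distribution)
        early = np.log(c[0] / np.interp(24.0, res.t, c)) / 24.0
        assert early > 2.0 * m.lambda_z

    def test_multiple_boluses_accumulate(self, scenario):
        sc = tp.default_scenario(t_end=200.0)
        sc.doses = [
            tp.DoseEvent(molecule="gD", time=0.0, amount=0.01, unit="mg"),
            tp.DoseEvent(molecule="gD", time=48.0, amount=0.01, unit="mg"),
        ]
        res = simulate(sc, "gD", rtol=1e-6)
        c = res.blood_conc_nM("tcb")
        before = np.interp(47.9, res.t, c)
        after = np.interp(48.5, res.t, c)
        assert after > before * 1.5
        assert res.tcb_mass_balance_error() < 1e-6


class TestLinearOracle:
    def test_non_binding_disposition_matches_matrix_exponential(self):
        """gD on a reduced 3-organ body is a linear system: the stiff solver
        must agree with the matrix-exponential solution to 1e-8 relative."""
        sc = reduced_body_scenario()
        system = assemble_system(sc, "gD")
        assert not len(system.reactions["iA"])  # fully linear
        assert np.allclose(system.const, 0.0)
        y0 = system.y_steady.copy()
        i_dose = system.layout.idx("venous_blood", "vascular", "tcb")
        y0[i_dose] += 0.0667
        t_checks = [1.0, 24.0, 240.0, 1000.0]
        res = simulate(sc, "gD", t_eval=np.array([0.0] + t_checks), rtol=1e-10, dose_nmol=0.0667)
        for k, t in enumerate(t_checks, start=1):
            y_ref = scipy.linalg.expm(system.matrix * t) @ y0
            scale = np.abs(y_ref).max()
            assert np.allclose(res.y[k], y_ref, rtol=1e-8, atol=scale * 1e-10)


class TestPKMetrics:
    def test_constant_concentration(self):
        t = np.linspace(0, 10, 50)
        m = pk_metrics(t, np.full_like(t, 3.0))
        assert m.auc_0_tend == pytest.approx(30.0, rel=1e-12)
        assert "non-decaying-tail" in m.flags

    def test_mono_exponential_extrapolates_to_c0_over_k(self):
        k, c0 = 0.05, 20.0
        t = np.linspace(0, 200, 400)
        m = pk_metrics(t, c0 * np.exp(-k * t))
        assert m.auc_0_inf == pytest.approx(c0 / k, rel=1e-3)
        assert m.lambda_z == pytest.approx(k, rel=1e-6)

    def test_iv_bolus_tmax_at_first_point(self, variant_results):
        res = variant_results["gD"]
        m = pk_metrics(res.t, res.blood_conc_nM("tcb"))
        assert m.tmax == res.t[0]

    def test_parabolic_refinement_recovers_off_grid_peak(self):
        t = np.linspace(0, 10, 21)  # peak of t*exp(-t/2) at t=2 not on grid edge
        c = t * np.exp(-t / 2.0)
        m = pk_metrics(t, c)
        assert m.tmax == pytest.approx(2.0, abs=0.1)
        assert m.cmax >= c.max()


class TestReceptorOccupancy:
    def test_no_drug_gives_free_occupancy_one(self, scenario):
        res = simulate(scenario, "HER2-CD3L", dose_nmol=0.0)
        ro = tp.receptor_occupancy(res, "HER2")
        assert np.allclose(ro.ro_free, 1.0, atol=1e-12)
        assert np.allclose(ro.ro_synapse, 0.0)

    def test_partition_identity(self, variant_results):
        ro = tp.receptor_occupancy(variant_results["HER2-CD3H"], "CD3")
        total = ro.ro_free + ro.ro_complex + ro.ro_synapse
        assert np.nanmax(np.abs(total - 1.0)) < 1e-9
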