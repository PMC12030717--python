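import numpy as np
import pytest
import scipy.integrate

from tcbpbpk import synapse
from tcbpbpk.synapse import ReceptorParams
from tcbpbpk.units import N_AVOGADRO


@pytest.fixture
def params():
    return ReceptorParams()


class TestStructuralConstraints:
    def test_cd3_internalization_is_half_recycling(self, params):
        assert params.k_int_CD3 == 0.5 * params.k_rec_CD3
        assert ReceptorParams(k_rec_CD3=1.7).k_int_CD3 == pytest.approx(0.85)

    def test_synapse_internalization_is_one_third_of_dimer(self, params):
        assert params.k_int_synapse == params.k_int_dimer / 3.0
        assert ReceptorParams(k_int_dimer=0.9).k_int_synapse == pytest.approx(0.3)

    def test_her2_complex_elimination_equals_degradation(self, params):
        assert params.k_elim_HER2complex == params.k_deg_HER2

    def test_her2_synthesis_balances_baseline(self, params):
        assert params.k_syn_HER2 / params.k_deg_HER2 == pytest.approx(
            params.her2_total_nmol
        )


class TestCD3Pool:
    def test_zero_cells_zero_receptors(self):
        assert synapse.cd3_pool_size(0.0, 1e5) == 0.0

    def test_avogadro_arithmetic(self):
        # 1e6 cells x 1e5 receptors = 1e11 receptors = 1.66e-4 nmol
        pool = synapse.cd3_pool_size(1e6, 1e5)
        assert pool == pytest.approx(1e11 / N_AVOGADRO * 1e9, rel=1e-12)
        assert pool == pytest.approx(1.66e-4, rel=1e-2)

    def test_linearity_in_cell_count(self):
        assert synapse.cd3_pool_size(2e6, 1e5) == pytest.approx(
            2.0 * synapse.cd3_pool_size(1e6, 1e5)
        )


class TestCD3Recycling:
    def test_closed_two_pool_steady_state_is_two_to_one(self, params):
        """Membrane:internal pins at k_rec/k_int = 2 exactly."""
        def rhs(t, y):
            d_mem, d_int = synapse.cd3_recycling_fluxes(y[0], y[1], params)
            return [d_mem, d_int]

        sol = scipy.integrate.solve_ivp(rhs, (0, 500), [10.0, 0.0], rtol=1e-10, atol=1e-12)
        mem, internal = sol.y[:, -1]
        assert mem / internal == pytest.approx(2.0, rel=1e-6)

    def test_relaxation_rate_matches_closed_form(self, params):
        """The split relaxes to 2:1 with rate k_rec + k_int."""
        k = params.k_rec_CD3 + params.k_int_CD3
        total = 9.0
        y0 = np.array([total, 0.0])

        def rhs(t, y):
            d_mem, d_int = synapse.cd3_recycling_fluxes(y[0], y[1], params)
            return [d_mem, d_int]

        t_probe = 1.7
        sol = scipy.integrate.solve_ivp(
            rhs, (0, t_probe), y0, rtol=1e-10, atol=1e-12, t_eval=[t_probe]
        )
        expected_mem = total * (2.0 / 3.0 + (1.0 / 3.0) * np.exp(-k * t_probe))
        assert sol.y[0, -1] == pytest.approx(expected_mem, rel=1e-8)

    def test_static_pool_without_rates(self):
        frozen = ReceptorParams(k_rec_CD3=0.0)
        assert synapse.cd3_recycling_fluxes(5.0, 0.0, frozen) == (0.0, 0.0)


def _binding_args(**overrides):
    base = dict(
        tcb_free=0.0,
        cd3_mem=0.0,
        her2_free=0.0,
        tcb_cd3=0.0,
        tcb_her2=0.0,
        synapse=0.0,
        volume_mL=0.1,
        kon_CD3=360.0,
        koff_CD3=18.0,
        kon_HER2=360.0,
        koff_HER2=1.8,
        avidity_factor=0.01,
    )
    base.update(overrides)
    return base


class TestBindingNetwork:
    def test_all_zero_state_gives_zero_fluxes(self):
        fluxes = synapse.binding_fluxes(**_binding_args())
        assert all(v == 0.0 for v in fluxes.values())

    def test_langmuir_equilibrium_single_reaction(self):
        """TCB + CD3 only: occupancy = C/(C + Kd) at equilibrium."""
        kon, koff, vol = 360.0, 18.0, 0.1  # Kd = koff/kon * 1000 / ... amount units
        cd3_total = 1e-7

        def rhs(t, y):
            f = synapse.binding_fluxes(
                **_binding_args(
                    tcb_free=y[0], cd3_mem=y[1], tcb_cd3=y[2],
                    kon_CD3=kon, koff_CD3=koff, kon_HER2=0.0, koff_HER2=0.0,
                )
            )
            return [f["tcb_free"], f["cd3_mem"], f["tcb_cd3"]]

        tcb0 = 0.05  # nmol, effectively unperturbed by the tiny receptor pool
        sol = scipy.integrate.solve_ivp(
            rhs, (0, 50), [tcb0, cd3_total, 0.0], rtol=1e-10, atol=1e-16
        )
        occupancy = sol.y[2, -1] / cd3_total
        conc = tcb0 / vol  # nmol/mL
        kd = koff / kon  # nmol/mL
        assert occupancy == pytest.approx(conc / (conc + kd), rel=1e-6)

    def test_thermodynamic_cycle_is_path_independent(self):
        """With avidity on both second-step koffs, the equilibrium-constant
        product along TCB->dimer->synapse is identical for the two paths."""
        kon_c, koff_c, kon_h, koff_h, av = 360.0, 18.0, 200.0, 3.0, 0.01
        path_via_cd3 = (kon_c / koff_c) * (kon_h / (koff_h * av))
        path_via_her2 = (kon_h / koff_h) * (kon_c / (koff_c * av))
        assert path_via_cd3 == pytest.approx(path_via_her2, rel=1e-12)


class TestInternalization:
    def test_zero_rate_preserves_ratio(self):
        p = ReceptorParams(k_int_dimer=0.0)
        f = synapse.internalization_fluxes(tcb_cd3=1.0, tcb_her2=0.0, synapse=1.0, params=p)
        assert f["synapse"] == 0.0 and f["tcb_cd3"] == 0.0

    def test_pulse_chase_synapse_decay(self):
        """A preformed synapse pool with only internalization active decays
        mono-exponentially at k_int_dimer/3, and the catabolized pool gains
        exactly the internalized amount."""
        p = ReceptorParams(k_int_dimer=0.3)
        syn0 = 2.0

        def rhs(t, y):
            f = synapse.internalization_fluxes(
                tcb_cd3=0.0, tcb_her2=0.0, synapse=y[0], params=p
            )
            return [f["synapse"], f["catabolized"]]

        sol = scipy.integrate.solve_ivp(rhs, (0, 10), [syn0, 0.0], rtol=1e-10, atol=1e-14)
        assert sol.y[0, -1] == pytest.approx(syn0 * np.exp(-0.1 * 10), rel=1e-7)
        assert sol.y[0, -1] + sol.y[1, -1] == pytest.approx(syn0, rel=1e-9)


class TestHER2Turnover:
    def test_baseline_steady_state(self):
        p = ReceptorParams()
        assert synapse.her2_turnover_fluxes(p.her2_total_nmol, p) == pytest.approx(0.0, abs=1e-15)

    def test_no_synthesis_decays_to_zero(self):
        p = ReceptorParams(receptors_per_tumor_cell=0.0)
        assert p.k_syn_HER2 == 0.0
        assert synapse.her2_turnover_fluxes(1.0, p) == pytest.approx(-p.k_deg_HER2)
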