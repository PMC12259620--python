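"""Single-neuron model: metabolic kinetics, currents, ion dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from digitoids import _kernel
from digitoids.neuron import (MembraneParams, MetabolicParams, NeuronState,
                              basal_consumption, firing_consumption,
                              gating_derivatives, gating_rates,
                              gating_steady_state, ion_derivatives,
                              leak_currents, membrane_currents, nernst,
                              neuron_rhs, potassium_in, pump_current,
                              pump_rate, resting_state, sodium_out,
                              total_consumption)


class TestMetabolism:
    def test_basal_consumption_michaelis_menten(self, mp):
        assert basal_consumption(0.0, mp) == 0.0
        assert basal_consumption(mp.km, mp) == pytest.approx(mp.R_max / 2)
        # saturation: 5.28e-14 g/s/cell * 1.2e13 cell/m3 = 0.6336 g m^-3 s^-1
        assert mp.R_max == pytest.approx(0.6336 / 32)
        assert basal_consumption(1e6, mp) == pytest.approx(mp.R_max, rel=1e-3)
        with pytest.raises(ValueError):
            basal_consumption(-0.1, mp)

    def test_pump_rate_sigmoid(self, mp):
        half = mp.c_half / mp.o2_scale
        assert pump_rate(half, mp) == pytest.approx(mp.rho_max / 2)
        assert pump_rate(1e3, mp) == pytest.approx(mp.rho_max)
        # at zero oxygen the sigmoid floor is rho_max / (1 + e^(20/3))
        assert pump_rate(0.0, mp) == pytest.approx(
            mp.rho_max / (1 + math.exp(20 / 3)))
        cs = np.linspace(0.0, 0.5, 200)
        rhos = [pump_rate(c, mp) for c in cs]
        assert np.all(np.diff(rhos) > 0)

    def test_pump_current_half_points_and_limits(self, mp):
        assert pump_current(25.0, 5.5, 1.0, mp) == pytest.approx(0.25)
        assert pump_current(18.0, 4.0, 0.0, mp) == 0.0
        assert pump_current(1e3, 1e3, 2.0, mp) == pytest.approx(2.0)
        # monotone in each substrate
        assert pump_current(30, 5.5, 1.0, mp) > pump_current(20, 5.5, 1.0, mp)
        assert pump_current(25, 8.0, 1.0, mp) > pump_current(25, 4.0, 1.0, mp)

    def test_firing_consumption_linear_in_pump(self, mp):
        assert firing_consumption(0.0, mp) == 0.0
        assert firing_consumption(1.0, mp) == pytest.approx(0.17)
        assert firing_consumption(2.0, mp) == pytest.approx(0.34)

    def test_total_consumption_additivity(self, mp):
        st_ = NeuronState(V=-65, m=0.05, p=0.9, n=0.2, Na_i=18.0, K_o=4.0)
        c = 0.15
        rho = pump_rate(mp.frac_f * c, mp)
        expected = (basal_consumption(mp.frac_nf * c, mp)
                    + firing_consumption(
                        pump_current(st_.Na_i, st_.K_o, rho, mp), mp))
        assert total_consumption(c, st_, mp) == expected
        # at zero oxygen the basal term vanishes; only the sigmoid floor of
        # the pump rate (~1.6e-3 rho_max) survives
        floor = firing_consumption(
            pump_current(st_.Na_i, st_.K_o, pump_rate(0.0, mp), mp), mp)
        assert basal_consumption(0.0, mp) == 0.0
        assert total_consumption(0.0, st_, mp) == pytest.approx(floor)
        assert total_consumption(0.0, st_, mp) < 1e-3 * mp.R_max


class TestNernstAndCurrents:
    def test_nernst_values(self):
        assert nernst(10.0, 10.0) == 0.0
        assert nernst(144.0, 18.0) == pytest.approx(26.64 * math.log(8))
        assert nernst(4.0, 140.0) == pytest.approx(-94.714, abs=1e-3)
        with pytest.raises(ValueError):
            nernst(0.0, 10.0)

    def test_ion_closures_at_reference(self, mb):
        assert sodium_out(mb.Na_i_ref, mb) == mb.Na_o_ref
        assert potassium_in(mb.Na_i_ref, mb) == mb.K_i_ref
        # conservation: Na entering the cell leaves the (beta-times smaller)
        # extracellular pool
        assert sodium_out(mb.Na_i_ref + 1.0, mb) == mb.Na_o_ref - mb.beta

    def test_currents_vanish_at_reversal_and_closed_gates(self, mb):
        E_Na = nernst(144.0, 18.0)
        s = NeuronState(V=E_Na, m=0.5, p=0.5, n=0.3, Na_i=18.0, K_o=4.0)
        I_Na, _, _ = membrane_currents(s, mb)
        assert I_Na == pytest.approx(0.0, abs=1e-12)
        s2 = NeuronState(V=-30.0, m=0.0, p=0.5, n=0.3, Na_i=18.0, K_o=4.0)
        I_Na2, _, _ = membrane_currents(s2, mb)
        assert I_Na2 == 0.0

    def test_currents_match_independent_evaluation(self, mb):
        V = -70.0
        m, p, n = gating_steady_state(V)
        s = NeuronState(V=V, m=m, p=p, n=n, Na_i=18.0, K_o=4.0)
        I_Na, I_K, I_Cl = membrane_currents(s, mb)
        E_Na = 26.64 * math.log(144.0 / 18.0)
        E_K = 26.64 * math.log(4.0 / 140.0)
        assert I_Na == pytest.approx(30.0 * m**3 * p * (V - E_Na))
        assert I_K == pytest.approx(25.0 * n**4 * (V - E_K))
        assert I_Cl == pytest.approx(0.05 * (V - 26.64 * math.log(6 / 130)))


class TestGating:
    @pytest.mark.parametrize("V", [-90.0, -70.0, -50.0, -30.0, 0.0, 30.0])
    def test_fixed_point_has_zero_derivative(self, V):
        m, p, n = gating_steady_state(V)
        s = NeuronState(V=V, m=m, p=p, n=n, Na_i=18.0, K_o=4.0)
        dm, dp, dn = gating_derivatives(s)
        assert abs(dm) < 1e-9 and abs(dp) < 1e-9 and abs(dn) < 1e-9
        assert 0.0 <= min(m, p, n) and max(m, p, n) <= 1.0

    def test_boundaries_repel(self):
        s0 = NeuronState(V=-50.0, m=0.0, p=0.0, n=0.0, Na_i=18.0, K_o=4.0)
        assert all(d >= 0 for d in gating_derivatives(s0))
        s1 = NeuronState(V=-50.0, m=1.0, p=1.0, n=1.0, Na_i=18.0, K_o=4.0)
        assert all(d <= 0 for d in gating_derivatives(s1))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(V=st.floats(-120.0, 60.0))
    def test_steady_state_contained(self, V):
        rates = gating_rates(V)
        assert all(r >= 0 for r in rates)
        m, p, n = gating_steady_state(V)
        assert 0.0 <= min(m, p, n) and max(m, p, n) <= 1.0


class TestIonDynamics:
    def test_zero_input_zero_derivative(self):
        mb0 = MembraneParams(eps_bath=0.0)
        s = NeuronState(V=-65, m=0, p=1, n=0, Na_i=18.0, K_o=4.0)
        assert ion_derivatives(s, 0.0, 0.0, 0.0, mb0) == (0.0, 0.0)

    def test_pump_stoichiometry(self):
        mb0 = MembraneParams(eps_bath=0.0)
        s = NeuronState(V=-65, m=0, p=1, n=0, Na_i=18.0, K_o=4.0)
        dKo, dNai = ion_derivatives(s, 0.0, 0.0, 0.1, mb0)
        assert dKo == pytest.approx(-2.0 * mb0.beta * 0.1)
        assert dNai == pytest.approx(-3.0 * 0.1)
        assert dNai / (dKo / mb0.beta) == pytest.approx(1.5)  # 3 Na : 2 K

    def test_gamma_beta_coupling_value(self):
        mb0 = MembraneParams(eps_bath=0.0)
        s = NeuronState(V=-65, m=0, p=1, n=0, Na_i=18.0, K_o=4.0)
        dKo, _ = ion_derivatives(s, 1.0, 0.0, 0.0, mb0)
        assert dKo == pytest.approx(0.04445 * 7.0)  # 0.31115 mM/s

    def test_bath_coupling_relaxes_to_bath(self):
        mb = MembraneParams(eps_bath=0.5, K_bath=4.0)
        s = NeuronState(V=-65, m=0, p=1, n=0, Na_i=18.0, K_o=6.0)
        dKo, _ = ion_derivatives(s, 0.0, 0.0, 0.0, mb)
        assert dKo == pytest.approx(0.5 * (4.0 - 6.0))


class TestRhs:
    def test_zero_current_fixed_point(self):
        mb = MembraneParams(G_Na_leak=0.0, G_K_leak=0.0, eps_bath=0.0)
        mp = MetabolicParams()
        s = NeuronState(V=mb.E_Cl, m=0.0, p=0.5, n=0.0, Na_i=18.0, K_o=4.0)
        d = neuron_rhs(s, 0.2, 0.0, 0.0, mp, mb, rho_override=0.0)
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_kernel_derivative_matches_python_rhs(self, mp, mb):
        """Term-by-term agreement of the numba kernel and the reference RHS."""
        rng = np.random.default_rng(7)
        n = 5
        Y = np.empty((7, n))
        Y[0] = rng.uniform(-80, 30, n)
        Y[1:4] = rng.uniform(0, 1, (3, n))
        Y[4] = rng.uniform(10, 30, n)
        Y[5] = rng.uniform(3, 12, n)
        Y[6] = rng.uniform(0, 1, n)
        A = (rng.uniform(0, 1, (n, n)) < 0.5).astype(float)
        A = np.triu(A, 1) + np.triu(A, 1).T
        Esyn = np.where(rng.uniform(0, 1, n) < 0.8, 0.0, -80.0)
        tau = np.where(Esyn == 0.0, 4e-3, 8e-3)
        rho = rng.uniform(0, 1.25, n)
        Iext = rng.uniform(0, 3, n)
        pv = _kernel.pack_params(mb, mp)
        K = np.empty((7, n))
        ip = np.empty(n)
        _kernel._deriv(Y, K, np.ascontiguousarray(A), Esyn, tau, rho, Iext,
                       pv, False, ip)
        for i in range(n):
            s = NeuronState(V=Y[0, i], m=Y[1, i], p=Y[2, i], n=Y[3, i],
                            Na_i=Y[4, i], K_o=Y[5, i])
            I_syn = float(np.sum(Y[6] * A[:, i] * (Esyn - Y[0, i])))
            d = neuron_rhs(s, 0.0, I_syn, Iext[i], mp, mb,
                           rho_override=rho[i])
            np.testing.assert_allclose(K[:6, i], d, rtol=1e-12, atol=1e-12)
            np.testing.assert_allclose(K[6, i], -Y[6, i] / tau[i], rtol=1e-12)
            assert ip[i] == pytest.approx(
                pump_current(Y[4, i], Y[5, i], rho[i], mp), rel=1e-12)

    def test_kernel_trajectory_matches_solve_ivp(self, mp, mb):
        """RK4 kernel vs an independent adaptive integration of the same ODE."""
        from scipy.integrate import solve_ivp
        from digitoids.engine import SimConfig, run

        I_ext = 6.0
        cfg = SimConfig(mode="hh_comparator", n=1, duration=0.25,
                        clamp_ions=True, I_ext=I_ext, record_dt=1e-4)
        res = run(cfg)
        s0 = resting_state(cfg.V_init, mb=mb)

        def rhs(t, y):
            s = NeuronState(V=y[0], m=y[1], p=y[2], n=y[3],
                            Na_i=s0.Na_i, K_o=s0.K_o)
            d = neuron_rhs(s, 0.0, 0.0, I_ext, mp, mb, clamp_ions=True,
                           rho_override=mp.rho_max)
            return d[:4]

        sol = solve_ivp(rhs, (0.0, 0.25), [s0.V, s0.m, s0.p, s0.n],
                        t_eval=res.t, rtol=1e-10, atol=1e-12, method="RK45",
                        max_step=1e-3)
        dv = np.abs(sol.y[0] - res.V[0])
        # spike alignment: phase error accumulates slowly; peaks must line up
        assert len(res.spikes[0]) > 5
        ref_spikes = res.t[np.nonzero((sol.y[0][:-1] < 0) & (sol.y[0][1:] >= 0))[0]]
        assert len(ref_spikes) == len(res.spikes[0])
        assert np.max(np.abs(ref_spikes - res.spikes[0])) < 5e-4
        # away from the steep upstrokes the traces coincide closely
        assert np.median(dv) < 0.5


class TestTrajectoryInvariants:
    def test_gating_contained_and_spikes_cross_zero(self, oxygenated_run):
        res = oxygenated_run
        spikes = res.spikes[0]
        assert len(spikes) > 50
        v, t = res.V[0], res.t
        for ts in spikes[::25]:
            i = np.searchsorted(t, ts)
            win = v[max(i - 5, 0):i + 5]
            assert win.min() < 0.0 <= win.max()

    def test_anoxia_silences_firing(self, anoxic_run):
        spikes = anoxic_run.spikes[0]
        late = [s for s in spikes if s > 6.0]
        assert late == []

    def test_firing_consumes_more_oxygen_than_rest(self, oxygenated_run,
                                                   quiescent_run):
        assert len(quiescent_run.spikes[0]) == 0
        used_firing = np.sum(oxygenated_run.R_window)
        used_rest = np.sum(quiescent_run.R_window)
        assert used_firing > used_rest
        # and the firing neuron depletes its column further
        assert (oxygenated_run.c_bottom[0, -1]
                < quiescent_run.c_bottom[0, -1])
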