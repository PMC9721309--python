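"""Pointwise dynamics, resets and spike detection of the three models."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from seizprop.neuron_models import (
    ADEX_FS, ADEX_RS, CADEX_FS, CADEX_RS, HH_FS, HH_RS,
    AdExParams, CAdExParams, HHParams, NeuronState,
    adex_derivative, adex_reset, cadex_derivative, cadex_reset,
    detect_spike, get_preset, hh_derivative, hh_rates, hh_steady_gates,
    params_from_dict, params_to_dict,
)
from seizprop.engine import simulate_single_neuron


class TestAdEx:
    def test_no_adaptation_drift_at_rest(self):
        st = NeuronState(V=ADEX_RS.EL, w=0.0)
        _, dw = adex_derivative(st, ADEX_RS, 0.0)
        assert dw == 0.0

    def test_derivative_at_threshold_point(self):
        # leak gL(EL-VT) = -150 pA plus spike-initiation gL*DeltaT = +20 pA
        st = NeuronState(V=ADEX_RS.VT, w=0.0)
        dV, _ = adex_derivative(st, ADEX_RS, 0.0)
        assert dV == pytest.approx((-150.0 + 20.0) / 200.0)  # -0.65 mV/ms

    def test_hyperpolarized_relaxes_upward(self):
        st = NeuronState(V=-80.0, w=0.0)
        dV, _ = adex_derivative(st, ADEX_RS, 0.0)
        assert dV > 0

    def test_nonfinite_input_rejected(self):
        st = NeuronState(V=-60.0, w=0.0)
        with pytest.raises(ValueError):
            adex_derivative(st, ADEX_RS, float("nan"))

    def test_reset_rs(self):
        st = NeuronState(V=-40.0, w=50.0)
        out = adex_reset(st, ADEX_RS)
        assert out.V == ADEX_RS.VR
        assert out.w == pytest.approx(150.0)
        assert out.refrac_remaining == ADEX_RS.t_ref

    def test_reset_fs_no_adaptation_jump(self):
        out = adex_reset(NeuronState(V=-40.0, w=0.0), ADEX_FS)
        assert out.w == 0.0

    def test_reset_additive_and_idempotent_on_v(self):
        st = NeuronState(V=-40.0, w=0.0)
        once = adex_reset(st, ADEX_RS)
        twice = adex_reset(NeuronState(V=-40.0, w=once.w), ADEX_RS)
        assert twice.w == pytest.approx(2 * ADEX_RS.b)
        assert once.V == twice.V == ADEX_RS.VR

    def test_reset_below_ceiling_is_contract_violation(self):
        with pytest.raises(ValueError):
            adex_reset(NeuronState(V=-60.0), ADEX_RS)

    def test_eif_relaxes_to_brute_force_fixed_point(self):
        # With a = b = 0 and no input the subthreshold fixed point solves
        # gL(EL-V) + gL*DeltaT*exp((V-VT)/DeltaT) = 0.
        p = AdExParams(a=0.0, b=0.0)
        f = lambda V: p.gL * (p.EL - V) + p.gL * p.DeltaT * math.exp(
            (V - p.VT) / p.DeltaT)
        v_star = brentq(f, -75.0, p.VT - 1e-6)
        _, V, spikes = simulate_single_neuron("adex", p, 0.0, 500.0, dt=0.01,
                                              V0=-75.0)
        assert spikes.size == 0
        assert V[-1] == pytest.approx(v_star, abs=1e-3)

    def test_tonic_isi_matches_finer_step_oracle(self):
        # Constant suprathreshold current: inter-spike interval at
        # dt = 0.01 ms agrees with a 10x finer reference to <1%.
        _, _, s1 = simulate_single_neuron("adex", ADEX_RS, 500.0, 2000.0,
                                          dt=0.01)
        _, _, s2 = simulate_single_neuron("adex", ADEX_RS, 500.0, 2000.0,
                                          dt=0.001)
        assert s1.size > 5 and s2.size > 5
        isi1 = np.diff(s1)[-3:].mean()
        isi2 = np.diff(s2)[-3:].mean()
        assert abs(isi1 - isi2) / isi2 < 0.01


class TestCAdEx:
    def test_adaptation_inactive_when_gbar_zero(self):
        st = NeuronState(V=-55.0, gA=0.0)
        _, dgA = cadex_derivative(st, CADEX_FS, 0.0)
        assert dgA == 0.0

    def test_half_activation_rate(self):
        p = CAdExParams(gA_bar=4.0)
        st = NeuronState(V=p.VA, gA=0.0)
        _, dgA = cadex_derivative(st, p, 0.0)
        assert dgA == pytest.approx((p.gA_bar / 2.0) / p.tau_A)

    def test_adaptation_current_contribution(self):
        # gA (EA - V) with gA=2 nS, EA=-70, V=EL=-65 contributes -10 pA
        p = CAdExParams(EA=-70.0)
        st = NeuronState(V=p.EL, gA=2.0)
        dV_with, _ = cadex_derivative(st, p, 0.0)
        dV_without, _ = cadex_derivative(NeuronState(V=p.EL, gA=0.0), p, 0.0)
        assert (dV_with - dV_without) * p.C == pytest.approx(-10.0)

    def test_reset_increments_conductance(self):
        out = cadex_reset(NeuronState(V=-40.0, gA=0.0), CADEX_RS)
        assert out.gA == pytest.approx(CADEX_RS.delta_gA)
        again = cadex_reset(NeuronState(V=-40.0, gA=out.gA), CADEX_RS)
        assert again.gA == pytest.approx(2 * CADEX_RS.delta_gA)
        assert again.V == CADEX_RS.VR

    def test_fs_reset_leaves_conductance(self):
        out = cadex_reset(NeuronState(V=-40.0, gA=0.3), CADEX_FS)
        assert out.gA == pytest.approx(0.3)


class TestHH:
    def test_sodium_term_vanishes_at_reversal(self):
        p = HHParams(gL=0.0)
        st = NeuronState(V=p.ENa, n=0.0, m=1.0, h=1.0)
        dV, *_ = hh_derivative(st, p, 0.0)
        assert dV == pytest.approx(0.0)

    def test_rate_functions_removable_singularity(self):
        # alpha_n has a 0/0 point at U = 15 (V = VT_shift + 15); the
        # filled-in value must match evaluation slightly off the pole.
        p = HH_RS
        V_pole = p.VT_shift + 15.0
        (a_n_pole, _), _, _ = hh_rates(V_pole, p)
        (a_n_near, _), _, _ = hh_rates(V_pole + 1e-6, p)
        assert a_n_pole == pytest.approx(0.032 * 5.0, rel=1e-9)
        assert a_n_near == pytest.approx(a_n_pole, rel=1e-5)
        V_pole_m = p.VT_shift + 13.0
        _, (a_m_pole, _), _ = hh_rates(V_pole_m, p)
        _, (a_m_near, _), _ = hh_rates(V_pole_m - 1e-6, p)
        assert a_m_pole == pytest.approx(0.32 * 4.0, rel=1e-9)
        assert a_m_near == pytest.approx(a_m_pole, rel=1e-5)

    def test_resting_state_is_fixed_point(self):
        # Root-find the full RHS (V with steady-state gates) and check the
        # free simulation relaxes there with no input.
        p = HH_RS

        def rhs(V):
            n, m, h = hh_steady_gates(V, p)
            st = NeuronState(V=V, n=n, m=m, h=h)
            return hh_derivative(st, p, 0.0)[0]

        v_star = brentq(rhs, -80.0, -55.0)
        _, V, spikes = simulate_single_neuron("hh", p, 0.0, 300.0, dt=0.01)
        assert spikes.size == 0
        assert V[-1] == pytest.approx(v_star, abs=0.1)

    def test_gates_stay_in_unit_interval_during_spiking(self):
        # Driven 1 s trajectory: all gating variables remain in [0, 1].
        p = HH_RS
        n_steps = 100_000
        dt = 0.01
        from seizprop.neuron_models import NeuronState as NS
        n0, m0, h0 = hh_steady_gates(p.EL, p)
        st = NS(V=p.EL, n=n0, m=m0, h=h0)
        lo = hi = 0.5
        for k in range(n_steps):
            dV, _, _, _ = hh_derivative(st, p, 400.0)
            (a_n, b_n), (a_m, b_m), (a_h, b_h) = hh_rates(st.V, p)

            def ee(x, a, b):
                tot = float(a) + float(b)
                return float(a) / tot + (x - float(a) / tot) * math.exp(-dt * tot)

            st = NS(V=st.V + dt * dV, n=ee(st.n, a_n, b_n),
                    m=ee(st.m, a_m, b_m), h=ee(st.h, a_h, b_h))
            lo = min(lo, st.n, st.m, st.h)
            hi = max(hi, st.n, st.m, st.h)
        assert 0.0 <= lo and hi <= 1.0

    def test_spikes_under_current_with_microsiemens_conductances(self):
        _, V, spikes = simulate_single_neuron("hh", HH_RS, 500.0, 300.0,
                                              dt=0.01)
        assert spikes.size >= 2
        assert V.max() > 0.0

    def test_gating_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            NeuronState(V=-65.0, m=1.5)


class TestDetectSpike:
    def test_adex_ceiling(self):
        assert detect_spike("adex", -50.0, ADEX_RS.VD, ADEX_RS)
        assert not detect_spike("adex", -50.0, ADEX_RS.VD - 1e-9, ADEX_RS)

    def test_hh_upward_crossing_only(self):
        assert detect_spike("hh", -1.0, 5.0, HH_RS)
        assert not detect_spike("hh", 5.0, -1.0, HH_RS)   # downward
        assert not detect_spike("hh", 3.0, 5.0, HH_RS)    # already above


class TestPresetsAndValidation:
    @pytest.mark.parametrize("model,cls", [
        ("adex", "RS"), ("adex", "FS"), ("cadex", "RS"),
        ("cadex", "FS"), ("hh", "RS"), ("hh", "FS"),
    ])
    def test_preset_roundtrip(self, model, cls):
        p = get_preset(model, cls)
        assert params_from_dict(model, params_to_dict(p)) == p

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            AdExParams(C=-1.0)
        with pytest.raises(ValueError):
            AdExParams(VR=-30.0, VD=-40.0)
        with pytest.raises(ValueError):
            CAdExParams(tau_A=0.0)
        with pytest.raises(ValueError):
            HHParams(ENa=-90.0, EK=60.0)

    def test_fs_adex_is_non_adapting(self):
        assert ADEX_FS.a == 0.0 and ADEX_FS.b == 0.0
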