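"""Single-neuron and synapse dynamics against closed-form oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from granlif.lif import (
    EXCITATORY,
    GOC,
    GRC,
    INHIBITORY,
    CellParams,
    NeuronState,
    ReceptorParams,
    apply_spike,
    membrane_update,
    synaptic_current,
    synaptic_decay,
    threshold_and_reset,
)


def one_step_implicit(params: CellParams, vm: float, h: float) -> float:
    """Closed-form backward-Euler step of the passive membrane."""
    hc = h / params.Cm
    return (vm + hc * (params.IE + params.gL * params.EL)) / (1 + hc * params.gL)


class TestMembraneUpdate:
    def test_goc_one_step_matches_closed_form(self):
        st_ = NeuronState(Vm=-75.0)
        v = membrane_update(st_, GOC, I_inj=0.0, h=0.1, scheme="implicit")
        assert v == pytest.approx(one_step_implicit(GOC, -75.0, 0.1), abs=1e-12)
        assert v == pytest.approx(-74.90473, abs=1e-5)

    def test_rest_is_fixed_point(self):
        # GRC has IE = 0 so Vm = EL is invariant for any h and scheme
        for h in (0.01, 0.1, 1.0):
            for scheme in ("implicit", "explicit"):
                st_ = NeuronState(Vm=GRC.EL)
                assert membrane_update(st_, GRC, 0.0, h, scheme=scheme) == pytest.approx(
                    GRC.EL, abs=1e-12
                )

    def test_relaxation_is_monotone_and_bounded(self):
        st_ = NeuronState(Vm=-84.0)
        v = membrane_update(st_, GRC, 0.0, 0.1)
        assert -84.0 < v < -74.0

    @pytest.mark.parametrize("scheme", ["implicit", "explicit"])
    def test_n_steps_converge_to_exact_exponential(self, scheme):
        """Error vs the exact solution shrinks linearly as h halves."""
        t_total, v0 = 10.0, -84.0
        exact = GRC.EL + (v0 - GRC.EL) * math.exp(-t_total / GRC.tau_m)
        errors = []
        for h in (0.1, 0.05, 0.025):
            st_ = NeuronState(Vm=v0)
            for _ in range(int(round(t_total / h))):
                st_.Vm = membrane_update(st_, GRC, 0.0, h, scheme=scheme)
            errors.append(abs(st_.Vm - exact))
        assert errors[0] > errors[1] > errors[2]
        # first-order: halving h about halves the error
        assert errors[1] == pytest.approx(errors[0] / 2, rel=0.25)
        assert errors[2] == pytest.approx(errors[1] / 2, rel=0.25)

    def test_convergence_to_steady_state_is_monotone(self):
        I_inj = 30.0
        v_inf = GRC.EL + (GRC.IE + I_inj) / GRC.gL
        st_ = NeuronState(Vm=-84.0)
        gaps = []
        for _ in range(200):
            st_.Vm = membrane_update(st_, GRC, I_inj, 0.1)
            gaps.append(abs(st_.Vm - v_inf))
        assert all(a > b for a, b in zip(gaps, gaps[1:]))

    def test_nonfinite_state_raises(self):
        with pytest.raises(FloatingPointError):
            membrane_update(NeuronState(Vm=float("nan")), GRC, 0.0, 0.1)
        with pytest.raises(ValueError):
            membrane_update(NeuronState(Vm=-70.0), GRC, 0.0, 0.0)


class TestSynapse:
    def test_decay_example(self):
        assert synaptic_decay(20.0, tau=0.5, h=0.5) == pytest.approx(7.3576, abs=5e-5)

    def test_zero_is_fixed_point(self):
        for h in (0.0, 0.1, 10.0):
            assert synaptic_decay(0.0, 10.0, h) == 0.0

    @given(
        g=st.floats(0, 1e3),
        tau=st.floats(0.1, 50),
        h=st.floats(0.001, 5),
        n=st.integers(1, 20),
    )
    @settings(deadline=None)
    def test_decay_semigroup(self, g, tau, h, n):
        """n steps of h equal one step of n*h (exponential semigroup)."""
        stepped = g
        for _ in range(n):
            stepped = synaptic_decay(stepped, tau, h)
        assert stepped == pytest.approx(synaptic_decay(g, tau, n * h), rel=1e-9, abs=1e-12)

    @given(g=st.floats(0, 1e3), tau=st.floats(0.1, 50), h=st.floats(0, 5))
    @settings(deadline=None)
    def test_decay_never_increases(self, g, tau, h):
        assert synaptic_decay(g, tau, h) <= g

    def test_bad_tau_raises(self):
        with pytest.raises(ValueError):
            synaptic_decay(1.0, tau=0.0, h=0.1)

    @pytest.mark.parametrize(
        "g,w,count,expected",
        [
            (0.0, 20.0, 1, 20.0),  # excitatory bump
            (0.0, -10.0, 1, 10.0),  # inhibitory weight stored as magnitude
            (5.0, 20.0, 2, 45.0),  # two spikes in one bin are additive
        ],
    )
    def test_apply_spike(self, g, w, count, expected):
        assert apply_spike(g, w, count) == expected

    @given(g=st.floats(0, 1e3), w=st.floats(-100, 100))
    @settings(deadline=None)
    def test_apply_spike_never_decreases(self, g, w):
        assert apply_spike(g, w) >= g


class TestSynapticCurrent:
    def test_excitatory_depolarizes(self):
        # one excitatory receptor, g = 20 nS, at Vm = -84 mV
        st_ = NeuronState(Vm=-84.0, receptor_g=np.array([20.0]))
        isyn = synaptic_current(st_, [EXCITATORY])
        assert isyn == pytest.approx(20.0 * (-84.0 - 0.0))  # -1680 pA
        # entering the membrane equation with a minus sign: +1680 pA inward
        assert -isyn == pytest.approx(1680.0)

    def test_all_zero_conductance(self):
        st_ = NeuronState(Vm=-60.0, receptor_g=np.zeros(3))
        assert synaptic_current(st_, [EXCITATORY, EXCITATORY, INHIBITORY]) == 0.0

    def test_inhibitory_reversal_point(self):
        st_ = NeuronState(Vm=-85.0, receptor_g=np.array([10.0]))
        assert synaptic_current(st_, [INHIBITORY]) == pytest.approx(0.0)

    def test_membrane_update_consistent_with_current(self):
        """Explicit scheme equals hand-assembled Eq with receptor current."""
        st_ = NeuronState(Vm=-70.0, receptor_g=np.array([4.0, 2.0]))
        receptors = [EXCITATORY, INHIBITORY]
        v = membrane_update(st_, GRC, 0.0, 0.1, receptors=receptors, scheme="explicit")
        isyn = synaptic_current(st_, receptors)
        expected = -70.0 + 0.1 / GRC.Cm * (
            GRC.IE - GRC.gL * (-70.0 - GRC.EL) - isyn
        )
        assert v == pytest.approx(expected, abs=1e-12)


class TestThresholdReset:
    def test_goc_spike_and_reset(self):
        st_ = NeuronState(Vm=-60.0)
        v, spiked = threshold_and_reset(-54.0, st_, GOC, h=0.1)
        assert (v, spiked) == (-75.0, True)
        assert st_.refractory_remaining == GOC.tref

    def test_below_threshold_passes_through(self):
        st_ = NeuronState(Vm=-60.0)
        assert threshold_and_reset(-60.0, st_, GOC, h=0.1) == (-60.0, False)

    def test_refractory_clamp(self):
        st_ = NeuronState(Vm=-75.0, refractory_remaining=GOC.tref)
        for _ in range(3):
            v, spiked = threshold_and_reset(-10.0, st_, GOC, h=0.1)
            assert (v, spiked) == (GOC.Vinit, False)
        assert st_.refractory_remaining == pytest.approx(GOC.tref - 0.3)


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CellParams(gL=0, EL=-74, IE=0, Cm=3, VTH=-42, Vinit=-84, tref=1.5)
        with pytest.raises(ValueError):
            CellParams(gL=1.5, EL=-74, IE=0, Cm=3, VTH=-90, Vinit=-84, tref=1.5)
        with pytest.raises(ValueError):
            ReceptorParams(Vrev=0, tau=0, w=20)

    def test_grc_is_silent_without_input(self):
        # V_inf = EL = -74 mV lies far below threshold -42 mV
        assert GRC.V_inf < GRC.VTH

    def test_goc_is_a_pacemaker(self):
        assert GOC.V_inf > GOC.VTH


class TestPacemakingLoop:
    """Step the bare primitives and compare against the discrete-map oracle."""

    @staticmethod
    def simulated_isi(params: CellParams, h: float, scheme: str = "implicit") -> float:
        st_ = NeuronState(Vm=params.Vinit)
        spikes = []
        for i in range(int(round(400.0 / h))):
            if st_.in_refractory:
                threshold_and_reset(st_.Vm, st_, params, h)
                continue
            cand = membrane_update(st_, params, 0.0, h, scheme=scheme)
            _, spiked = threshold_and_reset(cand, st_, params, h)
            if spiked:
                spikes.append(i * h)
        assert len(spikes) >= 3
        return spikes[-1] - spikes[-2]

    @staticmethod
    def discrete_isi(params: CellParams, h: float) -> float:
        """Exact crossing step of the backward-Euler map from Vinit to VTH."""
        r = 1.0 / (1.0 + h * params.gL / params.Cm)
        m = math.ceil(
            math.log((params.VTH - params.V_inf) / (params.Vinit - params.V_inf))
            / math.log(r)
        )
        n_clamped = math.ceil(params.tref / h)
        return (m + n_clamped) * h

    @pytest.mark.parametrize("h", [0.1, 0.05])
    def test_goc_isi_matches_discrete_map(self, h):
        assert self.simulated_isi(GOC, h) == pytest.approx(
            self.discrete_isi(GOC, h), abs=h / 2
        )

    def test_grc_never_spikes_without_input(self):
        st_ = NeuronState(Vm=GRC.Vinit)
        for _ in range(10_000):
            cand = membrane_update(st_, GRC, 0.0, 0.1)
            _, spiked = threshold_and_reset(cand, st_, GRC, 0.1)
            assert not spiked
        assert st_.Vm == pytest.approx(GRC.EL, abs=1e-6)
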