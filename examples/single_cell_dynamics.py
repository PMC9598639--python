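"""Single-neuron behavior of the two granular-layer cell types.

Steps the bare LIF primitives: the Golgi cell (GOC) pacemakes under its
intrinsic 36.75 pA drive, the granule cell (GRC) relaxes to its leak
reversal and stays silent.
"""

import numpy as np

from granlif import GOC, GRC, NeuronState, membrane_update, threshold_and_reset
from granlif.metrics import isi_closed_form


def simulate(params, tfin=1000.0, h=0.1):
    state = NeuronState(Vm=params.Vinit)
    spikes = []
    for i in range(int(tfin / h)):
        if state.in_refractory:
            threshold_and_reset(state.Vm, state, params, h)
            continue
        cand = membrane_update(state, params, 0.0, h)
        _, spiked = threshold_and_reset(cand, state, params, h)
        if spiked:
            spikes.append(i * h)
    return np.array(spikes), state.Vm


goc_spikes, _ = simulate(GOC)
isi = np.diff(goc_spikes)
print(f"GOC: {len(goc_spikes)} spikes in 1 s, simulated ISI {isi[-1]:.1f} ms")
print(f"     closed-form ISI {isi_closed_form(GOC):.2f} ms "
      "(tref + tau_m * ln((Vinit-Vinf)/(VTH-Vinf)))")
grc_spikes, vm = simulate(GRC)
print(f"GRC: {len(grc_spikes)} spikes; Vm settled at {vm:.2f} mV (= EL, below "
      f"threshold {GRC.VTH:.0f} mV, so the cell is silent without input)")
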