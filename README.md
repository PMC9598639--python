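# granlif

A conductance-based leaky integrate-and-fire (LIF) simulator of the
cerebellar granular layer, for computational neuroscientists who want a
reproducible, rule-based reconstruction of the granule-cell / Golgi-cell
microcircuit together with a deterministic, clock-driven spiking engine.

## The model

**Cells.** Two LIF populations: granule cells (GRC) and Golgi cells
(GOC). The subthreshold membrane follows

```
Cm dVm/dt = IE + I_inj − gL (Vm − EL) − Σ_k g_k (Vm − Vrev_k)
```

with a hard threshold: when `Vm ≥ VTH` the cell spikes, `Vm` resets to
`Vinit` and is clamped there for the refractory period `tref`. Each
synaptic receptor carries a conductance that jumps by `|w|` per incoming
spike and decays as `g(t+h) = g(t)·exp(−h/τ)`; polarity lives in the
reversal potential (0 mV excitatory, −85 mV inhibitory). The GOC's
intrinsic current (`IE = 36.75 pA`) makes it a natural pacemaker with

```
ISI = tref + (Cm/gL) · ln((Vinit − V∞)/(VTH − V∞)) ≈ 98.6 ms,
V∞ = EL + IE/gL
```

while the GRC (`IE = 0`) is silent without mossy-fiber input. Integration
is one-step backward Euler by default (forward Euler selectable), with
conductances held explicit over the step.

**Network.** Cells and glomeruli (GLO) are placed uniformly in a 3D box
at densities that reproduce the reference geometries (a 300×75×1200 μm³
slab holds 108,000 GRCs, 243 GOCs, 8,100 GLOs) and wired by anatomical
rules: 4 dendrites per GRC to distinct GLOs within 40 μm, ≤53 dendrites
per GLO, 50 GLOs per GOC dendritic tree, ≤40 GLOs per GOC axon with no
GRC inhibited twice by the same GOC, and 400 ascending-axon plus 1000
parallel-fiber GRC inputs per GOC. Every build returns an audit of the
emergent statistics.

**Engine.** Per-receptor spike queues hold future arrival times in
ascending order; each step collects the arrivals of the current bin,
batch-updates GOCs, routes their spikes (with per-connection propagation
delays, Uniform(0.1, 1) ms) to GRC inhibitory queues, then updates GRCs
and routes their spikes back to GOCs. Routing happens at serial barriers
in neuron-id order, so a partitioned run (populations split into blocks)
reproduces the monolithic raster bit for bit.

## Worked example

```python
from granlif import build_network, make_protocol, run
from granlif.io import NETWORK_PRESETS

net = build_network(NETWORK_PRESETS["tiny"], seed=11)   # 60×60×120 μm³
trains, _ = make_protocol("prot1", net.counts.n_mf, tfin=2000.0, seed=4)
res = run(net, trains, tfin=2000.0, h=0.1)
print(res.summary)
```

prints (see `examples/run_simulation.py`):

```
7852 spikes in 2 s
mean rates: GOC 18.0 Hz, GRC 2.23 Hz
partitioned (2 blocks) raster identical: True
```

The four GOCs pacemake continuously — their intrinsic drive alone gives
~10 Hz, and network excitation raises the mean to 18 Hz — while the
1,728 GRCs average 2.2 Hz, firing only around the sparse 1 Hz
mossy-fiber background events. `examples/` holds one short script per
capability (single-cell dynamics, network reconstruction and audit,
stimulation protocols, a full simulation, memory footprint), each
printing the numbers it computes.

## Memory footprint

Each cell stores 7 single-precision parameters plus 4 per receptor and a
4-byte arrival flag per receptor: 188 B per GRC (8 receptors) and 88 B
per GOC (3 receptors), so a network occupies `88·N_GOC + 188·N_GRC`
bytes — 77.53 MiB for the 600×150×1200 μm³ geometry, 310.14 MiB for
1200×300×1200 μm³ (`examples/memory_footprint.py`).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

rebuilds two networks from scratch and reports the measured connectivity
statistics: the mean number of GRC dendrites converging on one
glomerulus in the fully built 300×75×1200 μm³ geometry (rounded to the
nearest integer), and the per-GRC count of distinct glomerular targets
in the 60×60×120 μm³ test preset. Runs in well under a minute.

## Layout

- `src/granlif/lif.py` — cell/receptor parameters and one-step dynamics
- `src/granlif/network.py` — placement, wiring rules, audit
- `src/granlif/stimulus.py` — Poisson/burst mossy-fiber protocols
- `src/granlif/engine.py` — spike queues, the step loop, partitioned runs
- `src/granlif/metrics.py` — memory model, rates, ISI closed form
- `src/granlif/io.py` — YAML config, presets, lossless TSV round-trips
- `docs/methods.md` — modeling and numerical choices in detail
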