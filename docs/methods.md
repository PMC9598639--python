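# Methods

## Model

The granular layer is modeled as two point-neuron LIF populations —
granule cells (GRC) and Golgi cells (GOC) — coupled through glomeruli
(GLO), with mossy fibers (MF) as the only external input. The membrane
obeys

    Cm dVm/dt = IE + I_inj − gL (Vm − EL) − Σ_k g_k (Vm − Vrev_k)

with threshold/reset (`Vm ≥ VTH` → spike, reset to `Vinit`, clamp for
`tref`). Parameters (units: mV, ms, nS, pF, pA — a self-consistent set,
so no conversions appear in the code):

| parameter | GRC | GOC |
|---|---|---|
| gL (nS) | 1.5 | 3.6 |
| EL (mV) | −74 | −65 |
| IE (pA) | 0 | 36.75 |
| Cm (pF) | 3 | 76 |
| VTH (mV) | −42 | −55 |
| Vinit (mV) | −84 | −75 |
| tref (ms) | 1.5 | 2 |

Receptors: excitatory `Vrev = 0 mV, τ = 0.5 ms, w = 20 nS`; inhibitory
`Vrev = −85 mV, τ = 10 ms, w = 10 nS` (weights are stored as magnitudes;
polarity is carried entirely by the reversal potential, which is the
standard conductance-synapse formulation and the only reading under
which excitation depolarizes and inhibition hyperpolarizes). A GRC has
4 excitatory + 4 inhibitory receptor slots — one pair per dendrite, so
inhibition from a shared glomerulus targets the matching slot — and a
GOC has 2 excitatory (slot 0: glomerular/MF input, slot 1: GRC input)
plus 1 inhibitory slot, unconnected by default because nothing in the
modeled circuit inhibits Golgi cells.

With these constants the GOC is a pacemaker: `V∞ = EL + IE/gL =
−54.79 mV` exceeds threshold, giving the closed-form interval

    ISI = tref + (Cm/gL) ln((Vinit − V∞)/(VTH − V∞)) = 98.58 ms.

The GRC relaxes to `EL = −74 mV` and never fires unaided. (Note the
reset value `Vinit = −84 mV` is *below* `EL`, so the "resting" level an
undriven GRC maintains is EL, not Vinit; the equations are implemented
as stated and this is simply what they imply.)

## Numerics

- **Integration.** One-step backward (implicit) Euler by default:
  conductances are frozen over the step, making the ODE linear, and the
  voltage-dependent terms are evaluated at `t+h`:

      V' = (V + (h/Cm)(IE + I_inj + gL·EL + Σ g_k·Vrev_k))
           / (1 + (h/Cm)(gL + Σ g_k))

  This is unconditionally stable (relevant because an excited GRC's
  effective time constant drops to Cm/(gL+g) ≈ 0.14 ms, comparable to
  h). Forward Euler is available via `scheme="explicit"`.
- **Step size.** Default `h = 0.1 ms`, configurable. Both schemes are
  first-order: halving h halves the error against the exact exponential
  solution (asserted in the tests).
- **Pacemaking accuracy.** One-step Euler carries a threshold-crossing
  bias of `t_rise·gL·h/(2Cm) ≈ 2.3h` for the GOC constants (t_rise =
  96.6 ms of subthreshold integration), plus up to one step of threshold
  quantization: at h = 0.1 ms the simulated ISI is 98.9 ms vs the
  98.58 ms closed form. The error is O(h) and the tests validate the
  engine against the exact crossing time of the discrete map, which it
  matches to the step.
- **Ordering within a step.** Arriving spikes increment conductances
  first, the membrane then updates using those conductances, and decay
  `g ← g·e^{−h/τ}` is applied last. The printed decay law's exponent is
  interpreted per elapsed step (e^{−h/τ}); an absolute-time exponent
  would make decay non-stationary and contradict decay-to-zero.
- **Refractory semantics.** Only the potential is clamped at `Vinit`;
  conductances keep decaying and arriving spikes still increment them.
  The spike step arms the clamp (`tref`), and the clamp occupies the
  following `ceil(tref/h)` steps.
- **Threshold uses `≥ VTH` exactly.**

## Network reconstruction

Densities are reverse-derived from the reference geometries: ρ_GRC =
4.0×10⁻³, ρ_GOC = 9.0×10⁻⁶, ρ_GLO = 3.0×10⁻⁴ μm⁻³, and one MF per 20
GLOs (counts: `round(ρV)`; MFs: `ceil(n_glo/20)`). Placement is uniform
random — soma-exclusion zones and realistic dendritic geometry are out
of scope. Wiring, in order, with every stage seeded from a spawned
stream of the root seed:

1. **GRC dendrites**: each GRC picks 4 distinct GLOs uniformly among
   those within 40 μm whose load is below 53. GRCs are processed in a
   seeded random order. If fewer than 4 GLOs exist in range *at all*,
   the radius relaxes in +10 μm increments (logged). If in-range GLOs
   exist but are full, the remainder goes to the least-loaded in-range
   GLOs ("capacity overflow", counted in the audit). The overflow is
   unavoidable arithmetic, not an implementation choice: the mean load
   is 4·ρ_GRC/ρ_GLO = 53.33 dendrites per GLO, which no hard cap of 53
   can accommodate; preferring least-loaded neighbors keeps the maximum
   load at 54–57 in practice while keeping dendrites local, which is
   the anatomical point of the 40 μm rule.
2. **MF assignment**: GLOs are partitioned over MFs round-robin after a
   seeded shuffle, so MF loads differ by at most one.
3. **GOC dendrites**: 50 distinct GLOs per GOC within a 100 μm radius
   (a geometric default, relaxed like the dendrite rule). The number of
   distinct MFs this implies (~47 on the large geometry with 405 MFs —
   the occupancy expectation `n_mf(1−(1−1/n_mf)^50)`) is an audit
   statistic, not a constraint.
4. **GOC axon**: up to 40 distinct GLOs per GOC within 150 μm; each
   expands to inhibitory edges onto every GRC with a dendrite there, on
   the inhibitory slot paired with that dendrite; duplicate (GOC, GRC)
   pairs keep the first expansion. Fewer than 40 reachable GLOs is
   legal (the rule is a cap).
5. **GRC → GOC excitation**: 400 ascending-axon sources from a vertical
   column (lateral distance ≤ 50 μm in the x–z plane; y is the
   layer-thickness axis) and 1000 parallel-fiber sources volume-wide,
   distinct within each pathway, clipped with a warning when the volume
   holds fewer GRCs.

Propagation delays are Uniform(0.1, 1.0) ms per connection, drawn once
at build time (per-event resampling is available in the engine). MF
excitation is delivered through the GLO mapping at the MF spike time
itself — dendritic and GLO→GOC edges carry no delay of their own.

Hard invariants (validated before a network is returned): exactly 4
distinct GLOs per GRC, no duplicate (GRC, GLO) or (GOC, GRC) pairs,
≤ 40 GLOs per GOC axon, exactly 50 GLOs per GOC dendritic tree,
distinct-within-pathway aa/pf sources.

## Stimulation protocols

All four protocols are built from homogeneous Poisson processes with
independent per-MF streams: Prot1 = 1 Hz background on all MFs; Prot2 =
100 Hz burst for 50 ms on 10% of MFs (burst only); Prot3 = background +
burst on all MFs; Prot4 = background + burst on 1%. Percentages round
to the nearest count with a floor of one. Burst onset defaults to
200 ms (not anatomically meaningful; configurable). The burst is
Poisson (≈5 expected spikes per 50 ms window) with a regular-train mode
available. Merged background+burst trains stay strictly ascending —
coincident times are perturbed forward by 10⁻⁴ ms.

## Engine

Pending arrivals live in one ascending queue per (neuron, receptor
slot), indexed by a global min-heap so a step touches only queues that
deliver; an arrival is consumed exactly once when its time stamp falls
in the half-open bin [t, t+h), and multiple arrivals in one bin bump the
conductance by `count·|w|`. Each step: collect GOC flags → batch-update
GOCs → route GOC spikes (serial barrier, ascending neuron id) → collect
GRC flags → batch-update GRCs → route GRC spikes. Spike times are
recorded at the step start t; arrivals are scheduled at t + delay, and
since min delay = h no same-step causality loop is possible.
`run_partitioned(n)` splits each population into n contiguous blocks
updated independently between the barriers; because the per-row
arithmetic is identical and routing order is global, its raster equals
the monolithic run's exactly (asserted for n ∈ {1, 2, 4}).

## Memory model

Per cell: (7 + 4·n_receptors) single-precision values plus a 4-byte
flag per receptor → 156+32 = 188 B per GRC, 76+12 = 88 B per GOC, and `88·N_GOC + 188·N_GRC` bytes per network. Reported MiB values
are truncated (not rounded) to two decimals, which is the convention the
reference figures follow (77.53 and 310.14 MiB for the two larger
geometries). The smallest geometry evaluates to 19.38 MiB.

## What the synthetic world does and does not establish

The generator emulates the *stated* anatomy: densities, ratios, and
ranges above, with uniform placement and uniform candidate sampling. It
does not emulate soma exclusion, lamination, dendrite morphology,
synaptic plasticity, or non-homogeneous inputs. A green test therefore
establishes that the wiring rules, dynamics, scheduling and bookkeeping
are implemented to specification — not that the emergent rates match
biological recordings, beyond the qualitative behaviors (GOC pacemaking
near 10 Hz, GRC silence without input, excitatory bursts and
instantaneous inhibitory dips).

## Known limitations

- The 53-dendrite GLO cap conflicts arithmetically with the stated
  densities (mean 53.33); overflow is audited rather than hidden.
- ISI accuracy is first-order in h with a ≈2.3-step crossing bias; an
  exponential integrator would remove it but is outside the modeled
  scheme.
- GPU execution, asynchronous streams, and wall-clock performance are
  not modeled; the partitioned mode reproduces the *semantics* of a
  multi-device split, not its timing.
- Golgi-cell inhibitory input exists as a receptor slot but has no
  anatomical source in this circuit and is never wired by the builder.
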