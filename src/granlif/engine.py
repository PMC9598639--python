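"""Clock-driven simulation loop for the reconstructed granular layer.

Each step of size ``h`` does, in order:

1. collect the Golgi-cell (GOC) flag counts — spike arrivals whose queued
   time stamp falls in the current bin [t, t+h) — and batch-update all
   GOC membranes;
2. route every GOC spike to its granule-cell (GRC) inhibitory receptor
   queues at ``t + delay``;
3. collect the GRC flags (mossy-fiber excitation delivered through the
   glomerulus mapping, plus the inhibitory queues) and batch-update all
   GRCs;
4. route every GRC spike to its target GOC excitatory queues.

Spikes generated in a step are routed in (population, neuron id) order at
an explicit serial barrier, so a partitioned run — populations split into
contiguous blocks updated independently within a step — reproduces the
monolithic run bit for bit.  Per-edge propagation delays are fixed at
build time and are at least one step, so no same-step causality loop can
occur.

Pending arrivals live in :class:`SpikeQueueSet`: one ascending queue per
(neuron, receptor slot), indexed by a global min-heap so a step only
touches queues that actually deliver.
"""

from __future__ import annotations

import heapq
from bisect import insort
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from granlif.lif import (
    EXCITATORY,
    GOC,
    GOC_LAYOUT,
    GRC,
    GRC_LAYOUT,
    INHIBITORY,
    CellParams,
    ReceptorLayout,
    ReceptorParams,
)
from granlif.network import Network
from granlif.stimulus import SpikeTrain

__all__ = [
    "SpikeQueueSet",
    "schedule",
    "collect_flags",
    "Simulation",
    "SimulationResult",
    "run",
    "run_partitioned",
]


class SpikeQueueSet:
    """Pending spike arrivals for one population.

    One ascending queue per (neuron, receptor slot); ``schedule`` inserts
    preserving order, ``collect`` consumes every arrival in the current
    time bin exactly once.  Scheduling into the past raises (causality).
    """

    def __init__(self, n_neurons: int, n_slots: int):
        self.n_neurons = n_neurons
        self.n_slots = n_slots
        self._pending: dict[tuple[int, int], list[float]] = {}
        self._heap: list[tuple[float, int, int]] = []
        self.now = 0.0
        self.n_scheduled = 0
        self.n_consumed = 0

    def schedule(self, neuron: int, slot: int, t_arrival: float) -> None:
        if t_arrival < self.now:
            raise ValueError(
                f"causality violation: arrival {t_arrival} ms scheduled at "
                f"t={self.now} ms"
            )
        if not (0 <= neuron < self.n_neurons and 0 <= slot < self.n_slots):
            raise IndexError(f"no queue for neuron {neuron}, slot {slot}")
        key = (neuron, slot)
        q = self._pending.get(key)
        if q is None:
            self._pending[key] = [t_arrival]
        else:
            insort(q, t_arrival)
        heapq.heappush(self._heap, (t_arrival, neuron, slot))
        self.n_scheduled += 1

    def queue(self, neuron: int, slot: int) -> tuple[float, ...]:
        """Snapshot of one queue's pending arrival times (ascending)."""
        return tuple(self._pending.get((neuron, slot), ()))

    @property
    def n_pending(self) -> int:
        return len(self._heap)

    def collect(self, t: float, h: float, counts: np.ndarray | None = None) -> np.ndarray:
        """Consume all arrivals in [t, t+h); return per-slot spike counts.

        ``counts`` may be a reusable (n_neurons, n_slots) int array; it is
        zeroed and filled in place.
        """
        if not h > 0:
            raise ValueError(f"bin width h must be positive, got {h}")
        self.now = t
        if counts is None:
            counts = np.zeros((self.n_neurons, self.n_slots), dtype=np.int64)
        else:
            counts.fill(0)
        t_hi = t + h
        heap = self._heap
        while heap and heap[0][0] < t_hi:
            ta, neuron, slot = heapq.heappop(heap)
            q = self._pending[(neuron, slot)]
            q.pop(0)  # ta is this queue's head by heap/queue consistency
            counts[neuron, slot] += 1
            self.n_consumed += 1
        return counts


def schedule(queue_set: SpikeQueueSet, neuron: int, slot: int, t_arrival: float) -> SpikeQueueSet:
    """Functional wrapper around :meth:`SpikeQueueSet.schedule`."""
    queue_set.schedule(neuron, slot, t_arrival)
    return queue_set


def collect_flags(queue_set: SpikeQueueSet, t: float, h: float) -> np.ndarray:
    """Per-(neuron, slot) spike counts for the bin [t, t+h); consumes them."""
    return queue_set.collect(t, h)


@dataclass
class SimulationResult:
    """Raster, optional membrane traces and per-population summary rates."""

    raster: pd.DataFrame  # columns: time_ms, population, neuron_id
    traces: dict[tuple[str, int], np.ndarray]
    trace_times: np.ndarray
    summary: dict[str, float]  # population -> mean rate (Hz)
    tfin: float
    h: float


class _PopState:
    """Vectorized state and parameters of one population."""

    def __init__(
        self,
        name: str,
        n: int,
        params: CellParams,
        layout: ReceptorLayout,
        exc: ReceptorParams,
        inh: ReceptorParams,
        h: float,
    ):
        self.name = name
        self.n = n
        self.params = params
        self.layout = layout
        receptors = layout.receptors(exc, inh)
        self.vrev = np.array([r.Vrev for r in receptors])
        self.w = np.array([abs(r.w) for r in receptors])
        self.decay = np.array([np.exp(-h / r.tau) for r in receptors])
        self.vm = np.full(n, params.Vinit, dtype=float)
        self.ref = np.zeros(n, dtype=float)
        self.g = np.tile(
            np.array([abs(r.g0) for r in receptors], dtype=float), (n, 1)
        )
        self.queues = SpikeQueueSet(n, layout.n_receptors)
        self.counts = np.zeros((n, layout.n_receptors), dtype=np.int64)
        self.n_spikes = 0

    def update_block(self, lo: int, hi: int, h: float, scheme: str, spiked: np.ndarray) -> None:
        """Advance neurons [lo, hi): spike bumps, membrane step, threshold."""
        p = self.params
        sl = slice(lo, hi)
        g = self.g[sl]
        g += self.counts[sl] * self.w
        vm = self.vm[sl]
        hc = h / p.Cm
        gsum = g.sum(axis=1)
        gv = (g * self.vrev).sum(axis=1)  # row-wise; bit-identical under any row split
        if scheme == "implicit":
            cand = (vm + hc * (p.IE + p.gL * p.EL + gv)) / (
                1.0 + hc * (p.gL + gsum)
            )
        elif scheme == "explicit":
            cand = vm + hc * (p.IE - p.gL * (vm - p.EL) - (gsum * vm - gv))
        else:
            raise ValueError(f"unknown integration scheme {scheme!r}")
        ref = self.ref[sl]
        clamped = ref > 0.0
        fired = ~clamped & (cand >= p.VTH)
        vm[:] = np.where(clamped | fired, p.Vinit, cand)
        ref[clamped] = np.maximum(0.0, ref[clamped] - h)
        ref[fired] = p.tref
        g *= self.decay
        spiked[sl] = fired


def _csr(group_ids: np.ndarray, n_groups: int, order: np.ndarray) -> np.ndarray:
    """indptr for rows sorted by group (rows already ordered by ``order``)."""
    counts = np.bincount(group_ids[order], minlength=n_groups)
    return np.concatenate([[0], np.cumsum(counts)])


class Simulation:
    """A granular-layer network ready to step through time.

    Parameters
    ----------
    network : Network
        The wired network; its per-edge delays are used as propagation
        times (optionally resampled per event, see ``resample_delays``).
    mf_trains : list of SpikeTrain
        One train per mossy fiber; arrivals are delivered to every GRC
        dendrite and GOC dendrite reached through the fiber's glomeruli.
    h : float
        Integration step in ms.
    scheme : {'implicit', 'explicit'}
        One-step integration scheme for the membrane ODE.
    record : sequence of (population, neuron_id)
        Membrane potentials to record each step.
    resample_delays : None or (lo, hi)
        If given, each spike event draws a fresh Uniform(lo, hi) delay
        instead of reusing the per-connection build-time delay.
    """

    def __init__(
        self,
        network: Network,
        mf_trains: list[SpikeTrain],
        h: float = 0.1,
        scheme: str = "implicit",
        grc_params: CellParams = GRC,
        goc_params: CellParams = GOC,
        exc: ReceptorParams = EXCITATORY,
        inh: ReceptorParams = INHIBITORY,
        record: list[tuple[str, int]] | None = None,
        resample_delays: tuple[float, float] | None = None,
        seed: int = 0,
    ):
        if not h > 0:
            raise ValueError(f"timestep h must be positive, got {h}")
        self.network = network
        self.h = h
        self.scheme = scheme
        self.t = 0.0
        self.step_index = 0
        counts = network.counts
        self.grc = _PopState("grc", counts.n_grc, grc_params, GRC_LAYOUT, exc, inh, h)
        self.goc = _PopState("goc", counts.n_goc, goc_params, GOC_LAYOUT, exc, inh, h)
        self._resample = resample_delays
        self._rng = np.random.default_rng(seed)
        self._record_keys = [(p, int(i)) for p, i in (record or [])]
        self._trace: dict[tuple[str, int], list[float]] = {
            k: [] for k in self._record_keys
        }
        self._trace_t: list[float] = []
        self._raster_t: list[float] = []
        self._raster_pop: list[str] = []
        self._raster_id: list[int] = []

        # GOC -> GRC inhibition, CSR by source GOC, targets in GRC id order
        inh_df = network.goc_grc_inh.sort_values(["goc", "grc"], kind="stable")
        self._inh_order = inh_df.index.to_numpy()
        self._inh_grc = inh_df["grc"].to_numpy()
        # absolute slot: inhibitory block follows the excitatory block
        self._inh_slot = inh_df["slot"].to_numpy() + GRC_LAYOUT.n_excitatory
        self._inh_delay = inh_df["delay"].to_numpy()
        cnt = np.bincount(inh_df["goc"].to_numpy(), minlength=counts.n_goc)
        self._inh_ptr = np.concatenate([[0], np.cumsum(cnt)])

        # GRC -> GOC excitation (slot 1), CSR by source GRC
        exc_df = network.grc_goc_exc.sort_values(["grc", "goc"], kind="stable")
        self._exc_goc = exc_df["goc"].to_numpy()
        self._exc_delay = exc_df["delay"].to_numpy()
        cnt = np.bincount(exc_df["grc"].to_numpy(), minlength=counts.n_grc)
        self._exc_ptr = np.concatenate([[0], np.cumsum(cnt)])

        self._load_mf_trains(mf_trains)

    # -- mossy-fiber delivery through the glomerulus mapping ------------

    def _load_mf_trains(self, mf_trains: list[SpikeTrain]) -> None:
        net = self.network
        n_mf = net.counts.n_mf
        if len(mf_trains) != n_mf:
            raise ValueError(f"expected {n_mf} MF trains, got {len(mf_trains)}")
        glos_of_mf: list[list[int]] = [[] for _ in range(n_mf)]
        for glo, mf in enumerate(net.glo_to_mf):
            glos_of_mf[mf].append(glo)
        # per-GLO fanout
        grc_by_glo: dict[int, list[tuple[int, int]]] = {}
        for row in net.grc_glo.itertuples(index=False):
            grc_by_glo.setdefault(row.glo, []).append((row.grc, row.slot))
        goc_by_glo: dict[int, list[int]] = {}
        for row in net.glo_goc.itertuples(index=False):
            goc_by_glo.setdefault(row.glo, []).append(row.goc)
        for mf, train in enumerate(mf_trains):
            for s in train.times:
                for glo in glos_of_mf[mf]:
                    for grc_id, slot in grc_by_glo.get(glo, ()):
                        self.grc.queues.schedule(grc_id, slot, float(s))
                    for goc_id in goc_by_glo.get(glo, ()):
                        self.goc.queues.schedule(goc_id, 0, float(s))

    # -- one step of the main loop --------------------------------------

    def _route(self, out_queues: SpikeQueueSet, ptr, targets, slots, delays, spiking_ids) -> None:
        t = self.t
        if self._resample is not None:
            lo, hi = self._resample
        for i in spiking_ids:
            a, b = ptr[i], ptr[i + 1]
            if self._resample is not None:
                dly = self._rng.uniform(lo, hi, size=b - a)
            else:
                dly = delays[a:b]
            slot_arr = slots[a:b] if slots is not None else None
            for j in range(b - a):
                slot = int(slot_arr[j]) if slot_arr is not None else 1
                out_queues.schedule(int(targets[a + j]), slot, t + float(dly[j]))

    def step(self, blocks: list[tuple[int, int]] | None = None) -> dict[str, np.ndarray]:
        """Advance the network by one step; returns spiking neuron masks.

        ``blocks`` optionally lists fractional (start, stop) block bounds
        used by the partitioned runner; ``None`` means one block per
        population.
        """
        t, h = self.t, self.h
        # (1) GOC flags + batch update  -------------------------- barrier
        self.goc.queues.collect(t, h, self.goc.counts)
        goc_spiked = np.zeros(self.goc.n, dtype=bool)
        for lo, hi in self._blocks(self.goc.n, blocks):
            self.goc.update_block(lo, hi, h, self.scheme, goc_spiked)
        # (2) serial routing barrier: GOC spikes -> GRC inhibitory queues
        goc_ids = np.flatnonzero(goc_spiked)
        self.goc.n_spikes += goc_ids.size
        self._route(
            self.grc.queues,
            self._inh_ptr,
            self._inh_grc,
            self._inh_slot,
            self._inh_delay,
            goc_ids,
        )
        # (3) GRC flags + batch update  -------------------------- barrier
        self.grc.queues.collect(t, h, self.grc.counts)
        grc_spiked = np.zeros(self.grc.n, dtype=bool)
        for lo, hi in self._blocks(self.grc.n, blocks):
            self.grc.update_block(lo, hi, h, self.scheme, grc_spiked)
        # (4) serial routing barrier: GRC spikes -> GOC excitatory queues
        grc_ids = np.flatnonzero(grc_spiked)
        self.grc.n_spikes += grc_ids.size
        self._route(
            self.goc.queues,
            self._exc_ptr,
            self._exc_goc,
            None,
            self._exc_delay,
            grc_ids,
        )
        # recording
        for i in goc_ids:
            self._raster_t.append(t)
            self._raster_pop.append("goc")
            self._raster_id.append(int(i))
        for i in grc_ids:
            self._raster_t.append(t)
            self._raster_pop.append("grc")
            self._raster_id.append(int(i))
        if self._record_keys:
            self._trace_t.append(t + h)
            for key in self._record_keys:
                pop = self.grc if key[0] == "grc" else self.goc
                self._trace[key].append(float(pop.vm[key[1]]))
        self.t = round((self.step_index + 1) * h, 10)
        self.step_index += 1
        return {"goc": goc_spiked, "grc": grc_spiked}

    @staticmethod
    def _blocks(n: int, blocks: list[tuple[int, int]] | None) -> list[tuple[int, int]]:
        if blocks is None:
            return [(0, n)]
        out = []
        n_parts = len(blocks)
        if n_parts > n:
            raise ValueError(f"cannot split {n} neurons into {n_parts} parts")
        bounds = np.linspace(0, n, n_parts + 1).astype(int)
        return [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]

    def result(self) -> SimulationResult:
        tfin = self.t
        raster = pd.DataFrame(
            {
                "time_ms": np.array(self._raster_t, dtype=float),
                "population": self._raster_pop,
                "neuron_id": np.array(self._raster_id, dtype=np.int64),
            }
        )
        summary = {}
        for pop in (self.goc, self.grc):
            duration_s = tfin / 1000.0 if tfin > 0 else np.nan
            summary[pop.name] = (
                pop.n_spikes / pop.n / duration_s if tfin > 0 and pop.n else 0.0
            )
        traces = {k: np.array(v) for k, v in self._trace.items()}
        return SimulationResult(
            raster=raster,
            traces=traces,
            trace_times=np.array(self._trace_t),
            summary=summary,
            tfin=tfin,
            h=self.h,
        )

    @property
    def pending_spikes(self) -> int:
        return self.goc.queues.n_pending + self.grc.queues.n_pending

    @property
    def conservation(self) -> dict[str, int]:
        """Scheduled = consumed + pending, per population."""
        return {
            pop.name: pop.queues.n_scheduled
            - pop.queues.n_consumed
            - pop.queues.n_pending
            for pop in (self.goc, self.grc)
        }


def _n_steps(tfin: float, h: float) -> int:
    return int(np.ceil(tfin / h - 1e-9))


def run(
    network: Network,
    mf_trains: list[SpikeTrain],
    tfin: float,
    h: float = 0.1,
    seed: int = 0,
    record: list[tuple[str, int]] | None = None,
    scheme: str = "implicit",
    **kwargs,
) -> SimulationResult:
    """Simulate ``tfin`` ms of network activity and return the result."""
    if tfin < 0:
        raise ValueError(f"tfin must be non-negative, got {tfin}")
    sim = Simulation(
        network, mf_trains, h=h, scheme=scheme, record=record, seed=seed, **kwargs
    )
    for _ in range(_n_steps(tfin, h)):
        sim.step()
    return sim.result()


def run_partitioned(
    network: Network,
    mf_trains: list[SpikeTrain],
    tfin: float,
    n_parts: int,
    h: float = 0.1,
    seed: int = 0,
    record: list[tuple[str, int]] | None = None,
    scheme: str = "implicit",
    **kwargs,
) -> SimulationResult:
    """Like :func:`run`, with each population split into ``n_parts``
    contiguous blocks updated independently between the serial routing
    barriers.  The raster equals the monolithic run's exactly.
    """
    if n_parts < 1:
        raise ValueError(f"n_parts must be >= 1, got {n_parts}")
    counts = network.counts
    if n_parts > min(counts.n_goc, counts.n_grc):
        raise ValueError(
            f"n_parts={n_parts} exceeds a population size "
            f"({counts.n_goc} GOCs, {counts.n_grc} GRCs)"
        )
    sim = Simulation(
        network, mf_trains, h=h, scheme=scheme, record=record, seed=seed, **kwargs
    )
    blocks = [(0, 0)] * n_parts  # marker list; real bounds computed per pop
    for _ in range(_n_steps(tfin, h)):
        sim.step(blocks=blocks)
    return sim.result()
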