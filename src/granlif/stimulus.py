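"""Mossy-fiber stimulation protocols.

Four standard protocols drive the network through its mossy fibers:

==========  =========================================================
Prot1       1 Hz Poisson background on every MF
Prot2       100 Hz Poisson burst for 50 ms on 10% of the MFs
Prot3       background on all MFs + burst on all MFs (stress test)
Prot4       background on all MFs + burst on 1% of the MFs
==========  =========================================================

Bursts are Poisson at the burst rate (about 5 expected spikes in a
50 ms / 100 Hz window), not regular trains; a regular mode is available.
Every MF gets an independent random stream spawned from the protocol
seed, so spike times differ across MFs even at equal rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ProtocolSpec",
    "SpikeTrain",
    "PROTOCOLS",
    "poisson_train",
    "regular_train",
    "merge_trains",
    "make_protocol",
]

#: spacing inserted between coincident spike times when merging (ms)
MERGE_EPS = 1e-4


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly ascending spike times in ms."""

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size and not np.all(np.diff(t) > 0):
            raise ValueError("spike times must be strictly ascending")

    def __len__(self) -> int:
        return self.times.size

    def rate(self, duration_ms: float) -> float:
        """Mean firing rate in Hz over ``duration_ms``."""
        return len(self) / duration_ms * 1000.0


@dataclass(frozen=True)
class ProtocolSpec:
    """Parameters of one MF stimulation protocol.

    ``burst_fraction`` is the fraction of MFs receiving the burst,
    rounded to the nearest integer count with a floor of one whenever the
    fraction is positive.
    """

    protocol_id: str
    background_rate: float = 0.0  # Hz
    burst_rate: float = 0.0  # Hz
    burst_duration: float = 0.0  # ms
    burst_fraction: float = 0.0
    burst_onset: float = 200.0  # ms
    regular_burst: bool = False

    def __post_init__(self) -> None:
        if self.background_rate < 0 or self.burst_rate < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.burst_fraction <= 1.0:
            raise ValueError("burst_fraction must lie in [0, 1]")
        if self.burst_duration < 0:
            raise ValueError("burst_duration must be non-negative")


PROTOCOLS: dict[str, ProtocolSpec] = {
    "prot1": ProtocolSpec("prot1", background_rate=1.0),
    "prot2": ProtocolSpec(
        "prot2", burst_rate=100.0, burst_duration=50.0, burst_fraction=0.10
    ),
    "prot3": ProtocolSpec(
        "prot3",
        background_rate=1.0,
        burst_rate=100.0,
        burst_duration=50.0,
        burst_fraction=1.0,
    ),
    "prot4": ProtocolSpec(
        "prot4",
        background_rate=1.0,
        burst_rate=100.0,
        burst_duration=50.0,
        burst_fraction=0.01,
    ),
}


def poisson_train(
    rate: float, t0: float, t1: float, rng: np.random.Generator | int
) -> SpikeTrain:
    """Homogeneous Poisson spike train at ``rate`` Hz on [t0, t1) ms."""
    if t1 < t0:
        raise ValueError(f"need t1 >= t0, got [{t0}, {t1})")
    if rate < 0:
        raise ValueError(f"rate must be non-negative, got {rate}")
    if rate == 0 or t1 == t0:
        return SpikeTrain(np.empty(0))
    rng = np.random.default_rng(rng)
    mean_isi_ms = 1000.0 / rate
    # draw exponential gaps until past t1; chunked for speed
    times = []
    t = t0
    while True:
        gaps = rng.exponential(mean_isi_ms, size=max(16, int((t1 - t) / mean_isi_ms * 2) + 8))
        arr = t + np.cumsum(gaps)
        inside = arr[arr < t1]
        times.append(inside)
        if inside.size < arr.size:
            break
        t = arr[-1]
    return SpikeTrain(np.concatenate(times))


def regular_train(rate: float, t0: float, t1: float) -> SpikeTrain:
    """Deterministic evenly spaced train at ``rate`` Hz on [t0, t1)."""
    if rate <= 0 or t1 <= t0:
        return SpikeTrain(np.empty(0))
    period = 1000.0 / rate
    return SpikeTrain(np.arange(t0, t1, period))


def merge_trains(*trains: SpikeTrain, eps: float = MERGE_EPS) -> SpikeTrain:
    """Merge trains into one ascending train.

    Coincident times are perturbed forward by ``eps`` (deterministically)
    so the result stays strictly ascending.
    """
    times = np.sort(np.concatenate([t.times for t in trains])) if trains else np.empty(0)
    for i in range(1, times.size):
        if times[i] <= times[i - 1]:
            times[i] = times[i - 1] + eps
    return SpikeTrain(times)


def make_protocol(
    spec: ProtocolSpec | str,
    n_mf: int,
    tfin: float,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[list[SpikeTrain], np.ndarray]:
    """Build one spike train per MF plus the set of bursting MF ids.

    Background and burst components are independent Poisson processes per
    MF (independent spawned streams) clipped to [0, tfin); an MF with
    both components gets their merged train.
    """
    if isinstance(spec, str):
        try:
            spec = PROTOCOLS[spec.lower()]
        except KeyError:
            raise ValueError(
                f"unknown protocol {spec!r}; known: {sorted(PROTOCOLS)}"
            ) from None
    if n_mf < 1:
        raise ValueError(f"need at least one MF, got {n_mf}")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    s_select, *s_mf = ss.spawn(1 + n_mf)

    if spec.burst_fraction > 0 and spec.burst_rate > 0 and spec.burst_duration > 0:
        n_burst = max(1, int(round(spec.burst_fraction * n_mf)))
        bursting = np.sort(
            np.random.default_rng(s_select).choice(n_mf, size=n_burst, replace=False)
        )
    else:
        bursting = np.empty(0, dtype=np.int64)
    burst_set = set(bursting.tolist())

    burst_t0 = spec.burst_onset
    burst_t1 = min(spec.burst_onset + spec.burst_duration, tfin)

    trains: list[SpikeTrain] = []
    for m in range(n_mf):
        rng = np.random.default_rng(s_mf[m])
        parts = []
        if spec.background_rate > 0:
            parts.append(poisson_train(spec.background_rate, 0.0, tfin, rng))
        if m in burst_set and burst_t1 > burst_t0:
            if spec.regular_burst:
                parts.append(regular_train(spec.burst_rate, burst_t0, burst_t1))
            else:
                parts.append(poisson_train(spec.burst_rate, burst_t0, burst_t1, rng))
        trains.append(merge_trains(*parts) if parts else SpikeTrain(np.empty(0)))
    return trains, bursting
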