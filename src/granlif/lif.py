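"""Single-neuron LIF dynamics and conductance-based synapse dynamics.

The membrane follows the linear subthreshold ODE

    Cm dVm/dt = IE + I_inj - gL (Vm - EL) - sum_k g_k (Vm - Vrev_k)

with a hard threshold: when Vm >= VTH the cell emits a spike, Vm is reset
to ``Vinit`` and clamped there for the refractory period ``tref``.  Each
receptor carries a conductance ``g`` that jumps by ``|w|`` on every
incoming spike and decays exponentially with time constant ``tau``;
receptor polarity lives in the reversal potential (0 mV excitatory,
-85 mV inhibitory), so conductances are stored as magnitudes.

Units are the electrophysiologist's natural set — mV, ms, nS, pF, pA —
which is internally consistent (nS*mV = pA, pA*ms/pF = mV), so no unit
conversion appears anywhere in the math.

Default parameters for the two granular-layer cell types are exported as
:data:`GRC` and :data:`GOC`; the synapse defaults as :data:`EXCITATORY`
and :data:`INHIBITORY`.  With these values the Golgi cell is a natural
pacemaker (constant drive IE > 0 pushes V_inf above threshold) while the
granule cell is silent without mossy-fiber input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellParams",
    "ReceptorParams",
    "ReceptorLayout",
    "NeuronState",
    "GRC",
    "GOC",
    "EXCITATORY",
    "INHIBITORY",
    "GRC_LAYOUT",
    "GOC_LAYOUT",
    "membrane_update",
    "synaptic_decay",
    "apply_spike",
    "threshold_and_reset",
    "synaptic_current",
]


@dataclass(frozen=True)
class CellParams:
    """The seven constants of one LIF cell type.

    Parameters
    ----------
    gL : float
        Leak conductance (nS).
    EL : float
        Leak reversal potential (mV).
    IE : float
        Constant intrinsic current (pA); positive values drive pacemaking.
    Cm : float
        Membrane capacitance (pF).
    VTH : float
        Spike threshold (mV).
    Vinit : float
        Reset / initial potential (mV).
    tref : float
        Absolute refractory period (ms).
    """

    gL: float
    EL: float
    IE: float
    Cm: float
    VTH: float
    Vinit: float
    tref: float

    def __post_init__(self) -> None:
        if not self.Cm > 0:
            raise ValueError(f"Cm must be positive, got {self.Cm}")
        if not self.gL > 0:
            raise ValueError(f"gL must be positive, got {self.gL}")
        if self.tref < 0:
            raise ValueError(f"tref must be non-negative, got {self.tref}")
        if not self.Vinit < self.VTH:
            raise ValueError(
                f"Vinit ({self.Vinit}) must lie below VTH ({self.VTH})"
            )

    @property
    def tau_m(self) -> float:
        """Membrane time constant Cm/gL (ms)."""
        return self.Cm / self.gL

    @property
    def V_inf(self) -> float:
        """Steady-state potential EL + IE/gL under intrinsic drive only (mV)."""
        return self.EL + self.IE / self.gL


@dataclass(frozen=True)
class ReceptorParams:
    """Constants of one synaptic receptor.

    ``w`` may be given with the conventional sign (negative for
    inhibition); only its magnitude is added to the conductance — the
    hyperpolarizing action comes from ``Vrev`` below rest.
    """

    Vrev: float  # synaptic reversal potential (mV)
    tau: float  # conductance decay time constant (ms)
    w: float  # conductance increment per spike (nS, sign = polarity tag)
    g0: float = 0.0  # initial conductance (nS)

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.g0 < 0:
            raise ValueError(f"g0 must be non-negative, got {self.g0}")


@dataclass(frozen=True)
class ReceptorLayout:
    """Number of excitatory and inhibitory receptor slots on a cell.

    Granule cells carry four excitatory slots (one per dendrite, each
    reaching a distinct glomerulus) and four matching inhibitory slots;
    Golgi cells carry two excitatory slots (0: glomerular/mossy-fiber
    input, 1: granule-cell input via ascending axon and parallel fibers)
    and one inhibitory slot, unconnected by default.
    """

    n_excitatory: int
    n_inhibitory: int

    def __post_init__(self) -> None:
        if self.n_excitatory < 0 or self.n_inhibitory < 0:
            raise ValueError("receptor counts must be non-negative")

    @property
    def n_receptors(self) -> int:
        return self.n_excitatory + self.n_inhibitory

    def receptors(
        self,
        excitatory: "ReceptorParams" = None,
        inhibitory: "ReceptorParams" = None,
    ) -> list["ReceptorParams"]:
        """Expand the layout into a receptor list, excitatory slots first."""
        exc = EXCITATORY if excitatory is None else excitatory
        inh = INHIBITORY if inhibitory is None else inhibitory
        return [exc] * self.n_excitatory + [inh] * self.n_inhibitory


# Cell-type constants for the two granular-layer populations.
GRC = CellParams(gL=1.5, EL=-74.0, IE=0.0, Cm=3.0, VTH=-42.0, Vinit=-84.0, tref=1.5)
GOC = CellParams(gL=3.6, EL=-65.0, IE=36.75, Cm=76.0, VTH=-55.0, Vinit=-75.0, tref=2.0)

EXCITATORY = ReceptorParams(Vrev=0.0, tau=0.5, w=20.0, g0=0.0)
INHIBITORY = ReceptorParams(Vrev=-85.0, tau=10.0, w=-10.0, g0=0.0)

GRC_LAYOUT = ReceptorLayout(n_excitatory=4, n_inhibitory=4)
GOC_LAYOUT = ReceptorLayout(n_excitatory=2, n_inhibitory=1)


@dataclass
class NeuronState:
    """Mutable state of a single neuron: Vm, refractory clock, conductances."""

    Vm: float
    refractory_remaining: float = 0.0
    receptor_g: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.receptor_g = np.asarray(self.receptor_g, dtype=float)

    @property
    def in_refractory(self) -> bool:
        return self.refractory_remaining > 0.0


def synaptic_current(
    state: NeuronState, receptors: list[ReceptorParams], Vm: float | None = None
) -> float:
    """Total synaptic current sum_k |g_k| (Vm - Vrev_k), in pA.

    Positive values are outward (hyperpolarizing): the membrane update
    subtracts this term, so an excitatory conductance at Vm < 0 yields a
    negative Isyn, i.e. a depolarizing contribution.
    """
    if Vm is None:
        Vm = state.Vm
    g = np.abs(state.receptor_g)
    if len(receptors) != g.size:
        raise ValueError(
            f"{len(receptors)} receptors but {g.size} conductance slots"
        )
    vrev = np.array([r.Vrev for r in receptors])
    return float(np.sum(g * (Vm - vrev)))


def membrane_update(
    state: NeuronState,
    params: CellParams,
    I_inj: float = 0.0,
    h: float = 0.1,
    receptors: list[ReceptorParams] | None = None,
    scheme: str = "implicit",
) -> float:
    """Advance the membrane potential one step of size ``h`` (ms).

    The total current is IE + I_inj - gL(Vm-EL) - sum_k |g_k|(Vm-Vrev_k)
    with the conductances held fixed over the step (they decay separately,
    see :func:`synaptic_decay`).  The default backward-Euler scheme
    evaluates the voltage-dependent terms at t+h, which for this linear
    ODE is unconditionally stable:

        V' = (V + (h/Cm)(IE + I_inj + gL*EL + sum g_k*Vrev_k))
             / (1 + (h/Cm)(gL + sum g_k))

    ``scheme='explicit'`` selects forward Euler instead.  The function is
    pure: it returns the candidate potential without touching ``state``;
    threshold/reset and the refractory clamp live in
    :func:`threshold_and_reset`.
    """
    if not h > 0:
        raise ValueError(f"timestep h must be positive, got {h}")
    Vm = state.Vm
    g = np.abs(state.receptor_g)
    if receptors is None:
        if g.size:
            raise ValueError("receptor parameters required when conductances are set")
        vrev = np.zeros(0)
    else:
        if len(receptors) != g.size:
            raise ValueError(
                f"{len(receptors)} receptors but {g.size} conductance slots"
            )
        vrev = np.array([r.Vrev for r in receptors])
    if not (
        np.isfinite(Vm)
        and np.isfinite(I_inj)
        and np.all(np.isfinite(g))
    ):
        raise FloatingPointError("non-finite membrane state or input current")

    hc = h / params.Cm
    if scheme == "implicit":
        num = Vm + hc * (params.IE + I_inj + params.gL * params.EL + float(g @ vrev))
        den = 1.0 + hc * (params.gL + float(g.sum()))
        return num / den
    if scheme == "explicit":
        I_total = (
            params.IE
            + I_inj
            - params.gL * (Vm - params.EL)
            - float(np.sum(g * (Vm - vrev)))
        )
        return Vm + hc * I_total
    raise ValueError(f"unknown integration scheme {scheme!r}")


def synaptic_decay(g: float | np.ndarray, tau: float, h: float) -> float | np.ndarray:
    """Exponential conductance decay over one elapsed step: g * exp(-h/tau)."""
    if not tau > 0:
        raise ValueError(f"tau must be positive, got {tau}")
    if h < 0:
        raise ValueError(f"elapsed time must be non-negative, got {h}")
    return g * math.exp(-h / tau)


def apply_spike(g: float, w: float, count: int = 1) -> float:
    """Increment a conductance by ``count`` spike arrivals of weight ``|w|``."""
    return g + count * abs(w)


def threshold_and_reset(
    Vm_candidate: float, state: NeuronState, params: CellParams, h: float = 0.1
) -> tuple[float, bool]:
    """Apply the threshold/reset mechanism and refractory clamp.

    During the clamp the membrane is frozen at ``Vinit`` (conductances
    keep evolving elsewhere) and the clock is decremented by ``h``.
    Otherwise a candidate at or above VTH fires: the potential resets to
    ``Vinit`` and the clamp is armed for ``tref``.  Mutates ``state`` and
    returns ``(new_Vm, spiked)``.
    """
    if not h > 0:
        raise ValueError(f"timestep h must be positive, got {h}")
    if state.refractory_remaining > 0.0:
        state.refractory_remaining = max(0.0, state.refractory_remaining - h)
        state.Vm = params.Vinit
        return params.Vinit, False
    if Vm_candidate >= params.VTH:
        state.Vm = params.Vinit
        state.refractory_remaining = params.tref
        return params.Vinit, True
    state.Vm = Vm_candidate
    return Vm_candidate, False
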