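"""Memory-footprint model, firing statistics, and closed-form oracles.

The footprint model counts the IEEE 754 single-precision values a
simulator kernel keeps per cell: seven cell parameters plus four
parameters per synaptic receptor, and one 4-byte arrival flag per
receptor.  With the granular-layer receptor layouts (8 receptors on a
granule cell, 3 on a Golgi cell) this gives 156+32 = 188 B per GRC and
76+12 = 88 B per GOC, hence for a whole network

    RAM = 88 * N_GOC + 188 * N_GRC   bytes.

``isi_closed_form`` is the exact inter-spike interval of a pacemaking
LIF cell in the linear regime, used to validate the numerical engine:

    V_inf = EL + IE/gL
    ISI   = tref + (Cm/gL) * ln((Vinit - V_inf) / (VTH - V_inf))

whenever V_inf exceeds threshold (otherwise the cell never fires).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from granlif.lif import GOC_LAYOUT, GRC_LAYOUT, CellParams, ReceptorLayout

__all__ = [
    "BYTES_PER_VALUE",
    "CELL_PARAM_COUNT",
    "RECEPTOR_PARAM_COUNT",
    "per_cell_bytes",
    "memory_estimate",
    "firing_rate",
    "isi_closed_form",
]

BYTES_PER_VALUE = 4  # IEEE 754 single precision
CELL_PARAM_COUNT = 7  # gL, EL, IE, Cm, VTH, Vinit, tref
RECEPTOR_PARAM_COUNT = 4  # Vrev, tau, w, g0
FLAG_BYTES_PER_RECEPTOR = 4

_LAYOUTS = {"GRC": GRC_LAYOUT, "GOC": GOC_LAYOUT}


def per_cell_bytes(
    cell_type: str, layout: ReceptorLayout | None = None, include_flags: bool = True
) -> int:
    """Bytes of simulator state per cell of the given type.

    ``include_flags=False`` returns the parameter payload only
    (156 B for a GRC, 76 B for a GOC); with flags the totals are the
    coefficients of the network-level estimate (188 / 88 B).
    """
    if layout is None:
        try:
            layout = _LAYOUTS[cell_type.upper()]
        except KeyError:
            raise ValueError(
                f"unknown cell type {cell_type!r}; known: {sorted(_LAYOUTS)}"
            ) from None
    n_rec = layout.n_receptors
    params = (CELL_PARAM_COUNT + RECEPTOR_PARAM_COUNT * n_rec) * BYTES_PER_VALUE
    if not include_flags:
        return params
    return params + FLAG_BYTES_PER_RECEPTOR * n_rec


def memory_estimate(n_goc: int, n_grc: int) -> dict[str, float]:
    """Network memory footprint: 88*N_GOC + 188*N_GRC bytes, also in MiB."""
    if n_goc < 0 or n_grc < 0:
        raise ValueError("cell counts must be non-negative")
    nbytes = per_cell_bytes("GOC") * n_goc + per_cell_bytes("GRC") * n_grc
    # reported MiB is truncated, not rounded, to two decimals
    return {"bytes": nbytes, "MB": math.floor(nbytes / 2**20 * 100) / 100}


def firing_rate(
    raster: pd.DataFrame, population: str, window_ms: float
) -> tuple[pd.Series, float]:
    """Per-neuron firing rates (Hz) in a raster window, and their mean.

    Neurons that never appear in the raster contribute 0 Hz only through
    the caller's knowledge of population size; the returned mean is over
    neurons present in the raster (use the summary of a simulation
    result for population-mean rates including silent cells).
    """
    if not window_ms > 0:
        raise ValueError(f"window must be positive, got {window_ms}")
    sel = raster[raster["population"] == population]
    per_neuron = sel.groupby("neuron_id").size() / (window_ms / 1000.0)
    mean = float(per_neuron.mean()) if len(per_neuron) else 0.0
    return per_neuron, mean


def isi_closed_form(params: CellParams) -> float | None:
    """Exact pacemaking inter-spike interval (ms), or None if silent.

    Valid in the purely linear regime (no synaptic input): the membrane
    relaxes exponentially from Vinit toward V_inf = EL + IE/gL and fires
    when it crosses VTH, after which tref of clamp is added.
    """
    v_inf = params.V_inf
    if v_inf <= params.VTH:
        return None
    tau_m = params.Cm / params.gL
    return params.tref + tau_m * math.log(
        (params.Vinit - v_inf) / (params.VTH - v_inf)
    )
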