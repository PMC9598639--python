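import numpy as np
import pandas as pd
import pytest

from granlif.io import NETWORK_PRESETS
from granlif.network import Network, VolumeSpec, build_network


def _frame(**cols) -> pd.DataFrame:
    """Typed edge DataFrame; empty columns keep integer/float dtypes."""
    dtypes = {"delay": float, "pathway": object}
    return pd.DataFrame(
        {
            k: np.asarray(v, dtype=dtypes.get(k, np.int64))
            if k != "pathway"
            else list(v)
            for k, v in cols.items()
        }
    )


def micro_network(
    wire_inh: bool = False,
    wire_exc: bool = False,
    wire_mf_to_grc: bool = True,
    wire_mf_to_goc: bool = False,
    inh_delay: float = 0.5,
    exc_delay: float = 0.5,
    inh_slot: int = 0,
) -> Network:
    """Minimal hand-wired network: 1 GRC (4 GLOs), 1 GOC, 1 MF.

    Used for single-cell engine checks; bypasses the rule-based builder
    so the circuit is fully explicit.
    """
    glo_pos = np.array([[10.0, 10, 10], [20, 10, 10], [10, 20, 10], [10, 10, 20]])
    net = Network(
        volume=VolumeSpec(40, 40, 40),
        grc_pos=np.array([[15.0, 15, 15]]),
        goc_pos=np.array([[25.0, 25, 25]]),
        glo_pos=glo_pos,
        glo_to_mf=np.zeros(4, dtype=np.int64),
        grc_glo=(
            _frame(grc=[0, 0, 0, 0], glo=[0, 1, 2, 3], slot=[0, 1, 2, 3])
            if wire_mf_to_grc
            else _frame(grc=[], glo=[], slot=[])
        ),
        glo_goc=(
            _frame(glo=[0], goc=[0]) if wire_mf_to_goc else _frame(glo=[], goc=[])
        ),
        goc_glo=_frame(goc=[0], glo=[0]) if wire_inh else _frame(goc=[], glo=[]),
        goc_grc_inh=(
            _frame(goc=[0], grc=[0], slot=[inh_slot], delay=[inh_delay])
            if wire_inh
            else _frame(goc=[], grc=[], slot=[], delay=[])
        ),
        grc_goc_exc=(
            _frame(grc=[0], goc=[0], pathway=["pf"], delay=[exc_delay])
            if wire_exc
            else _frame(grc=[], goc=[], pathway=[], delay=[])
        ),
    )
    return net


@pytest.fixture(scope="session")
def tiny_net() -> Network:
    """The 60x60x120 um^3 test-preset network, built once per session."""
    return build_network(NETWORK_PRESETS["tiny"], seed=11)
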