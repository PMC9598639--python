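"""The four mossy-fiber stimulation protocols.

Generates each protocol for 100 MFs over one second and summarizes the
burst-set size and spike counts; the 1 Hz background yields about one
spike per MF, the 100 Hz / 50 ms burst about five extra on bursting MFs.
"""

import numpy as np

from granlif import make_protocol

for name in ("prot1", "prot2", "prot3", "prot4"):
    trains, bursting = make_protocol(name, n_mf=100, tfin=1000.0, seed=3)
    counts = np.array([len(t) for t in trains])
    print(
        f"{name}: {len(bursting):3d} bursting MFs; spikes/MF "
        f"mean {counts.mean():.2f}, "
        f"bursting-MF mean "
        f"{counts[bursting].mean() if len(bursting) else 0:.2f}"
    )
print("prot1: background only; prot2: burst only on 10%; "
      "prot3: both on all MFs; prot4: background plus burst on 1%")
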