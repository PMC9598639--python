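"""Memory footprint of the three reference network sizes.

Each cell stores 7 single-precision parameters plus 4 per receptor and a
4-byte flag per receptor: 188 B per granule cell, 88 B per Golgi cell,
so a network needs 88*N_GOC + 188*N_GRC bytes of device memory.
"""

from granlif import memory_estimate, per_cell_bytes, sample_counts
from granlif.io import NETWORK_PRESETS

print(f"per GRC: {per_cell_bytes('GRC')} B "
      f"({per_cell_bytes('GRC', include_flags=False)} params + flags)")
print(f"per GOC: {per_cell_bytes('GOC')} B "
      f"({per_cell_bytes('GOC', include_flags=False)} params + flags)")
for name in ("network1", "network2", "network3"):
    c = sample_counts(NETWORK_PRESETS[name])
    est = memory_estimate(c.n_goc, c.n_grc)
    print(f"{name}: {c.n_goc} GOCs + {c.n_grc} GRCs -> {est['MB']} MiB")
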