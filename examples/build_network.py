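"""Reconstruct the small test-preset granular-layer network and audit it.

Places cells at the reference densities in a 60x60x120 um^3 box and
applies the anatomical wiring rules; the audit reports how well the
emergent statistics match the convergence/divergence ratios.
"""

from granlif import build_network
from granlif.io import NETWORK_PRESETS

net = build_network(NETWORK_PRESETS["tiny"], seed=11)
c = net.counts
print(f"populations: {c.n_grc} GRCs, {c.n_goc} GOCs, {c.n_glo} GLOs, {c.n_mf} MFs")
print(f"edges: {len(net.grc_glo)} dendritic, {len(net.glo_goc)} GLO->GOC, "
      f"{len(net.goc_grc_inh)} inhibitory, {len(net.grc_goc_exc)} GRC->GOC")
print("audit (each GRC has exactly 4 dendrites; mean GLO load tracks "
      "4*rho_grc/rho_glo = 53.3):")
for key in (
    "dendrites_per_glo_mean",
    "dendrites_per_glo_max",
    "n_capacity_overflow_edges",
    "distinct_mfs_per_goc_mean",
    "glos_per_goc_axon_max",
    "n_duplicate_inhibition_dropped",
):
    print(f"  {key}: {net.audit[key]}")
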