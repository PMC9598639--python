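"""Simulate two seconds of test-preset network activity under Prot1.

Golgi cells pacemake continuously (their intrinsic drive keeps them near
10 Hz even without input, and network excitation raises that); granule
cells fire only around the sparse 1 Hz mossy-fiber events.  A partitioned
run (populations split into blocks, merged at the serial routing
barriers) reproduces the monolithic raster exactly.
"""

from granlif import build_network, make_protocol, run, run_partitioned
from granlif.io import NETWORK_PRESETS

net = build_network(NETWORK_PRESETS["tiny"], seed=11)
trains, _ = make_protocol("prot1", net.counts.n_mf, tfin=2000.0, seed=4)
res = run(net, trains, tfin=2000.0, h=0.1)
print(f"{len(res.raster)} spikes in 2 s")
print(f"mean rates: GOC {res.summary['goc']:.1f} Hz, GRC {res.summary['grc']:.2f} Hz")

part = run_partitioned(net, trains, tfin=2000.0, n_parts=2, h=0.1)
print("partitioned (2 blocks) raster identical:", res.raster.equals(part.raster))
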