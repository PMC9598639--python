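"""Configuration, presets, and lossless TSV round-trips for all artifacts.

Every artifact is tab-separated text with a ``#``-prefixed provenance
header (package version plus any caller-supplied metadata such as seed
and config hash) and a column-name header line.  Floats are written with
``repr`` so write -> read -> write is byte-identical.

File formats
------------
- positions: pop, id, x, y, z (um); volume recorded in the header.
- edge list: src_pop, src_id, dst_pop, dst_id, receptor_slot, delay_ms.
  The five anatomical edge sets and the MF->GLO assignment share the
  format, distinguished by the (src_pop, dst_pop) pair; the aa/pf
  pathway tag of granule-to-Golgi edges rides in src_pop (``grc_aa`` /
  ``grc_pf``).
- raster: time_ms, population, neuron_id.
- trace: time_ms followed by one ``pop:id`` column per recorded neuron.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from granlif import __version__ as _version
from granlif.network import DensityConfig, Network, RuleConfig, VolumeSpec
from granlif.stimulus import PROTOCOLS, ProtocolSpec

__all__ = [
    "NETWORK_PRESETS",
    "SimConfig",
    "load_config",
    "config_hash",
    "write_network",
    "read_network",
    "write_raster",
    "read_raster",
    "write_trace",
    "write_audit",
]

#: named network geometries (um); "tiny" is the test preset.
NETWORK_PRESETS: dict[str, VolumeSpec] = {
    "network1": VolumeSpec(300, 75, 1200),
    "network2": VolumeSpec(600, 150, 1200),
    "network3": VolumeSpec(1200, 300, 1200),
    "tiny": VolumeSpec(60, 60, 120),
}


@dataclass(frozen=True)
class SimConfig:
    """A fully validated simulation configuration."""

    volume: VolumeSpec
    densities: DensityConfig = field(default_factory=DensityConfig)
    rules: RuleConfig = field(default_factory=RuleConfig)
    protocol: ProtocolSpec = field(default_factory=lambda: PROTOCOLS["prot1"])
    h: float = 0.1
    tfin: float = 1000.0
    scheme: str = "implicit"
    seed: int = 0
    record: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.h > 0:
            raise ValueError(f"field 'h': must be positive, got {self.h}")
        if self.tfin < 0:
            raise ValueError(f"field 'tfin': must be non-negative, got {self.tfin}")
        if self.scheme not in ("implicit", "explicit"):
            raise ValueError(
                f"field 'scheme': must be 'implicit' or 'explicit', got {self.scheme!r}"
            )


_TOP_KEYS = {
    "preset",
    "volume",
    "densities",
    "rules",
    "protocol",
    "h",
    "tfin",
    "scheme",
    "seed",
    "record",
}


def _build_dataclass(cls, data: dict, where: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {where} field(s): {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path) -> SimConfig:
    """Parse, default and validate a YAML configuration file.

    A config names either a geometry ``preset`` (network1/2/3, tiny) or
    an explicit ``volume: {x, y, z}``; ``densities`` and ``rules``
    accept per-field overrides; ``protocol`` is a preset name (prot1-4)
    or a mapping of :class:`~granlif.stimulus.ProtocolSpec` fields.
    Unknown keys anywhere are rejected with a named-field message.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or not raw:
        raise ValueError(
            "empty or malformed config; required: 'preset' or 'volume' "
            f"(plus optional {sorted(_TOP_KEYS - {'preset', 'volume'})})"
        )
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "volume" in raw:
        vol = _build_dataclass(VolumeSpec, raw["volume"], "volume")
    elif "preset" in raw:
        name = str(raw["preset"]).lower()
        if name not in NETWORK_PRESETS:
            raise ValueError(
                f"unknown preset {name!r}; known: {sorted(NETWORK_PRESETS)}"
            )
        vol = NETWORK_PRESETS[name]
    else:
        raise ValueError("config must set either 'preset' or 'volume'")

    densities = _build_dataclass(DensityConfig, raw.get("densities", {}), "densities")
    rules = _build_dataclass(RuleConfig, raw.get("rules", {}), "rules")

    prot = raw.get("protocol", "prot1")
    if isinstance(prot, str):
        key = prot.lower()
        if key not in PROTOCOLS:
            raise ValueError(f"unknown protocol {prot!r}; known: {sorted(PROTOCOLS)}")
        protocol = PROTOCOLS[key]
    else:
        protocol = _build_dataclass(ProtocolSpec, prot, "protocol")

    record = tuple((str(p), int(i)) for p, i in raw.get("record", []))
    return SimConfig(
        volume=vol,
        densities=densities,
        rules=rules,
        protocol=protocol,
        h=float(raw.get("h", 0.1)),
        tfin=float(raw.get("tfin", 1000.0)),
        scheme=str(raw.get("scheme", "implicit")),
        seed=int(raw.get("seed", 0)),
        record=record,
    )


def config_hash(config: SimConfig) -> str:
    """Stable short hash of a configuration, for provenance headers."""
    blob = yaml.safe_dump(
        {
            "volume": [config.volume.x, config.volume.y, config.volume.z],
            "densities": vars(config.densities),
            "rules": {k: v for k, v in vars(config.rules).items()},
            "protocol": vars(config.protocol),
            "h": config.h,
            "tfin": config.tfin,
            "scheme": config.scheme,
            "seed": config.seed,
            "record": list(map(list, config.record)),
        },
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# TSV writers/readers
# ---------------------------------------------------------------------------


def _header_lines(meta: dict | None) -> list[str]:
    lines = [f"# granlif {_version}"]
    for key in sorted(meta or {}):
        lines.append(f"# {key}: {meta[key]}")
    return lines


def _read_meta(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
    return meta


def _fmt(v) -> str:
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    return str(v)


def write_network(
    net: Network,
    edges_path: str | Path,
    positions_path: str | Path,
    meta: dict | None = None,
) -> None:
    """Write a network as an edge-list TSV plus a positions TSV."""
    positions_path = Path(positions_path)
    pos_meta = dict(meta or {})
    pos_meta["volume_um"] = " ".join(
        _fmt(float(v)) for v in (net.volume.x, net.volume.y, net.volume.z)
    )
    with open(positions_path, "w") as fh:
        for line in _header_lines(pos_meta):
            fh.write(line + "\n")
        fh.write("pop\tid\tx\ty\tz\n")
        for pop, arr in (("grc", net.grc_pos), ("goc", net.goc_pos), ("glo", net.glo_pos)):
            for i, (x, y, z) in enumerate(arr):
                fh.write(f"{pop}\t{i}\t{_fmt(x)}\t{_fmt(y)}\t{_fmt(z)}\n")

    with open(Path(edges_path), "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        fh.write("src_pop\tsrc_id\tdst_pop\tdst_id\treceptor_slot\tdelay_ms\n")

        def row(sp, si, dp, di, slot, delay):
            fh.write(f"{sp}\t{si}\t{dp}\t{di}\t{slot}\t{_fmt(delay)}\n")

        for glo, mf in enumerate(net.glo_to_mf):
            row("mf", mf, "glo", glo, 0, 0.0)
        for r in net.grc_glo.itertuples(index=False):
            row("grc", r.grc, "glo", r.glo, r.slot, 0.0)
        for r in net.glo_goc.itertuples(index=False):
            row("glo", r.glo, "goc", r.goc, 0, 0.0)
        for r in net.goc_glo.itertuples(index=False):
            row("goc", r.goc, "glo", r.glo, 0, 0.0)
        for r in net.goc_grc_inh.itertuples(index=False):
            row("goc", r.goc, "grc", r.grc, r.slot, r.delay)
        for r in net.grc_goc_exc.itertuples(index=False):
            row(f"grc_{r.pathway}", r.grc, "goc", r.goc, 1, r.delay)


def read_network(
    edges_path: str | Path, positions_path: str | Path
) -> tuple[Network, dict]:
    """Read back a network written by :func:`write_network`."""
    positions_path = Path(positions_path)
    meta = _read_meta(positions_path)
    vx, vy, vz = (float(v) for v in meta["volume_um"].split())
    pos = pd.read_csv(
        positions_path, sep="\t", comment="#", float_precision="round_trip"
    )
    pos_arrays = {
        pop: grp.sort_values("id")[["x", "y", "z"]].to_numpy()
        for pop, grp in pos.groupby("pop")
    }
    edges = pd.read_csv(
        Path(edges_path), sep="\t", comment="#", float_precision="round_trip"
    )
    edge_meta = _read_meta(Path(edges_path))

    def sel(sp, dp):
        m = (edges["src_pop"] == sp) & (edges["dst_pop"] == dp)
        return edges[m]

    mf_rows = sel("mf", "glo").sort_values("dst_id")
    glo_to_mf = mf_rows["src_id"].to_numpy(dtype=np.int64)

    gg = sel("grc", "glo")
    grc_glo = pd.DataFrame(
        {
            "grc": gg["src_id"].to_numpy(np.int64),
            "glo": gg["dst_id"].to_numpy(np.int64),
            "slot": gg["receptor_slot"].to_numpy(np.int64),
        }
    )
    go = sel("glo", "goc")
    glo_goc = pd.DataFrame(
        {"glo": go["src_id"].to_numpy(np.int64), "goc": go["dst_id"].to_numpy(np.int64)}
    )
    ax = sel("goc", "glo")
    goc_glo = pd.DataFrame(
        {"goc": ax["src_id"].to_numpy(np.int64), "glo": ax["dst_id"].to_numpy(np.int64)}
    )
    ih = sel("goc", "grc")
    goc_grc_inh = pd.DataFrame(
        {
            "goc": ih["src_id"].to_numpy(np.int64),
            "grc": ih["dst_id"].to_numpy(np.int64),
            "slot": ih["receptor_slot"].to_numpy(np.int64),
            "delay": ih["delay_ms"].to_numpy(float),
        }
    )
    ex_parts = []
    for tag in ("aa", "pf"):
        part = sel(f"grc_{tag}", "goc")
        ex_parts.append(
            pd.DataFrame(
                {
                    "grc": part["src_id"].to_numpy(np.int64),
                    "goc": part["dst_id"].to_numpy(np.int64),
                    "pathway": [tag] * len(part),
                    "delay": part["delay_ms"].to_numpy(float),
                }
            )
        )
    grc_goc_exc = pd.concat(ex_parts, ignore_index=True)
    # restore the writer's per-GOC (aa block, pf block) interleaving
    grc_goc_exc = (
        grc_goc_exc.sort_values(["goc", "pathway", "grc"], kind="stable")
        .reset_index(drop=True)
    )

    net = Network(
        volume=VolumeSpec(vx, vy, vz),
        grc_pos=pos_arrays.get("grc", np.empty((0, 3))),
        goc_pos=pos_arrays.get("goc", np.empty((0, 3))),
        glo_pos=pos_arrays.get("glo", np.empty((0, 3))),
        glo_to_mf=glo_to_mf,
        grc_glo=grc_glo,
        glo_goc=glo_goc,
        goc_glo=goc_glo,
        goc_grc_inh=goc_grc_inh,
        grc_goc_exc=grc_goc_exc,
        audit={},
    )
    return net, edge_meta


def write_raster(raster: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Raster TSV: time_ms, population, neuron_id, ascending by time."""
    with open(Path(path), "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        fh.write("time_ms\tpopulation\tneuron_id\n")
        for r in raster.itertuples(index=False):
            fh.write(f"{_fmt(r.time_ms)}\t{r.population}\t{r.neuron_id}\n")


def read_raster(path: str | Path) -> tuple[pd.DataFrame, dict]:
    meta = _read_meta(Path(path))
    df = pd.read_csv(
        Path(path),
        sep="\t",
        comment="#",
        dtype={"time_ms": float, "population": str, "neuron_id": np.int64},
        float_precision="round_trip",
    )
    return df, meta


def write_trace(
    trace_times: np.ndarray,
    traces: dict[tuple[str, int], np.ndarray],
    path: str | Path,
    meta: dict | None = None,
) -> None:
    """Membrane-trace TSV: time_ms plus one ``pop:id`` column per neuron."""
    keys = list(traces)
    with open(Path(path), "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        fh.write("time_ms" + "".join(f"\t{p}:{i}" for p, i in keys) + "\n")
        for row_i, t in enumerate(trace_times):
            fh.write(
                _fmt(t)
                + "".join(f"\t{_fmt(traces[k][row_i])}" for k in keys)
                + "\n"
            )


def write_audit(audit: dict, path: str | Path, meta: dict | None = None) -> None:
    """Connectivity audit as key<TAB>value lines."""
    with open(Path(path), "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        fh.write("statistic\tvalue\n")
        for key, value in audit.items():
            fh.write(f"{key}\t{value}\n")
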