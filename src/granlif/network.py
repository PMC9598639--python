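"""Rule-based 3D reconstruction of the cerebellar granular layer.

Cells are placed uniformly at random in a box and wired by the anatomical
convergence/divergence rules of the granular layer:

* every granule cell (GRC) sends exactly 4 dendrites to 4 distinct
  glomeruli (GLOs) within 40 um, never two dendrites into one GLO;
* a GLO hosts at most 53 GRC dendrites (the 1:53 divergence rule);
* each Golgi cell (GOC) dendritic tree collects 50 distinct GLOs
  (the 50:1 convergence rule), which in practice samples ~40 distinct
  mossy fibers (MFs);
* each GOC axon inhibits at most 40 distinct GLOs, and through them every
  GRC with a dendrite in those GLOs — but never the same GRC twice;
* each GOC is excited by 400 GRC ascending axons (a vertical column) and
  1000 parallel fibers (sampled volume-wide).

Densities default to values reverse-derived from the reference network
sizes (GRC 4.0e-3, GOC 9.0e-6, GLO 3.0e-4 per um^3; 20 GLOs per MF), so a
300x75x1200 um^3 slab yields 108,000 GRCs, 243 GOCs and 8,100 GLOs.

Note an arithmetic tension in the rules themselves: at these densities
the mean GLO load is 4*rho_grc/rho_glo = 53.33 dendrites, which no hard
per-GLO cap of 53 can accommodate.  The builder therefore treats the cap
as a sampling constraint and, once every in-range GLO of a GRC is full,
falls back to the least-loaded in-range GLOs; every such overflow edge is
counted in the audit and the maximum load stays at ceil(mean).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "VolumeSpec",
    "DensityConfig",
    "RuleConfig",
    "Counts",
    "Network",
    "sample_counts",
    "place_cells",
    "assign_mfs",
    "connect_grc_dendrites",
    "connect_goc_dendrites",
    "connect_goc_axon",
    "connect_grc_to_goc",
    "build_network",
]


@dataclass(frozen=True)
class VolumeSpec:
    """Edge lengths of the tissue box in micrometres."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if min(self.x, self.y, self.z) <= 0:
            raise ValueError(f"volume edges must be positive, got {self}")

    @property
    def volume(self) -> float:
        return self.x * self.y * self.z

    @property
    def diagonal(self) -> float:
        return math.sqrt(self.x**2 + self.y**2 + self.z**2)

    @property
    def edges(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class DensityConfig:
    """Cell densities (per um^3) and the GLO-per-MF packing ratio."""

    rho_grc: float = 4.0e-3
    rho_goc: float = 9.0e-6
    rho_glo: float = 3.0e-4
    mf_per_glo_ratio: float = 20.0

    def __post_init__(self) -> None:
        if min(self.rho_grc, self.rho_goc, self.rho_glo, self.mf_per_glo_ratio) <= 0:
            raise ValueError("densities and MF ratio must be positive")


@dataclass(frozen=True)
class RuleConfig:
    """Wiring-rule constants.  Distances in micrometres, delays in ms.

    ``grc_dendrites`` through ``pf_per_goc`` are the anatomical
    convergence/divergence numbers; the radii for GOC dendrites/axon and
    the ascending-axon column are geometric defaults not fixed by the
    rules.  ``vertical_axis`` names the layer-thickness axis (0=x, 1=y,
    2=z); ascending axons run along it, so the column constraint is a
    lateral-distance bound in the other two axes.
    """

    grc_dendrites: int = 4
    grc_dendrite_max_dist: float = 40.0
    glo_grc_capacity: int = 53
    glo_per_goc_dendrite: int = 50
    goc_dendrite_radius: float = 100.0
    goc_axon_max_glo: int = 40
    goc_axon_radius: float = 150.0
    aa_per_goc: int = 400
    pf_per_goc: int = 1000
    aa_lateral_radius: float = 50.0
    vertical_axis: int = 1
    delay_min: float = 0.1
    delay_max: float = 1.0
    relax_step: float = 10.0
    allow_relaxation: bool = True
    allow_capacity_overflow: bool = True

    def __post_init__(self) -> None:
        if self.grc_dendrites < 1 or self.glo_grc_capacity < 1:
            raise ValueError("dendrite count and GLO capacity must be >= 1")
        if self.delay_min <= 0 or self.delay_max < self.delay_min:
            raise ValueError("need 0 < delay_min <= delay_max")
        if self.vertical_axis not in (0, 1, 2):
            raise ValueError("vertical_axis must be 0, 1 or 2")


class Counts(NamedTuple):
    n_goc: int
    n_grc: int
    n_glo: int
    n_mf: int


@dataclass
class Network:
    """A reconstructed granular-layer network: positions plus five edge sets.

    Edge tables are pandas DataFrames with 0-based integer ids:

    - ``grc_glo``: columns (grc, glo, slot) — GRC dendrite into a GLO,
      slot 0-3 is the GRC excitatory receptor fed through that GLO.
    - ``glo_goc``: columns (glo, goc) — GLO onto a GOC dendrite
      (MF-driven excitation, GOC receptor slot 0).
    - ``goc_glo``: columns (goc, glo) — GOC axon terminals.
    - ``goc_grc_inh``: columns (goc, grc, slot, delay) — expanded
      inhibition, slot is the GRC inhibitory receptor (0-3) matching the
      dendrite in the shared GLO.
    - ``grc_goc_exc``: columns (grc, goc, pathway, delay) — GRC
      excitation of GOCs, pathway "aa" or "pf", GOC receptor slot 1.
    """

    volume: VolumeSpec
    grc_pos: np.ndarray
    goc_pos: np.ndarray
    glo_pos: np.ndarray
    glo_to_mf: np.ndarray
    grc_glo: pd.DataFrame
    glo_goc: pd.DataFrame
    goc_glo: pd.DataFrame
    goc_grc_inh: pd.DataFrame
    grc_goc_exc: pd.DataFrame
    audit: dict = field(default_factory=dict)

    @property
    def counts(self) -> Counts:
        return Counts(
            n_goc=len(self.goc_pos),
            n_grc=len(self.grc_pos),
            n_glo=len(self.glo_pos),
            n_mf=int(self.glo_to_mf.max()) + 1 if len(self.glo_to_mf) else 0,
        )


def sample_counts(volume: VolumeSpec, densities: DensityConfig | None = None) -> Counts:
    """Population sizes from densities: round(rho*V) per type, MFs by GLO ratio."""
    d = densities or DensityConfig()
    v = volume.volume
    n_grc = int(round(d.rho_grc * v))
    n_goc = int(round(d.rho_goc * v))
    n_glo = int(round(d.rho_glo * v))
    if n_goc == 0 or n_glo == 0:
        raise ValueError(
            f"volume {volume} too small: {n_goc} GOCs / {n_glo} GLOs; "
            "use a larger volume or pass explicit counts"
        )
    n_mf = math.ceil(n_glo / d.mf_per_glo_ratio)
    return Counts(n_goc=n_goc, n_grc=n_grc, n_glo=n_glo, n_mf=n_mf)


def place_cells(
    counts: Counts, volume: VolumeSpec, rng: np.random.Generator | int
) -> dict[str, np.ndarray]:
    """Uniformly random somata/glomerulus positions inside the box."""
    rng = np.random.default_rng(rng)
    edges = volume.edges
    return {
        "grc": rng.uniform(0, 1, size=(counts.n_grc, 3)) * edges,
        "goc": rng.uniform(0, 1, size=(counts.n_goc, 3)) * edges,
        "glo": rng.uniform(0, 1, size=(counts.n_glo, 3)) * edges,
    }


def assign_mfs(
    n_glo: int, ratio: float, rng: np.random.Generator | int
) -> np.ndarray:
    """Partition GLOs over ceil(n_glo/ratio) mossy fibers, loads balanced."""
    if ratio < 1:
        raise ValueError(f"mf_per_glo_ratio must be >= 1, got {ratio}")
    rng = np.random.default_rng(rng)
    n_mf = math.ceil(n_glo / ratio)
    glo_to_mf = np.empty(n_glo, dtype=np.int64)
    perm = rng.permutation(n_glo)
    glo_to_mf[perm] = np.arange(n_glo) % n_mf
    return glo_to_mf


def _in_range(
    tree: cKDTree, point: np.ndarray, radius: float
) -> np.ndarray:
    return np.asarray(tree.query_ball_point(point, radius), dtype=np.int64)


def connect_grc_dendrites(
    grc_pos: np.ndarray,
    glo_pos: np.ndarray,
    rules: RuleConfig,
    rng: np.random.Generator | int,
) -> tuple[pd.DataFrame, dict]:
    """Wire every GRC to ``grc_dendrites`` distinct GLOs within range.

    Targets are drawn uniformly among in-range GLOs whose dendrite load
    is below capacity.  Two fallbacks, both logged in the returned audit
    fragment: if fewer than the required number of GLOs exist in range at
    all, the distance bound relaxes in ``relax_step`` increments; if the
    in-range GLOs exist but are at capacity, the least-loaded in-range
    GLOs absorb the remainder (capacity overflow).
    """
    rng = np.random.default_rng(rng)
    n_grc, n_glo = len(grc_pos), len(glo_pos)
    k = rules.grc_dendrites
    if n_glo < k:
        raise ValueError(f"need at least {k} GLOs, have {n_glo}")
    tree = cKDTree(glo_pos)
    neighbors = tree.query_ball_point(grc_pos, rules.grc_dendrite_max_dist)

    load = np.zeros(n_glo, dtype=np.int64)
    src = np.empty(n_grc * k, dtype=np.int64)
    dst = np.empty(n_grc * k, dtype=np.int64)
    n_relaxed = 0
    max_relaxed_dist = rules.grc_dendrite_max_dist
    n_overflow_edges = 0

    # Random processing order so late ids are not systematically the ones
    # hitting full glomeruli.
    order = rng.permutation(n_grc)
    for i in order:
        cand = np.asarray(neighbors[i], dtype=np.int64)
        radius = rules.grc_dendrite_max_dist
        while cand.size < k:
            if not rules.allow_relaxation:
                raise RuntimeError(
                    f"GRC {i}: only {cand.size} GLOs within "
                    f"{radius} um and relaxation is disabled"
                )
            radius += rules.relax_step
            if radius > _diag(grc_pos, glo_pos):
                raise RuntimeError(
                    f"GRC {i}: cannot find {k} GLOs within any radius"
                )
            cand = _in_range(tree, grc_pos[i], radius)
        if radius > rules.grc_dendrite_max_dist:
            n_relaxed += 1
            max_relaxed_dist = max(max_relaxed_dist, radius)
            logger.info("GRC %d: dendrite range relaxed to %.0f um", i, radius)

        open_cand = cand[load[cand] < rules.glo_grc_capacity]
        if open_cand.size >= k:
            chosen = rng.choice(open_cand, size=k, replace=False)
        else:
            if not rules.allow_capacity_overflow:
                raise RuntimeError(
                    f"GRC {i}: only {open_cand.size} in-range GLOs below "
                    f"capacity {rules.glo_grc_capacity}"
                )
            # take every open one, then fill from the least-loaded rest
            chosen = open_cand.copy()
            rest = np.setdiff1d(cand, open_cand, assume_unique=True)
            need = k - chosen.size
            order_rest = rest[np.argsort(load[rest], kind="stable")]
            extra = order_rest[:need]
            n_overflow_edges += need
            chosen = np.concatenate([chosen, extra])
        load[chosen] += 1
        src[i * k : (i + 1) * k] = i
        dst[i * k : (i + 1) * k] = chosen

    edges = pd.DataFrame(
        {
            "grc": src,
            "glo": dst,
            "slot": np.tile(np.arange(k, dtype=np.int64), n_grc),
        }
    )
    audit = {
        "dendrites_per_glo_min": int(load.min()),
        "dendrites_per_glo_mean": float(load.mean()),
        "dendrites_per_glo_max": int(load.max()),
        "n_grc_distance_relaxed": n_relaxed,
        "max_relaxed_dist_um": float(max_relaxed_dist),
        "n_capacity_overflow_edges": n_overflow_edges,
    }
    if n_overflow_edges:
        logger.warning(
            "GLO capacity %d exceeded for %d dendrites (mean load %.2f); "
            "max load %d",
            rules.glo_grc_capacity,
            n_overflow_edges,
            load.mean(),
            load.max(),
        )
    return edges, audit


def _diag(*position_sets: np.ndarray) -> float:
    lo = np.min([p.min(axis=0) for p in position_sets if len(p)], axis=0)
    hi = np.max([p.max(axis=0) for p in position_sets if len(p)], axis=0)
    return float(np.linalg.norm(hi - lo)) + 1.0


def connect_goc_dendrites(
    goc_pos: np.ndarray,
    glo_pos: np.ndarray,
    glo_to_mf: np.ndarray,
    rules: RuleConfig,
    rng: np.random.Generator | int,
) -> tuple[pd.DataFrame, dict]:
    """Give every GOC ``glo_per_goc_dendrite`` distinct GLO inputs.

    GLOs are sampled uniformly within the dendritic radius (relaxed in
    increments when too few are in range).  The number of distinct MFs
    this implies per GOC is an emergent statistic reported in the audit,
    not a constraint.
    """
    rng = np.random.default_rng(rng)
    n_goc, n_glo = len(goc_pos), len(glo_pos)
    k = rules.glo_per_goc_dendrite
    if n_glo < k:
        raise ValueError(f"need at least {k} GLOs for GOC dendrites, have {n_glo}")
    tree = cKDTree(glo_pos)
    rows_glo = np.empty(n_goc * k, dtype=np.int64)
    rows_goc = np.empty(n_goc * k, dtype=np.int64)
    distinct_mfs = np.empty(n_goc, dtype=np.int64)
    n_relaxed = 0
    for j in range(n_goc):
        radius = rules.goc_dendrite_radius
        cand = _in_range(tree, goc_pos[j], radius)
        while cand.size < k:
            if not rules.allow_relaxation:
                raise RuntimeError(
                    f"GOC {j}: only {cand.size} GLOs within {radius} um"
                )
            radius += rules.relax_step
            if radius > _diag(goc_pos, glo_pos):
                raise RuntimeError(f"GOC {j}: cannot reach {k} GLOs")
            cand = _in_range(tree, goc_pos[j], radius)
        if radius > rules.goc_dendrite_radius:
            n_relaxed += 1
        chosen = rng.choice(cand, size=k, replace=False)
        rows_glo[j * k : (j + 1) * k] = chosen
        rows_goc[j * k : (j + 1) * k] = j
        distinct_mfs[j] = len(np.unique(glo_to_mf[chosen]))
    edges = pd.DataFrame({"glo": rows_glo, "goc": rows_goc})
    audit = {
        "distinct_mfs_per_goc_min": int(distinct_mfs.min()),
        "distinct_mfs_per_goc_mean": float(distinct_mfs.mean()),
        "distinct_mfs_per_goc_max": int(distinct_mfs.max()),
        "n_goc_dendrite_relaxed": n_relaxed,
    }
    return edges, audit


def connect_goc_axon(
    goc_pos: np.ndarray,
    glo_pos: np.ndarray,
    grc_glo: pd.DataFrame,
    rules: RuleConfig,
    rng: np.random.Generator | int,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Wire GOC axons to <= ``goc_axon_max_glo`` GLOs and expand to GRCs.

    Each selected GLO turns into inhibitory edges onto every GRC with a
    dendrite in it, on the inhibitory receptor slot paired with that
    dendrite.  Duplicate (GOC, GRC) pairs keep only the first expansion.
    Fewer reachable GLOs than the maximum is fine — the rule is a cap.
    """
    rng = np.random.default_rng(rng)
    n_goc = len(goc_pos)
    tree = cKDTree(glo_pos)
    # per-GLO list of (grc, slot) for fast expansion
    by_glo_grc: list[np.ndarray] = [np.empty(0, dtype=np.int64)] * len(glo_pos)
    by_glo_slot: list[np.ndarray] = [np.empty(0, dtype=np.int64)] * len(glo_pos)
    grouped = grc_glo.sort_values(["glo", "grc"], kind="stable").groupby("glo")
    for glo_id, grp in grouped:
        by_glo_grc[glo_id] = grp["grc"].to_numpy()
        by_glo_slot[glo_id] = grp["slot"].to_numpy()

    axon_goc, axon_glo = [], []
    inh_goc, inh_grc, inh_slot = [], [], []
    dropped_dups = 0
    glos_per_goc = np.zeros(n_goc, dtype=np.int64)
    for j in range(n_goc):
        cand = _in_range(tree, goc_pos[j], rules.goc_axon_radius)
        if cand.size > rules.goc_axon_max_glo:
            chosen = rng.choice(cand, size=rules.goc_axon_max_glo, replace=False)
        else:
            chosen = cand
        chosen = np.sort(chosen)
        glos_per_goc[j] = chosen.size
        axon_goc.extend([j] * chosen.size)
        axon_glo.extend(chosen.tolist())
        seen: set[int] = set()
        for g in chosen:
            for grc_id, slot in zip(by_glo_grc[g], by_glo_slot[g]):
                if grc_id in seen:
                    dropped_dups += 1
                    continue
                seen.add(int(grc_id))
                inh_goc.append(j)
                inh_grc.append(int(grc_id))
                inh_slot.append(int(slot))
    n_inh = len(inh_goc)
    delays = rng.uniform(rules.delay_min, rules.delay_max, size=n_inh)
    goc_glo = pd.DataFrame(
        {"goc": np.array(axon_goc, dtype=np.int64), "glo": np.array(axon_glo, dtype=np.int64)}
    )
    goc_grc_inh = pd.DataFrame(
        {
            "goc": np.array(inh_goc, dtype=np.int64),
            "grc": np.array(inh_grc, dtype=np.int64),
            "slot": np.array(inh_slot, dtype=np.int64),
            "delay": delays,
        }
    )
    audit = {
        "glos_per_goc_axon_min": int(glos_per_goc.min()) if n_goc else 0,
        "glos_per_goc_axon_mean": float(glos_per_goc.mean()) if n_goc else 0.0,
        "glos_per_goc_axon_max": int(glos_per_goc.max()) if n_goc else 0,
        "n_inhibitory_edges": n_inh,
        "n_duplicate_inhibition_dropped": dropped_dups,
    }
    return goc_glo, goc_grc_inh, audit


def connect_grc_to_goc(
    grc_pos: np.ndarray,
    goc_pos: np.ndarray,
    rules: RuleConfig,
    rng: np.random.Generator | int,
) -> tuple[pd.DataFrame, dict]:
    """Excite each GOC by 400 ascending axons and 1000 parallel fibers.

    Ascending-axon sources come from a vertical column (lateral distance
    to the GOC at most ``aa_lateral_radius``); parallel-fiber sources are
    sampled volume-wide.  Counts clip to the available GRCs with a logged
    warning.  Sources are distinct within each pathway; a GRC may appear
    in both (two anatomically distinct synapse sites).
    """
    rng = np.random.default_rng(rng)
    n_grc, n_goc = len(grc_pos), len(goc_pos)
    if n_grc == 0:
        raise ValueError("no GRCs to connect")
    lateral_axes = [a for a in range(3) if a != rules.vertical_axis]
    lat_tree = cKDTree(grc_pos[:, lateral_axes])
    frames = []
    aa_counts = np.zeros(n_goc, dtype=np.int64)
    pf_counts = np.zeros(n_goc, dtype=np.int64)
    clipped = 0
    for j in range(n_goc):
        col = np.asarray(
            lat_tree.query_ball_point(goc_pos[j, lateral_axes], rules.aa_lateral_radius),
            dtype=np.int64,
        )
        n_aa = min(rules.aa_per_goc, col.size)
        if n_aa < rules.aa_per_goc:
            clipped += 1
            logger.warning(
                "GOC %d: only %d GRCs in the ascending-axon column (need %d)",
                j,
                col.size,
                rules.aa_per_goc,
            )
        aa_src = rng.choice(col, size=n_aa, replace=False) if n_aa else np.empty(0, np.int64)
        n_pf = min(rules.pf_per_goc, n_grc)
        if n_pf < rules.pf_per_goc:
            clipped += 1
            logger.warning(
                "GOC %d: parallel-fiber sources clipped to %d of %d requested",
                j,
                n_pf,
                rules.pf_per_goc,
            )
        pf_src = rng.choice(n_grc, size=n_pf, replace=False)
        aa_counts[j], pf_counts[j] = n_aa, n_pf
        n_edges = n_aa + n_pf
        frames.append(
            pd.DataFrame(
                {
                    "grc": np.concatenate([np.sort(aa_src), np.sort(pf_src)]),
                    "goc": np.full(n_edges, j, dtype=np.int64),
                    "pathway": ["aa"] * n_aa + ["pf"] * n_pf,
                    "delay": rng.uniform(rules.delay_min, rules.delay_max, size=n_edges),
                }
            )
        )
    edges = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["grc", "goc", "pathway", "delay"]
    )
    audit = {
        "aa_per_goc_min": int(aa_counts.min()) if n_goc else 0,
        "aa_per_goc_max": int(aa_counts.max()) if n_goc else 0,
        "pf_per_goc_min": int(pf_counts.min()) if n_goc else 0,
        "pf_per_goc_max": int(pf_counts.max()) if n_goc else 0,
        "n_goc_source_clipped": clipped,
    }
    return edges, audit


def _validate(net: Network, rules: RuleConfig) -> None:
    """Hard invariants; a network violating any of them is never returned."""
    k = rules.grc_dendrites
    per_grc = net.grc_glo.groupby("grc")["glo"].nunique()
    if len(per_grc) != len(net.grc_pos) or per_grc.min() != k or per_grc.max() != k:
        raise AssertionError("exactly-%d-dendrites rule violated" % k)
    if net.grc_glo.duplicated(["grc", "glo"]).any():
        raise AssertionError("duplicate (GRC, GLO) dendrite")
    if net.goc_grc_inh.duplicated(["goc", "grc"]).any():
        raise AssertionError("a GRC is inhibited twice by the same GOC")
    if len(net.goc_glo):
        if net.goc_glo.groupby("goc")["glo"].nunique().max() > rules.goc_axon_max_glo:
            raise AssertionError("GOC axon exceeds max GLO targets")
    per_goc_dend = net.glo_goc.groupby("goc")["glo"].nunique()
    if len(per_goc_dend) and (
        per_goc_dend.min() != rules.glo_per_goc_dendrite
        or per_goc_dend.max() != rules.glo_per_goc_dendrite
    ):
        raise AssertionError("GOC dendritic GLO count rule violated")
    dup_path = net.grc_goc_exc.duplicated(["grc", "goc", "pathway"])
    if dup_path.any():
        raise AssertionError("duplicate source within an aa/pf pathway")


def build_network(
    volume: VolumeSpec,
    densities: DensityConfig | None = None,
    rules: RuleConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    counts: Counts | None = None,
) -> Network:
    """Run the five wiring stages and return an audited :class:`Network`.

    All randomness flows from ``seed`` through spawned, stage-specific
    streams, so identical (config, seed) gives identical networks.
    """
    densities = densities or DensityConfig()
    rules = rules or RuleConfig()
    if counts is None:
        counts = sample_counts(volume, densities)
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    s_place, s_dend, s_mf, s_gocd, s_axon, s_exc = ss.spawn(6)

    pos = place_cells(counts, volume, np.random.default_rng(s_place))
    glo_to_mf = assign_mfs(
        counts.n_glo, densities.mf_per_glo_ratio, np.random.default_rng(s_mf)
    )
    grc_glo, audit_d = connect_grc_dendrites(
        pos["grc"], pos["glo"], rules, np.random.default_rng(s_dend)
    )
    glo_goc, audit_g = connect_goc_dendrites(
        pos["goc"], pos["glo"], glo_to_mf, rules, np.random.default_rng(s_gocd)
    )
    goc_glo, goc_grc_inh, audit_a = connect_goc_axon(
        pos["goc"], pos["glo"], grc_glo, rules, np.random.default_rng(s_axon)
    )
    grc_goc_exc, audit_e = connect_grc_to_goc(
        pos["grc"], pos["goc"], rules, np.random.default_rng(s_exc)
    )

    audit = {
        "counts": counts._asdict(),
        **audit_d,
        **audit_g,
        **audit_a,
        **audit_e,
    }
    net = Network(
        volume=volume,
        grc_pos=pos["grc"],
        goc_pos=pos["goc"],
        glo_pos=pos["glo"],
        glo_to_mf=glo_to_mf,
        grc_glo=grc_glo,
        glo_goc=glo_goc,
        goc_glo=goc_glo,
        goc_grc_inh=goc_grc_inh,
        grc_goc_exc=grc_goc_exc,
        audit=audit,
    )
    _validate(net, rules)
    return net
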