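"""Pool design: who can be multiplexed without tags, and what a run costs.

Two specimens are compatible when their mitogenomes diverge enough to be
demultiplexed by sequence alone.  The default policy mirrors the
screening rule used throughout the toolkit: a Folmer-COI p-distance of
at least 15%, or — when a sliding-window profile is available — no
single 450 bp window below 5% divergence.  Pools are cliques of the
compatibility graph; a sample set is partitioned into the fewest runs by
colouring the incompatibility graph.

The run capacity calculator turns a sequencer's minimum throughput into
the number of complete mitogenomes per run, assuming 17,000 bp per
genome and an enrichment yielding 50% mitochondrial DNA at equimolarity.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import networkx as nx

from .mitoseq_io import MitoseqError
from . import divergence as dv

EXACT_CLIQUE_LIMIT = 25


@dataclass
class CompatPolicy:
    """Thresholds deciding whether a specimen pair may share a run."""

    coi_threshold: float = 0.15
    window_threshold: float = 0.05
    window_length: int = 450
    step: int = 45
    mode: str = "windows_preferred"  # proxy_only | windows_only | windows_preferred

    def __post_init__(self) -> None:
        for t in (self.coi_threshold, self.window_threshold):
            if not 0 < t < 1:
                raise MitoseqError(f"thresholds must lie in (0,1), got {t}")
        if self.mode not in ("proxy_only", "windows_only", "windows_preferred"):
            raise MitoseqError(f"unknown policy mode {self.mode!r}")


@dataclass
class PairEvidence:
    coi_proxy: float | None = None
    min_window: float | None = None
    window_length: int | None = None
    note: str = ""


@dataclass
class CompatibilityMatrix:
    ids: list[str]
    evidence: dict[frozenset, PairEvidence]
    compatible: dict[frozenset, bool]
    policy: CompatPolicy

    def is_compatible(self, a: str, b: str) -> bool:
        if a == b:
            return False
        return self.compatible[frozenset((a, b))]

    def pairs(self):
        return itertools.combinations(self.ids, 2)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.ids)
        g.add_edges_from(
            (a, b) for a, b in self.pairs() if self.is_compatible(a, b)
        )
        return g

    def incompatibility_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.ids)
        g.add_edges_from(
            (a, b) for a, b in self.pairs() if not self.is_compatible(a, b)
        )
        return g


@dataclass
class PoolPlan:
    members: list[str]
    min_pairwise: float | None
    policy: CompatPolicy


@dataclass
class RunSpec:
    """A sequencing run: minimum throughput (bp), cost per run, target coverage."""

    throughput_bp: float
    run_cost: float
    coverage: float
    genome_length_bp: float = 17_000
    mito_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("throughput_bp", "run_cost", "coverage", "genome_length_bp", "mito_fraction"):
            if getattr(self, name) <= 0:
                raise MitoseqError(f"RunSpec.{name} must be positive")


@dataclass
class CapacityResult:
    genomes_per_run: int
    cost_per_genome: float
    raw: float


# throughput (bp) and list cost per run for the desktop and high-throughput
# sequencers compared in the capacity table; coverage marks the depth the
# printed per-genome cost refers to
PLATFORM_PRESETS: dict[str, dict] = {
    "454 GS Junior": {"throughput_bp": 35e6, "run_cost": 1100, "cost_coverage": 20},
    "Ion Torrent PGM 314": {"throughput_bp": 10e6, "run_cost": 225, "cost_coverage": 50},
    "Ion Torrent PGM 316": {"throughput_bp": 100e6, "run_cost": 425, "cost_coverage": 50},
    "Ion Torrent PGM 318": {"throughput_bp": 1e9, "run_cost": 625, "cost_coverage": 50},
    "Illumina MiSeq": {"throughput_bp": 1.5e9, "run_cost": 750, "cost_coverage": 50},
    "Illumina HiSeq2000": {"throughput_bp": 600e9, "run_cost": 42000, "cost_coverage": 100},
    "Illumina HiSeq2000 1/15": {"throughput_bp": 40e9, "run_cost": 2800, "cost_coverage": 100},
}


# ---------------------------------------------------------------------------
# compatibility
# ---------------------------------------------------------------------------

def build_compatibility(
    genomes,
    policy: CompatPolicy | None = None,
    profiles: dict[frozenset, "dv.DivergenceProfile"] | None = None,
) -> CompatibilityMatrix:
    """Evaluate every specimen pair against the pooling policy.

    ``profiles`` maps frozenset({idA, idB}) to a precomputed sliding
    window profile.  In windows modes, pairs without a supplied profile
    are profiled by anchored alignment where possible; pairs with no
    usable evidence are conservatively incompatible ("insufficient data").
    """
    policy = policy or CompatPolicy()
    profiles = profiles or {}
    if len(genomes) < 2:
        raise MitoseqError("need at least 2 genomes to build a compatibility matrix")
    ids = [g.id for g in genomes]
    if len(set(ids)) != len(ids):
        raise MitoseqError("duplicate genome ids")
    by_id = {g.id: g for g in genomes}
    evidence: dict[frozenset, PairEvidence] = {}
    compatible: dict[frozenset, bool] = {}
    for a, b in itertools.combinations(ids, 2):
        key = frozenset((a, b))
        ev = PairEvidence(window_length=policy.window_length)
        if policy.mode in ("proxy_only", "windows_preferred"):
            try:
                ev.coi_proxy = dv.folmer_proxy(by_id[a], by_id[b])
            except MitoseqError as exc:
                ev.note = f"no COI proxy: {exc}"
        if policy.mode in ("windows_only", "windows_preferred"):
            prof = profiles.get(key)
            if prof is None and policy.mode == "windows_only":
                prof = _try_profile(by_id[a], by_id[b], policy)
            if prof is not None:
                ev.min_window = dv.min_window_divergence(prof)
        compatible[key] = _decide(ev, policy)
        if not compatible[key] and ev.coi_proxy is None and ev.min_window is None:
            ev.note = (ev.note + "; " if ev.note else "") + "insufficient data"
        evidence[key] = ev
    return CompatibilityMatrix(ids, evidence, compatible, policy)


def _try_profile(ga, gb, policy: CompatPolicy):
    try:
        return dv.profile_pair(ga, gb, policy.window_length, policy.step)
    except MitoseqError:
        return None


def _decide(ev: PairEvidence, policy: CompatPolicy) -> bool:
    if policy.mode == "proxy_only":
        return ev.coi_proxy is not None and ev.coi_proxy >= policy.coi_threshold
    if policy.mode == "windows_only":
        return ev.min_window is not None and ev.min_window >= policy.window_threshold
    if ev.min_window is not None:
        return ev.min_window >= policy.window_threshold
    return ev.coi_proxy is not None and ev.coi_proxy >= policy.coi_threshold


def _pair_metric(ev: PairEvidence) -> float | None:
    return ev.min_window if ev.min_window is not None else ev.coi_proxy


def _min_pairwise(matrix: CompatibilityMatrix, members) -> float | None:
    vals = [
        _pair_metric(matrix.evidence[frozenset(p)])
        for p in itertools.combinations(sorted(members), 2)
    ]
    vals = [v for v in vals if v is not None]
    return min(vals) if vals else None


# ---------------------------------------------------------------------------
# pool construction
# ---------------------------------------------------------------------------

def max_pool(matrix: CompatibilityMatrix, seed: int = 0) -> PoolPlan:
    """Largest mutually compatible pool (maximum clique).

    Exact (maximal-clique enumeration) up to 25 specimens; greedy with
    seeded local swaps above.  Ties break on the lexicographically
    smallest member list.
    """
    g = matrix.graph()
    if g.number_of_nodes() <= EXACT_CLIQUE_LIMIT:
        best: list[str] | None = None
        for clique in nx.find_cliques(g):
            cand = sorted(clique)
            if best is None or len(cand) > len(best) or (
                len(cand) == len(best) and cand < best
            ):
                best = cand
        members = best or []
    else:
        members = _greedy_clique(g, seed)
    return PoolPlan(members, _min_pairwise(matrix, members), matrix.policy)


def _greedy_clique(g: nx.Graph, seed: int) -> list[str]:
    rng = random.Random(seed)
    best: list[str] = []
    nodes = sorted(g.nodes)
    for start in nodes:
        clique = [start]
        order = sorted(g[start])
        rng.shuffle(order)
        for v in order:
            if all(g.has_edge(v, u) for u in clique):
                clique.append(v)
        # single-swap improvement: try replacing one member to admit two
        improved = True
        while improved:
            improved = False
            for v in nodes:
                if v in clique:
                    continue
                missing = [u for u in clique if not g.has_edge(v, u)]
                if len(missing) == 0:
                    clique.append(v)
                    improved = True
                elif len(missing) == 1:
                    cand = [u for u in clique if u != missing[0]] + [v]
                    ext = [
                        w
                        for w in nodes
                        if w not in cand and all(g.has_edge(w, u) for u in cand)
                    ]
                    if len(cand) + len(ext) > len(clique):
                        clique = cand + ext
                        improved = True
        if len(clique) > len(best) or (
            len(clique) == len(best) and sorted(clique) < sorted(best)
        ):
            best = sorted(clique)
    return best


def partition_pools(matrix: CompatibilityMatrix) -> list[PoolPlan]:
    """Partition all specimens into internally compatible pools.

    DSATUR colouring of the incompatibility graph; the returned list is
    ordered by decreasing pool size, then lexicographically.  The number
    of pools is at most (lower bound + small excess); the lower bound —
    the largest mutually incompatible set — is attached to each plan's
    policy snapshot via :func:`partition_lower_bound`.
    """
    inc = matrix.incompatibility_graph()
    colors = nx.coloring.greedy_color(inc, strategy="DSATUR")
    groups: dict[int, list[str]] = {}
    for node, c in colors.items():
        groups.setdefault(c, []).append(node)
    pools = [
        PoolPlan(sorted(members), _min_pairwise(matrix, members), matrix.policy)
        for members in groups.values()
    ]
    pools.sort(key=lambda p: (-len(p.members), p.members))
    return pools


def partition_lower_bound(matrix: CompatibilityMatrix) -> int:
    """Largest mutually incompatible set — no partition can use fewer pools."""
    inc = matrix.incompatibility_graph()
    if inc.number_of_nodes() <= EXACT_CLIQUE_LIMIT:
        return max((len(c) for c in nx.find_cliques(inc)), default=0)
    return len(_greedy_clique(inc, seed=0))


# ---------------------------------------------------------------------------
# run capacity and cost
# ---------------------------------------------------------------------------

def _half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def run_capacity(spec: RunSpec) -> CapacityResult:
    """Genomes per run and cost per genome for one sequencer configuration.

    raw = throughput x mito_fraction / (genome_length x coverage);
    the genome count is raw rounded half-up, the per-genome cost is the
    run cost divided by the *unrounded* quotient, rounded half-up to two
    decimals.
    """
    raw = spec.throughput_bp * spec.mito_fraction / (
        spec.genome_length_bp * spec.coverage
    )
    return CapacityResult(
        genomes_per_run=int(_half_up(raw)),
        cost_per_genome=_half_up(spec.run_cost / raw, 2),
        raw=raw,
    )


def capacity_table(coverages=(20, 50, 100)) -> list[dict]:
    """Capacity and cost rows for the built-in platform presets."""
    rows = []
    for name, preset in PLATFORM_PRESETS.items():
        row: dict = {"platform": name}
        for cov in coverages:
            res = run_capacity(
                RunSpec(preset["throughput_bp"], preset["run_cost"], cov)
            )
            row[f"genomes_{cov}x"] = res.genomes_per_run
            if cov == preset["cost_coverage"]:
                row["cost_per_genome"] = res.cost_per_genome
                row["cost_coverage"] = cov
        rows.append(row)
    return rows
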