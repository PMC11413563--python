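"""Semantic speech graphs.

Units of meaning in a narrative — content-word types or whole utterances —
are represented by embedding vectors; the graph links units whose pairwise
similarity ranks among the strongest.  Edge density is chosen per graph by
proportional thresholding: the lowest retention fraction on the grid
0.05, 0.10, ..., 0.80 whose graph has mean degree above 2*ln(N), the
sparsest graph still dense enough for small-world structure to be
measurable.  From the binarized graph we take closeness centrality, global
efficiency, the mean clustering coefficient, and the small-worldness
coefficient sigma against degree-preserving rewired nulls.

Because thresholding is proportional (rank-based), any strictly monotone
rescaling of the similarities — raw cosine, (cos+1)/2, min-max — yields
the identical graph; the normalization choice is immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "UnitSet",
    "UnitGraph",
    "SemanticMetrics",
    "THRESHOLD_GRID",
    "similarity_matrix",
    "select_threshold",
    "graph_metrics",
    "small_worldness",
    "analyze_narratives",
]

THRESHOLD_GRID = tuple(np.round(np.arange(0.05, 0.801, 0.05), 2))
MIN_UNITS = 4  # a small-world graph is not meaningful below four nodes


@dataclass
class UnitSet:
    """Labelled speech units with their embedding vectors."""

    labels: list[str]
    embeddings: np.ndarray
    level: str = "lexical"  # or "utterance"

    def __post_init__(self) -> None:
        self.embeddings = np.asarray(self.embeddings, dtype=float)
        if self.embeddings.ndim != 2 or self.embeddings.shape[0] != len(self.labels):
            raise ValueError("embeddings must be unit x dim with one row per label")
        if not np.all(np.isfinite(self.embeddings)):
            raise ValueError("embeddings must be finite")

    @property
    def n_units(self) -> int:
        return len(self.labels)


@dataclass
class UnitGraph:
    """Binarized similarity graph over speech units."""

    nodes: list[str]
    adjacency: np.ndarray
    threshold_used: float
    fallback: bool = False  # no grid value met the 2 ln N rule; 0.80 used

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / len(self.nodes)

    def to_networkx(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency)
        return nx.relabel_nodes(g, dict(enumerate(self.nodes)))


@dataclass
class SemanticMetrics:
    """Narrative-averaged semantic graph metrics (None = not computable)."""

    ent_num: float
    utt_num: float | None
    cc: float | None
    ge: float | None
    clustering: float | None
    sigma: float | None
    threshold: float | None
    n_narratives: int
    n_narratives_used: int


def similarity_matrix(units: UnitSet) -> np.ndarray:
    """Normalized cosine similarity ``(cos + 1) / 2`` between unit embeddings."""
    e = units.embeddings
    if units.n_units < 2:
        raise ValueError("need at least 2 units for a similarity matrix")
    norms = np.linalg.norm(e, axis=1)
    if np.any(norms == 0):
        bad = [units.labels[i] for i in np.flatnonzero(norms == 0)]
        raise ValueError(f"zero-norm embedding for unit(s): {', '.join(bad)}")
    cos = np.clip((e @ e.T) / np.outer(norms, norms), -1.0, 1.0)
    sim = (cos + 1.0) / 2.0
    np.fill_diagonal(sim, 1.0)
    return sim


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def select_threshold(sim: np.ndarray, labels: list[str] | None = None,
                     grid=THRESHOLD_GRID) -> tuple[UnitGraph, float]:
    """Pick the sparsest proportional threshold with mean degree > 2 ln N.

    Candidate t keeps the ``round(t * N(N-1)/2)`` strongest off-diagonal
    pairs (round half away from zero; ties broken by pair index, lower
    first).  The chosen threshold is the smallest grid value whose graph
    has ``2E/N > 2 ln N``; if none qualifies the densest grid value is
    used and the graph is flagged as a fallback.
    """
    sim = np.asarray(sim, dtype=float)
    n = sim.shape[0]
    if n < MIN_UNITS:
        raise ValueError(f"need at least {MIN_UNITS} units, got {n}")
    if labels is None:
        labels = [f"u{i}" for i in range(n)]
    iu, ju = np.triu_indices(n, k=1)
    vals = sim[iu, ju]
    # stable sort by descending similarity, then pair index order
    order = np.argsort(-vals, kind="stable")
    n_pairs = len(vals)
    target = 2.0 * np.log(n)

    def build(t: float) -> UnitGraph:
        e = min(_round_half_away(t * n_pairs), n_pairs)
        adj = np.zeros((n, n), dtype=int)
        sel = order[:e]
        adj[iu[sel], ju[sel]] = 1
        adj += adj.T
        return UnitGraph(nodes=list(labels), adjacency=adj, threshold_used=t)

    for t in grid:
        g = build(float(t))
        if g.mean_degree > target:
            return g, float(t)
    g = build(float(grid[-1]))
    g.fallback = True
    return g, float(grid[-1])


def graph_metrics(g: UnitGraph) -> tuple[float, float, float]:
    """(closeness centrality, global efficiency, mean clustering).

    Closeness uses the Wasserman-Faust correction for disconnected graphs
    (each node's closeness over its reachable set, scaled by the reachable
    fraction) and is averaged over nodes.  Global efficiency averages 1/d
    over ordered pairs with 0 for unreachable pairs.  Clustering is the
    mean local clustering coefficient (degree < 2 contributes 0).
    """
    gx = g.to_networkx()
    cc = float(np.mean(list(nx.closeness_centrality(gx, wf_improved=True).values())))
    ge = float(nx.global_efficiency(gx))
    clustering = float(nx.average_clustering(gx))
    return cc, ge, clustering


def _rewire(adj: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Degree-preserving Maslov-Sneppen rewiring with 10*E attempted swaps."""
    a = adj.copy()
    edges = np.argwhere(np.triu(a, k=1) == 1)
    e = len(edges)
    edges = [tuple(p) for p in edges]
    for _ in range(10 * e):
        i, j = rng.integers(0, e, size=2)
        if i == j:
            continue
        (u, v), (x, y) = edges[i], edges[j]
        # swap to (u, y), (x, v); reject self-loops and duplicate edges
        if len({u, v, x, y}) < 4:
            continue
        if a[u, y] or a[x, v]:
            continue
        a[u, v] = a[v, u] = 0
        a[x, y] = a[y, x] = 0
        a[u, y] = a[y, u] = 1
        a[x, v] = a[v, x] = 1
        edges[i] = (u, y)
        edges[j] = (x, v)
    return a


def _avg_path_largest_component(gx: nx.Graph) -> float:
    comp = max(nx.connected_components(gx), key=len)
    sub = gx.subgraph(comp)
    return float(nx.average_shortest_path_length(sub)) if len(comp) > 1 else np.nan


def small_worldness(g: UnitGraph, n_null: int = 20, seed: int = 0) -> float | None:
    """Small-worldness sigma = (C/<C_rand>) / (L/<L_rand>).

    Null graphs are degree-preserving rewirings (10*E attempted swaps
    each); L is the average shortest path length on the largest connected
    component.  Returns None when sigma is undefined (graph too small,
    disconnected, clustering 0 in all nulls).
    """
    gx = g.to_networkx()
    if len(g.nodes) < MIN_UNITS or not nx.is_connected(gx):
        return None
    c = nx.average_clustering(gx)
    length = _avg_path_largest_component(gx)
    rng = np.random.default_rng(seed)
    c_rand, l_rand = [], []
    for _ in range(n_null):
        null_adj = _rewire(g.adjacency, rng)
        null_gx = nx.from_numpy_array(null_adj)
        c_rand.append(nx.average_clustering(null_gx))
        l_rand.append(_avg_path_largest_component(null_gx))
    c_bar, l_bar = float(np.mean(c_rand)), float(np.nanmean(l_rand))
    if c_bar == 0 or not np.isfinite(l_bar) or l_bar == 0 or length == 0:
        return None
    return float((c / c_bar) / (length / l_bar))


def analyze_narratives(narratives: list[UnitSet], n_null: int = 20,
                       seed: int = 0) -> SemanticMetrics:
    """Per-narrative graph metrics averaged across a subject's narratives.

    Narratives with fewer than four units contribute to the unit counts
    but are excluded from the graph-metric averages; a sigma that is
    undefined for some narrative is excluded pairwise from the sigma mean.
    """
    if not narratives:
        raise ValueError("need at least one narrative")
    counts = [u.n_units for u in narratives]
    ent_num = float(np.mean(counts))
    utt_num = ent_num if narratives[0].level == "utterance" else None
    ccs, ges, cls, sigmas, thresholds = [], [], [], [], []
    used = 0
    for i, units in enumerate(narratives):
        if units.n_units < MIN_UNITS:
            continue
        used += 1
        sim = similarity_matrix(units)
        g, t = select_threshold(sim, labels=units.labels)
        cc, ge, clustering = graph_metrics(g)
        ccs.append(cc)
        ges.append(ge)
        cls.append(clustering)
        thresholds.append(t)
        s = small_worldness(g, n_null=n_null, seed=seed + i)
        if s is not None:
            sigmas.append(s)
    return SemanticMetrics(
        ent_num=ent_num,
        utt_num=utt_num,
        cc=float(np.mean(ccs)) if ccs else None,
        ge=float(np.mean(ges)) if ges else None,
        clustering=float(np.mean(cls)) if cls else None,
        sigma=float(np.mean(sigmas)) if sigmas else None,
        threshold=float(np.mean(thresholds)) if thresholds else None,
        n_narratives=len(narratives),
        n_narratives_used=used,
    )
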