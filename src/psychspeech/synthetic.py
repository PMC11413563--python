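"""Synthetic cohort generator.

Everything the pipeline consumes can be simulated here: ROI time series
with a planted unimodal-to-transmodal connectivity hierarchy and a
controllable group "compression" of that hierarchy, clustered unit
embeddings standing in for language-model vectors, probabilistic-grammar
constituency trees, and a matched subject table.

The fMRI generator plants its group effect at the level of network factor
correlations, never in gradient space, so that recovery by the gradient
pipeline is a genuine test of the downstream chain.  Each of seven
canonical resting-state networks has a latent standard-normal factor;
factors correlate according to a transmodality axis (unimodal VN/SMN at
one end, DMN at the other), and each ROI mixes the factors through a
fixed, deterministic "atlas" of loadings (see :func:`roi_loadings`) plus
white noise.  ``compression`` in [0, 1] moves the visual-DMN factor
correlation from the healthy baseline toward a high value (functional
distance collapses) while pulling the somatomotor-DMN correlation down —
the planted analogue of a compressed cortical hierarchy in psychosis.

Language group effects follow the same dial: patient-like narratives get a
more homogeneous embedding space (weaker cluster structure) and grammar
probabilities shifted toward verb-phrase chaining and away from noun-phrase
embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .semgraph import UnitSet
from .syntree import Tree

__all__ = [
    "NETWORKS",
    "TreeParams",
    "CohortSpec",
    "SyntheticCohort",
    "gen_timeseries",
    "gen_embeddings",
    "gen_trees",
    "gen_cohort",
]

NETWORKS = ("VN", "SMN", "DAN", "VAN", "LN", "FPN", "DMN")

#: Position of each network along the planted unimodal->transmodal axis.
_TRANSMODALITY = {"VN": 0.0, "SMN": 0.0, "DAN": 0.4, "VAN": 0.5,
                  "LN": 0.7, "FPN": 0.8, "DMN": 1.0}

_GROUP_CODE = {"HC": 0, "FEP": 1}


@dataclass
class TreeParams:
    """Grammar probabilities for the constituency-tree generator."""

    p_np_embed: float = 0.25
    p_vp_chain: float = 0.05
    mean_len: float = 12.0
    p_sbar: float = 0.10
    p_det: float = 0.9
    p_intrans: float = 0.1
    depth_cap: int = 12

    def __post_init__(self) -> None:
        for name in ("p_np_embed", "p_vp_chain", "p_sbar", "p_det", "p_intrans"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mean_len <= 0:
            raise ValueError("mean_len must be positive")


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults emulate the reference design: 29 subjects per group, three
    one-minute picture-description narratives each, a 7-network cortical
    parcellation, and a compression effect planted at the network-factor
    level.
    """

    n_per_group: int = 29
    n_rois: int = 100
    n_timepoints: int = 240
    compression: float = 0.8
    semantic_spread: float = 0.15
    tree_params: TreeParams = field(default_factory=TreeParams)
    seed: int = 0
    n_narratives: int = 3
    n_units_per_narrative: int = 24
    n_clusters: int = 4
    embedding_dim: int = 50
    n_utts_per_narrative: int = 8
    c0: float = 0.1       # healthy VN-DMN / SMN-DMN factor correlation
    c1: float = 0.6       # fully compressed VN-DMN factor correlation
    c_adjacent: float = 0.45  # factor correlation at zero transmodality distance
    noise_sd: float = 0.5
    roi_jitter: float = 0.3   # ROI spread around its network's axis position
    loading_tau: float = 0.2  # width of the ROI->factor loading kernel
    amp_hi: float = 1.7       # strongest (core) ROI signal amplitude
    amp_lo: float = 0.3       # weakest (periphery) ROI signal amplitude
    cross_max: float = 0.6    # strongest secondary network membership
    end_cross_max: float = 0.3  # strongest membership toward the opposite axis end

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_rois < 3 * len(NETWORKS):
            raise ValueError(f"n_rois must be >= {3 * len(NETWORKS)}")
        if self.n_timepoints <= self.n_rois / 5:
            raise ValueError("n_timepoints must exceed n_rois / 5")
        if not 0 <= self.compression <= 1:
            raise ValueError("compression must be in [0, 1]")
        if self.semantic_spread <= 0:
            raise ValueError("semantic_spread must be positive")

    @property
    def network_labels(self) -> list[str]:
        """Network assignment per ROI (contiguous, near-equal blocks)."""
        sizes = np.full(len(NETWORKS), self.n_rois // len(NETWORKS))
        sizes[: self.n_rois % len(NETWORKS)] += 1
        return [net for net, s in zip(NETWORKS, sizes) for _ in range(s)]

    @property
    def roi_labels(self) -> list[str]:
        counts: dict[str, int] = {}
        out = []
        for net in self.network_labels:
            counts[net] = counts.get(net, 0) + 1
            out.append(f"{net}_{counts[net]}")
        return out


@dataclass
class SyntheticCohort:
    """Bundled synthetic inputs for the full pipeline."""

    timeseries: dict[str, np.ndarray]            # subject id -> T x R
    embeddings: dict[str, list[UnitSet]]         # subject id -> per-narrative units
    trees: dict[str, list[list[str]]]            # subject id -> per-narrative strings
    subjects: pd.DataFrame                       # id, group, age, sex, education
    roi_labels: list[str]
    network_labels: list[str]


def _factor_correlation(spec: CohortSpec, group: str) -> np.ndarray:
    h = np.array([_TRANSMODALITY[n] for n in NETWORKS])
    dist = np.abs(h[:, None] - h[None, :])
    c = spec.c0 + (spec.c_adjacent - spec.c0) * (1.0 - dist)
    np.fill_diagonal(c, 1.0)
    iv, ism, idmn = NETWORKS.index("VN"), NETWORKS.index("SMN"), NETWORKS.index("DMN")
    # healthy baseline: both unimodal ends sit at c0 from the DMN
    c[iv, idmn] = c[idmn, iv] = spec.c0
    c[ism, idmn] = c[idmn, ism] = spec.c0
    if group == "FEP":
        vn_dmn = spec.c0 + spec.compression * (spec.c1 - spec.c0)
        smn_dmn = spec.c0 - spec.compression * spec.c0 * 0.8
        c[iv, idmn] = c[idmn, iv] = vn_dmn
        c[ism, idmn] = c[idmn, ism] = smn_dmn
    return c


_PHI = (np.sqrt(5.0) - 1.0) / 2.0  # golden-ratio fraction for low-discrepancy grades


def roi_loadings(spec: CohortSpec) -> np.ndarray:
    """R x 7 loading matrix of ROIs onto the network factors — the "atlas".

    The atlas is deterministic (a parcellation is a fixed property of the
    study, shared by both groups, all subjects, and all cohort seeds) and
    mimics three well-known features of real parcellations, without which
    row sparsification of FC would erase all between-network structure:

    * a transmodality axis: each ROI sits at its network's axis position
      plus an evenly spaced within-network offset and loads on every
      network factor through a Gaussian kernel in axis distance, so
      connectivity profiles vary smoothly along the hierarchy;
    * core-periphery amplitude: within each network, ROI signal strength
      falls linearly from ``amp_hi`` to ``amp_lo``, so within-network
      correlations span a wide range rather than being uniformly high;
    * connector heterogeneity: every ROI carries a secondary membership in
      another network (targets cycle over the other six; magnitudes follow
      a low-discrepancy golden-ratio grade up to ``cross_max``), and ROIs
      of networks at the axis extremes additionally carry a graded
      membership in the opposite-end network (up to ``end_cross_max``) —
      the synthetic analogue of connector hubs, which is what lets a
      change in end-to-end factor correlation move edges across the
      row-sparsification threshold.
    """
    nets = spec.network_labels
    h = np.array([_TRANSMODALITY[n] for n in NETWORKS])
    n = spec.n_rois
    w = np.zeros((n, len(NETWORKS)))
    amp = np.empty(n)
    pos = np.empty(n)
    net_arr = np.array(nets)
    for ni, net in enumerate(NETWORKS):
        idx = np.flatnonzero(net_arr == net)
        m = len(idx)
        pos[idx] = _TRANSMODALITY[net] + np.linspace(-spec.roi_jitter, spec.roi_jitter, m)
        amp[idx] = np.linspace(spec.amp_hi, spec.amp_lo, m)
        hn = _TRANSMODALITY[net]
        opp = NETWORKS.index("DMN") if hn < 0.5 else NETWORKS.index("VN")
        for r, i in enumerate(idx):
            others = [k for k in range(len(NETWORKS)) if k != ni]
            w[i, others[r % len(others)]] += spec.cross_max * ((r * _PHI) % 1.0)
            if abs(hn - h[opp]) >= 0.5:
                w[i, opp] += spec.end_cross_max * (((r + 3) * _PHI) % 1.0)
    w += np.exp(-((pos[:, None] - h[None, :]) ** 2) / (2.0 * spec.loading_tau**2))
    w /= np.linalg.norm(w, axis=1, keepdims=True)
    return w * amp[:, None]


def population_covariance(spec: CohortSpec, group: str) -> np.ndarray:
    """Exact ROI covariance implied by the generative model, ``W C W' + s^2 I``."""
    c = _factor_correlation(spec, group)
    w = roi_loadings(spec)
    return w @ c @ w.T + spec.noise_sd**2 * np.eye(spec.n_rois)


def gen_timeseries(spec: CohortSpec, group: str) -> dict[str, np.ndarray]:
    """Per-subject time x ROI matrices for one group.

    Each time point draws the seven correlated network factors; ROI i is
    its loading-weighted combination of the factors plus iid noise of
    scale ``noise_sd``.  The groups are matched by common random numbers:
    subject s of either group uses the identical latent factor and noise
    stream, so the only difference between groups is the planted factor
    correlation structure (at ``compression = 0`` the groups are
    byte-identical).  Deterministic given ``spec.seed``.  Raises if the
    implied factor correlation matrix is not positive definite (e.g.
    extreme c0/c1 overrides).
    """
    if group not in _GROUP_CODE:
        raise ValueError(f"group must be one of {sorted(_GROUP_CODE)}")
    c = _factor_correlation(spec, group)
    try:
        chol = np.linalg.cholesky(c)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "factor correlation matrix is not positive definite for "
            f"group={group!r} (c0={spec.c0}, c1={spec.c1}, "
            f"c_adjacent={spec.c_adjacent}, compression={spec.compression}); "
            "reduce the planted correlations"
        ) from err
    w = roi_loadings(spec)
    out: dict[str, np.ndarray] = {}
    for s in range(spec.n_per_group):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, s, 11]))
        z = rng.standard_normal((spec.n_timepoints, len(NETWORKS)))
        factors = z @ chol.T
        noise = rng.standard_normal((spec.n_timepoints, spec.n_rois))
        out[f"{group}{s + 1:03d}"] = factors @ w.T + spec.noise_sd * noise
    return out


def gen_embeddings(n_units: int, n_clusters: int, spread: float, dim: int = 50,
                   seed: int = 0) -> np.ndarray:
    """Clustered unit embeddings on the unit sphere.

    Cluster centers are drawn uniformly on the sphere; each unit is its
    cluster center plus isotropic Gaussian noise of scale ``spread``, then
    L2-normalized.  Small spread gives tight, well-separated semantic
    clusters; large spread approaches a homogeneous (unstructured) space.
    """
    if n_units < 4:
        raise ValueError("need at least 4 units (smaller graphs are rejected downstream)")
    if n_clusters < 1 or n_clusters > n_units:
        raise ValueError("n_clusters must be in [1, n_units]")
    if spread < 0:
        raise ValueError("spread must be nonnegative")
    rng = np.random.default_rng(seed)
    centers = rng.standard_normal((n_clusters, dim))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    assign = np.arange(n_units) % n_clusters
    e = centers[assign] + spread * rng.standard_normal((n_units, dim))
    norms = np.linalg.norm(e, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return e / norms


def _gen_np(rng: np.random.Generator, p: TreeParams, depth: int) -> Tree:
    if depth < p.depth_cap and rng.random() < p.p_np_embed:
        inner = _gen_np(rng, p, depth + 2)
        pp = Tree("PP", [Tree("IN"), _gen_np(rng, p, depth + 2)])
        return Tree("NP", [inner, pp])
    children = [Tree("NN")]
    if rng.random() < p.p_det:
        children.insert(0, Tree("DT"))
    return Tree("NP", children)


def _gen_vp(rng: np.random.Generator, p: TreeParams, depth: int) -> Tree:
    if depth < p.depth_cap and rng.random() < p.p_vp_chain:
        return Tree("VP", [Tree("ADVP", [Tree("RB")]), _gen_vp(rng, p, depth + 1)])
    if rng.random() < p.p_intrans:
        return Tree("VP", [Tree("VB")])
    if depth < p.depth_cap and rng.random() < p.p_sbar:
        return Tree("VP", [Tree("VB"), Tree("SBAR", [_gen_clause(rng, p, depth + 2)])])
    return Tree("VP", [Tree("VB"), _gen_np(rng, p, depth + 1)])


def _gen_clause(rng: np.random.Generator, p: TreeParams, depth: int = 1) -> Tree:
    return Tree("S", [_gen_np(rng, p, depth + 1), _gen_vp(rng, p, depth + 1)])


def expected_clause_length(params: TreeParams) -> float:
    """Expected token count of one clause under the grammar (fixed point)."""
    p, pc, ps = params.p_np_embed, params.p_vp_chain, params.p_sbar
    pd, pi = params.p_det, params.p_intrans
    e_np = (p + (1.0 - p) * (1.0 + pd)) / max(1.0 - 2.0 * p, 1e-3)
    e_s = e_np + 2.0  # initial guess
    for _ in range(20):
        head = pi * 1.0 + (1.0 - pi) * (ps * (1.0 + e_s) + (1.0 - ps) * (1.0 + e_np))
        e_vp = (pc + (1.0 - pc) * head) / max(1.0 - pc, 1e-3)
        e_s = min(e_np + e_vp, 4.0 * params.mean_len)
    return e_s


def gen_trees(n_utts: int, params: TreeParams, seed: int = 0) -> list[str]:
    """Bracketed constituency trees from a small probabilistic grammar.

    Utterances are one or more coordinated clauses (S -> NP VP); NP
    embedding (NP -> NP PP) fires with ``p_np_embed``, adverbial VP
    chaining (VP -> ADVP VP, one added word per level) with
    ``p_vp_chain``, clausal complements with ``p_sbar``.  Recursion is capped at ``depth_cap``, where categories
    fall back to terminal expansions.  ``mean_len`` sets the expected
    utterance length: the number of coordinated clauses adapts to the
    expected clause length under the grammar, so a grammar of short,
    simple clauses yields run-on coordination (more clauses) at the same
    overall utterance length.  Every string parses back losslessly.
    """
    rng = np.random.default_rng(seed)
    out = []
    e_len = expected_clause_length(params)
    lam = max(0.0, (params.mean_len - e_len) / (e_len + 1.0))
    for _ in range(n_utts):
        n_clauses = 1 + rng.poisson(lam)
        clauses = [_gen_clause(rng, params) for _ in range(n_clauses)]
        if n_clauses == 1:
            root = clauses[0]
        else:
            children: list[Tree] = []
            for i, cl in enumerate(clauses):
                if i:
                    children.append(Tree("CC"))
                children.append(cl)
            root = Tree("S", children)
        out.append(root.serialize())
    return out


def _fep_tree_params(p: TreeParams, compression: float) -> TreeParams:
    """Patient-like grammar shift, scaled by the compression dial.

    More auxiliary chaining and clause coordination, less noun-phrase
    embedding and clausal complementation, barer noun phrases: the same
    amount of speech built from more, shorter, simpler pieces.
    """
    return TreeParams(
        p_np_embed=p.p_np_embed * (1.0 - 0.75 * compression),
        p_vp_chain=p.p_vp_chain + compression * (0.675 - p.p_vp_chain),
        mean_len=p.mean_len,
        p_sbar=p.p_sbar * (1.0 - 0.625 * compression),
        p_det=p.p_det * (1.0 - 0.833 * compression),
        p_intrans=p.p_intrans + compression * (0.475 - p.p_intrans),
        depth_cap=p.depth_cap,
    )


def gen_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Full synthetic cohort: time series, embeddings, trees, covariates.

    Group effects all scale with ``spec.compression``; covariates are
    generated independently of group (a matched design).  Deterministic
    given ``spec.seed``.
    """
    timeseries: dict[str, np.ndarray] = {}
    embeddings: dict[str, list[UnitSet]] = {}
    trees: dict[str, list[list[str]]] = {}
    rows = []
    cov_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    for group in ("HC", "FEP"):
        timeseries.update(gen_timeseries(spec, group))
        spread = spec.semantic_spread
        tp = spec.tree_params
        if group == "FEP":
            # patient-like: more homogeneous semantic space, shifted grammar
            spread = spec.semantic_spread * (1.0 + 3.0 * spec.compression)
            tp = _fep_tree_params(spec.tree_params, spec.compression)
        for s in range(spec.n_per_group):
            sid = f"{group}{s + 1:03d}"
            base = np.random.SeedSequence([spec.seed, _GROUP_CODE[group], s, 23])
            sub_seeds = base.generate_state(2 * spec.n_narratives)
            embeddings[sid] = [
                UnitSet(
                    labels=[f"w{j}" for j in range(spec.n_units_per_narrative)],
                    embeddings=gen_embeddings(
                        spec.n_units_per_narrative, spec.n_clusters, spread,
                        dim=spec.embedding_dim, seed=int(sub_seeds[2 * k] % 2**31),
                    ),
                )
                for k in range(spec.n_narratives)
            ]
            trees[sid] = [
                gen_trees(spec.n_utts_per_narrative, tp,
                          seed=int(sub_seeds[2 * k + 1] % 2**31))
                for k in range(spec.n_narratives)
            ]
            rows.append({
                "id": sid,
                "group": group,
                "age": float(cov_rng.normal(21.5, 3.0)),
                "sex": int(cov_rng.random() < 0.26),
                "education": int(cov_rng.random() < 0.6),
            })
    subjects = pd.DataFrame(rows)
    return SyntheticCohort(
        timeseries=timeseries, embeddings=embeddings, trees=trees,
        subjects=subjects, roi_labels=spec.roi_labels,
        network_labels=spec.network_labels,
    )
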