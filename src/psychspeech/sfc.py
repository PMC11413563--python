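"""Stepwise functional connectivity (SFC).

SFC characterizes how connectivity from a seed region reaches the rest of
the cortex through progressively longer chains of links.  The FC matrix is
binarized by the statistical significance of each correlation (BH-FDR over
the unique ROI pairs, positive correlations only), and the step-k SFC
degree of a region j is the number of length-k walks from the seed set to
j in that binary graph — computed as seed-row sums of the k-th adjacency
power.  Walks (which may revisit nodes) are what adjacency powers count;
counting simple paths instead is computationally intractable and is not
what the seed-based SFC literature computes.

Subject maps are min-max normalized per step and multiplied by the
group-level map for robustness; convergence across steps is detected by
the spatial correlation of consecutive step maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .gradients import ConnectivityMatrix
from .stats import bh_fdr

__all__ = [
    "BinaryGraph",
    "SFCMap",
    "binarize_fc",
    "sfc_degrees",
    "normalize_map",
    "combine_subject_group",
    "convergence_step",
]


@dataclass
class BinaryGraph:
    """Significance-binarized FC graph (0/1 symmetric, zero diagonal)."""

    adjacency: np.ndarray
    q_threshold: float
    roi_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)


@dataclass
class SFCMap:
    """Per-step SFC degree vectors from a seed set.

    ``degrees[k - 1]`` holds the step-k degrees.  Raw maps are nonnegative
    integers; normalized maps are in [0, 1].
    """

    seeds: list[int]
    degrees: np.ndarray  # steps x R
    normalized: bool = False
    roi_labels: list[str] | None = None

    @property
    def n_steps(self) -> int:
        return self.degrees.shape[0]


def binarize_fc(fc: ConnectivityMatrix, n_timepoints: int | None = None,
                q: float = 0.001) -> BinaryGraph:
    """Binarize an FC matrix by FDR-corrected correlation significance.

    Two-sided p-values come from ``t = r * sqrt((n - 2) / (1 - r^2))`` on
    the raw correlation (recovered as ``tanh(z)``); BH-FDR runs over the
    R(R-1)/2 unique pairs; an edge requires ``q_value < q`` AND ``r > 0``.
    """
    n = n_timepoints if n_timepoints is not None else fc.n_timepoints_used
    if n <= 3:
        raise ValueError("need more than 3 time points for correlation p-values")
    z = fc.values
    r_mat = np.tanh(z)
    iu = np.triu_indices_from(r_mat, k=1)
    r = r_mat[iu]
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    qv = bh_fdr(p)
    edge = (qv < q) & (r > 0)
    adj = np.zeros_like(r_mat, dtype=int)
    adj[iu] = edge.astype(int)
    adj = adj + adj.T
    return BinaryGraph(adjacency=adj, q_threshold=q, roi_labels=fc.roi_labels)


def _seed_indices(g: BinaryGraph, seeds) -> list[int]:
    if len(seeds) == 0:
        raise ValueError("seed set must be non-empty")
    if all(isinstance(s, (int, np.integer)) for s in seeds):
        return [int(s) for s in seeds]
    if g.roi_labels is None:
        raise ValueError("graph has no ROI labels; pass integer seed indices")
    pos = {lab: i for i, lab in enumerate(g.roi_labels)}
    missing = [s for s in seeds if s not in pos]
    if missing:
        raise ValueError(f"unknown seed ROI(s): {', '.join(map(str, missing))}")
    return [pos[s] for s in seeds]


def sfc_degrees(g: BinaryGraph, seeds, max_steps: int = 6) -> SFCMap:
    """Exact-length walk counts from a seed set, one row per step.

    ``degrees[k, j] = sum_{s in seeds} (A^k)[s, j]``, computed by iterated
    vector-matrix products (A^k is never materialized).
    """
    idx = _seed_indices(g, seeds)
    a = g.adjacency.astype(float)
    r = a.shape[0]
    v = np.zeros(r)
    v[idx] = 1.0  # counts duplicate seeds once each if repeated
    out = np.empty((max_steps, r))
    for k in range(max_steps):
        v = v @ a
        out[k] = v
    return SFCMap(seeds=idx, degrees=out, normalized=False, roi_labels=g.roi_labels)


def normalize_map(m: SFCMap) -> SFCMap:
    """Min-max scale each step map into [0, 1] (constant steps map to 0)."""
    deg = m.degrees.astype(float).copy()
    for k in range(deg.shape[0]):
        lo, hi = deg[k].min(), deg[k].max()
        if hi == lo:
            deg[k] = 0.0
        else:
            deg[k] = (deg[k] - lo) / (hi - lo)
    return replace(m, degrees=deg, normalized=True)


def combine_subject_group(subject: SFCMap, group: SFCMap) -> SFCMap:
    """Element-wise product of normalized subject and group maps."""
    if not (subject.normalized and group.normalized):
        raise ValueError("both maps must be normalized before combining")
    if subject.degrees.shape != group.degrees.shape:
        raise ValueError("subject and group maps must share shape")
    return replace(subject, degrees=subject.degrees * group.degrees)


def convergence_step(m: SFCMap, r_threshold: float = 0.999) -> tuple[int, bool]:
    """First step whose map correlates > ``r_threshold`` with the next one.

    Returns ``(step, converged)``; if no consecutive pair exceeds the
    threshold, ``(n_steps, False)``.  A step with zero variance makes the
    comparison undefined; it is skipped with a warning and its correlation
    treated as 0.
    """
    deg = m.degrees
    if deg.shape[0] < 2:
        raise ValueError("need at least 2 steps to assess convergence")
    for k in range(deg.shape[0] - 1):
        x, y = deg[k], deg[k + 1]
        if x.std() == 0 or y.std() == 0:
            warnings.warn(
                f"zero-variance SFC map at step {k + 1} or {k + 2}; "
                "correlation treated as 0",
                stacklevel=2,
            )
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if r > r_threshold:
            return k + 1, True
    return deg.shape[0], False
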