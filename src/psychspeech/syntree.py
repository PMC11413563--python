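"""Constituency-tree syntax metrics.

Utterances arrive as Penn-style bracketed constituency trees whose leaves
are part-of-speech preterminals, one per token (an optional token string
after the POS tag is accepted and preserved for round-tripping).  Each
tree is normalized — punctuation leaves removed, then right-factored
binarization so no node has more than two children — and summarized by:

* production quantity: number of leaves (words), total nodes, and the
  phrase fraction (phrasal nodes per leaf);
* hierarchical complexity: the per-token depth series (edges from the root
  to each leaf, on the binarized tree), its maximum, mean, and approximate
  entropy (Pincus ApEn, a regularity statistic — low values mean the depth
  of the next token is predictable from recent ones);
* NP/VP structure: counts, nesting ratios (share of NPs/VPs properly
  dominating another of the same category), and mean phrase length in
  words.

Binarization intermediates (labels containing ``|``) are artifacts of the
normal form: they deepen leaves uniformly but are never counted as nodes,
phrases, NPs or VPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Tree",
    "SyntaxMetrics",
    "PUNCT_LABELS",
    "parse_bracketed",
    "strip_punctuation",
    "binarize",
    "depth_series",
    "approx_entropy",
    "phrase_metrics",
    "utterance_metrics",
    "aggregate",
]

#: Penn Treebank punctuation POS tags.
PUNCT_LABELS = frozenset({".", ",", ":", "``", "''", "-LRB-", "-RRB-", "HYPH", "SYM"})

_METRIC_FIELDS = (
    "leaf_num", "nodes", "phrase_fraction", "depth", "depth_mean", "depth_apen",
    "np_count", "np_nest", "np_length", "vp_count", "vp_nest", "vp_length",
)


@dataclass
class Tree:
    """Rooted ordered labelled tree; a node with no children is a leaf
    (a POS preterminal), optionally carrying its surface token."""

    label: str
    children: list["Tree"] = field(default_factory=list)
    token: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Tree"]:
        if self.is_leaf:
            return [self]
        out: list[Tree] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def descendants(self) -> list["Tree"]:
        out: list[Tree] = []
        for c in self.children:
            out.append(c)
            out.extend(c.descendants())
        return out

    def serialize(self) -> str:
        if self.is_leaf:
            inner = f"{self.label} {self.token}" if self.token is not None else self.label
            return f"({inner})"
        return f"({self.label} " + " ".join(c.serialize() for c in self.children) + ")"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.serialize()


class ParseError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} at offset {position}")
        self.position = position


def parse_bracketed(text: str) -> Tree:
    """Parse one bracketed tree; round-trips losslessly up to whitespace."""
    s = text.strip()
    if not s:
        raise ParseError("empty input", 0)
    pos = 0

    def skip_ws(i: int) -> int:
        while i < len(s) and s[i].isspace():
            i += 1
        return i

    def read_token(i: int) -> tuple[str, int]:
        j = i
        while j < len(s) and not s[j].isspace() and s[j] not in "()":
            j += 1
        if j == i:
            raise ParseError("expected a label", i)
        return s[i:j], j

    def read_node(i: int) -> tuple[Tree, int]:
        if i >= len(s) or s[i] != "(":
            raise ParseError("expected '('", i)
        i = skip_ws(i + 1)
        label, i = read_token(i)
        node = Tree(label)
        i = skip_ws(i)
        while i < len(s) and s[i] != ")":
            if s[i] == "(":
                child, i = read_node(i)
                node.children.append(child)
            else:
                tok, i = read_token(i)
                if node.token is not None or node.children:
                    raise ParseError("unexpected token", i - len(tok))
                node.token = tok
            i = skip_ws(i)
        if i >= len(s):
            raise ParseError("unbalanced parentheses", len(s))
        return node, i + 1

    root, pos = read_node(skip_ws(pos))
    pos = skip_ws(pos)
    if pos != len(s):
        raise ParseError("trailing content", pos)
    return root


def strip_punctuation(t: Tree, punct_labels=PUNCT_LABELS) -> Tree | None:
    """Remove punctuation leaves; prune internal nodes left childless.

    Returns None when the whole tree collapses (punctuation-only input).
    """
    if t.is_leaf:
        return None if t.label in punct_labels else Tree(t.label, token=t.token)
    kept = [c for c in (strip_punctuation(c, punct_labels) for c in t.children) if c]
    if not kept:
        return None
    return Tree(t.label, kept)


def binarize(t: Tree) -> Tree:
    """Right-factored binarization; intermediates are labelled ``parent|<...>``."""
    if t.is_leaf:
        return Tree(t.label, token=t.token)
    children = [binarize(c) for c in t.children]
    if len(children) <= 2:
        return Tree(t.label, children)
    head = t.label.split("|")[0]
    rest_labels = "-".join(c.label for c in children[1:])
    inter = binarize(Tree(f"{head}|<{rest_labels}>", children[1:]))
    return Tree(t.label, [children[0], inter])


def depth_series(t: Tree) -> list[int]:
    """Edges from the root to each leaf, in surface (left-to-right) order."""
    out: list[int] = []

    def walk(node: Tree, d: int) -> None:
        if node.is_leaf:
            out.append(d)
        else:
            for c in node.children:
                walk(c, d + 1)

    walk(t, 0)
    return out


def approx_entropy(series, m: int = 2, r_factor: float = 0.2) -> float | None:
    """Pincus approximate entropy ApEn(m, r) with r = r_factor * SD.

    Self-matches are included; a constant series has ApEn 0; series shorter
    than m + 2 return None (not computable).
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < m + 2:
        return None
    sd = x.std()  # population SD
    if sd == 0:
        return 0.0
    r = r_factor * sd

    def phi(k: int) -> float:
        n_win = n - k + 1
        win = np.lib.stride_tricks.sliding_window_view(x, k)
        # Chebyshev distance between all window pairs
        d = np.max(np.abs(win[:, None, :] - win[None, :, :]), axis=2)
        c = (d <= r).sum(axis=1) / n_win
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def _base_label(label: str) -> str:
    """Category label with functional annotations stripped (NP-SBJ -> NP)."""
    return label.split("-")[0].split("=")[0]


def _is_intermediate(label: str) -> bool:
    return "|" in label


def phrase_metrics(t: Tree) -> dict:
    """Phrase and NP/VP measures of a punctuation-stripped tree.

    Binarization intermediates never count; results are identical whether
    the input is binarized or not.  Ratios over an empty NP/VP set are
    None, not 0.
    """
    leaves = t.leaves()
    all_nodes = [t] + t.descendants()
    real = [n for n in all_nodes if not _is_intermediate(n.label)]
    phrases = [n for n in real if not n.is_leaf]
    out = {
        "leaf_num": float(len(leaves)),
        "nodes": float(len(real)),
        "phrase_fraction": len(phrases) / len(leaves),
    }
    for cat in ("NP", "VP"):
        members = [n for n in real if not n.is_leaf and _base_label(n.label) == cat]
        out[f"{cat.lower()}_count"] = float(len(members))
        if members:
            nested = sum(
                1 for n in members
                if any(not d.is_leaf and not _is_intermediate(d.label)
                       and _base_label(d.label) == cat for d in n.descendants())
            )
            out[f"{cat.lower()}_nest"] = nested / len(members)
            out[f"{cat.lower()}_length"] = float(np.mean([len(n.leaves()) for n in members]))
        else:
            out[f"{cat.lower()}_nest"] = None
            out[f"{cat.lower()}_length"] = None
    return out


@dataclass
class SyntaxMetrics:
    """Per-utterance (or aggregated) syntax measures; None = missing."""

    leaf_num: float | None = None
    nodes: float | None = None
    phrase_fraction: float | None = None
    depth: float | None = None
    depth_mean: float | None = None
    depth_apen: float | None = None
    np_count: float | None = None
    np_nest: float | None = None
    np_length: float | None = None
    vp_count: float | None = None
    vp_nest: float | None = None
    vp_length: float | None = None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in _METRIC_FIELDS}


def utterance_metrics(text: str, punct_labels=PUNCT_LABELS, m: int = 2,
                      r_factor: float = 0.2) -> SyntaxMetrics | None:
    """All Table-of-measures metrics for one bracketed utterance.

    Depth and its ApEn are computed on the binarized, punctuation-stripped
    tree; phrase/NP/VP metrics exclude binarization intermediates.  Returns
    None for an utterance that collapses entirely (punctuation only).
    """
    stripped = strip_punctuation(parse_bracketed(text), punct_labels)
    if stripped is None:
        return None
    binary = binarize(stripped)
    depths = depth_series(binary)
    pm = phrase_metrics(stripped)
    return SyntaxMetrics(
        depth=float(max(depths)),
        depth_mean=float(np.mean(depths)),
        depth_apen=approx_entropy(depths, m=m, r_factor=r_factor),
        **pm,
    )


def aggregate(per_narrative: list[list[SyntaxMetrics | None]]) -> SyntaxMetrics:
    """Two-stage mean: utterances within narrative, then across narratives.

    Missing values (None) are excluded pairwise at each stage; a metric
    missing everywhere stays missing.
    """
    if not any(per_narrative):
        raise ValueError("need at least one utterance")
    agg: dict[str, float | None] = {}
    for name in _METRIC_FIELDS:
        narr_means = []
        for utts in per_narrative:
            vals = [getattr(u, name) for u in utts if u is not None and getattr(u, name) is not None]
            if vals:
                narr_means.append(float(np.mean(vals)))
        agg[name] = float(np.mean(narr_means)) if narr_means else None
    return SyntaxMetrics(**agg)
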