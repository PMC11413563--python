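"""Functional-connectivity gradients of cortical organization.

The stage chain implemented here turns regional fMRI time series into a
low-dimensional "gradient" representation of the cortical functional
hierarchy:

1. pairwise Pearson correlation of ROI time series, Fisher z-transformed
   (:func:`compute_fc`);
2. row-wise sparsification keeping only the strongest positive connections
   (:func:`sparsify_rows`);
3. a cosine-based affinity kernel between connectivity profiles
   (:func:`affinity`);
4. diffusion-map embedding of the affinity matrix
   (:class:`DiffusionGradients`), whose first component (G1) spans the
   unimodal (sensorimotor) to transmodal (default-mode) axis;
5. orthogonal Procrustes alignment of subject-level gradients to a group
   template (:class:`ProcrustesAlignment`);
6. dispersion statistics quantifying between-network separation and
   within-network spread in gradient space.

The same chain applies unchanged to an ROI subset (e.g. a left-hemisphere
semantic network).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ConnectivityMatrix",
    "GradientSet",
    "compute_fc",
    "sparsify_rows",
    "affinity",
    "DiffusionGradients",
    "ProcrustesAlignment",
    "diffusion_gradients",
    "align_gradients",
    "dispersion_between",
    "dispersion_within",
    "fit_cohort_gradients",
]

#: |r| is clipped here before arctanh so perfect correlations stay finite.
R_CLIP = 0.999999


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI matrix of Fisher z-transformed correlations."""

    values: np.ndarray
    roi_labels: list[str]
    n_timepoints_used: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if len(self.roi_labels) != self.values.shape[0]:
            raise ValueError("roi_labels length must match matrix size")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class GradientSet:
    """ROI x K gradient coordinates with eigenvalue bookkeeping.

    ``coords[:, 0]`` is G1, ``coords[:, 1]`` is G2, and so on.
    ``variance_explained`` holds each retained eigenvalue as a fraction of
    the positive non-trivial spectrum.
    """

    coords: np.ndarray
    lambdas: np.ndarray
    variance_explained: np.ndarray
    roi_labels: list[str] | None = None
    aligned_to: str | None = None

    @property
    def n_rois(self) -> int:
        return self.coords.shape[0]

    @property
    def n_gradients(self) -> int:
        return self.coords.shape[1]


def compute_fc(ts: np.ndarray, roi_labels: list[str] | None = None) -> ConnectivityMatrix:
    """Fisher z-transformed Pearson correlation matrix of a time x ROI array.

    Correlations are clipped to ``+-R_CLIP`` before ``arctanh`` and the
    diagonal is set to zero.  A constant column is an error (its correlation
    is undefined) and is reported by ROI name.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be a 2-D time x ROI array")
    n_t, n_r = ts.shape
    if n_t < 4:
        raise ValueError(f"need at least 4 time points, got {n_t}")
    if roi_labels is None:
        roi_labels = [f"roi{i}" for i in range(n_r)]
    sd = ts.std(axis=0)
    if np.any(sd == 0):
        bad = [roi_labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant time series for ROI(s): {', '.join(bad)}")
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip(r, -R_CLIP, R_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0  # enforce exact symmetry against fp noise
    return ConnectivityMatrix(values=z, roi_labels=list(roi_labels), n_timepoints_used=n_t)


def sparsify_rows(values: np.ndarray, keep_fraction: float = 0.10) -> np.ndarray:
    """Zero negatives, then keep only the strongest entries per row.

    Per row, ``ceil(keep_fraction * (R - 1))`` largest positive off-diagonal
    entries survive (fewer if the row has fewer positives).  Ties are broken
    deterministically: the entry with the lower column index wins.  The
    result is generally asymmetric.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    a = np.asarray(values, dtype=float)
    r = a.shape[0]
    m = int(np.ceil(keep_fraction * (r - 1)))
    out = np.zeros_like(a)
    for i in range(r):
        row = a[i].copy()
        row[i] = 0.0
        pos = np.flatnonzero(row > 0)
        if pos.size == 0:
            continue
        # stable sort on -value keeps lower column index first among ties
        order = pos[np.argsort(-row[pos], kind="stable")]
        keep = order[:m]
        out[i, keep] = row[keep]
    return out


def affinity(fc_sparse: np.ndarray, kernel: str = "normalized_angle",
             roi_labels: list[str] | None = None) -> np.ndarray:
    """Affinity between connectivity profiles (rows of a sparsified FC).

    ``normalized_angle`` maps the angle between profiles onto [0, 1]:
    ``a_ij = 1 - arccos(cos(row_i, row_j)) / pi`` (identical rows -> 1,
    orthogonal -> 0.5, antipodal -> 0).  ``cosine`` returns the raw cosine.
    """
    a = np.asarray(fc_sparse, dtype=float)
    norms = np.linalg.norm(a, axis=1)
    if np.any(norms == 0):
        labels = roi_labels or [f"roi{i}" for i in range(a.shape[0])]
        bad = [labels[i] for i in np.flatnonzero(norms == 0)]
        raise ValueError(f"all-zero connectivity profile for ROI(s): {', '.join(bad)}")
    cos = (a @ a.T) / np.outer(norms, norms)
    cos = np.clip(cos, -1.0, 1.0)
    if kernel == "cosine":
        out = cos
    elif kernel == "normalized_angle":
        out = 1.0 - np.arccos(cos) / np.pi
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 1.0)
    return out


class DiffusionGradients(BaseEstimator, TransformerMixin):
    """Diffusion-map embedding of an affinity matrix.

    Parameters
    ----------
    n_components : int
        Number of gradients to retain (K).
    alpha : float
        Density-normalization exponent; 0.5 approximates the
        Fokker-Planck diffusion operator and is the common connectomics
        default.

    The anisotropic kernel ``W = D^-alpha A D^-alpha`` is row-normalized to
    a Markov matrix whose non-trivial eigenvectors, scaled by their
    eigenvalues (diffusion time 0 convention), form the gradient
    coordinates.  Eigenvector sign is fixed deterministically: the entry of
    largest magnitude in each column is made positive.

    Fitted attributes: ``gradients_`` (R x K), ``lambdas_``,
    ``variance_explained_``.
    """

    def __init__(self, n_components: int = 10, alpha: float = 0.5):
        self.n_components = n_components
        self.alpha = alpha

    def fit(self, X: np.ndarray, y=None) -> "DiffusionGradients":
        a = np.asarray(X, dtype=float)
        r = a.shape[0]
        if a.ndim != 2 or a.shape[1] != r:
            raise ValueError("affinity must be square")
        if self.n_components >= r:
            raise ValueError("n_components must be smaller than the matrix size")
        n_comp, _ = connected_components(a > 0, directed=False)
        if n_comp > 1:
            raise ValueError(
                "affinity graph is disconnected; the diffusion operator is "
                "reducible — use a denser affinity (lower sparsity or a "
                "different kernel)"
            )
        d = a.sum(axis=1)
        w = a / np.outer(d**self.alpha, d**self.alpha)
        d2 = w.sum(axis=1)
        sq = np.sqrt(d2)
        m = w / np.outer(sq, sq)  # symmetric conjugate of the Markov matrix
        m = (m + m.T) / 2.0
        evals, evecs = linalg.eigh(m)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        # drop the trivial stationary eigenvector (eigenvalue 1)
        lambdas = evals[1 : self.n_components + 1]
        psi = evecs[:, 1 : self.n_components + 1] / sq[:, None]
        # deterministic sign: largest-magnitude loading positive
        for j in range(psi.shape[1]):
            k = np.argmax(np.abs(psi[:, j]))
            if psi[k, j] < 0:
                psi[:, j] = -psi[:, j]
        coords = psi * lambdas[None, :]
        pos = evals[1:][evals[1:] > 0]
        total = pos.sum()
        if total > 0:
            ve = np.clip(lambdas, 0.0, None) / total
        else:
            ve = np.zeros_like(lambdas)
        self.gradients_ = coords
        self.lambdas_ = lambdas
        self.variance_explained_ = ve
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Return the fitted gradient coordinates (the embedding of X)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "gradients_")
        return self.gradients_

    def to_gradient_set(self, roi_labels: list[str] | None = None) -> GradientSet:
        return GradientSet(
            coords=self.gradients_.copy(),
            lambdas=self.lambdas_.copy(),
            variance_explained=self.variance_explained_.copy(),
            roi_labels=roi_labels,
        )


class ProcrustesAlignment(BaseEstimator, TransformerMixin):
    """Orthogonal Procrustes alignment of gradients to a template.

    Pure rotation/reflection (no scaling, no translation), so within-subject
    pairwise ROI distances in gradient space are preserved exactly.
    """

    def __init__(self, template: np.ndarray | None = None):
        self.template = template

    def fit(self, X: np.ndarray, y=None) -> "ProcrustesAlignment":
        if self.template is None:
            raise ValueError("a template must be provided")
        self.template_ = np.asarray(self.template, dtype=float)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.shape != self.template_.shape:
            raise ValueError(
                f"shape mismatch: subject {x.shape} vs template {self.template_.shape}"
            )
        rot, _ = linalg.orthogonal_procrustes(x, self.template_)
        return x @ rot


def diffusion_gradients(aff: np.ndarray, k: int = 10, alpha: float = 0.5,
                        roi_labels: list[str] | None = None) -> GradientSet:
    """Functional wrapper around :class:`DiffusionGradients`."""
    est = DiffusionGradients(n_components=k, alpha=alpha).fit(aff)
    return est.to_gradient_set(roi_labels)


def align_gradients(subject: GradientSet, template: GradientSet,
                    template_id: str = "template") -> GradientSet:
    """Rotate a subject's gradients onto a template (wrapper)."""
    if subject.coords.shape != template.coords.shape:
        raise ValueError("subject and template must share R and K")
    aligned = ProcrustesAlignment(template=template.coords).fit(None).transform(subject.coords)
    return replace(subject, coords=aligned, aligned_to=template_id)


def _subset_indices(g: GradientSet, part: dict[str, str], network: str) -> np.ndarray:
    if g.roi_labels is None:
        raise ValueError("gradient set has no ROI labels")
    idx = np.array([i for i, lab in enumerate(g.roi_labels) if part.get(lab) == network])
    if idx.size == 0:
        raise ValueError(f"network {network!r} has no ROIs")
    return idx


def dispersion_between(g: GradientSet, part: dict[str, str], net_a: str, net_b: str,
                       gradient_index: int = 0, absolute: bool = False) -> float:
    """Between-network dispersion: difference of network-mean gradient values.

    Signed by default (``mean(A) - mean(B)``, antisymmetric in A/B); pass
    ``absolute=True`` for an orientation-free distance.
    """
    ia = _subset_indices(g, part, net_a)
    ib = _subset_indices(g, part, net_b)
    d = float(g.coords[ia, gradient_index].mean() - g.coords[ib, gradient_index].mean())
    return abs(d) if absolute else d


def dispersion_within(g: GradientSet, rois: list[str] | np.ndarray,
                      gradient_index: int = 0) -> float:
    """Within-set dispersion: sum of squared distances to the centroid."""
    if g.roi_labels is not None and len(rois) and isinstance(rois[0], str):
        pos = {lab: i for i, lab in enumerate(g.roi_labels)}
        idx = np.array([pos[r] for r in rois])
    else:
        idx = np.asarray(rois, dtype=int)
    if idx.size < 2:
        raise ValueError("within-network dispersion needs at least 2 ROIs")
    v = g.coords[idx, gradient_index]
    return float(np.sum((v - v.mean()) ** 2))


def fit_cohort_gradients(
    ts_list: list[np.ndarray],
    roi_labels: list[str] | None = None,
    k: int = 10,
    alpha: float = 0.5,
    keep_fraction: float = 0.10,
    kernel: str = "normalized_angle",
) -> tuple[GradientSet, list[GradientSet], list[ConnectivityMatrix]]:
    """Template-plus-subjects gradient fit.

    Subject FC matrices are averaged into a template; the template and each
    subject are embedded by the identical sparsify -> affinity -> diffusion
    chain, and every subject is Procrustes-aligned to the template.  Returns
    ``(template_gradients, aligned_subject_gradients, subject_fcs)``.
    """
    fcs = [compute_fc(ts, roi_labels) for ts in ts_list]
    labels = fcs[0].roi_labels
    mean_fc = np.mean([fc.values for fc in fcs], axis=0)

    def embed(values: np.ndarray) -> GradientSet:
        sp = sparsify_rows(values, keep_fraction)
        af = affinity(sp, kernel=kernel, roi_labels=labels)
        return diffusion_gradients(af, k=k, alpha=alpha, roi_labels=labels)

    template = embed(mean_fc)
    subjects = [align_gradients(embed(fc.values), template) for fc in fcs]
    return template, subjects, fcs
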