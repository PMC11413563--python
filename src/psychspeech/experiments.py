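"""Reproducible study-level experiments on synthetic cohorts.

These functions bundle the replication studies the package is validated
with: recovery of the planted gradient compression across cohort seeds,
the semantic-graph response to embedding-space homogeneity, the syntax
response to the patient-like grammar shift, and the calibration of the
statistics layer.  They are used by the test suite and by the acceptance
script, and are available to users who want to rerun the studies at other
problem sizes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gradients import dispersion_between, fit_cohort_gradients
from .semgraph import UnitSet, graph_metrics, select_threshold, similarity_matrix, small_worldness
from .stats import chi2_2x2, cohens_d, fit_glm, mass_univariate, welch_t
from .syntree import utterance_metrics
from .synthetic import CohortSpec, TreeParams, _fep_tree_params, gen_embeddings, gen_timeseries, gen_trees

__all__ = [
    "table1_statistics",
    "dispersion_recovery",
    "semantic_spread_contrast",
    "grammar_contrast",
    "mass_univariate_type1_rate",
    "glm_wald_coverage",
]

#: Syntax measures expected to rise / fall under the patient-like grammar.
SYNTAX_UP = ("nodes", "depth", "depth_mean", "vp_count")
SYNTAX_DOWN = ("depth_apen", "np_count", "np_nest", "np_length", "vp_length")


def table1_statistics() -> dict:
    """Cohort-table statistics recomputed from the printed summaries.

    Sex: 7/29 vs 8/29 female (the printed 24.1% vs 27.6%); education:
    20/28 vs 15/29 with >12 years (the printed 71.4% vs 51.7%, which
    implies one missing control); thought-disorganization ratings:
    0.18 +- 0.26 vs 1.09 +- 1.12 at n = 29 per group.
    """
    sex = chi2_2x2(7, 22, 8, 21)
    edu = chi2_2x2(20, 8, 15, 14)
    tli = welch_t(0.18, 0.26, 29, 1.09, 1.12, 29)
    return {
        "sex_chi2_p": sex.p,
        "sex_contingency_C": sex.effect_size,
        "education_chi2_p": edu.p,
        "education_contingency_C": edu.effect_size,
        "tli_disorganization_cohens_d": abs(tli.effect_size),
        "tli_disorganization_p": tli.p,
    }


def dispersion_recovery(n_seeds: int = 100, base_seed: int = 0,
                        **spec_overrides) -> dict:
    """Fraction of cohort seeds recovering the planted gradient compression.

    For each seed a full cohort (default 29 + 29, 100 ROIs, 240 time
    points, compression 0.8) is simulated, every subject's gradients are
    fit and aligned to the pooled template, and the seed counts as a
    success when the patient group's mean absolute VN-DMN G1 dispersion is
    lower than the control group's.
    """
    successes = 0
    margins = []
    for i in range(n_seeds):
        spec = CohortSpec(**{"compression": 0.8, **spec_overrides,
                             "seed": base_seed + i})
        ts = {**gen_timeseries(spec, "HC"), **gen_timeseries(spec, "FEP")}
        _, subs, _ = fit_cohort_gradients(list(ts.values()),
                                          roi_labels=spec.roi_labels, k=10)
        part = dict(zip(spec.roi_labels, spec.network_labels))
        d = [abs(dispersion_between(g, part, "VN", "DMN", 0)) for g in subs]
        n = spec.n_per_group
        margin = float(np.mean(d[:n]) - np.mean(d[n:]))  # HC minus FEP
        margins.append(margin)
        successes += margin > 0
    return {"success_rate": successes / n_seeds, "n_seeds": n_seeds,
            "mean_margin": float(np.mean(margins))}


def _graph_summary(embeddings: np.ndarray, seed: int) -> tuple:
    u = UnitSet([f"w{i}" for i in range(len(embeddings))], embeddings)
    g, _ = select_threshold(similarity_matrix(u))
    cc, ge, _ = graph_metrics(g)
    sigma = small_worldness(g, seed=seed)
    return cc, ge, sigma


def semantic_spread_contrast(n_seeds: int = 100, tight: float = 0.15,
                             homogeneous: float = 0.6, n_units: int = 24,
                             n_clusters: int = 4, dim: int = 50,
                             base_seed: int = 0) -> dict:
    """Semantic-graph response to homogenizing the embedding space.

    Per seed, two unit sets are generated: tightly clustered (control-like)
    and homogeneous (patient-like).  A seed succeeds when the homogeneous
    space shows higher closeness centrality and global efficiency and a
    lower small-worldness sigma — the patient-direction pattern.
    """
    joint = 0
    per = {"cc": 0, "ge": 0, "sigma": 0}
    for i in range(n_seeds):
        seed = base_seed + i
        t = _graph_summary(gen_embeddings(n_units, n_clusters, tight, dim, seed), seed)
        h = _graph_summary(gen_embeddings(n_units, n_clusters, homogeneous, dim,
                                          seed + 50_000), seed)
        oks = {
            "cc": h[0] > t[0],
            "ge": h[1] > t[1],
            "sigma": t[2] is not None and h[2] is not None and h[2] < t[2],
        }
        for k, v in oks.items():
            per[k] += v
        joint += all(oks.values())
    return {"success_rate": joint / n_seeds, "n_seeds": n_seeds,
            "per_metric": {k: v / n_seeds for k, v in per.items()}}


def grammar_contrast(n_seeds: int = 100, n_utts: int = 200,
                     compression: float = 0.8, base_seed: int = 0) -> dict:
    """Syntax-metric response to the patient-like grammar shift.

    Per seed, metric means over ``n_utts`` utterances from the control
    grammar and from the compression-shifted grammar are compared; a seed
    succeeds when all expected directions hold jointly (more nodes, deeper
    trees, lower depth entropy, fewer/simpler/shorter NPs, more but
    shorter VPs).
    """
    hc = TreeParams()
    fep = _fep_tree_params(hc, compression)

    def means(params: TreeParams, seed: int) -> dict:
        ms = [utterance_metrics(t) for t in gen_trees(n_utts, params, seed)]
        return {f: np.mean([getattr(m, f) for m in ms
                            if m is not None and getattr(m, f) is not None])
                for f in SYNTAX_UP + SYNTAX_DOWN}

    joint = 0
    per = {f: 0 for f in SYNTAX_UP + SYNTAX_DOWN}
    for i in range(n_seeds):
        mh = means(hc, base_seed + 10_000 + i)
        mf = means(fep, base_seed + 20_000 + i)
        oks = {f: mf[f] > mh[f] for f in SYNTAX_UP}
        oks.update({f: mf[f] < mh[f] for f in SYNTAX_DOWN})
        for k, v in oks.items():
            per[k] += v
        joint += all(oks.values())
    return {"success_rate": joint / n_seeds, "n_seeds": n_seeds,
            "per_metric": {k: v / n_seeds for k, v in per.items()}}


def mass_univariate_type1_rate(n_rois: int = 1000, n_per_group: int = 20,
                               seed: int = 0, alpha: float = 0.05) -> dict:
    """Uncorrected type-I error of the parcel-wise group model under the null."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    subjects = pd.DataFrame({
        "group": ["HC"] * n_per_group + ["FEP"] * n_per_group,
        "age": rng.normal(21.5, 3, n),
        "sex": rng.integers(0, 2, n),
        "education": rng.integers(0, 2, n),
    })
    values = rng.standard_normal((n, n_rois))
    res = mass_univariate(values, subjects)
    return {"type1_rate": float((res["p"] < alpha).mean()), "n_rois": n_rois}


def glm_wald_coverage(n_reps: int = 200, n: int = 500, beta=(0.5, 0.8),
                      shape: float = 5.0, seed: int = 0) -> dict:
    """Coverage of 95% Wald intervals in a gamma-log GLM with known effects.

    Also reports how often the deviance goodness-of-fit test rejects the
    (true) model at alpha = 0.05.
    """
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, dtype=float)
    covered = 0
    gof_reject = 0
    for _ in range(n_reps):
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        mu = np.exp(x @ beta)
        y = rng.gamma(shape, mu / shape)
        res = fit_glm(y, x, "gamma-log")
        lo = res.params[1] - 1.959963984540054 * res.bse[1]
        hi = res.params[1] + 1.959963984540054 * res.bse[1]
        covered += lo <= beta[1] <= hi
        gof_reject += res.gof_p < 0.05
    return {"coverage": covered / n_reps, "gof_rejection_rate": gof_reject / n_reps,
            "n_reps": n_reps, "n": n}
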