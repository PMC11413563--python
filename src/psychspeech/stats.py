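"""Group statistics: descriptive tests, FDR, partial rank correlation,
GLM families, and mass-univariate parcel models.

Closed-form tests (Welch t from summaries, Pearson chi-square without
continuity correction, Mann-Whitney U) reproduce the conventions of common
psychiatry cohort tables: Cohen's d uses the equal-weight pooled SD, the
chi-square effect size is the contingency coefficient C = sqrt(X2/(X2+n)).
GLMs delegate to statsmodels (Gaussian/identity, Gamma/log, Tweedie/log)
with a deviance goodness-of-fit check.  The mass-univariate parcel model is
a vectorized per-ROI OLS with a group term and covariates, BH-FDR corrected
across parcels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as scipy_linalg
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "TestResult",
    "GLMResult",
    "welch_t",
    "welch_t_samples",
    "cohens_d",
    "chi2_2x2",
    "mann_whitney",
    "bh_fdr",
    "partial_spearman",
    "fit_glm",
    "mass_univariate",
    "brainlang_glm",
]


@dataclass
class TestResult:
    statistic: float
    df: float | None
    p: float
    effect_size: float | None
    effect_name: str | None
    test_name: str


@dataclass
class GLMResult:
    params: np.ndarray
    bse: np.ndarray
    z_values: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    family: str
    link: str
    deviance: float
    gof_p: float
    names: list[str]


def cohens_d(mean1: float, sd1: float, mean2: float, sd2: float) -> float | None:
    """Cohen's d with the equal-weight pooled SD, ``(m2 - m1) / s_p``."""
    sp = np.sqrt((sd1**2 + sd2**2) / 2.0)
    if sp == 0:
        return None
    return float((mean2 - mean1) / sp)


def welch_t(mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int) -> TestResult:
    """Welch's unequal-variance t test from summary statistics.

    Satterthwaite degrees of freedom, two-sided p, Cohen's d (equal-weight
    pooled SD) as the effect size.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    se = np.sqrt(v1 + v2)
    if se == 0:
        return TestResult(0.0, float(n1 + n2 - 2), 1.0, 0.0, "cohens_d", "welch_t")
    t = (mean2 - mean1) / se
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p), cohens_d(mean1, sd1, mean2, sd2),
                      "cohens_d", "welch_t")


def welch_t_samples(x, y) -> TestResult:
    """Welch's t test from raw samples (reduces to the summary form)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    return welch_t(x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y))


def chi2_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Pearson chi-square on a 2x2 table (no continuity correction).

    Effect size is the contingency coefficient ``C = sqrt(X2 / (X2 + n))``.
    Rows are groups, columns outcomes: table [[a, b], [c, d]].
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("2x2 table has a zero margin")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    n = table.sum()
    cc = float(np.sqrt(chi2 / (chi2 + n)))
    return TestResult(float(chi2), float(dof), float(p), cc, "contingency_C", "chi2")


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration for small samples (both n <= 8, no ties), otherwise
    the normal approximation with tie correction.  Rank-biserial
    correlation ``1 - 2U/(n1 n2)`` is reported as the effect size.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        u = len(x) * len(y) / 2.0
        return TestResult(u, None, 1.0, 0.0, "rank_biserial", "mann_whitney")
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(x), len(y)) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u = float(res.statistic)
    rb = 1.0 - 2.0 * u / (len(x) * len(y))
    return TestResult(u, None, float(min(res.pvalue, 1.0)), rb, "rank_biserial", "mann_whitney")


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-D")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(ranked, 0.0, 1.0)
    return q


def partial_spearman(x, y, covariates=None) -> TestResult:
    """Partial Spearman correlation of x and y given covariates.

    All variables are rank-transformed; x and y ranks are residualized on
    the covariate ranks (plus intercept) by least squares, and the Pearson
    correlation of the residuals is tested with a t statistic on
    ``n - 2 - k`` degrees of freedom.  With no covariates this is plain
    Spearman's rho.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, float)
        if cov.ndim == 1:
            cov = cov[:, None]
    k = cov.shape[1]
    if n <= k + 2:
        raise ValueError("need n > #covariates + 2")
    for name, v in (("x", x), ("y", y)):
        if np.all(v == v[0]):
            raise ValueError(f"variable {name} is constant")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rc = np.column_stack([np.ones(n)] + [stats.rankdata(cov[:, j]) for j in range(k)])
    ex = rx - rc @ np.linalg.lstsq(rc, rx, rcond=None)[0]
    ey = ry - rc @ np.linalg.lstsq(rc, ry, rcond=None)[0]
    denom = np.sqrt((ex**2).sum() * (ey**2).sum())
    rho = float((ex * ey).sum() / denom) if denom > 0 else 0.0
    df = n - 2 - k
    rho_c = np.clip(rho, -0.9999999999, 0.9999999999)
    t = rho_c * np.sqrt(df / (1.0 - rho_c**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(rho, float(df), float(p), rho, "partial_rho", "partial_spearman")


_FAMILIES = {
    "gaussian-identity": lambda power: sm.families.Gaussian(sm.families.links.Identity()),
    "gamma-log": lambda power: sm.families.Gamma(sm.families.links.Log()),
    "tweedie-log": lambda power: sm.families.Tweedie(sm.families.links.Log(),
                                                     var_power=power),
}


def fit_glm(y, design, family: str = "gaussian-identity", tweedie_power: float = 1.5,
            names: list[str] | None = None) -> GLMResult:
    """IRLS GLM fit with Wald z tests and a deviance goodness-of-fit p.

    ``design`` must include an intercept column if one is wanted.  For the
    log-link families y must be strictly positive.  The goodness-of-fit p
    is ``chi2.sf(deviance / scale, df_resid)`` with the Pearson-estimated
    dispersion; for the Gaussian family with estimated scale this check is
    uninformative and is reported for completeness only.
    """
    y = np.asarray(y, float)
    x = np.asarray(design, float)
    if names is None:
        names = [f"x{j}" for j in range(x.shape[1])]
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {sorted(_FAMILIES)}")
    if family.endswith("-log") or family in ("gamma-log", "tweedie-log"):
        bad = np.flatnonzero(y <= 0)
        if family != "gaussian-identity" and bad.size:
            raise ValueError(
                f"log-link family needs positive responses; offending rows: {bad.tolist()[:10]}"
            )
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # rank-revealing QR: the trailing pivots are the aliased columns
        _, _, piv = scipy_linalg.qr(x, pivoting=True)
        aliased = [names[j] for j in piv[rank:]]
        raise ValueError(f"design is rank deficient; aliased columns: {aliased}")
    fam = _FAMILIES[family](tweedie_power)
    model = sm.GLM(y, x, family=fam)
    res = model.fit()
    z = res.params / res.bse
    p = 2.0 * stats.norm.sf(np.abs(z))
    q = bh_fdr(p)
    scale = res.scale if res.scale > 0 else 1.0
    gof_p = float(stats.chi2.sf(res.deviance / scale, res.df_resid))
    return GLMResult(
        params=np.asarray(res.params), bse=np.asarray(res.bse), z_values=np.asarray(z),
        p_values=np.asarray(p), q_values=q, family=family,
        link="identity" if family == "gaussian-identity" else "log",
        deviance=float(res.deviance), gof_p=gof_p, names=names,
    )


def _group_design(subjects: pd.DataFrame, covariates: list[str],
                  group_col: str = "group") -> tuple[np.ndarray, list[str]]:
    g = subjects[group_col]
    if g.dtype == object or str(g.dtype) == "category":
        levels = sorted(g.unique())
        if len(levels) != 2:
            raise ValueError("group column must have exactly 2 levels")
        gv = (g == levels[1]).astype(float).to_numpy()
    else:
        gv = g.astype(float).to_numpy()
    cols = [np.ones(len(subjects)), gv]
    names = ["intercept", "group"]
    for c in covariates:
        cols.append(subjects[c].astype(float).to_numpy())
        names.append(c)
    return np.column_stack(cols), names


def mass_univariate(values: np.ndarray, subjects: pd.DataFrame,
                    covariates: list[str] = ("age", "sex", "education"),
                    group_col: str = "group", q_threshold: float = 0.05) -> pd.DataFrame:
    """Per-ROI linear model of a subject x ROI measure on group + covariates.

    Vectorized OLS across ROIs; the group-term t and two-sided p per ROI are
    BH-FDR corrected across ROIs, with a significance mask at
    ``q < q_threshold``.  Returns a DataFrame with columns
    ``beta, t, p, q, significant`` indexed like the ROI axis.
    """
    yv = np.asarray(values, float)
    n, r = yv.shape
    x, names = _group_design(subjects, list(covariates), group_col)
    if len(subjects) != n:
        raise ValueError("subjects table and value rows must align")
    counts = subjects[group_col].value_counts()
    if (counts < 2).any():
        raise ValueError("need at least 2 subjects per group")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("collinear covariates in the design")
    p_dim = x.shape[1]
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ yv  # p x R
    resid = yv - x @ beta
    dof = n - p_dim
    sigma2 = (resid**2).sum(axis=0) / dof
    gi = names.index("group")
    se = np.sqrt(sigma2 * xtx_inv[gi, gi])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[gi] / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    q = bh_fdr(p)
    return pd.DataFrame({
        "beta": beta[gi], "t": t, "p": p, "q": q, "significant": q < q_threshold,
    })


def brainlang_glm(dispersion: pd.DataFrame, language: pd.DataFrame,
                  subjects: pd.DataFrame,
                  covariates: list[str] = ("age", "sex", "education"),
                  family: str = "tweedie-log", tweedie_power: float = 1.5,
                  shift_eps: float = 1e-6) -> pd.DataFrame:
    """Predict each gradient-dispersion score from each language measure.

    One GLM per (dispersion, language) pair with demographic covariates;
    the language-term z values are BH-FDR corrected within each dispersion
    column.  Signed dispersion scores are shifted by ``|min| + eps`` when a
    log link demands positivity (flagged in the output).
    """
    rows = []
    for disp_name in dispersion.columns:
        y = dispersion[disp_name].to_numpy(float)
        shifted = False
        if family != "gaussian-identity" and y.min() <= 0:
            y = y + abs(y.min()) + shift_eps
            shifted = True
        for lang_name in language.columns:
            lv = language[lang_name].to_numpy(float)
            cols = [np.ones(len(y)), lv]
            names = ["intercept", lang_name]
            for c in covariates:
                cols.append(subjects[c].to_numpy(float))
                names.append(c)
            res = fit_glm(y, np.column_stack(cols), family=family,
                          tweedie_power=tweedie_power, names=names)
            rows.append({
                "dispersion": disp_name, "language": lang_name,
                "beta": res.params[1], "z": res.z_values[1], "p": res.p_values[1],
                "gof_p": res.gof_p, "shifted": shifted,
            })
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for disp_name in dispersion.columns:
        mask = out["dispersion"] == disp_name
        out.loc[mask, "q"] = bh_fdr(out.loc[mask, "p"].to_numpy())
    out["significant"] = out["q"] < 0.05
    return out
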