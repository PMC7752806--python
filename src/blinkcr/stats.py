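"""Inferential machinery: mixed RM-ANCOVA, sphericity handling, contrasts.

The central model is the study's 2 x 2 x k mixed factorial: two
between-subject factors (PTSD, mTBI), blockwise CR% as the k-level repeated
measure, and age as a between-subject covariate.  Between effects use Type
III sums of squares with sum-to-zero coding against the between-subject
error; within effects (Block and its interactions) are evaluated on
orthonormal contrast scores against the Block x subject error, with
Mauchly's sphericity test and Greenhouse-Geisser degree-of-freedom
correction.  Effect sizes are partial eta squared, SS_effect /
(SS_effect + SS_error).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats as spstats

__all__ = [
    "MauchlyResult",
    "RmAncovaResult",
    "ContrastResult",
    "mauchly_test",
    "gg_epsilon",
    "mixed_rm_ancova",
    "bonferroni_adjust",
    "helmert_contrasts",
    "two_sample_t",
    "one_way_anova",
]


@dataclass(frozen=True)
class MauchlyResult:
    W: float
    chi_sq: float
    df: int
    p: float


@dataclass(frozen=True)
class ContrastResult:
    name: str
    estimate: float
    se: float
    t: float
    df: int
    p: float


@dataclass
class RmAncovaResult:
    """Effect table of a mixed RM-ANCOVA plus sphericity diagnostics."""

    table: pd.DataFrame
    mauchly: MauchlyResult | None
    gg_epsilon: float | None
    gg_applied: bool
    n: int
    k: int

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]

    def to_text(self) -> str:
        cols = ["ss", "df_num", "df_den", "F", "p_uncorrected", "p_gg",
                "partial_eta_sq"]
        return self.table[cols].to_string(float_format=lambda v: f"{v:.4f}")


def _contrast_scores(data: np.ndarray) -> np.ndarray:
    """Orthonormal within-subject contrast scores Z = Y C' ((k-1) contrasts)."""
    k = data.shape[1]
    C = sla.helmert(k, full=False)  # (k-1) x k, orthonormal rows
    return data @ C.T


def _residual_contrast_cov(Z: np.ndarray, X: np.ndarray | None) -> tuple[np.ndarray, int]:
    """Covariance of contrast scores about the between-model fit."""
    n = Z.shape[0]
    if X is None:
        R = Z - Z.mean(axis=0, keepdims=True)
        n_e = n - 1
    else:
        beta, *_ = np.linalg.lstsq(X, Z, rcond=None)
        R = Z - X @ beta
        n_e = n - X.shape[1]
    return (R.T @ R) / n_e, n_e


def mauchly_test(
    within_data: np.ndarray, design: np.ndarray | None = None
) -> MauchlyResult:
    """Mauchly's sphericity test on a subjects x k repeated-measures matrix.

    ``design`` optionally supplies the between-subject model matrix whose
    residuals define the contrast covariance (default: column centering,
    i.e. an intercept-only model).  k = 2 always yields W = 1, p = 1.
    """
    Y = np.asarray(within_data, dtype=float)
    n, k = Y.shape
    p_model = design.shape[1] if design is not None else 1
    if n - p_model < k - 1:
        raise ValueError("insufficient residual degrees of freedom for Mauchly")
    d = k - 1
    df = k * (k - 1) // 2 - 1
    if k == 2:
        return MauchlyResult(W=1.0, chi_sq=0.0, df=df, p=1.0)
    S_c, n_e = _residual_contrast_cov(_contrast_scores(Y), design)
    W = float(np.linalg.det(S_c) / (np.trace(S_c) / d) ** d)
    W = min(max(W, np.finfo(float).tiny), 1.0)
    # Box's chi-square approximation with the second-order term
    f = 1.0 - (2 * d**2 + d + 2) / (6.0 * d * n_e)
    chi = -n_e * f * np.log(W)
    w2 = (
        (d + 2) * (d - 1) * (d - 2) * (2 * d**3 + 6 * d**2 + 3 * k + 2)
        / (288.0 * (n_e * d * f) ** 2)
    )
    p1 = spstats.chi2.sf(chi, df)
    p2 = spstats.chi2.sf(chi, df + 4)
    p = float(p1 + w2 * (p2 - p1))
    return MauchlyResult(W=W, chi_sq=float(chi), df=df, p=p)


def gg_epsilon(
    within_data: np.ndarray, design: np.ndarray | None = None
) -> float:
    """Greenhouse-Geisser sphericity estimate, clipped to [1/(k-1), 1]."""
    Y = np.asarray(within_data, dtype=float)
    k = Y.shape[1]
    d = k - 1
    if d == 1:
        return 1.0
    S_c, _ = _residual_contrast_cov(_contrast_scores(Y), design)
    eps = np.trace(S_c) ** 2 / (d * np.trace(S_c @ S_c))
    return float(np.clip(eps, 1.0 / d, 1.0))


def _build_between_design(
    factor_a: np.ndarray, factor_b: np.ndarray, covariate: np.ndarray | None
) -> tuple[np.ndarray, list[str]]:
    """Sum-to-zero coded design: intercept, A, B, AxB [, centered covariate]."""
    a = np.where(np.asarray(factor_a, dtype=bool), 1.0, -1.0)
    b = np.where(np.asarray(factor_b, dtype=bool), 1.0, -1.0)
    cols = [np.ones_like(a), a, b, a * b]
    names = ["intercept", "A", "B", "A:B"]
    if covariate is not None:
        c = np.asarray(covariate, dtype=float)
        cols.append(c - c.mean())
        names.append("cov")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (collinear covariate or factor)")
    return X, names


def _type3_ss(Y: np.ndarray, X: np.ndarray, term_cols: dict[str, list[int]]):
    """Per-term Type III SS by full-vs-reduced residual comparison.

    ``Y`` may hold several response columns; SS are summed across them
    (the multivariate-to-univariate pooling used for within-subject
    effects on orthonormal contrast scores).
    """
    def rss(M):
        beta, *_ = np.linalg.lstsq(M, Y, rcond=None)
        R = Y - M @ beta
        return float(np.sum(R * R))

    rss_full = rss(X)
    ss = {}
    for term, cols in term_cols.items():
        keep = [j for j in range(X.shape[1]) if j not in cols]
        ss[term] = rss(X[:, keep]) - rss_full
    return ss, rss_full


def mixed_rm_ancova(
    blocks,
    factor_a,
    factor_b,
    covariate=None,
    factor_names: tuple[str, str] = ("PTSD", "mTBI"),
    within_name: str = "Block",
    gg_policy: str = "mauchly",  # "mauchly" | "always" | "never"
    alpha_sphericity: float = 0.05,
) -> RmAncovaResult:
    """Mixed 2 x 2 x k repeated-measures ANCOVA.

    Parameters
    ----------
    blocks : (n, k) array or DataFrame
        Repeated measure, one column per level (block).
    factor_a, factor_b : boolean arrays, length n
        Between-subject group indicators.
    covariate : array or None
        Between-subject covariate (mean-centered internally).
    gg_policy : str
        When to report Greenhouse-Geisser-corrected p values as the
        headline ``p_gg``: only if Mauchly rejects ("mauchly", default),
        unconditionally ("always"), or never.
    """
    Y = np.asarray(blocks, dtype=float)
    if Y.ndim != 2:
        raise ValueError("blocks must be a subjects x k matrix")
    n, k = Y.shape
    a = np.asarray(factor_a, dtype=bool)
    b = np.asarray(factor_b, dtype=bool)
    cells, counts = np.unique(np.column_stack([a, b]), axis=0, return_counts=True)
    if len(cells) < 4 or counts.min() < 2:
        raise ValueError("design-deficient: need >= 2 subjects in each of 4 cells")
    X, names = _build_between_design(a, b, covariate)
    p_model = X.shape[1]
    na, nb = factor_names

    term_cols = {na: [1], nb: [2], f"{na}:{nb}": [3]}
    if covariate is not None:
        term_cols["age"] = [4]

    # --- between-subject stratum: k * (subject means), orthonormal scale
    M = Y.mean(axis=1, keepdims=True) * np.sqrt(k)
    ss_b, rss_b = _type3_ss(M, X, term_cols)
    df_den_b = n - p_model

    # --- within-subject stratum: orthonormal contrast scores
    Z = _contrast_scores(Y)
    d = k - 1
    within_terms = {within_name: [0]}
    within_terms.update({f"{within_name}:{t}": c for t, c in term_cols.items()})
    ss_w, rss_w = _type3_ss(Z, X, within_terms)
    df_den_w = (n - p_model) * d

    eps = gg_epsilon(Y, design=X)
    mauchly = mauchly_test(Y, design=X) if n - p_model >= d else None
    apply_gg = {
        "always": True,
        "never": False,
        "mauchly": mauchly is not None and mauchly.p < alpha_sphericity,
    }[gg_policy]

    rows = []
    for term, ss in ss_b.items():
        msw = rss_b / df_den_b
        F = (ss / 1) / msw
        rows.append(
            {
                "effect": term,
                "ss": ss,
                "df_num": 1.0,
                "df_den": float(df_den_b),
                "F": F,
                "p_uncorrected": float(spstats.f.sf(F, 1, df_den_b)),
                "gg_epsilon": np.nan,
                "df_num_gg": np.nan,
                "df_den_gg": np.nan,
                "p_gg": np.nan,
                "partial_eta_sq": ss / (ss + rss_b),
            }
        )
    for term, ss in ss_w.items():
        msw = rss_w / df_den_w
        F = (ss / d) / msw
        p_unc = float(spstats.f.sf(F, d, df_den_w))
        dn_gg, dd_gg = d * eps, df_den_w * eps
        p_gg = float(spstats.f.sf(F, dn_gg, dd_gg))
        rows.append(
            {
                "effect": term,
                "ss": ss,
                "df_num": float(d),
                "df_den": float(df_den_w),
                "F": F,
                "p_uncorrected": p_unc,
                "gg_epsilon": eps,
                "df_num_gg": dn_gg,
                "df_den_gg": dd_gg,
                "p_gg": p_gg if apply_gg else p_unc,
                "partial_eta_sq": ss / (ss + rss_w),
            }
        )
    table = pd.DataFrame(rows).set_index("effect")
    return RmAncovaResult(
        table=table, mauchly=mauchly, gg_epsilon=eps, gg_applied=apply_gg,
        n=n, k=k,
    )


def bonferroni_adjust(pvals, m: int | None = None) -> list[float]:
    """Bonferroni correction: p -> min(1, p * m); m defaults to len(pvals)."""
    pvals = list(pvals)
    m = len(pvals) if m is None else m
    if any(not 0.0 <= p <= 1.0 for p in pvals):
        raise ValueError("p-values must lie in [0, 1]")
    return [min(1.0, p * m) for p in pvals]


def one_way_anova(groups) -> tuple[float, tuple[int, int], float, float]:
    """One-way ANOVA: returns (F, (df1, df2), p, partial_eta_sq)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    N = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    df1, df2 = len(groups) - 1, N - len(groups)
    F = (ssb / df1) / (ssw / df2)
    return float(F), (df1, df2), float(spstats.f.sf(F, df1, df2)), float(ssb / (ssb + ssw))


def two_sample_t(x, y) -> tuple[float, int, float]:
    """Pooled-variance (Student) two-sided t-test: (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    df = x.size + y.size - 2
    sp2 = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / df
    denom = np.sqrt(sp2 * (1 / x.size + 1 / y.size))
    if denom == 0:
        return 0.0, df, 1.0
    t = float((x.mean() - y.mean()) / denom)
    return t, df, float(2 * spstats.t.sf(abs(t), df))


def helmert_contrasts(groups, names=("Low", "Mid", "High")) -> list[ContrastResult]:
    """Ordered-group Helmert contrasts on the one-way ANOVA error term.

    For three ordered groups: contrast 1 compares the first group against
    the mean of the remaining two; contrast 2 compares the second against
    the third.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) != 3:
        raise ValueError("helmert_contrasts expects exactly 3 ordered groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    N = sum(g.size for g in groups)
    df = N - 3
    mse = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups) / df
    means = [g.mean() for g in groups]
    ns = [g.size for g in groups]
    specs = [
        (f"{names[0]} vs mean({names[1]},{names[2]})", [1.0, -0.5, -0.5]),
        (f"{names[1]} vs {names[2]}", [0.0, 1.0, -1.0]),
    ]
    out = []
    for label, w in specs:
        est = float(sum(wi * mi for wi, mi in zip(w, means)))
        se = float(np.sqrt(mse * sum(wi**2 / ni for wi, ni in zip(w, ns))))
        t = est / se if se > 0 else 0.0
        p = float(2 * spstats.t.sf(abs(t), df)) if se > 0 else 1.0
        out.append(ContrastResult(label, est, se, float(t), df, p))
    return out
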