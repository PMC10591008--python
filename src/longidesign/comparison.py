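"""Statistical comparison of participant change vectors across designs.

One-way within-subjects (repeated-measures) ANOVA over designs, with
Mauchly's sphericity test, the Greenhouse-Geisser degrees-of-freedom
correction when sphericity is rejected, Tukey post-hoc comparisons built on
the within-subjects error term, Benjamini-Hochberg FDR adjustment across a
comparison family, and pairwise Pearson similarity between designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DesignComparisonResult",
    "ComparisonError",
    "rm_anova",
    "mauchly_test",
    "gg_epsilon",
    "tukey_posthoc",
    "bh_fdr",
    "design_similarity",
    "similarity_to_reference",
]


class ComparisonError(ValueError):
    """Invalid input to a design-comparison statistic."""


@dataclass
class DesignComparisonResult:
    """Within-subjects ANOVA output for one participant x design matrix."""

    F: float
    df1: float
    df2: float
    p: float
    mauchly_W: Optional[float] = None
    mauchly_p: Optional[float] = None
    epsilon_gg: float = 1.0
    epsilon_applied: bool = False
    ms_error: float = np.nan
    df_error: float = np.nan
    n: int = 0
    m: int = 0
    posthoc: Optional[pd.DataFrame] = None
    fdr_adjusted_p: dict = field(default_factory=dict)
    similarity: Optional[pd.DataFrame] = None


def _as_matrix(matrix: Union[np.ndarray, pd.DataFrame]) -> np.ndarray:
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ComparisonError("expected a 2-D participants x designs matrix")
    if np.isnan(x).any():
        raise ComparisonError("matrix has missing cells; complete cases required")
    return x


def _contrast_basis(m: int) -> np.ndarray:
    """Orthonormal (m x (m-1)) basis of the contrast space (orthogonal to 1).

    Built from Helmert contrasts; any orthonormal basis gives identical
    Mauchly W and Greenhouse-Geisser epsilon.
    """
    helmert = np.zeros((m, m - 1))
    for j in range(1, m):
        helmert[:j, j - 1] = 1.0
        helmert[j, j - 1] = -j
    return helmert / np.linalg.norm(helmert, axis=0)


def mauchly_test(matrix: Union[np.ndarray, pd.DataFrame]) -> tuple[float, float]:
    """Mauchly's sphericity test on a participants x conditions matrix.

    W = det(C'SC) / (tr(C'SC)/(m-1))^(m-1) for an orthonormal contrast
    basis C and the sample covariance S; the p-value uses the chi-square
    approximation with the standard small-sample correction factor.
    Requires n > m - 1, otherwise the contrast covariance is singular and
    the test is undefined.
    """
    x = _as_matrix(matrix)
    n, m = x.shape
    if m < 3:
        return 1.0, 1.0  # a single contrast cannot violate sphericity
    if n <= m - 1:
        raise ComparisonError(
            f"Mauchly test undefined for n={n} <= m-1={m - 1}; apply the "
            "epsilon correction unconditionally instead")
    C = _contrast_basis(m)
    S = np.cov(x, rowvar=False, ddof=1)
    A = C.T @ S @ C
    d = m - 1
    trace = np.trace(A)
    if trace <= 0:
        raise ComparisonError("degenerate covariance: zero variance in contrasts")
    sign, logdet = np.linalg.slogdet(A)
    if sign <= 0:
        return 0.0, 0.0
    log_w = logdet - d * np.log(trace / d)
    W = float(np.exp(log_w))
    df = d * (d + 1) // 2 - 1
    f_corr = 1.0 - (2 * d ** 2 + d + 2) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * f_corr * log_w
    p = float(stats.chi2.sf(chi2, df))
    return min(W, 1.0), p


def gg_epsilon(matrix: Union[np.ndarray, pd.DataFrame]) -> float:
    """Greenhouse-Geisser nonsphericity correction factor.

    epsilon = (sum lambda)^2 / ((m-1) sum lambda^2) over the eigenvalues of
    the contrast-space sample covariance, clipped to [1/(m-1), 1].
    """
    x = _as_matrix(matrix)
    m = x.shape[1]
    if m < 3:
        return 1.0
    C = _contrast_basis(m)
    S = np.cov(x, rowvar=False, ddof=1)
    lam = np.linalg.eigvalsh(C.T @ S @ C)
    total = lam.sum()
    if total <= 0:
        raise ComparisonError("degenerate covariance: all contrast eigenvalues zero")
    eps = total ** 2 / ((m - 1) * float(lam @ lam))
    return float(np.clip(eps, 1.0 / (m - 1), 1.0))


def rm_anova(matrix: Union[np.ndarray, pd.DataFrame],
             mauchly_alpha: float = 0.05,
             correction: str = "auto") -> DesignComparisonResult:
    """One-way within-subjects ANOVA on a participants x designs matrix.

    Subject effects are removed before the error term:
    F = MS_conditions / MS_error with df (m-1), (n-1)(m-1).  With
    ``correction="auto"`` the Greenhouse-Geisser epsilon multiplies both
    degrees of freedom when Mauchly's test rejects sphericity at
    ``mauchly_alpha``; ``"always"`` applies it unconditionally and
    ``"never"`` not at all.
    """
    if correction not in ("auto", "always", "never"):
        raise ComparisonError(f"unknown correction mode {correction!r}")
    x = _as_matrix(matrix)
    n, m = x.shape
    if n < 3 or m < 2:
        raise ComparisonError("need >= 3 participants and >= 2 designs")

    grand = x.mean()
    col_means = x.mean(axis=0)
    row_means = x.mean(axis=1)
    ss_cond = n * float(((col_means - grand) ** 2).sum())
    ss_subj = m * float(((row_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_error = ss_total - ss_cond - ss_subj

    df1 = float(m - 1)
    df2 = float((n - 1) * (m - 1))
    ms_cond = ss_cond / df1
    ms_error = max(ss_error, 0.0) / df2

    mauchly_W = mauchly_p = None
    eps = gg_epsilon(x) if m >= 3 else 1.0
    apply_eps = correction == "always"
    if correction == "auto" and m >= 3:
        try:
            mauchly_W, mauchly_p = mauchly_test(x)
            apply_eps = mauchly_p < mauchly_alpha
        except ComparisonError:
            # test undefined (n <= m-1): correct unconditionally
            apply_eps = True

    if ms_error <= 0:
        if ss_cond > 0:
            warnings.warn("zero error variance with unequal design means; "
                          "F reported as +inf", stacklevel=2)
            F, p = np.inf, 0.0
        else:
            F, p = 0.0, 1.0
    else:
        F = ms_cond / ms_error
        d1, d2 = (df1 * eps, df2 * eps) if apply_eps else (df1, df2)
        p = float(stats.f.sf(F, d1, d2))

    return DesignComparisonResult(
        F=float(F),
        df1=df1 * eps if apply_eps else df1,
        df2=df2 * eps if apply_eps else df2,
        p=float(p),
        mauchly_W=mauchly_W,
        mauchly_p=mauchly_p,
        epsilon_gg=eps,
        epsilon_applied=apply_eps,
        ms_error=ms_error,
        df_error=df2,
        n=n,
        m=m,
    )


def tukey_posthoc(matrix: Union[np.ndarray, pd.DataFrame],
                  anova: Optional[DesignComparisonResult] = None,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Tukey studentized-range comparisons of all design pairs.

    Uses the within-subjects MS_error and its (n-1)(m-1) degrees of freedom
    from the repeated-measures ANOVA: q = |mean_A - mean_B| /
    sqrt(MS_error / n), with p from the studentized range distribution with
    (m, df_error).
    """
    x = _as_matrix(matrix)
    n, m = x.shape
    names = (list(matrix.columns) if isinstance(matrix, pd.DataFrame)
             else [f"c{j}" for j in range(m)])
    if anova is None:
        anova = rm_anova(x, correction="never")
    ms_error, df_error = anova.ms_error, anova.df_error
    if ms_error <= 0:
        warnings.warn("zero within-subjects error variance; q degenerate",
                      stacklevel=2)
    se = np.sqrt(ms_error / n) if ms_error > 0 else 0.0
    means = x.mean(axis=0)
    rows = []
    for a in range(m):
        for b in range(a + 1, m):
            diff = means[a] - means[b]
            if se > 0:
                q = abs(diff) / se
                p = float(stats.studentized_range.sf(q, m, df_error))
            else:
                q = 0.0 if diff == 0 else np.inf
                p = 1.0 if diff == 0 else 0.0
            rows.append({"design_A": names[a], "design_B": names[b],
                         "mean_diff": float(diff), "q": float(q),
                         "p": p, "significant": p < alpha})
    return pd.DataFrame(rows)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ComparisonError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def design_similarity(change_vectors: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between every pair of design slope vectors.

    Zero-variance columns give undefined correlations, reported as NaN with
    a warning (the diagonal stays 1).
    """
    x = _as_matrix(change_vectors)
    names = list(change_vectors.columns)
    sd = x.std(axis=0, ddof=1)
    degenerate = [names[j] for j in np.flatnonzero(sd == 0)]
    if degenerate:
        warnings.warn(f"zero-variance design column(s) {degenerate}: "
                      "correlations undefined", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=names, columns=names)


def similarity_to_reference(similarity: pd.DataFrame,
                            reference: str = "D_R") -> pd.Series:
    """The reference column of a similarity matrix, without the reference
    itself — the per-design agreement with the full design."""
    if reference not in similarity.columns:
        raise ComparisonError(f"reference design {reference!r} not in matrix")
    return similarity[reference].drop(index=reference)
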