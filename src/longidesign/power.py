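"""Power and sample size for one-group within-subjects ANOVA.

Implements the repeated-measures power calculation that desk tools expose
as "ANOVA: repeated measures, within factors": with Cohen effect size
f = sigma_means / sigma (sigma the within-cell standard deviation), m
repeated measurements whose average pairwise correlation is rho, and
nonsphericity correction epsilon, the F statistic under the alternative is
noncentral F with

    df1 = (m - 1) eps,   df2 = (n - 1)(m - 1) eps,
    lambda = f^2 * n * m * eps / (1 - rho).

The repeated-measures correlation enters through the 1/(1 - rho) factor:
removing the shared subject component shrinks the error term, so higher
correlation buys power.  The convention is validated against a direct
Monte-Carlo oracle (:func:`mc_power_rm_anova`) rather than against any
particular software's output.

rho itself is estimated from data as the average of all pairwise Pearson
correlations between session columns, averaged on the Fisher-z scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .designs import DesignSpec, subsample
from .synthetic import LongitudinalDataset

__all__ = [
    "PowerConfig",
    "PowerResult",
    "PowerError",
    "estimate_rho",
    "power_rm_anova",
    "mc_power_rm_anova",
    "solve_sample_size",
    "sample_size_sweep",
]

_Z_CAP = 1.0 - 1e-7  # |r| guard before the Fisher transform


class PowerError(ValueError):
    """Invalid power configuration or unreachable target."""


@dataclass(frozen=True)
class PowerConfig:
    """Inputs of the within-subjects power calculation.

    f=0.2 / alpha=0.05 / target_power=0.8 is the conventional
    small-effect planning setting.  ``epsilon`` defaults to 1 (sphericity
    assumed at the planning stage); ``rho`` must exceed the compound-symmetry
    lower bound -1/(m-1).
    """

    f: float = 0.2
    alpha: float = 0.05
    target_power: float = 0.8
    m: int = 5
    k: int = 1
    rho: float = 0.5
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        if self.f < 0:
            raise PowerError("effect size f must be >= 0")
        if not 0 < self.alpha < 1 or not 0 < self.target_power < 1:
            raise PowerError("alpha and target_power must be in (0, 1)")
        if self.m < 2:
            raise PowerError("need m >= 2 repeated measurements")
        if self.k < 1:
            raise PowerError("k must be >= 1")
        if not -1.0 / (self.m - 1) < self.rho < 1.0:
            raise PowerError(
                f"rho must be in (-1/(m-1), 1) = ({-1.0 / (self.m - 1):.3f}, 1)")
        if not 1.0 / (self.m - 1) <= self.epsilon <= 1.0:
            raise PowerError("epsilon must be in [1/(m-1), 1]")

    def with_(self, **kwargs) -> "PowerConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PowerResult:
    """Minimal sample size and the power it achieves."""

    n_required: int
    achieved_power: float
    lam: float
    df1: float
    df2: float


def estimate_rho(dataset: LongitudinalDataset, bundle: str, measure: str,
                 design: Optional[DesignSpec] = None,
                 average: str = "fisher") -> float:
    """Average pairwise Pearson correlation between session columns.

    Participants are the observations; all m(m-1)/2 session pairs are
    correlated and averaged on the Fisher-z scale (back-transformed), or
    arithmetically with ``average="arithmetic"``.  Zero-variance columns
    skip their pairs with a warning.
    """
    if average not in ("fisher", "arithmetic"):
        raise PowerError(f"unknown averaging mode {average!r}")
    data = subsample(dataset, design) if design is not None else dataset
    sub = data.records[(data.records["bundle"] == bundle)
                       & (data.records["measure"] == measure)]
    if sub.empty:
        raise PowerError(f"no records for ({bundle}, {measure})")
    wide = sub.pivot(index="participant_id", columns="session_index",
                     values="value").dropna()
    n, m = wide.shape
    if m < 2:
        raise PowerError("need >= 2 sessions to estimate rho")
    if n < 4:
        raise PowerError("need >= 4 participants with complete data")
    x = wide.to_numpy()
    sd = x.std(axis=0, ddof=1)
    rs = []
    for a in range(m):
        for b in range(a + 1, m):
            if sd[a] == 0 or sd[b] == 0:
                warnings.warn(
                    f"zero-variance session column; skipping pair ({a}, {b})",
                    stacklevel=2)
                continue
            rs.append(float(np.corrcoef(x[:, a], x[:, b])[0, 1]))
    if not rs:
        raise PowerError("all session pairs degenerate; rho inestimable")
    rs = np.clip(rs, -_Z_CAP, _Z_CAP)
    if average == "fisher":
        return float(np.tanh(np.mean(np.arctanh(rs))))
    return float(np.mean(rs))


def _dfs_lambda(n: int, config: PowerConfig) -> tuple[float, float, float]:
    eps, m, k = config.epsilon, config.m, config.k
    df1 = (m - 1) * eps
    df2 = (n - k) * (m - 1) * eps
    lam = config.f ** 2 * n * m * eps / (1.0 - config.rho)
    return df1, df2, lam


def power_rm_anova(n: int, config: PowerConfig) -> float:
    """Analytic power of the within-subjects F test at sample size ``n``."""
    if n <= config.k:
        raise PowerError(f"need n > k = {config.k}")
    df1, df2, lam = _dfs_lambda(n, config)
    f_crit = stats.f.isf(config.alpha, df1, df2)
    if lam == 0.0:
        return float(config.alpha)  # central F: rejection rate is exactly alpha
    return float(stats.ncf.sf(f_crit, df1, df2, lam))


def mc_power_rm_anova(n: int, config: PowerConfig, n_reps: int = 5000,
                      seed: int = 0) -> tuple[float, float]:
    """Monte-Carlo rejection rate of the repeated-measures F test.

    Independent oracle for :func:`power_rm_anova`: draws compound-symmetric
    data (unit total variance, subject-component variance rho) with
    condition means of population spread f around zero, computes the
    within-subjects F for each replicate directly from sums of squares, and
    counts rejections at the central-F critical value.

    Returns ``(rate, binomial standard error)``.
    """
    rng = np.random.default_rng(seed)
    m = config.m
    mu = np.linspace(-1.0, 1.0, m)
    mu -= mu.mean()
    spread = np.sqrt((mu ** 2).mean())
    mu = mu / spread * config.f if spread > 0 else mu
    sd_subj = np.sqrt(max(config.rho, 0.0))
    sd_err = np.sqrt(1.0 - max(config.rho, 0.0))

    subj = rng.normal(0.0, sd_subj, size=(n_reps, n, 1))
    err = rng.normal(0.0, sd_err, size=(n_reps, n, m))
    y = mu[None, None, :] + subj + err

    grand = y.mean(axis=(1, 2), keepdims=True)
    colm = y.mean(axis=1, keepdims=True)
    rowm = y.mean(axis=2, keepdims=True)
    ss_cond = (n * ((colm - grand) ** 2).sum(axis=2)).ravel()
    ss_err = ((y - colm - rowm + grand) ** 2).sum(axis=(1, 2))
    df1, df2 = m - 1, (n - 1) * (m - 1)
    F = (ss_cond / df1) / (ss_err / df2)
    f_crit = stats.f.isf(config.alpha, df1, df2)
    rate = float(np.mean(F > f_crit))
    se = float(np.sqrt(rate * (1.0 - rate) / n_reps))
    return rate, se


def solve_sample_size(config: PowerConfig, n_max: int = 1_000_000) -> PowerResult:
    """Smallest n whose analytic power reaches ``config.target_power``.

    Bracket-and-bisect on the monotone power curve; the result carries a
    minimality certificate (power(n) >= target > power(n-1)).
    """
    lo = config.k + 1
    if power_rm_anova(lo, config) >= config.target_power:
        df1, df2, lam = _dfs_lambda(lo, config)
        return PowerResult(lo, power_rm_anova(lo, config), lam, df1, df2)
    hi = lo
    while power_rm_anova(hi, config) < config.target_power:
        hi *= 2
        if hi > n_max:
            raise PowerError(
                f"target power {config.target_power} unreachable below "
                f"n_max={n_max} (f={config.f})")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_rm_anova(mid, config) >= config.target_power:
            hi = mid
        else:
            lo = mid
    df1, df2, lam = _dfs_lambda(hi, config)
    return PowerResult(hi, power_rm_anova(hi, config), lam, df1, df2)


def sample_size_sweep(dataset: LongitudinalDataset,
                      designs: Sequence[DesignSpec],
                      bundles: Optional[Sequence[str]] = None,
                      measures: Optional[Sequence[str]] = None,
                      config: Optional[PowerConfig] = None) -> pd.DataFrame:
    """Required n per (bundle, measure, design).

    For each cell, rho is estimated from that design's session columns and
    m is the design's acquisition count; cells whose estimation or solve
    fails are reported with NaN.
    """
    config = config or PowerConfig()
    bundles = list(bundles) if bundles is not None \
        else sorted(dataset.records["bundle"].unique())
    measures = list(measures) if measures is not None \
        else sorted(dataset.records["measure"].unique())
    rows = []
    for d in designs:
        for bundle in bundles:
            for measure in measures:
                row = {"bundle": bundle, "measure": measure,
                       "design_name": d.name, "m": d.m,
                       "rho": np.nan, "n_required": np.nan,
                       "achieved_power": np.nan}
                try:
                    rho = estimate_rho(dataset, bundle, measure, design=d)
                    res = solve_sample_size(config.with_(m=d.m, rho=rho))
                    row.update(rho=rho, n_required=res.n_required,
                               achieved_power=res.achieved_power)
                except PowerError as exc:
                    warnings.warn(f"{d.name}/{bundle}/{measure}: {exc}",
                                  stacklevel=2)
                rows.append(row)
    return pd.DataFrame(rows)
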