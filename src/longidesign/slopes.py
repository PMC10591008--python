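"""Participant-specific change-over-time from linear mixed models.

For one (bundle, measure) under one design, fits

    value ~ 1 + week [+ covariates]   with correlated random
                                      intercept + slope per participant,

by REML.  Each participant's change over time is the fixed time coefficient
plus that participant's predicted random slope (the conditional mode /
BLUP), so individual slopes are shrunk toward the population slope in
proportion to how noisy the individual data are.

Three-timepoint random-slope fits are fragile; when the full model fails to
converge or its random-effects covariance is singular, the fit falls back
to (1) independent random intercept and slope, then (2) a random-intercept
model whose fixed slope is combined with centred per-participant OLS slope
deviations.  The route taken is recorded in the fit metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLMParams
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .designs import DesignSpec, subsample
from .synthetic import LongitudinalDataset

__all__ = ["SlopeTable", "FitError", "fit_lmm", "fit_design_slopes",
           "extract_change_vectors"]


class FitError(RuntimeError):
    """Mixed-model estimation failed beyond all fallbacks."""


@dataclass
class SlopeTable:
    """Tidy participant slopes plus per-fit metadata.

    ``entries`` columns: participant_id, bundle, measure, design_name, slope
    (measure units per week).  ``fit_meta`` maps
    (bundle, measure, design_name) -> dict with fixed effects, variance
    components, the estimation route and a convergence flag.
    """

    entries: pd.DataFrame
    fit_meta: dict = field(default_factory=dict)

    def concat(self, other: "SlopeTable") -> "SlopeTable":
        return SlopeTable(
            entries=pd.concat([self.entries, other.entries], ignore_index=True),
            fit_meta={**self.fit_meta, **other.fit_meta},
        )


def _design_matrices(df: pd.DataFrame, covariates: Sequence[str]):
    exog = pd.DataFrame({"Intercept": 1.0, "week": df["week"]}, index=df.index)
    for cov in covariates:
        if cov == "sex":
            exog["sex"] = (df["sex"] == "M").astype(float)
        else:
            col = df[cov].astype(float)
            exog[cov] = col - col.mean()
    return df["value"], exog


def _ols_slopes(df: pd.DataFrame) -> pd.Series:
    """Per-participant ordinary least-squares slope of value on week."""
    def slope(g: pd.DataFrame) -> float:
        w = g["week"].to_numpy()
        v = g["value"].to_numpy()
        wc = w - w.mean()
        denom = float(wc @ wc)
        if denom == 0:
            return np.nan
        return float(wc @ (v - v.mean()) / denom)
    return df.groupby("participant_id").apply(slope, include_groups=False)


def _try_mixedlm(endog, exog, groups, exog_re, free=None):
    model = sm.MixedLM(endog, exog, groups=groups, exog_re=exog_re)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            result = model.fit(reml=True, free=free, method="bfgs", maxiter=500)
        except (np.linalg.LinAlgError, ValueError):
            return None
    if not np.all(np.isfinite(result.fe_params)):
        return None
    return result


def _cov_re_singular(result, rtol: float = 1e-4) -> bool:
    cov = np.atleast_2d(np.asarray(result.cov_re))
    eig = np.linalg.eigvalsh(cov)
    scale = max(eig.max(), 1e-300)
    return bool(eig.min() / scale < rtol)


def fit_lmm(dataset: LongitudinalDataset, bundle: str, measure: str,
            covariates: Sequence[str] = (),
            design_name: str = "D_R",
            time: str = "acquisition_week") -> SlopeTable:
    """Fit the mixed model for one (bundle, measure) and return participant
    slopes.

    Parameters
    ----------
    dataset
        Long-format dataset (already subsampled to the design of interest).
    bundle, measure
        Cell of the measure grid to fit.
    covariates
        Baseline fixed-effect adjusters; any of ``age``, ``sex``,
        ``disease_duration`` (empty for a healthy-cohort analysis).
    design_name
        Label stored in the output (the fit itself only sees the data).
    time
        ``"acquisition_week"`` (real jittered weeks, default) or
        ``"nominal_week"`` — which clock to use as the time covariate.
    """
    sub = dataset.records[
        (dataset.records["bundle"] == bundle)
        & (dataset.records["measure"] == measure)
    ]
    if sub.empty:
        raise FitError(f"no records for ({bundle}, {measure})")
    df = sub.merge(dataset.covariates, on="participant_id", how="left")
    if time == "nominal_week":
        # nominal clock: average acquisition week per session index
        nominal = sub.groupby("session_index")["acquisition_week"].mean()
        df["week"] = df["session_index"].map(nominal)
    else:
        df["week"] = df["acquisition_week"]

    counts = df.groupby("participant_id").size()
    if (counts < 2).any():
        df = df[df["participant_id"].isin(counts[counts >= 2].index)]
    if df["participant_id"].nunique() < 3:
        raise FitError("need at least 3 participants with >= 2 sessions")

    endog, exog = _design_matrices(df, covariates)
    groups = df["participant_id"]
    exog_re = exog[["Intercept", "week"]]

    meta = {"bundle": bundle, "measure": measure, "design": design_name,
            "covariates": list(covariates), "converged": True}

    # Degenerate noise-free data: every participant lies exactly on a line,
    # the residual variance is zero and the mixed model is singular.  The
    # conditional modes then coincide with the per-participant OLS slopes,
    # which we return exactly instead of pushing a 0/0 problem through REML.
    ols = _ols_slopes(df)
    resid_ss = 0.0
    for pid, g in df.groupby("participant_id"):
        w = g["week"].to_numpy()
        v = g["value"].to_numpy()
        pred = v.mean() + ols.loc[pid] * (w - w.mean())
        resid_ss += float(((v - pred) ** 2).sum())
    value_scale = max(float(df["value"].var(ddof=0)), 1e-300)
    if resid_ss <= 1e-12 * value_scale * len(df):
        slopes = {pid: float(ols.loc[pid]) for pid in ols.index}
        meta.update(method="ols_exact_degenerate",
                    fixed_effects={"week": float(np.mean(list(slopes.values())))},
                    cov_re=[[0.0, 0.0], [0.0, float(np.var(list(slopes.values())))]],
                    resid_var=0.0)
        entries = pd.DataFrame({
            "participant_id": sorted(slopes),
            "bundle": bundle, "measure": measure, "design_name": design_name,
            "slope": [slopes[p] for p in sorted(slopes)],
        })
        return SlopeTable(entries=entries,
                          fit_meta={(bundle, measure, design_name): meta})

    # centre the response so estimates are exactly location-invariant
    endog_mean = float(endog.mean())
    endog = endog - endog_mean

    result = _try_mixedlm(endog, exog, groups, exog_re)
    method = "reml_correlated"
    if result is not None and (not result.converged or _cov_re_singular(result)):
        result = None
    if result is None:
        # fallback 1: independent random intercept and slope
        free = MixedLMParams.from_components(
            fe_params=np.ones(exog.shape[1]), cov_re=np.eye(2))
        result = _try_mixedlm(endog, exog, groups, exog_re, free=free)
        method = "reml_independent"
        if result is not None and not result.converged:
            result = None

    if result is not None:
        fixed_slope = float(result.fe_params["week"])
        re = result.random_effects
        slopes = {pid: fixed_slope + float(eff.get("week", 0.0))
                  for pid, eff in re.items()}
        fe = {k: float(v) for k, v in result.fe_params.items()}
        fe["Intercept"] += endog_mean
        meta.update(
            method=method,
            fixed_effects=fe,
            cov_re=np.atleast_2d(np.asarray(result.cov_re)).tolist(),
            resid_var=float(result.scale),
        )
    else:
        # fallback 2: random intercept only + centred per-participant OLS
        # slope deviations around the fixed slope
        result = _try_mixedlm(endog, exog, groups, exog_re[["Intercept"]])
        if result is None:
            raise FitError(
                f"mixed model failed to converge for ({bundle}, {measure}, "
                f"{design_name}) after all fallbacks")
        method = "intercept_only_ols_slopes"
        fixed_slope = float(result.fe_params["week"])
        dev = ols - ols.mean()
        slopes = {pid: fixed_slope + float(dev.loc[pid]) for pid in ols.index}
        fe = {k: float(v) for k, v in result.fe_params.items()}
        fe["Intercept"] += endog_mean
        meta.update(
            method=method,
            fixed_effects=fe,
            cov_re=np.atleast_2d(np.asarray(result.cov_re)).tolist(),
            resid_var=float(result.scale),
        )
        meta["converged"] = bool(result.converged)

    entries = pd.DataFrame({
        "participant_id": sorted(slopes),
        "bundle": bundle,
        "measure": measure,
        "design_name": design_name,
        "slope": [slopes[p] for p in sorted(slopes)],
    })
    if not np.all(np.isfinite(entries["slope"])):
        raise FitError(f"non-finite slopes for ({bundle}, {measure}, {design_name})")
    return SlopeTable(entries=entries,
                      fit_meta={(bundle, measure, design_name): meta})


def fit_design_slopes(dataset: LongitudinalDataset,
                      designs: Sequence[DesignSpec],
                      bundles: Optional[Sequence[str]] = None,
                      measures: Optional[Sequence[str]] = None,
                      covariates: Sequence[str] = (),
                      time: str = "acquisition_week") -> SlopeTable:
    """Fit every (bundle, measure, design) cell and pool the slope tables.

    Cells whose fit fails beyond all fallbacks are skipped with a warning
    rather than aborting the sweep.
    """
    bundles = list(bundles) if bundles is not None \
        else sorted(dataset.records["bundle"].unique())
    measures = list(measures) if measures is not None \
        else sorted(dataset.records["measure"].unique())
    table: Optional[SlopeTable] = None
    for d in designs:
        data_d = subsample(dataset, d)
        for bundle in bundles:
            for measure in measures:
                try:
                    part = fit_lmm(data_d, bundle, measure, covariates,
                                   design_name=d.name, time=time)
                except FitError as exc:
                    warnings.warn(str(exc), stacklevel=2)
                    continue
                table = part if table is None else table.concat(part)
    if table is None:
        raise FitError("no (bundle, measure, design) cell could be fitted")
    return table


def extract_change_vectors(slopes: SlopeTable, designs: Sequence[str],
                           bundle: str, measure: str) -> pd.DataFrame:
    """Participant x design matrix of slopes for one (bundle, measure).

    Rows are the participants present in *all* requested designs, sorted by
    id; participants missing from any design are dropped (their count is
    reported via a warning).
    """
    sub = slopes.entries[
        (slopes.entries["bundle"] == bundle)
        & (slopes.entries["measure"] == measure)
        & (slopes.entries["design_name"].isin(designs))
    ]
    found = set(sub["design_name"].unique())
    missing = [d for d in designs if d not in found]
    if missing:
        raise FitError(f"no slopes for design(s) {missing} in ({bundle}, {measure})")
    wide = sub.pivot(index="participant_id", columns="design_name", values="slope")
    wide = wide[list(designs)]
    n_all = len(wide)
    wide = wide.dropna()
    if len(wide) < n_all:
        warnings.warn(
            f"excluded {n_all - len(wide)} participant(s) missing from some design",
            stacklevel=2)
    return wide.sort_index()
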