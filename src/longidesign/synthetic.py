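"""Synthetic longitudinal tractometry-style data.

Generates per-participant, per-session, per-bundle, per-measure tables with
the statistical structure a longitudinal bundle-averaged MRI study assumes:
a population-level linear trend in time, correlated participant-specific
random intercepts and slopes, independent Gaussian residual noise, uniform
acquisition-day jitter around the nominal schedule, a participant covariate
table (age, sex, disease duration), and clinical change scores whose rank
correlation with the true slopes is controllable through a Gaussian copula.

The generative model for measure value :math:`y_{it}` of participant *i* at
acquisition week :math:`w_{it}` is

.. math::

    y_{it} = \\mu + \\beta w_{it} + x_i^\\top \\gamma
             + a_i + b_i w_{it} + \\varepsilon_{it},

with :math:`(a_i, b_i)` bivariate normal (standard deviations
``intercept_sd``/``slope_sd``, correlation ``intercept_slope_corr``),
:math:`\\varepsilon_{it} \\sim N(0, \\sigma^2)` independent, and covariate
coefficients :math:`\\gamma` zero by default.  The "true slope" recorded in
the truth table is :math:`\\beta + b_i`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimulationConfig",
    "LongitudinalDataset",
    "ConfigurationError",
    "SchemaError",
    "DEFAULT_BUNDLES",
    "DEFAULT_MEASURES",
    "DEFAULT_CLINICAL_SCORES",
    "simulate_dataset",
    "simulate_clinical",
    "write_dataset",
    "read_dataset",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


class SchemaError(ValueError):
    """A table read from disk violates the expected schema."""


#: Bundles of interest: anterior corpus callosum, corticospinal tract,
#: cingulate gyrus, middle superior longitudinal fasciculus, optic radiation.
DEFAULT_BUNDLES = ("CC3", "CST", "CG", "SLF2", "OR")

#: Diffusion- and myelin-sensitive per-bundle scalar measures.
DEFAULT_MEASURES = (
    "MD", "RD", "FW", "AFD_total", "ICvf", "ISOvf", "MTR", "ihMTdR1sat",
)

#: Clinical scores: (baseline mean, baseline sd, change mean, change sd).
#: Disability (EDSS), processing speed (SDMT), dexterity (9HPT) and walking
#: speed (T25FW) with moments matching a stable relapsing-remitting cohort.
DEFAULT_CLINICAL_SCORES: Mapping[str, tuple[float, float, float, float]] = {
    "EDSS": (2.0, 1.2, 0.0, 0.25),
    "SDMT": (57.1, 11.4, 4.4, 13.8),
    "9HPT": (23.5, 9.8, -0.9, 3.5),
    "T25FW": (6.2, 2.5, -0.12, 1.0),
}

ParamLike = Union[float, Mapping[str, float]]

REQUIRED_RECORD_COLUMNS = (
    "participant_id", "session_index", "acquisition_week",
    "bundle", "measure", "value",
)
REQUIRED_COVARIATE_COLUMNS = ("participant_id", "age", "sex", "disease_duration")
REQUIRED_CLINICAL_COLUMNS = (
    "participant_id", "score_name", "baseline_value", "followup_value",
)
REQUIRED_TRUTH_COLUMNS = ("participant_id", "bundle", "measure", "true_slope")


def _lookup(param: ParamLike, bundle: str, measure: str) -> float:
    """Resolve a scalar-or-mapping parameter for a (bundle, measure) cell.

    Mappings may be keyed by measure ("MD") or by "bundle:measure" ("CST:MD");
    the more specific key wins.
    """
    if isinstance(param, Mapping):
        key = f"{bundle}:{measure}"
        if key in param:
            return float(param[key])
        if measure in param:
            return float(param[measure])
        raise ConfigurationError(
            f"no parameter value for measure {measure!r} (bundle {bundle!r})"
        )
    return float(param)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic longitudinal study.

    Defaults emulate a 6-month monthly-MRI cohort: 20 participants scanned at
    5 sessions on a 4-week nominal schedule with +/- 1 week acquisition
    jitter, 5 bundles x 8 measures, and Table-1-style covariates (age 36
    (4.7) years, 4 male / 16 female, disease duration 7 (5.9) years).

    Measure values are on an arbitrary normalized scale with baseline level
    ~1.0; the default weekly decline (-0.002/week) with between-participant
    slope spread 0.004/week and residual noise 0.01 gives a high-information
    regime in which individual slopes are well identified from 5 sessions.
    """

    n_participants: int = 20
    session_weeks: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 16.0)
    jitter_days: float = 7.0
    bundles: tuple[str, ...] = DEFAULT_BUNDLES
    measures: tuple[str, ...] = DEFAULT_MEASURES
    intercept_mean: ParamLike = 1.0
    fixed_slope: ParamLike = -0.002          # measure units / week
    slope_sd: ParamLike = 0.004              # between-participant slope sd
    intercept_sd: ParamLike = 0.05           # between-participant intercept sd
    intercept_slope_corr: float = 0.0
    noise_sd: ParamLike = 0.01               # residual sd per (bundle, measure)
    # covariates
    age_mean: float = 36.0
    age_sd: float = 4.7
    n_male: int = 4
    n_female: int = 16
    disease_duration_mean: float = 7.0
    disease_duration_sd: float = 5.9
    # covariate fixed effects on the measure level (zero unless set)
    age_effect: float = 0.0
    sex_effect: float = 0.0
    disease_duration_effect: float = 0.0
    # clinical coupling
    clinical_scores: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_SCORES)
    )
    clinical_target_spearman: Union[float, Mapping[str, float]] = 0.5
    clinical_anchor: Optional[tuple[str, str]] = None  # (bundle, measure)
    # missingness
    session_missing_rate: Union[float, Mapping[int, float]] = 0.0
    n_dropout: int = 0                       # whole participants removed after baseline
    seed: int = 0

    def __post_init__(self) -> None:
        weeks = tuple(float(w) for w in self.session_weeks)
        object.__setattr__(self, "session_weeks", weeks)
        if len(weeks) < 2 or weeks[0] != 0.0:
            raise ConfigurationError("session_weeks must start at 0 and have >= 2 sessions")
        if any(b >= a for b, a in zip(weeks, weeks[1:])):
            raise ConfigurationError("session_weeks must be strictly increasing")
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be positive")
        if self.jitter_days < 0:
            raise ConfigurationError("jitter_days must be >= 0")
        for name in ("slope_sd", "intercept_sd", "noise_sd"):
            p = getattr(self, name)
            vals = p.values() if isinstance(p, Mapping) else (p,)
            if any(v < 0 for v in vals):
                raise ConfigurationError(f"{name} must be >= 0")
        if not -1.0 <= self.intercept_slope_corr <= 1.0:
            raise ConfigurationError("intercept_slope_corr must be in [-1, 1]")
        rho = self.clinical_target_spearman
        rhos = rho.values() if isinstance(rho, Mapping) else (rho,)
        if any(abs(r) > 1.0 for r in rhos):
            raise ConfigurationError("clinical_target_spearman must be in [-1, 1]")
        if self.n_dropout < 0 or self.n_dropout >= self.n_participants:
            raise ConfigurationError("n_dropout must be in [0, n_participants)")

    @property
    def anchor(self) -> tuple[str, str]:
        """(bundle, measure) whose true slopes drive the clinical coupling."""
        return self.clinical_anchor or (self.bundles[0], self.measures[0])

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class LongitudinalDataset:
    """Long-format measure records plus covariate, clinical and truth tables.

    ``records`` columns: participant_id, session_index (0-based),
    acquisition_week (real weeks from baseline), bundle, measure, value.
    ``truth`` is simulator-only: the true per-participant slope per
    (bundle, measure).
    """

    records: pd.DataFrame
    covariates: pd.DataFrame
    clinical: pd.DataFrame
    truth: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_RECORD_COLUMNS if c not in self.records.columns]
        if missing:
            raise SchemaError(f"records table missing column(s) {missing}")
        if len(self.records) == 0:
            warnings.warn("records table is empty", stacklevel=3)
            return
        base = self.records[self.records["session_index"] == 0]
        if not np.allclose(base["acquisition_week"], 0.0):
            raise SchemaError("session_index 0 must have acquisition_week == 0")

    @property
    def participants(self) -> list:
        return sorted(self.records["participant_id"].unique())

    @property
    def session_indices(self) -> list[int]:
        return sorted(int(s) for s in self.records["session_index"].unique())

    def n_participant_sessions(self) -> int:
        return len(
            self.records[["participant_id", "session_index"]].drop_duplicates()
        )


def _draw_covariates(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_participants
    ids = [f"P{i:03d}" for i in range(n)]
    age = rng.normal(config.age_mean, config.age_sd, size=n)
    # scale the configured male/female counts to the requested n
    frac_m = config.n_male / max(config.n_male + config.n_female, 1)
    n_male = int(round(frac_m * n))
    sex = np.array(["M"] * n_male + ["F"] * (n - n_male))
    rng.shuffle(sex)
    dd = np.abs(rng.normal(config.disease_duration_mean,
                           config.disease_duration_sd, size=n))
    return pd.DataFrame(
        {"participant_id": ids, "age": age, "sex": sex, "disease_duration": dd}
    )


def simulate_dataset(config: SimulationConfig,
                     seed: Optional[int] = None) -> LongitudinalDataset:
    """Simulate a complete longitudinal dataset under ``config``.

    The same (config, seed) pair always produces bit-identical tables.
    Acquisition weeks are the nominal session weeks plus uniform jitter of
    half-width ``jitter_days`` (converted to weeks); the baseline session is
    pinned at week 0 and is never jittered or dropped.

    Parameters
    ----------
    config
        Validated simulation parameters.
    seed
        Overrides ``config.seed`` when given.

    Returns
    -------
    LongitudinalDataset
        With the truth table populated (true slope = population slope +
        participant random slope, per bundle and measure).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_participants
    weeks = np.asarray(config.session_weeks)
    n_sessions = len(weeks)

    covariates = _draw_covariates(config, rng)
    ids = covariates["participant_id"].to_numpy()

    # shared acquisition times per participant-session (one scan per session)
    jitter_weeks = config.jitter_days / 7.0
    acq = np.tile(weeks, (n, 1))
    if jitter_weeks > 0:
        acq[:, 1:] += rng.uniform(-jitter_weeks, jitter_weeks, size=(n, n_sessions - 1))

    sex_num = (covariates["sex"] == "M").to_numpy(float)
    cov_shift = (
        config.age_effect * (covariates["age"].to_numpy() - config.age_mean)
        + config.sex_effect * sex_num
        + config.disease_duration_effect
        * (covariates["disease_duration"].to_numpy() - config.disease_duration_mean)
    )

    rec_frames = []
    truth_rows = []
    for bundle in config.bundles:
        for measure in config.measures:
            mu = _lookup(config.intercept_mean, bundle, measure)
            beta = _lookup(config.fixed_slope, bundle, measure)
            s_int = _lookup(config.intercept_sd, bundle, measure)
            s_slope = _lookup(config.slope_sd, bundle, measure)
            s_noise = _lookup(config.noise_sd, bundle, measure)
            r = config.intercept_slope_corr
            cov = np.array([[s_int ** 2, r * s_int * s_slope],
                            [r * s_int * s_slope, s_slope ** 2]])
            # svd handles the degenerate (zero-sd) covariance cases
            ab = rng.multivariate_normal([0.0, 0.0], cov, size=n,
                                         method="svd")
            a_i, b_i = ab[:, 0], ab[:, 1]
            eps = rng.normal(0.0, s_noise, size=(n, n_sessions)) if s_noise > 0 \
                else np.zeros((n, n_sessions))
            values = (mu + cov_shift[:, None]
                      + a_i[:, None]
                      + (beta + b_i)[:, None] * acq
                      + eps)
            rec_frames.append(pd.DataFrame({
                "participant_id": np.repeat(ids, n_sessions),
                "session_index": np.tile(np.arange(n_sessions), n),
                "acquisition_week": acq.ravel(),
                "bundle": bundle,
                "measure": measure,
                "value": values.ravel(),
            }))
            truth_rows.append(pd.DataFrame({
                "participant_id": ids,
                "bundle": bundle,
                "measure": measure,
                "true_slope": beta + b_i,
            }))

    records = pd.concat(rec_frames, ignore_index=True)
    truth = pd.concat(truth_rows, ignore_index=True)

    # per-session missingness (never at baseline)
    rate = config.session_missing_rate
    if (isinstance(rate, Mapping) and any(v > 0 for v in rate.values())) or (
            not isinstance(rate, Mapping) and rate > 0):
        keep = np.ones(len(ids) * n_sessions, dtype=bool).reshape(n, n_sessions)
        for s in range(1, n_sessions):
            r_s = rate.get(s, 0.0) if isinstance(rate, Mapping) else rate
            if r_s > 0:
                keep[:, s] &= rng.uniform(size=n) >= r_s
        keep_df = pd.DataFrame({
            "participant_id": np.repeat(ids, n_sessions),
            "session_index": np.tile(np.arange(n_sessions), n),
            "_keep": keep.ravel(),
        })
        records = records.merge(keep_df, on=["participant_id", "session_index"])
        records = records[records["_keep"]].drop(columns="_keep").reset_index(drop=True)

    # whole-participant dropout (mimics mid-study exclusion, e.g. a relapse)
    if config.n_dropout > 0:
        dropped = rng.choice(ids, size=config.n_dropout, replace=False)
        records = records[~records["participant_id"].isin(dropped)].reset_index(drop=True)
        truth = truth[~truth["participant_id"].isin(dropped)].reset_index(drop=True)
        covariates = covariates[~covariates["participant_id"].isin(dropped)]
        covariates = covariates.reset_index(drop=True)

    clinical = simulate_clinical(truth, config, rng=rng)
    return LongitudinalDataset(records=records, covariates=covariates,
                               clinical=clinical, truth=truth)


def simulate_clinical(truth: pd.DataFrame, config: SimulationConfig,
                      rng: Optional[np.random.Generator] = None,
                      seed: Optional[int] = None) -> pd.DataFrame:
    """Draw clinical change scores rank-coupled to the true slopes.

    The coupling is a Gaussian copula on ranks: the anchor (bundle, measure)
    slopes are converted to normal scores u, a latent
    ``v = r u + sqrt(1 - r^2) e`` is drawn with the latent Pearson r chosen
    so the population Spearman correlation equals the target
    (``r = 2 sin(pi * rho_s / 6)``), and the change score is
    ``change_mean + change_sd * v``.  Baselines are drawn independently from
    the configured marginals; followup = baseline + change.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    bundle, measure = config.anchor
    sub = truth[(truth["bundle"] == bundle) & (truth["measure"] == measure)]
    sub = sub.sort_values("participant_id").reset_index(drop=True)
    if len(sub) == 0:
        raise ConfigurationError(
            f"truth table has no rows for clinical anchor ({bundle}, {measure})"
        )
    slopes = sub["true_slope"].to_numpy()
    n = len(slopes)
    # normal scores of the slope ranks (average ranks for ties)
    u = stats.norm.ppf((stats.rankdata(slopes) - 0.5) / n)

    rows = []
    target = config.clinical_target_spearman
    for score, (b_mean, b_sd, c_mean, c_sd) in config.clinical_scores.items():
        rho_s = target.get(score, 0.0) if isinstance(target, Mapping) else target
        if abs(rho_s) > 1.0:
            raise ConfigurationError("clinical_target_spearman must be in [-1, 1]")
        r = 2.0 * np.sin(np.pi * rho_s / 6.0)
        v = r * u + np.sqrt(max(1.0 - r ** 2, 0.0)) * rng.standard_normal(n)
        change = c_mean + c_sd * v
        baseline = b_mean + b_sd * rng.standard_normal(n)
        rows.append(pd.DataFrame({
            "participant_id": sub["participant_id"],
            "score_name": score,
            "baseline_value": baseline,
            "followup_value": baseline + change,
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# I/O: plain CSV, one file per table, in a directory.

_TABLE_FILES = {
    "records": ("records.csv", REQUIRED_RECORD_COLUMNS),
    "covariates": ("covariates.csv", REQUIRED_COVARIATE_COLUMNS),
    "clinical": ("clinical.csv", REQUIRED_CLINICAL_COLUMNS),
    "truth": ("truth.csv", REQUIRED_TRUTH_COLUMNS),
}


def write_dataset(dataset: LongitudinalDataset, path: Union[str, Path]) -> Path:
    """Write all tables of ``dataset`` as CSV files under directory ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for attr, (fname, _) in _TABLE_FILES.items():
        table = getattr(dataset, attr)
        if table is None:
            continue
        table.to_csv(path / fname, index=False)
    return path


def read_dataset(path: Union[str, Path]) -> LongitudinalDataset:
    """Read a dataset previously written by :func:`write_dataset`.

    Raises :class:`SchemaError` naming the offending column if a required
    column is absent.
    """
    path = Path(path)
    tables = {}
    for attr, (fname, required) in _TABLE_FILES.items():
        fpath = path / fname
        if not fpath.exists():
            if attr == "truth":
                tables[attr] = None
                continue
            raise SchemaError(f"missing table file {fname} in {path}")
        df = pd.read_csv(fpath)
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{fname}: missing required column(s) {missing}")
        tables[attr] = df
    return LongitudinalDataset(**tables)
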