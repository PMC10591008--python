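"""End-to-end orchestration: simulate -> subsample -> fit -> compare ->
power -> associate, with all file I/O conventions and seeding in one place.

Randomness flows from a single root seed through named ``SeedSequence``
substreams (one per stage), so any stage can be re-run independently and a
rerun with the same config and seed is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .associations import association_grid, build_ledger, clinical_change
from .comparison import bh_fdr, design_similarity, rm_anova, tukey_posthoc
from .designs import DesignSpec, classify_design, default_designs, parse_design
from .power import PowerConfig, sample_size_sweep
from .slopes import extract_change_vectors, fit_design_slopes
from .synthetic import ConfigurationError, SimulationConfig, simulate_dataset, \
    write_dataset

__all__ = ["RunConfig", "run_study", "report", "stage_seed"]

logger = logging.getLogger("longidesign")

_STAGES = ("simulate", "clinical", "fit", "compare", "power", "associate")


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed (< 2^31)."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    """Everything an end-to-end run needs.

    ``designs`` is either ``"auto(k)"`` (reference + all baseline-anchored
    k-subsets of the simulated schedule) or an explicit list of design
    names / index lists.  Defaults mirror the packaged analysis: ANOVA at
    0.05, Mauchly at 0.05, associations at 0.01 uncorrected, power planning
    at f=0.2 / alpha=0.05 / power=0.8.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    designs: Union[str, Sequence] = "auto(3)"
    anova_alpha: float = 0.05
    mauchly_alpha: float = 0.05
    assoc_alpha: float = 0.01
    covariates: Sequence[str] = ()
    power: PowerConfig = field(default_factory=PowerConfig)
    output_dir: Union[str, Path] = "longidesign_run"
    seed: int = 0
    replicates: int = 1
    time: str = "acquisition_week"

    def __post_init__(self) -> None:
        for name in ("anova_alpha", "mauchly_alpha", "assoc_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigurationError(f"{name} must be in (0, 1), got {v}")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        bad = [c for c in self.covariates
               if c not in ("age", "sex", "disease_duration")]
        if bad:
            raise ConfigurationError(f"unknown covariate(s) {bad}")

    def resolve_designs(self) -> list[DesignSpec]:
        weeks = self.simulation.session_weeks
        if isinstance(self.designs, str):
            spec = self.designs.strip()
            if spec.startswith("auto(") and spec.endswith(")"):
                return default_designs(weeks, k=int(spec[5:-1]))
            raise ConfigurationError(f"cannot interpret designs spec {spec!r}")
        out = []
        for d in self.designs:
            if isinstance(d, DesignSpec):
                out.append(classify_design(d, weeks))
            elif isinstance(d, str):
                out.append(classify_design(parse_design(d, len(weeks)), weeks))
            else:
                name_d = DesignSpec(name="", session_indices=tuple(d))
                name_d = dataclasses.replace(
                    name_d, name="D_" + "".join(map(str, name_d.session_indices)))
                out.append(classify_design(name_d, weeks))
        return out

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        pw = PowerConfig(**raw.pop("power", {}))
        return cls(simulation=sim, power=pw, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["output_dir"] = str(self.output_dir)
        d["covariates"] = list(self.covariates)
        if not isinstance(d["designs"], str):
            d["designs"] = [getattr(x, "name", x) for x in self.designs]
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("output_dir")  # where results land does not change what they are
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stamp(df: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    df = df.copy()
    df["seed"] = config.seed
    df["config_hash"] = config.config_hash()
    return df


def run_study(config: RunConfig) -> Path:
    """Execute the full pipeline and write a result bundle to
    ``config.output_dir``.

    Outputs: ``dataset/`` (CSV tables), ``slopes.csv``, ``anova.csv``,
    ``posthoc.csv``, ``similarity/<bundle>_<measure>.csv``,
    ``power_sweep.csv``, ``associations.csv``, ``ledger.csv``,
    ``ledger_frequencies.csv`` and ``manifest.json``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    designs = config.resolve_designs()  # validates before any compute
    ref = designs[0].name

    logger.info("simulating dataset (seed %d)", config.seed)
    dataset = simulate_dataset(config.simulation,
                               seed=stage_seed(config.seed, "simulate"))
    write_dataset(dataset, outdir / "dataset")
    n_excluded = config.simulation.n_participants - len(dataset.covariates)
    if n_excluded:
        logger.info("excluded %d participant(s) by dropout", n_excluded)

    logger.info("fitting mixed models for %d designs", len(designs))
    slopes = fit_design_slopes(dataset, designs,
                               covariates=config.covariates, time=config.time)
    _stamp(slopes.entries, config).to_csv(outdir / "slopes.csv", index=False)
    meta_json = {f"{b}|{m}|{d}": v for (b, m, d), v in slopes.fit_meta.items()}
    (outdir / "fit_meta.json").write_text(json.dumps(meta_json, indent=1))

    logger.info("comparing designs")
    bundles = sorted(dataset.records["bundle"].unique())
    measures = sorted(dataset.records["measure"].unique())
    (outdir / "similarity").mkdir(exist_ok=True)
    anova_rows, posthoc_frames = [], []
    design_names = [d.name for d in designs]
    for bundle in bundles:
        for measure in measures:
            try:
                vecs = extract_change_vectors(slopes, design_names, bundle, measure)
            except Exception as exc:  # cell skipped upstream
                warnings.warn(f"{bundle}/{measure}: {exc}", stacklevel=2)
                continue
            res = rm_anova(vecs, mauchly_alpha=config.mauchly_alpha)
            anova_rows.append({
                "bundle": bundle, "measure": measure, "F": res.F,
                "df1": res.df1, "df2": res.df2, "p": res.p,
                "mauchly_W": res.mauchly_W, "mauchly_p": res.mauchly_p,
                "epsilon_gg": res.epsilon_gg,
                "epsilon_applied": res.epsilon_applied,
            })
            ph = tukey_posthoc(vecs, res, alpha=config.anova_alpha)
            ph.insert(0, "measure", measure)
            ph.insert(0, "bundle", bundle)
            posthoc_frames.append(ph)
            sim = design_similarity(vecs)
            sim.to_csv(outdir / "similarity" / f"{bundle}_{measure}.csv")
    anova_df = pd.DataFrame(anova_rows)
    if len(anova_df):
        anova_df["p_fdr"] = bh_fdr(anova_df["p"])
    _stamp(anova_df, config).to_csv(outdir / "anova.csv", index=False)
    posthoc = pd.concat(posthoc_frames, ignore_index=True) if posthoc_frames \
        else pd.DataFrame()
    if len(posthoc):
        # FDR family: all post-hoc pairs within each (bundle, measure) sweep
        posthoc["p_fdr"] = np.nan
        for _, idx in posthoc.groupby(["bundle", "measure"]).groups.items():
            posthoc.loc[idx, "p_fdr"] = bh_fdr(posthoc.loc[idx, "p"])
    _stamp(posthoc, config).to_csv(outdir / "posthoc.csv", index=False)

    logger.info("power sweep")
    sweep = sample_size_sweep(dataset, designs, config=config.power)
    _stamp(sweep, config).to_csv(outdir / "power_sweep.csv", index=False)

    logger.info("clinical associations")
    deltas = clinical_change(dataset.clinical)
    assoc = association_grid(slopes.entries, deltas, alpha=config.assoc_alpha)
    _stamp(assoc, config).to_csv(outdir / "associations.csv", index=False)
    ledger = build_ledger(assoc, reference=ref)
    _stamp(ledger.records, config).to_csv(outdir / "ledger.csv", index=False)
    _stamp(ledger.frequencies, config).to_csv(
        outdir / "ledger_frequencies.csv", index=False)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES},
        "designs": [
            {"name": d.name, "session_indices": list(d.session_indices),
             "duration_weeks": d.duration_weeks,
             "interval_type": d.interval_type} for d in designs],
        "thresholds": {"anova_alpha": config.anova_alpha,
                       "mauchly_alpha": config.mauchly_alpha,
                       "assoc_alpha": config.assoc_alpha,
                       "power_alpha": config.power.alpha,
                       "target_power": config.power.target_power},
        "reference_total": ledger.reference_total,
        "n_participants": len(dataset.covariates),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir


def report(outdir: Union[str, Path]) -> Mapping[str, pd.DataFrame]:
    """Summaries of a completed run: mean similarity-to-reference per
    design, the bundle x design sample-size matrix, and per-design
    preserved-association frequencies."""
    outdir = Path(outdir)
    required = ["manifest.json", "power_sweep.csv", "ledger_frequencies.csv"]
    missing = [f for f in required if not (outdir / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete result bundle: missing {missing}")
    manifest = json.loads((outdir / "manifest.json").read_text())
    ref = manifest["designs"][0]["name"]

    sims = []
    for f in sorted((outdir / "similarity").glob("*.csv")):
        mat = pd.read_csv(f, index_col=0)
        col = mat[ref].drop(index=ref)
        sims.append(col.rename(f.stem))
    sim_summary = (pd.concat(sims, axis=1).mean(axis=1)
                   .rename("mean_similarity_to_reference").to_frame()
                   if sims else pd.DataFrame())

    sweep = pd.read_csv(outdir / "power_sweep.csv")
    size_matrix = sweep.pivot_table(index=["bundle", "measure"],
                                    columns="design_name", values="n_required")
    freqs = pd.read_csv(outdir / "ledger_frequencies.csv")
    return {"similarity": sim_summary, "sample_size": size_matrix,
            "preserved": freqs}
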