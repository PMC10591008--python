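"""MRI-clinical associations and their preservation across designs.

Clinical change is always the last study visit minus baseline.  Slope vs
clinical-change associations use Spearman rank correlation at an
uncorrected p < 0.01 threshold.  Each tested design's associations are
audited against the full reference design and classified as *preserved*
(significant in both, same sign), *inverse* (significant in both, opposite
sign), *lost* (reference only) or *new* (tested design only); preserved /
inverse / lost partition the reference-significant set, and frequencies
are expressed as percentages of the reference total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssociationError",
    "AssociationLedger",
    "clinical_change",
    "wilcoxon_paired",
    "spearman_assoc",
    "association_grid",
    "build_ledger",
]


class AssociationError(ValueError):
    """Degenerate or mismatched association input."""


def clinical_change(clinical: pd.DataFrame) -> pd.DataFrame:
    """Per-participant change scores: delta = followup - baseline.

    Rows with a missing baseline or follow-up value are skipped (their
    count is reported via a warning); an empty table warns and returns an
    empty frame.
    """
    if len(clinical) == 0:
        warnings.warn("empty clinical table", stacklevel=2)
        return pd.DataFrame(columns=["participant_id", "score_name", "delta"])
    ok = clinical["baseline_value"].notna() & clinical["followup_value"].notna()
    if (~ok).any():
        warnings.warn(f"skipped {int((~ok).sum())} clinical record(s) with "
                      "missing values", stacklevel=2)
    sub = clinical[ok]
    return pd.DataFrame({
        "participant_id": sub["participant_id"],
        "score_name": sub["score_name"],
        "delta": sub["followup_value"] - sub["baseline_value"],
    }).reset_index(drop=True)


def _signed_rank_exact_sf(n: int) -> np.ndarray:
    """Null distribution of W+ (sum of positive ranks) for n untied pairs.

    Returns counts[w] = number of sign assignments with W+ == w, via the
    standard subset-sum recursion; 2^n total assignments.
    """
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1, dtype=float)
    counts[0] = 1.0
    for rank in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[rank:] = counts[:max_w + 1 - rank]
        counts = counts + shifted
    return counts


def wilcoxon_paired(deltas: Sequence[float]) -> tuple[float, float, str]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zeros are dropped first.  With n <= 15 non-zero untied differences the
    p-value is exact (full enumeration of the 2^n sign assignments via the
    rank-sum recursion); otherwise a normal approximation with tie and
    continuity corrections is used.  Returns ``(W+, p, method)``.
    """
    d = np.asarray(list(deltas), dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise AssociationError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    has_ties = len(np.unique(np.abs(d))) < n

    if n <= 15 and not has_ties:
        counts = _signed_rank_exact_sf(n)
        total = counts.sum()
        w = int(round(w_plus))
        p_low = counts[: w + 1].sum() / total
        p_high = counts[w:].sum() / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        return w_plus, float(p), "exact"

    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts ** 3 - tie_counts).sum() / 48.0
    if var <= 0:
        raise AssociationError("zero variance in signed ranks")
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return w_plus, min(p, 1.0), "normal_approx"


def _spearman_exact_p(x_ranks: np.ndarray, y_ranks: np.ndarray,
                      rho_obs: float) -> float:
    """Exact two-sided permutation p for Spearman rho (n <= 9).

    Enumerates all n! orderings of one rank vector and counts permutations
    with |rho| >= |rho_obs| (tie-aware: rho computed as the Pearson
    correlation of the average-rank vectors).
    """
    n = len(x_ranks)
    xc = x_ranks - x_ranks.mean()
    denom_x = float(xc @ xc)
    perms = np.array(list(permutations(y_ranks)))
    yc = perms - perms.mean(axis=1, keepdims=True)
    denom_y = (yc ** 2).sum(axis=1)
    rhos = (yc @ xc) / np.sqrt(denom_x * denom_y)
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman_assoc(slopes: Sequence[float], deltas: Sequence[float],
                   exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rank correlation between MRI slopes and clinical changes.

    Average ranks for ties; p-value from the t approximation, or from the
    exact permutation distribution for n <= ``exact_max_n``.
    """
    x = np.asarray(list(slopes), dtype=float)
    y = np.asarray(list(deltas), dtype=float)
    if x.size != y.size:
        raise AssociationError("paired vectors of different length")
    n = x.size
    if n < 5:
        raise AssociationError("need >= 5 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AssociationError("constant input vector: correlation undefined")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        return rho, _spearman_exact_p(rx, ry, rho)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    return rho, float(2.0 * stats.t.sf(abs(t), n - 2))


def association_grid(slope_entries: pd.DataFrame, deltas: pd.DataFrame,
                     alpha: float = 0.01) -> pd.DataFrame:
    """Spearman associations for every (bundle, measure, design, score) cell.

    ``slope_entries`` is a SlopeTable entries frame; ``deltas`` comes from
    :func:`clinical_change`.  Cells with a degenerate input are skipped with
    a warning.
    """
    rows = []
    scores = sorted(deltas["score_name"].unique())
    keys = ["bundle", "measure", "design_name"]
    for (bundle, measure, design), grp in slope_entries.groupby(keys):
        grp = grp.set_index("participant_id")["slope"]
        for score in scores:
            dsc = deltas[deltas["score_name"] == score].set_index(
                "participant_id")["delta"]
            common = grp.index.intersection(dsc.index)
            try:
                rho, p = spearman_assoc(grp.loc[common], dsc.loc[common])
            except AssociationError as exc:
                warnings.warn(
                    f"{bundle}/{measure}/{design}/{score}: {exc}", stacklevel=2)
                continue
            rows.append({"bundle": bundle, "measure": measure,
                         "design_name": design, "score": score,
                         "rho": rho, "p": p, "significant": p < alpha})
    return pd.DataFrame(rows)


@dataclass
class AssociationLedger:
    """Preserved/new/inverse/lost bookkeeping relative to the reference.

    ``records`` carries one row per (bundle, measure, design, score) with
    the association and its status; ``frequencies`` summarises per design
    as percentages of ``reference_total`` (the count of
    reference-significant cells).
    """

    records: pd.DataFrame
    frequencies: pd.DataFrame
    reference_total: int
    by_measure: pd.DataFrame = field(default=None)
    by_bundle: pd.DataFrame = field(default=None)


def build_ledger(associations: pd.DataFrame,
                 reference: str = "D_R",
                 require_sign_match: bool = True) -> AssociationLedger:
    """Audit each tested design's associations against the reference design.

    ``associations`` must hold the reference and all tested designs on the
    same (bundle, measure, score) grid.  With ``require_sign_match`` (the
    default) a preserved association must be significant in both designs
    *and* keep the reference sign; opposite-sign pairs are counted as
    inverse.  With the flag off, sign is ignored and the inverse category
    stays empty.
    """
    designs = sorted(associations["design_name"].unique())
    if reference not in designs:
        raise AssociationError(f"reference design {reference!r} missing")
    grid_cols = ["bundle", "measure", "score"]
    ref = associations[associations["design_name"] == reference]
    ref = ref.set_index(grid_cols)
    ref_grid = set(ref.index)

    out_rows = []
    freq_rows = []
    ref_total = int(ref["significant"].sum())

    for _, row in ref.reset_index().iterrows():
        out_rows.append({**row, "status":
                         "reference" if row["significant"] else "none"})

    for design in designs:
        if design == reference:
            continue
        tst = associations[associations["design_name"] == design]
        tst = tst.set_index(grid_cols)
        if set(tst.index) != ref_grid:
            raise AssociationError(
                f"design {design} computed on a different "
                "(bundle, measure, score) grid than the reference")
        counts = {"preserved": 0, "inverse": 0, "lost": 0, "new": 0}
        for key in sorted(ref_grid):
            r_sig = bool(ref.loc[key, "significant"])
            t_sig = bool(tst.loc[key, "significant"])
            same_sign = np.sign(ref.loc[key, "rho"]) == np.sign(tst.loc[key, "rho"])
            if r_sig and t_sig:
                if require_sign_match and not same_sign:
                    status = "inverse"
                else:
                    status = "preserved"
            elif r_sig:
                status = "lost"
            elif t_sig:
                status = "new"
            else:
                status = "none"
            if status in counts:
                counts[status] += 1
            out_rows.append({**tst.loc[key].to_dict(),
                             "bundle": key[0], "measure": key[1],
                             "score": key[2], "design_name": design,
                             "status": status})
        pct = (lambda c: 100.0 * c / ref_total if ref_total else 0.0)
        freq_rows.append({
            "design_name": design,
            "preserved": counts["preserved"], "inverse": counts["inverse"],
            "lost": counts["lost"], "new": counts["new"],
            "preserved_pct": pct(counts["preserved"]),
            "inverse_pct": pct(counts["inverse"]),
            "lost_pct": pct(counts["lost"]),
        })

    records = pd.DataFrame(out_rows)
    freqs = pd.DataFrame(freq_rows)

    def _breakdown(level: str) -> pd.DataFrame:
        sub = records[records["status"] == "preserved"]
        if sub.empty:
            return pd.DataFrame(columns=[level, "design_name", "preserved_pct"])
        g = sub.groupby([level, "design_name"]).size().rename("count").reset_index()
        ref_by = ref[ref["significant"]].reset_index().groupby(level).size()
        g["preserved_pct"] = [
            100.0 * c / ref_by.get(lv, np.nan)
            for lv, c in zip(g[level], g["count"])]
        return g

    return AssociationLedger(
        records=records,
        frequencies=freqs,
        reference_total=ref_total,
        by_measure=_breakdown("measure"),
        by_bundle=_breakdown("bundle"),
    )
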