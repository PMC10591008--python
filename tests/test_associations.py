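"""Clinical change, exact small-sample tests, and the association ledger."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from longidesign import (build_ledger, clinical_change, spearman_assoc,
                         wilcoxon_paired)
from longidesign.associations import AssociationError


class TestClinicalChange:
    def test_delta_is_followup_minus_baseline(self):
        clin = pd.DataFrame({
            "participant_id": ["P0", "P1"],
            "score_name": ["9HPT", "9HPT"],
            "baseline_value": [23.5, 20.0],
            "followup_value": [22.7, 20.0],
        })
        out = clinical_change(clin)
        assert out["delta"].tolist() == pytest.approx([-0.8, 0.0])

    def test_missing_values_skipped_with_warning(self):
        clin = pd.DataFrame({
            "participant_id": ["P0", "P1"],
            "score_name": ["SDMT", "SDMT"],
            "baseline_value": [50.0, np.nan],
            "followup_value": [55.0, 60.0],
        })
        with pytest.warns(UserWarning, match="skipped 1"):
            out = clinical_change(clin)
        assert len(out) == 1

    def test_empty_table_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            out = clinical_change(pd.DataFrame(
                columns=["participant_id", "score_name",
                         "baseline_value", "followup_value"]))
        assert len(out) == 0


def brute_force_wilcoxon_p(d):
    """Two-sided p by enumerating all 2^n sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mid = n * (n + 1) / 4.0
    count = 0
    for signs in product([0, 1], repeat=n):
        w = ranks[np.array(signs, bool)].sum()
        if abs(w - mid) >= abs(w_obs - mid) - 1e-12:
            count += 1
    return count / 2 ** n


class TestWilcoxon:
    def test_all_positive_n5_exact(self):
        w, p, method = wilcoxon_paired([0.3, 1.2, 0.7, 2.0, 0.5])
        assert method == "exact"
        assert w == 15.0
        assert p == pytest.approx(2 / 2 ** 5)

    def test_antisymmetric_statistic_at_midpoint(self):
        d = [1.0, -1.5, 1.5, -1.0, 2.0, -2.0]
        w, p, _ = wilcoxon_paired(d)
        # W+ at its null mean n(n+1)/4
        assert w == pytest.approx(6 * 7 / 4)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_matches_sign_enumeration_n8(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(0.3, 1.0, size=8)
        w, p, method = wilcoxon_paired(d)
        assert method == "exact"
        assert p == pytest.approx(brute_force_wilcoxon_p(d), abs=1e-12)

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(5)
        d = rng.normal(0.5, 1.0, size=12)
        _, p, _ = wilcoxon_paired(d)
        assert p == pytest.approx(stats.wilcoxon(d, method="exact").pvalue,
                                  abs=1e-12)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(6)
        d = rng.normal(0.2, 1.0, size=40)
        _, p, method = wilcoxon_paired(d)
        assert method == "normal_approx"
        ref = stats.wilcoxon(d, correction=True, method="approx").pvalue
        assert p == pytest.approx(ref, rel=1e-6)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(AssociationError):
            wilcoxon_paired([0.0, 0.0, 0.0])


def brute_force_spearman_p(x, y):
    """Two-sided p over the full n! permutation distribution (scipy rho)."""
    from itertools import permutations
    rho_obs = abs(stats.spearmanr(x, y).statistic)
    y = np.asarray(y)
    count = total = 0
    for perm in permutations(range(len(y))):
        rho = abs(stats.spearmanr(x, y[list(perm)]).statistic)
        count += rho >= rho_obs - 1e-12
        total += 1
    return count / total


class TestSpearman:
    def test_monotone_pair_is_one(self):
        rho, _ = spearman_assoc([1, 2, 3, 4, 5], [2, 4, 8, 16, 32])
        assert rho == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        rho, _ = spearman_assoc([1, 2, 3, 4, 5], [10, 8, 6, 4, 2])
        assert rho == pytest.approx(-1.0)

    def test_exact_p_matches_full_permutation_n7(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=7), rng.normal(size=7)
        rho, p = spearman_assoc(x, y)
        assert rho == pytest.approx(stats.spearmanr(x, y).statistic)
        assert p == pytest.approx(brute_force_spearman_p(x, y), abs=1e-12)

    def test_t_approximation_for_larger_n(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=30), rng.normal(size=30)
        rho, p = spearman_assoc(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(AssociationError):
            spearman_assoc([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])


def _grid(designs, rho_map, p_map):
    """Build an association frame on a 2-bundle x 2-measure x 1-score grid."""
    rows = []
    for d in designs:
        for b, m in product(["CC3", "CST"], ["MD", "FW"]):
            rho = rho_map(d, b, m)
            p = p_map(d, b, m)
            rows.append({"bundle": b, "measure": m, "design_name": d,
                         "score": "SDMT", "rho": rho, "p": p,
                         "significant": p < 0.01})
    return pd.DataFrame(rows)


class TestLedger:
    def test_self_comparison_preserves_everything(self):
        assoc = _grid(["D_R", "D_copy"], lambda d, b, m: 0.7,
                      lambda d, b, m: 0.001)
        ledger = build_ledger(assoc)
        row = ledger.frequencies.iloc[0]
        assert row["preserved"] == ledger.reference_total == 4
        assert row["preserved_pct"] == 100.0
        assert row["new"] == 0 and row["inverse"] == 0 and row["lost"] == 0

    def test_sign_flip_counts_as_inverse(self):
        assoc = _grid(["D_R", "D_flip"],
                      lambda d, b, m: 0.7 if d == "D_R" else -0.7,
                      lambda d, b, m: 0.001)
        ledger = build_ledger(assoc)
        row = ledger.frequencies.iloc[0]
        assert row["inverse"] == ledger.reference_total
        assert row["preserved"] == 0

    def test_sign_flip_preserved_in_lax_mode(self):
        assoc = _grid(["D_R", "D_flip"],
                      lambda d, b, m: 0.7 if d == "D_R" else -0.7,
                      lambda d, b, m: 0.001)
        ledger = build_ledger(assoc, require_sign_match=False)
        assert ledger.frequencies.iloc[0]["preserved"] == 4

    def test_partition_identity(self):
        rng = np.random.default_rng(10)
        assoc = _grid(["D_R", "D_012", "D_034"],
                      lambda d, b, m: rng.uniform(-1, 1),
                      lambda d, b, m: rng.uniform(0, 0.05))
        ledger = build_ledger(assoc)
        for _, row in ledger.frequencies.iterrows():
            assert (row["preserved"] + row["inverse"] + row["lost"]
                    == ledger.reference_total)

    def test_frequencies_invariant_to_grid_order(self):
        rng = np.random.default_rng(11)
        assoc = _grid(["D_R", "D_012"],
                      lambda d, b, m: rng.uniform(-1, 1),
                      lambda d, b, m: rng.uniform(0, 0.05))
        shuffled = assoc.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = build_ledger(assoc).frequencies
        b = build_ledger(shuffled).frequencies
        pd.testing.assert_frame_equal(a, b)

    def test_grid_mismatch_rejected(self):
        assoc = _grid(["D_R", "D_012"], lambda d, b, m: 0.5,
                      lambda d, b, m: 0.001)
        assoc = assoc.drop(assoc[(assoc["design_name"] == "D_012")
                                 & (assoc["bundle"] == "CST")].index[:1])
        with pytest.raises(AssociationError, match="grid"):
            build_ledger(assoc)

    def test_missing_reference_rejected(self):
        assoc = _grid(["D_012"], lambda d, b, m: 0.5, lambda d, b, m: 0.001)
        with pytest.raises(AssociationError, match="reference"):
            build_ledger(assoc)
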