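"""RM-ANOVA machinery against definitional brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from longidesign import (bh_fdr, design_similarity, gg_epsilon, mauchly_test,
                         rm_anova, similarity_to_reference, tukey_posthoc)
from longidesign.comparison import ComparisonError


def brute_force_rm_anova(x):
    """Definitional two-way decomposition with explicit loops."""
    n, m = x.shape
    grand = x.mean()
    ss_cond = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(m))
    ss_err = sum((x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
                 for i in range(n) for j in range(m))
    return (ss_cond / (m - 1)) / (ss_err / ((n - 1) * (m - 1)))


def random_contrast_covariance(x, rng):
    """Contrast-space covariance through a *different* orthonormal basis."""
    m = x.shape[1]
    raw = rng.normal(size=(m, m - 1))
    raw -= raw.mean(axis=0)  # orthogonal to the unit vector
    q, _ = np.linalg.qr(raw)
    return q.T @ np.cov(x, rowvar=False, ddof=1) @ q


@st.composite
def matrices(draw):
    n = draw(st.integers(min_value=5, max_value=8))
    m = draw(st.integers(min_value=3, max_value=5))
    seed = draw(st.integers(min_value=0, max_value=2 ** 31 - 1))
    return np.random.default_rng(seed).normal(size=(n, m))


class TestRmAnova:
    @given(matrices())
    @settings(deadline=None, max_examples=60)
    def test_f_matches_brute_force_decomposition(self, x):
        res = rm_anova(x, correction="never")
        assert res.F == pytest.approx(brute_force_rm_anova(x), abs=1e-10)

    def test_identical_columns_give_null_effect(self, rng):
        col = rng.normal(size=10)
        res = rm_anova(np.tile(col[:, None], (1, 4)))
        assert res.F == 0.0 and res.p == 1.0

    def test_two_designs_never_need_sphericity_correction(self, rng):
        res = rm_anova(rng.normal(size=(10, 2)))
        assert res.epsilon_gg == 1.0 and not res.epsilon_applied

    def test_correction_shrinks_dfs_when_applied(self, rng):
        x = rng.normal(size=(12, 4))
        x[:, 0] += 5 * rng.normal(size=12)  # break sphericity hard
        res = rm_anova(x, correction="always")
        assert res.epsilon_applied
        assert res.df1 == pytest.approx(3 * res.epsilon_gg)
        assert res.df2 == pytest.approx(33 * res.epsilon_gg)

    def test_matches_independent_implementation(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.normal(size=(12, 4))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 4),
            "cond": np.tile(np.arange(4), 12),
            "y": x.ravel()})
        table = pg.rm_anova(data=long, dv="y", within="cond",
                            subject="subject", correction=False)
        res = rm_anova(x, correction="never")
        assert res.F == pytest.approx(float(table["F"].iloc[0]), rel=1e-9)
        assert res.p == pytest.approx(float(table["p_unc"].iloc[0]), rel=1e-9)

    def test_missing_cells_rejected(self):
        x = np.ones((5, 3))
        x[0, 0] = np.nan
        with pytest.raises(ComparisonError):
            rm_anova(x)


class TestMauchly:
    @given(matrices())
    @settings(deadline=None, max_examples=40)
    def test_w_matches_determinant_trace_definition(self, x):
        rng = np.random.default_rng(0)
        W, _ = mauchly_test(x)
        A = random_contrast_covariance(x, rng)
        d = x.shape[1] - 1
        W_direct = np.linalg.det(A) / (np.trace(A) / d) ** d
        assert W == pytest.approx(W_direct, abs=1e-10)

    def test_spherical_contrast_covariance_gives_w_one(self, rng):
        # independent equal-variance columns are spherical in expectation;
        # construct exact sphericity by whitening the contrast space
        x = rng.normal(size=(30, 4))
        C = np.linalg.qr(np.array([[1, 1, 1], [-1, 1, 1], [0, -2, 1],
                                   [0, 0, -3.0]]))[0]
        y = x - x.mean(axis=0)
        proj = y @ C
        cov = np.cov(proj, rowvar=False, ddof=1)
        L = np.linalg.cholesky(cov)
        y = proj @ np.linalg.inv(L).T @ C.T
        W, p = mauchly_test(y)
        assert W == pytest.approx(1.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_location_invariance(self, rng):
        x = rng.normal(size=(10, 3))
        assert mauchly_test(x)[0] == pytest.approx(
            mauchly_test(x + 7.5)[0], abs=1e-12)

    def test_matches_independent_implementation(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.normal(size=(10, 3))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(10), 3),
            "cond": np.tile(np.arange(3), 10),
            "y": x.ravel()})
        spher = pg.sphericity(long, dv="y", within="cond", subject="subject")
        W, p = mauchly_test(x)
        assert W == pytest.approx(spher.W, rel=1e-9)
        assert p == pytest.approx(spher.pval, rel=1e-6)

    def test_undefined_for_too_few_subjects(self, rng):
        with pytest.raises(ComparisonError, match="epsilon"):
            mauchly_test(rng.normal(size=(3, 4)))


class TestGgEpsilon:
    @given(matrices())
    @settings(deadline=None, max_examples=40)
    def test_matches_spectral_brute_force(self, x):
        rng = np.random.default_rng(1)
        A = random_contrast_covariance(x, rng)
        lam = np.linalg.eigvalsh(A)
        m = x.shape[1]
        eps_direct = lam.sum() ** 2 / ((m - 1) * (lam ** 2).sum())
        assert gg_epsilon(x) == pytest.approx(
            np.clip(eps_direct, 1 / (m - 1), 1), abs=1e-10)

    def test_exact_sphericity_gives_one(self, rng):
        # i.i.d. columns with huge n: epsilon -> 1; exact construction below
        x = rng.normal(size=(6, 3))
        C = np.array([[1, 1], [-1, 1], [0, -2.0]])
        C /= np.linalg.norm(C, axis=0)
        proj = (x - x.mean(0)) @ C
        cov = np.cov(proj, rowvar=False, ddof=1)
        L = np.linalg.cholesky(cov)
        y = proj @ np.linalg.inv(L).T @ C.T
        assert gg_epsilon(y) == pytest.approx(1.0, abs=1e-10)

    def test_rank_one_covariance_hits_lower_bound(self, rng):
        subj = rng.normal(size=10)
        dominant = np.outer(rng.normal(size=10), [1.0, -1.0, 0.5, 2.0])
        x = subj[:, None] + dominant
        assert gg_epsilon(x) == pytest.approx(1.0 / 3.0, abs=1e-9)


class TestTukey:
    def test_identical_columns_pair_has_p_one(self, rng):
        x = rng.normal(size=(8, 3))
        x[:, 1] = x[:, 0]
        table = tukey_posthoc(x)
        row = table[(table["design_A"] == "c0") & (table["design_B"] == "c1")]
        assert row["q"].iloc[0] == 0.0 and row["p"].iloc[0] == 1.0

    def test_p_monotone_in_mean_difference(self, rng):
        x = rng.normal(size=(10, 4))
        table = tukey_posthoc(x).sort_values("mean_diff", key=np.abs)
        assert (np.diff(table["p"]) <= 1e-12).all()

    def test_matches_direct_studentized_range(self, rng):
        x = rng.normal(size=(9, 3))
        res = rm_anova(x, correction="never")
        table = tukey_posthoc(x, res)
        for _, row in table.iterrows():
            q = abs(row["mean_diff"]) / np.sqrt(res.ms_error / 9)
            p = stats.studentized_range.sf(q, 3, res.df_error)
            assert row["p"] == pytest.approx(p, abs=1e-6)


class TestBhFdr:
    def test_hand_enumerated_step_up(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_ties_all_equal(self):
        assert np.allclose(bh_fdr([0.03] * 5), 0.03)

    def test_adjusted_at_least_raw_and_order_preserving(self, rng):
        p = rng.uniform(size=20)
        adj = bh_fdr(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1).all()
        # monotone: a smaller raw p never gets a larger adjusted p
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ComparisonError):
            bh_fdr([0.5, 1.2])


class TestSimilarity:
    def test_self_correlation_unit_diagonal(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        sim = design_similarity(df)
        assert np.allclose(np.diag(sim), 1.0)
        assert np.allclose(sim, sim.T)

    def test_sign_flip_gives_minus_one(self, rng):
        x = rng.normal(size=10)
        df = pd.DataFrame({"a": x, "b": -x})
        assert design_similarity(df).loc["a", "b"] == pytest.approx(-1.0)

    def test_zero_variance_column_reported_missing(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=8), "b": np.ones(8)})
        with pytest.warns(UserWarning, match="zero-variance"):
            sim = design_similarity(df)
        assert np.isnan(sim.loc["a", "b"])
        assert sim.loc["b", "b"] == 1.0

    def test_reference_column_extraction(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 3)),
                          columns=["D_R", "D_012", "D_034"])
        col = similarity_to_reference(design_similarity(df))
        assert list(col.index) == ["D_012", "D_034"]
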