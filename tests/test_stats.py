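from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from panelflow.qc import FeatureTable
from panelflow.stats import (
    benjamini_hochberg,
    boxcox_transform,
    compare_groups,
    dagostino_pearson,
    fold_change,
    mann_whitney_u,
    spearman_matrix,
    student_t,
)


def mw_exact_p_bruteforce(x, y):
    """Independent oracle: exact two-sided Mann–Whitney p by enumerating
    all C(n+m, n) assignments of the pooled (tie-free) values."""
    pooled = np.concatenate([x, y])
    n = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj) + 0.5 * sum(
        1 for xi in x for yj in y if xi == yj
    )
    mu = n * len(y) / 2
    count = total = 0
    for idx in combinations(range(len(pooled)), n):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        u = sum(1 for xi in xs for yj in ys if xi > yj)
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


def bh_reject_bruteforce(p, alpha):
    """Independent oracle: BH rejection set by its direct definition,
    max{i: p_(i) <= i*alpha/m}."""
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p)
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * alpha / m:
            k = i
    rejected = np.zeros(m, bool)
    rejected[order[:k]] = True
    return rejected


class TestMannWhitney:
    def test_disjoint_small_groups_exact_p(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)
        assert p == pytest.approx(mw_exact_p_bruteforce([1, 2, 3], [4, 5, 6]))

    def test_identical_groups_p_one(self):
        x = [1.5, 2.5, 3.5, 4.5]
        _, p = mann_whitney_u(x, x)
        assert p == pytest.approx(1.0, abs=0.01)

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_branch_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(0, 1, 5), rng.normal(0.8, 1, 6)
        _, p = mann_whitney_u(x, y)
        assert p == pytest.approx(mw_exact_p_bruteforce(x, y), abs=1e-10)

    @pytest.mark.parametrize("seed", range(25))
    def test_exact_and_asymptotic_agree_for_moderate_n(self, seed):
        # at n=m=15 the tie/continuity-corrected normal approximation sits
        # within 0.01 of the exact null distribution
        rng = np.random.default_rng(seed)
        x, y = rng.normal(0, 1, 15), rng.normal(0.5, 1, 15)
        exact = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        approx = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert approx == pytest.approx(exact, abs=0.01)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([np.nan], [1.0, 2.0])


class TestBenjaminiHochberg:
    def test_hand_stepped_example(self):
        # 0.01*4/1, 0.02*4/2, 0.03*4/3, 0.04*4/4 then monotone → all 0.04
        rejected, adj = benjamini_hochberg([0.01, 0.02, 0.03, 0.04], alpha=0.05)
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])
        assert rejected.all()

    def test_single_p_identity(self):
        _, adj = benjamini_hochberg([0.2])
        assert adj[0] == pytest.approx(0.2)

    @pytest.mark.parametrize("seed", range(50))
    def test_rejection_set_matches_definition(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(2, 40))
        rejected, _ = benjamini_hochberg(p, alpha=0.05)
        np.testing.assert_array_equal(rejected, bh_reject_bruteforce(p, 0.05))

    def test_adjusted_monotone_in_rank(self):
        rng = np.random.default_rng(7)
        p = rng.random(30)
        _, adj = benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])


class TestFoldChange:
    def test_ratio_of_means(self):
        assert fold_change([2, 4], [1, 2]) == pytest.approx(2.0)
        assert fold_change([1], [2]) == pytest.approx(0.5)
        assert fold_change([3, 3], [3, 3]) == pytest.approx(1.0)

    def test_zero_control_mean_is_nan(self):
        assert np.isnan(fold_change([1.0], [0.0]))


class TestCompareGroups:
    def _table(self, seed=0, shift=1.0):
        rng = np.random.default_rng(seed)
        hc = rng.lognormal(0, 0.3, (20, 3))
        pd_ = rng.lognormal(0, 0.3, (30, 3))
        pd_[:, 0] *= np.exp(shift)  # protein A up in PD
        values = pd.DataFrame(
            np.vstack([hc, pd_]), columns=["A", "B", "C"],
            index=[f"S{i}" for i in range(50)],
        )
        meta = pd.DataFrame({"group": ["HC"] * 20 + ["PD"] * 30}, index=values.index)
        return FeatureTable(values, meta)

    def test_shifted_protein_detected_with_direction(self):
        df = compare_groups(self._table(), "PD", "HC")
        row = df.set_index("protein_id").loc["A"]
        assert row["significant"]
        assert row["fold_change"] > 1
        assert row["direction"] == "up_in_affected"

    def test_direction_sign_consistency(self):
        df = compare_groups(self._table(seed=3), "PD", "HC")
        for _, r in df.iterrows():
            assert (r["fold_change"] >= 1) == (r["direction"] == "up_in_affected")
            # signed log10 p carries the fold-change sign
            if r["fold_change"] != 1:
                assert np.sign(r["signed_log10_p"]) == np.sign(np.log2(r["fold_change"]))

    def test_adjusted_at_least_raw(self):
        df = compare_groups(self._table(seed=5, shift=0.2), "PD", "HC")
        assert (df["p_adjusted"] >= df["p_value"] - 1e-12).all()


class TestSpearman:
    def _table(self, values, clinical):
        meta = pd.DataFrame({"score": clinical}, index=values.index)
        return FeatureTable(values, meta)

    def test_perfect_anticorrelation(self):
        vals = pd.DataFrame({"P1": [1.0, 2.0, 3.0]}, index=list("abc"))
        df = spearman_matrix(self._table(vals, [3, 2, 1]), ["score"])
        assert df.iloc[0]["rho"] == pytest.approx(-1.0)

    def test_monotone_rank_invariance(self):
        vals = pd.DataFrame({"P1": [1.0, 2.0, 3.0]}, index=list("abc"))
        df = spearman_matrix(self._table(vals, [1, 4, 9]), ["score"])
        assert df.iloc[0]["rho"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pearson_on_ranks(self, seed):
        rng = np.random.default_rng(seed)
        n = 25
        x, y = np.exp(rng.normal(0, 1, n)), rng.normal(0, 1, n)
        vals = pd.DataFrame({"P1": x}, index=[f"s{i}" for i in range(n)])
        df = spearman_matrix(self._table(vals, y), ["score"])
        oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert df.iloc[0]["rho"] == pytest.approx(oracle, abs=1e-12)

    def test_too_few_pairs_missing(self):
        vals = pd.DataFrame({"P1": [1.0, 2.0, np.nan]}, index=list("abc"))
        df = spearman_matrix(self._table(vals, [1, 2, 3]), ["score"])
        assert np.isnan(df.iloc[0]["rho"])

    def test_variablewise_bh_families(self):
        rng = np.random.default_rng(11)
        n = 30
        vals = pd.DataFrame(
            rng.normal(0, 1, (n, 4)), columns=list("ABCD"),
            index=[f"s{i}" for i in range(n)],
        )
        meta = pd.DataFrame(
            {"u": rng.normal(0, 1, n), "v": vals["A"] + rng.normal(0, 0.1, n)},
            index=vals.index,
        )
        df = spearman_matrix(FeatureTable(vals.abs(), meta), ["u", "v"])
        # adjustment within each variable family of 4 proteins
        for var in ("u", "v"):
            fam = df[df["variable"] == var]
            _, adj = benjamini_hochberg(fam["p_value"].to_numpy())
            np.testing.assert_allclose(fam["p_adjusted"].to_numpy(), adj)


class TestNormalityAndTransforms:
    def test_null_calibration(self):
        rng = np.random.default_rng(0)
        rejections = 0
        n_runs = 200
        for _ in range(n_runs):
            _, p = dagostino_pearson(rng.normal(0, 1, 500))
            rejections += p < 0.05
        assert 0.02 <= rejections / n_runs <= 0.09

    def test_lognormal_strongly_rejected(self):
        rng = np.random.default_rng(1)
        _, p = dagostino_pearson(rng.lognormal(0, 1, 500))
        assert p < 1e-3

    def test_small_n_refused(self):
        with pytest.raises(ValueError, match="20"):
            dagostino_pearson(np.arange(10))

    def test_boxcox_lambda_one_is_shift(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        out, lam = boxcox_transform(x, lmbda=1.0)
        np.testing.assert_allclose(out, x - 1)

    def test_boxcox_finds_log_for_lognormal(self):
        rng = np.random.default_rng(2)
        _, lam = boxcox_transform(rng.lognormal(0, 1, 500))
        assert -0.2 <= lam <= 0.2

    def test_boxcox_near_identity_for_normal(self):
        rng = np.random.default_rng(3)
        x = rng.normal(20, 1, 500)  # positive, already normal
        _, lam = boxcox_transform(x)
        assert abs(lam - 1) < 2.0  # profile likelihood is flat in location-scale

    def test_boxcox_rejects_nonpositive(self):
        with pytest.raises(ValueError, match="positive"):
            boxcox_transform([1.0, 0.0, 2.0])


class TestStudentT:
    def test_identical_groups(self):
        t, p = student_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_degenerate_zero_variance(self):
        t, p = student_t([0.0, 0.0], [1.0, 1.0])
        assert p < 1e-6

    def test_matches_hand_formula(self):
        x = np.array([4.2, 5.1, 3.9, 4.8, 5.0])
        y = np.array([3.1, 3.8, 2.9, 3.5, 3.3])
        nx, ny = len(x), len(y)
        sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
        t_hand = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
        p_hand = 2 * sps.t.sf(abs(t_hand), nx + ny - 2)
        t, p = student_t(x, y)
        assert t == pytest.approx(t_hand, abs=1e-9)
        assert p == pytest.approx(p_hand, abs=1e-9)
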