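"""Mann–Whitney U, Bonferroni thresholds, chi-squared and group comparison."""

import numpy as np
import pandas as pd
import pytest

from cypstab.group_stats import (
    GENOMIC_FAMILY,
    bonferroni_threshold,
    chi_squared,
    compare_groups,
    mann_whitney_u,
)


def exact_u_distribution(n_x: int, n_y: int) -> list:
    """Counts of rank-subsets per U value for tie-free samples (independent
    enumeration oracle): sweep ranks smallest to largest, assigning each to
    x or y; an x assignment wins one pair against every y already seen."""
    max_u = n_x * n_y
    n = n_x + n_y
    # dp[j][u] = ways to assign the first t ranks with j in x and U = u
    dp = [[0] * (max_u + 1) for _ in range(n_x + 1)]
    dp[0][0] = 1
    for t in range(n):
        new = [[0] * (max_u + 1) for _ in range(n_x + 1)]
        for j in range(min(t, n_x) + 1):
            y_seen = t - j
            row = dp[j]
            for u in range(max_u + 1):
                ways = row[u]
                if not ways:
                    continue
                if j < n_x:  # assign this rank to x
                    new[j + 1][u + y_seen] += ways
                if y_seen < n_y:  # assign to y
                    new[j][u] += ways
        dp = new
    return dp[n_x]


def exact_two_sided_p(x, y) -> float:
    """Enumeration oracle: two-sided p from the exact U distribution."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n_x, n_y = len(x), len(y)
    ranks = pd.Series(np.concatenate([x, y])).rank().to_numpy()
    u1 = ranks[:n_x].sum() - n_x * (n_x + 1) / 2
    dist = exact_u_distribution(n_x, n_y)
    total = sum(dist)
    u1 = int(round(u1))
    lower = sum(dist[: u1 + 1])
    upper = sum(dist[u1:])
    return float(min(1.0, 2 * min(lower, upper) / total))


class TestMannWhitney:
    def test_complete_separation_small_sample(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20 rank assignments as extreme

    def test_identical_samples(self):
        u, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_constant_sample_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            _, p = mann_whitney_u([2, 2], [2, 2, 2])
        assert p == 1.0

    def test_exact_matches_enumeration_oracle(self, rng):
        """Exact p agrees with the independent DP enumeration for a sweep of
        tie-free sample sizes with n_x * n_y <= 400."""
        for n_x, n_y in [(1, 5), (2, 9), (3, 3), (4, 25), (5, 5), (7, 8),
                         (10, 10), (12, 20), (20, 20)]:
            vals = rng.permutation(np.arange(n_x + n_y, dtype=float))
            x, y = vals[:n_x], vals[n_x:]
            _, p = mann_whitney_u(x, y)
            assert p == pytest.approx(exact_two_sided_p(x, y), abs=1e-12)

    def test_normal_approximation_vs_permutation_oracle(self, rng):
        """n=30/30 Gaussian data: the approximation is within 0.005 of a
        10^5-permutation estimate of the two-sided p."""
        n = 30
        x = rng.normal(0.0, 1.0, n)
        y = rng.normal(0.5, 1.0, n)
        combined = np.concatenate([x, y])
        ranks = pd.Series(combined).rank().to_numpy()
        observed = abs(ranks[:n].sum() - n * (2 * n + 1) / 2)
        n_perm = 100_000
        perm_ranks = np.array(
            [ranks[rng.permutation(2 * n)][:n].sum() for _ in range(n_perm)]
        )
        p_perm = np.mean(np.abs(perm_ranks - n * (2 * n + 1) / 2) >= observed - 1e-9)
        _, p_asym = mann_whitney_u(x, y)
        assert p_asym == pytest.approx(p_perm, abs=0.005)

    def test_exact_close_to_approximation(self, rng):
        """For tie-free samples of 10+ per group the asymptotic p stays
        within 0.01 of the exact value (below ~10 per group the normal
        approximation is outside its domain and deviates further)."""
        from scipy import stats

        for n_x, n_y in [(10, 10), (12, 15), (14, 20), (20, 20)]:
            vals = rng.normal(size=n_x + n_y)
            x, y = vals[:n_x], vals[n_x:]
            _, p_exact = mann_whitney_u(x, y)
            p_asym = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic"
            ).pvalue
            assert abs(p_exact - p_asym) < 0.01


class TestBonferroni:
    @pytest.mark.parametrize(
        "m,expected", [(6, 0.0083), (13, 0.0038), (20, 0.0025), (1, 0.05)]
    )
    def test_printed_thresholds(self, m, expected):
        assert bonferroni_threshold(0.05, m) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 4)


class TestChiSquared:
    def test_homogeneous_table(self):
        chi2, p, df = chi_squared([[10, 10], [10, 10]])
        assert chi2 == 0.0
        assert p == pytest.approx(1.0)
        assert df == 1

    def test_perfect_association_hand_computed(self):
        # expected all 10: chi2 = 4 * (10-0)^2/10 ... = 40 by Pearson's formula
        chi2, p, df = chi_squared([[20, 0], [0, 20]])
        assert chi2 == pytest.approx(40.0)
        assert df == 1

    def test_row_swap_invariance(self):
        table = [[12, 5, 9], [3, 14, 7]]
        assert chi_squared(table)[0] == pytest.approx(
            chi_squared(table[::-1])[0]
        )

    def test_low_expected_warns_and_zero_marginal_rejected(self):
        with pytest.warns(UserWarning, match="expected"):
            chi_squared([[1, 2], [2, 1]])
        with pytest.raises(ValueError, match="marginal"):
            chi_squared([[0, 5], [0, 7]])


class TestCompareGroups:
    @staticmethod
    def _frame(rng, shift=0.0):
        n = 30
        ids = [f"g{i}" for i in range(2 * n)]
        labels = pd.DataFrame(
            {"label": ["stable"] * n + ["labile"] * n}, index=ids
        )
        feats = pd.DataFrame(
            {
                "gene_length": np.concatenate(
                    [rng.normal(2100 + shift, 200, n), rng.normal(1800, 200, n)]
                ),
                "n_exons": np.concatenate(
                    [rng.integers(3, 6, n), rng.integers(2, 5, n)]
                ).astype(float),
                "exon_length": rng.normal(1500, 150, 2 * n),
                "intron_length": np.concatenate(
                    [rng.normal(600, 100, n), rng.normal(310, 80, n)]
                ),
                "n_transcripts": np.ones(2 * n),
                "gc_percent": rng.normal(46, 2, 2 * n),
            },
            index=ids,
        )
        return feats, labels

    def test_identical_groups_all_null(self, rng):
        feats, labels = self._frame(rng)
        feats = pd.concat([feats.iloc[:30]] * 2).set_axis(feats.index)
        with pytest.warns(UserWarning):
            results = compare_groups(feats, labels, GENOMIC_FAMILY)
        # same values in both groups: nothing can be significant
        assert not results["significant"].any()

    def test_family_of_six_reports_printed_threshold(self, rng):
        feats, labels = self._frame(rng)
        with pytest.warns(UserWarning):  # constant n_transcripts
            results = compare_groups(feats, labels, GENOMIC_FAMILY)
        assert (results["alpha_corr"] == 0.0083).all()
        assert results.set_index("feature").loc["gene_length", "significant"]

    def test_label_swap_symmetry(self, rng):
        feats, labels = self._frame(rng)
        swapped = labels.replace({"stable": "labile", "labile": "stable"})
        with pytest.warns(UserWarning):
            fwd = compare_groups(feats, labels, ["gene_length", "n_transcripts"])
        with pytest.warns(UserWarning):
            rev = compare_groups(feats, swapped, ["gene_length", "n_transcripts"])
        fwd = fwd.set_index("feature")
        rev = rev.set_index("feature")
        assert fwd.loc["gene_length", "p"] == pytest.approx(
            rev.loc["gene_length", "p"]
        )
        assert fwd.loc["gene_length", "median_stable"] == pytest.approx(
            rev.loc["gene_length", "median_labile"]
        )

    def test_missing_values_dropped_per_feature(self, rng):
        feats, labels = self._frame(rng)
        feats.loc[feats.index[:5], "gc_percent"] = np.nan
        results = compare_groups(feats, labels, ["gc_percent"]).set_index("feature")
        assert results.loc["gc_percent", "n_stable"] == 25
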