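"""Statistics layer: CGI means, rank tests, Bonferroni, Welch, ddCt."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from methassay.methstats import (
    MethylationMatrix,
    bonferroni,
    cgi_mean_per_sample,
    mann_whitney_u,
    relative_expression,
    significance_stars,
    stage_summary,
    welch_t_one_tailed,
)

from .oracles import exact_mwu_two_sided, welch_by_hand


def toy_matrix(values, island_flags=None):
    beta = pd.DataFrame(values)
    beta.index = [f"s{i}" for i in range(len(beta))]
    beta.columns = [f"p{i}" for i in range(beta.shape[1])]
    flags = island_flags if island_flags is not None else [True] * beta.shape[1]
    return MethylationMatrix(
        beta=beta,
        groups=pd.Series("g", index=beta.index),
        island_probes=pd.Series(flags, index=beta.columns),
    )


class TestCgiMean:
    def test_constant_matrix(self):
        m = toy_matrix(np.full((4, 5), 0.5))
        assert (cgi_mean_per_sample(m) == 0.5).all()

    def test_single_probe_island(self):
        vals = np.array([[0.1, 0.9], [0.4, 0.8]])
        m = toy_matrix(vals, island_flags=[True, False])
        assert list(cgi_mean_per_sample(m)) == [0.1, 0.4]

    def test_matches_arithmetic_oracle_with_missing(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(size=(6, 4))
        vals[0, 1] = np.nan
        m = toy_matrix(vals)
        got = cgi_mean_per_sample(m)
        for i in range(6):
            row = [v for v in vals[i] if not np.isnan(v)]
            assert got.iloc[i] == pytest.approx(sum(row) / len(row))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(size=(5, 6))
        m = toy_matrix(vals)
        base = cgi_mean_per_sample(m)
        perm = list(np.random.default_rng(3).permutation(m.beta.columns))
        m2 = MethylationMatrix(
            beta=m.beta[perm],
            groups=m.groups,
            island_probes=m.island_probes[perm],
        )
        got = cgi_mean_per_sample(m2).sort_index()
        assert got.to_numpy() == pytest.approx(base.sort_index().to_numpy())

    def test_empty_probe_set_is_error(self):
        m = toy_matrix(np.full((2, 2), 0.5))
        with pytest.raises(ValueError):
            cgi_mean_per_sample(m, island_probes=[])

    def test_beta_range_validated(self):
        with pytest.raises(ValueError):
            toy_matrix(np.array([[1.2]]))


class TestMannWhitney:
    def test_exact_small_example(self):
        _, p = mann_whitney_u([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_exact_interleaved_example(self):
        _, p = mann_whitney_u([1, 4], [2, 3])
        assert p == pytest.approx(1.0)

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [])

    def test_exact_matches_enumeration_for_small_samples(self):
        """Every tie-free case with n1 + n2 <= 10 agrees with brute-force
        enumeration over rank assignments."""
        rng = np.random.default_rng(4)
        for n1, n2 in [(1, 3), (2, 2), (2, 5), (3, 3), (3, 7), (4, 4), (5, 5)]:
            vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            a, b = vals[:n1], vals[n1:]
            _, p = mann_whitney_u(a, b)
            assert p == pytest.approx(exact_mwu_two_sided(a, b))

    def test_normal_approximation_close_to_exact_at_n8(self):
        """With n1 = n2 = 8 and no ties, the continuity-corrected normal
        approximation tracks the exact enumeration to about 0.01 on average."""
        rng = np.random.default_rng(6)
        diffs = []
        for _ in range(25):
            vals = rng.permutation(np.arange(1.0, 17))
            a, b = vals[:8], vals[8:]
            approx = st.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic"
            ).pvalue
            diffs.append(abs(approx - exact_mwu_two_sided(a, b)))
        assert np.mean(diffs) < 0.01


class TestBonferroni:
    def test_known_values(self):
        assert bonferroni([0.01], 3) == [pytest.approx(0.03)]
        assert bonferroni([0.5], 3) == [1.0]
        assert bonferroni([]) == []

    def test_never_decreases_and_caps_at_one(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=20)
        adj = bonferroni(p, 25)
        assert all(x >= y for x, y in zip(adj, p))
        assert all(x <= 1.0 for x in adj)

    def test_errors(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], 1)
        with pytest.raises(ValueError):
            bonferroni([1.5], 2)


class TestWelch:
    def test_fixed_triple_example(self):
        t, df, p = welch_t_one_tailed([1, 2, 3], [2, 3, 4], direction="a<b")
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert df == pytest.approx(4.0)
        t_o, df_o = welch_by_hand([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(t_o)
        assert p == pytest.approx(st.t.cdf(t_o, df_o))

    def test_identical_groups(self):
        t, _, p = welch_t_one_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "a<b")
        assert t == 0.0 and p == pytest.approx(0.5)

    def test_direction_flips_tail(self):
        _, _, p_less = welch_t_one_tailed([1, 2, 3], [2, 3, 4], "a<b")
        _, _, p_greater = welch_t_one_tailed([1, 2, 3], [2, 3, 4], "a>b")
        assert p_less + p_greater == pytest.approx(1.0)

    def test_too_small_group_is_error(self):
        with pytest.raises(ValueError):
            welch_t_one_tailed([1], [1, 2])


class TestRelativeExpression:
    def test_calibrator_equality_gives_unity(self):
        assert relative_expression([20.0], [15.0], 5.0) == pytest.approx(1.0)

    def test_ddct_of_two_gives_quarter(self):
        assert relative_expression([22.0], [15.0], 5.0) == pytest.approx(0.25)

    def test_quadruplicate_matches_hand_arithmetic(self):
        target = [24.1, 24.3, 23.9, 24.2]
        ref = [18.0, 18.2, 17.9, 18.1]
        delta = sum(target) / 4 - sum(ref) / 4
        assert relative_expression(target, ref, 4.0) == pytest.approx(
            2.0 ** -(delta - 4.0)
        )

    def test_empty_replicates_error(self):
        with pytest.raises(ValueError):
            relative_expression([], [20.0], 0.0)


class TestStageSummary:
    def test_identical_groups_not_significant(self):
        vals = list(np.linspace(0.1, 0.9, 12))
        summary, comps = stage_summary({"a": vals, "b": vals})
        assert summary.loc["a", "mean"] == summary.loc["b", "mean"]
        assert comps[0].p_adjusted == pytest.approx(1.0)
        assert comps[0].stars == "ns"

    def test_five_groups_give_ten_adjusted_comparisons(self):
        rng = np.random.default_rng(12)
        groups = {f"g{i}": rng.uniform(size=6) for i in range(5)}
        _, comps = stage_summary(groups)
        assert len(comps) == 10
        for c in comps:
            assert c.p_adjusted == pytest.approx(min(1.0, c.p_raw * 10))

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            stage_summary({"a": [1.0], "b": []})

    def test_stars_rendering(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(0.0004) == "***"
        assert significance_stars(0.2) == "ns"
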