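"""Ensemble statistics: Mann-Whitney, star mapping, group summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

import fcslab as f


def exact_two_sided_p(a, b):
    """Brute-force two-sided Mann-Whitney p by enumerating all labelings.

    Uses the symmetry of the null U distribution: p = fraction of labelings
    whose U deviates from n_a n_b / 2 at least as much as the observed one.
    """
    a, b = list(a), list(b)
    pooled = a + b
    n_a = len(a)
    m = n_a * (len(pooled) - n_a)

    def u_stat(group_a, group_b):
        return sum((x > y) + 0.5 * (x == y)
                   for x in group_a for y in group_b)

    u_obs = u_stat(a, b)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(ga, gb)
        total += 1
        if abs(u - m / 2) >= abs(u_obs - m / 2) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_disjoint_triplets_exact_p(self):
        res = f.mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.U == 0
        assert res.p == pytest.approx(0.1, abs=1e-12)
        assert res.stars == "NS"

    @pytest.mark.parametrize("a,b", [
        ([1.2, 3.4, 2.2, 5.0], [2.8, 4.1, 6.3, 7.7]),
        ([10.0, 11.0, 12.0, 13.0, 14.0], [11.5, 12.5, 13.5]),
        ([0.1, 0.2, 0.3], [0.15, 0.25, 0.35, 0.45]),
    ])
    def test_exact_p_matches_enumeration_oracle(self, a, b):
        res = f.mann_whitney(a, b)
        assert res.p == pytest.approx(exact_two_sided_p(a, b), abs=1e-9)

    def test_identical_groups(self):
        res = f.mann_whitney([2.0] * 5, [2.0] * 5)
        assert res.p == 1.0 and res.stars == "NS"

    def test_tied_groups_use_corrected_approximation(self):
        res = f.mann_whitney([1, 2, 2, 3, 4], [2, 2, 3, 3, 5])
        assert 0.0 < res.p <= 1.0

    def test_groups_too_small(self):
        with pytest.raises(ValueError):
            f.mann_whitney([1, 2], [3, 4, 5])

    def test_exact_and_asymptotic_agree_at_moderate_n(self):
        rng = np.random.default_rng(3)
        a = rng.lognormal(2.8, 0.3, 15)
        b = rng.lognormal(2.6, 0.3, 15)
        from scipy import stats
        p_exact = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="exact").pvalue
        p_asym = stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic").pvalue
        assert p_asym == pytest.approx(p_exact, rel=0.10)
        # package picks the exact branch here
        assert f.mann_whitney(a, b).p == pytest.approx(p_exact, abs=1e-12)

    def test_type_i_error_control(self):
        rng = np.random.default_rng(12)
        hits = 0
        reps = 200
        for _ in range(reps):
            a = f.sample_cell_values(17.3, 6.1, 20, rng)
            b = f.sample_cell_values(17.3, 6.1, 20, rng)
            if f.mann_whitney(a, b).p < 0.05:
                hits += 1
        rate = hits / reps
        assert 0.05 - 3 * np.sqrt(0.05 * 0.95 / reps) <= rate \
            <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)


class TestStars:
    @pytest.mark.parametrize("p,expected", [
        (0.0009, "***"), (0.001, "**"), (0.0099, "**"), (0.01, "*"),
        (0.049, "*"), (0.05, "NS"), (0.5, "NS"), (1.0, "NS"),
    ])
    def test_boundaries(self, p, expected):
        assert f.stars_for_p(p) == expected

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            f.stars_for_p(1.5)


def measurement(cond, channel, D, c, cell):
    return f.CellMeasurement(cell_id=f"{cond}_{cell}", compartment="cytosol",
                             condition=cond, channel=channel, D=D, c=c)


class TestSummarize:
    def test_single_value_group(self):
        rows = [measurement("x", "G", 10.0, 30.0, 0)]
        out = f.summarize(rows, min_n=1)
        assert len(out) == 1
        assert out.loc[0, "median_D"] == 10.0
        assert out.loc[0, "mad_D"] == 0.0

    def test_median_robust_to_outlier(self):
        rows = [measurement("x", "G", d, 1.0, i)
                for i, d in enumerate([1, 2, 3, 4, 100])]
        out = f.summarize(rows)
        assert out.loc[0, "median_D"] == 3.0
        assert bool(out.loc[0, "small_group"])

    def test_groups_split_by_keys(self):
        rows = [measurement("x", ch, 10.0, 30.0, i)
                for ch in "GR" for i in range(3)]
        rows += [measurement("y", "G", 20.0, 40.0, i) for i in range(3)]
        out = f.summarize(rows)
        assert len(out) == 3
        assert set(out["condition"]) == {"x", "y"}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            f.summarize([])


class TestCompareGroups:
    def test_pairwise_rows_and_stars(self):
        rng = np.random.default_rng(5)
        rows = [measurement("ctrl", "G", d, 30.0, i)
                for i, d in enumerate(f.sample_cell_values(17.3, 2.0, 20, rng))]
        rows += [measurement("drug", "G", d, 30.0, i)
                 for i, d in enumerate(f.sample_cell_values(8.0, 1.0, 20, rng))]
        out = f.compare_groups(rows, value="D")
        assert len(out) == 1
        assert out.loc[0, "stars"] == "***"
        assert {"group_a", "group_b", "U", "p"} <= set(out.columns)

    def test_undersized_groups_skipped_with_warning(self):
        rows = [measurement("a", "G", 1.0, 1.0, i) for i in range(2)]
        rows += [measurement("b", "G", 2.0, 1.0, i) for i in range(5)]
        with pytest.warns(UserWarning, match="fewer than 3"):
            out = f.compare_groups(rows, value="D")
        assert out.empty

    def test_accepts_dataframe_input(self):
        df = pd.DataFrame({
            "condition": ["a"] * 4 + ["b"] * 4,
            "compartment": ["cytosol"] * 8,
            "channel": ["G"] * 8,
            "D": [1.0, 1.1, 0.9, 1.2, 5.0, 5.2, 4.9, 5.1],
        })
        out = f.compare_groups(df, value="D")
        assert len(out) == 1
        assert out.loc[0, "p"] < 0.05
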