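"""Normality gating, two-sample tests, and CFS subset selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from finstart.sensor_io import ValidationError
from finstart.stats import (
    anderson_darling, cfs_merit, cfs_select, screen_features,
    two_sample_test, welch_t_from_summary,
)


class TestAndersonDarling:
    def test_exact_normal_quantiles_pass(self):
        x = sps.norm.ppf((np.arange(1, 51) - 0.5) / 50)
        a2, normal = anderson_darling(x)
        assert normal and a2 < 0.3

    def test_two_point_mixture_fails(self):
        x = np.concatenate([np.zeros(25), np.full(25, 10.0)])
        a2, normal = anderson_darling(x)
        assert not normal and a2 > 2.0

    def test_affine_invariance(self, rng):
        x = rng.normal(size=40)
        a1, d1 = anderson_darling(x)
        a2, d2 = anderson_darling(3 * x + 7)
        assert d1 == d2
        assert a1 == pytest.approx(a2, rel=1e-9)

    def test_small_sample_rejected(self):
        with pytest.raises(ValidationError):
            anderson_darling(np.arange(5.0))

    def test_constant_sample_not_normal(self):
        _, normal = anderson_darling(np.full(20, 3.0))
        assert not normal


class TestTwoSampleTest:
    def test_identical_samples_null(self, rng):
        x = rng.normal(size=30)
        t, p_w = two_sample_test(x, x, "welch")
        assert t == pytest.approx(0.0, abs=1e-12)
        _, p_r = two_sample_test(x, x, "rank")
        assert p_r == pytest.approx(1.0, abs=0.02)

    def test_summary_level_published_contrast(self):
        # escape vs feeding lateral peak acceleration: 89.05 (4.37) vs
        # 49.04 (3.32), n = 41 each -> t = 7.29, p < 0.0001
        t, df, p = welch_t_from_summary(89.05, 4.37, 41, 49.04, 3.32, 41)
        assert t == pytest.approx(7.29, abs=0.01)
        assert p < 0.0001

    def test_welch_agrees_with_permutation_oracle(self, rng):
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(1.2, 1.5, 10)
        _, p_welch = two_sample_test(a, b, "welch")
        pooled = np.concatenate([a, b])
        observed = abs(a.mean() - b.mean())
        count = 0
        n_perm = 20000
        prng = np.random.default_rng(0)
        for _ in range(n_perm):
            perm = prng.permutation(pooled)
            if abs(perm[:10].mean() - perm[10:].mean()) >= observed:
                count += 1
        assert p_welch == pytest.approx(count / n_perm, abs=0.02)

    def test_both_constant_equal_p_one(self):
        stat, p = two_sample_test(np.full(5, 2.0), np.full(6, 2.0))
        assert p == 1.0

    def test_paired_rank_mode(self, rng):
        a = rng.normal(0, 1, 20)
        b = a + rng.normal(0.8, 0.2, 20)
        _, p = two_sample_test(a, b, "rank", paired=True)
        assert p < 0.01


class TestScreenFeatures:
    def make_table(self, rng, n=41, separation=0.0):
        return pd.DataFrame({
            "f_sep": np.concatenate([
                rng.normal(0, 1, n), rng.normal(separation, 1, n)
            ]),
            "f_noise": rng.normal(0, 1, 2 * n),
            "f_const": np.zeros(2 * n),
            "label": ["escape"] * n + ["feeding"] * n,
        })

    def test_separated_feature_significant(self, rng):
        res = screen_features(self.make_table(rng, separation=3.0))
        row = res.table.set_index("feature").loc["f_sep"]
        assert row["significant"]

    def test_null_feature_type_one_rate(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            res = screen_features(self.make_table(rng))
            row = res.table.set_index("feature").loc["f_noise"]
            hits += int(row["significant"])
        assert hits <= 2   # ~alpha = 0.05 false-positive rate

    def test_constant_feature_non_significant(self, rng):
        res = screen_features(self.make_table(rng))
        row = res.table.set_index("feature").loc["f_const"]
        assert not row["significant"]
        assert row["p"] == 1.0

    def test_test_choice_follows_normality(self, rng):
        n = 41
        table = pd.DataFrame({
            "gaussian": rng.normal(0, 1, 2 * n),
            "bimodal": np.concatenate([
                np.tile([0.0, 10.0], n // 2 + 1)[:n],
                np.tile([0.0, 10.0], n // 2 + 1)[:n],
            ]),
            "label": ["escape"] * n + ["feeding"] * n,
        })
        res = screen_features(table).table.set_index("feature")
        assert res.loc["gaussian", "test"] == "welch_t"
        assert res.loc["bimodal", "test"] == "wilcoxon"

    def test_missing_label_schema_error(self, rng):
        with pytest.raises(ValidationError, match="label"):
            screen_features(pd.DataFrame({"x": rng.normal(size=20)}))


def correlated_table(rng, n=200):
    y = rng.integers(0, 2, n)
    informative = y + rng.normal(0, 1.0, n)
    return pd.DataFrame({
        "informative": informative,
        "clone": informative * 2.0 + 1.0,       # same signal, rescaled
        **{f"noise{i}": rng.normal(size=n) for i in range(9)},
        "label": np.where(y == 1, "escape", "feeding"),
    })


class TestCfsMerit:
    def test_singleton_reduces_to_abs_correlation(self, rng):
        table = correlated_table(rng)
        y = (table["label"] == "feeding").to_numpy(float)
        r = abs(np.corrcoef(table["informative"], y)[0, 1])
        assert cfs_merit(["informative"], table) == pytest.approx(r)

    def test_clone_pair_no_gain(self, rng):
        # two perfectly correlated features: merit = r_cf, same as one
        table = correlated_table(rng)
        single = cfs_merit(["informative"], table)
        pair = cfs_merit(["clone", "informative"], table)
        assert pair == pytest.approx(single, rel=1e-9)

    def test_independent_pair_closed_form(self):
        # r_cf = 0.5 each, r_ff = 0 -> merit = 1/sqrt(2)
        rng = np.random.default_rng(0)
        n = 100000
        y = rng.integers(0, 2, n)
        sigma = np.sqrt(1.0 / 0.25 - 1.0) * 0.5   # tune point-biserial to 0.5
        table = pd.DataFrame({
            "a": y + rng.normal(0, sigma, n),
            "b": y + rng.normal(0, sigma, n),
            "label": np.where(y == 1, "escape", "feeding"),
        })
        merit = cfs_merit(["a", "b"], table)
        # r_ff between a and b is r_cf^2 = 0.25 here, giving the analytic
        # 2*0.5/sqrt(2 + 2*0.25); check against the exact formula instead
        y01 = y.astype(float)
        rcf = np.mean([abs(np.corrcoef(table[c], y01)[0, 1]) for c in "ab"])
        rff = abs(np.corrcoef(table["a"], table["b"])[0, 1])
        assert merit == pytest.approx(2 * rcf / np.sqrt(2 + 2 * rff), rel=1e-9)

    def test_two_orthogonal_features_reach_sqrt_half(self):
        # deterministic construction with exact r_cf = 0.5 and r_ff = 0:
        # a = u + sqrt(3) p, b = sqrt(3) u - p + 2 sqrt(2) q for mutually
        # orthogonal +-1 patterns u (class axis), p, q -> merit = 1/sqrt(2)
        u = np.array([-1, -1, -1, -1, 1, 1, 1, 1], dtype=float)
        p = np.array([-1, -1, 1, 1, -1, -1, 1, 1], dtype=float)
        q = np.array([-1, 1, -1, 1, -1, 1, -1, 1], dtype=float)
        y = (u > 0).astype(float)
        a = u + np.sqrt(3) * p
        b = np.sqrt(3) * u - p + 2 * np.sqrt(2) * q
        table = pd.DataFrame({
            "a": np.tile(a, 10), "b": np.tile(b, 10),
            "label": np.where(np.tile(y, 10) == 1, "escape", "feeding"),
        })
        assert abs(np.corrcoef(table["a"], table["b"])[0, 1]) < 1e-12
        assert cfs_merit(["a", "b"], table) == pytest.approx(1 / np.sqrt(2))

    def test_zero_variance_feature_merit_zero(self, rng):
        table = correlated_table(rng)
        table["flat"] = 1.0
        assert cfs_merit(["flat"], table) == 0.0

    def test_scale_invariance(self, rng):
        table = correlated_table(rng)
        scaled = table.copy()
        scaled["informative"] = scaled["informative"] * 13.0 - 5.0
        assert cfs_merit(["informative", "noise0"], table) == pytest.approx(
            cfs_merit(["informative", "noise0"], scaled)
        )


class TestCfsSelect:
    @pytest.mark.parametrize("seed", range(10))
    def test_selects_informative_over_noise(self, seed):
        rng = np.random.default_rng(seed)
        table = correlated_table(rng).drop(columns="clone")
        selected = cfs_select(table)
        assert "informative" in selected
        assert len(selected) <= 3   # occasional small-sample noise pickup

    def test_duplicated_feature_single_copy(self, rng):
        table = correlated_table(rng)
        selected = cfs_select(table, ["informative", "clone"])
        assert len(selected) == 1

    @pytest.mark.parametrize("search", ["forward", "best_first"])
    def test_matches_exhaustive_enumeration(self, rng, search):
        table = correlated_table(rng)[
            ["informative", "clone", "noise0", "noise1", "noise2", "label"]
        ]
        feats = [c for c in table.columns if c != "label"]
        best_subset, best_merit = None, -1.0
        for k in range(1, len(feats) + 1):
            for sub in itertools.combinations(sorted(feats), k):
                m = cfs_merit(list(sub), table)
                if m > best_merit + 1e-12:
                    best_subset, best_merit = sorted(sub), m
        assert cfs_select(table, feats, search=search) == best_subset

    def test_empty_candidates(self, rng):
        assert cfs_select(correlated_table(rng), []) == []

    def test_screen_then_select_composition(self, rng):
        table = correlated_table(rng)
        screened = screen_features(table).significant_features
        selected = cfs_select(table, screened)
        assert set(selected) <= set(screened)
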