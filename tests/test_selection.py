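"""Collinearity pruning, ANOVA screen, Boruta wrapper."""

import numpy as np
import pandas as pd
import pytest

from octomics.selection import (
    InputError,
    anova_filter,
    boruta,
    prune_collinear,
    select_features,
)


def informative_table(n=300, n_signal=5, n_noise=95, shift=2.0, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    x = rng.standard_normal((n, n_signal + n_noise))
    x[:, :n_signal] += shift * y[:, None]
    cols = [f"sig{i}" for i in range(n_signal)] + [f"noise{i}" for i in range(n_noise)]
    return pd.DataFrame(x, columns=cols), y


class TestPruneCollinear:
    def test_duplicated_column_keeps_one_copy(self):
        rng = np.random.default_rng(0)
        a = rng.random(50)
        t = pd.DataFrame({"a": a, "a_copy": a, "b": rng.random(50)})
        kept = prune_collinear(t, 0.8)
        assert "b" in kept
        assert len([c for c in kept if c.startswith("a")]) == 1

    def test_independent_columns_all_retained(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame(rng.standard_normal((5000, 10)))
        assert len(prune_collinear(t, 0.8)) == 10

    def test_threshold_zero_leaves_one_per_block(self):
        rng = np.random.default_rng(2)
        t = pd.DataFrame(rng.standard_normal((30, 5)))
        kept = prune_collinear(t, 0.0)
        assert len(kept) == 1  # finite-sample r is never exactly 0

    def test_no_retained_pair_exceeds_threshold(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal((200, 4))
        t = pd.DataFrame(np.hstack([base, base + 0.1 * rng.standard_normal((200, 4))]))
        t.columns = [str(c) for c in t.columns]
        kept = prune_collinear(t, 0.8)
        sub = t[kept].corr().abs().to_numpy()
        np.fill_diagonal(sub, 0)
        assert sub.max() <= 0.8

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(4)
        t = pd.DataFrame(rng.standard_normal((100, 6)))
        t.columns = list("abcdef")
        shuffled = t.sample(frac=1.0, random_state=1)
        assert prune_collinear(t, 0.5) == prune_collinear(shuffled, 0.5)


class TestAnovaFilter:
    def test_constant_feature_not_retained(self):
        t = pd.DataFrame({"const": np.ones(40), "varies": np.arange(40.0)})
        groups = np.repeat([1, 2, 3, 4], 10)
        assert "const" not in anova_filter(t, groups)

    def test_group_indicator_retained(self):
        rng = np.random.default_rng(5)
        groups = np.repeat([1, 2], 20)
        t = pd.DataFrame({"ind": (groups == 2) + 1e-3 * rng.standard_normal(40)})
        assert anova_filter(t, groups) == ["ind"]

    def test_type_one_error_calibrated(self):
        # 1000 null features at alpha 0.05: retention rate 0.05 +/- 0.015
        rng = np.random.default_rng(6)
        groups = np.repeat([1, 2, 3, 4], 15)
        t = pd.DataFrame(rng.standard_normal((60, 1000)))
        t.columns = [f"f{i}" for i in range(1000)]
        rate = len(anova_filter(t, groups, alpha=0.05)) / 1000
        assert rate == pytest.approx(0.05, abs=0.015)

    def test_fdr_mode_is_more_conservative_under_null(self):
        rng = np.random.default_rng(7)
        groups = np.repeat([1, 2], 20)
        t = pd.DataFrame(rng.standard_normal((40, 200)))
        t.columns = [f"f{i}" for i in range(200)]
        assert len(anova_filter(t, groups, fdr=True)) <= len(anova_filter(t, groups))

    def test_tiny_group_rejected(self):
        t = pd.DataFrame({"a": np.arange(5.0)})
        with pytest.raises(InputError):
            anova_filter(t, np.array([1, 1, 1, 1, 2]))


class TestBoruta:
    def test_informative_confirmed_noise_rejected(self):
        t, y = informative_table(seed=8)
        res = boruta(t, y, max_iter=60, seed=0, rf_trees=80)
        assert set(res.confirmed) >= {f"sig{i}" for i in range(5)}
        assert len([c for c in res.rejected if c.startswith("noise")]) >= 85

    def test_all_noise_mostly_rejected(self):
        # with impurity importance a fixed noise table can carry one or two
        # chance-correlated columns that legitimately beat fresh shadows;
        # the bulk of null features must still be rejected
        rng = np.random.default_rng(9)
        t = pd.DataFrame(rng.standard_normal((100, 30)))
        t.columns = [f"n{i}" for i in range(30)]
        y = rng.integers(0, 2, 100)
        res = boruta(t, y, max_iter=40, seed=1, rf_trees=60)
        assert len(res.rejected) >= 24
        assert len(res.confirmed) <= 3

    def test_single_iteration_all_tentative(self):
        t, y = informative_table(n=50, n_signal=2, n_noise=8, seed=10)
        res = boruta(t, y, max_iter=1, seed=0, rf_trees=30)
        assert res.tentative == list(t.columns)
        assert res.n_iterations == 1

    def test_non_binary_target_rejected(self):
        t, _ = informative_table(n=30, n_signal=1, n_noise=4, seed=11)
        with pytest.raises(InputError):
            boruta(t, np.arange(30))

    def test_decisions_reproducible_given_seed(self):
        t, y = informative_table(n=120, n_signal=3, n_noise=17, seed=12)
        a = boruta(t, y, max_iter=30, seed=5, rf_trees=50)
        b = boruta(t, y, max_iter=30, seed=5, rf_trees=50)
        assert a.decisions == b.decisions


class TestCascade:
    def test_stage_sets_nested(self):
        t, y = informative_table(n=120, n_signal=3, n_noise=27, seed=13)
        # make two collinear copies to exercise stage 1
        t["sig0_copy"] = t["sig0"] + 1e-6
        groups = (y + 1) + (np.arange(len(y)) % 2) * 2  # 4 pseudo-clusters
        res = select_features(t, groups, y, boruta_iter=25, rf_trees=50, seed=0)
        assert set(res.stage2_retained) <= set(res.stage1_retained)
        s3 = set(res.stage3.confirmed) | set(res.stage3.tentative) | set(res.stage3.rejected)
        assert s3 == set(res.stage2_retained)
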