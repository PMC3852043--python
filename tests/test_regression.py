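import numpy as np
import pandas as pd
import pytest

from txpred.regression import (
    build_family, fit_linear, greedy_select, make_splits, pearson,
    score,
)

from .oracles import exhaustive_first_two


class TestMakeSplits:
    def test_nine_genes_split_three_ways(self):
        s = make_splits([f"g{i}" for i in range(9)], 2, seed=0)[0]
        assert (len(s.train), len(s.test), len(s.validation)) == (3, 3, 3)

    def test_remainder_goes_to_train_first(self):
        s = make_splits([f"g{i}" for i in range(10)], 1, seed=0)[0]
        assert (len(s.train), len(s.test), len(s.validation)) == (4, 3, 3)

    def test_partition_property_every_replicate(self):
        ids = [f"g{i}" for i in range(25)]
        for s in make_splits(ids, 20, seed=3):
            union = set(s.train) | set(s.test) | set(s.validation)
            assert union == set(ids)
            assert len(s.train) + len(s.test) + len(s.validation) == 25

    def test_reproducible_and_replicates_differ(self):
        ids = [f"g{i}" for i in range(30)]
        a = make_splits(ids, 5, seed=9)
        b = make_splits(ids, 5, seed=9)
        assert a == b
        assert a[0].train != a[1].train

    def test_too_few_genes_is_an_error(self):
        with pytest.raises(ValueError):
            make_splits(list("abcdefgh"), 1, seed=0)


class TestFitLinear:
    def test_recovers_noiseless_line(self):
        x = np.linspace(-1, 1, 20)[:, None]
        m = fit_linear(x, 2 * x[:, 0] + 1)
        assert m.coef[0] == pytest.approx(2.0)
        assert m.intercept == pytest.approx(1.0)

    def test_constant_target_gives_zero_slope(self):
        x = np.linspace(-1, 1, 20)[:, None]
        m = fit_linear(x, np.full(20, 5.0))
        assert m.coef[0] == pytest.approx(0.0, abs=1e-10)

    def test_duplicated_column_leaves_prediction_unchanged(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(30, 1))
        y = 3 * x[:, 0] + rng.normal(0, 0.1, 30)
        single = fit_linear(x, y)
        doubled = fit_linear(np.hstack([x, x]), y)
        assert np.allclose(doubled.predict(np.hstack([x, x])),
                           single.predict(x), atol=1e-8)

    def test_nonfinite_input_is_an_error(self):
        with pytest.raises(ValueError):
            fit_linear(np.array([[np.nan]]), np.array([1.0]))


class TestScore:
    def test_perfect_and_anticorrelated(self):
        y = np.arange(10.0)
        assert score(y, y) == pytest.approx(1.0)
        assert score(-y, y) == pytest.approx(-1.0)

    def test_constant_predictions_are_undefined(self):
        assert np.isnan(score(np.ones(10), np.arange(10.0)))

    def test_too_few_pairs_are_undefined(self):
        assert np.isnan(score(np.array([1.0, 2.0]), np.array([1.0, 2.0])))

    def test_log_pearson_acts_on_log_target(self):
        y = np.exp(np.arange(1.0, 11.0))
        preds = np.arange(1.0, 11.0)
        assert score(preds, y, "log_pearson") == pytest.approx(1.0)

    def test_spearman_is_rank_based(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        preds = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert score(preds, y, "spearman") == pytest.approx(1.0)


def _standardize(X):
    return (X - X.mean(axis=0)) / X.std(axis=0)


class TestGreedySelect:
    def _problem(self, seed, n=60, p=5, signal=None):
        rng = np.random.default_rng(seed)
        X = _standardize(rng.normal(size=(n, p)))
        if signal is None:
            signal = rng.normal(size=p) * (rng.random(p) < 0.6)
        y = X @ signal + rng.normal(0, 0.5, n)
        Xt = _standardize(rng.normal(size=(n, p)))
        yt = Xt @ signal + rng.normal(0, 0.5, n)
        return X, y, Xt, yt

    def test_exact_feature_selected_first_with_unit_correlation(self):
        rng = np.random.default_rng(0)
        X = _standardize(rng.normal(size=(40, 4)))
        y = X[:, 2].copy()
        feats, model, train_corr, _ = greedy_select(
            X, y, X, y, ["a", "b", "c", "d"])
        assert feats[0] == "c"
        assert train_corr == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(12))
    def test_first_two_match_exhaustive_pair_search(self, seed):
        X, y, Xt, yt = self._problem(seed, p=6)
        feats, *_ = greedy_select(X, y, Xt, yt,
                                  [f"f{j}" for j in range(6)],
                                  max_features=2, epsilon=-np.inf)
        first, second = exhaustive_first_two(X, y)
        want = [f"f{first}"] + ([f"f{second}"] if second is not None else [])
        assert feats == want[: len(feats)]

    @pytest.mark.parametrize("seed", range(8))
    def test_fast_path_equals_naive_refit_path(self, seed):
        """The projection-based linear argmax must reproduce the literal
        fit-every-candidate loop feature for feature."""
        X, y, Xt, yt = self._problem(seed, n=50, p=7)
        names = [f"f{j}" for j in range(7)]
        fast = greedy_select(X, y, Xt, yt, names, max_features=4,
                             epsilon=-np.inf)
        naive_selected = []
        remaining = list(range(7))
        for _ in range(4):
            best_j, best_c = None, -np.inf
            for j in remaining:
                cols = naive_selected + [j]
                m = fit_linear(X[:, cols], y)
                c = pearson(m.predict(X[:, cols]), y)
                if c > best_c + 1e-12:
                    best_j, best_c = j, c
            naive_selected.append(best_j)
            remaining.remove(best_j)
        assert fast[0] == [names[j] for j in naive_selected]

    def test_stopping_on_test_set_rejects_noise_features(self):
        rng = np.random.default_rng(5)
        n = 200
        X = _standardize(rng.normal(size=(n, 10)))
        y = 2 * X[:, 0] + rng.normal(0, 0.3, n)
        Xt = _standardize(rng.normal(size=(n, 10)))
        yt = 2 * Xt[:, 0] + rng.normal(0, 0.3, n)
        feats, *_ = greedy_select(X, y, Xt, yt,
                                  [f"f{j}" for j in range(10)])
        assert feats[0] == "f0"
        assert len(feats) <= 4  # noise additions stop quickly

    def test_pure_noise_candidates_rarely_change_selection(self):
        kept = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 150
            signal = np.array([1.0, -0.8, 0.6])
            X = _standardize(rng.normal(size=(n, 3)))
            y = X @ signal + rng.normal(0, 0.4, n)
            Xt = _standardize(rng.normal(size=(n, 3)))
            yt = Xt @ signal + rng.normal(0, 0.4, n)
            base, *_ = greedy_select(X, y, Xt, yt, ["a", "b", "c"])
            Xn = np.hstack([X, _standardize(rng.normal(size=(n, 20)))])
            Xtn = np.hstack([Xt, rng.normal(size=(n, 20))])
            noisy, *_ = greedy_select(
                Xn, y, Xtn, yt, ["a", "b", "c"] + [f"n{j}" for j in range(20)])
            kept += set(base) <= set(noisy) or base == noisy[: len(base)]
        assert kept >= 17

    def test_mars_model_kind_runs_end_to_end(self):
        X, y, Xt, yt = self._problem(3, n=80, p=4)
        feats, model, train_corr, _ = greedy_select(
            X, y, Xt, yt, list("abcd"), model_kind="mars",
            max_features=3, mars_params={"max_terms": 7, "max_knots": 8})
        assert 1 <= len(feats) <= 3
        assert np.isfinite(train_corr)


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(8)
    n, p = 120, 12
    X = pd.DataFrame(
        rng.normal(size=(n, p)),
        index=[f"g{i:03d}" for i in range(n)],
        columns=[f"f{j}" for j in range(p)],
    )
    y = pd.Series(X["f1"].to_numpy() - 0.8 * X["f4"].to_numpy()
                  + rng.normal(0, 0.5, n), index=X.index)
    return X, y


class TestBuildFamily:

    def test_prevalence_bounded_by_family_size(self, planted):
        X, y = planted
        fam = build_family(X, y, list(X.columns), n_replicates=15, seed=1)
        assert max(fam.prevalence.values()) <= 15
        assert fam.prevalence["f1"] == 15  # dominant planted feature

    def test_median_predictor_is_a_family_member(self, planted):
        X, y = planted
        fam = build_family(X, y, list(X.columns), n_replicates=15, seed=1)
        assert any(p is fam.median for p in fam.predictors)
        corrs = sorted(np.asarray(fam.validation_corrs()))
        assert fam.median_validation_corr == pytest.approx(corrs[7])

    def test_equal_seed_families_identical(self, planted):
        X, y = planted
        a = build_family(X, y, list(X.columns), n_replicates=8, seed=4)
        b = build_family(X, y, list(X.columns), n_replicates=8, seed=4)
        assert a.to_report() == b.to_report()

    def test_missing_targets_dropped_pairwise(self, planted):
        X, y = planted
        y2 = y.copy()
        y2.iloc[:10] = np.nan
        fam = build_family(X, y2, list(X.columns), n_replicates=6, seed=2)
        used = {g for p in fam.predictors for g in ()}  # structural only
        assert len(fam.predictors) == 6

    def test_scheme_b_hook_sees_only_train_ids(self, planted):
        X, y = planted
        seen: list[set] = []
        splits_log = {}

        def hook(train_ids):
            seen.append(set(train_ids))
            return pd.DataFrame({"b_feat": np.zeros(len(X))}, index=X.index)

        fam = build_family(X, y, list(X.columns) + ["b_feat"], scheme="B",
                           n_replicates=6, seed=3, scheme_b_hook=hook)
        splits = {p.replicate for p in fam.predictors}
        assert len(seen) == 6
        from txpred.regression import make_splits
        expected = make_splits(list(X.index), 6, seed=3)
        for s, got in zip(expected, seen):
            assert got == set(s.train)
            assert not got & (set(s.test) | set(s.validation))

    def test_predictor_coefficients_follow_planted_signs(self, planted):
        X, y = planted
        fam = build_family(X, y, list(X.columns), n_replicates=9, seed=5)
        coefs = fam.median.coefficients()
        assert coefs["f1"] > 0
        if "f4" in coefs:
            assert coefs["f4"] < 0
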