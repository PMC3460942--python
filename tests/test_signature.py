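import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccprog import (
    CompositionTable,
    augment_with_clinical,
    classification_metrics,
    exhaustive_cv,
    filter_enriched,
    n_cv_rounds,
    nsc_predict,
    nsc_train,
    sam_screen,
    select_top_genes,
)
from ccprog.signature import NscModel, enumerate_splits


class TestFilterEnriched:
    def comp(self, fracs):
        ids = [f"s{i}" for i in range(len(fracs))]
        return CompositionTable(ids, ["tumor", "stroma"], [[f, 1 - f] for f in fracs])

    def test_strictly_greater_than_threshold(self):
        assert filter_enriched(self.comp([0.6, 0.5, 0.49])) == ["s0"]

    def test_zero_threshold_keeps_positive_fractions(self):
        assert filter_enriched(self.comp([0.3, 0.0, 0.9]), threshold=0.0) == ["s0", "s2"]

    def test_impossible_threshold_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert filter_enriched(self.comp([0.4, 0.8]), threshold=1.0) == []


class TestSamScreen:
    def test_equal_group_means_give_null_statistic(self, rng):
        y = np.concatenate([rng.normal(5, 0.1, 4), rng.normal(5, 0.1, 4)])
        y = np.tile(y, (3, 1))
        y[:, :4] = y[:, 4:]  # identical group values per gene
        res = sam_screen(y, [1, 1, 1, 1, 0, 0, 0, 0], n_perm=200, seed=0, s0=0.0)
        assert np.all(np.abs(res["d"]) < 1e-12)
        assert np.all(res["perm_p"] > 0.9)

    def test_label_swap_negates_d_keeps_p(self, rng):
        Y = rng.normal(8, 1, (10, 12))
        labels = np.array([1] * 6 + [0] * 6)
        a = sam_screen(Y, labels, n_perm=500, seed=3, s0=0.1).set_index("gene_id")
        b = sam_screen(Y, 1 - labels, n_perm=500, seed=3, s0=0.1).set_index("gene_id")
        np.testing.assert_allclose(a["d"], -b.loc[a.index, "d"], atol=1e-12)
        np.testing.assert_allclose(a["perm_p"], b.loc[a.index, "perm_p"], atol=1e-12)

    def test_six_sample_toy_matches_full_enumeration(self):
        y = np.array([[4.0, 5.0, 6.0, 1.0, 2.0, 3.0]])
        labels = np.array([1, 1, 1, 0, 0, 0])
        res = sam_screen(y, labels, n_perm=10000, seed=0, s0=0.0)

        def d_stat(vals, g1_idx):
            g1 = vals[list(g1_idx)]
            g0 = np.delete(vals, list(g1_idx))
            sp = np.sqrt(
                (1 / 3 + 1 / 3) * (((g1 - g1.mean()) ** 2).sum() + ((g0 - g0.mean()) ** 2).sum()) / 4
            )
            return (g1.mean() - g0.mean()) / sp

        d_obs = d_stat(y[0], (0, 1, 2))
        assert res["d"][0] == pytest.approx(d_obs, abs=1e-12)
        perms = [d_stat(y[0], idx) for idx in combinations(range(6), 3)]
        assert len(perms) == 20
        p_expect = np.mean([abs(d) >= abs(d_obs) - 1e-12 for d in perms])
        assert res["perm_p"][0] == pytest.approx(p_expect, abs=1e-12)

    def test_fold_change_is_antilogged_mean_ratio(self):
        y = np.array([[3.0, 3.2, 1.0, 1.2]])
        res = sam_screen(y, [1, 1, 0, 0], n_perm=100, seed=0, s0=0.0)
        assert res["fold_change"][0] == pytest.approx(4.0)

    def test_planted_signal_ranks_first_and_gates(self, rng):
        Y = rng.normal(8, 0.5, (30, 20))
        labels = np.array([1] * 10 + [0] * 10)
        Y[0, labels == 1] += 2.0
        res = sam_screen(Y, labels, n_perm=2000, seed=1)
        assert res["gene_id"][0] == "g0"
        assert select_top_genes(res, n_top=7, p_threshold=0.002)[0] == "g0"


class TestNsc:
    def toy(self):
        X = np.array(
            [[1.0, 5.0], [1.2, 5.5], [0.8, 4.5], [1.1, 5.2],
             [3.0, 5.1], [3.2, 4.9], [2.8, 5.3], [3.1, 4.7]]
        )
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        return X, y

    def test_delta_zero_equals_plain_nearest_centroid(self, rng):
        X = rng.normal(0, 1, (20, 5))
        y = np.array([0] * 10 + [1] * 10)
        X[y == 1] += 0.8
        model = nsc_train(X, y, delta=0.0)
        pred, _ = nsc_predict(model, X)
        # oracle: unshrunken standardized nearest-centroid rule with priors
        cent = np.vstack([X[y == c].mean(axis=0) for c in (0, 1)])
        denom = (model.pooled_sd + model.s0) ** 2
        scores = np.stack(
            [((X - cent[k]) ** 2 / denom).sum(axis=1) - 2 * np.log(0.5) for k in range(2)],
            axis=1,
        )
        np.testing.assert_array_equal(pred, scores.argmin(axis=1))

    def test_discriminant_matches_hand_calculation(self):
        X, y = self.toy()
        delta = 0.5
        model = nsc_train(X, y, delta=delta)
        _, scores = nsc_predict(model, X)
        # hand oracle: full nearest-shrunken-centroid score function
        n, K = 8, 2
        nk = np.array([4, 4])
        overall = X.mean(axis=0)
        cent = np.vstack([X[y == c].mean(axis=0) for c in (0, 1)])
        sd = np.sqrt(sum(((X[y == c] - cent[k]) ** 2).sum(axis=0) for k, c in enumerate((0, 1))) / (n - K))
        s0 = np.median(sd)
        mk = np.sqrt(1 / nk - 1 / n)
        djk = (cent - overall) / (mk[:, None] * (sd + s0))
        dshr = np.sign(djk) * np.maximum(np.abs(djk) - delta, 0)
        cshr = overall + mk[:, None] * (sd + s0) * dshr
        expect = np.stack(
            [((X - cshr[k]) ** 2 / (sd + s0) ** 2).sum(axis=1) - 2 * np.log(nk[k] / n) for k in range(2)],
            axis=1,
        )
        np.testing.assert_allclose(scores, expect, atol=1e-12)

    def test_separating_feature_gives_zero_training_error(self):
        X, y = self.toy()
        model = nsc_train(X, y, delta=0.1)
        pred, _ = nsc_predict(model, X)
        np.testing.assert_array_equal(pred, y)

    def test_active_features_non_increasing_in_delta(self, rng):
        X = rng.normal(0, 1, (30, 10))
        y = np.array([0] * 15 + [1] * 15)
        X[y == 1, :3] += 1.0
        counts = [
            nsc_train(X, y, delta=d).n_active_features for d in np.linspace(0, 4, 15)
        ]
        assert np.all(np.diff(counts) <= 0)

    def test_infinite_shrinkage_collapses_to_overall_centroid(self, rng):
        X = rng.normal(0, 1, (16, 4))
        y = np.array([0] * 8 + [1] * 8)
        model = nsc_train(X, y, delta=1e6)
        np.testing.assert_allclose(model.shrunken_centroids[0], model.shrunken_centroids[1])
        np.testing.assert_allclose(model.shrunken_centroids[0], model.overall_centroid)

    def test_centroids_classify_to_own_class(self):
        X, y = self.toy()
        model = nsc_train(X, y, delta=0.2)
        pred, _ = nsc_predict(model, model.class_centroids)
        np.testing.assert_array_equal(pred, model.classes)

    def test_missing_feature_is_hard_error(self):
        X, y = self.toy()
        model = nsc_train(X, y, delta=0.0, feature_ids=["gA", "gB"])
        with pytest.raises(KeyError, match="gB"):
            nsc_predict(model, X[:, :1], feature_ids=["gA"])

    def test_inner_cv_picks_separating_delta(self, rng):
        X = rng.normal(0, 1, (40, 6))
        y = np.array([0] * 20 + [1] * 20)
        X[y == 1, 0] += 3.0
        model = nsc_train(X, y)
        pred, _ = nsc_predict(model, X)
        assert (pred == y).mean() >= 0.9

    def test_json_round_trip(self):
        X, y = self.toy()
        model = nsc_train(X, y, delta=0.3)
        back = NscModel.from_dict(model.to_dict())
        _, s1 = nsc_predict(model, X)
        _, s2 = nsc_predict(back, X)
        np.testing.assert_allclose(s1, s2)


class TestAugmentWithClinical:
    def test_appends_one_feature(self, rng):
        X = rng.normal(0, 1, (10, 7))
        Xa, ids, keep = augment_with_clinical(X, [f"g{i}" for i in range(7)], np.full(10, 7.0))
        assert Xa.shape == (10, 8)
        assert ids[-1] == "gleason"
        assert keep.all()

    def test_constant_gleason_has_no_effect_on_predictions(self, rng):
        X = rng.normal(0, 1, (20, 3))
        y = np.array([0] * 10 + [1] * 10)
        X[y == 1] += 1.5
        base = nsc_train(X, y, delta=0.5)
        Xa, ids, _ = augment_with_clinical(X, ["a", "b", "c"], np.full(20, 7.0))
        aug = nsc_train(Xa, y, delta=0.5, feature_ids=ids)
        assert aug.shrunken_differences[:, -1] == pytest.approx(0.0)
        p1, _ = nsc_predict(base, X)
        p2, _ = nsc_predict(aug, Xa)
        np.testing.assert_array_equal(p1, p2)

    def test_informative_gleason_improves_accuracy(self, rng):
        # genes are pure noise; gleason alone separates the classes
        X = rng.normal(0, 1, (30, 7))
        y = np.array([0] * 15 + [1] * 15)
        gleason = np.where(y == 1, 9.0, 6.0) + rng.normal(0, 0.2, 30)
        base = nsc_train(X, y, delta=0.0)
        acc_base = (nsc_predict(base, X)[0] == y).mean()
        Xa, ids, _ = augment_with_clinical(X, [f"g{i}" for i in range(7)], gleason)
        aug = nsc_train(Xa, y, delta=0.0, feature_ids=ids)
        acc_aug = (nsc_predict(aug, Xa)[0] == y).mean()
        assert acc_aug > acc_base

    def test_missing_gleason_excludes_sample(self, rng):
        X = rng.normal(0, 1, (5, 2))
        g = np.array([7.0, np.nan, 8.0, 6.0, np.nan])
        with pytest.warns(UserWarning, match="2 sample"):
            Xa, _, keep = augment_with_clinical(X, ["a", "b"], g)
        assert Xa.shape == (3, 3)
        np.testing.assert_array_equal(keep, [True, False, True, True, False])


class TestExhaustiveCv:
    @staticmethod
    def majority_trainer(X, y):
        vals, counts = np.unique(y, return_counts=True)
        return vals[np.argmax(counts)]

    @staticmethod
    def majority_predictor(model, X):
        return np.full(len(X), model)

    def test_study_scale_round_count(self):
        assert n_cv_rounds({"relapse": 12, "nonrelapse": 11}, {"relapse": 9, "nonrelapse": 8}) == 36300

    def test_small_enumeration_count_and_order(self):
        splits = list(enumerate_splits({0: [0, 1, 2], 1: [3, 4]}, {0: 2, 1: 1}))
        assert len(splits) == 6
        assert splits[0] == ([0, 1, 3], [2, 4])
        for train, test in splits:
            assert sorted(train + test) == [0, 1, 2, 3, 4]

    def test_empty_test_set_is_error(self, rng):
        X = rng.normal(0, 1, (5, 2))
        y = np.array([0, 0, 0, 1, 1])
        with pytest.raises(ValueError, match="empty"):
            exhaustive_cv(X, y, {0: 3, 1: 2}, self.majority_trainer, self.majority_predictor)

    def test_cap_exceeded_instructs_sampling(self, rng):
        X = rng.normal(0, 1, (60, 2))
        y = np.array([0] * 30 + [1] * 30)
        with pytest.raises(ValueError, match="cap"):
            exhaustive_cv(X, y, {0: 15, 1: 15}, self.majority_trainer, self.majority_predictor)

    def test_nsc_cv_on_separated_data(self, rng):
        X = rng.normal(0, 1, (12, 3))
        y = np.array([0] * 6 + [1] * 6)
        X[y == 1] += 3.0
        report = exhaustive_cv(
            X, y, {0: 4, 1: 4},
            trainer=lambda Xt, yt: nsc_train(Xt, yt, delta=0.0),
            predictor=lambda m, Xt: nsc_predict(m, Xt)[0],
        )
        assert report.n_rounds == math.comb(6, 4) ** 2
        assert report.accuracy >= 0.98
        assert report.sensitivity >= 0.95 and report.specificity >= 0.95

    @settings(max_examples=50, deadline=None)
    @given(
        st.integers(1, 12), st.integers(1, 12), st.integers(0, 12), st.integers(0, 12)
    )
    def test_round_count_matches_binomial_product(self, n1, n0, k1, k0):
        k1, k0 = min(k1, n1), min(k0, n0)
        assert n_cv_rounds({"r": n1, "n": n0}, {"r": k1, "n": k0}) == math.comb(n1, k1) * math.comb(n0, k0)


class TestClassificationMetrics:
    def test_nineteen_of_twentyfive_sensitivity(self):
        obs = np.array([1] * 25 + [0] * 17)
        pred = np.array([1] * 19 + [0] * 6 + [0] * 10 + [1] * 7)
        m = classification_metrics(pred, obs)
        assert m.sensitivity == pytest.approx(19 / 25)
        assert m.sensitivity_counts == (19, 25)
        assert "76% (19 of 25)" in str(m)

    def test_perfect_prediction(self):
        m = classification_metrics([1, 0, 1], [1, 0, 1])
        assert m.accuracy == m.sensitivity == m.specificity == 1.0

    def test_all_predicted_relapse_degenerate(self):
        m = classification_metrics([1, 1, 1, 1], [1, 1, 0, 0])
        assert m.sensitivity == 1.0
        assert m.specificity == 0.0

    def test_empty_class_is_undefined_not_zero(self):
        m = classification_metrics([1, 1], [1, 1])
        assert np.isnan(m.specificity)
        assert m.sensitivity == 1.0
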