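"""Tests of the discriminant quality model, CV, rankings and serialization."""

import itertools

import numpy as np
import pandas as pd
import pytest

from even.classify import (
    classify,
    cross_validate,
    decision_score,
    default_model,
    kendall_tau,
    load_model,
    max_normalize,
    normalized_even_score,
    rank_variants,
    save_model,
    score_raw,
    train_lda,
)

from .oracles import decision_score_by_hand, kendall_pair_count, lda_closed_form


def six_point_dataset():
    X = np.array([
        [0.2, 0.9], [0.3, 0.8], [0.25, 0.95],   # bad
        [0.8, 0.2], [0.9, 0.1], [0.85, 0.15],   # good
    ])
    y = np.array(["bad"] * 3 + ["good"] * 3)
    return X, y


def separable_clouds(n=40, seed=0):
    rng = np.random.default_rng(seed)
    good = rng.normal([3.0, 1.0], 0.2, size=(n, 2))
    bad = rng.normal([1.0, 3.0], 0.2, size=(n, 2))
    X = np.vstack([bad, good])
    y = np.array(["bad"] * n + ["good"] * n)
    g = np.arange(2 * n)
    return X, y, g


class TestMaxNormalize:
    def test_training_columns_reach_one(self, rng):
        X = rng.uniform(0.1, 5.0, size=(30, 2))
        Xn = max_normalize(X, X.max(axis=0))
        np.testing.assert_allclose(Xn.max(axis=0), [1.0, 1.0])

    def test_prediction_may_exceed_one(self):
        assert max_normalize(np.array([3.0, 1.0]), np.array([2.0, 2.0]))[0] == 1.5

    def test_round_trip(self, rng):
        x = rng.uniform(0.1, 1.0, size=5)
        m = rng.uniform(0.5, 2.0, size=5)
        np.testing.assert_allclose(max_normalize(x, m) * m, x, rtol=1e-15)

    def test_zero_max_error(self):
        with pytest.raises(ValueError, match="maxima"):
            max_normalize(np.ones(2), np.array([1.0, 0.0]))


class TestTrainLDA:
    def test_separable_clouds_fit_perfectly(self):
        X, y, _ = separable_clouds()
        model = train_lda(X, y)
        Xn = max_normalize(X, model.feature_max)
        pred = np.where(np.asarray(decision_score(model, Xn)) > 0, "good", "bad")
        assert (pred == y).all()

    def test_coefficients_match_closed_form_oracle(self):
        X, y = six_point_dataset()
        model = train_lda(X, y)
        oracle = lda_closed_form(X, y)
        np.testing.assert_allclose(model.coefficients, oracle["coefficients"],
                                   rtol=1e-10)
        np.testing.assert_allclose(model.means, oracle["means"], rtol=1e-12)
        np.testing.assert_allclose(model.shared_covariance, oracle["pooled"],
                                   rtol=1e-12)

    def test_internal_consistency_sigma_mu(self, trained_model):
        # c_k = Sigma^-1 mu_k  <=>  Sigma c_k = mu_k
        recon = trained_model.shared_covariance @ trained_model.coefficients.T
        np.testing.assert_allclose(recon.T, trained_model.means, rtol=1e-8)

    def test_synthetic_coefficient_signs(self, trained_model):
        # flat illumination raises E_edge (good), mosaic raises P_+ (bad)
        w = trained_model.good_direction()
        assert w[0] > 0   # e_edge
        assert w[1] < 0   # p_plus

    def test_agrees_with_sklearn_reference(self, training_set):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X, y, _ = training_set
        model = train_lda(X, y)
        Xn = max_normalize(X, model.feature_max)
        ours = np.where(np.asarray(decision_score(model, Xn)) > 0, "good", "bad")
        ref = LinearDiscriminantAnalysis().fit(Xn, y).predict(Xn)
        assert (ours == ref).mean() >= 0.95

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="2 samples"):
            train_lda(np.ones((3, 2)), np.array(["bad", "good", "good"]))


class TestDecisionScore:
    def test_score_at_good_mean_is_half_mahalanobis(self):
        X, y = six_point_dataset()
        model = train_lda(X, y, priors_mode="uniform")
        d = model.means[1] - model.means[0]
        maha = d @ np.linalg.solve(model.shared_covariance, d)
        s = decision_score(model, model.means[1])
        assert s == pytest.approx(0.5 * maha, rel=1e-10)
        assert s > 0

    def test_matches_hand_evaluated_decision_functions(self):
        X, y = six_point_dataset()
        model = train_lda(X, y)
        oracle = lda_closed_form(X, y)
        for x in max_normalize(X, model.feature_max):
            assert decision_score(model, x) == pytest.approx(
                decision_score_by_hand(oracle, x), rel=1e-10
            )

    def test_label_swap_negates_score(self, rng):
        X, y = six_point_dataset()
        model = train_lda(X, y)
        swapped = train_lda(X, np.where(y == "good", "bad", "good"))
        for x in rng.uniform(0, 1, size=(5, 2)):
            assert decision_score(swapped, x) == pytest.approx(
                -decision_score(model, x), rel=1e-9
            )

    def test_identical_class_means_score_zero(self):
        X = np.array([[0.5, 0.5], [0.7, 0.3], [0.5, 0.5], [0.7, 0.3]])
        y = np.array(["bad", "bad", "good", "good"])
        model = train_lda(X, y, priors_mode="uniform")
        assert decision_score(model, np.array([0.1, 0.9])) == pytest.approx(0.0, abs=1e-9)

    def test_dimension_mismatch(self, trained_model):
        with pytest.raises(ValueError, match="dimension"):
            decision_score(trained_model, np.ones(3))


class TestClassify:
    def test_sign_rule_and_tie(self):
        X, y = six_point_dataset()
        model = train_lda(X, y)
        label_good, s_good = classify(model, max_normalize(X[4], model.feature_max))
        label_bad, s_bad = classify(model, max_normalize(X[0], model.feature_max))
        assert label_good == "good" and s_good > 0
        assert label_bad == "bad" and s_bad < 0
        # exactly zero resolves to bad: midpoint of means with uniform priors
        m = train_lda(X, y, priors_mode="uniform")
        mid = (m.means[0] + m.means[1]) / 2
        label_mid, s_mid = classify(m, mid)
        assert abs(s_mid) < 1e-9
        assert label_mid == "bad"


class TestCrossValidate:
    def test_separable_set_perfect_accuracy(self):
        X, y, g = separable_clouds()
        cv = cross_validate(X, y, g, seed=1)
        assert cv["mean_accuracy"] == 1.0
        for fold in cv["folds"]:
            assert fold["accuracy"] == 1.0

    def test_each_sample_tested_exactly_once(self, training_set):
        X, y, g = training_set
        cv = cross_validate(X, y, g, seed=2)
        tested = np.concatenate([f["test_index"] for f in cv["folds"]])
        assert sorted(tested.tolist()) == list(range(len(y)))

    def test_shuffled_labels_score_at_chance(self):
        # permutation null: mean accuracy over 20 label shuffles stays near 0.5
        X, y, g = separable_clouds(n=30, seed=4)
        rng = np.random.default_rng(8)
        accs = []
        for _ in range(20):
            accs.append(
                cross_validate(X, rng.permutation(y), g, seed=5)["mean_accuracy"]
            )
        assert 0.35 <= np.mean(accs) <= 0.65

    def test_group_straddling_labels_is_rejected(self):
        X = np.random.default_rng(0).uniform(size=(8, 2))
        y = np.array(["bad", "good"] * 4)
        g = np.array([0, 0, 1, 1, 2, 2, 3, 3])
        with pytest.raises(ValueError, match="both labels"):
            cross_validate(X, y, g)


class TestRankVariants:
    def test_orders_by_score(self, trained_model):
        X, y = six_point_dataset()
        model = train_lda(X, y)
        feats = {"raw": X[0], "fourier": X[3], "cidre": X[4]}
        ranking = rank_variants(model, feats, channel_id="ch0")
        scores = [s for _, s in ranking.entries]
        assert scores == sorted(scores, reverse=True)
        assert ranking.best in ("fourier", "cidre")
        assert [v for v, _ in ranking.entries][-1] == "raw"

    def test_single_variant(self, trained_model):
        r = rank_variants(trained_model, {"only": np.array([0.5, 0.01])})
        assert len(r.entries) == 1 and r.best == "only"

    def test_tie_break_by_priority_then_lexical(self, trained_model):
        f = np.array([0.5, 0.01])
        r = rank_variants(
            trained_model, {"b": f, "a": f, "z": f}, method_priority=("z",)
        )
        assert [v for v, _ in r.entries] == ["z", "a", "b"]

    def test_empty_error(self, trained_model):
        with pytest.raises(ValueError, match="no variants"):
            rank_variants(trained_model, {})

    def test_clean_outranks_strong_degradation(
        self, packaged_model, blob_phantom, level_series
    ):
        from even.metrics import compute_features

        feats = {
            "clean": compute_features(blob_phantom).as_array(),
            "level5": compute_features(level_series[-1][0]).as_array(),
        }
        assert rank_variants(packaged_model, feats).best == "clean"


class TestKendallTau:
    def test_identical_and_reversed(self):
        assert kendall_tau(list("abcd"), list("abcd")) == 1.0
        assert kendall_tau(list("abcd"), list("dcba")) == -1.0

    def test_single_swap_example(self):
        assert kendall_tau(list("abcd"), list("acbd")) == pytest.approx(2 / 3)

    def test_matches_pair_count_for_all_permutations_of_five(self):
        base = list("abcde")
        for perm in itertools.permutations(base):
            assert kendall_tau(base, list(perm)) == pytest.approx(
                kendall_pair_count(base, list(perm)), abs=1e-12
            )

    def test_id_mismatch(self):
        with pytest.raises(ValueError, match="same set"):
            kendall_tau(["a", "b"], ["a", "c"])


class TestNormalizedEvenScore:
    def test_three_image_dataset(self):
        scores = pd.DataFrame({"ch0": [1.0, 2.0, 3.0]})
        z = normalized_even_score(scores)
        np.testing.assert_allclose(z.values, [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_shift_invariance_and_summation(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        z1 = normalized_even_score(pd.DataFrame({"c0": a, "c1": b}))
        z2 = normalized_even_score(pd.DataFrame({"c0": a + 100.0, "c1": b}))
        np.testing.assert_allclose(z1.values, z2.values, atol=1e-10)

    def test_zero_std_error(self):
        with pytest.raises(ValueError, match="zero score std"):
            normalized_even_score(pd.DataFrame({"c0": [1.0, 1.0, 1.0]}))

    def test_single_image_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            normalized_even_score(pd.DataFrame({"c0": [1.0]}))


class TestSerialization:
    def test_round_trip_scores(self, trained_model, tmp_path, rng):
        path = tmp_path / "model.json"
        save_model(trained_model, path)
        loaded = load_model(path)
        for x in rng.uniform(0, 1, size=(10, 2)):
            assert decision_score(loaded, x) == pytest.approx(
                decision_score(trained_model, x), rel=1e-12
            )

    def test_missing_field_error(self, trained_model, tmp_path):
        import json

        path = tmp_path / "model.json"
        save_model(trained_model, path)
        payload = json.loads(path.read_text())
        del payload["priors"]
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="priors"):
            load_model(path)

    def test_version_mismatch_warns(self, trained_model, tmp_path):
        import json

        path = tmp_path / "model.json"
        save_model(trained_model, path)
        payload = json.loads(path.read_text())
        payload["schema_version"] = "0"
        path.write_text(json.dumps(payload))
        with pytest.warns(UserWarning, match="schema version"):
            load_model(path)

    def test_packaged_model_is_labelled_synthetic(self, packaged_model):
        assert packaged_model.metadata["training_data"] == "synthetic"


class TestScoreRaw:
    def test_equals_normalize_then_score(self, trained_model, rng):
        x = rng.uniform(0.01, 0.5, size=2)
        direct = score_raw(trained_model, x)
        manual = decision_score(
            trained_model, max_normalize(x, trained_model.feature_max)
        )
        assert direct == pytest.approx(manual, rel=1e-14)
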