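import numpy as np
import pytest
from sklearn.feature_extraction import DictVectorizer
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from rbpspectrum.features import FeatureVector, build_vectors
from rbpspectrum.model import (
    GridSearchConfig,
    TrainedModel,
    cross_validate,
    decision_values,
    feature_weights,
    grid_search,
    load_model,
    out_of_domain_eval,
    predict_labels,
    record_labels,
    save_model,
    stratified_split,
    train_combined,
    train_svm,
)
from rbpspectrum.seqdata import SequenceRecord
from rbpspectrum.simulate import (
    TTP_LENGTH_MODEL,
    make_background,
    make_hur_like,
    make_ttp_like,
)


def _random_vectors(n, dim, rng, scale=1.0):
    names = [f"f{i}" for i in range(dim)]
    return [
        FeatureVector(
            {name: float(rng.normal(0, scale)) for name in names}
        )
        for _ in range(n)
    ]


class TestTrainSvm:
    def test_separable_symmetric_pair(self):
        vecs = [FeatureVector({"x": 1.0}), FeatureVector({"x": -1.0})]
        m = train_svm(vecs, [1, -1], c=1.0)
        assert m.weights["x"] > 0
        assert (predict_labels(m, vecs) == [1, -1]).all()

    def test_label_flip_antisymmetry(self):
        vecs = [FeatureVector({"x": 1.0}), FeatureVector({"x": -1.0})]
        m1 = train_svm(vecs, [1, -1], c=1.0)
        m2 = train_svm(vecs, [-1, 1], c=1.0)
        assert m1.weights["x"] == pytest.approx(-m2.weights["x"])

    def test_separable_points_rank_perfectly(self):
        rng = np.random.default_rng(0)
        pos = _random_vectors(10, 4, rng)
        neg = _random_vectors(10, 4, rng)
        for v in pos:
            v.entries["sig"] = 2.0
        for v in neg:
            v.entries["sig"] = -2.0
        m = train_svm(pos + neg, [1] * 10 + [-1] * 10, c=100.0)
        scores = decision_values(m, pos + neg)
        assert roc_auc_score([1] * 10 + [-1] * 10, scores) == 1.0

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            train_svm([FeatureVector({"x": 1.0})] * 2, [1, 1], c=1.0)

    def test_nonfinite_errors(self):
        with pytest.raises(ValueError):
            train_svm(
                [FeatureVector({"x": float("nan")}), FeatureVector({"x": 1.0})],
                [1, -1], c=1.0,
            )

    def test_bad_c_errors(self):
        with pytest.raises(ValueError):
            train_svm(
                [FeatureVector({"x": 1.0}), FeatureVector({"x": -1.0})],
                [1, -1], c=0.0,
            )

    def test_primal_weights_match_kernel_decision_function(self):
        """Explicit w.x + b equals the solver's kernel-form decision values."""
        rng = np.random.default_rng(3)
        vecs = _random_vectors(30, 6, rng)
        y = np.where(rng.random(30) < 0.5, 1, -1)
        y[:2] = [1, -1]
        m = train_svm(vecs, y, c=2.0)
        vectorizer = DictVectorizer(sparse=False)
        X = vectorizer.fit_transform([v.entries for v in vecs])
        clf = SVC(kernel="linear", C=2.0).fit(X, y)
        np.testing.assert_allclose(
            decision_values(m, vecs), clf.decision_function(X), atol=1e-6
        )

    def test_training_roc_nondecreasing_in_c_on_separable_data(self):
        rng = np.random.default_rng(4)
        vecs = _random_vectors(16, 3, rng, scale=0.3)
        y = [1] * 8 + [-1] * 8
        for v, label in zip(vecs, y):
            v.entries["sig"] = float(label)
        rocs = []
        for c in GridSearchConfig().c_grid:
            m = train_svm(vecs, y, c=c)
            rocs.append(roc_auc_score(y, decision_values(m, vecs)))
        assert all(b >= a - 1e-12 for a, b in zip(rocs, rocs[1:]))


class TestDecisionValues:
    def test_empty_support_gives_bias(self):
        m = TrainedModel(weights={"UUU": 2.0}, bias=-1.0, params={})
        assert decision_values(m, [FeatureVector({})])[0] == -1.0

    def test_manual_model(self):
        m = TrainedModel(weights={"UUU": 2.0}, bias=-1.0, params={})
        assert decision_values(m, [FeatureVector({"UUU": 1.0})])[0] == 1.0

    def test_unseen_features_ignored(self):
        m = TrainedModel(weights={"UUU": 2.0}, bias=0.0, params={})
        v1 = FeatureVector({"UUU": 1.0})
        v2 = FeatureVector({"UUU": 1.0, "AAA": 99.0})
        assert decision_values(m, [v1])[0] == decision_values(m, [v2])[0]

    def test_zero_maps_to_negative(self):
        m = TrainedModel(weights={}, bias=0.0, params={})
        assert predict_labels(m, [FeatureVector({})])[0] == -1


class TestFeatureWeights:
    def test_top_n_zero(self):
        m = TrainedModel(weights={"a": 1.0}, bias=0.0, params={})
        assert feature_weights(m, 0) == []

    def test_descending_order(self):
        m = TrainedModel(weights={"a": 1.0, "b": 3.0, "c": -2.0}, bias=0.0, params={})
        assert [f for f, _ in feature_weights(m)] == ["b", "a", "c"]

    def test_u_homopolymer_outranks_a_homopolymer(self):
        """U-rich positives vs A-rich negatives: U k-mers get top weights."""
        rng = np.random.default_rng(7)
        pos = [
            SequenceRecord(
                f"p{i}",
                "".join(rng.choice(list("ACGU"), 30, p=[0.1, 0.1, 0.1, 0.7])),
            )
            for i in range(40)
        ]
        neg = [
            SequenceRecord(
                f"n{i}",
                "".join(rng.choice(list("ACGU"), 30, p=[0.7, 0.1, 0.1, 0.1])),
                "negative",
            )
            for i in range(40)
        ]
        vecs = build_vectors(pos + neg, 3, 3)
        m = train_svm(vecs, [1] * 40 + [-1] * 40, c=1.0)
        assert m.weights.get("UUU", 0) > m.weights.get("AAA", 0)
        top = [f for f, _ in feature_weights(m, 5)]
        assert "AAA" not in top


class TestStratifiedSplit:
    def test_balanced_proportions(self):
        records = [SequenceRecord(f"p{i}", "ACGU") for i in range(100)] + [
            SequenceRecord(f"n{i}", "ACGU", "negative") for i in range(100)
        ]
        train, holdout = stratified_split(records, 0.2, seed=0)
        labels = record_labels(holdout)
        assert (labels == 1).sum() == 20 and (labels == -1).sum() == 20

    def test_imbalanced_proportions(self):
        records = [SequenceRecord(f"p{i}", "ACGU") for i in range(5)] + [
            SequenceRecord(f"n{i}", "ACGU", "negative") for i in range(95)
        ]
        _, holdout = stratified_split(records, 0.2, seed=0)
        labels = record_labels(holdout)
        assert (labels == 1).sum() == 1 and (labels == -1).sum() == 19

    def test_deterministic(self):
        records = [SequenceRecord(f"p{i}", "ACGU") for i in range(10)] + [
            SequenceRecord(f"n{i}", "ACGU", "negative") for i in range(10)
        ]
        a = stratified_split(records, 0.3, seed=5)
        b = stratified_split(records, 0.3, seed=5)
        assert [r.id for r in a[0]] == [r.id for r in b[0]]

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            stratified_split([SequenceRecord("p", "A")], 1.5, seed=0)


@pytest.fixture(scope="module")
def separable_records():
    pos = make_hur_like(30, seed=1)
    neg = [
        SequenceRecord(f"n{i}", "GC" * 15, "negative") for i in range(30)
    ]
    return pos + neg


class TestCrossValidate:
    def test_separable_mean_roc_is_one(self, separable_records):
        roc = cross_validate(
            separable_records, {"k1": 3, "k2": 3, "C": 10.0}, folds=5, seed=0
        )
        assert roc == 1.0

    def test_permuted_labels_near_chance(self, separable_records):
        rng = np.random.default_rng(11)
        labels = rng.permutation(
            ["positive"] * 30 + ["negative"] * 30
        )
        shuffled = [
            SequenceRecord(r.id, r.seq, label)
            for r, label in zip(separable_records, labels)
        ]
        roc = cross_validate(shuffled, {"k1": 3, "k2": 3, "C": 1.0}, folds=5, seed=0)
        assert abs(roc - 0.5) < 0.15

    def test_too_many_folds_errors(self, separable_records):
        with pytest.raises(ValueError, match="folds"):
            cross_validate(
                separable_records[:8], {"k1": 3, "k2": 3, "C": 1.0}, folds=10, seed=0
            )

    def test_deterministic(self, separable_records):
        params = {"k1": 3, "k2": 4, "C": 1.0}
        assert cross_validate(separable_records, params, 4, 9) == cross_validate(
            separable_records, params, 4, 9
        )


class TestGridSearch:
    def test_separable_toy_perfect(self, separable_records):
        config = GridSearchConfig(
            k_min=3, k_max=4, c_grid=(0.1, 1.0), folds=3, seed=0
        )
        res = grid_search(separable_records, config)
        assert res.cv_roc == 1.0
        assert res.holdout_report.roc_auc == 100.0

    def test_trace_row_count(self, separable_records):
        config = GridSearchConfig(k_min=3, k_max=5, c_grid=(0.1, 1.0), folds=2, seed=0)
        res = grid_search(
            separable_records, config,
            evaluator=lambda recs, params, folds, seed: 0.5,
        )
        assert len(res.trace) == 6 * 2  # C(3,2)+3 = 6 (k1<=k2) pairs x 2 C values

    def test_tie_breaking_prefers_simpler_models(self, separable_records):
        config = GridSearchConfig(k_min=3, k_max=5, c_grid=(10.0, 0.1), folds=2, seed=0)
        res = grid_search(
            separable_records, config,
            evaluator=lambda recs, params, folds, seed: 0.9,
        )
        assert res.best_params["C"] == 0.1
        assert res.best_params["k1"] == 3 and res.best_params["k2"] == 3

    def test_deterministic(self, separable_records):
        config = GridSearchConfig(k_min=3, k_max=3, c_grid=(1.0,), folds=3, seed=2)
        r1 = grid_search(separable_records, config)
        r2 = grid_search(separable_records, config)
        assert r1.best_params == r2.best_params
        assert r1.holdout_report == r2.holdout_report

    def test_default_grid_shape(self):
        config = GridSearchConfig()
        assert len(config.pairs) == 28
        assert len(config.c_grid) == 15


@pytest.fixture(scope="module")
def domain_datasets():
    hur = make_hur_like(60, seed=1) + make_background(60, seed=2, domain="HuR")
    ttp = make_ttp_like(60, seed=3) + make_background(
        60, seed=4, length_model=TTP_LENGTH_MODEL, domain="TTP"
    )
    return hur, ttp


class TestTrainCombined:
    def test_combined_feature_space_and_candidates(self, domain_datasets):
        hur, ttp = domain_datasets
        res = train_combined(hur, ttp, {"k1": 4, "k2": 4, "C": 1.0})
        assert res.candidate_features
        prefixes = {f.split("_")[0] for f in res.combined_model.weights if "_" in f}
        assert prefixes <= {"HuR", "TTP"}
        bare = {f for f in res.combined_model.weights if "_" not in f}
        assert bare <= res.candidate_features

    def test_identical_datasets_shared_features_dominate(self):
        data = make_hur_like(40, seed=5) + make_background(40, seed=6)
        hur = [SequenceRecord(r.id, r.seq, r.label, "HuR") for r in data]
        ttp = [SequenceRecord(r.id, r.seq, r.label, "TTP") for r in data]
        res = train_combined(hur, ttp, {"k1": 3, "k2": 3, "C": 1.0})
        w = res.combined_model.weights
        for feat in res.candidate_features:
            shared = abs(w.get(feat, 0.0))
            for dom in ("HuR", "TTP"):
                assert shared >= abs(w.get(f"{dom}_{feat}", 0.0)) - 1e-6

    def test_domain_specific_motif_ranks_above_foreign_copy(self, domain_datasets):
        hur, ttp = domain_datasets
        res = train_combined(hur, ttp, {"k1": 9, "k2": 9, "C": 1.0})
        w = res.combined_model.weights
        motif = "AUUUAUUUA"
        ttp_specific = max(w.get(f"TTP_{motif}", 0.0), w.get(motif, 0.0))
        assert ttp_specific > w.get(f"HuR_{motif}", 0.0)


class TestOutOfDomainEval:
    def test_training_data_is_optimistic_bound(self, domain_datasets):
        hur, _ = domain_datasets
        res = train_combined(*domain_datasets, {"k1": 4, "k2": 4, "C": 1.0})
        rep = out_of_domain_eval(res.hur_model, hur)
        assert rep.roc_auc >= 95.0

    def test_cross_domain_scores_lower_than_in_domain(self, domain_datasets):
        hur, ttp = domain_datasets
        res = train_combined(hur, ttp, {"k1": 5, "k2": 5, "C": 1.0})
        in_domain = out_of_domain_eval(res.ttp_model, ttp).roc_auc
        foreign = out_of_domain_eval(res.hur_model, ttp).roc_auc
        assert foreign < in_domain

    def test_empty_test_set(self, domain_datasets):
        res = train_combined(*domain_datasets, {"k1": 4, "k2": 4, "C": 1.0})
        with pytest.raises(ValueError):
            out_of_domain_eval(res.hur_model, [])


class TestSerialization:
    def test_model_roundtrip(self, tmp_path, domain_datasets):
        hur, _ = domain_datasets
        vecs = build_vectors(hur, 3, 3)
        m = train_svm(vecs, record_labels(hur), 1.0, {"k1": 3, "k2": 3})
        path = tmp_path / "model.txt"
        save_model(m, path)
        back = load_model(path)
        assert back.weights == pytest.approx(m.weights)
        assert back.bias == pytest.approx(m.bias)
        assert back.params["k1"] == 3
        np.testing.assert_allclose(
            decision_values(back, vecs), decision_values(m, vecs)
        )
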