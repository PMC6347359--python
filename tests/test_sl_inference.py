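"""Negative sampling, splitting, forest training, metrics, prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from synletcombo import (
    GenePair,
    LabeledInstance,
    PairFeatureVector,
    SLInteractionSet,
    evaluate_classifier,
    merge_sl_sets,
    metrics_from_scores,
    predict_candidates,
    run_classifier_benchmark,
    sample_negative_pairs,
    split_train_test,
    train_classifier,
)
from synletcombo.benchmark import make_labeled_instances
from synletcombo.network_features import FEATURE_ORDER
from synletcombo.sl_inference import NEGATIVE, POSITIVE
from synletcombo.synthetic_data import SyntheticWorldConfig, generate_world


def fv(values, version=None):
    kwargs = {} if version is None else {"feature_version": version}
    return PairFeatureVector.from_array(values, **kwargs)


def make_instances(X, y):
    return [
        LabeledInstance(
            pair=GenePair.make(f"G{i:03d}a", f"G{i:03d}b"),
            features=fv(row),
            label=POSITIVE if label else NEGATIVE,
        )
        for i, (row, label) in enumerate(zip(X, y))
    ]


class TestSampleNegativePairs:
    def test_sl_endpoints_excluded_from_universe(self):
        known = SLInteractionSet([("A", "X")])
        got = sample_negative_pairs({"A", "B", "C"}, known, n=1, seed=0)
        assert {p.as_tuple() for p in got} == {("B", "C")}

    def test_zero_returns_empty(self):
        assert sample_negative_pairs({"A", "B"}, SLInteractionSet(), 0, 0) == set()

    def test_excess_request_reports_maximum(self):
        with pytest.raises(ValueError, match="only 3"):
            sample_negative_pairs({"A", "B", "C"}, SLInteractionSet(), 4, 0)

    def test_seed_determinism_and_seed_sensitivity(self):
        genes = {f"G{i}" for i in range(20)}
        a = sample_negative_pairs(genes, SLInteractionSet(), 30, seed=7)
        b = sample_negative_pairs(genes, SLInteractionSet(), 30, seed=7)
        c = sample_negative_pairs(genes, SLInteractionSet(), 30, seed=8)
        assert a == b
        assert a != c

    def test_never_emits_known_sl_pair(self, default_world):
        known = default_world.sl_set
        got = sample_negative_pairs(
            set(default_world.genes), known, n=200, seed=3
        )
        assert len(got) == 200
        assert all(p not in known for p in got)


class TestSplitTrainTest:
    def make_balanced(self, n_per_class):
        X = np.arange(2 * n_per_class * 10, dtype=float).reshape(-1, 10)
        y = [1] * n_per_class + [0] * n_per_class
        return make_instances(X, y)

    def test_six_plus_six_split(self):
        train, test = split_train_test(self.make_balanced(6), seed=0)
        count = lambda group, lab: sum(1 for i in group if i.label == lab)
        assert count(train, POSITIVE) == count(train, NEGATIVE) == 4
        assert count(test, POSITIVE) == count(test, NEGATIVE) == 2
        assert {i.pair for i in train}.isdisjoint({i.pair for i in test})
        assert len(train) + len(test) == 12

    def test_balanced_1049_per_class(self):
        train, test = split_train_test(self.make_balanced(1049), seed=0)
        count = lambda group, lab: sum(1 for i in group if i.label == lab)
        assert count(train, POSITIVE) == count(train, NEGATIVE)
        assert 699 <= count(train, POSITIVE) <= 700
        assert 349 <= count(test, POSITIVE) <= 350

    def test_same_seed_same_membership(self):
        inst = self.make_balanced(10)
        t1, _ = split_train_test(inst, seed=5)
        t2, _ = split_train_test(inst, seed=5)
        assert [i.pair for i in t1] == [i.pair for i in t2]

    def test_too_few_per_class_raises(self):
        with pytest.raises(ValueError, match="at least 2"):
            split_train_test(self.make_balanced(6)[:7], seed=0)


class TestMetrics:
    class StubModel:
        feature_version = "synletcombo-features-v1"

        def __init__(self, scores):
            self._scores = np.asarray(scores, dtype=float)

        def scores(self, X):
            return self._scores[: len(X)]

    def test_perfect_predictions(self):
        m = metrics_from_scores([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2])
        assert (
            m.accuracy == m.precision == m.recall == m.f1 == m.specificity
            == m.auc == 1.0
        )

    def test_hand_confusion_matrix(self):
        # TP=3, FP=1, TN=4, FN=2
        y = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        s = [0.9, 0.8, 0.7, 0.1, 0.2, 0.6, 0.1, 0.2, 0.3, 0.4]
        m = metrics_from_scores(y, s)
        assert (m.tp, m.fp, m.tn, m.fn) == (3, 1, 4, 2)
        assert m.accuracy == pytest.approx(0.7)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.6)
        assert m.f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)
        assert m.specificity == pytest.approx(0.8)

    def test_constant_scores_give_auc_half(self):
        m = metrics_from_scores([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5])
        assert m.auc == pytest.approx(0.5)

    def test_undefined_precision_is_sentinel_not_zero(self):
        m = metrics_from_scores([1, 1, 0], [0.1, 0.2, 0.3])  # no positive calls
        assert m.precision is None
        assert m.f1 is None

    def test_single_class_test_set_raises(self):
        inst = make_instances(np.zeros((3, 10)), [1, 1, 1])
        with pytest.raises(ValueError, match="both classes"):
            evaluate_classifier(self.StubModel([0.5, 0.5, 0.5]), inst)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_vectors_match_brute_force_oracle(self, seed):
        """100 random prediction vectors vs direct-count confusion oracle."""
        rng = np.random.default_rng(seed)
        for _ in range(20):
            n = int(rng.integers(4, 40))
            y = rng.integers(0, 2, size=n)
            if len(set(y)) < 2:
                continue
            s = np.round(rng.random(n), 2)  # rounding forces score ties
            m = metrics_from_scores(y, s)
            pred = (s >= 0.5).astype(int)
            tp = sum(1 for yi, pi in zip(y, pred) if yi == 1 and pi == 1)
            fp = sum(1 for yi, pi in zip(y, pred) if yi == 0 and pi == 1)
            tn = sum(1 for yi, pi in zip(y, pred) if yi == 0 and pi == 0)
            fn = sum(1 for yi, pi in zip(y, pred) if yi == 1 and pi == 0)
            assert (m.tp, m.fp, m.tn, m.fn) == (tp, fp, tn, fn)
            assert m.accuracy == pytest.approx((tp + tn) / n)
            if tp + fp:
                assert m.precision == pytest.approx(tp / (tp + fp))
            assert m.auc == pytest.approx(roc_auc_score(y, s))


class TestTrainClassifier:
    def test_separable_features_pick_smallest_grid_size(self):
        rng = np.random.default_rng(0)
        n = 60
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        X = rng.normal(size=(n, 10))
        X[:, 0] = y * 10.0  # perfectly separating feature
        model = train_classifier(
            make_instances(X, y), cv_folds=5, tree_grid=(10, 50, 100), seed=0
        )
        assert all(acc == 1.0 for acc in model.cv_accuracy.values())
        assert model.n_trees == 10

    def test_pure_noise_accuracy_near_chance(self):
        rng = np.random.default_rng(42)
        n = 200
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        X = rng.normal(size=(n, 10))
        instances = make_instances(X, y)
        train, test = split_train_test(instances, seed=42)
        model = train_classifier(train, cv_folds=5, tree_grid=(25, 93), seed=42)
        metrics = evaluate_classifier(model, test)
        assert 0.4 <= metrics.accuracy <= 0.6

    def test_constant_feature_warns_but_trains(self):
        rng = np.random.default_rng(1)
        y = np.array([1] * 10 + [0] * 10)
        X = rng.normal(size=(20, 10))
        X[:, 3] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            model = train_classifier(
                make_instances(X, y), cv_folds=2, tree_grid=(10,), seed=0
            )
        assert model.n_trees == 10

    def test_planted_signal_world_is_learnable(self, default_benchmark):
        assert default_benchmark.metrics.accuracy >= 0.70


class TestPredictCandidates:
    def _model_and_candidates(self, default_benchmark):
        model = default_benchmark.model
        candidates = [
            (inst.pair, inst.features) for inst in default_benchmark.test
        ]
        return model, candidates

    def test_threshold_zero_returns_all(self, default_benchmark):
        model, candidates = self._model_and_candidates(default_benchmark)
        got = predict_candidates(model, candidates, threshold=0.0)
        assert len(got) == len({p for p, _ in candidates})

    def test_threshold_above_one_returns_none(self, default_benchmark):
        model, candidates = self._model_and_candidates(default_benchmark)
        assert predict_candidates(model, candidates, threshold=1.01) == set()

    def test_feature_version_mismatch_raises(self, default_benchmark):
        model, candidates = self._model_and_candidates(default_benchmark)
        stale = [(p, fv(f.as_array(), version="other-v0")) for p, f in candidates]
        with pytest.raises(ValueError, match="feature version"):
            predict_candidates(model, stale)

    def test_recovers_held_out_true_sl_pairs(self, default_benchmark):
        """>= 60% of held-out true SL pairs score above 0.5."""
        model = default_benchmark.model
        held_out = [
            (i.pair, i.features)
            for i in default_benchmark.test
            if i.label == POSITIVE
        ]
        got = predict_candidates(model, held_out, threshold=0.5)
        assert len(got) >= 0.6 * len(held_out)
        assert all(p.provenance == "predicted" for p in got)


class TestMergeSLSets:
    def test_disjoint_union(self):
        a = SLInteractionSet([("A", "B"), ("C", "D"), ("E", "F")])
        b = SLInteractionSet([("G", "H"), ("I", "J")])
        assert len(merge_sl_sets(a, b)) == 5

    def test_overlapping_hand_union(self):
        a = SLInteractionSet(
            [("A", "B"), ("C", "D"), ("E", "F"), ("G", "H"), ("I", "J")],
            provenance="yeast_derived",
        )
        b = SLInteractionSet(
            [("A", "B"), ("C", "D"), ("K", "L"), ("M", "N")],
            provenance="predicted",
        )
        merged = merge_sl_sets(a, b)
        assert len(merged) == 7
        assert merged.provenance_of(("A", "B")) == {"yeast_derived", "predicted"}
        assert merged.provenance_of(("E", "F")) == {"yeast_derived"}

    @given(
        a=st.sets(
            st.tuples(st.sampled_from("ABCDEFGH"), st.sampled_from("ABCDEFGH"))
            .filter(lambda t: t[0] < t[1]),
            max_size=15,
        ),
        b=st.sets(
            st.tuples(st.sampled_from("ABCDEFGH"), st.sampled_from("ABCDEFGH"))
            .filter(lambda t: t[0] < t[1]),
            max_size=15,
        ),
    )
    @settings(max_examples=80, deadline=None)
    def test_merge_law(self, a, b):
        sa, sb = SLInteractionSet(a), SLInteractionSet(b)
        assert len(merge_sl_sets(sa, sb)) == len(a) + len(b) - len(a & b)

    def test_gene_universe_is_endpoint_union(self):
        merged = merge_sl_sets(
            SLInteractionSet([("A", "B")]), SLInteractionSet([("B", "C")])
        )
        assert merged.gene_universe == {"A", "B", "C"}


class TestPipelineDeterminismAndSignal:
    def test_same_seed_gives_identical_predictions(self, tmp_path):
        from synletcombo.io import write_sl_pairs_tsv

        paths = []
        for run in range(2):
            res = run_classifier_benchmark(
                SyntheticWorldConfig(seed=5), cv_folds=3, tree_grid=(25,)
            )
            predicted = predict_candidates(
                res.model, [(i.pair, i.features) for i in res.test]
            )
            path = tmp_path / f"pred_{run}.tsv"
            write_sl_pairs_tsv(SLInteractionSet(predicted), path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_signal_worlds_beat_matched_null_worlds(self):
        """Planted-signal accuracy exceeds matched-null accuracy, paired."""
        diffs = []
        for seed in range(5):
            cfg = SyntheticWorldConfig(seed=seed)
            sig = run_classifier_benchmark(cfg, cv_folds=3, tree_grid=(50,))
            null = run_classifier_benchmark(
                cfg.null_variant(), cv_folds=3, tree_grid=(50,)
            )
            diffs.append(sig.metrics.accuracy - null.metrics.accuracy)
        assert np.mean(diffs) > 0
        assert sum(d > 0 for d in diffs) >= 4


def test_instances_balanced_and_disjoint(default_world):
    instances = make_labeled_instances(default_world)
    pos = [i for i in instances if i.label == POSITIVE]
    neg = [i for i in instances if i.label == NEGATIVE]
    assert len(pos) == len(neg) == len(default_world.true_sl)
    assert {i.pair for i in pos}.isdisjoint({i.pair for i in neg})
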