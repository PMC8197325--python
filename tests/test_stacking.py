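"""Out-of-fold Label-Proba construction and the combination search."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from xgbstack import (
    BaseLearnerSpec,
    Dataset,
    FusionConfig,
    LabelProbaMatrix,
    SplitSpec,
    enumerate_and_select,
    holdout_label_proba,
    oof_label_proba,
    sel_stacking_fit_predict,
    split_dataset,
)

from conftest import MajorityStub, RowFeatureStub, SpyStub


def four_sample_dataset():
    X = np.arange(8, dtype=float).reshape(4, 2)
    return Dataset(["a", "b"], X, np.array([0, 0, 1, 1]))


def spec(tag="stub"):
    return BaseLearnerSpec(tag=tag, feature_subset=frozenset({"a", "b"}))


class TestOofLabelProba:
    def test_two_fold_majority_stub_hand_computation(self):
        """With labels [0,0,1,1] and stratified 2-folds, every fold's training
        part holds one 0 and one 1, so the stub's class-1 frequency is 0.5
        and the thresholded label is 1 for every row."""
        ds = four_sample_dataset()
        m = oof_label_proba(ds, [spec()], K=2, seed=0,
                            learner_factory=lambda s: MajorityStub())
        np.testing.assert_array_equal(m.values[:, 0], np.ones(4))
        np.testing.assert_array_equal(m.values[:, 1], np.full(4, 0.5))

    def test_skewed_stub_frequencies(self):
        """With labels [0,0,0,1,1,1] and K=3 stratified folds, each training
        part holds two of each class, so proba is 2/4 = 0.5; with labels
        [0,0,0,0,1,1] folds differ and the frequencies are hand-checkable."""
        X = np.zeros((6, 1))
        ds = Dataset(["a"], X, np.array([0, 0, 0, 0, 1, 1]))
        m = oof_label_proba(ds, [BaseLearnerSpec("stub", frozenset({"a"}))],
                            K=2, seed=1, learner_factory=lambda s: MajorityStub())
        # each fold trains on 2 zeros + 1 one -> p1 = 1/3, label 0
        np.testing.assert_allclose(m.values[:, 1], np.full(6, 1 / 3))
        np.testing.assert_array_equal(m.values[:, 0], np.zeros(6))

    def test_invariants_and_determinism(self, small_synth):
        specs = [BaseLearnerSpec("knn", frozenset(small_synth.feature_names[:5]))]
        m1 = oof_label_proba(small_synth, specs, K=4, seed=2)
        m2 = oof_label_proba(small_synth, specs, K=4, seed=2)
        np.testing.assert_array_equal(m1.values, m2.values)
        assert np.isin(m1.values[:, 0], (0, 1)).all()
        assert ((m1.values[:, 1] >= 0) & (m1.values[:, 1] <= 1)).all()
        # thresholding convention ties the two columns together
        np.testing.assert_array_equal(m1.values[:, 0], m1.values[:, 1] >= 0.5)

    def test_no_row_sees_its_own_label(self):
        """Spy leakage test: the model producing a row's meta-features never
        trained on that row."""
        n = 30
        X = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
        y = np.tile([0, 1], n // 2)
        ds = Dataset(["row_id", "pad"], X, y)
        log: list = []
        oof_label_proba(ds, [BaseLearnerSpec("spy", frozenset({"row_id", "pad"}))],
                        K=3, seed=0, learner_factory=lambda s: SpyStub(log))
        assert len(log) == n
        for row, train_ids in log:
            assert row not in train_ids

    def test_zeroing_a_row_changes_only_its_own_meta_features(self):
        """With a learner whose prediction depends only on the scored row,
        zeroing one training row's features perturbs exactly that row's OOF
        entry."""
        rng = np.random.default_rng(4)
        X = rng.uniform(0.1, 0.9, size=(12, 2))
        y = np.tile([0, 1], 6)
        ds = Dataset(["a", "b"], X, y)
        specs = [BaseLearnerSpec("stub", frozenset({"a", "b"}))]
        factory = lambda s: RowFeatureStub()
        base = oof_label_proba(ds, specs, K=3, seed=0, learner_factory=factory)
        X2 = X.copy()
        X2[5] = 0.0
        ds2 = Dataset(["a", "b"], X2, y)
        pert = oof_label_proba(ds2, specs, K=3, seed=0, learner_factory=factory)
        diff = np.flatnonzero((base.values != pert.values).any(axis=1))
        np.testing.assert_array_equal(diff, [5])

    def test_single_class_fold_errors(self):
        ds = Dataset(["a"], np.zeros((4, 1)), np.array([0, 0, 0, 1]))
        with pytest.raises(ValueError, match="class"):
            oof_label_proba(ds, [BaseLearnerSpec("stub", frozenset({"a"}))],
                            K=4, seed=0, learner_factory=lambda s: MajorityStub())

    def test_too_many_folds(self):
        ds = four_sample_dataset()
        with pytest.raises(ValueError, match="folds"):
            oof_label_proba(ds, [spec()], K=10)


class TestHoldoutLabelProba:
    def test_stub_holdout_constant(self):
        ds = four_sample_dataset()
        hold = four_sample_dataset()
        m = holdout_label_proba(ds, hold, [spec()],
                                learner_factory=lambda s: MajorityStub())
        np.testing.assert_array_equal(m.values[:, 1], np.full(4, 0.5))
        assert m.values.shape == (4, 2)

    def test_column_count(self, small_synth):
        tr, va, _ = split_dataset(small_synth, SplitSpec(seed=1))
        specs = [BaseLearnerSpec("knn", frozenset(small_synth.feature_names[:4])),
                 BaseLearnerSpec("gbdt", frozenset(small_synth.feature_names[:4]),
                                 params={"n_estimators": 10})]
        m = holdout_label_proba(tr, va, specs)
        assert m.values.shape == (va.n_samples, 4)
        assert m.tags == ("knn", "gbdt")

    def test_memorizing_learner_reproduces_labels(self, small_synth):
        tr, _, _ = split_dataset(small_synth, SplitSpec(seed=1))
        specs = [BaseLearnerSpec("knn", frozenset(small_synth.feature_names),
                                 params={"n_neighbors": 1})]
        m = holdout_label_proba(tr, tr, specs)
        np.testing.assert_array_equal(m.values[:, 0], tr.y)


class TestLabelProbaMatrix:
    def test_shape_validation(self):
        with pytest.raises(ValueError, match="shape"):
            LabelProbaMatrix(np.zeros((3, 3)), ("a",))

    def test_value_validation(self):
        with pytest.raises(ValueError, match="label"):
            LabelProbaMatrix(np.full((2, 2), 0.5), ("a",))
        bad = np.array([[1.0, 1.5]])
        with pytest.raises(ValueError, match="probability"):
            LabelProbaMatrix(bad, ("a",))

    def test_input_mode_widths(self):
        vals = np.array([[1.0, 0.9, 0.0, 0.2], [0.0, 0.1, 1.0, 0.8]])
        m = LabelProbaMatrix(vals, ("p", "q"))
        assert m.select(("p", "q"), "label").shape == (2, 2)
        assert m.select(("p", "q"), "proba").shape == (2, 2)
        assert m.select(("p", "q"), "label_proba").shape == (2, 4)
        np.testing.assert_array_equal(m.select(("q",), "proba")[:, 0], [0.2, 0.8])


def lookup_matrix(tags, n=6):
    vals = np.zeros((n, 2 * len(tags)))
    vals[:, 1::2] = 0.5
    return LabelProbaMatrix(vals, tuple(tags))


class TestEnumerateAndSelect:
    def run_lookup(self, tags, table, default=0.5):
        m = lookup_matrix(tags)
        y = np.tile([0, 1], 3)
        score = lambda combo: table.get(frozenset(combo), default)
        return enumerate_and_select(m, m, y, y, candidates=tags, score_fn=score)

    def test_three_candidates_evaluate_seven_subsets(self):
        res = self.run_lookup(("A", "B", "C"), {})
        assert len(res.per_combination_scores) == 7

    def test_argmax_matches_independent_exhaustive_loop(self):
        rng = np.random.default_rng(8)
        for n_cand in (2, 3, 4):
            tags = tuple("ABCD"[:n_cand])
            table = {}
            for r in range(1, n_cand + 1):
                for combo in itertools.combinations(tags, r):
                    table[frozenset(combo)] = float(rng.uniform(0.5, 1.0))
            res = self.run_lookup(tags, table)
            # independent oracle: plain max with the documented tie-break
            best = None
            for r in range(1, n_cand + 1):
                for combo in itertools.combinations(tags, r):
                    key = (-table[frozenset(combo)], len(combo), combo)
                    if best is None or key < best[0]:
                        best = (key, combo)
            assert res.chosen_combination == best[1]
            assert res.val_accuracy == max(res.per_combination_scores.values())
            assert res.per_combination_scores[res.chosen_combination] == res.val_accuracy

    def test_constant_table_picks_first_singleton(self):
        res = self.run_lookup(("B", "A", "C"), {}, default=0.7)
        assert res.chosen_combination == ("A",)

    def test_failed_combination_excluded_with_warning(self):
        tags = ("A", "B")
        m = lookup_matrix(tags)
        y = np.tile([0, 1], 3)

        def score(combo):
            if combo == ("A",):
                raise RuntimeError("boom")
            return 0.7

        with pytest.warns(UserWarning, match="boom"):
            res = enumerate_and_select(m, m, y, y, candidates=tags, score_fn=score)
        assert ("A",) in res.failed_combinations
        assert ("A",) not in res.per_combination_scores

    def test_large_roster_refused_without_override(self):
        tags = tuple(f"c{i}" for i in range(13))
        m = lookup_matrix(tags)
        y = np.tile([0, 1], 3)
        with pytest.raises(ValueError, match="combinations"):
            enumerate_and_select(m, m, y, y, candidates=tags, score_fn=lambda c: 0.5)

    def test_svm_meta_end_to_end(self, small_synth):
        tr, va, _ = split_dataset(small_synth, SplitSpec(seed=2))
        specs = [BaseLearnerSpec("knn", frozenset(small_synth.feature_names[:4])),
                 BaseLearnerSpec("xgboost", frozenset(small_synth.feature_names[:6]),
                                 params={"n_estimators": 15})]
        oof = oof_label_proba(tr, specs, K=4, seed=2)
        vm = holdout_label_proba(tr, va, specs)
        res = enumerate_and_select(oof, vm, tr.y, va.y, meta="svm",
                                   candidates=[s.tag for s in specs])
        assert len(res.per_combination_scores) == 3
        assert res.val_accuracy == max(res.per_combination_scores.values())


@pytest.fixture(scope="module")
def parts(small_synth):
    return split_dataset(small_synth, SplitSpec(seed=6))


class TestSelStackingFitPredict:
    def test_single_candidate_reduces_to_plain_stacking(self, parts):
        tr, va, te = parts
        cfg = FusionConfig(
            candidates=[BaseLearnerSpec("knn", frozenset(tr.feature_names[:5]))],
            K=4, seed=6,
        )
        res = sel_stacking_fit_predict(tr, va, te, cfg)
        assert res.chosen_combination == ("knn",)
        assert 0.0 <= res.test_accuracy <= 1.0

    def test_validation_accuracy_is_argmax(self, parts):
        tr, va, te = parts
        cfg = FusionConfig(
            candidates=[
                BaseLearnerSpec("knn", frozenset(tr.feature_names[:5])),
                BaseLearnerSpec("xgboost", frozenset(tr.feature_names[:8]),
                                params={"n_estimators": 15}),
            ],
            K=4, seed=6,
        )
        res = sel_stacking_fit_predict(tr, va, te, cfg)
        assert all(res.val_accuracy >= v for v in res.per_combination_scores.values())

    def test_test_partition_used_only_after_selection(self, parts, monkeypatch):
        import xgbstack.stacking as stk

        tr, va, te = parts
        events: list[str] = []

        class LoggingDataset(Dataset):
            def columns(self, names):
                events.append("test_access")
                return super().columns(names)

        te_logged = LoggingDataset(list(te.feature_names), te.X, te.y,
                                   list(te.feature_kinds))
        orig = stk.enumerate_and_select

        def wrapped(*a, **kw):
            out = orig(*a, **kw)
            events.append("selection_done")
            return out

        monkeypatch.setattr(stk, "enumerate_and_select", wrapped)
        cfg = FusionConfig(
            candidates=[BaseLearnerSpec("knn", frozenset(tr.feature_names[:4]))],
            K=4, seed=6,
        )
        sel_stacking_fit_predict(tr, va, te_logged, cfg)
        assert "selection_done" in events and "test_access" in events
        assert events.index("selection_done") < events.index("test_access")
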