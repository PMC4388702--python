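"""Two-layered SVM training, cross-validation, and the performance metrics."""

from __future__ import annotations

import math

import numpy as np
import pytest

from sglut.classifier import (
    SVMConfig,
    compute_metrics,
    default_grid,
    five_fold_cv,
    grid_search,
    layered_trainer,
    load_model,
    predict_protein,
    predictions_frame,
    save_model,
    single_svm_trainer,
    train_layered,
    train_svm,
)
from sglut.features import get_encoder
from sglut.mdd import mdd_cluster
from sglut.seq_data import ProteinRecord

from .conftest import TWO_MOTIF_CONFIG, make_fragment


def metrics_oracle(tp, tn, fp, fn):
    """Re-derivation of the four measures from a raw prediction list."""
    y_true = [1] * tp + [1] * fn + [0] * tn + [0] * fp
    y_pred = [1] * tp + [0] * fn + [0] * tn + [1] * fp
    tp_ = sum(t == 1 and p == 1 for t, p in zip(y_true, y_pred))
    tn_ = sum(t == 0 and p == 0 for t, p in zip(y_true, y_pred))
    fp_ = sum(t == 0 and p == 1 for t, p in zip(y_true, y_pred))
    fn_ = sum(t == 1 and p == 0 for t, p in zip(y_true, y_pred))
    sn = tp_ / (tp_ + fn_) if tp_ + fn_ else 0.0
    sp = tn_ / (tn_ + fp_) if tn_ + fp_ else 0.0
    acc = (tp_ + tn_) / len(y_true)
    denom = (tp_ + fn_) * (tn_ + fp_) * (tp_ + fp_) * (tn_ + fn_)
    mcc = ((tp_ * tn_) - (fn_ * fp_)) / math.sqrt(denom) if denom else 0.0
    return sn, sp, acc, mcc


class TestComputeMetrics:
    @pytest.mark.parametrize(
        "tp, tn, fp, fn, sn, sp, acc, mcc",
        [
            (50, 50, 50, 50, 0.5, 0.5, 0.5, 0.0),
            (100, 100, 0, 0, 1.0, 1.0, 1.0, 1.0),
            (65, 66, 34, 35, 0.65, 0.66, 0.655, 0.3100),
        ],
    )
    def test_reference_values(self, tp, tn, fp, fn, sn, sp, acc, mcc):
        m = compute_metrics(tp, tn, fp, fn)
        assert m.sensitivity == pytest.approx(sn)
        assert m.specificity == pytest.approx(sp)
        assert m.accuracy == pytest.approx(acc)
        assert m.mcc == pytest.approx(mcc, abs=5e-4)

    def test_agrees_with_rederivation_on_random_confusions(self, rng):
        for _ in range(200):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 40, size=4))
            if tp + tn + fp + fn == 0:
                continue
            m = compute_metrics(tp, tn, fp, fn)
            sn, sp, acc, mcc = metrics_oracle(tp, tn, fp, fn)
            assert (m.sensitivity, m.specificity, m.accuracy) == pytest.approx(
                (sn, sp, acc)
            )
            assert m.mcc == pytest.approx(mcc, abs=1e-12)
            assert -1.0 <= m.mcc <= 1.0

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(0, 0, 0, 0)


def _blobs(rng, n=60, sep=4.0):
    X = np.vstack([
        rng.normal(0.0, 1.0, size=(n, 5)),
        rng.normal(sep, 1.0, size=(n, 5)),
    ])
    y = np.array([0] * n + [1] * n)
    return X, y


class TestTrainSVM:
    def test_separable_blobs_fit_accurately(self, rng):
        X, y = _blobs(rng)
        clf = train_svm(X, y, SVMConfig(), seed=0)
        assert (clf.predict(X) == y).mean() >= 0.95
        probs = clf.predict_proba(X)[:, 1]
        assert ((probs >= 0) & (probs <= 1)).all()

    def test_label_swap_flips_probabilities(self, rng):
        X, y = _blobs(rng)
        p = train_svm(X, y, SVMConfig(), seed=0).predict_proba(X)[:, 1]
        q = train_svm(X, 1 - y, SVMConfig(), seed=0).predict_proba(X)[:, 1]
        assert np.abs(p - (1 - q)).max() < 0.05

    def test_single_class_is_error(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="both classes"):
            train_svm(X, np.ones(10), SVMConfig(), seed=0)


class TestGridSearch:
    def test_single_point_grid_returns_it(self, rng):
        X, y = _blobs(rng, n=20)
        config = SVMConfig(C=4.0, gamma=0.25)
        assert grid_search(X, y, grid=[config], seed=0) == config

    def test_default_grid_covers_reference_hyperparameters(self):
        pairs = {(c.C, c.gamma) for c in default_grid()}
        assert (0.03125, 0.0078125) in pairs
        assert (32768.0, 0.5) in pairs
        assert (2048.0, 8.0) in pairs

    def test_deterministic(self, rng):
        X, y = _blobs(rng, n=25)
        grid = [SVMConfig(C=2.0 ** e, gamma=0.1) for e in (-2, 0, 2)]
        assert grid_search(X, y, grid=grid, seed=3) == grid_search(
            X, y, grid=grid, seed=3
        )


@pytest.fixture(scope="module")
def small_layered(two_motif_dataset):
    """A trained layered model on a subsample (kept small for speed)."""
    positives = two_motif_dataset.positives[:120]
    negatives = two_motif_dataset.negatives[:120]
    tree = mdd_cluster(positives, max_cluster_size=60)
    encoder = get_encoder("blosum62_aapc")
    model = train_layered(tree, positives, negatives, encoder,
                          seed=0, scheme="blosum62_aapc")
    return model, positives, negatives


class TestLayeredModel:
    def test_meta_dimension_matches_group_count(self, small_layered):
        model, positives, _ = small_layered
        assert model.meta_model.n_features_in_ == model.n_groups
        assert model.n_groups >= 2

    def test_single_leaf_tree_degenerates_to_one_svm(self, two_motif_dataset):
        positives = two_motif_dataset.positives[:60]
        negatives = two_motif_dataset.negatives[:60]
        tree = mdd_cluster(positives, threshold=1e9, max_cluster_size=300)
        assert len(tree.leaves) == 1
        encoder = get_encoder("binary")
        model = train_layered(tree, positives, negatives, encoder, seed=0)
        assert model.n_groups == 1
        probs = model.predict_proba(positives + negatives)
        leaf_probs = model.leaf_probabilities(positives + negatives)[:, 0]
        # meta over a single probability is monotone: calls agree
        assert (((probs > 0.5) == (leaf_probs > 0.5)).mean()) >= 0.9

    def test_retraining_same_seed_reproduces_predictions(self, two_motif_dataset):
        positives = two_motif_dataset.positives[:60]
        negatives = two_motif_dataset.negatives[:60]
        tree = mdd_cluster(positives, max_cluster_size=40)
        encoder = get_encoder("binary")
        p1 = train_layered(tree, positives, negatives, encoder,
                           seed=5).predict_proba(negatives)
        p2 = train_layered(tree, positives, negatives, encoder,
                           seed=5).predict_proba(negatives)
        assert np.array_equal(p1, p2)

    def test_predict_protein_empty_without_cysteines(self, small_layered):
        model, _, _ = small_layered
        assert predict_protein(model, ProteinRecord("Q1", "MKTAYIAK")) == []

    def test_planted_positive_protein_is_called_positive(
        self, small_layered, two_motif_data
    ):
        model, _, _ = small_layered
        protein = two_motif_data.proteins[140]  # outside the training subsample
        predictions = predict_protein(model, protein)
        by_pos = {p.position: p for p in predictions}
        positive_sites = [s.position for s in protein.sites if s.label == "positive"]
        called = [by_pos[pos].probability for pos in positive_sites]
        assert max(called) > 0.5

    def test_motif_path_predicates_hold_for_fragment(self, small_layered):
        model, positives, _ = small_layered
        for pred, frag in zip(model.predict_fragments(positives[:20]), positives[:20]):
            leaf = model.tree.route(frag)
            assert pred.motif_path == leaf.describe_path()
            for pos, group, rel in leaf.path:
                residue = frag.residue_at(pos)
                in_group = (residue != "X"
                            and model.tree.grouping.mapping.get(residue) == group)
                assert in_group == (rel == "has")

    def test_save_load_round_trip(self, small_layered, tmp_path):
        model, positives, negatives = small_layered
        path = tmp_path / "model.joblib"
        save_model(model, path)
        loaded = load_model(path)
        sample = positives[:10] + negatives[:10]
        assert np.array_equal(
            loaded.predict_proba(sample), model.predict_proba(sample)
        )

    def test_predictions_frame_has_contracted_columns(self, small_layered):
        model, positives, _ = small_layered
        frame = predictions_frame(model.predict_fragments(positives[:5]))
        assert list(frame.columns) == [
            "accession", "position", "fragment", "probability",
            "call", "matched_motif", "motif_path",
        ]
        assert (frame["fragment"].str[10] == "C").all()


class TestFiveFoldCV:
    def test_folds_partition_and_stay_balanced(self, two_motif_dataset):
        from sklearn.model_selection import StratifiedKFold

        frags = two_motif_dataset.fragments
        y = np.array([1 if f.label == "positive" else 0 for f in frags])
        splitter = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        seen = []
        for _, test_idx in splitter.split(np.zeros(len(y)), y):
            seen.extend(test_idx)
            per_class = np.bincount(y[test_idx])
            assert abs(per_class[0] - per_class[1]) <= 1
        assert sorted(seen) == list(range(len(y)))

    def test_pooled_counts_cover_every_sample_once(self, two_motif_dataset):
        sub = two_motif_dataset
        from sglut.dataset_prep import BalancedDataset

        dataset = BalancedDataset(sub.positives[:50], sub.negatives[:50], seed=0)
        encoder = get_encoder("binary")
        pooled, per_fold = five_fold_cv(
            dataset, single_svm_trainer(encoder), seed=0
        )
        assert pooled.TP + pooled.TN + pooled.FP + pooled.FN == 100
        assert len(per_fold) == 5
        assert sum(m.TP + m.TN + m.FP + m.FN for m in per_fold) == 100

    def test_too_few_samples_per_class_rejected(self, rng):
        from sglut.dataset_prep import BalancedDataset

        pos = [make_fragment("A" * 10 + "C" + "A" * 10, label="positive")] * 3
        neg = [make_fragment("K" * 10 + "C" + "K" * 10, label="negative")] * 3
        with pytest.raises(ValueError, match="at least"):
            five_fold_cv(BalancedDataset(pos, neg, seed=0),
                         single_svm_trainer(get_encoder("binary")), seed=0)
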