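"""Metrics, training determinism, CV/holdout protocols, grid search."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from epitopenet.model import ModelConfig
from epitopenet.seqio import encode_batch
from epitopenet.synth import SynthSpec, generate
from epitopenet.traineval import (
    ConfusionCounts,
    MetricsReport,
    TrainingError,
    compute_metrics,
    confusion_from_predictions,
    evaluate,
    export_activations,
    holdout_eval,
    kfold_cv,
    scale_search,
    stratified_folds,
    train,
    _split_records,
)


def brute_force_metrics(tp, tn, fp, fn):
    """Independent, literal evaluation of the four confusion-matrix indices."""
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / (tp + tn + fp + fn)
    den = math.sqrt((tp + fn) * (tn + fn) * (tp + fp) * (tn + fp))
    mcc = (tp * tn - fp * fn) / den if den else 0.0
    return sn, sp, acc, mcc


class TestComputeMetrics:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((50, 50, 0, 0), (1.0, 1.0, 1.0, 1.0)),       # perfect prediction
            ((0, 0, 50, 50), (0.0, 0.0, 0.0, -1.0)),      # inverse prediction
            ((40, 30, 20, 10), (0.80, 0.60, 0.70, 0.4082482904638630)),
        ],
    )
    def test_reference_confusion_tables(self, counts, expected):
        tp, tn, fp, fn = counts
        m = compute_metrics(ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn))
        assert np.allclose([m.Sn, m.Sp, m.ACC, m.MCC], expected, atol=1e-9)

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(1000):
            tp, tn, fp, fn = rng.integers(0, 200, size=4)
            if tp + tn + fp + fn == 0:
                continue
            m = compute_metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            expected = brute_force_metrics(tp, tn, fp, fn)
            assert np.allclose([m.Sn, m.Sp, m.ACC, m.MCC], expected, atol=1e-9)
            assert -1 <= m.MCC <= 1 and 0 <= m.ACC <= 1
            assert 0 <= m.Sn <= 1 and 0 <= m.Sp <= 1

    def test_degenerate_denominators_flagged_not_raised(self):
        m = compute_metrics(ConfusionCounts(TP=10, TN=0, FP=0, FN=0))
        assert m.Sp == 0.0 and "Sp" in m.degenerate and "MCC" in m.degenerate
        assert m.Sn == 1.0 and m.ACC == 1.0

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(TP=-1, TN=0, FP=0, FN=1)

    def test_mcc_near_zero_for_label_independent_predictions(self, rng):
        """Shuffling labels against fixed predictions should average MCC ~ 0."""
        n = 500
        preds = rng.random(n)
        labels = (rng.random(n) > 0.5).astype(int)
        mccs = []
        for _ in range(100):
            shuffled = rng.permutation(labels)
            m = compute_metrics(confusion_from_predictions(shuffled, preds))
            mccs.append(m.MCC)
        assert np.mean(np.abs(mccs)) < 0.1

    def test_threshold_tie_counts_as_positive_call(self):
        c = confusion_from_predictions(np.array([1, 0]), np.array([0.5, 0.5]), 0.5)
        assert (c.TP, c.FP, c.TN, c.FN) == (1, 1, 0, 0)


class TestTrain:
    def test_two_runs_same_seed_are_identical(self, tiny_config, small_batch):
        batch, labels = small_batch
        net1, hist1 = train(tiny_config, batch, labels)
        net2, hist2 = train(tiny_config, batch, labels)
        assert all((a == b).all() for a, b in zip(net1.get_weights(), net2.get_weights()))
        assert [h["train_loss"] for h in hist1] == [h["train_loss"] for h in hist2]

    def test_training_reduces_loss_on_planted_motif_data(self, small_batch):
        batch, labels = small_batch
        config = ModelConfig(embed_dim=16, lstm_units=16, cnn_filters=16,
                             dense_sizes=(16, 4, 1), seed=3, epochs=5,
                             batch_size=16)
        _, hist = train(config, batch, labels)
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]

    def test_validation_history_has_metrics_per_epoch(self, tiny_config, small_batch):
        batch, labels = small_batch
        _, hist = train(tiny_config, batch, labels, batch, labels)
        assert all(isinstance(h["valid_metrics"], MetricsReport) for h in hist)
        assert all("valid_loss" in h for h in hist)

    def test_single_class_labels_rejected(self, tiny_config, small_batch):
        batch, _ = small_batch
        with pytest.raises(TrainingError):
            train(tiny_config, batch, np.ones(batch.n, dtype=int))


class TestHoldout:
    def test_stratified_80_20_arithmetic(self):
        records = generate(SynthSpec(n_pos=50, n_neg=50, seed=0))
        train_recs, test_recs = _split_records(records, 0.8, seed=0)
        assert len(test_recs) == 20
        assert sum(r.label for r in test_recs) == 10

    def test_half_split_on_ten_samples(self):
        records = generate(SynthSpec(n_pos=5, n_neg=5, seed=0))
        train_recs, test_recs = _split_records(records, 0.5, seed=0)
        assert len(train_recs) == len(test_recs) == 5

    def test_same_seed_same_metrics(self, tiny_config):
        records = generate(SynthSpec(n_pos=20, n_neg=20, seed=4))
        m1 = holdout_eval(records, tiny_config)
        m2 = holdout_eval(records, tiny_config)
        assert m1 == m2

    def test_single_class_rejected(self, tiny_config):
        records = generate(SynthSpec(n_pos=20, n_neg=0, seed=4))
        with pytest.raises(TrainingError):
            holdout_eval(records, tiny_config)


class TestKFold:
    @pytest.mark.parametrize("n_pos,n_neg", [(10, 10), (27, 28), (555, 555)])
    def test_partition_disjoint_covering_stratified(self, n_pos, n_neg):
        # n in {20, 55, 1110}, k=10
        records = generate(SynthSpec(n_pos=n_pos, n_neg=n_neg, seed=1))
        folds = stratified_folds(records, k=10, seed=1)
        n = len(records)
        all_test = np.concatenate([test for _, test in folds])
        assert len(all_test) == n and len(set(all_test.tolist())) == n
        sizes = [len(test) for _, test in folds]
        assert max(sizes) - min(sizes) <= 1  # near-equal fold sizes
        labels = np.array([r.label for r in records])
        for train_idx, test_idx in folds:
            assert set(train_idx.tolist()).isdisjoint(test_idx.tolist())
            pos = labels[test_idx].sum()
            expected_pos = n_pos * len(test_idx) / n
            assert abs(pos - expected_pos) <= 1  # stratified

    def test_ten_fold_cv_report_invariants(self, tiny_config):
        records = generate(SynthSpec(n_pos=10, n_neg=10, seed=3))
        report = kfold_cv(records, tiny_config, k=10)
        assert report.k == 10
        assert len(report.fold_metrics) == 10
        # every sample tested exactly once, fold sizes of 2
        assert sorted(report.fold_assignment) == sorted(r.id for r in records)
        fold_sizes = pd.Series(list(report.fold_assignment.values())).value_counts()
        assert (fold_sizes == 2).all()
        # mean row is the arithmetic mean of the fold rows
        for col in ("Sn", "Sp", "ACC", "MCC"):
            mean = np.mean([getattr(m, col) for m in report.fold_metrics])
            assert abs(getattr(report.mean_metrics, col) - mean) < 1e-9
        frame = report.to_frame()
        assert len(frame) == 11 and frame.iloc[-1]["fold"] == "Mean"

    def test_k_below_two_rejected(self, tiny_config, small_dataset):
        with pytest.raises(ValueError):
            kfold_cv(small_dataset, tiny_config, k=1)


class TestScaleSearch:
    def test_full_candidate_grid_has_ten_triples(self, tiny_config):
        records = generate(SynthSpec(n_pos=20, n_neg=20, seed=5))
        config = replace(tiny_config, cnn_scales=(7, 9, 11, 13, 15),
                         active_scales=None, epochs=1)
        table, best = scale_search(records, config, (7, 9, 11, 13, 15))
        assert len(table) == 10
        best_row = table[(table.scale1 == best[0]) & (table.scale2 == best[1])
                         & (table.scale3 == best[2])].iloc[0]
        assert (best_row.ACC >= table.ACC - 1e-12).all()

    def test_three_candidates_single_combination(self, tiny_config):
        records = generate(SynthSpec(n_pos=20, n_neg=20, seed=5))
        config = replace(tiny_config, cnn_scales=(7, 9, 11, 13, 15),
                         active_scales=None, epochs=1)
        table, best = scale_search(records, config, (7, 9, 11))
        assert len(table) == 1 and best == (7, 9, 11)

    def test_too_few_candidates_rejected(self, tiny_config, small_dataset):
        with pytest.raises(ValueError):
            scale_search(small_dataset, tiny_config, (7, 9))


class TestExportActivations:
    def test_matrix_file_and_seeded_tsne(self, tiny_config, tmp_path):
        from epitopenet.model import EpitopeClassifier

        records = generate(SynthSpec(n_pos=25, n_neg=25, seed=6))
        batch, labels = encode_batch(records, tiny_config.L)
        net = EpitopeClassifier(tiny_config)
        out = tmp_path / "act.tsv"
        frame1 = export_activations(net, batch, "combined", out,
                                    tsne=True, labels=labels, seed=9)
        assert len(pd.read_csv(out, sep="\t")) == 50
        assert {"x", "y"} <= set(frame1.columns)
        frame2 = export_activations(net, batch, "combined", tmp_path / "b.tsv",
                                    tsne=True, labels=labels, seed=9)
        assert np.allclose(frame1[["x", "y"]], frame2[["x", "y"]])
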