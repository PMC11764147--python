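import numpy as np
import pytest
from sklearn.metrics import confusion_matrix, matthews_corrcoef, roc_auc_score

from dgil6.evaluation import (
    TrainConfig,
    ablation_run,
    apply_toggles,
    auc,
    compute_metrics,
    cross_validate,
    export_fused_features,
    grid_search,
    round_half_away,
    train,
)
from dgil6.nn import init_params


class TestComputeMetrics:
    def test_perfect_separation(self):
        report = compute_metrics([0.9, 0.95, 0.1, 0.2], [1, 1, 0, 0], 0.35)
        assert report.sn == report.sp == report.bacc == report.mcc == report.auc == 1.0

    def test_mcc_example(self):
        # TP=3, FP=1, TN=5, FN=1 -> MCC = 14/24
        scores = [0.9] * 3 + [0.1] + [0.9] + [0.1] * 5
        labels = [1] * 3 + [1] + [0] + [0] * 5
        report = compute_metrics(scores, labels, 0.35)
        assert (report.counts.tp, report.counts.fp, report.counts.tn, report.counts.fn) == (3, 1, 5, 1)
        assert report.mcc == pytest.approx(14 / 24)
        assert round_half_away(report.mcc) == 0.583

    def test_strict_threshold_boundary(self):
        report = compute_metrics([0.35], [1], 0.35)
        assert report.counts.fn == 1  # exactly at threshold is negative

    def test_bacc_identity_holds_exactly(self, rng):
        for _ in range(20):
            scores = rng.random(40)
            labels = (rng.random(40) > 0.6).astype(int)
            if labels.sum() in (0, 40):
                continue
            report = compute_metrics(scores, labels, 0.35)
            assert report.bacc == (report.sn + report.sp) / 2

    def test_matches_sklearn_confusion_and_mcc(self, rng):
        scores = rng.random(200)
        labels = (rng.random(200) > 0.5).astype(int)
        report = compute_metrics(scores, labels, 0.35)
        pred = (scores > 0.35).astype(int)
        tn, fp, fn, tp = confusion_matrix(labels, pred).ravel()
        assert (report.counts.tp, report.counts.fp, report.counts.tn, report.counts.fn) == (tp, fp, tn, fn)
        assert report.mcc == pytest.approx(matthews_corrcoef(labels, pred), abs=1e-12)

    def test_degenerate_mcc_is_zero(self):
        report = compute_metrics([0.9, 0.8], [1, 1], 0.35)  # single class
        assert report.mcc == 0.0 and np.isnan(report.auc)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([], [], 0.35)

    def test_counts_total_matches_sample_size(self, rng):
        scores, labels = rng.random(33), (rng.random(33) > 0.3).astype(int)
        assert compute_metrics(scores, labels).counts.total == 33


class TestAuc:
    def test_perfect_ranking(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_matches_sklearn(self, rng):
        scores = rng.random(100).round(1)  # coarse scores force ties
        labels = (rng.random(100) > 0.5).astype(int)
        assert auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.9], [1, 1])


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected", [(0.8375, 0.838), (0.7715, 0.772), (0.8165, 0.817), (-0.0005, -0.001)]
    )
    def test_half_away_from_zero(self, value, expected):
        assert round_half_away(value) == expected


class TestTrainConfig:
    def test_zero_epochs_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)

    def test_learning_rate_schedule_closed_form(self):
        est = TrainConfig().make_estimator()
        assert est.learning_rate_at(10) == pytest.approx(0.001 * 0.95**2)
        assert est.learning_rate_at(0) == 0.001
        assert est.learning_rate_at(4) == 0.001


def test_train_is_reproducible_for_fixed_seed(small_dataset):
    manifest, graphs = small_dataset
    subset, labels_manifest = graphs[:16], None
    config = TrainConfig(epochs=3, seed=42, batch_size=8)
    p1 = train(None, subset, config)
    p2 = train(None, subset, config)
    for key, arr in p1.state_dict().items():
        np.testing.assert_array_equal(arr, p2.state_dict()[key])


class TestCrossValidate:
    def test_partition_properties(self, small_dataset):
        manifest, graphs = small_dataset
        n = 50
        config = TrainConfig(epochs=1, seed=0)
        result = cross_validate(None, graphs[:n], k=5, config=config)
        assert len(result.fold_reports) == 5
        sizes = [r.counts.total for r in result.fold_reports]
        assert sum(sizes) == n and all(s == 10 for s in sizes)
        # stratification: fold positive counts within 1 of the global rate
        labels = np.array([g.label for g in graphs[:n]])
        global_rate = labels.mean()
        for report in result.fold_reports:
            fold_pos = report.counts.tp + report.counts.fn
            assert abs(fold_pos - global_rate * 10) <= 1
        assert result.mean.bacc == (result.mean.sn + result.mean.sp) / 2


class TestGridSearch:
    def test_single_candidate_returned(self, small_dataset):
        _, graphs = small_dataset
        config = TrainConfig(epochs=1, seed=0)
        best, best_auc, history = grid_search(
            None, graphs[:30], {"heads": [4]}, config=config, k=2
        )
        assert best == {"heads": 4} and len(history) == 1

    def test_dominant_candidate_wins(self, small_dataset):
        """A learning rate too small to leave initialisation must lose."""
        _, graphs = small_dataset
        config = TrainConfig(epochs=6, seed=1)
        best, best_auc, history = grid_search(
            None, graphs, [{"lr": 1e-12}, {"lr": 1e-3}], config=config, k=2
        )
        aucs = dict((tuple(s.items()), a) for s, a in history)
        assert best == {"lr": 1e-3}
        assert aucs[(("lr", 1e-3),)] > aucs[(("lr", 1e-12),)]

    def test_tie_breaks_to_first_candidate(self, small_dataset):
        _, graphs = small_dataset
        config = TrainConfig(epochs=2, seed=0)
        # decay_every beyond the horizon is behaviourally identical
        best, _, history = grid_search(
            None, graphs[:24], [{"decay_every": 99}, {"decay_every": 500}],
            config=config, k=2,
        )
        assert history[0][1] == history[1][1]
        assert best == {"decay_every": 99}

    def test_empty_grid_rejected(self, small_dataset):
        _, graphs = small_dataset
        with pytest.raises(ValueError):
            grid_search(None, graphs[:10], [], config=TrainConfig(epochs=1))


class TestAblation:
    def test_feature_toggles_shrink_width(self, small_dataset):
        _, graphs = small_dataset
        base_width = graphs[0].features.width
        dropped, overrides = apply_toggles(graphs[:4], {"no_onehot"})
        assert dropped[0].features.width == base_width - 20 and overrides == {}

    def test_channel_toggle_sets_override(self, small_dataset):
        _, graphs = small_dataset
        _, overrides = apply_toggles(graphs[:4], {"no_gat"})
        assert overrides == {"use_gat": False}

    def test_both_channels_disabled_rejected(self, small_dataset):
        _, graphs = small_dataset
        with pytest.raises(ValueError, match="both"):
            apply_toggles(graphs[:4], {"no_gat", "no_gcn"})

    def test_unknown_toggle_rejected(self, small_dataset):
        _, graphs = small_dataset
        with pytest.raises(ValueError, match="unknown"):
            apply_toggles(graphs[:4], {"no_everything"})

    def test_table_has_one_row_per_toggle_plus_full(self, small_dataset):
        _, graphs = small_dataset
        config = TrainConfig(epochs=1, seed=0)
        table = ablation_run(None, graphs[:40], ["no_gcn", "no_position"], config)
        assert set(table) == {"full", "no_gcn", "no_position"}
        assert all(r.counts.total == 8 for r in table.values())


class TestExportFusedFeatures:
    def test_shape_normalisation_and_provenance(self, small_dataset):
        _, graphs = small_dataset
        params = init_params(0, in_dim=graphs[0].features.width)
        matrix, provenance = export_fused_features(params, graphs[:12])
        assert matrix.shape == (12, 128)
        assert provenance[:64] == ["GAT"] * 64 and provenance[64:] == ["GCN"] * 64
        assert np.nanmin(matrix) >= 0.0 and np.nanmax(matrix) <= 1.0

    def test_constant_column_normalises_to_zero(self, small_dataset):
        _, graphs = small_dataset
        params = init_params(0, in_dim=graphs[0].features.width)
        # a single peptide makes every column constant
        matrix, _ = export_fused_features(params, graphs[:1])
        np.testing.assert_array_equal(matrix, 0.0)

    def test_single_channel_provenance(self, small_dataset):
        _, graphs = small_dataset
        params = init_params(0, in_dim=graphs[0].features.width, use_gat=False)
        matrix, provenance = export_fused_features(params, graphs[:3])
        assert matrix.shape == (3, 64) and provenance == ["GCN"] * 64
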