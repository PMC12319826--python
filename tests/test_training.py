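import math

import numpy as np
import pytest

from soundbrain.backbone import BackboneConfig, build_backbone, forward_features
from soundbrain.data import window_run
from soundbrain.encoding import EncodingModel, build_head
from soundbrain.training import (TrainConfig, evaluate_runs, grid_search,
                                 group_hyperparams, train_group_model,
                                 train_model)


def windows_of(dataset, w):
    runs = dataset.runs_for("sub-01")
    tw = [win for wav, b in runs[:3] for win in window_run(b, wav, w)]
    vw = [win for wav, b in runs[3:] for win in window_run(b, wav, w)]
    return tw, vw, runs


def fresh_model(dataset, k, depth="none", seed=2):
    cfg = BackboneConfig(fine_tune_depth=depth)
    net = build_backbone(cfg, weights=dataset.backbone.state_dict())
    head = build_head(1024, dataset.spec.n_targets, k, seed=seed)
    head.kernels.data[...] = 0.0
    return EncodingModel(net, head)


class TestTrainModel:
    def test_loss_drops_below_ten_percent_on_noiseless_data(self, tiny_noiseless):
        tw, vw, _ = windows_of(tiny_noiseless, 20)
        model = fresh_model(tiny_noiseless, tiny_noiseless.spec.kernel_size)
        cfg = TrainConfig(window_tr=20, kernel_size=2, learning_rate=3e-3,
                          weight_decay=1e-6, adam_eps=1e-2, max_epochs=50,
                          patience=50, delta=0.0, batch_size=3, seed=0)
        _, hist = train_model(model, tw, vw, cfg)
        assert hist.train_loss[-1] < 0.1 * hist.train_loss[0]

    def test_noiseless_recovery_reaches_high_r2(self, tiny_noiseless):
        tw, vw, runs = windows_of(tiny_noiseless, 20)
        model = fresh_model(tiny_noiseless, tiny_noiseless.spec.kernel_size)
        cfg = TrainConfig(window_tr=20, kernel_size=2, learning_rate=3e-3,
                          weight_decay=1e-5, adam_eps=1e-2, max_epochs=400,
                          patience=100, delta=1e-8, batch_size=3, seed=0)
        model, _ = train_model(model, tw, vw, cfg)
        r2 = evaluate_runs(model, runs[3:], 20)
        # desk-size fixture (60 training frames): generalisation is capped
        # well below the full-scale recovery protocol's level
        assert r2.min() > 0.65

    def test_patience_one_infinite_delta_stops_after_one_epoch(self, tiny_dataset):
        tw, vw, _ = windows_of(tiny_dataset, 20)
        model = fresh_model(tiny_dataset, 2)
        cfg = TrainConfig(window_tr=20, kernel_size=2, max_epochs=50,
                          patience=1, delta=math.inf, seed=0)
        _, hist = train_model(model, tw, vw, cfg)
        assert hist.stop_epoch == 1
        assert hist.stop_reason == "early_stop"

    def test_same_seed_identical_history(self, tiny_dataset):
        tw, vw, _ = windows_of(tiny_dataset, 20)
        hists = []
        for _ in range(2):
            model = fresh_model(tiny_dataset, 2)
            cfg = TrainConfig(window_tr=20, kernel_size=2, max_epochs=5,
                              patience=10, seed=7)
            _, hist = train_model(model, tw, vw, cfg)
            hists.append(hist)
        assert hists[0].train_loss == hists[1].train_loss
        assert hists[0].val_loss == hists[1].val_loss

    def test_frozen_backbone_unchanged_by_training(self, tiny_dataset, short_clip):
        tw, vw, _ = windows_of(tiny_dataset, 20)
        model = fresh_model(tiny_dataset, 2, depth="none")
        before = forward_features(model.backbone, short_clip).values.copy()
        cfg = TrainConfig(window_tr=20, kernel_size=2, max_epochs=3,
                          patience=10, seed=0)
        model, _ = train_model(model, tw, vw, cfg)
        after = forward_features(model.backbone, short_clip).values
        np.testing.assert_array_equal(before, after)

    def test_weight_decay_shrinks_kernel_norm(self, tiny_dataset):
        tw, vw, _ = windows_of(tiny_dataset, 20)
        norms = {}
        for wd in (0.0, 1.0):
            model = fresh_model(tiny_dataset, 2)
            model.head.kernels.data[...] = 0.01  # same nonzero start
            cfg = TrainConfig(window_tr=20, kernel_size=2, max_epochs=10,
                              patience=20, weight_decay=wd, seed=0)
            model, _ = train_model(model, tw, vw, cfg)
            norms[wd] = float(np.linalg.norm(model.head.kernels.data))
        assert norms[1.0] < norms[0.0]

    def test_empty_training_set_rejected(self, tiny_dataset):
        model = fresh_model(tiny_dataset, 2)
        with pytest.raises(ValueError, match="empty"):
            train_model(model, [], [], TrainConfig(window_tr=20,
                                                   kernel_size=2))

    def test_shuffled_pairs_score_worse_than_aligned(self, tiny_noiseless):
        tw, vw, runs = windows_of(tiny_noiseless, 20)
        shuffled = [(tw[(i + 1) % len(tw)][0], tw[i][1])
                    for i in range(len(tw))]
        scores = {}
        for name, wins in (("aligned", tw), ("shuffled", shuffled)):
            model = fresh_model(tiny_noiseless, 2)
            cfg = TrainConfig(window_tr=20, kernel_size=2, learning_rate=3e-3,
                              adam_eps=1e-2, max_epochs=100, patience=100,
                              delta=0.0, batch_size=3, seed=0)
            model, _ = train_model(model, wins, vw, cfg)
            scores[name] = np.median(evaluate_runs(model, runs[3:], 20))
        assert scores["aligned"] > scores["shuffled"]


class TestGridSearch:
    def _factory(self, dataset):
        return lambda cfg: fresh_model(dataset, cfg.kernel_size)

    def test_singleton_grid_returns_that_config(self, tiny_dataset):
        runs = tiny_dataset.runs_for("sub-01")
        cfg = TrainConfig(window_tr=20, kernel_size=2, max_epochs=3,
                          patience=5, seed=0)
        best, table = grid_search(self._factory(tiny_dataset),
                                  runs[:3], runs[3:], [cfg])
        assert best is cfg
        assert len(table) == 1

    def test_table_has_one_row_per_grid_point(self, tiny_dataset):
        runs = tiny_dataset.runs_for("sub-01")
        grid = [TrainConfig(window_tr=20, kernel_size=k, max_epochs=2,
                            patience=5, seed=0) for k in (1, 2)]
        best, table = grid_search(self._factory(tiny_dataset),
                                  runs[:3], runs[3:], grid)
        assert len(table) == 2
        assert best.kernel_size in (1, 2)
        assert table["val_r2_summary"].max() == pytest.approx(
            table.loc[table.kernel_size == best.kernel_size,
                      "val_r2_summary"].iloc[0])

    def test_empty_grid_rejected(self, tiny_dataset):
        runs = tiny_dataset.runs_for("sub-01")
        with pytest.raises(ValueError, match="empty grid"):
            grid_search(self._factory(tiny_dataset), runs[:3], runs[3:], [])


class TestGroupHyperparams:
    def _cfgs(self, windows, kernels):
        return [TrainConfig(window_tr=w, kernel_size=k)
                for w, k in zip(windows, kernels)]

    def test_median_of_five(self):
        cfgs = self._cfgs([50, 70, 70, 90, 100], [3, 5, 5, 7, 9])
        merged = group_hyperparams(cfgs)
        assert merged.window_tr == 70
        assert merged.kernel_size == 5

    def test_identical_configs_pass_through(self):
        cfgs = [TrainConfig(window_tr=30, kernel_size=3)] * 5
        assert group_hyperparams(cfgs) == cfgs[0]

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError, match="5"):
            group_hyperparams([TrainConfig()] * 4)


class TestGroupModel:
    def test_target_absent_rejected(self, tiny_dataset):
        runs = {"sub-01": tiny_dataset.runs_for("sub-01")}
        with pytest.raises(ValueError, match="not in manifest"):
            train_group_model("sub-09", runs, TrainConfig(),
                              lambda c: fresh_model(tiny_dataset, c.kernel_size))

    def test_needs_two_subjects(self, tiny_dataset):
        runs = {"sub-01": tiny_dataset.runs_for("sub-01")}
        with pytest.raises(ValueError, match="2 subjects"):
            train_group_model("sub-01", runs, TrainConfig(),
                              lambda c: fresh_model(tiny_dataset, c.kernel_size))
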