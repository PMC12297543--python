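"""Model configs, training protocol, inference contracts and persistence."""

import dataclasses

import numpy as np
import pytest

import ctfree_gfr as cg
from ctfree_gfr import models
from ctfree_gfr.models import (NetworkConfig, TrainConfig, build_network,
                               load_model, predict_labels, predict_mumap,
                               save_model, split_indices, train)
from ctfree_gfr.preprocess import NormalizationSpec
from ctfree_gfr.volume import Volume3D


def _tiny_seg_dataset(rng, n=4, shape=(8, 8, 8), n_classes=3):
    data = []
    for _ in range(n):
        x = rng.random((1, *shape)).astype(np.float32)
        lab = rng.integers(0, n_classes, size=shape)
        data.append((x, lab))
    return data


def _tiny_net(n_classes=3):
    cfg = NetworkConfig.for_segmentation(n_classes=n_classes, initial_neurons=2,
                                         depth=1)
    return cfg, build_network(cfg, seed=0)


class TestConfigs:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(task="diffusion")
        with pytest.raises(ValueError):
            NetworkConfig.for_segmentation(n_classes=4)
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0)
        with pytest.raises(ValueError):
            TrainConfig(epochs=5, early_stopping_patience=10)
        with pytest.raises(ValueError):
            TrainConfig(loss="hinge")

    def test_unimplemented_variants_flagged(self):
        with pytest.raises(NotImplementedError):
            NetworkConfig(norm_layer="batch")
        with pytest.raises(NotImplementedError):
            NetworkConfig(upsampling="transposed_conv")

    def test_paper_scale_profile(self):
        cfg = NetworkConfig.paper_scale()
        assert cfg.initial_neurons == 64 and cfg.depth == 4

    def test_split_is_8_1_1(self):
        tr, va, te = split_indices(50, seed=3)
        assert (len(tr), len(va), len(te)) == (40, 5, 5)
        assert sorted(tr + va + te) == list(range(50))


class TestTraining:
    def test_smoke_history_and_finite_losses(self, rng):
        cfg, net = _tiny_net()
        data = _tiny_seg_dataset(rng, n=4)
        tcfg = TrainConfig.desk(epochs=3, batch_size=2, seed=0, loss="GDSC")
        model = train(net, data, tcfg, network_config=cfg)
        assert len(model.history["train_loss"]) == 3
        assert np.isfinite(model.history["val_loss"]).all()

    def test_seeding_contract_identical_first_epoch(self, rng):
        data = _tiny_seg_dataset(rng, n=4)
        losses = []
        for _ in range(2):
            cfg, net = _tiny_net()
            tcfg = TrainConfig.desk(epochs=1, batch_size=2, seed=7, loss="CCE")
            model = train(net, data, tcfg, network_config=cfg)
            losses.append(model.history["train_loss"][0])
        assert losses[0] == losses[1]

    def test_empty_dataset_rejected(self):
        cfg, net = _tiny_net()
        with pytest.raises(ValueError):
            train(net, [], TrainConfig.desk(epochs=1), network_config=cfg)

    def test_two_class_training_runs(self, rng):
        cfg, net = _tiny_net(n_classes=2)
        data = _tiny_seg_dataset(rng, n=4, n_classes=2)
        model = train(net, data, TrainConfig.desk(epochs=1, batch_size=2, loss="GDSC"),
                      network_config=cfg)
        assert len(model.history["train_loss"]) == 1

    def test_segmentation_with_regression_loss_rejected(self, rng):
        cfg, net = _tiny_net()
        data = _tiny_seg_dataset(rng, n=4)
        with pytest.raises(ValueError):
            train(net, data, TrainConfig.desk(epochs=1, loss="MAE"),
                  network_config=cfg)


class TestInference:
    def _trained_stub(self, n_classes=3):
        cfg, net = _tiny_net(n_classes)
        return models.TrainedModel(
            network=net, network_config=cfg, train_config=TrainConfig.desk(epochs=1),
            normalization=NormalizationSpec("windowing_maximum", 0.5),
            history={}, best_epoch=0,
        )

    def test_predict_labels_shapes_and_probability_sum(self):
        model = self._trained_stub()
        mu = Volume3D(np.random.default_rng(0).random((8, 8, 8)) * 0.3)
        pm, lab = predict_labels(model, mu)
        assert pm.data.shape == (3, 8, 8, 8)
        assert np.allclose(pm.data.sum(axis=0), 1.0, atol=1e-5)
        assert lab.shape == mu.shape
        assert set(lab.present_classes()) <= {0, 1, 2}

    def test_normalization_mismatch_rejected(self):
        model = self._trained_stub()
        mu = Volume3D(np.ones((8, 8, 8)))
        with pytest.raises(ValueError, match="normalization"):
            predict_labels(model, mu, NormalizationSpec("maximum"))

    def test_argmax_of_one_hot_probabilities(self):
        pm = models.ProbabilityMap(
            np.moveaxis(np.eye(3)[np.random.default_rng(1).integers(0, 3, (4, 4, 4))],
                        -1, 0),
            (3.45,) * 3,
        )
        lab = pm.argmax_labels()
        assert np.array_equal(np.eye(3)[lab.data].transpose(3, 0, 1, 2), pm.data)

    def test_all_background_probabilities_give_empty_labels(self):
        p = np.zeros((3, 4, 4, 4))
        p[0] = 1.0
        lab = models.ProbabilityMap(p, (3.45,) * 3).argmax_labels()
        assert lab.present_classes() == [0]

    def test_mumap_prediction_robust_to_zero_counts(self):
        cfg = NetworkConfig.for_mumap(initial_neurons=2, depth=1)
        model = models.TrainedModel(
            network=build_network(cfg, seed=0), network_config=cfg,
            train_config=TrainConfig.desk(epochs=1),
            normalization=NormalizationSpec("log_maximum"),
            history={}, best_epoch=0,
        )
        zeros = Volume3D(np.zeros((8, 8, 8)))
        out = predict_mumap(model, zeros, zeros)
        assert out.shape == zeros.shape
        assert np.isfinite(out.data).all()
        assert out.data.min() >= 0

    def test_mumap_grid_mismatch_rejected(self):
        cfg = NetworkConfig.for_mumap(initial_neurons=2, depth=1)
        model = models.TrainedModel(
            network=build_network(cfg, seed=0), network_config=cfg,
            train_config=TrainConfig.desk(epochs=1),
            normalization=NormalizationSpec("log_maximum"),
            history={}, best_epoch=0,
        )
        with pytest.raises(ValueError):
            predict_mumap(model, Volume3D(np.zeros((8, 8, 8))),
                          Volume3D(np.zeros((4, 8, 8))))


def test_model_save_load_roundtrip(tmp_path, rng):
    cfg, net = _tiny_net()
    data = _tiny_seg_dataset(rng, n=4)
    model = train(net, data, TrainConfig.desk(epochs=1, batch_size=2, loss="GDSC"),
                  normalization=NormalizationSpec("windowing_maximum", 0.5),
                  network_config=cfg)
    mu = Volume3D(np.random.default_rng(3).random((8, 8, 8)) * 0.3)
    _, lab_before = predict_labels(model, mu)
    path = save_model(model, tmp_path / "seg.npz")
    loaded = load_model(path)
    _, lab_after = predict_labels(loaded, mu)
    assert np.array_equal(lab_before.data, lab_after.data)
    assert loaded.normalization == model.normalization


def test_flip_equivariance_of_trained_segmenter(trained_segmenter, eval_cases):
    """Predicting on a left-right mirrored attenuation map, then mirroring
    back and swapping the kidney classes, should largely agree with the direct
    prediction — the augmentation convention is anatomically consistent."""
    case = eval_cases[0]
    _, direct = predict_labels(trained_segmenter, case.mu_map)
    flipped_mu = case.mu_map.with_data(case.mu_map.data[:, :, ::-1].copy())
    _, flipped = predict_labels(trained_segmenter, flipped_mu)
    unflipped = flipped.data[:, :, ::-1].copy()
    swapped = unflipped.copy()
    swapped[unflipped == 1] = 2
    swapped[unflipped == 2] = 1
    agreement = cg.dsc(cg.LabelMap(swapped, case.labels.spacing_mm), direct, "total")
    assert agreement > 0.5
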