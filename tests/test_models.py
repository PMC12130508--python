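"""Architecture conformance, output contracts, and training-harness behavior."""

import numpy as np
import pytest

from airsig.errors import ConfigError, TrainingError
from airsig.models import (
    ARCHITECTURES,
    MCDCNNNet,
    ModelSpec,
    TrainConfig,
    build_model,
    plan_model_selection,
    predict_proba,
    run_model_selection,
    small_params,
    train_model,
)
from airsig.nn import Dense
from airsig.synthetic import GeneratorConfig, generate_dataset


@pytest.mark.parametrize("arch", ARCHITECTURES)
def test_probabilities_sum_to_one(arch):
    spec = ModelSpec(arch, 128, 9, 5, params=small_params(arch))
    net = build_model(spec, seed=0)
    x = np.random.default_rng(0).normal(size=(3, 128, 9))
    proba = predict_proba(net, x)
    assert proba.shape == (3, 5)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
    assert (proba >= 0).all()


class TestArchitectureAudits:
    def test_mlp_hidden_widths_are_732(self):
        net = build_model(ModelSpec("MLP", 100, 9, 5), seed=0)
        dense = [m for m in net.modules if isinstance(m, Dense)]
        assert [d.w.value.shape for d in dense] == [
            (900, 732), (732, 732), (732, 732), (732, 5)]

    def test_mcdcnn_has_one_branch_per_channel(self):
        net = build_model(ModelSpec("MCDCNN", 64, 9, 5), seed=0)
        assert isinstance(net, MCDCNNNet)
        assert len(net.branches) == 9
        assert net.hidden.w.value.shape[1] == 732

    def test_inception_module_has_five_conv_and_one_pool_branch(self):
        net = build_model(ModelSpec("InceptionTime", 128, 9, 5), seed=0)
        for block in (net.body.block1, net.body.block2):
            assert len(block) == 3
            for module in block:
                assert len(module.branch_convs) == 5
                assert [conv.kernel for conv in module.branch_convs] == [3, 5, 8, 11, 17]
                assert module.pool_conv.kernel == 1

    def test_resnet_filters_double(self):
        net = build_model(ModelSpec("ResNet", 128, 9, 5), seed=0)
        assert [b.filters for b in net.body.modules] == [64, 128, 256]
        first = net.body.modules[0].branch.modules[0]
        assert [c.kernel for c in net.body.modules[0].branch.modules[::3]] == [8, 5, 3]
        assert first.w.value.shape == (8, 9, 64)

    def test_fcn_layer_parameters(self):
        net = build_model(ModelSpec("FCN", 128, 9, 5), seed=0)
        convs = net.body.modules[::3]
        assert [(c.kernel, c.w.value.shape[2]) for c in convs] == [
            (8, 128), (5, 256), (3, 128)]

    def test_encoder_layer_parameters(self):
        net = build_model(ModelSpec("Encoder", 128, 9, 5), seed=0)
        from airsig.nn import Conv1d
        convs = [m for m in net.modules if isinstance(m, Conv1d)]
        assert [(c.kernel, c.w.value.shape[2], c.padding) for c in convs] == [
            (5, 128, "valid"), (11, 256, "valid"), (21, 512, "valid")]

    def test_timecnn_layer_parameters(self):
        from airsig.nn import Conv1d
        net = build_model(ModelSpec("TimeCNN", 90, 9, 5), seed=0)
        convs = [m for m in net.modules if isinstance(m, Conv1d)]
        assert [(c.kernel, c.w.value.shape[2]) for c in convs] == [(7, 6), (7, 12)]


class TestShapeErrors:
    def test_timecnn_pooling_chain_too_deep(self):
        with pytest.raises(ConfigError, match="timecnn"):
            build_model(ModelSpec("TimeCNN", 8, 2, 3), seed=0)

    def test_encoder_valid_convolutions_exhaust_length(self):
        net = build_model(ModelSpec("Encoder", 64, 2, 3), seed=0)
        with pytest.raises(ConfigError, match="encoder-conv3"):
            net.forward(np.zeros((1, 64, 2)), training=False)


class TestTrainConfig:
    def test_published_optimizer_table(self):
        config = TrainConfig(paper_defaults=True)
        assert config.resolve("MLP") == ("adadelta", 1e-5, 1500)
        assert config.resolve("MCDCNN") == ("sgd", 1e-5, 1500)
        for arch in ("FCN", "ResNet", "Encoder", "TimeCNN", "InceptionTime"):
            assert config.resolve(arch) == ("adam", 1e-5, 1500)

    def test_desk_defaults(self):
        opt, lr, epochs = TrainConfig().resolve("FCN")
        assert opt == "adam" and epochs == 100 and lr > 1e-5


@pytest.fixture(scope="module")
def arrays():
    config = GeneratorConfig(n_subjects=4, n_repetitions=6, duration_steps=40,
                             dwell_steps=2, channel_informativeness=(0.9,) * 9,
                             repetition_noise_sd=0.4, seed=13)
    ds = generate_dataset(config, "phone")
    from airsig.preprocess import dataset_to_arrays
    return dataset_to_arrays(ds, 36)


class TestTraining:
    def test_seeded_determinism(self, arrays):
        x, y, _ = arrays
        spec = ModelSpec("FCN", 36, 9, 4, params=small_params("FCN"))
        results = []
        for _ in range(2):
            net = build_model(spec, seed=5)
            res = train_model(net, (x, y), (x, y), TrainConfig(epochs=5, seed=5), spec=spec)
            results.append(res)
        assert results[0].train_loss == results[1].train_loss
        assert results[0].val_loss == results[1].val_loss

    def test_curve_lengths_match_epochs(self, arrays):
        x, y, _ = arrays
        spec = ModelSpec("MLP", 36, 9, 4, params=small_params("MLP"))
        net = build_model(spec, seed=0)
        res = train_model(net, (x, y), (x, y), TrainConfig(epochs=7, seed=0), spec=spec)
        assert len(res.train_loss) == len(res.val_loss) == 7
        assert 0.0 <= res.train_acc <= 1.0 and 0.0 <= res.val_acc <= 1.0

    def test_missing_class_in_train_is_error(self, arrays):
        x, y, _ = arrays
        spec = ModelSpec("MLP", 36, 9, 4, params=small_params("MLP"))
        net = build_model(spec, seed=0)
        keep = y != 2
        with pytest.raises(TrainingError, match="absent"):
            train_model(net, (x[keep], y[keep]), (x, y), TrainConfig(epochs=2), spec=spec)

    def test_random_labels_stay_near_chance(self, arrays):
        x, _, _ = arrays
        rng = np.random.default_rng(0)
        k = 4
        y_rand = rng.integers(0, k, len(x))
        y_val = rng.integers(0, k, len(x))
        spec = ModelSpec("MLP", 36, 9, k, params=small_params("MLP"))
        net = build_model(spec, seed=1)
        res = train_model(net, (x, y_rand), (x, y_val), TrainConfig(epochs=10, seed=1), spec=spec)
        se = np.sqrt((1 / k) * (1 - 1 / k) / len(y_val))
        assert abs(res.val_acc - 1 / k) <= 3 * se + 1e-9

    def test_sample_weights_accepted(self, arrays):
        x, y, _ = arrays
        w = np.where(y == 0, 2.0, 1.0)
        spec = ModelSpec("MLP", 36, 9, 4, params=small_params("MLP"))
        net = build_model(spec, seed=0)
        res = train_model(net, (x, y, w), (x, y), TrainConfig(epochs=3, seed=0), spec=spec)
        assert len(res.train_loss) == 3


class TestModelSelectionDesign:
    def test_cell_counts(self):
        assert len(plan_model_selection(n_devices=2)) == 140
        assert len(plan_model_selection(n_devices=1)) == 70

    def test_grid_runs_and_reports(self):
        config = GeneratorConfig(n_subjects=3, n_repetitions=5, duration_steps=30,
                                 dwell_steps=2, seed=17)
        ds = generate_dataset(config, "phone")
        # restrict to 2 channels to keep the grid small: (2 + 1) views x 2 archs
        from airsig.preprocess import Coalition, extract_coalition
        sub = extract_coalition(ds, Coalition((0, 1)))
        table = run_model_selection({"phone": sub}, TrainConfig(epochs=2, seed=0),
                                    input_length=24, architectures=("MLP", "TimeCNN"))
        assert len(table) == 3 * 2
        ok = table[table.error == ""]
        assert ((ok.val_acc >= 0) & (ok.val_acc <= 1)).all()
        assert len(ok) == len(table)
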