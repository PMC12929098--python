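import numpy as np
import pytest

from melafuse.bleach import extract_curve
from melafuse.net import ModelConfig, MultiHeadModel
from melafuse.simgen import SynthConfig, generate_dataset
from melafuse.trainer import (
    AugmentParams,
    PlateauScheduler,
    TrainConfig,
    apply_contrast,
    apply_gamma,
    augment_image,
    augment_tabular,
    build_training_data,
    make_splits,
    normalize_and_resize,
    run_repeated,
    train_model,
)


class TestSplits:
    def test_exact_80_10_10_for_n100(self):
        plan = make_splits(100, n_splits=1, seed=0)[0]
        assert (len(plan.train), len(plan.val), len(plan.test)) == (80, 10, 10)

    def test_floor_then_remainder_to_train_for_n103(self):
        plan = make_splits(103, n_splits=1, seed=0)[0]
        assert (len(plan.train), len(plan.val), len(plan.test)) == (83, 10, 10)

    def test_same_seed_identical_plans(self):
        a = make_splits(57, n_splits=3, seed=9)
        b = make_splits(57, n_splits=3, seed=9)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.train, pb.train)
            assert np.array_equal(pa.val, pb.val)
            assert np.array_equal(pa.test, pb.test)

    @pytest.mark.parametrize("n,seed", [(10, 0), (37, 1), (100, 2), (261, 3)])
    def test_disjoint_and_covering(self, n, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 3, n)
        for plan in make_splits(n, n_splits=2, seed=seed, labels=labels):
            merged = np.concatenate([plan.train, plan.val, plan.test])
            assert len(merged) == n
            assert np.array_equal(np.sort(merged), np.arange(n))

    def test_stratification_protects_small_class(self):
        # 10% minority class: every fold should still see it
        labels = np.array([0] * 90 + [1] * 10)
        plan = make_splits(100, n_splits=1, seed=4, labels=labels)[0]
        for fold in (plan.train, plan.val, plan.test):
            assert (labels[fold] == 1).sum() >= 1
        assert (len(plan.train), len(plan.val), len(plan.test)) == (80, 10, 10)

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            make_splits(100, ratios=(0.7, 0.1, 0.1))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            make_splits(5)


class TestNormalizeResize:
    def test_min_max_midpoint(self):
        image = np.full((1, 8, 8), 10.0)
        image[0, 0, 1] = 20.0
        image[0, 0, 2] = 15.0
        out = normalize_and_resize(image, 8)
        assert out[0, 0, 2] == pytest.approx(0.5)

    def test_idempotent_on_full_range_image(self):
        rng = np.random.default_rng(0)
        image = rng.random((3, 16, 16))
        image[0, 0, 0], image[0, 0, 1] = 0.0, 1.0  # pin the range
        assert np.allclose(normalize_and_resize(image, 16), image, atol=1e-6)

    def test_checkerboard_roundtrip_preserves_mean(self):
        board = np.indices((8, 8)).sum(axis=0) % 2
        board = board[None].astype(float)
        up = normalize_and_resize(board, 16)
        down = normalize_and_resize(up, 8)
        assert down.mean() == pytest.approx(board.mean(), rel=0.01)

    def test_constant_image_maps_to_zeros(self):
        assert not normalize_and_resize(np.full((2, 8, 8), 3.0), 8).any()

    def test_nonfinite_rejected(self):
        image = np.zeros((1, 8, 8))
        image[0, 0, 0] = np.inf
        with pytest.raises(ValueError):
            normalize_and_resize(image, 8)


class TestAugmentation:
    def test_degenerate_params_are_identity(self):
        rng = np.random.default_rng(0)
        image = rng.random((3, 8, 8))
        params = AugmentParams(gamma_range=(1, 1), contrast_range=(1, 1),
                               image_noise_sd=0.0, p_apply=1.0)
        assert np.allclose(augment_image(image, np.random.default_rng(1), params),
                           image, atol=1e-12)

    def test_gamma_two_squares_pixels(self):
        out = apply_gamma(np.full((4, 4), 0.5), 2.0)
        assert np.allclose(out, 0.25)

    def test_contrast_is_mean_anchored(self):
        rng = np.random.default_rng(2)
        image = rng.random((8, 8))
        out = apply_contrast(image, 1.2)
        assert out.mean() == pytest.approx(image.mean(), abs=1e-12)

    def test_output_always_clamped(self):
        rng = np.random.default_rng(3)
        params = AugmentParams(image_noise_sd=0.5, p_apply=1.0)
        for _ in range(10):
            out = augment_image(rng.random((2, 8, 8)), rng, params)
            assert out.min() >= 0.0 and out.max() <= 1.0

    def test_tabular_sigma_zero_identity(self):
        vec = np.arange(5.0)
        assert np.array_equal(augment_tabular(vec, np.random.default_rng(0), 0.0), vec)

    def test_tabular_noise_reproducible(self):
        vec = np.arange(5.0)
        a = augment_tabular(vec, np.random.default_rng(7), 0.1)
        b = augment_tabular(vec, np.random.default_rng(7), 0.1)
        assert np.array_equal(a, b)

    def test_tabular_noise_sd_calibrated(self):
        rng = np.random.default_rng(8)
        vec = np.zeros(10_000)
        out = augment_tabular(vec, rng, 0.3)
        assert np.std(out - vec) == pytest.approx(0.3, rel=0.05)

    def test_invalid_frames_untouched(self):
        vec = np.ones(4)
        valid = np.array([True, True, False, False])
        out = augment_tabular(vec, np.random.default_rng(9), 0.5, valid)
        assert np.array_equal(out[2:], vec[2:])
        assert not np.array_equal(out[:2], vec[:2])

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            augment_tabular(np.ones(3), np.random.default_rng(0), -0.1)


class TestPlateauScheduler:
    def test_improving_losses_keep_lr(self):
        sched = PlateauScheduler(2e-4, 0.5, 5)
        for loss in np.linspace(1.0, 0.1, 20):
            lr = sched.step(loss)
        assert lr == 2e-4

    def test_constant_stream_halves_at_epoch_six(self):
        sched = PlateauScheduler(2e-4, 0.5, 5)
        rates = [sched.step(1.0) for _ in range(6)]
        assert rates[:5] == [2e-4] * 5
        assert rates[5] == pytest.approx(1e-4)

    def test_second_plateau_halves_again(self):
        sched = PlateauScheduler(2e-4, 0.5, 5)
        rates = [sched.step(1.0) for _ in range(11)]
        assert rates[10] == pytest.approx(5e-5)

    def test_lr_sequence_never_increases(self):
        rng = np.random.default_rng(5)
        sched = PlateauScheduler(2e-4, 0.5, 3)
        prev = sched.lr
        for loss in rng.random(50):
            lr = sched.step(float(loss))
            assert lr <= prev
            prev = lr


@pytest.fixture(scope="module")
def trainer_setup():
    config = SynthConfig(n_per_class=40, image_size=16, n_channels=4,
                         noise_sd=0.01, seed=21)
    records = generate_dataset(config)
    curves = [extract_curve(r.frames, r.lesion_mask, lesion_id=r.record_id)
              for r in records]
    data = build_training_data(records, curves)
    labels = data.labels
    splits = make_splits(len(records), n_splits=1, seed=0, labels=labels)
    return data, splits


class TestTrainModel:
    def _model(self, seed=0, mode="multi"):
        return MultiHeadModel(
            ModelConfig(tabular_dim=10, mlp_hidden=(32,), backbone_channels=(8, 16)),
            input_channels=4, mode=mode, seed=seed,
        )

    def test_zero_epoch_budget_returns_initial_model(self, trainer_setup):
        data, splits = trainer_setup
        config = TrainConfig(max_epochs=0, image_size=16, n_splits=1, repeats=1)
        result = train_model(self._model(), data, splits[0], config)
        assert result.history.empty
        assert 0.0 <= result.metrics.accuracy <= 1.0

    def test_training_is_deterministic(self, trainer_setup):
        data, splits = trainer_setup
        config = TrainConfig(max_epochs=2, image_size=16, n_splits=1,
                             repeats=1, seed=3)
        r1 = train_model(self._model(seed=5), data, splits[0], config)
        r2 = train_model(self._model(seed=5), data, splits[0], config)
        assert r1.metrics == r2.metrics
        assert np.allclose(r1.history["val_loss"], r2.history["val_loss"])

    def test_checkpoint_is_validation_minimum(self, trainer_setup):
        data, splits = trainer_setup
        config = TrainConfig(max_epochs=5, image_size=16, n_splits=1, repeats=1)
        result = train_model(self._model(seed=1), data, splits[0], config)
        assert result.best_val_loss == pytest.approx(
            result.history["val_loss"].min()
        )

    def test_separable_data_recovered_quickly(self, trainer_setup):
        """Strongly class-separated synthetic data is classified with >= 0.9
        test accuracy within a 10-epoch budget."""
        data, splits = trainer_setup
        config = TrainConfig(max_epochs=10, image_size=16, n_splits=1, repeats=1)
        result = train_model(self._model(seed=2), data, splits[0], config)
        assert result.metrics.accuracy >= 0.9

    def test_single_head_mode_runs_on_identical_splits(self, trainer_setup):
        data, splits = trainer_setup
        config = TrainConfig(max_epochs=1, image_size=16, n_splits=1, repeats=1)
        multi = train_model(self._model(seed=4), data, splits[0], config)
        single = train_model(self._model(seed=4, mode="single"), data, splits[0],
                             config)
        assert multi.metrics.split_id == single.metrics.split_id

    def test_run_repeated_produces_per_run_table(self, trainer_setup):
        data, splits = trainer_setup
        config = TrainConfig(max_epochs=1, image_size=16, n_splits=1, repeats=2)
        model_config = ModelConfig(tabular_dim=10, mlp_hidden=(16,),
                                   backbone_channels=(8,))
        runs = run_repeated(data, splits, config, model_config)
        assert len(runs) == 2
        assert {(r.split_id, r.repeat_id) for r in runs} == {(0, 0), (0, 1)}


def test_build_training_data_frame_subset(trainer_setup):
    data, _ = trainer_setup
    assert data.tabular.shape[1] == 10
    assert data.images.min() >= 0 and data.images.max() <= 1
    assert data.hard.sum(axis=1) == pytest.approx(1.0)
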