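"""Regressor construction, augmentation, LR schedule, training mechanics."""

import dataclasses

import numpy as np
import pytest

from aacscore import regression
from aacscore.kauppila import Severity
from aacscore.regression import (
    AugmentConfig,
    RegressorConfig,
    TrainConfig,
    augment,
    build_regressor,
    lr_at,
    predict_category,
    predict_score,
    predict_score_clamped,
    train_regressor,
)

SMALL_RC = RegressorConfig(blocks_per_stage=(1, 1), stage_channels=(4, 8),
                           stem_channels=4, input_size=(32, 64), seed=0)


class TestLrSchedule:
    TC = TrainConfig()

    def test_warmup_start_is_one_third_of_base(self):
        assert lr_at(0, 10_000, self.TC) == pytest.approx(0.01 / 3)
        assert f"{lr_at(0, 10_000, self.TC):.4f}" == "0.0033"

    def test_warmup_end_reaches_base(self):
        assert lr_at(200, 10_000, self.TC) == pytest.approx(0.01)

    def test_final_step_reaches_floor(self):
        assert lr_at(9_999, 10_000, self.TC) == pytest.approx(0.0001)

    def test_continuous_at_warmup_boundary(self):
        left = lr_at(199, 10_000, self.TC)
        right = lr_at(200, 10_000, self.TC)
        assert abs(right - left) < (0.01 - 0.01 / 3) / 200 * 1.5

    def test_monotone_non_increasing_after_warmup(self):
        lrs = [lr_at(i, 2_000, self.TC) for i in range(200, 2_000)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))

    def test_negative_iteration_rejected(self):
        with pytest.raises(ValueError):
            lr_at(-1, 100, self.TC)


class TestAugment:
    def test_zero_magnitudes_identity(self, rng):
        x = rng.random((40, 30)).astype(np.float32)
        out = augment(x, AugmentConfig.disabled(), seed=3)
        assert np.array_equal(out, x)

    def test_fixed_seed_reproducible(self, rng):
        x = rng.random((40, 30)).astype(np.float32)
        cfg = AugmentConfig()
        assert np.array_equal(augment(x, cfg, seed=5), augment(x, cfg, seed=5))
        assert not np.array_equal(augment(x, cfg, seed=5), augment(x, cfg, seed=6))

    def test_shape_preserved(self, rng):
        x = rng.random((50, 20)).astype(np.float32)
        assert augment(x, AugmentConfig(), seed=0).shape == x.shape

    def test_shift_moves_centroid_as_configured(self):
        """A delta image shifted by the maximal +5% moves by 5% of size +/- 1 px."""
        x = np.zeros((100, 100), dtype=np.float32)
        x[50, 50] = 1.0
        cfg = AugmentConfig(brightness=0, contrast=0, noise_sigma=(0.0, 0.0),
                            shift=0.05, scale=0, rotation=0)
        # search seeds for a draw close to the configured maximum
        for seed in range(200):
            r = np.random.default_rng(seed)
            dr = r.uniform(-0.05, 0.05) * 100
            dc = r.uniform(-0.05, 0.05) * 100
            if dr > 4.5 and dc > 4.5:
                break
        out = augment(x, cfg, seed=seed)
        rows, cols = np.nonzero(out > 0.01)
        centroid = (np.average(rows, weights=out[rows, cols]),
                    np.average(cols, weights=out[rows, cols]))
        assert abs(centroid[0] - (50 + dr)) <= 1.0
        assert abs(centroid[1] - (50 + dc)) <= 1.0

    def test_noise_sigma_respects_intensity_scale(self, rng):
        x = np.zeros((200, 200), dtype=np.float32)
        x[0, 0] = 1.0  # range 1 => applied sigma <= 10/255
        cfg = AugmentConfig(brightness=0, contrast=0, noise_sigma=(10.0, 10.0),
                            shift=0, scale=0, rotation=0)
        out = augment(x, cfg, seed=1)
        assert np.std(out - x) == pytest.approx(10.0 / 255.0, rel=0.05)


class TestBuildRegressor:
    def test_forward_on_zero_patch_is_finite_scalar(self):
        model = build_regressor(SMALL_RC)
        y = model(np.zeros((1, 1, 64, 32), np.float32), train=False)
        assert y.shape == (1,) and np.isfinite(y[0])

    def test_same_seed_identical_parameters(self):
        a = build_regressor(SMALL_RC)
        b = build_regressor(SMALL_RC)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.value, pb.value)

    def test_attention_changes_parameter_count_by_exactly_the_se_modules(self):
        import aacscore.nn as nn

        with_attn = build_regressor(SMALL_RC)
        without = build_regressor(dataclasses.replace(SMALL_RC, attention=False))
        n_with = sum(p.value.size for p in with_attn.parameters())
        n_without = sum(p.value.size for p in without.parameters())
        expected = 0
        for ch in SMALL_RC.stage_channels:
            se = nn.SCse(ch, rng=np.random.default_rng(0))
            expected += sum(p.value.size for p in se.parameters())
        assert n_with - n_without == expected

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError, match="striding|input_size"):
            RegressorConfig(input_size=(4, 4), stage_channels=(8, 16, 32, 64),
                            blocks_per_stage=(1, 1, 1, 1)).validate()


class TestPredict:
    def test_clamped_in_range_and_category_rounding(self):
        model = build_regressor(SMALL_RC)
        patch = np.zeros((64, 32), np.float32)
        raw = predict_score(model, patch)
        clamped = predict_score_clamped(model, patch)
        assert 0.0 <= clamped <= 24.0
        assert np.isfinite(raw)
        assert predict_category(model, patch) in list(Severity)

    def test_category_boundary_rounding(self):
        # rounded 4.4 -> 4 -> no_mild; 4.6 -> 5 -> moderate
        from aacscore.kauppila import classify_severity

        assert classify_severity(int(np.round(4.4))) is Severity.no_mild
        assert classify_severity(int(np.round(4.6))) is Severity.moderate

    def test_shape_mismatch_rejected(self):
        model = build_regressor(SMALL_RC)
        with pytest.raises(ValueError, match="input"):
            predict_score(model, np.zeros((10, 10), np.float32))


class TestTrainRegressor:
    def _toy_data(self, n, rng):
        """Patches whose mean brightness encodes the target score."""
        scores = rng.uniform(0, 24, size=n)
        patches = [np.full((64, 32), s / 24.0, np.float32)
                   + rng.normal(0, 0.05, (64, 32)).astype(np.float32) for s in scores]
        return patches, scores

    def test_overfits_ten_samples_without_augmentation(self, rng):
        """Capacity check: dropout and augmentation off, training MSE -> ~0."""
        patches, scores = self._toy_data(10, rng)
        rc = dataclasses.replace(SMALL_RC, dropout=0.0)
        tc = TrainConfig(base_lr=0.002, min_lr=0.00005, batch_size=10, max_epochs=150,
                         warmup_iters=20, val_check_every=1000, patience=10, seed=0)
        model, history = train_regressor((patches, scores), (patches, scores),
                                         rc, tc, augment_config=None)
        final_train = np.mean([h["train_mse"] for h in history[-4:]])
        assert final_train < 0.5

    def test_history_lr_matches_schedule(self, rng):
        patches, scores = self._toy_data(8, rng)
        tc = TrainConfig(batch_size=4, max_epochs=3, val_check_every=1, patience=99, seed=0)
        _, history = train_regressor((patches, scores), (patches, scores),
                                     SMALL_RC, tc, augment_config=None)
        total = 3 * 2  # epochs x batches
        for h in history:
            assert h["lr"] == pytest.approx(lr_at(h["iter"], total, tc))

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError):
            train_regressor(([], []), ([np.zeros((64, 32))], [0]), SMALL_RC, TrainConfig())

    def test_out_of_range_scores_rejected(self, rng):
        patches, _ = self._toy_data(4, rng)
        with pytest.raises(ValueError, match="0, 24"):
            train_regressor((patches, [1, 2, 3, 30]), (patches, [1, 2, 3, 4]),
                            SMALL_RC, TrainConfig())
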