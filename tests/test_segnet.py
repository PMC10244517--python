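"""U-Net construction, folds, schedule, patch prediction, ensembling."""

import numpy as np
import pytest

from dixonmuscle.imgvol import LabelVolume, MuscleScheme
from dixonmuscle.phantom import PhantomConfig, generate_phantom
from dixonmuscle.preprocess import mirror_lr, split_midsagittal
from dixonmuscle.segnet import (
    SegModelSpec,
    TrainConfig,
    TrainingScan,
    build_model,
    ensemble_vote,
    finetune,
    lr_schedule_trace,
    make_folds,
    predict_volume,
    scans_from_subject,
    segment_subject,
    tile_starts,
    train,
)

TINY_SPEC = SegModelSpec(depth=2, base_filters=4, n_classes=3)


def _tiny_input(rng, shape=(2, 8, 8, 4)):
    return rng.normal(1000, 100, shape).astype(np.float32)


class TestModel:
    def test_probabilities_sum_to_one(self, rng):
        model = build_model(TINY_SPEC, 0)
        probs = model.forward_probs(_tiny_input(rng))
        np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-5)
        assert probs.shape == (3, 8, 8, 4)

    def test_seeded_init_reproducible(self):
        a = build_model(TINY_SPEC, 11)
        b = build_model(TINY_SPEC, 11)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_doubling_base_filters_quadruples_conv_params(self):
        def conv_weights(model):
            return sum(p.value.size for p in model.params() if p.value.ndim == 5)

        small = conv_weights(build_model(SegModelSpec(depth=3, base_filters=8), 0))
        big = conv_weights(build_model(SegModelSpec(depth=3, base_filters=16), 0))
        assert 3.5 < big / small < 4.2

    def test_indivisible_shape_rejected(self, rng):
        model = build_model(SegModelSpec(depth=3, base_filters=4, n_classes=3), 0)
        with pytest.raises(ValueError, match="divisible"):
            model.forward(rng.normal(size=(2, 10, 8, 8)).astype(np.float32))

    def test_save_load_round_trip(self, tmp_path, rng):
        model = build_model(TINY_SPEC, 3)
        model.meta["fold"] = 2
        x = _tiny_input(rng)
        expected = model.forward_probs(x)
        path = model.save(tmp_path / "ckpt.npz")
        from dixonmuscle.segnet import UNet3D

        back = UNet3D.load(path)
        assert back.meta["fold"] == 2
        np.testing.assert_allclose(back.forward_probs(x), expected, atol=1e-6)

    def test_gradients_match_finite_differences(self, rng):
        # spot-check the hand-written backward pass on a few parameters
        from dixonmuscle import nn

        model = build_model(SegModelSpec(depth=2, base_filters=2, n_classes=2), 1)
        x = rng.normal(1000, 100, (2, 4, 4, 4)).astype(np.float32)
        labels = rng.integers(0, 2, (4, 4, 4))
        _, dlogits = nn.cross_entropy(model.forward(x), labels)
        model.backward(dlogits)
        params = model.params()
        check = [(0, 0), (len(params) // 2, 0), (len(params) - 2, 0)]
        for pi, vi in check:
            p = params[pi]
            analytic = float(p.grad.ravel()[vi])
            eps = 1e-2
            orig = float(p.value.ravel()[vi])
            p.value.ravel()[vi] = orig + eps
            up, _ = nn.cross_entropy(model.forward(x), labels)
            p.value.ravel()[vi] = orig - eps
            down, _ = nn.cross_entropy(model.forward(x), labels)
            p.value.ravel()[vi] = orig
            numeric = (up - down) / (2 * eps)
            assert analytic == pytest.approx(numeric, abs=2e-4)


class TestFolds:
    def test_ten_subjects_five_folds_of_two(self):
        subjects = [(f"s{i}", [f"s{i}a"]) for i in range(10)]
        folds = make_folds(subjects, k=5, seed=0)
        assert all(len(f) == 2 for f in folds.folds)

    def test_partition_property(self):
        subjects = [(f"s{i}", [f"s{i}a"]) for i in range(7)]
        folds = make_folds(subjects, k=3, seed=1)
        flat = folds.subjects()
        assert sorted(flat) == sorted(s for s, _ in subjects)
        assert len(set(flat)) == len(flat)

    def test_scans_follow_their_subject(self):
        subjects = [("a", ["a1", "a2", "a3"]), ("b", ["b1"]), ("c", ["c1"])]
        folds = make_folds(subjects, k=2, seed=0)
        for fold in folds.folds:
            for sid in fold:
                assert folds.scans_by_subject[sid] == dict(subjects)[sid]

    def test_bad_k_rejected(self):
        subjects = [("a", []), ("b", [])]
        with pytest.raises(ValueError):
            make_folds(subjects, k=1)
        with pytest.raises(ValueError):
            make_folds(subjects, k=3)


class TestLRSchedule:
    def test_improving_loss_keeps_lr(self):
        losses = list(np.linspace(1.0, 0.1, 30))
        trace = lr_schedule_trace(losses, lr0=1e-4, patience=25)
        assert trace[-1] == pytest.approx(1e-4)

    def test_flat_sequence_halves_once_at_patience(self):
        trace = lr_schedule_trace([1.0] * 26, lr0=1e-4, factor=0.5, patience=25)
        assert trace[-1] == pytest.approx(5e-5)
        assert trace[-2] == pytest.approx(1e-4)

    def test_two_plateaus_halve_twice(self):
        trace = lr_schedule_trace([1.0] * 51, lr0=1e-4, factor=0.5, patience=25)
        assert trace[-1] == pytest.approx(2.5e-5)

    def test_tiny_improvements_do_not_reset(self):
        # improvements below tolerance are not improvements
        losses = [1.0 - 1e-9 * i for i in range(26)]
        trace = lr_schedule_trace(losses, lr0=1e-4, patience=25, tol=1e-6)
        assert trace[-1] == pytest.approx(5e-5)


class TestPredictVolume:
    def test_single_patch_equals_forward_pass(self, rng):
        model = build_model(TINY_SPEC, 0)
        channels = _tiny_input(rng)
        pv = predict_volume(model, channels, patch_slices=4)
        np.testing.assert_allclose(pv.probs, model.forward_probs(channels), atol=1e-6)
        assert (pv.coverage == 1).all()

    def test_averaging_identical_patches_changes_nothing(self, rng):
        # mean of equal values is the value: duplicated patch windows must
        # reproduce the single-patch probabilities exactly
        model = build_model(TINY_SPEC, 0)
        channels = _tiny_input(rng)
        pv_once = predict_volume(model, channels, patch_slices=4, starts=[0])
        pv_thrice = predict_volume(model, channels, patch_slices=4, starts=[0, 0, 0])
        assert (pv_thrice.coverage == 3).all()
        np.testing.assert_allclose(pv_thrice.probs, pv_once.probs, atol=1e-6)

    def test_full_coverage_under_default_tiling(self, rng):
        model = build_model(TINY_SPEC, 0)
        channels = rng.normal(1000, 100, (2, 8, 8, 20)).astype(np.float32)
        pv = predict_volume(model, channels, patch_slices=4)
        assert (pv.coverage >= 1).all()
        np.testing.assert_allclose(pv.probs.sum(axis=0), 1.0, atol=1e-5)

    def test_incomplete_user_starts_rejected(self, rng):
        model = build_model(TINY_SPEC, 0)
        channels = rng.normal(1000, 100, (2, 8, 8, 20)).astype(np.float32)
        with pytest.raises(ValueError, match="uncovered"):
            predict_volume(model, channels, patch_slices=4, starts=[0, 8])

    def test_random_policy_covers(self, rng):
        model = build_model(TINY_SPEC, 0)
        channels = rng.normal(1000, 100, (2, 8, 8, 20)).astype(np.float32)
        pv = predict_volume(model, channels, patch_slices=4, policy="random", rng=rng)
        assert (pv.coverage >= 1).all()

    def test_tile_starts_cover_and_end_flush(self):
        starts = tile_starts(140, 81, overlap_frac=0.5)
        assert starts[0] == 0 and starts[-1] == 140 - 81
        covered = set()
        for s in starts:
            covered.update(range(s, s + 81))
        assert covered == set(range(140))


class TestEnsemble:
    SCHEME = MuscleScheme.first(7)

    def _lv(self, values):
        return LabelVolume(np.asarray(values, dtype=np.uint8), self.SCHEME)

    def test_unanimous_inputs_returned(self):
        lv = self._lv(np.full((3, 3, 2), 4))
        out = ensemble_vote([lv, lv, lv])
        np.testing.assert_array_equal(out.values, lv.values)

    def test_majority_wins(self):
        a = self._lv(np.full((2, 2, 1), 3))
        b = self._lv(np.full((2, 2, 1), 7))
        out = ensemble_vote([a, a, a, b, b])
        assert (out.values == 3).all()

    def test_tie_broken_by_mean_probability(self):
        a = self._lv(np.full((1, 1, 1), 1))
        b = self._lv(np.full((1, 1, 1), 2))
        shape = (8, 1, 1, 1)

        def probs(winner, p):
            out = np.full(shape, (1 - p) / 7, dtype=np.float32)
            out[winner] = p
            return out

        # 1-1 vote; class 2 has the higher mean probability
        out = ensemble_vote([a, b], [probs(1, 0.40), probs(2, 0.45)])
        assert out.values[0, 0, 0] == 2

    def test_tie_without_probs_goes_to_lowest_id(self):
        a = self._lv(np.full((1, 1, 1), 5))
        b = self._lv(np.full((1, 1, 1), 2))
        out = ensemble_vote([a, b])
        assert out.values[0, 0, 0] == 2

    def test_grid_mismatch_rejected(self):
        a = self._lv(np.zeros((2, 2, 2)))
        b = self._lv(np.zeros((2, 2, 3)))
        with pytest.raises(ValueError, match="grid"):
            ensemble_vote([a, b])


class TestSegmentSubject:
    def test_mirror_symmetric_input_gives_mirror_symmetric_output(self):
        cfg = PhantomConfig(
            grid_shape=(64, 32, 8), n_muscles_per_leg=2, infiltration=(0.1, 0.5),
            noise_sigma=0.0,
        )
        dixon, truth = generate_phantom(cfg)
        model = build_model(SegModelSpec(depth=2, base_filters=4, n_classes=3), 0)
        pred = segment_subject(model, dixon, truth.labels.scheme, patch_slices=8)
        assert pred.shape == dixon.shape
        np.testing.assert_array_equal(pred.values, pred.values[::-1])

    def test_left_prediction_is_mirrored_right_prediction(self):
        cfg = PhantomConfig(
            grid_shape=(64, 32, 8), n_muscles_per_leg=2, infiltration=(0.2, 0.8),
            noise_sigma=0.0,
        )
        dixon, truth = generate_phantom(cfg)
        model = build_model(SegModelSpec(depth=2, base_filters=4, n_classes=3), 1)
        pred = segment_subject(model, dixon, truth.labels.scheme, patch_slices=8)
        right, left = split_midsagittal(pred.values)
        np.testing.assert_array_equal(mirror_lr(left), right)


def _tiny_scans(seed, n_subjects=2):
    cfg = PhantomConfig(
        grid_shape=(64, 32, 8), n_muscles_per_leg=2, infiltration=(0.0, 0.6),
        noise_sigma=0.0, seed=seed,
    )
    dixon, truth = generate_phantom(cfg)
    return scans_from_subject(dixon, truth.labels, f"s{seed}")


class TestTrainingLoop:
    def test_loss_descends_on_easy_two_muscle_phantom(self):
        train_scans = _tiny_scans(0)
        val_scans = _tiny_scans(1)
        model = build_model(SegModelSpec(depth=2, base_filters=4, n_classes=3), 0)
        config = TrainConfig(lr0=1e-3, max_epochs=20, patch_slices=8, seed=0, augment=None)
        model, history = train(model, train_scans, val_scans, config)
        assert history.loc[19, "train_loss"] < history.loc[0, "train_loss"]
        assert list(history.columns) == ["epoch", "train_loss", "val_loss", "lr"]

    def test_finetune_zero_epochs_keeps_parameters(self):
        scans = _tiny_scans(0)
        model = build_model(TINY_SPEC, 0)
        before = model.get_weights()
        tuned, _ = finetune(model, scans, scans, TrainConfig(max_epochs=0))
        for w0, w1 in zip(before, tuned.get_weights()):
            np.testing.assert_array_equal(w0, w1)
        assert tuned.meta["parent"] == model.model_id

    def test_empty_sets_rejected(self):
        model = build_model(TINY_SPEC, 0)
        with pytest.raises(ValueError, match="empty"):
            train(model, [], _tiny_scans(0), TrainConfig(max_epochs=1))
        with pytest.raises(ValueError, match="empty"):
            train(model, _tiny_scans(0), [], TrainConfig(max_epochs=1))

    def test_training_reproducible_under_seed(self):
        results = []
        for _ in range(2):
            model = build_model(TINY_SPEC, 5)
            config = TrainConfig(lr0=1e-3, max_epochs=3, patch_slices=8, seed=5, augment=None)
            model, history = train(model, _tiny_scans(0), _tiny_scans(1), config)
            results.append((history["train_loss"].to_numpy(), model.get_weights()))
        np.testing.assert_array_equal(results[0][0], results[1][0])
        for w0, w1 in zip(results[0][1], results[1][1]):
            np.testing.assert_array_equal(w0, w1)
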