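"""Splitting, augmentation, the optimization loop and checkpoint selection."""

import numpy as np
import pytest

from densicount import (
    CheckpointRecord,
    GenerationConfig,
    LossConfig,
    ModelConfig,
    SceneConfig,
    TrainConfig,
    augment,
    build_network,
    generate_density_map,
    generate_scene,
    load_checkpoint,
    prepare_scenes,
    select_best,
    split_dataset,
    train,
)
from densicount.losses import (
    masked_structural_loss_grad,
    weighted_cross_entropy_grad,
)
from densicount.nn import Adam
from densicount.targets import ConfigError, DensityMap, downsample_density
from densicount.training import optimizer_from_checkpoint


def make_scenes(counts, size=64, seed0=100):
    scenes = []
    for i, n in enumerate(counts):
        img, ann = generate_scene(
            SceneConfig(image_size=(size, size), n_objects=n, seed=seed0 + i)
        )
        scenes.append((img, ann))
    return scenes


class TestSplitDataset:
    def test_hundred_ids_split_60_20_20(self):
        tr, va, te = split_dataset(list(range(100)), seed=1)
        assert (len(tr), len(va), len(te)) == (60, 20, 20)

    def test_same_seed_same_split(self):
        a = split_dataset(list(range(50)), seed=9)
        b = split_dataset(list(range(50)), seed=9)
        assert a == b

    def test_remainder_goes_to_training(self):
        tr, va, te = split_dataset(list(range(7)), seed=0)
        assert (len(tr), len(va), len(te)) == (5, 1, 1)

    def test_disjoint_and_exhaustive(self):
        ids = [f"i{k}" for k in range(23)]
        tr, va, te = split_dataset(ids, seed=4)
        assert sorted(tr + va + te) == sorted(ids)
        assert not (set(tr) & set(va) or set(tr) & set(te) or set(va) & set(te))

    def test_too_few_items_rejected(self):
        with pytest.raises(ConfigError):
            split_dataset([1, 2, 3], seed=0)


class TestAugment:
    def _cfg(self, **kw):
        kw.setdefault("crop_size", 32)
        kw.setdefault("epochs", 1)
        return TrainConfig(**kw)

    def test_flip_is_involution(self, rng):
        img = rng.random((40, 40, 3))
        den = rng.random((40, 40))
        cfg = self._cfg(flip_prob=1.0)
        # same window both times: full-size crop
        cfg32 = TrainConfig(crop_size=32, epochs=1, flip_prob=1.0)
        i1, d1 = augment(img[:32, :32], den[:32, :32], cfg32, np.random.default_rng(0))
        i2, d2 = augment(i1, d1, cfg32, np.random.default_rng(0))
        np.testing.assert_array_equal(i2, img[:32, :32])
        np.testing.assert_array_equal(d2, den[:32, :32])

    def test_zero_density_crop_stays_zero(self, rng):
        img = rng.random((64, 64, 3))
        _, d = augment(img, np.zeros((64, 64)), self._cfg(), rng)
        assert not d.any()

    def test_crop_mass_equals_window_mass(self, rng):
        img = rng.random((64, 64, 3))
        den = rng.random((64, 64))
        cfg = self._cfg(flip_prob=0.0)
        r = np.random.default_rng(3)
        _, d = augment(img, den, cfg, r)
        # recover the window by matching content
        r2 = np.random.default_rng(3)
        top = int(r2.integers(0, 33))
        left = int(r2.integers(0, 33))
        np.testing.assert_array_equal(d, den[top : top + 32, left : left + 32])

    def test_small_images_are_padded(self, rng):
        img = rng.random((20, 20, 3))
        den = rng.random((20, 20))
        i, d = augment(img, den, self._cfg(), rng)
        assert i.shape[:2] == (32, 32) and d.shape == (32, 32)
        assert d.sum() == pytest.approx(den.sum(), rel=1e-12)

    def test_mean_crop_mass_matches_area_fraction(self):
        """Uniform windows: E[crop mass] = (crop area / scene area') * total,
        where area' counts valid window positions; checked by Monte Carlo."""
        img, ann = generate_scene(SceneConfig(image_size=(96, 96), n_objects=30, seed=5))
        den = generate_density_map(ann).values
        cfg = TrainConfig(crop_size=48, epochs=1, flip_prob=0.5)
        r = np.random.default_rng(0)
        masses = [augment(img, den, cfg, r)[1].sum() for _ in range(1000)]
        # expectation over uniform top-left positions, computed exactly
        n_pos = 96 - 48 + 1
        cum = np.cumsum(np.cumsum(den, 0), 1)
        pad = np.zeros((97, 97))
        pad[1:, 1:] = cum
        exact = np.mean(
            [
                pad[t + 48, l + 48] - pad[t, l + 48] - pad[t + 48, l] + pad[t, l]
                for t in range(n_pos)
                for l in range(n_pos)
            ]
        )
        assert np.mean(masses) == pytest.approx(exact, rel=0.05)


class TestSelection:
    def test_min_sum_rule_example(self):
        records = [
            CheckpointRecord(1, 5, 7),
            CheckpointRecord(2, 3, 10),
            CheckpointRecord(3, 4, 4),
        ]
        assert select_best(records).epoch == 3  # score 8 beats 12 and 13

    def test_tie_goes_to_earliest_epoch(self):
        records = [CheckpointRecord(1, 4, 4), CheckpointRecord(2, 3, 5)]
        assert select_best(records).epoch == 1

    def test_matches_brute_force_scan(self, rng):
        for _ in range(50):
            records = [
                CheckpointRecord(e, float(m), float(r))
                for e, (m, r) in enumerate(rng.random((10, 2)) * 20)
            ]
            best = select_best(records)
            scores = [r.val_mae + r.val_rmse for r in records]
            assert best.selection_score == min(scores)
            assert best.epoch == int(np.argmin(scores))

    def test_selection_score_invariant(self):
        r = CheckpointRecord(5, 1.25, 2.5)
        assert r.selection_score == 1.25 + 2.5


class TestTrainLoop:
    def _quick(self, seed=0, epochs=3, counts=(0, 3, 8, 15, 5, 0, 10, 20)):
        scenes = prepare_scenes(make_scenes(counts))
        net = build_network(ModelConfig.tiny(seed=seed))
        cfg = TrainConfig(
            crop_size=48, epochs=epochs, batch_size=4, learning_rate=1e-3,
            validate_after_epoch=1, seed=seed,
        )
        return net, scenes, cfg

    def test_loss_decreases_over_epochs(self):
        net, scenes, cfg = self._quick(epochs=6)
        result = train(net, (scenes[:6], scenes[6:]), cfg)
        losses = [h["train_loss"] for h in result.history]
        assert losses[-1] < losses[0]

    def test_best_checkpoint_is_argmin_of_history(self):
        net, scenes, cfg = self._quick(epochs=5)
        result = train(net, (scenes[:6], scenes[6:]), cfg)
        scored = [h for h in result.history if "selection_score" in h]
        assert result.best.selection_score == min(h["selection_score"] for h in scored)

    def test_two_runs_same_seed_identical(self):
        net1, scenes, cfg = self._quick(seed=2, epochs=3)
        r1 = train(net1, (scenes[:6], scenes[6:]), cfg)
        net2, scenes2, cfg2 = self._quick(seed=2, epochs=3)
        r2 = train(net2, (scenes2[:6], scenes2[6:]), cfg2)
        assert r1.history == r2.history
        assert r1.best.epoch == r2.best.epoch
        for a, b in zip(net1.params(), net2.params()):
            np.testing.assert_array_equal(a.value, b.value)

    def test_divergence_aborts_with_diagnostic(self):
        net, scenes, cfg = self._quick(epochs=2)
        scenes[0].image = scenes[0].image.astype(np.float64)
        scenes[0].image[0, 0] = np.nan
        with pytest.raises(RuntimeError, match="non-finite"):
            train(net, (scenes, []), cfg)

    def test_resume_reproduces_uninterrupted_run(self, tmp_path):
        # uninterrupted 4 epochs
        net_a, scenes, cfg = self._quick(seed=3, epochs=4)
        cfg_a = TrainConfig(**{**cfg.__dict__, "validate_after_epoch": 99})
        train(net_a, (scenes[:6], []), cfg_a)
        # interrupted after 2 epochs, then resumed
        net_b, scenes_b, _ = self._quick(seed=3, epochs=4)
        cfg_b2 = TrainConfig(**{**cfg_a.__dict__, "epochs": 2})
        ckpt = tmp_path / "last.npz"
        train(net_b, (scenes_b[:6], []), cfg_b2, checkpoint_path=ckpt)
        net_c, meta = load_checkpoint(ckpt)
        assert meta["extra"]["epoch"] == 2
        opt = optimizer_from_checkpoint(net_c, meta, cfg_a)
        train(net_c, (scenes_b[:6], []), cfg_a, start_epoch=3, optimizer=opt)
        for a, c in zip(net_a.params(), net_c.params()):
            np.testing.assert_array_equal(a.value, c.value)

    def test_overfit_single_batch_below_tenth_of_initial(self):
        """A fixed batch must be overfit to <10% of the initial loss within
        500 steps — the engine-works sanity check."""
        scenes = prepare_scenes(make_scenes([0, 5, 15, 30]))
        net = build_network(ModelConfig.tiny(seed=2))
        loss_cfg = LossConfig()
        gen = GenerationConfig()
        opt = Adam(net.params(), lr=1e-3, weight_decay=1e-4)
        x = np.stack([net.normalize(s.image) for s in scenes])
        dts = [downsample_density(DensityMap(s.density), 8).values for s in scenes]
        sgs = [(dt > gen.seg_epsilon).astype(float) for dt in dts]
        initial = None
        for step in range(500):
            dens, seg = net.forward_batch(x, train=True)
            gd = np.zeros(dens.shape)
            gs = np.zeros(seg.shape)
            loss = 0.0
            for j in range(4):
                sl, g1 = masked_structural_loss_grad(
                    dens[j, 0].astype(float), dts[j], sgs[j], loss_cfg
                )
                ce, g2 = weighted_cross_entropy_grad(
                    seg[j, 0].astype(float), sgs[j], loss_cfg
                )
                loss += sl + loss_cfg.lambda_seg * ce
                gd[j, 0] = g1 / 4
                gs[j, 0] = loss_cfg.lambda_seg * g2 / 4
            loss /= 4
            if initial is None:
                initial = loss
            if loss < 0.1 * initial:
                break
            net.backward_batch(gd, gs)
            opt.step()
            opt.zero_grad()
        assert loss < 0.1 * initial
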