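import numpy as np
import pytest

from conftest import make_class_samples
from pmfesn import nn
from pmfesn.model import (
    BranchSpec,
    ModelState,
    SiameseSpec,
    TrainConfig,
    bce_cosine_loss,
    build_branch,
    count_parameters,
    forward_pair,
    normalized_cosine,
    train,
)
from pmfesn.pairs import build_pairs, split_train_val

TOY = BranchSpec(backbone="toy", input_shape=(8, 8, 3), toy_filters=(4, 8))


def toy_spec():
    return SiameseSpec(branch=TOY)


def toy_pairs(counts=(3, 3), effect=5.0, seed=0):
    samples = make_class_samples(counts, shape=(8, 8, 3), seed=seed, effect=effect, noise=1.0)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ps = build_pairs(samples, seed=seed)
    return split_train_val(ps, seed=seed)


class TestArchitecture:
    def test_vgg16_branch_layer_algebra(self):
        layers = build_branch(BranchSpec())
        flat_idx = [i for i, l in enumerate(layers) if isinstance(l, nn.Flatten)][0]
        bn = layers[flat_idx + 1]
        d1, d2 = layers[flat_idx + 2], layers[flat_idx + 3]
        assert bn.gamma.shape == (1, 8192)  # 4 x 4 x 512 flattened
        assert sum(p.size for p in d1.params().values()) == 163_860
        assert sum(p.size for p in d2.params().values()) == 210
        assert sum(p.size for p in {**bn.params(), **bn.buffers()}.values()) == 32_768

    def test_vgg16_freeze_policy(self):
        layers = build_branch(BranchSpec())
        convs = [l for l in layers if isinstance(l, nn.Conv2D)]
        assert len(convs) == 13
        assert all(not c.trainable for c in convs[:10])  # blocks 1-4
        assert all(c.trainable for c in convs[10:])  # block 5
        assert all(c.W.shape[-1] for c in convs)
        block5 = convs[10:]
        assert all(sum(p.size for p in c.params().values()) == 2_359_808 for c in block5)

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError):
            BranchSpec(backbone="resnet")

    def test_embedding_dimension(self):
        assert toy_spec().embedding_dim == 60


class TestNormalizedCosine:
    def test_identity_antipodal_orthogonal(self, rng):
        u = rng.normal(size=60)
        assert normalized_cosine(u, u) == pytest.approx(1.0, abs=1e-6)
        assert normalized_cosine(u, -u) == pytest.approx(0.0, abs=1e-6)
        v = np.zeros(60)
        v[0], u = 1.0, np.zeros(60)
        u[1] = 1.0
        assert normalized_cosine(u, v) == pytest.approx(0.5)

    def test_zero_vector_gives_half(self):
        assert normalized_cosine(np.zeros(60), np.ones(60)) == pytest.approx(0.5)

    def test_symmetry_and_range(self, rng):
        for _ in range(50):
            u, v = rng.normal(size=60), rng.normal(size=60)
            s1, s2 = normalized_cosine(u, v), normalized_cosine(v, u)
            assert s1 == s2
            assert 0.0 <= s1 <= 1.0


class TestGradients:
    def test_bce_cosine_gradient_matches_central_differences(self, rng):
        """Analytic gradient of BCE(normalized cosine) w.r.t. embeddings."""
        u = rng.normal(size=(4, 10))
        v = rng.normal(size=(4, 10))
        y = np.array([1.0, 0.0, 1.0, 0.0])
        _, du, dv = bce_cosine_loss(u, v, y)
        eps = 1e-6
        for _ in range(20):
            i, j = rng.integers(0, 4), rng.integers(0, 10)
            up, um = u.copy(), u.copy()
            up[i, j] += eps
            um[i, j] -= eps
            num = (bce_cosine_loss(up, v, y)[0] - bce_cosine_loss(um, v, y)[0]) / (2 * eps)
            assert du[i, j] == pytest.approx(num, rel=1e-4, abs=1e-8)
            vp, vm = v.copy(), v.copy()
            vp[i, j] += eps
            vm[i, j] -= eps
            num = (bce_cosine_loss(u, vp, y)[0] - bce_cosine_loss(u, vm, y)[0]) / (2 * eps)
            assert dv[i, j] == pytest.approx(num, rel=1e-4, abs=1e-8)


class TestForwardPair:
    def test_identical_inputs_give_one(self):
        tr, _ = toy_pairs()
        state = ModelState.initialize(toy_spec(), TrainConfig(seed=1))
        p = tr[0]
        same = type(p)(a=p.a, b=p.a.__class__(
            case_id="copy", slabs={m: s.copy() for m, s in p.a.slabs.items()}, mrs=p.a.mrs
        ), pair_label=1)
        assert forward_pair(state, same) == pytest.approx(1.0, abs=1e-5)

    def test_swapped_pair_bit_identical(self):
        tr, _ = toy_pairs()
        state = ModelState.initialize(toy_spec(), TrainConfig(seed=1))
        p = tr[0]
        swapped = type(p)(a=p.b, b=p.a, pair_label=p.pair_label)
        assert forward_pair(state, p) == forward_pair(state, swapped)

    def test_similarity_in_unit_interval(self):
        tr, _ = toy_pairs()
        state = ModelState.initialize(toy_spec(), TrainConfig(seed=2))
        for p in tr[:10]:
            assert 0.0 <= forward_pair(state, p) <= 1.0


class TestTrain:
    def test_zero_lr_leaves_weights_unchanged(self):
        tr, val = toy_pairs()
        spec = toy_spec()
        cfg = TrainConfig(lr=0.0, max_epochs=2, seed=0)
        ref = ModelState.initialize(spec, cfg)
        before = [{k: v.copy() for k, v in l.params().items()} for l in ref.layers]
        state = train(spec, tr, val, cfg)
        for layer, snap in zip(state.layers, before):
            for k, v in layer.params().items():
                assert np.array_equal(v, snap[k])

    def test_frozen_layers_bit_identical_after_training(self):
        tr, val = toy_pairs()
        spec = toy_spec()
        cfg = TrainConfig(lr=0.05, max_epochs=3, seed=0)
        state = ModelState.initialize(spec, cfg)
        frozen_before = [
            {k: v.copy() for k, v in l.params().items()} for l in state.layers if not l.trainable
        ]
        trained = train(spec, tr, val, cfg)
        frozen_after = [
            {k: v for k, v in l.params().items()} for l in trained.layers if not l.trainable
        ]
        assert frozen_before  # the toy backbone freezes its first block
        for snap, now in zip(frozen_before, frozen_after):
            for k in snap:
                assert np.array_equal(snap[k], now[k])

    def test_early_stop_rule(self):
        """Once an epoch improves the training loss by <= min_delta, exactly
        ``patience`` more epochs run and training halts."""
        tr, val = toy_pairs()
        cfg = TrainConfig(lr=1e-9, max_epochs=10, early_stop_min_delta=1e-4, patience=1, seed=0)
        state = train(toy_spec(), tr, val, cfg)
        losses = state.history["train_loss"]
        # with a negligible lr the first comparison already triggers
        improvements = [losses[i - 1] - losses[i] for i in range(1, len(losses))]
        trigger = next(i + 1 for i, d in enumerate(improvements) if d <= 1e-4)
        assert len(losses) == trigger + cfg.patience + 1

    def test_single_label_pairs_rejected(self):
        tr, val = toy_pairs()
        only_same = [p for p in tr if p.pair_label == 1]
        with pytest.raises(ValueError, match="both labels"):
            train(toy_spec(), only_same, [], TrainConfig())

    def test_learns_similarity_on_separable_data(self):
        """After training on well-separated classes, held-out same-class
        pairs score higher than dissimilar ones in most seeds."""
        wins = 0
        for seed in range(5):
            tr, val = toy_pairs(counts=(4, 4), effect=5.0, seed=seed)
            cfg = TrainConfig(lr=0.05, max_epochs=5, seed=seed)
            state = train(toy_spec(), tr, val, cfg)
            same = [forward_pair(state, p) for p in val if p.pair_label == 1]
            diff = [forward_pair(state, p) for p in val if p.pair_label == 0]
            if same and diff and np.mean(same) > np.mean(diff):
                wins += 1
        assert wins >= 4

    def test_history_recorded(self):
        tr, val = toy_pairs()
        state = train(toy_spec(), tr, val, TrainConfig(lr=0.01, max_epochs=3, seed=0))
        assert 1 <= len(state.history["train_loss"]) <= 3
        assert len(state.history["val_loss"]) == len(state.history["train_loss"])


class TestPersistence:
    def test_save_load_bit_identical_predictions(self, tmp_path):
        tr, val = toy_pairs()
        state = train(toy_spec(), tr, val, TrainConfig(lr=0.05, max_epochs=2, seed=3))
        state.save(tmp_path / "model")
        loaded = ModelState.load(tmp_path / "model")
        for p in val[:5]:
            assert forward_pair(state, p) == forward_pair(loaded, p)


class TestCountParameters:
    def test_table_totals_for_vgg16_branch(self):
        total, trainable, non_trainable = count_parameters(build_branch(BranchSpec()))
        assert (total, trainable, non_trainable) == (14_911_526, 7_259_878, 7_651_648)

    def test_full_model_is_six_branches(self):
        state = ModelState.initialize(SiameseSpec(), TrainConfig())
        total, trainable, non_trainable = count_parameters(state)
        assert trainable == 6 * 7_259_878
        assert total == 6 * 14_911_526
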