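"""Loss function, fold harness and training loop."""

import numpy as np
import pytest

from headms import phantom, zoo
from headms.training import (
    TrainConfig,
    _augment_batch,
    cross_validate,
    cse_loss,
    make_folds,
    one_hot,
    normalize_slices,
    train,
)


def test_cse_uniform_prediction_is_log6():
    truth = one_hot(np.random.default_rng(0).integers(0, 6, (8, 8)))
    uniform = np.full((8, 8, 6), 1 / 6)
    assert cse_loss(uniform, truth) == pytest.approx(np.log(6), abs=1e-9)


def test_cse_perfect_prediction_is_nearly_zero():
    truth = one_hot(np.random.default_rng(1).integers(0, 6, (8, 8)))
    loss = cse_loss(truth, truth)
    assert loss == pytest.approx(-np.log(1 - 1e-7), abs=1e-12)
    assert loss >= 0


def test_cse_nonnegative_and_shape_checked(rng):
    p = rng.random((4, 4, 6))
    p /= p.sum(-1, keepdims=True)
    t = one_hot(rng.integers(0, 6, (4, 4)))
    assert cse_loss(p, t) >= 0
    with pytest.raises(ValueError, match="shape"):
        cse_loss(p, one_hot(rng.integers(0, 6, (5, 4))))


def test_make_folds_53_subjects_k10_sizes_and_partition():
    ids = [f"s{i:02d}" for i in range(53)]
    fa = make_folds(ids, k=10, seed=7)
    sizes = sorted(len(fa.members(f)) for f in range(10))
    assert sizes == [5] * 7 + [6] * 3  # 53 = 7*5 + 3*6
    all_members = [s for f in range(10) for s in fa.members(f)]
    assert sorted(all_members) == sorted(ids)  # disjoint cover
    assert make_folds(ids, k=10, seed=7).fold_of == fa.fold_of  # deterministic
    assert make_folds(ids, k=10, seed=8).fold_of != fa.fold_of


def test_make_folds_shuffled_input_same_membership():
    ids = [f"s{i}" for i in range(20)]
    fa1 = make_folds(ids, k=4, seed=3)
    fa2 = make_folds(list(reversed(ids)), k=4, seed=3)
    for f in range(4):
        assert fa1.members(f) == fa2.members(f)


def test_make_folds_edge_cases():
    assert sorted(
        make_folds(["a", "b"], k=2, seed=0).fold_of.values()
    ) == [0, 1]
    with pytest.raises(ValueError, match="exceeds"):
        make_folds(["a", "b"], k=3, seed=0)


def test_split_roles_are_disjoint_and_cover():
    ids = [f"s{i}" for i in range(20)]
    fa = make_folds(ids, k=4, seed=1)
    for fold in range(4):
        tr, va, te = fa.split(fold)
        assert not (set(tr) & set(va)) and not (set(tr) & set(te))
        assert not (set(va) & set(te))
        assert sorted(tr + va + te) == sorted(ids)
    # every subject is in the test set exactly once across folds
    seen = [s for fold in range(4) for s in fa.split(fold)[2]]
    assert sorted(seen) == sorted(ids)


def test_split_k2_has_no_validation_fold():
    fa = make_folds([f"s{i}" for i in range(6)], k=2, seed=0)
    tr, va, te = fa.split(0)
    assert va == [] and sorted(tr + te) == [f"s{i}" for i in range(6)]


def test_normalize_slices_to_unit_range(rng):
    x = rng.random((3, 8, 8)) * 5 + 2
    z = normalize_slices(x)
    assert z.min() == 0.0 and z.max() == 1.0


def test_augment_flip_swaps_left_right_classes():
    x = np.zeros((1, 4, 4, 1), dtype=np.float32)
    x[0, 0, 0, 0] = 1.0
    y = np.zeros((1, 4, 4, 6), dtype=np.float32)
    y[0, :, :, 0] = 1.0
    y[0, 1, 0] = 0.0
    y[0, 1, 0, 1] = 1.0  # right masseter at left edge

    class AlwaysFlip:
        def random(self, n):
            return np.zeros(n)

    xa, ya = _augment_batch(x, y, AlwaysFlip())
    assert xa[0, 0, 3, 0] == 1.0
    assert ya[0, 1, 3, 2] == 1.0  # becomes left masseter at right edge


def _toy_setup(n_slices=16, size=32, seed=0):
    spec = zoo.ArchitectureSpec("unet", encoder_widths=(4, 8, 12), n_classes=6)
    params = phantom.PhantomParams(image_size=size, n_slices=4)
    man = phantom.generate_cohort(n_slices // 4, params, seed=seed)
    xs = np.concatenate([v.voxels for v, _ in man.volumes.values()])
    ys = np.concatenate([l.labels for _, l in man.volumes.values()])
    return spec, xs, ys


def test_training_reduces_loss_on_toy_phantom():
    spec, xs, ys = _toy_setup()
    model = zoo.build_model(spec, seed=0)
    cfg = TrainConfig(learning_rate=1e-3, batch_size=4, epochs=5, k_folds=2, seed=0)
    hist = train(model, xs, ys, config=cfg)
    assert hist.train_loss[-1] < hist.train_loss[0]


def test_zero_learning_rate_leaves_parameters_unchanged():
    spec, xs, ys = _toy_setup()
    model = zoo.build_model(spec, seed=0)
    before = [p.data.copy() for p in model.parameters()]
    cfg = TrainConfig(learning_rate=0.0, batch_size=8, epochs=2, k_folds=2, seed=0)
    hist = train(model, xs, ys, config=cfg)
    for p, b in zip(model.parameters(), before):
        assert np.array_equal(p.data, b)
    # batch reshuffling alters batch-norm statistics slightly; parameters fixed
    assert hist.train_loss[0] == pytest.approx(hist.train_loss[1], rel=1e-3)


def test_training_is_seed_deterministic():
    spec, xs, ys = _toy_setup()
    cfg = TrainConfig(learning_rate=1e-3, batch_size=4, epochs=3, k_folds=2, seed=5)
    h1 = train(zoo.build_model(spec, seed=1), xs, ys, config=cfg)
    h2 = train(zoo.build_model(spec, seed=1), xs, ys, config=cfg)
    assert h1.train_loss == h2.train_loss


def test_empty_training_set_rejected():
    spec = zoo.ArchitectureSpec("unet", encoder_widths=(4, 8), n_classes=6)
    model = zoo.build_model(spec, seed=0)
    with pytest.raises(ValueError, match="empty"):
        train(model, np.zeros((0, 16, 16)), np.zeros((0, 16, 16), dtype=int))


def test_cross_validate_tiny_smoke(tiny_cohort):
    spec = zoo.ArchitectureSpec("unet", encoder_widths=(4, 8, 12), n_classes=6)
    cfg = TrainConfig(learning_rate=1e-3, batch_size=4, epochs=2, k_folds=3, seed=0)
    records = cross_validate(spec, tiny_cohort, cfg)
    # 3 folds x 5 tissues x 2 splits
    assert len(records) == 30
    splits = {r.split for r in records}
    assert splits == {"validation", "test"}
    for r in records:
        assert 0.0 <= r.dsc <= 100.0
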