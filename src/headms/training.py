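"""Loss, optimization and the subject-level k-fold cross-validation harness.

Training follows the fixed recipe: mini-batch gradient descent with Adam,
categorical cross-entropy, a fixed number of epochs, no early stopping and
no learning-rate schedule.  Splitting is by subject — all slices of a
subject stay in the same partition — so no subject leaks between the train,
validation and test sets of a run.  Within each of the k runs, one fold is
the test set and the next fold (cyclically) is the validation set used for
per-epoch monitoring; the remaining k-2 folds are the training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import io as hio
from . import nn
from .core import N_CLASSES, CohortManifest
from .metrics import MetricsRecord, evaluate_prediction
from .zoo import ArchitectureSpec, build_model

EPS = 1e-7


@dataclass
class TrainConfig:
    """Optimization settings.  The full-scale recipe is Adam at learning
    rate 1e-4, batch size 8, 200 epochs, k=10; the desk-scale defaults used
    throughout the test suite shrink epochs and raise the learning rate so a
    comparable number of effective updates fits a laptop-scale run."""

    learning_rate: float = 1e-4
    batch_size: int = 8
    epochs: int = 200
    optimizer: str = "adam"
    seed: int = 0
    k_folds: int = 10
    #: fraction of training subjects held out for monitoring when an explicit
    #: validation fold is not available (cross_validate uses one fold's worth)
    validation_fraction: float = 0.1
    #: optional augmentation: horizontal flip with left/right label swap
    augment: bool = False

    def __post_init__(self):
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")

    @classmethod
    def desk_scale(cls, **overrides):
        """Scaled-down settings for interactive/CI runs (20 epochs default)."""
        base = dict(learning_rate=1e-3, batch_size=2, epochs=20, k_folds=3)
        base.update(overrides)
        return cls(**base)


@dataclass
class FoldAssignment:
    """Subject-level partition into k folds."""

    fold_of: dict  # subject_id -> fold index
    k: int

    def members(self, fold: int):
        return sorted(s for s, f in self.fold_of.items() if f == fold)

    def split(self, test_fold: int):
        """(train_ids, validation_ids, test_ids) for one cross-validation run.

        With k >= 3 the fold following the test fold (cyclically) serves as
        the validation set; with k = 2 there is no spare fold, so validation
        is empty and training uses the whole non-test fold.
        """
        test = self.members(test_fold)
        if self.k == 2:
            train = sorted(s for s, f in self.fold_of.items() if f != test_fold)
            return train, [], test
        val_fold = (test_fold + 1) % self.k
        val = self.members(val_fold)
        train = sorted(
            s for s, f in self.fold_of.items() if f not in (test_fold, val_fold)
        )
        return train, val, test


def make_folds(subject_ids, k: int, seed: int) -> FoldAssignment:
    """Random subject-level partition into k folds of near-equal size."""
    ids = sorted(subject_ids)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the number of subjects ({len(ids)})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    fold_of = {ids[int(p)]: i % k for i, p in enumerate(perm)}
    return FoldAssignment(fold_of=fold_of, k=k)


def one_hot(labels: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    """(H, W) integer labels -> (H, W, C) float32 one-hot map."""
    eye = np.eye(n_classes, dtype=np.float32)
    return eye[labels]


def cse_loss(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean categorical cross-entropy per pixel, probabilities clipped to
    [eps, 1-eps] with eps = 1e-7."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p = np.clip(pred, EPS, 1.0 - EPS)
    n_pixels = truth.size // truth.shape[-1]
    return float(-(truth * np.log(p)).sum() / n_pixels)


def normalize_slices(stack: np.ndarray) -> np.ndarray:
    """Per-slice min-max normalization to [0, 1]."""
    stack = np.asarray(stack, dtype=np.float32)
    lo = stack.min(axis=(1, 2), keepdims=True)
    hi = stack.max(axis=(1, 2), keepdims=True)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    return (stack - lo) / span

_FLIP_PERM = np.array([0, 2, 1, 4, 3, 5])  # swap left/right classes


def _augment_batch(x, y, rng):
    """Horizontal flip (cols) with left/right one-hot channel swap."""
    flip = rng.random(x.shape[0]) < 0.5
    x = x.copy()
    y = y.copy()
    x[flip] = x[flip, :, ::-1]
    y[flip] = y[flip, :, ::-1][..., _FLIP_PERM]
    return x, y


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_mean_dsc: list = field(default_factory=list)


def _forward_batched(model, x, batch_size=8):
    out = []
    for i in range(0, x.shape[0], batch_size):
        out.append(model.predict_proba(x[i : i + batch_size]))
    return np.concatenate(out, axis=0)


def mean_foreground_dsc(model, x, labels) -> float:
    """Mean DSC (fraction) over the 5 tissues, slices pooled."""
    from .metrics import dice

    pred = np.argmax(_forward_batched(model, x), axis=-1)
    vals = []
    for code in range(1, N_CLASSES):
        vals.append(dice(pred == code, labels == code))
    return float(np.mean(vals))


def train(model, train_slices, train_labels, val_slices=None, val_labels=None,
          config: TrainConfig | None = None) -> TrainHistory:
    """Optimize the model in place; returns per-epoch loss/metric history.

    ``train_slices`` is (N, H, W) or (N, H, W, 1); inputs are min-max
    normalized per slice.  The final-epoch model is kept (no early stopping).
    """
    config = config or TrainConfig()
    x = normalize_slices(np.asarray(train_slices))
    if x.ndim == 3:
        x = x[..., None]
    if x.shape[0] == 0:
        raise ValueError("empty training set")
    y = np.stack([one_hot(l) for l in np.asarray(train_labels)])
    has_val = val_slices is not None and len(val_slices) > 0
    if has_val:
        xv = normalize_slices(np.asarray(val_slices))
        if xv.ndim == 3:
            xv = xv[..., None]
        yv_labels = np.asarray(val_labels)
        yv = np.stack([one_hot(l) for l in yv_labels])

    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history = TrainHistory()
    n = x.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x[idx], y[idx]
            if config.augment:
                xb, yb = _augment_batch(xb, yb, rng)
            model.zero_grad()
            logits = model.forward(xb, training=True)
            probs = nn.softmax(logits.data)
            loss = cse_loss(probs, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}"
                )
            n_pixels = probs.size // probs.shape[-1]
            nn.backward(logits, (probs - yb) / n_pixels)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        history.train_loss.append(epoch_loss / n_batches)
        if has_val:
            pv = _forward_batched(model, xv)
            history.val_loss.append(cse_loss(pv, yv))
            pred = np.argmax(pv, axis=-1)
            from .metrics import dice

            history.val_mean_dsc.append(
                float(np.mean([
                    dice(pred == c, yv_labels == c) for c in range(1, N_CLASSES)
                ]))
            )
    return history


def _gather_slices(manifest: CohortManifest, subject_ids, n_slices=5):
    """Stack the analysis slices (and labels) of the given subjects.

    Per subject, the ``n_slices`` slices where both masseters are largest are
    used — the same selection rule as the morphometry stage.
    """
    from .morphometry import select_slices

    xs, ys, owners = [], [], []
    for sid in subject_ids:
        vol, lab = hio.load_subject(manifest, sid)
        sel = select_slices(lab, min(n_slices, lab.shape[0]))
        xs.append(vol.voxels[sel])
        ys.append(lab.labels[sel])
        owners.extend([sid] * len(sel))
    return np.concatenate(xs), np.concatenate(ys), owners


def _per_subject_records(model, manifest, subject_ids, model_name, fold, split,
                         batch_size=8):
    """Evaluate per subject (slices pooled per subject), then one record per
    tissue holding the across-subject mean of each metric."""
    import pandas as pd

    from .morphometry import select_slices

    rows = []
    for sid in subject_ids:
        vol, lab = hio.load_subject(manifest, sid)
        sel = select_slices(lab, min(5, lab.shape[0]))
        x = normalize_slices(vol.voxels[sel])[..., None]
        pred = np.argmax(_forward_batched(model, x, batch_size), axis=-1)
        truth = lab.labels[sel]
        for frag in evaluate_prediction(pred, truth, spacing=lab.spacing):
            rows.append({"subject_id": sid, **frag})
    df = pd.DataFrame(rows)
    records = []
    for tissue, grp in df.groupby("tissue"):
        means = grp.drop(columns=["subject_id", "tissue"]).mean()
        records.append(
            MetricsRecord(
                model=model_name, tissue=tissue, fold=fold, split=split,
                **{k: float(means[k]) for k in means.index},
            )
        )
    return records


def cross_validate(spec: ArchitectureSpec, manifest: CohortManifest,
                   config: TrainConfig | None = None,
                   progress=None) -> list:
    """k-fold cross-validation of one architecture over a cohort.

    Returns a list of :class:`MetricsRecord` — k folds x 5 tissues x
    {validation, test} — computed per subject and averaged within each split.
    """
    config = config or TrainConfig()
    folds = make_folds(manifest.subject_ids, config.k_folds, config.seed)
    records = []
    for fold in range(config.k_folds):
        train_ids, val_ids, test_ids = folds.split(fold)
        if not test_ids:
            raise ValueError(f"fold {fold} has no test subjects")
        x_tr, y_tr, _ = _gather_slices(manifest, train_ids)
        x_va = y_va = None
        if val_ids:
            x_va, y_va, _ = _gather_slices(manifest, val_ids)
        model = build_model(spec, seed=config.seed + fold)
        train(model, x_tr, y_tr, x_va, y_va, config)
        for split, ids in (("validation", val_ids), ("test", test_ids)):
            if not ids:
                continue
            records.extend(
                _per_subject_records(
                    model, manifest, ids, spec.family, fold, split
                )
            )
        if progress is not None:
            progress(fold, records)
    return records
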