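"""Training regime: categorical cross-entropy, Adam (lr 0.001), batch size 8,
50 epochs by default, with per-epoch logging and 5-fold cross-validation.

Desk-scale by design: the defaults mirror the study regime, while input size,
epochs and batch size scale down for CPU-sized runs (the model architecture is
unchanged by input size).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict

import numpy as np

from .metrics import evaluate_predictions, f1, confusion, mean_response_time
from .model import CAUCNet, count_parameters
from .nn import autograd as ag
from .nn.layers import Adam
from .palettes import classes_to_onehot, mask_to_classes
from .pipeline import make_cv_folds


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    batch_size: int = 8
    learning_rate: float = 1e-3
    cv_folds: int = 5
    seed: int = 0
    variant: str = "V5"
    input_size: int = 224
    num_classes: int = 5
    device: str = "cpu"

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class EpochLog:
    epoch: int
    train_loss: float
    train_accuracy: float
    train_f1: float
    val_loss: float = float("nan")
    val_accuracy: float = float("nan")
    val_f1: float = float("nan")
    seconds: float = 0.0

    def as_dict(self):
        return asdict(self)


def bundle_arrays(bundle, input_size=None):
    """Stack a bundle into (images[0,1] float32, class rasters int64)."""
    if len(bundle) == 0:
        raise ValueError("empty bundle")
    images = np.stack([s.image for s in bundle.samples]).astype(np.float32) / 255.0
    classes = np.stack([mask_to_classes(s.mask, s.source_scheme, snap=False)
                        for s in bundle.samples])
    if input_size is not None and images.shape[1] != input_size:
        raise ValueError(
            f"bundle images are {images.shape[1]}px but the model expects {input_size}px")
    return images, classes


def _batched_probs(model, images, batch_size=8):
    model.eval()
    out = []
    for i in range(0, len(images), batch_size):
        out.append(model(ag.Tensor(images[i:i + batch_size])).data)
    return np.concatenate(out, axis=0)


def fit_model(model, images, classes, epochs, batch_size, learning_rate, seed,
              val=None, verbose=False):
    """Core optimization loop; returns the per-epoch logs."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 0x7EA1)))
    model.rng_state.reseed(int(rng.integers(2 ** 31)))
    onehot = np.stack([classes_to_onehot(c, model.num_classes) for c in classes])
    opt = Adam(model.parameters(), lr=learning_rate)
    logs = []
    n = len(images)
    for epoch in range(epochs):
        t0 = time.perf_counter()
        model.train()
        perm = rng.permutation(n)
        losses, tallies = [], None
        for i in range(0, n, batch_size):
            sel = perm[i:i + batch_size]
            logits = model.logits(ag.Tensor(images[sel]))
            loss = ag.softmax_cross_entropy(logits, onehot[sel])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {float(loss.data)!r}; aborting")
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            t = confusion(logits.data.argmax(-1), classes[sel], model.num_classes)
            tallies = t if tallies is None else _merge(tallies, t)
        from .metrics import accuracy as _acc

        log = EpochLog(epoch=epoch, train_loss=float(np.mean(losses)),
                       train_accuracy=_acc(tallies), train_f1=f1(tallies, "macro"))
        if val is not None:
            vi, vc = val
            probs = _batched_probs(model, vi, batch_size)
            v_onehot = np.stack([classes_to_onehot(c, model.num_classes) for c in vc])
            from .metrics import cce_loss

            vt = confusion(probs.argmax(-1), vc, model.num_classes)
            log.val_loss = cce_loss(probs, v_onehot)
            log.val_accuracy = _acc(vt)
            log.val_f1 = f1(vt, "macro")
        log.seconds = time.perf_counter() - t0
        logs.append(log)
        if verbose:
            print(f"epoch {epoch:3d}  loss {log.train_loss:.4f}  "
                  f"acc {log.train_accuracy:.4f}  val_acc {log.val_accuracy:.4f}")
    recalibrate_batchnorm(model, images, batch_size)
    return logs


def recalibrate_batchnorm(model, images, batch_size=8):
    """Precise-BN recalibration: recompute the batch-norm moving statistics
    with frozen weights and dropout disabled.

    Heavy channel dropout inflates the variance of the activations that the
    moving statistics average during training; inference (dropout off) then
    sees systematically mis-scaled normalizations.  A final pass over the
    training images with dropout off and cumulative averaging of the batch
    statistics restores train/eval consistency.
    """
    from .nn.layers import BatchNorm, Dropout

    bns = [m for m in model.modules() if isinstance(m, BatchNorm)]
    drops = [m for m in model.modules() if isinstance(m, Dropout)]
    saved = [(d.rate) for d in drops]
    saved_mom = [bn.momentum for bn in bns]
    for d in drops:
        d.rate = 0.0
    for bn in bns:
        bn.running_mean[:] = 0.0
        bn.running_var[:] = 0.0
    model.train()
    for k, i in enumerate(range(0, len(images), batch_size)):
        for bn in bns:
            bn.momentum = k / (k + 1.0)  # cumulative average over batches
        model(ag.Tensor(images[i:i + batch_size]))
    for bn, mom in zip(bns, saved_mom):
        bn.momentum = mom
    for d, r in zip(drops, saved):
        d.rate = r
    model.eval()


def _merge(a, b):
    a.tp += b.tp
    a.fp += b.fp
    a.fn += b.fn
    a.tn += b.tn
    return a


def train(config, train_bundle, val_bundle=None, verbose=False):
    """Train a fresh model on a bundle; returns (model, epoch logs)."""
    images, classes = bundle_arrays(train_bundle)
    model = CAUCNet(input_size=images.shape[1], num_classes=config.num_classes,
                    variant=config.variant, seed=config.seed)
    val = bundle_arrays(val_bundle) if val_bundle is not None and len(val_bundle) else None
    logs = fit_model(model, images, classes, config.epochs, config.batch_size,
                     config.learning_rate, config.seed, val=val, verbose=verbose)
    return model, logs


def evaluate(model, bundle, batch_size=8, time_repeats=1):
    """Full metrics report for a model on a bundle."""
    images, classes = bundle_arrays(bundle, model.input_size)
    probs = _batched_probs(model, images, batch_size)
    mrt = mean_response_time(model, images[: min(4, len(images))], repeats=time_repeats)
    return evaluate_predictions(probs, classes, npm=count_parameters(model), mrt=mrt)


def run_cv(config, bundle, verbose=False):
    """k-fold cross-validation; returns (per-fold reports, aggregate summary)."""
    folds = make_cv_folds(bundle, k=config.cv_folds, seed=config.seed)
    reports = []
    for i, (tr, va) in enumerate(folds):
        fold_cfg = TrainConfig(**{**asdict(config), "seed": config.seed + i})
        model, _ = train(fold_cfg, tr, verbose=verbose)
        reports.append(evaluate(model, va, batch_size=config.batch_size))
    keys = ("accuracy_micro", "loss", "f1_micro", "miou")
    summary = {k: {"mean": float(np.mean([getattr(r, k) for r in reports])),
                   "sd": float(np.std([getattr(r, k) for r in reports], ddof=1))
                   if len(reports) > 1 else 0.0}
               for k in keys}
    return reports, summary
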