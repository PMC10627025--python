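"""Cross-variety knowledge transfer: frozen-backbone fine-tuning and MixStyle.

Fine-tuning freezes every layer before the first fully connected layer of a
pretrained CNN and re-optimises only the dense head on the target variety.

MixStyle is a domain-generalisation layer applied after the last convolution
block during training only. For a combined batch x = [x_src, x_tgt] it forms
a reference batch x~ by swapping the two domain halves and shuffling each half
along the batch dimension, computes instance-level per-channel feature
statistics mu(x), sigma(x) over the spectral axis, draws instance-wise convex
weights lambda ~ Beta(alpha, alpha), and replaces each instance's style with
the mixture

    gamma_mix = lambda sigma(x) + (1 - lambda) sigma(x~)
    beta_mix  = lambda mu(x)    + (1 - lambda) mu(x~)
    MixStyle(x) = gamma_mix (x - mu(x)) / sigma(x) + beta_mix

The classification loss is computed on the source half only, so target labels
never enter the gradient; the target variety serves as validation/test. At
evaluation time MixStyle is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import nn
from .models import CNNSpec, PRESETS, TrainedModel, build_cnn, _eval_metrics

__all__ = [
    "TransferConfig", "MixStyleState", "fine_tune", "make_reference_indices",
    "make_reference_batch", "mixstyle_forward", "train_with_mixstyle",
]

MIXSTYLE_LR_RANGE = (0.000001, 0.0005)
_EPS = 1e-6


@dataclass(frozen=True)
class TransferConfig:
    """Shared configuration of the two transfer strategies."""

    mode: str = "mixstyle"
    source_domain: str = ""
    target_domain: str = ""
    alpha: float = 0.1
    learning_rate: float = 0.0003
    weight_decay: float = 0.0005
    epochs: int = 300
    seed: int = 0
    mix_prob: float = 1.0   # chance of activating MixStyle on a training batch

    def __post_init__(self):
        if self.mode not in ("fine_tune", "mixstyle"):
            raise ValueError(f"unknown transfer mode {self.mode!r}")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.mode == "mixstyle":
            lo, hi = MIXSTYLE_LR_RANGE
            if not lo <= self.learning_rate <= hi:
                raise ValueError(
                    f"mixstyle learning rate must lie in [{lo}, {hi}]")


# ---------------------------------------------------------------------------
# fine-tuning
# ---------------------------------------------------------------------------

def fine_tune(pretrained: TrainedModel, X_train, y_train, X_val, y_val,
              config: TransferConfig) -> TrainedModel:
    """Re-train the dense head on the target domain with a frozen backbone.

    Every parameter and buffer before the first fully connected layer is left
    bit-identical to the pretrained values (frozen batch-norm layers keep
    using their stored running statistics). With ``epochs=0`` the result is
    the pretrained model unchanged.
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    X_val = np.asarray(X_val, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=np.int64)
    y_val = np.asarray(y_val, dtype=np.int64)
    if X_train.shape[-1] != pretrained.spec.input_bands:
        raise ValueError("target data band count does not match the backbone")
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("training and validation splits must be non-empty")
    model = pretrained.model.copy()
    model.backbone.set_trainable(False)
    spec = replace(pretrained.spec, learning_rate=config.learning_rate,
                   epochs=config.epochs)

    # the frozen backbone (eval-mode BN) makes the conv features of a fixed
    # dataset constant, so they are computed once and only the head trains
    f_train = model.backbone.forward(X_train[:, None, :], training=False)
    f_val = model.backbone.forward(X_val[:, None, :], training=False)

    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.head.params(), lr=spec.learning_rate,
                  weight_decay=config.weight_decay)
    records = []
    best_state, best_acc, best_epoch = model.state_dict(), -1.0, 0
    n = len(f_train)

    def metrics(feats, labels):
        logits = model.head.forward(feats, training=False)
        loss, _ = nn.cross_entropy(logits, labels)
        return loss, float((logits.argmax(axis=1) == labels).mean())

    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        for start in range(0, n, spec.batch_size):
            idx = order[start:start + spec.batch_size]
            if len(idx) < 2:
                continue
            logits = model.head.forward(f_train[idx], training=True, rng=rng)
            _, grad = nn.cross_entropy(logits, y_train[idx])
            model.zero_grad()
            model.head.backward(grad)
            opt.step()
        train_loss, train_acc = metrics(f_train, y_train)
        val_loss, val_acc = metrics(f_val, y_val)
        records.append((epoch, train_loss, train_acc, val_loss, val_acc))
        if val_acc > best_acc:
            best_acc, best_epoch = val_acc, epoch
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    history = pd.DataFrame(records, columns=["epoch", "train_loss", "train_acc",
                                             "val_loss", "val_acc"])
    return TrainedModel(model=model, spec=spec, history=history,
                        best_epoch=best_epoch, seed=config.seed,
                        domain=config.target_domain or pretrained.domain)


# ---------------------------------------------------------------------------
# MixStyle
# ---------------------------------------------------------------------------

def make_reference_indices(batch_size: int, rng: np.random.Generator
                           ) -> np.ndarray:
    """Row indices building the reference batch x~ from x = [x_i, x_j]:
    the two domain halves are swapped and each half is independently shuffled
    along the batch dimension, so every source instance is paired with a
    target instance and vice versa."""
    b = batch_size
    return np.concatenate([b + rng.permutation(b), rng.permutation(b)])


def make_reference_batch(x_i: np.ndarray, x_j: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """The reference batch x~ for source batch ``x_i`` and target batch ``x_j``."""
    if len(x_i) != len(x_j):
        raise ValueError("the two domain batches must have equal size")
    x = np.concatenate([x_i, x_j], axis=0)
    return x[make_reference_indices(len(x_i), rng)]


@dataclass
class MixStyleState:
    """Per-forward-pass MixStyle quantities (shapes: lam (N,); others (N, C))."""

    lam: np.ndarray
    mu_x: np.ndarray
    sigma_x: np.ndarray
    mu_ref: np.ndarray
    sigma_ref: np.ndarray
    gamma_mix: np.ndarray
    beta_mix: np.ndarray


def _instance_stats(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Instance-level per-channel mean and epsilon-stabilised population std
    over the spectral axis of an (N, C, L) feature map."""
    mu = x.mean(axis=-1)
    sigma = np.sqrt(x.var(axis=-1) + _EPS)
    return mu, sigma


def mixstyle_forward(x: np.ndarray, x_ref: np.ndarray, alpha: float,
                     rng: np.random.Generator | None = None,
                     lam: np.ndarray | None = None
                     ) -> tuple[np.ndarray, MixStyleState]:
    """Apply MixStyle to feature maps ``x`` using reference maps ``x_ref``.

    ``lam`` overrides the Beta(alpha, alpha) draw (one weight per instance,
    shared across channels). Returns the mixed maps and the per-pass state.
    Training-time only; evaluation-mode forwards bypass this function.
    """
    if x.shape != x_ref.shape:
        raise ValueError("x and x_ref must have identical shapes")
    n = x.shape[0]
    if lam is None:
        if rng is None:
            raise ValueError("an rng is required when lam is not given")
        lam = rng.beta(alpha, alpha, size=n)
    lam = np.asarray(lam, dtype=np.float64).reshape(n)

    mu_x, sigma_x = _instance_stats(x)
    mu_ref, sigma_ref = _instance_stats(x_ref)
    l1 = lam[:, None]
    gamma_mix = l1 * sigma_x + (1.0 - l1) * sigma_ref
    beta_mix = l1 * mu_x + (1.0 - l1) * mu_ref

    out = (gamma_mix[..., None] * (x - mu_x[..., None]) / sigma_x[..., None]
           + beta_mix[..., None])
    state = MixStyleState(lam=lam, mu_x=mu_x, sigma_x=sigma_x, mu_ref=mu_ref,
                          sigma_ref=sigma_ref, gamma_mix=gamma_mix,
                          beta_mix=beta_mix)
    return out, state


def train_with_mixstyle(source_train: tuple[np.ndarray, np.ndarray],
                        target_train: tuple[np.ndarray, np.ndarray] | np.ndarray,
                        target_val: tuple[np.ndarray, np.ndarray],
                        spec: CNNSpec | str,
                        config: TransferConfig) -> TrainedModel:
    """Train a CNN from scratch with MixStyle after the last conv block.

    Each step draws equal half-batches from the source and target training
    sets, mixes feature statistics across the domain halves, and computes the
    cross-entropy loss on the source half only. The best checkpoint by target
    validation accuracy is retained; MixStyle is disabled at evaluation.

    The MixStyle statistics are treated as constants in the backward pass
    (gradients flow through the style-normalised features only), following
    the method's reference implementation.
    """
    if isinstance(spec, str):
        spec = PRESETS[spec]
    spec = replace(spec, learning_rate=config.learning_rate,
                   epochs=config.epochs)
    Xs, ys = source_train
    Xt = target_train[0] if isinstance(target_train, tuple) else target_train
    Xv, yv = target_val
    Xs = np.asarray(Xs, dtype=np.float64)
    Xt = np.asarray(Xt, dtype=np.float64)
    Xv = np.asarray(Xv, dtype=np.float64)
    ys = np.asarray(ys, dtype=np.int64)
    yv = np.asarray(yv, dtype=np.int64)
    if len(Xs) == 0 or len(Xt) == 0 or len(Xv) == 0:
        raise ValueError("source train, target train and target val must be non-empty")

    model = build_cnn(spec, seed=config.seed)
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.params(trainable_only=True), lr=spec.learning_rate,
                  weight_decay=config.weight_decay)
    half = max(2, spec.batch_size // 2)
    n_steps = max(1, min(len(Xs), len(Xt)) // half)

    records = []
    best_state, best_acc, best_epoch = model.state_dict(), -1.0, 0
    for epoch in range(spec.epochs):
        order_s = rng.permutation(len(Xs))
        order_t = rng.permutation(len(Xt))
        for step in range(n_steps):
            si = order_s[step * half:(step + 1) * half]
            ti = order_t[step * half:(step + 1) * half]
            if len(si) < 2 or len(ti) < 2:
                continue
            xb = np.concatenate([Xs[si], Xt[ti]])[:, None, :]
            feats = model.backbone.forward(xb, training=True, rng=rng)
            if rng.random() < config.mix_prob:
                ref_idx = make_reference_indices(len(si), rng)
                mixed, state = mixstyle_forward(feats, feats[ref_idx],
                                                config.alpha, rng)
                back_scale = (state.gamma_mix / state.sigma_x)[..., None]
            else:
                mixed, back_scale = feats, None
            logits = model.head.forward(mixed, training=True, rng=rng)
            _, grad_src = nn.cross_entropy(logits[:len(si)], ys[si])
            grad = np.zeros_like(logits)
            grad[:len(si)] = grad_src
            model.zero_grad()
            grad_feats = model.head.backward(grad)
            if back_scale is not None:
                grad_feats = grad_feats * back_scale
            model.backbone.backward(grad_feats)
            opt.step()
        train_loss, train_acc = _eval_metrics(model, Xs, ys)
        val_loss, val_acc = _eval_metrics(model, Xv, yv)
        records.append((epoch, train_loss, train_acc, val_loss, val_acc))
        if val_acc > best_acc:
            best_acc, best_epoch = val_acc, epoch
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    history = pd.DataFrame(records, columns=["epoch", "train_loss", "train_acc",
                                             "val_loss", "val_acc"])
    return TrainedModel(model=model, spec=spec, history=history,
                        best_epoch=best_epoch, seed=config.seed,
                        domain=config.target_domain)
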