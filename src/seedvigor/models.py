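"""Per-variety 1D CNN vigor classifiers and the three reference classifiers.

The CNN maps a length-181 reflectance vector to 3 aging-class scores through
2-4 convolution blocks (1x4 kernels, stride 1, batch norm + ReLU, 1x2 max
pooling) followed by fully connected layers with a 0.4 dropout. Four named
presets, one per rice variety, differ in depth and width within those
constraints, with batch size 32 and per-preset Adam learning rates of 0.005,
0.001, 0.0005 and 0.0005.

The estimator follows a fit/results split: :class:`VigorCNN` is configured
from a :class:`CNNSpec`, its :meth:`VigorCNN.fit` returns a
:class:`TrainedModel` carrying the best-validation checkpoint, the full
per-epoch history and a ``summary()`` table.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from . import nn
from .containers import N_RETAINED_BANDS

__all__ = [
    "CNNSpec", "PRESETS", "SpectralCNN", "build_cnn", "VigorCNN",
    "TrainedModel", "train_cnn", "predict", "BaselineConfig", "fit_baselines",
    "load_trained_model",
]

N_CLASSES = 3


@dataclass(frozen=True)
class CNNSpec:
    """Architecture + training hyperparameters of one spectral CNN."""

    conv_channels: tuple[int, ...] = (16, 32)
    pools: tuple[bool, ...] | None = None   # default: pool after every block
    kernel: int = 4
    fc_hidden: tuple[int, ...] = (64,)
    dropout: float = 0.4
    batch_size: int = 32
    learning_rate: float = 0.001
    epochs: int = 200
    input_bands: int = N_RETAINED_BANDS

    def __post_init__(self):
        if not 2 <= len(self.conv_channels) <= 4:
            raise ValueError("between 2 and 4 convolution blocks are required")
        pools = self.pools if self.pools is not None else (True,) * len(self.conv_channels)
        if len(pools) != len(self.conv_channels):
            raise ValueError("pools must match the number of conv blocks")
        object.__setattr__(self, "pools", tuple(pools))

    def feature_length(self) -> int:
        """Spectral length of the final conv-block output."""
        length = self.input_bands
        for pool in self.pools:
            length = length - self.kernel + 1
            if pool:
                length //= 2
        return length


#: one preset per variety; widths double per block (16/32/64/128 family)
PRESETS: dict[str, CNNSpec] = {
    "yongyou12": CNNSpec(conv_channels=(16, 32), learning_rate=0.005),
    "yongyou1540": CNNSpec(conv_channels=(16, 32, 64), learning_rate=0.001),
    "suxiangjing100": CNNSpec(conv_channels=(16, 32, 64, 128), learning_rate=0.0005),
    "longjingyou1212": CNNSpec(conv_channels=(32, 64, 128), learning_rate=0.0005),
}


class SpectralCNN:
    """Backbone (conv blocks) + head (dense classifier) on (N, 1, 181) input."""

    def __init__(self, spec: CNNSpec, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        backbone: list[nn.Layer] = []
        in_ch = 1
        for i, (out_ch, pool) in enumerate(zip(spec.conv_channels, spec.pools)):
            backbone.append(nn.Conv1d(in_ch, out_ch, spec.kernel, rng=rng,
                                      name=f"conv{i}"))
            backbone.append(nn.BatchNorm1d(out_ch, name=f"bn{i}"))
            backbone.append(nn.ReLU())
            if pool:
                backbone.append(nn.MaxPool1d(2))
            in_ch = out_ch
        self.backbone = nn.Sequential(backbone)

        n_flat = spec.feature_length() * spec.conv_channels[-1]
        head: list[nn.Layer] = [nn.Flatten()]
        prev = n_flat
        for j, width in enumerate(spec.fc_hidden):
            head.append(nn.Linear(prev, width, rng=rng, name=f"fc{j}"))
            head.append(nn.ReLU())
            head.append(nn.Dropout(spec.dropout))
            prev = width
        head.append(nn.Linear(prev, N_CLASSES, rng=rng, name="fc_out"))
        self.head = nn.Sequential(head)

    # -- inference -------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        feats = self.backbone.forward(x, training=training, rng=rng)
        return self.head.forward(feats, training=training, rng=rng)

    def logits(self, spectra: np.ndarray) -> np.ndarray:
        x = np.asarray(spectra, dtype=np.float64)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[-1] != self.spec.input_bands:
            raise ValueError(
                f"expected {self.spec.input_bands} bands, got {x.shape[-1]}")
        return self.forward(x[:, None, :], training=False)

    # -- plumbing --------------------------------------------------------
    def params(self, trainable_only: bool = False) -> list[nn.Param]:
        return (self.backbone.params(trainable_only)
                + self.head.params(trainable_only))

    def zero_grad(self) -> None:
        self.backbone.zero_grad()
        self.head.zero_grad()

    def n_params(self) -> int:
        return self.backbone.n_params() + self.head.n_params()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {**self.backbone.state_dict(), **self.head.state_dict()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self.backbone.load_state_dict(state)
        self.head.load_state_dict(state)

    def copy(self) -> "SpectralCNN":
        return copy.deepcopy(self)

    def last_relu_index(self) -> int:
        """Backbone index of the last conv block's ReLU (the saliency target)."""
        for i in range(len(self.backbone.layers) - 1, -1, -1):
            if isinstance(self.backbone.layers[i], nn.ReLU):
                return i
        raise RuntimeError("backbone has no ReLU layer")


def build_cnn(spec: CNNSpec | str, seed: int = 0) -> SpectralCNN:
    """Construct an untrained CNN from a spec or a variety preset name."""
    if isinstance(spec, str):
        try:
            spec = PRESETS[spec]
        except KeyError:
            raise ValueError(f"unknown variety preset {spec!r}; "
                             f"choose from {sorted(PRESETS)}") from None
    return SpectralCNN(spec, rng=np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """Fit results: the best-validation checkpoint plus training history."""

    model: SpectralCNN
    spec: CNNSpec
    history: pd.DataFrame       # epoch, train_loss, train_acc, val_loss, val_acc
    best_epoch: int
    seed: int | None = None
    domain: str = ""

    @property
    def best_val_accuracy(self) -> float:
        return float(self.history["val_acc"].iloc[self.best_epoch])

    def predict(self, spectra: np.ndarray) -> np.ndarray:
        return predict(self, spectra)[0]

    def predict_scores(self, spectra: np.ndarray) -> np.ndarray:
        return predict(self, spectra)[1]

    def accuracy(self, spectra: np.ndarray, labels: np.ndarray) -> float:
        return float((self.predict(spectra) == np.asarray(labels)).mean())

    def summary(self) -> str:
        lines = [
            "Spectral CNN fit results",
            "========================",
            f"domain:          {self.domain or '-'}",
            f"conv blocks:     {len(self.spec.conv_channels)} "
            f"{self.spec.conv_channels}",
            f"parameters:      {self.model.n_params()}",
            f"epochs run:      {len(self.history)}",
            f"best epoch:      {self.best_epoch}",
            f"train acc @best: {self.history['train_acc'].iloc[self.best_epoch]:.4f}",
            f"val acc @best:   {self.history['val_acc'].iloc[self.best_epoch]:.4f}",
        ]
        return "\n".join(lines)

    def save(self, path: str) -> None:
        """Checkpoint: parameters as .npz, spec/seed/history as sidecar JSON."""
        import dataclasses
        import json
        from pathlib import Path

        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.model.state_dict())
        sidecar = {
            "spec": dataclasses.asdict(self.spec),
            "seed": self.seed,
            "domain": self.domain,
            "best_epoch": int(self.best_epoch),
            "history": self.history.to_dict(orient="list"),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_trained_model(path: str) -> TrainedModel:
    """Rebuild a TrainedModel from a checkpoint written by ``save``."""
    import json
    from pathlib import Path

    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    raw_spec = sidecar["spec"]
    for key in ("conv_channels", "pools", "fc_hidden"):
        raw_spec[key] = tuple(raw_spec[key])
    spec = CNNSpec(**raw_spec)
    model = SpectralCNN(spec)
    with np.load(path.with_suffix(".npz")) as state:
        model.load_state_dict({k: state[k] for k in state.files})
    return TrainedModel(model=model, spec=spec,
                        history=pd.DataFrame(sidecar["history"]),
                        best_epoch=sidecar["best_epoch"],
                        seed=sidecar["seed"], domain=sidecar["domain"])


def _eval_metrics(model: SpectralCNN, X: np.ndarray, y: np.ndarray
                  ) -> tuple[float, float]:
    logits = model.forward(X[:, None, :], training=False)
    loss, _ = nn.cross_entropy(logits, y)
    acc = float((logits.argmax(axis=1) == y).mean())
    return loss, acc


def train_cnn(model: SpectralCNN, X_train: np.ndarray, y_train: np.ndarray,
              X_val: np.ndarray, y_val: np.ndarray,
              spec: CNNSpec | None = None, seed: int = 0,
              weight_decay: float = 0.0, domain: str = "",
              params: list[nn.Param] | None = None) -> TrainedModel:
    """Adam / cross-entropy training with per-epoch metrics and a
    best-validation-accuracy checkpoint. Fully deterministic given ``seed``.

    ``params`` restricts optimisation to a subset (used by fine-tuning);
    by default every trainable parameter is optimised.
    """
    spec = spec or model.spec
    X_train = np.asarray(X_train, dtype=np.float64)
    X_val = np.asarray(X_val, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=np.int64)
    y_val = np.asarray(y_val, dtype=np.int64)
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("training and validation splits must be non-empty")

    rng = np.random.default_rng(seed)
    opt = nn.Adam(params if params is not None else model.params(trainable_only=True),
                  lr=spec.learning_rate, weight_decay=weight_decay)
    records = []
    best_state, best_acc, best_epoch = model.state_dict(), -1.0, 0
    n = len(X_train)
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        for start in range(0, n, spec.batch_size):
            idx = order[start:start + spec.batch_size]
            if len(idx) < 2:
                continue  # BN needs more than one sample
            xb = X_train[idx][:, None, :]
            logits = model.forward(xb, training=True, rng=rng)
            _, grad = nn.cross_entropy(logits, y_train[idx])
            model.zero_grad()
            grad_feats = model.head.backward(grad)
            model.backbone.backward(grad_feats)
            opt.step()
        train_loss, train_acc = _eval_metrics(model, X_train, y_train)
        val_loss, val_acc = _eval_metrics(model, X_val, y_val)
        records.append((epoch, train_loss, train_acc, val_loss, val_acc))
        if val_acc > best_acc:
            best_acc, best_epoch = val_acc, epoch
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    history = pd.DataFrame(records, columns=["epoch", "train_loss", "train_acc",
                                             "val_loss", "val_acc"])
    return TrainedModel(model=model, spec=spec, history=history,
                        best_epoch=best_epoch, seed=seed, domain=domain)


class VigorCNN:
    """Estimator facade: configure from a spec/preset, ``fit`` to data."""

    def __init__(self, spec: CNNSpec | str = "yongyou12", epochs: int | None = None):
        if isinstance(spec, str):
            spec = PRESETS[spec]
        if epochs is not None:
            spec = replace(spec, epochs=epochs)
        self.spec = spec

    def fit(self, X_train, y_train, X_val, y_val, seed: int = 0,
            domain: str = "") -> TrainedModel:
        model = build_cnn(self.spec, seed=seed)
        return train_cnn(model, X_train, y_train, X_val, y_val,
                         spec=self.spec, seed=seed, domain=domain)


def predict(trained: TrainedModel | SpectralCNN, spectra: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    """Class labels and softmax scores for a batch of spectra."""
    model = trained.model if isinstance(trained, TrainedModel) else trained
    logits = model.logits(spectra)
    scores = nn.softmax(logits)
    return logits.argmax(axis=1), scores


# ---------------------------------------------------------------------------
# reference classifiers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BaselineConfig:
    """Hyperparameters of the three reference classifiers."""

    lr_C: float = 1000.0
    lr_penalty: str = "l2"
    xgb_reg_alpha: float = 0.1
    xgb_reg_lambda: float = 0.1
    xgb_max_depth: int = 2
    svm_kernels: tuple[str, ...] = ("rbf", "poly")
    svm_C_grid: tuple[float, ...] = (1, 10, 100, 1000, 10000)
    svm_gamma_grid: tuple[float, ...] = (1, 0.1, 0.01, 0.001)


@dataclass
class BaselineResults:
    models: dict[str, object]
    scaler: StandardScaler
    accuracies: dict[str, dict[str, float]]   # model -> split -> accuracy
    svm_best: dict[str, object]
    n_svm_candidates: int

    def predict(self, name: str, spectra: np.ndarray) -> np.ndarray:
        return self.models[name].predict(self.scaler.transform(spectra))


def fit_baselines(X_train, y_train, X_val, y_val,
                  config: BaselineConfig = BaselineConfig(),
                  seed: int = 0) -> BaselineResults:
    """LR and XGBoost at fixed hyperparameters; SVM chosen by grid search over
    the kernel/C/gamma grids on validation accuracy. Inputs are standardized
    per band with training-set statistics only."""
    y_train = np.asarray(y_train)
    y_val = np.asarray(y_val)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training data has a single class")
    scaler = StandardScaler().fit(X_train)
    Xtr = scaler.transform(X_train)
    Xva = scaler.transform(X_val)

    if config.lr_penalty != "l2":
        raise ValueError("only the L2 penalty is supported for LR")
    lr = LogisticRegression(C=config.lr_C, max_iter=5000)  # l2 is the default
    lr.fit(Xtr, y_train)

    xgb = XGBClassifier(reg_alpha=config.xgb_reg_alpha,
                        reg_lambda=config.xgb_reg_lambda,
                        max_depth=config.xgb_max_depth,
                        n_jobs=1, random_state=seed, verbosity=0)
    xgb.fit(Xtr, y_train)

    best = None
    n_candidates = 0
    for kernel in config.svm_kernels:
        for C in config.svm_C_grid:
            for gamma in config.svm_gamma_grid:
                n_candidates += 1
                cand = SVC(kernel=kernel, C=C, gamma=gamma, random_state=seed)
                cand.fit(Xtr, y_train)
                acc = float((cand.predict(Xva) == y_val).mean())
                key = (acc,)
                if best is None or key > best[0]:
                    best = (key, cand, {"kernel": kernel, "C": C, "gamma": gamma})
    svm, svm_params = best[1], best[2]

    models = {"LR": lr, "XGBoost": xgb, "SVC": svm}
    accs = {}
    for name, mdl in models.items():
        accs[name] = {
            "train": float((mdl.predict(Xtr) == y_train).mean()),
            "val": float((mdl.predict(Xva) == y_val).mean()),
        }
    return BaselineResults(models=models, scaler=scaler, accuracies=accs,
                           svm_best=svm_params, n_svm_candidates=n_candidates)
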