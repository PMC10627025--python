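"""Metrics, one-vs-rest confusion semantics, table-style reports, and the
end-to-end experiment orchestrator.

Accuracies are reported in percent with half-up rounding to 2 decimals and
non-viable rates to 4 decimals, matching the published table formats. The
confusion counts use one-vs-rest semantics per aging class: for class k, TP
counts seeds of class k predicted as k, FN seeds of class k predicted as
another class, FP seeds of another class predicted as k, and TN the rest.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import GerminationRecord
from .models import PRESETS, VigorCNN, fit_baselines
from .preprocess import split_dataset
from .synthetic import default_styles, make_domain_dataset, make_wavelength_grid
from .transfer import TransferConfig, fine_tune, train_with_mixstyle

__all__ = [
    "round_half_up", "ConfusionCounts", "confusion_counts", "accuracy",
    "non_viable_rate", "MetricsReport", "transfer_comparison",
    "ExperimentConfig", "run_experiment", "ExperimentResult",
]

N_CLASSES = 3

logger = logging.getLogger("seedvigor")


def round_half_up(x: float, decimals: int) -> float:
    """Round-half-up (0.005 -> 0.01), as in the published tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest TP/TN/FP/FN per aging class."""

    per_class: dict[int, dict[str, int]]
    n: int

    def precision_recall_f1(self) -> dict[int, dict[str, float]]:
        out = {}
        for cls, c in self.per_class.items():
            prec = c["TP"] / (c["TP"] + c["FP"]) if c["TP"] + c["FP"] else 0.0
            rec = c["TP"] / (c["TP"] + c["FN"]) if c["TP"] + c["FN"] else 0.0
            f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            out[cls] = {"precision": prec, "recall": rec, "f1": f1}
        return out


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    if y_true.size and not (np.isin(y_true, range(N_CLASSES)).all()
                            and np.isin(y_pred, range(N_CLASSES)).all()):
        raise ValueError("labels must be in {0, 1, 2}")
    per_class = {}
    for cls in range(N_CLASSES):
        tp = int(((y_true == cls) & (y_pred == cls)).sum())
        fn = int(((y_true == cls) & (y_pred != cls)).sum())
        fp = int(((y_true != cls) & (y_pred == cls)).sum())
        tn = int(((y_true != cls) & (y_pred != cls)).sum())
        per_class[cls] = {"TP": tp, "TN": tn, "FP": fp, "FN": fn}
    return ConfusionCounts(per_class=per_class, n=len(y_true))


def accuracy(y_true, y_pred) -> float:
    """Classification accuracy in percent, half-up rounded to 2 decimals."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    if y_true.size == 0:
        raise ValueError("cannot compute accuracy of an empty set")
    return round_half_up(100.0 * float((y_true == y_pred).mean()), 2)


def non_viable_rate(record: GerminationRecord | tuple[int, int]) -> float:
    """Non-viable fraction of a germination cohort, 4-decimal half-up."""
    if isinstance(record, GerminationRecord):
        n_nonviable, n_total = record.n_nonviable, record.n_total
    else:
        n_nonviable, n_total = record
    if n_total <= 0:
        raise ValueError("cohort size must be positive")
    return round_half_up(n_nonviable / n_total, 4)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricsReport:
    """Per-split accuracies in percent (2-decimal)."""

    train: float
    val: float
    test: float

    def as_dict(self) -> dict[str, float]:
        return {"train": self.train, "val": self.val, "test": self.test}


def transfer_comparison(report: MetricsReport, baseline: MetricsReport
                        ) -> dict[str, float]:
    """Signed per-split deltas (transfer minus baseline), 2-decimal."""
    return {split: round_half_up(
        report.as_dict()[split] - baseline.as_dict()[split], 2)
        for split in ("train", "val", "test")}


def format_delta(delta: float) -> str:
    return f"{delta:+.2f}"


# ---------------------------------------------------------------------------
# experiment orchestration
# ---------------------------------------------------------------------------

class ConfigError(ValueError):
    """Configuration problem, reported with the offending field path."""


_TRANSFER_KEYS = {"modes", "alpha", "learning_rate", "weight_decay", "epochs"}
_TOP_KEYS = {"seed", "varieties", "n_per_class", "epochs", "include_baselines",
             "transfer", "saliency", "saliency_max_per_class", "outdir"}


@dataclass(frozen=True)
class ExperimentConfig:
    varieties: tuple[str, ...]
    seed: int = 0
    n_per_class: int = 200
    epochs: int = 200
    include_baselines: bool = False
    transfer_modes: tuple[str, ...] = ("fine_tune", "mixstyle")
    transfer_alpha: float = 0.1
    transfer_lr: float = 0.0003
    transfer_weight_decay: float = 0.0005
    transfer_epochs: int = 300
    saliency: bool = True
    saliency_max_per_class: int = 10
    outdir: str = "seedvigor_run"

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        if "varieties" not in raw or not raw["varieties"]:
            raise ConfigError("varieties: at least one variety is required")
        styles = default_styles()
        for i, v in enumerate(raw["varieties"]):
            if v not in styles:
                raise ConfigError(f"varieties[{i}]: unknown variety {v!r}; "
                                  f"choose from {sorted(styles)}")
        t = raw.get("transfer", {})
        unknown_t = set(t) - _TRANSFER_KEYS
        if unknown_t:
            raise ConfigError(f"transfer: unknown field(s): {sorted(unknown_t)}")
        modes = tuple(t.get("modes", ("fine_tune", "mixstyle")))
        for j, m in enumerate(modes):
            if m not in ("fine_tune", "mixstyle"):
                raise ConfigError(f"transfer.modes[{j}]: unknown mode {m!r}")
        n_per_class = int(raw.get("n_per_class", 200))
        if n_per_class < 6:
            raise ConfigError("n_per_class: must be at least 6")
        return cls(
            varieties=tuple(raw["varieties"]),
            seed=int(raw.get("seed", 0)),
            n_per_class=n_per_class,
            epochs=int(raw.get("epochs", 200)),
            include_baselines=bool(raw.get("include_baselines", False)),
            transfer_modes=modes,
            transfer_alpha=float(t.get("alpha", 0.1)),
            transfer_lr=float(t.get("learning_rate", 0.0003)),
            transfer_weight_decay=float(t.get("weight_decay", 0.0005)),
            transfer_epochs=int(t.get("epochs", 300)),
            saliency=bool(raw.get("saliency", True)),
            saliency_max_per_class=int(raw.get("saliency_max_per_class", 10)),
            outdir=str(raw.get("outdir", "seedvigor_run")),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))


def _derive_seed(base: int, *tags: str) -> int:
    """Stable per-task seed below 2^31, derived from the base seed and tags."""
    import zlib
    h = zlib.crc32("/".join(tags).encode())
    return int((base * 1_000_003 + h) % (2 ** 31 - 1))


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    source_reports: dict[str, dict[str, MetricsReport]]
    transfer_reports: dict[tuple[str, str, str], dict]
    outdir: Path
    trained: dict[str, object] = field(default_factory=dict)


def run_experiment(config: ExperimentConfig | dict | str | Path
                   ) -> ExperimentResult:
    """Simulate, preprocess, train per-variety models, run all ordered
    transfer pairs in the requested modes, summarize saliency, and write
    CSV reports. Byte-reproducible from config + seed."""
    if isinstance(config, (str, Path)):
        config = ExperimentConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = ExperimentConfig.from_dict(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    styles = default_styles()
    grid = make_wavelength_grid()

    datasets: dict[str, dict] = {}
    source_reports: dict[str, dict[str, MetricsReport]] = {}
    trained: dict[str, object] = {}
    rows = []
    for variety in config.varieties:
        t0 = time.perf_counter()
        data = make_domain_dataset(
            styles[variety], config.n_per_class,
            np.random.default_rng(_derive_seed(config.seed, "data", variety)),
            grid=grid)
        split = split_dataset(
            data, np.random.default_rng(_derive_seed(config.seed, "split", variety)))
        X, y = data.spectra, data.labels
        bundle = {
            "X": X, "y": y, "split": split,
            "train": (X[split.train], y[split.train]),
            "val": (X[split.val], y[split.val]),
            "test": (X[split.test], y[split.test]),
        }
        datasets[variety] = bundle

        est = VigorCNN(PRESETS[variety], epochs=config.epochs)
        fit = est.fit(*bundle["train"], *bundle["val"],
                      seed=_derive_seed(config.seed, "train", variety),
                      domain=variety)
        trained[variety] = fit
        report = MetricsReport(
            train=accuracy(bundle["train"][1], fit.predict(bundle["train"][0])),
            val=accuracy(bundle["val"][1], fit.predict(bundle["val"][0])),
            test=accuracy(bundle["test"][1], fit.predict(bundle["test"][0])))
        source_reports[variety] = {"CNN": report}
        rows.append((variety, "CNN", report.train, report.val, report.test))

        if config.include_baselines:
            base = fit_baselines(*bundle["train"], *bundle["val"],
                                 seed=_derive_seed(config.seed, "baseline", variety))
            for name in ("LR", "XGBoost", "SVC"):
                rep = MetricsReport(
                    train=accuracy(bundle["train"][1],
                                   base.predict(name, bundle["train"][0])),
                    val=accuracy(bundle["val"][1],
                                 base.predict(name, bundle["val"][0])),
                    test=accuracy(bundle["test"][1],
                                  base.predict(name, bundle["test"][0])))
                source_reports[variety][name] = rep
                rows.append((variety, name, rep.train, rep.val, rep.test))
        logger.info("stage=source_model variety=%s elapsed=%.2fs val=%.2f",
                    variety, time.perf_counter() - t0, report.val)

    pd.DataFrame(rows, columns=["variety", "model", "train", "val", "test"]
                 ).to_csv(outdir / "source_models.csv", index=False,
                          float_format="%.2f")

    transfer_reports: dict[tuple[str, str, str], dict] = {}
    for mode in config.transfer_modes:
        mode_rows = []
        for source in config.varieties:
            for target in config.varieties:
                if source == target:
                    continue
                t0 = time.perf_counter()
                tcfg = TransferConfig(
                    mode=mode, source_domain=source, target_domain=target,
                    alpha=config.transfer_alpha,
                    learning_rate=config.transfer_lr,
                    weight_decay=config.transfer_weight_decay,
                    epochs=config.transfer_epochs,
                    seed=_derive_seed(config.seed, "transfer", mode, source, target))
                tgt = datasets[target]
                if mode == "fine_tune":
                    fit = fine_tune(trained[source], *tgt["train"], *tgt["val"],
                                    tcfg)
                else:
                    fit = train_with_mixstyle(datasets[source]["train"],
                                              tgt["train"], tgt["val"],
                                              PRESETS[source], tcfg)
                src = datasets[source]
                rep = MetricsReport(
                    train=accuracy(tgt["train"][1], fit.predict(tgt["train"][0])),
                    val=accuracy(tgt["val"][1], fit.predict(tgt["val"][0])),
                    test=accuracy(tgt["test"][1], fit.predict(tgt["test"][0])))
                train_source = accuracy(src["train"][1],
                                        fit.predict(src["train"][0]))
                deltas = transfer_comparison(rep, source_reports[target]["CNN"])
                transfer_reports[(mode, source, target)] = {
                    "report": rep, "train_source": train_source,
                    "deltas": deltas, "fit": fit}
                mode_rows.append((source, target, train_source, rep.train,
                                  rep.val, rep.test, deltas["train"],
                                  deltas["val"], deltas["test"]))
                logger.info("stage=transfer mode=%s pair=%s->%s "
                            "elapsed=%.2fs val=%.2f", mode, source, target,
                            time.perf_counter() - t0, rep.val)
        pd.DataFrame(mode_rows,
                     columns=["source", "target", "train_source", "train_target",
                              "val", "test", "d_train", "d_val", "d_test"]
                     ).to_csv(outdir / f"transfer_{mode}.csv", index=False,
                              float_format="%.2f")

    if config.saliency:
        from .interpret import gradcampp_1d, saliency_summary
        for variety in config.varieties:
            t0 = time.perf_counter()
            bundle = datasets[variety]
            Xte, yte = bundle["test"]
            curves = []
            for cls in range(N_CLASSES):
                idx = np.flatnonzero(yte == cls)[:config.saliency_max_per_class]
                for i in idx:
                    curves.append(gradcampp_1d(trained[variety], Xte[i], cls))
            summary = saliency_summary(curves)
            frames = []
            for row, cls in enumerate(summary.classes):
                frames.append(pd.DataFrame({
                    "wavelength_nm": grid.retained_nm,
                    "class": cls,
                    "mean_weight": summary.mean[row],
                    "std_weight": summary.std[row]}))
            pd.concat(frames).to_csv(outdir / f"saliency_{variety}.csv",
                                     index=False, float_format="%.6f")
            logger.info("stage=saliency variety=%s elapsed=%.2fs", variety,
                        time.perf_counter() - t0)

    return ExperimentResult(config=config, source_reports=source_reports,
                            transfer_reports=transfer_reports, outdir=outdir,
                            trained=trained)
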