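"""The style-shift transfer benchmark.

Source and target datasets share the same 3-class absorption structure but
differ by a configurable domain-style shift (baseline offset, gain and
curvature). A plain CNN trained on the source loses accuracy on the target;
the benchmark measures how much of that source-to-target gap each transfer
strategy (frozen-backbone fine-tuning, MixStyle) recovers:

    recovery = (transfer target acc - plain target acc)
               / (source val acc - plain target acc)

averaged over seeds. Sizes default to desk scale so a multi-seed run stays
within a single-CPU budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import CNNSpec, VigorCNN
from .preprocess import split_dataset
from .synthetic import make_domain_dataset, make_wavelength_grid, style_pair
from .transfer import TransferConfig, fine_tune, train_with_mixstyle

__all__ = ["TransferBenchmarkResult", "run_transfer_benchmark"]

#: benchmark architecture: shallow preset keeps multi-seed runs fast
BENCH_SPEC = CNNSpec(conv_channels=(16, 32), learning_rate=0.005)

#: style-shift magnitude of the headline benchmark; large enough that the
#: plain CNN's target accuracy falls well below its source accuracy
BENCH_SHIFT = 0.03


@dataclass
class TransferBenchmarkResult:
    """Per-seed accuracies and gap-recovery fractions."""

    table: pd.DataFrame   # seed, source_val, plain_target, finetune, mixstyle

    @property
    def mean_gap(self) -> float:
        return float((self.table["source_val"] - self.table["plain_target"]).mean())

    def recovery(self, mode: str) -> float:
        gaps = self.table["source_val"] - self.table["plain_target"]
        gains = self.table[mode] - self.table["plain_target"]
        return float((gains / gaps).mean())


def run_transfer_benchmark(seeds: list[int] | np.ndarray,
                           shift: float = BENCH_SHIFT,
                           n_per_class: int = 100,
                           epochs: int = 30,
                           finetune_epochs: int = 150,
                           mixstyle_epochs: int = 300,
                           spec: CNNSpec = BENCH_SPEC,
                           alpha: float = 0.1,
                           transfer_lr: float = 0.0005,
                           weight_decay: float = 0.0005
                           ) -> TransferBenchmarkResult:
    """Run the benchmark over the given seeds and return the result table."""
    grid = make_wavelength_grid()
    rows = []
    for seed in seeds:
        seed = int(seed)
        src_style, tgt_style = style_pair(shift)
        rng = np.random.default_rng(seed)
        src = make_domain_dataset(src_style, n_per_class, rng, grid=grid)
        tgt = make_domain_dataset(tgt_style, n_per_class, rng, grid=grid)
        s_split = split_dataset(src, np.random.default_rng(seed + 1))
        t_split = split_dataset(tgt, np.random.default_rng(seed + 2))
        sX, sy = src.spectra, src.labels
        tX, ty = tgt.spectra, tgt.labels
        s_train = (sX[s_split.train], sy[s_split.train])
        s_val = (sX[s_split.val], sy[s_split.val])
        t_train = (tX[t_split.train], ty[t_split.train])
        t_val = (tX[t_split.val], ty[t_split.val])

        plain = VigorCNN(spec, epochs=epochs).fit(*s_train, *s_val, seed=seed,
                                                  domain=src_style.name)
        source_val = plain.accuracy(*s_val)
        plain_target = plain.accuracy(*t_val)

        ft_cfg = TransferConfig(mode="fine_tune", source_domain=src_style.name,
                                target_domain=tgt_style.name,
                                learning_rate=transfer_lr,
                                weight_decay=weight_decay,
                                epochs=finetune_epochs, seed=seed)
        ft = fine_tune(plain, *t_train, *t_val, ft_cfg)
        ft_target = ft.accuracy(*t_val)

        mx_cfg = TransferConfig(mode="mixstyle", source_domain=src_style.name,
                                target_domain=tgt_style.name, alpha=alpha,
                                learning_rate=transfer_lr,
                                weight_decay=weight_decay,
                                epochs=mixstyle_epochs, seed=seed)
        mx = train_with_mixstyle(s_train, t_train, t_val, spec, mx_cfg)
        mx_target = mx.accuracy(*t_val)

        rows.append((seed, source_val, plain_target, ft_target, mx_target))
    table = pd.DataFrame(rows, columns=["seed", "source_val", "plain_target",
                                        "fine_tune", "mixstyle"])
    return TransferBenchmarkResult(table=table)


# ---------------------------------------------------------------------------
# saliency localization benchmark
# ---------------------------------------------------------------------------

#: construction where the 1450 nm dip is the only class-separating feature
LOC_STYLE_DEPTHS = {1450.0: (0.06, 0.11, 0.16)}
LOC_WINDOW_NM = (1400.0, 1500.0)


def run_localization_benchmark(seeds: list[int] | np.ndarray,
                               n_per_class: int = 60,
                               epochs: int = 25,
                               spec: CNNSpec = BENCH_SPEC) -> pd.DataFrame:
    """Train CNNs on data where only the 1450 nm absorption separates the
    classes and measure how much of the class-mean saliency curve's mass falls
    in the 1400-1500 nm window.

    The most-aged class (deepest absorption) is the probe: its class evidence
    is the *presence* of the dip. The not-aged class's evidence is the dip's
    absence — negative evidence that ReLU-gated channel weights cannot
    localize, a known blind spot of class-activation methods (recorded in the
    methods note).

    Returns a per-seed table with the saliency mass fraction and the top
    high-weight interval of the class-mean curve.
    """
    from .interpret import gradcampp_1d, saliency_summary, top_band_regions
    from .synthetic import VarietyStyle

    grid = make_wavelength_grid()
    style = VarietyStyle(name="localization", feature_depths=LOC_STYLE_DEPTHS)
    nm = grid.retained_nm
    window = (nm >= LOC_WINDOW_NM[0]) & (nm <= LOC_WINDOW_NM[1])
    probe_class = 2
    rows = []
    for seed in seeds:
        seed = int(seed)
        data = make_domain_dataset(style, n_per_class,
                                   np.random.default_rng(seed + 100), grid=grid)
        split = split_dataset(data, np.random.default_rng(seed))
        X, y = data.spectra, data.labels
        fit = VigorCNN(spec, epochs=epochs).fit(
            X[split.train], y[split.train], X[split.val], y[split.val],
            seed=seed)
        curves = [gradcampp_1d(fit, X[i], int(y[i])) for i in split.test]
        summary = saliency_summary(curves)
        row = list(summary.classes).index(probe_class)
        mean_curve = summary.mean[row]
        mass = float(mean_curve[window].sum() / mean_curve.sum())
        regions = top_band_regions(mean_curve / mean_curve.max(), grid, 0.5)
        peak_nm = float(nm[int(np.argmax(mean_curve))])
        top = next((r for r in regions if r[0] <= peak_nm <= r[1]), regions[0])
        rows.append((seed, mass, top[0], top[1], fit.best_val_accuracy))
    return pd.DataFrame(rows, columns=["seed", "mass_1400_1500",
                                       "top_interval_lo_nm",
                                       "top_interval_hi_nm", "val_acc"])
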