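"""Metric semantics, table arithmetic and experiment orchestration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seedvigor.containers import GerminationRecord
from seedvigor.evaluate import (ConfigError, ExperimentConfig, MetricsReport,
                                accuracy, confusion_counts, non_viable_rate,
                                round_half_up, run_experiment,
                                transfer_comparison)
from seedvigor.reference_tables import (GERMINATION_TABLE, SEED_COUNTS)


class TestConfusionCounts:
    def test_perfect_prediction(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        cc = confusion_counts(y, y)
        for cls in range(3):
            assert cc.per_class[cls]["FP"] == 0
            assert cc.per_class[cls]["FN"] == 0

    def test_all_predicted_class0_balanced_truth(self):
        y_true = np.repeat([0, 1, 2], 10)
        y_pred = np.zeros(30, dtype=int)
        cc = confusion_counts(y_true, y_pred)
        assert cc.per_class[0] == {"TP": 10, "TN": 0, "FP": 20, "FN": 0}

    def test_single_correct_sample(self):
        cc = confusion_counts([1], [1])
        assert cc.per_class[1]["TP"] == 1
        assert cc.per_class[0]["TN"] == 1
        assert cc.per_class[2]["TN"] == 1

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            confusion_counts([0, 1], [0])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 2), st.integers(0, 2)),
                    min_size=1, max_size=60))
    def test_consistency_identities(self, pairs):
        """TP+TN+FP+FN = N per class; sum of TPs = number correct."""
        y_true = np.array([p[0] for p in pairs])
        y_pred = np.array([p[1] for p in pairs])
        cc = confusion_counts(y_true, y_pred)
        n_correct = int((y_true == y_pred).sum())
        assert sum(cc.per_class[c]["TP"] for c in range(3)) == n_correct
        for cls in range(3):
            assert sum(cc.per_class[cls].values()) == len(pairs)


class TestAccuracy:
    def test_all_correct(self):
        assert accuracy([0, 1, 2], [0, 1, 2]) == 100.00

    def test_271_of_300(self):
        y_true = np.zeros(300, dtype=int)
        y_pred = y_true.copy()
        y_pred[:29] = 1
        assert accuracy(y_true, y_pred) == 90.33

    def test_none_correct(self):
        assert accuracy([0, 0], [1, 1]) == 0.00

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            accuracy([], [])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 3, 50)
        y_pred = rng.integers(0, 3, 50)
        perm = rng.permutation(50)
        assert accuracy(y_true, y_pred) == accuracy(y_true[perm], y_pred[perm])

    def test_half_up_rounding(self):
        assert round_half_up(90.005, 2) == 90.01
        assert round_half_up(0.17165, 4) == 0.1717


class TestNonViableRate:
    @pytest.mark.parametrize("count,total,expected", [
        (103, 600, 0.1717),
        (93, 500, 0.1860),
        (0, 600, 0.0000),
    ])
    def test_published_cells_and_zero(self, count, total, expected):
        assert non_viable_rate((count, total)) == expected

    def test_record_input(self):
        rec = GerminationRecord(variety="yongyou12", aging_class="aged_96h",
                                n_total=600, n_nonviable=291)
        assert non_viable_rate(rec) == 0.4850

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            non_viable_rate((0, 0))


class TestTransferComparison:
    def test_published_example_row(self):
        transferred = MetricsReport(train=92.50, val=86.67, test=90.00)
        baseline = MetricsReport(train=94.25, val=87.00, test=87.67)
        deltas = transfer_comparison(transferred, baseline)
        assert deltas == {"train": -1.75, "val": -0.33, "test": +2.33}

    def test_self_comparison_vanishes(self):
        rep = MetricsReport(train=84.67, val=80.00, test=75.50)
        assert all(v == 0.0 for v in transfer_comparison(rep, rep).values())

    def test_antisymmetry(self):
        a = MetricsReport(train=84.67, val=81.00, test=79.00)
        b = MetricsReport(train=88.21, val=78.75, test=83.40)
        d_ab = transfer_comparison(a, b)
        d_ba = transfer_comparison(b, a)
        for split in ("train", "val", "test"):
            assert d_ab[split] == -d_ba[split]


class TestExperimentConfig:
    def test_unknown_field_reported_with_path(self):
        with pytest.raises(ConfigError, match="unknown config field"):
            ExperimentConfig.from_dict({"varieties": ["yongyou12"], "foo": 1})

    def test_unknown_variety(self):
        with pytest.raises(ConfigError, match=r"varieties\[0\]"):
            ExperimentConfig.from_dict({"varieties": ["bad_variety"]})

    def test_unknown_transfer_mode(self):
        with pytest.raises(ConfigError, match=r"transfer\.modes\[0\]"):
            ExperimentConfig.from_dict({"varieties": ["yongyou12"],
                                        "transfer": {"modes": ["bogus"]}})


@pytest.fixture(scope="module")
def tiny_experiment(tmp_path_factory):
    cfg = {
        "seed": 5,
        "varieties": ["yongyou12", "yongyou1540"],
        "n_per_class": 24,
        "epochs": 6,
        "transfer": {"modes": ["fine_tune", "mixstyle"], "epochs": 6},
        "saliency": True,
        "saliency_max_per_class": 2,
        "outdir": str(tmp_path_factory.mktemp("exp") / "run"),
    }
    return cfg, run_experiment(cfg)


class TestRunExperiment:
    def test_report_combinatorics(self, tiny_experiment):
        _, result = tiny_experiment
        assert set(result.source_reports) == {"yongyou12", "yongyou1540"}
        modes = {k[0] for k in result.transfer_reports}
        assert modes == {"fine_tune", "mixstyle"}
        # 2 varieties -> 2 ordered pairs per mode
        assert len(result.transfer_reports) == 4

    def test_twelve_ordered_pairs_for_four_varieties(self):
        varieties = list(SEED_COUNTS)
        names = sorted({v for v, _ in SEED_COUNTS})
        pairs = [(s, t) for s in names for t in names if s != t]
        assert len(pairs) == 12

    def test_report_files_written(self, tiny_experiment):
        _, result = tiny_experiment
        assert (result.outdir / "source_models.csv").exists()
        assert (result.outdir / "transfer_fine_tune.csv").exists()
        assert (result.outdir / "transfer_mixstyle.csv").exists()
        assert (result.outdir / "saliency_yongyou12.csv").exists()

    def test_rerun_byte_identical(self, tiny_experiment, tmp_path):
        cfg, result = tiny_experiment
        cfg2 = dict(cfg, outdir=str(tmp_path / "rerun"))
        result2 = run_experiment(cfg2)
        for name in ("source_models.csv", "transfer_fine_tune.csv",
                     "transfer_mixstyle.csv", "saliency_yongyou12.csv"):
            b1 = (result.outdir / name).read_bytes()
            b2 = (result2.outdir / name).read_bytes()
            assert b1 == b2


def test_published_germination_table_consistency():
    """Every published cohort's printed rate equals count/total at 4 decimals."""
    for key, (count, printed_rate) in GERMINATION_TABLE.items():
        assert non_viable_rate((count, SEED_COUNTS[key])) == printed_rate
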