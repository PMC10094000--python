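"""Experiment harness: hybrid pipeline plumbing, ablation and reports.

These tests run the real pipeline end to end on a reduced protocol
(5 days x 9 classes x 2 replicates, short backbone schedules) to keep the
suite fast; the full-protocol runs live in the acceptance tests.
"""

import numpy as np
import pytest

from enoseml.backbone import TrainConfig
from enoseml.classify import GridSpec, fit_hybrid, predict_hybrid
from enoseml.data import SplitSpec, assemble_dataset, day_split
from enoseml.evaluation import run_ablation, run_experiment
from enoseml.features import to_tensor_set

SMALL_SPLIT = SplitSpec(train_days={1, 2, 3, 4}, test_days={5})
FAST_TRAIN = TrainConfig(epochs=4, batch_size=32, seed=0)
FAST_GRID = GridSpec(num_leaves_grid=(8,), learning_rate_grid=(0.1,), cv_folds=2)


@pytest.fixture(scope="module")
def small_hybrid(small_protocol_set):
    train, test = day_split(small_protocol_set, SMALL_SPLIT)
    Xtr, ytr, _ = to_tensor_set(train)
    Xte, yte, _ = to_tensor_set(test)
    model = fit_hybrid(Xtr, ytr, train_cfg=FAST_TRAIN, grid=FAST_GRID, seed=0)
    return model, Xtr, ytr, Xte, yte


class TestHybrid:
    def test_training_duplicate_predicted_as_its_training_label(self, small_hybrid):
        model, Xtr, ytr, _, _ = small_hybrid
        pred = predict_hybrid(model, Xtr[:10].copy())
        assert list(pred) == list(ytr[:10])

    def test_chosen_grid_point_comes_from_the_grid(self, small_hybrid):
        model, *_ = small_hybrid
        assert model.best_params == (8, 0.1)
        assert len(model.cv_table) == 1

    def test_no_test_set_leakage(self, small_hybrid, small_protocol_set):
        """Refitting with the test set deleted gives the identical model."""
        model, *_ = small_hybrid
        train, _ = day_split(small_protocol_set, SMALL_SPLIT)
        Xtr, ytr, _ = to_tensor_set(train)
        refit = fit_hybrid(Xtr, ytr, train_cfg=FAST_TRAIN, grid=FAST_GRID, seed=0)
        assert refit.backbone.parameter_checksum() == model.backbone.parameter_checksum()
        assert refit.best_params == model.best_params


class TestExperimentReports:
    def test_two_model_report_is_2_rows_by_5_metrics(self, small_protocol_set):
        report = run_experiment(
            small_protocol_set, "A", models=["knn", "resnet_gbm"],
            split=SMALL_SPLIT, train_cfg=FAST_TRAIN, grid=FAST_GRID, seed=0,
        )
        table = report.table()
        assert table.shape == (2, 5)
        assert list(table.columns) == ["accuracy", "sensitivity", "precision", "f1", "kappa"]
        assert ((table >= -1) & (table <= 1)).all().all()

    def test_per_class_f1_keys_for_commercial_variant(self, small_protocol_set):
        report = run_experiment(
            small_protocol_set, "B", models=["knn"], split=SMALL_SPLIT, seed=0,
        )
        assert set(report.per_class_f1_table().columns) == {"CL1", "CL2", "CL3"}

    def test_unknown_model_rejected(self, small_protocol_set):
        with pytest.raises(ValueError, match="unknown model"):
            run_experiment(small_protocol_set, "A", models=["perceptron"],
                           split=SMALL_SPLIT, seed=0)

    def test_report_files_written(self, small_protocol_set, tmp_path):
        report = run_experiment(
            small_protocol_set, "B", models=["knn"], split=SMALL_SPLIT, seed=0,
        )
        out = tmp_path / "report.csv"
        report.write(out)
        assert out.exists() and out.with_suffix(".txt").exists()
        assert "kappa" in out.read_text()

    def test_balanced_split_makes_sensitivity_equal_accuracy(self, small_protocol_set):
        report = run_experiment(
            small_protocol_set, "C", models=["knn"], split=SMALL_SPLIT, seed=0,
        )
        m = report.metrics["knn"]
        assert m.sensitivity == pytest.approx(m.accuracy, abs=1e-12)


@pytest.fixture(scope="module")
def paired_sets():
    from enoseml.synthetic import SyntheticConfig, default_signature_matrix, simulate_protocol

    out = {}
    for mode in ("well_separated", "overlapping"):
        cfg = SyntheticConfig(
            signature=default_signature_matrix(mode), seed=3,
            days=5, replicates_per_day=2,
        )
        out[mode] = simulate_protocol(cfg)
    return out


class TestSeparationContrast:
    """Paired runs: the well-separated signature regime is learnable, the
    overlapping regime collapses toward chance."""

    @pytest.mark.parametrize("kind", ["svm_rbf", "random_forest", "knn", "xgb", "mds_svm", "bpnn"])
    def test_baselines_learn_separated_and_degrade_on_overlap(self, paired_sets, kind):
        from enoseml.classify import BaselineSpec, fit_baseline, predict_baseline
        from enoseml.features import last20_matrix

        accs = {}
        for mode, mset in paired_sets.items():
            train, test = day_split(mset, SMALL_SPLIT)
            Xtr, ytr, _ = last20_matrix(train)
            Xte, yte, _ = last20_matrix(test)
            model = fit_baseline(Xtr, ytr, BaselineSpec(kind), seed=0)
            accs[mode] = (predict_baseline(model, Xte) == yte).mean()
        assert accs["well_separated"] >= 0.9
        assert accs["overlapping"] < accs["well_separated"]

    def test_hybrid_degrades_on_overlapping_signatures(self, paired_sets):
        accs = {}
        for mode, mset in paired_sets.items():
            train, test = day_split(mset, SMALL_SPLIT)
            Xtr, ytr, _ = to_tensor_set(train)
            Xte, yte, _ = to_tensor_set(test)
            model = fit_hybrid(Xtr, ytr, train_cfg=FAST_TRAIN, grid=FAST_GRID, seed=0)
            accs[mode] = (predict_hybrid(model, Xte) == np.array(yte)).mean()
        # absolute performance at full protocol scale is asserted in the
        # acceptance tests; at this tiny scale the robust property is the
        # separation-dependent contrast
        assert accs["overlapping"] <= accs["well_separated"] - 0.3


class TestAblation:
    def test_three_arms_and_determinism(self, small_protocol_set):
        data = assemble_dataset(small_protocol_set, "C")
        kw = dict(split=SMALL_SPLIT, train_cfg=FAST_TRAIN, grid=FAST_GRID, seed=0)
        r1 = run_ablation(data, **kw)
        assert set(r1.metrics) == {"gbdt", "resnet", "resnet_gbm"}
        r2 = run_ablation(data, **kw)
        assert r1.table().equals(r2.table())
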