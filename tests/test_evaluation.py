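import numpy as np
import pytest

from glapred.evaluation import (
    ConfusionCounts,
    compute_metrics,
    cross_validate,
    feature_combination_eval,
    independent_test,
    kfold_split,
    truncate3,
    window_sweep,
)
from glapred.model import SvmConfig, fit_predictor
from glapred.sequence_data import WindowConfig, extract_all_fragments
from glapred.synthetic import GeneratorSpec, generate


class TestComputeMetrics:
    def test_cross_validation_worked_example(self):
        """Pooled five-fold counts for the best model (302 positives, 567
        negatives) reproduce the printed metrics at 3-decimal truncation."""
        c = ConfusionCounts(tp=260, fn=42, fp=51, tn=516)
        assert c.tp + c.fn == 302 and c.tn + c.fp == 567
        report = compute_metrics(c)
        assert report.truncated() == {
            "precision": 0.836,
            "sensitivity": 0.860,
            "specificity": 0.910,
            "accuracy": 0.892,
            "mcc": 0.765,
        }

    def test_independent_testing_worked_example(self):
        """Independent-test counts (60 positives, 99 negatives) reproduce the
        printed metrics at 3-decimal truncation."""
        c = ConfusionCounts(tp=50, fn=10, fp=18, tn=81)
        assert c.tp + c.fn == 60 and c.tn + c.fp == 99
        report = compute_metrics(c)
        assert report.truncated() == {
            "precision": 0.735,
            "sensitivity": 0.833,
            "specificity": 0.818,
            "accuracy": 0.823,
            "mcc": 0.638,
        }

    def test_perfect_prediction(self):
        report = compute_metrics(ConfusionCounts(tp=5, tn=5))
        assert (
            report.precision
            == report.sensitivity
            == report.specificity
            == report.accuracy
            == report.mcc
            == 1.0
        )

    def test_random_prediction_mcc_zero(self):
        report = compute_metrics(ConfusionCounts(tp=1, fn=1, fp=1, tn=1))
        assert report.mcc == 0.0

    def test_degenerate_denominator_mcc_zero(self):
        # no predicted positives: TP+FP = 0
        report = compute_metrics(ConfusionCounts(tp=0, fn=3, fp=0, tn=7))
        assert report.mcc == 0.0 and report.precision == 0.0

    def test_all_wrong_mcc_minus_one(self):
        report = compute_metrics(ConfusionCounts(tp=0, fn=4, fp=4, tn=0))
        assert report.mcc == -1.0

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts())

    def test_metrics_match_brute_force_recount(self):
        """Metric formulas agree with a per-sample recount oracle on random
        label vectors, and all bounds hold."""
        rng = np.random.default_rng(4)
        for _ in range(25):
            yt = rng.integers(0, 2, size=60)
            yp = rng.integers(0, 2, size=60)
            if yt.sum() in (0, 60):
                continue
            c = ConfusionCounts.from_labels(yt, yp)
            # brute-force recount
            tp = sum(1 for a, b in zip(yt, yp) if a == 1 and b == 1)
            fp = sum(1 for a, b in zip(yt, yp) if a == 0 and b == 1)
            tn = sum(1 for a, b in zip(yt, yp) if a == 0 and b == 0)
            fn = sum(1 for a, b in zip(yt, yp) if a == 1 and b == 0)
            assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)
            r = compute_metrics(c)
            assert r.accuracy == pytest.approx(np.mean(yt == yp))
            for v in (r.precision, r.sensitivity, r.specificity, r.accuracy):
                assert 0 <= v <= 1
            assert -1 <= r.mcc <= 1

    def test_truncation_not_rounding(self):
        assert truncate3(0.89298) == 0.892
        assert truncate3(0.86093) == 0.860
        assert truncate3(0.9999) == 0.999


class TestKfoldSplit:
    def test_ten_samples_five_folds_of_two(self):
        folds = kfold_split([0, 1] * 5, k=5, seed=0)
        assert sorted(len(f) for f in folds) == [2] * 5

    def test_partition_property(self):
        y = np.array([0] * 30 + [1] * 17)
        folds = kfold_split(y, k=5, seed=3)
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(47))

    def test_deterministic_for_fixed_seed(self):
        y = np.array([0, 1] * 20)
        f1 = kfold_split(y, k=5, seed=9)
        f2 = kfold_split(y, k=5, seed=9)
        assert all(np.array_equal(a, b) for a, b in zip(f1, f2))

    def test_stratification_within_one_sample(self):
        y = np.array([0] * 60 + [1] * 31)
        folds = kfold_split(y, k=5, seed=1)
        for fold in folds:
            pos = int(y[fold].sum())
            assert abs(pos - 31 / 5) <= 1
            assert abs((len(fold) - pos) - 60 / 5) <= 1

    def test_k_exceeding_samples_rejected(self):
        with pytest.raises(ValueError):
            kfold_split([0, 1], k=5)


class TestCrossValidate:
    def test_pooled_counts_conserve_samples(self, dataset, fragments):
        result = cross_validate(
            fragments, dataset.profiles, ("AAC",), SvmConfig(), k=5, seed=0
        )
        assert result.counts.total == len(fragments)
        assert sum(c.total for c in result.fold_counts) == len(fragments)

    def test_informative_features_beat_ss_alone(self, dataset, fragments):
        """Sequence + accessibility features outperform secondary structure
        alone, mirroring the observed feature ranking."""
        best = cross_validate(
            fragments,
            dataset.profiles,
            ("AA_PWM", "AAC", "ASA"),
            SvmConfig(),
            k=5,
            seed=0,
        )
        ss_only = cross_validate(
            fragments, dataset.profiles, ("SS",), SvmConfig(), k=5, seed=0
        )
        assert best.report.accuracy > ss_only.report.accuracy

    def test_shuffled_labels_give_null_mcc(self, small_dataset):
        """Permuting labels destroys the signal: pooled MCC within +/-0.15
        of zero across 30 seeded permutations."""
        window = WindowConfig(7)
        frags = extract_all_fragments(small_dataset.records, window)
        rng = np.random.default_rng(0)
        labels = np.array([f.label for f in frags])
        mccs = []
        for _ in range(30):
            perm = rng.permutation(len(frags))
            shuffled = [
                type(f)(f.protein_id, f.center, f.window, labels[j])
                for f, j in zip(frags, perm)
            ]
            result = cross_validate(
                shuffled,
                small_dataset.profiles,
                ("AAC",),
                SvmConfig(),
                k=5,
                seed=1,
            )
            mccs.append(result.report.mcc)
        assert abs(float(np.mean(mccs))) < 0.15


class TestWindowSweep:
    def test_single_n_single_row(self, small_dataset):
        table = window_sweep(
            small_dataset.records,
            small_dataset.profiles,
            n_values=[7],
            seed=0,
        )
        assert len(table) == 1
        assert table.loc[0, "window_length"] == 15

    def test_row_count_matches_n_values(self, small_dataset):
        table = window_sweep(
            small_dataset.records,
            small_dataset.profiles,
            n_values=[4, 7, 10],
            selection=("AAC",),
            seed=0,
        )
        assert list(table["n"]) == [4, 7, 10]


class TestFeatureCombinationEval:
    def test_default_list_has_ten_rows(self, small_dataset):
        table = feature_combination_eval(
            small_dataset.records, small_dataset.profiles, seed=0
        )
        assert len(table) == 10
        assert table.loc[0, "features"] == "AA_PWM"

    def test_single_selection_single_row(self, small_dataset):
        table = feature_combination_eval(
            small_dataset.records,
            small_dataset.profiles,
            combinations=[("AAC",)],
            seed=0,
        )
        assert len(table) == 1
        for col in ("precision", "sensitivity", "specificity", "accuracy"):
            assert 0 <= table.loc[0, col] <= 1


class TestIndependentTest:
    def _trained(self, dataset, window):
        frags = extract_all_fragments(dataset.records, window)
        return fit_predictor(
            frags, dataset.profiles, ("AA_PWM", "AAC", "ASA"), SvmConfig(), window
        ), frags

    def test_overlap_with_training_rejected(self, small_dataset, window):
        model, frags = self._trained(small_dataset, window)
        with pytest.raises(ValueError, match="overlap"):
            independent_test(model, frags, small_dataset.profiles)

    def test_single_class_test_set_rejected(self, small_dataset, window):
        model, frags = self._trained(small_dataset, window)
        held = generate(GeneratorSpec(n_proteins=5, seed=99))
        for rec in held.records:
            rec.id = "H" + rec.id
        held.profiles = {"H" + k: v for k, v in held.profiles.items()}
        test_frags = [
            f
            for f in extract_all_fragments(held.records, window)
            if not f.is_positive
        ]
        with pytest.raises(ValueError, match="both classes"):
            independent_test(model, test_frags, held.profiles)

    def test_heldout_metrics_close_to_cv(self, window):
        """Stationary generator: independent-test metrics land within 0.1
        of the pooled CV metrics."""
        train_ds = generate(GeneratorSpec(n_proteins=60, seed=31))
        frags = extract_all_fragments(train_ds.records, window)
        cv = cross_validate(
            frags,
            train_ds.profiles,
            ("AA_PWM", "AAC", "ASA"),
            SvmConfig(),
            k=5,
            seed=0,
        )
        model = fit_predictor(
            frags, train_ds.profiles, ("AA_PWM", "AAC", "ASA"), SvmConfig(), window
        )
        held = generate(GeneratorSpec(n_proteins=25, seed=32))
        for rec in held.records:
            rec.id = "H" + rec.id
        held.profiles = {"H" + k: v for k, v in held.profiles.items()}
        test_frags = extract_all_fragments(held.records, window)
        _, report = independent_test(model, test_frags, held.profiles)
        assert abs(report.accuracy - cv.report.accuracy) < 0.1
        assert abs(report.mcc - cv.report.mcc) < 0.2
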