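"""Training protocol, early stopping, and evaluation metrics."""

import numpy as np
import pytest

import wsimil as w
from wsimil.losses import LossConfig
from wsimil.train import ConfusionMatrix, TrainConfig


def tiny_dataset(seed=0, n=30):
    spec = w.BagSimSpec(n_bags=n, prevalence=0.5, witness_rate=0.2, dim=16,
                        mu_signal=3.0, bag_size_range=(10, 20), seed=seed)
    return w.simulate_bags(spec).bags


class TestTrain:
    def test_validation_loss_improves_from_start(self, recovery_run):
        log = recovery_run["result"].log
        assert recovery_run["result"].best_val_loss < log[0]["val_loss"]
        assert recovery_run["result"].best_epoch > 0

    def test_patience_zero_stops_at_first_non_improvement(self):
        bags = tiny_dataset()
        # a vanishing learning rate freezes the validation loss, so the second
        # epoch cannot improve and patience 0 must stop there
        res = w.train(bags[:20], bags[20:], w.init_params("small", seed=1),
                      LossConfig(k_sample=2),
                      TrainConfig(seed=0, patience=0, max_epochs=50, lr=1e-30))
        # ran until the first epoch whose val loss failed to improve, then stopped
        n = len(res.log)
        assert n < 50
        assert res.log[-1]["val_loss"] >= res.best_val_loss
        assert res.best_epoch == n - 2

    def test_same_seed_reproduces_log_and_checkpoint(self):
        bags = tiny_dataset(seed=4)
        kw = dict(loss_cfg=LossConfig(k_sample=2),
                  cfg=TrainConfig(seed=7, max_epochs=4, patience=20))
        r1 = w.train(bags[:20], bags[20:], w.init_params("small", seed=1), **kw)
        r2 = w.train(bags[:20], bags[20:], w.init_params("small", seed=1), **kw)
        assert r1.log == r2.log
        for k, v in r1.best_params.arrays().items():
            np.testing.assert_array_equal(v, r2.best_params.arrays()[k])

    def test_empty_split_rejected(self):
        bags = tiny_dataset()
        with pytest.raises(ValueError, match="nonempty"):
            w.train(bags, [], w.init_params("small"))

    def test_best_checkpoint_is_running_minimum(self, recovery_run):
        log = recovery_run["result"].log
        assert recovery_run["result"].best_val_loss == min(r["val_loss"] for r in log)


class TestMetrics:
    def test_mean_ss_of_degenerate_all_positive_classifier(self):
        assert w.mean_ss(1.00, 0.00) == pytest.approx(0.50)

    def test_mean_ss_of_headline_operating_point(self):
        assert w.mean_ss(0.91, 0.71) == pytest.approx(0.81)

    def test_confusion_matrix_reproduces_headline_metrics(self):
        report = w.compute_metrics(ConfusionMatrix(tp=29, fn=3, tn=5, fp=2))
        assert report.accuracy == pytest.approx(0.872, abs=5e-4)
        assert report.precision == pytest.approx(0.935, abs=5e-4)
        assert report.sensitivity == pytest.approx(0.906, abs=5e-4)
        assert report.specificity == pytest.approx(0.714, abs=5e-4)
        assert round(report.accuracy, 2) == 0.87
        assert round(report.precision, 2) == 0.94
        assert round(report.sensitivity, 2) == 0.91
        assert round(report.specificity, 2) == 0.71
        assert round(report.mean_ss, 2) == 0.81

    def test_perfect_classifier(self):
        report = w.compute_metrics(ConfusionMatrix(tp=10, tn=5, fp=0, fn=0))
        assert report.accuracy == report.precision == 1.0
        assert report.mean_ss == 1.0

    def test_zero_denominator_is_nan_with_warning(self):
        with pytest.warns(UserWarning, match="precision"):
            report = w.compute_metrics(ConfusionMatrix(tp=0, tn=5, fp=0, fn=2))
        assert np.isnan(report.precision)

    def test_mean_ss_identity_holds(self):
        report = w.compute_metrics(ConfusionMatrix(tp=7, tn=3, fp=4, fn=1))
        assert report.mean_ss == (report.sensitivity + report.specificity) / 2

    def test_accuracy_is_prevalence_weighted_combination(self):
        cm = ConfusionMatrix(tp=29, fn=3, tn=5, fp=2)
        report = w.compute_metrics(cm)
        n_pos, n_neg = cm.tp + cm.fn, cm.tn + cm.fp
        blended = (n_pos * report.sensitivity + n_neg * report.specificity) / cm.total
        assert report.accuracy == pytest.approx(blended)


class TestEvaluate:
    def test_all_positive_predictor_pattern(self, monkeypatch):
        # an always-positive predictor on an 82%-positive test set shows the
        # degenerate pattern: sensitivity 1, specificity 0, mean SS 0.5
        spec = w.BagSimSpec(n_bags=50, prevalence=0.82, witness_rate=0.2, dim=16,
                            mu_signal=5.0, bag_size_range=(10, 20), seed=8)
        test_bags = w.simulate_bags(spec).bags

        import importlib

        train_mod = importlib.import_module("wsimil.train")

        class _AlwaysPositive:
            probs = np.array([0.0, 1.0])

        monkeypatch.setattr(train_mod, "forward", lambda bag, p: _AlwaysPositive())
        report, preds, cm = w.evaluate(w.init_params("small"), test_bags)
        assert all(p["pred"] == 1 for p in preds)
        assert report.sensitivity == 1.0
        assert report.specificity == 0.0
        assert report.mean_ss == 0.5
        assert report.accuracy == pytest.approx(0.82)

    def test_separable_bags_reach_perfect_accuracy(self, recovery_run):
        assert recovery_run["report"].accuracy == pytest.approx(1.0)

    def test_evaluate_is_deterministic(self, recovery_run):
        params = recovery_run["result"].best_params
        r1, p1, _ = w.evaluate(params, recovery_run["test_bags"])
        r2, p2, _ = w.evaluate(params, recovery_run["test_bags"])
        assert r1 == r2 and p1 == p2

    def test_unlabeled_bag_rejected(self):
        bag = w.FeatureBag(slide_id="x", features=np.zeros((2, 16), np.float32),
                           coords=np.zeros((2, 2)), label=-1)
        with pytest.raises(ValueError, match="label"):
            w.evaluate(w.init_params("small"), [bag])


class TestSplit:
    def test_stratified_split_disjoint_and_exhaustive(self):
        labels = [0] * 30 + [1] * 70
        tr, va, te = w.stratified_split(labels, seed=3)
        parts = [set(tr), set(va), set(te)]
        assert not (parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2])
        assert parts[0] | parts[1] | parts[2] == set(range(100))
        # stratification keeps class balance in each part
        for part in parts:
            frac_pos = np.mean([labels[i] for i in part])
            assert 0.6 <= frac_pos <= 0.8
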