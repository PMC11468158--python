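"""Training/evaluation protocol: splits, resampling, SGD readout, d-prime."""

import numpy as np
import pytest
from scipy.stats import norm

from earlyvis import models as md
from earlyvis import protocol as pr
from earlyvis import stimuli as st
from earlyvis.rng import substream


class TestSplits:
    def test_even_split_is_disjoint_halves(self):
        train, test = pr.split_sets(range(10), range(10), seed=0)
        for label in ("face", "nonface"):
            assert len(train[label]) == 5 and len(test[label]) == 5
            assert set(train[label]).isdisjoint(test[label])

    def test_odd_split_puts_extra_in_training(self):
        train, test = pr.split_sets(range(11), range(7), seed=1)
        assert len(train["face"]) == 6 and len(test["face"]) == 5
        assert len(train["nonface"]) == 4 and len(test["nonface"]) == 3
        assert set(train["face"]) | set(test["face"]) == set(range(11))
        assert set(train["face"]) & set(test["face"]) == set()

    def test_same_seed_same_split(self):
        a = pr.split_sets(range(20), range(20), seed=5)
        b = pr.split_sets(range(20), range(20), seed=5)
        for d1, d2 in zip(a, b):
            for label in d1:
                assert np.array_equal(d1[label], d2[label])

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            pr.split_sets([], range(3), seed=0)


class TestResampling:
    def test_with_replacement_from_small_pool(self):
        ids = np.arange(878)
        out = pr.resample_epoch_list(ids, 1500, seed=0)
        assert len(out) == 1500
        assert set(out) <= set(ids)

    def test_singleton_pool(self):
        assert list(pr.resample_epoch_list(["a"], 3, seed=0)) == ["a", "a", "a"]

    def test_expected_unique_fraction_matches_closed_form(self):
        """Empirical unique fraction vs m(1 - (1 - 1/m)^n)/n for sampling
        with replacement."""
        m, n = 40, 120
        expected = m * (1 - (1 - 1 / m) ** n) / n
        fracs = [len(np.unique(pr.resample_epoch_list(np.arange(m), n, seed=s))) / n
                 for s in range(200)]
        assert np.mean(fracs) == pytest.approx(expected, rel=0.02)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            pr.resample_epoch_list([1, 2], 0, seed=0)


def _toy_epoch_fn(n=1024, sep=4.0, seed=0):
    """Linearly separable two-feature stream: class 1 shifted by +sep."""
    def fn(epoch, rng):
        r = np.random.default_rng(seed + epoch)
        y = np.repeat([0, 1], n // 2)
        X = r.normal(size=(n, 2))
        X[y == 1] += sep
        return X, y
    return fn


class TestTraining:
    def test_zero_learning_rate_keeps_initialization(self):
        cfg = pr.TrainConfig(learning_rate=0.0, epochs=3)
        head = pr.train_on_features(_toy_epoch_fn(), 2, cfg, seed=9)
        init = pr.init_head(2, substream(9, "init"))
        assert np.array_equal(head.weights, init.weights)
        assert head.bias == 0.0

    def test_separable_toy_reaches_95_percent(self):
        cfg = pr.TrainConfig(epochs=10)
        head = pr.train_on_features(_toy_epoch_fn(), 2, cfg, seed=3)
        X, y = _toy_epoch_fn()(99, None)
        assert (head.predict(X) == y).mean() >= 0.95

    def test_identical_seeds_give_identical_weights(self):
        cfg = pr.TrainConfig(epochs=4)
        h1 = pr.train_on_features(_toy_epoch_fn(), 2, cfg, seed=5)
        h2 = pr.train_on_features(_toy_epoch_fn(), 2, cfg, seed=5)
        assert np.array_equal(h1.weights, h2.weights)
        assert h1.bias == h2.bias

    def test_kaiming_uniform_bound(self):
        head = pr.init_head(10_000, substream(0, "init"))
        bound = np.sqrt(6.0 / 10_000)
        assert head.weights.min() >= -bound and head.weights.max() <= bound
        assert np.abs(head.weights).max() > 0.9 * bound
        assert head.bias == 0.0


class TestEvaluate:
    def test_constant_positive_bias_says_face_always(self):
        head = pr.ReadoutHead(weights=np.zeros(2), bias=1.0)
        X = np.zeros((20, 2))
        y = np.repeat([1, 0], 10)
        acc, hit, fa = pr._score(head, X, y)
        assert (acc, hit, fa) == (0.5, 1.0, 1.0)

    def test_oracle_head_is_perfect(self):
        X, y = _toy_epoch_fn(sep=5.0)(0, None)
        head = pr.ReadoutHead(weights=np.array([1.0, 1.0]), bias=-5.0)
        acc, hit, fa = pr._score(head, X, y)
        assert acc == 1.0 and fa == 0.0

    def test_shuffled_labels_give_chance(self):
        """Permutation null: accuracy ~ Binomial(n, 0.5) under label shuffle."""
        X, y = _toy_epoch_fn(n=400, sep=5.0)(0, None)
        head = pr.ReadoutHead(weights=np.array([1.0, 1.0]), bias=-5.0)
        rng = np.random.default_rng(0)
        accs = [(head.predict(X) == rng.permutation(y)).mean() for _ in range(50)]
        # 5 sigma of the binomial mean over 50 repeats of n=400
        assert abs(np.mean(accs) - 0.5) < 5 * 0.5 / np.sqrt(400 * 50)

    def test_length_mismatch_rejected(self):
        head = pr.ReadoutHead(weights=np.zeros(3), bias=0.0)
        with pytest.raises(ValueError):
            pr._score(head, np.zeros((4, 2)), np.zeros(4))


class TestDPrime:
    def test_symmetric_values(self):
        assert pr.dprime(0.5) == 0.0
        assert pr.dprime(0.995) == 5.15
        assert pr.dprime(0.84) == pytest.approx(1.989, abs=0.001)

    def test_extreme_rates_clip_to_cap(self):
        assert pr.dprime(1.0) == 5.15
        assert pr.dprime(0.0) == -5.15
        assert pr.dprime(1.0, 0.0) == 5.15

    def test_monotone_and_antisymmetric(self):
        hs = np.linspace(0.02, 0.98, 30)
        ds = [pr.dprime(h) for h in hs]
        assert np.all(np.diff(ds) > 0)
        for h in hs:
            assert pr.dprime(h) == pytest.approx(-pr.dprime(1 - h), abs=1e-12)
            assert pr.dprime(h, h) == 0.0

    def test_two_rate_form_matches_quantiles(self):
        assert pr.dprime(0.9, 0.2) == pytest.approx(
            norm.ppf(0.9) - norm.ppf(0.2), abs=1e-12)


@pytest.fixture(scope="module")
def tiny_result(small_stimset):
    cond = pr.Condition(n_train_per_class=30, n_test_per_class=30, n_runs=3)
    model = md.make_model("LGN")
    return pr.run_condition(model, cond, small_stimset, master_seed=2,
                            cfg=pr.TrainConfig(epochs=2), cache_augmentations=2)


class TestRunCondition:
    def test_median_is_middle_order_statistic(self, tiny_result):
        accs = sorted(r.accuracy for r in tiny_result.runs)
        assert tiny_result.median_accuracy == accs[1]

    def test_two_run_median_is_mean(self, small_stimset):
        cond = pr.Condition(n_train_per_class=20, n_test_per_class=20, n_runs=2)
        model = md.make_model("LGN")
        res = pr.run_condition(model, cond, small_stimset, master_seed=4,
                               cfg=pr.TrainConfig(epochs=1), cache_augmentations=2)
        accs = [r.accuracy for r in res.runs]
        assert res.median_accuracy == pytest.approx(np.mean(accs))

    def test_cross_validation_hygiene(self, tiny_result):
        """No test id of a run ever appears among its training ids."""
        for r in tiny_result.runs:
            for label in ("face", "nonface"):
                assert set(r.train_ids[label]).isdisjoint(r.test_ids[label])

    def test_reproducible_given_master_seed(self, small_stimset, tiny_result):
        cond = pr.Condition(n_train_per_class=30, n_test_per_class=30, n_runs=3)
        model = md.make_model("LGN")
        again = pr.run_condition(model, cond, small_stimset, master_seed=2,
                                 cfg=pr.TrainConfig(epochs=2), cache_augmentations=2)
        assert [r.accuracy for r in again.runs] == [r.accuracy for r in tiny_result.runs]


class TestEarlyStopping:
    def test_constant_validation_stops_after_patience(self):
        """Flat validation accuracy: 1 improving + 5 non-improving epochs."""
        X_val = np.zeros((8, 2))
        y_val = np.repeat([0, 1], 4)  # any head scores 0.5 on this
        cfg = pr.TrainConfig(max_epochs=40, patience=5, learning_rate=0.0)
        head, log = pr.train_with_validation(None, _toy_epoch_fn(), (X_val, y_val),
                                             2, cfg, seed=0)
        assert log["epochs_run"] == 6

    def test_runs_all_epochs_when_always_improving(self, monkeypatch):
        calls = {"n": 0}

        def fake_score(head, X, y):
            calls["n"] += 1
            return calls["n"] / 100.0, 0.0, 0.0

        monkeypatch.setattr(pr, "_score", fake_score)
        cfg = pr.TrainConfig(max_epochs=12, patience=5)
        _, log = pr.train_with_validation(None, _toy_epoch_fn(), (np.zeros((4, 2)),
                                          np.zeros(4)), 2, cfg, seed=0)
        assert log["epochs_run"] == 12

    def test_returned_head_is_best_validation_epoch(self):
        rng = np.random.default_rng(0)
        X_val = rng.normal(size=(100, 2))
        X_val[50:] += 3.0
        y_val = np.repeat([0, 1], 50)
        cfg = pr.TrainConfig(max_epochs=15, patience=3)
        head, log = pr.train_with_validation(None, _toy_epoch_fn(), (X_val, y_val),
                                             2, cfg, seed=1)
        best_acc, _, _ = pr._score(head, X_val, y_val)
        assert best_acc == pytest.approx(log["best_val_accuracy"])
        assert best_acc == max(log["val_history"])

    def test_empty_validation_rejected(self):
        cfg = pr.TrainConfig()
        with pytest.raises(ValueError):
            pr.train_with_validation(None, _toy_epoch_fn(), (np.zeros((0, 2)), []),
                                     2, cfg, seed=0)


class TestPresenter:
    def test_fresh_augmentation_differs_across_epochs(self, small_stimset):
        cond = pr.Condition(scale_min=0.7, rot_max=45.0, n_train_per_class=4,
                            n_test_per_class=4, n_runs=1)
        ids = {"face": np.arange(4), "nonface": np.arange(4)}
        p = pr.Presenter(small_stimset, cond, ids, 4, seed=3)
        e0 = p.compose_epoch(0)
        e1 = p.compose_epoch(1)
        assert not np.array_equal(e0, e1)
        assert np.array_equal(e0, p.compose_epoch(0))  # but per-epoch deterministic

    def test_labels_align_with_classes(self, small_stimset):
        cond = pr.Condition(n_train_per_class=3, n_test_per_class=3, n_runs=1)
        ids = {"face": np.arange(3), "nonface": np.arange(3)}
        p = pr.Presenter(small_stimset, cond, ids, 3, seed=0)
        assert list(p.labels()) == [1, 1, 1, 0, 0, 0]
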