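import numpy as np
import pytest
from scipy.optimize import minimize

import errmon.decoding as dec
from errmon.decoding import (DecodingCurve, WindowGrid, balance_classes,
                             build_features, cv_accuracy, decode_subject,
                             group_analysis, shuffled_null,
                             train_linear_classifier)
from tests.conftest import make_epochs


def decoding_epochs(n_per_class=12, n_ch=4, signal=0.0, seed=0):
    """EpochSet on the [-100, 300) grid; class-mean shift added from 0 ms on."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    data = rng.normal(size=(n, n_ch, 200))
    labels = ["detected_error"] * n_per_class + ["correct_go"] * n_per_class
    if signal:
        data[:n_per_class, :, 50:] += signal  # samples at t >= 0
    return make_epochs(data, labels=labels)


class TestWindowGrid:
    def test_default_grid_structure(self):
        g = WindowGrid()
        assert g.n_windows == 40
        assert g.samples_per_window(500.0) == 5
        assert g.window_times()[10] == 0.0  # window 10 starts at response onset

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="non-overlapping"):
            WindowGrid(width=10.0, step=5.0)


class TestFeatures:
    def test_61_channels_gives_305_features(self, montage):
        n = len(montage.labels)
        data = np.zeros((3, n, 200))
        ep = make_epochs(data, channel_labels=list(montage.labels))
        X = build_features(ep, WindowGrid(), 0)
        assert X.shape == (3, 305)

    def test_channel_major_order(self):
        data = np.zeros((1, 2, 200))
        data[0, 0, :5] = [1, 2, 3, 4, 5]
        data[0, 1, :5] = [6, 7, 8, 9, 10]
        ep = make_epochs(data)
        X = build_features(ep, WindowGrid(), 0)
        assert X.shape == (1, 10)
        np.testing.assert_array_equal(X[0], [1, 2, 3, 4, 5, 6, 7, 8, 9, 10])

    def test_window_index_range(self):
        ep = make_epochs(np.zeros((1, 2, 200)))
        with pytest.raises(ValueError, match="out of range"):
            build_features(ep, WindowGrid(), 40)

    def test_eog_channels_excluded(self):
        data = np.ones((2, 3, 200))
        ep = make_epochs(data)
        ep.channel_kinds[2] = "eog"
        assert build_features(ep, WindowGrid(), 5).shape == (2, 10)


class TestBalanceClasses:
    def test_majority_subsampled(self):
        labels = np.array(["a"] * 120 + ["b"] * 15)
        keep = balance_classes(labels, seed=0)
        assert len(keep) == 30
        assert (labels[keep] == "a").sum() == 15
        assert np.all(np.diff(keep) > 0)  # order-preserving

    def test_already_balanced_identity(self):
        labels = np.array(["a"] * 12 + ["b"] * 12)
        np.testing.assert_array_equal(balance_classes(labels, seed=5),
                                      np.arange(24))

    def test_seed_contract(self):
        labels = np.array(["a"] * 40 + ["b"] * 12)
        k1 = balance_classes(labels, seed=1)
        k2 = balance_classes(labels, seed=1)
        k3 = balance_classes(labels, seed=2)
        np.testing.assert_array_equal(k1, k2)
        assert not np.array_equal(k1, k3)

    def test_minimum_trial_criterion(self):
        labels = np.array(["a"] * 40 + ["b"] * 9)
        with pytest.raises(ValueError, match="below the minimum"):
            balance_classes(labels, seed=0)


class TestLinearSvm:
    def test_separable_1d(self):
        w, b = train_linear_classifier(np.array([[-1.0], [1.0]]),
                                       np.array([-1, 1]))
        assert -b / w[0] == pytest.approx(0.0, abs=1e-9)

    def test_label_swap_negates_weights(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        y = np.array([0] * 5 + [1] * 5)
        w1, b1 = train_linear_classifier(X, y)
        w2, b2 = train_linear_classifier(X, 1 - y)
        np.testing.assert_allclose(w1, -w2, atol=1e-8)
        assert b1 == pytest.approx(-b2, abs=1e-8)

    def test_conflicting_duplicate_rows_no_crash(self):
        X = np.ones((4, 2))
        y = np.array([0, 1, 0, 1])
        w, b = train_linear_classifier(X, y)
        assert np.isfinite(w).all() and np.isfinite(b)

    def test_matches_dual_qp_oracle(self):
        """Decision values must match a brute-force solve of the SVM dual."""
        X = np.array([[-2.0, 0.0], [-1.0, -1.0], [-1.5, 1.0],
                      [2.0, 0.0], [1.0, 1.0], [1.5, -1.0]])
        y = np.array([-1, -1, -1, 1, 1, 1], dtype=float)
        C = 1.0
        Q = (y[:, None] * y[None, :]) * (X @ X.T)

        def neg_dual(a):
            return -(a.sum() - 0.5 * a @ Q @ a)

        res = minimize(neg_dual, np.full(6, 0.5), method="SLSQP",
                       bounds=[(0.0, C)] * 6,
                       constraints={"type": "eq", "fun": lambda a: a @ y},
                       options={"ftol": 1e-12, "maxiter": 500})
        a = res.x
        w_ref = (a * y) @ X
        sv = (a > 1e-6) & (a < C - 1e-6)
        b_ref = np.mean(y[sv] - X[sv] @ w_ref)
        w, b = train_linear_classifier(X, y, C=C)
        np.testing.assert_allclose(X @ w + b, X @ w_ref + b_ref, atol=1e-4)

    def test_offset_invariance_of_predictions(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(-2, 1, size=(10, 4)),
                       rng.normal(2, 1, size=(10, 4))])
        y = np.array([0] * 10 + [1] * 10)
        shift = np.array([10.0, -3.0, 0.5, 100.0])
        acc1 = cv_accuracy(X, y, folds=5, repeats=2, seed=0)
        acc2 = cv_accuracy(X + shift, y, folds=5, repeats=2, seed=0)
        assert acc1 == pytest.approx(acc2, abs=1e-12)

    def test_global_rescaling_keeps_separable_accuracy(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(-3, 0.5, size=(10, 4)),
                       rng.normal(3, 0.5, size=(10, 4))])
        y = np.array([0] * 10 + [1] * 10)
        assert cv_accuracy(X, y, 5, 2, 0) == 1.0
        assert cv_accuracy(X * 40.0, y, 5, 2, 0) == 1.0


class TestCrossValidation:
    def test_exactly_100_analyses(self, monkeypatch):
        fits = []
        real_svc = dec.SVC

        class CountingSVC(real_svc):
            def fit(self, X, y, **kw):
                fits.append(len(X))
                return super().fit(X, y, **kw)

        monkeypatch.setattr(dec, "SVC", CountingSVC)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 5))
        y = np.array([0] * 10 + [1] * 10)
        cv_accuracy(X, y, folds=10, repeats=10, seed=0)
        assert len(fits) == 100
        assert all(n == 18 for n in fits)  # 90% train / 10% test

    def test_separable_data_perfect_accuracy(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(-5, 0.3, size=(10, 3)),
                       rng.normal(5, 0.3, size=(10, 3))])
        y = np.array([0] * 10 + [1] * 10)
        assert cv_accuracy(X, y, folds=10, repeats=2, seed=0) == 1.0

    def test_chance_level_on_label_independent_data(self):
        accs = []
        for seed in range(40):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(20, 8))
            y = np.array([0] * 10 + [1] * 10)
            accs.append(cv_accuracy(X, y, folds=10, repeats=3, seed=seed))
        mean = np.mean(accs)
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(mean - 0.5) < 2 * se + 0.02

    def test_too_few_per_class_for_folds(self):
        X = np.zeros((12, 3))
        y = np.array([0] * 6 + [1] * 6)
        with pytest.raises(ValueError, match="folds"):
            cv_accuracy(X, y, folds=10)

    def test_determinism(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(24, 6))
        y = np.array([0] * 12 + [1] * 12)
        assert cv_accuracy(X, y, 6, 3, seed=9) == cv_accuracy(X, y, 6, 3, seed=9)
        assert shuffled_null(X, y, 6, 3, seed=9) == shuffled_null(X, y, 6, 3, seed=9)


class TestShuffledNull:
    def test_separable_real_vs_shuffled_gap(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(-3, 1, size=(15, 4)),
                       rng.normal(3, 1, size=(15, 4))])
        y = np.array([0] * 15 + [1] * 15)
        real = cv_accuracy(X, y, folds=5, repeats=4, seed=0)
        null = shuffled_null(X, y, folds=5, repeats=4, seed=0)
        assert real - null >= 0.3
        assert abs(null - 0.5) < 0.15


class TestDecodeSubject:
    def test_embedded_signal_found_after_onset_only(self):
        ep = decoding_epochs(n_per_class=12, signal=2.5, seed=5)
        curve = decode_subject(ep, "s1", folds=4, repeats=2, seed=1)
        pre = curve.accuracy[curve.window_start_ms < 0]
        post = curve.accuracy[curve.window_start_ms >= 0]
        assert post.mean() - pre.mean() > 0.3
        assert np.abs(curve.shuffled_accuracy.mean() - 0.5) < 0.08

    def test_deterministic_given_seed(self):
        ep = decoding_epochs(signal=1.0, seed=6)
        c1 = decode_subject(ep, "s", folds=4, repeats=2, seed=3)
        c2 = decode_subject(ep, "s", folds=4, repeats=2, seed=3)
        np.testing.assert_array_equal(c1.accuracy, c2.accuracy)
        np.testing.assert_array_equal(c1.shuffled_accuracy, c2.shuffled_accuracy)

    def test_undetected_errors_collapsed(self):
        ep = decoding_epochs(n_per_class=12, seed=7)
        labels = (["detected_error"] * 6 + ["undetected_error"] * 6
                  + ["correct_go"] * 12)
        ep.labels = labels
        curve = decode_subject(ep, "s", folds=4, repeats=1, seed=0)
        assert curve.n_per_class == 12


class TestGroupAnalysis:
    def make_curves(self, rng, n_sub, loc=0.5, scale=0.04):
        out = []
        for i in range(n_sub):
            out.append(DecodingCurve(
                f"s{i}", WindowGrid().window_times(),
                rng.normal(loc, scale, size=40),
                rng.normal(0.5, scale, size=40), 10))
        return out

    def test_adjusted_alpha(self):
        rng = np.random.default_rng(0)
        tab = group_analysis(self.make_curves(rng, 5), self.make_curves(rng, 6))
        assert tab.attrs["alpha_adjusted"] == pytest.approx(0.00125)
        assert len(tab) == 40

    def test_identical_groups_no_flags(self):
        rng = np.random.default_rng(1)
        a = self.make_curves(rng, 5)
        b = [DecodingCurve(f"t{i}", c.window_start_ms, c.accuracy.copy(),
                           c.shuffled_accuracy.copy(), 10)
             for i, c in enumerate(a)]
        tab = group_analysis(a, b)
        np.testing.assert_allclose(tab["t_between"], 0.0, atol=1e-12)
        assert not tab["sig_between"].any()

    def test_real_effect_flagged_within_group(self):
        rng = np.random.default_rng(2)
        a = self.make_curves(rng, 12, loc=0.75, scale=0.03)
        b = self.make_curves(rng, 12, loc=0.75, scale=0.03)
        tab = group_analysis(a, b)
        assert tab["sig_vs_null_patient"].all()

    def test_mismatched_grids_rejected(self):
        rng = np.random.default_rng(3)
        a = self.make_curves(rng, 3)
        b = self.make_curves(rng, 3)
        b[0].window_start_ms = b[0].window_start_ms + 5.0
        with pytest.raises(ValueError, match="grids"):
            group_analysis(a, b)

    def test_familywise_error_controlled_under_null(self):
        rng = np.random.default_rng(4)
        false_hits = 0
        n_cohorts = 60
        for _ in range(n_cohorts):
            a = self.make_curves(rng, 8)
            b = self.make_curves(rng, 8)
            if group_analysis(a, b)["sig_between"].any():
                false_hits += 1
        rate = false_hits / n_cohorts
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_cohorts)
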