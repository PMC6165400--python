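"""Conformal predictor: hand-worked examples, oracle agreement, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from conftest import scaled_features
from enosecp import (
    CPConfig,
    CPModel,
    FeatureMatrix,
    InsufficientDataError,
    calibration_curve,
    forced_prediction,
    format_prediction_row,
    knn_nonconformity,
    loo_evaluate,
    p_values,
    prediction_set,
)


def _model(points, labels, **cfg):
    X = np.asarray(points, dtype=float).reshape(len(points), -1)
    return CPModel(X, np.asarray(labels), CPConfig(**cfg))


class TestKnnNonconformity:
    def test_hand_enumerated_ratio(self):
        # class A at {0, 1}, class B at {10}; candidate x=0 labelled A,
        # excluding itself: same-label neighbour at 1, different at 10
        model = _model([0.0, 1.0, 10.0], ["A", "A", "B"], k=1)
        alpha = knn_nonconformity(model, [0.0], "A", exclude_index=0)
        assert alpha == pytest.approx(0.1, abs=0)

    def test_coincident_same_label_point_gives_zero(self):
        model = _model([0.0, 1.0, 10.0], ["A", "A", "B"], k=1)
        assert knn_nonconformity(model, [0.0], "A") == 0.0

    def test_swapped_label_inverts_ratio(self):
        # model points {1 (A), 10 (B)}; candidate x=0 labelled B:
        # same-label at distance 10, different-label at distance 1
        model = _model([1.0, 10.0], ["A", "B"], k=1)
        assert knn_nonconformity(model, [0.0], "B") == pytest.approx(10.0, abs=0)

    def test_insufficient_neighbours_rejected(self):
        model = _model([0.0, 1.0, 10.0], ["A", "A", "B"], k=2)
        with pytest.raises(InsufficientDataError):
            knn_nonconformity(model, [0.5], "B")


class TestPValues:
    def test_counting_rules_on_hand_checkable_bag(self):
        """1-D bag where every alpha can be enumerated by hand.

        Points 0, 1 (A) and 10, 11 (B), k=1, candidate x=0.5 labelled A:
        augmented alphas are all well below the rival-label candidate's, so
        both counting modes are fixed by rank arithmetic (checked against
        the brute-force oracle, which is itself hand-checkable here).
        """
        X = [[0.0], [1.0], [10.0], [11.0]]
        y = ["A", "A", "B", "B"]
        x_new = [0.5]
        for mode in ("strict", "standard"):
            model = _model([0.0, 1.0, 10.0, 11.0], y, k=1, p_value_mode=mode)
            got = p_values(model, x_new)
            want = oracles.naive_p_values(X, y, x_new, 1, mode)
            assert got == want
        # under label A the candidate is the most conforming of its group
        model = _model([0.0, 1.0, 10.0, 11.0], y, k=1, p_value_mode="standard")
        p = p_values(model, x_new)
        assert p["A"] > p["B"]

    def test_maximally_nonconforming_point(self):
        """A far outlier has strict-mode p = 0 and standard-mode p = 1/n."""
        pts = [0.0, 0.1, 10.0, 10.1]
        y = ["A", "A", "B", "B"]
        x_new = [1e6]
        n_aug = 5
        strict = p_values(_model(pts, y, k=1, p_value_mode="strict"), x_new)
        std = p_values(_model(pts, y, k=1, p_value_mode="standard"), x_new)
        for lab in ("A", "B"):
            assert strict[lab] == 0.0
            assert std[lab] == pytest.approx(1 / n_aug, abs=0)

    def test_standard_mode_p_at_least_1_over_n(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.integers(1, 4, size=20)
        model = CPModel(X, y, CPConfig(k=1, p_value_mode="standard"))
        p = p_values(model, rng.normal(size=3))
        assert all(1 / 21 <= pv <= 1.0 for pv in p.values())

    def test_label_permutation_equivariance(self, rng):
        """Renaming the classes permutes the p-value map consistently."""
        X = rng.normal(size=(18, 2))
        y = rng.integers(0, 3, size=18)
        x_new = rng.normal(size=2)
        swap = {0: 2, 1: 0, 2: 1}
        p_orig = p_values(CPModel(X, y, CPConfig(k=1)), x_new)
        y_swapped = np.array([swap[lab] for lab in y])
        p_swap = p_values(CPModel(X, y_swapped, CPConfig(k=1)), x_new)
        for lab, pv in p_orig.items():
            assert p_swap[swap[lab]] == pv


class TestPredictionSet:
    @pytest.mark.parametrize(
        "eps,expected",
        [(0.1, {"A"}), (0.01, {"A", "B"}), (0.9, set())],
    )
    def test_threshold_membership(self, eps, expected):
        got = prediction_set({"A": 0.8, "B": 0.05}, eps)
        assert set(got.members) == expected

    @pytest.mark.parametrize("eps", [0.0, 1.0, -0.2, 1.5])
    def test_epsilon_domain(self, eps):
        with pytest.raises(ValueError):
            prediction_set({"A": 0.5, "B": 0.1}, eps)

    def test_nestedness_on_epsilon_grid(self, rng):
        for _ in range(20):
            p = {lab: float(pv) for lab, pv in enumerate(rng.uniform(size=4))}
            sets = [prediction_set(p, eps) for eps in np.linspace(0.01, 0.99, 50)]
            for bigger_eps, smaller_eps in zip(sets[1:], sets[:-1]):
                assert bigger_eps.members <= smaller_eps.members


class TestForcedPrediction:
    def test_three_label_example(self):
        pred = forced_prediction({"A": 0.8, "B": 0.05, "C": 0.2})
        assert pred.forced_label == "A"
        assert pred.confidence == pytest.approx(0.8)
        assert pred.credibility == pytest.approx(0.8)

    def test_certain_prediction(self):
        pred = forced_prediction({"A": 1.0, "B": 0.0})
        assert (pred.forced_label, pred.confidence, pred.credibility) == ("A", 1.0, 1.0)

    def test_tie_broken_toward_smallest_label(self):
        pred = forced_prediction({2: 0.6, 1: 0.6, 3: 0.1})
        assert pred.forced_label == 1

    def test_single_label_rejected(self):
        with pytest.raises(ValueError):
            forced_prediction({"A": 0.9})

    def test_report_row_rendering(self):
        pred = forced_prediction({1: 0.7433, 2: 0.005, 3: 0.001})
        row = format_prediction_row(5, 1, pred, {1: "Astragalus"})
        assert row == "5, 1 (Astragalus), 1 (Astragalus), 0.9950, 0.7433"


class TestLooEvaluate:
    def test_well_separated_noiseless_classes_are_perfect(self):
        fm = scaled_features(
            2, 5, 3, 2.0, seed=1,
            noise_sd=0.0, drift_slope_sd=0.0, amplitude_jitter_sd=0.0,
        )
        _, acc = loo_evaluate(fm, CPConfig(k=1))
        assert acc == 1.0

    def test_permuted_labels_drop_to_chance(self, rng):
        """Destroying class structure pulls accuracy to ~ 1/n_classes."""
        accs = []
        for seed in range(10):
            fm = scaled_features(3, 8, 4, 1.0, seed=seed)
            shuffled = np.random.default_rng(seed).permutation(fm.labels)
            fm_perm = FeatureMatrix(fm.values, fm.feature_names, shuffled)
            _, acc = loo_evaluate(fm_perm, CPConfig(k=1))
            accs.append(acc)
        n_total = 10 * 24
        se = np.sqrt((1 / 3) * (2 / 3) / n_total)
        assert abs(np.mean(accs) - 1 / 3) <= 4 * se

    def test_minimal_four_sample_dataset_runs(self, rng):
        fm = FeatureMatrix.from_arrays(rng.normal(size=(4, 2)), [1, 1, 2, 2])
        preds, acc = loo_evaluate(fm, CPConfig(k=1))
        assert len(preds) == 4
        assert 0.0 <= acc <= 1.0

    @pytest.mark.parametrize("mode", ["strict", "standard"])
    @pytest.mark.parametrize("k", [1, 3])
    def test_fast_path_bit_identical_to_naive(self, rng, mode, k):
        X = rng.normal(size=(28, 3))
        y = rng.integers(1, 4, size=28)
        fm = FeatureMatrix.from_arrays(X, y)
        cfg = CPConfig(k=k, p_value_mode=mode)
        fast_preds, fast_acc = loo_evaluate(fm, cfg)
        naive_preds, naive_acc = loo_evaluate(fm, cfg, naive=True)
        assert fast_acc == naive_acc
        for f, n in zip(fast_preds, naive_preds):
            assert f.p_values == n.p_values  # exact float equality


class TestCalibrationCurve:
    def test_tiny_epsilon_excludes_nothing_in_standard_mode(self, small_features):
        errs = calibration_curve(small_features, CPConfig(k=1), [1e-12])
        assert errs[0] == 0.0

    def test_curve_nondecreasing(self, small_features):
        errs = calibration_curve(
            small_features, CPConfig(k=1), np.linspace(0.01, 0.9, 15)
        )
        assert np.all(np.diff(errs) >= 0)


@settings(deadline=None, derandomize=True, max_examples=20)
@given(seed=st.integers(min_value=0, max_value=2**31 - 1))
def test_prediction_identities_hold_on_random_data(seed):
    """confidence = 1 - second-largest p, credibility = largest p, argmax label."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(15, 2))
    y = rng.integers(1, 4, size=15)
    model = CPModel(X, y, CPConfig(k=1))
    p = p_values(model, rng.normal(size=2))
    pred = forced_prediction(p)
    ranked = sorted(p.values(), reverse=True)
    assert pred.credibility == ranked[0]
    assert pred.confidence == 1 - ranked[1]
    assert p[pred.forced_label] == ranked[0]
    assert all(0.0 <= pv <= 1.0 for pv in p.values())
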