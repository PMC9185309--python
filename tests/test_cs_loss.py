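"""Cost-sensitive loss algebra against an independent brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from csecg import (
    batch_rates,
    blend_weights,
    class_weights,
    compute_batch_cost,
    harmonic_cost,
    misclassification_cost,
    total_loss,
)

EPS = 1e-7  # smoothing constant of the harmonic-mean reciprocals


# ---------------------------------------------------------------------------
# Brute-force oracle: scalar loops written directly from the definitions,
# independent of the vectorised implementation.
# ---------------------------------------------------------------------------

def oracle_weights(counts, total, C):
    return [total / (C * n) if n > 0 else None for n in counts]


def oracle_blend(a, b):
    return [((x * x + y * y) / 2.0) ** 0.5 for x, y in zip(a, b)]


def oracle_rates(true, pred, C):
    fpr, fnr = [], []
    for c in range(C):
        tp = sum(1 for t, p in zip(true, pred) if t == c and p == c)
        fn = sum(1 for t, p in zip(true, pred) if t == c and p != c)
        fp = sum(1 for t, p in zip(true, pred) if t != c and p == c)
        tn = sum(1 for t, p in zip(true, pred) if t != c and p != c)
        fpr.append(fp / (fp + tn) if fp + tn else 0.0)
        fnr.append(fn / (fn + tp) if fn + tp else 0.0)
    return fpr, fnr


def oracle_harmonic(fpr, fnr):
    return [0.0 if a == 0 or b == 0
            else 2.0 / (1.0 / (a + EPS) + 1.0 / (b + EPS))
            for a, b in zip(fpr, fnr)]


def oracle_state(labels, preds, dataset_counts, C):
    M = len(labels)
    batch_counts = [sum(1 for y in labels if y == c) for c in range(C)]
    cw_d = oracle_weights(dataset_counts, sum(dataset_counts), C)
    cw_d = [0.0 if w is None else w for w in cw_d]
    cw_b = oracle_weights(batch_counts, M, C)
    cw_b = [cw_d[c] if w is None else w for c, w in enumerate(cw_b)]
    cw = oracle_blend(cw_b, cw_d)
    fpr, fnr = oracle_rates(labels, preds, C)
    hm = oracle_harmonic(fpr, fnr)
    phi = [w + h for w, h in zip(cw, hm)]
    return cw_b, cw_d, cw, fpr, fnr, hm, phi


# ---------------------------------------------------------------------------
# Unit behaviour
# ---------------------------------------------------------------------------

class TestClassWeights:
    def test_balanced_counts_give_unit_weights(self):
        np.testing.assert_allclose(class_weights([5, 5], 10, 2), [1.0, 1.0])

    def test_inverse_frequency_example(self):
        np.testing.assert_allclose(
            class_weights([8, 2], 10, 2), [0.625, 2.5])

    def test_minority_weight_ratio(self):
        w = class_weights([90, 10], 100, 2)
        assert w[1] / w[0] == pytest.approx(9.0)

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError):
            class_weights([0, 0], 0, 2)


class TestBlend:
    def test_equal_inputs_unchanged(self):
        w = np.array([0.3, 1.0, 4.0])
        np.testing.assert_allclose(blend_weights(w, w), w)

    def test_hand_example(self):
        out = blend_weights([0.625], [2.5])
        assert out[0] == pytest.approx(
            np.sqrt((0.390625 + 6.25) / 2), abs=1e-12)
        assert out[0] == pytest.approx(1.8222, abs=5e-5)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            blend_weights([-0.1], [1.0])

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 100), min_size=1, max_size=5),
           st.lists(st.floats(0, 100), min_size=1, max_size=5))
    def test_quadratic_mean_dominates_arithmetic(self, a, b):
        n = min(len(a), len(b))
        a, b = np.array(a[:n]), np.array(b[:n])
        qm = blend_weights(a, b)
        assert np.all(qm >= (a + b) / 2 - 1e-9)
        assert np.all(qm >= np.minimum(a, b) - 1e-12)
        assert np.all(qm <= np.maximum(a, b) + 1e-12)


class TestRates:
    def test_perfect_predictions(self):
        fpr, fnr = batch_rates([0, 1, 2], [0, 1, 2], 3)
        np.testing.assert_array_equal(fpr, 0.0)
        np.testing.assert_array_equal(fnr, 0.0)

    def test_hand_counted_two_class_table(self):
        fpr, fnr = batch_rates([0, 0, 1, 1], [0, 1, 1, 1], 2)
        assert fnr[0] == pytest.approx(0.5) and fpr[0] == 0.0
        assert fpr[1] == pytest.approx(0.5) and fnr[1] == 0.0

    def test_degenerate_all_majority(self):
        fpr, fnr = batch_rates([0, 0, 0, 1], [0, 0, 0, 0], 2)
        assert fnr[1] == 1.0 and fpr[0] == 1.0

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError):
            batch_rates([0, 1], [0], 2)


class TestHarmonic:
    def test_equal_rates_return_that_rate(self):
        out = harmonic_cost([0.3], [0.3])
        assert out[0] == pytest.approx(0.3, abs=1e-6)

    def test_hand_example(self):
        out = harmonic_cost([0.2], [0.1])
        assert out[0] == pytest.approx(2 / (1 / 0.2 + 1 / 0.1), abs=1e-6)

    def test_zero_rate_gives_zero(self):
        np.testing.assert_array_equal(harmonic_cost([0.0], [0.9]), [0.0])
        np.testing.assert_array_equal(harmonic_cost([0.9], [0.0]), [0.0])


class TestPhi:
    def test_additivity(self):
        cw = np.array([1.8222, 0.5])
        hm = np.array([0.1333, 0.0])
        np.testing.assert_array_equal(
            misclassification_cost(cw, hm), cw + hm)

    def test_zero_performance_term_reduces_to_weights(self):
        cw = np.array([2.0, 0.3, 1.0])
        np.testing.assert_array_equal(
            misclassification_cost(cw, np.zeros(3)), cw)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.integers(2, 5), st.integers(1, 16), st.integers(0, 10**6))
    def test_minority_phi_never_drops_when_rarer(self, C, M, seed):
        """Removing minority-class samples from a batch never lowers its phi."""
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, C, M)
        labels[0] = 0                   # guarantee class 0 present
        preds = rng.integers(0, C, M)
        dataset_counts = np.full(C, 1000)
        state = compute_batch_cost(labels, preds, dataset_counts, C)
        keep = np.flatnonzero(labels == 0)[:1]
        rest = np.flatnonzero(labels != 0)
        idx = np.concatenate([keep, rest])
        smaller = compute_batch_cost(
            labels[idx], preds[idx], dataset_counts, C)
        assert smaller.CW_b[0] >= state.CW_b[0] - 1e-12


class TestTotalLoss:
    def test_unit_phi_equals_plain_cross_entropy(self, rng):
        probs = rng.dirichlet(np.ones(5), size=64)
        labels = rng.integers(0, 5, 64)
        plain = -np.mean(np.log(probs[np.arange(64), labels]))
        assert total_loss(probs, labels, np.ones(5)) == pytest.approx(
            plain, abs=1e-9)

    def test_certain_prediction_zero_loss(self):
        probs = np.array([[0.0, 1.0, 0.0, 0.0, 0.0]])
        assert total_loss(probs, [1], np.ones(5)) == 0.0

    def test_hand_weighted_example(self):
        # true-label probabilities 0.5 and 0.25 with phi 2 and 1:
        # (2*ln 2 + 1*ln 4) / 2 = 2*ln 2
        probs = np.array([[0.5, 0.5], [0.75, 0.25]])
        labels = [0, 1]
        phi = np.array([2.0, 1.0])
        assert total_loss(probs, labels, phi) == pytest.approx(
            2 * np.log(2), rel=1e-12)

    def test_zero_probability_clamped_finite(self):
        probs = np.array([[1.0, 0.0]])
        assert np.isfinite(total_loss(probs, [1], np.ones(2)))

    def test_phi_cap_applies(self):
        probs = np.array([[0.5, 0.5]])
        capped = total_loss(probs, [0], np.array([10.0, 1.0]), phi_max=2.0)
        assert capped == pytest.approx(2 * np.log(2))


class TestBatchCostComposition:
    def test_balanced_perfect_batch_gives_unit_phi(self):
        labels = np.array([0, 1, 2, 3, 4] * 3)
        state = compute_batch_cost(labels, labels, np.full(5, 100), 5)
        np.testing.assert_allclose(state.phi, 1.0, atol=1e-12)

    def test_absent_class_falls_back_to_dataset_weight(self):
        labels = np.array([0, 0, 1, 2, 3])      # class 4 (Q) missing
        state = compute_batch_cost(
            labels, labels, np.array([880, 40, 60, 15, 5]), 5)
        assert np.isfinite(state.phi).all()
        assert state.CW_b[4] == state.CW_D[4]
        assert state.CW[4] == pytest.approx(state.CW_D[4])

    def test_single_class_batch_finite(self):
        labels = np.zeros(8, dtype=int)
        state = compute_batch_cost(
            labels, labels, np.array([900, 30, 50, 15, 5]), 5)
        assert np.isfinite(state.phi).all()

    def test_serializes_to_log_row(self):
        labels = np.array([0, 1, 2, 3, 4])
        state = compute_batch_cost(labels, labels, np.full(5, 10), 5)
        row = state.to_row()
        assert len(row) == 5 * 6
        assert all(isinstance(v, float) for v in row)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.integers(2, 5), st.integers(1, 16), st.integers(0, 10**6))
    def test_matches_brute_force_oracle(self, C, M, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, C, M)
        preds = rng.integers(0, C, M)
        dataset_counts = rng.integers(1, 1000, C)
        state = compute_batch_cost(labels, preds, dataset_counts, C)
        cw_b, cw_d, cw, fpr, fnr, hm, phi = oracle_state(
            labels.tolist(), preds.tolist(), dataset_counts.tolist(), C)
        np.testing.assert_allclose(state.CW_b, cw_b, atol=1e-12, rtol=0)
        np.testing.assert_allclose(state.CW_D, cw_d, atol=1e-12, rtol=0)
        np.testing.assert_allclose(state.CW, cw, atol=1e-12, rtol=0)
        np.testing.assert_allclose(state.FPR, fpr, atol=1e-12, rtol=0)
        np.testing.assert_allclose(state.FNR, fnr, atol=1e-12, rtol=0)
        np.testing.assert_allclose(state.HM_b, hm, atol=1e-12, rtol=0)
        np.testing.assert_allclose(state.phi, phi, atol=1e-12, rtol=0)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.integers(0, 10**6))
    def test_phi_bounds(self, seed):
        rng = np.random.default_rng(seed)
        M = int(rng.integers(1, 32))
        labels = rng.integers(0, 5, M)
        preds = rng.integers(0, 5, M)
        state = compute_batch_cost(labels, preds, np.full(5, 200), 5)
        assert np.all(state.HM_b >= 0) and np.all(state.HM_b <= 1)
        assert np.all(state.phi >= state.CW)
        np.testing.assert_array_equal(state.phi, state.CW + state.HM_b)
        assert np.all(state.CW >= np.minimum(state.CW_b, state.CW_D) - 1e-12)
        assert np.all(state.CW <= np.maximum(state.CW_b, state.CW_D) + 1e-12)
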