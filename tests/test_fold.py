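"""BN threshold folding, the FC2 lookup table, and the integer-only twin."""

import numpy as np
import pytest

from bdscnn import (BNParams, bn_threshold_real, build_fc2_lut, evaluate_model,
                    fold_bn_threshold, fold_bn_thresholds, fold_model, forward,
                    integer_forward, load_weights, random_weights, save_weights)


def _bn(gamma, beta, mu, sigma, eps=1e-4):
    return BNParams(gamma=gamma, beta=beta, mu=mu, sigma=sigma, eps=eps)


class TestThresholdFold:
    def test_worked_example_folds_to_3(self):
        """The published parameter set gives a pre-floor bound of ~3.4418
        (exact evaluation 3.4419; the printed inputs are themselves rounded
        to 4 decimals) and an integer threshold of 3."""
        p = _bn(0.7093, -2.0248, 0.8035, 0.9242, eps=0.0001)
        assert bn_threshold_real(p)[0] == pytest.approx(3.4418, abs=5e-4)
        assert fold_bn_threshold(p) == 3

    def test_identity_normalization_gives_zero(self):
        assert fold_bn_threshold(_bn(1.0, 0.0, 0.0, 1.0, eps=1e-12)) == 0

    def test_zero_beta_threshold_is_mu(self):
        assert fold_bn_threshold(_bn(2.5, 0.0, 5.0, 3.0)) == 5

    def test_gamma_zero_rejected(self):
        with pytest.raises(ValueError, match="gamma = 0"):
            fold_bn_threshold(_bn(0.0, 0.0, 1.0, 1.0))

    def test_fold_correctness_exhaustive(self, rng):
        """BN(s) > 0  <=>  s > threshold, for all integer s in 0..200 and
        random positive-gamma parameter draws."""
        s = np.arange(201)
        for _ in range(2000):
            p = _bn(rng.uniform(0.05, 3), rng.normal(0, 3),
                    rng.uniform(0, 100), rng.uniform(0.05, 30))
            thr = fold_bn_threshold(p)
            np.testing.assert_array_equal(p.apply(s[:, None])[:, 0] > 0, s > thr)

    def test_negative_gamma_flips_comparator(self, rng):
        s = np.arange(201)
        for _ in range(500):
            p = _bn(-rng.uniform(0.05, 3), rng.normal(0, 3),
                    rng.uniform(0, 100), rng.uniform(0.05, 30))
            with pytest.warns(UserWarning, match="negative gamma"):
                thr, flipped = fold_bn_thresholds(p)
            assert flipped[0]
            np.testing.assert_array_equal(p.apply(s[:, None])[:, 0] > 0,
                                          s <= thr[0])


class TestFC2Lut:
    def test_max_sum_31_gives_32_entries(self):
        lut = build_fc2_lut(_bn(1.0, 0.0, 0.0, 1.0), 31)
        assert lut.shape == (32,)

    def test_identity_bn_is_identity_at_fixed_point(self):
        lut = build_fc2_lut(_bn(1.0, 0.0, 0.0, 1.0, eps=1e-12), 31)
        np.testing.assert_allclose(lut, np.arange(32), atol=1 / 64)

    def test_positive_gamma_entries_nondecreasing(self, rng):
        for _ in range(100):
            p = _bn(rng.uniform(0.05, 2), rng.normal(0, 2),
                    rng.uniform(0, 32), rng.uniform(0.5, 10))
            assert np.all(np.diff(build_fc2_lut(p, 32)) >= 0)

    def test_range_overflow_reported(self):
        with pytest.raises(OverflowError, match="13-bit"):
            build_fc2_lut(_bn(100.0, 0.0, 0.0, 1.0, eps=1e-12), 31)


class TestIntegerForward:
    def test_one_hot_has_exactly_one_bit(self, rng):
        fm = fold_model(random_weights(seed=1))
        onehot, _ = integer_forward(rng.integers(0, 2, (32, 32)),
                                    rng.integers(0, 2, 4), fm)
        assert onehot.sum() == 1

    def test_zero_image_is_deterministic(self):
        fm = fold_model(random_weights(seed=2))
        a, va = integer_forward(np.zeros((32, 32), int), np.zeros(4, int), fm)
        b, vb = integer_forward(np.zeros((32, 32), int), np.zeros(4, int), fm)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(va, vb)

    @pytest.mark.parametrize("engine", ["layerwise", "blockwise"])
    def test_argmax_matches_float_reference(self, rng, engine):
        """Integer-threshold inference classifies exactly like the
        floating-point reference (exact: both reduce to the same
        comparisons) — spot check; the full 1,000-draw sweep runs in the
        acceptance suite."""
        for seed in range(30):
            w = random_weights(seed=seed)
            fm = fold_model(w)
            img = rng.integers(0, 2, (32, 32))
            rr = rng.integers(0, 2, 4)
            _, label = forward(img, rr, w)
            onehot, _ = integer_forward(img, rr, fm, engine=engine)
            assert int(np.argmax(onehot)) == label

    def test_engines_agree(self, rng):
        fm = fold_model(random_weights(seed=9))
        img = rng.integers(0, 2, (32, 32))
        rr = rng.integers(0, 2, 4)
        a, va = integer_forward(img, rr, fm, engine="layerwise")
        b, vb = integer_forward(img, rr, fm, engine="blockwise")
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(va, vb)

    def test_hardware_lut_stays_close_to_exact(self, rng):
        fm = fold_model(random_weights(seed=3))
        img = rng.integers(0, 2, (32, 32))
        rr = rng.integers(0, 2, 4)
        _, exact = integer_forward(img, rr, fm)
        _, quant = integer_forward(img, rr, fm, hardware_lut=True)
        np.testing.assert_allclose(quant, exact, atol=1 / 128 + 1e-12)


class TestRoundTrip:
    def test_fold_serialize_load_identical_classification(self, tmp_path, rng):
        w = random_weights(seed=11)
        save_weights(w, tmp_path / "m.json")
        w2 = load_weights(tmp_path / "m.json")
        fm, fm2 = fold_model(w), fold_model(w2)
        np.testing.assert_array_equal(fm.pw_thresholds, fm2.pw_thresholds)
        np.testing.assert_array_equal(fm.fc2_lut_exact, fm2.fc2_lut_exact)
        for _ in range(20):
            img = rng.integers(0, 2, (32, 32))
            rr = rng.integers(0, 2, 4)
            a, _ = integer_forward(img, rr, fm)
            b, _ = integer_forward(img, rr, fm2)
            np.testing.assert_array_equal(a, b)


class TestEvaluate:
    def _set(self, rng, n=40):
        return [(rng.integers(0, 2, (32, 32)), rng.integers(0, 2, 4),
                 rng.integers(0, 5)) for _ in range(n)]

    def test_column_sums_are_class_counts(self, rng):
        fm = fold_model(random_weights(seed=5))
        items = self._set(rng)
        cm, _ = evaluate_model(items, fm)
        truth = np.bincount([lab for _, _, lab in items], minlength=5)
        np.testing.assert_array_equal(cm.counts.sum(axis=0), truth)

    def test_perfect_predictor_is_diagonal(self, rng):
        fm = fold_model(random_weights(seed=5))
        # label every item with whatever the model predicts
        items = [(img, rr, int(np.argmax(integer_forward(img, rr, fm)[0])))
                 for img, rr, _ in self._set(rng, 20)]
        cm, report = evaluate_model(items, fm)
        assert np.trace(cm.counts) == 20
        assert report["five_class_Acc"] == 1.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate_model([], fold_model(random_weights(seed=5)))
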