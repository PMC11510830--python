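"""Class weighting, hyperparameter sampling, forest training, nested LOSO."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from swallowdetect import RfConfig, class_weights, nested_loso, sample_hyperparams, train_rf
from swallowdetect.forest import RANDOM_RANGES, WEIGHT1_GRID, select_hyperparams


class TestClassWeights:
    def test_printed_formula(self):
        assert class_weights(100, 20, 80, weight0=1.0, weight1=2.0) == \
            (pytest.approx(0.4), pytest.approx(0.2))

    def test_balanced_counts_symmetric(self):
        w0, w1 = class_weights(100, 50, 50)
        assert w0 == w1 == pytest.approx(0.25)

    def test_single_class_edge(self):
        w0, w1 = class_weights(10, 10, 0, weight1=0.5)
        assert (w0, w1) == (0.0, pytest.approx(0.25))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            class_weights(10, 5, 4)

    @given(st.integers(1, 500), st.integers(1, 500),
           st.floats(0.5, 3.0), st.floats(0.5, 3.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_weight_ratio_identity(self, it, if_, m0, m1):
        w0, w1 = class_weights(it + if_, it, if_, m0, m1)
        assert w0 / w1 == pytest.approx((m0 * if_) / (m1 * it))

    def test_inverse_frequency_mode_flips_direction(self):
        w0, w1 = class_weights(100, 20, 80, weighting="inverse_frequency")
        assert w1 > w0  # rarer class upweighted


class TestHyperparamSampling:
    def test_cartesian_product_count(self):
        assert len(sample_hyperparams(n_random=200, seed=1)) == 6 * 200

    def test_deterministic_under_seed(self):
        assert sample_hyperparams(n_random=20, seed=7) == sample_hyperparams(n_random=20, seed=7)

    def test_values_within_declared_ranges(self):
        lams = sample_hyperparams(n_random=50, seed=3)
        for lam in lams:
            assert lam["weight1"] in WEIGHT1_GRID
            for name, (lo, hi) in RANDOM_RANGES.items():
                assert lo <= lam[name] <= hi


class TestTrainRf:
    @staticmethod
    def _separable(n=200, seed=0):
        rng = np.random.default_rng(seed)
        x0 = rng.normal(-3, 0.5, (n // 2, 4))
        x1 = rng.normal(3, 0.5, (n // 2, 4))
        x = np.vstack([x0, x1])
        y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        return x, y

    def test_separable_data_training_f1_is_one(self):
        x, y = self._separable()
        model, leaves = train_rf(x, y)
        assert np.array_equal(model.predict(x), y)
        assert leaves > 0

    def test_permuted_labels_generalise_at_chance(self):
        x, y = self._separable(n=400)
        rng = np.random.default_rng(1)
        y_perm = rng.permutation(y)
        model, _ = train_rf(x[:300], y_perm[:300])
        acc = np.mean(model.predict(x[300:]) == y_perm[300:])
        assert abs(acc - 0.5) < 0.15

    def test_pruning_reduces_complexity(self):
        x, y = self._separable(n=300, seed=2)
        x += np.random.default_rng(3).normal(0, 3, x.shape)  # force impure splits
        _, leaves_free = train_rf(x, y, RfConfig(ccp_alpha=0.0))
        _, leaves_range_top = train_rf(x, y, RfConfig(ccp_alpha=0.00125))
        _, leaves_strong = train_rf(x, y, RfConfig(ccp_alpha=0.02))
        assert leaves_range_top <= leaves_free
        assert leaves_strong < leaves_free

    def test_single_class_rejected(self):
        x = np.zeros((10, 4))
        with pytest.raises(ValueError, match="both classes"):
            train_rf(x, np.zeros(10, int))


class TestSelectionRule:
    def test_hand_traced_complexity_tie_break(self):
        o = np.asarray([[0.8, 0.8, 0.8], [0.7, 0.9, 0.8]])
        c = np.asarray([[50, 50, 50], [30, 30, 30.0]])
        # equal row means, zero standard error -> both rows inside the
        # interval, lower mean complexity wins
        assert select_hyperparams(o, c) == 1

    def test_single_row(self):
        assert select_hyperparams(np.asarray([[0.5, 0.6]]), np.asarray([[10, 10.0]])) == 0

    def test_selected_row_stays_within_one_se(self, rng):
        o = rng.uniform(0.3, 0.9, (12, 6))
        c = rng.uniform(10, 90, (12, 6))
        l_opt = select_hyperparams(o, c)
        mu = o.mean(axis=1)
        l_max = int(np.argmax(mu))
        sigma_se = np.std(o[l_max]) / np.sqrt(o.shape[1])
        rho = np.corrcoef(o[l_max], o[l_opt])[0, 1]
        assert mu[l_opt] >= mu[l_max] - sigma_se * np.sqrt(1 - rho) - 1e-12


class TestNestedLoso:
    @staticmethod
    def _dataset(n_subjects=4, per_class=8, sep=4.0, seed=0):
        rng = np.random.default_rng(seed)
        xs, ys, ss = [], [], []
        for sub in range(1, n_subjects + 1):
            xs.append(rng.normal(0, 1, (per_class, 3)))
            ys.append(np.zeros(per_class, int))
            xs.append(rng.normal(sep, 1, (per_class, 3)))
            ys.append(np.ones(per_class, int))
            ss.append(np.full(2 * per_class, sub))
        return np.vstack(xs), np.concatenate(ys), np.concatenate(ss)

    def test_signal_recovered_and_reproducible(self):
        x, y, s = self._dataset()
        lams = sample_hyperparams(n_random=2, seed=1)[:4]
        r1 = nested_loso(x, y, s, lams)
        r2 = nested_loso(x, y, s, lams)
        assert np.median(r1.f1) >= 0.9
        np.testing.assert_array_equal(r1.f1, r2.f1)
        assert r1.chosen_lambda == r2.chosen_lambda

    def test_signal_beats_permutation_null(self):
        x, y, s = self._dataset(sep=4.0)
        rng = np.random.default_rng(5)
        y_perm = np.concatenate([rng.permutation(y[s == sub]) for sub in np.unique(s)])
        lams = sample_hyperparams(n_random=1, seed=1)[:2]
        real = nested_loso(x, y, s, lams)
        null = nested_loso(x, y_perm, s, lams)
        assert np.median(real.f1) > np.median(null.f1)

    def test_needs_three_subjects(self):
        x, y, s = self._dataset(n_subjects=2)
        with pytest.raises(ValueError, match="at least 3 subjects"):
            nested_loso(x, y, s, sample_hyperparams(n_random=1)[:1])
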