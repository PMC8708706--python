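"""Fuzzy ART module: complement coding, CBD choice, vigilance search, learning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from artflow.fuzzy_art import (
    CapacityError,
    FuzzyARTModule,
    FuzzyARTParams,
    complement_code,
    match,
)

unit_vectors = arrays(
    float, st.integers(1, 8),
    elements=st.floats(0, 1, allow_nan=False, allow_infinity=False),
)


class TestComplementCode:
    def test_definition(self):
        np.testing.assert_allclose(
            complement_code(np.array([0.2, 0.7])), [0.2, 0.7, 0.8, 0.3]
        )

    def test_all_zeros(self):
        x = complement_code(np.zeros(3))
        np.testing.assert_array_equal(x, [0, 0, 0, 1, 1, 1])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(unit_vectors)
    def test_l1_norm_conservation(self, m):
        """||x||_1 = M exactly for any input in [0,1]^M."""
        assert complement_code(m).sum() == pytest.approx(len(m), abs=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            complement_code(np.array([0.5, 1.2]))
        with pytest.raises(ValueError):
            complement_code(np.array([-0.1]))


class TestMatch:
    def test_identical_weights(self):
        x = complement_code(np.array([0.3, 0.8]))
        assert match(x, x) == pytest.approx(1.0)

    def test_superset_box(self):
        x = np.array([0.5, 0.5, 0.5, 0.5])
        assert match(x, np.ones(4)) == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        x = np.array([0.5, 0.5, 0.5, 0.5])
        w = np.array([0.25, 0.5, 0.5, 0.5])
        assert match(x, w) == pytest.approx(0.875)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            match(np.zeros(4), np.ones(4))


class TestChoiceActivation:
    def test_fast_committed_cell_reaches_m(self):
        """A cell whose weights equal the input has T = ||x||_1 = M."""
        mod = FuzzyARTModule(M=3, params=FuzzyARTParams(rho=0.5))
        m = np.array([0.2, 0.6, 0.9])
        x = complement_code(m)
        mod.train_step(x)
        assert mod.choice_activation(x)[0] == pytest.approx(3.0)

    def test_all_ones_weight_column(self):
        """Uncommitted (all-ones) weights give T = alpha * M under CBD."""
        mod = FuzzyARTModule(M=2, params=FuzzyARTParams(alpha=0.01, rho=0.5))
        mod.C = 1  # leave the column at its all-ones initialization
        x = complement_code(np.array([0.5, 0.5]))
        # T = M + (1 - alpha)(M - 2M) = alpha * M
        assert mod.choice_activation(x)[0] == pytest.approx(0.01 * 2)

    def test_empty_before_any_commit(self):
        mod = FuzzyARTModule(M=4, params=FuzzyARTParams())
        assert len(mod.choice_activation(complement_code(np.zeros(4)))) == 0


def brute_force_search(x, weights, M, alpha, rho):
    """Literal transcription of the CBD + vigilance search for the oracle:
    evaluate every T_j and Gamma_j, walk T in descending order (ties to the
    lower index), return the first j with Gamma_j >= rho, else None."""
    results = []
    for j, w in enumerate(weights):
        minsum = float(np.minimum(x, w).sum())
        t = minsum + (1 - alpha) * (M - float(np.sum(w)))
        results.append((t, j, minsum / float(np.sum(x))))
    for t, j, gamma in sorted(results, key=lambda r: (-r[0], r[1])):
        if gamma >= rho:
            return j
    return None


class TestTrainStep:
    def test_first_sample_fast_commits(self):
        mod = FuzzyARTModule(M=3, params=FuzzyARTParams(rho=0.7))
        m = np.array([0.1, 0.5, 0.9])
        x = complement_code(m)
        j, new = mod.train_step(x)
        assert (j, new, mod.C) == (0, True, 1)
        np.testing.assert_array_equal(mod.weights[:, 0], x)

    def test_rho_zero_single_cell(self, rng):
        """rho = 0: one coding cell encodes every sample."""
        mod = FuzzyARTModule(M=4, params=FuzzyARTParams(rho=0.0))
        for _ in range(50):
            mod.train_step(complement_code(rng.uniform(0, 1, 4)))
        assert mod.C == 1

    def test_rho_one_cell_per_distinct_sample(self):
        """rho = 1: a separate cell commits for every distinct input."""
        mod = FuzzyARTModule(M=2, params=FuzzyARTParams(rho=1.0))
        samples = [np.array([0.1, 0.2]), np.array([0.5, 0.6]), np.array([0.9, 0.1])]
        for m in samples * 2:  # repeats re-select their own cell
            mod.train_step(complement_code(m))
        assert mod.C == 3

    def test_weight_monotonicity(self, rng):
        """Committed weight components never increase during training."""
        mod = FuzzyARTModule(M=5, params=FuzzyARTParams(rho=0.6))
        prev = mod.W.copy()
        for _ in range(80):
            mod.train_step(complement_code(rng.uniform(0, 1, 5)))
            assert np.all(mod.W <= prev + 1e-15)
            prev = mod.W.copy()

    @pytest.mark.parametrize("rho", [0.0, 0.4, 0.75, 0.95])
    def test_winner_matches_brute_force_oracle(self, rho, rng):
        """Search winner equals exhaustive enumeration on tiny problems."""
        for trial in range(20):
            params = FuzzyARTParams(rho=rho)
            mod = FuzzyARTModule(M=3, params=params)
            for s in range(5):
                x = complement_code(rng.uniform(0, 1, 3))
                expected = brute_force_search(
                    x, [mod.W[:, j] for j in range(mod.C)], 3, params.alpha, rho
                )
                j, new = mod.train_step(x)
                if expected is None:
                    assert new
                else:
                    assert (j, new) == (expected, False)

    def test_capacity_error(self):
        mod = FuzzyARTModule(M=2, params=FuzzyARTParams(rho=1.0, c_max=2))
        mod.train_step(complement_code(np.array([0.1, 0.1])))
        mod.train_step(complement_code(np.array([0.9, 0.9])))
        with pytest.raises(CapacityError):
            mod.train_step(complement_code(np.array([0.5, 0.5])))

    def test_second_epoch_is_slow_recode(self, rng):
        """Re-presenting the training set changes weights by at most the
        slow-recode step; with beta_recode = 0 they are exactly fixed."""
        samples = [rng.uniform(0, 1, 4) for _ in range(20)]
        mod = FuzzyARTModule(M=4, params=FuzzyARTParams(rho=0.5))
        for m in samples:
            mod.train_step(complement_code(m))
        w1 = mod.weights.copy()
        c1 = mod.C
        for m in samples:
            mod.train_step(complement_code(m))
        # epoch-1 cells move by at most the slow-recode rate on average
        assert np.mean(np.abs(mod.weights[:, :c1] - w1)) <= mod.params.beta_recode

        frozen = FuzzyARTModule(
            M=4, params=FuzzyARTParams(rho=0.5, beta_recode=0.0)
        )
        for m in samples:
            frozen.train_step(complement_code(m))
        wf = frozen.weights.copy()
        cf = frozen.C
        for m in samples:
            frozen.train_step(complement_code(m))
        assert frozen.C == cf  # every sample re-matches its own cell
        np.testing.assert_array_equal(frozen.weights, wf)

    def test_gamma_in_unit_interval_and_box_inclusion(self, rng):
        mod = FuzzyARTModule(M=3, params=FuzzyARTParams(rho=0.5))
        for _ in range(30):
            x = complement_code(rng.uniform(0, 1, 3))
            mod.train_step(x)
            for j in range(mod.C):
                g = match(x, mod.W[:, j])
                assert 0.0 <= g <= 1.0 + 1e-12


class TestModuleOutput:
    def test_softmax_single_cell(self):
        mod = FuzzyARTModule(M=2, params=FuzzyARTParams(rho=0.5))
        mod.train_step(complement_code(np.array([0.3, 0.3])))
        np.testing.assert_allclose(mod.output(complement_code(np.array([0.4, 0.4])),
                                              "softmax"), [1.0])

    def test_identity_returns_choice_activation(self, rng):
        mod = FuzzyARTModule(M=3, params=FuzzyARTParams(rho=0.9))
        for _ in range(5):
            mod.train_step(complement_code(rng.uniform(0, 1, 3)))
        x = complement_code(rng.uniform(0, 1, 3))
        np.testing.assert_array_equal(mod.output(x, "identity"),
                                      mod.choice_activation(x))

    def test_softmax_normalization(self, rng):
        mod = FuzzyARTModule(M=4, params=FuzzyARTParams(rho=0.95))
        for _ in range(10):
            mod.train_step(complement_code(rng.uniform(0, 1, 4)))
        x = complement_code(rng.uniform(0, 1, 4))
        assert mod.output(x, "softmax").sum() == pytest.approx(1.0, abs=1e-12)

    def test_untrained_module_errors(self):
        mod = FuzzyARTModule(M=2, params=FuzzyARTParams())
        with pytest.raises(RuntimeError):
            mod.output(complement_code(np.array([0.5, 0.5])))
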