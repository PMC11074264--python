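import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cfnn import (
    DefuzzParams,
    FuzzyRuleBank,
    ValidationError,
    defuzzify,
    fuzzify,
    gaussian_membership,
    grad_check,
)


class TestGaussianMembership:
    def test_unity_at_mean(self):
        assert gaussian_membership(1.3, 1.3, 0.5) == 1.0

    def test_one_sigma_away(self):
        assert gaussian_membership(2.0, 1.0, 1.0) == pytest.approx(
            np.exp(-0.5), abs=1e-12
        )

    def test_symmetry(self):
        m, sigma = 0.7, 0.9
        for u in (-1.0, 0.0, 2.5):
            assert gaussian_membership(u, m, sigma) == pytest.approx(
                gaussian_membership(2 * m - u, m, sigma)
            )

    def test_small_sigma_rejected(self):
        with pytest.raises(ValidationError, match="sigma"):
            gaussian_membership(0.0, 0.0, 1e-4)


@pytest.fixture
def bank():
    rng = np.random.default_rng(0)
    return FuzzyRuleBank(
        means=rng.standard_normal((4, 3)),
        sigmas=0.5 + rng.uniform(0, 1, (4, 3)),
    )


class TestFuzzify:
    @pytest.mark.parametrize("aggregation", ["geometric-mean", "product-log"])
    def test_input_at_rule_mean_fires_fully(self, bank, aggregation):
        strengths = fuzzify(bank.means[:, 1], bank, aggregation)
        assert strengths[1] == pytest.approx(1.0)
        assert np.all(strengths > 0) and np.all(strengths <= 1)

    def test_hand_computed_value(self):
        bank = FuzzyRuleBank(means=np.zeros((2, 1)), sigmas=np.ones((2, 1)))
        # exponent (1/2 + 1/2), geometric mean over 2 inputs -> exp(-1/2)
        assert fuzzify(np.array([1.0, 1.0]), bank)[0] == pytest.approx(
            np.exp(-0.5), abs=1e-12
        )

    def test_permutation_symmetry(self, bank):
        x = np.array([0.3, -1.2, 0.8, 2.0])
        perm = np.array([2, 0, 3, 1])
        scrambled = FuzzyRuleBank(
            means=bank.means[perm], sigmas=bank.sigmas[perm]
        )
        np.testing.assert_allclose(
            fuzzify(x, bank), fuzzify(x[perm], scrambled), rtol=1e-12
        )

    def test_shape_mismatch_rejected(self, bank):
        with pytest.raises(ValidationError, match="shape"):
            fuzzify(np.zeros(5), bank)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_strengths_in_unit_interval_and_decreasing(self, seed):
        rng = np.random.default_rng(seed)
        bank = FuzzyRuleBank(
            means=rng.standard_normal((3, 2)),
            sigmas=0.5 + rng.uniform(0, 1, (3, 2)),
        )
        x = rng.standard_normal(3)
        s = fuzzify(x, bank)
        assert np.all((s > 0) & (s <= 1))
        # moving one coordinate farther from every rule mean lowers strengths
        i = int(rng.integers(0, 3))
        far = x.copy()
        far[i] = bank.means[i].max() + abs(x[i] - bank.means[i]).max() + 1.0
        assert np.all(fuzzify(far, bank) <= s + 1e-12)


class TestDefuzzify:
    def test_one_hot_selects_center(self):
        params = DefuzzParams(centers=np.array([[3.0, -1.0]]))
        out = defuzzify(np.array([1.0, 0.0]), params)
        assert out[0] == pytest.approx(3.0, rel=1e-8)

    def test_uniform_activation_gives_midpoint(self):
        params = DefuzzParams(centers=np.array([[0.0, 4.0]]))
        assert defuzzify(np.array([1.0, 1.0]), params)[0] == pytest.approx(2.0)

    def test_all_zero_activation_guarded(self):
        params = DefuzzParams(centers=np.array([[5.0, 5.0], [1.0, 2.0]]))
        np.testing.assert_array_equal(defuzzify(np.zeros(2), params), np.zeros(2))

    def test_output_within_center_hull(self):
        rng = np.random.default_rng(4)
        params = DefuzzParams(centers=rng.standard_normal((2, 5)))
        x = rng.uniform(0.1, 1, 5)
        out = defuzzify(x, params)
        for k in range(2):
            assert params.centers[k].min() - 1e-9 <= out[k] <= params.centers[k].max() + 1e-9

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), alpha=st.floats(0.1, 100.0))
    def test_scale_invariance(self, seed, alpha):
        rng = np.random.default_rng(seed)
        params = DefuzzParams(centers=rng.standard_normal((3, 4)))
        x = rng.uniform(0.5, 2.0, 4)
        np.testing.assert_allclose(
            defuzzify(alpha * x, params), defuzzify(x, params), rtol=1e-6
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="shape"):
            defuzzify(np.zeros(3), DefuzzParams(centers=np.zeros((2, 2))))


class TestGradCheck:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_fuzzify_gradients(self, seed):
        assert grad_check("fuzzify", n_inputs=5, n_rules=3, seed=seed) < 1e-4

    def test_fuzzify_product_log_gradients(self):
        assert grad_check("fuzzify", aggregation="product-log", seed=3) < 1e-4

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_defuzzify_gradients(self, seed):
        assert grad_check("defuzzify", n_rules=4, n_outputs=2, seed=seed) < 1e-4

    def test_corrupted_gradient_detected(self):
        assert grad_check("fuzzify", corruption=0.1) > 1e-2
        assert grad_check("defuzzify", corruption=0.1) > 1e-2

    def test_step_size_bounds(self):
        with pytest.raises(ValidationError, match="h"):
            grad_check("fuzzify", h=1e-2)


class TestRuleBankContract:
    def test_sigma_floor_enforced(self):
        with pytest.raises(ValidationError, match="sigma"):
            FuzzyRuleBank(means=np.zeros((2, 2)), sigmas=np.full((2, 2), 1e-5))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="shape"):
            FuzzyRuleBank(means=np.zeros((2, 2)), sigmas=np.ones((3, 2)))

    def test_consequent_weights_shape(self):
        bank = FuzzyRuleBank(
            means=np.zeros((2, 3)),
            sigmas=np.ones((2, 3)),
            consequent_weights=np.array([1.0, 2.0, 3.0]),
        )
        assert bank.consequent_weights.shape == (3,)
        with pytest.raises(ValidationError):
            FuzzyRuleBank(
                means=np.zeros((2, 3)),
                sigmas=np.ones((2, 3)),
                consequent_weights=np.array([1.0]),
            )
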