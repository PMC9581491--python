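"""Index estimators against analytic variance decompositions."""

import numpy as np
import pytest

from effdim.errors import DegenerateOutputError, MissingSubsetError, NearZeroMeanError
from effdim.estimators import (
    coefficient_of_variation,
    estimate_first_order,
    estimate_indices,
    estimate_interactions,
    estimate_total_order,
)
from effdim.sampling import build_design, evaluate_on_design
from effdim.test_functions import GFunctionSpec, g_analytic_indices, sample_g_coefficients, sobol_g


def test_single_variable_model_concentrates_first_order(design_k2):
    """f(x) = x1 puts all variance on the first parameter."""
    idx = estimate_indices(design_k2, f=lambda X: X[:, 0])
    assert abs(idx.first_order[0] - 1.0) < 0.01
    assert abs(idx.first_order[1]) < 0.01


def test_g_function_dominant_input(design_k3):
    """G with a=(0,99,99): nearly all variance from x1 (oracle 0.99973)."""
    spec = GFunctionSpec((0.0, 99.0, 99.0))
    idx = estimate_indices(design_k3, f=lambda X: sobol_g(X, spec))
    assert abs(idx.first_order[0] - 0.99973) < 0.01


def test_additive_equal_variance_total_order(design_k2):
    """f = x1 + x2 on U(0,1)^2: T_1 = T_2 = 1/2."""
    idx = estimate_indices(design_k2, f=lambda X: X[:, 0] + X[:, 1])
    assert np.all(np.abs(idx.total_order - 0.5) < 0.01)


def test_g_function_symmetric_total_order():
    """G with a=(0,0): T_i = 4/7 exactly in the oracle."""
    d = build_design(2 ** 13, 2)
    spec = GFunctionSpec((0.0, 0.0))
    idx = estimate_indices(d, f=lambda X: sobol_g(X, spec))
    assert np.all(np.abs(idx.total_order - 4.0 / 7.0) < 0.01)


def test_product_model_pure_interaction(design_k2):
    """f = x1*x2: V = 7/144, V_i = 1/48, pure pair index = 1/7."""
    idx = estimate_indices(design_k2, f=lambda X: X[:, 0] * X[:, 1])
    assert abs(idx.interactions[(0, 1)] - 1.0 / 7.0) < 0.02
    assert abs(idx.closed[(0, 1)] - 1.0) < 0.02


def test_additive_model_no_interaction(design_k2):
    idx = estimate_indices(design_k2, f=lambda X: X[:, 0] + X[:, 1])
    assert abs(idx.interactions[(0, 1)]) < 0.02


def test_g_pair_interaction(design_k2):
    spec = GFunctionSpec((0.0, 0.0))
    idx = estimate_indices(design_k2, f=lambda X: sobol_g(X, spec))
    assert abs(idx.interactions[(0, 1)] - 1.0 / 7.0) < 0.02


def test_constant_model_is_degenerate(design_k2):
    with pytest.raises(DegenerateOutputError, match="constant|variance"):
        estimate_indices(design_k2, f=lambda X: np.full(X.shape[0], 3.0))


def test_length_mismatch_rejected():
    with pytest.raises(ValueError):
        estimate_first_order(np.ones(8), np.ones(7), np.ones((1, 8)), np.ones((1, 8)))
    with pytest.raises(ValueError):
        estimate_total_order(np.ones(1), np.ones(1), np.ones((1, 1)), np.ones((1, 1)))


def test_missing_subset_raises(design_k2):
    out = evaluate_on_design(lambda X: X[:, 0] * X[:, 1], design_k2)
    with pytest.raises(MissingSubsetError):
        estimate_interactions(out["yA"], out["yB"], out["y_subsets"], [(0, 1), (0, 2)],
                              np.array([0.1, 0.1]))


def test_triplet_requires_contained_pairs(design_k3):
    out = evaluate_on_design(lambda X: X.sum(axis=1), design_k3)
    with pytest.raises(MissingSubsetError, match="contained pairs"):
        estimate_interactions(out["yA"], out["yB"], out["y_subsets"], [(0, 1, 2)],
                              np.zeros(3))


def test_inclusion_exclusion_holds_exactly(design_k3):
    """Stored pure indices reconstruct the stored closed indices identically."""
    spec = GFunctionSpec((0.0, 1.0, 0.0))
    idx = estimate_indices(design_k3, f=lambda X: sobol_g(X, spec))
    for (i, j), pure in ((u, v) for u, v in idx.interactions.items() if len(u) == 2):
        assert idx.closed[(i, j)] == pytest.approx(
            pure + idx.first_order[i] + idx.first_order[j], abs=1e-14)
    u = (0, 1, 2)
    recon = (idx.interactions[u]
             + sum(idx.interactions[p] for p in [(0, 1), (0, 2), (1, 2)])
             + idx.first_order.sum())
    assert idx.closed[u] == pytest.approx(recon, abs=1e-14)


def test_oracle_equivalence_on_random_g(rng):
    """Azzini estimates track the closed-form G oracle within 0.02."""
    d_cache = {}
    for _ in range(5):
        k = int(rng.integers(2, 7))
        spec = sample_g_coefficients(k, rng)
        d = d_cache.setdefault(k, build_design(2 ** 13, k))
        idx = estimate_indices(d, f=lambda X: sobol_g(X, spec))
        an = g_analytic_indices(spec)
        assert np.max(np.abs(idx.first_order - an.S)) < 0.02
        assert np.max(np.abs(idx.total_order - an.T)) < 0.02
        # ordering: total >= first within Monte Carlo tolerance
        assert np.all(idx.total_order >= idx.first_order - 0.02)


def test_additivity_of_first_order_for_additive_model():
    d = build_design(2 ** 13, 3)
    idx = estimate_indices(d, f=lambda X: X[:, 0] + 2 * X[:, 1] + 3 * X[:, 2])
    assert 0.97 <= idx.first_order.sum() <= 1.03


def test_tidy_frame_layout(design_k3):
    idx = estimate_indices(design_k3, f=lambda X: sobol_g(X, GFunctionSpec((0.0, 0.0, 1.0))))
    frame = idx.to_frame()
    assert set(frame.columns) == {"subset", "order", "index_type", "estimate"}
    assert "1,2" in set(frame.subset)
    assert {"Si", "Ti", "Sij", "Sijl"} <= set(frame.index_type)


class TestCoefficientOfVariation:
    def test_constant_vector_is_zero(self):
        assert coefficient_of_variation(np.full(10, 4.2)) == 0.0

    def test_two_point_example(self):
        assert coefficient_of_variation(np.array([1.0, 3.0])) == pytest.approx(np.sqrt(2) / 2)

    def test_near_zero_mean_raises(self):
        y = np.array([-1.0, 1.0, -1.0, 1.0]) + 1e-15
        with pytest.raises(NearZeroMeanError):
            coefficient_of_variation(y)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation(np.array([1.0]))
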