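"""Sampling designs: swap structure, determinism, marginal transforms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from effdim.sampling import (
    MarginalSpec,
    apply_marginals,
    build_design,
    export_design,
    import_outputs,
    split_outputs,
)


@pytest.mark.parametrize(
    "N,k,orders,n_matrices,budget",
    [
        (8, 2, (), 6, 48),
        (4, 3, (2,), 11, 44),
        (16, 4, (2, 3), 2 + 8 + 6 + 4, 16 * (2 + 8 + 6 + 4)),
    ],
)
def test_evaluation_budget_counts(N, k, orders, n_matrices, budget):
    d = build_design(N, k, subset_orders=orders)
    assert len(d.matrices_in_order()) == n_matrices
    assert d.evaluation_budget == budget


def test_full_experiment_budget_at_n_1024_k_10():
    d = build_design(1024, 10, subset_orders=(2, 3))
    assert d.evaluation_budget == 1024 * (2 + 20 + 45 + 120)


@given(st.integers(1, 6), st.integers(2, 5))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_swap_consistency(k, log2n):
    """AB(i) is A except column i (from B); BA(i) symmetric; AB(u) block swap."""
    N = 2 ** log2n
    orders = tuple(o for o in (2, 3) if o <= k)
    d = build_design(N, k, subset_orders=orders)
    for i in range(k):
        for j in range(k):
            src_ab = d.B if j == i else d.A
            src_ba = d.A if j == i else d.B
            assert np.array_equal(d.AB[i][:, j], src_ab[:, j])
            assert np.array_equal(d.BA[i][:, j], src_ba[:, j])
    for u, m in d.swapped_subsets.items():
        for j in range(k):
            src = d.B if j in u else d.A
            assert np.array_equal(m[:, j], src[:, j])
    assert np.all(d.base >= 0.0) and np.all(d.base < 1.0)


def test_determinism_and_scrambling():
    a = build_design(64, 3, subset_orders=(2,))
    b = build_design(64, 3, subset_orders=(2,))
    assert np.array_equal(a.base, b.base)
    s1 = build_design(64, 3, scramble_seed=7)
    s2 = build_design(64, 3, scramble_seed=7)
    s3 = build_design(64, 3, scramble_seed=8)
    assert np.array_equal(s1.base, s2.base)
    assert not np.array_equal(s1.base, s3.base)
    assert not np.array_equal(a.base, s1.base)


def test_low_discrepancy_column_means():
    d = build_design(2 ** 10, 5)
    assert np.all(np.abs(d.base.mean(axis=0) - 0.5) < 0.01)


def test_non_power_of_two_warns_but_builds():
    with pytest.warns(UserWarning, match="power of 2"):
        d = build_design(100, 2)
    assert d.N == 100


@pytest.mark.parametrize(
    "N,k,orders",
    [(0, 2, ()), (8, 0, ()), (-4, 3, ()), (8, 2, (3,))],
)
def test_invalid_arguments_rejected(N, k, orders):
    with pytest.raises(ValueError):
        build_design(N, k, subset_orders=orders)


def test_uniform_marginals_are_identity():
    d = build_design(128, 2)
    t = apply_marginals(d, [MarginalSpec("uniform", {"low": 0, "high": 1})] * 2)
    assert t.transformed
    assert np.allclose(t.A, d.A) and np.allclose(t.B, d.B)


def test_constant_marginal_yields_constant_column():
    d = build_design(64, 2)
    t = apply_marginals(d, [
        MarginalSpec("constant", {"value": 5.0}),
        MarginalSpec("uniform", {"low": 0, "high": 1}),
    ])
    assert np.all(t.A[:, 0] == 5.0) and np.all(t.B[:, 0] == 5.0)
    assert np.var(t.AB[0][:, 0]) == 0.0


def test_discrete_marginal_partitions_by_cumulative_weight():
    m = MarginalSpec("discrete", {"values": [1.0, 2.0], "weights": [0.5, 0.5]})
    assert m.ppf(np.array([0.49]))[0] == 1.0
    assert m.ppf(np.array([0.51]))[0] == 2.0
    assert m.ppf(np.array([0.5]))[0] == 2.0  # half-open intervals


def test_normal_and_lognormal_marginals_round_trip_moments():
    d = build_design(2 ** 12, 2)
    t = apply_marginals(d, [
        MarginalSpec("normal", {"mean": 3.0, "sd": 0.5}),
        MarginalSpec("lognormal", {"mu": 0.0, "sigma": 0.25}),
    ])
    assert abs(t.A[:, 0].mean() - 3.0) < 0.02
    assert abs(np.log(t.A[:, 1]).std(ddof=1) - 0.25) < 0.01


def test_apply_marginals_validates():
    d = build_design(16, 2)
    with pytest.raises(ValueError, match="expected 2 marginals"):
        apply_marginals(d, [MarginalSpec("uniform", {})])
    t = apply_marginals(d, [MarginalSpec("uniform", {})] * 2)
    with pytest.raises(ValueError, match="already transformed"):
        apply_marginals(t, [MarginalSpec("uniform", {})] * 2)
    with pytest.raises(ValueError):
        MarginalSpec("uniform", {"low": 1.0, "high": 0.0})
    with pytest.raises(ValueError):
        MarginalSpec("discrete", {"values": [1, 2], "weights": [0.5, 0.6]})
    with pytest.raises(ValueError):
        MarginalSpec("triangular", {})


def test_split_outputs_matches_matrix_order():
    d = build_design(8, 2, subset_orders=(2,))
    # encode each matrix's position in its outputs
    y = np.concatenate([np.full(8, i) for i in range(7)])
    out = split_outputs(d, y)
    assert np.all(out["yA"] == 0) and np.all(out["yB"] == 1)
    assert np.all(out["yAB"][0] == 2) and np.all(out["yBA"][1] == 5)
    assert np.all(out["y_subsets"][(0, 1)] == 6)
    with pytest.raises(ValueError, match="budget"):
        split_outputs(d, y[:-1])


def test_design_csv_round_trip(tmp_path):
    d = build_design(16, 3, subset_orders=(2,))
    export_design(d, tmp_path / "dsg")
    assert (tmp_path / "dsg" / "design.json").exists()
    loaded = np.loadtxt(tmp_path / "dsg" / "A.csv", delimiter=",", skiprows=1)
    assert np.allclose(loaded, d.A)
    y = d.stacked()[:, 0]
    np.savetxt(tmp_path / "y.csv", y, delimiter=",")
    out = import_outputs(d, tmp_path / "y.csv")
    assert np.allclose(out["yA"], d.A[:, 0])
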