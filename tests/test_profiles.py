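"""Ancestry-profile fitting: simplex constraints, oracle agreement,
pseudo-individual bootstrap."""

import numpy as np
import pandas as pd
import pytest

from coanpipe import (
    bootstrap_profile_intervals,
    cluster_mean_vector,
    donor_basis_vectors,
    donor_self_profile,
    fit_ancestry_profile,
)


def random_basis(G, seed=0, conc=5.0):
    rng = np.random.default_rng(seed)
    B = rng.dirichlet(np.full(G, conc), size=G)
    B += np.eye(G)  # diagonally dominant, well conditioned
    B /= B.sum(axis=1, keepdims=True)
    return pd.DataFrame(B, index=[f"g{k}" for k in range(G)],
                        columns=[f"g{k}" for k in range(G)])


def simplex_grid(G, step):
    """All grid points with coordinates multiple of step summing to 1."""
    n = int(round(1 / step))

    def rec(prefix, remaining, slots):
        if slots == 1:
            yield prefix + [remaining]
            return
        for k in range(remaining + 1):
            yield from rec(prefix + [k], remaining - k, slots - 1)

    for point in rec([], n, G):
        yield np.array(point) / n


def test_exact_self_and_mixture_recovery():
    B = random_basis(4, seed=1)
    for k in range(4):
        prof = fit_ancestry_profile(B.to_numpy()[k], B)
        expect = np.zeros(4)
        expect[k] = 1.0
        assert np.allclose(prof.coefficients, expect, atol=1e-8)
    beta = np.array([0.7, 0.3, 0.0, 0.0])
    y = B.to_numpy().T @ beta
    prof = fit_ancestry_profile(y, B)
    assert np.allclose(prof.coefficients, beta, atol=1e-8)


@pytest.mark.parametrize("seed", range(5))
def test_exact_mixture_recovery_random_simplex(seed):
    rng = np.random.default_rng(seed)
    B = random_basis(5, seed=seed + 10)
    beta = rng.dirichlet(np.ones(5))
    y = B.to_numpy().T @ beta
    prof = fit_ancestry_profile(y, B)
    kept = beta.copy()
    kept[kept < 1e-4] = 0.0  # reporting convention zeroes tiny coefficients
    kept /= kept.sum()
    assert np.abs(prof.coefficients - kept).max() < 1e-6


def test_profile_always_on_simplex():
    rng = np.random.default_rng(3)
    B = random_basis(3, seed=4)
    for _ in range(10):
        y = rng.dirichlet(np.ones(3))
        prof = fit_ancestry_profile(y, B)
        assert np.all(prof.coefficients >= 0)
        assert prof.coefficients.sum() == pytest.approx(1.0, abs=1e-9)


def test_agreement_with_simplex_grid_search_oracle():
    rng = np.random.default_rng(5)
    B = random_basis(3, seed=6)
    beta_true = np.array([0.55, 0.30, 0.15])
    y = B.to_numpy().T @ beta_true + rng.normal(0, 0.005, 3)
    prof = fit_ancestry_profile(y, B)
    best, best_r = None, np.inf
    for point in simplex_grid(3, 0.01):
        r = np.linalg.norm(B.to_numpy().T @ point - y)
        if r < best_r:
            best_r, best = r, point
    assert np.abs(prof.coefficients - best).max() < 0.02


def test_rank_deficient_basis_flagged():
    B = pd.DataFrame(
        [[0.5, 0.3, 0.2], [0.5, 0.3, 0.2], [0.2, 0.3, 0.5]],
        index=list("abc"), columns=list("abc"),
    )
    prof = fit_ancestry_profile(np.array([0.4, 0.3, 0.3]), B)
    assert prof.non_unique


def test_basis_rows_are_proportions(donor_panel, params):
    B = donor_basis_vectors(donor_panel["donors"], params)
    assert np.allclose(B.sum(axis=1), 1.0, atol=1e-9)
    # diverged groups copy themselves more than each other
    assert B.iloc[0, 0] > B.iloc[0, 1]
    assert B.iloc[1, 1] > B.iloc[1, 0]


def test_duplicated_donor_group_splits_mass(donor_panel, params):
    donors = donor_panel["donors"]
    meta = donors.metadata.copy()
    relabeled = meta.copy()
    half = [i for i, g in enumerate(meta["group"]) if g == "D1"][:4]
    relabeled.iloc[half, relabeled.columns.get_loc("group")] = "D1b"
    try:
        donors.metadata = relabeled
        B = donor_basis_vectors(donors, params)
        # a D2 target's former D1 mass is split between the twins
        d2 = B.loc["D2"]
        assert d2["D1"] > 0.05 and d2["D1b"] > 0.05
    finally:
        donors.metadata = meta


def test_single_member_group_rejected(donor_panel, params):
    donors = donor_panel["donors"]
    meta = donors.metadata.copy()
    solo = meta.copy()
    solo.iloc[0, solo.columns.get_loc("group")] = "solo"
    try:
        donors.metadata = solo
        with pytest.raises(ValueError, match="size 1"):
            donor_basis_vectors(donors, params)
    finally:
        donors.metadata = meta


def test_cluster_mean_vector_basics():
    X = pd.DataFrame(
        [[2.0, 2.0], [6.0, 2.0], [1.0, 3.0]], index=list("abc"), columns=["g1", "g2"]
    )
    single = cluster_mean_vector(X, ["a"])
    assert np.allclose(single, [0.5, 0.5])
    pair = cluster_mean_vector(X, ["a", "b"])
    assert np.allclose(pair, cluster_mean_vector(X, ["b", "a"]))
    assert np.allclose(pair, np.array([4.0, 2.0]) / 6.0)
    with pytest.raises(ValueError, match="empty"):
        cluster_mean_vector(X, [])


def test_bootstrap_zero_width_for_identical_members():
    B = random_basis(3, seed=7)
    # (members, chromosomes, groups): 4 identical members, 2 chromosomes
    member = np.array([[0.30, 0.20, 0.10], [0.25, 0.10, 0.05]])
    v = np.tile(member, (4, 1, 1))
    prof = bootstrap_profile_intervals(v, B, n_boot=50, seed=0)
    assert np.allclose(prof.lower, prof.coefficients, atol=1e-12)
    assert np.allclose(prof.upper, prof.coefficients, atol=1e-12)


def test_bootstrap_deterministic_and_brackets_point():
    rng = np.random.default_rng(8)
    B = random_basis(3, seed=9)
    v = rng.dirichlet(np.ones(3), size=(6, 4)) * 10
    p1 = bootstrap_profile_intervals(v, B, n_boot=100, seed=5)
    p2 = bootstrap_profile_intervals(v, B, n_boot=100, seed=5)
    assert np.array_equal(p1.lower, p2.lower) and np.array_equal(p1.upper, p2.upper)
    assert np.all(p1.lower <= p1.coefficients + 1e-12)
    assert np.all(p1.upper >= p1.coefficients - 1e-12)
    with pytest.raises(ValueError, match="chromosome"):
        bootstrap_profile_intervals(v[:, :1, :], B, n_boot=10, seed=0)


def test_bootstrap_interval_width_shrinks_with_members():
    rng = np.random.default_rng(11)
    B = random_basis(3, seed=12)
    widths = []
    for n in (4, 16, 64):
        v = rng.dirichlet(np.array([5.0, 3.0, 2.0]), size=(n, 4)) * 10
        p = bootstrap_profile_intervals(v, B, n_boot=150, seed=1)
        widths.append((p.upper - p.lower).mean())
    assert widths[0] > widths[1] > widths[2]


def test_donor_self_profile_exact_mixture():
    idx = list("abc")
    B = pd.DataFrame(
        [[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.45, 0.45, 0.10]],
        index=idx, columns=idx,
    )
    # group c's off-self copying is an exact 50/50 blend of a's and b's
    prof = donor_self_profile("c", B)
    assert prof.groups == ["a", "b"]
    assert np.allclose(prof.coefficients, [0.5, 0.5], atol=1e-8)
    with pytest.raises(ValueError, match="at least 3"):
        donor_self_profile("a", B.iloc[:2, :2])
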