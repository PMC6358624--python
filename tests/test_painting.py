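"""Copying-model painting: oracle equivalence, conservation, symmetries."""

import itertools

import numpy as np
import pytest
from scipy.stats import spearmanr

from coanpipe import (
    CopyingParams,
    GeneticMap,
    chromosome_level_vectors,
    coancestry_restricted,
    coancestry_square,
    paint_expected_lengths,
)


def brute_force_expected_lengths(rec, donors, gmap, params):
    """Exact expectation by enumerating every copying path."""
    D, S = donors.shape
    gaps = np.diff(gmap.cm)
    ns = np.exp(-params.switch_rate_per_cm * gaps)
    theta = params.miscopy
    total = 0.0
    exp_len = np.zeros(D)
    for path in itertools.product(range(D), repeat=S):
        p = 1.0 / D
        for t in range(S):
            p *= (1 - theta) if donors[path[t], t] == rec[t] else theta
            if t > 0:
                p *= ns[t - 1] * (path[t] == path[t - 1]) + (1 - ns[t - 1]) / D
        total += p
        for t in range(S - 1):
            exp_len[path[t]] += gaps[t] * p
    return exp_len / total


@pytest.mark.parametrize("seed,n_donors,n_sites", [(0, 3, 5), (1, 4, 6), (2, 2, 6)])
def test_forward_backward_matches_path_enumeration(seed, n_donors, n_sites):
    rng = np.random.default_rng(seed)
    cm = np.sort(rng.uniform(0, 8, n_sites))
    cm[0] = 0.0
    gmap = GeneticMap(
        np.array(["chr1"] * n_sites), (cm * 1e6).astype(np.int64) + 1, cm
    )
    rec = rng.integers(0, 2, n_sites).astype(np.int8)
    donors = rng.integers(0, 2, (n_donors, n_sites)).astype(np.int8)
    params = CopyingParams(switch_rate_per_cm=0.7, miscopy=0.05)
    oracle = brute_force_expected_lengths(rec, donors, gmap, params)
    fb = paint_expected_lengths(rec, donors, gmap, params)
    assert np.abs(fb - oracle).max() < 1e-8


def test_single_donor_gets_full_map(tiny_map, params):
    rng = np.random.default_rng(0)
    rec = rng.integers(0, 2, 6).astype(np.int8)
    donor = rng.integers(0, 2, (1, 6)).astype(np.int8)
    out = paint_expected_lengths(rec, donor, tiny_map, params)
    assert out.shape == (1,)
    assert out[0] == pytest.approx(tiny_map.total_span_cm, abs=1e-10)


def test_identical_donor_dominates(tiny_map):
    rng = np.random.default_rng(3)
    rec = rng.integers(0, 2, 6).astype(np.int8)
    donors = np.vstack([rec, 1 - rec])
    out = paint_expected_lengths(
        rec, donors, tiny_map, CopyingParams(miscopy=0.01)
    )
    assert out[0] / out.sum() >= 0.99


def test_empty_donor_set_rejected(tiny_map, params):
    rec = np.zeros(6, dtype=np.int8)
    with pytest.raises(ValueError, match="donor"):
        paint_expected_lengths(rec, np.empty((0, 6), dtype=np.int8), tiny_map, params)


def test_square_row_sums_conserved(three_deme):
    mat = three_deme["lengths"]
    span = 2 * three_deme["panel"].gmap.total_span_cm
    assert np.abs(mat.row_sums() / span - 1).max() < 1e-6
    assert np.all(np.diagonal(mat.values) == 0)


def test_square_permutation_equivariance(params):
    rng = np.random.default_rng(5)
    from coanpipe import HaplotypePanel

    cm = np.linspace(0, 20, 30)
    gmap = GeneticMap(np.array(["chr1"] * 30), (cm * 1e6).astype(np.int64) + 1, cm)
    haps = rng.integers(0, 2, (12, 30)).astype(np.int8)
    ids = [f"i{k}" for k in range(6)]
    panel = HaplotypePanel(haps, ids, gmap)
    mat = coancestry_square(panel, params)
    perm = [3, 1, 5, 0, 2, 4]
    permuted = panel.subset(perm)
    mat_p = coancestry_square(permuted, params)
    assert np.allclose(mat_p.values, mat.values[np.ix_(perm, perm)], atol=1e-9)


def test_near_identical_pair_has_row_maximum(params):
    rng = np.random.default_rng(7)
    from coanpipe import HaplotypePanel

    cm = np.linspace(0, 40, 60)
    gmap = GeneticMap(np.array(["chr1"] * 60), (cm * 1e6).astype(np.int64) + 1, cm)
    haps = rng.integers(0, 2, (12, 60)).astype(np.int8)
    haps[2:4] = haps[0:2]  # individual 1 duplicates individual 0
    panel = HaplotypePanel(haps, [f"i{k}" for k in range(6)], gmap)
    mat = coancestry_square(panel, params)
    assert np.argmax(mat.values[0]) == 1
    assert np.argmax(mat.values[1]) == 0


def test_restricted_aggregation_consistency(donor_panel, params):
    X, Xg = coancestry_restricted(donor_panel["study"], donor_panel["donors"], params)
    # aggregated row sums equal unaggregated row sums exactly
    assert np.allclose(Xg.values.sum(axis=1), X.values.sum(axis=1), atol=1e-9)
    # single donor group -> one column equal to row totals
    solo = donor_panel["donors"].metadata.copy()
    solo["group"] = "all"
    donors_solo = donor_panel["donors"]
    donors_solo_meta = donors_solo.metadata
    try:
        donors_solo.metadata = solo
        X1, Xg1 = coancestry_restricted(donor_panel["study"], donors_solo, params)
        assert Xg1.shape[1] == 1
        assert np.allclose(Xg1.values[:, 0], X1.values.sum(axis=1), atol=1e-9)
    finally:
        donors_solo.metadata = donors_solo_meta


def test_restricted_rejects_overlapping_ids(donor_panel, params):
    with pytest.raises(ValueError, match="overlap"):
        coancestry_restricted(donor_panel["study"], donor_panel["study"], params)


def test_strong_drift_recipients_prefer_own_pool(params):
    from coanpipe import simulate_structured_panel
    from coanpipe.simdata import DemeSpec, DemographicScenario, DonorSpec, GenomeSpec

    sc = DemographicScenario(
        demes=[
            # the first population naming a frequency pool fixes its drift
            DemeSpec("r1", 6, drift=0.5, pool="P1"),
            DemeSpec("r2", 6, drift=0.5, pool="P2"),
        ],
        donors=[
            DonorSpec("P1d", 8, divergence=0.5, pool="P1"),
            DonorSpec("P2d", 8, divergence=0.5, pool="P2"),
        ],
        genome=GenomeSpec(2, 80, 160),
        seed=21,
    )
    panel, _ = simulate_structured_panel(sc)
    roles = panel.metadata["role"]
    study = panel.subset_by_ids(list(roles[roles == "deme"].index))
    donors = panel.subset_by_ids(list(roles[roles == "donor"].index))
    _, Xg = coancestry_restricted(study, donors, params)
    groups = list(Xg.donors)
    own = ["P1d"] * 6 + ["P2d"] * 6
    for i in range(12):
        assert groups[int(np.argmax(Xg.values[i]))] == own[i]


def test_chromosome_vectors_sum_to_totals(donor_panel, params):
    vectors, ids, groups = chromosome_level_vectors(
        donor_panel["study"], donor_panel["donors"], params
    )
    _, Xg = coancestry_restricted(donor_panel["study"], donor_panel["donors"], params)
    assert ids == list(Xg.recipients) and groups == list(Xg.donors)
    assert np.allclose(vectors.sum(axis=1), Xg.values, atol=1e-9)


def test_swapping_chromosome_content_swaps_vectors(params):
    from coanpipe import HaplotypePanel

    rng = np.random.default_rng(9)
    cm = np.concatenate([np.linspace(0, 30, 40), np.linspace(0, 30, 40)])
    chrom = np.array(["chr1"] * 40 + ["chr2"] * 40)
    gmap = GeneticMap(chrom, (np.arange(80) * 1e5).astype(np.int64) + 1, cm)
    study_h = rng.integers(0, 2, (4, 80)).astype(np.int8)
    donor_h = rng.integers(0, 2, (8, 80)).astype(np.int8)
    import pandas as pd

    dmeta = pd.DataFrame(
        {"group": ["g1", "g1", "g2", "g2"]}, index=["d0", "d1", "d2", "d3"]
    )
    study = HaplotypePanel(study_h, ["s0", "s1"], gmap)
    donors = HaplotypePanel(donor_h, ["d0", "d1", "d2", "d3"], gmap, dmeta)
    v1, _, _ = chromosome_level_vectors(study, donors, params)
    # swap the two chromosomes' allele content for everyone
    swap = np.concatenate([np.arange(40, 80), np.arange(0, 40)])
    study_s = HaplotypePanel(study_h[:, swap], ["s0", "s1"], gmap)
    donors_s = HaplotypePanel(donor_h[:, swap], ["d0", "d1", "d2", "d3"], gmap, dmeta)
    v2, _, _ = chromosome_level_vectors(study_s, donors_s, params)
    assert np.allclose(v2[:, [1, 0], :], v1, atol=1e-9)


def test_identity_monotonicity(tiny_map):
    """Flipping a donor's mismatching alleles to match never decreases its
    expected copied length."""
    rng = np.random.default_rng(13)
    params = CopyingParams(miscopy=0.05)
    rec = rng.integers(0, 2, 6).astype(np.int8)
    donors = rng.integers(0, 2, (3, 6)).astype(np.int8)
    base = paint_expected_lengths(rec, donors, tiny_map, params)[0]
    current = donors.copy()
    for s in range(6):
        if current[0, s] != rec[s]:
            current = current.copy()
            current[0, s] = rec[s]
            improved = paint_expected_lengths(rec, current, tiny_map, params)[0]
            assert improved >= base - 1e-12
            base = improved


def test_chunk_count_ranking_matches_length_ranking(three_deme, params):
    counts = coancestry_square(three_deme["panel"], params, measure="count")
    lengths = three_deme["lengths"]
    rhos = []
    for i in range(0, 60, 7):
        mask = np.arange(60) != i
        rho, _ = spearmanr(lengths.values[i, mask], counts.values[i, mask])
        rhos.append(rho)
    assert np.mean(rhos) > 0.9
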