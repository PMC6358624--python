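"""Chromosome painting under a haplotype-copying hidden-state model.

Each recipient haplotype is modelled as an imperfect mosaic of the donor
haplotypes (Li & Stephens): a hidden copying state follows a Markov chain
along the genome, switching donor with probability 1 - exp(-rho * d) over an
inter-SNP gap of d cM (uniform choice of new donor), and emitting the
recipient allele with miscopy probability theta at each site. The painting
posterior is computed exactly by the forward-backward algorithm, and the
expected amount of genome copied from each donor is accumulated in cM by
attributing each inter-SNP interval to the posterior at its left SNP.

Conservation contract: the expected copied lengths of a recipient haplotype
sum exactly to the painted map span (first to last SNP of each chromosome),
so diploid individuals' coancestry rows sum to 2 x total span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import CoancestryMatrix, GeneticMap, HaplotypePanel

__all__ = [
    "CopyingParams",
    "PaintResult",
    "paint_expected_lengths",
    "paint_panel",
    "coancestry_square",
    "coancestry_restricted",
    "chromosome_level_vectors",
    "site_group_posteriors",
]

# recipient-block size chosen so the stored forward lattice stays ~tens of MB
_MAX_LATTICE_FLOATS = 8_000_000


@dataclass
class CopyingParams:
    """Copying-model parameters (fixed by configuration, not estimated).

    switch_rate_per_cm : expected recombination-driven copy switches per cM.
    miscopy            : per-site probability of emitting the wrong allele,
                         in [0, 0.5).
    """

    switch_rate_per_cm: float = 1.0
    miscopy: float = 0.01

    def __post_init__(self) -> None:
        if not self.switch_rate_per_cm > 0:
            raise ValueError("switch_rate_per_cm must be > 0")
        if not (0 <= self.miscopy < 0.5):
            raise ValueError("miscopy must be in [0, 0.5)")


@dataclass
class PaintResult:
    """Haplotype-level painting output.

    lengths : (R, D) expected cM copied from each donor haplotype.
    counts  : (R, D) expected number of copied chunks, or None.
    chrom_lengths : (R, C, D) per-chromosome expected cM, or None.
    site_group_posteriors : (R, S, G) posterior copying probability per donor
        group at every site, or None (only built when ``group_onehot`` given).
    """

    lengths: np.ndarray
    counts: np.ndarray | None = None
    chrom_lengths: np.ndarray | None = None
    site_group_posteriors: np.ndarray | None = None


def _paint_block(
    recips: np.ndarray,
    donors: np.ndarray,
    cm: np.ndarray,
    params: CopyingParams,
    mask: np.ndarray,
    want_counts: bool,
    group_onehot: np.ndarray | None,
):
    """Forward-backward over one chromosome for a block of recipients.

    recips (R, S), donors (D, S), cm (S,) cumulative, mask (R, D) boolean
    donor availability. Returns (lengths (R,D), counts (R,D) or None,
    site group posteriors (R,S,G) or None).
    """
    R, S = recips.shape
    D = donors.shape[0]
    theta = params.miscopy
    n_allowed = mask.sum(axis=1)
    if np.any(n_allowed == 0):
        raise ValueError("every recipient needs at least one allowed donor")
    u = mask / n_allowed[:, None]  # stationary / switch-target distribution

    gaps = np.diff(cm)
    no_switch = np.exp(-params.switch_rate_per_cm * gaps)

    # emission[t] built on the fly: match -> 1-theta, mismatch -> theta
    def emission(t: int) -> np.ndarray:
        match = recips[:, t][:, None] == donors[None, :, t]
        e = np.where(match, 1.0 - theta, theta)
        e *= mask
        return e

    fwd = np.empty((S, R, D))
    f = u * emission(0)
    f /= f.sum(axis=1, keepdims=True)
    fwd[0] = f
    for t in range(1, S):
        ns = no_switch[t - 1]
        f = (ns * f + (1.0 - ns) * u) * emission(t)  # sum(f) == 1 each step
        f /= f.sum(axis=1, keepdims=True)
        fwd[t] = f

    lengths = np.zeros((R, D))
    counts = np.zeros((R, D)) if want_counts else None
    gpost = None
    if group_onehot is not None:
        gpost = np.empty((R, S, group_onehot.shape[1]))

    b = np.ones((R, D)) * mask
    # site S-1: zero-length right interval; posterior still needed for
    # chunk counts and site posteriors
    gamma = fwd[S - 1] * b
    gamma /= gamma.sum(axis=1, keepdims=True)
    if gpost is not None:
        gpost[:, S - 1] = gamma @ group_onehot
    gamma_next = gamma
    for t in range(S - 2, -1, -1):
        ns = no_switch[t]
        eb = emission(t + 1) * b
        tot = (u * eb).sum(axis=1, keepdims=True)
        b = ns * eb + (1.0 - ns) * tot
        b /= b.max(axis=1, keepdims=True)
        gamma = fwd[t] * b
        gamma /= gamma.sum(axis=1, keepdims=True)
        lengths += gaps[t] * gamma
        if gpost is not None:
            gpost[:, t] = gamma @ group_onehot
        if want_counts:
            # probability the chain stays on the same donor across the gap
            stay_num = fwd[t] * (ns + (1.0 - ns) * u) * eb
            z = ((ns * fwd[t] + (1.0 - ns) * u) * eb).sum(axis=1, keepdims=True)
            xi_diag = stay_num / z
            counts += np.maximum(gamma_next - xi_diag, 0.0)
        gamma_next = gamma
    if want_counts:
        counts += gamma  # chunk open at the first SNP
    return lengths, counts, gpost


def paint_panel(
    recipient_haps: np.ndarray,
    donor_haps: np.ndarray,
    gmap: GeneticMap,
    params: CopyingParams,
    donor_mask: np.ndarray | None = None,
    want_counts: bool = False,
    per_chromosome: bool = False,
    group_onehot: np.ndarray | None = None,
) -> PaintResult:
    """Paint a batch of recipient haplotypes against a donor haplotype set.

    ``donor_mask`` (R, D) marks which donors each recipient may copy from
    (used for leave-own-haplotypes-out painting); default all available.
    """
    recipient_haps = np.atleast_2d(recipient_haps)
    donor_haps = np.atleast_2d(donor_haps)
    R = recipient_haps.shape[0]
    D = donor_haps.shape[0]
    if D == 0:
        raise ValueError("empty donor set")
    if recipient_haps.shape[1] != gmap.n_sites or donor_haps.shape[1] != gmap.n_sites:
        raise ValueError("recipient/donor SNP grid does not match the map")
    if donor_mask is None:
        donor_mask = np.ones((R, D), dtype=bool)

    chroms = gmap.chromosomes
    lengths = np.zeros((R, D))
    counts = np.zeros((R, D)) if want_counts else None
    chrom_lengths = np.zeros((R, len(chroms), D)) if per_chromosome else None
    gpost = (
        np.zeros((R, gmap.n_sites, group_onehot.shape[1]))
        if group_onehot is not None
        else None
    )

    block = max(1, int(_MAX_LATTICE_FLOATS // max(1, gmap.n_sites * D)))
    for ci, c in enumerate(chroms):
        sl = gmap.chrom_slice(c)
        cm = gmap.cm[sl]
        for r0 in range(0, R, block):
            rs = slice(r0, min(r0 + block, R))
            L, K, G = _paint_block(
                recipient_haps[rs, sl],
                donor_haps[:, sl],
                cm,
                params,
                donor_mask[rs],
                want_counts,
                group_onehot,
            )
            lengths[rs] += L
            if want_counts:
                counts[rs] += K
            if per_chromosome:
                chrom_lengths[rs, ci] = L
            if gpost is not None:
                gpost[rs, sl] = G
    return PaintResult(lengths, counts, chrom_lengths, gpost)


def paint_expected_lengths(
    recipient_hap: np.ndarray,
    donor_haps: np.ndarray,
    gmap: GeneticMap,
    params: CopyingParams,
) -> np.ndarray:
    """Expected cM copied from each donor haplotype for one recipient."""
    donor_haps = np.atleast_2d(donor_haps)
    if donor_haps.shape[0] == 0:
        raise ValueError("empty donor set")
    res = paint_panel(recipient_hap[None, :], donor_haps, gmap, params)
    return res.lengths[0]


def site_group_posteriors(
    recipient_panel: HaplotypePanel,
    donor_panel: HaplotypePanel,
    params: CopyingParams,
) -> tuple[np.ndarray, list]:
    """Per-site posterior copying probability per donor group for every
    recipient haplotype (input to coancestry-curve dating).

    Returns (posteriors (2N, S, G), donor group labels).
    """
    groups = donor_panel.groups()
    labels = list(dict.fromkeys(groups))
    onehot = np.zeros((2 * donor_panel.n_ind, len(labels)))
    for j, g in enumerate(groups):
        onehot[2 * j : 2 * j + 2, labels.index(g)] = 1.0
    res = paint_panel(
        recipient_panel.haplotypes,
        donor_panel.haplotypes,
        recipient_panel.gmap,
        params,
        group_onehot=onehot,
    )
    return res.site_group_posteriors, labels


def _hap_to_individual(hap_level: np.ndarray) -> np.ndarray:
    """Sum a (2N_r, 2N_d) haplotype matrix into an (N_r, N_d) individual one."""
    r2, d2 = hap_level.shape
    return hap_level.reshape(r2 // 2, 2, d2 // 2, 2).sum(axis=(1, 3))


def coancestry_square(
    panel: HaplotypePanel,
    params: CopyingParams,
    measure: str = "length",
) -> CoancestryMatrix:
    """All-vs-all leave-self-out painting: each individual painted using all
    other individuals' haplotypes as donors. Row sums equal 2 x map span.

    ``measure`` is "length" (total cM, the robust default) or "count"
    (expected number of chunks, the software-default alternative).
    """
    if panel.n_ind < 3:
        raise ValueError("square coancestry needs at least 3 individuals")
    H = panel.haplotypes
    n2 = H.shape[0]
    mask = np.ones((n2, n2), dtype=bool)
    for i in range(panel.n_ind):
        mask[2 * i : 2 * i + 2, 2 * i : 2 * i + 2] = False
    res = paint_panel(
        H, H, panel.gmap, params, donor_mask=mask, want_counts=(measure == "count")
    )
    hap_level = res.counts if measure == "count" else res.lengths
    vals = _hap_to_individual(hap_level)
    np.fill_diagonal(vals, 0.0)
    return CoancestryMatrix(vals, panel.ids, panel.ids, kind="square")


def coancestry_restricted(
    recipient_panel: HaplotypePanel,
    donor_panel: HaplotypePanel,
    params: CopyingParams,
    measure: str = "length",
) -> tuple[CoancestryMatrix, CoancestryMatrix]:
    """Restricted painting: recipients copy only from the external donor set.

    Returns the individual-level rectangular matrix X (N x M) and its
    donor-group aggregation (N x n_groups, columns summed within groups).
    """
    overlap = set(recipient_panel.ids) & set(donor_panel.ids)
    if overlap:
        raise ValueError(f"recipient and donor ids overlap: {sorted(overlap)[:5]}")
    res = paint_panel(
        recipient_panel.haplotypes,
        donor_panel.haplotypes,
        recipient_panel.gmap,
        params,
        want_counts=(measure == "count"),
    )
    hap_level = res.counts if measure == "count" else res.lengths
    vals = _hap_to_individual(hap_level)
    X = CoancestryMatrix(vals, recipient_panel.ids, donor_panel.ids, kind="rect")
    donor_to_group = donor_panel.groups().to_dict()
    return X, X.aggregate_donor_groups(donor_to_group)


def chromosome_level_vectors(
    recipient_panel: HaplotypePanel,
    donor_panel: HaplotypePanel,
    params: CopyingParams,
) -> tuple[np.ndarray, list, list]:
    """Per-individual, per-chromosome donor-group copying vectors.

    Returns (vectors (N, C, G), individual ids, group labels); vectors sum
    across chromosomes to the restricted coancestry rows exactly.
    """
    if len(recipient_panel.gmap.chromosomes) < 1:
        raise ValueError("no chromosomes in map")
    res = paint_panel(
        recipient_panel.haplotypes,
        donor_panel.haplotypes,
        recipient_panel.gmap,
        params,
        per_chromosome=True,
    )
    groups = donor_panel.groups()
    labels = list(dict.fromkeys(groups))
    # donor hap -> group one-hot (2 haps per donor individual)
    onehot = np.zeros((2 * donor_panel.n_ind, len(labels)))
    for j, g in enumerate(groups):
        onehot[2 * j : 2 * j + 2, labels.index(g)] = 1.0
    chrom_hap = res.chrom_lengths  # (2N, C, 2M)
    grouped = chrom_hap @ onehot  # (2N, C, G)
    n = recipient_panel.n_ind
    vectors = grouped.reshape(n, 2, grouped.shape[1], len(labels)).sum(axis=1)
    return vectors, list(recipient_panel.ids), labels
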