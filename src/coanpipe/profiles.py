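"""Ancestry profiles: sum-to-one non-negative mixtures of donor-group
copying vectors.

A target's donor-group copying vector (proportions of genome copied from
each external donor group) is modelled as a convex combination of the donor
groups' own self-copying vectors; the mixture coefficients are the ancestry
profile. Uncertainty comes from a pseudo-individual bootstrap: each pseudo
individual takes a randomly chosen cluster member's painting for every
chromosome, preserving within-chromosome correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .painting import CopyingParams, paint_panel
from .panel import HaplotypePanel

__all__ = [
    "AncestryProfile",
    "donor_basis_vectors",
    "cluster_mean_vector",
    "fit_ancestry_profile",
    "bootstrap_profile_intervals",
    "donor_self_profile",
]

_SUM_WEIGHT = 1e4  # augmentation weight enforcing the sum-to-one constraint
_ZERO_TOL = 1e-4  # coefficients below this are reported as exact zeros


@dataclass
class AncestryProfile:
    """Simplex coefficients over donor groups, with optional bootstrap bounds."""

    target: str
    groups: list
    coefficients: np.ndarray
    residual: float
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None
    non_unique: bool = False

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if np.any(self.coefficients < 0):
            raise ValueError("profile coefficients must be non-negative")
        if abs(self.coefficients.sum() - 1.0) > 1e-9:
            raise ValueError("profile coefficients must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"group": self.groups, "coefficient": self.coefficients}
        )
        if self.lower is not None:
            out["lo95"] = self.lower
            out["hi95"] = self.upper
        return out

    def reported_groups(self) -> list:
        """Donor groups with a bootstrap range excluding zero and a point
        estimate > 0.001 (the display convention for mixture bar plots)."""
        if self.lower is None:
            return [g for g, c in zip(self.groups, self.coefficients) if c > 0.001]
        return [
            g
            for g, c, lo in zip(self.groups, self.coefficients, self.lower)
            if c > 0.001 and lo > 0
        ]


def donor_basis_vectors(
    donor_panel: HaplotypePanel,
    params: CopyingParams | None = None,
    exclude_own_group: bool = False,
) -> pd.DataFrame:
    """Basis matrix B: row k is donor group k's self-copying vector.

    Each donor individual is painted against all donor haplotypes except its
    own two (leave-own-haplotypes-out; with ``exclude_own_group`` the whole
    group is excluded instead), results aggregated by donor group, averaged
    within group and normalized to proportions.
    """
    if params is None:
        params = CopyingParams()
    groups = donor_panel.groups()
    labels = list(dict.fromkeys(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 donor groups")
    sizes = groups.value_counts()
    singles = [g for g in labels if sizes[g] < 2]
    if singles and not exclude_own_group:
        raise ValueError(f"donor groups of size 1 cannot leave self out: {singles}")

    H = donor_panel.haplotypes
    n2 = H.shape[0]
    mask = np.ones((n2, n2), dtype=bool)
    garr = np.array([groups.iloc[j // 2] for j in range(n2)])
    for i in range(donor_panel.n_ind):
        if exclude_own_group:
            mask[2 * i : 2 * i + 2, :] = garr != garr[2 * i]
        else:
            mask[2 * i : 2 * i + 2, 2 * i : 2 * i + 2] = False
    res = paint_panel(H, H, donor_panel.gmap, params, donor_mask=mask)
    onehot = np.zeros((n2, len(labels)))
    for j in range(n2):
        onehot[j, labels.index(garr[j])] = 1.0
    hap_group = res.lengths @ onehot  # (2M, G)
    ind_group = hap_group.reshape(donor_panel.n_ind, 2, -1).sum(axis=1)
    B = np.zeros((len(labels), len(labels)))
    for k, g in enumerate(labels):
        rows = ind_group[np.asarray(groups == g)]
        B[k] = rows.mean(axis=0)
    if exclude_own_group:
        np.fill_diagonal(B, 0.0)
    B /= B.sum(axis=1, keepdims=True)
    return pd.DataFrame(B, index=labels, columns=labels)


def cluster_mean_vector(X_grouped: pd.DataFrame, members) -> np.ndarray:
    """Mean of the members' donor-group rows, normalized to proportions."""
    members = list(members)
    if len(members) == 0:
        raise ValueError("empty cluster")
    rows = X_grouped.loc[members].to_numpy(dtype=float)
    mean = rows.mean(axis=0)
    return mean / mean.sum()


def _simplex_nnls(A: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Non-negative least squares with the sum-to-one constraint imposed by
    a heavily weighted augmentation row, then exact renormalization."""
    G = A.shape[1]
    A_aug = np.vstack([A, _SUM_WEIGHT * np.ones((1, G))])
    y_aug = np.concatenate([y, [_SUM_WEIGHT]])
    beta, _ = nnls(A_aug, y_aug)
    s = beta.sum()
    if s <= 0:
        beta = np.full(G, 1.0 / G)
    else:
        beta = beta / s
    resid = float(np.linalg.norm(A @ beta - y))
    return beta, resid


def fit_ancestry_profile(
    y: np.ndarray, B: pd.DataFrame, target: str = "target"
) -> AncestryProfile:
    """Fit y ~ sum_k beta_k B[k] with beta on the simplex.

    Coefficients below 1e-4 are zeroed and the rest renormalized (reporting
    convention). Rank-deficient bases are solved but flagged non-unique.
    """
    y = np.asarray(y, dtype=float)
    Bv = B.to_numpy(dtype=float)
    if y.shape[0] != Bv.shape[1]:
        raise ValueError("target vector and basis dimensions disagree")
    beta, resid = _simplex_nnls(Bv.T, y)
    beta[beta < _ZERO_TOL] = 0.0
    beta /= beta.sum()
    non_unique = np.linalg.matrix_rank(Bv) < Bv.shape[0]
    return AncestryProfile(
        target=target,
        groups=list(B.index),
        coefficients=beta,
        residual=resid,
        non_unique=bool(non_unique),
    )


def bootstrap_profile_intervals(
    chrom_vectors: np.ndarray,
    B: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    target: str = "target",
) -> AncestryProfile:
    """Pseudo-individual bootstrap of an ancestry profile.

    ``chrom_vectors`` is (n_members, n_chrom, n_groups): each member's
    chromosome-level donor-group copying vectors. Every pseudo individual
    takes a random member's painting per chromosome; the cluster average is
    re-estimated from as many pseudo individuals as members, the profile
    refit, and the inner 95% range of the ``n_boot`` re-estimations
    reported.
    """
    v = np.asarray(chrom_vectors, dtype=float)
    if v.ndim != 3:
        raise ValueError("chrom_vectors must be (members, chromosomes, groups)")
    n_mem, n_chrom, G = v.shape
    if n_chrom < 2:
        raise ValueError("pseudo-individual bootstrap needs >= 2 chromosomes")
    if n_mem < 2:
        raise ValueError("need >= 2 cluster members")

    totals = v.sum(axis=1)  # (members, G)
    mean = totals.mean(axis=0)
    point = fit_ancestry_profile(mean / mean.sum(), B, target=target)

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, G))
    for r in range(n_boot):
        picks = rng.integers(0, n_mem, size=(n_mem, n_chrom))
        pseudo = v[picks, np.arange(n_chrom)[None, :], :].sum(axis=1)
        ybar = pseudo.mean(axis=0)
        boot[r] = fit_ancestry_profile(ybar / ybar.sum(), B).coefficients
    lower = np.quantile(boot, 0.025, axis=0)
    upper = np.quantile(boot, 0.975, axis=0)
    lower = np.minimum(lower, point.coefficients)
    upper = np.maximum(upper, point.coefficients)
    point.lower = lower
    point.upper = upper
    return point


def donor_self_profile(
    group: str, B: pd.DataFrame, y: np.ndarray | None = None
) -> AncestryProfile:
    """Mixture profile of one donor group over the remaining groups.

    The group's own entry is removed from its copying vector and from every
    basis row, everything renormalized, and the profile fit on the reduced
    problem (used to ask how much of a donor group's ancestry other groups
    can explain).
    """
    if group not in B.index:
        raise ValueError(f"unknown donor group: {group}")
    if len(B.index) < 3:
        raise ValueError("need at least 3 donor groups to leave one out")
    others = [g for g in B.index if g != group]
    target_vec = (B.loc[group] if y is None else pd.Series(y, index=B.columns)).drop(
        labels=[group]
    )
    target_vec = target_vec / target_vec.sum()
    B_red = B.loc[others, others]
    B_red = B_red.div(B_red.sum(axis=1), axis=0)
    return fit_ancestry_profile(target_vec.to_numpy(), B_red, target=group)
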