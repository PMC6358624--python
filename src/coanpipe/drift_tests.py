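"""Bootstrap test for excess cross-cluster coancestry.

Within-cluster coancestry in excess of cross-cluster coancestry measures a
cluster's private drift. The reverse pattern -- a recipient cluster whose
members share, on average, more coancestry with a source cluster than with
each other -- can only arise through admixture from a highly drifted group
into the recipient population, which makes it a targeted admixture signal.

The resampling protocol: every tested cluster is sub-sampled without
replacement to a common size (default 13; coancestry is undefined between an
individual and itself, so sampling is without replacement), the coancestry
matrix is re-computed by painting the sub-sampled panel only, and mean
within-cluster (diagonal excluded) and cross-cluster coancestries are
compared. Over R resamples (default 200), S counts the null-consistent
resamples (mean within >= mean cross) and p = (S + 1) / (R + 1), so an
excess-cross pair consistent across resamples yields a small p. Pairs with
p below the reporting threshold (default 0.02, uncorrected) are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .painting import CopyingParams, coancestry_square
from .panel import HaplotypePanel

__all__ = ["BootstrapTestResult", "bootstrap_within_between_test"]


@dataclass
class BootstrapTestResult:
    """Pairwise test output over recipient (rows) x source (columns) clusters."""

    clusters: list
    S: pd.DataFrame  # count of null-consistent resamples
    p: pd.DataFrame  # (S+1)/(n_resamples+1)
    n_resamples: int
    subsample_size: int
    within_means: np.ndarray  # (R, K) per-resample mean within coancestry
    cross_means: np.ndarray  # (R, K, K) per-resample mean cross coancestry
    excluded: list = field(default_factory=list)
    flag_threshold: float = 0.02

    def flagged_pairs(self) -> list:
        out = []
        for a in self.clusters:
            for b in self.clusters:
                if a != b and self.p.loc[a, b] < self.flag_threshold:
                    out.append((a, b))
        return out


def bootstrap_within_between_test(
    panel: HaplotypePanel,
    partition,
    params: CopyingParams | None = None,
    subsample_size: int = 13,
    n_resamples: int = 200,
    seed: int = 0,
    flag_threshold: float = 0.02,
    mode: str = "repaint",
    coancestry: np.ndarray | None = None,
) -> BootstrapTestResult:
    """Bootstrap within-vs-cross coancestry test over cluster pairs.

    ``partition`` maps panel individuals to clusters (a Partition, dict or
    pandas Series). Clusters smaller than ``subsample_size`` are excluded
    with a warning. ``mode`` "repaint" recomputes the coancestry matrix on
    every sub-sampled panel (the reference protocol); "slice" is a fast
    approximation that slices a single precomputed full-panel matrix
    (``coancestry``) instead.
    """
    if params is None:
        params = CopyingParams()
    if hasattr(partition, "ids") and hasattr(partition, "labels"):
        cluster_of = pd.Series(partition.labels, index=partition.ids)
    else:
        cluster_of = pd.Series(dict(partition))
    cluster_of = cluster_of.loc[panel.ids]

    sizes = cluster_of.value_counts()
    eligible = sorted(sizes[sizes >= subsample_size].index, key=str)
    excluded = sorted(sizes[sizes < subsample_size].index, key=str)
    if excluded:
        warnings.warn(
            f"clusters smaller than {subsample_size} excluded: {excluded}"
        )
    if len(eligible) < 2:
        raise ValueError("need at least 2 clusters of sufficient size")

    index_of = {v: k for k, v in enumerate(panel.ids)}
    members = {
        c: np.array([index_of[i] for i in cluster_of[cluster_of == c].index])
        for c in eligible
    }
    K = len(eligible)
    rng = np.random.default_rng(seed)

    if mode == "slice":
        if coancestry is None:
            full = coancestry_square(panel, params).values
        else:
            full = np.asarray(coancestry, dtype=float)
    elif mode != "repaint":
        raise ValueError("mode must be 'repaint' or 'slice'")

    within = np.empty((n_resamples, K))
    cross = np.empty((n_resamples, K, K))
    for r in range(n_resamples):
        chosen = {
            c: rng.choice(members[c], size=subsample_size, replace=False)
            for c in eligible
        }
        order = np.concatenate([chosen[c] for c in eligible])
        if mode == "repaint":
            sub = panel.subset(order)
            mat = coancestry_square(sub, params).values
        else:
            mat = full[np.ix_(order, order)]
        s = subsample_size
        for a in range(K):
            blk = mat[a * s : (a + 1) * s, a * s : (a + 1) * s]
            within[r, a] = blk.sum() / (s * (s - 1))  # diagonal zeros excluded
            for b in range(K):
                if b == a:
                    cross[r, a, b] = np.nan
                    continue
                cross[r, a, b] = mat[a * s : (a + 1) * s, b * s : (b + 1) * s].mean()

    with np.errstate(invalid="ignore"):
        null_consistent = within[:, :, None] >= cross  # (R, K, K)
    S = np.nansum(null_consistent, axis=0).astype(int)
    p = (S + 1) / (n_resamples + 1)
    np.fill_diagonal(S, 0)
    pdf = pd.DataFrame(p, index=eligible, columns=eligible)
    for c in eligible:
        pdf.loc[c, c] = np.nan
    return BootstrapTestResult(
        clusters=eligible,
        S=pd.DataFrame(S, index=eligible, columns=eligible),
        p=pdf,
        n_resamples=n_resamples,
        subsample_size=subsample_size,
        within_means=within,
        cross_means=cross,
        excluded=excluded,
        flag_threshold=flag_threshold,
    )
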