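"""Core containers: genetic map, phased haplotype panel, coancestry matrices.

Coancestry is measured as the total amount of genome (in cM) for which one
individual's haplotypes are most closely matched by another specific
individual among the sampled donors; these containers carry the phased 0/1
haplotypes, the cM coordinates needed to express results in map units, and
the recipient x donor matrices produced by the painting step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GeneticMap", "HaplotypePanel", "CoancestryMatrix"]


@dataclass
class GeneticMap:
    """Per-site genetic map: chromosome label, bp position, cumulative cM.

    Sites are stored in panel order (chromosome blocks, increasing cM within
    each chromosome). ``cm`` is cumulative within its chromosome.
    """

    chrom: np.ndarray  # (S,) str or int labels
    bp: np.ndarray  # (S,) int
    cm: np.ndarray  # (S,) float, cumulative within chromosome

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.bp = np.asarray(self.bp, dtype=np.int64)
        self.cm = np.asarray(self.cm, dtype=float)
        if not (len(self.chrom) == len(self.bp) == len(self.cm)):
            raise ValueError("chrom, bp and cm must have equal length")
        for c in self.chromosomes:
            cm = self.cm[self.chrom == c]
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"cM positions decrease within chromosome {c}")
            if cm[-1] - cm[0] <= 0:
                raise ValueError(f"chromosome {c} has non-positive map length")

    @property
    def n_sites(self) -> int:
        return len(self.cm)

    @property
    def chromosomes(self) -> list:
        # preserve order of first appearance
        _, idx = np.unique(self.chrom, return_index=True)
        return list(self.chrom[np.sort(idx)])

    def chrom_slice(self, c) -> slice:
        idx = np.flatnonzero(self.chrom == c)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def span_cm(self, c) -> float:
        """Painted map length of one chromosome (first to last SNP, cM)."""
        cm = self.cm[self.chrom == c]
        return float(cm[-1] - cm[0])

    @property
    def total_span_cm(self) -> float:
        return float(sum(self.span_cm(c) for c in self.chromosomes))

    def interval_cm(self, c) -> np.ndarray:
        """Inter-SNP interval lengths (cM) for one chromosome, length S_c - 1."""
        cm = self.cm[self.chrom == c]
        return np.diff(cm)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "bp": self.bp, "cM": self.cm})


@dataclass
class HaplotypePanel:
    """Phased biallelic panel: haplotypes 2i, 2i+1 belong to individual i."""

    haplotypes: np.ndarray  # (2N, S) int8 in {0, 1}
    ids: list
    gmap: GeneticMap
    metadata: pd.DataFrame = None  # indexed by id; at least a "group" column

    def __post_init__(self) -> None:
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.int8)
        self.ids = list(self.ids)
        if self.haplotypes.shape[0] != 2 * len(self.ids):
            raise ValueError("haplotype rows must be 2 x number of individuals")
        if self.haplotypes.shape[1] != self.gmap.n_sites:
            raise ValueError("site count does not match the genetic map")
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=pd.Index(self.ids, name="id"))
        else:
            self.metadata = self.metadata.loc[self.ids]

    @property
    def n_ind(self) -> int:
        return len(self.ids)

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def groups(self) -> pd.Series:
        if "group" not in self.metadata.columns:
            raise ValueError("panel metadata has no 'group' column")
        return self.metadata["group"]

    def hap_indices(self, individual_index: int) -> tuple[int, int]:
        return 2 * individual_index, 2 * individual_index + 1

    def subset(self, individual_indices) -> "HaplotypePanel":
        individual_indices = np.asarray(individual_indices, dtype=int)
        hap_idx = np.ravel(
            np.column_stack([2 * individual_indices, 2 * individual_indices + 1])
        )
        return HaplotypePanel(
            haplotypes=self.haplotypes[hap_idx].copy(),
            ids=[self.ids[i] for i in individual_indices],
            gmap=self.gmap,
            metadata=self.metadata.iloc[individual_indices].copy(),
        )

    def subset_by_ids(self, ids) -> "HaplotypePanel":
        pos = {v: k for k, v in enumerate(self.ids)}
        return self.subset([pos[i] for i in ids])

    def concat(self, other: "HaplotypePanel") -> "HaplotypePanel":
        if other.gmap.n_sites != self.gmap.n_sites:
            raise ValueError("panels are on different SNP grids")
        meta = pd.concat([self.metadata, other.metadata])
        return HaplotypePanel(
            haplotypes=np.vstack([self.haplotypes, other.haplotypes]),
            ids=self.ids + other.ids,
            gmap=self.gmap,
            metadata=meta,
        )


@dataclass
class CoancestryMatrix:
    """Recipients x donors matrix of expected genome copied, in cM.

    ``kind`` is "square" (all-vs-all, zero diagonal) or "rect" (restricted
    painting where recipients copy only from an external donor set; columns
    may be individual donors or aggregated donor groups).
    """

    values: np.ndarray
    recipients: list
    donors: list
    kind: str = "square"  # "square" | "rect"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.recipients = list(self.recipients)
        self.donors = list(self.donors)
        if self.values.shape != (len(self.recipients), len(self.donors)):
            raise ValueError("value shape does not match id lists")
        if np.any(self.values < -1e-12):
            raise ValueError("coancestry values must be non-negative")
        if self.kind == "square":
            if len(self.recipients) != len(self.donors):
                raise ValueError("square matrix must have equal axes")
            if np.any(np.abs(np.diagonal(self.values)) > 1e-12):
                raise ValueError("square coancestry matrix must have zero diagonal")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row_sums(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.recipients, columns=self.donors)

    def aggregate_donor_groups(self, donor_to_group: dict) -> "CoancestryMatrix":
        """Sum columns within each donor group (partition of the columns)."""
        groups = [donor_to_group[d] for d in self.donors]
        order = list(dict.fromkeys(groups))
        agg = np.zeros((self.values.shape[0], len(order)))
        for j, g in enumerate(groups):
            agg[:, order.index(g)] += self.values[:, j]
        return CoancestryMatrix(agg, self.recipients, order, kind="rect")
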