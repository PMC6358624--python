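"""File formats: phased VCF / HAP-SAMPLE panels, genetic maps, metadata,
coancestry matrices, partitions and Newick trees.

Everything tabular is TSV (human-diffable); matrices carry full ids and are
written at 1e-10 precision so write/read round-trips are exact to that
precision. Trees are Newick with merge scores as branch annotations.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .clustering import ClusterTree, Partition
from .panel import CoancestryMatrix, GeneticMap, HaplotypePanel

__all__ = [
    "read_haplotypes",
    "write_vcf",
    "write_hapsample",
    "read_genetic_map",
    "write_genetic_map",
    "read_metadata",
    "write_metadata",
    "read_matrix",
    "write_matrix",
    "read_partition",
    "write_partition",
    "write_newick",
    "read_newick",
]

_META_GP_COLS = [f"gp{k}_{ax}" for k in range(1, 5) for ax in "xy"]


# ---------------------------------------------------------------- genetic map
def read_genetic_map(path: str) -> GeneticMap:
    """3-column TSV: chrom, position_bp, cM (cumulative within chromosome)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"chrom", "position_bp", "cM"} - set(df.columns)
    if missing:
        raise ValueError(f"genetic map missing columns: {sorted(missing)}")
    return GeneticMap(
        df["chrom"].to_numpy(), df["position_bp"].to_numpy(), df["cM"].to_numpy()
    )


def write_genetic_map(gmap: GeneticMap, path: str) -> None:
    pd.DataFrame(
        {"chrom": gmap.chrom.astype(str), "position_bp": gmap.bp, "cM": gmap.cm}
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


# ------------------------------------------------------------------- panels
def write_vcf(panel: HaplotypePanel, path: str) -> None:
    """Minimal phased VCF (GT only, alleles A/G placeholders)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(i) for i in panel.ids)
            + "\n"
        )
        H = panel.haplotypes
        for s in range(panel.n_sites):
            gts = "\t".join(
                f"{H[2 * i, s]}|{H[2 * i + 1, s]}" for i in range(panel.n_ind)
            )
            fh.write(
                f"{panel.gmap.chrom[s]}\t{panel.gmap.bp[s]}\tsnp{s}\tA\tG\t.\t.\t.\tGT\t{gts}\n"
            )


def _read_vcf(path: str, gmap: GeneticMap | None):
    from cyvcf2 import VCF

    vcf = VCF(path)
    ids = list(vcf.samples)
    rows, chroms, bps = [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multiallelic site at {var.CHROM}:{var.POS} is not supported"
            )
        gt = np.array(var.genotypes)  # (N, 3): a, b, phased
        if np.any(gt[:, 2] == 0):
            raise ValueError(f"unphased genotype at {var.CHROM}:{var.POS}")
        if np.any(gt[:, :2] < 0):
            raise ValueError(f"missing genotype at {var.CHROM}:{var.POS}")
        rows.append(gt[:, :2].reshape(-1))
        chroms.append(var.CHROM)
        bps.append(var.POS)
    haps = np.array(rows, dtype=np.int8).T  # (2N, S)
    return haps, ids, np.array(chroms), np.array(bps)


def write_hapsample(panel: HaplotypePanel, hap_path: str, sample_path: str) -> None:
    """HAP/SAMPLE text pair: one site per HAP row
    (chrom id pos allele0 allele1 then one column per haplotype)."""
    H = panel.haplotypes
    with open(hap_path, "w") as fh:
        for s in range(panel.n_sites):
            cols = " ".join(str(int(v)) for v in H[:, s])
            fh.write(
                f"{panel.gmap.chrom[s]} snp{s} {panel.gmap.bp[s]} A G {cols}\n"
            )
    with open(sample_path, "w") as fh:
        fh.write("ID_1 ID_2 missing\n0 0 0\n")
        for i in panel.ids:
            fh.write(f"{i} {i} 0\n")


def _read_hapsample(hap_path: str, sample_path: str):
    with open(sample_path) as fh:
        lines = [l.split() for l in fh.read().strip().splitlines()]
    ids = [l[0] for l in lines[2:]]
    chroms, bps, rows = [], [], []
    with open(hap_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 5 + 2 * len(ids):
                raise ValueError(f"HAP line {lineno}: wrong column count")
            chroms.append(parts[0])
            bps.append(int(parts[2]))
            rows.append([int(v) for v in parts[5:]])
    haps = np.array(rows, dtype=np.int8).T
    return haps, ids, np.array(chroms), np.array(bps)


def read_haplotypes(
    path: str,
    gmap: GeneticMap,
    fmt: str = "vcf",
    sample_path: str | None = None,
    metadata: pd.DataFrame | None = None,
) -> HaplotypePanel:
    """Read a phased panel (``fmt`` "vcf" or "hapsample") against a map.

    Sites must match the map exactly (chromosome and bp, same order); the
    first few offenders are listed on mismatch.
    """
    if fmt == "vcf":
        haps, ids, chroms, bps = _read_vcf(path, gmap)
    elif fmt == "hapsample":
        if sample_path is None:
            sample_path = os.path.splitext(path)[0] + ".sample"
        haps, ids, chroms, bps = _read_hapsample(path, sample_path)
    else:
        raise ValueError(f"unknown format: {fmt!r}")
    if len(bps) != gmap.n_sites:
        raise ValueError(
            f"panel has {len(bps)} sites but map has {gmap.n_sites}"
        )
    bad = np.flatnonzero(
        (bps != gmap.bp) | (chroms.astype(str) != gmap.chrom.astype(str))
    )
    if len(bad):
        off = ", ".join(
            f"{chroms[i]}:{bps[i]} (map {gmap.chrom[i]}:{gmap.bp[i]})"
            for i in bad[:5]
        )
        raise ValueError(f"panel/map site mismatch at: {off}")
    return HaplotypePanel(haps, ids, gmap, metadata)


# ------------------------------------------------------------------ metadata
def read_metadata(path: str) -> pd.DataFrame:
    """Metadata TSV indexed by id; grandparent coordinate columns optional.

    A boolean ``placeable`` column records whether all four grandparent
    coordinates are present.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str}).set_index("id")
    have = [c for c in _META_GP_COLS if c in df.columns]
    if len(have) == len(_META_GP_COLS):
        df["placeable"] = df[_META_GP_COLS].notna().all(axis=1)
    else:
        df["placeable"] = False
    return df


def write_metadata(metadata: pd.DataFrame, path: str) -> None:
    metadata.drop(columns=["placeable"], errors="ignore").to_csv(
        path, sep="\t", index=True, index_label="id", float_format="%.10g"
    )


# ------------------------------------------------------------------ matrices
def write_matrix(matrix: CoancestryMatrix, path: str) -> None:
    matrix.to_frame().to_csv(
        path, sep="\t", index=True, index_label="id", float_format="%.10e"
    )


def read_matrix(path: str, kind: str = "rect") -> CoancestryMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    vals = df.to_numpy(dtype=float)
    if kind == "square":
        np.fill_diagonal(vals, 0.0)  # absorb printed-precision residue
    return CoancestryMatrix(vals, list(df.index), list(df.columns), kind=kind)


# ----------------------------------------------------------------- partitions
def write_partition(
    partition: Partition, path: str, certainty: pd.DataFrame | None = None
) -> None:
    df = partition.to_frame()
    if certainty is not None:
        own = [
            certainty.iloc[i, partition.labels[i] - 1]
            for i in range(len(partition.ids))
        ]
        df["certainty"] = own
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_partition(path: str) -> Partition:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    return Partition(list(df["id"]), df["cluster"].to_numpy())


# ---------------------------------------------------------------------- trees
def write_newick(tree: ClusterTree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")


def read_newick(path: str):
    """Parse a Newick tree (dendropy Tree object)."""
    import dendropy

    return dendropy.Tree.get(path=path, schema="newick")
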