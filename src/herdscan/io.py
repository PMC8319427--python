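"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel either as uncompressed VCF (GT subfield, unphased) or as a
TSV dialect: rows = individuals, columns = SNP ids, cells 0/1/2/NA, with a
sidecar SNP map TSV (columns ``snp``, ``chrom``, ``pos``).  Abundance tables
and distance matrices are TSV; metadata is CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix

_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write an uncompressed VCFv4.2 with unphased GT calls."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=herdscan\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.individuals)
            + "\n"
        )
        calls = g.calls
        for j, (snp_id, row) in enumerate(g.snps.iterrows()):
            gts = [
                "./." if np.isnan(c) else _GT_CODE[c] for c in calls[:, j]
            ]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{snp_id}\tA\tB\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read genotypes from a VCF via cyvcf2 (alternate-allele dosage)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    individuals = list(vcf.samples)
    snp_rows = []
    call_rows = []
    for var in vcf:
        # gts012: 0/1/2 = alt count, 3 = missing
        gt = np.asarray(var.gt_types, dtype=float)
        gt[gt == 3] = np.nan
        snp_rows.append((var.ID, str(var.CHROM), var.POS))
        call_rows.append(gt)
    vcf.close()
    snps = pd.DataFrame(
        snp_rows, columns=["snp", "chrom", "pos"]
    ).set_index("snp")
    calls = np.array(call_rows, dtype=float).T  # individuals x snps
    return GenotypeMatrix(calls, individuals, snps)


def write_genotype_tsv(g: GenotypeMatrix, path, map_path=None) -> None:
    """Write the TSV genotype dialect plus a SNP map sidecar."""
    path = Path(path)
    df = pd.DataFrame(g.calls, index=g.individuals, columns=g.snp_ids)
    out = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.index.name = "individual"
    out.to_csv(path, sep="\t")
    if map_path is None:
        map_path = path.with_suffix(".map.tsv")
    g.snps.rename_axis("snp").to_csv(map_path, sep="\t")


def read_genotype_tsv(path, map_path=None) -> GenotypeMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if map_path is None:
        map_path = path.with_suffix(".map.tsv")
    snps = pd.read_csv(map_path, sep="\t", index_col=0)
    snps["chrom"] = snps["chrom"].astype(str)
    snps = snps.loc[df.columns]
    return GenotypeMatrix(df.to_numpy(dtype=float), list(df.index), snps)


def write_abundance_tsv(table: pd.DataFrame, path) -> None:
    table.rename_axis("sample").to_csv(path, sep="\t")


def read_abundance_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_metadata_csv(meta: pd.DataFrame, path) -> None:
    meta.rename_axis("animal").to_csv(path)


def read_metadata_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_square_tsv(ids, matrix: np.ndarray, path) -> None:
    pd.DataFrame(matrix, index=ids, columns=ids).rename_axis("id").to_csv(
        path, sep="\t"
    )


def read_square_tsv(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return list(df.index), df.to_numpy(dtype=float)
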