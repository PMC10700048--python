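"""Reading and writing genotype matrices.

Two interchange formats are supported: a delimited genotype table
(individuals x loci, codes 0/1/2 with NA for missing) paired with a
two-column group-assignment table, and plain uncompressed VCF (biallelic,
unphased, contig-less locus ids — one synthetic contig per locus, as GBS
tags carry no genomic order).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .coalsim import GenotypeMatrix

__all__ = [
    "write_genotype_table",
    "read_genotype_table",
    "write_vcf",
    "read_vcf",
]


def write_genotype_table(G: GenotypeMatrix, geno_path, groups_path) -> None:
    df = pd.DataFrame(
        G.genotypes.astype(object), index=G.individual_ids, columns=G.locus_ids
    )
    df = df.mask(df < 0, "NA")
    df.to_csv(geno_path, sep="\t", index_label="individual")
    pd.DataFrame({
        "individual": G.individual_ids,
        "group": [G.group_names[i] for i in G.group_indices],
    }).to_csv(groups_path, sep="\t", index=False)


def read_genotype_table(geno_path, groups_path, group_order=None) -> GenotypeMatrix:
    df = pd.read_csv(geno_path, sep="\t", index_col=0, na_values=["NA"])
    grp = pd.read_csv(groups_path, sep="\t").set_index("individual")["group"]
    grp = grp.reindex(df.index)
    if grp.isna().any():
        missing = list(df.index[grp.isna()])
        raise ValueError(f"individuals without group assignment: {missing[:5]}")
    names = tuple(group_order) if group_order else tuple(dict.fromkeys(grp))
    gidx = np.array([names.index(g) for g in grp])
    genotypes = df.to_numpy(dtype=float)
    genotypes = np.where(np.isnan(genotypes), -1, genotypes).astype(np.int8)
    return GenotypeMatrix(genotypes, gidx, names,
                          individual_ids=list(df.index.astype(str)),
                          locus_ids=list(df.columns.astype(str)))


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write a minimal unphased biallelic VCF (one synthetic contig per locus)."""
    path = Path(path)
    code_to_gt = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=abcsnp\n")
        for lid in G.locus_ids:
            fh.write(f"##contig=<ID={lid},length=2>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.individual_ids) + "\n")
        for j, lid in enumerate(G.locus_ids):
            gts = "\t".join(code_to_gt[int(c)] for c in G.genotypes[:, j])
            fh.write(f"{lid}\t1\t{lid}\tA\tT\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path, groups_path=None, group_assignment=None, group_order=None) -> GenotypeMatrix:
    """Read a VCF into a genotype matrix of alt-allele dosages.

    Multi-allelic records are kept with their allele count recorded in
    ``n_alleles`` (dosage counts any non-reference allele), so the biallelic
    QC filter can drop them. Group labels come from a two-column table
    (``groups_path``) or an explicit mapping.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, ids, n_alleles = [], [], []
    for var in vcf:
        rows.append(var.gt_types.copy())
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        n_alleles.append(1 + len(var.ALT))
    vcf.close()
    gt = np.array(rows, dtype=np.int16).T  # samples x loci; 3 = unknown
    genotypes = np.where(gt == 3, -1, gt).astype(np.int8)

    if group_assignment is None:
        if groups_path is None:
            raise ValueError("either groups_path or group_assignment is required")
        grp = pd.read_csv(groups_path, sep="\t").set_index("individual")["group"]
        group_assignment = grp.to_dict()
    labels = [group_assignment[s] for s in samples]
    names = tuple(group_order) if group_order else tuple(dict.fromkeys(labels))
    gidx = np.array([names.index(g) for g in labels])
    return GenotypeMatrix(genotypes, gidx, names, individual_ids=samples,
                          locus_ids=ids, n_alleles=np.array(n_alleles))
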