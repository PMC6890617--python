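"""Reading and writing the pipeline's on-disk dialects.

Genotypes travel either as VCF v4.2 (biallelic SNPs, GT field) or as a
plain dosage TSV (rows = individuals, header = marker ids, missing = NA);
phenotypes as a TSV with columns id, sex (M/F) and one column per trait.
VCF reading goes through cyvcf2 when available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, validate_phenotypes

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_phenotypes",
    "read_phenotypes",
]

_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(genotypes: GenotypeMatrix, path: str) -> None:
    """Write biallelic GT-only VCF v4.2; missing dosages become ./. ."""
    m = genotypes.n_markers
    chrom = genotypes.chrom or ["1"] * m
    pos = genotypes.pos if genotypes.pos is not None else np.arange(1, m + 1)
    ref = genotypes.ref or ["A"] * m
    alt = genotypes.alt or ["G"] * m
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.individual_ids)
            + "\n"
        )
        for j in range(m):
            calls = "\t".join(
                _GT.get(d, "./.") if np.isfinite(d) else "./."
                for d in genotypes.dosages[:, j]
            )
            fh.write(
                f"{chrom[j]}\t{int(pos[j])}\t{genotypes.marker_ids[j]}\t{ref[j]}\t{alt[j]}"
                f"\t.\tPASS\t.\tGT\t{calls}\n"
            )


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF into dosages of the ALT allele (via cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    cols, mids, chrom, pos, ref, alt = [], [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"variant {var.ID or var.POS} is not biallelic")
        gts = np.asarray(var.genotype.array())[:, :2].astype(float)
        gts[gts < 0] = np.nan
        cols.append(gts.sum(axis=1))
        mids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
    return GenotypeMatrix(
        dosages=np.column_stack(cols) if cols else np.zeros((len(samples), 0)),
        individual_ids=samples,
        marker_ids=mids,
        chrom=chrom,
        pos=np.asarray(pos),
        ref=ref,
        alt=alt,
    )


def write_dosage_tsv(genotypes: GenotypeMatrix, path: str) -> None:
    df = pd.DataFrame(
        genotypes.dosages, index=genotypes.individual_ids, columns=genotypes.marker_ids
    )
    df.to_csv(path, sep="\t", index_label="id", na_rep="NA")


def read_dosage_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="id", na_values="NA")
    return GenotypeMatrix(
        dosages=df.to_numpy(float),
        individual_ids=[str(i) for i in df.index],
        marker_ids=[str(c) for c in df.columns],
    )


def write_phenotypes(pheno: pd.DataFrame, path: str) -> None:
    validate_phenotypes(pheno)
    pheno.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str) -> pd.DataFrame:
    pheno = pd.read_csv(path, sep="\t")
    validate_phenotypes(pheno)
    return pheno
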