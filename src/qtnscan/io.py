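"""Plain-text I/O: VCF 4.2 genotypes, pedigree/phenotype/expression TSV.

The writer emits minimal uncompressed VCF 4.2 with GT fields (phased '|'
when haplotypes are available, '/' otherwise); the reader accepts any
VCF-like text with GT as the first FORMAT key. TSV layouts follow the
containers: pedigree (id, sire, dam, sex, generation), phenotypes indexed
by animal id, expression counts genes x samples.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

__all__ = ["write_vcf", "read_vcf", "write_tsv", "read_pedigree",
           "read_phenotypes", "read_expression"]


def write_vcf(g: GenotypeMatrix, path) -> None:
    path = Path(path)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(g.samples),
    ]
    phased = g.haplotypes is not None
    for j, (snp_id, row) in enumerate(g.snps.iterrows()):
        calls = []
        for i in range(g.n_samples):
            if phased:
                h = g.haplotypes[i, j]
                call = "." if h[0] < 0 else f"{h[0]}|{h[1]}"
            else:
                dose = g.dosage[i, j]
                if np.isnan(dose):
                    call = "./."
                else:
                    call = {0: "0/0", 1: "0/1", 2: "1/1"}[int(dose)]
            calls.append(call)
        lines.append(
            f"{row['chrom']}\t{int(row['pos'])}\t{snp_id}\t{row.get('ref', 'C')}"
            f"\t{row.get('alt', 'A')}\t.\tPASS\t.\tGT\t" + "\t".join(calls)
        )
    path.write_text("\n".join(lines) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    samples: list[str] = []
    snp_rows = []
    dosages = []
    haps = []
    phased_all = True
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            chrom, pos, vid, ref, alt = fields[0], int(fields[1]), fields[2], fields[3], fields[4]
            snp_rows.append((vid, chrom, pos, pos / 1e6, ref, alt))
            row_d = []
            row_h = []
            for call in fields[9:]:
                gt = call.split(":")[0]
                if gt in (".", "./.", ".|."):
                    row_d.append(np.nan)
                    row_h.append((-1, -1))
                    continue
                sep = "|" if "|" in gt else "/"
                a, b = (int(x) for x in gt.split(sep))
                row_d.append(a + b)
                row_h.append((a, b) if sep == "|" else (-1, -1))
                if sep != "|":
                    phased_all = False
            dosages.append(row_d)
            haps.append(row_h)
    if not samples or not snp_rows:
        raise ValueError(f"no genotype records in {path}")
    snps = pd.DataFrame(
        snp_rows, columns=["id", "chrom", "pos", "cm", "ref", "alt"]
    ).set_index("id")
    dosage = np.array(dosages, dtype=float).T
    hap_arr = None
    if phased_all:
        hap_arr = np.array(haps, dtype=np.int8)  # (n_snps, n_samples, 2)
        hap_arr = hap_arr.transpose(1, 0, 2)     # (n_samples, n_snps, 2)
    return GenotypeMatrix(samples=samples, snps=snps, dosage=dosage,
                          haplotypes=hap_arr)


def write_tsv(df: pd.DataFrame, path, index_label=None) -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_pedigree(path) -> pd.DataFrame:
    ped = pd.read_csv(path, sep="\t", dtype={"id": str, "sire": str, "dam": str})
    return ped.set_index("id")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
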