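"""Readers and writers for the tabular interchange formats.

Genotypes travel either as VCF (biallelic SNPs, GT field; read through cyvcf2)
or as a dosage CSV (rows = individuals, columns = markers) accompanied by a
marker-map CSV (marker, chrom, pos_bp, pos_cM). Pedigree and phenotype tables
are plain CSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .simdata import DosageMatrix

__all__ = [
    "write_dosage_csv", "read_dosage_csv",
    "write_vcf", "read_vcf",
    "write_pedigree_csv", "read_pedigree_csv",
    "write_phenotypes_csv", "read_phenotypes_csv",
]


def write_dosage_csv(dm: DosageMatrix, dosage_path: str | Path,
                     map_path: str | Path | None = None) -> None:
    df = pd.DataFrame(dm.dosages, index=dm.individual_ids,
                      columns=dm.marker_ids)
    df.index.name = "individual_id"
    df.to_csv(dosage_path, float_format="%.6g")
    if map_path is not None:
        mp = dm.marker_map.copy()
        mp.index.name = "marker_id"
        mp.to_csv(map_path)


def read_dosage_csv(dosage_path: str | Path,
                    map_path: str | Path) -> DosageMatrix:
    df = pd.read_csv(dosage_path, index_col=0)
    mp = pd.read_csv(map_path, index_col=0)
    mp = mp.loc[df.columns]
    return DosageMatrix(list(df.index.astype(str)), list(df.columns),
                        df.to_numpy(dtype=float), mp)


def write_vcf(dm: DosageMatrix, path: str | Path,
              phased_ids: Sequence[str] = ()) -> None:
    """Minimal biallelic-SNP VCF with GT; phased (h1|h2) for individuals whose
    haplotypes are stored and listed in ``phased_ids``, unphased otherwise.

    Fractional dosages cannot be represented as GT and raise.
    """
    d = dm.dosages
    if not np.isin(d, (0.0, 1.0, 2.0)).all():
        raise ValueError("VCF output requires integer dosages")
    phased = set(phased_ids)
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
              "FORMAT"] + list(dm.individual_ids)
    lines.append("\t".join(header))
    unphased_gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    for j, m in enumerate(dm.marker_ids):
        row = dm.marker_map.iloc[j]
        fields = [str(row["chrom"]), str(int(row["pos_bp"])), m, "A", "T",
                  ".", "PASS", ".", "GT"]
        for i, ind in enumerate(dm.individual_ids):
            if ind in phased and dm.haplotypes is not None:
                h = dm.haplotypes[i, j]
                fields.append(f"{h[0]}|{h[1]}")
            else:
                fields.append(unphased_gt[int(d[i, j])])
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path, map_cM_per_Mb: float = 10.0) -> DosageMatrix:
    """Read biallelic SNP genotypes from VCF into a DosageMatrix.

    The cM position is approximated from bp with a constant rate unless a map
    is supplied separately. Phased genotypes populate the haplotype store when
    every record is phased.
    """
    from cyvcf2 import VCF  # optional dependency (extras: vcf)

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    dosages, hap_rows, rows, marker_ids = [], [], [], []
    all_phased = True
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        gts = var.genotype.array()
        dosages.append(gts[:, :2].sum(axis=1).astype(float))
        hap_rows.append(gts[:, :2].astype(np.int8))
        all_phased &= bool(gts[:, 2].all())
        marker_ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        rows.append((var.CHROM, var.POS, var.POS / 1e6 * map_cM_per_Mb))
    mp = pd.DataFrame(rows, columns=["chrom", "pos_bp", "pos_cM"],
                      index=marker_ids)
    hap = np.stack(hap_rows, axis=1) if all_phased else None
    return DosageMatrix(ids, marker_ids, np.array(dosages).T, mp,
                        haplotypes=hap)


def write_pedigree_csv(pop: pd.DataFrame, path: str | Path) -> None:
    off = pop[pop["role"] == "offspring"]
    out = off[["individual_id", "cross_id", "parent1", "parent2"]].rename(
        columns={"individual_id": "offspring", "cross_id": "cross"})
    out.to_csv(path, index=False)


def read_pedigree_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str)


def write_phenotypes_csv(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False, float_format="%.8g")


def read_phenotypes_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
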