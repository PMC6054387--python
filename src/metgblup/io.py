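"""Readers and writers for the package's plain-text formats.

Phenotypes travel as long-format CSV (``line,env,value``; an empty value
field marks a missing cell). Genotypes are a lines x markers dosage CSV
(header = marker ids, first column = line id) or a VCF of biallelic sites
(dosage = count of the alternate allele). Kinship matrices are square CSV
with line ids as header row and first column.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .grm import KinshipMatrix, MarkerMatrix

__all__ = [
    "read_phenotypes",
    "write_phenotypes",
    "read_genotypes_csv",
    "write_genotypes_csv",
    "read_genotypes_vcf",
    "write_genotypes_vcf",
    "read_kinship",
    "write_kinship",
    "read_genotypes",
]


def read_phenotypes(path) -> pd.DataFrame:
    """Long phenotype table; empty value fields become missing cells.

    Duplicate (line, env) records and malformed rows are rejected with the
    offending line number.
    """
    path = Path(path)
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ConfigError(f"{path}: empty phenotype file")
        header = [h.strip().lower() for h in header]
        if header[:3] != ["line", "env", "value"]:
            raise ConfigError(
                f"{path}: expected header 'line,env,value', got {','.join(header)}"
            )
        for lineno, rec in enumerate(reader, start=2):
            if not rec or all(not f.strip() for f in rec):
                continue
            if len(rec) < 3:
                raise ConfigError(f"{path}:{lineno}: expected 3 fields, got {len(rec)}")
            raw = rec[2].strip()
            if raw in ("", "NA", "nan"):
                val = np.nan
            else:
                try:
                    val = float(raw)
                except ValueError:
                    raise ConfigError(f"{path}:{lineno}: non-numeric value {raw!r}")
            rows.append({"line": rec[0].strip(), "env": rec[1].strip(), "value": val})
    df = pd.DataFrame(rows)
    if df.empty:
        raise ConfigError(f"{path}: no phenotype records")
    dup = df.duplicated(subset=["line", "env"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ConfigError(
            f"{path}: duplicate record for line={first['line']} env={first['env']}"
        )
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    out = df[["line", "env", "value"]].copy()
    out.to_csv(path, index=False, na_rep="")


def read_genotypes_csv(path) -> MarkerMatrix:
    df = pd.read_csv(path, index_col=0)
    return MarkerMatrix(
        df.to_numpy(dtype=float),
        [str(s) for s in df.index],
        [str(s) for s in df.columns],
    )


def write_genotypes_csv(mm: MarkerMatrix, path) -> None:
    pd.DataFrame(mm.dosages, index=mm.line_ids, columns=mm.marker_ids).to_csv(
        path, na_rep=""
    )


def read_genotypes_vcf(path) -> MarkerMatrix:
    """Biallelic sites from a VCF; dosage = alternate-allele count per line."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    lines = list(vcf.samples)
    dosages, ids = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        # gt_types: 0 hom-ref, 1 het, 3 hom-alt, 2 unknown
        gt = var.gt_types.astype(float)
        dos = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        dosages.append(dos)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
    vcf.close()
    if not dosages:
        raise ConfigError(f"{path}: no biallelic variants found")
    return MarkerMatrix(np.array(dosages).T, lines, ids)


def write_genotypes_vcf(mm: MarkerMatrix, path) -> None:
    """Minimal single-chromosome VCF with dosages encoded as diploid GT."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(mm.line_ids)
            + "\n"
        )
        for j, mid in enumerate(mm.marker_ids):
            calls = [
                gt_map.get(v, "./.") if np.isfinite(v) else "./."
                for v in mm.dosages[:, j]
            ]
            fh.write(f"1\t{j + 1}\t{mid}\tA\tB\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")


def read_genotypes(path) -> MarkerMatrix:
    """Dispatch on extension: .vcf/.vcf.gz -> VCF reader, else CSV."""
    name = str(path)
    if name.endswith((".vcf", ".vcf.gz")):
        return read_genotypes_vcf(path)
    return read_genotypes_csv(path)


def read_kinship(path) -> KinshipMatrix:
    df = pd.read_csv(path, index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ConfigError(f"{path}: kinship row and column ids disagree")
    return KinshipMatrix(df.to_numpy(dtype=float), [str(s) for s in df.index])


def write_kinship(K: KinshipMatrix, path) -> None:
    pd.DataFrame(K.values, index=K.line_ids, columns=K.line_ids).to_csv(path)
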