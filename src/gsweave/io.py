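"""Readers and writers for genotype, map and phenotype files.

Formats
-------
* genotype matrix: delimited text, header row = marker ids, first column =
  line ids, entries 0/1/2 (or -1/0/1, auto-detected) with a configurable
  missing sentinel; or VCF v4.x restricted to biallelic SNPs.
* marker map: delimited text with >= 3 columns
  (marker_name, chromosome_name, distance_from_origin).
* phenotypes: two-column delimited text (line_id, value), complete.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, MarkerMap, PhenotypeVector

__all__ = [
    "read_genotypes",
    "read_map",
    "read_phenotypes",
    "write_genotypes",
    "write_map",
    "write_phenotypes",
]


def _sep_for(path: str, sep):
    if sep is not None:
        return sep
    return "\t" if os.fspath(path).endswith((".tsv", ".txt")) else ","


def read_genotypes(
    path,
    format_hint: str = "auto",
    missing: str = "NA",
    sep: str | None = None,
) -> GenotypeMatrix:
    """Read a dosage matrix (lines x markers) from delimited text or VCF.

    {-1,0,1}-coded input (presence of -1, absence of 2) is detected and
    shifted to the canonical {0,1,2} coding.

    Parameters
    ----------
    format_hint : {"auto", "matrix", "vcf"}
    missing : missing-value sentinel for delimited input (default "NA";
        empty cells are always treated as missing).
    """
    path = os.fspath(path)
    fmt = format_hint
    if fmt == "auto":
        fmt = "vcf" if path.endswith((".vcf", ".vcf.gz")) else "matrix"
    if fmt == "vcf":
        return _read_vcf(path)

    df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0, dtype=str,
                     na_values=[missing, ""], keep_default_na=False)
    if df.empty:
        raise ValueError(f"{path}: no genotype rows found")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        # locate the offending cell for a useful message
        for i, row in enumerate(df.itertuples(index=True)):
            for j, cell in enumerate(row[1:]):
                if pd.isna(cell):
                    continue
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: unparseable genotype {cell!r} at line "
                        f"{row[0]!r}, marker {df.columns[j]!r}"
                    ) from None
        raise
    obs = values[~np.isnan(values)]
    if obs.size and obs.min() == -1 and obs.max() <= 1:
        values = values + 1.0  # {-1,0,1} coding detected
    return GenotypeMatrix(df.index.to_numpy(), df.columns.to_numpy(), values)


def _read_vcf(path: str) -> GenotypeMatrix:
    """Biallelic SNPs of a VCF converted to alt-allele dosage; multi-allelic
    records are rejected."""
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(path)
    line_ids = np.asarray(vcf.samples, dtype=str)
    marker_ids, columns = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"{path}: multi-allelic record at {var.CHROM}:{var.POS}; "
                "split or filter to biallelic SNPs first"
            )
        name = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        marker_ids.append(name)
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt(cyvcf2 gives 3), 2=unknown
        dos = np.asarray(var.gt_types, dtype=float)
        dos[dos == 2] = np.nan  # UNKNOWN
        dos[dos == 3] = 2.0
        columns.append(dos)
    if not columns:
        raise ValueError(f"{path}: no variants found")
    dosage = np.column_stack(columns)
    return GenotypeMatrix(line_ids, np.asarray(marker_ids, dtype=str), dosage)


def read_map(path, sep: str | None = None) -> MarkerMap:
    """Read a marker map with columns marker_name, chromosome_name,
    distance_from_origin (extra columns ignored); sorted by (chromosome,
    position) on load."""
    path = os.fspath(path)
    df = pd.read_csv(path, sep=_sep_for(path, "\t" if sep is None else sep))
    if df.shape[1] < 3:
        raise ValueError(f"{path}: marker map needs >= 3 columns "
                         "(marker_name, chromosome_name, distance_from_origin)")
    df = df.iloc[:, :3]
    df.columns = ["marker_id", "chromosome", "position"]
    try:
        df["position"] = pd.to_numeric(df["position"], errors="raise")
    except (ValueError, TypeError):
        raise ValueError(f"{path}: non-numeric map position") from None
    return MarkerMap(df)


def read_phenotypes(path, sep: str | None = None) -> PhenotypeVector:
    """Read a two-column (line_id, value) phenotype file; values must be
    numeric and complete."""
    path = os.fspath(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype={0: str})
    if df.empty:
        raise ValueError(f"{path}: empty phenotype file")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: phenotype file needs 2 columns (line_id, value)")
    ids = df.iloc[:, 0].astype(str)
    try:
        vals = pd.to_numeric(df.iloc[:, 1], errors="raise")
    except (ValueError, TypeError):
        raise ValueError(f"{path}: non-numeric phenotype value") from None
    return PhenotypeVector(pd.Series(vals.to_numpy(), index=ids.to_numpy()))


# -- writers (used by the simulator and the CLI) ------------------------


def write_genotypes(geno: GenotypeMatrix, path, missing: str = "NA", sep: str | None = None):
    df = geno.to_dataframe()
    df.to_csv(os.fspath(path), sep=_sep_for(path, sep), na_rep=missing)


def write_map(marker_map: MarkerMap, path):
    t = marker_map.table.rename(columns={
        "marker_id": "marker_name",
        "chromosome": "chromosome_name",
        "position": "distance_from_origin",
    })
    t.to_csv(os.fspath(path), sep="\t", index=False)


def write_phenotypes(pheno: PhenotypeVector, path, sep: str | None = None):
    df = pd.DataFrame({"line_id": pheno.line_ids, "value": pheno.values.to_numpy()})
    df.to_csv(os.fspath(path), sep=_sep_for(path, sep), index=False)
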