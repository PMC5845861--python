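"""Readers and writers for the package's tabular interchange formats.

All genomic coordinates are 1-based inclusive internally; BED exports are
0-based half-open.  Validation errors name the offending file, line and
value so a malformed table fails loudly at load time rather than deep in a
scan.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_data import validate_marker_map

__all__ = [
    "read_marker_map",
    "read_genotypes",
    "read_phenotypes",
    "read_plate",
    "read_gff3_genes",
    "write_bed",
]


class TableFormatError(ValueError):
    """A tabular input violated its schema."""


def read_marker_map(path) -> pd.DataFrame:
    """Read a marker map TSV (marker_id, chrom, pos_bp, pos_cm) with validation."""
    df = pd.read_csv(path, sep="\t")
    try:
        validate_marker_map(df)
    except ValueError as exc:
        raise TableFormatError(f"{path}: {exc}") from exc
    df["pos_bp"] = df["pos_bp"].astype(int)
    df["pos_cm"] = df["pos_cm"].astype(float)
    return df


def read_genotypes(path) -> pd.DataFrame:
    """Read a genotype TSV (rows = segregants, cells 0/1/NA).

    Any cell other than 0, 1 or NA raises TableFormatError naming the line
    (1-based, header = line 1) and column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for j, col in enumerate(df.columns):
        vals = df[col]
        for i, v in enumerate(vals):
            if pd.isna(v) or v in ("NA", "NaN", ""):
                out.iloc[i, j] = np.nan
            elif v in ("0", "0.0"):
                out.iloc[i, j] = 0.0
            elif v in ("1", "1.0"):
                out.iloc[i, j] = 1.0
            else:
                raise TableFormatError(
                    f"{path}: line {i + 2}, column {col!r}: invalid allele {v!r} "
                    "(expected 0, 1 or NA)"
                )
    out.index.name = "segregant_id"
    return out


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype TSV; requires strain_id and condition plus >= 1 value column."""
    df = pd.read_csv(path, sep="\t")
    missing = {"strain_id", "condition"} - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing columns {sorted(missing)}")
    value_cols = [c for c in df.columns if c not in ("strain_id", "condition", "replicate")]
    if not value_cols:
        raise TableFormatError(f"{path}: no phenotype value columns")
    return df


def read_plate(path) -> pd.DataFrame:
    """Read a long-format plate CSV (strain_id, condition, aging_day, time_h, od).

    Checks non-negative OD and strictly increasing time within each
    strain x condition x aging_day series.
    """
    df = pd.read_csv(path)
    missing = {"strain_id", "condition", "aging_day", "time_h", "od"} - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing columns {sorted(missing)}")
    if (df["od"] < 0).any():
        line = int(df.index[df["od"] < 0][0]) + 2
        raise TableFormatError(f"{path}: line {line}: negative OD")
    for key, grp in df.groupby(["strain_id", "condition", "aging_day"]):
        t = grp["time_h"].to_numpy()
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise TableFormatError(
                f"{path}: non-monotone or negative time for series {key}"
            )
    return df


def read_gff3_genes(path) -> tuple[pd.DataFrame, int]:
    """Extract gene features from a GFF3 file into (gene, chrom, start_bp, end_bp).

    Gene names come from the Name attribute, falling back to ID.  Malformed
    feature lines are skipped; returns (table, number of lines skipped).
    """
    rows, skipped = [], 0
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                skipped += 1
                continue
            chrom, _, ftype, start, end, _, _, _, attrs = parts
            if ftype != "gene":
                continue
            try:
                start_bp, end_bp = int(start), int(end)
            except ValueError:
                skipped += 1
                continue
            fields = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            name = fields.get("Name", fields.get("ID"))
            if name is None or start_bp > end_bp:
                skipped += 1
                continue
            rows.append(
                {"gene": name, "chrom": chrom, "start_bp": start_bp, "end_bp": end_bp}
            )
    return pd.DataFrame(rows, columns=["gene", "chrom", "start_bp", "end_bp"]), skipped


def write_bed(intervals: pd.DataFrame, path, name_col: str = "peak_marker") -> None:
    """Write intervals (1-based inclusive start_bp/end_bp) as 0-based half-open BED."""
    path = Path(path)
    with open(path, "w") as fh:
        for _, row in intervals.iterrows():
            name = row.get(name_col, ".")
            fh.write(
                f"{row['chrom']}\t{int(row['start_bp']) - 1}\t{int(row['end_bp'])}\t{name}\n"
            )
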