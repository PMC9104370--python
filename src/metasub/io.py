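"""Readers and writers for the tabular formats the pipeline consumes.

All coordinates are held 1-based inclusive internally (the SEG
convention); the BED reader converts from 0-based half-open on load.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEG_COLUMNS = ["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]
MAF_COLUMNS = [
    "Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification", "Protein_Change",
]


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a features x samples TSV matrix (expression, miRNA, ...).

    First column holds feature identifiers, header row holds sample IDs,
    body is numeric. Missing values and duplicate identifiers are
    rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate feature identifiers")
    if df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate sample identifiers")
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values not allowed in matrix input")
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path: str | Path, index_name: str = "gene") -> None:
    df = df.copy()
    df.index.name = index_name
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_seg(path: str | Path) -> pd.DataFrame:
    """Read segmented copy number (SEG): ID, chrom, loc.start, loc.end,
    num.mark, seg.mean; 1-based inclusive coordinates."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: SEG file missing columns {missing}")
    df = df[SEG_COLUMNS].copy()
    df["chrom"] = df["chrom"].astype(str)
    if (df["loc.start"] > df["loc.end"]).any():
        bad = df.index[df["loc.start"] > df["loc.end"]][0]
        raise ValueError(f"{path}: malformed segment at row {bad}: start > end")
    return df


def write_seg(df: pd.DataFrame, path: str | Path) -> None:
    df[SEG_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_maf(path: str | Path) -> pd.DataFrame:
    """Read a MAF-like mutation table; extra columns are ignored."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: mutation table missing columns {missing}")
    return df[MAF_COLUMNS].copy()


def write_maf(df: pd.DataFrame, path: str | Path) -> None:
    df[MAF_COLUMNS].to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read gene coordinates from BED (chrom, start, end, name).

    BED is 0-based half-open; the returned frame ('gene', 'chrom',
    'start', 'end') is 1-based inclusive.
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "gene"],
                     usecols=[0, 1, 2, 3])
    out = pd.DataFrame({
        "gene": df["gene"].astype(str),
        "chrom": df["chrom"].astype(str),
        "start": df["start"].astype(int) + 1,
        "end": df["end"].astype(int),
    })
    if (out["start"] > out["end"]).any():
        raise ValueError(f"{path}: gene with start > end")
    return out


def write_bed(coords: pd.DataFrame, path: str | Path) -> None:
    """Write 1-based inclusive gene coordinates back out as BED."""
    with Path(path).open("w") as fh:
        for row in coords.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.gene}\n")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read the clinical table: first column sample ID, then covariates.

    Survival outcomes use paired columns ``os_time``/``os_event`` and
    ``rfs_time``/``rfs_event`` (days; event 0/1). Empty cells are kept
    as NaN and handled pairwise downstream.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate sample identifiers")
    return df
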