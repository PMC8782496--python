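"""Readers and writers for the plain-text formats used throughout.

Conventions
-----------
* MAF-like mutation tables are tab-separated with 1-based inclusive
  coordinates (``Start_Position``).
* SEG-style segment tables are 1-based inclusive in files and converted
  to 0-based half-open internally.
* Methylation peak files are BED-like (0-based half-open) with two extra
  columns, ``enrichment_fold`` and ``q_value``.
* Count matrices are genes-in-rows TSVs.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import pandas as pd

# Internal mutation-table schema <-> MAF column names
_MAF_COLUMNS = {
    "gene": "Hugo_Symbol",
    "chrom": "Chromosome",
    "pos": "Start_Position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
    "consequence": "Variant_Classification",
    "depth_tumor": "t_depth",
    "alt_tumor": "t_alt_count",
    "depth_normal": "n_depth",
    "alt_normal": "n_alt_count",
}

# MAF Variant_Classification <-> internal consequence vocabulary
_MAF_CLASSIFICATION = {
    "missense": "Missense_Mutation",
    "nonsense": "Nonsense_Mutation",
    "splice_site": "Splice_Site",
    "frameshift": "Frame_Shift_Del",
    "inframe_indel": "In_Frame_Del",
    "synonymous": "Silent",
}
_MAF_CLASSIFICATION_REV = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Splice_Site": "splice_site",
    "Frame_Shift_Del": "frameshift",
    "Frame_Shift_Ins": "frameshift",
    "In_Frame_Del": "inframe_indel",
    "In_Frame_Ins": "inframe_indel",
    "Silent": "synonymous",
}

_SCORE_COLUMNS = [
    "popfreq_max",
    "fathmm_mkl",
    "sift",
    "polyphen2_class",
    "mutationassessor_class",
]


def resource_path(name: str) -> Path:
    """Path to a packaged data file under ``multilesion/resources``."""
    return Path(importlib.resources.files("multilesion") / "resources" / name)


def read_maf(path) -> pd.DataFrame:
    """Read a MAF-like TSV into the internal mutation-table schema.

    ``Tumor_Sample_Barcode`` of the form ``<patient>-<lesion>`` is split
    into ``patient`` and ``lesion`` columns.
    """
    raw = pd.read_csv(path, sep="\t", comment="#")
    df = pd.DataFrame()
    barcode = raw["Tumor_Sample_Barcode"].astype(str)
    df["patient"] = barcode.str.split("-").str[0]
    df["lesion"] = barcode.str.split("-").str[1]
    for internal, maf in _MAF_COLUMNS.items():
        df[internal] = raw[maf]
    df["consequence"] = df["consequence"].map(
        lambda c: _MAF_CLASSIFICATION_REV.get(c, c)
    )
    for col in _SCORE_COLUMNS:
        if col in raw.columns:
            df[col] = raw[col]
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_maf(df: pd.DataFrame, path) -> None:
    """Write an internal mutation table as a MAF-like TSV."""
    out = pd.DataFrame()
    out["Tumor_Sample_Barcode"] = (
        df["patient"].astype(str) + "-" + df["lesion"].astype(str)
    )
    for internal, maf in _MAF_COLUMNS.items():
        out[maf] = df[internal]
    out["Variant_Classification"] = out["Variant_Classification"].map(
        lambda c: _MAF_CLASSIFICATION.get(c, c)
    )
    for col in _SCORE_COLUMNS:
        if col in df.columns:
            out[col] = df[col]
    out.to_csv(path, sep="\t", index=False)


def read_segments(path) -> pd.DataFrame:
    """Read an extended SEG TSV (1-based inclusive) to internal 0-based.

    Expected columns: ``sample, chrom, start, end, num_mark, seg_mean``
    plus the allele-specific extension ``total_cn, major_cn, minor_cn,
    purity, ploidy``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df = df.copy()
    df["start"] = df["start"].astype(int) - 1  # to 0-based half-open
    df["end"] = df["end"].astype(int)
    return df


def write_segments(df: pd.DataFrame, path) -> None:
    """Write internal 0-based segments as a 1-based inclusive SEG TSV."""
    out = df.copy()
    out["start"] = out["start"].astype(int) + 1
    out["end"] = out["end"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_peaks(path) -> pd.DataFrame:
    """Read a BED+2 peak file: chrom, start, end, enrichment_fold, q_value."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "enrichment_fold", "q_value"],
        dtype={"chrom": str},
    )
    return df


def write_peaks(df: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end", "enrichment_fold", "q_value"]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_counts(path) -> pd.DataFrame:
    """Read a genes-in-rows count matrix TSV (first column = gene)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical table TSV (the packaged fixture's column layout)."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])
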