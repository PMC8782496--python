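"""Somatic-variant filtering, mutational burden and driver annotation.

Operates on mutation tables (:class:`pandas.DataFrame`) with one row per
variant call and the columns

``patient, lesion, chrom, pos, ref, alt, gene, consequence,
depth_tumor, alt_tumor, depth_normal, alt_normal, popfreq_max,
fathmm_mkl, sift, polyphen2_class, mutationassessor_class``

``consequence`` uses the vocabulary ``missense, nonsense, splice_site,
frameshift, inframe_indel, synonymous``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: consequence categories counted as nonsynonymous (protein-altering)
NONSYNONYMOUS = frozenset(
    {"missense", "nonsense", "splice_site", "frameshift", "inframe_indel"}
)
KNOWN_CONSEQUENCES = NONSYNONYMOUS | {"synonymous"}

#: truncating categories that qualify as candidate drivers outright
_TRUNCATING = frozenset({"nonsense", "frameshift", "splice_site"})

_DAMAGING_POLYPHEN = frozenset({"possibly_damaging", "probably_damaging"})
_DAMAGING_MA = frozenset({"medium", "high"})

# Default exome footprint (Mb) used to normalise mutation counts.
EXOME_SIZE_MB = 38.0


@dataclass(frozen=True)
class DriverCatalog:
    """Driver gene symbols with an origin tag per symbol.

    Origins distinguish a pan-cancer compilation from a disease-specific
    (e.g. pancreatic cancer) list; a gene may appear in both.
    """

    genes: dict = field(default_factory=dict)  # symbol -> frozenset of origins

    def __post_init__(self):
        if not self.genes:
            raise ValueError("DriverCatalog must not be empty")

    def __contains__(self, gene) -> bool:
        return gene in self.genes

    def symbols(self, origin: str | None = None) -> frozenset:
        if origin is None:
            return frozenset(self.genes)
        return frozenset(g for g, o in self.genes.items() if origin in o)

    @classmethod
    def from_lists(cls, pan_cancer=(), disease=()) -> "DriverCatalog":
        genes: dict = {}
        for g in pan_cancer:
            genes[g] = genes.get(g, frozenset()) | {"pan_cancer"}
        for g in disease:
            genes[g] = genes.get(g, frozenset()) | {"disease"}
        return cls(genes)


#: small built-in catalog of recurrently mutated pancreatic-cancer genes
#: plus common pan-cancer drivers; real analyses should supply their own.
DEFAULT_CATALOG = DriverCatalog.from_lists(
    pan_cancer=[
        "TP53", "KRAS", "PIK3CA", "PTEN", "APC", "BRAF", "EGFR", "MYC",
        "RB1", "ARID1A", "ATM", "BRCA1", "BRCA2", "SMAD4", "CDKN2A",
        "KMT2D", "KDM6A", "CTNNB1", "NRAS", "FBXW7",
    ],
    disease=[
        "KRAS", "TP53", "CDKN2A", "SMAD4", "ARID1A", "RNF43", "TGFBR2",
        "GNAS", "RREB1", "KDM6A", "MAP2K4", "U2AF1", "PLCB4", "ZNF521",
        "ACVR1B", "SF3B1",
    ],
)


def _validate_reads(table: pd.DataFrame) -> None:
    for col in ("depth_tumor", "alt_tumor", "depth_normal", "alt_normal"):
        if (table[col] < 0).any():
            raise ValueError(f"negative read counts in column {col!r}")
    if (table["alt_tumor"] > table["depth_tumor"]).any() or (
        table["alt_normal"] > table["depth_normal"]
    ).any():
        raise ValueError("alt read count exceeds depth")


def filter_somatic_variants(
    calls: pd.DataFrame,
    min_depth: int = 20,
    max_alt_normal: int = 5,
    min_alt_tumor: int = 5,
    max_popfreq: float = 0.01,
) -> pd.DataFrame:
    """Apply depth/support/population-frequency filters to variant calls.

    A call passes iff tumour and normal depth are both >= ``min_depth``,
    at most ``max_alt_normal`` alternative reads support it in the
    germline, at least ``min_alt_tumor`` support it in the tumour, and
    its maximum population frequency across databases is < ``max_popfreq``.
    Missing population frequency is treated as 0 (novel variant).

    Returns a copy with boolean ``passed_filter`` and
    ``is_nonsynonymous`` columns added.
    """
    table = calls.copy()
    if len(table) == 0:
        table["passed_filter"] = pd.Series(dtype=bool)
        table["is_nonsynonymous"] = pd.Series(dtype=bool)
        return table
    _validate_reads(table)
    popfreq = table.get("popfreq_max", pd.Series(0.0, index=table.index))
    popfreq = popfreq.fillna(0.0)
    table["passed_filter"] = (
        (table["depth_tumor"] >= min_depth)
        & (table["depth_normal"] >= min_depth)
        & (table["alt_normal"] <= max_alt_normal)
        & (table["alt_tumor"] >= min_alt_tumor)
        & (popfreq < max_popfreq)
    )
    table["is_nonsynonymous"] = table["consequence"].isin(NONSYNONYMOUS)
    return table


def compute_tmb(table: pd.DataFrame, exome_mb: float = EXOME_SIZE_MB) -> float:
    """Tumour mutational burden: passed nonsynonymous mutations per Mb."""
    if exome_mb <= 0:
        raise ValueError("exome_mb must be positive")
    if len(table) == 0:
        return 0.0
    n = int((table["passed_filter"] & table["is_nonsynonymous"]).sum())
    return n / exome_mb


def tmb_per_lesion(
    table: pd.DataFrame, exome_mb: float = EXOME_SIZE_MB
) -> pd.Series:
    """TMB for every (patient, lesion) in a filtered cohort table."""
    return table.groupby(["patient", "lesion"], sort=True).apply(
        lambda t: compute_tmb(t, exome_mb), include_groups=False
    )


def classify_mutation_types(table: pd.DataFrame):
    """Proportions of nonsynonymous consequence categories + multi-hit genes.

    Returns ``(proportions, multi_hit)`` where ``proportions`` is a
    Series over nonsynonymous categories summing to 1 and ``multi_hit``
    lists (patient, lesion, gene) combinations carrying >= 2 distinct
    passed nonsynonymous mutations.
    """
    unknown = set(table["consequence"]) - set(KNOWN_CONSEQUENCES)
    if unknown:
        raise ValueError(f"unknown consequence labels: {sorted(unknown)}")
    passed = table[table["passed_filter"] & table["is_nonsynonymous"]]
    counts = passed["consequence"].value_counts()
    proportions = counts / counts.sum() if counts.sum() else counts.astype(float)
    per_gene = passed.groupby(["patient", "lesion", "gene"]).size()
    multi_hit = per_gene[per_gene >= 2].reset_index(name="n_mutations")
    return proportions, multi_hit


def annotate_driver_mutations(
    table: pd.DataFrame, catalog: DriverCatalog = DEFAULT_CATALOG
) -> pd.DataFrame:
    """Flag candidate driver mutations.

    A passed mutation is a candidate driver iff its gene is in the
    catalog and it is either truncating (nonsense, frameshift,
    splice-site) or a missense call predicted damaging: FATHMM-MKL
    score > 0.5, or at least two concordant damaging predictions among
    SIFT (<= 0.05), PolyPhen2 (possibly/probably damaging),
    MutationAssessor (medium/high) and FATHMM-MKL (> 0.5).  Missing
    scores count as non-damaging.
    """
    table = table.copy()
    fathmm = pd.to_numeric(
        table.get("fathmm_mkl", np.nan), errors="coerce"
    ).fillna(-1.0)
    sift = pd.to_numeric(table.get("sift", np.nan), errors="coerce")
    polyphen = table.get("polyphen2_class", pd.Series("", index=table.index))
    ma = table.get("mutationassessor_class", pd.Series("", index=table.index))

    damaging_votes = (
        (fathmm > 0.5).astype(int)
        + sift.between(0.0, 0.05).fillna(False).astype(int)
        + polyphen.isin(_DAMAGING_POLYPHEN).astype(int)
        + ma.isin(_DAMAGING_MA).astype(int)
    )
    in_catalog = table["gene"].map(lambda g: g in catalog)
    truncating = table["consequence"].isin(_TRUNCATING)
    damaging_missense = (table["consequence"] == "missense") & (
        (fathmm > 0.5) | (damaging_votes >= 2)
    )
    passed = table.get("passed_filter", pd.Series(True, index=table.index))
    table["is_candidate_driver"] = (
        passed & in_catalog & (truncating | damaging_missense)
    )
    return table


def driver_mutation_frequency(table: pd.DataFrame) -> pd.Series:
    """Per-gene fraction of patients with >= 1 candidate driver mutation."""
    if "patient" not in table.columns or table["patient"].nunique() == 0:
        raise ValueError("no patients in table")
    n_patients = table["patient"].nunique()
    drivers = table[table["is_candidate_driver"]]
    per_gene = drivers.groupby("gene")["patient"].nunique()
    return (per_gene / n_patients).sort_values(ascending=False)
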