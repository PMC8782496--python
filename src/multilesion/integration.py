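"""Gene-level cross-omics correlation and concordance screening.

Expression (log2 fold change vs matched normal) is correlated per gene
with copy-number or methylation state across samples using Spearman's
rank correlation, with Benjamini-Hochberg adjustment across genes.  The
concordance screen flags genes whose alteration direction holds in all
samples up to a small tolerance — the pattern expected of a cohort-wide
biomarker (e.g. consistent expression loss, or consistent copy-number
deletion).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MIN_SAMPLES = 5


def correlate_layers(
    expr: pd.DataFrame, other: pd.DataFrame, min_samples: int = MIN_SAMPLES
) -> pd.DataFrame:
    """Per-gene Spearman correlation between two genes x samples layers.

    Only samples present in both layers are used; genes with fewer than
    ``min_samples`` complete pairs, or with a constant vector in either
    layer (correlation undefined), are skipped and listed in the
    ``skipped`` attribute of the result.

    Returns a DataFrame with columns ``rho, p_value, q_value, n``.
    """
    samples = expr.columns.intersection(other.columns)
    genes = expr.index.intersection(other.index)
    rows, skipped = [], []
    for gene in genes:
        x = expr.loc[gene, samples].astype(float)
        y = other.loc[gene, samples].astype(float)
        ok = x.notna() & y.notna()
        if ok.sum() < min_samples:
            skipped.append(gene)
            continue
        xv, yv = x[ok], y[ok]
        if xv.nunique() < 2 or yv.nunique() < 2:
            skipped.append(gene)
            continue
        rho, p = stats.spearmanr(xv, yv)
        rows.append((gene, rho, p, int(ok.sum())))
    result = pd.DataFrame(
        rows, columns=["gene", "rho", "p_value", "n"]
    ).set_index("gene")
    if len(result):
        result["q_value"] = multipletests(result["p_value"], method="fdr_bh")[1]
    else:
        result["q_value"] = pd.Series(dtype=float)
    result.attrs["skipped"] = skipped
    return result


def correlate_expression_cnv(
    expr: pd.DataFrame, cnv: pd.DataFrame, min_samples: int = MIN_SAMPLES
) -> pd.DataFrame:
    """Spearman correlation of expression with copy-number state."""
    return correlate_layers(expr, cnv, min_samples)


def correlate_expression_methylation(
    expr: pd.DataFrame, meth: pd.DataFrame, min_samples: int = MIN_SAMPLES
) -> pd.DataFrame:
    """Spearman correlation of expression with methylation state."""
    return correlate_layers(expr, meth, min_samples)


def screen_concordant_genes(
    layer: pd.DataFrame, direction: str = "down", tolerance: int = 1
) -> pd.DataFrame:
    """Genes whose alteration direction is near-universal across samples.

    ``direction="down"`` requires values < 0 (``"up"``: > 0;
    ``"loss"``: == -1; ``"gain"``: == 1) in at least ``n_samples -
    tolerance`` samples with data.  Returns the flagged genes with the
    count of concordant and discordant samples.
    """
    tests = {
        "down": lambda v: v < 0,
        "up": lambda v: v > 0,
        "loss": lambda v: v == -1,
        "gain": lambda v: v == 1,
    }
    if direction not in tests:
        raise ValueError(f"unknown direction {direction!r}")
    test = tests[direction]
    rows = []
    for gene, values in layer.iterrows():
        v = values.dropna()
        if len(v) == 0:
            continue
        hits = int(test(v).sum())
        if hits >= len(v) - tolerance:
            rows.append((gene, hits, len(v) - hits, len(v)))
    return pd.DataFrame(
        rows, columns=["gene", "concordant", "discordant", "n"]
    ).set_index("gene")
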