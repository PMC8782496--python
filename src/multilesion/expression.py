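"""Replicate-free differential expression and transcriptional heterogeneity.

For a single tumour/normal pair the read count of a gene is modelled as
Poisson; with a flat prior the posterior of the normalised expression
level given count ``k`` and size factor ``s`` is Gamma(k + 1, rate s).
The conservative signed log2 fold change ("GFOLD-style" statistic) is
the c-quantile of the posterior log2 ratio when that quantile is
positive, the (1-c)-quantile when negative, and 0 otherwise — i.e. the
fold change the data support with posterior probability 1 - c.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

#: posterior tail probability of the conservative fold-change quantile
DEFAULT_QUANTILE = 0.01

#: absolute fold-change statistic above which a gene is a DEG
DEG_THRESHOLD = 2.0


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Library-size factors: column totals scaled to mean 1."""
    totals = counts.sum(axis=0).astype(float)
    return totals / totals.mean()


def compute_gfold_statistic(
    tumor_counts,
    normal_counts,
    size_factor_tumor: float = 1.0,
    size_factor_normal: float = 1.0,
    c: float = DEFAULT_QUANTILE,
    n_draws: int = 10_000,
    seed: int = 0,
    method: str = "mc",
) -> pd.DataFrame:
    """Conservative posterior log2 fold change per gene (tumour vs normal).

    ``method="mc"`` draws ``n_draws`` posterior samples per gene (the
    default, seeded); ``method="analytic"`` uses the exact quantile of
    the Gamma-ratio (beta-prime) posterior.  Genes with zero counts in
    both samples get statistic 0.

    Returns a DataFrame indexed like the inputs with columns ``gfold``
    and ``raw_lfc`` (posterior-mean log2 fold change).
    """
    kt = np.asarray(tumor_counts)
    kn = np.asarray(normal_counts)
    if not (np.issubdtype(kt.dtype, np.integer) or np.allclose(kt, np.round(kt))):
        raise ValueError("tumour counts must be integers")
    if not (np.issubdtype(kn.dtype, np.integer) or np.allclose(kn, np.round(kn))):
        raise ValueError("normal counts must be integers")
    kt = kt.astype(float)
    kn = kn.astype(float)
    at, an = kt + 1.0, kn + 1.0  # Gamma posterior shapes
    scale_ratio = size_factor_normal / size_factor_tumor

    if method == "mc":
        rng = np.random.default_rng(seed)
        xt = rng.gamma(at, size=(n_draws, len(at)))
        xn = rng.gamma(an, size=(n_draws, len(an)))
        log2r = np.log2(xt / xn * scale_ratio)
        lo = np.quantile(log2r, c, axis=0)
        hi = np.quantile(log2r, 1.0 - c, axis=0)
    elif method == "analytic":
        # ratio of unit-scale Gammas ~ BetaPrime(at, an)
        lo = np.log2(stats.betaprime.ppf(c, at, an) * scale_ratio)
        hi = np.log2(stats.betaprime.ppf(1.0 - c, at, an) * scale_ratio)
    else:
        raise ValueError(f"unknown method {method!r}")

    gfold = np.where(lo > 0, lo, np.where(hi < 0, hi, 0.0))
    gfold = np.where((kt == 0) & (kn == 0), 0.0, gfold)
    raw = np.log2(at / an * scale_ratio)
    index = (
        tumor_counts.index
        if isinstance(tumor_counts, pd.Series)
        else pd.RangeIndex(len(kt))
    )
    return pd.DataFrame({"gfold": gfold, "raw_lfc": raw}, index=index)


def call_degs(
    results: pd.DataFrame, threshold: float = DEG_THRESHOLD
) -> pd.DataFrame:
    """Split genes into up/down DEGs by the fold-change statistic.

    Returns the DEG rows with a ``direction`` column ("up"/"down").
    """
    up = results[results["gfold"] > threshold].assign(direction="up")
    down = results[results["gfold"] < -threshold].assign(direction="down")
    return pd.concat([up, down]).sort_index()


def shared_private_degs(lesion_degs: dict) -> tuple[set, dict]:
    """Partition per-lesion DEG calls into shared and private sets.

    ``lesion_degs`` maps lesion id -> DEG DataFrame (as returned by
    :func:`call_degs`).  A gene is shared when it is a DEG *with the
    same direction* in every lesion of the patient; each lesion's
    private set is its DEG set minus the shared genes.

    Returns ``(shared, private)`` where shared is a set of (gene,
    direction) pairs and private maps lesion id -> set of (gene,
    direction) pairs.
    """
    directed = {
        lesion: set(zip(df.index, df["direction"]))
        for lesion, df in lesion_degs.items()
    }
    if not directed:
        return set(), {}
    shared = set.intersection(*directed.values())
    private = {lesion: s - shared for lesion, s in directed.items()}
    return shared, private


def cluster_samples(
    lfc_matrix: pd.DataFrame,
    patient_of: dict,
    linkage_method: str = "average",
    metric: str = "euclidean",
):
    """Hierarchical clustering of lesions on fold-change profiles.

    ``lfc_matrix`` is genes x lesions; ``patient_of`` maps lesion ->
    patient.  Returns a dict with the scipy ``linkage`` matrix, the
    leaf order, a Newick string, mean intra-/inter-patient pairwise
    distances, and the fraction of multi-lesion patients whose lesions
    form a contiguous clade.
    """
    samples = list(lfc_matrix.columns)
    if len(samples) < 2:
        raise ValueError("need >= 2 lesions to cluster")
    X = lfc_matrix.T.to_numpy()
    dvec = pdist(X, metric=metric)
    if np.allclose(dvec, 0):
        import warnings

        warnings.warn("constant matrix: all distances zero")
    dmat = pd.DataFrame(squareform(dvec), index=samples, columns=samples)
    Z = hierarchy.linkage(dvec, method=linkage_method)

    intra, inter = [], []
    for i, si in enumerate(samples):
        for j in range(i + 1, len(samples)):
            sj = samples[j]
            (intra if patient_of[si] == patient_of[sj] else inter).append(
                dmat.iloc[i, j]
            )

    # leaf sets of every internal node, to test patient contiguity
    tree = hierarchy.to_tree(Z)
    clades = []

    def collect(node):
        if node.is_leaf():
            return {samples[node.id]}
        leaves = collect(node.left) | collect(node.right)
        clades.append(leaves)
        return leaves

    collect(tree)
    by_patient: dict = {}
    for s, p in patient_of.items():
        if s in samples:
            by_patient.setdefault(p, set()).add(s)
    multi = {p: ls for p, ls in by_patient.items() if len(ls) > 1}
    contiguous = sum(1 for ls in multi.values() if ls in clades)
    frac_contiguous = contiguous / len(multi) if multi else float("nan")

    def newick(node):
        if node.is_leaf():
            return samples[node.id]
        return f"({newick(node.left)},{newick(node.right)}):{node.dist:.6g}"

    return {
        "linkage": Z,
        "leaves": [samples[i] for i in hierarchy.leaves_list(Z)],
        "newick": newick(tree) + ";",
        "distance_matrix": dmat,
        "mean_intra_patient": float(np.mean(intra)) if intra else float("nan"),
        "mean_inter_patient": float(np.mean(inter)) if inter else float("nan"),
        "fraction_patients_contiguous": frac_contiguous,
    }
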