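"""Private/shared DMR partitioning and phyloepigenetic trees.

Methylation peak sets (one per sample, with an enrichment fold and an
FDR-adjusted q-value per peak) are merged into a region universe;
significant regions present in exactly one sample are private DMRs,
those in two or more are shared.  Phyloepigenetic trees are built by
neighbour joining on Euclidean distances between the samples'
enrichment-fold vectors over the private-DMR universe, rooted at the
matched normal when present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

#: peaks with FDR-adjusted q below this enter the region universe
Q_CUTOFF = 0.01


@dataclass
class DMRPartition:
    """Merged region universe with per-sample presence and fold matrices."""

    regions: pd.DataFrame = field(repr=False)  # chrom, start, end
    presence: pd.DataFrame = field(repr=False)  # regions x samples, bool
    folds: pd.DataFrame = field(repr=False)  # regions x samples, float

    @property
    def private(self) -> pd.Index:
        return self.presence.index[self.presence.sum(axis=1) == 1]

    @property
    def shared(self) -> pd.Index:
        return self.presence.index[self.presence.sum(axis=1) >= 2]

    def private_by_sample(self) -> dict:
        out = {}
        priv = self.presence.loc[self.private]
        for sample in self.presence.columns:
            out[sample] = list(priv.index[priv[sample]])
        return out


def _merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent intervals per chromosome."""
    merged = []
    for chrom, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        cur_start = cur_end = None
        for _, row in grp.iterrows():
            if cur_start is None:
                cur_start, cur_end = row["start"], row["end"]
            elif row["start"] <= cur_end:
                cur_end = max(cur_end, row["end"])
            else:
                merged.append((chrom, cur_start, cur_end))
                cur_start, cur_end = row["start"], row["end"]
        if cur_start is not None:
            merged.append((chrom, cur_start, cur_end))
    return pd.DataFrame(merged, columns=["chrom", "start", "end"])


def classify_dmrs(peaksets: dict, q_cut: float = Q_CUTOFF) -> DMRPartition:
    """Build the merged significant-region universe and partition it.

    ``peaksets`` maps sample id -> peak DataFrame (``chrom, start, end,
    enrichment_fold, q_value``; 0-based half-open).  Only peaks with
    q < ``q_cut`` contribute.  A universe region is present in a sample
    when any of that sample's significant peaks overlaps it (>= 1 bp);
    the fold value is the maximum overlapping enrichment fold, 0 when
    absent.
    """
    significant = {
        s: df[df["q_value"] < q_cut] for s, df in peaksets.items()
    }
    all_peaks = [df for df in significant.values() if len(df)]
    if not all_peaks:
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        samples = list(peaksets)
        return DMRPartition(
            regions=empty,
            presence=pd.DataFrame(columns=samples, dtype=bool),
            folds=pd.DataFrame(columns=samples, dtype=float),
        )
    universe = _merge_intervals(pd.concat(all_peaks, ignore_index=True))
    universe.index = [
        f"{r.chrom}:{r.start}-{r.end}" for r in universe.itertuples()
    ]
    samples = list(peaksets)
    presence = pd.DataFrame(False, index=universe.index, columns=samples)
    folds = pd.DataFrame(0.0, index=universe.index, columns=samples)
    for sample, peaks in significant.items():
        for chrom, grp in peaks.groupby("chrom"):
            regs = universe[universe["chrom"] == chrom]
            if len(regs) == 0:
                continue
            for _, peak in grp.iterrows():
                hit = regs.index[
                    (regs["start"] < peak["end"]) & (regs["end"] > peak["start"])
                ]
                presence.loc[hit, sample] = True
                folds.loc[hit, sample] = np.maximum(
                    folds.loc[hit, sample], peak["enrichment_fold"]
                )
    return DMRPartition(regions=universe, presence=presence, folds=folds)


def build_phyloepigenetic_tree(
    fold_matrix: pd.DataFrame,
    root: str | None = None,
    method: str = "nj",
):
    """Sample tree from enrichment-fold vectors over private DMRs.

    ``fold_matrix`` is regions x samples (absent region = 0).  Pairwise
    Euclidean distances feed neighbour joining (default) or UPGMA;
    the tree is rooted at ``root`` (the matched normal) when given.
    With fewer than 3 samples only the distance matrix is returned
    (tree is None).

    Returns ``(tree, distance_matrix)`` where tree is an
    :class:`skbio.tree.TreeNode` (or None).
    """
    samples = list(fold_matrix.columns)
    X = fold_matrix.T.to_numpy(dtype=float)
    dmat = pd.DataFrame(
        squareform(pdist(X, metric="euclidean")), index=samples, columns=samples
    )
    if len(samples) < 3:
        return None, dmat
    return tree_from_distances(dmat, root=root, method=method), dmat


def tree_from_distances(
    dmat: pd.DataFrame, root: str | None = None, method: str = "nj"
):
    """Build a sample tree from a precomputed distance matrix.

    Neighbour joining (default) recovers the generating topology
    exactly when the matrix is additive; ``method="upgma"`` uses
    average-linkage agglomeration instead.  When ``root`` names a
    sample (the matched normal) the tree is rooted on its pendant edge.
    """
    samples = list(dmat.columns)
    if method == "nj":
        tree = nj(DistanceMatrix(dmat.to_numpy(dtype=float), ids=samples))
    elif method == "upgma":
        Z = hierarchy.linkage(squareform(dmat.to_numpy(dtype=float)),
                              method="average")
        scipy_tree = hierarchy.to_tree(Z)

        def to_newick(node):
            if node.is_leaf():
                return samples[node.id]
            return (
                f"({to_newick(node.left)},{to_newick(node.right)})"
                f":{node.dist:.6g}"
            )

        tree = TreeNode.read([to_newick(scipy_tree) + ";"])
    else:
        raise ValueError(f"unknown tree method {method!r}")
    if root is not None and root in samples:
        tree = tree.root_at(tree.find(root).parent)
    return tree


def hypermethylation_similarity(peaksets: dict, k: int = 2000) -> pd.DataFrame:
    """Jaccard similarity of the samples' top-k hypermethylated regions.

    Regions come from the shared universe of :func:`classify_dmrs`;
    each sample's top-k is ranked by its enrichment fold.  The matrix
    is symmetric with unit diagonal.
    """
    part = classify_dmrs(peaksets, q_cut=np.inf)  # rank all peaks
    folds = part.folds
    n_regions = folds.shape[0]
    if k > n_regions:
        warnings.warn(
            f"k={k} exceeds {n_regions} regions; using all regions"
        )
        k = n_regions
    tops = {
        s: set(folds[s].nlargest(k).index[folds[s].nlargest(k) > 0])
        for s in folds.columns
    }
    samples = list(folds.columns)
    sim = pd.DataFrame(np.eye(len(samples)), index=samples, columns=samples)
    for i, si in enumerate(samples):
        for j in range(i + 1, len(samples)):
            sj = samples[j]
            union = tops[si] | tops[sj]
            jac = len(tops[si] & tops[sj]) / len(union) if union else 0.0
            sim.iloc[i, j] = sim.iloc[j, i] = jac
    return sim
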