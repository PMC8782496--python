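"""Cancer-cell-fraction estimation, clonality, timing and clone trees.

The CCF model: a mutation with variant allele fraction ``VAF`` at a
locus of tumour total copy number ``CNt`` in a sample of purity ``rho``
carried on ``m`` copies per tumour cell satisfies

    VAF = CCF * rho * m / (rho * CNt + 2 * (1 - rho))

Multiplicity is estimated as ``m = max(1, round(VAF/rho * (rho*CNt +
2*(1-rho))))`` and CCF by inverting the identity at that m.  Clonal
mutations (CCF close to 1 in every region) are timed relative to genome
doubling by their multiplicity: a mutation on >= 2 copies of a doubled
region predates the doubling ("early"), one on a single copy postdates
it ("late").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

#: per-region CCF threshold for "close to 1" (clonal)
CLONAL_CCF = 0.9

#: CCF values are clipped here; anything above 1 is flagged
CCF_CLIP = 1.2

#: containment tolerance when ordering clusters into a tree
TREE_TOL = 0.1

#: cap for degenerate odds ratios after the 0.5 correction
OR_CAP = 100.0


def estimate_ccf(vaf, purity, cn_total):
    """Estimate multiplicity and CCF from VAF, purity and copy number.

    Vectorised; returns ``(multiplicity, ccf, gt1_flag)`` arrays.  CCF
    is clipped to [0, 1.2]; values that exceeded 1 before clipping are
    flagged.
    """
    vaf = np.asarray(vaf, dtype=float)
    purity = np.asarray(purity, dtype=float)
    cn_total = np.asarray(cn_total, dtype=float)
    if np.any(purity <= 0) or np.any(purity > 1):
        raise ValueError("purity must be in (0, 1]")
    if np.any(cn_total < 1):
        raise ValueError("CN total must be >= 1 at mutated sites")
    denom_reads = purity * cn_total + 2.0 * (1.0 - purity)
    m = np.maximum(1, np.round(vaf / purity * denom_reads)).astype(int)
    ccf = vaf * denom_reads / (purity * m)
    gt1 = ccf > 1.0
    return m, np.clip(ccf, 0.0, CCF_CLIP), gt1


def estimate_ccf_table(table: pd.DataFrame) -> pd.DataFrame:
    """Append ``vaf, multiplicity, ccf, ccf_gt1`` to a per-region table.

    Requires columns ``alt_tumor, depth_tumor, purity, cn_total``.
    """
    out = table.copy()
    depth = out["depth_tumor"].astype(float)
    out["vaf"] = np.where(depth > 0, out["alt_tumor"] / depth, 0.0)
    m, ccf, gt1 = estimate_ccf(out["vaf"], out["purity"], out["cn_total"])
    out["multiplicity"] = m
    out["ccf"] = ccf
    out["ccf_gt1"] = gt1
    return out


def ccf_matrix(
    table: pd.DataFrame, index="mutation_id", columns="lesion", values="ccf"
) -> pd.DataFrame:
    """Pivot a long CCF table into a mutations x regions matrix.

    Regions where a mutation was not observed become 0.
    """
    return table.pivot_table(
        index=index, columns=columns, values=values, fill_value=0.0
    )


def classify_mutation_clonality(
    ccfs: pd.DataFrame, threshold: float = CLONAL_CCF
) -> pd.Series:
    """Label each mutation clonal or subclonal from its per-region CCFs.

    Clonal iff present (CCF > 0) in every region of the patient and
    CCF >= ``threshold`` in each.
    """
    mat = ccfs.fillna(0.0)
    clonal = (mat >= threshold).all(axis=1)
    return pd.Series(
        np.where(clonal, "clonal", "subclonal"), index=mat.index, name="clonality"
    )


def _time_one_region(m, gd, major_cn):
    """Early/late/untimed call for one region, or None if untimeable."""
    if major_cn < 2:
        return None  # no copy gain at the locus: timing uninformative
    if gd:
        return "early" if m >= 2 else "late"
    return "early" if m >= major_cn else "late"


def time_clonal_mutation(multiplicities, gd_flags, major_cns) -> str:
    """Aggregate early/late timing of a clonal mutation over regions.

    Region-level: a mutation in a genome-doubled region is early when
    its multiplicity is >= 2; without doubling it is early when its
    multiplicity reaches the major copy number (>= 2).  Regions with
    major copy number 1 are untimeable.  The aggregate label requires a
    strict majority of timeable regions; ties or no information give
    "clonal untimed".
    """
    calls = [
        _time_one_region(m, gd, mc)
        for m, gd, mc in zip(multiplicities, gd_flags, major_cns)
    ]
    calls = [c for c in calls if c is not None]
    if not calls:
        return "clonal untimed"
    n_early = sum(c == "early" for c in calls)
    n_late = len(calls) - n_early
    if n_early > len(calls) / 2:
        return "clonal early"
    if n_late > len(calls) / 2:
        return "clonal late"
    return "clonal untimed"


def time_arm_event(
    state: str, clonal_multiplicities=(), minor_cns=()
) -> str:
    """Time a clonal arm-level event relative to genome doubling.

    Gains are timed by the mutations they carry: median multiplicity of
    clonal mutations on the arm >= 2 means the gain happened after the
    mutations, i.e. the mutations (and the arm gain they ride on) are
    early.  Losses are timed by LOH: minor copy number 0 in every
    region means the loss was early.  No informative mutations ->
    "clonal untimed".
    """
    if state == "gain":
        ms = np.asarray(list(clonal_multiplicities), dtype=float)
        if ms.size == 0:
            return "clonal untimed"
        return "clonal early" if np.median(ms) >= 2 else "clonal late"
    if state == "loss":
        minor = np.asarray(list(minor_cns), dtype=float)
        if minor.size == 0:
            return "clonal untimed"
        return "clonal early" if (minor == 0).all() else "clonal late"
    raise ValueError(f"cannot time arm state {state!r}")


def cluster_mutations(
    ccfs: pd.DataFrame, max_clusters: int = 10, merge_tol: float = 0.1
) -> tuple[pd.Series, pd.DataFrame]:
    """Group mutations into clone clusters from their CCF matrix.

    Mutations are first grouped by their presence pattern across
    regions, then split within each pattern by one-dimensional k-means
    on mean CCF (the smallest k whose within-cluster CCF range is
    <= ``merge_tol``, capped at ``max_clusters``).

    Returns ``(labels, cluster_ccf)``: a mutation -> cluster-id Series
    and a clusters x regions matrix of mean CCFs.
    """
    mat = ccfs.fillna(0.0)
    if (mat.to_numpy() == 0).all():
        raise ValueError("all-zero CCF matrix: nothing to cluster")
    present = mat > 0
    patterns = present.apply(lambda row: tuple(row), axis=1)
    labels = pd.Series(index=mat.index, dtype=object)
    next_id = 0
    for _, members in patterns.groupby(patterns, sort=False):
        idx = members.index
        mean_ccf = mat.loc[idx].apply(
            lambda row: row[row > 0].mean() if (row > 0).any() else 0.0, axis=1
        )
        values = mean_ccf.to_numpy().reshape(-1, 1)
        chosen = np.zeros(len(idx), dtype=int)
        for k in range(1, min(max_clusters, len(idx)) + 1):
            km = KMeans(n_clusters=k, n_init=10, random_state=0).fit(values)
            spread = max(
                np.ptp(values[km.labels_ == c]) if (km.labels_ == c).any() else 0.0
                for c in range(k)
            )
            chosen = km.labels_
            if spread <= merge_tol:
                break
        for c in np.unique(chosen):
            labels.loc[idx[chosen == c]] = next_id
            next_id += 1
    labels = labels.astype(int)
    cluster_ccf = mat.groupby(labels).mean()
    cluster_ccf.index.name = "cluster"
    return labels, cluster_ccf


@dataclass
class CloneTree:
    """Per-patient clone tree rooted at the germline.

    ``edges`` are (parent, child) cluster ids with the germline as the
    string ``"GL"``; ``cluster_ccf`` is the clusters x regions mean-CCF
    matrix.
    """

    patient: str
    cluster_ccf: pd.DataFrame = field(repr=False)
    edges: list = field(default_factory=list)
    truncal: int | None = None

    def children(self, node):
        return [c for p, c in self.edges if p == node]

    def to_newick(self) -> str:
        def fmt(node):
            kids = self.children(node)
            if not kids:
                return str(node)
            return "(" + ",".join(fmt(k) for k in kids) + ")" + str(node)

        return fmt("GL") + ";"


def build_clone_tree(
    cluster_ccf: pd.DataFrame, patient: str = "P", tol: float = TREE_TOL
) -> CloneTree:
    """Order clone clusters into a tree by CCF containment.

    The truncal cluster must have CCF >= ``1 - tol`` in every region.
    Every other cluster attaches to the already-placed cluster with the
    smallest total CCF that still contains it (parent CCF >= child CCF
    - ``tol`` in every region).
    """
    mat = cluster_ccf.astype(float)
    totals = mat.sum(axis=1)
    truncal_mask = (mat >= 1.0 - tol).all(axis=1)
    if not truncal_mask.any():
        raise ValueError("no truncal cluster (CCF ~ 1 in all regions)")
    truncal = totals[truncal_mask].idxmax()
    order = totals.drop(index=truncal).sort_values(ascending=False).index
    edges = [("GL", truncal)]
    placed = [truncal]
    for cid in order:
        child = mat.loc[cid]
        candidates = [
            p for p in placed if ((mat.loc[p] >= child - tol).all())
        ]
        if not candidates:
            warnings.warn(
                f"cluster {cid} violates containment; attached to trunk"
            )
            parent = truncal
        else:
            parent = min(candidates, key=lambda p: totals[p])
        edges.append((parent, cid))
        placed.append(cid)
    return CloneTree(
        patient=patient, cluster_ccf=mat, edges=edges, truncal=truncal
    )


def assign_trunk_branch(
    tree: CloneTree, labels: pd.Series
) -> tuple[pd.Series, pd.Series]:
    """Trunk/branch label per mutation plus the two proportions.

    Trunk mutations are the members of the truncal (first ancestor)
    cluster; every other mutation is branch.
    """
    tb = pd.Series(
        np.where(labels == tree.truncal, "trunk", "branch"),
        index=labels.index,
        name="trunk_branch",
    )
    proportions = tb.value_counts(normalize=True).reindex(
        ["trunk", "branch"], fill_value=0.0
    )
    return tb, proportions


@dataclass
class EnrichmentResult:
    """Downsampled driver-enrichment comparison between trunk and branch."""

    replicates: pd.DataFrame = field(repr=False)
    statistic: float = np.nan
    p_value: float = np.nan
    p_value_paired: float = np.nan
    n_reps: int = 0

    @property
    def median_or(self) -> float:
        return float(self.replicates["odds_ratio"].median())


def driver_fold_enrichment(
    labelled: pd.DataFrame,
    n_sample: int = 12,
    n_reps: int = 100,
    seed: int = 0,
    or_cap: float = OR_CAP,
) -> EnrichmentResult:
    """Driver-gene enrichment on the trunk versus the branch.

    ``labelled`` has one row per mutation with columns ``patient``,
    ``is_driver`` (bool) and ``trunk_branch`` ("trunk"/"branch").  Each
    replicate samples ``n_sample`` patients without replacement, builds
    the 2x2 table of driver status x trunk/branch with a 0.5
    Haldane-Anscombe correction when a cell is empty, and records the
    trunk odds ratio plus the fold enrichment of driver mutations in
    each compartment (driver proportion in the compartment / driver
    proportion overall).  The trunk and branch fold distributions are
    compared with a two-sided rank-sum test (a paired signed-rank p is
    also reported).
    """
    patients = labelled["patient"].unique()
    if n_sample > len(patients):
        raise ValueError("n_sample exceeds available patients")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_reps):
        chosen = rng.choice(patients, size=n_sample, replace=False)
        sub = labelled[labelled["patient"].isin(chosen)]
        trunk = sub["trunk_branch"] == "trunk"
        driver = sub["is_driver"].astype(bool)
        a = float((driver & trunk).sum())  # driver on trunk
        b = float((~driver & trunk).sum())
        c = float((driver & ~trunk).sum())
        d = float((~driver & ~trunk).sum())
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        odds = (a * d) / (b * c)
        odds = float(np.clip(odds, 1.0 / or_cap, or_cap))
        overall = (a + c) / (a + b + c + d)
        fold_trunk = (a / (a + b)) / overall
        fold_branch = (c / (c + d)) / overall
        rows.append((odds, fold_trunk, fold_branch))
    reps = pd.DataFrame(
        rows, columns=["odds_ratio", "fold_trunk", "fold_branch"]
    )
    stat, p = stats.mannwhitneyu(
        reps["fold_trunk"], reps["fold_branch"], alternative="two-sided"
    )
    diffs = reps["fold_trunk"] - reps["fold_branch"]
    if (diffs == 0).all():
        p_paired = 1.0
    else:
        p_paired = float(
            stats.wilcoxon(diffs[diffs != 0], alternative="two-sided").pvalue
        )
    return EnrichmentResult(
        replicates=reps,
        statistic=float(stat),
        p_value=float(p),
        p_value_paired=p_paired,
        n_reps=n_reps,
    )
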