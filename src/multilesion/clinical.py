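"""Clinical association statistics for multi-region tumour cohorts.

Reproduces the clinical analysis around per-patient genomic burden:
dichotomisation of the cohort at the median average CNV burden, Fisher
exact tests of clinicopathological variables against the burden group,
per-group burden summaries, a top-quartile split, and Kaplan-Meier /
log-rank survival comparisons.

The packaged fixture ``table2_pdac.tsv`` carries the 19-patient PDAC
cohort this analysis was developed on (per-patient demographics,
metastasis, survival, average TMB and average CNV burden).  One patient
(P17) died of a non-disease cause in the first post-operative week; his
survival fields are missing and he is excluded from survival analyses
while remaining in the contingency tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from multilesion.io import read_clinical, resource_path


def load_cohort(path=None) -> pd.DataFrame:
    """Load a clinical table; default: the packaged 19-patient cohort.

    Adds derived boolean columns used by the association tests:
    ``relapse`` (any metastasis/relapse after surgery),
    ``liver_metastasis``, ``lymph_node_metastasis`` (TNM contains N1;
    NX counts as node-negative), ``dead``, ``disease_specific_death``
    (dead with survival follow-up present; non-disease deaths carry no
    usable follow-up and are excluded from survival).
    """
    if path is None:
        path = resource_path("table2_pdac.tsv")
    df = read_clinical(path)
    meta = df["metastasis_after_surgery"].astype(str)
    df["relapse"] = meta.str.startswith("Yes")
    df["liver_metastasis"] = meta.str.contains("liver", case=False)
    df["lymph_node_metastasis"] = df["tnm"].astype(str).str.contains("N1")
    df["dead"] = df["status"].astype(str).str.lower() == "dead"
    df["disease_specific_death"] = df["dead"] & df["os_months"].notna()
    return df


def median_split_burden(records: pd.DataFrame) -> pd.Series:
    """Label each patient high/low average CNV burden.

    High iff burden is strictly greater than the cohort median (so with
    an odd cohort the median patient is low; all-equal burdens are all
    low).
    """
    burden = records["average_cnv_burden"].astype(float)
    if burden.isna().any():
        raise ValueError("burden missing for some patients")
    median = burden.median()
    return pd.Series(
        np.where(burden > median, "high", "low"),
        index=records.index,
        name="burden_group",
    )


@dataclass
class ContingencyResult:
    table: np.ndarray = field(repr=False)
    p_value: float = np.nan
    odds_ratio: float = np.nan

    def __repr__(self):
        return (
            f"ContingencyResult(p={self.p_value:.3f}, "
            f"OR={self.odds_ratio:.3g}, table={self.table.tolist()})"
        )


def fisher_test(table) -> ContingencyResult:
    """Two-sided Fisher exact test on a 2x2 table.

    The two-sided p sums hypergeometric probabilities of tables (at the
    observed margins) no more probable than the observed one.  The odds
    ratio uses a 0.5 correction when any cell is zero.  A degenerate
    margin returns p = 1 with a warning.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("degenerate margin: p = 1")
        p = 1.0
    else:
        p = float(stats.fisher_exact(t.astype(int), alternative="two-sided")[1])
    ct = t + 0.5 if (t == 0).any() else t
    odds = (ct[0, 0] * ct[1, 1]) / (ct[0, 1] * ct[1, 0])
    return ContingencyResult(table=t, p_value=p, odds_ratio=float(odds))


#: Table-1-style row definitions: variable -> (label_if_true, predicate)
TABLE1_VARIABLES = {
    "age_ge_60": lambda df: df["age"] >= 60,
    "gender_male": lambda df: df["gender"].astype(str) == "Male",
    "location_head": lambda df: df["location"].astype(str) == "Head",
    "size_gt_3cm": lambda df: df["max_diameter_cm"].astype(str) == ">3",
    "lymph_node_metastasis": lambda df: df["lymph_node_metastasis"],
    "relapse": lambda df: df["relapse"],
    "liver_metastasis": lambda df: df["liver_metastasis"],
    "stage_I": lambda df: df["clinical_stage"].astype(str).str.startswith("I")
    & ~df["clinical_stage"].astype(str).str.startswith("II"),
}


def fisher_association(
    records: pd.DataFrame, variable: str, grouping: pd.Series | None = None
) -> ContingencyResult:
    """Fisher test of a Table-1 variable against the burden group.

    ``variable`` is a key of :data:`TABLE1_VARIABLES` (or a boolean
    column name); ``grouping`` defaults to the median burden split.
    The 2x2 table is ``[[yes&low, yes&high], [no&low, no&high]]``.
    """
    if grouping is None:
        grouping = median_split_burden(records)
    if variable in TABLE1_VARIABLES:
        flag = TABLE1_VARIABLES[variable](records).astype(bool)
    else:
        flag = records[variable].astype(bool)
    low = grouping == "low"
    table = np.array(
        [
            [(flag & low).sum(), (flag & ~low).sum()],
            [(~flag & low).sum(), (~flag & ~low).sum()],
        ]
    )
    return fisher_test(table)


def table1(records: pd.DataFrame) -> pd.DataFrame:
    """All Table-1 associations against the median burden split."""
    grouping = median_split_burden(records)
    rows = []
    for var in TABLE1_VARIABLES:
        res = fisher_association(records, var, grouping)
        (yl, yh), (nl, nh) = res.table.astype(int)
        rows.append((var, yl, yh, nl, nh, round(res.p_value, 3)))
    return pd.DataFrame(
        rows,
        columns=["variable", "yes_low", "yes_high", "no_low", "no_high", "p"],
    ).set_index("variable")


def group_burden_summary(
    records: pd.DataFrame, by: str = "liver_metastasis"
) -> pd.Series:
    """Median average CNV burden per group of a boolean variable."""
    flag = records[by].astype(bool)
    burden = records["average_cnv_burden"].astype(float)
    return pd.Series(
        {
            True: burden[flag].median() if flag.any() else np.nan,
            False: burden[~flag].median() if (~flag).any() else np.nan,
        },
        name=f"median_burden_by_{by}",
    )


def quartile_split(records: pd.DataFrame) -> pd.Series:
    """Top-quartile vs rest labels on average CNV burden.

    Top quartile = burden strictly greater than the linear-interpolated
    75th percentile.  All-equal burdens give an empty top quartile
    (warned).
    """
    burden = records["average_cnv_burden"].astype(float)
    if len(burden) < 4:
        raise ValueError("need >= 4 patients for a quartile split")
    q75 = np.percentile(burden, 75)  # linear interpolation
    labels = pd.Series(
        np.where(burden > q75, "top", "rest"),
        index=records.index,
        name="quartile_group",
    )
    if (labels == "rest").all():
        warnings.warn("top quartile empty (tied burdens)")
    return labels


def survival_frame(
    records: pd.DataFrame, endpoint: str = "dfs", dfs_death_as_event=False
) -> pd.DataFrame:
    """Derive (time, event) pairs, dropping patients without follow-up.

    OS event = death from any cause.  DFS event = relapse or
    metastasis; deaths without relapse are censored at death unless
    ``dfs_death_as_event``.  Patients with missing survival fields
    (non-disease deaths without usable follow-up) are excluded.
    """
    df = records.copy()
    if endpoint == "os":
        df = df[df["os_months"].notna()]
        time = df["os_months"].astype(float)
        event = df["dead"]
    elif endpoint == "dfs":
        df = df[df["dfs_months"].notna()]
        time = df["dfs_months"].astype(float)
        event = df["relapse"] | (df["dead"] if dfs_death_as_event else False)
    else:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    return pd.DataFrame(
        {"time": time, "event": event.astype(bool)}, index=df.index
    )


def km_logrank(
    records: pd.DataFrame,
    grouping: pd.Series,
    endpoint: str = "dfs",
    dfs_death_as_event: bool = False,
) -> dict:
    """Kaplan-Meier curves per group and the two-group log-rank test.

    Returns a dict with per-group fitted
    :class:`lifelines.KaplanMeierFitter` objects, group medians, the
    log-rank chi-square statistic and its p-value.
    """
    surv = survival_frame(records, endpoint, dfs_death_as_event)
    grouping = grouping.loc[surv.index]
    groups = sorted(grouping.unique())
    if len(groups) != 2:
        raise ValueError("grouping must have exactly two levels")
    fits, frames = {}, {}
    for g in groups:
        sub = surv[grouping == g]
        if not sub["event"].any():
            warnings.warn(f"group {g!r} has zero events")
        kmf = KaplanMeierFitter(label=str(g))
        kmf.fit(sub["time"], sub["event"])
        fits[g] = kmf
        frames[g] = sub
    a, b = groups
    lr = logrank_test(
        frames[a]["time"],
        frames[b]["time"],
        event_observed_A=frames[a]["event"],
        event_observed_B=frames[b]["event"],
    )
    return {
        "fits": fits,
        "medians": {g: float(fits[g].median_survival_time_) for g in groups},
        "statistic": float(lr.test_statistic),
        "p_value": float(lr.p_value),
        "n": {g: int(len(frames[g])) for g in groups},
    }
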