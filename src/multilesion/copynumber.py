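"""Copy-number burden, wGII, arm-level events and genome-doubling calls.

Segments are ploidy-normalised before calling: a segment with total
copy number ``CN`` in a sample of ploidy ``P`` has ratio
``r = log2(CN / P)`` and is a gain when ``r >= log2(2.5/2)`` and a loss
when ``r <= log2(1.5/2)``.  An arm-level event requires >98% of the arm
length in the gained (or lost) state; across a patient's regions an arm
event is clonal when the same state recurs in >75% of the remaining
regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from multilesion.io import resource_path

#: ploidy-relative log2-ratio cutoffs for segment gain / loss
GAIN_CUTOFF = float(np.log2(2.5 / 2.0))
LOSS_CUTOFF = float(np.log2(1.5 / 2.0))

#: fraction of arm length required for an arm-level call
ARM_COVERAGE = 0.98

#: fraction of a patient's remaining regions required for clonality
CLONAL_FRACTION = 0.75


@dataclass
class SegmentProfile:
    """Allele-specific copy-number profile of one lesion sample.

    ``segments`` columns: ``chrom, start, end, total_cn, major_cn,
    minor_cn`` with 0-based half-open coordinates.
    """

    sample_id: str
    purity: float
    ploidy: float
    segments: pd.DataFrame = field(repr=False)
    patient: str | None = None
    lesion: str | None = None

    def __post_init__(self):
        if self.ploidy <= 0:
            raise ValueError("ploidy must be positive")
        seg = self.segments
        if (seg["end"] <= seg["start"]).any():
            raise ValueError("segment end must exceed start")
        if "major_cn" in seg.columns and "minor_cn" in seg.columns:
            if (seg["minor_cn"] < 0).any():
                raise ValueError("minor_cn must be >= 0")

    @property
    def genome_doubled(self) -> bool:
        return detect_genome_doubling(self)


def load_arm_definitions(name="hg19") -> pd.DataFrame:
    """Chromosome-arm boundaries as 0-based half-open intervals.

    ``name`` is ``"hg19"``, ``"toy"`` (3-chromosome test genome), or a
    path to a TSV with columns ``chrom, arm, start, end`` (1-based
    inclusive, as in cytoband-derived files).
    """
    if name in ("hg19", "toy"):
        path = resource_path(f"{name}_arms.tsv")
    else:
        path = name
    arms = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    arms["start"] = arms["start"].astype(int) - 1
    arms["end"] = arms["end"].astype(int)
    return arms


def chromosome_lengths(arms: pd.DataFrame) -> pd.Series:
    """Per-chromosome length implied by the arm definitions."""
    return arms.groupby("chrom")["end"].max()


def _segment_states(segments: pd.DataFrame, ploidy: float) -> pd.Series:
    cn = segments["total_cn"].astype(float)
    if (cn < 0).any():
        raise ValueError("total_cn must be >= 0")
    with np.errstate(divide="ignore"):
        r = np.log2(cn / ploidy)
    state = pd.Series("neutral", index=segments.index)
    state[r >= GAIN_CUTOFF] = "gain"
    state[r <= LOSS_CUTOFF] = "loss"
    return state


def compute_cnv_burden(profile: SegmentProfile) -> float:
    """Percent of the covered genome in gained or lost segments (0-100)."""
    seg = profile.segments
    lengths = (seg["end"] - seg["start"]).astype(float)
    covered = lengths.sum()
    if covered <= 0:
        raise ValueError("profile covers zero genome length")
    state = _segment_states(seg, profile.ploidy)
    altered = lengths[state != "neutral"].sum()
    return 100.0 * altered / covered


def compute_wgii(profile: SegmentProfile, arms: pd.DataFrame | None = None) -> float:
    """Weighted genome instability index in [0, 1].

    Mean over autosomes of the fraction of chromosome length whose
    rounded total copy number differs from the rounded sample ploidy.
    Chromosomes without segments are excluded with a warning.
    """
    if arms is None:
        arms = load_arm_definitions("hg19")
    chrom_len = chromosome_lengths(arms)
    seg = profile.segments
    ref_cn = round(profile.ploidy)
    altered = seg["total_cn"].round() != ref_cn
    lengths = (seg["end"] - seg["start"]).astype(float)
    per_chrom = (
        lengths.where(altered, 0.0).groupby(seg["chrom"].astype(str)).sum()
    )
    fractions = []
    for chrom, clen in chrom_len.items():
        if chrom not in per_chrom.index:
            warnings.warn(f"chromosome {chrom} has no segments; excluded")
            continue
        fractions.append(per_chrom[chrom] / clen)
    return float(np.mean(fractions)) if fractions else 0.0


def split_segments_at_arms(
    segments: pd.DataFrame, arms: pd.DataFrame
) -> pd.DataFrame:
    """Intersect segments with arm intervals, splitting at boundaries.

    Returns segment pieces with ``arm`` and ``arm_label`` columns; parts
    outside any arm (e.g. centromeric gaps) are dropped.
    """
    pieces = []
    for _, arm in arms.iterrows():
        on = segments[segments["chrom"].astype(str) == str(arm["chrom"])]
        if len(on) == 0:
            continue
        start = on["start"].clip(lower=arm["start"])
        end = on["end"].clip(upper=arm["end"])
        keep = end > start
        if not keep.any():
            continue
        piece = on[keep].copy()
        piece["start"] = start[keep]
        piece["end"] = end[keep]
        piece["arm"] = arm["arm"]
        piece["arm_label"] = f"{arm['chrom']}{arm['arm']}"
        pieces.append(piece)
    if not pieces:
        return segments.iloc[0:0].assign(arm=None, arm_label=None)
    return pd.concat(pieces, ignore_index=True)


def call_arm_events(
    profile: SegmentProfile,
    arms: pd.DataFrame | None = None,
    coverage: float = ARM_COVERAGE,
) -> pd.DataFrame:
    """Arm-level gain/loss calls for one sample.

    Returns a DataFrame with one row per arm: ``sample, arm, state,
    covered_fraction`` where ``covered_fraction`` is the fraction of arm
    length in the called state (the larger of the gain/loss fractions
    for neutral arms).
    """
    if arms is None:
        arms = load_arm_definitions("hg19")
    pieces = split_segments_at_arms(profile.segments, arms)
    rows = []
    for _, arm in arms.iterrows():
        label = f"{arm['chrom']}{arm['arm']}"
        arm_len = arm["end"] - arm["start"]
        on = pieces[pieces["arm_label"] == label]
        if len(on) == 0:
            rows.append((profile.sample_id, label, "neutral", 0.0))
            continue
        state = _segment_states(on, profile.ploidy)
        lengths = (on["end"] - on["start"]).astype(float)
        gain_frac = lengths[state == "gain"].sum() / arm_len
        loss_frac = lengths[state == "loss"].sum() / arm_len
        if gain_frac > coverage:
            rows.append((profile.sample_id, label, "gain", gain_frac))
        elif loss_frac > coverage:
            rows.append((profile.sample_id, label, "loss", loss_frac))
        else:
            rows.append(
                (profile.sample_id, label, "neutral", max(gain_frac, loss_frac))
            )
    return pd.DataFrame(
        rows, columns=["sample", "arm", "state", "covered_fraction"]
    )


def classify_arm_clonality(
    patient_calls: pd.DataFrame, clonal_fraction: float = CLONAL_FRACTION
) -> pd.DataFrame:
    """Classify each arm event as clonal or subclonal across regions.

    ``patient_calls`` concatenates :func:`call_arm_events` output for
    all regions of one patient.  An event exists when called in >= 1
    region; it is clonal when the same state is called in more than
    ``clonal_fraction`` of the *remaining* regions.  Single-region
    patients are clonal by convention (vacuous remainder); arms with
    conflicting gain and loss calls are subclonal.

    Returns one row per arm with an event: ``arm, state, clonality,
    n_regions, n_called``.
    """
    n_regions = patient_calls["sample"].nunique()
    rows = []
    for arm, calls in patient_calls.groupby("arm", sort=False):
        states = calls.loc[calls["state"] != "neutral", "state"]
        if len(states) == 0:
            continue
        unique_states = set(states)
        if len(unique_states) > 1:
            warnings.warn(f"conflicting gain/loss calls on arm {arm}")
            rows.append((arm, "conflict", "subclonal", n_regions, len(states)))
            continue
        state = states.iloc[0]
        n_called = len(states)
        if n_regions == 1:
            warnings.warn(
                "single-region patient: arm events clonal by convention"
            )
            clonality = "clonal"
        else:
            remaining = n_regions - 1
            clonality = (
                "clonal"
                if (n_called - 1) > clonal_fraction * remaining
                else "subclonal"
            )
        rows.append((arm, state, clonality, n_regions, n_called))
    return pd.DataFrame(
        rows, columns=["arm", "state", "clonality", "n_regions", "n_called"]
    )


def detect_genome_doubling(profile: SegmentProfile) -> bool:
    """Genome doubled iff > 50% of covered length has major_cn >= 2."""
    seg = profile.segments
    if "major_cn" not in seg.columns or seg["major_cn"].isna().any():
        raise ValueError("allele-specific copy number (major_cn) required")
    lengths = (seg["end"] - seg["start"]).astype(float)
    frac = lengths[seg["major_cn"] >= 2].sum() / lengths.sum()
    return bool(frac > 0.5)
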