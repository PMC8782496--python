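"""Synthetic multi-region cohort generator with full ground truth.

Emulates a multi-lesion tumour cohort: per patient, a rooted clone tree
with a truncal clone present in every region and branch clones with
region-specific cancer-cell fractions; somatic mutations assigned to
clones with driver genes planted at boosted odds on the trunk;
arm-level copy-number events (clonal and subclonal) on an hg19 arm
scaffold with optional whole-genome doubling; read counts drawn from
the CCF/purity/copy-number VAF model; lesion expression counts with
patient-shared and lesion-private differentially expressed genes;
methylation peak sets with shared and private regions; and clinical
records whose survival is tied to CNV burden through a proportional
hazard.

Everything downstream is generated from one integer seed; subsidiary
generators derive from it by fixed offsets, so identical configurations
give byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from multilesion.copynumber import SegmentProfile, load_arm_definitions
from multilesion.variants import DriverCatalog

#: observed nonsynonymous consequence mix (missense-dominant)
_CONSEQUENCE_P = {
    "missense": 0.918,
    "nonsense": 0.051,
    "splice_site": 0.024,
    "frameshift": 0.007,
}
#: fraction of all somatic calls that are synonymous
_SYNONYMOUS_FRACTION = 0.296

_RNG_OFFSETS = {
    "structure": 0,
    "cnv": 1,
    "mutations": 2,
    "expression": 3,
    "methylation": 4,
    "clinical": 5,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort; defaults mirror the study
    conditions the generator emulates (19 patients, 2-4 lesions each,
    branch-dominant clone trees, WES-scale depth)."""

    n_patients: int = 19
    regions_per_patient: tuple = (2, 4)
    n_clones: tuple = (6, 10)
    mutations_per_patient: tuple = (200, 400)
    purity: tuple = (0.3, 0.8)
    mean_depth: float = 150.0
    driver_gene_fraction: float = 0.05
    truncal_driver_boost: float = 4.0
    gd_probability: float = 0.3
    n_genes_expression: int = 2000
    deg_fraction: float = 0.1
    n_peak_regions: int = 1000
    private_dmr_fraction: float = 0.3
    burden_hazard_coef: float = 0.08
    seed: int = 0

    def __post_init__(self):
        for name in (
            "driver_gene_fraction",
            "gd_probability",
            "deg_fraction",
            "private_dmr_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "n_patients",
            "n_genes_expression",
            "n_peak_regions",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("regions_per_patient", "n_clones", "mutations_per_patient"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        lo, hi = self.purity
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError(f"invalid purity range ({lo}, {hi})")
        if self.truncal_driver_boost <= 0:
            raise ValueError("truncal_driver_boost must be positive")


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    clone_assignment: pd.Series = field(repr=False)  # mutation -> clone
    clone_tree_edges: dict = field(repr=False)  # patient -> [(parent, child)]
    clone_fractions: dict = field(repr=False)  # patient -> clones x regions CCF
    timing: pd.Series = field(repr=False)  # mutation -> timing label
    driver_flags: pd.Series = field(repr=False)  # mutation -> bool
    arm_events: pd.DataFrame = field(repr=False)
    gd_flags: dict = field(default_factory=dict)  # patient -> bool
    burdens: pd.Series | None = field(default=None, repr=False)
    deg_shared: dict = field(default_factory=dict)  # patient -> {(gene, dir)}
    deg_private: dict = field(default_factory=dict)  # sample -> {(gene, dir)}
    private_dmrs: dict = field(default_factory=dict)  # sample -> {region id}
    purities: dict = field(default_factory=dict)  # sample -> purity


@dataclass
class CohortBundle:
    """The emitted cohort: every table the analysis modules read."""

    mutations: pd.DataFrame = field(repr=False)
    profiles: dict = field(repr=False)  # sample -> SegmentProfile
    expression: pd.DataFrame = field(repr=False)  # genes x samples
    peaksets: dict = field(repr=False)  # sample -> peaks DataFrame
    clinical: pd.DataFrame = field(repr=False)
    catalog: DriverCatalog | None = None

    def write(self, outdir) -> None:
        """Dump the bundle in the same formats the analysis reads."""
        from pathlib import Path

        from multilesion import io

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_maf(self.mutations, outdir / "mutations.maf.tsv")
        seg_rows = []
        for sample, prof in self.profiles.items():
            seg = prof.segments.copy()
            seg.insert(0, "sample", sample)
            seg["purity"] = prof.purity
            seg["ploidy"] = prof.ploidy
            seg_rows.append(seg)
        io.write_segments(pd.concat(seg_rows, ignore_index=True),
                          outdir / "segments.seg.tsv")
        io.write_counts(self.expression, outdir / "expression_counts.tsv")
        peak_dir = outdir / "peaks"
        peak_dir.mkdir(exist_ok=True)
        for sample, peaks in self.peaksets.items():
            io.write_peaks(peaks, peak_dir / f"{sample}.bed")
        self.clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(config.seed + _RNG_OFFSETS[stream])


def _sample_clone_structure(config, rng):
    """Clone tree, region list and clones x regions CCF per patient."""
    structure = {}
    for p in range(1, config.n_patients + 1):
        patient = f"P{p}"
        n_regions = int(rng.integers(*config.regions_per_patient, endpoint=True))
        regions = [f"L{i + 1}" for i in range(n_regions)]
        k = int(rng.integers(*config.n_clones, endpoint=True))
        parents = {0: "GL"}
        for c in range(1, k):
            parents[c] = int(rng.integers(0, c))
        ccf = pd.DataFrame(0.0, index=range(k), columns=regions)
        ccf.loc[0] = 1.0
        children: dict = {}
        for c in range(1, k):
            children.setdefault(parents[c], []).append(c)
        order = [0]
        for node in order:
            kids = children.get(node, [])
            if not kids:
                continue
            order.extend(kids)
            for region in regions:
                parent_ccf = ccf.loc[node, region]
                if parent_ccf <= 0:
                    continue
                w = rng.dirichlet(np.ones(len(kids) + 1))
                for kid, wk in zip(kids, w[:-1]):
                    if rng.random() < 0.35:  # clone absent in this region
                        continue
                    ccf.loc[kid, region] = parent_ccf * wk
        # every clone must exist somewhere
        for c in range(1, k):
            if (ccf.loc[c] == 0).all():
                region = regions[int(rng.integers(n_regions))]
                parent_ccf = ccf.loc[parents[c], region]
                ccf.loc[c, region] = parent_ccf * rng.uniform(0.1, 0.5)
        edges = [("GL", 0)] + [(parents[c], c) for c in range(1, k)]
        structure[patient] = {
            "regions": regions,
            "edges": edges,
            "ccf": ccf,
        }
    return structure


def _simulate_copy_number(config, structure, arms, rng):
    """Arm-level segment profiles, GD flags, true events and burdens."""
    profiles: dict = {}
    gd_flags: dict = {}
    event_rows = []
    burden_rows = []
    purities: dict = {}
    arm_labels = [f"{r.chrom}{r.arm}" for r in arms.itertuples()]
    arm_len = {
        f"{r.chrom}{r.arm}": r.end - r.start for r in arms.itertuples()
    }
    total_len = float(sum(arm_len.values()))
    for patient, info in structure.items():
        gd = bool(rng.random() < config.gd_probability)
        gd_flags[patient] = gd
        ploidy = 4.0 if gd else 2.0
        base_major, base_minor = (2, 2) if gd else (1, 1)
        n_events = int(rng.integers(3, 10))
        event_arms = rng.choice(arm_labels, size=n_events, replace=False)
        regions = info["regions"]
        plan: dict = {}  # arm -> (state, set of regions)
        for arm in event_arms:
            state = "gain" if rng.random() < 0.5 else "loss"
            if rng.random() < 0.6 or len(regions) == 1:
                hit = set(regions)
                clonality = "clonal"
            else:
                n_hit = int(rng.integers(1, len(regions)))
                hit = set(rng.choice(regions, size=n_hit, replace=False))
                clonality = "clonal" if len(hit) == len(regions) else "subclonal"
            plan[arm] = (state, hit)
            event_rows.append((patient, arm, state, clonality))
        for region in regions:
            sample = f"{patient}-{region}"
            purities[sample] = float(rng.uniform(*config.purity))
            rows = []
            altered = 0.0
            for r in arms.itertuples():
                label = f"{r.chrom}{r.arm}"
                total, major, minor = (
                    base_major + base_minor,
                    base_major,
                    base_minor,
                )
                state, hit = plan.get(label, ("neutral", set()))
                if region in hit:
                    if state == "gain":
                        major = base_major + (2 if gd else 1)
                        total = major + minor
                    else:
                        minor = 0
                        major = base_major
                        total = major
                    altered += arm_len[label]
                rows.append(
                    (str(r.chrom), r.start, r.end, total, major, minor)
                )
            seg = pd.DataFrame(
                rows,
                columns=["chrom", "start", "end", "total_cn", "major_cn",
                         "minor_cn"],
            )
            profiles[sample] = SegmentProfile(
                sample_id=sample,
                purity=purities[sample],
                ploidy=ploidy,
                segments=seg,
                patient=patient,
                lesion=region,
            )
            burden_rows.append((patient, sample, 100.0 * altered / total_len))
    burdens = (
        pd.DataFrame(burden_rows, columns=["patient", "sample", "burden"])
        .groupby("patient")["burden"]
        .mean()
    )
    arm_events = pd.DataFrame(
        event_rows, columns=["patient", "arm", "state", "clonality"]
    )
    return profiles, gd_flags, arm_events, burdens, purities


def _make_catalog(config):
    n_driver = max(1, round(config.driver_gene_fraction * 400))
    drivers = [f"DRV{i:03d}" for i in range(n_driver)]
    passengers = [f"GENE{i:04d}" for i in range(400 - n_driver)]
    return DriverCatalog.from_lists(pan_cancer=drivers, disease=drivers[: max(
        1, n_driver // 2)]), drivers, passengers


def simulate_mutations(
    clone_ccf: pd.DataFrame,
    assignments: pd.Series,
    sites: pd.DataFrame,
    profiles: dict,
    purities: dict,
    mean_depth: float,
    rng: np.random.Generator,
    patient: str,
    noise: str = "binomial",
) -> pd.DataFrame:
    """Draw per-region read counts for one patient's mutations.

    ``sites`` has one row per mutation (indexed by mutation id) with
    columns ``chrom, pos, gene, consequence, multiplicity, arm_index``
    (the row of the sample's arm-level segment table the site falls
    in); the local copy number comes from each region's segment
    profile.  Expected VAF = CCF * purity * m / (purity * CNt +
    2 (1 - purity)); with ``noise="binomial"`` alt reads are binomial
    at Poisson depth, with ``noise="none"`` the expected VAF is emitted
    exactly (real-valued alt counts at fixed depth).  Mutations whose
    clone is absent from a region do not appear in that region's rows.
    A site on a fully deleted segment (CN 0) raises.
    """
    psites = sites.loc[assignments.index]
    arm_idx = psites["arm_index"].to_numpy()
    mult = psites["multiplicity"].to_numpy()
    clones = assignments.to_numpy()
    frames = []
    for region in clone_ccf.columns:
        sample = f"{patient}-{region}"
        prof = profiles[sample]
        purity = purities[sample]
        seg = prof.segments
        cnt = seg["total_cn"].to_numpy()[arm_idx]
        major = seg["major_cn"].to_numpy()[arm_idx]
        minor = seg["minor_cn"].to_numpy()[arm_idx]
        ccf = clone_ccf[region].to_numpy()[clones]
        present = ccf > 0
        if (cnt[present] == 0).any():
            raise ValueError(f"mutation on a zero-copy segment in {sample}")
        m = np.minimum(mult, np.maximum(major, 1))
        vaf = ccf * purity * m / (purity * cnt + 2.0 * (1.0 - purity))
        n = len(ccf)
        if noise == "binomial":
            depth = np.maximum(rng.poisson(mean_depth, size=n), 1)
            alt = rng.binomial(depth, np.minimum(vaf, 1.0))
            depth_n = np.maximum(rng.poisson(mean_depth, size=n), 1)
            alt_n = rng.binomial(depth_n, 1e-3)
        elif noise == "none":
            depth = np.full(n, int(round(mean_depth)))
            alt = vaf * depth  # real-valued: exact expected VAF
            depth_n = np.full(n, int(round(mean_depth)))
            alt_n = np.zeros(n, dtype=int)
        else:
            raise ValueError(f"unknown noise mode {noise!r}")
        frame = pd.DataFrame(
            {
                "patient": patient,
                "lesion": region,
                "mutation_id": psites.index,
                "chrom": psites["chrom"].to_numpy(),
                "pos": psites["pos"].to_numpy(),
                "ref": "C",
                "alt": "T",
                "gene": psites["gene"].to_numpy(),
                "consequence": psites["consequence"].to_numpy(),
                "depth_tumor": depth,
                "alt_tumor": alt,
                "depth_normal": depth_n,
                "alt_normal": alt_n,
                "popfreq_max": 0.0,
                "fathmm_mkl": psites["fathmm_mkl"].to_numpy(),
                "sift": psites["sift"].to_numpy(),
                "polyphen2_class": psites["polyphen2_class"].to_numpy(),
                "mutationassessor_class": psites[
                    "mutationassessor_class"
                ].to_numpy(),
                "purity": purity,
                "cn_total": cnt,
                "major_cn": major,
                "minor_cn": minor,
                "true_multiplicity": m,
                "true_ccf": ccf,
            }
        )
        frames.append(frame[present])
    return pd.concat(frames, ignore_index=True)


def _assign_mutations(config, structure, profiles, gd_flags, arms, rng):
    """Mutation sites, clone assignments, driver planting and timing truth."""
    catalog, drivers, passengers = _make_catalog(config)
    f = config.driver_gene_fraction
    boost = config.truncal_driver_boost
    p_trunk = boost * f / (boost * f + (1.0 - f))
    conseq = list(_CONSEQUENCE_P)
    conseq_p = np.array(list(_CONSEQUENCE_P.values()))
    conseq_p = conseq_p / conseq_p.sum()

    all_sites, all_assign, all_timing, all_driver = [], {}, {}, {}
    arm_rows = list(arms.itertuples())
    arm_weights = np.array([r.end - r.start for r in arm_rows], dtype=float)
    arm_weights /= arm_weights.sum()
    for patient, info in structure.items():
        k = len(info["ccf"])
        n_mut = int(rng.integers(*config.mutations_per_patient, endpoint=True))
        trunk_fraction = rng.uniform(0.02, 0.24) if k > 1 else 1.0
        n_trunk = max(3, round(n_mut * trunk_fraction)) if k > 1 else n_mut
        clones = np.concatenate(
            [
                np.zeros(n_trunk, dtype=int),
                rng.integers(1, k, size=n_mut - n_trunk) if k > 1 else
                np.zeros(0, dtype=int),
            ]
        )
        gd = gd_flags[patient]
        regions = info["regions"]
        # per-region major copy number indexed by arm row
        majors = {
            r: profiles[f"{patient}-{r}"].segments["major_cn"].to_numpy()
            for r in regions
        }
        for i, clone in enumerate(clones):
            mut_id = f"{patient}_M{i:04d}"
            truncal = clone == 0
            is_driver = rng.random() < (p_trunk if truncal else f)
            gene = (
                drivers[int(rng.integers(len(drivers)))]
                if is_driver
                else passengers[int(rng.integers(len(passengers)))]
            )
            if rng.random() < _SYNONYMOUS_FRACTION:
                consequence = "synonymous"
            else:
                consequence = conseq[int(rng.choice(len(conseq), p=conseq_p))]
            if is_driver and consequence == "missense":
                fathmm = rng.uniform(0.55, 0.99)
                sift = rng.uniform(0.0, 0.04)
                polyphen, ma = "probably_damaging", "high"
            else:
                fathmm = rng.uniform(0.0, 0.5)
                sift = rng.uniform(0.1, 1.0)
                polyphen, ma = "benign", "low"
            ai = int(rng.choice(len(arm_rows), p=arm_weights))
            arm = arm_rows[ai]
            pos = int(rng.integers(arm.start + 1, arm.end + 1))
            # multiplicity: truncal mutations may predate gains/doubling
            early_flag = truncal and rng.random() < 0.5
            multiplicity = 2 if early_flag else 1
            all_sites.append(
                (
                    mut_id, patient, str(arm.chrom), pos, ai, gene,
                    consequence, multiplicity, fathmm, sift, polyphen, ma,
                )
            )
            all_assign[mut_id] = clone
            all_driver[mut_id] = is_driver
            if not truncal:
                all_timing[mut_id] = "subclonal"
            else:
                calls = []
                for region in regions:
                    major = int(majors[region][ai])
                    m_eff = min(multiplicity, max(major, 1))
                    if major < 2:
                        continue
                    if gd:
                        calls.append("early" if m_eff >= 2 else "late")
                    else:
                        calls.append("early" if m_eff >= major else "late")
                n_early = sum(c == "early" for c in calls)
                if calls and n_early > len(calls) / 2:
                    all_timing[mut_id] = "clonal early"
                elif calls and (len(calls) - n_early) > len(calls) / 2:
                    all_timing[mut_id] = "clonal late"
                else:
                    all_timing[mut_id] = "clonal untimed"
    sites = pd.DataFrame(
        all_sites,
        columns=[
            "mutation_id", "patient", "chrom", "pos", "arm_index", "gene",
            "consequence", "multiplicity", "fathmm_mkl", "sift",
            "polyphen2_class", "mutationassessor_class",
        ],
    ).set_index("mutation_id")
    return (
        catalog,
        sites,
        pd.Series(all_assign, name="clone"),
        pd.Series(all_timing, name="timing"),
        pd.Series(all_driver, name="is_driver"),
    )


def _simulate_expression(config, structure, rng):
    """Counts for lesions + matched normals with planted DEGs."""
    genes = [f"EXPR{i:05d}" for i in range(config.n_genes_expression)]
    base = rng.lognormal(np.log(100.0), 1.0, size=len(genes))
    columns, data = [], []
    deg_shared: dict = {}
    deg_private: dict = {}
    n_shared = max(2, round(config.deg_fraction * len(genes)))
    n_private = max(1, n_shared // 4)
    lfc = 3.0  # planted effect, comfortably above the DEG threshold
    for patient, info in structure.items():
        shared_idx = rng.choice(len(genes), size=n_shared, replace=False)
        up = shared_idx[: n_shared // 2]
        down = shared_idx[n_shared // 2:]
        deg_shared[patient] = {(genes[i], "up") for i in up} | {
            (genes[i], "down") for i in down
        }
        normal_mean = base
        columns.append(f"{patient}-N")
        data.append(rng.poisson(normal_mean))
        remaining = np.setdiff1d(np.arange(len(genes)), shared_idx)
        for region in info["regions"]:
            sample = f"{patient}-{region}"
            priv_idx = rng.choice(remaining, size=n_private, replace=False)
            priv_up = priv_idx[: n_private // 2]
            priv_down = priv_idx[n_private // 2:]
            deg_private[sample] = {(genes[i], "up") for i in priv_up} | {
                (genes[i], "down") for i in priv_down
            }
            mean = base.copy()
            mean[up] *= 2.0 ** lfc
            mean[down] *= 2.0 ** -lfc
            mean[priv_up] *= 2.0 ** lfc
            mean[priv_down] *= 2.0 ** -lfc
            columns.append(sample)
            data.append(rng.poisson(mean))
    expression = pd.DataFrame(
        np.array(data).T, index=genes, columns=columns
    )
    return expression, deg_shared, deg_private


def _simulate_methylation(config, structure, rng):
    """Peak sets with patient-shared and lesion-private regions."""
    n = config.n_peak_regions
    chroms = [str(c) for c in range(1, 23)]
    universe = pd.DataFrame(
        {
            "chrom": [chroms[i % 22] for i in range(n)],
            "start": [2000 * (i // 22) for i in range(n)],
            "end": [2000 * (i // 22) + 1000 for i in range(n)],
        }
    )
    peaksets: dict = {}
    private_truth: dict = {}
    for patient, info in structure.items():
        regions = info["regions"]
        n_shared = max(5, int(0.25 * n))
        pool = rng.permutation(n)
        shared = pool[:n_shared]
        n_priv = max(1, int(config.private_dmr_fraction * n_shared /
                            max(len(regions), 1)))
        cursor = n_shared
        shared_folds = rng.uniform(2.0, 6.0, size=n_shared)
        # matched normal: its own modest peak set, disjoint from lesions
        n_norm = max(3, n_shared // 5)
        normal_idx = pool[cursor: cursor + n_norm]
        cursor += n_norm
        peaksets[f"{patient}-N"] = _peaks_frame(
            universe, normal_idx, rng.uniform(2.0, 4.0, size=n_norm), rng
        )
        for region in regions:
            sample = f"{patient}-{region}"
            priv = pool[cursor: cursor + n_priv]
            cursor += n_priv
            idx = np.concatenate([shared, priv])
            folds = np.concatenate(
                [
                    shared_folds * rng.uniform(0.9, 1.1, size=n_shared),
                    rng.uniform(2.0, 10.0, size=len(priv)),
                ]
            )
            peaksets[sample] = _peaks_frame(universe, idx, folds, rng)
            private_truth[sample] = {
                f"{universe.iloc[i]['chrom']}:{universe.iloc[i]['start']}-"
                f"{universe.iloc[i]['end']}"
                for i in priv
            }
    return peaksets, private_truth


def _peaks_frame(universe, idx, folds, rng):
    peaks = universe.iloc[np.sort(idx)].copy()
    order = np.argsort(idx)
    peaks["enrichment_fold"] = np.asarray(folds)[order]
    peaks["q_value"] = rng.uniform(1e-4, 9e-3, size=len(idx))
    return peaks.reset_index(drop=True)


def simulate_clinical(
    burdens: pd.Series,
    coef: float,
    seed: int,
    baseline_hazard: float = 0.03,
    tmb: pd.Series | None = None,
) -> pd.DataFrame:
    """Clinical records with survival tied to CNV burden.

    Event times are exponential with hazard proportional to
    ``exp(coef * (burden - mean))``; censoring is uniform over 12-36
    months of follow-up.  Liver-metastasis probability increases
    monotonically with burden.
    """
    rng = np.random.default_rng(seed)
    centred = burdens - burdens.mean()
    rows = []
    for patient, burden in burdens.items():
        hazard = baseline_hazard * float(np.exp(coef * centred[patient]))
        t_death = rng.exponential(1.0 / hazard)
        t_relapse = rng.exponential(1.0 / (1.5 * hazard))
        censor = rng.uniform(12.0, 36.0)
        os_m = min(t_death, censor)
        dead = t_death <= censor
        relapse_time = min(t_relapse, os_m)
        relapsed = t_relapse < os_m
        p_liver = 1.0 / (1.0 + np.exp(-(-1.5 + 0.12 * centred[patient])))
        liver = relapsed and (rng.random() < p_liver)
        meta = (
            "Yes (liver metastasis)"
            if liver
            else ("Yes (distant metastasis)" if relapsed else "No")
        )
        rows.append(
            (
                patient,
                "Male" if rng.random() < 0.5 else "Female",
                int(rng.integers(44, 73)),
                "Dead" if dead else "Live",
                meta,
                round(os_m, 1),
                round(relapse_time if relapsed else os_m, 1),
                round(float(tmb[patient]), 3) if tmb is not None else np.nan,
                round(float(burden), 3),
                "Head" if rng.random() < 0.6 else "Body and tail",
                "Moderate",
                "T3N1M0" if rng.random() < 0.5 else "T3N0M0",
                "IIB" if rng.random() < 0.5 else "IIA",
                ">3" if rng.random() < 0.5 else "<=3",
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "gender", "age", "status",
            "metastasis_after_surgery", "os_months", "dfs_months",
            "average_tmb", "average_cnv_burden", "location",
            "differentiation", "tnm", "clinical_stage", "max_diameter_cm",
        ],
    )


def generate_cohort(
    config: SimulationConfig, noise: str = "binomial"
) -> tuple[CohortBundle, GroundTruth]:
    """Generate a full multi-region cohort plus its ground truth."""
    arms = load_arm_definitions("hg19")
    rng_struct = _rng(config, "structure")
    structure = _sample_clone_structure(config, rng_struct)
    rng_cnv = _rng(config, "cnv")
    profiles, gd_flags, arm_events, burdens, purities = _simulate_copy_number(
        config, structure, arms, rng_cnv
    )
    rng_mut = _rng(config, "mutations")
    catalog, sites, assignments, timing, driver_flags = _assign_mutations(
        config, structure, profiles, gd_flags, arms, rng_mut
    )
    mutation_tables = []
    for patient, info in structure.items():
        patient_muts = assignments[
            assignments.index.str.startswith(patient + "_")
        ]
        mutation_tables.append(
            simulate_mutations(
                info["ccf"],
                patient_muts,
                sites,
                profiles,
                purities,
                config.mean_depth,
                rng_mut,
                patient,
                noise=noise,
            )
        )
    mutations = pd.concat(mutation_tables, ignore_index=True)
    rng_expr = _rng(config, "expression")
    expression, deg_shared, deg_private = _simulate_expression(
        config, structure, rng_expr
    )
    rng_meth = _rng(config, "methylation")
    peaksets, private_dmrs = _simulate_methylation(config, structure, rng_meth)
    nonsyn = mutations[
        ~mutations["consequence"].isin(["synonymous"])
    ]
    tmb = (
        nonsyn.groupby(["patient", "lesion"])["mutation_id"].nunique() / 38.0
    ).groupby("patient").mean()
    clinical = simulate_clinical(
        burdens,
        config.burden_hazard_coef,
        config.seed + _RNG_OFFSETS["clinical"],
        tmb=tmb,
    )
    bundle = CohortBundle(
        mutations=mutations,
        profiles=profiles,
        expression=expression,
        peaksets=peaksets,
        clinical=clinical,
        catalog=catalog,
    )
    truth = GroundTruth(
        clone_assignment=assignments,
        clone_tree_edges={p: s["edges"] for p, s in structure.items()},
        clone_fractions={p: s["ccf"] for p, s in structure.items()},
        timing=timing,
        driver_flags=driver_flags,
        arm_events=arm_events,
        gd_flags=gd_flags,
        burdens=burdens,
        deg_shared=deg_shared,
        deg_private=deg_private,
        private_dmrs=private_dmrs,
        purities=purities,
    )
    return bundle, truth


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
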