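"""Shared fixtures: synthetic cohorts and a planted clone-tree patient."""

import numpy as np
import pandas as pd
import pytest

from multilesion import clinical
from multilesion import synthetic as syn
from multilesion.copynumber import SegmentProfile, load_arm_definitions

#: desk-scale cohort for module tests (full study scale is used where a
#: test's claim depends on it)
SMALL = dict(
    n_patients=6,
    regions_per_patient=(2, 3),
    n_clones=(3, 5),
    mutations_per_patient=(60, 120),
    n_genes_expression=400,
    n_peak_regions=300,
    seed=7,
)


@pytest.fixture(scope="session")
def small_config():
    return syn.SimulationConfig(**SMALL)


@pytest.fixture(scope="session")
def cohort(small_config):
    """Small cohort with binomial read noise."""
    return syn.generate_cohort(small_config)


@pytest.fixture(scope="session")
def cohort_noisefree(small_config):
    """Small cohort with exact expected VAFs (no read noise)."""
    return syn.generate_cohort(small_config, noise="none")


@pytest.fixture(scope="session")
def study_cohort_noisefree():
    """Study-scale cohort (19 patients), noise-free reads."""
    return syn.generate_cohort(syn.SimulationConfig(seed=11), noise="none")


@pytest.fixture(scope="session")
def table2():
    """The packaged 19-patient clinical cohort."""
    return clinical.load_cohort()


@pytest.fixture(scope="session")
def planted_patient():
    """One patient with a designed, fully identifiable 5-clone tree.

    Clone CCFs are well separated with distinct presence patterns, so
    clustering and tree building have a unique right answer:
    GL -> 0 -> 1 -> 2 and 0 -> 3 -> 4.
    """
    arms = load_arm_definitions("hg19")
    seg = pd.DataFrame(
        {
            "chrom": [str(r.chrom) for r in arms.itertuples()],
            "start": [r.start for r in arms.itertuples()],
            "end": [r.end for r in arms.itertuples()],
            "total_cn": 2,
            "major_cn": 1,
            "minor_cn": 1,
        }
    )
    regions = ["L1", "L2", "L3"]
    profiles = {
        f"P1-{r}": SegmentProfile(
            f"P1-{r}", purity=0.6, ploidy=2.0, segments=seg.copy(),
            patient="P1", lesion=r,
        )
        for r in regions
    }
    purities = {f"P1-{r}": 0.6 for r in regions}
    clone_ccf = pd.DataFrame(
        [
            [1.0, 1.0, 1.0],
            [0.6, 0.5, 0.0],
            [0.3, 0.0, 0.0],
            [0.0, 0.0, 0.7],
            [0.0, 0.0, 0.3],
        ],
        index=range(5),
        columns=regions,
    )
    true_edges = {("GL", 0), (0, 1), (1, 2), (0, 3), (3, 4)}
    rng = np.random.default_rng(0)
    n = 150
    sites = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1000, 1000 + n),
            "arm_index": 0,
            "gene": "GENE0001",
            "consequence": "missense",
            "multiplicity": 1,
            "fathmm_mkl": 0.1,
            "sift": 0.5,
            "polyphen2_class": "benign",
            "mutationassessor_class": "low",
        },
        index=[f"P1_M{i:04d}" for i in range(n)],
    )
    assignments = pd.Series(rng.integers(0, 5, size=n), index=sites.index)
    table = syn.simulate_mutations(
        clone_ccf, assignments, sites, profiles, purities,
        mean_depth=100, rng=rng, patient="P1", noise="none",
    )
    return {
        "table": table,
        "assignments": assignments,
        "clone_ccf": clone_ccf,
        "true_edges": true_edges,
        "regions": regions,
    }
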