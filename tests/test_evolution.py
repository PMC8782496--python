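"""CCF model, clonality/timing rules, clone trees and driver enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from multilesion import evolution as evo


class TestEstimateCCF:
    @pytest.mark.parametrize(
        "vaf, purity, cnt, exp_m, exp_ccf",
        [
            (0.5, 1.0, 2, 1, 1.0),    # diploid clonal limit
            (0.25, 0.5, 2, 1, 1.0),   # half purity
            (0.25, 1.0, 4, 1, 1.0),   # tetraploid single copy
            (0.5, 1.0, 4, 2, 1.0),    # doubled mutation
            (0.25, 1.0, 2, 1, 0.5),   # subclonal
        ],
    )
    def test_hand_computed_values(self, vaf, purity, cnt, exp_m, exp_ccf):
        m, ccf, _ = evo.estimate_ccf(vaf, purity, cnt)
        assert m == exp_m
        assert ccf == pytest.approx(exp_ccf)

    def test_zero_purity_rejected(self):
        with pytest.raises(ValueError):
            evo.estimate_ccf(0.5, 0.0, 2)

    def test_ccf_above_one_flagged_and_clip_bounded(self):
        # VAF 0.55 at purity 1, CN 2 -> m = 1, CCF = 1.1 (> 1, flagged)
        m, ccf, flag = evo.estimate_ccf(0.55, 1.0, 2)
        assert m == 1 and flag
        assert ccf == pytest.approx(1.1)
        # far above: CCF capped at the clip bound (0.65*2 = 1.3 -> 1.2)
        m, ccf, flag = evo.estimate_ccf(0.65, 1.0, 2)
        assert flag and ccf == pytest.approx(evo.CCF_CLIP)

    @given(
        ccf=st.floats(0.05, 1.0),
        purity=st.floats(0.1, 1.0),
        cnt=st.integers(1, 6),
        m=st.integers(1, 3),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_inverts_the_vaf_model(self, ccf, purity, cnt, m):
        """A noise-free VAF is exactly reconstructed from the estimate
        (whenever the CCF was not clipped)."""
        m = min(m, cnt)
        denom = purity * cnt + 2 * (1 - purity)
        vaf = ccf * purity * m / denom
        m_est, ccf_est, flagged = evo.estimate_ccf(vaf, purity, cnt)
        if not flagged:
            back = ccf_est * purity * m_est / denom
            assert back == pytest.approx(vaf, rel=1e-9, abs=1e-12)

    def test_noise_free_cohort_inversion(self, cohort_noisefree):
        bundle, _ = cohort_noisefree
        est = evo.estimate_ccf_table(bundle.mutations)
        assert (est["ccf"] - est["true_ccf"]).abs().max() < 1e-6
        assert (est["multiplicity"] == est["true_multiplicity"]).all()


class TestClonality:
    def test_high_ccf_everywhere_is_clonal(self):
        mat = pd.DataFrame({"L1": [1.0], "L2": [0.98], "L3": [0.95]},
                           index=["m1"])
        assert evo.classify_mutation_clonality(mat)["m1"] == "clonal"

    def test_low_ccf_in_one_region_is_subclonal(self):
        mat = pd.DataFrame({"L1": [1.0], "L2": [0.3]}, index=["m1"])
        assert evo.classify_mutation_clonality(mat)["m1"] == "subclonal"

    def test_absence_in_one_region_is_subclonal(self):
        mat = pd.DataFrame({"L1": [1.0], "L2": [0.0]}, index=["m1"])
        assert evo.classify_mutation_clonality(mat)["m1"] == "subclonal"


class TestTiming:
    def test_doubled_multiplicity_two_everywhere_is_early(self):
        label = evo.time_clonal_mutation([2, 2, 2], [True] * 3, [2, 2, 2])
        assert label == "clonal early"

    def test_doubled_single_copy_is_late(self):
        label = evo.time_clonal_mutation([1, 1], [True, True], [2, 2])
        assert label == "clonal late"

    def test_tie_gives_untimed(self):
        label = evo.time_clonal_mutation([2, 1], [True, True], [2, 2])
        assert label == "clonal untimed"

    def test_untimeable_regions_excluded_from_majority(self):
        # one timeable region decides despite two untimeable ones
        label = evo.time_clonal_mutation(
            [1, 1, 2], [True] * 3, [1, 1, 2]
        )
        assert label == "clonal early"

    def test_no_copy_gain_anywhere_is_untimed(self):
        label = evo.time_clonal_mutation([1, 1], [False, False], [1, 1])
        assert label == "clonal untimed"

    def test_arm_gain_timed_by_multiplicity(self):
        assert evo.time_arm_event("gain", [2, 2, 1]) == "clonal early"
        assert evo.time_arm_event("gain", [1, 1, 2]) == "clonal late"
        assert evo.time_arm_event("gain", []) == "clonal untimed"

    def test_arm_loss_timed_by_loh(self):
        assert evo.time_arm_event("loss", minor_cns=[0, 0]) == "clonal early"
        assert evo.time_arm_event("loss", minor_cns=[0, 1]) == "clonal late"

    def test_neutral_arm_cannot_be_timed(self):
        with pytest.raises(ValueError):
            evo.time_arm_event("neutral")


class TestClustering:
    def test_identical_ccf_vectors_share_a_cluster(self):
        mat = pd.DataFrame(
            {"L1": [1.0, 1.0, 0.4], "L2": [1.0, 1.0, 0.0]},
            index=["m1", "m2", "m3"],
        )
        labels, _ = evo.cluster_mutations(mat)
        assert labels["m1"] == labels["m2"]
        assert labels["m1"] != labels["m3"]

    def test_single_mutation_single_cluster(self):
        mat = pd.DataFrame({"L1": [0.8]}, index=["m1"])
        labels, clusters = evo.cluster_mutations(mat)
        assert len(clusters) == 1

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            evo.cluster_mutations(pd.DataFrame({"L1": [0.0]}, index=["m1"]))

    def test_planted_clones_recovered(self, planted_patient):
        est = evo.estimate_ccf_table(planted_patient["table"])
        mat = evo.ccf_matrix(est).reindex(
            columns=planted_patient["regions"], fill_value=0.0
        )
        labels, clusters = evo.cluster_mutations(mat)
        truth = planted_patient["assignments"].loc[labels.index]
        mapping = {
            cid: truth[labels == cid].mode().iloc[0] for cid in clusters.index
        }
        accuracy = (labels.map(mapping) == truth).mean()
        assert len(clusters) == 5
        assert accuracy >= 0.9


class TestCloneTree:
    def test_containment_enumeration_example(self):
        cc = pd.DataFrame(
            {"L1": [1.0, 0.5, 0.0], "L2": [1.0, 0.0, 0.4]},
            index=[0, 1, 2],
        )
        tree = evo.build_clone_tree(cc)
        assert tree.truncal == 0
        assert set(tree.children(0)) == {1, 2}

    def test_single_cluster_trunk_only(self):
        cc = pd.DataFrame({"L1": [1.0], "L2": [0.97]}, index=[5])
        tree = evo.build_clone_tree(cc)
        assert tree.edges == [("GL", 5)]
        assert tree.to_newick() == "(5)GL;"

    def test_no_truncal_cluster_fails(self):
        cc = pd.DataFrame({"L1": [0.5, 0.3], "L2": [0.0, 0.4]}, index=[0, 1])
        with pytest.raises(ValueError):
            evo.build_clone_tree(cc)

    def test_planted_tree_edges_recovered(self, planted_patient):
        est = evo.estimate_ccf_table(planted_patient["table"])
        mat = evo.ccf_matrix(est).reindex(
            columns=planted_patient["regions"], fill_value=0.0
        )
        labels, clusters = evo.cluster_mutations(mat)
        tree = evo.build_clone_tree(clusters, patient="P1")
        truth = planted_patient["assignments"].loc[labels.index]
        mapping = {
            cid: truth[labels == cid].mode().iloc[0] for cid in clusters.index
        }
        predicted = {
            ("GL" if a == "GL" else mapping[a], mapping[b])
            for a, b in tree.edges
        }
        overlap = predicted & planted_patient["true_edges"]
        assert len(overlap) / len(planted_patient["true_edges"]) >= 0.8


class TestTrunkBranch:
    def test_trunk_only_tree_is_all_trunk(self):
        cc = pd.DataFrame({"L1": [1.0]}, index=[0])
        tree = evo.build_clone_tree(cc)
        labels = pd.Series([0, 0, 0], index=["m1", "m2", "m3"])
        tb, props = evo.assign_trunk_branch(tree, labels)
        assert (tb == "trunk").all()
        assert props["trunk"] == pytest.approx(1.0)

    def test_proportions_are_counting(self):
        cc = pd.DataFrame({"L1": [1.0, 0.5]}, index=[0, 1])
        tree = evo.build_clone_tree(cc)
        labels = pd.Series([0] * 5 + [1] * 95,
                           index=[f"m{i}" for i in range(100)])
        _, props = evo.assign_trunk_branch(tree, labels)
        assert props["trunk"] == pytest.approx(0.05)
        assert props.sum() == pytest.approx(1.0)

    def test_labels_stable_under_region_reordering(self, planted_patient):
        est = evo.estimate_ccf_table(planted_patient["table"])
        mat = evo.ccf_matrix(est).reindex(
            columns=planted_patient["regions"], fill_value=0.0
        )
        labels1, cl1 = evo.cluster_mutations(mat)
        mat2 = mat[mat.columns[::-1]]
        labels2, cl2 = evo.cluster_mutations(mat2)
        tb1, _ = evo.assign_trunk_branch(
            evo.build_clone_tree(cl1), labels1
        )
        tb2, _ = evo.assign_trunk_branch(
            evo.build_clone_tree(cl2), labels2
        )
        pd.testing.assert_series_equal(tb1.sort_index(), tb2.sort_index())

    def test_branch_dominant_cohort_proportions(self, study_cohort_noisefree):
        """Trunk fractions stay minor (branch-dominant clone structure)."""
        _, truth = study_cohort_noisefree
        fractions = []
        for patient in truth.clone_fractions:
            muts = truth.clone_assignment[
                truth.clone_assignment.index.str.startswith(patient + "_")
            ]
            fractions.append((muts != 0).mean())
        assert np.median(fractions) > 0.5  # branch mutations dominate


class TestDriverEnrichment:
    def _cohort(self, n_patients=15, trunk_driver=0.5, branch_driver=0.5,
                n_trunk=10, n_branch=40):
        rows = []
        for i in range(n_patients):
            for j in range(n_trunk):
                rows.append((f"P{i}", j < trunk_driver * n_trunk, "trunk"))
            for j in range(n_branch):
                rows.append((f"P{i}", j < branch_driver * n_branch, "branch"))
        return pd.DataFrame(
            rows, columns=["patient", "is_driver", "trunk_branch"]
        )

    def test_extreme_table_gives_capped_or(self):
        df = self._cohort(trunk_driver=1.0, branch_driver=0.0)
        res = evo.driver_fold_enrichment(df, n_sample=10, n_reps=20, seed=1)
        assert (res.replicates["odds_ratio"] > 1).all()
        assert res.replicates["odds_ratio"].max() <= evo.OR_CAP

    def test_no_enrichment_gives_unit_or_and_large_p(self):
        df = self._cohort(trunk_driver=0.2, branch_driver=0.2)
        res = evo.driver_fold_enrichment(df, n_sample=10, n_reps=50, seed=1)
        assert res.median_or == pytest.approx(1.0, abs=0.05)
        assert res.p_value > 0.05

    def test_fixed_seed_reproducible(self):
        df = self._cohort()
        a = evo.driver_fold_enrichment(df, n_sample=10, n_reps=30, seed=9)
        b = evo.driver_fold_enrichment(df, n_sample=10, n_reps=30, seed=9)
        pd.testing.assert_frame_equal(a.replicates, b.replicates)

    def test_oversampling_rejected(self):
        df = self._cohort(n_patients=5)
        with pytest.raises(ValueError):
            evo.driver_fold_enrichment(df, n_sample=12)

    def test_matches_permutation_oracle_under_null(self):
        """With equal driver fractions the rank-sum p is non-significant
        across independent seeds (permutation-style check)."""
        df = self._cohort(trunk_driver=0.3, branch_driver=0.3)
        low = sum(
            evo.driver_fold_enrichment(
                df, n_sample=10, n_reps=30, seed=s
            ).p_value
            < 0.05
            for s in range(20)
        )
        assert low <= 2
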