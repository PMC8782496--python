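"""CNV burden, wGII, arm-event and genome-doubling calls."""

import numpy as np
import pandas as pd
import pytest

from multilesion import copynumber as cn

ARMS = cn.load_arm_definitions("hg19")
CHROM_LEN = cn.chromosome_lengths(ARMS)


def _profile(segments, ploidy=2.0, purity=0.7, sample="S1"):
    return cn.SegmentProfile(
        sample_id=sample, purity=purity, ploidy=ploidy,
        segments=pd.DataFrame(segments),
    )


def _whole_genome(cn_map, ploidy=2.0):
    """One segment per chromosome covering it fully; cn_map: chrom->cn."""
    rows = []
    for chrom, length in CHROM_LEN.items():
        total = cn_map.get(chrom, round(ploidy))
        rows.append(
            dict(chrom=chrom, start=0, end=int(length), total_cn=total,
                 major_cn=total - total // 2, minor_cn=total // 2)
        )
    return _profile(rows, ploidy=ploidy)


class TestBurden:
    def test_all_neutral_is_zero(self):
        assert cn.compute_cnv_burden(_whole_genome({})) == 0.0

    def test_half_gained_is_fifty(self):
        seg = [
            dict(chrom="1", start=0, end=1000, total_cn=5, major_cn=4,
                 minor_cn=1),
            dict(chrom="1", start=1000, end=2000, total_cn=2, major_cn=1,
                 minor_cn=1),
        ]
        assert cn.compute_cnv_burden(_profile(seg)) == pytest.approx(50.0)

    def test_planted_burden_recovered(self, cohort):
        bundle, truth = cohort
        measured = (
            pd.Series(
                {
                    s: cn.compute_cnv_burden(p)
                    for s, p in bundle.profiles.items()
                }
            )
            .groupby(lambda s: s.split("-")[0])
            .mean()
        )
        for patient, expected in truth.burdens.items():
            assert measured[patient] == pytest.approx(expected, abs=1e-6)

    def test_zero_length_raises(self):
        with pytest.raises(ValueError):
            cn.compute_cnv_burden(
                _profile(
                    [dict(chrom="1", start=0, end=0, total_cn=2,
                          major_cn=1, minor_cn=1)]
                )
            )

    def test_invariant_to_segment_split(self):
        seg = [
            dict(chrom="1", start=0, end=2000, total_cn=4, major_cn=3,
                 minor_cn=1),
            dict(chrom="2", start=0, end=2000, total_cn=2, major_cn=1,
                 minor_cn=1),
        ]
        split = [
            dict(chrom="1", start=0, end=700, total_cn=4, major_cn=3,
                 minor_cn=1),
            dict(chrom="1", start=700, end=2000, total_cn=4, major_cn=3,
                 minor_cn=1),
            dict(chrom="2", start=0, end=2000, total_cn=2, major_cn=1,
                 minor_cn=1),
        ]
        assert cn.compute_cnv_burden(_profile(seg)) == pytest.approx(
            cn.compute_cnv_burden(_profile(split))
        )
        assert cn.compute_wgii(_profile(seg), ARMS) == pytest.approx(
            cn.compute_wgii(_profile(split), ARMS)
        )


class TestWGII:
    def test_diploid_is_zero(self):
        assert cn.compute_wgii(_whole_genome({}), ARMS) == 0.0

    def test_one_autosome_fully_gained(self):
        wgii = cn.compute_wgii(_whole_genome({"1": 3}), ARMS)
        assert wgii == pytest.approx(1 / 22)

    def test_doubled_genome_at_matching_ploidy_is_zero(self):
        prof = _whole_genome({c: 4 for c in CHROM_LEN.index}, ploidy=4.0)
        assert cn.compute_wgii(prof, ARMS) == 0.0

    def test_missing_chromosome_warns_and_excludes(self):
        seg = [dict(chrom="1", start=0, end=int(CHROM_LEN["1"]),
                    total_cn=3, major_cn=2, minor_cn=1)]
        with pytest.warns(UserWarning):
            wgii = cn.compute_wgii(_profile(seg), ARMS)
        assert wgii == pytest.approx(1.0)  # only chr1 considered, all altered


class TestArmEvents:
    def test_segment_cutoffs(self):
        # cn 5 at ploidy 2: log2(2.5) >= log2(1.25) -> gain
        arm1 = ARMS[(ARMS["chrom"] == "1") & (ARMS["arm"] == "p")].iloc[0]
        seg = [dict(chrom="1", start=arm1["start"], end=arm1["end"],
                    total_cn=5, major_cn=4, minor_cn=1)]
        calls = cn.call_arm_events(_profile(seg), ARMS)
        assert calls.set_index("arm").loc["1p", "state"] == "gain"

    def test_neutral_diploid_segment(self):
        arm1 = ARMS[(ARMS["chrom"] == "1") & (ARMS["arm"] == "p")].iloc[0]
        seg = [dict(chrom="1", start=arm1["start"], end=arm1["end"],
                    total_cn=2, major_cn=1, minor_cn=1)]
        calls = cn.call_arm_events(_profile(seg), ARMS)
        assert (calls["state"] == "neutral").all()

    def test_ploidy2_cutoffs_match_integer_copy_numbers(self):
        arm1 = ARMS[(ARMS["chrom"] == "1") & (ARMS["arm"] == "p")].iloc[0]
        for total, expected in [(3, "gain"), (2, "neutral"), (1, "loss")]:
            seg = [dict(chrom="1", start=arm1["start"], end=arm1["end"],
                        total_cn=total, major_cn=total, minor_cn=0)]
            calls = cn.call_arm_events(_profile(seg), ARMS)
            assert calls.set_index("arm").loc["1p", "state"] == expected

    def test_97_percent_gain_is_not_an_arm_event(self):
        arm1 = ARMS[(ARMS["chrom"] == "1") & (ARMS["arm"] == "p")].iloc[0]
        length = arm1["end"] - arm1["start"]
        cut = arm1["start"] + int(0.97 * length)
        seg = [
            dict(chrom="1", start=arm1["start"], end=cut, total_cn=5,
                 major_cn=4, minor_cn=1),
            dict(chrom="1", start=cut, end=arm1["end"], total_cn=2,
                 major_cn=1, minor_cn=1),
        ]
        calls = cn.call_arm_events(_profile(seg), ARMS)
        row = calls.set_index("arm").loc["1p"]
        assert row["state"] == "neutral"
        assert row["covered_fraction"] == pytest.approx(0.97, abs=0.001)

    def test_arm_calls_invariant_to_segment_order(self):
        arm1 = ARMS[(ARMS["chrom"] == "1") & (ARMS["arm"] == "p")].iloc[0]
        mid = (arm1["start"] + arm1["end"]) // 2
        rows = [
            dict(chrom="1", start=arm1["start"], end=mid, total_cn=5,
                 major_cn=4, minor_cn=1),
            dict(chrom="1", start=mid, end=arm1["end"], total_cn=5,
                 major_cn=4, minor_cn=1),
        ]
        a = cn.call_arm_events(_profile(rows), ARMS)
        b = cn.call_arm_events(_profile(rows[::-1]), ARMS)
        pd.testing.assert_frame_equal(a, b)

    def test_negative_copy_number_rejected(self):
        with pytest.raises(ValueError):
            arm1 = ARMS.iloc[0]
            seg = [dict(chrom=arm1["chrom"], start=arm1["start"],
                        end=arm1["end"], total_cn=-1, major_cn=0,
                        minor_cn=0)]
            cn.call_arm_events(_profile(seg), ARMS)


class TestArmClonality:
    def _calls(self, states_by_region, arm="1p"):
        rows = []
        for region, state in states_by_region.items():
            rows.append(dict(sample=region, arm=arm, state=state,
                             covered_fraction=1.0))
        return pd.DataFrame(rows)

    def test_event_in_all_regions_is_clonal(self):
        calls = self._calls({f"L{i}": "gain" for i in range(1, 5)})
        out = cn.classify_arm_clonality(calls)
        assert out.iloc[0]["clonality"] == "clonal"

    def test_event_in_one_of_four_is_subclonal(self):
        calls = self._calls(
            {"L1": "gain", "L2": "neutral", "L3": "neutral", "L4": "neutral"}
        )
        out = cn.classify_arm_clonality(calls)
        assert out.iloc[0]["clonality"] == "subclonal"

    def test_single_region_patient_clonal_by_convention(self):
        calls = self._calls({"L1": "loss"})
        with pytest.warns(UserWarning):
            out = cn.classify_arm_clonality(calls)
        assert out.iloc[0]["clonality"] == "clonal"

    def test_conflicting_calls_are_subclonal(self):
        calls = self._calls({"L1": "gain", "L2": "loss", "L3": "neutral"})
        with pytest.warns(UserWarning):
            out = cn.classify_arm_clonality(calls)
        assert out.iloc[0]["clonality"] == "subclonal"
        assert out.iloc[0]["state"] == "conflict"

    def test_synthetic_clonal_events_recovered(self, cohort):
        bundle, truth = cohort
        by_patient: dict = {}
        for sample, prof in bundle.profiles.items():
            by_patient.setdefault(prof.patient, []).append(prof)
        hits = total = 0
        for patient, profs in by_patient.items():
            calls = pd.concat(
                [cn.call_arm_events(p, ARMS) for p in profs],
                ignore_index=True,
            )
            out = cn.classify_arm_clonality(calls).set_index("arm")
            expected = truth.arm_events[truth.arm_events["patient"] == patient]
            for _, ev in expected.iterrows():
                total += 1
                if ev["arm"] in out.index:
                    row = out.loc[ev["arm"]]
                    hits += (
                        row["state"] == ev["state"]
                        and row["clonality"] == ev["clonality"]
                    )
        assert hits / total >= 0.95


class TestGenomeDoubling:
    def test_uniform_major_two_is_doubled(self):
        prof = _whole_genome({c: 4 for c in CHROM_LEN.index}, ploidy=4.0)
        prof.segments["major_cn"] = 2
        prof.segments["minor_cn"] = 2
        assert cn.detect_genome_doubling(prof) is True

    def test_diploid_heterozygous_is_not_doubled(self):
        prof = _whole_genome({})
        prof.segments["major_cn"] = 1
        prof.segments["minor_cn"] = 1
        assert cn.detect_genome_doubling(prof) is False

    def test_planted_doubling_recovered(self, cohort):
        bundle, truth = cohort
        correct = sum(
            cn.detect_genome_doubling(p) == truth.gd_flags[p.patient]
            for p in bundle.profiles.values()
        )
        assert correct / len(bundle.profiles) >= 0.95

    def test_missing_major_cn_raises(self):
        prof = _whole_genome({})
        seg = prof.segments.drop(columns=["major_cn"])
        prof2 = cn.SegmentProfile("S", purity=0.5, ploidy=2.0, segments=seg)
        with pytest.raises(ValueError):
            cn.detect_genome_doubling(prof2)
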