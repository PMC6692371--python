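import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import waikit
from waikit import (
    Genotype,
    TranscriptionClass,
    assign_genotype,
    classify_frame,
    depth_binned_summary,
    genotype_conversion,
    select_depth_cutoff,
)
from waikit.classify import assign_genotype_array


def brute_force_cutoff(summary, tolerance, window, default=10):
    """Independent scan over every candidate depth."""
    usable = summary[summary["props_defined"]].sort_values("depth_bin")
    diffs = np.abs(usable["prop_AB"].to_numpy() - usable["prop_BB"].to_numpy())
    depths = usable["depth_bin"].to_numpy()
    candidates = []
    for i in range(len(diffs) - window + 1):
        if all(abs(diffs[j] - diffs[i]) <= tolerance + 1e-12 for j in range(i, i + window)):
            candidates.append(int(depths[i]))
    return (min(candidates), False) if candidates else (default, True)


class TestAssignGenotype:
    @pytest.mark.parametrize(
        "vaf,expected",
        [(50, Genotype.AB), (80, Genotype.BB), (0, Genotype.AA),
         (2, Genotype.AB), (75, Genotype.AB), (75.01, Genotype.BB), (1.99, Genotype.AA)],
    )
    def test_band_assignment(self, vaf, expected):
        assert assign_genotype(vaf) is expected

    @pytest.mark.parametrize("vaf", [-1, 101])
    def test_domain_errors(self, vaf):
        with pytest.raises(ValueError):
            assign_genotype(vaf)

    @given(st.floats(min_value=0, max_value=100), st.floats(min_value=0, max_value=100))
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_vaf(self, v1, v2):
        order = [Genotype.AA, Genotype.AB, Genotype.BB]
        lo, hi = sorted([v1, v2])
        assert order.index(assign_genotype(lo)) <= order.index(assign_genotype(hi))

    def test_array_version_matches_scalar(self):
        vafs = np.linspace(0, 100, 201)
        arr = assign_genotype_array(vafs)
        assert all(arr[i] == assign_genotype(v).value for i, v in enumerate(vafs))


class TestClassifyTranscription:
    def test_small_table_classes(self, small_table):
        df = classify_frame(small_table)
        assert list(df["transcription_class"]) == [
            "TRANSCRIBED", "DNA_EXCLUSIVE", "RNA_EXCLUSIVE",
            "UNEVALUABLE", "TRANSCRIBED", "TRANSCRIBED",
        ]

    def test_classes_partition_observations(self, small_table):
        df = classify_frame(small_table)
        assert df["transcription_class"].value_counts().sum() == len(df)

    def test_absence_floors_respected(self, small_table):
        # RNA-absent at only 3x RNA coverage is unevaluable, not DNA-exclusive
        row = small_table.iloc[[1]].assign(rna_total_depth=3)
        assert classify_frame(row)["transcription_class"].iloc[0] == "UNEVALUABLE"
        # DNA-absent at 29x DNA coverage is unevaluable, not RNA-exclusive
        row = small_table.iloc[[2]].assign(dna_total_depth=29)
        assert classify_frame(row)["transcription_class"].iloc[0] == "UNEVALUABLE"

    @given(st.integers(min_value=1, max_value=5))
    @settings(max_examples=20, derandomize=True)
    def test_invariant_to_depth_scaling(self, factor):
        rows = pd.DataFrame(
            {
                "chrom": "chr1", "pos": 1, "ref": "A", "alt": "G",
                "sample_id": "S", "cohort": "C", "gene": "G",
                "variant_class": "SNV", "mutation_type": "nonsynonymous_SNV",
                "dna_total_depth": [200, 300, 50], "dna_alt_depth": [20, 30, 0],
                "rna_total_depth": [40, 12, 25], "rna_alt_depth": [5, 0, 6],
                "is_recurrent_mutation": True, "is_snp": False,
            }
        )
        base = classify_frame(rows)["transcription_class"]
        scaled = rows.assign(
            dna_total_depth=rows.dna_total_depth * factor,
            dna_alt_depth=rows.dna_alt_depth * factor,
            rna_total_depth=rows.rna_total_depth * factor,
            rna_alt_depth=rows.rna_alt_depth * factor,
        )
        assert list(classify_frame(scaled)["transcription_class"]) == list(base)


class TestGenotypeConversion:
    def _obs(self, dna_vaf, rna_vaf):
        from waikit import VariantKey, VariantObservation

        return VariantObservation(
            key=VariantKey("chr1", 1, "A", "G"), sample_id="S", cohort="C",
            gene="G", variant_class="SNV", mutation_type="nonsynonymous_SNV",
            dna_total_depth=1000, dna_alt_depth=int(10 * dna_vaf),
            rna_total_depth=100, rna_alt_depth=int(rna_vaf),
        )

    def test_ab_to_bb_admissible(self):
        conv = genotype_conversion(self._obs(45, 90))
        assert (conv.dna_genotype, conv.rna_genotype) == (Genotype.AB, Genotype.BB)
        assert conv.admissible

    def test_bb_to_ab_admissible_artifact(self):
        conv = genotype_conversion(self._obs(90, 50))
        assert (conv.dna_genotype, conv.rna_genotype) == (Genotype.BB, Genotype.AB)
        assert conv.admissible

    def test_low_dna_vaf_inadmissible(self):
        conv = genotype_conversion(self._obs(1.5, 30))
        assert not conv.admissible

    def test_bb_to_aa_inadmissible(self):
        obs = self._obs(90, 0)
        obs.rna_alt_depth = 0
        conv = genotype_conversion(obs)
        assert (conv.dna_genotype, conv.rna_genotype) == (Genotype.BB, Genotype.AA)
        assert not conv.admissible

    def test_rna_exclusive_raises(self):
        obs = self._obs(0, 30)
        obs.dna_alt_depth = 0
        with pytest.raises(ValueError, match="undefined"):
            genotype_conversion(obs)


class TestDepthBinnedSummary:
    def test_proportions_within_bin(self):
        df = pd.DataFrame(
            {
                "rna_total_depth": [12, 12, 12, 12],
                "transcription_class": ["TRANSCRIBED"] * 4,
                "rna_genotype": ["AB", "AB", "BB", "BB"],
            }
        )
        summary = depth_binned_summary(df)
        row = summary[summary["depth_bin"] == 12].iloc[0]
        assert row["prop_AB"] == 0.5 and row["prop_BB"] == 0.5

    def test_empty_input(self):
        assert depth_binned_summary(pd.DataFrame()).empty

    def test_dna_exclusive_only_bin_flagged(self):
        df = pd.DataFrame(
            {
                "rna_total_depth": [5, 5, 5],
                "transcription_class": ["DNA_EXCLUSIVE"] * 3,
                "rna_genotype": ["AA"] * 3,
            }
        )
        row = depth_binned_summary(df).iloc[0]
        assert row["n_dna_exclusive"] == 3
        assert not row["props_defined"]
        assert row["prop_AB"] == 0 and row["prop_BB"] == 0

    def test_overflow_bin(self):
        df = pd.DataFrame(
            {
                "rna_total_depth": [60, 70],
                "transcription_class": ["TRANSCRIBED"] * 2,
                "rna_genotype": ["AB", "AB"],
            }
        )
        summary = depth_binned_summary(df, max_depth=50)
        assert list(summary["depth_bin"]) == [51]
        assert summary.iloc[0]["n_transcribed"] == 2


class TestSelectDepthCutoff:
    def test_spec_profile_first_stable_bin(self):
        diffs = [0.4, 0.3, 0.05, 0.04, 0.04, 0.04, 0.05]
        summary = pd.DataFrame(
            {
                "depth_bin": range(1, len(diffs) + 1),
                "prop_AB": [0.5 + d / 2 for d in diffs],
                "prop_BB": [0.5 - d / 2 for d in diffs],
                "props_defined": True,
            }
        )
        result = select_depth_cutoff(summary, tolerance=0.02, window=3)
        assert (result.depth, result.default_used) == (3, False)
        assert brute_force_cutoff(summary, 0.02, 3) == (3, False)

    def test_constant_profile_selects_first_depth(self):
        summary = pd.DataFrame(
            {"depth_bin": range(1, 11), "prop_AB": 0.6, "prop_BB": 0.4, "props_defined": True}
        )
        assert select_depth_cutoff(summary).depth == 1

    def test_insufficient_bins_fall_back_to_default(self):
        summary = pd.DataFrame(
            {"depth_bin": [1, 2], "prop_AB": [0.6, 0.6], "prop_BB": [0.4, 0.4],
             "props_defined": True}
        )
        result = select_depth_cutoff(summary, window=5)
        assert (result.depth, result.default_used) == (10, True)

    def test_invalid_tolerance(self):
        with pytest.raises(ValueError):
            select_depth_cutoff(pd.DataFrame(), tolerance=0)

    @pytest.mark.parametrize("d", [5, 10, 20])
    def test_constructed_profiles_match_brute_force(self, d):
        profile = waikit.make_convergence_profile(d)
        result = select_depth_cutoff(profile)
        assert (result.depth, result.default_used) == (d, False)
        assert brute_force_cutoff(profile, 0.02, 5) == (d, False)

    @pytest.mark.parametrize("d", [5, 10, 20])
    def test_cutoff_never_decreases_as_tolerance_tightens(self, d):
        profile = waikit.make_convergence_profile(d)
        tolerances = [0.5, 0.2, 0.1, 0.05, 0.02, 0.01]
        cutoffs = [select_depth_cutoff(profile, tolerance=t).depth for t in tolerances]
        assert cutoffs == sorted(cutoffs)
        for t, c in zip(tolerances, cutoffs):
            assert brute_force_cutoff(profile, t, 5)[0] == c
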