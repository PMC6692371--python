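import numpy as np
import pandas as pd
import pytest

import waikit
from waikit import (
    WAIModelSpec,
    WAIRegressor,
    expected_rna_variant_depth,
    fit_wai,
    fit_wai_snps,
    multiple_testing,
    select_model_variants,
)
from waikit.classify import classify_frame

from conftest import brute_force_bh


class TestExpectedDepth:
    @pytest.mark.parametrize(
        "vaf,depth,expected",
        [(50, 100, 50.0), (0, 200, 0.0), (33.3, 60, 19.98), (100, 7, 7.0)],
    )
    def test_formula(self, vaf, depth, expected):
        assert expected_rna_variant_depth(vaf, depth) == pytest.approx(expected, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            expected_rna_variant_depth(101, 10)
        with pytest.raises(ValueError):
            expected_rna_variant_depth(50, -1)


class TestMultipleTesting:
    def test_hand_worked_example(self):
        assert multiple_testing([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_and_zero(self):
        assert multiple_testing([0.5]) == pytest.approx([0.5])
        assert multiple_testing([0.0, 0.5])[0] == 0.0

    def test_empty(self):
        assert multiple_testing([]).size == 0

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(multiple_testing(p), brute_force_bh(p), atol=1e-12)


class TestWAIRegressorExactness:
    @pytest.mark.parametrize("k", [0.5, 1.0, 1.5, 2.0])
    def test_exact_proportionality_recovery(self, k, fixture_suite):
        df = classify_frame(fixture_suite["proportionality"][k])
        results = fit_wai(df, WAIModelSpec(bootstrap_reps=100, seed=0))
        assert len(results) == 1
        assert results[0].wai == pytest.approx(k, abs=1e-9)

    def test_exactness_regardless_of_covariate_composition(self):
        # observed = 1.25 x expected with two mutation types present
        rna_totals = np.array([40, 80, 160, 320, 640, 1280, 80, 240])
        df = waikit.make_proportionality_group(1.0, n=8).assign(
            rna_total_depth=rna_totals,
            rna_alt_depth=(1.25 * 0.5 * rna_totals).astype(int),
            mutation_type=["nonsynonymous_SNV"] * 4 + ["synonymous_SNV"] * 4,
        )
        df = classify_frame(waikit.add_vaf_columns(df))
        res = fit_wai(df, WAIModelSpec(bootstrap_reps=100, seed=0))
        assert res[0].wai == pytest.approx(1.25, abs=1e-9)

    def test_perfect_balance_gives_large_p(self, fixture_suite):
        df = classify_frame(fixture_suite["proportionality"][1.0])
        res = fit_wai(df, WAIModelSpec(bootstrap_reps=500, seed=0))
        assert res[0].wai == pytest.approx(1.0, abs=1e-9)
        assert res[0].p_value > 0.5

    def test_scale_equivariance(self, fixture_suite):
        df = classify_frame(fixture_suite["proportionality"][1.5])
        c = 3
        scaled = classify_frame(
            waikit.add_vaf_columns(
                df.assign(
                    rna_total_depth=df.rna_total_depth * c,
                    rna_alt_depth=df.rna_alt_depth * c,
                )
            )
        )
        r1 = fit_wai(df, WAIModelSpec(bootstrap_reps=100, seed=0))[0]
        r2 = fit_wai(scaled, WAIModelSpec(bootstrap_reps=100, seed=0))[0]
        assert r2.wai == pytest.approx(r1.wai, abs=1e-9)

    def test_single_cohort_model3_equals_model1(self, fixture_suite):
        df = classify_frame(fixture_suite["proportionality"][1.5])
        model1 = WAIModelSpec(covariates=("mutation_type",), bootstrap_reps=200, seed=4)
        model3 = WAIModelSpec(covariates=("mutation_type", "cohort"), bootstrap_reps=200, seed=4)
        r1, r3 = fit_wai(df, model1)[0], fit_wai(df, model3)[0]
        assert r3.wai == r1.wai
        assert r3.ci_low == r1.ci_low and r3.ci_high == r1.ci_high
        assert r3.p_value == r1.p_value

    def test_degenerate_group_flagged_not_fitted(self):
        df = waikit.make_proportionality_group(1.0)
        df = classify_frame(df.assign(rna_total_depth=100, rna_alt_depth=50))
        res = fit_wai(df, WAIModelSpec(bootstrap_reps=100))
        assert res[0].degenerate
        assert np.isnan(res[0].wai)
        assert res[0].direction == "none"

    def test_bootstrap_deterministic_given_seed(self, fixture_suite):
        df = classify_frame(fixture_suite["proportionality"][1.5])
        noisy = df.assign(rna_alt_depth=df.rna_alt_depth + np.arange(len(df)) % 3)
        noisy = classify_frame(waikit.add_vaf_columns(noisy))
        spec = WAIModelSpec(bootstrap_reps=300, seed=11)
        r1, r2 = fit_wai(noisy, spec)[0], fit_wai(noisy, spec)[0]
        assert (r1.wai, r1.ci_low, r1.ci_high, r1.p_value) == (r2.wai, r2.ci_low, r2.ci_high, r2.p_value)

    def test_estimate_inside_its_own_ci(self):
        cfg = waikit.SimulationConfig(
            genes=(waikit.GeneSpec("G", 1.3, 100),), n_samples=100,
            nontranscribed_fraction=0, rna_exclusive_rate=0, snp_sites_per_gene=0, seed=5,
        )
        obs, _ = waikit.simulate_cohort(cfg)
        res = fit_wai(classify_frame(obs), WAIModelSpec(bootstrap_reps=400, seed=5))[0]
        assert res.ci_contains_estimate
        assert res.ci_low <= res.wai <= res.ci_high


class TestSelectModelVariants:
    def _cohort(self):
        cfg = waikit.SimulationConfig(
            genes=(waikit.GeneSpec("BIG", 1.0, 30), waikit.GeneSpec("TINY", 1.0, 4)),
            n_samples=30, nontranscribed_fraction=0, rna_exclusive_rate=0,
            snp_sites_per_gene=0, seed=2,
        )
        obs, _ = waikit.simulate_cohort(cfg)
        return classify_frame(obs)

    def test_small_group_dropped(self):
        sub = select_model_variants(self._cohort(), WAIModelSpec(min_group_size=5))
        assert "TINY" not in set(sub["gene"])
        assert "BIG" in set(sub["gene"])

    def test_homozygous_rows_excluded(self):
        df = self._cohort()
        df.loc[df.index[:3], "dna_genotype"] = "BB"
        sub = select_model_variants(df, WAIModelSpec())
        assert (sub["dna_genotype"] == "AB").all()

    def test_rna_exclusive_rows_excluded(self):
        df = self._cohort()
        sub = select_model_variants(df, WAIModelSpec())
        assert set(sub["transcription_class"]) <= {"TRANSCRIBED", "DNA_EXCLUSIVE"}

    def test_multiple_mutations_per_patient_kept_as_rows(self):
        df = self._cohort()
        dup = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        sub = select_model_variants(dup, WAIModelSpec())
        first = df.iloc[0]
        same = sub[(sub["pos"] == first["pos"]) & (sub["sample_id"] == first["sample_id"])]
        assert len(same) == 2

    def test_requires_classification(self, small_table):
        with pytest.raises(ValueError, match="classified"):
            select_model_variants(small_table, WAIModelSpec())

    def test_empty_selection_gives_empty_results(self, small_table):
        df = classify_frame(small_table).assign(is_recurrent_mutation=False)
        assert fit_wai(df, WAIModelSpec()) == []


class TestModelSpecValidation:
    def test_grouping_cannot_be_covariate(self):
        with pytest.raises(ValueError):
            WAIModelSpec(grouping="per_gene", covariates=("gene",))

    def test_min_bootstrap(self):
        with pytest.raises(ValueError):
            WAIModelSpec(bootstrap_reps=10)


class TestSNPWai:
    def _snp_cohort(self, seed=3):
        cfg = waikit.SimulationConfig(
            genes=tuple(waikit.GeneSpec(g, 1.0, 0) for g in ["G1", "G2", "G3"]),
            n_samples=80, rna_exclusive_rate=0, snp_sites_per_gene=2, seed=seed,
        )
        obs, _ = waikit.simulate_cohort(cfg)
        return classify_frame(obs)

    def test_balanced_snps_near_one(self):
        df = self._snp_cohort()
        res = fit_wai_snps(df, WAIModelSpec(covariates=(), bootstrap_reps=500, seed=3))
        assert res, "expected at least one analysable gene"
        for r in res:
            assert r.wai == pytest.approx(1.0, abs=0.15)

    def test_small_snp_groups_excluded(self):
        df = self._snp_cohort()
        counts = df[df.is_snp & (df.dna_genotype == "AB")].groupby("gene").size()
        big_n = int(counts.max())
        res = fit_wai_snps(df, WAIModelSpec(covariates=(), bootstrap_reps=100,
                                            min_group_size=big_n + 1))
        assert res == []

    def test_imbalanced_snp_set_recovered(self):
        # plant imbalance 1.3 on the minor allele by scaling RNA alt counts
        rng = np.random.default_rng(7)
        df = self._snp_cohort(seed=7)
        snp = df["is_snp"] & (df["dna_genotype"] == "AB")
        vaf = df.loc[snp, "dna_vaf"].to_numpy()
        rt = df.loc[snp, "rna_total_depth"].to_numpy()
        maf_frac = np.where(vaf <= 50, vaf, 100 - vaf) / 100.0
        minor_counts = rng.binomial(rt.astype(int), np.minimum(1.3 * maf_frac, 1))
        new_alt = np.where(vaf <= 50, minor_counts, rt - minor_counts)
        df.loc[snp, "rna_alt_depth"] = new_alt
        df = classify_frame(waikit.add_vaf_columns(df))
        res = fit_wai_snps(df, WAIModelSpec(covariates=(), bootstrap_reps=500, seed=7))
        for r in res:
            assert r.ci_low <= 1.3 <= r.ci_high
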