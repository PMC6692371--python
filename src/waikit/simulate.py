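"""Synthetic paired DNA/RNA variant cohorts with known ground truth.

The generator is the package's test bed: it emulates a targeted-DNA-seq +
RNA-seq cohort of recurrently mutated genes so every pipeline stage —
classification, filtering, cutoff calibration and WAI inference — can be
verified against planted truth without any external data.

Generative model, per mutation:

* DNA and RNA total depths follow negative-binomial laws (defaults: mean
  542x for the targeted DNA assay, 85x for RNA, matching deep amplicon
  panels paired with whole-transcriptome coverage), clipped below at the
  assay floors so depth is never the limiting factor unless asked for.
* The true DNA VAF is subclonal: Beta(2, 3) scaled to [2, 75] percent
  (median ~ 30%), the heterozygous band by construction.
* ``dna_alt_depth ~ Binomial(dna_total_depth, vaf/100)``.
* With probability ``nontranscribed_fraction`` the mutant allele is not
  transcribed: the RNA alternate count is 0 (true class DNA_EXCLUSIVE).
* Otherwise ``rna_alt_depth ~ Binomial(rna_total_depth,
  min(1, true_wai * vaf/100))`` — the per-gene imbalance factor multiplies
  the allele-sampling probability, which makes the expected/observed
  regression slope equal to the generative factor (the estimand).
  Probabilities clamped at 1 are counted and reported.
* RNA-exclusive decoys (sequencing-error false positives) are appended per
  sample at a Poisson rate, with zero DNA alternate reads at well-covered
  DNA loci.
* Common SNPs at true WAI 1 and population MAF near 50% are planted in
  mutation-free samples as the negative control.

Setting ``sampling_noise=False`` replaces every binomial draw by its
rounded expectation, which makes genotype-conversion counts exactly
predictable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .records import INDEL_MUTATION_TYPES, SNV_MUTATION_TYPES, add_vaf_columns
from .regions import RegionSet

#: Synthetic genome layout: each gene occupies a 10 kb window on chr1.
GENE_SPAN = 10_000


@dataclass(frozen=True)
class GeneSpec:
    """One recurrently mutated gene in the simulation."""

    symbol: str
    true_wai: float
    n_mutations: int
    mutation_type_mix: tuple = (("nonsynonymous_SNV", 0.7), ("synonymous_SNV", 0.2), ("stopgain_SNV", 0.1))

    def __post_init__(self) -> None:
        if self.true_wai <= 0:
            raise ValueError("true_wai must be > 0")


# Default panel: imbalance factors are modest (the study's finding is a
# small but significant imbalance), with mutant-abundant, balanced and
# wild-type-abundant genes and two INDEL-dominated genes.
_INDEL_MIX = (("frameshift_insertion", 0.5), ("frameshift_deletion", 0.3), ("nonframeshift_insertion", 0.2))
DEFAULT_GENES = (
    GeneSpec("GATA2", 1.4, 20),
    GeneSpec("RUNX1", 1.2, 30),
    GeneSpec("TET2", 1.15, 30),
    GeneSpec("SRSF2", 1.1, 25),
    GeneSpec("IDH2", 1.1, 25),
    GeneSpec("PTPN11", 0.75, 25),
    GeneSpec("U2AF1", 1.0, 20),
    GeneSpec("FLT3", 1.0, 40),
    GeneSpec("NPM1", 1.25, 40, _INDEL_MIX),
    GeneSpec("CEBPA", 0.8, 25, _INDEL_MIX),
    GeneSpec("WT1", 0.85, 20, _INDEL_MIX),
)


@dataclass
class SimulationConfig:
    """Generative parameters of a synthetic paired cohort.

    Depth laws are (mean, dispersion) of a negative binomial (variance =
    mean + mean^2 / dispersion), clipped below at ``*_depth_min``.  The DNA
    VAF law is a Beta(a, b) scaled to [low, high] percent.
    """

    genes: tuple = DEFAULT_GENES
    n_samples: int = 246
    cohorts: tuple = (("AMLCG", 1.0),)
    dna_depth_law: tuple = (542.0, 8.0)
    rna_depth_law: tuple = (85.0, 5.0)
    dna_depth_min: int = 30
    rna_depth_min: int = 10
    dna_vaf_law: tuple = (2.0, 3.0, 2.0, 75.0)   # (a, b, low_pct, high_pct)
    nontranscribed_fraction: float = 0.04
    rna_exclusive_rate: float = 15.0
    snp_sites_per_gene: int = 3
    snp_maf_center: float = 50.0
    snp_maf_sd: float = 5.0
    sampling_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.nontranscribed_fraction <= 1:
            raise ValueError("nontranscribed_fraction must be in [0, 1]")
        if self.dna_depth_law[0] < 1 or self.rna_depth_law[0] < 1:
            raise ValueError("depth means must be >= 1")
        if self.rna_exclusive_rate < 0:
            raise ValueError("rna_exclusive_rate must be >= 0")


def _nbinom(rng: np.random.Generator, mean: float, dispersion: float, size: int, floor: int) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    draws = rng.negative_binomial(dispersion, p, size=size)
    return np.maximum(draws, floor)


def _scaled_beta(rng: np.random.Generator, law: tuple, size: int) -> np.ndarray:
    a, b, low, high = law
    return low + (high - low) * rng.beta(a, b, size=size)


def _binom(rng: np.random.Generator, n: np.ndarray, p: np.ndarray, noise: bool) -> np.ndarray:
    if noise:
        return rng.binomial(n.astype(int), p)
    return np.rint(n * p).astype(int)


def _gene_positions(genes) -> dict:
    return {g.symbol: 1_000_000 * (i + 1) for i, g in enumerate(genes)}


def gene_regions(config: SimulationConfig) -> RegionSet:
    """BED-convention regions covering each simulated gene's window."""
    starts = _gene_positions(config.genes)
    return RegionSet(
        [("chr1", start - 1, start - 1 + GENE_SPAN, g.symbol) for g, start in
         ((g, starts[g.symbol]) for g in config.genes)]
    )


def simulate_cohort(config: SimulationConfig | None = None, seed: int | None = None):
    """Generate one synthetic cohort.

    Returns ``(observations, truth)``: the consolidated variant table and a
    ground-truth table aligned on ``obs_id``, carrying the true
    transcription class, true DNA/RNA genotypes (from the generative allele
    probabilities, not the sampled reads) and the generating gene's WAI.
    ``truth.attrs["per_gene_wai"]`` maps gene symbol to true WAI;
    ``truth.attrs["n_clamped"]`` counts allele probabilities clamped at 1.
    Fully deterministic given the config seed.
    """
    from .classify import HET_HIGH, HET_LOW, TranscriptionClass, assign_genotype_array

    config = config or SimulationConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)

    cohort_names = [c[0] for c in config.cohorts]
    weights = np.array([c[1] for c in config.cohorts], dtype=float)
    weights /= weights.sum()
    samples = [f"S{i:04d}" for i in range(config.n_samples)]
    sample_cohort = rng.choice(len(cohort_names), size=config.n_samples, p=weights)
    gene_start = _gene_positions(config.genes)

    obs_rows: list[dict] = []
    truth_rows: list[dict] = []
    n_clamped = 0
    mutated_samples: set[str] = set()

    for gene in config.genes:
        n = gene.n_mutations
        sample_idx = rng.integers(0, config.n_samples, size=n)
        dna_total = _nbinom(rng, *config.dna_depth_law, n, config.dna_depth_min)
        rna_total = _nbinom(rng, *config.rna_depth_law, n, config.rna_depth_min)
        vaf = _scaled_beta(rng, config.dna_vaf_law, n)
        dna_alt = _binom(rng, dna_total, vaf / 100.0, config.sampling_noise)
        # RNA allele sampling conditions on the *recorded* DNA VAF (the
        # regressor the model will see), so the regression slope's estimand
        # is exactly the generative imbalance factor.
        recorded_vaf = np.where(dna_total > 0, 100.0 * dna_alt / dna_total, 0.0)
        p_rna_raw = gene.true_wai * recorded_vaf / 100.0
        clamped = p_rna_raw > 1.0
        n_clamped += int(clamped.sum())
        p_rna = np.minimum(p_rna_raw, 1.0)
        nontranscribed = rng.random(n) < config.nontranscribed_fraction
        rna_alt = _binom(rng, rna_total, p_rna, config.sampling_noise)
        rna_alt[nontranscribed] = 0

        types, probs = zip(*gene.mutation_type_mix)
        mtypes = rng.choice(types, size=n, p=np.asarray(probs) / np.sum(probs))
        positions = gene_start[gene.symbol] + rng.integers(0, GENE_SPAN - 10, size=n)

        if config.sampling_noise:
            true_dna_geno = assign_genotype_array(vaf)
            true_rna_geno = assign_genotype_array(np.minimum(100.0 * p_rna, 100.0))
        else:
            # without sampling noise the realised VAFs (up to rounding) are
            # the generative ones; truth must match what rounding produced
            true_dna_geno = assign_genotype_array(
                np.where(dna_total > 0, 100.0 * dna_alt / dna_total, 0.0)
            )
            true_rna_geno = assign_genotype_array(
                np.where(rna_total > 0, 100.0 * rna_alt / rna_total, 0.0)
            )
        true_rna_geno = np.where(nontranscribed, "AA", true_rna_geno)

        for j in range(n):
            sid = samples[sample_idx[j]]
            mutated_samples.add(sid)
            ref, alt = _alleles_for(mtypes[j], rng)
            obs_rows.append(
                {
                    "chrom": "chr1",
                    "pos": int(positions[j]),
                    "ref": ref,
                    "alt": alt,
                    "sample_id": sid,
                    "cohort": cohort_names[sample_cohort[sample_idx[j]]],
                    "gene": gene.symbol,
                    "variant_class": "SNV" if mtypes[j].endswith("_SNV") else "INDEL",
                    "mutation_type": mtypes[j],
                    "dna_total_depth": int(dna_total[j]),
                    "dna_alt_depth": int(dna_alt[j]),
                    "rna_total_depth": int(rna_total[j]),
                    "rna_alt_depth": int(rna_alt[j]),
                    "is_recurrent_mutation": True,
                    "is_snp": False,
                }
            )
            truth_rows.append(
                {
                    "true_class": (
                        TranscriptionClass.DNA_EXCLUSIVE.value
                        if nontranscribed[j]
                        else TranscriptionClass.TRANSCRIBED.value
                    ),
                    "true_dna_genotype": true_dna_geno[j],
                    "true_rna_genotype": true_rna_geno[j],
                    "gene_true_wai": gene.true_wai,
                }
            )

    # RNA-exclusive decoys: sequencing-error artefacts seen only in RNA.
    if config.rna_exclusive_rate > 0 and config.genes:
        n_decoys = rng.poisson(config.rna_exclusive_rate, size=config.n_samples)
        total_decoys = int(n_decoys.sum())
        if total_decoys:
            gene_choice = rng.integers(0, len(config.genes), size=total_decoys)
            dna_total = _nbinom(rng, *config.dna_depth_law, total_decoys, max(31, config.dna_depth_min))
            rna_total = _nbinom(rng, *config.rna_depth_law, total_decoys, config.rna_depth_min)
            err_vaf = rng.uniform(2.0, 20.0, size=total_decoys)
            rna_alt = np.maximum(1, _binom(rng, rna_total, err_vaf / 100.0, config.sampling_noise))
            k = 0
            for si, count in enumerate(n_decoys):
                for _ in range(count):
                    gene = config.genes[gene_choice[k]]
                    pos = gene_start[gene.symbol] + int(rng.integers(0, GENE_SPAN - 10))
                    ref, alt = _alleles_for("nonsynonymous_SNV", rng)
                    obs_rows.append(
                        {
                            "chrom": "chr1",
                            "pos": pos,
                            "ref": ref,
                            "alt": alt,
                            "sample_id": samples[si],
                            "cohort": cohort_names[sample_cohort[si]],
                            "gene": gene.symbol,
                            "variant_class": "SNV",
                            "mutation_type": "nonsynonymous_SNV",
                            "dna_total_depth": int(dna_total[k]),
                            "dna_alt_depth": 0,
                            "rna_total_depth": int(rna_total[k]),
                            "rna_alt_depth": int(rna_alt[k]),
                            "is_recurrent_mutation": False,
                            "is_snp": False,
                        }
                    )
                    truth_rows.append(
                        {
                            "true_class": TranscriptionClass.RNA_EXCLUSIVE.value,
                            "true_dna_genotype": "AA",
                            "true_rna_genotype": "",
                            "gene_true_wai": np.nan,
                        }
                    )
                    k += 1

    # Common SNPs (true WAI = 1) in mutation-free samples.
    snp_free = [s for s in samples if s not in mutated_samples]
    if config.snp_sites_per_gene > 0 and snp_free and config.genes:
        for gene in config.genes:
            for site in range(config.snp_sites_per_gene):
                maf = float(
                    np.clip(
                        rng.normal(config.snp_maf_center, config.snp_maf_sd), 20.0, 50.0
                    )
                )
                pos = gene_start[gene.symbol] + GENE_SPAN - 100 + site * 3
                ref, alt = _alleles_for("synonymous_SNV", rng)
                f = maf / 100.0
                p_het, p_hom = 2 * f * (1 - f), f * f
                for sid in snp_free:
                    u = rng.random()
                    if u < p_hom:
                        allele_frac = 1.0
                    elif u < p_hom + p_het:
                        allele_frac = 0.5
                    else:
                        continue
                    dna_total = int(_nbinom(rng, *config.dna_depth_law, 1, config.dna_depth_min)[0])
                    rna_total = int(_nbinom(rng, *config.rna_depth_law, 1, config.rna_depth_min)[0])
                    dna_alt = int(_binom(rng, np.array([dna_total]), np.array([allele_frac]), config.sampling_noise)[0])
                    # SNP true WAI is 1: RNA sampling conditions on the
                    # recorded DNA VAF, as for mutations
                    recorded = dna_alt / dna_total if dna_total else 0.0
                    rna_alt = int(_binom(rng, np.array([rna_total]), np.array([recorded]), config.sampling_noise)[0])
                    cohort = cohort_names[sample_cohort[samples.index(sid)]]
                    obs_rows.append(
                        {
                            "chrom": "chr1",
                            "pos": pos,
                            "ref": ref,
                            "alt": alt,
                            "sample_id": sid,
                            "cohort": cohort,
                            "gene": gene.symbol,
                            "variant_class": "SNV",
                            "mutation_type": "synonymous_SNV",
                            "dna_total_depth": dna_total,
                            "dna_alt_depth": dna_alt,
                            "rna_total_depth": rna_total,
                            "rna_alt_depth": rna_alt,
                            "is_recurrent_mutation": False,
                            "is_snp": True,
                        }
                    )
                    truth_rows.append(
                        {
                            "true_class": TranscriptionClass.TRANSCRIBED.value,
                            "true_dna_genotype": "BB" if allele_frac == 1.0 else "AB",
                            "true_rna_genotype": "BB" if allele_frac == 1.0 else "AB",
                            "gene_true_wai": 1.0,
                        }
                    )

    observations = add_vaf_columns(pd.DataFrame(obs_rows))
    observations.insert(0, "obs_id", np.arange(len(observations)))
    truth = pd.DataFrame(truth_rows)
    truth.insert(0, "obs_id", np.arange(len(truth)))
    truth.attrs["per_gene_wai"] = {g.symbol: g.true_wai for g in config.genes}
    truth.attrs["n_clamped"] = n_clamped
    if n_clamped:
        warnings.warn(
            f"{n_clamped} allele-sampling probabilities clamped at 1 "
            "(true_wai x vaf/100 > 1)",
            RuntimeWarning,
            stacklevel=2,
        )
    return observations, truth


_BASES = np.array(list("ACGT"))


def _alleles_for(mutation_type: str, rng: np.random.Generator):
    ref = str(rng.choice(_BASES))
    if mutation_type.endswith("_SNV"):
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        return ref, alt
    ins = "".join(rng.choice(_BASES, size=3))
    if "insertion" in mutation_type:
        length = 1 if mutation_type.startswith("frameshift") else 3
        return ref, ref + ins[:length]
    if "deletion" in mutation_type:
        length = 1 if mutation_type.startswith("frameshift") else 3
        return ref + ins[:length], ref
    # substitution: length-changing for frameshift, length-preserving pair otherwise
    if mutation_type.startswith("frameshift"):
        return ref + ins[:2], ref + ins[:1] if ins[:1] != ins[:2] else ref
    alt = "".join(rng.choice(_BASES, size=2))
    ref2 = ref + str(rng.choice(_BASES))
    while alt == ref2:
        alt = "".join(rng.choice(_BASES, size=2))
    return ref2, alt


# -- canonical test fixtures --------------------------------------------------

def make_proportionality_group(k: float, gene: str | None = None, n: int = 8) -> pd.DataFrame:
    """A modelling-ready group where observed RNA depth = k x expected exactly.

    DNA VAF is 50% and RNA total depths are spread so the expected depths
    are distinct; the regression slope on this group is exactly k.
    """
    rna_totals = np.arange(1, n + 1) * 20          # expected = 10, 20, ..., 10n
    expected = 50.0 * rna_totals / 100.0
    observed = k * expected
    if not np.allclose(observed, np.rint(observed)):
        raise ValueError(f"k={k} does not yield integer observed depths on this grid")
    df = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1000, 1000 + n),
            "ref": "A",
            "alt": "G",
            "sample_id": [f"S{i:02d}" for i in range(n)],
            "cohort": "AMLCG",
            "gene": gene or f"GENE_K{str(k).replace('.', '_')}",
            "variant_class": "SNV",
            "mutation_type": "nonsynonymous_SNV",
            "dna_total_depth": 500,
            "dna_alt_depth": 250,
            "rna_total_depth": rna_totals,
            "rna_alt_depth": observed.astype(int),
            "is_recurrent_mutation": True,
            "is_snp": False,
        }
    )
    return add_vaf_columns(df)


def make_convergence_profile(converge_depth: int, max_depth: int = 40, window: int = 5) -> pd.DataFrame:
    """A depth-bin summary whose AB/BB proportion gap stabilises exactly at
    ``converge_depth``: the gap falls in steps of 0.1 before that depth and
    is constant from it onward.
    """
    # pre-convergence gaps shrink by a constant step large enough that no
    # window before converge_depth is stable under the default tolerance
    step = min(0.1, 0.9 / converge_depth)
    rows = []
    for d in range(1, max_depth + 1):
        gap = 0.05 + step * max(0, converge_depth - d)
        rows.append(
            {
                "depth_bin": d,
                "n_transcribed": 100,
                "n_dna_exclusive": 0,
                "n_rna_exclusive": 0,
                "prop_AB": 0.5 + gap / 2,
                "prop_BB": 0.5 - gap / 2,
                "props_defined": True,
            }
        )
    return pd.DataFrame(rows)


def make_blacklist_fixture():
    """Observations plus a blacklist set hitting exactly rows 1 and 3."""
    from .filters import BlacklistSet

    df = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": [100, 200, 300, 400, 500],
            "ref": "A",
            "alt": "T",
            "sample_id": "S0",
            "cohort": "AMLCG",
            "gene": "G1",
            "variant_class": "SNV",
            "mutation_type": "nonsynonymous_SNV",
            "dna_total_depth": 200,
            "dna_alt_depth": 60,
            "rna_total_depth": 80,
            "rna_alt_depth": 25,
            "is_recurrent_mutation": True,
            "is_snp": False,
        }
    )
    blacklists = BlacklistSet(
        rna_editing_sites=RegionSet([("chr1", 199, 200, "edit_site")]),
        repeat_regions=RegionSet([("chr1", 390, 410, "repeat")]),
    )
    return add_vaf_columns(df), blacklists, {"rna_editing": [1], "repeat": [3]}


def make_fixture_suite() -> dict:
    """Bundle of canonical fixtures with expected-output manifests."""
    proportionality = {k: make_proportionality_group(k) for k in (0.5, 1.0, 1.5, 2.0)}
    profiles = {d: make_convergence_profile(d) for d in (5, 10, 20)}
    blacklist_df, blacklists, planted = make_blacklist_fixture()
    bh_vectors = [
        np.array([0.01, 0.02, 0.03]),
        np.array([0.5]),
        np.array([0.0, 0.04, 1.0, 0.2, 0.2]),
        np.linspace(0.001, 1.0, 20),
    ]
    return {
        "proportionality": proportionality,
        "proportionality_manifest": {k: k for k in proportionality},
        "cutoff_profiles": profiles,
        "cutoff_manifest": {d: d for d in profiles},
        "blacklist": (blacklist_df, blacklists),
        "blacklist_manifest": planted,
        "bh_vectors": bh_vectors,
    }
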