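"""Weighted allelic imbalance (WAI) estimation.

For a heterozygous variant i, the RNA alternate-read depth expected under
allelic balance is

    expected_i = dna_vaf_i * rna_total_depth_i / 100        (VAF in percent)

The WAI of a group of variants (a gene, or a mutation type) is the slope of
an ordinary-least-squares regression of the *observed* RNA alternate-read
depth on this expected depth, adjusted for categorical covariates
(mutation type, gene, cohort) with an intercept:

    observed_i ~ expected_i + covariates          WAI := coefficient on expected_i

WAI = 1 means the mutant and wild-type alleles are equally represented in
the transcriptome; WAI > 1 means preferential mutant transcript abundance,
WAI < 1 preferential wild-type abundance.  Because depths, not VAFs, are
regressed, high-coverage variants carry more weight — the "weighted" in the
name.  Inference is by nonparametric case-resampling bootstrap: resample
variant rows within the group, refit, take percentile confidence intervals,
and test H0: WAI = 1 with a two-sided tail-count p-value.

Only DNA-heterozygous variants (VAF in [2, 75]%) that are transcribed or
DNA-exclusive enter the model; homozygous and RNA-exclusive variants are
excluded, groups need at least 5 qualifying variants, and SNVs and INDELs
are always modelled separately.  Each mutation pair is one independent row
even when a patient carries several mutations in the same gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .classify import HET_HIGH, HET_LOW, Genotype, TranscriptionClass

MODELLABLE_CLASSES = (
    TranscriptionClass.TRANSCRIBED.value,
    TranscriptionClass.DNA_EXCLUSIVE.value,
)


def expected_rna_variant_depth(dna_vaf, rna_total_depth):
    """Expected RNA alternate-read depth under allelic balance.

    ``dna_vaf`` is in percent, so the expectation is
    ``dna_vaf * rna_total_depth / 100`` (unrounded).  Accepts scalars or
    arrays.
    """
    dna_vaf = np.asarray(dna_vaf, dtype=float)
    rna_total_depth = np.asarray(rna_total_depth, dtype=float)
    if np.any(dna_vaf < 0) or np.any(dna_vaf > 100):
        raise ValueError("dna_vaf must be in [0, 100]")
    if np.any(rna_total_depth < 0):
        raise ValueError("rna_total_depth must be >= 0")
    out = dna_vaf * rna_total_depth / 100.0
    return float(out) if out.ndim == 0 else out


def multiple_testing(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class WAIModelSpec:
    """Configuration of one WAI analysis.

    ``grouping`` decides what a WAI is computed *for* (a gene, or a mutation
    type); ``covariates`` are the categorical adjustments entering the
    regression alongside the expected depth.  The gene-wise primary-cohort
    model adjusts for mutation type; the mutation-type-wise model adjusts
    for gene; the pooled multi-cohort model adds a cohort term.
    """

    grouping: str = "per_gene"
    covariates: tuple = ("mutation_type",)
    min_group_size: int = 5
    bootstrap_reps: int = 2000
    seed: int = 0
    variant_class: str = "SNV"

    def __post_init__(self) -> None:
        if self.grouping not in ("per_gene", "per_mutation_type"):
            raise ValueError(f"unknown grouping {self.grouping!r}")
        group_col = "gene" if self.grouping == "per_gene" else "mutation_type"
        if group_col in self.covariates:
            raise ValueError(f"grouping variable {group_col!r} cannot also be a covariate")
        if self.bootstrap_reps < 100:
            raise ValueError("bootstrap_reps must be >= 100")
        if self.variant_class not in ("SNV", "INDEL"):
            raise ValueError(f"unknown variant_class {self.variant_class!r}")

    @property
    def group_column(self) -> str:
        return "gene" if self.grouping == "per_gene" else "mutation_type"


@dataclass
class WAIResult:
    """Per-group WAI estimate with bootstrap inference."""

    group: str
    variant_class: str
    wai: float
    ci_low: float
    ci_high: float
    p_value: float
    p_adjusted: float
    n_variants: int
    direction: str = "none"
    degenerate: bool = False
    ci_contains_estimate: bool = True
    n_boot_effective: int = 0


class WAIRegressor(BaseEstimator, RegressorMixin):
    """OLS slope-on-expected-depth estimator with case-resampling bootstrap.

    Parameters
    ----------
    covariates : tuple of str
        Column names in X treated as categorical covariates (dummy-coded
        with a reference level; constant columns are dropped).
    bootstrap_reps : int
        Number of bootstrap resamples B.
    random_state : int
        Seed for the resampling RNG; results are reproducible bit-for-bit
        given (random_state, bootstrap_reps).
    null_value : float
        Slope value under H0 (1 = no allelic imbalance).
    ci_level : float
        Percentile confidence level.

    Attributes
    ----------
    wai_ : float
        Slope on the expected-depth regressor (the WAI). NaN when the group
        is degenerate (fewer than two distinct expected depths).
    ci_low_, ci_high_ : float
        Percentile bootstrap bounds.
    p_value_ : float
        Two-sided bootstrap p for H0: slope == null_value, with +1 smoothing.
    coef_, feature_names_, n_, n_boot_effective_, degenerate_,
    ci_contains_estimate_ : fit diagnostics.
    """

    _MAX_REDRAW_ROUNDS = 10

    def __init__(
        self,
        covariates: tuple = (),
        bootstrap_reps: int = 2000,
        random_state: int = 0,
        null_value: float = 1.0,
        ci_level: float = 0.95,
    ):
        self.covariates = covariates
        self.bootstrap_reps = bootstrap_reps
        self.random_state = random_state
        self.null_value = null_value
        self.ci_level = ci_level

    # -- design -------------------------------------------------------------
    def _build_design(self, X: pd.DataFrame):
        if "expected" not in X.columns:
            raise ValueError("X must contain an 'expected' column")
        n = len(X)
        cols = [np.ones(n), X["expected"].to_numpy(dtype=float)]
        names = ["intercept", "expected"]
        for cov in self.covariates:
            if cov not in X.columns:
                continue
            values = X[cov].astype(str)
            levels = sorted(values.unique())
            # first level is the reference; single-level covariates drop out
            for level in levels[1:]:
                cols.append((values == level).to_numpy(dtype=float))
                names.append(f"{cov}[{level}]")
        return np.column_stack(cols), names

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=float)
        design, names = self._build_design(X)
        n = design.shape[0]
        if n != y.shape[0]:
            raise ValueError("X and y length mismatch")
        self.feature_names_ = names
        self.n_ = n
        expected = design[:, 1]
        if np.unique(expected).size < 2:
            # degenerate: the slope is not identifiable
            self.degenerate_ = True
            self.wai_ = float("nan")
            self.coef_ = np.full(design.shape[1], np.nan)
            self.ci_low_ = self.ci_high_ = float("nan")
            self.p_value_ = float("nan")
            self.n_boot_effective_ = 0
            self.ci_contains_estimate_ = False
            return self

        self.degenerate_ = False
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        self.coef_ = coef
        self.wai_ = float(coef[1])

        slopes = self._bootstrap_slopes(design, y)
        self.n_boot_effective_ = int(slopes.size)
        alpha = 1.0 - self.ci_level
        self.ci_low_ = float(np.quantile(slopes, alpha / 2))
        self.ci_high_ = float(np.quantile(slopes, 1 - alpha / 2))
        b = slopes.size
        lower = (np.sum(slopes <= self.null_value) + 1) / (b + 1)
        upper = (np.sum(slopes >= self.null_value) + 1) / (b + 1)
        self.p_value_ = float(min(1.0, 2.0 * min(lower, upper)))
        self.ci_contains_estimate_ = bool(self.ci_low_ <= self.wai_ <= self.ci_high_)
        return self

    def _bootstrap_slopes(self, design: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Case-resampling bootstrap of the slope, vectorised.

        Resampling n rows with replacement is encoded as multinomial row
        weights c, so each replicate's normal equations are
        (X' diag(c) X) beta = X' diag(c) y — solved in one batched call.
        Singular replicates (a dummy level absent from the resample) are
        redrawn, with a bounded number of rounds; a shortfall is reported
        via ``n_boot_effective_``.
        """
        rng = np.random.default_rng(self.random_state)
        n, p = design.shape
        need = self.bootstrap_reps
        slopes = np.empty(0)
        probs = np.full(n, 1.0 / n)
        for _ in range(self._MAX_REDRAW_ROUNDS):
            if slopes.size >= need:
                break
            m = need - slopes.size
            counts = rng.multinomial(n, probs, size=m).astype(float)
            xtx = np.einsum("bn,np,nq->bpq", counts, design, design, optimize=True)
            xty = np.einsum("bn,np,n->bp", counts, design, y, optimize=True)
            sign, _ = np.linalg.slogdet(xtx)
            ok = sign > 0
            if not np.any(ok):
                continue
            beta = np.linalg.solve(xtx[ok], xty[ok][..., None])[..., 0]
            new = beta[:, 1]
            new = new[np.isfinite(new)]
            slopes = np.concatenate([slopes, new])
        return slopes[:need] if slopes.size >= need else slopes

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "coef_")
        design, names = self._build_design(X)
        if names != self.feature_names_:
            raise ValueError("X levels differ from the fitted design")
        return design @ self.coef_


# -- group-wise drivers ------------------------------------------------------

def select_model_variants(df: pd.DataFrame, spec: WAIModelSpec) -> pd.DataFrame:
    """Extract the modelling set for one analysis.

    Keeps recurrent mutations of the requested variant class that are
    DNA-heterozygous (AB), transcribed or DNA-exclusive, admissible as a
    genotype conversion and (when a filter report is present) passing all
    filters; then drops groups below ``min_group_size``.  Each row is one
    independent mutation pair.  Requires the annotation columns added by
    :func:`waikit.classify.classify_frame`.
    """
    required = {"transcription_class", "dna_genotype", "admissible"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"observations must be classified first; missing {sorted(missing)}")
    mask = (
        df["is_recurrent_mutation"].astype(bool)
        & (df["variant_class"] == spec.variant_class)
        & df["transcription_class"].isin(MODELLABLE_CLASSES)
        & (df["dna_genotype"] == Genotype.AB.value)
        & df["admissible"].astype(bool)
    )
    if "filter_passed" in df.columns:
        mask &= df["filter_passed"].astype(bool)
    sub = df[mask].copy()
    if sub.empty:
        return sub
    counts = sub.groupby(spec.group_column)[spec.group_column].transform("size")
    return sub[counts >= spec.min_group_size].copy()


def _fit_groups(
    sub: pd.DataFrame,
    spec: WAIModelSpec,
    expected: np.ndarray,
    observed: np.ndarray,
) -> list[WAIResult]:
    results: list[WAIResult] = []
    if sub.empty:
        return results
    sub = sub.assign(_expected=expected, _observed=observed)
    seeds = np.random.SeedSequence(spec.seed)
    groups = sorted(sub[spec.group_column].unique())
    children = seeds.spawn(len(groups))
    for group, child in zip(groups, children):
        g = sub[sub[spec.group_column] == group]
        X = pd.DataFrame({"expected": g["_expected"].to_numpy()})
        for cov in spec.covariates:
            if cov in g.columns:
                X[cov] = g[cov].to_numpy()
        est = WAIRegressor(
            covariates=spec.covariates,
            bootstrap_reps=spec.bootstrap_reps,
            random_state=child,
        ).fit(X, g["_observed"].to_numpy())
        results.append(
            WAIResult(
                group=str(group),
                variant_class=spec.variant_class,
                wai=est.wai_,
                ci_low=est.ci_low_,
                ci_high=est.ci_high_,
                p_value=est.p_value_,
                p_adjusted=float("nan"),
                n_variants=est.n_,
                degenerate=est.degenerate_,
                ci_contains_estimate=est.ci_contains_estimate_,
                n_boot_effective=est.n_boot_effective_,
            )
        )
    _adjust_and_tag(results)
    return results


def _adjust_and_tag(results: list[WAIResult]) -> None:
    """BH-adjust across the groups of one analysis and set direction tags."""
    testable = [r for r in results if not r.degenerate]
    if testable:
        adjusted = multiple_testing([r.p_value for r in testable])
        for r, padj in zip(testable, adjusted):
            r.p_adjusted = float(padj)
    for r in results:
        if r.degenerate or not np.isfinite(r.p_adjusted) or r.p_adjusted >= 0.05:
            r.direction = "none"
        else:
            r.direction = "mutant_abundant" if r.wai > 1 else "wildtype_abundant"


def fit_wai(df: pd.DataFrame, spec: WAIModelSpec) -> list[WAIResult]:
    """Group-wise WAI for recurrent mutations.

    ``df`` is the modelling set from :func:`select_model_variants` (it is
    re-selected here if the annotation columns indicate raw input).  Returns
    one :class:`WAIResult` per group with BH adjustment across the groups of
    this analysis.
    """
    sub = select_model_variants(df, spec)
    expected = expected_rna_variant_depth(
        sub["dna_vaf"].to_numpy(), sub["rna_total_depth"].to_numpy()
    ) if not sub.empty else np.array([])
    observed = sub["rna_alt_depth"].to_numpy(dtype=float) if not sub.empty else np.array([])
    return _fit_groups(sub, spec, expected, observed)


def fit_wai_snps(df: pd.DataFrame, spec: WAIModelSpec | None = None) -> list[WAIResult]:
    """WAI of common SNPs on the minor-allele scale (negative control).

    Identical machinery to :func:`fit_wai`, with the DNA minor-allele
    frequency replacing the mutation VAF: when the DNA VAF exceeds 50% the
    minor allele is REF, so the expected depth uses 100 - VAF and the
    observed count is ``rna_total_depth - rna_alt_depth``.  Only
    DNA-heterozygous SNPs in genes with at least ``min_group_size`` SNPs are
    analysed; callers should supply observations drawn from samples without
    recurrent mutations in the target genes.
    """
    spec = spec or WAIModelSpec(grouping="per_gene", covariates=())
    required = {"transcription_class", "dna_genotype", "admissible"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"observations must be classified first; missing {sorted(missing)}")
    mask = (
        df["is_snp"].astype(bool)
        & (df["variant_class"] == spec.variant_class)
        & df["transcription_class"].isin(MODELLABLE_CLASSES)
        & (df["dna_genotype"] == Genotype.AB.value)
        & df["admissible"].astype(bool)
    )
    if "filter_passed" in df.columns:
        mask &= df["filter_passed"].astype(bool)
    sub = df[mask].copy()
    if sub.empty:
        return []
    counts = sub.groupby(spec.group_column)[spec.group_column].transform("size")
    sub = sub[counts >= spec.min_group_size].copy()
    if sub.empty:
        return []
    dna_vaf = sub["dna_vaf"].to_numpy(dtype=float)
    rna_total = sub["rna_total_depth"].to_numpy(dtype=float)
    rna_alt = sub["rna_alt_depth"].to_numpy(dtype=float)
    alt_is_minor = dna_vaf <= 50.0
    maf = np.where(alt_is_minor, dna_vaf, 100.0 - dna_vaf)
    expected = expected_rna_variant_depth(maf, rna_total)
    observed = np.where(alt_is_minor, rna_alt, rna_total - rna_alt)
    return _fit_groups(sub, spec, expected, observed)


def results_to_frame(results: list[WAIResult]) -> pd.DataFrame:
    """Tabular view of a list of WAI results."""
    cols = [
        "group", "variant_class", "n_variants", "wai", "ci_low", "ci_high",
        "p_value", "p_adjusted", "direction", "degenerate",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results], columns=cols)
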