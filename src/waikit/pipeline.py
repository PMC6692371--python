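"""End-to-end orchestration: classify -> filter -> cutoff -> WAI -> SNP control."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import classify_frame, conversion_matrix, depth_binned_summary, select_depth_cutoff
from .filters import BlacklistSet, FilterConfig, apply_filters
from .io import read_variant_table, write_results, write_variant_table
from .model import WAIModelSpec, fit_wai, fit_wai_snps
from .regions import RegionSet


@dataclass
class RunConfig:
    """One reproducible pipeline run."""

    variants: str
    output_dir: str
    regions: str | None = None
    rna_editing_bed: str | None = None
    repeat_bed: str | None = None
    error_prone_bed: str | None = None
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    bootstrap_reps: int = 2000
    min_group_size: int = 5
    seed: int = 0
    cutoff_tolerance: float = 0.02
    cutoff_window: int = 5

    def validate(self) -> None:
        for name in ("variants", "regions", "rna_editing_bed", "repeat_bed", "error_prone_bed"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name} file not found: {path}")

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def _load_blacklists(config: RunConfig) -> BlacklistSet:
    def load(path):
        return RegionSet.from_bed(path) if path else RegionSet()

    return BlacklistSet(
        rna_editing_sites=load(config.rna_editing_bed),
        repeat_regions=load(config.repeat_bed),
        error_prone_regions=load(config.error_prone_bed),
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the output tables plus a run manifest.

    Outputs (TSV unless noted): classified variant table, depth-bin summary,
    genotype-conversion matrix, filter report, selected cutoff (in the
    manifest), WAI tables per gene and per mutation type for SNVs and INDELs
    (pooled across cohorts with a cohort covariate when the input has more
    than one cohort), the SNP control table, and ``manifest.json``.
    Deterministic given (inputs, seed).
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "waikit_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }

    table = read_variant_table(config.variants)
    df = table.frame
    manifest["stages"]["input"] = {
        "n_rows": int(len(df)),
        "n_rejected": int(len(table.rejected)),
    }

    df = classify_frame(df)
    class_counts = df["transcription_class"].value_counts().to_dict()
    manifest["stages"]["classify"] = {k: int(v) for k, v in class_counts.items()}
    write_variant_table(df, out / "classified.tsv")
    conversion_matrix(df).to_csv(out / "genotype_conversions.tsv", sep="\t")

    summary = depth_binned_summary(df)
    summary.to_csv(out / "depth_bins.tsv", sep="\t", index=False)
    cutoff = select_depth_cutoff(summary, config.cutoff_tolerance, config.cutoff_window)
    manifest["stages"]["cutoff"] = {
        "selected_depth": cutoff.depth,
        "default_used": cutoff.default_used,
    }

    df = apply_filters(df, config.filter_config, _load_blacklists(config))
    manifest["stages"]["filter"] = {
        "n_passed": int(df["filter_passed"].sum()),
        "n_failed": int((~df["filter_passed"]).sum()),
    }
    df[["chrom", "pos", "ref", "alt", "sample_id", "filter_passed", "failed_filters"]].to_csv(
        out / "filter_report.tsv", sep="\t", index=False
    )

    multi_cohort = df["cohort"].nunique() > 1
    analyses = {}
    for vclass in ("SNV", "INDEL"):
        covariates = ("mutation_type", "cohort") if multi_cohort else ("mutation_type",)
        analyses[f"wai_per_gene_{vclass}"] = WAIModelSpec(
            grouping="per_gene", covariates=covariates, variant_class=vclass,
            bootstrap_reps=config.bootstrap_reps, seed=config.seed,
            min_group_size=config.min_group_size,
        )
        gene_cov = ("gene", "cohort") if multi_cohort else ("gene",)
        analyses[f"wai_per_mutation_type_{vclass}"] = WAIModelSpec(
            grouping="per_mutation_type", covariates=gene_cov, variant_class=vclass,
            bootstrap_reps=config.bootstrap_reps, seed=config.seed,
            min_group_size=config.min_group_size,
        )
    for name, spec in analyses.items():
        results = fit_wai(df, spec)
        write_results(results, out / f"{name}.tsv")
        manifest["stages"][name] = {"n_groups": len(results)}

    snp_spec = WAIModelSpec(
        grouping="per_gene", covariates=(), variant_class="SNV",
        bootstrap_reps=config.bootstrap_reps, seed=config.seed,
        min_group_size=config.min_group_size,
    )
    snp_results = fit_wai_snps(df, snp_spec)
    write_results(snp_results, out / "wai_snp_control.tsv")
    manifest["stages"]["wai_snp_control"] = {"n_groups": len(snp_results)}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
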