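"""Readers and writers: paired VCFs, the consolidated TSV dialect, and the
WAI report.

The consolidated table is a tab-separated file whose header carries the
columns in :data:`waikit.records.TABLE_COLUMNS` (VAF columns are recomputed
on read, never trusted).  Paired VCF input merges a DNA-assay and an
RNA-assay VCF by normalised variant identity inside a region set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import (
    MUTATION_TYPES,
    TABLE_COLUMNS,
    VariantKey,
    add_vaf_columns,
    normalize_key,
)
from .regions import RegionSet

logger = logging.getLogger(__name__)


@dataclass
class TableReadResult:
    """A validated variant table plus the rows rejected with reasons."""

    frame: pd.DataFrame
    rejected: pd.DataFrame


def read_variant_table(path, as_records: bool = False):
    """Read the consolidated TSV dialect with row-wise validation.

    Rows violating record invariants (depth inconsistency, bad position,
    identical alleles, conflicting recurrent/SNP flags) are rejected
    individually with a reason; a missing mandatory column is an input
    error.  VAFs are recomputed from depths.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table {path} is missing mandatory columns: {missing}")
    df = df[[c for c in df.columns if c in TABLE_COLUMNS or c not in ("dna_vaf", "rna_vaf")]]

    reasons = np.full(len(df), "", dtype=object)

    def flag(mask, reason):
        fresh = (reasons == "") & mask.to_numpy()
        reasons[fresh] = reason

    flag(df["dna_alt_depth"] > df["dna_total_depth"], "depth inconsistency")
    flag(df["rna_alt_depth"] > df["rna_total_depth"], "depth inconsistency")
    flag(
        (df["dna_alt_depth"] < 0) | (df["rna_alt_depth"] < 0)
        | (df["dna_total_depth"] < 0) | (df["rna_total_depth"] < 0),
        "negative depth",
    )
    flag(df["pos"] < 1, "invalid position")
    flag(df["ref"].astype(str) == df["alt"].astype(str), "identical alleles")
    flag(~df["ref"].astype(str).str.fullmatch("[ACGT]+"), "invalid ref allele")
    flag(~df["alt"].astype(str).str.fullmatch("[ACGT]+"), "invalid alt allele")
    flag(~df["mutation_type"].isin(MUTATION_TYPES), "unknown mutation type")
    flag(
        df["is_recurrent_mutation"].astype(bool) & df["is_snp"].astype(bool),
        "both recurrent-mutation and SNP",
    )

    bad = reasons != ""
    rejected = df[bad].copy()
    rejected["reason"] = reasons[bad]
    if bad.any():
        logger.warning("rejected %d/%d rows from %s", int(bad.sum()), len(df), path)
    frame = add_vaf_columns(df[~bad].reset_index(drop=True))
    if as_records:
        from .records import frame_to_observations

        return frame_to_observations(frame)
    return TableReadResult(frame=frame, rejected=rejected)


def write_variant_table(df: pd.DataFrame, path) -> None:
    """Write the consolidated TSV dialect (round-trips with the reader)."""
    df.to_csv(path, sep="\t", index=False)


# -- paired VCF input ---------------------------------------------------------

def _record_depths(variant, skip_log, source):
    """Extract (total_depth, alt_depth) from a single-sample VCF record."""
    total = alt = None
    try:
        fmt_dp = variant.format("DP")
        if fmt_dp is not None:
            total = int(fmt_dp[0][0])
    except KeyError:
        pass
    if total is None:
        total = int(variant.INFO.get("DP", -1))
        if total < 0:
            total = None
    try:
        fmt_ad = variant.format("AD")
        if fmt_ad is not None:
            ad = fmt_ad[0]
            alt = int(ad[1])
            if total is None:
                total = int(ad[0]) + int(ad[1])
    except KeyError:
        pass
    if alt is None:
        try:
            fmt_ao = variant.format("AO")
            if fmt_ao is not None:
                alt = int(fmt_ao[0][0])
        except KeyError:
            pass
    if total is None or alt is None:
        skip_log.append((source, variant.CHROM, variant.POS, "missing depth fields"))
        return None
    return total, alt


def _read_vcf_calls(path, regions: RegionSet, skip_log, source):
    from cyvcf2 import VCF

    calls = {}
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # unreadable file is an input error naming the file
        raise OSError(f"cannot read VCF file {path}: {exc}") from exc
    for variant in vcf:
        if not variant.ALT:
            continue
        depths = _record_depths(variant, skip_log, source)
        if depths is None:
            continue
        key = normalize_key(
            VariantKey(variant.CHROM, variant.POS, variant.REF.upper(), variant.ALT[0].upper())
        )
        if not regions.contains_variant(key.chrom, key.pos):
            continue
        calls[key] = depths
    return calls


def _default_annotation(key: VariantKey, regions: RegionSet):
    labels = regions.labels_at_variant(key.chrom, key.pos)
    gene = labels[0] if labels else "NA"
    if key.variant_class == "SNV":
        mtype = "nonsynonymous_SNV"
    else:
        delta = abs(len(key.alt) - len(key.ref))
        kind = "insertion" if len(key.alt) > len(key.ref) else (
            "deletion" if len(key.alt) < len(key.ref) else "substitution"
        )
        frame = "nonframeshift" if delta % 3 == 0 and delta > 0 else "frameshift"
        if kind == "substitution":
            frame = "nonframeshift" if delta % 3 == 0 else "frameshift"
        mtype = f"{frame}_{kind}"
    return gene, mtype


def read_paired_vcf(
    dna_vcf,
    rna_vcf,
    regions: RegionSet,
    annotations: dict | None = None,
    sample_id: str = "S0",
    cohort: str = "NA",
):
    """Merge one sample's DNA and RNA VCFs into the consolidated table.

    Records are matched by parsimony-normalised (chrom, pos, ref, alt)
    inside ``regions``; a variant present in only one assay yields a row
    with the other assay's depths set to 0 (locus coverage is not
    recoverable from a sites-only VCF).  ``annotations`` optionally maps
    ``(chrom, pos, ref, alt)`` to ``(gene, mutation_type)``; unannotated
    variants get the enclosing region's label as gene and an
    allele-length-based mutation type.  Returns ``(frame, skip_log)`` where
    the skip log lists records lacking depth fields.
    """
    skip_log: list = []
    dna_calls = _read_vcf_calls(dna_vcf, regions, skip_log, "DNA")
    rna_calls = _read_vcf_calls(rna_vcf, regions, skip_log, "RNA")
    rows = []
    for key in sorted(set(dna_calls) | set(rna_calls)):
        dna_total, dna_alt = dna_calls.get(key, (0, 0))
        rna_total, rna_alt = rna_calls.get(key, (0, 0))
        ann = (annotations or {}).get((key.chrom, key.pos, key.ref, key.alt))
        gene, mtype = ann if ann else _default_annotation(key, regions)
        rows.append(
            {
                "chrom": key.chrom,
                "pos": key.pos,
                "ref": key.ref,
                "alt": key.alt,
                "sample_id": sample_id,
                "cohort": cohort,
                "gene": gene,
                "variant_class": key.variant_class,
                "mutation_type": mtype,
                "dna_total_depth": dna_total,
                "dna_alt_depth": dna_alt,
                "rna_total_depth": rna_total,
                "rna_alt_depth": rna_alt,
                "is_recurrent_mutation": False,
                "is_snp": False,
            }
        )
    frame = add_vaf_columns(pd.DataFrame(rows, columns=list(TABLE_COLUMNS)))
    for entry in skip_log:
        logger.warning("skipped %s record %s:%s (%s)", *entry)
    return frame, skip_log


# -- report output ------------------------------------------------------------

REPORT_COLUMNS = (
    "group", "variant_class", "n_variants", "wai", "ci_low", "ci_high",
    "p_value", "p_adjusted", "significant", "abundance", "direction",
)


def write_results(results, path) -> None:
    """Write a WAI report: one row per group.

    ``abundance`` tags the sign of the estimate (mutant-abundant when
    WAI > 1, wild-type-abundant otherwise); ``significant`` and
    ``direction`` reflect the BH-adjusted p at the 0.05 level.
    """
    rows = []
    for r in results:
        abundance = "mutant-abundant" if r.wai > 1 else "wild-type-abundant"
        if not np.isfinite(r.wai):
            abundance = "NA"
        rows.append(
            {
                "group": r.group,
                "variant_class": r.variant_class,
                "n_variants": r.n_variants,
                "wai": r.wai,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "significant": bool(np.isfinite(r.p_adjusted) and r.p_adjusted < 0.05),
                "abundance": abundance,
                "direction": r.direction,
            }
        )
    pd.DataFrame(rows, columns=list(REPORT_COLUMNS)).to_csv(path, sep="\t", index=False)
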