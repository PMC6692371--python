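"""Bias filters and blacklists for paired DNA/RNA variant calls.

Read-depth floors alone do not remove the bulk of RNA-exclusive false
positives; sequencing-bias tests (strand bias, read-position bias, mapping
and base-quality shifts between alt- and ref-supporting reads) and region
blacklists (RNA-editing sites, repeats, error-prone regions) do most of the
work.  Every filter is evaluated for every variant — no short-circuiting —
so the report lists all reasons a variant failed.

Bias evidence beyond depths is optional in the consolidated table dialect;
a bias test whose evidence columns are absent auto-passes.  Thresholds are
configuration, not constants: a variant fails a bias filter when its
p-value falls strictly below the configured threshold (default 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy import stats

from .regions import RegionSet

#: Names of the individual filters, in report order.
FILTER_NAMES = (
    "dna_depth",
    "rna_depth",
    "alt_reads",
    "strand_bias",
    "position_bias",
    "mapping_quality",
    "base_quality",
    "rna_editing",
    "repeat",
    "error_prone",
)

#: Optional evidence columns consumed by the bias tests.
EVIDENCE_COLUMNS = (
    "alt_fwd", "alt_rev", "ref_fwd", "ref_rev",          # strand counts
    "alt_read_positions", "read_length",                  # within-read offsets
    "alt_map_quals", "ref_map_quals",                     # per-read MAPQ
    "alt_base_quals", "ref_base_quals",                   # per-read base quality
)


@dataclass
class FilterConfig:
    """Thresholds of the bias-filter stack.

    Depth floors default to the study's assay floors (30x DNA, 10x RNA).
    Each ``*_p`` field is the significance level below which the
    corresponding bias test fails a variant.
    """

    min_dna_depth: int = 30
    min_rna_depth: int = 10
    max_strand_bias_p: float = 0.01
    min_mapping_quality_delta_p: float = 0.01
    min_base_quality_delta_p: float = 0.01
    min_position_bias_p: float = 0.01
    min_alt_reads: int = 2

    def __post_init__(self) -> None:
        for f in fields(self):
            val = getattr(self, f.name)
            if f.name.endswith("_p"):
                if not 0 < val <= 1:
                    raise ValueError(f"{f.name} must be in (0, 1], got {val}")
            elif val < 0:
                raise ValueError(f"{f.name} must be >= 0, got {val}")

    @classmethod
    def permissive(cls) -> "FilterConfig":
        """A configuration under which every variant passes."""
        return cls(
            min_dna_depth=0, min_rna_depth=0,
            max_strand_bias_p=1e-300, min_mapping_quality_delta_p=1e-300,
            min_base_quality_delta_p=1e-300, min_position_bias_p=1e-300,
            min_alt_reads=0,
        )


@dataclass
class BlacklistSet:
    """Region blacklists; a variant anchored inside any region fails."""

    rna_editing_sites: RegionSet = field(default_factory=RegionSet)
    repeat_regions: RegionSet = field(default_factory=RegionSet)
    error_prone_regions: RegionSet = field(default_factory=RegionSet)


@dataclass
class FilterOutcome:
    obs: object
    passed: bool
    failed_filters: list

    def __post_init__(self) -> None:
        if self.passed != (len(self.failed_filters) == 0):
            raise ValueError("passed flag inconsistent with failed_filters")


def strand_bias_test(alt_fwd: int, alt_rev: int, ref_fwd: int, ref_rev: int) -> float:
    """Two-sided Fisher's exact p on the ref/alt x fwd/rev 2x2 table.

    An all-zero table is untestable and returns 1 by convention.
    """
    table = np.array([[alt_fwd, alt_rev], [ref_fwd, ref_rev]])
    if np.any(table < 0):
        raise ValueError("strand counts must be non-negative")
    if table.sum() == 0:
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def positional_bias_test(alt_read_positions, read_length: int, min_n: int = 2) -> float:
    """Test alt-supporting read offsets against a uniform null over the read.

    One-sample Kolmogorov-Smirnov test of the offsets against
    Uniform[0, read_length).  Fewer than ``min_n`` offsets are untestable
    and return p = 1.
    """
    positions = np.asarray(list(alt_read_positions), dtype=float)
    if positions.size and (positions.min() < 0 or positions.max() >= read_length):
        raise ValueError("offsets must lie in [0, read_length)")
    if positions.size < min_n:
        return 1.0
    return float(stats.kstest(positions, stats.uniform(loc=0, scale=read_length).cdf).pvalue)


def quality_bias_test(alt_quals, ref_quals, min_n: int = 2) -> float:
    """Mann-Whitney rank test of alt- vs ref-supporting read qualities.

    Auto-passes (p = 1) when either side has fewer than ``min_n`` reads —
    the table dialect does not always carry per-read qualities.
    """
    alt = np.asarray(list(alt_quals), dtype=float)
    ref = np.asarray(list(ref_quals), dtype=float)
    if alt.size < min_n or ref.size < min_n:
        return 1.0
    if np.ptp(np.concatenate([alt, ref])) == 0:
        return 1.0
    return float(stats.mannwhitneyu(alt, ref, alternative="two-sided").pvalue)


def _parse_num_list(value) -> list[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return []
    if isinstance(value, str):
        value = value.strip()
        return [float(tok) for tok in value.split(",") if tok != ""] if value else []
    return [float(v) for v in value]


def apply_filters(
    df: pd.DataFrame,
    config: FilterConfig | None = None,
    blacklists: BlacklistSet | None = None,
) -> pd.DataFrame:
    """Evaluate every filter for every observation.

    Returns a copy of ``df`` with ``filter_passed`` (bool) and
    ``failed_filters`` (semicolon-joined names, empty string when passed).
    Row order is preserved and all filters are always evaluated.
    """
    config = config or FilterConfig()
    blacklists = blacklists or BlacklistSet()
    df = df.copy()
    n = len(df)
    failed: list[list[str]] = [[] for _ in range(n)]

    dna_total = df["dna_total_depth"].to_numpy()
    rna_total = df["rna_total_depth"].to_numpy()
    dna_alt = df["dna_alt_depth"].to_numpy()
    rna_alt = df["rna_alt_depth"].to_numpy()

    fail_masks = {
        "dna_depth": dna_total < config.min_dna_depth,
        "rna_depth": rna_total < config.min_rna_depth,
        # alt-read floor: the variant must be supported by enough alternate
        # reads in at least one assay
        "alt_reads": np.maximum(dna_alt, rna_alt) < config.min_alt_reads,
    }

    has_strand = all(c in df.columns for c in ("alt_fwd", "alt_rev", "ref_fwd", "ref_rev"))
    strand_fail = np.zeros(n, dtype=bool)
    if has_strand:
        for i, row in enumerate(df.itertuples(index=False)):
            if any(pd.isna(getattr(row, c)) for c in ("alt_fwd", "alt_rev", "ref_fwd", "ref_rev")):
                continue
            p = strand_bias_test(
                int(row.alt_fwd), int(row.alt_rev), int(row.ref_fwd), int(row.ref_rev)
            )
            strand_fail[i] = p < config.max_strand_bias_p
    fail_masks["strand_bias"] = strand_fail

    pos_fail = np.zeros(n, dtype=bool)
    if "alt_read_positions" in df.columns and "read_length" in df.columns:
        for i, row in enumerate(df.itertuples(index=False)):
            offsets = _parse_num_list(row.alt_read_positions)
            if not offsets or pd.isna(row.read_length):
                continue
            p = positional_bias_test(offsets, int(row.read_length))
            pos_fail[i] = p < config.min_position_bias_p
    fail_masks["position_bias"] = pos_fail

    for name, alt_col, ref_col, thresh in (
        ("mapping_quality", "alt_map_quals", "ref_map_quals", config.min_mapping_quality_delta_p),
        ("base_quality", "alt_base_quals", "ref_base_quals", config.min_base_quality_delta_p),
    ):
        mask = np.zeros(n, dtype=bool)
        if alt_col in df.columns and ref_col in df.columns:
            for i, row in enumerate(df.itertuples(index=False)):
                p = quality_bias_test(
                    _parse_num_list(getattr(row, alt_col)),
                    _parse_num_list(getattr(row, ref_col)),
                )
                mask[i] = p < thresh
        fail_masks[name] = mask

    chroms = df["chrom"].astype(str).to_numpy()
    positions = df["pos"].to_numpy()
    for name, regions in (
        ("rna_editing", blacklists.rna_editing_sites),
        ("repeat", blacklists.repeat_regions),
        ("error_prone", blacklists.error_prone_regions),
    ):
        mask = np.zeros(n, dtype=bool)
        if len(regions):
            mask = np.array(
                [regions.contains_variant(c, int(p)) for c, p in zip(chroms, positions)]
            )
        fail_masks[name] = mask

    for name in FILTER_NAMES:
        for i in np.flatnonzero(fail_masks[name]):
            failed[i].append(name)

    df["filter_passed"] = [len(f) == 0 for f in failed]
    df["failed_filters"] = [";".join(f) for f in failed]
    return df


def filter_outcomes(df: pd.DataFrame) -> list[FilterOutcome]:
    """Record-level view of an :func:`apply_filters` result."""
    out = []
    for row in df.itertuples(index=False):
        names = [f for f in row.failed_filters.split(";") if f]
        out.append(FilterOutcome(obs=row, passed=row.filter_passed, failed_filters=names))
    return out
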