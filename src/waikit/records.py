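"""Core variant records and the consolidated paired-variant table dialect.

The atomic unit of the pipeline is one variant observed in one sample with
read-depth evidence from both a DNA assay and an RNA assay.  In memory the
canonical container is a :class:`pandas.DataFrame` using the column dialect
in :data:`TABLE_COLUMNS`; :class:`VariantObservation` is the record-level
view used by the VCF reader and for validation.

Variant allele frequencies (VAFs) are always *recomputed* from depths and
expressed in percent (0-100); they are never trusted from an input file.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

_ALLELE_RE = re.compile(r"^[ACGT]+$")

VARIANT_CLASSES = ("SNV", "INDEL")

#: Mutation-type vocabulary (ANNOVAR-style exonic consequence labels).
MUTATION_TYPES = (
    "synonymous_SNV",
    "nonsynonymous_SNV",
    "stopgain_SNV",
    "frameshift_insertion",
    "frameshift_deletion",
    "frameshift_substitution",
    "nonframeshift_insertion",
    "nonframeshift_deletion",
    "nonframeshift_substitution",
)

SNV_MUTATION_TYPES = tuple(t for t in MUTATION_TYPES if t.endswith("_SNV"))
INDEL_MUTATION_TYPES = tuple(t for t in MUTATION_TYPES if not t.endswith("_SNV"))

#: Mandatory columns of the consolidated TSV dialect.
TABLE_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "sample_id",
    "cohort",
    "gene",
    "variant_class",
    "mutation_type",
    "dna_total_depth",
    "dna_alt_depth",
    "rna_total_depth",
    "rna_alt_depth",
    "is_recurrent_mutation",
    "is_snp",
)

#: Derived columns appended by :func:`add_vaf_columns`.
VAF_COLUMNS = ("dna_vaf", "rna_vaf")


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a variant: chromosome, 1-based position, REF and ALT allele.

    Used to match DNA-assay and RNA-assay calls of the same event.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ, got {self.ref!r}")
        for name in ("ref", "alt"):
            allele = getattr(self, name)
            if not _ALLELE_RE.match(allele):
                raise ValueError(f"{name} must be an uppercase A/C/G/T string, got {allele!r}")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt) or len(self.ref) > 1

    @property
    def variant_class(self) -> str:
        return "INDEL" if self.is_indel else "SNV"


def normalize_key(key: VariantKey) -> VariantKey:
    """Parsimony-normalise an allele pair without a reference genome.

    Shared leading bases are trimmed first (the position advances by the
    number removed), then shared trailing bases, keeping at least one base
    on each side.  Trimming the prefix first unifies differently anchored
    spellings of the same INDEL (e.g. ATG>AG at p and TG>G at p+1).  DNA and
    RNA INDEL calls from different callers are matched only after this
    normalisation; matching is exact, never fuzzy.
    """
    ref, alt, pos = key.ref, key.alt, key.pos
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    if (ref, alt, pos) == (key.ref, key.alt, key.pos):
        return key
    return VariantKey(key.chrom, pos, ref, alt)


@dataclass
class VariantObservation:
    """One variant in one sample with paired DNA and RNA depth evidence."""

    key: VariantKey
    sample_id: str
    cohort: str
    gene: str
    variant_class: str
    mutation_type: str
    dna_total_depth: int
    dna_alt_depth: int
    rna_total_depth: int
    rna_alt_depth: int
    is_recurrent_mutation: bool = False
    is_snp: bool = False

    def __post_init__(self) -> None:
        for assay in ("dna", "rna"):
            total = getattr(self, f"{assay}_total_depth")
            alt = getattr(self, f"{assay}_alt_depth")
            if not (0 <= alt <= total):
                raise ValueError(
                    f"{assay} depth inconsistency: alt={alt}, total={total}"
                )
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant_class {self.variant_class!r}")
        if self.is_recurrent_mutation and self.is_snp:
            raise ValueError("a variant cannot be both a recurrent mutation and a SNP")

    @property
    def dna_vaf(self) -> float:
        """DNA variant allele frequency in percent; 0 when depth is 0."""
        if self.dna_total_depth == 0:
            return 0.0
        return 100.0 * self.dna_alt_depth / self.dna_total_depth

    @property
    def rna_vaf(self) -> float:
        """RNA VAF in percent; NaN when the locus has no RNA coverage."""
        if self.rna_total_depth == 0:
            return math.nan
        return 100.0 * self.rna_alt_depth / self.rna_total_depth


def observations_to_frame(observations) -> pd.DataFrame:
    """Build the canonical table from a sequence of observations."""
    rows = []
    for obs in observations:
        rows.append(
            {
                "chrom": obs.key.chrom,
                "pos": obs.key.pos,
                "ref": obs.key.ref,
                "alt": obs.key.alt,
                "sample_id": obs.sample_id,
                "cohort": obs.cohort,
                "gene": obs.gene,
                "variant_class": obs.variant_class,
                "mutation_type": obs.mutation_type,
                "dna_total_depth": obs.dna_total_depth,
                "dna_alt_depth": obs.dna_alt_depth,
                "rna_total_depth": obs.rna_total_depth,
                "rna_alt_depth": obs.rna_alt_depth,
                "is_recurrent_mutation": obs.is_recurrent_mutation,
                "is_snp": obs.is_snp,
            }
        )
    df = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    return add_vaf_columns(df)


def frame_to_observations(df: pd.DataFrame) -> list[VariantObservation]:
    """Convert table rows to validated records (raises on invariant breach)."""
    out = []
    for row in df.itertuples(index=False):
        out.append(
            VariantObservation(
                key=VariantKey(str(row.chrom), int(row.pos), row.ref, row.alt),
                sample_id=str(row.sample_id),
                cohort=str(row.cohort),
                gene=str(row.gene),
                variant_class=row.variant_class,
                mutation_type=row.mutation_type,
                dna_total_depth=int(row.dna_total_depth),
                dna_alt_depth=int(row.dna_alt_depth),
                rna_total_depth=int(row.rna_total_depth),
                rna_alt_depth=int(row.rna_alt_depth),
                is_recurrent_mutation=bool(row.is_recurrent_mutation),
                is_snp=bool(row.is_snp),
            )
        )
    return out


def add_vaf_columns(df: pd.DataFrame) -> pd.DataFrame:
    """(Re)compute dna_vaf / rna_vaf in percent from the depth columns.

    rna_vaf is NaN where the RNA assay has zero coverage at the locus.
    """
    df = df.copy()
    dna_total = df["dna_total_depth"].to_numpy(dtype=float)
    rna_total = df["rna_total_depth"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        dna_vaf = np.where(
            dna_total > 0, 100.0 * df["dna_alt_depth"].to_numpy(dtype=float) / dna_total, 0.0
        )
        rna_vaf = np.where(
            rna_total > 0,
            100.0 * df["rna_alt_depth"].to_numpy(dtype=float) / rna_total,
            np.nan,
        )
    df["dna_vaf"] = dna_vaf
    df["rna_vaf"] = rna_vaf
    return df
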