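"""Transcription classes, VAF-band genotypes, genotype conversions and the
RNA read-depth cutoff calibration.

A paired DNA/RNA variant falls into one of four transcription classes:

* ``TRANSCRIBED`` — alternate reads present in both assays, with the RNA
  locus covered at or above the detection floor (default 10x);
* ``DNA_EXCLUSIVE`` — alternate reads in DNA only, with enough RNA coverage
  (default 4x) to assert absence — evidence of non-transcription;
* ``RNA_EXCLUSIVE`` — alternate reads in RNA only, with enough DNA coverage
  (default 30x) to assert the site is not a germline/somatic DNA variant —
  predominantly sequencing error, occasionally RNA editing;
* ``UNEVALUABLE`` — neither assertion is supported by the depths.

Genotypes are assigned from the VAF in percent using a heterozygous band:
VAF in [2, 75] is AB, above 75 is BB, below 2 is AA.  Comparing the DNA and
the RNA genotype of a variant yields a *genotype conversion* (e.g. AB→BB:
mutant-allele-abundant in RNA).  Conversions are inadmissible for BB→AA
changes and for variants with DNA VAF below 2%.

The depth-cutoff calibration bins transcribed variants by RNA read depth and
finds the smallest depth at which the AB vs BB proportion difference has
stabilised; in the study that convergence motivated the 10x RNA floor.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

HET_LOW = 2.0
HET_HIGH = 75.0

DEFAULT_CUTOFF = 10
DEFAULT_TOLERANCE = 0.02
DEFAULT_WINDOW = 5


class TranscriptionClass(str, enum.Enum):
    TRANSCRIBED = "TRANSCRIBED"
    DNA_EXCLUSIVE = "DNA_EXCLUSIVE"
    RNA_EXCLUSIVE = "RNA_EXCLUSIVE"
    UNEVALUABLE = "UNEVALUABLE"


class Genotype(str, enum.Enum):
    AA = "AA"
    AB = "AB"
    BB = "BB"


@dataclass(frozen=True)
class GenotypeConversion:
    dna_genotype: Genotype
    rna_genotype: Genotype
    admissible: bool


@dataclass(frozen=True)
class CutoffResult:
    depth: int
    default_used: bool


def assign_genotype(vaf: float, het_low: float = HET_LOW, het_high: float = HET_HIGH) -> Genotype:
    """Genotype from a VAF in percent: AA below the band, AB inside, BB above.

    Both band edges are inclusive for AB.
    """
    if not 0 <= vaf <= 100:
        raise ValueError(f"vaf must be in [0, 100], got {vaf}")
    if vaf < het_low:
        return Genotype.AA
    if vaf <= het_high:
        return Genotype.AB
    return Genotype.BB


def assign_genotype_array(vaf, het_low: float = HET_LOW, het_high: float = HET_HIGH) -> np.ndarray:
    """Vectorised :func:`assign_genotype`; NaN VAFs yield the empty string."""
    vaf = np.asarray(vaf, dtype=float)
    finite = ~np.isnan(vaf)
    if np.any((vaf[finite] < 0) | (vaf[finite] > 100)):
        raise ValueError("vaf values must be in [0, 100]")
    out = np.full(vaf.shape, "", dtype=object)
    out[finite & (vaf < het_low)] = Genotype.AA.value
    out[finite & (vaf >= het_low) & (vaf <= het_high)] = Genotype.AB.value
    out[finite & (vaf > het_high)] = Genotype.BB.value
    return out


def classify_transcription(
    obs,
    min_rna_depth_absent: int = 4,
    min_dna_depth_absent: int = 30,
    min_rna_depth_detect: int = 10,
) -> TranscriptionClass:
    """Transcription class of one observation (see module docstring).

    "Detected in RNA" requires at least one alternate read *and* RNA
    coverage at or above ``min_rna_depth_detect``; the lower
    ``min_rna_depth_absent`` floor applies only when asserting absence.
    """
    return TranscriptionClass(
        _classify_arrays(
            np.asarray([obs.dna_alt_depth]),
            np.asarray([obs.dna_total_depth]),
            np.asarray([obs.rna_alt_depth]),
            np.asarray([obs.rna_total_depth]),
            min_rna_depth_absent,
            min_dna_depth_absent,
            min_rna_depth_detect,
        )[0]
    )


def _classify_arrays(
    dna_alt, dna_total, rna_alt, rna_total,
    min_rna_depth_absent, min_dna_depth_absent, min_rna_depth_detect,
) -> np.ndarray:
    if np.any(dna_alt < 0) or np.any(rna_alt < 0):
        raise ValueError("depths must be non-negative")
    out = np.full(dna_alt.shape, TranscriptionClass.UNEVALUABLE.value, dtype=object)
    transcribed = (dna_alt >= 1) & (rna_alt >= 1) & (rna_total >= min_rna_depth_detect)
    dna_excl = (dna_alt >= 1) & (rna_alt == 0) & (rna_total >= min_rna_depth_absent)
    rna_excl = (rna_alt >= 1) & (dna_alt == 0) & (dna_total >= min_dna_depth_absent)
    out[rna_excl] = TranscriptionClass.RNA_EXCLUSIVE.value
    out[dna_excl] = TranscriptionClass.DNA_EXCLUSIVE.value
    out[transcribed] = TranscriptionClass.TRANSCRIBED.value
    return out


def classify_frame(
    df: pd.DataFrame,
    min_rna_depth_absent: int = 4,
    min_dna_depth_absent: int = 30,
    min_rna_depth_detect: int = 10,
    het_low: float = HET_LOW,
    het_high: float = HET_HIGH,
) -> pd.DataFrame:
    """Annotate a variant table with transcription class, genotypes and
    conversion admissibility.

    Adds columns ``transcription_class``, ``dna_genotype``, ``rna_genotype``
    (empty string where no RNA evidence is interpretable) and ``admissible``.
    """
    from .records import add_vaf_columns

    if "dna_vaf" not in df.columns or "rna_vaf" not in df.columns:
        df = add_vaf_columns(df)
    else:
        df = df.copy()
    tclass = _classify_arrays(
        df["dna_alt_depth"].to_numpy(),
        df["dna_total_depth"].to_numpy(),
        df["rna_alt_depth"].to_numpy(),
        df["rna_total_depth"].to_numpy(),
        min_rna_depth_absent,
        min_dna_depth_absent,
        min_rna_depth_detect,
    )
    df["transcription_class"] = tclass
    df["dna_genotype"] = assign_genotype_array(df["dna_vaf"], het_low, het_high)
    rna_geno = assign_genotype_array(df["rna_vaf"].fillna(0.0), het_low, het_high)
    # RNA genotype is only meaningful where the variant is evaluable in RNA:
    # DNA-exclusive loci are AA by definition; RNA-exclusive/unevaluable get "".
    rna_geno = np.where(
        tclass == TranscriptionClass.DNA_EXCLUSIVE.value, Genotype.AA.value, rna_geno
    )
    rna_geno = np.where(
        np.isin(
            tclass,
            [TranscriptionClass.RNA_EXCLUSIVE.value, TranscriptionClass.UNEVALUABLE.value],
        ),
        "",
        rna_geno,
    )
    df["rna_genotype"] = rna_geno
    dna_vaf = df["dna_vaf"].to_numpy(dtype=float)
    inadmissible = (dna_vaf < het_low) | (
        (df["dna_genotype"].to_numpy() == Genotype.BB.value)
        & (df["rna_genotype"].to_numpy() == Genotype.AA.value)
    )
    df["admissible"] = ~inadmissible
    return df


def genotype_conversion(
    obs_or_row,
    het_low: float = HET_LOW,
    het_high: float = HET_HIGH,
    min_rna_depth_absent: int = 4,
    min_dna_depth_absent: int = 30,
    min_rna_depth_detect: int = 10,
) -> GenotypeConversion:
    """DNA→RNA genotype conversion for a TRANSCRIBED or DNA_EXCLUSIVE variant.

    DNA-exclusive variants have RNA genotype AA by definition.  The
    conversion is inadmissible for BB→AA changes and whenever the DNA VAF is
    below the heterozygous band's lower edge.
    """
    tclass = classify_transcription(
        obs_or_row, min_rna_depth_absent, min_dna_depth_absent, min_rna_depth_detect
    )
    if tclass not in (TranscriptionClass.TRANSCRIBED, TranscriptionClass.DNA_EXCLUSIVE):
        raise ValueError(f"genotype conversion undefined for {tclass.value} variants")
    dna_vaf = obs_or_row.dna_vaf
    dna_geno = assign_genotype(dna_vaf, het_low, het_high)
    if tclass is TranscriptionClass.DNA_EXCLUSIVE:
        rna_geno = Genotype.AA
    else:
        rna_geno = assign_genotype(obs_or_row.rna_vaf, het_low, het_high)
    admissible = not (
        dna_vaf < het_low or (dna_geno is Genotype.BB and rna_geno is Genotype.AA)
    )
    return GenotypeConversion(dna_geno, rna_geno, admissible)


def conversion_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """3x3 DNA-genotype x RNA-genotype count matrix over convertible variants.

    Only TRANSCRIBED and DNA_EXCLUSIVE rows contribute (the classes for
    which an RNA genotype is defined).
    """
    levels = [g.value for g in Genotype]
    sub = df[
        df["transcription_class"].isin(
            [TranscriptionClass.TRANSCRIBED.value, TranscriptionClass.DNA_EXCLUSIVE.value]
        )
    ]
    mat = pd.crosstab(sub["dna_genotype"], sub["rna_genotype"])
    return mat.reindex(index=levels, columns=levels, fill_value=0).astype(int)


def depth_binned_summary(df: pd.DataFrame, max_depth: int = 50) -> pd.DataFrame:
    """Per-RNA-read-depth accounting of transcription classes and, among
    transcribed variants, the AB vs BB genotype proportions.

    Bins are unit-depth up to ``max_depth``; deeper loci share one overflow
    bin labelled ``max_depth + 1``.  ``props_defined`` is False (and both
    proportions 0) in bins with no transcribed variants.
    """
    if df.empty:
        return pd.DataFrame(
            columns=[
                "depth_bin", "n_transcribed", "n_dna_exclusive", "n_rna_exclusive",
                "prop_AB", "prop_BB", "props_defined",
            ]
        )
    depth = df["rna_total_depth"].to_numpy(dtype=int)
    bin_id = np.minimum(depth, max_depth + 1)
    tclass = df["transcription_class"].to_numpy()
    rna_geno = df["rna_genotype"].to_numpy()
    rows = []
    for b in np.unique(bin_id):
        sel = bin_id == b
        is_tr = sel & (tclass == TranscriptionClass.TRANSCRIBED.value)
        n_tr = int(is_tr.sum())
        n_ab = int((is_tr & (rna_geno == Genotype.AB.value)).sum())
        n_bb = int((is_tr & (rna_geno == Genotype.BB.value)).sum())
        rows.append(
            {
                "depth_bin": int(b),
                "n_transcribed": n_tr,
                "n_dna_exclusive": int((sel & (tclass == TranscriptionClass.DNA_EXCLUSIVE.value)).sum()),
                "n_rna_exclusive": int((sel & (tclass == TranscriptionClass.RNA_EXCLUSIVE.value)).sum()),
                "prop_AB": n_ab / n_tr if n_tr else 0.0,
                "prop_BB": n_bb / n_tr if n_tr else 0.0,
                "props_defined": n_tr > 0,
            }
        )
    return pd.DataFrame(rows).sort_values("depth_bin", ignore_index=True)


def select_depth_cutoff(
    summaries: pd.DataFrame,
    tolerance: float = DEFAULT_TOLERANCE,
    window: int = DEFAULT_WINDOW,
    default: int = DEFAULT_CUTOFF,
) -> CutoffResult:
    """Smallest RNA read depth at which |prop_AB - prop_BB| has stabilised.

    A depth d is *stable* when, over the ``window`` consecutive evaluable
    bins starting at d, every bin's proportion difference deviates from the
    first bin's by at most ``tolerance``.  When fewer than ``window``
    evaluable bins exist, or no depth is stable, the adopted default (10x)
    is returned with ``default_used=True``.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    if window < 1:
        raise ValueError("window must be >= 1")
    usable = summaries[summaries["props_defined"]].sort_values("depth_bin")
    diffs = np.abs(usable["prop_AB"].to_numpy() - usable["prop_BB"].to_numpy())
    depths = usable["depth_bin"].to_numpy()
    n = len(diffs)
    if n < window:
        return CutoffResult(default, True)
    for i in range(n - window + 1):
        win = diffs[i : i + window]
        if np.all(np.abs(win - win[0]) <= tolerance + 1e-12):
            return CutoffResult(int(depths[i]), False)
    return CutoffResult(default, True)
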