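import numpy as np
import pandas as pd
import pytest

import waikit


@pytest.fixture(scope="session")
def fixture_suite():
    return waikit.make_fixture_suite()


@pytest.fixture()
def small_table() -> pd.DataFrame:
    """Six hand-written observations covering all transcription classes."""
    rows = [
        # chrom pos ref alt dna_tot dna_alt rna_tot rna_alt  -> expected class
        ("chr1", 100, "A", "G", 200, 20, 40, 5),    # TRANSCRIBED
        ("chr1", 200, "C", "T", 300, 30, 12, 0),    # DNA_EXCLUSIVE
        ("chr1", 300, "G", "A", 50, 0, 25, 6),      # RNA_EXCLUSIVE
        ("chr1", 400, "T", "C", 20, 0, 3, 1),       # UNEVALUABLE (both floors fail)
        ("chr1", 500, "A", "T", 400, 360, 80, 75),  # TRANSCRIBED, BB in both
        ("chr1", 600, "AG", "A", 250, 100, 60, 30), # TRANSCRIBED INDEL
    ]
    df = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "dna_total_depth", "dna_alt_depth",
                 "rna_total_depth", "rna_alt_depth"],
    )
    df["sample_id"] = "S0"
    df["cohort"] = "AMLCG"
    df["gene"] = "GENE1"
    df["variant_class"] = np.where(df["ref"].str.len() == df["alt"].str.len(), "SNV", "INDEL")
    df["mutation_type"] = np.where(
        df["variant_class"] == "SNV", "nonsynonymous_SNV", "frameshift_deletion"
    )
    df["is_recurrent_mutation"] = True
    df["is_snp"] = False
    return waikit.add_vaf_columns(df[list(waikit.TABLE_COLUMNS)])


def brute_force_bh(p):
    """Independent step-up BH reference."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        idx = order[rank_from_top]
        candidate = p[idx] * m / (rank_from_top + 1)
        running_min = min(running_min, candidate)
        adjusted[idx] = min(1.0, running_min)
    return adjusted


def brute_force_fisher(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    from scipy.stats import hypergeom

    n = a + b + c + d
    if n == 0:
        return 1.0
    row1, col1 = a + b, a + c
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, row1, col1)
    p_obs = hypergeom.pmf(a, n, row1, col1)
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
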