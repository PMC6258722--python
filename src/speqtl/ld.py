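"""Pairwise linkage disequilibrium (composite genotypic r²) among SNPs.

r² is computed as the squared Pearson correlation of 0/1/2 dosage vectors —
the unphased composite estimator, which tracks haplotype r² closely under
Hardy-Weinberg equilibrium and needs no phasing.  Strength labels follow the
conventional thresholds: robust when r² > 0.8, weak when r² <= 0.6,
intermediate between.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

LD_PAIR_COLS = ["snp_a", "snp_b", "r_squared", "n_samples", "strength"]


def pairwise_r2(dosages_a, dosages_b) -> tuple[float | None, int]:
    """Composite r² between two dosage vectors, missing dropped pairwise.

    Returns (r², n_complete_pairs); r² is None when either SNP is
    monomorphic after filtering (correlation undefined — reported as
    missing, never as 0).
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must be paired")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    n = a.size
    if n < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return None, n
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r), n


def strength_label(r2: float | None) -> str:
    if r2 is None:
        return "missing"
    if r2 > 0.8:
        return "robust"
    if r2 <= 0.6:
        return "weak"
    return "intermediate"


def ld_matrix(genotypes, snp_ids=None) -> tuple[pd.DataFrame, float]:
    """All C(n,2) unordered SNP pairs with r², n, and a strength label, plus
    the maximum off-diagonal r² (NaN if every pair is missing).
    """
    dosage = genotypes.dosages if hasattr(genotypes, "dosages") else genotypes
    ids = list(snp_ids) if snp_ids is not None else list(dosage.index)
    if len(ids) < 2:
        raise ValueError("need at least two SNPs for an LD matrix")
    missing = [s for s in ids if s not in dosage.index]
    if missing:
        raise KeyError(f"SNPs absent from genotype panel: {missing[:5]}")
    rows = []
    for sa, sb in combinations(ids, 2):
        r2, n = pairwise_r2(dosage.loc[sa].to_numpy(), dosage.loc[sb].to_numpy())
        rows.append((sa, sb, np.nan if r2 is None else r2, n, strength_label(r2)))
    table = pd.DataFrame(rows, columns=LD_PAIR_COLS)
    max_r2 = float(table["r_squared"].max()) if table["r_squared"].notna().any() else float("nan")
    return table, max_r2
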