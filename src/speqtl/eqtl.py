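"""Genotype-expression association testing over spatial SNP-gene pairs.

Each spatial pair is tested in every tissue by ordinary least squares of
expression on additive allele dosage (0/1/2) with an intercept; the slope's
two-sided t-test (n-2 df) gives the nominal p.  Benjamini-Hochberg step-up
controls the FDR over all executed tests jointly (or per tissue, by config),
and each association is classified cis (same chromosome, |SNP - TSS| below
the 1 Mb window) or trans (at or beyond the window, or inter-chromosomal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CIS_WINDOW_BP = 1_000_000

RESULT_COLS = [
    "snp_id", "gene_id", "tissue_id", "beta", "se", "p_nominal", "q_value",
    "n_samples", "distance_bp", "category", "significant",
]


@dataclass
class AssociationResult:
    beta: float
    se: float
    p_nominal: float
    n: int
    skipped: str | None = None  # reason code when the test was not run


def test_association(dosages, expression, min_samples: int = 70) -> AssociationResult:
    """OLS slope of expression on dosage; missing dosages dropped pairwise.

    Skips (with a reason code) when fewer than min_samples complete pairs
    remain or the SNP is monomorphic after the missing-drop.
    """
    x = np.asarray(dosages, dtype=float)
    y = np.asarray(expression, dtype=float)
    if x.shape != y.shape:
        raise ValueError("dosage and expression vectors must be paired")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < min_samples:
        return AssociationResult(np.nan, np.nan, np.nan, n, skipped="insufficient_samples")
    if np.ptp(x) == 0:
        return AssociationResult(np.nan, np.nan, np.nan, n, skipped="monomorphic")
    fit = stats.linregress(x, y)
    return AssociationResult(float(fit.slope), float(fit.stderr), float(fit.pvalue), n)


def bh_fdr(p_values, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_i = min over {j : p_j >= p_i} of m * p_j / rank_j, capped at 1, where
    rank is the ascending rank among the observed p-values and m defaults to
    their number (pass a larger m to correct within a wider family).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    m = n if m is None else int(m)
    if m < n:
        raise ValueError("family size m cannot be smaller than the number of tests")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def classify_cis_trans(snp_chrom: str, snp_pos: int, gene_chrom: str, tss: int,
                       cis_window: int = CIS_WINDOW_BP) -> tuple[str, float]:
    """Classify an association and return (category, signed SNP-TSS distance).

    cis requires the same chromosome and |SNP - TSS| strictly below the
    window (a distance of exactly the window is trans); inter-chromosomal
    pairs are trans with distance NaN (reported as "interchromosomal").
    """
    if snp_chrom != gene_chrom:
        return "trans", float("nan")
    dist = int(snp_pos) - int(tss)
    return ("cis" if abs(dist) < cis_window else "trans"), float(dist)


def run_eqtl_stage(pairs: pd.DataFrame, genotypes, expression_panels, genes: pd.DataFrame,
                   snps: pd.DataFrame, q_threshold: float = 0.05, min_samples: int = 70,
                   fdr_scope: str = "joint", cis_window: int = CIS_WINDOW_BP,
                   distance_anchor: str = "tss") -> tuple[pd.DataFrame, dict]:
    """Test every spatial pair in every tissue and adjust for multiple testing.

    Returns the per-test result table (one row per executed SNP x gene x
    tissue test) and a summary with significant counts under both countings
    (triples, and unique SNP-gene pairs), split cis/trans, plus skip tallies.
    """
    if fdr_scope not in ("joint", "per-tissue"):
        raise ValueError("fdr_scope must be 'joint' or 'per-tissue'")
    if distance_anchor not in ("tss", "nearest-gene-edge"):
        raise ValueError("distance_anchor must be 'tss' or 'nearest-gene-edge'")
    gene_index = genes.set_index("gene_id")
    snp_index = snps.set_index("snp_id")
    dosage = genotypes.dosages if hasattr(genotypes, "dosages") else genotypes

    rows, skipped = [], {"insufficient_samples": 0, "monomorphic": 0, "unresolved": 0}
    for panel in expression_panels:
        expr = panel.values
        samples = list(expr.columns)
        for pair in pairs.itertuples(index=False):
            if pair.snp_id not in snp_index.index or pair.gene_id not in gene_index.index:
                skipped["unresolved"] += 1
                continue
            if pair.snp_id not in dosage.index or pair.gene_id not in expr.index:
                skipped["unresolved"] += 1
                continue
            s = snp_index.loc[pair.snp_id]
            g = gene_index.loc[pair.gene_id]
            res = test_association(
                dosage.loc[pair.snp_id, samples].to_numpy(dtype=float),
                expr.loc[pair.gene_id].to_numpy(dtype=float),
                min_samples=min_samples,
            )
            if res.skipped:
                skipped[res.skipped] += 1
                continue
            if distance_anchor == "tss":
                anchor = int(g.tss)
            else:
                anchor = int(np.clip(int(s.pos), g.start, g.end - 1))
            category, dist = classify_cis_trans(s.chrom, int(s.pos), g.chrom, anchor, cis_window)
            rows.append((pair.snp_id, pair.gene_id, panel.tissue_id, res.beta, res.se,
                         res.p_nominal, np.nan, res.n, dist, category, False))

    results = pd.DataFrame(rows, columns=RESULT_COLS)
    if results.empty:
        warnings.warn("no testable SNP-gene-tissue combinations")
        return results, _summarize(results, skipped)

    if fdr_scope == "joint":
        results["q_value"] = bh_fdr(results["p_nominal"].to_numpy())
    else:
        for tissue, idx in results.groupby("tissue_id").groups.items():
            results.loc[idx, "q_value"] = bh_fdr(results.loc[idx, "p_nominal"].to_numpy())
    results["significant"] = results["q_value"] < q_threshold
    results = results.sort_values(["snp_id", "gene_id", "tissue_id"]).reset_index(drop=True)
    return results, _summarize(results, skipped)


def _summarize(results: pd.DataFrame, skipped: dict) -> dict:
    sig = results[results["significant"]] if not results.empty else results
    summary = {
        "n_tests": int(len(results)),
        "n_significant_triples": int(len(sig)),
        "skipped": skipped,
    }
    for counting in ("triples", "pairs"):
        if sig.empty:
            cis = trans = 0
        elif counting == "triples":
            cis = int((sig["category"] == "cis").sum())
            trans = int((sig["category"] == "trans").sum())
        else:
            upair = sig.drop_duplicates(["snp_id", "gene_id"])
            cis = int((upair["category"] == "cis").sum())
            trans = int((upair["category"] == "trans").sum())
        summary[f"n_cis_{counting}"] = cis
        summary[f"n_trans_{counting}"] = trans
    summary["n_egenes"] = int(sig["gene_id"].nunique()) if not sig.empty else 0
    summary["n_esnps"] = int(sig["snp_id"].nunique()) if not sig.empty else 0
    return summary


def links_table(results: pd.DataFrame, snps: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Significant SNP-gene links with coordinates, for circos-style plotting."""
    sig = results[results["significant"]].drop_duplicates(["snp_id", "gene_id"])
    snp_index = snps.set_index("snp_id")
    gene_index = genes.set_index("gene_id")
    rows = []
    for r in sig.itertuples(index=False):
        s = snp_index.loc[r.snp_id]
        g = gene_index.loc[r.gene_id]
        rows.append((s.chrom, int(s.pos), g.chrom, int(g.tss), r.category))
    return pd.DataFrame(rows, columns=["chrom_a", "pos_a", "chrom_b", "pos_b", "category"])
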