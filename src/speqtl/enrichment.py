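"""Supporting statistics for the spatial-eQTL pipeline.

Monte Carlo SNP-set enrichment against random control sets, Fisher exact
cis:trans contrast for regulatory SNPs, per-tissue HLA contribution
summaries, and hypergeometric gene-set enrichment with BH FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import stage_rng
from .eqtl import bh_fdr


@dataclass
class MonteCarloResult:
    """Observed connection count for the catalog set vs the null distribution
    over random, equally sized control sets.

    p_value is the one-sample two-sided t-test of the null counts against the
    observed count; p_permutation = (#{null >= observed} + 1) / (n_sets + 1)
    is the rank-based alternative, robust to non-normal null counts.
    """

    observed_connections: int
    null_connections: np.ndarray
    n_sets: int
    t_statistic: float
    p_value: float
    p_permutation: float


def monte_carlo_enrichment(catalog_snps, snp_universe, pipeline_fn,
                           n_sets: int = 100, seed: int = 0) -> MonteCarloResult:
    """Compare the catalog's significant SNP-gene connection count against
    equally sized random SNP sets drawn (without replacement, per set) from
    the control universe.

    pipeline_fn(snp_ids) must run the spatial and eQTL stages for the given
    SNP set and return its significant connection count.  Each of the n_sets
    null runs uses a deterministic sub-seed derived from ``seed``.
    """
    catalog = list(catalog_snps)
    universe = list(snp_universe)
    if n_sets < 2:
        raise ValueError("n_sets must be >= 2 (null variance undefined otherwise)")
    if len(universe) < len(catalog):
        raise ValueError("control universe smaller than the catalog set")
    observed = int(pipeline_fn(catalog))
    null = np.empty(n_sets, dtype=float)
    for k in range(n_sets):
        rng = stage_rng(seed, "monte_carlo", extra=k)
        idx = rng.choice(len(universe), size=len(catalog), replace=False)
        null[k] = pipeline_fn([universe[i] for i in idx])
    if np.std(null, ddof=1) == 0:
        # degenerate null: all control sets identical; t undefined
        t_stat = np.inf if observed != null[0] else 0.0
        p_t = 0.0 if observed != null[0] else 1.0
    else:
        t_stat, p_t = stats.ttest_1samp(null, popmean=observed)
    p_perm = (np.sum(null >= observed) + 1) / (n_sets + 1)
    return MonteCarloResult(observed, null, n_sets, float(t_stat), float(p_t), float(p_perm))


def fisher_cis_trans(reg_cis: int, reg_trans: int, nonreg_cis: int,
                     nonreg_trans: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on the 2x2 table

        [[reg_cis, reg_trans], [nonreg_cis, nonreg_trans]]

    using the summed-probabilities rule (all tables with point probability
    <= the observed one), the convention of scipy and R.  Returns the sample
    odds ratio and the two-sided p.  A zero margin makes the table
    uninformative: p = 1 with a warning.
    """
    table = np.array([[reg_cis, reg_trans], [nonreg_cis, nonreg_trans]])
    if np.any(table < 0) or table.dtype.kind not in "iu" and np.any(table != table.astype(int)):
        raise ValueError("counts must be non-negative integers")
    if 0 in table.sum(axis=0) or 0 in table.sum(axis=1):
        warnings.warn("zero margin in 2x2 table: Fisher test uninformative, p = 1")
        return float("nan"), 1.0
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def regulatory_partition(snps: pd.DataFrame, score_threshold: float = 0.05
                         ) -> tuple[set[str], set[str], set[str]]:
    """Split SNPs into predicted-regulatory (score strictly < threshold) and
    non-regulatory; SNPs with a missing score go to non-regulatory and are
    also returned separately so callers can see the unflagged subset.
    """
    score = pd.to_numeric(snps["regulatory_score"], errors="coerce")
    missing = snps.loc[score.isna(), "snp_id"]
    reg = snps.loc[score < score_threshold, "snp_id"]
    nonreg = snps.loc[~snps["snp_id"].isin(reg), "snp_id"]
    return set(reg), set(nonreg), set(missing)


def tissue_contribution(eqtl_results: pd.DataFrame, snps: pd.DataFrame,
                        significant_only: bool = True
                        ) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Per-tissue HLA contribution: HLA-class eQTLs as a percentage of that
    tissue's significant eQTLs, with tissues grouped high / mid / low by the
    strict +/-1 SD rule over all contributing tissues.

    Tissues with zero significant eQTLs are excluded from the mean/SD (and
    the returned table) with a warning.
    """
    res = eqtl_results[eqtl_results["significant"]] if significant_only else eqtl_results
    locus = snps.set_index("snp_id")["locus_class"]
    if res.empty:
        warnings.warn("no significant eQTLs: tissue summary is empty")
        return pd.DataFrame(columns=["tissue_id", "n_eqtls_total", "n_eqtls_hla",
                                     "contribution_pct", "group"]), (float("nan"), float("nan"))
    rows = []
    for tissue, grp in res.groupby("tissue_id"):
        total = len(grp)
        hla = int((locus.reindex(grp["snp_id"]).to_numpy() == "HLA").sum())
        rows.append((tissue, total, hla, 100.0 * hla / total))
    table = pd.DataFrame(rows, columns=["tissue_id", "n_eqtls_total", "n_eqtls_hla",
                                        "contribution_pct"])
    mean = float(table["contribution_pct"].mean())
    sd = float(table["contribution_pct"].std(ddof=1)) if len(table) > 1 else 0.0
    table["group"] = "mid"
    table.loc[table["contribution_pct"] > mean + sd, "group"] = "high"
    table.loc[table["contribution_pct"] < mean - sd, "group"] = "low"
    return table.sort_values("tissue_id").reset_index(drop=True), (mean, sd)


def geneset_enrichment(query_genes, annotation_sets: dict[str, set[str]],
                       background_size: int) -> pd.DataFrame:
    """One-sided hypergeometric (upper tail) enrichment of the query gene list
    in each annotation set, BH-corrected across sets, sorted by q.

    background_size is the size of the annotation universe (e.g. all human
    protein-coding genes); the query must be drawn from that universe.
    """
    query = set(query_genes)
    if not annotation_sets:
        return pd.DataFrame(columns=["set_id", "k_overlap", "K_set_size", "n_query",
                                     "N_background", "p_hyper", "q_value"])
    if background_size < len(query):
        raise ValueError("background smaller than the query list")
    rows = []
    for set_id, members in annotation_sets.items():
        if not members:
            raise ValueError(f"annotation set {set_id!r} is empty")
        k = len(query & members)
        K = len(members)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, background_size, K, len(query)))
        rows.append((set_id, k, K, len(query), background_size,
                     min(max(p, 5e-324), 1.0)))
    table = pd.DataFrame(rows, columns=["set_id", "k_overlap", "K_set_size", "n_query",
                                        "N_background", "p_hyper"])
    table["q_value"] = bh_fdr(table["p_hyper"].to_numpy())
    return table.sort_values(["q_value", "p_hyper", "set_id"]).reset_index(drop=True)
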