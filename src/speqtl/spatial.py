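"""Spatial SNP-gene pairing from restriction-fragment Hi-C contact lists.

A SNP and a gene form a spatial pair when the fragment carrying the SNP is
recorded in contact with any fragment overlapping the gene body, in at least
one cell line.  Cell lines are pooled (union of contacts) with provenance
retained.  A SNP sitting on a fragment that itself overlaps a gene is a
trivially co-localized pair and is flagged ``same_fragment`` so callers can
keep or drop it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SPATIAL_PAIR_COLS = ["snp_id", "gene_id", "supporting_contacts", "n_cell_lines", "same_fragment"]


@dataclass
class SpatialPair:
    snp_id: str
    gene_id: str
    supporting_contacts: int
    cell_lines: frozenset = field(default_factory=frozenset)
    snp_fragment_id: str = ""
    gene_fragment_ids: frozenset = field(default_factory=frozenset)
    same_fragment: bool = False


def assign_to_fragments(points: pd.DataFrame, fragments: pd.DataFrame) -> pd.Series:
    """Map each (chrom, pos) point to the half-open fragment containing it.

    Fragments must tile each chromosome (sorted, disjoint).  Points outside
    every fragment get NaN, so unmapped records are explicit rather than
    silently dropped.
    """
    result = pd.Series(np.nan, index=points.index, dtype=object)
    for chrom, group in points.groupby("chrom"):
        frs = fragments[fragments["chrom"] == chrom].sort_values("start")
        if frs.empty:
            continue
        starts = frs["start"].to_numpy()
        ends = frs["end"].to_numpy()
        ids = frs["fragment_id"].to_numpy()
        pos = group["pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        vals = np.where(ok, ids[np.clip(idx, 0, len(ids) - 1)], None)
        result.loc[group.index] = vals
    return result


def assign_snps_to_fragments(snps: pd.DataFrame, fragments: pd.DataFrame) -> dict[str, str]:
    """snp_id -> fragment_id for SNPs that fall inside a fragment."""
    assigned = assign_to_fragments(snps[["chrom", "pos"]], fragments)
    return {
        snp_id: frag
        for snp_id, frag in zip(snps["snp_id"], assigned)
        if frag is not None and not (isinstance(frag, float) and np.isnan(frag))
    }


def gene_fragment_map(genes: pd.DataFrame, fragments: pd.DataFrame) -> dict[str, set[str]]:
    """gene_id -> set of fragment_ids overlapping the gene body (half-open)."""
    out: dict[str, set[str]] = {}
    for chrom, group in genes.groupby("chrom"):
        frs = fragments[fragments["chrom"] == chrom].sort_values("start")
        if frs.empty:
            for gid in group["gene_id"]:
                out[gid] = set()
            continue
        starts = frs["start"].to_numpy()
        ends = frs["end"].to_numpy()
        ids = frs["fragment_id"].to_numpy()
        for _, g in group.iterrows():
            # overlap [g.start, g.end): first fragment ending after g.start,
            # last fragment starting before g.end
            lo = int(np.searchsorted(ends, g.start, side="right"))
            hi = int(np.searchsorted(starts, g.end, side="left"))
            out[g.gene_id] = set(ids[lo:hi])
    return out


def find_spatial_pairs(snps: pd.DataFrame, genes: pd.DataFrame, fragments: pd.DataFrame,
                       contacts: pd.DataFrame, min_count: int = 1,
                       include_same_fragment: bool = True) -> pd.DataFrame:
    """Join SNPs to genes through the fragment contact list.

    A pair is emitted when (snp_fragment, any gene fragment) appears with a
    per-record count >= min_count in at least one cell line; supporting
    contacts are summed over all qualifying records and cell lines.  Pairs
    where the SNP's own fragment overlaps the gene are emitted with
    ``same_fragment=True`` (implicit self co-localization, one supporting
    contact floor) when include_same_fragment is set.
    """
    if contacts.empty:
        warnings.warn("empty contact table: no spatial pairs can be found")
    snp_frag = assign_snps_to_fragments(snps, fragments)
    gfrags = gene_fragment_map(genes, fragments)

    frag_to_snps: dict[str, list[str]] = {}
    for snp_id, frag in snp_frag.items():
        frag_to_snps.setdefault(frag, []).append(snp_id)
    frag_to_genes: dict[str, list[str]] = {}
    for gene_id, frs in gfrags.items():
        for frag in frs:
            frag_to_genes.setdefault(frag, []).append(gene_id)

    support: dict[tuple[str, str], dict] = {}

    def _add(snp_id, gene_id, count, line):
        rec = support.setdefault(
            (snp_id, gene_id), {"count": 0, "lines": set(), "gene_frags": set()}
        )
        rec["count"] += int(count)
        rec["lines"].add(line)

    cols = zip(contacts["frag_id_a"], contacts["frag_id_b"],
               contacts["count"], contacts["cell_line"])
    for fid_a, fid_b, count, line in cols:
        if int(count) < min_count:
            continue
        orientations = ((fid_a, fid_b),) if fid_a == fid_b else ((fid_a, fid_b), (fid_b, fid_a))
        for fa, fb in orientations:
            for snp_id in frag_to_snps.get(fa, ()):
                for gene_id in frag_to_genes.get(fb, ()):
                    _add(snp_id, gene_id, count, line)

    if include_same_fragment:
        for snp_id, frag in snp_frag.items():
            for gene_id in frag_to_genes.get(frag, ()):
                rec = support.setdefault(
                    (snp_id, gene_id), {"count": 0, "lines": set(), "gene_frags": set()}
                )
                rec["same_fragment"] = True

    rows = []
    for (snp_id, gene_id), rec in support.items():
        same = rec.get("same_fragment", False)
        count = rec["count"]
        if count == 0 and same:
            count = 1  # implicit self co-localization
        if count < max(min_count, 1) and not same:
            continue
        rows.append((snp_id, gene_id, count, len(rec["lines"]), same))
    out = pd.DataFrame(rows, columns=SPATIAL_PAIR_COLS)
    return out.sort_values(["snp_id", "gene_id"]).reset_index(drop=True)
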