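"""Readers and writers for the pipeline's tabular interchange formats.

All coordinates are 0-based half-open internally.  BED files are written
natively (already 0-based half-open); the SNP table carries a 1-based
position column on disk (``pos_1based``) which is converted to the internal
0-based ``pos`` at the reader boundary.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

FRAGMENT_COLS = ["chrom", "start", "end", "fragment_id"]
GENE_COLS = ["chrom", "start", "end", "gene_id", "score", "strand"]
SNP_COLS = ["snp_id", "chrom", "pos_1based", "trait_p", "locus_class", "regulatory_score"]
CONTACT_COLS = ["frag_id_a", "frag_id_b", "count", "cell_line"]


def write_fragments_bed(fragments: pd.DataFrame, path) -> None:
    fragments[FRAGMENT_COLS].to_csv(path, sep="\t", header=False, index=False)


def read_fragments_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=FRAGMENT_COLS)
    return df.astype({"start": int, "end": int})


def write_genes_bed(genes: pd.DataFrame, path) -> None:
    out = genes.copy()
    if "score" not in out:
        out["score"] = "."
    out[GENE_COLS].to_csv(path, sep="\t", header=False, index=False)


def read_genes_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=GENE_COLS)
    df = df.astype({"start": int, "end": int})
    # TSS: start of the gene body on the + strand, last base on the - strand
    df["tss"] = df["start"].where(df["strand"] == "+", df["end"] - 1)
    return df


def write_snps_tsv(snps: pd.DataFrame, path) -> None:
    out = snps.copy()
    out["pos_1based"] = out["pos"] + 1
    out[SNP_COLS].to_csv(path, sep="\t", index=False)


def read_snps_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["pos"] = df["pos_1based"].astype(int) - 1
    return df


def write_contacts_tsv(contacts: pd.DataFrame, path) -> None:
    contacts[CONTACT_COLS].to_csv(path, sep="\t", index=False)


def read_contacts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    """Write a feature × sample matrix with the feature id as the index column."""
    matrix.to_csv(path, sep="\t")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT gene-set file: set_id <tab> description <tab> gene ids."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: dict[str, set[str]], path, descriptions: dict[str, str] | None = None) -> None:
    lines = []
    for set_id, genes in sets.items():
        desc = (descriptions or {}).get(set_id, "na")
        lines.append("\t".join([set_id, desc, *sorted(genes)]))
    Path(path).write_text("\n".join(lines) + "\n")
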