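"""Synthetic inputs for the spatial-eQTL pipeline, with planted ground truth.

The generator emulates the study's data layers — a multi-chromosome genome
tiled into restriction fragments, gene models, a catalog of trait-associated
SNPs (with an HLA-like locus label), sparse fragment-fragment Hi-C contact
lists, Hardy-Weinberg genotype dosages, and per-tissue expression matrices
with additive planted eQTL effects — so every downstream stage can be tested
against a known answer.  It does not simulate sequence, reads, or realistic
LD block structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from ._util import stage_rng
from .spatial import assign_snps_to_fragments, gene_fragment_map

DEFAULT_CELL_LINES = ("IMR90", "HMEC", "NHEK", "KBM7", "HUVEC")


@dataclass
class GenomeSpec:
    """Layout of the synthetic genome.

    chromosomes: (name, length in bp) pairs.
    fragment_size_mean: mean restriction-fragment length (bp).
    n_genes / n_snps: counts drawn within chromosome bounds.
    hla_like_interval: (chrom, start, end), 0-based half-open; catalog SNPs
        inside it are labeled HLA-class, all others non-HLA.
    """

    chromosomes: list[tuple[str, int]]
    fragment_size_mean: int = 1000
    n_genes: int = 20
    n_snps: int = 50
    hla_like_interval: tuple[str, int, int] = ("chr1", 0, 0)
    gene_length_min: int = 2000
    gene_length_max: int = 20000

    def __post_init__(self):
        if not self.chromosomes:
            raise ValueError("at least one chromosome required")
        lengths = dict(self.chromosomes)
        if any(l <= 0 for l in lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.fragment_size_mean <= 0:
            raise ValueError("fragment_size_mean must be positive")
        c, s, e = self.hla_like_interval
        if c not in lengths or not (0 <= s <= e <= lengths[c]):
            raise ValueError("hla_like_interval must lie within a declared chromosome")
        if not (0 < self.gene_length_min <= self.gene_length_max):
            raise ValueError("invalid gene length range")

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)


@dataclass
class PlantedEffect:
    """Ground-truth eQTL: +beta expression units per alternate allele."""

    snp_id: str
    gene_id: str
    tissue_ids: tuple[str, ...]
    beta: float
    is_trans: bool

    def __post_init__(self):
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")
        if not self.tissue_ids:
            raise ValueError("tissue_ids must be non-empty")


@dataclass
class GenotypePanel:
    """Biallelic dosages (0/1/2, NaN = missing) as a SNP × sample frame."""

    dosages: pd.DataFrame  # index snp_id, columns sample_id
    maf: pd.Series  # allele frequency used at generation

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.index)


@dataclass
class ExpressionPanel:
    """One tissue's gene × sample expression matrix (residual-SD scale)."""

    tissue_id: str
    values: pd.DataFrame  # index gene_id, columns sample_id (subset of panel)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def _tile_chromosome(name: str, length: int, mean: int, rng: np.random.Generator) -> list[tuple]:
    """Tile [0, length) with geometric-length fragments, last one truncated."""
    rows, pos, i = [], 0, 0
    while pos < length:
        frag_len = int(rng.geometric(1.0 / mean))
        end = min(pos + frag_len, length)
        rows.append((name, pos, end, f"{name}:f{i:06d}"))
        pos, i = end, i + 1
    return rows


def simulate_genome(spec: GenomeSpec, seed: int) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (fragments, genes, snps) for the spec.

    Fragments tile each chromosome exactly (0-based half-open, no gaps or
    overlaps).  Each gene gets a strand and TSS; each SNP gets a unique
    position, a trait p-value below the catalog threshold, a locus class
    (HLA iff inside the HLA-like interval), and a regulatory score in [0,1].
    """
    rng = stage_rng(seed, "genome")
    frag_rows = []
    for name, length in spec.chromosomes:
        frag_rows.extend(_tile_chromosome(name, length, spec.fragment_size_mean, rng))
    fragments = pd.DataFrame(frag_rows, columns=sio.FRAGMENT_COLS)

    chrom_names = [c for c, _ in spec.chromosomes]
    chrom_lengths = np.array([l for _, l in spec.chromosomes], dtype=float)
    chrom_p = chrom_lengths / chrom_lengths.sum()

    gene_rows = []
    for i in range(spec.n_genes):
        ci = rng.choice(len(chrom_names), p=chrom_p)
        chrom, clen = chrom_names[ci], int(chrom_lengths[ci])
        glen = int(rng.integers(spec.gene_length_min, spec.gene_length_max + 1))
        glen = min(glen, clen)
        start = int(rng.integers(0, clen - glen + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        gene_rows.append((chrom, start, start + glen, f"g{i:04d}", ".", strand))
    genes = pd.DataFrame(gene_rows, columns=sio.GENE_COLS)
    genes["tss"] = genes["start"].where(genes["strand"] == "+", genes["end"] - 1)

    snps = _draw_snps(spec, rng, spec.n_snps, prefix="rsS", catalog=True)
    return fragments, genes, snps


def _draw_snps(spec: GenomeSpec, rng: np.random.Generator, n: int, prefix: str,
               catalog: bool, taken: set | None = None) -> pd.DataFrame:
    if n > spec.total_length - len(taken or ()):
        raise ValueError(f"cannot place {n} SNPs in {spec.total_length} bp")
    chrom_names = [c for c, _ in spec.chromosomes]
    lengths = {c: l for c, l in spec.chromosomes}
    chrom_p = np.array([lengths[c] for c in chrom_names], dtype=float)
    chrom_p /= chrom_p.sum()
    seen = set(taken or ())
    positions: list[tuple[str, int]] = []
    while len(positions) < n:
        chrom = chrom_names[rng.choice(len(chrom_names), p=chrom_p)]
        pos = int(rng.integers(0, lengths[chrom]))
        if (chrom, pos) in seen:
            continue
        seen.add((chrom, pos))
        positions.append((chrom, pos))
    hc, hs, he = spec.hla_like_interval
    rows = []
    for i, (chrom, pos) in enumerate(positions):
        locus = "HLA" if (chrom == hc and hs <= pos < he) else "non-HLA"
        if catalog:
            trait_p = 10.0 ** rng.uniform(-12, np.log10(9.0e-6))
        else:
            trait_p = float(rng.uniform(0.1, 1.0))
        score = round(float(rng.random()), 4)
        rows.append((f"{prefix}{i:05d}", chrom, pos, trait_p, locus, score))
    df = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "trait_p",
                                     "locus_class", "regulatory_score"])
    return df


def simulate_control_snps(spec: GenomeSpec, catalog_snps: pd.DataFrame, n: int,
                          seed: int) -> pd.DataFrame:
    """Draw a control-SNP universe disjoint in position from the catalog."""
    rng = stage_rng(seed, "genome", extra=1)
    taken = set(zip(catalog_snps["chrom"], catalog_snps["pos"]))
    return _draw_snps(spec, rng, n, prefix="rsC", catalog=False, taken=taken)


def simulate_genotypes(snp_ids, n_samples: int, seed: int,
                       maf_range: tuple[float, float] = (0.1, 0.5),
                       missing_rate: float = 0.0) -> GenotypePanel:
    """Hardy-Weinberg dosages at per-SNP MAF drawn uniformly from maf_range.

    A column that comes out monomorphic is redrawn (deterministically from
    the same stream) so every SNP is testable; missingness is applied after.
    """
    rng = stage_rng(seed, "genotypes")
    snp_ids = list(snp_ids)
    samples = [f"s{i:04d}" for i in range(n_samples)]
    maf = rng.uniform(*maf_range, size=len(snp_ids))
    dos = rng.binomial(2, maf[:, None], size=(len(snp_ids), n_samples)).astype(float)
    for i in range(len(snp_ids)):
        tries = 0
        while np.nanstd(dos[i]) == 0 and tries < 100:
            dos[i] = rng.binomial(2, maf[i], size=n_samples)
            tries += 1
    if missing_rate > 0:
        mask = rng.random(dos.shape) < missing_rate
        dos[mask] = np.nan
    frame = pd.DataFrame(dos, index=snp_ids, columns=samples)
    return GenotypePanel(dosages=frame, maf=pd.Series(maf, index=snp_ids))


def _gene_anchor_fragment(gene_row, gene_fragments: set[str]) -> str | None:
    """The TSS-side fragment used to anchor a gene's planted contacts."""
    frs = sorted(gene_fragments)
    if not frs:
        return None
    return frs[0] if gene_row.strand == "+" else frs[-1]


def plant_effects(fragments: pd.DataFrame, genes: pd.DataFrame, snps: pd.DataFrame,
                  tissues: list[str], n_cis: int, n_trans: int, beta: float,
                  seed: int, cis_window: int = 1_000_000,
                  exclusive_support: bool = True) -> list[PlantedEffect]:
    """Choose ground-truth SNP-gene pairs: n_cis within cis_window of a TSS on
    the same chromosome, n_trans beyond it or inter-chromosomal.

    With exclusive_support (the default) planted pairs are uniquely
    recoverable: the SNP's fragment carries no other catalog SNP and overlaps
    no gene, and the gene's contact-anchor fragment overlaps no other gene
    and carries no catalog SNP, so a zero-background contact list supports
    exactly the planted pairs and nothing else.
    """
    rng = stage_rng(seed, "effects")
    snp_frag = assign_snps_to_fragments(snps, fragments)
    gfrags = gene_fragment_map(genes, fragments)

    frag_snp_count: dict[str, int] = {}
    for f in snp_frag.values():
        frag_snp_count[f] = frag_snp_count.get(f, 0) + 1
    frag_genes: dict[str, set[str]] = {}
    for gid, frs in gfrags.items():
        for f in frs:
            frag_genes.setdefault(f, set()).add(gid)

    def snp_ok(snp_id):
        f = snp_frag.get(snp_id)
        if f is None:
            return False
        return frag_snp_count[f] == 1 and not frag_genes.get(f)

    def gene_ok(gene_row):
        anchor = _gene_anchor_fragment(gene_row, gfrags.get(gene_row.gene_id, set()))
        if anchor is None:
            return False
        return frag_genes.get(anchor) == {gene_row.gene_id} and anchor not in frag_snp_count

    cis_cands, trans_cands = [], []
    for _, s in snps.iterrows():
        for _, g in genes.iterrows():
            if exclusive_support and not (snp_ok(s.snp_id) and gene_ok(g)):
                continue
            same = s.chrom == g.chrom
            if same and abs(int(s.pos) - int(g.tss)) < cis_window:
                cis_cands.append((s.snp_id, g.gene_id))
            else:
                trans_cands.append((s.snp_id, g.gene_id))
    if len(cis_cands) < n_cis or len(trans_cands) < n_trans:
        raise ValueError(
            f"not enough candidate pairs (cis {len(cis_cands)}/{n_cis}, "
            f"trans {len(trans_cands)}/{n_trans}); enlarge the genome"
        )

    effects: list[PlantedEffect] = []
    used_snps: set[str] = set()

    def pick(cands, k, is_trans):
        order = rng.permutation(len(cands))
        taken = 0
        for idx in order:
            snp_id, gene_id = cands[idx]
            if snp_id in used_snps:
                continue
            used_snps.add(snp_id)
            effects.append(PlantedEffect(snp_id, gene_id, tuple(tissues), beta, is_trans))
            taken += 1
            if taken == k:
                return
        raise ValueError("not enough distinct SNPs for the requested effects")

    pick(cis_cands, n_cis, False)
    pick(trans_cands, n_trans, True)
    return effects


def simulate_contacts(fragments: pd.DataFrame, genes: pd.DataFrame, snps: pd.DataFrame,
                      planted: list[PlantedEffect], background_rate: float, seed: int,
                      cell_lines: tuple[str, ...] = DEFAULT_CELL_LINES) -> pd.DataFrame:
    """Emit a fragment-pair contact list guaranteeing spatial support for every
    planted effect, plus Poisson background pairs at background_rate contacts
    per fragment pair.  Pairs are stored lexicographically smaller id first.
    """
    rng = stage_rng(seed, "contacts")
    snp_frag = assign_snps_to_fragments(snps, fragments)
    gfrags = gene_fragment_map(genes, fragments)
    tss_frag = {}
    for _, g in genes.iterrows():
        anchor = _gene_anchor_fragment(g, gfrags.get(g.gene_id, set()))
        if anchor is not None:
            tss_frag[g.gene_id] = anchor

    snp_index = snps.set_index("snp_id")
    gene_index = genes.set_index("gene_id")
    rows = []
    for eff in planted:
        if eff.snp_id not in snp_index.index or eff.gene_id not in gene_index.index:
            raise KeyError(f"planted pair ({eff.snp_id}, {eff.gene_id}) not in inputs")
        fa = snp_frag[eff.snp_id]
        fb = tss_frag[eff.gene_id]
        a, b = sorted((fa, fb))
        count = 1 + int(rng.poisson(2))
        rows.append((a, b, count, cell_lines[rng.integers(len(cell_lines))]))

    n_frags = len(fragments)
    n_pairs = n_frags * (n_frags - 1) // 2
    n_bg = int(rng.poisson(background_rate * n_pairs)) if background_rate > 0 else 0
    frag_ids = fragments["fragment_id"].to_numpy()
    for _ in range(n_bg):
        i, j = rng.choice(n_frags, size=2, replace=False)
        a, b = sorted((frag_ids[i], frag_ids[j]))
        rows.append((a, b, 1 + int(rng.poisson(1)), cell_lines[rng.integers(len(cell_lines))]))
    return pd.DataFrame(rows, columns=sio.CONTACT_COLS)


def simulate_expression(genotypes: GenotypePanel, genes: pd.DataFrame, tissues: list[str],
                        planted: list[PlantedEffect], noise_sd: float = 1.0,
                        seed: int = 0, samples_per_tissue: int | None = None,
                        min_samples: int = 70) -> list[ExpressionPanel]:
    """Per-tissue expression: Gaussian noise plus beta x dosage for each planted
    effect targeting that (gene, tissue); non-target genes are pure noise.
    """
    for eff in planted:
        if not np.isfinite(eff.beta):
            raise ValueError("planted beta must be finite")
    gene_ids = list(genes["gene_id"])
    all_samples = np.array(genotypes.sample_ids)
    panels = []
    for ti, tissue in enumerate(tissues):
        rng = stage_rng(seed, "expression", extra=ti)
        if samples_per_tissue is not None and samples_per_tissue < len(all_samples):
            keep = np.sort(rng.choice(len(all_samples), size=samples_per_tissue, replace=False))
            samples = all_samples[keep]
        else:
            samples = all_samples
        if len(samples) < min_samples:
            raise ValueError(
                f"tissue {tissue}: {len(samples)} samples < min_samples {min_samples}"
            )
        expr = rng.normal(0.0, noise_sd, size=(len(gene_ids), len(samples)))
        frame = pd.DataFrame(expr, index=gene_ids, columns=samples)
        for eff in planted:
            if tissue not in eff.tissue_ids or eff.gene_id not in frame.index:
                continue
            dose = genotypes.dosages.loc[eff.snp_id, samples].to_numpy(dtype=float)
            frame.loc[eff.gene_id] += eff.beta * np.nan_to_num(dose)
        panels.append(ExpressionPanel(tissue_id=tissue, values=frame))
    return panels


@dataclass
class SimulationConfig:
    """Everything needed to generate one complete synthetic study."""

    genome: GenomeSpec
    tissues: list[str] = field(default_factory=lambda: ["tissueA", "tissueB"])
    n_samples: int = 120
    n_control_snps: int = 0
    n_cis_effects: int = 5
    n_trans_effects: int = 2
    beta: float = 1.5
    noise_sd: float = 1.0
    background_rate: float = 0.0
    maf_range: tuple[float, float] = (0.1, 0.5)
    missing_rate: float = 0.0
    min_samples: int = 70

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        g = d["genome"]
        spec = GenomeSpec(
            chromosomes=[tuple(c) for c in g["chromosomes"]],
            fragment_size_mean=g.get("fragment_size_mean", 1000),
            n_genes=g.get("n_genes", 20),
            n_snps=g.get("n_snps", 50),
            hla_like_interval=tuple(g["hla_like_interval"]),
            gene_length_min=g.get("gene_length_min", 2000),
            gene_length_max=g.get("gene_length_max", 20000),
        )
        kwargs = {k: v for k, v in d.items() if k != "genome"}
        if "maf_range" in kwargs:
            kwargs["maf_range"] = tuple(kwargs["maf_range"])
        return cls(genome=spec, **kwargs)


def run_simulation(cfg: SimulationConfig, seed: int, outdir) -> dict:
    """Generate a full input set and write the interchange files to outdir.

    Returns the in-memory tables keyed by name (fragments, genes, snps,
    control_snps, contacts, genotypes, expression panels, planted truth).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fragments, genes, snps = simulate_genome(cfg.genome, seed)
    planted = plant_effects(fragments, genes, snps, cfg.tissues,
                            cfg.n_cis_effects, cfg.n_trans_effects, cfg.beta, seed)
    contacts = simulate_contacts(fragments, genes, snps, planted,
                                 cfg.background_rate, seed)
    control = (simulate_control_snps(cfg.genome, snps, cfg.n_control_snps, seed)
               if cfg.n_control_snps else None)
    all_snp_ids = list(snps["snp_id"]) + (list(control["snp_id"]) if control is not None else [])
    genotypes = simulate_genotypes(all_snp_ids, cfg.n_samples, seed,
                                   cfg.maf_range, cfg.missing_rate)
    panels = simulate_expression(genotypes, genes, cfg.tissues, planted,
                                 cfg.noise_sd, seed, min_samples=cfg.min_samples)

    sio.write_fragments_bed(fragments, outdir / "fragments.bed")
    sio.write_genes_bed(genes, outdir / "genes.bed")
    sio.write_snps_tsv(snps, outdir / "snps.tsv")
    if control is not None:
        sio.write_snps_tsv(control, outdir / "control_snps.tsv")
    sio.write_contacts_tsv(contacts, outdir / "contacts.tsv")
    sio.write_matrix_tsv(genotypes.dosages, outdir / "genotypes.tsv")
    for panel in panels:
        sio.write_matrix_tsv(panel.values, outdir / f"expression.{panel.tissue_id}.tsv")
    truth = pd.DataFrame(
        [(e.snp_id, e.gene_id, ",".join(e.tissue_ids), e.beta, e.is_trans) for e in planted],
        columns=["snp_id", "gene_id", "tissue_ids", "beta", "is_trans"],
    )
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return {
        "fragments": fragments, "genes": genes, "snps": snps, "control_snps": control,
        "contacts": contacts, "genotypes": genotypes, "expression": panels,
        "planted": planted, "truth": truth,
    }
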