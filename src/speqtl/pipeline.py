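"""End-to-end orchestration: simulate/load inputs, map spatial pairs, test
eQTLs, run the supporting statistics, and write a consolidated report."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as sio
from ._util import StageTimer, get_logger
from .enrichment import (fisher_cis_trans, monte_carlo_enrichment,
                         regulatory_partition, tissue_contribution)
from .eqtl import links_table, run_eqtl_stage
from .ld import ld_matrix
from .spatial import find_spatial_pairs
from .synthetic import GenotypePanel, ExpressionPanel, SimulationConfig, run_simulation


@dataclass
class RunConfig:
    """Run-wide thresholds and options; defaults mirror the study's stated
    criteria (q < 0.05, cis window < 1 Mb) and its data-driven gates
    (>= 70 samples per tissue)."""

    q_threshold: float = 0.05
    cis_distance: int = 1_000_000
    min_count: int = 1
    min_samples: int = 70
    fdr_scope: str = "joint"  # or "per-tissue"
    distance_anchor: str = "tss"  # or "nearest-gene-edge"
    include_same_fragment: bool = True
    score_threshold: float = 0.05  # regulatory-call threshold on the score column
    n_sets: int = 100  # Monte Carlo control sets (0 disables the stage)
    seed: int = 0
    simulate: SimulationConfig | None = None
    inputs: dict = field(default_factory=dict)  # explicit paths when not simulating
    gmt: str | None = None
    background_genes: int | None = None  # gene-set enrichment universe size

    def __post_init__(self):
        if self.q_threshold < 0 or self.cis_distance <= 0 or self.min_samples <= 0:
            raise ValueError("thresholds must be positive (q_threshold may be 0)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw.get("analysis", {}))
        kwargs["seed"] = raw.get("seed", kwargs.get("seed", 0))
        if "simulate" in raw:
            kwargs["simulate"] = SimulationConfig.from_dict(raw["simulate"])
        kwargs["inputs"] = raw.get("inputs", {})
        kwargs["gmt"] = raw.get("gmt")
        kwargs["background_genes"] = raw.get("background_genes")
        return cls(**kwargs)

    def to_jsonable(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k not in ("simulate", "inputs")}
        d["inputs"] = {k: str(v) for k, v in self.inputs.items()}
        d["simulated"] = self.simulate is not None
        return d


def load_inputs(paths: dict) -> dict:
    """Load the interchange files named in the config's ``inputs`` block."""
    data = {
        "fragments": sio.read_fragments_bed(paths["fragments"]),
        "genes": sio.read_genes_bed(paths["genes"]),
        "snps": sio.read_snps_tsv(paths["snps"]),
        "contacts": sio.read_contacts_tsv(paths["contacts"]),
    }
    dosages = sio.read_matrix_tsv(paths["genotypes"])
    data["genotypes"] = GenotypePanel(dosages=dosages, maf=dosages.mean(axis=1) / 2)
    data["expression"] = [
        ExpressionPanel(tissue_id=t, values=sio.read_matrix_tsv(p))
        for t, p in sorted(paths["expression"].items())
    ]
    if "control_snps" in paths:
        data["control_snps"] = sio.read_snps_tsv(paths["control_snps"])
    else:
        data["control_snps"] = None
    return data


def run_all(config: RunConfig, outdir) -> dict:
    """Execute map-spatial -> eqtl -> enrich -> ld and write all stage outputs
    plus report.json under outdir.  Returns the report dict."""
    logger = get_logger()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        with StageTimer("simulate", logger):
            data = run_simulation(config.simulate, config.seed, outdir / "inputs")
    else:
        data = load_inputs(config.inputs)

    snps, genes, fragments = data["snps"], data["genes"], data["fragments"]
    genotypes, panels = data["genotypes"], data["expression"]

    with StageTimer("map-spatial", logger):
        pairs = find_spatial_pairs(snps, genes, fragments, data["contacts"],
                                   min_count=config.min_count,
                                   include_same_fragment=config.include_same_fragment)
        pairs.to_csv(outdir / "spatial_pairs.tsv", sep="\t", index=False)
        logger.info("stage=map-spatial n_snps=%d n_contacts=%d n_pairs=%d",
                    len(snps), len(data["contacts"]), len(pairs))

    with StageTimer("eqtl", logger):
        results, summary = run_eqtl_stage(
            pairs, genotypes, panels, genes, snps,
            q_threshold=config.q_threshold, min_samples=config.min_samples,
            fdr_scope=config.fdr_scope, cis_window=config.cis_distance,
            distance_anchor=config.distance_anchor)
        results.to_csv(outdir / "eqtl_results.tsv", sep="\t", index=False)
        links_table(results, snps, genes).to_csv(outdir / "links.tsv", sep="\t", index=False)

    report = {"config": config.to_jsonable(), "counts": summary}

    with StageTimer("enrich", logger):
        tissue_table, (mean_pct, sd_pct) = tissue_contribution(results, snps)
        tissue_table.to_csv(outdir / "tissue_summary.tsv", sep="\t", index=False)
        report["tissue_contribution"] = {
            "mean_pct": round(mean_pct, 4), "sd_pct": round(sd_pct, 4),
            "n_tissues": int(len(tissue_table)),
        }

        sig = results[results["significant"]]
        reg, _nonreg, _missing = regulatory_partition(snps, config.score_threshold)
        sig_pairs = sig.drop_duplicates(["snp_id", "gene_id"])
        is_reg = sig_pairs["snp_id"].isin(reg)
        table = [
            int(((sig_pairs["category"] == "cis") & is_reg).sum()),
            int(((sig_pairs["category"] == "trans") & is_reg).sum()),
            int(((sig_pairs["category"] == "cis") & ~is_reg).sum()),
            int(((sig_pairs["category"] == "trans") & ~is_reg).sum()),
        ]
        odds, p = fisher_cis_trans(*table)
        fisher = {"table": table, "odds_ratio": None if pd.isna(odds) else round(odds, 6),
                  "p_two_sided": round(p, 8)}
        report["fisher_regulatory_cis_trans"] = fisher
        pd.DataFrame([fisher]).to_csv(outdir / "fisher.tsv", sep="\t", index=False)

        if config.n_sets >= 2 and data.get("control_snps") is not None:
            universe = list(data["control_snps"]["snp_id"])
            all_snps = pd.concat([snps, data["control_snps"]], ignore_index=True)

            def count_connections(snp_ids):
                sub = all_snps[all_snps["snp_id"].isin(set(snp_ids))]
                sub_pairs = find_spatial_pairs(
                    sub, genes, fragments, data["contacts"], min_count=config.min_count,
                    include_same_fragment=config.include_same_fragment)
                if sub_pairs.empty:
                    return 0
                res, _ = run_eqtl_stage(
                    sub_pairs, genotypes, panels, genes, all_snps,
                    q_threshold=config.q_threshold, min_samples=config.min_samples,
                    fdr_scope=config.fdr_scope, cis_window=config.cis_distance,
                    distance_anchor=config.distance_anchor)
                if res.empty:
                    return 0
                return len(res[res["significant"]].drop_duplicates(["snp_id", "gene_id"]))

            mc = monte_carlo_enrichment(list(snps["snp_id"]), universe,
                                        count_connections, n_sets=config.n_sets,
                                        seed=config.seed)
            report["monte_carlo"] = {
                "observed_connections": mc.observed_connections,
                "null_mean": round(float(mc.null_connections.mean()), 4),
                "null_sd": round(float(mc.null_connections.std(ddof=1)), 4),
                "n_sets": mc.n_sets,
                "t_statistic": round(mc.t_statistic, 4) if pd.notna(mc.t_statistic)
                               and abs(mc.t_statistic) != float("inf") else None,
                "p_value": round(mc.p_value, 10),
                "p_permutation": round(mc.p_permutation, 10),
            }
            pd.DataFrame({"null_connections": mc.null_connections}).to_csv(
                outdir / "monte_carlo.tsv", sep="\t", index=False)

        if config.gmt:
            from .enrichment import geneset_enrichment
            sets = sio.read_gmt(config.gmt)
            background = config.background_genes or len(genes)
            enr = geneset_enrichment(set(sig["gene_id"]), sets, background)
            enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            report["geneset_enrichment"] = {
                "n_sets": int(len(enr)),
                "n_significant": int((enr["q_value"] < config.q_threshold).sum()),
            }

    with StageTimer("ld", logger):
        hla = snps.loc[snps["locus_class"] == "HLA", "snp_id"]
        ld_ids = list(hla) if len(hla) >= 2 else list(snps["snp_id"])
        ld_set_name = "HLA" if len(hla) >= 2 else "catalog"
        if len(ld_ids) >= 2 and all(s in genotypes.dosages.index for s in ld_ids):
            ld_table, max_r2 = ld_matrix(genotypes, ld_ids)
            ld_table.to_csv(outdir / "ld_pairs.tsv", sep="\t", index=False)
            report["ld"] = {
                "snp_set": ld_set_name, "n_snps": len(ld_ids),
                "n_pairs": int(len(ld_table)),
                "max_r_squared": None if pd.isna(max_r2) else round(max_r2, 6),
            }

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    logger.info("stage=report path=%s", report_path)
    return report


def tissue_barchart(tissue_summary: pd.DataFrame, path) -> None:
    """Minimal bar chart of per-tissue HLA contribution percentages."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(tissue_summary)), 3))
    colors = {"high": "#c0392b", "mid": "#7f8c8d", "low": "#2980b9"}
    ax.bar(tissue_summary["tissue_id"], tissue_summary["contribution_pct"],
           color=[colors[g] for g in tissue_summary["group"]])
    ax.set_ylabel("HLA : total eQTLs (%)")
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
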