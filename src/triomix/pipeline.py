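"""End-to-end orchestration: simulate -> preprocess -> diff -> DMR ->
integrate -> enrich, with a machine-readable summary per run.

Every stage is a pure function of its inputs and the configuration, so a
rerun with the same config and seed reproduces the summary exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .crossomics import contrast_correlation, pca_separation, triple_overlap
from .diffstats import PairedDifferential
from .dmr import call_dmrs, overlap_genes
from .enrich import GeneSetCollection, integrative_enrichment
from .io import write_bed
from .layers import CONTRASTS
from .preprocess import filter_complete, normalize_protein
from .simulate import PlantedSet, SimConfig, generate_dataset

logger = logging.getLogger(__name__)


class RunConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Thresholds and stage parameters for a full pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    primary_fdr: float = 0.001      # headline per-feature threshold
    secondary_fdr: float = 0.05     # supporting-evidence threshold
    lambda_bp: int = 1_000
    min_probes: int = 2
    n_rand: int = 1_000
    per_layer_alpha: float = 0.05
    min_support_genes: int = 5
    min_support_layers: int = 2
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("primary_fdr", "secondary_fdr", "per_layer_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise RunConfigError(f"{name}={v} outside (0, 1)")
        if self.primary_fdr > self.secondary_fdr:
            raise RunConfigError("primary_fdr must not exceed secondary_fdr")
        if self.min_probes < 1 or self.lambda_bp < 1:
            raise RunConfigError("DMR parameters must be positive")
        if self.n_rand < 100:
            raise RunConfigError("n_rand must be >= 100")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        planted = [PlantedSet(**p) for p in sim_raw.pop("planted_sets", [])] \
            if "planted_sets" in sim_raw else None
        sim = SimConfig(**sim_raw) if planted is None else \
            SimConfig(**sim_raw, planted_sets=planted)
        cfg = cls(sim=sim, **raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage on a simulated dataset; write outputs and a summary.

    Returns the summary dict (also written as ``summary.json``).
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_config = dataclasses.replace(config.sim, seed=config.seed)

    logger.info("simulate: %d genes, %d proteins, %d probes, seed=%d",
                sim_config.n_genes, sim_config.n_proteins,
                sim_config.total_probes, sim_config.seed)
    data = generate_dataset(sim_config)
    data.write(out / "data")

    # preprocess (protein: complete-case + published normalisation)
    protein = normalize_protein(filter_complete(data.layers["protein"]))
    layers = {"methylation": data.layers["methylation"],
              "rna": data.layers["rna"], "protein": protein}
    logger.info("preprocess: protein %d -> %d complete features",
                data.layers["protein"].values.shape[0],
                protein.values.shape[0])

    # differential analysis, all layers x contrasts
    results: dict[tuple[str, str], object] = {}
    counts: dict[str, dict[str, int]] = {}
    diff_dir = out / "diff"
    diff_dir.mkdir(exist_ok=True)
    for layer_name, layer in layers.items():
        counts[layer_name] = {}
        for contrast in CONTRASTS:
            res = PairedDifferential(layer, contrast).fit()
            results[(layer_name, contrast)] = res
            res.to_tsv(diff_dir / f"{layer_name}_{contrast}.tsv")
            n_sig = len(res.significant(config.primary_fdr))
            counts[layer_name][contrast] = n_sig
            logger.info("diff %s %s: %d/%d significant at %g%% FDR",
                        layer_name, contrast, n_sig, len(res.table),
                        config.primary_fdr * 100)

    # DMR calling on the primary contrast
    dmr_counts = {}
    dmr_summaries = {}
    for contrast, fdr in (("O_vs_L", config.primary_fdr),
                          ("O_vs_H", config.secondary_fdr)):
        regions = call_dmrs(results[("methylation", contrast)],
                            data.probe_annotation,
                            lambda_bp=config.lambda_bp,
                            min_probes=config.min_probes,
                            probe_fdr=config.primary_fdr if contrast == "O_vs_L"
                            else config.secondary_fdr)
        summary = overlap_genes(regions, data.gene_intervals,
                                data.probe_annotation,
                                results[("methylation", contrast)],
                                probe_fdr=config.primary_fdr
                                if contrast == "O_vs_L" else config.secondary_fdr)
        dmr_summaries[contrast] = summary
        dmr_counts[contrast] = {"regions": int(len(regions)),
                                "genes": int(len(summary))}
        regions.to_csv(out / f"dmrs_{contrast}.tsv", sep="\t", index=False)
        if len(regions):
            reg = regions.assign(probe_id=regions["probe_ids"])
            write_bed(reg, out / f"dmrs_{contrast}.bed", name_col="probe_id")
        logger.info("dmr %s: %d regions overlapping %d genes", contrast,
                    len(regions), len(summary))

    # gene-level integration on the primary contrast
    secondary = {
        "rna": set(results[("rna", "O_vs_H")].significant(config.secondary_fdr)),
        "protein": set(results[("protein", "O_vs_H")].significant(config.secondary_fdr)),
        "methylation": set(dmr_summaries["O_vs_H"].index),
    }
    table1 = triple_overlap(
        results[("rna", "O_vs_L")], results[("protein", "O_vs_L")],
        dmr_summaries["O_vs_L"], fdr=config.primary_fdr, secondary=secondary)
    table1.to_csv(out / "cross_omics_genes.tsv", sep="\t")
    n_conc = int(table1["rna_protein_concordant"].sum()) if len(table1) else 0
    logger.info("integrate: %d triple-significant genes, %d RNA/protein "
                "concordant", len(table1), n_conc)

    corr = contrast_correlation(results[("rna", "O_vs_L")],
                                results[("rna", "H_vs_L")])
    with open(out / "concordance_rna_OvL_vs_HvL.tsv", "w") as fh:
        for k, v in corr.to_dict().items():
            fh.write(f"{k}\t{v}\n")

    pca = pca_separation(layers["rna"],
                         set(results[("rna", "O_vs_L")].significant(config.primary_fdr))
                         or set(layers["rna"].features))
    pca.scores.to_csv(out / "pca_rna.tsv", sep="\t")

    # integrative enrichment at the secondary (5%) FDR per-layer lists
    sig_per_layer = {
        "methylation": set(dmr_summaries["O_vs_L"].index),
        "rna": set(results[("rna", "O_vs_L")].significant(config.secondary_fdr)),
        "protein": set(results[("protein", "O_vs_L")].significant(config.secondary_fdr)),
    }
    collection = GeneSetCollection(
        dict(data.gene_sets),
        universes={
            "methylation": set(data.gene_intervals["gene"]),
            "rna": set(layers["rna"].features),
            "protein": set(layers["protein"].features),
        },
    )
    enrichment = integrative_enrichment(
        sig_per_layer, collection, n_rand=config.n_rand, seed=config.seed,
        per_layer_alpha=config.per_layer_alpha,
        min_support_genes=config.min_support_genes,
        min_support_layers=config.min_support_layers)
    enrichment.to_csv(out / "enrichment.tsv", sep="\t")
    enriched = enrichment[(enrichment["integrative_q"] <= 0.05)
                          & (enrichment["filtered_reason"] == "none")]
    logger.info("enrich: %d/%d sets at integrative q<=0.05 after support filter",
                len(enriched), len(enrichment))

    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "significant_features": counts,
        "dmrs": dmr_counts,
        "triple_overlap_genes": int(len(table1)),
        "rna_protein_concordant": n_conc,
        "rna_OvL_vs_HvL_spearman": corr.spearman_rho,
        "pca_rna_separated": bool(pca.separated),
        "enriched_sets": sorted(enriched.index),
        "n_enriched_sets": int(len(enriched)),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
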