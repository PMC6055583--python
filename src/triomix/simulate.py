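"""Matched multi-omics data generator with known ground truth.

The generator emulates the statistical structure of a three-grade matched
cartilage study: nine patients each contribute one osteophytic, one
high-grade and one low-grade articular sample, profiled on a methylation
array, by RNA-seq (log2 expression) and by quantitative proteomics (raw
abundances).  Effects are planted per gene, shared (with a configurable
correlation) between the RNA and protein layers, applied coherently to all
probes of a gene on the methylation layer, and attenuated in the high-grade
tissue so that osteophytic-vs-low differences dominate.

The model behind each measured value is

    x[f, patient, grade] = baseline[f] + b[f, patient] + effect[f, grade] + e

with a per-feature/per-patient random intercept ``b`` (which the paired
design cancels) and i.i.d. Gaussian noise ``e``.  Because the three grades
share one mean per gene, the three pairwise contrasts are additive:
``OvL = OvH + HvL`` exactly.  The two attenuation dials are therefore
reconciled by giving the high-grade tissue the mean
``((1 - effect_ratio_OvH) + effect_ratio_HvL) / 2 * delta`` (see docs).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (write_gene_intervals, write_gmt, write_probe_annotation)
from .layers import GRADES, OmicsLayer, sample_id

GENE_LENGTH = 1_000   # bp occupied by each synthetic gene body
GENE_GAP = 2_000      # bp between consecutive gene bodies
CHROM = "chr1"


class SimConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


@dataclass(frozen=True)
class PlantedSet:
    """A gene set drawn preferentially from affected genes.

    ``affected_fraction`` of the members come from truly affected genes
    (or as many as exist), the rest from unaffected genes.
    """

    name: str
    size: int
    affected_fraction: float = 0.9


def _default_planted() -> list[PlantedSet]:
    return [PlantedSet(f"planted_{i}", 40, 0.9) for i in range(1, 4)]


def _default_noise() -> dict[str, float]:
    return {"rna": 1.0, "protein": 1.0, "methylation": 0.6}


@dataclass(frozen=True)
class SimConfig:
    """Study-design and effect-structure parameters.

    Defaults are a scaled-down version of the motivating study: 9 patients,
    2 000 genes (of 14 029), roughly a third of genes quantified as proteins
    (4 653 of 14 029 in the study), and 5 probes per gene (~30 in the 450k
    universe).  Effect ratios encode the observed ordering
    osteophytic-vs-low > osteophytic-vs-high >> high-vs-low.
    """

    n_patients: int = 9
    n_genes: int = 2_000
    n_proteins: int = 660
    n_probes: int | None = None          # default: probes_per_gene * n_genes
    probes_per_gene: int = 5
    frac_affected_genes: float = 0.2
    effect_scale_ovl: float = 1.5        # log2 units; minimum planted |logFC|
    effect_ratio_ovh: float = 0.9
    effect_ratio_hvl: float = 0.3
    rna_protein_corr: float = 0.6
    noise_sd: dict[str, float] = field(default_factory=_default_noise)
    patient_sd: float = 0.5
    planted_sets: list[PlantedSet] = field(default_factory=_default_planted)
    n_decoy_sets: int = 60
    decoy_set_size: int = 40
    protein_missing_frac: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for fname in ("n_patients", "n_genes", "n_proteins", "probes_per_gene"):
            if getattr(self, fname) <= 0:
                raise SimConfigError(f"{fname} must be a positive count")
        for fname in ("frac_affected_genes", "rna_protein_corr",
                      "protein_missing_frac"):
            v = getattr(self, fname)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{fname}={v} outside [0, 1]")
        if not 0.0 < self.effect_ratio_ovh <= 1.0:
            raise SimConfigError("effect_ratio_ovh must lie in (0, 1]")
        if not 0.0 < self.effect_ratio_hvl < 1.0:
            raise SimConfigError(
                "effect_ratio_hvl must lie in (0, 1): high-vs-low differences "
                "are attenuated relative to osteophytic-vs-low"
            )
        if self.n_proteins > self.n_genes:
            raise SimConfigError("n_proteins must not exceed n_genes")
        if self.effect_scale_ovl <= 0:
            raise SimConfigError("effect_scale_ovl must be positive")
        if self.patient_sd < 0:
            raise SimConfigError("patient_sd must be non-negative")
        for layer, sd in self.noise_sd.items():
            if sd <= 0:
                raise SimConfigError(f"noise_sd[{layer!r}] must be positive")
        n_probes = self.total_probes
        if n_probes < 2 * self.n_genes:
            raise SimConfigError(
                "n_probes must allow at least 2 probes per gene "
                f"(need >= {2 * self.n_genes}, got {n_probes})"
            )
        for ps in self.planted_sets:
            if ps.size <= 0:
                raise SimConfigError(f"planted_sets[{ps.name!r}].size must be positive")
            if not 0.0 <= ps.affected_fraction <= 1.0:
                raise SimConfigError(
                    f"planted_sets[{ps.name!r}].affected_fraction outside [0, 1]"
                )

    @property
    def total_probes(self) -> int:
        return self.n_probes if self.n_probes is not None else (
            self.probes_per_gene * self.n_genes
        )

    @property
    def high_grade_fraction(self) -> float:
        """Fraction of the OvL effect given to the high-grade mean.

        The additive design allows only one free high-grade mean, so the two
        ratio dials are averaged: ``((1 - r_OvH) + r_HvL) / 2``.
        """
        return ((1.0 - self.effect_ratio_ovh) + self.effect_ratio_hvl) / 2.0


@dataclass
class GroundTruth:
    """Per-gene true effects and affected flags; per-set enrichment flags.

    ``effects`` has one row per gene with columns
    ``{layer}_{contrast}`` (true logFC / M-value shift) plus ``affected``.
    """

    effects: pd.DataFrame
    planted_sets: dict[str, bool]

    @property
    def affected_genes(self) -> set[str]:
        return set(self.effects.index[self.effects["affected"]])

    def to_tsv(self, path: str | Path) -> None:
        self.effects.to_csv(path, sep="\t", index_label="gene")


@dataclass
class SimulatedDataset:
    config: SimConfig
    layers: dict[str, OmicsLayer]
    probe_annotation: pd.DataFrame
    gene_intervals: pd.DataFrame
    gene_sets: dict[str, set[str]]
    truth: GroundTruth

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, layer in self.layers.items():
            layer.to_tsv(out / f"{name}.tsv")
        write_probe_annotation(self.probe_annotation, out / "probes.tsv")
        write_gene_intervals(self.gene_intervals, out / "genes.tsv")
        write_gmt(self.gene_sets, out / "gene_sets.gmt")
        self.truth.to_tsv(out / "ground_truth.tsv")


def _effect_magnitudes(rng: np.random.Generator, n: int, scale: float) -> np.ndarray:
    """Planted |logFC|: scale * (1 + 0.5|Z|), bounded away from zero."""
    return scale * (1.0 + 0.5 * np.abs(rng.standard_normal(n)))


def generate_dataset(config: SimConfig) -> SimulatedDataset:
    """Draw one full matched dataset plus its ground truth.

    Fixed seed gives byte-identical output.  All randomness flows from one
    ``numpy.random.default_rng(config.seed)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_genes = config.n_genes
    genes = np.array([f"G{i:05d}" for i in range(1, n_genes + 1)])
    patients = [f"P{i}" for i in range(1, config.n_patients + 1)]
    columns = [sample_id(p, g) for p in patients for g in GRADES]

    # --- which genes carry effects ---------------------------------------
    n_affected = int(round(config.frac_affected_genes * n_genes))
    affected_idx = rng.choice(n_genes, size=n_affected, replace=False)
    affected = np.zeros(n_genes, dtype=bool)
    affected[affected_idx] = True

    # --- correlated RNA/protein effect signs and magnitudes --------------
    rho = config.rna_protein_corr
    z_rna = rng.standard_normal(n_genes)
    z_prot = rho * z_rna + np.sqrt(1.0 - rho**2) * rng.standard_normal(n_genes)
    mag_rna = _effect_magnitudes(rng, n_genes, config.effect_scale_ovl)
    mag_prot = _effect_magnitudes(rng, n_genes, config.effect_scale_ovl)
    # the latent Gaussian pair carries the correlation through its signs;
    # magnitudes are drawn independently and bounded away from zero
    delta_rna = np.where(affected, np.sign(z_rna) * mag_rna, 0.0)
    delta_prot = np.where(affected, np.sign(z_prot) * mag_prot, 0.0)

    # methylation direction independent of expression direction
    sign_meth = rng.choice([-1.0, 1.0], size=n_genes)
    mag_meth = _effect_magnitudes(rng, n_genes, config.effect_scale_ovl)
    delta_meth = np.where(affected, sign_meth * mag_meth, 0.0)

    h = config.high_grade_fraction

    # --- protein subset ---------------------------------------------------
    prot_idx = np.sort(rng.choice(n_genes, size=config.n_proteins, replace=False))
    protein_genes = genes[prot_idx]

    # --- probe layout: every gene gets >= 2 probes ------------------------
    n_probes = config.total_probes
    extra = rng.multinomial(n_probes - 2 * n_genes, np.full(n_genes, 1.0 / n_genes))
    probe_counts = 2 + extra
    gene_starts = 1 + np.arange(n_genes) * (GENE_LENGTH + GENE_GAP)
    gene_ends = gene_starts + GENE_LENGTH - 1
    probe_gene_idx = np.repeat(np.arange(n_genes), probe_counts)
    offsets = np.concatenate([
        np.sort(rng.choice(GENE_LENGTH, size=c, replace=False))
        for c in probe_counts
    ])
    probe_pos = gene_starts[probe_gene_idx] + offsets
    probe_ids = np.array([f"cg{i:07d}" for i in range(1, n_probes + 1)])
    # per-probe attenuation keeps the shift coherent in sign across the gene
    probe_atten = rng.uniform(0.7, 1.0, size=n_probes)
    probe_delta = delta_meth[probe_gene_idx] * probe_atten

    # --- sampling helpers -------------------------------------------------
    def sample_matrix(n_feat: int, baseline: np.ndarray, delta: np.ndarray,
                      noise_sd: float) -> np.ndarray:
        b = rng.normal(0.0, config.patient_sd, size=(n_feat, config.n_patients))
        out = np.empty((n_feat, config.n_patients * len(GRADES)))
        grade_effect = {"osteophytic": delta, "high": h * delta,
                        "low": np.zeros(n_feat)}
        col = 0
        for p in range(config.n_patients):
            for g in GRADES:
                noise = rng.normal(0.0, noise_sd, size=n_feat)
                out[:, col] = baseline + b[:, p] + grade_effect[g] + noise
                col += 1
        return out

    # RNA: log2 expression
    rna_baseline = rng.normal(7.0, 1.5, size=n_genes)
    rna_mat = sample_matrix(n_genes, rna_baseline, delta_rna,
                            config.noise_sd["rna"])
    rna = OmicsLayer("rna", pd.DataFrame(rna_mat, index=genes, columns=columns),
                     scale="log")

    # Protein: generated on log2 scale, shipped as raw abundances so the
    # published normalisation (sum-scaling, log2, quantile) applies
    prot_baseline = rng.normal(7.0, 1.5, size=config.n_proteins)
    prot_signal = sample_matrix(config.n_proteins, prot_baseline,
                                delta_prot[prot_idx], config.noise_sd["protein"])
    prot_raw = np.power(2.0, prot_signal)
    if config.protein_missing_frac > 0:
        mask = rng.random(prot_raw.shape) < config.protein_missing_frac
        prot_raw = np.where(mask, np.nan, prot_raw)
    protein = OmicsLayer(
        "protein", pd.DataFrame(prot_raw, index=protein_genes, columns=columns),
        scale="raw")

    # Methylation: M-values directly (array normalisation is out of scope);
    # bimodal baseline mimics the usual two-peak M-value distribution
    comp = rng.random(n_probes) < 0.5
    meth_baseline = np.where(comp, rng.normal(2.5, 1.0, size=n_probes),
                             rng.normal(-2.5, 1.0, size=n_probes))
    meth_mat = sample_matrix(n_probes, meth_baseline, probe_delta,
                             config.noise_sd["methylation"])
    methylation = OmicsLayer(
        "methylation", pd.DataFrame(meth_mat, index=probe_ids, columns=columns),
        scale="m")

    # --- annotation tables ------------------------------------------------
    probe_annotation = pd.DataFrame({
        "chrom": CHROM,
        "start": probe_pos,
        "end": probe_pos,
        "probe_id": probe_ids,
        "gene": genes[probe_gene_idx],
    })
    gene_intervals = pd.DataFrame({
        "chrom": CHROM, "start": gene_starts, "end": gene_ends, "gene": genes,
    })

    # --- gene sets --------------------------------------------------------
    affected_pool = list(genes[affected])
    unaffected_pool = list(genes[~affected])
    gene_sets: dict[str, set[str]] = {}
    planted_flags: dict[str, bool] = {}
    for ps in config.planted_sets:
        k_aff = min(int(round(ps.affected_fraction * ps.size)), len(affected_pool))
        k_un = min(ps.size - k_aff, len(unaffected_pool))
        members = set()
        if k_aff:
            members |= set(rng.choice(affected_pool, size=k_aff, replace=False))
        if k_un:
            members |= set(rng.choice(unaffected_pool, size=k_un, replace=False))
        gene_sets[ps.name] = members
        planted_flags[ps.name] = k_aff > 0
    for i in range(1, config.n_decoy_sets + 1):
        name = f"decoy_{i:03d}"
        size = min(config.decoy_set_size, n_genes)
        gene_sets[name] = set(rng.choice(genes, size=size, replace=False))
        planted_flags[name] = False

    # --- ground truth -----------------------------------------------------
    effects = pd.DataFrame(index=pd.Index(genes, name="gene"))
    effects["affected"] = affected
    on_protein = np.zeros(n_genes, dtype=bool)
    on_protein[prot_idx] = True
    effects["on_protein_layer"] = on_protein
    for label, d in (("rna", delta_rna), ("protein", np.where(on_protein, delta_prot, np.nan)),
                     ("methylation", delta_meth)):
        effects[f"{label}_O_vs_L"] = d
        effects[f"{label}_O_vs_H"] = (1.0 - h) * d
        effects[f"{label}_H_vs_L"] = h * d
    truth = GroundTruth(effects=effects, planted_sets=planted_flags)

    return SimulatedDataset(
        config=config,
        layers={"methylation": methylation, "rna": rna, "protein": protein},
        probe_annotation=probe_annotation,
        gene_intervals=gene_intervals,
        gene_sets=gene_sets,
        truth=truth,
    )


def null_config(**overrides) -> SimConfig:
    """Convenience: a configuration with no planted effects."""
    base = SimConfig(frac_affected_genes=0.0, planted_sets=[])
    return replace(base, **overrides)
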