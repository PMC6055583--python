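"""Gene-level integration across omics layers and tissue contrasts.

Covers the ID-mapping filter (unique Ensembl ID <-> unique name), the
triple-significant gene list (significant on RNA and protein and overlapped
by a DMR), exact one-sided binomial tests for directional concordance,
cross-contrast correlation / CI-overlap reports and a PCA separation check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .diffstats import DifferentialResults
from .layers import OmicsLayer


def map_gene_ids(mapping: pd.DataFrame) -> pd.DataFrame:
    """Keep only (ensembl_id, gene_name) pairs where both occur exactly once."""
    df = mapping[["ensembl_id", "gene_name"]].copy()
    id_unique = ~df["ensembl_id"].duplicated(keep=False)
    name_unique = ~df["gene_name"].duplicated(keep=False)
    return df[id_unique & name_unique].reset_index(drop=True)


def triple_overlap(
    rna: DifferentialResults,
    protein: DifferentialResults,
    dmr_summary: pd.DataFrame,
    fdr: float = 0.001,
    secondary: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Genes significant on RNA AND protein AND overlapping a DMR.

    ``dmr_summary`` is the per-gene table from :func:`triomix.dmr.overlap_genes`
    (its index is the DMR-overlapped gene set).  ``secondary`` optionally maps
    layer name -> genes supported in the secondary contrast (e.g. O-vs-H at
    5% FDR); a gene is flagged supported when present in all provided sets.

    Directions are signs of logFC; methylation direction is hyper- when the
    proportion of positive-shift DMPs is >= 0.5 (NaN when the gene has no
    DMPs of its own inside overlapping regions).
    """
    rna_sig = set(rna.significant(fdr))
    prot_sig = set(protein.significant(fdr))
    genes = sorted(rna_sig & prot_sig & set(dmr_summary.index))
    rows = []
    for g in genes:
        rna_lfc = float(rna.table.at[g, "logFC"])
        prot_lfc = float(protein.table.at[g, "logFC"])
        n_dmps = dmr_summary.at[g, "n_dmps_in_dmrs"]
        prop_pos = dmr_summary.at[g, "prop_pos_beta"]
        if pd.notna(n_dmps) and n_dmps > 0:
            meth_dir = 1 if prop_pos >= 0.5 else -1
        else:
            meth_dir = np.nan
        supported = np.nan
        if secondary is not None:
            supported = all(g in s for s in secondary.values())
        rows.append({
            "gene": g,
            "n_dmps_in_dmrs": n_dmps,
            "prop_pos_beta": prop_pos,
            "rna_logFC": rna_lfc,
            "rna_q": float(rna.table.at[g, "q"]),
            "protein_logFC": prot_lfc,
            "protein_q": float(protein.table.at[g, "q"]),
            "rna_direction": int(np.sign(rna_lfc)) if rna_lfc else 0,
            "protein_direction": int(np.sign(prot_lfc)) if prot_lfc else 0,
            "methylation_direction": meth_dir,
            "rna_protein_concordant": bool(rna_lfc * prot_lfc > 0),
            "o_vs_h_supported": supported,
        })
    out = pd.DataFrame(rows, columns=[
        "gene", "n_dmps_in_dmrs", "prop_pos_beta", "rna_logFC", "rna_q",
        "protein_logFC", "protein_q", "rna_direction", "protein_direction",
        "methylation_direction", "rna_protein_concordant", "o_vs_h_supported",
    ])
    return out.set_index("gene")


def binomial_concordance(n_concordant: int, n_total: int) -> float:
    """Exact one-sided tail P(X >= n_concordant), X ~ Binomial(n_total, 1/2)."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_concordant <= n_total:
        raise ValueError("need 0 <= n_concordant <= n_total")
    return float(stats.binom.sf(n_concordant - 1, n_total, 0.5))


@dataclass
class ConcordanceReport:
    """Directional agreement between two sets of per-feature effects."""

    n_total: int
    n_concordant: int
    binomial_p: float
    spearman_rho: float
    rho_p: float
    ci_overlap_fraction: float | None = None

    @property
    def proportion(self) -> float:
        return self.n_concordant / self.n_total

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_concordant": self.n_concordant,
            "proportion": self.proportion,
            "binomial_p": self.binomial_p,
            "spearman_rho": self.spearman_rho,
            "rho_p": self.rho_p,
            "ci_overlap_fraction": self.ci_overlap_fraction,
        }


def contrast_correlation(
    diff_a: DifferentialResults,
    diff_b: DifferentialResults,
    features: set[str] | None = None,
) -> ConcordanceReport:
    """Spearman correlation, sign agreement and CI overlap of two result sets.

    Works both across contrasts within one layer and across layers within one
    contrast; only the shared feature namespace matters.
    """
    shared = diff_a.table.index.intersection(diff_b.table.index)
    if features is not None:
        shared = shared.intersection(pd.Index(sorted(features)))
    if len(shared) < 3:
        raise ValueError("need at least 3 shared features")
    a = diff_a.table.loc[shared]
    b = diff_b.table.loc[shared]
    rho, rho_p = stats.spearmanr(a["logFC"], b["logFC"])
    same_sign = int(((a["logFC"].to_numpy() * b["logFC"].to_numpy()) > 0).sum())
    ci_overlap = float(np.mean(
        (a["ci_lo"].to_numpy() <= b["ci_hi"].to_numpy())
        & (b["ci_lo"].to_numpy() <= a["ci_hi"].to_numpy())
    ))
    return ConcordanceReport(
        n_total=len(shared),
        n_concordant=same_sign,
        binomial_p=binomial_concordance(same_sign, len(shared)),
        spearman_rho=float(rho),
        rho_p=float(rho_p),
        ci_overlap_fraction=ci_overlap,
    )


@dataclass
class PcaSeparation:
    scores: pd.DataFrame          # samples x (PC1, PC2), with patient/grade
    explained: np.ndarray
    separated: bool
    method: str                   # "pc1-threshold" | "pc1-pc2-lda" | "none"


def _threshold_separable(x: np.ndarray, labels: np.ndarray) -> bool:
    """Is there a threshold on x classifying the two label groups exactly?"""
    a = x[labels]
    b = x[~labels]
    return a.min() > b.max() or a.max() < b.min()


def pca_separation(layer: OmicsLayer, feature_subset: set[str] | pd.Index,
                   target_grade: str = "osteophytic") -> PcaSeparation:
    """PCA on a feature subset; does PC1 (or PC1-PC2) isolate one grade?

    The verdict is "separated" when an exhaustive PC1 threshold classifies
    the target-grade samples against all others without error, or, failing
    that, when LDA on the PC1-PC2 scores does.
    """
    subset = [f for f in layer.features if f in set(feature_subset)]
    if len(subset) < 2:
        raise ValueError("feature subset must contain at least 2 features")
    mat = layer.values.loc[subset].to_numpy(dtype=float).T  # samples x features
    n_comp = min(2, mat.shape[0], len(subset))
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(mat - mat.mean(axis=0, keepdims=True))
    design = layer.sample_design
    is_target = (design["grade"] == target_grade).to_numpy()

    separated = _threshold_separable(scores[:, 0], is_target)
    method = "pc1-threshold"
    if not separated and n_comp == 2:
        lda = LinearDiscriminantAnalysis()
        lda.fit(scores, is_target)
        separated = bool((lda.predict(scores) == is_target).all())
        method = "pc1-pc2-lda"
    if not separated:
        method = "none"

    score_df = design.copy()
    for i in range(n_comp):
        score_df[f"PC{i + 1}"] = scores[:, i]
    return PcaSeparation(scores=score_df, explained=pca.explained_variance_ratio_,
                         separated=separated, method=method)
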