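"""Differentially methylated region (DMR) calling and gene overlap.

Probes significant at the probe-level FDR threshold are merged into
maximal runs: consecutive significant probes on the same chromosome at
most ``lambda_bp`` apart fall in one region, and runs with fewer than
``min_probes`` probes are discarded.  Each region receives a signed
Stouffer statistic: per probe z = Phi^{-1}(1 - p/2) * sign(logFC), and
region_p is the one-sided normal tail of |sum z| / sqrt(k).  Region-level
BH adjustment yields region_q.

A region overlaps a gene iff the 1-based inclusive intervals share at
least one base.  Per-gene summaries count the gene's own significant
probes that fall inside overlapping regions (differentially methylated
probes, DMPs) and the proportion of those with increased methylation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffstats import DifferentialResults, bh_adjust

P_FLOOR = 1e-300  # guards the inverse-normal transform

REGION_COLUMNS = ["chrom", "start", "end", "n_probes", "stat",
                  "region_p", "region_q", "probe_ids"]


def call_dmrs(
    probe_results: DifferentialResults | pd.DataFrame,
    annotation: pd.DataFrame,
    lambda_bp: int = 1_000,
    min_probes: int = 2,
    probe_fdr: float = 0.001,
) -> pd.DataFrame:
    """Merge significant probes into regions; one row per region.

    ``annotation`` must carry chrom / start / end / probe_id / gene for every
    probe in the results (1-based inclusive; probes are single positions).
    """
    table = probe_results.table if isinstance(probe_results, DifferentialResults) \
        else probe_results
    ann = annotation.set_index("probe_id")
    unknown = table.index.difference(ann.index)
    if len(unknown):
        raise ValueError(f"probe {unknown[0]!r} missing from the annotation")

    sig = table[table["q"] <= probe_fdr]
    if sig.empty:
        return pd.DataFrame(columns=REGION_COLUMNS)

    probes = ann.loc[sig.index, ["chrom", "start"]].copy()
    probes["p"] = sig["p"].to_numpy()
    probes["logFC"] = sig["logFC"].to_numpy()
    probes = probes.sort_values(["chrom", "start"], kind="mergesort")

    rows = []
    for chrom, grp in probes.groupby("chrom", sort=True):
        pos = grp["start"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > lambda_bp) + 1
        for run in np.split(np.arange(len(grp)), breaks):
            if len(run) < min_probes:
                continue
            sub = grp.iloc[run]
            p = np.clip(sub["p"].to_numpy(), P_FLOOR, 1.0)
            z = stats.norm.isf(p / 2.0) * np.sign(sub["logFC"].to_numpy())
            stat = np.abs(z.sum()) / np.sqrt(len(z))
            rows.append({
                "chrom": chrom,
                "start": int(sub["start"].min()),
                "end": int(sub["start"].max()),
                "n_probes": len(sub),
                "stat": stat,
                "region_p": float(stats.norm.sf(stat)),
                "probe_ids": ",".join(sub.index),
            })
    if not rows:
        return pd.DataFrame(columns=REGION_COLUMNS)
    regions = pd.DataFrame(rows)
    regions["region_q"] = bh_adjust(regions["region_p"].to_numpy())
    return regions[REGION_COLUMNS]


def overlap_genes(
    regions: pd.DataFrame,
    gene_intervals: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    probe_results: DifferentialResults | pd.DataFrame | None = None,
    probe_fdr: float = 0.001,
) -> pd.DataFrame:
    """Per overlapped gene: region list, DMP count, proportion hyper-methylated.

    Returns a DataFrame indexed by gene with columns ``regions`` (list of
    region row indices), ``n_dmps_in_dmrs`` and ``prop_pos_beta``.  Genes
    overlapping no region are absent.  DMP summaries need ``annotation`` and
    ``probe_results``; without them the counts are NaN.
    """
    if regions.empty:
        return pd.DataFrame(columns=["regions", "n_dmps_in_dmrs", "prop_pos_beta"])

    r_chrom = regions["chrom"].to_numpy()
    r_start = regions["start"].to_numpy()
    r_end = regions["end"].to_numpy()
    g_chrom = gene_intervals["chrom"].to_numpy()
    g_start = gene_intervals["start"].to_numpy()
    g_end = gene_intervals["end"].to_numpy()

    # 1-based inclusive intersection, vectorized region x gene
    hits = (
        (r_chrom[:, None] == g_chrom[None, :])
        & (r_start[:, None] <= g_end[None, :])
        & (g_start[None, :] <= r_end[:, None])
    )

    dmp_table = None
    if annotation is not None and probe_results is not None:
        table = probe_results.table if isinstance(probe_results, DifferentialResults) \
            else probe_results
        ann = annotation.set_index("probe_id")
        sig = table[table["q"] <= probe_fdr]
        dmp_table = ann.loc[ann.index.intersection(sig.index)].copy()
        dmp_table["logFC"] = sig.loc[dmp_table.index, "logFC"]

    out_rows = {}
    for gi, gene in enumerate(gene_intervals["gene"]):
        region_idx = np.flatnonzero(hits[:, gi])
        if region_idx.size == 0:
            continue
        n_dmps = np.nan
        prop_pos = np.nan
        if dmp_table is not None:
            own = dmp_table[dmp_table["gene"] == gene]
            if len(own):
                inside = np.zeros(len(own), dtype=bool)
                for ri in region_idx:
                    inside |= (
                        (own["chrom"].to_numpy() == r_chrom[ri])
                        & (own["start"].to_numpy() >= r_start[ri])
                        & (own["start"].to_numpy() <= r_end[ri])
                    )
                own = own[inside]
            n_dmps = int(len(own))
            prop_pos = float((own["logFC"] > 0).mean()) if n_dmps else 0.0
        out_rows[gene] = {
            "regions": region_idx.tolist(),
            "n_dmps_in_dmrs": n_dmps,
            "prop_pos_beta": prop_pos,
        }
    out = pd.DataFrame.from_dict(out_rows, orient="index")
    out.index.name = "gene"
    return out


def dmr_gene_set(
    probe_results: DifferentialResults | pd.DataFrame,
    annotation: pd.DataFrame,
    gene_intervals: pd.DataFrame,
    lambda_bp: int = 1_000,
    min_probes: int = 2,
    probe_fdr: float = 0.001,
) -> set[str]:
    """Convenience: the set of genes overlapped by any DMR."""
    regions = call_dmrs(probe_results, annotation, lambda_bp=lambda_bp,
                        min_probes=min_probes, probe_fdr=probe_fdr)
    overlap = overlap_genes(regions, gene_intervals, annotation, probe_results,
                            probe_fdr=probe_fdr)
    return set(overlap.index)
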