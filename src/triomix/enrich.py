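"""Integrative cross-omics gene-set enrichment.

Per layer, enrichment of each gene set in the significant-gene list is a
one-sided hypergeometric test against the layer's testable universe.  The
three per-layer P-values are combined with Fisher's method (X^2 = -2 sum
ln p, reference chi^2 with 6 df), and final inference uses a randomization
FDR: per randomization the per-layer significant labels are independently
re-drawn over the universe (preserving list sizes), all combined statistics
recomputed, and each set's integrative q is the BH-style empirical ratio
(mean null count at or below its combined p) / (observed count), clipped to
[0, 1] and monotonized.  Support filters then drop sets enriched on only
one layer or with fewer than five contributing genes on at least two layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import read_gmt, write_gmt

P_FLOOR = 1e-300
LAYER_ORDER = ("methylation", "rna", "protein")


@dataclass
class GeneSetCollection:
    """Named gene sets plus the per-layer testable universes."""

    sets: dict[str, set[str]]
    universes: dict[str, set[str]]

    def __post_init__(self) -> None:
        if not self.universes:
            raise ValueError("at least one layer universe is required")
        union = set().union(*self.universes.values())
        self.sets = {
            name: members & union for name, members in self.sets.items()
        }
        empty = [n for n, m in self.sets.items() if not m]
        for n in empty:
            del self.sets[n]

    @classmethod
    def from_gmt(cls, path: str | Path,
                 universes: dict[str, set[str]]) -> "GeneSetCollection":
        return cls(read_gmt(path), universes)

    def to_gmt(self, path: str | Path) -> None:
        write_gmt(self.sets, path)


def hypergeom_enrich(sig_genes: set[str], term_genes: set[str],
                     universe: set[str]) -> tuple[int, float, float]:
    """Overlap count N, fold-change enrichment and one-sided hypergeometric P.

    N = |sig & term|; expected = |sig|*|term|/|universe|; FC = N/expected;
    p = P(X >= N) with X hypergeometric (exact summation).  FC is NaN when
    the expectation is zero.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not sig_genes <= universe or not term_genes <= universe:
        raise ValueError("significant and term genes must lie in the universe")
    m = len(universe)
    k_sig = len(sig_genes)
    k_term = len(term_genes)
    n_obs = len(sig_genes & term_genes)
    expected = k_sig * k_term / m
    fc = n_obs / expected if expected > 0 else np.nan
    p = float(stats.hypergeom.sf(n_obs - 1, m, k_term, k_sig))
    return n_obs, fc, p


def combine_levels(p_values: np.ndarray | list[float]) -> tuple[float, float]:
    """Fisher's statistic and its chi^2 (2k df) reference P for k levels."""
    p = np.clip(np.asarray(p_values, dtype=float), P_FLOOR, 1.0)
    x2 = float(-2.0 * np.log(p).sum())
    return x2, float(stats.chi2.sf(x2, 2 * p.size))


def _layer_enrichment(sig: set[str], collection: GeneSetCollection,
                      layer: str) -> pd.DataFrame:
    universe = collection.universes[layer]
    sig = sig & universe
    rows = {}
    for name, members in collection.sets.items():
        term = members & universe
        if term:
            n, fc, p = hypergeom_enrich(sig, term, universe)
        else:
            n, fc, p = 0, np.nan, 1.0
        rows[name] = {"N": n, "FC": fc, "p": p}
    return pd.DataFrame.from_dict(rows, orient="index")


def _null_combined_p(collection: GeneSetCollection, layers: list[str],
                     sig_sizes: dict[str, int], n_rand: int,
                     rng: np.random.Generator) -> np.ndarray:
    """(n_rand, n_sets) matrix of combined P under label randomization."""
    set_names = list(collection.sets)
    x2_null = np.zeros((n_rand, len(set_names)))
    for layer in layers:
        universe = sorted(collection.universes[layer])
        m = len(universe)
        k_sig = sig_sizes[layer]
        gene_pos = {g: i for i, g in enumerate(universe)}
        membership = np.zeros((len(set_names), m), dtype=bool)
        for si, name in enumerate(set_names):
            for g in collection.sets[name] & collection.universes[layer]:
                membership[si, gene_pos[g]] = True
        k_term = membership.sum(axis=1)
        n_null = np.empty((n_rand, len(set_names)), dtype=np.int64)
        for r in range(n_rand):
            draw = rng.permutation(m)[:k_sig]
            n_null[r] = membership[:, draw].sum(axis=1)
        p_null = stats.hypergeom.sf(n_null - 1, m, k_term[None, :], k_sig)
        p_null = np.where(k_term[None, :] > 0, p_null, 1.0)
        x2_null += -2.0 * np.log(np.clip(p_null, P_FLOOR, 1.0))
    df = 2 * len(layers)
    return stats.chi2.sf(x2_null, df)


def randomization_fdr(
    observed_p: np.ndarray,
    null_p: np.ndarray,
) -> np.ndarray:
    """Empirical BH-style FDR of observed combined P against a null matrix.

    q_i = (mean over randomizations of #{null <= p_i}) / #{observed <= p_i},
    clipped to [0, 1] and monotonized from least to most significant.
    """
    observed_p = np.asarray(observed_p, dtype=float)
    n_sets = observed_p.size
    order = np.argsort(observed_p, kind="stable")
    q = np.empty(n_sets)
    sorted_null = np.sort(null_p.ravel())
    sorted_obs = np.sort(observed_p)
    n_rand = null_p.shape[0]
    for idx in order:
        null_count = np.searchsorted(sorted_null, observed_p[idx], side="right")
        obs_count = np.searchsorted(sorted_obs, observed_p[idx], side="right")
        q[idx] = (null_count / n_rand) / obs_count
    q = np.clip(q, 0.0, 1.0)
    # monotonize: a more significant set never gets a larger q
    running = 1.0
    for idx in order[::-1]:
        running = min(running, q[idx])
        q[idx] = running
    return q


def support_filter(records: pd.DataFrame, per_layer_alpha: float = 0.05,
                   min_genes: int = 5, min_layers: int = 2) -> pd.Series:
    """Reason a set fails the multi-layer support rule (``none`` = passes).

    Passing requires per-layer enrichment p < alpha on at least
    ``min_layers`` layers AND overlap N >= ``min_genes`` on at least
    ``min_layers`` layers.
    """
    p_cols = [c for c in records.columns
              if c.endswith("_p") and c != "combined_p"]
    n_cols = [c.replace("_p", "_N") for c in p_cols]
    n_enriched = (records[p_cols] < per_layer_alpha).sum(axis=1)
    n_supported = (records[n_cols].to_numpy() >= min_genes).sum(axis=1)
    reason = pd.Series("none", index=records.index, dtype=object)
    reason[n_supported < min_layers] = "insufficient-support"
    reason[n_enriched < min_layers] = "single-layer-only"
    return reason


def integrative_enrichment(
    sig_per_layer: dict[str, set[str]],
    collection: GeneSetCollection,
    n_rand: int = 1_000,
    seed: int = 0,
    per_layer_alpha: float = 0.05,
    min_support_genes: int = 5,
    min_support_layers: int = 2,
) -> pd.DataFrame:
    """Full integrative analysis: one row per gene set (a Table-2-style record).

    Columns: per layer N / FC / p, combined_stat, combined_p, integrative_q,
    filtered_reason.
    """
    if n_rand < 100:
        raise ValueError("n_rand must be >= 100 for a usable empirical FDR")
    layers = [l for l in LAYER_ORDER if l in sig_per_layer] or list(sig_per_layer)
    per_layer = {}
    for layer in layers:
        if layer not in collection.universes:
            raise ValueError(f"no universe defined for layer {layer!r}")
        per_layer[layer] = _layer_enrichment(set(sig_per_layer[layer]),
                                             collection, layer)
    set_names = list(collection.sets)
    records = pd.DataFrame(index=pd.Index(set_names, name="set"))
    for layer in layers:
        records[f"{layer}_N"] = per_layer[layer]["N"]
        records[f"{layer}_FC"] = per_layer[layer]["FC"]
        records[f"{layer}_p"] = per_layer[layer]["p"]
    p_matrix = records[[f"{l}_p" for l in layers]].to_numpy()
    combined = [combine_levels(row) for row in p_matrix]
    records["combined_stat"] = [c[0] for c in combined]
    records["combined_p"] = [c[1] for c in combined]

    rng = np.random.default_rng(seed)
    sig_sizes = {
        l: len(set(sig_per_layer[l]) & collection.universes[l]) for l in layers
    }
    if records.empty or all(v == 0 for v in sig_sizes.values()):
        records["integrative_q"] = 1.0
    else:
        null_p = _null_combined_p(collection, layers, sig_sizes, n_rand, rng)
        records["integrative_q"] = randomization_fdr(
            records["combined_p"].to_numpy(), null_p)
    records["filtered_reason"] = support_filter(
        records, per_layer_alpha=per_layer_alpha,
        min_genes=min_support_genes, min_layers=min_support_layers)
    return records.sort_values("combined_p", kind="mergesort")
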