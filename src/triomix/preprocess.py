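"""Layer-specific normalisation applied before differential analysis.

Protein abundances are scaled by each sample's total, log2-transformed and
quantile normalized; analysis is restricted to features quantified in every
sample (complete cases).  Methylation beta values are converted to M-values,
M = log2(beta / (1 - beta)).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .layers import LayerError, OmicsLayer

logger = logging.getLogger(__name__)


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Map every column to the mean of the column-wise sorted vectors.

    Ties within a column receive the mean of the reference values at their
    rank positions (average-rank dialect), so tied inputs stay tied.
    """
    arr = values.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("quantile normalization requires a complete matrix")
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    n = arr.shape[0]
    for j in range(arr.shape[1]):
        order = np.argsort(arr[:, j], kind="stable")
        ref_assigned = np.empty(n)
        ref_assigned[order] = reference
        # average the reference over tied input values
        col = pd.Series(ref_assigned).groupby(pd.Series(arr[:, j])).transform("mean")
        out[:, j] = col.to_numpy()
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def normalize_protein(layer: OmicsLayer, epsilon: float = 0.0) -> OmicsLayer:
    """Sum-scale each sample to 1, log2-transform, quantile-normalize.

    ``epsilon`` is an optional offset added before the log for user data
    containing zeros; with complete-case filtering of positive abundances
    it is not needed and defaults to 0.
    """
    if layer.scale != "raw":
        raise LayerError("normalize_protein expects a raw-abundance layer")
    vals = layer.values
    arr = vals.to_numpy(dtype=float)
    if np.nanmin(arr) < 0:
        raise LayerError("protein abundances must be non-negative")
    colsums = np.nansum(arr, axis=0)
    zero = np.flatnonzero(colsums <= 0)
    if zero.size:
        raise LayerError(f"sample {vals.columns[zero[0]]!r} has zero total abundance")
    fractions = arr / colsums
    with np.errstate(divide="ignore"):
        logged = np.log2(fractions + epsilon)
    if not np.all(np.isfinite(logged[~np.isnan(arr)])):
        raise LayerError(
            "zero abundances encountered; filter incomplete features first "
            "or pass a positive epsilon"
        )
    qn = quantile_normalize(pd.DataFrame(logged, index=vals.index,
                                         columns=vals.columns))
    return layer.with_values(qn, scale="log")


def filter_complete(layer: OmicsLayer) -> OmicsLayer:
    """Keep only features with no missing value in any sample (order kept)."""
    mask = layer.values.notna().all(axis=1)
    kept = layer.values.loc[mask]
    dropped = int((~mask).sum())
    if dropped:
        logger.info("filter_complete[%s]: dropped %d of %d features",
                    layer.name, dropped, len(mask))
    if kept.empty:
        logger.warning("filter_complete[%s]: no complete features remain",
                       layer.name)
    return layer.with_values(kept.copy())


def beta_to_m(layer: OmicsLayer) -> OmicsLayer:
    """Elementwise M = log2(beta / (1 - beta))."""
    if layer.scale != "beta":
        raise LayerError("beta_to_m expects a beta-scale layer")
    arr = layer.values.to_numpy(dtype=float)
    bad = (arr <= 0) | (arr >= 1)
    if bad[np.isfinite(arr)].any() if np.isnan(arr).any() else bad.any():
        raise LayerError("beta values at or beyond {0,1}; clip with clip_beta first")
    m = np.log2(arr / (1.0 - arr))
    return layer.with_values(
        pd.DataFrame(m, index=layer.values.index, columns=layer.values.columns),
        scale="m")


def clip_beta(values: pd.DataFrame, eps: float = 1e-6) -> pd.DataFrame:
    """Clip beta values into [eps, 1 - eps] ahead of the logit transform."""
    if not 0 < eps < 0.5:
        raise ValueError("eps must lie in (0, 0.5)")
    return values.clip(lower=eps, upper=1.0 - eps)
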