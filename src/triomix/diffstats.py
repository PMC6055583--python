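"""Paired differential analysis with empirical-Bayes variance moderation.

Each feature is tested for a difference between two tissue grades within
patients: with both grades present for every patient, the least-squares fit
with patient indicator covariates reduces to the one-sample analysis of the
within-patient differences, so

    logFC = mean of paired differences,   df = n_patients - 1.

Residual variances are shrunk toward a common prior (Smyth-style): the
prior df ``d0`` and prior variance ``s0^2`` are estimated by method of
moments on log s^2 (closed form via trigamma inversion), and the moderated
t-statistic ``t = logFC / (s_tilde / sqrt(n))`` is referred to a
t-distribution with ``d0 + df`` degrees of freedom.  Benjamini-Hochberg
adjustment is applied per layer and contrast.

The surface follows the Model/Results convention: build a
:class:`PairedDifferential` from a layer and a contrast, call ``fit()``,
and read estimates off the returned :class:`DifferentialResults`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq
from statsmodels.stats.multitest import multipletests

from .layers import LayerError, OmicsLayer, resolve_contrast


def paired_differences(layer: OmicsLayer, contrast: str | tuple[str, str]) -> pd.DataFrame:
    """Feature x patient matrix of within-patient differences (A - B)."""
    label, grade_a, grade_b = resolve_contrast(contrast)
    layer.check_paired((grade_a, grade_b))
    a = layer.grade_matrix(grade_a)
    b = layer.grade_matrix(grade_b)
    return a - b


def paired_fit(layer: OmicsLayer, contrast: str | tuple[str, str]) -> pd.DataFrame:
    """Per-feature paired estimates: logFC, residual variance s2, df_resid.

    Equivalent to the per-feature least-squares fit with patient covariates
    restricted to the two grades of the contrast.
    """
    diffs = paired_differences(layer, contrast)
    n = diffs.shape[1]
    if n < 2:
        raise LayerError("paired fit needs at least 2 patients")
    d = diffs.to_numpy(dtype=float)
    if np.isnan(d).any():
        raise LayerError("missing values in paired differences; filter first")
    logfc = d.mean(axis=1)
    s2 = d.var(axis=1, ddof=1)
    return pd.DataFrame(
        {"logFC": logfc, "s2": s2, "df_resid": float(n - 1), "n_pairs": n},
        index=diffs.index,
    )


# ------------------------------------------------------------ eBayes pieces
def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton with a bracketing fallback)."""
    if y <= 0:
        raise ValueError("trigamma is positive; y must be > 0")
    # Newton iteration on the monotone decreasing trigamma
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            return float(x)
    # fallback: bisection-style bracketing
    return float(brentq(lambda v: special.polygamma(1, v) - y, 1e-8, 1e8,
                        xtol=1e-12, rtol=1e-12))


def estimate_prior(s2: np.ndarray, df_resid: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from the spread of log s2.

    Models s2 ~ s0^2 * F(df_resid, d0).  If the observed spread of log s2
    does not exceed what df_resid alone explains, d0 = inf (all features
    share one variance).
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.size < 2:
        raise ValueError("need at least 2 features to estimate the prior")
    positive = s2[s2 > 0]
    if positive.size < 2:
        raise ValueError("need at least 2 positive residual variances")
    z = np.log(positive)
    e = z - special.digamma(df_resid / 2.0) + np.log(df_resid / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1)
    target = evar - special.polygamma(1, df_resid / 2.0)
    if target <= 1e-12:
        return np.inf, float(np.mean(positive))
    d0 = 2.0 * trigamma_inverse(target)
    s02 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s02)


def ebayes_moderate(
    s2: np.ndarray,
    df_resid: float,
    logfc: np.ndarray,
    se_scale: float,
    d0: float | None = None,
    s02: float | None = None,
) -> pd.DataFrame:
    """Moderated t, two-sided P and total df for each feature.

    ``se_scale`` converts a residual SD into the standard error of logFC
    (1/sqrt(n) for a paired mean difference).  ``d0``/``s02`` may be forced,
    e.g. ``d0=0`` recovers the ordinary paired t and ``d0=inf`` the
    pooled-variance z-like statistic.
    """
    s2 = np.asarray(s2, dtype=float)
    logfc = np.asarray(logfc, dtype=float)
    if d0 is None:
        d0, s02_est = estimate_prior(s2, df_resid)
        if s02 is None:
            s02 = s02_est
    elif s02 is None:
        # prior variance only matters when the prior carries weight
        s02 = 0.0 if d0 == 0 else estimate_prior(s2, df_resid)[1]

    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_post) * se_scale
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, logfc / se, np.where(logfc == 0, 0.0,
                                                      np.sign(logfc) * np.inf))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
        tq = stats.norm.ppf(0.975)
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
        tq = stats.t.ppf(0.975, df_total)
    return pd.DataFrame({
        "t": t_mod,
        "p": p,
        "df_total": df_total,
        "s2_post": s2_post,
        "ci_lo": logfc - tq * se,
        "ci_hi": logfc + tq * se,
    })


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, in [0, 1])."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.isnan(arr).any() or arr.min() < 0 or arr.max() > 1:
        raise ValueError("p-values must lie in [0, 1] with no missing entries")
    _, q, _, _ = multipletests(arr, method="fdr_bh")
    return q


# ------------------------------------------------------------ Model/Results
class PairedDifferential:
    """Paired differential-expression model for one layer and contrast.

    Examples
    --------
    >>> model = PairedDifferential(layer, "O_vs_L")
    >>> res = model.fit()
    >>> res.significant(fdr=0.001)
    """

    def __init__(self, layer: OmicsLayer, contrast: str | tuple[str, str]):
        self.layer = layer
        self.contrast = resolve_contrast(contrast)[0]

    @classmethod
    def from_dataframe(cls, values: pd.DataFrame, name: str,
                       contrast: str | tuple[str, str],
                       scale: str = "log") -> "PairedDifferential":
        return cls(OmicsLayer(name, values, scale), contrast)

    def fit(self, moderate: bool = True, d0: float | None = None,
            s02: float | None = None) -> "DifferentialResults":
        base = paired_fit(self.layer, self.contrast)
        n = int(base["n_pairs"].iloc[0])
        df_resid = float(base["df_resid"].iloc[0])
        if not moderate:
            d0 = 0.0
        mod = ebayes_moderate(base["s2"].to_numpy(), df_resid,
                              base["logFC"].to_numpy(), 1.0 / np.sqrt(n),
                              d0=d0, s02=s02)
        table = pd.DataFrame({
            "logFC": base["logFC"],
            "s2": base["s2"],
            "t": mod["t"].to_numpy(),
            "df_total": mod["df_total"].to_numpy(),
            "p": mod["p"].to_numpy(),
            "q": bh_adjust(mod["p"].to_numpy()),
            "ci_lo": mod["ci_lo"].to_numpy(),
            "ci_hi": mod["ci_hi"].to_numpy(),
        }, index=base.index)
        fitted_d0 = float(mod["df_total"].iloc[0] - df_resid) if np.isfinite(
            mod["df_total"].iloc[0]) else np.inf
        return DifferentialResults(
            table=table, layer=self.layer.name, contrast=self.contrast,
            n_pairs=n, d0=fitted_d0,
        )


@dataclass
class DifferentialResults:
    """Per-feature paired-contrast statistics for one omics layer."""

    table: pd.DataFrame
    layer: str
    contrast: str
    n_pairs: int
    d0: float

    @property
    def features(self) -> pd.Index:
        return self.table.index

    def significant(self, fdr: float = 0.05) -> pd.Index:
        """Features with q <= fdr (the classical BH rejection set)."""
        if not 0 < fdr <= 1:
            raise ValueError("fdr threshold must lie in (0, 1]")
        return self.table.index[self.table["q"] <= fdr]

    def summary(self, fdr: tuple[float, ...] = (0.001, 0.05), top: int = 5) -> str:
        lines = [
            f"Paired differential analysis: layer={self.layer} "
            f"contrast={self.contrast}",
            f"  features: {len(self.table)}   pairs: {self.n_pairs}   "
            f"prior df d0: {self.d0:.3g}",
        ]
        for f in fdr:
            lines.append(f"  significant at {f * 100:g}% FDR: "
                         f"{len(self.significant(f))}")
        head = self.table.nsmallest(top, "q")
        lines.append("  top features (by q):")
        for feat, row in head.iterrows():
            lines.append(
                f"    {feat}: logFC={row['logFC']:+.3f} t={row['t']:+.2f} "
                f"p={row['p']:.3g} q={row['q']:.3g}"
            )
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        cols = ["logFC", "t", "p", "q", "ci_lo", "ci_hi"]
        self.table[cols].to_csv(path, sep="\t", index_label="feature")

    @classmethod
    def from_tsv(cls, path: str | Path, layer: str, contrast: str,
                 n_pairs: int = 0, d0: float = np.nan) -> "DifferentialResults":
        table = pd.read_csv(path, sep="\t", index_col="feature")
        return cls(table=table, layer=layer, contrast=contrast,
                   n_pairs=n_pairs, d0=d0)


def significant_features(result: DifferentialResults, fdr: float) -> set[str]:
    """Functional alias for :meth:`DifferentialResults.significant`."""
    return set(result.significant(fdr))
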