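"""Two-group differential expression with empirical-Bayes moderation.

Per-gene pooled-variance t-tests between two molecular subtypes, with
gene-wise variances shrunk toward an inverse-gamma prior fitted across all
genes (the standard moderated-t construction for log-scale expression).
The DEG filter keeps genes with |log2FC| >= 0.5 (inclusive) and raw
p < 0.05 (strict); BH-adjusted FDR is reported alongside for transparency
but is not part of the filter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datasets import ExpressionMatrix
from .errors import InputError

__all__ = ["moderated_t_test", "filter_degs", "fit_variance_prior"]


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(variances: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square prior.

    Returns (prior_df d0, prior_variance s0^2).  d0 may be inf when the
    observed log-variances are less dispersed than pure chi-square noise,
    in which case every posterior variance equals s0^2.
    """
    v = np.asarray(variances, dtype=float)
    v = v[v > 0]
    if v.size < 2:
        return 0.0, float(np.mean(variances)) if len(variances) else 1.0
    z = np.log(v)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = np.mean((e - emean) ** 2) * v.size / (v.size - 1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(emean)
    return float(d0), float(s0_sq)


def moderated_t_test(X: ExpressionMatrix | pd.DataFrame | np.ndarray,
                     labels: np.ndarray,
                     prior_df: float | None = None) -> pd.DataFrame:
    """Moderated t-test of every gene between two groups.

    Parameters
    ----------
    X : genes x samples log2 expression.
    labels : two-level per-sample group labels; log2FC is the mean of the
        higher-sorted level minus the mean of the lower-sorted level.
    prior_df : force the prior degrees of freedom (0 disables moderation
        and recovers the ordinary pooled t-test); None estimates it from
        the data.

    Returns a DataFrame with columns gene_id, log2FC, t_stat, p_value,
    fdr, zero_variance, in input gene order.
    """
    if isinstance(X, ExpressionMatrix):
        gene_ids, values = X.gene_ids, X.values
    elif isinstance(X, pd.DataFrame):
        gene_ids, values = list(X.index), X.to_numpy(dtype=float)
    else:
        values = np.asarray(X, dtype=float)
        gene_ids = [f"g{i}" for i in range(values.shape[0])]

    labels = np.asarray(labels)
    levels = np.unique(labels)
    if len(levels) != 2:
        raise InputError(f"exactly two groups required, got {len(levels)}")
    m1 = labels == levels[0]
    m2 = labels == levels[1]
    n1, n2 = int(m1.sum()), int(m2.sum())
    if n1 < 2 or n2 < 2:
        raise InputError("each group needs at least 2 samples")
    if values.shape[1] != len(labels):
        raise InputError("label length does not match sample count")

    x1, x2 = values[:, m1], values[:, m2]
    mean1, mean2 = x1.mean(axis=1), x2.mean(axis=1)
    lfc = mean2 - mean1
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * x1.var(axis=1, ddof=1) + (n2 - 1) * x2.var(axis=1, ddof=1)) / df

    if prior_df is None:
        d0, s0_sq = fit_variance_prior(pooled, df)
    elif prior_df == 0:
        d0, s0_sq = 0.0, 0.0
    else:
        d0 = float(prior_df)
        _, s0_sq = fit_variance_prior(pooled, df)

    if np.isinf(d0):
        post_var = np.full_like(pooled, s0_sq)
        total_df = np.inf
    else:
        post_var = (d0 * s0_sq + df * pooled) / (d0 + df)
        total_df = df + d0

    # no within-group variation in either group (relative rounding threshold)
    zero_var = pooled <= (1e-12 * np.maximum(1.0, np.abs(mean1) + np.abs(mean2))) ** 2
    se = np.sqrt(post_var * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
        t = np.where((se == 0) & (lfc != 0), np.sign(lfc) * np.inf, t)
    if np.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
    p = np.where(zero_var & (lfc == 0), 1.0, p)
    p = np.clip(p, 0.0, 1.0)

    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({
        "gene_id": gene_ids,
        "log2FC": lfc,
        "t_stat": t,
        "p_value": p,
        "fdr": fdr,
        "zero_variance": zero_var,
    })


def filter_degs(table: pd.DataFrame, lfc_min: float = 0.5,
                p_max: float = 0.05) -> list[str]:
    """Keep genes with |log2FC| >= lfc_min and p_value < p_max.

    The fold-change bound is inclusive and the p bound strict; the result
    is ordered by ascending p-value.  An empty result is allowed.
    """
    if table.empty:
        raise InputError("DEG table is empty")
    keep = table[(table["log2FC"].abs() >= lfc_min) & (table["p_value"] < p_max)]
    return list(keep.sort_values("p_value", kind="stable")["gene_id"])
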