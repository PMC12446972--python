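"""Moderated two-group differential abundance with BH control.

The ``eb`` mode implements an empirical-Bayes moderated t-statistic: the
per-feature pooled variance ``s^2`` (residual df ``d``) is shrunk towards
a prior ``(d0, s0^2)`` estimated across features by the method of moments
on ``log s^2`` (the expectation/variance of the log of a scaled
chi-square), giving the posterior variance

    s~^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

and a t-statistic on ``d0 + d`` degrees of freedom. When the observed
spread of ``log s^2`` is no larger than chi-square sampling noise, the
prior df is infinite and the test reduces to a z-test against the common
variance ``s0^2``. ``welch`` mode is an unmoderated cross-check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .io import QuantMatrix


def _trigamma(x: np.ndarray | float) -> np.ndarray | float:
    return special.polygamma(1, x)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (y > 0); returns inf for y <= 0."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    lo, hi = 1e-8, 1e12
    return float(optimize.brentq(lambda x: _trigamma(x) - y, lo, hi, xtol=1e-12))


def estimate_variance_prior(
    s2: np.ndarray, df: np.ndarray
) -> tuple[float, float]:
    """Method-of-moments prior (d0, s0^2) from per-feature variances.

    Works on ``log s^2``: subtracting the known chi-square log-moment
    terms leaves a sample whose excess variance over ``trigamma(df/2)``
    identifies ``trigamma(d0/2)``.
    """
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise ValueError("need at least 2 features with positive variance")
    s2 = s2[ok]
    df = df[ok].astype(float)
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = e.var(ddof=1) - np.mean(_trigamma(df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(e.mean()))
    half_d0 = _trigamma_inverse(evar)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(e.mean() + special.digamma(half_d0) - np.log(half_d0)))
    return float(d0), s0_sq


def moderated_ttest(
    qm: QuantMatrix | pd.DataFrame,
    group1: list[str],
    group2: list[str],
    moderation: str = "eb",
    alpha: float = 0.05,
    fc_threshold: float = 1.5,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> pd.DataFrame:
    """Two-group differential abundance on a log2 matrix.

    ``log2fc`` is group1 minus group2. Missing values are handled
    complete-case per feature. ``prior_df`` / ``prior_var`` override the
    estimated prior (``prior_df=0`` recovers the ordinary pooled t-test,
    ``prior_df=inf`` a z-test against ``prior_var``).
    """
    if moderation not in ("eb", "welch"):
        raise ValueError(f"unknown moderation {moderation!r}")
    data = qm.data if isinstance(qm, QuantMatrix) else qm
    X1 = data[list(group1)].to_numpy(dtype=float)
    X2 = data[list(group2)].to_numpy(dtype=float)
    if X1.shape[1] < 2 or X2.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")

    import warnings as _warnings

    n1 = (~np.isnan(X1)).sum(axis=1).astype(float)
    n2 = (~np.isnan(X2)).sum(axis=1).astype(float)
    with np.errstate(all="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(X1, axis=1)
        m2 = np.nanmean(X2, axis=1)
        v1 = np.nanvar(X1, axis=1, ddof=1)
        v2 = np.nanvar(X2, axis=1, ddof=1)
    fc = m1 - m2
    valid = (n1 >= 2) & (n2 >= 2)

    t = np.full(data.shape[0], np.nan)
    p = np.full(data.shape[0], np.nan)
    df_total = np.full(data.shape[0], np.nan)
    degenerate = np.zeros(data.shape[0], dtype=bool)

    if moderation == "eb":
        d = n1 + n2 - 2.0
        v1z = np.where(n1 >= 2, v1, 0.0)
        v2z = np.where(n2 >= 2, v2, 0.0)
        with np.errstate(all="ignore"):
            s2 = ((n1 - 1) * v1z + (n2 - 1) * v2z) / d
        if prior_df is None or prior_var is None:
            d0_est, s0_est = estimate_variance_prior(
                np.where(valid, s2, np.nan), np.where(valid, d, 0.0)
            )
        else:
            d0_est, s0_est = np.nan, np.nan
        d0 = prior_df if prior_df is not None else d0_est
        s0 = prior_var if prior_var is not None else s0_est
        with np.errstate(all="ignore"):
            if np.isinf(d0):
                s2_post = np.full_like(s2, s0)
                df_t = np.full_like(s2, np.inf)
            else:
                s2_post = (d0 * s0 + d * s2) / (d0 + d)
                df_t = d0 + d
            se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
            tt = fc / se
        t = np.where(valid, tt, np.nan)
        df_total = np.where(valid, df_t, np.nan)
        finite_df = np.isfinite(df_total) & valid
        p = np.full_like(t, np.nan)
        p[finite_df] = 2.0 * stats.t.sf(np.abs(t[finite_df]), df_total[finite_df])
        inf_df = valid & ~np.isfinite(df_total)
        p[inf_df] = 2.0 * stats.norm.sf(np.abs(t[inf_df]))
        # exact null: zero pooled variance and zero posterior variance
        zero_var = valid & (se == 0)
        same = zero_var & (fc == 0)
        p[same], t[same] = 1.0, 0.0
        diff = zero_var & (fc != 0)
        p[diff] = 0.0
        t[diff] = np.where(fc[diff] > 0, np.inf, -np.inf)
        degenerate |= diff
    else:  # welch
        with np.errstate(all="ignore"):
            se2 = v1 / n1 + v2 / n2
            tt = fc / np.sqrt(se2)
            df_w = se2**2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        t = np.where(valid, tt, np.nan)
        df_total = np.where(valid, df_w, np.nan)
        ok = valid & np.isfinite(t) & np.isfinite(df_total) & (df_total > 0)
        p = np.full_like(t, np.nan)
        p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df_total[ok])
        zero_var = valid & (se2 == 0)
        same = zero_var & (fc == 0)
        p[same], t[same], df_total[same] = 1.0, 0.0, n1[same] + n2[same] - 2
        diff = zero_var & (fc != 0)
        p[diff] = 0.0
        t[diff] = np.where(fc[diff] > 0, np.inf, -np.inf)
        degenerate |= diff

    adj = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        adj[ok] = bh_adjust(p[ok])
    lfc_cut = np.log2(fc_threshold)
    significant = ok & (adj <= alpha) & (np.abs(fc) >= lfc_cut)
    return pd.DataFrame(
        {
            "log2fc": fc,
            "t_stat": t,
            "df_total": df_total,
            "p": p,
            "adj_p": adj,
            "significant": significant,
            "degenerate": degenerate,
        },
        index=data.index.rename("feature_id"),
    )


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``adj_(i) = min_{k >= i} min(1, m * p_(k) / k)`` over the ordered
    p-values; order-preserving and idempotent at the extremes.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def pc_unique_signature(
    da_vs_nat: pd.DataFrame,
    da_vs_tumor: pd.DataFrame,
    fc: float = 1.5,
    alpha: float = 0.05,
) -> tuple[set[str], set[str]]:
    """Features uniquely enriched/depleted in one compartment vs both others.

    Both tables must carry log2fc computed as "compartment minus other".
    ``up`` requires significance and log2fc >= log2(fc) in BOTH contrasts;
    ``down`` is symmetric. The returned sets are disjoint by construction.
    """
    common = da_vs_nat.index.intersection(da_vs_tumor.index)
    if len(common) < len(da_vs_nat.index) or len(common) < len(da_vs_tumor.index):
        import logging

        logging.getLogger(__name__).warning(
            "feature universes differ; intersecting to %d features", len(common)
        )
    if len(common) == 0:
        raise ValueError("no shared features between the two DA tables")
    a = da_vs_nat.loc[common]
    b = da_vs_tumor.loc[common]
    lfc = np.log2(fc)
    sig_a = (a["adj_p"] <= alpha) & np.isfinite(a["adj_p"])
    sig_b = (b["adj_p"] <= alpha) & np.isfinite(b["adj_p"])
    up = set(common[(sig_a & (a["log2fc"] >= lfc)) & (sig_b & (b["log2fc"] >= lfc))])
    down = set(
        common[(sig_a & (a["log2fc"] <= -lfc)) & (sig_b & (b["log2fc"] <= -lfc))]
    )
    return up, down
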