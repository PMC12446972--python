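"""Compartment-level structure of the protein matrix.

PCA embedding, monotone NAT -> PC -> TUMOR trend assignment, the
tumor-size correlation screen within the pseudocapsule, anchor-vs-panel
marker correlations per compartment, and peptide-protein fold-change
concordance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .da import bh_adjust
from .io import COMPARTMENTS, QuantMatrix

logger = logging.getLogger(__name__)


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    variance_explained: np.ndarray  # percent, non-increasing


def pca(qm: QuantMatrix, scale: bool = False, n_components: int | None = None) -> PCAResult:
    """Principal component analysis of samples on a complete log2 matrix.

    Samples are observations (matrix columns); features are centered
    (and standardized if ``scale``). Sign convention: the
    largest-magnitude loading of each component is positive.
    """
    X = qm.values.T  # samples x features
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; impute before PCA")
    if X.shape[0] < 3:
        raise ValueError("PCA needs at least 3 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(X.shape) if n_components is None else min(n_components, min(X.shape))
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # deterministic sign: largest |loading| positive per component
    for i in range(k):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    scores = U * s
    var = s**2 / np.sum(np.var(Xc, axis=0, ddof=0)) / X.shape[0] * 100.0
    comp_names = [f"PC{i+1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=qm.sample_ids, columns=comp_names),
        loadings=pd.DataFrame(Vt.T, index=qm.feature_ids, columns=comp_names),
        variance_explained=var,
    )


def trend_clusters(
    qm: QuantMatrix, metadata: pd.DataFrame, margin: float = 0.5
) -> pd.DataFrame:
    """Assign features to monotone abundance trends across compartments.

    Each feature is z-scored across samples; a feature is ``increasing``
    if its compartment means satisfy NAT <= PC <= TUMOR with a total span
    (TUMOR - NAT, in sd units) of at least ``margin``; ``decreasing`` is
    symmetric; anything else is ``none``.
    """
    meta = metadata.loc[qm.sample_ids]
    comp = meta["compartment"]
    for c in COMPARTMENTS:
        if (comp == c).sum() == 0:
            raise ValueError(f"compartment {c} absent from metadata")
    X = qm.values
    with np.errstate(all="ignore"):
        mu = np.nanmean(X, axis=1, keepdims=True)
        sd = np.nanstd(X, axis=1, ddof=1, keepdims=True)
        Z = (X - mu) / np.where(sd == 0, np.nan, sd)
    means = {}
    for c in COMPARTMENTS:
        cols = (comp == c).to_numpy()
        with np.errstate(all="ignore"):
            means[c] = np.nanmean(Z[:, cols], axis=1)
    m_nat, m_pc, m_tum = means["NAT"], means["PC"], means["TUMOR"]
    span = m_tum - m_nat
    inc = (m_nat <= m_pc) & (m_pc <= m_tum) & (span >= margin)
    dec = (m_nat >= m_pc) & (m_pc >= m_tum) & (-span >= margin)
    cluster = np.where(inc, "increasing", np.where(dec, "decreasing", "none"))
    cluster = np.where(
        np.isnan(m_nat) | np.isnan(m_pc) | np.isnan(m_tum), "none", cluster
    )
    # pooled within-compartment sd of the z-scores, for an effect size
    pooled = []
    comp_arr = comp.to_numpy()
    for c in COMPARTMENTS:
        cols = comp_arr == c
        with np.errstate(all="ignore"):
            pooled.append(np.nanvar(Z[:, cols], axis=1, ddof=1))
    pooled_sd = np.sqrt(np.nanmean(np.vstack(pooled), axis=0))
    with np.errstate(all="ignore"):
        effect = np.abs(span) / np.where(pooled_sd == 0, np.nan, pooled_sd)
    return pd.DataFrame(
        {
            "cluster": cluster,
            "mean_NAT": m_nat,
            "mean_PC": m_pc,
            "mean_TUMOR": m_tum,
            "effect_size": effect,
        },
        index=qm.data.index.rename("feature_id"),
    )


def _pearson_rows(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Pearson r of X (features x n) against y (n,), complete-case.

    Returns (r, p, n_used); constant rows give NaN r.
    """
    F, n = X.shape
    r = np.full(F, np.nan)
    pv = np.full(F, np.nan)
    n_used = np.zeros(F, dtype=int)
    for i in range(F):
        ok = ~np.isnan(X[i]) & ~np.isnan(y)
        m = int(ok.sum())
        n_used[i] = m
        if m < 3:
            continue
        xi, yi = X[i, ok], y[ok]
        sx, sy = xi.std(), yi.std()
        if sx == 0 or sy == 0:
            continue
        rr = float(np.corrcoef(xi, yi)[0, 1])
        rr = max(-1.0, min(1.0, rr))
        r[i] = rr
        if abs(rr) == 1.0:
            pv[i] = 0.0
        else:
            t = rr * np.sqrt((m - 2) / (1.0 - rr**2))
            pv[i] = 2.0 * stats.t.sf(abs(t), m - 2)
    return r, pv, n_used


def size_correlation(
    qm: QuantMatrix,
    diameters: pd.Series,
    alpha: float = 0.05,
    method: str = "pearson",
) -> pd.DataFrame:
    """Per-feature correlation of log2 abundance with tumor diameter.

    Intended for the pseudocapsule compartment: every sample inherits the
    diameter of its matched tumor lesion. Two-sided p from the t
    transform, BH across features, direction positive/negative/ns.
    Constant features are reported ``ns`` with ``constant=True``.
    """
    common = [s for s in qm.sample_ids if s in diameters.index]
    d = diameters.loc[common].to_numpy(dtype=float)
    ok = ~np.isnan(d)
    if ok.sum() < 5:
        raise ValueError("need at least 5 samples with diameters")
    X = qm.data[common].to_numpy(dtype=float)[:, ok]
    y = d[ok]
    if method == "spearman":
        y = stats.rankdata(y)
        Xr = np.full_like(X, np.nan)
        for i in range(X.shape[0]):
            m = ~np.isnan(X[i])
            Xr[i, m] = stats.rankdata(X[i, m])
        X = Xr
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    r, p, n_used = _pearson_rows(X, y)
    adj = np.full_like(p, np.nan)
    okp = np.isfinite(p)
    if okp.any():
        adj[okp] = bh_adjust(p[okp])
    direction = np.where(
        okp & (adj <= alpha) & (r > 0),
        "positive",
        np.where(okp & (adj <= alpha) & (r < 0), "negative", "ns"),
    )
    return pd.DataFrame(
        {
            "r": r,
            "p": p,
            "adj_p": adj,
            "direction": direction,
            "n": n_used,
            "constant": ~np.isfinite(r),
        },
        index=qm.data.index.rename("feature_id"),
    )


def marker_correlation(
    qm: QuantMatrix,
    metadata: pd.DataFrame,
    anchor: str,
    panel: list[str],
) -> pd.DataFrame:
    """Pearson r of an anchor feature vs each panel feature per compartment.

    Returns long form: compartment, panel feature, r, n. Panel features
    absent from the matrix give a missing cell with a warning.
    """
    if anchor not in qm.data.index:
        raise ValueError(f"anchor feature {anchor!r} not in matrix")
    meta = metadata.loc[qm.sample_ids]
    rows = []
    for compn in COMPARTMENTS:
        cols = meta.index[meta["compartment"] == compn]
        a = qm.data.loc[anchor, cols].to_numpy(dtype=float)
        for g in panel:
            if g not in qm.data.index:
                logger.warning("panel feature %s absent from matrix", g)
                rows.append(
                    {"compartment": compn, "feature": g, "r": np.nan, "n": 0}
                )
                continue
            b = qm.data.loc[g, cols].to_numpy(dtype=float)
            ok = ~np.isnan(a) & ~np.isnan(b)
            n = int(ok.sum())
            if n < 3 or a[ok].std() == 0 or b[ok].std() == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(a[ok], b[ok])[0, 1])
            rows.append({"compartment": compn, "feature": g, "r": r, "n": n})
    return pd.DataFrame(rows)


def peptide_protein_concordance(
    peptide_da: pd.DataFrame,
    protein_da: pd.DataFrame,
    mapping: pd.Series,
    fc: float = 1.5,
    alpha: float = 0.05,
) -> tuple[float, pd.DataFrame]:
    """Global peptide-vs-protein fold-change correlation + discordant list.

    ``mapping`` maps peptide id -> protein feature id. Discordant =
    peptide significant (adj p <= alpha and |log2fc| >= log2(fc)) while
    the parent protein is non-significant or changes in the opposite
    direction.
    """
    common = peptide_da.index.intersection(mapping.index)
    mapped = mapping.loc[common]
    mapped = mapped[mapped.isin(protein_da.index)]
    if mapped.empty:
        raise ValueError("no peptide maps to a protein present in the protein table")
    pep = peptide_da.loc[mapped.index]
    prot = protein_da.loc[mapped.to_numpy()]
    x = pep["log2fc"].to_numpy(dtype=float)
    y = prot["log2fc"].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() >= 3:
        r = float(np.corrcoef(x[ok], y[ok])[0, 1])
    else:
        r = float("nan")  # too few pairs for a meaningful global r

    lfc = np.log2(fc)
    pep_sig = (pep["adj_p"].to_numpy() <= alpha) & (np.abs(x) >= lfc)
    prot_sig = prot["significant"].to_numpy(dtype=bool)
    opposite = np.sign(x) * np.sign(y) < 0
    disc_mask = pep_sig & (~prot_sig | opposite) & ok
    discordant = pd.DataFrame(
        {
            "peptide_id": mapped.index[disc_mask],
            "protein": mapped.to_numpy()[disc_mask],
            "peptide_log2fc": x[disc_mask],
            "protein_log2fc": y[disc_mask],
            "protein_significant": prot_sig[disc_mask],
        }
    ).set_index("peptide_id")
    return r, discordant
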