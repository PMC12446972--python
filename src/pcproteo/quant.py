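"""Protein-level quantification from peptide intensities.

Roll-up follows the MaxLFQ idea: for every pair of samples, the protein
log-ratio is estimated as the median of the peptide-wise log2 differences
over peptides observed in both samples, and per-sample protein values are
the least-squares solution of the over-determined system
``v_i - v_j = r_ij``. Only proteotypic peptides are used. Two-tier
completeness filtering (a strict "core" tier requiring presence in every
compartment, and a permissive "extended" tier requiring presence in at
least one) and a left-shifted Gaussian MNAR imputation complete the
protein matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io import QuantMatrix, COMPARTMENTS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Two-tier completeness filtering thresholds.

    ``core``: presence fraction >= core_threshold in EACH compartment.
    ``extended``: presence fraction >= extended_threshold in AT LEAST ONE
    compartment (tolerates compartment-restricted expression).
    """

    mode: str = "core"
    core_threshold: float = 0.70
    extended_threshold: float = 0.50

    def __post_init__(self) -> None:
        if self.mode not in ("core", "extended"):
            raise ValueError(f"unknown filter mode {self.mode!r}")
        for t in (self.core_threshold, self.extended_threshold):
            if not (0 < t <= 1):
                raise ValueError("thresholds must lie in (0, 1]")


def rollup_maxlfq(peptide_log2: np.ndarray, min_shared: int = 1) -> np.ndarray:
    """Roll one protein's peptides up to a per-sample log2 profile.

    ``peptide_log2`` is peptides x samples with NaN for missing. Samples
    connected through shared peptides are solved jointly; each connected
    component is anchored so that the mean of the solved values over its
    samples equals the mean of the per-sample observed peptide means
    (the unweighted anchor makes the roll-up exactly shift-equivariant
    even under unbalanced missingness). Samples with no peptide data
    return NaN.
    """
    X = np.asarray(peptide_log2, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    n_pep, n_samp = X.shape
    obs = ~np.isnan(X)
    has_data = obs.any(axis=0)
    out = np.full(n_samp, np.nan)
    if not has_data.any():
        return out

    # pairwise median log-ratios over shared peptides
    diffs = X[:, :, None] - X[:, None, :]  # (P, S, S); diffs[p,i,j] = x_pi - x_pj
    shared = (obs[:, :, None] & obs[:, None, :]).sum(axis=0)
    import warnings

    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        R = np.nanmedian(diffs, axis=0)
    valid = (shared >= max(1, min_shared)) & ~np.eye(n_samp, dtype=bool)
    valid &= has_data[:, None] & has_data[None, :]

    adj = csr_matrix(valid.astype(np.int8))
    n_comp, labels = connected_components(adj, directed=False)
    for c in range(n_comp):
        members = np.where(labels == c)[0]
        members = members[has_data[members]]
        if members.size == 0:
            continue
        if members.size == 1:
            i = members[0]
            out[i] = np.nanmean(X[:, i])
            continue
        sub_valid = valid[np.ix_(members, members)]
        sub_R = np.where(sub_valid, R[np.ix_(members, members)], 0.0)
        # least squares on the graph Laplacian; minimal-norm solution has
        # zero mean over the component, then re-anchor to the data
        deg = sub_valid.sum(axis=1)
        L = np.diag(deg.astype(float)) - sub_valid.astype(float)
        b = sub_R.sum(axis=1)
        v, *_ = np.linalg.lstsq(L, b, rcond=None)
        v = v - v.mean()
        anchor = float(np.mean(np.nanmean(X[:, members], axis=0)))
        out[members] = v + anchor
    return out


def rollup_proteins(
    peptide_quant: QuantMatrix,
    peptide_info: pd.DataFrame,
    min_shared: int = 1,
) -> tuple[QuantMatrix, pd.DataFrame]:
    """Roll a full peptide matrix up to proteins, proteotypic peptides only.

    ``peptide_info`` must share the peptide index and carry
    ``protein_group``, ``gene`` and ``proteotypic`` columns. Proteins with
    zero proteotypic peptides are dropped with a warning. Returns the
    protein QuantMatrix (indexed by accession) and a feature table with
    gene symbols and peptide counts.
    """
    info = peptide_info.loc[peptide_quant.data.index]
    mask = info["proteotypic"].astype(bool)
    groups = info.loc[mask].groupby("protein_group", sort=True)
    dropped = set(info.loc[~mask, "protein_group"]) - set(groups.groups)
    if dropped:
        logger.warning(
            "%d protein group(s) had no proteotypic peptide and were dropped",
            len(dropped),
        )
    profiles = {}
    feat_rows = []
    for acc, idx in groups.groups.items():
        sub = peptide_quant.data.loc[idx].to_numpy(dtype=float)
        profiles[acc] = rollup_maxlfq(sub, min_shared=min_shared)
        genes = info.loc[idx, "gene"].unique()
        feat_rows.append(
            {"accession": acc, "gene": genes[0] if len(genes) else "", "n_peptides": len(idx)}
        )
    prot = pd.DataFrame(profiles, index=peptide_quant.sample_ids).T
    prot.index.name = "feature_id"
    features = pd.DataFrame(feat_rows).set_index("accession")
    return QuantMatrix(data=prot, level="protein"), features


def completeness_filter(
    qm: QuantMatrix, metadata: pd.DataFrame, spec: FilterSpec | str = "core"
) -> tuple[QuantMatrix, pd.DataFrame]:
    """Keep proteins meeting the per-compartment presence thresholds.

    Returns the filtered matrix (feature order preserved) and a report
    with per-compartment completeness and both tier verdicts.
    """
    if isinstance(spec, str):
        spec = FilterSpec(mode=spec)
    meta = metadata.loc[qm.sample_ids]
    present = ~np.isnan(qm.values)
    frac = {}
    for comp in COMPARTMENTS:
        cols = np.asarray(meta["compartment"] == comp)
        if cols.sum() == 0:
            raise ValueError(f"compartment {comp} has no samples")
        frac[comp] = present[:, cols].mean(axis=1)
    report = pd.DataFrame(frac, index=qm.data.index)
    core_keep = np.all(
        [report[c] >= spec.core_threshold for c in COMPARTMENTS], axis=0
    )
    ext_keep = np.any(
        [report[c] >= spec.extended_threshold for c in COMPARTMENTS], axis=0
    )
    report["core"] = core_keep
    report["extended"] = ext_keep
    keep = core_keep if spec.mode == "core" else ext_keep
    out = qm.copy_with(qm.data.loc[keep])
    return out, report


def impute_mnar(
    qm: QuantMatrix, seed: int, shift: float = 1.8, width: float = 0.3
) -> QuantMatrix:
    """Left-shifted Gaussian imputation of missing values (MinProb style).

    Each missing cell in sample ``s`` is drawn from
    ``Normal(mu_s - shift * sd_s, (width * sd_s)^2)`` where ``mu_s`` and
    ``sd_s`` are the observed mean and standard deviation of that sample.
    Present values are never altered; deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    X = qm.values.copy()
    miss = np.isnan(X)
    for j, s in enumerate(qm.sample_ids):
        col = X[:, j]
        obs = col[~miss[:, j]]
        if obs.size == 0:
            raise ValueError(f"sample {s} is entirely missing; cannot impute")
        if obs.size < 3:
            raise ValueError(f"sample {s} has fewer than 3 observed values")
        mu, sd = obs.mean(), obs.std(ddof=1)
        n_miss = int(miss[:, j].sum())
        if n_miss:
            X[miss[:, j], j] = rng.normal(mu - shift * sd, width * sd, size=n_miss)
    return qm.copy_with(pd.DataFrame(X, index=qm.data.index, columns=qm.data.columns))


def normalize_median(qm: QuantMatrix) -> QuantMatrix:
    """Shift each sample so its median equals the median of sample medians.

    The median-of-medians target is robust: a level shift of a single
    sample is removed exactly without moving the target.
    """
    X = qm.values.copy()
    med = np.nanmedian(X, axis=0)
    X = X - med[None, :] + np.median(med)
    return qm.copy_with(pd.DataFrame(X, index=qm.data.index, columns=qm.data.columns))
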