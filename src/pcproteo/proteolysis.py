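"""Proteolysis read-outs from specificity annotations.

Per-sample semi-specific fractions (by count and by proportional
intensity), rank-based and parametric compartment comparisons, per-gene
semi-peptide counts, protein-family shares, and cleavage-site motif
enrichment around the P4..P4' window.

Terminal-excluded peptides are removed from both numerator and
denominator everywhere; nonspecific peptides (both termini
non-enzymatic) are counted separately and excluded from the
semi-specific statistics.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .da import bh_adjust
from .io import AMINO_ACIDS, ProteinEntry
from .specificity import EnzymeRule, SEMI_CLASSES, cleavage_window

logger = logging.getLogger(__name__)

WINDOW_POSITIONS = ("P4", "P3", "P2", "P1", "P1'", "P2'", "P3'", "P4'")


def semi_fraction_per_sample(
    annotations: pd.DataFrame, intensities: pd.DataFrame
) -> pd.DataFrame:
    """Semi-specific peptide fraction per sample, by count and intensity.

    ``intensities`` is a linear-scale peptide x sample frame sharing the
    annotation index (NaN = missing). The count fraction uses peptides
    with a present intensity in that sample; the intensity fraction is
    the summed raw intensity of semi peptides over full + semi peptides.
    Samples with zero classified peptides are reported with NaN fractions.
    """
    ann = annotations.loc[annotations.index.intersection(intensities.index)]
    keep = ~ann["terminal_excluded"].astype(bool)
    is_semi = ann["spec_class"].isin(SEMI_CLASSES) & keep
    is_full = (ann["spec_class"] == "full") & keep
    use = is_semi | is_full
    X = intensities.loc[ann.index].to_numpy(dtype=float)
    present = ~np.isnan(X)

    rows = []
    semi_mask = is_semi.to_numpy()
    full_mask = is_full.to_numpy()
    use_mask = use.to_numpy()
    for j, sample in enumerate(intensities.columns):
        pres = present[:, j] & use_mask
        n_semi = int((pres & semi_mask).sum())
        n_full = int((pres & full_mask).sum())
        total = n_semi + n_full
        if total == 0:
            logger.warning("sample %s has zero classified peptides", sample)
            rows.append(
                {
                    "sample_id": sample,
                    "n_full": 0,
                    "n_semi": 0,
                    "fraction_count": np.nan,
                    "fraction_intensity": np.nan,
                }
            )
            continue
        col = X[:, j]
        semi_int = np.nansum(np.where(pres & semi_mask, col, 0.0))
        tot_int = np.nansum(np.where(pres, col, 0.0))
        rows.append(
            {
                "sample_id": sample,
                "n_full": n_full,
                "n_semi": n_semi,
                "fraction_count": n_semi / total,
                "fraction_intensity": semi_int / tot_int if tot_int > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def dunn_test(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons with tie correction.

    z follows the standard Kruskal-Wallis rank framework:
    ``z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))``
    with tie term ``T = sum(t^3 - t) / (12 (N - 1))``. Two-sided normal
    p-values; BH adjustment across the pairs.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    N = values.size
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    T = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1)) if N > 1 else 0.0
    var_term = N * (N + 1) / 12.0 - T

    labels = pd.unique(groups)
    rows = []
    for g1, g2 in itertools.combinations(labels, 2):
        i1, i2 = groups == g1, groups == g2
        n1, n2 = int(i1.sum()), int(i2.sum())
        if n1 < 2 or n2 < 2:
            logger.warning("contrast %s-%s skipped: fewer than 2 samples", g1, g2)
            continue
        if var_term <= 0:
            z, p = 0.0, 1.0
        else:
            se = np.sqrt(var_term * (1.0 / n1 + 1.0 / n2))
            z = (ranks[i1].mean() - ranks[i2].mean()) / se
            p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group1": g1, "group2": g2, "n1": n1, "n2": n2, "z": z, "p": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["adj_p"] = bh_adjust(out["p"].to_numpy())
    return out


def group_compare_fractions(
    fractions: pd.Series, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Omnibus + pairwise comparison of a per-sample statistic by compartment.

    Emits both the rank-based route (Kruskal-Wallis omnibus, Dunn
    pairwise, BH-adjusted) and the parametric route (one-way ANOVA, Tukey
    HSD pairwise) for every compartment pair.
    """
    s = fractions.dropna()
    meta = metadata.loc[s.index]
    groups = meta["compartment"].to_numpy()
    values = s.to_numpy(dtype=float)
    labels = [g for g in pd.unique(groups)]
    by_group = [values[groups == g] for g in labels]
    usable = [g for g, v in zip(labels, by_group) if v.size >= 2]
    if len(usable) < 2:
        raise ValueError("need at least 2 groups with at least 2 samples each")

    if np.ptp(values) == 0:
        kw_p = anova_p = 1.0
    else:
        try:
            kw_p = float(stats.kruskal(*[v for v in by_group if v.size >= 2]).pvalue)
        except ValueError:
            kw_p = 1.0
        anova_p = float(stats.f_oneway(*[v for v in by_group if v.size >= 2]).pvalue)

    dunn = dunn_test(values, groups)
    if np.ptp(values) == 0:
        tukey_p = {tuple(sorted((r["group1"], r["group2"]))): 1.0 for _, r in dunn.iterrows()}
    else:
        res = pairwise_tukeyhsd(values, groups)
        tukey_p = {}
        for (g1, g2), p in zip(
            itertools.combinations(res.groupsunique, 2), res.pvalues
        ):
            tukey_p[tuple(sorted((g1, g2)))] = float(p)
    dunn = dunn.rename(columns={"z": "dunn_z", "p": "dunn_p", "adj_p": "dunn_adj_p"})
    dunn["tukey_p"] = [
        tukey_p.get(tuple(sorted((r["group1"], r["group2"]))), np.nan)
        for _, r in dunn.iterrows()
    ]
    dunn["kruskal_p"] = kw_p
    dunn["anova_p"] = anova_p
    return dunn


def semi_counts_per_protein(
    annotations: pd.DataFrame,
    intensities: pd.DataFrame,
    genes: Iterable[str],
) -> pd.DataFrame:
    """Distinct semi-specific peptide count per gene per sample.

    A peptide counts if it is semi-specific, not terminal-excluded, and
    has a present intensity in the sample; duplicate rows of the same
    stripped sequence count once. Unknown genes are skipped with a
    warning. Returns samples x genes counts.
    """
    genes = list(genes)
    known = set(annotations["gene"])
    out = pd.DataFrame(0, index=intensities.columns, columns=genes, dtype=int)
    ann = annotations.loc[annotations.index.intersection(intensities.index)]
    sel = ann["spec_class"].isin(SEMI_CLASSES) & ~ann["terminal_excluded"].astype(bool)
    for gene in genes:
        if gene not in known:
            logger.warning("gene %s not present among annotated peptides", gene)
            continue
        idx = ann.index[sel & (ann["gene"] == gene)]
        if len(idx) == 0:
            continue
        sub = intensities.loc[idx]
        seqs = ann.loc[idx, "peptide"]
        present = ~sub.isna()
        for sample in intensities.columns:
            out.loc[sample, gene] = int(seqs[present[sample].to_numpy()].nunique())
    out.index.name = "sample_id"
    return out


def protein_family_share(
    annotations: pd.DataFrame, family_map: Mapping[str, str]
) -> pd.Series:
    """Share of distinct semi-specific peptides per protein family.

    Genes absent from ``family_map`` fall into "other". Shares sum to 1.
    """
    sel = annotations["spec_class"].isin(SEMI_CLASSES) & ~annotations[
        "terminal_excluded"
    ].astype(bool)
    sub = annotations.loc[sel, ["peptide", "gene"]].drop_duplicates("peptide")
    if sub.empty:
        return pd.Series(dtype=float)
    fam = sub["gene"].map(lambda g: family_map.get(g, "other"))
    share = fam.value_counts(normalize=True).sort_index()
    share.name = "share"
    return share


def motif_enrichment(
    events: pd.DataFrame,
    proteins: Iterable[ProteinEntry] | Mapping[str, ProteinEntry],
    background: str = "proteome",
    pseudocount: float = 1.0,
    rule: EnzymeRule = EnzymeRule(),
) -> pd.DataFrame:
    """Positional log2 residue enrichment of cleavage windows vs background.

    For each window position p and residue a:
    ``log2[ (count(a,p) + pc) / (total_p + 20 pc) / bg(a, p) ]``.
    'X' pads are excluded from counts. Background is either the overall
    residue frequency of the protein database (``proteome``) or the
    position-specific frequency around all in-silico fully enzymatic
    cleavage sites (``tryptic_sites``). Rows are the 20 amino acids,
    columns P4..P4'.
    """
    if events.empty:
        raise ValueError("motif_enrichment requires at least one cleavage event")
    if background not in ("proteome", "tryptic_sites"):
        raise ValueError(f"unknown background {background!r}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if isinstance(proteins, Mapping):
        prot_list = list(proteins.values())
    else:
        prot_list = list(proteins)

    counts = _window_counts(events["window"])
    freq = (counts + pseudocount) / (
        counts.sum(axis=0) + 20.0 * pseudocount
    )

    if background == "proteome":
        bg_counts = np.zeros(20)
        aa_idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
        for e in prot_list:
            for ch in e.sequence:
                i = aa_idx.get(ch)
                if i is not None:
                    bg_counts[i] += 1
        bg = (bg_counts + pseudocount) / (bg_counts.sum() + 20.0 * pseudocount)
        bg_mat = np.tile(bg[:, None], (1, 8))
    else:
        windows = []
        for e in prot_list:
            seq = e.sequence
            for i in range(1, len(seq)):  # cut after residue i (1-based)
                if seq[i - 1] in rule.cleave_after and not (
                    rule.proline_block and seq[i] == "P"
                ):
                    windows.append(cleavage_window(seq, i))
        if not windows:
            raise ValueError("no enzymatic sites found for tryptic_sites background")
        bg_counts = _window_counts(pd.Series(windows))
        bg_mat = (bg_counts + pseudocount) / (
            bg_counts.sum(axis=0) + 20.0 * pseudocount
        )

    mat = np.log2(freq / bg_mat)
    return pd.DataFrame(mat, index=list(AMINO_ACIDS), columns=list(WINDOW_POSITIONS))


def _window_counts(windows: pd.Series) -> np.ndarray:
    """20 x 8 residue counts from 8-mer windows, ignoring 'X' pads."""
    counts = np.zeros((20, 8))
    aa_idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    for w in windows:
        if len(w) != 8:
            raise ValueError(f"window {w!r} does not have length 8")
        for pos, ch in enumerate(w):
            i = aa_idx.get(ch)
            if i is not None:
                counts[i, pos] += 1
    return counts
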