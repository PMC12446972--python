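"""End-to-end orchestration of the compartment-resolved analysis.

Chains the whole workflow on an in-memory cohort: terminus
classification, proteolysis read-outs, protein roll-up, two-tier
filtering and MNAR imputation, differential abundance with the
compartment-unique signature, trend clustering, tumor-size and marker
correlations, peptide-protein concordance, and cleavage-motif
enrichment. Used by the ``report`` CLI subcommand and by the
reproduction script.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import compartment as comp_mod
from . import da as da_mod
from . import proteolysis as prot_mod
from . import quant as quant_mod
from .enrichment import packaged_matrisome_table
from .io import PeptideRecord, ProteinEntry, QuantMatrix, write_table
from .specificity import EnzymeRule, classify_table, extract_cleavage_events

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    summary: dict
    annotations: pd.DataFrame
    fractions: pd.DataFrame
    fraction_tests: pd.DataFrame
    protein_core: QuantMatrix
    protein_extended: QuantMatrix  # imputed
    filter_report: pd.DataFrame
    da_tables: dict = field(default_factory=dict)
    signature_up: set = field(default_factory=set)
    signature_down: set = field(default_factory=set)
    trends: pd.DataFrame | None = None
    size_corr: pd.DataFrame | None = None
    marker_corr: pd.DataFrame | None = None
    concordance_r: float = float("nan")
    discordant: pd.DataFrame | None = None
    motif: pd.DataFrame | None = None
    pca_variance: np.ndarray | None = None


def _records_from_info(pep_info: pd.DataFrame) -> list[PeptideRecord]:
    return [
        PeptideRecord(
            stripped_sequence=row["peptide"],
            protein_accessions=tuple(row["protein_group"].split(";")),
            gene=row["gene"],
            proteotypic=bool(row["proteotypic"]),
            intensities={},
        )
        for _, row in pep_info.iterrows()
    ]


def run_pipeline(
    proteins: list[ProteinEntry],
    pep_info: pd.DataFrame,
    intensities: pd.DataFrame,
    metadata: pd.DataFrame,
    seed: int = 1,
    fc: float = 1.5,
    alpha: float = 0.05,
    rule: EnzymeRule = EnzymeRule(),
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis on a peptide-level dataset.

    ``pep_info`` carries peptide / protein_group / gene / proteotypic
    columns indexed by peptide id; ``intensities`` is the matching
    linear-scale matrix. All randomness (imputation) flows from ``seed``.
    """
    prot_index = {p.accession: p for p in proteins}
    lfc_cut = math.log2(fc)

    # 1. terminus classification and proteolysis read-outs
    ann, n_dropped = classify_table(
        _records_from_info(pep_info), prot_index, rule, "most_specific"
    )
    intens = intensities.loc[ann.index]
    fractions = prot_mod.semi_fraction_per_sample(ann, intens)
    fraction_tests = prot_mod.group_compare_fractions(
        fractions["fraction_intensity"], metadata
    )

    # 2. protein roll-up from fully tryptic peptides, log2 scale
    full_ids = ann.index[ann["spec_class"] == "full"]
    pep_log2 = QuantMatrix(data=np.log2(intens), level="peptide")
    full_qm = QuantMatrix(data=pep_log2.data.loc[full_ids], level="peptide")
    rollup_info = pd.DataFrame(
        {
            "protein_group": ann.loc[full_ids, "accession"],
            "gene": ann.loc[full_ids, "gene"],
            "proteotypic": pep_info.loc[full_ids, "proteotypic"],
        }
    )
    protein_qm, features = quant_mod.rollup_proteins(full_qm, rollup_info)
    protein_qm = quant_mod.normalize_median(protein_qm)

    # 3. two-tier completeness filtering; impute the extended tier only
    core_qm, filter_report = quant_mod.completeness_filter(
        protein_qm, metadata, "core"
    )
    ext_qm, _ = quant_mod.completeness_filter(protein_qm, metadata, "extended")
    ext_imp = quant_mod.impute_mnar(ext_qm, seed=seed)

    # 4. differential abundance and the PC-unique signature
    by_comp = {
        c: list(metadata.index[metadata["compartment"] == c])
        for c in ("NAT", "PC", "TUMOR")
    }
    da_tables = {
        "PC_vs_NAT": da_mod.moderated_ttest(
            ext_imp, by_comp["PC"], by_comp["NAT"], alpha=alpha, fc_threshold=fc
        ),
        "PC_vs_TUMOR": da_mod.moderated_ttest(
            ext_imp, by_comp["PC"], by_comp["TUMOR"], alpha=alpha, fc_threshold=fc
        ),
        "TUMOR_vs_NAT": da_mod.moderated_ttest(
            ext_imp, by_comp["TUMOR"], by_comp["NAT"], alpha=alpha, fc_threshold=fc
        ),
    }
    sig_up, sig_down = da_mod.pc_unique_signature(
        da_tables["PC_vs_NAT"], da_tables["PC_vs_TUMOR"], fc=fc, alpha=alpha
    )

    # 5. compartment structure
    trends = comp_mod.trend_clusters(ext_imp, metadata)
    pca_res = comp_mod.pca(ext_imp, n_components=5)
    pc_samples = by_comp["PC"]
    pc_qm = QuantMatrix(data=ext_imp.data[pc_samples], level="protein")
    size_corr = comp_mod.size_correlation(
        pc_qm, metadata.loc[pc_samples, "tumor_diameter"], alpha=alpha
    )

    gene_to_acc = {p.gene: p.accession for p in proteins if p.gene}
    marker_corr = None
    anchor_acc = gene_to_acc.get("PCNA")
    panel_accs = [
        gene_to_acc[g]
        for g in ("MCM2", "MCM3", "MCM4", "MCM5", "MCM6", "MCM7")
        if g in gene_to_acc and gene_to_acc[g] in ext_imp.data.index
    ]
    if anchor_acc in ext_imp.data.index and panel_accs:
        marker_corr = comp_mod.marker_correlation(
            ext_imp, metadata, anchor_acc, panel_accs
        )

    # 6. peptide-protein concordance (tryptic peptides, tumor vs NAT)
    pep_da = da_mod.moderated_ttest(
        full_qm, by_comp["TUMOR"], by_comp["NAT"], alpha=alpha, fc_threshold=fc
    )
    mapping = ann.loc[full_ids, "accession"]
    conc_r, discordant = comp_mod.peptide_protein_concordance(
        pep_da, da_tables["TUMOR_vs_NAT"], mapping, fc=fc, alpha=alpha
    )

    # 7. cleavage motif of significantly tumor-upregulated semi peptides
    semi_ids = ann.index[
        ann["spec_class"].isin(("semi_N", "semi_C"))
        & ~ann["terminal_excluded"].astype(bool)
    ]
    motif = None
    up_events = pd.DataFrame()
    if len(semi_ids) >= 2:
        semi_qm = QuantMatrix(data=pep_log2.data.loc[semi_ids], level="peptide")
        semi_da = da_mod.moderated_ttest(
            semi_qm, by_comp["TUMOR"], by_comp["NAT"], alpha=alpha, fc_threshold=fc
        )
        up_ids = semi_da.index[
            (semi_da["adj_p"] <= alpha) & (semi_da["log2fc"] >= lfc_cut)
        ]
        if len(up_ids):
            up_events = extract_cleavage_events(ann.loc[up_ids], prot_index)
        if not up_events.empty:
            motif = prot_mod.motif_enrichment(up_events, proteins, "proteome")

    # 8. collagen family share among semi peptides (matrisome lookup)
    mat = packaged_matrisome_table()
    collagen_genes = set(mat.loc[mat["category"] == "collagens", "gene"])
    family_map = {g: "collagens" for g in collagen_genes}
    shares = prot_mod.protein_family_share(ann, family_map)
    semi_col = ann.loc[
        ann.index.isin(semi_ids) & ann["gene"].isin(collagen_genes)
    ].drop_duplicates("peptide")
    if len(semi_col):
        col16 = semi_col["gene"].str.startswith(("COL1A", "COL6A")).mean()
    else:
        col16 = float("nan")

    n_semi = int(len(semi_ids))
    n_classified = int((~ann["terminal_excluded"].astype(bool)).sum())
    summary = {
        "n_peptides": int(len(ann)),
        "n_semi_peptides": n_semi,
        "semi_peptide_pct": 100.0 * n_semi / n_classified if n_classified else np.nan,
        "semi_fraction_intensity_NAT": _comp_mean(fractions, metadata, "NAT"),
        "semi_fraction_intensity_PC": _comp_mean(fractions, metadata, "PC"),
        "semi_fraction_intensity_TUMOR": _comp_mean(fractions, metadata, "TUMOR"),
        "dunn_adj_p_tumor_vs_nat": _pair_p(fraction_tests, "TUMOR", "NAT"),
        "n_proteins_quantified": int(protein_qm.data.shape[0]),
        "n_core_proteins": int(core_qm.data.shape[0]),
        "n_extended_proteins": int(ext_qm.data.shape[0]),
        "pc_unique_up_n": len(sig_up),
        "pc_unique_down_n": len(sig_down),
        "trend_increasing_n": int((trends["cluster"] == "increasing").sum()),
        "trend_decreasing_n": int((trends["cluster"] == "decreasing").sum()),
        "size_corr_positive_n": int((size_corr["direction"] == "positive").sum()),
        "size_corr_negative_n": int((size_corr["direction"] == "negative").sum()),
        "concordance_r": float(conc_r),
        "discordant_peptides_n": int(len(discordant)),
        "collagen_semi_col1a_col6a_share": float(col16),
        "pca_pc1_var_pct": float(pca_res.variance_explained[0]),
        "n_dropped_peptides": int(n_dropped),
    }
    if marker_corr is not None:
        tum = marker_corr[marker_corr["compartment"] == "TUMOR"]["r"]
        nat = marker_corr[marker_corr["compartment"] == "NAT"]["r"]
        summary["marker_panel_mean_r_tumor"] = float(tum.mean())
        summary["marker_panel_mean_r_nat"] = float(nat.mean())
    if motif is not None:
        summary["motif_p1prime_L_log2"] = float(motif.loc["L", "P1'"])

    result = PipelineResult(
        summary=summary,
        annotations=ann,
        fractions=fractions,
        fraction_tests=fraction_tests,
        protein_core=core_qm,
        protein_extended=ext_imp,
        filter_report=filter_report,
        da_tables=da_tables,
        signature_up=sig_up,
        signature_down=sig_down,
        trends=trends,
        size_corr=size_corr,
        marker_corr=marker_corr,
        concordance_r=conc_r,
        discordant=discordant,
        motif=motif,
        pca_variance=pca_res.variance_explained,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _comp_mean(fractions: pd.DataFrame, metadata: pd.DataFrame, comp: str) -> float:
    ids = metadata.index[metadata["compartment"] == comp]
    vals = fractions.loc[fractions.index.intersection(ids), "fraction_intensity"]
    return float(vals.mean())


def _pair_p(tests: pd.DataFrame, g1: str, g2: str) -> float:
    for _, row in tests.iterrows():
        if {row["group1"], row["group2"]} == {g1, g2}:
            return float(row["dunn_adj_p"])
    return float("nan")


def _write_outputs(res: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_table(res.annotations, out / "annotations.tsv")
    write_table(res.fractions, out / "semi_fractions.tsv")
    write_table(res.fraction_tests, out / "fraction_tests.tsv", index=False)
    res.protein_extended.to_tsv(out / "protein_matrix_extended_imputed.tsv")
    res.protein_core.to_tsv(out / "protein_matrix_core.tsv")
    write_table(res.filter_report, out / "filter_report.tsv")
    for name, tab in res.da_tables.items():
        write_table(tab, out / f"da_{name}.tsv")
    sig = pd.DataFrame(
        {
            "feature_id": sorted(res.signature_up) + sorted(res.signature_down),
            "direction": ["up"] * len(res.signature_up)
            + ["down"] * len(res.signature_down),
        }
    )
    write_table(sig, out / "pc_unique_signature.tsv", index=False)
    if res.trends is not None:
        write_table(res.trends, out / "trend_clusters.tsv")
    if res.size_corr is not None:
        write_table(res.size_corr, out / "size_correlation.tsv")
    if res.marker_corr is not None:
        write_table(res.marker_corr, out / "marker_correlation.tsv", index=False)
    if res.motif is not None:
        write_table(res.motif, out / "motif_matrix.tsv", index_label="residue")
    if res.discordant is not None:
        write_table(res.discordant, out / "discordant_peptides.tsv")
    write_table(
        pd.DataFrame(
            [{"metric": k, "value": v} for k, v in res.summary.items()]
        ),
        out / "summary.tsv",
        index=False,
    )
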