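"""Synthetic compartment-resolved proteomics cohort generator.

Generates a complete, fully deterministic study — protein database,
peptide quantification table, sample metadata, and a ground-truth
record — with the statistical structure the analysis pipeline assumes:

* a patient-matched cohort (default 34 patients; 54 tumor, 45
  pseudocapsule and 31 normal-adjacent samples, metachronous lesions
  allowed) with per-lesion tumor diameters;
* random protein sequences digested in silico (cut after K/R, one
  missed cleavage, 7-30 residue peptides);
* endogenous (pre-digestion) proteolysis producing semi-specific
  peptides whose per-compartment share of total signal is configurable,
  with a protease P1' residue preference;
* planted compartment effect panels, tumor-size slope proteins,
  marker-panel co-expression, patient random effects, and
  cleavage-driven peptide-specific shifts;
* intensity-dependent (MNAR) plus completely-at-random missingness.

Proteins are random sequences, not real human proteins, keeping the
repository database-free; panel genes carry familiar symbols (COL1A1
and friends) as aliases so annotation fixtures work end to end.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import (
    AMINO_ACIDS,
    PeptideRecord,
    ProteinEntry,
    write_fasta,
    write_metadata,
    write_peptide_table,
    write_table,
)
from .specificity import EnzymeRule

DEFAULT_EFFECT = math.log2(1.5) * 1.33  # log2 shift of planted panels

PC_UP_GENES = (
    "COL1A1", "COL1A2", "COL6A1", "COL6A2", "COL6A3", "COL14A1", "ELN",
    "FBN1", "FN1", "BGN", "DCN", "LTBP1", "MMP7", "MMP14", "TIMP1",
    "POSTN", "PDGFRB", "TGFB2", "CCN2", "S100A4",
)
TUMOR_UP_GENES = (
    "HK1", "HK2", "PKM", "LDHA", "ENO1", "ENO2", "GAPDH", "PGK1", "ALDOA",
    "PFKP", "SLC2A1", "VEGFA", "CA9", "PFKM", "KRT14",
)
TUMOR_DOWN_GENES = (
    "NDUFA9", "NDUFS1", "SDHA", "SDHB", "UQCRC1", "UQCRC2", "COX4I1",
    "COX5A", "ATP5F1A", "ATP5F1B", "CS", "FH", "MDH2", "IDH3A", "ACO2",
)
SLOPE_POS_GENES = ("CASP1", "CD14", "CD163", "C3", "C1QA")
SLOPE_NEG_GENES = ("ETFA", "ETFB", "ACAT1", "HADHA", "HADHB")
MARKER_ANCHOR = "PCNA"
MARKER_PANEL = ("MCM2", "MCM3", "MCM4", "MCM5", "MCM6", "MCM7")


@dataclass(frozen=True)
class PanelSpec:
    """A planted effect panel: genes and their per-compartment log2 shift."""

    genes: tuple[str, ...]
    effects: tuple[float, float, float]  # (NAT, PC, TUMOR)


def default_panels() -> dict[str, PanelSpec]:
    return {
        "pc_up": PanelSpec(PC_UP_GENES, (0.0, DEFAULT_EFFECT, 0.0)),
        "tumor_up": PanelSpec(TUMOR_UP_GENES, (0.0, 0.0, DEFAULT_EFFECT)),
        "tumor_down": PanelSpec(TUMOR_DOWN_GENES, (0.0, 0.0, -DEFAULT_EFFECT)),
    }


@dataclass
class SimConfig:
    """Study conditions of the synthetic cohort.

    Sample counts, digestion constraints and per-compartment semi-specific
    intensity shares mirror the emulated study design; abundance and noise
    scales are typical of log2 label-free FFPE tissue data.
    """

    # cohort structure
    n_patients: int = 34
    n_nat: int = 31
    n_pc: int = 45
    n_tumor: int = 54
    n_metachronous_patients: int = 12

    # proteome + digestion
    n_proteins: int = 300
    protein_len_range: tuple[int, int] = (150, 1000)
    kr_frequency: float = 0.11
    uniform_alphabet: bool = False
    pep_len_range: tuple[int, int] = (7, 30)
    max_missed_cleavages: int = 1
    max_peptides_per_protein: int = 10

    # endogenous proteolysis
    semi_share: dict = field(
        default_factory=lambda: {"NAT": 0.10, "PC": 0.15, "TUMOR": 0.25}
    )
    semi_events_per_protein: int = 2
    p1prime_preference: dict = field(default_factory=lambda: {"L": 8.0})
    # endogenous cleavage concentrates on a protein family (collagens by
    # default): `total_share` of all events land in the family, of which
    # `bias_share` land on the designated chains
    semi_family_bias_genes: tuple[str, ...] = (
        "COL1A1", "COL1A2", "COL6A1", "COL6A2", "COL6A3",
    )
    semi_family_other_genes: tuple[str, ...] = ("COL14A1",)
    semi_family_bias_share: float = 0.75
    semi_family_total_share: float = 0.40
    pc_restricted_semi_genes: tuple[str, ...] = ("COL1A1", "COL6A1")

    # planted effects
    panels: dict = field(default_factory=default_panels)
    slope_pos_genes: tuple[str, ...] = SLOPE_POS_GENES
    slope_neg_genes: tuple[str, ...] = SLOPE_NEG_GENES
    size_r: float = 0.6
    marker_anchor: str = MARKER_ANCHOR
    marker_panel: tuple[str, ...] = MARKER_PANEL
    marker_r: float = 0.6
    discordant_fraction: float = 0.05
    discordant_shift: float = 1.5

    # intensity model (log2 scale)
    base_mean: float = 20.0
    base_sd: float = 2.0
    peptide_offset_sd: float = 1.5
    noise_sd: float = 0.3
    patient_sd: float = 0.4

    # tumor diameters (mm, log-normal)
    diameter_log_mean: float = math.log(35.0)
    diameter_log_sd: float = 0.4

    # missingness
    mnar_midpoint: float = 16.0
    mnar_steepness: float = 1.5
    mcar_rate: float = 0.02

    def __post_init__(self) -> None:
        for c, s in self.semi_share.items():
            if not (0.0 <= s < 1.0):
                raise ValueError(f"semi share for {c} must lie in [0, 1)")
        if not (0.0 <= self.mcar_rate <= 1.0):
            raise ValueError("mcar_rate must lie in [0, 1]")
        if self.mnar_steepness < 0:
            raise ValueError("mnar_steepness must be >= 0")
        genes: list[str] = []
        for spec in self.panels.values():
            genes.extend(spec.genes)
        genes.extend(self.slope_pos_genes)
        genes.extend(self.slope_neg_genes)
        genes.append(self.marker_anchor)
        genes.extend(self.marker_panel)
        if len(genes) != len(set(genes)):
            raise ValueError("planted gene panels must be disjoint")
        if len(set(genes)) > self.n_proteins:
            raise ValueError("n_proteins too small for the configured panels")

    @property
    def special_genes(self) -> list[str]:
        out: list[str] = []
        for spec in self.panels.values():
            out.extend(spec.genes)
        out.extend(self.slope_pos_genes)
        out.extend(self.slope_neg_genes)
        out.append(self.marker_anchor)
        out.extend(self.marker_panel)
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "panels" in raw:
            raw["panels"] = {
                k: PanelSpec(tuple(v["genes"]), tuple(v["effects"]))
                for k, v in raw["panels"].items()
            }
        for key in (
            "protein_len_range",
            "pep_len_range",
            "semi_family_bias_genes",
            "semi_family_other_genes",
            "pc_restricted_semi_genes",
            "slope_pos_genes",
            "slope_neg_genes",
            "marker_panel",
        ):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["panels"] = {
            k: {"genes": list(v["genes"]), "effects": list(v["effects"])}
            for k, v in d["panels"].items()
        }
        for k, v in list(d.items()):
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Cohort structure


def make_cohort_metadata(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Patient-matched sample table with lesions, diameters and grades.

    Metachronous lesions are assigned round-robin to the first
    ``n_metachronous_patients`` patients; pseudocapsule samples inherit
    the diameter of their matched tumor lesion via (patient, lesion).
    """
    cfg = config
    if cfg.n_tumor < cfg.n_patients:
        raise ValueError("need at least one tumor lesion per patient")
    patients = [f"P{i + 1:02d}" for i in range(cfg.n_patients)]
    lesions: list[tuple[str, int]] = [(p, 1) for p in patients]
    extra = cfg.n_tumor - cfg.n_patients
    nxt = {p: 2 for p in patients}
    while extra > 0:
        progressed = False
        for p in patients[: cfg.n_metachronous_patients]:
            if extra == 0:
                break
            lesions.append((p, nxt[p]))
            nxt[p] += 1
            extra -= 1
            progressed = True
        if not progressed:
            raise ValueError("cannot place metachronous lesions")
    lesions.sort(key=lambda x: (x[1], x[0]))

    diam = {
        les: float(np.exp(rng.normal(cfg.diameter_log_mean, cfg.diameter_log_sd)))
        for les in lesions
    }
    grades = rng.choice(["G1", "G2", "G3"], size=len(lesions), p=[11 / 54, 40 / 54, 3 / 54])

    rows = []
    for (pat, li), grade in zip(lesions, grades):
        rows.append(
            {
                "sample_id": f"T_{pat}_L{li}",
                "patient_id": pat,
                "compartment": "TUMOR",
                "tumor_diameter": diam[(pat, li)],
                "grade": grade,
                "lesion_index": li,
            }
        )
    if cfg.n_pc > len(lesions):
        raise ValueError("more PC samples than tumor lesions")
    for (pat, li) in lesions[: cfg.n_pc]:
        rows.append(
            {
                "sample_id": f"PC_{pat}_L{li}",
                "patient_id": pat,
                "compartment": "PC",
                "tumor_diameter": diam[(pat, li)],
                "grade": "unknown",
                "lesion_index": li,
            }
        )
    if cfg.n_nat > cfg.n_patients:
        raise ValueError("more NAT samples than patients")
    for pat in patients[: cfg.n_nat]:
        rows.append(
            {
                "sample_id": f"N_{pat}",
                "patient_id": pat,
                "compartment": "NAT",
                "tumor_diameter": np.nan,
                "grade": "unknown",
                "lesion_index": 1,
            }
        )
    meta = pd.DataFrame(rows)
    return meta.set_index("sample_id", drop=False)


# ---------------------------------------------------------------------------
# Proteome and digestion


def make_proteome(config: SimConfig, rng: np.random.Generator) -> list[ProteinEntry]:
    """Random protein sequences with tryptic-friendly K/R content.

    Panel genes come first as header aliases; the remainder are numbered
    symbols.
    """
    cfg = config
    aas = list(AMINO_ACIDS)
    if cfg.uniform_alphabet:
        probs = np.full(20, 1.0 / 20.0)
    else:
        probs = np.full(20, (1.0 - cfg.kr_frequency) / 18.0)
        for res in "KR":
            probs[aas.index(res)] = cfg.kr_frequency / 2.0
    special = cfg.special_genes
    genes = special + [
        f"GENE{i + 1:04d}" for i in range(cfg.n_proteins - len(special))
    ]
    lo, hi = cfg.protein_len_range
    entries = []
    for i, gene in enumerate(genes):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(aas, size=length, p=probs))
        entries.append(
            ProteinEntry(accession=f"SYN{i + 1:04d}", gene=gene, sequence=seq)
        )
    return entries


def digest(
    sequence: str,
    rule: EnzymeRule = EnzymeRule(),
    max_missed: int = 1,
    min_len: int = 7,
    max_len: int = 30,
) -> list[tuple[str, int, int]]:
    """Fully enzymatic peptides of a protein, with positions.

    Returns deduplicated ``(peptide, start, end)`` triples (1-based
    inclusive) whose termini are enzymatic or protein-terminal, with at
    most ``max_missed`` internal cleavage sites, within the length range.
    """
    bounds = [0]
    for i in range(1, len(sequence)):
        if sequence[i - 1] in rule.cleave_after and not (
            rule.proline_block and sequence[i] == "P"
        ):
            bounds.append(i)
    bounds.append(len(sequence))
    peps: list[tuple[str, int, int]] = []
    seen: set[str] = set()
    for a in range(len(bounds) - 1):
        for b in range(a + 1, min(a + max_missed + 2, len(bounds))):
            s, e = bounds[a], bounds[b]
            if min_len <= e - s <= max_len:
                pep = sequence[s:e]
                if pep not in seen:
                    seen.add(pep)
                    peps.append((pep, s + 1, e))
    return peps


def apply_endogenous_cleavage(
    protein: ProteinEntry,
    tryptic_peptides: list[tuple[str, int, int]],
    n_events: int,
    p1prime_preference: dict[str, float],
    rng: np.random.Generator,
    rule: EnzymeRule = EnzymeRule(),
    min_len: int = 7,
    max_len: int = 30,
) -> list[dict]:
    """Sample endogenous cleavage events and the semi peptides they create.

    Candidate cuts lie inside tryptic peptides at non-enzymatic P1
    residues; each cut truncates the parent peptide into a semi_N or
    semi_C fragment of valid length that avoids the protein termini.
    Sites are drawn with probability proportional to the P1' residue
    preference (the special key ``"*"`` sets the weight of unlisted
    residues; zero-weight sites are never drawn). Returns up to
    ``n_events`` fragments.
    """
    seq = protein.sequence
    default_w = float(p1prime_preference.get("*", 1.0))
    tryptic_seqs = {p for p, _, _ in tryptic_peptides}
    candidates: list[dict] = []
    weights: list[float] = []
    seen: set[str] = set()
    for pep, s, e in tryptic_peptides:
        for pos in range(s, e):  # cut between residues pos and pos+1; P1 = pos
            if seq[pos - 1] in rule.cleave_after:
                continue
            w = float(p1prime_preference.get(seq[pos], default_w))
            left_len = pos - s + 1
            right_len = e - pos
            if (
                min_len <= left_len <= max_len
                and s > rule.nterm_window
                and e - s + 1 > left_len
            ):
                frag = seq[s - 1 : pos]
                if frag not in tryptic_seqs and frag not in seen:
                    seen.add(frag)
                    candidates.append(
                        {
                            "sequence": frag,
                            "side": "semi_C",
                            "p1_pos": pos,
                            "p1prime": seq[pos],
                            "start": s,
                            "end": pos,
                        }
                    )
                    weights.append(w)
            if (
                min_len <= right_len <= max_len
                and e < len(seq)
                and pos + 1 > rule.nterm_window
                and e - s + 1 > right_len
            ):
                frag = seq[pos:e]
                if frag not in tryptic_seqs and frag not in seen:
                    seen.add(frag)
                    candidates.append(
                        {
                            "sequence": frag,
                            "side": "semi_N",
                            "p1_pos": pos,
                            "p1prime": seq[pos],
                            "start": pos + 1,
                            "end": e,
                        }
                    )
                    weights.append(w)
    if n_events <= 0 or not candidates:
        return []
    w_arr = np.asarray(weights, dtype=float)
    keep = w_arr > 0
    if not keep.any():
        return []
    candidates = [c for c, k in zip(candidates, keep) if k]
    w_arr = w_arr[keep]
    k = min(n_events, len(candidates))
    idx = rng.choice(len(candidates), size=k, replace=False, p=w_arr / w_arr.sum())
    return [candidates[i] for i in sorted(idx)]


# ---------------------------------------------------------------------------
# Intensities and missingness


def _allocate_semi_events(
    config: SimConfig, proteins: list[ProteinEntry], rng: np.random.Generator
) -> dict[str, int]:
    """Events per accession honouring the family bias structure."""
    cfg = config
    total = cfg.semi_events_per_protein * cfg.n_proteins
    by_gene = {p.gene: p.accession for p in proteins}
    bias_accs = [by_gene[g] for g in cfg.semi_family_bias_genes if g in by_gene]
    other_accs = [by_gene[g] for g in cfg.semi_family_other_genes if g in by_gene]
    alloc = {p.accession: 0 for p in proteins}
    rest = total
    if (bias_accs or other_accs) and cfg.semi_family_total_share > 0:
        n_fam = int(round(total * cfg.semi_family_total_share))
        n_bias = int(round(n_fam * cfg.semi_family_bias_share)) if other_accs else n_fam
        if not bias_accs:
            n_bias = 0
        for i in range(n_bias):
            alloc[bias_accs[i % len(bias_accs)]] += 1
        for i in range(n_fam - n_bias):
            alloc[other_accs[i % len(other_accs)]] += 1
        rest = total - n_fam
    family = set(bias_accs) | set(other_accs)
    others = [p.accession for p in proteins if p.accession not in family]
    if others and rest > 0:
        base, rem = divmod(rest, len(others))
        for acc in others:
            alloc[acc] += base
        if rem:
            picks = rng.choice(len(others), size=rem, replace=False)
            for i in picks:
                alloc[others[i]] += 1
    return alloc


def simulate_intensities(
    proteins: list[ProteinEntry],
    pep_info: pd.DataFrame,
    metadata: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """Linear-scale peptide x sample intensities under the planted model.

    log2 intensity = protein base + planted compartment effect + size
    slope (slope genes, PC samples) + marker coupling (tumor samples) +
    patient random effect + peptide offset + cleavage-driven peptide
    shift (discordant peptides, tumor samples) + Gaussian noise. Semi
    peptide intensities are rescaled per sample so the semi-specific
    share of total signal equals the configured compartment share
    exactly before missingness.
    """
    cfg = config
    acc_list = [p.accession for p in proteins]
    acc_idx = {a: i for i, a in enumerate(acc_list)}
    gene_of = {p.accession: p.gene for p in proteins}
    n_prot = len(proteins)
    samples = list(metadata.index)
    n_samp = len(samples)
    comp = metadata["compartment"].to_numpy()
    patients = sorted(metadata["patient_id"].unique())
    pat_idx = {p: i for i, p in enumerate(patients)}

    pep_acc = pep_info["protein_group"].str.split(";").str[0].map(acc_idx).to_numpy()
    is_semi = pep_info["is_semi"].to_numpy(dtype=bool)
    n_pep = len(pep_info)

    base = rng.normal(cfg.base_mean, cfg.base_sd, size=n_prot)
    offset = rng.normal(0.0, cfg.peptide_offset_sd, size=n_pep)
    patient_eff = rng.normal(0.0, cfg.patient_sd, size=(len(patients), n_prot))
    noise = rng.normal(0.0, cfg.noise_sd, size=(n_pep, n_samp))

    comp_order = {"NAT": 0, "PC": 1, "TUMOR": 2}
    comp_effect = np.zeros((n_prot, 3))
    gene_to_prot = {p.gene: acc_idx[p.accession] for p in proteins}
    for spec in cfg.panels.values():
        for g in spec.genes:
            if g in gene_to_prot:
                comp_effect[gene_to_prot[g]] = spec.effects

    sigma_prot = math.sqrt(cfg.patient_sd**2 + cfg.noise_sd**2)
    diam = metadata["tumor_diameter"].to_numpy(dtype=float)
    pc_mask = comp == "PC"
    tum_mask = comp == "TUMOR"
    pc_diam = diam[pc_mask]
    sd_diam = pc_diam.std(ddof=1) if pc_diam.size > 1 else 1.0
    mean_diam = pc_diam.mean() if pc_diam.size else 0.0
    slope_mag = (
        cfg.size_r / math.sqrt(1.0 - cfg.size_r**2) * sigma_prot / sd_diam
        if sd_diam > 0
        else 0.0
    )
    slope = np.zeros(n_prot)
    for g in cfg.slope_pos_genes:
        if g in gene_to_prot:
            slope[gene_to_prot[g]] = slope_mag
    for g in cfg.slope_neg_genes:
        if g in gene_to_prot:
            slope[gene_to_prot[g]] = -slope_mag

    marker_lambda = sigma_prot * math.sqrt(cfg.marker_r / (1.0 - cfg.marker_r))
    marker_prots = [
        gene_to_prot[g]
        for g in (cfg.marker_anchor, *cfg.marker_panel)
        if g in gene_to_prot
    ]
    marker_latent = rng.normal(0.0, 1.0, size=n_samp)

    # cleavage-driven peptide-specific shifts on tryptic peptides of
    # otherwise-null proteins (tumor compartment only)
    planted_genes = set(cfg.special_genes)
    eligible = np.where(
        (~is_semi)
        & ~pep_info["gene"].isin(planted_genes).to_numpy()
        & pep_info["proteotypic"].to_numpy(dtype=bool)
    )[0]
    n_disc = int(round(cfg.discordant_fraction * eligible.size))
    disc_idx = (
        rng.choice(eligible, size=n_disc, replace=False) if n_disc else np.array([], int)
    )
    disc_sign = rng.choice([-1.0, 1.0], size=n_disc)

    M = np.empty((n_pep, n_samp))
    comp_col = np.array([comp_order[c] for c in comp])
    pat_col = np.array([pat_idx[p] for p in metadata["patient_id"]])
    M[:] = base[pep_acc][:, None] + offset[:, None] + noise
    M += comp_effect[pep_acc][:, comp_col]
    M += patient_eff[pat_col][:, pep_acc].T
    size_term = np.zeros(n_samp)
    size_term[pc_mask] = diam[pc_mask] - mean_diam
    M += slope[pep_acc][:, None] * size_term[None, :]
    if marker_prots:
        mrk = np.isin(pep_acc, marker_prots)
        M[np.ix_(mrk, tum_mask)] += marker_lambda * marker_latent[tum_mask][None, :]
    if n_disc:
        shift = disc_sign[:, None] * cfg.discordant_shift
        M[np.ix_(disc_idx, tum_mask)] += np.broadcast_to(
            shift, (n_disc, int(tum_mask.sum()))
        )

    X = np.power(2.0, M)

    # pseudocapsule-restricted semi peptides are simply absent elsewhere
    restricted = is_semi & pep_info["gene"].isin(cfg.pc_restricted_semi_genes).to_numpy()
    if restricted.any():
        X[np.ix_(restricted, ~pc_mask)] = np.nan

    # enforce the per-compartment semi-specific intensity share exactly
    shares = np.array([cfg.semi_share[c] for c in comp])
    for j in range(n_samp):
        s = shares[j]
        semi_col = X[is_semi, j]
        full_sum = np.nansum(X[~is_semi, j])
        semi_sum = np.nansum(semi_col)
        if semi_sum > 0 and full_sum > 0:
            target = s / (1.0 - s) * full_sum
            X[is_semi, j] = semi_col * (target / semi_sum)

    intens = pd.DataFrame(X, index=pep_info.index, columns=samples)
    truth = {
        "discordant_peptides": list(pep_info.index[disc_idx]),
        "slope_genes": {
            **{g: 1 for g in cfg.slope_pos_genes},
            **{g: -1 for g in cfg.slope_neg_genes},
        },
        "marker_genes": [cfg.marker_anchor, *cfg.marker_panel],
    }
    return intens, truth


def apply_missingness(
    intensities: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Delete cells with MNAR (logistic in log2 intensity) + MCAR noise."""
    cfg = config
    X = intensities.to_numpy(dtype=float).copy()
    with np.errstate(all="ignore"):
        logv = np.log2(X)
    if cfg.mnar_steepness == 0:
        p_mnar = np.where(logv < cfg.mnar_midpoint, 1.0, 0.0)
    else:
        z = (cfg.mnar_midpoint - logv) / cfg.mnar_steepness
        p_mnar = 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))
    p = np.clip(p_mnar + cfg.mcar_rate, 0.0, 1.0)
    drop = rng.random(X.shape) < p
    X[drop] = np.nan
    return pd.DataFrame(X, index=intensities.index, columns=intensities.columns)


# ---------------------------------------------------------------------------
# Whole-cohort assembly


@dataclass
class Cohort:
    """A fully simulated study: database, peptides, samples, and truth."""

    config: SimConfig
    seed: int
    proteins: list[ProteinEntry]
    pep_info: pd.DataFrame  # peptide_id x (peptide, protein_group, gene, proteotypic, is_semi, side, p1prime)
    intensities: pd.DataFrame  # linear scale, NaN = missing
    metadata: pd.DataFrame
    truth: dict

    def to_records(self) -> list[PeptideRecord]:
        records = []
        for pep_id, row in self.pep_info.iterrows():
            vals = self.intensities.loc[pep_id]
            intens = {s: float(v) for s, v in vals.items() if not pd.isna(v)}
            records.append(
                PeptideRecord(
                    stripped_sequence=row["peptide"],
                    protein_accessions=tuple(row["protein_group"].split(";")),
                    gene=row["gene"],
                    proteotypic=bool(row["proteotypic"]),
                    intensities=intens,
                )
            )
        return records


def simulate_cohort(config: SimConfig | None = None, seed: int = 1) -> Cohort:
    """Generate a complete synthetic cohort, deterministic in (config, seed)."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)
    rule = EnzymeRule()
    lo, hi = cfg.pep_len_range

    metadata = make_cohort_metadata(cfg, rng)
    proteins = make_proteome(cfg, rng)
    alloc = _allocate_semi_events(cfg, proteins, rng)

    full_rows: list[dict] = []
    semi_rows: list[dict] = []
    for prot in proteins:
        tryptic = digest(
            prot.sequence, rule, cfg.max_missed_cleavages, lo, hi
        )
        if not tryptic:
            continue
        if len(tryptic) > cfg.max_peptides_per_protein:
            picks = sorted(
                rng.choice(
                    len(tryptic), size=cfg.max_peptides_per_protein, replace=False
                )
            )
            sampled = [tryptic[i] for i in picks]
        else:
            sampled = tryptic
        for pep, s, e in sampled:
            full_rows.append(
                {
                    "peptide": pep,
                    "accession": prot.accession,
                    "gene": prot.gene,
                    "is_semi": False,
                    "side": "",
                    "p1prime": "",
                }
            )
        events = apply_endogenous_cleavage(
            prot, tryptic, alloc.get(prot.accession, 0),
            cfg.p1prime_preference, rng, rule, lo, hi,
        )
        for ev in events:
            semi_rows.append(
                {
                    "peptide": ev["sequence"],
                    "accession": prot.accession,
                    "gene": prot.gene,
                    "is_semi": True,
                    "side": ev["side"],
                    "p1prime": ev["p1prime"],
                }
            )

    # resolve sequence collisions: shared tryptic sequences become
    # non-proteotypic multi-mapping records; ambiguous semi sequences are
    # discarded so that ground truth stays clean
    full_seqs: dict[str, list[dict]] = {}
    for r in full_rows:
        full_seqs.setdefault(r["peptide"], []).append(r)
    info_rows = []
    for seq, rows in full_seqs.items():
        accs = sorted({r["accession"] for r in rows})
        info_rows.append(
            {
                "peptide": seq,
                "protein_group": ";".join(accs),
                "gene": rows[0]["gene"],
                "proteotypic": len(accs) == 1,
                "is_semi": False,
                "side": "",
                "p1prime": "",
            }
        )
    taken = set(full_seqs)
    semi_seen: dict[str, str] = {}
    for r in semi_rows:
        if r["peptide"] in taken:
            continue
        prev = semi_seen.get(r["peptide"])
        if prev is not None and prev != r["accession"]:
            semi_seen[r["peptide"]] = "__AMBIGUOUS__"
            continue
        semi_seen[r["peptide"]] = r["accession"]
    for r in semi_rows:
        if r["peptide"] in taken or semi_seen.get(r["peptide"]) == "__AMBIGUOUS__":
            continue
        taken.add(r["peptide"])
        info_rows.append(
            {
                "peptide": r["peptide"],
                "protein_group": r["accession"],
                "gene": r["gene"],
                "proteotypic": True,
                "is_semi": True,
                "side": r["side"],
                "p1prime": r["p1prime"],
            }
        )
    pep_info = pd.DataFrame(info_rows).set_index(
        pd.Index([r["peptide"] for r in info_rows], name="peptide_id")
    )

    intens, truth = simulate_intensities(proteins, pep_info, metadata, cfg, rng)
    intens = apply_missingness(intens, cfg, rng)

    truth.update(
        {
            "panels": {
                name: {"genes": list(spec.genes), "effects": list(spec.effects)}
                for name, spec in cfg.panels.items()
            },
            "semi_share": dict(cfg.semi_share),
            "semi_peptides": list(pep_info.index[pep_info["is_semi"]]),
            "pc_restricted_semi_genes": list(cfg.pc_restricted_semi_genes),
            "family_bias_genes": list(cfg.semi_family_bias_genes),
            "family_other_genes": list(cfg.semi_family_other_genes),
            "family_bias_share": cfg.semi_family_bias_share,
            "family_total_share": cfg.semi_family_total_share,
        }
    )
    return Cohort(
        config=cfg,
        seed=seed,
        proteins=proteins,
        pep_info=pep_info,
        intensities=intens,
        metadata=metadata,
        truth=truth,
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write cohort.fasta, peptides.tsv (wide), metadata.tsv and truth.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "cohort.fasta",
        "peptides": out / "peptides.tsv",
        "metadata": out / "metadata.tsv",
        "truth": out / "truth.tsv",
    }
    write_fasta(cohort.proteins, paths["fasta"])
    write_peptide_table(
        cohort.to_records(), paths["peptides"], list(cohort.metadata.index)
    )
    write_metadata(cohort.metadata, paths["metadata"])

    rows = []
    for name, panel in cohort.truth["panels"].items():
        for g in panel["genes"]:
            rows.append(
                {
                    "entity": "gene",
                    "id": g,
                    "property": f"panel:{name}",
                    "value": ";".join(f"{e:g}" for e in panel["effects"]),
                }
            )
    for g, sign in cohort.truth["slope_genes"].items():
        rows.append({"entity": "gene", "id": g, "property": "size_slope_sign", "value": sign})
    for pid in cohort.truth["semi_peptides"]:
        rows.append({"entity": "peptide", "id": pid, "property": "is_semi", "value": 1})
    for pid in cohort.truth["discordant_peptides"]:
        rows.append(
            {"entity": "peptide", "id": pid, "property": "discordant", "value": 1}
        )
    for c, s in cohort.truth["semi_share"].items():
        rows.append({"entity": "cohort", "id": c, "property": "semi_share", "value": s})
    write_table(pd.DataFrame(rows), paths["truth"], index=False)
    return paths
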