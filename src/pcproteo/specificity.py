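"""Enzymatic-specificity classification of identified peptides.

A bottom-up experiment digests with trypsin (here after tandem Lys-C +
trypsin digestion, both cutting C-terminal of K/R). A peptide terminus
that is not explained by the digestion enzyme — and is not the annotated
protein N- or C-terminus — evidences endogenous proteolysis that happened
in the tissue before digestion. Classifying both termini of every peptide
against the protein database yields four specificity classes:

* ``full``        – both termini enzymatic,
* ``semi_N``      – non-enzymatic N-terminus, enzymatic C-terminus,
* ``semi_C``      – the mirror case,
* ``nonspecific`` – both termini non-enzymatic.

Peptides touching the annotated protein termini are flagged
``terminal_excluded`` and removed from all downstream proteolysis
statistics, because a protein terminus needs no proteolytic event to
explain it. For the purpose of assigning a class, a protein-terminal
terminus counts as enzymatic-equivalent.

Coordinates are 1-based inclusive throughout; a cleavage site is named by
the index of its P1 residue (the cut lies between P1 and P1').
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import PeptideRecord, ProteinEntry

logger = logging.getLogger(__name__)

NTERM_STATUS = ("enzymatic", "nonenzymatic", "protein_terminal")
SPEC_CLASSES = ("full", "semi_N", "semi_C", "nonspecific")
SEMI_CLASSES = ("semi_N", "semi_C")

# ordering used by the most_specific multi-mapping policy
_CLASS_RANK = {"full": 0, "semi_N": 1, "semi_C": 1, "nonspecific": 2}


@dataclass(frozen=True)
class EnzymeRule:
    """Cleavage specificity of the digestion protease.

    Defaults describe tandem Lys-C + trypsin: cut after K or R. The
    proline block (no cut before P) is off by default, matching the
    common Trypsin/P search convention. ``nterm_window`` start positions
    at the protein N-terminus count as protein-terminal, absorbing
    initiator-methionine excision (positions 1 and 2 by default).
    """

    cleave_after: frozenset = frozenset("KR")
    proline_block: bool = False
    nterm_window: int = 2

    def __post_init__(self) -> None:
        if not self.cleave_after:
            raise ValueError("cleave_after must be non-empty")
        if self.nterm_window < 1:
            raise ValueError("nterm_window must be >= 1")


@dataclass(frozen=True)
class SpecificityAnnotation:
    peptide: str
    accession: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    nterm_status: str
    cterm_status: str
    spec_class: str
    terminal_excluded: bool


@dataclass(frozen=True)
class CleavageEvent:
    """A non-enzymatic terminus mapped onto its protein.

    ``position`` is the 1-based index of the P1 residue; the scissile
    bond lies between ``position`` and ``position + 1``. ``window`` is
    the 8-mer P4 P3 P2 P1 | P1' P2' P3' P4', padded with ``X`` beyond the
    protein ends, so ``window[4]`` is always the first residue after the
    cut.
    """

    accession: str
    position: int
    window: str
    side: str  # peptide_N | peptide_C

    def __post_init__(self) -> None:
        if len(self.window) != 8:
            raise ValueError("cleavage window must have length 8")


def locate_peptide(peptide: str, protein_sequence: str) -> list[int]:
    """All 1-based start positions of ``peptide`` in ``protein_sequence``.

    Overlapping occurrences are reported; an empty list means the peptide
    does not occur.
    """
    starts: list[int] = []
    i = protein_sequence.find(peptide)
    while i != -1:
        starts.append(i + 1)
        i = protein_sequence.find(peptide, i + 1)
    return starts


def classify_terminus(
    protein_sequence: str, start: int, end: int, side: str, rule: EnzymeRule
) -> str:
    """Classify one terminus of the occurrence ``start..end`` (1-based)."""
    n = len(protein_sequence)
    if not (1 <= start <= end <= n):
        raise ValueError(f"coordinates {start}..{end} out of range for length {n}")
    if side == "N":
        if start <= rule.nterm_window:
            return "protein_terminal"
        prev = protein_sequence[start - 2]
        if prev in rule.cleave_after and not (
            rule.proline_block and protein_sequence[start - 1] == "P"
        ):
            return "enzymatic"
        return "nonenzymatic"
    if side == "C":
        if end == n:
            return "protein_terminal"
        last = protein_sequence[end - 1]
        if last in rule.cleave_after and not (
            rule.proline_block and protein_sequence[end] == "P"
        ):
            return "enzymatic"
        return "nonenzymatic"
    raise ValueError(f"side must be 'N' or 'C', got {side!r}")


def _class_from_statuses(nterm: str, cterm: str) -> str:
    # protein_terminal termini are enzymatic-equivalent for class purposes:
    # they require no endogenous cleavage to explain them.
    n_ok = nterm != "nonenzymatic"
    c_ok = cterm != "nonenzymatic"
    if n_ok and c_ok:
        return "full"
    if not n_ok and c_ok:
        return "semi_N"
    if n_ok and not c_ok:
        return "semi_C"
    return "nonspecific"


def classify_occurrence(
    peptide: str, protein_sequence: str, accession: str, start: int, rule: EnzymeRule
) -> SpecificityAnnotation:
    end = start + len(peptide) - 1
    nterm = classify_terminus(protein_sequence, start, end, "N", rule)
    cterm = classify_terminus(protein_sequence, start, end, "C", rule)
    return SpecificityAnnotation(
        peptide=peptide,
        accession=accession,
        start=start,
        end=end,
        nterm_status=nterm,
        cterm_status=cterm,
        spec_class=_class_from_statuses(nterm, cterm),
        terminal_excluded=(nterm == "protein_terminal" or cterm == "protein_terminal"),
    )


def classify_peptide(
    peptide: str, protein: ProteinEntry, rule: EnzymeRule = EnzymeRule()
) -> SpecificityAnnotation:
    """Best annotation of ``peptide`` within one protein.

    If the peptide occurs several times, the most specific occurrence
    wins (full > semi > nonspecific); ties resolve to the smallest start,
    avoiding overcalling of endogenous proteolysis.
    """
    starts = locate_peptide(peptide, protein.sequence)
    if not starts:
        raise ValueError(f"peptide {peptide!r} does not occur in {protein.accession}")
    anns = [
        classify_occurrence(peptide, protein.sequence, protein.accession, s, rule)
        for s in starts
    ]
    anns.sort(key=lambda a: (_CLASS_RANK[a.spec_class], a.start))
    return anns[0]


def classify_table(
    records: Sequence[PeptideRecord],
    proteins: Mapping[str, ProteinEntry] | Iterable[ProteinEntry],
    rule: EnzymeRule = EnzymeRule(),
    multimap_policy: str = "most_specific",
) -> tuple[pd.DataFrame, int]:
    """Classify every peptide record against the protein database.

    Returns ``(annotations, n_dropped)``. Under ``most_specific`` a
    peptide's class is the best class over all mapped proteins; under
    ``proteotypic_only`` non-proteotypic records are dropped and only the
    single mapped accession is considered. Records whose accessions are
    unresolvable or whose sequence is not found in any mapped protein are
    dropped with a counted warning.

    The result has one row per retained input record, indexed by a unique
    peptide id (sequence, suffixed on duplicates).
    """
    if multimap_policy not in ("most_specific", "proteotypic_only"):
        raise ValueError(f"unknown multimap_policy {multimap_policy!r}")
    if not isinstance(proteins, Mapping):
        proteins = {p.accession: p for p in proteins}

    rows: list[dict] = []
    ids: list[str] = []
    counts: dict[str, int] = {}
    n_dropped = 0
    for rec in records:
        seq = rec.stripped_sequence
        k = counts.get(seq, 0)
        counts[seq] = k + 1
        pep_id = seq if k == 0 else f"{seq}#{k}"

        if multimap_policy == "proteotypic_only" and not rec.proteotypic:
            n_dropped += 1
            continue
        candidates: list[SpecificityAnnotation] = []
        unresolved: list[str] = []
        for acc in sorted(rec.protein_accessions):
            prot = proteins.get(acc)
            if prot is None:
                unresolved.append(acc)
                continue
            if not locate_peptide(seq, prot.sequence):
                continue
            candidates.append(classify_peptide(seq, prot, rule))
        if unresolved:
            logger.warning(
                "peptide %s: unresolvable accession(s) %s", seq, unresolved
            )
        if not candidates:
            n_dropped += 1
            logger.warning("peptide %s: no mapping located; dropped", seq)
            continue
        candidates.sort(key=lambda a: (_CLASS_RANK[a.spec_class], a.accession, a.start))
        best = candidates[0]
        ids.append(pep_id)
        rows.append(
            {
                "peptide": best.peptide,
                "accession": best.accession,
                "gene": rec.gene,
                "proteotypic": rec.proteotypic,
                "start": best.start,
                "end": best.end,
                "nterm_status": best.nterm_status,
                "cterm_status": best.cterm_status,
                "spec_class": best.spec_class,
                "terminal_excluded": best.terminal_excluded,
            }
        )
    df = pd.DataFrame(rows, index=pd.Index(ids, name="peptide_id"))
    if df.empty:
        df = pd.DataFrame(
            columns=[
                "peptide",
                "accession",
                "gene",
                "proteotypic",
                "start",
                "end",
                "nterm_status",
                "cterm_status",
                "spec_class",
                "terminal_excluded",
            ],
            index=pd.Index([], name="peptide_id"),
        )
    return df, n_dropped


def cleavage_window(sequence: str, position: int) -> str:
    """P4..P4' 8-mer around the cut after ``position`` (1-based P1 index)."""
    out = []
    for idx in range(position - 3, position + 5):  # 1-based residue indices
        if 1 <= idx <= len(sequence):
            out.append(sequence[idx - 1])
        else:
            out.append("X")
    return "".join(out)


def extract_cleavage_events(
    annotations: pd.DataFrame,
    proteins: Mapping[str, ProteinEntry] | Iterable[ProteinEntry],
) -> pd.DataFrame:
    """One cleavage event per non-enzymatic terminus of each semi peptide.

    Terminal-excluded peptides yield no events. Nonspecific peptides are
    deliberately skipped: the proteolysis read-outs analyse semi-specific
    peptides only.
    """
    if not isinstance(proteins, Mapping):
        proteins = {p.accession: p for p in proteins}
    rows = []
    for pep_id, a in annotations.iterrows():
        if a["terminal_excluded"] or a["spec_class"] not in SEMI_CLASSES:
            continue
        seq = proteins[a["accession"]].sequence
        if a["spec_class"] == "semi_N":
            pos = int(a["start"]) - 1
            side = "peptide_N"
        else:
            pos = int(a["end"])
            side = "peptide_C"
        rows.append(
            {
                "peptide_id": pep_id,
                "accession": a["accession"],
                "position": pos,
                "window": cleavage_window(seq, pos),
                "side": side,
            }
        )
    return pd.DataFrame(
        rows, columns=["peptide_id", "accession", "position", "window", "side"]
    )
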