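"""Terminus classification against an independent brute-force checker."""

from __future__ import annotations

import numpy as np
import pytest

from pcproteo.io import PeptideRecord, ProteinEntry
from pcproteo.specificity import (
    EnzymeRule,
    classify_peptide,
    classify_table,
    classify_terminus,
    cleavage_window,
    extract_cleavage_events,
    locate_peptide,
)

from conftest import DEMO_SEQ

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# independent oracle: direct residue inspection, no shared code paths


def oracle_terminus(seq: str, start: int, end: int, side: str, window=2, cleave="KR"):
    if side == "N":
        if start <= window:
            return "protein_terminal"
        return "enzymatic" if seq[start - 2] in cleave else "nonenzymatic"
    if end == len(seq):
        return "protein_terminal"
    return "enzymatic" if seq[end - 1] in cleave else "nonenzymatic"


def oracle_classify(pep: str, seq: str):
    """Most-specific occurrence classification by exhaustive inspection."""
    rank = {"full": 0, "semi_N": 1, "semi_C": 1, "nonspecific": 2}
    best = None
    for start in range(1, len(seq) - len(pep) + 2):
        if seq[start - 1 : start - 1 + len(pep)] != pep:
            continue
        end = start + len(pep) - 1
        n = oracle_terminus(seq, start, end, "N")
        c = oracle_terminus(seq, start, end, "C")
        n_ok = n in ("enzymatic", "protein_terminal")
        c_ok = c in ("enzymatic", "protein_terminal")
        if n_ok and c_ok:
            cls = "full"
        elif c_ok:
            cls = "semi_N"
        elif n_ok:
            cls = "semi_C"
        else:
            cls = "nonspecific"
        excl = "protein_terminal" in (n, c)
        cand = (rank[cls], start, cls, excl)
        if best is None or cand[:2] < best[:2]:
            best = cand
    assert best is not None
    return best[2], best[3]


# ---------------------------------------------------------------------------


def test_locate_peptide_basics():
    assert locate_peptide("AGDSTK", DEMO_SEQ) == [6]
    assert locate_peptide("AA", "AAA") == [1, 2]  # overlaps allowed
    assert locate_peptide("ZZZ", DEMO_SEQ) == []


@pytest.mark.parametrize(
    "start,end,side,expected",
    [
        (6, 11, "N", "enzymatic"),  # preceded by R at 5
        (6, 11, "C", "enzymatic"),  # ends in K
        (7, 11, "N", "nonenzymatic"),  # preceded by A
        (1, 5, "N", "protein_terminal"),  # start within N-terminal window
        (2, 5, "N", "protein_terminal"),  # initiator-Met excision window
        (12, 15, "C", "protein_terminal"),  # protein C-terminus
    ],
)
def test_classify_terminus_rules(start, end, side, expected):
    assert classify_terminus(DEMO_SEQ, start, end, side, EnzymeRule()) == expected


def test_classify_terminus_out_of_range():
    with pytest.raises(ValueError):
        classify_terminus(DEMO_SEQ, 0, 5, "N", EnzymeRule())
    with pytest.raises(ValueError):
        classify_terminus(DEMO_SEQ, 1, 99, "C", EnzymeRule())


def test_proline_block_changes_status():
    seq = "AAKPLLLRAAA"
    # C-terminus at K followed by P: enzymatic without the block, not with it
    assert classify_terminus(seq, 1, 3, "C", EnzymeRule()) == "enzymatic"
    assert (
        classify_terminus(seq, 1, 3, "C", EnzymeRule(proline_block=True))
        == "nonenzymatic"
    )


def test_classify_peptide_spec_classes(demo_protein):
    assert classify_peptide("AGDSTK", demo_protein).spec_class == "full"
    ann = classify_peptide("GDSTK", demo_protein)
    assert ann.spec_class == "semi_N" and not ann.terminal_excluded
    term = classify_peptide("MKLVR", demo_protein)
    assert term.terminal_excluded
    # non-occurring peptide is an error
    with pytest.raises(ValueError):
        classify_peptide("WWWW", demo_protein)


def test_cleavage_event_coordinates(demo_protein):
    ann, _ = classify_table(
        [PeptideRecord("GDSTK", ("P0TEST",), "DEMO", True, {})],
        [demo_protein],
    )
    ev = extract_cleavage_events(ann, [demo_protein])
    assert len(ev) == 1
    row = ev.iloc[0]
    # endogenous cut lies between residues 6 and 7: P1 = A(6), P1' = G(7)
    assert row["side"] == "peptide_N"
    assert row["position"] == 6
    assert row["window"] == "LVRAGDST"
    assert row["window"][4] == DEMO_SEQ[6]  # P1' is first residue after the cut


def test_cleavage_window_padding():
    # cut after position 2 of a short protein: P4, P3 padded
    assert cleavage_window("ABCDEF", 2) == "XXABCDEF"
    # cut near the C-terminus: P2'..P4' padded
    assert cleavage_window("ABCDEF", 5) == "BCDEFXXX"


def test_semi_C_event_near_terminus():
    # peptide ends at position length-1 with nonenzymatic C terminus
    seq = "MKRAAAALLLLDDDDW"
    prot = ProteinEntry(accession="A1", gene="", sequence=seq)
    pep = seq[3:15]  # starts after R(3), ends at D(15), seq[14]='D' nonenzymatic
    ann, _ = classify_table([PeptideRecord(pep, ("A1",), "", True, {})], [prot])
    assert ann.iloc[0]["spec_class"] == "semi_C"
    ev = extract_cleavage_events(ann, [prot])
    assert ev.iloc[0]["position"] == 15
    assert ev.iloc[0]["window"].endswith("XXX")  # P2'..P4' beyond the protein


def test_terminal_excluded_produces_no_events(demo_protein):
    ann, _ = classify_table(
        [
            PeptideRecord("MKLVR", ("P0TEST",), "DEMO", True, {}),
            PeptideRecord("AGDSTK", ("P0TEST",), "DEMO", True, {}),
        ],
        [demo_protein],
    )
    assert extract_cleavage_events(ann, [demo_protein]).empty


def test_exhaustive_substring_oracle(rng):
    """Every 7-30mer of a random protein agrees with direct inspection."""
    seq = "".join(rng.choice(list(AA), size=80))
    prot = ProteinEntry(accession="R1", gene="", sequence=seq)
    n_checked = 0
    for length in range(7, 31):
        for start in range(1, len(seq) - length + 2):
            pep = seq[start - 1 : start - 1 + length]
            ann = classify_peptide(pep, prot)
            cls, excl = oracle_classify(pep, seq)
            assert ann.spec_class == cls, (pep, start)
            assert ann.terminal_excluded == excl, (pep, start)
            n_checked += 1
    assert n_checked > 1000


def test_classify_table_count_conservation_and_order_invariance(rng):
    seq = "".join(rng.choice(list(AA), size=120))
    prot = ProteinEntry(accession="R1", gene="G", sequence=seq)
    peps = [seq[i : i + 9] for i in range(0, 100, 3)]
    records = [PeptideRecord(p, ("R1",), "G", True, {}) for p in peps]
    records.append(PeptideRecord("WWWWWWWW", ("MISSING",), "G", True, {}))
    ann, dropped = classify_table(records, [prot])
    assert len(ann) + dropped == len(records)
    shuffled = [records[i] for i in rng.permutation(len(records))]
    ann2, dropped2 = classify_table(shuffled, [prot])
    assert dropped2 == dropped
    a = ann.sort_values(["peptide", "start"]).reset_index(drop=True)
    b = ann2.sort_values(["peptide", "start"]).reset_index(drop=True)
    assert a.equals(b)


def test_cleave_after_monotonicity(rng):
    """Adding a residue to cleave_after never turns enzymatic into nonenzymatic."""
    seq = "".join(rng.choice(list(AA), size=60))
    base = EnzymeRule()
    wider = EnzymeRule(cleave_after=frozenset("KRL"))
    for start in range(3, 40):
        for end in range(start + 6, min(start + 20, len(seq))):
            for side in "NC":
                s1 = classify_terminus(seq, start, end, side, base)
                s2 = classify_terminus(seq, start, end, side, wider)
                if s1 == "enzymatic":
                    assert s2 == "enzymatic"


def test_multimap_policy():
    pa = ProteinEntry(accession="A", gene="", sequence="MKLVRAGDSTKNNFW")
    pb = ProteinEntry(accession="B", gene="", sequence="MMMWAGDSTKWWWW")
    rec = PeptideRecord("AGDSTK", ("A", "B"), "", False, {})
    ann, _ = classify_table([rec], [pa, pb], multimap_policy="most_specific")
    # full in A (after R), semi_N in B (after W) -> most specific wins
    assert ann.iloc[0]["spec_class"] == "full"
    assert ann.iloc[0]["accession"] == "A"
    ann2, dropped = classify_table([rec], [pa, pb], multimap_policy="proteotypic_only")
    assert len(ann2) == 0 and dropped == 1
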