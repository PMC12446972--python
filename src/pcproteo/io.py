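"""Readers and writers for the external formats of the pipeline.

All tabular interchange is plain TSV (UTF-8, '.' decimal separator).
Missing intensities are encoded as empty cells on disk; an intensity of 0
is treated as missing on read, following the DIA-NN convention (and
avoiding log2(0) downstream).

No science lives here: this module only parses, validates, and round-trips
the domain types used by the analysis modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

COMPARTMENTS = ("NAT", "PC", "TUMOR")
GRADES = ("G1", "G2", "G3", "unknown")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_SEQ_ALPHABET = set(AMINO_ACIDS) | {"X"}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ProteinEntry:
    """One protein database entry.

    ``sequence`` is uppercase, 20-letter amino-acid alphabet (``X``
    allowed as an unknown residue).
    """

    accession: str
    gene: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"empty sequence for accession {self.accession!r}")
        bad = set(self.sequence) - _SEQ_ALPHABET
        if bad:
            raise FormatError(
                f"invalid residues {sorted(bad)} in sequence of {self.accession!r}"
            )


@dataclass
class PeptideRecord:
    """One identified stripped peptide with protein mappings and intensities.

    ``intensities`` maps sample_id -> linear (non-log) intensity; absent
    keys are missing values.
    """

    stripped_sequence: str
    protein_accessions: tuple[str, ...]
    gene: str
    proteotypic: bool
    intensities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.stripped_sequence or not self.stripped_sequence.isalpha():
            raise FormatError(
                f"stripped sequence must be plain letters: {self.stripped_sequence!r}"
            )
        self.stripped_sequence = self.stripped_sequence.upper()
        self.protein_accessions = tuple(self.protein_accessions)
        if len(self.protein_accessions) < 1:
            raise FormatError(
                f"peptide {self.stripped_sequence} maps to no protein accession"
            )
        if self.proteotypic and len(self.protein_accessions) != 1:
            raise FormatError(
                f"peptide {self.stripped_sequence} is flagged proteotypic but maps "
                f"to {len(self.protein_accessions)} accessions"
            )
        for s, v in self.intensities.items():
            if v < 0 or not math.isfinite(v):
                raise FormatError(
                    f"negative or non-finite intensity {v} for peptide "
                    f"{self.stripped_sequence} in sample {s}"
                )


@dataclass
class QuantMatrix:
    """Features x samples matrix of log2 intensities; NaN marks missing."""

    data: pd.DataFrame
    level: str = "protein"

    def __post_init__(self) -> None:
        if self.level not in ("peptide", "protein"):
            raise ValueError(f"unknown level {self.level!r}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][:3].tolist()
            raise FormatError(f"duplicate feature ids, e.g. {dup}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][:3].tolist()
            raise FormatError(f"duplicate sample ids, e.g. {dup}")
        vals = self.data.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise FormatError("QuantMatrix contains non-finite present values")
        self.data = self.data.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def copy_with(self, data: pd.DataFrame) -> "QuantMatrix":
        return QuantMatrix(data=data, level=self.level)

    def to_tsv(self, path: str | Path) -> None:
        write_table(self.data, path, index_label="feature_id")

    @classmethod
    def read_tsv(cls, path: str | Path, level: str = "protein") -> "QuantMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(data=df, level=level)


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"gene set {self.set_id!r} is empty")


# ---------------------------------------------------------------------------
# FASTA


def _parse_fasta_header(header_id: str, description: str, recno: int) -> tuple[str, str]:
    """Return (accession, gene) from a FASTA header id + description.

    Accepts the UniProt ``sp|ACC|NAME`` / ``tr|ACC|NAME`` dialect and the
    bare ``>ACC`` dialect. A ``GN=SYMBOL`` token in the description sets
    the gene symbol.
    """
    if "|" in header_id:
        parts = header_id.split("|")
        if len(parts) < 3 or not parts[1]:
            raise FormatError(
                f"malformed UniProt-style header in record {recno}: {header_id!r}"
            )
        accession = parts[1]
    else:
        accession = header_id
    if not accession:
        raise FormatError(f"empty accession in record {recno}")
    gene = ""
    for tok in description.split():
        if tok.startswith("GN="):
            gene = tok[3:]
            break
    return accession, gene


def read_fasta(path: str | Path) -> list[ProteinEntry]:
    """Read a protein database; sequences are uppercased and validated."""
    entries: list[ProteinEntry] = []
    seen: set[str] = set()
    for recno, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        accession, gene = _parse_fasta_header(rec.id, rec.description, recno)
        seq = str(rec.seq).upper().strip()
        if not seq:
            raise FormatError(f"empty sequence for {accession!r} (record {recno})")
        if accession in seen:
            raise FormatError(f"duplicate accession {accession!r} (record {recno})")
        seen.add(accession)
        entries.append(ProteinEntry(accession=accession, gene=gene, sequence=seq))
    if not entries:
        raise FormatError(f"no FASTA records found in {path}")
    return entries


def write_fasta(entries: Iterable[ProteinEntry], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in entries:
            gn = f" GN={e.gene}" if e.gene else ""
            fh.write(f">sp|{e.accession}|{e.accession}_SYN{gn}\n")
            for i in range(0, len(e.sequence), 60):
                fh.write(e.sequence[i : i + 60] + "\n")


def protein_index(entries: Iterable[ProteinEntry]) -> dict[str, ProteinEntry]:
    return {e.accession: e for e in entries}


# ---------------------------------------------------------------------------
# Peptide tables

_PEP_REQUIRED = ["protein_group", "gene", "stripped_sequence", "proteotypic"]


def _parse_bool(x: object) -> bool:
    s = str(x).strip().lower()
    if s in ("1", "true", "t", "yes"):
        return True
    if s in ("0", "false", "f", "no", ""):
        return False
    raise FormatError(f"cannot parse boolean value {x!r}")


def _parse_intensity(x: object) -> float | None:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return None
    s = str(x).strip()
    if s == "" or s.lower() == "nan":
        return None
    v = float(s)
    if v < 0:
        raise FormatError(f"negative intensity {v}")
    if v == 0:
        return None  # DIA-NN convention: zero == not quantified
    return v


def read_peptide_table(path: str | Path, layout: str = "wide") -> list[PeptideRecord]:
    """Read a peptide-level quantification table.

    ``wide``: one column per sample after the required columns.
    ``long``: required columns plus ``sample_id`` and ``intensity``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _PEP_REQUIRED if c not in df.columns]
    if layout == "long":
        missing += [c for c in ("sample_id", "intensity") if c not in df.columns]
    if missing:
        raise FormatError(f"peptide table missing required columns: {missing}")

    records: list[PeptideRecord] = []
    if layout == "wide":
        sample_cols = [c for c in df.columns if c not in _PEP_REQUIRED]
        for _, row in df.iterrows():
            intens: dict[str, float] = {}
            for s in sample_cols:
                v = _parse_intensity(row[s])
                if v is not None:
                    intens[s] = v
            records.append(_make_record(row, intens))
    elif layout == "long":
        keys = ["protein_group", "gene", "stripped_sequence", "proteotypic"]
        for key, grp in df.groupby(keys, sort=False):
            intens = {}
            for _, row in grp.iterrows():
                v = _parse_intensity(row["intensity"])
                if v is not None:
                    intens[str(row["sample_id"])] = v
            records.append(_make_record(grp.iloc[0], intens))
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return records


def _make_record(row: pd.Series, intensities: dict[str, float]) -> PeptideRecord:
    accs = tuple(a for a in str(row["protein_group"]).split(";") if a)
    gene = "" if pd.isna(row["gene"]) else str(row["gene"])
    return PeptideRecord(
        stripped_sequence=str(row["stripped_sequence"]),
        protein_accessions=accs,
        gene=gene,
        proteotypic=_parse_bool(row["proteotypic"]),
        intensities=intensities,
    )


def write_peptide_table(
    records: Sequence[PeptideRecord], path: str | Path, sample_ids: Sequence[str]
) -> None:
    """Write records as a wide TSV (missing = empty cell)."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "protein_group": ";".join(r.protein_accessions),
            "gene": r.gene,
            "stripped_sequence": r.stripped_sequence,
            "proteotypic": int(r.proteotypic),
        }
        for s in sample_ids:
            v = r.intensities.get(s)
            row[s] = "" if v is None else v
        rows.append(row)
    write_table(pd.DataFrame(rows), path, index=False)


def records_to_frames(
    records: Sequence[PeptideRecord], sample_ids: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into an info frame and a linear-intensity frame.

    Peptide ids equal the stripped sequence; duplicated sequences get a
    ``#k`` suffix so that both frames have unique indices.
    """
    ids: list[str] = []
    counts: dict[str, int] = {}
    for r in records:
        k = counts.get(r.stripped_sequence, 0)
        counts[r.stripped_sequence] = k + 1
        ids.append(r.stripped_sequence if k == 0 else f"{r.stripped_sequence}#{k}")
    info = pd.DataFrame(
        {
            "peptide": [r.stripped_sequence for r in records],
            "protein_group": [";".join(r.protein_accessions) for r in records],
            "gene": [r.gene for r in records],
            "proteotypic": [r.proteotypic for r in records],
        },
        index=pd.Index(ids, name="peptide_id"),
    )
    mat = np.full((len(records), len(sample_ids)), np.nan)
    col = {s: j for j, s in enumerate(sample_ids)}
    for i, r in enumerate(records):
        for s, v in r.intensities.items():
            if s in col:
                mat[i, col[s]] = v
    intens = pd.DataFrame(mat, index=info.index, columns=list(sample_ids))
    return info, intens


# ---------------------------------------------------------------------------
# Sample metadata

_META_REQUIRED = [
    "sample_id",
    "patient_id",
    "compartment",
    "tumor_diameter",
    "grade",
    "lesion_index",
]


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata; returns a validated DataFrame indexed by sample_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _META_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"metadata missing required columns: {missing}")
    out = pd.DataFrame(
        {
            "sample_id": df["sample_id"].astype(str),
            "patient_id": df["patient_id"].astype(str),
            "compartment": df["compartment"].astype(str),
        }
    )
    bad = sorted(set(out["compartment"]) - set(COMPARTMENTS))
    if bad:
        raise FormatError(
            f"unknown compartment value(s) {bad}; allowed: {list(COMPARTMENTS)}"
        )
    diam = pd.to_numeric(df["tumor_diameter"], errors="coerce")
    if ((diam <= 0) & diam.notna()).any():
        raise FormatError("tumor_diameter must be positive (millimetres)")
    out["tumor_diameter"] = diam
    grade = df["grade"].fillna("unknown").replace("", "unknown")
    badg = sorted(set(grade) - set(GRADES))
    if badg:
        raise FormatError(f"unknown grade value(s) {badg}; allowed: {list(GRADES)}")
    out["grade"] = grade
    lesion = pd.to_numeric(df["lesion_index"], errors="raise").astype(int)
    if (lesion < 1).any():
        raise FormatError("lesion_index must be >= 1")
    out["lesion_index"] = lesion
    if out["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in metadata")
    return out.set_index("sample_id", drop=False)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    write_table(meta.reset_index(drop=True), path, index=False)


# ---------------------------------------------------------------------------
# Gene sets and matrisome categories


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: set_id <TAB> name <TAB> member1 <TAB> member2 ..."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT line {lineno} has fewer than 3 fields")
            members = [g for g in parts[2:] if g]
            if len(members) != len(set(members)):
                raise FormatError(f"GMT line {lineno} has duplicate members")
            sets.append(GeneSet(set_id=parts[0], name=parts[1], members=frozenset(members)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.name, *sorted(s.members)]) + "\n")


_MATRISOME_DIVISIONS = ("core matrisome", "matrisome-associated", "non-matrisome")
_MATRISOME_CATEGORIES = (
    "collagens",
    "ECM glycoproteins",
    "proteoglycans",
    "ECM regulators",
    "secreted factors",
    "ECM-affiliated",
    "other",
)


def read_matrisome_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for c in ("gene", "division", "category"):
        if c not in df.columns:
            raise FormatError(f"matrisome table missing column {c!r}")
    bad_div = sorted(set(df["division"]) - set(_MATRISOME_DIVISIONS))
    bad_cat = sorted(set(df["category"]) - set(_MATRISOME_CATEGORIES))
    if bad_div or bad_cat:
        raise FormatError(
            f"matrisome table has unknown division {bad_div} or category {bad_cat}"
        )
    if df["gene"].str.upper().duplicated().any():
        raise FormatError("matrisome table has duplicate gene rows")
    return df


# ---------------------------------------------------------------------------
# Generic table writing

# %.17g round-trips IEEE doubles exactly, satisfying the >=12 significant
# digit round-trip contract.
_FLOAT_FMT = "%.17g"


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    index: bool = True,
    index_label: str | None = None,
) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(
        path,
        sep="\t",
        na_rep="",
        float_format=_FLOAT_FMT,
        index=index,
        index_label=index_label,
    )
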