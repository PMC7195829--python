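"""Readers and writers for every external representation the pipeline touches.

Formats
-------
* FASTA (multi-line, ``>`` headers) for protein sequences.
* PSI-BLAST ASCII PSSM (the ``-out_ascii_pssm`` dialect): header line with the
  residue column order, one row per sequence position carrying the position
  index, the residue, 20 integer log-odds scores and further columns that are
  ignored here.
* Tab-separated tables (UTF-8, ``.`` decimal, header row) for the domain
  catalog, protein-to-domain annotations, the amino-acid index table, labeled
  datasets, and all pipeline outputs.
* Trained models are stored as a single self-describing joblib archive with a
  format-version stamp.

The packaged domain catalog and amino-acid index table (files named
``*_synthetic.tsv``) are synthetic stand-ins with the same shape as the
curated resources a production run would use: 63 extracellular-matrix domain
accessions and 24 physicochemical properties covering all 20 residues.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import joblib
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: PSI-BLAST residue column order.
AA_ORDER: tuple[str, ...] = tuple("ARNDCQEGHILKMFPSTWYV")
VALID_RESIDUES: frozenset[str] = frozenset(AA_ORDER) | {"X"}

ECM = "ECM"
NON_ECM = "nonECM"
LABELS = (ECM, NON_ECM)

MODEL_FORMAT_VERSION = 1


class FormatError(ValueError):
    """Raised when an input file violates its expected layout."""


@dataclasses.dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("protein record with empty identifier")
        if len(self.sequence) < 1:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise FormatError(
                f"record {self.id!r}: invalid residue(s) {sorted(bad)!r}; "
                f"allowed are the 20 canonical letters plus 'X'"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass(frozen=True)
class PSSM:
    """Position-specific scoring matrix: one integer log-odds row per residue."""

    protein_id: str
    scores: np.ndarray  # (L, 20) int
    residue_columns: tuple[str, ...] = AA_ORDER

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise FormatError(
                f"PSSM for {self.protein_id!r}: expected an L x 20 matrix, "
                f"got shape {scores.shape}"
            )
        if not np.issubdtype(scores.dtype, np.integer):
            raise FormatError(f"PSSM for {self.protein_id!r}: scores must be integers")
        object.__setattr__(self, "scores", scores)

    @property
    def length(self) -> int:
        return int(self.scores.shape[0])


@dataclasses.dataclass(frozen=True)
class DomainCatalog:
    """Ordered list of extracellular-matrix domain accessions (D_1..D_n)."""

    accessions: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.accessions)) != len(self.accessions):
            raise FormatError("domain catalog contains duplicate accessions")

    def __len__(self) -> int:
        return len(self.accessions)


@dataclasses.dataclass(frozen=True)
class AAIndexTable:
    """Named physicochemical properties, each mapping the 20 residues to a value."""

    values: pd.DataFrame  # index: property names, columns: residue letters

    def __post_init__(self) -> None:
        missing_cols = set(AA_ORDER) - set(self.values.columns)
        if missing_cols:
            raise FormatError(f"amino-acid index table lacks residue column(s) {sorted(missing_cols)}")
        for prop in self.values.index:
            row = self.values.loc[prop, list(AA_ORDER)]
            if row.isna().any():
                residue = row.index[row.isna()][0]
                raise FormatError(
                    f"property {prop!r} is missing a value for residue {residue!r}"
                )

    @property
    def properties(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    def value(self, prop: str, residue: str) -> float:
        return float(self.values.at[prop, residue])


@dataclasses.dataclass
class LabeledDataset:
    """Protein records with ECM / nonECM class labels."""

    records: list[tuple[ProteinRecord, str]]

    def __post_init__(self) -> None:
        for _, label in self.records:
            if label not in LABELS:
                raise FormatError(f"unknown class label {label!r}; expected one of {LABELS}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_pos(self) -> int:
        return sum(1 for _, lab in self.records if lab == ECM)

    @property
    def n_neg(self) -> int:
        return sum(1 for _, lab in self.records if lab == NON_ECM)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "UniprotID": [r.id for r, _ in self.records],
                "Class": [lab for _, lab in self.records],
                "FastaSequence": [r.sequence for r, _ in self.records],
            }
        )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into validated :class:`ProteinRecord` objects.

    Residues are upper-cased; the identifier is the first whitespace-delimited
    token after ``>``. Duplicate identifiers and residues outside the
    20-letter alphabet plus ``X`` are errors.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence identifier {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq).upper()))
    if not records:
        raise FormatError(f"no records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM


def read_pssm(
    path: str | Path,
    expected_length: int | None = None,
    protein_id: str | None = None,
) -> PSSM:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    Only the first 20 score columns of each row are consumed; the weighted
    percentage block and the trailing information-content columns are ignored.
    The residue column order is taken from the file's header line.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    header_idx = None
    columns: tuple[str, ...] | None = None
    for i, line in enumerate(lines):
        tokens = line.split()
        if len(tokens) >= 20 and all(t in VALID_RESIDUES and len(t) == 1 for t in tokens[:20]):
            header_idx = i
            columns = tuple(tokens[:20])
            break
    if header_idx is None or columns is None:
        raise FormatError(f"{path}: no PSSM header line with residue columns found")

    rows: list[list[int]] = []
    for i in range(header_idx + 1, len(lines)):
        tokens = lines[i].split()
        if not tokens:
            if rows:
                break
            continue
        if not tokens[0].lstrip("-").isdigit():
            break
        row_no = len(rows) + 1
        if len(tokens) < 22:
            raise FormatError(
                f"{path}: row {row_no} has {max(len(tokens) - 2, 0)} score "
                f"column(s); expected 20"
            )
        try:
            scores = [int(t) for t in tokens[2:22]]
        except ValueError as exc:
            raise FormatError(f"{path}: row {row_no}: non-integer score ({exc})") from None
        rows.append(scores)

    if not rows:
        raise FormatError(f"{path}: header found but no score rows")
    if expected_length is not None and len(rows) != expected_length:
        raise FormatError(
            f"{path}: PSSM has {len(rows)} rows but the protein sequence has "
            f"length {expected_length}"
        )
    return PSSM(
        protein_id=protein_id or path.stem,
        scores=np.asarray(rows, dtype=np.int64),
        residue_columns=columns,
    )


# ---------------------------------------------------------------------------
# Tabular inputs


def read_domain_catalog(path: str | Path | None = None) -> DomainCatalog:
    """Read the ECM-domain catalog; defaults to the packaged synthetic fixture."""
    if path is None:
        path = resources.files("ecmpredict.data") / "domain_catalog_synthetic.tsv"
    df = pd.read_csv(path, sep="\t", dtype=str)
    accessions = tuple(a.strip() for a in df.iloc[:, 0])
    return DomainCatalog(accessions=accessions)


def read_domain_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read (protein_id, accession) pairs into a protein -> domain-set map.

    Proteins absent from the map are treated downstream as having no domains.
    Accessions are compared case-sensitively after whitespace trimming.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: annotation file needs (protein_id, accession) columns")
    mapping: dict[str, set[str]] = {}
    for pid, acc in zip(df.iloc[:, 0], df.iloc[:, 1]):
        mapping.setdefault(str(pid).strip(), set()).add(str(acc).strip())
    return mapping


def read_aaindex_table(path: str | Path | None = None) -> AAIndexTable:
    """Read the physicochemical property table; defaults to the packaged fixture."""
    if path is None:
        path = resources.files("ecmpredict.data") / "aaindex24_synthetic.tsv"
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    return AAIndexTable(values=df)


def read_labeled_dataset(path: str | Path) -> LabeledDataset:
    """Read a labeled training table (UniprotID, Class, FastaSequence)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    id_col = cols.get("uniprotid", df.columns[0])
    class_col = cols.get("class", df.columns[1])
    seq_col = cols.get("fastasequence", df.columns[2])
    records = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        pid = str(row[id_col]).strip()
        if pid in seen:
            raise FormatError(f"{path}: duplicate protein id {pid!r}")
        seen.add(pid)
        label = str(row[class_col]).strip()
        if label not in LABELS:
            raise FormatError(f"{path}: unknown class label {label!r} for {pid!r}")
        records.append((ProteinRecord(id=pid, sequence=str(row[seq_col]).strip().upper()), label))
    return LabeledDataset(records=records)


def write_labeled_dataset(dataset: LabeledDataset | pd.DataFrame, path: str | Path) -> None:
    frame = dataset.to_frame() if isinstance(dataset, LabeledDataset) else dataset
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Feature tables and generic TSV helpers


def write_feature_table(features: pd.DataFrame, path: str | Path) -> None:
    """Write a per-protein feature table (index = protein id)."""
    features.to_csv(path, sep="\t", index=True, index_label="protein_id")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="protein_id")


def read_labels_table(path: str | Path) -> pd.Series:
    """Read a (protein_id, label) TSV into a Series indexed by protein id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    ser = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="label")
    bad = set(ser.unique()) - set(LABELS)
    if bad:
        raise FormatError(f"{path}: unknown class label(s) {sorted(bad)!r}")
    return ser


# ---------------------------------------------------------------------------
# Model persistence


def save_model(model, path: str | Path) -> None:
    """Serialize a trained ensemble with a format-version stamp."""
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path: str | Path):
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupt / not a joblib archive
        raise FormatError(f"{path}: cannot read model archive ({exc})") from None
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise FormatError(f"{path}: not a recognized model archive")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise FormatError(
            f"{path}: model format version {payload['format_version']} is not "
            f"supported (expected {MODEL_FORMAT_VERSION})"
        )
    return payload["model"]
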