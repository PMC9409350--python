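"""Sequence, dataset and report I/O.

Reads and writes the plain-text formats the pipeline consumes: FASTA protein
sequences, labeled training/testing tables (TSV), and prediction reports
(TSV).  Product classes are the chain-length categories of linear polyprenyl
pyrophosphates: C10 (GPP), C15 (FPP), C20 (GGPP), C25 (GFPP) and >=C30 (PPP),
plus NA for enzymes with no detectable activity.  C10 and NA occur only as
experimental labels; the predictor never emits them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "ProductClass",
    "ProteinSequence",
    "LabeledRecord",
    "PredictionReportRow",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_labeled_dataset",
    "write_labeled_dataset",
    "read_prediction_report",
    "write_prediction_report",
    "REPORT_COLUMNS",
]

#: The 20 canonical one-letter amino-acid codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# 'X' (unknown residue) is tolerated in sequences but cannot sit on a floor
# site; the floors module rejects it there.
_SEQUENCE_ALPHABET = frozenset(AMINO_ACIDS + "X")


class FormatError(ValueError):
    """Raised for malformed input files."""


class ProductClass(enum.Enum):
    """Product chain-length class of a trans-prenyltransferase.

    Ordered by chain length.  ``carbons`` is the carbon count of the product
    (30 stands for the open-ended ">=C30" bin); NA has no carbon count.
    """

    C10 = "C10"
    C15 = "C15"
    C20 = "C20"
    C25 = "C25"
    GE_C30 = ">=C30"
    NA = "NA"

    @property
    def carbons(self) -> int | None:
        return _CARBONS[self]

    @classmethod
    def parse(cls, text: str) -> "ProductClass":
        """Parse a label cell; accepts 'C20', '>=C30', 'GE_C30', '≥C30'."""
        t = text.strip().replace("≥", ">=").upper()
        aliases = {
            "GE_C30": cls.GE_C30,
            ">=C30": cls.GE_C30,
            ">C30": cls.GE_C30,
            "C30": cls.GE_C30,
        }
        if t in aliases:
            return aliases[t]
        for member in cls:
            if member.value.upper() == t or member.name == t:
                return member
        raise FormatError(f"unknown product class label: {text!r}")

    def __str__(self) -> str:  # report cells print 'C20', '>=C30', ...
        return self.value


_CARBONS = {
    ProductClass.C10: 10,
    ProductClass.C15: 15,
    ProductClass.C20: 20,
    ProductClass.C25: 25,
    ProductClass.GE_C30: 30,
    ProductClass.NA: None,
}

#: Experimental product-detection methods seen in the literature tables.
DETECTION_METHODS = ("radio-GC", "radio-HPLC", "TLC", "HPLC-MS/MS", "unknown")


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence with optional taxonomy annotation.

    ``residues`` is uppercase, non-empty, over the 20 canonical codes plus X.
    """

    id: str
    residues: str
    description: str = ""
    kingdom: str | None = None
    phylum: str | None = None
    organism: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence id must be non-empty")
        seq = self.residues.upper()
        if not seq:
            raise FormatError(f"{self.id}: empty sequence")
        for i, ch in enumerate(seq, start=1):
            if ch not in _SEQUENCE_ALPHABET:
                raise FormatError(
                    f"{self.id}: illegal residue character {ch!r} at position {i}"
                )
        object.__setattr__(self, "residues", seq)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class LabeledRecord:
    """A sequence with its experimentally determined product class."""

    sequence: ProteinSequence
    label: ProductClass
    label_secondary: ProductClass | None = None
    source_method: str = "unknown"

    def __post_init__(self) -> None:
        if self.source_method not in DETECTION_METHODS:
            raise FormatError(
                f"{self.sequence.id}: unknown detection method "
                f"{self.source_method!r}; expected one of {DETECTION_METHODS}"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a protein FASTA file.

    Headers are split at the first whitespace into id and description;
    sequence lines may be wrapped; blank lines are ignored; trailing '*'
    stop characters are stripped.  Raises :class:`FormatError` for an empty
    file, a duplicate id, or an illegal residue character (reported with its
    1-based position).
    """
    path = Path(path)
    records: list[ProteinSequence] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        parts = header.split(None, 1)
        rid = parts[0]
        desc = parts[1] if len(parts) > 1 else ""
        if rid in seen:
            raise FormatError(f"{path}: duplicate sequence id {rid!r}")
        seen.add(rid)
        seq = "".join(chunks)
        if seq.endswith("*"):
            seq = seq.rstrip("*")
        records.append(ProteinSequence(id=rid, residues=seq, description=desc))

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                chunks = []
            else:
                if header is None:
                    raise FormatError(f"{path}: sequence data before first header")
                chunks.append(line)
    flush()
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinSequence], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA with lines wrapped at ``width`` residues."""
    with open(path, "w") as fh:
        for rec in records:
            head = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{head}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Labeled dataset TSV
# ---------------------------------------------------------------------------

_REQUIRED_DATASET_COLUMNS = ("id", "label")


def read_labeled_dataset(
    path: str | Path,
    fasta: str | Path | None = None,
) -> list[LabeledRecord]:
    """Read a labeled dataset TSV.

    Required columns: ``id``, ``label``, and either an inline ``sequence``
    column or a companion FASTA file (``fasta=``) supplying the sequences by
    id.  Optional columns: ``kingdom``, ``phylum``, ``organism``, ``method``,
    ``label_secondary``.  Rows with unparseable labels are rejected with
    their row number.
    """
    path = Path(path)
    # keep_default_na: 'NA' is a real label (no detectable activity)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_DATASET_COLUMNS if c not in df.columns]
    if "sequence" not in df.columns and fasta is None:
        missing.append("sequence (or supply fasta=)")
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    seq_by_id: dict[str, ProteinSequence] = {}
    if fasta is not None:
        seq_by_id = {r.id: r for r in read_fasta(fasta)}

    records: list[LabeledRecord] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # 1-based, counting the header line
        rid = row["id"].strip()
        if not rid:
            raise FormatError(f"{path}: row {rownum}: empty id")
        if rid in seen:
            raise FormatError(f"{path}: row {rownum}: duplicate id {rid!r}")
        seen.add(rid)
        try:
            label = ProductClass.parse(row["label"])
        except FormatError as exc:
            raise FormatError(f"{path}: row {rownum}: {exc}") from exc
        secondary = None
        if row.get("label_secondary", ""):
            secondary = ProductClass.parse(row["label_secondary"])
        if "sequence" in df.columns and row["sequence"].strip():
            seq = ProteinSequence(
                id=rid,
                residues=row["sequence"].strip(),
                kingdom=row.get("kingdom", "") or None,
                phylum=row.get("phylum", "") or None,
                organism=row.get("organism", "") or None,
            )
        else:
            if rid not in seq_by_id:
                raise FormatError(f"{path}: row {rownum}: id {rid!r} not in FASTA")
            base = seq_by_id[rid]
            seq = ProteinSequence(
                id=rid,
                residues=base.residues,
                description=base.description,
                kingdom=row.get("kingdom", "") or None,
                phylum=row.get("phylum", "") or None,
                organism=row.get("organism", "") or None,
            )
        method = row.get("method", "").strip() or "unknown"
        records.append(
            LabeledRecord(sequence=seq, label=label, label_secondary=secondary, source_method=method)
        )
    if not records:
        raise FormatError(f"{path}: dataset has no rows")
    return records


def write_labeled_dataset(records: Iterable[LabeledRecord], path: str | Path) -> None:
    """Write labeled records as a TSV with inline sequences."""
    rows = []
    for rec in records:
        rows.append(
            {
                "id": rec.sequence.id,
                "sequence": rec.sequence.residues,
                "label": str(rec.label),
                "label_secondary": str(rec.label_secondary) if rec.label_secondary else "",
                "kingdom": rec.sequence.kingdom or "",
                "phylum": rec.sequence.phylum or "",
                "organism": rec.sequence.organism or "",
                "method": rec.source_method,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Prediction report TSV
# ---------------------------------------------------------------------------

#: Fixed report column order.  Floor cells hold the query residue one-letter
#: code with its 1-based query position (e.g. "L121") or "-" for a gap.
REPORT_COLUMNS = (
    "query_id",
    "best_template",
    "identity_pct",
    "floor1_site1",
    "floor1_site2",
    "floor1_site3",
    "floor2_site1",
    "floor2_site2",
    "floor2_site3",
    "floor3_site1",
    "floor3_site2",
    "floor3_site3",
    "score_floor1",
    "score_floor2",
    "score_floor3",
    "predicted",
    "flags",
)


@dataclass(frozen=True)
class PredictionReportRow:
    """One report line per query; mirrors the screening-table layout
    (best template, percent identity, predicted class)."""

    query_id: str
    best_template: str
    identity: float  # fraction in [0, 1]
    floor_cells: tuple[str, ...]  # 9 cells, residue+position or "-"
    floor_scores: tuple[float, float, float]
    predicted: tuple[ProductClass, ...]  # (primary,) or (primary, secondary)
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.floor_cells) != 9:
            raise FormatError("expected 9 floor cells")
        if not 1 <= len(self.predicted) <= 2:
            raise FormatError("expected one or two predicted classes")

    @property
    def predicted_text(self) -> str:
        """Dual calls print shorter-chain first, e.g. 'C20/C25'."""
        ordered = sorted(self.predicted, key=lambda c: c.carbons)
        return "/".join(str(c) for c in ordered)


def write_prediction_report(rows: Sequence[PredictionReportRow], path: str | Path) -> None:
    """Write a prediction report TSV with the fixed column order."""
    out = []
    for row in rows:
        rec = {
            "query_id": row.query_id,
            "best_template": row.best_template,
            "identity_pct": f"{100.0 * row.identity:.1f}",
            "score_floor1": f"{row.floor_scores[0]:.6f}",
            "score_floor2": f"{row.floor_scores[1]:.6f}",
            "score_floor3": f"{row.floor_scores[2]:.6f}",
            "predicted": row.predicted_text,
            "flags": ",".join(row.flags) if row.flags else "-",
        }
        for cell, col in zip(row.floor_cells, REPORT_COLUMNS[3:12]):
            rec[col] = cell
        out.append(rec)
    df = pd.DataFrame(out, columns=list(REPORT_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def read_prediction_report(path: str | Path) -> list[PredictionReportRow]:
    """Read back a prediction report written by :func:`write_prediction_report`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing report column(s): {', '.join(missing)}")
    rows: list[PredictionReportRow] = []
    for _, r in df.iterrows():
        predicted = tuple(ProductClass.parse(p) for p in r["predicted"].split("/"))
        flags = tuple(f for f in r["flags"].split(",") if f and f != "-")
        rows.append(
            PredictionReportRow(
                query_id=r["query_id"],
                best_template=r["best_template"],
                identity=float(r["identity_pct"]) / 100.0,
                floor_cells=tuple(r[c] for c in REPORT_COLUMNS[3:12]),
                floor_scores=(
                    float(r["score_floor1"]),
                    float(r["score_floor2"]),
                    float(r["score_floor3"]),
                ),
                predicted=predicted,
                flags=flags,
            )
        )
    return rows
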