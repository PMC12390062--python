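"""Sequence I/O and the internal record model.

FASTA reading/writing goes through Biopython; records are normalised into
:class:`ToxinRecord` (upper-case residues, terminal stop stripped, strict
amino-acid alphabet).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}

FORMS = ("mature", "precursor_with_signal", "precursor_signal_removed")


class FastaError(ValueError):
    """Malformed FASTA input."""


class RecordError(ValueError):
    """A single record violates the sequence alphabet."""


@dataclass
class ToxinRecord:
    """One input sequence.

    ``form`` distinguishes mature toxins from precursors; signal-peptide
    handling is by annotation only — no prediction is attempted.
    """

    id: str
    residues: str
    description: str = ""
    form: str = "mature"
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r}")
        seq = self.residues.upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise RecordError(f"record {self.id!r}: empty sequence")
        if any(ch in "-." for ch in seq):
            raise RecordError(f"record {self.id!r}: gapped input not accepted")
        bad = sorted(set(seq) - VALID_RESIDUES)
        if bad:
            raise RecordError(
                f"record {self.id!r}: invalid residue symbol(s) {', '.join(bad)}")
        self.residues = seq
        if self.atypical_length and "atypical_length" not in self.metadata:
            self.metadata["atypical_length"] = "1"

    @property
    def atypical_length(self) -> bool:
        """True for mature sequences outside the 40–120 residue range."""
        return self.form == "mature" and not 40 <= len(self.residues) <= 120

    def __len__(self) -> int:
        return len(self.residues)


def _dedupe(records: list[ToxinRecord]) -> list[ToxinRecord]:
    seen: dict[str, int] = {}
    for rec in records:
        if rec.id in seen:
            seen[rec.id] += 1
            new_id = f"{rec.id}.{seen[rec.id]}"
            warnings.warn(f"duplicate record id {rec.id!r}; renamed to {new_id!r}")
            rec.id = new_id
        else:
            seen[rec.id] = 0
    return records


def read_fasta(path: str | Path, form: str = "mature") -> list[ToxinRecord]:
    """Read a FASTA file into a list of :class:`ToxinRecord`, order preserved."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    try:
        for i, sr in enumerate(SeqIO.parse(str(path), "fasta")):
            if not sr.id:
                raise FastaError(f"{path}: entry {i + 1} has no identifier")
            records.append(ToxinRecord(id=sr.id, residues=str(sr.seq),
                                       description=sr.description, form=form))
    except RecordError:
        raise
    except ValueError as exc:  # Biopython parse failure
        raise FastaError(f"{path}: {exc}") from exc
    if not records:
        raise FastaError(f"{path}: no FASTA entries found")
    return _dedupe(records)


def write_fasta(records: list[ToxinRecord], path: str | Path) -> None:
    srs = [SeqRecord(Seq(r.residues), id=r.id,
                     description=r.description if r.description != r.id else "")
           for r in records]
    SeqIO.write(srs, str(path), "fasta")


#: fixed column order of the classification report
ANNOTATION_COLUMNS = (
    "id", "family", "class", "group", "subgroup", "confidence", "satisfied",
    "violated", "ncys", "fifth_ss_loop", "loop1len", "loop2len", "loop3len",
    "ctail_len", "site_residues", "pro_flanks", "motifs", "cterm_gly",
    "nterm_gln", "nterm_ext_len", "processing_site", "notes",
)


def write_annotations(results, path: str | Path, format: str = "tsv") -> None:
    """Write classification results as TSV (fixed column order) or JSON.

    ``results`` is a non-empty list of objects exposing ``as_row()``
    (see :class:`tfx.taxonomy.ClassificationResult`).
    """
    if not results:
        raise ValueError("no results to write")
    rows = [r.as_row() for r in results]
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
            for row in rows:
                fh.write("\t".join(str(row[c]) for c in ANNOTATION_COLUMNS) + "\n")
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_annotations(path: str | Path):
    """Re-read an annotation table written by :func:`write_annotations`."""
    path = Path(path)
    if path.suffix == ".json" or open(path).read(1) in "[{":
        with open(path) as fh:
            return json.load(fh)
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            vals = line.rstrip("\n").split("\t")
            rows.append(dict(zip(header, vals)))
    return rows
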