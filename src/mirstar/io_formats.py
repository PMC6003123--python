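"""Reading and writing the file formats the tool touches.

FASTA input goes through Biopython's SeqIO; Vienna dot-bracket files
(RNAfold's three-line record layout) and the tabular prediction report
are simple enough to be handled directly.  All sequences are normalized
on ingest: uppercase, DNA ``T`` transcribed to ``U``, whitespace
stripped, and anything outside the RNA + IUPAC-ambiguity alphabet
rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Unambiguous RNA plus the IUPAC ambiguity letters found in miRBase files.
RNA_ALPHABET = frozenset("ACGU" "RYSWKMBDHVN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def normalize_sequence(raw: str) -> str:
    """Normalize a raw nucleotide string to uppercase RNA.

    Uppercases, removes internal whitespace, replaces T with U, and
    validates every character against the RNA + IUPAC alphabet.

    Raises
    ------
    FormatError
        If the string is empty after stripping, or contains a character
        outside the allowed alphabet (the message reports the offending
        character and its 1-based position in the cleaned string).
    """
    cleaned = "".join(raw.split()).upper().replace("T", "U")
    if not cleaned:
        raise FormatError("empty sequence")
    for i, ch in enumerate(cleaned):
        if ch not in RNA_ALPHABET:
            raise FormatError(
                f"disallowed character {ch!r} at position {i + 1}"
            )
    return cleaned


@dataclass(frozen=True)
class RnaSequence:
    """A named RNA sequence (precursor or mature miRNA).

    ``id`` is the FASTA header token up to the first whitespace;
    ``description`` keeps the remainder of the header line.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"invalid sequence id {self.id!r}")
        if not self.seq:
            raise FormatError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ViennaRecord:
    """One RNAfold-style record: header, sequence, dot-bracket line."""

    id: str
    seq: str
    structure: str
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.seq):
            raise FormatError(
                f"record {self.id!r}: structure length {len(self.structure)} "
                f"!= sequence length {len(self.seq)}"
            )
        depth = 0
        for ch in self.structure:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise FormatError(
                        f"record {self.id!r}: unbalanced brackets"
                    )
            elif ch != ".":
                raise FormatError(
                    f"record {self.id!r}: foreign character {ch!r} "
                    "in structure"
                )
        if depth != 0:
            raise FormatError(f"record {self.id!r}: unbalanced brackets")


def read_fasta(path: str | Path) -> list[RnaSequence]:
    """Read a multi-FASTA file into normalized :class:`RnaSequence` records.

    Wrapped sequence lines are concatenated.  Duplicate ids are kept
    verbatim (miRBase reuses family names across species files) but
    logged as a warning.

    Raises
    ------
    FormatError
        If the file contains no FASTA record, or a record has an empty
        sequence.
    """
    path = Path(path)
    records: list[RnaSequence] = []
    seen: set[str] = set()
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if not rec.id:
                raise FormatError(f"{path}: record with empty header")
            try:
                seq = normalize_sequence(str(rec.seq))
            except FormatError as exc:
                raise FormatError(
                    f"{path}: record {rec.id!r}: {exc}"
                ) from exc
            desc = rec.description[len(rec.id):].strip()
            if rec.id in seen:
                logger.warning("duplicate FASTA id %r in %s", rec.id, path)
            seen.add(rec.id)
            records.append(RnaSequence(id=rec.id, seq=seq, description=desc))
    except ValueError as exc:  # Biopython rejects text before '>'
        if isinstance(exc, FormatError):
            raise
        raise FormatError(f"{path}: not FASTA-formatted: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[RnaSequence], path: str | Path) -> None:
    """Write records as unwrapped FASTA (one sequence line per record)."""
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(f"{header}\n{rec.seq}\n")


def _strip_energy(line: str) -> str:
    """Drop RNAfold's trailing free-energy token, e.g. ``(((...))) (-1.20)``."""
    token = line.split(None, 1)[0] if line.split() else line
    return token


def read_vienna(path: str | Path) -> list[ViennaRecord]:
    """Read a Vienna/RNAfold dot-bracket file.

    Each record is three lines: a ``>`` header, the sequence, and the
    structure line.  A trailing free-energy token after whitespace on
    the structure line is stripped.
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    records: list[ViennaRecord] = []
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise FormatError(f"{path}: expected '>' header at line {i + 1}")
        if i + 2 >= len(lines):
            raise FormatError(
                f"{path}: truncated record {lines[i][1:].split()[0]!r}"
            )
        header = lines[i][1:].strip()
        rec_id = header.split()[0] if header.split() else ""
        if not rec_id:
            raise FormatError(f"{path}: record with empty header")
        desc = header[len(rec_id):].strip()
        seq = normalize_sequence(lines[i + 1])
        structure = _strip_energy(lines[i + 2].strip())
        records.append(
            ViennaRecord(id=rec_id, seq=seq, structure=structure,
                         description=desc)
        )
        i += 3
    if not records:
        raise FormatError(f"{path}: no records found")
    return records


def write_vienna(records: Iterable[ViennaRecord], path: str | Path) -> None:
    """Write Vienna records (header, sequence, dot-bracket; no energy)."""
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(f"{header}\n{rec.seq}\n{rec.structure}\n")


#: TSV report column order (coordinates are 1-based inclusive).
REPORT_COLUMNS = (
    "precursor_id",
    "mature_id",
    "mature_start",
    "mature_end",
    "star_start",
    "star_end",
    "star_seq",
    "status",
    "flags",
    "duplicate_of",
)


def star_record_id(prediction) -> str:
    """FASTA record id for one successful prediction."""
    return (
        f"{prediction.entry.precursor_id}|{prediction.entry.mature_id}"
        f"|{prediction.star_start + 1}-{prediction.star_end + 1}"
    )


def write_predictions(
    predictions: Sequence,
    path: str | Path,
    format: str = "tsv",
) -> None:
    """Serialize star predictions as a TSV report or a FASTA of stars.

    The TSV carries every prediction, including failures (with empty
    star columns and a failure status) and deduplicated rows (with a
    ``duplicate_of`` reference).  The FASTA carries only unique,
    successful stars.  Coordinates in the TSV are 1-based inclusive.
    """
    if format not in {"tsv", "fasta"}:
        raise ValueError(f"unknown report format {format!r}")
    with open(path, "w") as fh:
        if format == "tsv":
            fh.write("\t".join(REPORT_COLUMNS) + "\n")
            for p in predictions:
                e = p.entry
                if p.status == "ok":
                    star_cols = [
                        str(p.star_start + 1),
                        str(p.star_end + 1),
                        p.star_seq,
                    ]
                else:
                    star_cols = ["", "", ""]
                row = [
                    e.precursor_id,
                    e.mature_id,
                    str(e.mature_start + 1),
                    str(e.mature_end + 1),
                    *star_cols,
                    p.status,
                    ";".join(str(f) for f in p.flags),
                    p.duplicate_of or "",
                ]
                fh.write("\t".join(row) + "\n")
        else:
            for p in predictions:
                if p.status != "ok" or p.duplicate_of:
                    continue
                fh.write(f">{star_record_id(p)}\n{p.star_seq}\n")
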