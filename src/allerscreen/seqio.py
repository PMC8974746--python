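"""Sequence and metadata I/O.

Three formats are handled:

* FASTA — the exchange format for query proteins and allergen databases.
* A minimal line-keyed flat file carrying the annotation fields that the
  keyword triage inspects: definition line, source organism, taxonomy
  group, entry date, submission-provenance tag and free-text notes.
  Blocks are separated by ``//`` lines; every line is ``KEY  value`` with
  the residues following the ``SEQUENCE`` key until the end of the block.
* The tab-separated allergen metadata table with the fixed column set
  used by database releases (Species, Common Name, Description, IUIS
  Name, Accession, Length, Year Adopted, Parent Accession).

Parsing is strict: sequences must be drawn from the 20 amino-acid letters
plus the ambiguity letters B, Z, X, U, J and O, and any violation fails
the parse rather than being silently coerced.
"""
from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Letters tolerated beyond the 20 standard amino acids: B (Asx), Z (Glx),
#: X (unknown), U (selenocysteine), J (Ile/Leu), O (pyrrolysine).
AMBIGUITY_LETTERS = "BZXUJO"
VALID_RESIDUES = frozenset(AMINO_ACIDS + AMBIGUITY_LETTERS)

TAXONOMY_GROUPS = ("animal", "plant", "fungus", "protist", "other")

ENTRY_TABLE_COLUMNS = [
    "Species",
    "Common Name",
    "Description",
    "IUIS Name",
    "Accession",
    "Length",
    "Year Adopted",
    "Parent Accession",
]


@dataclass
class SequenceRecord:
    """One annotated protein record.

    The sequence is upper-cased on construction and checked against the
    residue alphabet; ``features`` is an ordered list of (key, value)
    pairs, of which only ``note`` features are carried by the flat-file
    dialect.
    """

    accession: str
    sequence: str
    definition: str = ""
    organism: str | None = None
    taxonomy_group: str | None = None
    entry_date: datetime.date | None = None
    features: list[tuple[str, str]] = field(default_factory=list)
    source_tag: str | None = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValidationError("accession must be non-empty")
        if not self.sequence:
            raise ValidationError(f"{self.accession}: sequence must be non-empty")
        self.sequence = self.sequence.upper()
        for ch in self.sequence:
            if ch not in VALID_RESIDUES:
                raise ValidationError(
                    f"{self.accession}: invalid residue {ch!r} "
                    f"(allowed: {AMINO_ACIDS + AMBIGUITY_LETTERS})"
                )
        if self.taxonomy_group is not None and self.taxonomy_group not in TAXONOMY_GROUPS:
            raise ValidationError(
                f"{self.accession}: taxonomy_group {self.taxonomy_group!r} "
                f"not one of {TAXONOMY_GROUPS}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def notes(self) -> list[str]:
        """Values of all ``note`` features, in order."""
        return [v for k, v in self.features if k == "note"]

    def text_fields(self) -> list[str]:
        """Every free-text field a keyword rule may inspect."""
        out = [self.definition]
        out.extend(self.notes())
        if self.organism:
            out.append(self.organism)
        if self.source_tag:
            out.append(self.source_tag)
        return out


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[SequenceRecord]:
    """Parse a FASTA file into records.

    The header token before the first whitespace becomes the accession and
    the remainder the definition; sequence lines are concatenated with all
    whitespace removed and upper-cased.  An empty file yields an empty
    list.  Malformed input (sequence before any header, a header with no
    sequence lines, duplicate accessions, residues outside the alphabet)
    raises :class:`ParseError`.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    acc: str | None = None
    definition = ""
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if acc is None:
            return
        if not chunks:
            raise ParseError(f"{path}: line {header_line}: header {acc!r} has no sequence lines")
        try:
            records.append(SequenceRecord(acc, "".join(chunks), definition))
        except ValidationError as exc:
            raise ParseError(f"{path}: {exc}") from exc

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise ParseError(f"{path}: line {lineno}: empty FASTA header")
                parts = header.split(None, 1)
                acc = parts[0]
                definition = parts[1].strip() if len(parts) > 1 else ""
                if acc in seen:
                    raise ParseError(f"{path}: line {lineno}: duplicate accession {acc!r}")
                seen.add(acc)
                header_line = lineno
                chunks = []
            else:
                if acc is None:
                    raise ParseError(
                        f"{path}: line {lineno}: sequence data before any '>' header"
                    )
                chunks.append("".join(line.split()))
    flush()
    return records


def write_fasta(records, path, wrap: int = 60) -> None:
    """Write records as FASTA with sequences wrapped at ``wrap`` columns."""
    if wrap < 1:
        raise ValueError("wrap must be a positive integer")
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            header = f">{rec.accession}"
            if rec.definition:
                header += f" {rec.definition}"
            fh.write(header + "\n")
            seq = rec.sequence
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


# ---------------------------------------------------------------------------
# Annotated flat file

_FLATFILE_KEYS = {
    "ACCESSION",
    "DEFINITION",
    "ORGANISM",
    "TAXGROUP",
    "DATE",
    "SOURCETAG",
    "NOTE",
    "SEQUENCE",
}


def read_flatfile(path) -> list[SequenceRecord]:
    """Parse the line-keyed annotated flat-file dialect.

    Mandatory keys are ACCESSION and SEQUENCE; ORGANISM, TAXGROUP, DATE
    (ISO-8601), SOURCETAG and repeatable NOTE lines are optional.  Residue
    lines following the SEQUENCE key run until the ``//`` block terminator.
    """
    records: list[SequenceRecord] = []
    block: dict = {}
    notes: list[tuple[str, str]] = []
    chunks: list[str] = []
    in_seq = False
    block_start = 1

    def finish(lineno: int) -> None:
        nonlocal block, notes, chunks, in_seq
        if not block and not chunks and not notes:
            return
        if "ACCESSION" not in block:
            raise ParseError(f"{path}: block starting at line {block_start}: missing ACCESSION")
        seq = "".join(chunks)
        if not seq:
            raise ParseError(
                f"{path}: block starting at line {block_start}: missing SEQUENCE"
            )
        try:
            records.append(
                SequenceRecord(
                    accession=block["ACCESSION"],
                    sequence=seq,
                    definition=block.get("DEFINITION", ""),
                    organism=block.get("ORGANISM"),
                    taxonomy_group=block.get("TAXGROUP"),
                    entry_date=block.get("DATE"),
                    features=list(notes),
                    source_tag=block.get("SOURCETAG"),
                )
            )
        except ValidationError as exc:
            raise ParseError(f"{path}: block ending at line {lineno}: {exc}") from exc
        block, notes, chunks, in_seq = {}, [], [], False

    with open(path, encoding="utf-8") as fh:
        lineno = 0
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if line.strip() == "//":
                finish(lineno)
                block_start = lineno + 1
                continue
            if not line.strip():
                continue
            if in_seq:
                chunks.append("".join(line.split()))
                continue
            parts = line.strip().split(None, 1)
            key = parts[0]
            value = parts[1].strip() if len(parts) > 1 else ""
            if key not in _FLATFILE_KEYS:
                raise ParseError(f"{path}: line {lineno}: unknown key {key!r}")
            if key == "SEQUENCE":
                in_seq = True
                if value:
                    chunks.append("".join(value.split()))
            elif key == "NOTE":
                notes.append(("note", value))
            elif key == "DATE":
                try:
                    block["DATE"] = datetime.date.fromisoformat(value)
                except ValueError as exc:
                    raise ParseError(
                        f"{path}: line {lineno}: unparseable date {value!r} "
                        "(expected YYYY-MM-DD)"
                    ) from exc
            else:
                block[key] = value
        finish(lineno)
    return records


def write_flatfile(records, path, wrap: int = 60) -> None:
    """Write records in the flat-file dialect (only ``note`` features carry over)."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f"ACCESSION  {rec.accession}\n")
            if rec.definition:
                fh.write(f"DEFINITION  {rec.definition}\n")
            if rec.organism:
                fh.write(f"ORGANISM  {rec.organism}\n")
            if rec.taxonomy_group:
                fh.write(f"TAXGROUP  {rec.taxonomy_group}\n")
            if rec.entry_date:
                fh.write(f"DATE  {rec.entry_date.isoformat()}\n")
            if rec.source_tag:
                fh.write(f"SOURCETAG  {rec.source_tag}\n")
            for note in rec.notes():
                fh.write(f"NOTE  {note}\n")
            seq = rec.sequence
            fh.write(f"SEQUENCE  {seq[:wrap]}\n")
            for i in range(wrap, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")
            fh.write("//\n")


# ---------------------------------------------------------------------------
# Entry metadata table


def read_entry_table(path) -> list[dict]:
    """Read the tab-separated allergen metadata table.

    Returns one dict per row keyed by the canonical column names, with
    ``Length`` converted to int.  A missing or unexpected column, an
    unparseable length, or a duplicate accession raises :class:`SchemaError`.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file, expected a header row") from exc
    missing = [c for c in ENTRY_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns: {', '.join(missing)}")
    unexpected = [c for c in df.columns if c not in ENTRY_TABLE_COLUMNS]
    if unexpected:
        raise SchemaError(f"{path}: unexpected columns: {', '.join(unexpected)}")
    rows = []
    seen: set[str] = set()
    for i, rec in enumerate(df.to_dict("records"), 2):
        acc = rec["Accession"]
        if acc in seen:
            raise SchemaError(f"{path}: duplicate accession {acc!r}")
        seen.add(acc)
        try:
            rec["Length"] = int(rec["Length"])
        except ValueError as exc:
            raise SchemaError(
                f"{path}: row {i}: Length {rec['Length']!r} is not an integer"
            ) from exc
        rows.append({c: rec[c] for c in ENTRY_TABLE_COLUMNS})
    return rows


def write_entry_table(rows, path) -> None:
    """Write metadata rows as a tab-separated table with the canonical header."""
    for row in rows:
        missing = [c for c in ENTRY_TABLE_COLUMNS if c not in row]
        if missing:
            raise SchemaError(f"row missing keys: {', '.join(missing)}")
    df = pd.DataFrame(
        [{c: row[c] for c in ENTRY_TABLE_COLUMNS} for row in rows],
        columns=ENTRY_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def check_table_consistency(rows, records) -> list[str]:
    """Cross-check a metadata table against FASTA records by accession.

    Returns human-readable violation strings; an empty list means every
    table row pairs with a sequence of matching length.
    """
    by_acc = {r.accession: r for r in records}
    problems = []
    for row in rows:
        acc = row["Accession"]
        rec = by_acc.get(acc)
        if rec is None:
            problems.append(f"{acc}: present in table but not in FASTA")
        elif rec.length != row["Length"]:
            problems.append(
                f"{acc}: table Length {row['Length']} != sequence length {rec.length}"
            )
    return problems
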