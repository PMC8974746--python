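"""Entry validation, review decisions, versioned releases and exports.

A curated allergen entry needs peer-reviewed evidence: at least one
supporting publication and demonstrated IgE binding from human sera.
These requirements are encoded as machine-checkable structure rules:
:func:`validate_entry` checks an entry's internal consistency, and a
:class:`DecisionLedger` records accept/reject verdicts from the expert
review with a controlled vocabulary of criteria codes (the free-text
comment carries everything the codes cannot).

Releases are versioned and conservative: building a new release never
removes or mutates an entry of its base — the foundational list imported
from the pre-2017 database era stays intact, and that imported base
(year adopted 2016 or earlier) is exempt from the publication requirement
because it predates the review process.  Entries found by retrospective
("historic") screening are stamped with an ``H`` suffix on the adoption
year, or ``H_MS`` for mass-spectrometry peptide fragments, so regular and
historic additions remain distinguishable.  Peptide fragments must be at
least 10 residues and may carry a parent accession pointing at the full
protein they derive from (metadata only — the parent itself need not be
an entry).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from . import seqio
from .errors import ReleaseConflictError, ValidationError
from .seqio import VALID_RESIDUES, SequenceRecord

ENTRY_KINDS = ("full_protein", "partial", "ms_peptide")

#: First adoption year whose entries went through the expert review and
#: therefore must cite supporting literature.
REVIEW_START_YEAR = 2017

#: Minimum length of a mass-spectrometry-identified peptide entry.
MS_PEPTIDE_MIN_LENGTH = 10

INCLUSION_CODES = frozenset({"IGE_BINDING_EVIDENCE", "SERA_QUALITY_OK", "ASSAY_VALID"})
EXCLUSION_CODES = frozenset(
    {
        "NO_NEGATIVE_CONTROL",
        "INSUFFICIENT_PURITY",
        "CCD_ONLY_BINDING",
        "HOMOLOGY_ONLY",
        "SEQUENCE_MISMATCH",
    }
)
CRITERIA_CODES = INCLUSION_CODES | EXCLUSION_CODES


@dataclass(frozen=True)
class Reference:
    """One supporting citation."""

    ref_id: str
    title: str = ""
    year: int | None = None


@dataclass
class AllergenEntry:
    accession: str
    species: str
    common_name: str
    description: str
    sequence: str
    length: int
    year_adopted: str
    entry_kind: str = "full_protein"
    iuis_name: str | None = None
    references: list[Reference] = field(default_factory=list)
    parent_accession: str | None = None


def year_numeric(label: str) -> int | None:
    """Numeric year of an adoption label ('2020H_MS' -> 2020); None if unparseable."""
    m = re.match(r"(\d{4})", label or "")
    return int(m.group(1)) if m else None


def validate_entry(entry: AllergenEntry) -> list[str]:
    """Structure-level checks on one entry; returns violation codes.

    Checks: non-empty alphabet-valid sequence, stored length equal to the
    residue count, a parseable adoption-year label, a known entry kind,
    the 10-residue floor for mass-spectrometry peptides, and at least one
    reference for entries adopted in the review era (2017 onward).
    Violations are data, not exceptions: an empty list means valid.
    """
    violations = []
    if not entry.sequence:
        violations.append("EMPTY_SEQUENCE")
    else:
        if any(ch not in VALID_RESIDUES for ch in entry.sequence.upper()):
            violations.append("BAD_RESIDUE")
        if entry.length != len(entry.sequence):
            violations.append("LENGTH_MISMATCH")
    if entry.entry_kind not in ENTRY_KINDS:
        violations.append("BAD_ENTRY_KIND")
    year = year_numeric(entry.year_adopted)
    if year is None:
        violations.append("BAD_YEAR_LABEL")
    elif year >= REVIEW_START_YEAR and not entry.references:
        violations.append("NO_REFERENCE")
    if entry.entry_kind == "ms_peptide" and len(entry.sequence) < MS_PEPTIDE_MIN_LENGTH:
        violations.append("PEPTIDE_TOO_SHORT")
    return violations


@dataclass(frozen=True)
class ReviewDecision:
    accession: str
    verdict: str  # ACCEPT or REJECT
    criteria_codes: tuple[str, ...]
    comment: str
    cycle_year: int


class DecisionLedger:
    """Append-only record of expert review decisions.

    Recording never mutates prior decisions, and the same accession may
    reappear in a later cycle: candidates rejected for lack of evidence
    can be revisited when new evidence becomes available.
    """

    def __init__(self) -> None:
        self._decisions: list[ReviewDecision] = []

    def record_decision(
        self,
        candidate,
        verdict: str,
        criteria_codes,
        comment: str = "",
        cycle_year: int = 0,
    ) -> ReviewDecision:
        """Validate and append one decision; returns the stored decision.

        ACCEPT requires the IGE_BINDING_EVIDENCE code (IgE binding is the
        minimal inclusion evidence); REJECT requires at least one
        exclusion code.  Unknown codes are rejected outright.
        """
        accession = getattr(candidate, "accession", candidate)
        codes = tuple(criteria_codes)
        unknown = [c for c in codes if c not in CRITERIA_CODES]
        if unknown:
            raise ValidationError(f"unknown criteria codes: {', '.join(unknown)}")
        if verdict == "ACCEPT":
            if "IGE_BINDING_EVIDENCE" not in codes:
                raise ValidationError(
                    "ACCEPT requires the IGE_BINDING_EVIDENCE inclusion code"
                )
        elif verdict == "REJECT":
            if not any(c in EXCLUSION_CODES for c in codes):
                raise ValidationError("REJECT requires at least one exclusion code")
        else:
            raise ValidationError(f"verdict must be ACCEPT or REJECT, got {verdict!r}")
        decision = ReviewDecision(accession, verdict, codes, comment, cycle_year)
        self._decisions.append(decision)
        return decision

    @property
    def decisions(self) -> tuple[ReviewDecision, ...]:
        return tuple(self._decisions)

    def __len__(self) -> int:
        return len(self._decisions)

    def __iter__(self):
        return iter(self._decisions)


@dataclass
class Release:
    """A versioned, diffable collection of validated entries."""

    version_label: str
    entries: dict[str, AllergenEntry] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)


def _adoption_label(version_label: str, entry: AllergenEntry, historic: bool) -> str:
    if not historic:
        return version_label
    return version_label + ("H_MS" if entry.entry_kind == "ms_peptide" else "H")


def build_release(
    base: Release,
    accepted: list[AllergenEntry],
    version_label: str,
    historic: bool = False,
    allow_update: bool = False,
) -> Release:
    """Extend a base release with accepted entries under a new version label.

    Every base entry is carried over unchanged (entries are never
    removed).  Accepted entries are stamped with the new version label —
    with the ``H``/``H_MS`` suffix when they come from a historic
    screening — and must validate after stamping.  An accession collision
    with the base is a conflict unless ``allow_update`` is set, which is
    the explicit metadata-update mode (silent overwrite is forbidden).
    """
    entries = dict(base.entries)
    n_new = 0
    n_updated = 0
    for entry in accepted:
        stamped = replace(entry, year_adopted=_adoption_label(version_label, entry, historic))
        violations = validate_entry(stamped)
        if violations:
            raise ValidationError(
                f"entry {entry.accession!r} rejected: {', '.join(violations)}"
            )
        if stamped.accession in entries:
            if not allow_update:
                raise ReleaseConflictError(
                    f"accession {stamped.accession!r} already present in "
                    f"{base.version_label}; pass allow_update for metadata updates"
                )
            n_updated += 1
        else:
            n_new += 1
        entries[stamped.accession] = stamped
    provenance = list(base.provenance)
    provenance.append(
        f"release {version_label}: {len(base.entries)} base + {n_new} new"
        + (f" + {n_updated} updated" if n_updated else "")
        + (" (historic screening)" if historic else "")
    )
    return Release(version_label, entries, provenance)


_DIFF_FIELDS = (
    "species",
    "common_name",
    "description",
    "sequence",
    "length",
    "year_adopted",
    "entry_kind",
    "iuis_name",
    "references",
    "parent_accession",
)


@dataclass
class ReleaseDiff:
    added: list[str]
    removed: list[str]
    changed: dict[str, list[str]]  # accession -> differing field names

    @property
    def is_empty(self) -> bool:
        return not (self.added or self.removed or self.changed)


def diff_releases(old: Release, new: Release) -> ReleaseDiff:
    """Accession- and field-level differences between two releases."""
    old_accs = set(old.entries)
    new_accs = set(new.entries)
    added = sorted(new_accs - old_accs)
    removed = sorted(old_accs - new_accs)
    changed: dict[str, list[str]] = {}
    for acc in sorted(old_accs & new_accs):
        fields_differ = [
            f for f in _DIFF_FIELDS
            if getattr(old.entries[acc], f) != getattr(new.entries[acc], f)
        ]
        if fields_differ:
            changed[acc] = fields_differ
    return ReleaseDiff(added, removed, changed)


# ---------------------------------------------------------------------------
# Transparency and release exports


def _clean_cell(text: str) -> str:
    return " ".join(str(text).split())


def export_transparency(ledger: DecisionLedger, path) -> None:
    """Write the public per-candidate decision record as a TSV file.

    One row per decision: accession, review cycle, verdict, criteria
    codes and the reviewers' comment — the published transparency file
    mirroring what the expert panel decided and why.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("Accession\tCycle Year\tVerdict\tCriteria Codes\tComment\n")
        for d in ledger:
            fh.write(
                "\t".join(
                    [
                        d.accession,
                        str(d.cycle_year),
                        d.verdict,
                        ";".join(d.criteria_codes),
                        _clean_cell(d.comment),
                    ]
                )
                + "\n"
            )


def export_release(release: Release, fasta_path, table_path) -> None:
    """Write a release as mutually consistent FASTA + metadata table.

    Both files are ordered by accession; the table's Length column equals
    the FASTA sequence length row by row.
    """
    entries = [release.entries[acc] for acc in sorted(release.entries)]
    records = [
        SequenceRecord(e.accession, e.sequence, definition=e.description)
        for e in entries
    ]
    seqio.write_fasta(records, fasta_path)
    rows = [
        {
            "Species": e.species,
            "Common Name": e.common_name,
            "Description": e.description,
            "IUIS Name": e.iuis_name or "",
            "Accession": e.accession,
            "Length": e.length,
            "Year Adopted": e.year_adopted,
            "Parent Accession": e.parent_accession or "",
        }
        for e in entries
    ]
    seqio.write_entry_table(rows, table_path)


def import_release(fasta_path, table_path, version_label: str = "") -> Release:
    """Re-assemble a release from its exported FASTA + metadata table.

    References are not part of the tabular export, so imported entries
    carry empty reference lists; the entry kind is inferred from the
    adoption label (``..H_MS`` marks a mass-spectrometry peptide).  The
    two files must agree on accessions and lengths.
    """
    records = seqio.read_fasta(fasta_path)
    rows = seqio.read_entry_table(table_path)
    problems = seqio.check_table_consistency(rows, records)
    by_acc = {r.accession: r for r in records}
    missing = [r.accession for r in records if r.accession not in {x["Accession"] for x in rows}]
    if missing:
        problems.append(f"FASTA accessions missing from table: {', '.join(missing)}")
    if problems:
        raise ValidationError("; ".join(problems))
    entries = {}
    for row in rows:
        acc = row["Accession"]
        entries[acc] = AllergenEntry(
            accession=acc,
            species=row["Species"],
            common_name=row["Common Name"],
            description=row["Description"],
            sequence=by_acc[acc].sequence,
            length=row["Length"],
            year_adopted=row["Year Adopted"],
            entry_kind="ms_peptide" if row["Year Adopted"].endswith("H_MS") else "full_protein",
            iuis_name=row["IUIS Name"] or None,
            parent_accession=row["Parent Accession"] or None,
        )
    return Release(version_label or "imported", entries)
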