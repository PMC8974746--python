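"""Deterministic synthetic data for every screening surface.

Three generators cover the toolkit's inputs without any external
downloads:

* :func:`make_db` — random protein databases (i.i.d. residues over the 20
  amino-acid alphabet, uniform lengths) for alignment and screening runs.
* :func:`make_annotated_records` — annotated flat-file-style records with
  planted triage categories (automated-pipeline provenance, "allerg*" in
  the definition, note-only allergy mentions, allergen-family keywords,
  irrelevant controls) together with the ground-truth label each record
  should receive, so filter runs can be scored exactly.
* :func:`implant_homolog` — sequence pairs with an exact, position-wise
  identity count, for probing the >35%-identity window rule at its
  boundary.  Substituted positions receive conservative replacements
  (positive substitution score, never identical), so the planted region's
  optimal local alignment is the full-length, gap-free one and the
  identity fraction of the alignment equals the planted count exactly.

All randomness flows through ``numpy.random.default_rng`` (PCG64) seeded
from the spec, so a fixed seed reproduces byte-identical fixtures on any
platform.  The sequences are i.i.d. noise: they model no composition
bias, repeats, domains or homology structure beyond what is explicitly
implanted.
"""
from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import numpy as np

from . import align as _align
from .errors import ValidationError
from .seqio import AMINO_ACIDS, SequenceRecord

#: Triage categories understood by :func:`make_annotated_records`, with the
#: label the default rule set assigns to each.
CATEGORY_LABELS = {
    "automated_pipeline": "EXCLUDED",
    "definition_allerg": "CANDIDATE",
    "note_allerg": "EXCLUDED",
    "keyword": "CANDIDATE",
    "irrelevant": "CANDIDATE",  # fail-open default keeps unrecognised records
}

DEFAULT_CATEGORY_MIX = {
    "automated_pipeline": 0.20,
    "definition_allerg": 0.25,
    "note_allerg": 0.20,
    "keyword": 0.20,
    "irrelevant": 0.15,
}

#: The annual primary-search window the generated entry dates cluster in.
PRIMARY_WINDOW = (datetime.date(2015, 5, 30), datetime.date(2016, 5, 14))

_ORGANISMS = {
    "animal": ["Dermatophagoides pteronyssinus", "Penaeus monodon", "Felis catus"],
    "plant": ["Betula pendula", "Arachis hypogaea", "Triticum aestivum"],
    "fungus": ["Aspergillus fumigatus", "Alternaria alternata"],
    "protist": ["Plasmodium falciparum"],
    "other": ["Escherichia coli"],
}

_ALLERG_DEFINITIONS = [
    "major allergen precursor",
    "pollen allergen, partial",
    "allergenic seed storage protein",
    "minor allergen isoform 2",
]
_KEYWORD_DEFINITIONS = [
    "tropomyosin, partial",
    "profilin isoform A",
    "parvalbumin beta",
    "ovalbumin-related protein Y",
]
_NOTE_ALLERG_NOTES = [
    "isolated from a patient with allergic rhinitis",
    "sample obtained from an allergy clinic cohort",
    "cross-referenced in an allergy screening study of the host species",
]
_IRRELEVANT_DEFINITIONS = [
    "membrane transport protein",
    "hypothetical protein",
    "DNA-directed RNA polymerase subunit",
    "cytochrome c oxidase subunit I",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic data set; same spec => identical bytes."""

    seed: int
    n_entries: int = 50
    length_range: tuple[int, int] = (90, 400)
    category_mix: dict = field(default_factory=lambda: dict(DEFAULT_CATEGORY_MIX))
    alphabet: str = AMINO_ACIDS

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValidationError(f"degenerate length range {self.length_range}")
        if self.n_entries < 0:
            raise ValidationError("n_entries must be >= 0")
        if abs(sum(self.category_mix.values()) - 1.0) > 1e-9:
            raise ValidationError("category proportions must sum to 1")


@dataclass(frozen=True)
class RecordTruth:
    """Planted properties of one generated record, for exact scoring."""

    accession: str
    category: str
    expected_label: str
    has_allerg_text: bool
    has_keyword: bool
    in_primary_window: bool


def _random_sequence(rng: np.random.Generator, length: int, alphabet: str) -> str:
    letters = np.array(list(alphabet))
    return "".join(letters[rng.integers(0, len(letters), length)])


def make_db(spec: FixtureSpec) -> list[SequenceRecord]:
    """Random protein database: accessions SYN000001..., uniform lengths."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    records = []
    for i in range(spec.n_entries):
        length = int(rng.integers(lo, hi + 1))
        records.append(
            SequenceRecord(
                accession=f"SYN{i + 1:06d}",
                sequence=_random_sequence(rng, length, spec.alphabet),
                definition=f"synthetic protein {i + 1}",
            )
        )
    return records


def _category_counts(mix: dict, n: int) -> dict[str, int]:
    # Largest-remainder apportionment so counts sum to n deterministically.
    raw = {c: p * n for c, p in mix.items()}
    counts = {c: int(v) for c, v in raw.items()}
    deficit = n - sum(counts.values())
    by_frac = sorted(raw, key=lambda c: (-(raw[c] - counts[c]), c))
    for c in by_frac[:deficit]:
        counts[c] += 1
    return counts


def make_annotated_records(
    spec: FixtureSpec,
    frac_out_of_window: float = 0.1,
    frac_other_taxa: float = 0.1,
) -> tuple[list[SequenceRecord], list[RecordTruth]]:
    """Annotated records with planted triage categories and ground truth.

    Each record carries exactly the textual features of its category, so
    the default rule set must reproduce ``expected_label`` for every
    record.  Entry dates fall inside the annual primary-search window
    except for a planted ``frac_out_of_window`` share, and taxonomy
    groups are animal/plant/fungus/protist except for a planted
    ``frac_other_taxa`` share, so date- and taxon-constrained queries can
    be scored exactly as well.
    """
    unknown = set(spec.category_mix) - set(CATEGORY_LABELS)
    if unknown:
        raise ValidationError(f"unknown categories: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)
    counts = _category_counts(spec.category_mix, spec.n_entries)
    categories = [c for c in sorted(counts) for _ in range(counts[c])]
    categories = [categories[i] for i in rng.permutation(len(categories))]
    lo, hi = spec.length_range
    win_lo, win_hi = PRIMARY_WINDOW
    span = (win_hi - win_lo).days
    records: list[SequenceRecord] = []
    truths: list[RecordTruth] = []
    for i, category in enumerate(categories):
        acc = f"REC{i + 1:06d}"
        in_window = bool(rng.random() >= frac_out_of_window)
        if in_window:
            entry_date = win_lo + datetime.timedelta(days=int(rng.integers(0, span + 1)))
        else:
            entry_date = win_lo - datetime.timedelta(days=int(rng.integers(30, 400)))
        if rng.random() < frac_other_taxa:
            taxgroup = "other"
        else:
            taxgroup = ["animal", "plant", "fungus", "protist"][int(rng.integers(0, 4))]
        organism = _ORGANISMS[taxgroup][int(rng.integers(0, len(_ORGANISMS[taxgroup])))]
        features: list[tuple[str, str]] = []
        source_tag = "manual_submission"
        has_allerg = False
        has_keyword = False
        if category == "automated_pipeline":
            source_tag = "automated_pipeline"
            definition = "predicted allergen-like protein"  # step 1 fires before step 2
            has_allerg = True
        elif category == "definition_allerg":
            definition = _ALLERG_DEFINITIONS[int(rng.integers(0, len(_ALLERG_DEFINITIONS)))]
            has_allerg = True
        elif category == "note_allerg":
            definition = _IRRELEVANT_DEFINITIONS[
                int(rng.integers(0, len(_IRRELEVANT_DEFINITIONS)))
            ]
            features.append(
                ("note", _NOTE_ALLERG_NOTES[int(rng.integers(0, len(_NOTE_ALLERG_NOTES)))])
            )
            has_allerg = True
        elif category == "keyword":
            definition = _KEYWORD_DEFINITIONS[int(rng.integers(0, len(_KEYWORD_DEFINITIONS)))]
            has_keyword = True
        else:  # irrelevant
            definition = _IRRELEVANT_DEFINITIONS[
                int(rng.integers(0, len(_IRRELEVANT_DEFINITIONS)))
            ]
            features.append(("note", "expressed in root tissue"))
        records.append(
            SequenceRecord(
                accession=acc,
                sequence=_random_sequence(rng, int(rng.integers(lo, hi + 1)), spec.alphabet),
                definition=definition,
                organism=organism,
                taxonomy_group=taxgroup,
                entry_date=entry_date,
                features=features,
                source_tag=source_tag,
            )
        )
        truths.append(
            RecordTruth(
                accession=acc,
                category=category,
                expected_label=CATEGORY_LABELS[category],
                has_allerg_text=has_allerg,
                has_keyword=has_keyword,
                in_primary_window=in_window,
            )
        )
    return records, truths


def _conservative_partners(matrix_name: str = "BLOSUM50") -> dict[str, list[str]]:
    """aa -> non-identical standard residues with a positive substitution score."""
    m = _align.load_matrix(matrix_name)
    partners: dict[str, list[str]] = {}
    for a in AMINO_ACIDS:
        partners[a] = sorted(b for b in AMINO_ACIDS if b != a and m[a, b] > 0)
    return partners


def _fallback_partner(aa: str, matrix_name: str = "BLOSUM50") -> str:
    """Best-scoring non-identical replacement (for residues like C or P
    with no positively scoring partner)."""
    m = _align.load_matrix(matrix_name)
    return max((b for b in AMINO_ACIDS if b != aa), key=lambda b: (m[aa, b], -ord(b)))


def implant_homolog(
    base: str,
    n_identical: int,
    region_len: int,
    seed: int,
    matrix_name: str = "BLOSUM50",
) -> str:
    """A variant of ``base[:region_len]`` with an exact identity count.

    The returned string differs from the base region at exactly
    ``region_len - n_identical`` positions; substitutions are drawn from
    positively scoring non-identical residues wherever possible so the
    pair's optimal local alignment stays gap-free and full-length, which
    makes the alignment identity fraction exactly
    ``n_identical / region_len``.
    """
    if not (0 <= n_identical <= region_len <= len(base)):
        raise ValidationError(
            f"need 0 <= n_identical ({n_identical}) <= region_len ({region_len}) "
            f"<= len(base) ({len(base)})"
        )
    region = list(base[:region_len].upper())
    n_sub = region_len - n_identical
    if n_sub == 0:
        return "".join(region)
    partners = _conservative_partners(matrix_name)
    rng = np.random.default_rng(seed)
    eligible = [i for i, aa in enumerate(region) if partners.get(aa)]
    others = [i for i in range(region_len) if i not in set(eligible)]
    if n_sub <= len(eligible):
        positions = rng.choice(len(eligible), size=n_sub, replace=False)
        chosen = [eligible[int(p)] for p in positions]
    else:
        extra = rng.choice(len(others), size=n_sub - len(eligible), replace=False)
        chosen = eligible + [others[int(p)] for p in extra]
    for pos in chosen:
        aa = region[pos]
        opts = partners.get(aa)
        if opts:
            region[pos] = opts[int(rng.integers(0, len(opts)))]
        else:
            region[pos] = _fallback_partner(aa, matrix_name)
    return "".join(region)
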