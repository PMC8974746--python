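"""Keyword-based triage of annotated protein records.

Annual screening of public protein repositories for new allergen
candidates starts from a deliberately broad query — any record mentioning
an "allerg"-prefixed term (allergen, allergy, allergenic, ...) from
animals, plants, fungi or protists within a date window — and then applies
an ordered rule set to separate records worth expert review (CANDIDATE)
from noise (EXCLUDED).  Rules are data, not code: each inspects one text
field of the record with one matching primitive and either labels the
record or passes it to the next step, and every disposition records which
rule fired.

The shipped default rule set is a reconstruction of the published
screening categories (automated-pipeline provenance, definition-line
"allerg*" terms, allergen-family keywords such as profilin or tropomyosin,
and note-only contextual mentions); the terminal default is CANDIDATE, so
a record no rule recognises is kept for review rather than silently
dropped — excluding a real allergen is the costlier mistake.
"""
from __future__ import annotations

import datetime
import re
from collections import Counter
from dataclasses import dataclass, field

import yaml

from .errors import ConfigError, ValidationError
from .seqio import TAXONOMY_GROUPS, SequenceRecord

FIELD_SELECTORS = ("definition", "note", "organism", "taxonomy_group", "source_tag", "any_text")
MATCH_KINDS = ("substring", "prefix_wildcard", "keyword_list", "regex", "date_range", "taxa_set")
ACTIONS = ("EXCLUDE", "CANDIDATE", "CONTINUE")
POLARITIES = ("when_matched", "when_not_matched")

CANDIDATE = "CANDIDATE"
EXCLUDED = "EXCLUDED"

#: Source-organism groups searched for allergen candidates.
PRIMARY_TAXA = frozenset({"animal", "plant", "fungus", "protist"})

#: Allergen-designation keywords used by the supplemental search: protein
#: families so strongly associated with allergy that records naming them
#: are candidates even without any "allerg*" term.  The set is
#: configurable; this default covers widely recognised allergen families.
DEFAULT_ALLERGEN_KEYWORDS = (
    "profilin",
    "tropomyosin",
    "parvalbumin",
    "thaumatin",
    "lipocalin",
    "ovalbumin",
    "ovomucoid",
    "vicilin",
    "legumin",
    "gliadin",
    "glutenin",
    "casein",
    "arginine kinase",
    "lipid transfer protein",
)


@dataclass
class FilterRule:
    """One triage step: inspect a field, match a pattern, act or continue."""

    rule_id: str
    step_index: int
    field_selector: str
    match_kind: str
    pattern: object
    action: str
    polarity: str = "when_matched"


@dataclass
class Disposition:
    """The labeled outcome for one record, with rule provenance."""

    accession: str
    label: str
    fired_rule_id: str
    fired_step_index: int | None


def validate_ruleset(rules: list[FilterRule]) -> None:
    """Check a rule set before any record is processed; raises ConfigError."""
    steps = [r.step_index for r in rules]
    if len(set(steps)) != len(steps):
        raise ConfigError("step_index values must be unique within a rule set")
    for r in rules:
        if r.step_index < 1:
            raise ConfigError(f"rule {r.rule_id!r}: step_index must be >= 1")
        if r.field_selector not in FIELD_SELECTORS:
            raise ConfigError(
                f"rule {r.rule_id!r}: unknown field_selector {r.field_selector!r} "
                f"(expected one of {FIELD_SELECTORS})"
            )
        if r.match_kind not in MATCH_KINDS:
            raise ConfigError(f"rule {r.rule_id!r}: unknown match_kind {r.match_kind!r}")
        if r.action not in ACTIONS:
            raise ConfigError(f"rule {r.rule_id!r}: unknown action {r.action!r}")
        if r.polarity not in POLARITIES:
            raise ConfigError(f"rule {r.rule_id!r}: unknown polarity {r.polarity!r}")
        if r.match_kind == "regex":
            try:
                re.compile(r.pattern)
            except re.error as exc:
                raise ConfigError(f"rule {r.rule_id!r}: bad regex: {exc}") from exc
        if r.match_kind == "taxa_set":
            bad = set(_as_list(r.pattern)) - set(TAXONOMY_GROUPS)
            if bad:
                raise ConfigError(f"rule {r.rule_id!r}: unknown taxonomy groups {sorted(bad)}")
        if r.match_kind == "date_range":
            _parse_date_range(r)


def _as_list(pattern) -> list:
    return list(pattern) if isinstance(pattern, (list, tuple, set)) else [pattern]


def _parse_date_range(rule: FilterRule):
    p = rule.pattern
    if isinstance(p, dict):
        lo, hi = p.get("from"), p.get("to")
    elif isinstance(p, (list, tuple)) and len(p) == 2:
        lo, hi = p
    else:
        raise ConfigError(f"rule {rule.rule_id!r}: date_range pattern must be [from, to]")
    try:
        lo = datetime.date.fromisoformat(lo) if isinstance(lo, str) else lo
        hi = datetime.date.fromisoformat(hi) if isinstance(hi, str) else hi
    except ValueError as exc:
        raise ConfigError(f"rule {rule.rule_id!r}: bad date: {exc}") from exc
    if lo is not None and hi is not None and lo > hi:
        raise ConfigError(f"rule {rule.rule_id!r}: inverted date range")
    return lo, hi


def _texts_for(record: SequenceRecord, selector: str) -> list[str]:
    if selector == "definition":
        return [record.definition] if record.definition else []
    if selector == "note":
        return record.notes()
    if selector == "organism":
        return [record.organism] if record.organism else []
    if selector == "taxonomy_group":
        return [record.taxonomy_group] if record.taxonomy_group else []
    if selector == "source_tag":
        return [record.source_tag] if record.source_tag else []
    return record.text_fields()  # any_text


def word_start_pattern(prefix: str) -> re.Pattern:
    """Case-insensitive match of ``prefix`` at the start of a word.

    Mirrors search-engine stemming of a trailing wildcard: "allerg"
    matches allergen, allergy, allergenic and allergen-like, but not
    "hypoallergenic"-style embeddings inside a word.
    """
    return re.compile(rf"(?<![A-Za-z0-9]){re.escape(prefix)}", re.IGNORECASE)


def whole_word_pattern(word: str) -> re.Pattern:
    return re.compile(rf"(?<![A-Za-z0-9]){re.escape(word)}(?![A-Za-z0-9])", re.IGNORECASE)


def _rule_matches(rule: FilterRule, record: SequenceRecord) -> bool:
    kind = rule.match_kind
    if kind == "date_range":
        if record.entry_date is None:
            return False
        lo, hi = _parse_date_range(rule)
        return (lo is None or record.entry_date >= lo) and (
            hi is None or record.entry_date <= hi
        )
    if kind == "taxa_set":
        return record.taxonomy_group in set(_as_list(rule.pattern))
    texts = _texts_for(record, rule.field_selector)
    if kind == "substring":
        needle = str(rule.pattern).lower()
        return any(needle in t.lower() for t in texts)
    if kind == "prefix_wildcard":
        pat = word_start_pattern(str(rule.pattern))
        return any(pat.search(t) for t in texts)
    if kind == "keyword_list":
        pats = [whole_word_pattern(str(k)) for k in _as_list(rule.pattern)]
        return any(p.search(t) for t in texts for p in pats)
    if kind == "regex":
        pat = re.compile(rule.pattern)
        return any(pat.search(t) for t in texts)
    raise ConfigError(f"unknown match_kind {kind!r}")


def apply_filter(
    records: list[SequenceRecord],
    ruleset: list[FilterRule],
    default_action: str = CANDIDATE,
) -> list[Disposition]:
    """Evaluate rules in ascending step order; first EXCLUDE/CANDIDATE wins.

    Each record is judged independently, so output order matches input
    order and a record's label does not depend on its neighbours.  Records
    reaching the end of the rule set receive the default action
    (CANDIDATE unless configured otherwise — the fail-open choice).
    """
    validate_ruleset(ruleset)
    if default_action not in (CANDIDATE, "EXCLUDE", EXCLUDED):
        raise ConfigError(f"unknown default action {default_action!r}")
    default_label = CANDIDATE if default_action == CANDIDATE else EXCLUDED
    ordered = sorted(ruleset, key=lambda r: r.step_index)
    out = []
    for rec in records:
        disposition = None
        for rule in ordered:
            matched = _rule_matches(rule, rec)
            fired = matched if rule.polarity == "when_matched" else not matched
            if not fired or rule.action == "CONTINUE":
                continue
            label = CANDIDATE if rule.action == "CANDIDATE" else EXCLUDED
            disposition = Disposition(rec.accession, label, rule.rule_id, rule.step_index)
            break
        if disposition is None:
            disposition = Disposition(rec.accession, default_label, "default", None)
        out.append(disposition)
    return out


def primary_query(
    records: list[SequenceRecord],
    date_from: datetime.date | None = None,
    date_to: datetime.date | None = None,
    taxa: frozenset | set | None = PRIMARY_TAXA,
) -> list[SequenceRecord]:
    """The broad primary search: "allerg*" anywhere, date window, taxa set.

    Keeps records in which any text field contains a word starting with
    "allerg" (case-insensitive), whose entry date lies inside
    [date_from, date_to] (inclusive; pass None to disable either bound)
    and whose taxonomy group is in ``taxa`` (None disables the taxon
    constraint).  Records lacking a date or taxonomy group are kept only
    when the corresponding constraint is disabled.
    """
    if date_from is not None and date_to is not None and date_from > date_to:
        raise ValidationError(f"inverted date range: {date_from} > {date_to}")
    pat = word_start_pattern("allerg")
    out = []
    for rec in records:
        if not any(pat.search(t) for t in rec.text_fields()):
            continue
        if (date_from is not None or date_to is not None):
            if rec.entry_date is None:
                continue
            if date_from is not None and rec.entry_date < date_from:
                continue
            if date_to is not None and rec.entry_date > date_to:
                continue
        if taxa is not None and rec.taxonomy_group not in taxa:
            continue
        out.append(rec)
    return out


def supplemental_keyword_query(
    records: list[SequenceRecord],
    keywords: list[str] | tuple[str, ...] = DEFAULT_ALLERGEN_KEYWORDS,
) -> list[SequenceRecord]:
    """Keyword search for records the "allerg*" query misses.

    Keeps records whose definition or notes contain any of the allergen
    designations (whole-word, case-insensitive).  Run in parallel to the
    primary query to recover entries annotated only with a family name
    such as profilin or tropomyosin.
    """
    if not keywords:
        raise ConfigError("keyword list must be non-empty")
    pats = [whole_word_pattern(k) for k in keywords]
    out = []
    for rec in records:
        texts = [rec.definition] + rec.notes()
        if any(p.search(t) for t in texts for p in pats):
            out.append(rec)
    return out


def default_ruleset() -> list[FilterRule]:
    """The shipped triage rule set (a reconstruction of the published categories).

    1. Records submitted through an automated annotation pipeline are
       excluded: bulk genome-project annotations are the dominant noise
       source.
    2. An "allerg*" term in the protein definition line marks a candidate.
    3. A known allergen-family designation anywhere in the record marks a
       candidate.
    4. Records whose only "allerg*" occurrence is in a contextual note
       (e.g. sample provenance) rather than the protein description are
       excluded.
    The terminal default is CANDIDATE (fail-open).
    """
    return [
        FilterRule(
            "exclude-automated-pipeline", 1, "source_tag", "substring",
            "automated_pipeline", "EXCLUDE",
        ),
        FilterRule("definition-allerg", 2, "definition", "prefix_wildcard", "allerg", "CANDIDATE"),
        FilterRule(
            "allergen-family-keywords", 3, "any_text", "keyword_list",
            list(DEFAULT_ALLERGEN_KEYWORDS), "CANDIDATE",
        ),
        FilterRule("note-allerg-context-only", 4, "note", "prefix_wildcard", "allerg", "EXCLUDE"),
    ]


@dataclass
class FilterReport:
    label_counts: dict
    rule_counts: dict
    rows: list = field(default_factory=list)  # (accession, label, rule_id, step)

    def to_tsv(self) -> str:
        lines = ["accession\tlabel\tfired_rule\tfired_step"]
        for acc, label, rule_id, step in self.rows:
            lines.append(f"{acc}\t{label}\t{rule_id}\t{'' if step is None else step}")
        return "\n".join(lines) + "\n"


def filter_report(dispositions: list[Disposition]) -> FilterReport:
    """Per-label and per-rule counts plus the full per-record table."""
    labels = Counter(d.label for d in dispositions)
    rules = Counter(d.fired_rule_id for d in dispositions)
    rows = [(d.accession, d.label, d.fired_rule_id, d.fired_step_index) for d in dispositions]
    return FilterReport(dict(labels), dict(rules), rows)


# ---------------------------------------------------------------------------
# Rule sets as config files


def ruleset_to_yaml(rules: list[FilterRule], path) -> None:
    validate_ruleset(rules)
    doc = [
        {
            "rule_id": r.rule_id,
            "step_index": r.step_index,
            "field_selector": r.field_selector,
            "match_kind": r.match_kind,
            "pattern": r.pattern,
            "polarity": r.polarity,
            "action": r.action,
        }
        for r in sorted(rules, key=lambda r: r.step_index)
    ]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def ruleset_from_yaml(path) -> list[FilterRule]:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, list):
        raise ConfigError(f"{path}: rule file must be a list of rules")
    rules = []
    for i, item in enumerate(doc):
        try:
            rules.append(
                FilterRule(
                    rule_id=item["rule_id"],
                    step_index=int(item["step_index"]),
                    field_selector=item["field_selector"],
                    match_kind=item["match_kind"],
                    pattern=item["pattern"],
                    action=item["action"],
                    polarity=item.get("polarity", "when_matched"),
                )
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"{path}: rule #{i + 1} malformed: {exc}") from exc
    validate_ruleset(rules)
    return rules
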