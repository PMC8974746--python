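"""Entry validation, the decision ledger, releases, diffs and exports."""
import pytest

from allerscreen.curation import (
    AllergenEntry,
    DecisionLedger,
    Reference,
    Release,
    build_release,
    diff_releases,
    export_release,
    export_transparency,
    import_release,
    validate_entry,
)
from allerscreen.errors import ReleaseConflictError, ValidationError

REF = Reference("PMID:1", "IgE binding of the purified protein", 2019)


def make_entry(acc="E1", seq="ACDEFGHIKL", year="2019", kind="full_protein", refs=(REF,), **kw):
    return AllergenEntry(
        accession=acc,
        species="Betula pendula",
        common_name="birch",
        description="major pollen allergen",
        sequence=seq,
        length=len(seq),
        year_adopted=year,
        entry_kind=kind,
        references=list(refs),
        **kw,
    )


@pytest.fixture()
def base_release():
    entries = {}
    for i in range(10):
        # imported foundational entries predate the review era: no references
        e = make_entry(acc=f"B{i:03d}", seq="ACDEFGHIKL" + "MNPQ"[: i % 4 + 1], year="2016", refs=())
        entries[e.accession] = e
    return Release("2016-base", entries)


class TestValidateEntry:
    def test_fully_populated_entry_is_valid(self):
        assert validate_entry(make_entry()) == []

    def test_ms_peptide_length_floor(self):
        nine = make_entry(seq="ACDEFGHIK", kind="ms_peptide")
        ten = make_entry(seq="ACDEFGHIKL", kind="ms_peptide")
        assert "PEPTIDE_TOO_SHORT" in validate_entry(nine)
        assert validate_entry(ten) == []

    def test_review_era_entry_requires_a_reference(self):
        assert "NO_REFERENCE" in validate_entry(make_entry(refs=()))
        # pre-review imports are exempt
        assert validate_entry(make_entry(year="2016", refs=())) == []
        # historic-screening labels still carry a review-era year
        assert "NO_REFERENCE" in validate_entry(make_entry(year="2020H", refs=()))

    def test_length_and_alphabet_checks(self):
        bad_len = make_entry()
        bad_len.length = 99
        assert "LENGTH_MISMATCH" in validate_entry(bad_len)
        bad_seq = make_entry()
        bad_seq.sequence = "ACDEF1HIKL"
        assert "BAD_RESIDUE" in validate_entry(bad_seq)
        assert "BAD_YEAR_LABEL" in validate_entry(make_entry(year="early"))


class TestDecisionLedger:
    def test_accept_requires_ige_binding_code(self):
        ledger = DecisionLedger()
        with pytest.raises(ValidationError, match="IGE_BINDING_EVIDENCE"):
            ledger.record_decision("E1", "ACCEPT", ["ASSAY_VALID"], "", 2019)
        d = ledger.record_decision("E1", "ACCEPT", ["IGE_BINDING_EVIDENCE"], "", 2019)
        assert d.verdict == "ACCEPT"

    def test_reject_requires_an_exclusion_code(self):
        ledger = DecisionLedger()
        with pytest.raises(ValidationError):
            ledger.record_decision("E1", "REJECT", ["IGE_BINDING_EVIDENCE"], "", 2019)
        d = ledger.record_decision("E1", "REJECT", ["CCD_ONLY_BINDING"], "glycan only", 2019)
        assert "CCD_ONLY_BINDING" in d.criteria_codes

    def test_unknown_code_and_verdict_rejected(self):
        ledger = DecisionLedger()
        with pytest.raises(ValidationError, match="unknown criteria"):
            ledger.record_decision("E1", "REJECT", ["BAD_CODE"], "", 2019)
        with pytest.raises(ValidationError):
            ledger.record_decision("E1", "MAYBE", ["IGE_BINDING_EVIDENCE"], "", 2019)

    def test_rejected_candidate_can_be_revisited_in_a_later_cycle(self):
        ledger = DecisionLedger()
        ledger.record_decision("E1", "REJECT", ["HOMOLOGY_ONLY"], "no direct data", 2019)
        ledger.record_decision(
            "E1", "ACCEPT", ["IGE_BINDING_EVIDENCE"], "new sera study", 2020
        )
        assert [d.cycle_year for d in ledger] == [2019, 2020]
        assert [d.verdict for d in ledger] == ["REJECT", "ACCEPT"]

    def test_ledger_is_append_only(self):
        ledger = DecisionLedger()
        first = ledger.record_decision("E1", "REJECT", ["HOMOLOGY_ONLY"], "", 2019)
        ledger.record_decision("E2", "ACCEPT", ["IGE_BINDING_EVIDENCE"], "", 2019)
        assert ledger.decisions[0] == first


class TestBuildRelease:
    def test_base_plus_accepted_conserves_counts(self, base_release):
        accepted = [make_entry(acc=f"N{i}") for i in range(3)]
        rel = build_release(base_release, accepted, "2019")
        assert len(rel.entries) == 13
        for acc, entry in base_release.entries.items():
            assert rel.entries[acc] == entry  # base preserved unchanged
        assert all(rel.entries[f"N{i}"].year_adopted == "2019" for i in range(3))

    def test_historic_labels_by_entry_kind(self, base_release):
        protein = make_entry(acc="H1")
        peptide = make_entry(acc="H2", seq="ACDEFGHIKL", kind="ms_peptide",
                             parent_accession="B000")
        rel = build_release(base_release, [protein, peptide], "2020", historic=True)
        assert rel.entries["H1"].year_adopted == "2020H"
        assert rel.entries["H2"].year_adopted == "2020H_MS"
        assert rel.entries["H2"].parent_accession == "B000"

    def test_invalid_entry_is_rejected_with_its_violations(self, base_release):
        bad = make_entry(acc="N1", seq="ACDEFGHIK", kind="ms_peptide")
        with pytest.raises(ValidationError, match="PEPTIDE_TOO_SHORT"):
            build_release(base_release, [bad], "2019")

    def test_accession_collision_needs_explicit_update_mode(self, base_release):
        clash = make_entry(acc="B000")
        with pytest.raises(ReleaseConflictError):
            build_release(base_release, [clash], "2019")
        rel = build_release(base_release, [clash], "2019", allow_update=True)
        assert len(rel.entries) == 10
        assert rel.entries["B000"].year_adopted == "2019"

    def test_rebuild_with_identical_inputs_is_byte_identical_on_export(
        self, base_release, tmp_path
    ):
        accepted = [make_entry(acc=f"N{i}") for i in range(3)]
        paths = []
        for run in ("a", "b"):
            rel = build_release(base_release, accepted, "2019")
            fa, tb = tmp_path / f"{run}.fasta", tmp_path / f"{run}.tsv"
            export_release(rel, fa, tb)
            paths.append((fa.read_bytes(), tb.read_bytes()))
        assert paths[0] == paths[1]


class TestDiff:
    def test_identical_releases_give_empty_diff(self, base_release):
        diff = diff_releases(base_release, base_release)
        assert diff.is_empty

    def test_field_level_change_is_named(self, base_release):
        import copy

        edited = copy.deepcopy(base_release)
        edited.entries["B003"].description = "renamed allergen"
        diff = diff_releases(base_release, edited)
        assert diff.changed == {"B003": ["description"]}
        assert diff.added == [] and diff.removed == []

    def test_diff_equals_independent_set_arithmetic(self, base_release):
        accepted = [make_entry(acc=f"N{i}") for i in range(3)]
        new = build_release(base_release, accepted, "2019")
        diff = diff_releases(base_release, new)
        old_accs, new_accs = set(base_release.entries), set(new.entries)
        assert set(diff.added) == new_accs - old_accs
        assert set(diff.removed) == old_accs - new_accs
        assert len(new.entries) == len(base_release.entries) - len(diff.removed) + len(diff.added)


class TestExports:
    def test_transparency_export_has_one_row_per_decision(self, tmp_path):
        ledger = DecisionLedger()
        ledger.record_decision("E1", "ACCEPT", ["IGE_BINDING_EVIDENCE"], "solid data", 2019)
        ledger.record_decision("E2", "REJECT", ["INSUFFICIENT_PURITY"], "smeared blot", 2019)
        p = tmp_path / "transparency.tsv"
        export_transparency(ledger, p)
        lines = p.read_text().splitlines()
        assert len(lines) == 3
        assert lines[1].split("\t")[:3] == ["E1", "2019", "ACCEPT"]
        assert "INSUFFICIENT_PURITY" in lines[2]

    def test_release_export_import_round_trip(self, base_release, tmp_path):
        accepted = [
            make_entry(acc="N1", iuis_name="Bet v 99"),
            make_entry(acc="N2", seq="ACDEFGHIKLMNPQ", kind="ms_peptide",
                       parent_accession="N1"),
        ]
        rel = build_release(base_release, accepted, "2020", historic=True)
        fa, tb = tmp_path / "rel.fasta", tmp_path / "rel.tsv"
        export_release(rel, fa, tb)
        back = import_release(fa, tb, "2020")
        assert set(back.entries) == set(rel.entries)
        for acc, orig in rel.entries.items():
            got = back.entries[acc]
            for field in ("species", "common_name", "description", "sequence",
                          "length", "year_adopted", "iuis_name", "parent_accession",
                          "entry_kind"):
                assert getattr(got, field) == getattr(orig, field), (acc, field)

    def test_exported_table_lengths_match_exported_fasta(self, base_release, tmp_path):
        from allerscreen import seqio

        fa, tb = tmp_path / "rel.fasta", tmp_path / "rel.tsv"
        export_release(base_release, fa, tb)
        records = {r.accession: r for r in seqio.read_fasta(fa)}
        for row in seqio.read_entry_table(tb):
            assert row["Length"] == records[row["Accession"]].length
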