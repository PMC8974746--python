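# allerscreen

A toolkit for allergen-database screening and curation. It is written for
the people who build and use curated protein-allergen databases: risk
assessors screening novel proteins (e.g. from genetically modified crops)
for potential cross-reactivity with known allergens, and database
curators who triage public sequence records, record expert review
decisions and publish versioned, transparent database releases.

## What it computes

**Screening.** A query protein is compared to an allergen database with
the three modes recommended by FAO/WHO and CODEX Alimentarius guidance:

1. *Full-length search* — exact Smith–Waterman local alignment of the
   whole query against every database entry under an affine gap model
   (BLOSUM50, gap open −10, extend −2 by default), ranked by a
   Karlin–Altschul E-value `E = K·m·n·exp(−λS)` against a user-settable
   threshold.
2. *80-aa sliding window* — every contiguous 80-residue fragment of the
   query is aligned against every entry; an alignment with identity
   strictly greater than 35% spanning at least 80 columns is a hit
   (the CODEX cross-reactivity criterion). Queries shorter than 80
   residues are screened whole and flagged.
3. *8-mer exact match* — every identical stretch of eight contiguous
   residues shared with an entry. Kept for guideline completeness;
   reports carry the standard caveat about its high false-positive rate.

**Triage.** An ordered, configurable keyword rule engine partitions
annotated protein records (definition line, notes, organism, provenance
tag) into allergen candidates and excluded noise, with full provenance of
which rule fired. The default terminal action is CANDIDATE: a record no
rule recognises goes to expert review rather than being dropped.

**Curation.** Entries are validated against machine-checkable review
criteria (at least one supporting publication for review-era entries,
a 10-residue floor for mass-spectrometry peptide entries, sequence/length
consistency); accept/reject decisions are recorded in an append-only
ledger with a controlled criteria vocabulary (acceptance requires IgE
binding evidence); releases are versioned, conservative (base entries are
never removed or mutated), diffable, and exportable as mutually
consistent FASTA + metadata tables plus a public transparency file.

**Fixtures.** Deterministic synthetic data generators cover every
surface, including homolog pairs with an exact planted identity count for
probing the 35% window rule at its boundary.

## Worked example

Screen a synthetic protein against a small database that contains the
query itself and an implanted 40%-identity homolog:

```python
from allerscreen.fixtures import FixtureSpec, make_db, implant_homolog
from allerscreen.seqio import SequenceRecord
from allerscreen.screen import run_screen, format_report

db = make_db(FixtureSpec(seed=1, n_entries=5, length_range=(100, 160)))
base = db[0].sequence
variant = implant_homolog(base[:120], 48, 120, seed=2)   # 48/120 = 40% identity
db.append(SequenceRecord("SYN000006", variant, "implanted homolog of SYN000001"))
print(format_report(run_screen(db[0], db, db_label="demo-db"), "txt"))
```

which prints:

```
Screen report for query SYN000001 vs database demo-db
parameters: db_entries=6; db_label=demo-db; db_residues=754; e_threshold=1.0; gap_extend=-2; gap_open=-10; identity_threshold=0.35; ka_k=0.112; ka_lambda=0.232; kmer_k=8; matrix=BLOSUM50; modes=full,window,kmer; window_width=80

[1] full-length search: 5 hit(s) with E <= 1.0
    SYN000001  score=939  E=2.65e-91  identity=100.0% over 128 columns
    SYN000006  score=529  E=5.42e-50  identity=40.0% over 120 columns
    SYN000002  score=89  E=1.17e-05  identity=24.8% over 117 columns
    SYN000003  score=70  E=0.000957  identity=24.1% over 83 columns
    SYN000004  score=50  E=0.0991  identity=20.9% over 110 columns
[2] 80-aa sliding-window scan (>35% identity rule): 70 hit(s)
[3] 8-mer exact match: 121 hit(s). Note: 8-mer exact matching has a high false-positive rate and adds little value to allergenicity risk assessment; review hits with caution.

summary flags: full_hit=True window_hit=True kmer_hit=True
```

Reading the output: the query finds itself at 100% identity with a
vanishing E-value; the implanted homolog aligns gap-free over its full
120 residues at exactly the planted 40% identity, which clears the >35%
window criterion and so contributes sliding-window hits (the remaining
window hits are the query's 49 windows matching itself); the unrelated
random entries score low but still pass the permissive default E ≤ 1
cut-off on the full-length search, which is why that threshold is
user-settable. All 121 8-mer hits come from the query and its homolog —
none from the unrelated entries.

The same run is available from the shell:

```sh
allerscreen fixtures db --seed 1 --n 5 --out work/
allerscreen screen --query work/db.fasta --db work/db.fasta --out work/report.tsv
allerscreen filter --records records.flat --out dispositions.tsv
allerscreen release build --add-fasta new.fasta --add-table new.tsv \
    --references refs.tsv --version 2021 --out-fasta rel.fasta --out-table rel.tsv
```

Exit codes are stable (0 ok, 1 validation/configuration error, 2
I/O/parse error) and every run logs its effective parameter set.

## Documentation

`docs/methods.md` describes the models and procedures, the default
parameters and why, what the synthetic data does and does not emulate,
and known limitations.
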