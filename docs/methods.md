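# Methods

This note documents the models and procedures implemented by
`allerscreen`, the defaults and why they were chosen, the numerical and
design decisions taken where practice leaves room, and what the
synthetic test data does and does not demonstrate.

## Local alignment

The computational core is exact Smith–Waterman local alignment with
affine gaps (Gotoh's three-matrix recurrence), not a heuristic
seed-and-extend search. The choice is deliberate: exact dynamic
programming is deterministic, strictly at least as sensitive as heuristic
protein search tools, and checkable against a brute-force enumeration
oracle on small instances — which the test suite does. The JIT-compiled
kernel (numba) makes the exhaustive sliding-window scans tractable at
around 10^8 dynamic-programming cells per second on one core.

Scoring model and defaults:

* **Matrix** — BLOSUM50 (default) or BLOSUM62, loaded through Biopython;
  any matrix in NCBI text format can be supplied by path. BLOSUM50 with
  gap open −10 / extend −2 mirrors common protein-search defaults for
  full-length and fragment comparisons. A gap of length L costs
  |open| + (L−1)·|extend|; the constraint `gap_open <= gap_extend < 0`
  is enforced.
* **Percent identity** — identities divided by *all* alignment columns,
  gap columns included in the denominator and never the numerator. This
  is the conservative reading when an alignment contains gaps; the
  alternative (identities over the fixed window length) coincides with
  it for the gap-free alignments the boundary tests construct.
* **Ambiguity letters** — X scores whatever the matrix assigns but never
  counts as an identity, even X-vs-X, so masked or unknown regions
  cannot inflate identity. Residue letters absent from the matrix
  (U, J, O under the bundled BLOSUMs) are an argument error rather than
  being silently remapped.
* **Tie-breaking** — among equal-scoring alignments, the smallest query
  start wins, then the smallest subject start, then the fewest columns.
  Candidate end cells are enumerated from the score matrix and each is
  traced back with a fixed move preference (substitution, then gap in
  subject, then gap in query). Reports are therefore byte-reproducible.
* **E-values** — the ungapped Karlin–Altschul form
  `E = K·m·n·exp(−λS)` with the standard tabulated ungapped (λ, K)
  pairs: (0.232, 0.112) for BLOSUM50 and (0.318, 0.134) for BLOSUM62.
  Because the alignments are gapped, these E-values are an approximation
  suitable for ranking and thresholding, not for publication-grade
  significance; the report snapshot records the constants used. `n` is
  the summed residue count of the database being searched.

## Screening modes

* **Full-length search** aligns the whole query to every entry and keeps
  hits with E at or below the threshold (default 1.0 — deliberately
  permissive, and user-settable, because the full-length mode is a
  ranking aid rather than a decision rule). Hits sort by ascending
  E-value, then descending score, then accession.
* **Sliding-window scan** enumerates every 80-residue query fragment
  (L−79 windows for a query of length L) and aligns each *locally*
  against every full subject; the fragment is not forced to align end to
  end. A hit requires identity strictly greater than 0.35 — 28/80
  (exactly 35%) is not a hit, 29/80 is — and an alignment spanning at
  least 80 columns. Queries shorter than 80 residues are screened as a
  single whole-sequence window that must be covered end to end; such
  hits are flagged `short_window` because they fall outside the strict
  80-aa criterion while still being reported (short proteins should not
  silently escape screening).
* **8-mer exact match** indexes every 8-residue substring of the
  database in a hash map and reports every exact match with
  coordinates. 8-mers containing ambiguity letters are excluded from
  both index and query side: an unknown residue is not an exact match.
  The mode is retained because guidelines historically include it, and
  every report of its output carries the high-false-positive caveat.

Modes are independent — disabling one never changes another's output —
and each report embeds the full parameter snapshot needed to reproduce
the run.

## Keyword triage

The candidate filter models the annual screening funnel: a deliberately
broad primary query (any word starting with "allerg", case-insensitive,
restricted to animal/plant/fungus/protist sources and an entry-date
window — the default window is 2015-05-30 to 2016-05-14, a one-year
culling period), a supplemental whole-word search for allergen-family
designations (profilin, tropomyosin, parvalbumin, ...) that catches
records annotated only with a family name, and an ordered rule engine.

Rules are data (YAML), not code, so a refined production rule set can be
dropped in without touching the engine. Each rule names a field
(definition, note, organism, taxonomy group, provenance tag, or any
text), a matching primitive (substring, word-start prefix, whole-word
keyword list, regex, date range, taxon set), a polarity and an action
(EXCLUDE, CANDIDATE, CONTINUE). Rules run in ascending step order and the
first terminal action wins, so every disposition carries the rule and
step that produced it.

The shipped default set reconstructs the four published screening
categories: exclude automated-annotation-pipeline submissions (the
dominant noise source), accept definitions containing "allerg*", accept
allergen-family keywords, and exclude records whose only "allerg*"
occurrence is a contextual note (e.g. sample provenance) unrelated to
the protein itself. The terminal default is CANDIDATE — fail-open —
because wrongly excluding a real allergen is the costlier error. That
choice gives the engine a provable monotonicity property exercised by
the tests: removing any EXCLUDE rule can only increase the candidate
count.

## Curation and releases

The review requirements are encoded as pure validation functions:

* every entry's stored length must equal its residue count and its
  sequence must be alphabet-valid;
* entries adopted from 2017 onward must cite at least one supporting
  publication (the imported pre-2017 foundational entries are exempt,
  since they predate the review process);
* mass-spectrometry peptide entries must be at least 10 residues and may
  carry a parent accession as metadata linking them to their source
  protein (the parent need not itself be an entry).

Review decisions live in an append-only ledger with a controlled
vocabulary (inclusion: IGE_BINDING_EVIDENCE, SERA_QUALITY_OK,
ASSAY_VALID; exclusion: NO_NEGATIVE_CONTROL, INSUFFICIENT_PURITY,
CCD_ONLY_BINDING, HOMOLOGY_ONLY, SEQUENCE_MISMATCH). ACCEPT requires the
IgE-binding code — IgE binding in human sera is the minimal inclusion
evidence — and REJECT requires at least one exclusion code; free-text
comments carry the nuance the codes cannot. The same accession may be
re-decided in a later cycle: rejection for lack of evidence is not
permanent.

Release building is conservative by construction: every base entry is
carried over unchanged; accepted entries are stamped with the release
label, suffixed `H` (or `H_MS` for peptide entries) when they come from
retrospective "historic" screening of older records; accession
collisions are a hard error unless the explicit metadata-update mode is
requested. Diffs report added and removed accessions and field-level
changes for shared ones; what counts as a *policy-relevant* change is
left to the operator, since silent correction versus versioned update is
a governance question, not a computation. The transparency export writes
one row per decision (accession, cycle, verdict, codes, comment),
mirroring the public decision record a curated database publishes.

## Synthetic data

The fixture generators drive all tests; no external downloads occur.
Sequences are i.i.d. uniform over the 20 standard amino acids with
uniform lengths (90–400 for screening databases — typical mature protein
lengths), via `numpy.random.default_rng` (PCG64), so a fixed seed
reproduces identical bytes on any platform.

Annotated-record generation plants exactly one triage category per
record (20% automated-pipeline, 25% definition-line "allerg*", 20%
note-only mentions, 20% family keywords, 15% irrelevant controls — a mix
chosen to exercise every rule with comfortable counts at n = 500) plus
planted date and taxon noise (10% of dates outside the primary window,
10% of taxa outside the searched groups), and returns the ground-truth
label alongside, so filter accuracy is scored exactly rather than
estimated.

Homolog implantation replaces a chosen number of positions in a sequence
region with *conservative* substitutions — non-identical residues with a
positive substitution score, preferring positions where such a
replacement exists (every residue except cysteine and proline has one
under BLOSUM50). Because every aligned column then scores positive, the
optimal local alignment of the pair is provably the full-length,
gap-free one, and the alignment's identity fraction equals the planted
count exactly. This is what makes the 28/80-vs-29/80 boundary test
well-defined rather than dependent on where a trimmed alignment happens
to end.

What passing these tests does *not* show: real protein databases have
composition bias, low-complexity regions, repeats and genuine homology
families, all absent from i.i.d. noise; E-value calibration against
random-sequence nulls is therefore easier here than in practice, and the
triage rules are only shown to separate the planted categories, not the
full messiness of real annotation text. The screening arithmetic
(window counts, identity thresholds, k-mer coordinates) is insensitive
to these differences, which is why the suite focuses its exactness
claims there.

## Problem sizes and numerics

The alignment oracle suite uses 200 random pairs of length ≤ 6 over a
4-letter alphabet — small enough for true enumeration of every substring
pair and every gapped alignment, large enough to cover all move
combinations. The self-screen suite uses a 50-entry database with
lengths 90–400 (~8×10⁹ DP cells for the full all-windows-vs-all-entries
scan), the triage suite 500 records, and the k-mer oracle 100
query/database pairs. Scores are exact 32-bit integers; identity
fractions are exact rationals evaluated in double precision; no
tolerance is needed anywhere except the trivial floating-point equality
of recomputed fractions.

## Known limitations

* E-values use ungapped (λ, K) constants with gapped alignments; they
  rank correctly but are biased relative to empirically fitted gapped
  statistics.
* The bundled rule set is a documented reconstruction of the published
  screening categories, not the verbatim production filter (whose full
  step list is supplementary material elsewhere); the YAML format exists
  precisely so a verbatim set can replace it.
* The flat-file dialect carries only the annotation fields the filter
  inspects; it is not a general GenPept/UniProt parser.
* Screening is protein-vs-protein only: no translated or nucleotide
  queries, no banded or heuristic acceleration, no visualization.
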