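"""Three-mode screening of a query protein against an allergen database.

The three comparison modes follow the FAO/WHO–CODEX bioinformatic
assessment of potential cross-reactivity:

1. **Full-length search** — local alignment of the whole query against
   every database entry, ranked by E-value against a user-settable
   threshold.
2. **Sliding-window scan** — every contiguous 80-residue fragment of the
   query is aligned against every database entry; an alignment with
   strictly more than 35% identity spanning at least 80 columns is a hit.
   Queries shorter than 80 residues are screened as a single whole-length
   window and flagged as short (outside the letter of the CODEX rule).
3. **8-mer exact match** — every identical stretch of eight contiguous
   residues shared with a database entry.  This screen has a high false
   positive rate and is provided for guideline completeness; reports
   carry that caveat.

All hit orderings are fully specified so reports are reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .align import Aligner, AlignParams, LocalAlignment, evalue as _evalue
from .errors import ValidationError
from .seqio import AMBIGUITY_LETTERS, SequenceRecord

#: CODEX sliding-window defaults: >35% identity over >= 80 aligned columns.
IDENTITY_THRESHOLD = 0.35
WINDOW_WIDTH = 80
KMER_K = 8
DEFAULT_E_THRESHOLD = 1.0

KMER_CAVEAT = (
    "8-mer exact matching has a high false-positive rate and adds little "
    "value to allergenicity risk assessment; review hits with caution"
)


@dataclass(frozen=True)
class ScreenConfig:
    """Effective screening parameters; snapshotted into every report."""

    params: AlignParams = field(default_factory=AlignParams)
    e_threshold: float = DEFAULT_E_THRESHOLD
    identity_threshold: float = IDENTITY_THRESHOLD
    window_width: int = WINDOW_WIDTH
    kmer_k: int = KMER_K
    modes: tuple[str, ...] = ("full", "window", "kmer")

    def snapshot(self, db_label: str, n_db: int, db_residues: int) -> dict:
        return {
            "matrix": self.params.matrix_name,
            "gap_open": self.params.gap_open,
            "gap_extend": self.params.gap_extend,
            "ka_lambda": self.params.ka_lambda,
            "ka_k": self.params.ka_k,
            "e_threshold": self.e_threshold,
            "identity_threshold": self.identity_threshold,
            "window_width": self.window_width,
            "kmer_k": self.kmer_k,
            "modes": ",".join(self.modes),
            "db_label": db_label,
            "db_entries": n_db,
            "db_residues": db_residues,
        }


@dataclass
class FullHit:
    subject_accession: str
    alignment: LocalAlignment
    evalue: float


@dataclass
class Window:
    start: int  # 1-based offset in the query
    seq: str
    short: bool  # query shorter than the nominal window width


@dataclass
class WindowHit:
    window_start: int
    window_seq: str
    subject_accession: str
    alignment: LocalAlignment
    is_hit: bool
    is_short: bool


@dataclass
class WindowTrace:
    """Best identity seen for one window across the whole database."""

    window_start: int
    best_subject: str | None
    best_identity: float
    best_n_columns: int
    is_short: bool


@dataclass
class KmerHit:
    query_pos: int  # 1-based
    subject_accession: str
    subject_pos: int  # 1-based
    kmer: str


@dataclass
class ScreenReport:
    query_accession: str
    db_version_label: str
    parameters: dict
    full_hits: list[FullHit]
    window_hits: list[WindowHit]
    window_trace: list[WindowTrace]
    kmer_hits: list[KmerHit]

    @property
    def any_full_hit_below_threshold(self) -> bool:
        return len(self.full_hits) > 0

    @property
    def any_window_hit(self) -> bool:
        return len(self.window_hits) > 0

    @property
    def any_kmer_hit(self) -> bool:
        return len(self.kmer_hits) > 0


def _check_db(db) -> None:
    if not db:
        raise ValidationError("allergen database must contain at least one entry")


def fullseq_search(
    query: SequenceRecord,
    db: list[SequenceRecord],
    params: AlignParams | None = None,
    e_threshold: float = DEFAULT_E_THRESHOLD,
) -> list[FullHit]:
    """Align the whole query against every database entry.

    Returns the entries whose E-value is at or below ``e_threshold``,
    sorted by ascending E-value, ties by descending score then accession.
    The database size for the E-value is the summed length of all entries.
    """
    _check_db(db)
    if e_threshold <= 0:
        raise ValidationError("e_threshold must be positive")
    params = params or AlignParams()
    aligner = Aligner(params)
    db_residues = sum(r.length for r in db)
    hits = []
    for rec in db:
        aln = aligner.align(query.sequence, rec.sequence)
        ev = _evalue(aln.score, query.length, db_residues, params)
        if ev <= e_threshold:
            hits.append(FullHit(rec.accession, aln, ev))
    hits.sort(key=lambda h: (h.evalue, -h.alignment.score, h.subject_accession))
    return hits


def make_windows(query: str, width: int = WINDOW_WIDTH, stride: int = 1) -> list[Window]:
    """Sequentially overlapping fragments of the query.

    A query of length L >= width yields windows starting at 1..L-width+1
    (stride 1 gives exactly L-79 for the 80-residue default); a shorter
    query yields a single whole-sequence window marked short.
    """
    if not query:
        raise ValidationError("query must be non-empty")
    if width < 1 or stride < 1:
        raise ValidationError("width and stride must be positive")
    L = len(query)
    if L < width:
        return [Window(1, query, True)]
    return [Window(s + 1, query[s : s + width], False) for s in range(0, L - width + 1, stride)]


def window_scan(
    query: SequenceRecord,
    db: list[SequenceRecord],
    params: AlignParams | None = None,
    identity_threshold: float = IDENTITY_THRESHOLD,
    width: int = WINDOW_WIDTH,
) -> tuple[list[WindowHit], list[WindowTrace]]:
    """Scan every query window against every database entry.

    A full-size window is a hit when its best local alignment to an entry
    has identity strictly greater than ``identity_threshold`` over at
    least ``width`` columns.  A short window (query shorter than
    ``width``) must instead span at least its own length; such hits are
    flagged so downstream reporting can mark them as outside the strict
    CODEX criterion.  Also returns, for every window, the best identity
    observed across the database (the per-window trace).
    """
    _check_db(db)
    params = params or AlignParams()
    aligner = Aligner(params)
    windows = make_windows(query.sequence, width)
    subjects = [(rec.accession, rec.sequence, aligner.encode(rec.sequence)) for rec in db]
    hits: list[WindowHit] = []
    trace: list[WindowTrace] = []
    for w in windows:
        wc = aligner.encode(w.seq)
        need = len(w.seq) if w.short else width
        best_ident = 0.0
        best_subject: str | None = None
        best_ncols = 0
        for acc, sseq, scodes in subjects:
            st = aligner.stats(wc, scodes)
            if st.n_columns == 0:
                continue
            ident = st.n_identities / st.n_columns
            if ident > best_ident or (ident == best_ident and best_subject is None):
                best_ident, best_subject, best_ncols = ident, acc, st.n_columns
            if ident > identity_threshold and st.n_columns >= need:
                aln = aligner.align(w.seq, sseq)
                hits.append(WindowHit(w.start, w.seq, acc, aln, True, w.short))
        trace.append(WindowTrace(w.start, best_subject, best_ident, best_ncols, w.short))
    return hits, trace


def build_kmer_index(
    db: list[SequenceRecord], k: int = KMER_K
) -> dict[str, list[tuple[str, int]]]:
    """Index every k-length substring of every database sequence.

    Positions are 1-based.  K-mers containing ambiguity letters (B, Z, X,
    U, J, O) are excluded: an unknown or ambiguous residue is not an exact
    match.  Entries shorter than k contribute nothing.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    ambiguous = set(AMBIGUITY_LETTERS)
    index: dict[str, list[tuple[str, int]]] = {}
    for rec in db:
        seq = rec.sequence
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if ambiguous.intersection(kmer):
                continue
            index.setdefault(kmer, []).append((rec.accession, i + 1))
    return index


def kmer_scan(
    query: SequenceRecord | str,
    index: dict[str, list[tuple[str, int]]],
    k: int = KMER_K,
) -> list[KmerHit]:
    """Exact k-mer matches of the query against an index.

    Returns every (query position, subject, subject position) triple with
    an identical k-residue stretch, sorted by query position, then subject
    accession, then subject position.  A query shorter than k yields an
    empty list.
    """
    seq = query if isinstance(query, str) else query.sequence
    ambiguous = set(AMBIGUITY_LETTERS)
    hits: list[KmerHit] = []
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if ambiguous.intersection(kmer):
            continue
        for acc, pos in index.get(kmer, ()):
            hits.append(KmerHit(i + 1, acc, pos, kmer))
    hits.sort(key=lambda h: (h.query_pos, h.subject_accession, h.subject_pos))
    return hits


def run_screen(
    query: SequenceRecord,
    db: list[SequenceRecord],
    config: ScreenConfig | None = None,
    db_label: str = "db",
) -> ScreenReport:
    """Run the configured screening modes and aggregate one report.

    Modes are independent: disabling one never changes another's hits.
    The report embeds a parameter snapshot sufficient to reproduce the run.
    """
    config = config or ScreenConfig()
    _check_db(db)
    db_residues = sum(r.length for r in db)
    full_hits: list[FullHit] = []
    window_hits: list[WindowHit] = []
    trace: list[WindowTrace] = []
    kmer_hits: list[KmerHit] = []
    if "full" in config.modes:
        full_hits = fullseq_search(query, db, config.params, config.e_threshold)
    if "window" in config.modes:
        window_hits, trace = window_scan(
            query, db, config.params, config.identity_threshold, config.window_width
        )
    if "kmer" in config.modes:
        kmer_hits = kmer_scan(query, build_kmer_index(db, config.kmer_k), config.kmer_k)
    return ScreenReport(
        query_accession=query.accession,
        db_version_label=db_label,
        parameters=config.snapshot(db_label, len(db), db_residues),
        full_hits=full_hits,
        window_hits=window_hits,
        window_trace=trace,
        kmer_hits=kmer_hits,
    )


_TSV_COLUMNS = [
    "mode",
    "query",
    "subject",
    "window_start",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "n_columns",
    "identity",
    "score",
    "evalue",
    "kmer",
    "note",
]


def format_report(report: ScreenReport, style: str = "tsv") -> str:
    """Deterministically format a report as a TSV hit table or readable text."""
    if style == "tsv":
        return _format_tsv(report)
    if style == "txt":
        return _format_txt(report)
    raise ValidationError(f"unknown report style {style!r} (expected 'tsv' or 'txt')")


def _format_tsv(report: ScreenReport) -> str:
    lines = [f"# {k}={report.parameters[k]}" for k in sorted(report.parameters)]
    lines.append("\t".join(_TSV_COLUMNS))
    q = report.query_accession
    for h in report.full_hits:
        a = h.alignment
        lines.append(
            "\t".join(
                [
                    "full", q, h.subject_accession, "",
                    str(a.q_start), str(a.q_end), str(a.s_start), str(a.s_end),
                    str(a.n_columns), f"{a.identity_fraction:.4f}", str(a.score),
                    f"{h.evalue:.3g}", "", "",
                ]
            )
        )
    for h in report.window_hits:
        a = h.alignment
        lines.append(
            "\t".join(
                [
                    "window", q, h.subject_accession, str(h.window_start),
                    str(a.q_start), str(a.q_end), str(a.s_start), str(a.s_end),
                    str(a.n_columns), f"{a.identity_fraction:.4f}", str(a.score),
                    "", "", "short_window" if h.is_short else "",
                ]
            )
        )
    for h in report.kmer_hits:
        lines.append(
            "\t".join(
                [
                    "kmer", q, h.subject_accession, "",
                    str(h.query_pos), str(h.query_pos + len(h.kmer) - 1),
                    str(h.subject_pos), str(h.subject_pos + len(h.kmer) - 1),
                    str(len(h.kmer)), "1.0000", "", "", h.kmer, "",
                ]
            )
        )
    return "\n".join(lines) + "\n"


def _format_txt(report: ScreenReport) -> str:
    p = report.parameters
    lines = [
        f"Screen report for query {report.query_accession} "
        f"vs database {report.db_version_label}",
        "parameters: " + "; ".join(f"{k}={p[k]}" for k in sorted(p)),
        "",
        f"[1] full-length search: {len(report.full_hits)} hit(s) with "
        f"E <= {p['e_threshold']}",
    ]
    for h in report.full_hits[:10]:
        a = h.alignment
        lines.append(
            f"    {h.subject_accession}  score={a.score}  E={h.evalue:.3g}  "
            f"identity={a.identity_fraction:.1%} over {a.n_columns} columns"
        )
    if len(report.full_hits) > 10:
        lines.append(f"    ... and {len(report.full_hits) - 10} more")
    n_short = sum(1 for h in report.window_hits if h.is_short)
    lines.append(
        f"[2] {p['window_width']}-aa sliding-window scan "
        f"(>35% identity rule): {len(report.window_hits)} hit(s)"
        + (f" ({n_short} from short windows, outside the strict CODEX rule)" if n_short else "")
    )
    lines.append(
        f"[3] {p['kmer_k']}-mer exact match: {len(report.kmer_hits)} hit(s). "
        f"Note: {KMER_CAVEAT}."
    )
    lines.append("")
    lines.append(
        "summary flags: "
        f"full_hit={report.any_full_hit_below_threshold} "
        f"window_hit={report.any_window_hit} "
        f"kmer_hit={report.any_kmer_hit}"
    )
    return "\n".join(lines) + "\n"
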