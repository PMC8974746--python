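"""Local pairwise protein alignment with affine gaps.

This module implements exact Smith–Waterman local alignment under the
affine gap model (a gap of length L costs ``|gap_open| + (L-1)*|gap_extend|``),
together with percent identity over alignment columns and an ungapped
Karlin–Altschul E-value approximation

    E = K * m * n * exp(-lambda * S)

where ``m`` is the query length, ``n`` the summed residue count of the
database and ``S`` the alignment score.  The (lambda, K) pairs shipped for
BLOSUM50 and BLOSUM62 are the standard ungapped values tabulated for those
matrices; because the alignments themselves are gapped, reported E-values
are a documented approximation, suitable for ranking hits rather than for
rigorous significance claims.

Substitution matrices are loaded through Biopython: the bundled names
(BLOSUM50, the default, and BLOSUM62) plus any file in NCBI matrix text
format.  The dynamic programming fill and traceback are JIT-compiled with
numba; scores are exact integers.

Determinism: among equal-scoring alignments the one with the smallest
query start, then smallest subject start, then fewest columns is returned.
Candidate end cells are enumerated from the score matrix and each is traced
back with a fixed move preference (match/mismatch, then gap in subject,
then gap in query), so repeated runs always produce the same alignment.

The ambiguity letter X scores whatever the matrix assigns it but never
counts as an identity, even against another X, so masked regions cannot
inflate percent identity.
"""
from __future__ import annotations

import math
import os
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numba import njit
from Bio.Align import substitution_matrices

from .errors import AlignmentError, ConfigError

#: Ungapped Karlin–Altschul parameters (lambda, K) per substitution matrix.
KARLIN_ALTSCHUL = {
    "BLOSUM50": (0.232, 0.112),
    "BLOSUM62": (0.318, 0.134),
}

GAP = "-"


@dataclass(frozen=True)
class AlignParams:
    """Scoring parameters for local alignment and E-value estimation.

    ``gap_open`` is the score of the first column of a gap and
    ``gap_extend`` of each subsequent column; both are negative and
    ``gap_open <= gap_extend`` (opening is at least as expensive).
    """

    matrix_name: str = "BLOSUM50"
    gap_open: int = -10
    gap_extend: int = -2
    ka_lambda: float = 0.232
    ka_k: float = 0.112

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend < 0):
            raise ConfigError(
                f"require gap_open <= gap_extend < 0, got "
                f"open={self.gap_open}, extend={self.gap_extend}"
            )
        if self.ka_lambda <= 0 or self.ka_k <= 0:
            raise ConfigError("Karlin–Altschul lambda and K must be positive")

    @classmethod
    def for_matrix(cls, matrix_name: str, **kwargs) -> "AlignParams":
        """Parameters with the tabulated (lambda, K) for a bundled matrix."""
        if matrix_name not in KARLIN_ALTSCHUL:
            raise ConfigError(
                f"no tabulated Karlin–Altschul parameters for {matrix_name!r}; "
                "pass ka_lambda and ka_k explicitly"
            )
        lam, k = KARLIN_ALTSCHUL[matrix_name]
        return cls(matrix_name=matrix_name, ka_lambda=lam, ka_k=k, **kwargs)


@dataclass(frozen=True)
class SWStats:
    """Coordinates and identity counts of one optimal local alignment."""

    score: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    n_identities: int
    n_columns: int

    @property
    def identity_fraction(self) -> float:
        return self.n_identities / self.n_columns if self.n_columns else 0.0

    @property
    def is_empty(self) -> bool:
        return self.n_columns == 0


@dataclass
class LocalAlignment:
    """A scored local alignment with explicit columns.

    Coordinates are 1-based inclusive; ``columns`` pairs residues with the
    gap symbol ``-`` on at most one side.  An empty alignment (score 0,
    no columns) means the sequences share no positively scoring local
    similarity.
    """

    score: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    columns: list[tuple[str, str]]
    n_identities: int
    n_columns: int

    @property
    def identity_fraction(self) -> float:
        return self.n_identities / self.n_columns if self.n_columns else 0.0

    @property
    def is_empty(self) -> bool:
        """True when no similarity was found (best local score is 0)."""
        return self.n_columns == 0


@lru_cache(maxsize=8)
def load_matrix(name_or_path: str):
    """Load a substitution matrix by bundled name or NCBI-format file path."""
    if name_or_path in substitution_matrices.load():
        return substitution_matrices.load(name_or_path)
    if os.path.exists(name_or_path):
        return substitution_matrices.read(name_or_path)
    raise ConfigError(
        f"unknown substitution matrix {name_or_path!r}: not a bundled name "
        "and not a readable file"
    )


@lru_cache(maxsize=8)
def _prepared(name_or_path: str):
    """(alphabet, int32 score matrix, ASCII lookup table, X code) for a matrix."""
    m = load_matrix(name_or_path)
    alphabet = str(m.alphabet)
    scores = np.rint(np.asarray(m)).astype(np.int32)
    lut = np.full(128, -1, dtype=np.int64)
    for i, ch in enumerate(alphabet):
        lut[ord(ch)] = i
    x_code = alphabet.index("X") if "X" in alphabet else -1
    return alphabet, scores, lut, x_code


_NEG = -(1 << 28)


@njit(cache=False)
def _trace(Hp, Ep, Fp, q, s, i, j, x_code, qpath, spath, record):
    """Walk one traceback path; returns (q_start, s_start, n_columns, n_identities).

    With ``record`` set, fills ``qpath``/``spath`` (residue codes, -1 for a
    gap) from the end of the arrays backwards; the arrays must already have
    the path length.
    """
    state = 0  # 0 = match state, 1 = gap in subject (up), 2 = gap in query (left)
    ncols = 0
    nid = 0
    k = qpath.shape[0] - 1
    while True:
        if state == 0:
            p = Hp[i, j]
            if p == 0:
                break
            if p == 1:
                qi = q[i - 1]
                sj = s[j - 1]
                if qi == sj and qi != x_code:
                    nid += 1
                if record:
                    qpath[k] = qi
                    spath[k] = sj
                    k -= 1
                ncols += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            opened = Fp[i, j] == 0
            if record:
                qpath[k] = q[i - 1]
                spath[k] = -1
                k -= 1
            ncols += 1
            i -= 1
            if opened:
                state = 0
        else:
            opened = Ep[i, j] == 0
            if record:
                qpath[k] = -1
                spath[k] = s[j - 1]
                k -= 1
            ncols += 1
            j -= 1
            if opened:
                state = 0
    return i + 1, j + 1, ncols, nid


@njit(cache=False)
def _sw_core(q, s, mat, gap_open, gap_extend, x_code):
    """Affine-gap Smith–Waterman (Gotoh) with deterministic traceback.

    Returns (score, q_start, q_end, s_start, s_end, n_identities,
    n_columns, qpath, spath); coordinates are 1-based inclusive and all
    zero for an empty alignment.
    """
    m = q.shape[0]
    n = s.shape[0]
    H = np.zeros((m + 1, n + 1), np.int32)
    E = np.full((m + 1, n + 1), _NEG, np.int32)
    F = np.full((m + 1, n + 1), _NEG, np.int32)
    Hp = np.zeros((m + 1, n + 1), np.uint8)
    Ep = np.zeros((m + 1, n + 1), np.uint8)
    Fp = np.zeros((m + 1, n + 1), np.uint8)
    best = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            eo = H[i, j - 1] + gap_open
            ee = E[i, j - 1] + gap_extend
            if ee > eo:
                E[i, j] = ee
                Ep[i, j] = 1
            else:
                E[i, j] = eo
            fo = H[i - 1, j] + gap_open
            fe = F[i - 1, j] + gap_extend
            if fe > fo:
                F[i, j] = fe
                Fp[i, j] = 1
            else:
                F[i, j] = fo
            hv = H[i - 1, j - 1] + mat[qi, s[j - 1]]
            pv = 1
            if F[i, j] > hv:
                hv = F[i, j]
                pv = 2
            if E[i, j] > hv:
                hv = E[i, j]
                pv = 3
            if hv <= 0:
                hv = 0
                pv = 0
            H[i, j] = hv
            Hp[i, j] = pv
            if hv > best:
                best = int(hv)

    empty = np.empty(0, np.int64)
    if best == 0:
        return 0, 0, 0, 0, 0, 0, 0, empty, empty

    big = 1 << 30
    bqs = big
    bss = big
    blen = big
    bnid = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            if H[i, j] == best:
                qs, ss, ncols, nid = _trace(Hp, Ep, Fp, q, s, i, j, x_code, empty, empty, 0)
                if qs < bqs or (
                    qs == bqs and (ss < bss or (ss == bss and ncols < blen))
                ):
                    bqs, bss, blen, bnid, bi, bj = qs, ss, ncols, nid, i, j

    qpath = np.empty(blen, np.int64)
    spath = np.empty(blen, np.int64)
    _trace(Hp, Ep, Fp, q, s, bi, bj, x_code, qpath, spath, 1)
    return best, bqs, bi, bss, bj, bnid, blen, qpath, spath


class Aligner:
    """Reusable Smith–Waterman aligner bound to one parameter set.

    Encoding sequences once via :meth:`encode` and passing the integer
    arrays to :meth:`stats` avoids re-translating database entries when
    scanning many windows.
    """

    def __init__(self, params: AlignParams | None = None):
        self.params = params or AlignParams()
        self.alphabet, self._mat, self._lut, self._x = _prepared(self.params.matrix_name)

    def encode(self, seq: str) -> np.ndarray:
        if not seq:
            raise AlignmentError("cannot align an empty sequence")
        try:
            raw = np.frombuffer(seq.encode("ascii"), np.uint8).astype(np.int64)
        except UnicodeEncodeError as exc:
            raise AlignmentError(f"non-ASCII character in sequence: {exc}") from exc
        codes = self._lut[raw]
        if codes.min() < 0:
            bad = seq[int(np.argmin(codes >= 0))]
            raise AlignmentError(
                f"residue {bad!r} absent from matrix {self.params.matrix_name}"
            )
        return codes

    def _as_codes(self, seq) -> np.ndarray:
        return seq if isinstance(seq, np.ndarray) else self.encode(seq)

    def stats(self, query, subject) -> SWStats:
        """Score/coordinates/identities of the optimal local alignment.

        Accepts residue strings or arrays pre-encoded with :meth:`encode`.
        """
        q = self._as_codes(query)
        s = self._as_codes(subject)
        score, qs, qe, ss, se, nid, ncols, _, _ = _sw_core(
            q, s, self._mat, self.params.gap_open, self.params.gap_extend, self._x
        )
        return SWStats(int(score), qs, qe, ss, se, nid, ncols)

    def align(self, query, subject) -> LocalAlignment:
        """Full optimal local alignment with explicit columns."""
        q = self._as_codes(query)
        s = self._as_codes(subject)
        score, qs, qe, ss, se, nid, ncols, qpath, spath = _sw_core(
            q, s, self._mat, self.params.gap_open, self.params.gap_extend, self._x
        )
        ab = self.alphabet
        columns = [
            (ab[qc] if qc >= 0 else GAP, ab[sc] if sc >= 0 else GAP)
            for qc, sc in zip(qpath.tolist(), spath.tolist())
        ]
        return LocalAlignment(int(score), qs, qe, ss, se, columns, nid, ncols)


def smith_waterman(
    query: str, subject: str, params: AlignParams | None = None
) -> LocalAlignment:
    """Optimal affine-gap local alignment of two residue strings.

    If the best local score is 0 (no similarity under the matrix) an empty
    alignment is returned.  Empty input sequences or residues absent from
    the matrix raise :class:`AlignmentError`.
    """
    return Aligner(params).align(query, subject)


def percent_identity(aln: LocalAlignment | SWStats) -> float:
    """Identity fraction of an alignment: identities / all columns.

    Gap columns count in the denominator and never in the numerator;
    undefined (raises) for an empty alignment.
    """
    if aln.n_columns == 0:
        raise AlignmentError("percent identity is undefined for an empty alignment")
    return aln.n_identities / aln.n_columns


def evalue(
    score: int, query_len: int, db_residues: int, params: AlignParams | None = None
) -> float:
    """Ungapped Karlin–Altschul E-value: K * m * n * exp(-lambda * S)."""
    params = params or AlignParams()
    if query_len <= 0 or db_residues <= 0:
        raise AlignmentError("query_len and db_residues must be positive")
    return params.ka_k * query_len * db_residues * math.exp(-params.ka_lambda * score)
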