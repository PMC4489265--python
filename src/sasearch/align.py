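"""Banded local alignment and Karlin–Altschul significance statistics.

Candidates retrieved by suffix voting are re-scored with a Smith–Waterman
style local alignment restricted to a diagonal band around the winning
vote diagonal, and the expected number of chance hits at that score is

    E = K * m * n * exp(-lambda * S)

with m the query length, n the total residue count of the database and
(lambda, K) the Karlin–Altschul constants of the scoring scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from . import _kernels
from .db import ALPHABET, encode

GAP = "-"

#: BLAST-compatible gapped defaults per bundled matrix:
#: (gap_open, gap_extend, lambda, K)
BUNDLED_MATRICES = {
    "BLOSUM62": (11, 1, 0.267, 0.041),
    "BLOSUM45": (14, 2, 0.195, 0.0325),
    "BLOSUM80": (10, 1, 0.299, 0.071),
}


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix over the 21-letter alphabet plus gap penalties
    and the Karlin–Altschul ``(lambda, K)`` pair valid for them."""

    name: str
    matrix: np.ndarray      # int32, 21 x 21, indexed by ALPHABET order
    gap_open: int
    gap_extend: int
    lam: float              # per score unit
    K: float

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(ALPHABET), len(ALPHABET)):
            raise ValueError("matrix must cover the 20 residues plus X")
        if not np.array_equal(m, m.T):
            raise ValueError("substitution matrix must be symmetric")
        if not (self.gap_open >= self.gap_extend >= 1):
            raise ValueError("require gap_open >= gap_extend >= 1")
        if not (self.lam > 0 and self.K > 0):
            raise ValueError("lambda and K must be positive")

    def score(self, a: str, b: str) -> int:
        """Substitution score of residue pair (a, b)."""
        return int(self.matrix[ALPHABET.index(a), ALPHABET.index(b)])


def _subset_matrix(arr: substitution_matrices.Array) -> np.ndarray:
    letters = arr.alphabet
    missing = [c for c in ALPHABET if c not in letters]
    if missing:
        raise ValueError(f"matrix is missing residue {missing[0]!r}")
    out = np.empty((len(ALPHABET), len(ALPHABET)), dtype=np.int32)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            out[i, j] = int(arr[a, b])
    return out


def load_matrix(
    name_or_path: str | Path,
    *,
    gap_open: int | None = None,
    gap_extend: int | None = None,
    lam: float | None = None,
    K: float | None = None,
) -> ScoringScheme:
    """Load a bundled matrix by name or an NCBI-format matrix file.

    Bundled names (BLOSUM62, BLOSUM45, BLOSUM80) come with BLAST's default
    gap penalties and the matching published gapped Karlin–Altschul
    constants; any of these may be overridden.  A custom matrix file must
    be accompanied by explicit ``lam`` and ``K`` (there is no universal
    default for an arbitrary matrix).
    """
    name = str(name_or_path)
    if name.upper() in BUNDLED_MATRICES:
        name = name.upper()
        d_open, d_ext, d_lam, d_k = BUNDLED_MATRICES[name]
        arr = substitution_matrices.load(name)
        return ScoringScheme(
            name=name,
            matrix=_subset_matrix(arr),
            gap_open=d_open if gap_open is None else gap_open,
            gap_extend=d_ext if gap_extend is None else gap_extend,
            lam=d_lam if lam is None else lam,
            K=d_k if K is None else K,
        )
    path = Path(name_or_path)
    if not path.exists():
        raise FileNotFoundError(f"no bundled matrix or file named {name_or_path!r}")
    if lam is None or K is None:
        raise ValueError(
            "custom matrices carry no Karlin-Altschul constants: "
            "lambda and K must be supplied in the configuration"
        )
    arr = substitution_matrices.read(str(path))
    return ScoringScheme(
        name=path.stem,
        matrix=_subset_matrix(arr),
        gap_open=11 if gap_open is None else gap_open,
        gap_extend=1 if gap_extend is None else gap_extend,
        lam=lam,
        K=K,
    )


_DEFAULT_SCHEME: ScoringScheme | None = None


def default_scheme() -> ScoringScheme:
    """The package default: BLOSUM62, gap open 11, gap extend 1."""
    global _DEFAULT_SCHEME
    if _DEFAULT_SCHEME is None:
        _DEFAULT_SCHEME = load_matrix("BLOSUM62")
    return _DEFAULT_SCHEME


@dataclass
class Alignment:
    """A gapped local alignment in matrix score units.

    Intervals are 0-based half-open over the ungapped sequences; identity
    is identical columns divided by all aligned columns.
    """

    score: int
    query_aligned: str
    target_aligned: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    identity: float

    @property
    def n_columns(self) -> int:
        return len(self.query_aligned)


def _empty_alignment() -> Alignment:
    return Alignment(0, "", "", 0, 0, 0, 0, 0.0)


def _identity(aq: str, at: str) -> float:
    if not aq:
        return 0.0
    matches = sum(1 for a, b in zip(aq, at) if a == b and a != GAP)
    return matches / len(aq)


def banded_align(
    query: str | np.ndarray,
    target: str | np.ndarray,
    center_diagonal: int,
    half_band: int,
    scheme: ScoringScheme | None = None,
) -> Alignment:
    """Local alignment restricted to ``|
    (q_pos - t_pos) - center_diagonal| <= half_band``.

    Optimal within the band; with a band covering the whole matrix this is
    plain Smith–Waterman.  Traceback ties prefer diagonal over up (gap in
    target) over left (gap in query).  A band that excludes the entire
    matrix yields the empty zero-score alignment.
    """
    if scheme is None:
        scheme = default_scheme()
    if half_band < 1:
        raise ValueError("half_band must be >= 1")
    q = encode(query) if isinstance(query, str) else query
    t = encode(target) if isinstance(target, str) else target
    if len(q) == 0 or len(t) == 0:
        raise ValueError("sequences must be non-empty")
    # cell diagonals span [1 - len(t), len(q) - 1]
    if center_diagonal - half_band > len(q) - 1 or center_diagonal + half_band < 1 - len(t):
        return _empty_alignment()

    score, bi, bj, ph, pe, pf = _kernels.banded_sw(
        q, t, scheme.matrix, scheme.gap_open, scheme.gap_extend,
        center_diagonal, half_band,
    )
    score = int(score)
    if score <= 0:
        return _empty_alignment()

    qs = str(query) if isinstance(query, str) else None
    ts = str(target) if isinstance(target, str) else None
    from .db import decode
    if qs is None:
        qs = decode(q)
    if ts is None:
        ts = decode(t)

    aq: list[str] = []
    at: list[str] = []
    i, j = int(bi), int(bj)
    state = "H"
    while True:
        if state == "H":
            move = ph[i, j]
            if move == _kernels.STOP:
                break
            if move == _kernels.DIAG:
                aq.append(qs[i - 1])
                at.append(ts[j - 1])
                i -= 1
                j -= 1
            elif move == _kernels.UP:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            opened = pf[i, j]
            aq.append(qs[i - 1])
            at.append(GAP)
            i -= 1
            state = "H" if opened else "F"
        else:  # E
            opened = pe[i, j]
            aq.append(GAP)
            at.append(ts[j - 1])
            j -= 1
            state = "H" if opened else "E"
    aq.reverse()
    at.reverse()
    a_q = "".join(aq)
    a_t = "".join(at)
    return Alignment(
        score=score,
        query_aligned=a_q,
        target_aligned=a_t,
        q_start=i,
        q_end=int(bi),
        t_start=j,
        t_end=int(bj),
        identity=_identity(a_q, a_t),
    )


def smith_waterman_score(
    query: str | np.ndarray,
    target: str | np.ndarray,
    scheme: ScoringScheme | None = None,
) -> int:
    """Unbanded Smith–Waterman score (no traceback); used for exhaustive
    reference-set construction."""
    if scheme is None:
        scheme = default_scheme()
    q = encode(query) if isinstance(query, str) else query
    t = encode(target) if isinstance(target, str) else target
    return int(_kernels.sw_score(q, t, scheme.matrix, scheme.gap_open,
                                 scheme.gap_extend))


def score_alignment(query_aligned: str, target_aligned: str,
                    scheme: ScoringScheme | None = None) -> int:
    """Re-score a gapped alignment under affine gap penalties.

    A gap run of length k costs gap_open + k * gap_extend.
    """
    if scheme is None:
        scheme = default_scheme()
    if len(query_aligned) != len(target_aligned):
        raise ValueError("aligned strings must have equal length")
    total = 0
    in_gap_q = in_gap_t = False
    for a, b in zip(query_aligned, target_aligned):
        if a == GAP and b == GAP:
            raise ValueError("double-gap column")
        if a == GAP:
            total -= scheme.gap_extend + (0 if in_gap_q else scheme.gap_open)
            in_gap_q, in_gap_t = True, False
        elif b == GAP:
            total -= scheme.gap_extend + (0 if in_gap_t else scheme.gap_open)
            in_gap_q, in_gap_t = False, True
        else:
            total += scheme.score(a, b)
            in_gap_q = in_gap_t = False
    return total


def evalue(score: float, m: int, n: int, scheme: ScoringScheme | None = None) -> float:
    """Karlin–Altschul expected number of chance hits scoring >= ``score``:
    ``K * m * n * exp(-lambda * score)``."""
    if scheme is None:
        scheme = default_scheme()
    if m < 1 or n < 1:
        raise ValueError("m and n must be >= 1")
    if score < 0:
        raise ValueError("score must be >= 0")
    return scheme.K * m * n * math.exp(-scheme.lam * score)
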