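"""Suffix-array neighborhood search: voting, candidate selection, modes.

For every suffix of the query we binary-search its insertion position in
the database suffix array and inspect the ``W`` lexicographic neighbors on
each side.  A neighbor whose longest common prefix with the query suffix
is at least ``min_match`` residues casts one vote for its protein on the
diagonal band containing ``query_pos - target_pos``.  Banding the votes
(rather than summing per protein) confines evidence to one alignment
register, the same selectivity idea FASTA's best-diagonal statistic uses.

Four search protocols trade depth for speed:

* ``verifast`` — report the H highest-vote proteins; no alignments.
* ``fast``     — align the H highest-vote proteins, resort by score.
* ``slow``     — align the 2H highest-vote proteins, resort by score.
* ``verislow`` — align up to 4000 highest-vote proteins, resort by score.

Aligning modes report only hits with e-value below the cutoff (default 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .align import Alignment, ScoringScheme, banded_align, default_scheme, evalue
from .db import (
    KEY_BITS,
    KEY_LEN,
    ProteinDatabase,
    ProteinRecord,
    SuffixArray,
    encode,
    pack_query_keys,
)

logger = logging.getLogger(__name__)

MODES = ("verifast", "fast", "slow", "verislow")

#: Verislow candidate-pool ceiling.
VERISLOW_POOL = 4000

#: Minimum best-band vote for a protein to be reported in verifast mode.
#: Calibrated on the default synthetic benchmark as the smallest threshold
#: whose decoy (chance-protein) share of reported hits is at most 2%; see
#: scripts/calibrate_vote_threshold.py for the calibration sweep.
VERIFAST_VOTE_THRESHOLD = 3


@dataclass
class SearchParams:
    """Tunable knobs of one search.

    window is the number of suffix-array neighbors inspected on *each*
    side of an insertion position; min_match the minimum common-prefix
    length for a vote; band_width the diagonal-band granularity in
    residues; half_band the half-width of the alignment band.
    """

    mode: str = "fast"
    H: int = 50
    window: int = 16
    min_match: int = 6
    band_width: int = 16
    vote_threshold: int = VERIFAST_VOTE_THRESHOLD
    evalue_cutoff: float = 1.0
    stable_h: bool = False
    stable_patience: int | None = None  # defaults to H
    half_band: int = 32
    scheme: ScoringScheme | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown search mode {self.mode!r}; choose from {MODES}")
        if self.H < 1:
            raise ValueError("H must be >= 1")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.min_match < 1:
            raise ValueError("min_match must be >= 1")
        if self.band_width < 1:
            raise ValueError("band_width must be >= 1")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be > 0")
        if self.half_band < 1:
            raise ValueError("half_band must be >= 1")

    @property
    def patience(self) -> int:
        return self.H if self.stable_patience is None else self.stable_patience

    def resolved_scheme(self) -> ScoringScheme:
        return self.scheme if self.scheme is not None else default_scheme()

    def with_mode(self, mode: str) -> "SearchParams":
        return replace(self, mode=mode)


class VoteTable:
    """Sparse (protein, diagonal band) -> vote accumulator for one query.

    A protein's vote is the *maximum* over its bands, and its winning band
    is the band attaining that maximum (lowest band index on ties).
    """

    def __init__(self, counts: dict[tuple[int, int], int] | None = None):
        self.counts: dict[tuple[int, int], int] = counts or {}
        self.protein_votes: dict[int, int] = {}
        self.best_band: dict[int, int] = {}
        for (prot, band) in sorted(self.counts):
            c = self.counts[(prot, band)]
            if c > self.protein_votes.get(prot, 0):
                self.protein_votes[prot] = c
                self.best_band[prot] = band

    def __len__(self) -> int:
        return len(self.counts)

    def vote_of(self, protein: int) -> int:
        return self.protein_votes.get(protein, 0)

    @property
    def n_voted_proteins(self) -> int:
        return len(self.protein_votes)


def _empty_votes() -> VoteTable:
    return VoteTable({})


def _refine_insertions(
    ins: np.ndarray,
    qcodes: np.ndarray,
    qkeys: np.ndarray,
    sa: SuffixArray,
    db: ProteinDatabase,
) -> None:
    """Correct key-based insertion positions for query suffixes longer than
    KEY_LEN that tie with database suffixes on the full packed key."""
    n = len(sa)
    text = db.text_bytes
    pos = sa.positions
    keys = sa.keys
    L = len(qcodes)
    for u in range(len(ins)):
        if L - u <= KEY_LEN:
            continue  # key determines order exactly for short suffixes
        i = int(ins[u])
        if i >= n or keys[i] != qkeys[u]:
            continue
        qb = qcodes[u:].tobytes()
        m = len(qb)
        lo = i
        hi = int(np.searchsorted(keys, qkeys[u], side="right"))
        while lo < hi:
            mid = (lo + hi) // 2
            p = int(pos[mid])
            if text[p:p + m] >= qb:
                hi = mid
            else:
                lo = mid + 1
        ins[u] = lo


def vote(
    query: ProteinRecord,
    sa: SuffixArray,
    db: ProteinDatabase,
    params: SearchParams,
) -> VoteTable:
    """Accumulate diagonal-band votes for every suffix of ``query``.

    Each query suffix contributes at most one vote per (protein, band)
    pair, so a repeated query substring cannot inflate a single band.
    """
    qcodes = encode(query.sequence)
    L = len(qcodes)
    if L < params.min_match:
        logger.warning(
            "query %s shorter than min_match (%d < %d): no votes cast",
            query.id, L, params.min_match,
        )
        return _empty_votes()

    qkeys = pack_query_keys(qcodes)
    n_pos = L - params.min_match + 1  # suffixes long enough to vote
    ins = np.searchsorted(sa.keys, qkeys[:n_pos], side="left").astype(np.int64)
    _refine_insertions(ins, qcodes, qkeys, sa, db)

    W = params.window
    nsa = len(sa)
    offs = np.arange(-W, W, dtype=np.int64)          # window [i - W, i + W)
    idx = ins[:, None] + offs[None, :]
    valid = (idx >= 0) & (idx < nsa)
    idx_c = np.clip(idx, 0, nsa - 1)
    skeys = sa.keys[idx_c]

    mm = params.min_match
    if mm <= KEY_LEN:
        shift = np.uint64(KEY_BITS * (KEY_LEN - mm))
        match = (skeys >> shift) == (qkeys[:n_pos, None] >> shift)
    else:
        match = skeys == qkeys[:n_pos, None]
    match &= valid

    uu, ww = np.nonzero(match)
    if len(uu) == 0:
        return _empty_votes()
    sa_idx = idx_c[uu, ww]
    tpos = sa.positions[sa_idx]

    if mm > KEY_LEN:
        # keys only certify a common prefix of KEY_LEN; extend exactly
        text = db.text_bytes
        keep = np.ones(len(uu), dtype=bool)
        for k in range(len(uu)):
            u = int(uu[k])
            p = int(tpos[k])
            if text[p:p + mm] != qcodes[u:u + mm].tobytes():
                keep[k] = False
        uu, tpos = uu[keep], tpos[keep]
        if len(uu) == 0:
            return _empty_votes()

    prot = db.protein_of[tpos].astype(np.int64)
    toff = tpos - db.offsets[prot]
    diag = uu - toff
    band = np.floor_divide(diag, params.band_width)

    bmin = int(band.min())
    nb = int(band.max()) - bmin + 1
    P = db.n_proteins
    triple = (uu * P + prot) * nb + (band - bmin)
    triple = np.unique(triple)           # one vote per (query pos, protein, band)
    pair = triple % (P * nb)
    pairs, cnt = np.unique(pair, return_counts=True)
    counts = {
        (int(p // nb), int(p % nb) + bmin): int(c)
        for p, c in zip(pairs, cnt)
    }
    return VoteTable(counts)


def select_candidates(votes: VoteTable, params: SearchParams) -> list[int]:
    """Vote-ranked candidate proteins, truncated by mode.

    Sorted by best-band vote descending, ties by ascending protein index;
    pool depth is H (verifast, fast), 2H (slow) or min(4000, voted)
    (verislow); verifast additionally drops proteins below the vote
    threshold.
    """
    ranked = sorted(votes.protein_votes.items(), key=lambda kv: (-kv[1], kv[0]))
    if params.mode == "verifast":
        ranked = [(p, v) for p, v in ranked if v >= params.vote_threshold]
        depth = params.H
    elif params.mode == "fast":
        depth = params.H
    elif params.mode == "slow":
        depth = 2 * params.H
    else:  # verislow
        depth = min(VERISLOW_POOL, len(ranked))
    return [p for p, _ in ranked[:depth]]


@dataclass
class Hit:
    """One reported query-protein match."""

    query_id: str
    protein_index: int
    protein_id: str
    vote: int
    band: int
    score: int | None = None
    evalue: float | None = None
    identity: float | None = None
    q_start: int | None = None   # 0-based half-open intervals
    q_end: int | None = None
    t_start: int | None = None
    t_end: int | None = None
    query_aligned: str | None = None
    target_aligned: str | None = None
    target_sequence: str | None = None

    @property
    def has_alignment(self) -> bool:
        return self.query_aligned is not None


def _band_center(band: int, band_width: int) -> int:
    return band * band_width + band_width // 2


def _align_candidate(
    query: ProteinRecord,
    prot: int,
    votes: VoteTable,
    db: ProteinDatabase,
    params: SearchParams,
    scheme: ScoringScheme,
) -> Hit:
    target = db.sequence(prot)
    band = votes.best_band[prot]
    aln = banded_align(
        query.sequence, target,
        center_diagonal=_band_center(band, params.band_width),
        half_band=params.half_band, scheme=scheme,
    )
    e = evalue(aln.score, len(query.sequence), db.n_residues, scheme)
    return Hit(
        query_id=query.id,
        protein_index=prot,
        protein_id=db.ids[prot],
        vote=votes.vote_of(prot),
        band=band,
        score=aln.score,
        evalue=e,
        identity=aln.identity,
        q_start=aln.q_start,
        q_end=aln.q_end,
        t_start=aln.t_start,
        t_end=aln.t_end,
        query_aligned=aln.query_aligned,
        target_aligned=aln.target_aligned,
        target_sequence=target,
    )


def search(
    query: ProteinRecord,
    index: tuple[ProteinDatabase, SuffixArray],
    params: SearchParams | None = None,
) -> list[Hit]:
    """Run one query against an index and return ranked hits.

    verifast hits carry only vote information; all other modes align their
    candidate pool, sort by score descending (ties: e-value ascending,
    then protein index), drop hits at or above the e-value cutoff and
    truncate to H.  With ``stable_h`` the vote-ranked list is walked until
    ``stable_patience`` consecutive extra alignments leave the H-th best
    score unchanged.
    """
    db, sa = index
    if params is None:
        params = SearchParams()
    votes = vote(query, sa, db, params)

    if params.mode == "verifast":
        return [
            Hit(
                query_id=query.id,
                protein_index=p,
                protein_id=db.ids[p],
                vote=votes.vote_of(p),
                band=votes.best_band[p],
                target_sequence=db.sequence(p),
            )
            for p in select_candidates(votes, params)
        ]

    scheme = params.resolved_scheme()
    if params.stable_h:
        ranked = sorted(votes.protein_votes.items(), key=lambda kv: (-kv[1], kv[0]))
        hits: list[Hit] = []
        scores: list[int] = []
        streak = 0
        for prot, _v in ranked:
            hit = _align_candidate(query, prot, votes, db, params, scheme)
            hits.append(hit)
            scores.append(hit.score)
            if len(scores) > params.H:
                hth_before = sorted(scores[:-1], reverse=True)[params.H - 1]
                hth_after = sorted(scores, reverse=True)[params.H - 1]
                streak = streak + 1 if hth_after == hth_before else 0
                if streak >= params.patience:
                    break
    else:
        hits = [
            _align_candidate(query, prot, votes, db, params, scheme)
            for prot in select_candidates(votes, params)
        ]

    hits.sort(key=lambda h: (-h.score, h.evalue, h.protein_index))
    hits = [h for h in hits if h.evalue < params.evalue_cutoff]
    return hits[: params.H]


def search_many(
    queries: list[ProteinRecord],
    index: tuple[ProteinDatabase, SuffixArray],
    params: SearchParams | None = None,
) -> dict[str, list[Hit]]:
    """Run queries sequentially in input order; returns hits keyed by query id."""
    return {q.id: search(q, index, params) for q in queries}
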