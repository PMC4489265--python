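"""Seeded synthetic benchmarks: decoy databases with implanted homologs.

The generator emulates the classic sensitivity-benchmark design for
database-search tools: a database of unrelated random proteins (decoys)
plus homologs of known percent identity implanted at controlled amounts,
with the query set being the homologs' parents.  The reference ("TRUE")
set is built by exhaustive unbanded Smith–Waterman of every query against
every database protein at a fixed e-value cutoff, and recall is reported
per identity bin of the implanted pair.

Everything is a pure function of (spec, seed): two runs with the same
seed produce byte-identical FASTA and metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .align import ScoringScheme, default_scheme, evalue
from .db import RESIDUES, ProteinDatabase, ProteinRecord, encode
from .search import Hit

#: Default identity bins: 10-point bins from 50% plus an exact-copy bin.
DEFAULT_BINS = (
    (0.5, 0.6), (0.6, 0.7), (0.7, 0.8), (0.8, 0.9), (0.9, 1.0), (1.0, 1.0),
)

METADATA_COLUMNS = (
    "query_id", "hit_id", "bin_low", "bin_high",
    "target_identity", "realized_identity", "length",
)


@dataclass
class BenchmarkSpec:
    """Composition of one synthetic benchmark.

    Decoy lengths are uniform over ``decoy_length``; the residue
    background is uniform over the 20 letters unless given.  Bins are
    ``[low, high)`` intervals of target identity (a degenerate
    ``(x, x)`` bin means exact copies).
    """

    n_decoys: int = 1000
    decoy_length: tuple[int, int] = (100, 400)
    bins: tuple[tuple[float, float], ...] = DEFAULT_BINS
    homologs_per_bin: int = 50
    seed: int = 42
    background: np.ndarray | None = None
    indels: bool = False

    def __post_init__(self) -> None:
        if self.n_decoys < 0 or self.homologs_per_bin < 0:
            raise ValueError("counts must be >= 0")
        lo, hi = self.decoy_length
        if not (1 <= lo <= hi):
            raise ValueError("decoy_length must satisfy 1 <= min <= max")
        for low, high in self.bins:
            if not (0.0 < low <= high <= 1.0):
                raise ValueError(f"identity bin ({low}, {high}) outside (0, 1]")

    def resolved_background(self) -> np.ndarray:
        if self.background is None:
            return np.full(len(RESIDUES), 1.0 / len(RESIDUES))
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (len(RESIDUES),) or bg.min() < 0 or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be 20 non-negative frequencies summing to 1")
        return bg


def random_protein(
    length: int,
    rng: np.random.Generator,
    background: np.ndarray | None = None,
) -> str:
    """An i.i.d. random protein over the 20-letter alphabet."""
    if length < 1:
        raise ValueError("protein length must be >= 1")
    if background is None:
        background = np.full(len(RESIDUES), 1.0 / len(RESIDUES))
    letters = rng.choice(len(RESIDUES), size=length, p=background)
    return "".join(RESIDUES[i] for i in letters)


def mutate_homolog(
    parent: str,
    target_identity: float,
    rng: np.random.Generator,
    background: np.ndarray | None = None,
) -> str:
    """Substitute residues so realized identity is exactly
    ``round(target_identity * len) / len``.

    Mutated positions are chosen without replacement; each substitution is
    drawn from the background excluding the original letter.
    """
    if not (0.0 <= target_identity <= 1.0):
        raise ValueError("target_identity must lie in [0, 1]")
    L = len(parent)
    n_keep = round(target_identity * L)
    n_sub = L - n_keep
    if n_sub == 0:
        return parent
    if background is None:
        background = np.full(len(RESIDUES), 1.0 / len(RESIDUES))
    positions = rng.choice(L, size=n_sub, replace=False)
    seq = list(parent)
    for p in positions:
        orig = RESIDUES.index(seq[p])
        probs = background.copy()
        probs[orig] = 0.0
        probs /= probs.sum()
        seq[p] = RESIDUES[rng.choice(len(RESIDUES), p=probs)]
    return "".join(seq)


def realized_identity(a: str, b: str) -> float:
    """Position-wise identity of two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x == y for x, y in zip(a, b)) / len(a)


@dataclass
class Benchmark:
    """Generated database records, query records and implant metadata."""

    spec: BenchmarkSpec
    database: list[ProteinRecord]
    queries: list[ProteinRecord]
    metadata: pd.DataFrame   # one row per implanted (query, homolog) pair


def generate_benchmark(spec: BenchmarkSpec) -> Benchmark:
    """Generate decoys + implanted homologs deterministically from the seed."""
    rng = np.random.default_rng(spec.seed)
    bg = spec.resolved_background()
    lo, hi = spec.decoy_length

    database: list[ProteinRecord] = []
    for k in range(spec.n_decoys):
        length = int(rng.integers(lo, hi + 1))
        database.append(
            ProteinRecord(id=f"decoy_{k + 1:05d}",
                          sequence=random_protein(length, rng, bg))
        )

    queries: list[ProteinRecord] = []
    rows: list[dict] = []
    for b, (blow, bhigh) in enumerate(spec.bins):
        for j in range(spec.homologs_per_bin):
            length = int(rng.integers(lo, hi + 1))
            parent = random_protein(length, rng, bg)
            if blow == bhigh:
                target = blow
            else:
                target = float(rng.uniform(blow, bhigh))
            homolog = mutate_homolog(parent, target, rng, bg)
            qid = f"query_b{b + 1}_{j + 1:03d}"
            hid = f"homolog_b{b + 1}_{j + 1:03d}"
            queries.append(ProteinRecord(id=qid, sequence=parent))
            database.append(ProteinRecord(id=hid, sequence=homolog))
            rows.append({
                "query_id": qid,
                "hit_id": hid,
                "bin_low": blow,
                "bin_high": bhigh,
                "target_identity": target,
                "realized_identity": realized_identity(parent, homolog),
                "length": length,
            })
    metadata = pd.DataFrame(rows, columns=list(METADATA_COLUMNS))
    return Benchmark(spec=spec, database=database, queries=queries,
                     metadata=metadata)


def build_true_set(
    queries: list[ProteinRecord],
    db: ProteinDatabase,
    scheme: ScoringScheme | None = None,
    evalue_cutoff: float = 1.0,
) -> dict[str, set[str]]:
    """Exhaustive full-DP reference set.

    Every query is aligned against every database protein with unbanded
    Smith–Waterman; pairs with e-value below the cutoff form the TRUE set.
    This plays the role a rigorous full-DP searcher plays in published
    sensitivity benchmarks.
    """
    if scheme is None:
        scheme = default_scheme()
    # score cutoff equivalent to the e-value cutoff, per query length
    starts = db.offsets.astype(np.int64)
    lengths = db.lengths.astype(np.int64)
    true_set: dict[str, set[str]] = {}
    for q in queries:
        qc = encode(q.sequence)
        scores = _kernels.sw_score_many(
            qc, db.codes, starts, lengths, scheme.matrix,
            scheme.gap_open, scheme.gap_extend,
        )
        evals = scheme.K * len(qc) * db.n_residues * np.exp(
            -scheme.lam * scores.astype(float)
        )
        hits = {db.ids[i] for i in np.nonzero(evals < evalue_cutoff)[0]}
        true_set[q.id] = hits
    return true_set


def recall_by_identity(
    hits: dict[str, list[Hit] | list[str] | set[str]],
    true_set: dict[str, set[str]],
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Per-bin recall of the implanted pairs that the TRUE set confirms.

    ``hits`` maps query id to reported hits (Hit objects or plain ids).
    Returns a table with one row per identity bin:
    (bin_low, bin_high, n_true, n_found, recall).
    """
    hit_ids: dict[str, set[str]] = {}
    for qid, hs in hits.items():
        ids = {h.protein_id if isinstance(h, Hit) else str(h) for h in hs}
        hit_ids[qid] = ids

    rows = []
    for (blow, bhigh), group in metadata.groupby(
        ["bin_low", "bin_high"], sort=True
    ):
        n_true = 0
        n_found = 0
        for _, rec in group.iterrows():
            qid, hid = rec["query_id"], rec["hit_id"]
            if hid in true_set.get(qid, set()):
                n_true += 1
                if hid in hit_ids.get(qid, set()):
                    n_found += 1
        rows.append({
            "bin_low": blow,
            "bin_high": bhigh,
            "n_true": n_true,
            "n_found": n_found,
            "recall": (n_found / n_true) if n_true else 0.0,
        })
    return pd.DataFrame(rows, columns=["bin_low", "bin_high", "n_true",
                                       "n_found", "recall"])
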