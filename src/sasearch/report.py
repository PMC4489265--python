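"""Render hit lists: TSV table, BLAST-like text report, FASTA, stacking.

Stacked alignments project every pairwise alignment onto query
coordinates: target residues aligned to a query column occupy that
column, deletions relative to the query appear as ``-``, and insertions
(target residues aligned to query gaps) are omitted, so every row has
exactly the query's length.  Omitted insertions are counted per row so
the information loss is visible downstream.

All writers are pure functions of their inputs; coordinates are 1-based
inclusive in human-readable output only.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import GAP, ScoringScheme, default_scheme
from .db import ProteinRecord
from .search import Hit

TSV_COLUMNS = (
    "query_id", "hit_id", "rank", "vote", "score", "evalue",
    "identity_pct", "q_start", "q_end", "t_start", "t_end",
)

_REPORT_WIDTH = 60


def _fmt_evalue(e: float) -> str:
    return f"{e:.2g}"


def _fmt_identity(identity: float) -> str:
    return f"{identity * 100:.1f}"


@dataclass
class StackedRow:
    id: str
    row: str                 # gapped string of exactly the query's length
    score: int | None
    evalue: float | None
    identity: float | None
    insertions: int          # target residues omitted (aligned to query gaps)


@dataclass
class StackedAlignment:
    query_id: str
    query_sequence: str
    rows: list[StackedRow]


def _require_alignments(hits: list[Hit]) -> None:
    for h in hits:
        if not h.has_alignment:
            raise ValueError(
                f"hit {h.protein_id!r} carries no alignment "
                "(verifast mode computes none); rerun in an aligning mode"
            )


def stack_alignments(query: ProteinRecord, hits: list[Hit]) -> StackedAlignment:
    """Project each hit's pairwise alignment onto the query sequence."""
    _require_alignments(hits)
    L = len(query.sequence)
    rows: list[StackedRow] = []
    for h in hits:
        row = [GAP] * L
        qi = h.q_start
        insertions = 0
        for qc, tc in zip(h.query_aligned, h.target_aligned):
            if qc == GAP:
                insertions += 1       # insertion relative to query: omitted
                continue
            row[qi] = tc              # residue or '-' for a deletion
            qi += 1
        rows.append(
            StackedRow(
                id=h.protein_id,
                row="".join(row),
                score=h.score,
                evalue=h.evalue,
                identity=h.identity,
                insertions=insertions,
            )
        )
    return StackedAlignment(
        query_id=query.id, query_sequence=query.sequence, rows=rows
    )


def write_tabular(hits: list[Hit]) -> str:
    """Tab-separated hit table; alignment fields are empty for verifast
    hits.  Coordinates are 1-based inclusive."""
    lines = ["\t".join(TSV_COLUMNS)]
    for rank, h in enumerate(hits, start=1):
        if h.has_alignment:
            fields = [
                h.query_id, h.protein_id, str(rank), str(h.vote),
                str(h.score), _fmt_evalue(h.evalue), _fmt_identity(h.identity),
                str(h.q_start + 1), str(h.q_end), str(h.t_start + 1), str(h.t_end),
            ]
        else:
            fields = [h.query_id, h.protein_id, str(rank), str(h.vote),
                      "", "", "", "", "", "", ""]
        lines.append("\t".join(fields))
    return "\n".join(lines) + "\n"


def _midline(qc: str, tc: str, scheme: ScoringScheme) -> str:
    if qc == GAP or tc == GAP:
        return " "
    if qc == tc:
        return qc
    return "+" if scheme.score(qc, tc) > 0 else " "


def write_report(
    query: ProteinRecord,
    hits: list[Hit],
    scheme: ScoringScheme | None = None,
) -> str:
    """BLAST-like plain-text report: header, one-line summaries, pairwise
    blocks with a match midline."""
    _require_alignments(hits)
    if scheme is None:
        scheme = default_scheme()
    out: list[str] = []
    out.append(f"Query: {query.id}  ({len(query.sequence)} residues)")
    out.append("")
    out.append(f"{'Hit':<30} {'Vote':>5} {'Score':>6} {'E-value':>9} {'Ident%':>7}")
    for h in hits:
        out.append(
            f"{h.protein_id:<30} {h.vote:>5} {h.score:>6} "
            f"{_fmt_evalue(h.evalue):>9} {_fmt_identity(h.identity):>7}"
        )
    for h in hits:
        out.append("")
        out.append(f">{h.protein_id}")
        out.append(
            f" Score = {h.score}, E-value = {_fmt_evalue(h.evalue)}, "
            f"Identities = {_fmt_identity(h.identity)}%"
        )
        qpos, tpos = h.q_start, h.t_start
        aq, at = h.query_aligned, h.target_aligned
        for start in range(0, len(aq), _REPORT_WIDTH):
            qchunk = aq[start:start + _REPORT_WIDTH]
            tchunk = at[start:start + _REPORT_WIDTH]
            mid = "".join(_midline(a, b, scheme) for a, b in zip(qchunk, tchunk))
            q_adv = sum(1 for c in qchunk if c != GAP)
            t_adv = sum(1 for c in tchunk if c != GAP)
            out.append(f"Query {qpos + 1:>6} {qchunk} {qpos + q_adv:>6}")
            out.append(f"      {'':>6} {mid}")
            out.append(f"Sbjct {tpos + 1:>6} {tchunk} {tpos + t_adv:>6}")
            qpos += q_adv
            tpos += t_adv
    return "\n".join(out) + "\n"


def write_fasta_hits(
    query: ProteinRecord,
    hits: list[Hit],
    aligned: bool = False,
) -> str:
    """FASTA of hit sequences.

    ``aligned=False`` emits the raw full-length hit sequences;
    ``aligned=True`` emits the stacked gapped rows with the query first,
    so all records share the query's length.
    """
    out: list[str] = []
    if aligned:
        stacked = stack_alignments(query, hits)
        out.append(f">{stacked.query_id}")
        out.append(stacked.query_sequence)
        for row in stacked.rows:
            out.append(
                f">{row.id} score={row.score} evalue={_fmt_evalue(row.evalue)} "
                f"identity={_fmt_identity(row.identity)} insertions={row.insertions}"
            )
            out.append(row.row)
    else:
        for h in hits:
            if h.target_sequence is None:
                raise ValueError(f"hit {h.protein_id!r} carries no sequence")
            out.append(f">{h.protein_id}")
            out.append(h.target_sequence)
    return "\n".join(out) + "\n"
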