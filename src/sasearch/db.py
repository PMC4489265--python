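"""Protein FASTA I/O, concatenated database text and suffix arrays.

The searchable corpus is a single residue string built by concatenating
every protein followed by a sentinel character.  The sentinel sorts below
every amino-acid letter, so a suffix comparison never crosses a protein
boundary; suffixes that *start* on a sentinel are excluded from the array.

Alongside the sorted suffix positions we precompute, for every suffix, a
64-bit "neighborhood key": its first 12 residues packed at 5 bits per
letter (masked to zero beyond the protein's end).  Keys sort in the same
order as the suffixes they summarize, which lets the search layer do bulk
``numpy.searchsorted`` insertion lookups and constant-time prefix-identity
tests instead of per-suffix string comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid letters.
RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
#: Ambiguity letter; every non-standard input character is mapped to it.
AMBIGUOUS = "X"
#: Full internal alphabet, in lexicographic order (X sorts between W and Y).
ALPHABET = "ACDEFGHIKLMNPQRSTVWXY"
#: Protein terminator inside the concatenated text; sorts below all letters.
SENTINEL = "$"
#: Number of leading residues packed into one uint64 neighborhood key.
KEY_LEN = 12
#: Bits per residue in a packed key.
KEY_BITS = 5

_CODE = {c: i + 1 for i, c in enumerate(ALPHABET)}
_CODE[SENTINEL] = 0
_DECODE = np.array([SENTINEL] + list(ALPHABET), dtype="<U1")
_VALID = frozenset(RESIDUES)

_ENCODE_LUT = np.zeros(128, dtype=np.uint8)
for _c, _i in _CODE.items():
    _ENCODE_LUT[ord(_c)] = _i

INDEX_FORMAT_VERSION = 1


def encode(sequence: str) -> np.ndarray:
    """Encode a residue string over ``ALPHABET`` (+ sentinel) as uint8 codes."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE_LUT[raw]
    bad = (codes == 0) & (raw != ord(SENTINEL))
    if bad.any():
        ch = chr(int(raw[bad][0]))
        raise ValueError(f"character {ch!r} is not in the residue alphabet")
    return codes


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return "".join(_DECODE[codes])


def normalize_sequence(sequence: str, record_id: str = "?") -> str:
    """Upper-case and map non-standard characters (B, Z, J, U, O, ``*``,
    gaps, ...) to ``X``, logging one warning per record."""
    seq = sequence.upper()
    replaced = sorted({c for c in seq if c not in _VALID and c != AMBIGUOUS})
    if replaced:
        logger.warning(
            "record %s: mapped non-standard characters %s to %s",
            record_id, "".join(replaced), AMBIGUOUS,
        )
        seq = "".join(c if c in _VALID or c == AMBIGUOUS else AMBIGUOUS for c in seq)
    return seq


@dataclass
class ProteinRecord:
    """One FASTA entry: identifier, free-text description, residue string."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        if SENTINEL in self.sequence:
            raise ValueError(f"record {self.id!r} contains the sentinel character")

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into normalized :class:`ProteinRecord` s.

    Sequences are upper-cased; characters outside the 20-letter alphabet
    are mapped to ``X`` with a warning.  An entry with an empty sequence is
    a format error.
    """
    records: list[ProteinRecord] = []
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq)
            if not seq:
                raise ValueError(f"FASTA record {rec.id!r} has an empty sequence")
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            records.append(
                ProteinRecord(id=rec.id, sequence=normalize_sequence(seq, rec.id),
                              description=desc)
            )
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    """Write records as wrapped FASTA (inverse of :func:`read_fasta`)."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seqrecords, handle, "fasta")


@dataclass
class ProteinDatabase:
    """Concatenated, sentinel-terminated residue text plus per-protein metadata.

    ``n_residues`` (total residues, sentinels excluded) is the database
    length *n* used by the Karlin–Altschul e-value.
    """

    codes: np.ndarray          # uint8 text, one 0-sentinel after each protein
    offsets: np.ndarray        # int64 start of each protein in codes
    lengths: np.ndarray        # int64 residue count of each protein
    ids: list[str]
    descriptions: list[str]
    protein_of: np.ndarray     # int32 protein index for every text position
    n_residues: int
    _bytes: bytes | None = field(default=None, repr=False, compare=False)

    @property
    def n_proteins(self) -> int:
        return len(self.ids)

    @property
    def text(self) -> str:
        """The concatenated text as a string (sentinels included)."""
        return decode(self.codes)

    @property
    def text_bytes(self) -> bytes:
        """Raw code bytes; byte order equals lexicographic suffix order."""
        if self._bytes is None:
            self._bytes = self.codes.tobytes()
        return self._bytes

    def sequence(self, i: int) -> str:
        """Residue string of protein ``i``."""
        o = int(self.offsets[i])
        return decode(self.codes[o:o + int(self.lengths[i])])

    def record(self, i: int) -> ProteinRecord:
        return ProteinRecord(id=self.ids[i], sequence=self.sequence(i),
                             description=self.descriptions[i])


def build_database(records: list[ProteinRecord]) -> ProteinDatabase:
    """Concatenate records into a sentinel-terminated database text.

    Duplicate identifiers are disambiguated with ``_2``, ``_3``, ... and a
    warning is logged.
    """
    if not records:
        raise ValueError("cannot build a database from an empty record list")
    seen: dict[str, int] = {}
    ids: list[str] = []
    for rec in records:
        count = seen.get(rec.id, 0) + 1
        seen[rec.id] = count
        if count == 1:
            ids.append(rec.id)
        else:
            new_id = f"{rec.id}_{count}"
            logger.warning("duplicate id %r renamed to %r", rec.id, new_id)
            ids.append(new_id)

    parts = []
    for rec in records:
        parts.append(encode(rec.sequence))
        parts.append(np.zeros(1, dtype=np.uint8))
    codes = np.concatenate(parts)
    lengths = np.array([len(r.sequence) for r in records], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths + 1)[:-1]]).astype(np.int64)
    protein_of = np.repeat(
        np.arange(len(records), dtype=np.int32), lengths + 1
    )
    return ProteinDatabase(
        codes=codes,
        offsets=offsets,
        lengths=lengths,
        ids=ids,
        descriptions=[r.description for r in records],
        protein_of=protein_of,
        n_residues=int(lengths.sum()),
    )


@dataclass
class SuffixArray:
    """Lexicographically sorted residue positions of a database text.

    ``positions[i]`` is the text position whose (sentinel-terminated)
    suffix is the ``i``-th smallest; equal suffixes tie-break by ascending
    position.  ``keys[i]`` is the packed 12-residue prefix of that suffix.
    """

    positions: np.ndarray  # int64
    keys: np.ndarray       # uint64, same order as positions

    def __len__(self) -> int:
        return len(self.positions)


def _pack_keys(codes: np.ndarray, limits: np.ndarray) -> np.ndarray:
    """Pack, for every start position, its first KEY_LEN usable characters
    (``limits[p]`` of them; the rest zero-filled) into a uint64 key."""
    n = len(codes)
    padded = np.concatenate([codes, np.zeros(KEY_LEN, dtype=np.uint8)])
    keys = np.zeros(n, dtype=np.uint64)
    for j in range(KEY_LEN):
        c = padded[j:j + n].astype(np.uint64)
        c[limits <= j] = 0
        keys = (keys << np.uint64(KEY_BITS)) | c
    return keys


def pack_query_keys(codes: np.ndarray) -> np.ndarray:
    """Packed neighborhood keys for every suffix of a sentinel-free query."""
    limits = len(codes) - np.arange(len(codes), dtype=np.int64)
    return _pack_keys(codes, limits)


def _suffix_order(codes: np.ndarray, n_sentinels: int) -> np.ndarray:
    """Sort all suffixes of the full text by prefix doubling.

    Each sentinel is given a unique rank increasing with position and
    smaller than every residue rank, so the induced order equals
    sentinel-terminated comparison with ties broken by ascending position.
    """
    n = len(codes)
    is_sent = codes == 0
    rank = np.where(
        is_sent,
        np.cumsum(is_sent) - 1,
        codes.astype(np.int64) + n_sentinels - 1,
    ).astype(np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        if k < n:
            key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r1 = rank[order]
        r2 = key2[order]
        newrank = np.empty(n, dtype=np.int64)
        diff = np.empty(n, dtype=bool)
        diff[0] = True
        diff[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        newrank[order] = np.cumsum(diff) - 1
        rank = newrank
        if rank[order[-1]] == n - 1:
            return order
        k *= 2


def build_suffix_array(db: ProteinDatabase) -> SuffixArray:
    """Suffix array of ``db``: residue positions sorted by their suffix.

    Suffix comparison stops at the first sentinel (never crossing a protein
    boundary); sentinel-started suffixes are excluded; equal suffixes sort
    by ascending position.
    """
    order = _suffix_order(db.codes, db.n_proteins)
    positions = order[db.codes[order] != 0].astype(np.int64)

    # distance from each position to its protein's terminating sentinel
    n = len(db.codes)
    nxt = np.where(db.codes == 0, np.arange(n), n)
    nxt = np.minimum.accumulate(nxt[::-1])[::-1]
    limits = nxt - np.arange(n)
    keys_all = _pack_keys(db.codes, limits)
    return SuffixArray(positions=positions, keys=keys_all[positions])


def suffix_string(db: ProteinDatabase, position: int) -> str:
    """The sentinel-terminated suffix starting at ``position``, as a string."""
    codes = db.codes[position:]
    stop = np.argmax(codes == 0)  # text always ends in a sentinel
    return decode(codes[:stop])


def locate_suffix(sa: SuffixArray, db: ProteinDatabase, query_suffix: str) -> int:
    """Binary-search insertion position of ``query_suffix`` in the array.

    Returns the smallest index ``i`` such that the suffix at
    ``sa.positions[i]`` compares greater-or-equal to the query suffix
    (``i == len(sa)`` if the query exceeds every suffix).
    """
    if not query_suffix:
        raise ValueError("query suffix must be non-empty")
    qb = encode(query_suffix).tobytes()
    m = len(qb)
    text = db.text_bytes
    pos = sa.positions
    lo, hi = 0, len(pos)
    while lo < hi:
        mid = (lo + hi) // 2
        p = int(pos[mid])
        # slices include sentinel zeros, which sort below every residue,
        # so bytes comparison equals sentinel-terminated suffix comparison
        if text[p:p + m] >= qb:
            hi = mid
        else:
            lo = mid + 1
    return lo


def save_index(db: ProteinDatabase, sa: SuffixArray, path: str | Path) -> None:
    """Persist database + suffix array as a single ``.npz`` sidecar file."""
    np.savez(
        path,
        version=np.array([INDEX_FORMAT_VERSION], dtype=np.int64),
        codes=db.codes,
        offsets=db.offsets,
        lengths=db.lengths,
        ids=np.array(db.ids, dtype="U"),
        descriptions=np.array(db.descriptions, dtype="U"),
        positions=sa.positions,
        keys=sa.keys,
    )


def load_index(path: str | Path) -> tuple[ProteinDatabase, SuffixArray]:
    """Load an index written by :func:`save_index`."""
    with np.load(path, allow_pickle=False) as data:
        version = int(data["version"][0])
        if version != INDEX_FORMAT_VERSION:
            raise ValueError(f"unsupported index format version {version}")
        lengths = data["lengths"].astype(np.int64)
        codes = data["codes"]
        db = ProteinDatabase(
            codes=codes,
            offsets=data["offsets"].astype(np.int64),
            lengths=lengths,
            ids=[str(x) for x in data["ids"]],
            descriptions=[str(x) for x in data["descriptions"]],
            protein_of=np.repeat(
                np.arange(len(lengths), dtype=np.int32), lengths + 1
            ),
            n_residues=int(lengths.sum()),
        )
        sa = SuffixArray(
            positions=data["positions"].astype(np.int64),
            keys=data["keys"].astype(np.uint64),
        )
    return db, sa
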