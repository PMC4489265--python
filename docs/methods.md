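# Methods

## Data model

The database is a single uint8-encoded residue string: each protein's
sequence followed by a sentinel byte (code 0). Residues are encoded
1–21 in the lexicographic order `ACDEFGHIKLMNPQRSTVWXY`; every
non-standard input letter (B, Z, J, U, O, `*`, gaps) is normalized to the
ambiguity letter X, which orders like an ordinary letter and scores
through the substitution matrix's X row. Because the sentinel sorts below
every residue, a suffix comparison terminates at the end of its protein:
no vote or alignment can span two proteins. Sentinel-started suffixes are
excluded from the array. Coordinates are 0-based half-open everywhere in
the library; only rendered reports use 1-based inclusive positions.

The suffix array is built by numpy prefix doubling over integer ranks.
Initial ranks give each sentinel a unique value increasing with position
(all below every residue rank), which simultaneously realizes
protein-bounded comparison and the deterministic tie-break (equal
suffixes order by ascending text position). Construction is
O(n log² n) with vectorized sorts; correctness is defined — and tested —
against brute-force sorting of all suffix strings. Memory is a few
machine words per residue; the design target of a handful of bytes per
amino acid would need packed integer types and is documented here rather
than enforced.

Alongside each suffix we store a packed key: its first 12 residues at
5 bits each in a uint64, zero-filled past the protein end. Keys sort
exactly like their suffixes, so

* bulk insertion lookups are one `numpy.searchsorted` over the key
  array, corrected by an exact binary search only where a database
  suffix ties with the query suffix on the full 12-residue key (for
  query suffixes of 12 residues or fewer the key decides the order
  exactly);
* "common prefix ≥ `min_match`" is an equality test on the top
  `5·min_match` bits whenever `min_match ≤ 12` (an exact string check
  handles the larger—rarely useful—settings).

`locate_suffix` itself is the plain exact binary search over suffix
bytes; the vectorized path must and does agree with it (tested against a
linear-scan oracle).

## Voting

For every query suffix (of length at least `min_match`) the `W` array
neighbors on each side of the insertion position are inspected; window
`[i−W, i+W)`. A neighbor with common prefix ≥ `min_match` votes for
(its protein, band) where the diagonal `d = query_pos − target_pos` is
floored into bands of `band_width` residues (flooring toward −∞, so
negative diagonals band consistently). At most one vote per (query
position, protein, band) prevents repeat regions from inflating one band.
A protein's score is the **maximum** over its bands — the band-local,
selective reading of diagonal accumulation, mirroring FASTA's
best-diagonal logic — and its winning band seeds the alignment band
center.

Defaults `W = 16`, `min_match = 6`, `band_width = 16` were chosen so
that, at desk scale (≈3·10⁵ database residues), unrelated proteins rarely
collect more than one vote in any band: the expected number of decoy
suffixes sharing a random 6-mer with a 250-residue query is of order one,
and two such chance seeds almost never fall in the same band of the same
decoy. All three are CLI-tunable.

## Search protocols

The four modes differ only in candidate-pool depth and alignment policy:
verifast reports the top-H proteins by vote with no alignments; fast
aligns the top-H and re-sorts by score; slow aligns the top-2H; verislow
aligns up to 4000 voted proteins. Aligning modes drop hits with e-value
at or above the cutoff (default 1.0) and truncate to H; ties break by
e-value then ascending protein index, and every tie-break in the package
is by ascending database index, so identical inputs give byte-identical
output. Multi-query input is processed sequentially in input order.

**Verifast vote threshold.** Verifast computes no e-values, so a vote
cutoff stands in for the significance filter. The shipped default (3) is
the smallest threshold whose decoy share of reported hits on the default
synthetic benchmark is at most 2%: the sweep
(`scripts/calibrate_vote_threshold.py`) measures 40.9% at threshold 1,
3.6% at 2 and 0.0% at 3, so the integer vote grid jumps straight past the
nominal 1–2% operating point and 3 is the sensitivity-maximizing choice
under the cap.

**Stable-H option.** The vote is positively but imperfectly correlated
with alignment score, so a fixed pool can truncate just above a strong
hit. With `stable_h`, candidates are aligned in vote order until
`stable_patience` (default H) consecutive additional alignments leave the
H-th best score unchanged. A concrete patience is required for
termination; H makes the stopping rule scale with the request size.

## Alignment and statistics

Candidate alignment is Smith–Waterman-style local DP with affine gaps
(gap of length k costs `gap_open + k·gap_extend`), restricted to cells
whose diagonal lies within `half_band` (default 32) of the winning vote
band's central diagonal. Local (rather than global-in-band) alignment is
used so Karlin–Altschul theory applies to the scores. Traceback ties
prefer diagonal, then up (gap in target), then left; gap states prefer
opening over extending on ties; the best cell is the first maximum in
row-major order. With a band covering the whole matrix the result is
exactly unbanded Smith–Waterman, which is how the implementation is
validated against an independent aligner. A band that misses the matrix
entirely yields the empty zero-score alignment. Inner loops are
numba-compiled; scores are int32 matrix units.

E-values use `E = K·m·n·exp(−λS)` with m the query length and n the
**total database residue count** — database-search semantics, so a cutoff
of 1 means "one expected chance hit per database scan". Bundled matrices
(BLOSUM62 default, BLOSUM45, BLOSUM80) come from Biopython's published
tables with BLAST's default gap penalties and the corresponding published
gapped (λ, K) pairs; a custom NCBI-format matrix file must be supplied
with explicit λ and K, since no universal constants exist for an
arbitrary matrix. The bundled constants are valid at the default gap
penalties; overriding the penalties without overriding λ/K shifts the
absolute e-value scale (e-values are in general not comparable across
scoring conventions).

Identity is identical columns over all aligned columns (gap columns
count in the denominator; pairwise alignments have no double-gap
columns).

## Stacked alignments

Pairwise alignments are projected onto query coordinates: target
residues occupy the query column they align to, deletions relative to
the query appear as `-`, unaligned query flanks are padded with `-`, and
insertions (target residues aligned to query gaps) are omitted so every
row has exactly the query's length. The number of omitted residues is
kept as per-row `insertions=k` metadata, so downstream consumers can see
what the projection dropped.

## Synthetic benchmark

`generate_benchmark` emulates the standard sensitivity-benchmark design:
unrelated i.i.d. random decoys (uniform residue background, lengths
uniform in 100–400) plus homologs implanted at controlled identity. Each
homolog's parent is the query; substitution positions are drawn without
replacement so the realized identity is exactly `round(t·L)/L`, with
substitutions drawn from the background excluding the original letter.
The default composition is 1,000 decoys and 50 homologs in each of six
bins — five 10-point bins from 50% to 100% plus an exact-copy bin — at
seed 42. Generation is a pure function of (spec, seed): two runs produce
byte-identical FASTA.

The reference ("TRUE") set is built by exhaustive **unbanded**
Smith–Waterman of every query against every database protein at the
e-value cutoff — the role a rigorous full-DP searcher plays in published
benchmarks — using the package's score-only DP kernel, which is itself
cross-checked against an independent aligner in the tests. Recall is
reported per identity bin of the implanted pair (known by construction),
so chance decoy pairs that clear the e-value cutoff do not contaminate
the bins.

What the generator does *not* emulate: real amino-acid composition and
repeat structure, domain architecture, indel-rich divergence (indels are
off by default; the mutation model is substitution-only), and
database-scale redundancy. Passing the synthetic benchmark therefore
demonstrates the retrieval machinery (seeding, voting, banding, ranking,
statistics) at desk scale, not field sensitivity on real proteomes —
where low-complexity regions and compositional bias would raise the
chance-vote floor, and remote homologs with many indels would stress the
fixed alignment band.

## Problem sizes and numerical choices

The shipped benchmark scale (≈1,300 proteins, ≈3.3·10⁵ residues, 300
queries) keeps an exhaustive full-DP reference set cheap to rebuild while
leaving roughly three decades between homolog and decoy e-values.
Tolerances are not needed anywhere in the core: scores and votes are
integers, and every determinism claim is exact (byte-identical output).
Degenerate inputs are defined rather than left to chance: queries
shorter than `min_match` yield an empty vote table with a warning; an
all-negative scoring pair yields the empty alignment with score 0 and
identity 0; duplicate database identifiers are disambiguated with a
numeric suffix and a warning.

## Known limitations

* Sensitivity decays below ~50–60% identity, inherent to exact 6-residue
  seeding; reduced alphabets or spaced seeds are out of scope.
* One process, one thread; the client–server and MPI parallelization of
  the original method family is deliberately not reproduced, and
  multi-query requests are served sequentially.
* A single highest-scoring alignment per pair (no sum statistics over
  multiple segment pairs, no composition-based score adjustment).
* The `.npz` index is a cache, not an interchange format.
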