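# sasearch

Fast protein homology search by **suffix-array neighborhood voting**.

Sequence databases have grown to the point where a classical full
dynamic-programming (or even BLAST) scan per query is a bottleneck for
interactive exploration and annotation pipelines. `sasearch` indexes a
protein FASTA database into a suffix array and retrieves a query's
sequence neighbors in a fraction of the time an alignment-first search
takes, at a sensitivity comparable to alignment-based methods for matches
above roughly 50% sequence identity. It is aimed at people who need
approximate nearest-neighbor retrieval from a protein database — for
functional annotation, homolog collection, or alignment seeding — and at
anyone who wants a small, fully testable reference implementation of the
suffix-array voting idea.

## Method

1. **Index.** The database is concatenated into one residue string with a
   sentinel after each protein (the sentinel sorts below every residue, so
   suffix comparisons never cross protein boundaries). A suffix array — the
   lexicographically sorted list of all residue positions — is built over it.
2. **Vote.** For every suffix of the query, a binary search finds its
   insertion position in the suffix array; the `W` lexicographic neighbors on
   each side (default 16) are inspected. A neighbor whose common prefix with
   the query suffix is at least `min_match` residues (default 6) casts one
   vote for its protein on the diagonal band containing
   `d = query_pos − target_pos` (band width 16). Banding votes by diagonal —
   the same idea as FASTA's best-diagonal statistic — keeps the evidence in a
   consistent alignment register. A protein's vote is the maximum over its
   bands.
3. **Align and rank.** Candidates are re-scored with a banded
   Smith–Waterman local alignment (affine gaps, BLOSUM62 11/1 by default)
   centered on the winning diagonal band, and the significance of a score
   *S* for a query of length *m* against a database of *n* residues is the
   Karlin–Altschul expectation

   &nbsp;&nbsp;&nbsp;&nbsp;`E = K · m · n · exp(−λ S)`

   with the published gapped constants (λ = 0.267, K = 0.041 for
   BLOSUM62 11/1). Aligning modes report only hits with `E` below the
   cutoff (default 1).

Four protocols trade candidate-pool depth for speed: **verifast** (top-H
by vote, no alignments; a calibrated vote threshold suppresses chance
hits), **fast** (align top-H), **slow** (align top-2H), **verislow**
(align up to 4000 voted proteins). An optional *stable-H* rule keeps
aligning down the vote list until the H-th best alignment score stops
changing.

## Worked example

Generate a small synthetic benchmark (200 random decoys plus 30 implanted
homologs of known identity), index it, and search one query:

```sh
$ sasearch generate bench --seed 42 --n-decoys 200 --homologs-per-bin 5 \
      --min-length 80 --max-length 200
wrote 230 database and 30 query proteins to bench
$ sasearch index bench/db.fasta db.idx.npz
indexed 230 proteins, 32280 residues -> db.idx.npz
$ sasearch search db.idx.npz q1.fasta --mode slow -H 3
query_id      hit_id          rank  vote  score  evalue   identity_pct  q_start  q_end  t_start  t_end
query_b1_001  homolog_b1_001  1     6     374    6.6e-39  59.1          2        116    2        116
```

The single reported hit is the homolog implanted for this query: it drew
a best-band vote of 6, its banded alignment scores 374 matrix units over
query residues 2–116 (1-based, inclusive) at 59.1% identity, and the
e-value 6.6×10⁻³⁹ says a chance hit this strong is essentially impossible
in a 32,280-residue database — the decoys are correctly absent.

`sasearch bench` searches a whole benchmark and scores recall per
identity bin against an exhaustive full-DP reference set computed on the
fly:

```sh
$ sasearch bench db.idx.npz bench/queries.fasta bench/metadata.tsv --mode slow -H 10
bin_low  bin_high  n_true  n_found  recall
0.5000   0.6000    5       4        0.8000
0.6000   0.7000    5       5        1.0000
...
1.0000   1.0000    5       5        1.0000
```

Recall is 1.0 for every bin at or above 60% identity; below that a
homolog occasionally presents no 6-residue exact seed and is missed —
the expected failure mode of seed-based search.

Other output formats: `--format report` (BLAST-like pairwise report),
`--format fasta` (hit sequences), `--format stacked` (all hits projected
onto query coordinates, insertions omitted, so every row has the query's
length — ready for logo/visualization tools).

## Index file

`sasearch index` writes a versioned `.npz` sidecar holding the encoded
database text, per-protein offsets/lengths/identifiers, and the suffix
array positions together with packed 12-residue prefix keys. It is
loadable with `sasearch.load_index()` and is a cache only — it can always
be regenerated from the FASTA.

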