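"""Calibration sweep behind the shipped verifast vote threshold.

Runs verifast mode over the default synthetic benchmark for a range of
vote thresholds and prints, for each, how many reported hits are decoys
(unrelated random proteins).  The shipped default
(sasearch.search.VERIFAST_VOTE_THRESHOLD) is the smallest threshold whose
decoy share of reported hits is at most 2%.

Usage:  python scripts/calibrate_vote_threshold.py [--seed 42]
"""

from __future__ import annotations

import argparse

import sasearch as ss


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--thresholds", type=int, nargs="+", default=[1, 2, 3, 4, 5])
    args = ap.parse_args()

    bench = ss.generate_benchmark(ss.BenchmarkSpec(seed=args.seed))
    db = ss.build_database(bench.database)
    sa = ss.build_suffix_array(db)

    print(f"seed={args.seed}  db={db.n_proteins} proteins / {db.n_residues} residues")
    print(f"{'threshold':>9} {'hits':>6} {'decoy_hits':>10} {'decoy_rate_%':>12}")
    for thr in args.thresholds:
        params = ss.SearchParams(mode="verifast", H=50, vote_threshold=thr)
        n_hits = n_decoy = 0
        for q in bench.queries:
            for h in ss.search(q, (db, sa), params):
                n_hits += 1
                n_decoy += h.protein_id.startswith("decoy")
        rate = 100.0 * n_decoy / max(n_hits, 1)
        print(f"{thr:>9} {n_hits:>6} {n_decoy:>10} {rate:>12.2f}")


if __name__ == "__main__":
    main()
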