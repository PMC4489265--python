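import numpy as np
import pytest

import sasearch as ss
from sasearch.db import suffix_string
from sasearch.search import VoteTable, select_candidates, vote


def linear_scan_insertion(db, query_suffix):
    """Independent oracle: count suffix strings smaller than the query."""
    suffixes = np.array(
        [suffix_string(db, p) for p in range(len(db.codes)) if db.codes[p] != 0]
    )
    return int((suffixes < query_suffix).sum())


class TestLocateSuffix:
    def test_hand_example(self):
        db = ss.build_database([ss.ProteinRecord("p", "ARA")])
        sa = ss.build_suffix_array(db)
        assert ss.locate_suffix(sa, db, "AR") == 1

    def test_greater_than_all(self):
        db = ss.build_database([ss.ProteinRecord("p", "ARA")])
        sa = ss.build_suffix_array(db)
        assert ss.locate_suffix(sa, db, "YY") == 3

    def test_empty_suffix_rejected(self):
        db = ss.build_database([ss.ProteinRecord("p", "ARA")])
        sa = ss.build_suffix_array(db)
        with pytest.raises(ValueError):
            ss.locate_suffix(sa, db, "")

    def test_matches_linear_scan(self, rng):
        recs = [ss.ProteinRecord(f"r{i}", ss.random_protein(int(rng.integers(3, 40)), rng))
                for i in range(30)]
        db = ss.build_database(recs)
        sa = ss.build_suffix_array(db)
        for _ in range(100):
            if rng.random() < 0.5:
                qs = ss.random_protein(int(rng.integers(1, 12)), rng)
            else:  # suffix of a database protein, exercising ties
                r = recs[int(rng.integers(len(recs)))]
                qs = r.sequence[int(rng.integers(len(r.sequence))):]
            assert ss.locate_suffix(sa, db, qs) == linear_scan_insertion(db, qs)


class TestVote:
    def test_self_match_vote_arithmetic(self, rng):
        seq = ss.random_protein(40, rng)
        db = ss.build_database(
            [ss.ProteinRecord("self", seq), ss.ProteinRecord("other", ss.random_protein(50, rng))]
        )
        sa = ss.build_suffix_array(db)
        params = ss.SearchParams()
        vt = vote(ss.ProteinRecord("q", seq), sa, db, params)
        assert vt.counts[(0, 0)] == len(seq) - params.min_match + 1
        assert vt.best_band[0] == 0

    def test_disjoint_alphabets_give_empty_table(self):
        db = ss.build_database([ss.ProteinRecord("p", "WWWWWWWWWW")])
        sa = ss.build_suffix_array(db)
        vt = vote(ss.ProteinRecord("q", "AAAAAAAAAA"), sa, db, ss.SearchParams())
        assert len(vt) == 0

    def test_query_shorter_than_min_match_warns(self, caplog):
        db = ss.build_database([ss.ProteinRecord("p", "ACDEFGHIKL")])
        sa = ss.build_suffix_array(db)
        with caplog.at_level("WARNING"):
            vt = vote(ss.ProteinRecord("q", "ACD"), sa, db, ss.SearchParams())
        assert len(vt) == 0
        assert "min_match" in caplog.text

    def test_implanted_homolog_gets_highest_vote(self, small_benchmark):
        bench, db, sa = small_benchmark
        params = ss.SearchParams()
        # high-identity implants must dominate the vote table
        high = bench.metadata[bench.metadata.bin_low >= 0.8]
        for _, row in high.iterrows():
            q = next(q for q in bench.queries if q.id == row.query_id)
            vt = vote(q, sa, db, params)
            best = max(vt.protein_votes, key=lambda p: (vt.protein_votes[p], -p))
            assert db.ids[best] == row.hit_id

    def test_exhaustive_vote_recomputation(self, small_benchmark):
        """Votes agree with a direct re-derivation from locate_suffix and
        explicit common-prefix checks."""
        bench, db, sa = small_benchmark
        params = ss.SearchParams(window=8)
        q = bench.queries[0]
        vt = vote(q, sa, db, params)

        expected = {}
        seen = set()
        seq = q.sequence
        for u in range(len(seq) - params.min_match + 1):
            qs = seq[u:]
            i = ss.locate_suffix(sa, db, qs)
            for j in range(max(0, i - params.window),
                           min(len(sa), i + params.window)):
                p = int(sa.positions[j])
                s = suffix_string(db, p)
                lcp = 0
                for a, b in zip(qs, s):
                    if a != b:
                        break
                    lcp += 1
                if lcp < params.min_match:
                    continue
                prot = int(db.protein_of[p])
                diag = u - (p - int(db.offsets[prot]))
                band = diag // params.band_width
                if (u, prot, band) in seen:
                    continue
                seen.add((u, prot, band))
                expected[(prot, band)] = expected.get((prot, band), 0) + 1
        assert vt.counts == expected

    def test_window_monotonicity(self, small_benchmark):
        bench, db, sa = small_benchmark
        q = bench.queries[5]
        prev = {}
        for w in (2, 4, 8, 16, 32):
            vt = vote(q, sa, db, ss.SearchParams(window=w))
            for key, c in prev.items():
                assert vt.counts.get(key, 0) >= c
            prev = vt.counts


class TestSelectCandidates:
    def make_votes(self):
        return VoteTable({(3, 0): 10, (1, 0): 10, (7, 0): 4})

    def test_slow_tie_and_truncation(self):
        got = select_candidates(self.make_votes(), ss.SearchParams(mode="slow", H=2))
        assert got == [1, 3, 7]  # 2H = 4 >= 3 available

    def test_fast_truncates_to_h(self):
        got = select_candidates(self.make_votes(), ss.SearchParams(mode="fast", H=2))
        assert got == [1, 3]

    def test_verifast_threshold_drops_low_votes(self):
        votes = VoteTable({(1, 0): 5, (2, 0): 1})
        got = select_candidates(
            votes, ss.SearchParams(mode="verifast", H=10, vote_threshold=3)
        )
        assert got == [1]

    def test_verislow_caps_at_4000(self):
        votes = VoteTable({(p, 0): 1 for p in range(5000)})
        got = select_candidates(votes, ss.SearchParams(mode="verislow", H=10))
        assert len(got) == 4000


class TestSearch:
    def test_self_hit_in_every_mode(self, small_benchmark):
        bench, db, sa = small_benchmark
        q = db.record(0)
        for mode in ("verifast", "fast", "slow", "verislow"):
            hits = ss.search(q, (db, sa), ss.SearchParams(mode=mode, H=5))
            assert hits[0].protein_id == q.id
            if mode == "verifast":
                assert hits[0].score is None and hits[0].evalue is None
            else:
                assert hits[0].identity == 1.0
                assert hits[0].evalue < 1.0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            ss.SearchParams(mode="turbo")

    def test_determinism(self, small_benchmark):
        bench, db, sa = small_benchmark
        params = ss.SearchParams(mode="slow", H=10)
        q = bench.queries[3]
        first = ss.search(q, (db, sa), params)
        second = ss.search(q, (db, sa), params)
        assert first == second

    def test_slow_hits_subset_of_verislow(self, small_benchmark):
        bench, db, sa = small_benchmark
        for q in bench.queries[:10]:
            slow = {h.protein_id for h in
                    ss.search(q, (db, sa), ss.SearchParams(mode="slow", H=10))}
            veri = {h.protein_id for h in
                    ss.search(q, (db, sa), ss.SearchParams(mode="verislow", H=10))}
            assert slow <= veri

    def test_stable_h_matches_deep_search_on_benchmark(self, small_benchmark):
        bench, db, sa = small_benchmark
        q = bench.queries[2]
        stable = ss.search(q, (db, sa),
                           ss.SearchParams(mode="slow", H=5, stable_h=True))
        deep = ss.search(q, (db, sa), ss.SearchParams(mode="verislow", H=5))
        assert [h.protein_id for h in stable][:1] == [h.protein_id for h in deep][:1]
        assert stable[0].score == deep[0].score

    def test_search_many_preserves_input_order(self, small_benchmark):
        bench, db, sa = small_benchmark
        queries = bench.queries[:4]
        out = ss.search_many(queries, (db, sa), ss.SearchParams(mode="fast", H=3))
        assert list(out) == [q.id for q in queries]
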