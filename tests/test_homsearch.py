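"""Seeded search, semi-global alignment and iterated search."""

import math
import random

import pytest

from rfamforge.seqio import SequenceRecord, reverse_complement
from rfamforge.homsearch import (
    Candidate,
    CandidateStatus,
    Locus,
    PivotTranscript,
    SearchParams,
    dinucleotide_shuffle,
    evalue,
    extend_and_trim,
    iterate_search,
    reciprocal_overlap,
    seeded_search,
    semiglobal_align,
)
from rfamforge.seqio import RepliconClass

from conftest import random_seq


class TestEvalue:
    def test_closed_form(self):
        # K*m*n*exp(-lambda*S) at S=30, m=100, n=1000, lambda=.5, K=.1
        want = 0.1 * 100 * 1000 * math.exp(-15)
        assert evalue(30, 100, 1000, 0.5, 0.1) == pytest.approx(want)
        assert want == pytest.approx(3.059e-3, rel=1e-3)

    def test_monotone_in_score(self):
        es = [evalue(s, 100, 1000, 0.5, 0.1) for s in range(0, 200, 10)]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_linear_in_database_size(self):
        assert evalue(30, 100, 2000, 0.5, 0.1) == pytest.approx(
            2 * evalue(30, 100, 1000, 0.5, 0.1)
        )

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            evalue(30, 100, 1000, -1, 0.1)


class TestSemiglobal:
    LINEAR = SearchParams(gap_open=0, gap_extend=2)

    def test_known_embedding(self):
        # ref ACGT inside GGACGTCC: perfect match, free cand end gaps
        res = semiglobal_align("ACGT", "GGACGTCC", self.LINEAR)
        assert res.score == 8
        assert res.cand_span == (2, 6)

    def test_identity_scores_twice_length(self):
        rng = random.Random(1)
        for _ in range(10):
            s = random_seq(rng, rng.randint(4, 30))
            assert semiglobal_align(s, s).score == 2 * len(s)

    def test_matches_bruteforce_all_short_pairs(self):
        """Optimal score equals exhaustive alignment enumeration for 100
        random pairs up to 8 nt (affine gaps, free cand terminal gaps)."""
        rng = random.Random(3)
        p = SearchParams()

        def brute(ref, cand):
            best = -1e9
            # alignment = choice of cand span [i, j) + sequence of ops
            def rec(r, c, c_end, state, score):
                nonlocal best
                if r == len(ref):
                    best = max(best, score)
                    return
                # substitution
                if c < c_end:
                    rec(r + 1, c + 1, c_end, "M",
                        score + (p.match if ref[r] == cand[c] else p.mismatch))
                # gap in cand (consume ref)
                open_cost = p.gap_open if state != "X" else 0
                rec(r + 1, c, c_end, "X", score - open_cost - p.gap_extend)
                # gap in ref (consume cand)
                if c < c_end:
                    open_cost = p.gap_open if state != "Y" else 0
                    rec(r, c + 1, c_end, "Y", score - open_cost - p.gap_extend)

            for i in range(len(cand) + 1):
                for j in range(i, len(cand) + 1):
                    rec(0, i, j, "M", 0)
            return best

        for _ in range(100):
            ref = random_seq(rng, rng.randint(1, 8))
            cand = random_seq(rng, rng.randint(1, 8))
            got = semiglobal_align(ref, cand, p).score
            assert got == pytest.approx(brute(ref, cand)), (ref, cand)


class TestSeededSearch:
    @pytest.fixture(scope="class")
    @staticmethod
    def planted():
        rng = random.Random(1)
        genome = random_seq(rng, 10000)
        query = random_seq(rng, 60)
        rec = SequenceRecord("g1", genome[:4000] + query + genome[4000:])
        return query, rec

    def test_planted_query_recovered_rank1(self, planted):
        query, rec = planted
        hits = seeded_search(query, [rec], query_id="q")
        assert hits
        top = hits[0]
        truth = Locus("g1", 4000, 4060, "+")
        assert top.locus.overlap(truth) > 0

    def test_strand_symmetry(self, planted):
        query, rec = planted
        rc = SequenceRecord("g1", reverse_complement(rec.sequence))
        fwd = seeded_search(query, [rec])[0]
        rev = seeded_search(query, [rc])[0]
        assert rev.locus.strand == "-"
        assert rev.locus.start == len(rec) - fwd.locus.end
        assert rev.locus.end == len(rec) - fwd.locus.start

    def test_unrelated_query_no_hits(self):
        rng = random.Random(2)
        rec = SequenceRecord("g2", random_seq(rng, 10000))
        q = random_seq(rng, 30)
        assert seeded_search(q, [rec]) == []

    def test_empty_db(self):
        assert seeded_search("ACGTACGTACGT", []) == []

    def test_evalues_sorted_ascending(self, planted):
        query, rec = planted
        hits = seeded_search(query, [rec])
        es = [h.evalue for h in hits]
        assert es == sorted(es)


class TestExtendAndTrim:
    def test_partial_hit_recovers_full_homolog(self):
        """A 60-nt partial hit of a 100-nt reference extends and trims to
        the full planted locus (length within [90, 110])."""
        rng = random.Random(11)
        ref = random_seq(rng, 100)
        genome = random_seq(rng, 3000)
        planted = genome[:1500] + ref + genome[1500:]
        rec = SequenceRecord("g", planted)
        hits = seeded_search(ref[20:80], [rec], query_id="part")
        # reinterpret the partial hit in the full reference's coordinates
        h = hits[0]
        h.query_span = (h.query_span[0] + 20, h.query_span[1] + 20)
        cand = extend_and_trim(h, rec, ref)
        assert cand is not None
        assert 90 <= len(cand.sequence) <= 110
        truth = Locus("g", 1500, 1600, "+")
        assert reciprocal_overlap(cand.locus, truth) >= 0.9

    def test_left_clip_at_replicon_start(self):
        rng = random.Random(12)
        ref = random_seq(rng, 60)
        rec = SequenceRecord("g", ref[2:] + random_seq(rng, 500))
        hits = seeded_search(ref, [rec])
        cand = extend_and_trim(hits[0], rec, ref)
        assert cand is not None
        assert cand.locus.start == 0  # clipped, no error

    def test_verbatim_plant_trims_to_exact_ref(self):
        rng = random.Random(13)
        ref = random_seq(rng, 80)
        genome = random_seq(rng, 2000)
        rec = SequenceRecord("g", genome[:900] + ref + genome[900:])
        hits = seeded_search(ref, [rec])
        cand = extend_and_trim(hits[0], rec, ref)
        assert cand.sequence == ref
        assert (cand.locus.start, cand.locus.end) == (900, 980)


class TestIterateSearch:
    def _chain_fixture(self):
        """A -> B -> C transitive homology by successive divergence:
        B is 20% diverged from A, C another 20% from B, so C is beyond
        the direct detection horizon of A but within B's."""
        rng = random.Random(4)

        def mutate(s, d):
            return "".join(
                rng.choice("ACGT".replace(c, "")) if rng.random() < d else c
                for c in s
            )

        a = random_seq(rng, 80)
        b = mutate(a, 0.20)
        c = mutate(b, 0.20)
        g = random_seq(rng, 9000)
        genome = SequenceRecord(
            "g", g[:2000] + b + g[2000:5000] + c + g[5000:]
        )
        pivot = PivotTranscript("SmelC001", a, Locus("gp", 0, 80, "+"),
                                RepliconClass.CHROMOSOME)
        return pivot, genome, Locus("g", 2000, 2080, "+"), Locus("g", 5080, 5160, "+")

    def test_transitive_homolog_needs_round_two(self):
        pivot, genome, locus_b, locus_c = self._chain_fixture()
        one = iterate_search([pivot], [genome], max_rounds=1,
                             use_semiglobal_scan=False)
        multi = iterate_search([pivot], [genome], max_rounds=3,
                               use_semiglobal_scan=False)
        def covers(cands, locus):
            return any(reciprocal_overlap(c.locus, locus) >= 0.5 for c in cands)
        assert covers(one, locus_b)
        assert not covers(one, locus_c)
        assert covers(multi, locus_b)
        assert covers(multi, locus_c)

    def test_round_cap_honoured(self):
        pivot, genome, *_ = self._chain_fixture()
        log = []
        iterate_search([pivot], [genome], max_rounds=3, log=log,
                       use_semiglobal_scan=False)
        assert len(log) <= 3

    def test_deterministic(self):
        pivot, genome, *_ = self._chain_fixture()
        r1 = iterate_search([pivot], [genome], use_semiglobal_scan=False)
        r2 = iterate_search([pivot], [genome], use_semiglobal_scan=False)
        assert [(c.locus, c.sequence) for c in r1] == [
            (c.locus, c.sequence) for c in r2
        ]

    def test_dedup_no_reciprocal_overlap_pairs(self):
        pivot, genome, *_ = self._chain_fixture()
        cands = iterate_search([pivot], [genome], use_semiglobal_scan=False)
        for i, a in enumerate(cands):
            for b in cands[i + 1 :]:
                if a.locus.strand == b.locus.strand:
                    assert reciprocal_overlap(a.locus, b.locus) < 0.5


class TestCandidateStatus:
    def test_forward_only(self):
        c = Candidate("c", Locus("g", 0, 10), "ACGTACGTAC", "seeded_search")
        c.advance(CandidateStatus.RETAINED)
        c.advance(CandidateStatus.AUTO_ACCEPTED)
        with pytest.raises(ValueError):
            c.advance(CandidateStatus.RAW)

    def test_discarded_keeps_ledger(self):
        c = Candidate("c", Locus("g", 0, 10), "ACGTACGTAC", "seeded_search",
                      ledger={"loc": 12.0})
        c.advance(CandidateStatus.DISCARDED, reason="prefilter")
        assert c.ledger["loc"] == 12.0
        assert "prefilter" in c.ledger["flags"]


class TestShuffle:
    def test_preserves_dinucleotide_counts(self):
        rng = random.Random(7)
        for _ in range(20):
            s = random_seq(rng, rng.randint(10, 60))
            t = dinucleotide_shuffle(s, rng)
            def counts(x):
                d = {}
                for a, b in zip(x, x[1:]):
                    d[a + b] = d.get(a + b, 0) + 1
                return d
            assert counts(s) == counts(t)
            assert t[0] == s[0] and t[-1] == s[-1]

    def test_actually_shuffles(self):
        rng = random.Random(8)
        s = random_seq(rng, 200)
        t = dinucleotide_shuffle(s, rng)
        assert t != s


class TestTaxonFilter:
    def test_family_level_partition(self):
        import pandas as pd
        from rfamforge.homsearch import filter_db_by_taxa

        tax = pd.DataFrame(
            [("o1", "f1"), ("o2", "f1"), ("o3", "f2")],
            columns=["organism", "family"],
        )
        db = [
            SequenceRecord("g1", "ACGT", organism="o1"),
            SequenceRecord("g2", "ACGT", organism="o2"),
            SequenceRecord("g3", "ACGT", organism="o3"),
            SequenceRecord("g4", "ACGT", organism="unknown_org"),
        ]
        assert [r.id for r in filter_db_by_taxa(db, tax, ["f1"])] == ["g1", "g2"]
        assert [r.id for r in filter_db_by_taxa(db, tax, ["f2"])] == ["g3"]
        assert filter_db_by_taxa(db, tax, None) == db
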