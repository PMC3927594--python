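"""Covariance model topology, CYK against parse enumeration, scanning."""

import random

import pytest

from rfamforge.seqio import SequenceRecord, StockholmAlignment, reverse_complement
from rfamforge.cmodel import CovarianceModel, build_cm, scan_cm, score_cm
from rfamforge.homsearch import dinucleotide_shuffle

from conftest import random_seq


def aln_of(seqs, ss):
    return StockholmAlignment(
        rows={f"s{i}": s for i, s in enumerate(seqs)}, ss_cons=ss
    )


def cyk_oracle(cm: CovarianceModel, seq: str) -> float:
    """Exhaustive parse enumeration: recursively try match/delete and
    every explicit insert count and bifurcation split."""
    n = len(seq)
    from rfamforge.cmodel import _IDX
    pen = cm.insert_penalty
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(v: int, i: int, j: int) -> float:
        node = cm.nodes[v]
        NEG = float("-inf")
        out = NEG
        if node.kind == "E":
            return -pen * (j - i)
        # inserts on either flank, enumerated explicitly
        for li in range(0, j - i + 1):
            for ri in range(0, j - i - li + 1):
                cost = -pen * (li + ri)
                a, b = i + li, j - ri
                if node.kind == "P":
                    if b - a >= 2:
                        e = node.emit[_IDX[seq[a]] * 4 + _IDX[seq[b - 1]]]
                        out = max(out, cost + e + node.t_match
                                  + best(node.children[0], a + 1, b - 1))
                    out = max(out, cost + node.t_delete
                              + best(node.children[0], a, b))
                elif node.kind == "L":
                    if b - a >= 1:
                        e = node.emit[_IDX[seq[a]]]
                        out = max(out, cost + e + node.t_match
                                  + best(node.children[0], a + 1, b))
                    out = max(out, cost + node.t_delete
                              + best(node.children[0], a, b))
                elif node.kind == "R":
                    if b - a >= 1:
                        e = node.emit[_IDX[seq[b - 1]]]
                        out = max(out, cost + e + node.t_match
                                  + best(node.children[0], a, b - 1))
                    out = max(out, cost + node.t_delete
                              + best(node.children[0], a, b))
                elif node.kind == "B":
                    for k in range(a, b + 1):
                        out = max(out, cost + best(node.children[0], a, k)
                                  + best(node.children[1], k, b))
        return out

    return best(cm.root, 0, n)


class TestBuildCm:
    def test_hairpin_topology(self):
        cm = build_cm(aln_of(["GGGAAACCC"] * 2, "(((...)))"))
        assert cm.n_pair_nodes == 3
        assert cm.n_single_nodes == 3
        assert cm.n_bifurcations == 0

    def test_two_hairpins_one_bifurcation(self):
        cm = build_cm(aln_of(["GGAAAACCGGAAAACC"] * 2, "((....))((....))"))
        assert cm.n_bifurcations == 1

    def test_model_length_is_alignment_length(self):
        aln = aln_of(["GG-AAACC", "GGCAAACC"], "((....))")
        assert build_cm(aln).model_length == 8

    def test_unbalanced_ss_cons_rejected(self):
        import pytest
        from rfamforge.seqio import StructureError

        with pytest.raises(StructureError):
            aln_of(["GGGAAACCC"] * 2, "(((...)()")

    def test_json_round_trip(self, tmp_path):
        cm = build_cm(aln_of(["GGGAAACCC"] * 2, "(((...)))"))
        p = tmp_path / "m.json"
        cm.to_json(p)
        back = CovarianceModel.from_json(p)
        assert score_cm(back, "GGGAAACCC") == score_cm(cm, "GGGAAACCC")


class TestScoreCm:
    def test_member_beats_shuffles(self):
        """Training member scores above each of 20 dinucleotide shuffles."""
        member = "GGCGCAAAGCGCCATAGGGCGTTTCGCCC"
        ss = "(((((...)))))...(((((...)))))"
        cm = build_cm(aln_of([member, member], ss))
        m_bits = score_cm(cm, member)
        rng = random.Random(11)
        wins = sum(
            1 for _ in range(20)
            if m_bits > score_cm(cm, dinucleotide_shuffle(member, rng))
        )
        assert wins == 20

    def test_compensatory_beats_pair_violations(self):
        member = "GGGGAAACCCC"
        ss = "((((...))))"
        cm = build_cm(aln_of([member, member], ss))
        compensatory = "CCCCAAAGGGG"  # every pair swapped, still canonical
        violating = "GGGGAAAGGGG"     # every pair broken
        assert score_cm(cm, compensatory) > score_cm(cm, violating)

    def test_cyk_matches_parse_enumeration(self):
        """CYK equals exhaustive parse enumeration for models up to 12
        columns and sequences up to 12 nt."""
        rng = random.Random(31)
        cases = [
            (["GGGAAACCC"] * 2, "(((...)))"),
            (["GAAACGAAAAC"] * 2, "(...)(....)"),  # bifurcation
            (["GCAAAAGCAGCA"] * 2, "((....))...."),
            (["AGGGAAACCCTA", "AGGTAAAACCTA"], ".(((...))).."),
        ]
        for seqs, ss in cases:
            cm = build_cm(aln_of(seqs, ss))
            for _ in range(6):
                s = random_seq(rng, rng.randint(4, 12))
                assert score_cm(cm, s) == pytest.approx(
                    cyk_oracle(cm, s), abs=1e-6
                ), (ss, s)


class TestScanCm:
    @pytest.fixture(scope="class")
    @staticmethod
    def model_and_genome():
        member = "GGCGGGAAACCCGCCAAGGGCGAAAGCCCTT"
        ss = "(((((...)))))..((((.....)))).."
        cm = build_cm(aln_of([member, member], ss + "."))
        rng = random.Random(12)
        g = random_seq(rng, 3000)
        genome = SequenceRecord(
            "g", g[:800] + member + g[800:1600] + member + g[1600:2400] + member + g[2400:]
        )
        truth = [(800, 831), (1631, 1662), (2462, 2493)]
        return cm, genome, member, truth

    def test_planted_members_rank_first(self, model_and_genome):
        cm, genome, member, truth = model_and_genome
        hits = scan_cm(cm, [genome])
        top3 = {(h.locus.start, h.locus.end) for h in hits[:3]}
        assert top3 == set(truth)

    def test_best_fifty_truncation(self):
        member = "GGGGGAAACCCCC"
        ss = "(((((...)))))"
        cm = build_cm(aln_of([member, member], ss))
        rng = random.Random(33)
        spacer = lambda: "".join(rng.choice("AT") for _ in range(12))
        genome = SequenceRecord("g", spacer() + (member + spacer()) * 60)
        hits = scan_cm(cm, [genome])
        assert len(hits) == 50
        assert [h.rank for h in hits] == list(range(1, 51))

    def test_strand_symmetry(self, model_and_genome):
        cm, genome, member, truth = model_and_genome
        rc = SequenceRecord("g", reverse_complement(genome.sequence))
        fwd = {(h.locus.start, h.locus.end) for h in scan_cm(cm, [genome])[:3]}
        rev = scan_cm(cm, [rc])[:3]
        n = len(genome)
        mapped = {(n - h.locus.end, n - h.locus.start) for h in rev}
        assert mapped == fwd
        assert all(h.locus.strand == "-" for h in rev)

    def test_deterministic(self, model_and_genome):
        cm, genome, *_ = model_and_genome
        a = [(h.locus, h.bits) for h in scan_cm(cm, [genome])]
        b = [(h.locus, h.bits) for h in scan_cm(cm, [genome])]
        assert a == b
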