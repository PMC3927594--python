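"""Motif DSL parsing and the constrained-folding scanner."""

import itertools
import random

import pytest

from rfamforge.seqio import SequenceRecord
from rfamforge.rnastruct import can_pair, structure_energy, mfe_fold
from rfamforge.tdm import (
    MotifParseError,
    motif_from_structure,
    multi_module_classify,
    parse_motif,
    tdm_scan,
    terminator_mask,
)

from conftest import random_seq


class TestParseMotif:
    def test_three_module_asd_motif(self):
        spec = parse_motif("hairpin{stem 4..8; loop 9..12 motif CCUCCUCCC} x3")
        assert spec.module_count == 3
        assert all(m.loop.motif == "CCTCCTCCC" for m in spec.modules)
        assert spec.modules[0].stem.min_bp == 4
        assert spec.modules[0].stem.max_bp == 8

    def test_single_module_gaugua(self):
        spec = parse_motif("hairpin{stem 3..6; loop 6..8 motif GAUGUA}")
        assert spec.module_count == 1
        assert spec.modules[0].loop.motif == "GATGTA"

    def test_motif_longer_than_loop_rejected(self):
        with pytest.raises(MotifParseError):
            parse_motif("hairpin{stem 3..6; loop 4..5 motif GAUGUAGG}")

    def test_explicit_spacer(self):
        spec = parse_motif(
            "hairpin{stem 3..5; loop 4..6}; spacer 2..9; hairpin{stem 3..5; loop 4..6}"
        )
        assert spec.module_count == 2
        assert (spec.spacers[0].min_len, spec.spacers[0].max_len) == (2, 9)

    def test_garbage_rejected_with_position(self):
        with pytest.raises(MotifParseError):
            parse_motif("hairpin{stem 3..5 loop}")


def _constraint_check(spec, seq, hit):
    """Independent validator: every reported hit satisfies the motif."""
    from rfamforge.tdm import _IUPAC

    assert len(hit.boundaries) == spec.module_count
    for (a, b), mod in zip(hit.boundaries, spec.modules):
        sub = seq[a:b]
        matched = False
        for k in range(mod.stem.min_bp, mod.stem.max_bp + 1):
            m = len(sub) - 2 * k
            if not (mod.loop.min_len <= m <= mod.loop.max_len):
                continue
            if not all(can_pair(sub[t], sub[-1 - t]) for t in range(k)):
                continue
            loop = sub[k : k + m]
            if mod.loop.motif:
                lm = len(mod.loop.motif)
                if not any(
                    all(c in _IUPAC[mc] for mc, c in zip(mod.loop.motif, loop[o : o + lm]))
                    for o in range(m - lm + 1)
                ):
                    continue
            matched = True
        assert matched, (sub, mod)


class TestTdmScan:
    def test_planted_hairpin_exact_boundaries(self):
        """The 19-nt planted stem+motif hairpin is found with exact
        boundaries and the energy of its constrained structure."""
        rng = random.Random(14)
        bg = "".join(rng.choice("AT") for _ in range(200))
        planted = "GCGCG" + "CCTCCTCCC" + "CGCGC"
        rec = SequenceRecord("t", bg[:100] + planted + bg[100:])
        spec = parse_motif("hairpin{stem 5..5; loop 9..9 motif CCUCCUCCC}")
        hits = tdm_scan(spec, [rec])
        assert [(h.locus.start, h.locus.end) for h in hits] == [(100, 119)]
        want = structure_energy(planted, "(((((.........)))))")
        assert hits[0].energy == pytest.approx(want)

    def test_random_genome_without_motif_no_hits(self):
        rng = random.Random(14)
        rec = SequenceRecord("r", random_seq(rng, 5000))
        spec = parse_motif("hairpin{stem 5..5; loop 9..9 motif CCUCCUCCC}")
        assert tdm_scan(spec, [rec]) == []

    def test_hits_satisfy_constraints_postchecked(self):
        rng = random.Random(15)
        spec = parse_motif("hairpin{stem 3..6; loop 4..8}")
        rec = SequenceRecord("g", random_seq(rng, 800))
        for h in tdm_scan(spec, [rec], ceiling=-1.0):
            assert h.strand in "+-"
            seq = rec.sequence
            if h.strand == "-":
                from rfamforge.seqio import reverse_complement

                seq = reverse_complement(rec.sequence)
                bounds = [(len(seq) - b, len(seq) - a) for a, b in reversed(h.boundaries)]
                h.boundaries = bounds
            _constraint_check(spec, seq, h)

    def test_matches_exhaustive_enumeration_small(self):
        """On sequences <= 25 nt the best reported energy equals a brute
        force over all (window, stem length, loop length) realisations."""
        from rfamforge.seqio import reverse_complement

        rng = random.Random(16)
        spec = parse_motif("hairpin{stem 3..6; loop 3..8}")
        for _ in range(40):
            fwd = random_seq(rng, rng.randint(10, 25))
            best = None
            for seq in (fwd, reverse_complement(fwd)):
                best = self._brute_best(seq, best)
            hits = tdm_scan(spec, [SequenceRecord("x", fwd)], ceiling=-0.5)
            got = min((h.energy for h in hits), default=None)
            if best is None or best > -0.5:
                assert got is None or got > -0.5
            else:
                assert got == pytest.approx(best), fwd

    @staticmethod
    def _brute_best(seq, best):
        for s in range(len(seq)):
                for k in range(3, 7):
                    for m in range(3, 9):
                        e = s + 2 * k + m
                        if e > len(seq):
                            continue
                        if not all(
                            can_pair(seq[s + t], seq[e - 1 - t]) for t in range(k)
                        ):
                            continue
                        en = structure_energy(
                            seq[s:e], "(" * k + "." * m + ")" * k
                        )
                        if best is None or en < best:
                            best = en
        return best

    def test_relaxing_bounds_monotone(self):
        """Widening the stem range never loses hits."""
        rng = random.Random(19)
        rec = SequenceRecord("g", random_seq(rng, 600))
        tight = parse_motif("hairpin{stem 4..5; loop 4..6}")
        loose = parse_motif("hairpin{stem 3..7; loop 4..6}")
        tight_hits = {
            (h.locus.start, h.locus.end, h.locus.strand)
            for h in tdm_scan(tight, [rec], ceiling=-2.0)
        }
        loose_loci = [h.locus for h in tdm_scan(loose, [rec], ceiling=-2.0)]
        # every tight hit region is covered by some loose hit
        from rfamforge.homsearch import Locus

        for s, e, st in tight_hits:
            assert any(
                l.strand == st and l.overlap(Locus("g", s, e, st)) > 0
                for l in loose_loci
            )


class TestMultiModule:
    def _array_genome(self):
        rng = random.Random(15)
        bg = "".join(rng.choice("AT") for _ in range(400))
        mod = "GGCGC" + "CCTCCTCCC" + "GCGCC"
        arr4 = mod + "ATAT" + mod + "TATA" + mod + "ATTA" + mod
        return SequenceRecord("a", bg[:200] + arr4 + bg[200:]), 200, 200 + len(arr4)

    def test_four_module_array_classified_once(self):
        rec, a, b = self._array_genome()
        base = parse_motif("hairpin{stem 4..6; loop 9..11 motif CCUCCUCCC}")
        lists = {
            k: tdm_scan(base.with_module_count(k), [rec], ceiling=-5.0)
            for k in (2, 3, 4)
        }
        resolved = multi_module_classify(lists)
        assert len(resolved) == 1
        assert resolved[0].module_count == 4
        # boundaries may stretch by a base when background happens to
        # extend a stem within the allowed range
        assert abs(resolved[0].locus.start - a) <= 2
        assert abs(resolved[0].locus.end - b) <= 2

    def test_disjoint_arrays_kept_separately(self):
        rng = random.Random(20)
        bg = "".join(rng.choice("AT") for _ in range(300))
        mod = "GGCGC" + "CCTCCTCCC" + "GCGCC"
        arr2 = mod + "ATAT" + mod
        rec = SequenceRecord("d", bg[:100] + arr2 + bg[100:200] + arr2 + bg[200:])
        base = parse_motif("hairpin{stem 4..6; loop 9..11 motif CCUCCUCCC}")
        lists = {2: tdm_scan(base.with_module_count(2), [rec], ceiling=-5.0)}
        resolved = multi_module_classify(lists)
        assert len(resolved) == 2
        assert all(h.module_count == 2 for h in resolved)

    def test_no_overlap_identity(self):
        rec, *_ = self._array_genome()
        base = parse_motif("hairpin{stem 4..6; loop 9..11 motif CCUCCUCCC}")
        only4 = tdm_scan(base.with_module_count(4), [rec], ceiling=-5.0)
        resolved = multi_module_classify({4: only4})
        assert [(h.locus, h.energy) for h in resolved] == [
            (h.locus, h.energy) for h in only4
        ]


class TestTerminatorMask:
    def test_terminator_pattern_masked(self):
        seq = "AAAA" + "GGGGCGC" + "AAAA" + "GCGCCCC" + "TTTTT" + "AAAA"
        masked = terminator_mask([SequenceRecord("m", seq)])
        assert "m" in masked
        (a, b), = masked["m"]
        assert a <= 4 and b >= len(seq) - 5

    def test_at_only_sequence_unmasked(self):
        assert terminator_mask([SequenceRecord("m", "ATATATATATATATAT")]) == {}

    def test_masking_off_scan_unchanged(self):
        rng = random.Random(22)
        bg = "".join(rng.choice("AT") for _ in range(150))
        planted = "GCGCG" + "CCTCCTCCC" + "CGCGC"
        rec = SequenceRecord("t", bg[:70] + planted + bg[70:])
        spec = parse_motif("hairpin{stem 5..5; loop 9..9 motif CCUCCUCCC}")
        with_none = tdm_scan(spec, [rec], mask=None)
        with_empty = tdm_scan(spec, [rec], mask={})
        assert [(h.locus, h.energy) for h in with_none] == [
            (h.locus, h.energy) for h in with_empty
        ]


class TestDerivedMotif:
    def test_round_trip_pivot_recovery(self):
        """A motif derived from a folded transcript finds that transcript."""
        seq = "GGCGCCCTCCTCCCGCGCC"
        db = mfe_fold(seq).dotbracket
        spec = motif_from_structure(seq, db)
        hits = tdm_scan(spec, [SequenceRecord("self", seq)], ceiling=0.0)
        assert hits
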