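"""Funnel thresholds, synteny evidence, plausibility and pruning."""

import random

import pandas as pd
import pytest

from rfamforge.seqio import (
    AnnotationRecord,
    RepliconClass,
    SequenceRecord,
)
from rfamforge.homsearch import Candidate, CandidateStatus, Locus, Provenance
from rfamforge.rnastruct import PointedShape, mfe_fold, pointed_shape
from rfamforge.assess import (
    AssessmentConfig,
    FamilyMember,
    assess_candidates,
    auto_accept,
    plausibility_flags,
    prefilter,
    prune_outliers,
    score_candidate,
    synteny_support,
)
from rfamforge.synthetic import evolve_member, simulate_ancestor

from conftest import random_seq


def mk_cand(loc_value=None, sci_value=None, shape=None, cid="c1"):
    c = Candidate(cid, Locus("g", 100, 180), "ACGT" * 20,
                  Provenance.SEEDED_SEARCH)
    if loc_value is not None:
        c.ledger["loc"] = loc_value
    if sci_value is not None:
        c.ledger["sci"] = sci_value
    if shape is not None:
        c.ledger["pointed_shape"] = shape
    return c


class TestPrefilter:
    def test_strictly_above_threshold_retained(self):
        c = mk_cand(34.0)
        assert prefilter(100.0, [c]) == [c]
        assert c.status is CandidateStatus.RETAINED

    def test_boundary_value_dropped(self):
        c = mk_cand(33.0)
        assert prefilter(100.0, [c]) == []
        assert c.status is CandidateStatus.DISCARDED

    def test_self_equal_score_retained(self):
        c = mk_cand(100.0)
        assert prefilter(100.0, [c]) == [c]

    def test_missing_ledger_is_error(self):
        with pytest.raises(ValueError):
            prefilter(100.0, [mk_cand()])


class TestAutoAccept:
    """The three-condition rule is threshold-sharp: flipping any one
    criterion across its boundary flips the outcome."""

    PIVOT = "GGGAAACCC"

    def _shape(self, like_pivot=True):
        ps = pointed_shape(mfe_fold(self.PIVOT).dotbracket)
        if like_pivot:
            return ps
        return PointedShape("[][]", [ps.centers[0], ps.centers[0] + 10])

    def _check(self, ratio, sci_v, good_shape):
        cfg = AssessmentConfig()
        c = mk_cand(ratio * 42.0, sci_v, self._shape(good_shape))
        return auto_accept(self.PIVOT, c, cfg, loc_self=42.0)

    def test_all_three_pass(self):
        assert self._check(0.76, 0.91, True) is True

    def test_sci_boundary_fails(self):
        assert self._check(0.76, 0.89, True) is False
        assert self._check(0.76, 0.90, True) is False  # strict >

    def test_loc_ratio_boundary(self):
        assert self._check(0.74, 0.95, True) is False
        assert self._check(0.76, 0.95, True) is True

    def test_shape_mismatch_fails(self):
        assert self._check(0.90, 0.95, False) is False

    def test_center_tolerance(self):
        cfg = AssessmentConfig(center_tolerance_nt=2.0)
        ps = pointed_shape(mfe_fold(self.PIVOT).dotbracket)
        shifted = PointedShape(ps.shape, [c + 2 for c in ps.centers])
        too_far = PointedShape(ps.shape, [c + 3 for c in ps.centers])
        c1 = mk_cand(40.0, 0.95, shifted)
        c2 = mk_cand(40.0, 0.95, too_far)
        assert auto_accept(self.PIVOT, c1, cfg, loc_self=42.0) is True
        assert auto_accept(self.PIVOT, c2, cfg, loc_self=42.0) is False

    def test_missing_entry_raises(self):
        with pytest.raises(ValueError):
            auto_accept(self.PIVOT, mk_cand(40.0), AssessmentConfig())


def _orf(rng, n_codons=40):
    stops = {"TAA", "TAG", "TGA"}
    out = ["ATG"]
    for _ in range(n_codons):
        while True:
            c = random_seq(rng, 3)
            if c not in stops:
                out.append(c)
                break
    out.append("TAA")
    return "".join(out)


class TestSyntenySupport:
    def _fixture(self, conserve=True):
        """Member genome and candidate genome; candidate's flanks are
        either copies of the member's markers or unrelated ORFs."""
        rng = random.Random(9)
        up, down = _orf(rng), _orf(rng)
        srna = random_seq(rng, 60)
        g1seq = random_seq(rng, 200) + up + random_seq(rng, 25) + srna \
            + random_seq(rng, 25) + down + random_seq(rng, 200)
        g1 = SequenceRecord("m1", g1seq)
        m_start = 200 + len(up) + 25
        member_locus = Locus("m1", m_start, m_start + 60, "+")
        if conserve:
            up2, down2 = up, down
        else:
            up2, down2 = _orf(rng), _orf(rng)
        cand_srna = random_seq(rng, 60)
        g2seq = random_seq(rng, 150) + up2 + random_seq(rng, 20) + cand_srna \
            + random_seq(rng, 20) + down2 + random_seq(rng, 150)
        g2 = SequenceRecord("c1", g2seq)
        c_start = 150 + len(up2) + 20
        cand = Candidate("cand", Locus("c1", c_start, c_start + 60, "+"),
                         cand_srna, Provenance.SEEDED_SEARCH)
        anns = [
            AnnotationRecord("m_up", "m1", 201, 200 + len(up), "+"),
            AnnotationRecord("m_down", "m1", m_start + 60 + 25 + 1,
                             m_start + 60 + 25 + len(down), "+"),
            AnnotationRecord("c_up", "c1", 151, 150 + len(up2), "+"),
            AnnotationRecord("c_down", "c1", c_start + 60 + 20 + 1,
                             c_start + 60 + 20 + len(down2), "+"),
        ]
        genomes = {"m1": g1, "c1": g2}
        return cand, [member_locus], anns, genomes

    def test_conserved_flanks_accept(self):
        cand, mloci, anns, genomes = self._fixture(conserve=True)
        ev = synteny_support(cand, mloci, anns, genomes)
        assert ev.flank_up_conserved and ev.flank_down_conserved
        assert ev.supported

    def test_shuffled_flanks_no_support(self):
        cand, mloci, anns, genomes = self._fixture(conserve=False)
        ev = synteny_support(cand, mloci, anns, genomes)
        assert not ev.supported

    def test_one_flank_suffices_at_replicon_end(self):
        cand, mloci, anns, genomes = self._fixture(conserve=True)
        # drop the candidate's upstream gene annotation entirely
        anns = [a for a in anns if a.gene_id != "c_up"]
        ev = synteny_support(cand, mloci, anns, genomes)
        assert not ev.flank_up_present
        assert ev.flank_down_conserved
        assert ev.supported


class TestPlausibility:
    TAX = pd.DataFrame(
        [
            ("orgA", "st1", "sp1", "gen1", "fam1", "ord1"),
            ("orgB", "st2", "sp1", "gen1", "fam1", "ord1"),
            ("orgC", "st3", "sp9", "gen9", "fam9", "ord1"),
        ],
        columns=["organism", "strain", "species", "genus", "family", "order"],
    )

    def _cand(self, seqid):
        return Candidate("c", Locus(seqid, 0, 50), "ACGT" * 15,
                         Provenance.SEEDED_SEARCH)

    def test_lone_remote_discarded(self):
        meta = {
            "gA": ("orgA", RepliconClass.CHROMOSOME),
            "gC": ("orgC", RepliconClass.CHROMOSOME),
        }
        flags = plausibility_flags(
            self._cand("gC"), [Locus("gA", 0, 50)], self.TAX, meta
        )
        assert "LONE_REMOTE" in flags

    def test_replicon_mismatch_same_species(self):
        meta = {
            "gA": ("orgA", RepliconClass.CHROMOSOME),
            "gB": ("orgB", RepliconClass.ACCESSORY_PLASMID),
        }
        flags = plausibility_flags(
            self._cand("gB"), [Locus("gA", 0, 50)], self.TAX, meta
        )
        assert "REPLICON_MISMATCH" in flags

    def test_same_species_same_replicon_clean(self):
        meta = {
            "gA": ("orgA", RepliconClass.CHROMOSOME),
            "gB": ("orgB", RepliconClass.CHROMOSOME),
        }
        flags = plausibility_flags(
            self._cand("gB"), [Locus("gA", 0, 50)], self.TAX, meta
        )
        assert flags == []

    def test_missing_taxonomy_is_error(self):
        meta = {"gX": ("orgX", RepliconClass.CHROMOSOME)}
        with pytest.raises(KeyError):
            plausibility_flags(self._cand("gX"), [], self.TAX, meta)


class TestPruneOutliers:
    def _members(self, n=5, seed=10):
        anc = simulate_ancestor(60, 2, seed=seed)
        out = [FamilyMember("m0", anc.sequence)]
        for k in range(1, n):
            hom = evolve_member(anc, 0.15, seed=seed + k)
            out.append(FamilyMember(f"m{k}", hom.sequence))
        return out

    def test_planted_random_outlier_removed(self):
        rng = random.Random(10)
        members = self._members(5)
        members.append(FamilyMember("junk", random_seq(rng, 60)))
        pruned = prune_outliers(members)
        ids = {m.id for m in pruned}
        assert "junk" not in ids
        assert {"m0", "m1", "m2", "m3", "m4"} <= ids

    def test_homogeneous_family_untouched(self):
        members = self._members(4)
        assert len(prune_outliers(members)) == 4

    def test_idempotent(self):
        rng = random.Random(10)
        members = self._members(5)
        members.append(FamilyMember("junk", random_seq(rng, 60)))
        once = prune_outliers(members)
        twice = prune_outliers(once)
        assert [m.id for m in once] == [m.id for m in twice]

    def test_small_families_passed_through(self):
        members = self._members(2)
        assert prune_outliers(members) == members


class TestConfigValidation:
    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            AssessmentConfig(prefilter_ratio=0.8, accept_ratio=0.75)

    def test_sci_range(self):
        with pytest.raises(ValueError):
            AssessmentConfig(sci_min=1.5)
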