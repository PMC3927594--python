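"""The candidate-selection funnel.

Putative homologs of a pivot sRNA S pass through ordered stages, each
recording its evidence in the candidate's ledger:

1. **prefilter** — keep c only if loc(S, c) > 0.33 * loc(S, S)
   (strict), trading inspection effort against loss of true homologs;
2. **structural auto-accept** — c qualifies without further evidence if
   loc(S, c) > 0.75 * loc(S, S), sci(S, c) > 0.9, and the pointed
   shapes agree (same abstract shape, hairpin centers within a small
   tolerance);
3. **synteny** — otherwise c is accepted when at least one of its
   flanking protein-coding genes is homologous (protein-level
   E <= 1e-6) to the corresponding flank of an already accepted member;
4. **phylogenetic/replicon plausibility** — accepted candidates are
   discarded (by default) when they sit on a different replicon class
   in a strain of the same species as a member, or when they are the
   lone hit in a remote taxonomic group;
5. **outlier pruning** — members whose row in the multiple structural
   alignment realises too few consensus pairs are removed one at a
   time, recomputing the alignment after each removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .seqio import (
    AnnotationRecord,
    RepliconClass,
    SequenceRecord,
    StockholmAlignment,
    reverse_complement,
)
from .homsearch import Candidate, CandidateStatus, Locus, PivotTranscript, evalue
from .rnastruct import can_pair, consensus_fold, mfe_fold, map_consensus_to_row, pointed_shape
from .structalign import LocConfig, loc_score, sci, star_alignment

__all__ = [
    "AssessmentConfig",
    "SyntenyEvidence",
    "FamilyMember",
    "RnaFamilyModel",
    "prefilter",
    "score_candidate",
    "auto_accept",
    "protein_local_align",
    "synteny_support",
    "plausibility_flags",
    "prune_outliers",
    "assess_candidates",
    "nearest_flanks",
]


@dataclass(frozen=True)
class AssessmentConfig:
    """Thresholds of the selection funnel."""

    prefilter_ratio: float = 0.33
    accept_ratio: float = 0.75
    sci_min: float = 0.9
    synteny_evalue_max: float = 1e-6
    center_tolerance_nt: float = 2.0
    agreement_min: float = 0.5        # outlier pruning threshold
    discard_flagged: bool = True      # plausibility flags discard by default
    cds_overlap_frac_max: float = 0.5  # candidates mostly inside a gene drop
    flank_max_dist_nt: int = 300       # a gene farther away is not "adjacent"
    loc: LocConfig = field(default_factory=LocConfig)

    def __post_init__(self):
        if not (0 < self.prefilter_ratio < self.accept_ratio <= 1):
            raise ValueError("need 0 < prefilter_ratio < accept_ratio <= 1")
        if not (0 < self.sci_min <= 1):
            raise ValueError("sci_min must be in (0, 1]")


DEFAULT_CONFIG = AssessmentConfig()


@dataclass
class SyntenyEvidence:
    candidate_id: str
    flank_up_conserved: bool = False
    flank_down_conserved: bool = False
    evalue_up: float | None = None
    evalue_down: float | None = None
    flank_up_present: bool = True
    flank_down_present: bool = True

    @property
    def supported(self) -> bool:
        return self.flank_up_conserved or self.flank_down_conserved


@dataclass
class FamilyMember:
    id: str
    sequence: str
    locus: Locus | None = None
    provenance: str = "pivot"
    scores: dict = field(default_factory=dict)


@dataclass
class RnaFamilyModel:
    """A family: accepted members plus their structural summary."""

    family_id: str
    pivot: PivotTranscript
    members: list[FamilyMember] = field(default_factory=list)
    microsynteny_type: str = "NA"
    sci_value: float | None = None
    cm: object | None = None

    def __post_init__(self):
        if not self.members:
            self.members.append(
                FamilyMember(self.pivot.name, self.pivot.sequence, self.pivot.locus)
            )

    def add_member(self, sequence: str, locus: Locus | None, provenance: str = "",
                   **scores) -> FamilyMember:
        m = FamilyMember(
            id=f"{self.family_id}_m{len(self.members)}",
            sequence=sequence,
            locus=locus,
            provenance=provenance,
            scores=scores,
        )
        self.members.append(m)
        return m

    def build_alignment(self, cfg: LocConfig | None = None) -> StockholmAlignment:
        """Multiple structural alignment (star, pivot-centred) with the
        consensus structure as SS_cons."""
        cfg = cfg or LocConfig()
        rows = [m.sequence for m in self.members]
        if len(rows) == 1:
            s = mfe_fold(rows[0])
            return StockholmAlignment(
                rows={self.members[0].id: rows[0]}, ss_cons=s.dotbracket
            )
        aligned = star_alignment(rows, cfg)
        ss, _e = consensus_fold(aligned)
        return StockholmAlignment(
            rows={m.id: r for m, r in zip(self.members, aligned)}, ss_cons=ss
        )

    def family_sci(self, cfg: LocConfig | None = None) -> float:
        if len(self.members) < 2:
            return float("nan")
        aln = self.build_alignment(cfg)
        v = sci(list(aln.rows.values()), aligned=True)
        self.sci_value = v.value
        return v.value


# --- stage 1: prefilter --------------------------------------------------

def prefilter(
    loc_self: float, candidates: list[Candidate], config: AssessmentConfig = DEFAULT_CONFIG
) -> list[Candidate]:
    """Retain candidates with loc(S, c) strictly above the prefilter
    fraction of the self-score; others are discarded with a reason."""
    retained = []
    for c in candidates:
        if "loc" not in c.ledger:
            raise ValueError(f"candidate {c.id}: loc score missing from ledger")
        if c.ledger["loc"] > config.prefilter_ratio * loc_self:
            c.advance(CandidateStatus.RETAINED)
            retained.append(c)
        else:
            c.advance(CandidateStatus.DISCARDED, reason="prefilter_loc_ratio")
    return retained


# --- stage 2: structural auto-accept -------------------------------------

def score_candidate(
    pivot_seq: str, cand: Candidate, config: AssessmentConfig = DEFAULT_CONFIG
) -> None:
    """Fill the candidate's ledger with loc, sci and pointed shapes.

    The pairwise consensus structure is mapped back onto the pivot row,
    giving the candidate-conditioned pointed shape p(S, c) that is
    compared against p(S, S) from the pivot's MFE structure.
    """
    res = loc_score(pivot_seq, cand.sequence, config.loc)
    cand.ledger["loc"] = res.score
    aln = [res.aligned_a, res.aligned_b]
    singles = [mfe_fold(r.replace("-", "")).energy for r in aln]
    mean_mfe = sum(singles) / len(singles)
    ss_cons, cons_e = consensus_fold(aln)
    cand.ledger["sci"] = 0.0 if mean_mfe == 0 else round(cons_e / mean_mfe, 10)
    mapped = map_consensus_to_row(res.aligned_a, ss_cons)
    cand.ledger["pointed_shape"] = pointed_shape(mapped.dotbracket)


def auto_accept(
    pivot_seq: str, cand: Candidate, config: AssessmentConfig = DEFAULT_CONFIG,
    loc_self: float | None = None,
) -> bool:
    """The three-condition structural acceptance test.

    True iff loc(S,c) > accept_ratio * loc(S,S), sci(S,c) > sci_min, and
    p(S,c) equals p(S,S) (same shape string, centers within tolerance).
    """
    for key in ("loc", "sci", "pointed_shape"):
        if key not in cand.ledger:
            raise ValueError(f"candidate {cand.id}: {key} missing from ledger")
    if loc_self is None:
        loc_self = loc_score(pivot_seq, pivot_seq, config.loc).score
    p_self = pointed_shape(mfe_fold(pivot_seq).dotbracket)
    ok = (
        cand.ledger["loc"] > config.accept_ratio * loc_self
        and cand.ledger["sci"] > config.sci_min
        and cand.ledger["pointed_shape"].matches(p_self, config.center_tolerance_nt)
    )
    return ok


# --- stage 3: synteny ----------------------------------------------------

_BLOSUM = substitution_matrices.load("BLOSUM62")
# published gapped Karlin-Altschul constants for BLOSUM62 (open 11, ext 1)
_PROT_LAMBDA = 0.267
_PROT_K = 0.041


def protein_local_align(a: str, b: str, gap_open: float = 11.0,
                        gap_extend: float = 1.0) -> float:
    """Smith-Waterman score of two protein sequences under BLOSUM62."""
    na, nb = len(a), len(b)
    NEG = float("-inf")
    best = 0.0
    M = [[0.0] * (nb + 1) for _ in range(na + 1)]
    Ix = [[NEG] * (nb + 1) for _ in range(na + 1)]
    Iy = [[NEG] * (nb + 1) for _ in range(na + 1)]
    for i in range(1, na + 1):
        ai = a[i - 1]
        for j in range(1, nb + 1):
            Ix[i][j] = max(M[i - 1][j] - gap_open, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - gap_open, Iy[i][j - 1] - gap_extend)
            try:
                s = _BLOSUM[ai, b[j - 1]]
            except (KeyError, IndexError):
                s = -1.0
            v = max(0.0, M[i - 1][j - 1] + s, Ix[i][j], Iy[i][j])
            M[i][j] = v
            if v > best:
                best = v
    return best


def _translate(gene: AnnotationRecord, genome: SequenceRecord) -> str:
    seq = genome.sequence[gene.start - 1 : gene.end]
    if gene.strand == "-":
        seq = reverse_complement(seq)
    seq = seq[: len(seq) - len(seq) % 3]
    return str(Seq(seq).translate()).rstrip("*")


def cds_overlap_frac(locus: Locus, annotations: list[AnnotationRecord]) -> float:
    """Largest fraction of the locus covered by one annotated gene.

    Trans-encoded sRNAs lie at loci distinct from protein-coding genes;
    a candidate sitting mostly inside an annotated ORF is a protein-gene
    hit (e.g. a conserved flanking marker), not an sRNA homolog.
    """
    best = 0.0
    for a in annotations:
        if a.seqid != locus.seqid:
            continue
        ov = max(0, min(locus.end, a.end) - max(locus.start, a.start - 1))
        if ov / len(locus) > best:
            best = ov / len(locus)
    return best


def nearest_flanks(
    locus: Locus,
    annotations: list[AnnotationRecord],
    exclude_overlapping: bool = True,
    max_dist: int | None = None,
) -> tuple[AnnotationRecord | None, AnnotationRecord | None]:
    """Nearest non-overlapping protein-coding gene on each side of a locus.

    With ``max_dist`` set, a gene whose nearest edge lies farther than
    that from the locus does not count as adjacent (bacterial neighbours
    sit within a few hundred bases; an unbounded lookup would let a
    distant gene masquerade as a conserved flank in sparse annotation).
    """
    up = down = None
    for a in annotations:
        if a.seqid != locus.seqid:
            continue
        if max_dist is not None:
            gap = max(locus.start - a.end, (a.start - 1) - locus.end)
            if gap > max_dist:
                continue
        a0, a1 = a.start - 1, a.end  # to 0-based half-open
        overlaps = a1 > locus.start and a0 < locus.end
        if overlaps and exclude_overlapping:
            continue
        if a1 <= locus.start or (overlaps and a0 < locus.start):
            if up is None or a1 > up.end:
                up = a
        elif a0 >= locus.end or overlaps:
            if down is None or a0 < down.start - 1:
                down = a
    if locus.strand == "-":
        up, down = down, up
    return up, down


def synteny_support(
    cand: Candidate,
    member_loci: list[Locus],
    annotations: list[AnnotationRecord],
    genomes: dict[str, SequenceRecord],
    config: AssessmentConfig = DEFAULT_CONFIG,
) -> SyntenyEvidence:
    """Flanking-gene conservation of a candidate against accepted members.

    A flank counts as conserved when its translated product aligns to
    the corresponding flank of at least one member with protein-level
    E <= the synteny threshold.  A side with no annotated gene is
    *absent*, not failing; one conserved flank suffices for acceptance.
    """
    ev = SyntenyEvidence(candidate_id=cand.id)
    dmax = config.flank_max_dist_nt
    c_up, c_down = nearest_flanks(cand.locus, annotations, max_dist=dmax)
    ev.flank_up_present = c_up is not None
    ev.flank_down_present = c_down is not None
    member_flanks = [
        (l, nearest_flanks(l, annotations, max_dist=dmax)) for l in member_loci
    ]
    for side, c_gene in (("up", c_up), ("down", c_down)):
        if c_gene is None:
            continue
        prot_c = _translate(c_gene, genomes[c_gene.seqid])
        if not prot_c:
            continue
        c_parallel = c_gene.strand == cand.locus.strand
        best_e = None
        for m_locus, (m_up, m_down) in member_flanks:
            m_gene = m_up if side == "up" else m_down
            if m_gene is None:
                continue
            # synteny = conserved order *and* orientation: the flank
            # gene must sit on the same relative strand as it does in
            # the member's context
            if (m_gene.strand == m_locus.strand) != c_parallel:
                continue
            prot_m = _translate(m_gene, genomes[m_gene.seqid])
            if not prot_m:
                continue
            score = protein_local_align(prot_c, prot_m)
            E = evalue(score, len(prot_c), len(prot_m), _PROT_LAMBDA, _PROT_K)
            if best_e is None or E < best_e:
                best_e = E
        if side == "up":
            ev.evalue_up = best_e
        else:
            ev.evalue_down = best_e
        if best_e is not None and best_e <= config.synteny_evalue_max:
            if side == "up":
                ev.flank_up_conserved = True
            else:
                ev.flank_down_conserved = True
    cand.ledger["synteny"] = ev
    return ev


# --- stage 4: plausibility ------------------------------------------------

_LEVELS = ["species", "genus", "family"]


def plausibility_flags(
    cand: Candidate,
    member_loci: list[Locus],
    taxonomy: pd.DataFrame,
    genome_meta: dict[str, tuple[str, RepliconClass]],
) -> list[str]:
    """Phylogeny/replicon sanity flags for an accepted candidate.

    ``taxonomy`` indexes organisms with nested group columns
    (strain < species < genus < family); ``genome_meta`` maps seqid to
    (organism, replicon_class).  Flags:

    * ``REPLICON_MISMATCH`` — same species as a member but a different
      replicon class;
    * ``LONE_REMOTE`` — sole family hit in its family-level group, with
      no hits in any closer group.
    """
    tax = taxonomy.set_index("organism") if "organism" in taxonomy.columns else taxonomy
    org_c, rc_c = genome_meta[cand.locus.seqid]
    if org_c not in tax.index:
        raise KeyError(f"organism {org_c!r} missing from taxonomy table")
    flags: list[str] = []
    member_orgs = []
    for l in member_loci:
        org, rc = genome_meta[l.seqid]
        if org not in tax.index:
            raise KeyError(f"organism {org!r} missing from taxonomy table")
        member_orgs.append((org, rc))
    # replicon consistency within the same species
    sp_c = tax.at[org_c, "species"]
    same_species = [(o, rc) for o, rc in member_orgs if tax.at[o, "species"] == sp_c]
    if same_species and all(rc is not rc_c for _o, rc in same_species):
        flags.append("REPLICON_MISMATCH")
    # lone hit in a remote group
    shared_level = None
    for lvl in _LEVELS:
        g = tax.at[org_c, lvl]
        if any(tax.at[o, lvl] == g for o, _rc in member_orgs):
            shared_level = lvl
            break
    if shared_level is None or shared_level == "family":
        fam_c = tax.at[org_c, "family"]
        hits_in_family_group = sum(
            1 for o, _rc in member_orgs if tax.at[o, "family"] == fam_c
        )
        closer = any(
            tax.at[org_c, lvl] == tax.at[o, lvl]
            for o, _rc in member_orgs
            for lvl in ("species", "genus")
        )
        if hits_in_family_group == 0 and not closer:
            flags.append("LONE_REMOTE")
    cand.ledger.setdefault("flags", []).extend(flags)
    return flags


# --- stage 5: outlier pruning ---------------------------------------------

def _member_agreement(member_seq: str, center_seq: str,
                      center_pairs: list[tuple[int, int]]) -> float:
    """Fraction of consensus pairs a member can realise.

    The consensus pairs (given on the alignment center's ungapped
    positions) are projected onto the member through a *sequence-only*
    semi-global alignment, and count as realised when the projected
    positions are aligned, complementary, and occur in the member's own
    suboptimal folding band.  Projecting through a sequence alignment —
    rather than reading the structural MSA row — is what makes a
    "scattered" member visible: the Sankoff aligner would happily drag
    any sequence's pairable positions onto the consensus stems, whereas
    a true homolog keeps its (compensatory) pairs at sequence-anchored
    positions.
    """
    from .homsearch import semiglobal_align
    from .rnastruct import pair_band_set

    if not center_pairs:
        return 1.0
    res = semiglobal_align(center_seq, member_seq)
    c2m: dict[int, int] = {}
    ci = mi = 0
    span0 = res.cand_span[0]
    mi = span0
    for a, b in zip(res.aligned_ref, res.aligned_cand):
        if a != "-" and b != "-":
            c2m[ci] = mi
        if a != "-":
            ci += 1
        if b != "-":
            mi += 1
    band = pair_band_set(member_seq)
    ok = 0
    slack = 1  # alignment jitter tolerance, in nt
    for i, j in center_pairs:
        mi_, mj_ = c2m.get(i), c2m.get(j)
        if mi_ is None or mj_ is None:
            continue
        if any(
            abs(bi - mi_) <= slack and abs(bj - mj_) <= slack
            for bi, bj in band
        ):
            ok += 1
    return ok / len(center_pairs)


def prune_outliers(
    members: list[FamilyMember],
    cfg: LocConfig | None = None,
    agreement_min: float = 0.5,
    log: list | None = None,
) -> list[FamilyMember]:
    """Remove members that scatter the multiple structural alignment.

    The member realising the smallest fraction of consensus pairs is
    removed while that fraction is below ``agreement_min``; the
    alignment is recomputed after each removal.  Stops rather than
    reduce the family below two members.
    """
    if len(members) < 3:
        return list(members)
    cfg = cfg or LocConfig()
    current = list(members)
    while len(current) > 2:
        aligned = star_alignment([m.sequence for m in current], cfg)
        ss, _ = consensus_fold(aligned)
        center_struct = map_consensus_to_row(aligned[0], ss)
        center_pairs = center_struct.pairs
        center_seq = current[0].sequence
        agreements = [1.0] + [
            _member_agreement(m.sequence, center_seq, center_pairs)
            for m in current[1:]
        ]
        worst = min(range(len(current)), key=lambda k: agreements[k])
        if agreements[worst] >= agreement_min:
            break
        removed = current.pop(worst)
        if log is not None:
            log.append({"removed": removed.id, "agreement": agreements[worst]})
    return current


# --- the full funnel -------------------------------------------------------

def assess_candidates(
    pivot: PivotTranscript,
    candidates: list[Candidate],
    genomes: list[SequenceRecord],
    annotations: list[AnnotationRecord],
    taxonomy: pd.DataFrame | None,
    config: AssessmentConfig = DEFAULT_CONFIG,
    family_id: str | None = None,
) -> tuple[RnaFamilyModel, pd.DataFrame]:
    """Run every funnel stage over raw candidates and build the family.

    Returns the family model (pivot + accepted members, pruned) and a
    per-candidate decision ledger as a DataFrame.
    """
    by_id = {g.id: g for g in genomes}
    genome_meta = {g.id: (g.organism or g.id, g.replicon_class) for g in genomes}
    loc_self = loc_score(pivot.sequence, pivot.sequence, config.loc).score
    fam = RnaFamilyModel(family_id or f"RFM_{pivot.name}", pivot)

    clean: list[Candidate] = []
    for c in candidates:
        if annotations and cds_overlap_frac(c.locus, annotations) > config.cds_overlap_frac_max:
            c.advance(CandidateStatus.DISCARDED, reason="CDS_OVERLAP")
            continue
        clean.append(c)
    for c in clean:
        if "loc" not in c.ledger:
            score_candidate(pivot.sequence, c, config)
    retained = prefilter(loc_self, clean, config)

    accepted: list[Candidate] = []
    needs_synteny: list[Candidate] = []
    for c in retained:
        if auto_accept(pivot.sequence, c, config, loc_self=loc_self):
            c.advance(CandidateStatus.AUTO_ACCEPTED)
            accepted.append(c)
        else:
            needs_synteny.append(c)

    member_loci = [l for l in [pivot.locus] if l is not None] + [
        c.locus for c in accepted
    ]
    for c in needs_synteny:
        if annotations:
            ev = synteny_support(c, member_loci, annotations, by_id, config)
            if ev.supported:
                c.advance(CandidateStatus.SYNTENY_ACCEPTED)
                accepted.append(c)
                member_loci.append(c.locus)
                continue
        c.advance(CandidateStatus.DISCARDED, reason="no_structure_or_synteny_support")

    if taxonomy is not None:
        survivors = []
        for c in accepted:
            flags = plausibility_flags(
                c, [l for l in member_loci if l != c.locus], taxonomy, genome_meta
            )
            if flags and config.discard_flagged:
                c.advance(CandidateStatus.DISCARDED, reason=";".join(flags))
            else:
                survivors.append(c)
        accepted = survivors

    for c in accepted:
        fam.add_member(
            c.sequence, c.locus, provenance=c.provenance.value,
            loc=c.ledger.get("loc"), sci=c.ledger.get("sci"),
        )
    fam.members = prune_outliers(fam.members, config.loc, config.agreement_min)

    ledger = pd.DataFrame(
        [
            {
                "candidate": c.id,
                "locus": f"{c.locus.seqid}:{c.locus.start + 1}-{c.locus.end}"
                f"({c.locus.strand})",
                "provenance": c.provenance.value,
                "status": c.status.value,
                "evalue": c.ledger.get("evalue"),
                "loc": c.ledger.get("loc"),
                "loc_ratio": (c.ledger.get("loc") / loc_self) if loc_self else None,
                "sci": c.ledger.get("sci"),
                "flags": ";".join(c.ledger.get("flags", [])),
            }
            for c in candidates
        ]
    )
    return fam, ledger
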