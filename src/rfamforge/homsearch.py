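"""Phase-1 sequence homology search for sRNA pivots.

The search runs in two complementary modes, mirroring common practice
for short noncoding RNAs:

* ``seeded_search`` — exact-word seeds (default word size 7) extended
  into gapped local alignments under a blastn-like scoring scheme
  (match +2, mismatch -3, affine gaps open 2 / extend 2), reported with
  extreme-value E-values and kept below a stringent threshold
  (default E < 1e-5);
* ``semiglobal_scan`` — a full semi-global alignment of the reference
  against every database record (global in the reference, free terminal
  gaps in the record), which finds diverged homologs that no longer
  share an exact word.

Karlin-Altschul parameters (lambda, K) for both score types are
calibrated empirically: maximal scores on dinucleotide-shuffled decoy
sequences are fitted with a Gumbel distribution (scipy), giving
lambda = 1/scale and K = exp(loc/scale) / (m*n).  The calibration is
seeded and cached per scoring configuration.

Raw hits are post-processed by ``extend_and_trim``: the candidate locus
is widened to cover the region homologous to the whole reference plus
10% of the reference length on each side, then semi-globally aligned to
the reference and trimmed to the aligned span.  ``iterate_search``
repeats the whole search with newly accepted members as extra queries,
for at most three rounds, at the same stringent threshold each round.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache

from scipy import stats

from .seqio import SequenceRecord, RepliconClass, reverse_complement

__all__ = [
    "Locus",
    "PivotTranscript",
    "SeedHit",
    "Candidate",
    "CandidateStatus",
    "Provenance",
    "SearchParams",
    "evalue",
    "calibrate_evd",
    "seeded_search",
    "semiglobal_align",
    "semiglobal_scan",
    "filter_db_by_taxa",
    "extend_and_trim",
    "iterate_search",
    "reciprocal_overlap",
]

_NEG = float("-inf")


@dataclass(frozen=True)
class Locus:
    """A genomic interval, 0-based half-open, stranded."""

    seqid: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid locus {self.seqid}:{self.start}-{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Locus") -> int:
        if self.seqid != other.seqid:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def reciprocal_overlap(a: Locus, b: Locus) -> float:
    """min(overlap/len(a), overlap/len(b)) — the dedup criterion."""
    ov = a.overlap(b)
    if ov == 0:
        return 0.0
    return min(ov / len(a), ov / len(b))


_NAME_CLASS = {
    "A": RepliconClass.CHROMID_MEGAPLASMID,  # pSymA
    "B": RepliconClass.CHROMID_MEGAPLASMID,  # pSymB
    "C": RepliconClass.CHROMOSOME,
}


@dataclass
class PivotTranscript:
    """An experimentally defined sRNA seeding one family model.

    Names follow the SmelXnnn convention, X in {A, B, C} encoding the
    source replicon (megaplasmid pSymA/pSymB or the chromosome).
    """

    name: str
    sequence: str
    locus: Locus | None = None
    replicon_class: RepliconClass = RepliconClass.UNKNOWN

    def __post_init__(self):
        self.sequence = self.sequence.upper().replace("U", "T")
        if (
            self.replicon_class is not RepliconClass.UNKNOWN
            and len(self.name) >= 5
            and self.name.startswith("Smel")
            and self.name[4] in _NAME_CLASS
            and _NAME_CLASS[self.name[4]] is not self.replicon_class
        ):
            raise ValueError(
                f"{self.name}: replicon letter {self.name[4]} inconsistent with "
                f"replicon_class {self.replicon_class.value}"
            )


@dataclass
class SeedHit:
    """One gapped local hit from the seeded search."""

    query_id: str
    locus: Locus
    raw_score: int
    evalue: float
    query_span: tuple[int, int]  # 0-based half-open on the query

    def __post_init__(self):
        if self.evalue <= 0:
            raise ValueError("E-value must be positive")


class Provenance(str, Enum):
    SEEDED_SEARCH = "seeded_search"
    SEMIGLOBAL_SCAN = "semiglobal_scan"
    CM_SCAN = "cm_scan"
    TDM_SCAN = "tdm_scan"


class CandidateStatus(str, Enum):
    RAW = "raw"
    RETAINED = "retained"
    AUTO_ACCEPTED = "auto_accepted"
    SYNTENY_ACCEPTED = "synteny_accepted"
    DISCARDED = "discarded"


_STATUS_ORDER = {
    CandidateStatus.RAW: 0,
    CandidateStatus.RETAINED: 1,
    CandidateStatus.AUTO_ACCEPTED: 2,
    CandidateStatus.SYNTENY_ACCEPTED: 2,
    CandidateStatus.DISCARDED: 3,
}


@dataclass
class Candidate:
    """A putative homolog moving through the selection funnel.

    The ledger accumulates every score the funnel computes (E-value,
    loc, sci, pointed shape, synteny, flags); a discarded candidate
    keeps its ledger so each rejection is auditable.  Status only moves
    forward.
    """

    id: str
    locus: Locus
    sequence: str
    provenance: Provenance
    ledger: dict = field(default_factory=dict)
    status: CandidateStatus = CandidateStatus.RAW

    @property
    def accepted(self) -> bool:
        return self.status in (
            CandidateStatus.AUTO_ACCEPTED,
            CandidateStatus.SYNTENY_ACCEPTED,
        )

    def advance(self, new: CandidateStatus, reason: str = "") -> None:
        if _STATUS_ORDER[new] < _STATUS_ORDER[self.status]:
            raise ValueError(f"status cannot move back: {self.status} -> {new}")
        self.status = new
        if reason:
            self.ledger.setdefault("flags", []).append(reason)


@dataclass(frozen=True)
class SearchParams:
    """Seeded-search scoring (blastn-style) and threshold."""

    word_size: int = 7
    match: int = 2
    mismatch: int = -3
    gap_open: int = 2
    gap_extend: int = 2
    evalue_max: float = 1e-5
    band: int = 24          # diagonal band half-width for seed extension
    calibration_seed: int = 0


DEFAULT_PARAMS = SearchParams()


def evalue(raw_score: float, m: int, n: int, lam: float, K: float) -> float:
    """Karlin-Altschul expectation K * m * n * exp(-lambda * S)."""
    if lam <= 0 or K <= 0:
        raise ValueError("lambda and K must be positive")
    return K * m * n * math.exp(-lam * raw_score)


def dinucleotide_shuffle(seq: str, rng: random.Random) -> str:
    """Altschul-Erikson shuffle: a uniform random sequence with exactly
    the original dinucleotide (edge) multiset, via a random Eulerian
    walk on the dinucleotide multigraph."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    first, last = seq[0], seq[-1]
    vertices = sorted(edges)
    for _attempt in range(1000):
        # pick a random last edge per vertex (except the walk's end) and
        # require the last-edge graph to lead every vertex to the end
        last_edge: dict[str, str] = {}
        ok = True
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = rng.choice(edges[v])
        for v in vertices:
            if v == last:
                continue
            seen, cur = {v}, v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if not ok:
            continue
        out: dict[str, list[str]] = {}
        for v in vertices:
            rest = list(edges[v])
            if v in last_edge:
                rest.remove(last_edge[v])
            rng.shuffle(rest)
            if v in last_edge:
                rest.append(last_edge[v])
            out[v] = rest
        walk = [first]
        ptr = {v: 0 for v in vertices}
        cur = first
        for _ in range(len(seq) - 1):
            nxt = out[cur][ptr[cur]]
            ptr[cur] += 1
            walk.append(nxt)
            cur = nxt
        return "".join(walk)
    return seq  # pragma: no cover - degenerate composition


# --- alignment kernels ---------------------------------------------------

def _local_align(
    q: str, s: str, p: SearchParams, dlo: int | None = None, dhi: int | None = None
) -> tuple[int, int, int, int, int]:
    """Smith-Waterman with affine gaps; returns (score, qs, qe, ss, se),
    spans 0-based half-open.  Deterministic: first-found maximum.
    With ``dlo``/``dhi`` the DP is banded to diagonals j - i in
    [dlo - band, dhi + band] around the seeds that raised the window."""
    nq, ns = len(q), len(s)
    if dlo is None:
        lo_d, hi_d = -nq, ns
    else:
        lo_d, hi_d = dlo - p.band, dhi + p.band
    best, bq, bs = 0, 0, 0
    M = [[0] * (ns + 1) for _ in range(nq + 1)]
    Ix = [[_NEG] * (ns + 1) for _ in range(nq + 1)]
    Iy = [[_NEG] * (ns + 1) for _ in range(nq + 1)]
    for i in range(1, nq + 1):
        qi = q[i - 1]
        Mi, Mi1 = M[i], M[i - 1]
        Ixi, Ixi1 = Ix[i], Ix[i - 1]
        Iyi = Iy[i]
        jlo = max(1, i + lo_d)
        jhi = min(ns, i + hi_d)
        for j in range(jlo, jhi + 1):
            Ixi[j] = max(Mi1[j] - p.gap_open, Ixi1[j]) - p.gap_extend
            Iyi[j] = max(Mi[j - 1] - p.gap_open, Iyi[j - 1]) - p.gap_extend
            sub = Mi1[j - 1] + (p.match if qi == s[j - 1] else p.mismatch)
            v = sub
            if Ixi[j] > v:
                v = Ixi[j]
            if Iyi[j] > v:
                v = Iyi[j]
            if v < 0:
                v = 0
            Mi[j] = v
            if v > best:
                best, bq, bs = v, i, j
    if best == 0:
        return 0, 0, 0, 0, 0
    # traceback for start coordinates
    i, j, state = bq, bs, "M"
    while i > 0 and j > 0:
        if state == "M":
            if M[i][j] == 0:
                break
            sub = M[i - 1][j - 1] + (p.match if q[i - 1] == s[j - 1] else p.mismatch)
            if M[i][j] == sub:
                i, j = i - 1, j - 1
            elif M[i][j] == Ix[i][j]:
                state = "Ix"
            else:
                state = "Iy"
        elif state == "Ix":
            state = "M" if Ix[i][j] == M[i - 1][j] - p.gap_open - p.gap_extend else "Ix"
            i -= 1
        else:
            state = "M" if Iy[i][j] == M[i][j - 1] - p.gap_open - p.gap_extend else "Iy"
            j -= 1
    return best, i, bq, j, bs


@dataclass
class SemiGlobalResult:
    score: float
    aligned_ref: str
    aligned_cand: str
    cand_span: tuple[int, int]  # 0-based half-open aligned span in cand


def semiglobal_align(
    ref: str, cand: str, params: SearchParams = DEFAULT_PARAMS
) -> SemiGlobalResult:
    """Align ``ref`` globally against ``cand`` with free terminal gaps in
    ``cand`` (Gotoh affine gaps).  Ties resolve to the leftmost start and
    fewest gaps by a fixed traceback preference."""
    if not ref or not cand:
        raise ValueError("empty sequence")
    ref = ref.upper().replace("U", "T")
    cand = cand.upper().replace("U", "T")
    nr, nc = len(ref), len(cand)
    go, ge = params.gap_open, params.gap_extend
    M = [[_NEG] * (nc + 1) for _ in range(nr + 1)]
    Ix = [[_NEG] * (nc + 1) for _ in range(nr + 1)]  # gap in cand (ref consumed)
    Iy = [[_NEG] * (nc + 1) for _ in range(nr + 1)]  # gap in ref (cand consumed)
    M[0] = [0.0] * (nc + 1)  # free leading gap in cand
    for i in range(1, nr + 1):
        Ix[i][0] = -go - ge * i
    for i in range(1, nr + 1):
        ri = ref[i - 1]
        for j in range(0, nc + 1):
            Ix[i][j] = max(
                Ix[i][j],
                max(M[i - 1][j] - go, Ix[i - 1][j]) - ge,
            )
            if j > 0:
                Iy[i][j] = max(M[i][j - 1] - go, Iy[i][j - 1]) - ge
                sub = M[i - 1][j - 1] + (
                    params.match if ri == cand[j - 1] else params.mismatch
                )
            else:
                sub = _NEG
            M[i][j] = max(sub, Ix[i][j], Iy[i][j])
    # free trailing gap in cand: best over last row
    end_j = max(range(nc + 1), key=lambda j: (M[nr][j], -j))
    score = M[nr][end_j]
    # traceback
    i, j, state = nr, end_j, "M"
    a_ref, a_cand = [], []
    start_j = end_j
    while i > 0:
        if state == "M":
            sub = (
                M[i - 1][j - 1]
                + (params.match if ref[i - 1] == cand[j - 1] else params.mismatch)
                if j > 0
                else _NEG
            )
            if j > 0 and M[i][j] == sub:
                a_ref.append(ref[i - 1])
                a_cand.append(cand[j - 1])
                i, j = i - 1, j - 1
            elif M[i][j] == Ix[i][j]:
                state = "Ix"
            else:
                state = "Iy"
        elif state == "Ix":
            a_ref.append(ref[i - 1])
            a_cand.append("-")
            nxt = "M" if M[i - 1][j] - go - ge == Ix[i][j] else "Ix"
            i -= 1
            state = nxt
        else:
            a_ref.append("-")
            a_cand.append(cand[j - 1])
            nxt = "M" if M[i][j - 1] - go - ge == Iy[i][j] else "Iy"
            j -= 1
            state = nxt
        start_j = j
    return SemiGlobalResult(
        score=score,
        aligned_ref="".join(reversed(a_ref)),
        aligned_cand="".join(reversed(a_cand)),
        cand_span=(start_j, end_j),
    )


# --- E-value calibration -------------------------------------------------

@lru_cache(maxsize=8)
def calibrate_evd(
    params: SearchParams = DEFAULT_PARAMS,
    mode: str = "local",
    n_decoys: int = 200,
    query_len: int = 40,
    decoy_len: int = 2000,
) -> tuple[float, float]:
    """Empirical Karlin-Altschul calibration (lambda, K).

    Maximal ``mode`` alignment scores of a random query against
    dinucleotide-shuffled decoys are fitted with a Gumbel distribution;
    lambda = 1/scale and K = exp(loc/scale)/(m*n).  Seeded by
    ``params.calibration_seed`` and cached per configuration.
    """
    rng = random.Random(params.calibration_seed)
    query = "".join(rng.choice("ACGT") for _ in range(query_len))
    base = "".join(rng.choice("ACGT") for _ in range(decoy_len))
    scores = []
    if mode == "semiglobal":
        decoy_len = int(query_len * 1.5)
        base = "".join(rng.choice("ACGT") for _ in range(decoy_len))
    for _ in range(n_decoys):
        decoy = dinucleotide_shuffle(base, rng)
        if mode == "local":
            s = _best_seeded_score(query, decoy, params)
            if s <= 0:  # no seed found in this decoy: censored
                continue
        else:
            s = semiglobal_align(query, decoy, params).score
        scores.append(s)
    loc, scale = stats.gumbel_r.fit(scores)
    lam = 1.0 / scale
    K = math.exp(loc / scale) / (query_len * decoy_len)
    return lam, K


def _seed_matches(query: str, subject: str, w: int):
    index: dict[str, list[int]] = {}
    for i in range(len(query) - w + 1):
        index.setdefault(query[i : i + w], []).append(i)
    for j in range(len(subject) - w + 1):
        for i in index.get(subject[j : j + w], ()):
            yield i, j


def _best_seeded_score(query: str, subject: str, p: SearchParams) -> int:
    best = 0
    for _s, hit in _seeded_hits_one_strand(query, subject, p):
        best = max(best, hit[0])
    return best


def _seeded_hits_one_strand(query: str, subject: str, p: SearchParams):
    """Cluster seed matches by diagonal, run local alignments on windows.

    Yields (window_offset, (score, qs, qe, ss, se)) per cluster.
    """
    m = len(query)
    diags: dict[int, list[int]] = {}
    for qi, sj in _seed_matches(query, subject, p.word_size):
        diags.setdefault(sj - qi, []).append(sj)
    # merge nearby diagonals into windows, carrying the diagonal range
    windows: list[tuple[int, int, int]] = []
    for d, poss in sorted(diags.items()):
        lo = max(0, min(poss) - m)
        hi = min(len(subject), max(poss) + 2 * m)
        windows.append((lo, hi, d))
    windows.sort()
    merged: list[list[int]] = []  # [lo, hi, dmin, dmax]
    for lo, hi, d in windows:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
            merged[-1][3] = max(merged[-1][3], d)
        else:
            merged.append([lo, hi, d, d])
    for lo, hi, dmin, dmax in merged:
        res = _local_align(query, subject[lo:hi], p, dmin - lo, dmax - lo)
        if res[0] > 0:
            yield lo, res


def seeded_search(
    query: str,
    db: list[SequenceRecord],
    params: SearchParams = DEFAULT_PARAMS,
    query_id: str = "query",
) -> list[SeedHit]:
    """Word-seeded gapped local search of ``query`` against ``db``.

    Both strands are searched; hits with E-value below
    ``params.evalue_max`` are returned sorted by ascending E-value.
    """
    query = query.upper().replace("U", "T")
    if len(query) < params.word_size:
        raise ValueError("query shorter than word size")
    if not db:
        return []
    lam, K = calibrate_evd(params)
    n_total = sum(len(r) for r in db)
    m = len(query)
    hits: list[SeedHit] = []
    for rec in db:
        for strand in "+-":
            subject = rec.sequence if strand == "+" else reverse_complement(rec.sequence)
            for off, (score, qs, qe, ss, se) in _seeded_hits_one_strand(
                query, subject, params
            ):
                E = evalue(score, m, n_total, lam, K)
                if E >= params.evalue_max:
                    continue
                if strand == "+":
                    start, end = off + ss, off + se
                else:
                    start = len(rec) - (off + se)
                    end = len(rec) - (off + ss)
                hits.append(
                    SeedHit(
                        query_id=query_id,
                        locus=Locus(rec.id, start, end, strand),
                        raw_score=score,
                        evalue=E,
                        query_span=(qs, qe),
                    )
                )
    # merge near-duplicate hits (same locus found via adjacent windows)
    hits.sort(key=lambda h: (h.evalue, h.locus.seqid, h.locus.start))
    kept: list[SeedHit] = []
    for h in hits:
        if any(
            k.locus.strand == h.locus.strand and reciprocal_overlap(k.locus, h.locus) >= 0.5
            for k in kept
        ):
            continue
        kept.append(h)
    return kept


def filter_db_by_taxa(
    db: list[SequenceRecord],
    taxonomy,
    families: list[str] | None = None,
    level: str = "family",
) -> list[SequenceRecord]:
    """Restrict a genome database to records whose organism belongs to
    the given taxonomic groups.

    ``taxonomy`` is a table (pandas DataFrame) with an ``organism``
    column and nested group columns; records whose organism is missing
    from the table are dropped.  With ``families`` None the database is
    returned unchanged.  This implements family-partitioned scan
    databases (e.g. scanning only the closest relatives with the
    expensive semi-global pass).
    """
    if families is None:
        return list(db)
    tax = taxonomy.set_index("organism") if "organism" in taxonomy.columns else taxonomy
    keep = []
    for rec in db:
        org = rec.organism or rec.id
        if org in tax.index and tax.at[org, level] in families:
            keep.append(rec)
    return keep


def semiglobal_scan(
    ref: str,
    db: list[SequenceRecord],
    params: SearchParams = DEFAULT_PARAMS,
    query_id: str = "query",
    evalue_max: float | None = None,
) -> list[SeedHit]:
    """Semi-global scan of ``ref`` against every database record.

    Plays the role of a free-end-gap database scanner for diverged
    homologs; scores are converted to E-values with a calibration of
    semi-global decoy scores.  Scan windows are sized 1.5x the reference
    and tiled with 50% overlap so one best hit per window survives.
    """
    ref = ref.upper().replace("U", "T")
    if not db:
        return []
    lam, K = calibrate_evd(params, mode="semiglobal")
    thresh = params.evalue_max if evalue_max is None else evalue_max
    m = len(ref)
    win = int(1.5 * m)
    step = max(1, win // 2)
    n_total = sum(len(r) for r in db)
    hits: list[SeedHit] = []
    for rec in db:
        for strand in "+-":
            subject = rec.sequence if strand == "+" else reverse_complement(rec.sequence)
            best_by_region: list[SeedHit] = []
            for off in range(0, max(1, len(subject) - win + 1), step):
                chunk = subject[off : off + win]
                if len(chunk) < m // 2:
                    continue
                res = semiglobal_align(ref, chunk, params)
                E = evalue(res.score, m, n_total, lam, K)
                if E >= thresh:
                    continue
                s0, s1 = res.cand_span
                if strand == "+":
                    start, end = off + s0, off + s1
                else:
                    start = len(rec) - (off + s1)
                    end = len(rec) - (off + s0)
                if end <= start:
                    continue
                best_by_region.append(
                    SeedHit(
                        query_id=query_id,
                        locus=Locus(rec.id, start, end, strand),
                        raw_score=int(res.score),
                        evalue=E,
                        query_span=(0, m),
                    )
                )
            best_by_region.sort(key=lambda h: h.evalue)
            for h in best_by_region:
                if any(
                    reciprocal_overlap(k.locus, h.locus) >= 0.5
                    and k.locus.strand == h.locus.strand
                    for k in hits
                ):
                    continue
                hits.append(h)
    hits.sort(key=lambda h: (h.evalue, h.locus.seqid, h.locus.start))
    return hits


def extend_and_trim(
    hit: SeedHit,
    genome: SequenceRecord,
    ref: str,
    params: SearchParams = DEFAULT_PARAMS,
    cand_id: str | None = None,
    provenance: Provenance = Provenance.SEEDED_SEARCH,
) -> Candidate | None:
    """Widen a partial hit to cover the full reference plus 10% margins,
    then semi-globally align and trim unmatched leading/trailing bases.

    Returns the trimmed Candidate, or None when trimming collapses the
    candidate to nothing (recorded as impossible span).
    """
    ref = ref.upper().replace("U", "T")
    m = len(ref)
    margin = math.ceil(0.10 * m)
    qs, qe = hit.query_span
    left_missing = qs + margin
    right_missing = (m - qe) + margin
    loc = hit.locus
    if loc.strand == "+":
        start = max(0, loc.start - left_missing)
        end = min(len(genome), loc.end + right_missing)
    else:
        start = max(0, loc.start - right_missing)
        end = min(len(genome), loc.end + left_missing)
    segment = genome.sequence[start:end]
    if loc.strand == "-":
        segment = reverse_complement(segment)
    res = semiglobal_align(ref, segment, params)
    s0, s1 = res.cand_span
    if s1 <= s0:
        return None
    if loc.strand == "+":
        fstart, fend = start + s0, start + s1
    else:
        fstart, fend = start + (len(segment) - s1), start + (len(segment) - s0)
    seq = segment[s0:s1]
    cand = Candidate(
        id=cand_id or f"{hit.query_id}|{loc.seqid}:{fstart + 1}-{fend}({loc.strand})",
        locus=Locus(loc.seqid, fstart, fend, loc.strand),
        sequence=seq,
        provenance=provenance,
        ledger={"evalue": hit.evalue, "raw_score": hit.raw_score},
    )
    return cand


def iterate_search(
    refs: list[PivotTranscript],
    db: list[SequenceRecord],
    params: SearchParams = DEFAULT_PARAMS,
    max_rounds: int = 3,
    use_semiglobal_scan: bool = True,
    accept=None,
    log: list | None = None,
) -> list[Candidate]:
    """Iterated homology search with a stringent threshold per round.

    Round k searches with the pivots plus every candidate accepted
    through round k-1 (each new homolog searches individually).  The
    per-round E-value threshold is identical in every round.  Candidates
    are deduplicated by >= 50% reciprocal locus overlap; iteration stops
    early when a round adds nothing, and never exceeds ``max_rounds``.

    ``accept`` is an optional predicate Candidate -> bool gating which
    candidates seed the next round (defaults to all).
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    by_id = {r.id: r for r in db}
    pivot_loci = [p.locus for p in refs if p.locus is not None]
    candidates: list[Candidate] = []
    queries: list[tuple[str, str]] = [(p.name, p.sequence) for p in refs]
    searched: set[str] = set()
    for rnd in range(1, max_rounds + 1):
        new_round: list[Candidate] = []
        for qid, qseq in queries:
            if qid in searched:
                continue
            searched.add(qid)
            hit_lists = [seeded_search(qseq, db, params, query_id=qid)]
            if use_semiglobal_scan and rnd == 1:
                hit_lists.append(semiglobal_scan(qseq, db, params, query_id=qid))
            for hits in hit_lists:
                prov = (
                    Provenance.SEEDED_SEARCH
                    if hits is hit_lists[0]
                    else Provenance.SEMIGLOBAL_SCAN
                )
                for h in hits:
                    cand = extend_and_trim(
                        h, by_id[h.locus.seqid], qseq, params, provenance=prov
                    )
                    if cand is None:
                        continue
                    if any(
                        cand.locus.strand == p.strand
                        and reciprocal_overlap(cand.locus, p) >= 0.5
                        for p in pivot_loci
                    ):
                        continue  # the pivot's own locus
                    if any(
                        cand.locus.strand == c.locus.strand
                        and reciprocal_overlap(cand.locus, c.locus) >= 0.5
                        for c in candidates + new_round
                    ):
                        continue
                    cand.ledger["round"] = rnd
                    new_round.append(cand)
        if log is not None:
            log.append({"round": rnd, "new_candidates": len(new_round)})
        if not new_round:
            break
        candidates.extend(new_round)
        next_queries = [
            (c.id, c.sequence)
            for c in new_round
            if accept is None or accept(c)
        ]
        queries = next_queries
        if not queries:
            break
    return candidates
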