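"""Thermodynamic matchers: motif-constrained folding scanners.

A thermodynamic matcher (TDM) searches genomes for subsequences that
fold *well* into a prescribed structural motif — typically one or more
hairpins whose stems may vary freely in sequence ("no weight to the
stem sequences") while the hairpin loop must contain a conserved
sequence motif (e.g. the anti-Shine-Dalgarno loop CCUCCUCCC).  Hits are
scored by the folding energy of the best structure satisfying every
constraint, under the package's energy model
(:mod:`rfamforge.rnastruct`).

Motifs are written in a small text DSL (one motif per string)::

    motif   := module (';' (module | spacer))* ('x' INT)?
    module  := 'hairpin' '{' 'stem' INT '..' INT (',' 'internal')? ';'
               'loop' INT '..' INT ('motif' IUPAC)? '}' ('x' INT)?
    spacer  := 'spacer' INT '..' INT

Examples::

    hairpin{stem 4..8; loop 9..12 motif CCUCCUCCC} x3
    hairpin{stem 3..6; loop 6..8 motif GAUGUA}

``x N`` repeats the module N times (consecutive hairpin copies joined
by an implicit spacer, default 0..10 nt).  IUPAC ambiguity codes are
allowed in motifs.  Because families with a variable number of hairpin
modules cannot be expressed in one model, the workflow builds one
matcher per module count and resolves overlapping hits to the highest
count afterwards (``multi_module_classify``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .seqio import SequenceRecord, reverse_complement
from .homsearch import Locus, reciprocal_overlap
from .rnastruct import EnergyModel, DEFAULT_MODEL, can_pair

__all__ = [
    "Stem",
    "HairpinLoop",
    "Spacer",
    "MotifSpec",
    "TdmHit",
    "MotifParseError",
    "parse_motif",
    "tdm_scan",
    "multi_module_classify",
    "terminator_mask",
    "motif_from_structure",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class MotifParseError(ValueError):
    """Raised with a position for DSL grammar or semantic violations."""


@dataclass(frozen=True)
class Stem:
    min_bp: int
    max_bp: int
    allow_internal: bool = False


@dataclass(frozen=True)
class HairpinLoop:
    min_len: int
    max_len: int
    motif: str | None = None  # IUPAC, stored as uppercase DNA


@dataclass(frozen=True)
class Spacer:
    min_len: int
    max_len: int


@dataclass(frozen=True)
class Module:
    """One hairpin module: a stem plus its loop."""

    stem: Stem
    loop: HairpinLoop


@dataclass
class MotifSpec:
    """A validated structural motif: modules separated by spacers."""

    name: str
    modules: list[Module]
    spacers: list[Spacer] = field(default_factory=list)  # len = len(modules) - 1

    def __post_init__(self):
        if not self.modules:
            raise MotifParseError("motif needs at least one stem+hairpin module")
        while len(self.spacers) < len(self.modules) - 1:
            self.spacers.append(Spacer(0, 10))
        for m in self.modules:
            if m.loop.motif and len(m.loop.motif) > m.loop.max_len:
                raise MotifParseError(
                    f"motif {m.loop.motif!r} longer than loop maximum {m.loop.max_len}"
                )
            if m.stem.min_bp < 1 or m.stem.min_bp > m.stem.max_bp:
                raise MotifParseError("invalid stem bounds")
            if m.loop.min_len < 3 or m.loop.min_len > m.loop.max_len:
                raise MotifParseError("invalid loop bounds (min 3)")

    @property
    def module_count(self) -> int:
        return len(self.modules)

    def with_module_count(self, k: int) -> "MotifSpec":
        """Variant of a homogeneous motif with k copies of module 1."""
        sp = self.spacers[0] if self.spacers else Spacer(0, 10)
        return MotifSpec(
            name=f"{self.name}_x{k}",
            modules=[self.modules[0]] * k,
            spacers=[sp] * (k - 1),
        )


@dataclass
class TdmHit:
    locus: Locus
    strand: str
    energy: float
    boundaries: list[tuple[int, int]]  # per module: (start, end) half-open, genome fwd coords
    module_count: int
    structure: str = ""


_TOKEN = re.compile(
    r"\s*(hairpin|spacer|stem|loop|motif|internal|x\s*\d+|\d+\.\.\d+|\d+"
    r"|[ACGTURYSWKMBDHVN]+|[{};,])"
)


def parse_motif(text: str, name: str = "motif") -> MotifSpec:
    """Parse the motif DSL into a validated :class:`MotifSpec`."""
    pos = 0
    tokens: list[tuple[str, int]] = []
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            if text[pos:].strip() == "":
                break
            raise MotifParseError(f"cannot tokenise at position {pos}: {text[pos:pos+12]!r}")
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()

    i = 0

    def peek():
        return tokens[i][0] if i < len(tokens) else None

    def take(expect: str | None = None):
        nonlocal i
        if i >= len(tokens):
            raise MotifParseError(f"unexpected end of motif (wanted {expect})")
        tok, at = tokens[i]
        if expect and tok != expect and not (expect == "RANGE" and ".." in tok):
            raise MotifParseError(f"expected {expect!r} at position {at}, got {tok!r}")
        i += 1
        return tok, at

    def take_range():
        tok, at = take("RANGE")
        lo, hi = tok.split("..")
        return int(lo), int(hi)

    def parse_module() -> tuple[Module, int]:
        take("hairpin")
        take("{")
        take("stem")
        smin, smax = take_range()
        internal = False
        if peek() == ",":
            take(",")
            take("internal")
            internal = True
        take(";")
        take("loop")
        lmin, lmax = take_range()
        motif = None
        if peek() == "motif":
            take("motif")
            tok, at = take()
            motif = tok.upper().replace("U", "T")
            for c in motif:
                if c not in _IUPAC:
                    raise MotifParseError(f"invalid IUPAC character {c!r} at position {at}")
        take("}")
        repeat = 1
        if peek() and peek().startswith("x"):
            tok, _ = take()
            repeat = int(tok[1:].strip())
            if repeat < 1:
                raise MotifParseError("repeat count must be >= 1")
        return Module(Stem(smin, smax, internal), HairpinLoop(lmin, lmax, motif)), repeat

    modules: list[Module] = []
    spacers: list[Spacer] = []
    pending_spacer: Spacer | None = None
    while i < len(tokens):
        tok = peek()
        if tok == ";":
            take(";")
            continue
        if tok == "spacer":
            take("spacer")
            lo, hi = take_range()
            pending_spacer = Spacer(lo, hi)
            continue
        if tok == "hairpin":
            mod, repeat = parse_module()
            if modules:
                spacers.append(pending_spacer or Spacer(0, 10))
            pending_spacer = None
            modules.append(mod)
            for _ in range(repeat - 1):
                spacers.append(Spacer(0, 10))
                modules.append(mod)
            continue
        raise MotifParseError(f"unexpected token {tok!r}")
    return MotifSpec(name=name, modules=modules, spacers=spacers)


def _iupac_match(motif: str, s: str) -> bool:
    return len(motif) == len(s) and all(c in _IUPAC[mc] for mc, c in zip(motif, s))


def _motif_positions(motif: str, seq: str) -> list[int]:
    return [
        i
        for i in range(len(seq) - len(motif) + 1)
        if _iupac_match(motif, seq[i : i + len(motif)])
    ]


def _hairpin_energy(seq: str, start: int, k: int, loop: int,
                    model: EnergyModel) -> float | None:
    """Energy of a k-bp contiguous stem with given loop length at start,
    or None if any stem pair is non-canonical."""
    end = start + 2 * k + loop  # exclusive
    for t in range(k):
        if not can_pair(seq[start + t], seq[end - 1 - t]):
            return None
    e = model.hairpin(loop)
    for t in range(k - 1):
        e += model.stack(
            seq[start + t] + seq[end - 1 - t],
            seq[start + t + 1] + seq[end - 2 - t],
        )
    return e


def _match_module(seq: str, pos: int, mod: Module, model: EnergyModel):
    """All (end_pos, energy, dotbracket) realisations of ``mod`` with its
    first stem base exactly at ``pos``."""
    out = []
    n = len(seq)
    stem, loop = mod.stem, mod.loop
    for k in range(stem.min_bp, stem.max_bp + 1):
        for m in range(loop.min_len, loop.max_len + 1):
            end = pos + 2 * k + m
            if end > n:
                continue
            if loop.motif is not None:
                window = seq[pos + k : pos + k + m]
                if not any(
                    _iupac_match(loop.motif, window[o : o + len(loop.motif)])
                    for o in range(m - len(loop.motif) + 1)
                ):
                    continue
            e = _hairpin_energy(seq, pos, k, m, model)
            if e is None:
                continue
            db = "(" * k + "." * m + ")" * k
            out.append((end, e, db))
    if stem.allow_internal and stem.max_bp >= 2:
        # one internal loop/bulge splitting the stem (bounded 1..3 nt a side)
        for k1 in range(1, stem.max_bp):
            for k2 in range(max(1, stem.min_bp - k1), stem.max_bp - k1 + 1):
                for b1 in range(0, 4):
                    for b2 in range(0, 4):
                        if b1 == 0 and b2 == 0:
                            continue
                        for m in range(loop.min_len, loop.max_len + 1):
                            end = pos + 2 * (k1 + k2) + b1 + b2 + m
                            if end > n:
                                continue
                            inner = pos + k1 + b1
                            inner_end = end - k1 - b2
                            ok = all(
                                can_pair(seq[pos + t], seq[end - 1 - t])
                                for t in range(k1)
                            ) and all(
                                can_pair(seq[inner + t], seq[inner_end - 1 - t])
                                for t in range(k2)
                            )
                            if not ok:
                                continue
                            if loop.motif is not None:
                                window = seq[inner + k2 : inner + k2 + m]
                                if not any(
                                    _iupac_match(loop.motif, window[o : o + len(loop.motif)])
                                    for o in range(m - len(loop.motif) + 1)
                                ):
                                    continue
                            e = model.hairpin(m) + model.internal(b1, b2)
                            for t in range(k1 - 1):
                                e += model.stack(
                                    seq[pos + t] + seq[end - 1 - t],
                                    seq[pos + t + 1] + seq[end - 2 - t],
                                )
                            for t in range(k2 - 1):
                                e += model.stack(
                                    seq[inner + t] + seq[inner_end - 1 - t],
                                    seq[inner + t + 1] + seq[inner_end - 2 - t],
                                )
                            db = (
                                "(" * k1 + "." * b1 + "(" * k2 + "." * m
                                + ")" * k2 + "." * b2 + ")" * k1
                            )
                            out.append((end, e, db))
    return out


def _scan_strand(seq: str, spec: MotifSpec, model: EnergyModel, ceiling: float):
    """Yield (start, end, energy, boundaries, structure) matches on one strand."""
    n = len(seq)
    first = spec.modules[0]
    # anchor on the first module's loop motif when available
    if first.loop.motif:
        anchors = set()
        for mp in _motif_positions(first.loop.motif, seq):
            for k in range(first.stem.min_bp, first.stem.max_bp + 1):
                lm = len(first.loop.motif)
                for m in range(first.loop.min_len, first.loop.max_len + 1):
                    for off in range(m - lm + 1):
                        start = mp - off - k
                        if start >= 0:
                            anchors.add(start)
        starts = sorted(anchors)
    else:
        starts = range(n)

    def chain(pos: int, mi: int, energy: float, bounds, struct):
        if mi == len(spec.modules):
            yield pos, energy, bounds, struct
            return
        for end, e, db in _match_module(seq, pos, spec.modules[mi], model):
            new_struct = struct + db
            if mi + 1 == len(spec.modules):
                yield from chain(end, mi + 1, energy + e, bounds + [(pos, end)], new_struct)
            else:
                sp = spec.spacers[mi]
                for gap in range(sp.min_len, sp.max_len + 1):
                    if end + gap > n:
                        break
                    yield from chain(
                        end + gap, mi + 1, energy + e,
                        bounds + [(pos, end)], new_struct + "." * gap
                    )

    for s in starts:
        best = None
        for end, energy, bounds, struct in chain(s, 0, 0.0, [], ""):
            if energy > ceiling:
                continue
            if best is None or energy < best[2]:
                best = (s, end, energy, bounds, struct)
        if best is not None:
            yield best


def tdm_scan(
    spec: MotifSpec,
    genomes: list[SequenceRecord],
    ceiling: float = -5.0,
    model: EnergyModel = DEFAULT_MODEL,
    mask: dict[str, list[tuple[int, int]]] | None = None,
) -> list[TdmHit]:
    """Scan genomes for minimal-energy realisations of a structural motif.

    Stem base identity is unconstrained (only pairability matters), the
    loop must contain its motif as an IUPAC match, and all length bounds
    hold.  Both strands are scanned; hits at or below the energy ceiling
    are reported, overlap-merged keeping the best (lowest) energy.  With
    ``mask`` (seqid -> intervals), hits lying entirely inside a masked
    interval — e.g. Rho-independent terminators — are suppressed.
    """
    hits: list[TdmHit] = []
    for rec in genomes:
        for strand in "+-":
            seq = rec.sequence if strand == "+" else reverse_complement(rec.sequence)
            for s, end, energy, bounds, struct in _scan_strand(seq, spec, model, ceiling):
                if strand == "+":
                    locus = Locus(rec.id, s, end, "+")
                    fbounds = [(a, b) for a, b in bounds]
                else:
                    locus = Locus(rec.id, len(seq) - end, len(seq) - s, "-")
                    fbounds = [(len(seq) - b, len(seq) - a) for a, b in reversed(bounds)]
                if mask and _inside_mask(locus, mask.get(rec.id, [])):
                    continue
                hits.append(
                    TdmHit(locus, strand, round(energy, 10), fbounds,
                           spec.module_count, struct)
                )
    hits.sort(key=lambda h: (h.energy, h.locus.seqid, h.locus.start))
    merged: list[TdmHit] = []
    for h in hits:
        if any(
            m.locus.strand == h.locus.strand and reciprocal_overlap(m.locus, h.locus) >= 0.5
            for m in merged
        ):
            continue
        merged.append(h)
    merged.sort(key=lambda h: (h.locus.seqid, h.locus.start))
    return merged


def _inside_mask(locus: Locus, intervals: list[tuple[int, int]]) -> bool:
    return any(a <= locus.start and locus.end <= b for a, b in intervals)


def multi_module_classify(hit_lists: dict[int, list[TdmHit]]) -> list[TdmHit]:
    """Resolve overlapping hits from per-module-count matcher variants.

    Matchers with fewer modules produce sub-hits inside the loci of
    higher-count arrays; each overlapping cluster is assigned to the
    highest module count whose hit covers the region, and lower-count
    sub-hits are suppressed.  Disjoint hits pass through unchanged.
    """
    all_hits = [
        (count, h) for count, hs in sorted(hit_lists.items(), reverse=True) for h in hs
    ]
    kept: list[TdmHit] = []
    for count, h in all_hits:
        if any(k.locus.strand == h.locus.strand and k.locus.overlap(h.locus) > 0
               for k in kept):
            continue
        h = replace_count(h, count)
        kept.append(h)
    kept.sort(key=lambda h: (h.locus.seqid, h.locus.start))
    return kept


def replace_count(h: TdmHit, count: int) -> TdmHit:
    h.module_count = count
    return h


def terminator_mask(
    genomes: list[SequenceRecord],
    min_stem: int = 6,
    max_stem: int = 12,
    loop_range: tuple[int, int] = (3, 8),
    gc_min: float = 0.7,
    u_run: int = 4,
    max_gap: int = 5,
) -> dict[str, list[tuple[int, int]]]:
    """Flag Rho-independent-terminator-like intervals per replicon.

    A GC-rich hairpin (>= ``min_stem`` bp, loop 3-8 nt) followed within
    ``max_gap`` nt by a run of >= ``u_run`` U/T is masked; motif scans
    may exclude hits falling entirely inside such intervals, since short
    GC-rich sRNA hairpins are easily confused with terminators.
    """
    out: dict[str, list[tuple[int, int]]] = {}
    for rec in genomes:
        seq = rec.sequence
        n = len(seq)
        intervals: list[tuple[int, int]] = []
        for start in range(n):
            for k in range(min_stem, max_stem + 1):
                for loop in range(loop_range[0], loop_range[1] + 1):
                    end = start + 2 * k + loop
                    if end > n:
                        continue
                    ok = all(
                        can_pair(seq[start + t], seq[end - 1 - t]) for t in range(k)
                    )
                    if not ok:
                        continue
                    stembases = seq[start : start + k] + seq[end - k : end]
                    gc = sum(1 for c in stembases if c in "GC") / len(stembases)
                    if gc < gc_min:
                        continue
                    tail = seq[end : end + max_gap + u_run]
                    if re.search("T" * u_run, tail):
                        tail_end = end + tail.index("T" * u_run) + u_run
                        intervals.append((start, tail_end))
        merged: list[list[int]] = []
        for a, b in sorted(intervals):
            if merged and a <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        if merged:
            out[rec.id] = [tuple(x) for x in merged]
    return out


def motif_from_structure(
    seq: str,
    structure: str,
    stem_slack: int = 1,
    loop_slack: int = 2,
    spacer_slack: float = 0.5,
    name: str = "derived",
) -> MotifSpec:
    """Derive a motif description from one folded transcript.

    Each hairpin of the structure becomes a module: the stem bound is
    the closing helix's pair count +/- ``stem_slack``, the loop keeps
    its observed sequence as the (exact) motif with the length relaxed
    by ``loop_slack``, and inter-hairpin distances become spacers
    relaxed by ``spacer_slack``.  This automates the initial, restrictive
    matcher design that is then manually relaxed in practice.
    """
    from .rnastruct import parse_dotbracket

    seq = seq.upper().replace("U", "T")
    pairs = parse_dotbracket(structure)
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    paired = set(partner)
    modules: list[Module] = []
    spacers: list[Spacer] = []
    hairpins = []  # (outer_start, outer_end, k, loop_len, loop_seq)
    for i, j in sorted(pairs):
        if all(k not in paired for k in range(i + 1, j)):
            # walk outwards to measure the contiguous closing helix
            k = 1
            a, b = i, j
            while a - 1 in partner and partner[a - 1] == b + 1:
                a, b = a - 1, b + 1
                k += 1
            hairpins.append((a, b, k, j - i - 1, seq[i + 1 : j]))
    hairpins.sort()
    prev_end = None
    for a, b, k, loop_len, loop_seq in hairpins:
        stem = Stem(max(2, k - stem_slack), k + stem_slack)
        loop = HairpinLoop(
            max(3, loop_len - loop_slack), loop_len + loop_slack, loop_seq
        )
        if prev_end is not None:
            gap = a - prev_end - 1
            lo = max(0, int(gap * (1 - spacer_slack)))
            hi = int(gap * (1 + spacer_slack)) + 2
            spacers.append(Spacer(lo, hi))
        modules.append(Module(stem, loop))
        prev_end = b
    if not modules:
        raise ValueError("structure has no hairpin to derive a motif from")
    return MotifSpec(name=name, modules=modules, spacers=spacers)
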