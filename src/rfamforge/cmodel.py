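"""Simplified covariance model (profile SCFG) build, score and scan.

A covariance model captures the joint sequence and secondary-structure
conservation of an alignment: paired consensus columns emit base *pairs*
(16-way emission), unpaired columns emit single bases, and multiloop
branch points become bifurcations.  Scoring a sequence asks for the
best parse of the sequence by this grammar, in log-odds bits against a
uniform background (0.25 per base, 0.0625 per pair).

This implementation is intentionally compact: match/delete per node
plus linearly penalised insertions, no local begins/ends and no HMM
prefilter — sRNA-sized models (50-250 columns) parse quickly with a
vectorised CYK.  Discrimination (members score above shuffles and above
structure-violating sequences), not parity with any particular CM
toolchain, is the contract, and hit handling follows the family-model
workflow: the best 50 hits per scan, at most three build-scan-assess
cycles, and a 25%-of-maximum score cutoff in the third cycle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio import SequenceRecord, StockholmAlignment, reverse_complement
from .homsearch import Locus, reciprocal_overlap
from .rnastruct import parse_dotbracket

__all__ = [
    "CmNode",
    "CovarianceModel",
    "CmHit",
    "build_cm",
    "score_cm",
    "scan_cm",
    "refine_family",
]

_ALPHA = "ACGT"
_IDX = {c: i for i, c in enumerate(_ALPHA)}
NEG = -1e30


@dataclass
class CmNode:
    """One guide-tree node: P (pair), L (left single), R (right single),
    B (bifurcation) or E (end)."""

    kind: str                  # P | L | R | B | E
    cols: tuple[int, ...]      # alignment columns emitted (0-based)
    emit: list[float] = field(default_factory=list)   # log-odds, 16 or 4
    t_match: float = 0.0       # log2 P(match)
    t_delete: float = NEG      # log2 P(delete)
    children: tuple[int, ...] = ()


@dataclass
class CovarianceModel:
    nodes: list[CmNode]
    root: int
    model_length: int          # alignment columns
    insert_penalty: float = 2.0  # bits per inserted base

    @property
    def n_pair_nodes(self) -> int:
        return sum(1 for n in self.nodes if n.kind == "P")

    @property
    def n_single_nodes(self) -> int:
        return sum(1 for n in self.nodes if n.kind in "LR")

    @property
    def n_bifurcations(self) -> int:
        return sum(1 for n in self.nodes if n.kind == "B")

    def to_json(self, path: str | Path) -> None:
        data = {
            "model_length": self.model_length,
            "root": self.root,
            "insert_penalty": self.insert_penalty,
            "nodes": [
                {
                    "kind": n.kind,
                    "cols": list(n.cols),
                    "emit": n.emit,
                    "t_match": n.t_match,
                    "t_delete": n.t_delete,
                    "children": list(n.children),
                }
                for n in self.nodes
            ],
        }
        Path(path).write_text(json.dumps(data))

    @classmethod
    def from_json(cls, path: str | Path) -> "CovarianceModel":
        data = json.loads(Path(path).read_text())
        nodes = [
            CmNode(
                kind=d["kind"],
                cols=tuple(d["cols"]),
                emit=d["emit"],
                t_match=d["t_match"],
                t_delete=d["t_delete"],
                children=tuple(d["children"]),
            )
            for d in data["nodes"]
        ]
        return cls(
            nodes=nodes,
            root=data["root"],
            model_length=data["model_length"],
            insert_penalty=data["insert_penalty"],
        )


@dataclass
class CmHit:
    locus: Locus
    strand: str
    bits: float
    rank: int = 0


def _column_counts(rows: list[str], col: int, pseudo: float) -> tuple[list[float], float]:
    counts = [pseudo] * 4
    gaps = 0
    for r in rows:
        c = r[col]
        if c in _IDX:
            counts[_IDX[c]] += 1
        else:
            gaps += 1
    total = sum(counts)
    logodds = [math.log2((c / total) / 0.25) for c in counts]
    pd = (gaps + pseudo) / (len(rows) + 2 * pseudo)
    return logodds, pd


# pair-emission prior: canonical/GU pairs carry most of the pseudocount
# mass, so an unobserved compensatory pair still outscores a pair-breaking
# substitution (the point of a covariance model)
_CANONICAL = {"AT", "TA", "GC", "CG", "GT", "TG"}
_PAIR_PRIOR = [
    (0.9 / 6 if _ALPHA[i] + _ALPHA[j] in _CANONICAL else 0.1 / 10)
    for i in range(4)
    for j in range(4)
]


def _pair_counts(rows: list[str], ci: int, cj: int, pseudo: float) -> tuple[list[float], float]:
    counts = [pseudo * 16 * p for p in _PAIR_PRIOR]
    gaps = 0
    for r in rows:
        a, b = r[ci], r[cj]
        if a in _IDX and b in _IDX:
            counts[_IDX[a] * 4 + _IDX[b]] += 1
        else:
            gaps += 1
    total = sum(counts)
    logodds = [math.log2((c / total) / 0.0625) for c in counts]
    pd = (gaps + pseudo) / (len(rows) + 2 * pseudo)
    return logodds, pd


def build_cm(
    aln: StockholmAlignment, pseudocount: float = 1.0, insert_penalty: float = 2.0
) -> CovarianceModel:
    """Build a covariance model from an alignment plus consensus structure.

    One pair node per SS_cons base pair, a left-single node per unpaired
    column, bifurcations at multiloop splits; emissions are Laplace-
    smoothed column (or column-pair) frequencies as log-odds against a
    uniform background.
    """
    if not aln.ss_cons:
        raise ValueError("alignment lacks an SS_cons line")
    rows = [r.upper().replace("U", "T") for r in aln.rows.values()]
    if len(rows) < 2:
        raise ValueError("need at least 2 alignment rows")
    L = aln.length
    pairs = dict(parse_dotbracket(aln.ss_cons))
    partner = {}
    for i, j in pairs.items():
        partner[i] = j
        partner[j] = i

    nodes: list[CmNode] = []

    def build(i: int, j: int) -> int:
        """Node covering columns [i, j]; returns node index."""
        if i > j:
            nodes.append(CmNode("E", ()))
            return len(nodes) - 1
        if i not in partner:
            emit, pd = _column_counts(rows, i, pseudocount)
            child = build(i + 1, j)
            nodes.append(
                CmNode("L", (i,), emit, _log2p(1 - pd), _log2p(pd), (child,))
            )
            return len(nodes) - 1
        if j not in partner:
            emit, pd = _column_counts(rows, j, pseudocount)
            child = build(i, j - 1)
            nodes.append(
                CmNode("R", (j,), emit, _log2p(1 - pd), _log2p(pd), (child,))
            )
            return len(nodes) - 1
        if partner[i] == j:
            emit, pd = _pair_counts(rows, i, j, pseudocount)
            child = build(i + 1, j - 1)
            nodes.append(
                CmNode("P", (i, j), emit, _log2p(1 - pd), _log2p(pd), (child,))
            )
            return len(nodes) - 1
        # i pairs inside: bifurcate after i's partner
        k = partner[i]
        left = build(i, k)
        right = build(k + 1, j)
        nodes.append(CmNode("B", (), children=(left, right)))
        return len(nodes) - 1

    root = build(0, L - 1)
    return CovarianceModel(nodes=nodes, root=root, model_length=L,
                           insert_penalty=insert_penalty)


def _log2p(p: float) -> float:
    return math.log2(p) if p > 0 else NEG


_KIND = {"E": 0, "L": 1, "R": 2, "P": 3, "B": 4}


def _flatten(cm: CovarianceModel):
    """Flatten the guide tree into postorder arrays for the CYK kernel."""
    V = len(cm.nodes)
    kinds = np.zeros(V, dtype=np.int8)
    ch1 = np.full(V, -1, dtype=np.int32)
    ch2 = np.full(V, -1, dtype=np.int32)
    tm = np.zeros(V, dtype=np.float64)
    td = np.full(V, NEG, dtype=np.float64)
    es = np.zeros((V, 4), dtype=np.float64)
    ep = np.zeros((V, 16), dtype=np.float64)
    for v, node in enumerate(cm.nodes):
        kinds[v] = _KIND[node.kind]
        if node.children:
            ch1[v] = node.children[0]
            if len(node.children) > 1:
                ch2[v] = node.children[1]
        tm[v] = node.t_match
        td[v] = node.t_delete
        if node.kind in "LR":
            es[v] = node.emit
        elif node.kind == "P":
            ep[v] = node.emit
    return kinds, ch1, ch2, tm, td, es, ep, cm.root


try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (a and callable(a[0])) else a[0]


@njit(cache=False)
def _cyk_kernel(kinds, ch1, ch2, tm, td, es, ep, x, pen, root):
    """CYK for one window: returns the root's (n+1, n+1) matrix over
    half-open spans [i, j).  Nodes are in postorder (children first);
    insertions cost ``pen`` bits per base and are relaxed on the side(s)
    each node is responsible for."""
    n = x.shape[0]
    V = kinds.shape[0]
    S = np.full((V, n + 1, n + 1), NEG)
    for v in range(V):
        k = kinds[v]
        if k == 0:  # E: spans generated purely by inserts
            for i in range(n + 1):
                for j in range(i, n + 1):
                    S[v, i, j] = -pen * (j - i)
        elif k == 1 or k == 2 or k == 3:
            c = ch1[v]
            for i in range(n + 1):
                for j in range(i, n + 1):
                    best = td[v] + S[c, i, j]
                    if k == 1 and j >= i + 1:  # L: emit base i
                        cand = es[v, x[i]] + tm[v] + S[c, i + 1, j]
                        if cand > best:
                            best = cand
                    elif k == 2 and j >= i + 1:  # R: emit base j-1
                        cand = es[v, x[j - 1]] + tm[v] + S[c, i, j - 1]
                        if cand > best:
                            best = cand
                    elif k == 3 and j >= i + 2:  # P: emit pair (i, j-1)
                        cand = (ep[v, x[i] * 4 + x[j - 1]] + tm[v]
                                + S[c, i + 1, j - 1])
                        if cand > best:
                            best = cand
                    S[v, i, j] = best
            # insert relaxation: L relaxes its left flank, R its right,
            # P both; deeper nodes absorb the other side
            if k == 1 or k == 3:
                for j in range(n + 1):
                    for i in range(min(j, n) - 1, -1, -1):
                        cand = S[v, i + 1, j] - pen
                        if cand > S[v, i, j]:
                            S[v, i, j] = cand
            if k == 2 or k == 3:
                for i in range(n + 1):
                    for j in range(i + 1, n + 1):
                        cand = S[v, i, j - 1] - pen
                        if cand > S[v, i, j]:
                            S[v, i, j] = cand
        else:  # B: bifurcation
            a = ch1[v]
            b = ch2[v]
            for i in range(n + 1):
                for j in range(i, n + 1):
                    best = NEG
                    for m in range(i, j + 1):
                        cand = S[a, i, m] + S[b, m, j]
                        if cand > best:
                            best = cand
                    S[v, i, j] = best
    return S[root]


def _encode(seq: str) -> np.ndarray:
    return np.array([_IDX.get(c, 0) for c in seq.upper().replace("U", "T")],
                    dtype=np.int64)


def _cyk_matrices(cm: CovarianceModel, seq: str) -> np.ndarray:
    """Single-sequence CYK: the root's (n+1)x(n+1) score matrix."""
    kinds, ch1, ch2, tm, td, es, ep, root = _flatten(cm)
    return _cyk_kernel(kinds, ch1, ch2, tm, td, es, ep, _encode(seq),
                       cm.insert_penalty, root)


def score_cm(cm: CovarianceModel, seq: str) -> float:
    """Best global parse of ``seq`` (bits, log2 odds against background)."""
    if not seq:
        raise ValueError("empty sequence")
    S = _cyk_matrices(cm, seq)
    return float(S[0, len(seq)])


def scan_cm(
    cm: CovarianceModel,
    genomes: list[SequenceRecord],
    window: int | None = None,
    top: int = 50,
    bits_min: float = 0.0,
) -> list[CmHit]:
    """Scan genomes with a covariance model, both strands.

    Sliding windows of 1.2x the model length (50% overlap) are parsed;
    within each window the best-scoring subspan is the hit (flanking
    window bases are free).  Overlapping hits keep the best bits, and at
    most the best ``top`` hits (default 50) are returned, sorted by
    descending bits.
    """
    if window is None:
        window = int(math.ceil(1.2 * cm.model_length))
    if window < cm.model_length / 1.2 - 1:
        raise ValueError("window too small for model")
    # stride must not exceed window - model_length, or a full-length
    # occurrence could straddle every window boundary and be truncated
    step = max(1, window - cm.model_length)
    hits: list[CmHit] = []
    kinds, ch1, ch2, tm, td, es, ep, root = _flatten(cm)
    pen = cm.insert_penalty
    for rec in genomes:
        for strand in "+-":
            subject = rec.sequence if strand == "+" else reverse_complement(rec.sequence)
            ns = len(subject)
            if ns <= window:
                offs = [0]
                win = ns
            else:
                offs = list(range(0, ns - window + 1, step))
                if offs[-1] + window < ns:
                    offs.append(ns - window)
                win = window
            enc = _encode(subject)
            for off in offs:
                S = _cyk_kernel(kinds, ch1, ch2, tm, td, es, ep,
                                enc[off : off + win], pen, root)
                flat = S.ravel()
                bi = int(flat.argmax())
                bits = float(flat[bi])
                i, j = divmod(bi, win + 1)
                if bits <= bits_min or j <= i:
                    continue
                if strand == "+":
                    start, end = off + i, off + j
                else:
                    start, end = ns - (off + j), ns - (off + i)
                hits.append(
                    CmHit(Locus(rec.id, start, end, strand), strand, bits)
                )
    hits.sort(key=lambda h: (-h.bits, h.locus.seqid, h.locus.start))
    merged: list[CmHit] = []
    for h in hits:
        if any(
            m.locus.strand == h.locus.strand and reciprocal_overlap(m.locus, h.locus) >= 0.5
            for m in merged
        ):
            continue
        merged.append(h)
    merged = merged[:top]
    for r, h in enumerate(merged, 1):
        h.rank = r
    return merged


def refine_family(
    family,
    genomes: list[SequenceRecord],
    assess_hit,
    max_cycles: int = 3,
    score_cutoff_frac: float = 0.25,
    top: int = 50,
    log: list | None = None,
):
    """Iterate model build -> genome scan -> hit assessment, growing the
    family, for at most ``max_cycles`` cycles.

    ``family`` must provide ``members`` (list of objects with
    ``sequence`` and ``locus``) and ``build_alignment()`` returning a
    StockholmAlignment; ``assess_hit(hit, sequence)`` decides admission.
    The third cycle additionally requires a hit's bits to reach
    ``score_cutoff_frac`` of the highest member score.
    """
    by_id = {r.id: r for r in genomes}
    for cycle in range(1, max_cycles + 1):
        aln = family.build_alignment()
        cm = build_cm(aln)
        hits = scan_cm(cm, genomes, top=top)
        member_bits = [score_cm(cm, m.sequence) for m in family.members]
        max_bits = max(member_bits) if member_bits else 0.0
        added = 0
        for hit in hits:
            if cycle >= max_cycles and hit.bits < score_cutoff_frac * max_bits:
                continue
            # a hit substantially overlapping an existing member is a
            # shifted re-detection of the same locus, not a new copy
            # (distinct sRNA copies do not overlap)
            if any(
                m.locus is not None
                and m.locus.seqid == hit.locus.seqid
                and hit.locus.overlap(m.locus)
                > 0.2 * min(len(hit.locus), len(m.locus))
                for m in family.members
            ):
                continue
            rec = by_id[hit.locus.seqid]
            seq = rec.sequence[hit.locus.start : hit.locus.end]
            if hit.locus.strand == "-":
                seq = reverse_complement(seq)
            if assess_hit(hit, seq):
                family.add_member(seq, hit.locus, bits=hit.bits, provenance="cm_scan")
                added += 1
        if log is not None:
            log.append({"cycle": cycle, "hits": len(hits), "added": added})
        if added == 0:
            break
    return family
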