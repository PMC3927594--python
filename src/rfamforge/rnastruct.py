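"""RNA secondary-structure engine.

Minimum-free-energy (MFE) folding, alignment consensus folding, abstract
shapes, hairpin centers and pointed shapes, under a compact
nearest-neighbour energy model:

* canonical pairs AU/UA/GC/CG plus wobble GU/UG (DNA letters internally,
  so AT/TA/GC/CG/GT/TG);
* stabilising stacking energies for adjacent pairs, from a 6x6 table
  parameterised by pair strength (GC > AU > GU);
* destabilising affine loop penalties for hairpins (>= 3 unpaired bases),
  internal loops/bulges, and multiloops;
* external (unpaired, outside all pairs) bases are free.

The model is deliberately *not* a reproduction of the Turner/Vienna
parameter set: it is a self-contained, versioned table whose behaviour
is pinned by exhaustive-enumeration oracles in the test suite.  All
downstream statistics (SCI, loc-scores, TDM energies) are defined
relative to this model.

Energies are in kcal/mol-like model units; more negative is more stable.
The all-unpaired structure always has energy 0, so ``mfe_fold`` never
returns a positive energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache

__all__ = [
    "EnergyModel",
    "DEFAULT_MODEL",
    "SecondaryStructure",
    "PointedShape",
    "can_pair",
    "parse_dotbracket",
    "pairs_to_dotbracket",
    "structure_energy",
    "mfe_fold",
    "consensus_fold",
    "pair_band_set",
    "abstract_shape",
    "hairpin_centers",
    "pointed_shape",
    "map_consensus_to_row",
]

HP_MIN = 3  # minimum unpaired bases in a hairpin loop
MAXLOOP = 30  # largest internal/bulge loop the folding DP enumerates

_PAIRS = {"AT", "TA", "GC", "CG", "GT", "TG", "AU", "UA", "GU", "UG"}

# pair "strength" drives the stacking table: GC pairs stack best, wobble worst
_STRENGTH = {
    "GC": 1.5, "CG": 1.5,
    "AT": 1.0, "TA": 1.0, "AU": 1.0, "UA": 1.0,
    "GT": 0.5, "TG": 0.5, "GU": 0.5, "UG": 0.5,
}


@dataclass(frozen=True)
class EnergyModel:
    """Tunable parameters of the folding model (model units, kcal/mol-like)."""

    stack_base: float = 0.4       # constant part of a stacking increment
    hairpin_a: float = 3.0        # hairpin penalty: a + b * loop_len
    hairpin_b: float = 0.3
    internal_a: float = 1.6      # internal/bulge penalty: a + b * (l1 + l2)
    internal_b: float = 0.4
    ml_close: float = 3.4        # multiloop closing penalty (incl. closing branch)
    ml_branch: float = 0.4       # per inner branch
    ml_unpaired: float = 0.1     # per unpaired base inside a multiloop

    def stack(self, pair_out: str, pair_in: str) -> float:
        """Energy of stacking ``pair_in`` directly inside ``pair_out`` (< 0)."""
        return -(self.stack_base + _STRENGTH[pair_out] + _STRENGTH[pair_in])

    def hairpin(self, loop_len: int) -> float:
        return self.hairpin_a + self.hairpin_b * loop_len

    def internal(self, l1: int, l2: int) -> float:
        return self.internal_a + self.internal_b * (l1 + l2)


DEFAULT_MODEL = EnergyModel()


def can_pair(a: str, b: str) -> bool:
    return a + b in _PAIRS


@dataclass
class SecondaryStructure:
    """A pseudoknot-free structure in dot-bracket notation with its energy."""

    dotbracket: str
    energy: float

    def __post_init__(self) -> None:
        parse_dotbracket(self.dotbracket)  # validates balance

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return parse_dotbracket(self.dotbracket)

    def __len__(self) -> int:
        return len(self.dotbracket)


@dataclass
class PointedShape:
    """Abstract shape plus the ordered hairpin-center positions.

    The shape abstracts helix topology (``[]`` per hairpin nesting at
    level 5, ``_`` for an open chain); each hairpin contributes a center
    (i + j) / 2 of its closing pair (1-based, exact halves kept).
    Together they form the structure-equality surface used by the
    candidate auto-accept rule.
    """

    shape: str
    centers: list[Fraction] = field(default_factory=list)

    def __post_init__(self) -> None:
        # each innermost "[]" of a level-5 shape is a hairpin; enclosing
        # brackets (multiloop-closing helices) carry no center
        n_hp = self.shape.count("[]")
        if self.shape != "_" and n_hp != len(self.centers):
            raise ValueError(
                f"pointed-shape invariant broken: {n_hp} hairpins vs "
                f"{len(self.centers)} centers"
            )

    def matches(self, other: "PointedShape", tolerance_nt: float = 0.0) -> bool:
        """Equality up to a per-center positional tolerance (in nt)."""
        if self.shape != other.shape or len(self.centers) != len(other.centers):
            return False
        return all(
            abs(a - b) <= tolerance_nt for a, b in zip(self.centers, other.centers)
        )


def parse_dotbracket(db: str) -> list[tuple[int, int]]:
    """Return 0-based (i, j) pairs; raises on unbalanced input."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i + 1}")
            pairs.append((stack.pop(), i))
        elif c != ".":
            raise ValueError(f"invalid character {c!r} at position {i + 1}")
    if stack:
        raise ValueError("unbalanced '(' left open")
    return sorted(pairs)


def pairs_to_dotbracket(pairs: list[tuple[int, int]], n: int) -> str:
    db = ["."] * n
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return "".join(db)


# --- energy of a given structure (loop decomposition) --------------------

def structure_energy(
    seq: str, structure: str | list[tuple[int, int]], model: EnergyModel = DEFAULT_MODEL
) -> float:
    """Energy of ``structure`` on ``seq`` by loop decomposition.

    This is the ground truth the folding DP optimises; oracle tests
    enumerate structures and evaluate them through this function.
    """
    seq = seq.upper().replace("U", "T")
    pairs = parse_dotbracket(structure) if isinstance(structure, str) else sorted(structure)
    partner = {}
    for i, j in pairs:
        if not can_pair(seq[i], seq[j]):
            raise ValueError(f"non-canonical pair {seq[i]}{seq[j]} at {i + 1},{j + 1}")
        partner[i] = j
        partner[j] = i

    def children(i: int, j: int) -> tuple[list[tuple[int, int]], int]:
        """Directly enclosed pairs and unpaired count in the loop of (i, j)."""
        kids, unpaired, k = [], 0, i + 1
        while k < j:
            if k in partner and partner[k] > k:
                kids.append((k, partner[k]))
                k = partner[k] + 1
            else:
                unpaired += 1
                k += 1
        return kids, unpaired

    total = 0.0
    for i, j in pairs:
        kids, unpaired = children(i, j)
        if not kids:
            if unpaired < HP_MIN:
                raise ValueError(f"hairpin of ({i + 1},{j + 1}) shorter than {HP_MIN}")
            total += model.hairpin(unpaired)
        elif len(kids) == 1:
            (k, l) = kids[0]
            l1, l2 = k - i - 1, j - l - 1
            if l1 == 0 and l2 == 0:
                total += model.stack(seq[i] + seq[j], seq[k] + seq[l])
            else:
                total += model.internal(l1, l2)
        else:
            total += model.ml_close + model.ml_branch * len(kids) + model.ml_unpaired * unpaired
    return round(total, 10)


# --- generic Zuker-style folding engine ----------------------------------
#
# The engine is shared between single-sequence MFE folding and alignment
# consensus folding; a "context" supplies pairability, stacking energies
# and a per-pair adjustment (covariance bonus / non-pairing penalty for
# alignments, zero for single sequences).

class _SeqContext:
    def __init__(self, seq: str, model: EnergyModel):
        self.seq = seq.upper().replace("U", "T")
        self.n = len(self.seq)
        self.model = model

    def pairable(self, i: int, j: int) -> bool:
        return can_pair(self.seq[i], self.seq[j])

    def stack(self, i: int, j: int, k: int, l: int) -> float:
        return self.model.stack(self.seq[i] + self.seq[j], self.seq[k] + self.seq[l])

    def pair_adj(self, i: int, j: int) -> float:
        return 0.0


class _AlnContext:
    """Column-wise folding context for an alignment.

    A column pair is allowed when at least one row forms a canonical/GU
    pair in both columns (rows gapped in either column abstain).  Each
    allowed pair carries an adjustment:

        - covariance_bonus * (distinct pair types - 1)
        + nonpair_penalty  * (rows with both columns present but unable to pair)

    Stacking between adjacent column pairs is the mean stack energy over
    rows that realise both pairs.  Loop lengths are measured in columns.
    For an alignment of identical gap-free rows all adjustments vanish
    and the consensus energy equals the single-sequence MFE.
    """

    def __init__(self, rows: list[str], model: EnergyModel,
                 covariance_bonus: float, nonpair_penalty: float,
                 min_pair_frac: float = 0.5):
        self.rows = [r.upper().replace("U", "T").replace(".", "-") for r in rows]
        self.n = len(self.rows[0])
        self.model = model
        self.cov = covariance_bonus
        self.pen = nonpair_penalty
        self.min_pair_frac = min_pair_frac

    def _row_pairs(self, i: int, j: int) -> tuple[list[str], int]:
        ok, bad = [], 0
        for r in self.rows:
            a, b = r[i], r[j]
            if a == "-" or b == "-":
                continue
            if can_pair(a, b):
                ok.append(a + b)
            else:
                bad += 1
        return ok, bad

    def pairable(self, i: int, j: int) -> bool:
        # majority rule over *all* rows (gapped rows count against): a
        # column pair is admitted only when at least min_pair_frac of
        # the alignment can realise it, so neither a single aberrant row
        # nor a sparsely occupied column region can carry a pair
        ok, _bad = self._row_pairs(i, j)
        if not ok:
            return False
        return len(ok) >= self.min_pair_frac * len(self.rows)

    def pair_adj(self, i: int, j: int) -> float:
        ok, bad = self._row_pairs(i, j)
        distinct = len(set(ok))
        return -self.cov * (distinct - 1) + self.pen * bad

    def stack(self, i: int, j: int, k: int, l: int) -> float:
        vals = []
        for r in self.rows:
            outer, inner = r[i] + r[j], r[k] + r[l]
            if "-" in outer or "-" in inner:
                continue
            if outer in _PAIRS and inner in _PAIRS:
                vals.append(self.model.stack(outer, inner))
        return sum(vals) / len(vals) if vals else 0.0


_INF = float("inf")


class _Fold:
    """Inside DP (V/M/M2/W) with deterministic traceback."""

    def __init__(self, ctx):
        self.ctx = ctx
        self.m = ctx.model
        n = ctx.n
        self.n = n
        self.V = [[_INF] * n for _ in range(n)]
        self.M = [[_INF] * n for _ in range(n)]   # >=1 multiloop branch
        self.M2 = [[_INF] * n for _ in range(n)]  # >=2 multiloop branches
        self._run()

    def _run(self) -> None:
        ctx, m, n = self.ctx, self.m, self.n
        V, M, M2 = self.V, self.M, self.M2
        for span in range(HP_MIN + 1, n):
            for i in range(0, n - span):
                j = i + span
                if ctx.pairable(i, j):
                    best = m.hairpin(j - i - 1) if j - i - 1 >= HP_MIN else _INF
                    # stack / internal loop
                    for k in range(i + 1, min(j - 1, i + 2 + MAXLOOP)):
                        l1 = k - i - 1
                        for l in range(max(k + HP_MIN + 1, j - 1 - (MAXLOOP - l1)), j):
                            if V[k][l] == _INF:
                                continue
                            l2 = j - l - 1
                            if l1 == 0 and l2 == 0:
                                e = V[k][l] + ctx.stack(i, j, k, l)
                            else:
                                e = V[k][l] + m.internal(l1, l2)
                            if e < best:
                                best = e
                    # multiloop
                    if M2[i + 1][j - 1] != _INF:
                        e = M2[i + 1][j - 1] + m.ml_close
                        if e < best:
                            best = e
                    if best != _INF:
                        V[i][j] = best + ctx.pair_adj(i, j)
                # M: segment of a multiloop with >= 1 branch
                best_m = _INF
                if j > i and M[i][j - 1] != _INF:
                    best_m = M[i][j - 1] + m.ml_unpaired
                if j > i and M2[i][j - 1] != _INF:
                    M2[i][j] = M2[i][j - 1] + m.ml_unpaired
                for k in range(i, j - HP_MIN):
                    if V[k][j] == _INF:
                        continue
                    e = m.ml_unpaired * (k - i) + V[k][j] + m.ml_branch
                    if e < best_m:
                        best_m = e
                for k in range(i + 1, j - HP_MIN):
                    if V[k][j] == _INF or M[i][k - 1] == _INF:
                        continue
                    e = M[i][k - 1] + V[k][j] + m.ml_branch
                    if e < best_m:
                        best_m = e
                    if e < M2[i][j]:
                        M2[i][j] = e
                M[i][j] = best_m
        # external loop
        W = [0.0] * (n + 1)
        for j in range(1, n + 1):
            W[j] = W[j - 1]
            for i in range(1, j + 1):
                v = V[i - 1][j - 1]
                if v != _INF and W[i - 1] + v < W[j]:
                    W[j] = W[i - 1] + v
        self.W = W

    # -- traceback (first-found in a fixed scan order => deterministic) --

    def traceback(self) -> list[tuple[int, int]]:
        pairs: list[tuple[int, int]] = []
        self._tb_w(self.n, pairs)
        return sorted(pairs)

    def _tb_w(self, j: int, pairs: list) -> None:
        W, V = self.W, self.V
        while j > 0:
            if W[j] == W[j - 1]:
                j -= 1
                continue
            for i in range(1, j + 1):
                v = V[i - 1][j - 1]
                if v != _INF and abs(W[i - 1] + v - W[j]) < 1e-9:
                    self._tb_v(i - 1, j - 1, pairs)
                    j = i - 1
                    break
            else:  # pragma: no cover - defensive
                raise AssertionError("external traceback failed")

    def _tb_v(self, i: int, j: int, pairs: list) -> None:
        ctx, m, V = self.ctx, self.m, self.V
        pairs.append((i, j))
        target = V[i][j] - ctx.pair_adj(i, j)
        if j - i - 1 >= HP_MIN and abs(m.hairpin(j - i - 1) - target) < 1e-9:
            return
        for k in range(i + 1, min(j - 1, i + 2 + MAXLOOP)):
            l1 = k - i - 1
            for l in range(max(k + HP_MIN + 1, j - 1 - (MAXLOOP - l1)), j):
                if V[k][l] == _INF:
                    continue
                l2 = j - l - 1
                if l1 == 0 and l2 == 0:
                    e = V[k][l] + ctx.stack(i, j, k, l)
                else:
                    e = V[k][l] + m.internal(l1, l2)
                if abs(e - target) < 1e-9:
                    self._tb_v(k, l, pairs)
                    return
        if self.M2[i + 1][j - 1] != _INF and abs(
            self.M2[i + 1][j - 1] + m.ml_close - target
        ) < 1e-9:
            self._tb_m(i + 1, j - 1, pairs, need_two=True)
            return
        raise AssertionError("pair traceback failed")  # pragma: no cover

    def _tb_m(self, i: int, j: int, pairs: list, need_two: bool = False) -> None:
        m, V, M, M2 = self.m, self.V, self.M, self.M2
        target = M2[i][j] if need_two else M[i][j]
        if need_two:
            if j > i and M2[i][j - 1] != _INF and abs(
                M2[i][j - 1] + m.ml_unpaired - target
            ) < 1e-9:
                self._tb_m(i, j - 1, pairs, need_two=True)
                return
            for k in range(i + 1, j - HP_MIN):
                if V[k][j] == _INF or M[i][k - 1] == _INF:
                    continue
                if abs(M[i][k - 1] + V[k][j] + m.ml_branch - target) < 1e-9:
                    self._tb_m(i, k - 1, pairs)
                    self._tb_v(k, j, pairs)
                    return
            raise AssertionError("M2 traceback failed")  # pragma: no cover
        if j > i and M[i][j - 1] != _INF and abs(M[i][j - 1] + m.ml_unpaired - target) < 1e-9:
            self._tb_m(i, j - 1, pairs)
            return
        for k in range(i, j - HP_MIN):
            if V[k][j] == _INF:
                continue
            if abs(m.ml_unpaired * (k - i) + V[k][j] + m.ml_branch - target) < 1e-9:
                self._tb_v(k, j, pairs)
                return
        for k in range(i + 1, j - HP_MIN):
            if V[k][j] == _INF or M[i][k - 1] == _INF:
                continue
            if abs(M[i][k - 1] + V[k][j] + m.ml_branch - target) < 1e-9:
                self._tb_m(i, k - 1, pairs)
                self._tb_v(k, j, pairs)
                return
        raise AssertionError("M traceback failed")  # pragma: no cover


def mfe_fold(seq: str, model: EnergyModel = DEFAULT_MODEL) -> SecondaryStructure:
    """Minimum-free-energy nested structure of ``seq``.

    Deterministic: co-optimal structures are resolved by a fixed
    traceback preference (hairpin, then stack/internal by ascending
    inner-pair position, then multiloop; external branches leftmost).
    The all-unpaired structure (energy 0) is returned when nothing
    stabilising exists, so the result never has positive energy.
    """
    if not seq:
        raise ValueError("empty sequence")
    if len(seq) <= HP_MIN + 1:
        return SecondaryStructure("." * len(seq), 0.0)
    fold = _Fold(_SeqContext(seq, model))
    pairs = fold.traceback()
    db = pairs_to_dotbracket(pairs, len(seq))
    return SecondaryStructure(db, round(fold.W[len(seq)], 10))


def consensus_fold(
    rows: list[str] | dict[str, str],
    model: EnergyModel = DEFAULT_MODEL,
    covariance_bonus: float = 1.0,
    nonpair_penalty: float = 1.0,
    min_pair_frac: float = 0.5,
) -> tuple[str, float]:
    """Consensus structure and energy of an alignment (list of gapped rows).

    Column pairs are scored by the mean pairing energy of rows able to
    pair, rewarded per distinct compensatory pair type and penalised per
    row unable to pair; the same folding DP as ``mfe_fold`` then runs
    over columns.  A single row falls back to ``mfe_fold``.
    """
    if isinstance(rows, dict):
        rows = list(rows.values())
    if not rows:
        raise ValueError("empty alignment")
    if len(rows) == 1:
        s = mfe_fold(rows[0].replace("-", "").replace(".", ""), model)
        return s.dotbracket, s.energy
    if len({len(r) for r in rows}) != 1:
        raise ValueError("alignment rows differ in length")
    n = len(rows[0])
    if n <= HP_MIN + 1:
        return "." * n, 0.0
    ctx = _AlnContext(rows, model, covariance_bonus, nonpair_penalty, min_pair_frac)
    fold = _Fold(ctx)
    pairs = fold.traceback()
    return pairs_to_dotbracket(pairs, n), round(fold.W[n], 10)


# --- suboptimal-band pair sets (inside-outside) --------------------------

def pair_band_set(
    seq: str,
    band: float = 0.2,
    model: EnergyModel = DEFAULT_MODEL,
) -> dict[tuple[int, int], float]:
    """Pairs realisable in structures within ``band`` of the MFE.

    For each pairable (i, j), the best total energy of any structure
    containing that pair is V(i,j) + O(i,j) (inside plus outside).  The
    returned dict maps each pair whose best containing structure has
    energy <= (1 - band) * MFE (and <= 0) to that energy.  These pair
    sets restrict the Sankoff-style alignment DP to a tractable size.
    """
    n = len(seq)
    if n <= HP_MIN + 1:
        return {}
    fold = _Fold(_SeqContext(seq, model))
    m, V, M = fold.ctx.model, fold.V, fold.M
    mfe = fold.W[n]
    theta = min(0.0, (1.0 - band) * mfe) + 1e-9

    # prefix/suffix external energies
    Wp = fold.W  # prefix: Wp[i] = best fold of seq[0:i]
    Ws = [0.0] * (n + 2)  # suffix: Ws[j] = best fold of seq[j-1:], 1-based j
    for i in range(n, 0, -1):
        Ws[i] = Ws[i + 1]
        for j in range(i, n + 1):
            v = V[i - 1][j - 1]
            if v != _INF and v + Ws[j + 1] < Ws[i]:
                Ws[i] = v + Ws[j + 1]

    M0 = [[0.0] * n for _ in range(n)]  # multiloop segment, >= 0 branches
    for i in range(n):
        for j in range(i, n):
            e = m.ml_unpaired * (j - i + 1)
            if M[i][j] < e:
                e = M[i][j]
            M0[i][j] = e

    O = [[_INF] * n for _ in range(n)]
    order = sorted(
        ((i, j) for i in range(n) for j in range(i + HP_MIN + 1, n) if V[i][j] != _INF),
        key=lambda p: p[0] - p[1],  # decreasing span: outer pairs first
    )
    for i, j in order:
        best = Wp[i] + Ws[j + 2]  # external branch
        # directly inside (p, q) via stack or internal loop
        for p in range(max(0, i - 1 - MAXLOOP), i):
            l1 = i - p - 1
            for q in range(j + 1, min(n, j + 2 + (MAXLOOP - l1))):
                if V[p][q] == _INF or O[p][q] == _INF:
                    continue
                l2 = q - j - 1
                cost = (
                    fold.ctx.stack(p, q, i, j)
                    if l1 == 0 and l2 == 0
                    else m.internal(l1, l2)
                )
                e = O[p][q] + cost
                if e < best:
                    best = e
        # branch of a multiloop closed by (p, q), >= 1 sibling branch
        for p in range(0, i):
            for q in range(j + 1, n):
                if V[p][q] == _INF or O[p][q] == _INF:
                    continue
                left_any = M0[p + 1][i - 1] if p + 1 <= i - 1 else 0.0
                right_any = M0[j + 1][q - 1] if j + 1 <= q - 1 else 0.0
                left_one = M[p + 1][i - 1] if p + 1 <= i - 1 else _INF
                right_one = M[j + 1][q - 1] if j + 1 <= q - 1 else _INF
                sib = min(left_one + right_any, left_any + right_one)
                if sib == _INF:
                    continue
                e = O[p][q] + m.ml_close + m.ml_branch + sib
                if e < best:
                    best = e
        O[i][j] = best

    out: dict[tuple[int, int], float] = {}
    for i, j in order:
        e = V[i][j] + O[i][j]
        if e <= theta:
            out[(i, j)] = round(e, 10)
    return out


# --- abstract shapes / pointed shapes ------------------------------------

def _pair_tree(pairs: list[tuple[int, int]], n: int):
    """Nested forest of pairs: list of (i, j, children)."""
    root: list = []
    stack = [(-1, n, root)]
    for i, j in sorted(pairs):
        while stack[-1][1] < j:
            stack.pop()
        node = (i, j, [])
        stack[-1][2].append(node)
        stack.append(node)
    return root


def abstract_shape(structure: str, level: int = 5) -> str:
    """Abstract shape of a dot-bracket structure.

    Level 5 (default): every maximal chain of nested helices collapses to
    one ``[ ]`` and unpaired stretches are dropped; an open chain is
    ``_``.  Levels <= 3 keep helix interruptions (each contiguous stack
    run becomes its own bracket pair).
    """
    pairs = parse_dotbracket(structure)
    if not pairs:
        return "_"
    forest = _pair_tree(pairs, len(structure))

    def render(node) -> str:
        i, j, kids = node
        if level >= 4:
            # collapse chains: descend through single-child pair nodes
            while len(kids) == 1:
                i, j, kids = kids[0]
        else:
            # keep only contiguous-stack collapsing
            while len(kids) == 1 and kids[0][0] == i + 1 and kids[0][1] == j - 1:
                i, j, kids = kids[0]
        inner = "".join(render(k) for k in kids)
        return "[" + inner + "]"

    return "".join(render(node) for node in forest)


def hairpin_centers(structure: str) -> list[Fraction]:
    """Centers (i + j) / 2 of hairpin-closing pairs, 1-based, exact halves."""
    pairs = parse_dotbracket(structure)
    paired = set()
    for i, j in pairs:
        paired.add(i)
        paired.add(j)
    centers = []
    for i, j in pairs:
        if all(k not in paired for k in range(i + 1, j)):
            centers.append(Fraction((i + 1) + (j + 1), 2))
    return sorted(centers)


def pointed_shape(structure: str, level: int = 5) -> PointedShape:
    """Shape string plus hairpin centers — the pointed shape."""
    return PointedShape(abstract_shape(structure, level), hairpin_centers(structure))


def map_consensus_to_row(
    aln_row: str, ss_cons: str
) -> SecondaryStructure:
    """Project an alignment consensus structure onto one (gapped) row.

    Columns where the row is gapped are removed; pairs losing either
    partner are opened; hairpins shorter than the minimum are repaired
    by opening the offending closing pair, scanning left to right, until
    the structure is valid.  Energy is not recomputed here (set to 0).
    """
    if len(aln_row) != len(ss_cons):
        raise ValueError("row and SS_cons length differ")
    pairs = parse_dotbracket(ss_cons)
    keep = [c not in "-." for c in aln_row]
    newpos = {}
    p = 0
    for col, k in enumerate(keep):
        if k:
            newpos[col] = p
            p += 1
    mapped = [
        (newpos[i], newpos[j]) for i, j in pairs if keep[i] and keep[j]
    ]
    n = p
    # repair short hairpins: open violating closing pairs until stable
    changed = True
    while changed:
        changed = False
        mapped.sort()
        paired = set()
        for i, j in mapped:
            paired.update((i, j))
        for i, j in mapped:
            inner = range(i + 1, j)
            if all(k not in paired for k in inner) and (j - i - 1) < HP_MIN:
                mapped.remove((i, j))
                changed = True
                break
    return SecondaryStructure(pairs_to_dotbracket(mapped, n), 0.0)


@lru_cache(maxsize=4096)
def cached_mfe(seq: str) -> SecondaryStructure:
    """Memoised ``mfe_fold`` under the default model (hot path in scans)."""
    return mfe_fold(seq)
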