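"""Synthetic sRNA families, genomes and truth tables.

The generator emulates the hard case of sRNA homology search: families
whose *structure* is conserved while the *sequence* diverges.  An
ancestral transcript is designed with a prescribed hairpin architecture
(optionally with a conserved loop motif such as the anti-Shine-Dalgarno
CCUCCUCCC); homologs are evolved from it with compensatory
substitutions (paired positions only swap to other canonical/GU pairs,
loop-motif positions are frozen, other unpaired positions drift
freely, and short indels fall only in unpaired non-motif regions).
Members are planted into i.i.d.-uniform random genomes, each flanked by
two family-specific marker genes (protein-coding ORFs mutated at the
same divergence) so that flanking-gene synteny is testable; decoys are
dinucleotide-shuffled members planted without markers.  A taxonomy
table assigns the genomes to nested strain/species/genus/family groups.

The default dataset — three families of increasing divergence
(0.1 / 0.25 / 0.4) across six genomes, the most diverged family being
a three-hairpin loop-motif family — spans the regimes where plain
sequence search suffices, where covariance-model iteration is needed,
and where only the motif (thermodynamic-matcher) route still finds the
members.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .seqio import (
    AnnotationRecord,
    RepliconClass,
    SequenceRecord,
    write_fasta,
    write_gff3,
)
from .homsearch import Locus, PivotTranscript, dinucleotide_shuffle
from .rnastruct import mfe_fold, parse_dotbracket

__all__ = [
    "Ancestor",
    "FamilySpec",
    "SyntheticDataset",
    "simulate_ancestor",
    "evolve_member",
    "plant_genomes",
    "default_families",
    "make_default_dataset",
]

_PAIR_TYPES = ["GC", "CG", "AT", "TA", "GT", "TG"]
_PAIR_WEIGHTS = [0.30, 0.30, 0.15, 0.15, 0.05, 0.05]
_UNPAIRED_ALPHABET = "AACC"  # A/C cannot pair with each other: quiet spacers


@dataclass
class Ancestor:
    """A designed transcript: sequence, its MFE structure, and the
    frozen loop-motif positions (0-based)."""

    sequence: str
    structure: str
    motif_positions: list[int] = field(default_factory=list)


@dataclass
class FamilySpec:
    family_id: str
    ancestor: Ancestor
    divergence: float
    loop_motif: str | None = None


class AncestorDesignError(RuntimeError):
    pass


def simulate_ancestor(
    length: int,
    n_hairpins: int,
    loop_motif: str | None = None,
    seed: int = 0,
    stem_len: int = 6,
    max_tries: int = 80,
) -> Ancestor:
    """Design a sequence whose MFE structure is the prescribed hairpin
    array (rejection sampling until the fold matches the design).

    Stems are GC-biased so the designed structure dominates; unpaired
    regions are drawn from {A, C}, which cannot pair with each other.
    The loop motif, when given, is embedded verbatim in every loop.
    ``n_hairpins = 0`` yields an unstructured (shape ``_``) sequence.
    """
    rng = random.Random(seed)
    motif = (loop_motif or "").upper().replace("U", "T")
    if n_hairpins == 0:
        seq = "".join(rng.choice(_UNPAIRED_ALPHABET) for _ in range(length))
        return Ancestor(seq, "." * length, [])
    loop_len = max(len(motif), 6)
    per_hairpin = 2 * stem_len + loop_len
    n_spacer = length - n_hairpins * per_hairpin
    if n_spacer < 2 * (n_hairpins + 1):
        raise AncestorDesignError(
            f"length {length} too small for {n_hairpins} hairpins "
            f"(need >= {n_hairpins * per_hairpin + 2 * (n_hairpins + 1)})"
        )
    for _try in range(max_tries):
        # distribute spacer length over n_hairpins + 1 gaps, >= 2 each
        gaps = [2] * (n_hairpins + 1)
        for _ in range(n_spacer - 2 * (n_hairpins + 1)):
            gaps[rng.randrange(len(gaps))] += 1
        chars: list[str] = []
        struct: list[str] = []
        motif_pos: list[int] = []
        for h in range(n_hairpins):
            chars.extend(rng.choice(_UNPAIRED_ALPHABET) for _ in range(gaps[h]))
            struct.extend("." * gaps[h])
            stem_pairs = rng.choices(_PAIR_TYPES, weights=_PAIR_WEIGHTS, k=stem_len)
            left = [p[0] for p in stem_pairs]
            right = [p[1] for p in reversed(stem_pairs)]
            if motif:
                pad = loop_len - len(motif)
                lpad = rng.randint(0, pad)
                loop = (
                    [rng.choice(_UNPAIRED_ALPHABET) for _ in range(lpad)]
                    + list(motif)
                    + [rng.choice(_UNPAIRED_ALPHABET) for _ in range(pad - lpad)]
                )
                mstart = len(chars) + stem_len + lpad
                motif_pos.extend(range(mstart, mstart + len(motif)))
            else:
                loop = [rng.choice(_UNPAIRED_ALPHABET) for _ in range(loop_len)]
            chars.extend(left + loop + right)
            struct.extend("(" * stem_len + "." * loop_len + ")" * stem_len)
        chars.extend(rng.choice(_UNPAIRED_ALPHABET) for _ in range(gaps[-1]))
        struct.extend("." * gaps[-1])
        seq = "".join(chars)
        designed = "".join(struct)
        if mfe_fold(seq).dotbracket == designed:
            return Ancestor(seq, designed, motif_pos)
    raise AncestorDesignError(
        f"no sequence folding into the design after {max_tries} tries; "
        "try a larger length or fewer hairpins"
    )


def evolve_member(ancestor: Ancestor, divergence: float, seed: int = 0) -> Ancestor:
    """Evolve a homolog at the given divergence.

    Paired positions mutate only compensatorily (the pair is replaced
    by another canonical/GU pair, both partners together); loop-motif
    positions are frozen; other unpaired positions substitute freely at
    the divergence rate; indels (rate divergence/5) occur only at
    unpaired, non-motif positions.  All ancestral pairs therefore stay
    realisable in the homolog.
    """
    if not (0 <= divergence <= 1):
        raise ValueError("divergence must be in [0, 1]")
    rng = random.Random(seed)
    seq = list(ancestor.sequence)
    pairs = parse_dotbracket(ancestor.structure)
    frozen = set(ancestor.motif_positions)
    paired = set()
    for i, j in pairs:
        paired.update((i, j))
    # compensatory pair replacement: substitutions act per *site* at the
    # divergence rate, and a compensatory event hits both partners, so a
    # pair is replaced (by a different canonical/GU pair) whenever either
    # of its two sites is hit: probability 1 - (1 - d)^2
    pair_rate = 1 - (1 - divergence) ** 2
    for i, j in pairs:
        if rng.random() < pair_rate:
            current = seq[i] + seq[j]
            p = rng.choice([t for t in _PAIR_TYPES if t != current])
            seq[i], seq[j] = p[0], p[1]
    # free substitutions at unpaired, non-motif positions
    for k in range(len(seq)):
        if k in paired or k in frozen:
            continue
        if rng.random() < divergence:
            seq[k] = rng.choice("ACGT".replace(seq[k], ""))
    # indels in unpaired non-motif regions
    indel_rate = divergence / 5
    out: list[str] = []
    out_struct: list[str] = []
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    new_motif: list[int] = []
    for k, c in enumerate(seq):
        editable = k not in paired and k not in frozen
        if editable and rng.random() < indel_rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(rng.choice(_UNPAIRED_ALPHABET))  # insertion before k
            out_struct.append(".")
        if k in frozen:
            new_motif.append(len(out))
        out.append(c)
        out_struct.append(ancestor.structure[k])
    return Ancestor("".join(out), "".join(out_struct), new_motif)


@dataclass
class SyntheticDataset:
    genomes: list[SequenceRecord]
    annotations: list[AnnotationRecord]
    taxonomy: pd.DataFrame
    truth: pd.DataFrame
    pivots: list[PivotTranscript]
    families: list[FamilySpec]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genomes, outdir / "genomes.fa")
        write_gff3(self.annotations, outdir / "annotations.gff3")
        self.taxonomy.to_csv(outdir / "taxonomy.tsv", sep="\t", index=False)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        pivot_records = [
            SequenceRecord(p.name, p.sequence, organism="org0",
                           replicon_class=p.replicon_class)
            for p in self.pivots
        ]
        write_fasta(pivot_records, outdir / "pivots.fa")


def _random_orf(rng: random.Random, n_codons: int = 50) -> str:
    codons = []
    bases = "ACGT"
    stops = {"TAA", "TAG", "TGA"}
    for _ in range(n_codons - 1):
        while True:
            c = "".join(rng.choice(bases) for _ in range(3))
            if c not in stops:
                codons.append(c)
                break
    return "ATG" + "".join(codons) + "TAA"


def _mutate_orf(orf: str, divergence: float, rng: random.Random) -> str:
    """Mutate an ORF at ~divergence/4 per site, never creating a stop."""
    stops = {"TAA", "TAG", "TGA"}
    codons = [orf[i : i + 3] for i in range(0, len(orf), 3)]
    out = [codons[0]]
    for c in codons[1:-1]:
        new = c
        for _ in range(10):
            trial = "".join(
                (rng.choice("ACGT".replace(b, ""))
                 if rng.random() < divergence / 4 else b)
                for b in c
            )
            if trial not in stops:
                new = trial
                break
        out.append(new)
    out.append(codons[-1])
    return "".join(out)


_DEFAULT_TAXONOMY = [
    # organism, strain, species, genus, family, order
    ("org0", "st0", "sp1", "gen1", "fam1", "ord1"),
    ("org1", "st1", "sp1", "gen1", "fam1", "ord1"),
    ("org2", "st2", "sp2", "gen1", "fam1", "ord1"),
    ("org3", "st3", "sp3", "gen2", "fam1", "ord1"),
    ("org4", "st4", "sp4", "gen3", "fam2", "ord1"),
    ("org5", "st5", "sp5", "gen3", "fam2", "ord1"),
]


def plant_genomes(
    families: list[FamilySpec],
    n_genomes: int = 6,
    genome_len: int = 8000,
    seed: int = 18,
    gc: float = 0.5,
    marker_codons: int = 50,
    with_decoys: bool = True,
) -> SyntheticDataset:
    """Plant family members (with flanking marker genes) and decoys into
    random genomes; emit genomes, annotations, taxonomy and truth.

    Genome 0 carries each family's ancestor verbatim (the pivot); every
    other genome carries one member evolved at the family's divergence.
    Each member cassette is ``markerA -- gap -- member -- gap --
    markerB`` with the markers mutated at the same divergence; decoys
    are dinucleotide-shuffled members planted without markers.  Output
    is byte-identical for a given seed.
    """
    rng = random.Random(seed)
    bases = "GC" if gc >= 1 else "ACGT"
    taxonomy_rows = [
        _DEFAULT_TAXONOMY[i % len(_DEFAULT_TAXONOMY)] for i in range(n_genomes)
    ]
    taxonomy = pd.DataFrame(
        taxonomy_rows,
        columns=["organism", "strain", "species", "genus", "family", "order"],
    )

    def bg(n: int) -> str:
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        return "".join(rng.choices("ACGT", weights=p, k=n))

    markers = {
        f.family_id: (_random_orf(rng, marker_codons), _random_orf(rng, marker_codons))
        for f in families
    }

    genomes: list[SequenceRecord] = []
    annotations: list[AnnotationRecord] = []
    truth_rows: list[dict] = []
    pivots: list[PivotTranscript] = []

    for g in range(n_genomes):
        seqid = f"g{g}"
        organism = taxonomy.at[g, "organism"]
        cassettes: list[tuple[str, list]] = []  # (sequence, metadata list)
        for f in families:
            if g == 0:
                member = f.ancestor
            else:
                member = evolve_member(
                    f.ancestor, f.divergence, seed=rng.randrange(2**31)
                )
            up = _mutate_orf(markers[f.family_id][0], f.divergence if g else 0.0, rng)
            down = _mutate_orf(markers[f.family_id][1], f.divergence if g else 0.0, rng)
            gap1 = bg(rng.randint(15, 30))
            gap2 = bg(rng.randint(15, 30))
            cassette = up + gap1 + member.sequence + gap2 + down
            meta = [
                ("marker", f.family_id, "up", 0, len(up)),
                ("member", f.family_id, member,
                 len(up) + len(gap1), len(up) + len(gap1) + len(member.sequence)),
                ("marker", f.family_id, "down",
                 len(cassette) - len(down), len(cassette)),
            ]
            cassettes.append((cassette, meta))
            if with_decoys:
                decoy = dinucleotide_shuffle(member.sequence, rng)
                cassettes.append(
                    (decoy, [("decoy", f.family_id, None, 0, len(decoy))])
                )
        rng.shuffle(cassettes)
        total_cassette = sum(len(c) for c, _m in cassettes)
        n_bg = genome_len - total_cassette
        if n_bg < (len(cassettes) + 1) * 50:
            raise ValueError("genome_len too small for planted material")
        gap_sizes = [50] * (len(cassettes) + 1)
        for _ in range(n_bg - 50 * (len(cassettes) + 1)):
            gap_sizes[rng.randrange(len(gap_sizes))] += 1
        parts: list[str] = []
        pos = 0
        for idx, (cassette, meta) in enumerate(cassettes):
            chunk = bg(gap_sizes[idx])
            parts.append(chunk)
            pos += len(chunk)
            parts.append(cassette)
            for kind, fam_id, payload, a, b in meta:
                start, end = pos + a, pos + b
                if kind == "marker":
                    annotations.append(
                        AnnotationRecord(
                            gene_id=f"{fam_id}_{seqid}_{payload}",
                            seqid=seqid,
                            start=start + 1,
                            end=end,
                            strand="+",
                            product=f"{fam_id} flanking marker ({payload})",
                        )
                    )
                elif kind == "member":
                    truth_rows.append(
                        {
                            "family_id": fam_id,
                            "genome": seqid,
                            "start": start + 1,
                            "end": end,
                            "strand": "+",
                            "divergence": 0.0 if g == 0 else _fam_div(families, fam_id),
                            "role": "member",
                        }
                    )
                    if g == 0:
                        pivots.append(
                            PivotTranscript(
                                name=_pivot_name(fam_id),
                                sequence=payload.sequence,
                                locus=Locus(seqid, start, end, "+"),
                                replicon_class=RepliconClass.CHROMOSOME,
                            )
                        )
                else:
                    truth_rows.append(
                        {
                            "family_id": fam_id,
                            "genome": seqid,
                            "start": start + 1,
                            "end": end,
                            "strand": "+",
                            "divergence": _fam_div(families, fam_id),
                            "role": "decoy",
                        }
                    )
            pos += len(cassette)
        parts.append(bg(gap_sizes[-1]))
        genomes.append(
            SequenceRecord(
                seqid,
                "".join(parts),
                organism=organism,
                replicon_class=RepliconClass.CHROMOSOME,
            )
        )

    truth = pd.DataFrame(truth_rows)
    return SyntheticDataset(genomes, annotations, taxonomy, truth, pivots, families)


def _fam_div(families: list[FamilySpec], fam_id: str) -> float:
    return next(f.divergence for f in families if f.family_id == fam_id)


def _pivot_name(fam_id: str) -> str:
    return f"Smel{fam_id[-4:]}" if not fam_id.startswith("Smel") else fam_id


def default_families(seed: int = 16) -> list[FamilySpec]:
    """The standard study conditions: three families of increasing
    divergence; the most diverged one is a three-hairpin family with
    the anti-Shine-Dalgarno loop motif in every hairpin."""
    a1 = simulate_ancestor(70, 2, None, seed=seed)
    a2 = simulate_ancestor(70, 2, None, seed=seed + 1)
    a3 = simulate_ancestor(90, 3, "CCUCCUCCC", seed=seed + 2)
    return [
        FamilySpec("famA", a1, 0.10),
        FamilySpec("famB", a2, 0.25),
        FamilySpec("famC", a3, 0.40, loop_motif="CCUCCUCCC"),
    ]


def make_default_dataset(seed: int = 18) -> SyntheticDataset:
    """Three families x six genomes at divergences 0.1 / 0.25 / 0.4."""
    fams = default_families(seed=16)
    return plant_genomes(fams, n_genomes=6, genome_len=8000, seed=seed)
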