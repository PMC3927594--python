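"""Readers/writers for FASTA, GFF3 and Stockholm, plus strand-aware extraction.

Conventions
-----------
* Internal coordinates are 0-based half-open; everything crossing an I/O
  boundary (FASTA headers, GFF3, reports) is 1-based inclusive.
* Sequences are stored as DNA over {A,C,G,T}; U is accepted on read and
  mapped to T.  Folding/display modules convert back to RNA as needed.
* FASTA header metadata uses a ``key=value`` convention:
  ``>id organism=... replicon_class=...``.
* Stockholm alignments carry the consensus structure on a
  ``#=GC SS_cons`` line (dot-bracket; WUSS bracket variants ``<>``,
  ``[]``, ``{}`` are normalised to ``()`` on read).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

__all__ = [
    "RepliconClass",
    "SequenceRecord",
    "AnnotationRecord",
    "StockholmAlignment",
    "FastaParseError",
    "StructureError",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_stockholm",
    "write_stockholm",
    "extract_locus",
    "reverse_complement",
]


class RepliconClass(str, Enum):
    """Bacterial replicon categories used by the plausibility rules.

    Many alphaproteobacteria carry, besides the chromosome, one or more
    large stable secondary replicons (chromids/megaplasmids) and smaller
    accessory plasmids; sRNA families tend to stay on the same replicon
    class within closely related strains.
    """

    CHROMOSOME = "chromosome"
    CHROMID_MEGAPLASMID = "chromid_megaplasmid"
    ACCESSORY_PLASMID = "accessory_plasmid"
    UNKNOWN = "unknown"


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; carries the offending line number."""


class StructureError(ValueError):
    """Raised for unbalanced or otherwise invalid consensus structures."""


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_VALID = set("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _clean_sequence(raw: str, lineno: int, mask_ambiguous: bool) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _VALID
    if bad:
        if mask_ambiguous:
            seq = "".join(c if c in _VALID else "N" for c in seq)
        else:
            raise FastaParseError(
                f"line {lineno}: ambiguous/invalid characters {sorted(bad)}"
            )
    return seq


@dataclass
class SequenceRecord:
    """One replicon (or transcript) sequence with organism/replicon metadata."""

    id: str
    sequence: str
    organism: str = ""
    replicon_class: RepliconClass = RepliconClass.UNKNOWN

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if isinstance(self.replicon_class, str):
            self.replicon_class = RepliconClass(self.replicon_class)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AnnotationRecord:
    """A protein-coding gene annotation (1-based inclusive coordinates)."""

    gene_id: str
    seqid: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: invalid span {self.start}..{self.end}"
            )
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")


@dataclass
class StockholmAlignment:
    """A multiple alignment with a consensus-structure (SS_cons) line."""

    rows: dict[str, str] = field(default_factory=dict)
    ss_cons: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if self.ss_cons:
            lengths.add(len(self.ss_cons))
        if len(lengths) > 1:
            raise StructureError(f"ragged alignment: lengths {sorted(lengths)}")
        if self.ss_cons:
            _check_balanced(self.ss_cons)

    @property
    def length(self) -> int:
        if self.ss_cons:
            return len(self.ss_cons)
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def ungapped(self, name: str) -> str:
        return self.rows[name].replace("-", "").replace(".", "")


def _check_balanced(ss: str) -> None:
    depth = 0
    for i, c in enumerate(ss):
        if c == "(":
            depth += 1
        elif c == ")":
            depth -= 1
            if depth < 0:
                raise StructureError(f"unbalanced SS_cons at column {i + 1}")
    if depth != 0:
        raise StructureError("unbalanced SS_cons: unclosed '('")


def _parse_header(line: str) -> tuple[str, str, RepliconClass]:
    fields = line[1:].split()
    if not fields:
        raise FastaParseError("empty FASTA header")
    rid = fields[0]
    organism = ""
    rclass = RepliconClass.UNKNOWN
    for tok in fields[1:]:
        if "=" not in tok:
            continue
        key, val = tok.split("=", 1)
        if key == "organism":
            organism = val
        elif key == "replicon_class":
            try:
                rclass = RepliconClass(val)
            except ValueError:
                rclass = RepliconClass.UNKNOWN
    return rid, organism, rclass


def read_fasta(path: str | Path | io.TextIOBase, *, mask_ambiguous: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, in file order.

    ``U`` is mapped to ``T``; other non-ACGT characters raise
    :class:`FastaParseError` unless ``mask_ambiguous`` is set (then they
    become ``N`` — note downstream search modules treat N as unmatched).
    """
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
    else:
        lines = Path(path).read_text().splitlines()
    records: list[SequenceRecord] = []
    header: tuple[str, str, RepliconClass] | None = None
    chunks: list[str] = []
    header_line = 0

    def flush(lineno: int) -> None:
        if header is None:
            return
        seq = _clean_sequence("".join(chunks), lineno, mask_ambiguous)
        if not seq:
            raise FastaParseError(f"line {header_line}: record {header[0]!r} has no sequence")
        records.append(SequenceRecord(header[0], seq, header[1], header[2]))

    for i, line in enumerate(lines, 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush(i)
            header = _parse_header(line)
            header_line = i
            chunks = []
        else:
            if header is None:
                raise FastaParseError(f"line {i}: sequence before first header")
            chunks.append(line)
    flush(len(lines))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, *, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            meta = ""
            if rec.organism:
                meta += f" organism={rec.organism}"
            if rec.replicon_class is not RepliconClass.UNKNOWN:
                meta += f" replicon_class={rec.replicon_class.value}"
            fh.write(f">{rec.id}{meta}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def extract_locus(record: SequenceRecord, start: int, end: int, strand: str) -> str:
    """Extract ``record[start..end]`` (1-based inclusive); minus strand is
    reverse-complemented."""
    if not (1 <= start <= end <= len(record)):
        raise IndexError(
            f"span {start}..{end} out of range for {record.id!r} (len {len(record)})"
        )
    sub = record.sequence[start - 1 : end]
    return reverse_complement(sub) if strand == "-" else sub


# --- GFF3 ---------------------------------------------------------------

def read_gff3(path: str | Path) -> list[AnnotationRecord]:
    """Read protein-coding gene features (type ``gene`` or ``CDS``) from GFF3."""
    out: list[AnnotationRecord] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise FastaParseError(f"line {lineno}: GFF3 needs 9 columns")
        seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts
        if ftype not in ("gene", "CDS"):
            continue
        attr = dict(
            kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
        )
        gid = attr.get("ID") or attr.get("Name") or f"{seqid}:{start}-{end}"
        out.append(
            AnnotationRecord(
                gene_id=gid,
                seqid=seqid,
                start=int(start),
                end=int(end),
                strand=strand,
                product=attr.get("product", ""),
            )
        )
    return out


def write_gff3(annotations: Iterable[AnnotationRecord], path: str | Path, *, source: str = "rfamforge") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            attrs = f"ID={a.gene_id}"
            if a.product:
                attrs += f";product={a.product}"
            fh.write(
                f"{a.seqid}\t{source}\tgene\t{a.start}\t{a.end}\t.\t{a.strand}\t.\t{attrs}\n"
            )


# --- Stockholm ----------------------------------------------------------

_WUSS = str.maketrans("<>[]{}", "()()()")


def read_stockholm(path: str | Path | io.TextIOBase) -> StockholmAlignment:
    """Read a (single) Stockholm alignment with a ``#=GC SS_cons`` line.

    Interleaved blocks are concatenated per row name; WUSS-style brackets
    in SS_cons are normalised to plain parentheses and non-bracket
    annotation characters to dots.
    """
    if isinstance(path, io.TextIOBase):
        text = path.read()
    else:
        text = Path(path).read_text()
    rows: dict[str, str] = {}
    ss_parts: list[str] = []
    for line in text.splitlines():
        line = line.rstrip()
        if not line or line.startswith("//") or line == "# STOCKHOLM 1.0":
            continue
        if line.startswith("#=GC SS_cons"):
            ss_parts.append(line.split(None, 2)[2])
        elif line.startswith("#"):
            continue
        else:
            name, seq = line.split(None, 1)
            rows[name] = rows.get(name, "") + seq.replace(" ", "")
    ss = "".join(ss_parts).translate(_WUSS)
    ss = "".join(c if c in "()" else "." for c in ss)
    return StockholmAlignment(rows=rows, ss_cons=ss)


def write_stockholm(aln: StockholmAlignment, path: str | Path) -> None:
    aln.validate()
    width = max((len(n) for n in aln.rows), default=0)
    width = max(width, len("#=GC SS_cons"))
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n\n")
        for name, seq in aln.rows.items():
            fh.write(f"{name:<{width}}  {seq}\n")
        if aln.ss_cons:
            fh.write(f"{'#=GC SS_cons':<{width}}  {aln.ss_cons}\n")
        fh.write("//\n")
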