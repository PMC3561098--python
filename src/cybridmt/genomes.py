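"""Circular genome data model, wraparound interval algebra, and standard-format I/O.

Plant mitochondrial genomes are conventionally reported as a single circular
"master circle" with 1-based inclusive coordinates.  Everything downstream
(synteny, repeats, unique regions) works in that convention; conversion to
0-based half-open happens only at the BED boundary.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Malformed input file (names the record and offset where possible)."""


class DomainError(ValueError):
    """An operation was asked for outside its domain (e.g. wrap on linear seq)."""


def revcomp(s: str) -> str:
    """Reverse complement of a nucleotide string over {A,C,G,T,N}."""
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CircularSeq:
    """A (usually circular) nucleotide sequence with a text label.

    ``length`` always equals ``len(seq)``; the sequence is stored uppercase
    over the alphabet {A,C,G,T,N}.
    """

    id: str
    seq: str
    is_circular: bool = True

    def __post_init__(self) -> None:
        if len(self.seq) == 0:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - VALID_BASES
        if bad:
            for off, c in enumerate(self.seq):
                if c not in VALID_BASES:
                    raise FormatError(
                        f"record {self.id!r}: non-nucleotide character "
                        f"{c!r} at position {off + 1}"
                    )

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Interval:
    """1-based inclusive interval; ``start > end`` marks a wraparound interval
    on a circular sequence (it covers start..L then 1..end)."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise DomainError(f"interval coordinates must be >= 1: {self}")
        if self.strand not in ("+", "-"):
            raise DomainError(f"strand must be '+' or '-': {self.strand!r}")

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def span(self, L: int | None = None) -> int:
        """Number of positions covered; a wrapping interval needs ``L``."""
        if not self.wraps:
            return self.end - self.start + 1
        if L is None:
            raise DomainError("span of a wrapping interval requires the genome length")
        return L - self.start + 1 + self.end

    def positions(self, L: int) -> list[int]:
        """All covered 1-based positions in order (small intervals/tests only)."""
        if not self.wraps:
            return list(range(self.start, self.end + 1))
        return list(range(self.start, L + 1)) + list(range(1, self.end + 1))


@dataclass
class GeneModel:
    """A gene as an ordered list of exon intervals (handles trans/cis splicing)."""

    gene_id: str
    intervals: list[Interval]
    type: str = "protein"  # protein | tRNA | rRNA | orf
    product: str = ""

    def __post_init__(self) -> None:
        if not self.intervals:
            raise DomainError(f"gene {self.gene_id!r}: no intervals")

    @property
    def strand(self) -> str:
        return self.intervals[0].strand

    def cds_length(self, L: int | None = None) -> int:
        return sum(iv.span(L) for iv in self.intervals)


def extract(seq: CircularSeq, iv: Interval) -> str:
    """Extract the bases covered by ``iv``; minus strand returns the reverse
    complement.  Wrapping intervals are only legal on circular sequences."""
    L = seq.length
    if iv.end > L or iv.start > L:
        raise DomainError(
            f"interval {iv.start}-{iv.end} out of range for {seq.id!r} (L={L})"
        )
    if iv.wraps:
        if not seq.is_circular:
            raise DomainError(
                f"wrapping interval {iv.start}-{iv.end} on linear sequence {seq.id!r}"
            )
        s = seq.seq[iv.start - 1 :] + seq.seq[: iv.end]
    else:
        s = seq.seq[iv.start - 1 : iv.end]
    return revcomp(s) if iv.strand == "-" else s


def gc_content(seq: CircularSeq) -> float:
    """G+C fraction over unambiguous bases (N excluded from both counts)."""
    g = seq.seq.count("G")
    c = seq.seq.count("C")
    acgt = g + c + seq.seq.count("A") + seq.seq.count("T")
    if acgt == 0:
        raise DomainError(f"{seq.id!r}: GC content undefined (no A/C/G/T bases)")
    return (g + c) / acgt


# ---------------------------------------------------------------------------
# interval algebra helpers

def _linear_pieces(iv: Interval, L: int) -> list[tuple[int, int]]:
    if iv.wraps:
        return [(iv.start, L), (1, iv.end)]
    return [(iv.start, iv.end)]


def union_length(intervals: Iterable[Interval], L: int) -> int:
    """Total number of distinct positions covered by the intervals
    (wraparound-aware; overlaps counted once)."""
    pieces = sorted(
        p for iv in intervals for p in _linear_pieces(iv, L)
    )
    total = 0
    cur_s = cur_e = None
    for s, e in pieces:
        if cur_e is None:
            cur_s, cur_e = s, e
        elif s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    if cur_e is not None:
        total += cur_e - cur_s + 1
    return total


def coverage_mask(intervals: Iterable[Interval], L: int):
    """Boolean numpy array of length L; index i covers 1-based position i+1."""
    import numpy as np

    mask = np.zeros(L, dtype=bool)
    for iv in intervals:
        for s, e in _linear_pieces(iv, L):
            mask[s - 1 : e] = True
    return mask


# ---------------------------------------------------------------------------
# FASTA I/O

def read_fasta(path: str | Path, circular: bool = True) -> list[CircularSeq]:
    """Read a FASTA file into CircularSeq records (uppercased, validated).

    Circularity comes from the ``circular`` flag, or per record from a
    ``circular=true/false`` token in the description; default circular.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    out: list[CircularSeq] = []
    for rec in records:
        s = str(rec.seq).upper()
        is_circ = circular
        desc = rec.description.lower()
        if "circular=false" in desc or "linear" in desc.split():
            is_circ = False
        elif "circular=true" in desc:
            is_circ = True
        out.append(CircularSeq(id=rec.id, seq=s, is_circular=is_circ))
    return out


def write_fasta(seqs: Sequence[CircularSeq], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(s.seq), id=s.id,
                  description=f"circular={'true' if s.is_circular else 'false'}")
        for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# annotation I/O: GFF3 canonical, 4-column TSV accepted for fixtures

def read_annotations(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (via gffutils) or a simple TSV
    (gene_id, start, end, strand[, type])."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##gff") or "\t" in first and len(first.split("\t")) == 9:
        return _read_gff3(path)
    return _read_tsv_annotations(path)


def _read_gff3(path: Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", force=True,
        keep_order=True,
    )
    genes: dict[str, GeneModel] = {}
    wanted = {"gene", "CDS", "tRNA", "rRNA", "ORF"}
    for feat in db.all_features():
        if feat.featuretype not in wanted:
            continue
        gid = feat.attributes.get("ID", feat.attributes.get("Parent", [feat.id]))[0]
        ftype = {"tRNA": "tRNA", "rRNA": "rRNA", "ORF": "orf"}.get(
            feat.featuretype, "protein"
        )
        iv = Interval(feat.start, feat.end, feat.strand if feat.strand in "+-" else "+")
        if feat.featuretype == "CDS" and gid in genes:
            genes[gid].intervals.append(iv)
        elif gid not in genes:
            product = (feat.attributes.get("product") or [""])[0]
            genes[gid] = GeneModel(gid, [iv], type=ftype, product=product)
    return list(genes.values())


def _read_tsv_annotations(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected >=4 tab-separated columns")
            gid, start, end, strand = parts[:4]
            gtype = parts[4] if len(parts) > 4 else "protein"
            genes.append(GeneModel(gid, [Interval(int(start), int(end), strand)], type=gtype))
    return genes


def write_gff3(genes: Sequence[GeneModel], seqid: str, path: str | Path,
               source: str = "cybridmt") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            ftype = {"protein": "gene", "orf": "ORF"}.get(g.type, g.type)
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            for iv in g.intervals:
                fh.write(
                    f"{seqid}\t{source}\t{ftype}\t{iv.start}\t{iv.end}\t.\t"
                    f"{iv.strand}\t.\t{attrs}\n"
                )


def to_bed_line(seqid: str, iv: Interval, name: str, L: int | None = None) -> str:
    """BED (0-based half-open) export; a wrapping interval emits two lines."""
    if iv.wraps:
        if L is None:
            raise DomainError("BED export of a wrapping interval needs genome length")
        return (f"{seqid}\t{iv.start - 1}\t{L}\t{name}\t0\t{iv.strand}\n"
                f"{seqid}\t0\t{iv.end}\t{name}\t0\t{iv.strand}")
    return f"{seqid}\t{iv.start - 1}\t{iv.end}\t{name}\t0\t{iv.strand}"


def write_bed(entries: Iterable[tuple[str, Interval, str]], path: str | Path,
              L: int | None = None) -> None:
    with open(path, "w") as fh:
        for seqid, iv, name in entries:
            fh.write(to_bed_line(seqid, iv, name, L) + "\n")
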