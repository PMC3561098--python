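"""Repeat detection within a single genome.

Plant mitogenomes carry a small number of large repeats (kilobase scale,
the substrate of intramolecular recombination that yields subgenomic
circles) and many short repeats (tens to hundreds of bp) implicated in
rearrangement.  Both are found by genome self-comparison with the seeded
aligner; repeats are counted as PAIRS of disjoint copies, direct or
inverted, with tandem (overlapping) arrangements excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genomes import CircularSeq, Interval, union_length
from .localalign import LocalMatch, find_local_matches


@dataclass(frozen=True)
class RepeatPair:
    """Two disjoint copies of a repeated sequence; iv1 precedes iv2."""

    iv1: Interval
    iv2: Interval
    kind: str  # direct | inverted
    identity: float
    rep_len: int

    @property
    def name(self) -> str:
        return f"{self.kind[0].upper()}{self.iv1.start}-{self.iv2.start}"


@dataclass
class RepeatSet:
    large: list[RepeatPair] = field(default_factory=list)
    short: list[RepeatPair] = field(default_factory=list)
    short_fraction: float = 0.0


def _canonical_pairs(matches: list[LocalMatch], L: int,
                     min_identity: float) -> list[RepeatPair]:
    """Self-comparison matches come in mirrored duplicates; canonicalize so
    iv1 starts before iv2, require disjoint copies, and deduplicate."""
    seen = set()
    pairs = []
    for m in matches:
        if m.identity < min_identity:
            continue
        iv_a, iv_b = m.q_iv, m.t_iv
        if iv_a.start > iv_b.start:
            iv_a, iv_b = iv_b, iv_a
        if _overlap(iv_a, iv_b, L):
            continue  # tandem/self-overlapping: different phenomenon
        key = (iv_a.start, iv_a.end, iv_b.start, iv_b.end, m.strand)
        if key in seen:
            continue
        seen.add(key)
        kind = "direct" if m.strand == "+" else "inverted"
        rep_len = max(iv_a.span(L), iv_b.span(L))
        pairs.append(RepeatPair(iv_a, iv_b, kind, m.identity, rep_len))
    pairs.sort(key=lambda p: (p.iv1.start, p.iv2.start))
    return pairs


def _overlap(a: Interval, b: Interval, L: int) -> bool:
    pos_a = set(a.positions(L)) if a.wraps else None
    if a.wraps or b.wraps:
        sa = set(a.positions(L))
        return bool(sa & set(b.positions(L)))
    return a.start <= b.end and b.start <= a.end


def find_repeats(
    g: CircularSeq,
    min_len: int = 30,
    max_len: int = 500,
    min_identity: float = 0.90,
    include_inverted: bool = True,
    *,
    seed_k: int = 8,
) -> list[RepeatPair]:
    """Short repeats: disjoint copy pairs with ``min_len <= rep_len <=
    max_len`` at ``>= min_identity``, direct and (optionally) inverted."""
    if min_len > max_len:
        raise ValueError(f"min_len ({min_len}) > max_len ({max_len})")
    matches = find_local_matches(
        g, g, min_len=max(min_len, seed_k), min_identity=min_identity,
        seed_k=seed_k,
    )
    pairs = _canonical_pairs(matches, g.length, min_identity)
    out = []
    for p in pairs:
        if not include_inverted and p.kind == "inverted":
            continue
        if min_len <= p.rep_len <= max_len:
            out.append(p)
    return out


def find_large_repeats(
    g: CircularSeq,
    large_min: int = 1000,
    min_identity: float = 0.95,
    *,
    seed_k: int = 12,
) -> list[RepeatPair]:
    """Large repeats (recombination substrate), sorted by length descending."""
    matches = find_local_matches(
        g, g, min_len=large_min, min_identity=min_identity, seed_k=seed_k,
    )
    pairs = _canonical_pairs(matches, g.length, min_identity)
    pairs = [p for p in pairs if p.rep_len >= large_min]
    pairs.sort(key=lambda p: (-p.rep_len, p.iv1.start))
    return pairs


def short_repeat_fraction(pairs: list[RepeatPair], L: int) -> float:
    """Union span of all short-repeat copies (both copies of each pair,
    overlaps counted once) divided by genome length."""
    ivs = [iv for p in pairs for iv in (p.iv1, p.iv2)]
    return union_length(ivs, L) / L


def detect_repeats(
    g: CircularSeq,
    short_min: int = 30,
    short_max: int = 500,
    short_identity: float = 0.90,
    large_min: int = 1000,
    large_identity: float = 0.95,
) -> RepeatSet:
    """Convenience wrapper: both repeat classes plus the short-repeat
    genome fraction."""
    short = find_repeats(g, short_min, short_max, short_identity)
    large = find_large_repeats(g, large_min, large_identity)
    return RepeatSet(large=large, short=short,
                     short_fraction=short_repeat_fraction(short, g.length))


def repeats_to_frame(pairs: list[RepeatPair]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "kind": p.kind,
                "start1": p.iv1.start,
                "end1": p.iv1.end,
                "start2": p.iv2.start,
                "end2": p.iv2.end,
                "rep_len": p.rep_len,
                "identity": round(p.identity, 4),
            }
            for p in pairs
        ],
        columns=["kind", "start1", "end1", "start2", "end2", "rep_len",
                 "identity"],
    )
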