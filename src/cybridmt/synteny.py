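"""Syntenic-region detection between two mitotype genomes.

Local matches are chained into syntenic regions (labelled S1, S2, ... in
focal-genome coordinate order), overlap on the focal genome is resolved in
favour of the higher-scoring region, and per-genome coverage fractions are
reported.  Dot-plot segment endpoints can be exported for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .genomes import CircularSeq, Interval, union_length
from .localalign import LocalMatch, find_local_matches


@dataclass(frozen=True)
class SyntenicRegion:
    label: str
    a_iv: Interval
    b_iv: Interval
    orientation: str  # same | opposite
    identity: float
    score: int = 0


@dataclass(frozen=True)
class SyntenyMap:
    regions: list[SyntenicRegion]
    coverage_a: float
    coverage_b: float
    a_len: int
    b_len: int
    a_id: str = "A"
    b_id: str = "B"


def detect_syntenic_regions(
    a: CircularSeq,
    b: CircularSeq,
    min_len: int = 1000,
    min_identity: float = 0.95,
    *,
    chain_gap: int = 100,
    overlap_slack: int = 50,
    seed_k: int = 12,
) -> SyntenyMap:
    """Detect syntenic regions of at least ``min_len`` bp and
    ``min_identity`` similarity between genomes ``a`` and ``b``.

    Matches are chained during alignment (co-linear neighbours within
    ``chain_gap``); candidate regions overlapping on genome A by more than
    ``overlap_slack`` are trimmed in favour of the higher-scoring one.
    """
    matches = find_local_matches(
        a, b, min_len=min_len, min_identity=min_identity, seed_k=seed_k,
        merge_gap=chain_gap, join_gap=chain_gap,
    )
    matches = _resolve_overlaps(matches, a.length, min_len, overlap_slack)
    matches.sort(key=lambda m: (m.q_iv.start, m.t_iv.start))
    regions = [
        SyntenicRegion(
            label=f"S{i + 1}",
            a_iv=m.q_iv,
            b_iv=m.t_iv,
            orientation="same" if m.strand == "+" else "opposite",
            identity=m.identity,
            score=m.score,
        )
        for i, m in enumerate(matches)
    ]
    cov_a = union_length([r.a_iv for r in regions], a.length) / a.length
    cov_b = union_length([r.b_iv for r in regions], b.length) / b.length
    return SyntenyMap(regions, cov_a, cov_b, a.length, b.length, a.id, b.id)


def _resolve_overlaps(matches: list[LocalMatch], La: int, min_len: int,
                      slack: int) -> list[LocalMatch]:
    """Keep higher-scoring regions intact; trim lower-scoring ones so the
    overlap on genome A does not exceed ``slack`` (wrapping matches are kept
    as-is — they are rare and trimming across the origin is ambiguous)."""
    order = sorted(matches, key=lambda m: -m.score)
    kept: list[LocalMatch] = []
    for m in order:
        if m.q_iv.wraps:
            kept.append(m)
            continue
        s, e = m.q_iv.start, m.q_iv.end
        for k in kept:
            if k.q_iv.wraps:
                continue
            ks, ke = k.q_iv.start, k.q_iv.end
            if s <= ke - slack and e >= ks + slack:  # overlap beyond slack
                if ks <= s and ke >= e:
                    s, e = 1, 0  # fully contained: drop
                    break
                if s < ks:
                    e = min(e, ks + slack - 1)
                else:
                    s = max(s, ke - slack + 1)
        length = e - s + 1
        if length < min_len:
            continue
        if (s, e) != (m.q_iv.start, m.q_iv.end):
            m = _trim_match(m, s, e)
        kept.append(m)
    return kept


def _trim_match(m: LocalMatch, new_s: int, new_e: int) -> LocalMatch:
    """Trim a match's A-interval to [new_s, new_e], shifting the B-interval
    by the same amounts (approximate under gaps, exact for ungapped chains)."""
    dl = new_s - m.q_iv.start
    dr = m.q_iv.end - new_e
    if m.strand == "+":
        t_iv = Interval(m.t_iv.start + dl, m.t_iv.end - dr)
    else:
        t_iv = Interval(m.t_iv.start + dr, m.t_iv.end - dl)
    new_len = max(1, m.aln_len - dl - dr)
    return replace(m, q_iv=Interval(new_s, new_e), t_iv=t_iv,
                   aln_len=new_len,
                   matches=min(m.matches, new_len))


def coverage_fraction(m: SyntenyMap, which: str) -> float:
    """Union span of the chosen genome's region intervals / genome length."""
    if which.upper() == "A":
        return union_length([r.a_iv for r in m.regions], m.a_len) / m.a_len
    if which.upper() == "B":
        return union_length([r.b_iv for r in m.regions], m.b_len) / m.b_len
    raise ValueError(f"which must be 'A' or 'B', got {which!r}")


def dotplot_points(m: SyntenyMap) -> list[tuple[int, int, int, int, str]]:
    """Segment endpoints (a_start, b_start, a_end, b_end, orientation) for a
    dot plot; opposite-orientation regions run to descending b coordinates."""
    pts = []
    for r in m.regions:
        if r.orientation == "same":
            pts.append((r.a_iv.start, r.b_iv.start, r.a_iv.end, r.b_iv.end,
                        "same"))
        else:
            pts.append((r.a_iv.start, r.b_iv.end, r.a_iv.end, r.b_iv.start,
                        "opposite"))
    return pts


def regions_to_frame(m: SyntenyMap):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "label": r.label,
                "a_start": r.a_iv.start,
                "a_end": r.a_iv.end,
                "b_start": r.b_iv.start,
                "b_end": r.b_iv.end,
                "orientation": r.orientation,
                "identity": round(r.identity, 4),
            }
            for r in m.regions
        ],
        columns=["label", "a_start", "a_end", "b_start", "b_end",
                 "orientation", "identity"],
    )
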