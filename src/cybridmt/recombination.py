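"""Repeat-mediated intramolecular recombination models.

A direct repeat pair on a master circle recombines the molecule into two
subgenomic circles whose sizes sum to the master length; an inverted pair
yields an equal-length isomer with the inter-copy arc reversed.  Short
repeats flanking syntenic-junction breakpoints are scored as candidate
mediators of observed rearrangements.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genomes import CircularSeq, DomainError, Interval, extract, revcomp
from .repeats import RepeatPair, RepeatSet
from .synteny import SyntenyMap


@dataclass(frozen=True)
class SubgenomicCircle:
    """A predicted recombination product of the master circle.

    ``member_iv`` is the master-circle arc it derives from (start-of-copy to
    start-of-next-copy, so each subcircle keeps exactly one fused repeat
    copy, identified by ``carries_repeat_copy``).
    """

    size: int
    member_iv: Interval
    carries_repeat_copy: int  # 1 or 2


def predict_subgenomic_circles(
    master: CircularSeq, pair: RepeatPair
) -> tuple[SubgenomicCircle, SubgenomicCircle]:
    """Split a master circle across a direct repeat pair.

    Sizes are the two arc distances between the copies' start coordinates,
    so size1 + size2 == L exactly.
    """
    if pair.kind != "direct":
        raise DomainError(
            "subgenomic circles require a direct repeat pair; for an inverted "
            "pair use predict_inverted_isomer"
        )
    if not master.is_circular:
        raise DomainError("subgenomic circles are defined on circular genomes")
    L = master.length
    s1, s2 = pair.iv1.start, pair.iv2.start
    size1 = (s2 - s1) % L
    size2 = L - size1
    arc1 = Interval(s1, (s2 - 2) % L + 1)  # s1 .. s2-1, circular
    arc2 = Interval(s2, (s1 - 2) % L + 1)
    c1 = SubgenomicCircle(size1, arc1, 1)
    c2 = SubgenomicCircle(size2, arc2, 2)
    return (c1, c2)


def subcircle_sequence(master: CircularSeq, sub: SubgenomicCircle) -> CircularSeq:
    """Emit the subcircle's sequence as its own circular record."""
    seq = extract(master, sub.member_iv)
    return CircularSeq(f"{master.id}_sub{sub.carries_repeat_copy}", seq,
                       is_circular=True)


def predict_inverted_isomer(master: CircularSeq, pair: RepeatPair) -> CircularSeq:
    """Isomeric form from recombination across an inverted repeat pair: the
    arc strictly between the two copies is reverse-complemented.  Applying
    the operation twice restores the original."""
    if pair.kind != "inverted":
        raise DomainError(
            "isomer prediction requires an inverted repeat pair; for a direct "
            "pair use predict_subgenomic_circles"
        )
    s = master.seq
    a_end = pair.iv1.end  # 1-based inclusive
    b_start = pair.iv2.start
    if b_start <= a_end + 1:
        flipped = s
    else:
        flipped = s[:a_end] + revcomp(s[a_end : b_start - 1]) + s[b_start - 1 :]
    return CircularSeq(f"{master.id}_isomer", flipped, is_circular=master.is_circular)


def canonical_rotation(seq: str) -> str:
    """Lexicographically minimal rotation (Booth's candidates via doubling);
    used for rotation-normalized equality of circles."""
    d = seq + seq
    n = len(seq)
    best = 0
    for i in range(1, n):
        if d[i : i + n] < d[best : best + n]:
            best = i
    return d[best : best + n]


def circles_equal(a: CircularSeq, b: CircularSeq) -> bool:
    """Rotation-normalized equality of two circular sequences (either strand)."""
    if a.length != b.length:
        return False
    ca = canonical_rotation(a.seq)
    return ca == canonical_rotation(b.seq) or ca == canonical_rotation(revcomp(b.seq))


# ---------------------------------------------------------------------------
# junction explanation by flanking short repeats

@dataclass(frozen=True)
class JunctionExplanation:
    """A syntenic junction in genome B whose A-side images are non-adjacent,
    with a candidate mediating repeat pair from genome A (or none)."""

    junction: str  # "Sx|Sy" labels of the adjacent B regions
    b_pos: int  # junction coordinate on B
    a_break1: int  # A-side breakpoint of the left region
    a_break2: int  # A-side breakpoint of the right region
    repeat: RepeatPair | None
    offsets: tuple[int, int] | None
    plausible: bool


def _circ_dist(p: int, iv: Interval, L: int) -> int:
    """Circular distance from position p to interval iv (0 if inside)."""
    if iv.wraps:
        if p >= iv.start or p <= iv.end:
            return 0
    elif iv.start <= p <= iv.end:
        return 0

    def d(x, y):
        diff = abs(x - y)
        return min(diff, L - diff)

    return min(d(p, iv.start), d(p, iv.end))


def explain_junctions_by_repeats(
    m: SyntenyMap,
    rs: RepeatSet | list[RepeatPair],
    flank_window: int = 500,
    *,
    adjacency_tol: int = 200,
) -> list[JunctionExplanation]:
    """For each adjacency of syntenic regions in genome-B order whose A-side
    images are NOT adjacent, test every repeat pair (detected on genome A)
    for copies lying within ``flank_window`` of BOTH A-side breakpoints.

    All candidate pairs within 4x the window are reported with their offsets;
    ``plausible`` is set when both offsets are within the window.  A junction
    with no candidate at all is still reported (repeat None, plausible False).
    """
    pairs = (rs.short + rs.large) if isinstance(rs, RepeatSet) else list(rs)
    regions = sorted(m.regions, key=lambda r: r.b_iv.start)
    out: list[JunctionExplanation] = []
    La = m.a_len
    n = len(regions)
    if n < 2:
        return out
    for i in range(n):
        r1 = regions[i]
        r2 = regions[(i + 1) % n]
        if r1 is r2:
            continue
        # A-side coordinates facing this B-junction
        a1 = r1.a_iv.end if r1.orientation == "same" else r1.a_iv.start
        a2 = r2.a_iv.start if r2.orientation == "same" else r2.a_iv.end
        gap_a = min(abs(a2 - a1), La - abs(a2 - a1))
        if gap_a <= adjacency_tol:
            continue  # images adjacent on A: no rearrangement here
        junction = f"{r1.label}|{r2.label}"
        b_pos = r1.b_iv.end
        candidates = []
        for p in pairs:
            # each copy must flank one of the two breakpoints; best assignment
            o_a = (_circ_dist(a1, p.iv1, La), _circ_dist(a2, p.iv2, La))
            o_b = (_circ_dist(a1, p.iv2, La), _circ_dist(a2, p.iv1, La))
            offs = o_a if max(o_a) <= max(o_b) else o_b
            if max(offs) <= 4 * flank_window:
                candidates.append((offs, p))
        if not candidates:
            out.append(JunctionExplanation(junction, b_pos, a1, a2, None,
                                           None, False))
            continue
        candidates.sort(key=lambda c: (max(c[0]), c[0][0] + c[0][1]))
        for offs, p in candidates:
            out.append(
                JunctionExplanation(
                    junction, b_pos, a1, a2, p, offs,
                    plausible=max(offs) <= flank_window,
                )
            )
    return out


def junctions_to_frame(explanations: list[JunctionExplanation]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "junction": e.junction,
                "b_pos": e.b_pos,
                "a_break1": e.a_break1,
                "a_break2": e.a_break2,
                "repeat": e.repeat.name if e.repeat else ".",
                "offset1": e.offsets[0] if e.offsets else -1,
                "offset2": e.offsets[1] if e.offsets else -1,
                "plausible": e.plausible,
            }
            for e in explanations
        ],
        columns=["junction", "b_pos", "a_break1", "a_break2", "repeat",
                 "offset1", "offset2", "plausible"],
    )
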