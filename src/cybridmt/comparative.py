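"""Multi-genome comparisons of a focal mitogenome.

Unique-region calling finds focal intervals with no appreciable similarity
to ANY comparator mitotype (candidate exogenous introgressions from the
donor parent); plastid-segment detection finds high-identity matches to the
chloroplast genome (mitochondrial plastid-derived transfers, MTPTs); ORF
sharedness classifies each focal ORF as shared / partial / unique across
the comparator panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genomes import CircularSeq, Interval, coverage_mask
from .localalign import TargetIndex, find_local_matches
from .genes import OrfRecord

# Uniqueness is about absence of ANY appreciable homology, so the coverage
# thresholds sit far below the 95% synteny regime.
DEFAULT_COVER_MIN_LEN = 50
DEFAULT_COVER_MIN_IDENTITY = 0.70
DEFAULT_MIN_UNIQUE_LEN = 400


@dataclass(frozen=True)
class UniqueRegion:
    label: str  # U1, U2, ... in coordinate order
    iv: Interval
    length: int
    orfs_contained: tuple[str, ...] = ()


@dataclass(frozen=True)
class CpSegment:
    label: str  # H1, H2, ... by length descending
    iv: Interval  # on the mt genome
    cp_iv: Interval  # on the chloroplast genome
    identity: float
    length: int


def call_unique_regions(
    focal: CircularSeq,
    comparators: list[CircularSeq],
    cover_min_len: int = DEFAULT_COVER_MIN_LEN,
    cover_min_identity: float = DEFAULT_COVER_MIN_IDENTITY,
    min_unique_len: int = DEFAULT_MIN_UNIQUE_LEN,
    *,
    seed_k: int = 12,
) -> list[UniqueRegion]:
    """Maximal focal-genome runs covered by NO comparator.

    Per comparator the covered set is the union of local-match intervals on
    the focal genome; the unique set is the intersection of the uncovered
    sets, filtered to ``>= min_unique_len`` and labelled U1... in coordinate
    order.  Runs separated by any covered position are reported separately.
    """
    if not comparators:
        raise ValueError("at least one comparator genome is required")
    L = focal.length
    uncovered_all = np.ones(L, dtype=bool)
    for comp in comparators:
        if comp is focal or comp.seq == focal.seq:
            return []  # the focal genome covers itself entirely
        matches = find_local_matches(
            focal, comp, min_len=cover_min_len,
            min_identity=cover_min_identity, seed_k=seed_k,
        )
        covered = coverage_mask([m.q_iv for m in matches], L)
        uncovered_all &= ~covered
        if not uncovered_all.any():
            break
    return _mask_to_regions(uncovered_all, L, min_unique_len,
                            circular=focal.is_circular)


def _mask_to_regions(mask: np.ndarray, L: int, min_len: int,
                     circular: bool) -> list[UniqueRegion]:
    """Maximal True runs of a position mask as labelled regions
    (wraparound-joined on circular genomes)."""
    if not mask.any():
        return []
    if mask.all():
        return [UniqueRegion("U1", Interval(1, L), L)]
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]  # 0-based
    ends = np.nonzero(d == -1)[0] - 1
    runs = list(zip(starts.tolist(), ends.tolist()))
    if circular and len(runs) >= 2 and runs[0][0] == 0 and runs[-1][1] == L - 1:
        first = runs.pop(0)
        last = runs.pop()
        runs.append((last[0], first[1]))  # wrapping run
    regions = []
    for s, e in runs:
        if e >= s:
            length = e - s + 1
        else:  # wrapping
            length = (L - s) + (e + 1)
        if length >= min_len:
            regions.append((s, e, length))
    regions.sort(key=lambda r: r[0])
    return [
        UniqueRegion(f"U{i + 1}", Interval(s + 1, e + 1), length)
        for i, (s, e, length) in enumerate(regions)
    ]


def unique_fraction(regions: list[UniqueRegion], L: int) -> float:
    return sum(r.length for r in regions) / L


def attach_orfs(regions: list[UniqueRegion], orfs: list[OrfRecord],
                L: int) -> list[UniqueRegion]:
    """Annotate each unique region with the ORFs that overlap it."""
    out = []
    for r in regions:
        rmask = coverage_mask([r.iv], L)
        hit = tuple(
            o.orf_id for o in orfs
            if (coverage_mask([o.iv], L) & rmask).any()
        )
        out.append(UniqueRegion(r.label, r.iv, r.length, hit))
    return out


def find_cp_segments(
    mt: CircularSeq,
    cp: CircularSeq,
    min_identity: float = 0.95,
    min_len: int = 100,
    *,
    seed_k: int = 12,
) -> list[CpSegment]:
    """Chloroplast-derived segments of the mt genome: local matches to the
    plastid genome above thresholds, labelled H1... by length descending."""
    matches = find_local_matches(
        mt, cp, min_len=min_len, min_identity=min_identity, seed_k=seed_k,
    )
    matches.sort(key=lambda m: (-m.q_iv.span(mt.length), m.q_iv.start))
    return [
        CpSegment(
            label=f"H{i + 1}",
            iv=m.q_iv,
            cp_iv=m.t_iv,
            identity=m.identity,
            length=m.q_iv.span(mt.length),
        )
        for i, m in enumerate(matches)
    ]


def cp_fraction(segments: list[CpSegment], L: int) -> float:
    return sum(s.length for s in segments) / L


def classify_orf_sharedness(
    focal: CircularSeq,
    orfs: list[OrfRecord],
    comparators: list[CircularSeq],
    shared_min_identity: float = 0.99,
    *,
    partial_min_cover: float = 0.30,
    full_cover: float = 0.95,
    seed_k: int = 12,
) -> dict[str, str]:
    """Label each ORF shared / partial / unique across the comparator panel.

    shared: some comparator covers (near-)full ORF length at
    >= ``shared_min_identity``; partial: >= ``partial_min_cover`` of the ORF
    is covered at that identity but not full length; unique: neither.
    ORF nucleotide sequences are extracted from ``focal``.
    """
    from .genomes import extract

    labels: dict[str, str] = {}
    indexes = [TargetIndex(c, seed_k) for c in comparators]
    for orf in orfs:
        nt = extract(focal, orf.iv)
        n = len(nt)
        q = CircularSeq(orf.orf_id or "orf", nt, is_circular=False)
        best_cover = 0.0
        for comp, idx in zip(comparators, indexes):
            matches = find_local_matches(
                q, comp, min_len=max(30, seed_k),
                min_identity=shared_min_identity, seed_k=seed_k,
                target_index=idx,
            )
            if not matches:
                continue
            mask = coverage_mask([m.q_iv for m in matches], n)
            best_cover = max(best_cover, float(mask.mean()))
            if best_cover >= full_cover:
                break
        if best_cover >= full_cover:
            labels[orf.orf_id] = "shared"
        elif best_cover >= partial_min_cover:
            labels[orf.orf_id] = "partial"
        else:
            labels[orf.orf_id] = "unique"
    return labels


def unique_to_frame(regions: list[UniqueRegion]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "label": r.label,
                "length": r.length,
                "start": r.iv.start,
                "end": r.iv.end,
                "orfs": ",".join(r.orfs_contained) or ".",
            }
            for r in regions
        ],
        columns=["label", "length", "start", "end", "orfs"],
    )


def cp_to_frame(segments: list[CpSegment]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "label": s.label,
                "mt_start": s.iv.start,
                "mt_end": s.iv.end,
                "cp_start": s.cp_iv.start,
                "cp_end": s.cp_iv.end,
                "length": s.length,
                "identity": round(s.identity, 4),
            }
            for s in segments
        ],
        columns=["label", "mt_start", "mt_end", "cp_start", "cp_end",
                 "length", "identity"],
    )
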