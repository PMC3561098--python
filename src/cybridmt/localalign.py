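"""Seeded local-similarity engine and an exact global-alignment oracle.

One aligner serves every similarity search in the pipeline (synteny, repeat
finding, unique-region coverage, plastid-segment detection) so that a single
definition of "percent identity" — identical columns / alignment columns,
gap columns counting against — applies throughout.

The engine is the classic k-mer seed / two-hit trigger / gapped-extension
design: exact k-mer hits are grouped on diagonals into ungapped runs,
co-linear runs are chained (small gaps closed by exact dynamic programming),
and chain ends are extended ungapped under an X-drop rule.

``align_pair`` is the exact quadratic global aligner (Needleman–Wunsch with
linear gap costs) used both to close inter-seed gaps and, in tests, as the
independent oracle for seeded matches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genomes import CircularSeq, DomainError, Interval, revcomp

DEFAULT_SEED_K = 12
DEFAULT_MATCH = 1
DEFAULT_MISMATCH = -1
DEFAULT_GAP = -2
DEFAULT_XDROP = 20
ALIGN_PAIR_CAP = 20_000


class SizeError(ValueError):
    """Input too large for the exact quadratic aligner."""


@dataclass(frozen=True)
class Alignment:
    """Result of an exact global alignment.

    ``ops`` is an edit script over the alignment columns: M match, X mismatch,
    D gap in the second sequence (consumes a), I gap in the first (consumes b).
    """

    aln_len: int
    matches: int
    identity: float
    ops: str
    score: int


def align_pair(
    a: str,
    b: str,
    match: int = DEFAULT_MATCH,
    mismatch: int = DEFAULT_MISMATCH,
    gap: int = DEFAULT_GAP,
    cap: int = ALIGN_PAIR_CAP,
) -> Alignment:
    """Optimal global alignment of two nucleotide strings.

    Deterministic tie-breaking: a substitution (diagonal move) is preferred
    over a gap, and a gap in ``b`` over a gap in ``a``.  Quadratic in time and
    memory; inputs beyond ``cap`` raise SizeError (use find_local_matches).
    """
    n, m = len(a), len(b)
    if n > cap or m > cap:
        raise SizeError(
            f"align_pair is exact/quadratic; inputs of {n} and {m} bp exceed the "
            f"{cap} bp cap — use find_local_matches for long sequences"
        )
    if n == 0 or m == 0:
        ops = "D" * n + "I" * m
        return Alignment(n + m, 0, 0.0 if (n + m) else 1.0, ops, gap * (n + m))

    a_arr = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    b_arr = np.frombuffer(b.encode("ascii"), dtype=np.uint8)

    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 diag, 1 up, 2 left
    ptr[0, 1:] = 2
    ptr[1:, 0] = 1
    idx = np.arange(m + 1, dtype=np.int64)
    gap_ramp = gap * idx
    h_prev = gap_ramp.copy()

    for i in range(1, n + 1):
        s = np.where(b_arr == a_arr[i - 1], match, mismatch)
        diag = h_prev[:-1] + s
        up = h_prev[1:] + gap
        best = np.maximum(diag, up)
        base = np.empty(m + 1, dtype=np.int64)
        base[0] = gap * i
        base[1:] = best
        # left-gap chains: H[j] = gap*j + running-max of (base[k] - gap*k)
        h = np.maximum.accumulate(base - gap_ramp) + gap_ramp
        ptr[i, 1:] = np.where(h[1:] == diag, 0, np.where(h[1:] == up, 1, 2))
        h_prev = h

    score = int(h_prev[m])
    # traceback
    ops_rev = []
    i, j = n, m
    matches = 0
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 0:
            if a_arr[i - 1] == b_arr[j - 1]:
                ops_rev.append("M")
                matches += 1
            else:
                ops_rev.append("X")
            i -= 1
            j -= 1
        elif p == 1:
            ops_rev.append("D")
            i -= 1
        else:
            ops_rev.append("I")
            j -= 1
    ops = "".join(reversed(ops_rev))
    aln_len = len(ops)
    return Alignment(aln_len, matches, matches / aln_len, ops, score)


# ---------------------------------------------------------------------------
# seeding machinery

_ENC_TABLE = np.full(256, 4, dtype=np.int64)
for _i, _c in enumerate("ACGT"):
    _ENC_TABLE[ord(_c)] = _i


def _encode(s: str) -> np.ndarray:
    return _ENC_TABLE[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 codes for every N-free k-mer window; returns (codes, positions)."""
    n = len(enc)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    nw = n - k + 1
    codes = np.zeros(nw, dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + enc[j : j + nw]
    bad = (enc >= 4).astype(np.int64)
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = (cs[k:] - cs[:-k]) == 0
    pos = np.nonzero(valid)[0]
    return codes[pos], pos


class TargetIndex:
    """Sorted k-mer index over both strands of a target, reusable across
    queries (comparative stages query many sequences against one genome)."""

    def __init__(self, target: CircularSeq, seed_k: int = DEFAULT_SEED_K):
        if seed_k < 8:
            raise DomainError(f"seed_k must be >= 8, got {seed_k}")
        self.target = target
        self.seed_k = seed_k
        self.strand_data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for strand in "+-":
            seq = target.seq if strand == "+" else revcomp(target.seq)
            enc = _encode(seq)
            codes, pos = _kmer_codes(enc, seed_k)
            order = np.argsort(codes, kind="stable")
            self.strand_data[strand] = (codes[order], pos[order], enc)

    def hits(self, q_codes: np.ndarray, q_pos: np.ndarray, strand: str,
             max_kmer_hits: int) -> tuple[np.ndarray, np.ndarray]:
        t_codes, t_pos, _ = self.strand_data[strand]
        left = np.searchsorted(t_codes, q_codes, "left")
        right = np.searchsorted(t_codes, q_codes, "right")
        counts = right - left
        keep = (counts > 0) & (counts <= max_kmer_hits)
        counts = counts[keep]
        starts = left[keep]
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        qpos = np.repeat(q_pos[keep], counts)
        offs = np.arange(total, dtype=np.int64) - np.repeat(
            np.cumsum(counts) - counts, counts
        )
        tpos = t_pos[np.repeat(starts, counts) + offs]
        return qpos, tpos


@dataclass(frozen=True)
class LocalMatch:
    """A scored local similarity segment between a query and a target.

    Strand '-' means the query matches the reverse strand of the target
    (ascending query coordinates pair with descending target coordinates).
    """

    q_iv: Interval
    t_iv: Interval
    strand: str
    identity: float
    aln_len: int
    matches: int
    gap_cols: int
    score: int


class _Chain:
    __slots__ = ("qs", "qe", "ts", "te", "matches", "cols", "gap_cols")

    def __init__(self, qs, qe, ts, te, matches):
        self.qs, self.qe, self.ts, self.te = qs, qe, ts, te
        self.matches = matches
        self.cols = qe - qs + 1
        self.gap_cols = 0


def _segments_from_hits(qpos, tpos, q_enc, t_enc, k, merge_gap, min_len):
    """Group hits per diagonal into ungapped runs; a run needs at least two
    hits (the two-hit trigger) unless min_len <= k."""
    if len(qpos) == 0:
        return []
    diag = qpos - tpos
    order = np.lexsort((qpos, diag))
    d = diag[order]
    q = qpos[order]
    brk = np.nonzero((np.diff(d) != 0) | (np.diff(q) > merge_gap + k))[0] + 1
    gs = np.concatenate([[0], brk])
    ge = np.concatenate([brk, [len(q)]])
    sizes = ge - gs
    if min_len > k:
        keep = sizes >= 2
        gs, ge = gs[keep], ge[keep]
    segs = []
    for a, b in zip(gs, ge):
        q0 = int(q[a])
        q1 = int(q[b - 1]) + k - 1
        t0 = q0 - int(d[a])
        seg_len = q1 - q0 + 1
        m = int(np.count_nonzero(q_enc[q0 : q1 + 1] == t_enc[t0 : t0 + seg_len]))
        segs.append((q0, q1, t0, t0 + seg_len - 1, m))
    return segs


def _chain_segments(segs, q_enc, t_enc, join_gap, match, mismatch, gap,
                    min_identity=0.0):
    """Greedy chaining of co-linear ungapped runs; gaps between neighbours are
    closed with the exact aligner so column accounting stays exact.

    A join that would dilute the chain below ``min_identity`` is declined —
    chaining must never turn a reportable match unreportable (random nearby
    runs would otherwise get welded on through low-identity gap columns)."""
    segs.sort()
    closed: list[_Chain] = []
    open_chains: list[_Chain] = []
    letters = "ACGTN"
    for qs, qe, ts, te, m in segs:
        best = None
        best_cost = None
        still_open = []
        for ch in open_chains:
            if ch.qe < qs - join_gap - 1:
                closed.append(ch)
                continue
            still_open.append(ch)
            qgap = qs - ch.qe - 1
            tgap = ts - ch.te - 1
            if 0 <= qgap <= join_gap and 0 <= tgap <= join_gap:
                cost = max(qgap, tgap)
                if best is None or cost < best_cost:
                    best, best_cost = ch, cost
        open_chains = still_open
        seg_len = qe - qs + 1
        if best is not None:
            qgap = qs - best.qe - 1
            tgap = ts - best.te - 1
            gap_cols = gap_matches = gap_gapcols = 0
            if qgap > 0 and tgap > 0:
                astr = "".join(letters[c] for c in q_enc[best.qe + 1 : qs])
                bstr = "".join(letters[c] for c in t_enc[best.te + 1 : ts])
                res = align_pair(astr, bstr, match, mismatch, gap)
                gap_cols = res.aln_len
                gap_matches = res.matches
                gap_gapcols = res.ops.count("I") + res.ops.count("D")
            elif qgap > 0 or tgap > 0:
                gap_cols = gap_gapcols = max(qgap, tgap)
            joint_matches = best.matches + gap_matches + m
            joint_cols = best.cols + gap_cols + seg_len
            if joint_matches / joint_cols < min_identity:
                best = None  # decline the join
            else:
                best.cols = joint_cols
                best.matches = joint_matches
                best.gap_cols += gap_gapcols
                best.qe, best.te = qe, te
        if best is None:
            open_chains.append(_Chain(qs, qe, ts, te, m))
    closed.extend(open_chains)
    return closed


def _extension_penalty(min_identity: float, xdrop: int) -> int:
    """Mismatch penalty for end extension, scaled so that extensions kept are
    at least as identical as the reporting threshold (a +1/-1 walk would
    happily append ~50%-identity tails and dilute borderline matches below
    threshold)."""
    if min_identity >= 1.0:
        return -(xdrop + 1)
    return -max(1, round(min_identity / (1.0 - min_identity)))


def _xdrop_extend(ch: _Chain, q_enc, t_enc, xdrop, match, mismatch):
    """Ungapped X-drop extension of both chain ends; keeps the best-scoring
    prefix/suffix and updates the match count."""
    # left
    i, j = ch.qs - 1, ch.ts - 1
    score = best = 0
    best_ext = 0
    best_matches = 0
    run_matches = 0
    ext = 0
    while i >= 0 and j >= 0 and score > best - xdrop:
        if q_enc[i] == t_enc[j] and q_enc[i] < 4:
            score += match
            run_matches += 1
        else:
            score += mismatch
        ext += 1
        if score > best:
            best = score
            best_ext = ext
            best_matches = run_matches
        i -= 1
        j -= 1
    ch.qs -= best_ext
    ch.ts -= best_ext
    ch.cols += best_ext
    ch.matches += best_matches
    # right
    nq, nt = len(q_enc), len(t_enc)
    i, j = ch.qe + 1, ch.te + 1
    score = best = 0
    best_ext = 0
    best_matches = 0
    run_matches = 0
    ext = 0
    while i < nq and j < nt and score > best - xdrop:
        if q_enc[i] == t_enc[j] and q_enc[i] < 4:
            score += match
            run_matches += 1
        else:
            score += mismatch
        ext += 1
        if score > best:
            best = score
            best_ext = ext
            best_matches = run_matches
        i += 1
        j += 1
    ch.qe += best_ext
    ch.te += best_ext
    ch.cols += best_ext
    ch.matches += best_matches


def find_local_matches(
    query: CircularSeq,
    target: CircularSeq,
    min_len: int = 100,
    min_identity: float = 0.7,
    seed_k: int = DEFAULT_SEED_K,
    *,
    merge_gap: int = 100,
    join_gap: int = 100,
    xdrop: int = DEFAULT_XDROP,
    match: int = DEFAULT_MATCH,
    mismatch: int = DEFAULT_MISMATCH,
    gap: int = DEFAULT_GAP,
    max_kmer_hits: int = 200,
    target_index: TargetIndex | None = None,
) -> list[LocalMatch]:
    """Find local similarity matches of ``query`` against both strands of
    ``target``.

    Every reported match has ``aln_len >= min_len`` and
    ``identity >= min_identity``.  Circular queries are searched on an
    internally doubled sequence and matches whose start lies beyond L are
    deduplicated, so matches may cross the query origin (reported as a
    wrapping interval).  When query and target are the same sequence the
    trivial self-diagonal is suppressed.  Output is sorted by
    (query start, target start, strand).
    """
    if seed_k < 8:
        raise DomainError(f"seed_k must be >= 8, got {seed_k}")
    if min_len < seed_k:
        raise DomainError(f"min_len ({min_len}) must be >= seed_k ({seed_k})")
    if len(query) == 0 or len(target) == 0:
        raise DomainError("cannot align empty sequences")
    Lq, Lt = len(query), len(target)
    self_cmp = query is target

    q_work = query.seq * 2 if query.is_circular else query.seq
    q_enc = _encode(q_work)
    q_codes, q_pos = _kmer_codes(q_enc, seed_k)
    if target_index is None or target_index.seed_k != seed_k:
        target_index = TargetIndex(target, seed_k)

    out: list[LocalMatch] = []
    for strand in "+-":
        qpos, tpos = target_index.hits(q_codes, q_pos, strand, max_kmer_hits)
        if self_cmp and strand == "+" and len(qpos):
            if query.is_circular:
                keep = (qpos - tpos) % Lq != 0
            else:
                keep = qpos != tpos
            qpos, tpos = qpos[keep], tpos[keep]
        t_enc = target_index.strand_data[strand][2]
        segs = _segments_from_hits(qpos, tpos, q_enc, t_enc, seed_k,
                                   merge_gap, min_len)
        chains = _chain_segments(segs, q_enc, t_enc, join_gap, match, mismatch,
                                 gap, min_identity)
        ext_pen = _extension_penalty(min_identity, xdrop)
        for ch in chains:
            if query.is_circular and ch.qs >= Lq:
                continue  # duplicate from the doubled query
            _xdrop_extend(ch, q_enc, t_enc, xdrop, match, ext_pen)
            if query.is_circular and ch.qs >= Lq:
                continue
            if ch.cols < min_len:
                continue
            identity = ch.matches / ch.cols
            if identity < min_identity:
                continue
            q_span = ch.qe - ch.qs + 1
            if query.is_circular and q_span > Lq:
                continue  # over-wound artefact of the doubled query
            q_end0 = ch.qe - Lq if (query.is_circular and ch.qe >= Lq) else ch.qe
            q_iv = Interval(ch.qs + 1, q_end0 + 1)
            if strand == "+":
                t_iv = Interval(ch.ts + 1, ch.te + 1)
            else:
                t_iv = Interval(Lt - ch.te, Lt - ch.ts)
            mism = ch.cols - ch.matches - ch.gap_cols
            score = ch.matches * match + mism * mismatch + ch.gap_cols * gap
            out.append(LocalMatch(q_iv, t_iv, strand, identity, ch.cols,
                                  ch.matches, ch.gap_cols, score))
    out = _drop_wrap_shadows(out, Lq)
    seen = set()
    uniq = []
    for mrec in sorted(out, key=lambda r: (r.q_iv.start, r.t_iv.start, r.strand)):
        key = (mrec.q_iv.start, mrec.q_iv.end, mrec.t_iv.start, mrec.t_iv.end,
               mrec.strand)
        if key not in seen:
            seen.add(key)
            uniq.append(mrec)
    return uniq


def _drop_wrap_shadows(matches: list[LocalMatch], Lq: int) -> list[LocalMatch]:
    """Drop matches that are mere shadows of an origin-crossing match: the
    doubled-query view reports the post-origin tail of a wrapping alignment a
    second time as a standalone match."""
    wraps = [m for m in matches if m.q_iv.wraps]
    if not wraps:
        return matches
    kept = []
    for m in matches:
        shadow = False
        if not m.q_iv.wraps:
            for w in wraps:
                if (w.strand == m.strand
                        and m.q_iv.end <= w.q_iv.end
                        and m.t_iv.start >= w.t_iv.start
                        and m.t_iv.end <= w.t_iv.end):
                    shadow = True
                    break
        if not shadow:
            kept.append(m)
    return kept


def matches_to_frame(matches: list[LocalMatch], q_id: str, t_id: str):
    """Match list as a pandas DataFrame in the TSV export layout."""
    import pandas as pd

    rows = [
        {
            "query": q_id,
            "q_start": m.q_iv.start,
            "q_end": m.q_iv.end,
            "target": t_id,
            "t_start": m.t_iv.start,
            "t_end": m.t_iv.end,
            "strand": m.strand,
            "identity": round(m.identity, 4),
            "aln_len": m.aln_len,
            "score": m.score,
        }
        for m in matches
    ]
    return pd.DataFrame(
        rows,
        columns=["query", "q_start", "q_end", "target", "t_start", "t_end",
                 "strand", "identity", "aln_len", "score"],
    )
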