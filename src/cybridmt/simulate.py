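"""Synthetic cybrid-mitogenome generator with full ground truth.

Emulates the inferred history of a somatic-hybrid (cybrid) mitochondrial
genome: a recipient-like circular backbone carrying protein-coding genes is
cut into blocks, permuted and partly inverted (with short repeats planted at
the broken adjacencies, mimicking repeat-mediated rearrangement); segments
from a donor mitogenome and from the chloroplast genome are inserted; one
large repeat is duplicated (the substrate of subgenomic-circle formation);
scattered coding SNPs with a transition excess and two gene-boundary shifts
(a displaced stop codon and an upstream in-frame start extension) complete
the picture.  Comparator genomes are recipient-derived (substitution noise
plus a few neutral block moves, no donor or plastid content) so that
unique-region calling has a clean negative set.

Every planted feature is recorded in final cybrid coordinates in a
``SimTruth`` catalogue, so each pipeline stage can be scored against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genomes import CircularSeq, GeneModel, Interval, revcomp

BASES = np.array(list("ACGT"))
STOPS = ("TAA", "TAG", "TGA")
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

# plant mitochondrial gene complement used for planted genes
MT_GENE_NAMES = [
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6", "nad7", "nad9",
    "cox1", "cox2", "cox3", "cob", "atp1", "atp4", "atp6", "atp8", "atp9",
    "ccmB", "ccmC", "ccmFC", "ccmFN", "tatC", "rps3", "rps4", "rps12",
    "rpl2", "rpl5", "rpl16", "matR", "mttB",
]

GENE_MARGIN = 700  # bp kept clear around every gene (boundary-shift room)
SPLIT_MARGIN = 1500  # bp kept clear from piece edges when splitting


class SimCapacityError(RuntimeError):
    """The configuration demands more insertions/overwrites than the genome
    can accommodate without collisions."""


@dataclass
class SimConfig:
    """Generator parameters; the defaults emulate a rapeseed-scale cybrid.

    ``seed`` is mandatory — all randomness flows from one generator.
    """

    seed: int
    recipient_len: int = 221853
    gc: float = 0.4521
    n_blocks: int = 8
    n_inversions: int = 3
    large_repeat_len: int = 9731
    mediator_repeats: tuple[int, ...] = (310, 232)
    short_repeat_spec: tuple[tuple[int, float, int], ...] = (
        (50, 0.95, 20), (100, 0.92, 20), (200, 0.90, 15), (350, 0.90, 5),
    )
    donor_segments: tuple[int, ...] = (
        2220, 2220, 469, 469, 5130, 1052, 445, 3572, 2700, 3828, 879,
    )
    cp_segments: tuple[int, ...] = (2196, 1880, 1362, 1159, 673, 178)
    n_coding_snps: int = 40
    titv_bias: float = 29 / 40
    boundary_shifts: tuple[tuple[str, int], ...] = (("3prime", 27), ("5prime", 498))
    n_genes: int = 23
    n_comparators: int = 6
    comparator_sub_rate: float = 0.005
    comparator_max_moves: int = 3
    donor_len: int = 150_000
    cp_len: int = 130_000
    cp_gc: float = 0.37
    plant_cms_orf: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("recipient_len", "large_repeat_len", "donor_len", "cp_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.gc <= 1 and 0 <= self.titv_bias <= 1):
            raise ValueError("fractions must lie in [0, 1]")

    @property
    def final_length(self) -> int:
        # plastid segments live in the recipient backbone (every mitotype
        # carries them), so only donor segments and the duplicated large
        # repeat add length
        return (self.recipient_len + sum(self.donor_segments)
                + self.large_repeat_len)


def table_echo_config(seed: int) -> SimConfig:
    """Configuration whose final cybrid is exactly 258,473 bp: the recipient
    length absorbs the planted donor/large-repeat insertions."""
    cfg = SimConfig(seed=seed)
    target = 258_473
    cfg.recipient_len = (target - sum(cfg.donor_segments)
                         - cfg.large_repeat_len)
    assert cfg.final_length == target
    return cfg


# ---------------------------------------------------------------------------
# truth records


@dataclass(frozen=True)
class TruthFeature:
    """One planted feature in final cybrid coordinates."""

    feature_class: str  # block | large_repeat | short_repeat | donor | cp |
    #                     snp | boundary_shift | gene | cms_orf
    name: str
    start: int  # 1-based inclusive on the cybrid; 0 for non-positional rows
    end: int
    strand: str = "+"
    src_start: int = 0  # source coordinates (recipient/donor/cp), 1-based
    src_end: int = 0
    mate_start: int = 0  # second copy, for repeat pairs
    mate_end: int = 0
    kind: str = ""  # direct | inverted | 5prime | 3prime | ...
    identity: float = 1.0
    info: str = ""  # free-form key=value;... payload


@dataclass
class SimTruth:
    features: list[TruthFeature] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)

    def of_class(self, cls: str) -> list[TruthFeature]:
        return [f for f in self.features if f.feature_class == cls]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(f) for f in self.features])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimTruth":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        feats = [
            TruthFeature(
                feature_class=str(r.feature_class), name=str(r.name),
                start=int(r.start), end=int(r.end), strand=str(r.strand),
                src_start=int(r.src_start), src_end=int(r.src_end),
                mate_start=int(r.mate_start), mate_end=int(r.mate_end),
                kind=str(r.kind), identity=float(r.identity), info=str(r.info),
            )
            for r in df.itertuples()
        ]
        return cls(features=feats)


# ---------------------------------------------------------------------------
# low-level sequence helpers


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.arange(4), size=n, p=p)


_IDX2BASE = np.array(list("ACGT"))
_BASE2IDX = {b: i for i, b in enumerate("ACGT")}


def _to_str(arr: np.ndarray) -> str:
    return "".join(_IDX2BASE[arr])


def _sense_codon(rng: np.random.Generator) -> str:
    while True:
        c = "".join(_IDX2BASE[rng.integers(0, 4, 3)])
        if c not in STOPS:
            return c


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = "".join(_sense_codon(rng) for _ in range(n_codons - 2))
    return "ATG" + body + "TAA"


def _mutate_copy(rng: np.random.Generator, seq: str, identity: float) -> str:
    """Substitute enough positions to bring a copy down to ~identity."""
    n_mut = int(round((1 - identity) * len(seq)))
    if n_mut == 0:
        return seq
    arr = list(seq)
    for p in rng.choice(len(seq), size=n_mut, replace=False):
        arr[p] = rng.choice([b for b in "ACGT" if b != arr[p]])
    return "".join(arr)


# ---------------------------------------------------------------------------
# the generator


@dataclass
class _Piece:
    kind: str  # block | donor | cp | large2
    seq: str
    src_start: int = 0  # 0-based source start (recipient / donor / cp)
    src_end: int = 0  # 0-based inclusive
    inverted: bool = False
    name: str = ""


def simulate_cybrid(cfg: SimConfig) -> tuple[
    CircularSeq, list[CircularSeq], CircularSeq, CircularSeq, CircularSeq, SimTruth
]:
    """Generate (recipient, comparators, donor, cp, cybrid, truth).

    Deterministic for a given config (same seed => byte-identical output).
    """
    rng = np.random.default_rng(cfg.seed)
    L0 = cfg.recipient_len

    # --- recipient backbone with planted genes
    rec_arr = _random_seq(rng, L0, cfg.gc)
    gene_names = (MT_GENE_NAMES * ((cfg.n_genes // len(MT_GENE_NAMES)) + 1))[: cfg.n_genes]
    slot = L0 // cfg.n_genes
    if slot < 2 * GENE_MARGIN + 2200:
        raise SimCapacityError(
            f"recipient of {L0} bp cannot hold {cfg.n_genes} genes with margins"
        )
    rec_genes: list[tuple[str, int, int, str]] = []  # name, s0, e0 (0-based), strand
    for i, name in enumerate(gene_names):
        n_codons = int(rng.integers(110, 480))
        cds = _random_cds(rng, n_codons)
        lo = i * slot + GENE_MARGIN
        hi = (i + 1) * slot - GENE_MARGIN - len(cds)
        s0 = int(rng.integers(lo, hi))
        strand = "+" if rng.random() < 0.5 else "-"
        ins = cds if strand == "+" else revcomp(cds)
        rec_arr[s0 : s0 + len(cds)] = [_BASE2IDX[b] for b in ins]
        rec_genes.append((name, s0, s0 + len(cds) - 1, strand))
    # --- donor and chloroplast genomes
    donor = CircularSeq("donor", _to_str(_random_seq(rng, cfg.donor_len, cfg.gc)),
                        is_circular=True)
    cp = CircularSeq("chloroplast",
                     _to_str(_random_seq(rng, cfg.cp_len, cfg.cp_gc)),
                     is_circular=True)

    # --- plastid-derived segments go into the RECIPIENT backbone: every
    # mitotype of the genus carries them, so comparators inherit them and
    # they never masquerade as unique regions
    gene_mask0 = np.zeros(L0, dtype=bool)
    for _, s0, e0, _ in rec_genes:
        gene_mask0[max(0, s0 - GENE_MARGIN) : min(L0, e0 + GENE_MARGIN + 1)] = True
    cp_windows = _disjoint_windows(rng, cfg.cp_len, cfg.cp_segments)
    rec_cp: list[tuple[int, int, int, int]] = []  # rec s0,e0 / cp s0,e0
    for (ws, we) in cp_windows:
        length = we - ws + 1
        for _ in range(2000):
            s = int(rng.integers(GENE_MARGIN, L0 - length - GENE_MARGIN))
            window_clear = not gene_mask0[max(0, s - 200) : s + length + 200].any()
            if window_clear and all(
                s + length + 200 < rs or s > re + 200 for rs, re, _, _ in rec_cp
            ):
                rec_arr[s : s + length] = [_BASE2IDX[b] for b in cp.seq[ws : we + 1]]
                rec_cp.append((s, s + length - 1, ws, we))
                break
        else:
            raise SimCapacityError("no room for plastid segments in the recipient")
        gene_mask0[max(0, s - 200) : min(L0, s + length + 200)] = True

    recipient_seq = _to_str(rec_arr)
    recipient = CircularSeq("recipient", recipient_seq, is_circular=True)

    # --- comparators: recipient + substitution noise + neutral block moves
    comparators = []
    for ci in range(cfg.n_comparators):
        seq = _mutate_whole(rng, recipient_seq, cfg.comparator_sub_rate)
        n_moves = int(rng.integers(0, cfg.comparator_max_moves + 1))
        for _ in range(n_moves):
            seq = _neutral_move(rng, seq)
        comparators.append(CircularSeq(f"comparator{ci + 1}", seq, is_circular=True))

    # --- cut recipient into blocks (cuts avoid genes and plastid segments)
    gene_mask = np.zeros(L0, dtype=bool)
    for _, s0, e0, _ in rec_genes:
        gene_mask[max(0, s0 - GENE_MARGIN) : min(L0, e0 + GENE_MARGIN + 1)] = True
    for rs, re, _, _ in rec_cp:
        gene_mask[max(0, rs - 200) : min(L0, re + 201)] = True
    cuts = _choose_cuts(rng, L0, cfg.n_blocks - 1, gene_mask)
    bounds = [0] + cuts + [L0]
    blocks = [(bounds[i], bounds[i + 1] - 1) for i in range(cfg.n_blocks)]

    perm = list(rng.permutation(cfg.n_blocks))
    if cfg.n_blocks > 1 and perm == sorted(perm):
        perm = perm[1:] + perm[:1]
    inverted_ids = set(
        rng.choice(cfg.n_blocks, size=min(cfg.n_inversions, cfg.n_blocks),
                   replace=False).tolist()
    )
    pieces: list[_Piece] = []
    for bi in perm:
        s, e = blocks[bi]
        sub = recipient_seq[s : e + 1]
        inv = bi in inverted_ids
        pieces.append(_Piece("block", revcomp(sub) if inv else sub, s, e, inv,
                             name=f"B{bi + 1}"))

    # --- the large repeat: source window inside a block, second copy inserted
    src_ls = _find_window_in_blocks(rng, pieces, cfg.large_repeat_len, gene_mask)
    large_seq = recipient_seq[src_ls : src_ls + cfg.large_repeat_len]
    forbidden = [(src_ls, src_ls + cfg.large_repeat_len - 1)]
    _insert_piece(rng, pieces,
                  _Piece("large2", large_seq, src_ls,
                         src_ls + cfg.large_repeat_len - 1, name="R'"),
                  gene_mask, forbidden)

    # --- donor and cp insertions
    donor_windows = _disjoint_windows(rng, cfg.donor_len, cfg.donor_segments)
    cms_target_idx = (
        int(np.argmax(cfg.donor_segments)) if cfg.plant_cms_orf else -1
    )
    for di, (length, (ws, we)) in enumerate(zip(cfg.donor_segments, donor_windows)):
        seq = donor.seq[ws : we + 1]
        near_gene = di == cms_target_idx
        _insert_piece(rng, pieces,
                      _Piece("donor", seq, ws, we, name=f"D{di + 1}"),
                      gene_mask, forbidden, prefer_near_gene=near_gene)

    # --- assemble; map recipient coordinates to final coordinates
    final_parts = []
    offsets = []
    pos = 0
    for p in pieces:
        offsets.append(pos)
        final_parts.append(p.seq)
        pos += len(p.seq)
    cyb = np.frombuffer("".join(final_parts).encode("ascii"), dtype=np.uint8).copy()
    Lf = len(cyb)
    assert Lf == cfg.final_length

    def rec_to_final(p0: int) -> tuple[int, bool]:
        """Recipient 0-based position -> (final 0-based position, inverted)."""
        for piece, off in zip(pieces, offsets):
            if piece.kind == "block" and piece.src_start <= p0 <= piece.src_end:
                if piece.inverted:
                    return off + (piece.src_end - p0), True
                return off + (p0 - piece.src_start), False
        raise KeyError(p0)

    truth = SimTruth()
    protected = np.zeros(Lf, dtype=bool)

    # block map + genes in final coordinates
    for piece, off in zip(pieces, offsets):
        iv = Interval(off + 1, off + len(piece.seq))
        if piece.kind == "block":
            truth.features.append(TruthFeature(
                "block", piece.name, iv.start, iv.end,
                strand="-" if piece.inverted else "+",
                src_start=piece.src_start + 1, src_end=piece.src_end + 1,
                kind="inverted" if piece.inverted else "direct",
            ))
        elif piece.kind == "donor":
            truth.features.append(TruthFeature(
                "donor", piece.name, iv.start, iv.end,
                src_start=piece.src_start + 1, src_end=piece.src_end + 1,
            ))
            protected[off : off + len(piece.seq)] = True
    # plastid segments rode along inside recipient blocks; map to final coords
    for hi, (rs, re, ws, we) in enumerate(rec_cp):
        f1, inv1 = rec_to_final(rs)
        f2, _ = rec_to_final(re)
        a, b = sorted([f1, f2])
        truth.features.append(TruthFeature(
            "cp", f"H{hi + 1}", a + 1, b + 1,
            strand="-" if inv1 else "+",
            src_start=ws + 1, src_end=we + 1,
        ))
        protected[a : b + 1] = True

    # large repeat pair: in-situ copy + inserted copy
    c1f, c1_inv = rec_to_final(src_ls)
    if c1_inv:
        c1_start = c1f - (cfg.large_repeat_len - 1)
    else:
        c1_start = c1f
    for piece, off in zip(pieces, offsets):
        if piece.kind == "large2":
            c2_start = off
            break
    lr_kind = "inverted" if c1_inv else "direct"
    a, b = sorted([c1_start, c2_start])
    truth.features.append(TruthFeature(
        "large_repeat", "R", a + 1, a + cfg.large_repeat_len,
        mate_start=b + 1, mate_end=b + cfg.large_repeat_len, kind=lr_kind,
    ))
    protected[a : a + cfg.large_repeat_len] = True
    protected[b : b + cfg.large_repeat_len] = True

    # genes in final coordinates (+ margins protected)
    final_genes: list[tuple[str, int, int, str]] = []
    for name, s0, e0, strand in rec_genes:
        fs, inv = rec_to_final(s0)
        fe, _ = rec_to_final(e0)
        gs, ge = sorted([fs, fe])
        gstrand = strand if not inv else ("-" if strand == "+" else "+")
        final_genes.append((name, gs, ge, gstrand))
        truth.genes.append(GeneModel(name, [Interval(gs + 1, ge + 1, gstrand)]))
        truth.features.append(TruthFeature(
            "gene", name, gs + 1, ge + 1, strand=gstrand,
            src_start=s0 + 1, src_end=e0 + 1,
        ))
        protected[max(0, gs - GENE_MARGIN) : min(Lf, ge + GENE_MARGIN + 1)] = True

    # --- mediating short repeats at broken adjacencies
    broken = _broken_adjacencies(pieces, offsets, blocks, perm)
    rng_med = rng
    for mlen, (bp1, bp2) in zip(cfg.mediator_repeats, broken):
        rep = _to_str(_random_seq(rng_med, mlen, cfg.gc))
        w1 = _place_near(rng_med, protected, Lf, bp1, mlen)
        if w1 is not None:
            protected[w1 : w1 + mlen] = True
        w2 = _place_near(rng_med, protected, Lf, bp2, mlen)
        if w1 is None or w2 is None:
            continue
        for w in (w1, w2):
            cyb[w : w + mlen] = np.frombuffer(rep.encode(), dtype=np.uint8)
            protected[max(0, w - 150) : min(Lf, w + mlen + 150)] = True
        a, b = sorted([w1, w2])
        truth.features.append(TruthFeature(
            "short_repeat", f"M{mlen}", a + 1, a + mlen,
            mate_start=b + 1, mate_end=b + mlen, kind="direct", identity=1.0,
            info="role=mediator",
        ))

    # --- scattered background short repeats (fresh random content, so they
    # match nothing but each other)
    ri = 0
    for rep_len, identity, count in cfg.short_repeat_spec:
        for _ in range(count):
            rep = _to_str(_random_seq(rng, rep_len, cfg.gc))
            w1 = _place_anywhere(rng, protected, Lf, rep_len)
            if w1 is not None:
                protected[w1 : w1 + rep_len] = True
            w2 = _place_anywhere(rng, protected, Lf, rep_len)
            if w1 is None or w2 is None:
                raise SimCapacityError("no room left for short repeats")
            kind = "direct" if rng.random() < 0.5 else "inverted"
            copy2 = _mutate_copy(rng, rep, identity)
            if kind == "inverted":
                copy2 = revcomp(copy2)
            cyb[w1 : w1 + rep_len] = np.frombuffer(rep.encode(), dtype=np.uint8)
            cyb[w2 : w2 + rep_len] = np.frombuffer(copy2.encode(), dtype=np.uint8)
            for w in (w1, w2):
                protected[max(0, w - 150) : min(Lf, w + rep_len + 150)] = True
            a, b = sorted([w1, w2])
            ri += 1
            truth.features.append(TruthFeature(
                "short_repeat", f"SR{ri}", a + 1, a + rep_len,
                mate_start=b + 1, mate_end=b + rep_len, kind=kind,
                identity=identity,
            ))

    # --- CMS-candidate ORF inside the largest donor segment
    if cfg.plant_cms_orf:
        _plant_cms_orf(rng, cyb, truth, final_genes, Lf)

    # --- boundary shifts (length-preserving engineering of existing context)
    shift_genes = []
    gene_pool = list(range(len(final_genes)))
    for (end, shift_len) in cfg.boundary_shifts:
        gi = gene_pool.pop(int(rng.integers(0, len(gene_pool))))
        shift_genes.append(gi)
        name, gs, ge, strand = final_genes[gi]
        if end == "3prime":
            _plant_3prime_shift(cyb, gs, ge, strand, shift_len, Lf)
        else:
            _plant_5prime_shift(cyb, gs, ge, strand, shift_len, Lf)
        truth.features.append(TruthFeature(
            "boundary_shift", name, gs + 1, ge + 1, strand=strand,
            kind=end, info=f"shift_len={shift_len}",
        ))

    # --- coding SNPs with transition bias
    snp_pool = [i for i in range(len(final_genes)) if i not in shift_genes]
    used_codons: set[tuple[int, int]] = set()
    planted = 0
    attempts = 0
    while planted < cfg.n_coding_snps and attempts < 50 * cfg.n_coding_snps:
        attempts += 1
        gi = int(rng.integers(0, len(snp_pool)))
        gidx = snp_pool[gi]
        name, gs, ge, strand = final_genes[gidx]
        n_codons = (ge - gs + 1) // 3
        ci = int(rng.integers(1, n_codons - 1))  # skip start and stop codons
        if (gidx, ci) in used_codons:
            continue
        off = int(rng.integers(0, 3))
        cds_pos = 3 * ci + off + 1
        gpos = gs + (cds_pos - 1) if strand == "+" else ge - (cds_pos - 1)
        ref_cds_base = chr(cyb[gpos]) if strand == "+" else _comp(chr(cyb[gpos]))
        if rng.random() < cfg.titv_bias:
            alt = _TRANSITION[ref_cds_base]
            snp_type = "transition"
        else:
            alt = _TRANSVERSIONS[ref_cds_base][int(rng.integers(0, 2))]
            snp_type = "transversion"
        codon_s = gs + 3 * ci if strand == "+" else ge - 3 * ci - 2
        codon = "".join(chr(c) for c in cyb[codon_s : codon_s + 3])
        if strand == "-":
            codon = revcomp(codon)
        new_codon = codon[:off] + alt + codon[off + 1 :]
        if new_codon in STOPS:
            continue
        written = alt if strand == "+" else _comp(alt)
        cyb[gpos] = ord(written)
        used_codons.add((gidx, ci))
        planted += 1
        from Bio.Seq import Seq

        ref_aa = str(Seq(codon).translate(table=1))
        alt_aa = str(Seq(new_codon).translate(table=1))
        truth.features.append(TruthFeature(
            "snp", name, gpos + 1, gpos + 1, strand=strand,
            kind=snp_type,
            info=(f"cds_pos={cds_pos};ref={ref_cds_base};alt={alt};"
                  f"codon_index={ci + 1};"
                  f"effect={'synonymous' if ref_aa == alt_aa else 'non-synonymous'}"),
        ))
    if planted < cfg.n_coding_snps:
        raise SimCapacityError("could not place all requested coding SNPs")

    cybrid = CircularSeq("cybrid", cyb.tobytes().decode("ascii"), is_circular=True)
    return recipient, comparators, donor, cp, cybrid, truth


def _comp(b: str) -> str:
    return {"A": "T", "T": "A", "C": "G", "G": "C"}[b]


def _mutate_whole(rng: np.random.Generator, seq: str, rate: float) -> str:
    n = len(seq)
    k = rng.binomial(n, rate)
    if k == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    pos = rng.choice(n, size=k, replace=False)
    for p in pos:
        cur = chr(arr[p])
        arr[p] = ord(rng.choice([b for b in "ACGT" if b != cur]))
    return arr.tobytes().decode()


def _neutral_move(rng: np.random.Generator, seq: str) -> str:
    n = len(seq)
    length = int(rng.integers(5000, 20000))
    s = int(rng.integers(0, n - length))
    seg = seq[s : s + length]
    rest = seq[:s] + seq[s + length :]
    p = int(rng.integers(0, len(rest)))
    if rng.random() < 0.3:
        seg = revcomp(seg)
    return rest[:p] + seg + rest[p:]


def _choose_cuts(rng, L0, n_cuts, gene_mask) -> list[int]:
    cuts: list[int] = []
    for _ in range(2000):
        if len(cuts) == n_cuts:
            break
        c = int(rng.integers(2000, L0 - 2000))
        if gene_mask[max(0, c - 1000) : c + 1000].any():
            continue
        if any(abs(c - x) < 4000 for x in cuts):
            continue
        cuts.append(c)
    if len(cuts) < n_cuts:
        raise SimCapacityError("could not place block cut points clear of genes")
    return sorted(cuts)


def _find_window_in_blocks(rng, pieces, length, gene_mask) -> int:
    """A recipient-coordinate window of ``length`` inside some block, clear of
    genes and piece edges."""
    candidates = [p for p in pieces if p.kind == "block"
                  and (p.src_end - p.src_start + 1) > length + 2 * SPLIT_MARGIN]
    for ci in rng.permutation(len(candidates)):
        p = candidates[int(ci)]
        for _ in range(200):
            s = int(rng.integers(p.src_start + SPLIT_MARGIN,
                                 p.src_end - SPLIT_MARGIN - length))
            if not gene_mask[s : s + length].any():
                return s
    raise SimCapacityError("no room for the large-repeat source window")


def _insert_piece(rng, pieces, new: _Piece, gene_mask, forbidden,
                  prefer_near_gene: bool = False) -> None:
    """Split a random block piece at a safe recipient position and insert
    ``new`` between the halves."""
    order = list(range(len(pieces)))
    rng.shuffle(order)
    for attempt in range(4000):
        idx = order[attempt % len(order)]
        p = pieces[idx]
        if p.kind != "block":
            continue
        if p.src_end - p.src_start + 1 < 2 * SPLIT_MARGIN + 10:
            continue
        q = int(rng.integers(p.src_start + SPLIT_MARGIN, p.src_end - SPLIT_MARGIN))
        if gene_mask[max(0, q - GENE_MARGIN) : q + GENE_MARGIN].any():
            continue
        if prefer_near_gene and not gene_mask[max(0, q - 1200) : q + 1200].any():
            # want the split within ~1.2 kb of a gene so a planted ORF at the
            # segment edge lands near a functional gene
            continue
        if any(fs - 50 <= q <= fe + 50 for fs, fe in forbidden):
            continue
        left = _Piece("block", "", p.src_start, q - 1, p.inverted, p.name + "a")
        right = _Piece("block", "", q, p.src_end, p.inverted, p.name + "b")
        # re-derive sequences from source coordinates
        return _do_split(pieces, idx, p, left, right, new)
    raise SimCapacityError(f"no valid insertion site for piece {new.name!r}")


def _do_split(pieces, idx, p, left, right, new) -> None:
    full = p.seq if not p.inverted else revcomp(p.seq)  # recipient orientation
    lseq = full[: left.src_end - left.src_start + 1]
    rseq = full[left.src_end - left.src_start + 1 :]
    left.seq = lseq if not p.inverted else revcomp(lseq)
    right.seq = rseq if not p.inverted else revcomp(rseq)
    if p.inverted:
        pieces[idx : idx + 1] = [right, new, left]
    else:
        pieces[idx : idx + 1] = [left, new, right]


def _disjoint_windows(rng, L, lengths) -> list[tuple[int, int]]:
    used: list[tuple[int, int]] = []
    out = []
    for length in lengths:
        for _ in range(1000):
            s = int(rng.integers(0, L - length))
            if all(s + length + 100 < us or s > ue + 100 for us, ue in used):
                used.append((s, s + length - 1))
                out.append((s, s + length - 1))
                break
        else:
            raise SimCapacityError("source genome too small for requested segments")
    return out


def _broken_adjacencies(pieces, offsets, blocks, perm) -> list[tuple[int, int]]:
    """Final-coordinate breakpoint pairs for recipient adjacencies broken by
    the permutation: for each original cut, the final positions of the two
    recipient positions that used to touch."""
    ends: dict[int, tuple[int, bool]] = {}
    starts: dict[int, tuple[int, bool]] = {}
    for piece, off in zip(pieces, offsets):
        if piece.kind != "block":
            continue
        if piece.inverted:
            ends[piece.src_end] = (off, True)
            starts[piece.src_start] = (off + (piece.src_end - piece.src_start), True)
        else:
            starts[piece.src_start] = (off, False)
            ends[piece.src_end] = (off + (piece.src_end - piece.src_start), False)
    out = []
    for bi in range(len(blocks) - 1):
        e = blocks[bi][1]
        s = blocks[bi + 1][0]
        if e not in ends or s not in starts:
            continue
        fe = ends[e][0]
        fs = starts[s][0]
        if abs(fs - fe) == 1:
            continue  # still adjacent: not broken
        out.append((fe, fs))
    return out


def _place_near(rng, protected, Lf, anchor, length, max_offset=120):
    """Window of ``length`` with an end within ``max_offset`` of ``anchor``."""
    for _ in range(200):
        off = int(rng.integers(5, max_offset))
        side = rng.random() < 0.5
        s = anchor - off - length if side else anchor + off
        if s < 0 or s + length > Lf:
            continue
        if not protected[s : s + length].any():
            return s
    return None


def _place_anywhere(rng, protected, Lf, length):
    for _ in range(2000):
        s = int(rng.integers(0, Lf - length))
        if not protected[s : s + length].any():
            return s
    return None


def _plant_cms_orf(rng, cyb, truth, final_genes, Lf) -> None:
    """Write an orf138-like chimeric ORF near the edge of the largest donor
    segment: unique (donor context), one strong transmembrane block, close to
    a functional gene."""
    donor_feats = [f for f in truth.features if f.feature_class == "donor"]
    if not donor_feats:
        return
    target = max(donor_feats, key=lambda f: f.end - f.start)
    # 138 codons: polar head, 25-residue hydrophobic core, polar tail
    aa = ("M" + "".join(rng.choice(list("STNQDEKR"), 20))
          + "".join(rng.choice(list("LIVF"), 25))
          + "".join(rng.choice(list("STNQDEKRGAP"), 92)))
    codon_of = {
        "M": "ATG", "S": "TCT", "T": "ACT", "N": "AAT", "Q": "CAA",
        "D": "GAT", "E": "GAA", "K": "AAA", "R": "CGT", "L": "CTT",
        "I": "ATT", "V": "GTT", "F": "TTT", "G": "GGT", "A": "GCT",
        "P": "CCT",
    }
    nt = "".join(codon_of[c] for c in aa) + "TAA"
    seg_s0, seg_e0 = target.start - 1, target.end - 1
    # place at whichever segment edge is closer to a gene
    dist_left = min((abs(seg_s0 - ge) for _, _, ge, _ in final_genes), default=Lf)
    dist_right = min((abs(gs - seg_e0) for _, gs, _, _ in final_genes), default=Lf)
    if dist_left <= dist_right:
        s = seg_s0 + 60
    else:
        s = seg_e0 - 60 - len(nt)
    # guard stops so the ORF boundaries are exactly as planted
    guard5 = "TAA"
    cyb[s - 3 : s] = np.frombuffer(guard5.encode(), dtype=np.uint8)
    cyb[s : s + len(nt)] = np.frombuffer(nt.encode(), dtype=np.uint8)
    truth.features.append(TruthFeature(
        "cms_orf", "orf138like", s + 1, s + len(nt), strand="+",
        info=f"in_segment={target.name}",
    ))


def _plant_3prime_shift(cyb, gs, ge, strand, shift_len, Lf) -> None:
    """Disrupt the stop codon and make the next in-frame stop sit exactly
    ``shift_len`` bp downstream (oriented)."""
    k = shift_len // 3
    if strand == "+":
        stop0 = ge - 2

        def put(p, codon):
            cyb[p : p + 3] = np.frombuffer(codon.encode(), dtype=np.uint8)

        def get(p):
            return cyb[p : p + 3].tobytes().decode()

        step = 3
    else:
        stop0 = gs  # stop codon occupies gs..gs+2 in genome; oriented via revcomp

        def put(p, codon):
            cyb[p : p + 3] = np.frombuffer(revcomp(codon).encode(), dtype=np.uint8)

        def get(p):
            return revcomp(cyb[p : p + 3].tobytes().decode())

        step = -3
    # 1. disrupt the stop (TAA->CAA style: mutate first base to C)
    old = get(stop0)
    put(stop0, "C" + old[1:] if old[0] != "C" else "G" + old[1:])
    # 2. clear stops from the next k-1 downstream codons
    for j in range(1, k):
        p = stop0 + step * j
        if get(p) in STOPS:
            put(p, "CAA")
    # 3. place the new stop k codons downstream
    put(stop0 + step * k, "TAA")


def _plant_5prime_shift(cyb, gs, ge, strand, shift_len, Lf) -> None:
    """Engineer an in-frame ATG-led upstream open extension of exactly
    ``shift_len`` bp by minimally editing the existing upstream context
    (so the region still matches the recipient-derived comparators)."""
    k = shift_len // 3
    if strand == "+":
        start0 = gs

        def put(p, codon):
            cyb[p : p + 3] = np.frombuffer(codon.encode(), dtype=np.uint8)

        def get(p):
            return cyb[p : p + 3].tobytes().decode()

        step = 3
    else:
        start0 = ge - 2

        def put(p, codon):
            cyb[p : p + 3] = np.frombuffer(revcomp(codon).encode(), dtype=np.uint8)

        def get(p):
            return revcomp(cyb[p : p + 3].tobytes().decode())

        step = -3
    # new start codon shift_len bp upstream; stop guard immediately before it
    put(start0 - step * k, "ATG")
    put(start0 - step * (k + 1), "TAA")
    # clear intervening stops and premature ATGs would be fine (farthest wins);
    # only stops must go
    for j in range(1, k):
        p = start0 - step * j
        if get(p) in STOPS:
            put(p, "CAA")


# ---------------------------------------------------------------------------
# recovery scoring


@dataclass
class RecoveryReport:
    precision: float
    recall: float
    mean_boundary_error: float
    n_called: int
    n_truth: int
    matched: list[tuple[int, int]] = field(default_factory=list)


def score_recovery(
    called: list[Interval],
    truth: list[Interval],
    L: int,
    boundary_tol: int = 100,
    min_reciprocal: float = 0.8,
) -> RecoveryReport:
    """Match called intervals to truth intervals (reciprocal overlap >=
    ``min_reciprocal`` and both boundary errors <= ``boundary_tol``) and
    report precision, recall and the mean boundary error of matches."""
    from .genomes import coverage_mask

    t_masks = [coverage_mask([iv], L) for iv in truth]
    c_masks = [coverage_mask([iv], L) for iv in called]
    used_called: set[int] = set()
    matched = []
    errors = []
    for ti, (t_iv, tm) in enumerate(zip(truth, t_masks)):
        best = None
        for ci, (c_iv, cm) in enumerate(zip(called, c_masks)):
            if ci in used_called:
                continue
            ov = int((tm & cm).sum())
            if ov == 0:
                continue
            if ov / tm.sum() < min_reciprocal or ov / cm.sum() < min_reciprocal:
                continue
            e1 = _cdist(t_iv.start, c_iv.start, L)
            e2 = _cdist(t_iv.end, c_iv.end, L)
            if max(e1, e2) > boundary_tol:
                continue
            if best is None or ov > best[1]:
                best = (ci, ov, (e1 + e2) / 2)
        if best is not None:
            used_called.add(best[0])
            matched.append((ti, best[0]))
            errors.append(best[2])
    n_t, n_c = len(truth), len(called)
    recall = len(matched) / n_t if n_t else 1.0
    precision = len(matched) / n_c if n_c else 1.0
    mbe = float(np.mean(errors)) if errors else 0.0
    return RecoveryReport(precision, recall, mbe, n_c, n_t, matched)


def _cdist(a: int, b: int, L: int) -> int:
    d = abs(a - b)
    return min(d, L - d)
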