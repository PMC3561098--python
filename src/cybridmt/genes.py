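"""Gene-level comparisons between orthologous mitochondrial genes.

Covers substitution calling within aligned CDS pairs (synonymous /
non-synonymous and transition / transversion typing), detection of in-frame
gene-boundary shifts (displaced stop codons, upstream in-frame start
extensions), six-frame ORF finding on circular genomes, Kyte–Doolittle
transmembrane-segment prediction, and the three-criterion screen for
cytoplasmic-male-sterility candidate ORFs (mitotype-unique, membrane
spanning, near a functional gene).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from .genomes import CircularSeq, DomainError, GeneModel, Interval, extract, revcomp
from .localalign import find_local_matches

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# Kyte & Doolittle hydropathy scale
KD_SCALE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class SnpRecord:
    gene_id: str
    cds_pos: int  # 1-based within the CDS
    ref_base: str
    alt_base: str
    codon_index: int  # == ceil(cds_pos / 3)
    ref_aa: str
    alt_aa: str
    effect: str  # synonymous | non-synonymous
    snp_type: str  # transition | transversion


@dataclass(frozen=True)
class BoundaryShift:
    gene_id: str
    end: str  # 5prime | 3prime
    shift_len: int  # positive = extension, in bp
    new_boundary: Interval


@dataclass(frozen=True)
class OrfRecord:
    orf_id: str
    iv: Interval
    strand: str
    length: int  # nucleotides, stop codon included
    protein: str


def classify_substitution(ref: str, alt: str) -> str:
    """Transition (purine<->purine or pyrimidine<->pyrimidine) vs
    transversion."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in "ACGT" or alt not in "ACGT":
        raise DomainError(f"bases must be unambiguous A/C/G/T: {ref!r}, {alt!r}")
    if ref == alt:
        raise DomainError(f"not a substitution: {ref} -> {alt}")
    same_class = ({ref, alt} <= PURINES) or ({ref, alt} <= PYRIMIDINES)
    return "transition" if same_class else "transversion"


def _translate(codon: str) -> str:
    return str(Seq(codon).translate(table=1))


def call_gene_snps(ref_cds: str, alt_cds: str, gene_id: str = "") -> list[SnpRecord]:
    """Substitution records between two equal-length, in-frame CDSs.

    Codons carrying several substitutions are translated jointly but each
    site still emits its own record (labelled with the joint amino-acid
    effect).  Unequal lengths are indel/boundary-shift territory and raise.
    """
    ref_cds, alt_cds = ref_cds.upper(), alt_cds.upper()
    if len(ref_cds) != len(alt_cds):
        raise DomainError(
            f"{gene_id or 'CDS'}: unequal CDS lengths ({len(ref_cds)} vs "
            f"{len(alt_cds)}); use detect_boundary_shift for indel/extension cases"
        )
    if len(ref_cds) % 3 != 0:
        raise DomainError(f"{gene_id or 'CDS'}: length not a multiple of 3")
    out: list[SnpRecord] = []
    n_codons = len(ref_cds) // 3
    for ci in range(n_codons):
        rc = ref_cds[3 * ci : 3 * ci + 3]
        ac = alt_cds[3 * ci : 3 * ci + 3]
        if rc == ac:
            continue
        ref_aa, alt_aa = _translate(rc), _translate(ac)
        if ci < n_codons - 1 and ("*" in (ref_aa, alt_aa)):
            warnings.warn(
                f"{gene_id or 'CDS'}: internal stop codon at codon {ci + 1}",
                stacklevel=2,
            )
        effect = "synonymous" if ref_aa == alt_aa else "non-synonymous"
        for off in range(3):
            if rc[off] != ac[off]:
                pos = 3 * ci + off + 1
                out.append(
                    SnpRecord(
                        gene_id=gene_id,
                        cds_pos=pos,
                        ref_base=rc[off],
                        alt_base=ac[off],
                        codon_index=math.ceil(pos / 3),
                        ref_aa=ref_aa,
                        alt_aa=alt_aa,
                        effect=effect,
                        snp_type=classify_substitution(rc[off], ac[off]),
                    )
                )
    return out


# ---------------------------------------------------------------------------
# boundary shifts


def _oriented_view(genome: CircularSeq, strand: str) -> str:
    return genome.seq if strand == "+" else revcomp(genome.seq)


def _upstream_open_extension(seq_f: str, start0: int, max_codons: int) -> int:
    """Longest in-frame ATG-led extension upstream of ``start0`` (0-based,
    oriented) with no intervening stop codon, in bp; 0 if none."""
    best = 0
    for k in range(1, max_codons + 1):
        p = start0 - 3 * k
        if p < 0:
            break
        codon = seq_f[p : p + 3]
        if codon in STOP_CODONS:
            break
        if codon == "ATG":
            best = 3 * k
    return best


def detect_boundary_shift(
    ref_model: GeneModel,
    ref_genome: CircularSeq,
    alt_genome: CircularSeq,
    *,
    min_core_identity: float = 0.90,
    max_scan_codons: int = 200,
) -> list[BoundaryShift]:
    """Detect in-frame 5'/3' extensions of an orthologous gene.

    The reference CDS is located in the alternative genome by local match
    (>= ``min_core_identity``); from the matched core the detector scans in
    frame: a 3' extension is reported when the orthologous stop codon is
    disrupted and the next in-frame stop lies k codons downstream
    (shift_len = 3k); a 5' extension when the alt genome has an in-frame
    ATG-led upstream open extension that the reference genome itself lacks.

    Single-interval gene models only (plant mt protein genes as handled
    here are unspliced).
    """
    if len(ref_model.intervals) != 1:
        raise DomainError("detect_boundary_shift expects a single-interval model")
    ref_iv = ref_model.intervals[0]
    ref_cds = extract(ref_genome, ref_iv)
    cds_len = len(ref_cds)
    query = CircularSeq(f"{ref_model.gene_id}_cds", ref_cds, is_circular=False)
    matches = find_local_matches(
        query, alt_genome,
        min_len=max(30, cds_len // 3),
        min_identity=min_core_identity,
    )
    if not matches:
        raise LookupError(
            f"{ref_model.gene_id}: core CDS not found in {alt_genome.id!r} at "
            f">= {min_core_identity:.0%} identity"
        )
    best = max(matches, key=lambda m: m.score)
    Lt = alt_genome.length
    st = best.strand
    alt_f = _oriented_view(alt_genome, st)
    # oriented 0-based start of the (projected) full CDS in alt
    if st == "+":
        core_start_f = best.t_iv.start - 1
    else:
        core_start_f = Lt - best.t_iv.end
    est_start0 = core_start_f - (best.q_iv.start - 1)

    out: list[BoundaryShift] = []

    # --- 3' end: displaced stop codon
    exp_stop0 = est_start0 + cds_len - 3
    if 0 <= exp_stop0 and exp_stop0 + 3 <= len(alt_f):
        if alt_f[exp_stop0 : exp_stop0 + 3] not in STOP_CODONS:
            for k in range(1, max_scan_codons + 1):
                p = exp_stop0 + 3 * k
                if p + 3 > len(alt_f):
                    break
                if alt_f[p : p + 3] in STOP_CODONS:
                    new_end_f = p + 2
                    out.append(
                        BoundaryShift(
                            ref_model.gene_id, "3prime", 3 * k,
                            _from_oriented(exp_stop0 + 3, new_end_f, st, Lt),
                        )
                    )
                    break

    # --- 5' end: upstream in-frame ATG-led extension absent from the reference
    ext_alt = _upstream_open_extension(alt_f, est_start0, max_scan_codons)
    if ext_alt > 0:
        ref_f = _oriented_view(ref_genome, ref_iv.strand)
        if ref_iv.strand == "+":
            ref_start0 = ref_iv.start - 1
        else:
            ref_start0 = ref_genome.length - ref_iv.end
        ext_ref = _upstream_open_extension(ref_f, ref_start0, max_scan_codons)
        if ext_alt != ext_ref:
            out.append(
                BoundaryShift(
                    ref_model.gene_id, "5prime", ext_alt,
                    _from_oriented(est_start0 - ext_alt, est_start0 - 1, st, Lt),
                )
            )
    return out


def _from_oriented(s0: int, e0: int, strand: str, L: int) -> Interval:
    """Map an oriented 0-based inclusive range back to 1-based genome coords."""
    if strand == "+":
        return Interval(s0 + 1, e0 + 1, "+")
    return Interval(L - e0, L - s0, "-")


# ---------------------------------------------------------------------------
# ORF finding


def find_orfs(g: CircularSeq, min_orf_len: int = 300) -> list[OrfRecord]:
    """Six-frame ATG-to-stop ORFs of length >= ``min_orf_len`` (stop codon
    included).  On circular genomes ORFs may cross the origin (reported once,
    as a wrapping interval); nested starts sharing a stop report only the
    longest ORF per (stop, frame)."""
    L = g.length
    found: dict[tuple[str, int], tuple[int, int, int]] = {}
    for strand in "+-":
        base = g.seq if strand == "+" else revcomp(g.seq)
        work = base * 2 if g.is_circular else base
        n = len(work)
        for frame in range(3):
            start = None
            p = frame
            while p + 3 <= n:
                codon = work[p : p + 3]
                if codon in STOP_CODONS:
                    if start is not None:
                        length = p + 3 - start
                        if (length >= min_orf_len and start < L
                                and length <= L):
                            # same strand + same genomic stop position ==
                            # same ORF (doubled-sequence duplicates collapse)
                            key = (strand, (p + 3) % L)
                            prev = found.get(key)
                            if prev is None or length > prev[2]:
                                found[key] = (start, p + 2, length)
                        start = None
                elif codon == "ATG" and start is None:
                    start = p
                p += 3
    records: list[OrfRecord] = []
    for (strand, _stop), (s0, e0, length) in found.items():
        s0m, e0m = s0 % L, e0 % L
        if strand == "+":
            iv = Interval(s0m + 1, e0m + 1, "+")
        else:
            iv = Interval(L - e0m, L - s0m, "-")
        seq = g.seq[s0m:] + g.seq[: e0m + 1] if strand == "+" and s0m > e0m else None
        if strand == "+":
            orf_nt = seq if seq is not None else g.seq[s0m : e0m + 1]
        else:
            orf_nt = extract(g, iv)
        protein = str(Seq(orf_nt[:-3]).translate(table=1))
        records.append(OrfRecord("", iv, strand, length, protein))
    records.sort(key=lambda r: (r.iv.start, r.iv.end, r.strand))
    # paper-style names: orf<aa length>, -n suffix disambiguates duplicates
    counts: dict[str, int] = {}
    named = []
    for r in records:
        base_name = f"orf{len(r.protein)}"
        counts[base_name] = counts.get(base_name, 0) + 1
        named.append(r)
    totals = {}
    final = []
    for r in named:
        base_name = f"orf{len(r.protein)}"
        if counts[base_name] > 1:
            totals[base_name] = totals.get(base_name, 0) + 1
            name = f"{base_name}-{totals[base_name]}"
        else:
            name = base_name
        final.append(OrfRecord(name, r.iv, r.strand, r.length, r.protein))
    return final


# ---------------------------------------------------------------------------
# transmembrane segments and the CMS screen


def predict_tm_segments(
    protein: str, window: int = 19, threshold: float = 1.6
) -> list[tuple[int, int]]:
    """Candidate membrane-spanning segments by Kyte–Doolittle sliding-window
    hydropathy: maximal runs of windows whose mean exceeds ``threshold``,
    merged and reported as 1-based residue ranges."""
    protein = protein.upper().rstrip("*")
    if any(c not in KD_SCALE for c in protein):
        bad = next(c for c in protein if c not in KD_SCALE)
        raise DomainError(f"non-standard amino acid {bad!r} in protein")
    n = len(protein)
    if n < window:
        return []
    vals = np.array([KD_SCALE[c] for c in protein])
    means = np.convolve(vals, np.ones(window) / window, mode="valid")
    above = means > threshold
    segments: list[tuple[int, int]] = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            segments.append((i + 1, j + window))  # 1-based residues
            i = j + 1
        else:
            i += 1
    return segments


@dataclass(frozen=True)
class CmsCandidate:
    orf_id: str
    is_unique: bool
    has_tm: bool
    near_gene: bool
    nearest_gene: str
    gene_distance: int
    criteria_met: int


def _interval_distance(a: Interval, b: Interval, L: int) -> int:
    """Minimal circular distance between two intervals (0 if overlapping)."""
    pa = [(a.start, a.end)] if not a.wraps else [(a.start, L), (1, a.end)]
    pb = [(b.start, b.end)] if not b.wraps else [(b.start, L), (1, b.end)]
    best = L
    for s1, e1 in pa:
        for s2, e2 in pb:
            if s1 <= e2 and s2 <= e1:
                return 0
            d = min(abs(s2 - e1), abs(s1 - e2))
            best = min(best, d, L - d)
    return best


def screen_cms_candidates(
    orfs: list[OrfRecord],
    sharedness: dict[str, str],
    gene_annotations: list[GeneModel],
    L: int,
    proximity: int = 2000,
    *,
    tm_window: int = 19,
    tm_threshold: float = 1.6,
) -> list[CmsCandidate]:
    """Rank ORFs by the three classic CMS-gene criteria: unique to the
    mitotype, predicted membrane-spanning segment, and proximity (<=
    ``proximity`` bp) to a functional gene.  ORFs meeting all three rank
    first; each report lists which criteria were met."""
    functional = [g for g in gene_annotations
                  if g.type in ("protein", "tRNA", "rRNA")]
    out = []
    for orf in orfs:
        unique = sharedness.get(orf.orf_id, "unique") == "unique"
        tm = bool(
            len(orf.protein) >= tm_window
            and predict_tm_segments(orf.protein, tm_window, tm_threshold)
        )
        nearest, dist = ".", L
        for g in functional:
            for iv in g.intervals:
                d = _interval_distance(orf.iv, iv, L)
                if d < dist:
                    nearest, dist = g.gene_id, d
        near = dist <= proximity
        out.append(
            CmsCandidate(orf.orf_id, unique, tm, near, nearest, dist,
                         int(unique) + int(tm) + int(near))
        )
    out.sort(key=lambda c: (-c.criteria_met, c.gene_distance, c.orf_id))
    return out


def load_reference_snp_table():
    """The published gene-level SNP table between the oguC cybrid and the
    nap mitotype (39 printed rows), as a pandas DataFrame.  Missing
    amino-acid columns are '.'; one typographic variant of 'transition' in
    the source is normalized."""
    from importlib.resources import files

    import pandas as pd

    path = files("cybridmt.data").joinpath("snp_table_oguC_nap.tsv")
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t", keep_default_na=False)


def snps_to_frame(records: list[SnpRecord]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene": r.gene_id,
                "cds_pos": r.cds_pos,
                "ref": r.ref_base,
                "alt": r.alt_base,
                "codon_index": r.codon_index,
                "ref_aa": r.ref_aa,
                "alt_aa": r.alt_aa,
                "effect": r.effect,
                "snp_type": r.snp_type,
            }
            for r in records
        ],
        columns=["gene", "cds_pos", "ref", "alt", "codon_index", "ref_aa",
                 "alt_aa", "effect", "snp_type"],
    )
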