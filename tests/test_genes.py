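"""Gene-level operations: substitution typing, boundary shifts, ORF finding,
hydropathy segments and the CMS screen."""

import itertools
import math

import numpy as np
import pytest

from cybridmt.genes import (
    STOP_CODONS, classify_substitution, call_gene_snps, detect_boundary_shift,
    find_orfs, load_reference_snp_table, predict_tm_segments,
    screen_cms_candidates,
)
from cybridmt.genomes import (
    CircularSeq, DomainError, GeneModel, Interval, extract, revcomp,
)

from conftest import random_seq


class TestClassifySubstitution:
    def test_published_examples(self):
        assert classify_substitution("C", "T") == "transition"
        assert classify_substitution("T", "G") == "transversion"

    def test_all_twelve_ordered_pairs(self):
        labels = [classify_substitution(a, b)
                  for a, b in itertools.permutations("ACGT", 2)]
        assert labels.count("transition") == 4
        assert labels.count("transversion") == 8

    def test_errors(self):
        with pytest.raises(DomainError):
            classify_substitution("A", "A")
        with pytest.raises(DomainError):
            classify_substitution("A", "N")


class TestReferenceSnpTable:
    """The published cybrid-vs-nap SNP table is internally consistent with
    the classifier and the codon-index arithmetic."""

    def test_typing_reproduced_for_every_row(self):
        df = load_reference_snp_table()
        assert len(df) == 39
        for r in df.itertuples():
            assert classify_substitution(r.ref, r.alt) == r.snp_type

    def test_synonymous_count(self):
        df = load_reference_snp_table()
        assert (df.effect == "S").sum() == 13

    def test_codon_index_arithmetic(self):
        df = load_reference_snp_table()
        rows = df[df.aa_pos != "."]
        assert len(rows) > 0
        for r in rows.itertuples():
            assert int(r.aa_pos) == math.ceil(int(r.cds_pos) / 3)


def _cds_with_codons(n_codons, rng):
    from cybridmt.simulate import _random_cds

    return _random_cds(rng, n_codons)


class TestCallGeneSnps:
    def test_published_style_substitution(self):
        """A C->T at CDS position 571 turning CTT(Leu) into TTT(Phe) is a
        non-synonymous transition in codon 191."""
        rng = np.random.default_rng(60)
        ref = _cds_with_codons(220, rng)
        ref = ref[:570] + "CTT"[0:0] + ref[570:]  # no-op, positions aligned
        ref = ref[: 3 * 190] + "CTT" + ref[3 * 190 + 3 :]
        alt = ref[:570] + "T" + ref[571:]
        recs = call_gene_snps(ref, alt, "nad1")
        assert len(recs) == 1
        r = recs[0]
        assert (r.cds_pos, r.codon_index) == (571, 191)
        assert (r.ref_aa, r.alt_aa) == ("L", "F")
        assert (r.effect, r.snp_type) == ("non-synonymous", "transition")

    def test_ile_to_val_at_codon_22(self):
        rng = np.random.default_rng(61)
        ref = _cds_with_codons(80, rng)
        ref = ref[: 3 * 21] + "ATT" + ref[3 * 21 + 3 :]
        alt = ref[:63] + "G" + ref[64:]
        (r,) = call_gene_snps(ref, alt, "atp9")
        assert (r.cds_pos, r.codon_index) == (64, 22)
        assert (r.ref_aa, r.alt_aa) == ("I", "V")
        assert r.snp_type == "transition"

    def test_identical_empty(self):
        rng = np.random.default_rng(62)
        cds = _cds_with_codons(50, rng)
        assert call_gene_snps(cds, cds) == []

    def test_unequal_length_directed_to_boundary_shift(self):
        with pytest.raises(DomainError, match="boundary"):
            call_gene_snps("ATGAAATAA", "ATGAAAAAATAA")

    def test_multi_hit_codon_joint_translation(self):
        ref = "ATG" + "CTT" + "TAA"  # Leu
        alt = "ATG" + "GAT" + "TAA"  # Asp (codon fully rewritten)
        recs = call_gene_snps(ref, alt)
        assert len(recs) == 2  # positions 4 and 5 differ; position 6 is T==T
        assert all(r.effect == "non-synonymous" for r in recs)
        assert all((r.ref_aa, r.alt_aa) == ("L", "D") for r in recs)

    def test_internal_stop_warns(self):
        ref = "ATG" + "TAC" + "AAA" + "TAA"
        alt = "ATG" + "TAA" + "AAA" + "TAA"  # internal stop created
        with pytest.warns(UserWarning, match="internal stop"):
            recs = call_gene_snps(ref, alt)
        assert len(recs) == 1


def _construct_ortholog(rng, cds, up=900, down=900, strand="+"):
    """Plant a CDS (with a stop guard just upstream) into a random genome."""
    upstream = random_seq(rng, up - 3) + "TAA"
    downstream = random_seq(rng, down)
    seq = upstream + cds + downstream
    if strand == "-":
        seq = revcomp(seq)
        iv = Interval(down + 1, down + len(cds), "-")
    else:
        iv = Interval(up + 1, up + len(cds), "+")
    return CircularSeq("g", random_seq(rng, 2000) + seq + random_seq(rng, 2000),
                       is_circular=False), iv


class TestBoundaryShift:
    def _make_pair(self, rng, strand="+"):
        cds = _cds_with_codons(150, rng)
        up = random_seq(rng, 897) + "TAA"
        down = random_seq(rng, 900)
        ref_core = up + cds + down
        ref = CircularSeq("ref", ref_core, is_circular=False)
        iv = Interval(901, 900 + len(cds), "+")
        return cds, up, down, ref, iv

    def test_displaced_stop_detected(self):
        """Stop disrupted, next in-frame stop 9 codons downstream -> +27."""
        rng = np.random.default_rng(63)
        cds, up, down, ref, iv = self._make_pair(rng)
        body = cds[:-3]
        # disrupted stop + 8 cleared codons + new stop = 27 bp displacement
        cleared = "CAA" + "".join(_nonstop(rng) for _ in range(8))
        alt_core = up + body + cleared + "TAA" + down[30:]
        alt = CircularSeq("alt", alt_core, is_circular=False)
        model = GeneModel("tatC-like", [iv])
        shifts = detect_boundary_shift(model, ref, alt)
        assert [(s.end, s.shift_len) for s in shifts] == [("3prime", 27)]

    def test_upstream_extension_detected(self):
        """An in-frame ATG-led 498 bp prefix with a stop guard -> +498."""
        rng = np.random.default_rng(64)
        cds, up, down, ref, iv = self._make_pair(rng)
        ext = "ATG" + "".join(_nonstop(rng) for _ in range(165))
        assert len(ext) == 498
        alt_core = up[: 900 - 498 - 3] + "TAA" + ext + cds + down
        alt = CircularSeq("alt", alt_core, is_circular=False)
        model = GeneModel("atp6-like", [iv])
        shifts = detect_boundary_shift(model, ref, alt)
        assert ("5prime", 498) in [(s.end, s.shift_len) for s in shifts]

    def test_unmodified_ortholog_empty(self):
        rng = np.random.default_rng(65)
        cds, up, down, ref, iv = self._make_pair(rng)
        alt = CircularSeq("alt", ref.seq, is_circular=False)
        model = GeneModel("g", [iv])
        assert detect_boundary_shift(model, ref, alt) == []

    def test_missing_core_raises(self):
        rng = np.random.default_rng(66)
        cds, up, down, ref, iv = self._make_pair(rng)
        alt = CircularSeq("alt", random_seq(rng, 5000), is_circular=False)
        with pytest.raises(LookupError):
            detect_boundary_shift(GeneModel("g", [iv]), ref, alt)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_constructs_recover_planted_shifts(self, seed):
        """Planted 3' displacements of random size are recovered exactly."""
        rng = np.random.default_rng(700 + seed)
        cds, up, down, ref, iv = self._make_pair(rng)
        k = int(rng.integers(1, 30))
        cleared = "CAA" + "".join(_nonstop(rng) for _ in range(k - 1))
        alt_core = up + cds[:-3] + cleared + "TAA" + down[3 * k + 3 :]
        alt = CircularSeq("alt", alt_core, is_circular=False)
        shifts = detect_boundary_shift(GeneModel("g", [iv]), ref, alt)
        three = [s for s in shifts if s.end == "3prime"]
        assert [s.shift_len for s in three] == [3 * k]


def _nonstop(rng):
    while True:
        c = random_seq(rng, 3)
        if c not in STOP_CODONS:
            return c


def _brute_force_orfs(g: CircularSeq, min_orf_len: int):
    """Independent six-frame scanner (first ATG after each stop, per frame)."""
    L = g.length
    out = set()
    for strand in "+-":
        base = g.seq if strand == "+" else revcomp(g.seq)
        work = base * 2 if g.is_circular else base
        for frame in range(3):
            start = None
            for p in range(frame, len(work) - 2, 3):
                codon = work[p : p + 3]
                if codon in STOP_CODONS:
                    if start is not None:
                        length = p + 3 - start
                        if length >= min_orf_len and start < L and length <= L:
                            out.add((strand, (p + 3) % L, length))
                    start = None
                elif codon == "ATG" and start is None:
                    start = p
    # longest per (strand, stop)
    best = {}
    for strand, stop, length in out:
        key = (strand, stop)
        if key not in best or length > best[key]:
            best[key] = length
    return {(s, st, ln) for (s, st), ln in best.items()}


class TestFindOrfs:
    def test_planted_minimal_orf(self):
        rng = np.random.default_rng(67)
        orf = "ATG" + "AAA" * 33 + "TAA"
        g = CircularSeq("g", random_seq(rng, 497) + "TAA" + orf
                        + random_seq(rng, 500), is_circular=False)
        found = [o for o in find_orfs(g, min_orf_len=100)
                 if o.length == 105 and o.iv.start == 501]
        assert len(found) == 1
        assert found[0].protein == "M" + "K" * 33

    def test_orf_across_origin(self):
        rng = np.random.default_rng(68)
        orf = "ATG" + "GCA" * 40 + "TAA"
        ring = random_seq(rng, 2000 - 3) + "TAA" + orf
        # rotate so the ORF crosses the origin
        rot = ring[-60:] + ring[:-60]
        g = CircularSeq("g", rot, is_circular=True)
        hits = [o for o in find_orfs(g, min_orf_len=120) if o.length == 126]
        assert len(hits) == 1
        assert hits[0].iv.wraps

    def test_reverse_strand_protein(self):
        rng = np.random.default_rng(69)
        orf = "ATG" + "TGG" * 50 + "TAA"
        g = CircularSeq("g", random_seq(rng, 800) + revcomp("TAA" + orf)
                        + random_seq(rng, 800), is_circular=False)
        hits = [o for o in find_orfs(g, min_orf_len=150) if o.strand == "-"
                and o.length == 156]
        assert len(hits) == 1
        assert hits[0].protein == "M" + "W" * 50

    @pytest.mark.parametrize("min_len", [60, 150, 300])
    def test_equals_brute_force_scanner(self, min_len):
        rng = np.random.default_rng(70)
        for is_circ in (False, True):
            g = CircularSeq("g", random_seq(rng, 9000), is_circular=is_circ)
            L = g.length
            got = set()
            for o in find_orfs(g, min_len):
                if o.strand == "+":
                    stop_end = o.iv.end % L
                else:
                    stop_end = (L - (o.iv.start - 1)) % L
                got.add((o.strand, stop_end, o.length))
            assert got == _brute_force_orfs(g, min_len)


class TestTmSegments:
    def test_leucine_block_in_polar_context(self):
        protein = "D" * 30 + "L" * 30 + "D" * 30
        segs = predict_tm_segments(protein)
        assert len(segs) == 1
        s, e = segs[0]
        assert s < 45 < e

    def test_all_polar_none(self):
        assert predict_tm_segments("D" * 100) == []

    def test_two_blocks(self):
        protein = "D" * 20 + "L" * 25 + "D" * 40 + "L" * 25 + "D" * 20
        assert len(predict_tm_segments(protein)) == 2

    def test_nonstandard_letter_rejected(self):
        with pytest.raises(DomainError):
            predict_tm_segments("LLLLLLLLLLLLLLLLLLLB")


class TestCmsScreen:
    def test_three_criteria_ranking(self):
        from cybridmt.genes import OrfRecord

        tm_protein = "M" + "S" * 20 + "L" * 25 + "S" * 92
        polar = "M" + "S" * 137
        orfs = [
            OrfRecord("orf_cms", Interval(10_000, 10_416), "+", 417, tm_protein),
            OrfRecord("orf_shared", Interval(30_000, 30_416), "+", 417, tm_protein),
            OrfRecord("orf_no_tm", Interval(50_000, 50_416), "+", 417, polar),
        ]
        shared = {"orf_cms": "unique", "orf_shared": "shared",
                  "orf_no_tm": "unique"}
        genes = [GeneModel("atp6", [Interval(11_200, 12_000)]),
                 GeneModel("nad1", [Interval(51_000, 52_000)])]
        ranked = screen_cms_candidates(orfs, shared, genes, L=100_000,
                                       proximity=2000)
        assert ranked[0].orf_id == "orf_cms"
        assert ranked[0].criteria_met == 3
        by_id = {c.orf_id: c for c in ranked}
        assert by_id["orf_shared"].criteria_met < 3
        assert not by_id["orf_shared"].is_unique
        assert by_id["orf_no_tm"].criteria_met == 2
        assert not by_id["orf_no_tm"].has_tm

    def test_simulated_cms_orf_tops_screen(self, echo_sim):
        cfg, (recipient, comps, donor, cp, cybrid, truth) = echo_sim
        cms = truth.of_class("cms_orf")[0]
        orfs = find_orfs(cybrid, min_orf_len=300)
        planted = [o for o in orfs
                   if o.iv.start == cms.start and o.iv.end == cms.end]
        assert len(planted) == 1
        sharedness = {o.orf_id: "shared" for o in orfs}
        sharedness[planted[0].orf_id] = "unique"
        ranked = screen_cms_candidates(orfs, sharedness, truth.genes,
                                       cybrid.length)
        assert ranked[0].orf_id == planted[0].orf_id
        assert ranked[0].criteria_met == 3
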