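"""Unique-region calling, plastid-segment detection and ORF sharedness."""

import numpy as np
import pytest

from cybridmt.comparative import (
    call_unique_regions, classify_orf_sharedness, cp_fraction,
    find_cp_segments, unique_fraction,
)
from cybridmt.genes import OrfRecord, find_orfs
from cybridmt.genomes import CircularSeq, Interval, coverage_mask, extract
from cybridmt.localalign import find_local_matches
from cybridmt.simulate import score_recovery

from conftest import mutate, random_seq


class TestUniqueRegions:
    def test_focal_in_comparators_empty(self):
        rng = np.random.default_rng(80)
        f = CircularSeq("f", random_seq(rng, 30_000))
        assert call_unique_regions(f, [f]) == []

    def test_requires_comparator(self):
        rng = np.random.default_rng(81)
        f = CircularSeq("f", random_seq(rng, 1000))
        with pytest.raises(ValueError):
            call_unique_regions(f, [])

    def test_insert_absent_from_one_comparator_not_unique(self):
        """Unique means missing from EVERY comparator."""
        rng = np.random.default_rng(82)
        backbone = random_seq(rng, 30_000)
        insert = random_seq(rng, 2000)
        f = CircularSeq("f", backbone[:15_000] + insert + backbone[15_000:])
        with_insert = CircularSeq("c1", backbone[:10_000] + insert
                                  + backbone[10_000:])
        without = CircularSeq("c2", backbone)
        assert call_unique_regions(f, [with_insert, without]) == []
        regs = call_unique_regions(f, [without])
        assert len(regs) == 1
        assert abs(regs[0].length - 2000) <= 60

    def test_unique_disjoint_from_coverage_by_position_oracle(self):
        """Per-position check: no unique position is covered by any match."""
        rng = np.random.default_rng(83)
        backbone = random_seq(rng, 20_000)
        f = CircularSeq("f", backbone[:8000] + random_seq(rng, 1500)
                        + backbone[8000:])
        comp = CircularSeq("c", mutate(rng, backbone, 100))
        regs = call_unique_regions(f, [comp])
        matches = find_local_matches(f, comp, min_len=50, min_identity=0.70)
        covered = coverage_mask([m.q_iv for m in matches], f.length)
        unique_mask = coverage_mask([r.iv for r in regs], f.length)
        assert not (covered & unique_mask).any()

    def test_adding_comparator_never_enlarges_unique(self, small_sim):
        cfg, (recipient, comps, donor, cp, cybrid, truth) = small_sim
        r1 = call_unique_regions(cybrid, comps[:1])
        r2 = call_unique_regions(cybrid, comps[:2])
        m1 = coverage_mask([r.iv for r in r1], cybrid.length)
        m2 = coverage_mask([r.iv for r in r2], cybrid.length)
        assert not (m2 & ~m1).any()
        assert unique_fraction(r2, cybrid.length) \
            <= unique_fraction(r1, cybrid.length) + 1e-12

    def test_simulated_donor_segments_recovered(self, small_sim):
        cfg, (recipient, comps, donor, cp, cybrid, truth) = small_sim
        regs = call_unique_regions(cybrid, comps)
        rep = score_recovery(
            [r.iv for r in regs],
            [Interval(f.start, f.end) for f in truth.of_class("donor")],
            cybrid.length, boundary_tol=100,
        )
        assert rep.recall == 1.0
        assert rep.precision == 1.0


class TestCpSegments:
    def test_planted_fragments_recovered(self, small_sim):
        cfg, (recipient, comps, donor, cp, cybrid, truth) = small_sim
        segs = find_cp_segments(cybrid, cp)
        truth_cp = truth.of_class("cp")
        assert len(segs) == len(truth_cp)
        rep = score_recovery(
            [s.iv for s in segs],
            [Interval(f.start, f.end) for f in truth_cp],
            cybrid.length, boundary_tol=50,
        )
        assert rep.recall == 1.0
        # labels ordered by length descending
        lengths = [s.length for s in segs]
        assert lengths == sorted(lengths, reverse=True)

    def test_cp_coordinates_verify(self, small_sim):
        """Reported plastid-side intervals really contain the mt sequence."""
        cfg, (recipient, comps, donor, cpg, cybrid, truth) = small_sim
        for s in find_cp_segments(cybrid, cpg):
            mt_seq = extract(cybrid, s.iv)
            cp_seq = extract(
                cpg, Interval(s.cp_iv.start, s.cp_iv.end,
                              "-" if s.iv.strand == "-" else "+"))
            from cybridmt.localalign import align_pair

            if len(mt_seq) <= 20_000:
                r = align_pair(mt_seq, cp_seq)
                assert r.identity >= 0.95 or align_pair(
                    mt_seq, extract(cpg, Interval(s.cp_iv.start, s.cp_iv.end,
                                                  "-"))).identity >= 0.95

    def test_random_cp_no_segments(self):
        rng = np.random.default_rng(85)
        mt = CircularSeq("mt", random_seq(rng, 50_000))
        cp = CircularSeq("cp", random_seq(rng, 30_000))
        assert find_cp_segments(mt, cp) == []

    def test_94_percent_fragment_excluded_at_95(self):
        rng = np.random.default_rng(86)
        frag = random_seq(rng, 1000)
        mt = CircularSeq("mt", random_seq(rng, 10_000) + mutate(rng, frag, 60)
                         + random_seq(rng, 10_000))
        cp = CircularSeq("cp", random_seq(rng, 5000) + frag
                         + random_seq(rng, 5000))
        assert find_cp_segments(mt, cp, min_identity=0.95) == []
        assert len(find_cp_segments(mt, cp, min_identity=0.90)) == 1


class TestOrfSharedness:
    def _genomes(self, rng):
        from cybridmt.simulate import _random_cds

        backbone = random_seq(rng, 30_000)
        orf_shared = _random_cds(rng, 122)
        orf_half = _random_cds(rng, 122)
        orf_unique = _random_cds(rng, 122)
        focal_seq = (backbone[:5000] + "TAA" + orf_shared + backbone[5000:10_000]
                     + "TAA" + orf_half + backbone[10_000:15_000]
                     + "TAA" + orf_unique + backbone[15_000:])
        focal = CircularSeq("f", focal_seq)
        comp_seq = (random_seq(rng, 8000) + orf_shared
                    + random_seq(rng, 4000) + orf_half[: len(orf_half) // 2]
                    + random_seq(rng, 8000))
        comp = CircularSeq("c", comp_seq)
        return focal, comp, orf_shared, orf_half, orf_unique

    def test_shared_partial_unique(self):
        rng = np.random.default_rng(87)
        focal, comp, s, h, u = self._genomes(rng)
        orfs = [o for o in find_orfs(focal, min_orf_len=300)
                if o.length == len(s) and o.strand == "+"]
        assert len(orfs) == 3
        labels = classify_orf_sharedness(focal, orfs, [comp])
        by_start = sorted(orfs, key=lambda o: o.iv.start)
        assert labels[by_start[0].orf_id] == "shared"
        assert labels[by_start[1].orf_id] == "partial"
        assert labels[by_start[2].orf_id] == "unique"

    def test_unique_orf_flagged_in_unique_region(self, small_sim):
        """The planted donor-borne ORF is unique and overlaps a called
        unique region."""
        cfg, (recipient, comps, donor, cp, cybrid, truth) = small_sim
        cms = truth.of_class("cms_orf")[0]
        orfs = [o for o in find_orfs(cybrid, 300)
                if o.iv.start == cms.start and o.iv.end == cms.end]
        assert len(orfs) == 1
        labels = classify_orf_sharedness(cybrid, orfs, comps)
        assert labels[orfs[0].orf_id] == "unique"
        regs = call_unique_regions(cybrid, comps)
        from cybridmt.comparative import attach_orfs

        annotated = attach_orfs(regs, orfs, cybrid.length)
        assert any(orfs[0].orf_id in r.orfs_contained for r in annotated)
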