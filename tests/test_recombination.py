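"""Intramolecular recombination models: subgenomic circles, inverted
isomers, and repeat-mediated junction explanations."""

import numpy as np
import pytest

from cybridmt.genomes import CircularSeq, DomainError, Interval, extract
from cybridmt.recombination import (
    circles_equal, explain_junctions_by_repeats, predict_inverted_isomer,
    predict_subgenomic_circles, subcircle_sequence,
)
from cybridmt.repeats import RepeatPair, RepeatSet
from cybridmt.synteny import detect_syntenic_regions

from conftest import random_seq


def _pair(s1, e1, s2, e2, kind="direct"):
    return RepeatPair(Interval(s1, e1), Interval(s2, e2), kind, 1.0, e1 - s1 + 1)


class TestSubgenomicCircles:
    def test_published_arithmetic(self):
        """Direct repeat copies 56,610 bp apart on a 258,473 bp master circle
        split it into 56,610 and 201,863 bp subcircles."""
        rng = np.random.default_rng(40)
        master = CircularSeq("m", random_seq(rng, 258_473))
        pair = _pair(10_001, 19_731, 66_611, 76_341)
        c1, c2 = predict_subgenomic_circles(master, pair)
        assert {c1.size, c2.size} == {56_610, 201_863}
        assert c1.size + c2.size == master.length

    def test_symmetric_split(self):
        rng = np.random.default_rng(41)
        master = CircularSeq("m", random_seq(rng, 100))
        c1, c2 = predict_subgenomic_circles(master, _pair(1, 10, 51, 60))
        assert (c1.size, c2.size) == (50, 50)

    def test_random_instances_match_position_list_oracle(self):
        """Sizes equal a brute force that literally cuts the position list."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            L = int(rng.integers(200, 5000))
            rep = int(rng.integers(5, 40))
            s1 = int(rng.integers(1, L - 2 * rep))
            gap = int(rng.integers(rep + 1, L - s1 - rep))
            s2 = s1 + gap
            master = CircularSeq("m", random_seq(rng, L))
            c1, c2 = predict_subgenomic_circles(
                master, _pair(s1, s1 + rep - 1, s2, s2 + rep - 1))
            positions = list(range(1, L + 1))
            arc1 = positions[s1 - 1 : s2 - 1]
            arc2 = positions[s2 - 1 :] + positions[: s1 - 1]
            assert (c1.size, c2.size) == (len(arc1), len(arc2))
            assert c1.size + c2.size == L

    def test_sequences_reassemble_to_master(self):
        rng = np.random.default_rng(43)
        master = CircularSeq("m", random_seq(rng, 4000))
        c1, c2 = predict_subgenomic_circles(master, _pair(301, 400, 1801, 1900))
        s1 = subcircle_sequence(master, c1)
        s2 = subcircle_sequence(master, c2)
        assert s1.length + s2.length == master.length
        rejoined = CircularSeq("r", s1.seq + s2.seq)
        assert circles_equal(rejoined, master)

    def test_each_subcircle_contains_one_repeat_copy(self):
        rng = np.random.default_rng(44)
        master = CircularSeq("m", random_seq(rng, 5000))
        pair = _pair(501, 700, 3001, 3200)
        c1, c2 = predict_subgenomic_circles(master, pair)
        copy1 = extract(master, pair.iv1)
        copy2 = extract(master, pair.iv2)
        assert copy1 in subcircle_sequence(master, c1).seq
        assert copy2 in subcircle_sequence(master, c2).seq

    def test_inverted_pair_rejected(self):
        rng = np.random.default_rng(45)
        master = CircularSeq("m", random_seq(rng, 1000))
        with pytest.raises(DomainError):
            predict_subgenomic_circles(master, _pair(1, 50, 501, 550, "inverted"))

    def test_linear_genome_rejected(self):
        rng = np.random.default_rng(46)
        g = CircularSeq("m", random_seq(rng, 1000), is_circular=False)
        with pytest.raises(DomainError):
            predict_subgenomic_circles(g, _pair(1, 50, 501, 550))


class TestInvertedIsomer:
    def test_involution(self):
        rng = np.random.default_rng(47)
        master = CircularSeq("m", random_seq(rng, 3000))
        pair = _pair(201, 300, 2001, 2100, "inverted")
        once = predict_inverted_isomer(master, pair)
        twice = predict_inverted_isomer(once, pair)
        assert once.length == master.length
        assert once.seq != master.seq
        assert twice.seq == master.seq

    def test_gene_in_flipped_arc_changes_strand(self):
        rng = np.random.default_rng(48)
        gene = "ATG" + "CAT" * 40 + "TAA"
        seq = random_seq(rng, 1000) + gene + random_seq(rng, 1000)
        master = CircularSeq("m", seq)
        pair = _pair(1, 50, len(seq) - 49, len(seq), "inverted")
        iso = predict_inverted_isomer(master, pair)
        assert gene not in iso.seq[50 : len(seq) - 50]
        from cybridmt.genomes import revcomp

        assert revcomp(gene) in iso.seq

    def test_zero_length_arc_identity(self):
        rng = np.random.default_rng(49)
        master = CircularSeq("m", random_seq(rng, 500))
        pair = _pair(101, 150, 151, 200, "inverted")
        assert predict_inverted_isomer(master, pair).seq == master.seq

    def test_direct_pair_rejected(self):
        rng = np.random.default_rng(50)
        master = CircularSeq("m", random_seq(rng, 500))
        with pytest.raises(DomainError):
            predict_inverted_isomer(master, _pair(1, 50, 301, 350))


class TestJunctionExplanations:
    def test_identical_genomes_no_junctions(self):
        rng = np.random.default_rng(51)
        s = random_seq(rng, 60_000)
        a = CircularSeq("A", s, is_circular=False)
        b = CircularSeq("B", s, is_circular=False)
        m = detect_syntenic_regions(a, b)
        rs = RepeatSet()
        assert explain_junctions_by_repeats(m, rs) == []

    def test_mediated_swap_found_in_simulation(self, echo_sim):
        """Junctions created by the planted mediator repeats are explained by
        those repeats with small offsets."""
        cfg, (recipient, comps, donor, cp, cybrid, truth) = echo_sim
        from cybridmt.repeats import detect_repeats

        m = detect_syntenic_regions(cybrid, recipient)
        rs = detect_repeats(cybrid)
        explanations = explain_junctions_by_repeats(m, rs)
        plausible = [e for e in explanations if e.plausible]
        mediators = [f for f in truth.of_class("short_repeat")
                     if "mediator" in f.info]
        assert mediators
        for med in mediators:
            hits = [
                e for e in plausible
                if e.repeat is not None
                and abs(e.repeat.iv1.start - med.start) <= 30
                and abs(e.repeat.iv2.start - med.mate_start) <= 30
            ]
            assert hits, f"mediator at {med.start}/{med.mate_start} unexplained"
            assert all(max(e.offsets) <= 500 for e in hits)

    def test_unmediated_rearrangement_reported_without_explanation(self):
        """A block swap with no repeat near the breakpoints yields junctions
        whose best explanation is not plausible."""
        rng = np.random.default_rng(52)
        s = random_seq(rng, 60_000)
        b_seq = s[30_000:] + s[:30_000][::-1].translate(
            str.maketrans("ACGT", "TGCA"))
        a = CircularSeq("A", s, is_circular=False)
        b = CircularSeq("B", b_seq, is_circular=False)
        m = detect_syntenic_regions(a, b)
        explanations = explain_junctions_by_repeats(m, RepeatSet())
        junctions = {e.junction for e in explanations}
        assert junctions  # the rearrangement is visible
        assert not any(e.plausible for e in explanations)
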