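"""Chromosome event algebra, script replay and merge-timing inference."""

from collections import Counter

import pytest

from paleoploid.karyotype import (AncestralSegment, Chromosome, EventScript,
                                  Karyotype, KaryotypeEvent,
                                  ancestral_karyotype, apply_event,
                                  combination_counts, correspondence_profile,
                                  infer_merge_timing,
                                  load_packaged_trajectory, parse_event,
                                  replay_script, timing_label_apiaceae)


@pytest.fixture
def k7():
    return ancestral_karyotype([f"E{i}" for i in range(1, 8)], 100, "E")


class TestEvents:
    def test_wgt_triples_chromosome_count(self, k7):
        out = apply_event(k7, KaryotypeEvent("WGT"))
        assert out.n_chromosomes == 21
        assert out.content() == Counter({k: 3 * v
                                         for k, v in k7.content().items()})

    def test_wgd_doubles(self, k7):
        out = apply_event(k7, KaryotypeEvent("WGD"))
        assert out.n_chromosomes == 14

    def test_ej_conserves_content_and_reduces_count_after_satloss(self, k7):
        ej = KaryotypeEvent("EJ", operands=("E1", "E2"), products=("F1", "S1"))
        out = apply_event(k7, ej)
        assert out.n_chromosomes == 6  # satellite excluded from the count
        assert out.n_satellites == 1
        assert out.content() == k7.content()
        out2 = apply_event(out, KaryotypeEvent("LOSS", operands=("S1",)))
        assert out2.n_chromosomes == 6 and out2.n_satellites == 0

    def test_loss_of_non_satellite_rejected(self, k7):
        with pytest.raises(ValueError, match="satellite"):
            apply_event(k7, KaryotypeEvent("LOSS", operands=("E1",)))

    def test_inversion_is_involution(self, k7):
        inv = KaryotypeEvent("INV", operands=("E3",), span=(10, 60))
        once = apply_event(k7, inv)
        assert once["E3"].segments != k7["E3"].segments
        twice = apply_event(once, inv)
        assert twice["E3"].segments == k7["E3"].segments

    def test_crossover_swaps_distal_arms(self, k7):
        x = KaryotypeEvent("X", operands=("E1", "E2"), breakpoints=(30, 70),
                           products=("N1", "N2"))
        out = apply_event(k7, x)
        assert len(out["N1"]) == 30 + 30  # E1[:30] + E2[70:]
        assert len(out["N2"]) == 70 + 70
        assert out.content() == k7.content()

    def test_nested_fusion_inserts_whole_chromosome(self, k7):
        ncf = KaryotypeEvent("NCF", operands=("E1", "E2"), breakpoints=(40,),
                             products=("N", "S1"))
        out = apply_event(k7, ncf)
        segs = out["N"].segments
        assert [s.source for s in segs] == ["E2", "E1", "E2"]
        assert len(out["N"]) == 200
        assert out.content() == k7.content()

    def test_breakpoint_out_of_range_rejected(self, k7):
        x = KaryotypeEvent("X", operands=("E1", "E2"), breakpoints=(500, 10),
                           products=("a", "b"))
        with pytest.raises(ValueError, match="breakpoint"):
            apply_event(k7, x)

    def test_unknown_operand_rejected(self, k7):
        with pytest.raises(KeyError):
            apply_event(k7, KaryotypeEvent("EJ", operands=("E1", "nope"),
                                           products=("a", "S")))


class TestScript:
    def test_parse_roundtrip(self):
        text = ("NODE E\nWGD\nX c1a@12 c2a@30 -> d1 d2\n"
                "EJ c3a c4a -> c5 +S1\nNCF c5 d1@5 -> c6 +S2\n"
                "INV c6 4..9\nLOSS S1\nREN c6 z1\nNODE P\n")
        script = EventScript.parse(text)
        assert EventScript.parse(script.dump()).dump() == script.dump()
        assert script.checkpoints == ["E", "P"]

    def test_empty_script_single_snapshot(self, k7):
        snaps = replay_script(k7, EventScript([]))
        assert list(snaps) == ["E"]
        assert snaps["E"].content() == k7.content()

    def test_parse_error_carries_line_number(self):
        with pytest.raises(ValueError, match="line 2"):
            EventScript.parse("WGD\nFROB x y\n")

    def test_replay_failure_names_event(self, k7):
        script = EventScript.parse("EJ E1 missing -> F +S\n")
        with pytest.raises(RuntimeError, match="event 1"):
            replay_script(k7, script)

    def test_packaged_trajectory_node_counts(self):
        """The shipped trajectory visits 7 -> 21 -> 8 -> 10 -> 11 chromosomes
        at the E, H, P, Q, R nodes."""
        init, script = load_packaged_trajectory()
        snaps = replay_script(init, script)
        counts = {node: k.n_chromosomes for node, k in snaps.items()}
        assert counts == {"E": 7, "H": 21, "P": 8, "Q": 10, "R": 11}

    def test_packaged_trajectory_conserves_content(self):
        init, script = load_packaged_trajectory()
        snaps = replay_script(init, script)
        base = init.content()
        # 3x from the triplication, then 2x and 2x from the duplications;
        # satellites are gene-free so losses remove no content
        assert snaps["H"].content() == Counter({k: 3 * v for k, v in base.items()})
        assert snaps["R"].content() == Counter({k: 12 * v for k, v in base.items()})

    def test_random_script_multiset_accounting(self, rng):
        """Random EJ/X/INV/WGD sequences conserve segment content (modulo
        polyploidy multiplication)."""
        k = ancestral_karyotype(["c1", "c2", "c3", "c4"], 50, "n0")
        expected = Counter(k.content())
        mult = 1
        for step in range(30):
            kinds = ["EJ", "X", "INV"]
            non_sat = [c.id for c in k.chromosomes.values()
                       if not c.is_satellite and len(c) > 2]
            if len(non_sat) < 2:
                break
            kind = kinds[int(rng.integers(0, len(kinds)))]
            if kind == "EJ":
                a, b = rng.choice(non_sat, size=2, replace=False)
                e = KaryotypeEvent("EJ", operands=(a, b),
                                   products=(f"f{step}", f"S{step}"))
            elif kind == "X":
                a, b = rng.choice(non_sat, size=2, replace=False)
                pa = int(rng.integers(1, len(k[a])))
                pb = int(rng.integers(1, len(k[b])))
                e = KaryotypeEvent("X", operands=(a, b), breakpoints=(pa, pb),
                                   products=(f"x{step}a", f"x{step}b"))
            else:
                a = non_sat[int(rng.integers(0, len(non_sat)))]
                lo = int(rng.integers(0, len(k[a]) - 1))
                hi = int(rng.integers(lo + 1, len(k[a]) + 1))
                e = KaryotypeEvent("INV", operands=(a,), span=(lo, hi))
            k = apply_event(k, e)
            assert k.content() == Counter({key: mult * v
                                           for key, v in expected.items()})


class TestCorrespondence:
    def test_single_block_profile(self):
        from paleoploid.collinearity import Anchor, CollinearBlock

        b = CollinearBlock("ref", "tgt", "A", "X",
                           [Anchor("r0", "t0", 0, 0)], "parallel")
        prof = correspondence_profile([b], min_anchors=1)
        assert prof == {"X": {"A"}}
        assert combination_counts(prof, size=1) == {frozenset({"A"}): 1}

    def test_hand_dot_plot_tabulation(self):
        from paleoploid.collinearity import Anchor, CollinearBlock

        def blk(ref_chrom, tgt_chrom, n):
            return CollinearBlock("ref", "tgt", ref_chrom, tgt_chrom,
                                  [Anchor(f"r{i}", f"t{i}", i, i)
                                   for i in range(n)], "parallel")

        blocks = [blk("A", "X", 5), blk("B", "X", 5), blk("A", "Y", 5),
                  blk("B", "Y", 5), blk("A", "Z", 5), blk("C", "Z", 2)]
        prof = correspondence_profile(blocks, min_anchors=3)
        assert prof == {"X": {"A", "B"}, "Y": {"A", "B"}, "Z": {"A"}}
        cc = combination_counts(prof)
        assert cc == {frozenset({"A", "B"}): 2}

    def test_timing_thresholds(self):
        counts = {frozenset({"A", "B"}): 4, frozenset({"C", "D"}): 2,
                  frozenset({"E", "F"}): 1, frozenset({"G", "H"}): 3}
        timing = infer_merge_timing(counts, ploidy_series=(2, 2))
        assert timing_label_apiaceae(timing[frozenset({"A", "B"})]) == "pre-ω"
        assert timing_label_apiaceae(timing[frozenset({"C", "D"})]) == "post-ω/pre-α"
        assert timing_label_apiaceae(timing[frozenset({"E", "F"})]) == "post-α"
        assert timing[frozenset({"G", "H"})] == "ambiguous"

    def test_timing_generalizes_to_other_ploidy_series(self):
        counts = {frozenset({"A", "B"}): 6, frozenset({"C", "D"}): 2}
        timing = infer_merge_timing(counts, ploidy_series=(3, 2))
        assert timing[frozenset({"A", "B"})] == "pre-first"
        assert timing[frozenset({"C", "D"})] == "between-1"


class TestSegmentGeometry:
    def test_split_inside_reversed_segment(self):
        c = Chromosome("c", [AncestralSegment("E1", 0, 10, "-"),
                             AncestralSegment("E2", 0, 10, "+")])
        left, right = c.split(4)
        # the first 4 units of a reversed E1 segment are its last 4 positions
        assert left == [AncestralSegment("E1", 6, 10, "-")]
        assert right[0] == AncestralSegment("E1", 0, 6, "-")
        assert sum(s.end - s.start for s in left + right) == 20

    def test_split_at_boundary(self):
        c = Chromosome("c", [AncestralSegment("E1", 0, 10),
                             AncestralSegment("E2", 0, 10)])
        left, right = c.split(10)
        assert [s.source for s in left] == ["E1"]
        assert [s.source for s in right] == ["E2"]
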