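import numpy as np
import pytest

from paleohexkit.karyotype import (CP_COLINEAR, CP_INVERTED, CP_UNLINKED,
                                   Karyotype, KaryotypeError,
                                   RearrangementEvent, RegionCopy, Segment,
                                   apply_event, chromosome_count_after,
                                   connection_patterns, expected_chromosomes,
                                   infer_shared_fusions, junctions,
                                   read_karyotype,
                                   reconstruct_ancestral_karyotype,
                                   two_step_inference, write_karyotype)


def kary(*chroms, name="k", strict=True):
    return Karyotype(name, [[Segment(s.lstrip("-"),
                                     "-" if s.startswith("-") else "+")
                             for s in chrom] for chrom in chroms],
                     strict=strict)


class TestApplyEvent:
    def test_eej_concatenates(self):
        k = kary(["A1", "A2"], ["B1"])
        out = apply_event(k, RearrangementEvent("EEJ", (0, 1)))
        assert out.n_chromosomes == 1
        assert [s.id for s in out.chromosomes[0]] == ["A1", "A2", "B1"]

    def test_eej_flip(self):
        k = kary(["A1"], ["B1", "B2"])
        out = apply_event(k, RearrangementEvent("EEJ", (0, 1, True)))
        assert [(s.id, s.orientation) for s in out.chromosomes[0]] == \
            [("A1", "+"), ("B2", "-"), ("B1", "-")]

    def test_ncf_inserts_whole_chromosome(self):
        k = kary(["A1", "A2"], ["B1"])
        out = apply_event(k, RearrangementEvent("NCF", (0, 1, 1)))
        assert out.n_chromosomes == 1
        assert [s.id for s in out.chromosomes[0]] == ["A1", "B1", "A2"]

    def test_ncf_terminal_position_rejected(self):
        k = kary(["A1", "A2"], ["B1"])
        for pos in (0, 2):
            with pytest.raises(KaryotypeError, match="EEJ"):
                apply_event(k, RearrangementEvent("NCF", (0, 1, pos)))

    def test_rct_swaps_tails_conserving_segments(self):
        k = kary(["A1", "A2", "A3"], ["B1", "B2"])
        out = apply_event(k, RearrangementEvent("RCT", (0, 1, 1, 1)))
        assert out.n_chromosomes == 2
        assert [s.id for s in out.chromosomes[0]] == ["A1", "B2"]
        assert [s.id for s in out.chromosomes[1]] == ["B1", "A2", "A3"]
        assert out.segment_ids() == k.segment_ids()

    def test_nct_moves_segment_run(self):
        k = kary(["A1", "A2", "A3"], ["B1"])
        out = apply_event(k, RearrangementEvent("NCT", (0, 1, 2, 1, 1)))
        assert [s.id for s in out.chromosomes[0]] == ["A1", "A3"]
        assert [s.id for s in out.chromosomes[1]] == ["B1", "A2"]

    def test_nct_whole_chromosome_rejected(self):
        k = kary(["A1", "A2"], ["B1"])
        with pytest.raises(KaryotypeError, match="fusion"):
            apply_event(k, RearrangementEvent("NCT", (0, 0, 2, 1, 0)))

    def test_nct_run_crossing_ends_rejected(self):
        k = kary(["A1", "A2"], ["B1"])
        with pytest.raises(KaryotypeError):
            apply_event(k, RearrangementEvent("NCT", (0, 1, 3, 1, 0)))

    def test_fission_splits(self):
        k = kary(["A1", "A2"])
        out = apply_event(k, RearrangementEvent("FISSION", (0, 1)))
        assert out.n_chromosomes == 2

    def test_wgt_triplicates_with_suffixed_ids(self):
        k = kary(*[[f"A{i}"] for i in range(1, 8)])
        out = apply_event(k, RearrangementEvent("WGT"))
        assert out.n_chromosomes == 21
        assert len(out.segment_ids()) == 21

    def test_segment_multiset_conserved_outside_wgd(self):
        k = kary(["A1", "A2", "A3"], ["B1", "B2"], ["C1"])
        for ev in (RearrangementEvent("EEJ", (0, 1)),
                   RearrangementEvent("NCF", (0, 2, 1)),
                   RearrangementEvent("RCT", (0, 1, 1, 1)),
                   RearrangementEvent("NCT", (0, 0, 1, 1, 0)),
                   RearrangementEvent("FISSION", (0, 2))):
            assert apply_event(k, ev).segment_ids() == k.segment_ids()


class TestChromosomeCount:
    @pytest.mark.parametrize("initial,events,expected", [
        (7, ["WGT"], 21),
        (21, [("EEJ", 11), ("NCF", 1), ("RCT", 2), ("NCT", 3)], 9),
        (9, ["WGT"], 27),
        (27, [("EEJ", 10), ("NCF", 2), ("RCT", 2), ("NCT", 2)], 15),
        (15, [("EEJ", 5), ("NCF", 1), ("RCT", 1), ("NCT", 4)], 9),
        (15, ["WGD", ("EEJ", 8), ("NCF", 5), ("RCT", 2), ("NCT", 27)], 17),
    ])
    def test_published_trajectories(self, initial, events, expected):
        assert chromosome_count_after(initial, events) == expected

    def test_count_below_one_rejected(self):
        with pytest.raises(KaryotypeError):
            chromosome_count_after(2, [("EEJ", 2)])

    def test_expected_chromosomes_without_fusion(self):
        assert expected_chromosomes(7, ["WGT", "WGT"]) == 63
        assert expected_chromosomes(7, []) == 7
        assert expected_chromosomes(9, ["WGT"]) == 27

    def test_agrees_with_stepwise_application(self, rng):
        """1000 random event sequences: the arithmetic matches actually
        applying the events."""
        for _ in range(1000):
            n0 = int(rng.integers(2, 6))
            k = Karyotype("k", [[Segment(f"S{i}.{j}") for j in range(3)]
                                for i in range(n0)])
            events = []
            for _ in range(int(rng.integers(0, 6))):
                kind = ["EEJ", "NCF", "RCT", "NCT", "FISSION", "WGD"][
                    int(rng.integers(0, 6))]
                n = k.n_chromosomes
                try:
                    if kind == "EEJ" and n >= 2:
                        i, j = map(int, rng.choice(n, 2, replace=False))
                        ev = RearrangementEvent("EEJ", (i, j))
                    elif kind == "NCF" and n >= 2:
                        i, j = map(int, rng.choice(n, 2, replace=False))
                        if len(k.chromosomes[i]) < 2:
                            continue
                        ev = RearrangementEvent("NCF", (i, j, 1))
                    elif kind == "RCT" and n >= 2:
                        i, j = map(int, rng.choice(n, 2, replace=False))
                        ev = RearrangementEvent(
                            "RCT", (i, 1, j, 1))
                        if len(k.chromosomes[i]) < 2 or \
                                len(k.chromosomes[j]) < 2:
                            continue
                    elif kind == "NCT" and n >= 2:
                        i, j = map(int, rng.choice(n, 2, replace=False))
                        if len(k.chromosomes[i]) < 2:
                            continue
                        ev = RearrangementEvent("NCT", (i, 0, 1, j, 0))
                    elif kind == "FISSION":
                        i = int(rng.integers(0, n))
                        if len(k.chromosomes[i]) < 2:
                            continue
                        ev = RearrangementEvent("FISSION", (i, 1))
                    elif kind == "WGD":
                        ev = RearrangementEvent("WGD")
                    else:
                        continue
                    k = apply_event(k, ev)
                    events.append(ev)
                except KaryotypeError:
                    continue
            assert chromosome_count_after(n0, events) == k.n_chromosomes


class TestJunctions:
    def test_flip_invariance(self):
        k1 = kary(["A1", "A2", "-B1"])
        k2 = kary(["B1", "-A2", "-A1"])  # same chromosome read backwards
        assert junctions(k1) == junctions(k2)

    def test_shared_junction_assigned_to_ancestor(self):
        d1 = kary(["C4", "A5"], ["B2"], name="d1", strict=False)
        d2 = kary(["C4", "A5"], ["B2"], name="d2", strict=False)
        outgroup = kary(["C4"], ["A5"], ["B2"], name="og", strict=False)
        res = infer_shared_fusions({"d1": d1, "d2": d2}, outgroup)
        from paleohexkit.karyotype import canonical_junction
        assert res.shared == {canonical_junction(Segment("C4"),
                                                 Segment("A5"))}

    def test_private_junction_not_ancestral(self):
        d1 = kary(["C4", "A5"], ["B2"], name="d1", strict=False)
        d2 = kary(["C4"], ["A5", "B2"], name="d2", strict=False)
        outgroup = kary(["C4"], ["A5"], ["B2"], name="og", strict=False)
        res = infer_shared_fusions({"d1": d1, "d2": d2}, outgroup)
        assert res.shared == set()

    def test_conflicting_orientation_flagged(self):
        d1 = kary(["C4", "A5"], name="d1", strict=False)
        d2 = kary(["C4", "-A5"], name="d2", strict=False)
        res = infer_shared_fusions(
            {"d1": d1, "d2": d2}, kary(["C4"], ["A5"], name="og",
                                       strict=False))
        assert res.shared == set()
        assert res.conflicting == [frozenset({"C4", "A5"})]


class TestReconstruction:
    def test_fully_shared_two_fusions(self):
        d1 = kary(["A", "B"], ["C", "D"], name="d1", strict=False)
        d2 = kary(["A", "B"], ["C", "D"], name="d2", strict=False)
        outgroup = kary(["A"], ["B"], ["C"], ["D"], name="og", strict=False)
        ancestor, events, warnings = reconstruct_ancestral_karyotype(
            {"d1": d1, "d2": d2}, outgroup)
        assert ancestor.n_chromosomes == 2
        assert sorted(e.kind for e in events) == ["EEJ", "EEJ"]
        assert not warnings

    def test_no_shared_junctions_leaves_outgroup_karyotype(self):
        d1 = kary(["A", "B"], ["C"], name="d1", strict=False)
        d2 = kary(["A"], ["B", "C"], name="d2", strict=False)
        outgroup = kary(["A"], ["B"], ["C"], name="og", strict=False)
        ancestor, events, _ = reconstruct_ancestral_karyotype(
            {"d1": d1, "d2": d2}, outgroup)
        assert ancestor.n_chromosomes == 3
        assert events == []

    def test_nested_fusion_detected_as_ncf(self):
        d1 = kary(["Y", "X", "Y"], name="d1", strict=False)
        d2 = kary(["Y", "X", "Y"], name="d2", strict=False)
        outgroup = kary(["X"], ["Y"], name="og", strict=False)
        ancestor, events, _ = reconstruct_ancestral_karyotype(
            {"d1": d1, "d2": d2}, outgroup)
        assert ancestor.n_chromosomes == 1
        assert [e.kind for e in events] == ["NCF"]

    def test_simulator_scenario_count_recovered(self, small_sim):
        maps = small_sim.truth.segment_maps
        base_ids = sorted(set().union(*(m.segment_ids()
                                        for m in maps.values())))
        outgroup = Karyotype("base", [[Segment(s)] for s in base_ids])
        ancestor, events, _ = reconstruct_ancestral_karyotype(maps, outgroup)
        # 4 chromosomes x 3 subgenomes, one planted shared EEJ
        assert ancestor.n_chromosomes == 11
        assert [e.kind for e in events] == ["EEJ"]
        assert {e.operands for e in events} == {("chr1.sg1", "chr2.sg1")}


class TestConnectionPatterns:
    def test_patterns(self):
        copies = [RegionCopy("lf", "c3", "c3", "-"),
                  RegionCopy("mf1", "c6", "c6", "-"),
                  RegionCopy("mf2", "c6", "c9", "+"),
                  RegionCopy("out", "v2", "v2", "+")]
        cps = connection_patterns(copies)
        assert cps == {"lf": CP_INVERTED, "mf1": CP_INVERTED,
                       "mf2": CP_UNLINKED, "out": CP_COLINEAR}

    def test_two_step_resolved(self):
        result = two_step_inference(
            {"LF": CP_INVERTED, "MF1": CP_INVERTED, "MF2": CP_COLINEAR},
            CP_COLINEAR)
        assert result.status == "resolved"
        assert set(result.first_step) == {"LF", "MF1"}
        assert result.second_step == "MF2"

    def test_all_derived_uninformative(self):
        result = two_step_inference(
            {"LF": CP_INVERTED, "MF1": CP_INVERTED, "MF2": CP_INVERTED},
            CP_COLINEAR)
        assert result.status == "uninformative"

    def test_single_derived_uninformative(self):
        result = two_step_inference(
            {"LF": CP_COLINEAR, "MF1": CP_COLINEAR, "MF2": CP_INVERTED},
            CP_COLINEAR)
        assert result.status == "uninformative"

    def test_ambiguous_outgroup(self):
        result = two_step_inference(
            {"LF": CP_INVERTED, "MF1": CP_INVERTED, "MF2": CP_COLINEAR},
            CP_UNLINKED)
        assert result.status == "uninformative(outgroup)"


def test_karyotype_text_round_trip(tmp_path):
    k = kary(["A1", "-A2"], ["B1"], name="toy")
    p = tmp_path / "k.txt"
    write_karyotype(k, p)
    back = read_karyotype(p)
    assert back.name == "toy"
    assert [[(s.id, s.orientation) for s in c] for c in back.chromosomes] == \
        [[(s.id, s.orientation) for s in c] for c in k.chromosomes]
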