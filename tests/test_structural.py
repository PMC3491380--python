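"""Structural variants: small-indel filters, mate-pair calls, inversions."""

import numpy as np
import pandas as pd
import pytest

from macseq.structural import (InversionWindow, LargeIndelCall, LibrarySpec,
                               SmallIndelThresholds, call_small_indels,
                               detect_large_indels, inversion_scan, merge_calls,
                               small_indel_profile, sv_context)

QV60 = {"c": np.full(200_000, 60, dtype=np.int16)}


def evidence(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "vtype", "length",
                                       "support", "depth"])


class TestCallSmallIndels:
    def test_length_limits(self):
        ev = evidence([
            ("c", 100, "del", 11, 10, 40),   # retained: del < 12
            ("c", 200, "del", 12, 10, 40),   # out of range
            ("c", 300, "ins", 3, 10, 40),    # retained: ins < 4
            ("c", 400, "ins", 4, 10, 40),    # out of range
        ])
        calls, tally = call_small_indels(ev, QV60)
        assert sorted(calls["pos"]) == [100, 300]
        assert tally["out_of_range"] == 2

    def test_reference_qv_boundary(self):
        qv = {"c": np.full(1000, 60, dtype=np.int16)}
        qv["c"][100] = 44
        qv["c"][200] = 45
        ev = evidence([("c", 100, "del", 2, 10, 40),
                       ("c", 200, "del", 2, 10, 40)])
        calls, tally = call_small_indels(ev, qv)
        assert calls["pos"].tolist() == [200]
        assert tally["ref_qv"] == 1

    def test_support_threshold_and_zygosity(self):
        ev = evidence([("c", 100, "del", 2, 2, 40),    # support < 3
                       ("c", 200, "del", 2, 35, 40),   # hom (frac 0.875)
                       ("c", 300, "ins", 1, 18, 40)])  # het (frac 0.45)
        calls, tally = call_small_indels(ev, QV60)
        assert tally["support"] == 1
        assert calls.set_index("pos")["zygosity"].to_dict() == {
            200: "hom", 300: "het"}


class TestSmallIndelProfile:
    def _qv_track(self, n_low, n_high):
        qv = np.concatenate([np.full(n_low, 40), np.full(n_high, 60)])
        return {"c": qv.astype(np.int16)}

    def test_no_indels_zero_rates(self):
        prof = small_indel_profile(evidence([]), self._qv_track(500, 500),
                                   pd.Series({40: 500, 60: 500}))
        assert (prof["del_rate"] == 0).all()

    def test_uniform_rate_is_flat(self):
        """Chi-square homogeneity across QV strata accepts a uniform
        simulated indel rate (alpha = 0.01)."""
        from scipy.stats import chi2_contingency

        rng = np.random.default_rng(0)
        n = 50_000
        qv = self._qv_track(n, n)
        rows = []
        for stratum, offset in ((40, 0), (60, n)):
            hits = rng.random(n) < 2e-3
            for p in np.flatnonzero(hits):
                rows.append(("c", offset + p, "del", 2, 20, 40))
        prof = small_indel_profile(evidence(rows), qv,
                                   pd.Series({40: n, 60: n}))
        by = prof.set_index("ref_qv")
        table = [[by.loc[40, "del_rate"] * n, n],
                 [by.loc[60, "del_rate"] * n, n]]
        _, p, _, _ = chi2_contingency(table, correction=False)
        assert p > 0.01

    def test_planted_low_qv_excess_detected(self):
        rng = np.random.default_rng(1)
        n = 50_000
        qv = self._qv_track(n, n)
        rows = []
        for stratum, offset, rate in ((40, 0, 6e-3), (60, n, 2e-3)):
            for p in np.flatnonzero(rng.random(n) < rate):
                rows.append(("c", offset + p, "del", 2, 20, 40))
        prof = small_indel_profile(evidence(rows), qv,
                                   pd.Series({40: n, 60: n}))
        by = prof.set_index("ref_qv")
        ratio = by.loc[40, "del_rate"] / by.loc[60, "del_rate"]
        assert abs(ratio - 3.0) < 0.9   # within 30%


LIB_A = LibrarySpec("A", 600, 800)


def pairs_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos1", "pos2", "span",
                                       "congruent", "library"])


def make_pairs(pos1, spans, library="A", congruent=True, chrom="c"):
    rows = [(chrom, p, p + s, s, congruent, library)
            for p, s in zip(pos1, spans)]
    return pairs_frame(rows)


class TestDetectLargeIndels:
    def test_inflated_spans_call_deletion_with_size(self):
        pairs = make_pairs(np.arange(1000, 1200, 20), [1000] * 10)
        calls = detect_large_indels(pairs, LIB_A)
        assert len(calls) == 1
        assert calls[0].svtype == "del"
        assert calls[0].size == pytest.approx(300)   # 1000 - midpoint 700
        assert calls[0].support == 10

    def test_in_range_spans_make_no_call(self):
        pairs = make_pairs(np.arange(1000, 1200, 20), [650] * 10)
        assert detect_large_indels(pairs, LIB_A) == []

    def test_deflated_spans_call_insertion(self):
        pairs = make_pairs(np.arange(1000, 1200, 20), [450] * 10)
        calls = detect_large_indels(pairs, LIB_A)
        assert calls[0].svtype == "ins"
        assert calls[0].size == pytest.approx(250)

    def test_min_support_respected(self):
        pairs = make_pairs([1000, 1020], [1000, 1000])
        assert detect_large_indels(pairs, LIB_A, min_support=3) == []

    def test_planted_deletion_recovered_in_simulation(self):
        from macseq.simulate import (SimulationConfig, StructuralVariant,
                                     TmrcaTract, emit_matepairs,
                                     impose_variants, simulate_reference)
        sv = StructuralVariant("c", 500_000, "del", 400)
        cfg = SimulationConfig(chrom_lengths={"c": 1_000_000}, rng_seed=21,
                               gap_density=0.0, planted_svs=(sv,))
        ref = simulate_reference(cfg)
        truth = impose_variants(ref, [TmrcaTract("c", 0, 1_000_000, 1e4)], cfg)
        pairs = emit_matepairs(ref, truth, "A", cfg, physical_coverage=40)
        calls = detect_large_indels(pairs, LIB_A)
        dels = [c for c in calls if c.svtype == "del"]
        assert len(dels) == 1
        assert abs(dels[0].size - 400) <= (800 - 600) / 2
        assert dels[0].start <= 500_000 <= dels[0].end + 400


class TestMergeCalls:
    def _call(self, start, end, svtype="del", size=300.0, support=5, lib="A"):
        return LargeIndelCall("c", start, end, svtype, size, support,
                              frozenset([lib]))

    def test_identical_calls_merge_with_both_libraries(self):
        merged = merge_calls([self._call(100, 400)],
                             [self._call(100, 400, lib="B")])
        assert len(merged) == 1
        assert merged[0].libraries == frozenset("AB")
        assert merged[0].support == 10

    def test_disjoint_calls_concatenate(self):
        merged = merge_calls([self._call(100, 400)],
                             [self._call(5000, 5300, lib="B")])
        assert len(merged) == 2

    def test_size_is_support_weighted_mean(self):
        merged = merge_calls([self._call(100, 400, size=300, support=9)],
                             [self._call(100, 400, size=400, support=1, lib="B")])
        assert merged[0].size == pytest.approx(310)

    def test_transitive_chain_matches_connected_components(self):
        """Chained overlaps merge transitively, agreeing with a
        brute-force connected-components oracle on random call sets."""
        import networkx as nx

        rng = np.random.default_rng(2)
        calls = [self._call(int(s), int(s + rng.integers(100, 300)))
                 for s in rng.integers(0, 3000, 30)]
        merged = merge_calls(calls[:15], calls[15:])
        g = nx.Graph()
        g.add_nodes_from(range(len(calls)))
        for i in range(len(calls)):
            for j in range(i + 1, len(calls)):
                a, b = calls[i], calls[j]
                ov = min(a.end, b.end) - max(a.start, b.start)
                la, lb = a.end - a.start, b.end - b.start
                if ov > 0 and ov / la >= 0.5 and ov / lb >= 0.5:
                    g.add_edge(i, j)
        assert len(merged) == nx.number_connected_components(g)
        assert sum(m.support for m in merged) == sum(c.support for c in calls)


class TestInversionScan:
    def test_no_incongruent_pairs_no_windows(self):
        pairs = make_pairs([100, 300], [700, 700])
        assert inversion_scan(pairs, {"c": 10_000}) == []

    @pytest.mark.parametrize("count,flagged", [(49, False), (50, True)])
    def test_min_count_boundary(self, count, flagged):
        pairs = make_pairs([1000 + i for i in range(count)], [700] * count,
                           congruent=False)
        windows = inversion_scan(pairs, {"c": 10_000})
        hit = [w for w in windows if w.start == 1000]
        assert hit[0].flagged is flagged

    def test_planted_inversion_flags_breakpoint_windows_only(self):
        from macseq.simulate import (SimulationConfig, StructuralVariant,
                                     TmrcaTract, emit_matepairs,
                                     impose_variants, simulate_reference)
        sv = StructuralVariant("c", 300_000, "inv", 50_000)
        cfg = SimulationConfig(chrom_lengths={"c": 1_000_000}, rng_seed=22,
                               gap_density=0.0, planted_svs=(sv,))
        ref = simulate_reference(cfg)
        truth = impose_variants(ref, [TmrcaTract("c", 0, 1_000_000, 1e4)], cfg)
        pairs = emit_matepairs(ref, truth, "A", cfg, physical_coverage=80)
        windows = inversion_scan(pairs, {"c": 1_000_000}, min_count=50)
        flagged = [w for w in windows if w.flagged]
        assert flagged, "expected flagged windows at the breakpoints"
        for w in flagged:
            near_bp = min(abs(w.start - 300_000 + 700),
                          abs(w.start - 350_000 + 700))
            assert near_bp < 1_500

    def test_clean_simulation_zero_false_calls(self, deep_sim):
        """40x mate-pair coverage with no SVs yields no large-indel calls
        and no flagged inversion windows at min_support 3."""
        from macseq.simulate import emit_matepairs
        pairs = emit_matepairs(deep_sim["ref"], deep_sim["truth"], "A",
                               deep_sim["config"], physical_coverage=40)
        assert detect_large_indels(pairs, LIB_A, min_support=3) == []
        windows = inversion_scan(pairs, {"chr1": 10_000_000})
        assert [w for w in windows if w.flagged] == []


class TestSvContext:
    def test_flags_and_tally(self):
        calls = [LargeIndelCall("c", 100, 400, "del", 300, 5, frozenset("A")),
                 LargeIndelCall("c", 5000, 5200, "del", 200, 5, frozenset("A")),
                 LargeIndelCall("c", 9000, 9100, "ins", 100, 5, frozenset("A"))]
        repeat = {"c": np.array([[150, 160]])}
        gap = {"c": np.array([[5100, 5400]])}
        flagged, tally = sv_context(calls, repeat, gap)
        assert [c.repeat_context for c in flagged] == [True, False, False]
        assert [c.gap_context for c in flagged] == [False, True, False]
        t = tally.set_index("svtype")
        assert t.loc["del", "repeat_context"] == 1
        assert t.loc["del", "gap_context"] == 1

    def test_random_calls_match_interval_oracle(self):
        rng = np.random.default_rng(3)
        calls = [LargeIndelCall("c", int(s), int(s + l), "del", float(l), 3,
                                frozenset("A"))
                 for s, l in zip(rng.integers(0, 10_000, 50),
                                 rng.integers(50, 500, 50))]
        mask = np.sort(rng.integers(0, 10_000, (20, 1)), axis=0)
        mask = np.hstack([mask, mask + rng.integers(10, 300, (20, 1))])
        flagged, _ = sv_context(calls, {"c": mask}, {})
        for c in flagged:
            want = any(c.start < e and s < c.end for s, e in mask)
            assert c.repeat_context == want
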