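"""Synthetic-data engine: reference, coalescent tracts, variants, evidence."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from macseq.simulate import (DemographicHistory, SimulationConfig,
                             StructuralVariant, TmrcaTract,
                             emit_gap_evidence, emit_matepairs, emit_pileup,
                             impose_variants, simulate_annotation,
                             simulate_reference, simulate_tmrca)


# -- reference -------------------------------------------------------------

class TestSimulateReference:
    def test_length_and_track_conservation(self):
        cfg = SimulationConfig(chrom_lengths={"c": 10_000}, rng_seed=1)
        ref = simulate_reference(cfg)
        assert len(ref.chroms["c"]) == 10_000
        assert len(ref.qv["c"]) == 10_000

    def test_qv60_fraction_close_to_target(self):
        cfg = SimulationConfig(chrom_lengths={"c": 1_000_000},
                               qv60_fraction=0.94, rng_seed=2)
        ref = simulate_reference(cfg)
        assert abs((ref.qv["c"] == 60).mean() - 0.94) < 0.01

    def test_no_gaps_when_density_zero(self):
        cfg = SimulationConfig(chrom_lengths={"c": 50_000}, gap_density=0.0,
                               rng_seed=3)
        ref = simulate_reference(cfg)
        assert "N" not in ref.chroms["c"]
        assert len(ref.gaps["c"]) == 0

    def test_gap_mask_exactly_marks_n_runs(self, small_ref):
        for chrom, seq in small_ref.chroms.items():
            arr = np.frombuffer(seq.encode(), dtype="S1") == b"N"
            from macseq.intervals import mask_array
            assert np.array_equal(arr, mask_array(small_ref.gaps[chrom], len(seq)))

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(chrom_lengths={"c": 0})

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(chrom_lengths={"c": 30_000}, rng_seed=9)
        a = simulate_reference(cfg)
        b = simulate_reference(cfg)
        assert a.chroms == b.chroms
        assert np.array_equal(a.qv["c"], b.qv["c"])
        assert np.array_equal(a.repeats["c"], b.repeats["c"])


# -- annotation ------------------------------------------------------------

class TestSimulateAnnotation:
    def test_cds_length_multiple_of_three(self, small_annotation):
        assert all(t.cds_length % 3 == 0 for t in small_annotation.transcripts)

    def test_exons_within_bounds(self, small_annotation):
        for t in small_annotation.transcripts:
            L = small_annotation.chrom_lengths[t.chrom]
            assert all(0 <= s < e <= L for s, e in t.exons)

    def test_requested_gene_count(self, small_config, small_ref):
        ann = simulate_annotation(small_config, small_ref, n_genes=17)
        assert len(ann.gene_ids) == 17


# -- coalescent tracts -----------------------------------------------------

class TestSimulateTmrca:
    def test_zero_recombination_gives_one_tract_per_chromosome(self):
        hist = DemographicHistory([(0, 5000)])
        rng = np.random.default_rng(0)
        tracts = simulate_tmrca(hist, {"a": 1000, "b": 2000}, 0.0, rng)
        assert [t.chrom for t in tracts] == ["a", "b"]
        assert tracts[0].end - tracts[0].start == 1000

    def test_sitewise_mean_tmrca_is_2n(self):
        """Genome-average TMRCA of a constant-N walk equals E[T] = 2N.

        The Monte-Carlo SE comes from splitting the genome into blocks
        (tract lengths and times are dependent, so per-tract SEs would
        be wrong).
        """
        n = 10_000
        L = 10_000_000
        hist = DemographicHistory([(0, n)])
        rng = np.random.default_rng(42)
        tracts = simulate_tmrca(hist, {"c": L}, 1e-8, rng)
        site_t = np.empty(L)
        for t in tracts:
            site_t[t.start:t.end] = t.tmrca
        blocks = site_t.reshape(100, -1).mean(axis=1)
        se = blocks.std(ddof=1) / np.sqrt(len(blocks))
        assert abs(blocks.mean() - 2 * n) < 3 * se

    @pytest.mark.parametrize("epochs", [
        [(0, 10_000)],
        [(0, 15_000), (6_000, 4_000), (20_000, 20_000)],
        [(0, 2_000), (5_000, 30_000)],
    ])
    def test_site_marginal_matches_coalescent_cdf(self, epochs):
        """Per-site TMRCA of the stationary walk follows the plain
        coalescent distribution (KS test, alpha = 0.01).

        The recombination rate is raised so that even young tracts are
        much shorter than the chromosome; otherwise end-of-chromosome
        truncation of multi-Mb tracts distorts their site share.
        """
        hist = DemographicHistory(epochs)
        rng = np.random.default_rng(7)
        tracts = simulate_tmrca(hist, {"c": 20_000_000}, 5e-7, rng)
        bounds = np.cumsum([0] + [t.end - t.start for t in tracts])
        tm = np.array([t.tmrca for t in tracts])
        sites = rng.integers(0, bounds[-1], size=1500)
        site_t = tm[np.searchsorted(bounds, sites, side="right") - 1]
        res = stats.kstest(site_t, hist.cdf)
        assert res.pvalue > 0.01

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            DemographicHistory([])

    def test_history_invariants(self):
        with pytest.raises(ValueError):
            DemographicHistory([(5, 100)])       # must start at 0
        with pytest.raises(ValueError):
            DemographicHistory([(0, 100), (0, 50)])  # strictly increasing
        with pytest.raises(ValueError):
            DemographicHistory([(0, -5)])


def test_msprime_cross_check_bottleneck_marginal():
    """Independent oracle: site TMRCA distribution of the walk matches
    msprime's pairwise coalescence times under the same history."""
    msprime = pytest.importorskip("msprime")
    epochs = [(0, 8_000), (4_000, 2_000), (12_000, 15_000)]
    hist = DemographicHistory(epochs)
    demogr = msprime.Demography()
    demogr.add_population(initial_size=8_000)
    demogr.add_population_parameters_change(time=4_000, initial_size=2_000)
    demogr.add_population_parameters_change(time=12_000, initial_size=15_000)
    times = []
    for rep in range(400):
        ts = msprime.sim_ancestry(samples=1, demography=demogr,
                                  random_seed=rep + 1)
        times.append(ts.first().time(ts.first().root))
    rng = np.random.default_rng(3)
    # high rho keeps tracts far shorter than the chromosome (no edge bias)
    tracts = simulate_tmrca(hist, {"c": 10_000_000}, 5e-7, rng)
    bounds = np.cumsum([0] + [t.end - t.start for t in tracts])
    tm = np.array([t.tmrca for t in tracts])
    sites = rng.integers(0, bounds[-1], size=400)
    site_t = tm[np.searchsorted(bounds, sites, side="right") - 1]
    res = stats.ks_2samp(times, site_t)
    assert res.pvalue > 0.01


# -- variant placement -----------------------------------------------------

def _flat_tracts(lengths, tmrca):
    return [TmrcaTract(c, 0, L, tmrca) for c, L in lengths.items()]


class TestImposeVariants:
    def test_no_mutation_no_divergence_gives_empty(self, small_ref):
        cfg = SimulationConfig(chrom_lengths=dict(small_ref.lengths),
                               mutation_rate=0.0, reference_divergence=0.0,
                               small_indel_rate=0.0, rng_seed=4)
        truth = impose_variants(small_ref, _flat_tracts(small_ref.lengths, 1e4), cfg)
        assert len(truth.snvs) == 0

    def test_het_fraction_matches_2_mu_t(self):
        cfg = SimulationConfig(chrom_lengths={"c": 10_000_000},
                               reference_divergence=0.0, small_indel_rate=0.0,
                               gap_density=0.0, rng_seed=5)
        ref = simulate_reference(cfg)
        t = 20_000.0
        truth = impose_variants(ref, _flat_tracts(ref.lengths, t), cfg)
        p = 2 * cfg.mutation_rate * t
        n, L = (truth.snvs["zygosity"] == "het").sum(), 10_000_000
        se = np.sqrt(p * (1 - p) * L)
        assert abs(n - p * L) < 3 * se

    def test_ts_tv_bias_is_honoured(self, deep_sim):
        snvs = deep_sim["truth"].snvs
        from macseq.popgen import ts_tv
        assert abs(ts_tv(snvs) - 2.39) < 0.1

    def test_model_breakdown_rejected(self, small_ref):
        cfg = SimulationConfig(chrom_lengths=dict(small_ref.lengths), rng_seed=6)
        huge = _flat_tracts(small_ref.lengths, 1.0 / cfg.mutation_rate)
        with pytest.raises(ValueError, match="0.5"):
            impose_variants(small_ref, huge, cfg)

    def test_tract_tiling_enforced(self, small_ref):
        cfg = SimulationConfig(chrom_lengths=dict(small_ref.lengths), rng_seed=6)
        partial = [TmrcaTract(c, 0, L // 2, 1e4)
                   for c, L in small_ref.lengths.items()]
        with pytest.raises(ValueError, match="tile"):
            impose_variants(small_ref, partial, cfg)

    def test_deterministic(self, small_ref):
        cfg = SimulationConfig(chrom_lengths=dict(small_ref.lengths), rng_seed=12)
        tracts = _flat_tracts(small_ref.lengths, 2e4)
        a = impose_variants(small_ref, tracts, cfg)
        b = impose_variants(small_ref, tracts, cfg)
        pd.testing.assert_frame_equal(a.snvs, b.snvs)
        pd.testing.assert_frame_equal(a.small_indels, b.small_indels)


# -- pileup evidence -------------------------------------------------------

class TestEmitPileup:
    def test_error_free_hom_ref_sites_show_only_ref(self):
        cfg = SimulationConfig(chrom_lengths={"c": 5_000}, base_error_rate=0.0,
                               mutation_rate=0.0, reference_divergence=0.0,
                               small_indel_rate=0.0, gap_density=0.0, rng_seed=7)
        ref = simulate_reference(cfg)
        truth = impose_variants(ref, _flat_tracts(ref.lengths, 1e4), cfg)
        pileup = emit_pileup(ref, truth, cfg)
        counts = pileup[["nA", "nC", "nG", "nT"]].to_numpy()
        ref_count = counts[np.arange(len(pileup)), pileup["ref_code"]]
        assert (ref_count == pileup["depth"]).all()

    def test_mean_depth(self, deep_sim):
        pileup = deep_sim["pileup"]
        se = pileup["depth"].std() / np.sqrt(len(pileup))
        assert abs(pileup["depth"].mean() - 41.5) < 3 * se

    def test_het_sites_show_half_alt(self, deep_sim):
        truth, pileup = deep_sim["truth"], deep_sim["pileup"]
        het = truth.snvs[truth.snvs["zygosity"] == "het"]
        merged = het.merge(pileup, on=["chrom", "pos"])
        counts = merged[["nA", "nC", "nG", "nT"]].to_numpy()
        alt_idx = merged["alt"].map("ACGT".index).to_numpy()
        alt_n = counts[np.arange(len(merged)), alt_idx].sum()
        depth_n = merged["depth"].sum()
        # alt reads: half the alleles, minus/plus symmetric error flow
        p = 0.5 * (1 - deep_sim["config"].base_error_rate) \
            + 0.5 * deep_sim["config"].base_error_rate / 3
        se = np.sqrt(p * (1 - p) * depth_n)
        assert abs(alt_n - p * depth_n) < 3 * se

    def test_every_truth_het_has_alt_evidence_in_aggregate(self, deep_sim):
        """Truth and evidence agree: het sites carry alt reads on average."""
        truth, pileup = deep_sim["truth"], deep_sim["pileup"]
        het = truth.snvs[truth.snvs["zygosity"] == "het"]
        merged = het.merge(pileup, on=["chrom", "pos"])
        counts = merged[["nA", "nC", "nG", "nT"]].to_numpy()
        alt_idx = merged["alt"].map("ACGT".index).to_numpy()
        alt_n = counts[np.arange(len(merged)), alt_idx]
        assert (alt_n > 0).mean() > 0.999


# -- mate pairs ------------------------------------------------------------

class TestEmitMatepairs:
    def test_no_svs_all_congruent_in_range(self):
        cfg = SimulationConfig(chrom_lengths={"c": 100_000}, rng_seed=8,
                               gap_density=0.0)
        ref = simulate_reference(cfg)
        truth = impose_variants(ref, _flat_tracts(ref.lengths, 1e4), cfg)
        pairs = emit_matepairs(ref, truth, "A", cfg, physical_coverage=5)
        assert pairs["congruent"].all()
        assert pairs["span"].between(600, 800).all()

    def test_planted_deletion_inflates_spans(self):
        sv = StructuralVariant("c", 50_000, "del", 300)
        cfg = SimulationConfig(chrom_lengths={"c": 100_000}, rng_seed=9,
                               gap_density=0.0, planted_svs=(sv,))
        ref = simulate_reference(cfg)
        truth = impose_variants(ref, _flat_tracts(ref.lengths, 1e4), cfg)
        pairs = emit_matepairs(ref, truth, "A", cfg, physical_coverage=30)
        straddle = pairs[(pairs["pos1"] < 50_000) & (pairs["pos2"] > 50_300)]
        assert len(straddle) > 10
        assert abs(straddle["span"].median() - (700 + 300)) <= 100

    def test_inversion_straddlers_flagged(self):
        sv = StructuralVariant("c", 40_000, "inv", 5_000)
        cfg = SimulationConfig(chrom_lengths={"c": 100_000}, rng_seed=10,
                               gap_density=0.0, planted_svs=(sv,))
        ref = simulate_reference(cfg)
        truth = impose_variants(ref, _flat_tracts(ref.lengths, 1e4), cfg)
        pairs = emit_matepairs(ref, truth, "A", cfg, physical_coverage=20)
        for bp in (40_000, 45_000):
            straddle = (pairs["pos1"] < bp) & (bp < pairs["pos2"])
            assert (~pairs.loc[straddle, "congruent"]).all()
        clear = (pairs["pos2"] < 40_000) | (pairs["pos1"] > 45_000)
        assert pairs.loc[clear, "congruent"].all()

    def test_insert_exceeding_chromosome_rejected(self):
        cfg = SimulationConfig(chrom_lengths={"c": 900}, rng_seed=11,
                               gap_density=0.0)
        ref = simulate_reference(cfg)
        truth = impose_variants(ref, _flat_tracts(ref.lengths, 1e4), cfg)
        with pytest.raises(ValueError, match="insert"):
            emit_matepairs(ref, truth, "B", cfg)


def test_gap_evidence_covers_all_truth_indels(small_ref):
    cfg = SimulationConfig(chrom_lengths=dict(small_ref.lengths),
                           small_indel_rate=1e-3, rng_seed=13)
    truth = impose_variants(small_ref, _flat_tracts(small_ref.lengths, 1e4), cfg)
    ev = emit_gap_evidence(truth, cfg)
    assert len(ev) == len(truth.small_indels)
    assert (ev["support"] <= ev["depth"]).all()
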