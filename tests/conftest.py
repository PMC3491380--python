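"""Shared fixtures.

The expensive 10-Mb end-to-end simulation (reference + truth + pileup +
calls) is session-scoped so that genotype-recovery and diversity tests
share one run.
"""

from __future__ import annotations

import numpy as np
import pytest

from macseq.genotyping import apply_filters, call_pileup
from macseq.simulate import (DemographicHistory, SimulationConfig,
                             emit_pileup, impose_variants, simulate_annotation,
                             simulate_reference, simulate_tmrca)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(chrom_lengths={"chr1": 120_000, "chr2": 80_000},
                            rng_seed=11)


@pytest.fixture(scope="session")
def small_ref(small_config):
    return simulate_reference(small_config)


@pytest.fixture(scope="session")
def small_annotation(small_config, small_ref):
    return simulate_annotation(small_config, small_ref, n_genes=30)


@pytest.fixture(scope="session")
def deep_sim():
    """10-Mb constant-size simulation with pileup evidence and calls.

    Study conditions: N = 10,000, mu = 2.5e-8, divergence 0.4%, depth
    41.5x, base error 1%.
    """
    config = SimulationConfig(chrom_lengths={"chr1": 10_000_000},
                              rng_seed=202, gap_density=0.001)
    history = DemographicHistory([(0, 10_000)])
    ref = simulate_reference(config)
    tracts = simulate_tmrca(history, config.chrom_lengths,
                            config.recombination_rate, config.rng("tmrca"))
    truth = impose_variants(ref, tracts, config)
    pileup = emit_pileup(ref, truth, config)
    calls = call_pileup(pileup)
    retained, tally = apply_filters(calls)
    return {"config": config, "history": history, "ref": ref,
            "tracts": tracts, "truth": truth, "pileup": pileup,
            "calls": calls, "retained": retained, "tally": tally}
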