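"""Placement of diploid variants on a simulated reference.

Heterozygous SNVs arise along each TMRCA tract at per-site probability
2*mu*T (two branches of length T generations each); homozygous SNVs
model fixed differences from the reference at the configured divergence.
Substitution types follow the transition:transversion bias.  Small
indels are placed uniformly; large indels and inversions come from the
planted-SV list in the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .. import intervals as iv
from .coalescent import TmrcaTract
from .reference import ReferenceAssembly, SimulationConfig, StructuralVariant

__all__ = ["SampleTruth", "impose_variants"]

# code order A,C,G,T; transitions A<->G, C<->T
_TRANSITION = np.array([2, 3, 0, 1])
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])
_BASES = "ACGT"


@dataclass
class SampleTruth:
    """Known diploid variants of one simulated individual.

    ``snvs``: chrom, pos, ref, alt, zygosity (het/hom).
    ``small_indels``: chrom, pos, vtype (ins/del), length, zygosity.
    ``svs``: the planted large indels and inversions.
    """

    snvs: pd.DataFrame
    small_indels: pd.DataFrame
    svs: tuple[StructuralVariant, ...] = ()

    def het_positions(self, chrom: str) -> np.ndarray:
        s = self.snvs
        m = (s["chrom"] == chrom) & (s["zygosity"] == "het")
        return s.loc[m, "pos"].to_numpy()


def _check_tiling(tracts: list[TmrcaTract], lengths: dict[str, int]) -> None:
    by_chrom: dict[str, list[TmrcaTract]] = {}
    for t in tracts:
        by_chrom.setdefault(t.chrom, []).append(t)
    for chrom, L in lengths.items():
        ts = sorted(by_chrom.get(chrom, []), key=lambda t: t.start)
        if not ts or ts[0].start != 0 or ts[-1].end != L:
            raise ValueError(f"tracts do not tile chromosome {chrom!r}")
        for a, b in zip(ts, ts[1:]):
            if a.end != b.start:
                raise ValueError(f"tract gap/overlap on {chrom!r} at {a.end}")


def _draw_alt(ref_codes: np.ndarray, bias: float, rng) -> np.ndarray:
    """Alternate-allele codes under the transition:transversion bias.

    Each site mutates to the transition partner with probability
    bias/(bias+1), otherwise to one of its two transversion partners.
    """
    n = len(ref_codes)
    is_ts = rng.random(n) < bias / (bias + 1.0)
    tv_pick = rng.integers(0, 2, size=n)
    alt = np.where(is_ts, _TRANSITION[ref_codes],
                   _TRANSVERSIONS[ref_codes, tv_pick])
    return alt


def impose_variants(ref: ReferenceAssembly, tracts: list[TmrcaTract],
                    config: SimulationConfig) -> SampleTruth:
    """Generate the diploid truth set implied by TMRCA tracts + config."""
    _check_tiling(tracts, ref.lengths)
    mu = config.mutation_rate
    for t in tracts:
        if mu * t.tmrca >= 0.5:
            raise ValueError(
                f"mu*tmrca = {mu * t.tmrca:.3f} >= 0.5 on {t.chrom}:{t.start}; "
                "small-rate SNV model breaks down")
    rng = config.rng("variants")

    snv_rows = {"chrom": [], "pos": [], "ref": [], "alt": [], "zygosity": []}
    codes_by_chrom = {c: ref.codes(c) for c in ref.chroms}

    def add_snvs(chrom: str, pos: np.ndarray, zygosity: str):
        codes = codes_by_chrom[chrom]
        pos = np.unique(pos)
        pos = pos[codes[pos] < 4]  # never inside N runs
        if len(pos) == 0:
            return
        refc = codes[pos]
        altc = _draw_alt(refc, config.ts_tv_bias, rng)
        snv_rows["chrom"].extend([chrom] * len(pos))
        snv_rows["pos"].extend(pos.tolist())
        snv_rows["ref"].extend(_BASES[c] for c in refc)
        snv_rows["alt"].extend(_BASES[c] for c in altc)
        snv_rows["zygosity"].extend([zygosity] * len(pos))

    # heterozygous SNVs per tract
    for t in tracts:
        L = t.end - t.start
        p_het = 2.0 * mu * t.tmrca
        n = rng.binomial(L, p_het)
        if n:
            add_snvs(t.chrom, t.start + rng.choice(L, size=n, replace=False), "het")

    # homozygous SNVs: divergence from the reference, genome-wide
    for chrom, L in ref.lengths.items():
        n = rng.binomial(L, config.reference_divergence)
        if n:
            add_snvs(chrom, rng.choice(L, size=n, replace=False), "hom")

    snvs = pd.DataFrame(snv_rows)
    if len(snvs):
        # a site can be drawn both het and hom; keep the first occurrence
        snvs = snvs.drop_duplicates(subset=["chrom", "pos"], keep="first")
        snvs = snvs.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    # small indels: uniform rate, short lengths within caller limits
    ind_rows = {"chrom": [], "pos": [], "vtype": [], "length": [], "zygosity": []}
    for chrom, L in ref.lengths.items():
        codes = codes_by_chrom[chrom]
        n = rng.binomial(L, config.small_indel_rate)
        if n == 0:
            continue
        pos = np.unique(rng.choice(L, size=n, replace=False))
        pos = pos[codes[pos] < 4]
        is_del = rng.random(len(pos)) < config.indel_del_fraction
        # geometric lengths truncated to the detectable windows
        dl = np.minimum(11, rng.geometric(0.45, size=len(pos)))
        il = np.minimum(3, rng.geometric(0.6, size=len(pos)))
        length = np.where(is_del, dl, il)
        zyg = np.where(rng.random(len(pos)) < 0.5, "het", "hom")
        ind_rows["chrom"].extend([chrom] * len(pos))
        ind_rows["pos"].extend(pos.tolist())
        ind_rows["vtype"].extend(np.where(is_del, "del", "ins").tolist())
        ind_rows["length"].extend(length.tolist())
        ind_rows["zygosity"].extend(zyg.tolist())
    small_indels = pd.DataFrame(ind_rows)

    return SampleTruth(snvs=snvs, small_indels=small_indels,
                       svs=tuple(config.planted_svs))
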