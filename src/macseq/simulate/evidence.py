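"""Sequencing-evidence emulation: pileups, gapped-alignment indel support,
and mate-pair records.

Pileups carry per-site read-base counts drawn from the diploid genotype
with symmetric substitution errors.  Mate pairs are sampled uniformly
along the *sample* genome and mapped back to reference coordinates, so
planted deletions inflate and insertions deflate the observed span, and
pairs whose fragment straddles an inversion breakpoint are flagged
orientation-incongruent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .reference import ReferenceAssembly, SimulationConfig
from .variants import SampleTruth

__all__ = ["emit_pileup", "emit_matepairs", "emit_gap_evidence"]

_BASES = "ACGT"


def _error_profile(code: int, eps: float) -> np.ndarray:
    """P(observed base | true allele): 1-eps on the allele, eps/3 elsewhere."""
    p = np.full(4, eps / 3.0)
    p[code] = 1.0 - eps
    return p


def emit_pileup(ref: ReferenceAssembly, truth: SampleTruth,
                config: SimulationConfig,
                chroms: list[str] | None = None) -> pd.DataFrame:
    """Per-site pileup columns for every non-N reference site.

    Depth is Poisson(mean_depth); each read draws one of the two alleles
    with probability 1/2 and is observed correctly with probability
    1 - base_error_rate, otherwise as one of the three other bases
    uniformly.  Columns: chrom, pos, ref_code (0..3), ref_qv, depth,
    nA, nC, nG, nT.
    """
    eps = config.base_error_rate
    rng = config.rng("pileup")
    frames = []
    for chrom in (chroms or list(ref.chroms)):
        codes = ref.codes(chrom)
        valid = codes < 4
        pos = np.flatnonzero(valid)
        n = len(pos)
        a1 = codes[pos].copy()
        a2 = codes[pos].copy()
        # apply truth SNVs onto the two haplotypes
        s = truth.snvs
        s = s[s["chrom"] == chrom]
        if len(s):
            spos = s["pos"].to_numpy()
            alt = np.array([_BASES.index(b) for b in s["alt"]], dtype=np.uint8)
            het = (s["zygosity"] == "het").to_numpy()
            idx = np.searchsorted(pos, spos)
            ok = (idx < n) & (pos[np.minimum(idx, n - 1)] == spos)
            idx, alt, het = idx[ok], alt[ok], het[ok]
            a2[idx] = alt
            a1[idx[~het]] = alt[~het]
        depth = rng.poisson(config.mean_depth, size=n).astype(np.int32)
        counts = np.zeros((n, 4), dtype=np.int32)
        # group sites by unordered genotype for vectorised multinomials
        geno = np.minimum(a1, a2).astype(np.int16) * 4 + np.maximum(a1, a2)
        for g in np.unique(geno):
            sel = geno == g
            p = 0.5 * (_error_profile(g // 4, eps) + _error_profile(g % 4, eps))
            counts[sel] = rng.multinomial(depth[sel], p)
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos.astype(np.int64),
            "ref_code": codes[pos].astype(np.int8),
            "ref_qv": ref.qv[chrom][pos].astype(np.int16),
            "depth": depth,
            "nA": counts[:, 0], "nC": counts[:, 1],
            "nG": counts[:, 2], "nT": counts[:, 3]}))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "pos", "ref_code", "ref_qv", "depth", "nA", "nC", "nG", "nT"])


def emit_gap_evidence(truth: SampleTruth, config: SimulationConfig,
                      hom_support_rate: float = 0.95,
                      het_support_rate: float = 0.5) -> pd.DataFrame:
    """Gapped-alignment support rows for the truth small indels.

    Each indel gets a Poisson site depth and a binomial supporting-read
    count: half the reads carry a heterozygous indel, nearly all carry a
    homozygous one.  Columns: chrom, pos, vtype, length, support, depth.
    """
    rng = config.rng("gap_evidence")
    ind = truth.small_indels
    depth = rng.poisson(config.mean_depth, size=len(ind))
    rate = np.where(ind["zygosity"].to_numpy() == "hom",
                    hom_support_rate, het_support_rate)
    support = rng.binomial(depth, rate)
    return pd.DataFrame({
        "chrom": ind["chrom"].to_numpy(), "pos": ind["pos"].to_numpy(),
        "vtype": ind["vtype"].to_numpy(), "length": ind["length"].to_numpy(),
        "support": support, "depth": depth})


def _segment_map(L_ref: int, svs) -> tuple[list[tuple[int, int, int]], int, list[int]]:
    """Piecewise map from sample coordinates to reference coordinates.

    Returns (segments, sample_length, inversion_breakpoints); each
    segment is (sample_start, ref_start, length) of colinear sequence.
    Insertions contribute unmappable sample intervals (no segment);
    deletions skip reference sequence; inversions keep coordinates but
    contribute breakpoints.
    """
    segs: list[tuple[int, int, int]] = []
    breakpoints: list[int] = []
    s_pos = 0
    r_pos = 0
    for sv in sorted(svs, key=lambda v: v.pos):
        if sv.svtype == "inv":
            breakpoints.extend([sv.pos, sv.pos + sv.length])
            continue
        run = sv.pos - r_pos
        if run < 0:
            raise ValueError("overlapping planted SVs are not supported")
        if run:
            segs.append((s_pos, r_pos, run))
        s_pos += run
        r_pos += run
        if sv.svtype == "del":
            r_pos += sv.length          # sample lacks these reference bases
        else:  # ins: sample has extra, unmappable bases
            s_pos += sv.length
    if L_ref - r_pos > 0:
        segs.append((s_pos, r_pos, L_ref - r_pos))
        s_pos += L_ref - r_pos
    return segs, s_pos, breakpoints


#: span (physical) coverage implied by the study's library table: sequence
#: coverage 3.4x / 4.8x with 2x25 bp tags on ~700 / ~900 bp inserts gives
#: 3.4 * 700/50 ~ 48x and 4.8 * 900/50 ~ 86x fragment coverage.
STUDY_PHYSICAL_COVERAGE = {"A": 48.0, "B": 86.0}


def emit_matepairs(ref: ReferenceAssembly, truth: SampleTruth,
                   library_id: str, config: SimulationConfig,
                   physical_coverage: float = 40.0) -> pd.DataFrame:
    """Mate-pair records for one library, mapped to reference coordinates.

    Fragments are placed uniformly on the sample genome with insert size
    uniform over the library's range; ``physical_coverage`` is the mean
    number of fragments spanning a site (see
    :data:`STUDY_PHYSICAL_COVERAGE` for the study-scale values).  Pairs
    with a tag inside an insertion are dropped (unmappable).  Columns:
    chrom, pos1, pos2, span, congruent, library.
    """
    insert_min, insert_max = config.libraries[library_id]
    rng = config.rng(f"matepairs_{library_id}")
    frames = []
    for chrom, L in ref.lengths.items():
        if insert_max >= L:
            raise ValueError(f"insert max {insert_max} >= length of {chrom}")
        svs = [v for v in truth.svs if v.chrom == chrom]
        segs, L_sample, bps = _segment_map(L, svs)
        n_pairs = int(physical_coverage * L_sample / ((insert_min + insert_max) / 2.0))
        u = rng.integers(insert_min, insert_max + 1, size=n_pairs)
        x = rng.integers(0, L_sample - insert_max, size=n_pairs)
        # map sample positions through the colinear segments
        seg_s = np.array([s for s, _, _ in segs])
        seg_r = np.array([r for _, r, _ in segs])
        seg_l = np.array([l for _, _, l in segs])

        def to_ref(sp: np.ndarray) -> np.ndarray:
            i = np.searchsorted(seg_s, sp, side="right") - 1
            i = np.clip(i, 0, len(segs) - 1)
            off = sp - seg_s[i]
            out = seg_r[i] + off
            out[(off < 0) | (off >= seg_l[i])] = -1  # inside an insertion
            return out

        r1 = to_ref(x)
        r2 = to_ref(x + u)
        ok = (r1 >= 0) & (r2 >= 0)
        r1, r2 = r1[ok], r2[ok]
        congruent = np.ones(len(r1), dtype=bool)
        for b in bps:
            congruent &= ~((r1 < b) & (b < r2))
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos1": r1, "pos2": r2,
            "span": r2 - r1, "congruent": congruent,
            "library": library_id}))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "pos1", "pos2", "span", "congruent", "library"])
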