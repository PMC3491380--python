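"""Diploid genotype calling from pileup columns.

The caller evaluates all ten unordered diploid genotypes under a
binomial-mixture read model: each read draws one of the two alleles with
probability 1/2 and is observed correctly with probability 1 - eps,
otherwise as one of the other three bases uniformly.  Posteriors combine
the likelihood with a prior that places most mass on homozygous
reference, a per-site heterozygosity-scale mass on reference-containing
heterozygotes, and a divergence-scale mass on homozygous alternates.

Variant calls are then passed through the study's quality filters:
depth >= 5, call QV >= 40 and reference-assembly QV >= 45, and the
discovery-rate profile against reference QV is the diagnostic that
motivates the assembly-quality cutoff.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GENOTYPES", "PileupColumn", "GenotypeCall", "FilterThresholds",
    "genotype_posteriors", "call_site", "call_pileup", "apply_filters",
    "male_x_mode", "discovery_profile",
]

_BASES = "ACGT"
#: the 10 unordered diploid genotypes as (code, code) with a <= b
GENOTYPES: tuple[tuple[int, int], ...] = tuple(
    itertools.combinations_with_replacement(range(4), 2))
_CALL_QV_CAP = 99.0
# conservative tie-break order for zygosity classes
_ZYG_RANK = {"hom_ref": 0, "het": 1, "hom_alt": 2}


@dataclass(frozen=True)
class PileupColumn:
    """One site of pileup evidence."""

    chrom: str
    pos: int
    ref: str
    ref_qv: int
    counts: tuple[int, int, int, int]  # A, C, G, T

    @property
    def depth(self) -> int:
        return int(sum(self.counts))

    @property
    def ref_code(self) -> int:
        return _BASES.index(self.ref)


@dataclass(frozen=True)
class GenotypeCall:
    """A per-site diploid call."""

    chrom: str
    pos: int
    ref: str
    alt: str | None
    zygosity: str  # hom_ref | het | hom_alt | ambiguous | no_call
    call_qv: float
    depth: int
    ref_qv: int


@dataclass(frozen=True)
class FilterThresholds:
    """Variant retention thresholds (depth, call QV, reference QV)."""

    min_depth: int = 5
    min_call_qv: float = 40.0
    min_ref_qv: int = 45

    def __post_init__(self):
        if min(self.min_depth, self.min_call_qv, self.min_ref_qv) < 0:
            raise ValueError("thresholds must be >= 0")


def _log_read_probs(error_rate: float) -> np.ndarray:
    """(10, 4) log P(observed base | genotype) under the mixture model."""
    e = error_rate
    per_allele = np.full((4, 4), e / 3.0)
    np.fill_diagonal(per_allele, 1.0 - e)
    probs = np.array([0.5 * (per_allele[a] + per_allele[b]) for a, b in GENOTYPES])
    return np.log(probs)


def _log_prior_table(het_prior: float, hom_alt_prior: float) -> np.ndarray:
    """(4, 10) log prior over genotypes for each reference base.

    Reference-containing heterozygotes split ``het_prior``; homozygous
    alternates split ``hom_alt_prior``; heterozygotes without the
    reference allele get a doubly-small mass (het * hom_alt scale) so
    they are possible but never favoured a priori.  Rows are
    renormalised.
    """
    table = np.empty((4, len(GENOTYPES)))
    tiny = het_prior * hom_alt_prior
    for r in range(4):
        row = np.empty(len(GENOTYPES))
        for g, (a, b) in enumerate(GENOTYPES):
            if a == b == r:
                row[g] = 1.0 - het_prior - hom_alt_prior
            elif a == b:
                row[g] = hom_alt_prior / 3.0
            elif r in (a, b):
                row[g] = het_prior / 3.0
            else:
                row[g] = tiny / 3.0
        table[r] = row / row.sum()
    return np.log(table)


def genotype_posteriors(column: PileupColumn, error_rate: float = 0.01,
                        het_prior: float = 0.003,
                        hom_alt_prior: float = 0.004) -> np.ndarray:
    """Posterior over the 10 unordered genotypes at one site.

    With zero depth the prior itself is returned (the site becomes a
    ``no_call`` downstream).
    """
    if not 0.0 < error_rate < 0.75:
        raise ValueError("error_rate must lie in (0, 0.75)")
    if not 0.0 < het_prior < 1.0:
        raise ValueError("het_prior must lie in (0, 1)")
    log_prior = _log_prior_table(het_prior, hom_alt_prior)[column.ref_code]
    if column.depth == 0:
        return np.exp(log_prior)
    counts = np.asarray(column.counts, dtype=float)
    loglik = _log_read_probs(error_rate) @ counts
    logpost = log_prior + loglik
    logpost -= logpost.max()
    post = np.exp(logpost)
    return post / post.sum()


def _zygosity_of(genotype: tuple[int, int], ref_code: int) -> str:
    a, b = genotype
    if a == b:
        return "hom_ref" if a == ref_code else "hom_alt"
    return "het"


def call_site(posteriors: np.ndarray, column: PileupColumn,
              ambiguity_margin: float = 10.0) -> GenotypeCall:
    """MAP genotype call with Phred call quality and ambiguity handling.

    Call QV is ``-10 log10(1 - p_MAP)`` capped at 99.  If the two most
    probable genotypes disagree on zygosity and their posterior ratio is
    below ``ambiguity_margin`` the call is ``ambiguous`` (such sites are
    excluded from SNV counts).  Exact posterior ties break toward the
    zygosity-conservative class (hom_ref > het > hom_alt).
    """
    if abs(posteriors.sum() - 1.0) > 1e-6:
        raise ValueError("posteriors must be normalised")
    r = column.ref_code
    order = sorted(
        range(len(GENOTYPES)),
        key=lambda g: (-posteriors[g], _ZYG_RANK[_zygosity_of(GENOTYPES[g], r)]))
    top, second = order[0], order[1]
    zyg = _zygosity_of(GENOTYPES[top], r)
    if column.depth == 0:
        return GenotypeCall(column.chrom, column.pos, column.ref, None,
                            "no_call", 0.0, 0, column.ref_qv)
    p_map = posteriors[top]
    call_qv = _CALL_QV_CAP if p_map >= 1.0 else min(
        _CALL_QV_CAP, -10.0 * np.log10(1.0 - p_map))
    second_zyg = _zygosity_of(GENOTYPES[second], r)
    if (second_zyg != zyg and posteriors[second] > 0
            and p_map / posteriors[second] < ambiguity_margin):
        zyg = "ambiguous"
    alt = None
    if zyg in ("het", "hom_alt"):
        a, b = GENOTYPES[top]
        if a == b:
            alt = _BASES[a]
        else:
            non_ref = [c for c in (a, b) if c != r]
            if len(non_ref) == 1:
                alt = _BASES[non_ref[0]]
            else:  # heterozygote without the reference allele
                alt = _BASES[max(non_ref, key=lambda c: column.counts[c])]
    return GenotypeCall(column.chrom, column.pos, column.ref, alt, zyg,
                        float(call_qv), column.depth, column.ref_qv)


def call_pileup(pileup: pd.DataFrame, error_rate: float = 0.01,
                het_prior: float = 0.003, hom_alt_prior: float = 0.004,
                ambiguity_margin: float = 10.0,
                chunk_size: int = 1_000_000) -> pd.DataFrame:
    """Vectorised genotype calling over a pileup table.

    ``pileup`` uses the simulator/IO schema (chrom, pos, ref_code,
    ref_qv, depth, nA..nT).  Returns a call table with columns chrom,
    pos, ref, alt, zygosity, call_qv, depth, ref_qv.  Agrees site-by-site
    with :func:`genotype_posteriors` + :func:`call_site`.
    """
    log_read = _log_read_probs(error_rate)          # (10, 4)
    log_prior = _log_prior_table(het_prior, hom_alt_prior)  # (4, 10)
    n_g = len(GENOTYPES)
    zyg_code_by_ref = np.empty((4, n_g), dtype=np.int8)
    alt_code_by_ref = np.full((4, n_g), -1, dtype=np.int8)
    alt2_code = np.full((4, n_g), -1, dtype=np.int8)
    for r in range(4):
        for g, (a, b) in enumerate(GENOTYPES):
            z = _zygosity_of((a, b), r)
            zyg_code_by_ref[r, g] = _ZYG_RANK[z]
            if z == "hom_alt":
                alt_code_by_ref[r, g] = a
            elif z == "het":
                non_ref = [c for c in (a, b) if c != r]
                alt_code_by_ref[r, g] = non_ref[0]
                if len(non_ref) == 2:
                    alt2_code[r, g] = non_ref[1]
    # conservative tie-break: tiny rank-ordered penalty, well below float
    # posterior resolution
    tie_bias = -1e-12 * zyg_code_by_ref

    out = {k: [] for k in ("chrom", "pos", "ref", "alt", "zygosity",
                           "call_qv", "depth", "ref_qv")}
    zyg_names = np.array(["hom_ref", "het", "hom_alt"])
    counts_all = pileup[["nA", "nC", "nG", "nT"]].to_numpy()
    ref_code_all = pileup["ref_code"].to_numpy()
    depth_all = pileup["depth"].to_numpy()

    for lo in range(0, len(pileup), chunk_size):
        hi = min(lo + chunk_size, len(pileup))
        counts = counts_all[lo:hi].astype(np.float64)
        rc = ref_code_all[lo:hi]
        logpost = counts @ log_read.T + log_prior[rc]
        logpost -= logpost.max(axis=1, keepdims=True)
        post = np.exp(logpost)
        post /= post.sum(axis=1, keepdims=True)
        ranked = post + tie_bias[rc]
        top = np.argmax(ranked, axis=1)
        p_map = post[np.arange(len(post)), top]
        masked = ranked.copy()
        masked[np.arange(len(post)), top] = -np.inf
        second = np.argmax(masked, axis=1)
        p_second = post[np.arange(len(post)), second]

        zyg = zyg_code_by_ref[rc, top]
        second_zyg = zyg_code_by_ref[rc, second]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(p_second > 0, p_map / p_second, np.inf)
        ambiguous = (second_zyg != zyg) & (ratio < ambiguity_margin)

        call_qv = np.where(p_map >= 1.0, _CALL_QV_CAP,
                           np.minimum(_CALL_QV_CAP,
                                      -10.0 * np.log10(np.maximum(1e-300, 1.0 - p_map))))
        alt_code = alt_code_by_ref[rc, top]
        a2 = alt2_code[rc, top]
        has2 = a2 >= 0
        if has2.any():
            i = np.flatnonzero(has2)
            swap = counts[i, a2[i]] > counts[i, alt_code[i]]
            alt_code[i[swap]] = a2[i][swap]

        zyg_label = zyg_names[zyg].astype(object)
        zyg_label[ambiguous] = "ambiguous"
        depth = depth_all[lo:hi]
        zyg_label[depth == 0] = "no_call"
        call_qv = np.where(depth == 0, 0.0, call_qv)

        alt = np.full(hi - lo, None, dtype=object)
        variant = np.isin(zyg_label, ("het", "hom_alt"))
        alt[variant] = np.array(list(_BASES), dtype=object)[alt_code[variant]]

        out["chrom"].append(pileup["chrom"].to_numpy()[lo:hi])
        out["pos"].append(pileup["pos"].to_numpy()[lo:hi])
        out["ref"].append(np.array(list(_BASES), dtype=object)[rc])
        out["alt"].append(alt)
        out["zygosity"].append(zyg_label)
        out["call_qv"].append(call_qv)
        out["depth"].append(depth)
        out["ref_qv"].append(pileup["ref_qv"].to_numpy()[lo:hi])

    return pd.DataFrame({k: np.concatenate(v) if v else np.array([])
                         for k, v in out.items()})


def apply_filters(calls: pd.DataFrame,
                  thresholds: FilterThresholds = FilterThresholds()
                  ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Retain variant calls passing depth, call-QV and reference-QV cuts.

    Input rows whose zygosity is not het/hom_alt are dropped (they are
    not variant calls).  The tally assigns each rejected variant to its
    *first* failing rule, in the order depth, call QV, reference QV.
    Idempotent on its own output.
    """
    v = calls[calls["zygosity"].isin(("het", "hom_alt"))]
    fail_depth = v["depth"].to_numpy() < thresholds.min_depth
    fail_qv = v["call_qv"].to_numpy() < thresholds.min_call_qv
    fail_ref = v["ref_qv"].to_numpy() < thresholds.min_ref_qv
    tally = {
        "depth": int(fail_depth.sum()),
        "call_qv": int((~fail_depth & fail_qv).sum()),
        "ref_qv": int((~fail_depth & ~fail_qv & fail_ref).sum()),
    }
    keep = ~(fail_depth | fail_qv | fail_ref)
    return v[keep].reset_index(drop=True), tally


def male_x_mode(calls: pd.DataFrame, x_chrom_name: str = "chrX"
                ) -> tuple[pd.DataFrame, int]:
    """Drop heterozygous calls on the X chromosome of a male sample.

    A male is hemizygous on X, so X heterozygotes are artifacts; only
    homozygous X SNVs are counted.  Returns (calls, n_excluded).
    """
    drop = (calls["chrom"] == x_chrom_name) & (calls["zygosity"] == "het")
    return calls[~drop].reset_index(drop=True), int(drop.sum())


def discovery_profile(calls: pd.DataFrame,
                      thresholds: FilterThresholds = FilterThresholds()
                      ) -> pd.DataFrame:
    """SNV discovery rate stratified by reference-assembly QV.

    ``calls`` must be the *per-site* call table (all sites, before any
    filtering).  For each reference QV value present, counts callable
    sites (depth >= min_depth) and the rate of het and hom SNVs among
    them, applying the depth and call-QV filters but NOT the
    reference-QV filter — the profile is that filter's diagnostic.
    """
    callable_mask = calls["depth"].to_numpy() >= thresholds.min_depth
    sites = calls[callable_mask]
    is_var = sites["zygosity"].isin(("het", "hom_alt")).to_numpy()
    passing = is_var & (sites["call_qv"].to_numpy() >= thresholds.min_call_qv)
    het = passing & (sites["zygosity"].to_numpy() == "het")
    hom = passing & (sites["zygosity"].to_numpy() == "hom_alt")
    df = pd.DataFrame({"ref_qv": sites["ref_qv"].to_numpy(),
                       "het": het, "hom": hom})
    grouped = df.groupby("ref_qv").agg(callable=("het", "size"),
                                       het_snvs=("het", "sum"),
                                       hom_snvs=("hom", "sum")).reset_index()
    grouped["het_rate"] = grouped["het_snvs"] / grouped["callable"]
    grouped["hom_rate"] = grouped["hom_snvs"] / grouped["callable"]
    return grouped
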