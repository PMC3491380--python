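"""Population-genetic summaries of a single resequenced diploid genome.

Against a reference from a sister species, heterozygous SNVs measure
within-species nucleotide diversity (pi: two sampled chromosomes differ)
while homozygous SNVs plus half the heterozygous ones measure
between-species divergence (Nei's d_xy: the average sequenced chromosome
differs from the reference chromosome).  Nonsynonymous/synonymous ratios
contrast the strength of purifying selection within and between species
(nearly neutral theory: larger populations purge slightly deleterious
variants more efficiently, depressing the within-species ratio).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaincc

__all__ = ["DiversityEstimate", "CodingRatio", "Chi2Result",
           "diversity_pi", "divergence_dxy", "coding_ratio", "chi2_2x2",
           "ts_tv", "density_windows"]

_TS_PAIRS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass(frozen=True)
class DiversityEstimate:
    """Per-site diversity/divergence over a callable-site denominator."""

    callable_sites: int
    het_snvs: int
    hom_snvs: int

    @property
    def pi(self) -> float:
        return self.het_snvs / self.callable_sites

    @property
    def dxy(self) -> float:
        return (self.hom_snvs + 0.5 * self.het_snvs) / self.callable_sites


@dataclass(frozen=True)
class CodingRatio:
    nonsynonymous: float
    synonymous: float

    @property
    def ratio(self) -> float:
        if self.synonymous == 0:
            raise ZeroDivisionError("no synonymous variants: N/S undefined")
        return self.nonsynonymous / self.synonymous


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p_value: float


def _count_zygosity(calls: pd.DataFrame) -> tuple[int, int]:
    z = calls["zygosity"]
    return int((z == "het").sum()), int((z == "hom_alt").sum())


def diversity_pi(calls: pd.DataFrame, callable_sites: int) -> DiversityEstimate:
    """Nucleotide diversity from retained calls: pi = het / callable."""
    if callable_sites <= 0:
        raise ValueError("callable_sites must be positive")
    het, hom = _count_zygosity(calls)
    return DiversityEstimate(callable_sites, het, hom)


def divergence_dxy(calls: pd.DataFrame, callable_sites: int) -> DiversityEstimate:
    """Divergence from the reference: d_xy = (hom + het/2) / callable."""
    return diversity_pi(calls, callable_sites)


def coding_ratio(effects: pd.DataFrame, scope: str = "within") -> CodingRatio:
    """Nonsynonymous/synonymous ratio of coding SNVs.

    ``within`` counts heterozygous SNVs only (diversity); ``between``
    weights hom + 0.5*het, consistent with the d_xy definition.
    ``effects`` needs columns ``coding_effect`` and ``zygosity``.
    """
    if scope not in ("within", "between"):
        raise ValueError("scope must be 'within' or 'between'")
    nonsyn = effects["coding_effect"].isin(("nonsynonymous", "nonsense"))
    syn = effects["coding_effect"] == "synonymous"
    het = (effects["zygosity"] == "het").to_numpy()
    hom = (effects["zygosity"] == "hom").to_numpy() | \
          (effects["zygosity"] == "hom_alt").to_numpy()
    if scope == "within":
        w = het.astype(float)
    else:
        w = hom + 0.5 * het
    return CodingRatio(float(w[nonsyn].sum()), float(w[syn].sum()))


def chi2_2x2(n11: float, n12: float, n21: float, n22: float) -> Chi2Result:
    """Pearson chi-square test of homogeneity on a 2x2 table, df = 1.

    No continuity correction.  The p-value is the chi2(1) upper tail via
    the regularised incomplete gamma function Q(1/2, x/2).
    """
    n11, n12, n21, n22 = (float(n) for n in (n11, n12, n21, n22))
    for n in (n11, n12, n21, n22):
        if n < 0:
            raise ValueError("counts must be >= 0")
    r1, r2 = n11 + n12, n21 + n22
    c1, c2 = n11 + n21, n12 + n22
    total = r1 + r2
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("chi-square undefined: zero margin")
    stat = total * (n11 * n22 - n12 * n21) ** 2 / (r1 * r2 * c1 * c2)
    p = float(gammaincc(0.5, stat / 2.0))
    return Chi2Result(float(stat), 1, p)


def ts_tv(snvs: pd.DataFrame) -> float:
    """Transition/transversion ratio of a SNV table (ref, alt columns)."""
    pairs = list(zip(snvs["ref"], snvs["alt"]))
    ts = sum(p in _TS_PAIRS for p in pairs)
    tv = len(pairs) - ts
    if tv == 0:
        raise ZeroDivisionError("no transversions: Ts/Tv undefined")
    return ts / tv


def density_windows(calls: pd.DataFrame, chrom_lengths: dict[str, int],
                    window: int = 1_000_000, step: int = 100_000) -> pd.DataFrame:
    """Sliding-window SNV counts by zygosity.

    Half-open windows ``[k*step, k*step + window)`` per chromosome, for
    all k with window start inside the chromosome.  Returns chrom, start,
    end, het, hom.
    """
    if not (window >= step > 0):
        raise ValueError("need window >= step > 0")
    rows = []
    for chrom, L in chrom_lengths.items():
        sub = calls[calls["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        het = (sub["zygosity"] == "het").to_numpy()
        starts = np.arange(0, L, step)
        for s in starts:
            e = min(int(s) + window, L)
            inside = (pos >= s) & (pos < e)
            rows.append({"chrom": chrom, "start": int(s), "end": e,
                         "het": int((inside & het).sum()),
                         "hom": int((inside & ~het).sum())})
    return pd.DataFrame(rows)
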