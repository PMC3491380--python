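"""Structural-variant detection from gapped-alignment and mate-pair evidence.

Small indels (deletions < 12 bp, insertions < 4 bp — the limits of the
gapped short-read caller) come from pre-extracted alignment support and
are filtered on supporting reads and reference-assembly QV.  Large
indels are detected from mate-pair spans that fall outside the library
insert range: deletions inflate the observed span, insertions deflate
it; discordant pairs of the same sign are clustered and sized against
the insert-range midpoint.  Inversions are screened by counting
orientation-incongruent pairs in sliding windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import intervals as iv

__all__ = ["SmallIndelThresholds", "LibrarySpec", "LargeIndelCall",
           "InversionWindow", "call_small_indels", "small_indel_profile",
           "detect_large_indels", "merge_calls", "inversion_scan",
           "sv_context"]

MAX_DEL_LEN = 12   # deletions strictly shorter than this are callable
MAX_INS_LEN = 4    # insertions strictly shorter than this are callable


@dataclass(frozen=True)
class SmallIndelThresholds:
    min_support: int = 3
    min_ref_qv: int = 45
    hom_fraction: float = 0.75  # supporting fraction at/above which a call is hom


@dataclass(frozen=True)
class LibrarySpec:
    """A mate-pair library and its expected insert range."""

    id: str
    insert_min: int
    insert_max: int

    def __post_init__(self):
        if not 0 < self.insert_min < self.insert_max:
            raise ValueError("need 0 < insert_min < insert_max")

    @property
    def midpoint(self) -> float:
        return (self.insert_min + self.insert_max) / 2.0


@dataclass
class LargeIndelCall:
    chrom: str
    start: int
    end: int
    svtype: str           # 'ins' | 'del'
    size: float
    support: int
    libraries: frozenset[str]
    repeat_context: bool = False
    gap_context: bool = False


@dataclass(frozen=True)
class InversionWindow:
    chrom: str
    start: int
    end: int
    incongruent: int
    flagged: bool


def call_small_indels(evidence: pd.DataFrame, ref_qv: dict[str, np.ndarray],
                      thresholds: SmallIndelThresholds = SmallIndelThresholds()
                      ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Filter gapped-alignment indel candidates.

    ``evidence`` columns: chrom, pos, vtype (ins/del), length, support,
    depth.  Candidates out of the caller's length range are tallied as
    out_of_range; the rest must pass support and reference-QV filters.
    Zygosity is hom when the supporting fraction reaches
    ``hom_fraction``, else het.
    """
    ev = evidence.copy()
    is_del = ev["vtype"].to_numpy() == "del"
    length = ev["length"].to_numpy()
    out_of_range = np.where(is_del, length >= MAX_DEL_LEN, length >= MAX_INS_LEN)
    site_qv = np.array([ref_qv[c][p] for c, p in zip(ev["chrom"], ev["pos"])],
                       dtype=int)
    low_support = ev["support"].to_numpy() < thresholds.min_support
    low_qv = site_qv < thresholds.min_ref_qv
    tally = {
        "out_of_range": int(out_of_range.sum()),
        "support": int((~out_of_range & low_support).sum()),
        "ref_qv": int((~out_of_range & ~low_support & low_qv).sum()),
    }
    keep = ~(out_of_range | low_support | low_qv)
    out = ev[keep].reset_index(drop=True)
    frac = out["support"] / out["depth"].clip(lower=1)
    out["zygosity"] = np.where(frac >= thresholds.hom_fraction, "hom", "het")
    out["ref_qv"] = site_qv[keep]
    return out, tally


def small_indel_profile(evidence: pd.DataFrame, ref_qv: dict[str, np.ndarray],
                        callable_per_qv: pd.Series,
                        thresholds: SmallIndelThresholds = SmallIndelThresholds()
                        ) -> pd.DataFrame:
    """Indel discovery rate per reference-QV value, before the QV filter.

    ``callable_per_qv`` maps QV value -> number of callable sites at that
    QV (the rate denominator).  Support and length filters apply; the
    reference-QV filter does not (the profile is its diagnostic).
    """
    relaxed = SmallIndelThresholds(min_support=thresholds.min_support,
                                   min_ref_qv=0,
                                   hom_fraction=thresholds.hom_fraction)
    calls, _ = call_small_indels(evidence, ref_qv, relaxed)
    per_qv = calls.groupby(["ref_qv", "vtype"]).size().unstack(fill_value=0)
    rows = []
    for qv, callable_n in callable_per_qv.items():
        if callable_n == 0:
            continue
        n_del = int(per_qv["del"].get(qv, 0)) if "del" in per_qv else 0
        n_ins = int(per_qv["ins"].get(qv, 0)) if "ins" in per_qv else 0
        rows.append({"ref_qv": qv, "callable": int(callable_n),
                     "del_rate": n_del / callable_n,
                     "ins_rate": n_ins / callable_n})
    return pd.DataFrame(rows)


def detect_large_indels(pairs: pd.DataFrame, lib: LibrarySpec,
                        min_support: int = 3) -> list[LargeIndelCall]:
    """Cluster insert-size-discordant mate pairs into large-indel calls.

    A pair is a deletion signal when its reference span exceeds
    ``insert_max`` and an insertion signal when it falls below
    ``insert_min``.  Same-sign discordant pairs are clustered while
    their implied intervals (the inner gap between tags) overlap; a
    cluster of at least ``min_support`` pairs becomes a call with size
    |median span - insert-range midpoint| and interval the intersection
    of its supporting pairs' inner gaps.
    """
    p = pairs[pairs["library"] == lib.id] if "library" in pairs else pairs
    calls: list[LargeIndelCall] = []
    for chrom, sub in p.groupby("chrom", sort=False):
        span = sub["span"].to_numpy()
        for svtype, mask in (("del", span > lib.insert_max),
                             ("ins", span < lib.insert_min)):
            d = sub[mask].sort_values("pos1")
            if len(d) == 0:
                continue
            pos1 = d["pos1"].to_numpy()
            pos2 = d["pos2"].to_numpy()
            spn = d["span"].to_numpy()
            cluster: list[int] = []
            lo = hi = None

            def flush():
                if len(cluster) >= min_support:
                    size = abs(float(np.median(spn[cluster])) - lib.midpoint)
                    s, e = int(lo), int(hi)
                    if e - s < size:
                        # inner-gap intersections can collapse to a sliver
                        # (especially for insertions); widen to the size
                        # estimate so cross-library merging sees
                        # commensurate intervals
                        mid = (s + e) // 2
                        s, e = mid - int(size / 2), mid + int(np.ceil(size / 2))
                    calls.append(LargeIndelCall(
                        chrom=chrom, start=s, end=e, svtype=svtype,
                        size=size, support=len(cluster),
                        libraries=frozenset([lib.id])))

            for i in range(len(d)):
                s, e = int(pos1[i]), int(pos2[i])  # inner gap of the pair
                if not cluster:
                    cluster, lo, hi = [i], s, e
                elif s < hi:  # overlaps running intersection
                    cluster.append(i)
                    lo, hi = max(lo, s), min(hi, e)
                else:
                    flush()
                    cluster, lo, hi = [i], s, e
            flush()
    return calls


def merge_calls(calls_a: list[LargeIndelCall], calls_b: list[LargeIndelCall],
                min_reciprocal_overlap: float = 0.5) -> list[LargeIndelCall]:
    """Merge same-type calls across libraries by reciprocal overlap.

    Calls whose intervals reciprocally overlap by at least
    ``min_reciprocal_overlap`` are joined transitively (connected
    components); the merged size is the support-weighted mean and the
    source-library sets are unioned.
    """
    pool = list(calls_a) + list(calls_b)
    n = len(pool)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            a, b = pool[i], pool[j]
            if a.chrom != b.chrom or a.svtype != b.svtype:
                continue
            ov = min(a.end, b.end) - max(a.start, b.start)
            la, lb = max(1, a.end - a.start), max(1, b.end - b.start)
            if ov > 0 and ov / la >= min_reciprocal_overlap \
                    and ov / lb >= min_reciprocal_overlap:
                union(i, j)

    groups: dict[int, list[LargeIndelCall]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(pool[i])
    merged = []
    for members in groups.values():
        support = sum(m.support for m in members)
        size = sum(m.size * m.support for m in members) / support
        merged.append(LargeIndelCall(
            chrom=members[0].chrom,
            start=min(m.start for m in members),
            end=max(m.end for m in members),
            svtype=members[0].svtype, size=size, support=support,
            libraries=frozenset().union(*(m.libraries for m in members))))
    merged.sort(key=lambda c: (c.chrom, c.start))
    return merged


def inversion_scan(pairs: pd.DataFrame, chrom_lengths: dict[str, int],
                   window: int = 500, step: int = 250,
                   min_count: int = 50) -> list[InversionWindow]:
    """Count orientation-incongruent pairs in sliding windows.

    A pair is binned by the window(s) containing its leftmost tag; a
    window is flagged when its incongruent count reaches ``min_count``.
    Only windows with at least one incongruent pair are returned.
    """
    out: list[InversionWindow] = []
    inc = pairs[~pairs["congruent"].astype(bool)]
    for chrom, L in chrom_lengths.items():
        sub = inc[inc["chrom"] == chrom]
        if len(sub) == 0:
            continue
        left = np.minimum(sub["pos1"].to_numpy(), sub["pos2"].to_numpy())
        for s in range(0, L, step):
            e = min(s + window, L)
            count = int(((left >= s) & (left < e)).sum())
            if count > 0:
                out.append(InversionWindow(chrom, s, e, count,
                                           flagged=count >= min_count))
    return out


def sv_context(calls: list[LargeIndelCall], repeat_mask: dict[str, np.ndarray],
               gap_mask: dict[str, np.ndarray]
               ) -> tuple[list[LargeIndelCall], pd.DataFrame]:
    """Flag calls overlapping repeat or assembly-gap (N-run) intervals.

    Returns flagged copies of the calls and a tally of flags by SV type.
    """
    empty = np.empty((0, 2), dtype=np.int64)
    flagged = []
    for c in calls:
        rep = bool(iv.overlaps_any([c.start], [c.end],
                                   iv.merge(repeat_mask.get(c.chrom, empty)))[0])
        gap = bool(iv.overlaps_any([c.start], [c.end],
                                   iv.merge(gap_mask.get(c.chrom, empty)))[0])
        flagged.append(LargeIndelCall(c.chrom, c.start, c.end, c.svtype, c.size,
                                      c.support, c.libraries, rep, gap))
    rows = []
    for svtype in ("ins", "del"):
        sub = [c for c in flagged if c.svtype == svtype]
        rows.append({"svtype": svtype, "n": len(sub),
                     "repeat_context": sum(c.repeat_context for c in sub),
                     "gap_context": sum(c.gap_context for c in sub)})
    return flagged, pd.DataFrame(rows)
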