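"""Summary-table aggregation and formatting.

Builds the study-style summary tables: a sequencing-library table
(reads, mapped reads, analyzed reads, coverage depth with percentage
columns) and a per-chromosome-class variant table (heterozygous /
homozygous SNVs and annotation-class counts), each with a totals row
that is checked to be the exact column sum.  Percentages round half-up,
matching the tables' printed style.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = ["percent", "aggregate_sequencing_summary", "aggregate_variant_summary"]


def percent(part: float, whole: float, decimals: int = 1) -> float:
    """100 * part / whole, rounded half-up to ``decimals`` places."""
    if whole <= 0:
        raise ValueError("percentage undefined for whole <= 0")
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(100.0 * part / whole).quantize(q, rounding=ROUND_HALF_UP))


_SEQ_COUNT_COLS = ["runs", "reads", "mapped_reads", "analyzed_reads", "coverage_depth"]


def aggregate_sequencing_summary(rows: pd.DataFrame) -> pd.DataFrame:
    """Append a totals row to a sequencing-library summary.

    ``rows`` columns: library, runs, reads, mapped_reads, analyzed_reads,
    coverage_depth.  The totals row sums the count columns; percentage
    columns (mapped_pct, analyzed_pct, of total reads) are recomputed
    for every row including the total.
    """
    if len(rows) == 0:
        raise ValueError("need at least one library row")
    out = rows.copy()
    total = {"library": "Total"}
    for col in _SEQ_COUNT_COLS:
        total[col] = out[col].sum()
    out = pd.concat([out, pd.DataFrame([total])], ignore_index=True)
    out["mapped_pct"] = [percent(m, r, 1) for m, r in zip(out["mapped_reads"], out["reads"])]
    out["analyzed_pct"] = [percent(a, r, 1) for a, r in zip(out["analyzed_reads"], out["reads"])]
    return out


_VARIANT_COLS = ["het_snvs", "hom_snvs", "nonsynonymous", "synonymous",
                 "utr", "intronic", "intergenic"]


def aggregate_variant_summary(rows: pd.DataFrame) -> pd.DataFrame:
    """Append a totals row (exact column sums) to a variant summary.

    ``rows`` columns: chromosome_class plus any of the count columns
    (het_snvs, hom_snvs, nonsynonymous, synonymous, utr, intronic,
    intergenic).  Missing cells (e.g. het SNVs on a hemizygous X) count
    as zero.
    """
    if len(rows) == 0:
        raise ValueError("need at least one row")
    out = rows.copy()
    total = {"chromosome_class": "Total"}
    for col in _VARIANT_COLS:
        if col in out.columns:
            total[col] = out[col].fillna(0).sum()
    out = pd.concat([out, pd.DataFrame([total])], ignore_index=True)
    return out
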