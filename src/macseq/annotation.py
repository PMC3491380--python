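"""Genomic-context and coding-effect classification of variants.

Sites are classified by a fixed priority over all transcripts overlapping
them (coding exon > non-coding exon (UTR) > intron > intergenic), coding
SNVs by codon translation (synonymous / nonsynonymous / nonsense) and
coding indels by frame preservation (length divisible by 3 or not).
Transcript models are validated against the reference before use: CDS
length must be a multiple of 3, the CDS must not contain internal stop
codons, intervals must lie within chromosome bounds, and genes mapped to
multiple genomic loci are dropped entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import intervals as iv

__all__ = [
    "Transcript",
    "AnnotationSet",
    "AnnotationIndex",
    "validate_models",
    "classify_site",
    "snv_effect",
    "indel_effect",
    "repeat_overlap",
    "effect_table",
]

SITE_CLASSES = ("coding_exon", "noncoding_exon", "intron", "intergenic")
_PRIORITY = {c: i for i, c in enumerate(SITE_CLASSES)}


@dataclass(frozen=True)
class Transcript:
    """A protein-coding transcript model.

    ``exons`` and ``cds`` are tuples of 0-based half-open ``(start, end)``
    intervals in genomic order (ascending), with CDS a subset of the exons.
    """

    tx_id: str
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def cds_positions(self) -> np.ndarray:
        """Genomic positions of CDS bases in *coding* order (5'->3')."""
        pos = np.concatenate([np.arange(s, e) for s, e in self.cds])
        return pos[::-1] if self.strand == "-" else pos

    def coding_sequence(self, ref) -> str:
        parts = [ref.fetch(self.chrom, s, e) for s, e in self.cds]
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass
class AnnotationSet:
    """A bag of transcript models plus chromosome sizes."""

    transcripts: list[Transcript]
    chrom_lengths: dict[str, int]

    @property
    def gene_ids(self) -> set[str]:
        return {t.gene_id for t in self.transcripts}


def _gene_locus_count(txs: list[Transcript]) -> int:
    """Number of distinct genomic loci covered by one gene's transcripts.

    Transcripts are clustered by span overlap per chromosome; each cluster
    is one locus.
    """
    n = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for t in txs:
        by_chrom.setdefault(t.chrom, []).append(t.span)
    for spans in by_chrom.values():
        n += len(iv.merge(spans))
    return n


def validate_models(annotation: AnnotationSet, ref) -> tuple[list[Transcript], pd.DataFrame]:
    """Filter transcript models against the reference sequence.

    Returns the retained transcripts and a table of rejects with the first
    failing reason per transcript (``bounds``, ``cds_frame``,
    ``internal_stop``, ``multi_locus``).
    """
    by_gene: dict[str, list[Transcript]] = {}
    for t in annotation.transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    multi = {g for g, txs in by_gene.items() if _gene_locus_count(txs) > 1}

    retained, rejects = [], []

    def reject(t, reason):
        rejects.append({"tx_id": t.tx_id, "gene_id": t.gene_id, "reason": reason})

    for t in annotation.transcripts:
        length = annotation.chrom_lengths.get(t.chrom)
        if t.gene_id in multi:
            reject(t, "multi_locus")
            continue
        if length is None or t.span[0] < 0 or t.span[1] > length:
            reject(t, "bounds")
            continue
        if t.cds_length % 3 != 0 or t.cds_length == 0:
            reject(t, "cds_frame")
            continue
        aa = str(Seq(t.coding_sequence(ref)).translate())
        if "*" in aa[:-1]:
            reject(t, "internal_stop")
            continue
        retained.append(t)
    return retained, pd.DataFrame(rejects, columns=["tx_id", "gene_id", "reason"])


class AnnotationIndex:
    """Interval indexes over validated transcripts for fast classification.

    Builds, per chromosome, canonical masks for CDS, UTR (exonic non-CDS)
    and intron, applied in priority order, plus a position->transcript map
    for coding-effect lookups.
    """

    def __init__(self, transcripts: list[Transcript], chrom_lengths: dict[str, int]):
        self.transcripts = list(transcripts)
        self.chrom_lengths = dict(chrom_lengths)
        cds, utr, intron = {}, {}, {}
        for c in chrom_lengths:
            cds_l, exon_l, span_l = [], [], []
            for t in self.transcripts:
                if t.chrom != c:
                    continue
                cds_l.extend(t.cds)
                exon_l.extend(t.exons)
                span_l.append(t.span)
            cds[c] = iv.merge(cds_l)
            utr[c] = iv.merge(exon_l)
            intron[c] = iv.merge(span_l)
        self.cds_mask, self.utr_mask, self.intron_mask = cds, utr, intron
        self._by_chrom: dict[str, list[Transcript]] = {}
        for t in self.transcripts:
            self._by_chrom.setdefault(t.chrom, []).append(t)

    def classify_positions(self, chrom: str, pos) -> np.ndarray:
        """Priority site class for each position (vectorised).

        Returns an object array over ``SITE_CLASSES``.
        """
        pos = np.asarray(pos, dtype=np.int64)
        out = np.full(pos.shape, "intergenic", dtype=object)
        out[iv.point_in(pos, self.intron_mask.get(chrom, np.empty((0, 2), int)))] = "intron"
        out[iv.point_in(pos, self.utr_mask.get(chrom, np.empty((0, 2), int)))] = "noncoding_exon"
        out[iv.point_in(pos, self.cds_mask.get(chrom, np.empty((0, 2), int)))] = "coding_exon"
        return out

    def coding_transcript_at(self, chrom: str, pos: int) -> Transcript | None:
        """Transcript whose CDS covers ``pos``; longest CDS wins ties."""
        best = None
        for t in self._by_chrom.get(chrom, []):
            if any(s <= pos < e for s, e in t.cds):
                if best is None or t.cds_length > best.cds_length:
                    best = t
        return best


def classify_site(pos: int, chrom: str, index: AnnotationIndex) -> str:
    """Site class of a single position under the priority rule."""
    return str(index.classify_positions(chrom, [pos])[0])


def snv_effect(pos: int, alt: str, transcript: Transcript, ref) -> str:
    """Coding effect of a SNV inside the CDS of ``transcript``.

    The codon containing the site is extracted in coding orientation
    (reverse-complemented on the minus strand), the alternate base is
    substituted, and both codons are translated with the standard nuclear
    code.  Returns ``synonymous``, ``nonsynonymous``, ``nonsense`` (new
    stop), or ``unknown`` when the reference codon contains N.
    """
    cds_pos = transcript.cds_positions()
    hits = np.flatnonzero(cds_pos == pos)
    if len(hits) == 0:
        raise ValueError(f"position {pos} not in CDS of {transcript.tx_id}")
    i = int(hits[0])
    codon_start = i - i % 3
    codon_positions = cds_pos[codon_start:codon_start + 3]
    if len(codon_positions) < 3:
        return "unknown"  # truncated terminal codon

    def base_at(p: int) -> str:
        b = ref.fetch(transcript.chrom, p, p + 1)
        return str(Seq(b).complement()) if transcript.strand == "-" else b

    codon = [base_at(int(p)) for p in codon_positions]
    if any(b not in "ACGT" for b in codon):
        return "unknown"
    alt_coding = str(Seq(alt).complement()) if transcript.strand == "-" else alt
    mutated = list(codon)
    mutated[i % 3] = alt_coding
    aa_ref = str(Seq("".join(codon)).translate())
    aa_alt = str(Seq("".join(mutated)).translate())
    if aa_alt == aa_ref:
        return "synonymous"
    if aa_alt == "*":
        return "nonsense"
    return "nonsynonymous"


def indel_effect(length: int, site_class: str) -> str:
    """Frame consequence of an indel: frameshift / in_frame in coding exons,
    ``none`` elsewhere."""
    if length <= 0:
        raise ValueError("indel length must be positive")
    if site_class != "coding_exon":
        return "none"
    return "in_frame" if length % 3 == 0 else "frameshift"


def repeat_overlap(variants: pd.DataFrame, repeat_mask: dict[str, np.ndarray]) -> np.ndarray:
    """Flag variants whose reference interval intersects the repeat mask.

    ``variants`` needs ``chrom``, ``pos`` and optionally ``ref_span``
    (reference bases consumed; defaults to 1 for SNVs/insertions).
    """
    flags = np.zeros(len(variants), dtype=bool)
    span = variants["ref_span"].to_numpy() if "ref_span" in variants else np.ones(len(variants), dtype=np.int64)
    pos = variants["pos"].to_numpy()
    for chrom, idx in variants.groupby("chrom", sort=False).indices.items():
        mask = repeat_mask.get(chrom, np.empty((0, 2), dtype=np.int64))
        flags[idx] = iv.overlaps_any(pos[idx], pos[idx] + span[idx], mask)
    return flags


def effect_table(variants: pd.DataFrame, index: AnnotationIndex, ref,
                 repeat_mask: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
    """Annotate a variant table with site class, coding effect and indel effect.

    ``variants`` columns: chrom, pos, ref, alt, and optionally ``vtype``
    (``snv``/``ins``/``del``, default snv) and ``length`` for indels.
    Every variant receives exactly one site class; coding effects are
    computed against the longest-CDS transcript covering the site.
    """
    df = variants.copy()
    if "vtype" not in df:
        df["vtype"] = "snv"
    site = np.empty(len(df), dtype=object)
    for chrom, idx in df.groupby("chrom", sort=False).indices.items():
        site[idx] = index.classify_positions(chrom, df["pos"].to_numpy()[idx])
    df["site_class"] = site

    coding = np.full(len(df), "none", dtype=object)
    indel = np.full(len(df), "none", dtype=object)
    pos_arr = df["pos"].to_numpy()
    for i, (chrom, p, alt, vtype, sclass) in enumerate(
        zip(df["chrom"], pos_arr, df["alt"], df["vtype"], df["site_class"])
    ):
        if sclass != "coding_exon":
            continue
        if vtype == "snv":
            tx = index.coding_transcript_at(chrom, int(p))
            if tx is not None:
                coding[i] = snv_effect(int(p), alt, tx, ref)
        else:
            length = int(df["length"].iloc[i]) if "length" in df else len(alt)
            indel[i] = indel_effect(length, sclass)
    df["coding_effect"] = coding
    df["indel_effect"] = indel
    if repeat_mask is not None:
        df["repeat_overlap"] = repeat_overlap(df, repeat_mask)
    return df
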