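"""Synthetic reference assemblies and gene annotations.

The reference emulates a draft mammalian assembly: random base
composition, a per-base Phred assembly-quality (QV) track dominated by
QV 60 with lower-quality blocks, assembly gaps (N runs) and a repeat
mask.  Gene models are simple multi-exon protein-coding transcripts with
valid open reading frames, built so that overlapping feature classes
exercise the site-priority rules downstream.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .. import intervals as iv
from ..annotation import AnnotationSet, Transcript

__all__ = ["SimulationConfig", "StructuralVariant", "ReferenceAssembly",
           "simulate_reference", "simulate_annotation"]

BASES = np.frombuffer(b"ACGT", dtype="S1")
# transition partner of A,C,G,T (A<->G, C<->T)
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class StructuralVariant:
    """A planted large indel or inversion (reference coordinates)."""

    chrom: str
    pos: int
    svtype: str  # 'del' | 'ins' | 'inv'
    length: int

    def __post_init__(self):
        if self.svtype not in ("del", "ins", "inv"):
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if self.length <= 0:
            raise ValueError("SV length must be positive")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic resequencing study.

    Defaults follow the macaque study conditions: mutation rate
    2.5e-8 /site/generation, ~0.4% divergence from the reference,
    transition:transversion bias 2.39, 41.5x mean depth, 94% of the
    assembly at QV 60, and mate-pair libraries with 600-800 and
    800-1000 bp inserts.  The recombination rate is a conventional
    primate-scale placeholder (1e-8).
    """

    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 1_000_000})
    mutation_rate: float = 2.5e-8
    recombination_rate: float = 1.0e-8
    ts_tv_bias: float = 2.39
    reference_divergence: float = 0.004
    small_indel_rate: float = 3.0e-4
    indel_del_fraction: float = 0.6
    planted_svs: tuple[StructuralVariant, ...] = ()
    mean_depth: float = 41.5
    base_error_rate: float = 0.01
    libraries: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"A": (600, 800), "B": (800, 1000)})
    qv60_fraction: float = 0.94
    qv_block_length: int = 200
    gap_density: float = 0.001
    gap_mean_length: int = 500
    repeat_density: float = 0.05
    repeat_mean_length: int = 300
    rng_seed: int = 0

    def __post_init__(self):
        for name, L in self.chrom_lengths.items():
            if L <= 0:
                raise ValueError(f"chromosome {name!r} must have positive length")
        for r in (self.mutation_rate, self.recombination_rate,
                  self.reference_divergence, self.small_indel_rate,
                  self.mean_depth, self.base_error_rate, self.gap_density,
                  self.repeat_density):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if not 0.0 <= self.qv60_fraction <= 1.0:
            raise ValueError("qv60_fraction must lie in [0, 1]")
        for lib, (lo, hi) in self.libraries.items():
            if not 0 < lo < hi:
                raise ValueError(f"library {lib!r}: insert range must satisfy 0 < min < max")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-stage stream derived from the root seed."""
        tag = zlib.crc32(stream.encode()) % (2**31)
        seq = np.random.SeedSequence([self.rng_seed, tag])
        return np.random.default_rng(seq)


@dataclass
class ReferenceAssembly:
    """Reference sequence plus assembly-quality and mask tracks.

    ``chroms`` maps name -> uppercase sequence string over ACGTN;
    ``qv`` maps name -> int16 Phred array of identical length; ``gaps``
    and ``repeats`` are canonical half-open interval arrays.  The gap
    mask exactly marks the N runs.
    """

    chroms: dict[str, str]
    qv: dict[str, np.ndarray]
    gaps: dict[str, np.ndarray]
    repeats: dict[str, np.ndarray]

    def __post_init__(self):
        for c, seq in self.chroms.items():
            if len(self.qv[c]) != len(seq):
                raise ValueError(f"QV track length mismatch on {c}")

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.chroms.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.chroms[chrom][start:end]

    def codes(self, chrom: str) -> np.ndarray:
        """Sequence as uint8 codes 0..3 (ACGT), 4 for N."""
        raw = np.frombuffer(self.chroms[chrom].encode(), dtype="S1")
        out = np.full(len(raw), 4, dtype=np.uint8)
        for i, b in enumerate(BASES):
            out[raw == b] = i
        return out


def _draw_intervals(rng, length: int, density: float, mean_len: int) -> np.ndarray:
    """Poisson-placed intervals with exponential lengths covering ~density."""
    if density <= 0 or length == 0:
        return np.empty((0, 2), dtype=np.int64)
    n = rng.poisson(density * length / mean_len)
    if n == 0:
        return np.empty((0, 2), dtype=np.int64)
    starts = rng.integers(0, length, size=n)
    lens = np.maximum(1, rng.exponential(mean_len, size=n).astype(np.int64))
    ends = np.minimum(length, starts + lens)
    return iv.merge(np.stack([starts, ends], axis=1))


def simulate_reference(config: SimulationConfig) -> ReferenceAssembly:
    """Draw a reference assembly with QV track, gaps and repeats.

    The QV track is blockwise: contiguous blocks (geometric length,
    mean ``qv_block_length``) are QV 60 with probability
    ``qv60_fraction`` and otherwise uniform in 20..59, mimicking locally
    correlated draft-assembly quality.
    """
    rng = config.rng("reference")
    chroms, qvs, gaps, repeats = {}, {}, {}, {}
    for name, L in config.chrom_lengths.items():
        seq = BASES[rng.integers(0, 4, size=L)]
        gap_mask = _draw_intervals(rng, L, config.gap_density, config.gap_mean_length)
        for s, e in gap_mask:
            seq[s:e] = b"N"
        # blockwise QV track
        n_blocks = max(1, int(np.ceil(L / config.qv_block_length * 2)))
        block_lens = np.maximum(1, rng.geometric(1.0 / config.qv_block_length, size=n_blocks))
        while block_lens.sum() < L:
            block_lens = np.concatenate(
                [block_lens, np.maximum(1, rng.geometric(1.0 / config.qv_block_length, size=n_blocks))])
        is60 = rng.random(len(block_lens)) < config.qv60_fraction
        block_qv = np.where(is60, 60, rng.integers(20, 60, size=len(block_lens)))
        qv = np.repeat(block_qv, block_lens)[:L].astype(np.int16)
        chroms[name] = seq.tobytes().decode()
        qvs[name] = qv
        gaps[name] = gap_mask
        repeats[name] = _draw_intervals(rng, L, config.repeat_density, config.repeat_mean_length)
    return ReferenceAssembly(chroms, qvs, gaps, repeats)


def simulate_annotation(config: SimulationConfig, ref: ReferenceAssembly,
                        n_genes: int = 50, exons_per_gene: int = 3,
                        exon_length: int = 150, intron_length: int = 300,
                        utr_length: int = 60,
                        overlap_fraction: float = 0.1) -> AnnotationSet:
    """Place multi-exon protein-coding gene models on the reference.

    Each gene gets one transcript with ``exons_per_gene`` exons, UTRs on
    the terminal exons and a CDS whose length is a multiple of 3 and
    whose reading frame is repaired to contain no internal stop codon
    (internal stops are edited out of the reference).  A fraction of
    genes is placed overlapping the previous gene (on the opposite
    strand) so that site-priority rules are exercised.
    """
    rng = config.rng("annotation")
    transcripts: list[Transcript] = []
    lengths = ref.lengths
    names = list(lengths)
    gene_span = exons_per_gene * exon_length + (exons_per_gene - 1) * intron_length
    gi = 0
    prev_start: dict[str, int] = {}
    while gi < n_genes:
        chrom = names[gi % len(names)]
        L = lengths[chrom]
        if L < gene_span + 2:
            raise ValueError(f"chromosome {chrom} too short for gene models")
        gap_mask = ref.gaps.get(chrom, np.empty((0, 2), dtype=np.int64))
        if chrom in prev_start and rng.random() < overlap_fraction:
            start = min(prev_start[chrom] + exon_length // 2, L - gene_span - 1)
        else:
            # keep gene models clear of assembly gaps (N runs)
            for _ in range(200):
                start = int(rng.integers(0, L - gene_span))
                if not iv.overlaps_any([start], [start + gene_span], gap_mask)[0]:
                    break
            else:
                raise ValueError(f"could not place a gap-free gene on {chrom}")
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        p = start
        for _ in range(exons_per_gene):
            exons.append((p, p + exon_length))
            p += exon_length + intron_length
        # CDS trims the UTRs off the terminal exons; total must be %3 == 0
        cds = [list(e) for e in exons]
        cds[0][0] += utr_length
        cds[-1][1] -= utr_length
        total = sum(e - s for s, e in cds)
        cds[-1][1] -= total % 3
        tx = Transcript(
            tx_id=f"tx{gi}", gene_id=f"gene{gi}", chrom=chrom, strand=strand,
            exons=tuple(map(tuple, exons)), cds=tuple(map(tuple, cds)))
        _repair_orf(tx, ref, rng)
        transcripts.append(tx)
        prev_start[chrom] = start
        gi += 1
    return AnnotationSet(transcripts, dict(lengths))


def _repair_orf(tx: Transcript, ref: ReferenceAssembly, rng) -> None:
    """Edit the reference in place so the transcript has a clean ORF.

    Internal stop codons (and Ns within the CDS) are replaced by random
    sense codons; the mutation is written back through the reference
    sequence in genomic orientation.
    """
    sense = [c for c in ("".join(p) for p in itertools.product("ACGT", repeat=3))
             if c not in ("TAA", "TAG", "TGA")]
    pos = tx.cds_positions()
    seq = tx.coding_sequence(ref)
    codons = [seq[i:i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
    edits: dict[int, str] = {}
    for ci, codon in enumerate(codons):
        bad = codon in ("TAA", "TAG", "TGA") and ci < len(codons) - 1
        if bad or "N" in codon:
            new = sense[rng.integers(0, len(sense))]
            for k in range(3):
                gpos = int(pos[3 * ci + k])
                base = new[k]
                if tx.strand == "-":
                    base = str(Seq(base).complement())
                edits[gpos] = base
    if edits:
        s = list(ref.chroms[tx.chrom])
        for gpos, base in edits.items():
            s[gpos] = base
        ref.chroms[tx.chrom] = "".join(s)
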