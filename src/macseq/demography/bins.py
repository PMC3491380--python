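"""Input binning and time-grid plumbing for SMC demographic inference.

The genome is reduced to 100-bp bins with a three-letter alphabet:
``K`` (at least one retained heterozygous SNV), ``T`` (callable, no
het) and ``N`` (insufficiently callable).  Inference runs on a
discretised scaled-time grid with exponentially spaced boundaries;
atomic intervals are tied into parameter groups by a pattern string
such as ``"6+29*2"`` (one group spanning 6 atomic intervals, then 29
groups of 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BinSequence", "TimeGrid", "make_bins", "bins_from_het_positions",
           "parse_pattern", "time_grid"]

SYM_T, SYM_K, SYM_N = 0, 1, 2
_SYMBOLS = "TKN"


@dataclass
class BinSequence:
    """Per-chromosome bin symbols (uint8 codes over T/K/N)."""

    bin_size: int
    chroms: dict[str, np.ndarray]

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for c, a in self.chroms.items():
            if a.dtype != np.uint8 or (a > 2).any():
                raise ValueError(f"invalid symbols on {c}")

    @property
    def n_bins(self) -> int:
        return sum(len(a) for a in self.chroms.values())

    def counts(self) -> dict[str, int]:
        tot = np.zeros(3, dtype=np.int64)
        for a in self.chroms.values():
            tot += np.bincount(a, minlength=3)
        return {"T": int(tot[0]), "K": int(tot[1]), "N": int(tot[2])}

    def to_text(self) -> str:
        """FASTA-like text: one header per chromosome, 60 symbols/line."""
        lines = []
        for c, a in self.chroms.items():
            lines.append(f">{c} bin_size={self.bin_size}")
            s = "".join(_SYMBOLS[x] for x in a)
            lines.extend(s[i:i + 60] for i in range(0, len(s), 60))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "BinSequence":
        chroms: dict[str, list[str]] = {}
        bin_size = 100
        name = None
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                fields = line[1:].split()
                name = fields[0]
                for f in fields[1:]:
                    if f.startswith("bin_size="):
                        bin_size = int(f.split("=", 1)[1])
                chroms[name] = []
            else:
                if name is None:
                    raise ValueError("symbol line before any header")
                chroms[name].append(line)
        arrays = {}
        for c, parts in chroms.items():
            s = "".join(parts)
            bad = set(s) - set(_SYMBOLS)
            if bad:
                raise ValueError(f"unknown symbols {bad} on {c}")
            arrays[c] = np.frombuffer(
                s.translate(str.maketrans("TKN", "\x00\x01\x02")).encode("latin1"),
                dtype=np.uint8).copy()
        return cls(bin_size, arrays)


def make_bins(calls: pd.DataFrame, callable_mask: dict[str, np.ndarray],
              bin_size: int = 100,
              min_callable_fraction: float = 0.5) -> BinSequence:
    """Bin retained calls into the T/K/N alphabet.

    A bin is ``K`` when it contains at least one retained heterozygous
    SNV, ``N`` when less than ``min_callable_fraction`` of its bases are
    callable, and ``T`` otherwise.  ``callable_mask`` is a dense boolean
    array per chromosome.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    chroms = {}
    for chrom, mask in callable_mask.items():
        L = len(mask)
        n = (L + bin_size - 1) // bin_size
        padded = np.zeros(n * bin_size, dtype=bool)
        padded[:L] = mask
        frac = padded.reshape(n, bin_size).mean(axis=1)
        # the tail bin's denominator is its real width
        if L % bin_size:
            frac[-1] = mask[(n - 1) * bin_size:].mean()
        sym = np.where(frac < min_callable_fraction, SYM_N, SYM_T).astype(np.uint8)
        sub = calls[(calls["chrom"] == chrom) & (calls["zygosity"] == "het")]
        if len(sub):
            k_bins = np.unique(sub["pos"].to_numpy() // bin_size)
            sym[k_bins[k_bins < n]] = SYM_K
        chroms[chrom] = sym
    return BinSequence(bin_size, chroms)


def bins_from_het_positions(het_positions: dict[str, np.ndarray],
                            chrom_lengths: dict[str, int],
                            bin_size: int = 100) -> BinSequence:
    """Bin known heterozygous-site positions with a fully callable genome."""
    chroms = {}
    for chrom, L in chrom_lengths.items():
        n = (L + bin_size - 1) // bin_size
        sym = np.zeros(n, dtype=np.uint8)
        pos = het_positions.get(chrom, np.array([], dtype=np.int64))
        k_bins = np.unique(np.asarray(pos) // bin_size)
        sym[k_bins[k_bins < n]] = SYM_K
        chroms[chrom] = sym
    return BinSequence(bin_size, chroms)


def parse_pattern(text: str) -> list[int]:
    """Parse a grouping pattern like ``"6+29*2"`` into group spans.

    Grammar: terms joined by ``+``; a term is either ``s`` (one group
    spanning s atomic intervals) or ``n*s`` (n groups of span s).
    """
    spans: list[int] = []
    for term in text.replace(" ", "").split("+"):
        if not term:
            raise ValueError(f"empty term in pattern {text!r}")
        if "*" in term:
            n_s = term.split("*")
            if len(n_s) != 2:
                raise ValueError(f"malformed term {term!r}")
            n, s = (int(x) for x in n_s)
            if n <= 0 or s <= 0:
                raise ValueError(f"non-positive term {term!r}")
            spans.extend([s] * n)
        else:
            s = int(term)
            if s <= 0:
                raise ValueError(f"non-positive term {term!r}")
            spans.append(s)
    return spans


@dataclass(frozen=True)
class TimeGrid:
    """Discretised scaled-time grid with parameter grouping.

    ``boundaries`` has ``atomic_count + 1`` strictly increasing entries
    starting at 0; ``group_spans`` ties consecutive atomic intervals to
    shared size parameters.
    """

    boundaries: np.ndarray
    group_spans: tuple[int, ...]

    def __post_init__(self):
        b = self.boundaries
        if b[0] != 0 or (np.diff(b) <= 0).any():
            raise ValueError("boundaries must increase strictly from 0")
        if sum(self.group_spans) != len(b) - 1:
            raise ValueError("group spans must sum to the atomic interval count")

    @property
    def atomic_count(self) -> int:
        return len(self.boundaries) - 1

    @property
    def n_groups(self) -> int:
        return len(self.group_spans)

    @property
    def group_index(self) -> np.ndarray:
        """Atomic interval -> group id."""
        return np.repeat(np.arange(self.n_groups), self.group_spans)


def time_grid(atomic_count: int, t_max: float = 15.0, alpha: float = 0.1,
              pattern: str | None = None) -> TimeGrid:
    """Exponentially spaced boundaries t_k = alpha*(exp(k/n*ln(1+t_max/alpha))-1).

    With no pattern every atomic interval is its own group.
    """
    if atomic_count < 2:
        raise ValueError("need at least 2 atomic intervals")
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    k = np.arange(atomic_count + 1)
    b = alpha * np.expm1(k / atomic_count * np.log1p(t_max / alpha))
    spans = parse_pattern(pattern) if pattern else [1] * atomic_count
    return TimeGrid(b, tuple(spans))
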