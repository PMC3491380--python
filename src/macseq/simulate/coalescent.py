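"""Sequential-coalescent TMRCA machinery for a single diploid genome.

The two haplotypes of one diploid individual coalesce at a locus-specific
time (the TMRCA).  Along a recombining chromosome the TMRCA is piecewise
constant: recombination breaks the genome into tracts, each with its own
coalescence time.  This module samples TMRCA values under a
piecewise-constant demographic history and walks tracts along chromosomes
under the sequentially Markovian coalescent (SMC) approximation with full
resampling at every breakpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DemographicHistory", "TmrcaTract", "simulate_tmrca"]


@dataclass(frozen=True)
class DemographicHistory:
    """Piecewise-constant diploid population size N(t).

    Parameters
    ----------
    epochs : sequence of (start_time, diploid_size)
        ``start_time`` is in generations before present; the first epoch
        must start at 0 and start times must be strictly increasing.  The
        last epoch extends to infinity.
    """

    epochs: tuple[tuple[float, float], ...]

    def __init__(self, epochs) -> None:
        epochs = tuple((float(t), float(n)) for t, n in epochs)
        if not epochs:
            raise ValueError("history needs at least one epoch")
        starts = [t for t, _ in epochs]
        if starts[0] != 0.0:
            raise ValueError("first epoch must start at time 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("epoch start times must be strictly increasing")
        if any(n <= 0 for _, n in epochs):
            raise ValueError("population sizes must be positive")
        object.__setattr__(self, "epochs", epochs)

    @property
    def starts(self) -> np.ndarray:
        return np.array([t for t, _ in self.epochs])

    @property
    def sizes(self) -> np.ndarray:
        return np.array([n for _, n in self.epochs])

    def cumulative_hazard(self, t):
        """Integrated pairwise coalescence rate ``int_0^t dt' / (2 N(t'))``.

        Vectorised over ``t`` (generations).
        """
        t = np.asarray(t, dtype=float)
        starts, sizes = self.starts, self.sizes
        ends = np.append(starts[1:], np.inf)
        # overlap of [0, t] with each epoch
        overlap = np.clip(t[..., None], starts, ends) - starts
        return (overlap / (2.0 * sizes)).sum(axis=-1)

    def cdf(self, t):
        """CDF of the pairwise coalescence time, ``1 - exp(-Lambda(t))``."""
        return -np.expm1(-self.cumulative_hazard(t))

    def sample_tmrca(self, rng: np.random.Generator, size=None) -> np.ndarray:
        """Draw pairwise coalescence times by inverting the hazard."""
        e = rng.exponential(size=size)
        return self.invert_hazard(e)

    def invert_hazard(self, e):
        """Solve ``Lambda(t) = e`` for t; vectorised, exact per epoch."""
        e = np.asarray(e, dtype=float)
        starts, sizes = self.starts, self.sizes
        lam_at_start = self.cumulative_hazard(starts)
        idx = np.searchsorted(lam_at_start, e, side="right") - 1
        idx = np.clip(idx, 0, len(starts) - 1)
        return starts[idx] + (e - lam_at_start[idx]) * 2.0 * sizes[idx]

    def sample_tract_tmrca(self, rng: np.random.Generator, size=None,
                           grid_points: int = 4096) -> np.ndarray:
        """Draw coalescence times from the length-biased density ~ t*f(t).

        This is the distribution of the TMRCA of a *tract* in the
        stationary sequential-coalescent walk: tracts with older TMRCA
        recombine more often (rate proportional to t), so the
        equilibrium per-site TMRCA marginal equals the plain coalescent
        density f only when breakpoint resampling is length-biased.
        Sampled by numeric inverse-CDF on a fine grid (cached).
        """
        cache = getattr(self, "_lb_cache", None)
        if cache is None or cache[2] != grid_points:
            t_hi = float(self.invert_hazard(np.log(1e13)))  # ~1-1e-13 quantile
            t = np.concatenate([[0.0], np.geomspace(t_hi * 1e-8, t_hi, grid_points)])
            dens = t * np.exp(-self.cumulative_hazard(t)) / (2.0 * self._size_at(t))
            cdf = np.concatenate([[0.0], np.cumsum(
                0.5 * (dens[1:] + dens[:-1]) * np.diff(t))])
            cdf /= cdf[-1]
            object.__setattr__(self, "_lb_cache", (t, cdf, grid_points))
            cache = (t, cdf, grid_points)
        t, cdf, _ = cache
        u = rng.random(size=size)
        return np.interp(u, cdf, t)

    def _size_at(self, t):
        idx = np.searchsorted(self.starts, np.asarray(t, dtype=float),
                              side="right") - 1
        return self.sizes[np.clip(idx, 0, len(self.sizes) - 1)]


@dataclass(frozen=True)
class TmrcaTract:
    """A maximal run of sites sharing one coalescence time.

    ``start``/``end`` are 0-based half-open reference coordinates;
    ``tmrca`` is in generations.
    """

    chrom: str
    start: int
    end: int
    tmrca: float


def simulate_tmrca(
    history: DemographicHistory,
    chrom_lengths: dict[str, int],
    recombination_rate: float,
    rng: np.random.Generator,
) -> list[TmrcaTract]:
    """Walk SMC tracts along each chromosome.

    A tract with TMRCA ``T`` ends after an exponential distance with rate
    ``2 * rho * T`` per bp (recombination anywhere on the two branches of
    total length 2T); at each breakpoint the TMRCA is resampled afresh
    (full resampling) from the *length-biased* coalescent density
    ~ t*f(t), the stationary choice for a t-proportional breakpoint
    rate: it makes the per-site TMRCA marginal equal the plain
    coalescent density, so genome heterozygosity obeys pi = 4*N*mu.
    The first tract of each chromosome draws from the plain coalescent.
    ``rho == 0`` yields a single tract per chromosome.
    """
    if recombination_rate < 0:
        raise ValueError("recombination rate must be >= 0")
    tracts: list[TmrcaTract] = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length")
        pos = 0
        first = True
        while pos < length:
            if first:
                t = float(history.sample_tmrca(rng))
                first = False
            else:
                t = float(history.sample_tract_tmrca(rng))
            if recombination_rate == 0.0:
                end = length
            else:
                dist = rng.exponential(1.0 / (2.0 * recombination_rate * t))
                end = min(length, pos + max(1, int(np.ceil(dist))))
            tracts.append(TmrcaTract(chrom, pos, end, t))
            pos = end
    return tracts
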