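"""PSMC-style demographic inference: model and results objects.

:class:`PsmcModel` wraps a binned diploid genome (T/K/N symbols) and a
discretised scaled-time grid; ``fit()`` runs EM (Baum-Welch E-step with
a numerically maximised M-step over the grouped size parameters and the
scaled mutation rate) and returns a :class:`PsmcResults` carrying the
piecewise-constant size trajectory, the log-likelihood path, and
optional block-bootstrap confidence intervals.

Scaled units: time is measured in units of 2*N0 generations, sizes
relative to N0, where N0 = theta / (4 * mu * bin_size).  The
recombination parameter rho is held fixed during EM (default theta/5),
which stabilises the fit at small data sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .bins import BinSequence, TimeGrid, time_grid
from .hmm import HmmParams, forward, sequence_stats, transition_matrix

__all__ = ["SmcModel", "ScalingConstants", "PsmcModel", "PsmcResults",
           "state_quantities", "forward_backward", "scale_fit"]


@dataclass(frozen=True)
class ScalingConstants:
    """Physical scaling: mutation rate per site per generation and
    generation time in years."""

    mu: float = 2.5e-8
    generation_years: float = 6.0

    def __post_init__(self):
        if self.mu <= 0 or self.generation_years <= 0:
            raise ValueError("scaling constants must be positive")


@dataclass(frozen=True)
class SmcModel:
    """Parameters of the discretised SMC HMM."""

    theta: float          # per-bin scaled mutation rate
    rho: float            # per-bin scaled recombination rate
    lambdas: np.ndarray   # relative size per parameter group

    def __post_init__(self):
        if self.theta <= 0 or self.rho <= 0 or (np.asarray(self.lambdas) <= 0).any():
            raise ValueError("theta, rho and all lambdas must be positive")


def state_quantities(grid: TimeGrid, model: SmcModel
                     ) -> tuple[np.ndarray, np.ndarray, HmmParams]:
    """Per-state prior, representative TMRCA and HMM parameters.

    The prior over atomic intervals is the coalescent mass under the
    piecewise-constant sizes (the last interval absorbs the tail to
    infinity); the representative TMRCA of an interval is the mean of
    the coalescent density truncated to it.
    """
    lam = np.asarray(model.lambdas, dtype=float)[grid.group_index]
    b = grid.boundaries
    widths = np.diff(b)
    haz = widths / lam
    cum = np.concatenate([[0.0], np.cumsum(haz)])
    surv = np.exp(-cum)                      # survival at boundaries
    pi = surv[:-1] - surv[1:]
    pi[-1] = surv[-2]                        # tail mass beyond t_{n-1}
    # truncated-exponential mean within each interval
    w = widths / lam
    with np.errstate(over="ignore", invalid="ignore"):
        frac = np.where(w > 1e-12, widths * np.exp(-w) / -np.expm1(-w),
                        lam - widths / 2.0)
    tbar = b[:-1] + lam - frac
    tbar[-1] = b[-2] + lam[-1]               # open-ended last interval
    pi = pi / pi.sum()
    stay = np.exp(-model.rho * tbar)
    # jump target: length-biased prior, the stationary choice for a
    # t-proportional recombination rate (matches the tract simulator)
    jump = pi * tbar
    jump = jump / jump.sum()
    p_k = -np.expm1(-model.theta * tbar)
    emit = np.column_stack([1.0 - p_k, p_k, np.ones_like(p_k)])
    return pi, tbar, HmmParams(stay, pi, jump, emit)


def forward_backward(binseq: BinSequence, model: SmcModel, grid: TimeGrid
                     ) -> tuple[float, dict[str, np.ndarray]]:
    """Log-likelihood and per-bin state posteriors of a bin sequence."""
    _, _, params = state_quantities(grid, model)
    loglik = 0.0
    posteriors: dict[str, np.ndarray] = {}
    from .hmm import backward_stats  # local import to keep namespace tidy

    for chrom, obs in binseq.chroms.items():
        if len(obs) == 0:
            continue
        ll, alpha, c = forward(obs, params)
        loglik += ll
        # recover full posteriors via a second scaled backward pass
        n = params.n_states
        beta = np.ones(n)
        gam = np.empty((len(obs), n))
        gam[-1] = alpha[-1] / alpha[-1].sum()
        for i in range(len(obs) - 2, -1, -1):
            w = params.emit[:, obs[i + 1]] * beta / c[i + 1]
            beta = params.stay * w + (1.0 - params.stay) * (params.jump @ w)
            g = alpha[i] * beta
            gam[i] = g / g.sum()
        posteriors[chrom] = gam
    return loglik, posteriors


def scale_fit(theta: float, lambdas_atomic: np.ndarray, grid: TimeGrid,
              constants: ScalingConstants, bin_size: int) -> pd.DataFrame:
    """Convert a fitted model to years and diploid individuals.

    N0 = theta / (4 mu bin_size); interval boundaries in years are
    2 * N0 * t * generation_time.
    """
    n0 = theta / (4.0 * constants.mu * bin_size)
    b = grid.boundaries
    years = 2.0 * n0 * b * constants.generation_years
    return pd.DataFrame({
        "t_low_years": years[:-1],
        "t_high_years": years[1:],
        "diploid_size": n0 * np.asarray(lambdas_atomic),
    })


class PsmcModel:
    """Single-genome demographic-inference model.

    Parameters
    ----------
    binseq : BinSequence
        T/K/N bins of the diploid genome.
    pattern : str
        Parameter-grouping pattern over atomic time intervals, e.g.
        ``"6+29*2"`` (64 atomic intervals in 30 free groups).
    t_max, alpha : float
        Scaled-time grid extent and curvature.
    rho_over_theta : float
        Fixed ratio of the per-bin recombination to mutation parameter.
    """

    def __init__(self, binseq: BinSequence, pattern: str = "6+29*2",
                 t_max: float = 15.0, alpha: float = 0.1,
                 rho_over_theta: float = 0.2,
                 theta0: float | None = None):
        counts = binseq.counts()
        if counts["K"] == 0 or counts["T"] == 0:
            raise ValueError("degenerate input: need both K and T bins")
        self.binseq = binseq
        from .bins import parse_pattern
        spans = parse_pattern(pattern)
        self.grid = time_grid(sum(spans), t_max=t_max, alpha=alpha,
                              pattern=pattern)
        if theta0 is None:
            f_k = counts["K"] / (counts["K"] + counts["T"])
            theta0 = -np.log1p(-f_k)     # E[tbar] ~ 1 in scaled units
        self.theta0 = float(theta0)
        self.rho = rho_over_theta * self.theta0
        self._sequences = [obs for obs in binseq.chroms.values() if len(obs)]

    # -- EM ---------------------------------------------------------------

    def _q_function(self, model: SmcModel, xi, emit_counts, gamma0) -> float:
        """Expected complete-data log-likelihood under ``model``."""
        pi, _, params = state_quantities(self.grid, model)
        a = transition_matrix(params.stay, params.jump)
        tiny = 1e-300
        q = float(gamma0 @ np.log(pi + tiny))
        q += float((xi * np.log(a + tiny)).sum())
        q += float((emit_counts[:, :2] * np.log(params.emit[:, :2] + tiny)).sum())
        return q

    def fit(self, iterations: int = 25, bounds: tuple[float, float] = (-4.0, 4.0)
            ) -> "PsmcResults":
        """Run EM and return the fitted results object.

        Each M-step numerically maximises the expected complete-data
        log-likelihood over log-lambdas and log-theta (a generalised EM
        step: the update is accepted only when it improves the
        objective, so the log-likelihood path is non-decreasing).
        """
        g = self.grid.n_groups
        lambdas = np.ones(g)
        theta = self.theta0
        loglik_path: list[float] = []
        for _ in range(iterations):
            model = SmcModel(theta, self.rho, lambdas)
            _, _, params = state_quantities(self.grid, model)
            loglik, xi, emit_counts, gamma0 = sequence_stats(self._sequences, params)
            loglik_path.append(loglik)

            def neg_q(x):
                m = SmcModel(float(np.exp(x[g])), self.rho, np.exp(x[:g]))
                return -self._q_function(m, xi, emit_counts, gamma0)

            x0 = np.concatenate([np.log(lambdas), [np.log(theta)]])
            res = minimize(neg_q, x0, method="L-BFGS-B",
                           bounds=[bounds] * g + [(np.log(theta) - 2, np.log(theta) + 2)])
            if res.success and -res.fun > -neg_q(x0):
                lambdas = np.exp(res.x[:g])
                theta = float(np.exp(res.x[g]))
        model = SmcModel(theta, self.rho, lambdas)
        _, _, params = state_quantities(self.grid, model)
        final_ll, *_ = sequence_stats(self._sequences, params)
        loglik_path.append(final_ll)
        return PsmcResults(self, model, np.array(loglik_path))


class PsmcResults:
    """Fitted piecewise-constant size trajectory with diagnostics."""

    def __init__(self, model: PsmcModel, params: SmcModel,
                 loglik_path: np.ndarray):
        self.model = model
        self.params = params
        self.loglik_path = loglik_path
        self.grid = model.grid
        self.bootstrap_lambdas: np.ndarray | None = None

    @property
    def theta(self) -> float:
        return self.params.theta

    @property
    def lambdas_atomic(self) -> np.ndarray:
        return np.asarray(self.params.lambdas)[self.grid.group_index]

    def trajectory(self, constants: ScalingConstants = ScalingConstants(),
                   level: float = 0.95) -> pd.DataFrame:
        """Size trajectory in years/diploid individuals, with bootstrap
        CIs when :meth:`bootstrap_ci` has been run."""
        out = scale_fit(self.theta, self.lambdas_atomic, self.grid,
                        constants, self.model.binseq.bin_size)
        if self.bootstrap_lambdas is not None:
            n0 = self.theta / (4.0 * constants.mu * self.model.binseq.bin_size)
            lo = (1.0 - level) / 2.0
            out["size_lo"] = n0 * np.quantile(self.bootstrap_lambdas, lo, axis=0)
            out["size_hi"] = n0 * np.quantile(self.bootstrap_lambdas, 1 - lo, axis=0)
        return out

    def bootstrap_ci(self, reps: int = 20, block_bp: int = 5_000_000,
                     seed: int = 0, iterations: int = 10,
                     level: float = 0.95) -> pd.DataFrame | None:
        """Block-bootstrap CIs: resample genome blocks with replacement,
        refit, and take percentile intervals per atomic interval."""
        if reps == 0:
            return None
        bs = self.model.binseq
        block_bins = max(1, block_bp // bs.bin_size)
        blocks = []
        for obs in bs.chroms.values():
            for s in range(0, len(obs), block_bins):
                blocks.append(obs[s:s + block_bins])
        if len(blocks) < 2:
            raise ValueError("need at least 2 blocks for the bootstrap")
        rng = np.random.default_rng(seed)
        samples = []
        pattern = "+".join(str(s) for s in self.grid.group_spans)
        for _ in range(reps):
            pick = rng.integers(0, len(blocks), size=len(blocks))
            resampled = BinSequence(bs.bin_size, {
                "bootstrap": np.concatenate([blocks[i] for i in pick])})
            m = PsmcModel(resampled, pattern=pattern,
                          t_max=float(self.grid.boundaries[-1]),
                          rho_over_theta=self.model.rho / self.model.theta0,
                          theta0=self.model.theta0)
            r = m.fit(iterations=iterations)
            samples.append(r.lambdas_atomic)
        self.bootstrap_lambdas = np.array(samples)
        return self.trajectory(level=level)

    def summary(self, constants: ScalingConstants = ScalingConstants()) -> str:
        """Human-readable fit summary."""
        traj = self.trajectory(constants)
        n0 = self.theta / (4.0 * constants.mu * self.model.binseq.bin_size)
        lines = [
            "PSMC-style demographic fit",
            "=" * 60,
            f"bins: {self.model.binseq.n_bins}  (bin size {self.model.binseq.bin_size} bp)",
            f"theta per bin: {self.theta:.6f}   rho per bin: {self.params.rho:.6f}",
            f"N0: {n0:,.0f} diploids   groups: {self.grid.n_groups}",
            f"log-likelihood: {self.loglik_path[-1]:,.2f} "
            f"({len(self.loglik_path) - 1} EM iterations)",
            "-" * 60,
            f"{'t_low (yr)':>14} {'t_high (yr)':>14} {'N (diploid)':>14}",
        ]
        for _, row in traj.iterrows():
            lines.append(f"{row.t_low_years:>14,.0f} {row.t_high_years:>14,.0f} "
                         f"{row.diploid_size:>14,.0f}")
        return "\n".join(lines)

    def plot(self, ax=None, constants: ScalingConstants = ScalingConstants()):
        """Step plot of the size trajectory (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        traj = self.trajectory(constants)
        t = np.repeat(traj["t_high_years"].to_numpy(), 2)[:-1]
        t = np.concatenate([[max(traj["t_low_years"].iloc[0], 1.0)], t])
        n = np.repeat(traj["diploid_size"].to_numpy(), 2)
        ax.plot(t[:len(n)], n, drawstyle="default")
        ax.set_xscale("log")
        ax.set_xlabel("years before present")
        ax.set_ylabel("diploid population size")
        return ax
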