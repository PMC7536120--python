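"""Single-locus coalescent simulation and the diversity-ratio sweep test.

A Hudson-style coalescent without recombination, under a piecewise-constant
population-size history, supports a domestication-bottleneck test: severity
of the bottleneck is calibrated so the simulated genome-wide diversity
ratio between the domesticate and its wild progenitor matches an observed
value, and the probability of an observed local pi ratio under that null
model is then estimated from fresh replicates.

Times are measured in units of 4*N0 generations backward from the present;
per-window theta = 4*N0*mu*L.  The simulator draws coalescence waiting
times by time-rescaling (exponentials at rate C(k,2) in rescaled time
mapped through the cumulative coalescent intensity of the size history) and
drops Poisson(theta/2 * total branch length) infinite-sites mutations on
the genealogy; the number of leaves subtended by a mutation at a level with
k lineages follows the classical branch-size distribution
P(i | k) = C(n-i-1, k-2) / C(n-1, k-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import comb

from .errors import CalibrationError, ParameterError

# Documented defaults for the domestication-bottleneck null model: a large
# wild progenitor population (N0), one generation per year, bottleneck
# starting 8,000 years ago with duration half its age, and the study's
# neutral mutation rate.
DEFAULT_N0 = 100_000
DEFAULT_MU = 6.5e-9
DEFAULT_GENERATION_YEARS = 1.0
DEFAULT_BOTTLENECK_START_YEARS = 8_000.0


@dataclass(frozen=True)
class Demography:
    """Piecewise-constant size history.

    ``epochs`` lists (start_time, relative_size) with times in 4*N0
    generations increasing from 0; the last epoch extends to infinity.
    """

    epochs: tuple[tuple[float, float], ...] = ((0.0, 1.0),)
    sample_size: int = 40

    def __post_init__(self):
        times = [t for t, _ in self.epochs]
        sizes = [s for _, s in self.epochs]
        if times[0] != 0:
            raise ParameterError("first epoch must start at time 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ParameterError("epoch times must strictly increase")
        if any(s <= 0 for s in sizes):
            raise ParameterError("relative sizes must be positive")
        if self.sample_size < 2:
            raise ParameterError("sample_size must be >= 2")

    @classmethod
    def constant(cls, n: int = 40) -> "Demography":
        return cls(((0.0, 1.0),), n)

    @classmethod
    def bottleneck(
        cls,
        severity: float,
        start: float = DEFAULT_BOTTLENECK_START_YEARS
        / (4 * DEFAULT_N0 * DEFAULT_GENERATION_YEARS),
        duration: float | None = None,
        n: int = 40,
    ) -> "Demography":
        """Present size 1, size ``severity`` during [start, start+duration),
        ancestral size 1."""
        if not 0 < severity <= 1:
            raise ParameterError("severity must lie in (0, 1]")
        if duration is None:
            duration = start / 2
        if severity == 1.0:
            return cls(((0.0, 1.0),), n)
        return cls(((0.0, 1.0), (start, severity), (start + duration, 1.0)), n)

    def intensity_knots(self, t_max: float) -> tuple[np.ndarray, np.ndarray]:
        """Knots (t_i, Lambda(t_i)) of the cumulative coalescent intensity
        Lambda(t) = integral of dt/size(t), extended past ``t_max``."""
        times = [t for t, _ in self.epochs]
        sizes = [s for _, s in self.epochs]
        ts = list(times) + [max(t_max, times[-1] + 1.0)]
        lam = [0.0]
        for i in range(len(times)):
            lam.append(lam[-1] + (ts[i + 1] - ts[i]) / sizes[i])
        return np.array(ts), np.array(lam)


@dataclass
class SimReplicate:
    """One simulated window: branch length (4*N0 units), S, pi."""

    total_branch_length: float
    S: int
    pi: float
    window_bp: int = 0


def _branch_size_pmf(n: int) -> np.ndarray:
    """P(i | k): probability a branch at the level with k lineages subtends
    i of the n leaves; rows k = 2..n, columns i = 1..n-1."""
    pmf = np.zeros((n + 1, n))
    for k in range(2, n + 1):
        i = np.arange(1, n - k + 2)
        pmf[k, i - 1] = comb(n - i - 1, k - 2) / comb(n - 1, k - 1)
    return pmf


def _coalescent_intervals(demography: Demography, reps: int, rng) -> np.ndarray:
    """Inter-coalescent interval lengths (reps x n-1), levels k = n..2."""
    n = demography.sample_size
    k = np.arange(n, 1, -1)
    rates = k * (k - 1) / 2.0
    rescaled = rng.exponential(1.0 / rates, size=(reps, n - 1)).cumsum(axis=1)
    ts, lam = demography.intensity_knots(float(rescaled.max()) + 1.0)
    # invert Lambda: rescaled time -> real time (piecewise linear)
    real = np.interp(rescaled, lam, ts)
    # extrapolate past the last knot at the final epoch's slope
    over = rescaled > lam[-1]
    if over.any():
        real[over] = ts[-1] + (rescaled[over] - lam[-1]) * demography.epochs[-1][1]
    return np.diff(np.concatenate([np.zeros((reps, 1)), real], axis=1), axis=1)


def simulate_batch(
    demography: Demography,
    theta: float,
    reps: int,
    rng: np.random.Generator,
    chunk: int = 1_000_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised simulation of ``reps`` windows.

    Returns arrays (total branch length, S, pi).  Mutations are placed by
    drawing, for each mutation, the level k with probability proportional to
    the branch length at that level, then the subtended leaf count i from
    P(i | k); each mutation adds 2*i*(n-i)/(n*(n-1)) to pi.
    """
    if theta <= 0:
        raise ParameterError("theta must be positive")
    n = demography.sample_size
    intervals = _coalescent_intervals(demography, reps, rng)
    k = np.arange(n, 1, -1)
    level_len = intervals * k  # branch length at each level (reps x n-1)
    L = level_len.sum(axis=1)
    S = rng.poisson(theta / 2.0 * L)

    level_cdf = np.cumsum(level_len, axis=1) / L[:, None]
    pmf = _branch_size_pmf(n)
    pmf_cdf = np.cumsum(pmf, axis=1)
    pair_norm = n * (n - 1) / 2.0

    rep_ids = np.repeat(np.arange(reps), S)
    total = int(S.sum())
    pi = np.zeros(reps)
    for lo in range(0, total, chunk):
        hi = min(lo + chunk, total)
        ids = rep_ids[lo:hi]
        u = rng.random(hi - lo)
        lev_idx = (u[:, None] > level_cdf[ids]).sum(axis=1)
        levels = k[lev_idx]
        v = rng.random(hi - lo)
        i = 1 + (v[:, None] > pmf_cdf[levels]).sum(axis=1)
        i = np.minimum(i, n - levels + 1)  # guard float roundoff at the CDF tail
        np.add.at(pi, ids, i * (n - i) / pair_norm)
    return L, S, pi


def simulate_coalescent(
    demography: Demography,
    theta: float,
    reps: int = 1,
    seed: int | np.random.Generator = 0,
    window_bp: int = 20_000,
) -> list[SimReplicate]:
    """Simulate ``reps`` independent windows under the size history.

    ``theta`` is the per-window population mutation rate 4*N0*mu*L.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    L, S, pi = simulate_batch(demography, theta, reps, rng)
    return [
        SimReplicate(float(L[r]), int(S[r]), float(pi[r]), window_bp)
        for r in range(reps)
    ]


def mean_pi(replicates: list[SimReplicate]) -> float:
    return float(np.mean([r.pi for r in replicates]))


def theta_per_window(
    window_bp: int = 20_000,
    n0: float = DEFAULT_N0,
    mu: float = DEFAULT_MU,
) -> float:
    return 4.0 * n0 * mu * window_bp


def paired_diversity_ratio(
    demography_a: Demography,
    demography_b: Demography,
    theta: float,
    reps: int,
    seed: int,
) -> float:
    """mean(pi_a)/mean(pi_b) over paired replicates.

    Both histories consume identical random draws (common random numbers),
    so genealogical noise largely cancels from the ratio of means.
    """
    _, _, pi_a = simulate_batch(demography_a, theta, reps, np.random.default_rng(seed))
    _, _, pi_b = simulate_batch(demography_b, theta, reps, np.random.default_rng(seed))
    return float(pi_a.mean() / pi_b.mean())


def calibrate_bottleneck(
    target_ratio: float,
    bottleneck_start: float = DEFAULT_BOTTLENECK_START_YEARS
    / (4 * DEFAULT_N0 * DEFAULT_GENERATION_YEARS),
    bottleneck_duration: float | None = None,
    n: int = 40,
    theta: float | None = None,
    reps: int = 3000,
    seed: int = 0,
    tol: float = 0.01,
    max_iter: int = 40,
) -> float:
    """Bisect the bottleneck severity f so that the mean diversity ratio
    mean(pi_bottleneck)/mean(pi_constant) over paired replicates matches
    ``target_ratio``.

    Paired replicates share the rescaled coalescent draws (common random
    numbers), making the simulated ratio monotone in f so bisection
    converges; ``target_ratio`` = 1 returns f = 1 immediately.
    """
    if not 0 < target_ratio <= 1:
        raise ParameterError("target_ratio must lie in (0, 1]")
    if target_ratio == 1.0:
        return 1.0
    theta = theta or theta_per_window()
    if bottleneck_duration is None:
        bottleneck_duration = bottleneck_start / 2

    def ratio(f: float) -> float:
        dem_b = Demography.bottleneck(f, bottleneck_start, bottleneck_duration, n)
        dem_c = Demography.constant(n)
        return paired_diversity_ratio(dem_b, dem_c, theta, reps, seed)

    lo, hi = 1e-6, 1.0
    r_lo, r_hi = ratio(lo), ratio(hi)
    if not r_lo - tol <= target_ratio <= r_hi + tol:
        raise CalibrationError(
            f"target ratio {target_ratio} outside attainable range "
            f"[{r_lo:.3f}, {r_hi:.3f}] for this start/duration"
        )
    for _ in range(max_iter):
        mid = math.sqrt(lo * hi)  # f spans orders of magnitude; bisect in log
        r_mid = ratio(mid)
        if abs(r_mid - target_ratio) <= tol:
            return mid
        if r_mid > target_ratio:
            hi = mid
        else:
            lo = mid
    raise CalibrationError("bisection did not converge")


def pi_ratio_test(
    observed_ratio: float,
    demography_bottleneck: Demography,
    demography_constant: Demography,
    theta: float | None = None,
    window_bp: int = 20_000,
    reps: int = 100_000,
    seed: int = 0,
) -> dict:
    """Empirical p-value of an observed local diversity ratio.

    Simulates ``reps`` independent window pairs under the two histories,
    forms per-replicate ratios pi_bottleneck / pi_constant (replicates with
    pi_constant = 0 are discarded and counted), and reports the add-one
    empirical p = (1 + #{ratio <= observed}) / (kept + 1).
    """
    if observed_ratio < 0:
        raise ParameterError("observed_ratio must be >= 0")
    if reps < 100:
        raise ParameterError("reps < 100 gives an unstable p-value")
    theta = theta or theta_per_window(window_bp)
    rng = np.random.default_rng(seed)
    _, _, pi_b = simulate_batch(demography_bottleneck, theta, reps, rng)
    _, _, pi_c = simulate_batch(demography_constant, theta, reps, rng)
    keep = pi_c > 0
    ratios = pi_b[keep] / pi_c[keep]
    kept = int(keep.sum())
    p = (1 + int(np.sum(ratios <= observed_ratio))) / (kept + 1)
    return {
        "p": p,
        "n_replicates": kept,
        "n_discarded": int(reps - kept),
        "mean_ratio": float(pi_b[keep].mean() / pi_c[keep].mean()),
        "ratio_quantiles": {
            q: float(np.quantile(ratios, q)) for q in (0.01, 0.05, 0.5, 0.95, 0.99)
        },
    }
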