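"""Linkage-disequilibrium decay: pairwise r2, thinning, pruning, the
distance-binned decay profile, a nonlinear fit and the extent at a
threshold.

The default decay model is the Hill & Weir (1988) expectation of r2 for a
sample of n chromosomes at recombination-scaled distance C = c*d:

    E[r2] = (10+C) / ((2+C)(11+C)) * [1 + ((3+C)(12+12C+C^2)) / (n(2+C)(11+C))]

with the single free parameter c (per-bp recombination scale).  A simple
hyperbolic fallback a/(1+b*d) is available when the Hill-Weir form is not
wanted.  The LD-decay extent is the smallest distance at which the fitted
curve reaches a threshold (0.2 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

from .dataio import MISSING
from .errors import DataError, FitError, ParameterError

logger = logging.getLogger(__name__)


def genotype_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float | None:
    """Squared Pearson correlation of two dosage vectors.

    Computed over pairwise-complete (both non-missing) samples; returns
    ``None`` when fewer than two complete pairs remain or either site is
    monomorphic among them.
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape:
        raise DataError("dosage vectors must have equal length")
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        logger.debug("r2 undefined (monomorphic or too few complete pairs)")
        return None
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def thin_by_bp(positions: np.ndarray, min_bp: int = 100) -> np.ndarray:
    """Greedy left-to-right thinning: keep a SNP iff it lies at least
    ``min_bp`` beyond the last kept SNP.  Returns indices of kept SNPs."""
    positions = np.asarray(positions)
    kept = []
    last = None
    for i, p in enumerate(positions):
        if last is None or p >= last + min_bp:
            kept.append(i)
            last = p
    return np.asarray(kept, dtype=np.int64)


@dataclass
class LDProfile:
    """Distance-binned mean r2 (left-closed 100-bp bins by default)."""

    bin_left: np.ndarray
    mean_r2: np.ndarray
    counts: np.ndarray
    bin_bp: int = 100

    @property
    def midpoints(self) -> np.ndarray:
        return self.bin_left + self.bin_bp / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_left,
                "midpoint": self.midpoints,
                "mean_r2": self.mean_r2,
                "n_pairs": self.counts,
            }
        )


def ld_profile(
    positions: np.ndarray,
    dosages: np.ndarray,
    max_pairs_window: int = 500,
    max_bp: int = 2_000_000,
    bin_bp: int = 100,
    subsample: int | None = None,
    seed: int = 0,
) -> LDProfile:
    """Mean r2 in distance bins over SNP pairs within two windows.

    Pairs are restricted to at most ``max_pairs_window`` SNPs apart and at
    most ``max_bp`` bp apart, then binned by distance into left-closed
    ``bin_bp`` bins.  ``dosages`` is sites x samples.  ``subsample`` caps
    the number of SNPs used (seeded random draw, logged).
    """
    positions = np.asarray(positions)
    dosages = np.asarray(dosages, dtype=float)
    if subsample is not None and subsample < len(positions):
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(len(positions), subsample, replace=False))
        logger.info("subsampled %d of %d SNPs", subsample, len(positions))
        positions, dosages = positions[keep], dosages[keep]

    n_bins = int(np.ceil(max_bp / bin_bp))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    n_sites = len(positions)
    for i in range(n_sites):
        for j in range(i + 1, min(i + 1 + max_pairs_window, n_sites)):
            d = positions[j] - positions[i]
            if d > max_bp:
                break
            r2 = genotype_r2(dosages[i], dosages[j])
            if r2 is None:
                continue
            b = min(int(d // bin_bp), n_bins - 1)
            sums[b] += r2
            counts[b] += 1
    if counts.sum() == 0:
        raise DataError("no computable SNP pairs")
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LDProfile(np.arange(n_bins) * bin_bp, means, counts, bin_bp)


# ---------------------------------------------------------------------------
# Decay models
# ---------------------------------------------------------------------------


def hill_weir_expected_r2(d: np.ndarray, c: float, n: int) -> np.ndarray:
    """Hill-Weir expected r2 at distance d for recombination scale c."""
    C = c * np.asarray(d, dtype=float)
    term1 = (10 + C) / ((2 + C) * (11 + C))
    term2 = 1 + ((3 + C) * (12 + 12 * C + C**2)) / (n * (2 + C) * (11 + C))
    return term1 * term2


def hyperbolic_r2(d: np.ndarray, a: float, b: float) -> np.ndarray:
    return a / (1.0 + b * np.asarray(d, dtype=float))


@dataclass
class DecayFit:
    model: str  # "hill_weir" or "hyperbolic"
    params: dict[str, float]
    n: int | None
    rss: float

    def predict(self, d: np.ndarray) -> np.ndarray:
        if self.model == "hill_weir":
            return hill_weir_expected_r2(d, self.params["c"], self.n)
        return hyperbolic_r2(d, self.params["a"], self.params["b"])


def fit_decay(
    profile: LDProfile, n: int | None = None, model: str = "hill_weir"
) -> DecayFit:
    """Weighted least-squares fit of a decay curve to a binned profile.

    Bins are weighted by their pair counts.  ``n`` (number of sampled
    chromosomes) is required for the Hill-Weir model.  A profile flat at its
    maximum (no decay information) raises :class:`FitError`.
    """
    ok = profile.counts > 0
    d = profile.midpoints[ok]
    y = profile.mean_r2[ok]
    w = profile.counts[ok].astype(float)
    if len(d) < 2:
        raise FitError("profile has fewer than two informative bins")
    if np.ptp(y) < 1e-12:
        raise FitError("flat r2 profile: decay parameters are unidentifiable")
    sigma = 1.0 / np.sqrt(w)
    try:
        if model == "hill_weir":
            if n is None:
                raise ParameterError("hill_weir model needs the sample size n")
            popt, _ = curve_fit(
                lambda dd, c: hill_weir_expected_r2(dd, c, n),
                d,
                y,
                p0=[1.0 / max(d.mean(), 1.0)],
                sigma=sigma,
                bounds=(1e-12, np.inf),
                maxfev=10_000,
            )
            params = {"c": float(popt[0])}
            resid = y - hill_weir_expected_r2(d, popt[0], n)
        elif model == "hyperbolic":
            popt, _ = curve_fit(
                hyperbolic_r2,
                d,
                y,
                p0=[float(y[0]), 1.0 / max(d.mean(), 1.0)],
                sigma=sigma,
                bounds=(1e-12, np.inf),
                maxfev=10_000,
            )
            params = {"a": float(popt[0]), "b": float(popt[1])}
            resid = y - hyperbolic_r2(d, *popt)
        else:
            raise ParameterError(f"unknown model {model!r}")
    except RuntimeError as exc:
        raise FitError(f"decay fit did not converge: {exc}") from exc
    rss = float(np.sum(w * resid**2))
    return DecayFit(model, params, n, rss)


def decay_extent(
    fit: DecayFit, threshold: float = 0.2, d_max: float = 1e9
) -> float:
    """Smallest distance at which the fitted (monotone) curve reaches
    ``threshold``, found by root bracketing.  Raises :class:`FitError` when
    the curve never crosses the threshold within ``d_max``."""
    f0 = float(fit.predict(np.array([0.0]))[0])
    if f0 < threshold:
        raise FitError(
            f"curve maximum {f0:.4f} lies below the threshold {threshold}"
        )
    if f0 == threshold:
        return 0.0
    f_end = float(fit.predict(np.array([d_max]))[0])
    if f_end > threshold:
        raise FitError(
            f"fitted curve never reaches r2 = {threshold} within {d_max:g} bp"
        )
    return float(brentq(lambda d: float(fit.predict(np.array([d]))[0]) - threshold, 0.0, d_max))


def ld_prune(
    positions: np.ndarray,
    dosages: np.ndarray,
    window_snps: int = 50,
    step_snps: int = 50,
    r2_max: float = 0.5,
) -> np.ndarray:
    """plink-style LD pruning; returns indices of kept SNPs.

    Within each ``window_snps`` window, the later SNP of any pair with
    r2 > ``r2_max`` is removed iteratively until no such pair remains; the
    window then advances by ``step_snps``.  Removing the later SNP is the
    deterministic tie-break.
    """
    n_sites = len(positions)
    keep = np.ones(n_sites, dtype=bool)
    start = 0
    while start < n_sites:
        window = [i for i in range(start, min(start + window_snps, n_sites)) if keep[i]]
        changed = True
        while changed:
            changed = False
            for ai in range(len(window)):
                for bi in range(ai + 1, len(window)):
                    i, j = window[ai], window[bi]
                    if not (keep[i] and keep[j]):
                        continue
                    r2 = genotype_r2(dosages[i], dosages[j])
                    if r2 is not None and r2 > r2_max:
                        keep[j] = False  # drop the later SNP
                        changed = True
            window = [i for i in window if keep[i]]
        start += step_snps
    return np.flatnonzero(keep)
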