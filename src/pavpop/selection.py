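"""Windowed diversity and haplotype-based selection statistics.

Implements nucleotide diversity (pi) and Tajima's D in physical windows,
extended haplotype homozygosity (EHH), the integrated haplotype score (iHS)
with frequency-bin standardization, a generic sliding-window scanner, and
outlier-window calling.  Window coordinates are 0-based half-open; variant
positions are 1-based bp.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import HaplotypeSet, MISSING, VariantTable
from .errors import DataError, ParameterError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------


def site_pi(derived: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Per-site pi = 2*c1*c0 / (n*(n-1)) from derived counts and sample sizes.

    Sites with fewer than two non-missing alleles contribute 0 (logged by
    callers that care).
    """
    derived = np.asarray(derived, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * derived * (n - derived) / (n * (n - 1.0))
    return np.where(n >= 2, pi, 0.0)


def allele_counts(table: VariantTable) -> tuple[np.ndarray, np.ndarray]:
    """(derived allele count, non-missing allele count) per site."""
    g = table.genotypes
    present = g != MISSING
    derived = np.where(present, g, 0).sum(axis=1)
    n = 2 * present.sum(axis=1)
    return derived.astype(float), n.astype(float)


def haplotype_counts(haps: HaplotypeSet) -> tuple[np.ndarray, np.ndarray]:
    derived = haps.alleles.sum(axis=0).astype(float)
    n = np.full(haps.n_sites, float(haps.n_hap))
    return derived, n


def window_pi(
    positions: np.ndarray,
    derived: np.ndarray,
    n: np.ndarray,
    window: tuple[int, int],
) -> float:
    """Mean pairwise diversity per bp over a 0-based half-open window.

    Summed per-site pi over SNPs inside the window divided by the window
    length; monomorphic and SNP-free stretches contribute zero.
    """
    start, end = window
    if end <= start:
        raise ParameterError("window end must exceed start")
    inside = (positions > start) & (positions <= end)  # 1-based pos in [start, end)
    n_in = n[inside]
    if (n_in < 2).any():
        logger.debug("skipping %d sites with n < 2", int((n_in < 2).sum()))
    return float(site_pi(derived[inside], n_in).sum() / (end - start))


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TajimaConstants:
    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    """Coefficients of the D statistic's variance for n sampled haplotypes."""
    if n < 2:
        raise ParameterError("need n >= 2 haplotypes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n, a1, a2, b1, b2, c1, c2, e1, e2)


def tajima_d(S: int, pi_sum: float, n: int) -> float | None:
    """Tajima's D from segregating sites and summed mean pairwise differences.

    ``pi_sum`` is the window's average number of pairwise differences (a
    count, not per-bp).  Returns ``None`` when S = 0 (D undefined); negative
    values indicate an excess of rare variants, as after a sweep or
    expansion.
    """
    if S < 0:
        raise ParameterError("S must be >= 0")
    if n < 4:
        raise ParameterError("Tajima's D needs n >= 4")
    if S == 0:
        return None
    c = tajima_constants(n)
    var = c.e1 * S + c.e2 * S * (S - 1)
    return float((pi_sum - S / c.a1) / math.sqrt(var))


def tajima_windows(
    positions: np.ndarray,
    derived: np.ndarray,
    n_alleles: np.ndarray,
    n_hap: int,
    window_bp: int = 10_000,
    step_bp: int | None = None,
) -> pd.DataFrame:
    """Tajima's D in physical windows (non-overlapping by default)."""
    step_bp = step_bp or window_bp
    pi_sites = site_pi(derived, n_alleles)
    seg = (derived > 0) & (derived < n_alleles)
    rows = []
    if len(positions) == 0:
        return pd.DataFrame(columns=["start", "end", "n_snps", "S", "pi_sum", "D"])
    last = int(positions.max())
    for start in range(0, last + 1, step_bp):
        end = start + window_bp
        inside = (positions > start) & (positions <= end)
        S = int(seg[inside].sum())
        pi_sum = float(pi_sites[inside].sum())
        D = tajima_d(S, pi_sum, n_hap) if S > 0 else None
        rows.append((start, end, int(inside.sum()), S, pi_sum, D))
    return pd.DataFrame(rows, columns=["start", "end", "n_snps", "S", "pi_sum", "D"])


# ---------------------------------------------------------------------------
# EHH / iHS
# ---------------------------------------------------------------------------


def ehh(
    haps: HaplotypeSet,
    core_index: int,
    core_allele: int,
    direction: str = "right",
) -> tuple[np.ndarray, np.ndarray]:
    """Extended haplotype homozygosity among carriers of ``core_allele``.

    Walking marker by marker away from the core site, haplotypes are grouped
    by identity over the interval from the core to the current marker;
    EHH(x) = sum_h C(count_h, 2) / C(n_carriers, 2).  Returns (positions,
    EHH values) starting at the core site, where EHH = 1 by definition.
    """
    if direction not in ("left", "right"):
        raise ParameterError("direction must be 'left' or 'right'")
    carriers = np.flatnonzero(haps.alleles[:, core_index] == core_allele)
    n_c = len(carriers)
    if n_c < 2:
        raise DataError("need >= 2 carriers of the core allele")
    denom = n_c * (n_c - 1) / 2

    step = 1 if direction == "right" else -1
    idx = core_index
    positions = [haps.positions[core_index]]
    values = [1.0]
    # group id per carrier haplotype, refined at each marker
    group = np.zeros(n_c, dtype=np.int64)
    while True:
        idx += step
        if idx < 0 or idx >= haps.n_sites:
            break
        alleles = haps.alleles[carriers, idx].astype(np.int64)
        group = group * 2 + alleles
        _, counts = np.unique(group, return_counts=True)
        homo = float(np.sum(counts * (counts - 1) / 2) / denom)
        positions.append(haps.positions[idx])
        values.append(homo)
        if homo == 0.0:
            break
        # re-encode groups compactly to avoid unbounded integers
        _, group = np.unique(group, return_inverse=True)
    return np.asarray(positions), np.asarray(values)


def _ihh_one_side(positions, values, core_pos, cutoff) -> float | None:
    """Trapezoidal integral of an EHH curve, truncated at the cutoff.

    Integration runs to the first marker where EHH < cutoff (that trapezoid
    included).  Returns ``None`` when the curve never falls below the cutoff
    before the edge of the data, in which case the core site is dropped.
    """
    dist = np.abs(np.asarray(positions, dtype=float) - core_pos)
    vals = np.asarray(values, dtype=float)
    below = np.flatnonzero(vals < cutoff)
    if len(below) == 0:
        return None
    stop = below[0]
    if stop == 0:
        return 0.0
    return float(np.trapezoid(vals[: stop + 1], dist[: stop + 1]))


@dataclass
class IhsRecord:
    index: int
    position: int
    derived_freq: float
    ihh_ancestral: float
    ihh_derived: float
    ihs: float  # unstandardized ln(iHH_A / iHH_D)
    ihs_std: float | None = None


def ihs_unstandardized(
    haps: HaplotypeSet, core_index: int, cutoff: float = 0.05
) -> IhsRecord | None:
    """Unstandardized iHS at one site: ln(iHH_ancestral / iHH_derived).

    iHH per allele is the trapezoidal integral of EHH over physical distance
    on both sides of the core, truncated where EHH drops below ``cutoff``.
    Returns ``None`` (site skipped, logged) when EHH reaches a chromosome
    edge before falling below the cutoff, or when an iHH integral is zero.
    """
    if not 0 < cutoff < 1:
        raise ParameterError("cutoff must lie in (0, 1)")
    counts = np.bincount(haps.alleles[:, core_index], minlength=2)
    if counts[0] < 2 or counts[1] < 2:
        raise DataError("both alleles need >= 2 carriers")
    core_pos = haps.positions[core_index]
    ihh = {}
    for allele in (0, 1):
        total = 0.0
        for direction in ("left", "right"):
            pos, val = ehh(haps, core_index, allele, direction)
            part = _ihh_one_side(pos, val, core_pos, cutoff)
            if part is None:
                logger.debug("site %d: EHH hit the edge; skipped", core_index)
                return None
            total += part
        ihh[allele] = total
    if ihh[0] <= 0 or ihh[1] <= 0:
        logger.debug("site %d: zero-width iHH; skipped", core_index)
        return None
    return IhsRecord(
        index=core_index,
        position=int(core_pos),
        derived_freq=float(counts[1] / haps.n_hap),
        ihh_ancestral=ihh[0],
        ihh_derived=ihh[1],
        ihs=float(np.log(ihh[0] / ihh[1])),
    )


def ihs_scan(haps: HaplotypeSet, cutoff: float = 0.05, min_maf: float = 0.05):
    """iHS at every site with minor-allele frequency >= ``min_maf``."""
    records = []
    freq = haps.derived_freq()
    for j in range(haps.n_sites):
        if min(freq[j], 1 - freq[j]) < min_maf:
            continue
        rec = ihs_unstandardized(haps, j, cutoff)
        if rec is not None:
            records.append(rec)
    return records


def standardize_ihs(
    records: list[IhsRecord], n_bins: int = 50, min_bin_size: int = 20
) -> list[IhsRecord]:
    """Standardize iHS within derived-allele-frequency bins.

    Records are binned into ``n_bins`` equal-width frequency bins; bins with
    fewer than ``min_bin_size`` records are merged with their neighbour
    (left to right) before each bin is centred and scaled to unit sd.
    """
    if not records:
        return records
    freqs = np.array([r.derived_freq for r in records])
    raw = np.array([r.ihs for r in records])
    edges = np.linspace(0, 1, n_bins + 1)
    bin_of = np.clip(np.digitize(freqs, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(bin_of, minlength=n_bins)

    # walk bins left to right, closing a group once it holds min_bin_size
    # records; a small trailing group is folded into the previous one
    group_id = np.zeros(n_bins, dtype=int)
    gid, size = 0, 0
    for b in range(n_bins):
        group_id[b] = gid
        size += counts[b]
        if size >= min_bin_size and b < n_bins - 1:
            gid, size = gid + 1, 0
    if size and size < min_bin_size and gid > 0:
        group_id[group_id == gid] = gid - 1

    group_of = group_id[bin_of]
    std = np.empty_like(raw)
    for g in np.unique(group_of):
        sel = group_of == g
        mu = raw[sel].mean()
        sd = raw[sel].std()
        std[sel] = 0.0 if sd == 0 else (raw[sel] - mu) / sd
    for rec, z in zip(records, std):
        rec.ihs_std = float(z)
    return records


# ---------------------------------------------------------------------------
# Window scanning and outliers
# ---------------------------------------------------------------------------


def scan_windows(
    positions: np.ndarray,
    values: np.ndarray,
    window_bp: int = 100_000,
    step_bp: int = 10_000,
    stat: str = "fraction_extreme",
    threshold: float = 2.0,
    min_snps: int = 10,
) -> pd.DataFrame:
    """Sliding-window summary of per-site values.

    ``stat`` is one of ``fraction_extreme`` (fraction with |value| >
    ``threshold``), ``mean`` or ``sum``.  Windows are 0-based half-open
    ``[start, start+window_bp)`` advanced by ``step_bp``; windows with fewer
    than ``min_snps`` sites get a null value.
    """
    if stat not in ("fraction_extreme", "mean", "sum"):
        raise ParameterError(f"unknown stat {stat!r}")
    positions = np.asarray(positions)
    values = np.asarray(values, dtype=float)
    rows = []
    last = int(positions.max()) if len(positions) else 0
    for start in range(0, last + 1, step_bp):
        end = start + window_bp
        inside = (positions > start) & (positions <= end)
        n = int(inside.sum())
        if n < min_snps:
            val = np.nan
        elif stat == "fraction_extreme":
            val = float(np.mean(np.abs(values[inside]) > threshold))
        elif stat == "mean":
            val = float(values[inside].mean())
        else:
            val = float(values[inside].sum())
        rows.append((start, end, n, val))
    return pd.DataFrame(rows, columns=["start", "end", "n_snps", "value"])


def outlier_windows(
    windows: pd.DataFrame, tail: str = "lower", fraction: float = 0.01
) -> pd.DataFrame:
    """Flag the extreme ``fraction`` of non-null windows, ties included."""
    if tail not in ("upper", "lower"):
        raise ParameterError("tail must be 'upper' or 'lower'")
    if not 0 < fraction < 1:
        raise ParameterError("fraction must lie in (0, 1)")
    valid = windows.dropna(subset=["value"])
    if valid.empty:
        return valid.assign(outlier=pd.Series(dtype=bool))
    n_flag = max(1, int(math.floor(len(valid) * fraction)))
    ranked = valid.sort_values("value", ascending=(tail == "lower"))
    cut = ranked["value"].iloc[n_flag - 1]
    if tail == "lower":
        mask = valid["value"] <= cut
    else:
        mask = valid["value"] >= cut
    if mask.sum() > n_flag:
        logger.warning("ties at the outlier cut: flagging %d windows", mask.sum())
    out = windows.copy()
    out["outlier"] = False
    out.loc[valid.index[mask], "outlier"] = True
    return out
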