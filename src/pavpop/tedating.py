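"""Kimura-2-parameter distances, retrotransposon burst/insertion dating and
junction-spanning-read insertion detection.

Dating assumes divergence accrues on both lineages after the burst (or
after insertion, for the two LTRs of one element), so age = K / (2*mu)
where K is the corrected distance in substitutions per site and mu the
neutral substitution rate per bp per year.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError, SaturationError

logger = logging.getLogger(__name__)

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class K2PResult:
    P: float  # transition proportion
    Q: float  # transversion proportion
    K: float  # corrected distance, substitutions per site
    n_sites: int  # comparable (ungapped, unambiguous) columns


def k2p(seq_a: str, seq_b: str) -> K2PResult:
    """Kimura-2-parameter distance between two aligned, equal-length sequences.

    Columns containing gaps or ambiguity codes in either sequence are
    excluded pairwise.  K = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q); saturation
    (non-positive log argument) raises :class:`SaturationError`.
    """
    if len(seq_a) != len(seq_b):
        raise DataError("sequences must be aligned to equal length")
    a = np.frombuffer(seq_a.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.upper().encode(), dtype=np.uint8)
    acgt = np.frombuffer(b"ACGT", dtype=np.uint8)
    valid = np.isin(a, acgt) & np.isin(b, acgt)
    a, b = a[valid], b[valid]
    n = len(a)
    if n == 0:
        raise DataError("no comparable sites")
    diff = a != b
    purines = np.frombuffer(b"AG", dtype=np.uint8)
    pur = np.isin(a, purines)
    pur_b = np.isin(b, purines)
    transitions = np.sum(diff & (pur == pur_b))
    transversions = np.sum(diff & (pur != pur_b))
    P = transitions / n
    Q = transversions / n
    arg1 = 1.0 - 2.0 * P - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0 or arg2 <= 0:
        raise SaturationError(f"K2P undefined for P={P:.3f}, Q={Q:.3f}")
    K = -0.5 * np.log(arg1) - 0.25 * np.log(arg2)
    return K2PResult(float(P), float(Q), float(K), int(n))


def pairwise_distance_matrix(seqs: dict[str, str]) -> pd.DataFrame:
    """Symmetric K2P distance matrix; saturated pairs become NaN (warned)."""
    names = list(seqs)
    d = pd.DataFrame(0.0, index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        try:
            k = k2p(seqs[a], seqs[b]).K
        except SaturationError:
            logger.warning("saturated pair (%s, %s) recorded as missing", a, b)
            k = np.nan
        d.at[a, b] = d.at[b, a] = k
    return d


def burst_age(distances: pd.DataFrame | np.ndarray, mu: float = 6.5e-9) -> dict:
    """Date a single-burst TE family from its pairwise distance matrix.

    Each copy pair diverged for 2*age*mu substitutions per site, so the age
    per pair is K/(2*mu); reported are the mean and the (min, max) range
    over all defined pairs.
    """
    if mu <= 0:
        raise ParameterError("mu must be positive")
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise DataError("expected a square distance matrix")
    iu = np.triu_indices(d.shape[0], k=1)
    vals = d[iu]
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        raise DataError("no defined pairwise distances")
    ages = vals / (2.0 * mu)
    return {
        "mean_age": float(ages.mean()),
        "min_age": float(ages.min()),
        "max_age": float(ages.max()),
        "mean_K": float(vals.mean()),
        "n_pairs": int(len(vals)),
    }


def ltr_age(ltr1: str, ltr2: str, mu: float = 6.5e-9) -> float:
    """Insertion age of one element from its two LTRs.

    The LTRs are identical at insertion and diverge at 2*mu per site per
    year afterwards; identical LTRs date the insertion to 0 years.
    """
    if mu <= 0:
        raise ParameterError("mu must be positive")
    return k2p(ltr1, ltr2).K / (2.0 * mu)


# ---------------------------------------------------------------------------
# Insertion detection from junction-spanning read pairs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InsertionCall:
    left_support: int
    right_support: int
    empty_site_pairs: int
    verdict: str  # present / absent / ambiguous


def detect_insertion(
    read_pairs: pd.DataFrame,
    left_junction: int,
    right_junction: int,
    min_pairs: int = 2,
) -> InsertionCall:
    """Call a TE insertion from paired reads mapped to the insertion-bearing
    reference (element occupying [left_junction, right_junction)).

    A pair supports the left junction when read 1 lies entirely outside-left
    and read 2 entirely inside the element (and mirrored for the right
    junction); a pair spans the empty site when its reads flank the whole
    element.  Verdict: ``present`` when both junctions have >= ``min_pairs``
    support; ``absent`` when neither has any support and >= ``min_pairs``
    span the empty site; ``ambiguous`` otherwise.
    """
    if right_junction <= left_junction:
        raise ParameterError("right_junction must exceed left_junction")
    if read_pairs.empty:
        return InsertionCall(0, 0, 0, "ambiguous")
    r1e = read_pairs["r1_end"].to_numpy()
    r1s = read_pairs["r1_start"].to_numpy()
    r2s = read_pairs["r2_start"].to_numpy()
    r2e = read_pairs["r2_end"].to_numpy()
    inside_r2 = (r2s >= left_junction) & (r2e <= right_junction)
    inside_r1 = (r1s >= left_junction) & (r1e <= right_junction)
    left_support = int(np.sum((r1e <= left_junction) & inside_r2))
    right_support = int(np.sum(inside_r1 & (r2s >= right_junction)))
    empty = int(np.sum((r1e <= left_junction) & (r2s >= right_junction)))
    if left_support >= min_pairs and right_support >= min_pairs:
        verdict = "present"
    elif left_support == 0 and right_support == 0 and empty >= min_pairs:
        verdict = "absent"
    else:
        verdict = "ambiguous"
    return InsertionCall(left_support, right_support, empty, verdict)
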