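"""Pan-genome presence calling, occupancy classification and enrichment.

The pipeline implemented here mirrors a pan-genome PAV analysis of a
diversity panel: per-library presence calls from alignment hits, a
minimum-gene-count library filter, clustering of per-gene occupancy into
core/shell/cloud classes (successive 1-D k-means with BIC-based choice of
k), a chi-square test for subpopulation over-/under-representation of each
gene with Benjamini-Hochberg correction, private-gene detection, and
Jaccard distances between presence profiles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from scipy.spatial.distance import pdist
from scipy.stats import chi2
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning
from statsmodels.stats.multitest import multipletests

from .dataio import PAVMatrix
from .errors import DataError, ParameterError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PresenceRule:
    """Alignment thresholds for calling a gene present in a library.

    A gene on a single contig is present when identity and coverage are
    strictly above the ``single_*`` thresholds; a gene split over
    2..``max_split_contigs`` contigs needs identity and coverage at or above
    the (stricter) ``split_*`` thresholds.
    """

    single_min_identity: float
    single_min_coverage: float
    split_min_identity: float
    split_min_coverage: float
    max_split_contigs: int = 3

    def __post_init__(self):
        if self.split_min_identity < self.single_min_identity or (
            self.split_min_coverage < self.single_min_coverage
        ):
            raise ParameterError("split thresholds must be >= single thresholds")
        if self.max_split_contigs < 1:
            raise ParameterError("max_split_contigs must be >= 1")


#: Same-genus panel preset: >85/85 single-contig, >=90/90 split.
WITHIN_GENUS = PresenceRule(85.0, 85.0, 90.0, 90.0, 3)
#: Cross-genus preset (divergent outgroup gene sets): >70 identity / >75
#: coverage single-contig, >=80/80 split.
CROSS_GENUS = PresenceRule(70.0, 75.0, 80.0, 80.0, 3)

PRESETS = {"within_genus": WITHIN_GENUS, "cross_genus": CROSS_GENUS}


def call_presence(
    identity: float | np.ndarray,
    coverage: float | np.ndarray,
    n_contigs: int | np.ndarray,
    rule: PresenceRule = WITHIN_GENUS,
):
    """Vectorised presence call from aggregated per-gene x library hits."""
    identity = np.asarray(identity, dtype=float)
    coverage = np.asarray(coverage, dtype=float)
    n_contigs = np.asarray(n_contigs, dtype=int)
    if (coverage > 100).any() or (identity > 100).any():
        raise DataError("identity/coverage must be <= 100")
    if (n_contigs < 1).any():
        raise DataError("n_contigs must be >= 1")
    single = (
        (n_contigs == 1)
        & (identity > rule.single_min_identity)
        & (coverage > rule.single_min_coverage)
    )
    split = (
        (n_contigs >= 2)
        & (n_contigs <= rule.max_split_contigs)
        & (identity >= rule.split_min_identity)
        & (coverage >= rule.split_min_coverage)
    )
    out = single | split
    return bool(out) if out.ndim == 0 else out


def presence_matrix_from_hits(
    hits: pd.DataFrame, rule: PresenceRule = WITHIN_GENUS
) -> PAVMatrix:
    """Build a PAV matrix from a hit table with columns
    ``gene, library, identity, coverage, n_contigs`` (one row per gene x
    library; absent combinations become 0)."""
    flags = call_presence(
        hits["identity"].to_numpy(),
        hits["coverage"].to_numpy(),
        hits["n_contigs"].to_numpy(),
        rule,
    )
    table = (
        hits.assign(present=np.asarray(flags, dtype=np.int8))
        .pivot_table(index="gene", columns="library", values="present", fill_value=0)
        .astype(np.int8)
    )
    table.columns.name = None
    table.index.name = None
    return PAVMatrix(table)


def filter_libraries(
    pav: PAVMatrix, min_present: int = 39_000
) -> tuple[PAVMatrix, list[str]]:
    """Drop libraries with fewer than ``min_present`` genes called present."""
    counts = pav.presence_counts()
    excluded = sorted(counts.index[counts < min_present])
    if excluded:
        logger.info("excluding %d libraries below %d genes", len(excluded), min_present)
    kept = PAVMatrix(pav.data.drop(columns=excluded))
    return kept, excluded


# ---------------------------------------------------------------------------
# Occupancy classification
# ---------------------------------------------------------------------------

CLASS_NAMES = ("core", "shell", "cloud")


@dataclass
class OccupancyClassification:
    """Result of successive k-means clustering of per-gene occupancy."""

    labels: pd.Series  # per-gene class name, ordered by descending mean occupancy
    k: int
    cluster_means: np.ndarray  # descending
    bic: dict[int, float]
    cluster_index: pd.Series = field(default=None)  # per-gene 0-based cluster rank

    @property
    def class_names(self) -> list[str]:
        names = list(CLASS_NAMES[: min(self.k, 3)])
        names += [f"class{i}" for i in range(len(names), self.k)]
        return names


def kmeans_bic(occupancy: np.ndarray, k: int, restarts: int, seed: int):
    """1-D k-means at a fixed k; returns (assignment, sorted-desc means, BIC).

    BIC is the within-cluster-sum-of-squares form n*ln(WSS/n) + k*ln(n).
    """
    x = np.asarray(occupancy, dtype=float).reshape(-1, 1)
    n = len(x)
    with warnings.catch_warnings():
        # duplicate occupancy values can collapse clusters at large k;
        # the BIC trace handles that case, so the warning is noise here
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(x)
    wss = max(km.inertia_, 1e-12)
    bic = n * np.log(wss / n) + k * np.log(n)
    return km.labels_, km.cluster_centers_.ravel(), bic


def classify_occupancy(
    occupancy: pd.Series | np.ndarray,
    k_max: int = 6,
    restarts: int = 20,
    seed: int = 0,
) -> OccupancyClassification:
    """Cluster per-gene occupancy into pan-genome classes.

    k-means is run for k = 1..k_max; BIC(k) = n*ln(WSS_k/n) + k*ln(n) is
    recorded for each k.  Because the WSS term rewards any further split of
    a continuous cluster by far more than the k*ln(n) penalty, the BIC curve
    decreases for all k on real occupancy data; k* is therefore chosen at
    the elbow of the curve (the k with the largest second-order difference),
    the same way successive-k-means BIC traces are read in practice.  Data
    whose single-cluster fit is already (near-)exact short-circuits to
    k* = 1.  Clusters are relabelled by descending mean occupancy, so
    ``core`` is always the highest-occupancy class.
    """
    occ = np.asarray(occupancy, dtype=float)
    if np.any((occ < 0) | (occ > 1)):
        raise ParameterError("occupancy values must lie in [0, 1]")
    index = (
        occupancy.index
        if isinstance(occupancy, pd.Series)
        else pd.RangeIndex(len(occ))
    )
    n = len(occ)
    if n == 0:
        raise DataError("no genes to classify")
    if n < k_max:
        logger.warning("fewer genes (%d) than k_max; shrinking", n)
        k_max = n

    results = {}
    bics = {}
    for k in range(1, k_max + 1):
        labels, centers, bic = kmeans_bic(occ, k, restarts, seed)
        results[k] = (labels, centers)
        bics[k] = bic

    # near-degenerate data: a single tight cluster explains everything
    wss1 = np.sum((occ - occ.mean()) ** 2)
    if wss1 / n < 1e-10:
        k_star = 1
    elif k_max <= 2:
        k_star = int(min(bics, key=bics.get))
    else:
        ks = np.arange(1, k_max + 1)
        b = np.array([bics[k] for k in ks])
        curvature = b[2:] - 2 * b[1:-1] + b[:-2]  # at k = 2..k_max-1
        k_star = int(ks[1:-1][np.argmax(curvature)])

    labels, centers = results[k_star]
    order = np.argsort(centers)[::-1]  # descending mean occupancy
    rank_of = np.empty_like(order)
    rank_of[order] = np.arange(k_star)
    ranks = rank_of[labels]
    names = list(CLASS_NAMES[: min(k_star, 3)])
    names += [f"class{i}" for i in range(len(names), k_star)]
    out_labels = pd.Series([names[r] for r in ranks], index=index, name="class")
    return OccupancyClassification(
        labels=out_labels,
        k=k_star,
        cluster_means=centers[order],
        bic=bics,
        cluster_index=pd.Series(ranks, index=index, name="cluster"),
    )


# ---------------------------------------------------------------------------
# Subpopulation enrichment
# ---------------------------------------------------------------------------


def chisq_enrichment(
    pav: PAVMatrix, metadata: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Chi-square test of gene presence counts across subpopulations.

    Expected counts follow the subpopulation proportions: e_i = O * n_i / N
    where O is the gene's total presence count and n_i the subpopulation
    sizes.  Admixed samples must already be excluded (rows labelled
    ``admixed`` are dropped here).  Genes with O = 0 are excluded (expected
    counts would all be zero).  Returns one row per tested gene with
    observed/expected counts, chi2, df, p, BH-adjusted q and a
    ``candidate`` flag for chi2 above the alpha critical value.
    """
    meta = metadata[metadata["subpop"] != "admixed"]
    libs = [lib for lib in pav.libraries if lib in meta.index]
    if not libs:
        raise DataError("no non-admixed libraries in the matrix")
    groups = meta.loc[libs].groupby("subpop").groups
    subpops = sorted(groups)
    if len(subpops) < 2:
        raise DataError("need >= 2 subpopulations")
    sizes = np.array([len(groups[s]) for s in subpops], dtype=float)
    if (sizes == 0).any():
        raise DataError("empty subpopulation")
    N = sizes.sum()

    observed = np.column_stack(
        [pav.data[list(groups[s])].sum(axis=1).to_numpy() for s in subpops]
    ).astype(float)
    totals = observed.sum(axis=1)
    tested = totals > 0
    n_dropped = int((~tested).sum())
    if n_dropped:
        logger.info("excluding %d genes with zero observations", n_dropped)

    obs = observed[tested]
    O = totals[tested]
    expected = O[:, None] * sizes[None, :] / N
    stat = ((obs - expected) ** 2 / expected).sum(axis=1)
    df = len(subpops) - 1
    pvals = chi2.sf(stat, df)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    critical = chi2.ppf(1 - alpha, df)

    result = pd.DataFrame(
        {
            **{f"observed_{s}": obs[:, i] for i, s in enumerate(subpops)},
            **{f"expected_{s}": expected[:, i] for i, s in enumerate(subpops)},
            "chi2": stat,
            "df": df,
            "p": pvals,
            "q": qvals,
            "candidate": stat > critical,
        },
        index=pav.genes[tested],
    )
    result.attrs["critical_value"] = float(critical)
    result.attrs["subpop_sizes"] = dict(zip(subpops, sizes.astype(int)))
    return result


def chisq_critical_value(df: int = 3, alpha: float = 0.05) -> float:
    """Upper critical value of the chi-square distribution."""
    return float(chi2.ppf(1 - alpha, df))


def private_genes(
    pav: PAVMatrix,
    metadata: pd.DataFrame,
    min_freq: float = 0.1,
    max_other_freq: float = 0.0,
) -> pd.DataFrame:
    """Genes private to one subpopulation.

    A gene is private to subpopulation s when its within-s presence
    frequency is strictly greater than ``min_freq`` and its frequency in
    every other subpopulation is at most ``max_other_freq`` (0 = strict
    absence).  Returns a frame gene -> subpopulation.
    """
    meta = metadata[metadata["subpop"] != "admixed"]
    libs = [lib for lib in pav.libraries if lib in meta.index]
    groups = meta.loc[libs].groupby("subpop").groups
    subpops = sorted(groups)
    freqs = pd.DataFrame(
        {s: pav.data[list(groups[s])].mean(axis=1) for s in subpops}
    )
    rows = []
    for s in subpops:
        others = [t for t in subpops if t != s]
        mask = (freqs[s] > min_freq) & (freqs[others].le(max_other_freq).all(axis=1))
        for gene in freqs.index[mask]:
            rows.append((gene, s, freqs.at[gene, s]))
    return pd.DataFrame(rows, columns=["gene", "subpop", "freq"]).set_index("gene")


# ---------------------------------------------------------------------------
# Presence-profile distances
# ---------------------------------------------------------------------------


def jaccard_distance(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Pairwise Jaccard distance 1 - |a&b|/|a|b| between binary profiles.

    Rows are profiles.  A pair of all-zero profiles has distance 0 (with a
    warning), matching the convention that two empty sets are identical.
    """
    if isinstance(matrix, pd.DataFrame):
        names = matrix.index
        x = matrix.to_numpy().astype(bool)
    else:
        x = np.asarray(matrix).astype(bool)
        names = pd.RangeIndex(x.shape[0])
    empty = ~x.any(axis=1)
    if empty.any():
        logger.warning("%d all-empty profiles; their mutual distance is 0", empty.sum())
    if x.shape[0] < 2:
        return pd.DataFrame(np.zeros((x.shape[0],) * 2), index=names, columns=names)
    d = squareform(pdist(x, metric="jaccard"))
    # scipy leaves 0/0 = 0 for empty pairs, which is the convention we want
    return pd.DataFrame(d, index=names, columns=names)
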