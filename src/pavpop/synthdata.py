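"""Synthetic-data generators with known ground truth.

Every generator is a pure function of its parameters and an integer seed,
and emulates one of the data shapes the analysis modules consume:

* a gene presence/absence (PAV) matrix with planted occupancy classes,
* a retrotransposon family diverging from a single burst under a
  Kimura-2-parameter substitution process,
* phased haplotypes carrying a planted partial hard sweep,
* haplotypes with distance-decaying linkage disequilibrium from a
  template-copying process,
* paired-read coordinates around a transposon insertion junction.

The defaults mirror the study conditions of the wild-grass diversity panel
the package targets (302 libraries, three occupancy classes near 98%, 56%
and 12%, a TE burst dated with mu = 6.5e-9 substitutions/bp/yr).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import HaplotypeSet, PAVMatrix
from .errors import ParameterError

TRANSITions = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PAVClassSpec:
    """One occupancy class of a synthetic pan-genome.

    ``mean_occupancy`` is the Beta-distributed per-gene occupancy mean;
    ``concentration`` its Beta concentration (a+b); mean 1.0 degenerates to
    an always-present class.
    """

    n_genes: int
    mean_occupancy: float
    concentration: float = 200.0

    def __post_init__(self):
        if not 0 < self.mean_occupancy <= 1:
            raise ParameterError("mean_occupancy must lie in (0, 1]")
        if self.n_genes < 1:
            raise ParameterError("n_genes must be >= 1")
        if self.concentration <= 0:
            raise ParameterError("concentration must be positive")


@dataclass(frozen=True)
class TEBurstSpec:
    """A single-burst retrotransposon family.

    All copies descend from one ancestral element ``burst_age`` years ago and
    accumulate substitutions at ``mu`` per bp per year with
    transition:transversion ratio ``kappa``; the element carries two
    initially identical LTRs of ``ltr_length`` bp at its ends.
    """

    n_copies: int = 12
    element_length: int = 6500
    burst_age: float = 45_000.0
    mu: float = 6.5e-9
    kappa: float = 2.0
    ltr_length: int = 451

    def __post_init__(self):
        if self.mu <= 0:
            raise ParameterError("mu must be positive")
        if self.burst_age < 0:
            raise ParameterError("burst_age must be >= 0")
        if self.kappa <= 0:
            raise ParameterError("kappa must be positive")
        if self.element_length < 2 * self.ltr_length:
            raise ParameterError("element must fit two LTRs")


def gen_pav_matrix(
    specs: list[PAVClassSpec],
    n_libraries: int = 302,
    subpop_sizes: dict[str, int] | None = None,
    seed: int = 0,
) -> tuple[PAVMatrix, pd.DataFrame]:
    """Generate a PAV matrix with planted occupancy classes.

    Per gene an occupancy p is drawn from Beta(mean*c, (1-mean)*c) and
    presence in each library is Bernoulli(p), independently across
    libraries.  Returns the matrix and a truth frame with the planted class
    index and realised occupancy per gene, plus a library->subpopulation
    assignment in ``truth.attrs['subpop_of_library']``.
    """
    rng = np.random.default_rng(seed)
    if subpop_sizes is None:
        subpop_sizes = {"pop1": n_libraries}
    if sum(subpop_sizes.values()) != n_libraries:
        raise ParameterError("subpop sizes must sum to n_libraries")

    blocks, classes, ps = [], [], []
    for ci, spec in enumerate(specs):
        if spec.mean_occupancy == 1.0:
            p = np.ones(spec.n_genes)
        else:
            a = spec.mean_occupancy * spec.concentration
            b = (1 - spec.mean_occupancy) * spec.concentration
            p = rng.beta(a, b, spec.n_genes)
        pres = rng.random((spec.n_genes, n_libraries)) < p[:, None]
        blocks.append(pres.astype(np.int8))
        classes.extend([ci] * spec.n_genes)
        ps.append(p)

    matrix = np.vstack(blocks)
    genes = [f"gene{i:06d}" for i in range(matrix.shape[0])]
    libraries = [f"lib{i:04d}" for i in range(n_libraries)]
    pav = PAVMatrix(pd.DataFrame(matrix, index=genes, columns=libraries))
    truth = pd.DataFrame(
        {
            "true_class": classes,
            "true_occupancy": np.concatenate(ps),
            "realized_occupancy": matrix.mean(axis=1),
        },
        index=genes,
    )
    subpop_of_library = {}
    start = 0
    for name, size in subpop_sizes.items():
        for lib in libraries[start : start + size]:
            subpop_of_library[lib] = name
        start += size
    truth.attrs["subpop_of_library"] = subpop_of_library
    return pav, truth


def subpop_metadata(truth: pd.DataFrame, qi: float = 1.0) -> pd.DataFrame:
    """Build a sample-metadata frame from a generator truth sidecar."""
    mapping = truth.attrs["subpop_of_library"]
    return pd.DataFrame(
        {"subpop": list(mapping.values()), "qi": qi},
        index=pd.Index(list(mapping.keys()), name="sample"),
    )


# ---------------------------------------------------------------------------
# TE family
# ---------------------------------------------------------------------------


def _mutate(seq: np.ndarray, n_subs: int, kappa: float, rng) -> np.ndarray:
    """Apply ``n_subs`` K2P substitutions at distinct sites of ``seq``."""
    out = seq.copy()
    if n_subs == 0:
        return out
    sites = rng.choice(len(seq), size=min(n_subs, len(seq)), replace=False)
    p_ts = kappa / (kappa + 2.0)
    for s in sites:
        base = out[s]
        if rng.random() < p_ts:
            out[s] = TRANSITions[base]
        else:
            out[s] = TRANSVERSIONS[base][rng.integers(2)]
    return out


def gen_te_family(spec: TEBurstSpec, seed: int = 0) -> dict[str, str]:
    """Simulate a TE family diverging from one ancestor at a single burst.

    Returns FASTA-style records: the ancestor, each copy, and each copy's two
    LTRs.  Copy ids are ``copy00 .. ``; LTR ids ``copy00_ltr5``/``_ltr3``.
    The ancestral element carries identical LTRs at both ends, so each
    copy's LTR pair diverges under the same clock as the copies themselves.
    """
    rng = np.random.default_rng(seed)
    L = spec.element_length
    core = rng.choice(BASES, size=L - spec.ltr_length)
    anc = np.concatenate([core[: spec.ltr_length].copy(), core])
    # ancestral element: [LTR][internal ... LTR], with the 3' LTR identical
    # to the 5' LTR at insertion time
    anc[-spec.ltr_length :] = anc[: spec.ltr_length]

    records = {"ancestor": "".join(anc)}
    lam = spec.burst_age * spec.mu * L
    for i in range(spec.n_copies):
        n_subs = rng.poisson(lam)
        copy = _mutate(anc, n_subs, spec.kappa, rng)
        name = f"copy{i:02d}"
        records[name] = "".join(copy)
        records[f"{name}_ltr5"] = "".join(copy[: spec.ltr_length])
        records[f"{name}_ltr3"] = "".join(copy[-spec.ltr_length :])
    return records


# ---------------------------------------------------------------------------
# Sweep haplotypes
# ---------------------------------------------------------------------------


def gen_sweep_haplotypes(
    n_hap: int = 200,
    n_snps: int = 500,
    region_bp: int = 1_000_000,
    core_freq: float = 0.4,
    sweep_width_bp: int = 200_000,
    seed: int = 0,
) -> tuple[HaplotypeSet, dict]:
    """Plant a hard partial sweep in otherwise independent neutral sites.

    Background alleles are Bernoulli at per-site frequencies drawn uniform on
    (0.05, 0.95), independent across sites.  Carriers of the derived core
    allele share one identical haplotype over ``sweep_width_bp`` centred on
    the core site, giving them EHH = 1 across the swept interval.

    Returns the haplotypes and a truth dict with the core site index,
    position and carrier rows.
    """
    if not 0 < core_freq < 1:
        raise ParameterError("core_freq must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(np.arange(1, region_bp + 1), size=n_snps, replace=False))
    freqs = rng.uniform(0.05, 0.95, n_snps)
    alleles = (rng.random((n_hap, n_snps)) < freqs).astype(np.uint8)

    core_idx = int(np.argmin(np.abs(positions - region_bp // 2)))
    n_carriers = max(2, round(core_freq * n_hap))
    carriers = rng.choice(n_hap, size=n_carriers, replace=False)
    alleles[:, core_idx] = 0
    alleles[carriers, core_idx] = 1

    half = sweep_width_bp // 2
    core_pos = positions[core_idx]
    in_sweep = (positions >= core_pos - half) & (positions <= core_pos + half)
    template = alleles[carriers[0], in_sweep].copy()
    for h in carriers:
        alleles[h, in_sweep] = template
    alleles[carriers, core_idx] = 1  # template carries the derived core allele

    haps = HaplotypeSet(
        positions=positions,
        alleles=alleles,
        sample_of_origin=[f"hap{i}" for i in range(n_hap)],
    )
    truth = {
        "core_index": core_idx,
        "core_position": int(core_pos),
        "carriers": np.sort(carriers),
        "sweep_interval": (int(core_pos - half), int(core_pos + half)),
    }
    return haps, truth


# ---------------------------------------------------------------------------
# LD haplotypes
# ---------------------------------------------------------------------------


def gen_ld_haplotypes(
    n_hap: int = 200,
    n_snps: int = 400,
    spacing_bp: int = 500,
    switch_prob_per_bp: float = 1e-4,
    mutation_prob: float = 0.01,
    n_founders: int = 10,
    seed: int = 0,
) -> HaplotypeSet:
    """Haplotype-copying process yielding LD that decays with distance.

    ``n_founders`` haplotypes are drawn site-wise at random frequencies;
    each subsequent haplotype copies a uniformly chosen earlier one,
    switching to a new random template between adjacent sites with
    probability ``1 - exp(-switch_prob_per_bp * d)``.  A small per-site
    copying error (``mutation_prob``) keeps sites polymorphic.  With
    ``switch_prob_per_bp = 0`` and no mutation every haplotype is an exact
    copy of one of the founders.
    """
    rng = np.random.default_rng(seed)
    if not 1 <= n_founders <= n_hap:
        raise ParameterError("n_founders must lie in [1, n_hap]")
    positions = np.arange(1, n_snps + 1, dtype=np.int64) * spacing_bp
    alleles = np.zeros((n_hap, n_snps), dtype=np.uint8)
    founder_freq = rng.uniform(0.1, 0.9, n_snps)
    alleles[:n_founders] = rng.random((n_founders, n_snps)) < founder_freq
    p_switch = 1.0 - np.exp(-switch_prob_per_bp * spacing_bp)
    for h in range(n_founders, n_hap):
        tmpl = rng.integers(0, h)
        row = np.empty(n_snps, dtype=np.uint8)
        for s in range(n_snps):
            if s > 0 and rng.random() < p_switch:
                tmpl = rng.integers(0, h)
            row[s] = alleles[tmpl, s]
        if switch_prob_per_bp > 0 and mutation_prob > 0:
            flips = rng.random(n_snps) < mutation_prob
            row[flips] ^= 1
        alleles[h] = row
    return HaplotypeSet(
        positions=positions,
        alleles=alleles,
        sample_of_origin=[f"hap{i}" for i in range(n_hap)],
    )


# ---------------------------------------------------------------------------
# Junction-spanning read pairs
# ---------------------------------------------------------------------------


def gen_read_pairs_over_junction(
    insertion_present: bool,
    n_pairs: int = 50,
    read_len: int = 100,
    insert_size: int = 400,
    junctions: tuple[int, int] = (10_000, 16_500),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate paired-read coordinates around a TE insertion site.

    Coordinates are in the insertion-bearing reference.  With the insertion
    present, pairs are drawn locally so that reads fall on opposite sides of
    each junction point; with it absent, pairs bridge the whole element (as
    reads from an empty-site individual map when lifted to this reference),
    i.e. read 1 ends before the left junction and read 2 starts after the
    right one.

    Returns a frame with columns ``r1_start, r1_end, r2_start, r2_end``
    (0-based half-open per read).
    """
    rng = np.random.default_rng(seed)
    left, right = junctions
    gap = max(insert_size - 2 * read_len, 1)
    rows = []
    for i in range(n_pairs):
        if insertion_present:
            if i % 2 == 0:  # left junction: read 1 outside, read 2 inside
                r1_end = left - rng.integers(0, gap + 1)
                r2_start = left + rng.integers(0, gap + 1)
            else:  # right junction: read 1 inside, read 2 outside
                r1_end = right - rng.integers(0, gap + 1)
                r2_start = right + rng.integers(0, gap + 1)
        else:  # empty-site pair bridges the whole element interval
            r1_end = left - rng.integers(0, gap + 1)
            r2_start = right + rng.integers(0, gap + 1)
        rows.append((r1_end - read_len, r1_end, r2_start, r2_start + read_len))
    return pd.DataFrame(
        rows, columns=["r1_start", "r1_end", "r2_start", "r2_end"], dtype=np.int64
    )
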