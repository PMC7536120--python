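"""Readers and writers for the formats the analysis modules consume.

No science lives here: this module converts between on-disk VCF / FASTA / TSV
and the in-memory containers (:class:`VariantTable`, :class:`HaplotypeSet`,
:class:`PAVMatrix`, sample metadata frames) that the rest of the package
operates on.

Coordinate conventions: variant positions are 1-based, as in VCF; every
window elsewhere in the package is 0-based half-open ``[start, end)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError, FormatError, PhasingError

logger = logging.getLogger(__name__)

MISSING = -1  # sentinel dosage / haplotype allele


@dataclass
class VariantTable:
    """Biallelic SNPs with per-sample dosages.

    ``genotypes`` is a sites x samples int8 matrix of dosages 0/1/2, with
    :data:`MISSING` (-1) for missing calls.  Positions are strictly
    increasing within each chromosome.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    samples: list[str] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        for c in np.unique(np.asarray(self.chrom)):
            p = self.pos[np.asarray(self.chrom) == c]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise DataError(f"positions not strictly increasing on {c}")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise DataError("dosages must be 0/1/2 or missing")


@dataclass
class HaplotypeSet:
    """Phased binary haplotypes (0 = ancestral/REF, 1 = derived/ALT).

    ``alleles`` is a haplotypes x sites uint8 matrix.  ``sample_of_origin``
    maps each haplotype row to its source sample (two rows per diploid).
    """

    positions: np.ndarray
    alleles: np.ndarray
    sample_of_origin: list[str] = field(default_factory=list)

    @property
    def n_hap(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if not np.isin(self.alleles, (0, 1)).all():
            raise DataError("haplotype alleles must be 0/1")

    def derived_freq(self) -> np.ndarray:
        return self.alleles.mean(axis=0)

    def to_dosages(self) -> np.ndarray:
        """Collapse haplotype pairs back to per-sample dosages (sites x samples)."""
        if self.n_hap % 2:
            raise DataError("odd haplotype count cannot form diploid dosages")
        paired = self.alleles.reshape(self.n_hap // 2, 2, self.n_sites).sum(axis=1)
        return paired.T.astype(np.int8)


@dataclass
class PAVMatrix:
    """Gene x library boolean presence matrix backed by a DataFrame."""

    data: pd.DataFrame

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def libraries(self) -> pd.Index:
        return self.data.columns

    def occupancy(self) -> pd.Series:
        """Fraction of libraries in which each gene is present."""
        return self.data.mean(axis=1)

    def presence_counts(self) -> pd.Series:
        """Number of genes called present in each library."""
        return self.data.sum(axis=0)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_SNP_ALLELES = frozenset("ACGT")


def read_vcf(path, phased_required: bool = False):
    """Read biallelic SNPs from a VCF 4.x file.

    Multiallelic and indel records are skipped (counted, logged).  When every
    genotype of every retained record is phased, a :class:`HaplotypeSet` is
    returned alongside the table; with ``phased_required`` an unphased
    heterozygous genotype raises :class:`PhasingError` instead.

    Returns ``(table, haplotypes_or_None, skip_counts)``.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises on malformed/missing headers
        raise FormatError(f"not a parseable VCF: {path}: {exc}") from exc

    samples = list(vcf.samples)
    chroms, poss, refs, alts = [], [], [], []
    dosages: list[np.ndarray] = []
    haps: list[np.ndarray] = []
    phased_ok = True
    skip = {"multiallelic": 0, "indel": 0}
    for var in vcf:
        if len(var.ALT) != 1:
            skip["multiallelic"] += 1
            continue
        if var.REF not in _SNP_ALLELES or var.ALT[0] not in _SNP_ALLELES:
            skip["indel"] += 1
            continue
        gts = var.genotypes  # [[a, b, phased], ...]
        row = np.empty(len(samples), dtype=np.int8)
        hrow = np.empty(2 * len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            a, b, phased = g[0], g[1], bool(g[-1])
            if a < 0 or b < 0:
                row[i] = MISSING
                hrow[2 * i : 2 * i + 2] = MISSING
                continue
            row[i] = a + b
            if not phased and a != b:
                if phased_required:
                    raise PhasingError(
                        f"unphased genotype for sample {samples[i]} at "
                        f"{var.CHROM}:{var.POS}"
                    )
                phased_ok = False
            hrow[2 * i] = a
            hrow[2 * i + 1] = b
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        dosages.append(row)
        haps.append(hrow)

    n = len(samples)
    table = VariantTable(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        genotypes=(
            np.vstack(dosages) if dosages else np.empty((0, n), dtype=np.int8)
        ),
        samples=samples,
    )
    if skip["multiallelic"] or skip["indel"]:
        logger.info("read_vcf skipped records: %s", skip)

    hapset = None
    hap_matrix = (
        np.vstack(haps).T if haps else np.empty((2 * n, 0), dtype=np.int8)
    )
    if phased_ok and not (hap_matrix == MISSING).any():
        origin = [s for s in samples for _ in range(2)]
        hapset = HaplotypeSet(
            positions=table.pos.copy(),
            alleles=hap_matrix.astype(np.uint8),
            sample_of_origin=origin,
        )
    return table, hapset, skip


def write_vcf(table: VariantTable, path, phased_haps: HaplotypeSet | None = None) -> None:
    """Write a minimal GT-only VCF 4.2 file.

    If ``phased_haps`` is given its alleles are emitted as ``a|b`` fields;
    otherwise dosages are written unphased (``0/0``, ``0/1``, ``1/1``).
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(pd.Series(table.chrom)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        for j in range(table.n_sites):
            fields = [
                str(table.chrom[j]),
                str(table.pos[j]),
                ".",
                str(table.ref[j]),
                str(table.alt[j]),
                ".",
                "PASS",
                ".",
                "GT",
            ]
            for i in range(table.n_samples):
                if phased_haps is not None:
                    a = phased_haps.alleles[2 * i, j]
                    b = phased_haps.alleles[2 * i + 1, j]
                    gt = f"{a}|{b}"
                else:
                    d = table.genotypes[j, i]
                    gt = "./." if d == MISSING else ("0/0", "0/1", "1/1")[d]
                fields.append(gt)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# PAV matrices and tables
# ---------------------------------------------------------------------------


def read_pav_matrix(path) -> PAVMatrix:
    """Read a genes x libraries 0/1 TSV (first column gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(
            f"non-binary PAV cell at gene {df.index[r]!r}, "
            f"library {df.columns[c]!r}: {values[r, c]!r}"
        )
    return PAVMatrix(df.astype(np.int8))


def write_pav_matrix(pav: PAVMatrix, path) -> None:
    pav.data.to_csv(path, sep="\t")


def read_sample_metadata(path, q_threshold: float = 0.7) -> pd.DataFrame:
    """Read sample metadata TSV with columns ``sample``, ``subpop``, ``qi``.

    Samples whose maximum membership coefficient qi is below ``q_threshold``
    are relabelled ``admixed``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "subpop": str})
    required = {"sample", "subpop", "qi"}
    if not required.issubset(df.columns):
        raise FormatError(f"metadata must have columns {sorted(required)}")
    if ((df["qi"] < 0) | (df["qi"] > 1)).any():
        raise DataError("qi must lie in [0, 1]")
    df = df.copy()
    df.loc[df["qi"] < q_threshold, "subpop"] = "admixed"
    return df.set_index("sample")


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """Write a results table as TSV with a deterministic column order."""
    df.to_csv(path, sep="\t", index=index)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an ordered ``{id: uppercase sequence}`` mapping."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(records: dict[str, str] | Sequence[tuple[str, str]], path) -> None:
    items = records.items() if isinstance(records, dict) else records
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(seqs, str(path), "fasta")
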