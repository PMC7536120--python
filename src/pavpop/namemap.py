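"""Annotation name carry-forward between assembly/annotation versions.

Locus names move forward when the old and new loci overlap uniquely on the
same strand and at least one pair of their translated transcripts are
mutual best hits (MBHs) with >= 70% normalized identity; transcript names
additionally require >= 90% identity (either a protein MBH, or a >= 90%
protein pair whose transcripts are MBHs at >= 90%).  Normalized identity is
the number of identical aligned residues divided by the length of the
longer sequence, computed from a deterministic global alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import DataError, ParameterError

logger = logging.getLogger(__name__)


def _aligner(kind: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if kind == "protein":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -0.5
    elif kind == "nucleotide":
        aligner.match_score = 2.0
        aligner.mismatch_score = -1.0
        aligner.open_gap_score = -5.0
        aligner.extend_gap_score = -2.0
    else:
        raise ParameterError(f"unknown sequence kind {kind!r}")
    return aligner


def normalized_identity(seq_a: str, seq_b: str, kind: str = "protein") -> float:
    """Identical aligned residues divided by the longer sequence length."""
    if not seq_a or not seq_b:
        raise DataError("sequences must be non-empty")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    aln = _aligner(kind).align(seq_a, seq_b)[0]
    identities = aln.counts().identities
    return identities / max(len(seq_a), len(seq_b))


def mutual_best_hits(
    set_a: dict[str, str], set_b: dict[str, str], kind: str = "protein"
) -> list[tuple[str, str, float]]:
    """Mutual best hit pairs between two sequence sets by normalized identity.

    (a, b) is an MBH when b is a's best match and a is b's best match.
    Exact score ties are broken toward the lexicographically smaller id and
    logged.  Pairs with zero identity are not reported.
    """
    if not set_a or not set_b:
        return []
    scores = {
        (a, b): normalized_identity(sa, sb, kind)
        for a, sa in set_a.items()
        for b, sb in set_b.items()
    }

    def best(candidates, score_of):
        ranked = sorted(candidates, key=lambda x: (-score_of(x), x))
        if len(ranked) > 1 and score_of(ranked[0]) == score_of(ranked[1]):
            logger.info("tie for best hit broken lexicographically: %s", ranked[:2])
        return ranked[0]

    best_of_a = {a: best(set_b, lambda b, a=a: scores[(a, b)]) for a in set_a}
    best_of_b = {b: best(set_a, lambda a, b=b: scores[(a, b)]) for b in set_b}
    pairs = [
        (a, b, scores[(a, b)])
        for a, b in best_of_a.items()
        if best_of_b[b] == a and scores[(a, b)] > 0
    ]
    return sorted(pairs)


@dataclass(frozen=True)
class Locus:
    """One annotated locus: interval, strand, and its transcript models."""

    id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str  # '+' or '-'
    proteins: dict[str, str] = field(default_factory=dict)
    transcripts: dict[str, str] = field(default_factory=dict)

    def overlaps(self, other: "Locus") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def unique_same_strand_overlaps(
    old_loci: list[Locus], new_loci: list[Locus]
) -> list[tuple[Locus, Locus]]:
    """Pairs of loci overlapping uniquely (1:1) on the same strand."""
    overlaps_of_old = {
        o.id: [n for n in new_loci if o.overlaps(n) and o.strand == n.strand]
        for o in old_loci
    }
    overlaps_of_new = {
        n.id: [o for o in old_loci if o.overlaps(n) and o.strand == n.strand]
        for n in new_loci
    }
    pairs = []
    for o in old_loci:
        hits = overlaps_of_old[o.id]
        if len(hits) == 1 and len(overlaps_of_new[hits[0].id]) == 1:
            pairs.append((o, hits[0]))
    return pairs


def map_locus_names(
    old_loci: list[Locus],
    new_loci: list[Locus],
    min_identity: float = 0.70,
    fresh_name: callable = None,
) -> dict[str, dict]:
    """Carry locus names forward.

    A new locus inherits the old locus name when the two overlap uniquely on
    the same strand and at least one MBH transcript-protein pair reaches
    ``min_identity`` normalized identity.  Unmapped new loci receive fresh
    names from ``fresh_name`` (default ``novel_0001`` style).  Returns
    {new locus id: {name, source, identity}}.
    """
    if fresh_name is None:
        counter = iter(range(1, len(new_loci) + 1))
        fresh_name = lambda: f"novel_{next(counter):04d}"  # noqa: E731
    mapping: dict[str, dict] = {}
    for old, new in unique_same_strand_overlaps(old_loci, new_loci):
        mbhs = mutual_best_hits(old.proteins, new.proteins)
        qualifying = [m for m in mbhs if m[2] >= min_identity]
        if qualifying:
            best_pair = max(qualifying, key=lambda m: m[2])
            mapping[new.id] = {
                "name": old.id,
                "source": "carried",
                "identity": best_pair[2],
            }
    used = {v["name"] for v in mapping.values()}
    for new in new_loci:
        if new.id not in mapping:
            name = fresh_name()
            while name in used:
                name = fresh_name()
            used.add(name)
            mapping[new.id] = {"name": name, "source": "fresh", "identity": None}
    return mapping


def map_transcript_names(
    old_locus: Locus,
    new_locus: Locus,
    min_identity: float = 0.90,
) -> dict[str, dict]:
    """Carry transcript names forward within one mapped locus pair.

    Rule 1: the proteins are MBHs with >= ``min_identity``.  Rule 2: the
    proteins reach >= ``min_identity`` without being MBHs, but the
    transcript sequences are MBHs at >= ``min_identity`` (covers models
    differing mainly by UTR extension).  Returns
    {new transcript id: {name, rule, identity}}.
    """
    prot_mbh = {
        (a, b): s for a, b, s in mutual_best_hits(old_locus.proteins, new_locus.proteins)
    }
    tx_mbh = {
        (a, b): s
        for a, b, s in mutual_best_hits(
            old_locus.transcripts, new_locus.transcripts, kind="nucleotide"
        )
    }
    mapping: dict[str, dict] = {}
    claimed_old: set[str] = set()
    for (a, b), s in sorted(prot_mbh.items()):
        if s >= min_identity and b not in mapping and a not in claimed_old:
            mapping[b] = {"name": a, "rule": 1, "identity": s}
            claimed_old.add(a)
    for b, seq_b in sorted(new_locus.transcripts.items()):
        if b in mapping:
            continue
        for a, seq_a in sorted(old_locus.transcripts.items()):
            if a in claimed_old:
                continue
            if a not in old_locus.proteins or b not in new_locus.proteins:
                continue
            prot_id = normalized_identity(
                old_locus.proteins[a], new_locus.proteins[b]
            )
            if prot_id >= min_identity and (a, b) not in prot_mbh:
                tx_score = tx_mbh.get((a, b))
                if tx_score is not None and tx_score >= min_identity:
                    mapping[b] = {"name": a, "rule": 2, "identity": prot_id}
                    claimed_old.add(a)
                    break
    return mapping
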