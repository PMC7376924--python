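"""Initial sequence clustering and pairwise identity computations.

The pipeline first groups genes into tight families at a high identity
threshold (98% by default, following standard pangenome practice) before any
graph construction.  Clustering is greedy incremental star clustering:
sequences are sorted longest-first and each joins the first existing
representative it matches at or above the threshold, otherwise it founds a
new cluster.  Every emitted cluster therefore satisfies the *star property*:
all members align to the representative at >= the threshold.

All pairwise statistics are computed with edlib edit-distance alignments.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib

from .annotation_io import GeneRecord

__all__ = [
    "SeqCluster",
    "AlignStats",
    "cluster_sequences",
    "pairwise_stats",
    "infix_stats",
]

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class AlignStats:
    """Identity and coverage of one pairwise alignment.

    identity: fraction of matching columns over the alignment length.
    coverage: number of columns where both sequences contribute a residue,
        over the length of the shorter sequence (global mode) or of the query
        (infix mode).
    """

    identity: float
    coverage: float


def _cigar_columns(cigar: str) -> tuple[int, int]:
    """Return (alignment_length, both-residue columns) from an edlib cigar."""
    alen = 0
    both = 0
    for count, op in _CIGAR_RE.findall(cigar):
        n = int(count)
        alen += n
        if op in "=XM":
            both += n
    return alen, both


def pairwise_stats(a: str, b: str) -> AlignStats:
    """Global (end-to-end) alignment statistics between two sequences.

    identity = 1 - editdistance / alignment_length; symmetric in a, b.
    """
    if not a or not b:
        raise ValueError("pairwise_stats requires two non-empty sequences")
    res = edlib.align(a, b, mode="NW", task="path")
    alen, both = _cigar_columns(res["cigar"])
    identity = 1.0 - res["editDistance"] / alen
    coverage = both / min(len(a), len(b))
    return AlignStats(identity=identity, coverage=coverage)


def infix_stats(query: str, target: str) -> AlignStats:
    """Best-infix alignment of *query* inside *target* (edlib HW mode).

    Used where one sequence may be a fragment of the other (mistranslation
    merging, missing-gene refinding).  identity is computed over the aligned
    region only; coverage is the fraction of the query involved in the
    alignment.
    """
    if not query or not target:
        raise ValueError("infix_stats requires two non-empty sequences")
    res = edlib.align(query, target, mode="HW", task="path")
    alen, both = _cigar_columns(res["cigar"])
    if alen == 0:
        return AlignStats(identity=0.0, coverage=0.0)
    identity = 1.0 - res["editDistance"] / alen
    coverage = both / len(query)
    return AlignStats(identity=identity, coverage=coverage)


def infix_locate(query: str, target: str) -> tuple[AlignStats, tuple[int, int]]:
    """Like :func:`infix_stats` but also return the (start, end) hit span
    (0-based half-open) of the best infix alignment on the target."""
    res = edlib.align(query, target, mode="HW", task="path")
    alen, both = _cigar_columns(res["cigar"])
    if alen == 0:
        return AlignStats(0.0, 0.0), (0, 0)
    stats = AlignStats(1.0 - res["editDistance"] / alen, both / len(query))
    loc = res["locations"][0]
    return stats, (loc[0], loc[1] + 1)


@dataclass
class SeqCluster:
    cluster_id: int
    representative: str            # gene_id of the longest member
    members: list[str]             # gene_ids, representative included
    identity_threshold_used: float

    def __len__(self) -> int:
        return len(self.members)


def _kmers(seq: str, k: int) -> set[str]:
    if len(seq) < k:
        return {seq}
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def cluster_sequences(
    records: Sequence[GeneRecord] | Iterable[GeneRecord],
    identity: float = 0.98,
    level: str = "protein",
) -> list[SeqCluster]:
    """Greedy incremental star clustering of gene sequences.

    Sequences are processed longest-first (equal lengths broken
    lexicographically by gene_id, making the result deterministic).  Each
    sequence joins the earliest-founded cluster whose representative it
    matches at >= *identity* global identity, else it founds a new cluster.
    A k-mer prefilter (word size 5 for proteins, 10 for DNA) and a length
    guard (candidates whose lengths differ by more than (1 - identity) + 0.05
    as a fraction are skipped) mirror the screening heuristics of standard
    greedy clusterers; the final alignment check guards correctness.
    """
    if identity <= 0:
        raise ValueError(f"identity threshold must be positive, got {identity}")
    if identity > 1:
        raise ValueError(f"identity threshold must be <= 1, got {identity}")
    if level not in ("protein", "dna"):
        raise ValueError(f"level must be 'protein' or 'dna', got {level!r}")
    records = list(records)
    if not records:
        return []

    k = 5 if level == "protein" else 10
    len_slack = (1.0 - identity) + 0.05

    def seq_of(r: GeneRecord) -> str:
        s = r.prot_seq if level == "protein" else r.dna_seq
        return s if s else r.dna_seq  # fall back for untranslatable stubs

    ordered = sorted(records, key=lambda r: (-len(seq_of(r)), r.gene_id))

    rep_seqs: list[str] = []
    rep_ids: list[str] = []
    members: list[list[str]] = []
    kmer_index: dict[str, set[int]] = defaultdict(set)

    for rec in ordered:
        seq = seq_of(rec)
        hit = None
        candidates = set()
        for km in _kmers(seq, k):
            candidates |= kmer_index.get(km, set())
        for ci in sorted(candidates):
            rs = rep_seqs[ci]
            shorter, longer = sorted((len(seq), len(rs)))
            if longer - shorter > len_slack * longer:
                continue
            if pairwise_stats(seq, rs).identity >= identity:
                hit = ci
                break
        if hit is not None:
            members[hit].append(rec.gene_id)
        else:
            ci = len(rep_seqs)
            rep_seqs.append(seq)
            rep_ids.append(rec.gene_id)
            members.append([rec.gene_id])
            for km in _kmers(seq, k):
                kmer_index[km].add(ci)

    return [
        SeqCluster(
            cluster_id=i,
            representative=rep_ids[i],
            members=members[i],
            identity_threshold_used=identity,
        )
        for i in range(len(rep_ids))
    ]
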