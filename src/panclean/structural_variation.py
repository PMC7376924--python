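"""Gene-triplet structural-variant calling.

A genome passes through each node of the pangenome graph at most once, so
alternative paths through a region show up as different *consecutive
triplets* of gene families.  Summarising every genome path as its set of
triplets yields a binary genomes x triplets matrix that can feed a bacterial
GWAS directly (larger insertions/deletions are represented once rather than
once per gene).

Triplet orientation is canonicalised — (a, b, c) and (c, b, a) are the same
variant — so the matrix is invariant to reverse-complementing whole contigs.
By default only variant-informative triplets are emitted: those whose centre
node has population graph degree > 2, i.e. where genomes actually take
different paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .pangraph import PangenomeGraph

__all__ = ["call_triplets", "triplet_name", "write_rtab"]


def triplet_name(a: int | str, b: int | str, c: int | str) -> str:
    return f"{a}-{b}-{c}"


def _canonical(t: tuple[int, int, int]) -> tuple[int, int, int]:
    rev = (t[2], t[1], t[0])
    return min(t, rev)


def call_triplets(
    g: PangenomeGraph,
    informative_only: bool = True,
    node_labels: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Binary genomes x triplets presence matrix from the stored paths.

    With *informative_only* (default) a triplet is emitted only when its
    centre node has graph degree > 2 across the population; constant
    triplets carry no association signal.  Contigs with fewer than three
    genes contribute nothing.
    """
    G = g.graph()
    seen: dict[tuple[int, int, int], set[str]] = {}
    for (genome, _contig), path in sorted(g.paths().items()):
        # a genome passes through a node once: collapse tandem self-repeats
        dedup: list[int] = []
        for n in path:
            if not dedup or dedup[-1] != n:
                dedup.append(n)
        for a, b, c in zip(dedup, dedup[1:], dedup[2:]):
            if informative_only:
                deg = sum(1 for nb in G.neighbors(b) if nb != b)
                if deg <= 2:
                    continue
            seen.setdefault(_canonical((a, b, c)), set()).add(genome)

    labels = node_labels or {}
    cols = {}
    for trip in sorted(seen):
        name = triplet_name(*(labels.get(n, n) for n in trip))
        cols[name] = [1 if gn in seen[trip] else 0 for gn in g.genomes]
    df = pd.DataFrame(cols, index=list(g.genomes), dtype=int)
    df.index.name = "genome"
    return df


def write_rtab(matrix: pd.DataFrame, path) -> None:
    """Write a genomes x variants matrix as an Rtab file (variants as rows,
    first column the variant name, header row the genomes) — the
    tab-separated binary format consumed by bacterial GWAS tools."""
    out = matrix.T
    out.index.name = "Gene"
    out.to_csv(path, sep="\t")
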