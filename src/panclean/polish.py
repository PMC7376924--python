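"""Annotation error correction on the pangenome graph.

Five stages run in a fixed order, mirroring the graph signatures of the
error classes they target:

1. ``trim_contig_end_stubs`` — mis-annotations near contig breaks appear as
   short, poorly supported paths ending in a degree-1 node; these are
   recursively removed (bounded depth).
2. ``remove_contamination`` — contaminant contigs appear as disconnected,
   uniformly low-support components; they are dissolved by the same
   recursive degree-<=1 deletion, which retains rare genes attached to
   well-supported graph regions.
3. ``merge_mistranslations`` — the same DNA annotated in different frames or
   split by a frame shift yields near-identical nucleotide sequence in
   nearby nodes; the lower-support node is absorbed and per-genome fragments
   are rejoined.
4. ``collapse_families`` — diverse gene families oversplit by the strict
   initial clustering are re-merged when two nodes share a graph neighbour
   and align above a relaxed protein threshold (70% by default).
5. ``refind_missing_genes`` — genes whose annotation was dropped but whose
   DNA is intact are recovered by an edit-distance infix search of the
   sequence flanking a neighbouring gene.

Three modes tune the aggressiveness: ``strict`` (support threshold scales
with the collection size), ``moderate`` (fixed minimal threshold, the
default) and ``sensitive`` (never deletes a gene cluster).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .annotation_io import ContigSeq, GeneRecord, reverse_complement, translate
from .clustering import SeqCluster, cluster_sequences, infix_locate, infix_stats, pairwise_stats
from .pangraph import PangenomeGraph, build_graph, collapse_paralogs

__all__ = [
    "CleanConfig",
    "trim_contig_end_stubs",
    "remove_contamination",
    "merge_mistranslations",
    "collapse_families",
    "refind_missing_genes",
    "polish_graph",
    "build_pangenome",
]


@dataclass
class CleanConfig:
    """Tuning knobs for the correction stages.

    ``min_trailing_support`` defaults to max(2, ceil(0.05 * n_genomes)) in
    strict mode and 2 in moderate mode; sensitive mode never deletes.
    """

    mode: str = "moderate"
    min_trailing_support: int | None = None
    trailing_recursion_depth: int = 2
    family_threshold: float = 0.70
    merge_coverage: float = 0.95
    merge_identity: float = 0.99
    refind_identity: float = 0.99
    refind_coverage: float = 0.80
    search_radius: int = 5000
    merge_proximity: int = 3          # graph distance for mistranslation pairs
    cluster_identity: float = 0.98    # initial clustering threshold

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "moderate", "sensitive"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name in ("family_threshold", "merge_coverage", "merge_identity",
                     "refind_identity", "refind_coverage", "cluster_identity"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")

    def support_threshold(self, n_genomes: int) -> int:
        if self.min_trailing_support is not None:
            return self.min_trailing_support
        if self.mode == "strict":
            return max(2, math.ceil(0.05 * n_genomes))
        return 2


# ------------------------------------------------------------------ stage 1/2


def trim_contig_end_stubs(g: PangenomeGraph, cfg: CleanConfig) -> list[dict]:
    """Recursively remove degree-<=1 nodes below the support threshold.

    Bounded to ``trailing_recursion_depth`` rounds so that genuine rare
    operons hanging off the graph are not eaten whole.  No-op in sensitive
    mode.  Returns the removal log entries added.
    """
    if cfg.mode == "sensitive":
        return []
    thr = cfg.support_threshold(g.n_genomes)
    before = len(g.removal_log)
    for _ in range(cfg.trailing_recursion_depth):
        doomed = [n for n in g.nodes() if g.degree(n) <= 1 and g.support(n) < thr]
        if not doomed:
            break
        for n in doomed:
            g.delete_node(n, f"degree<=1 stub with support {g.support(n)} < {thr}",
                          "trim_stubs")
    return g.removal_log[before:]


def remove_contamination(g: PangenomeGraph, cfg: CleanConfig) -> list[dict]:
    """Dissolve connected components whose nodes all fall below the support
    threshold, by recursive degree-<=1 deletion.  Rare genes attached to
    well-supported regions survive.  No-op in sensitive mode."""
    if cfg.mode == "sensitive":
        return []
    thr = cfg.support_threshold(g.n_genomes)
    before = len(g.removal_log)
    while True:
        G = g.graph()
        low_comp_nodes: set[int] = set()
        for comp in nx.connected_components(G):
            if all(g.support(n) < thr for n in comp):
                low_comp_nodes |= comp
        doomed = [n for n in sorted(low_comp_nodes) if g.degree(n) <= 1]
        if not doomed:
            break
        for n in doomed:
            g.delete_node(n, f"low-support component (support < {thr})",
                          "contamination")
    return g.removal_log[before:]


# -------------------------------------------------------------------- stage 3


def _within_distance(G: nx.Graph, node: int, radius: int) -> set[int]:
    seen = {node}
    frontier = {node}
    out: set[int] = set()
    for _ in range(radius):
        nxt = set()
        for n in frontier:
            for nb in G.neighbors(n):
                if nb not in seen:
                    seen.add(nb)
                    nxt.add(nb)
                    out.add(nb)
        frontier = nxt
    return out


def merge_mistranslations(g: PangenomeGraph, cfg: CleanConfig) -> PangenomeGraph:
    """Merge nearby nodes whose DNA matches at high identity and coverage.

    Comparison is at the nucleotide level with infix alignment (the shorter
    representative searched within the longer), so frame-shift fragments and
    alternative-frame translations of the same locus are caught.  The
    lower-support node is absorbed into the higher-support one (ties: longer
    representative, then smaller node id); a genome left with several members
    has contig-adjacent copies rejoined into one logical gene.
    """
    changed = True
    while changed:
        changed = False
        G = g.graph()
        live = set(g.node_info)
        for n in sorted(live):
            if n not in g.node_info:
                continue
            for m in sorted(_within_distance(g.graph(), n, cfg.merge_proximity)):
                if m <= n or m not in g.node_info or n not in g.node_info:
                    continue
                a = g.rep_record(n).dna_seq
                b = g.rep_record(m).dna_seq
                if not a or not b:
                    continue
                query, target = (a, b) if len(a) <= len(b) else (b, a)
                st = infix_stats(query, target)
                if st.identity >= cfg.merge_identity and st.coverage >= cfg.merge_coverage:
                    keep, drop = _merge_order(g, n, m)
                    g.merge_nodes(keep, drop)
                    changed = True
                    break
    return g


def _merge_order(g: PangenomeGraph, n: int, m: int) -> tuple[int, int]:
    """(keep, drop): higher support wins; ties go to the longer
    representative, then to the smaller node id."""
    sn, sm = g.support(n), g.support(m)
    if sn != sm:
        return (n, m) if sn > sm else (m, n)
    ln, lm = len(g.rep_record(n).dna_seq), len(g.rep_record(m).dna_seq)
    if ln != lm:
        return (n, m) if ln > lm else (m, n)
    return (n, m)


# -------------------------------------------------------------------- stage 4


def collapse_families(g: PangenomeGraph, cfg: CleanConfig) -> PangenomeGraph:
    """Merge nodes that share a graph neighbour and whose protein
    representatives align at >= ``family_threshold`` identity; merged nodes
    are flagged as diverse families.  Iterates to a fixpoint."""
    changed = True
    while changed:
        changed = False
        G = g.graph()
        for centre in sorted(g.node_info):
            if centre not in g.node_info:
                continue
            nbrs = sorted(nb for nb in g.graph().neighbors(centre) if nb != centre)
            for i, u in enumerate(nbrs):
                if u not in g.node_info:
                    continue
                for v in nbrs[i + 1 :]:
                    if v not in g.node_info or u not in g.node_info or u == v:
                        continue
                    pu = g.rep_record(u).prot_seq or g.rep_record(u).dna_seq
                    pv = g.rep_record(v).prot_seq or g.rep_record(v).dna_seq
                    if not pu or not pv:
                        continue
                    # cheap length screen: < threshold identity is impossible
                    # when lengths differ too much for a global alignment
                    if min(len(pu), len(pv)) / max(len(pu), len(pv)) < cfg.family_threshold - 0.05:
                        continue
                    if pairwise_stats(pu, pv).identity >= cfg.family_threshold:
                        keep, drop = _merge_order(g, u, v)
                        g.merge_nodes(keep, drop)
                        g.node_info[keep].diverse_family = True
                        changed = True
    return g


# -------------------------------------------------------------------- stage 5


def refind_missing_genes(
    g: PangenomeGraph,
    cfg: CleanConfig,
    contigs: Mapping[tuple[str, str], str],
) -> list[dict]:
    """Search for unannotated copies of each node near its graph neighbours.

    For every (node, genome) pair where the genome is absent from the node
    but present in one of its neighbours, the contig window of
    +-``search_radius`` bp around the neighbouring gene is scanned with an
    edit-distance infix alignment of the node's DNA representative (both
    strands).  Hits meeting ``refind_identity`` and ``refind_coverage`` (of
    the representative length) are added as ``refound`` members; contig
    annotations on disk are never altered.

    *contigs* maps (genome_id, contig_id) to the contig sequence.
    """
    before = len(g.refind_log)
    counter = 0
    for node in g.nodes():
        rep = g.rep_record(node).dna_seq
        if not rep:
            continue
        present = set(g.node_members[node])
        absent = [gn for gn in g.genomes if gn not in present]
        if not absent:
            continue
        # search with several member alleles, not just the representative:
        # the nearest allele in the population is far less diverged from the
        # target genome than an arbitrary single representative
        queries = [rep]
        for genome in sorted(present):
            alt = g.records[g.node_members[node][genome][0]].dna_seq
            if alt and alt not in queries:
                queries.append(alt)
            if len(queries) >= 6:
                break
        G = g.graph()
        nbr_nodes = sorted(nb for nb in G.neighbors(node) if nb != node)
        for genome in absent:
            hit = None
            for nb in nbr_nodes:
                anchor_ids = g.node_members.get(nb, {}).get(genome)
                if not anchor_ids:
                    continue
                anchor = g.records[anchor_ids[0]]
                seq = contigs.get((genome, anchor.contig_id))
                if seq is None:
                    continue
                w_start = max(0, anchor.start - cfg.search_radius)
                w_end = min(len(seq), anchor.end + cfg.search_radius)
                clipped = (anchor.start - cfg.search_radius < 0) or (
                    anchor.end + cfg.search_radius > len(seq)
                )
                window = seq[w_start:w_end]
                if len(window) < 3:
                    continue
                for q in queries:
                    for strand, query in (("+", q), ("-", reverse_complement(q))):
                        st, (h0, h1) = infix_locate(query, window)
                        if st.identity >= cfg.refind_identity and st.coverage >= cfg.refind_coverage:
                            hit = (anchor.contig_id, w_start + h0, w_start + h1, strand, clipped)
                            break
                    if hit:
                        break
                if hit:
                    break
            if hit is None:
                continue
            contig_id, h0, h1, strand, truncated = hit
            span = contigs[(genome, contig_id)][h0:h1]
            dna = reverse_complement(span) if strand == "-" else span
            counter += 1
            rec = GeneRecord(
                gene_id=f"{genome}|refound_{node}_{counter}",
                genome_id=genome,
                contig_id=contig_id,
                start=h0,
                end=h1,
                strand=strand,
                dna_seq=dna,
                prot_seq=translate(dna) if len(dna) >= 3 else "",
                annotation=g.consensus_annotation(node),
                pseudo=(len(dna) % 3) != 0,
                refound=True,
            )
            note = "sequence match near neighbouring gene"
            if truncated:
                note += " (window truncated at contig edge)"
            g.add_refound(node, rec, note)
    return g.refind_log[before:]


# ------------------------------------------------------------------- pipeline


def polish_graph(
    g: PangenomeGraph,
    cfg: CleanConfig,
    contigs: Mapping[tuple[str, str], str] | None = None,
    refind: bool = True,
) -> PangenomeGraph:
    """Run all five correction stages in order on *g* (mutated in place)."""
    trim_contig_end_stubs(g, cfg)
    remove_contamination(g, cfg)
    merge_mistranslations(g, cfg)
    collapse_families(g, cfg)
    if refind and contigs is not None:
        refind_missing_genes(g, cfg, contigs)
    return g


def build_pangenome(
    records: Sequence[GeneRecord],
    contig_seqs: Iterable[ContigSeq] | Mapping[tuple[str, str], str],
    cfg: CleanConfig | None = None,
    genomes: Iterable[str] | None = None,
    refind: bool = True,
) -> PangenomeGraph:
    """Full pipeline: cluster -> build graph -> resolve paralogs -> polish."""
    cfg = cfg or CleanConfig()
    if isinstance(contig_seqs, Mapping):
        contig_map = dict(contig_seqs)
    else:
        contig_map = {(c.genome_id, c.contig_id): c.sequence for c in contig_seqs}
    clusters = cluster_sequences(records, identity=cfg.cluster_identity)
    g = build_graph(clusters, records, genomes=genomes)
    collapse_paralogs(g)
    polish_graph(g, cfg, contig_map, refind=refind)
    return g
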