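"""The population gene-adjacency pangenome graph.

Nodes are clusters of orthologous genes (gene families); an edge joins two
nodes when their genes appear adjacent on at least one contig in any genome.
Each genome's gene order induces a *path* through the graph, and the graph is
always derivable from the current gene table — node membership plus the
per-contig gene order are the single source of truth, so edges stay
consistent through every correction stage.

Paralogous families (more than one gene in some genome) are first split into
one node per gene occurrence and then collapsed back to the maximum
per-genome copy number, with occurrences grouped by shared neighbourhood
context.
"""

from __future__ import annotations

import bisect
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .annotation_io import GeneRecord, translate
from .clustering import SeqCluster

__all__ = ["PangenomeGraph", "build_graph", "collapse_paralogs"]


@dataclass
class NodeInfo:
    rep_gene: str                  # gene_id of the representative sequence
    family: int                    # initial cluster id (stable family label)
    is_paralog_copy: bool = False
    diverse_family: bool = False


class PangenomeGraph:
    """Mutable pangenome graph backed by the gene table.

    Attributes
    ----------
    records : dict gene_id -> GeneRecord (live genes only)
    gene_node : dict gene_id -> node_id
    node_info : dict node_id -> NodeInfo
    node_members : dict node_id -> {genome_id: [gene_id, ...]}
    contig_genes : dict (genome_id, contig_id) -> [gene_id, ...] ordered by start
    """

    def __init__(self, genomes: Iterable[str] = ()) -> None:
        self.records: dict[str, GeneRecord] = {}
        self.gene_node: dict[str, int] = {}
        self.node_info: dict[int, NodeInfo] = {}
        self.node_members: dict[int, dict[str, list[str]]] = {}
        self.contig_genes: dict[tuple[str, str], list[str]] = {}
        self.genomes: list[str] = sorted(set(genomes))
        self.removal_log: list[dict] = []
        self.refind_log: list[dict] = []
        self._graph: nx.Graph | None = None
        self._next_node = 0

    # ------------------------------------------------------------------ basics

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)

    def nodes(self) -> list[int]:
        return sorted(self.node_info)

    def support(self, node: int) -> int:
        return len(self.node_members[node])

    def members(self, node: int) -> dict[str, list[str]]:
        return self.node_members[node]

    def rep_record(self, node: int) -> GeneRecord:
        return self.records[self.node_info[node].rep_gene]

    def total_gene_count(self) -> int:
        return len(self.gene_node)

    def _invalidate(self) -> None:
        self._graph = None

    def _new_node(self, rep_gene: str, family: int, paralog: bool = False) -> int:
        nid = self._next_node
        self._next_node += 1
        self.node_info[nid] = NodeInfo(rep_gene, family, is_paralog_copy=paralog)
        self.node_members[nid] = {}
        return nid

    def _attach(self, node: int, rec: GeneRecord) -> None:
        self.records[rec.gene_id] = rec
        self.gene_node[rec.gene_id] = node
        self.node_members[node].setdefault(rec.genome_id, []).append(rec.gene_id)

    # ------------------------------------------------------------------- paths

    def paths(self) -> dict[tuple[str, str], list[int]]:
        """Per-contig node paths (raw; tandem repeats appear as equal
        consecutive entries)."""
        return {
            key: [self.gene_node[g] for g in genes]
            for key, genes in self.contig_genes.items()
            if genes
        }

    def graph(self) -> nx.Graph:
        """The adjacency graph rebuilt from the current gene table (cached)."""
        if self._graph is not None:
            return self._graph
        G = nx.Graph()
        for nid in self.node_info:
            G.add_node(nid, support=self.support(nid))
        for (genome, _contig), genes in self.contig_genes.items():
            for a, b in zip(genes, genes[1:]):
                u, v = self.gene_node[a], self.gene_node[b]
                if G.has_edge(u, v):
                    G[u][v]["genomes"].add(genome)
                else:
                    G.add_edge(u, v, genomes={genome})
        for u, v, data in G.edges(data=True):
            data["support"] = len(data["genomes"])
        self._graph = G
        return G

    def degree(self, node: int) -> int:
        """Graph degree ignoring self-loops (tandem-repeat edges)."""
        G = self.graph()
        return sum(1 for nb in G.neighbors(node) if nb != node)

    # -------------------------------------------------------------- mutations

    def delete_node(self, node: int, reason: str, stage: str) -> None:
        for genome, genes in self.node_members[node].items():
            for gid in genes:
                self.removal_log.append(
                    {
                        "node_id": node,
                        "genome_id": genome,
                        "gene_id": gid,
                        "action": "removed",
                        "reason": reason,
                        "stage": stage,
                    }
                )
                rec = self.records.pop(gid)
                self.gene_node.pop(gid)
                self.contig_genes[(rec.genome_id, rec.contig_id)].remove(gid)
        del self.node_members[node]
        del self.node_info[node]
        self._invalidate()

    def merge_nodes(self, keep: int, drop: int) -> None:
        """Absorb *drop* into *keep*; genomes ending up with several members
        have contig-adjacent copies rejoined into one logical gene."""
        for genome, genes in self.node_members[drop].items():
            self.node_members[keep].setdefault(genome, []).extend(genes)
            for gid in genes:
                self.gene_node[gid] = keep
        del self.node_members[drop]
        del self.node_info[drop]
        self._invalidate()
        self._rejoin_adjacent(keep)

    def _rejoin_adjacent(self, node: int) -> None:
        """Within *node*, merge members of the same genome that sit adjacent
        on a contig into a single concatenated logical gene (fragment
        rejoin after a frame-shift or mistranslation merge)."""
        for genome in list(self.node_members[node]):
            genes = self.node_members[node][genome]
            if len(genes) <= 1:
                continue
            by_contig: dict[str, list[str]] = defaultdict(list)
            for gid in genes:
                by_contig[self.records[gid].contig_id].append(gid)
            for contig, gids in by_contig.items():
                order = self.contig_genes[(genome, contig)]
                idx = sorted(order.index(g) for g in gids)
                # split into maximal runs of consecutive contig positions
                runs: list[list[int]] = [[idx[0]]]
                for i in idx[1:]:
                    if i == runs[-1][-1] + 1:
                        runs[-1].append(i)
                    else:
                        runs.append([i])
                for run in runs:
                    if len(run) > 1:
                        self._concatenate(node, genome, contig, [order[i] for i in run])

    def _concatenate(self, node: int, genome: str, contig: str, gids: list[str]) -> None:
        recs = [self.records[g] for g in gids]
        recs.sort(key=lambda r: r.start)
        strand = recs[0].strand
        parts = recs if strand == "+" else list(reversed(recs))
        dna = "".join(r.dna_seq for r in parts)
        merged = GeneRecord(
            gene_id="+".join(r.gene_id for r in parts),
            genome_id=genome,
            contig_id=contig,
            start=min(r.start for r in recs),
            end=max(r.end for r in recs),
            strand=strand,
            dna_seq=dna,
            prot_seq=translate(dna) if len(dna) >= 3 else "",
            annotation=next((r.annotation for r in recs if r.annotation), ""),
            pseudo=(len(dna) % 3) != 0,
            refound=all(r.refound for r in recs),
        )
        order = self.contig_genes[(genome, contig)]
        first = min(order.index(g) for g in gids)
        for g in gids:
            order.remove(g)
            del self.records[g]
            del self.gene_node[g]
        order.insert(first, merged.gene_id)
        if self.node_info[node].rep_gene in gids:
            self.node_info[node].rep_gene = merged.gene_id
        members = self.node_members[node][genome]
        self.node_members[node][genome] = [g for g in members if g not in gids]
        self._attach(node, merged)
        self._invalidate()

    def add_refound(self, node: int, rec: GeneRecord, note: str = "") -> None:
        """Insert a gene located by sequence search (no annotation on disk)."""
        key = (rec.genome_id, rec.contig_id)
        order = self.contig_genes.setdefault(key, [])
        starts = [self.records[g].start for g in order]
        pos = bisect.bisect_left(starts, rec.start)
        order.insert(pos, rec.gene_id)
        self._attach(node, rec)
        self.refind_log.append(
            {
                "node_id": node,
                "genome_id": rec.genome_id,
                "gene_id": rec.gene_id,
                "action": "refound",
                "reason": note or "sequence match near neighbouring gene",
                "stage": "refind",
            }
        )
        self._invalidate()

    # ------------------------------------------------------------- utilities

    def neighbour_families(self, node: int, radius: int = 1) -> set[int]:
        """Family labels of all nodes within graph distance *radius*."""
        G = self.graph()
        seen = {node}
        frontier = {node}
        fams: set[int] = set()
        for _ in range(radius):
            nxt = set()
            for n in frontier:
                for nb in G.neighbors(n):
                    if nb not in seen:
                        nxt.add(nb)
                        seen.add(nb)
                        fams.add(self.node_info[nb].family)
            frontier = nxt
        return fams

    def consensus_annotation(self, node: int) -> str:
        anns = [
            self.records[g].annotation
            for genes in self.node_members[node].values()
            for g in genes
            if self.records[g].annotation
        ]
        informative = [a for a in anns if a.lower() != "hypothetical protein"]
        pool = informative or anns
        if not pool:
            return "hypothetical protein"
        return Counter(pool).most_common(1)[0][0]

    def copy(self) -> "PangenomeGraph":
        import copy as _copy

        return _copy.deepcopy(self)


# ---------------------------------------------------------------------- build


def build_graph(
    clusters: Sequence[SeqCluster],
    records: Sequence[GeneRecord],
    genomes: Iterable[str] | None = None,
) -> PangenomeGraph:
    """Assemble the initial graph from sequence clusters.

    Clusters with at most one gene per genome become single nodes; paralogous
    clusters are split into one node per gene occurrence (they are collapsed
    back by :func:`collapse_paralogs`).  Genomes listed in *genomes* but
    absent from *records* are retained as empty paths.
    """
    rec_by_id = {r.gene_id: r for r in records}
    genome_set = {r.genome_id for r in records}
    if genomes is not None:
        genome_set |= set(genomes)
    g = PangenomeGraph(genome_set)

    for rec in sorted(records, key=lambda r: (r.genome_id, r.contig_id, r.start)):
        g.contig_genes.setdefault((rec.genome_id, rec.contig_id), []).append(rec.gene_id)

    for cl in clusters:
        per_genome = Counter(rec_by_id[gid].genome_id for gid in cl.members)
        paralog = any(c > 1 for c in per_genome.values())
        if not paralog:
            node = g._new_node(cl.representative, cl.cluster_id)
            for gid in cl.members:
                g._attach(node, rec_by_id[gid])
        else:
            for gid in sorted(cl.members):
                node = g._new_node(gid, cl.cluster_id, paralog=True)
                g._attach(node, rec_by_id[gid])
    return g


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def collapse_paralogs(g: PangenomeGraph) -> PangenomeGraph:
    """Collapse per-occurrence paralog nodes back to the maximum per-genome
    copy number, grouping occurrences by shared neighbourhood context.

    The context score is the Jaccard overlap of neighbour family sets at
    graph distance 1, extended to distance <= 3 on ties; remaining ties fall
    back to larger target-node support, then node id order.  After collapsing,
    every genome contributes at most one gene per node.
    """
    by_family: dict[int, list[int]] = defaultdict(list)
    for nid, info in g.node_info.items():
        if info.is_paralog_copy:
            by_family[info.family].append(nid)

    for family in sorted(by_family):
        occs = sorted(by_family[family])
        if len(occs) <= 1:
            continue
        per_genome: dict[str, list[int]] = defaultdict(list)
        for nid in occs:
            (genome,) = g.node_members[nid].keys()
            per_genome[genome].append(nid)
        kmax = max(len(v) for v in per_genome.values())
        seed_genome = min(gn for gn, v in per_genome.items() if len(v) == kmax)
        bins = sorted(
            per_genome[seed_genome],
            key=lambda n: (g.rep_record(n).contig_id, g.rep_record(n).start),
        )
        for genome in sorted(per_genome):
            if genome == seed_genome:
                continue
            occ_list = sorted(per_genome[genome])
            scored = []
            for occ in occ_list:
                occ_ctx1 = g.neighbour_families(occ, 1)
                occ_ctx3 = g.neighbour_families(occ, 3)
                for b in bins:
                    s1 = _jaccard(occ_ctx1, g.neighbour_families(b, 1))
                    s3 = _jaccard(occ_ctx3, g.neighbour_families(b, 3))
                    scored.append((-s1, -s3, -g.support(b), b, occ))
            scored.sort()
            used_bins: set[int] = set()
            used_occs: set[int] = set()
            for _s1, _s3, _sup, b, occ in scored:
                if b in used_bins or occ in used_occs:
                    continue
                used_bins.add(b)
                used_occs.add(occ)
                g.merge_nodes(b, occ)
    return g
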