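"""Standard output formats, summary statistics and input quality control.

Everything here derives from one in-memory :class:`~panclean.pangraph.PangenomeGraph`:
the Roary-style gene presence/absence CSV and its binary Rtab twin, a fully
annotated GML graph for Cytoscape, per-cluster unaligned FASTA, prevalence
summaries (core / soft-core / shell / cloud), an annotation-conflict audit,
and a robust contig/gene-count outlier screen for input genomes.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .annotation_io import GeneRecord
from .pangraph import PangenomeGraph

__all__ = [
    "node_label",
    "presence_absence",
    "write_matrix",
    "read_rtab",
    "read_presence_csv",
    "write_gml",
    "read_gml",
    "write_cluster_fasta",
    "PangenomeSummary",
    "summarise",
    "count_annotation_conflicts",
    "qc_outliers",
    "write_logs",
]

REFOUND_TAG = "_refound"


def node_label(node_id: int) -> str:
    return f"group_{node_id}"


def _ordered_nodes(g: PangenomeGraph) -> list[int]:
    # deterministic output order: support descending, then node id
    return sorted(g.nodes(), key=lambda n: (-g.support(n), n))


def presence_absence(g: PangenomeGraph) -> pd.DataFrame:
    """Binary genomes x clusters matrix; column sums equal node supports."""
    nodes = _ordered_nodes(g)
    data = np.zeros((len(g.genomes), len(nodes)), dtype=int)
    gidx = {gn: i for i, gn in enumerate(g.genomes)}
    for j, n in enumerate(nodes):
        for genome in g.node_members[n]:
            data[gidx[genome], j] = 1
    df = pd.DataFrame(data, index=list(g.genomes),
                      columns=[node_label(n) for n in nodes])
    df.index.name = "genome"
    return df


def write_matrix(g: PangenomeGraph, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write gene_presence_absence.csv (Roary-style) and .Rtab.

    CSV columns: Gene, Annotation, No. isolates, then one column per genome
    holding the member gene ids (multiple ids joined by ';'; refound members
    tagged with a ``_refound`` suffix).
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    nodes = _ordered_nodes(g)
    rows = []
    for n in nodes:
        row = {
            "Gene": node_label(n),
            "Annotation": g.consensus_annotation(n),
            "No. isolates": g.support(n),
        }
        for genome in g.genomes:
            ids = []
            for gid in g.node_members[n].get(genome, []):
                local = g.records[gid].gene_id
                if g.records[gid].refound:
                    local += REFOUND_TAG
                ids.append(local)
            row[genome] = ";".join(ids)
        rows.append(row)
    csv_path = out_prefix.with_suffix(".csv")
    pd.DataFrame(rows).to_csv(csv_path, index=False)

    rtab_path = out_prefix.with_suffix(".Rtab")
    mat = presence_absence(g).T
    mat.index.name = "Gene"
    mat.to_csv(rtab_path, sep="\t")
    return csv_path, rtab_path


def read_rtab(path: str | Path) -> pd.DataFrame:
    """Read an Rtab file back to a genomes x clusters binary matrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    out = df.T.astype(int)
    out.index.name = "genome"
    return out


def read_presence_csv(path: str | Path) -> pd.DataFrame:
    """Reconstruct the binary matrix from the Roary-style CSV (a cell is
    present iff its gene-id field is non-empty)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    genomes = [c for c in df.columns if c not in ("Gene", "Annotation", "No. isolates")]
    data = {
        row["Gene"]: [1 if row[gn] else 0 for gn in genomes]
        for _, row in df.iterrows()
    }
    out = pd.DataFrame(data, index=genomes, dtype=int)
    out.index.name = "genome"
    return out


# ------------------------------------------------------------------ GML/FASTA


def _nx_export(g: PangenomeGraph) -> nx.Graph:
    G = nx.Graph()
    for n in sorted(g.node_info):
        info = g.node_info[n]
        G.add_node(
            node_label(n),
            annotation=g.consensus_annotation(n),
            support=g.support(n),
            genomes=";".join(sorted(g.node_members[n])),
            paralog=int(info.is_paralog_copy),
            diverse=int(info.diverse_family),
            dna=g.rep_record(n).dna_seq,
        )
    H = g.graph()
    for u, v, data in H.edges(data=True):
        G.add_edge(
            node_label(u),
            node_label(v),
            genomes=";".join(sorted(data["genomes"])),
            support=data["support"],
        )
    return G


def write_gml(g: PangenomeGraph, path: str | Path) -> None:
    """Annotated pangenome graph in GML for Cytoscape-style viewers.

    Node attributes: genome list, consensus annotation, support, paralog and
    diverse-family flags, representative DNA.  networkx escapes GML-reserved
    characters, so the file round-trips through any generic GML parser.
    """
    nx.write_gml(_nx_export(g), str(path))


def read_gml(path: str | Path) -> nx.Graph:
    return nx.read_gml(str(path))


def write_cluster_fasta(g: PangenomeGraph, out_dir: str | Path) -> list[Path]:
    """One unaligned DNA FASTA per cluster (all member sequences)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for n in _ordered_nodes(g):
        p = out_dir / f"{node_label(n)}.fasta"
        with open(p, "w") as fh:
            for genome in sorted(g.node_members[n]):
                for gid in g.node_members[n][genome]:
                    fh.write(f">{gid}\n{g.records[gid].dna_seq}\n")
        paths.append(p)
    return paths


def write_logs(g: PangenomeGraph, path: str | Path) -> None:
    """Removal/refind audit trail as TSV (node, genome, gene, action, reason)."""
    rows = g.removal_log + g.refind_log
    cols = ["node_id", "genome_id", "gene_id", "action", "reason", "stage"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# -------------------------------------------------------------------- summary


@dataclass
class PangenomeSummary:
    core: int
    soft_core: int
    shell: int
    cloud: int

    @property
    def total(self) -> int:
        return self.core + self.soft_core + self.shell + self.cloud


def summarise(
    g: PangenomeGraph,
    core_threshold: float = 0.99,
    soft_core: float = 0.95,
    shell: float = 0.15,
) -> PangenomeSummary:
    """Bin clusters by prevalence: core >= 99% of genomes by default (the
    Roary convention), then soft-core, shell, and cloud below that."""
    if not (core_threshold > soft_core > shell):
        raise ValueError("thresholds must be strictly decreasing: core > soft_core > shell")
    counts = [0, 0, 0, 0]
    n = g.n_genomes
    for node in g.nodes():
        prev = g.support(node) / n
        if prev >= core_threshold:
            counts[0] += 1
        elif prev >= soft_core:
            counts[1] += 1
        elif prev >= shell:
            counts[2] += 1
        else:
            counts[3] += 1
    return PangenomeSummary(*counts)


# ------------------------------------------------------------------ conflicts


_COPY_SUFFIX = re.compile(r"_\d+$")


def _normalise_annotation(text: str) -> str:
    t = " ".join(text.lower().split())
    return _COPY_SUFFIX.sub("", t)


def count_annotation_conflicts(g: PangenomeGraph) -> tuple[int, dict[int, set[str]]]:
    """Clusters whose members carry conflicting product annotations.

    'hypothetical protein' and fragment-flagged (partial) members are
    excluded before comparison — such annotations are frequently erroneous
    and would inflate the count.  Returns (count, {node: conflicting set}).
    """
    conflicts: dict[int, set[str]] = {}
    for n in g.nodes():
        anns = set()
        for genome, genes in g.node_members[n].items():
            for gid in genes:
                rec = g.records[gid]
                if rec.partial or rec.refound:
                    continue
                norm = _normalise_annotation(rec.annotation)
                if norm and norm != "hypothetical protein":
                    anns.add(norm)
        if len(anns) >= 2:
            conflicts[n] = anns
    return len(conflicts), conflicts


# ------------------------------------------------------------------------- QC


def qc_outliers(
    genomes: dict[str, list[GeneRecord]], k: float = 3.0
) -> pd.DataFrame:
    """Flag genomes whose contig count or gene count lies outside
    median +- k*MAD across the collection.  Advisory only — nothing is
    excluded automatically.  Requires at least five genomes."""
    if len(genomes) < 5:
        raise ValueError("outlier screening needs at least 5 genomes")
    rows = []
    for genome in sorted(genomes):
        recs = genomes[genome]
        rows.append(
            {
                "genome": genome,
                "n_genes": len(recs),
                "n_contigs": len({r.contig_id for r in recs}),
            }
        )
    df = pd.DataFrame(rows).set_index("genome")
    for col in ("n_genes", "n_contigs"):
        x = df[col].to_numpy(dtype=float)
        med = np.median(x)
        # MAD floored at one count so clonal collections (MAD = 0) still
        # have a non-degenerate fence
        mad = max(np.median(np.abs(x - med)), 1.0)
        df[f"{col}_outlier"] = np.abs(x - med) > k * mad
    df["flagged"] = df["n_genes_outlier"] | df["n_contigs_outlier"]
    return df
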