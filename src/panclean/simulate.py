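"""Synthetic pangenome generator with annotation-error injection.

The generator emulates, at the annotation level, the standard way bacterial
pangenome variation is simulated: a Kingman-coalescent genealogy over the
sampled genomes, gene gain and loss along its branches (each gained gene
founds a new family — the infinitely-many-genes regime — on top of a fixed
persistent core), per-gene nucleotide substitution, and a syntenic circular
gene order that is linearised at a shared origin, mimicking complete
assemblies rotated to a fixed origin gene.

``inject_errors`` then reproduces the error classes that real annotation
pipelines introduce:

* **fragmentation** — the chromosome is cut into contigs; genes severed by a
  cut survive as partial CDS (or lose their annotation if the piece is tiny);
* **contamination** — 10-kb foreign segments (count ~ Poisson per genome)
  carrying genes from a disjoint synthetic contaminant namespace are added
  as extra contigs;
* **dropout** — annotations deleted while the DNA stays intact;
* **frame-shift splitting** — a CDS is broken into two adjacent features.

Every event is recorded in :class:`SimTruth`, which carries the ground-truth
family of every emitted gene and the pre-error presence/absence matrix, so
pipeline output can be scored exactly.
"""

from __future__ import annotations

import copy
import json
import random as _random
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .annotation_io import ContigSeq, GeneRecord, reverse_complement, translate, write_gff3
from .pangraph import PangenomeGraph

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimulatedPangenome",
    "simulate_pangenome",
    "inject_errors",
    "split_gene",
    "score_against_truth",
    "ErrorReport",
]

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Rates are per unit coalescent time (the tree height is O(1) in these
    units).  ``substitution_rate`` is per site per unit time.  The default
    error-injection fields are all off; scenario runs switch them on.
    """

    n_genomes: int = 20
    n_core_genes: int = 200
    gain_rate: float = 20.0
    loss_rate: float = 0.5
    substitution_rate: float = 0.001
    gene_length_mean: int = 900
    gene_length_sd: int = 150
    gene_length_min: int = 300
    spacer_min: int = 50
    spacer_max: int = 200
    n_paralog_families: int = 0
    paralog_carrier_fraction: float = 0.5
    fragmentation: int = 1                 # target contig count per genome
    contamination_mean: float = 0.0        # Poisson mean segments per genome
    contamination_segment_length: int = 10_000
    dropout_prob: float = 0.0
    frameshift_prob: float = 0.0
    min_partial_length: int = 150          # smaller severed pieces lose annotation
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dropout_prob", "frameshift_prob", "paralog_carrier_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_genomes < 2:
            raise ValueError("need at least two genomes")
        if self.fragmentation < 1:
            raise ValueError("fragmentation is a contig count, must be >= 1")


@dataclass
class SimTruth:
    """Ground truth for scoring: the true family of every emitted gene, the
    injected-error event lists, and the pre-error presence/absence matrix."""

    family_of: dict[str, str]
    matrix: pd.DataFrame                      # genomes x families, pre-error
    tree_newick: str
    paralog_copy: dict[str, int] = field(default_factory=dict)
    contaminant_genes: set[str] = field(default_factory=set)
    contaminant_families: set[str] = field(default_factory=set)
    dropped_genes: set[str] = field(default_factory=set)
    severed_genes: set[str] = field(default_factory=set)
    frameshift_pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "family_of": self.family_of,
            "matrix": {
                "index": list(self.matrix.index),
                "columns": list(self.matrix.columns),
                "data": self.matrix.to_numpy(dtype=int).tolist(),
            },
            "tree_newick": self.tree_newick,
            "paralog_copy": self.paralog_copy,
            "contaminant_genes": sorted(self.contaminant_genes),
            "contaminant_families": sorted(self.contaminant_families),
            "dropped_genes": sorted(self.dropped_genes),
            "severed_genes": sorted(self.severed_genes),
            "frameshift_pairs": [list(p) for p in self.frameshift_pairs],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        m = d["matrix"]
        return cls(
            family_of=d["family_of"],
            matrix=pd.DataFrame(m["data"], index=m["index"], columns=m["columns"]),
            tree_newick=d["tree_newick"],
            paralog_copy={k: int(v) for k, v in d["paralog_copy"].items()},
            contaminant_genes=set(d["contaminant_genes"]),
            contaminant_families=set(d["contaminant_families"]),
            dropped_genes=set(d["dropped_genes"]),
            severed_genes=set(d["severed_genes"]),
            frameshift_pairs=[tuple(p) for p in d["frameshift_pairs"]],
        )


@dataclass
class SimulatedPangenome:
    """Per-genome annotated assemblies held in memory."""

    genomes: dict[str, tuple[list[GeneRecord], list[ContigSeq]]]

    def records(self) -> list[GeneRecord]:
        return [r for recs, _ in self.genomes.values() for r in recs]

    def contig_map(self) -> dict[tuple[str, str], str]:
        return {
            (c.genome_id, c.contig_id): c.sequence
            for _, contigs in self.genomes.values()
            for c in contigs
        }

    def write(self, out_dir: str | Path) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for genome in sorted(self.genomes):
            recs, contigs = self.genomes[genome]
            p = out_dir / f"{genome}.gff"
            write_gff3(recs, contigs, p)
            paths.append(p)
        return paths

    def copy(self) -> "SimulatedPangenome":
        return copy.deepcopy(self)


# --------------------------------------------------------------- simulation


def _random_coding_seq(rng: np.random.Generator, length: int) -> str:
    n_codons = max(2, length // 3)
    body = "".join(
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons - 2)
    )
    return "ATG" + body + _STOPS[rng.integers(0, 3)]


def _mutate(seq: str, rate: float, t: float, rng: np.random.Generator) -> str:
    nsub = rng.poisson(rate * t * len(seq))
    if nsub == 0:
        return seq
    chars = list(seq)
    for pos in rng.integers(0, len(chars), nsub):
        old = chars[pos]
        alts = [b for b in _BASES if b != old]
        chars[pos] = alts[rng.integers(0, 3)]
    return "".join(chars)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, length))


def _gene_length(cfg: SimConfig, rng: np.random.Generator) -> int:
    L = int(round(rng.normal(cfg.gene_length_mean, cfg.gene_length_sd)))
    L = max(cfg.gene_length_min, L)
    return (L // 3) * 3


def simulate_pangenome(
    cfg: SimConfig, out_dir: str | Path | None = None
) -> tuple[SimulatedPangenome, SimTruth]:
    """Simulate a pangenome under the configured study conditions.

    Returns the in-memory assemblies and the ground truth; if *out_dir* is
    given, one Prokka-dialect GFF3 per genome is also written there.  Output
    is fully determined by ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    genome_ids = [f"genome_{i:03d}" for i in range(cfg.n_genomes)]

    # genealogy: Kingman coalescent, ultrametric, time in coalescent units
    taxa = dendropy.TaxonNamespace(genome_ids)
    tree = treesim.pure_kingman_tree(
        taxon_namespace=taxa, pop_size=1.0, rng=_random.Random(int(rng.integers(2**31)))
    )
    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()

    # gene content along the tree: persistent core + IMG-style accessory
    fam_counter = [0]

    def new_family() -> str:
        fam_counter[0] += 1
        return f"acc_{fam_counter[0]:05d}"

    core_fams = [f"core_{i:04d}" for i in range(cfg.n_core_genes)]
    root_pool = 0
    if cfg.loss_rate > 0 and cfg.gain_rate > 0:
        root_pool = int(rng.poisson(cfg.gain_rate / cfg.loss_rate))
    root_acc = [new_family() for _ in range(root_pool)]

    content: dict[int, list[str]] = {id(tree.seed_node): list(root_acc)}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length or 0.0
        parent = content[id(node.parent_node)]
        surv = [f for f in parent if rng.random() < np.exp(-cfg.loss_rate * t)]
        for _ in range(rng.poisson(cfg.gain_rate * t)):
            u = rng.uniform(0, t)
            if rng.random() < np.exp(-cfg.loss_rate * (t - u)):
                surv.append(new_family())
            else:
                fam_counter[0] += 1  # gained and lost on the branch, unseen
        content[id(node)] = surv

    leaf_content = {
        node.taxon.label: set(content[id(node)]) for node in tree.leaf_node_iter()
    }
    observed_acc = sorted(set().union(*leaf_content.values())) if leaf_content else []

    # chromosome geometry: circular order linearised at a shared origin just
    # before the first core gene; accessory genes insert between core genes
    core_keys = dict(zip(core_fams, np.sort(rng.uniform(0.0, 1.0, cfg.n_core_genes))))
    if cfg.n_core_genes == 0:
        raise ValueError("n_core_genes must be positive (genomes would be empty)")
    lo_key, hi_key = min(core_keys.values()), max(core_keys.values())
    all_fams = core_fams + observed_acc
    position_key: dict[str, float] = dict(core_keys)
    for fam in observed_acc:
        position_key[fam] = float(rng.uniform(lo_key, hi_key))
    strand_of = {fam: ("+" if rng.random() < 0.5 else "-") for fam in all_fams}

    # optional duplicated (paralogous) families: a second syntenic slot
    paralog_fams: list[str] = []
    paralog_key2: dict[str, float] = {}
    paralog_carriers: dict[str, set[str]] = {}
    if cfg.n_paralog_families > 0:
        picks = rng.choice(cfg.n_core_genes, size=cfg.n_paralog_families, replace=False)
        for pi in sorted(int(i) for i in picks):
            fam = core_fams[pi]
            paralog_fams.append(fam)
            paralog_key2[fam] = float(rng.uniform(lo_key, hi_key))
            k = int(round(cfg.paralog_carrier_fraction * cfg.n_genomes))
            carriers = rng.choice(cfg.n_genomes, size=k, replace=False)
            paralog_carriers[fam] = {genome_ids[int(i)] for i in sorted(carriers)}

    # sequences: created at the family's origin node, mutated down the tree
    seqs_at: dict[int, dict[str, str]] = {}
    root_seqs = {}
    for fam in core_fams + root_acc:
        root_seqs[fam] = _random_coding_seq(rng, _gene_length(cfg, rng))
    seqs_at[id(tree.seed_node)] = root_seqs
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length or 0.0
        parent_seqs = seqs_at[id(node.parent_node)]
        here: dict[str, str] = {}
        fams_here = set(core_fams) | set(content[id(node)])
        for fam in sorted(fams_here):
            if fam in parent_seqs:
                here[fam] = _mutate(parent_seqs[fam], cfg.substitution_rate, t, rng)
            else:  # gained on this branch: fresh sequence
                here[fam] = _random_coding_seq(rng, _gene_length(cfg, rng))
        seqs_at[id(node)] = here
    leaf_seqs = {
        node.taxon.label: seqs_at[id(node)] for node in tree.leaf_node_iter()
    }

    # assemble one chromosome per genome
    genomes: dict[str, tuple[list[GeneRecord], list[ContigSeq]]] = {}
    family_of: dict[str, str] = {}
    paralog_copy: dict[str, int] = {}
    for genome in genome_ids:
        fams = [(position_key[f], f, 1) for f in core_fams]
        fams += [(position_key[f], f, 1) for f in sorted(leaf_content[genome])]
        for fam in paralog_fams:
            if genome in paralog_carriers[fam]:
                fams.append((paralog_key2[fam], fam, 2))
        fams.sort()
        parts: list[str] = []
        records: list[GeneRecord] = []
        pos = 0
        for idx, (_key, fam, cp) in enumerate(fams):
            spacer = _random_dna(rng, int(rng.integers(cfg.spacer_min, cfg.spacer_max + 1)))
            parts.append(spacer)
            pos += len(spacer)
            coding = leaf_seqs[genome][fam]
            strand = strand_of[fam]
            parts.append(coding if strand == "+" else reverse_complement(coding))
            gid = f"{genome}|{genome}_{idx + 1:05d}"
            records.append(
                GeneRecord(
                    gene_id=gid,
                    genome_id=genome,
                    contig_id="chromosome",
                    start=pos,
                    end=pos + len(coding),
                    strand=strand,
                    dna_seq=coding,
                    prot_seq=translate(coding),
                    annotation=fam,
                    position_index=idx,
                )
            )
            family_of[gid] = fam
            if cp == 2:
                paralog_copy[gid] = 2
            elif fam in paralog_carriers and cp == 1:
                paralog_copy[gid] = 1
            pos += len(coding)
        tail = _random_dna(rng, int(rng.integers(cfg.spacer_min, cfg.spacer_max + 1)))
        parts.append(tail)
        contig = ContigSeq(genome, "chromosome", "".join(parts))
        if not records:
            raise ValueError(
                f"{genome} received no genes; raise n_core_genes or gain/loss rates"
            )
        genomes[genome] = (records, [contig])

    truth_cols = sorted(all_fams)
    data = np.zeros((cfg.n_genomes, len(truth_cols)), dtype=int)
    col_idx = {f: j for j, f in enumerate(truth_cols)}
    for i, genome in enumerate(genome_ids):
        for f in core_fams:
            data[i, col_idx[f]] = 1
        for f in leaf_content[genome]:
            data[i, col_idx[f]] = 1
    matrix = pd.DataFrame(data, index=genome_ids, columns=truth_cols)

    sim = SimulatedPangenome(genomes)
    truth = SimTruth(
        family_of=family_of,
        matrix=matrix,
        tree_newick=newick,
        paralog_copy=paralog_copy,
    )
    if out_dir is not None:
        sim.write(out_dir)
    return sim, truth


# ----------------------------------------------------------- error injection


def _reindex(records: list[GeneRecord]) -> None:
    records.sort(key=lambda r: (r.contig_id, r.start))
    counters: dict[str, int] = {}
    for r in records:
        r.position_index = counters.get(r.contig_id, 0)
        counters[r.contig_id] = r.position_index + 1


def split_gene(
    sim: SimulatedPangenome,
    truth: SimTruth,
    gene_id: str,
    cut_fraction: float = 0.5,
) -> tuple[str, str]:
    """Split one gene's CDS into two adjacent features at *cut_fraction* of
    its genomic span (the frame-shift mis-annotation scenario).  Mutates
    *sim*/*truth* in place and returns the two new gene ids."""
    genome = gene_id.split("|", 1)[0]
    records, contigs = sim.genomes[genome]
    rec = next(r for r in records if r.gene_id == gene_id)
    contig = next(c for c in contigs if c.contig_id == rec.contig_id)
    cut = rec.start + max(3, int(rec.length * cut_fraction))
    cut = min(cut, rec.end - 3)
    halves = []
    for tag, (s, e) in zip(("_1", "_2"), ((rec.start, cut), (cut, rec.end))):
        sub = contig.sequence[s:e]
        dna = reverse_complement(sub) if rec.strand == "-" else sub
        halves.append(
            GeneRecord(
                gene_id=rec.gene_id + tag,
                genome_id=genome,
                contig_id=rec.contig_id,
                start=s,
                end=e,
                strand=rec.strand,
                dna_seq=dna,
                prot_seq=translate(dna) if len(dna) >= 3 else "",
                annotation=rec.annotation,
                pseudo=(len(dna) % 3) != 0,
            )
        )
    records.remove(rec)
    records.extend(halves)
    _reindex(records)
    fam = truth.family_of.get(gene_id)
    if fam is not None:
        for h in halves:
            truth.family_of[h.gene_id] = fam
            if gene_id in truth.paralog_copy:
                truth.paralog_copy[h.gene_id] = truth.paralog_copy[gene_id]
    truth.frameshift_pairs.append((halves[0].gene_id, halves[1].gene_id))
    return halves[0].gene_id, halves[1].gene_id


def _add_contamination(
    sim: SimulatedPangenome,
    truth: SimTruth,
    cfg: SimConfig,
    rng: np.random.Generator,
    counter: list[int],
) -> None:
    for genome in sorted(sim.genomes):
        records, contigs = sim.genomes[genome]
        nseg = int(rng.poisson(cfg.contamination_mean))
        for si in range(nseg):
            contig_id = f"contam_{si + 1:02d}"
            parts: list[str] = []
            pos = 0
            new_recs: list[GeneRecord] = []
            while True:
                spacer = _random_dna(
                    rng, int(rng.integers(cfg.spacer_min, cfg.spacer_max + 1))
                )
                glen = _gene_length(cfg, rng)
                if pos + len(spacer) + glen > cfg.contamination_segment_length:
                    break
                parts.append(spacer)
                pos += len(spacer)
                counter[0] += 1
                fam = f"contam_{counter[0]:05d}"
                coding = _random_coding_seq(rng, glen)
                strand = "+" if rng.random() < 0.5 else "-"
                parts.append(coding if strand == "+" else reverse_complement(coding))
                gid = f"{genome}|{fam}"
                new_recs.append(
                    GeneRecord(
                        gene_id=gid,
                        genome_id=genome,
                        contig_id=contig_id,
                        start=pos,
                        end=pos + glen,
                        strand=strand,
                        dna_seq=coding,
                        prot_seq=translate(coding),
                        annotation=fam,
                    )
                )
                truth.family_of[gid] = fam
                truth.contaminant_genes.add(gid)
                truth.contaminant_families.add(fam)
                pos += glen
            pad = cfg.contamination_segment_length - pos
            if pad > 0:
                parts.append(_random_dna(rng, pad))
            contigs.append(ContigSeq(genome, contig_id, "".join(parts)))
            records.extend(new_recs)
        _reindex(records)


def _fragment_genome(
    sim: SimulatedPangenome,
    truth: SimTruth,
    cfg: SimConfig,
    rng: np.random.Generator,
    genome: str,
) -> None:
    records, contigs = sim.genomes[genome]
    chrom = next(c for c in contigs if c.contig_id == "chromosome")
    chrom_recs = sorted(
        (r for r in records if r.contig_id == "chromosome"), key=lambda r: r.start
    )
    n_cuts = cfg.fragmentation - 1
    cuts: list[int] = []
    for _ in range(n_cuts):
        if rng.random() < 0.8 or not chrom_recs:
            # intergenic cut: a point in a random gap between genes
            gaps = []
            prev = 0
            for r in chrom_recs:
                if r.start > prev:
                    gaps.append((prev, r.start))
                prev = max(prev, r.end)
            if prev < len(chrom):
                gaps.append((prev, len(chrom)))
            g0, g1 = gaps[int(rng.integers(0, len(gaps)))]
            cuts.append(int(rng.integers(g0, g1 + 1)))
        else:
            r = chrom_recs[int(rng.integers(0, len(chrom_recs)))]
            cuts.append(int(rng.integers(r.start + 3, r.end - 2)))
    cuts = sorted(set(cuts))
    bounds = [0] + cuts + [len(chrom)]

    new_contigs = [c for c in contigs if c.contig_id != "chromosome"]
    new_records = [r for r in records if r.contig_id != "chromosome"]
    for k, (b0, b1) in enumerate(zip(bounds, bounds[1:])):
        frag_id = f"chromosome_f{k + 1:02d}"
        new_contigs.append(ContigSeq(genome, frag_id, chrom.sequence[b0:b1]))
        for r in chrom_recs:
            if r.end <= b0 or r.start >= b1:
                continue
            if r.start >= b0 and r.end <= b1:          # intact on this fragment
                r2 = copy.copy(r)
                r2.contig_id = frag_id
                r2.start -= b0
                r2.end -= b0
                new_records.append(r2)
            else:                                       # severed by the cut
                s, e = max(r.start, b0), min(r.end, b1)
                truth.severed_genes.add(r.gene_id)
                if e - s < cfg.min_partial_length:
                    continue                            # piece too small: unannotated
                sub = chrom.sequence[s:e]
                dna = reverse_complement(sub) if r.strand == "-" else sub
                tag = "_p1" if r.start >= b0 else "_p2"
                pid = r.gene_id + tag
                new_records.append(
                    GeneRecord(
                        gene_id=pid,
                        genome_id=genome,
                        contig_id=frag_id,
                        start=s - b0,
                        end=e - b0,
                        strand=r.strand,
                        dna_seq=dna,
                        prot_seq=translate(dna) if len(dna) >= 3 else "",
                        annotation=r.annotation,
                        pseudo=(len(dna) % 3) != 0,
                        partial=True,
                    )
                )
                fam = truth.family_of.get(r.gene_id)
                if fam is not None:
                    truth.family_of[pid] = fam
    sim.genomes[genome] = (new_records, new_contigs)
    _reindex(new_records)


def inject_errors(
    sim: SimulatedPangenome, truth: SimTruth, cfg: SimConfig
) -> tuple[SimulatedPangenome, SimTruth]:
    """Apply the configured error classes to a clean simulation.

    Returns modified copies; the inputs are untouched.  Genes not named in
    any event list are byte-identical before and after.  Assembly-level
    errors are applied before annotation-level ones, matching the physical
    process: fragmentation, contamination, then annotation dropout and
    frame-shift splits.
    """
    sim = sim.copy()
    truth = copy.deepcopy(truth)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 17]))

    if cfg.fragmentation > 1:
        for genome in sorted(sim.genomes):
            _fragment_genome(sim, truth, cfg, rng, genome)

    if cfg.contamination_mean > 0:
        _add_contamination(sim, truth, cfg, rng, counter=[0])

    if cfg.dropout_prob > 0:
        for genome in sorted(sim.genomes):
            records, contigs = sim.genomes[genome]
            keep = []
            for r in sorted(records, key=lambda r: (r.contig_id, r.start)):
                if rng.random() < cfg.dropout_prob:
                    truth.dropped_genes.add(r.gene_id)
                else:
                    keep.append(r)
            sim.genomes[genome] = (keep, contigs)
            _reindex(keep)

    if cfg.frameshift_prob > 0:
        for genome in sorted(sim.genomes):
            records, _ = sim.genomes[genome]
            for gid in [r.gene_id for r in sorted(records, key=lambda r: r.gene_id)]:
                rec = next(r for r in records if r.gene_id == gid)
                if rec.length >= 18 and rng.random() < cfg.frameshift_prob:
                    split_gene(sim, truth, gid, cut_fraction=float(rng.uniform(0.3, 0.7)))

    return sim, truth


# -------------------------------------------------------------------- scoring


@dataclass
class ErrorReport:
    """Counts of erroneous inferred clusters, partitioned by error class,
    plus the cell-level confusion against the truth matrix."""

    accessory_inflation: int = 0     # clusters matching no simulated family
    missing_gene_clusters: int = 0   # families with >=1 false-negative genome
    wrong_merges: int = 0            # clusters mixing several true families
    wrong_splits: int = 0            # extra clusters mapping to the same family
    confusion: dict = field(default_factory=dict)   # tp/fp/fn/tn cells
    inflation_nodes: list = field(default_factory=list)
    inferred_matrix: pd.DataFrame | None = None

    @property
    def total_erroneous_clusters(self) -> int:
        return (
            self.accessory_inflation
            + self.missing_gene_clusters
            + self.wrong_merges
            + self.wrong_splits
        )


def _base_gene_ids(gene_id: str) -> list[str]:
    # concatenation-merged logical genes carry their source ids joined by '+'
    return gene_id.split("+")


def score_against_truth(
    graph_or_clusters: PangenomeGraph | dict,
    truth: SimTruth,
) -> ErrorReport:
    """Score an inferred clustering against the simulator's ground truth.

    Each cluster is assigned to a true family by majority vote over its
    members' truth labels (refound members carry no label and inherit the
    cluster's).  Clusters whose majority label is a contaminant family or
    unmappable count as accessory inflation; clusters mixing several true
    families are wrong merges; families claimed by several clusters are
    wrong splits (one error per extra cluster); families with at least one
    genome present in the truth matrix but absent from the inferred matrix
    are missing-gene errors.
    """
    if isinstance(graph_or_clusters, PangenomeGraph):
        g = graph_or_clusters
        cluster_members = {n: g.node_members[n] for n in g.nodes()}
        refound = {gid for gid, r in g.records.items() if r.refound}
    else:
        cluster_members = graph_or_clusters
        refound = set()

    report = ErrorReport()
    family_clusters: dict[str, list] = defaultdict(list)
    cluster_majority: dict = {}

    for node in sorted(cluster_members):
        labels: list[str] = []
        for genes in cluster_members[node].values():
            for gid in genes:
                if gid in refound:
                    continue
                for base in _base_gene_ids(gid):
                    fam = truth.family_of.get(base)
                    if fam is not None:
                        labels.append(fam)
        if not labels:
            report.accessory_inflation += 1
            report.inflation_nodes.append(node)
            continue
        counts = Counter(labels)
        maxc = max(counts.values())
        majority = min(f for f, c in counts.items() if c == maxc)
        cluster_majority[node] = majority
        if majority in truth.contaminant_families:
            report.accessory_inflation += 1
            report.inflation_nodes.append(node)
            continue
        non_artefact = {f for f in counts if f not in truth.contaminant_families}
        if len(non_artefact) > 1:
            report.wrong_merges += 1
        family_clusters[majority].append(node)

    # a duplicated family legitimately occupies one cluster per copy
    expected_clusters: dict[str, int] = {}
    for gid, cp in truth.paralog_copy.items():
        fam = truth.family_of.get(gid)
        if fam is not None:
            expected_clusters[fam] = max(expected_clusters.get(fam, 1), cp)
    for fam, nodes in family_clusters.items():
        report.wrong_splits += max(0, len(nodes) - expected_clusters.get(fam, 1))

    genomes = list(truth.matrix.index)
    inferred = pd.DataFrame(
        0, index=genomes, columns=list(truth.matrix.columns), dtype=int
    )
    for fam, nodes in family_clusters.items():
        if fam not in inferred.columns:
            continue
        for node in nodes:
            for genome in cluster_members[node]:
                if genome in inferred.index:
                    inferred.loc[genome, fam] = 1
    report.inferred_matrix = inferred

    T = truth.matrix.to_numpy(dtype=int)
    I = inferred.to_numpy(dtype=int)
    report.confusion = {
        "tp": int(((T == 1) & (I == 1)).sum()),
        "fn": int(((T == 1) & (I == 0)).sum()),
        "fp": int(((T == 0) & (I == 1)).sum()),
        "tn": int(((T == 0) & (I == 0)).sum()),
    }
    fn_per_family = ((T == 1) & (I == 0)).sum(axis=0)
    report.missing_gene_clusters = int((fn_per_family > 0).sum())
    return report
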