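"""The five correction stages and the mode contract."""

import copy

import pytest

from panclean import (
    CleanConfig,
    SimConfig,
    build_pangenome,
    inject_errors,
    split_gene,
)
from panclean.clustering import cluster_sequences
from panclean.pangraph import build_graph, collapse_paralogs
from panclean.polish import (
    collapse_families,
    merge_mistranslations,
    polish_graph,
    remove_contamination,
    trim_contig_end_stubs,
)
from panclean.outputs_qc import presence_absence
from helpers import make_genomes, SEQS


def _core_layout(n, fams=("A", "B", "C", "D")):
    return {f"gn{i:02d}": list(fams) for i in range(n)}


def test_config_validation():
    with pytest.raises(ValueError):
        CleanConfig(mode="aggressive")
    with pytest.raises(ValueError):
        CleanConfig(family_threshold=0.0)
    assert CleanConfig(mode="strict").support_threshold(100) == 5
    assert CleanConfig(mode="strict").support_threshold(20) == 2
    assert CleanConfig(mode="moderate").support_threshold(100) == 2


def test_dangling_stub_removed_except_in_sensitive_mode():
    layouts = _core_layout(10)
    layouts["gn00"] = ["Y", "A", "B", "C", "D"]    # support-1 stub at a path end
    recs, cls = make_genomes(layouts, SEQS)
    for mode, kept in (("strict", False), ("moderate", False), ("sensitive", True)):
        g = collapse_paralogs(build_graph(cls, recs))
        trim_contig_end_stubs(g, CleanConfig(mode=mode))
        names = {g.records[g.node_info[n].rep_gene].annotation for n in g.nodes()}
        assert ("Y" in names) == kept


def test_supported_path_end_never_removed():
    recs, cls = make_genomes(_core_layout(10), SEQS)
    g = collapse_paralogs(build_graph(cls, recs))
    trim_contig_end_stubs(g, CleanConfig(mode="strict"))
    assert len(g.nodes()) == 4     # A..D all retained: support 10 >= threshold


def test_disconnected_low_support_chain_is_contamination():
    layouts = _core_layout(10)
    recs, cls = make_genomes(layouts, SEQS)
    # one genome gets an extra 3-gene contig seen nowhere else
    extra_layout = {"gn00": ["X", "Y", "A"]}
    extra_seqs = dict(SEQS)
    extra_recs, _ = make_genomes({"gn00": ["X", "Y"]}, extra_seqs)
    for r in extra_recs:
        r.contig_id = "c2"
        r.gene_id = r.gene_id.replace("|g", "|h")
    all_recs = recs + extra_recs
    cls2 = cluster_sequences(all_recs)
    g = collapse_paralogs(build_graph(cls2, all_recs))
    assert len(g.nodes()) == 6
    removed = remove_contamination(g, CleanConfig(mode="strict"))
    assert len(g.nodes()) == 4 and len(removed) == 2

    g2 = collapse_paralogs(build_graph(cls2, all_recs))
    removed2 = remove_contamination(g2, CleanConfig(mode="sensitive"))
    assert len(g2.nodes()) == 6 and removed2 == []


def test_rare_gene_attached_to_main_graph_survives():
    layouts = _core_layout(10)
    layouts["gn00"] = ["A", "Y", "B", "C", "D"]    # rare but embedded in core path
    recs, cls = make_genomes(layouts, SEQS)
    g = collapse_paralogs(build_graph(cls, recs))
    trim_contig_end_stubs(g, CleanConfig(mode="strict"))
    remove_contamination(g, CleanConfig(mode="strict"))
    names = {g.records[g.node_info[n].rep_gene].annotation for n in g.nodes()}
    assert "Y" in names


def test_frameshift_halves_merge_into_full_gene_node(small_sim):
    cfg, sim, truth = small_sim
    sim2, truth2 = sim.copy(), copy.deepcopy(truth)
    fam = "core_0010"
    split = 0
    for genome in sorted(sim2.genomes):
        if split >= 2:
            break
        recs, _ = sim2.genomes[genome]
        gid = next(r.gene_id for r in recs if truth2.family_of.get(r.gene_id) == fam)
        split_gene(sim2, truth2, gid, 0.5)
        split += 1
    g = build_pangenome(sim2.records(), sim2.contig_map(), CleanConfig(mode="moderate"),
                        genomes=list(truth2.matrix.index))
    nodes = [
        n for n in g.nodes()
        if any(
            truth2.family_of.get(b) == fam
            for genes in g.node_members[n].values()
            for gid in genes
            for b in gid.split("+")
        )
    ]
    assert len(nodes) == 1
    assert g.support(nodes[0]) == cfg.n_genomes


def test_distinct_neighbours_below_identity_never_merge():
    recs, cls = make_genomes(_core_layout(5), SEQS)
    g = collapse_paralogs(build_graph(cls, recs))
    n_before = len(g.nodes())
    merge_mistranslations(g, CleanConfig())
    assert len(g.nodes()) == n_before


def test_merge_thresholds_defaults():
    cfg = CleanConfig()
    assert cfg.merge_coverage == 0.95 and cfg.merge_identity == 0.99
    assert cfg.family_threshold == 0.70


def test_family_collapse_requires_shared_neighbour():
    # E and F are ~87% identical variants of the same family
    seqs = dict(SEQS)
    base = "ATG" + "AAACGT" * 40 + "TAA"
    var = base[:60] + base[60:].replace("AAACGT", "AAACGG", 16)
    seqs["E"], seqs["F"] = base, var
    # shared flanks A and B -> collapse
    layouts = {"gn0": ["A", "E", "B"], "gn1": ["A", "F", "B"]}
    recs, cls = make_genomes(layouts, seqs)
    g = collapse_paralogs(build_graph(cls, recs))
    assert len(g.nodes()) == 4
    collapse_families(g, CleanConfig())
    assert len(g.nodes()) == 3
    merged = [n for n in g.nodes() if g.node_info[n].diverse_family]
    assert len(merged) == 1 and g.support(merged[0]) == 2

    # no shared neighbour -> never merged even at high identity
    layouts2 = {"gn0": ["A", "E", "B"], "gn1": ["C", "F", "D"]}
    recs2, cls2 = make_genomes(layouts2, seqs)
    g2 = collapse_paralogs(build_graph(cls2, recs2))
    n_before = len(g2.nodes())
    collapse_families(g2, CleanConfig())
    assert len(g2.nodes()) == n_before


def test_dropped_annotations_are_refound(small_sim):
    cfg, sim, truth = small_sim
    cfg2 = SimConfig(**{**cfg.__dict__, "dropout_prob": 0.05})
    sim2, truth2 = inject_errors(sim, truth, cfg2)
    assert truth2.dropped_genes
    g = build_pangenome(sim2.records(), sim2.contig_map(), CleanConfig(mode="moderate"),
                        genomes=list(truth2.matrix.index))
    refound = [r for r in g.records.values() if r.refound]
    assert len(g.refind_log) == len(refound)
    # every refound hit meets the identity/coverage contract vs the window
    cm = sim2.contig_map()
    for r in refound:
        window = cm[(r.genome_id, r.contig_id)][r.start : r.end]
        assert window  # coordinates map back into the contig


def test_truly_deleted_gene_not_refound(small_sim):
    """A family absent from a genome (gene loss) must not be invented."""
    cfg, sim, truth = small_sim
    g = build_pangenome(sim.records(), sim.contig_map(), CleanConfig(mode="moderate"),
                        genomes=list(truth.matrix.index))
    m = presence_absence(g)
    # graph presence never exceeds truth presence for clean data
    from panclean import score_against_truth

    rep = score_against_truth(g, truth)
    assert rep.confusion["fp"] == 0


def test_polish_is_idempotent(small_sim):
    cfg, sim, truth = small_sim
    g = build_pangenome(sim.records(), sim.contig_map(), CleanConfig(),
                        genomes=list(truth.matrix.index))
    before = presence_absence(g)
    polish_graph(g, CleanConfig(), sim.contig_map())
    assert presence_absence(g).equals(before)


def test_ledger_balances(small_sim):
    """Genes are only removed with a logged reason or added as refound."""
    cfg, sim, truth = small_sim
    cfg2 = SimConfig(**{**cfg.__dict__, "dropout_prob": 0.03})
    sim2, truth2 = inject_errors(sim, truth, cfg2)
    g = build_pangenome(sim2.records(), sim2.contig_map(), CleanConfig(mode="strict"),
                        genomes=list(truth2.matrix.index))
    input_ids = {r.gene_id for r in sim2.records()}
    live_parts = {b for gid in g.gene_node for b in gid.split("+") if not g.records.get(gid, None) or not g.records[gid].refound}
    live_annotated = {
        b for gid, rec in g.records.items() if not rec.refound for b in gid.split("+")
    }
    removed = {e["gene_id"] for e in g.removal_log}
    removed_parts = {b for gid in removed for b in gid.split("+")}
    assert live_annotated | removed_parts == input_ids
    assert live_annotated & removed_parts == set()
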