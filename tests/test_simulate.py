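"""The pangenome simulator, error injection and truth-based scoring."""

import copy
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from panclean import (
    SimConfig,
    SimTruth,
    inject_errors,
    score_against_truth,
    simulate_pangenome,
    split_gene,
)


def _hash_dir(d):
    h = hashlib.sha256()
    for p in sorted(Path(d).glob("*")):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


def test_zero_rates_give_clonal_pangenome():
    cfg = SimConfig(n_genomes=4, n_core_genes=15, gain_rate=0.0, loss_rate=0.0, seed=1)
    sim, truth = simulate_pangenome(cfg)
    assert (truth.matrix.to_numpy() == 1).all()
    contents = {
        tuple(sorted(truth.family_of[r.gene_id] for r in recs))
        for recs, _ in sim.genomes.values()
    }
    assert len(contents) == 1


def test_fixed_seed_gives_byte_identical_output(tmp_path):
    cfg = SimConfig(n_genomes=4, n_core_genes=10, seed=8, gain_rate=5.0)
    simulate_pangenome(cfg, tmp_path / "a")
    simulate_pangenome(cfg, tmp_path / "b")
    assert _hash_dir(tmp_path / "a") == _hash_dir(tmp_path / "b")


def test_truth_row_sums_equal_emitted_gene_counts(small_sim):
    _, sim, truth = small_sim
    for genome, (recs, _) in sim.genomes.items():
        assert truth.matrix.loc[genome].sum() == len(recs)


def test_gene_coordinates_consistent_with_contig(small_sim):
    _, sim, _ = small_sim
    from panclean.annotation_io import reverse_complement

    for recs, contigs in sim.genomes.values():
        seq = contigs[0].sequence
        for r in recs:
            sub = seq[r.start : r.end]
            assert (reverse_complement(sub) if r.strand == "-" else sub) == r.dna_seq


def test_error_free_injection_is_identity(small_sim, tmp_path):
    cfg, sim, truth = small_sim
    noop = SimConfig(**{**cfg.__dict__, "fragmentation": 1, "contamination_mean": 0.0,
                        "dropout_prob": 0.0, "frameshift_prob": 0.0})
    sim2, truth2 = inject_errors(sim, truth, noop)
    sim.write(tmp_path / "a")
    sim2.write(tmp_path / "b")
    assert _hash_dir(tmp_path / "a") == _hash_dir(tmp_path / "b")


def test_contamination_defaults_and_segment_length():
    cfg = SimConfig()
    assert cfg.contamination_segment_length == 10_000
    small = SimConfig(n_genomes=6, n_core_genes=10, seed=2, contamination_mean=2.0)
    sim, truth = simulate_pangenome(small)
    sim2, truth2 = inject_errors(sim, truth, small)
    for recs, contigs in sim2.genomes.values():
        for c in contigs:
            if c.contig_id.startswith("contam"):
                assert len(c.sequence) == 10_000
    assert truth2.contaminant_genes
    # contaminant families never enter the truth matrix
    assert not (truth2.contaminant_families & set(truth2.matrix.columns))


def test_contamination_counts_are_poissonian():
    """Total segment count over many genomes stays within 3 sigma of the
    Poisson mean for several seeds."""
    n, mean = 60, 1.0
    for seed in (0, 1, 2):
        cfg = SimConfig(n_genomes=n, n_core_genes=3, gain_rate=0.0, loss_rate=0.0,
                        seed=seed, contamination_mean=mean,
                        contamination_segment_length=3000)
        sim, truth = simulate_pangenome(cfg)
        sim2, _ = inject_errors(sim, truth, cfg)
        total = sum(
            sum(1 for c in contigs if c.contig_id.startswith("contam"))
            for _, contigs in sim2.genomes.values()
        )
        assert abs(total - n * mean) <= 3 * np.sqrt(n * mean)


def test_unaffected_genes_are_untouched_by_injection(small_sim):
    cfg, sim, truth = small_sim
    noisy = SimConfig(**{**cfg.__dict__, "dropout_prob": 0.1, "frameshift_prob": 0.05})
    sim2, truth2 = inject_errors(sim, truth, noisy)
    touched = truth2.dropped_genes | {g for pair in truth2.frameshift_pairs for g in
                                      (pair[0].rsplit("_", 1)[0],)}
    for genome, (recs, _) in sim.genomes.items():
        after = {r.gene_id: r for r in sim2.genomes[genome][0]}
        for r in recs:
            if r.gene_id in truth2.dropped_genes or r.gene_id in truth2.severed_genes:
                continue
            if any(p.startswith(r.gene_id + "_") for pair in truth2.frameshift_pairs
                   for p in pair):
                continue
            assert after[r.gene_id].dna_seq == r.dna_seq
            assert after[r.gene_id].start == r.start


def test_split_gene_halves_reconstruct_original(small_sim):
    cfg, sim, truth = small_sim
    sim2, truth2 = sim.copy(), copy.deepcopy(truth)
    recs, _ = sim2.genomes["genome_000"]
    target = recs[5].gene_id
    dna = recs[5].dna_seq
    strand = recs[5].strand
    a, b = split_gene(sim2, truth2, target, 0.4)
    ra = next(r for r in sim2.genomes["genome_000"][0] if r.gene_id == a)
    rb = next(r for r in sim2.genomes["genome_000"][0] if r.gene_id == b)
    joined = ra.dna_seq + rb.dna_seq if strand == "+" else rb.dna_seq + ra.dna_seq
    assert joined == dna
    assert (a, b) in truth2.frameshift_pairs


def test_truth_round_trips_through_json(small_sim, tmp_path):
    _, _, truth = small_sim
    p = tmp_path / "truth.json"
    truth.to_json(p)
    back = SimTruth.from_json(p)
    assert back.family_of == truth.family_of
    assert back.matrix.equals(truth.matrix)
    assert back.tree_newick == truth.tree_newick


# ------------------------------------------------------------------- scoring


def _toy_truth():
    matrix = pd.DataFrame(
        [[1, 1], [1, 1]], index=["gn0", "gn1"], columns=["famA", "famB"]
    )
    family_of = {
        "gn0|a": "famA", "gn1|a": "famA", "gn0|b": "famB", "gn1|b": "famB",
    }
    return SimTruth(family_of=family_of, matrix=matrix, tree_newick="")


def test_perfect_clustering_scores_zero_errors():
    truth = _toy_truth()
    clusters = {
        0: {"gn0": ["gn0|a"], "gn1": ["gn1|a"]},
        1: {"gn0": ["gn0|b"], "gn1": ["gn1|b"]},
    }
    rep = score_against_truth(clusters, truth)
    assert rep.total_erroneous_clusters == 0
    assert rep.confusion == {"tp": 4, "fn": 0, "fp": 0, "tn": 0}


def test_duplicated_family_under_two_cluster_ids_is_one_oversplit():
    truth = _toy_truth()
    clusters = {
        0: {"gn0": ["gn0|a"]},
        1: {"gn1": ["gn1|a"]},          # famA split across two clusters
        2: {"gn0": ["gn0|b"], "gn1": ["gn1|b"]},
    }
    rep = score_against_truth(clusters, truth)
    assert rep.wrong_splits == 1
    assert rep.total_erroneous_clusters == 1


def test_mixed_family_cluster_is_one_wrong_merge():
    truth = _toy_truth()
    clusters = {
        0: {"gn0": ["gn0|a", "gn0|b"], "gn1": ["gn1|a", "gn1|b"]},
    }
    rep = score_against_truth(clusters, truth)
    assert rep.wrong_merges == 1


def test_report_totals_consistent_with_cellwise_confusion(small_sim, small_graph):
    _, _, truth = small_sim
    rep = score_against_truth(small_graph, truth)
    c = rep.confusion
    assert c["tp"] + c["fn"] + c["fp"] + c["tn"] == truth.matrix.size
    assert (rep.missing_gene_clusters > 0) == (c["fn"] > 0)


def test_empty_genome_config_is_rejected():
    with pytest.raises(ValueError):
        simulate_pangenome(SimConfig(n_genomes=3, n_core_genes=0, gain_rate=0.0,
                                     loss_rate=0.0, seed=0))
    with pytest.raises(ValueError):
        SimConfig(dropout_prob=1.5)
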