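"""Gain/loss model likelihoods, spectrum fits and coincident-gene screening."""

import itertools
import random

import dendropy
import numpy as np
import pandas as pd
import pytest
from dendropy.simulate import treesim
from scipy.linalg import expm

from panclean.evolution_models import (
    _img_spectrum_parts,
    coincident_genes,
    expected_img_spectrum,
    fit_fmg,
    fit_img,
    fmg_loglikelihood,
    gene_frequency_spectrum,
    load_dated_tree,
    mutual_information,
    simulate_fmg_matrix,
    simulate_img_matrix,
)


def coalescent_tree(n, seed):
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n)])
    return treesim.pure_kingman_tree(
        taxon_namespace=taxa, pop_size=1.0, rng=random.Random(seed)
    )


def enumeration_loglik(tree, matrix, a, v):
    """Brute-force likelihood: sum over all internal-state assignments with
    matrix-exponential transition probabilities (independent oracle)."""
    Q = np.array([[-a, a], [v, -v]])
    prior = np.array([0.5, 0.5]) if a + v == 0 else np.array([v / (a + v), a / (a + v)])
    nodes = list(tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    order = [lf.taxon.label for lf in tree.leaf_node_iter()]
    X = matrix.loc[order].to_numpy()

    def col_prob(col):
        leaf_state = {id(lf): int(s) for lf, s in zip(tree.leaf_node_iter(), col)}
        total = 0.0
        for assign in itertools.product([0, 1], repeat=len(internal)):
            st = dict(leaf_state)
            for n, s in zip(internal, assign):
                st[id(n)] = s
            p = prior[st[id(tree.seed_node)]]
            for n in nodes:
                if n is tree.seed_node:
                    continue
                P = expm(Q * (n.edge.length or 0.0))
                p *= P[st[id(n.parent_node)], st[id(n)]]
            total += p
        return total

    p_absent = col_prob(np.zeros(len(order)))
    return sum(
        np.log(col_prob(X[:, j])) - np.log(1 - p_absent) for j in range(X.shape[1])
    )


@pytest.mark.parametrize("nleaves", [2, 3, 4])
def test_pruning_equals_state_enumeration(nleaves, rng):
    """Felsenstein pruning matches exhaustive enumeration on small trees."""
    for seed in range(3):
        tree = coalescent_tree(nleaves, seed)
        a, v = rng.uniform(0.2, 1.5, 2)
        m = simulate_fmg_matrix(tree, a, v, 15, rng)
        assert fmg_loglikelihood(tree, m, a, v) == pytest.approx(
            enumeration_loglik(tree, m, a, v), abs=1e-10
        )


def test_all_present_columns_have_unit_likelihood_at_zero_rates():
    """With a = v = 0 and a present root, presence is certain everywhere."""
    tree = coalescent_tree(4, 1)
    order = [lf.taxon.label for lf in tree.leaf_node_iter()]
    m = pd.DataFrame(np.ones((4, 5), dtype=int), index=order)
    ll = fmg_loglikelihood(tree, m, 1e-9, 1e-9, condition_on_presence=False)
    assert ll == pytest.approx(np.log(0.5) * 5, rel=1e-3)   # root prior only


def test_likelihood_invariant_to_column_order_and_leaf_relabelling(rng):
    tree = coalescent_tree(6, 2)
    m = simulate_fmg_matrix(tree, 0.7, 0.5, 40, rng)
    shuffled = m.sample(frac=1, axis=1, random_state=0)
    assert fmg_loglikelihood(tree, m, 0.7, 0.5) == pytest.approx(
        fmg_loglikelihood(tree, shuffled, 0.7, 0.5)
    )
    perm = m.sample(frac=1, axis=0, random_state=1)   # rows shuffled, labels kept
    assert fmg_loglikelihood(tree, m, 0.7, 0.5) == pytest.approx(
        fmg_loglikelihood(tree, perm, 0.7, 0.5)
    )


def test_fmg_rejects_degenerate_matrices():
    tree = coalescent_tree(3, 3)
    order = [lf.taxon.label for lf in tree.leaf_node_iter()]
    with pytest.raises(ValueError, match="core-only"):
        fit_fmg(pd.DataFrame(np.ones((3, 4), dtype=int), index=order), tree)
    bad = pd.DataFrame(np.zeros((3, 2), dtype=int), index=order)
    with pytest.raises(ValueError, match="all-absent"):
        fit_fmg(bad, tree)


def test_fmg_recovery_on_moderate_tree(rng):
    tree = coalescent_tree(25, 9)
    a0, v0 = 0.6, 0.4
    m = simulate_fmg_matrix(tree, a0, v0, 400, rng)
    p = fit_fmg(m, tree)
    assert p.converged
    assert abs(p.gain_rate - a0) / a0 < 0.35
    assert abs(p.loss_rate - v0) / v0 < 0.35


def test_img_spectrum_matches_naive_column_count(rng):
    tree = coalescent_tree(12, 4)
    m = simulate_img_matrix(tree, 25.0, 0.5, rng)
    p = fit_img(m, tree)
    naive = np.bincount(m.to_numpy().sum(axis=0), minlength=13)[1:]
    assert np.array_equal(p.spectrum, naive)
    assert np.array_equal(gene_frequency_spectrum(m), naive)


def test_img_expected_spectrum_matches_simulation_mean(rng):
    """Monte-Carlo check of the closed-form spectrum recursion."""
    tree = coalescent_tree(6, 5)
    theta, rho = 30.0, 0.8
    tot = np.zeros(6)
    n_rep = 150
    for _ in range(n_rep):
        m = simulate_img_matrix(tree, theta, rho, rng)
        if m.shape[1]:
            tot += np.bincount(m.to_numpy().sum(axis=0), minlength=7)[1:]
    mean = tot / n_rep
    expected = theta * expected_img_spectrum(tree, rho)
    # 3 sigma on each Poisson class
    for k in range(6):
        sd = np.sqrt(expected[k] / n_rep) + 1e-9
        assert abs(mean[k] - expected[k]) < 4 * sd + 0.5


def test_lossless_data_fits_near_zero_loss_rate():
    tree = coalescent_tree(15, 7)
    m = simulate_img_matrix(tree, 100.0, 0.0, np.random.default_rng(3))
    p = fit_img(m, tree)
    assert p.loss_rate < 1e-3


def test_ultrametric_warning(tmp_path):
    nwk = "((a:1,b:1):1,c:1.5);"
    with pytest.warns(UserWarning, match="ultrametric"):
        load_dated_tree(nwk)
    with pytest.raises(ValueError, match="leaves"):
        load_dated_tree("((a:1,b:1):1,c:2);", leaf_names={"a", "b", "x"})


# ------------------------------------------------------------ coincident genes


def _matrix(cols):
    return pd.DataFrame({f"c{i}": c for i, c in enumerate(cols)},
                        index=[f"g{j}" for j in range(len(cols[0]))])


def test_identical_columns_are_top_correlated_pair(rng):
    base = rng.integers(0, 2, 40)
    noise = [rng.integers(0, 2, 40) for _ in range(6)]
    m = _matrix([base, base.copy()] + noise)
    out = coincident_genes(m)
    assert out, "identical columns should clear the outlier fence"
    a, b, mi, flag = out[0]
    assert {a, b} == {"c0", "c1"} and flag == "correlated"


def test_complementary_columns_have_equal_mi_and_anti_flag(rng):
    base = rng.integers(0, 2, 40)
    comp = 1 - base
    noise = [rng.integers(0, 2, 40) for _ in range(6)]
    m1 = _matrix([base, base.copy()] + noise)
    m2 = _matrix([base, comp] + noise)
    o1 = coincident_genes(m1)
    o2 = coincident_genes(m2)
    assert o2[0][3] == "anti-correlated"
    assert o1[0][2] == pytest.approx(o2[0][2], abs=1e-12)   # MI is sign-blind


def test_mi_matches_contingency_table_oracle(rng):
    """Weighted MI equals the direct plug-in value from the 2x2 table."""
    for _ in range(20):
        x = rng.integers(0, 2, 30)
        y = rng.integers(0, 2, 30)
        w = rng.uniform(0.2, 1.0, 30)
        n = np.zeros((2, 2))
        for xi, yi, wi in zip(x, y, w):
            n[xi, yi] += wi
        n += 0.5
        tot = n.sum()
        p = n / tot
        px, py = p.sum(axis=1), p.sum(axis=0)
        direct = sum(
            p[i, j] * np.log(p[i, j] / (px[i] * py[j]))
            for i in range(2)
            for j in range(2)
        )
        assert mutual_information(x, y, w) == pytest.approx(direct, abs=1e-12)


def test_constant_columns_are_excluded(rng):
    m = _matrix([np.ones(20, dtype=int), rng.integers(0, 2, 20),
                 rng.integers(0, 2, 20)])
    out = coincident_genes(m)
    assert all("c0" not in (a, b) for a, b, _, _ in out)
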