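"""Gene gain/loss models on a dated phylogeny and coincident-gene detection.

Two standard models of pangenome dynamics are implemented as post-processing
on the gene presence/absence matrix:

* **FMG (finitely many genes).**  Each of ``M`` gene slots evolves along the
  dated tree as an independent two-state continuous-time Markov chain with
  gain rate ``a`` (absent -> present, per slot per unit time) and loss rate
  ``v`` (present -> absent, per gene per unit time).  The per-column
  likelihood is computed with the Felsenstein pruning recursion from the
  2x2 transition matrices, with the stationary distribution
  ``(v/(a+v), a/(a+v))`` as root prior, and is conditioned on at least one
  observed presence (all-absent slots are unobservable).

* **IMG (infinitely many genes).**  New genes arise at rate ``theta`` per
  unit branch length, each unique, and are lost independently at per-gene
  rate ``rho``; genes present at the root follow the stationary Poisson
  pool of size ``theta/rho``.  The expected *gene frequency spectrum* (the
  number of genes present in exactly k of n genomes) has a closed-form
  recursion on any fixed tree, and observed spectrum counts are independent
  Poisson draws around it, giving an exact likelihood.  The gain rate enters
  linearly and is profiled out; the loss rate is fitted by 1-D bounded
  optimisation.  Classes present in every genome are excluded from the fit
  (the persistent core is not part of the gain/loss process).

Also provided: a mutual-information screen for coincident (co-occurring or
avoiding) gene pairs with sequence reweighting against population structure
and ARACNE-style triangle pruning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger("panclean")

__all__ = [
    "load_dated_tree",
    "FMGParams",
    "IMGParams",
    "fit_fmg",
    "fit_img",
    "fmg_loglikelihood",
    "expected_img_spectrum",
    "gene_frequency_spectrum",
    "simulate_fmg_matrix",
    "simulate_img_matrix",
    "coincident_genes",
    "mutual_information",
]


# ------------------------------------------------------------------ tree I/O


def load_dated_tree(source: str, leaf_names: set[str] | None = None,
                    tol: float = 1e-6) -> dendropy.Tree:
    """Load a rooted dated tree from a Newick string or file path.

    Warns if the tree is not ultrametric within *tol* (relative to the root
    height); errors if *leaf_names* is given and does not match the leaf set.
    """
    import os

    if os.path.exists(source):
        tree = dendropy.Tree.get(path=source, schema="newick")
    else:
        tree = dendropy.Tree.get(data=source, schema="newick")
    depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
    height = max(depths)
    if height > 0 and (max(depths) - min(depths)) > tol * height:
        warnings.warn("tree is not ultrametric; rate estimates assume a dated tree")
    if leaf_names is not None:
        labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
        if labels != set(leaf_names):
            raise ValueError(
                f"tree leaves do not match matrix rows: "
                f"{sorted(labels ^ set(leaf_names))[:5]} ..."
            )
    return tree


def tree_height(tree: dendropy.Tree) -> float:
    return max(tree.calc_node_root_distances(return_leaf_distances_only=True))


def _leaf_order(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


# ------------------------------------------------------------------------ FMG


@dataclass
class FMGParams:
    gain_rate: float          # a: gains per empty slot per unit time
    loss_rate: float          # v: losses per gene per unit time
    pool_size: int            # M: total gene slots
    log_likelihood: float
    converged: bool = True


def _pmatrix(a: float, v: float, t: float) -> np.ndarray:
    """2x2 transition matrix for the absent(0)/present(1) chain."""
    s = a + v
    if s == 0 or t == 0:
        return np.eye(2)
    e = np.exp(-s * t)
    return np.array(
        [
            [(v + a * e) / s, (a - a * e) / s],
            [(v - v * e) / s, (a + v * e) / s],
        ]
    )


def _column_likelihoods(
    tree: dendropy.Tree, patterns: np.ndarray, a: float, v: float
) -> tuple[np.ndarray, float]:
    """Pruning likelihood of each column pattern and of the all-absent
    pattern.  *patterns* is (ncols, nleaves) with leaves in
    ``_leaf_order(tree)`` order."""
    ncols, nleaves = patterns.shape
    leaf_idx = {label: i for i, label in enumerate(_leaf_order(tree))}
    partial: dict[int, np.ndarray] = {}
    absent: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            x = patterns[:, leaf_idx[node.taxon.label]]
            L = np.zeros((ncols, 2))
            L[x == 0, 0] = 1.0
            L[x == 1, 1] = 1.0
            partial[id(node)] = L
            absent[id(node)] = np.array([1.0, 0.0])
        else:
            L = np.ones((ncols, 2))
            L0 = np.ones(2)
            for child in node.child_nodes():
                t = child.edge.length or 0.0
                P = _pmatrix(a, v, t)
                L *= partial.pop(id(child)) @ P.T
                L0 *= P @ absent.pop(id(child))
            partial[id(node)] = L
            absent[id(node)] = L0
    root = tree.seed_node
    s = a + v
    prior = np.array([0.5, 0.5]) if s == 0 else np.array([v / s, a / s])
    col = partial[id(root)] @ prior
    p_absent = float(absent[id(root)] @ prior)
    return col, p_absent


def fmg_loglikelihood(
    tree: dendropy.Tree,
    matrix: pd.DataFrame,
    a: float,
    v: float,
    condition_on_presence: bool = True,
) -> float:
    """Total log-likelihood of a genomes x genes binary matrix under the
    two-state gain/loss chain, conditioned (by default) on each column
    being observed in at least one genome."""
    X = _matrix_for_tree(matrix, tree)           # (nleaves, ncols)
    pats, counts = np.unique(X.T, axis=0, return_counts=True)
    col, p_absent = _column_likelihoods(tree, pats, a, v)
    ll = float(np.sum(counts * np.log(np.maximum(col, 1e-300))))
    if condition_on_presence:
        ll -= counts.sum() * np.log(max(1.0 - p_absent, 1e-300))
    return ll


def _matrix_for_tree(matrix: pd.DataFrame, tree: dendropy.Tree) -> np.ndarray:
    order = _leaf_order(tree)
    missing = set(order) ^ set(matrix.index)
    if missing:
        raise ValueError(f"matrix rows and tree leaves differ: {sorted(missing)[:5]}")
    return matrix.loc[order].to_numpy(dtype=int)


def fit_fmg(
    matrix: pd.DataFrame,
    tree: dendropy.Tree,
    pool_factor: float = 1.5,
    profile_pool_size: bool = False,
) -> FMGParams:
    """Maximum-likelihood gain and loss rates under the FMG model.

    The likelihood is conditioned on columns being observed, so the rates
    are identifiable without knowing the true slot count; ``pool_size`` is
    reported as ``pool_factor`` x the observed pangenome size, or profiled
    over a grid (joint likelihood including unobserved all-absent slots)
    when *profile_pool_size* is set.  Optimisation is bounded quasi-Newton
    from five fixed starting points, so the fit is deterministic.
    """
    X = matrix.loc[_leaf_order(tree)].to_numpy(dtype=int)
    if X.min() < 0 or X.max() > 1:
        raise ValueError("matrix must be binary")
    colsum = X.sum(axis=0)
    if (colsum == 0).any():
        raise ValueError("matrix contains all-absent columns; drop them first")
    n, G = X.shape
    if (colsum == n).all():
        raise ValueError("core-only matrix: gain/loss rates are not identifiable")

    pats, counts = np.unique(X.T, axis=0, return_counts=True)

    h = tree_height(tree)
    scale = 1.0 / h

    def nll(logp: np.ndarray) -> float:
        a, v = np.exp(logp)
        col, p_absent = _column_likelihoods(tree, pats, a, v)
        ll = np.sum(counts * np.log(np.maximum(col, 1e-300)))
        ll -= counts.sum() * np.log(max(1.0 - p_absent, 1e-300))
        return -float(ll)

    starts = [
        (0.5 * scale, 0.5 * scale),
        (2.0 * scale, 2.0 * scale),
        (0.5 * scale, 2.0 * scale),
        (2.0 * scale, 0.5 * scale),
        (1.0 * scale, 1.0 * scale),
    ]
    lo, hi = np.log(1e-8 * scale), np.log(1e4 * scale)
    best = None
    for s in starts:
        res = optimize.minimize(
            nll,
            x0=np.log(s),
            method="L-BFGS-B",
            bounds=[(lo, hi), (lo, hi)],
        )
        if best is None or res.fun < best.fun:
            best = res
    a, v = np.exp(best.x)
    at_bound = bool(np.any(np.isclose(best.x, lo, atol=1e-6) | np.isclose(best.x, hi, atol=1e-6)))
    params = FMGParams(
        gain_rate=float(a),
        loss_rate=float(v),
        pool_size=int(np.ceil(pool_factor * G)),
        log_likelihood=-float(best.fun),
        converged=bool(best.success) and not at_bound,
    )
    if profile_pool_size:
        params = _profile_pool(matrix, tree, params, pats, counts)
    return params


def _profile_pool(matrix, tree, params, pats, counts) -> FMGParams:
    from scipy.special import gammaln

    G = counts.sum()
    best = params
    best_ll = -np.inf
    for mult in (1.0, 1.25, 1.5, 2.0, 3.0, 5.0):
        M = int(np.ceil(mult * G))
        col, p_absent = _column_likelihoods(tree, pats, params.gain_rate, params.loss_rate)
        ll = float(np.sum(counts * np.log(np.maximum(col, 1e-300))))
        ll += (M - G) * np.log(max(p_absent, 1e-300))
        ll += gammaln(M + 1) - gammaln(G + 1) - gammaln(M - G + 1)
        if ll > best_ll:
            best_ll = ll
            best = FMGParams(params.gain_rate, params.loss_rate, M, ll, params.converged)
    return best


def simulate_fmg_matrix(
    tree: dendropy.Tree,
    gain_rate: float,
    loss_rate: float,
    n_columns: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate observed presence/absence columns under the FMG chain
    (stationary root state, conditioned on >= 1 presence)."""
    order = _leaf_order(tree)
    s = gain_rate + loss_rate
    prior1 = 0.5 if s == 0 else gain_rate / s
    cols: list[np.ndarray] = []
    collected = 0
    while collected < n_columns:
        batch = max(n_columns, 64)
        states: dict[int, np.ndarray] = {
            id(tree.seed_node): (rng.random(batch) < prior1).astype(int)
        }
        leaf_states = {}
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            P = _pmatrix(gain_rate, loss_rate, node.edge.length or 0.0)
            parent = states[id(node.parent_node)]
            u = rng.random(batch)
            st = np.where(parent == 0, (u < P[0, 1]).astype(int), (u < P[1, 1]).astype(int))
            states[id(node)] = st
            if node.is_leaf():
                leaf_states[node.taxon.label] = st
        X = np.vstack([leaf_states[label] for label in order])
        keep = X.sum(axis=0) > 0
        cols.append(X[:, keep])
        collected += int(keep.sum())
    X = np.hstack(cols)[:, :n_columns]
    return pd.DataFrame(X, index=order,
                        columns=[f"slot_{i}" for i in range(n_columns)])


# ------------------------------------------------------------------------ IMG


@dataclass
class IMGParams:
    gain_rate: float                  # theta: new genes per unit branch length
    loss_rate: float                  # rho: per-gene loss rate
    effective_pangenome_size: float   # core + theta/rho equilibrium accessory pool
    log_likelihood: float
    spectrum: np.ndarray = field(default_factory=lambda: np.array([]))
    expected_spectrum: np.ndarray = field(default_factory=lambda: np.array([]))


def gene_frequency_spectrum(matrix: pd.DataFrame) -> np.ndarray:
    """Observed spectrum: entry k-1 is the number of genes present in
    exactly k of the n genomes (k = 1..n)."""
    X = matrix.to_numpy(dtype=int)
    n = X.shape[0]
    sums = X.sum(axis=0)
    return np.bincount(sums, minlength=n + 1)[1:]


def _img_spectrum_parts(
    tree: dendropy.Tree, loss_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Branch-gain and root-gene spectrum components on a fixed tree.

    Returns ``(b, r)`` where ``b[k-1]`` is the expected number of genes in
    exactly k leaves per unit gain rate (gains along branches, each gained
    gene surviving with the exponential loss kernel) and ``r[k-1]`` is the
    probability that a single gene present at the root survives in exactly
    k leaves.  Computed by a subtree recursion on f_v(k), the probability a
    gene present at node v is retained by exactly k of its descendant
    leaves; a branch of length L contributes gains with effective weight
    (1 - exp(-rho L)) / rho.
    """
    rho = loss_rate
    nleaves = sum(1 for _ in tree.leaf_node_iter())
    f: dict[int, np.ndarray] = {}
    b = np.zeros(nleaves + 1)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            fv = np.zeros(nleaves + 1)
            fv[1] = 1.0
        else:
            fv = None
            for child in node.child_nodes():
                L = child.edge.length or 0.0
                p = np.exp(-rho * L)
                d = p * f.pop(id(child))
                d[0] += 1.0 - p
                fv = d if fv is None else np.convolve(fv, d)[: nleaves + 1]
        f[id(node)] = fv
        if node is not tree.seed_node:
            L = node.edge.length or 0.0
            w = L if rho == 0 else -np.expm1(-rho * L) / rho
            b += w * fv
    return b[1:], f[id(tree.seed_node)][1:]


def expected_img_spectrum(tree: dendropy.Tree, loss_rate: float) -> np.ndarray:
    """Expected gene frequency spectrum per unit gain rate on a fixed tree,
    with the root pool at its stationary size theta/rho.

    Entry k-1 is E[number of genes in exactly k leaves] / theta for
    k = 1..n.
    """
    b, r = _img_spectrum_parts(tree, loss_rate)
    if loss_rate > 0:
        return b + r / loss_rate
    return b


def fit_img(matrix: pd.DataFrame, tree: dendropy.Tree) -> IMGParams:
    """Fit gain (theta) and loss (rho) rates to the gene frequency spectrum.

    Spectrum classes k = 1..n-1 are used (genes present in every genome are
    treated as persistent core, outside the gain/loss process).  Counts are
    modelled as independent Poisson around the expected spectrum.  The
    intensity is linear in two non-negative sizes — the gain rate theta
    (gains along branches) and the ancestral root pool G0 — which are
    profiled by a multiplicative fixed-point update at each loss rate; the
    loss rate is optimised on a deterministic log grid followed by bounded
    refinement.
    """
    X = matrix.loc[_leaf_order(tree)]
    obs = gene_frequency_spectrum(X)
    n = X.shape[0]
    acc = obs[:-1].astype(float)            # k = 1..n-1
    core = int(obs[-1])
    if acc.sum() == 0:
        raise ValueError("no accessory genes: IMG rates are not identifiable")
    h = tree_height(tree)

    def profile_nll(log_rho: float) -> tuple[float, float, float]:
        rho = float(np.exp(log_rho))
        b, r = _img_spectrum_parts(tree, rho)
        b, r = np.maximum(b[:-1], 1e-300), np.maximum(r[:-1], 1e-300)
        theta = acc.sum() / b.sum()
        g0 = 1.0
        for _ in range(200):       # EM-style updates for Poisson intensities
            lam = theta * b + g0 * r
            theta_new = theta * np.sum(acc * b / lam) / b.sum()
            g0_new = g0 * np.sum(acc * r / lam) / r.sum()
            if abs(theta_new - theta) < 1e-10 * (theta + 1e-12) and \
               abs(g0_new - g0) < 1e-10 * (g0 + 1e-12):
                theta, g0 = theta_new, g0_new
                break
            theta, g0 = theta_new, g0_new
        lam = theta * b + g0 * r
        ll = float(np.sum(acc * np.log(lam)) - lam.sum())
        return -ll, theta, g0

    grid = np.log(np.logspace(-4, 3, 60) / h)
    nlls = np.array([profile_nll(lr)[0] for lr in grid])
    i = int(np.argmin(nlls))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda lr: profile_nll(lr)[0], bounds=(lo, hi), method="bounded"
    )
    nll, theta, g0 = profile_nll(res.x)
    rho = float(np.exp(res.x))
    b, r = _img_spectrum_parts(tree, rho)
    return IMGParams(
        gain_rate=float(theta),
        loss_rate=rho,
        effective_pangenome_size=float(core + theta / max(rho, 1e-12)),
        log_likelihood=-nll,
        spectrum=obs,
        expected_spectrum=theta * b + g0 * r,
    )


def simulate_img_matrix(
    tree: dendropy.Tree,
    gain_rate: float,
    loss_rate: float,
    rng: np.random.Generator,
    root_pool: int | None = None,
) -> pd.DataFrame:
    """Simulate accessory gene presence/absence under the IMG process on a
    fixed tree (each gained gene is unique; losses are irreversible)."""
    order = _leaf_order(tree)
    counter = [0]
    leaf_content: dict[str, set[int]] = {}

    if root_pool is None:
        root_pool = 0 if loss_rate == 0 else int(rng.poisson(gain_rate / loss_rate))
    root_genes = set(range(root_pool))
    counter[0] = root_pool
    content: dict[int, set[int]] = {id(tree.seed_node): root_genes}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length or 0.0
        parent = content[id(node.parent_node)]
        surv = {gid for gid in parent if rng.random() < np.exp(-loss_rate * t)}
        ngain = rng.poisson(gain_rate * t)
        for _ in range(ngain):
            u = rng.uniform(0, t)
            if rng.random() < np.exp(-loss_rate * (t - u)):
                surv.add(counter[0])
            counter[0] += 1
        content[id(node)] = surv
        if node.is_leaf():
            leaf_content[node.taxon.label] = surv
    all_genes = sorted(set().union(*leaf_content.values())) if leaf_content else []
    X = np.zeros((len(order), len(all_genes)), dtype=int)
    gidx = {gid: j for j, gid in enumerate(all_genes)}
    for i, label in enumerate(order):
        for gid in leaf_content[label]:
            X[i, gidx[gid]] = 1
    return pd.DataFrame(X, index=order, columns=[f"acc_{g}" for g in all_genes])


# ----------------------------------------------------------- coincident genes


def mutual_information(
    x: np.ndarray, y: np.ndarray, weights: np.ndarray, pseudocount: float = 0.5
) -> float:
    """Weighted mutual information (nats) between two binary columns with
    pseudo-count-smoothed 2x2 cell probabilities."""
    w = weights
    n11 = float(np.sum(w * x * y)) + pseudocount
    n10 = float(np.sum(w * x * (1 - y))) + pseudocount
    n01 = float(np.sum(w * (1 - x) * y)) + pseudocount
    n00 = float(np.sum(w * (1 - x) * (1 - y))) + pseudocount
    tot = n11 + n10 + n01 + n00
    mi = 0.0
    for nab, na, nb in (
        (n11, n11 + n10, n11 + n01),
        (n10, n11 + n10, n10 + n00),
        (n01, n01 + n00, n11 + n01),
        (n00, n01 + n00, n10 + n00),
    ):
        mi += (nab / tot) * np.log(nab * tot / (na * nb))
    return mi


def _structure_weights(X: np.ndarray, hamming_radius: float) -> np.ndarray:
    """Inverse-neighbourhood-size genome weights (Hamming fraction on the
    matrix rows), damping clonal oversampling."""
    n = X.shape[0]
    diff = (X[:, None, :] != X[None, :, :]).mean(axis=2)
    sizes = (diff < hamming_radius).sum(axis=1)
    return 1.0 / sizes


def coincident_genes(
    matrix: pd.DataFrame,
    max_pairs: int | None = None,
    hamming_radius: float = 0.1,
    pseudocount: float = 0.5,
) -> list[tuple[str, str, float, str]]:
    """Screen for gene pairs with outlying presence/absence association.

    Pairwise weighted mutual information is computed for every non-constant
    column pair, the outlier threshold is the upper Tukey fence
    (Q3 + 1.5 IQR) of the MI distribution, triangles among outlying pairs
    are pruned ARACNE-style (the weakest edge of each triangle is dropped),
    and each surviving pair is flagged ``correlated`` or ``anti-correlated``
    from the direction of the 2x2 odds ratio.
    """
    X = matrix.to_numpy(dtype=int)
    names = list(matrix.columns)
    keep = [j for j in range(X.shape[1]) if 0 < X[:, j].sum() < X.shape[0]]
    dropped = X.shape[1] - len(keep)
    if dropped:
        logger.info("coincident_genes: excluded %d constant columns", dropped)
    X = X[:, keep]
    names = [names[j] for j in keep]
    ncols = X.shape[1]
    if ncols < 2:
        return []
    w = _structure_weights(X, hamming_radius)

    mis = {}
    odds_sign = {}
    for i in range(ncols):
        for j in range(i + 1, ncols):
            mi = mutual_information(X[:, i], X[:, j], w, pseudocount)
            mis[(i, j)] = mi
            n11 = np.sum(w * X[:, i] * X[:, j]) + pseudocount
            n10 = np.sum(w * X[:, i] * (1 - X[:, j])) + pseudocount
            n01 = np.sum(w * (1 - X[:, i]) * X[:, j]) + pseudocount
            n00 = np.sum(w * (1 - X[:, i]) * (1 - X[:, j])) + pseudocount
            odds_sign[(i, j)] = "correlated" if n11 * n00 >= n10 * n01 else "anti-correlated"

    vals = np.array(list(mis.values()))
    q1, q3 = np.percentile(vals, [25, 75])
    fence = q3 + 1.5 * (q3 - q1)
    strong = {pair for pair, mi in mis.items() if mi > fence}

    # ARACNE: within every triangle of outlying edges, drop the weakest
    adj: dict[int, set[int]] = {}
    for i, j in strong:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    pruned: set[tuple[int, int]] = set()
    for i, j in sorted(strong):
        for k in sorted(adj.get(i, set()) & adj.get(j, set())):
            tri = [tuple(sorted(p)) for p in ((i, j), (i, k), (j, k))]
            weakest = min(tri, key=lambda p: (mis[p], p))
            pruned.add(weakest)

    out = [
        (names[i], names[j], mis[(i, j)], odds_sign[(i, j)])
        for (i, j) in sorted(strong - pruned)
    ]
    out.sort(key=lambda t: -t[2])
    if max_pairs is not None:
        out = out[:max_pairs]
    return out
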