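"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive quantities by different routes than
the package (explicit path walking for distances, full-matrix multivariate
normal densities for likelihoods, message-passing ancestral reconstruction
for imputation) so that agreement is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import phylofee as pf
from phylofee.tree import Phylogeny, read_newick_string


# ---------------------------------------------------------------- small trees

@pytest.fixture
def three_tip() -> Phylogeny:
    return read_newick_string("(A:1,(B:0.5,C:0.5):0.5):0;")


@pytest.fixture
def star4() -> Phylogeny:
    return read_newick_string("(A:1,B:1,C:1,D:1):0;")


# ------------------------------------------------------------------- oracles

def path_walk_distance(phylo: Phylogeny, a: str, b: str) -> float:
    """Tip-to-tip distance by explicitly climbing to the common ancestor."""
    leaves = {l.taxon.label: l for l in phylo.tree.leaf_node_iter()}
    anc = {}
    node, cum = leaves[a], 0.0
    while node is not None:
        anc[id(node)] = cum
        cum += node.edge.length or 0.0
        node = node.parent_node
    node, cum = leaves[b], 0.0
    while id(node) not in anc:
        cum += node.edge.length or 0.0
        node = node.parent_node
    return cum + anc[id(node)]


def mvn_profile_loglik(x: np.ndarray, C: np.ndarray, lam: float) -> float:
    """Brute-force profile log-likelihood: lambda-transform by hand, GLS
    estimates via explicit matrix inversion, density via scipy's MVN."""
    Cl = lam * C.copy()
    np.fill_diagonal(Cl, np.diag(C))
    Ci = np.linalg.inv(Cl)
    ones = np.ones(len(x))
    mu = (ones @ Ci @ x) / (ones @ Ci @ ones)
    r = x - mu
    s2 = (r @ Ci @ r) / len(x)
    return float(stats.multivariate_normal(mean=mu * ones, cov=s2 * Cl).logpdf(x))


def pruning_impute(phylo: Phylogeny, x: pd.Series, missing: str) -> float:
    """Reroot-and-reconstruct oracle: Felsenstein-pruning ML ancestral state
    at the missing tip's attachment node, via message passing on the tree
    viewed as an undirected graph."""
    leaves = {l.taxon.label: l for l in phylo.tree.leaf_node_iter()}
    m = leaves[missing]
    attach = m.parent_node
    values = x.dropna()

    # undirected adjacency: node -> [(neighbour, branch length)]
    adj: dict[int, list[tuple[object, float]]] = {}
    nodes = {}
    for node in phylo.tree.preorder_node_iter():
        nodes[id(node)] = node
        for ch in node.child_nodes():
            adj.setdefault(id(node), []).append((ch, ch.edge.length))
            adj.setdefault(id(ch), []).append((node, ch.edge.length))

    def message(node, come_from) -> tuple[float, float]:
        """(mean, variance) of the subtree behind `node`, seen from `come_from`."""
        if node.is_leaf():
            lbl = node.taxon.label
            if lbl == missing or lbl not in values.index:
                return (np.nan, np.inf)
            return (float(values[lbl]), 0.0)
        msgs = []
        for nb, blen in adj[id(node)]:
            if nb is come_from:
                continue
            mean, var = message(nb, node)
            if np.isfinite(var):
                msgs.append((mean, var + blen))
        if not msgs:
            return (np.nan, np.inf)
        w = np.array([1.0 / v if v > 0 else 1e18 for _, v in msgs])
        means = np.array([mm for mm, _ in msgs])
        return (float((w * means).sum() / w.sum()), float(1.0 / w.sum()))

    msgs = []
    for nb, blen in adj[id(attach)]:
        if nb is m:
            continue
        mean, var = message(nb, attach)
        if np.isfinite(var):
            msgs.append((mean, var + blen))
    w = np.array([1.0 / v if v > 0 else 1e18 for _, v in msgs])
    means = np.array([mm for mm, _ in msgs])
    return float((w * means).sum() / w.sum())


def lattice_objective(values: dict, fees: dict) -> float:
    """Sum over single-addition edges of the squared, 1/sigma_i^2-weighted
    FEE residual; assembled independently of the package's solver."""
    total = 0.0
    keys = list(values)
    for S in keys:
        for strain, fee in fees.items():
            if strain in S:
                continue
            Sp = tuple(sorted(S + (strain,)))
            if Sp not in values:
                continue
            resid = values[Sp] - (1.0 + fee.b) * values[S] - fee.a
            total += resid**2 / fee.sigma2
    return total


# ------------------------------------------------- expensive shared fixtures

@pytest.fixture(scope="session")
def tree100():
    return pf.simulate_yule_tree(100, seed=7)


@pytest.fixture(scope="session")
def engine100(tree100):
    from phylofee.signal import LambdaEngine
    return LambdaEngine.from_tree(tree100)


@pytest.fixture(scope="session")
def null_pvalues_200(tree100, engine100):
    """Permutation-test p-values for 200 iid-normal (lambda = 0) traits on a
    100-tip tree, n_perm = 199: the type-I-error / validity reference set."""
    rng = np.random.default_rng(2024)
    pvals = []
    for _ in range(200):
        x = pd.Series(rng.standard_normal(100), index=engine100.labels)
        res = pf.lambda_significance(
            x, tree100, n_perm=199, seed=int(rng.integers(2**31 - 1)),
            _engine=engine100,
        )
        pvals.append(res.p_value)
    return np.array(pvals)


@pytest.fixture(scope="session")
def landscape_runs():
    """End-to-end landscape evaluation over 20 seeds at tau = eps = 0.01:
    fit FEEs on the simulated design, predict 100+ held-out communities,
    score FEE and additive models."""
    pool = [f"ns{k:02d}" for k in range(1, 11)]
    runs = []
    for seed in range(1, 21):
        ds, truth = pf.simulate_community_experiment(tau=0.01, eps=0.01, seed=seed)
        fees = pf.fit_all_fees(ds)
        val = pf.simulate.sample_validation_communities(
            truth, ds, pool, focal="sc01", n=110, seed=seed + 1000
        )
        fee_pred = pd.Series(
            {k: pf.predict_function(k, ds, fees).F_pred for k in val.index}
        )
        add_pred = pd.Series(
            {k: pf.additive_from_dataset(ds, k, "sc01")[0] for k in val.index}
        )
        runs.append(
            {
                "seed": seed,
                "fee": pf.evaluate_predictions(fee_pred, val),
                "additive": pf.evaluate_predictions(add_pred, val),
            }
        )
    return runs
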