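"""Binary-trait Markov models and stochastic character mapping on phylogenies.

The conservation-status character (0 = not of concern, 1 = of concern) is
modelled as a continuous-time symmetric two-state Markov chain (equal-rates
Mk) along the branches of a rooted tree.  Transition probabilities over a
branch of length t are closed-form:

    P_same(t) = (1 + exp(-2 q t)) / 2,   P_diff(t) = (1 - exp(-2 q t)) / 2

The likelihood is computed with Felsenstein's pruning algorithm and an
equal (0.5/0.5) root prior; the rate q is fitted by bounded 1-D search.
Stochastic maps draw joint internal-node states from the conditional
distribution given the tips (root from prior x partial likelihoods, then
pre-order conditional sampling); the per-node probability of concern is
the fraction of maps in state 1.  Branch histories are sampled by
rejection of forward simulations conditioned on endpoints, falling back to
uniformization when rejection keeps failing.

Trees are dendropy objects; polytomies are resolved with zero-length
branches (likelihood-neutral) before computing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "prune_tree",
    "mk_loglik",
    "MkFit",
    "fit_mk",
    "marginal_ancestral_probs",
    "stochastic_maps",
    "NodeStateMap",
]


def _p_same(q: float, t: float) -> float:
    return 0.5 * (1.0 + math.exp(-2.0 * q * t))


def _trans_matrix(q: float, t: float) -> np.ndarray:
    ps = _p_same(q, t)
    return np.array([[ps, 1 - ps], [1 - ps, ps]])


def prune_tree(tree: dendropy.Tree, species: list[str]) -> dendropy.Tree:
    """Induced subtree on the matched species; patristic distances preserved.

    Unmatched species are reported in a warning; fewer than two matches is
    an error.
    """
    labels = {l.taxon.label for l in tree.leaf_node_iter()}
    wanted = [s for s in species if s in labels]
    missing = sorted(set(species) - labels)
    if missing:
        warnings.warn(f"{len(missing)} species not in tree: {missing[:5]}...")
    if len(wanted) < 2:
        raise ValueError("fewer than two species matched the tree")
    sub = tree.clone(depth=1)
    taxa = [t for t in sub.taxon_namespace if t.label in set(wanted)]
    sub.retain_taxa(taxa)
    # merge unifurcations left by pruning so path lengths are preserved
    sub.suppress_unifurcations()
    return sub


def _prep(tree: dendropy.Tree, tip_states: dict[str, int]):
    """Binary-resolved working copy with per-node indices and tip states."""
    work = tree.clone(depth=1)
    work.resolve_polytomies(limit=2, update_bipartitions=False)
    nodes = list(work.postorder_node_iter())
    for i, nd in enumerate(nodes):
        nd._ix = i
    for leaf in work.leaf_node_iter():
        lab = leaf.taxon.label
        if lab not in tip_states:
            raise ValueError(f"tip {lab!r} has no state")
        s = int(tip_states[lab])
        if s not in (0, 1):
            raise ValueError(f"tip state must be 0/1, got {s!r}")
        leaf._state = s
    return work, nodes


def _down_partials(nodes, q: float):
    """Postorder partial likelihoods with log-scaling.

    Returns (partials[n,2], logscale) where the root row combined with the
    prior gives the likelihood.
    """
    n = len(nodes)
    L = np.empty((n, 2))
    logscale = 0.0
    for nd in nodes:
        i = nd._ix
        if nd.is_leaf():
            L[i] = 0.0
            L[i][nd._state] = 1.0
            continue
        row = np.ones(2)
        for ch in nd.child_nodes():
            P = _trans_matrix(q, ch.edge.length or 0.0)
            row = row * (P @ L[ch._ix])
        m = row.max()
        if m <= 0:
            return L, -math.inf
        L[i] = row / m
        logscale += math.log(m)
    return L, logscale


def mk_loglik(tree: dendropy.Tree, tip_states: dict[str, int],
              q: float) -> float:
    """Log-likelihood of tip states under the symmetric Mk model at rate q,
    with the equal (0.5, 0.5) root prior."""
    if q < 0:
        raise ValueError("q must be non-negative")
    work, nodes = _prep(tree, tip_states)
    L, logscale = _down_partials(nodes, q)
    root = nodes[-1]
    lik = 0.5 * L[root._ix].sum()
    if lik <= 0:
        return -math.inf
    return math.log(lik) + logscale


@dataclass
class MkFit:
    q: float
    loglik: float
    converged: bool
    root_prior: tuple[float, float] = (0.5, 0.5)


def fit_mk(tree: dendropy.Tree, tip_states: dict[str, int],
           q_bounds: tuple[float, float] = (1e-8, 100.0)) -> MkFit:
    """Maximum-likelihood rate of the symmetric Mk model (bounded search).

    If all tips share one state the likelihood is maximised at the q -> 0
    boundary; that is returned with a warning.
    """
    states = {tip_states[l.taxon.label] for l in tree.leaf_node_iter()}
    if len(states) < 2:
        warnings.warn("all tips share one state; q at the lower boundary")
        lo = q_bounds[0]
        return MkFit(lo, mk_loglik(tree, tip_states, lo), True)
    res = minimize_scalar(lambda lq: -mk_loglik(tree, tip_states, math.exp(lq)),
                          bounds=(math.log(q_bounds[0]), math.log(q_bounds[1])),
                          method="bounded",
                          options={"xatol": 1e-8})
    q = math.exp(res.x)
    return MkFit(q, -res.fun, bool(res.success))


def marginal_ancestral_probs(tree: dendropy.Tree, tip_states: dict[str, int],
                             q: float) -> pd.DataFrame:
    """Marginal probability of state 1 at every node (pruning up-down pass)."""
    work, nodes = _prep(tree, tip_states)
    L, _ = _down_partials(nodes, q)
    n = len(nodes)
    up = np.empty((n, 2))
    root = nodes[-1]
    up[root._ix] = 0.5  # prior
    for nd in reversed(nodes):  # preorder
        for ch in nd.child_nodes():
            # message to child: (up(parent) * siblings' contributions) x P
            contrib = up[nd._ix].copy()
            for sib in nd.child_nodes():
                if sib is ch:
                    continue
                P = _trans_matrix(q, sib.edge.length or 0.0)
                contrib = contrib * (P @ L[sib._ix])
            P = _trans_matrix(q, ch.edge.length or 0.0)
            msg = P.T @ contrib
            m = msg.max()
            up[ch._ix] = msg / m if m > 0 else msg
    rows = []
    for nd in nodes:
        post = up[nd._ix] * L[nd._ix]
        post = post / post.sum()
        rows.append(dict(node=_fingerprint(nd), is_leaf=nd.is_leaf(),
                         p_state1=float(post[1])))
    return pd.DataFrame(rows)


def _fingerprint(nd) -> str:
    if nd.is_leaf():
        return nd.taxon.label
    tips = sorted(l.taxon.label for l in nd.leaf_iter())
    return "|".join(tips)


def _branch_history(q: float, t: float, i: int, j: int,
                    rng: np.random.Generator, max_tries: int = 50) -> int:
    """Number of state changes on a branch conditioned on its endpoints.

    Rejection sampling of forward trajectories; uniformization fallback.
    """
    if q == 0 or t == 0:
        return 0 if i == j else 1
    for _ in range(max_tries):
        state, time, changes = i, 0.0, 0
        while True:
            time += rng.exponential(1.0 / q)
            if time >= t:
                break
            state ^= 1
            changes += 1
        if state == j:
            return changes
    # uniformization: N | endpoints, with flip chain R = [[0,1],[1,0]]
    pij = _trans_matrix(q, t)[i, j]
    lam = q * t
    probs = []
    n_, term = 0, math.exp(-lam)
    while n_ < 200 and (n_ < 5 or term > 1e-12):
        # R^n alternates between I and the flip matrix
        rn = 1.0 if (n_ % 2 == 0) == (i == j) else 0.0
        probs.append(term * rn / pij)
        n_ += 1
        term *= lam / n_
    probs = np.array(probs)
    probs = probs / probs.sum()
    n_jumps = rng.choice(len(probs), p=probs)
    # virtual jumps with even/odd parity matching give real changes = jumps here
    return int(n_jumps)


@dataclass
class NodeStateMap:
    table: pd.DataFrame      # node fingerprint, p_state1, n_maps
    n_maps: int
    mean_changes: float      # mean number of state changes per map


def stochastic_maps(tree: dendropy.Tree, tip_states: dict[str, int],
                    fit: MkFit | float, n_maps: int = 500,
                    seed: int = 0) -> NodeStateMap:
    """Stochastic character maps: per-node probability of state 1.

    Joint node states are sampled exactly (root from prior x partials, then
    preorder conditional draws), so node frequencies over many maps agree
    with the pruning marginals.  Tips keep their observed state.
    """
    q = fit.q if isinstance(fit, MkFit) else float(fit)
    rng = np.random.default_rng(seed)
    work, nodes = _prep(tree, tip_states)
    L, _ = _down_partials(nodes, q)
    root = nodes[-1]
    Pcache = {nd._ix: _trans_matrix(q, nd.edge.length or 0.0)
              for nd in nodes if nd is not root}

    counts = np.zeros(len(nodes))
    total_changes = 0
    order = list(reversed(nodes))  # preorder
    state = np.empty(len(nodes), dtype=int)
    for _ in range(n_maps):
        w = 0.5 * L[root._ix]
        state[root._ix] = int(rng.random() * w.sum() >= w[0])
        for nd in order:
            if nd is root:
                continue
            P = Pcache[nd._ix]
            w = P[state[nd.parent_node._ix]] * L[nd._ix]
            state[nd._ix] = int(rng.random() * w.sum() >= w[0])
            total_changes += _branch_history(
                q, nd.edge.length or 0.0,
                int(state[nd.parent_node._ix]), int(state[nd._ix]), rng)
        counts += state
    rows = [dict(node=_fingerprint(nd), is_leaf=nd.is_leaf(),
                 p_state1=counts[nd._ix] / n_maps) for nd in nodes]
    return NodeStateMap(pd.DataFrame(rows), n_maps, total_changes / n_maps)
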