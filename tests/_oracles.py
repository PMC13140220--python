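"""Independent brute-force oracles used only by the test suite.

These enumerate over all internal-node state assignments (likelihood,
posteriors) or all internal state combinations (parsimony), so they are exact
on small trees and entirely independent of the pruning/DP implementations.
"""

import itertools

import numpy as np


def brute_force_site_likelihoods(model, tree, seqs):
    """Per-site likelihood by exhaustive enumeration (single rate category)."""
    idx = model.state_index()
    n = model.nstates
    p_mats = {v: model.transition_matrix(tree.lengths[v])
              for v in range(tree.n_nodes) if tree.parent[v] >= 0}
    internal = [v for v in range(tree.n_nodes) if tree.children[v]]
    length = len(next(iter(seqs.values())))
    out = np.zeros(length)
    for site in range(length):
        total = 0.0
        for assign in itertools.product(range(n), repeat=len(internal)):
            a = dict(zip(internal, assign))
            for v in tree.tips:
                a[v] = idx[seqs[tree.tip_names[v]][site]]
            p = model.pi[a[tree.root]]
            for v in range(tree.n_nodes):
                if tree.parent[v] >= 0:
                    p *= p_mats[v][a[tree.parent[v]], a[v]]
            total += p
        out[site] = total
    return out


def brute_force_loglik(model, tree, seqs):
    return float(np.log(brute_force_site_likelihoods(model, tree, seqs)).sum())


def brute_force_posteriors(model, tree, seqs, node):
    """Marginal posteriors at ``node`` by exhaustive Bayes."""
    idx = model.state_index()
    n = model.nstates
    p_mats = {v: model.transition_matrix(tree.lengths[v])
              for v in range(tree.n_nodes) if tree.parent[v] >= 0}
    internal = [v for v in range(tree.n_nodes) if tree.children[v]]
    length = len(next(iter(seqs.values())))
    post = np.zeros((length, n))
    for site in range(length):
        for assign in itertools.product(range(n), repeat=len(internal)):
            a = dict(zip(internal, assign))
            for v in tree.tips:
                a[v] = idx[seqs[tree.tip_names[v]][site]]
            p = model.pi[a[tree.root]]
            for v in range(tree.n_nodes):
                if tree.parent[v] >= 0:
                    p *= p_mats[v][a[tree.parent[v]], a[v]]
            post[site, a[node]] += p
    return post / post.sum(axis=1, keepdims=True)


def brute_force_min_changes(tree, tip_states, node, state):
    """Minimum number of binary-character changes with ``node`` fixed to
    ``state``, by exhaustive search over internal assignments."""
    internal = [v for v in range(tree.n_nodes) if tree.children[v]]
    best = None
    for assign in itertools.product(range(2), repeat=len(internal)):
        a = dict(zip(internal, assign))
        if a.get(node, tip_states.get(tree.tip_names.get(node))) != state:
            if node in a:
                continue
        for v in tree.tips:
            a[v] = tip_states[tree.tip_names[v]]
        if a[node] != state:
            continue
        changes = sum(1 for v in range(tree.n_nodes)
                      if tree.parent[v] >= 0 and a[v] != a[tree.parent[v]])
        best = changes if best is None else min(best, changes)
    return best


def brute_force_mpr_states(tree, tip_states, node):
    """Set of states at ``node`` that occur in at least one most-parsimonious
    reconstruction."""
    costs = {s: brute_force_min_changes(tree, tip_states, node, s) for s in (0, 1)}
    best = min(c for c in costs.values() if c is not None)
    return {s for s, c in costs.items() if c == best}
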