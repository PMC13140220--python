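"""Felsenstein pruning on a fixed rooted topology, with marginal posteriors.

Site patterns are compressed once at construction; gaps, ``N`` and any state
outside the model alphabet enter as missing data (partial likelihood 1 over all
states).  Per-node scaling keeps partial likelihoods in range for arbitrarily
large trees.  Marginal ancestral posteriors use the inside-outside recursion,
which for reversible models equals rerooting the tree at the query node and
combining partial likelihoods with the stationary distribution.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError, NumericalError
from .substmodels import SubstitutionModel
from .trees import TreeIndex

_TINY = 1e-300


class PartitionEngine:
    """Pruning likelihood for one partition class (one model, one set of columns).

    Parameters
    ----------
    tree : TreeIndex
    tip_codes : dict mapping tip node index -> (ncols,) int array of state
        indices, with -1 for missing data.
    nstates : size of the model state space.
    """

    def __init__(self, tree: TreeIndex, tip_codes: dict[int, np.ndarray], nstates: int):
        self.tree = tree
        self.nstates = nstates
        tips = tree.tips
        if set(tip_codes) != set(tips):
            raise InputError("tip codes do not match tree tips")
        mat = np.stack([np.asarray(tip_codes[i], dtype=int) for i in tips], axis=0)
        self.ncols = mat.shape[1]
        patterns, inverse, counts = np.unique(
            mat, axis=1, return_inverse=True, return_counts=True
        )
        self.pattern_weights = counts.astype(float)
        self.col_to_pattern = inverse
        self.npat = patterns.shape[1]
        # Pre-build tip partial likelihood matrices (nstates, npat) per tip.
        self._tip_partials: dict[int, np.ndarray] = {}
        for row, tip in enumerate(tips):
            codes = patterns[row]
            part = np.zeros((nstates, self.npat))
            obs = codes >= 0
            part[codes[obs], np.nonzero(obs)[0]] = 1.0
            part[:, ~obs] = 1.0
            self._tip_partials[tip] = part

    # -- inside (postorder) pass ------------------------------------------------

    def _inside(self, p_mats: list[np.ndarray]) -> tuple[list, list, np.ndarray]:
        """Return per-node conditional partials D, child messages T, and the
        cumulative log scaling at the root (per pattern)."""
        n = self.tree.n_nodes
        d: list[np.ndarray | None] = [None] * n
        t: list[np.ndarray | None] = [None] * n  # message P_v @ D_v from child v
        cum = [np.zeros(self.npat) for _ in range(n)]
        for u in self.tree.postorder:
            kids = self.tree.children[u]
            if not kids:
                d[u] = self._tip_partials[u]
                continue
            m = np.ones((self.nstates, self.npat))
            csum = np.zeros(self.npat)
            for v in kids:
                t[v] = p_mats[v] @ d[v]
                m *= t[v]
                csum += cum[v]
            s = m.max(axis=0)
            # a pattern can be impossible in one rate category (e.g. conflicting
            # tips under a near-zero rate); carry a floored scale, the category
            # then contributes ~0 likelihood instead of blowing up
            s = np.where(s > 0, s, 1.0)
            d[u] = m / s
            cum[u] = csum + np.log(s)
        return d, t, cum[self.tree.root]

    def _p_mats(self, model: SubstitutionModel, lengths: np.ndarray, rate: float) -> list:
        return [
            model.transition_matrix(max(lengths[v], 0.0) * rate) if self.tree.parent[v] >= 0 else None
            for v in range(self.tree.n_nodes)
        ]

    # -- public API -------------------------------------------------------------

    def site_logliks(
        self,
        model: SubstitutionModel,
        lengths: np.ndarray,
        cat_rates: np.ndarray,
        cat_weights: np.ndarray,
        rate_multiplier: float = 1.0,
    ) -> np.ndarray:
        """(npat,) log-likelihood per site pattern, mixed over rate categories."""
        logs = np.empty((len(cat_rates), self.npat))
        for c, r in enumerate(cat_rates):
            p_mats = self._p_mats(model, lengths, r * rate_multiplier)
            d, _, scale = self._inside(p_mats)
            root_lik = model.pi @ d[self.tree.root]
            logs[c] = np.log(np.maximum(root_lik, _TINY)) + scale
        lw = np.log(cat_weights)[:, None] + logs
        mx = lw.max(axis=0)
        return mx + np.log(np.exp(lw - mx).sum(axis=0))

    def loglik(self, model, lengths, cat_rates, cat_weights, rate_multiplier=1.0) -> float:
        site = self.site_logliks(model, lengths, cat_rates, cat_weights, rate_multiplier)
        total = float((site * self.pattern_weights).sum())
        if not np.isfinite(total):
            raise NumericalError("non-finite log-likelihood")
        return total

    def node_posteriors(
        self,
        model: SubstitutionModel,
        lengths: np.ndarray,
        cat_rates: np.ndarray,
        cat_weights: np.ndarray,
        node: int,
        rate_multiplier: float = 1.0,
    ) -> np.ndarray:
        """(ncols, nstates) empirical-Bayes marginal posterior at an internal node."""
        if node in self.tree.tip_names:
            raise InputError("marginal posteriors are defined for internal nodes")
        ncat = len(cat_rates)
        post_c = np.empty((ncat, self.nstates, self.npat))
        site_logs = np.empty((ncat, self.npat))
        for c, r in enumerate(cat_rates):
            p_mats = self._p_mats(model, lengths, r * rate_multiplier)
            d, t, scale = self._inside(p_mats)
            root_lik = model.pi @ d[self.tree.root]
            site_logs[c] = np.log(np.maximum(root_lik, _TINY)) + scale
            # outside pass
            u_arr: list[np.ndarray | None] = [None] * self.tree.n_nodes
            u_arr[self.tree.root] = np.repeat(model.pi[:, None], self.npat, axis=1)
            for u in self.tree.preorder():
                kids = self.tree.children[u]
                if not kids:
                    continue
                for v in kids:
                    out = u_arr[u].copy()
                    for w in kids:
                        if w != v:
                            out *= t[w]
                    uv = p_mats[v].T @ out
                    mx = uv.max(axis=0)
                    mx[mx <= 0] = 1.0
                    u_arr[v] = uv / mx
            unnorm = u_arr[node] * d[node]
            tot = unnorm.sum(axis=0)
            tot[tot <= 0] = 1.0
            post_c[c] = unnorm / tot
        # mix categories by their per-pattern posterior weight
        lw = np.log(cat_weights)[:, None] + site_logs
        lw -= lw.max(axis=0, keepdims=True)
        w = np.exp(lw)
        w /= w.sum(axis=0, keepdims=True)
        mixed = (post_c * w[:, None, :]).sum(axis=0)  # (nstates, npat)
        return mixed[:, self.col_to_pattern].T


def encode_sequences(
    seqs: dict[str, str], tree: TreeIndex, states: tuple[str, ...], chunk: int = 1
) -> dict[int, np.ndarray]:
    """Encode tip sequences as state-index arrays (-1 = missing).

    ``chunk`` > 1 groups characters (codons): any chunk containing a character
    outside the alphabet (gap, N, stop codon) becomes missing data.
    """
    index = {s: i for i, s in enumerate(states)}
    out: dict[int, np.ndarray] = {}
    for tip in tree.tips:
        name = tree.tip_names[tip]
        if name not in seqs:
            raise InputError(f"tree tip {name!r} absent from alignment")
        seq = seqs[name]
        if chunk == 1:
            codes = np.array([index.get(ch, -1) for ch in seq], dtype=int)
        else:
            codes = np.array(
                [index.get(seq[i : i + chunk], -1) for i in range(0, len(seq), chunk)],
                dtype=int,
            )
        out[tip] = codes
    return out
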