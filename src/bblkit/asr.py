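"""Empirical-Bayes marginal ancestral sequence reconstruction on a fixed topology.

The central object is :class:`AncestralReconstruction`, a model built from an
alignment, a rooted tree with named internal nodes, and a substitution-model
specification.  ``fit()`` maximizes the likelihood over branch lengths and free
model parameters (coordinate-wise Brent on branches interleaved with bounded
quasi-Newton on parameters) and returns :class:`ASRResults`, which exposes the
estimates, per-node marginal posteriors, MAP sequences and a summary table.

Three model kinds are supported, mirroring the usual multi-model consensus
practice for ancestor resurrection: partitioned nucleotide GTR+Gamma, empirical
amino-acid JTT+Gamma, and the M0 codon model with F1x4 frequencies.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .alignment import MSA, Partition, translate
from .errors import ConvergenceWarning, InputError
from .likelihood import PartitionEngine, encode_sequences
from .substmodels import (
    CODON_STATES,
    SubstitutionModel,
    codon_m0,
    discrete_gamma,
    gtr,
    jtt,
)
from .trees import TreeIndex, check_tip_match, read_tree

BL_BOUNDS = (1e-8, 10.0)
_LOG_BOUND = (np.log(1e-4), np.log(1e4))
_ALPHA_BOUND = (np.log(0.02), np.log(100.0))


@dataclass
class PartitionParams:
    """Free parameters of one partition class."""

    model: SubstitutionModel
    alpha: float
    rate: float = 1.0  # class rate multiplier, weighted mean 1 across classes

    def to_dict(self) -> dict:
        d = {"kind": self.model.kind, "alpha": self.alpha, "rate": self.rate,
             "pi": self.model.pi.tolist()}
        if self.model.kind == "gtr":
            s = self.model.exchangeabilities
            pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
            d["exchangeabilities"] = [float(s[i, j]) for i, j in pairs]
        return d


@dataclass
class SitePosterior:
    """Per-column posterior distribution over states at one internal node."""

    node: str
    states: tuple[str, ...]
    probs: np.ndarray  # (ncols, nstates), rows sum to 1
    level: str  # nucleotide | protein | codon

    def __post_init__(self) -> None:
        sums = self.probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise InputError("posterior rows must sum to 1")

    @property
    def max_posterior(self) -> np.ndarray:
        return self.probs.max(axis=1)

    def to_tsv(self, path: str | Path, refmap=None) -> None:
        with open(path, "w") as fh:
            fh.write("node\tcolumn\tref_residue\tstate\tprobability\n")
            for col in range(self.probs.shape[0]):
                i = int(self.probs[col].argmax())
                ref = refmap.label_of(col) if refmap is not None else ""
                fh.write(
                    f"{self.node}\t{col}\t{ref}\t{self.states[i]}\t{self.probs[col, i]:.6f}\n"
                )


@dataclass
class AncestralSequence:
    """MAP ancestral sequence with per-column confidence."""

    node: str
    states: list[str]  # per column; '-' where masked as ancestral gap
    max_posterior: np.ndarray
    mean_posterior: float
    model: str
    level: str
    ambiguous_columns: list[int] = field(default_factory=list)
    gap_mask: np.ndarray | None = None

    @property
    def sequence(self) -> str:
        return "".join(self.states)

    def protein(self) -> str:
        if self.level == "protein":
            return self.sequence
        return translate(self.sequence)


def map_sequence(posterior: SitePosterior, gap_mask: np.ndarray | None = None,
                 model_tag: str | None = None) -> AncestralSequence:
    """MAP state per column; ties broken by fixed (alphabetical) state order and
    flagged ambiguous; mean max-posterior over non-gap columns only."""
    probs = posterior.probs
    ncols = probs.shape[0]
    if gap_mask is None:
        gap_mask = np.zeros(ncols, dtype=bool)
    gap_mask = np.asarray(gap_mask, dtype=bool)
    if gap_mask.shape != (ncols,):
        raise InputError("gap mask length does not match posterior columns")
    best = probs.argmax(axis=1)
    mx = probs.max(axis=1)
    ties = (np.abs(probs - mx[:, None]) < 1e-12).sum(axis=1) > 1
    states = ["-" if gap_mask[c] else posterior.states[best[c]] for c in range(ncols)]
    nongap = ~gap_mask
    mean_pp = float(mx[nongap].mean()) if nongap.any() else float("nan")
    return AncestralSequence(
        node=posterior.node,
        states=states,
        max_posterior=mx,
        mean_posterior=mean_pp,
        model=model_tag or "",
        level=posterior.level,
        ambiguous_columns=[int(c) for c in np.nonzero(ties & nongap)[0]],
        gap_mask=gap_mask,
    )


class AncestralReconstruction:
    """Fixed-topology likelihood model for ancestral state reconstruction.

    Parameters
    ----------
    msa : MSA
        Codon-aware nucleotide alignment (translated internally for protein
        models, chunked into codons for the codon model).
    tree : dendropy.Tree, newick string/path, or TreeIndex
        Rooted topology with named internal nodes; tip labels must be a subset
        of the alignment ids.  Input branch lengths seed the optimizer.
    model : {"gtr", "jtt", "codon_m0"}
    partition : Partition, str scheme ("12_3", "1_2_3", "none"), or None
        Site classes (nucleotide model only).
    ncat : int
        Discrete-gamma categories (category means).
    """

    def __init__(
        self,
        msa: MSA,
        tree,
        model: str = "gtr",
        partition: str | Partition | None = "12_3",
        ncat: int = 5,
        freqs: str = "empirical",
    ):
        self.msa = msa
        if isinstance(tree, TreeIndex):
            self.tree = tree
        else:
            if isinstance(tree, (str, Path)):
                tree = read_tree(tree)
            if not isinstance(tree, dendropy.Tree):
                raise InputError("tree must be a newick string/path or dendropy.Tree")
            self.tree = TreeIndex.from_dendropy(tree)
        check_tip_match(self.tree, msa.ids)
        self.model_kind = model
        self.ncat = int(ncat)
        self.freqs_mode = freqs
        seqs = dict(msa.records)
        tip_seqs = {t: seqs[t] for t in self.tree.tip_labels}

        if model == "gtr":
            self.level = "nucleotide"
            if partition is None:
                partition = Partition.single(msa.length)
            elif isinstance(partition, str):
                partition = Partition.codon_positions(msa.length, scheme=partition)
            self.partition = partition
            codes_all = encode_sequences(tip_seqs, self.tree, ("A", "C", "G", "T"))
            self.engines = []
            self._class_pis = []
            for cols in partition.classes:
                sub = {t: codes_all[t][cols] for t in codes_all}
                self.engines.append(PartitionEngine(self.tree, sub, 4))
                self._class_pis.append(_empirical_freqs(sub, 4))
        elif model == "jtt":
            self.level = "protein"
            prot = msa.to_protein()
            pseqs = dict(prot.records)
            tip_prot = {t: pseqs[t] for t in self.tree.tip_labels}
            self.partition = Partition.single(prot.length)
            codes = encode_sequences(tip_prot, self.tree, jtt().states)
            self.engines = [PartitionEngine(self.tree, codes, 20)]
            self._class_pis = [
                _empirical_freqs(codes, 20) if freqs == "empirical" else jtt().pi
            ]
        elif model == "codon_m0":
            self.level = "codon"
            if msa.length % 3 != 0:
                raise InputError("codon model needs an in-frame alignment")
            self.partition = Partition.single(msa.length // 3)
            codes = encode_sequences(tip_seqs, self.tree, CODON_STATES, chunk=3)
            self.engines = [PartitionEngine(self.tree, codes, 61)]
            nt_codes = encode_sequences(tip_seqs, self.tree, ("A", "C", "G", "T"))
            self._nt_freqs = _empirical_freqs(nt_codes, 4)
        else:
            raise InputError(f"unknown model kind {model!r}")
        self._class_weights = np.array([e.ncols for e in self.engines], dtype=float)

    # -- parameter plumbing -------------------------------------------------------

    def _init_params(self) -> list[PartitionParams]:
        if self.model_kind == "gtr":
            return [
                PartitionParams(model=gtr(pi=pi), alpha=1.0, rate=1.0)
                for pi in self._class_pis
            ]
        if self.model_kind == "jtt":
            return [PartitionParams(model=jtt(pi=self._class_pis[0]), alpha=1.0)]
        return [PartitionParams(model=codon_m0(nt_freqs=self._nt_freqs), alpha=1.0)]

    def _theta_spec(self, fixed_alpha) -> list[tuple[int, str, tuple[float, float]]]:
        """(class index, name, bounds) for each free scalar, in packing order."""
        spec = []
        for k in range(len(self.engines)):
            if self.model_kind == "gtr":
                for name in ("rAC", "rAG", "rAT", "rCG", "rCT"):
                    spec.append((k, name, _LOG_BOUND))
            elif self.model_kind == "codon_m0":
                spec.append((k, "kappa", _LOG_BOUND))
                spec.append((k, "omega", (np.log(1e-4), np.log(50.0))))
            if fixed_alpha is None and self.ncat > 1:
                spec.append((k, "alpha", _ALPHA_BOUND))
            if len(self.engines) > 1:
                spec.append((k, "rate", (-5.0, 5.0)))
        return spec

    def _pack(self, params: list[PartitionParams], spec) -> np.ndarray:
        vals = []
        for k, name, _ in spec:
            p = params[k]
            if name.startswith("r") and self.model_kind == "gtr" and name != "rate":
                idx = {"rAC": (0, 1), "rAG": (0, 2), "rAT": (0, 3),
                       "rCG": (1, 2), "rCT": (1, 3)}[name]
                vals.append(np.log(max(p.model.exchangeabilities[idx], 1e-6)))
            elif name == "kappa":
                vals.append(np.log(p.model.exchangeabilities[
                    CODON_STATES.index("AAA"), CODON_STATES.index("AAG")]))
            elif name == "omega":
                vals.append(np.log(self._current_omega(p.model)))
            elif name == "alpha":
                vals.append(np.log(p.alpha))
            elif name == "rate":
                vals.append(np.log(p.rate))
        return np.array(vals)

    @staticmethod
    def _current_omega(model: SubstitutionModel) -> float:
        # AAA (K) -> ACA (T) is a nonsynonymous transversion: rate = omega
        i, j = CODON_STATES.index("AAA"), CODON_STATES.index("ACA")
        return max(float(model.exchangeabilities[i, j]), 1e-6)

    def _unpack(self, theta: np.ndarray, params: list[PartitionParams], spec,
                fixed_alpha) -> list[PartitionParams]:
        new = [PartitionParams(p.model, p.alpha, p.rate) for p in params]
        by_class: dict[int, dict[str, float]] = {}
        for val, (k, name, _) in zip(theta, spec):
            by_class.setdefault(k, {})[name] = float(np.exp(val)) if name != "rate" else float(np.exp(val))
        for k, vals in by_class.items():
            p = new[k]
            if self.model_kind == "gtr":
                rates = [vals.get("rAC"), vals.get("rAG"), vals.get("rAT"),
                         vals.get("rCG"), vals.get("rCT"), 1.0]
                if rates[0] is not None:
                    p.model = gtr(rates=np.array(rates), pi=p.model.pi)
            elif self.model_kind == "codon_m0":
                if "kappa" in vals:
                    p.model = codon_m0(kappa=vals["kappa"], omega=vals["omega"],
                                       nt_freqs=self._nt_freqs)
            if "alpha" in vals:
                p.alpha = vals["alpha"]
            elif fixed_alpha is not None:
                p.alpha = fixed_alpha
            if "rate" in vals:
                p.rate = vals["rate"]
        # enforce identifiability: column-weighted mean rate multiplier = 1
        if len(new) > 1:
            w = self._class_weights
            mean = float(sum(wi * p.rate for wi, p in zip(w, new)) / w.sum())
            for p in new:
                p.rate /= mean
        return new

    def _loglik(self, params: list[PartitionParams], lengths: np.ndarray) -> float:
        total = 0.0
        for eng, p in zip(self.engines, params):
            rates = discrete_gamma(p.alpha, self.ncat)
            total += eng.loglik(p.model, lengths, rates, np.full(self.ncat, 1.0 / self.ncat),
                                rate_multiplier=p.rate)
        return total

    # -- fitting ------------------------------------------------------------------

    def fit(
        self,
        optimize_branch_lengths: bool = True,
        scale_only: bool = False,
        fixed_alpha: float | None = None,
        init_lengths: np.ndarray | None = None,
        max_rounds: int = 30,
        tol: float = 1e-6,
    ) -> "ASRResults":
        """Maximize the log-likelihood; returns an :class:`ASRResults`.

        ``scale_only=True`` optimizes a single multiplicative tree scale instead
        of individual branch lengths (useful when reusing branch lengths fitted
        under another model).
        """
        params = self._init_params()
        if fixed_alpha is not None:
            for p in params:
                p.alpha = fixed_alpha
        lengths = (np.asarray(init_lengths, dtype=float).copy()
                   if init_lengths is not None else self.tree.lengths.copy())
        lengths = np.clip(lengths, BL_BOUNDS[0], BL_BOUNDS[1])
        lengths[self.tree.root] = 0.0
        spec = self._theta_spec(fixed_alpha)
        lnl = self._loglik(params, lengths)
        converged = False
        n_rounds = 0
        for _ in range(max_rounds):
            n_rounds += 1
            prev = lnl
            if spec:
                theta0 = self._pack(params, spec)
                bounds = [b for _, _, b in spec]

                def obj(theta):
                    return -self._loglik(self._unpack(theta, params, spec, fixed_alpha), lengths)

                res = minimize(obj, theta0, method="L-BFGS-B", bounds=bounds,
                               options={"maxiter": 200, "ftol": 1e-10})
                if -res.fun > lnl:
                    params = self._unpack(res.x, params, spec, fixed_alpha)
                    lnl = -res.fun
            if optimize_branch_lengths:
                if scale_only:
                    def sobj(logs):
                        return -self._loglik(params, np.clip(lengths * np.exp(logs), *BL_BOUNDS))

                    sres = minimize_scalar(sobj, bounds=(-4.0, 4.0), method="bounded",
                                           options={"xatol": 1e-8})
                    if -sres.fun > lnl:
                        lengths = np.clip(lengths * np.exp(sres.x), *BL_BOUNDS)
                        lengths[self.tree.root] = 0.0
                        lnl = -sres.fun
                else:
                    for v in self.tree.postorder:
                        if self.tree.parent[v] < 0:
                            continue

                        def bobj(t, _v=v):
                            trial = lengths.copy()
                            trial[_v] = t
                            return -self._loglik(params, trial)

                        bres = minimize_scalar(bobj, bounds=BL_BOUNDS, method="bounded",
                                               options={"xatol": 1e-9})
                        if -bres.fun >= lnl:
                            lengths[v] = bres.x
                            lnl = -bres.fun
            if lnl - prev < tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"optimizer stopped after {n_rounds} rounds (last improvement "
                f"{lnl - prev:.3g})", ConvergenceWarning, stacklevel=2)
        return ASRResults(model=self, params=params, branch_lengths=lengths,
                          loglik=lnl, converged=converged, n_rounds=n_rounds)


def _empirical_freqs(codes: dict[int, np.ndarray], nstates: int) -> np.ndarray:
    counts = np.zeros(nstates)
    for arr in codes.values():
        obs = arr[arr >= 0]
        counts += np.bincount(obs, minlength=nstates)
    counts += 0.5  # tiny pseudocount guards against absent states
    return counts / counts.sum()


class ASRResults:
    """Fitted ancestral-reconstruction model.

    Carries the ML parameter estimates and branch lengths, and computes
    empirical-Bayes marginal posteriors / MAP sequences at any named internal
    node.
    """

    def __init__(self, model: AncestralReconstruction, params, branch_lengths,
                 loglik, converged, n_rounds):
        self.model = model
        self.params: list[PartitionParams] = params
        self.branch_lengths = branch_lengths
        self.loglik = float(loglik)
        self.converged = converged
        self.n_rounds = n_rounds

    @property
    def tree_length(self) -> float:
        return float(self.branch_lengths.sum() - self.branch_lengths[self.model.tree.root])

    def marginal_posteriors(self, node: str) -> SitePosterior:
        """Marginal posterior state distributions at a named internal node."""
        m = self.model
        idx = m.tree.node(node)
        if m.model_kind == "gtr":
            ncols = m.msa.length
            probs = np.empty((ncols, 4))
            for eng, p, cols in zip(m.engines, self.params, m.partition.classes):
                rates = discrete_gamma(p.alpha, m.ncat)
                post = eng.node_posteriors(p.model, self.branch_lengths, rates,
                                           np.full(m.ncat, 1.0 / m.ncat), idx,
                                           rate_multiplier=p.rate)
                probs[np.asarray(cols)] = post
            states: tuple[str, ...] = ("A", "C", "G", "T")
        else:
            p = self.params[0]
            rates = discrete_gamma(p.alpha, m.ncat)
            probs = m.engines[0].node_posteriors(p.model, self.branch_lengths, rates,
                                                 np.full(m.ncat, 1.0 / m.ncat), idx,
                                                 rate_multiplier=p.rate)
            states = p.model.states
        return SitePosterior(node=node, states=states, probs=probs, level=m.level)

    def map_sequence(self, node: str, gap_mask: np.ndarray | None = None) -> AncestralSequence:
        return map_sequence(self.marginal_posteriors(node), gap_mask,
                            model_tag=self.model_tag)

    @property
    def model_tag(self) -> str:
        return f"{self.model.model_kind}+G{self.model.ncat}"

    def to_json(self, path: str | Path) -> None:
        tree = self.model.tree
        by_node = {}
        for v in range(tree.n_nodes):
            if tree.parent[v] < 0:
                continue
            name = tree.tip_names.get(v) or next(
                (lbl for lbl, i in tree.labels.items() if i == v), f"node{v}")
            by_node[name] = float(self.branch_lengths[v])
        payload = {
            "model": self.model_tag,
            "loglik": self.loglik,
            "converged": self.converged,
            "partitions": [p.to_dict() for p in self.params],
            "branch_lengths": by_node,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def summary(self) -> str:
        lines = [
            "Ancestral Reconstruction Results",
            "=" * 46,
            f"model:            {self.model_tag}",
            f"partitions:       {len(self.params)}",
            f"log-likelihood:   {self.loglik:.4f}",
            f"tree length:      {self.tree_length:.4f} subst/site",
            f"converged:        {self.converged} ({self.n_rounds} rounds)",
            "-" * 46,
        ]
        for k, p in enumerate(self.params):
            lines.append(f"partition {k}: alpha={p.alpha:.4f} rate={p.rate:.4f}")
            if p.model.kind == "gtr":
                pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
                ex = [f"{p.model.exchangeabilities[i, j]:.3f}" for i, j in pairs]
                lines.append(f"  GTR rates (AC,AG,AT,CG,CT,GT): {', '.join(ex)}")
                lines.append("  pi (A,C,G,T): "
                             + ", ".join(f"{x:.3f}" for x in p.model.pi))
            elif p.model.kind == "codon_m0":
                i, j = CODON_STATES.index("AAA"), CODON_STATES.index("AAG")
                kappa = p.model.exchangeabilities[i, j]
                omega = AncestralReconstruction._current_omega(p.model)
                lines.append(f"  kappa={kappa:.3f} omega={omega:.3f} (F1x4)")
        return "\n".join(lines)


def ensemble_reconstruct(
    msa: MSA,
    tree,
    specs: list[dict],
    node: str,
    init_lengths: np.ndarray | None = None,
) -> tuple[list[AncestralSequence], np.ndarray]:
    """Reconstruct one ancestor under several model specs.

    Each spec is a dict with keys ``model`` (gtr/jtt/codon_m0) and optionally
    ``partition``, ``ncat``, ``scale_only``, ``fixed_alpha``.  Returns the MAP
    sequences and a protein-level agreement matrix (fraction of comparable
    residue columns with identical states).
    """
    if not specs:
        raise InputError("at least one model spec required")
    seqs: list[AncestralSequence] = []
    lengths = init_lengths
    for sp in specs:
        kind = sp.get("model", "gtr")
        ar = AncestralReconstruction(
            msa, tree, model=kind,
            partition=sp.get("partition", "12_3") if kind == "gtr" else None,
            ncat=sp.get("ncat", 5),
        )
        res = ar.fit(
            scale_only=sp.get("scale_only", kind != "gtr" and lengths is not None),
            fixed_alpha=sp.get("fixed_alpha"),
            init_lengths=lengths if kind != "gtr" else init_lengths,
            max_rounds=sp.get("max_rounds", 30),
        )
        if kind == "gtr" and lengths is None:
            lengths = res.branch_lengths  # seed later (slower) models
        seqs.append(res.map_sequence(node))
    return seqs, agreement_matrix(seqs)


def protein_states(anc: AncestralSequence) -> str:
    """Reconstruction expressed at residue granularity for cross-model comparison."""
    if anc.level == "protein":
        return anc.sequence
    if anc.level == "codon":
        return translate("".join(anc.states))
    return translate(anc.sequence)


def agreement_matrix(seqs: list[AncestralSequence]) -> np.ndarray:
    prots = [protein_states(s) for s in seqs]
    n = len(prots)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            pairs = [(a, b) for a, b in zip(prots[i], prots[j])
                     if a not in "-X" and b not in "-X"]
            frac = (sum(a == b for a, b in pairs) / len(pairs)) if pairs else np.nan
            mat[i, j] = mat[j, i] = frac
    return mat
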