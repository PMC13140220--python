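"""Pruning engine and model fitting against exact oracles."""

import warnings

import numpy as np
import pytest

from bblkit.alignment import MSA
from bblkit.asr import AncestralReconstruction
from bblkit.likelihood import PartitionEngine, encode_sequences
from bblkit.substmodels import (
    codon_m0,
    discrete_gamma,
    gtr,
    jc69,
    jtt,
)
from bblkit.trees import TreeIndex, read_tree

from ._oracles import brute_force_loglik

NUC = ("A", "C", "G", "T")


def make_engine(newick, seqs, states=NUC):
    tree = TreeIndex.from_dendropy(read_tree(newick))
    codes = encode_sequences(seqs, tree, states)
    return tree, PartitionEngine(tree, codes, len(states))


class TestSubstitutionModels:
    @pytest.mark.parametrize("model", [jc69(), gtr(rates=[1, 3, 0.5, 0.8, 3, 1],
                                                   pi=[0.3, 0.2, 0.2, 0.3]),
                                       jtt(), codon_m0(kappa=2.5, omega=0.1)])
    def test_generator_invariants(self, model):
        q = model.rate_matrix
        assert np.allclose(q.sum(axis=1), 0, atol=1e-12)
        assert np.isclose(-(model.pi * np.diag(q)).sum(), 1.0)  # mean rate 1
        # detailed balance (reversibility)
        flux = model.pi[:, None] * q
        assert np.allclose(flux, flux.T, atol=1e-12)

    @pytest.mark.parametrize("t", [0.0, 0.01, 0.5, 5.0])
    def test_transition_matrix_is_stochastic(self, t):
        p = gtr(rates=[1, 4, 1, 1, 4, 1], pi=[0.3, 0.2, 0.2, 0.3]).transition_matrix(t)
        assert np.allclose(p.sum(axis=1), 1)
        assert (p >= 0).all()

    def test_chapman_kolmogorov(self):
        m = jtt()
        assert np.allclose(m.transition_matrix(0.3) @ m.transition_matrix(0.2),
                           m.transition_matrix(0.5), atol=1e-10)

    def test_discrete_gamma_mean_one(self):
        for alpha in (0.2, 1.0, 7.0):
            rates = discrete_gamma(alpha, 5)
            assert np.isclose(rates.mean(), 1.0, atol=1e-6)
            assert (np.diff(rates) > 0).all()

    def test_codon_space_excludes_stops(self):
        m = codon_m0()
        assert m.nstates == 61
        assert not {"TAA", "TAG", "TGA"} & set(m.states)


class TestPruning:
    def test_identical_tips_zero_length_limit(self):
        _, eng = make_engine("(a:0.0000001,b:0.0000001)r;", {"a": "A", "b": "A"})
        lnl = eng.loglik(jc69(), np.array([1e-7, 1e-7, 0.0]), np.ones(1), np.ones(1))
        assert lnl == pytest.approx(np.log(0.25), abs=1e-6)

    @pytest.mark.parametrize("newick,ntips", [
        ("((a:0.1,b:0.2)x:0.15,(c:0.3,d:0.05)y:0.12)r;", 4),
        ("(((a:0.1,b:0.2)x:0.1,c:0.25)y:0.05,(d:0.3,e:0.02)z:0.2)r;", 5),
    ])
    def test_matches_exhaustive_enumeration(self, newick, ntips):
        rng = np.random.default_rng(ntips)
        names = "abcde"[:ntips]
        seqs = {n: "".join(rng.choice(list("ACGT"), 25)) for n in names}
        tree, eng = make_engine(newick, seqs)
        model = gtr(rates=[1, 3, 1, 1, 3, 1], pi=[0.3, 0.2, 0.2, 0.3])
        lnl = eng.loglik(model, tree.lengths, np.ones(1), np.ones(1))
        assert abs(lnl - brute_force_loglik(model, tree, seqs)) < 1e-8

    def test_gaps_and_n_are_missing_data(self):
        # a fully missing tip cannot change the likelihood
        seqs3 = {"a": "ACGT", "b": "AGGT", "c": "NNNN"}
        tree3, eng3 = make_engine("((a:0.1,b:0.2)x:0.1,c:0.3)r;", seqs3)
        lnl3 = eng3.loglik(jc69(), tree3.lengths, np.ones(1), np.ones(1))
        seqs2 = {"a": "ACGT", "b": "AGGT"}
        # same two-taxon likelihood: a-b path length 0.3
        tree2, eng2 = make_engine("(a:0.1,b:0.2)r;", seqs2)
        lnl2 = eng2.loglik(jc69(), tree2.lengths, np.ones(1), np.ones(1))
        assert lnl3 == pytest.approx(lnl2, abs=1e-9)

    def test_rerooting_invariance(self):
        rng = np.random.default_rng(5)
        seqs = {n: "".join(rng.choice(list("ACGT"), 30)) for n in "abcd"}
        model = gtr(rates=[1, 2, 1, 1, 2, 1], pi=[0.28, 0.22, 0.22, 0.28])
        # same unrooted tree, two rootings along different branches
        t1, e1 = make_engine("((a:0.1,b:0.2)x:0.07,(c:0.3,d:0.05)y:0.08)r;", seqs)
        t2, e2 = make_engine("(a:0.05,(b:0.2,(c:0.3,d:0.05)y:0.15)x:0.05)r;", seqs)
        lnl1 = e1.loglik(model, t1.lengths, np.ones(1), np.ones(1))
        lnl2 = e2.loglik(model, t2.lengths, np.ones(1), np.ones(1))
        assert lnl1 == pytest.approx(lnl2, abs=1e-9)

    def test_pattern_compression_preserves_likelihood(self):
        rng = np.random.default_rng(3)
        base = {n: "".join(rng.choice(list("ACGT"), 10)) for n in "abcd"}
        doubled = {n: s + s for n, s in base.items()}
        tree, e1 = make_engine("((a:0.1,b:0.2)x:0.1,(c:0.2,d:0.1)y:0.1)r;", base)
        _, e2 = make_engine("((a:0.1,b:0.2)x:0.1,(c:0.2,d:0.1)y:0.1)r;", doubled)
        l1 = e1.loglik(jc69(), tree.lengths, np.ones(1), np.ones(1))
        l2 = e2.loglik(jc69(), tree.lengths, np.ones(1), np.ones(1))
        assert l2 == pytest.approx(2 * l1, abs=1e-9)


class TestFitting:
    def test_two_taxon_jc_closed_form(self):
        # 20 sites, 4 differences: t_hat = -(3/4) ln(1 - (4/3) p_hat)
        msa = MSA([("a", "ACGTACGTACGTACGTACGT"), ("b", "ACGTACGTACGTACGTTTTA")])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ar = AncestralReconstruction(msa, "(a:0.1,b:0.1)r;", model="gtr",
                                         partition="none", ncat=1)
            from scipy.optimize import minimize_scalar

            eng = ar.engines[0]

            def nll(t):
                lengths = ar.tree.lengths.copy()
                for v in range(ar.tree.n_nodes):
                    if ar.tree.parent[v] >= 0:
                        lengths[v] = t / 2
                return -eng.loglik(jc69(), lengths, np.ones(1), np.ones(1))

            res = minimize_scalar(nll, bounds=(1e-6, 5), method="bounded",
                                  options={"xatol": 1e-10})
        closed = -0.75 * np.log(1 - 4 / 3 * 0.2)
        assert res.x == pytest.approx(closed, abs=1e-6)

    def test_jc_simulation_recovers_near_equal_exchangeabilities(self):
        from bblkit.simulate import SimulationSpec, simulate_alignment

        spec = SimulationSpec(
            newick="((a:0.08,b:0.08)x:0.06,(c:0.08,d:0.08)y:0.06)r;",
            length_codons=1200,  # ~3.3 kb
            gtr_rates=(1, 1, 1, 1, 1, 1), pi=(0.25, 0.25, 0.25, 0.25),
            alpha=10.0, ncat=1, class_rates=(1.0, 1.0), seed=11)
        msa, _ = simulate_alignment(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ar = AncestralReconstruction(msa, spec.newick, model="gtr",
                                         partition="none", ncat=1)
            res = ar.fit(max_rounds=6)
        ex = res.params[0].model.exchangeabilities
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        rates = np.array([ex[i, j] for i, j in pairs])
        assert rates.max() / rates.min() < 1.8  # near-equal under JC truth
        assert np.allclose(res.params[0].model.pi, 0.25, atol=0.03)

    def test_fixed_alpha_respected(self, small_study):
        spec, msa, _ = small_study
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ar = AncestralReconstruction(msa, spec.newick, model="gtr", ncat=4)
            res = ar.fit(fixed_alpha=0.77, max_rounds=1)
        assert all(p.alpha == 0.77 for p in res.params)

    def test_lnl_improves_over_init(self, small_study):
        spec, msa, _ = small_study
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ar = AncestralReconstruction(msa, spec.newick, model="gtr", ncat=4)
            init = ar._loglik(ar._init_params(), ar.tree.lengths)
            res = ar.fit(max_rounds=2)
        assert res.loglik > init

    def test_branch_length_error_shrinks_with_length(self):
        from bblkit.simulate import SimulationSpec, simulate_alignment

        newick = "((a:0.1,b:0.05)x:0.08,(c:0.12,d:0.03)y:0.06)r;"
        true = {"a": 0.1, "b": 0.05, "c": 0.12, "d": 0.03, "x": 0.08, "y": 0.06}
        errs = []
        for n_codons in (100, 1000):
            spec = SimulationSpec(newick=newick, length_codons=n_codons,
                                  gtr_rates=(1, 1, 1, 1, 1, 1),
                                  pi=(0.25,) * 4, alpha=5.0, ncat=1,
                                  class_rates=(1.0, 1.0), seed=23)
            msa, _ = simulate_alignment(spec)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ar = AncestralReconstruction(msa, newick, model="gtr",
                                             partition="none", ncat=1)
                res = ar.fit(max_rounds=5)
            fitted = {lbl: res.branch_lengths[i] for lbl, i in ar.tree.labels.items()
                      if lbl in true}
            errs.append(np.mean([abs(fitted[k] - true[k]) for k in true]))
        assert errs[1] < errs[0]
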