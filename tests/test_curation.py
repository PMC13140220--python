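"""Curation rules: parsimony gap placement, posterior thresholding, resolution."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bblkit.alignment import MSA
from bblkit.asr import AncestralSequence, SitePosterior
from bblkit.curation import (
    AmbiguityRecord,
    _sankoff_state_sets,
    assemble_ancestor,
    build_ambiguity_records,
    flag_ambiguous,
    indel_blocks,
    infer_ancestral_gaps,
    replay,
    resolve_ambiguity,
)
from bblkit.errors import InputError, UnresolvedAmbiguityError
from bblkit.trees import TreeIndex, read_tree

from ._oracles import brute_force_mpr_states

NUC = ("A", "C", "G", "T")


def posterior_from(rows):
    probs = np.asarray(rows, dtype=float)
    return SitePosterior(node="n", states=NUC, probs=probs, level="nucleotide")


class TestIndelBlocks:
    def test_blocks_are_maximal_and_pattern_homogeneous(self):
        msa = MSA([("a", "ACG---TT--A"), ("b", "ACGGGGTT--A"), ("c", "ACGGGGTTCCA")])
        blocks = indel_blocks(msa)
        assert [b.columns for b in blocks] == [[3, 4, 5], [8, 9]]
        assert blocks[0].presence == {"a": 0, "b": 1, "c": 1}
        assert blocks[1].presence == {"a": 0, "b": 0, "c": 1}

    def test_adjacent_blocks_with_different_patterns_split(self):
        msa = MSA([("a", "A--G"), ("b", "A-GG"), ("c", "AGGG")])
        blocks = indel_blocks(msa)
        assert [b.columns for b in blocks] == [[1], [2]]


class TestFitchParsimony:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_min_change_on_6_taxa(self, seed):
        newick = "(((a:1,b:1)x:1,(c:1,d:1)y:1)w:1,(e:1,f:1)z:1)r;"
        tree = TreeIndex.from_dendropy(read_tree(newick))
        rng = np.random.default_rng(seed)
        tip_states = {t: int(rng.integers(2)) for t in tree.tip_labels}
        sets = _sankoff_state_sets(tree, tip_states)
        for label in ("x", "y", "z", "w", "r"):
            node = tree.node(label)
            assert sets[node] == brute_force_mpr_states(tree, tip_states, node)

    def test_private_gap_block_is_ancestrally_absent(self, small_study):
        # the A4x-private insertion must be absent at every named ancestor
        spec, msa, truth = small_study
        tree = TreeIndex.from_dendropy(read_tree(spec.newick))
        cols = truth.insertion_columns["A4x"]
        for node in ("HCa", "Ca", "A1A2a"):
            mask, _ = infer_ancestral_gaps(msa, tree, node)
            assert mask[cols].all()

    def test_clade_insertion_present_at_ca_absent_at_hca(self, small_study):
        spec, msa, truth = small_study
        tree = TreeIndex.from_dendropy(read_tree(spec.newick))
        cols = truth.insertion_columns["Ca"]
        for node, expected_gap in (("Ca", False), ("A1A2a", False), ("HCa", True)):
            mask, _ = infer_ancestral_gaps(msa, tree, node)
            assert mask[cols].all() == expected_gap or (~mask[cols]).all() == (not expected_gap)

    def test_equal_cost_tie_resolves_to_absent_with_warning(self):
        # two sister pairs, one present and one absent each: root is ambiguous
        newick = "((a:1,b:1)x:1,(c:1,d:1)y:1)r;"
        msa = MSA([("a", "AAA"), ("b", "---"), ("c", "AAA"), ("d", "---")])
        tree = TreeIndex.from_dendropy(read_tree(newick))
        with pytest.warns(UserWarning, match="equal-cost"):
            mask, blocks = infer_ancestral_gaps(msa, tree, "r")
        assert mask.all() and blocks[0].ambiguous


class TestFlagAmbiguous:
    def test_threshold_semantics(self):
        post = posterior_from([[0.59, 0.41, 0, 0], [0.95, 0.05, 0, 0],
                               [0.25, 0.25, 0.25, 0.25], [0.6, 0.4, 0, 0]])
        flagged = flag_ambiguous(post, 0.6)
        assert flagged == [0, 2]  # equality (0.60) keeps the site

    def test_bad_threshold_rejected(self):
        post = posterior_from([[1, 0, 0, 0]])
        with pytest.raises(InputError):
            flag_ambiguous(post, 0.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(min_value=0.3, max_value=0.7),
           st.floats(min_value=0.05, max_value=0.3))
    def test_raising_threshold_never_unflags(self, t_low, delta):
        rng = np.random.default_rng(41)
        probs = rng.dirichlet(np.ones(4), size=30)
        post = posterior_from(probs)
        low = set(flag_ambiguous(post, t_low))
        high = set(flag_ambiguous(post, min(t_low + delta, 1.0)))
        assert low <= high


class TestResolveAmbiguity:
    def make_record(self, proposals):
        return AmbiguityRecord(codon_index=5, columns=[15, 16, 17], ref_label="6",
                               proposals=proposals, posteriors={"primary": 0.5})

    def test_consensus_when_all_models_agree(self):
        rec = self.make_record({"primary": "GCT", "alt": "GCT"})
        assert resolve_ambiguity(rec) == "GCT"
        assert rec.classification == "consensus"

    def test_silent_alternatives_keep_map(self):
        rec = self.make_record({"primary": "GCT", "alt": "GCC"})  # both Ala
        assert resolve_ambiguity(rec) == "GCT"
        assert rec.classification == "silent"

    def test_missense_uses_ranked_policy(self):
        rec = self.make_record({"primary": "GCT", "alt": "ACT"})  # Ala vs Thr
        decided = resolve_ambiguity(rec, policy={"6": ["T", "A"]})
        assert decided == "ACT"
        assert "policy" in rec.rationale

    def test_missense_without_policy_errors(self):
        rec = self.make_record({"primary": "GCT", "alt": "ACT"})
        with pytest.raises(UnresolvedAmbiguityError):
            resolve_ambiguity(rec)

    def test_map_fallback_mode(self):
        rec = self.make_record({"primary": "GCT", "alt": "ACT"})
        assert resolve_ambiguity(rec, on_missing_policy="map") == "GCT"

    def test_policy_without_matching_aa_keeps_map(self):
        rec = self.make_record({"primary": "GCT", "alt": "ACT"})
        decided = resolve_ambiguity(rec, policy={"6": ["W"]})
        assert decided == "GCT" and "MAP retained" in rec.rationale


class TestAssemble:
    def make_map_seq(self, states, node="anc"):
        n = len(states)
        return AncestralSequence(node=node, states=list(states),
                                 max_posterior=np.ones(n), mean_posterior=1.0,
                                 model="gtr+G5", level="nucleotide")

    def test_identity_without_ambiguity_or_gaps(self):
        anc = self.make_map_seq("ATGGCT")
        cur = assemble_ancestor(anc, np.zeros(6, bool), [])
        assert cur.coding_sequence == "ATGGCT" and cur.protein == "MA"

    def test_gap_columns_removed_in_codon_blocks(self):
        anc = self.make_map_seq("ATGGCTAAA")
        mask = np.array([False] * 3 + [True] * 3 + [False] * 3)
        cur = assemble_ancestor(anc, mask, [])
        assert cur.coding_sequence == "ATGAAA"

    def test_resolutions_applied_and_replayable(self):
        anc = self.make_map_seq("ATGGCTAAA")
        rec = AmbiguityRecord(codon_index=1, columns=[3, 4, 5], ref_label="2",
                              proposals={"primary": "GCT", "alt": "ACT"},
                              posteriors={"primary": 0.55})
        resolve_ambiguity(rec, policy={"2": ["T"]})
        cur = assemble_ancestor(anc, np.zeros(9, bool), [rec])
        assert cur.coding_sequence == "ATGACTAAA"
        assert replay(anc, cur) == cur.coding_sequence

    def test_unresolved_record_rejected(self):
        anc = self.make_map_seq("ATGGCT")
        rec = AmbiguityRecord(codon_index=0, columns=[0, 1, 2], ref_label="1",
                              proposals={"primary": "ATG"}, posteriors={})
        with pytest.raises(UnresolvedAmbiguityError):
            assemble_ancestor(anc, np.zeros(6, bool), [rec])

    def test_audit_table_lists_every_decision(self, curated_small):
        for node, nr in curated_small.nodes.items():
            table = nr.curated.audit_table()
            assert len(table) == len(nr.curated.records)
            if len(table):
                assert table["decision"].ne("").all()

    def test_curated_ancestors_replayable(self, curated_small):
        for nr in curated_small.nodes.values():
            assert replay(nr.map_seq, nr.curated) == nr.curated.coding_sequence

    def test_hca_shorter_than_ca_by_insertion(self, curated_small, small_study):
        spec, _, _ = small_study
        ins = [e for e in spec.insertions if e.node == "Ca"][0]
        hca = curated_small.nodes["HCa"].curated
        ca = curated_small.nodes["Ca"].curated
        assert len(ca.protein) - len(hca.protein) == ins.length_codons


class TestAmbiguityRecords:
    def test_records_built_per_flagged_codon(self):
        probs = np.full((6, 4), [0.7, 0.1, 0.1, 0.1])
        probs[4] = [0.4, 0.3, 0.2, 0.1]  # flagged column in codon 1
        post = posterior_from(probs)
        anc_states = ["A"] * 6
        records = build_ambiguity_records(post, anc_states, [], threshold=0.6)
        assert len(records) == 1
        rec = records[0]
        assert rec.codon_index == 1 and rec.columns == [3, 4, 5]
        assert rec.proposals["primary"] == "AAA"
        assert rec.proposals["second_best"] == "ACA"  # runner-up at column 4
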