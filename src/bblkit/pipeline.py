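"""End-to-end orchestration: fit, reconstruct, curate, and validate ancestors.

Glues the likelihood engine, the curation rules and the synthetic-data
generator into the standard reconstruction chain: fit a partitioned GTR+Gamma
model on the fixed topology, compute empirical-Bayes marginal posteriors at
the requested internal nodes, place ancestral gaps by parsimony, flag and
resolve low-confidence codons (optionally against a multi-model ensemble), and
assemble curated coding sequences with a full audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import MSA
from .asr import AncestralReconstruction, ASRResults, AncestralSequence, map_sequence
from .curation import (
    CuratedAncestor,
    assemble_ancestor,
    build_ambiguity_records,
    infer_ancestral_gaps,
    resolve_ambiguity,
)
from .trees import TreeIndex, read_tree


@dataclass
class NodeReconstruction:
    """Everything computed for one ancestor."""

    node: str
    map_seq: AncestralSequence
    curated: CuratedAncestor
    mean_posterior: float
    gap_blocks: list = field(default_factory=list)
    ensemble: list[AncestralSequence] = field(default_factory=list)


@dataclass
class PipelineResult:
    results: ASRResults
    nodes: dict[str, NodeReconstruction]


def reconstruct_and_curate(
    msa: MSA,
    tree,
    nodes: list[str],
    ensemble_models: tuple[str, ...] = (),
    threshold: float = 0.6,
    policy: dict | None = None,
    on_missing_policy: str = "map",
    ncat: int = 5,
    max_rounds: int = 30,
    refmap=None,
) -> PipelineResult:
    """Run the full reconstruction chain for the named internal nodes.

    ``ensemble_models`` may add "jtt" and/or "codon_m0" reconstructions (fitted
    with a single tree-scale on the GTR branch lengths) whose states feed the
    multi-model consensus step of the curation rules.
    """
    if isinstance(tree, (str,)):
        tree = read_tree(tree)
    if not isinstance(tree, TreeIndex):
        tree = TreeIndex.from_dendropy(tree)
    primary = AncestralReconstruction(msa, tree, model="gtr", partition="12_3", ncat=ncat)
    res = primary.fit(max_rounds=max_rounds)

    extra_results: list[ASRResults] = []
    for kind in ensemble_models:
        alt = AncestralReconstruction(msa, tree, model=kind, partition=None, ncat=ncat)
        extra_results.append(alt.fit(scale_only=True,
                                     init_lengths=res.branch_lengths,
                                     max_rounds=max_rounds))

    out: dict[str, NodeReconstruction] = {}
    for node in nodes:
        gap_mask, blocks = infer_ancestral_gaps(msa, tree, node)
        posterior = res.marginal_posteriors(node)
        map_seq = map_sequence(posterior, gap_mask, model_tag=res.model_tag)
        ensemble = [r.map_sequence(node) for r in extra_results]
        records = build_ambiguity_records(posterior, map_seq.states, ensemble,
                                          threshold=threshold, refmap=refmap)
        for rec in records:
            resolve_ambiguity(rec, policy=policy, on_missing_policy=on_missing_policy)
        curated = assemble_ancestor(map_seq, gap_mask, records, provenance={
            "model": res.model_tag,
            "ensemble": [r.model_tag for r in extra_results],
            "threshold": threshold,
            "policy": "user" if policy else on_missing_policy,
        })
        nongap = ~np.asarray(gap_mask, dtype=bool)
        mean_pp = float(posterior.max_posterior[nongap].mean())
        out[node] = NodeReconstruction(node=node, map_seq=map_seq, curated=curated,
                                       mean_posterior=mean_pp, gap_blocks=blocks,
                                       ensemble=ensemble)
    return PipelineResult(results=res, nodes=out)
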