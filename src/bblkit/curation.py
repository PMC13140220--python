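"""Rule-based curation of reconstructed ancestors.

Likelihood reconstruction places a state in every alignment column, including
columns that are gaps in most sequences; curation decides (i) which columns are
ancestrally absent (parsimony over indel presence/absence characters), (ii)
which retained states are too uncertain (maximum posterior below a threshold,
0.6 by default), and (iii) how uncertain codons are resolved: multi-model
consensus first, silent alternatives by MAP, and remaining missense
ambiguities by an explicit hypothesis-facilitating policy (a ranked amino-acid
preference list per reference position).  Every decision is logged so a curated
sequence is replayable bit-exactly from its audit trail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import MSA, translate, translate_codon
from .asr import AncestralSequence, SitePosterior
from .errors import InputError, UnresolvedAmbiguityError
from .trees import TreeIndex, check_tip_match

PRESENT, ABSENT = 1, 0


@dataclass
class IndelCharacter:
    """One presence/absence character: a maximal column block with a shared gap pattern."""

    event_id: int
    columns: list[int]
    presence: dict[str, int]  # tip -> 1 (residues present) / 0 (all-gap)
    state_at_node: int = PRESENT
    ambiguous: bool = False


def indel_blocks(msa: MSA) -> list[IndelCharacter]:
    """Partition gap-containing columns into maximal runs with identical
    tip presence/absence patterns."""
    patterns = []
    for col in range(msa.length):
        pat = tuple(0 if seq[col] == "-" else 1 for _, seq in msa.records)
        patterns.append(pat)
    blocks: list[IndelCharacter] = []
    current_cols: list[int] = []
    current_pat: tuple[int, ...] | None = None
    eid = 0
    for col, pat in enumerate(patterns):
        if 0 not in pat:
            if current_cols:
                blocks.append(IndelCharacter(eid, current_cols,
                                             dict(zip(msa.ids, current_pat))))
                eid += 1
                current_cols, current_pat = [], None
            continue
        if pat == current_pat and current_cols and col == current_cols[-1] + 1:
            current_cols.append(col)
        else:
            if current_cols:
                blocks.append(IndelCharacter(eid, current_cols,
                                             dict(zip(msa.ids, current_pat))))
                eid += 1
            current_cols, current_pat = [col], pat
    if current_cols:
        blocks.append(IndelCharacter(eid, current_cols, dict(zip(msa.ids, current_pat))))
    return blocks


def _sankoff_state_sets(tree: TreeIndex, tip_states: dict[str, int]) -> dict[int, set[int]]:
    """Most-parsimonious state sets per node for a binary character
    (unit change cost), via inside-outside dynamic programming."""
    big = 10**9
    n = tree.n_nodes
    inside = np.zeros((n, 2))
    for u in tree.postorder:
        kids = tree.children[u]
        if not kids:
            s = tip_states[tree.tip_names[u]]
            inside[u] = [0 if s == k else big for k in range(2)]
            continue
        for s in range(2):
            inside[u, s] = sum(
                min(inside[v, t] + (0 if s == t else 1) for t in range(2)) for v in kids
            )
    outside = np.zeros((n, 2))
    for u in tree.preorder():
        kids = tree.children[u]
        for v in kids:
            sib = np.zeros(2)
            for s in range(2):
                sib[s] = sum(
                    min(inside[w, t] + (0 if s == t else 1) for t in range(2))
                    for w in kids if w != v
                )
            for t in range(2):
                outside[v, t] = min(
                    outside[u, s] + sib[s] + (0 if s == t else 1) for s in range(2)
                )
    sets: dict[int, set[int]] = {}
    for u in range(n):
        total = inside[u] + outside[u]
        best = total.min()
        sets[u] = {s for s in range(2) if total[s] == best}
    return sets


def infer_ancestral_gaps(
    msa: MSA, tree: TreeIndex, node: str
) -> tuple[np.ndarray, list[IndelCharacter]]:
    """Parsimony gap placement for one ancestor.

    Returns a boolean mask (True = column is an ancestral gap at ``node``) and
    the per-block report.  Equal-cost ties at the query node resolve to absent
    (the shorter ancestor) with a warning; blocks private to a single tip are
    ancestrally absent by construction.
    """
    check_tip_match(tree, msa.ids)
    idx = tree.node(node)
    blocks = indel_blocks(msa)
    mask = np.zeros(msa.length, dtype=bool)
    for blk in blocks:
        tip_states = {t: blk.presence[t] for t in tree.tip_labels}
        # mixed columns inside a block cannot happen by construction; tips with
        # partial gaps across the block were already classed per column
        sets = _sankoff_state_sets(tree, tip_states)
        states = sets[idx]
        if len(states) == 2:
            blk.ambiguous = True
            blk.state_at_node = ABSENT
            warnings.warn(
                f"indel block {blk.event_id} (cols {blk.columns[0]}-{blk.columns[-1]}) "
                f"has equal-cost states at {node}; resolved to absent", stacklevel=2)
        else:
            blk.state_at_node = states.pop()
        if blk.state_at_node == ABSENT:
            mask[blk.columns] = True
    return mask, blocks


def flag_ambiguous(posterior: SitePosterior, threshold: float = 0.6) -> list[int]:
    """Columns whose maximum posterior is below ``threshold``.

    A state is kept iff its posterior is >= threshold (equality keeps).
    """
    if not 0 < threshold <= 1:
        raise InputError("threshold must lie in (0, 1]")
    mx = posterior.probs.max(axis=1)
    return [int(c) for c in np.nonzero(mx < threshold)[0]]


@dataclass
class AmbiguityRecord:
    """One low-confidence codon with the per-model proposals and its resolution."""

    codon_index: int
    columns: list[int]
    ref_label: str
    proposals: dict[str, str]  # model tag -> codon
    posteriors: dict[str, float]
    classification: str = ""  # silent | missense | consensus
    decision: str = ""
    rationale: str = ""


def second_best_codon(posterior: SitePosterior, codon_index: int,
                      flagged_cols: list[int]) -> str:
    """Codon obtained by swapping flagged positions to their runner-up state."""
    codon = []
    for k in range(3):
        col = 3 * codon_index + k
        probs = posterior.probs[col]
        order = np.argsort(probs)[::-1]
        pick = order[1] if col in flagged_cols else order[0]
        codon.append(posterior.states[pick])
    return "".join(codon)


def build_ambiguity_records(
    posterior: SitePosterior,
    map_states: list[str],
    ensemble: list[AncestralSequence],
    threshold: float = 0.6,
    refmap=None,
) -> list[AmbiguityRecord]:
    """Group flagged nucleotide columns into codon-level ambiguity records.

    The primary reconstruction's MAP codon and its second-best alternative are
    always proposed; additional models contribute their codon where they are
    codon-resolved (nucleotide or codon level).
    """
    if posterior.level != "nucleotide":
        raise InputError("ambiguity records are built from the nucleotide posterior")
    flagged = flag_ambiguous(posterior, threshold)
    records: list[AmbiguityRecord] = []
    for cidx in sorted({c // 3 for c in flagged}):
        cols = [3 * cidx, 3 * cidx + 1, 3 * cidx + 2]
        map_codon = "".join(map_states[c] for c in cols)
        proposals = {"primary": map_codon,
                     "second_best": second_best_codon(posterior, cidx, flagged)}
        posteriors = {"primary": float(np.prod([posterior.probs[c].max() for c in cols]))}
        for anc in ensemble:
            if anc.level == "nucleotide":
                proposals[anc.model or "alt"] = "".join(anc.states[c] for c in cols)
            elif anc.level == "codon":
                proposals[anc.model or "alt"] = anc.states[cidx]
        label = refmap.label_of(cidx) if refmap is not None else str(cidx + 1)
        records.append(AmbiguityRecord(codon_index=cidx, columns=cols, ref_label=label,
                                       proposals=proposals, posteriors=posteriors))
    return records


def resolve_ambiguity(record: AmbiguityRecord, policy: dict | None = None,
                      on_missing_policy: str = "error") -> str:
    """Resolve one ambiguous codon; returns the decided codon and fills the record.

    Decision order: (1) all models agree -> consensus; (2) alternatives all
    synonymous -> keep the MAP codon ("silent"); (3) otherwise consult the
    hypothesis-facilitating policy: a mapping from reference label (or codon
    index) to a ranked list of preferred amino acids.  A missense ambiguity
    with no policy entry raises by default; ``on_missing_policy="map"`` keeps
    the MAP codon instead, with the fallback logged in the rationale.
    """
    proposals = {k: v for k, v in record.proposals.items() if "-" not in v and "N" not in v}
    if not proposals:
        raise UnresolvedAmbiguityError(f"no gap-free proposals at codon {record.codon_index}")
    distinct = set(proposals.values())
    map_codon = record.proposals.get("primary") or next(iter(proposals.values()))
    if len(distinct) == 1:
        record.classification = "consensus"
        record.decision = next(iter(distinct))
        record.rationale = "all models agree"
        return record.decision
    aas = {translate_codon(c) for c in distinct}
    if len(aas) == 1:
        record.classification = "silent"
        record.decision = map_codon
        record.rationale = "alternatives synonymous; MAP retained"
        return record.decision
    record.classification = "missense"
    key = record.ref_label if policy and record.ref_label in policy else record.codon_index
    prefs = (policy or {}).get(key)
    if not prefs:
        if on_missing_policy == "map":
            record.decision = map_codon
            record.rationale = "missense; no policy entry; MAP retained (flagged)"
            return record.decision
        raise UnresolvedAmbiguityError(
            f"missense ambiguity at codon {record.codon_index} (ref {record.ref_label}) "
            f"with no policy entry; proposals: {sorted(distinct)}")
    ranked = {aa: r for r, aa in enumerate(prefs)}
    scored = [(ranked[translate_codon(c)], c) for c in sorted(distinct)
              if translate_codon(c) in ranked]
    if scored:
        record.decision = min(scored)[1]
        record.rationale = (f"hypothesis-facilitating policy prefers "
                            f"{translate_codon(record.decision)}")
    else:
        record.decision = map_codon
        record.rationale = "policy lists no proposed amino acid; MAP retained"
    return record.decision


@dataclass
class CuratedAncestor:
    """Final curated coding sequence with full audit trail."""

    node: str
    coding_sequence: str
    protein: str
    gap_mask: np.ndarray
    records: list[AmbiguityRecord] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def audit_table(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "codon_index": r.codon_index,
                "ref_label": r.ref_label,
                "proposals": ";".join(f"{k}={v}" for k, v in sorted(r.proposals.items())),
                "map_posterior": r.posteriors.get("primary", np.nan),
                "classification": r.classification,
                "decision": r.decision,
                "rationale": r.rationale,
            })
        return pd.DataFrame(rows, columns=["codon_index", "ref_label", "proposals",
                                           "map_posterior", "classification",
                                           "decision", "rationale"])

    def write_audit(self, path: str | Path) -> None:
        self.audit_table().to_csv(path, sep="\t", index=False)


def assemble_ancestor(
    map_seq: AncestralSequence,
    gap_mask: np.ndarray,
    records: list[AmbiguityRecord],
    provenance: dict | None = None,
) -> CuratedAncestor:
    """Apply resolutions, drop ancestral-gap columns, translate, and log."""
    unresolved = [r.codon_index for r in records if not r.decision]
    if unresolved:
        raise UnresolvedAmbiguityError(f"unresolved codons: {unresolved}")
    states = list(map_seq.states)
    gap_mask = np.asarray(gap_mask, dtype=bool)
    if gap_mask.shape != (len(states),):
        raise InputError("gap mask length mismatch")
    for r in records:
        for col, base in zip(r.columns, r.decision):
            if not gap_mask[col]:
                states[col] = base
    cds = "".join(s for s, g in zip(states, gap_mask) if not g)
    if len(cds) % 3 != 0:
        raise InputError(
            f"curated sequence length {len(cds)} not a multiple of 3; "
            "gap mask does not respect codon boundaries")
    return CuratedAncestor(
        node=map_seq.node,
        coding_sequence=cds,
        protein=translate(cds),
        gap_mask=gap_mask,
        records=records,
        provenance=provenance or {},
    )


def replay(map_seq: AncestralSequence, curated: CuratedAncestor) -> str:
    """Rebuild the curated coding sequence from the MAP states plus the audit
    trail; used to verify replayability."""
    return assemble_ancestor(map_seq, curated.gap_mask, curated.records).coding_sequence
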