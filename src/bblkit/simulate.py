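"""Synthetic study generator: alignments with known ancestors, and noisy assay tables.

The generator emulates the structure of a curated oxidocyclase dataset: coding
sequences evolved root-to-tips on a rooted tree under a partitioned nucleotide
model (codon positions 1+2 vs 3, discrete-gamma site rates), scripted in-frame
insertions (a clade-defining one inherited by every descendant of its branch,
plus optional tip-private ones), tip-specific frameshift pseudogenization
re-padded with ``N``, and triplicate assay measurements with Gaussian noise
around true specific activities and product fractions.  Indels are scripted
rather than drawn from a stochastic indel process so the recorded truth is
exact.

All randomness flows from one seed; independent streams are spawned per
component (sequence evolution, insertion content, assay noise) so changing one
does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import MSA, Partition, pad_frameshift
from .errors import InputError
from .regions import RegionAnnotation
from .substmodels import SubstitutionModel, codon_translation, discrete_gamma, gtr
from .trees import TreeIndex, read_tree

_STOPS = ("TAA", "TAG", "TGA")
_NT = np.array(list("ACGT"))


@dataclass
class InsertionEvent:
    """A scripted in-frame insertion on the branch above ``node`` (an internal
    label or a tip name); every tip below inherits it."""

    node: str
    after_codon: int  # 0-based codon index in root coordinates; insert after it
    length_codons: int = 4


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic dataset."""

    newick: str
    length_codons: int
    gtr_rates: tuple[float, ...] = (1.0, 4.0, 1.0, 1.0, 4.0, 1.0)
    pi: tuple[float, ...] = (0.31, 0.19, 0.22, 0.28)
    alpha: float = 1.0
    ncat: int = 5
    class_rates: tuple[float, float] = (0.55, 1.9)  # codon pos 1+2 vs pos 3
    insertions: list[InsertionEvent] = field(default_factory=list)
    pseudogene_tips: dict[str, list[int]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_codons <= 0:
            raise InputError("length_codons must be positive")
        positions = [ev.after_codon for ev in self.insertions]
        if len(positions) != len(set(positions)):
            raise InputError("insertion events must use distinct positions")


@dataclass
class SimTruth:
    """Everything the generator knows: sequences at every internal node, indel
    states, and the generating parameters."""

    node_sequences: dict[str, str]  # aligned nucleotide sequences, named nodes
    insertion_columns: dict[str, list[int]]  # event node -> alignment columns
    insertion_carriers: dict[str, set[str]]  # event node -> carrier tip names
    carrier_nodes: dict[str, set[str]]  # event node -> carrier internal labels
    pseudogene_edits: dict[str, list[int]]
    params: dict

    def has_insertion(self, event_node: str, node: str) -> bool:
        return (node in self.carrier_nodes.get(event_node, set())
                or node in self.insertion_carriers.get(event_node, set())
                or node == event_node)

    def gap_mask(self, node: str) -> np.ndarray:
        seq = self.node_sequences[node]
        return np.array([c == "-" for c in seq], dtype=bool)


def _draw_codons(rng: np.random.Generator, n_codons: int, pi: np.ndarray) -> np.ndarray:
    """Draw nucleotide states codon-wise, rejecting stop codons."""
    out = np.empty(3 * n_codons, dtype=int)
    for c in range(n_codons):
        while True:
            states = rng.choice(4, size=3, p=pi)
            if "".join(_NT[states]) not in _STOPS:
                out[3 * c : 3 * c + 3] = states
                break
    return out


def _evolve_branch(parent: np.ndarray, t: float, site_rate: np.ndarray,
                   site_class: np.ndarray, models: list[SubstitutionModel],
                   rng: np.random.Generator) -> np.ndarray:
    child = parent.copy()
    for cls, model in enumerate(models):
        for rate in np.unique(site_rate[site_class == cls]):
            sel = (site_class == cls) & (site_rate == rate)
            p = model.transition_matrix(t * rate)
            cdf = p[parent[sel]].cumsum(axis=1)
            u = rng.random(sel.sum())
            child[sel] = (u[:, None] > cdf).sum(axis=1)
    return child


def _site_arrays(n: int, class_rates, cat_rates, rng) -> tuple[np.ndarray, np.ndarray]:
    site_class = np.array([0 if i % 3 in (0, 1) else 1 for i in range(n)])
    site_rate = cat_rates[rng.integers(len(cat_rates), size=n)].astype(float)
    site_rate *= np.where(site_class == 0, class_rates[0], class_rates[1])
    return site_class, site_rate


def simulate_alignment(spec: SimulationSpec) -> tuple[MSA, SimTruth]:
    """Evolve a codon-aware alignment with exact recorded truth."""
    ss = np.random.SeedSequence(spec.seed)
    rng_seq, rng_ins, _rng_assay = [np.random.default_rng(s) for s in ss.spawn(3)]
    tree = TreeIndex.from_dendropy(read_tree(spec.newick))
    for ev in spec.insertions:
        if ev.node not in tree.labels:
            raise InputError(f"insertion branch node {ev.node!r} not in tree")
        if not 0 <= ev.after_codon < spec.length_codons:
            raise InputError("insertion position outside sequence")
    for tip in spec.pseudogene_tips:
        if tree.labels.get(tip) not in tree.tip_names:
            raise InputError(f"pseudogene tip {tip!r} not a tree tip")

    nsites = 3 * spec.length_codons
    pi = np.array(spec.pi, dtype=float)
    models = [gtr(rates=np.array(spec.gtr_rates), pi=pi) for _ in range(2)]
    cat_rates = discrete_gamma(spec.alpha, spec.ncat)
    site_class, site_rate = _site_arrays(nsites, spec.class_rates, cat_rates, rng_seq)

    states: dict[int, np.ndarray] = {tree.root: _draw_codons(rng_seq, spec.length_codons, pi)}
    for u in tree.preorder():
        for v in tree.children[u]:
            states[v] = _evolve_branch(states[u], tree.lengths[v], site_rate,
                                       site_class, models, rng_seq)

    # scripted insertions: each block is simulated over its carrier subtree
    events = sorted(spec.insertions, key=lambda ev: ev.after_codon)
    ev_states: list[dict[int, np.ndarray]] = []
    ev_carriers: list[set[int]] = []
    for ev in events:
        n_nt = 3 * ev.length_codons
        icls, irate = _site_arrays(n_nt, spec.class_rates, cat_rates, rng_ins)
        origin = tree.node(ev.node)
        block_states = {origin: _draw_codons(rng_ins, ev.length_codons, pi)}
        carriers = {origin}
        for u in tree.preorder():
            if u not in carriers:
                continue
            for v in tree.children[u]:
                block_states[v] = _evolve_branch(block_states[u], tree.lengths[v],
                                                 irate, icls, models, rng_ins)
                carriers.add(v)
        ev_states.append(block_states)
        ev_carriers.append(carriers)

    def assemble(node: int) -> str:
        core = "".join(_NT[states[node]])
        pieces = []
        prev = 0
        for ev, bst, carr in zip(events, ev_states, ev_carriers):
            cut = 3 * (ev.after_codon + 1)
            pieces.append(core[prev:cut])
            if node in carr:
                pieces.append("".join(_NT[bst[node]]))
            else:
                pieces.append("-" * (3 * ev.length_codons))
            prev = cut
        pieces.append(core[prev:])
        return "".join(pieces)

    records = []
    pseudo_edits: dict[str, list[int]] = {}
    for tip in tree.tips:
        name = tree.tip_names[tip]
        seq = assemble(tip)
        if name in spec.pseudogene_tips:
            sites = sorted(spec.pseudogene_tips[name])
            for pos in sites:
                if pos >= len(seq) or seq[pos] == "-":
                    raise InputError(f"pseudogene edit at gap/out-of-range site {pos}")
            ungapped_positions = [p - seq[:p].count("-") for p in sites]
            degapped = seq.replace("-", "")
            drop = set(ungapped_positions)
            deleted = "".join(ch for i, ch in enumerate(degapped) if i not in drop)
            repadded = pad_frameshift(deleted, ungapped_positions)
            it = iter(repadded)
            seq = "".join("-" if ch == "-" else next(it) for ch in seq)
            pseudo_edits[name] = sites
        records.append((name, seq))
    msa = MSA(records)

    node_sequences: dict[str, str] = {}
    carrier_nodes: dict[str, set[str]] = {ev.node: set() for ev in events}
    for label, idx in tree.labels.items():
        if idx in tree.tip_names:
            continue
        node_sequences[label] = assemble(idx)
        for ev, carr in zip(events, ev_carriers):
            if idx in carr:
                carrier_nodes[ev.node].add(label)
    # alignment columns of each block
    insertion_columns: dict[str, list[int]] = {}
    offset = 0
    for ev in events:
        cut = 3 * (ev.after_codon + 1) + offset
        insertion_columns[ev.node] = list(range(cut, cut + 3 * ev.length_codons))
        offset += 3 * ev.length_codons
    truth = SimTruth(
        node_sequences=node_sequences,
        insertion_columns=insertion_columns,
        insertion_carriers={
            ev.node: {tree.tip_names[t] for t in tree.tips if t in carr}
            for ev, carr in zip(events, ev_carriers)},
        carrier_nodes=carrier_nodes,
        pseudogene_edits=pseudo_edits,
        params={"gtr_rates": list(spec.gtr_rates), "pi": list(spec.pi),
                "alpha": spec.alpha, "ncat": spec.ncat,
                "class_rates": list(spec.class_rates), "seed": spec.seed},
    )
    return msa, truth


# -- the packaged default study ---------------------------------------------------

#: Rooted study topology: two outgroup tips, a grade of three "clade H" tips,
#: and a recent radiation of three subclades (A: THCAS/CBCAS-like, B:
#: CBDAS-like, C) below the named ancestors HCa, Ca and A1A2a.
DEFAULT_NEWICK = (
    "((OutT1:0.05,OutT2:0.05)OUT:0.16,"
    "((HopBBL:0.07,(H2:0.045,H3:0.045)Hsub:0.03)CladeH:0.08,"
    "((((THCAS:0.018,A1y:0.018)A1:0.02,(CBCAS:0.018,A2y:0.018)A2:0.02)A1A2a:0.035,"
    "(A3x:0.04,A4x:0.04)A34:0.025)CladeA:0.04,"
    "((CBDAS:0.025,B1y:0.025)B1:0.035,(C1x:0.03,C2x:0.03)CladeC:0.03)BC:0.04)Ca:0.07)"
    "HCa:0.06)ROOT;"
)

#: The clade-defining insertion after reference codon 358 (residues 359-362 in
#: reference numbering) plus a private insertion in pseudogene A4x.
DEFAULT_INSERTIONS = [
    InsertionEvent(node="Ca", after_codon=357, length_codons=4),  # residues 359-362
    InsertionEvent(node="A4x", after_codon=150, length_codons=2),
]

DEFAULT_LENGTH_CODONS = 536  # core length; carriers of the main event reach 540

#: Tip-private frameshifts (1-nt deletions, N-padded) in two pseudogenes.
DEFAULT_PSEUDOGENES = {"A4x": [451], "B1y": [902]}


def default_study(seed: int = 0, length_codons: int = DEFAULT_LENGTH_CODONS) -> SimulationSpec:
    """The packaged synthetic study emulating the oxidocyclase dataset.

    At the canonical length (536 core codons) the clade-defining insertion sits
    at reference residues 359-362; shorter lengths keep the same event
    structure at proportional positions.
    """
    if length_codons == DEFAULT_LENGTH_CODONS:
        insertions = list(DEFAULT_INSERTIONS)
        pseudogenes = {k: list(v) for k, v in DEFAULT_PSEUDOGENES.items()}
    else:
        main_after = (2 * length_codons) // 3
        private_after = length_codons // 4
        insertions = [
            InsertionEvent(node="Ca", after_codon=main_after, length_codons=4),
            InsertionEvent(node="A4x", after_codon=private_after, length_codons=2),
        ]
        pseudogenes = {"A4x": [3 * (length_codons // 6) + 1],
                       "B1y": [3 * (length_codons // 2) + 2]}
    return SimulationSpec(
        newick=DEFAULT_NEWICK,
        length_codons=length_codons,
        insertions=insertions,
        pseudogene_tips=pseudogenes,
        seed=seed,
    )


_SBR_EXTRA = (116, 176, 212, 292, 343, 385, 404, 448, 484, 511)
_FBS_POSITIONS = (77, 99, 110, 114, 174, 210, 241, 268, 410, 475)


def default_region_table(n_residues: int = 540) -> RegionAnnotation:
    """Region annotation for the synthetic reference: the ASA-loop span
    354-380 plus fixed cavity-lining (SBR) and FAD-contact (FBS) positions."""
    regions = {}
    for pos in range(1, n_residues + 1):
        if 354 <= pos <= 380:
            regions[pos] = "ASA"
        elif pos in _SBR_EXTRA:
            regions[pos] = "SBR"
        elif pos in _FBS_POSITIONS:
            regions[pos] = "FBS"
        else:
            regions[pos] = "other"
    return RegionAnnotation(regions=regions, provenance="table-loaded")


def study_region_table(length_codons: int = DEFAULT_LENGTH_CODONS) -> RegionAnnotation:
    """Region annotation matched to :func:`default_study` at any length.

    The loop (ASA) span stays anchored on the clade-defining insertion exactly
    as at full scale (5 residues before it, 18 after), and the SBR/FBS
    positions keep their relative locations along the protein.
    """
    if length_codons == DEFAULT_LENGTH_CODONS:
        return default_region_table(540)
    ins = [e for e in default_study(length_codons=length_codons).insertions
           if e.node == "Ca"][0]
    n_res = length_codons + ins.length_codons
    ins_start = ins.after_codon + 2  # first inserted residue, reference numbering
    asa_lo = max(1, ins_start - 5)
    asa_hi = min(n_res, ins_start + ins.length_codons - 1 + 18)
    sbr = {max(1, min(n_res, round(p / 540 * n_res))) for p in _SBR_EXTRA}
    fbs = {max(1, min(n_res, round(p / 540 * n_res))) for p in _FBS_POSITIONS} - sbr
    regions = {}
    for pos in range(1, n_res + 1):
        if asa_lo <= pos <= asa_hi:
            regions[pos] = "ASA"
        elif pos in sbr:
            regions[pos] = "SBR"
        elif pos in fbs:
            regions[pos] = "FBS"
        else:
            regions[pos] = "other"
    return RegionAnnotation(regions=regions, provenance="table-loaded")


# -- assay simulation --------------------------------------------------------------

#: True specific activities (umol min^-1 g^-1) and product fractions of the
#: characterized enzyme panel under standardized conditions (30 ug/mL enzyme,
#: 75 uM CBGA, 30 min, pH 5, 30 C).
DEFAULT_ASSAY_TRUTH: dict[str, tuple[float, dict[str, float]]] = {
    "THCAS": (50.0, {"THCA": 0.95, "CBDA": 0.00, "CBCA": 0.05}),
    "A1A2a": (42.0, {"THCA": 0.87, "CBDA": 0.00, "CBCA": 0.13}),
    "Ca": (25.0, {"THCA": 0.60, "CBDA": 0.30, "CBCA": 0.10}),
    "CBDAS": (6.0, {"THCA": 0.03, "CBDA": 0.89, "CBCA": 0.08}),
}

_PRODUCT_COL = {"THCA": "thca_uM", "CBDA": "cbda_uM", "CBCA": "cbca_uM"}


def simulate_assays(
    truth: dict[str, tuple[float, dict[str, float]]] | None = None,
    noise_sd: float = 0.02,
    replicates: int = 3,
    time_min: float = 30.0,
    enzyme_ug_per_ml: float = 30.0,
    substrate_uM: float = 75.0,
    pH: float = 5.0,
    temp_C: float = 30.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Triplicate assay records with relative Gaussian noise, truncated at zero.

    ``noise_sd`` is the standard deviation as a fraction of each true product
    concentration; total product is capped at the substrate concentration.
    """
    if noise_sd < 0:
        raise InputError("noise sd must be non-negative")
    truth = DEFAULT_ASSAY_TRUTH if truth is None else truth
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
    rows = []
    for enzyme, (activity, fractions) in truth.items():
        if activity > 0 and abs(sum(fractions.values()) - 1.0) > 1e-9:
            raise InputError(f"{enzyme}: product fractions must sum to 1")
        total_true = activity * time_min * enzyme_ug_per_ml * 1e-3  # uM
        for rep in range(1, replicates + 1):
            concs = {}
            for product, frac in fractions.items():
                true_c = total_true * frac
                noisy = true_c + rng.normal(0.0, noise_sd * true_c) if noise_sd else true_c
                concs[product] = max(noisy, 0.0)
            tot = sum(concs.values())
            if tot > substrate_uM:
                concs = {p: c * substrate_uM / tot for p, c in concs.items()}
            row = {"enzyme": enzyme, "replicate": rep, "pH": pH, "temp_C": temp_C,
                   "time_min": time_min, "enzyme_ug_per_ml": enzyme_ug_per_ml,
                   "substrate_uM": substrate_uM}
            row.update({_PRODUCT_COL[p]: concs.get(p, 0.0) for p in _PRODUCT_COL})
            rows.append(row)
    return pd.DataFrame(rows)


#: Relative activity of the oldest active ancestor across pH, peaking at 5.5.
DEFAULT_PH_PROFILE = {3.0: 0.05, 4.0: 0.45, 4.5: 0.80, 5.0: 0.93, 5.5: 1.00,
                      6.0: 0.85, 7.0: 0.50, 8.0: 0.20}
#: Relative activity across temperature with a 45-50 C plateau.
DEFAULT_TEMP_PROFILE = {30.0: 0.55, 35.0: 0.70, 40.0: 0.85, 45.0: 0.97,
                        50.0: 1.00, 55.0: 0.65, 60.0: 0.25}


def simulate_profile(
    profile: dict[float, float],
    variable: str = "pH",
    enzyme: str = "Ca",
    peak_activity: float = 25.0,
    fractions: dict[str, float] | None = None,
    noise_sd: float = 0.02,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Assay records across a pH or temperature series with a known optimum."""
    fractions = fractions or DEFAULT_ASSAY_TRUTH["Ca"][1]
    frames = []
    for i, (level, rel) in enumerate(sorted(profile.items())):
        truth = {enzyme: (peak_activity * rel, fractions)}
        df = simulate_assays(truth, noise_sd=noise_sd, replicates=replicates,
                             seed=seed + 1000 * i)
        df[variable] = level
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# -- synthetic backbone/donor pairs for hybrid round-trip checks -------------------

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def simulate_protein_pair(
    seed: int,
    n_residues: int = 120,
    n_substitutions: int = 12,
    insertion: tuple[int, int] | None = (60, 4),
) -> dict:
    """A random backbone/donor CDS pair with known aligned differences.

    ``insertion=(anchor, k)`` puts a k-residue donor-only insertion after
    backbone residue ``anchor`` (1-based).  Returns aligned proteins, coding
    sequences, and the true substitution count.
    """
    rng = np.random.default_rng(seed)
    aa_codons = {aa: sorted(c for c, a in codon_translation().items() if a == aa)
                 for aa in _AA20}
    backbone_aa = [str(rng.choice(list(_AA20))) for _ in range(n_residues)]
    donor_aa = backbone_aa.copy()
    sub_pos = rng.choice(n_residues, size=n_substitutions, replace=False)
    for p in sub_pos:
        donor_aa[p] = str(rng.choice([a for a in _AA20 if a != backbone_aa[p]]))

    def cds_of(aas: list[str]) -> str:
        return "".join(str(rng.choice(aa_codons[a])) for a in aas)

    backbone_cds = cds_of(backbone_aa)
    donor_core_cds = cds_of(donor_aa)
    if insertion:
        anchor, k = insertion
        ins_aa = [str(rng.choice(list(_AA20))) for _ in range(k)]
        ins_cds = cds_of(ins_aa)
        aligned_backbone = "".join(backbone_aa[:anchor]) + "-" * k + "".join(backbone_aa[anchor:])
        aligned_donor = "".join(donor_aa[:anchor]) + "".join(ins_aa) + "".join(donor_aa[anchor:])
        donor_cds = donor_core_cds[: 3 * anchor] + ins_cds + donor_core_cds[3 * anchor :]
    else:
        aligned_backbone = "".join(backbone_aa)
        aligned_donor = "".join(donor_aa)
        donor_cds = donor_core_cds
    return {
        "backbone_cds": backbone_cds,
        "donor_cds": donor_cds,
        "backbone_aligned": aligned_backbone,
        "donor_aligned": aligned_donor,
        "n_substitutions": int(n_substitutions),
        "insertion": insertion,
    }


def partition_for(msa: MSA) -> Partition:
    return Partition.codon_positions(msa.length)


# -- reconstruction-recovery experiments --------------------------------------------


def recovery_experiment(
    spec: SimulationSpec,
    nodes: list[str] | None = None,
    threshold: float = 0.6,
    max_rounds: int = 10,
    calibration_bins: tuple[float, ...] = (0.0, 0.5, 0.7, 0.9, 1.0),
) -> dict:
    """Simulate, reconstruct, curate, and score recovery against the truth.

    Returns per-node site recovery (fraction of truth-residue, non-masked
    columns whose MAP state equals the true state), indel-state recovery over
    all scripted insertion events, and a posterior calibration table (binned
    MAP posterior vs empirical accuracy, pooled over nodes).
    """
    from .pipeline import reconstruct_and_curate  # local import avoids a cycle

    msa, truth = simulate_alignment(spec)
    if nodes is None:
        nodes = sorted(truth.node_sequences)
    result = reconstruct_and_curate(msa, read_tree(spec.newick), nodes,
                                    threshold=threshold, max_rounds=max_rounds)
    site_recovery: dict[str, float] = {}
    pooled_pp: list[np.ndarray] = []
    pooled_ok: list[np.ndarray] = []
    indel_total = indel_correct = 0
    for node in nodes:
        nr = result.nodes[node]
        true_seq = np.array(list(truth.node_sequences[node]))
        inferred = np.array(nr.map_seq.states)
        mask = np.asarray(nr.map_seq.gap_mask, dtype=bool)
        usable = (true_seq != "-") & ~mask
        ok = inferred[usable] == true_seq[usable]
        site_recovery[node] = float(ok.mean())
        pooled_pp.append(nr.map_seq.max_posterior[usable])
        pooled_ok.append(ok)
        # indel truth: is each scripted event's block present at this node?
        for ev_node, cols in truth.insertion_columns.items():
            truth_present = truth.node_sequences[node][cols[0]] != "-"
            inferred_present = not mask[cols[0]]
            indel_total += 1
            indel_correct += int(truth_present == inferred_present)
    pp = np.concatenate(pooled_pp)
    okv = np.concatenate(pooled_ok)
    calib = []
    edges = list(calibration_bins)
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (pp >= lo) & (pp <= hi if hi == 1.0 else pp < hi)
        calib.append({"bin": (lo, hi), "n": int(sel.sum()),
                      "accuracy": float(okv[sel].mean()) if sel.any() else float("nan"),
                      "mean_posterior": float(pp[sel].mean()) if sel.any() else float("nan")})
    return {
        "site_recovery": site_recovery,
        "indel_recovery": indel_correct / indel_total if indel_total else float("nan"),
        "calibration": calib,
        "mean_posterior": {n: result.nodes[n].mean_posterior for n in nodes},
        "overall_accuracy": float(okv.mean()),
        "overall_mean_posterior": float(pp.mean()),
        "result": result,
        "truth": truth,
        "msa": msa,
    }
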