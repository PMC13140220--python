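"""Backbone-donor sequence diffing and incremental hybrid enzyme design.

A hybrid is a backbone coding sequence in which selected residues are replaced
by their equivalents from an evolutionarily more recent donor.  Positions are
expressed in reference (THCAS) numbering via a :class:`ReferenceMap`, and each
substitution/indel carries its structural region label so hybrids can be built
incrementally (SBR only, SBR plus insertion, SBR plus insertion plus FBS, ...).
Edits are realized at codon level by copying the donor's codon, keeping
nucleotide provenance traceable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .alignment import ReferenceMap, translate
from .errors import InputError, MappingError
from .regions import RegionAnnotation
from .substmodels import codon_translation

_CODON_OF_AA: dict[str, list[str]] = {}
for _codon, _aa in codon_translation().items():
    _CODON_OF_AA.setdefault(_aa, []).append(_codon)


@dataclass(frozen=True)
class Substitution:
    column: int  # residue column in the shared alignment
    label: str  # reference-numbering label (e.g. "292" or "358a")
    backbone_aa: str
    donor_aa: str
    region: str
    donor_codon: str | None = None


@dataclass(frozen=True)
class IndelEvent:
    kind: str  # "insertion" (backbone gap, donor residues) or "deletion"
    columns: tuple[int, ...]
    anchor_label: str
    residues: str  # donor residues inserted, or backbone residues deleted
    region: str
    donor_codons: tuple[str, ...] = ()


@dataclass
class MutationSet:
    """Complete positioned inventory of backbone -> donor changes."""

    backbone_id: str
    donor_id: str
    substitutions: list[Substitution] = field(default_factory=list)
    indels: list[IndelEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        cols = [s.column for s in self.substitutions]
        if len(cols) != len(set(cols)):
            raise InputError("duplicate substitution columns")
        for s in self.substitutions:
            if s.backbone_aa == s.donor_aa:
                raise InputError(f"null substitution at {s.label}")

    def counts_by_region(self) -> dict[str, int]:
        out: dict[str, int] = {"ASA": 0, "SBR": 0, "FBS": 0, "other": 0}
        for s in self.substitutions:
            out[s.region] += 1
        return out

    @property
    def n_substitutions(self) -> int:
        return len(self.substitutions)

    def n_in_sbr(self) -> int:
        c = self.counts_by_region()
        return c["ASA"] + c["SBR"]

    def select(self, regions: set[str] | None = None, include_indels: bool = False,
               labels: set[str] | None = None) -> "MutationSet":
        """Subset by region labels (``"SBR"`` implies ASA membership) and/or
        explicit position labels."""
        def keep(region: str, label: str) -> bool:
            if labels is not None:
                return label in labels
            if regions is None:
                return True
            expanded = set(regions) | ({"ASA"} if "SBR" in regions else set())
            return region in expanded

        return MutationSet(
            backbone_id=self.backbone_id,
            donor_id=self.donor_id,
            substitutions=[s for s in self.substitutions if keep(s.region, s.label)],
            indels=[i for i in self.indels if include_indels and keep(i.region, i.anchor_label)],
        )


def _region_of_label(label: str, regions: RegionAnnotation) -> str:
    digits = "".join(ch for ch in label if ch.isdigit())
    if not digits:
        raise MappingError(f"unparseable position label {label!r}")
    return regions.region_of(int(digits))


def diff_sequences(
    backbone: str,
    donor: str,
    refmap: ReferenceMap,
    regions: RegionAnnotation,
    backbone_id: str = "backbone",
    donor_id: str = "donor",
    donor_cds: str | None = None,
) -> MutationSet:
    """Inventory all substitutions and indel events between two aligned proteins.

    ``backbone`` and ``donor`` are aligned amino-acid strings in the same
    coordinate system as ``refmap``.  When ``donor_cds`` (the donor's ungapped
    coding sequence) is given, each change carries the donor codon.
    """
    if len(backbone) != len(donor):
        raise InputError("backbone and donor must be aligned to equal length")
    donor_res = -1  # donor residue counter (0-based, ungapped)
    subs: list[Substitution] = []
    indel_runs: list[tuple[str, list[int]]] = []
    run_kind: str | None = None
    for col, (b, d) in enumerate(zip(backbone, donor)):
        if d != "-":
            donor_res += 1
        try:
            label = refmap.label_of(col)
        except MappingError:
            label = str(col + 1)
        if b == "-" and d == "-":
            run_kind = None
            continue
        kind = "insertion" if b == "-" else "deletion" if d == "-" else None
        if kind:
            if kind == run_kind and indel_runs and indel_runs[-1][1][-1] == col - 1:
                indel_runs[-1][1].append(col)
            else:
                indel_runs.append((kind, [col]))
            run_kind = kind
            continue
        run_kind = None
        if b != d:
            codon = None
            if donor_cds is not None:
                codon = donor_cds[3 * donor_res : 3 * donor_res + 3]
            subs.append(Substitution(
                column=col, label=label, backbone_aa=b, donor_aa=d,
                region=_region_of_label(label, regions), donor_codon=codon))
    indels: list[IndelEvent] = []
    for kind, cols in indel_runs:
        labels = []
        for c in cols:
            try:
                labels.append(refmap.label_of(c))
            except MappingError:
                labels.append(str(c + 1))
        residues = "".join((donor if kind == "insertion" else backbone)[c] for c in cols)
        codons: tuple[str, ...] = ()
        if kind == "insertion" and donor_cds is not None:
            start = sum(1 for ch in donor[: cols[0]] if ch != "-")
            codons = tuple(donor_cds[3 * (start + k) : 3 * (start + k) + 3]
                           for k in range(len(cols)))
        indels.append(IndelEvent(
            kind=kind, columns=tuple(cols), anchor_label=labels[0],
            residues=residues, region=_region_of_label(labels[0], regions),
            donor_codons=codons))
    return MutationSet(backbone_id=backbone_id, donor_id=donor_id,
                       substitutions=subs, indels=indels)


def _fallback_codon(aa: str, backbone_cds: str) -> str:
    """Most frequent codon encoding ``aa`` in the backbone gene."""
    counts = Counter(backbone_cds[i : i + 3] for i in range(0, len(backbone_cds), 3))
    candidates = _CODON_OF_AA.get(aa)
    if not candidates:
        raise InputError(f"cannot encode residue {aa!r}")
    return max(candidates, key=lambda c: (counts.get(c, 0), c))


def apply_mutations(
    backbone_cds: str,
    backbone_aligned: str,
    mutation_sets: MutationSet | list[MutationSet],
) -> tuple[str, str]:
    """Realize protein-level edits at codon level.

    ``mutation_sets`` may be a single (sub)set or an ordered list of layers
    (later layers override earlier ones at the same column, enabling
    multi-donor designs).  Untouched codons are copied verbatim from the
    backbone.  Returns ``(hybrid_cds, hybrid_protein)``.
    """
    if isinstance(mutation_sets, MutationSet):
        mutation_sets = [mutation_sets]
    if len(backbone_cds) % 3 != 0:
        raise InputError("backbone coding sequence must be in frame")
    n_res = sum(1 for ch in backbone_aligned if ch != "-")
    if n_res != len(backbone_cds) // 3:
        raise InputError("backbone CDS and aligned protein disagree in residue count")

    sub_at: dict[int, Substitution] = {}
    ins_at: dict[int, tuple[str, tuple[str, ...]]] = {}  # first column -> residues, codons
    del_cols: set[int] = set()
    for mset in mutation_sets:
        for s in mset.substitutions:
            sub_at[s.column] = s  # ordered layers: later wins
        for ev in mset.indels:
            if ev.kind == "insertion":
                ins_at[ev.columns[0]] = (ev.residues, ev.donor_codons)
            else:
                del_cols.update(ev.columns)

    codons = [backbone_cds[i : i + 3] for i in range(0, len(backbone_cds), 3)]
    out: list[str] = []
    res_idx = -1
    for col, aa in enumerate(backbone_aligned):
        if col in ins_at and aa == "-":
            residues, dc = ins_at[col]
            for k, r in enumerate(residues):
                out.append(dc[k] if dc else _fallback_codon(r, backbone_cds))
        if aa == "-":
            continue
        res_idx += 1
        if col in del_cols:
            continue
        if col in sub_at:
            s = sub_at[col]
            if s.backbone_aa != aa:
                raise InputError(
                    f"backbone residue at column {col} is {aa}, expected {s.backbone_aa}")
            out.append(s.donor_codon or _fallback_codon(s.donor_aa, backbone_cds))
        else:
            out.append(codons[res_idx])
    hybrid = "".join(out)
    return hybrid, translate(hybrid)


@dataclass
class HybridSpec:
    """Named selection over a computed mutation set (e.g. SBR, SBR+Ins, SBR+Ins+FBS)."""

    name: str
    backbone_id: str
    donor_id: str
    regions: set[str] = field(default_factory=lambda: {"SBR"})
    include_indels: bool = False
    labels: set[str] | None = None  # explicit position labels override regions

    def select(self, mset: MutationSet) -> MutationSet:
        if mset.backbone_id != self.backbone_id or mset.donor_id != self.donor_id:
            raise InputError(
                f"spec {self.name}: mutation set is {mset.backbone_id}->{mset.donor_id}")
        return mset.select(regions=self.regions, include_indels=self.include_indels,
                           labels=self.labels)


def hybrid_report(mset: MutationSet, selection: MutationSet) -> pd.DataFrame:
    """Machine twin of a mutation table: every backbone->donor change with its
    region and whether the hybrid includes it."""
    included_cols = {s.column for s in selection.substitutions}
    included_ins = {ev.columns for ev in selection.indels}
    rows = []
    for s in sorted(mset.substitutions, key=lambda s: s.column):
        rows.append({"position": s.label, "region": s.region,
                     "backbone_aa": s.backbone_aa, "donor_aa": s.donor_aa,
                     "included": s.column in included_cols})
    for ev in mset.indels:
        rows.append({"position": ev.anchor_label,
                     "region": ev.region,
                     "backbone_aa": "-" * len(ev.residues) if ev.kind == "insertion" else ev.residues,
                     "donor_aa": ev.residues if ev.kind == "insertion" else "-" * len(ev.residues),
                     "included": ev.columns in included_ins})
    return pd.DataFrame(rows, columns=["position", "region", "backbone_aa",
                                       "donor_aa", "included"])
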