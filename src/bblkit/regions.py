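"""Structural region classification in THCAS numbering.

Residues are classed into the active-site-adjacent loop (ASA, residues 354-380
by definition, a subset of the substrate binding region), the wider substrate
binding region (SBR: residues shaping the substrate cavity plus residues near
the FAD isoalloxazine ring), the FAD binding site (FBS: residues surrounding
the FAD cofactor not already in the SBR), and "other".  The annotation can be
derived from a coordinate file containing the FAD ligand, or loaded from a
residue-region table, which bypasses all distance logic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InputError, MappingError

ASA_RANGE = (354, 380)
FAD_CUTOFF = 4.5  # heavy-atom distance (angstrom) defining the FAD binding site
CAVITY_CUTOFF = 6.0  # distance to the cavity reference defining the SBR core
# atom names of the FAD isoalloxazine ring system (standard PDB nomenclature)
ISOALLOXAZINE_ATOMS = frozenset({
    "N1", "C2", "O2", "N3", "C4", "O4", "C4X", "N5", "C5X", "C6", "C7", "C7M",
    "C8", "C8M", "C9", "C9A", "N10", "C10",
})

REGIONS = ("ASA", "SBR", "FBS", "other")


@dataclass
class RegionAnnotation:
    """Residue number (1-based, reference numbering) -> region label.

    ASA residues are part of the SBR by definition; ``region_of`` returns the
    most specific label and ``in_sbr`` treats ASA as SBR membership.
    """

    regions: dict[int, str]
    provenance: str = "table-loaded"

    def __post_init__(self) -> None:
        bad = {p: r for p, r in self.regions.items() if r not in REGIONS}
        if bad:
            raise InputError(f"unknown region labels: {bad}")

    def region_of(self, position: int) -> str:
        return self.regions.get(position, "other")

    def in_sbr(self, position: int) -> bool:
        return self.region_of(position) in ("ASA", "SBR")

    def in_fbs(self, position: int) -> bool:
        return self.region_of(position) == "FBS"

    def counts(self) -> dict[str, int]:
        out = {r: 0 for r in REGIONS}
        for r in self.regions.values():
            out[r] += 1
        return out

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("position\tregion\n")
            for pos in sorted(self.regions):
                fh.write(f"{pos}\t{self.regions[pos]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegionAnnotation":
        regions: dict[int, str] = {}
        lines = Path(path).read_text().splitlines()
        if not lines or not lines[0].lower().startswith("position"):
            raise InputError(f"{path}: expected header 'position<TAB>region'")
        for line in lines[1:]:
            if not line.strip():
                continue
            pos, region = line.split("\t")[:2]
            regions[int(pos)] = region
        return cls(regions=regions, provenance="table-loaded")


def _read_structure(path: str | Path):
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, altloc="first")
    return atoms


def classify_regions(
    structure: str | Path,
    fad_resname: str = "FAD",
    fad_cutoff: float = FAD_CUTOFF,
    cavity_cutoff: float = CAVITY_CUTOFF,
    cavity_center: np.ndarray | None = None,
    cavity_ligand: str | None = None,
    asa_range: tuple[int, int] = ASA_RANGE,
) -> RegionAnnotation:
    """Distance-based region classification from a PDB-format coordinate file.

    SBR = ASA residues, plus residues with a heavy atom within
    ``cavity_cutoff`` of the cavity reference (a bound ligand or an explicit
    centroid), plus residues within ``cavity_cutoff`` of the FAD isoalloxazine
    ring.  FBS = residues with a heavy atom within ``fad_cutoff`` of any FAD
    atom, not already in the SBR.  Deterministic given the inputs.
    """
    if fad_cutoff <= 0 or cavity_cutoff <= 0:
        raise InputError("cutoffs must be positive")
    atoms = _read_structure(structure)
    heavy = atoms[atoms.element != "H"]
    fad = heavy[heavy.res_name == fad_resname]
    if fad.array_length() == 0:
        raise InputError(f"no {fad_resname} ligand in structure")
    protein = heavy[~heavy.hetero]
    if protein.array_length() == 0:
        raise MappingError("no protein atoms in structure")

    iso = fad[np.isin(fad.atom_name, list(ISOALLOXAZINE_ATOMS))]
    iso_coord = iso.coord if iso.array_length() else fad.coord

    if cavity_center is not None:
        cavity_ref = np.asarray(cavity_center, dtype=float).reshape(1, 3)
    elif cavity_ligand is not None:
        lig = heavy[heavy.res_name == cavity_ligand]
        if lig.array_length() == 0:
            raise InputError(f"no {cavity_ligand} ligand in structure")
        cavity_ref = lig.coord
    else:
        cavity_ref = iso_coord  # cavity sits over the isoalloxazine re-face

    def min_dist(coords: np.ndarray, ref: np.ndarray) -> float:
        diff = coords[:, None, :] - ref[None, :, :]
        return float(np.sqrt((diff**2).sum(-1)).min())

    regions: dict[int, str] = {}
    for res_id in np.unique(protein.res_id):
        res_atoms = protein[protein.res_id == res_id]
        pos = int(res_id)
        if asa_range[0] <= pos <= asa_range[1]:
            regions[pos] = "ASA"
            continue
        near_cavity = min_dist(res_atoms.coord, cavity_ref) <= cavity_cutoff
        near_iso = min_dist(res_atoms.coord, iso_coord) <= cavity_cutoff
        if near_cavity or near_iso:
            regions[pos] = "SBR"
        elif min_dist(res_atoms.coord, fad.coord) <= fad_cutoff:
            regions[pos] = "FBS"
        else:
            regions[pos] = "other"
    return RegionAnnotation(regions=regions, provenance="distance-derived")
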