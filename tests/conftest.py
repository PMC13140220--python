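import warnings

import pytest

from bblkit.pipeline import reconstruct_and_curate
from bblkit.simulate import default_study, simulate_alignment
from bblkit.trees import read_tree

ANCESTOR_NODES = ["HCa", "Ca", "A1A2a"]


@pytest.fixture(scope="session")
def small_study():
    """Scaled-down synthetic study: 15 tips, 120 core codons, both scripted
    insertions and both pseudogenes."""
    spec = default_study(seed=7, length_codons=120)
    msa, truth = simulate_alignment(spec)
    return spec, msa, truth


@pytest.fixture(scope="session")
def curated_small(small_study):
    """Full reconstruction + curation of the three named ancestors (shared
    across tests because the fit is the expensive step)."""
    spec, msa, _ = small_study
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return reconstruct_and_curate(msa, read_tree(spec.newick), ANCESTOR_NODES,
                                      max_rounds=5)


def make_synthetic_pdb(path):
    """Write a synthetic miniature coordinate file (PDB format): a FAD ligand
    whose isoalloxazine sits at the origin and a ribityl tail along +x, plus
    protein residues placed at controlled distances.  Synthetic stand-in for a
    real oxidocyclase structure; geometry chosen to make region membership
    unambiguous."""
    lines = []
    serial = [0]

    def atom(record, name, resname, chain, resseq, x, y, z, element):
        serial[0] += 1
        name_f = f" {name:<3s}" if len(name) < 4 else name
        lines.append(
            f"{record:<6s}{serial[0]:>5d} {name_f}{'':1s}{resname:>3s} {chain}"
            f"{resseq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {element:>2s}"
        )

    # protein residues (CA only; one has an extra hydrogen to test heavy-atom rule)
    atom("ATOM", "CA", "ALA", "A", 100, 3.0, 0.0, 0.0, "C")     # SBR (near isoalloxazine)
    atom("ATOM", "CA", "GLY", "A", 150, 5.5, 0.0, 0.0, "C")     # SBR (5.5 A from ring)
    atom("ATOM", "CA", "SER", "A", 200, 8.0, 3.0, 0.0, "C")     # FBS (3 A from tail)
    atom("ATOM", "CA", "LEU", "A", 250, 8.0, 3.9, 0.0, "C")     # FBS (3.9 A from tail)
    atom("ATOM", "CA", "VAL", "A", 300, 30.0, 30.0, 30.0, "C")  # other
    atom("ATOM", "H", "VAL", "A", 300, 0.5, 0.0, 0.0, "H")      # hydrogen: ignored
    atom("ATOM", "CA", "THR", "A", 360, 20.0, 0.0, 0.0, "C")    # ASA by numbering
    # FAD ligand: two isoalloxazine atoms at the origin, tail atoms at +x
    atom("HETATM", "N5", "FAD", "A", 600, 0.0, 0.0, 0.0, "N")
    atom("HETATM", "C4X", "FAD", "A", 600, 1.2, 0.0, 0.0, "C")
    atom("HETATM", "C1'", "FAD", "A", 600, 8.0, 0.0, 0.0, "C")
    atom("HETATM", "N9", "FAD", "A", 600, 10.0, 0.0, 0.0, "N")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
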