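"""Canonical caulamidine A fixture: structure, assignments, correlations.

Caulamidine A is a trichlorinated marine alkaloid (C23H21Cl3N4, 14 indices
of hydrogen deficiency) with a hexahydro-2,6-naphthyridine core carrying
two amidine units (N1-C2-N3 fused into a dihydroindole-type system, ring B;
N13-C14-N15 into a tetrahydroquinoline-type system, ring E), two
1,2,4-trisubstituted benzene rings (C and F), two N-methyls (C26, C27) and
chlorines at C-7, C-11 and C-19; relative/absolute configuration
(10S,11S,23S).  The connectivity below is encoded position-by-position from
the published assignment table and ring arguments.

The shipped SDF conformer was generated from this graph (ETKDG embedding,
seed 2024, MMFF-relaxed) and is the reference geometry for NOE and
anisotropic calculations.  Diastereotopic proton sites (12a/b, 22a/b,
24a/b, 25a/b) are geometric labels assigned on that conformer so that the
reported NOE contacts are internally consistent; they are a modelling
choice, not an experimental assignment.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .graph import MoleculeGraph, read_structure
from .tables import AssignmentRow, CorrelationSet, read_assignment_table, read_correlations

#: Position labels of every heavy atom, in fixture atom order.
POSITIONS = ["1-N", "2", "3-N", "4", "5", "6", "7", "8", "9", "10", "11",
             "12", "13-N", "14", "15-N", "16", "17", "18", "19", "20", "21",
             "22", "23", "24", "25", "26", "27"]

#: Heavy-atom bond list (position labels, order: 1 single, 2 double,
#: 12 aromatic).  Chlorines at C-7, C-11, C-19 are appended by the builder.
BONDS = [
    ("1-N", "2", 1), ("1-N", "25", 1), ("1-N", "26", 1),
    ("2", "3-N", 2), ("2", "10", 1),
    ("3-N", "4", 1),
    ("4", "5", 12), ("5", "6", 12), ("6", "7", 12),
    ("7", "8", 12), ("8", "9", 12), ("9", "4", 12),
    ("9", "10", 1), ("10", "11", 1), ("10", "23", 1),
    ("11", "12", 1), ("12", "13-N", 1), ("13-N", "14", 1), ("13-N", "27", 1),
    ("14", "15-N", 2), ("14", "23", 1), ("15-N", "16", 1),
    ("16", "17", 12), ("17", "18", 12), ("18", "19", 12),
    ("19", "20", 12), ("20", "21", 12), ("21", "16", 12),
    ("21", "22", 1), ("22", "23", 1), ("23", "24", 1), ("24", "25", 1),
]

CHLORINE_CARBONS = ["7", "11", "19"]
STEREOCENTRES = ["10", "11", "23"]


def build_caulamidine_a(embed_seed: int = 2024,
                        optimize: bool = True):
    """Construct caulamidine A as an RDKit molecule with explicit hydrogens
    and a 3D conformer in the (10S,11S,23S) configuration.

    Returns ``(mol, index_map)`` where ``index_map`` maps heavy-atom
    position labels to atom indices.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    em = Chem.RWMol()
    idx: dict[str, int] = {}
    for pos in POSITIONS:
        idx[pos] = em.AddAtom(Chem.Atom("N" if pos.endswith("-N") else "C"))
    for pos in CHLORINE_CARBONS:
        cl = em.AddAtom(Chem.Atom("Cl"))
        em.AddBond(idx[pos], cl, Chem.BondType.SINGLE)
    bt = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
          12: Chem.BondType.AROMATIC}
    for a, b, o in BONDS:
        em.AddBond(idx[a], idx[b], bt[o])
        if o == 12:
            em.GetAtomWithIdx(idx[a]).SetIsAromatic(True)
            em.GetAtomWithIdx(idx[b]).SetIsAromatic(True)
    mol = em.GetMol()
    Chem.SanitizeMol(mol)
    # chiral tags found to give CIP (10S,11S,23S) for this connectivity
    tags = {"10": Chem.ChiralType.CHI_TETRAHEDRAL_CW,
            "11": Chem.ChiralType.CHI_TETRAHEDRAL_CW,
            "23": Chem.ChiralType.CHI_TETRAHEDRAL_CCW}
    for pos, tag in tags.items():
        mol.GetAtomWithIdx(idx[pos]).SetChiralTag(tag)
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    mol = Chem.AddHs(mol)
    ps = AllChem.ETKDGv3()
    ps.randomSeed = embed_seed
    if AllChem.EmbedMolecule(mol, ps) != 0:
        raise RuntimeError("embedding failed")
    if optimize:
        AllChem.MMFFOptimizeMolecule(mol, maxIters=2000)
    return mol, idx


def _data_path(name: str) -> Path:
    return Path(resources.files("anisoverify") / "data" / name)


def load_caulamidine_a() -> MoleculeGraph:
    """The shipped caulamidine A conformer with all position labels."""
    return read_structure(_data_path("caulamidine_a.sdf"),
                          label_map=_data_path("caulamidine_a_labels.csv"),
                          name="caulamidine_A")


def load_assignments() -> list[AssignmentRow]:
    """The published assignment table (27 positions + diastereotopic rows)."""
    return read_assignment_table(_data_path("caulamidine_a_assignments.csv"))


def load_correlations(experiment=None) -> list[CorrelationSet]:
    """Typed correlation sets encoding the printed HMBC column plus the
    schematically reported COSY / long-range / ADEQUATE / NOESY data."""
    return read_correlations(_data_path("caulamidine_a_correlations.csv"),
                             experiment=experiment,
                             assignments=load_assignments())
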