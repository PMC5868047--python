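"""Molecular graphs and correlation-network consistency checking.

A candidate structure is a labelled molecular graph: atoms, bonds, optional
3D coordinates, and a mapping from NMR position labels to atom indices.
Every heteronuclear correlation then has an unambiguous *bond count* — the
shortest bond path from the observed proton to the target heavy atom — and
each 2D experiment type has a known window of bond counts it can produce
(HMBC: 2–3, rarely 4; LR-HSQMBC: out to 6; 1,1-HD-ADEQUATE: exactly 2,
i.e. the carbon adjacent to a protonated one).  Classifying every observed
correlation against those windows turns a printed correlation table into a
quantitative consistency test of the structure, and NOESY/ROESY contacts
add a through-space (distance) test when coordinates are present.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .tables import CorrelationSet, Experiment, carbon_of_position


class StructureError(ValueError):
    """Invalid molecular graph or structure file."""


@dataclass
class Atom:
    index: int
    element: str
    label: str | None = None
    coords: np.ndarray | None = None
    formal_charge: int = 0


@dataclass
class MoleculeGraph:
    """Atoms + bonds + position labels; the substrate for every check."""

    atoms: list[Atom]
    bonds: list[tuple[int, int, float]]      # (i, j, bond order)
    labels: dict[str, int] = field(default_factory=dict)
    explicit_H: bool = True
    name: str = ""
    _nx: nx.Graph | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise StructureError(f"bond ({i},{j}) has invalid endpoints")
        for lbl, idx in self.labels.items():
            if not 0 <= idx < n:
                raise StructureError(f"label {lbl!r} mapped to nonexistent atom {idx}")

    # -- basic accessors ---------------------------------------------------

    @property
    def nx_graph(self) -> nx.Graph:
        if self._nx is None:
            g = nx.Graph()
            g.add_nodes_from(range(len(self.atoms)))
            g.add_edges_from((i, j) for i, j, _ in self.bonds)
            self._nx = g
        return self._nx

    def element(self, i: int) -> str:
        return self.atoms[i].element

    def has_coordinates(self) -> bool:
        return all(a.coords is not None for a in self.atoms)

    def coordinates(self) -> np.ndarray:
        if not self.has_coordinates():
            raise StructureError("structure has no (complete) coordinates")
        return np.array([a.coords for a in self.atoms], dtype=float)

    def neighbors(self, i: int) -> list[int]:
        return list(self.nx_graph.neighbors(i))

    def hydrogens_of(self, i: int) -> list[int]:
        return [j for j in self.neighbors(i) if self.element(j) == "H"]

    def heavy_formula_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for a in self.atoms:
            counts[a.element] = counts.get(a.element, 0) + 1
        return counts

    # -- label resolution --------------------------------------------------

    def atom_of(self, position: str) -> int:
        """Heavy atom carrying a position label (proton sites resolve to
        their bonded heavy atom)."""
        idx = self.labels.get(position)
        if idx is None:
            idx = self.labels.get(carbon_of_position(position))
        if idx is None:
            raise StructureError(f"position {position!r} not labelled in structure")
        if self.element(idx) == "H":
            heavies = [j for j in self.neighbors(idx) if self.element(j) != "H"]
            if not heavies:
                raise StructureError(f"labelled proton {position!r} is unbonded")
            return heavies[0]
        return idx

    def protons_of(self, position: str) -> list[int]:
        """Proton atoms observable at a position label.

        An explicitly labelled proton site (``"22a"`` mapped to one H atom)
        resolves to that single proton; a heavy-atom label resolves to all
        its attached hydrogens.
        """
        idx = self.labels.get(position)
        if idx is not None and self.element(idx) == "H":
            return [idx]
        heavy = self.atom_of(position)
        hs = self.hydrogens_of(heavy)
        if not hs:
            raise StructureError(f"position {position!r} carries no protons")
        return hs

    # -- validation --------------------------------------------------------

    def validate(self, require_connected: bool = True) -> None:
        if require_connected and len(self.atoms) > 1 and not nx.is_connected(self.nx_graph):
            raise StructureError("molecular graph is disconnected")
        if self.has_coordinates():
            xyz = self.coordinates()
            for i, j, _ in self.bonds:
                d = float(np.linalg.norm(xyz[i] - xyz[j]))
                if not 0.8 <= d <= 2.0:
                    raise StructureError(
                        f"bonded pair ({i},{j}) at {d:.2f} A outside 0.8-2.0 A")

    # -- rdkit bridge ------------------------------------------------------

    def to_rdkit(self):
        from rdkit import Chem
        from rdkit.Chem import AllChem

        em = Chem.RWMol()
        for a in self.atoms:
            at = Chem.Atom(a.element)
            at.SetFormalCharge(a.formal_charge)
            at.SetNoImplicit(True)
            em.AddAtom(at)
        order_map = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
                     3.0: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}
        for i, j, o in self.bonds:
            em.AddBond(i, j, order_map.get(float(o), Chem.BondType.SINGLE))
        mol = em.GetMol()
        Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_ALL
                         ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE)
        if self.has_coordinates():
            conf = Chem.Conformer(mol.GetNumAtoms())
            for a in self.atoms:
                conf.SetAtomPosition(a.index, [float(x) for x in a.coords])
            mol.AddConformer(conf, assignId=True)
        return mol

    @classmethod
    def from_rdkit(cls, mol, labels: dict[str, int] | None = None,
                   name: str = "") -> "MoleculeGraph":
        conf = mol.GetConformer() if mol.GetNumConformers() else None
        atoms = []
        for a in mol.GetAtoms():
            xyz = None
            if conf is not None:
                p = conf.GetAtomPosition(a.GetIdx())
                xyz = np.array([p.x, p.y, p.z])
            atoms.append(Atom(a.GetIdx(), a.GetSymbol(), None, xyz, a.GetFormalCharge()))
        bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
                 for b in mol.GetBonds()]
        labels = dict(labels or {})
        for lbl, idx in labels.items():
            if 0 <= idx < len(atoms):
                atoms[idx].label = lbl
        return cls(atoms, bonds, labels, explicit_H=True, name=name)

    def copy(self) -> "MoleculeGraph":
        return MoleculeGraph(
            [Atom(a.index, a.element, a.label,
                  None if a.coords is None else np.array(a.coords), a.formal_charge)
             for a in self.atoms],
            list(self.bonds), dict(self.labels), self.explicit_H, self.name)


# --------------------------------------------------------------------------
# structure file input


def read_label_map(path: str | Path) -> dict[str, int]:
    """CSV with columns ``position, atom_index`` (0-based atom indices)."""
    df = pd.read_csv(path, dtype=str)
    if "position" not in df.columns or "atom_index" not in df.columns:
        raise StructureError("label map needs position and atom_index columns")
    return {str(p).strip(): int(i) for p, i in zip(df["position"], df["atom_index"])}


def read_structure(path: str | Path,
                   label_map: str | Path | dict[str, int] | None = None,
                   bond_list: str | Path | None = None,
                   allow_disconnected: bool = False,
                   name: str | None = None) -> MoleculeGraph:
    """Read SDF/MOL (V2000) or XYZ (+ bond-list CSV) into a MoleculeGraph.

    Hydrogens are made explicit (added per standard valence, with generated
    coordinates, when the file stores them implicitly).  ``label_map`` maps
    position labels to 0-based atom indices of the file as read.
    """
    from rdkit import Chem

    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".sdf", ".mol"}:
        mol = Chem.MolFromMolFile(str(path), removeHs=False, sanitize=False)
        if mol is None:
            raise StructureError(f"could not parse {path}")
        try:
            Chem.SanitizeMol(mol)
        except Exception as exc:
            raise StructureError(f"invalid structure in {path}: {exc}") from exc
        n_before = mol.GetNumAtoms()
        if any(a.GetNumImplicitHs() for a in mol.GetAtoms()):
            mol = Chem.AddHs(mol, addCoords=mol.GetNumConformers() > 0)
        if mol.GetNumAtoms() != n_before:
            pass  # appended Hs keep original indices valid for the label map
    elif suffix == ".xyz":
        mol = _mol_from_xyz(path, bond_list)
    else:
        raise StructureError(f"unsupported structure format {suffix!r}")

    labels: dict[str, int] = {}
    if isinstance(label_map, (str, Path)):
        labels = read_label_map(label_map)
    elif label_map:
        labels = dict(label_map)
    g = MoleculeGraph.from_rdkit(mol, labels, name=name or path.stem)
    g.validate(require_connected=not allow_disconnected)
    return g


def _mol_from_xyz(path: Path, bond_list: str | Path | None):
    from rdkit import Chem

    lines = path.read_text().splitlines()
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise StructureError("malformed XYZ header") from exc
    em = Chem.RWMol()
    conf = Chem.Conformer(n)
    for i, line in enumerate(lines[2:2 + n]):
        sym, x, y, z = line.split()[:4]
        at = Chem.Atom(sym)
        at.SetNoImplicit(True)
        em.AddAtom(at)
        conf.SetAtomPosition(i, (float(x), float(y), float(z)))
    if bond_list is None:
        raise StructureError("XYZ input requires a bond-list CSV")
    df = pd.read_csv(bond_list)
    for _, row in df.iterrows():
        order = float(row.get("order", 1.0)) if "order" in df.columns else 1.0
        bt = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
              3.0: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}.get(order, Chem.BondType.SINGLE)
        em.AddBond(int(row["a"]), int(row["b"]), bt)
    mol = em.GetMol()
    mol.AddConformer(conf, assignId=True)
    Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_ALL
                     ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE)
    return mol


# --------------------------------------------------------------------------
# path lengths and classification


def bond_path_length(g: MoleculeGraph, a: int | str, b: int | str) -> int:
    """Number of bonds on the shortest path between two atoms (or labels)."""
    ia = g.labels[a] if isinstance(a, str) and a in g.labels else (
        g.atom_of(a) if isinstance(a, str) else int(a))
    ib = g.labels[b] if isinstance(b, str) and b in g.labels else (
        g.atom_of(b) if isinstance(b, str) else int(b))
    for idx in (ia, ib):
        if not 0 <= idx < len(g.atoms):
            raise StructureError(f"atom {idx} not in graph")
    try:
        return nx.shortest_path_length(g.nx_graph, ia, ib)
    except nx.NetworkXNoPath:
        return -1


@dataclass
class CorrelationRecord:
    experiment: str
    from_position: str
    to_position: str
    bond_count: int | None
    distance_A: float | None
    verdict: str            # expected | tolerated | violation | unreachable


@dataclass
class ConsistencyReport:
    records: list[CorrelationRecord]

    @property
    def counts(self) -> dict[str, int]:
        c = {"expected": 0, "tolerated": 0, "violation": 0, "unreachable": 0}
        for r in self.records:
            c[r.verdict] += 1
        return c

    @property
    def passed(self) -> bool:
        return self.counts["violation"] == 0

    def to_dict(self) -> dict:
        return {"records": [vars(r) for r in self.records],
                "counts": self.counts, "passed": self.passed}

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


#: Default bond-count windows per experiment: (expected, tolerated).
DEFAULT_RULES: dict[Experiment, tuple[frozenset[int], frozenset[int]]] = {
    Experiment.HSQC: (frozenset({1}), frozenset()),
    Experiment.HMBC_CH: (frozenset({2, 3}), frozenset({4})),
    Experiment.HMBC_NH: (frozenset({2, 3}), frozenset({4})),
    Experiment.COSY: (frozenset({2, 3}), frozenset({4})),
    Experiment.LR_HSQMBC: (frozenset({2, 3, 4, 5, 6}), frozenset()),
    Experiment.ADEQUATE_1_1: (frozenset({2}), frozenset()),
}

#: Experiments whose bond count is proton-to-proton, not proton-to-heavy.
_H_TO_H = {Experiment.COSY}

MAX_RELAY_HOPS = 4          # TOCSY relay depth bound
RELAY_COUPLING_BONDS = 3    # max H-H bond separation counted as J-coupled


def load_rules(path: str | Path) -> dict[Experiment, tuple[frozenset[int], frozenset[int]]]:
    """Read a YAML rule table: ``EXPERIMENT: {expected: [..], tolerated: [..]}``."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    rules = dict(DEFAULT_RULES)
    for key, val in (raw or {}).items():
        rules[Experiment(key)] = (frozenset(val.get("expected", [])),
                                  frozenset(val.get("tolerated", [])))
    return rules


def _tocsy_reachable(g: MoleculeGraph, start_protons: list[int], target: int,
                     max_hops: int = MAX_RELAY_HOPS) -> bool:
    """Topological relay model: hop between J-coupled protons (each hop
    <= RELAY_COUPLING_BONDS bonds), then a final <= 3-bond H -> heavy step."""
    all_protons = [i for i, a in enumerate(g.atoms) if a.element == "H"]
    lengths = {}
    reached = set(start_protons)
    frontier = set(start_protons)
    for _ in range(max_hops + 1):
        for h in frontier:
            lengths.setdefault(h, dict(nx.single_source_shortest_path_length(
                g.nx_graph, h, cutoff=RELAY_COUPLING_BONDS)))
            if lengths[h].get(target, 99) <= 3:
                return True
        nxt = set()
        for h in frontier:
            for p in all_protons:
                if p not in reached and lengths[h].get(p, 99) <= RELAY_COUPLING_BONDS:
                    nxt.add(p)
        reached |= nxt
        frontier = nxt
        if not frontier:
            break
    return False


def classify_correlations(g: MoleculeGraph, cs: CorrelationSet,
                          rules: dict | None = None) -> ConsistencyReport:
    """Classify each correlation by bond count against the experiment's window.

    The bond count of a multi-proton from-position is the minimum over its
    protons (any one proton suffices to produce the cross peak).  Verdicts:
    ``expected`` within the expected window, ``tolerated`` within the
    tolerated window, ``violation`` otherwise, and ``unreachable`` when no
    bond path exists at all.
    """
    rules = rules or DEFAULT_RULES
    exp = cs.experiment
    if exp in (Experiment.NOESY, Experiment.ROESY):
        return noe_distance_check(g, cs)
    if exp is not Experiment.HSQMBC_TOCSY and exp not in rules:
        raise StructureError(f"rule table has no entry for {exp.value}")
    records = []
    for frm, to in cs.pairs:
        protons = g.protons_of(frm)
        if exp in _H_TO_H:
            targets = g.protons_of(to)
        else:
            targets = [g.atom_of(to)]
        paths = [bond_path_length(g, h, t) for h in protons for t in targets]
        # H-to-H experiments: a proton is not its own coupling partner
        reachable = [p for p in paths if p >= (1 if exp in _H_TO_H else 0)]
        n = min(reachable) if reachable else None
        if n is None:
            verdict = "unreachable"
        elif exp is Experiment.HSQMBC_TOCSY:
            verdict = ("expected"
                       if _tocsy_reachable(g, protons, targets[0]) else "violation")
        else:
            expected, tolerated = rules[exp]
            verdict = ("expected" if n in expected
                       else "tolerated" if n in tolerated else "violation")
        records.append(CorrelationRecord(exp.value, frm, to, n, None, verdict))
    return ConsistencyReport(records)


def noe_distance_check(g: MoleculeGraph, cs: CorrelationSet,
                       cutoff_A: float = 5.0) -> ConsistencyReport:
    """Through-space check of NOESY/ROESY contacts against proton distances.

    The distance of a contact is the minimum over the candidate protons on
    each side (a specific proton when the site is individually labelled).
    Verdict is ``expected`` iff that distance is within ``cutoff_A``.
    """
    if not g.has_coordinates():
        raise StructureError("NOE check requires coordinates")
    xyz = g.coordinates()
    records = []
    for frm, to in cs.pairs:
        ha, hb = g.protons_of(frm), g.protons_of(to)
        d = float(min(np.linalg.norm(xyz[i] - xyz[j]) for i in ha for j in hb))
        verdict = "expected" if d <= cutoff_A else "violation"
        records.append(CorrelationRecord(cs.experiment.value, frm, to, None, d, verdict))
    return ConsistencyReport(records)


def compare_candidates_by_consistency(
        candidates: list[MoleculeGraph],
        data: list[CorrelationSet],
        rules: dict | None = None,
        noe_cutoff_A: float = 5.0,
) -> list[tuple[MoleculeGraph, dict[str, int]]]:
    """Rank candidates by (violations, unreachable, tolerated), ascending.

    Ties keep input order (stable sort), so identical candidates stay in
    the order given.
    """
    if not candidates:
        raise StructureError("need at least one candidate")
    summaries = []
    for g in candidates:
        totals = {"expected": 0, "tolerated": 0, "violation": 0, "unreachable": 0}
        for cs in data:
            if cs.experiment in (Experiment.NOESY, Experiment.ROESY):
                rep = noe_distance_check(g, cs, cutoff_A=noe_cutoff_A)
            else:
                rep = classify_correlations(g, cs, rules)
            for k, v in rep.counts.items():
                totals[k] += v
        summaries.append((g, totals))
    return sorted(summaries, key=lambda t: (t[1]["violation"], t[1]["unreachable"],
                                            t[1]["tolerated"]))
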