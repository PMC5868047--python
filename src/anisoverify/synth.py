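"""Synthetic anisotropic datasets, decoy structures, and correlation tables.

Everything the verification pipeline consumes can be generated here from a
known ground truth, which makes the whole chain testable at desk scale:
draw an alignment tensor, back-calculate RDC/RCSA observations from a
structure (plus Gaussian noise at stated levels), build decoy structures
that differ in constitution or configuration, and enumerate correlation
tables with the bond-count semantics of each experiment type.

All generators are deterministic per seed.  Shielding tensors are synthetic:
principal-axis frames are anchored to the local bonding geometry (so that a
decoy's tensors move with its geometry, as DFT tensors would) with
anisotropy spans drawn from typical 13C ranges — aromatic/sp2 carbons far
exceeding sp3 ones.  They emulate the *role* of computed tensors, not any
specific molecule's values.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .graph import MoleculeGraph, StructureError
from .saupe import (AlignmentTensor, RCSARecord, RDCRecord,
                    rcsa_back_calculate, rdc_back_calculate)
from .tables import CorrelationSet, Experiment

#: Anisotropy span (ppm) ranges for synthetic 13C shielding tensors.
SP2_SPAN_PPM = (140.0, 200.0)
SP3_SPAN_PPM = (20.0, 60.0)

DECOY_MODES = ("delete_bond", "swap_halogen_positions",
               "invert_stereocenters", "mirror_all")


@dataclass
class SynthConfig:
    seed: int = 0
    n_rdc: int = 10
    n_rcsa: int = 12
    rdc_noise_Hz: float = 0.5
    rcsa_noise_ppb: float = 2.0
    tensor_magnitude: float = 5e-4
    correlation_dropout: float = 0.0
    decoy_mode: str = "delete_bond"
    #: carbon labels excluded from RDC site selection (e.g. sites not
    #: protonated in every candidate of a cross-candidate comparison)
    rdc_exclude_positions: tuple = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.correlation_dropout <= 1.0:
            raise ValueError("dropout must be in [0, 1]")
        if self.rdc_noise_Hz < 0 or self.rcsa_noise_ppb < 0:
            raise ValueError("noise levels must be >= 0")
        if self.decoy_mode not in DECOY_MODES:
            raise ValueError(f"unknown decoy mode {self.decoy_mode!r}")


def _label_rng(seed: int, label: str, environment: str = "") -> np.random.Generator:
    key = f"{label}|{environment}"
    return np.random.default_rng([int(seed), zlib.crc32(key.encode())])


def gen_alignment_tensor(seed: int, magnitude: float = 5e-4) -> AlignmentTensor:
    """Random symmetric traceless tensor scaled so the largest-magnitude
    eigenvalue equals ``magnitude`` (a generalized degree of order)."""
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    rng = np.random.default_rng(seed)
    m = rng.standard_normal((3, 3))
    m = 0.5 * (m + m.T)
    m -= np.eye(3) * np.trace(m) / 3.0
    eig = np.linalg.eigvalsh(m)
    m *= magnitude / np.max(np.abs(eig))
    return AlignmentTensor(m)


# --------------------------------------------------------------------------
# shielding tensors


def _is_sp2(g: MoleculeGraph, i: int) -> bool:
    return len(g.neighbors(i)) == 3


def _local_frame(g: MoleculeGraph, i: int) -> np.ndarray:
    """Orthonormal frame anchored to the first two bonds of atom ``i``.

    Built from bond vectors and their cross product; under any orthogonal
    transform of the coordinates the frame vectors follow up to sign, so
    tensors built from outer products transform correctly (including under
    reflection).
    """
    xyz = g.coordinates()
    nb = sorted(g.neighbors(i))
    if len(nb) < 2:
        raise StructureError(f"atom {i} has fewer than 2 neighbours")
    b1 = xyz[nb[0]] - xyz[i]
    b2 = xyz[nb[1]] - xyz[i]
    e1 = b1 / np.linalg.norm(b1)
    n = np.cross(b1, b2)
    if np.linalg.norm(n) < 1e-8:            # collinear fallback
        n = np.cross(b1, b1 + [0.1, 0.2, 0.3])
    e3 = n / np.linalg.norm(n)
    e2 = np.cross(e3, e1)
    return np.column_stack([e1, e2, e3])


def gen_shielding_tensors(g: MoleculeGraph, seed: int,
                          positions: list[str] | None = None,
                          ) -> dict[str, np.ndarray]:
    """Synthetic molecular-frame 13C shielding tensors (ppm) per position.

    Principal values are drawn per (label, substitution environment), so a
    label keeps the same principal values across candidate geometries as
    long as its bonded neighbours are chemically the same — a carbon whose
    substitution differs between candidates (e.g. H exchanged for Cl) draws
    different values, as a computed tensor would.  Spans come from
    :data:`SP2_SPAN_PPM` / :data:`SP3_SPAN_PPM`; principal axes follow the
    local bonding frame of each candidate.
    """
    if positions is None:
        positions = [lbl for lbl in g.labels
                     if g.element(g.atom_of(lbl)) == "C"]
    out: dict[str, np.ndarray] = {}
    for lbl in positions:
        i = g.atom_of(lbl)
        if g.element(i) != "C":
            raise StructureError(f"position {lbl!r} is not a carbon")
        env = "".join(sorted(g.element(j) for j in g.neighbors(i)))
        rng = _label_rng(seed, lbl, env)
        lo, hi = SP2_SPAN_PPM if _is_sp2(g, i) else SP3_SPAN_PPM
        span = rng.uniform(lo, hi)
        mid = rng.uniform(-0.2, 0.2) * span
        iso = rng.uniform(10.0, 180.0)
        d = np.array([span / 2.0, mid, -span / 2.0])
        d -= d.mean()
        frame = _local_frame(g, i)
        out[lbl] = frame @ np.diag(d) @ frame.T + iso * np.eye(3)
    return out


# --------------------------------------------------------------------------
# observation datasets


def gen_aniso_dataset(g: MoleculeGraph, S: AlignmentTensor, cfg: SynthConfig,
                      ) -> tuple[list[RDCRecord], list[RCSARecord], dict[str, np.ndarray]]:
    """Noisy RDC/RCSA observations back-calculated from a known tensor.

    RDC sites are labelled protonated carbons (CH2 protons enter as two
    independent records when individually labelled); RCSA sites are labelled
    carbons with synthetic shielding tensors.  Record sigmas are set to the
    generating noise level (with a tiny floor so weighting stays defined).
    """
    if not g.has_coordinates():
        raise StructureError("dataset generation requires coordinates")
    rng = np.random.default_rng(cfg.seed)

    ch_pairs: list[tuple[str, str]] = []
    for lbl, idx in sorted(g.labels.items()):
        if g.element(idx) != "C" or lbl in cfg.rdc_exclude_positions:
            continue
        hs = g.hydrogens_of(idx)
        if len(hs) in (1, 3):
            ch_pairs.append((lbl, lbl))
        elif len(hs) == 2:
            proton_labels = [p for p, j in sorted(g.labels.items()) if j in hs]
            if proton_labels:
                ch_pairs.extend((lbl, p) for p in proton_labels)
            else:
                ch_pairs.append((lbl, lbl))
    if cfg.n_rdc > len(ch_pairs):
        raise ValueError(f"requested {cfg.n_rdc} RDCs but only "
                         f"{len(ch_pairs)} C-H sites available")
    chosen = [ch_pairs[k] for k in
              sorted(rng.choice(len(ch_pairs), size=cfg.n_rdc, replace=False))]
    sigma_d = max(cfg.rdc_noise_Hz, 1e-9)
    rdc = [RDCRecord(c, p, 0.0, sigma_d) for c, p in chosen]
    clean = rdc_back_calculate(g, S, rdc)
    noise = rng.normal(0.0, cfg.rdc_noise_Hz, size=len(rdc)) if cfg.rdc_noise_Hz else 0.0
    for rec, d in zip(rdc, clean + noise):
        rec.D_obs_Hz = float(d)

    carbons = [lbl for lbl, idx in sorted(g.labels.items())
               if g.element(idx) == "C" and len(g.neighbors(idx)) >= 2]
    if cfg.n_rcsa > len(carbons):
        raise ValueError(f"requested {cfg.n_rcsa} RCSAs but only "
                         f"{len(carbons)} carbons available")
    chosen_c = [carbons[k] for k in
                sorted(rng.choice(len(carbons), size=cfg.n_rcsa, replace=False))]
    shieldings = gen_shielding_tensors(g, cfg.seed, chosen_c)
    sigma_r = max(cfg.rcsa_noise_ppb, 1e-9)
    rcsa = [RCSARecord(c, 0.0, sigma_r, shieldings[c]) for c in chosen_c]
    clean_r = rcsa_back_calculate(rcsa, S)
    noise_r = rng.normal(0.0, cfg.rcsa_noise_ppb, size=len(rcsa)) if cfg.rcsa_noise_ppb else 0.0
    for rec, v in zip(rcsa, clean_r + noise_r):
        rec.rcsa_obs_ppb = float(v)
    return rdc, rcsa, shieldings


# --------------------------------------------------------------------------
# decoy structures


def _cycle_bonds(g: MoleculeGraph) -> list[tuple[int, int]]:
    import networkx as nx
    out = []
    for i, j, _ in g.bonds:
        h = g.nx_graph.copy()
        h.remove_edge(i, j)
        if nx.is_connected(h):
            out.append((i, j))
    return out


def _delete_bond(g: MoleculeGraph, seed: int,
                 bond: tuple[str, str] | None = None) -> MoleculeGraph:
    if bond is not None:
        i, j = g.atom_of(bond[0]), g.atom_of(bond[1])
    else:
        candidates = [(i, j) for i, j in _cycle_bonds(g)
                      if g.element(i) != "H" and g.element(j) != "H"]
        if not candidates:
            raise StructureError("no ring bond available to delete")
        i, j = candidates[np.random.default_rng(seed).integers(len(candidates))]
    new = g.copy()
    before = len(new.bonds)
    new.bonds = [b for b in new.bonds if {b[0], b[1]} != {i, j}]
    if len(new.bonds) == before:
        raise StructureError(f"no bond between atoms {i} and {j}")
    new._nx = None
    new.name = (g.name or "structure") + "_delbond"
    new.validate(require_connected=True)
    return new


def _swap_halogen(g: MoleculeGraph, seed: int,
                  carbons: tuple[str, str] | None = None) -> MoleculeGraph:
    halogens = {"F", "Cl", "Br", "I"}
    if carbons is not None:
        c_from, c_to = g.atom_of(carbons[0]), g.atom_of(carbons[1])
    else:
        options = []
        for lbl, idx in sorted(g.labels.items()):
            if g.element(idx) != "C":
                continue
            if any(g.element(j) in halogens for j in g.neighbors(idx)):
                for j in g.neighbors(idx):
                    if g.element(j) == "C" and g.hydrogens_of(j):
                        options.append((idx, j))
        if not options:
            raise StructureError("no adjacent C(Hal)/C(H) pair to swap")
        c_from, c_to = options[np.random.default_rng(seed).integers(len(options))]
    hal = next((j for j in g.neighbors(c_from) if g.element(j) in halogens), None)
    hyd = next(iter(g.hydrogens_of(c_to)), None)
    if hal is None or hyd is None:
        raise StructureError("swap_halogen needs a halogen on one carbon and "
                             "an H on the other")
    new = g.copy()

    def rebond(old_nb, old_c, new_c):
        for k, (a, b, o) in enumerate(new.bonds):
            if {a, b} == {old_nb, old_c}:
                new.bonds[k] = (old_nb, new_c, o)
                return
        raise StructureError("bond bookkeeping failure")

    rebond(hal, c_from, c_to)
    rebond(hyd, c_to, c_from)
    if new.has_coordinates():
        xyz = new.coordinates()
        u_from = xyz[hal] - xyz[c_from]
        u_from /= np.linalg.norm(u_from)
        u_to = xyz[hyd] - xyz[c_to]
        u_to /= np.linalg.norm(u_to)
        bond_len = {"F": 1.35, "Cl": 1.74, "Br": 1.90, "I": 2.10}
        new.atoms[hal].coords = xyz[c_to] + u_to * bond_len.get(g.element(hal), 1.8)
        new.atoms[hyd].coords = xyz[c_from] + u_from * 1.09
    new._nx = None
    new.name = (g.name or "structure") + "_halswap"
    return new


def _invert_stereocenters(g: MoleculeGraph, seed: int,
                          centers: list[str] | None = None) -> MoleculeGraph:
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = g.to_rdkit()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        pass
    Chem.AssignStereochemistryFrom3D(mol)
    if centers is None:
        idxs = [a.GetIdx() for a in mol.GetAtoms()
                if a.GetChiralTag() in (Chem.ChiralType.CHI_TETRAHEDRAL_CW,
                                        Chem.ChiralType.CHI_TETRAHEDRAL_CCW)]
        if not idxs:
            raise StructureError("no stereocentres to invert")
        idxs = [idxs[int(np.random.default_rng(seed).integers(len(idxs)))]]
        centers_tag = "-".join(str(i) for i in idxs)
    else:
        idxs = [g.atom_of(c) for c in centers]
        centers_tag = "-".join(centers)
    flip = {Chem.ChiralType.CHI_TETRAHEDRAL_CW: Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
            Chem.ChiralType.CHI_TETRAHEDRAL_CCW: Chem.ChiralType.CHI_TETRAHEDRAL_CW}
    for i in idxs:
        atom = mol.GetAtomWithIdx(i)
        tag = atom.GetChiralTag()
        if tag not in flip:
            raise StructureError(f"atom {i} is not a resolvable stereocentre")
        atom.SetChiralTag(flip[tag])
    ps = AllChem.ETKDGv3()
    ps.randomSeed = int(seed) % (2**31 - 1)
    mol_h = Chem.Mol(mol)
    if AllChem.EmbedMolecule(mol_h, ps) != 0:
        ps.useRandomCoords = True
        if AllChem.EmbedMolecule(mol_h, ps) != 0:
            raise StructureError("re-embedding of stereo-inverted structure failed")
    try:
        AllChem.MMFFOptimizeMolecule(mol_h, maxIters=500)
    except Exception:
        pass
    new = MoleculeGraph.from_rdkit(mol_h, g.labels,
                                   name=(g.name or "structure")
                                   + f"_epi{centers_tag}")
    return new


def reembed(g: MoleculeGraph, seed: int = 0, optimize: bool = True) -> MoleculeGraph:
    """Regenerate 3D coordinates for a graph (ETKDG, seeded; MMFF-relaxed).

    Used to give a decoy its own independently modelled conformer, the way
    each candidate in a structure-verification study is modelled separately
    rather than inheriting the reference geometry.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = g.to_rdkit()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        pass
    ps = AllChem.ETKDGv3()
    ps.randomSeed = int(seed) % (2**31 - 1)
    if AllChem.EmbedMolecule(mol, ps) != 0:
        ps.useRandomCoords = True
        if AllChem.EmbedMolecule(mol, ps) != 0:
            raise StructureError("re-embedding failed")
    if optimize:
        try:
            AllChem.MMFFOptimizeMolecule(mol, maxIters=2000)
        except Exception:
            pass
    new = MoleculeGraph.from_rdkit(mol, g.labels, name=g.name)
    return new


def _mirror_all(g: MoleculeGraph) -> MoleculeGraph:
    new = g.copy()
    for a in new.atoms:
        if a.coords is not None:
            a.coords = -a.coords
    new.name = (g.name or "structure") + "_ent"
    return new


def gen_decoys(g: MoleculeGraph, mode: str, seed: int = 0,
               **options) -> list[MoleculeGraph]:
    """Decoy structures sharing the position-label vocabulary of ``g``.

    Modes: ``delete_bond`` (constitutional, removes a ring bond — pass
    ``bond=("22","23")`` to choose), ``swap_halogen_positions``
    (constitutional, exchanges a halogen with an adjacent aromatic H — pass
    ``carbons=("7","6")``), ``invert_stereocenters`` (configurational:
    flips chiral tags and re-embeds 3D coordinates — pass
    ``centers=["11"]``), ``mirror_all`` (enantiomer: negates coordinates).
    """
    if mode == "delete_bond":
        return [_delete_bond(g, seed, options.get("bond"))]
    if mode == "swap_halogen_positions":
        return [_swap_halogen(g, seed, options.get("carbons"))]
    if mode == "invert_stereocenters":
        return [_invert_stereocenters(g, seed, options.get("centers"))]
    if mode == "mirror_all":
        return [_mirror_all(g)]
    raise ValueError(f"unknown decoy mode {mode!r}")


# --------------------------------------------------------------------------
# correlation tables


def gen_correlation_table(g: MoleculeGraph, experiment: Experiment | str,
                          bond_range: set[int], dropout: float = 0.0,
                          seed: int = 0) -> CorrelationSet:
    """All H(position) -> heavy(position) pairs whose bond count falls in
    ``bond_range``, each retained with probability ``1 - dropout``.

    Targets are carbons, except HMBC_NH where they are nitrogens.  COSY
    bond counts are proton-to-proton.
    """
    experiment = Experiment(experiment)
    if not bond_range:
        raise ValueError("bond range must be non-empty")
    if not 0.0 <= dropout < 1.0:
        raise ValueError("dropout must be in [0, 1)")
    import networkx as nx

    rng = np.random.default_rng(seed)
    heavy_labels = {lbl: idx for lbl, idx in g.labels.items()
                    if g.element(idx) != "H"}
    from_labels = []
    for lbl, idx in sorted(heavy_labels.items()):
        if g.element(idx) == "C" and g.hydrogens_of(idx):
            from_labels.append(lbl)
    target_el = "N" if experiment is Experiment.HMBC_NH else "C"
    pairs = []
    for frm in from_labels:
        protons = g.protons_of(frm)
        dist = {}
        for h in protons:
            for node, d in nx.single_source_shortest_path_length(
                    g.nx_graph, h, cutoff=max(bond_range)).items():
                dist[node] = min(dist.get(node, 99), d)
        for to, t_idx in sorted(heavy_labels.items()):
            if g.element(t_idx) != target_el:
                continue
            if experiment is Experiment.COSY:
                if to == frm:
                    continue
                hs = g.hydrogens_of(t_idx)
                if not hs:
                    continue
                n = min((dist.get(h, 99) for h in hs), default=99)
            else:
                n = dist.get(t_idx, 99)
            if n in bond_range and (dropout == 0.0 or rng.random() >= dropout):
                pairs.append((frm, to))
    return CorrelationSet(experiment, pairs)
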