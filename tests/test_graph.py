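"""Molecular-graph I/O, bond-path lengths, and correlation classification."""

from collections import deque

import numpy as np
import pytest

from anisoverify.datasets import load_correlations
from anisoverify.graph import (MoleculeGraph, StructureError, bond_path_length,
                               classify_correlations,
                               compare_candidates_by_consistency,
                               noe_distance_check, read_structure)
from anisoverify.tables import CorrelationSet, Experiment


def bfs_oracle(n_atoms, bonds, a, b):
    """Independent breadth-first search over an adjacency list."""
    adj = {i: [] for i in range(n_atoms)}
    for i, j, *_ in bonds:
        adj[i].append(j)
        adj[j].append(i)
    seen, queue = {a: 0}, deque([a])
    while queue:
        x = queue.popleft()
        if x == b:
            return seen[x]
        for y in adj[x]:
            if y not in seen:
                seen[y] = seen[x] + 1
                queue.append(y)
    return -1


class TestReadStructure:
    def test_caulamidine_fixture_composition(self, caulamidine):
        counts = caulamidine.heavy_formula_counts()
        assert counts == {"C": 23, "N": 4, "Cl": 3, "H": 21}
        assert caulamidine.has_coordinates()
        caulamidine.validate()

    def test_methane_sdf(self, tmp_path):
        from rdkit import Chem
        from rdkit.Chem import AllChem

        mol = Chem.AddHs(Chem.MolFromSmiles("C"))
        AllChem.EmbedMolecule(mol, randomSeed=7)
        p = tmp_path / "methane.sdf"
        Chem.MolToMolFile(mol, str(p))
        g = read_structure(p)
        assert g.heavy_formula_counts() == {"C": 1, "H": 4}
        assert len(g.bonds) == 4

    def test_pentavalent_carbon_rejected(self, tmp_path):
        block = (
            "bad\n     RDKit          3D\n\n"
            "  6  5  0  0  0  0  0  0  0  0999 V2000\n"
            + "    0.0000    0.0000    0.0000 C   0  0\n"
            + "".join(f"    1.0000    {i}.0000    0.0000 H   0  0\n"
                      for i in range(5))
            + "".join(f"  1  {i}  1  0\n" for i in range(2, 7))
            + "M  END\n")
        p = tmp_path / "bad.mol"
        p.write_text(block)
        with pytest.raises(StructureError):
            read_structure(p)

    def test_xyz_with_bond_list(self, tmp_path):
        xyz = tmp_path / "hcl.xyz"
        xyz.write_text("2\nhydrogen chloride\nCl 0 0 0\nH 0 0 1.27\n")
        bonds = tmp_path / "bonds.csv"
        bonds.write_text("a,b\n0,1\n")
        g = read_structure(xyz, bond_list=bonds)
        assert g.heavy_formula_counts() == {"Cl": 1, "H": 1}

    def test_disconnected_rejected(self, tmp_path):
        xyz = tmp_path / "two.xyz"
        xyz.write_text("2\ntwo atoms\nC 0 0 0\nC 5 0 0\n")
        bonds = tmp_path / "bonds.csv"
        bonds.write_text("a,b\n")
        with pytest.raises(StructureError, match="disconnected"):
            read_structure(xyz, bond_list=bonds)


class TestBondPathLength:
    def test_benzene_para(self, benzene):
        assert bond_path_length(benzene, "1", "4") == 3

    def test_identity_is_zero(self, benzene):
        assert bond_path_length(benzene, "3", "3") == 0

    def test_h26_to_amidine_carbon(self, caulamidine):
        # the N-methyl protons reach the amidine carbon through the nitrogen
        h26 = caulamidine.protons_of("26")[0]
        assert bond_path_length(caulamidine, h26, "2") == 3

    @pytest.mark.parametrize("trial", range(20))
    def test_symmetry_and_triangle_inequality_random_graphs(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(4, 12))
        # random connected graph: spanning tree + extra edges
        bonds = [(int(rng.integers(0, i)), i, 1.0) for i in range(1, n)]
        for _ in range(int(rng.integers(0, n))):
            i, j = rng.integers(0, n, 2)
            if i != j and not any({a, b} == {int(i), int(j)} for a, b, _ in bonds):
                bonds.append((int(i), int(j), 1.0))
        from anisoverify.graph import Atom
        g = MoleculeGraph([Atom(i, "C") for i in range(n)], bonds)
        for _ in range(15):
            a, b, c = (int(x) for x in rng.integers(0, n, 3))
            dab = bond_path_length(g, a, b)
            assert dab == bfs_oracle(n, bonds, a, b)
            assert dab == bond_path_length(g, b, a)
            assert dab <= bond_path_length(g, a, c) + bond_path_length(g, c, b)


class TestClassifyCorrelations:
    def test_full_hmbc_fixture_consistent(self, caulamidine, correlations):
        for key in ("HMBC_CH", "HMBC_NH"):
            rep = classify_correlations(caulamidine, correlations[key])
            assert rep.counts["violation"] == 0
            assert rep.counts["unreachable"] == 0
            assert len(rep.records) == len(correlations[key].pairs)

    def test_oracle_agreement_on_hmbc(self, caulamidine, correlations):
        # independent all-pairs shortest-path classification
        bonds = caulamidine.bonds
        n = len(caulamidine.atoms)
        for rec in classify_correlations(caulamidine,
                                         correlations["HMBC_CH"]).records:
            protons = caulamidine.protons_of(rec.from_position)
            target = caulamidine.atom_of(rec.to_position)
            oracle = min(bfs_oracle(n, bonds, h, target) for h in protons)
            assert rec.bond_count == oracle
            assert rec.verdict == ("expected" if oracle in (2, 3)
                                   else "tolerated" if oracle == 4 else "violation")

    def test_hsqc_identity(self, caulamidine):
        cs = CorrelationSet(Experiment.HSQC, [("11", "11")])
        rep = classify_correlations(caulamidine, cs)
        assert rep.records[0].bond_count == 1
        assert rep.records[0].verdict == "expected"

    def test_adequate_h5_to_c4(self, caulamidine):
        # one-bond C-C connectivity: H at C-5 sees the adjacent quaternary C-4
        cs = CorrelationSet(Experiment.ADEQUATE_1_1, [("5", "4")])
        rep = classify_correlations(caulamidine, cs)
        assert rep.records[0].bond_count == 2
        assert rep.records[0].verdict == "expected"

    def test_all_fixture_experiments_pass(self, caulamidine):
        for cs in load_correlations():
            if cs.experiment in (Experiment.NOESY, Experiment.ROESY):
                rep = noe_distance_check(caulamidine, cs)
            else:
                rep = classify_correlations(caulamidine, cs)
            assert rep.counts["violation"] == 0, cs.experiment
            assert rep.counts["unreachable"] == 0

    def test_record_count_conservation(self, caulamidine, correlations):
        for cs in correlations.values():
            if cs.experiment in (Experiment.NOESY, Experiment.ROESY):
                continue
            rep = classify_correlations(caulamidine, cs)
            assert len(rep.records) == len(cs.pairs)

    def test_synthetic_round_trip_zero_violations(self, caulamidine):
        from anisoverify.synth import gen_correlation_table

        cs = gen_correlation_table(caulamidine, Experiment.HMBC_CH,
                                   bond_range={2, 3}, seed=5)
        rep = classify_correlations(caulamidine, cs)
        assert rep.counts["violation"] == 0
        assert rep.counts["tolerated"] == 0


class TestNOEDistanceCheck:
    def test_fixture_noe_contacts_within_cutoff(self, caulamidine, correlations):
        rep = noe_distance_check(caulamidine, correlations["NOESY"])
        assert all(r.verdict == "expected" for r in rep.records)
        assert all(r.distance_A <= 5.0 for r in rep.records)

    def test_cutoff_behaviour(self):
        from anisoverify.graph import Atom

        atoms = [Atom(0, "C", "1", np.zeros(3)), Atom(1, "H", None, np.array([1.09, 0, 0])),
                 Atom(2, "C", "2", np.array([0, 3.0, 0])), Atom(3, "H", None, np.array([1.09, 3.0, 0])),
                 Atom(4, "C", None, np.array([0, 1.5, 0]))]
        bonds = [(0, 1, 1.0), (2, 3, 1.0), (0, 4, 1.0), (2, 4, 1.0)]
        g = MoleculeGraph(atoms, bonds, {"1": 0, "2": 2})
        cs = CorrelationSet(Experiment.NOESY, [("1", "2")])
        assert noe_distance_check(g, cs, cutoff_A=5.0).records[0].verdict == "expected"
        assert noe_distance_check(g, cs, cutoff_A=2.0).records[0].verdict == "violation"

    def test_requires_coordinates(self, benzene):
        cs = CorrelationSet(Experiment.NOESY, [("1", "2")])
        with pytest.raises(StructureError, match="coordinates"):
            noe_distance_check(benzene, cs)


class TestCompareCandidates:
    def test_bond_deleted_decoy_ranks_below_true(self, caulamidine, correlations):
        from anisoverify.synth import gen_decoys

        decoy = gen_decoys(caulamidine, "delete_bond", bond=("22", "23"))[0]
        data = [correlations["HMBC_CH"], correlations["HMBC_NH"]]
        ranked = compare_candidates_by_consistency([decoy, caulamidine], data)
        assert ranked[0][0] is caulamidine
        assert ranked[1][1]["violation"] >= 1

    def test_single_candidate(self, caulamidine, correlations):
        ranked = compare_candidates_by_consistency(
            [caulamidine], [correlations["HMBC_CH"]])
        assert len(ranked) == 1

    def test_identical_candidates_keep_input_order(self, caulamidine, correlations):
        twin = caulamidine.copy()
        twin.name = "twin"
        ranked = compare_candidates_by_consistency(
            [caulamidine, twin], [correlations["HMBC_CH"]])
        assert [g.name for g, _ in ranked] == ["caulamidine_A", "twin"]
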