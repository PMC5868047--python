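"""Regenerate the packaged caulamidine A fixture files.

Writes, under ``src/anisoverify/data/``:

* ``caulamidine_a.sdf`` — the (10S,11S,23S) conformer (ETKDG seed 2024,
  MMFF-relaxed) with explicit hydrogens;
* ``caulamidine_a_labels.csv`` — position -> atom-index map, including
  geometric a/b labels for the diastereotopic CH2 protons chosen so the
  reported NOE contacts (H-8/H-22a, H-11/H-24a, H-22b/H-24b) are
  internally consistent on this conformer;
* ``caulamidine_a_assignments.csv`` — the published assignment table;
* ``caulamidine_a_correlations.csv`` — typed correlation sets.

Run from the repository root: ``python scripts/make_fixtures.py``.
"""
from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from rdkit import Chem  # noqa: E402

from anisoverify.datasets import build_caulamidine_a  # noqa: E402

DATA = ROOT / "src" / "anisoverify" / "data"
DATA.mkdir(parents=True, exist_ok=True)


def hydrogens(mol, idx):
    return [n.GetIdx() for n in mol.GetAtomWithIdx(idx).GetNeighbors()
            if n.GetSymbol() == "H"]


def main() -> None:
    mol, idx = build_caulamidine_a(embed_seed=2024)
    Chem.MolToMolFile(mol, str(DATA / "caulamidine_a.sdf"))

    P = mol.GetConformer().GetPositions()

    def closest(h_candidates, ref_h):
        return min(h_candidates, key=lambda h: np.linalg.norm(P[h] - P[ref_h]))

    h8 = hydrogens(mol, idx["8"])[0]
    h11 = hydrogens(mol, idx["11"])[0]
    h22 = hydrogens(mol, idx["22"])
    h24 = hydrogens(mol, idx["24"])
    h12 = sorted(hydrogens(mol, idx["12"]))
    h25 = sorted(hydrogens(mol, idx["25"]))

    # geometric a/b choice consistent with the reported NOE set
    h22a = closest(h22, h8)
    h22b = next(h for h in h22 if h != h22a)
    h24a = closest(h24, h11)
    h24b = next(h for h in h24 if h != h24a)
    assert np.linalg.norm(P[h22b] - P[h24b]) <= 5.0, "NOE 22b/24b inconsistent"

    labels = {pos: i for pos, i in idx.items()}
    labels.update({"12a": h12[0], "12b": h12[1], "25a": h25[0], "25b": h25[1],
                   "22a": h22a, "22b": h22b, "24a": h24a, "24b": h24b})
    pd.DataFrame(sorted(labels.items()), columns=["position", "atom_index"]) \
        .to_csv(DATA / "caulamidine_a_labels.csv", index=False)

    # ---- assignment table (published values) -----------------------------
    A = [  # position, carbon_of, dC, dN, dH, mult, J, nH
        ("1-N", "", "", 78.9, "", "", "", 0),
        ("2", "", 174.0, "", "", "", "", 0),
        ("3-N", "", "", 241.7, "", "", "", 0),
        ("4", "", 156.0, "", "", "", "", 0),
        ("5", "", 117.8, "", 7.17, "d", "8.5", 1),
        ("6", "", 129.4, "", 7.31, "dd", "8.4;2.0", 1),
        ("7", "", 126.3, "", "", "", "", 0),
        ("8", "", 123.8, "", 6.95, "bs", "", 1),
        ("9", "", 133.3, "", "", "", "", 0),
        ("10", "", 58.9, "", "", "", "", 0),
        ("11", "", 54.8, "", 5.02, "dd", "10.8;4.7", 1),
        ("12a", "12", 52.6, "", 3.87, "dd", "13.3;6.6", 1),
        ("12b", "12", "", "", 3.66, "dd", "13.3;10.5", 1),
        ("13-N", "", "", 87.5, "", "", "", 0),
        ("14", "", 159.1, "", "", "", "", 0),
        ("15-N", "", "", 216.6, "", "", "", 0),
        ("16", "", 143.9, "", "", "", "", 0),
        ("17", "", 124.2, "", 6.94, "d", "8.2", 1),
        ("18", "", 127.2, "", 7.12, "dd", "8.2;2.4", 1),
        ("19", "", 125.8, "", "", "", "", 0),
        ("20", "", 127.3, "", 6.96, "s", "", 1),
        ("21", "", 125.4, "", "", "", "", 0),
        ("22a", "22", 29.6, "", 2.48, "d", "15.9", 1),
        ("22b", "22", "", "", 2.28, "d", "15.9", 1),
        ("23", "", 39.8, "", "", "", "", 0),
        ("24a", "24", 24.7, "", 2.25, "m", "", 1),
        ("24b", "24", "", "", 1.73, "dd", "15.0;6.2", 1),
        ("25a", "25", 47.4, "", 3.38, "ddd", "12.5;7.5;1.6", 1),
        ("25b", "25", "", "", 3.18, "dt", "11.7;5.9", 1),
        ("26", "", 37.2, "", 3.00, "s", "", 3),
        ("27", "", 35.8, "", 3.24, "s", "", 3),
    ]
    pd.DataFrame(A, columns=["position", "carbon_of", "delta_C", "delta_N",
                             "delta_H", "mult", "J", "nH"]) \
        .to_csv(DATA / "caulamidine_a_assignments.csv", index=False)

    # ---- correlations ----------------------------------------------------
    HMBC = {  # published HMBC column; targets split CH / NH by element
        "5": ["3-N", "4", "6", "7", "9"], "6": ["4", "5", "7", "8"],
        "8": ["4", "6", "7", "10"],
        "11": ["2", "9", "10", "12", "23"],
        "12a": ["11", "13-N", "14", "15-N", "27"],
        "12b": ["11", "13-N", "14", "15-N"],
        "17": ["15-N", "16", "19", "21"], "18": ["16", "19"],
        "20": ["16", "18", "19", "21", "22"],
        "22a": ["10", "14", "16", "21", "23", "24"],
        "22b": ["10", "13-N", "14", "16", "21", "23", "24"],
        "24a": ["10", "14", "22", "23", "25"],
        "24b": ["1-N", "10", "22", "23", "25"],
        "25a": ["2", "3-N", "24"], "25b": ["24", "26"],
        "26": ["1-N", "2", "3-N", "25"], "27": ["12", "13-N", "14", "15-N"],
    }
    rows = []
    for frm, tgts in HMBC.items():
        for to in tgts:
            exp = "HMBC_NH" if to.endswith("-N") else "HMBC_CH"
            rows.append((exp, frm, to))
    for frm in ["5", "6", "8", "11", "17", "18", "20", "26", "27"]:
        rows.append(("HSQC", frm, frm))
    for frm in ["12a", "12b", "22a", "22b", "24a", "24b", "25a", "25b"]:
        rows.append(("HSQC", frm, frm[:-1]))
    rows += [("COSY", a, b) for a, b in [
        ("5", "6"), ("6", "8"), ("12a", "11"), ("12b", "11"),
        ("25a", "24"), ("25b", "24"), ("12a", "12"), ("22a", "22")]]
    rows += [("LR_HSQMBC", a, b) for a, b in [
        ("26", "24"), ("5", "10"), ("8", "11"), ("17", "14"), ("20", "23"),
        ("22a", "25"), ("11", "14"), ("24a", "11"), ("26", "10"),
        ("5", "11"), ("6", "9")]]
    rows += [("HSQMBC_TOCSY", a, b) for a, b in [
        ("11", "27"), ("12a", "9"), ("5", "8"), ("6", "4"), ("25b", "23")]]
    rows += [("ADEQUATE_1_1", a, b) for a, b in [
        ("5", "4"), ("8", "9"), ("11", "10"), ("17", "16"), ("20", "21"),
        ("22a", "23"), ("24a", "23"), ("12a", "11")]]
    rows += [("NOESY", a, b) for a, b in [
        ("8", "22a"), ("11", "24a"), ("22b", "24b")]]
    pd.DataFrame(rows, columns=["experiment", "from", "to"]) \
        .to_csv(DATA / "caulamidine_a_correlations.csv", index=False)

    # ---- self-check ------------------------------------------------------
    from anisoverify.datasets import load_caulamidine_a, load_correlations
    from anisoverify.graph import classify_correlations, noe_distance_check
    from anisoverify.tables import Experiment

    g = load_caulamidine_a()
    for cs in load_correlations():
        if cs.experiment in (Experiment.NOESY, Experiment.ROESY):
            rep = noe_distance_check(g, cs)
        else:
            rep = classify_correlations(g, cs)
        print(cs.experiment.value, rep.counts)
        assert rep.counts["violation"] == 0, (cs.experiment, rep.records)
        assert rep.counts["unreachable"] == 0


if __name__ == "__main__":
    main()
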