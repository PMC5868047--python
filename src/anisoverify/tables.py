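"""Assignment tables and typed 2D-correlation lists.

The data model mirrors how tabulated NMR data for a small molecule is
printed: one row per position label (heavy atom or individual diastereotopic
proton site, e.g. ``"12a"``/``"12b"``; nitrogens carry an ``"-N"`` suffix,
e.g. ``"1-N"``), plus per-experiment lists of (from-H, to-heavy-atom)
correlations.  Position labels are plain strings; diastereotopic proton rows
point at their carbon through the ``carbon_of`` column.

CSV schemas (UTF-8, comma-separated, ``.`` decimal, header mandatory):

* assignments: ``position, carbon_of, delta_C, delta_N, delta_H, mult, J, nH``
  (``J`` is a ``;``-separated Hz list; empty cells allowed)
* correlations: ``experiment, from, to``
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd


class Experiment(str, Enum):
    HSQC = "HSQC"
    HMBC_CH = "HMBC_CH"
    HMBC_NH = "HMBC_NH"
    COSY = "COSY"
    LR_HSQMBC = "LR_HSQMBC"
    HSQMBC_TOCSY = "HSQMBC_TOCSY"
    ADEQUATE_1_1 = "ADEQUATE_1_1"
    NOESY = "NOESY"
    ROESY = "ROESY"


class TableError(ValueError):
    """Malformed assignment or correlation table."""


def carbon_of_position(position: str) -> str:
    """Carbon label owning a proton-site label: ``"12a" -> "12"``."""
    if len(position) > 1 and position[-1] in "ab" and position[:-1].isdigit():
        return position[:-1]
    return position


@dataclass
class AssignmentRow:
    position: str
    delta_C: float | None = None
    delta_N: float | None = None
    delta_H: float | None = None
    multiplicity: str | None = None
    couplings_Hz: list[float] = field(default_factory=list)
    proton_count: int = 0
    carbon_of: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.delta_C is None and self.delta_N is None and self.delta_H is None:
            raise TableError(f"row {self.position!r}: needs at least one shift")
        if any(j <= 0 for j in self.couplings_Hz):
            raise TableError(f"row {self.position!r}: couplings must be > 0 Hz")
        if self.proton_count < 0:
            raise TableError(f"row {self.position!r}: negative proton count")


@dataclass
class CorrelationSet:
    """Deduplicated (from-H-position, to-heavy-position) pairs of one experiment."""

    experiment: Experiment
    pairs: list[tuple[str, str]]
    optimization_Hz: float | None = None

    def __post_init__(self) -> None:
        self.experiment = Experiment(self.experiment)
        seen, out = set(), []
        for a, b in self.pairs:
            key = (str(a), str(b))
            if key not in seen:
                seen.add(key)
                out.append(key)
        self.pairs = out

    def __len__(self) -> int:
        return len(self.pairs)


def _opt_float(cell) -> float | None:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return None
    try:
        return float(cell)
    except (TypeError, ValueError) as exc:
        raise TableError(f"non-numeric shift cell {cell!r}") from exc


def read_assignment_table(path: str | Path) -> list[AssignmentRow]:
    """Read an assignment table from CSV (or a JSON mirror of the rows)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
        records = raw["rows"] if isinstance(raw, dict) else raw
        df = pd.DataFrame(records)
    else:
        try:
            df = pd.read_csv(path, dtype=str, keep_default_na=False)
        except pd.errors.EmptyDataError as exc:
            raise TableError("missing position column (empty file)") from exc
    if "position" not in df.columns:
        raise TableError("missing position column")
    rows: list[AssignmentRow] = []
    seen: set[str] = set()
    for rec in df.to_dict("records"):
        pos = str(rec["position"]).strip()
        if not pos:
            raise TableError("empty position label")
        if pos in seen:
            raise TableError(f"duplicate position label {pos!r}")
        seen.add(pos)
        j_cell = str(rec.get("J", "") or "")
        couplings = [float(tok) for tok in j_cell.replace(",", ";").split(";") if tok.strip()]
        nh_cell = str(rec.get("nH", "") or "").strip()
        carbon = str(rec.get("carbon_of", "") or "").strip() or None
        rows.append(AssignmentRow(
            position=pos,
            delta_C=_opt_float(rec.get("delta_C")),
            delta_N=_opt_float(rec.get("delta_N")),
            delta_H=_opt_float(rec.get("delta_H")),
            multiplicity=(str(rec.get("mult", "") or "").strip() or None),
            couplings_Hz=couplings,
            proton_count=int(nh_cell) if nh_cell else (1 if _opt_float(rec.get("delta_H")) is not None else 0),
            carbon_of=carbon,
        ))
    return rows


def write_assignment_table(rows: list[AssignmentRow], path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame([
        {
            "position": r.position,
            "carbon_of": r.carbon_of or "",
            "delta_C": "" if r.delta_C is None else r.delta_C,
            "delta_N": "" if r.delta_N is None else r.delta_N,
            "delta_H": "" if r.delta_H is None else r.delta_H,
            "mult": r.multiplicity or "",
            "J": ";".join(format(j, "g") for j in r.couplings_Hz),
            "nH": r.proton_count,
        }
        for r in rows
    ])
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps({"rows": df.to_dict("records")}, indent=1))
    else:
        df.to_csv(path, index=False)


def read_correlations(path: str | Path,
                      experiment: Experiment | str | None = None,
                      assignments: list[AssignmentRow] | None = None,
                      ) -> list[CorrelationSet]:
    """Read correlation CSV rows, grouped per experiment.

    If ``experiment`` is given, only that experiment's rows are returned
    (still as a one-element list when present; an empty ``experiment``
    column defaults to the requested experiment).  With ``assignments``,
    referential integrity is enforced: every position must resolve, and the
    from-position of an H-detected experiment must carry at least one proton.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("from", "to"):
        if col not in df.columns:
            raise TableError(f"missing {col!r} column")
    if "experiment" not in df.columns:
        if experiment is None:
            raise TableError("missing experiment column and no experiment given")
        df["experiment"] = Experiment(experiment).value
    df.loc[df["experiment"] == "", "experiment"] = (
        Experiment(experiment).value if experiment is not None else "")
    sets: list[CorrelationSet] = []
    for exp_name, grp in df.groupby("experiment", sort=False):
        exp = Experiment(exp_name)
        if experiment is not None and exp != Experiment(experiment):
            continue
        pairs = [(str(a).strip(), str(b).strip()) for a, b in zip(grp["from"], grp["to"])]
        cs = CorrelationSet(exp, pairs)
        if assignments is not None:
            validate_correlations(cs, assignments)
        sets.append(cs)
    return sets


def write_correlations(sets: list[CorrelationSet], path: str | Path) -> None:
    recs = [
        {"experiment": cs.experiment.value, "from": a, "to": b}
        for cs in sets for a, b in cs.pairs
    ]
    pd.DataFrame(recs, columns=["experiment", "from", "to"]).to_csv(path, index=False)


_H_DETECTED = {
    Experiment.HSQC, Experiment.HMBC_CH, Experiment.HMBC_NH, Experiment.COSY,
    Experiment.LR_HSQMBC, Experiment.HSQMBC_TOCSY, Experiment.ADEQUATE_1_1,
    Experiment.NOESY, Experiment.ROESY,
}


def validate_correlations(cs: CorrelationSet, assignments: list[AssignmentRow]) -> None:
    """Referential-integrity check of a correlation set against a table."""
    by_pos = {r.position: r for r in assignments}
    protons_of: dict[str, int] = {}
    known = set(by_pos)
    for r in assignments:
        carbon = r.carbon_of or carbon_of_position(r.position)
        known.add(carbon)
        protons_of[carbon] = protons_of.get(carbon, 0) + r.proton_count
    for a, b in cs.pairs:
        for pos in (a, b):
            if pos not in known and carbon_of_position(pos) not in known:
                raise TableError(
                    f"{cs.experiment.value}: position {pos!r} not in assignment table")
        if cs.experiment in _H_DETECTED:
            row = by_pos.get(a)
            n_h = row.proton_count if row is not None and row.proton_count else \
                protons_of.get(carbon_of_position(a), 0)
            if n_h == 0:
                raise TableError(
                    f"{cs.experiment.value}: from-position {a!r} carries no protons")


def shift_delta_report(exp_rows: list[AssignmentRow],
                       calc_shifts: dict[str, float],
                       ) -> list[tuple[str, float, float, float]]:
    """Per-position (position, exp, calc, exp - calc) carbon-shift deviations."""
    by_pos = {r.position: r for r in exp_rows}
    out = []
    for pos, calc in calc_shifts.items():
        row = by_pos.get(pos)
        if row is None or row.delta_C is None:
            raise TableError(f"position {pos!r} has no experimental delta_C")
        out.append((pos, row.delta_C, float(calc), row.delta_C - float(calc)))
    return out
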