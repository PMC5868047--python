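"""Agreement statistics between experimental and computed chemical shifts.

Complementary to the anisotropic Q factor: simple per-position deviation
statistics (MAE, RMSD, maximum deviation) between an experimental shift set
and a candidate's computed shifts, optionally after an ordinary
least-squares linear rescaling of the computed values (slope/intercept),
which absorbs systematic method/reference offsets.  Candidates are ranked
ascending by a configurable statistic; the correct structure is expected to
give the smallest deviations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _st


@dataclass
class ShiftComparison:
    n: int
    mae: float
    rmsd: float
    max_abs_dev: float
    slope: float
    intercept: float
    corrected_mae: float
    corrected_rmsd: float
    corrected_max_abs_dev: float

    def statistic(self, name: str) -> float:
        try:
            return float(getattr(self, name))
        except AttributeError as exc:
            raise ValueError(f"unknown statistic {name!r}") from exc


def _shared(exp: dict[str, float], calc: dict[str, float]) -> tuple[np.ndarray, np.ndarray]:
    keys = [k for k in exp if k in calc]
    if len(keys) != len(set(keys)):
        raise ValueError("duplicate position labels")
    if len(keys) < 2:
        raise ValueError("need at least 2 shared positions")
    e = np.array([float(exp[k]) for k in keys])
    c = np.array([float(calc[k]) for k in keys])
    return e, c


def compare_shift_sets(exp: dict[str, float], calc: dict[str, float],
                       rescale: bool = True) -> ShiftComparison:
    """Deviation statistics over positions shared by both shift sets.

    With ``rescale``, computed shifts are replaced by
    ``slope * calc + intercept`` from an OLS regression of exp on calc
    before the ``corrected_*`` statistics; least squares minimizes the
    squared error, so corrected RMSD never exceeds the raw RMSD (the
    corrected MAE may).
    """
    e, c = _shared(exp, calc)
    dev = e - c
    if rescale and np.ptp(c) > 0:
        fit = _st.linregress(c, e)
        slope, intercept = float(fit.slope), float(fit.intercept)
    else:
        slope, intercept = 1.0, 0.0
    cdev = e - (slope * c + intercept)
    return ShiftComparison(
        n=e.size,
        mae=float(np.mean(np.abs(dev))),
        rmsd=float(np.sqrt(np.mean(dev**2))),
        max_abs_dev=float(np.max(np.abs(dev))),
        slope=slope,
        intercept=intercept,
        corrected_mae=float(np.mean(np.abs(cdev))),
        corrected_rmsd=float(np.sqrt(np.mean(cdev**2))),
        corrected_max_abs_dev=float(np.max(np.abs(cdev))),
    )


def d_custom(exp: dict[str, float], calc: dict[str, float]) -> float:
    """Plain ``sqrt(sum (dd)^2 / n)`` deviation, no rescaling.

    Provided as an explicitly-named probe statistic; proprietary
    shift-deviation scores in elucidation software are not necessarily
    defined this way.
    """
    e, c = _shared(exp, calc)
    return float(np.sqrt(np.mean((e - c) ** 2)))


def rank_by_shift_agreement(candidates: dict[str, dict[str, float]],
                            exp: dict[str, float],
                            statistic: str = "corrected_rmsd",
                            rescale: bool = True,
                            ) -> list[tuple[str, ShiftComparison]]:
    """Rank candidate shift sets ascending by the chosen statistic.

    Deterministic: ties break alphabetically by candidate name.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    scored = []
    for name in sorted(candidates):
        comp = compare_shift_sets(exp, candidates[name], rescale=rescale)
        scored.append((name, comp))
    scored.sort(key=lambda t: (t[1].statistic(statistic), t[0]))
    return scored
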