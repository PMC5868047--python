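"""Molecular formulas, hydrogen-deficiency indices, and halogen A+2 patterns.

A molecular formula alone already carries two diagnostic quantities that a
mass spectrometrist reads off before any NMR is run: the indices of hydrogen
deficiency (rings plus pi-bonds) and, for Cl/Br-containing ions, the A+2
isotopologue intensity pattern.  This module computes both, and inverts the
pattern to a halogen count.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .constants import ISOTOPE_ABUNDANCE, SIMPLIFIED_HALOGEN, STANDARD_VALENCE

_KNOWN_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni "
    "Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I "
    "Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir Pt "
    "Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U D".split()
)

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

#: Hill convention: carbon, then hydrogen, then everything else alphabetically.
def _hill_key(symbol: str) -> tuple[int, str]:
    return {"C": (0, ""), "H": (1, "")}.get(symbol, (2, symbol))


class FormulaError(ValueError):
    """Malformed or unsupported molecular formula."""


@dataclass(frozen=True)
class MolecularFormula:
    """Element counts of a neutral (or even-electron ion) composition."""

    element_counts: dict[str, int]

    def __post_init__(self) -> None:
        if not self.element_counts:
            raise FormulaError("formula has no elements")
        for el, n in self.element_counts.items():
            if el not in _KNOWN_ELEMENTS:
                raise FormulaError(f"unknown element symbol {el!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"count for {el} must be a non-negative integer")

    def count(self, element: str) -> int:
        return self.element_counts.get(element, 0)

    def to_string(self) -> str:
        """Canonical Hill-order string (C, H, then alphabetical)."""
        parts = []
        for el in sorted(self.element_counts, key=_hill_key):
            n = self.element_counts[el]
            if n == 0:
                continue
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def parse_formula(text: str) -> MolecularFormula:
    """Parse a formula string like ``"C23H21Cl3N4"`` into element counts.

    Implicit counts are 1; repeated element tokens accumulate.  Raises
    :class:`FormulaError` on empty input, unknown symbols, or stray
    characters.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"malformed token at {text[pos:]!r}")
        if not m.group(0):
            break
        sym, digits = m.group(1), m.group(2)
        if sym not in _KNOWN_ELEMENTS:
            raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
        counts[sym] = counts.get(sym, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"malformed token at {text[pos:]!r}")
    return MolecularFormula(counts)


def hydrogen_deficiency(f: MolecularFormula | str,
                        valences: dict[str, int] | None = None) -> float:
    """Indices of hydrogen deficiency (degree of unsaturation, DBE).

    Uses the generalized valence formula ``DBE = 1 + sum n_i (v_i - 2) / 2``,
    which reduces to ``C + 1 + N/2 - (H + X)/2`` for CHN-halide formulas.
    Every element present must have a configured standard valence.
    """
    if isinstance(f, str):
        f = parse_formula(f)
    val = dict(STANDARD_VALENCE)
    if valences:
        val.update(valences)
    total = Fraction(1)
    for el, n in f.element_counts.items():
        if el not in val:
            raise FormulaError(f"no standard valence configured for element {el!r}")
        total += Fraction(n * (val[el] - 2), 2)
    return float(total)


# --------------------------------------------------------------------------
# Isotope patterns


@dataclass
class IsotopePattern:
    """Relative abundances of the A, A+2, A+4, ... isotopologue peaks."""

    abundances: np.ndarray
    normalization: str = "unit_sum"   # unit_sum | base_peak_100 | custom_scale

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.ndim != 1 or self.abundances.size == 0:
            raise ValueError("pattern must be a non-empty 1-D array")
        if np.any(self.abundances < 0):
            raise ValueError("pattern abundances must be non-negative")

    def normalized(self, normalization: str = "unit_sum", scale: float = 1.0) -> "IsotopePattern":
        a = self.abundances
        if normalization == "unit_sum":
            total = a.sum()
            if total == 0:
                raise ValueError("all-zero pattern cannot be normalized")
            return IsotopePattern(a / total, "unit_sum")
        if normalization == "base_peak_100":
            return IsotopePattern(100.0 * a / a.max(), "base_peak_100")
        if normalization == "custom_scale":
            return IsotopePattern(scale * a / a[0], "custom_scale")
        raise ValueError(f"unknown normalization {normalization!r}")


def _convolve_binomial(doublet: tuple[float, float], n: int) -> np.ndarray:
    out = np.array([1.0])
    kernel = np.asarray(doublet, dtype=float)
    for _ in range(n):
        out = np.convolve(out, kernel)
    return out


def isotope_pattern(f: MolecularFormula | str,
                    mode: str = "halogen_simplified",
                    threshold: float = 1e-4) -> IsotopePattern:
    """A+2-series isotopologue pattern of a formula.

    ``halogen_simplified``
        Only Cl (3:1) and Br (1:1) contribute; every other element is taken
        as monoisotopic.  The Cl_n pattern is then exactly the binomial
        expansion of ``(3/4 + 1/4)**n``.

    ``full_convolution``
        Convolves the per-atom natural-abundance table over nominal mass
        offsets.  Odd-mass contributions (13C, 15N) are folded into the
        nearest A+2k bin (ties toward the lower bin), emulating how a
        low-resolution A+2 profile is read.

    Trailing peaks below ``threshold`` (relative abundance, unit-sum scale)
    are trimmed.  The result is unit-sum normalized.
    """
    if isinstance(f, str):
        f = parse_formula(f)
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if mode == "halogen_simplified":
        dist = np.array([1.0])
        for el in ("Cl", "Br"):
            n = f.count(el)
            if n:
                # doublet at 2-Da spacing -> direct convolution in A+2k space
                dist_h = _convolve_binomial(SIMPLIFIED_HALOGEN[el], n)
                dist = np.convolve(dist, dist_h)
        series = dist
    elif mode == "full_convolution":
        # distribution over nominal 1-Da offsets
        dist = np.array([1.0])
        for el, n in f.element_counts.items():
            table = ISOTOPE_ABUNDANCE.get(el)
            if table is None or n == 0:
                continue
            width = max(table) + 1
            kernel = np.zeros(width)
            for off, ab in table.items():
                kernel[off] = ab
            kernel /= kernel.sum()
            for _ in range(n):
                dist = np.convolve(dist, kernel)
        # fold 1-Da offsets onto the 2-Da grid (ties toward lower bin)
        n_bins = dist.size // 2 + 1
        series = np.zeros(n_bins)
        for off, ab in enumerate(dist):
            series[min(round(off / 2 - 0.001) if off else 0, n_bins - 1)] += ab
    else:
        raise ValueError(f"unknown mode {mode!r}")

    series = series / series.sum()
    keep = np.nonzero(series >= threshold)[0]
    last = keep.max() if keep.size else 0
    series = series[: last + 1]
    return IsotopePattern(series / series.sum(), "unit_sum")


def infer_halogen_count(pattern: IsotopePattern | np.ndarray,
                        halogen: str = "Cl",
                        max_n: int = 6) -> tuple[int, float]:
    """Halogen count whose simplified A+2 pattern best matches ``pattern``.

    Both candidate and input are unit-sum normalized and compared by sum of
    squared deviations over a common (zero-padded) length; ties break toward
    the smaller count.  Returns ``(count, residual)``.
    """
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    if halogen not in SIMPLIFIED_HALOGEN:
        raise ValueError(f"no simplified doublet for halogen {halogen!r}")
    obs = pattern.abundances if isinstance(pattern, IsotopePattern) else np.asarray(pattern, float)
    if obs.size < 2:
        raise ValueError("pattern needs at least 2 peaks")
    total = obs.sum()
    if total == 0:
        raise ValueError("all-zero pattern")
    obs = obs / total
    best_n, best_res = 0, np.inf
    for n in range(max_n + 1):
        model = _convolve_binomial(SIMPLIFIED_HALOGEN[halogen], n)
        width = max(model.size, obs.size)
        o = np.zeros(width); o[: obs.size] = obs
        m = np.zeros(width); m[: model.size] = model
        res = float(np.sum((o - m) ** 2))
        if res < best_res - 1e-15:
            best_n, best_res = n, res
    return best_n, best_res
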