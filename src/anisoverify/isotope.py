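"""35/37Cl isotope shifts on 13C and the split-peak signature they produce.

A carbon bonded to chlorine resonates a few ppb apart in its 35Cl and 37Cl
isotopologues.  At the carbon observe frequency of a modern spectrometer
that is a fraction of a hertz — resolvable as a split cross peak or a
shoulder on a 1D slice in band-selective high-resolution experiments.  This
module converts shifts between ppb and Hz, simulates the isotopologue
multiplet as a sum of Lorentzian (or Gaussian) components weighted by the
natural 35/37Cl abundances, and detects/extracts the splitting back from a
1D trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from . import constants as const


@dataclass
class IsotopeShift:
    ppb: float
    hz: float
    observe_frequency_MHz: float
    carbon_position: str = ""


@dataclass
class SimulatedSlice:
    """1D trace with its generating components (offset, weight, linewidth)."""

    frequency_Hz: np.ndarray
    intensity: np.ndarray
    components: list[tuple[float, float, float]]

    def __post_init__(self) -> None:
        self.frequency_Hz = np.asarray(self.frequency_Hz, float)
        self.intensity = np.asarray(self.intensity, float)
        if self.frequency_Hz.shape != self.intensity.shape:
            raise ValueError("frequency and intensity shapes differ")


def carbon_observe_frequency(proton_frequency_MHz: float) -> float:
    """13C observe frequency for a spectrometer of given 1H frequency."""
    if proton_frequency_MHz <= 0:
        raise ValueError("proton frequency must be positive")
    return proton_frequency_MHz * const.GAMMA_RATIO_C_OVER_H


def ppb_to_hz(ppb: float, observe_frequency_MHz: float) -> float:
    """Shift in Hz equivalent to ``ppb`` at an observe frequency in MHz."""
    if observe_frequency_MHz <= 0:
        raise ValueError("observe frequency must be positive")
    return ppb * observe_frequency_MHz * 1e-3


def hz_to_ppb(hz: float, observe_frequency_MHz: float) -> float:
    if observe_frequency_MHz <= 0:
        raise ValueError("observe frequency must be positive")
    return hz / (observe_frequency_MHz * 1e-3)


def isotope_shift(ppb: float, proton_frequency_MHz: float = 600.0,
                  carbon_position: str = "") -> IsotopeShift:
    f_c = carbon_observe_frequency(proton_frequency_MHz)
    return IsotopeShift(ppb, ppb_to_hz(ppb, f_c), f_c, carbon_position)


def _lorentzian(f, f0, fwhm):
    g = fwhm / 2.0
    return g**2 / ((f - f0) ** 2 + g**2)


def _gaussian(f, f0, fwhm):
    s = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((f - f0) / s) ** 2)


def cl_isotopologue_components(shift_hz: float, n_cl: int,
                               linewidth_Hz: float) -> list[tuple[float, float, float]]:
    """(offset, weight, linewidth) per Cl isotopologue: binomial 35/37 weights,
    offsets at k * shift for k 37Cl substitutions."""
    if n_cl not in (1, 2, 3):
        raise ValueError("n_cl_attached must be 1, 2 or 3")
    p35, p37 = const.CL35_ABUNDANCE, const.CL37_ABUNDANCE
    comps = []
    from math import comb
    for k in range(n_cl + 1):
        w = comb(n_cl, k) * p35 ** (n_cl - k) * p37 ** k
        comps.append((k * shift_hz, w, linewidth_Hz))
    total = sum(w for _, w, _ in comps)
    return [(o, w / total, lw) for o, w, lw in comps]


def simulate_cl_slice(shift_ppb: float, observe_MHz: float,
                      linewidth_Hz: float, n_cl_attached: int = 1,
                      lineshape: str = "lorentzian",
                      n_points: int = 512,
                      span_Hz: float | None = None) -> SimulatedSlice:
    """Simulate the 1D 13C slice of a Cl-bearing carbon.

    One component per chlorine isotopologue, offset by multiples of the
    isotope shift (in Hz at ``observe_MHz``) and weighted by the natural
    35/37Cl abundances.  ``linewidth_Hz`` is the FWHM of each component.
    """
    if linewidth_Hz <= 0:
        raise ValueError("linewidth must be positive")
    shape = {"lorentzian": _lorentzian, "gaussian": _gaussian}.get(lineshape)
    if shape is None:
        raise ValueError(f"unknown lineshape {lineshape!r}")
    shift_hz = ppb_to_hz(shift_ppb, observe_MHz)
    comps = cl_isotopologue_components(shift_hz, n_cl_attached, linewidth_Hz)
    if span_Hz is None:
        span_Hz = max(6.0 * linewidth_Hz, 4.0 * abs(shift_hz) * n_cl_attached, 1.0)
    f = np.linspace(-span_Hz / 2, span_Hz / 2 + abs(shift_hz) * n_cl_attached,
                    n_points)
    y = np.zeros_like(f)
    for off, w, lw in comps:
        y += w * shape(f, off, lw)
    return SimulatedSlice(f, y, comps)


def detect_splitting(trace: SimulatedSlice | tuple[np.ndarray, np.ndarray],
                     min_separation_Hz: float = 0.1,
                     ) -> tuple[bool, float | None]:
    """Detect a resolved isotopologue splitting in a 1D trace.

    A splitting is called resolved when either a second local maximum or a
    curvature shoulder (second pair of inflection points) sits at least
    ``min_separation_Hz`` from the main peak.  When resolved, the offset is
    refined by a two-Lorentzian least-squares fit with 35/37Cl-abundance
    weights.  Returns ``(resolved, estimated_offset_Hz_or_None)``.
    """
    if isinstance(trace, SimulatedSlice):
        f, y = trace.frequency_Hz, trace.intensity
    else:
        f, y = np.asarray(trace[0], float), np.asarray(trace[1], float)
    if f.size < 16:
        raise ValueError("trace needs at least 16 points")
    if np.all(y == 0) or np.ptp(y) == 0:
        raise ValueError("flat trace: nothing to detect")

    main = int(np.argmax(y))
    peaks, _ = find_peaks(y, prominence=0.01 * np.ptp(y))
    second = [p for p in peaks if abs(f[p] - f[main]) >= min_separation_Hz]
    resolved = bool(second)
    if not resolved:
        # shoulder: local maxima of curvature magnitude away from the peak
        d2 = np.gradient(np.gradient(y, f), f)
        curv_peaks, _ = find_peaks(-d2, prominence=0.01 * np.max(np.abs(d2)))
        second = [p for p in curv_peaks if abs(f[p] - f[main]) >= min_separation_Hz]
        resolved = bool(second)
    if not resolved:
        return False, None

    sep0 = min(abs(f[p] - f[main]) for p in second)
    sign = np.sign(f[second[int(np.argmin([abs(f[p] - f[main]) for p in second]))]]
                   - f[main]) or 1.0
    p35, p37 = const.CL35_ABUNDANCE, const.CL37_ABUNDANCE

    def model(theta):
        amp, f0, off, lw = theta
        return amp * (p35 * _lorentzian(f, f0, lw) + p37 * _lorentzian(f, f0 + off, lw))

    fwhm0 = np.ptp(f) / 8.0
    theta0 = np.array([y.max() / p35, f[main], sign * sep0, fwhm0])
    sol = least_squares(lambda th: model(th) - y, theta0,
                        bounds=([0, f.min(), -np.ptp(f), 1e-6],
                                [np.inf, f.max(), np.ptp(f), np.ptp(f)]))
    return True, float(abs(sol.x[2]))
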