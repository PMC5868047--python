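"""Physical and isotopic constants used across the package.

All values are stored here as versioned module-level constants so that
numerical expectations in downstream analyses stay stable.
"""

from __future__ import annotations

#: Natural isotopic abundances used by the full-convolution isotope-pattern
#: model.  Keys are element symbols; values map *nominal mass offset in Da*
#: (relative to the lightest isotope) to abundance.  Elements absent from
#: this table are treated as monoisotopic.
ISOTOPE_ABUNDANCE: dict[str, dict[int, float]] = {
    "Cl": {0: 0.7576, 2: 0.2424},   # 35Cl / 37Cl
    "Br": {0: 0.5069, 2: 0.4931},   # 79Br / 81Br
    "C": {0: 0.9893, 1: 0.0107},    # 12C / 13C
    "N": {0: 0.99636, 1: 0.00364},  # 14N / 15N
}

#: Textbook "3:1" / "1:1" halogen doublets used by the simplified A+2 model.
SIMPLIFIED_HALOGEN: dict[str, tuple[float, float]] = {
    "Cl": (0.75, 0.25),
    "Br": (0.5, 0.5),
}

#: Standard valences used for indices of hydrogen deficiency (DBE).
#: DBE = 1 + sum_i n_i (v_i - 2) / 2 over all elements.
STANDARD_VALENCE: dict[str, int] = {
    "C": 4, "Si": 4,
    "N": 3, "P": 3, "B": 3,
    "O": 2, "S": 2,
    "H": 1, "D": 1, "F": 1, "Cl": 1, "Br": 1, "I": 1,
}

# --- NMR / magnetic constants -------------------------------------------

#: gamma / 2 pi in MHz per tesla.
GAMMA_H_MHZ_PER_T = 42.577
GAMMA_C_MHZ_PER_T = 10.708

#: 13C/1H gyromagnetic ratio used to convert spectrometer (proton) frequency
#: to the carbon observe frequency: f_C = 0.251450 * f_H.
GAMMA_RATIO_C_OVER_H = 0.251450

#: Vacuum permeability (SI) and Planck constant.
MU_0 = 4.0e-7 * 3.141592653589793
PLANCK_H = 6.62607015e-34

#: Fallback one-bond C-H distance in angstrom when a structure carries no
#: usable hydrogen coordinates.
DEFAULT_CH_BOND_ANGSTROM = 1.09

#: Lorentzian-vs-Gaussian choice and 35/37Cl weights for isotopologue
#: lineshape simulation reuse the abundance table above.
CL35_ABUNDANCE = ISOTOPE_ABUNDANCE["Cl"][0]
CL37_ABUNDANCE = ISOTOPE_ABUNDANCE["Cl"][2]
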