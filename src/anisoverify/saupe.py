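"""Saupe alignment-tensor fitting of RDC/RCSA data and Q-factor ranking.

Partial alignment of a molecule in an anisotropic medium is described by the
Saupe order matrix ``S``: a symmetric, traceless 3x3 tensor with five free
parameters.  Both anisotropic observables used here are *linear* in ``S``:

* residual dipolar coupling of a one-bond C-H pair with unit bond vector
  ``v``:  ``D = D_max(r) * v^T S v`` with
  ``D_max(r) = -(mu0 gammaH gammaC h) / (16 pi^3 r^3)``;
* residual chemical shift anisotropy of a carbon with shielding tensor
  ``sigma`` (ppm, molecular frame):
  ``RCSA = -(2/3) * sum_ij S_ij sigma~_ij`` (ppm -> ppb), where ``sigma~``
  is the traceless part of ``sigma`` — any isotropic offset drops out.

Fitting ``S`` to observed data is therefore a 5-parameter weighted linear
least-squares problem, solved by SVD pseudoinverse; the residual is globally
minimal by convexity.  Structure candidates are scored by the quality factor

    Q = sqrt( sum_k w_k (obs_k - calc_k)^2 / sum_k w_k obs_k^2 ),

each candidate fitted with its own best tensor; the lowest Q wins.  RDC and
RCSA are blind to a global inversion of the structure, so an enantiomer
always ties its mirror image — absolute configuration needs other evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import constants as const
from .graph import MoleculeGraph, StructureError


class FitError(ValueError):
    """Degenerate or underdetermined alignment fit."""


# Five basis matrices for the parameter vector
# (Szz, Sxx - Syy, Sxy, Sxz, Syz).
def _basis() -> list[np.ndarray]:
    b = []
    m = np.diag([-0.5, -0.5, 1.0]); b.append(m)                  # Szz
    m = np.diag([0.5, -0.5, 0.0]); b.append(m)                   # Sxx - Syy
    for (i, j) in ((0, 1), (0, 2), (1, 2)):                      # off-diagonals
        m = np.zeros((3, 3)); m[i, j] = m[j, i] = 1.0
        b.append(m)
    return b


_BASIS = _basis()


@dataclass(frozen=True)
class AlignmentTensor:
    """Symmetric traceless order matrix (5 independent parameters)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("alignment tensor must be 3x3")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("alignment tensor must be symmetric")
        if abs(np.trace(m)) > 1e-9:
            raise ValueError("alignment tensor must be traceless")
        object.__setattr__(self, "matrix", 0.5 * (m + m.T)
                           - np.eye(3) * np.trace(m) / 3.0)

    @classmethod
    def from_params(cls, params: np.ndarray) -> "AlignmentTensor":
        p = np.asarray(params, dtype=float)
        if p.shape != (5,):
            raise ValueError("need 5 parameters (Szz, Sxx-Syy, Sxy, Sxz, Syz)")
        return cls(sum(pi * bi for pi, bi in zip(p, _BASIS)))

    @property
    def params(self) -> np.ndarray:
        m = self.matrix
        return np.array([m[2, 2], m[0, 0] - m[1, 1], m[0, 1], m[0, 2], m[1, 2]])

    @property
    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvalsh(self.matrix)

    def contract(self, v: np.ndarray) -> float:
        """``v^T S v`` for a unit vector ``v``."""
        v = np.asarray(v, float)
        return float(v @ self.matrix @ v)


@dataclass
class RDCRecord:
    carbon_position: str
    proton_position: str
    D_obs_Hz: float
    sigma_Hz: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_Hz <= 0:
            raise ValueError("RDC sigma must be > 0")


@dataclass
class RCSARecord:
    carbon_position: str
    rcsa_obs_ppb: float
    sigma_ppb: float = 1.0
    shielding_tensor_ppm: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.sigma_ppb <= 0:
            raise ValueError("RCSA sigma must be > 0")
        if self.shielding_tensor_ppm is not None:
            t = np.asarray(self.shielding_tensor_ppm, float)
            if t.shape != (3, 3):
                raise ValueError("shielding tensor must be 3x3")
            if not np.allclose(t, t.T, atol=1e-6):
                raise ValueError("shielding tensor must be symmetric")
            self.shielding_tensor_ppm = 0.5 * (t + t.T)


def d_max_hz(r_angstrom: float) -> float:
    """Static one-bond dipolar coupling constant, Hz, for C-H distance r."""
    gh = 2 * np.pi * const.GAMMA_H_MHZ_PER_T * 1e6
    gc = 2 * np.pi * const.GAMMA_C_MHZ_PER_T * 1e6
    r = r_angstrom * 1e-10
    return -(const.MU_0 * gh * gc * const.PLANCK_H) / (16 * np.pi**3 * r**3)


def q_factor(obs, calc, weights=None) -> float:
    """Normalized rms deviation between observed and back-calculated data."""
    obs = np.asarray(obs, float)
    calc = np.asarray(calc, float)
    if obs.shape != calc.shape:
        raise ValueError("obs and calc must have equal length")
    if obs.size == 0:
        raise ValueError("empty observation vector")
    w = np.ones_like(obs) if weights is None else np.asarray(weights, float)
    denom = float(np.sum(w * obs**2))
    if denom == 0:
        raise ValueError("all-zero observations: Q undefined")
    return float(np.sqrt(np.sum(w * (obs - calc) ** 2) / denom))


# --------------------------------------------------------------------------
# geometry helpers


def _ch_geometry(g: MoleculeGraph, rec: RDCRecord) -> tuple[np.ndarray, float, float]:
    """Unit interaction vector, effective C-H distance (A) and scaling for
    one RDC record.  Methyl groups use the C3-axis vector (C -> attached
    heavy atom) with the standard -1/3 projection factor; other pairs use
    the C-H bond vector itself."""
    c = g.atom_of(rec.carbon_position)
    hs = g.protons_of(rec.proton_position)
    xyz = g.coordinates()
    c_hs = g.hydrogens_of(c)
    if not c_hs:
        raise StructureError(f"carbon {rec.carbon_position!r} carries no protons")
    r_ch = float(np.mean([np.linalg.norm(xyz[h] - xyz[c]) for h in c_hs]))
    if len(c_hs) == 3:
        heavies = [j for j in g.neighbors(c) if g.element(j) != "H"]
        if not heavies:
            raise StructureError("isolated methyl carbon")
        axis = xyz[c] - xyz[heavies[0]]
        return axis / np.linalg.norm(axis), r_ch, -1.0 / 3.0
    h = hs[0]
    if h not in c_hs:
        raise StructureError(
            f"pair {rec.carbon_position!r}-{rec.proton_position!r} is not one-bond")
    v = xyz[h] - xyz[c]
    return v / np.linalg.norm(v), r_ch, 1.0


def rdc_back_calculate(g: MoleculeGraph, S: AlignmentTensor,
                       records: list[RDCRecord]) -> np.ndarray:
    """Back-calculated RDCs (Hz) for one-bond C-H records."""
    out = np.empty(len(records))
    for k, rec in enumerate(records):
        v, r, scale = _ch_geometry(g, rec)
        out[k] = scale * d_max_hz(r) * S.contract(v)
    return out


def _traceless(t: np.ndarray) -> np.ndarray:
    return t - np.eye(3) * np.trace(t) / 3.0


def rcsa_back_calculate(records: list[RCSARecord], S: AlignmentTensor) -> np.ndarray:
    """Back-calculated RCSAs (ppb) from molecular-frame shielding tensors."""
    out = np.empty(len(records))
    for k, rec in enumerate(records):
        if rec.shielding_tensor_ppm is None:
            raise ValueError(f"record {rec.carbon_position!r} has no shielding tensor")
        sig = _traceless(np.asarray(rec.shielding_tensor_ppm, float))
        out[k] = -(2.0 / 3.0) * float(np.sum(S.matrix * sig)) * 1e3
    return out


# --------------------------------------------------------------------------
# model / results


def _design_rows_rdc(g: MoleculeGraph, records: list[RDCRecord]) -> np.ndarray:
    rows = np.empty((len(records), 5))
    for k, rec in enumerate(records):
        v, r, scale = _ch_geometry(g, rec)
        dm = scale * d_max_hz(r)
        rows[k] = [dm * float(v @ b @ v) for b in _BASIS]
    return rows


def _design_rows_rcsa(records: list[RCSARecord]) -> np.ndarray:
    rows = np.empty((len(records), 5))
    for k, rec in enumerate(records):
        if rec.shielding_tensor_ppm is None:
            raise ValueError(f"record {rec.carbon_position!r} has no shielding tensor")
        sig = _traceless(np.asarray(rec.shielding_tensor_ppm, float))
        rows[k] = [-(2.0 / 3.0) * float(np.sum(b * sig)) * 1e3 for b in _BASIS]
    return rows


class SaupeModel:
    """Weighted linear model of RDC/RCSA observations for one structure.

    Parameters
    ----------
    structure : MoleculeGraph with coordinates.
    rdc, rcsa : observation records (either list may be empty, jointly >= 5).
    weighting : ``"by_sigma"`` (rows weighted 1/sigma_k) or ``"by_type_rms"``
        (each data type normalized to unit rms before stacking).
    """

    def __init__(self, structure: MoleculeGraph,
                 rdc: list[RDCRecord] | None = None,
                 rcsa: list[RCSARecord] | None = None,
                 weighting: str = "by_sigma"):
        if weighting not in ("by_sigma", "by_type_rms"):
            raise ValueError(f"unknown weighting {weighting!r}")
        if not structure.has_coordinates():
            raise StructureError("alignment fitting requires coordinates")
        self.structure = structure
        self.rdc = list(rdc or [])
        self.rcsa = list(rcsa or [])
        self.weighting = weighting
        if len(self.rdc) + len(self.rcsa) < 5:
            raise FitError(
                f"underdetermined: {len(self.rdc)} RDC + {len(self.rcsa)} RCSA "
                "observations < 5 tensor parameters")

    def _stack(self):
        blocks_A, blocks_y, blocks_w = [], [], []
        if self.rdc:
            A = _design_rows_rdc(self.structure, self.rdc)
            y = np.array([r.D_obs_Hz for r in self.rdc])
            if self.weighting == "by_sigma":
                w = 1.0 / np.array([r.sigma_Hz for r in self.rdc])
            else:
                w = np.full(len(y), 1.0 / max(np.sqrt(np.mean(y**2)), 1e-30))
            blocks_A.append(A); blocks_y.append(y); blocks_w.append(w)
        if self.rcsa:
            A = _design_rows_rcsa(self.rcsa)
            y = np.array([r.rcsa_obs_ppb for r in self.rcsa])
            if self.weighting == "by_sigma":
                w = 1.0 / np.array([r.sigma_ppb for r in self.rcsa])
            else:
                w = np.full(len(y), 1.0 / max(np.sqrt(np.mean(y**2)), 1e-30))
            blocks_A.append(A); blocks_y.append(y); blocks_w.append(w)
        return (np.vstack(blocks_A), np.concatenate(blocks_y),
                np.concatenate(blocks_w))

    def fit(self) -> "SaupeResults":
        A, y, w = self._stack()
        Aw = A * w[:, None]
        yw = y * w
        u, s, vt = np.linalg.svd(Aw, full_matrices=False)
        rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
        if rank < 5:
            raise FitError(f"design matrix rank {rank} < 5: geometry/tensor set "
                           "does not determine the alignment tensor")
        cond = float(s[0] / s[-1])
        if cond > 1e6:
            warnings.warn(f"ill-conditioned alignment fit (condition number "
                          f"{cond:.3g})", stacklevel=2)
        params = vt.T @ ((u.T @ yw) / s)
        tensor = AlignmentTensor.from_params(params)
        calc = A @ params
        n_rdc = len(self.rdc)
        calc_rdc, calc_rcsa = calc[:n_rdc], calc[n_rdc:]
        dof = max(y.size - 5, 1)
        sigma2 = float(np.sum((yw - Aw @ params) ** 2)) / dof
        cov = (vt.T / s**2) @ vt * sigma2
        return SaupeResults(model=self, tensor=tensor, params=params,
                            cov_params=cov, condition_number=cond,
                            calc_rdc=calc_rdc, calc_rcsa=calc_rcsa,
                            weights=w, obs=y)


@dataclass
class SaupeResults:
    """Fitted alignment tensor plus per-type back-calculations and Q factors."""

    model: SaupeModel
    tensor: AlignmentTensor
    params: np.ndarray
    cov_params: np.ndarray
    condition_number: float
    calc_rdc: np.ndarray
    calc_rcsa: np.ndarray
    weights: np.ndarray
    obs: np.ndarray

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def n_rdc(self) -> int:
        return len(self.model.rdc)

    @property
    def n_rcsa(self) -> int:
        return len(self.model.rcsa)

    @property
    def fittedvalues(self) -> np.ndarray:
        return np.concatenate([self.calc_rdc, self.calc_rcsa])

    @property
    def resid(self) -> np.ndarray:
        return self.obs - self.fittedvalues

    @property
    def q_rdc(self) -> float | None:
        if not self.n_rdc:
            return None
        return q_factor(self.obs[:self.n_rdc], self.calc_rdc)

    @property
    def q_rcsa(self) -> float | None:
        if not self.n_rcsa:
            return None
        return q_factor(self.obs[self.n_rdc:], self.calc_rcsa)

    @property
    def q_total(self) -> float:
        """Q on the stacked weighted observation vector."""
        return q_factor(self.obs * self.weights, self.fittedvalues * self.weights)

    def summary(self) -> str:
        lines = [
            "Saupe alignment tensor fit",
            "==========================",
            f"structure:        {self.model.structure.name or '<unnamed>'}",
            f"observations:     {self.n_rdc} RDC, {self.n_rcsa} RCSA",
            f"weighting:        {self.model.weighting}",
            f"condition number: {self.condition_number:.4g}",
            "",
            "parameter        estimate      std err",
        ]
        names = ["Szz", "Sxx-Syy", "Sxy", "Sxz", "Syz"]
        for name, p, se in zip(names, self.params, self.bse):
            lines.append(f"{name:<12} {p: .6e}  {se:.3e}")
        lines.append("")
        if self.q_rdc is not None:
            lines.append(f"Q(RDC)   = {self.q_rdc:.4f}")
        if self.q_rcsa is not None:
            lines.append(f"Q(RCSA)  = {self.q_rcsa:.4f}")
        lines.append(f"Q(total) = {self.q_total:.4f}")
        return "\n".join(lines)

    def plot_correlation(self, ax=None):
        """Observed-vs-calculated scatter (RDC in Hz, RCSA in ppb)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.n_rdc:
            ax.scatter(self.obs[:self.n_rdc], self.calc_rdc,
                       c="crimson", label="RDC (Hz)")
        if self.n_rcsa:
            ax.scatter(self.obs[self.n_rdc:], self.calc_rcsa,
                       c="royalblue", label="RCSA (ppb)")
        lo = min(self.obs.min(), self.fittedvalues.min())
        hi = max(self.obs.max(), self.fittedvalues.max())
        ax.plot([lo, hi], [lo, hi], "k--", lw=0.8)
        ax.set_xlabel("observed")
        ax.set_ylabel("back-calculated")
        ax.legend()
        ax.set_title(f"Q = {self.q_total:.3f}")
        return ax


def fit_alignment(g: MoleculeGraph, rdc=None, rcsa=None,
                  weighting: str = "by_sigma") -> SaupeResults:
    """Convenience wrapper: build a :class:`SaupeModel` and fit it."""
    return SaupeModel(g, rdc, rcsa, weighting=weighting).fit()


def rank_structures(candidates: list[MoleculeGraph],
                    rdc: list[RDCRecord] | None = None,
                    rcsa: list[RCSARecord] | None = None,
                    shieldings: list[dict[str, np.ndarray] | None] | None = None,
                    weighting: str = "by_sigma",
                    ) -> list[tuple[MoleculeGraph, SaupeResults]]:
    """Fit each candidate independently and order ascending by total Q.

    ``shieldings`` optionally supplies per-candidate shielding tensors
    (mapping carbon label -> 3x3 ppm matrix) substituted into the RCSA
    records, since DFT tensors are geometry-specific.  Ties keep input
    order (stable sort).
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    if shieldings is not None and len(shieldings) != len(candidates):
        raise ValueError("one shielding map per candidate required")
    out = []
    for i, g in enumerate(candidates):
        rcsa_i = list(rcsa or [])
        if shieldings is not None and shieldings[i] is not None and rcsa_i:
            sub = []
            for rec in rcsa_i:
                if rec.carbon_position not in shieldings[i]:
                    raise ValueError(f"candidate {g.name or i}: no shielding tensor "
                                     f"for {rec.carbon_position!r}")
                sub.append(RCSARecord(rec.carbon_position, rec.rcsa_obs_ppb,
                                      rec.sigma_ppb,
                                      shieldings[i][rec.carbon_position]))
            rcsa_i = sub
        out.append((g, SaupeModel(g, rdc, rcsa_i, weighting=weighting).fit()))
    return sorted(out, key=lambda t: t[1].q_total)


# --------------------------------------------------------------------------
# CSV input/output of anisotropic observations


def read_rdc_csv(path) -> list[RDCRecord]:
    """Columns: ``carbon, proton, D_obs_Hz, sigma_Hz`` (sigma optional)."""
    import pandas as pd

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for rec in df.to_dict("records"):
        out.append(RDCRecord(str(rec["carbon"]).strip(),
                             str(rec.get("proton", rec["carbon"])).strip()
                             or str(rec["carbon"]).strip(),
                             float(rec["D_obs_Hz"]),
                             float(rec.get("sigma_Hz") or 1.0)))
    return out


def write_rdc_csv(records: list[RDCRecord], path) -> None:
    import pandas as pd

    pd.DataFrame([{"carbon": r.carbon_position, "proton": r.proton_position,
                   "D_obs_Hz": r.D_obs_Hz, "sigma_Hz": r.sigma_Hz}
                  for r in records]).to_csv(path, index=False)


def read_shielding_csv(path) -> dict[str, np.ndarray]:
    """Columns: ``carbon, sxx, syy, szz, sxy, sxz, syz`` (ppm, molecular frame)."""
    import pandas as pd

    df = pd.read_csv(path)
    out: dict[str, np.ndarray] = {}
    for rec in df.to_dict("records"):
        sxx, syy, szz = float(rec["sxx"]), float(rec["syy"]), float(rec["szz"])
        sxy, sxz, syz = float(rec["sxy"]), float(rec["sxz"]), float(rec["syz"])
        out[str(rec["carbon"]).strip()] = np.array(
            [[sxx, sxy, sxz], [sxy, syy, syz], [sxz, syz, szz]])
    return out


def write_shielding_csv(shieldings: dict[str, np.ndarray], path) -> None:
    import pandas as pd

    rows = []
    for lbl, t in shieldings.items():
        t = np.asarray(t, float)
        rows.append({"carbon": lbl, "sxx": t[0, 0], "syy": t[1, 1],
                     "szz": t[2, 2], "sxy": t[0, 1], "sxz": t[0, 2],
                     "syz": t[1, 2]})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_rcsa_csv(path, shieldings: dict[str, np.ndarray] | None = None,
                  ) -> list[RCSARecord]:
    """Columns: ``carbon, rcsa_ppb, sigma_ppb`` (sigma optional); tensors
    are attached from ``shieldings`` when given."""
    import pandas as pd

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for rec in df.to_dict("records"):
        lbl = str(rec["carbon"]).strip()
        tensor = shieldings.get(lbl) if shieldings else None
        out.append(RCSARecord(lbl, float(rec["rcsa_ppb"]),
                              float(rec.get("sigma_ppb") or 1.0), tensor))
    return out


def write_rcsa_csv(records: list[RCSARecord], path) -> None:
    import pandas as pd

    pd.DataFrame([{"carbon": r.carbon_position, "rcsa_ppb": r.rcsa_obs_ppb,
                   "sigma_ppb": r.sigma_ppb} for r in records]).to_csv(path, index=False)
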