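"""Debye-equation SAXS forward model and curve analytics.

Scattering from a bead structure is computed with the Debye equation

    I(q) = sum_i sum_j f_i(q) f_j(q) sin(q r_ij) / (q r_ij),

the exact orientational average for point scatterers, with sin(x)/x -> 1
as x -> 0, so I(0) = (sum_i f_i(0))^2.  Bead form factors are looked up by
bead class; the default table assigns each residue class an effective
scattering length in electron units, Z_res - rho_solvent * V_res, i.e. the
residue electron count minus the displaced-solvent contribution at the
electron density of water (0.334 e/A^3).  A uniform table (f = 1) is
provided for tests and geometry-only work.

q is in nm^-1 internally; Angstrom^-1 input is converted at the I/O
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .chain import BeadChain

__all__ = [
    "FormFactorTable",
    "SaxsCurve",
    "debye_intensity",
    "ensemble_average_intensity",
    "kratky_transform",
    "guinier_rg",
    "restraint_grid",
    "smooth_experimental",
    "initial_scaling",
]

WATER_ELECTRON_DENSITY = 0.334  # e / A^3

# residue electron count and mean solvent-excluded volume (A^3)
_RESIDUE_Z_V: dict[str, tuple[float, float]] = {
    "GLY": (30, 63.8), "ALA": (38, 90.1), "VAL": (54, 139.1),
    "LEU": (62, 164.6), "ILE": (62, 164.9), "PRO": (52, 123.1),
    "PHE": (78, 190.8), "TRP": (98, 226.4), "MET": (70, 167.7),
    "SER": (46, 94.2), "THR": (54, 120.0), "CYS": (54, 103.5),
    "TYR": (86, 194.6), "ASN": (60, 127.5), "GLN": (68, 149.4),
    "ASP": (59, 117.1), "GLU": (67, 140.8), "LYS": (71, 170.0),
    "ARG": (85, 192.8), "HIS": (72, 159.3),
}


@dataclass(frozen=True)
class FormFactorTable:
    """Map bead class -> effective scattering length (q-independent).

    Users may supply their own published coarse-grained parameters as a
    plain ``{class: value}`` mapping; values are in arbitrary consistent
    units (electrons for the residue default).
    """

    values: dict[str, float]

    def lookup(self, bead_classes: np.ndarray) -> np.ndarray:
        try:
            return np.array([self.values[c] for c in bead_classes], dtype=float)
        except KeyError as exc:
            raise KeyError(f"no form factor for bead class {exc.args[0]!r}") from None

    @classmethod
    def uniform(cls, classes: tuple[str, ...] = ("BB",), value: float = 1.0
                ) -> "FormFactorTable":
        return cls({c: value for c in classes})

    @classmethod
    def residue_default(cls) -> "FormFactorTable":
        """One class per amino acid, excess electrons over displaced water."""
        return cls({aa: z - WATER_ELECTRON_DENSITY * v
                    for aa, (z, v) in _RESIDUE_Z_V.items()})


@dataclass
class SaxsCurve:
    """A scattering curve: q (nm^-1, strictly ascending), I(q), optional sigma."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or self.intensity.shape != self.q.shape:
            raise ValueError("q and intensity must be equal-length 1-D arrays")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly ascending")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma length mismatch")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive where present")

    def __len__(self) -> int:
        return len(self.q)


def debye_intensity(chain: BeadChain, q_grid: np.ndarray,
                    table: FormFactorTable) -> SaxsCurve:
    """Debye scattering of a single bead structure on ``q_grid`` (nm^-1).

    Vectorized over the n(n-1)/2 distinct pairs; exactly equal to the
    double-loop Debye sum.  Rotation/translation invariant by construction
    (depends on pair distances only).
    """
    q = np.asarray(q_grid, dtype=float)
    if chain.n_beads < 1:
        raise ValueError("chain has no beads")
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    f = table.lookup(chain.bead_class)
    self_term = float(np.sum(f * f))
    if chain.n_beads == 1:
        return SaxsCurve(q, np.full_like(q, self_term))
    r = pdist(chain.positions)
    iu, ju = np.triu_indices(chain.n_beads, k=1)
    ff = f[iu] * f[ju]
    # np.sinc(x/pi) = sin(x)/x with the x -> 0 limit handled
    intensity = np.empty_like(q)
    chunk = max(1, int(2e6 / max(len(r), 1)))
    for s in range(0, len(q), chunk):
        qs = q[s:s + chunk, None]
        intensity[s:s + chunk] = self_term + 2.0 * (ff * np.sinc(qs * r / np.pi)).sum(axis=1)
    return SaxsCurve(q, intensity)


def ensemble_average_intensity(frames, weights, q_grid: np.ndarray,
                               table: FormFactorTable) -> SaxsCurve:
    """Weighted mean of per-frame Debye curves; weights normalized internally."""
    w = np.asarray(weights, dtype=float)
    if len(w) != len(frames):
        raise ValueError("one weight per frame required")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights sum to zero")
    w = w / total
    q = np.asarray(q_grid, dtype=float)
    acc = np.zeros_like(q)
    for frame, wk in zip(frames, w):
        if wk > 0:
            acc += wk * debye_intensity(frame, q, table).intensity
    return SaxsCurve(q, acc)


def kratky_transform(curve: SaxsCurve) -> SaxsCurve:
    """Kratky representation (q, q^2 I(q)); sigma propagated as q^2 sigma."""
    q2 = curve.q ** 2
    sig = None if curve.sigma is None else q2 * curve.sigma
    if sig is not None and np.any(sig <= 0):
        sig = None  # q = 0 point would give zero sigma
    return SaxsCurve(curve.q, q2 * curve.intensity, sig)


def guinier_rg(curve: SaxsCurve, qmax_rg_product: float = 1.0,
               max_iter: int = 20) -> tuple[float, float, dict]:
    """Guinier radius of gyration from the low-q limit.

    Fits ln I = ln I0 - q^2 Rg^2 / 3 by (sigma-)weighted linear least
    squares over the largest prefix window satisfying q_max * Rg <=
    ``qmax_rg_product``, iterating the window to a fixed point.  Returns
    (Rg [nm], I0, diagnostics); a window that fails to converge or a
    non-decaying curve is flagged in the diagnostics, with Rg = 0 for a
    non-negative slope.
    """
    q, intensity = curve.q, curve.intensity
    window = len(q)
    diag = {"converged": False, "n_points": window, "iterations": 0}
    rg = 0.0
    i0 = float(intensity[0]) if len(intensity) else 0.0
    for it in range(max_iter):
        if window < 3:
            diag.update(n_points=window, iterations=it)
            return rg, i0, diag
        qs, ints = q[:window], intensity[:window]
        if np.any(ints <= 0):
            raise ValueError("non-positive intensity inside the Guinier window")
        x, y = qs ** 2, np.log(ints)
        if curve.sigma is not None:
            w = (ints / curve.sigma[:window]) ** 2  # var of ln I = (sigma/I)^2
        else:
            w = np.ones_like(x)
        slope, icept = np.polyfit(x, y, 1, w=np.sqrt(w))
        i0 = float(np.exp(icept))
        rg = float(np.sqrt(-3.0 * slope)) if slope < 0 else 0.0
        if rg == 0.0:
            diag.update(converged=True, n_points=window, iterations=it + 1)
            return rg, i0, diag
        new_window = int(np.searchsorted(q, qmax_rg_product / rg, side="right"))
        new_window = min(max(new_window, 3), len(q))
        diag["iterations"] = it + 1
        if new_window == window:
            diag.update(converged=True, n_points=window)
            return rg, i0, diag
        window = new_window
    diag.update(n_points=window)
    return rg, i0, diag


def restraint_grid(q_min: float, q_max: float, n_points: int) -> np.ndarray:
    """Equidistant q points including both endpoints (restraint placement)."""
    if n_points < 2:
        raise ValueError("need at least 2 points")
    if not q_min < q_max:
        raise ValueError("q_min must be < q_max")
    return np.linspace(q_min, q_max, n_points)


def smooth_experimental(curve: SaxsCurve, degree: int = 16,
                        eval_grid: np.ndarray | None = None) -> SaxsCurve:
    """Polynomial smoothing of an experimental curve for restraint points.

    Least-squares polynomial of the given degree in q (fitted on a scaled
    domain for conditioning), evaluated on ``eval_grid``; sigma at the
    evaluation points is linearly interpolated from the data.
    """
    if len(curve) <= degree + 1:
        raise ValueError(
            f"{len(curve)} data points cannot constrain a degree-{degree} polynomial")
    grid = curve.q if eval_grid is None else np.asarray(eval_grid, dtype=float)
    poly = np.polynomial.Polynomial.fit(curve.q, curve.intensity, degree)
    smoothed = poly(grid)
    sig = None
    if curve.sigma is not None:
        sig = np.interp(grid, curve.q, curve.sigma)
    return SaxsCurve(grid, smoothed, sig)


def initial_scaling(experimental: SaxsCurve, computed: SaxsCurve) -> float:
    """Scale factor I_exp / I_calc at the lowest shared q point."""
    if not np.isclose(experimental.q[0], computed.q[0]):
        raise ValueError("curves do not share their lowest q point")
    if computed.intensity[0] == 0:
        raise ValueError("computed intensity is zero at the lowest q")
    return float(experimental.intensity[0] / computed.intensity[0])
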