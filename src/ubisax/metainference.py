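"""Bayesian (metainference) scoring of ensemble-averaged SAXS predictions.

The score compares the forward-modelled, ensemble-averaged intensity f_i at
each restraint point with the experimental value d_i under a long-tailed
"outlier" noise model obtained by marginalizing a Gaussian noise level with
a Jeffreys-like prior:

    E_i = -ln[(1 - exp(-lambda_i)) / lambda_i],
    lambda_i = (d_i - s*f_i - o)^2 / (2 sigma_i^2),

which behaves like the Gaussian score lambda/2 for small residuals and
grows only logarithmically for large ones, making single bad points
non-catastrophic.  A Gaussian alternative (E_i = lambda_i) is available
behind a flag.  The effective sigma_i combines the sampled/fixed noise
level sigma_B with sigma_mean, the standard error of the ensemble-averaged
forward model, sigma_i^2 = sigma_B,i^2 + sigma_mean,i^2.

A uniform scaling s in [0.9, 1.1] and offset o in [-1, 1] of the data are
sampled by Metropolis moves under flat priors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .saxs import FormFactorTable, SaxsCurve, debye_intensity

__all__ = [
    "MetainferenceParams",
    "RestraintSet",
    "sigma_mean_estimate",
    "outlier_negloglik",
    "metainference_energy",
    "sample_scaling_offset",
    "reweight_to_saxs",
]

KT_300K = 2.494  # kJ/mol at 300 K


@dataclass(frozen=True)
class MetainferenceParams:
    scaling: float = 1.0
    offset: float = 0.0
    sigma_b: float | np.ndarray | None = None  # None -> use restraint sigmas
    sigma_mean: float | np.ndarray = 0.0
    kT: float = KT_300K
    stride: int = 5  # restraint evaluation every fifth sampler step
    scaling_bounds: tuple[float, float] = (0.9, 1.1)
    offset_bounds: tuple[float, float] = (-1.0, 1.0)
    noise_model: str = "outlier"  # or "gaussian"


@dataclass(frozen=True)
class RestraintSet:
    """Experimental restraint points: q grid, values d_i, uncertainties."""

    q: np.ndarray
    values: np.ndarray
    sigma: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "q", np.asarray(self.q, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        if not (len(self.q) == len(self.values) == len(self.sigma)):
            raise ValueError("q, values and sigma must have equal length")
        if np.any(self.sigma <= 0):
            raise ValueError("restraint sigmas must be positive")

    def __len__(self) -> int:
        return len(self.q)


def sigma_mean_estimate(series: np.ndarray, block_size: int,
                        floor: float = 0.0) -> np.ndarray:
    """Per-point sigma_mean: maximum over blocks of the block-mean SE.

    ``series`` is (n_samples, n_points); it is cut into consecutive blocks
    of ``block_size`` samples (the paper's 2 ps span) and for each point
    the returned value is the largest standard error of the mean across
    blocks, floored at ``floor``.
    """
    arr = np.atleast_2d(np.asarray(series, dtype=float))
    if arr.shape[0] == 1 and arr.ndim == 2 and series.ndim == 1:
        arr = arr.T
    n_blocks = arr.shape[0] // block_size
    if n_blocks < 2:
        raise ValueError(
            f"{arr.shape[0]} samples give {n_blocks} blocks of {block_size}; need >= 2")
    blocks = arr[: n_blocks * block_size].reshape(n_blocks, block_size, -1)
    se = blocks.std(axis=1, ddof=1) / np.sqrt(block_size)
    return np.maximum(se.max(axis=0), floor)


def _effective_sigma(restraints: RestraintSet, params: MetainferenceParams
                     ) -> np.ndarray:
    sigma_b = restraints.sigma if params.sigma_b is None else np.asarray(params.sigma_b, dtype=float)
    sigma_b = np.broadcast_to(sigma_b, restraints.values.shape)
    sigma_mean = np.broadcast_to(np.asarray(params.sigma_mean, dtype=float),
                                 restraints.values.shape)
    return np.sqrt(sigma_b ** 2 + sigma_mean ** 2)


def outlier_negloglik(d, f, s: float = 1.0, o: float = 0.0, sigma=1.0):
    """Negative log-likelihood of the marginalized (outlier) noise model.

    Vectorized over inputs.  Zero at zero residual, ~lambda/2 for small
    residuals (the Gaussian limit), ~ln(lambda) for large ones.
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    resid = np.asarray(d, dtype=float) - s * np.asarray(f, dtype=float) - o
    lam = resid ** 2 / (2.0 * sigma ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(lam > 1e-12, -np.expm1(-lam) / np.where(lam > 0, lam, 1.0), 1.0 - lam / 2.0)
        energy = -np.log(ratio)
    return energy if energy.ndim else float(energy)


def metainference_energy(restraints: RestraintSet, forward: np.ndarray,
                         params: MetainferenceParams) -> float:
    """Total restraint energy, kT * sum_i E_i (kJ/mol)."""
    f = np.asarray(forward, dtype=float)
    if f.shape != restraints.values.shape:
        raise ValueError(f"forward model has {f.shape} points, "
                         f"restraints have {restraints.values.shape}")
    sigma = _effective_sigma(restraints, params)
    if params.noise_model == "gaussian":
        resid = restraints.values - params.scaling * f - params.offset
        per_point = resid ** 2 / (2.0 * sigma ** 2)
    else:
        per_point = outlier_negloglik(restraints.values, f, params.scaling,
                                      params.offset, sigma)
    return float(params.kT * np.sum(per_point))


def sample_scaling_offset(params: MetainferenceParams, forward: np.ndarray,
                          restraints: RestraintSet, rng: np.random.Generator,
                          step_scaling: float = 0.02, step_offset: float = 0.1,
                          ) -> tuple[MetainferenceParams, bool]:
    """One Metropolis move on (scaling, offset) under their flat priors.

    Proposals are uniform displacements; anything landing outside the prior
    box is rejected outright, which together with the symmetric proposal
    gives detailed balance w.r.t. exp(-E/kT) restricted to the box.
    """
    s_new = params.scaling + rng.uniform(-step_scaling, step_scaling)
    o_new = params.offset + rng.uniform(-step_offset, step_offset)
    lo_s, hi_s = params.scaling_bounds
    lo_o, hi_o = params.offset_bounds
    if not (lo_s <= s_new <= hi_s and lo_o <= o_new <= hi_o):
        return params, False
    e_old = metainference_energy(restraints, forward, params)
    proposal = replace(params, scaling=s_new, offset=o_new)
    e_new = metainference_energy(restraints, forward, proposal)
    if e_new <= e_old or rng.random() < np.exp(-(e_new - e_old) / params.kT):
        return proposal, True
    return params, False


def reweight_to_saxs(frames, weights, restraints: RestraintSet,
                     table: FormFactorTable, theta: float = 1.0,
                     params: MetainferenceParams | None = None) -> np.ndarray:
    """Reweight an ensemble toward experimental SAXS restraint points.

    Maximum-entropy update consistent with the Gaussian limit of the noise
    model: find weights w minimizing chi^2/2 - theta * S_rel(w||w0) via the
    convex dual over Lagrange multipliers (one per restraint point).
    ``theta`` balances fit against proximity to the prior weights; smaller
    values fit tighter.  Returns normalized weights.
    """
    params = params or MetainferenceParams()
    w0 = np.asarray(weights, dtype=float)
    w0 = w0 / w0.sum()
    curves = np.stack([debye_intensity(fr, restraints.q, table).intensity
                       for fr in frames])
    # uniform scale so the optimizer works near unit magnitude
    scale = restraints.values[0]
    d = restraints.values / scale
    sig = _effective_sigma(restraints, params) / scale
    x = curves * (params.scaling / scale) + params.offset / scale

    def dual(lam):
        logits = np.log(w0) - x @ lam
        m = logits.max()
        logz = m + np.log(np.sum(np.exp(logits - m)))
        return logz + lam @ d + 0.5 * theta * np.sum((lam * sig) ** 2)

    def grad(lam):
        logits = np.log(w0) - x @ lam
        w = np.exp(logits - logits.max())
        w /= w.sum()
        return d - w @ x + theta * lam * sig ** 2

    res = minimize(dual, np.zeros(len(d)), jac=grad, method="L-BFGS-B")
    logits = np.log(w0) - x @ res.x
    w = np.exp(logits - logits.max())
    return w / w.sum()
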