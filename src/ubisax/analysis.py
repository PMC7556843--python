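"""Ensemble observables: free-energy surfaces, compactness, contacts,
polymer scaling and binding-competence probabilities.

All operations act on a :class:`WeightedEnsemble` (frames plus normalized
statistical weights, e.g. from metadynamics reweighting).  Compactness
follows the minimum inter-core bead distance with a 0.6 nm open/compact
threshold; chain-length scaling is summarized by a power law
e2e(N) = A * N^nu whose exponent is compared with the Flory value ~0.588
for self-avoiding polymers.  Binding competence of a neighbor domain pair
is judged by backbone RMSD to a reference bound pair after optimal (Kabsch)
superposition, optionally excluding frames where the rest of the chain
would clash with a rigid partner surrogate placed onto the bound pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial.distance import cdist

from .chain import BeadChain, DomainTopology

__all__ = [
    "WeightedEnsemble",
    "FES2D",
    "PowerLawFit",
    "fes2d",
    "min_core_distance",
    "classify_open",
    "compact_fraction",
    "contact_map",
    "end_to_end",
    "fit_power_law",
    "predict_linkage_scaling",
    "min_chain_length_for_two_dimers",
    "rmsd_to_reference",
    "kabsch_transform",
    "bound_like_probability",
    "BoundLikeResult",
    "average_structure",
]

KT_300K = 2.494


@dataclass
class WeightedEnsemble:
    """Frames with normalized statistical weights."""

    frames: list
    weights: np.ndarray
    topology: DomainTopology

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if len(w) != len(self.frames):
            raise ValueError("one weight per frame required")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        self.weights = w / w.sum()

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class FES2D:
    """Free-energy surface over two CVs; min over occupied bins is 0,
    empty bins are NaN (not zero)."""

    cv_labels: tuple[str, str]
    edges_a: np.ndarray
    edges_b: np.ndarray
    free_energy: np.ndarray  # kJ/mol, NaN where unoccupied
    kT: float


@dataclass
class PowerLawFit:
    """e2e(N) = A * N^nu with fit diagnostics."""

    prefactor: float
    exponent: float
    covariance: np.ndarray | None = None
    mode: str = "both-free"

    def __post_init__(self) -> None:
        if self.prefactor <= 0:
            raise ValueError("prefactor must be positive")

    def __call__(self, n) -> np.ndarray:
        return self.prefactor * np.asarray(n, dtype=float) ** self.exponent

    @property
    def exponent_stderr(self) -> float:
        if self.covariance is None or self.covariance.shape[0] < 2:
            return np.nan
        return float(np.sqrt(self.covariance[1, 1]))


def fes2d(ensemble: WeightedEnsemble, cv_a, cv_b, bins=40,
          kT: float = KT_300K, ranges=None) -> FES2D:
    """F(a, b) = -kT ln(weighted 2-D histogram), shifted so min = 0.

    ``cv_a``/``cv_b`` are callables frame -> value, or precomputed arrays.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    a = np.asarray([cv_a(f) for f in ensemble.frames] if callable(cv_a) else cv_a,
                   dtype=float)
    b = np.asarray([cv_b(f) for f in ensemble.frames] if callable(cv_b) else cv_b,
                   dtype=float)
    hist, ea, eb = np.histogram2d(a, b, bins=bins, range=ranges,
                                  weights=ensemble.weights)
    with np.errstate(divide="ignore"):
        fe = -kT * np.log(hist)
    fe[hist == 0] = np.nan
    fe -= np.nanmin(fe)
    labels = (getattr(cv_a, "__name__", "cv_a"), getattr(cv_b, "__name__", "cv_b"))
    return FES2D(labels, ea, eb, fe, kT)


def _core_mask(frame: BeadChain, topology: DomainTopology, domain: int,
               backbone_only: bool = False) -> np.ndarray:
    lo, hi = topology.core_ranges[domain]
    mask = (frame.residue_index >= lo) & (frame.residue_index <= hi)
    if backbone_only:
        mask &= frame.backbone
    return mask


def min_core_distance(frame: BeadChain, topology: DomainTopology,
                      i: int, j: int) -> float:
    """Minimum bead-pair distance (nm) between the cores of domains i, j."""
    pi = frame.positions[_core_mask(frame, topology, i)]
    pj = frame.positions[_core_mask(frame, topology, j)]
    return float(cdist(pi, pj).min())


def classify_open(min_distance: float, threshold: float = 0.6) -> str:
    """'open' iff the minimum inter-core distance exceeds the threshold."""
    if min_distance < 0:
        raise ValueError("distance cannot be negative")
    return "open" if min_distance > threshold else "compact"


def compact_fraction(ensemble: WeightedEnsemble, i: int, j: int,
                     threshold: float = 0.6) -> float:
    """Weighted fraction of frames whose (i, j) core pair is compact."""
    flags = np.array([classify_open(min_core_distance(f, ensemble.topology, i, j),
                                    threshold) == "compact"
                      for f in ensemble.frames])
    return float(ensemble.weights[flags].sum())


def contact_map(ensemble: WeightedEnsemble, i: int, j: int,
                contact_cutoff: float = 0.6) -> np.ndarray:
    """Residue-by-residue contact probability between two cores.

    Entry (a, b) is the weighted probability that any bead of core-i
    residue a lies within ``contact_cutoff`` of any bead of core-j residue
    b.  Rows/columns follow core residue order N-to-C.
    """
    if contact_cutoff <= 0:
        raise ValueError("cutoff must be positive")
    top = ensemble.topology
    res_i = np.array(list(top.core_residues(i)))
    res_j = np.array(list(top.core_residues(j)))
    prob = np.zeros((len(res_i), len(res_j)))
    for frame, w in zip(ensemble.frames, ensemble.weights):
        mi = _core_mask(frame, top, i)
        mj = _core_mask(frame, top, j)
        d = cdist(frame.positions[mi], frame.positions[mj])
        ri = np.searchsorted(res_i, frame.residue_index[mi])
        rj = np.searchsorted(res_j, frame.residue_index[mj])
        contact = d <= contact_cutoff
        if contact.any():
            hit = np.zeros_like(prob, dtype=bool)
            a, b = np.where(contact)
            hit[ri[a], rj[b]] = True
            prob += w * hit
    return prob


def end_to_end(frame: BeadChain, topology: DomainTopology) -> float:
    """Distance (nm) between the first backbone bead of residue 1 and the
    last backbone bead of the final residue."""
    bb = np.where(frame.backbone)[0]
    first = bb[frame.residue_index[bb] == 1][0]
    last = bb[frame.residue_index[bb] == topology.n_residues][-1]
    return float(np.linalg.norm(frame.positions[last] - frame.positions[first]))


def fit_power_law(lengths, e2e_values, mode: str = "both-free",
                  fixed_exponent: float = 0.6,
                  sigma=None) -> PowerLawFit:
    """Fit e2e(N) = A * N^nu by nonlinear least squares.

    ``mode='fixed-exponent'`` fits only A at the given exponent (the
    construction used to extrapolate to other linkage chemistries from a
    measured prefactor).
    """
    n = np.asarray(lengths, dtype=float)
    y = np.asarray(e2e_values, dtype=float)
    if np.any(n <= 0) or np.any(y <= 0):
        raise ValueError("lengths and e2e values must be positive")
    if mode == "fixed-exponent":
        xp = n ** fixed_exponent
        a = float(np.sum(xp * y) / np.sum(xp * xp))
        return PowerLawFit(a, fixed_exponent, mode=mode)
    if len(n) < 2:
        raise ValueError("need at least 2 points for a two-parameter fit")
    p0 = (y[0] / n[0] ** 0.6, 0.6)
    popt, pcov = curve_fit(lambda x, a, nu: a * x ** nu, n, y, p0=p0,
                           sigma=sigma, maxfev=10000)
    return PowerLawFit(float(popt[0]), float(popt[1]), covariance=pcov)


def predict_linkage_scaling(prefactor: float, n, exponent: float = 0.6
                            ) -> np.ndarray:
    """Extrapolated e2e for a linkage with a given characteristic length."""
    if prefactor <= 0:
        raise ValueError("prefactor must be positive")
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < 1):
        raise ValueError("chain length must be >= 1")
    out = prefactor * n_arr ** exponent
    return float(out) if out.ndim == 0 else out


def min_chain_length_for_two_dimers(fit: PowerLawFit, span_length: float,
                                    n_max: int = 10000) -> int:
    """Smallest N >= 3 such that e2e(N - 2) >= span_length.

    Two domain pairs engage the two ends of a partner of the given span
    (nm); the N - 2 domains between them must bridge it.
    """
    if span_length < 0:
        raise ValueError("span length cannot be negative")
    for n in range(3, n_max + 1):
        if fit(n - 2) >= span_length:
            return n
    raise ValueError(f"no chain length up to {n_max} spans {span_length} nm")


def kabsch_transform(mobile: np.ndarray, target: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t mapping mobile onto target
    (least-squares, proper rotation): x -> R @ x + t."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    return rot, tc - rot @ mc


def rmsd_to_reference(coords: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD (nm) after optimal rigid superposition (Kabsch)."""
    a = np.asarray(coords, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"selections differ: {a.shape} vs {b.shape}")
    rot, t = kabsch_transform(a, b)
    moved = a @ rot.T + t
    return float(np.sqrt(((moved - b) ** 2).sum(axis=1).mean()))


def average_structure(coord_sets: list, n_iter: int = 3) -> np.ndarray:
    """Per-bead mean after iterative superposition onto a running mean."""
    mean = np.asarray(coord_sets[0], dtype=float)
    for _ in range(n_iter):
        aligned = []
        for c in coord_sets:
            rot, t = kabsch_transform(np.asarray(c, dtype=float), mean)
            aligned.append(np.asarray(c) @ rot.T + t)
        mean = np.mean(aligned, axis=0)
    return mean


@dataclass
class BoundLikeResult:
    per_pair: np.ndarray        # weighted bound-like probability per neighbor pair
    aggregate: float            # probability of >= 1 bound-like pair
    mode: str
    rmsd_threshold: float


def _pair_backbone(frame: BeadChain, topology: DomainTopology, k: int
                   ) -> np.ndarray:
    mask = (_core_mask(frame, topology, k, backbone_only=True)
            | _core_mask(frame, topology, k + 1, backbone_only=True))
    return frame.positions[mask]


def bound_like_probability(ensemble: WeightedEnsemble, reference: BeadChain,
                           rmsd_threshold: float = 0.6,
                           mode: str = "any-pair",
                           nemo_surrogate: BeadChain | None = None,
                           clash_cutoff: float = 0.5) -> BoundLikeResult:
    """Probability that neighbor domain pairs adopt the bound-like geometry.

    A pair counts as bound-like when the backbone RMSD of its two cores to
    the two-domain reference (after Kabsch superposition) is below
    ``rmsd_threshold`` (nm).  ``mode='clash-excluded'`` additionally places
    the rigid partner surrogate onto each bound-like pair (using the
    superposition transform) and discounts frames in which any bead outside
    the pair comes within ``clash_cutoff`` of the surrogate.
    """
    if mode not in ("any-pair", "clash-excluded"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "clash-excluded" and nemo_surrogate is None:
        raise ValueError("clash-excluded mode needs a partner surrogate")
    top = ensemble.topology
    ref_top = DomainTopology(2, top.residues_per_domain, top.core_span,
                             core_ranges=top.core_ranges[:2],
                             linker_ranges=top.linker_ranges[:1])
    ref_sel = _pair_backbone(reference, ref_top, 0)
    n_pairs = top.n_domains - 1
    per_pair = np.zeros(n_pairs)
    aggregate = 0.0
    for frame, w in zip(ensemble.frames, ensemble.weights):
        any_ok = False
        for k in range(n_pairs):
            sel = _pair_backbone(frame, top, k)
            if rmsd_to_reference(sel, ref_sel) >= rmsd_threshold:
                continue
            if mode == "clash-excluded":
                # move the surrogate from reference frame onto this pair
                rot, t = kabsch_transform(ref_sel, sel)
                surrogate = nemo_surrogate.positions @ rot.T + t
                pair_mask = ((frame.domain_id == k) | (frame.domain_id == k + 1))
                rest = frame.positions[~pair_mask]
                if len(rest) and cdist(rest, surrogate).min() < clash_cutoff:
                    continue
            per_pair[k] += w
            any_ok = True
        if any_ok:
            aggregate += w
    return BoundLikeResult(per_pair=per_pair, aggregate=float(aggregate),
                           mode=mode, rmsd_threshold=rmsd_threshold)
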