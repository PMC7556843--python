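"""Monte-Carlo sampling with well-tempered parallel-bias metadynamics.

Chains are sampled as rigid domains connected by flexible linkers under a
surrogate potential (hard-core excluded volume, intra-core elastic network,
harmonic linker bonds, optional inter-domain attraction).  The move set --
pivot rotations about linker beads, single-linker-bead displacements and
whole-domain spins -- never deforms a core, so the elastic network acts
only as a guard term.

Enhanced sampling follows parallel-bias well-tempered metadynamics: each
collective variable carries its own one-dimensional bias V_k, deposited
Gaussians decay with the well-tempered factor exp(-V/(kT(gamma-1))), and the
combined bias is V_PB = -kT ln sum_k exp(-V_k/kT).  Final-bias reweighting
(w_t proportional to exp(+V_PB(s_t)/kT)) recovers unbiased averages.

Metainference restraints, when configured, are evaluated on the
walker-averaged forward model every ``stride`` steps (energy held constant
in between) and enter the Metropolis acceptance at those steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .chain import BeadChain, DomainTopology, ElasticNetworkSpec
from .cvs import CvDescriptor, evaluate_cv_set
from .metainference import (MetainferenceParams, RestraintSet,
                            metainference_energy, sample_scaling_offset)
from .saxs import FormFactorTable, debye_intensity

__all__ = [
    "ToyPotentialParams",
    "HillRecord",
    "BiasState",
    "toy_energy",
    "wt_hill_height",
    "pbmetad_bias",
    "run_metad_1d",
    "run_sampler",
    "reweight_final_bias",
    "SamplerResult",
]

KT_300K = 2.494  # kJ/mol


@dataclass(frozen=True)
class ToyPotentialParams:
    """Surrogate interaction parameters (kJ/mol, nm)."""

    hardcore_diameter: float = 0.4
    elastic_k: float = 500.0
    bond_length: float = 0.35
    bond_k: float = 1000.0
    attraction_depth: float = 0.0     # well between neighbor core centers
    attraction_center: float = 2.6
    attraction_width: float = 0.4


@dataclass(frozen=True)
class HillRecord:
    cv: int
    center: float
    width: float
    height: float
    step: int
    walker: int

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("hill width must be positive")
        if self.height < 0:
            raise ValueError("hill height must be non-negative")


@dataclass
class BiasState:
    """Per-CV one-dimensional bias grids plus the shared hill history."""

    cv_labels: list
    grid_edges: list          # per CV: (min, max)
    widths: np.ndarray        # per-CV Gaussian sigma
    gamma: float = 10.0
    kT: float = KT_300K
    base_height: float = 0.1  # kJ/mol
    hill_stride: int = 200
    n_grid: int = 512
    grids: list = field(default_factory=list)
    values: list = field(default_factory=list)
    hills: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.gamma <= 1:
            raise ValueError("bias factor gamma must exceed 1")
        self.widths = np.asarray(self.widths, dtype=float)
        if not self.grids:
            for lo, hi in self.grid_edges:
                self.grids.append(np.linspace(lo, hi, self.n_grid))
                self.values.append(np.zeros(self.n_grid))

    @property
    def n_cvs(self) -> int:
        return len(self.cv_labels)

    def bias_values(self, cv_values: np.ndarray) -> np.ndarray:
        """Per-CV bias V_k(s_k) by linear interpolation on the grids."""
        out = np.zeros(self.n_cvs)
        for k, s in enumerate(np.asarray(cv_values, dtype=float)):
            if np.isfinite(s):
                out[k] = np.interp(s, self.grids[k], self.values[k])
        return out

    def deposit(self, cv_values: np.ndarray, step: int = 0, walker: int = 0) -> None:
        """Add one parallel-bias hill set at the current CV values.

        Each CV receives a Gaussian whose height carries both the
        well-tempered decay and the parallel-bias conditional weight
        exp(-V_k/kT) / sum_j exp(-V_j/kT).
        """
        s = np.asarray(cv_values, dtype=float)
        v = self.bias_values(s)
        logw = -v / self.kT
        logw -= logsumexp(logw)
        cond = np.exp(logw)
        for k in range(self.n_cvs):
            if not np.isfinite(s[k]):
                continue
            h = wt_hill_height(v[k], self.base_height, self.gamma, self.kT) * cond[k]
            self.values[k] += h * np.exp(
                -0.5 * ((self.grids[k] - s[k]) / self.widths[k]) ** 2)
            self.hills.append(HillRecord(k, float(s[k]), float(self.widths[k]),
                                         float(h), step, walker))


def wt_hill_height(v_bias: float, base_height: float, gamma: float,
                   kT: float) -> float:
    """Well-tempered hill height: base * exp(-V/(kT*(gamma-1)))."""
    if gamma <= 1:
        raise ValueError("bias factor gamma must exceed 1")
    return float(base_height * np.exp(-v_bias / (kT * (gamma - 1.0))))


def pbmetad_bias(cv_values: np.ndarray, bias: BiasState) -> float:
    """Parallel-bias combination V_PB = -kT ln sum_k exp(-V_k(s_k)/kT)."""
    if bias.n_cvs == 0:
        raise ValueError("bias state has no CVs")
    v = bias.bias_values(cv_values)
    return float(-bias.kT * logsumexp(-v / bias.kT))


def reweight_final_bias(cv_values: np.ndarray, bias: BiasState) -> np.ndarray:
    """Final-bias weights w_t proportional to exp(+V_PB(s_t)/kT), normalized."""
    arr = np.atleast_2d(np.asarray(cv_values, dtype=float))
    v = np.array([pbmetad_bias(row, bias) for row in arr])
    logw = v / bias.kT
    w = np.exp(logw - logw.max())
    return w / w.sum()


def toy_energy(chain: BeadChain, params: ToyPotentialParams,
               topology: DomainTopology | None = None,
               en_spec: ElasticNetworkSpec | None = None) -> float:
    """Surrogate potential energy of one conformation (kJ/mol).

    Hard-core overlap between beads of different domains returns +inf (the
    move is then always rejected).
    """
    pos = chain.positions
    energy = 0.0
    # excluded volume between core beads of different domains (linker beads
    # are bonded pathways and carry no hard core)
    dom = chain.domain_id
    if topology is not None:
        in_core = np.zeros(len(pos), dtype=bool)
        for lo, hi in topology.core_ranges:
            in_core |= (chain.residue_index >= lo) & (chain.residue_index <= hi)
    else:
        in_core = np.ones(len(pos), dtype=bool)
    cp = pos[in_core]
    cd = dom[in_core]
    diff = cp[:, None, :] - cp[None, :, :]
    dm = np.sqrt((diff ** 2).sum(axis=-1))
    inter = cd[:, None] != cd[None, :]
    if np.any(dm[inter] < params.hardcore_diameter):
        return np.inf
    # elastic network
    if en_spec is not None and en_spec.member_pairs:
        ii, jj = np.array(en_spec.member_pairs).T
        r = np.linalg.norm(pos[ii] - pos[jj], axis=1)
        r0 = np.asarray(en_spec.reference_distances)
        energy += 0.5 * en_spec.force_constant * np.sum((r - r0) ** 2)
    # linker bonds: consecutive backbone beads spanning a linker residue
    if topology is not None and topology.n_domains > 1:
        bb = np.where(chain.backbone)[0]
        res = chain.residue_index[bb]
        linker_res = np.zeros(topology.n_residues + 1, dtype=bool)
        for lo, hi in topology.linker_ranges:
            linker_res[lo:hi + 1] = True
        a, b = bb[:-1], bb[1:]
        involves = linker_res[res[:-1]] | linker_res[res[1:]]
        if involves.any():
            r = np.linalg.norm(pos[a[involves]] - pos[b[involves]], axis=1)
            energy += 0.5 * params.bond_k * np.sum((r - params.bond_length) ** 2)
    # optional attraction between neighboring core centers
    if params.attraction_depth > 0 and topology is not None:
        from .chain import domain_center
        centers = np.array([domain_center(chain, topology, d)
                            for d in range(topology.n_domains)])
        for d in range(topology.n_domains - 1):
            dist = np.linalg.norm(centers[d + 1] - centers[d])
            energy -= params.attraction_depth * np.exp(
                -0.5 * ((dist - params.attraction_center) / params.attraction_width) ** 2)
    return float(energy)


def _random_rotation(rng: np.random.Generator, max_angle: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(-max_angle, max_angle)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def _propose_move(chain: BeadChain, topology: DomainTopology,
                  rng: np.random.Generator, max_angle: float,
                  max_disp: float) -> BeadChain:
    pos = chain.positions.copy()
    kind = rng.random()
    if kind < 0.5 and topology.n_domains > 1:
        # pivot: rotate everything downstream of a random linker bead
        lo, hi = topology.linker_ranges[rng.integers(topology.n_domains - 1)]
        cands = np.where((chain.residue_index >= lo) & (chain.residue_index <= hi))[0]
        pivot = int(rng.choice(cands))
        rot = _random_rotation(rng, max_angle)
        pos[pivot + 1:] = (pos[pivot + 1:] - pos[pivot]) @ rot.T + pos[pivot]
    elif kind < 0.8 and topology.n_domains > 1:
        # displace one linker bead
        linker_mask = np.zeros(len(pos), dtype=bool)
        for lo, hi in topology.linker_ranges:
            linker_mask |= (chain.residue_index >= lo) & (chain.residue_index <= hi)
        cands = np.where(linker_mask)[0]
        b = int(rng.choice(cands))
        pos[b] += rng.uniform(-max_disp, max_disp, size=3)
    else:
        # spin one domain about its core centroid
        d = int(rng.integers(topology.n_domains))
        mask = chain.domain_id == d
        center = pos[mask].mean(axis=0)
        rot = _random_rotation(rng, max_angle)
        pos[mask] = (pos[mask] - center) @ rot.T + center
    out = BeadChain(pos, chain.residue_index, chain.domain_id,
                    chain.bead_class, chain.backbone, chain.chain_length_residues)
    return out


@dataclass
class SamplerResult:
    frames: list                 # saved BeadChain frames (all walkers)
    frame_walkers: np.ndarray
    cv_log: np.ndarray           # (n_records, 2 + n_cvs): step, walker, CVs
    bias: BiasState | None
    acceptance_rate: float
    energies: np.ndarray
    params_log: list             # (step, scaling, offset) if metainference


def run_sampler(initial_chains: list, topology: DomainTopology,
                n_steps: int, potential: ToyPotentialParams,
                cv_set: list[CvDescriptor],
                seed: int,
                en_spec: ElasticNetworkSpec | None = None,
                bias: BiasState | None = None,
                restraints: RestraintSet | None = None,
                table: FormFactorTable | None = None,
                mi_params: MetainferenceParams | None = None,
                max_angle: float = 0.5, max_disp: float = 0.1,
                save_stride: int = 50) -> SamplerResult:
    """Multiple-walker Metropolis MC, optionally biased and restrained.

    All walkers share one hill history.  With restraints, the
    metainference energy of the walker-averaged forward model enters the
    acceptance only every ``mi_params.stride`` steps, and (scaling, offset)
    are Gibbs-updated at the same cadence.  Fully reproducible from
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    walkers = [BeadChain(c.positions.copy(), c.residue_index, c.domain_id,
                         c.bead_class, c.backbone, c.chain_length_residues)
               for c in initial_chains]
    n_walkers = len(walkers)
    energies = [toy_energy(w, potential, topology, en_spec) for w in walkers]
    cvs_now = [evaluate_cv_set(w, topology, cv_set) for w in walkers]
    kT = bias.kT if bias is not None else (mi_params.kT if mi_params else KT_300K)

    use_mi = restraints is not None
    if use_mi:
        mi_params = mi_params or MetainferenceParams()
        fwd = np.stack([debye_intensity(w, restraints.q, table).intensity
                        for w in walkers])
        mi_energy = metainference_energy(restraints, fwd.mean(axis=0), mi_params)

    frames, frame_walkers, cv_rows, params_log = [], [], [], []
    accepted = attempted = 0
    for step in range(n_steps):
        mi_step = use_mi and (step % mi_params.stride == 0)
        for k in range(n_walkers):
            prop = _propose_move(walkers[k], topology, rng, max_angle, max_disp)
            e_new = toy_energy(prop, potential, topology, en_spec)
            delta = e_new - energies[k]
            cvs_new = None
            if np.isfinite(e_new) and bias is not None:
                cvs_new = evaluate_cv_set(prop, topology, cv_set)
                delta += pbmetad_bias(cvs_new, bias) - pbmetad_bias(cvs_now[k], bias)
            fwd_new = mi_new = None
            if np.isfinite(delta) and mi_step:
                fwd_new = debye_intensity(prop, restraints.q, table).intensity
                mean_new = (fwd.sum(axis=0) - fwd[k] + fwd_new) / n_walkers
                mi_new = metainference_energy(restraints, mean_new, mi_params)
                delta += mi_new - mi_energy
            attempted += 1
            if np.isfinite(delta) and (delta <= 0 or rng.random() < np.exp(-delta / kT)):
                accepted += 1
                walkers[k] = prop
                energies[k] = e_new
                cvs_now[k] = (cvs_new if cvs_new is not None
                              else evaluate_cv_set(prop, topology, cv_set))
                if mi_step and fwd_new is not None:
                    fwd[k] = fwd_new
                    mi_energy = mi_new
        if use_mi and step % mi_params.stride == 0:
            mi_params, _ = sample_scaling_offset(mi_params, fwd.mean(axis=0),
                                                 restraints, rng)
            mi_energy = metainference_energy(restraints, fwd.mean(axis=0), mi_params)
            params_log.append((step, mi_params.scaling, mi_params.offset))
        if bias is not None and step > 0 and step % bias.hill_stride == 0:
            for k in range(n_walkers):
                bias.deposit(cvs_now[k], step=step, walker=k)
        if step % save_stride == 0:
            for k in range(n_walkers):
                frames.append(walkers[k])
                frame_walkers.append(k)
                cv_rows.append(np.concatenate(([step, k], cvs_now[k])))
    return SamplerResult(frames=frames,
                         frame_walkers=np.array(frame_walkers),
                         cv_log=np.array(cv_rows),
                         bias=bias,
                         acceptance_rate=accepted / max(attempted, 1),
                         energies=np.array(energies),
                         params_log=params_log)


def run_metad_1d(potential, x0: float, n_steps: int, bias: BiasState,
                 seed: int, step_size: float = 0.2,
                 ) -> tuple[np.ndarray, BiasState]:
    """Well-tempered metadynamics on a one-dimensional potential.

    A calibration utility: Metropolis MC on ``potential(x)`` (kJ/mol) with
    a single-CV bias (the coordinate itself).  Returns the visited
    coordinates (one per step) and the final bias, from which
    ``reweight_final_bias`` recovers unbiased statistics.
    """
    if bias.n_cvs != 1:
        raise ValueError("run_metad_1d needs a single-CV bias state")
    rng = np.random.default_rng(seed)
    x = float(x0)
    u = float(potential(x))
    xs = np.empty(n_steps)
    for step in range(n_steps):
        xp = x + rng.uniform(-step_size, step_size)
        up = float(potential(xp))
        delta = (up - u) + (bias.bias_values([xp])[0] - bias.bias_values([x])[0])
        if delta <= 0 or rng.random() < np.exp(-delta / bias.kT):
            x, u = xp, up
        if step > 0 and step % bias.hill_stride == 0:
            bias.deposit(np.array([x]), step=step)
        xs[step] = x
    return xs, bias
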