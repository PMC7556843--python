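"""Synthetic multidomain ensembles and noisy SAXS curves for closure tests.

The domain surrogate is a rigid icosahedral bead shell (12 beads, radius
~1.2 nm, the size of a ubiquitin core) -- deliberately not a force-field
ubiquitin: the generators exercise the statistical structure the analyses
assume (mixtures of compact/open neighbor pairs, self-avoiding chains,
independently bound-like pairs), not side-chain chemistry.  Chains follow
the package topology convention with 18 residues per domain (12-bead core
+ 6-bead linker), one backbone bead per residue.

Modes
-----
saw
    Pivot-algorithm Monte Carlo over rigid domains with hard-core excluded
    volume between cores: a self-avoiding chain whose end-to-end scaling
    should follow the Flory exponent ~0.59.
two_state
    Each neighbor pair is independently compact (minimum inter-core bead
    distance <= 0.6 nm) with probability ``p_compact``, else open.
bound_like
    Each neighbor pair independently adopts a stored reference "bound"
    geometry with probability ``p_bound``, else an open placement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .analysis import WeightedEnsemble
from .chain import BeadChain, DomainTopology, build_topology
from .saxs import FormFactorTable, SaxsCurve, ensemble_average_intensity

__all__ = [
    "GeneratorConfig",
    "surrogate_topology",
    "synth_chain_ensemble",
    "synth_saxs",
    "synth_reference_bound_pair",
]

RESIDUES_PER_DOMAIN = 18
CORE_SPAN = 12


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic generators.

    Defaults mirror the modelled system: ~1.2 nm domain cores, 6-bead
    linkers, neighbor-pair compact fraction ~45% (the diubiquitin range),
    bound-like pair probability ~3.2%, 2% multiplicative SAXS noise.
    """

    n_domains: int = 2
    frames: int = 200
    mode: str = "two_state"  # saw | two_state | bound_like
    p_compact: float = 0.45
    p_bound: float = 0.032
    core_radius: float = 1.2       # nm
    hardcore_diameter: float = 0.4  # nm, inter-core bead exclusion
    span_min: float = 0.5          # nm, linker anchor-to-anchor bounds
    span_max: float = 1.8
    noise_fraction: float = 0.02
    nemo_length: float = 11.4      # nm, partner surrogate span
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_compact <= 1 or not 0 <= self.p_bound <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_domains < 1:
            raise ValueError("n_domains must be >= 1")


def surrogate_topology(n_domains: int) -> DomainTopology:
    return build_topology(n_domains, residues_per_domain=RESIDUES_PER_DOMAIN,
                          core_span=CORE_SPAN)


def _ico_vertices(radius: float) -> np.ndarray:
    """12 icosahedron vertices, ordered so the first and last are antipodal
    (chain entry and exit points of the core)."""
    phi = (1 + np.sqrt(5)) / 2
    base = []
    for s1 in (1, -1):
        for s2 in (1, -1):
            base += [(0, s1, s2 * phi), (s1, s2 * phi, 0), (s2 * phi, 0, s1)]
    v = np.array(base, dtype=float)
    v /= np.linalg.norm(v[0])
    # reorder: v[0] first, its antipode last
    anti = int(np.argmin(v @ v[0]))
    order = [0] + [k for k in range(12) if k not in (0, anti)] + [anti]
    return v[order] * radius


def _rand_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _rand_unit(rng: np.random.Generator) -> np.ndarray:
    u = rng.normal(size=3)
    return u / np.linalg.norm(u)


class _ChainState:
    """Sequential parametrization of a rigid-domain chain: per-domain
    rotations R_k and per-joint (span, direction)."""

    def __init__(self, n_domains: int, template: np.ndarray):
        self.n = n_domains
        self.template = template  # (12, 3), vertex 0 at entry
        self.rotations = [np.eye(3) for _ in range(n_domains)]
        self.spans = np.full(max(n_domains - 1, 1), 2.4)[: n_domains - 1]
        self.dirs = [np.array([1.0, 0.0, 0.0]) for _ in range(n_domains - 1)]

    def core_positions(self) -> np.ndarray:
        """(n_domains, 12, 3) core bead coordinates."""
        out = np.empty((self.n, len(self.template), 3))
        start = np.zeros(3)
        for k in range(self.n):
            rel = (self.template - self.template[0]) @ self.rotations[k].T
            out[k] = start + rel
            if k < self.n - 1:
                anchor = out[k][-1]
                start = anchor + self.spans[k] * self.dirs[k]
        return out

    def min_intercore_distance(self, cores: np.ndarray | None = None) -> float:
        cores = self.core_positions() if cores is None else cores
        flat = cores.reshape(-1, 3)
        d = cdist(flat, flat)
        nb = len(self.template)
        dom = np.repeat(np.arange(self.n), nb)
        mask = dom[:, None] != dom[None, :]
        return float(d[mask].min()) if self.n > 1 else np.inf

    def to_chain(self, topology: DomainTopology) -> BeadChain:
        cores = self.core_positions()
        nb = len(self.template)
        linker_len = topology.linker_length
        positions, residues, domains = [], [], []
        for k in range(self.n):
            base_res = topology.residues_per_domain * k
            positions.append(cores[k])
            residues.extend(base_res + np.arange(1, nb + 1))
            domains.extend([k] * nb)
            if k < self.n - 1:
                anchor = cores[k][-1]
                nxt = cores[k + 1][0]
                frac = np.arange(1, linker_len + 1) / (linker_len + 1)
                beads = anchor + frac[:, None] * (nxt - anchor)
                # zigzag off the axis so linker dihedrals are well defined
                axis = nxt - anchor
                perp = np.cross(axis, [0.0, 0.0, 1.0])
                if np.linalg.norm(perp) < 1e-8:
                    perp = np.cross(axis, [1.0, 0.0, 0.0])
                perp /= np.linalg.norm(perp)
                perp2 = np.cross(axis, perp)
                perp2 /= np.linalg.norm(perp2)
                signs = (-1.0) ** np.arange(linker_len)
                beads = beads + 0.06 * signs[:, None] * perp + \
                    0.04 * np.cos(np.arange(linker_len))[:, None] * perp2
                positions.append(beads)
                residues.extend(base_res + nb + np.arange(1, linker_len + 1))
                domains.extend([k] * linker_len)
        pos = np.vstack(positions)
        n_beads = len(pos)
        return BeadChain(pos, np.array(residues), np.array(domains),
                         np.array(["BB"] * n_beads, dtype=object),
                         np.ones(n_beads, dtype=bool),
                         topology.n_residues)


def _pivot_move(state: _ChainState, rng: np.random.Generator,
                cfg: GeneratorConfig) -> bool:
    """One pivot/spin/stretch move; accepted iff self-avoiding."""
    old_rot = [r.copy() for r in state.rotations]
    old_spans = state.spans.copy()
    old_dirs = [d.copy() for d in state.dirs]
    kind = rng.random()
    if state.n == 1 or kind < 0.55:
        if state.n == 1:
            state.rotations[0] = _rand_rotation(rng) @ state.rotations[0]
        else:
            j = int(rng.integers(state.n - 1))
            q = _rand_rotation(rng)
            for m in range(j, state.n - 1):
                state.dirs[m] = q @ state.dirs[m]
            for m in range(j + 1, state.n):
                state.rotations[m] = q @ state.rotations[m]
    elif kind < 0.8:
        j = int(rng.integers(1, state.n))
        state.rotations[j] = _rand_rotation(rng) @ state.rotations[j]
    else:
        j = int(rng.integers(state.n - 1))
        state.spans[j] = rng.uniform(cfg.span_min, cfg.span_max)
    if state.min_intercore_distance() < cfg.hardcore_diameter:
        state.rotations, state.spans, state.dirs = old_rot, old_spans, old_dirs
        return False
    return True


def _saw_frames(cfg: GeneratorConfig, topology: DomainTopology,
                template: np.ndarray, rng: np.random.Generator) -> list:
    state = _ChainState(cfg.n_domains, template)
    burn_in = 30 * cfg.n_domains
    per_frame = 3 * max(cfg.n_domains - 1, 1)
    for _ in range(burn_in):
        _pivot_move(state, rng, cfg)
    frames = []
    for _ in range(cfg.frames):
        for _ in range(per_frame):
            _pivot_move(state, rng, cfg)
        frames.append(state.to_chain(topology))
    return frames


def _place_joint(state: _ChainState, joint: int, target_min: float,
                 rng: np.random.Generator, cfg: GeneratorConfig,
                 max_tries: int = 60) -> None:
    """Sample joint geometry so that the (joint, joint+1) minimum inter-core
    distance hits ``target_min`` and no hard-core overlap with the partial
    chain exists."""
    nb = len(state.template)
    for _ in range(max_tries):
        state.dirs[joint] = _rand_unit(rng)
        state.rotations[joint + 1] = _rand_rotation(rng)
        state.spans[joint] = max(target_min + 2 * cfg.core_radius * 0.2, cfg.span_min)
        ok = False
        for _ in range(12):
            cores = state.core_positions()
            m = float(cdist(cores[joint], cores[joint + 1]).min())
            if abs(m - target_min) < 0.02:
                ok = True
                break
            state.spans[joint] += target_min - m
            if state.spans[joint] <= 0.1:
                break
        if not ok:
            continue
        # check the new domain against all earlier ones
        cores = state.core_positions()
        earlier = cores[: joint + 1].reshape(-1, 3)
        d_all = cdist(earlier, cores[joint + 1])
        dom = np.repeat(np.arange(joint + 1), nb)
        non_neighbor = dom < joint
        hard_ok = d_all[non_neighbor].min() >= cfg.hardcore_diameter if non_neighbor.any() else True
        if hard_ok and d_all[~non_neighbor].min() >= min(target_min - 0.02,
                                                         cfg.hardcore_diameter):
            return
    raise RuntimeError(f"could not place joint {joint} at min distance "
                       f"{target_min:.2f} nm within {max_tries} tries")


def _two_state_frame(cfg: GeneratorConfig, topology: DomainTopology,
                     template: np.ndarray, rng: np.random.Generator,
                     bound_joint: tuple | None = None) -> BeadChain:
    """One frame with independently compact/open (or bound/open) joints.

    ``bound_joint``, when given, is ((span, direction, rotation), p_bound):
    joints adopt that exact geometry with probability p_bound.
    """
    state = _ChainState(cfg.n_domains, template)
    state.rotations[0] = _rand_rotation(rng)
    for j in range(cfg.n_domains - 1):
        if bound_joint is not None:
            geom, p = bound_joint
            if rng.random() < p:
                span, direction, rot = geom
                state.spans[j] = span
                # rotate the stored joint geometry into the current frame
                prev = state.rotations[j]
                state.dirs[j] = prev @ direction
                state.rotations[j + 1] = prev @ rot
                cores = state.core_positions()
                earlier = cores[:j].reshape(-1, 3) if j else np.empty((0, 3))
                if len(earlier) and cdist(earlier, cores[j + 1]).min() < cfg.hardcore_diameter:
                    raise RuntimeError("bound placement clashes")
                continue
            target = rng.uniform(0.8, 2.2)
        elif rng.random() < cfg.p_compact:
            target = rng.uniform(cfg.hardcore_diameter + 0.02, 0.58)
        else:
            target = rng.uniform(0.8, 2.2)
        _place_joint(state, j, target, rng, cfg)
    return state.to_chain(topology)


def synth_chain_ensemble(config: GeneratorConfig,
                         reference_joint=None) -> WeightedEnsemble:
    """Generate a uniformly weighted synthetic ensemble per ``config.mode``.

    Reproducible from ``config.seed``; raises after bounded retries if the
    requested geometry is infeasible.
    """
    rng = np.random.default_rng(config.seed)
    topology = surrogate_topology(config.n_domains)
    template = _ico_vertices(config.core_radius)
    if config.mode == "saw":
        frames = _saw_frames(config, topology, template, rng)
    elif config.mode in ("two_state", "bound_like"):
        bound = None
        if config.mode == "bound_like":
            if reference_joint is None:
                reference_joint = _reference_joint_geometry(config)
            bound = (reference_joint, config.p_bound)
        frames = []
        for _ in range(config.frames):
            for attempt in range(30):
                try:
                    frames.append(_two_state_frame(config, topology, template,
                                                   rng, bound_joint=bound))
                    break
                except RuntimeError:
                    if attempt == 29:
                        raise
    else:
        raise ValueError(f"unknown mode {config.mode!r}")
    weights = np.full(len(frames), 1.0 / len(frames))
    return WeightedEnsemble(frames=frames, weights=weights, topology=topology)


def synth_saxs(ensemble: WeightedEnsemble, q_grid: np.ndarray,
               table: FormFactorTable, noise_fraction: float,
               seed: int) -> SaxsCurve:
    """Ensemble-averaged Debye curve with multiplicative Gaussian noise.

    The sigma column records the noise scale per point; with zero noise the
    clean curve is returned unchanged (no sigma).
    """
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    clean = ensemble_average_intensity(ensemble.frames, ensemble.weights,
                                       q_grid, table)
    if noise_fraction == 0:
        return clean
    rng = np.random.default_rng(seed)
    noisy = clean.intensity * (1.0 + noise_fraction * rng.standard_normal(len(clean)))
    sigma = noise_fraction * np.abs(clean.intensity)
    return SaxsCurve(clean.q, noisy, sigma)


def _reference_joint_geometry(config: GeneratorConfig):
    """Deterministic compact joint geometry used as the 'bound' reference:
    (span, direction, relative rotation), tuned so the pair's minimum
    inter-core distance is ~0.45 nm."""
    template = _ico_vertices(config.core_radius)
    c, s = np.cos(2.0), np.sin(2.0)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    direction = np.array([1.0, 0.0, 0.0])
    state = _ChainState(2, template)
    state.rotations[1] = rot
    state.dirs[0] = direction
    target = 0.45
    state.spans[0] = 1.2
    for _ in range(20):
        cores = state.core_positions()
        m = float(cdist(cores[0], cores[1]).min())
        if abs(m - target) < 1e-6:
            break
        state.spans[0] += target - m
    return (float(state.spans[0]), direction, rot)


def synth_reference_bound_pair(config: GeneratorConfig | None = None
                               ) -> tuple[BeadChain, BeadChain]:
    """Deterministic bound-like two-domain reference plus partner surrogate.

    The partner surrogate is a rigid two-rod (coiled-coil-like) bead model
    whose first and last beads sit on the rod axis ``config.nemo_length``
    apart (11.4 nm by default), placed alongside the bound pair without
    touching it.
    """
    config = config or GeneratorConfig()
    template = _ico_vertices(config.core_radius)
    span, direction, rot = _reference_joint_geometry(config)
    state = _ChainState(2, template)
    state.spans[0] = span
    state.dirs[0] = direction
    state.rotations[1] = rot
    topology = surrogate_topology(2)
    reference = state.to_chain(topology)

    cores = state.core_positions()
    mid = cores.reshape(-1, 3).mean(axis=0)
    half = config.nemo_length / 2.0
    # rods sit 1 nm above the topmost reference bead: alongside, not touching
    axis_z = reference.positions[:, 2].max() + 1.0
    xs = np.arange(-half + 0.15, half, 0.3)
    rod1 = np.column_stack([mid[0] + xs, np.full_like(xs, mid[1] - 0.4),
                            np.full_like(xs, axis_z)])
    rod2 = np.column_stack([mid[0] + xs, np.full_like(xs, mid[1] + 0.4),
                            np.full_like(xs, axis_z)])
    cap_a = np.array([[mid[0] - half, mid[1], axis_z]])
    cap_b = np.array([[mid[0] + half, mid[1], axis_z]])
    pos = np.vstack([cap_a, rod1, rod2, cap_b])
    n = len(pos)
    nemo = BeadChain(pos, np.arange(1, n + 1), np.zeros(n, dtype=int),
                     np.array(["NEMO"] * n, dtype=object),
                     np.ones(n, dtype=bool), n)
    return reference, nemo
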