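"""Residue/domain bookkeeping and geometric primitives for linear multidomain chains.

A chain of N domains is laid out head-to-tail: each domain contributes a
rigid "core" of ``core_span`` residues followed by a flexible linker of
``residues_per_domain - core_span`` residues, except the last domain which
ends at its core.  For linear polyubiquitin the defaults are 76 residues
per domain with a 70-residue core, giving cores 1-70, 77-146, 153-222,
229-298, ... and 6-residue linkers in between.

All coordinates are in nanometres internally; Angstrom conversion happens
only at the file I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DomainTopology",
    "BeadChain",
    "ElasticNetworkSpec",
    "build_topology",
    "build_elastic_network",
    "domain_center",
]


@dataclass(frozen=True)
class DomainTopology:
    """Residue layout of an N-domain linear chain.

    ``core_ranges`` and ``linker_ranges`` are inclusive 1-based residue
    intervals; residue numbering is global over the whole chain.
    """

    n_domains: int
    residues_per_domain: int = 76
    core_span: int = 70
    core_ranges: tuple[tuple[int, int], ...] = field(default=())
    linker_ranges: tuple[tuple[int, int], ...] = field(default=())

    @property
    def n_residues(self) -> int:
        """Total residue count; the last domain carries no trailing linker."""
        return self.residues_per_domain * (self.n_domains - 1) + self.core_span

    @property
    def linker_length(self) -> int:
        return self.residues_per_domain - self.core_span

    def domain_of_residue(self, residue: int) -> int:
        """0-based domain index owning a global residue number."""
        if not 1 <= residue <= self.n_residues:
            raise ValueError(f"residue {residue} outside chain (1..{self.n_residues})")
        return min((residue - 1) // self.residues_per_domain, self.n_domains - 1)

    def core_residues(self, domain: int) -> range:
        lo, hi = self.core_ranges[domain]
        return range(lo, hi + 1)


def build_topology(
    n_domains: int,
    residues_per_domain: int = 76,
    core_span: int = 70,
) -> DomainTopology:
    """Construct the residue layout of an ``n_domains``-long linear chain.

    With the polyubiquitin defaults cores fall at [76k+1, 76k+70] and the
    6-residue linkers at [76k+71, 76k+76] for every junction.
    """
    if not isinstance(n_domains, (int, np.integer)) or n_domains < 1:
        raise ValueError(f"n_domains must be a positive integer, got {n_domains!r}")
    if not 1 <= core_span <= residues_per_domain:
        raise ValueError("core_span must satisfy 1 <= core_span <= residues_per_domain")
    P, S = residues_per_domain, core_span
    cores = tuple((P * k + 1, P * k + S) for k in range(n_domains))
    linkers = (tuple((P * k + S + 1, P * (k + 1)) for k in range(n_domains - 1))
               if S < P else ())
    return DomainTopology(
        n_domains=int(n_domains),
        residues_per_domain=P,
        core_span=S,
        core_ranges=cores,
        linker_ranges=linkers,
    )


@dataclass
class BeadChain:
    """One conformation: bead coordinates with residue/domain/class labels.

    positions : (n_beads, 3) float array, nm
    residue_index : 1-based global residue number per bead (non-decreasing)
    domain_id : 0-based domain index per bead
    bead_class : label per bead, keys the scattering form-factor table
    backbone : boolean flag per bead (CVs and elastic networks use backbone
        beads only)
    """

    positions: np.ndarray
    residue_index: np.ndarray
    domain_id: np.ndarray
    bead_class: np.ndarray
    backbone: np.ndarray
    chain_length_residues: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.domain_id = np.asarray(self.domain_id, dtype=int)
        self.bead_class = np.asarray(self.bead_class, dtype=object)
        self.backbone = np.asarray(self.backbone, dtype=bool)
        n = len(self.positions)
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be (n, 3)")
        for name in ("residue_index", "domain_id", "bead_class", "backbone"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length {len(getattr(self, name))} != {n} beads")
        if self.chain_length_residues == 0:
            self.chain_length_residues = int(self.residue_index.max(initial=0))

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def validate(self, bond_bounds: tuple[float, float] = (0.2, 0.5),
                 check_bonds: bool = False) -> None:
        """Check structural invariants; raise ValueError on violation.

        Bond-length checking between consecutive backbone beads is optional
        because surrogate bead geometries (e.g. shell cores) use wider
        spacings than a Martini backbone.
        """
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if np.any(np.diff(self.residue_index) < 0):
            raise ValueError("residue indices must be non-decreasing")
        present = np.unique(self.residue_index)
        expected = np.arange(1, self.chain_length_residues + 1)
        if not np.array_equal(present, expected):
            missing = sorted(set(expected) - set(present))
            raise ValueError(f"residues without beads: {missing[:5]}")
        if check_bonds:
            bb = self.positions[self.backbone]
            d = np.linalg.norm(np.diff(bb, axis=0), axis=1)
            lo, hi = bond_bounds
            bad = np.where((d < lo) | (d > hi))[0]
            if bad.size:
                raise ValueError(
                    f"backbone bond {bad[0]} length {d[bad[0]]:.3f} nm outside "
                    f"[{lo}, {hi}] nm"
                )

    def select(self, residues: Sequence[int] | None = None,
               backbone_only: bool = False,
               domain: int | None = None) -> np.ndarray:
        """Boolean mask over beads."""
        mask = np.ones(self.n_beads, dtype=bool)
        if residues is not None:
            mask &= np.isin(self.residue_index, np.asarray(list(residues)))
        if backbone_only:
            mask &= self.backbone
        if domain is not None:
            mask &= self.domain_id == domain
        return mask

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "BeadChain":
        """Return a rigidly transformed copy (rotation applied first)."""
        pos = self.positions
        if rotation is not None:
            pos = pos @ np.asarray(rotation).T
        if translation is not None:
            pos = pos + np.asarray(translation)
        return BeadChain(pos, self.residue_index.copy(), self.domain_id.copy(),
                         self.bead_class.copy(), self.backbone.copy(),
                         self.chain_length_residues)


def domain_center(chain: BeadChain, topology: DomainTopology, domain: int,
                  sub_range: tuple[int, int] | None = None) -> np.ndarray:
    """Geometric center of the backbone beads of one domain core.

    ``sub_range`` is a domain-local inclusive residue interval (e.g. (1, 36)
    for the first half of a ubiquitin core) and must lie within the core.
    CG bead masses are nearly uniform, so the unweighted geometric center
    stands in for the center of mass.
    """
    if not 0 <= domain < topology.n_domains:
        raise ValueError(f"domain {domain} outside 0..{topology.n_domains - 1}")
    lo, hi = topology.core_ranges[domain]
    if sub_range is not None:
        a, b = sub_range
        if not (1 <= a <= b <= topology.core_span):
            raise ValueError(f"sub_range {sub_range} outside core (1..{topology.core_span})")
        offset = topology.residues_per_domain * domain
        lo, hi = offset + a, offset + b
    mask = chain.backbone & (chain.residue_index >= lo) & (chain.residue_index <= hi)
    if not mask.any():
        raise ValueError(f"no backbone beads in residues {lo}..{hi}")
    return chain.positions[mask].mean(axis=0)


@dataclass(frozen=True)
class ElasticNetworkSpec:
    """Harmonic restraints holding one domain core rigid.

    member_pairs index backbone beads within a single core; reference
    distances are taken from the structure the network was built on.
    """

    force_constant: float = 500.0  # kJ mol^-1 nm^-2
    cutoff: float = 0.9  # nm
    member_pairs: tuple[tuple[int, int], ...] = ()
    reference_distances: tuple[float, ...] = ()


def build_elastic_network(chain: BeadChain, topology: DomainTopology,
                          cutoff: float = 0.9,
                          force_constant: float = 500.0) -> ElasticNetworkSpec:
    """Collect backbone-bead pairs within ``cutoff`` inside each core.

    Pairs never span domains and never touch linker residues: the network
    preserves each fold while leaving inter-domain arrangement free.
    """
    pairs: list[tuple[int, int]] = []
    dists: list[float] = []
    for d in range(topology.n_domains):
        lo, hi = topology.core_ranges[d]
        idx = np.where(chain.backbone & (chain.residue_index >= lo)
                       & (chain.residue_index <= hi))[0]
        pos = chain.positions[idx]
        diff = pos[:, None, :] - pos[None, :, :]
        dm = np.linalg.norm(diff, axis=-1)
        ii, jj = np.where(np.triu(dm <= cutoff, k=1))
        for a, b in zip(ii, jj):
            pairs.append((int(idx[a]), int(idx[b])))
            dists.append(float(dm[a, b]))
    return ElasticNetworkSpec(force_constant=force_constant, cutoff=cutoff,
                              member_pairs=tuple(pairs),
                              reference_distances=tuple(dists))
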