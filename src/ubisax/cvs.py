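"""Collective variables for multidomain chains.

Four CV kinds drive the enhanced sampling and the analyses: pairwise
distances between domain-core centers, inter-domain torsions (the dihedral
of the two domain axes, each axis running from the first to the second half
of its core), the backbone radius of gyration, and one "alphabeta" torsional
similarity per linker, alphabeta = 1/2 * sum_k (1 + cos(phi_k - phi_ref_k))
over the linker backbone dihedrals.

For an N-domain chain the full set is one distance and one torsion per
unordered domain pair, a single Rg, and one alphabeta per linker:
2*C(N,2) + 1 + (N-1) descriptors, i.e. 4, 9, 16 for N = 2, 3, 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chain import BeadChain, DomainTopology, domain_center

__all__ = [
    "CvDescriptor",
    "core_center_distance",
    "interdomain_torsion",
    "backbone_rg",
    "linker_dihedrals",
    "alphabeta",
    "enumerate_cv_set",
    "evaluate_cv",
    "evaluate_cv_set",
]

TORSION_UNDEFINED = np.nan  # sentinel for degenerate (collinear) geometry


@dataclass(frozen=True)
class CvDescriptor:
    """One collective variable: its kind and the selections it acts on."""

    kind: str  # core_distance | interdomain_torsion | backbone_rg | alphabeta
    domains: tuple[int, ...] = ()
    linker: int | None = None
    reference_angles: tuple[float, ...] = ()

    @property
    def label(self) -> str:
        if self.kind == "core_distance":
            return f"d_{self.domains[0]}_{self.domains[1]}"
        if self.kind == "interdomain_torsion":
            return f"phi_{self.domains[0]}_{self.domains[1]}"
        if self.kind == "backbone_rg":
            return "rg"
        return f"alphabeta_{self.linker}"


def core_center_distance(chain: BeadChain, topology: DomainTopology,
                         i: int, j: int) -> float:
    """Euclidean distance (nm) between the core centers of domains i and j."""
    if i == j:
        raise ValueError("domain indices must differ")
    ci = domain_center(chain, topology, i)
    cj = domain_center(chain, topology, j)
    return float(np.linalg.norm(ci - cj))


def _dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
              p3: np.ndarray) -> float:
    """IUPAC (right-handed) dihedral of four points, in (-pi, pi]."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12 or nb2 < 1e-12:
        return TORSION_UNDEFINED
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / nb2
    return float(np.arctan2(y, x))


def _core_halves(topology: DomainTopology) -> tuple[tuple[int, int], tuple[int, int]]:
    """Split a core into its two halves; the first half takes the extra
    residue (70 -> 1..36 and 37..70)."""
    span = topology.core_span
    if span < 2:
        raise ValueError("core span < 2 cannot define a domain axis")
    split = min(span // 2 + 1, span - 1)
    return (1, split), (split + 1, span)


def interdomain_torsion(chain: BeadChain, topology: DomainTopology,
                        i: int, j: int) -> float:
    """Dihedral between the axes of domains i and j, radians in (-pi, pi].

    Each domain axis runs N->C, from the center of the first half of its
    core to the center of the second half; the dihedral is taken over the
    points (i first-half, i second-half, j second-half, j first-half).
    Returns NaN for degenerate collinear geometry.
    """
    if i == j:
        raise ValueError("domain indices must differ")
    h1, h2 = _core_halves(topology)
    a = domain_center(chain, topology, i, h1)
    b = domain_center(chain, topology, i, h2)
    c = domain_center(chain, topology, j, h2)
    d = domain_center(chain, topology, j, h1)
    return _dihedral(a, b, c, d)


def backbone_rg(chain: BeadChain) -> float:
    """Radius of gyration (nm) over backbone beads only."""
    pos = chain.positions[chain.backbone]
    if len(pos) == 0:
        raise ValueError("chain has no backbone beads")
    centered = pos - pos.mean(axis=0)
    return float(np.sqrt((centered ** 2).sum(axis=1).mean()))


def linker_dihedrals(chain: BeadChain, topology: DomainTopology,
                     linker: int) -> np.ndarray:
    """Backbone dihedrals over consecutive beads of one linker (radians).

    A linker of L backbone beads yields L - 3 dihedrals.
    """
    lo, hi = topology.linker_ranges[linker]
    idx = np.where(chain.backbone & (chain.residue_index >= lo)
                   & (chain.residue_index <= hi))[0]
    pos = chain.positions[idx]
    if len(pos) < 4:
        raise ValueError(f"linker {linker} has {len(pos)} backbone beads; need >= 4")
    return np.array([_dihedral(*pos[k:k + 4]) for k in range(len(pos) - 3)])


def alphabeta(dihedrals: np.ndarray, reference_angles: np.ndarray | float = 0.0) -> float:
    """Torsional-similarity CV: 1/2 * sum_k (1 + cos(phi_k - phi_ref_k)).

    Ranges from 0 (every angle anti to its reference) to n (all at
    reference).
    """
    phi = np.asarray(dihedrals, dtype=float)
    ref = np.broadcast_to(np.asarray(reference_angles, dtype=float), phi.shape)
    return float(0.5 * np.sum(1.0 + np.cos(phi - ref)))


def enumerate_cv_set(topology: DomainTopology) -> list[CvDescriptor]:
    """The full CV set for biasing an N-domain chain.

    Ordering is deterministic: core distances for all pairs (lexicographic),
    then inter-domain torsions (same order), then the backbone Rg, then one
    alphabeta per linker N-to-C.
    """
    n = topology.n_domains
    if n < 2:
        raise ValueError("CV enumeration requires at least 2 domains")
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    cvs = [CvDescriptor("core_distance", domains=p) for p in pairs]
    cvs += [CvDescriptor("interdomain_torsion", domains=p) for p in pairs]
    cvs.append(CvDescriptor("backbone_rg"))
    n_dihedrals = max(topology.linker_length - 3, 0)
    cvs += [CvDescriptor("alphabeta", linker=k,
                         reference_angles=(0.0,) * n_dihedrals)
            for k in range(n - 1)]
    return cvs


def evaluate_cv(chain: BeadChain, topology: DomainTopology,
                descriptor: CvDescriptor) -> float:
    if descriptor.kind == "core_distance":
        return core_center_distance(chain, topology, *descriptor.domains)
    if descriptor.kind == "interdomain_torsion":
        return interdomain_torsion(chain, topology, *descriptor.domains)
    if descriptor.kind == "backbone_rg":
        return backbone_rg(chain)
    if descriptor.kind == "alphabeta":
        phi = linker_dihedrals(chain, topology, descriptor.linker)
        ref = descriptor.reference_angles or 0.0
        return alphabeta(phi, np.asarray(ref) if descriptor.reference_angles else 0.0)
    raise ValueError(f"unknown CV kind {descriptor.kind!r}")


def evaluate_cv_set(chain: BeadChain, topology: DomainTopology,
                    descriptors: list[CvDescriptor]) -> np.ndarray:
    return np.array([evaluate_cv(chain, topology, d) for d in descriptors])
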