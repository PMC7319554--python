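"""Cα elastic network: springs, perturbations, Hessians and normal modes.

The protein is a set of unit-mass beads at the Cα positions, joined by
harmonic springs between all pairs within a distance cutoff:

    E = Σ_<i,j> k_ij (d_ij − d0_ij)²

with d0 the native pair distance, so the native structure is the energy
minimum.  Perturbations act on the spring constants only:

* ligand binding to a site S adds springs of stiffness α·k between the
  residue pairs of S (the bound ligand rigidly couples the pocket);
* an UP (stabilizing, bulkier-residue) mutation at m multiplies every
  spring incident to m by θ_up > 1; a DOWN (destabilizing, Ala/Gly-like)
  mutation multiplies them by θ_down < 1.

Normal modes are eigenpairs of the 3N×3N Hessian of E at the native
coordinates; the six zero-frequency rigid-body modes are discarded and the
lowest-frequency internal modes retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .structures import CaStructure, ResidueId, Site

logger = logging.getLogger(__name__)

__all__ = [
    "ElasticNetwork",
    "Perturbation",
    "ModeSet",
    "NetworkError",
    "build_network",
    "perturb_network",
    "hessian",
    "normal_modes",
    "elastic_energy",
]

UP = "UP"
DOWN = "DOWN"


class NetworkError(ValueError):
    """Raised for invalid or disconnected elastic networks."""


@dataclass
class ElasticNetwork:
    """Springs over a Cα structure.

    ``edges_i < edges_j`` elementwise, no duplicates; ``d0`` holds the native
    pair distances (Å); ``k`` the per-spring constants (k_BT/Å²); ``k_unit``
    the uniform build constant referenced by binding perturbations.
    """

    structure: CaStructure
    edges_i: np.ndarray
    edges_j: np.ndarray
    k: np.ndarray
    d0: np.ndarray
    cutoff: float
    k_unit: float

    @property
    def n_nodes(self) -> int:
        return len(self.structure)

    @property
    def n_edges(self) -> int:
        return len(self.k)

    def neighbor_lists(self) -> list[list[int]]:
        nbrs: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, j in zip(self.edges_i, self.edges_j):
            nbrs[i].append(j)
            nbrs[j].append(i)
        return nbrs

    def edge_index(self) -> dict[tuple[int, int], int]:
        return {(int(i), int(j)): e for e, (i, j) in enumerate(zip(self.edges_i, self.edges_j))}


@dataclass(frozen=True)
class Perturbation:
    """Ligand bindings and point mutations applied jointly in one energy.

    ``binding_sites`` is a sequence of (Site, α) with α > 0; ``mutations`` a
    sequence of (ResidueId, 'UP' | 'DOWN', θ) with θ > 1 for UP and
    0 ≤ θ < 1 for DOWN.  A residue may carry at most one mutation.
    """

    binding_sites: tuple = ()
    mutations: tuple = ()

    def __post_init__(self):
        for site, alpha in self.binding_sites:
            if alpha <= 0:
                raise ValueError(f"binding scale α must be > 0 (site {site.label!r})")
        seen: set[ResidueId] = set()
        for rid, direction, theta in self.mutations:
            if direction == UP and theta <= 1:
                raise ValueError(f"UP mutation at {rid} needs θ > 1, got {theta}")
            if direction == DOWN and not 0 <= theta < 1:
                raise ValueError(f"DOWN mutation at {rid} needs 0 ≤ θ < 1, got {theta}")
            if direction not in (UP, DOWN):
                raise ValueError(f"mutation direction must be UP or DOWN, got {direction!r}")
            if rid in seen:
                raise ValueError(f"residue {rid} mutated more than once")
            seen.add(rid)

    @property
    def is_empty(self) -> bool:
        return not self.binding_sites and not self.mutations

    @classmethod
    def binding(cls, site: Site, alpha: float = 1.0) -> "Perturbation":
        return cls(binding_sites=((site, alpha),))

    @classmethod
    def mutation(cls, rid: ResidueId, direction: str, theta: float) -> "Perturbation":
        return cls(mutations=((rid, direction, theta),))

    def describe(self) -> dict:
        return {
            "binding_sites": [
                {"label": s.label, "residues": sorted(str(r) for r in s.members), "alpha": a}
                for s, a in self.binding_sites
            ],
            "mutations": [
                {"residue": str(r), "direction": d, "theta": t} for r, d, t in self.mutations
            ],
        }


@dataclass
class ModeSet:
    """Retained non-rigid normal modes, lowest frequency first.

    ``vectors`` has shape (n_kept, 3N); ``vectors3`` views each mode as
    per-residue 3-vectors.  Eigenvectors are orthonormal and sign-fixed
    (first component of magnitude > 1e-8 made positive).
    """

    eigenvalues: np.ndarray
    vectors: np.ndarray
    n_rigid: int

    @property
    def n_kept(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_residues(self) -> int:
        return self.vectors.shape[1] // 3

    @property
    def vectors3(self) -> np.ndarray:
        return self.vectors.reshape(self.n_kept, self.n_residues, 3)


def build_network(structure: CaStructure, cutoff: float = 10.0, k: float = 1.0) -> ElasticNetwork:
    """Connect all Cα pairs within ``cutoff`` Å with uniform springs.

    Raises :class:`NetworkError` (listing the components) if the resulting
    network is disconnected — downstream free energies would be meaningless.
    """
    if cutoff <= 3.8:
        raise NetworkError("cutoff must exceed 3.8 Å or consecutive residues disconnect")
    if k <= 0:
        raise NetworkError("spring constant must be positive")
    d = squareform(pdist(structure.coords))
    n = len(structure)
    iu, ju = np.triu_indices(n, k=1)
    mask = d[iu, ju] <= cutoff
    ei, ej = iu[mask], ju[mask]
    d0 = d[ei, ej]

    adj = coo_matrix((np.ones_like(d0), (ei, ej)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        comps = [
            [str(structure.residues[i].rid) for i in np.flatnonzero(labels == c)]
            for c in range(n_comp)
        ]
        raise NetworkError(
            f"elastic network disconnected at cutoff {cutoff} Å: "
            + "; ".join(f"component {c}: {m[0]}..{m[-1]} ({len(m)})" for c, m in enumerate(comps))
        )
    return ElasticNetwork(
        structure=structure,
        edges_i=ei.astype(np.intp),
        edges_j=ej.astype(np.intp),
        k=np.full(len(d0), float(k)),
        d0=d0.astype(float),
        cutoff=float(cutoff),
        k_unit=float(k),
    )


def perturb_network(
    network: ElasticNetwork,
    perturbation: Perturbation,
    site_pairs: str = "all",
) -> ElasticNetwork:
    """Return a new network with the perturbed spring constants.

    Mutations rescale the native springs incident to the mutated residue by
    θ.  Binding then adds springs of stiffness α·k_unit between the residue
    pairs of each bound site — between all pairs when ``site_pairs='all'``
    (a bound ligand couples the whole pocket, even across the cutoff), or
    only between pairs within the network cutoff otherwise.  Equilibrium
    lengths never change; the input network is not modified.
    """
    structure = network.structure
    for rid, _, _ in perturbation.mutations:
        structure.index(rid)  # KeyError naming the residue if absent
    for site, _ in perturbation.binding_sites:
        site.validate(structure)

    k = network.k.copy()
    ei = list(network.edges_i)
    ej = list(network.edges_j)
    d0 = list(network.d0)

    for rid, _, theta in perturbation.mutations:
        m = structure.index(rid)
        incident = (network.edges_i == m) | (network.edges_j == m)
        k[incident] *= theta

    k = list(k)
    eidx = network.edge_index()
    coords = structure.coords
    for site, alpha in perturbation.binding_sites:
        members = sorted(structure.index(r) for r in site.members)
        add = alpha * network.k_unit
        for a_pos, i in enumerate(members):
            for j in members[a_pos + 1:]:
                key = (i, j)
                if key in eidx:
                    k[eidx[key]] += add
                elif site_pairs == "all":
                    dist = float(np.linalg.norm(coords[i] - coords[j]))
                    eidx[key] = len(ei)
                    ei.append(i)
                    ej.append(j)
                    d0.append(dist)
                    k.append(add)
                # site_pairs == 'within_cutoff': pairs beyond cutoff get no spring

    return ElasticNetwork(
        structure=structure,
        edges_i=np.array(ei, dtype=np.intp),
        edges_j=np.array(ej, dtype=np.intp),
        k=np.array(k, dtype=float),
        d0=np.array(d0, dtype=float),
        cutoff=network.cutoff,
        k_unit=network.k_unit,
    )


def hessian(network: ElasticNetwork) -> np.ndarray:
    """Analytic 3N×3N Hessian of the network energy at the native coordinates.

    For E = Σ k_ij (d_ij − d0_ij)² evaluated at d = d0, the off-diagonal 3×3
    block of edge (i, j) is −2 k_ij û ûᵀ with û the unit bond vector, and
    each diagonal block is minus the sum of its row's off-diagonal blocks
    (translation invariance).
    """
    n = network.n_nodes
    coords = network.structure.coords
    H = np.zeros((3 * n, 3 * n))
    for i, j, kij, d0 in zip(network.edges_i, network.edges_j, network.k, network.d0):
        u = (coords[j] - coords[i]) / d0
        block = 2.0 * kij * np.outer(u, u)
        si, sj = 3 * i, 3 * j
        H[si:si + 3, sj:sj + 3] -= block
        H[sj:sj + 3, si:si + 3] -= block
        H[si:si + 3, si:si + 3] += block
        H[sj:sj + 3, sj:sj + 3] += block
    return H


def elastic_energy(network: ElasticNetwork, coords: np.ndarray) -> float:
    """Network energy at arbitrary coordinates (k_BT)."""
    diff = coords[network.edges_j] - coords[network.edges_i]
    d = np.linalg.norm(diff, axis=1)
    return float(np.sum(network.k * (d - network.d0) ** 2))


def _fix_signs(vectors: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    out = vectors.copy()
    for row in out:
        nz = np.flatnonzero(np.abs(row) > tol)
        if nz.size and row[nz[0]] < 0:
            row *= -1.0
    return out


def normal_modes(H: np.ndarray, n_modes: int = 10, rigid_tol: float = 1e-9) -> ModeSet:
    """Diagonalize a Hessian and keep the ``n_modes`` lowest internal modes.

    Modes with eigenvalue below ``rigid_tol`` times the largest eigenvalue
    are classified as rigid-body motion and dropped; a connected 3D network
    in general position has exactly six (a warning is logged otherwise).
    """
    if not np.allclose(H, H.T, atol=1e-10 * max(1.0, np.abs(H).max())):
        raise ValueError("Hessian must be symmetric")
    evals, evecs = eigh(H)
    lam_max = float(evals[-1])
    if lam_max <= 0:
        raise NetworkError("Hessian has no positive eigenvalues; degenerate network")
    rigid = evals < rigid_tol * lam_max
    n_rigid = int(rigid.sum())
    if n_rigid != 6:
        logger.warning("expected 6 rigid-body modes, found %d", n_rigid)
    n_avail = len(evals) - n_rigid
    if n_avail < n_modes:
        raise NetworkError(
            f"only {n_avail} non-rigid modes available; request n_modes ≤ {n_avail}"
        )
    sel = slice(n_rigid, n_rigid + n_modes)
    return ModeSet(
        eigenvalues=evals[sel].copy(),
        vectors=_fix_signs(evecs[:, sel].T),
        n_rigid=n_rigid,
    )
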