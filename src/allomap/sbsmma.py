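"""Per-residue allosteric free energies from normal-mode couplings.

The model evaluates the elastic work a collective motion exerts on each
residue.  For a retained mode μ with per-residue displacement vectors
e_{μ,i}, the mode–residue coupling is

    ε_{μ,i} = Σ_j |e_{μ,i} − e_{μ,j}|²

with j running over the network neighbors of i (the springs attached to i;
a sum over all residues is available as an option).  Treating the mode
amplitudes as a harmonic configurational ensemble gives the per-residue
free energy g_i = ½ k_BT Σ_μ ln ε_{μ,i} up to a constant.  Comparing the
unperturbed (0) and perturbed (P) states yields the allosteric free energy

    Δg_i = ½ k_BT Σ_μ ln( ε^(P)_{μ,i} / ε^(0)_{μ,i} )

and the background-free allosteric modulation Δh_i = Δg_i − ⟨Δg⟩_chain.
Δh_i > 0 means configurational work is exerted on residue i (conformational
change promoted); Δh_i < 0 means the perturbation stabilizes it.  Values
exceeding ~1 k_BT indicate strong allosteric communication.  All energies
are in k_BT (k_BT ≡ 1 internally).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .enm import (
    ElasticNetwork,
    ModeSet,
    Perturbation,
    build_network,
    hessian,
    normal_modes,
    perturb_network,
)
from .structures import CaStructure, ResidueId, Site

logger = logging.getLogger(__name__)

__all__ = [
    "CouplingMatrix",
    "ResponseProfile",
    "mode_couplings",
    "free_energy_profile",
    "response_profile",
    "modulation_range",
    "site_signal",
    "pair_modes",
    "allosteric_response",
    "unperturbed_state",
]

#: couplings below this are clamped before taking logs
EPS_FLOOR = 1e-12


@dataclass
class CouplingMatrix:
    """Mode–residue elastic couplings ε_{μ,i} ≥ 0, shape (n_modes, N)."""

    eps: np.ndarray
    structure: CaStructure

    @property
    def n_modes(self) -> int:
        return self.eps.shape[0]

    @property
    def n_residues(self) -> int:
        return self.eps.shape[1]


@dataclass
class ResponseProfile:
    """Per-residue allosteric response to one perturbation, in k_BT.

    ``dg`` is the allosteric free energy Δg_i, ``dh`` the background-free
    modulation Δh_i (zero mean over the analyzed residues by construction).
    """

    dg: np.ndarray
    dh: np.ndarray
    structure: CaStructure
    perturbation: Perturbation | None = None
    n_clamped: int = 0

    def __len__(self) -> int:
        return len(self.dg)

    def to_dataframe(self) -> pd.DataFrame:
        rids = self.structure.residue_ids
        return pd.DataFrame(
            {
                "residue_id": [str(r) for r in rids],
                "chain": [r.chain_id for r in rids],
                "resseq": [r.resseq for r in rids],
                "dg_kbt": self.dg,
                "dh_kbt": self.dh,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6f")

    def to_json_dict(self) -> dict:
        return {
            "perturbation": self.perturbation.describe() if self.perturbation else None,
            "residues": [str(r) for r in self.structure.residue_ids],
            "dg_kbt": [float(v) for v in self.dg],
            "dh_kbt": [float(v) for v in self.dh],
        }

    def dh_of(self, rid: ResidueId) -> float:
        return float(self.dh[self.structure.index(rid)])


def mode_couplings(
    modes: ModeSet,
    network: ElasticNetwork,
    neighbors: bool = True,
) -> CouplingMatrix:
    """ε_{μ,i} = Σ_j |e_{μ,i} − e_{μ,j}|² over neighbors j of i (or all j)."""
    n = network.n_nodes
    if modes.n_residues != n:
        raise ValueError(
            f"mode set covers {modes.n_residues} residues but network has {n}"
        )
    e = modes.vectors3  # (M, N, 3)
    eps = np.zeros((modes.n_kept, n))
    if neighbors:
        diff = e[:, network.edges_i, :] - e[:, network.edges_j, :]
        sq = np.sum(diff * diff, axis=2)  # (M, n_edges)
        acc = np.zeros((n, modes.n_kept))
        np.add.at(acc, network.edges_i, sq.T)
        np.add.at(acc, network.edges_j, sq.T)
        eps = acc.T
    else:
        # Σ_j |e_i − e_j|² = N|e_i|² − 2 e_i·Σ_j e_j + Σ_j |e_j|²
        norms = np.sum(e * e, axis=2)  # (M, N)
        total = np.sum(e, axis=1)  # (M, 3)
        total_norm = np.sum(norms, axis=1)  # (M,)
        cross = np.einsum("mni,mi->mn", e, total)
        eps = n * norms - 2.0 * cross + total_norm[:, None]
    return CouplingMatrix(eps=np.maximum(eps, 0.0), structure=network.structure)


def free_energy_profile(c: CouplingMatrix) -> np.ndarray:
    """g_i = ½ Σ_μ ln ε_{μ,i} in k_BT, dropping the additive constant."""
    eps, n_clamped = _clamped(c.eps)
    if n_clamped:
        logger.warning("%d couplings clamped to %.0e before log", n_clamped, EPS_FLOOR)
    return 0.5 * np.sum(np.log(eps), axis=0)


def _clamped(eps: np.ndarray) -> tuple[np.ndarray, int]:
    n_below = int(np.count_nonzero(eps < EPS_FLOOR))
    return np.maximum(eps, EPS_FLOOR), n_below


def _center(dg: np.ndarray, structure: CaStructure, center: str) -> np.ndarray:
    if center == "per_chain":
        dh = np.empty_like(dg)
        for chain in structure.chains:
            idx = structure.chain_indices(chain)
            dh[idx] = dg[idx] - dg[idx].mean()
        return dh
    return dg - dg.mean()


def response_profile(
    c0: CouplingMatrix,
    cP: CouplingMatrix,
    perturbation: Perturbation | None = None,
    center: str = "global",
) -> ResponseProfile:
    """Δg and Δh from unperturbed (0) and perturbed (P) couplings.

    Δg_i = ½ Σ_μ ln(ε^(P)/ε^(0)); Δh_i subtracts the chain mean of Δg.
    Couplings below the numerical floor are clamped symmetrically in both
    states (counted on the profile) so an isolated or rigidly co-moving
    residue cannot produce ±∞.
    """
    if c0.eps.shape != cP.eps.shape:
        raise ValueError(
            f"mode/residue count mismatch: {c0.eps.shape} vs {cP.eps.shape}"
        )
    e0, n0 = _clamped(c0.eps)
    eP, nP = _clamped(cP.eps)
    n_clamped = n0 + nP
    if n_clamped:
        logger.warning("%d couplings clamped to %.0e before log ratio", n_clamped, EPS_FLOOR)
    dg = 0.5 * np.sum(np.log(eP) - np.log(e0), axis=0)
    dh = _center(dg, c0.structure, center)
    return ResponseProfile(
        dg=dg, dh=dh, structure=c0.structure, perturbation=perturbation, n_clamped=n_clamped
    )


def modulation_range(up: ResponseProfile, down: ResponseProfile) -> np.ndarray:
    """Allosteric modulation range Δh_i^(m↓↑) = Δh_i^(m↑) − Δh_i^(m↓).

    The maximal allosteric signal obtainable at each residue by mutating
    position m from the smallest (Ala/Gly-like) to the bulkiest amino acid.
    Both profiles must come from mutations of the same residue.
    """
    if len(up) != len(down):
        raise ValueError("profiles cover different residue counts")
    m_up = _mutated_residue(up)
    m_down = _mutated_residue(down)
    if m_up is not None and m_down is not None and m_up != m_down:
        raise ValueError(
            f"modulation range needs UP/DOWN profiles of the same residue, got {m_up} and {m_down}"
        )
    return up.dh - down.dh


def _mutated_residue(profile: ResponseProfile) -> ResidueId | None:
    p = profile.perturbation
    if p is None or len(p.mutations) != 1 or p.binding_sites:
        return None
    return p.mutations[0][0]


def site_signal(profile: ResponseProfile, site: Site) -> float:
    """Unweighted mean of Δh over the residues of a site, in k_BT."""
    idx = [profile.structure.index(r) for r in site.members if r in profile.structure]
    if not idx:
        raise KeyError(f"site {site.label!r} shares no residues with the profile")
    if len(idx) != len(site.members):
        raise KeyError(f"site {site.label!r} has members outside the profile's structure")
    return float(profile.dh[idx].mean())


def pair_modes(modes0: ModeSet, modesP: ModeSet, method: str = "rank") -> np.ndarray:
    """Indices pairing each unperturbed mode with a perturbed mode.

    ``rank`` pairs by frequency rank (identity).  ``overlap`` greedily
    assigns, for each unperturbed mode in ascending frequency order, the
    unassigned perturbed mode with the largest |eigenvector dot product|.
    """
    if modes0.n_kept != modesP.n_kept:
        raise ValueError("mode sets retain different numbers of modes")
    if method == "rank":
        return np.arange(modes0.n_kept)
    if method != "overlap":
        raise ValueError("method must be 'rank' or 'overlap'")
    overlap = np.abs(modes0.vectors @ modesP.vectors.T)
    out = np.full(modes0.n_kept, -1)
    taken = np.zeros(modesP.n_kept, dtype=bool)
    for mu in range(modes0.n_kept):
        order = np.argsort(-overlap[mu])
        for cand in order:
            if not taken[cand]:
                out[mu] = cand
                taken[cand] = True
                break
    return out


@dataclass
class UnperturbedState:
    """Cached reference-state pieces shared across an exhaustive scan."""

    network: ElasticNetwork
    modes: ModeSet
    couplings: CouplingMatrix


def unperturbed_state(structure: CaStructure, config: RunConfig) -> UnperturbedState:
    network = build_network(structure, cutoff=config.cutoff_A, k=config.k)
    modes = normal_modes(hessian(network), n_modes=config.n_modes, rigid_tol=config.rigid_tol)
    couplings = mode_couplings(modes, network, neighbors=config.coupling_neighbors_only)
    return UnperturbedState(network=network, modes=modes, couplings=couplings)


def allosteric_response(
    structure: CaStructure,
    perturbation: Perturbation,
    config: RunConfig | None = None,
    state: UnperturbedState | None = None,
) -> ResponseProfile:
    """Full pipeline: network → perturbed network → modes → Δg, Δh.

    The reference (unperturbed) network, modes and couplings may be passed
    in via ``state`` so exhaustive scans compute them once; the result is
    identical either way.  A null perturbation returns exactly zero response
    (the same coupling matrix is compared with itself).
    """
    config = config or RunConfig()
    if state is None:
        state = unperturbed_state(structure, config)
    if perturbation.is_empty:
        return response_profile(state.couplings, state.couplings,
                                perturbation=perturbation, center=config.center)
    netP = perturb_network(state.network, perturbation, site_pairs=config.site_pairs)
    modesP = normal_modes(hessian(netP), n_modes=config.n_modes, rigid_tol=config.rigid_tol)
    if config.mode_matching == "overlap":
        order = pair_modes(state.modes, modesP, method="overlap")
        modesP = ModeSet(
            eigenvalues=modesP.eigenvalues[order],
            vectors=modesP.vectors[order],
            n_rigid=modesP.n_rigid,
        )
    cP = mode_couplings(modesP, netP, neighbors=config.coupling_neighbors_only)
    return response_profile(state.couplings, cP, perturbation=perturbation, center=config.center)
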