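"""Exhaustive perturbation scans: signaling maps, probing maps, probe design.

The Allosteric Signaling Map (ASM) perturbs every residue in turn with a
stabilizing (UP) and a destabilizing (DOWN) mutation and records the
modulation range Δh_i^(m↓↑) each position m induces on every responding
residue i — an exhaustive residue-by-residue description of the allosteric
control available in the structure.

The Allosteric Probing Map (APM) slides a small ligand-mimicking probe —
a binding perturbation over a window of three consecutive residues — along
each chain and records the modulation Δh_i^(Probe) it causes, supporting
fragment-based screening for latent allosteric sites.  Probes can then be
extended with extra residues to tune the signal toward a site of interest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .config import RunConfig
from .enm import DOWN, UP, Perturbation
from .sbsmma import (
    ResponseProfile,
    allosteric_response,
    modulation_range,
    unperturbed_state,
)
from .structures import CaStructure, ResidueId, Site

logger = logging.getLogger(__name__)

__all__ = [
    "ResponseMap",
    "ASM",
    "APM",
    "compute_asm",
    "compute_apm",
    "signaling_to_site",
    "extend_probe",
    "noncontact_filter",
    "chain_windows",
]

#: soft capacity guardrail (matches typical interactive-use limits; not enforced)
MAX_RESIDUES_WARN = 1800
MAX_CHAINS_WARN = 26


@dataclass
class ResponseMap:
    """Perturbed position (rows) × responding residue (columns) matrix, k_BT."""

    values: np.ndarray
    row_labels: list[str]
    structure: CaStructure
    config: dict

    @property
    def col_labels(self) -> list[str]:
        return self.structure.labels()

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels, columns=self.col_labels)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", float_format="%.6f")

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path,
            values=self.values,
            row_labels=np.array(self.row_labels),
            col_labels=np.array(self.col_labels),
        )

    def plot_heatmap(self, path, cmap: str = "RdBu_r") -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 7))
        vmax = float(np.abs(self.values).max()) or 1.0
        im = ax.imshow(self.values, cmap=cmap, vmin=-vmax, vmax=vmax, aspect="auto")
        ax.set_xlabel("responding residue")
        ax.set_ylabel("perturbed position")
        fig.colorbar(im, ax=ax, label="Δh (k_BT)")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


class ASM(ResponseMap):
    """Allosteric Signaling Map: rows are mutated residues, values Δh^(m↓↑)."""


class APM(ResponseMap):
    """Allosteric Probing Map: rows are 3-residue probe windows, values Δh^(Probe)."""


def _capacity_warning(structure: CaStructure) -> None:
    if len(structure) > MAX_RESIDUES_WARN or len(structure.chains) > MAX_CHAINS_WARN:
        logger.warning(
            "structure has %d residues / %d chains; exhaustive scans may be slow",
            len(structure), len(structure.chains),
        )


def compute_asm(
    structure: CaStructure,
    config: RunConfig | None = None,
    perturbed_residues: list[ResidueId] | None = None,
) -> ASM:
    """Scan UP and DOWN mutations over every residue (or a chosen subset).

    Each row is the modulation range of position m: the Δh profile of the
    UP mutation minus that of the DOWN mutation, computed through exactly
    the same single-perturbation pipeline a direct call would use.  The
    unperturbed eigendecomposition is computed once and shared; perturbed
    systems are re-diagonalized exactly, row by row.
    """
    config = config or RunConfig()
    _capacity_warning(structure)
    state = unperturbed_state(structure, config)
    rows = perturbed_residues if perturbed_residues is not None else structure.residue_ids
    values = np.empty((len(rows), len(structure)))
    for r, rid in enumerate(rows):
        up = allosteric_response(
            structure, Perturbation.mutation(rid, UP, config.theta_up), config, state=state
        )
        down = allosteric_response(
            structure, Perturbation.mutation(rid, DOWN, config.theta_down), config, state=state
        )
        values[r] = modulation_range(up, down)
    return ASM(
        values=values,
        row_labels=[str(r) for r in rows],
        structure=structure,
        config=config.to_dict(),
    )


def chain_windows(
    structure: CaStructure, probe_len: int = 3, break_distance: float = 4.5
) -> list[list[int]]:
    """Windows of ``probe_len`` consecutive residues, per chain.

    Windows never span chain boundaries; a chain-break heuristic also splits
    wherever consecutive Cα atoms are further than ``break_distance`` Å apart
    or author numbering jumps by more than 1.
    """
    coords = structure.coords
    windows: list[list[int]] = []
    for chain in structure.chains:
        idx = structure.chain_indices(chain)
        segments: list[list[int]] = [[idx[0]]]
        for prev, cur in zip(idx, idx[1:]):
            gap = structure.residues[cur].rid.resseq - structure.residues[prev].rid.resseq
            dist = float(np.linalg.norm(coords[cur] - coords[prev]))
            if gap > 1 or dist > break_distance:
                segments.append([cur])
            else:
                segments[-1].append(cur)
        short = [s for s in segments if len(s) < probe_len]
        if short:
            logger.warning(
                "chain %s: %d segment(s) shorter than the %d-residue probe skipped",
                chain, len(short), probe_len,
            )
        for seg in segments:
            for start in range(len(seg) - probe_len + 1):
                windows.append(seg[start:start + probe_len])
    return windows


def _window_label(structure: CaStructure, window: list[int]) -> str:
    first = structure.residues[window[0]].rid
    last = structure.residues[window[-1]].rid
    return f"{first.chain_id}.{first.resseq}{first.icode}-{last.resseq}{last.icode}"


def compute_apm(
    structure: CaStructure,
    config: RunConfig | None = None,
    probe_len: int | None = None,
) -> APM:
    """Slide a binding probe along each chain and collect Δh^(Probe) rows.

    A chain of L contiguous residues contributes L − probe_len + 1 rows
    (L − 2 for the default three-residue probe).  Each row is the ordinary
    binding-site pipeline run on that window with scale α.
    """
    config = config or RunConfig()
    if probe_len is None:
        probe_len = config.probe_len
    if probe_len < 1:
        raise ValueError("probe_len must be ≥ 1")
    _capacity_warning(structure)
    state = unperturbed_state(structure, config)
    windows = chain_windows(structure, probe_len=probe_len)
    values = np.empty((len(windows), len(structure)))
    labels = []
    for r, window in enumerate(windows):
        site = Site(
            label=_window_label(structure, window),
            members=frozenset(structure.residues[i].rid for i in window),
        )
        profile = allosteric_response(
            structure, Perturbation.binding(site, config.alpha), config, state=state
        )
        values[r] = profile.dh
        labels.append(site.label)
    return APM(values=values, row_labels=labels, structure=structure, config=config.to_dict())


def signaling_to_site(
    response_map: ResponseMap,
    site: Site,
    sort_by_magnitude: bool = False,
) -> pd.Series:
    """Mean map value over a site's columns, for every perturbed row.

    The per-row analogue of averaging Δh over a functional site: how strongly
    each candidate mutation/probe modulates the chosen site, in k_BT.
    """
    cols = [response_map.structure.index(r) for r in site.members if r in response_map.structure]
    if not cols:
        raise KeyError(f"site {site.label!r} shares no residues with the map columns")
    if len(cols) != len(site.members):
        raise KeyError(f"site {site.label!r} has members outside the map's structure")
    series = pd.Series(
        response_map.values[:, cols].mean(axis=1), index=response_map.row_labels, name=site.label
    )
    if sort_by_magnitude:
        series = series.iloc[np.argsort(-series.abs().values, kind="stable")]
    return series


def extend_probe(
    structure: CaStructure,
    base_probe: Site,
    extras: list[ResidueId],
    config: RunConfig | None = None,
) -> ResponseProfile:
    """Bind a probe extended with extra residues and return its Δh profile.

    The composition primitive of fragment-based effector design: start from
    a probing-map window, add adjacent residues, and recompute the full
    response.  Extras already inside the base probe are tolerated (warned).
    """
    config = config or RunConfig()
    base_probe.validate(structure)
    for rid in extras:
        structure.index(rid)
    extra_set = set(extras)
    if extra_set and extra_set <= base_probe.members:
        logger.warning("all extras already belong to probe %r", base_probe.label)
    union = Site(
        label=base_probe.label + (("+" + ",".join(str(r) for r in extras)) if extras else ""),
        members=base_probe.members | frozenset(extras),
        ligand_id=base_probe.ligand_id,
    )
    return allosteric_response(structure, Perturbation.binding(union, config.alpha), config)


def noncontact_filter(
    structure: CaStructure,
    perturbed: set[ResidueId],
    responding: set[ResidueId],
    cutoff: float = 11.0,
) -> bool:
    """True iff every perturbed Cα is farther than ``cutoff`` Å from every
    responding Cα — the operational test that a candidate effector site is
    not in contact with the responding residues and must act allosterically.
    """
    pi = [structure.index(r) for r in perturbed]
    ri = [structure.index(r) for r in responding]
    if not pi or not ri:
        raise ValueError("both residue sets must be non-empty")
    d = cdist(structure.coords[pi], structure.coords[ri])
    return bool(np.all(d > cutoff))
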