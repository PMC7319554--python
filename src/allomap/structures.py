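"""Coarse-grained protein structures: Cα models, ligand-binding sites, fixtures.

The statistical-mechanical model downstream operates on a single node per
residue, placed at the Cα position.  This module reads standard PDB files
into that representation, detects ligand-binding sites from HETATM records
(residues within a distance cutoff of any ligand atom, 4.5 Å by default),
and generates deterministic synthetic Cα-only structures so the whole
pipeline can be exercised without downloading anything.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "ResidueId",
    "CaResidue",
    "CaStructure",
    "Site",
    "StructureError",
    "parse_ca_structure",
    "ligand_sites",
    "make_fixture",
    "write_ca_pdb",
    "sites_to_json",
    "sites_from_json",
]

FIXTURE_KINDS = ("helix", "dumbbell", "sym_dimer", "coil")

#: Single-atom HET residues treated as ions, not ligands.
_ION_CODES = frozenset(
    "LI NA K RB CS MG CA SR BA MN FE CO NI CU ZN CD HG CL BR I F".split()
)


class StructureError(ValueError):
    """Raised when a PDB input cannot yield a valid Cα model."""


@dataclass(frozen=True, order=True)
class ResidueId:
    """Author-numbered residue identity: chain, residue number, insertion code.

    The string form follows the ``chain.resseq`` convention used throughout
    the field's allostery literature, e.g. ``"A.301"`` or ``"B.52A"`` for a
    residue with insertion code A.
    """

    chain_id: str
    resseq: int
    icode: str = ""

    def __str__(self) -> str:
        return f"{self.chain_id}.{self.resseq}{self.icode}"

    @classmethod
    def from_string(cls, spec: str) -> "ResidueId":
        """Parse ``"A.301"`` / ``"B.52A"`` style labels."""
        try:
            chain, rest = spec.split(".", 1)
            rest = rest.strip()
            icode = ""
            if rest and rest[-1].isalpha():
                icode = rest[-1]
                rest = rest[:-1]
            return cls(chain, int(rest), icode)
        except (ValueError, IndexError) as exc:
            raise ValueError(f"malformed residue spec {spec!r}; expected e.g. 'A.301'") from exc


@dataclass(frozen=True)
class CaResidue:
    rid: ResidueId
    name: str
    coord: tuple[float, float, float]


class CaStructure:
    """Ordered Cα nodes with residue identity, in file (chain-by-chain) order."""

    def __init__(self, residues: list[CaResidue], source: str = ""):
        if len(residues) < 2:
            raise StructureError(
                f"a Cα model needs at least 2 residues, got {len(residues)} ({source or 'input'})"
            )
        coords = np.array([r.coord for r in residues], dtype=float)
        if not np.all(np.isfinite(coords)):
            raise StructureError("non-finite Cα coordinates")
        rids = [r.rid for r in residues]
        if len(set(rids)) != len(rids):
            raise StructureError("duplicate residue identities in Cα model")
        self.residues: list[CaResidue] = list(residues)
        self.source = source
        self._coords = coords
        self._index = {rid: i for i, rid in enumerate(rids)}
        self.chains: list[str] = []
        for r in residues:
            if r.rid.chain_id not in self.chains:
                self.chains.append(r.rid.chain_id)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) array of Cα coordinates in Å."""
        return self._coords

    @property
    def residue_ids(self) -> list[ResidueId]:
        return [r.rid for r in self.residues]

    def index(self, rid: ResidueId) -> int:
        try:
            return self._index[rid]
        except KeyError:
            raise KeyError(f"residue {rid} not in structure ({self.source or 'input'})") from None

    def __contains__(self, rid: ResidueId) -> bool:
        return rid in self._index

    def chain_indices(self, chain_id: str) -> list[int]:
        return [i for i, r in enumerate(self.residues) if r.rid.chain_id == chain_id]

    def labels(self) -> list[str]:
        return [str(r.rid) for r in self.residues]

    def __repr__(self) -> str:
        return f"CaStructure({len(self)} residues, chains={self.chains}, source={self.source!r})"


@dataclass(frozen=True)
class Site:
    """A set of residues acting as one binding/functional/allosteric site."""

    label: str
    members: frozenset[ResidueId]
    ligand_id: str | None = None

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"site {self.label!r} has no members")

    def validate(self, structure: CaStructure) -> None:
        missing = [str(r) for r in sorted(self.members) if r not in structure]
        if missing:
            raise KeyError(f"site {self.label!r} references unknown residues: {', '.join(missing)}")


def _first_model(pdb_text: str, source: str):
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(source or "input", io.StringIO(pdb_text))
    models = list(structure)
    if not models:
        raise StructureError(f"no models in PDB input ({source})")
    # multi-model files: the method is single-conformation, keep the first
    return models[0]


def parse_ca_structure(
    pdb_text: str,
    chain_filter: set[str] | None = None,
    source: str = "",
) -> CaStructure:
    """Read PDB text into a Cα model.

    One node per residue; disordered (altloc) atoms resolve to the highest
    occupancy conformer (ties broken by file order); residues without a Cα
    atom are skipped with a log message.

    Raises :class:`StructureError` if fewer than 2 Cα nodes remain after
    applying ``chain_filter``.
    """
    model = _first_model(pdb_text, source)
    residues: list[CaResidue] = []
    skipped = 0
    for chain in model:
        if chain_filter is not None and chain.id not in chain_filter:
            continue
        for res in chain:
            hetflag, resseq, icode = res.id
            if hetflag.strip():  # HETATM / water
                continue
            if "CA" not in res:
                skipped += 1
                continue
            atom = res["CA"]  # DisorderedAtom resolves to highest occupancy
            x, y, z = (float(v) for v in atom.get_coord())
            rid = ResidueId(chain.id, int(resseq), icode.strip())
            residues.append(CaResidue(rid, res.get_resname().strip(), (x, y, z)))
    if skipped:
        logger.info("skipped %d residues lacking a Cα atom (%s)", skipped, source or "input")
    if len(residues) < 2:
        raise StructureError(
            f"fewer than 2 Cα nodes in {source or 'input'}"
            + (f" with chain filter {sorted(chain_filter)}" if chain_filter else "")
        )
    return CaStructure(residues, source=source)


def ligand_sites(
    pdb_text: str,
    structure: CaStructure,
    cutoff: float = 4.5,
    include_ions: bool = False,
    include_waters: bool = False,
    source: str = "",
) -> list[Site]:
    """Detect ligand-binding sites from HETATM records.

    One :class:`Site` per distinct ligand instance (HET residue).  A protein
    residue belongs to the site if any of its atoms — all atoms when the file
    has them, otherwise just its Cα — lies within ``cutoff`` Å of any ligand
    atom.  Waters and single-atom ions are excluded from ligand detection by
    default.  Returns an empty list (logged) when no ligands are present.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    model = _first_model(pdb_text, source)

    # atoms of every residue present in the Cα model
    res_atoms: dict[ResidueId, np.ndarray] = {}
    ligands: list[tuple[str, str, int, np.ndarray]] = []  # (het code, chain, resseq, coords)
    for chain in model:
        for res in chain:
            hetflag, resseq, icode = res.id
            coords = np.array([a.get_coord() for a in res.get_atoms()], dtype=float)
            if not hetflag.strip():
                rid = ResidueId(chain.id, int(resseq), icode.strip())
                if rid in structure:
                    res_atoms[rid] = coords
                continue
            name = res.get_resname().strip()
            if hetflag == "W" or name == "HOH":
                if not include_waters:
                    continue
            if name in _ION_CODES and len(coords) == 1 and not include_ions:
                continue
            ligands.append((name, chain.id, int(resseq), coords))

    if not ligands:
        logger.info("no ligand HETATM records found (%s)", source or "input")
        return []

    sites: list[Site] = []
    for name, chain_id, resseq, lig_xyz in ligands:
        members = {
            rid
            for rid, xyz in res_atoms.items()
            if cdist(xyz, lig_xyz).min() <= cutoff
        }
        if not members:
            logger.info("ligand %s %s.%d has no residues within %.1f Å; dropped",
                        name, chain_id, resseq, cutoff)
            continue
        sites.append(Site(label=f"{name}.{chain_id}.{resseq}", members=frozenset(members),
                          ligand_id=name))
    return sites


# ---------------------------------------------------------------------------
# fixture generation


def _atom_line(serial: int, resname: str, chain: str, resseq: int, xyz) -> str:
    x, y, z = xyz
    return (
        f"ATOM  {serial:5d}  CA  {resname:<3s} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}           C"
    )


def write_ca_pdb(structure: CaStructure) -> str:
    """Serialize a Cα model back to PDB text (ATOM + TER records)."""
    lines = []
    serial = 1
    prev_chain = None
    for res in structure.residues:
        if prev_chain is not None and res.rid.chain_id != prev_chain:
            lines.append("TER")
        lines.append(_atom_line(serial, res.name, res.rid.chain_id, res.rid.resseq, res.coord))
        serial += 1
        prev_chain = res.rid.chain_id
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def _helix_points(n: int, origin=(0.0, 0.0, 0.0), radius=2.3, rise=1.5, twist_deg=100.0):
    """Ideal α-helical Cα trace: ~3.8 Å between consecutive points."""
    ox, oy, oz = origin
    pts = np.empty((n, 3))
    for i in range(n):
        t = math.radians(twist_deg) * i
        pts[i] = (ox + radius * (math.cos(t) - 1.0), oy + radius * math.sin(t), oz + rise * i)
    return pts


def _coil_points(n: int, rng: np.random.Generator, step=3.8, min_sep=3.5):
    """Compact self-avoiding random walk with fixed step length.

    Steps are biased back toward the centroid so the chain folds into a
    globule of protein-like packing density; a fully extended walk would
    leave under-coordinated stretches that behave as floppy mechanisms in
    the downstream spring network.
    """
    pts = [np.zeros(3)]
    while len(pts) < n:
        centroid = np.mean(pts, axis=0)
        for _ in range(200):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            to_center = centroid - pts[-1]
            dist = float(np.linalg.norm(to_center))
            if dist > 1e-9:
                u = u + 0.9 * min(1.0, dist / 8.0) * (to_center / dist)
                u /= np.linalg.norm(u)
            cand = pts[-1] + step * u
            prev = np.array(pts[:-1]) if len(pts) > 1 else None
            if prev is None or np.min(np.linalg.norm(prev - cand, axis=1)) >= min_sep:
                pts.append(cand)
                break
        else:  # dead end: back up one step and retry
            if len(pts) > 1:
                pts.pop()
    return np.array(pts)


def _dumbbell_points(n: int):
    """Two compact helical lobes joined by an extended linker along z."""
    n_lobe = max(4, int(round(0.4 * n)))
    n_link = n - 2 * n_lobe
    if n_link < 2:
        n_link = 2
        n_lobe = (n - n_link) // 2
    lobe_a = _helix_points(n_lobe, origin=(0.0, 0.0, 0.0))
    # extended but non-collinear linker; a straight (or too sparse) bead chain
    # would be a floppy central-force mechanism with spurious zero modes
    link = _helix_points(
        n_link + 1, origin=tuple(lobe_a[-1]), radius=1.5, rise=2.5, twist_deg=120.0
    )[1:]
    anchor = link[-1] + np.array([0.0, 0.0, 3.6])
    lobe_b = _helix_points(n - n_lobe - n_link, origin=tuple(anchor))
    return np.vstack([lobe_a, link, lobe_b]), n_lobe, n_link


def make_fixture(kind: str, n_residues: int, seed: int) -> str:
    """Generate a synthetic Cα-only PDB file, deterministic in (kind, n, seed).

    Kinds: ``helix`` (ideal α-helical trace: rise 1.5 Å, 100°/residue,
    radius 2.3 Å), ``dumbbell`` (two compact lobes joined by an extended
    linker), ``sym_dimer`` (chain A plus its exact image under a 180°
    rotation about z as chain B), ``coil`` (self-avoiding random walk with
    3.8 Å steps).
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    if n_residues < 4:
        raise ValueError("n_residues must be ≥ 4")
    rng = np.random.default_rng(seed)

    if kind == "helix":
        pts = _helix_points(n_residues)
        chains = [("A", pts)]
    elif kind == "coil":
        pts = _coil_points(n_residues, rng)
        chains = [("A", pts)]
    elif kind == "dumbbell":
        pts, _, _ = _dumbbell_points(n_residues)
        chains = [("A", pts)]
    else:  # sym_dimer: jittered helix offset from the C2 axis, plus its image
        a = _helix_points(n_residues) + np.array([6.5, 0.0, 0.0])
        a += rng.normal(scale=0.05, size=a.shape)
        b = a * np.array([-1.0, -1.0, 1.0])  # 180° rotation about z
        chains = [("A", a), ("B", b)]

    residues = []
    for chain_id, pts in chains:
        # round to PDB field precision so the written file IS the model
        pts = np.round(pts, 3)
        for i, p in enumerate(pts):
            residues.append(
                CaResidue(ResidueId(chain_id, i + 1), "ALA", (p[0], p[1], p[2]))
            )
    structure = CaStructure(residues, source=f"fixture:{kind}(n={n_residues},seed={seed})")
    return write_ca_pdb(structure)


# ---------------------------------------------------------------------------
# site (de)serialization


def sites_to_json(sites: list[Site]) -> list[dict]:
    return [
        {"label": s.label, "residues": sorted(str(r) for r in s.members),
         **({"ligand_id": s.ligand_id} if s.ligand_id else {})}
        for s in sites
    ]


def sites_from_json(data: list[dict]) -> list[Site]:
    return [
        Site(
            label=d["label"],
            members=frozenset(ResidueId.from_string(r) for r in d["residues"]),
            ligand_id=d.get("ligand_id"),
        )
        for d in data
    ]
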