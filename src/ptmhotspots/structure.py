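"""Structure parsing, per-residue solvent accessibility, and interfaces.

SASA is computed with the Shrake–Rupley sphere-point method on *isolated*
chains, so that crystal-packing neighbors and binding partners never deflate
the accessibility of a residue; interface residence is detected separately
as an inter-chain heavy-atom contact within a distance cutoff, which by
construction ignores same-chain crystallographic artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: van der Waals radii (Å) by element; heavy atoms only, hydrogens ignored.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
DEFAULT_VDW_RADIUS = 1.70

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Theoretical maximum solvent accessibility per residue type (Å²),
#: Tien et al. 2013 (theoretical column); used to normalize SASA and to
#: assign full accessibility to disordered unresolved residues.
MAX_SASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

DEFAULT_PROBE_RADIUS = 1.4  # water probe, Å
DEFAULT_N_POINTS = 960
DEFAULT_CONTACT_CUTOFF = 5.0  # inter-chain heavy-atom contact, Å


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray  # shape (3,), Å
    radius: float  # van der Waals, Å


@dataclass
class Residue:
    name: str  # 3-letter code
    seq_id: int  # author residue number
    icode: str
    atoms: list[Atom]

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE[self.name]


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue]

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    @property
    def author_seq_ids(self) -> list[int]:
        return [r.seq_id for r in self.residues]

    def atom_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(coords (N,3), radii (N,), residue position index (N,))."""
        coords, radii, res_idx = [], [], []
        for i, res in enumerate(self.residues):
            for atom in res.atoms:
                coords.append(atom.xyz)
                radii.append(atom.radius)
                res_idx.append(i)
        return np.asarray(coords, float), np.asarray(radii, float), np.asarray(res_idx, int)


@dataclass
class StructureModel:
    structure_id: str
    chains: list[Chain]

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(f"no chain {chain_id!r} in structure {self.structure_id}")


def _element_symbol(atom: gemmi.Atom) -> str:
    sym = atom.element.name
    if sym and sym not in ("X",):
        return sym.upper() if len(sym) == 1 else sym[0].upper() + sym[1:].lower()
    # element column blank: infer from the atom name's first alphabetic char
    for char in atom.name:
        if char.isalpha():
            return char.upper()
    return "C"


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties broken alphabetically."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in residue:
        alt = atom.altloc if atom.altloc not in ("\0", "\x00") else ""
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
            continue
        prev_alt = prev.altloc if prev.altloc not in ("\0", "\x00") else ""
        if (atom.occ, _neg_ord(alt)) > (prev.occ, _neg_ord(prev_alt)):
            by_name[atom.name] = atom
    return list(by_name.values())


def _neg_ord(alt: str) -> int:
    # sort helper: higher occupancy wins, then alphabetically earlier altloc
    return -ord(alt) if alt else 0


def read_structure(source, structure_id: str | None = None) -> StructureModel:
    """Parse a PDB file (path, handle, or text) into a :class:`StructureModel`.

    Only the first model of multi-model (NMR-style) files is read; altlocs
    resolve to the highest-occupancy conformer; hydrogens are dropped; and
    HETATM ligands / non-standard residues are ignored for the analysis
    (logged).  van der Waals radii come from the built-in element table.
    """
    if hasattr(source, "read"):
        st = gemmi.read_pdb_string(source.read())
    elif isinstance(source, str) and "\n" in source:
        st = gemmi.read_pdb_string(source)
    else:
        st = gemmi.read_structure(str(Path(source)), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise ValidationError("no models / ATOM records in structure input")
    if len(st) > 1:
        logger.info("multi-model structure: keeping model 1 of %d", len(st))
    model = st[0]

    chains: list[Chain] = []
    n_skipped_res = 0
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            if gres.name not in THREE_TO_ONE:
                n_skipped_res += 1
                continue
            atoms: list[Atom] = []
            for gatom in _resolve_altlocs(gres):
                element = _element_symbol(gatom)
                if element in ("H", "D"):
                    continue
                atoms.append(
                    Atom(
                        name=gatom.name,
                        element=element,
                        xyz=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                        radius=VDW_RADII.get(element, DEFAULT_VDW_RADIUS),
                    )
                )
            if atoms:
                residues.append(
                    Residue(
                        name=gres.name,
                        seq_id=gres.seqid.num,
                        icode=(gres.seqid.icode or "").strip(),
                        atoms=atoms,
                    )
                )
        if residues:
            chains.append(Chain(chain_id=gchain.name, residues=residues))
    if n_skipped_res:
        logger.info("ignored %d non-standard/HETATM residues", n_skipped_res)
    if not chains:
        raise ValidationError("no standard amino-acid ATOM records in structure input")
    sid = structure_id or st.name or "structure"
    for atom_list in (res for ch in chains for res in ch.residues):
        for atom in atom_list.atoms:
            if not np.all(np.isfinite(atom.xyz)):
                raise ValidationError("non-finite coordinates in structure input")
    return StructureModel(structure_id=sid, chains=chains)


@lru_cache(maxsize=8)
def sphere_points(n_points: int) -> np.ndarray:
    """Deterministic unit-sphere lattice (golden-section spiral), shape (n, 3)."""
    i = np.arange(n_points, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    z = 1.0 - (2.0 * i + 1.0) / n_points
    radius = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = phi * i
    pts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), z])
    pts.setflags(write=False)
    return pts


def shrake_rupley_sasa(
    chain: Chain,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> dict[int, float]:
    """Per-residue solvent accessible surface area (Å²) of an isolated chain.

    Each heavy atom is expanded by the probe radius and sampled with a fixed
    deterministic point lattice; a sample point is accessible when it lies
    outside every neighboring expanded sphere.  Residue SASA is the sum over
    its atoms, keyed by author residue number.  The chain is treated in
    isolation so binding partners never occlude its surface.
    """
    coords, radii, res_idx = chain.atom_arrays()
    if len(coords) == 0:
        raise ValidationError("chain has no heavy atoms")
    expanded = radii + probe_radius
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    atom_sasa = np.zeros(len(coords))
    for i in range(len(coords)):
        r_i = expanded[i]
        neighbors = [
            j
            for j in tree.query_ball_point(coords[i], r_i + expanded.max())
            if j != i and np.linalg.norm(coords[j] - coords[i]) < r_i + expanded[j]
        ]
        pts = coords[i] + r_i * unit  # (n_points, 3)
        if neighbors:
            ncoords = coords[neighbors]  # (k, 3)
            nrad = expanded[neighbors]  # (k,)
            d2 = ((pts[:, None, :] - ncoords[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nrad**2)[None, :]).any(axis=1)
            accessible = np.count_nonzero(~buried)
        else:
            accessible = n_points
        atom_sasa[i] = 4.0 * np.pi * r_i**2 * accessible / n_points

    out: dict[int, float] = {}
    for i, res in enumerate(chain.residues):
        out[res.seq_id] = out.get(res.seq_id, 0.0) + float(
            atom_sasa[res_idx == i].sum()
        )
    return out


def detect_interface_residues(
    structure: StructureModel, contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
) -> set[tuple[str, int]]:
    """Residues with any heavy atom within ``contact_cutoff`` of another chain.

    Same-chain contacts never count, so crystallographic same-chain
    artifacts cannot create spurious interfaces.  Single-chain structures
    return the empty set.
    """
    if len(structure.chains) < 2:
        return set()
    coords, chain_ids, seq_ids = [], [], []
    for ch in structure.chains:
        for res in ch.residues:
            for atom in res.atoms:
                coords.append(atom.xyz)
                chain_ids.append(ch.chain_id)
                seq_ids.append(res.seq_id)
    coords = np.asarray(coords)
    tree = cKDTree(coords)
    interface: set[tuple[str, int]] = set()
    for i, j in tree.query_pairs(contact_cutoff):
        if chain_ids[i] != chain_ids[j]:
            interface.add((chain_ids[i], seq_ids[i]))
            interface.add((chain_ids[j], seq_ids[j]))
    return interface
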