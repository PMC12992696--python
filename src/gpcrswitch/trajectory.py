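"""Trajectory and topology I/O.

Reads multi-model PDB trajectories (one MODEL per frame) and a simple
whitespace XYZ-per-frame dialect, plus the receptor annotation config
that binds Ballesteros-Weinstein roles (toggle switch, ionic lock,
sodium site, polar triad...) to concrete residues and ligand atoms.

Conventions: coordinates are Angstrom; the membrane normal is +z with
extracellular pointing up unless the receptor-axis operation overrides
it; HETATM records are treated like ATOM; altlocs other than blank/'A'
are dropped with a warning. Waters are recognised by residue name
(HOH/WAT/SOL/TIP3/OPC) and ions by element or residue name, matching
common MD force-field naming.
"""
from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .errors import ConfigError, PdbParseError, SelectionError, TopologyError

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Frame",
    "Trajectory",
    "ResidueMap",
    "ResidueEntry",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_xyz_frames",
    "write_xyz_frames",
    "load_residue_map",
    "select_atoms",
    "WATER_RESNAMES",
    "ION_ELEMENTS",
    "REQUIRED_ROLES",
]

WATER_RESNAMES = {"HOH", "WAT", "SOL", "TIP3", "OPC"}
ION_ELEMENTS = {"NA", "CL"}
ION_RESNAMES = {"NA+", "SOD", "CLA", "CL-"}

_BW_RE = re.compile(r"^\d+\.\d+$")

#: roles every downstream module relies on; each must occur exactly once
REQUIRED_ROLES = {
    "toggle": "6.48",
    "ionic_lock_arg": "3.50",
    "ionic_lock_glu": "6.30",
    "tm6_gap": "6.34",
    "na_site": "2.50",
    "na_stabilizer": "7.49",
    "na_backup": "3.39",
    "na_lid": "6.44",
    "polar_ser1": "5.44",
    "polar_ser2": "5.46",
    "polar_asn": "6.55",
    "anchor": "3.32",
    "depth_anchor": "5.35",
    "base": "3.37",
}
#: roles that may occur any number of times
MULTI_ROLES = {"tm", "vestibule", "none"}


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    residue_name: str
    residue_number: int
    chain_id: str
    element: str
    coordinates: np.ndarray  # 3-vector, Angstrom

    def __post_init__(self) -> None:
        xyz = np.asarray(self.coordinates, dtype=float)
        if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
            raise TopologyError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not self.element:
            raise TopologyError(f"atom {self.name}: empty element symbol")
        object.__setattr__(self, "coordinates", xyz)

    @property
    def key(self) -> tuple[str, int, str]:
        """Identity within a frame: (chain, residue number, atom name)."""
        return (self.chain_id, self.residue_number, self.name)


@dataclass
class Frame:
    index: int
    time_ns: float
    atoms: list[Atom]
    _coords: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array, cached."""
        if self._coords is None:
            self._coords = np.array([a.coordinates for a in self.atoms], dtype=float)
        return self._coords

    def validate_unique_keys(self) -> None:
        keys = [a.key for a in self.atoms]
        if len(set(keys)) != len(keys):
            raise TopologyError("duplicate (chain, resnum, name) within a frame")


def _topology_hash(atoms: Sequence[Atom]) -> str:
    h = hashlib.sha1()
    for a in atoms:
        h.update(f"{a.chain_id}|{a.residue_number}|{a.residue_name}|{a.name}|{a.element};".encode())
    return h.hexdigest()


@dataclass
class Trajectory:
    frames: list[Frame]
    stride_ns: float = 1.0
    topology_hash: str = ""

    def __post_init__(self) -> None:
        if not self.frames:
            raise TopologyError("a trajectory needs at least one frame")
        if self.stride_ns <= 0:
            raise ValueError("stride_ns must be positive")
        ref = self.frames[0]
        ref.validate_unique_keys()
        if not self.topology_hash:
            self.topology_hash = _topology_hash(ref.atoms)
        for fr in self.frames:
            if _topology_hash(fr.atoms) != self.topology_hash:
                raise TopologyError(f"frame {fr.index} does not match trajectory topology")
        times = [fr.time_ns for fr in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise TopologyError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def topology(self) -> list[Atom]:
        return self.frames[0].atoms

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    def coords(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stacked coordinates."""
        return np.stack([fr.coords for fr in self.frames])


# ---------------------------------------------------------------------------
# PDB I/O (fixed-column, MODEL/ENDMDL)

def _parse_pdb_atom(line: str, lineno: int, serial_fallback: int) -> Atom | None:
    try:
        serial = int(line[6:11]) if line[6:11].strip() else serial_fallback
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:21].strip()
        chain = line[21].strip() or "A"
        resnum = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PdbParseError(f"malformed ATOM record at line {lineno}: {exc}") from exc
    if altloc not in ("", "A"):
        logger.warning("dropping altloc %r atom at line %d", altloc, lineno)
        return None
    if not element:
        element = re.sub(r"\d", "", name)[:1].upper() or "X"
        # two-letter guess for common MD ion names
        if name.upper() in ("NA", "CL", "MG", "ZN"):
            element = name.upper()
    return Atom(serial, name, resname, resnum, chain, element.upper(), np.array([x, y, z]))


def read_multimodel_pdb(path: str | Path, stride_ns: float = 1.0) -> Trajectory:
    """Read a multi-model PDB; one Frame per MODEL block.

    Files without MODEL records are read as a single frame. Frame times
    are ``index * stride_ns`` (default 1.0 ns/frame).
    """
    path = Path(path)
    frames: list[Frame] = []
    current: list[Atom] = []
    in_model = False
    saw_model = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model = True
                in_model = True
                current = []
            elif rec == "ENDMDL":
                in_model = False
                frames.append(Frame(len(frames), len(frames) * stride_ns, current))
                current = []
            elif rec in ("ATOM", "HETATM"):
                atom = _parse_pdb_atom(line, lineno, serial_fallback=len(current) + 1)
                if atom is not None:
                    current.append(atom)
    if current and not saw_model:
        frames.append(Frame(0, 0.0, current))
    elif current and in_model:
        raise PdbParseError(f"{path}: MODEL block not closed by ENDMDL")
    if not frames:
        raise PdbParseError(f"{path}: no coordinate records found")
    counts = {len(fr.atoms) for fr in frames}
    if len(counts) != 1:
        raise TopologyError(f"{path}: inconsistent atom count between models: {sorted(counts)}")
    return Trajectory(frames, stride_ns=stride_ns)


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as MODEL/ENDMDL blocks, 3-decimal coordinates."""
    path = Path(path)
    with path.open("w") as fh:
        for fr in traj.frames:
            fh.write(f"MODEL     {fr.index + 1:4d}\n")
            for a in fr.atoms:
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                x, y, z = a.coordinates
                fh.write(
                    f"ATOM  {a.serial:5d} {name:<4s}{'':1s}{a.residue_name:<4s}"
                    f"{a.chain_id:1s}{a.residue_number:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                    f"{a.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# XYZ frame-block dialect: blank-line-separated blocks of "label x y z"

def read_xyz_frames(path: str | Path, names: Sequence[str] | None = None,
                    stride_ns: float = 1.0) -> Trajectory:
    """Read whitespace XYZ frame blocks; labels attached positionally.

    Each block is one frame: lines of ``label x y z`` separated by blank
    lines. If ``names`` is given it overrides the per-line labels and
    must match the block length.
    """
    path = Path(path)
    blocks: list[list[tuple[str, float, float, float]]] = []
    current: list[tuple[str, float, float, float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                if current:
                    blocks.append(current)
                    current = []
                continue
            parts = stripped.split()
            if len(parts) != 4:
                raise PdbParseError(f"{path}:{lineno}: expected 'label x y z'")
            try:
                blocks_entry = (parts[0], float(parts[1]), float(parts[2]), float(parts[3]))
            except ValueError as exc:
                raise PdbParseError(f"{path}:{lineno}: bad coordinate: {exc}") from exc
            current.append(blocks_entry)
    if current:
        blocks.append(current)
    if not blocks:
        raise PdbParseError(f"{path}: no frames")
    n = len(blocks[0])
    if any(len(b) != n for b in blocks):
        raise TopologyError(f"{path}: unequal frame block lengths")
    if names is not None and len(names) != n:
        raise TopologyError(f"{path}: {len(names)} names for {n} coordinates per frame")
    frames = []
    for i, block in enumerate(blocks):
        atoms = []
        for j, (label, x, y, z) in enumerate(block):
            name = names[j] if names is not None else label
            element = re.sub(r"\d", "", name)[:1].upper() or "X"
            atoms.append(Atom(j + 1, name, "UNK", 1, "A", element, np.array([x, y, z])))
        frames.append(Frame(i, i * stride_ns, atoms))
    return Trajectory(frames, stride_ns=stride_ns)


def write_xyz_frames(traj: Trajectory, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for k, fr in enumerate(traj.frames):
            if k:
                fh.write("\n")
            for a in fr.atoms:
                x, y, z = a.coordinates
                fh.write(f"{a.name} {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# Residue annotation map

@dataclass(frozen=True)
class ResidueEntry:
    residue_number: int
    chain_id: str
    bw_index: str
    role: str


@dataclass
class ResidueMap:
    """Binds receptor roles and ligand atom roles to the topology."""

    entries: list[ResidueEntry]
    ligand_residue_name: str
    ligand_chain_id: str
    ligand_atom_roles: dict[str, str]  # atom name -> role

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        for e in self.entries:
            if not _BW_RE.match(e.bw_index):
                raise ConfigError(f"bad BW index {e.bw_index!r} (want 'T.NN')")
            if e.role in REQUIRED_ROLES:
                seen[e.role] = seen.get(e.role, 0) + 1
            elif e.role not in MULTI_ROLES:
                raise ConfigError(f"unknown role {e.role!r}")
        missing = sorted(r for r in REQUIRED_ROLES if seen.get(r, 0) == 0)
        if missing:
            raise ConfigError(f"residue map missing required roles: {', '.join(missing)}")
        dupes = sorted(r for r, n in seen.items() if n > 1)
        if dupes:
            raise ConfigError(f"roles assigned more than once: {', '.join(dupes)}")

    def residue(self, role: str) -> ResidueEntry:
        for e in self.entries:
            if e.role == role:
                return e
        raise ConfigError(f"role {role!r} not in residue map")

    def residues(self, role: str) -> list[ResidueEntry]:
        return [e for e in self.entries if e.role == role]

    def atom_index(self, traj: Trajectory, role: str, atom_name: str) -> int:
        """Topology index of a named atom of the residue holding ``role``."""
        e = self.residue(role)
        for i, a in enumerate(traj.topology):
            if (a.chain_id == e.chain_id and a.residue_number == e.residue_number
                    and a.name == atom_name):
                return i
        raise TopologyError(
            f"residue {e.residue_number} (role {role}) has no atom {atom_name!r}")

    def atom_indices(self, traj: Trajectory, role: str, atom_names: Iterable[str]) -> list[int]:
        return [self.atom_index(traj, role, n) for n in atom_names]

    def role_ca_indices(self, traj: Trajectory, role: str) -> list[int]:
        """CA indices of every residue carrying a (possibly multi-) role."""
        keys = {(e.chain_id, e.residue_number) for e in self.residues(role)}
        out = [i for i, a in enumerate(traj.topology)
               if (a.chain_id, a.residue_number) in keys and a.name == "CA"]
        if not out:
            raise TopologyError(f"no CA atoms found for role {role!r}")
        return out

    def ligand_atom_index(self, traj: Trajectory, atom_name: str) -> int:
        for i, a in enumerate(traj.topology):
            if (a.residue_name == self.ligand_residue_name
                    and a.chain_id == self.ligand_chain_id and a.name == atom_name):
                return i
        raise TopologyError(f"ligand has no atom {atom_name!r}")

    def ligand_atoms_by_role(self, role: str) -> list[str]:
        return [n for n, r in self.ligand_atom_roles.items() if r == role]


def load_residue_map(path: str | Path) -> ResidueMap:
    """Load and validate a YAML residue annotation config.

    Expected layout::

        ligand:
          residue_name: LIG
          chain_id: A
          atom_roles: {NT: amine_n, N1: indole_n, H1: indole_h, ...}
        residues:
          - {number: 336, chain: A, bw: "6.48", role: toggle}
          - ...
    """
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(data, dict) or "residues" not in data or "ligand" not in data:
        raise ConfigError(f"{path}: config needs 'ligand' and 'residues' sections")
    entries = []
    for row in data["residues"]:
        try:
            entries.append(ResidueEntry(int(row["number"]), str(row.get("chain", "A")),
                                        str(row["bw"]), str(row["role"])))
        except KeyError as exc:
            raise ConfigError(f"{path}: residue entry missing key {exc}") from exc
    lig = data["ligand"]
    return ResidueMap(
        entries=entries,
        ligand_residue_name=str(lig.get("residue_name", "LIG")),
        ligand_chain_id=str(lig.get("chain_id", "A")),
        ligand_atom_roles={str(k): str(v) for k, v in (lig.get("atom_roles") or {}).items()},
    )


def dump_residue_map(rmap: ResidueMap, path: str | Path) -> None:
    data = {
        "ligand": {
            "residue_name": rmap.ligand_residue_name,
            "chain_id": rmap.ligand_chain_id,
            "atom_roles": dict(rmap.ligand_atom_roles),
        },
        "residues": [
            {"number": e.residue_number, "chain": e.chain_id, "bw": e.bw_index, "role": e.role}
            for e in rmap.entries
        ],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# Atom selection mini-language: "field value" clauses joined by and/or,
# with AND binding tighter than OR. Fields: resnum, resname, name, chain,
# element. Example: "resnum 155 and name OD1 or resnum 155 and name OD2".

_FIELDS = {
    "resnum": lambda a, v: a.residue_number == int(v),
    "resname": lambda a, v: a.residue_name.upper() == v.upper(),
    "name": lambda a, v: a.name.upper() == v.upper(),
    "chain": lambda a, v: a.chain_id == v,
    "element": lambda a, v: a.element.upper() == v.upper(),
}


def _parse_query(query: str):
    tokens = query.split()
    if not tokens:
        raise SelectionError("empty selection expression")
    or_clauses: list[list[tuple[str, str]]] = [[]]
    i = 0
    expect_cond = True
    while i < len(tokens):
        tok = tokens[i].lower()
        if tok == "or" and not expect_cond:
            or_clauses.append([])
            expect_cond = True
            i += 1
        elif tok == "and" and not expect_cond:
            expect_cond = True
            i += 1
        elif expect_cond:
            if tok not in _FIELDS:
                raise SelectionError(f"unknown selection field {tokens[i]!r}")
            if i + 1 >= len(tokens):
                raise SelectionError(f"field {tok!r} missing a value")
            or_clauses[-1].append((tok, tokens[i + 1]))
            expect_cond = False
            i += 2
        else:
            raise SelectionError(f"expected and/or before {tokens[i]!r}")
    if expect_cond:
        raise SelectionError("selection ends with a dangling operator")
    return or_clauses


def select_atoms(traj: Trajectory, query: str) -> list[int]:
    """Evaluate a selection expression on the topology; stable index order."""
    clauses = _parse_query(query)
    out = []
    for i, a in enumerate(traj.topology):
        for clause in clauses:
            try:
                ok = all(_FIELDS[f](a, v) for f, v in clause)
            except ValueError as exc:
                raise SelectionError(f"bad value in selection: {exc}") from exc
            if ok:
                out.append(i)
                break
    return out


def is_water_oxygen(atom: Atom) -> bool:
    return atom.residue_name.upper() in WATER_RESNAMES and atom.element == "O"


def is_sodium(atom: Atom) -> bool:
    return atom.element == "NA" or atom.residue_name.upper() in ("NA+", "SOD", "NA")
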