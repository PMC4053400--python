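"""Structure, trajectory and parameter-table I/O.

The on-disk formats are deliberately minimal and text-only:

* single-model PDB for structures,
* multi-model PDB (``MODEL``/``ENDMDL`` blocks) for trajectories,
* a TSV parameter table with header exactly
  ``res_name  atom_name  charge  lj_rmin_half  lj_epsilon  vdw_radius``.

PDB parsing/writing is delegated to :mod:`biotite`; this module wraps it in
the package's domain types and adds the validation the analysis stages rely
on (unique atom keys, integer residue charges after parameter assignment,
disjoint protein/ligand selections).

Trajectory readers are pluggable: any callable ``(path, system) ->
Trajectory`` registered in :data:`TRAJECTORY_READERS` can be selected by
format name, so binary formats can be added without touching analysis code.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)

#: Residue names treated as water (excluded from protein/ligand groups).
WATER_RES_NAMES = frozenset({"HOH", "WAT", "TIP", "TIP3", "SOL", "H2O"})

#: Exact header required for parameter tables.
PARAMETER_COLUMNS = (
    "res_name",
    "atom_name",
    "charge",
    "lj_rmin_half",
    "lj_epsilon",
    "vdw_radius",
)


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed."""


class ParameterError(ValueError):
    """Raised on parameter-table problems (missing entries, bad header)."""


class SelectionError(KeyError):
    """Raised when a named selection or residue does not exist."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class AtomRecord:
    """One atom with coordinates and (optionally) force-field annotation.

    ``charge`` (e), ``lj_rmin_half`` (A), ``lj_epsilon`` (kcal/mol) and
    ``vdw_radius`` (A) are NaN until :func:`assign_parameters` runs.
    """

    serial: int
    name: str
    element: str
    res_name: str
    res_id: int
    chain: str
    coords: np.ndarray
    charge: float = math.nan
    lj_rmin_half: float = math.nan
    lj_epsilon: float = math.nan
    vdw_radius: float = math.nan
    ins_code: str = ""
    hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"atom {self.name}: coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")

    @property
    def key(self) -> Tuple[str, int, str, str]:
        """Identity key ``(chain, res_id, ins_code, name)``."""
        return (self.chain, self.res_id, self.ins_code, self.name)

    @property
    def residue_key(self) -> Tuple[str, int, str]:
        return (self.chain, self.res_id, self.ins_code)

    @property
    def label(self) -> str:
        """Human-readable label like ``A:ARG126:NH2``."""
        return f"{self.chain}:{self.res_name}{self.res_id}{self.ins_code}:{self.name}"


class MolecularSystem:
    """An ordered collection of atoms plus named index selections.

    The canonical groups ``protein`` (non-HETATM, non-water) and ``ligand``
    (HETATM, non-water) are built automatically; additional named selections
    may be added via :meth:`add_group`.
    """

    def __init__(self, atoms: Sequence[AtomRecord],
                 groups: Mapping[str, np.ndarray] | None = None) -> None:
        self.atoms: List[AtomRecord] = list(atoms)
        self.groups: Dict[str, np.ndarray] = {}
        if groups is None:
            self._build_default_groups()
        else:
            for name, idx in groups.items():
                self.add_group(name, idx)
        self._check_unique_keys()
        if "protein" in self.groups and "ligand" in self.groups:
            overlap = set(self.groups["protein"]) & set(self.groups["ligand"])
            if overlap:
                raise ValueError(f"protein/ligand selections overlap: {sorted(overlap)}")

    # -- construction helpers ------------------------------------------------

    def _build_default_groups(self) -> None:
        protein, ligand = [], []
        for i, a in enumerate(self.atoms):
            if a.res_name in WATER_RES_NAMES:
                continue
            (ligand if a.hetero else protein).append(i)
        self.groups["protein"] = np.asarray(protein, dtype=int)
        self.groups["ligand"] = np.asarray(ligand, dtype=int)

    def _check_unique_keys(self) -> None:
        seen: Dict[Tuple[str, int, str, str], int] = {}
        for i, a in enumerate(self.atoms):
            if a.key in seen:
                raise ValueError(
                    f"duplicate atom key {a.key} (atoms {seen[a.key]} and {i})")
            seen[a.key] = i

    # -- basic accessors -----------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in A."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def lj_rmin_half(self) -> np.ndarray:
        return np.array([a.lj_rmin_half for a in self.atoms], dtype=float)

    @property
    def lj_epsilon(self) -> np.ndarray:
        return np.array([a.lj_epsilon for a in self.atoms], dtype=float)

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    @property
    def elements(self) -> List[str]:
        return [a.element for a in self.atoms]

    def add_group(self, name: str, indices: Iterable[int]) -> None:
        idx = np.asarray(sorted(set(int(i) for i in indices)), dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_atoms):
            raise SelectionError(f"selection {name!r} has out-of-range indices")
        self.groups[name] = idx

    def select(self, name: str) -> np.ndarray:
        try:
            return self.groups[name]
        except KeyError:
            raise SelectionError(
                f"no selection named {name!r}; available: {sorted(self.groups)}")

    def residue_indices(self, res_id: int, chain: str | None = None) -> np.ndarray:
        """Indices of all atoms of residue ``res_id`` (author numbering)."""
        idx = [i for i, a in enumerate(self.atoms)
               if a.res_id == res_id and (chain is None or a.chain == chain)]
        if not idx:
            where = f"chain {chain}" if chain else "any chain"
            raise SelectionError(f"residue {res_id} not found in {where}")
        return np.asarray(idx, dtype=int)

    def iter_residues(self):
        """Yield ``(residue_key, indices)`` in order of first appearance."""
        order: Dict[Tuple[str, int, str], List[int]] = {}
        for i, a in enumerate(self.atoms):
            order.setdefault(a.residue_key, []).append(i)
        for key, idx in order.items():
            yield key, np.asarray(idx, dtype=int)

    def atom_index(self, chain: str, res_id: int, name: str,
                   ins_code: str = "") -> int:
        for i, a in enumerate(self.atoms):
            if a.key == (chain, res_id, ins_code, name):
                return i
        raise SelectionError(f"atom ({chain}, {res_id}{ins_code}, {name}) not found")

    def ca_indices(self, group: str = "protein") -> np.ndarray:
        idx = self.select(group)
        return np.asarray([i for i in idx if self.atoms[i].name == "CA"], dtype=int)

    # -- derived systems -----------------------------------------------------

    def with_coords(self, coords: np.ndarray) -> "MolecularSystem":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(f"expected coords of shape ({self.n_atoms}, 3)")
        atoms = [replace(a, coords=coords[i]) for i, a in enumerate(self.atoms)]
        return MolecularSystem(atoms, groups=self.groups)

    def subset(self, indices: Iterable[int]) -> "MolecularSystem":
        """New system containing only ``indices``, default groups rebuilt."""
        idx = list(indices)
        atoms = [replace(self.atoms[i]) for i in idx]
        return MolecularSystem(atoms)

    # -- validation ----------------------------------------------------------

    def validate(self) -> None:
        """Check field invariants; parameter fields are checked only if set."""
        for a in self.atoms:
            if not np.all(np.isfinite(a.coords)):
                raise ValueError(f"{a.label}: non-finite coordinates")
            if not math.isnan(a.lj_epsilon) and a.lj_epsilon < 0:
                raise ValueError(f"{a.label}: negative lj_epsilon")
            if not math.isnan(a.vdw_radius) and a.vdw_radius <= 0:
                raise ValueError(f"{a.label}: non-positive vdw_radius")
        self._check_unique_keys()

    def check_residue_charges(self, tol: float = 0.01) -> None:
        """Require every residue's summed charge to be near-integer."""
        for key, idx in self.iter_residues():
            q = float(np.nansum([self.atoms[i].charge for i in idx]))
            if abs(q - round(q)) > tol:
                chain, res_id, ins = key
                res = self.atoms[idx[0]].res_name
                raise ParameterError(
                    f"residue {chain}:{res}{res_id}{ins} has non-integer net "
                    f"charge {q:.4f} (tolerance {tol})")


@dataclass
class Trajectory:
    """A stack of coordinate frames sharing the parent system's atom order.

    ``frames`` has shape (F, N, 3) in A; ``frame_interval`` is the sampling
    interval in ps (metadata only).
    """

    frames: np.ndarray
    frame_interval: float = 2.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (F, N, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("trajectory contains non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def __getitem__(self, i) -> np.ndarray:
        return self.frames[i]

    def equilibrium_window(self, fraction: float = 1.0 / 3.0) -> "Trajectory":
        """Last ``fraction`` of the frames (default: final third)."""
        start = self.n_frames - max(1, int(round(self.n_frames * fraction)))
        return Trajectory(self.frames[start:], self.frame_interval)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _prescan_pdb(path: Path) -> None:
    """Validate coordinate fields line by line so errors can name the line."""
    has_altloc = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(f"{path}, line {lineno}: truncated record")
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise PDBParseError(
                        f"{path}, line {lineno}: malformed {what} coordinate "
                        f"field {line[lo:hi]!r}") from None
            if line[16] not in (" ", ""):
                has_altloc = True
    if has_altloc:
        logger.info(
            "%s: alternate locations present; keeping highest occupancy "
            "(ties: first encountered)", path)


def _atoms_from_array(arr: "struc.AtomArray") -> List[AtomRecord]:
    serials = (arr.get_annotation("atom_id") if "atom_id" in arr.get_annotation_categories()
               else np.arange(1, arr.array_length() + 1))
    ins = (arr.get_annotation("ins_code") if "ins_code" in arr.get_annotation_categories()
           else np.full(arr.array_length(), ""))
    atoms = []
    for i in range(arr.array_length()):
        atoms.append(AtomRecord(
            serial=int(serials[i]),
            name=str(arr.atom_name[i]),
            element=str(arr.element[i]).capitalize(),
            res_name=str(arr.res_name[i]),
            res_id=int(arr.res_id[i]),
            chain=str(arr.chain_id[i]),
            coords=np.array(arr.coord[i], dtype=float),
            ins_code=str(ins[i]).strip(),
            hetero=bool(arr.hetero[i]),
        ))
    return atoms


def read_pdb(path: str | Path) -> MolecularSystem:
    """Read a single-model PDB file into a :class:`MolecularSystem`.

    ATOM and HETATM records are parsed, insertion codes preserved and
    alternate locations resolved to the highest-occupancy conformer.
    Duplicate ``(chain, res_id, name)`` keys raise ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan_pdb(path)
    try:
        pdbf = PDBFile.read(str(path))
        arr = pdbf.get_structure(
            model=1, altloc="occupancy", extra_fields=["atom_id"])
    except Exception as exc:  # biotite raises several error types
        if isinstance(exc, (ValueError, struc.BadStructureError)):
            raise PDBParseError(f"{path}: {exc}") from exc
        raise
    return MolecularSystem(_atoms_from_array(arr))


def _system_to_atom_array(system: MolecularSystem) -> "struc.AtomArray":
    n = system.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = system.coords
    arr.set_annotation("chain_id", np.array([a.chain for a in system.atoms]))
    arr.set_annotation("res_id", np.array([a.res_id for a in system.atoms]))
    arr.set_annotation("ins_code", np.array([a.ins_code for a in system.atoms]))
    arr.set_annotation("res_name", np.array([a.res_name for a in system.atoms]))
    arr.set_annotation("atom_name", np.array([a.name for a in system.atoms]))
    arr.set_annotation("element", np.array([a.element.upper() for a in system.atoms]))
    arr.set_annotation("hetero", np.array([a.hetero for a in system.atoms]))
    arr.set_annotation("atom_id", np.array([a.serial for a in system.atoms]))
    return arr


def write_pdb(system: MolecularSystem, path: str | Path) -> None:
    """Write a system as a single-model PDB file."""
    pdbf = PDBFile()
    pdbf.set_structure(_system_to_atom_array(system))
    pdbf.write(str(path))


def _model_atom_counts(path: Path) -> List[int]:
    counts, current, in_model = [], 0, False
    with open(path) as fh:
        for line in fh:
            if line.startswith("MODEL"):
                in_model, current = True, 0
            elif line.startswith("ENDMDL"):
                counts.append(current)
                in_model = False
            elif line.startswith(("ATOM  ", "HETATM")):
                current += 1
    if not counts and current:
        counts = [current]  # no MODEL blocks: a single implicit model
    return counts


def read_trajectory(path: str | Path, system: MolecularSystem,
                    frame_interval: float = 2.0) -> Trajectory:
    """Read a multi-model PDB as a trajectory matching ``system``'s atoms.

    Every ``MODEL`` block must contain exactly the system's atom count; a
    mismatch raises :class:`PDBParseError` naming the offending model index
    (1-based).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan_pdb(path)
    counts = _model_atom_counts(path)
    for m, c in enumerate(counts, start=1):
        if c != system.n_atoms:
            raise PDBParseError(
                f"{path}: model {m} has {c} atoms, expected {system.n_atoms}")
    try:
        pdbf = PDBFile.read(str(path))
        coords = pdbf.get_coord(model=None)
    except Exception as exc:
        if isinstance(exc, (ValueError, struc.BadStructureError)):
            raise PDBParseError(f"{path}: {exc}") from exc
        raise
    return Trajectory(np.asarray(coords, dtype=float), frame_interval)


def write_trajectory(system: MolecularSystem, traj: Trajectory,
                     path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (one MODEL block per frame)."""
    if traj.n_atoms != system.n_atoms:
        raise ValueError("trajectory atom count does not match system")
    template = _system_to_atom_array(system)
    stack = struc.from_template(template, traj.frames)
    pdbf = PDBFile()
    pdbf.set_structure(stack)
    pdbf.write(str(path))


#: Pluggable trajectory reader registry: format name -> reader callable.
TRAJECTORY_READERS: Dict[str, Callable[..., Trajectory]] = {
    "pdb": read_trajectory,
}


# ---------------------------------------------------------------------------
# Parameter tables
# ---------------------------------------------------------------------------

def read_parameter_table(path: str | Path) -> Dict[Tuple[str, str], Dict[str, float]]:
    """Read a TSV parameter table into a ``(res_name, atom_name)`` mapping.

    The header must be exactly ``res_name atom_name charge lj_rmin_half
    lj_epsilon vdw_radius`` (tab separated).
    """
    df = pd.read_csv(path, sep="\t", dtype={"res_name": str, "atom_name": str})
    if tuple(df.columns) != PARAMETER_COLUMNS:
        raise ParameterError(
            f"{path}: expected columns {list(PARAMETER_COLUMNS)}, "
            f"got {list(df.columns)}")
    mapping: Dict[Tuple[str, str], Dict[str, float]] = {}
    for row in df.itertuples(index=False):
        key = (row.res_name, row.atom_name)
        if key in mapping:
            raise ParameterError(f"{path}: duplicate entry for {key}")
        mapping[key] = {
            "charge": float(row.charge),
            "lj_rmin_half": float(row.lj_rmin_half),
            "lj_epsilon": float(row.lj_epsilon),
            "vdw_radius": float(row.vdw_radius),
        }
    return mapping


def write_parameter_table(mapping: Mapping[Tuple[str, str], Mapping[str, float]],
                          path: str | Path) -> None:
    rows = [
        {"res_name": rn, "atom_name": an, **params}
        for (rn, an), params in mapping.items()
    ]
    df = pd.DataFrame(rows, columns=list(PARAMETER_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def assign_parameters(system: MolecularSystem,
                      mapping: Mapping[Tuple[str, str], Mapping[str, float]],
                      charge_tol: float = 0.01,
                      check_charges: bool = True) -> MolecularSystem:
    """Annotate every protein/ligand atom from the parameter mapping.

    Atoms in the protein or ligand selections without a table entry cause a
    :class:`ParameterError` listing them (no silent defaults).  After
    assignment, each residue's net charge must be within ``charge_tol`` of an
    integer.
    """
    required = set(system.select("protein")) | set(system.select("ligand"))
    missing = []
    atoms = []
    for i, a in enumerate(system.atoms):
        params = mapping.get((a.res_name, a.name))
        if params is None:
            if i in required:
                missing.append(a.label)
            atoms.append(replace(a))
            continue
        atoms.append(replace(
            a,
            charge=params["charge"],
            lj_rmin_half=params["lj_rmin_half"],
            lj_epsilon=params["lj_epsilon"],
            vdw_radius=params["vdw_radius"],
        ))
    if missing:
        raise ParameterError(
            "no parameter-table entry for atoms: " + ", ".join(missing))
    out = MolecularSystem(atoms, groups=system.groups)
    out.validate()
    if check_charges:
        out.check_residue_charges(tol=charge_tol)
    return out


def total_charge(system: MolecularSystem, group: str | None = None) -> float:
    """Summed partial charge of a group (or the whole system)."""
    if group is None:
        q = system.charges
    else:
        q = system.charges[system.select(group)]
    return float(np.nansum(q))
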