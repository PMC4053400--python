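"""Synthetic toy complexes and trajectories with planted statistics.

Everything the analysis pipeline consumes can be generated here without
external data: a small helical peptide carrying one arginine (charge +1,
guanidinium donors), one tyrosine (hydroxyl donor) and one leucine
(hydrophobic probe), bound to a carboxylate ligand of net charge -1 whose
oxygens sit in hydrogen-bond geometry with the arginine and tyrosine; plus

* :func:`gaussian_trajectory` — correlated Gaussian fluctuations about the
  reference with a planted inter-residue correlation structure and optional
  rigid-body noise (so superposition is exercised nontrivially), and
* :func:`planted_hbond_trajectory` — the H...acceptor distance follows the
  specified Gaussian peak(s) while everything else stays rigid.

Geometry is schematic, not physical (bond lengths are approximate, there is
no force field); the generators' only contract is that every planted
statistical parameter is recoverable by the corresponding analysis stage.
All randomness flows through ``numpy.random.default_rng(seed)`` (PCG64), so
equal seeds give bitwise-identical output on any platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from siescan.structure_io import (
    AtomRecord,
    MolecularSystem,
    Trajectory,
    assign_parameters,
)

__all__ = [
    "SyntheticSpec",
    "build_toy_complex",
    "gaussian_trajectory",
    "planted_hbond_trajectory",
]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic complex and trajectory generators."""

    n_residues: int = 8
    n_frames: int = 100
    seed: int = 0
    #: Per-residue fluctuation amplitude (A); scalar or per-residue array.
    sigma: float | Sequence[float] = 0.3
    #: Planted correlation blocks: (first_res_id, last_res_id, rho).
    correlation_blocks: List[Tuple[int, int, float]] = field(
        default_factory=lambda: [(2, 4, 0.8)])
    #: H...acceptor distance peaks: (mean A, sigma A, weight).
    hbond_peaks: List[Tuple[float, float, float]] = field(
        default_factory=lambda: [(1.81, 0.10, 1.0)])
    frame_interval: float = 2.0
    #: Rigid-body noise per frame; set both to 0 for a lab-frame trajectory.
    rigid_rotation_deg: float = 5.0
    rigid_translation: float = 1.0

    def __post_init__(self) -> None:
        if self.n_residues < 8:
            raise ValueError("toy complex needs at least 8 residues")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        sig = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if np.any(sig < 0):
            raise ValueError("sigma must be non-negative")
        for lo, hi, rho in self.correlation_blocks:
            if not (-1.0 < rho < 1.0):
                raise ValueError(f"planted correlation {rho} outside (-1, 1)")
            if hi < lo:
                raise ValueError(f"empty correlation block {lo}-{hi}")
        for mean, sig_p, w in self.hbond_peaks:
            if mean <= 0 or sig_p < 0 or w <= 0:
                raise ValueError("invalid hbond peak specification")


# ---------------------------------------------------------------------------
# Residue templates (local coordinates; +x points away from the helix axis)
# ---------------------------------------------------------------------------

def _t(d: Dict[str, Tuple[float, float, float]]):
    return {k: np.asarray(v, dtype=float) for k, v in d.items()}


_BACKBONE = {
    "N": (-0.70, -1.10, -0.45),
    "H": (-0.75, -2.05, -0.75),
    "CA": (0.0, 0.0, 0.0),
    "HA": (-0.52, 0.52, 0.80),
    "C": (0.45, 1.15, -0.85),
    "O": (0.95, 1.05, -1.95),
}

_ALA_SIDE = {
    "CB": (1.40, -0.40, 0.45),
    "HB1": (2.00, 0.40, 0.75),
    "HB2": (1.30, -1.10, 1.25),
    "HB3": (2.00, -0.90, -0.25),
}

_ARG_SIDE = {
    "CB": (1.45, -0.45, 0.40),
    "HB2": (1.45, -1.20, 1.15),
    "HB3": (1.30, -1.00, -0.55),
    "CG": (2.85, 0.10, 0.60),
    "HG2": (2.85, 0.85, 1.35),
    "HG3": (3.15, 0.60, -0.30),
    "CD": (4.25, -0.45, 0.80),
    "HD2": (4.25, -1.20, 1.55),
    "HD3": (4.55, -0.95, -0.10),
    "NE": (5.60, 0.10, 1.00),
    "HE": (5.70, 1.05, 1.35),
    "CZ": (6.90, -0.25, 0.90),
    "NH1": (7.55, 0.90, 1.05),
    "HH11": (8.55, 0.90, 1.00),
    "HH12": (7.10, 1.80, 1.20),
    "NH2": (7.55, -1.40, 0.70),
    "HH21": (8.55, -1.45, 0.65),
    "HH22": (7.10, -2.30, 0.60),
}

_TYR_SIDE = {
    "CB": (1.45, -0.45, 0.40),
    "HB2": (1.45, -1.20, 1.15),
    "HB3": (1.30, -1.00, -0.55),
    "CG": (2.85, 0.05, 0.60),
    "CD1": (3.55, 1.25, 0.60),
    "HD1": (3.05, 2.18, 0.60),
    "CD2": (3.55, -1.15, 0.60),
    "HD2": (3.05, -2.08, 0.60),
    "CE1": (4.95, 1.25, 0.60),
    "HE1": (5.45, 2.18, 0.60),
    "CE2": (4.95, -1.15, 0.60),
    "HE2": (5.45, -2.08, 0.60),
    "CZ": (5.65, 0.05, 0.60),
    "OH": (7.00, 0.10, 0.60),
    "HH": (7.40, 0.95, 0.55),
}

_LEU_SIDE = {
    "CB": (1.45, -0.45, 0.40),
    "HB2": (1.45, -1.20, 1.15),
    "HB3": (1.30, -1.00, -0.55),
    "CG": (2.85, 0.10, 0.60),
    "HG": (2.90, 0.85, 1.35),
    "CD1": (4.10, -0.75, 0.80),
    "HD11": (5.00, -0.15, 0.90),
    "HD12": (4.20, -1.40, 1.65),
    "HD13": (4.05, -1.40, -0.05),
    "CD2": (3.05, 1.05, -0.55),
    "HD21": (3.95, 1.65, -0.45),
    "HD22": (2.20, 1.70, -0.55),
    "HD23": (3.10, 0.50, -1.48),
}

_SIDE_CHAINS = {
    "ALA": _t(_ALA_SIDE),
    "ARG": _t(_ARG_SIDE),
    "TYR": _t(_TYR_SIDE),
    "LEU": _t(_LEU_SIDE),
}

# Charges (e); any rounding residual relative to the residue's formal charge
# is folded onto CB so each residue sums exactly to an integer.
_CHARGES: Dict[str, Tuple[float, Dict[str, float]]] = {
    "ALA": (0.0, {
        "N": -0.4157, "H": 0.2719, "CA": 0.0337, "HA": 0.0823,
        "CB": -0.1825, "HB1": 0.0603, "HB2": 0.0603, "HB3": 0.0603,
        "C": 0.5973, "O": -0.5679,
    }),
    "ARG": (1.0, {
        "N": -0.3479, "H": 0.2747, "CA": -0.2637, "HA": 0.1560,
        "CB": -0.0007, "HB2": 0.0327, "HB3": 0.0327,
        "CG": 0.0390, "HG2": 0.0285, "HG3": 0.0285,
        "CD": 0.0486, "HD2": 0.0687, "HD3": 0.0687,
        "NE": -0.5295, "HE": 0.3456, "CZ": 0.8076,
        "NH1": -0.8627, "HH11": 0.4478, "HH12": 0.4478,
        "NH2": -0.8627, "HH21": 0.4478, "HH22": 0.4478,
        "C": 0.7341, "O": -0.5894,
    }),
    "TYR": (0.0, {
        "N": -0.4157, "H": 0.2719, "CA": -0.0014, "HA": 0.0876,
        "CB": -0.0152, "HB2": 0.0295, "HB3": 0.0295,
        "CG": -0.0011, "CD1": -0.1906, "HD1": 0.1699,
        "CD2": -0.1906, "HD2": 0.1699, "CE1": -0.2341, "HE1": 0.1656,
        "CE2": -0.2341, "HE2": 0.1656, "CZ": 0.3226,
        "OH": -0.5579, "HH": 0.3992, "C": 0.5973, "O": -0.5679,
    }),
    "LEU": (0.0, {
        "N": -0.4157, "H": 0.2719, "CA": -0.0518, "HA": 0.0922,
        "CB": -0.1102, "HB2": 0.0457, "HB3": 0.0457,
        "CG": 0.3531, "HG": -0.0361,
        "CD1": -0.4121, "HD11": 0.1000, "HD12": 0.1000, "HD13": 0.1000,
        "CD2": -0.4121, "HD21": 0.1000, "HD22": 0.1000, "HD23": 0.1000,
        "C": 0.5973, "O": -0.5679,
    }),
    "LIG": (-1.0, {
        "C1": 0.70, "O1": -0.80, "O2": -0.80,
        "C2": -0.10, "C3": 0.00, "CM": 0.00,
    }),
}

#: Hydrogens attached to N/O (small radius, no LJ well to speak of).
_POLAR_H = frozenset({"H", "HE", "HH11", "HH12", "HH21", "HH22", "HH"})

# element -> (rmin/2 A, epsilon kcal/mol); vdW radius = rmin/2
_LJ_BY_ELEMENT = {
    "C": (1.9080, 0.1094),
    "N": (1.8240, 0.1700),
    "O": (1.6612, 0.2100),
    "S": (2.0000, 0.2500),
    "H": (1.3870, 0.0157),
}
_LJ_POLAR_H = (0.6000, 0.0157)


def _element_of(name: str) -> str:
    return name[0]


def _lj_of(name: str) -> Tuple[float, float]:
    if _element_of(name) == "H" and name in _POLAR_H:
        return _LJ_POLAR_H
    return _LJ_BY_ELEMENT[_element_of(name)]


def _parameter_mapping(res_names: Sequence[str]):
    """Build the (res_name, atom_name) parameter table for the toy system."""
    mapping = {}
    for rn in dict.fromkeys(res_names):
        target, charges = _CHARGES[rn]
        residual = target - math.fsum(charges.values())
        for an, q in charges.items():
            rh, eps = _lj_of(an)
            if an == "CB":
                q = q + residual
            mapping[(rn, an)] = {
                "charge": round(q, 6),
                "lj_rmin_half": rh,
                "lj_epsilon": eps,
                "vdw_radius": rh,
            }
    return mapping


# ---------------------------------------------------------------------------
# Toy complex construction
# ---------------------------------------------------------------------------

_HELIX_RADIUS = 2.3     # A
_HELIX_RISE = 1.5       # A per residue
_HELIX_TWIST = 100.0    # degrees per residue


def _sequence(n_residues: int) -> List[str]:
    seq = ["ALA", "ALA", "LEU", "ARG", "ALA", "ALA", "ALA", "TYR"]
    seq += ["ALA"] * (n_residues - len(seq))
    return seq


def _residue_frame(i: int) -> Tuple[np.ndarray, np.ndarray]:
    """CA position and local->world rotation for helix residue ``i``."""
    theta = math.radians(_HELIX_TWIST) * i
    ca = np.array([_HELIX_RADIUS * math.cos(theta),
                   _HELIX_RADIUS * math.sin(theta),
                   _HELIX_RISE * i])
    out = np.array([math.cos(theta), math.sin(theta), 0.0])   # local +x
    tang = np.array([-math.sin(theta), math.cos(theta), 0.0])  # local +y
    axis = np.array([0.0, 0.0, 1.0])                           # local +z
    rot = np.column_stack([out, tang, axis])
    return ca, rot


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def build_toy_complex(spec: SyntheticSpec | None = None
                      ) -> Tuple[MolecularSystem, dict]:
    """Build the annotated toy complex and its parameter mapping.

    The arginine guanidinium HH21 and the tyrosine hydroxyl HH are each
    placed 1.9 A from a carboxylate oxygen (donor-H...acceptor angle 180
    degrees), and the leucine CD1 methyl carbon sits 3.5 A from the ligand
    methyl carbon.  Returns ``(system, parameter_mapping)`` with parameters
    already assigned.
    """
    spec = spec or SyntheticSpec()
    seq = _sequence(spec.n_residues)
    placed: Dict[Tuple[int, str], np.ndarray] = {}
    atoms: List[AtomRecord] = []

    for i, rn in enumerate(seq):
        ca, rot = _residue_frame(i)
        template = dict(_t(_BACKBONE))
        template.update(_SIDE_CHAINS[rn])
        for an, local in template.items():
            placed[(i, an)] = ca + rot @ local

    arg_i = seq.index("ARG")
    tyr_i = seq.index("TYR")
    leu_i = seq.index("LEU")

    # Ligand: carboxylate O1 on the ARG NH2-HH21 axis at 1.9 A from HH21.
    nh2, hh21 = placed[(arg_i, "NH2")], placed[(arg_i, "HH21")]
    u = _unit(hh21 - nh2)
    _, arg_rot = _residue_frame(arg_i)
    up = np.array([0.0, 0.0, 1.0])
    o1 = hh21 + 1.9 * u
    c1 = o1 + 1.30 * _unit(u + 0.8 * up)
    o2 = c1 + 1.25 * _unit(up + 0.3 * u)
    c2 = c1 + 1.52 * _unit(u - 0.5 * up)
    c3 = c2 + 1.52 * _unit(u + 0.2 * up)
    side = _unit(np.cross(u, up))
    cm = c3 + 1.52 * _unit(u + 0.8 * side)
    lig_xyz = {"C1": c1, "O1": o1, "O2": o2, "C2": c2, "C3": c3, "CM": cm}

    # Re-aim the tyrosine hydroxyl at O2 (angle OH-HH...O2 = 180 degrees).
    v = _unit(placed[(tyr_i, "CZ")] - o2)
    placed[(tyr_i, "HH")] = o2 + 1.9 * v
    placed[(tyr_i, "OH")] = o2 + (1.9 + 0.97) * v

    # Pull the leucine CD1 methyl to 3.5 A from the ligand methyl carbon,
    # approaching from the side facing away from the rest of the ligand.
    old_cd1 = placed[(leu_i, "CD1")]
    lig_centroid = (c1 + o1 + o2 + c2 + c3) / 5.0
    new_cd1 = cm + 3.5 * _unit(cm - lig_centroid)
    shift = new_cd1 - old_cd1
    for an in ("CD1", "HD11", "HD12", "HD13"):
        placed[(leu_i, an)] = placed[(leu_i, an)] + shift

    serial = 0
    for i, rn in enumerate(seq):
        order = list(_BACKBONE) + list(_SIDE_CHAINS[rn])
        # conventional PDB ordering: N, CA, C, O first, then side chain, H's
        heavy = [a for a in order if _element_of(a) != "H"]
        hydro = [a for a in order if _element_of(a) == "H"]
        for an in heavy + hydro:
            serial += 1
            atoms.append(AtomRecord(
                serial=serial, name=an, element=_element_of(an),
                res_name=rn, res_id=i + 1, chain="A",
                coords=placed[(i, an)], hetero=False))
    for an in ("C1", "O1", "O2", "C2", "C3", "CM"):
        serial += 1
        atoms.append(AtomRecord(
            serial=serial, name=an, element=_element_of(an),
            res_name="LIG", res_id=len(seq) + 1, chain="A",
            coords=lig_xyz[an], hetero=True))

    mapping = _parameter_mapping(seq + ["LIG"])
    system = assign_parameters(MolecularSystem(atoms), mapping)

    # guard against accidental construction clashes
    xyz = system.coords
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    if d.min() < 0.5:
        i, j = np.unravel_index(int(d.argmin()), d.shape)
        raise RuntimeError(
            f"toy geometry clash: {system.atoms[i].label} vs "
            f"{system.atoms[j].label} at {d.min():.2f} A")
    return system, mapping


# ---------------------------------------------------------------------------
# Trajectory generators
# ---------------------------------------------------------------------------

def _residue_correlation(res_ids: np.ndarray,
                         blocks: Sequence[Tuple[int, int, float]]) -> np.ndarray:
    n = len(res_ids)
    corr = np.eye(n)
    for lo, hi, rho in blocks:
        members = np.nonzero((res_ids >= lo) & (res_ids <= hi))[0]
        for a in members:
            for b in members:
                if a != b:
                    corr[a, b] = rho
    # validity check: the block structure must be a correlation matrix
    if np.linalg.eigvalsh(corr).min() < -1e-10:
        raise ValueError("planted correlation blocks are not positive "
                         "semidefinite")
    return corr


def _random_rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    if max_deg <= 0:
        return np.eye(3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = math.radians(max_deg) * rng.uniform(-1.0, 1.0)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def gaussian_trajectory(system: MolecularSystem,
                        spec: SyntheticSpec) -> Trajectory:
    """Correlated Gaussian fluctuations about the reference structure.

    Each residue (the ligand counts as one) receives an isotropic Gaussian
    displacement of amplitude ``sigma``, drawn per axis from the planted
    residue-residue correlation matrix and applied rigidly to all of its
    atoms; per-frame rigid-body noise is layered on top.  Fully
    deterministic for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    residues = list(system.iter_residues())
    res_ids = np.array([key[1] for key, _ in residues])
    n_res = len(residues)
    sigma = np.broadcast_to(np.atleast_1d(np.asarray(spec.sigma, float)),
                            (n_res,)).copy()
    corr = _residue_correlation(res_ids, spec.correlation_blocks)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(n_res))

    ref = system.coords
    frames = np.empty((spec.n_frames, system.n_atoms, 3))
    # (F, 3, n_res) standard normals -> correlated residue displacements
    z = rng.standard_normal((spec.n_frames, 3, n_res))
    disp = np.einsum("rs,fas->far", chol, z) * sigma[None, None, :]
    for f in range(spec.n_frames):
        xyz = ref.copy()
        for r, (_, idx) in enumerate(residues):
            xyz[idx] += disp[f, :, r]
        if spec.rigid_rotation_deg > 0 or spec.rigid_translation > 0:
            rot = _random_rotation(rng, spec.rigid_rotation_deg)
            trans = (rng.uniform(-1.0, 1.0, size=3) * spec.rigid_translation
                     if spec.rigid_translation > 0 else np.zeros(3))
            centroid = xyz.mean(axis=0)
            xyz = (xyz - centroid) @ rot.T + centroid + trans
        frames[f] = xyz
    return Trajectory(frames, spec.frame_interval)


def planted_hbond_trajectory(system: MolecularSystem, spec: SyntheticSpec,
                             hydrogen: int | None = None,
                             acceptor: int | None = None) -> Trajectory:
    """Trajectory whose H...acceptor distance follows the planted peaks.

    Defaults to the arginine HH21 / ligand O1 pair of the toy complex.  Per
    frame the whole ligand is translated along the H->acceptor axis so the
    distance matches a draw from the specified Gaussian mixture; all other
    atoms stay fixed.  With peak sigma = 0 every frame's distance equals the
    peak position exactly.
    """
    if hydrogen is None:
        hydrogen = next(i for i, a in enumerate(system.atoms)
                        if a.name == "HH21")
    if acceptor is None:
        acceptor = next(i for i, a in enumerate(system.atoms)
                        if a.hetero and a.name == "O1")
    rng = np.random.default_rng(spec.seed)
    ref = system.coords
    lig_idx = system.select("ligand")
    h_pos = ref[hydrogen]
    axis = _unit(ref[acceptor] - h_pos)
    d0 = float(np.linalg.norm(ref[acceptor] - h_pos))

    means = np.array([p[0] for p in spec.hbond_peaks])
    sigs = np.array([p[1] for p in spec.hbond_peaks])
    weights = np.array([p[2] for p in spec.hbond_peaks], dtype=float)
    weights /= weights.sum()

    which = rng.choice(len(means), size=spec.n_frames, p=weights)
    draws = rng.normal(means[which], sigs[which])
    draws = np.maximum(draws, 0.5)

    frames = np.repeat(ref[None, :, :], spec.n_frames, axis=0)
    for f in range(spec.n_frames):
        frames[f, lig_idx] += (draws[f] - d0) * axis
    return Trajectory(frames, spec.frame_interval)
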