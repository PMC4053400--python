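"""Hydrogen-bond, screened-Coulomb polar and hydrophobic-contact analysis.

Three empirical models live here:

* a geometric hydrogen-bond detector (donor-acceptor distance plus
  donor-H...acceptor angle, with a trajectory occupancy threshold),
* the calibrated 12-10 hydrogen-bond energy in the H...acceptor distance,
* a per-residue screened-Coulomb polar energy using the sigmoidal
  distance-dependent dielectric popularized by the AutoDock 3 docking
  program (Mehler-Solmajer parameterization).

Hydrophobic contacts follow the LIGPLOT-style convention: carbon/sulfur
heavy-atom pairs within a distance cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from siescan import constants
from siescan.structure_io import MolecularSystem, Trajectory

__all__ = [
    "HBondSeries",
    "HBondEnergyModel",
    "PolarInteractionModel",
    "DistanceDistribution",
    "ContactProfile",
    "detect_hbonds",
    "distance_distribution",
    "hbond_energy",
    "hbond_energy_mean",
    "complex_hbond_total",
    "residue_polar_energy",
    "polar_total",
    "hydrophobic_contacts",
    "find_donor_hydrogens",
]

#: Elements that can donate or accept hydrogen bonds.
POLAR_ELEMENTS = frozenset({"N", "O", "S"})

#: Elements counted as nonpolar for hydrophobic contacts.
NONPOLAR_ELEMENTS = frozenset({"C", "S"})


class MissingHydrogensError(ValueError):
    """Raised when H-bond analysis runs on a structure without hydrogens."""


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBondEnergyModel:
    """Empirical 12-10 hydrogen-bond energy in the H...acceptor distance d:

        E(d) = a / d**12 - b / d**10   (kcal/mol, d in A)

    with calibrated a = 5.571 and b = 668.580.  Beyond the form's optimum the
    magnitude decays monotonically with distance.
    """

    a12: float = constants.HBOND_A12
    b10: float = constants.HBOND_B10

    def energy(self, distance: float | np.ndarray) -> float | np.ndarray:
        d = np.asarray(distance, dtype=float)
        if np.any(d <= 0):
            raise ValueError("distance must be positive")
        e = self.a12 / d ** 12 - self.b10 / d ** 10
        return float(e) if np.isscalar(distance) else e


@dataclass(frozen=True)
class PolarInteractionModel:
    """Screened Coulomb with a sigmoidal distance-dependent dielectric.

        E = scale * sum_ij 332.0637 * q_i * q_j / (eps(r_ij) * r_ij)

        eps(r) = A + B / (1 + k * exp(-lambda * B * r)),  B = eps0 - A

    ``eps(r)`` is monotonically non-decreasing and approaches ``eps0`` (bulk
    water) at large separation.
    """

    scale: float = constants.POLAR_SCALE
    eps0: float = constants.MS_EPS0
    a: float = constants.MS_A
    lam: float = constants.MS_LAMBDA
    k: float = constants.MS_K

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def dielectric(self, r: float | np.ndarray) -> float | np.ndarray:
        b = self.eps0 - self.a
        e = self.a + b / (1.0 + self.k * np.exp(-self.lam * b * np.asarray(r, float)))
        return float(e) if np.isscalar(r) else e

    def pair_energy(self, q1: float, q2: float, r: float) -> float:
        if r <= 0:
            raise ValueError("distance must be positive")
        return (self.scale * constants.COULOMB_CONSTANT * q1 * q2
                / (self.dielectric(r) * r))


# ---------------------------------------------------------------------------
# Hydrogen-bond detection
# ---------------------------------------------------------------------------

@dataclass
class HBondSeries:
    """One detected hydrogen bond with its per-frame H...acceptor distances."""

    donor: int
    hydrogen: int
    acceptor: int
    label: str
    distances: np.ndarray
    occupancy: float

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if np.any(self.distances <= 0):
            raise ValueError("H...acceptor distances must be positive")


def find_donor_hydrogens(system: MolecularSystem,
                         max_bond: float = constants.COVALENT_H_MAX
                         ) -> List[Tuple[int, int]]:
    """Pairs ``(donor_index, hydrogen_index)`` of polar heavy atoms with a
    covalently attached hydrogen (H within ``max_bond`` of N/O/S)."""
    coords = system.coords
    h_idx = [i for i, a in enumerate(system.atoms) if a.element == "H"]
    heavy = [i for i, a in enumerate(system.atoms) if a.element in POLAR_ELEMENTS]
    pairs = []
    for h in h_idx:
        best, best_d = None, max_bond
        for d in heavy:
            dist = float(np.linalg.norm(coords[h] - coords[d]))
            if dist <= best_d:
                best, best_d = d, dist
        if best is not None:
            pairs.append((best, h))
    return pairs


def detect_hbonds(traj: Trajectory, system: MolecularSystem,
                  d_max: float = constants.HBOND_DONOR_ACCEPTOR_MAX,
                  angle_min: float = constants.HBOND_ANGLE_MIN,
                  occupancy_min: float = constants.HBOND_OCCUPANCY_MIN,
                  group_a: str | Sequence[int] = "protein",
                  group_b: str | Sequence[int] = "ligand") -> List[HBondSeries]:
    """Detect hydrogen bonds between two groups across a trajectory.

    A frame satisfies the bond when donor...acceptor distance <= ``d_max``
    and the donor-H...acceptor angle >= ``angle_min`` degrees; bonds present
    in at least ``occupancy_min`` of frames are returned (both donor->
    acceptor directions between the groups are considered).  Structures
    without hydrogens raise :class:`MissingHydrogensError` — add explicit
    hydrogens upstream; protonation assignment is not performed here.
    """
    if not any(a.element == "H" for a in system.atoms):
        raise MissingHydrogensError(
            "structure has no hydrogen atoms; H-bond analysis requires "
            "explicit hydrogens (structures lacking them are read but "
            "refused here)")
    ga = set(system.select(group_a) if isinstance(group_a, str) else group_a)
    gb = set(system.select(group_b) if isinstance(group_b, str) else group_b)
    dh_pairs = find_donor_hydrogens(system)
    acceptors = [i for i, a in enumerate(system.atoms)
                 if a.element in POLAR_ELEMENTS]

    candidates = []
    for don, h in dh_pairs:
        for acc in acceptors:
            if acc == don:
                continue
            if (don in ga and acc in gb) or (don in gb and acc in ga):
                candidates.append((don, h, acc))
    if not candidates:
        return []

    cand = np.asarray(candidates, dtype=int)
    f = traj.frames
    d_pos, h_pos, a_pos = f[:, cand[:, 0]], f[:, cand[:, 1]], f[:, cand[:, 2]]
    ha = a_pos - h_pos
    ha_dist = np.linalg.norm(ha, axis=2)
    da_dist = np.linalg.norm(a_pos - d_pos, axis=2)
    hd = d_pos - h_pos
    cosang = np.sum(ha * hd, axis=2) / (
        ha_dist * np.linalg.norm(hd, axis=2) + 1e-12)
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ok = (da_dist <= d_max) & (angle >= angle_min)
    occupancy = ok.mean(axis=0)

    out = []
    for j, (don, h, acc) in enumerate(candidates):
        if occupancy[j] >= occupancy_min:
            label = (f"{system.atoms[acc].label}...{system.atoms[h].label}")
            out.append(HBondSeries(
                donor=don, hydrogen=h, acceptor=acc, label=label,
                distances=ha_dist[:, j], occupancy=float(occupancy[j])))
    out.sort(key=lambda s: -s.occupancy)
    return out


# ---------------------------------------------------------------------------
# Distance distributions
# ---------------------------------------------------------------------------

@dataclass
class DistanceDistribution:
    """Normalized histogram of H...acceptor distances."""

    bin_centers: np.ndarray
    frequencies: np.ndarray
    bin_width: float

    @property
    def peak(self) -> float:
        """Center of the modal bin."""
        return float(self.bin_centers[int(np.argmax(self.frequencies))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_center": self.bin_centers,
                             "frequency": self.frequencies})

    def local_maxima(self) -> List[float]:
        """Bin centers that are strict local maxima of the frequency curve."""
        f = self.frequencies
        out = []
        for i in range(len(f)):
            left = f[i - 1] if i > 0 else -np.inf
            right = f[i + 1] if i < len(f) - 1 else -np.inf
            if f[i] > 0 and f[i] >= left and f[i] >= right and \
                    (f[i] > left or f[i] > right):
                out.append(float(self.bin_centers[i]))
        return out


def distance_distribution(series: HBondSeries | np.ndarray,
                          bin_width: float = 0.05) -> DistanceDistribution:
    """Histogram of per-frame distances; frequencies sum to exactly 1."""
    d = series.distances if isinstance(series, HBondSeries) else \
        np.asarray(series, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance series")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = math.floor(d.min() / bin_width) * bin_width
    n_bins = max(1, int(math.ceil((d.max() - lo) / bin_width)) or 1)
    if d.max() >= lo + n_bins * bin_width:
        n_bins += 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(d, bins=edges)
    freq = counts / counts.sum()
    centers = edges[:-1] + bin_width / 2.0
    return DistanceDistribution(centers, freq, bin_width)


# ---------------------------------------------------------------------------
# Hydrogen-bond energies
# ---------------------------------------------------------------------------

def hbond_energy(distance: float, model: HBondEnergyModel = HBondEnergyModel()
                 ) -> float:
    """Empirical hydrogen-bond energy at one H...acceptor distance."""
    if distance <= 0:
        raise ValueError("distance must be positive")
    return float(model.energy(distance))


def hbond_energy_mean(series: HBondSeries | np.ndarray,
                      model: HBondEnergyModel = HBondEnergyModel()
                      ) -> Tuple[float, float]:
    """Trajectory mean and standard deviation of the per-frame bond energy."""
    d = series.distances if isinstance(series, HBondSeries) else \
        np.asarray(series, dtype=float)
    e = model.energy(d)
    mean = float(np.mean(e))
    sd = float(np.std(e, ddof=1)) if e.size > 1 else 0.0
    return mean, sd


def complex_hbond_total(per_bond_energies: Sequence[float]) -> float:
    """Exact sum of per-bond energies (order-stable compensated summation)."""
    return math.fsum(per_bond_energies)


# ---------------------------------------------------------------------------
# Per-residue screened-Coulomb polar energy
# ---------------------------------------------------------------------------

def residue_polar_energy(traj: Trajectory | np.ndarray,
                         system: MolecularSystem,
                         residue_id: int,
                         ligand_group: str | Sequence[int] = "ligand",
                         model: PolarInteractionModel = PolarInteractionModel(),
                         chain: str | None = None) -> Tuple[float, float]:
    """Mean +/- SEM screened-Coulomb energy between one residue and the
    ligand over a trajectory, kcal/mol.

    Per frame: ``scale * sum_ij 332.0637 q_i q_j / (eps(r_ij) r_ij)`` over
    residue atoms x ligand atoms.  A residue whose charges are all zero
    yields exactly 0.
    """
    res_idx = system.residue_indices(residue_id, chain=chain)
    lig_idx = (system.select(ligand_group) if isinstance(ligand_group, str)
               else np.asarray(ligand_group, dtype=int))
    qr = system.charges[res_idx]
    ql = system.charges[lig_idx]
    if np.any(np.isnan(qr)) or np.any(np.isnan(ql)):
        raise ValueError("charges not assigned; run assign_parameters")
    frames = traj.frames if isinstance(traj, Trajectory) else \
        np.asarray(traj, dtype=float)[None, ...]
    qq = np.outer(qr, ql)
    per_frame = np.empty(frames.shape[0])
    for f in range(frames.shape[0]):
        diff = frames[f][res_idx][:, None, :] - frames[f][lig_idx][None, :, :]
        r = np.sqrt(np.sum(diff ** 2, axis=2))
        if np.any(r <= 0):
            raise ValueError("coincident residue/ligand atoms")
        eps = model.dielectric(r)
        per_frame[f] = model.scale * constants.COULOMB_CONSTANT * \
            np.sum(qq / (eps * r))
    mean = float(per_frame.mean())
    sem = (float(per_frame.std(ddof=1) / math.sqrt(per_frame.size))
           if per_frame.size > 1 else 0.0)
    return mean, sem


def polar_total(residue_energies: Sequence[float]) -> float:
    """Exact sum of per-residue polar energies."""
    return math.fsum(residue_energies)


# ---------------------------------------------------------------------------
# Hydrophobic contacts
# ---------------------------------------------------------------------------

@dataclass
class ContactProfile:
    """Per-frame hydrophobic contact table.

    ``frame_table`` is frames x residue-labels (bool: residue has at least
    one qualifying nonpolar pair with the ligand that frame).
    """

    frame_table: pd.DataFrame

    @property
    def occupancy(self) -> pd.Series:
        """Fraction of frames each residue is in contact."""
        return self.frame_table.mean(axis=0)


def hydrophobic_contacts(traj: Trajectory, system: MolecularSystem,
                         cutoff: float = constants.HYDROPHOBIC_CUTOFF,
                         protein_group: str = "protein",
                         ligand_group: str = "ligand") -> ContactProfile:
    """Residues making nonpolar (C/S) heavy-atom contacts with the ligand.

    A residue is in contact in a frame when any of its carbon/sulfur atoms
    lies within ``cutoff`` of a ligand carbon/sulfur atom.
    """
    prot = [i for i in system.select(protein_group)
            if system.atoms[i].element in NONPOLAR_ELEMENTS]
    lig = [i for i in system.select(ligand_group)
           if system.atoms[i].element in NONPOLAR_ELEMENTS]
    res_of = {}
    labels = []
    for i in prot:
        a = system.atoms[i]
        lab = f"{a.chain}:{a.res_name}{a.res_id}{a.ins_code}"
        if lab not in res_of.values():
            labels.append(lab)
        res_of[i] = lab
    table = pd.DataFrame(False, index=range(traj.n_frames), columns=labels)
    if not prot or not lig:
        return ContactProfile(table)
    prot_arr = np.asarray(prot, dtype=int)
    lig_arr = np.asarray(lig, dtype=int)
    for f in range(traj.n_frames):
        diff = traj.frames[f][prot_arr][:, None, :] - \
            traj.frames[f][lig_arr][None, :, :]
        close = np.any(np.sum(diff ** 2, axis=2) <= cutoff ** 2, axis=1)
        for i, hit in zip(prot_arr, close):
            if hit:
                table.loc[f, res_of[i]] = True
    return ContactProfile(table)
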