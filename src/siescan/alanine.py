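"""Computational alanine scanning: side-chain truncation and ddG reporting.

A mutant is built directly from wild-type coordinates: every side-chain atom
beyond C-beta is removed and the gamma heavy atom is replaced by a hydrogen
placed on the old C-beta -> C-gamma axis at the standard C-H bond length.
The residue is renamed ALA and re-parameterized with alanine charges and LJ
parameters.  No repacking or minimization is performed; by default mutant
energies are rescored on (mutated) wild-type snapshots, which is an
approximation relative to running fresh mutant dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from siescan import constants
from siescan.energetics import EnergyComponents
from siescan.structure_io import MolecularSystem, SelectionError, Trajectory

__all__ = [
    "MutationSpec",
    "MutationError",
    "ALA_PARAMETERS",
    "mutate_to_alanine",
    "mutate_trajectory",
    "alanine_scan_report",
]


class MutationError(ValueError):
    """Raised for invalid mutation requests (Gly/Ala target, missing atoms)."""


#: Alanine per-atom parameters (charge e, rmin/2 A, epsilon kcal/mol,
#: vdW radius A); net charge sums to exactly 0.
ALA_PARAMETERS: Dict[str, Tuple[float, float, float, float]] = {
    "N":   (-0.4157, 1.8240, 0.1700, 1.8240),
    "H":   (0.2719, 0.6000, 0.0157, 0.6000),
    "CA":  (0.0337, 1.9080, 0.1094, 1.9080),
    "HA":  (0.0823, 1.3870, 0.0157, 1.3870),
    "CB":  (-0.1825, 1.9080, 0.1094, 1.9080),
    "HB1": (0.0603, 1.4870, 0.0157, 1.4870),
    "HB2": (0.0603, 1.4870, 0.0157, 1.4870),
    "HB3": (0.0603, 1.4870, 0.0157, 1.4870),
    "C":   (0.5973, 1.9080, 0.0860, 1.9080),
    "O":   (-0.5679, 1.6612, 0.2100, 1.6612),
    "OXT": (-0.5679, 1.6612, 0.2100, 1.6612),
}

#: Backbone + beta atoms retained through the truncation (PDB v3 names).
_KEPT_NAMES = frozenset({
    "N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3",
    "HA", "HA2", "HA3", "CB", "HB", "HB1", "HB2", "HB3",
})

#: Gamma-position heavy atoms in preference order.
_GAMMA_NAMES = ("CG", "CG1", "OG", "OG1", "SG", "CG2")


@dataclass(frozen=True)
class MutationSpec:
    """A single X -> ALA mutation (author residue numbering)."""

    chain: str
    res_id: int
    original: str | None = None
    target: str = "ALA"

    def __post_init__(self) -> None:
        if self.target != "ALA":
            raise MutationError("only mutations to alanine are supported")

    @classmethod
    def parse(cls, text: str) -> "MutationSpec":
        """Parse ``"A:126"`` style residue addresses."""
        chain, _, res = text.partition(":")
        if not res:
            raise MutationError(f"cannot parse residue address {text!r}")
        return cls(chain=chain, res_id=int(res))


def _mutation_plan(system: MolecularSystem, spec: MutationSpec):
    """Resolve the residue, validate it, and plan the truncation.

    Returns ``(kept_old_indices, cb_index, gamma_index, insert_after)`` where
    ``insert_after`` is the position of CB within the kept list (the new HB1
    goes right after it).
    """
    res_idx = system.residue_indices(spec.res_id, chain=spec.chain)
    res_name = system.atoms[res_idx[0]].res_name
    if spec.original is not None and res_name != spec.original:
        raise MutationError(
            f"residue {spec.chain}:{spec.res_id} is {res_name}, "
            f"expected {spec.original}")
    if res_name in ("GLY", "ALA"):
        raise MutationError(
            f"residue {spec.chain}:{res_name}{spec.res_id} has no side chain "
            "beyond C-beta to truncate")
    names = {system.atoms[i].name: i for i in res_idx}
    if "CB" not in names:
        raise MutationError(
            f"residue {spec.chain}:{res_name}{spec.res_id} lacks a CB atom")
    gamma = next((names[g] for g in _GAMMA_NAMES if g in names), None)
    if gamma is None:
        raise MutationError(
            f"residue {spec.chain}:{res_name}{spec.res_id} lacks a gamma "
            "heavy atom (CG/OG/SG)")
    res_set = set(res_idx)
    kept = [i for i in range(system.n_atoms)
            if i not in res_set or system.atoms[i].name in _KEPT_NAMES]
    cb = names["CB"]
    insert_after = kept.index(cb)
    return kept, cb, gamma, insert_after


def _hb1_position(cb: np.ndarray, cg: np.ndarray,
                  length: float = constants.CH_BOND_LENGTH) -> np.ndarray:
    axis = cg - cb
    norm = np.linalg.norm(axis)
    if norm < 1e-6:
        raise MutationError("CB and gamma atom coincide")
    return cb + length * axis / norm


def mutate_to_alanine(system: MolecularSystem, spec: MutationSpec,
                      parameters: Mapping[str, Tuple[float, float, float, float]]
                      | None = None) -> MolecularSystem:
    """Truncate a residue's side chain at C-gamma, producing an ALA mutant.

    Side-chain atoms beyond C-beta are dropped; a new ``HB1`` hydrogen is
    placed along the former CB->CG direction at 1.09 A; the residue is
    renamed ALA and its atoms re-parameterized from ``parameters`` (default
    :data:`ALA_PARAMETERS`).  All other atoms are untouched (coordinates
    compare bitwise equal).
    """
    params = ALA_PARAMETERS if parameters is None else parameters
    kept, cb, gamma, insert_after = _mutation_plan(system, spec)
    target_res = system.atoms[cb].residue_key
    hb1_xyz = _hb1_position(system.atoms[cb].coords, system.atoms[gamma].coords)

    max_serial = max(a.serial for a in system.atoms)
    new_atoms = []
    for pos, i in enumerate(kept):
        a = system.atoms[i]
        if a.residue_key == target_res:
            name = a.name
            if name not in params:
                raise MutationError(
                    f"no alanine parameters for retained atom {name!r}")
            q, rh, eps, vdw = params[name]
            a = replace(a, res_name="ALA", charge=q, lj_rmin_half=rh,
                        lj_epsilon=eps, vdw_radius=vdw)
        else:
            a = replace(a)
        new_atoms.append(a)
        if pos == insert_after:
            q, rh, eps, vdw = params["HB1"]
            new_atoms.append(replace(
                system.atoms[cb], serial=max_serial + 1, name="HB1",
                element="H", res_name="ALA", coords=hb1_xyz,
                charge=q, lj_rmin_half=rh, lj_epsilon=eps, vdw_radius=vdw))
    return MolecularSystem(new_atoms)


def mutate_trajectory(traj: Trajectory, system: MolecularSystem,
                      spec: MutationSpec,
                      parameters=None
                      ) -> Tuple[MolecularSystem, Trajectory]:
    """Apply the truncation to every frame of a wild-type trajectory.

    The HB1 position is rebuilt per frame from that frame's CB/CG
    coordinates.  Returns the mutant system (reference coordinates) and the
    matching mutant trajectory.
    """
    if traj.n_atoms != system.n_atoms:
        raise ValueError("trajectory does not match system")
    mutant = mutate_to_alanine(system, spec, parameters)
    kept, cb, gamma, insert_after = _mutation_plan(system, spec)
    frames = np.empty((traj.n_frames, len(kept) + 1, 3))
    kept_arr = np.asarray(kept, dtype=int)
    before = kept_arr[: insert_after + 1]
    after = kept_arr[insert_after + 1:]
    for f in range(traj.n_frames):
        xyz = traj.frames[f]
        hb1 = _hb1_position(xyz[cb], xyz[gamma])
        frames[f] = np.vstack([xyz[before], hb1[None, :], xyz[after]])
    return mutant, Trajectory(frames, traj.frame_interval)


# ---------------------------------------------------------------------------
# ddG reporting
# ---------------------------------------------------------------------------

def alanine_scan_report(wild: EnergyComponents, mutant: EnergyComponents,
                        wild_polar: Mapping[str, float] | None = None,
                        mutant_polar: Mapping[str, float] | None = None,
                        reported_ddg: float | None = None,
                        tol: float = 0.02) -> pd.DataFrame:
    """Component-wise mutant-minus-wild differences and ddG.

    ``ddG = dG_bind(mutant) - dG_bind(wild)``; positive values mark an
    unfavourable mutation.  If ``reported_ddg`` (an externally stated value)
    disagrees with the recomputed one by more than ``tol``, the row is
    flagged rather than overwritten.  Optional per-residue polar tables are
    appended as extra rows.
    """
    rows = []
    for name, (w, ws), (m, ms) in zip(
            wild.as_dict().keys(),
            wild.as_dict().values(),
            mutant.as_dict().values()):
        rows.append({"quantity": name, "wild": w, "mutant": m,
                     "difference": m - w, "flag": ""})
    ddg = mutant.dg_bind - wild.dg_bind
    flag = ""
    if reported_ddg is not None and abs(reported_ddg - ddg) > tol:
        flag = (f"stated ddG {reported_ddg:+.2f} inconsistent with "
                f"dG columns (recomputed {ddg:+.2f}); recomputed value used")
    rows.append({"quantity": "ddG_bind", "wild": 0.0, "mutant": ddg,
                 "difference": ddg, "flag": flag})
    if wild_polar is not None and mutant_polar is not None:
        for label in wild_polar:
            w = wild_polar[label]
            m = mutant_polar.get(label, math.nan)
            rows.append({"quantity": f"polar:{label}", "wild": w, "mutant": m,
                         "difference": m - w, "flag": ""})
    return pd.DataFrame(rows, columns=["quantity", "wild", "mutant",
                                       "difference", "flag"])
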