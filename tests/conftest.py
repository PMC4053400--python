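"""Shared fixtures: toy complex, tiny fast-scoring system, oracles."""

from __future__ import annotations

import numpy as np
import pytest

from siescan.structure_io import AtomRecord, MolecularSystem
from siescan.synth import SyntheticSpec, build_toy_complex


@pytest.fixture(scope="session")
def toy():
    """(system, parameter_mapping) of the default toy complex."""
    return build_toy_complex()


@pytest.fixture(scope="session")
def toy_system(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_mapping(toy):
    return toy[1]


@pytest.fixture
def lab_spec():
    """Generator spec without rigid-body noise (lab-frame trajectory)."""
    return SyntheticSpec(n_frames=50, seed=7, rigid_rotation_deg=0.0,
                         rigid_translation=0.0)


def _atom(serial, name, element, res_name, res_id, coords, charge,
          rh=1.7, eps=0.12, vdw=1.7, hetero=False, chain="A"):
    return AtomRecord(serial=serial, name=name, element=element,
                      res_name=res_name, res_id=res_id, chain=chain,
                      coords=np.asarray(coords, float), charge=charge,
                      lj_rmin_half=rh, lj_epsilon=eps, vdw_radius=vdw,
                      hetero=hetero)


@pytest.fixture(scope="session")
def tiny_complex():
    """4-atom charged complex for fast full-SIE evaluations."""
    atoms = [
        _atom(1, "N1", "N", "PRT", 1, (0.0, 0.0, 0.0), 0.5, rh=1.824,
              vdw=1.824),
        _atom(2, "C1", "C", "PRT", 1, (1.5, 0.0, 0.0), -0.5, rh=1.908,
              vdw=1.908),
        _atom(3, "O1", "O", "LIG", 2, (0.0, 4.0, 0.0), -0.5, rh=1.661,
              vdw=1.661, hetero=True),
        _atom(4, "C2", "C", "LIG", 2, (1.5, 4.0, 0.0), 0.5, rh=1.908,
              vdw=1.908, hetero=True),
    ]
    return MolecularSystem(atoms)


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------

def naive_coulomb(system, ia, ib, dielectric=1.0, coords=None):
    xyz = system.coords if coords is None else coords
    q = system.charges
    total = 0.0
    for i in ia:
        for j in ib:
            r = float(np.linalg.norm(xyz[i] - xyz[j]))
            total += 332.0637 * q[i] * q[j] / (dielectric * r)
    return total


def naive_lj(system, ia, ib, coords=None):
    xyz = system.coords if coords is None else coords
    rh, eps = system.lj_rmin_half, system.lj_epsilon
    total = 0.0
    for i in ia:
        for j in ib:
            r = float(np.linalg.norm(xyz[i] - xyz[j]))
            rmin = rh[i] + rh[j]
            e = (eps[i] * eps[j]) ** 0.5
            total += e * ((rmin / r) ** 12 - 2.0 * (rmin / r) ** 6)
    return total


def grid_min_rmsd(mobile, reference, levels=5):
    """Brute-force rotation-grid minimum RMSD (after centroid alignment)."""
    from scipy.spatial.transform import Rotation

    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)

    def rmsd_for(eulers):
        mats = Rotation.from_euler("zyx", eulers, degrees=True).as_matrix()
        fitted = np.einsum("kij,nj->kni", mats, x)
        return np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=2), axis=1))

    step = 15.0
    center = np.zeros(3)
    spans = (np.arange(-180.0, 180.0, step),
             np.arange(-90.0, 90.0 + step, step),
             np.arange(-180.0, 180.0, step))
    grid = np.array(np.meshgrid(*spans, indexing="ij")).reshape(3, -1).T
    r = rmsd_for(grid)
    best = grid[np.argmin(r)]
    best_rmsd = r.min()
    for _ in range(levels):
        step /= 4.0
        offs = np.array(np.meshgrid(*([np.linspace(-4 * step, 4 * step, 9)] * 3),
                                    indexing="ij")).reshape(3, -1).T
        cand = best + offs
        r = rmsd_for(cand)
        if r.min() < best_rmsd:
            best_rmsd = r.min()
            best = cand[np.argmin(r)]
    return float(best_rmsd)


def two_sphere_union_area(r1, r2, d):
    """Analytic surface area of the union of two overlapping spheres."""
    if d >= r1 + r2:
        return 4.0 * np.pi * (r1 ** 2 + r2 ** 2)
    x1 = (d * d + r1 * r1 - r2 * r2) / (2.0 * d)
    x2 = d - x1
    h1 = r1 - x1
    h2 = r2 - x2
    return (4.0 * np.pi * r1 ** 2 - 2.0 * np.pi * r1 * h1
            + 4.0 * np.pi * r2 ** 2 - 2.0 * np.pi * r2 * h2)
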