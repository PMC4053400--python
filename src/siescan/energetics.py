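"""Solvated interaction energy (SIE) machinery.

The endpoint binding free energy is the calibrated linear combination

    dG_bind = alpha * (E_c + E_vdw + dG_R + gamma*dMSA) + C

with intermolecular Coulomb (``E_c``) and Lennard-Jones (``E_vdw``)
energies, the reaction-field change on binding (``dG_R``) from a
two-dielectric Poisson solve, and the molecular-surface-area term
(``gamma*dMSA``).  Atomic van der Waals radii are linearly scaled by
``rho_radii`` before the surface and reaction-field evaluations.

The reaction field uses a finite-difference Poisson solver on a cubic grid
(7-point stencil, fractionally smoothed dielectric boundary, analytic
Dirichlet boundary values); the reported energy is the difference between
the two-dielectric solve and a uniform interior-dielectric solve on the same
grid, so the grid self-energy cancels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence, Tuple

import numpy as np
from scipy.sparse import coo_matrix, diags
from scipy.sparse.linalg import cg
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from siescan import constants
from siescan.structure_io import MolecularSystem, Trajectory

__all__ = [
    "SIECoefficients",
    "EnergyComponents",
    "coulomb_energy",
    "lj_energy",
    "sasa",
    "delta_msa",
    "reaction_field",
    "delta_reaction_field",
    "sie_combine",
    "sie_snapshot",
    "sie_trajectory",
    "ic50_to_dg",
]


# ---------------------------------------------------------------------------
# Coefficients / components
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SIECoefficients:
    """Calibrated SIE coefficients (defaults: standard published values)."""

    alpha_global: float = constants.SIE_ALPHA
    d_in: float = constants.SIE_DIELECTRIC_IN
    rho_radii: float = constants.SIE_RADIUS_SCALE
    gamma_msa: float = constants.SIE_GAMMA
    c_const: float = constants.SIE_CONSTANT

    def __post_init__(self) -> None:
        if self.d_in < 1.0:
            raise ValueError("interior dielectric must be >= 1")
        if self.rho_radii <= 0.0:
            raise ValueError("radius scaling must be positive")


@dataclass
class EnergyComponents:
    """Snapshot statistics of the SIE terms (mean and standard error).

    ``dg_bind`` is the linear combination of the four component means; the
    ``validate`` method checks that identity against a coefficient set.
    """

    e_coulomb: float
    e_vdw: float
    g_reaction: float
    gamma_msa_term: float
    dg_bind: float
    e_coulomb_sem: float = 0.0
    e_vdw_sem: float = 0.0
    g_reaction_sem: float = 0.0
    gamma_msa_term_sem: float = 0.0
    dg_bind_sem: float = 0.0
    n_snapshots: int = 1

    def __post_init__(self) -> None:
        if self.n_snapshots < 1:
            raise ValueError("n_snapshots must be >= 1")

    def validate(self, coefficients: SIECoefficients, tol: float = 1e-9) -> None:
        expected = sie_combine(self, coefficients)
        if abs(expected - self.dg_bind) > tol:
            raise ValueError(
                f"dg_bind {self.dg_bind} inconsistent with component "
                f"combination {expected}")

    def as_dict(self) -> dict:
        return {
            "dE_vdw": (self.e_vdw, self.e_vdw_sem),
            "dE_c": (self.e_coulomb, self.e_coulomb_sem),
            "gamma_dMSA": (self.gamma_msa_term, self.gamma_msa_term_sem),
            "dG_R": (self.g_reaction, self.g_reaction_sem),
            "dG_bind": (self.dg_bind, self.dg_bind_sem),
        }


# ---------------------------------------------------------------------------
# Pairwise intermolecular energies
# ---------------------------------------------------------------------------

def _group_indices(system: MolecularSystem, group) -> np.ndarray:
    if isinstance(group, str):
        return system.select(group)
    return np.asarray(group, dtype=int)


def _pair_distances(system: MolecularSystem, ia: np.ndarray, ib: np.ndarray,
                    coords: np.ndarray | None, min_sep: float = 0.1) -> np.ndarray:
    xyz = system.coords if coords is None else np.asarray(coords, float)
    r = cdist(xyz[ia], xyz[ib])
    bad = np.argwhere(r < min_sep)
    if bad.size:
        i, j = bad[0]
        a, b = system.atoms[ia[i]], system.atoms[ib[j]]
        raise ValueError(
            f"atoms {a.label} and {b.label} overlap (r = {r[i, j]:.3f} A)")
    return r


def _require_charges(system: MolecularSystem, idx: np.ndarray) -> np.ndarray:
    q = system.charges[idx]
    if np.any(np.isnan(q)):
        raise ValueError("partial charges not assigned; run assign_parameters")
    return q


def coulomb_energy(system: MolecularSystem, group_a, group_b,
                   dielectric: float = 1.0,
                   coords: np.ndarray | None = None) -> float:
    """Intermolecular Coulomb energy between two disjoint groups, kcal/mol.

    ``sum over a in A, b in B of 332.0637 * q_a * q_b / (dielectric * r_ab)``.
    """
    ia, ib = _group_indices(system, group_a), _group_indices(system, group_b)
    if set(ia) & set(ib):
        raise ValueError("groups must be disjoint")
    qa, qb = _require_charges(system, ia), _require_charges(system, ib)
    r = _pair_distances(system, ia, ib, coords)
    e = constants.COULOMB_CONSTANT * np.outer(qa, qb) / (dielectric * r)
    return float(e.sum())


def lj_energy(system: MolecularSystem, group_a, group_b,
              coords: np.ndarray | None = None) -> float:
    """Intermolecular 12-6 Lennard-Jones energy, kcal/mol.

    Lorentz-Berthelot combination: ``r_min = rmin_half_a + rmin_half_b``,
    ``eps = sqrt(eps_a * eps_b)``; minimum energy ``-eps`` at ``r = r_min``.
    """
    ia, ib = _group_indices(system, group_a), _group_indices(system, group_b)
    if set(ia) & set(ib):
        raise ValueError("groups must be disjoint")
    rha, rhb = system.lj_rmin_half[ia], system.lj_rmin_half[ib]
    ea, eb = system.lj_epsilon[ia], system.lj_epsilon[ib]
    if np.any(np.isnan(rha)) or np.any(np.isnan(rhb)) or \
            np.any(np.isnan(ea)) or np.any(np.isnan(eb)):
        raise ValueError("LJ parameters not assigned; run assign_parameters")
    r = _pair_distances(system, ia, ib, coords)
    rmin = np.add.outer(rha, rhb)
    eps = np.sqrt(np.outer(ea, eb))
    x = (rmin / r) ** 6
    return float(np.sum(eps * (x * x - 2.0 * x)))


# ---------------------------------------------------------------------------
# Surface area (Shrake-Rupley)
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Near-uniform unit-sphere quadrature points (golden-spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def sasa(system: MolecularSystem, group,
         probe_radius: float = constants.PROBE_RADIUS,
         radius_scale: float = 1.0,
         n_points: int = 960,
         coords: np.ndarray | None = None) -> float:
    """Solvent-accessible surface area of a group in isolation, A^2.

    Shrake-Rupley quadrature with ``n_points`` test points per atom; atomic
    radii are multiplied by ``radius_scale`` before the probe is added.
    Atoms outside ``group`` do not occlude.
    """
    idx = _group_indices(system, group)
    radii = system.vdw_radii[idx]
    if np.any(np.isnan(radii)) or np.any(radii <= 0):
        raise ValueError("all group atoms need a positive vdw_radius")
    xyz = (system.coords if coords is None else np.asarray(coords, float))[idx]
    big = radii * radius_scale + probe_radius
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(xyz)
    # neighbours closer than the sum of the two largest extended radii can occlude
    pairs = tree.query_ball_tree(tree, r=2.0 * big.max())
    total = 0.0
    for i in range(len(idx)):
        pts = xyz[i] + big[i] * sphere
        exposed = np.ones(n_points, dtype=bool)
        for j in pairs[i]:
            if j == i:
                continue
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            exposed &= d2 > big[j] ** 2
            if not exposed.any():
                break
        total += 4.0 * math.pi * big[i] ** 2 * exposed.sum() / n_points
    return float(total)


def delta_msa(system: MolecularSystem,
              protein_group="protein", ligand_group="ligand",
              gamma: float = constants.SIE_GAMMA,
              radius_scale: float = constants.SIE_RADIUS_SCALE,
              probe_radius: float = constants.PROBE_RADIUS,
              n_points: int = 960,
              coords: np.ndarray | None = None) -> Tuple[float, float]:
    """Surface-area change on binding and its energy term.

    Returns ``(dMSA, gamma * dMSA)`` with
    ``dMSA = MSA(complex) - MSA(protein) - MSA(ligand)``; burying surface on
    binding makes both values negative for ``gamma > 0``.
    """
    ip = _group_indices(system, protein_group)
    il = _group_indices(system, ligand_group)
    both = np.concatenate([ip, il])
    kw = dict(probe_radius=probe_radius, radius_scale=radius_scale,
              n_points=n_points, coords=coords)
    dmsa = (sasa(system, both, **kw)
            - sasa(system, ip, **kw)
            - sasa(system, il, **kw))
    return float(dmsa), float(gamma * dmsa)


# ---------------------------------------------------------------------------
# Finite-difference Poisson reaction field
# ---------------------------------------------------------------------------

def _surface_distance(points: np.ndarray, centers: np.ndarray,
                      radii: np.ndarray, pad: float) -> np.ndarray:
    """min over atoms of (|p - center| - radius); +inf far outside.

    Only evaluated within ``radius + pad`` of each atom — distant points keep
    +inf, which downstream code treats as solvent.
    """
    d = np.full(points.shape[:-1], np.inf)
    flat = points.reshape(-1, 3)
    tree = cKDTree(flat)
    dflat = d.reshape(-1)
    for c, r in zip(centers, radii):
        js = np.asarray(tree.query_ball_point(c, r + pad), dtype=int)
        if js.size == 0:
            continue
        dist = np.linalg.norm(flat[js] - c, axis=1) - r
        np.minimum.at(dflat, js, dist)
    return dflat.reshape(points.shape[:-1])


def _face_dielectric(mid: np.ndarray, centers: np.ndarray, radii: np.ndarray,
                     h: float, eps_in: float, eps_out: float) -> np.ndarray:
    """Harmonically interpolated dielectric on cell faces.

    The fraction of a face inside the solute is approximated from the signed
    distance of its midpoint to the molecular (vdW) surface, linearized over
    one grid spacing.
    """
    d = _surface_distance(mid, centers, radii, pad=2.0 * h)
    frac = np.clip(0.5 - d / h, 0.0, 1.0)
    return 1.0 / (frac / eps_in + (1.0 - frac) / eps_out)


def _grid_axes(origin: np.ndarray, n: Tuple[int, int, int], h: float):
    return [origin[k] + h * np.arange(n[k]) for k in range(3)]


def _trilinear_weights(origin: np.ndarray, h: float, n: Tuple[int, int, int],
                       pos: np.ndarray):
    """Node indices and weights spreading/interpolating at ``pos``."""
    t = (pos - origin) / h
    i0 = np.floor(t).astype(int)
    f = t - i0
    out = []
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = ((f[0] if dx else 1 - f[0])
                     * (f[1] if dy else 1 - f[1])
                     * (f[2] if dz else 1 - f[2]))
                idx = (i0[0] + dx, i0[1] + dy, i0[2] + dz)
                for k in range(3):
                    if idx[k] < 0 or idx[k] >= n[k]:
                        raise ValueError("charge outside grid")
                out.append((idx, float(w)))
    return out


def _solve_poisson(origin: np.ndarray, n: Tuple[int, int, int], h: float,
                   eps_faces, rho: np.ndarray, phi_boundary: np.ndarray
                   ) -> np.ndarray:
    """Solve div(eps grad phi) = -4 pi k rho with Dirichlet boundary.

    ``eps_faces`` = (ex, ey, ez) face-dielectric arrays; ``rho`` is the
    node-spread charge (e); returns the potential on all nodes.
    """
    nx, ny, nz = n
    ex, ey, ez = eps_faces
    interior = np.zeros(n, dtype=bool)
    interior[1:-1, 1:-1, 1:-1] = True
    idx_map = -np.ones(n, dtype=np.int64)
    idx_map[interior] = np.arange(interior.sum())
    n_unknown = int(interior.sum())

    ii, jj, kk = np.nonzero(interior)
    center = idx_map[ii, jj, kk]
    rows, cols, vals = [], [], []
    b = 4.0 * math.pi * constants.COULOMB_CONSTANT * rho[ii, jj, kk] / h
    diag = np.zeros(n_unknown)

    neighbor_specs = [
        (ex[ii - 1, jj, kk], ii - 1, jj, kk),
        (ex[ii, jj, kk],     ii + 1, jj, kk),
        (ey[ii, jj - 1, kk], ii, jj - 1, kk),
        (ey[ii, jj, kk],     ii, jj + 1, kk),
        (ez[ii, jj, kk - 1], ii, jj, kk - 1),
        (ez[ii, jj, kk],     ii, jj, kk + 1),
    ]
    for w, ni, nj, nk in neighbor_specs:
        diag += w
        nb = idx_map[ni, nj, nk]
        is_interior = nb >= 0
        rows.append(center[is_interior])
        cols.append(nb[is_interior])
        vals.append(-w[is_interior])
        # boundary neighbours contribute to the RHS
        bmask = ~is_interior
        np.add.at(b, np.nonzero(bmask)[0],
                  w[bmask] * phi_boundary[ni[bmask], nj[bmask], nk[bmask]])

    rows.append(center)
    cols.append(center)
    vals.append(diag)
    a = coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_unknown, n_unknown)).tocsr()
    x, info = cg(a, b, rtol=1e-10, atol=0.0, maxiter=20000,
                 M=diags(1.0 / a.diagonal()),
                 x0=phi_boundary[interior].astype(float))
    if info != 0:
        raise RuntimeError(f"Poisson CG failed to converge (info={info})")
    phi = phi_boundary.copy()
    phi[interior] = x
    return phi


def _coulomb_potential_on_nodes(axes, pos: np.ndarray, q: np.ndarray,
                                eps: float) -> np.ndarray:
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    phi = np.zeros(gx.shape)
    for p, qi in zip(pos, q):
        r = np.sqrt((gx - p[0]) ** 2 + (gy - p[1]) ** 2 + (gz - p[2]) ** 2)
        r = np.maximum(r, 1e-6)
        phi += constants.COULOMB_CONSTANT * qi / (eps * r)
    return phi


def reaction_field(system: MolecularSystem, group,
                   d_in: float = constants.SIE_DIELECTRIC_IN,
                   d_solvent: float = constants.WATER_DIELECTRIC,
                   radius_scale: float = constants.SIE_RADIUS_SCALE,
                   spacing: float = 0.5,
                   margin: float = 10.0,
                   coords: np.ndarray | None = None,
                   box: Tuple[np.ndarray, float] | None = None,
                   max_nodes: int = 6_000_000) -> float:
    """Electrostatic solvation (reaction-field) energy of a group, kcal/mol.

    Two finite-difference solves on the same cubic grid — two-dielectric
    (solute ``d_in`` inside the scaled-vdW surface, ``d_solvent`` outside)
    and uniform ``d_in`` — are differenced at the charge sites, cancelling
    the grid self-energy.  ``box=(center, edge_length)`` pins the grid
    explicitly; it must enclose the solute plus ``margin`` on each side.
    """
    idx = _group_indices(system, group)
    q = _require_charges(system, idx)
    radii = system.vdw_radii[idx] * radius_scale
    if np.any(np.isnan(radii)) or np.any(radii <= 0):
        raise ValueError("all group atoms need a positive vdw_radius")
    pos = (system.coords if coords is None else np.asarray(coords, float))[idx]

    lo_need = pos.min(axis=0) - margin
    hi_need = pos.max(axis=0) + margin
    if box is None:
        lo, hi = lo_need, hi_need
    else:
        center, edge = np.asarray(box[0], float), float(box[1])
        lo = center - edge / 2.0
        hi = center + edge / 2.0
        if np.any(lo > lo_need) or np.any(hi < hi_need):
            raise ValueError(
                "grid box too small to enclose solute plus margin")
    h = float(spacing)
    n = tuple(int(math.ceil((hi[k] - lo[k]) / h)) + 1 for k in range(3))
    if n[0] * n[1] * n[2] > max_nodes:
        raise ValueError(
            f"grid of {n} nodes exceeds max_nodes={max_nodes}; "
            "increase spacing or shrink the margin")
    origin = lo
    axes = _grid_axes(origin, n, h)

    if np.allclose(q, 0.0):
        return 0.0

    # face midpoints per orientation
    def face_mid(axis: int) -> np.ndarray:
        a = [ax.copy() for ax in axes]
        a[axis] = a[axis][:-1] + h / 2.0
        gx, gy, gz = np.meshgrid(*a, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    eps_faces = tuple(
        _face_dielectric(face_mid(axis), pos, radii, h, d_in, d_solvent)
        for axis in range(3))
    eps_uniform = tuple(np.full_like(e, d_in) for e in eps_faces)

    rho = np.zeros(n)
    spreads = []
    for p, qi in zip(pos, q):
        w = _trilinear_weights(origin, h, n, p)
        spreads.append(w)
        for (i, j, k), wt in w:
            rho[i, j, k] += qi * wt

    phi_b_solv = _coulomb_potential_on_nodes(axes, pos, q, d_solvent)
    phi_b_ref = _coulomb_potential_on_nodes(axes, pos, q, d_in)
    phi_solv = _solve_poisson(origin, n, h, eps_faces, rho, phi_b_solv)
    phi_ref = _solve_poisson(origin, n, h, eps_uniform, rho, phi_b_ref)
    dphi = phi_solv - phi_ref

    energy = 0.0
    for w, qi in zip(spreads, q):
        val = sum(wt * dphi[i, j, k] for (i, j, k), wt in w)
        energy += 0.5 * qi * val
    return float(energy)


def delta_reaction_field(system: MolecularSystem,
                         protein_group="protein", ligand_group="ligand",
                         coords: np.ndarray | None = None,
                         **kwargs) -> float:
    """Reaction-field change on binding:
    ``RF(complex) - RF(protein) - RF(ligand)``, kcal/mol.

    For a charged ligand binding into a pocket this is positive (the
    desolvation penalty).
    """
    ip = _group_indices(system, protein_group)
    il = _group_indices(system, ligand_group)
    both = np.concatenate([ip, il])
    return (reaction_field(system, both, coords=coords, **kwargs)
            - reaction_field(system, ip, coords=coords, **kwargs)
            - reaction_field(system, il, coords=coords, **kwargs))


# ---------------------------------------------------------------------------
# Combination, snapshot statistics, experiment conversion
# ---------------------------------------------------------------------------

def sie_combine(components, coefficients: SIECoefficients = SIECoefficients()
                ) -> float:
    """The calibrated linear combination giving dG_bind (kcal/mol).

    ``components`` may be an :class:`EnergyComponents` or any mapping with
    keys ``e_coulomb, e_vdw, g_reaction, gamma_msa_term`` (the last already
    multiplied by gamma).
    """
    if isinstance(components, EnergyComponents):
        terms = (components.e_coulomb, components.e_vdw,
                 components.g_reaction, components.gamma_msa_term)
    else:
        terms = (components["e_coulomb"], components["e_vdw"],
                 components["g_reaction"], components["gamma_msa_term"])
    if not all(math.isfinite(t) for t in terms):
        raise ValueError("all components must be finite")
    return coefficients.alpha_global * sum(terms) + coefficients.c_const


def sie_snapshot(system: MolecularSystem, coords: np.ndarray,
                 coefficients: SIECoefficients = SIECoefficients(),
                 protein_group="protein", ligand_group="ligand",
                 probe_radius: float = constants.PROBE_RADIUS,
                 sasa_points: int = 960,
                 rf_spacing: float = 0.5, rf_margin: float = 10.0) -> dict:
    """All SIE terms for one coordinate frame."""
    e_c = coulomb_energy(system, protein_group, ligand_group,
                         dielectric=1.0, coords=coords)
    e_vdw = lj_energy(system, protein_group, ligand_group, coords=coords)
    _, gamma_term = delta_msa(system, protein_group, ligand_group,
                              gamma=coefficients.gamma_msa,
                              radius_scale=coefficients.rho_radii,
                              probe_radius=probe_radius,
                              n_points=sasa_points, coords=coords)
    g_r = delta_reaction_field(system, protein_group, ligand_group,
                               coords=coords, d_in=coefficients.d_in,
                               radius_scale=coefficients.rho_radii,
                               spacing=rf_spacing, margin=rf_margin)
    comp = {"e_coulomb": e_c, "e_vdw": e_vdw, "g_reaction": g_r,
            "gamma_msa_term": gamma_term}
    comp["dg_bind"] = sie_combine(comp, coefficients)
    return comp


def _mean_sem(x: np.ndarray) -> Tuple[float, float]:
    x = np.asarray(x, dtype=float)
    mean = float(x.mean())
    if x.size < 2:
        return mean, 0.0
    return mean, float(x.std(ddof=1) / math.sqrt(x.size))


def sie_trajectory(traj: Trajectory, system: MolecularSystem,
                   coefficients: SIECoefficients = SIECoefficients(),
                   snapshot_stride: int = 1,
                   **snapshot_kwargs) -> EnergyComponents:
    """Evaluate every SIE term on strided snapshots; mean +/- standard error.

    ``dg_bind`` is recomputed from the component means (identical to the mean
    of per-snapshot dG because the combination is linear).
    """
    if snapshot_stride < 1:
        raise ValueError("snapshot_stride must be >= 1")
    frames = traj.frames[::snapshot_stride]
    per_term = {k: [] for k in
                ("e_coulomb", "e_vdw", "g_reaction", "gamma_msa_term", "dg_bind")}
    for coords in frames:
        comp = sie_snapshot(system, coords, coefficients, **snapshot_kwargs)
        for k in per_term:
            per_term[k].append(comp[k])
    stats = {k: _mean_sem(np.array(v)) for k, v in per_term.items()}
    means = {k: stats[k][0] for k in per_term}
    out = EnergyComponents(
        e_coulomb=means["e_coulomb"], e_vdw=means["e_vdw"],
        g_reaction=means["g_reaction"], gamma_msa_term=means["gamma_msa_term"],
        dg_bind=sie_combine(means, coefficients),
        e_coulomb_sem=stats["e_coulomb"][1], e_vdw_sem=stats["e_vdw"][1],
        g_reaction_sem=stats["g_reaction"][1],
        gamma_msa_term_sem=stats["gamma_msa_term"][1],
        dg_bind_sem=stats["dg_bind"][1],
        n_snapshots=len(frames),
    )
    out.validate(coefficients)
    return out


def ic50_to_dg(ic50: float, temperature: float = 300.0) -> float:
    """Binding free energy estimated from an IC50 (molar), kcal/mol.

    ``dG = R*T*ln(IC50)``: sub-molar IC50 gives a negative (favourable)
    binding free energy, e.g. 1 uM at 300 K -> -8.24 kcal/mol.
    """
    if ic50 <= 0:
        raise ValueError("IC50 must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return constants.GAS_CONSTANT * temperature * math.log(ic50)
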