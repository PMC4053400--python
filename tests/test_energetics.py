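import math

import numpy as np
import pytest

from siescan import constants
from siescan.energetics import (
    EnergyComponents,
    SIECoefficients,
    coulomb_energy,
    delta_msa,
    delta_reaction_field,
    ic50_to_dg,
    lj_energy,
    reaction_field,
    sasa,
    sie_combine,
    sie_trajectory,
)
from siescan.structure_io import AtomRecord, MolecularSystem, Trajectory

from conftest import naive_coulomb, naive_lj, two_sphere_union_area


def make_system(specs):
    """specs: list of (coords, charge, rmin_half, eps, vdw, hetero)."""
    atoms = []
    for i, (xyz, q, rh, eps, vdw, het) in enumerate(specs):
        atoms.append(AtomRecord(
            serial=i + 1, name=f"X{i+1}", element="C",
            res_name="LIG" if het else "PRT", res_id=2 if het else 1,
            chain="A", coords=np.asarray(xyz, float), charge=q,
            lj_rmin_half=rh, lj_epsilon=eps, vdw_radius=vdw, hetero=het))
    return MolecularSystem(atoms)


def random_two_group_system(rng, n=8, spread=6.0):
    specs = []
    while True:
        pts = rng.uniform(-spread, spread, size=(n, 3))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        np.fill_diagonal(d, np.inf)
        if d.min() > 1.0:
            break
    for i in range(n):
        specs.append((pts[i], rng.uniform(-1, 1), rng.uniform(1.2, 2.0),
                      rng.uniform(0.05, 0.3), 1.7, i >= n // 2))
    return make_system(specs)


class TestCoulomb:
    def test_hand_evaluated_pair(self):
        system = make_system([
            ((0, 0, 0), 1.0, 1.9, 0.1, 1.9, False),
            ((3.32, 0, 0), -1.0, 1.9, 0.1, 1.9, True),
        ])
        e = coulomb_energy(system, "protein", "ligand", dielectric=1.0)
        assert e == pytest.approx(-constants.COULOMB_CONSTANT / 3.32, abs=1e-9)
        assert e == pytest.approx(-100.02, abs=0.01)

    def test_zero_ligand_charges(self):
        system = make_system([
            ((0, 0, 0), 0.7, 1.9, 0.1, 1.9, False),
            ((4, 0, 0), 0.0, 1.9, 0.1, 1.9, True),
            ((0, 4, 0), 0.0, 1.9, 0.1, 1.9, True),
        ])
        assert coulomb_energy(system, "protein", "ligand") == 0.0

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(10)
        system = random_two_group_system(rng)
        ia, ib = system.select("protein"), system.select("ligand")
        got = coulomb_energy(system, "protein", "ligand", dielectric=2.0)
        want = naive_coulomb(system, ia, ib, dielectric=2.0)
        assert got == pytest.approx(want, abs=1e-10)

    def test_overlap_names_pair(self):
        system = make_system([
            ((0, 0, 0), 1.0, 1.9, 0.1, 1.9, False),
            ((0.05, 0, 0), -1.0, 1.9, 0.1, 1.9, True),
        ])
        with pytest.raises(ValueError, match="overlap"):
            coulomb_energy(system, "protein", "ligand")


class TestLennardJones:
    def test_minimum_at_rmin(self):
        rh_a, rh_b, eps_a, eps_b = 1.8, 1.6, 0.2, 0.05
        system = make_system([
            ((0, 0, 0), 0.0, rh_a, eps_a, 1.8, False),
            ((rh_a + rh_b, 0, 0), 0.0, rh_b, eps_b, 1.6, True),
        ])
        e = lj_energy(system, "protein", "ligand")
        assert e == pytest.approx(-math.sqrt(eps_a * eps_b), abs=1e-12)

    def test_vanishes_at_long_range(self):
        system = make_system([
            ((0, 0, 0), 0.0, 1.9, 0.2, 1.9, False),
            ((1e4, 0, 0), 0.0, 1.9, 0.2, 1.9, True),
        ])
        assert abs(lj_energy(system, "protein", "ligand")) < 1e-12

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(11)
        system = random_two_group_system(rng)
        ia, ib = system.select("protein"), system.select("ligand")
        got = lj_energy(system, "protein", "ligand")
        want = naive_lj(system, ia, ib)
        assert got == pytest.approx(want, abs=1e-10)


class TestSasa:
    def single_atom(self, r):
        return make_system([((0, 0, 0), 0.0, r, 0.1, r, False)])

    def test_single_sphere_analytic(self):
        for r in (1.2, 1.7, 2.4):
            system = self.single_atom(r)
            scale, probe = 1.1, 1.4
            got = sasa(system, "protein", probe_radius=probe,
                       radius_scale=scale)
            want = 4.0 * math.pi * (r * scale + probe) ** 2
            assert got == pytest.approx(want, rel=0.005)

    def test_distant_atoms_additive(self):
        system = make_system([
            ((0, 0, 0), 0.0, 1.7, 0.1, 1.7, False),
            ((100, 0, 0), 0.0, 1.4, 0.1, 1.4, False),
        ])
        got = sasa(system, "protein", probe_radius=1.4)
        want = 4 * math.pi * ((1.7 + 1.4) ** 2 + (1.4 + 1.4) ** 2)
        assert got == pytest.approx(want, rel=0.005)

    def test_two_sphere_lens_analytic(self):
        r1, r2, probe = 1.9, 1.6, 1.4
        d = 2.8
        system = make_system([
            ((0, 0, 0), 0.0, r1, 0.1, r1, False),
            ((d, 0, 0), 0.0, r2, 0.1, r2, False),
        ])
        got = sasa(system, "protein", probe_radius=probe, n_points=2000)
        want = two_sphere_union_area(r1 + probe, r2 + probe, d)
        assert got == pytest.approx(want, rel=0.01)

    def test_nonpositive_radius_rejected(self):
        system = self.single_atom(1.7)
        object.__setattr__  # no-op; AtomRecord is mutable
        system.atoms[0].vdw_radius = -1.0
        with pytest.raises(ValueError, match="radius"):
            sasa(system, "protein")


class TestDeltaMsa:
    def test_far_ligand_near_zero(self):
        system = make_system([
            ((0, 0, 0), 0.0, 1.9, 0.1, 1.9, False),
            ((100, 0, 0), 0.0, 1.9, 0.1, 1.9, True),
        ])
        dmsa, term = delta_msa(system)
        assert abs(dmsa) < 1.0     # quadrature noise only
        assert abs(term) < 0.05

    def test_docked_pose_buries_surface(self, toy_system):
        dmsa, term = delta_msa(toy_system)
        assert dmsa < 0
        assert term < 0            # gamma > 0: matches the bound-state sign


class TestReactionField:
    def born_system(self, radius, q=1.0):
        return make_system([((0, 0, 0), q, radius, 0.1, radius, True)])

    def born_exact(self, radius, q, d_in, d_out):
        return (-constants.COULOMB_CONSTANT / 2.0 * q * q / radius
                * (1.0 / d_in - 1.0 / d_out))

    def test_born_ion_radius_sweep(self):
        d_in, d_out = 2.25, 78.4
        for radius in (1.5, 2.0, 3.0, 4.0):
            system = self.born_system(radius)
            got = reaction_field(system, "ligand", d_in=d_in,
                                 d_solvent=d_out, radius_scale=1.0,
                                 spacing=0.4, margin=8.0)
            want = self.born_exact(radius, 1.0, d_in, d_out)
            assert got == pytest.approx(want, rel=0.03)

    def test_zero_charges_zero_energy(self):
        system = self.born_system(2.0, q=0.0)
        assert reaction_field(system, "ligand", spacing=0.5, margin=6.0) == 0.0

    def test_grid_halving_converges(self, toy_system):
        coarse = delta_reaction_field(toy_system, spacing=1.2, margin=6.0)
        fine = delta_reaction_field(toy_system, spacing=0.6, margin=6.0)
        assert fine == pytest.approx(coarse, rel=0.02)

    def test_positive_for_bound_toy_complex(self, toy_system):
        rf = delta_reaction_field(toy_system, spacing=0.8, margin=6.0)
        assert rf > 0              # desolvation penalty

    def test_box_too_small_rejected(self):
        system = self.born_system(2.0)
        with pytest.raises(ValueError, match="too small"):
            reaction_field(system, "ligand", margin=10.0,
                           box=(np.zeros(3), 10.0))


class TestSieCombine:
    def test_zero_components_give_constant(self):
        coeffs = SIECoefficients()
        zero = dict(e_coulomb=0.0, e_vdw=0.0, g_reaction=0.0,
                    gamma_msa_term=0.0)
        assert sie_combine(zero, coeffs) == pytest.approx(coeffs.c_const)

    def test_reproduces_published_8ca_binding_energy(self):
        comp = dict(e_coulomb=-57.40, e_vdw=-33.35, g_reaction=43.81,
                    gamma_msa_term=-7.55)
        assert sie_combine(comp) == pytest.approx(-8.63, abs=0.05)

    def test_linearity(self):
        rng = np.random.default_rng(12)
        coeffs = SIECoefficients()
        comp = dict(zip(
            ("e_coulomb", "e_vdw", "g_reaction", "gamma_msa_term"),
            rng.normal(size=4) * 20))
        one = sie_combine(comp, coeffs) - coeffs.c_const
        doubled = {k: 2 * v for k, v in comp.items()}
        two = sie_combine(doubled, coeffs) - coeffs.c_const
        assert two == pytest.approx(2 * one, abs=1e-12)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError, match="finite"):
            sie_combine(dict(e_coulomb=math.nan, e_vdw=0.0,
                             g_reaction=0.0, gamma_msa_term=0.0))

    def test_invalid_coefficients(self):
        with pytest.raises(ValueError):
            SIECoefficients(d_in=0.5)
        with pytest.raises(ValueError):
            SIECoefficients(rho_radii=-1.0)


FAST_SIE = dict(rf_spacing=0.8, rf_margin=5.0, sasa_points=120)


class TestSieTrajectory:
    def test_single_frame_sem_zero(self, tiny_complex):
        traj = Trajectory(tiny_complex.coords[None])
        comp = sie_trajectory(traj, tiny_complex, **FAST_SIE)
        assert comp.n_snapshots == 1
        assert comp.e_coulomb_sem == 0.0
        assert comp.dg_bind_sem == 0.0
        comp.validate(SIECoefficients())

    def test_duplicated_frames_sem_zero_mean_unchanged(self, tiny_complex):
        one = Trajectory(tiny_complex.coords[None])
        many = Trajectory(np.repeat(tiny_complex.coords[None], 200, axis=0))
        a = sie_trajectory(one, tiny_complex, **FAST_SIE)
        b = sie_trajectory(many, tiny_complex, **FAST_SIE)
        assert b.n_snapshots == 200
        assert b.e_coulomb == pytest.approx(a.e_coulomb, abs=1e-12)
        assert b.dg_bind == pytest.approx(a.dg_bind, abs=1e-12)
        assert b.g_reaction_sem == pytest.approx(0.0, abs=1e-9)

    def test_statistics_match_oracle_loop(self, tiny_complex):
        rng = np.random.default_rng(13)
        frames = tiny_complex.coords[None] + \
            rng.normal(scale=0.05, size=(5, 4, 3))
        traj = Trajectory(frames)
        comp = sie_trajectory(traj, tiny_complex, **FAST_SIE)
        per_frame = [naive_coulomb(tiny_complex,
                                   tiny_complex.select("protein"),
                                   tiny_complex.select("ligand"),
                                   coords=f) for f in frames]
        assert comp.e_coulomb == pytest.approx(np.mean(per_frame), abs=1e-10)
        want_sem = np.std(per_frame, ddof=1) / math.sqrt(5)
        assert comp.e_coulomb_sem == pytest.approx(want_sem, abs=1e-10)

    def test_snapshot_stride(self, tiny_complex):
        frames = np.repeat(tiny_complex.coords[None], 6, axis=0)
        comp = sie_trajectory(Trajectory(frames), tiny_complex,
                              snapshot_stride=2, **FAST_SIE)
        assert comp.n_snapshots == 3


class TestEnergyComponents:
    def test_validate_consistency(self):
        coeffs = SIECoefficients()
        means = dict(e_coulomb=-50.0, e_vdw=-30.0, g_reaction=40.0,
                     gamma_msa_term=-7.0)
        comp = EnergyComponents(**means, dg_bind=sie_combine(means, coeffs))
        comp.validate(coeffs)
        bad = EnergyComponents(**means, dg_bind=0.0)
        with pytest.raises(ValueError, match="inconsistent"):
            bad.validate(coeffs)

    def test_requires_snapshots(self):
        with pytest.raises(ValueError, match="n_snapshots"):
            EnergyComponents(0, 0, 0, 0, 0, n_snapshots=0)


class TestIc50:
    def test_one_molar_is_zero(self):
        assert ic50_to_dg(1.0, 300.0) == 0.0

    def test_micromolar_hand_value(self):
        got = ic50_to_dg(1e-6, 300.0)
        want = 1.9872e-3 * 300.0 * math.log(1e-6)
        assert got == pytest.approx(want, abs=1e-12)
        assert got == pytest.approx(-8.236, abs=1e-3)

    def test_monotonic(self):
        assert ic50_to_dg(1e-9) < ic50_to_dg(1e-6) < ic50_to_dg(1e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ic50_to_dg(0.0)
        with pytest.raises(ValueError):
            ic50_to_dg(1e-6, temperature=-1.0)
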