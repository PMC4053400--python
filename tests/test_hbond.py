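import math

import numpy as np
import pytest

from siescan import constants
from siescan.data import HBOND_ENERGIES, POLAR_INTERACTIONS, data_path
from siescan.hbond import (
    ContactProfile,
    HBondEnergyModel,
    HBondSeries,
    MissingHydrogensError,
    PolarInteractionModel,
    complex_hbond_total,
    detect_hbonds,
    distance_distribution,
    hbond_energy,
    hbond_energy_mean,
    hydrophobic_contacts,
    polar_total,
    residue_polar_energy,
)
from siescan.report import read_bond_table, read_residue_table
from siescan.structure_io import Trajectory
from siescan.synth import SyntheticSpec, build_toy_complex, \
    planted_hbond_trajectory


class TestHBondEnergyModel:
    def test_matches_independent_oracle_at_2A(self):
        # one-line transcription of the calibrated 12-10 form
        d = 2.0
        want = 5.571 / d ** 12 - 668.580 / d ** 10
        assert hbond_energy(d) == pytest.approx(want, abs=1e-10)

    def test_magnitude_decays_beyond_optimum(self):
        model = HBondEnergyModel()
        for d in (1.5, 1.8, 2.2, 3.0, 5.0):
            assert abs(model.energy(d + 2.0)) < abs(model.energy(d))

    def test_favourable_at_typical_distances(self):
        for d in (1.7, 1.8, 2.0, 2.6):
            assert hbond_energy(d) < 0

    def test_rejects_nonpositive_distance(self):
        with pytest.raises(ValueError):
            hbond_energy(0.0)

    def test_mean_and_sd(self):
        model = HBondEnergyModel()
        const = np.full(10, 1.9)
        mean, sd = hbond_energy_mean(const, model)
        assert sd == 0.0
        assert mean == pytest.approx(model.energy(1.9))
        rng = np.random.default_rng(0)
        d = rng.normal(2.0, 0.1, size=500)
        mean, sd = hbond_energy_mean(d, model)
        e = model.energy(d)
        assert mean == pytest.approx(e.mean(), abs=1e-12)
        assert sd == pytest.approx(e.std(ddof=1), abs=1e-12)


class TestDielectric:
    def test_monotone_and_approaches_bulk(self):
        model = PolarInteractionModel()
        r = np.linspace(0.1, 50.0, 2000)
        eps = model.dielectric(r)
        assert np.all(np.diff(eps) >= -1e-12)
        assert eps[-1] == pytest.approx(constants.WATER_DIELECTRIC, abs=0.5)
        assert eps[0] < 2.0

    def test_scale_must_be_positive(self):
        with pytest.raises(ValueError):
            PolarInteractionModel(scale=0.0)


class TestDetect:
    def test_planted_bond_full_occupancy(self, toy_system):
        spec = SyntheticSpec(n_frames=25, seed=1,
                             hbond_peaks=[(1.8, 0.0, 1.0)])
        traj = planted_hbond_trajectory(toy_system, spec)
        bonds = detect_hbonds(traj, toy_system)
        planted = [b for b in bonds if "HH21" in b.label]
        assert len(planted) == 1
        assert planted[0].occupancy == 1.0
        np.testing.assert_allclose(planted[0].distances, 1.8, atol=1e-9)

    def test_long_distance_not_detected(self, toy_system):
        spec = SyntheticSpec(n_frames=10, seed=2,
                             hbond_peaks=[(5.5, 0.0, 1.0)])
        traj = planted_hbond_trajectory(toy_system, spec)
        bonds = detect_hbonds(traj, toy_system)
        assert not any("HH21" in b.label for b in bonds)

    def test_occupancy_threshold(self, toy_system):
        # 60% of frames bonded at 1.8 A, 40% far away
        spec_near = SyntheticSpec(n_frames=60, seed=3,
                                  hbond_peaks=[(1.8, 0.0, 1.0)])
        spec_far = SyntheticSpec(n_frames=40, seed=4,
                                 hbond_peaks=[(8.0, 0.0, 1.0)])
        near = planted_hbond_trajectory(toy_system, spec_near)
        far = planted_hbond_trajectory(toy_system, spec_far)
        traj = Trajectory(np.concatenate([near.frames, far.frames]))
        at_50 = detect_hbonds(traj, toy_system, occupancy_min=0.5)
        at_70 = detect_hbonds(traj, toy_system, occupancy_min=0.7)
        assert any("HH21" in b.label for b in at_50)
        assert not any("HH21" in b.label for b in at_70)
        planted = next(b for b in at_50 if "HH21" in b.label)
        assert planted.occupancy == pytest.approx(0.6)

    def test_refuses_structures_without_hydrogens(self, toy_system):
        heavy = toy_system.subset(
            [i for i, a in enumerate(toy_system.atoms) if a.element != "H"])
        traj = Trajectory(heavy.coords[None])
        with pytest.raises(MissingHydrogensError, match="hydrogen"):
            detect_hbonds(traj, heavy)


class TestDistribution:
    def test_identical_distances_single_bin(self):
        dist = distance_distribution(np.full(50, 1.8), bin_width=0.05)
        assert dist.frequencies.max() == pytest.approx(1.0)
        assert (dist.frequencies > 0).sum() == 1
        assert dist.peak == pytest.approx(1.8, abs=0.05)

    def test_gaussian_peak_recovered(self):
        rng = np.random.default_rng(5)
        d = rng.normal(1.81, 0.1, size=20_000)
        dist = distance_distribution(d, bin_width=0.05)
        assert abs(dist.peak - 1.81) <= dist.bin_width

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            d = rng.uniform(1.0, 4.0, size=rng.integers(3, 500))
            dist = distance_distribution(d)
            assert dist.frequencies.sum() == pytest.approx(1.0, abs=1e-12)

    def test_rejects_empty_and_bad_width(self):
        with pytest.raises(ValueError):
            distance_distribution(np.array([]))
        with pytest.raises(ValueError):
            distance_distribution(np.array([1.8]), bin_width=0.0)


class TestTotals:
    def test_published_8ca_total(self):
        assert complex_hbond_total([-0.76, -2.50, -1.81, -0.69]) == \
            pytest.approx(-5.76, abs=1e-12)

    def test_published_totals_from_bundled_table(self):
        df = read_bond_table(data_path(HBOND_ENERGIES))
        totals = df.groupby("complex", sort=False)["mean"].agg(
            lambda x: complex_hbond_total(list(x)))
        assert totals["8CA"] == pytest.approx(-5.76, abs=1e-9)
        assert totals["F8A"] == pytest.approx(-5.45, abs=1e-9)
        assert totals["I4A"] == pytest.approx(-6.80, abs=1e-9)

    def test_empty_list_zero(self):
        assert complex_hbond_total([]) == 0.0
        assert polar_total([]) == 0.0

    def test_published_polar_totals(self):
        df = read_residue_table(data_path(POLAR_INTERACTIONS))
        totals = df.groupby("complex", sort=False)["wild_mean"].agg(
            lambda x: polar_total(list(x)))
        assert totals["I4A"] == pytest.approx(-41.25, abs=1e-9)
        assert totals["8CA"] == pytest.approx(-38.10, abs=1e-9)
        assert totals["F8A"] == pytest.approx(-34.10, abs=1e-9)
        # shift of the charged-residue total relative to the parent compound
        assert totals["8CA"] - totals["F8A"] == pytest.approx(-4.00, abs=1e-9)


class TestResiduePolar:
    def test_neutral_residue_exactly_zero(self, toy_system):
        # alanine 1 carries partial charges; zero them for this check
        import copy
        system = copy.deepcopy(toy_system)
        for i in system.residue_indices(1):
            system.atoms[i].charge = 0.0
        e, sem = residue_polar_energy(system.coords, system, 1)
        assert e == 0.0 and sem == 0.0

    def test_single_pair_matches_independent_script(self, tiny_complex):
        # independent evaluation of the screened pair energy
        model = PolarInteractionModel()
        e, _ = residue_polar_energy(tiny_complex.coords, tiny_complex, 1)
        want = 0.0
        for i in tiny_complex.select("protein"):
            for j in tiny_complex.select("ligand"):
                r = float(np.linalg.norm(
                    tiny_complex.coords[i] - tiny_complex.coords[j]))
                b = 78.4 - (-8.5525)
                eps = -8.5525 + b / (1 + 7.7839 * math.exp(-0.003627 * b * r))
                want += (1.558 * 332.0637 * tiny_complex.charges[i]
                         * tiny_complex.charges[j] / (eps * r))
        assert e == pytest.approx(want, abs=1e-10)

    def test_oppositely_charged_pair_favourable(self, toy_system):
        # arginine (+1) against the carboxylate ligand (-1)
        e, _ = residue_polar_energy(toy_system.coords, toy_system, 4)
        assert e < 0

    def test_missing_residue_rejected(self, toy_system):
        from siescan.structure_io import SelectionError
        with pytest.raises(SelectionError):
            residue_polar_energy(toy_system.coords, toy_system, 99)

    def test_trajectory_statistics(self, toy_system):
        spec = SyntheticSpec(n_frames=30, seed=7)
        traj = planted_hbond_trajectory(toy_system, spec)
        mean, sem = residue_polar_energy(traj, toy_system, 4)
        per_frame = [residue_polar_energy(traj.frames[f], toy_system, 4)[0]
                     for f in range(30)]
        assert mean == pytest.approx(np.mean(per_frame), abs=1e-10)
        assert sem == pytest.approx(
            np.std(per_frame, ddof=1) / math.sqrt(30), abs=1e-10)


class TestHydrophobic:
    def test_far_ligand_no_contacts(self, toy_system):
        far = toy_system.coords.copy()
        far[toy_system.select("ligand")] += 100.0
        profile = hydrophobic_contacts(Trajectory(far[None]), toy_system)
        assert not profile.frame_table.to_numpy().any()

    def test_planted_contact_occupancy(self, toy_system):
        # methyl-methyl pair at 3.5 A in 80% of frames
        near = toy_system.coords
        far = near.copy()
        far[toy_system.select("ligand")] += 100.0
        frames = np.array([near] * 8 + [far] * 2)
        profile = hydrophobic_contacts(Trajectory(frames), toy_system)
        assert profile.occupancy["A:LEU3"] == pytest.approx(0.8)

    def test_occupancy_bounded(self, toy_system):
        spec = SyntheticSpec(n_frames=15, seed=8)
        traj = planted_hbond_trajectory(toy_system, spec)
        occ = hydrophobic_contacts(traj, toy_system).occupancy
        assert ((occ >= 0) & (occ <= 1)).all()
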