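"""Trajectory observable tests: distances, H-bonds, order, tilt, energies."""

import numpy as np
import pytest

from conftest import make_topology, make_trajectory
from memtool.synthetic import gen_bilayer_trajectory
from memtool.trajectory import (
    Trajectory,
    hbond_time_fractions,
    pairwise_interaction_energy,
    scd_profile,
    tilt_distribution,
    z_distance_distribution,
)


def two_particle_topology():
    return make_topology(
        [
            ("P1", "PRB", 1, "probe", 0.0, 3.0, 0.1, 10.0, -1),
            ("R1", "REF", 2, "ref", 0.0, 3.0, 0.1, 10.0, -1),
        ],
        selections={"probe": [0], "ref": [1]},
    )


class TestZDistanceDistribution:
    def test_fixed_offset_concentrates_in_one_bin(self):
        topo = two_particle_topology()
        coords = np.zeros((20, 2, 3))
        coords[:, 0, 2] = 10.0
        dist = z_distance_distribution(
            make_trajectory(coords), topo, "probe", "ref", bin_width=1.0
        )
        centers = 0.5 * (dist.bin_edges[:-1] + dist.bin_edges[1:])
        assert dist.density[np.argmax(dist.density)] == pytest.approx(1.0)
        assert centers[np.argmax(dist.density)] == pytest.approx(10.0, abs=0.5)

    def test_uniform_probe_gives_flat_density(self):
        topo = two_particle_topology()
        rng = np.random.default_rng(0)
        n = 10_000
        coords = np.zeros((n, 2, 3))
        coords[:, 0, 2] = rng.uniform(0.0, 20.0, n)
        dist = z_distance_distribution(
            make_trajectory(coords), topo, "probe", "ref", bin_width=2.0
        )
        inner = (dist.bin_edges[:-1] >= 0) & (dist.bin_edges[1:] <= 20)
        assert np.allclose(dist.density[inner], 0.05, atol=0.01)

    def test_z_reflection_negates_mean(self):
        topo = two_particle_topology()
        rng = np.random.default_rng(1)
        coords = np.zeros((200, 2, 3))
        coords[:, 0, 2] = rng.normal(8.0, 1.0, 200)
        traj = make_trajectory(coords)
        flipped = make_trajectory(-coords)
        d1 = z_distance_distribution(traj, topo, "probe", "ref")
        d2 = z_distance_distribution(flipped, topo, "probe", "ref")
        assert d2.mean == pytest.approx(-d1.mean, rel=1e-9)

    def test_density_normalized(self):
        traj, topo, _ = gen_bilayer_trajectory(seed=2, n_frames=30)
        dist = z_distance_distribution(traj, topo, "probe_ring", "lipids")
        assert np.sum(dist.density * np.diff(dist.bin_edges)) == pytest.approx(1.0, abs=1e-9)

    def test_empty_selection_rejected(self):
        topo = two_particle_topology()
        with pytest.raises((ValueError, KeyError)):
            z_distance_distribution(
                make_trajectory(np.zeros((2, 2, 3))), topo, "nonexistent", "ref"
            )


class TestHbondTimeFractions:
    def _coords(self, n_frames, second_acceptor_on_even_frames):
        # donor O at origin, H on +x; acceptors placed on/off the criteria
        coords = np.zeros((n_frames, 4, 3))
        coords[:, 1, 0] = 0.96
        coords[:, 2, 0] = 2.8  # acceptor 1 always bonded
        for f in range(n_frames):
            on = second_acceptor_on_even_frames and f % 2 == 0
            coords[f, 3] = [2.8 * np.cos(0.35), 2.8 * np.sin(0.35), 0.0] if on else [6.0, 2.0, 0.0]
        return coords

    def test_full_time_plus_half_time_bond_gives_three_halves(self, oh_probe_topology):
        traj = make_trajectory(self._coords(50, True))
        report = hbond_time_fractions(traj, oh_probe_topology, "donors", "acceptors")
        assert report.fractions["OH"] == pytest.approx(1.5)
        assert report.fractions["A1"] == pytest.approx(1.0)
        assert report.fractions["A2"] == pytest.approx(0.5)

    def test_persistent_single_bond_is_one(self, oh_probe_topology):
        traj = make_trajectory(self._coords(50, False))
        report = hbond_time_fractions(traj, oh_probe_topology, "donors", "acceptors")
        assert report.fractions["OH"] == pytest.approx(1.0)

    def test_just_beyond_cutoff_is_zero(self, oh_probe_topology):
        coords = np.zeros((10, 4, 3))
        coords[:, 1, 0] = 0.96
        coords[:, 2, 0] = 3.6  # d_max + 0.1
        coords[:, 3, 0] = 3.6
        report = hbond_time_fractions(
            make_trajectory(coords), oh_probe_topology, "donors", "acceptors"
        )
        assert report.fractions == {}

    def test_bent_geometry_fails_angle_criterion(self, oh_probe_topology):
        coords = np.zeros((5, 4, 3))
        coords[:, 1, 0] = 0.96
        coords[:, 2, 1] = 2.0  # acceptor perpendicular: D-H...A angle ~ 64 deg
        coords[:, 3, 0] = 6.0
        report = hbond_time_fractions(
            make_trajectory(coords), oh_probe_topology, "donors", "acceptors"
        )
        assert report.fractions == {}

    def test_donor_without_hydrogen_rejected(self):
        topo = make_topology(
            [
                ("O1", "DOX", 1, "OH", -0.6, 3.0, 0.1, 16.0, -1),
                ("OA1", "ACP", 2, "A1", -0.5, 3.0, 0.1, 16.0, -1),
            ],
            selections={"donors": [0], "acceptors": [1]},
        )
        with pytest.raises(ValueError, match="no bonded hydrogen"):
            hbond_time_fractions(make_trajectory(np.zeros((2, 2, 3))), topo, "donors", "acceptors")

    def test_generator_schedule_reproduced(self):
        traj, topo, truth = gen_bilayer_trajectory(seed=8, n_frames=40)
        report = hbond_time_fractions(traj, topo, "donors", "acceptors")
        for group, expected in truth["expected_hbond_fractions"].items():
            assert report.fractions[group] == pytest.approx(expected)


def chain_topology(n_carbons=4):
    rows = []
    for k in range(n_carbons):
        rows.append((f"C{k + 1}", "LIP", 1, "tail", -0.1, 3.4, 0.1, 12.011, -1))
    for k in range(n_carbons):
        rows.append((f"H{k + 1}A", "LIP", 1, "tail", 0.05, 2.65, 0.016, 1.008, k))
        rows.append((f"H{k + 1}B", "LIP", 1, "tail", 0.05, 2.65, 0.016, 1.008, k))
    return make_topology(rows, selections={"chains": list(range(3 * n_carbons))})


class TestScdProfile:
    def test_aligned_all_trans_chain_is_minus_half(self):
        traj, topo, _ = gen_bilayer_trajectory(seed=0, tilt_mean=0.0, tilt_sd=0.0, n_frames=3)
        prof = scd_profile(traj, topo, "chains")
        assert np.allclose(prof.scd, -0.5, atol=1e-12)

    def test_isotropic_ch_vectors_average_to_zero(self):
        # Monte-Carlo: one carbon with two H in random directions per frame
        topo = chain_topology(n_carbons=1)
        rng = np.random.default_rng(123)
        n = 50_000
        v = rng.normal(size=(n, 2, 3))
        v /= np.linalg.norm(v, axis=2, keepdims=True)
        coords = np.zeros((n, 3, 3))
        coords[:, 1:, :] = 1.09 * v
        prof = scd_profile(make_trajectory(coords), topo, "chains")
        assert prof.scd[0] == pytest.approx(0.0, abs=0.01)

    @pytest.mark.parametrize("alpha", [30.0, 60.0, 90.0])
    def test_tilted_chain_matches_closed_form(self, alpha):
        traj, topo, _ = gen_bilayer_trajectory(
            seed=13,
            tilt_mean=alpha,
            tilt_sd=0.0,
            n_frames=2000,
            n_lipids_per_leaflet=4,
            lattice_spacing=25.0,
        )
        prof = scd_profile(traj, topo, "chains")
        a = np.radians(alpha)
        expected = (3.0 * np.sin(a) ** 2 / 2.0 - 1.0) / 2.0
        assert np.mean(prof.scd) == pytest.approx(expected, abs=0.005)

    def test_bounds_never_violated(self):
        traj, topo, _ = gen_bilayer_trajectory(seed=3, n_frames=20)
        prof = scd_profile(traj, topo, "chains")
        assert np.all(prof.scd >= -0.5) and np.all(prof.scd <= 1.0)

    def test_absolute_presentation_flag(self):
        traj, topo, _ = gen_bilayer_trajectory(seed=0, tilt_mean=0.0, tilt_sd=0.0, n_frames=3)
        prof = scd_profile(traj, topo, "chains", absolute=True)
        assert np.allclose(prof.scd, 0.5)

    def test_carbon_without_hydrogens_needs_reconstruction_flag(self):
        rows = [(f"C{k + 1}", "LIP", 1, "tail", 0.0, 3.4, 0.1, 12.011, -1) for k in range(4)]
        topo = make_topology(rows, selections={"chains": [0, 1, 2, 3]})
        b, a = 1.2574, 0.4446
        coords = np.array(
            [[[a * (-1) ** k, 0.0, b * k] for k in range(4)]]
        )
        with pytest.raises(ValueError, match="no bonded hydrogens"):
            scd_profile(make_trajectory(coords), topo, "chains")
        prof = scd_profile(make_trajectory(coords), topo, "chains", reconstruct_h=True)
        # interior carbons of a z-aligned all-trans chain reconstruct to -0.5
        assert np.allclose(prof.scd, -0.5, atol=1e-9)


class TestTiltDistribution:
    def test_aligned_leaflets_give_delta_peaks(self):
        traj, topo, _ = gen_bilayer_trajectory(seed=0, tilt_mean=0.0, tilt_sd=0.0, n_frames=3)
        unfolded = tilt_distribution(traj, topo, "chains", fold=False)
        peaks = unfolded.samples
        assert np.all((peaks < 1e-6) | (peaks > 180.0 - 1e-6))
        folded = tilt_distribution(traj, topo, "chains", fold=True)
        assert folded.mean == pytest.approx(0.0, abs=1e-9)

    def test_mirrored_leaflets_symmetric_about_ninety(self):
        traj, topo, _ = gen_bilayer_trajectory(seed=7, n_frames=300)
        unfolded = tilt_distribution(traj, topo, "chains", fold=False, bin_width=5.0)
        mid = 0.5 * (unfolded.bin_edges[:-1] + unfolded.bin_edges[1:])
        # compare density at theta with density at 180 - theta
        assert np.allclose(unfolded.density, unfolded.density[::-1], atol=0.004)
        assert np.mean(unfolded.samples) == pytest.approx(90.0, abs=1.0)

    def test_generator_tilt_mean_recovered(self):
        traj, topo, truth = gen_bilayer_trajectory(seed=7, tilt_mean=33.0, tilt_sd=5.0, n_frames=200)
        folded = tilt_distribution(traj, topo, "chains", fold=True)
        assert folded.mean == pytest.approx(33.0, abs=1.0)

    def test_normalization(self):
        traj, topo, _ = gen_bilayer_trajectory(seed=5, n_frames=20)
        for fold in (False, True):
            dist = tilt_distribution(traj, topo, "chains", fold=fold)
            assert np.sum(dist.density * np.diff(dist.bin_edges)) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_vector_rejected(self):
        rows = [
            ("C1", "LIP", 1, "tail", 0.0, 3.4, 0.1, 12.011, -1),
            ("C2", "LIP", 1, "tail", 0.0, 3.4, 0.1, 12.011, -1),
        ]
        topo = make_topology(rows, selections={"chains": [0, 1]})
        with pytest.raises(ValueError, match="zero-length"):
            tilt_distribution(make_trajectory(np.zeros((1, 2, 3))), topo, "chains")


def random_two_selection_system(seed, n_a=20, n_mols_b=6, atoms_per_mol=8, box=30.0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_a):
        rows.append((f"A{i}", "PRB", 1, "probe", rng.normal(0, 0.3), rng.uniform(2.5, 3.5),
                     rng.uniform(0.05, 0.2), 12.0, -1))
    for m in range(n_mols_b):
        for j in range(atoms_per_mol):
            rows.append((f"B{j}", "LIP", 2 + m, "lipid", rng.normal(0, 0.3),
                         rng.uniform(2.5, 3.5), rng.uniform(0.05, 0.2), 12.0, -1))
    n = n_a + n_mols_b * atoms_per_mol
    topo = make_topology(rows, selections={"a": list(range(n_a)), "b": list(range(n_a, n))})
    coords = rng.uniform(0, box, (3, n, 3))
    return topo, make_trajectory(coords, box=box), rng


def brute_force_energy(topo, traj, a_idx, b_idx, cutoff):
    """Independent all-pairs oracle restricted to in-cutoff molecules."""
    q = topo.atoms["charge_e"].to_numpy(float)
    sg = topo.atoms["sigma_A"].to_numpy(float)
    ep = topo.atoms["epsilon_kcal"].to_numpy(float)
    rid = topo.atoms["resid"].to_numpy(int)
    elec = np.zeros(traj.n_frames)
    vdw = np.zeros(traj.n_frames)
    for f in range(traj.n_frames):
        c, box = traj.coordinates[f], traj.box[f]

        def mi_dist(i, j):
            d = c[j] - c[i]
            d = d - box * np.round(d / box)
            return float(np.linalg.norm(d))

        keep = set()
        for r in sorted(set(rid[b_idx])):
            members = [j for j in b_idx if rid[j] == r]
            if min(mi_dist(i, j) for i in a_idx for j in members) <= cutoff:
                keep.add(r)
        for i in a_idx:
            for j in b_idx:
                if rid[j] not in keep:
                    continue
                r_ = mi_dist(i, j)
                elec[f] += 332.0636 * q[i] * q[j] / r_
                s_ = 0.5 * (sg[i] + sg[j])
                e_ = np.sqrt(ep[i] * ep[j])
                vdw[f] += 4.0 * e_ * ((s_ / r_) ** 12 - (s_ / r_) ** 6)
    return elec, vdw


class TestPairwiseInteractionEnergy:
    def test_unit_charges_at_three_angstrom(self):
        rows = [
            ("P", "PRB", 1, "a", 1.0, 3.0, 0.0, 10.0, -1),
            ("N", "ION", 2, "b", -1.0, 3.0, 0.0, 10.0, -1),
        ]
        topo = make_topology(rows, selections={"a": [0], "b": [1]})
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = 3.0
        trace = pairwise_interaction_energy(make_trajectory(coords), topo, "a", "b")
        assert trace.electrostatic[0] == pytest.approx(-110.69, abs=0.01)
        assert trace.van_der_waals[0] == pytest.approx(0.0)

    def test_lennard_jones_roots_and_minimum(self):
        rows = [
            ("P", "PRB", 1, "a", 0.0, 3.4, 0.1, 10.0, -1),
            ("Q", "ION", 2, "b", 0.0, 3.4, 0.1, 10.0, -1),
        ]
        topo = make_topology(rows, selections={"a": [0], "b": [1]})
        for r, expected in [(3.4, 0.0), (3.4 * 2 ** (1 / 6), -0.1)]:
            coords = np.zeros((1, 2, 3))
            coords[0, 1, 0] = r
            trace = pairwise_interaction_energy(make_trajectory(coords), topo, "a", "b")
            assert trace.van_der_waals[0] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_brute_force_oracle(self, seed):
        topo, traj, _ = random_two_selection_system(seed)
        trace = pairwise_interaction_energy(traj, topo, "a", "b", cutoff=12.0)
        elec, vdw = brute_force_energy(topo, traj, topo.selections["a"], topo.selections["b"], 12.0)
        assert np.allclose(trace.electrostatic, elec, rtol=1e-8)
        assert np.allclose(trace.van_der_waals, vdw, rtol=1e-8)

    def test_rigid_translation_invariance(self):
        topo, traj, _ = random_two_selection_system(4)
        shifted = Trajectory(traj.coordinates + np.array([5.0, -3.0, 11.0]), traj.box)
        t1 = pairwise_interaction_energy(traj, topo, "a", "b")
        t2 = pairwise_interaction_energy(shifted, topo, "a", "b")
        assert np.allclose(t1.electrostatic, t2.electrostatic, rtol=1e-9)
        assert np.allclose(t1.van_der_waals, t2.van_der_waals, rtol=1e-9)

    def test_periodic_wrapping_invariance(self):
        topo, traj, _ = random_two_selection_system(5, box=30.0)
        wrapped = Trajectory(np.mod(traj.coordinates + 17.0, 30.0), traj.box)
        t1 = pairwise_interaction_energy(traj, topo, "a", "b")
        t2 = pairwise_interaction_energy(wrapped, topo, "a", "b")
        assert np.allclose(t1.electrostatic, t2.electrostatic, rtol=1e-9)
        assert np.allclose(t1.van_der_waals, t2.van_der_waals, rtol=1e-9)

    def test_missing_parameters_listed(self):
        rows = [
            ("P", "PRB", 1, "a", 1.0, np.nan, 0.1, 10.0, -1),
            ("Q", "ION", 2, "b", -1.0, 3.0, 0.1, 10.0, -1),
        ]
        topo = make_topology(rows, selections={"a": [0], "b": [1]})
        with pytest.raises(ValueError, match=r"atom\(s\) \[1\]"):
            pairwise_interaction_energy(make_trajectory(np.zeros((1, 2, 3))), topo, "a", "b")
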