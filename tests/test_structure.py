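"""Orientation angles, z-profiles, thickness, flips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bilayerlab as bl
from bilayerlab import synthetic
from bilayerlab.errors import ValidationError
from bilayerlab.structure import DensityProfile


def rod_traj(end_a, cor, end_b, box=200.0):
    pos = np.array([[end_a, cor, end_b]], dtype=float)
    traj = bl.Trajectory(positions=pos, box=np.array([box] * 3), dt=1.0, wrapped=False)
    mol = bl.AdditiveMolecule(backbone_end_a=0, backbone_end_b=2,
                              cor_ring_atoms=np.array([1]), ch3_terminal=0,
                              cf3_terminal=2)
    spec = bl.GroupSpec(groups={"additives": np.arange(3)}, additive_molecules=[mol])
    return traj, spec


class TestBackboneAngles:
    def test_straight_trans_bilayer_rod(self):
        traj, spec = rod_traj([10, 10, 15], [10, 10, 10], [10, 10, 5])
        s = bl.backbone_angles(traj, spec)
        assert s.alpha1[0, 0] == pytest.approx(0.0, abs=1e-9)
        assert s.alpha2[0, 0] == pytest.approx(180.0, abs=1e-9)
        assert s.beta[0, 0] == pytest.approx(180.0, abs=1e-9)

    def test_right_angle_arms_in_plane(self):
        traj, spec = rod_traj([15, 10, 10], [10, 10, 10], [10, 15, 10])
        s = bl.backbone_angles(traj, spec)
        assert s.alpha1[0, 0] == pytest.approx(90.0, abs=1e-9)
        assert s.alpha2[0, 0] == pytest.approx(90.0, abs=1e-9)
        assert s.beta[0, 0] == pytest.approx(90.0, abs=1e-9)

    def test_generator_roundtrip_20_30(self):
        spec = synthetic.RodSpec(alpha1=20.0, alpha2=30.0, noise_sigma=0.0)
        traj, gspec = synthetic.gen_rod_frames(spec, 5, seed=2)
        s = bl.backbone_angles(traj, gspec)
        np.testing.assert_allclose(s.alpha1, 20.0, atol=1e-9)
        np.testing.assert_allclose(s.alpha2, 150.0, atol=1e-9)
        np.testing.assert_allclose(s.beta, 130.0, atol=1e-9)

    def test_noisy_tilt_recovered_in_distribution(self):
        spec = synthetic.RodSpec(alpha1=30.0, alpha2=30.0, noise_sigma=5.0)
        traj, gspec = synthetic.gen_rod_frames(spec, 2000, seed=3)
        s = bl.backbone_angles(traj, gspec)
        hist = bl.angle_histogram(s.alpha1, bin_width=1.0)
        mean = (hist.bin_centers * hist.density * hist.bin_width).sum()
        se = 5.0 / np.sqrt(2000)
        assert abs(mean - 30.0) < 3 * se + 0.5  # half-bin quantization margin

    def test_invariant_under_rotation_about_normal_and_translation(self):
        spec = synthetic.RodSpec(alpha1=25.0, alpha2=40.0, noise_sigma=0.0)
        traj, gspec = synthetic.gen_rod_frames(spec, 3, seed=4)
        s0 = bl.backbone_angles(traj, gspec)
        th = 1.1
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        pos = traj.positions @ R.T + np.array([3.0, -2.0, 7.0])
        moved = bl.Trajectory(positions=pos, box=traj.box * 10, dt=1.0, wrapped=False)
        s1 = bl.backbone_angles(moved, gspec)
        np.testing.assert_allclose(s1.alpha1, s0.alpha1, atol=1e-9)
        np.testing.assert_allclose(s1.beta, s0.beta, atol=1e-9)

    def test_measure_regenerate_roundtrip(self):
        spec = synthetic.RodSpec(alpha1=35.0, alpha2=55.0, noise_sigma=0.0)
        traj, gspec = synthetic.gen_rod_frames(spec, 1, seed=6)
        s = bl.backbone_angles(traj, gspec)
        spec2 = synthetic.RodSpec(alpha1=s.alpha1[0, 0], alpha2=180.0 - s.alpha2[0, 0],
                                  noise_sigma=0.0)
        traj2, gspec2 = synthetic.gen_rod_frames(spec2, 1, seed=99)
        s2 = bl.backbone_angles(traj2, gspec2)
        np.testing.assert_allclose(s2.beta, s.beta, atol=1e-9)

    def test_zero_length_vector_rejected(self):
        traj, spec = rod_traj([10, 10, 10], [10, 10, 10], [10, 10, 5])
        with pytest.raises(ValidationError, match="zero-length"):
            bl.backbone_angles(traj, spec)


class TestSideChainAngle:
    @pytest.mark.parametrize(
        "terminal_offset,expected",
        [((0, 0, -4.0), 0.0), ((4.0, 0, 0), 90.0), ((3.0, 0, 3.0), 135.0)],
    )
    def test_reference_geometries(self, terminal_offset, expected):
        cor = np.array([10.0, 10.0, 10.0])
        term = cor + terminal_offset
        pos = np.array([[term, cor, cor + [0, 0, 5.0]]])
        traj = bl.Trajectory(positions=pos, box=np.array([200.0] * 3), dt=1.0,
                             wrapped=False)
        mol = bl.AdditiveMolecule(backbone_end_a=2, backbone_end_b=2,
                                  cor_ring_atoms=np.array([1]), ch3_terminal=0,
                                  cf3_terminal=0)
        spec = bl.GroupSpec(groups={"additives": np.arange(3)}, additive_molecules=[mol])
        ang = bl.side_chain_angle(traj, spec, terminal="ch3")
        assert ang[0, 0] == pytest.approx(expected, abs=1e-9)


class TestAngleHistogram:
    def test_single_value_single_bin(self):
        hist = bl.angle_histogram(np.full(50, 90.0), bin_width=2.0)
        nz = np.flatnonzero(hist.density)
        assert len(nz) == 1
        assert hist.bin_centers[nz[0]] == 91.0

    def test_uniform_samples_flat(self):
        rng = np.random.default_rng(5)
        hist = bl.angle_histogram(rng.uniform(0, 180, 200_000), bin_width=5.0)
        np.testing.assert_allclose(hist.density, 1 / 180.0, atol=5e-4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bl.angle_histogram(np.array([10.0, 190.0]))

    @given(
        values=st.lists(st.floats(0.0, 180.0), min_size=1, max_size=200),
        bin_width=st.sampled_from([0.5, 1.0, 2.0, 7.0]),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_normalization_property(self, values, bin_width):
        hist = bl.angle_histogram(np.array(values), bin_width=bin_width)
        assert (hist.density * hist.bin_width).sum() == pytest.approx(1.0, abs=1e-9)


class TestZProfile:
    def test_all_at_reference_com(self):
        pos = np.zeros((3, 4, 3)) + [5.0, 5.0, 17.0]
        traj = bl.Trajectory(positions=pos, box=np.array([50.0] * 3), dt=1.0,
                             wrapped=False)
        prof = bl.z_profile(traj, np.arange(4), np.arange(4))
        nz = np.flatnonzero(prof.density)
        assert len(nz) == 1
        assert prof.z_bin_centers[nz[0]] == 0.0

    def test_noiseless_slab_two_delta_bins(self):
        spec = synthetic.BilayerSlabSpec(thickness=40.0, roughness_sigma=0.0,
                                         n_lipids_per_leaflet=12)
        traj, gspec = synthetic.gen_bilayer_slab(spec, 5, seed=0)
        prof = bl.z_profile(traj, gspec.group("headgroups"), gspec.group("all"))
        nz = prof.z_bin_centers[np.flatnonzero(prof.density)]
        np.testing.assert_array_equal(np.sort(nz), [-20.0, 20.0])

    def test_profile_normalized(self):
        spec = synthetic.BilayerSlabSpec(roughness_sigma=2.0, n_lipids_per_leaflet=30)
        traj, gspec = synthetic.gen_bilayer_slab(spec, 10, seed=1)
        prof = bl.z_profile(traj, gspec.group("headgroups"), gspec.group("all"))
        assert (prof.density * prof.bin_width).sum() == pytest.approx(1.0, abs=1e-9)

    def test_invariant_under_collective_drift(self):
        spec = synthetic.BilayerSlabSpec(roughness_sigma=1.0, n_lipids_per_leaflet=20)
        traj, gspec = synthetic.gen_bilayer_slab(spec, 8, seed=2)
        prof0 = bl.z_profile(traj, gspec.group("headgroups"), gspec.group("all"))
        drift = np.outer(np.arange(8), [0.0, 0.0, 1.5])
        moved = bl.Trajectory(positions=traj.positions + drift[:, None, :],
                              box=traj.box * 5, dt=1.0, wrapped=False)
        prof1 = bl.z_profile(moved, gspec.group("headgroups"), gspec.group("all"))
        np.testing.assert_allclose(prof1.density, prof0.density, atol=1e-12)


class TestThicknessAndMidplane:
    def _profile(self, z_up, z_lo):
        spec = synthetic.BilayerSlabSpec(thickness=z_up - z_lo, roughness_sigma=0.0,
                                         n_lipids_per_leaflet=12)
        traj, gspec = synthetic.gen_bilayer_slab(spec, 3, seed=0)
        return bl.z_profile(traj, gspec.group("headgroups"), gspec.group("all"))

    def test_noiseless_planes_give_exact_thickness(self):
        assert bl.bilayer_thickness(self._profile(20.0, -20.0)) == pytest.approx(40.0)

    def test_thickness_scales_linearly(self):
        assert bl.bilayer_thickness(self._profile(17.5, -17.5)) == pytest.approx(35.0, abs=1.0)

    def test_single_sided_profile_rejected(self):
        z = np.arange(-10.0, 11.0)
        d = np.zeros(21)
        d[z > 3] = 0.1
        prof = DensityProfile(z_bin_centers=z, density=d)
        with pytest.raises(ValidationError):
            bl.bilayer_thickness(prof)

    def test_midplane_ratio_flat_and_empty(self):
        z = np.arange(-10.0, 11.0)
        flat = DensityProfile(z_bin_centers=z, density=np.full(21, 0.05))
        assert bl.midplane_ratio(flat) == pytest.approx(1.0)
        d = np.full(21, 0.05)
        d[np.abs(z) <= 2] = 0.0
        hollow = DensityProfile(z_bin_centers=z, density=d)
        assert bl.midplane_ratio(hollow) == pytest.approx(0.0)

    def test_midplane_ratio_one_ninth_plateau(self):
        z = np.arange(-25.0, 26.0)
        d = np.zeros(51)
        d[np.abs(np.abs(z) - 20) <= 1] = 0.09
        d[np.abs(z) <= 2] = 0.01
        prof = DensityProfile(z_bin_centers=z, density=d)
        assert bl.midplane_ratio(prof, center_halfwidth=2.0) == pytest.approx(1 / 9, abs=1e-9)


class TestFlipEvents:
    def test_constant_series_no_events(self):
        ev = bl.flip_events(np.full(100, 15.0), dt=0.1)
        assert ev.n_events == 0

    def test_single_step_flip(self):
        z = np.full(20, 15.0)
        z[10:] = -15.0
        ev = bl.flip_events(z, dt=0.1)
        assert ev.n_events == 1
        assert ev.times[0] == pytest.approx(1.0)

    def test_excursion_returning_to_same_band_not_a_flip(self):
        z = np.array([15.0, 15.0, 5.0, 0.0, 5.0, 15.0, 15.0])
        ev = bl.flip_events(z, dt=1.0)
        assert ev.n_events == 0

    def test_telegraph_driven_dwell_times(self):
        spec = synthetic.TelegraphSpec(tau=1.0, p_on=0.5, dt=0.01, n_steps=100_000,
                                       seed=7)
        states = synthetic.gen_telegraph(spec)
        z = np.where(states == 1, 15.0, -15.0)
        ev = bl.flip_events(z, dt=spec.dt, threshold=10.0)
        # expected dwell: geometric holding time of the discrete chain
        lam = np.exp(-spec.dt / spec.tau)
        expected = spec.dt / (0.5 * (1 - lam))
        mean_dwell = ev.dwell_durations.mean()
        se = expected / np.sqrt(ev.n_events)
        assert abs(mean_dwell - expected) < 3 * se
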