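"""Langevin chain simulator and its analysis estimators."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from pssk import cgsim
from pssk.cgsim import (BinodalModel, ChainTrajectory, DensityProfile,
                        DistanceScalingModel, ForceField, KB,
                        center_profile, dense_dilute_densities, fit_binodal,
                        fit_scaling_exponent, mean_bond_length,
                        radius_of_gyration, simulate_chain,
                        theta_temperature)
from pssk.sequences import AminoAcidSequence
from pssk.synth import (synth_binodal_points, synth_density_profile,
                        synth_distance_curve)


def thermal_mean_bond(temperature, k=1000.0, r0=0.38):
    """Exact canonical <r> of a 3-D harmonic bond (r^2 Jacobian included)."""
    beta = 1.0 / (KB * temperature)
    w = lambda r: np.exp(-0.5 * beta * k * (r - r0) ** 2)
    num = quad(lambda r: r ** 3 * w(r), 0, 5 * r0)[0]
    den = quad(lambda r: r ** 2 * w(r), 0, 5 * r0)[0]
    return num / den


class TestForceField:
    def test_pair_tables_symmetric_and_arg_override(self):
        ff = ForceField().build(AminoAcidSequence("t", "RKDER"))
        assert np.allclose(ff["lambda_ij"], ff["lambda_ij"].T)
        assert np.allclose(ff["sigma_ij"], ff["sigma_ij"].T)
        assert ff["lambda_ij"][0, 4] == 0.01    # Arg-Arg override
        assert ff["qq_ij"][0, 1] > 0            # R-K repulsion
        assert ff["qq_ij"][0, 2] < 0            # R-D attraction

    def test_phospho_residues_change_charge(self):
        seq = AminoAcidSequence("t", "ASTA")
        from pssk.sequences import PhosphoPattern
        pat = PhosphoPattern((2, 3), frozenset((2, 3)))
        ff = ForceField().build(seq, pat)
        assert np.allclose(ff["charge"], [0, -2, -2, 0])
        assert ff["names"][1:3] == ["pS", "pT"]


class TestDynamics:
    def test_same_seed_reproduces_bitwise(self):
        seq = AminoAcidSequence("t", "ASTDKRAGNQ")
        t1 = simulate_chain(seq, 300.0, n_steps=2000, seed=3,
                            save_interval=100)
        t2 = simulate_chain(seq, 300.0, n_steps=2000, seed=3,
                            save_interval=100)
        assert np.array_equal(t1.frames, t2.frames)
        t3 = simulate_chain(seq, 300.0, n_steps=2000, seed=4,
                            save_interval=100)
        assert not np.array_equal(t1.frames, t3.frames)

    def test_bond_length_matches_canonical_average(self):
        # the thermal mean exceeds r0 through the r^2 Jacobian and
        # anharmonic weighting; the integrator must reproduce the exact
        # canonical value, not r0 itself
        seq = AminoAcidSequence("t", "A" * 30)
        traj = simulate_chain(seq, 300.0, n_steps=120_000, seed=9,
                              bonded_only=True, save_interval=200)
        expected = thermal_mean_bond(300.0)
        assert mean_bond_length(traj, discard_fraction=0.1) == \
            pytest.approx(expected, rel=0.02)

    def test_kinetic_temperature(self):
        seq = AminoAcidSequence("t", "ASTDKRAGNQ" * 4)
        traj = simulate_chain(seq, 320.0, n_steps=150_000, seed=2,
                              bonded_only=True, save_interval=150)
        assert traj.kinetic_temperature() == pytest.approx(320.0, rel=0.03)

    def test_desk_scale_cap(self):
        with pytest.raises(ValueError, match="N = 500"):
            simulate_chain(AminoAcidSequence("t", "A" * 501), 300.0,
                           n_steps=1000)


class TestRadiusOfGyration:
    def test_identical_frames_have_zero_sem(self):
        frame = np.random.default_rng(0).normal(size=(1, 8, 3))
        traj = ChainTrajectory(np.repeat(frame, 20, axis=0), np.zeros(20),
                               300.0)
        rg, sem = radius_of_gyration(traj, n_blocks=10)
        assert sem == 0.0

    def test_straight_rod_closed_form(self):
        # beads at 0, b, 2b, ...: Rg^2 = b^2 (N^2 - 1) / 12
        n, b = 25, 0.38
        pos = np.zeros((1, n, 3))
        pos[0, :, 0] = np.arange(n) * b
        traj = ChainTrajectory(np.repeat(pos, 12, axis=0), np.zeros(12),
                               300.0)
        rg, _ = radius_of_gyration(traj, n_blocks=12)
        assert rg == pytest.approx(b * math.sqrt((n ** 2 - 1) / 12.0),
                                   rel=1e-12)

    def test_mean_independent_of_blocking(self):
        rng = np.random.default_rng(1)
        traj = ChainTrajectory(rng.normal(size=(40, 6, 3)), np.zeros(40),
                               300.0)
        r10, _ = radius_of_gyration(traj, n_blocks=10)
        r20, _ = radius_of_gyration(traj, n_blocks=20)
        assert r10 == pytest.approx(r20, rel=1e-12)

    def test_too_few_frames(self):
        traj = ChainTrajectory(np.zeros((4, 5, 3)), np.zeros(4), 300.0)
        with pytest.raises(ValueError):
            radius_of_gyration(traj, n_blocks=10)


class TestScalingFit:
    @pytest.mark.parametrize("nu", [0.5, 1.0, 0.33, 0.588])
    def test_exact_on_noise_free_curves(self, nu):
        s, r, _ = synth_distance_curve(nu=nu)
        assert fit_scaling_exponent(s, r) == pytest.approx(nu, abs=1e-10)

    def test_noise_robustness(self):
        hits = 0
        for seed in range(100):
            s, r, _ = synth_distance_curve(nu=0.55, noise_sd=0.01,
                                           seed=seed)
            if abs(fit_scaling_exponent(s, r) - 0.55) < 0.01:
                hits += 1
        assert hits >= 95

    def test_input_guards(self):
        with pytest.raises(ValueError):
            DistanceScalingModel([1, 2, 3], [1, 1, 1])   # all below min_sep
        with pytest.raises(ValueError):
            DistanceScalingModel(np.arange(5, 20), -np.ones(15))


class TestThetaTemperature:
    def test_linear_interpolation(self):
        assert theta_temperature([300, 320], [0.45, 0.55]) == \
            pytest.approx(310.0)

    def test_exact_grid_point(self):
        assert theta_temperature([280, 300, 320], [0.4, 0.5, 0.6]) == 300

    def test_not_determined(self):
        assert theta_temperature([300, 320], [0.40, 0.45]) is None

    def test_multiple_crossings_warns_and_returns_lowest(self):
        with pytest.warns(UserWarning, match="multiple"):
            t = theta_temperature([1, 2, 3, 4], [0.4, 0.6, 0.4, 0.6])
        assert t == pytest.approx(1.5)


class TestDensityWindows:
    def test_uniform_profile(self):
        z = np.linspace(0.5, 199.5, 200)
        rho_h, rho_l = dense_dilute_densities(DensityProfile(z,
                                                             np.full(200,
                                                                     7.0)))
        assert rho_h == pytest.approx(7.0)
        assert rho_l == pytest.approx(7.0)

    def test_step_profile(self):
        z = np.linspace(0.5, 199.5, 200)
        d = np.where((z > 80) & (z < 120), 42.0, 0.0)
        rho_h, rho_l = dense_dilute_densities(DensityProfile(z, d),
                                              centred=True)
        assert rho_h == pytest.approx(42.0)
        assert rho_l == pytest.approx(0.0)

    def test_off_centre_slab_recentred(self):
        centred, _ = synth_density_profile(centre=100.0)
        shifted, _ = synth_density_profile(centre=60.0)
        assert dense_dilute_densities(shifted) == \
            pytest.approx(dense_dilute_densities(centred), rel=1e-9)

    def test_centre_profile_moves_midpoint(self):
        prof, _ = synth_density_profile(centre=30.0)
        c = center_profile(prof)
        mid = (c.density * c.z).sum() / c.density.sum()
        assert mid == pytest.approx(100.0, abs=2.0)

    def test_nonstandard_span_warns(self):
        z = np.linspace(0.25, 99.75, 200)
        with pytest.warns(UserWarning, match="rescaled"):
            dense_dilute_densities(DensityProfile(z, np.full(200, 1.0)))


class TestBinodalFit:
    def test_exact_recovery(self):
        T, d, _ = synth_binodal_points(A=1.0, T_c=2.0)
        A, tc = fit_binodal(T, d)
        assert A == pytest.approx(1.0, abs=1e-8)
        assert tc == pytest.approx(2.0, abs=1e-8)

    def test_amplitude_plug_in(self):
        # at T_c - T = 1 the width equals A
        res = BinodalModel([1.0, 1.5, 1.8],
                           [1.3 * (2.0 - t) ** 0.325
                            for t in (1.0, 1.5, 1.8)]).fit()
        assert res.A * (res.T_c - 1.0) ** 0.325 == pytest.approx(1.3,
                                                                 abs=1e-6)

    def test_noisy_recovery(self):
        hits = 0
        for seed in range(100):
            T, d, _ = synth_binodal_points(A=1.0, T_c=2.0, noise_sd=0.02,
                                           seed=seed)
            _, tc = fit_binodal(T, d)
            hits += abs(tc - 2.0) / 2.0 < 0.02
        assert hits >= 90

    def test_non_monotone_flagged(self):
        with pytest.warns(UserWarning, match="monotone"):
            res = BinodalModel([1.0, 1.2, 1.4], [1.0, 1.1, 0.7]).fit()
        assert not res.monotone_input


class TestEnergyInvariance:
    def test_forces_invariant_under_rigid_motion(self):
        from pssk.cgsim import _forces
        seq = AminoAcidSequence("t", "DKRESTAGNQ")
        ff = ForceField().build(seq)
        rng = np.random.default_rng(5)
        pos = rng.normal(scale=0.5, size=(10, 3))
        args = (ff["qq_ij"], ff["lambda_ij"], ff["sigma_ij"], ff["eps_lj"],
                ff["bond_k"], ff["bond_r0"], 1.0 / ff["debye_length"],
                ff["coulomb_cutoff"] ** 2, ff["lj_cutoff_sigmas"], True)
        F1 = np.zeros_like(pos)
        _forces(pos, *args, F1)
        # translation
        F2 = np.zeros_like(pos)
        _forces(pos + np.array([3.0, -1.0, 2.0]), *args, F2)
        assert np.allclose(F1, F2, atol=1e-9)
        # rotation (forces co-rotate; magnitudes preserved)
        th = 0.7
        R = np.array([[math.cos(th), -math.sin(th), 0],
                      [math.sin(th), math.cos(th), 0], [0, 0, 1.0]])
        F3 = np.zeros_like(pos)
        _forces(pos @ R.T, *args, F3)
        assert np.allclose(F3, F1 @ R.T, atol=1e-9)
        assert np.allclose(np.linalg.norm(F3, axis=1),
                           np.linalg.norm(F1, axis=1), atol=1e-9)

    def test_net_force_is_zero(self):
        from pssk.cgsim import _forces
        seq = AminoAcidSequence("t", "DKREST")
        ff = ForceField().build(seq)
        pos = np.random.default_rng(0).normal(scale=0.4, size=(6, 3))
        F = np.zeros_like(pos)
        _forces(pos, ff["qq_ij"], ff["lambda_ij"], ff["sigma_ij"],
                ff["eps_lj"], ff["bond_k"], ff["bond_r0"],
                1.0 / ff["debye_length"], ff["coulomb_cutoff"] ** 2,
                ff["lj_cutoff_sigmas"], True, F)
        scale = np.abs(F).max() or 1.0
        assert np.allclose(F.sum(axis=0) / scale, 0.0, atol=1e-12)


class TestTrajectoryIO:
    def test_save_and_xyz(self, tmp_path):
        seq = AminoAcidSequence("t", "ASTDK")
        traj = simulate_chain(seq, 300.0, n_steps=500, seed=0,
                              save_interval=100)
        traj.save(tmp_path / "run")
        assert (tmp_path / "run.npz").exists()
        assert (tmp_path / "run.json").exists()
        traj.to_xyz(tmp_path / "run.xyz")
        lines = (tmp_path / "run.xyz").read_text().splitlines()
        assert lines[0] == "5"
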