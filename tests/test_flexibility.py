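import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foldhelix import (EnsembleSpec, Trajectory, bending_persistence_per_step,
                       exclusion_mask, excluded_ranges, exo_periodicity,
                       flexibility_summary, fluctuation_covariance,
                       generate_ensemble, helix_series, rmsd_series, rmsf)
from foldhelix._geom import rotation_about_axis


class TestExclusionMask:
    def test_all_low_rmsd_keeps_everything(self):
        mask = exclusion_mask(np.full(50, 3.0))
        assert mask.all()

    def test_frames_above_threshold_excluded_exactly(self):
        rmsd = np.full(40, 3.0)
        rmsd[10:20] = 6.5
        mask = exclusion_mask(rmsd, threshold=6.0)
        assert (~mask).sum() == 10
        assert excluded_ranges(mask) == [(10, 20)]

    def test_zero_threshold_boundary(self):
        rmsd = np.array([0.0, 0.1, 0.0, 2.0])
        mask = exclusion_mask(rmsd, threshold=0.0)
        assert mask.tolist() == [True, False, True, False]


class TestFlexibilitySummary:
    def test_rigid_ensemble_flags_infinite_stiffness(self, ideal_base):
        traj = generate_ensemble(ideal_base, EnsembleSpec(n_frames=5, seed=0))
        s = helix_series(traj, traj.topology)
        fs = flexibility_summary(s)
        assert math.isinf(fs.bending_persistence)
        assert "bending_persistence_infinite" in fs.flags
        assert fs.rise_variance == pytest.approx(0.0, abs=1e-20)
        assert fs.mean_twist == pytest.approx(36.0, abs=1e-6)

    def test_bending_persistence_recovery(self, ideal_base):
        spec = EnsembleSpec(n_frames=5000, lp_bend=400.0, sigma_twist=2.0,
                            sigma_rise=0.1, seed=21)
        s = helix_series(generate_ensemble(ideal_base, spec),
                         ideal_base[1])
        fs = flexibility_summary(s)
        assert abs(fs.bending_persistence - 400.0) / 400.0 < 0.10

    def test_twist_persistence_closed_form(self):
        from foldhelix import HelixSpec, build_ideal_helix

        base = build_ideal_helix(HelixSpec(rise_per_unit=3.66))
        spec = EnsembleSpec(n_frames=5000, sigma_twist=5.73, seed=2)
        s = helix_series(generate_ensemble(base, spec), base[1])
        fs = flexibility_summary(s)
        expect = 3.66 / np.radians(5.73) ** 2   # ~366 Å
        assert abs(fs.twist_persistence - expect) / expect < 0.10

    def test_generator_moments_recovered_within_3_se(self, small_ensemble):
        traj, spec = small_ensemble
        s = helix_series(traj, traj.topology)
        fs = flexibility_summary(s)
        n = s.rise.size
        se_rise = spec.sigma_rise / np.sqrt(n)
        assert abs(fs.mean_rise - 3.5) < 3 * se_rise + 1e-9
        se_twist = spec.sigma_twist / np.sqrt(s.twist.size)
        assert abs(fs.mean_twist - 36.0) < 3 * se_twist
        var = spec.sigma_rise**2
        se_var = var * np.sqrt(2.0 / n)
        assert abs(fs.rise_variance - var) < 3 * se_var

    def test_estimator_cross_check_on_wlc(self, ideal_base):
        for lp in (100.0, 1000.0):
            spec = EnsembleSpec(n_frames=3000, lp_bend=lp, seed=int(lp))
            s = helix_series(generate_ensemble(ideal_base, spec),
                             ideal_base[1])
            e2e = flexibility_summary(s).bending_persistence
            step = bending_persistence_per_step(s)
            assert abs(e2e - step) / step < 0.15

    def test_single_frame_rejected(self, ideal_traj, ideal_base):
        s = helix_series(ideal_traj, ideal_base[1])
        with pytest.raises(ValueError, match="frames"):
            flexibility_summary(s)


class TestExoPeriodicity:
    @pytest.mark.parametrize("twist,units,rounded", [
        (28.8, 12.5, 12.5),
        (36.0, 10.0, 10.0),
        (25.5, 360.0 / 25.5, 14.0),
    ])
    def test_reference_twists(self, twist, units, rounded):
        p = exo_periodicity(twist)
        assert p.units == pytest.approx(units, abs=1e-12)
        assert p.rounded == rounded

    def test_exact_at_crystal_twist(self):
        assert exo_periodicity(36.0).units == 10.0

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(1.0, 170.0), st.floats(0.01, 10.0))
    def test_strictly_decreasing_in_twist(self, twist, delta):
        assert exo_periodicity(twist + delta).units < exo_periodicity(twist).units

    @pytest.mark.parametrize("bad", [0.0, -10.0, 360.0])
    def test_nonpositive_or_full_turn_rejected(self, bad):
        with pytest.raises(ValueError):
            exo_periodicity(bad)


class TestCovariance:
    def test_offset_zero_equals_sample_variance(self, small_ensemble):
        traj, _ = small_ensemble
        s = helix_series(traj, traj.topology)
        prof = fluctuation_covariance(s, center_step=8, max_offset=3)
        center = s.twist[:, 8] - s.twist[:, 8].mean()
        var = float(center @ center / (len(center) - 1))
        i0 = list(prof.offsets).index(0)
        assert prof.twist_cov[i0] == pytest.approx(var, rel=1e-12)

    def test_independent_steps_have_no_cross_covariance(self, ideal_base):
        spec = EnsembleSpec(n_frames=5000, sigma_twist=5.0, seed=13)
        s = helix_series(generate_ensemble(ideal_base, spec), ideal_base[1])
        prof = fluctuation_covariance(s, center_step=8, max_offset=1)
        se = (5.0**2) / np.sqrt(s.n_frames)
        for off in (-1, 1):
            i = list(prof.offsets).index(off)
            assert abs(prof.twist_cov[i]) < 3 * se

    def test_shared_noise_gives_positive_neighbor_covariance(self, ideal_base):
        spec = EnsembleSpec(n_frames=2000, sigma_twist=4.0, seed=5)
        traj = generate_ensemble(ideal_base, spec)
        s = helix_series(traj, traj.topology)
        # impose correlation by symmetrizing neighboring twist columns in a
        # reconstructed series (shared noise on steps 7 and 8)
        twist = s.twist.copy()
        shared = 0.5 * (twist[:, 7] + twist[:, 8])
        twist[:, 7] = twist[:, 8] = shared
        s2 = type(s)(rise=s.rise, twist=twist, bend=s.bend,
                     frame_times=s.frame_times, seg_tangents=s.seg_tangents)
        prof = fluctuation_covariance(s2, center_step=8, max_offset=1)
        i = list(prof.offsets).index(-1)
        se = prof.twist_cov[list(prof.offsets).index(0)] / np.sqrt(s.n_frames)
        assert prof.twist_cov[i] > 3 * se

    def test_single_frame_rejected(self, ideal_traj, ideal_base):
        s = helix_series(ideal_traj, ideal_base[1])
        with pytest.raises(ValueError, match="frames"):
            fluctuation_covariance(s, center_step=8, max_offset=1)

    def test_window_outside_series_rejected(self, small_ensemble):
        traj, _ = small_ensemble
        s = helix_series(traj, traj.topology)
        with pytest.raises(ValueError, match="offset"):
            fluctuation_covariance(s, center_step=0, max_offset=2)


class TestRmsd:
    def test_identical_frame_is_zero(self, ideal_traj):
        assert rmsd_series(ideal_traj)[0] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_rotation_is_removed(self, ideal_traj, ideal_base):
        R = rotation_about_axis([0.0, 1.0, 0.0], 90.0)
        rotated = Trajectory(coords=ideal_traj.coords @ R.T,
                             atom_names=ideal_traj.atom_names,
                             resids=ideal_traj.resids,
                             resnames=ideal_traj.resnames,
                             topology=ideal_base[1])
        r = rmsd_series(rotated, reference=ideal_traj.coords[0])
        assert r[0] == pytest.approx(0.0, abs=1e-6)

    def test_single_displaced_atom_matches_formula(self, ideal_traj,
                                                   ideal_base):
        _, topo = ideal_base
        coords = ideal_traj.coords.copy()
        n_heavy = int(topo.heavy_atom_mask.sum())
        d = 0.5
        # displace one heavy atom; on the pre-aligned structures RMSD is
        # d / sqrt(N) up to the (small) re-superposition correction
        i = np.flatnonzero(topo.heavy_atom_mask)[10]
        coords[0, i, 0] += d
        moved = Trajectory(coords=coords, atom_names=ideal_traj.atom_names,
                           resids=ideal_traj.resids,
                           resnames=ideal_traj.resnames, topology=topo)
        r = rmsd_series(moved, reference=ideal_traj.coords[0])
        assert r[0] == pytest.approx(d / np.sqrt(n_heavy), rel=0.05)

    def test_atom_count_mismatch_rejected(self, ideal_traj):
        with pytest.raises(ValueError, match="atom count"):
            rmsd_series(ideal_traj, reference=np.zeros((3, 3)))


class TestRmsf:
    def test_static_ensemble_is_zero(self, ideal_base):
        traj = generate_ensemble(ideal_base, EnsembleSpec(n_frames=4, seed=0))
        assert np.abs(rmsf(traj)).max() < 1e-9

    def test_isotropic_jitter_gives_sigma_sqrt3(self, rng):
        n_atoms, n_frames, sigma = 40, 5000, 0.25
        base = rng.normal(0, 5.0, (n_atoms, 3))
        coords = np.repeat(base[None], n_frames, axis=0)
        coords[:, 7, :] += rng.normal(0, sigma, (n_frames, 3))
        traj = Trajectory(coords=coords,
                          atom_names=[f"C{i}" for i in range(n_atoms)],
                          resids=np.zeros(n_atoms, dtype=int),
                          resnames=["UNK"] * n_atoms)
        out = rmsf(traj)
        assert out[7] == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_jittered_phosphonates_peak_in_rmsf(self, ideal_base, rng):
        frame, topo = ideal_base
        traj = generate_ensemble((frame, topo),
                                 EnsembleSpec(n_frames=200, sigma_twist=0.5,
                                              sigma_rise=0.02, seed=9))
        coords = traj.coords.copy()
        side = np.zeros(topo.n_atoms, dtype=bool)
        for g in topo.phosphonate_groups():
            side[g["P"]] = True
            side[g["acceptors"]] = True
        coords[:, side, :] += rng.normal(0, 0.8, (traj.n_frames,
                                                  int(side.sum()), 3))
        jittered = Trajectory(coords=coords, atom_names=traj.atom_names,
                              resids=traj.resids, resnames=traj.resnames,
                              topology=topo)
        out = rmsf(jittered)
        heavy = topo.heavy_atom_mask
        assert out[side & heavy].mean() > 2 * out[~side & heavy].mean()
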