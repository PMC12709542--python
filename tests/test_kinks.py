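import numpy as np
import pytest

from foldhelix import (EnsembleSpec, KinkParams, KinkSpec, Trajectory,
                       detect_kinks, detect_unstacking, dihedral_series,
                       generate_ensemble, helix_series, inject_kink, kink_rate,
                       phosphonate_contacts)
from foldhelix._geom import dihedral_deg, rotation_about_axis
from foldhelix.coarse_grain import coarse_grain_coords
from foldhelix.kinks import circular_mode


class TestDihedralSeries:
    def test_planar_zigzag_is_180(self):
        p = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0],
                      [2.0, 1.0, 0.0], [3.0, 0.0, 0.0]])
        assert abs(dihedral_deg(*p)) == pytest.approx(180.0, abs=1e-9)

    def test_rigid_input_has_zero_spread(self, ideal_base):
        traj = generate_ensemble(ideal_base, EnsembleSpec(n_frames=6, seed=0))
        ds = dihedral_series(traj, traj.topology)
        assert ds.values.shape == (6, 18, 6)
        assert np.nanmax(ds.values.std(axis=0)) < 1e-9

    def test_injected_gamma_offset_appears_exactly(self, ideal_base):
        traj = generate_ensemble(ideal_base, EnsembleSpec(n_frames=30, seed=0))
        out, _ = inject_kink(traj, KinkSpec(unit_index=5, frame_start=10,
                                            frame_end=20, bend_angle=0.0,
                                            gamma_offset=60.0))
        ds = dihedral_series(out, traj.topology)
        gi = ds.label_index("gamma")
        g = ds.values[:, 5, gi]
        delta = g[10:20] - g[0]
        assert np.abs(np.abs(delta) - 60.0).max() < 1e-6
        assert np.abs(g[:10] - g[0]).max() < 1e-9
        assert np.abs(g[20:] - g[0]).max() < 1e-9

    def test_rigid_motion_invariance(self, small_ensemble):
        traj, _ = small_ensemble
        ds0 = dihedral_series(traj, traj.topology)
        R = rotation_about_axis([1.0, 2.0, 3.0], 71.0)
        moved = Trajectory(coords=traj.coords @ R.T + np.array([5., -3., 2.]),
                           atom_names=traj.atom_names, resids=traj.resids,
                           resnames=traj.resnames, topology=traj.topology)
        ds1 = dihedral_series(moved, traj.topology)
        assert np.nanmax(np.abs(ds0.values - ds1.values)) < 1e-9


class TestCircularMode:
    def test_concentrated_sample(self):
        vals = np.array([170.0, 175.0, -178.0, 172.0, -179.0])
        m = circular_mode(vals)
        assert min(abs(m - 173.0), abs(m + 187.0)) < 8.0

    def test_ignores_nan(self):
        assert np.isfinite(circular_mode(np.array([10.0, 12.0, np.nan])))


class TestDetectKinks:
    def test_clean_ensemble_has_no_events(self, small_ensemble):
        traj, _ = small_ensemble
        ds = dihedral_series(traj, traj.topology)
        s = helix_series(traj, traj.topology)
        assert detect_kinks(ds, s.bend) == []

    def test_minor_kink_round_trip(self, ideal_base):
        traj = generate_ensemble(ideal_base,
                                 EnsembleSpec(n_frames=100, seed=1),
                                 timestep=0.01)
        out, truth = inject_kink(traj, KinkSpec(unit_index=6, frame_start=50,
                                                frame_end=53, bend_angle=0.0,
                                                gamma_offset=50.0))
        ds = dihedral_series(out, traj.topology)
        s = helix_series(out, traj.topology)
        events = detect_kinks(ds, s.bend)
        assert len(events) == 1
        ev = events[0]
        assert ev.unit_index == 6
        assert ev.kink_class == "minor"
        assert abs(ev.frame_start - 50) <= 2 and abs(ev.frame_end - 53) <= 2
        assert ev.dihedral_deltas["gamma"] == pytest.approx(50.0, abs=1.0)

    def test_major_kink_round_trip(self, ideal_base):
        traj = generate_ensemble(ideal_base,
                                 EnsembleSpec(n_frames=100, seed=2),
                                 timestep=1.0)
        out, truth = inject_kink(traj, KinkSpec(unit_index=8, frame_start=30,
                                                frame_end=80, bend_angle=40.0,
                                                gamma_offset=60.0,
                                                delta_offset=120.0))
        ds = dihedral_series(out, traj.topology)
        s = helix_series(out, traj.topology)
        events = detect_kinks(ds, s.bend)
        assert len(events) == 1
        ev = events[0]
        assert ev.kink_class == "major"
        assert ev.unit_index == truth.unit_index
        assert ev.max_bend == pytest.approx(40.0, abs=1.0)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            KinkParams(gamma_threshold=-1.0).validate()


class TestKinkRate:
    @pytest.mark.parametrize("n,total_ns,expected", [
        (12, 100.0, 120.0), (0, 50.0, 0.0), (95, 1000.0, 95.0),
    ])
    def test_rate_arithmetic(self, n, total_ns, expected):
        events = [object()] * n
        assert kink_rate(events, total_ns) == pytest.approx(expected)

    def test_zero_time_rejected(self):
        with pytest.raises(ValueError):
            kink_rate([], 0.0)


class TestUnstacking:
    def test_rigid_helix_has_none(self, small_ensemble):
        traj, _ = small_ensemble
        _, urc, _ = coarse_grain_coords(traj.coords, traj.topology)
        assert detect_unstacking(urc) == []

    def test_doubled_pair_distance_detected(self, ideal_base):
        traj = generate_ensemble(ideal_base, EnsembleSpec(n_frames=50, seed=0))
        _, urc, _ = coarse_grain_coords(traj.coords, traj.topology)
        urc = urc.copy()
        sep = urc[:, 9] - urc[:, 8]
        urc[10:15, 9:] += sep[10:15, None, :]  # doubles pair-8 spacing
        events = detect_unstacking(urc, min_dwell_frames=1, timestep=0.1)
        assert len(events) == 1
        ev = events[0]
        assert ev.pair_index == 8
        assert (ev.frame_start, ev.frame_end) == (10, 15)
        assert ev.lifetime == pytest.approx(0.5)
        assert ev.max_ratio == pytest.approx(2.0, rel=0.05)

    def test_factor_at_or_below_one_rejected(self, small_ensemble):
        traj, _ = small_ensemble
        _, urc, _ = coarse_grain_coords(traj.coords, traj.topology)
        with pytest.raises(ValueError):
            detect_unstacking(urc, factor=1.0)


class TestPhosphonateContacts:
    def _isolated_pair(self, ideal_base, d):
        """Trajectory with all groups far apart except one H..O at d Å."""
        frame, topo = ideal_base
        coords = frame.coords.copy() * 100.0  # scatter everything
        groups = topo.phosphonate_groups()
        h = groups[0]["donors"][0]
        o = groups[2]["acceptors"][0]
        coords[h] = np.array([0.0, 0.0, 0.0])
        coords[o] = np.array([d, 0.0, 0.0])
        return Trajectory(coords=coords[None], atom_names=frame.atom_names,
                          resids=frame.resids, resnames=frame.resnames,
                          topology=topo), len(groups)

    @pytest.mark.parametrize("d,bonded", [(2.4, True), (2.5, False),
                                          (2.6, False)])
    def test_cutoff_boundary_is_strict(self, ideal_base, d, bonded):
        traj, n_groups = self._isolated_pair(ideal_base, d)
        stats = phosphonate_contacts(traj, traj.topology)
        expected = 2.0 / n_groups if bonded else 0.0
        assert stats.hbond_fraction[0] == pytest.approx(expected)

    def test_intra_group_contact_never_counted(self, ideal_base):
        frame, topo = ideal_base
        coords = frame.coords.copy() * 100.0
        g = topo.phosphonate_groups()[0]
        coords[g["donors"][0]] = np.array([0.0, 0.0, 0.0])
        coords[g["acceptors"][0]] = np.array([1.0, 0.0, 0.0])
        traj = Trajectory(coords=coords[None], atom_names=frame.atom_names,
                          resids=frame.resids, resnames=frame.resnames,
                          topology=topo)
        assert phosphonate_contacts(traj, topo).hbond_fraction[0] == 0.0

    def test_half_bonded_fraction(self, ideal_base):
        frame, topo = ideal_base
        coords = frame.coords.copy() * 100.0
        groups = topo.phosphonate_groups()
        # bond 9 disjoint pairs -> 18 of 36 groups in >= 1 bond
        for pair_i in range(9):
            g1, g2 = groups[4 * pair_i], groups[4 * pair_i + 2]
            base = np.array([9000.0 + 300.0 * pair_i, 9000.0, 9000.0])
            coords[g1["donors"][0]] = base
            coords[g2["acceptors"][0]] = base + np.array([2.0, 0.0, 0.0])
        traj = Trajectory(coords=coords[None], atom_names=frame.atom_names,
                          resids=frame.resids, resnames=frame.resnames,
                          topology=topo)
        stats = phosphonate_contacts(traj, topo)
        assert stats.hbond_fraction[0] == pytest.approx(0.5)

    def test_fraction_monotone_in_cutoff(self, small_ensemble):
        traj, _ = small_ensemble
        sub = Trajectory(coords=traj.coords[:20], atom_names=traj.atom_names,
                         resids=traj.resids, resnames=traj.resnames,
                         topology=traj.topology)
        fracs = [phosphonate_contacts(sub, traj.topology, hbond_cutoff=c)
                 .hbond_fraction.mean() for c in (1.0, 2.5, 4.0, 8.0)]
        assert all(a <= b + 1e-12 for a, b in zip(fracs, fracs[1:]))

    def test_no_phosphonates_warns_and_returns_empty(self):
        from foldhelix import HelixSpec, build_ideal_helix

        frame, topo = build_ideal_helix(HelixSpec(include_phosphonate=False))
        traj = generate_ensemble((frame, topo), EnsembleSpec(n_frames=2))
        with pytest.warns(UserWarning, match="phosphonate"):
            stats = phosphonate_contacts(traj, topo)
        assert stats.pp_distances.shape == (2, 0)
        assert np.all(stats.hbond_fraction == 0.0)
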