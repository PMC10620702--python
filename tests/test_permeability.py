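"""Crossing detection, collective coordinate and pf estimation tests."""

import numpy as np
import pytest

import permlab as pl
from conftest import make_membership, make_frames


def brute_force_crossings(inside, side):
    """Independent state machine over one water's frame labels."""
    events = []
    run_start = None
    entry = None
    for f in range(len(inside)):
        if inside[f] and run_start is None:
            run_start = f
            entry = side[f - 1] if f > 0 else None
        elif not inside[f] and run_start is not None:
            if entry in (-1, 1) and side[f] == -entry:
                events.append((run_start, f, "up" if entry == -1 else "down"))
            run_start = None
    return events


class TestDetectCrossings:
    def test_monotonic_traversal_counts_once_upward(self):
        inside = [False, True, True, True, False]
        side = [-1, 0, 0, 0, 1]
        membership = make_membership(inside, side)
        events = pl.detect_crossings(membership, make_frames(5))
        assert len(events) == 1
        assert events[0].direction == "up"
        assert events[0].t_enter == 1.0 and events[0].t_exit == 4.0

    def test_retreat_through_entry_face_is_no_event(self):
        membership = make_membership([False, True, True, False],
                                     [-1, 0, 0, -1])
        assert pl.detect_crossings(membership, make_frames(4)) == []

    def test_wall_entry_is_no_event(self):
        # side 0 before the run: the water slipped through the cylinder wall
        membership = make_membership([False, True, True, False],
                                     [0, 0, 0, 1])
        assert pl.detect_crossings(membership, make_frames(4)) == []

    def test_truncated_runs_do_not_count(self):
        membership = make_membership([True, True, False], [0, 0, 1])
        assert pl.detect_crossings(membership, make_frames(3)) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_state_machine(self, seed):
        rng = np.random.default_rng(seed)
        n_frames, n_waters = 200, 50
        region = pl.PoreRegion(monomer_label="A", center_xy=np.zeros(2),
                               radius=6.0, z_low=30.0, z_high=60.0)
        side = rng.choice([-1, 0, 1], size=(n_frames, n_waters),
                          p=[0.35, 0.3, 0.35]).astype(np.int8)
        inside = (side == 0) & (rng.uniform(size=side.shape) < 0.8)
        membership = pl.RegionMembership(
            water_indices=np.arange(n_waters), regions=[region],
            inside=inside[:, :, None], side=side)
        events = pl.detect_crossings(membership, make_frames(n_frames,
                                                             n_waters))
        expected = []
        for w in range(n_waters):
            expected.extend((f0, f1, d) for f0, f1, d
                            in brute_force_crossings(inside[:, w],
                                                     side[:, w]))
        got = sorted((e.t_enter, e.t_exit, e.direction) for e in events)
        assert got == sorted((float(a), float(b), d)
                             for a, b, d in expected)

    def test_time_reversal_swaps_directions(self, null_system, null_regions):
        particles, frames, _ = null_system
        regions, membership = null_regions
        events = pl.detect_crossings(membership, frames, regions)
        reversed_frames = pl.FrameSeries(
            times=frames.times,
            coordinates=frames.coordinates[::-1].copy(),
            box=frames.box)
        membership_r = pl.assign_waters(particles, reversed_frames, regions)
        events_r = pl.detect_crossings(membership_r, reversed_frames, regions)
        assert len(events) == len(events_r)
        fwd = sorted(e.direction for e in events)
        rev = sorted({"up": "down", "down": "up"}[e.direction]
                     for e in events_r)
        assert fwd == rev


class TestCountCrossings:
    def _events(self):
        return [pl.CrossingEvent(0, "A", 1.0, 2.0, "up"),
                pl.CrossingEvent(1, "A", 3.0, 5.0, "down"),
                pl.CrossingEvent(2, "B", 4.0, 8.0, "up")]

    def test_window_counts(self):
        assert pl.count_crossings(self._events(), (0.0, 10.0)) == 3
        assert pl.count_crossings(self._events(), (10.0, 20.0)) == 0

    def test_monomer_split_sums_to_tetramer(self):
        events = self._events()
        per = pl.count_crossings(events, (0.0, 10.0), per="monomer")
        assert sum(per.values()) == pl.count_crossings(events, (0.0, 10.0))

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            pl.count_crossings(self._events(), (5.0, 5.0))


class TestCollectiveCoordinate:
    def _system(self, z_path):
        """Single water moving along the axis of a 30 A section."""
        n = len(z_path)
        region = pl.PoreRegion(monomer_label="A",
                               center_xy=np.array([20.0, 20.0]), radius=6.0,
                               z_low=30.0, z_high=60.0)
        coords = np.zeros((n, 1, 3), dtype=np.float32)
        coords[:, 0, :2] = 20.0
        coords[:, 0, 2] = z_path
        frames = pl.FrameSeries(times=np.arange(n, dtype=float),
                                coordinates=coords,
                                box=np.tile([40.0, 40.0, 90.0], (n, 1)))
        inside = ((np.asarray(z_path) >= 30) & (np.asarray(z_path) <= 60))
        membership = pl.RegionMembership(
            water_indices=np.array([0]), regions=[region],
            inside=inside[:, None, None],
            side=np.zeros((n, 1), np.int8))
        return membership, frames, region

    def test_full_length_displacement_gives_unit_n(self):
        membership, frames, region = self._system([30.0, 40, 50, 60.0])
        series = pl.collective_coordinate(membership, frames, region)
        assert series.n[-1] == pytest.approx(1.0)

    def test_immobile_waters_give_zero(self):
        membership, frames, region = self._system([45.0] * 5)
        series = pl.collective_coordinate(membership, frames, region)
        assert np.all(series.n == 0)

    def test_matches_hand_summed_displacements(self):
        rng = np.random.default_rng(0)
        z = 45 + np.cumsum(rng.normal(0, 2, 50))
        z = np.clip(z, 31, 59)
        membership, frames, region = self._system(z)
        series = pl.collective_coordinate(membership, frames, region)
        assert series.n[-1] == pytest.approx((z[-1] - z[0]) / 30.0, rel=1e-5)


class TestEstimateDn:
    def _brownian_series(self, d_true, n_frames=20000, dt=0.01, seed=0):
        rng = np.random.default_rng(seed)
        n = np.concatenate([[0.0], np.cumsum(
            rng.normal(0, np.sqrt(2 * d_true * dt), n_frames - 1))])
        return pl.CollectiveCoordinateSeries(
            monomer_label="A", times=np.arange(n_frames) * dt, n=n, L=30.0)

    @pytest.mark.parametrize("d_true", [0.2, 0.7])
    def test_recovers_known_diffusion(self, d_true):
        series = self._brownian_series(d_true)
        d_est, stderr, _ = pl.estimate_Dn(series)
        assert abs(d_est - d_true) < 3 * stderr
        assert abs(d_est - d_true) / d_true < 0.2

    def test_constant_series_gives_zero(self):
        series = pl.CollectiveCoordinateSeries(
            monomer_label="A", times=np.arange(1000) * 0.01,
            n=np.zeros(1000), L=30.0)
        d_est, _, _ = pl.estimate_Dn(series)
        assert d_est == pytest.approx(0.0, abs=1e-12)

    def test_linear_drift_flagged_as_nonlinear(self):
        t = np.arange(5000) * 0.01
        series = pl.CollectiveCoordinateSeries(
            monomer_label="A", times=t, n=2.0 * t, L=30.0)
        _, _, nonlin = pl.estimate_Dn(series)
        # MSD = (c*lag)^2 is purely quadratic
        assert nonlin > 0.5

    def test_window_beyond_span_rejected(self):
        series = self._brownian_series(0.5, n_frames=150)
        with pytest.raises(ValueError):
            pl.estimate_Dn(series, fit_window=(0.1, 2.0))

    def test_halved_sampling_rate_consistent(self):
        series = self._brownian_series(0.5)
        coarse = pl.CollectiveCoordinateSeries(
            monomer_label="A", times=series.times[::2], n=series.n[::2],
            L=30.0)
        d_fine, se, _ = pl.estimate_Dn(series)
        d_coarse, se2, _ = pl.estimate_Dn(coarse)
        assert abs(d_fine - d_coarse) < 3 * max(se, se2)


class TestComputePf:
    def test_zero_diffusion_zero_pf(self):
        assert pl.compute_pf(0.0).pf_cm3_per_s == 0.0

    def test_known_conversion(self):
        # D_n = 0.669/ns corresponds to ~2e-14 cm^3/s
        pf = pl.compute_pf(0.669).pf_cm3_per_s
        assert pf == pytest.approx(2.0e-14, rel=2e-3)

    def test_negative_diffusion_rejected(self):
        with pytest.raises(ValueError):
            pl.compute_pf(-0.1)


def test_equilibrium_up_down_balance(null_regions, null_system):
    """Without a gradient, up and down crossings balance within noise."""
    _, frames, _ = null_system
    regions, membership = null_regions
    events = pl.detect_crossings(membership, frames, regions)
    ups = sum(e.direction == "up" for e in events)
    downs = len(events) - ups
    assert abs(ups - downs) <= 4 * np.sqrt(len(events) or 1)
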