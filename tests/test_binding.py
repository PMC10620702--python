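"""Hydrogen bonds, bound windows, contact scoring and K_D tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import permlab as pl
from permlab.binding import CONTACT_CLASSES, _contact_class


def _hbond_system(d_da=3.0, angle_deg=10.0):
    """Ligand hydroxyl donating to one protein acceptor oxygen."""
    names = np.array(["O1", "H2", "C3", "O1", "C2"])
    resnames = np.array(["LIGA", "LIGA", "LIGA", "ARGA", "ARGA"])
    resids = np.array([500, 500, 500, 187, 187])
    particles = pl.trajectory_io.particles_from_labels(
        names, resnames, resids, pl.SelectionConfig())
    donor = np.array([0.0, 0.0, 0.0])
    theta = np.deg2rad(angle_deg)
    acceptor = donor + d_da * np.array([np.sin(theta), 0, np.cos(theta)])
    hydrogen = donor + np.array([0.0, 0.0, 0.97])   # along +z
    coords = np.array([[donor, hydrogen, [5.0, 5.0, 0.0], acceptor,
                        acceptor + [1.3, 0, 0]]], dtype=np.float32)
    frames = pl.FrameSeries(times=np.array([0.0]), coordinates=coords,
                            box=np.tile([50.0, 50.0, 50.0], (1, 1)))
    return particles, frames


class TestDetectHbonds:
    def test_geometry_within_criteria_reported(self):
        particles, frames = _hbond_system(3.0, 10.0)
        series = pl.detect_hbonds(particles, frames)
        assert len(series.bonds) == 1
        assert series.bound_to_anchor[0]

    def test_distance_violation_rejected(self):
        particles, frames = _hbond_system(3.6, 10.0)
        series = pl.detect_hbonds(particles, frames)
        assert len(series.bonds) == 0

    def test_angle_violation_rejected(self):
        particles, frames = _hbond_system(3.0, 40.0)
        series = pl.detect_hbonds(particles, frames)
        assert len(series.bonds) == 0

    def test_no_polar_atoms_rejected(self):
        particles, frames = _hbond_system()
        mask = particles.elements == "C"
        with pytest.raises(ValueError, match="polar"):
            pl.detect_hbonds(particles, frames, ligand_mask=mask,
                             protein_mask=particles.mask("protein"))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_geometric_oracle(self, seed):
        """Random donor/acceptor geometries against a plain-loop check."""
        rng = np.random.default_rng(seed)
        particles, frames = _hbond_system()
        n_trials = 50
        hits_pkg, hits_oracle = 0, 0
        for _ in range(n_trials):
            coords = frames.coordinates.copy()
            coords[0, 3] = rng.uniform(-1, 1, 3) * 3.0   # acceptor
            coords[0, 1] = rng.normal(0, 0.6, 3)          # hydrogen
            coords[0, 1] *= 0.97 / np.linalg.norm(coords[0, 1])
            f2 = pl.FrameSeries(times=frames.times, coordinates=coords,
                                box=frames.box)
            series = pl.detect_hbonds(particles, f2)
            hits_pkg += int(len(series.bonds) > 0)
            da = coords[0, 3] - coords[0, 0]
            dh = coords[0, 1] - coords[0, 0]
            cos = np.dot(da, dh) / (np.linalg.norm(da) * np.linalg.norm(dh))
            ok = (np.linalg.norm(da) <= 3.5
                  and np.degrees(np.arccos(np.clip(cos, -1, 1))) <= 30.0)
            hits_oracle += int(ok)
            assert (len(series.bonds) > 0) == ok
        assert hits_pkg == hits_oracle

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            pl.HBondCriteria(max_da_distance=-1.0)
        with pytest.raises(ValueError):
            pl.HBondCriteria(max_hda_angle=120.0)


def _series_from_bool(bound, dt=1.0):
    return pl.HBondSeries(times=np.arange(len(bound)) * dt,
                          bonds=pd.DataFrame(),
                          bound_to_anchor=np.asarray(bound, bool))


def exhaustive_best_window(bound, times, span, stride):
    best = (-1.0, None)
    t0 = times[0]
    while t0 + span <= times[-1] + 1e-9:
        mask = (times >= t0 - 1e-9) & (times < t0 + span - 1e-9)
        freq = bound[mask].mean()
        if freq > best[0] + 1e-12:
            best = (freq, t0)
        t0 += stride
    return best


class TestBestBoundWindow:
    def test_all_bound_gives_first_window(self):
        win = pl.best_bound_window(_series_from_bool([True] * 101), span=50)
        assert (win.t_start, win.t_end) == (0.0, 50.0)
        assert win.hbond_frequency == 1.0

    def test_block_of_binding_found(self):
        bound = np.zeros(201, bool)
        bound[120:181] = True
        win = pl.best_bound_window(_series_from_bool(bound), span=50)
        assert 115 <= win.t_start <= 130
        assert win.hbond_frequency > 0.9

    def test_never_bound_warns(self):
        with pytest.warns(UserWarning, match="never"):
            win = pl.best_bound_window(_series_from_bool([False] * 101),
                                       span=50)
        assert win.hbond_frequency == 0.0

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            pl.best_bound_window(_series_from_bool([True] * 10), span=50)

    @pytest.mark.parametrize("seed", range(100))
    def test_equals_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        bound = rng.uniform(size=151) < rng.uniform(0.1, 0.9)
        series = _series_from_bool(bound)
        win = pl.best_bound_window(series, span=50, stride=1)
        freq, t0 = exhaustive_best_window(bound, series.times, 50, 1)
        assert win.hbond_frequency == pytest.approx(freq)
        assert win.t_start == pytest.approx(t0)


def _toy_pose(seed, n_lig=20, n_pro=30):
    rng = np.random.default_rng(seed)
    elems = np.array(list("CNOSPH"))
    lig_e = rng.choice(elems, n_lig)
    pro_e = rng.choice(elems, n_pro)
    names = ([f"{e}{i}" for i, e in enumerate(lig_e, 1)]
             + [f"{e}{i}" for i, e in enumerate(pro_e, 1)])
    resnames = ["LIGA"] * n_lig + ["RNGA"] * n_pro
    resids = [900] * n_lig + [1] * n_pro
    particles = pl.trajectory_io.particles_from_labels(
        np.array(names), np.array(resnames), np.array(resids),
        pl.SelectionConfig())
    coords = rng.uniform(0, 25, (n_lig + n_pro, 3))
    return particles, coords


def _two_atom_pose(separation):
    particles = pl.trajectory_io.particles_from_labels(
        np.array(["C1", "N1"]), np.array(["LIGA", "RNGA"]),
        np.array([900, 1]), pl.SelectionConfig())
    coords = np.array([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]])
    return particles, coords


class TestCountContacts:
    def test_pair_just_inside_cutoff(self):
        particles, coords = _two_atom_pose(10.4)
        counts = pl.count_contacts(particles, coords,
                                   particles.mask("ligand"),
                                   particles.mask("protein"), cutoff=10.5)
        assert counts["CN"] == 1 and sum(counts.values()) == 1

    def test_pair_just_outside_cutoff(self):
        particles, coords = _two_atom_pose(10.6)
        counts = pl.count_contacts(particles, coords,
                                   particles.mask("ligand"),
                                   particles.mask("protein"), cutoff=10.5)
        assert sum(counts.values()) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pair_enumeration_oracle(self, seed):
        particles, coords = _toy_pose(seed)
        counts = pl.count_contacts(particles, coords,
                                   particles.mask("ligand"),
                                   particles.mask("protein"), cutoff=10.5)
        expected = dict.fromkeys(CONTACT_CLASSES, 0)
        lig = np.flatnonzero(particles.mask("ligand"))
        pro = np.flatnonzero(particles.mask("protein"))
        for i in lig:
            for j in pro:
                if particles.elements[i] == "H" \
                        or particles.elements[j] == "H":
                    continue
                if np.linalg.norm(coords[i] - coords[j]) <= 10.5:
                    expected[_contact_class(particles.elements[i],
                                            particles.elements[j])] += 1
        assert counts == expected

    def test_symmetric_under_role_swap(self):
        particles, coords = _toy_pose(3)
        a = pl.count_contacts(particles, coords, particles.mask("ligand"),
                              particles.mask("protein"), cutoff=10.5)
        b = pl.count_contacts(particles, coords, particles.mask("protein"),
                              particles.mask("ligand"), cutoff=10.5)
        assert a == b

    def test_empty_selection_rejected(self):
        particles, coords = _toy_pose(0)
        with pytest.raises(ValueError):
            pl.count_contacts(particles, coords,
                              np.zeros(particles.n_atoms, bool),
                              particles.mask("protein"), cutoff=10.5)


class TestScoring:
    def test_zero_counts_give_intercept(self):
        coeff = pl.ScoringCoefficients(intercept=-5.0, weights={})
        assert pl.score_binding_energy(
            dict.fromkeys(CONTACT_CLASSES, 0), coeff) == -5.0

    def test_unit_counts_unit_weights(self):
        coeff = pl.ScoringCoefficients(
            intercept=0.0, weights=dict.fromkeys(CONTACT_CLASSES, 1.0))
        counts = dict.fromkeys(CONTACT_CLASSES, 1)
        assert pl.score_binding_energy(counts, coeff) == len(CONTACT_CLASSES)

    def test_missing_weight_for_observed_class(self):
        coeff = pl.ScoringCoefficients(intercept=0.0, weights={"CC": -1.0})
        with pytest.raises(ValueError, match="OO"):
            pl.score_binding_energy({"CC": 1, "OO": 2}, coeff)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_dot_product(self, seed):
        rng = np.random.default_rng(seed)
        weights = {c: rng.normal() for c in CONTACT_CLASSES}
        counts = {c: int(rng.integers(0, 30)) for c in CONTACT_CLASSES}
        coeff = pl.ScoringCoefficients(intercept=rng.normal(),
                                       weights=weights)
        expected = coeff.intercept + np.dot(
            [weights[c] for c in CONTACT_CLASSES],
            [counts[c] for c in CONTACT_CLASSES])
        assert pl.score_binding_energy(counts, coeff) == pytest.approx(
            expected, abs=1e-12)

    def test_default_coefficients_complete(self):
        coeff = pl.ScoringCoefficients.default()
        assert set(coeff.weights) == set(CONTACT_CLASSES)
        assert coeff.cutoff > 0


class TestKdConversion:
    def test_zero_energy_is_one_molar(self):
        assert pl.kd_from_dg(0.0) == pytest.approx(1e9)

    def test_hundred_nanomolar_point(self):
        kd = pl.kd_from_dg(-9.93, 310.15)
        assert kd == pytest.approx(100.0, rel=0.01)

    @given(st.floats(min_value=-15, max_value=2),
           st.floats(min_value=250, max_value=370))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip_identity(self, dg, temperature):
        back = pl.dg_from_kd(pl.kd_from_dg(dg, temperature), temperature)
        assert back == pytest.approx(dg, abs=1e-10)

    @given(st.floats(min_value=-15, max_value=0),
           st.floats(min_value=0.01, max_value=5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotonicity(self, dg, delta):
        assert pl.kd_from_dg(dg - delta) < pl.kd_from_dg(dg)


class TestAffinityOverTrajectory:
    def test_constant_pose_median_equals_mean(self, null_system):
        particles, frames, manifest = pl.make_preset(
            "inhibited", seed=3, duration_ns=10.0, frame_interval_ns=1.0,
            bulk_density=0.0)
        est = pl.affinity_over_trajectory(particles, frames)
        assert est.kd_median_nM == pytest.approx(est.kd_mean_nM, rel=1e-9)
        assert est.kd_median_nM == pytest.approx(
            manifest.ligand["bound"]["KD_nM"], rel=1e-6)

    def test_two_state_median_tracks_majority(self, two_state_system):
        particles, frames, manifest = two_state_system
        est = pl.affinity_over_trajectory(particles, frames,
                                          sample_stride_ns=0.5)
        states = np.array(manifest.ligand["states_per_frame_bound"])
        majority = ("bound" if states.mean() > 0.5 else "unbound")
        assert est.kd_median_nM == pytest.approx(
            manifest.ligand[majority]["KD_nM"], rel=1e-6)

    def test_unbound_frames_score_the_intercept(self, two_state_system):
        particles, frames, manifest = two_state_system
        states = np.array(manifest.ligand["states_per_frame_bound"])
        assert (~states).any(), "fixture seed must visit the unbound state"
        f = int(np.flatnonzero(~states)[0])
        counts = pl.count_contacts(
            particles, frames.coordinates[f].astype(float),
            particles.mask("ligand"), particles.mask("protein"),
            cutoff=pl.ScoringCoefficients.default().cutoff)
        assert sum(counts.values()) == 0
        dg = pl.score_binding_energy(counts,
                                     pl.ScoringCoefficients.default())
        assert dg == pl.ScoringCoefficients.default().intercept

    def test_ligand_free_system_rejected(self, null_system):
        particles, frames, _ = null_system
        with pytest.raises(ValueError, match="ligand"):
            pl.affinity_over_trajectory(particles, frames)
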