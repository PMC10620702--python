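"""Shared synthetic fixtures; everything is generated at run time."""

import numpy as np
import pytest

import permlab as pl


@pytest.fixture(scope="session")
def null_system():
    """Short steroid-free tetramer with bulk water and lipids."""
    return pl.make_preset("null", seed=11, duration_ns=20.0,
                          frame_interval_ns=0.2)


@pytest.fixture(scope="session")
def two_state_system():
    """200 ns system with a Markov-switching ligand (no bulk water)."""
    return pl.make_preset("two-state", seed=5, duration_ns=200.0,
                          frame_interval_ns=0.5, bulk_density=0.0)


@pytest.fixture(scope="session")
def null_regions(null_system):
    particles, frames, _ = null_system
    regions = pl.define_pore_regions(particles, frames)
    membership = pl.assign_waters(particles, frames, regions)
    return regions, membership


def make_membership(inside_column, side_column, region=None):
    """Hand-built single-water membership for crossing-logic tests."""
    region = region or pl.PoreRegion(monomer_label="A",
                                     center_xy=np.zeros(2), radius=6.0,
                                     z_low=30.0, z_high=60.0)
    inside = np.asarray(inside_column, bool)[:, None, None]
    side = np.asarray(side_column, np.int8)[:, None]
    return pl.RegionMembership(water_indices=np.array([0]),
                               regions=[region], inside=inside, side=side)


def make_frames(n_frames, n_atoms=1, box=(90.0, 90.0, 90.0), dt=1.0):
    return pl.FrameSeries(
        times=np.arange(n_frames) * dt,
        coordinates=np.zeros((n_frames, n_atoms, 3), dtype=np.float32),
        box=np.tile(box, (n_frames, 1)))
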