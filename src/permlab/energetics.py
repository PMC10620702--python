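"""Axial water density and Gibbs free-energy profiles along the pore.

The pore section is sliced along z in 0.5 A bins; the mean water-oxygen
number density per slice, referenced to the bulk density, yields the
potential of mean force by Boltzmann inversion:

    G(z) = -kT ln( rho(z) / rho_bulk )

Slices never visited by a water would give infinite G; they are assigned
a finite cap (default 6 kcal/mol) and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import kT
from .trajectory_io import (ParticleSet, FrameSeries, PoreRegion,
                            RegionMembership)


@dataclass
class DensityProfile:
    z_centers: np.ndarray      # A
    rho: np.ndarray            # 1/A^3
    rho_bulk: float            # 1/A^3
    n_frames: int
    slice_width: float = 0.5

    def __post_init__(self) -> None:
        if np.any(self.rho < 0):
            raise ValueError("densities must be non-negative")
        # rho_bulk may be NaN until a bulk estimate is attached
        if np.isfinite(self.rho_bulk) and self.rho_bulk <= 0:
            raise ValueError("bulk density must be positive")


@dataclass
class FreeEnergyProfile:
    z_centers: np.ndarray
    G: np.ndarray              # kcal/mol
    temperature: float
    cap: float
    capped: np.ndarray = field(default_factory=lambda: np.array([], int))

    def in_kT(self) -> np.ndarray:
        return self.G / kT(self.temperature)


def density_profile(membership: RegionMembership, frames: FrameSeries,
                    region: PoreRegion, slice_width: float = 0.5
                    ) -> DensityProfile:
    """Mean water-oxygen density per axial slice of one pore."""
    if frames.n_frames == 0:
        raise ValueError("no frames")
    if slice_width <= 0:
        raise ValueError("slice width must be positive")
    r = membership.regions.index(region)
    z = frames.coordinates[:, membership.water_indices, 2].astype(float)
    z = np.mod(z, frames.box[:, 2][:, None])
    z_in = z[membership.inside[:, :, r]]
    n_slices = int(np.ceil(region.length / slice_width - 1e-9))
    edges = region.z_low + slice_width * np.arange(n_slices + 1)
    counts, _ = np.histogram(z_in, bins=edges)
    slice_volume = np.pi * region.radius ** 2 * slice_width
    rho = counts / (frames.n_frames * slice_volume)
    return DensityProfile(
        z_centers=0.5 * (edges[:-1] + edges[1:]), rho=rho,
        rho_bulk=np.nan, n_frames=frames.n_frames, slice_width=slice_width)


def bulk_density(particles: ParticleSet, frames: FrameSeries,
                 bulk_z_range: tuple[float, float],
                 membrane_z_range: tuple[float, float] | None = None,
                 ) -> float:
    """Water-oxygen number density in a bulk z-slab (full box cross-section).

    Warns when the slab overlaps the declared membrane span: densities
    sampled there are depleted and bias the profile reference.
    """
    z0, z1 = bulk_z_range
    if z1 <= z0:
        raise ValueError("empty bulk region")
    if membrane_z_range is not None:
        m0, m1 = membrane_z_range
        if z0 < m1 and z1 > m0:
            warnings.warn("bulk slab overlaps the membrane z-span; "
                          "the density estimate will be biased low")
    widx = particles.water_oxygen_indices
    z = frames.coordinates[:, widx, 2].astype(float)
    z = np.mod(z, frames.box[:, 2][:, None])
    counts = ((z >= z0) & (z < z1)).sum(axis=1)
    volumes = frames.box[:, 0] * frames.box[:, 1] * (z1 - z0)
    return float(np.mean(counts / volumes))


def free_energy_profile(density: DensityProfile, temperature: float = 310.15,
                        rho_bulk: float | None = None,
                        cap: float = 6.0) -> FreeEnergyProfile:
    """Boltzmann inversion of a density profile.

    ``rho_bulk`` overrides the value stored on the profile.  Empty slices
    receive the cap value and are listed in ``capped``.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    bulk = density.rho_bulk if rho_bulk is None else rho_bulk
    if not np.isfinite(bulk) or bulk <= 0:
        raise ValueError("a positive bulk density is required")
    kt = kT(temperature)
    with np.errstate(divide="ignore"):
        G = -kt * np.log(density.rho / bulk)
    capped = np.flatnonzero(~np.isfinite(G) | (G > cap))
    G = np.where(np.isfinite(G), np.minimum(G, cap), cap)
    return FreeEnergyProfile(z_centers=density.z_centers, G=G,
                             temperature=temperature, cap=cap, capped=capped)


def rebin_pairwise(profile: DensityProfile) -> DensityProfile:
    """Merge adjacent slices pairwise (halved resolution); used to check
    that profiles are stable under re-binning."""
    rho = profile.rho
    if len(rho) % 2:
        rho = rho[:-1]
    z = profile.z_centers[:len(rho)]
    return DensityProfile(
        z_centers=0.5 * (z[0::2] + z[1::2]),
        rho=0.5 * (rho[0::2] + rho[1::2]),
        rho_bulk=profile.rho_bulk, n_frames=profile.n_frames,
        slice_width=profile.slice_width * 2)
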