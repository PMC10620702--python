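"""System loading, atom-role resolution and pore geometry.

Reads standard MD topology/trajectory formats through MDAnalysis, resolves
named selections (waters, ligand, protein monomers, the ar/R anchor
arginine) into atom roles, and builds one cylindrical pore region per
monomer of the tetramer.  All downstream analyses (permeation counting,
the collective coordinate, density profiles, hydrogen bonds) operate on
the plain-array containers defined here, never on file handles.

Conventions: coordinates in Angstrom, times in ns, the membrane normal is
the z axis of the box.  Unit conversion happens at the I/O boundary only.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

#: atom roles
ROLE_WATER_O = "water_oxygen"
ROLE_PROTEIN = "protein"
ROLE_LIGAND = "ligand"
ROLE_ION = "ion"
ROLE_LIPID = "lipid"

_MONOMER_LETTERS = "ABCDEFGH"


@dataclass
class SelectionConfig:
    """Named selections mapping topology labels to roles.

    Monomer assignment uses a resname-suffix convention: protein and
    ligand residue names consist of a prefix plus one letter (A-D) naming
    the monomer, e.g. ``RNGA``/``ARGB``/``LIGA``.
    """

    water_resnames: tuple[str, ...] = ("SOL", "TIP3", "WAT", "HOH")
    ligand_prefixes: tuple[str, ...] = ("LIG",)
    protein_prefixes: tuple[str, ...] = ("RNG", "ARG")
    lipid_resnames: tuple[str, ...] = ("POPC", "POPE", "DPPC")
    anchor_prefix: str = "ARG"
    anchor_resid: int = 187
    radius: float = 6.0
    section_length: float = 30.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SelectionConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("water_resnames", "ligand_prefixes", "protein_prefixes",
                    "lipid_resnames"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        anchor = raw.get("anchor", {})
        if "prefix" in anchor:
            kwargs["anchor_prefix"] = anchor["prefix"]
        if "resid" in anchor:
            kwargs["anchor_resid"] = int(anchor["resid"])
        for key in ("radius", "section_length"):
            if key in raw:
                kwargs[key] = float(raw[key])
        return cls(**kwargs)


@dataclass
class ParticleSet:
    """Per-atom topology labels and resolved roles."""

    atom_ids: np.ndarray          # (n,) int
    elements: np.ndarray          # (n,) str
    residue_names: np.ndarray     # (n,) str
    residue_ids: np.ndarray       # (n,) int
    roles: np.ndarray             # (n,) str
    monomer_labels: np.ndarray    # (n,) str, "" where not applicable

    def __post_init__(self) -> None:
        if len(np.unique(self.atom_ids)) != len(self.atom_ids):
            raise ValueError("atom_ids must be unique")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_ids)

    def mask(self, role: str) -> np.ndarray:
        return self.roles == role

    @property
    def water_oxygen_indices(self) -> np.ndarray:
        return np.flatnonzero(self.roles == ROLE_WATER_O)

    def monomers(self) -> list[str]:
        labels = sorted(set(self.monomer_labels[self.roles == ROLE_PROTEIN]))
        return [m for m in labels if m]


@dataclass
class FrameSeries:
    """Time-ordered coordinates with box dimensions.

    times in ns (strictly increasing), coordinates (n_frames, n_atoms, 3)
    in Angstrom, box (n_frames, 3) orthorhombic box lengths in Angstrom.
    """

    times: np.ndarray
    coordinates: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, atoms, 3)")
        if len(self.times) != len(self.coordinates):
            raise ValueError("times and coordinates disagree on frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        self.box = np.asarray(self.box, dtype=float)
        if self.box.shape != (len(self.times), 3):
            raise ValueError("box must have shape (frames, 3)")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def dt(self) -> float:
        """Median frame spacing in ns."""
        return float(np.median(np.diff(self.times)))


@dataclass
class PoreRegion:
    """Cylindrical conducting-pore section of one monomer."""

    monomer_label: str
    center_xy: np.ndarray
    radius: float
    z_low: float
    z_high: float
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("pore radius must be positive")
        if self.z_high <= self.z_low:
            raise ValueError("z_high must exceed z_low")
        self.center_xy = np.asarray(self.center_xy, dtype=float)

    @property
    def length(self) -> float:
        return self.z_high - self.z_low


@dataclass
class RegionMembership:
    """Per-frame pore occupancy of every water oxygen.

    ``inside[f, w, r]`` is True when water ``w`` lies inside region ``r``
    at frame ``f``; ``side[f, w]`` is -1 below, 0 within and +1 above the
    common z-section of the regions.
    """

    water_indices: np.ndarray     # (W,) indices into ParticleSet
    regions: list[PoreRegion]
    inside: np.ndarray            # (F, W, R) bool
    side: np.ndarray              # (F, W) int8

    def __post_init__(self) -> None:
        if np.any(self.inside.sum(axis=2) > 1):
            raise ValueError("a water cannot occupy two pores at once")


def _element_from_name(name: str) -> str:
    """Infer a chemical element from an atom name (GRO has no element field)."""
    m = re.match(r"[A-Za-z]+", name.strip())
    head = (m.group(0) if m else "C").upper()
    two = head[:2].capitalize()
    if two in ("Cl", "Na", "Br", "Mg", "Ca", "Zn", "Fe"):
        return two
    return head[0]


def _resolve_roles(resnames: np.ndarray, resids: np.ndarray,
                   elements: np.ndarray, config: SelectionConfig
                   ) -> tuple[np.ndarray, np.ndarray]:
    n = len(resnames)
    roles = np.full(n, ROLE_ION, dtype=object)
    monomer = np.full(n, "", dtype=object)
    water = np.isin(resnames, config.water_resnames)
    roles[water & (elements == "O")] = ROLE_WATER_O
    roles[water & (elements != "O")] = "water_other"
    roles[np.isin(resnames, config.lipid_resnames)] = ROLE_LIPID
    for i, (rn, _) in enumerate(zip(resnames, resids)):
        if water[i] or rn in config.lipid_resnames:
            continue
        for prefix in config.ligand_prefixes:
            if rn.startswith(prefix):
                roles[i] = ROLE_LIGAND
                if len(rn) > len(prefix) and rn[-1] in _MONOMER_LETTERS:
                    monomer[i] = rn[-1]
                break
        else:
            for prefix in config.protein_prefixes:
                if rn.startswith(prefix):
                    roles[i] = ROLE_PROTEIN
                    if len(rn) > len(prefix) and rn[-1] in _MONOMER_LETTERS:
                        monomer[i] = rn[-1]
                    break
    return roles.astype(str), monomer.astype(str)


def particles_from_labels(atom_names: np.ndarray, resnames: np.ndarray,
                          resids: np.ndarray, config: SelectionConfig
                          ) -> ParticleSet:
    """Build a ParticleSet from raw topology labels."""
    elements = np.array([_element_from_name(n) for n in atom_names])
    roles, monomer = _resolve_roles(np.asarray(resnames, dtype=str),
                                    np.asarray(resids), elements, config)
    return ParticleSet(
        atom_ids=np.arange(len(atom_names)),
        elements=elements,
        residue_names=np.asarray(resnames, dtype=str),
        residue_ids=np.asarray(resids, dtype=int),
        roles=roles,
        monomer_labels=monomer,
    )


def load_system(topology_path: str | Path, trajectory_path: str | Path,
                selection_config: SelectionConfig | str | Path | None = None,
                ) -> tuple[ParticleSet, FrameSeries]:
    """Read topology + trajectory files and resolve atom roles.

    Raises ValueError on atom-count mismatch between the two files and on
    non-monotonic frame times.
    """
    import MDAnalysis as mda

    if isinstance(selection_config, (str, Path)):
        selection_config = SelectionConfig.from_yaml(selection_config)
    config = selection_config or SelectionConfig()

    for p in (topology_path, trajectory_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(topology_path), str(trajectory_path))
    except (ValueError, IOError) as exc:
        raise ValueError(
            f"topology/trajectory are inconsistent: {exc}") from exc

    particles = particles_from_labels(u.atoms.names, u.atoms.resnames,
                                      u.atoms.resids, config)
    known = set(config.water_resnames) | set(config.lipid_resnames)
    for rn in np.unique(particles.residue_names[particles.roles == ROLE_ION]):
        if len(rn) > 3 and rn not in known:
            warnings.warn(f"unrecognised residue name {rn!r} mapped to 'ion'")

    n_frames = len(u.trajectory)
    coords = np.empty((n_frames, len(u.atoms), 3), dtype=np.float32)
    times = np.empty(n_frames)
    box = np.empty((n_frames, 3))
    for i, ts in enumerate(u.trajectory):
        coords[i] = ts.positions
        times[i] = ts.time / 1000.0  # ps -> ns
        box[i] = ts.dimensions[:3]
    frames = FrameSeries(times=times, coordinates=coords, box=box)
    return particles, frames


def define_pore_regions(particles: ParticleSet, frames: FrameSeries,
                        anchor_prefix: str = "ARG", anchor_resid: int = 187,
                        radius: float = 6.0, length: float = 30.0,
                        ) -> list[PoreRegion]:
    """One cylinder per monomer, centred laterally on the time-averaged
    anchor (ar/R arginine) position and axially on the membrane midplane.

    The midplane is the time-averaged mean z of lipid phosphorus atoms
    when lipids are present, otherwise of all protein atoms.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    monomers = particles.monomers()
    if not monomers:
        raise ValueError("no protein monomers found")

    lipid_p = (particles.roles == ROLE_LIPID) & (particles.elements == "P")
    if lipid_p.any():
        ref = lipid_p
    else:
        ref = particles.roles == ROLE_PROTEIN
    midplane = float(frames.coordinates[:, ref, 2].mean())

    regions = []
    for label in monomers:
        anchor = ((particles.monomer_labels == label)
                  & (particles.roles == ROLE_PROTEIN)
                  & np.char.startswith(particles.residue_names.astype(str),
                                       anchor_prefix)
                  & (particles.residue_ids == anchor_resid))
        if not anchor.any():
            raise ValueError(
                f"anchor {anchor_prefix}{anchor_resid} absent in monomer "
                f"{label}")
        center_xy = frames.coordinates[:, anchor, :2].mean(axis=(0, 1))
        regions.append(PoreRegion(
            monomer_label=label, center_xy=center_xy, radius=radius,
            z_low=midplane - length / 2, z_high=midplane + length / 2))
    return regions


def assign_waters(particles: ParticleSet, frames: FrameSeries,
                  regions: list[PoreRegion]) -> RegionMembership:
    """Classify every water oxygen per frame: inside which pore, and on
    which side of the membrane section.

    Coordinates are wrapped into the primary box; the radial test uses
    the minimum-image lateral distance to each pore axis.
    """
    for i, a in enumerate(regions):
        for b in regions[i + 1:]:
            if np.linalg.norm(a.center_xy - b.center_xy) < a.radius + b.radius:
                raise ValueError(
                    f"pore regions {a.monomer_label} and {b.monomer_label} "
                    "overlap in the membrane plane")

    widx = particles.water_oxygen_indices
    xyz = frames.coordinates[:, widx, :].astype(float)   # (F, W, 3)
    box = frames.box[:, None, :]                         # (F, 1, 3)
    xyz = np.mod(xyz, box)

    z_low, z_high = regions[0].z_low, regions[0].z_high
    z = xyz[:, :, 2]
    side = np.zeros(z.shape, dtype=np.int8)
    side[z < z_low] = -1
    side[z > z_high] = 1

    inside = np.empty(z.shape + (len(regions),), dtype=bool)
    for r, region in enumerate(regions):
        d = xyz[:, :, :2] - region.center_xy
        d -= box[:, :, :2] * np.round(d / box[:, :, :2])
        radial = np.einsum("fwk,fwk->fw", d, d)
        inside[:, :, r] = ((radial <= region.radius ** 2)
                           & (z >= region.z_low) & (z <= region.z_high))
    return RegionMembership(water_indices=widx, regions=regions,
                            inside=inside, side=side)
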