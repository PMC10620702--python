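"""Ground-truth-labelled synthetic channel systems.

Generates toy membrane-channel trajectories that exercise every analysis
stage with exactly known expectations: a scaffold of four pseudo-atom
"monomers" (two rings of pore-lining atoms, one designated anchor
"arginine" per monomer, lipid-phosphate markers fixing the membrane
midplane), pore waters with prescribed transport statistics, ideal bulk
water at a prescribed density, and optionally a steroid-like ligand whose
anchor hydrogen-bonding follows a two-state Markov process.

Two water-dynamics modes are provided:

* ``single_file`` (flat potential) -- the pore water file moves
  collectively: the file coordinate performs Brownian motion with
  diffusion D/N, so the collective coordinate has exactly
  D_n = N * D / L**2 (hence pf = v_w * D_n) and tagged waters complete
  full traversals at the analytic one-way rate D / L**2 per monomer.
  Water exchange with the vestibule reservoirs happens at the section
  faces, and every admission/release is logged, so the manifest carries
  the exact crossing-event ledger alongside the analytic rates.

* ``independent`` -- non-interacting waters follow overdamped Langevin
  dynamics along z on the periodic box with an imposed axial potential
  U(z); the stationary density is exactly Boltzmann, exp(-U/kT), which
  is what the density/free-energy estimators must recover.

Neither mode is a physical water model (no sterics, no electrostatics,
no lipid dynamics); both are statistically exact references for the
estimators they validate.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .constants import (SINGLE_WATER_VOLUME_CM3, BULK_WATER_DENSITY,
                        DEFAULT_TEMPERATURE, R_KCAL, kT)
from .trajectory_io import ParticleSet, FrameSeries, SelectionConfig, \
    particles_from_labels
from .binding import ScoringCoefficients

_LETTERS = "ABCD"


# --------------------------------------------------------------------------
# specifications

@dataclass
class PiecewisePotential:
    """Piecewise-linear axial potential on the pore section.

    ``points`` are (z_offset_from_section_bottom [A], U [kcal/mol]) pairs;
    U is zero outside the section.
    """

    points: list[tuple[float, float]]

    def table(self, z_low: float, z_high: float
              ) -> tuple[np.ndarray, np.ndarray]:
        zs = np.array([z_low + p[0] for p in self.points])
        us = np.array([p[1] for p in self.points])
        if np.any(np.diff(zs) < 0):
            raise ValueError("potential breakpoints must be sorted")
        if zs[0] > z_low:
            zs, us = np.r_[z_low, zs], np.r_[0.0, us]
        if zs[-1] < z_high:
            zs, us = np.r_[zs, z_high], np.r_[us, 0.0]
        return zs, us

    @staticmethod
    def step(height: float, start: float, stop: float,
             ramp: float = 1.0) -> "PiecewisePotential":
        """A flat-topped step of ``height`` kcal/mol between ``start`` and
        ``stop`` (offsets from the section bottom), with short ramps."""
        return PiecewisePotential([
            (0.0, 0.0), (start - ramp, 0.0), (start, height),
            (stop, height), (stop + ramp, 0.0)])


@dataclass
class SyntheticPoreSpec:
    """Study conditions for the synthetic channel.

    Defaults mirror the simulated system the analyses are meant for: a
    four-monomer channel with a 30 A conducting section, ~7 single-file
    pore waters per monomer, an axial water diffusivity chosen so the
    default single-channel permeability is ~2e-14 cm^3/s, TIP3-like bulk
    water density, and 310.15 K.
    """

    n_monomers: int = 4
    section_length: float = 30.0
    radius: float = 6.0
    axial_diffusion: float = 85.9          # A^2/ns
    mean_occupancy: float = 7.0
    potential: PiecewisePotential | None = None
    bulk_density: float = BULK_WATER_DENSITY
    buffer: float = 30.0                   # vestibule half-height, A
    monomer_spacing: float = 16.0
    temperature: float = DEFAULT_TEMPERATURE
    exchange_pool: int = 12                # vestibule waters per monomer
    dynamics: str = "auto"                 # auto | single_file | independent
    xy_jitter: float = 0.3
    substeps: int | None = None            # None -> adaptive Euler step

    def __post_init__(self) -> None:
        for name in ("section_length", "radius", "mean_occupancy",
                     "buffer", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        # zero diffusivity is legal: frozen waters, zero transport
        if self.axial_diffusion < 0 or self.bulk_density < 0:
            raise ValueError("diffusivity and density must be non-negative")

    @property
    def mode(self) -> str:
        if self.dynamics != "auto":
            return self.dynamics
        return "independent" if self.potential is not None else "single_file"

    @property
    def box_xy(self) -> float:
        cols = math.ceil(math.sqrt(self.n_monomers))
        return cols * self.monomer_spacing

    @property
    def box_z(self) -> float:
        return self.section_length + 2 * self.buffer

    @property
    def z_low(self) -> float:
        return self.buffer

    @property
    def z_high(self) -> float:
        return self.buffer + self.section_length

    def monomer_centers(self) -> list[np.ndarray]:
        cols = math.ceil(math.sqrt(self.n_monomers))
        s = self.monomer_spacing
        return [np.array([s / 2 + s * (i % cols), s / 2 + s * (i // cols)])
                for i in range(self.n_monomers)]


@dataclass
class LigandKineticsSpec:
    """Two-state Markov kinetics of the steroid's anchor hydrogen bond."""

    k_on: float = 0.04     # unbound -> bound rate, 1/ns
    k_off: float = 0.02    # bound -> unbound rate, 1/ns
    monomer: str = "A"
    start_bound: bool | None = None   # None -> draw from the stationary law
    pose_jitter: float = 0.0          # rigid-body positional jitter, A

    def __post_init__(self) -> None:
        if self.k_on < 0 or self.k_off < 0 or self.k_on + self.k_off <= 0:
            raise ValueError("rates must be non-negative, not both zero")

    @property
    def stationary_bound_fraction(self) -> float:
        return self.k_on / (self.k_on + self.k_off)


@dataclass
class GroundTruthManifest:
    """Everything needed to recompute expected estimates independently."""

    mode: str
    seed: int | None
    duration_ns: float
    frame_interval_ns: float
    n_monomers: int
    section: tuple[float, float]
    radius: float
    diffusion: float
    occupancy: float
    temperature: float
    dn_true_per_ns: float | None
    pf_true_cm3_s: float | None
    crossing_rate_oneway_per_ns: float | None
    events: list[dict] = field(default_factory=list)
    potential_table: list[list[float]] | None = None
    density_truth: list[list[float]] | None = None
    ligand: dict | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def crossing_counts(self, window: tuple[float, float] | None = None
                        ) -> int:
        if window is None:
            return len(self.events)
        t0, t1 = window
        return sum(1 for e in self.events if t0 <= e["t_exit"] < t1)


def diffusion_for_pf(pf_cm3_s: float, occupancy: float = 7.0,
                     section_length: float = 30.0) -> float:
    """Axial diffusivity (A^2/ns) imposing a target single-channel pf in
    the single-file mode (pf = v_w * N * D / L**2)."""
    d_n = pf_cm3_s / (SINGLE_WATER_VOLUME_CM3 * 1e9)
    return d_n * section_length ** 2 / occupancy


# --------------------------------------------------------------------------
# scaffold

_RING_ELEMENTS = ("C", "C", "C", "N", "C", "O", "C", "S")


@dataclass
class _Scaffold:
    names: list[str]
    resnames: list[str]
    resids: list[int]
    coords: np.ndarray
    anchor_N: dict[str, np.ndarray]   # per-monomer donor nitrogen position


def _build_scaffold(spec: SyntheticPoreSpec) -> _Scaffold:
    names, resnames, resids, coords = [], [], [], []
    anchor_N = {}
    resid = 0
    ring_r = spec.radius
    for m, center in enumerate(spec.monomer_centers()):
        letter = _LETTERS[m]
        # two rings of pore-lining pseudo-atoms at the section faces
        resid += 1
        for z in (spec.z_low, spec.z_high):
            for i, elem in enumerate(_RING_ELEMENTS):
                ang = 2 * np.pi * i / len(_RING_ELEMENTS)
                names.append(f"{elem}{i + 1}")
                resnames.append(f"RNG{letter}")
                resids.append(resid)
                coords.append([center[0] + ring_r * np.cos(ang),
                               center[1] + ring_r * np.sin(ang), z])
        # anchor "arginine": N-H donor, carbonyl O acceptor, one C
        n_pos = np.array([center[0] + 1.2, center[1], spec.z_high - 1.0])
        anchor_N[letter] = n_pos
        for name, pos in (
                ("N", n_pos),
                ("HN", n_pos + [0.0, 0.0, 1.0]),
                ("C", n_pos + [1.4, 0.0, -0.8]),
                ("O", n_pos + [2.3, 0.8, -0.8])):
            names.append(name)
            resnames.append(f"ARG{letter}")
            resids.append(187)
            coords.append(pos)
        # lipid-phosphate markers, symmetric about the midplane
        for z in (spec.z_low, spec.z_high):
            resid += 1
            names.append("P8")
            resnames.append("POPC")
            resids.append(resid)
            coords.append([(center[0] + 14.0) % spec.box_xy, center[1], z])
    return _Scaffold(names, resnames, resids,
                     np.array(coords, dtype=float), anchor_N)


# --------------------------------------------------------------------------
# water engines

def _single_file_engine(spec: SyntheticPoreSpec, times: np.ndarray,
                        rng: np.random.Generator, monomer: str
                        ) -> tuple[np.ndarray, list[dict]]:
    """Collectively moving water file with reservoir exchange.

    Returns the z trajectory (F, N + pool) of this monomer's waters and
    the exact crossing-event ledger.
    """
    L, z1, z2 = spec.section_length, spec.z_low, spec.z_high
    n_slots = int(round(spec.mean_occupancy))
    a = L / n_slots
    d_file = spec.axial_diffusion / n_slots
    n_pool = max(2, spec.exchange_pool)
    n_w = n_slots + n_pool
    n_frames = len(times)
    dts = np.diff(times)

    x = np.empty(n_frames)
    x[0] = rng.uniform(0, a)
    x[1:] = x[0] + np.cumsum(rng.normal(0.0, 1.0, n_frames - 1)
                             * np.sqrt(2 * d_file * dts))
    kmin = np.ceil((z1 - x) / a - 1e-12).astype(np.int64)

    def draw_buffer(size: int) -> np.ndarray:
        u = rng.uniform(0, 2 * spec.buffer, size)
        return np.where(u < spec.buffer, u, u + L)

    z = np.empty((n_frames, n_w))
    occupants: dict[int, int] = {}
    admit: dict[int, tuple[int, float]] = {}
    for i, k in enumerate(range(kmin[0], kmin[0] + n_slots)):
        occupants[k] = i
        admit[i] = (0, times[0])       # unknown entry side at t0
        z[0, i] = k * a + x[0]
    pool = set(range(n_slots, n_w))
    z[0, sorted(pool)] = draw_buffer(n_pool)

    events: list[dict] = []
    for f in range(1, n_frames):
        pooled = sorted(pool)
        z[f, pooled] = draw_buffer(len(pooled))
        k0, k1 = kmin[f - 1], kmin[f]
        if k1 != k0:
            # release occupants whose slot left the window (any jump size)
            for k in sorted(occupants):
                if k1 <= k < k1 + n_slots:
                    continue
                atom = occupants.pop(k)
                theta = k * a + x[f]
                z[f, atom] = theta
                exit_side = 1 if theta >= z2 else -1
                side_in, t_in = admit.pop(atom)
                if side_in != 0 and exit_side == -side_in:
                    events.append({
                        "water": atom, "monomer": monomer,
                        "t_enter": float(t_in), "t_exit": float(times[f]),
                        "direction": "up" if side_in == -1 else "down"})
                pool.add(atom)
            # admit reservoir waters into newly exposed slots
            for k in range(k1, k1 + n_slots):
                if k in occupants:
                    continue
                need_side = -1 if k < k0 else 1
                pooled_now = sorted(pool)
                prev_z = np.mod(z[f - 1, pooled_now], spec.box_z)
                sides = np.where(prev_z < z1, -1,
                                 np.where(prev_z > z2, 1, 0))
                match = [at for at, s in zip(pooled_now, sides)
                         if s == need_side]
                donor = match[0] if match else pooled_now[0]
                actual = int(sides[pooled_now.index(donor)])
                pool.remove(donor)
                occupants[k] = donor
                admit[donor] = (actual, float(times[f]))
                z[f, donor] = k * a + x[f]
        for k, atom in occupants.items():
            z[f, atom] = k * a + x[f]
    return np.mod(z, spec.box_z), events


def _boltzmann_sample(zs: np.ndarray, us: np.ndarray, lo: float, hi: float,
                      n: int, temperature: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample z in [lo, hi] from exp(-U(z)/kT) (U interpolated
    piecewise-linearly, zero outside the table)."""
    kt = kT(temperature)
    u_ref = min(0.0, float(us.min()))
    out = np.empty(0)
    while len(out) < n:
        cand = rng.uniform(lo, hi, 4 * n)
        u = np.interp(cand, zs, us, left=0.0, right=0.0)
        keep = rng.uniform(0, 1, len(cand)) < np.exp(-(u - u_ref) / kt)
        out = np.concatenate([out, cand[keep]])
    return out[:n]


def _independent_engine(spec: SyntheticPoreSpec, times: np.ndarray,
                        rng: np.random.Generator, monomer: str,
                        n_substeps: int | None = None
                        ) -> tuple[np.ndarray, list[dict]]:
    """Non-interacting overdamped Langevin waters on the periodic box with
    the imposed axial potential; crossings logged at substep resolution.

    ``n_substeps=None`` chooses the Euler step adaptively so the drift
    per substep stays below 0.1 A; an explicit substep count that
    yields a drift above L/10 is rejected as unstable.
    """
    L, z1, z2 = spec.section_length, spec.z_low, spec.z_high
    box_z = spec.box_z
    kt = kT(spec.temperature)
    d = spec.axial_diffusion
    pot = spec.potential or PiecewisePotential([(0.0, 0.0)])
    zs, us = pot.table(z1, z2)
    weight_sec = np.trapezoid(np.exp(-us / kt), zs)
    z_ring = weight_sec + (box_z - L)
    n_w = max(1, int(round(spec.mean_occupancy * z_ring / weight_sec)))

    n_frames = len(times)
    dt_frame = float(np.median(np.diff(times)))
    slopes = np.diff(us) / np.diff(zs)
    max_slope = float(np.max(np.abs(slopes))) if len(slopes) else 0.0
    if n_substeps is None:
        dt_drift = (0.1 * kt / (d * max_slope)) if max_slope else dt_frame
        n_substeps = max(10, int(np.ceil(dt_frame / dt_drift)))
    dt = dt_frame / n_substeps
    if d / kt * max_slope * dt > L / 10:
        raise ValueError("unstable integration step: reduce the frame "
                         "interval or the potential slope")

    def force(pos: np.ndarray) -> np.ndarray:
        if max_slope == 0.0:
            return np.zeros_like(pos)
        seg = np.clip(np.searchsorted(zs, pos) - 1, 0, len(slopes) - 1)
        f = -slopes[seg]
        f[(pos < zs[0]) | (pos > zs[-1])] = 0.0
        return f

    def side_of(pos: np.ndarray) -> np.ndarray:
        return np.where(pos < z1, -1,
                        np.where(pos > z2, 1, 0)).astype(np.int8)

    theta = _boltzmann_sample(zs, us, 0.0, box_z, n_w, spec.temperature, rng)
    z = np.empty((n_frames, n_w))
    z[0] = theta
    sigma = np.sqrt(2 * d * dt)
    side = side_of(theta)
    entry_side = np.zeros(n_w, dtype=np.int8)
    entry_time = np.zeros(n_w)
    events: list[dict] = []

    t = float(times[0])
    for fidx in range(1, n_frames):
        for _ in range(n_substeps):
            theta = np.mod(theta + d / kt * force(theta) * dt
                           + rng.normal(0.0, sigma, n_w), box_z)
            t += dt
            new_side = side_of(theta)
            entering = (new_side == 0) & (side != 0)
            if entering.any():
                entry_side[entering] = side[entering]
                entry_time[entering] = t
            leaving = (new_side != 0) & (side == 0)
            if leaving.any():
                complete = leaving & (new_side == -entry_side) \
                    & (entry_side != 0)
                for w in np.flatnonzero(complete):
                    events.append({
                        "water": int(w), "monomer": monomer,
                        "t_enter": float(entry_time[w]), "t_exit": t,
                        "direction": "up" if entry_side[w] == -1 else "down"})
                entry_side[leaving] = 0
            side = new_side
        z[fidx] = theta
    return z, events


# --------------------------------------------------------------------------
# ligand

#: steroid-like rigid heavy-atom template (element, position relative to
#: the hydroxyl oxygen that hydrogen-bonds to the anchor)
_LIGAND_TEMPLATE = (
    ("O", (0.0, 0.0, 0.0)),      # anchor-binding hydroxyl oxygen
    ("H", (0.8, 0.0, -0.55)),    # its hydroxyl hydrogen
    ("C", (0.0, 0.0, 1.4)),
    ("C", (1.2, 0.0, 2.2)),
    ("C", (-1.2, 0.0, 2.2)),
    ("C", (0.0, 1.2, 2.6)),
    ("C", (0.0, -1.2, 2.6)),
    ("C", (0.8, 0.8, 3.8)),
    ("C", (-0.8, -0.8, 3.8)),
    ("C", (1.5, 0.0, 5.0)),
    ("C", (-1.5, 0.0, 5.0)),
    ("N", (0.0, 0.0, 5.5)),
    ("O", (2.2, 0.0, 6.2)),
    ("O", (-2.2, 0.0, 6.2)),
    ("S", (0.0, 0.0, 7.0)),
    ("C", (0.0, 1.5, 7.5)),
    ("C", (0.0, -1.5, 7.5)),
)

#: donor N to hydroxyl O distance in the bound pose, A (a textbook
#: moderate hydrogen bond; the anchor H sits on the N->O axis)
_HBOND_DA = 2.9


def _ligand_poses(spec: SyntheticPoreSpec, scaffold: _Scaffold,
                  monomer: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(elements kept by caller) bound and unbound rigid poses."""
    template = np.array([p for _, p in _LIGAND_TEMPLATE])
    anchor_n = scaffold.anchor_N[monomer]
    bound = template + anchor_n + np.array([0.0, 0.0, _HBOND_DA])
    far = np.array([spec.box_xy / 2, spec.box_xy / 2,
                    spec.box_z - 4.0])
    unbound = template + far
    return template, bound, unbound


def _brute_contact_counts(lig_elements: list[str], lig_pos: np.ndarray,
                          pro_elements: np.ndarray, pro_pos: np.ndarray,
                          cutoff: float) -> dict[str, int]:
    """Independent plain-loop contact counter used only for ground truth."""
    def cls(e: str) -> str:
        return e if e in ("C", "N", "O") else "X"
    counts: dict[str, int] = {}
    for el, p in zip(lig_elements, lig_pos):
        if el == "H":
            continue
        for eo, q in zip(pro_elements, pro_pos):
            if eo == "H":
                continue
            if math.dist(p, q) <= cutoff:
                key = "".join(sorted((cls(el), cls(eo))))
                counts[key] = counts.get(key, 0) + 1
    return counts


def simulate_ligand(spec: LigandKineticsSpec, pore_spec: SyntheticPoreSpec,
                    scaffold: _Scaffold, times: np.ndarray,
                    rng: np.random.Generator,
                    coefficients: ScoringCoefficients | None = None
                    ) -> tuple[list[str], np.ndarray, dict]:
    """Two-state Markov ligand: bound frames place the hydroxyl donor
    geometry on the anchor (D-A 2.9 A, collinear H); unbound frames park
    the ligand in bulk, beyond the contact cutoff plus 5 A from every
    protein atom.  Returns (element labels, coords (F, n, 3), manifest).
    """
    coefficients = coefficients or ScoringCoefficients.default()
    duration = float(times[-1] - times[0])
    rate_total = spec.k_on + spec.k_off
    if duration * rate_total < 5 and 0 < spec.k_off:
        warnings.warn("trajectory short relative to ligand kinetics; "
                      "state statistics will be poor")

    if spec.start_bound is None:
        start_bound = bool(rng.uniform() < spec.stationary_bound_fraction)
    else:
        start_bound = spec.start_bound
    bound_now = start_bound
    t = float(times[0])
    t_end = float(times[-1])
    intervals: list[tuple[float, float, bool]] = []
    switches: list[float] = []
    while t < t_end:
        rate = spec.k_off if bound_now else spec.k_on
        dwell = np.inf if rate == 0 else rng.exponential(1.0 / rate)
        intervals.append((t, min(t + dwell, t_end), bound_now))
        t += dwell
        if t < t_end:
            switches.append(t)
        bound_now = not bound_now

    n_switched = np.searchsorted(np.asarray(switches), times, side="right")
    states = np.where(n_switched % 2 == 0, start_bound, not start_bound)
    states = states.astype(bool)

    elements = [e for e, _ in _LIGAND_TEMPLATE]
    _, bound_pose, unbound_pose = _ligand_poses(pore_spec, scaffold,
                                                spec.monomer)
    coords = np.where(states[:, None, None], bound_pose, unbound_pose)
    coords = coords + rng.normal(0.0, spec.pose_jitter,
                                 (len(times), 1, 3))

    is_protein = np.array([rn.startswith(("RNG", "ARG"))
                           for rn in scaffold.resnames])
    pro_elem = np.array([n[0] if not n[0].isdigit() else "C"
                         for n in scaffold.names])[is_protein]
    pro_pos = scaffold.coords[is_protein]
    truth = {}
    for label, pose in (("bound", bound_pose), ("unbound", unbound_pose)):
        counts = _brute_contact_counts(elements, pose, pro_elem,
                                       pro_pos, coefficients.cutoff)
        dg = coefficients.intercept + sum(
            coefficients.weights[k] * v for k, v in counts.items())
        kd_nM = math.exp(dg / (R_KCAL * pore_spec.temperature)) * 1e9
        truth[label] = {"contacts": counts, "dG_kcal_mol": dg, "KD_nM": kd_nM}

    manifest = {
        "k_on_per_ns": spec.k_on, "k_off_per_ns": spec.k_off,
        "monomer": spec.monomer,
        "stationary_bound_fraction": spec.stationary_bound_fraction,
        "realized_bound_fraction": float(states.mean()),
        "intervals": [[t0, t1, bool(b)] for t0, t1, b in intervals],
        "states_per_frame_bound": states.tolist(),
        "hbond_geometry": {"donor_acceptor_A": _HBOND_DA, "angle_deg": 0.0},
        **truth,
    }
    return elements, coords, manifest


# --------------------------------------------------------------------------
# assembly

def generate_condition(spec: SyntheticPoreSpec | None = None,
                       ligand_spec: LigandKineticsSpec | None = None,
                       duration_ns: float = 200.0,
                       frame_interval_ns: float = 0.1,
                       seed: int | None = 0,
                       coefficients: ScoringCoefficients | None = None,
                       ) -> tuple[ParticleSet, FrameSeries,
                                  GroundTruthManifest]:
    """Build a complete labelled system: scaffold + pore waters + ideal
    bulk water + optional ligand, with its ground-truth manifest."""
    spec = spec or SyntheticPoreSpec()
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_ns / frame_interval_ns)) + 1
    times = np.arange(n_frames) * frame_interval_ns
    L = spec.section_length

    scaffold = _build_scaffold(spec)

    # --- pore waters -----------------------------------------------------
    single_file = spec.mode == "single_file"
    if single_file and spec.potential is not None:
        raise ValueError("single_file dynamics requires a flat potential")
    monomer_z, raw_events, block_sizes = [], [], []
    for m in range(spec.n_monomers):
        label = _LETTERS[m]
        if single_file:
            z, ev = _single_file_engine(spec, times, rng, label)
        else:
            z, ev = _independent_engine(spec, times, rng, label,
                                        n_substeps=spec.substeps)
        monomer_z.append(z)
        raw_events.append(ev)
        block_sizes.append(z.shape[1])

    centers = spec.monomer_centers()
    water_blocks = []
    n_pore_waters = 0
    # lateral placement: fixed sub-axis offsets plus clipped jitter, bounded
    # so pore waters never leave the analysis cylinder (radius - margin)
    for m, z in enumerate(monomer_z):
        n_w = z.shape[1]
        n_pore_waters += n_w
        r_max = max(0.5, spec.radius - 4.0)
        r = np.sqrt(rng.uniform(0, 1, n_w)) * r_max
        ang = rng.uniform(0, 2 * np.pi, n_w)
        offsets = np.stack([r * np.cos(ang), r * np.sin(ang)], axis=1)
        jitter = np.clip(rng.normal(0, spec.xy_jitter, (n_frames, n_w, 2)),
                         -3 * spec.xy_jitter, 3 * spec.xy_jitter)
        xy = (centers[m] + offsets)[None, :, :] + jitter
        water_blocks.append(np.concatenate([xy, z[:, :, None]], axis=2))

    # --- ideal bulk water -------------------------------------------------
    buffer_volume = spec.box_xy ** 2 * (spec.box_z - L)
    if single_file:
        n_nonideal_in_buffer = spec.n_monomers * max(2, spec.exchange_pool)
    else:
        n_nonideal_in_buffer = n_pore_waters * (spec.box_z - L) / spec.box_z
    n_bulk = max(0, int(round(spec.bulk_density * buffer_volume
                              - n_nonideal_in_buffer)))
    if n_bulk:
        xy = rng.uniform(0, spec.box_xy, (n_frames, n_bulk, 2))
        u = rng.uniform(0, spec.box_z - L, (n_frames, n_bulk))
        zb = np.where(u < spec.buffer, u, u + L)
        water_blocks.append(np.concatenate([xy, zb[:, :, None]], axis=2))

    water_coords = np.concatenate(water_blocks, axis=1)
    n_waters = water_coords.shape[1]

    # --- ligand ------------------------------------------------------------
    ligand_manifest = None
    lig_coords = None
    lig_elements: list[str] = []
    if ligand_spec is not None:
        lig_elements, lig_coords, ligand_manifest = simulate_ligand(
            ligand_spec, spec, scaffold, times, rng, coefficients)

    # --- particle table ----------------------------------------------------
    names = list(scaffold.names)
    resnames = list(scaffold.resnames)
    resids = list(scaffold.resids)
    next_resid = max(resids) + 1
    if ligand_spec is not None:
        for i, e in enumerate(lig_elements):
            names.append(f"{e}{i + 1}")
            resnames.append(f"LIG{ligand_spec.monomer}")
            resids.append(next_resid)
        next_resid += 1
    for _ in range(n_waters):
        names.append("OW")
        resnames.append("SOL")
        resids.append(next_resid)
        next_resid += 1

    particles = particles_from_labels(
        np.array(names), np.array(resnames), np.array(resids),
        SelectionConfig())

    # remap per-monomer water indices in the event ledger to atom indices
    n_before_waters = len(scaffold.names) + len(lig_elements)
    events: list[dict] = []
    offset = n_before_waters
    for ev_block, size in zip(raw_events, block_sizes):
        for e in ev_block:
            events.append({**e, "water": int(e["water"] + offset)})
        offset += size
    events.sort(key=lambda e: e["t_exit"])

    static = np.broadcast_to(scaffold.coords,
                             (n_frames,) + scaffold.coords.shape)
    parts = [static]
    if lig_coords is not None:
        parts.append(lig_coords)
    parts.append(water_coords)
    coords = np.concatenate(parts, axis=1).astype(np.float32)
    box = np.tile([spec.box_xy, spec.box_xy, spec.box_z], (n_frames, 1))
    frames = FrameSeries(times=times, coordinates=coords, box=box)

    # --- ground truth -------------------------------------------------------
    if single_file:
        n_slots = int(round(spec.mean_occupancy))
        occupancy = float(n_slots)
        dn_true = n_slots * spec.axial_diffusion / L ** 2
        pf_true = SINGLE_WATER_VOLUME_CM3 * dn_true * 1e9
        rate_oneway = spec.axial_diffusion / L ** 2
    else:
        occupancy = spec.mean_occupancy
        dn_true = pf_true = rate_oneway = None
    pot_table = None
    density_truth = None
    if spec.potential is not None:
        zs, us = spec.potential.table(spec.z_low, spec.z_high)
        pot_table = [list(map(float, zs)), list(map(float, us))]
        grid = np.linspace(spec.z_low, spec.z_high, 121)
        dens = np.exp(-np.interp(grid, zs, us) / kT(spec.temperature))
        density_truth = [list(map(float, grid)), list(map(float, dens))]

    manifest = GroundTruthManifest(
        mode=spec.mode, seed=seed, duration_ns=duration_ns,
        frame_interval_ns=frame_interval_ns, n_monomers=spec.n_monomers,
        section=(spec.z_low, spec.z_high), radius=spec.radius,
        diffusion=spec.axial_diffusion, occupancy=occupancy,
        temperature=spec.temperature, dn_true_per_ns=dn_true,
        pf_true_cm3_s=pf_true, crossing_rate_oneway_per_ns=rate_oneway,
        events=events, potential_table=pot_table,
        density_truth=density_truth, ligand=ligand_manifest)
    return particles, frames, manifest


def sample_equilibrium_frames(spec: SyntheticPoreSpec | None = None,
                              n_waters: int = 50, n_frames: int = 2000,
                              seed: int | None = 0
                              ) -> tuple[ParticleSet, FrameSeries]:
    """Frames of i.i.d. Boltzmann-distributed pore waters (monomer A).

    Every frame redraws ``n_waters`` axial positions from
    exp(-U(z)/kT) over the section, so the sampled density is exactly
    the stationary law with ``n_frames * n_waters`` independent samples;
    used to validate the density -> free-energy chain without dynamical
    correlations.
    """
    spec = spec or SyntheticPoreSpec()
    rng = np.random.default_rng(seed)
    scaffold = _build_scaffold(spec)
    pot = spec.potential or PiecewisePotential([(0.0, 0.0)])
    zs, us = pot.table(spec.z_low, spec.z_high)
    n_frames = int(n_frames)

    z = _boltzmann_sample(zs, us, spec.z_low, spec.z_high,
                          n_frames * n_waters, spec.temperature,
                          rng).reshape(n_frames, n_waters)
    center = spec.monomer_centers()[0]
    r_max = max(0.5, spec.radius - 4.0)
    r = np.sqrt(rng.uniform(0, 1, (n_frames, n_waters))) * r_max
    ang = rng.uniform(0, 2 * np.pi, (n_frames, n_waters))
    xy = np.stack([center[0] + r * np.cos(ang),
                   center[1] + r * np.sin(ang)], axis=2)
    water_coords = np.concatenate([xy, z[:, :, None]], axis=2)

    names = list(scaffold.names) + ["OW"] * n_waters
    resnames = list(scaffold.resnames) + ["SOL"] * n_waters
    base = max(scaffold.resids) + 1
    resids = list(scaffold.resids) + [base + i for i in range(n_waters)]
    particles = particles_from_labels(
        np.array(names), np.array(resnames), np.array(resids),
        SelectionConfig())

    static = np.broadcast_to(scaffold.coords,
                             (n_frames,) + scaffold.coords.shape)
    coords = np.concatenate([static, water_coords], axis=1
                            ).astype(np.float32)
    times = np.arange(n_frames) * 1.0
    box = np.tile([spec.box_xy, spec.box_xy, spec.box_z], (n_frames, 1))
    return particles, FrameSeries(times=times, coordinates=coords, box=box)


def simulate_pore_waters(spec: SyntheticPoreSpec | None = None,
                         duration_ns: float = 200.0,
                         frame_interval_ns: float = 0.1,
                         seed: int | None = 0
                         ) -> tuple[ParticleSet, FrameSeries,
                                    GroundTruthManifest]:
    """Ligand-free synthetic system (see :func:`generate_condition`)."""
    return generate_condition(spec, None, duration_ns, frame_interval_ns,
                              seed)


# --------------------------------------------------------------------------
# file output and presets

def write_system(particles: ParticleSet, frames: FrameSeries,
                 topology_path: str | Path, trajectory_path: str | Path
                 ) -> None:
    """Emit a GRO topology and an XTC trajectory readable by
    :func:`permlab.trajectory_io.load_system`."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    res_index = np.zeros(particles.n_atoms, dtype=int)
    res_names = []
    res_ids = []
    current = None
    for i in range(particles.n_atoms):
        key = (particles.residue_names[i], particles.residue_ids[i])
        if key != current:
            current = key
            res_names.append(key[0])
            res_ids.append(int(key[1]))
        res_index[i] = len(res_names) - 1

    u = mda.Universe.empty(particles.n_atoms, n_residues=len(res_names),
                           atom_resindex=res_index, trajectory=True)
    u.add_TopologyAttr("names", [str(n) for n in _atom_names(particles)])
    u.add_TopologyAttr("resnames", res_names)
    u.add_TopologyAttr("resids", res_ids)

    dt_ps = frames.dt * 1000.0
    dims = np.hstack([frames.box,
                      np.full((frames.n_frames, 3), 90.0)]).astype(np.float32)
    u.load_new(frames.coordinates.astype(np.float64), format=MemoryReader,
               dimensions=dims, dt=dt_ps)
    u.trajectory[0]
    u.atoms.write(str(topology_path))
    with mda.Writer(str(trajectory_path), particles.n_atoms) as writer:
        for _ in u.trajectory:
            writer.write(u.atoms)


def _atom_names(particles: ParticleSet) -> list[str]:
    names = []
    for i, e in enumerate(particles.elements):
        if particles.roles[i] == "water_oxygen":
            names.append("OW")
        else:
            names.append(f"{e}{(i % 99) + 1}")
    return names


PRESETS = ("null", "inhibited", "two-state")


def make_preset(name: str, seed: int | None = 0, duration_ns: float = 200.0,
                frame_interval_ns: float = 0.1, **overrides
                ) -> tuple[ParticleSet, FrameSeries, GroundTruthManifest]:
    """Canned study conditions.

    * ``null`` -- steroid-free control at the default permeability.
    * ``inhibited`` -- a permanently anchor-bound steroid with the pore
      diffusivity reduced to one quarter (a strong inhibitor).
    * ``two-state`` -- default permeability with a ligand alternating
      between ACBS-bound and unbound states (k_on 0.04/ns, k_off 0.02/ns).
    """
    if name == "null":
        spec = SyntheticPoreSpec(**overrides)
        lig = None
    elif name == "inhibited":
        base = SyntheticPoreSpec()
        spec = SyntheticPoreSpec(**{
            "axial_diffusion": base.axial_diffusion * 0.25, **overrides})
        lig = LigandKineticsSpec(k_on=1.0, k_off=0.0, start_bound=True)
    elif name == "two-state":
        spec = SyntheticPoreSpec(**overrides)
        lig = LigandKineticsSpec(k_on=0.04, k_off=0.02)
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    return generate_condition(spec, lig, duration_ns, frame_interval_ns,
                              seed)
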