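"""Water-transport observables: permeation counts and osmotic permeability.

Two complementary observables are computed from an equilibrium trajectory:

* full-section crossing events -- a water enters the 30 A trans-membrane
  pore section through one z face and leaves through the opposite face,
  having stayed within the monomer's cylinder throughout; and

* the single-channel osmotic permeability coefficient pf, from the
  collective coordinate n(t): the cumulative sum of axial displacements
  of in-pore waters divided by the section length.  n(t) performs a
  random walk whose diffusion coefficient D_n gives pf = v_w * D_n, with
  v_w the volume of one water molecule.

Counts are the more robust statistic (the collective-coordinate route is
sensitive to thermal agitation of vestibule waters); both are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import SINGLE_WATER_VOLUME_CM3
from .trajectory_io import FrameSeries, PoreRegion, RegionMembership


@dataclass
class CrossingEvent:
    water_id: int
    monomer_label: str
    t_enter: float
    t_exit: float
    direction: str  # "up" | "down"

    def __post_init__(self) -> None:
        if self.t_exit <= self.t_enter:
            raise ValueError("t_exit must exceed t_enter")
        if self.direction not in ("up", "down"):
            raise ValueError(f"bad direction {self.direction!r}")


@dataclass
class CollectiveCoordinateSeries:
    monomer_label: str
    times: np.ndarray
    n: np.ndarray
    L: float

    def __post_init__(self) -> None:
        if self.n[0] != 0:
            raise ValueError("collective coordinate must start at zero")


@dataclass
class PermeabilityEstimate:
    monomer_label: str
    D_n: float                 # 1/ns
    D_n_stderr: float          # 1/ns
    pf_cm3_per_s: float
    fit_window: tuple[float, float]
    nonlinearity_ratio: float = 0.0

    def __post_init__(self) -> None:
        if self.pf_cm3_per_s < 0:
            raise ValueError("pf must be non-negative")


def detect_crossings(membership: RegionMembership, frames: FrameSeries,
                     regions: list[PoreRegion] | None = None,
                     ) -> list[CrossingEvent]:
    """Find complete pore traversals.

    An event is a maximal run of frames inside one monomer's cylinder
    whose flanking side labels are opposite (below -> above = "up").
    Runs that start at the first frame or end at the last frame, and runs
    entered and left through the same face (re-crossings), produce no
    event.  Waters that slip in through the cylinder wall (side label
    'inside' just before the run) are likewise discarded.
    """
    regions = regions if regions is not None else membership.regions
    times = frames.times
    events: list[CrossingEvent] = []
    n_frames = membership.inside.shape[0]
    for r, region in enumerate(regions):
        ins = membership.inside[:, :, r]
        candidates = np.flatnonzero(ins.any(axis=0))
        for w in candidates:
            col = ins[:, w]
            edges = np.flatnonzero(np.diff(col.astype(np.int8)))
            starts = edges[col[edges + 1]] + 1
            ends = edges[~col[edges + 1]] + 1
            if col[0]:
                starts = np.concatenate([[0], starts])
            if col[-1]:
                ends = np.concatenate([ends, [n_frames]])
            for i0, i1 in zip(starts, ends):
                if i0 == 0 or i1 == n_frames:
                    continue  # truncated at trajectory boundary
                s_in = membership.side[i0 - 1, w]
                s_out = membership.side[i1, w]
                if s_in == 0 or s_out != -s_in:
                    continue
                events.append(CrossingEvent(
                    water_id=int(membership.water_indices[w]),
                    monomer_label=region.monomer_label,
                    t_enter=float(times[i0]),
                    t_exit=float(times[i1]),
                    direction="up" if s_in == -1 else "down"))
    return events


def count_crossings(events: list[CrossingEvent],
                    window: tuple[float, float],
                    per: str = "tetramer") -> int | dict[str, int]:
    """Count events whose exit time falls in ``window`` = [t0, t1)."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty counting window")
    selected = [e for e in events if t0 <= e.t_exit < t1]
    if per == "tetramer":
        return len(selected)
    if per == "monomer":
        out: dict[str, int] = {}
        for e in selected:
            out[e.monomer_label] = out.get(e.monomer_label, 0) + 1
        return out
    raise ValueError(f"per must be 'tetramer' or 'monomer', got {per!r}")


def collective_coordinate(membership: RegionMembership, frames: FrameSeries,
                          region: PoreRegion) -> CollectiveCoordinateSeries:
    """Cumulative collective water displacement through one pore.

    n(t+dt) = n(t) + sum_i dz_i / L over waters inside the region at both
    frame endpoints; axial displacements are minimum-image unwrapped.
    """
    r = membership.regions.index(region)
    z = frames.coordinates[:, membership.water_indices, 2].astype(float)
    box_z = frames.box[:, 2][:, None]
    z = np.mod(z, box_z)
    dz = np.diff(z, axis=0)
    dz -= box_z[:-1] * np.round(dz / box_z[:-1])
    both = membership.inside[:-1, :, r] & membership.inside[1:, :, r]
    dn = (dz * both).sum(axis=1) / region.length
    n = np.concatenate([[0.0], np.cumsum(dn)])
    return CollectiveCoordinateSeries(
        monomer_label=region.monomer_label, times=frames.times, n=n,
        L=region.length)


def estimate_Dn(series: CollectiveCoordinateSeries,
                fit_window: tuple[float, float] = (0.1, 1.0),
                n_blocks: int = 10) -> tuple[float, float, float]:
    """Collective diffusion coefficient from the MSD of n(t).

    MSD(lag) over all overlapping time origins, least-squares line on the
    lag range ``fit_window`` (ns); D_n = slope / 2.  The uncertainty is
    the standard error over ``n_blocks`` trajectory blocks, which unlike
    the naive fit error accounts for origin overlap.  Returns
    (D_n, stderr, nonlinearity_ratio); the last is |quadratic|/|linear|
    contribution at the longest lag and flags drift-dominated series.
    """
    t, n = series.times, series.n
    dt = float(np.median(np.diff(t)))
    span = t[-1] - t[0]
    lo, hi = fit_window
    if hi >= span / 2:
        raise ValueError("fit window exceeds half the series span")
    lags = np.unique(np.round(np.linspace(lo / dt, hi / dt, 12)).astype(int))
    lags = lags[lags >= 1]
    if len(lags) < 2:
        raise ValueError("fit window too narrow for the frame spacing")

    def _msd(series_n: np.ndarray) -> np.ndarray:
        return np.array([np.mean((series_n[k:] - series_n[:-k]) ** 2)
                         for k in lags])

    msd = _msd(n)
    tau = lags * dt
    slope, _ = np.polyfit(tau, msd, 1)
    d_n = slope / 2.0

    q2, q1, _ = np.polyfit(tau, msd, 2)
    denom = abs(q1) * tau[-1]
    nonlin = abs(q2) * tau[-1] ** 2 / denom if denom > 0 else np.inf

    block_len = len(n) // n_blocks
    block_ds = []
    for b in range(n_blocks):
        seg = n[b * block_len:(b + 1) * block_len]
        if len(seg) > lags[-1] + 1:
            block_ds.append(np.polyfit(tau, _msd(seg), 1)[0] / 2.0)
    if len(block_ds) >= 2:
        stderr = float(np.std(block_ds, ddof=1) / np.sqrt(len(block_ds)))
    else:
        stderr = np.nan
    return float(d_n), stderr, float(nonlin)


def compute_pf(D_n: float, temperature: float = 310.15,
               monomer_label: str = "", D_n_stderr: float = 0.0,
               fit_window: tuple[float, float] = (0.1, 1.0),
               nonlinearity_ratio: float = 0.0) -> PermeabilityEstimate:
    """Osmotic permeability pf = v_w * D_n (D_n in 1/ns -> pf in cm^3/s).

    temperature is carried for provenance; the conversion itself is
    temperature-independent.
    """
    del temperature
    if D_n < 0:
        raise ValueError("D_n must be non-negative")
    pf = SINGLE_WATER_VOLUME_CM3 * D_n * 1e9
    return PermeabilityEstimate(
        monomer_label=monomer_label, D_n=D_n, D_n_stderr=D_n_stderr,
        pf_cm3_per_s=pf, fit_window=fit_window,
        nonlinearity_ratio=nonlinearity_ratio)
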