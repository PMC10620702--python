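"""Steroid-channel hydrogen bonds, bound-state windows and binding affinity.

The bound state of a steroid at the extracellular vestibule is defined by
hydrogen bonding to the conserved ar/R-constriction arginine (Arg187 in
AQP2).  A geometric criterion is used: donor-acceptor distance <= 3.5 A
and hydrogen-donor-acceptor angle <= 30 degrees.  The 50 ns trajectory
window with the highest anchor H-bond frequency defines the bound-state
window used for bound-state permeability comparison.

Binding affinity is scored per frame from heavy-atom ligand-protein
contact counts, classified by the unordered element pair (C, N, O, X =
other), through a linear empirical model

    dG_S = intercept + sum_class weight_class * count_class   (kcal/mol)

whose coefficients live entirely in configuration.  The dissociation
constant follows as K_D = exp(dG_S / RT) at the 1 M standard state
(dG_S < 0 for favourable binding), reported in nM.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import R_KCAL
from .trajectory_io import ParticleSet, FrameSeries, ROLE_LIGAND, ROLE_PROTEIN

CONTACT_CLASSES = ("CC", "CN", "CO", "CX", "NN", "NO", "NX", "OO", "OX", "XX")


@dataclass
class HBondCriteria:
    max_da_distance: float = 3.5        # donor-acceptor, A
    max_hda_angle: float = 30.0         # hydrogen-donor-acceptor, degrees

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.max_hda_angle <= 90:
            raise ValueError("angle cutoff must be in (0, 90] degrees")


@dataclass
class HBondSeries:
    times: np.ndarray
    bonds: pd.DataFrame            # frame, time_ns, donor, hydrogen, acceptor,
    #                                partner_resname, partner_resid
    bound_to_anchor: np.ndarray    # (F,) bool


@dataclass
class BoundWindow:
    t_start: float
    t_end: float
    hbond_frequency: float
    alternate_site_label: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.hbond_frequency <= 1:
            raise ValueError("frequency must lie in [0, 1]")


@dataclass
class ScoringCoefficients:
    """Linear contact-score coefficients; pure configuration."""
    intercept: float
    weights: dict[str, float]
    cutoff: float = 10.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScoringCoefficients":
        raw = yaml.safe_load(Path(path).read_text())
        # guard against YAML 1.1 booleanisation of bare NO/ON keys
        fixups = {True: "ON", False: "NO"}
        weights = {fixups.get(k, str(k)): float(v)
                   for k, v in raw["weights"].items()}
        return cls(intercept=float(raw["intercept"]), weights=weights,
                   cutoff=float(raw.get("cutoff", 10.5)))

    @classmethod
    def default(cls) -> "ScoringCoefficients":
        ref = importlib.resources.files("permlab.data").joinpath(
            "contact_score_synthetic_defaults.yaml")
        with importlib.resources.as_file(ref) as path:
            return cls.from_yaml(path)


@dataclass
class AffinityEstimate:
    per_frame: pd.DataFrame        # time_ns, one column per class, dG, KD_nM
    kd_median_nM: float
    kd_mean_nM: float
    sample_stride_ns: float
    temperature: float

    def __post_init__(self) -> None:
        kd = self.per_frame["KD_nM"].to_numpy()
        if not kd.min() <= self.kd_median_nM <= kd.max():
            raise ValueError("median K_D outside per-frame range")


def _polar_mask(particles: ParticleSet, mask: np.ndarray) -> np.ndarray:
    return mask & np.isin(particles.elements, ("N", "O"))


def infer_donors(particles: ParticleSet, coords0: np.ndarray,
                 mask: np.ndarray, max_dh: float = 1.25
                 ) -> list[tuple[int, int]]:
    """(donor, hydrogen) pairs: an H within ``max_dh`` A of an N/O of the
    same residue in the reference frame is treated as covalently bound."""
    polar = np.flatnonzero(_polar_mask(particles, mask))
    hydrogens = np.flatnonzero(mask & (particles.elements == "H"))
    pairs = []
    for h in hydrogens:
        same = polar[particles.residue_ids[polar]
                     == particles.residue_ids[h]]
        if len(same) == 0:
            continue
        d = np.linalg.norm(coords0[same] - coords0[h], axis=1)
        j = int(np.argmin(d))
        if d[j] <= max_dh:
            pairs.append((int(same[j]), int(h)))
    return pairs


def detect_hbonds(particles: ParticleSet, frames: FrameSeries,
                  criteria: HBondCriteria | None = None,
                  ligand_mask: np.ndarray | None = None,
                  protein_mask: np.ndarray | None = None,
                  anchor_prefix: str = "ARG", anchor_resid: int = 187,
                  ) -> HBondSeries:
    """Geometric ligand-protein hydrogen bonds over all frames.

    Both donation directions are evaluated.  ``bound_to_anchor`` marks
    frames with at least one bond whose protein partner is the anchor
    residue.
    """
    criteria = criteria or HBondCriteria()
    if ligand_mask is None:
        ligand_mask = particles.mask(ROLE_LIGAND)
    if protein_mask is None:
        protein_mask = particles.mask(ROLE_PROTEIN)
    if not _polar_mask(particles, ligand_mask).any():
        raise ValueError("no polar (N/O) atoms in the ligand selection")
    if not _polar_mask(particles, protein_mask).any():
        raise ValueError("no polar (N/O) atoms in the protein selection")

    coords0 = frames.coordinates[0].astype(float)
    pairs = []  # (donor, hydrogen, acceptor) index triples
    for d_mask, a_mask in ((ligand_mask, protein_mask),
                           (protein_mask, ligand_mask)):
        acceptors = np.flatnonzero(_polar_mask(particles, a_mask))
        for donor, hydrogen in infer_donors(particles, coords0, d_mask):
            for acc in acceptors:
                pairs.append((donor, hydrogen, int(acc)))

    xyz = frames.coordinates.astype(float)
    cos_cut = np.cos(np.deg2rad(criteria.max_hda_angle))
    records = []
    bound = np.zeros(frames.n_frames, dtype=bool)
    is_anchor = (np.char.startswith(particles.residue_names.astype(str),
                                    anchor_prefix)
                 & (particles.residue_ids == anchor_resid))
    for donor, hydrogen, acc in pairs:
        da = xyz[:, acc] - xyz[:, donor]
        d_da = np.linalg.norm(da, axis=1)
        dh = xyz[:, hydrogen] - xyz[:, donor]
        d_dh = np.linalg.norm(dh, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.einsum("fi,fi->f", da, dh) / (d_da * d_dh)
        hit = (d_da <= criteria.max_da_distance) & (cosang >= cos_cut)
        if not hit.any():
            continue
        partner = acc if particles.roles[acc] == ROLE_PROTEIN else donor
        if is_anchor[partner]:
            bound |= hit
        for f in np.flatnonzero(hit):
            records.append((int(f), float(frames.times[f]), donor, hydrogen,
                            acc, particles.residue_names[partner],
                            int(particles.residue_ids[partner])))
    bonds = pd.DataFrame(records, columns=[
        "frame", "time_ns", "donor", "hydrogen", "acceptor",
        "partner_resname", "partner_resid"])
    return HBondSeries(times=frames.times, bonds=bonds,
                       bound_to_anchor=bound)


def best_bound_window(series: HBondSeries, span: float = 50.0,
                      stride: float = 1.0) -> BoundWindow:
    """Sliding 50 ns window maximising the anchor H-bond frequency.

    Candidate starts are stride-aligned from the first frame; frames with
    t in [t0, t0 + span) count.  Ties resolve to the earliest window.
    """
    t = series.times
    if t[-1] - t[0] < span:
        raise ValueError("trajectory shorter than the window span")
    bound = series.bound_to_anchor.astype(float)
    csum = np.concatenate([[0.0], np.cumsum(bound)])
    starts = []
    t0 = t[0]
    while t0 + span <= t[-1] + 1e-9:
        starts.append(t0)
        t0 += stride
    best = (-1.0, 0.0)
    for t0 in starts:
        i0 = int(np.searchsorted(t, t0 - 1e-9))
        i1 = int(np.searchsorted(t, t0 + span - 1e-9))
        if i1 <= i0:
            continue
        freq = (csum[i1] - csum[i0]) / (i1 - i0)
        if freq > best[0] + 1e-12:
            best = (freq, t0)
    freq, t0 = best
    if freq == 0.0:
        warnings.warn("ligand never hydrogen-bonds to the anchor; the "
                      "bound-state window is arbitrary")
    return BoundWindow(t_start=float(t0), t_end=float(t0 + span),
                       hbond_frequency=float(max(freq, 0.0)))


def _contact_class(e1: str, e2: str) -> str:
    a = e1 if e1 in ("C", "N", "O") else "X"
    b = e2 if e2 in ("C", "N", "O") else "X"
    return "".join(sorted((a, b)))


def count_contacts(particles: ParticleSet, frame_coords: np.ndarray,
                   ligand_mask: np.ndarray, protein_mask: np.ndarray,
                   cutoff: float = 10.5) -> dict[str, int]:
    """Heavy-atom ligand-protein contacts within ``cutoff``, classified by
    unordered element pair with elements mapped to {C, N, O, X}."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lig = np.flatnonzero(ligand_mask & (particles.elements != "H"))
    pro = np.flatnonzero(protein_mask & (particles.elements != "H"))
    if len(lig) == 0 or len(pro) == 0:
        raise ValueError("empty ligand or protein selection")
    d = np.linalg.norm(frame_coords[lig, None, :] - frame_coords[None, pro, :],
                       axis=2)
    counts = dict.fromkeys(CONTACT_CLASSES, 0)
    for i, j in zip(*np.nonzero(d <= cutoff)):
        counts[_contact_class(particles.elements[lig[i]],
                              particles.elements[pro[j]])] += 1
    return counts


def score_binding_energy(contact_counts: dict[str, int],
                         coefficients: ScoringCoefficients) -> float:
    """dG_S = intercept + sum_class weight * count  (kcal/mol)."""
    dg = coefficients.intercept
    for cls, count in contact_counts.items():
        if count == 0:
            continue
        if cls not in coefficients.weights:
            raise ValueError(f"no weight configured for contact class {cls}")
        dg += coefficients.weights[cls] * count
    return float(dg)


def kd_from_dg(dg: float, temperature: float = 310.15) -> float:
    """K_D in nM from a binding free energy in kcal/mol.

    K_D(M) = exp(dG / RT) at the 1 M standard state; negative dG means
    favourable binding and sub-molar K_D.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return float(np.exp(dg / (R_KCAL * temperature)) * 1e9)


def dg_from_kd(kd_nM: float, temperature: float = 310.15) -> float:
    """Inverse of :func:`kd_from_dg`."""
    if kd_nM <= 0:
        raise ValueError("K_D must be positive")
    return float(np.log(kd_nM * 1e-9) * R_KCAL * temperature)


def affinity_over_trajectory(particles: ParticleSet, frames: FrameSeries,
                             coefficients: ScoringCoefficients | None = None,
                             ligand_mask: np.ndarray | None = None,
                             protein_mask: np.ndarray | None = None,
                             sample_stride_ns: float = 1.0,
                             temperature: float = 310.15) -> AffinityEstimate:
    """Contacts -> dG_S -> K_D at every sampled frame; median and mean K_D
    over all sampled frames (bound or not)."""
    coefficients = coefficients or ScoringCoefficients.default()
    if ligand_mask is None:
        ligand_mask = particles.mask(ROLE_LIGAND)
    if not ligand_mask.any():
        raise ValueError("no ligand present")
    if protein_mask is None:
        protein_mask = particles.mask(ROLE_PROTEIN)

    t = frames.times
    wanted = np.arange(t[0], t[-1] + 1e-9, sample_stride_ns)
    idx = np.unique(np.searchsorted(t, wanted - 1e-9))
    idx = idx[idx < len(t)]

    rows = []
    for f in idx:
        counts = count_contacts(particles, frames.coordinates[f].astype(float),
                                ligand_mask, protein_mask,
                                cutoff=coefficients.cutoff)
        dg = score_binding_energy(counts, coefficients)
        rows.append({"time_ns": float(t[f]), **counts, "dG_kcal_mol": dg,
                     "KD_nM": kd_from_dg(dg, temperature)})
    per_frame = pd.DataFrame(rows)
    return AffinityEstimate(
        per_frame=per_frame,
        kd_median_nM=float(per_frame["KD_nM"].median()),
        kd_mean_nM=float(per_frame["KD_nM"].mean()),
        sample_stride_ns=sample_stride_ns, temperature=temperature)
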