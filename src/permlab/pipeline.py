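"""Per-condition analysis orchestration and cross-condition comparison.

``analyze_condition`` runs the full chain on an in-memory system
(geometry -> membership -> crossings/replicates -> collective-coordinate
permeability -> density/free-energy profiles -> ligand affinity when a
ligand is present) and returns a ConditionReport.  ``run_condition`` is
the file-based wrapper.  ``compare_conditions`` assembles the replicate
table across conditions, runs the pairwise Wilcoxon/Bonferroni tests and
computes WIP coefficients against the control.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .trajectory_io import (ParticleSet, FrameSeries, SelectionConfig,
                            load_system, define_pore_regions, assign_waters,
                            ROLE_LIGAND)
from .permeability import (detect_crossings, collective_coordinate,
                           estimate_Dn, compute_pf, PermeabilityEstimate)
from .energetics import density_profile, bulk_density, free_energy_profile
from .binding import (HBondCriteria, ScoringCoefficients, detect_hbonds,
                      best_bound_window, affinity_over_trajectory)
from .inhibition import (ReplicateTable, split_replicates, wilcoxon_pairwise,
                         pairwise_to_frame, compute_wip)


@dataclass
class RunConfig:
    label: str
    topology: str
    trajectory: str
    selections: SelectionConfig = field(default_factory=SelectionConfig)
    coefficients: ScoringCoefficients | None = None
    hbond_criteria: HBondCriteria = field(default_factory=HBondCriteria)
    window_ns: float = 10.0
    sample_stride_ns: float = 1.0
    temperature: float = 310.15
    fit_window: tuple[float, float] = (0.1, 1.0)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text())
        sel = raw.get("selections")
        kwargs = dict(
            label=raw["label"], topology=raw["topology"],
            trajectory=raw["trajectory"])
        if sel:
            kwargs["selections"] = SelectionConfig.from_yaml(sel) \
                if isinstance(sel, str) else SelectionConfig(**sel)
        if "coefficients" in raw:
            kwargs["coefficients"] = ScoringCoefficients.from_yaml(
                raw["coefficients"])
        for key in ("window_ns", "sample_stride_ns", "temperature"):
            if key in raw:
                kwargs[key] = float(raw[key])
        return cls(**kwargs)


@dataclass
class ConditionReport:
    label: str
    replicates: pd.DataFrame          # window_index, monomer, count
    window_ns: float
    pf: list[PermeabilityEstimate]
    free_energy: pd.DataFrame         # z_center, G per monomer column
    rho_bulk: float
    kd_median_nM: float | None
    kd_mean_nM: float | None
    best_window: tuple[float, float] | None
    hbond_frequency: float | None
    provenance: str = ""

    @property
    def mean_count(self) -> float:
        return float(self.replicates["count"].mean())

    def pf_mean(self) -> float:
        return float(np.mean([p.pf_cm3_per_s for p in self.pf]))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "label": self.label, "window_ns": self.window_ns,
            "mean_count": self.mean_count,
            "replicates": self.replicates.to_dict(orient="records"),
            "pf": [vars(p) for p in self.pf],
            "pf_mean_cm3_s": self.pf_mean(),
            "rho_bulk": self.rho_bulk,
            "free_energy": self.free_energy.to_dict(orient="list"),
            "kd_median_nM": self.kd_median_nM,
            "kd_mean_nM": self.kd_mean_nM,
            "best_window": self.best_window,
            "hbond_frequency": self.hbond_frequency,
            "provenance": self.provenance,
            "version": __version__,
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=float))


def _provenance(label: str, extras: dict) -> str:
    digest = hashlib.sha256(
        json.dumps({"label": label, **extras}, sort_keys=True,
                   default=str).encode()).hexdigest()
    return digest[:16]


def analyze_condition(particles: ParticleSet, frames: FrameSeries,
                      label: str,
                      selections: SelectionConfig | None = None,
                      coefficients: ScoringCoefficients | None = None,
                      hbond_criteria: HBondCriteria | None = None,
                      window_ns: float = 10.0,
                      sample_stride_ns: float = 1.0,
                      temperature: float = 310.15,
                      fit_window: tuple[float, float] = (0.1, 1.0),
                      compute_profiles: bool = True) -> ConditionReport:
    """Full single-condition analysis on an in-memory system."""
    sel = selections or SelectionConfig()
    regions = define_pore_regions(
        particles, frames, anchor_prefix=sel.anchor_prefix,
        anchor_resid=sel.anchor_resid, radius=sel.radius,
        length=sel.section_length)
    membership = assign_waters(particles, frames, regions)

    events = detect_crossings(membership, frames, regions)
    replicates = split_replicates(
        events, float(frames.times[0]), float(frames.times[-1]),
        window_ns=window_ns,
        monomer_labels=[r.monomer_label for r in regions])

    pf_estimates = []
    for region in regions:
        series = collective_coordinate(membership, frames, region)
        try:
            d_n, stderr, nonlin = estimate_Dn(series, fit_window=fit_window)
        except ValueError:
            continue
        pf_estimates.append(compute_pf(
            max(d_n, 0.0), temperature, monomer_label=region.monomer_label,
            D_n_stderr=stderr, fit_window=fit_window,
            nonlinearity_ratio=nonlin))

    fe = pd.DataFrame()
    rho_bulk = float("nan")
    if compute_profiles:
        z_low, z_high = regions[0].z_low, regions[0].z_high
        box_z = float(frames.box[0, 2])
        slab = (z_high + 2.0, min(z_high + 12.0, box_z))
        rho_bulk = bulk_density(particles, frames, slab,
                                membrane_z_range=(z_low, z_high))
        for region in regions:
            dens = density_profile(membership, frames, region)
            profile = free_energy_profile(dens, temperature,
                                          rho_bulk=rho_bulk)
            if fe.empty:
                fe["z_center"] = profile.z_centers
            fe[f"G_{region.monomer_label}"] = profile.G

    kd_median = kd_mean = None
    best = None
    freq = None
    if particles.mask(ROLE_LIGAND).any():
        series = detect_hbonds(particles, frames,
                               hbond_criteria or HBondCriteria(),
                               anchor_prefix=sel.anchor_prefix,
                               anchor_resid=sel.anchor_resid)
        span = float(frames.times[-1] - frames.times[0])
        window_span = min(50.0, span)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bw = best_bound_window(series, span=window_span,
                                   stride=sample_stride_ns)
        best = (bw.t_start, bw.t_end)
        freq = bw.hbond_frequency
        affinity = affinity_over_trajectory(
            particles, frames, coefficients,
            sample_stride_ns=sample_stride_ns, temperature=temperature)
        kd_median = affinity.kd_median_nM
        kd_mean = affinity.kd_mean_nM

    return ConditionReport(
        label=label, replicates=replicates, window_ns=window_ns,
        pf=pf_estimates, free_energy=fe, rho_bulk=rho_bulk,
        kd_median_nM=kd_median, kd_mean_nM=kd_mean, best_window=best,
        hbond_frequency=freq,
        provenance=_provenance(label, {
            "n_frames": frames.n_frames, "n_atoms": particles.n_atoms,
            "window_ns": window_ns, "stride": sample_stride_ns}))


def run_condition(config: RunConfig) -> ConditionReport:
    """Load a condition from files and analyse it."""
    particles, frames = load_system(config.topology, config.trajectory,
                                    config.selections)
    return analyze_condition(
        particles, frames, config.label, selections=config.selections,
        coefficients=config.coefficients,
        hbond_criteria=config.hbond_criteria, window_ns=config.window_ns,
        sample_stride_ns=config.sample_stride_ns,
        temperature=config.temperature, fit_window=config.fit_window)


@dataclass
class ComparisonResult:
    replicate_table: ReplicateTable
    tests: pd.DataFrame
    wip_table: pd.DataFrame

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.replicate_table.to_tsv(outdir / "replicates.tsv")
        self.tests.to_csv(outdir / "pairwise_tests.tsv", sep="\t",
                          index=False)
        self.wip_table.to_csv(outdir / "wip.tsv", sep="\t", index=False)


def compare_conditions(reports: list[ConditionReport], control_label: str,
                       concentration_nM: float = 100.0) -> ComparisonResult:
    """Wilcoxon/Bonferroni comparisons and WIP ranking vs the control."""
    labels = [r.label for r in reports]
    if control_label not in labels:
        raise ValueError(f"control condition {control_label!r} missing")
    if len(reports) < 2:
        raise ValueError("need at least two conditions")
    reports = sorted(reports, key=lambda r: (r.label != control_label,
                                             r.label))
    table = ReplicateTable()
    for rep in reports:
        table.add_condition(rep.label, rep.replicates)
    tests = pairwise_to_frame(wilcoxon_pairwise(table))

    control = next(r for r in reports if r.label == control_label)
    wip_rows = []
    for rep in reports:
        if rep.label == control_label or rep.kd_median_nM is None:
            continue
        n_monomers = rep.replicates["monomer"].nunique()
        res = compute_wip(control.mean_count, rep.mean_count,
                          rep.window_ns, rep.kd_median_nM,
                          condition=rep.label, n_monomers=n_monomers,
                          concentration_nM=concentration_nM)
        wip_rows.append(vars(res))
    wip = pd.DataFrame(wip_rows)
    if not wip.empty:
        wip = wip.sort_values("wip_cm3_s_nM", ascending=False,
                              ignore_index=True)
    return ComparisonResult(replicate_table=table, tests=tests,
                            wip_table=wip)
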