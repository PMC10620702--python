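"""Replicate bookkeeping, pairwise Wilcoxon tests and the WIP coefficient.

Each 200 ns trajectory is split into 10 ns sub-trajectories analysed per
monomer, yielding 80 replicate crossing counts per condition for a
4-monomer channel.  Conditions are compared pairwise with the two-sided
Wilcoxon rank-sum (Mann-Whitney) test under Bonferroni correction.

The Water-fluxes Inhibitory Potential coefficient combines the mean
crossing-count reduction relative to the steroid-free control with the
median dissociation constant of the docked steroid:

    WIP = delta_counts[1/s] * (V_m / N_A) / K_D_median   [cm^3/s/nM]

so that WIP * concentration estimates the single-tetramer water-flux
reduction (cm^3/s) at that steroid concentration.  The placement of the
constants follows from dimensional analysis against the stated unit.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .constants import SINGLE_WATER_VOLUME_CM3, NS_TO_S
from .permeability import CrossingEvent


@dataclass
class PairwiseTestResult:
    condition_a: str
    condition_b: str
    statistic: float
    p_raw: float
    p_adjusted: float
    n_comparisons: int
    method: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.p_adjusted + 1e-15 < self.p_raw:
            raise ValueError("adjusted p cannot be below raw p")


@dataclass
class WIPResult:
    condition: str
    delta_counts_per_s: float
    kd_median_nM: float
    wip_cm3_s_nM: float
    concentration_nM: float
    flux_reduction_cm3_s: float
    enhancement: bool = False


class ReplicateTable:
    """Per-condition replicate water-crossing counts.

    Wraps a DataFrame with columns (condition, window_index, monomer,
    count); one row per 10 ns window per monomer.
    """

    COLUMNS = ("condition", "window_index", "monomer", "count")

    def __init__(self, df: pd.DataFrame | None = None):
        self.df = (df if df is not None
                   else pd.DataFrame(columns=list(self.COLUMNS)))
        if list(self.df.columns) != list(self.COLUMNS):
            raise ValueError(f"expected columns {self.COLUMNS}")
        if len(self.df) and (self.df["count"] < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.df["condition"]))

    def add_condition(self, label: str, replicates: pd.DataFrame) -> None:
        block = replicates.assign(condition=label)[list(self.COLUMNS)]
        self.df = pd.concat([self.df, block], ignore_index=True)

    def counts(self, condition: str) -> np.ndarray:
        sel = self.df[self.df["condition"] == condition]["count"]
        if sel.empty:
            raise KeyError(f"no condition {condition!r}")
        return sel.to_numpy(dtype=float)

    def n_replicates(self, condition: str) -> int:
        return len(self.counts(condition))

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReplicateTable":
        return cls(pd.read_csv(path, sep="\t")[list(cls.COLUMNS)])


def split_replicates(events: list[CrossingEvent], t_start: float,
                     t_end: float, window_ns: float = 10.0,
                     monomer_labels: list[str] | None = None) -> pd.DataFrame:
    """One crossing count per (window, monomer); events assigned by exit
    time.  A trailing partial window is dropped with a warning."""
    if window_ns <= 0:
        raise ValueError("window must be positive")
    span = t_end - t_start
    n_windows = int(span / window_ns + 1e-9)
    if n_windows < 1:
        raise ValueError("trajectory shorter than one window")
    if span - n_windows * window_ns > 1e-6 * window_ns:
        warnings.warn(f"dropping trailing {span - n_windows * window_ns:.3g} "
                      "ns that does not fill a window")
    if monomer_labels is None:
        monomer_labels = sorted({e.monomer_label for e in events})
    rows = [
        {"window_index": w, "monomer": m,
         "count": sum(1 for e in events
                      if e.monomer_label == m
                      and t_start + w * window_ns <= e.t_exit
                      < t_start + (w + 1) * window_ns)}
        for w in range(n_windows) for m in monomer_labels
    ]
    return pd.DataFrame(rows)


def rank_sum_test(a: np.ndarray, b: np.ndarray, exact_max_n: int = 12
                  ) -> tuple[float, float, str, bool]:
    """Two-sided Mann-Whitney rank-sum test.

    Exact null distribution when both samples have <= ``exact_max_n``
    observations and there are no ties; tie-corrected normal
    approximation otherwise.  Two identical constant samples are
    degenerate and return p = 1.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if min(len(a), len(b)) < 3:
        raise ValueError("need at least 3 replicates per condition")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 0.5 * len(a) * len(b), 1.0, "degenerate", True
    ties = len(np.unique(pooled)) < len(pooled)
    if not ties and max(len(a), len(b)) <= exact_max_n:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0)), method, False


def wilcoxon_pairwise(table: ReplicateTable, exact_max_n: int = 12
                      ) -> list[PairwiseTestResult]:
    """All unordered condition pairs, Bonferroni-corrected over the number
    of pairs tested."""
    conditions = table.conditions
    pairs = list(itertools.combinations(conditions, 2))
    m = len(pairs)
    if m == 0:
        raise ValueError("need at least two conditions")
    results = []
    for ca, cb in pairs:
        stat, p, method, degen = rank_sum_test(
            table.counts(ca), table.counts(cb), exact_max_n=exact_max_n)
        results.append(PairwiseTestResult(
            condition_a=ca, condition_b=cb, statistic=stat, p_raw=p,
            p_adjusted=min(1.0, m * p), n_comparisons=m, method=method,
            degenerate=degen))
    return results


def pairwise_to_frame(results: list[PairwiseTestResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def compute_wip(mean_counts_control: float, mean_counts_condition: float,
                window_duration_ns: float, kd_median_nM: float,
                condition: str = "", n_monomers: int = 4,
                per: str = "tetramer",
                concentration_nM: float = 100.0) -> WIPResult:
    """WIP coefficient from replicate-mean crossing counts.

    ``mean_counts_*`` are means over (window x monomer) replicates; the
    count difference is converted to a tetramer-wide (or per-monomer)
    rate in 1/s before scaling by v_w / K_D.  A negative difference
    (flux enhancement) is preserved and flagged.
    """
    if kd_median_nM <= 0:
        raise ValueError("K_D must be positive")
    if window_duration_ns <= 0:
        raise ValueError("window duration must be positive")
    scale = n_monomers if per == "tetramer" else 1
    delta = ((mean_counts_control - mean_counts_condition) * scale
             / (window_duration_ns * NS_TO_S))
    wip = delta * SINGLE_WATER_VOLUME_CM3 / kd_median_nM
    enhancement = delta < 0
    if enhancement:
        warnings.warn(f"condition {condition!r} increases water counts; "
                      "WIP reported with negative sign")
    return WIPResult(
        condition=condition, delta_counts_per_s=delta,
        kd_median_nM=kd_median_nM, wip_cm3_s_nM=wip,
        concentration_nM=concentration_nM,
        flux_reduction_cm3_s=wip * concentration_nM, enhancement=enhancement)
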