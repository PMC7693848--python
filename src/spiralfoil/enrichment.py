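"""Enrichment-performance statistics for one- and two-cycle processing.

Count-based metrics for a size-selective CTC chip: bead recovery and
purity, per-cycle WBC depletion and CTC recovery (both cycles referenced
to the original inlet), viable/total cell loss from Trypan-blue counts,
the through-origin linear-fit recovery estimator used on spiking series,
the CTC enrichment factor implied by WBC depletion, and the volume/time
bookkeeping of the two-cycle protocol.

All percentages are on the 0–100 scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import UndefinedMetricError, SpiralfoilError

__all__ = [
    "BeadCounts",
    "CycleCounts",
    "ViabilityCounts",
    "SpikingSeries",
    "CycleVolumes",
    "bead_recovery",
    "bead_purity",
    "wbc_depletion",
    "ctc_recovery",
    "cell_loss",
    "linear_fit_recovery",
    "enrichment_factor",
    "cycle_bookkeeping",
]


def _check_nonneg(**counts: float) -> None:
    for name, value in counts.items():
        if value < 0:
            raise SpiralfoilError(f"{name} cannot be negative")


@dataclass(frozen=True)
class BeadCounts:
    """Microbead counts at the two outlets (17 µm = CTC surrogate)."""

    n17_ctc: int
    n17_waste: int
    n10_ctc: int
    n10_waste: int

    def __post_init__(self) -> None:
        _check_nonneg(**self.__dict__)


@dataclass(frozen=True)
class CycleCounts:
    """WBC and MCF7 counts across a two-cycle run.

    Cycle-2 outlet counts describe the re-processed CTC-1 fraction; both
    cycles' metrics are referenced to the original inlet.
    """

    wbc_inlet: int
    wbc_ctc_c1: int
    wbc_ctc_c2: int
    mcf7_inlet: int
    mcf7_waste_c1: int
    mcf7_waste_c2: int

    def __post_init__(self) -> None:
        _check_nonneg(**self.__dict__)
        if not (self.wbc_ctc_c2 <= self.wbc_ctc_c1 <= self.wbc_inlet):
            warnings.warn(
                "WBC counts do not decrease along the cycles as expected",
                RuntimeWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class ViabilityCounts:
    """Trypan-blue viable/total counts at inlet and (pooled) outlets."""

    viable_inlet: int
    total_inlet: int
    viable_outlets: int
    total_outlets: int

    def __post_init__(self) -> None:
        _check_nonneg(**self.__dict__)
        if self.viable_inlet > self.total_inlet or self.viable_outlets > self.total_outlets:
            raise SpiralfoilError("viable count exceeds total count")


@dataclass(frozen=True)
class SpikingSeries:
    """Spiked-vs-recovered pairs from a dilution series."""

    levels: np.ndarray    # n_spiked per experiment
    recovered: np.ndarray

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, dtype=float)
        rc = np.asarray(self.recovered, dtype=float)
        if lv.size != rc.size or lv.size < 3:
            raise SpiralfoilError("need at least 3 matched spiking levels")
        if np.any(rc > lv):
            warnings.warn(
                "recovered exceeds spiked at some level", RuntimeWarning, stacklevel=2
            )
        object.__setattr__(self, "levels", lv)
        object.__setattr__(self, "recovered", rc)


@dataclass(frozen=True)
class CycleVolumes:
    """Processed volume, outlet split ratio and flow rate of one cycle."""

    input_volume_ml: float
    split_ratio: tuple[float, float] = (2.0, 3.0)  # CTC : waste
    flow_rate_ml_min: float = 1.2

    def __post_init__(self) -> None:
        if self.input_volume_ml <= 0 or self.flow_rate_ml_min <= 0:
            raise SpiralfoilError("volumes and flow rate must be positive")
        if min(self.split_ratio) <= 0:
            raise SpiralfoilError("split ratio components must be positive")


# --------------------------------------------------------------------------- #
# metrics
# --------------------------------------------------------------------------- #

def bead_recovery(counts: BeadCounts) -> float:
    """Percent of 17 µm beads collected at the CTC outlet."""
    denom = counts.n17_ctc + counts.n17_waste
    if denom == 0:
        raise UndefinedMetricError("no 17 µm beads at either outlet")
    return 100.0 * counts.n17_ctc / denom


def bead_purity(counts: BeadCounts) -> float:
    """Percent of beads at the CTC outlet that are 17 µm."""
    denom = counts.n17_ctc + counts.n10_ctc
    if denom == 0:
        raise UndefinedMetricError("no beads at the CTC outlet")
    return 100.0 * counts.n17_ctc / denom


def wbc_depletion(counts: CycleCounts, cycle: int) -> float:
    """Percent of inlet WBCs removed after the given cycle (1 or 2)."""
    if counts.wbc_inlet == 0:
        raise UndefinedMetricError("zero inlet WBC count")
    outlet = {1: counts.wbc_ctc_c1, 2: counts.wbc_ctc_c2}[cycle]
    return 100.0 * (1.0 - outlet / counts.wbc_inlet)


def ctc_recovery(counts: CycleCounts, cycle: int) -> float:
    """Percent of inlet MCF7 cells retained after the given cycle (1 or 2).

    Cycle 2 counts the cumulative escape to both waste outlets relative to
    the original inlet.
    """
    if counts.mcf7_inlet == 0:
        raise UndefinedMetricError("zero inlet MCF7 count")
    waste = {
        1: counts.mcf7_waste_c1,
        2: counts.mcf7_waste_c1 + counts.mcf7_waste_c2,
    }[cycle]
    return 100.0 * (1.0 - waste / counts.mcf7_inlet)


def cell_loss(v: ViabilityCounts) -> dict[str, float]:
    """Viable and total cell loss plus viabilities at inlet and outlets."""
    if v.viable_inlet == 0 or v.total_inlet == 0:
        raise UndefinedMetricError("zero inlet cell count")
    return {
        "viable_loss": 100.0 * (v.viable_inlet - v.viable_outlets) / v.viable_inlet,
        "total_loss": 100.0 * (v.total_inlet - v.total_outlets) / v.total_inlet,
        "viability_in": 100.0 * v.viable_inlet / v.total_inlet,
        "viability_out": (
            100.0 * v.viable_outlets / v.total_outlets if v.total_outlets else float("nan")
        ),
    }


def linear_fit_recovery(series: SpikingSeries) -> dict[str, float]:
    """Recovery rate from a through-origin least-squares fit.

    Regresses recovered on spiked counts with zero intercept (a zero-spike
    sample recovers zero cells); the slope times 100 is the recovery rate
    in percent, with R² evaluated on the through-origin model.
    """
    x, y = series.levels, series.recovered
    sxx = float(np.dot(x, x))
    if sxx == 0.0 or np.ptp(x) == 0.0:
        raise UndefinedMetricError("degenerate spiking series (no spread)")
    slope = float(np.dot(x, y)) / sxx
    resid = y - slope * x
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.dot(y, y))  # uncentered total SS for a no-intercept model
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return {"rate": 100.0 * slope, "r_squared": r2}


def enrichment_factor(depletion_percent: float) -> float:
    """Fold enrichment implied by a WBC depletion: 100 / (100 − depletion)."""
    if not (0.0 <= depletion_percent <= 100.0):
        raise SpiralfoilError("depletion must lie in [0, 100]")
    if depletion_percent == 100.0:
        return float("inf")
    return 100.0 / (100.0 - depletion_percent)


def cycle_bookkeeping(v: CycleVolumes) -> dict[str, float]:
    """Split the processed volume by the outlet ratio and report run time.

    The exact split ratio is applied; volume is conserved exactly and the
    process time is input volume over flow rate.
    """
    c, w = v.split_ratio
    ctc = v.input_volume_ml * c / (c + w)
    return {
        "ctc_volume_ml": ctc,
        "waste_volume_ml": v.input_volume_ml - ctc,
        "process_time_min": v.input_volume_ml / v.flow_rate_ml_min,
    }
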