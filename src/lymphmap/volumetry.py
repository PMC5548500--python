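"""Compartment and tissue volumes per arm, and paired excess metrics.

All volumes come from voxel counting at 1 mm isotropic resolution
(1 voxel = 1 mm^3 = 0.001 mL). Six volumes describe one arm: total arm,
subfascial, epifascial, muscle (subfascial), fat (epifascial) and fluid
(epifascial). Mixed-composition voxels count toward the compartment volumes
(they are tissue) but toward no single tissue volume. Fluid found inside the
subfascial compartment is counted in the subfascial volume but not in the
epifascial fluid volume; its count is kept as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compartments import Compartment
from .exceptions import LymphmapError, ShapeMismatchError
from .segmentation import Tissue
from .volume_io import VOXEL_ML

#: the six per-arm volume metrics, in reporting order
METRICS = ("total_arm", "subfascial", "epifascial",
           "muscle_subfascial", "fat_epifascial", "fluid_epifascial")


@dataclass
class CompartmentVolumes:
    """The six per-arm volumes, in mL."""

    total_arm: float
    subfascial: float
    epifascial: float
    muscle_subfascial: float
    fat_epifascial: float
    fluid_epifascial: float
    subfascial_fluid_voxels: int = 0   # diagnostic: fluid misplaced below the fascia

    def __post_init__(self) -> None:
        vals = self.as_dict()
        if any(v < 0 for v in vals.values()):
            raise LymphmapError(f"volumes must be non-negative: {vals}")

    def as_dict(self) -> dict[str, float]:
        return {m: float(getattr(self, m)) for m in METRICS}


def measure_volumes(labels: np.ndarray, compartments: np.ndarray) -> CompartmentVolumes:
    """Count voxels per compartment/tissue and convert to mL.

    Fat and fluid are counted only within the epifascial compartment, muscle
    only within the subfascial compartment.
    """
    labels = np.asarray(labels)
    compartments = np.asarray(compartments)
    if labels.shape != compartments.shape:
        raise ShapeMismatchError(
            f"labels {labels.shape} vs compartments {compartments.shape}")
    sub = compartments == Compartment.SUBFASCIAL
    epi = compartments == Compartment.EPIFASCIAL
    return CompartmentVolumes(
        total_arm=float(sub.sum() + epi.sum()) * VOXEL_ML,
        subfascial=float(sub.sum()) * VOXEL_ML,
        epifascial=float(epi.sum()) * VOXEL_ML,
        muscle_subfascial=float((sub & (labels == Tissue.MUSCLE)).sum()) * VOXEL_ML,
        fat_epifascial=float((epi & (labels == Tissue.FAT)).sum()) * VOXEL_ML,
        fluid_epifascial=float((epi & (labels == Tissue.FLUID)).sum()) * VOXEL_ML,
        subfascial_fluid_voxels=int((sub & (labels == Tissue.FLUID)).sum()))


@dataclass
class ArmComparison:
    """Affected vs unaffected volumes with excesses and percentage changes.

    ``percent_change[m]`` is (affected - unaffected) / unaffected * 100, and
    is None where the unaffected volume is zero (undefined, not infinity).
    ``relative_excess`` normalizes the epifascial, fat and fluid excesses by
    the unaffected arm's epifascial volume, removing arm-size differences.
    """

    affected: dict[str, float]
    unaffected: dict[str, float]
    excess: dict[str, float] = field(init=False)
    percent_change: dict[str, float | None] = field(init=False)
    relative_excess: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.excess = {m: self.affected[m] - self.unaffected[m] for m in METRICS}
        self.percent_change = {
            m: (100.0 * self.excess[m] / self.unaffected[m]) if self.unaffected[m] > 0 else None
            for m in METRICS}
        denom = self.unaffected["epifascial"]
        if denom > 0:
            self.relative_excess = {
                m: self.excess[m] / denom
                for m in ("epifascial", "fat_epifascial", "fluid_epifascial")}
        else:
            self.relative_excess = {}

    def to_frame(self) -> pd.DataFrame:
        """Table with one row per metric: affected, unaffected, excess, % change."""
        return pd.DataFrame({
            "metric": METRICS,
            "affected_ml": [self.affected[m] for m in METRICS],
            "unaffected_ml": [self.unaffected[m] for m in METRICS],
            "excess_ml": [self.excess[m] for m in METRICS],
            "percent_change": [self.percent_change[m] for m in METRICS],
        })


def compare_arms(affected: CompartmentVolumes, unaffected: CompartmentVolumes) -> ArmComparison:
    """Paired comparison of the six volumes of an affected/unaffected pair."""
    return ArmComparison(affected=affected.as_dict(), unaffected=unaffected.as_dict())


def epifascial_share_of_excess(comparison: ArmComparison) -> float:
    """Fraction of the total-arm excess volume located in the epifascial layer."""
    total = comparison.excess["total_arm"]
    if total == 0:
        raise LymphmapError("total excess volume is zero; share undefined")
    return comparison.excess["epifascial"] / total


__all__ = ["METRICS", "CompartmentVolumes", "ArmComparison", "measure_volumes",
           "compare_arms", "epifascial_share_of_excess"]
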