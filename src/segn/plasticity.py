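"""Dynamic plasticity: treatment-difference time courses.

Dynamic transcriptional plasticity (DTP) of a gene, and dynamic phenotypic
plasticity (DPP) of a trait, are the differences of the entity's value
between a stress treatment (2) and a control treatment (1) over a shared
time schedule.  Replicates within each (treatment, time) cell are averaged
before differencing: clonal replicates are exchangeable, so the design is
unpaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .lop import LopCurve, fit_lop_curve, select_lop_order

__all__ = ["SampleDesign", "PlasticitySeries", "compute_plasticity", "fit_plasticity_curve"]


@dataclass(frozen=True)
class SampleDesign:
    """Two-treatment longitudinal design with replicates.

    ``time_points`` may be unevenly spaced but must be strictly increasing,
    and every (treatment, time) cell needs at least one replicate.
    """

    entity_ids: tuple[str, ...]
    time_points: tuple[float, ...]
    replicates: Mapping[tuple[int, float], int] = field(default_factory=dict)

    def __post_init__(self):
        tp = np.asarray(self.time_points, dtype=float)
        if len(tp) < 2 or np.any(np.diff(tp) <= 0):
            raise ValueError("time_points must be strictly increasing with >= 2 points")
        for key, count in self.replicates.items():
            if count < 1:
                raise ValueError(f"cell {key} has no replicates")


@dataclass
class PlasticitySeries:
    """Per-entity plasticity values on the design time grid."""

    entity_id: str
    times: np.ndarray
    values: np.ndarray
    kind: Literal["gene", "trait"] = "gene"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must align")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite plasticity values for {self.entity_id}")


def _cell_means(series: Mapping[float, Sequence[float]]) -> dict[float, float]:
    means = {}
    for t, reps in series.items():
        reps = np.asarray(reps, dtype=float)
        if reps.size == 0:
            raise ValueError(f"empty replicate cell at time {t}")
        means[float(t)] = float(reps.mean())
    return means


def compute_plasticity(
    series_t1: Mapping[float, Sequence[float]],
    series_t2: Mapping[float, Sequence[float]],
    entity_id: str = "",
    kind: Literal["gene", "trait"] = "gene",
) -> PlasticitySeries:
    """Treatment-2 minus treatment-1 cell means on the shared time grid.

    ``series_tk`` maps time -> replicate values under treatment k.  Raises
    on mismatched grids or empty cells.
    """
    t1 = _cell_means(series_t1)
    t2 = _cell_means(series_t2)
    if set(t1) != set(t2):
        raise ValueError(
            f"treatment time grids differ for {entity_id!r}: "
            f"{sorted(set(t1) ^ set(t2))} not shared"
        )
    times = np.array(sorted(t1))
    values = np.array([t2[t] - t1[t] for t in times])
    return PlasticitySeries(entity_id=entity_id, times=times, values=values, kind=kind)


def fit_plasticity_curve(
    series: PlasticitySeries, order: int | None = 4, select_by_aic: bool = False
) -> LopCurve:
    """Smooth LOP fit of a plasticity series.

    With ``select_by_aic`` the order is chosen per entity over 2..6;
    otherwise the given order (default 4) is used.
    """
    if select_by_aic:
        return select_lop_order(series.times, series.values)
    return fit_lop_curve(series.times, series.values, order)
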