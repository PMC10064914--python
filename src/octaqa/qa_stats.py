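"""The intraeye quadrant-asymmetry (QA) statistic.

QA of a metric is the maximum minus the minimum of its four quadrant values
within one eye.  Because both extremes come from the same eye, QA is immune
to eye-level confounders (age, axial length, refraction, signal strength)
that plague between-eye comparisons of raw OCTA densities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .etdrs_grid import QUADRANTS
from .vessel_metrics import QuadrantMetrics

__all__ = ["GROUPS", "METRICS", "EyeRecord", "QAValue", "quadrant_asymmetry", "cohort_qa_table"]

GROUPS = ("control", "non_ischemic", "ischemic")
METRICS = ("vld", "pd")


@dataclass(frozen=True)
class EyeRecord:
    """One eye at one timepoint: identity, group label and quadrant metrics."""

    patient_id: str
    eye_id: str
    group: str
    laterality: str
    metrics: QuadrantMetrics

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.laterality not in ("OD", "OS"):
            raise ValueError(f"laterality must be 'OD' or 'OS', got {self.laterality!r}")


@dataclass(frozen=True)
class QAValue:
    """max - min across the four quadrants, with the attaining quadrants."""

    metric: str
    value: float
    argmax_quadrant: str
    argmin_quadrant: str

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("QA is a range and cannot be negative")


def quadrant_asymmetry(metrics: QuadrantMetrics, metric: str) -> QAValue:
    """QA = max - min of the four quadrant values of ``metric``.

    Ties for the extremes are broken by the fixed quadrant order
    (superior, inferior, nasal, temporal) so provenance is deterministic.
    The value itself is invariant to any relabeling of quadrants.
    """
    values = metrics.values(metric)
    arr = np.array([values[q] for q in QUADRANTS], dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite quadrant value in {metric}: {values}")
    i_max = int(np.argmax(arr))  # argmax/argmin return the first of tied extremes
    i_min = int(np.argmin(arr))
    return QAValue(
        metric=metric,
        value=float(arr[i_max] - arr[i_min]),
        argmax_quadrant=QUADRANTS[i_max],
        argmin_quadrant=QUADRANTS[i_min],
    )


def cohort_qa_table(records: list[EyeRecord]) -> pd.DataFrame:
    """One QA row per eye per metric.

    Columns: patient_id, eye_id, group, laterality, metric, qa,
    max_quadrant, min_quadrant.
    """
    if not records:
        raise ValueError("cohort is empty")
    rows = []
    for rec in records:
        for metric in METRICS:
            qa = quadrant_asymmetry(rec.metrics, metric)
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "eye_id": rec.eye_id,
                    "group": rec.group,
                    "laterality": rec.laterality,
                    "metric": metric,
                    "qa": qa.value,
                    "max_quadrant": qa.argmax_quadrant,
                    "min_quadrant": qa.argmin_quadrant,
                }
            )
    return pd.DataFrame(rows)
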