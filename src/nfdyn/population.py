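"""Population-level readouts: dose–response, average time courses, cosine
distances between conditions, and the soluble-TNF-receptor effect.

Average time courses are computed over cells classified active, resampled to
a common 5-minute grid; conditions are compared by the cosine distance
1 − u·v / (‖u‖‖v‖) between their average courses, on raw (not baseline-
subtracted, not rescaled) profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import Trace

__all__ = [
    "ConditionSummary",
    "SimilarityMatrix",
    "ReceptorEffect",
    "default_grid",
    "average_time_course",
    "cosine_distance",
    "similarity_matrix",
    "fraction_active",
    "receptor_effect",
]


def default_grid(t_max: float = 595.0, dt: float = 5.0) -> np.ndarray:
    """Common post-stimulus time grid for averaging, minutes."""
    return np.arange(0.0, t_max + dt / 2, dt)


@dataclass
class ConditionSummary:
    """Aggregate of one (preparation, concentration, sTNFRII) condition."""

    preparation: str
    concentration: float
    stnfr: bool
    n_total: int
    n_active: int
    grid: np.ndarray
    average_course: np.ndarray | None  # None marks an empty condition
    feature_means: dict = field(default_factory=dict)
    feature_sds: dict = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return self.average_course is None

    @property
    def fraction_active(self) -> float:
        return self.n_active / self.n_total if self.n_total else float("nan")

    @property
    def label(self) -> str:
        tag = "+sTNFRII" if self.stnfr else ""
        return f"{self.preparation} {self.concentration:g}{tag}"


@dataclass
class SimilarityMatrix:
    labels: list[str]
    distances: np.ndarray


@dataclass
class ReceptorEffect:
    """Cosine distance between average courses with and without sTNFRII.

    ``defensible`` is False when either arm had no active cells (the distance
    is then NaN, reported but not interpretable).
    """

    preparation: str
    concentration: float
    distance: float
    n_active_control: int
    n_active_stnfr: int
    defensible: bool


def average_time_course(
    traces: list[Trace], grid: np.ndarray | None = None
) -> np.ndarray | None:
    """Pointwise mean of active-cell traces resampled to a common grid.

    Each trace is linearly interpolated on its valid frames (edge values held
    beyond the first/last valid frame).  Returns None for an empty set — the
    explicit empty-condition marker consumed by downstream comparisons.
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if not traces:
        return None
    resampled = np.empty((len(traces), grid.size))
    for i, trace in enumerate(traces):
        ok = trace.valid
        if not ok.any():
            raise ValueError(f"trace {trace.track_id} has no valid frames")
        resampled[i] = np.interp(grid, trace.time[ok], trace.values[ok])
    return resampled.mean(axis=0)


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 − cos(angle between u and v); 0 for proportional profiles."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"shape mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine distance undefined for a zero vector")
    return float(1.0 - np.dot(u, v) / (nu * nv))


def similarity_matrix(summaries: list[ConditionSummary]) -> SimilarityMatrix:
    """Pairwise cosine distances between condition averages.

    Conditions are ordered by preparation (input order of first appearance),
    then by descending concentration within each preparation.
    """
    nonempty = [s for s in summaries if not s.empty]
    if not nonempty:
        raise ValueError("no non-empty conditions to compare")
    grids = {tuple(np.round(s.grid, 9)) for s in nonempty}
    if len(grids) > 1:
        raise ValueError("condition averages are on different time grids")
    prep_order: dict[str, int] = {}
    for s in nonempty:
        prep_order.setdefault(s.preparation, len(prep_order))
    ordered = sorted(
        nonempty, key=lambda s: (prep_order[s.preparation], -s.concentration, s.stnfr)
    )
    n = len(ordered)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = cosine_distance(ordered[i].average_course, ordered[j].average_course)
            dist[i, j] = dist[j, i] = d
    return SimilarityMatrix(labels=[s.label for s in ordered], distances=dist)


def fraction_active(features: pd.DataFrame) -> tuple[int, int, float]:
    """(N_active, N_total, fraction) from a per-cell feature table."""
    n_total = len(features)
    if n_total < 1:
        raise ValueError("feature table is empty")
    n_active = int(features["active"].sum())
    return n_active, n_total, n_active / n_total


def receptor_effect(
    control: ConditionSummary, blocked: ConditionSummary
) -> ReceptorEffect:
    """Cosine distance between the ±sTNFRII average courses of one condition."""
    if (
        control.preparation != blocked.preparation
        or control.concentration != blocked.concentration
    ):
        raise ValueError(
            f"condition mismatch: {control.label!r} vs {blocked.label!r}"
        )
    if control.stnfr or not blocked.stnfr:
        raise ValueError("expected (control, +sTNFRII) in that order")
    if control.empty or blocked.empty:
        return ReceptorEffect(
            preparation=control.preparation,
            concentration=control.concentration,
            distance=float("nan"),
            n_active_control=control.n_active,
            n_active_stnfr=blocked.n_active,
            defensible=False,
        )
    if control.grid.shape != blocked.grid.shape or np.any(control.grid != blocked.grid):
        raise ValueError("conditions are on different time grids")
    return ReceptorEffect(
        preparation=control.preparation,
        concentration=control.concentration,
        distance=cosine_distance(control.average_course, blocked.average_course),
        n_active_control=control.n_active,
        n_active_stnfr=blocked.n_active,
        defensible=True,
    )
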