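"""Hair-germ volume dynamics: normalization, behavior classification, contraction stats.

Intravital time-lapse imaging of resting (telogen) hair follicles shows the hair
germ (HG) — the cluster of ~10-20 primed progenitors at the follicle base —
pulsing in volume while the neighbouring bulge stays put.  The quantification
convention is to express each HG's volume trajectory relative to its own largest
observed volume (= 100%) and then to ask three questions:

* does a follicle enlarge continuously, contract continuously, or pulse?
* pooling every imaging time point, what fraction of observations sit below
  90% of the per-follicle maximum (the "contraction fraction")?
* what is the average per-cell volume (total HG volume / cell count)?

The behavior rule set operationalizes "substantial (>10%) contraction": a
trajectory is a *continuous contraction* when it ends at least ``threshold``
percent below its maximum and never re-inflates more than ``threshold`` above
its running minimum after the maximum; a *continuous enlargement* when it ends
no lower than it started and never draws down more than ``threshold``; anything
else is *pulsatile*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InsufficientDataError, ValidationError

CATEGORIES = ("continuous_enlargement", "pulsatile", "continuous_contraction")

STAGES = ("telogen1", "anagen_early", "telogen2", "induced")


@dataclass
class VolumeTrajectory:
    """One compartment's volume time series (µm³) at minute resolution."""

    follicle_id: str
    stage: str
    times: np.ndarray  # minutes, strictly increasing
    volumes: np.ndarray  # µm³, positive
    cell_count: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.times.size != self.volumes.size:
            raise ValidationError("times and volumes must have equal length")
        if self.times.size < 2:
            raise ValidationError("a trajectory needs at least 2 time points")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(self.volumes <= 0):
            raise ValidationError("volumes must be positive")


@dataclass
class RelativeTrajectory:
    """Volumes as percent of the per-trajectory maximum (max = 100 exactly)."""

    percentages: np.ndarray
    argmax_index: int
    follicle_id: str = ""
    stage: str = ""

    def __post_init__(self) -> None:
        self.percentages = np.asarray(self.percentages, dtype=float)
        if not np.isclose(self.percentages.max(), 100.0):
            raise ValidationError("RelativeTrajectory must have max == 100")


@dataclass(frozen=True)
class BehaviorCall:
    category: str
    net_change_pct: float
    max_drawdown_pct: float
    crossings_below_90: int
    follicle_id: str = ""


@dataclass(frozen=True)
class ContractionSummary:
    n_timepoints: int
    n_below_threshold: int
    fraction_pct: float
    threshold_pct: float = 90.0


def normalize_trajectory(
    traj: VolumeTrajectory, smooth: bool = False
) -> RelativeTrajectory:
    """Scale volumes so the largest observed volume is exactly 100%.

    Ties on the maximum are broken by the earliest index.  Normalizing an
    already-relative trajectory is a no-op (idempotence).  ``smooth`` applies
    an optional window-3 rolling median before normalization for noisy
    segmentations; off by default since no upstream filtering is assumed.
    """
    if isinstance(traj, RelativeTrajectory):
        return RelativeTrajectory(
            traj.percentages.copy(), traj.argmax_index, traj.follicle_id, traj.stage
        )
    v = traj.volumes
    if smooth:
        padded = np.concatenate([v[:1], v, v[-1:]])
        v = np.median(np.lib.stride_tricks.sliding_window_view(padded, 3), axis=1)
    idx = int(np.argmax(v))  # argmax returns the first maximal index
    pct = 100.0 * v / v[idx]
    pct[idx] = 100.0  # exact, not just within float error
    return RelativeTrajectory(pct, idx, traj.follicle_id, traj.stage)


def _running_max_drawdown(pct: np.ndarray) -> float:
    return float(np.max(np.maximum.accumulate(pct) - pct))


def classify_behavior(
    rel: RelativeTrajectory, contraction_threshold_pct: float = 10.0
) -> BehaviorCall:
    """Assign one of the three HG behavior categories to a normalized trajectory."""
    pct = rel.percentages
    if pct.size < 3:
        raise InsufficientDataError("classification needs at least 3 time points")
    thr = contraction_threshold_pct
    net = float(pct[-1] - pct[0])
    drawdown = _running_max_drawdown(pct)

    line = 100.0 - thr
    below = pct < line
    crossings = int(np.sum(below[1:] & ~below[:-1]) + (1 if below[0] else 0))

    # continuous contraction: ends below the line and never re-inflates past
    # the threshold once past the maximum
    after_max = pct[rel.argmax_index :]
    rebound = float(np.max(after_max - np.minimum.accumulate(after_max)))
    if pct[-1] <= line and rebound <= thr:
        category = "continuous_contraction"
    elif pct[-1] >= pct[0] and drawdown <= thr:
        category = "continuous_enlargement"
    else:
        category = "pulsatile"
    return BehaviorCall(category, net, drawdown, crossings, rel.follicle_id)


def _round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_categories(
    calls: Iterable[BehaviorCall] | Mapping[str, int],
) -> dict[str, dict[str, float]]:
    """Per-category counts and percentages (half-up, one decimal).

    Accepts either a list of :class:`BehaviorCall` or an already-tallied
    mapping ``{category: count}`` (e.g. counts read off a published figure).
    """
    if isinstance(calls, Mapping):
        counts = {k: int(v) for k, v in calls.items()}
    else:
        counts = {}
        for call in calls:
            counts[call.category] = counts.get(call.category, 0) + 1
    n = sum(counts.values())
    if n == 0:
        raise ValidationError("summarize_categories: no calls given")
    return {
        cat: {"count": cnt, "percent": _round_half_up(100.0 * cnt / n)}
        for cat, cnt in counts.items()
    }


def contraction_fraction(
    rels: Sequence[RelativeTrajectory],
    threshold_pct: float = 90.0,
    weight: str = "points",
) -> ContractionSummary:
    """Pool all time points; fraction strictly below ``threshold_pct`` of max.

    "Smaller than 90% of the largest volume" is read as strictly below.
    ``weight="points"`` (default) weights every time point equally;
    ``weight="follicles"`` averages per-trajectory fractions so follicles
    with longer observation windows do not dominate.
    """
    if len(rels) == 0:
        raise ValidationError("contraction_fraction: no trajectories given")
    for r in rels:
        if not isinstance(r, RelativeTrajectory):
            raise ValidationError(
                "contraction_fraction expects normalized RelativeTrajectory inputs"
            )
    pooled = np.concatenate([r.percentages for r in rels])
    below = int(np.sum(pooled < threshold_pct))
    if weight == "points":
        fraction = 100.0 * below / pooled.size
    elif weight == "follicles":
        fraction = float(
            np.mean([100.0 * np.mean(r.percentages < threshold_pct) for r in rels])
        )
    else:
        raise ValidationError("weight must be 'points' or 'follicles'")
    return ContractionSummary(
        n_timepoints=pooled.size,
        n_below_threshold=below,
        fraction_pct=fraction,
        threshold_pct=threshold_pct,
    )


def mean_cell_volume(traj: VolumeTrajectory) -> dict[str, object]:
    """Per-time-point volume per cell (µm³) and its time average."""
    if traj.cell_count is None or traj.cell_count <= 0:
        raise ValidationError("mean_cell_volume requires a positive cell_count")
    per_point = traj.volumes / traj.cell_count
    return {"per_timepoint_um3": per_point, "mean_um3": float(per_point.mean())}


def bulge_drift_metrics(
    width_series: Sequence[float],
    length_series: Sequence[float],
    neighbor_distances: Sequence[float],
) -> dict[str, float]:
    """Max percent deviation from the initial value, per bulge-stability series.

    The bulge is expected to stay put while the hair germ pulses; these metrics
    quantify "remained constant" for width, length and a cell's distance to its
    neighbours.
    """
    out = {}
    for name, series in (
        ("width", width_series),
        ("length", length_series),
        ("neighbor_distance", neighbor_distances),
    ):
        arr = np.asarray(series, dtype=float)
        if arr.size == 0:
            raise ValidationError(f"bulge_drift_metrics: empty series {name!r}")
        if arr[0] == 0:
            raise ValidationError(f"bulge_drift_metrics: zero initial value in {name!r}")
        out[name + "_max_dev_pct"] = float(np.max(np.abs(arr - arr[0]) / abs(arr[0])) * 100.0)
    return out
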