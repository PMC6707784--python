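"""Erythrocyte-associated transients: RBC detection, cycle classification, pooled Po2.

In a capillary the oxygen level seen by the sensor is not constant: each
passing red blood cell unloads oxygen, producing a local Po2 peak that
relaxes toward a baseline between cells (the erythrocyte-associated
transient, EAT). Pooling phosphorescence decays by their timing relative to
RBC passages therefore yields three distinct quantities:

* ``Po2 RBC`` — decays recorded 1-3.5 ms from an RBC edge (the plasma side
  of either edge), reflecting Po2 carried by the cells;
* ``Po2 InterRBC`` — decays at mid-distance between RBCs (window of at
  least 5 ms), a proxy for the surrounding tissue Po2;
* ``Po2 Mean`` — all decays pooled (see :func:`plmox.decay.po2_mean_from_trace`).

RBC passages themselves are detected as dips of the on-phase (AOM-open)
fluorescence: an RBC occupying the focal volume displaces the labeled
plasma and darkens the signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter, uniform_filter1d

from .calibration import CalibrationSet
from .decay import LifetimeFit, PhotonTrace, accumulate_decay, fit_lifetime

logger = logging.getLogger(__name__)

__all__ = [
    "RBCEvent",
    "EATWindows",
    "EATClassification",
    "CapillaryResult",
    "PoolTooSmallError",
    "detect_rbc_passages",
    "classify_cycles",
    "po2_pool",
    "rbc_flux",
    "eat_profile",
    "LABELS",
]

#: cycle pool labels
INSIDE_RBC, BORDER, INTER_RBC, UNCLASSIFIED = "inside_rbc", "border", "inter_rbc", "unclassified"
LABELS = (INSIDE_RBC, BORDER, INTER_RBC, UNCLASSIFIED)


@dataclass(frozen=True)
class RBCEvent:
    """One detected (or planted) RBC passage through the measurement point."""

    entry_ms: float
    exit_ms: float
    trough_intensity: float = float("nan")

    def __post_init__(self) -> None:
        if not self.exit_ms > self.entry_ms:
            raise ValueError("exit_ms must exceed entry_ms")


@dataclass(frozen=True)
class EATWindows:
    """Timing windows that define the Po2 RBC and Po2 InterRBC pools.

    ``border_window_ms``: offsets from an RBC edge (outside the cell, either
    side) pooled as the RBC-border population. ``inter_min_window_ms``:
    minimum width of the mid-gap window eligible for the inter-RBC pool.
    """

    border_window_ms: tuple[float, float] = (1.0, 3.5)
    inter_min_window_ms: float = 5.0

    def __post_init__(self) -> None:
        lo, hi = self.border_window_ms
        if not lo < hi:
            raise ValueError("border_window_ms must be increasing")
        if not self.inter_min_window_ms > 0:
            raise ValueError("inter_min_window_ms must be > 0")

    @property
    def min_inter_gap_ms(self) -> float:
        """Smallest inter-event gap that admits an inter-RBC window."""
        return 2.0 * self.border_window_ms[1] + self.inter_min_window_ms


@dataclass
class EATClassification:
    """Per-cycle pool labels together with the rule and events that generated them."""

    labels: np.ndarray  # array of strings from LABELS, one per cycle
    windows: EATWindows
    events: list[RBCEvent]

    def indices(self, label: str) -> np.ndarray:
        if label == "all":
            return np.arange(len(self.labels))
        if label not in LABELS:
            raise ValueError(f"unknown label {label!r}; use one of {LABELS} or 'all'")
        return np.flatnonzero(self.labels == label)

    def counts(self) -> dict[str, int]:
        return {lab: int(np.sum(self.labels == lab)) for lab in LABELS}


@dataclass
class CapillaryResult:
    """Summary of one capillary under one condition."""

    capillary_id: str
    condition_label: str
    temperature_c: float
    po2_mean_mmHg: float
    po2_rbc_mmHg: float
    po2_inter_rbc_mmHg: float
    so2_fraction: float
    rbc_flux_per_s: float
    velocity_mm_s: float | None = None
    capillary_diameter_um: float | None = None
    mouse_id: str | None = None

    def __post_init__(self) -> None:
        for name in ("po2_mean_mmHg", "po2_rbc_mmHg", "po2_inter_rbc_mmHg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.so2_fraction <= 1.0:
            raise ValueError("so2_fraction must lie in [0, 1]")
        if self.rbc_flux_per_s < 0:
            raise ValueError("rbc_flux_per_s must be >= 0")


class PoolTooSmallError(ValueError):
    """A cycle pool is below the configured floor for a stable lifetime fit."""


def detect_rbc_passages(
    on_intensity: np.ndarray,
    cycle_times_ms: np.ndarray,
    threshold_fraction: float = 0.5,
    baseline_window: int = 501,
    smooth_window: int = 3,
    min_duration_cycles: int = 2,
    floor_quantile: float = 0.02,
    min_range_sigmas: float = 4.0,
) -> list[RBCEvent]:
    """Detect RBC passages as dips of the on-phase fluorescence.

    The signal is lightly smoothed (moving average of ``smooth_window``
    cycles), a slow baseline is taken as a rolling median over
    ``baseline_window`` cycles, and the trough floor as the
    ``floor_quantile`` quantile of the smoothed signal. A cycle belongs to a
    passage while the smoothed signal sits below

        threshold = baseline - threshold_fraction * (baseline - floor).

    Runs shorter than ``min_duration_cycles`` are discarded; event edges are
    refined to the linear threshold crossing between neighbouring cycles.
    A signal whose dynamic range does not exceed ``min_range_sigmas`` shot-
    noise standard deviations yields no events and a logged warning.
    """
    y = np.asarray(on_intensity, dtype=float)
    t = np.asarray(cycle_times_ms, dtype=float)
    if len(y) < 100:
        raise ValueError(f"need >= 100 cycles to detect passages, got {len(y)}")
    if y.shape != t.shape:
        raise ValueError("on_intensity and cycle_times_ms must align")

    smooth = uniform_filter1d(y, size=max(1, smooth_window), mode="nearest")
    # reflective padding: a record starting/ending inside an RBC must not
    # drag the edge baseline down to the trough level
    baseline = median_filter(smooth, size=min(baseline_window, len(y) | 1), mode="reflect")
    floor = float(np.quantile(smooth, floor_quantile))
    base_level = float(np.median(baseline))
    if base_level - floor < min_range_sigmas * np.sqrt(max(base_level, 1.0)):
        logger.warning(
            "on-phase intensity has no usable dynamic range (baseline %.1f, floor %.1f); "
            "no RBC passages detected",
            base_level,
            floor,
        )
        return []

    threshold = baseline - threshold_fraction * (baseline - floor)
    below = smooth < threshold

    events: list[RBCEvent] = []
    edges = np.flatnonzero(np.diff(below.astype(np.int8)))
    starts = list(edges[~below[edges]] + 1) if len(edges) else []
    if below[0]:
        starts = [0] + starts
    ends = list(edges[below[edges]] + 1) if len(edges) else []
    if below[-1]:
        ends = ends + [len(y)]
    for s, e in zip(starts, ends):
        if e - s < min_duration_cycles:
            continue
        # refine edges by linear interpolation of the threshold crossing
        if s > 0:
            f = (smooth[s - 1] - threshold[s - 1]) / (
                (smooth[s - 1] - threshold[s - 1]) - (smooth[s] - threshold[s])
            )
            entry = t[s - 1] + f * (t[s] - t[s - 1])
        else:
            entry = t[0]
        if e < len(y):
            f = (threshold[e - 1] - smooth[e - 1]) / (
                (threshold[e - 1] - smooth[e - 1]) - (threshold[e] - smooth[e])
            )
            exit_ = t[e - 1] + f * (t[e] - t[e - 1])
        else:
            exit_ = t[-1]
        if exit_ <= entry:
            continue
        events.append(
            RBCEvent(entry_ms=float(entry), exit_ms=float(exit_), trough_intensity=float(y[s:e].min()))
        )
    return events


def classify_cycles(
    events: Sequence[RBCEvent], trace: PhotonTrace, windows: EATWindows = EATWindows()
) -> EATClassification:
    """Label every cycle relative to the RBC passages.

    * ``inside_rbc`` — cycle mid-time within [entry, exit] of an event;
    * ``border`` — outside every event, distance to the nearest event edge
      within ``windows.border_window_ms`` (both flanks of both edges pool);
    * ``inter_rbc`` — in a gap between consecutive events long enough to fit
      both flanking border zones plus the minimum window
      (gap >= 2*border_hi + inter_min); the window is centred at mid-gap
      with width gap - 2*border_hi, so it abuts but never enters a border
      zone. Segments before the first and after the last event are never
      pooled as inter-RBC;
    * ``unclassified`` — everything else.
    """
    t = trace.cycle_mid_ms
    labels = np.full(len(t), UNCLASSIFIED, dtype=object)
    events = sorted(events, key=lambda e: e.entry_ms)
    if events:
        entries = np.array([e.entry_ms for e in events])
        exits = np.array([e.exit_ms for e in events])
        if np.any(entries[1:] < exits[:-1]):
            raise ValueError("events must be non-overlapping and time-ordered")

        j = np.searchsorted(entries, t, side="right") - 1
        jc = np.clip(j, 0, None)
        inside = (j >= 0) & (t <= exits[jc])
        d_prev = np.where(j >= 0, t - exits[jc], np.inf)  # distance past previous exit
        k = np.clip(j + 1, 0, len(entries) - 1)
        d_next = np.where(j + 1 < len(entries), entries[k] - t, np.inf)
        dist = np.minimum(np.clip(d_prev, 0.0, None), np.clip(d_next, 0.0, None))

        b_lo, b_hi = windows.border_window_ms
        border = ~inside & (dist >= b_lo) & (dist <= b_hi)

        gap = np.where(
            (j >= 0) & (j + 1 < len(entries)), entries[k] - exits[jc], -np.inf
        )
        in_gap = ~inside & (d_prev > 0) & (d_next > 0)
        inter = (
            in_gap
            & (gap >= windows.min_inter_gap_ms)
            & (d_prev > b_hi)
            & (d_next > b_hi)
        )
        inter &= ~border

        labels[inside] = INSIDE_RBC
        labels[border & ~inside] = BORDER
        labels[inter] = INTER_RBC
    return EATClassification(labels=np.asarray(labels, dtype=object), windows=windows, events=list(events))


def po2_pool(
    trace: PhotonTrace,
    classification: EATClassification,
    label: str,
    cal_set: CalibrationSet,
    temperature_c: float,
    pool_floor: int = 500,
    compute_ci: bool = False,
) -> tuple[float, LifetimeFit]:
    """Pooled Po2 for one cycle label: accumulate, fit once, convert once."""
    idx = classification.indices(label)
    if len(idx) < pool_floor:
        raise PoolTooSmallError(
            f"pool {label!r} holds {len(idx)} cycles, below the floor of {pool_floor}"
        )
    fit = fit_lifetime(accumulate_decay(trace, idx), compute_ci=compute_ci)
    return cal_set.po2_from_tau(fit.tau_us, temperature_c), fit


def rbc_flux(events: Sequence[RBCEvent], duration_s: float) -> float:
    """RBC flux (cells/s) as event count over record duration."""
    if not duration_s > 0:
        raise ValueError("duration_s must be > 0")
    return len(events) / duration_s


def eat_profile(
    trace: PhotonTrace,
    events: Sequence[RBCEvent],
    cal_set: CalibrationSet,
    temperature_c: float,
    bin_ms: float = 0.5,
    max_offset_ms: float = 10.0,
    pool_floor: int = 200,
) -> pd.DataFrame:
    """Po2 versus signed time from the nearest RBC edge.

    Cycles are binned by offset (negative inside an RBC, positive in
    plasma); each bin with at least ``pool_floor`` cycles gets a pooled
    fit-then-convert Po2. Returns a DataFrame with columns
    ``offset_ms`` (bin centre), ``po2_mmHg`` and ``n_cycles``.
    """
    events = sorted(events, key=lambda e: e.entry_ms)
    if len(events) < 10:
        raise ValueError(f"need >= 10 events for an EAT profile, got {len(events)}")
    t = trace.cycle_mid_ms
    entries = np.array([e.entry_ms for e in events])
    exits = np.array([e.exit_ms for e in events])
    all_edges = np.sort(np.concatenate([entries, exits]))
    nearest = np.clip(np.searchsorted(all_edges, t), 1, len(all_edges) - 1)
    d_edge = np.minimum(np.abs(t - all_edges[nearest - 1]), np.abs(t - all_edges[nearest]))

    j = np.searchsorted(entries, t, side="right") - 1
    inside = (j >= 0) & (t <= exits[np.clip(j, 0, None)])
    signed = np.where(inside, -d_edge, d_edge)

    bins = np.arange(-max_offset_ms, max_offset_ms + bin_ms, bin_ms)
    which = np.digitize(signed, bins) - 1
    rows = []
    for b in range(len(bins) - 1):
        idx = np.flatnonzero(which == b)
        if len(idx) < pool_floor:
            continue
        fit = fit_lifetime(accumulate_decay(trace, idx), compute_ci=False)
        rows.append(
            {
                "offset_ms": 0.5 * (bins[b] + bins[b + 1]),
                "po2_mmHg": cal_set.po2_from_tau(fit.tau_us, temperature_c),
                "n_cycles": len(idx),
            }
        )
    return pd.DataFrame(rows, columns=["offset_ms", "po2_mmHg", "n_cycles"])
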