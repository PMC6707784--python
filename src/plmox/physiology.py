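"""Hemoglobin saturation (Hill equation) and paired condition comparisons.

Hemoglobin oxygen saturation follows the Hill equation

    SO2 = Po2^n / (Po2^n + P50^n)

with the cooperativity coefficient ``n`` and half-saturation pressure
``P50``. The defaults (n = 2.59, P50 = 40.2 mmHg) are the values for
C57BL/6 mouse blood. The saturation assigned to a capillary uses the
RBC-border Po2, which reflects the oxygen level inside the cells.

Condition comparisons are paired per capillary: each capillary measured
under two or more imaging conditions (e.g. dry objective vs room-
temperature immersion vs heated immersion) contributes its own delta and
percent change, summarized as mean +/- s.e.m. with the capillary as the
statistical unit. Mouse identity is carried as metadata only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .eat import CapillaryResult

logger = logging.getLogger(__name__)

__all__ = [
    "HillParameters",
    "ConditionComparison",
    "so2_from_po2",
    "po2_from_so2",
    "percent_change",
    "compare_conditions",
    "summarize_temperature_series",
]

#: metrics of a CapillaryResult that enter paired comparisons
_METRICS = (
    "po2_mean_mmHg",
    "po2_rbc_mmHg",
    "po2_inter_rbc_mmHg",
    "so2_fraction",
    "rbc_flux_per_s",
    "velocity_mm_s",
)


@dataclass(frozen=True)
class HillParameters:
    """Hill-equation parameters; defaults are for C57BL/6 mouse hemoglobin."""

    n: float = 2.59
    p50_mmHg: float = 40.2

    def __post_init__(self) -> None:
        if not self.n > 0 or not self.p50_mmHg > 0:
            raise ValueError("Hill n and P50 must be > 0")


def so2_from_po2(po2_mmHg, hill: HillParameters = HillParameters()):
    """Hemoglobin saturation fraction at an oxygen partial pressure (mmHg)."""
    po2 = np.asarray(po2_mmHg, dtype=float)
    if np.any(po2 < 0):
        raise ValueError("po2 must be >= 0")
    r = (po2 / hill.p50_mmHg) ** hill.n
    out = r / (r + 1.0)
    return float(out) if out.ndim == 0 else out


def po2_from_so2(so2, hill: HillParameters = HillParameters()):
    """Closed-form inverse of the Hill equation; ``so2`` must lie in (0, 1)."""
    s = np.asarray(so2, dtype=float)
    if np.any((s <= 0.0) | (s >= 1.0)):
        raise ValueError("so2 must lie strictly within (0, 1)")
    out = hill.p50_mmHg * (s / (1.0 - s)) ** (1.0 / hill.n)
    return float(out) if out.ndim == 0 else out


def percent_change(baseline: float, value: float) -> float:
    """100 * (value - baseline) / baseline."""
    if baseline == 0:
        raise ValueError("baseline must be non-zero for a percent change")
    return 100.0 * (value - baseline) / baseline


def summarize_temperature_series(temperature_c: np.ndarray) -> dict[str, float]:
    """Trivial summary of a brain-temperature time series (mean/sd/min/max/n).

    Thermocouple time-course analysis proper is out of scope; this exists so
    a recorded series can be reduced to the single conversion temperature
    plus a stability check before curve selection.
    """
    t = np.asarray(temperature_c, dtype=float)
    t = t[~np.isnan(t)]
    if t.size == 0:
        raise ValueError("empty temperature series")
    return {
        "mean_c": float(np.mean(t)),
        "sd_c": float(np.std(t, ddof=1)) if t.size > 1 else 0.0,
        "min_c": float(np.min(t)),
        "max_c": float(np.max(t)),
        "n": int(t.size),
    }


@dataclass
class ConditionComparison:
    """Paired per-capillary comparison across condition labels.

    ``per_capillary`` has one row per (capillary, non-baseline condition,
    metric) with the baseline value, the condition value, the delta and the
    percent change. ``summary`` aggregates mean, s.e.m. and n per
    (condition, metric), including the baseline's own means.
    """

    baseline_condition: str
    per_capillary: pd.DataFrame
    summary: pd.DataFrame
    n_capillaries: int
    n_mice: int | None = None
    excluded: dict[str, list[str]] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.per_capillary.to_csv(path, index=False)

    def to_json(self, path) -> None:
        import json

        doc = {
            "baseline_condition": self.baseline_condition,
            "n_capillaries": self.n_capillaries,
            "n_mice": self.n_mice,
            "excluded": self.excluded,
            "summary": self.summary.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)


def _sem(x: np.ndarray) -> float:
    x = x[~np.isnan(x)]
    if len(x) < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def compare_conditions(
    results: Sequence[CapillaryResult], baseline_condition: str | None = None
) -> ConditionComparison:
    """Pair capillaries across conditions and summarize deltas and percent changes.

    Every capillary must appear under at least two conditions; capillaries
    missing a condition are excluded from that pairing with a logged note.
    The result is invariant to the input order.
    """
    if not results:
        raise ValueError("no results to compare")
    rows = []
    for r in results:
        row = {"capillary_id": r.capillary_id, "condition": r.condition_label, "mouse_id": r.mouse_id}
        for m in _METRICS:
            row[m] = getattr(r, m)
        rows.append(row)
    df = pd.DataFrame(rows).sort_values(["capillary_id", "condition"]).reset_index(drop=True)
    conditions = sorted(df["condition"].unique())
    if len(conditions) < 2:
        raise ValueError("need at least two distinct conditions")
    if baseline_condition is None:
        baseline_condition = conditions[0]
    if baseline_condition not in conditions:
        raise ValueError(f"baseline condition {baseline_condition!r} not present")

    base = df[df["condition"] == baseline_condition].set_index("capillary_id")
    if base.index.duplicated().any():
        raise ValueError("duplicate capillary under the baseline condition")

    paired_rows = []
    excluded: dict[str, list[str]] = {}
    for cond in conditions:
        if cond == baseline_condition:
            continue
        other = df[df["condition"] == cond].set_index("capillary_id")
        missing = sorted(set(base.index).symmetric_difference(other.index))
        if missing:
            excluded[cond] = [str(m) for m in missing]
            logger.info("condition %r: excluding unpaired capillaries %s", cond, missing)
        common = sorted(set(base.index) & set(other.index))
        for cap in common:
            for m in _METRICS:
                b, v = base.loc[cap, m], other.loc[cap, m]
                if b is None or v is None or (isinstance(b, float) and np.isnan(b)):
                    continue
                paired_rows.append(
                    {
                        "capillary_id": cap,
                        "condition": cond,
                        "metric": m,
                        "baseline": float(b),
                        "value": float(v),
                        "delta": float(v) - float(b),
                        "percent_change": percent_change(float(b), float(v)) if b != 0 else float("nan"),
                    }
                )
    if not paired_rows:
        raise ValueError("no complete capillary pairings across conditions")
    per_cap = pd.DataFrame(paired_rows).sort_values(["condition", "metric", "capillary_id"]).reset_index(drop=True)

    summary_rows = []
    for cond in conditions:
        sub = df[df["condition"] == cond]
        for m in _METRICS:
            vals = pd.to_numeric(sub[m], errors="coerce").to_numpy(dtype=float)
            if np.all(np.isnan(vals)):
                continue
            summary_rows.append(
                {
                    "condition": cond,
                    "metric": m,
                    "mean": float(np.nanmean(vals)),
                    "sem": _sem(vals),
                    "n": int(np.sum(~np.isnan(vals))),
                }
            )
    for cond in sorted(per_cap["condition"].unique()):
        for m in _METRICS:
            sub = per_cap[(per_cap["condition"] == cond) & (per_cap["metric"] == m)]
            if sub.empty:
                continue
            pc = sub["percent_change"].to_numpy(dtype=float)
            summary_rows.append(
                {
                    "condition": f"{cond} vs {baseline_condition}",
                    "metric": f"{m}_percent_change",
                    "mean": float(np.nanmean(pc)),
                    "sem": _sem(pc),
                    "n": int(np.sum(~np.isnan(pc))),
                }
            )
    summary = pd.DataFrame(summary_rows)

    mice = df["mouse_id"].dropna().unique()
    return ConditionComparison(
        baseline_condition=baseline_condition,
        per_capillary=per_cap,
        summary=summary,
        n_capillaries=int(df["capillary_id"].nunique()),
        n_mice=int(len(mice)) if len(mice) else None,
        excluded=excluded,
    )
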