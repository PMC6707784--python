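"""Readers and writers for the pipeline's on-disk formats.

* gated acquisitions: an HDF5 container with ``/gate`` attributes and
  ``/cycles/{start_ms,on_intensity,off_counts}`` datasets, plus a flat CSV
  fallback (one row per cycle);
* calibration runs: CSV with columns ``lifetime_us, po2_mmHg,
  temperature_c`` (several temperatures may share one file); fitted curves
  as a JSON document;
* line scans: single-channel TIFF with a JSON sidecar carrying
  ``line_period_ms`` and ``pixel_size_um`` (see :class:`plmox.linescan.LineScanImage`);
* results: CapillaryResult rows as CSV/JSON, RBC events as CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import h5py
import pandas as pd

from .calibration import CalibrationPoint, CalibrationSet, fit_calibration_curve
from .decay import GateConfig, PhotonTrace
from .eat import CapillaryResult, RBCEvent

__all__ = [
    "write_trace_h5",
    "read_trace_h5",
    "write_trace_csv",
    "read_trace_csv",
    "read_calibration_csv",
    "write_calibration_csv",
    "fit_calibration_csv",
    "write_events_csv",
    "read_events_csv",
    "write_results",
    "read_results_csv",
]


# -- gated acquisition container ------------------------------------------


def write_trace_h5(path, trace: PhotonTrace, ground_truth: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        gate = f.create_group("gate")
        for k, v in trace.gate.to_attrs().items():
            gate.attrs[k] = v
        cyc = f.create_group("cycles")
        cyc.create_dataset("start_ms", data=trace.cycle_start_ms)
        cyc.create_dataset("on_intensity", data=trace.on_phase_intensity)
        cyc.create_dataset("off_counts", data=trace.off_phase_counts)
        if ground_truth is not None:
            f.attrs["ground_truth_json"] = json.dumps(ground_truth)


def read_trace_h5(path) -> PhotonTrace:
    with h5py.File(path, "r") as f:
        gate = GateConfig(**{k: float(v) for k, v in f["gate"].attrs.items()})
        return PhotonTrace(
            cycle_start_ms=f["cycles/start_ms"][:],
            on_phase_intensity=f["cycles/on_intensity"][:],
            off_phase_counts=f["cycles/off_counts"][:],
            gate=gate,
        )


def write_trace_csv(path, trace: PhotonTrace) -> None:
    """Flat fallback: one row per cycle, off-phase bins as b0..bN columns."""
    n_bins = trace.off_phase_counts.shape[1]
    cols = {"start_ms": trace.cycle_start_ms, "on_intensity": trace.on_phase_intensity}
    cols.update({f"b{j}": trace.off_phase_counts[:, j] for j in range(n_bins)})
    pd.DataFrame(cols).to_csv(path, index=False)


def read_trace_csv(path, gate: GateConfig = GateConfig()) -> PhotonTrace:
    df = pd.read_csv(path)
    bin_cols = [c for c in df.columns if c.startswith("b") and c[1:].isdigit()]
    bin_cols.sort(key=lambda c: int(c[1:]))
    return PhotonTrace(
        cycle_start_ms=df["start_ms"].to_numpy(),
        on_phase_intensity=df["on_intensity"].to_numpy(),
        off_phase_counts=df[bin_cols].to_numpy(),
        gate=gate,
    )


# -- calibration ------------------------------------------------------------


def read_calibration_csv(path) -> list[CalibrationPoint]:
    """Read calibration points; raises with the line number on a malformed row."""
    df = pd.read_csv(path)
    required = {"lifetime_us", "po2_mmHg", "temperature_c"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"calibration CSV must have columns {sorted(required)}, got {list(df.columns)}"
        )
    if df.empty:
        raise ValueError("calibration CSV holds no data rows")
    points = []
    for i, row in df.iterrows():
        try:
            points.append(
                CalibrationPoint(
                    lifetime_us=float(row["lifetime_us"]),
                    po2_mmHg=float(row["po2_mmHg"]),
                    temperature_c=float(row["temperature_c"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed calibration row at line {i + 2}: {exc}") from exc
    return points


def fit_calibration_csv(path) -> CalibrationSet:
    """Fit one Stern-Volmer curve per temperature present in a calibration CSV."""
    points = read_calibration_csv(path)
    temps = sorted({p.temperature_c for p in points})
    curves = [
        fit_calibration_curve([p for p in points if p.temperature_c == t], t)
        for t in temps
    ]
    return CalibrationSet(curves=curves)


def write_calibration_csv(path, points: Sequence[CalibrationPoint]) -> None:
    pd.DataFrame(
        [
            {"lifetime_us": p.lifetime_us, "po2_mmHg": p.po2_mmHg, "temperature_c": p.temperature_c}
            for p in points
        ]
    ).to_csv(path, index=False)


# -- events and results ------------------------------------------------------


def write_events_csv(path, events: Sequence[RBCEvent]) -> None:
    pd.DataFrame(
        [
            {"entry_ms": e.entry_ms, "exit_ms": e.exit_ms, "trough_intensity": e.trough_intensity}
            for e in events
        ],
        columns=["entry_ms", "exit_ms", "trough_intensity"],
    ).to_csv(path, index=False)


def read_events_csv(path) -> list[RBCEvent]:
    df = pd.read_csv(path)
    return [
        RBCEvent(
            entry_ms=float(r["entry_ms"]),
            exit_ms=float(r["exit_ms"]),
            trough_intensity=float(r.get("trough_intensity", float("nan"))),
        )
        for _, r in df.iterrows()
    ]


def write_results(stem, results: Sequence[CapillaryResult], extra: dict | None = None) -> None:
    """Write CapillaryResult rows to ``<stem>.csv`` and ``<stem>.json``."""
    stem = Path(stem)
    rows = [dataclasses.asdict(r) for r in results]
    pd.DataFrame(rows).to_csv(stem.with_suffix(".csv"), index=False)
    doc = {"results": rows}
    if extra:
        doc.update(extra)
    stem.with_suffix(".json").write_text(json.dumps(doc, indent=2))


def read_results_csv(path) -> list[CapillaryResult]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        kwargs = {k: r[k] for k in df.columns if k in {f.name for f in dataclasses.fields(CapillaryResult)}}
        for opt in ("velocity_mm_s", "capillary_diameter_um", "mouse_id"):
            if opt in kwargs and pd.isna(kwargs[opt]):
                kwargs[opt] = None
        out.append(CapillaryResult(**kwargs))
    return out
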