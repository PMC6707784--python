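"""End-to-end analysis of one gated capillary acquisition."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .calibration import CalibrationSet
from .decay import PhotonTrace, po2_mean_from_trace
from .eat import (
    CapillaryResult,
    EATClassification,
    EATWindows,
    classify_cycles,
    detect_rbc_passages,
    po2_pool,
    rbc_flux,
)
from .physiology import HillParameters, so2_from_po2

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "CapillaryAnalysis", "analyze_capillary"]


@dataclass
class AnalysisConfig:
    """Tunable parameters of the capillary analysis."""

    windows: EATWindows = field(default_factory=EATWindows)
    hill: HillParameters = field(default_factory=HillParameters)
    pool_floor: int = 500
    threshold_fraction: float = 0.5
    baseline_window: int = 501
    min_duration_cycles: int = 2
    tau_tolerance: float = 0.02
    temperature_c: float | None = None  # conversion temperature, settable from file

    @classmethod
    def from_dict(cls, doc: dict) -> "AnalysisConfig":
        """Build from a flat JSON-style mapping (unknown keys rejected)."""
        doc = dict(doc)
        windows = EATWindows(
            border_window_ms=tuple(doc.pop("border_window_ms", (1.0, 3.5))),
            inter_min_window_ms=doc.pop("inter_min_window_ms", 5.0),
        )
        hill = HillParameters(
            n=doc.pop("hill_n", 2.59), p50_mmHg=doc.pop("hill_p50_mmHg", 40.2)
        )
        known = {f for f in cls.__dataclass_fields__ if f not in ("windows", "hill")}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown analysis config keys: {sorted(unknown)}")
        return cls(windows=windows, hill=hill, **doc)


@dataclass
class CapillaryAnalysis:
    """A CapillaryResult plus the intermediates that produced it."""

    result: CapillaryResult
    events: list
    classification: EATClassification
    pool_sizes: dict[str, int]


def analyze_capillary(
    trace: PhotonTrace,
    cal_set: CalibrationSet,
    temperature_c: float,
    capillary_id: str = "cap0",
    condition_label: str = "default",
    velocity_mm_s: float | None = None,
    config: AnalysisConfig | None = None,
    **result_metadata,
) -> CapillaryAnalysis:
    """Run detection, classification, pooled conversions and saturation.

    The conversion temperature must be admissible for the calibration set
    (checked up front so a wrong-temperature analysis fails loudly rather
    than silently corrupting Po2).
    """
    cfg = config or AnalysisConfig()
    cal_set.curve_at(temperature_c)  # raises if the temperature is out of policy

    events = detect_rbc_passages(
        trace.on_phase_intensity,
        trace.cycle_mid_ms,
        threshold_fraction=cfg.threshold_fraction,
        baseline_window=cfg.baseline_window,
        min_duration_cycles=cfg.min_duration_cycles,
    )
    classification = classify_cycles(events, trace, cfg.windows)
    pool_sizes = classification.counts()
    logger.info("pool sizes: %s", pool_sizes)

    po2_mean, _ = po2_mean_from_trace(trace, cal_set, temperature_c)
    po2_rbc, _ = po2_pool(
        trace, classification, "border", cal_set, temperature_c, pool_floor=cfg.pool_floor
    )
    po2_inter, _ = po2_pool(
        trace, classification, "inter_rbc", cal_set, temperature_c, pool_floor=cfg.pool_floor
    )
    flux = rbc_flux(events, trace.duration_s)
    so2 = float(so2_from_po2(po2_rbc, cfg.hill))

    result = CapillaryResult(
        capillary_id=capillary_id,
        condition_label=condition_label,
        temperature_c=temperature_c,
        po2_mean_mmHg=po2_mean,
        po2_rbc_mmHg=po2_rbc,
        po2_inter_rbc_mmHg=po2_inter,
        so2_fraction=so2,
        rbc_flux_per_s=flux,
        velocity_mm_s=velocity_mm_s,
        **result_metadata,
    )
    return CapillaryAnalysis(
        result=result, events=events, classification=classification, pool_sizes=pool_sizes
    )
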