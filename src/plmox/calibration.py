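"""Temperature-indexed lifetime/Po2 calibration of a phosphorescent oxygen sensor.

Phosphorescence of PtP-C343-type probes is quenched by molecular oxygen,
shortening the triplet lifetime tau. Over the physiological range the
quenching follows the Stern-Volmer relation

    1/tau = 1/tau0 + kq * Po2

where ``tau0`` is the zero-oxygen lifetime and ``kq`` the bimolecular
quenching constant. Both parameters drift with temperature, so a separate
curve is fitted for every bath temperature at which a calibration run was
acquired, and in vivo conversions must use a curve matched (or interpolated)
to the brain temperature at measurement time. Converting with a curve at the
wrong temperature biases Po2: at fixed tau, a colder curve implies a higher
Po2 (the curves "shift right" as temperature falls).

The default curve model is linear Stern-Volmer fitted by least squares on
inverse lifetime, which is invertible in closed form. A monotone-spline
alternative (:class:`SplineCalibrationCurve`) is provided for sensors whose
response departs from linearity.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "CalibrationSet",
    "SplineCalibrationCurve",
    "fit_calibration_curve",
    "tau_from_po2",
    "po2_from_tau",
    "interpolate_curve",
]

#: Hard physical bounds on Po2 accepted in calibration data (mmHg).
PO2_MIN, PO2_MAX = 0.0, 200.0

#: How far (degC) a conversion temperature may sit beyond the node range
#: before it is rejected instead of clamped to the nearest curve.
TEMPERATURE_SLACK_C = 0.5


@dataclass(frozen=True)
class CalibrationPoint:
    """One (lifetime, Po2) observation from a calibration run at a known bath temperature."""

    lifetime_us: float
    po2_mmHg: float
    temperature_c: float

    def __post_init__(self) -> None:
        if not self.lifetime_us > 0:
            raise ValueError(f"lifetime_us must be > 0, got {self.lifetime_us}")
        if not (PO2_MIN <= self.po2_mmHg <= PO2_MAX):
            raise ValueError(
                f"po2_mmHg must lie in [{PO2_MIN}, {PO2_MAX}] mmHg, got {self.po2_mmHg}"
            )


@dataclass
class CalibrationCurve:
    """Fitted Stern-Volmer curve ``1/tau = 1/tau0 + kq * Po2`` at one temperature.

    Parameters
    ----------
    temperature_c
        Bath temperature of the calibration run, degrees Celsius.
    tau0_us
        Zero-oxygen lifetime, microseconds.
    kq_per_us_mmHg
        Quenching constant, 1/(us * mmHg).
    fit_residual
        Root-mean-square residual of the fit in lifetime units (us).
    valid_po2_range
        (min, max) Po2 of the data the curve was fitted on, mmHg. Inversions
        are only accepted for lifetimes implied by this range (plus a small
        relative tolerance on tau).
    warning
        Set when the input data were non-monotone beyond the noise level.
    """

    temperature_c: float
    tau0_us: float
    kq_per_us_mmHg: float
    fit_residual: float = 0.0
    valid_po2_range: tuple[float, float] = (0.0, 160.0)
    warning: str | None = None

    def __post_init__(self) -> None:
        if not self.tau0_us > 0:
            raise ValueError("tau0_us must be > 0")
        if not self.kq_per_us_mmHg > 0:
            raise ValueError("kq_per_us_mmHg must be > 0")
        lo, hi = self.valid_po2_range
        if not lo < hi:
            raise ValueError("valid_po2_range must be increasing")

    # -- forward / inverse -------------------------------------------------

    def tau_from_po2(self, po2: float | np.ndarray) -> float | np.ndarray:
        """Lifetime (us) at oxygen partial pressure ``po2`` (mmHg)."""
        po2 = np.asarray(po2, dtype=float)
        if np.any(po2 < 0):
            raise ValueError("po2 must be >= 0")
        out = 1.0 / (1.0 / self.tau0_us + self.kq_per_us_mmHg * po2)
        return float(out) if out.ndim == 0 else out

    def lifetime_range(self) -> tuple[float, float]:
        """(tau_min, tau_max) implied by ``valid_po2_range`` (tau decreases with Po2)."""
        lo, hi = self.valid_po2_range
        return (float(self.tau_from_po2(hi)), float(self.tau_from_po2(lo)))

    def po2_from_tau(self, tau_us: float, tau_tolerance: float = 0.02) -> float:
        """Invert the curve: Po2 (mmHg) for an observed lifetime (us).

        ``tau_tolerance`` extends the admissible lifetime interval by the
        given relative fraction on both sides; values outside it raise,
        values in the tolerance band are clamped to the fitted Po2 range.
        """
        tmin, tmax = self.lifetime_range()
        lo_adm, hi_adm = tmin * (1.0 - tau_tolerance), tmax * (1.0 + tau_tolerance)
        if not (lo_adm <= tau_us <= hi_adm):
            raise ValueError(
                f"lifetime {tau_us:.4g} us outside admissible interval "
                f"[{lo_adm:.4g}, {hi_adm:.4g}] us for the "
                f"{self.temperature_c:g} degC curve"
            )
        po2 = (1.0 / tau_us - 1.0 / self.tau0_us) / self.kq_per_us_mmHg
        lo, hi = self.valid_po2_range
        if po2 < lo:
            return float(lo)
        if po2 > hi:
            return float(hi)
        return float(po2)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["valid_po2_range"] = list(self.valid_po2_range)
        return d


@dataclass
class CalibrationSet:
    """Calibration curves at distinct, strictly increasing temperatures."""

    curves: list[CalibrationCurve]
    interpolation_policy: str = "linear_tau0_kq"

    def __post_init__(self) -> None:
        if not self.curves:
            raise ValueError("CalibrationSet needs at least one curve")
        self.curves = sorted(self.curves, key=lambda c: c.temperature_c)
        temps = self.temperatures
        if np.any(np.diff(temps) <= 0):
            raise ValueError("curve temperatures must be distinct")

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([c.temperature_c for c in self.curves])

    def curve_at(self, temperature_c: float) -> CalibrationCurve:
        return interpolate_curve(self, temperature_c)

    def po2_from_tau(
        self, tau_us: float, temperature_c: float, tau_tolerance: float = 0.02
    ) -> float:
        return self.curve_at(temperature_c).po2_from_tau(tau_us, tau_tolerance)

    # -- serialization -----------------------------------------------------

    def to_json(self, path) -> None:
        doc = {
            "interpolation_policy": self.interpolation_policy,
            "curves": [c.to_dict() for c in self.curves],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibrationSet":
        with open(path) as fh:
            doc = json.load(fh)
        curves = [
            CalibrationCurve(
                temperature_c=c["temperature_c"],
                tau0_us=c["tau0_us"],
                kq_per_us_mmHg=c["kq_per_us_mmHg"],
                fit_residual=c.get("fit_residual", 0.0),
                valid_po2_range=tuple(c.get("valid_po2_range", (0.0, 160.0))),
                warning=c.get("warning"),
            )
            for c in doc["curves"]
        ]
        return cls(curves=curves, interpolation_policy=doc.get("interpolation_policy", "linear_tau0_kq"))


def fit_calibration_curve(
    points: Sequence[CalibrationPoint], temperature_c: float | None = None
) -> CalibrationCurve:
    """Fit a Stern-Volmer curve to calibration points by least squares on 1/tau.

    Requires at least 4 points spanning at least 50 mmHg, all at one
    temperature. Non-monotone lifetimes beyond the noise level are recorded
    as a warning on the returned curve, not raised.
    """
    if len(points) < 4:
        raise ValueError(f"need >= 4 calibration points, got {len(points)}")
    temps = np.array([p.temperature_c for p in points])
    if temperature_c is None:
        temperature_c = float(temps[0])
    if not np.allclose(temps, temperature_c, atol=1e-6):
        raise ValueError("all points must share the stated run temperature")
    po2 = np.array([p.po2_mmHg for p in points], dtype=float)
    tau = np.array([p.lifetime_us for p in points], dtype=float)
    span = po2.max() - po2.min()
    if span < 50.0:
        raise ValueError(f"Po2 span {span:.1f} mmHg < 50 mmHg; sweep a wider range")

    # linear model in inverse lifetime: 1/tau = a + b * Po2
    b, a = np.polyfit(po2, 1.0 / tau, 1)
    if a <= 0 or b <= 0:
        raise ValueError(
            "non-physical fit (tau0 or kq <= 0); check units and data quality"
        )
    tau0 = 1.0 / a
    kq = float(b)
    tau_model = 1.0 / (a + b * po2)
    resid = float(np.sqrt(np.mean((tau - tau_model) ** 2)))

    warning = None
    order = np.argsort(po2)
    dtau = np.diff(tau[order])
    # lifetime should fall as Po2 rises; flag rises above 5% of the sweep's
    # dynamic range (scale-based, so an outlier cannot inflate its own floor)
    noise_floor = max(0.05 * float(np.ptp(tau)), 1e-9 * tau0)
    n_bad = int(np.sum(dtau > noise_floor))
    if n_bad:
        warning = (
            f"{n_bad} adjacent point pair(s) non-monotone beyond noise "
            f"tolerance ({noise_floor:.3g} us)"
        )

    return CalibrationCurve(
        temperature_c=float(temperature_c),
        tau0_us=float(tau0),
        kq_per_us_mmHg=kq,
        fit_residual=resid,
        valid_po2_range=(float(po2.min()), float(po2.max())),
        warning=warning,
    )


def tau_from_po2(curve: CalibrationCurve, po2: float | np.ndarray):
    """Forward-evaluate a curve: lifetime (us) at ``po2`` (mmHg)."""
    return curve.tau_from_po2(po2)


def interpolate_curve(cal_set: CalibrationSet, temperature_c: float) -> CalibrationCurve:
    """Curve at an arbitrary temperature, linear in (tau0, kq) between nodes.

    At a stored node temperature the stored curve is returned unchanged.
    Up to ``TEMPERATURE_SLACK_C`` beyond the node range the nearest node
    curve is used (no parameter extrapolation); farther out is an error.
    """
    temps = cal_set.temperatures
    hit = np.where(np.isclose(temps, temperature_c, atol=1e-9))[0]
    if hit.size:
        return cal_set.curves[int(hit[0])]
    tmin, tmax = float(temps[0]), float(temps[-1])
    if temperature_c < tmin - TEMPERATURE_SLACK_C or temperature_c > tmax + TEMPERATURE_SLACK_C:
        raise ValueError(
            f"temperature {temperature_c:g} degC outside calibrated range "
            f"[{tmin - TEMPERATURE_SLACK_C:g}, {tmax + TEMPERATURE_SLACK_C:g}] degC"
        )
    if temperature_c < tmin:
        return cal_set.curves[0]
    if temperature_c > tmax:
        return cal_set.curves[-1]
    j = int(np.searchsorted(temps, temperature_c))
    lo, hi = cal_set.curves[j - 1], cal_set.curves[j]
    w = (temperature_c - lo.temperature_c) / (hi.temperature_c - lo.temperature_c)
    rng = (
        (1 - w) * lo.valid_po2_range[0] + w * hi.valid_po2_range[0],
        (1 - w) * lo.valid_po2_range[1] + w * hi.valid_po2_range[1],
    )
    return CalibrationCurve(
        temperature_c=float(temperature_c),
        tau0_us=(1 - w) * lo.tau0_us + w * hi.tau0_us,
        kq_per_us_mmHg=(1 - w) * lo.kq_per_us_mmHg + w * hi.kq_per_us_mmHg,
        fit_residual=(1 - w) * lo.fit_residual + w * hi.fit_residual,
        valid_po2_range=rng,
    )


def po2_from_tau(
    cal_set: CalibrationSet,
    tau_us: float,
    temperature_c: float,
    tau_tolerance: float = 0.02,
) -> float:
    """Convert a lifetime to Po2 using the curve matched/interpolated to ``temperature_c``."""
    return cal_set.po2_from_tau(tau_us, temperature_c, tau_tolerance)


class SplineCalibrationCurve:
    """Monotone-spline lifetime/Po2 map for sensors that depart from linear quenching.

    Fits a shape-preserving PCHIP through the median lifetime at each Po2
    level; the inverse is the PCHIP through the reflected data. Only
    guaranteed sensible for data that are monotone within noise.
    """

    def __init__(self, points: Sequence[CalibrationPoint], temperature_c: float | None = None):
        po2 = np.array([p.po2_mmHg for p in points], dtype=float)
        tau = np.array([p.lifetime_us for p in points], dtype=float)
        order = np.argsort(po2)
        po2, tau = po2[order], tau[order]
        # collapse duplicate Po2 levels and enforce strict decrease
        upo2, idx = np.unique(po2, return_inverse=True)
        utau = np.array([tau[idx == k].mean() for k in range(len(upo2))])
        utau = np.minimum.accumulate(utau)  # clip noise-driven rises
        keep = np.concatenate([[True], np.diff(utau) < 0])
        upo2, utau = upo2[keep], utau[keep]
        if len(upo2) < 4:
            raise ValueError("need >= 4 distinct monotone Po2 levels for a spline curve")
        self.temperature_c = float(temperature_c if temperature_c is not None else points[0].temperature_c)
        self.valid_po2_range = (float(upo2[0]), float(upo2[-1]))
        self._fwd = PchipInterpolator(upo2, utau)

    def tau_from_po2(self, po2):
        po2 = np.asarray(po2, dtype=float)
        lo, hi = self.valid_po2_range
        if np.any((po2 < lo) | (po2 > hi)):
            raise ValueError(f"po2 outside spline support [{lo}, {hi}] mmHg")
        out = self._fwd(po2)
        return float(out) if out.ndim == 0 else out

    def po2_from_tau(self, tau_us: float, tau_tolerance: float = 0.02) -> float:
        from scipy.optimize import brentq

        lo, hi = self.valid_po2_range
        tmin, tmax = float(self._fwd(hi)), float(self._fwd(lo))
        if not (tmin * (1 - tau_tolerance) <= tau_us <= tmax * (1 + tau_tolerance)):
            raise ValueError(
                f"lifetime {tau_us:.4g} us outside admissible interval "
                f"[{tmin * (1 - tau_tolerance):.4g}, {tmax * (1 + tau_tolerance):.4g}] us"
            )
        target = float(np.clip(tau_us, tmin, tmax))
        if target >= tmax:
            return lo
        if target <= tmin:
            return hi
        # exact inverse of the forward spline by root finding (monotone curve)
        return float(brentq(lambda p: float(self._fwd(p)) - target, lo, hi, xtol=1e-10))
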