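"""Gated phosphorescence acquisitions: cycle segmentation, decay accumulation, lifetime fitting.

The acquisition alternates a short excitation gate (AOM on, fluorescence
collected for RBC detection) with a long dark phase in which single
phosphorescence photons are binned at the digitizer rate. One such
on/off pair is a *cycle*; capillary point measurements repeat the cycle
every 250 us for seconds at a time. Per-cycle photon counts are far too
sparse to fit, so decays from many cycles are accumulated bin-wise before
a single-exponential-plus-background model is fitted by Poisson maximum
likelihood. The first few microseconds after the gate are discarded to
reject gate transients and prompt fluorescence.

The nominal 250 us period at a 1.25 MHz sampling clock is 312.5 samples;
internally a cycle carries 312 whole 0.8 us bins (249.6 us of samples)
while cycle start times keep the nominal period.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize

logger = logging.getLogger(__name__)

__all__ = [
    "GateConfig",
    "PhotonTrace",
    "DecayCurve",
    "LifetimeFit",
    "FitError",
    "segment_cycles",
    "accumulate_decay",
    "fit_lifetime",
    "po2_mean_from_trace",
]


@dataclass(frozen=True)
class GateConfig:
    """Timing of the gated acquisition cycle (all durations in microseconds)."""

    cycle_period_us: float = 250.0
    excitation_on_us: float = 25.0
    collection_off_us: float = 225.0
    discard_after_gate_us: float = 5.6
    sampling_rate_hz: float = 1.25e6

    def __post_init__(self) -> None:
        if not math.isclose(
            self.excitation_on_us + self.collection_off_us, self.cycle_period_us
        ):
            raise ValueError("excitation_on_us + collection_off_us must equal cycle_period_us")
        if not self.discard_after_gate_us < self.collection_off_us:
            raise ValueError("discard_after_gate_us must be shorter than the off phase")

    @property
    def bin_us(self) -> float:
        """Width of one digitizer bin (0.8 us at 1.25 MHz)."""
        return 1e6 / self.sampling_rate_hz

    @property
    def bins_per_cycle(self) -> int:
        """Whole bins in one cycle (312 for the defaults; the half-bin is dropped)."""
        return int(self.cycle_period_us / self.bin_us)

    @property
    def on_bins(self) -> int:
        return int(self.excitation_on_us / self.bin_us)

    @property
    def off_bins(self) -> int:
        return self.bins_per_cycle - self.on_bins

    @property
    def discard_bins(self) -> int:
        """Leading off-phase bins whose start falls before the discard deadline."""
        return int(np.ceil(self.discard_after_gate_us / self.bin_us))

    def off_bin_centers_us(self) -> np.ndarray:
        """Centers of all off-phase bins, microseconds after the gate end."""
        return (np.arange(self.off_bins) + 0.5) * self.bin_us

    def to_attrs(self) -> dict:
        return {
            "cycle_period_us": self.cycle_period_us,
            "excitation_on_us": self.excitation_on_us,
            "collection_off_us": self.collection_off_us,
            "discard_after_gate_us": self.discard_after_gate_us,
            "sampling_rate_hz": self.sampling_rate_hz,
        }


@dataclass
class PhotonTrace:
    """Per-cycle gated photon data for one capillary point measurement.

    ``off_phase_counts`` has shape (n_cycles, gate.off_bins); counts are
    non-negative (integers for measured data, expectations for noiseless
    synthetic traces).
    """

    cycle_start_ms: np.ndarray
    on_phase_intensity: np.ndarray
    off_phase_counts: np.ndarray
    gate: GateConfig = field(default_factory=GateConfig)

    def __post_init__(self) -> None:
        self.cycle_start_ms = np.asarray(self.cycle_start_ms, dtype=float)
        self.on_phase_intensity = np.asarray(self.on_phase_intensity)
        self.off_phase_counts = np.atleast_2d(np.asarray(self.off_phase_counts))
        n = len(self.cycle_start_ms)
        if self.on_phase_intensity.shape != (n,) or self.off_phase_counts.shape[0] != n:
            raise ValueError("per-cycle arrays disagree on cycle count")
        if n == 0:
            raise ValueError("empty trace")
        if np.any(self.off_phase_counts < 0) or np.any(self.on_phase_intensity < 0):
            raise ValueError("photon counts must be non-negative")
        if n > 1 and np.any(np.diff(self.cycle_start_ms) <= 0):
            raise ValueError("cycle start times must be strictly increasing")

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_start_ms)

    @property
    def cycle_mid_ms(self) -> np.ndarray:
        """Cycle mid-times, used as the cycle's timestamp for classification."""
        return self.cycle_start_ms + self.gate.cycle_period_us / 2000.0

    @property
    def duration_s(self) -> float:
        return self.n_cycles * self.gate.cycle_period_us * 1e-6


@dataclass
class DecayCurve:
    """Accumulated, discard-trimmed phosphorescence decay."""

    time_us: np.ndarray
    counts: np.ndarray
    n_cycles_averaged: int

    def __post_init__(self) -> None:
        self.time_us = np.asarray(self.time_us, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.time_us.shape != self.counts.shape:
            raise ValueError("time and count vectors must align")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.n_cycles_averaged < 1:
            raise ValueError("n_cycles_averaged must be >= 1")


@dataclass
class LifetimeFit:
    """Result of a Poisson maximum-likelihood single-exponential fit."""

    tau_us: float
    amplitude: float
    background: float
    ci95_us: float
    n_photons: float


class FitError(RuntimeError):
    """Lifetime fit failed; ``best_guess`` carries the best grid point found."""

    def __init__(self, message: str, best_guess: tuple | None = None):
        super().__init__(message)
        self.best_guess = best_guess


def segment_cycles(raw_samples: np.ndarray, gate: GateConfig = GateConfig()) -> PhotonTrace:
    """Split a flat binned count stream into cycles.

    ``raw_samples`` is a 1-D array of photon counts in consecutive
    ``gate.bin_us`` bins laid out as repeating cycles of
    ``gate.bins_per_cycle`` bins (on-phase bins first). A trailing partial
    cycle is dropped with a logged warning.
    """
    raw = np.asarray(raw_samples)
    if raw.ndim != 1:
        raise ValueError("raw_samples must be 1-D")
    spc = gate.bins_per_cycle
    n_cycles = len(raw) // spc
    if n_cycles == 0:
        raise ValueError(f"stream of {len(raw)} samples is shorter than one cycle ({spc} samples)")
    if len(raw) % spc:
        logger.warning(
            "dropping trailing partial cycle (%d of %d samples)", len(raw) % spc, spc
        )
    cycles = raw[: n_cycles * spc].reshape(n_cycles, spc)
    return PhotonTrace(
        cycle_start_ms=np.arange(n_cycles) * gate.cycle_period_us / 1000.0,
        on_phase_intensity=cycles[:, : gate.on_bins].sum(axis=1),
        off_phase_counts=cycles[:, gate.on_bins :],
        gate=gate,
    )


def accumulate_decay(trace: PhotonTrace, cycle_indices=None) -> DecayCurve:
    """Sum off-phase bins across selected cycles and trim the post-gate discard window.

    ``cycle_indices`` is any numpy-style selection (default: all cycles).
    Bins whose start time falls before ``gate.discard_after_gate_us`` after
    the gate end are removed.
    """
    gate = trace.gate
    if cycle_indices is None:
        sel = np.arange(trace.n_cycles)
    else:
        sel = np.atleast_1d(np.asarray(cycle_indices))
        if sel.dtype == bool:
            sel = np.flatnonzero(sel)
    if sel.size == 0:
        raise ValueError("empty cycle selection")
    if sel.min() < 0 or sel.max() >= trace.n_cycles:
        raise IndexError("cycle selection out of range")
    counts = trace.off_phase_counts[sel].sum(axis=0)
    k = gate.discard_bins
    return DecayCurve(
        time_us=gate.off_bin_centers_us()[k:],
        counts=counts[k:],
        n_cycles_averaged=int(sel.size),
    )


def _nll_and_grad(theta: np.ndarray, t: np.ndarray, y: np.ndarray):
    """Poisson negative log-likelihood of A*exp(-t/tau)+B in (log tau, log A, B)."""
    log_tau, log_a, b = theta
    tau, a = np.exp(log_tau), np.exp(log_a)
    e = np.exp(-t / tau)
    mu = a * e + b + 1e-12
    nll = float(np.sum(mu - y * np.log(mu)))
    w = 1.0 - y / mu
    g_logtau = float(np.sum(w * a * e * t / tau))
    g_loga = float(np.sum(w * a * e))
    g_b = float(np.sum(w))
    return nll, np.array([g_logtau, g_loga, g_b])


def _fit_ab_given_tau(t: np.ndarray, y: np.ndarray, tau: float, a0: float, b0: float) -> tuple[float, float, float]:
    """Profile out (A, B) at fixed tau; returns (nll, A, B)."""
    e = np.exp(-t / tau)

    def nll_ab(p):
        a, b = np.exp(p[0]), p[1]
        mu = a * e + b + 1e-12
        nll = float(np.sum(mu - y * np.log(mu)))
        w = 1.0 - y / mu
        return nll, np.array([float(np.sum(w * a * e)), float(np.sum(w))])

    res = minimize(
        nll_ab,
        x0=np.array([np.log(max(a0, 1e-9)), max(b0, 0.0)]),
        jac=True,
        method="L-BFGS-B",
        bounds=[(-40, 40), (0, None)],
        options={"maxiter": 200, "ftol": 1e-12},
    )
    return float(res.fun), float(np.exp(res.x[0])), float(res.x[1])


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Log-linear regression on background-subtracted counts."""
    tail = max(5, len(y) // 10)
    b0 = float(max(np.mean(np.sort(y)[:tail]) * 0.5, 0.0))
    ysub = y - b0
    mask = ysub > 0
    if mask.sum() >= 3:
        # weight by counts so early (high-count) bins dominate, as in a Poisson fit
        coef = np.polyfit(t[mask], np.log(ysub[mask]), 1, w=np.sqrt(ysub[mask]))
        slope, intercept = coef[0], coef[1]
        tau0 = -1.0 / slope if slope < 0 else (t[-1] - t[0])
        a0 = float(np.exp(intercept))
    else:
        tau0, a0 = (t[-1] - t[0]) / 3.0, float(max(y.max(), 1e-6))
    tau0 = float(np.clip(tau0, 0.5, 10.0 * (t[-1] - t[0])))
    return tau0, a0, b0


#: chi-square(1) 95% quantile / 2, the profile-likelihood threshold
_PROFILE_DELTA = 1.9207293


def fit_lifetime(
    decay: DecayCurve,
    tau_bounds_us: tuple[float, float] = (1.0, 500.0),
    compute_ci: bool = True,
) -> LifetimeFit:
    """Poisson MLE of ``counts ~ Poisson(A*exp(-t/tau) + B)`` on a trimmed decay.

    The 95% confidence half-width on tau comes from the profile likelihood
    (chi-square threshold); when the profile never crosses the threshold
    inside ``tau_bounds_us`` the interval is reported clipped to the bounds,
    i.e. an unidentifiable decay yields a CI spanning the whole search range.
    Deterministic for identical input.
    """
    t, y = decay.time_us, decay.counts
    if len(t) < 10:
        raise ValueError(f"need >= 10 post-discard bins, got {len(t)}")
    total = float(y.sum())
    if total <= 0:
        raise ValueError("decay has zero total counts")

    tau0, a0, b0 = _initial_guess(t, y)
    tau0 = float(np.clip(tau0, *tau_bounds_us))
    res = minimize(
        _nll_and_grad,
        x0=np.array([np.log(tau0), np.log(max(a0, 1e-9)), b0]),
        args=(t, y),
        jac=True,
        method="L-BFGS-B",
        bounds=[(np.log(tau_bounds_us[0]), np.log(tau_bounds_us[1])), (-40, 40), (0, None)],
        options={"maxiter": 500, "ftol": 1e-15, "gtol": 1e-12},
    )
    tau_hat = float(np.exp(res.x[0]))
    a_hat = float(np.exp(res.x[1]))
    b_hat = float(res.x[2])
    nll_hat = float(res.fun)

    # guard against a bad basin: coarse profile over tau must not beat the optimum
    grid = np.geomspace(tau_bounds_us[0], tau_bounds_us[1], 40)
    prof = np.array([_fit_ab_given_tau(t, y, g, a_hat, b_hat)[0] for g in grid])
    if prof.min() < nll_hat - 1e-6:
        j = int(np.argmin(prof))
        res2 = minimize(
            _nll_and_grad,
            x0=np.array([np.log(grid[j]), res.x[1], b_hat]),
            args=(t, y),
            jac=True,
            method="L-BFGS-B",
            bounds=[(np.log(tau_bounds_us[0]), np.log(tau_bounds_us[1])), (-40, 40), (0, None)],
            options={"maxiter": 500, "ftol": 1e-15, "gtol": 1e-12},
        )
        if res2.fun <= prof[j] + 1e-9:
            tau_hat, a_hat, b_hat, nll_hat = (
                float(np.exp(res2.x[0])),
                float(np.exp(res2.x[1])),
                float(res2.x[2]),
                float(res2.fun),
            )
        else:
            raise FitError(
                "lifetime fit failed to converge",
                best_guess=(float(grid[j]), a_hat, b_hat),
            )

    ci95 = float("nan")
    if compute_ci:
        thresh = nll_hat + _PROFILE_DELTA

        def excess(tau):
            return _fit_ab_given_tau(t, y, tau, a_hat, b_hat)[0] - thresh

        lo, hi = tau_bounds_us
        try:
            lo_ci = brentq(excess, lo, tau_hat, xtol=1e-4) if excess(lo) > 0 else lo
        except ValueError:
            lo_ci = lo
        try:
            hi_ci = brentq(excess, tau_hat, hi, xtol=1e-4) if excess(hi) > 0 else hi
        except ValueError:
            hi_ci = hi
        ci95 = float((hi_ci - lo_ci) / 2.0)

    return LifetimeFit(
        tau_us=tau_hat, amplitude=a_hat, background=b_hat, ci95_us=ci95, n_photons=total
    )


def po2_mean_from_trace(
    trace: PhotonTrace, cal_set, temperature_c: float, compute_ci: bool = False
) -> tuple[float, LifetimeFit]:
    """All-cycle Po2: accumulate every cycle, fit one lifetime, convert once.

    This fit-then-convert order is the pipeline's definition of the mean
    capillary Po2; it is not the average of per-cycle conversions.
    """
    fit = fit_lifetime(accumulate_decay(trace), compute_ci=compute_ci)
    po2 = cal_set.po2_from_tau(fit.tau_us, temperature_c)
    return po2, fit
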