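"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package's estimators: the
Stern-Volmer oracle scans a dense (tau0, kq) grid against the summed squared
inverse-lifetime residuals, and the lifetime oracle scans a (tau, A, B) grid
against the exact Poisson negative log-likelihood, refining each around the
coarse winner.
"""

from __future__ import annotations

import numpy as np


def sv_grid_search(
    po2: np.ndarray,
    tau: np.ndarray,
    tau0_range=(20.0, 80.0),
    kq_range=(3e-4, 3e-3),
    n_grid: int = 201,
    n_refine: int = 4,
) -> tuple[float, float]:
    """Brute-force least squares on 1/tau over a (tau0, kq) grid.

    The refinement window stays wide (+/- 15 steps) because the (tau0, kq)
    objective has a long correlated valley: the coarse-grid argmin can sit
    several steps along the valley away from the continuous optimum.
    """
    inv = 1.0 / np.asarray(tau, dtype=float)
    po2 = np.asarray(po2, dtype=float)
    t_lo, t_hi = tau0_range
    k_lo, k_hi = kq_range
    best = (np.nan, np.nan)
    for _ in range(n_refine + 1):
        tau0s = np.linspace(t_lo, t_hi, n_grid)
        kqs = np.linspace(k_lo, k_hi, n_grid)
        # residual sum over the full grid, vectorized
        pred = 1.0 / tau0s[:, None, None] + kqs[None, :, None] * po2[None, None, :]
        sse = ((pred - inv[None, None, :]) ** 2).sum(axis=2)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        best = (float(tau0s[i]), float(kqs[j]))
        dt = (t_hi - t_lo) / (n_grid - 1)
        dk = (k_hi - k_lo) / (n_grid - 1)
        t_lo, t_hi = best[0] - 15 * dt, best[0] + 15 * dt
        k_lo, k_hi = best[1] - 15 * dk, best[1] + 15 * dk
    return best


def poisson_mle_grid_search(
    t: np.ndarray,
    y: np.ndarray,
    tau_range=(5.0, 100.0),
    n_tau: int = 120,
    n_ab: int = 40,
    n_refine: int = 3,
) -> tuple[float, float, float]:
    """Brute-force Poisson MLE of y ~ Poisson(A exp(-t/tau) + B) on a 3-D grid."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    # data-driven amplitude/background brackets
    a_hat = max(y[: max(3, len(y) // 20)].mean(), 1e-6)
    b_hat = max(y[-max(3, len(y) // 20) :].mean(), 0.0)
    a_lo, a_hi = a_hat * 0.2, a_hat * 5.0
    b_lo, b_hi = 0.0, max(b_hat * 5.0, 1e-3)
    t_lo, t_hi = tau_range

    best = (np.nan, np.nan, np.nan)
    for _ in range(n_refine + 1):
        taus = np.linspace(t_lo, t_hi, n_tau)
        amps = np.linspace(a_lo, a_hi, n_ab)
        bgs = np.linspace(b_lo, b_hi, n_ab)
        e = np.exp(-t[None, :] / taus[:, None])  # (n_tau, n_bins)
        best_here = (np.inf, None)
        for ia, a in enumerate(amps):
            mu = a * e[:, None, :] + bgs[None, :, None] + 1e-12  # (n_tau, n_ab, n_bins)
            nll = (mu - y[None, None, :] * np.log(mu)).sum(axis=2)
            k = np.unravel_index(np.argmin(nll), nll.shape)
            if nll[k] < best_here[0]:
                best_here = (float(nll[k]), (float(taus[k[0]]), float(a), float(bgs[k[1]])))
        best = best_here[1]
        dtau = (t_hi - t_lo) / (n_tau - 1)
        da = (a_hi - a_lo) / (n_ab - 1)
        db = (b_hi - b_lo) / (n_ab - 1)
        t_lo, t_hi = max(best[0] - 2 * dtau, 0.1), best[0] + 2 * dtau
        a_lo, a_hi = max(best[1] - 2 * da, 1e-9), best[1] + 2 * da
        b_lo, b_hi = max(best[2] - 2 * db, 0.0), best[2] + 2 * db
    return best
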