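"""Voxel-wise T1 mapping from inversion-recovery image series.

An inversion-recovery (IR) acquisition inverts longitudinal
magnetization and samples the magnitude signal after a delay TI. With
three parameters — the relaxation time T1, the equilibrium
magnetization M0 and the effective post-inversion magnetization
M(0) — the magnitude signal follows

    y(t) = | M0 - (M0 - M(0)) * exp(-t / T1) |

Each pixel is fitted by nonlinear least squares with multiple starts
(a log-spaced T1 grid crossed with both inversion polarities) so the
absolute value's non-convexity cannot trap the fit in a local minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

#: Inversion times (ms) of the study's 8-point fast-spin-echo IR schedule.
STUDY_TI_MS = (100.0, 170.0, 310.0, 530.0, 940.0, 1640.0, 2900.0, 5000.0)

#: Multi-start T1 grid in ms.
T1_STARTS_MS = (100.0, 300.0, 1000.0, 3000.0)


@dataclass
class InversionRecoverySeries:
    """Magnitude IR images stacked over inversion time.

    ``signals`` has shape (ny, nx, n_ti); ``brain_mask`` selects pixels
    to fit.
    """

    ti_ms: np.ndarray
    signals: np.ndarray
    brain_mask: np.ndarray
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ti_ms = np.asarray(self.ti_ms, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if not np.all(np.diff(self.ti_ms) > 0):
            raise ValueError("inversion times must be strictly increasing")
        if self.signals.shape[-1] != self.ti_ms.size:
            raise ValueError("signal series length does not match TI list")
        if self.signals.min() < 0:
            raise ValueError("magnitude signals must be non-negative")
        if self.brain_mask.shape != self.signals.shape[:-1]:
            raise ValueError("mask shape does not match image shape")


@dataclass
class T1FitResult:
    t1_ms: float
    m0: float
    m_init: float
    rss: float
    converged: bool


def ir_model(t, t1: float, m0: float, m_init: float):
    """Magnitude IR signal |M0 - (M0 - M(0)) exp(-t/T1)|."""
    if t1 <= 0:
        raise ValueError("t1 must be positive")
    t = np.asarray(t, dtype=float)
    return np.abs(m0 - (m0 - m_init) * np.exp(-t / t1))


def _residuals(params, t, y):
    t1, m0, m_init = params
    return np.abs(m0 - (m0 - m_init) * np.exp(-t / t1)) - y


def fit_t1_pixel(series: np.ndarray, ti_ms: np.ndarray,
                 rel_tol: float = 1e-8) -> T1FitResult:
    """Three-parameter IR fit for one pixel's signal-vs-TI curve.

    Runs least squares from every start on the T1 grid crossed with both
    signs of the initial magnetization and keeps the lowest-residual
    solution. Flat or all-zero series cannot constrain T1 and are
    returned non-converged.
    """
    y = np.asarray(series, dtype=float)
    t = np.asarray(ti_ms, dtype=float)
    if y.size != t.size:
        raise ValueError("series and TI list differ in length")
    if y.size < 4:
        raise ValueError("need at least 4 inversion times for a 3-parameter fit")

    if np.ptp(y) == 0:
        return T1FitResult(np.nan, np.nan, np.nan, np.nan, converged=False)

    m0_guess = float(y.max())
    best = None
    for t1_0 in T1_STARTS_MS:
        for m_init_0 in (-m0_guess, m0_guess):
            try:
                sol = least_squares(
                    _residuals, x0=[t1_0, m0_guess, m_init_0],
                    args=(t, y), method="trf",
                    bounds=([1e-3, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
                    xtol=rel_tol, ftol=rel_tol, gtol=rel_tol,
                )
            except Exception:
                continue
            rss = float(np.sum(sol.fun ** 2))
            if best is None or rss < best[0]:
                best = (rss, sol)
    if best is None:
        return T1FitResult(np.nan, np.nan, np.nan, np.nan, converged=False)
    rss, sol = best
    t1, m0, m_init = (float(v) for v in sol.x)
    ok = bool(sol.success) and np.isfinite(t1) and t1 > 0
    return T1FitResult(t1, m0, m_init, rss, converged=ok)


@dataclass
class T1MapResult:
    """Per-pixel T1 map with quality-control companions."""

    t1_map: np.ndarray
    m0_map: np.ndarray
    m_init_map: np.ndarray
    rss_map: np.ndarray
    converged: np.ndarray
    n_fitted: int
    n_converged: int


def fit_t1_map(stack: InversionRecoverySeries) -> T1MapResult:
    """Fit every masked pixel of an IR stack; NaN outside the mask."""
    if not stack.brain_mask.any():
        raise ValueError("brain mask is empty")
    shape = stack.brain_mask.shape
    t1 = np.full(shape, np.nan)
    m0 = np.full(shape, np.nan)
    m_init = np.full(shape, np.nan)
    rss = np.full(shape, np.nan)
    conv = np.zeros(shape, dtype=bool)
    idx = np.argwhere(stack.brain_mask)
    for iy, ix in idx:
        res = fit_t1_pixel(stack.signals[iy, ix], stack.ti_ms)
        conv[iy, ix] = res.converged
        if res.converged:
            t1[iy, ix] = res.t1_ms
            m0[iy, ix] = res.m0
            m_init[iy, ix] = res.m_init
            rss[iy, ix] = res.rss
    return T1MapResult(t1, m0, m_init, rss, conv,
                       n_fitted=len(idx), n_converged=int(conv.sum()))


def regional_t1(result: T1MapResult, region_mask: np.ndarray,
                min_converged_fraction: float = 0.5) -> dict:
    """Mean T1 over converged pixels of a region, with a coverage flag.

    Regions where fewer than ``min_converged_fraction`` of the pixels
    converged are flagged unreliable.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    n = int(region_mask.sum())
    if n == 0:
        raise ValueError("empty region mask")
    conv = result.converged & region_mask
    n_conv = int(conv.sum())
    mean_t1 = float(np.nanmean(result.t1_map[conv])) if n_conv else float("nan")
    return {
        "mean_t1_ms": mean_t1,
        "n_pixels": n,
        "n_converged": n_conv,
        "reliable": n_conv >= min_converged_fraction * n,
    }
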