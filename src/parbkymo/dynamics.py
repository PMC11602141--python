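"""Diffusion estimation from 1-D kymograph tracks.

The apparent diffusion constant of a feature (ParB dimer, plectoneme or
condensate) is estimated from the time-averaged mean squared displacement
MSD(tau) over lag times of 2-20 frames, fit to the 1-D Brownian form
MSD = 2 D tau (no intercept). An 11-frame moving window yields an apparent
D over time, used to detect arrest of plectoneme motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import smooth_series

__all__ = ["DiffusionEstimate", "msd", "fit_D", "moving_window_D"]

GLOBAL_LAGS = range(2, 21)
WINDOW_LAGS = range(1, 5)


@dataclass
class DiffusionEstimate:
    """Apparent 1-D diffusion constant in kb^2/s with fit metadata."""

    D_kb2_per_s: float
    fit_stderr: float
    n_points: int
    lag_range_frames: tuple[int, int]
    method: str = "msd-global"
    clipped: bool = False  # negative fitted slope clipped to zero


def msd(positions_kb: np.ndarray, lags=GLOBAL_LAGS) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged MSD over the given frame lags.

    ``positions_kb`` is a per-frame position series; gap frames are NaN and
    pairs containing them are skipped. Returns ``(lags, msd_kb2)`` with NaN
    where a lag has no valid pair.
    """
    x = np.asarray(positions_kb, dtype=float)
    if x.ndim != 1:
        raise ValueError("positions must be a 1-D per-frame series")
    lags = np.asarray(list(lags), dtype=int)
    if x.size <= lags.min():
        raise ValueError("track shorter than the minimum lag")
    out = np.full(lags.size, np.nan)
    for i, lag in enumerate(lags):
        if lag >= x.size:
            continue
        d = x[lag:] - x[:-lag]
        d = d[~np.isnan(d)]
        if d.size:
            out[i] = float(np.mean(d * d))
    return lags, out


def fit_D(
    lags_frames: np.ndarray,
    msd_kb2: np.ndarray,
    frame_interval_s: float,
    n_frames: int | None = None,
    weighting: str = "variance",
    method: str = "msd-global",
) -> DiffusionEstimate:
    """Weighted least-squares fit of MSD = 2 D tau through the origin.

    tau is the lag in seconds and D = slope / 2. The time-averaged MSD of
    a Brownian track of length N has variance growing roughly as
    tau^2 (2 tau^2 + 1) / (3 tau (N - tau + 1)) relative to its square, so
    by default lags are weighted inversely to that variance (the weights
    do not depend on D itself); pass ``weighting="uniform"`` for the plain
    unweighted fit, which is also used when ``n_frames`` is unknown.
    Negative slopes are clipped to zero and flagged; the standard error of
    D comes from the weighted residual variance.
    """
    lags_frames = np.asarray(lags_frames, dtype=float)
    m = np.asarray(msd_kb2, dtype=float)
    keep = ~np.isnan(m)
    lag = lags_frames[keep]
    tau = lag * frame_interval_s
    m = m[keep]
    if m.size < 2:
        return DiffusionEstimate(np.nan, np.nan, int(m.size),
                                 (int(lags_frames.min()), int(lags_frames.max())),
                                 method=method, clipped=False)
    if weighting == "variance" and n_frames is not None:
        w = 3.0 * lag * (n_frames - lag + 1.0) / (lag ** 2 * (2.0 * lag ** 2 + 1.0))
    elif weighting in ("variance", "uniform"):
        w = np.ones_like(tau)
    else:
        raise ValueError("weighting must be 'variance' or 'uniform'")
    denom = float(np.sum(w * tau * tau))
    slope = float(np.sum(w * tau * m)) / denom
    resid = m - slope * tau
    var_slope = float(np.sum(w * resid * resid)) / (m.size - 1) / denom
    stderr = 0.5 * np.sqrt(max(var_slope, 0.0))
    clipped = slope < 0
    D = max(slope, 0.0) / 2.0
    return DiffusionEstimate(D, stderr, int(m.size),
                             (int(lag.min()), int(lag.max())),
                             method=method, clipped=clipped)


def moving_window_D(
    positions_kb: np.ndarray,
    frame_interval_s: float,
    window_frames: int = 11,
    lags=WINDOW_LAGS,
    smooth_window: int | None = 9,
) -> np.ndarray:
    """Apparent diffusion constant per frame from a centered moving window.

    Each frame's D is a no-intercept MSD fit (lags 1-4 by default, all
    that a short window supports) on the centered ``window_frames``
    sub-track; frames whose window is incomplete or runs off the series
    yield NaN. With ``smooth_window`` the trace is median-filtered.
    """
    if window_frames < 3 or window_frames % 2 == 0:
        raise ValueError("window_frames must be odd and >= 3")
    x = np.asarray(positions_kb, dtype=float)
    half = window_frames // 2
    n = x.size
    out = np.full(n, np.nan)
    lag_list = list(lags)
    for i in range(half, n - half):
        seg = x[i - half:i + half + 1]
        if np.isnan(seg).all():
            continue
        try:
            lag_arr, m = msd(seg, lags=lag_list)
        except ValueError:
            continue
        est = fit_D(lag_arr, m, frame_interval_s, n_frames=window_frames,
                    method="moving-window")
        out[i] = est.D_kb2_per_s
    if smooth_window:
        out = smooth_series(out, smooth_window)
    return out
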