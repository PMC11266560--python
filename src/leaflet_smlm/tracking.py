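"""Mean-square-displacement analysis of single-molecule trajectories.

For a trajectory of N positions sampled every delta-t, the MSD at lag
n*delta-t is the overlapping-window average

    MSD(n dt) = (1/(N-n)) * sum_{j=1..N-n} |r((j+n) dt) - r(j dt)|^2,

i.e. the square displacements over n steps of all N-n partial trajectories
of n+1 consecutive positions. Effective diffusion coefficients are obtained
by ordinary least squares over a named fit window of the MSD-lag plot; the
slope divided by 4 (two dimensions) is D_eff, and the intercept — which
absorbs the localization-error offset 4*sigma^2 — is reported, never
silently subtracted.

Apparent-Brownian classification uses a relative-deviation statistic: the
ratio of the observed long-lag MSD to the value extrapolated from a
short-lag fit, compared against the 2.5th/97.5th percentile envelope of the
same statistic over simulated Brownian trajectories matched in length and
frame interval. The envelope scheme is this package's own documented choice
of classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import TrajectorySet
from .simulate import TrajectoryModelParams, gen_trajectories

NM2_TO_UM2 = 1e-6

#: named fit windows -> lag timepoints in seconds
FIT_WINDOWS: dict[str, tuple[float, ...]] = {
    # 4-ms resolution: single-molecule window of 12 ms (points 8, 12, 16 ms)
    "12ms@4ms": (0.008, 0.012, 0.016),
    # 4-ms resolution: ensemble window of 24 ms (points 8..40 ms)
    "24ms@4ms": tuple(np.round(np.arange(0.008, 0.040 + 1e-9, 0.004), 9)),
    # 1-ms resolution: window of 3 ms on the 2-10 ms time scale
    "3ms@1ms": tuple(np.round(np.arange(0.002, 0.010 + 1e-9, 0.001), 9)),
}


@dataclass
class MSDCurve:
    """MSD(lag) with per-lag standard errors, in um^2 vs seconds."""

    lags: np.ndarray  # s, n*dt for n = 1..N-1
    msd: np.ndarray  # um^2
    se: np.ndarray  # um^2; zeros for a single trajectory
    n_segments: np.ndarray  # contributing displacement pairs per lag
    frame_interval: float

    def value_at(self, lag: float) -> float:
        i = int(round(lag / self.frame_interval)) - 1
        if not (0 <= i < len(self.lags)) or abs(self.lags[i] - lag) > 1e-9:
            raise ValueError(f"lag {lag} s not on this curve")
        return float(self.msd[i])


@dataclass
class DiffusionEstimate:
    """OLS fit of an MSD window: D_eff = slope/4."""

    d_eff: float  # um^2/s
    window: str
    intercept: float  # um^2 (absorbs the localization-error offset)
    r_squared: float
    non_diffusive: bool = False  # fitted slope was negative; D_eff clamped to 0


def msd(track: np.ndarray, frame_interval: float) -> MSDCurve:
    """Single-trajectory MSD over all lags 1..N-1 (overlapping windows).

    ``track`` is an (N, 2) position array in nm with uniform frame spacing
    (gap-containing tracks must be split upstream).
    """
    track = np.asarray(track, dtype=float)
    n_pos = len(track)
    if n_pos < 2:
        raise ValueError("trajectory must have at least 2 positions")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    lags = frame_interval * np.arange(1, n_pos)
    vals = np.empty(n_pos - 1)
    counts = np.empty(n_pos - 1, dtype=int)
    for n in range(1, n_pos):
        d = track[n:] - track[:-n]
        vals[n - 1] = np.mean((d**2).sum(axis=1)) * NM2_TO_UM2
        counts[n - 1] = n_pos - n
    return MSDCurve(
        lags=lags,
        msd=vals,
        se=np.zeros(n_pos - 1),
        n_segments=counts,
        frame_interval=frame_interval,
    )


def ensemble_msd(
    trajectories: TrajectorySet, min_length: int = 2, weighted: bool = True
) -> MSDCurve:
    """Ensemble-averaged MSD-lag curve over all qualifying trajectories.

    Per lag, single-trajectory MSD values are averaged with weights equal to
    their number of contributing displacement pairs (``weighted=False`` gives
    the plain mean). The standard error is computed across trajectories —
    overlapping windows within one trajectory are strongly correlated and
    would understate it.
    """
    curves = [
        msd(pos, trajectories.frame_interval)
        for _, pos in trajectories.iter_tracks()
        if len(pos) >= max(min_length, 2)
    ]
    if not curves:
        raise ValueError("no trajectory meets min_length")
    max_lags = max(len(c.lags) for c in curves)
    vals = np.full((len(curves), max_lags), np.nan)
    wts = np.zeros((len(curves), max_lags))
    for i, c in enumerate(curves):
        vals[i, : len(c.lags)] = c.msd
        wts[i, : len(c.lags)] = c.n_segments if weighted else 1.0
    have = ~np.isnan(vals)
    w = np.where(have, wts, 0.0)
    wsum = w.sum(axis=0)
    mean = np.nansum(vals * w, axis=0) / wsum
    n_traj = have.sum(axis=0)
    resid = np.where(have, vals - mean, 0.0)
    var = np.where(
        n_traj > 1,
        (resid**2 * w).sum(axis=0) / np.maximum(wsum, 1e-300) * n_traj / np.maximum(n_traj - 1, 1),
        0.0,
    )
    se = np.sqrt(var / np.maximum(n_traj, 1))
    return MSDCurve(
        lags=trajectories.frame_interval * np.arange(1, max_lags + 1),
        msd=mean,
        se=se,
        n_segments=w.sum(axis=0).astype(int),
        frame_interval=trajectories.frame_interval,
    )


def fit_deff(curve: MSDCurve, window: str = "12ms@4ms") -> DiffusionEstimate:
    """Effective diffusion coefficient from an OLS line over a fit window.

    ``window`` names a preset lag set (see :data:`FIT_WINDOWS`). All window
    timepoints must exist on the curve. A negative fitted slope yields
    D_eff = 0 with the ``non_diffusive`` flag set.
    """
    if window not in FIT_WINDOWS:
        raise ValueError(f"unknown window {window!r}; options: {sorted(FIT_WINDOWS)}")
    lags = np.array(FIT_WINDOWS[window])
    y = np.array([curve.value_at(t) for t in lags])
    slope, intercept = np.polyfit(lags, y, 1)
    pred = slope * lags + intercept
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if slope < 0:
        return DiffusionEstimate(0.0, window, float(intercept), r2, non_diffusive=True)
    return DiffusionEstimate(float(slope) / 4.0, window, float(intercept), r2)


def per_trajectory_deff(
    trajectories: TrajectorySet, window: str = "12ms@4ms", min_length: int | None = None
) -> pd.DataFrame:
    """Single-molecule D_eff for every trajectory long enough for the window."""
    lags = FIT_WINDOWS[window]
    need = int(round(max(lags) / trajectories.frame_interval)) + 1
    if min_length is not None:
        need = max(need, min_length)
    rows = []
    for tid, pos in trajectories.iter_tracks():
        if len(pos) < need:
            continue
        est = fit_deff(msd(pos, trajectories.frame_interval), window)
        rows.append(
            {
                "track_id": tid,
                "n_frames": len(pos),
                "d_eff_um2_s": est.d_eff,
                "intercept_um2": est.intercept,
                "r_squared": est.r_squared,
                "non_diffusive": est.non_diffusive,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "track_id",
            "n_frames",
            "d_eff_um2_s",
            "intercept_um2",
            "r_squared",
            "non_diffusive",
        ],
    )


# ---------------------------------------------------------------------------
# apparent-motion classification


@dataclass
class BrownianEnvelope:
    """Percentile envelope of the relative-deviation statistic under
    Brownian motion, for trajectories of fixed length and frame interval."""

    n_frames: int
    frame_interval: float
    short_lags: int
    long_lag: int
    lower: float  # 2.5th percentile
    upper: float  # 97.5th percentile


def _relative_deviation(pos: np.ndarray, dt: float, short_lags: int, long_lag: int) -> float:
    """Observed long-lag MSD over the short-lag-fit extrapolation.

    The short-lag slope is a least-squares line through the origin: a free
    intercept makes the slope estimate sign-indefinite on strongly confined
    trajectories (whose MSD saturates within a frame), which would send the
    ratio to garbage. Through the origin the slope is strictly positive for
    any non-degenerate trajectory, so the statistic stays well defined.
    """
    curve = msd(pos, dt)
    t = np.arange(1, short_lags + 1) * dt
    m = curve.msd[:short_lags]
    slope = float(np.dot(t, m) / np.dot(t, t))
    if slope <= 0:
        return 0.0  # all short-lag MSD zero: maximally suppressed
    return float(curve.msd[long_lag - 1] / (slope * long_lag * dt))


def brownian_envelope(
    n_frames: int,
    frame_interval: float,
    n_simulations: int = 1000,
    short_lags: int = 3,
    long_lag: int | None = None,
    seed: int = 0,
) -> BrownianEnvelope:
    """Calibrate the relative-deviation envelope from simulated Brownian motion.

    The statistic is scale-free in D, so the calibration D is arbitrary.
    """
    if long_lag is None:
        long_lag = max(short_lags + 1, min(n_frames - 1, max(10, (n_frames - 1) // 2)))
    params = TrajectoryModelParams(
        model="brownian", D=1.0, frame_interval=frame_interval, n_frames=n_frames, seed=seed
    )
    sims = gen_trajectories(params, n_simulations)
    rds = np.array(
        [
            _relative_deviation(pos, frame_interval, short_lags, long_lag)
            for _, pos in sims.iter_tracks()
        ]
    )
    lo, hi = np.percentile(rds, [2.5, 97.5])
    return BrownianEnvelope(
        n_frames=n_frames,
        frame_interval=frame_interval,
        short_lags=short_lags,
        long_lag=long_lag,
        lower=float(lo),
        upper=float(hi),
    )


def classify_motion(pos: np.ndarray, calibration: BrownianEnvelope) -> str:
    """Classify one trajectory as suppressed / simple-Brownian / directed.

    The trajectory must be at least as long as the calibration length; only
    the first ``n_frames`` positions are used so the statistic is matched.
    """
    if len(pos) < calibration.n_frames:
        raise ValueError(
            f"trajectory ({len(pos)} frames) shorter than calibration "
            f"({calibration.n_frames} frames)"
        )
    rd = _relative_deviation(
        np.asarray(pos, float)[: calibration.n_frames],
        calibration.frame_interval,
        calibration.short_lags,
        calibration.long_lag,
    )
    if rd < calibration.lower:
        return "suppressed"
    if rd > calibration.upper:
        return "directed"
    return "simple-Brownian"
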