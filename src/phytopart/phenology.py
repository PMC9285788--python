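"""Bloom phenology from community-wise column-integrated chlorophyll.

A threshold/cumulative-sum algorithm on an annual series: the series is
linearly interpolated to daily steps, smoothed with a 15-day
Savitzky-Golay filter, and anomalies are formed against a threshold of
the window median plus 5%.  The gradient of the cumulative anomaly sum
marks the bloom: initiation is the first day the gradient turns positive
and stays positive for more than 15 days; termination is the first
subsequent day it turns negative and stays negative for more than
15 days; duration is the difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .chl import integrate_column
from .config import PhenologyConfig

__all__ = [
    "PhenologyMetrics",
    "to_daily",
    "smooth_series",
    "detect_bloom",
    "community_series",
]


@dataclass
class PhenologyMetrics:
    """Bloom timing for one community's annual window.

    ``initiation``/``termination``/``duration`` are None when no bloom
    satisfies the persistence rule ("no bloom" is an explicit result,
    not an error).
    """

    community: int
    window_start: pd.Timestamp
    window_end: pd.Timestamp
    initiation: pd.Timestamp | None = None
    termination: pd.Timestamp | None = None

    @property
    def duration(self) -> int | None:
        """Bloom duration in days."""
        if self.initiation is None or self.termination is None:
            return None
        return int((self.termination - self.initiation) / pd.Timedelta(days=1))

    @property
    def bloom_detected(self) -> bool:
        return self.initiation is not None and self.termination is not None


def to_daily(times, values) -> pd.Series:
    """Linearly interpolate an irregular series to a daily time step.

    Duplicate timestamps are averaged with a warning.  Returns a pandas
    Series on consecutive daily stamps spanning the input range.
    """
    idx = pd.DatetimeIndex([pd.Timestamp(t) for t in times])
    s = pd.Series(np.asarray(values, dtype=float), index=idx).sort_index()
    if s.index.has_duplicates:
        warnings.warn("duplicate timestamps averaged", stacklevel=2)
        s = s.groupby(level=0).mean()
    if s.size < 2:
        raise ValueError("need at least 2 time points")
    days = pd.date_range(s.index[0].normalize(), s.index[-1].normalize(), freq="D")
    x = (s.index - s.index[0]) / pd.Timedelta(days=1)
    xd = (days - s.index[0]) / pd.Timedelta(days=1)
    return pd.Series(np.interp(xd, x, s.to_numpy()), index=days)


def smooth_series(daily: pd.Series, window: int = 15, order: int = 2) -> pd.Series:
    """Savitzky-Golay smoothing (window in days, nearest-edge handling)."""
    if daily.size < window:
        raise ValueError(f"series of length {daily.size} shorter than window {window}")
    smoothed = savgol_filter(daily.to_numpy(), window_length=window,
                             polyorder=order, mode="nearest")
    return pd.Series(smoothed, index=daily.index)


def _first_persistent_run(sign: np.ndarray, start: int, min_run: int) -> int | None:
    """Index of the first run of True of length > min_run at/after start."""
    i = start
    n = sign.size
    while i < n:
        if sign[i]:
            j = i
            while j < n and sign[j]:
                j += 1
            if j - i > min_run:
                return i
            i = j
        else:
            i += 1
    return None


def detect_bloom(
    smoothed: pd.Series,
    window_start,
    window_end,
    community: int = 1,
    config: PhenologyConfig | None = None,
) -> PhenologyMetrics:
    """Apply the threshold/cumulative-sum criterion over an annual window.

    The threshold is 1.05 × the window median (configurable to an
    amplitude-based form); persistence of "more than 15 days" means at
    least 16 consecutive days of one gradient sign.
    """
    cfg = config or PhenologyConfig()
    t0, t1 = pd.Timestamp(window_start), pd.Timestamp(window_end)
    series = smoothed.loc[t0:t1]
    if series.size < 2 * cfg.persistence_days:
        raise ValueError("annual window not sufficiently covered by the series")
    values = series.to_numpy()
    med = np.median(values)
    if cfg.threshold_mode == "multiplicative":
        threshold = cfg.threshold_factor * med
    elif cfg.threshold_mode == "amplitude":
        threshold = med + (cfg.threshold_factor - 1.0) * (values.max() - values.min())
    else:
        raise ValueError(f"unknown threshold_mode {cfg.threshold_mode!r}")
    anomalies = values - threshold
    csum = np.cumsum(anomalies)
    grad = np.gradient(csum)
    metrics = PhenologyMetrics(community=community, window_start=t0, window_end=t1)
    i_init = _first_persistent_run(grad > 0, 0, cfg.persistence_days)
    if i_init is None:
        return metrics
    metrics.initiation = series.index[i_init]
    i_term = _first_persistent_run(grad < 0, i_init + 1, cfg.persistence_days)
    if i_term is None:
        return metrics
    metrics.termination = series.index[i_term]
    return metrics


def community_series(records, fits, contexts, community: int, tau_limit: float = 6.9):
    """Column-integrated community chlorophyll time series (mg m^-2).

    For each fitted profile, the community's modelled chlorophyll is
    evaluated on the observed depth grid and trapezoid-integrated down to
    z = τ_limit/Kd.  A community absent from a profile contributes zero.
    Skipped profiles (fit of None) are omitted.  Returns (times, values).
    """
    times, values = [], []
    for rec, fit, ctx in zip(records, fits, contexts):
        if fit is None or ctx is None:
            continue
        z_limit = tau_limit / ctx.kd
        z = rec.depth[np.isfinite(rec.depth)]
        if z.size < 2 or z[0] > z_limit:
            continue
        chl = fit.community_profile(z, community)
        times.append(pd.Timestamp(rec.time))
        values.append(integrate_column(chl, z, z_limit))
    return np.array(times, dtype=object), np.asarray(values, dtype=float)
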