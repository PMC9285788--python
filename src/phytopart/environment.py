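"""Per-profile optical and physical context.

Derives, for each float cycle, the scalars the partitioning model needs:
the diffuse attenuation coefficient Kd (Beer-Lambert fit to PAR, with an
empirical chlorophyll fallback), the euphotic depth Z_p = 4.6/Kd, surface
chlorophyll and backscattering (medians over the first optical depth),
daily PAR from a sinusoidal light cycle, potential density and the
Brunt-Väisälä buoyancy frequency N², a stratification index (mean N²
above 6.9 optical depths), and the mixed-layer depth Z_m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import seawater
from .config import EnvironmentConfig
from .profiles import ProfileRecord

__all__ = [
    "OpticalContext",
    "KdFitError",
    "NightProfileError",
    "fit_kd",
    "kd_from_chl",
    "euphotic_depth",
    "optical_depth",
    "daily_par",
    "density_profile",
    "brunt_vaisala",
    "stratification_index",
    "mixed_layer_depth",
    "MLDResult",
    "mean_light",
    "compute_context",
]

GRAVITY = 9.81  # m s^-2


class KdFitError(ValueError):
    """Raised when the Beer-Lambert Kd fit has too few usable points or a
    non-positive slope; callers fall back to the empirical relation."""


class NightProfileError(ValueError):
    """Raised for PAR measurements outside local sunrise-sunset."""


@dataclass
class OpticalContext:
    """Derived per-profile scalars used throughout the pipeline."""

    kd: float                 # m^-1
    kd_source: str            # "fitted" | "empirical"
    b_s: float                # mg m^-3, median chl over first optical depth
    b_s10: float              # mg m^-3, mean chl over top 10 m
    b_bp_s: float             # m^-1, median bbp over first optical depth
    z_p: float                # m, euphotic depth = 4.6/kd
    z_m: float                # m, mixed-layer depth
    strat_index: float        # s^-2, mean N² above τ = 6.9
    fully_mixed: bool = False
    par_daily_surface: float | None = None  # mol quanta m^-2 d^-1
    par_ml: float | None = None             # mean daily PAR in mixed layer
    par_below_ml: float | None = None       # between Z_m and Z_p


def fit_kd(depth, par, max_depth: float = 100.0) -> float:
    """Diffuse attenuation coefficient from a Beer-Lambert (log-linear)
    least-squares fit of PAR against depth in the top ``max_depth`` m.

    Raises :class:`KdFitError` with fewer than 4 positive PAR samples above
    ``max_depth`` or when the fitted Kd is not positive.
    """
    depth = np.asarray(depth, dtype=float)
    par = np.asarray(par, dtype=float)
    ok = np.isfinite(depth) & np.isfinite(par) & (par > 0) & (depth <= max_depth)
    if ok.sum() < 4:
        raise KdFitError(f"only {int(ok.sum())} usable PAR samples above {max_depth} m (need 4)")
    slope = stats.linregress(depth[ok], np.log(par[ok])).slope
    kd = -slope
    if kd <= 0:
        raise KdFitError(f"non-positive Kd from PAR fit ({kd:.4g} m^-1)")
    return float(kd)


def kd_from_chl(b_s10: float, slope: float = 0.036, intercept: float = 0.049) -> float:
    """Empirical fallback Kd = 0.036·B_s10 + 0.049 (from the float's own
    PAR-derived Kd regressed on mean chl in the top 10 m)."""
    if not np.isfinite(b_s10) or b_s10 < 0:
        raise ValueError(f"B_s10 must be non-negative, got {b_s10}")
    return slope * b_s10 + intercept


def euphotic_depth(kd: float) -> float:
    """Z_p = 4.6/Kd, the 1% light depth."""
    if kd <= 0:
        raise ValueError(f"Kd must be positive, got {kd}")
    return 4.6 / kd


def optical_depth(z, kd: float):
    """Dimensionless optical depth τ = z·Kd."""
    if kd <= 0:
        raise ValueError(f"Kd must be positive, got {kd}")
    z = np.asarray(z, dtype=float)
    out = z * kd
    return out if out.ndim else float(out)


def _solar_geometry(time_utc, latitude: float, longitude: float):
    """(day length D in hours, hours since local sunrise)."""
    t = pd.Timestamp(time_utc)
    doy = t.dayofyear
    decl = np.deg2rad(23.45) * np.sin(2 * np.pi * (284 + doy) / 365.0)
    phi = np.deg2rad(latitude)
    cos_h0 = -np.tan(phi) * np.tan(decl)
    cos_h0 = np.clip(cos_h0, -1.0, 1.0)
    h0 = np.arccos(cos_h0)               # sunrise hour angle, radians
    day_length = 24.0 * h0 / np.pi       # hours
    local_solar = (t.hour + t.minute / 60 + t.second / 3600 + longitude / 15.0) % 24.0
    since_sunrise = local_solar - (12.0 - day_length / 2.0)
    return day_length, since_sunrise


def daily_par(
    par_instant: float, time_utc, latitude: float, longitude: float = 0.0
) -> float:
    """Daily PAR integral (mol quanta m^-2 d^-1) from one instantaneous
    measurement (µmol quanta m^-2 s^-1), assuming a sinusoidal light cycle.

    The day length D follows from solar declination and latitude; the noon
    amplitude is inferred from the sinusoid at the measurement's
    time-since-sunrise; the daily integral is (2D/π)·E_noon.  Measurements
    outside sunrise-sunset raise :class:`NightProfileError` (such profiles'
    PAR is disregarded).
    """
    day_length, since_sunrise = _solar_geometry(time_utc, latitude, longitude)
    if day_length <= 0 or not (0.0 < since_sunrise < day_length):
        raise NightProfileError(
            f"measurement {since_sunrise:.2f} h after sunrise is outside the "
            f"{day_length:.2f} h day"
        )
    e_noon = par_instant / np.sin(np.pi * since_sunrise / day_length)
    integral_umol = (2.0 * day_length * 3600.0 / np.pi) * e_noon  # µmol m^-2 d^-1
    return integral_umol * 1e-6


def density_profile(temperature, salinity, pressure):
    """In-situ EOS-80 density (kg m^-3); out-of-range T/S masked with a warning."""
    t = np.asarray(temperature, dtype=float)
    s = np.asarray(salinity, dtype=float)
    p = np.asarray(pressure, dtype=float)
    bad = (s < 0) | (s > 45) | (t < -2.5) | (t > 45)
    bad &= np.isfinite(s) & np.isfinite(t)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} T/S samples outside EOS-80 range; masked",
                      stacklevel=2)
    rho = np.asarray(seawater.density(s, t, p), dtype=float)
    rho[bad] = np.nan
    return rho


def brunt_vaisala(density, depth):
    """Brunt-Väisälä buoyancy frequency N² (s^-2) at layer midpoints.

    N² = (g/ρ̄)·Δρ/Δz with z positive downward, from adjacent differences
    of (potential) density.  Returns ``(z_mid, n2)``.
    """
    rho = np.asarray(density, dtype=float)
    z = np.asarray(depth, dtype=float)
    if z.size < 2:
        raise ValueError("need at least 2 depths for N²")
    dz = np.diff(z)
    drho = np.diff(rho)
    rho_mid = 0.5 * (rho[1:] + rho[:-1])
    n2 = GRAVITY / rho_mid * drho / dz
    z_mid = 0.5 * (z[1:] + z[:-1])
    return z_mid, n2


def stratification_index(n2, tau, tau_limit: float = 6.9) -> float:
    """Depth-weighted (trapezoid) mean of N² over optical depths τ ≤ τ_limit.

    ``n2`` and ``tau`` are aligned arrays (typically at layer midpoints);
    the profile is linearly interpolated to the τ_limit endpoint when it
    extends beyond it.
    """
    tau = np.asarray(tau, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    ok = np.isfinite(tau) & np.isfinite(n2)
    tau, n2 = tau[ok], n2[ok]
    if tau.size == 0 or tau.min() > tau_limit:
        raise ValueError("no N² samples above the τ limit")
    inside = tau <= tau_limit
    t_in, n_in = tau[inside], n2[inside]
    if t_in.max() < tau_limit and (~inside).any():
        n_end = np.interp(tau_limit, tau, n2)
        t_in = np.append(t_in, tau_limit)
        n_in = np.append(n_in, n_end)
    if t_in.size == 1:
        return float(n_in[0])
    return float(np.trapezoid(n_in, t_in) / (t_in[-1] - t_in[0]))


@dataclass
class MLDResult:
    """Mixed-layer depth with provenance flags."""

    zm: float
    method: str
    fully_mixed: bool = False

    def __float__(self) -> float:
        return float(self.zm)


def _threshold_mld(temperature, depth, threshold: float) -> MLDResult:
    t_ref = np.interp(10.0, depth, temperature)
    below = depth >= 10.0
    dt = np.abs(temperature - t_ref)
    idx = np.nonzero(below & (dt >= threshold))[0]
    if idx.size == 0:
        return MLDResult(float(depth[-1]), "threshold", fully_mixed=True)
    i = idx[0]
    if i == 0:
        return MLDResult(float(depth[0]), "threshold")
    # interpolate to the exact |ΔT| = threshold crossing
    z = np.interp(threshold, [dt[i - 1], dt[i]], [depth[i - 1], depth[i]])
    return MLDResult(float(z), "threshold")


def _fit_intersection_mld(temperature, depth) -> float | None:
    """Intersection of a surface mixed-layer line and a thermocline line,
    the core construction of the Holte-Talley temperature algorithm."""
    n = depth.size
    if n < 4:
        return None
    # mixed-layer line: fit over the near-surface points (down to ~10 m)
    k = max(2, int(np.searchsorted(depth, max(10.0, depth[0] + 1e-9))) + 1)
    k = min(k, n - 2)
    ml_fit = np.polyfit(depth[:k], temperature[:k], 1)
    # thermocline line: through the steepest adjacent-difference segment,
    # which stays local even for a sharp two-layer step
    dz = np.diff(depth)
    grad = np.diff(temperature) / dz
    j = int(np.argmax(np.abs(grad)))
    tc_fit = np.polyfit(depth[j : j + 2], temperature[j : j + 2], 1)
    denom = ml_fit[0] - tc_fit[0]
    if denom == 0:
        return None
    z = (tc_fit[1] - ml_fit[1]) / denom
    if not (depth[0] <= z <= depth[-1]):
        return None
    return float(z)


def mixed_layer_depth(
    temperature,
    depth,
    salinity=None,
    method: str = "holte_talley_temp",
    threshold: float = 0.2,
) -> MLDResult:
    """Mixed-layer depth from the temperature profile.

    ``method="holte_talley_temp"`` follows the Holte-Talley temperature
    algorithm's construction: candidate depths from (a) the ΔT threshold
    from the 10 m reference, (b) the maximum-gradient location, and (c) the
    intersection of a fitted mixed-layer line with a fitted thermocline
    line; the fit intersection is preferred when it agrees with the
    threshold estimate (within 25%), otherwise the threshold depth is used.
    ``method="threshold"`` uses (a) alone.  A profile never exceeding the
    ΔT criterion is flagged fully mixed with Z_m at the deepest sample.
    """
    t = np.asarray(temperature, dtype=float)
    z = np.asarray(depth, dtype=float)
    ok = np.isfinite(t) & np.isfinite(z)
    t, z = t[ok], z[ok]
    if z.size < 2 or z.max() < 10.0:
        raise ValueError("profile must reach below 10 m for MLD")
    thr = _threshold_mld(t, z, threshold)
    if method == "threshold":
        return thr
    if method != "holte_talley_temp":
        raise ValueError(f"unknown MLD method {method!r}")
    if thr.fully_mixed:
        return MLDResult(thr.zm, "holte_talley_temp", fully_mixed=True)
    z_fit = _fit_intersection_mld(t, z)
    grad = np.diff(t) / np.diff(z)
    jg = int(np.argmax(np.abs(grad)))
    z_grad = float(0.5 * (z[jg] + z[jg + 1]))
    candidates = [c for c in (z_fit, z_grad) if c is not None]
    for cand in candidates:
        if abs(cand - thr.zm) <= 0.25 * thr.zm:
            return MLDResult(cand, "holte_talley_temp")
    return MLDResult(thr.zm, "holte_talley_temp")


def mean_light(par_daily_surface: float, kd: float, z_top: float, z_bottom: float) -> float:
    """Layer-mean daily PAR from the Beer-Lambert profile,
    PAR(0)·(e^{-Kd·z_top} − e^{-Kd·z_bottom}) / (Kd·(z_bottom − z_top))."""
    if kd <= 0:
        raise ValueError(f"Kd must be positive, got {kd}")
    if z_bottom < z_top or z_top < 0:
        raise ValueError("layer must satisfy 0 <= z_top <= z_bottom")
    if z_bottom == z_top:
        return float(par_daily_surface * np.exp(-kd * z_top))
    return float(
        par_daily_surface
        * (np.exp(-kd * z_top) - np.exp(-kd * z_bottom))
        / (kd * (z_bottom - z_top))
    )


def _surface_median(values, tau, chl_floor: float | None = None) -> float:
    ok = np.isfinite(values) & np.isfinite(tau) & (tau <= 1.0)
    if chl_floor is not None:
        ok &= values >= chl_floor
    if not ok.any():
        return np.nan
    return float(np.median(values[ok]))


def compute_context(record: ProfileRecord, config: EnvironmentConfig | None = None) -> OpticalContext:
    """Derive the full :class:`OpticalContext` for one profile.

    Kd comes from the PAR Beer-Lambert fit when a usable daytime PAR
    profile exists, otherwise from the empirical chlorophyll relation.
    """
    cfg = config or EnvironmentConfig()
    chl_ok = np.isfinite(record.chl)
    top10 = chl_ok & (record.depth <= 10.0)
    b_s10 = float(np.mean(record.chl[top10])) if top10.any() else np.nan

    kd = None
    kd_source = "empirical"
    par_daily = None
    if record.par is not None:
        try:
            par_daily = daily_par(
                float(np.nanmax(record.par[record.depth <= 5.0]))
                if (record.depth <= 5.0).any() else float(np.nanmax(record.par)),
                record.time, record.latitude, record.longitude,
            )
            kd = fit_kd(record.depth, record.par, cfg.kd_fit_max_depth)
            kd_source = "fitted"
        except (NightProfileError, KdFitError, ValueError):
            kd = None
            par_daily = None
    if kd is None:
        if not np.isfinite(b_s10):
            raise ValueError(
                f"cycle {record.cycle_id}: no PAR-based Kd and no top-10 m chl "
                "for the empirical fallback"
            )
        kd = kd_from_chl(b_s10, cfg.empirical_kd_slope, cfg.empirical_kd_intercept)

    z_p = euphotic_depth(kd)
    tau = optical_depth(record.depth, kd)
    b_s = _surface_median(record.chl, tau, chl_floor=0.01)
    b_bp_s = _surface_median(record.bbp700, tau)

    mld = mixed_layer_depth(
        record.temperature, record.depth, record.salinity,
        method=cfg.mld_method, threshold=cfg.mld_threshold,
    )

    rho_pot = seawater.potential_density(record.salinity, record.temperature, record.pressure)
    z_mid, n2 = brunt_vaisala(rho_pot, record.depth)
    tau_mid = optical_depth(z_mid, kd)
    try:
        strat = stratification_index(n2, tau_mid, cfg.strat_tau_limit)
    except ValueError:
        strat = np.nan

    par_ml = par_below = None
    if par_daily is not None:
        par_ml = mean_light(par_daily, kd, 0.0, mld.zm)
        if z_p > mld.zm:
            par_below = mean_light(par_daily, kd, mld.zm, z_p)
    return OpticalContext(
        kd=kd,
        kd_source=kd_source,
        b_s=b_s,
        b_s10=b_s10,
        b_bp_s=b_bp_s,
        z_p=z_p,
        z_m=mld.zm,
        strat_index=strat,
        fully_mixed=mld.fully_mixed,
        par_daily_surface=par_daily,
        par_ml=par_ml,
        par_below_ml=par_below,
    )
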