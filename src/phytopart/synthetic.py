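"""Synthetic float profiles and seasonal series with known ground truth.

The generator forward-evaluates the two-community model (sigmoid +
Gaussian chlorophyll, community-scaled backscattering with a constant
background, Beer-Lambert PAR) onto a depth grid, adds multiplicative
Gaussian noise, and wraps the result in the same :class:`ProfileRecord`
the readers produce — so every fitting module can be exercised end to
end without any download, and recovered parameters can be compared with
the embedded truth.

The default :class:`ScenarioSpec` emulates a subtropical seasonal cycle
of the kind seen in the northern Red Sea: deep winter mixed layers with
elevated, vertically uniform chlorophyll (community 1 blooming roughly
November-March), and summer stratification with a shallow mixed layer
and a deep chlorophyll maximum near 100 m (community 2 active roughly
mid-April to mid-October).  Surface chlorophyll spans ~0.08-0.5 mg m^-3,
Kd follows the empirical chlorophyll relation, and surface b_bp is
1.75e-3 m^-1 with a background fraction of 0.2 (so the background
coefficient is 3.5e-4 m^-1, a realistic non-algal level for clear
subtropical water).  Relative noise defaults to 5% on chl, b_bp and PAR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chl import community1, community2
from .config import ChlFitConfig
from .environment import _solar_geometry
from .profiles import ProfileRecord
from .seawater import depth_from_pressure

__all__ = ["ScenarioSpec", "make_profile", "make_seasonal_series"]


def _pressure_from_depth(depth, latitude):
    """Invert the UNESCO depth formula by fixed-point iteration."""
    depth = np.asarray(depth, dtype=float)
    p = depth * 1.01
    for _ in range(3):
        z = depth_from_pressure(p, latitude)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(z > 0, p * depth / z, depth * 1.01)
    return p


def _smooth_box(doy: float, start: float, end: float, ramp: float = 15.0) -> float:
    """Smooth 0..1 boxcar over day-of-year with wraparound and cosine ramps."""
    length = (end - start) % 365.0
    x = (doy - start) % 365.0
    if x > length:
        return 0.0
    edge = min(x, length - x)
    if edge >= ramp:
        return 1.0
    return 0.5 * (1.0 - np.cos(np.pi * edge / ramp))


@dataclass
class ScenarioSpec:
    """Seasonal float-like scenario with embedded ground truth."""

    start: str = "2015-07-01"
    end: str = "2017-01-01"
    cadence_days: int = 5
    latitude: float = 25.0
    longitude: float = 35.5
    #: mixed-layer depth (m): deep in winter, shallow in summer
    zm_winter: float = 180.0
    zm_summer: float = 20.0
    #: winter mixing window (day-of-year, wraparound) controlling Z_m and B_s
    mixing_start_doy: float = 305.0   # ~1 Nov
    mixing_end_doy: float = 91.0      # ~1 Apr
    #: surface chlorophyll (mg m^-3)
    bs_winter: float = 0.5
    bs_summer: float = 0.08
    #: community-2 activity window and Gaussian parameters
    c2_start_doy: float = 105.0       # ~15 Apr
    c2_end_doy: float = 288.0         # ~15 Oct
    b2m_star_peak: float = 3.0
    dcm_depth: float = 100.0          # m
    dcm_width: float = 25.0           # m (Gaussian e-folding half-width)
    #: backscattering partition
    omega2: float = 0.3
    bbpk_star: float = 0.2
    b_bp_s: float = 0.00175           # m^-1
    #: hydrography
    t_deep: float = 21.7
    t_surf_winter: float = 24.0
    t_surf_summer: float = 30.0
    s_surf: float = 39.5
    s_deep: float = 40.6
    #: light
    noon_par_winter: float = 1200.0   # µmol quanta m^-2 s^-1
    noon_par_summer: float = 2000.0
    profile_hour_local: float = 10.0
    #: multiplicative noise (relative σ)
    noise_chl: float = 0.05
    noise_bbp: float = 0.05
    noise_par: float = 0.05
    ramp_days: float = 20.0
    depth_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 301.0, 1.0)
    )
    seed: int = 42
    #: empirical-relation coefficients used to link τ1, P1 to Z_m·Kd
    chl_config: ChlFitConfig = field(default_factory=ChlFitConfig)


def make_profile(
    params: dict,
    kd: float,
    b_s: float,
    b_bp_s: float,
    *,
    time,
    latitude: float = 25.0,
    longitude: float = 35.5,
    cycle_id: int = 0,
    depth=None,
    zm: float = 50.0,
    t_surf: float = 26.0,
    t_deep: float = 21.7,
    s_surf: float = 39.5,
    s_deep: float = 40.6,
    noon_par: float = 1500.0,
    noise_chl: float = 0.05,
    noise_bbp: float = 0.05,
    noise_par: float = 0.05,
    rng: np.random.Generator | None = None,
) -> ProfileRecord:
    """Forward-evaluate the model into one profile record.

    ``params`` holds the dimensionless truth: ``mode``, ``p1``, ``tau1``,
    and for two-community profiles ``b2m_star``, ``tau2``, ``sigma``,
    plus ``omega2`` and ``bbpk_star`` for backscattering.  The truth is
    embedded in ``record.metadata["truth"]``.  Inadmissible parameters
    (P1 outside [4.6, 100], τ2 < 3σ) raise ValueError.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    p1, tau1 = params["p1"], params["tau1"]
    if not (4.6 <= p1 <= 100.0):
        raise ValueError(f"P1={p1} outside the admissible box [4.6, 100]")
    if tau1 <= 0:
        raise ValueError("tau1 must be positive")
    mode = params.get("mode", "two_community")
    depth = np.arange(0.0, 301.0, 1.0) if depth is None else np.asarray(depth, float)
    tau = depth * kd
    b_star = community1(tau, p1, tau1)
    b2 = np.zeros_like(tau)
    if mode == "two_community":
        b2m, tau2, sigma = params["b2m_star"], params["tau2"], params["sigma"]
        if not (0.0 <= b2m <= 100.0) or sigma <= 0 or tau2 < 3.0 * sigma - 1e-12:
            raise ValueError("community-2 parameters outside the admissible box")
        b2 = community2(tau, b2m, tau2, sigma)
    b_star = b_star + b2
    chl = b_s * b_star * (1.0 + noise_chl * rng.standard_normal(depth.size))
    chl = np.clip(chl, 1e-6, None)

    omega2 = params.get("omega2", 0.3)
    bbpk_star = params.get("bbpk_star", 0.2)
    bbp1B = (1.0 - bbpk_star) * b_bp_s / b_s
    bbp2B = omega2 * b_bp_s / b_s
    bbpk = bbpk_star * b_bp_s
    b1_phys = b_s * community1(tau, p1, tau1)
    b2_phys = b_s * b2
    bbp = bbp1B * b1_phys + bbp2B * b2_phys + bbpk
    bbp = bbp * (1.0 + noise_bbp * rng.standard_normal(depth.size))
    bbp = np.clip(bbp, 1e-8, None)

    day_length, since_sunrise = _solar_geometry(time, latitude, longitude)
    par = None
    if 0.0 < since_sunrise < day_length:
        e0 = noon_par * np.sin(np.pi * since_sunrise / day_length)
        par = e0 * np.exp(-kd * depth) * np.exp(
            noise_par * rng.standard_normal(depth.size)
        )

    w = 2.0  # m, thermocline transition half-width
    trans = 1.0 / (1.0 + np.exp((depth - zm) / w))
    temperature = t_deep + (t_surf - t_deep) * trans
    salinity = s_deep + (s_surf - s_deep) * trans
    truth = dict(params)
    truth.update(kd=kd, b_s=b_s, b_bp_s=b_bp_s, zm=zm, mode=mode,
                 bbp1B=bbp1B, bbp2B=bbp2B if mode == "two_community" else None,
                 bbpk=bbpk, noon_par=noon_par)
    return ProfileRecord(
        cycle_id=cycle_id,
        time=np.datetime64(pd.Timestamp(time).to_datetime64()),
        latitude=latitude,
        longitude=longitude,
        depth=depth,
        pressure=_pressure_from_depth(depth, latitude),
        temperature=temperature,
        salinity=salinity,
        chl=chl,
        bbp700=bbp,
        par=par,
        metadata={"truth": truth},
    )


def scenario_truth_at(spec: ScenarioSpec, time) -> dict:
    """Ground-truth scenario state (parameters and context) for one date."""
    t = pd.Timestamp(time)
    doy = float(t.dayofyear)
    mix = _smooth_box(doy, spec.mixing_start_doy, spec.mixing_end_doy, spec.ramp_days)
    b_s = spec.bs_summer + (spec.bs_winter - spec.bs_summer) * mix
    zm = spec.zm_summer + (spec.zm_winter - spec.zm_summer) * mix
    cfg = spec.chl_config
    # surface chl is vertically uniform near the top, so B_s ≈ B_s10 and the
    # empirical Kd(chl) relation keeps the scenario optically self-consistent
    kd = 0.036 * b_s + 0.049
    zm_kd = zm * kd
    tau1 = cfg.emp_tau1_slope * zm_kd + cfg.emp_tau1_intercept
    p1 = float(np.clip(10.0 ** (cfg.emp_logp1_slope * tau1 + cfg.emp_logp1_intercept),
                       *cfg.p1_bounds))
    c2 = _smooth_box(doy, spec.c2_start_doy, spec.c2_end_doy, spec.ramp_days)
    b2m = spec.b2m_star_peak * c2
    params: dict = {"p1": p1, "tau1": tau1,
                    "omega2": spec.omega2, "bbpk_star": spec.bbpk_star}
    if b2m > 0.05:
        tau2 = spec.dcm_depth * kd
        sigma = min(spec.dcm_width * kd, tau2 / 3.0)
        params.update(mode="two_community", b2m_star=b2m, tau2=tau2, sigma=sigma)
    else:
        params["mode"] = "one_community"
    # annual temperature cycle: coldest surface in winter, warmest in August
    warm = _smooth_box(doy, 135.0, 288.0, 45.0)
    t_surf = spec.t_surf_winter + (spec.t_surf_summer - spec.t_surf_winter) * warm
    noon = spec.noon_par_winter + (spec.noon_par_summer - spec.noon_par_winter) * warm
    return {"params": params, "kd": kd, "b_s": b_s, "zm": zm,
            "t_surf": t_surf, "noon_par": noon}


def make_seasonal_series(spec: ScenarioSpec | None = None) -> list[ProfileRecord]:
    """Generate the full seasonal sequence of profile records.

    Deterministic for a fixed ``spec.seed``: the same spec yields
    byte-identical arrays.
    """
    spec = spec or ScenarioSpec()
    rng = np.random.default_rng(spec.seed)
    times = pd.date_range(spec.start, spec.end, freq=f"{spec.cadence_days}D")
    records = []
    for i, t in enumerate(times):
        state = scenario_truth_at(spec, t)
        t_obs = t + pd.Timedelta(
            hours=spec.profile_hour_local - spec.longitude / 15.0
        )
        rec = make_profile(
            state["params"], state["kd"], state["b_s"], spec.b_bp_s,
            time=t_obs, latitude=spec.latitude, longitude=spec.longitude,
            cycle_id=i + 1, depth=spec.depth_grid.copy(),
            zm=state["zm"], t_surf=state["t_surf"], t_deep=spec.t_deep,
            s_surf=spec.s_surf, s_deep=spec.s_deep,
            noon_par=state["noon_par"],
            noise_chl=spec.noise_chl, noise_bbp=spec.noise_bbp,
            noise_par=spec.noise_par, rng=rng,
        )
        records.append(rec)
    return records
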