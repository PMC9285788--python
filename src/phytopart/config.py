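"""Configuration containers with the model's default constants.

Every empirically derived constant of the method (regression coefficients,
gates, bounds, filter windows) is surfaced here so it can be overridden
without touching code.  Defaults are the values the method was developed
with on the northern Red Sea float record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

__all__ = ["EnvironmentConfig", "ChlFitConfig", "BbpFitConfig", "PhenologyConfig", "Config"]


@dataclass
class EnvironmentConfig:
    #: maximum depth (m) of PAR samples entering the Beer-Lambert Kd fit
    kd_fit_max_depth: float = 100.0
    #: empirical Kd(B_s10) fallback: Kd = slope * B_s10 + intercept
    empirical_kd_slope: float = 0.036
    empirical_kd_intercept: float = 0.049
    #: "holte_talley_temp" or "threshold"
    mld_method: str = "holte_talley_temp"
    #: ΔT (°C) from the 10 m reference for the threshold MLD method
    mld_threshold: float = 0.2
    #: stratification index averages N² above this optical depth (1.5 Z_p)
    strat_tau_limit: float = 6.9


@dataclass
class ChlFitConfig:
    #: step-1 variance-explained gate: r² above this means community 1 alone
    r2_gate: float = 0.9
    #: optical-depth truncation for fitting when Z_m·Kd is below it
    tau_fit_limit: float = 9.2
    #: minimum number of usable samples (N > 6)
    min_points: int = 7
    bootstrap_n: int = 1000
    #: fraction of failed bootstrap replicates above which the fit fails
    max_bootstrap_failures: float = 0.5
    p1_bounds: tuple = (4.6, 100.0)
    b2m_bounds: tuple = (0.0, 100.0)
    #: surface-median validity floor (mg m^-3)
    chl_floor: float = 0.01
    #: step-1 initial guess for P1 (τ1 starts at Z_m·Kd)
    p1_init: float = 9.0
    #: empirical relations used to fix P1, τ1 in step 2:
    #: τ1 = a·Z_m·Kd + b;  P1 = 10^(c·τ1 + d)
    emp_tau1_slope: float = 0.62
    emp_tau1_intercept: float = 2.29
    emp_logp1_slope: float = 0.08
    emp_logp1_intercept: float = 0.66
    #: bootstrap RNG seed (reproducible confidence intervals)
    seed: int = 20490


@dataclass
class BbpFitConfig:
    bbp_fit_max_depth: float = 500.0
    bbpk_star_bounds: tuple = (0.01, 0.95)
    omega2_lower: float = 0.01
    init_bbpk_star: float = 0.2
    init_omega2: float = 0.3
    despike_window: int = 11
    bootstrap_n: int = 1000
    max_bootstrap_failures: float = 0.5
    min_points: int = 7
    seed: int = 20491


@dataclass
class PhenologyConfig:
    #: Savitzky-Golay smoothing window (days) and polynomial order
    sg_window: int = 15
    sg_order: int = 2
    #: bloom threshold = threshold_factor × median of the series
    threshold_factor: float = 1.05
    #: "multiplicative" (factor × median) or "amplitude"
    #: (median + (factor-1) × series amplitude)
    threshold_mode: str = "multiplicative"
    #: gradient must keep its sign for more than this many days
    persistence_days: int = 15


@dataclass
class Config:
    """Bundle of all module configurations."""

    environment: EnvironmentConfig = field(default_factory=EnvironmentConfig)
    chl: ChlFitConfig = field(default_factory=ChlFitConfig)
    bbp: BbpFitConfig = field(default_factory=BbpFitConfig)
    phenology: PhenologyConfig = field(default_factory=PhenologyConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "Config":
        def build(klass, key):
            sub = dict(data.get(key, {}))
            for name in ("p1_bounds", "b2m_bounds", "bbpk_star_bounds"):
                if name in sub and isinstance(sub[name], list):
                    sub[name] = tuple(sub[name])
            return klass(**sub)

        return cls(
            environment=build(EnvironmentConfig, "environment"),
            chl=build(ChlFitConfig, "chl"),
            bbp=build(BbpFitConfig, "bbp"),
            phenology=build(PhenologyConfig, "phenology"),
        )
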