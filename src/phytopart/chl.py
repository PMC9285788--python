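"""Two-community decomposition of normalized chlorophyll-a profiles.

The chlorophyll-a profile, normalized by its surface value B_s and
expressed against optical depth τ = z·Kd, is modelled as the sum of two
phytoplankton communities:

* community 1 — a surface mixed-layer population described by a sigmoid
  B1*(τ) = 1 − 1/(1 + exp(−(P1/τ1)(τ − τ1))), which tends to 1 at the
  surface (enforced by P1 ≥ 4.6, so community 1 is >99% of the surface
  total) and to 0 at depth;
* community 2 — a deep-chlorophyll-maximum population described by a
  Gaussian B2*(τ) = B2m*·exp(−((τ − τ2)/σ)²), kept negligible at the
  surface by the constraint τ2 ≥ 3σ.

Tuning is a two-step process.  Step 1 fits the sigmoid alone; if it
explains more than 90% of the profile variance (squared Pearson r), the
profile is one-community.  Otherwise P1 and τ1 are fixed from empirical
relations in Z_m·Kd and the full five-parameter model is fitted for the
Gaussian parameters; the two-community model is retained only if its AIC
improves on step 1.  Parameter uncertainty comes from a case-resampling
bootstrap (median and 2.5/97.5 percentile intervals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .config import ChlFitConfig
from .environment import OpticalContext, optical_depth
from .profiles import ProfileRecord

__all__ = [
    "NormalizedProfile",
    "ChlPartitionResult",
    "ProfileSkipped",
    "FitFailure",
    "normalize_chl",
    "community1",
    "community2",
    "total_chl_star",
    "empirical_tau1",
    "empirical_p1",
    "fit_step1",
    "fit_step2",
    "partition_profile",
    "integrate_column",
]


class ProfileSkipped(ValueError):
    """Profile fails a fitting precondition (too few points, no surface
    samples); the pipeline logs and moves on."""


class FitFailure(RuntimeError):
    """Optimizer or bootstrap failure beyond the tolerated rate."""


@dataclass
class NormalizedProfile:
    """Dimensionless chlorophyll profile: B* = B/B_s against τ = z·Kd."""

    tau: np.ndarray
    b_star: np.ndarray
    b_s: float

    @property
    def n(self) -> int:
        return self.tau.size


@dataclass
class ChlPartitionResult:
    """Fitted two-community (or one-community) chlorophyll model."""

    mode: str                      # "one_community" | "two_community"
    p1: float
    tau1: float
    b2m_star: float | None
    tau2: float | None
    sigma: float | None
    ci: dict = field(default_factory=dict)   # param -> (2.5%, 97.5%)
    r2_step1: float = np.nan
    aic_step1: float = np.nan
    aic_step2: float = np.nan
    n_points: int = 0
    b_s: float = np.nan
    kd: float = np.nan
    cycle_id: int | None = None
    medians_reprojected: bool = False

    @property
    def s1(self) -> float:
        """Sigmoid slope S1 = P1/τ1."""
        return self.p1 / self.tau1

    def evaluate(self, tau) -> np.ndarray:
        """Total B*(τ) under the selected mode."""
        params = {"p1": self.p1, "tau1": self.tau1}
        if self.mode == "two_community":
            params.update(b2m_star=self.b2m_star, tau2=self.tau2, sigma=self.sigma)
        return total_chl_star(tau, params, self.mode)

    def community_profile(self, depth, community: int) -> np.ndarray:
        """Community chlorophyll in mg m^-3 on a depth grid (τ = z·Kd,
        rescaled by B_s)."""
        tau = optical_depth(depth, self.kd)
        if community == 1:
            return self.b_s * community1(tau, self.p1, self.tau1)
        if community == 2:
            if self.mode != "two_community":
                return np.zeros_like(np.asarray(tau, dtype=float))
            return self.b_s * community2(tau, self.b2m_star, self.tau2, self.sigma)
        raise ValueError(f"community must be 1 or 2, got {community}")


def community1(tau, p1: float, tau1: float):
    """Sigmoid community-1 profile, B1*(τ) = 1 − 1/(1+exp(−(P1/τ1)(τ−τ1)))."""
    if tau1 <= 0:
        raise ValueError(f"tau1 must be positive, got {tau1}")
    tau = np.asarray(tau, dtype=float)
    out = 1.0 - stats.logistic.cdf((p1 / tau1) * (tau - tau1))
    return out if out.ndim else float(out)


def community2(tau, b2m_star: float, tau2: float, sigma: float):
    """Gaussian community-2 profile, B2*(τ) = B2m*·exp(−((τ−τ2)/σ)²)."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if b2m_star < 0:
        raise ValueError(f"b2m_star must be non-negative, got {b2m_star}")
    tau = np.asarray(tau, dtype=float)
    out = b2m_star * np.exp(-(((tau - tau2) / sigma) ** 2))
    return out if out.ndim else float(out)


def total_chl_star(tau, params: dict, mode: str = "two_community"):
    """Total B*(τ): community 1 plus, in two-community mode, community 2."""
    out = community1(tau, params["p1"], params["tau1"])
    if mode == "two_community":
        out = out + community2(tau, params["b2m_star"], params["tau2"], params["sigma"])
    elif mode != "one_community":
        raise ValueError(f"unknown mode {mode!r}")
    return out


def normalize_chl(
    profile: ProfileRecord,
    context: OpticalContext,
    config: ChlFitConfig | None = None,
) -> NormalizedProfile:
    """Normalize a chlorophyll profile for fitting.

    B_s is the median chlorophyll over the first optical depth after
    removing unrealistically low values (< 0.01 mg m^-3).  When
    Z_m·Kd < 9.2 the fitted data are truncated to τ < 9.2 (twice the
    euphotic depth); otherwise the full profile is kept.  Profiles with
    no valid surface sample or N ≤ 6 raise :class:`ProfileSkipped`.
    """
    cfg = config or ChlFitConfig()
    tau = optical_depth(profile.depth, context.kd)
    chl = profile.chl
    surf = np.isfinite(chl) & (tau <= 1.0) & (chl >= cfg.chl_floor)
    if not surf.any():
        raise ProfileSkipped(
            f"cycle {profile.cycle_id}: no valid chl sample in the first optical depth"
        )
    b_s = float(np.median(chl[surf]))
    keep = np.isfinite(chl) & (chl > 0)
    if context.z_m * context.kd < cfg.tau_fit_limit:
        keep &= tau < cfg.tau_fit_limit
    if keep.sum() < cfg.min_points:
        raise ProfileSkipped(
            f"cycle {profile.cycle_id}: {int(keep.sum())} usable samples "
            f"(need > {cfg.min_points - 1})"
        )
    return NormalizedProfile(tau=tau[keep], b_star=chl[keep] / b_s, b_s=b_s)


def empirical_tau1(zm_kd: float, config: ChlFitConfig | None = None) -> float:
    """Empirical mid-point relation τ1 = 0.62·Z_m·Kd + 2.29, derived from
    one-community fits in mixed waters (Z_p < Z_m)."""
    cfg = config or ChlFitConfig()
    if zm_kd < 0:
        raise ValueError(f"Z_m·Kd must be non-negative, got {zm_kd}")
    return cfg.emp_tau1_slope * zm_kd + cfg.emp_tau1_intercept


def empirical_p1(tau1: float, config: ChlFitConfig | None = None) -> float:
    """Empirical slope relation P1 = 10^(0.08·τ1 + 0.66), clipped to the
    admissible P1 box."""
    cfg = config or ChlFitConfig()
    p1 = 10.0 ** (cfg.emp_logp1_slope * tau1 + cfg.emp_logp1_intercept)
    return float(np.clip(p1, *cfg.p1_bounds))


def _r_squared(observed, fitted) -> float:
    if np.std(observed) == 0 or np.std(fitted) == 0:
        return 0.0
    return float(np.corrcoef(observed, fitted)[0, 1] ** 2)


def _aic(rss: float, n: int, k: int) -> float:
    """Least-squares AIC, n·ln(RSS/n) + 2k."""
    return n * np.log(max(rss, 1e-300) / n) + 2 * k


def _bootstrap(fit_once, tau, b_star, n_boot, max_fail, rng, param_names):
    """Case-resampling bootstrap: refit on resampled (τ, B*) pairs and
    return {param: samples}.  Replicates whose fit fails are dropped;
    exceeding the failure budget raises :class:`FitFailure`."""
    n = tau.size
    samples = {p: [] for p in param_names}
    failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            est = fit_once(tau[idx], b_star[idx])
        except Exception:
            failed += 1
            continue
        for p in param_names:
            samples[p].append(est[p])
    if n_boot and failed > max_fail * n_boot:
        raise FitFailure(f"{failed}/{n_boot} bootstrap replicates failed")
    return {p: np.asarray(v) for p, v in samples.items()}


def _summarize(samples: dict) -> tuple[dict, dict]:
    med = {p: float(np.median(v)) for p, v in samples.items()}
    ci = {
        p: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
        for p, v in samples.items()
    }
    return med, ci


@dataclass
class StepFit:
    """One fitting step: point estimates, bootstrap medians, diagnostics."""

    params: dict            # direct full-data fit
    medians: dict           # bootstrap medians (== params when bootstrap_n=0)
    ci: dict
    r2: float
    aic: float
    rss: float
    n: int


def fit_step1(
    norm: NormalizedProfile,
    context: OpticalContext,
    config: ChlFitConfig | None = None,
    rng: np.random.Generator | None = None,
) -> StepFit:
    """Step 1: bounded least squares of the sigmoid-only model.

    Initial guess τ1 = Z_m·Kd, P1 = 9; P1 bounded to [4.6, 100], τ1 ≥ 0.
    """
    cfg = config or ChlFitConfig()
    if norm.n < cfg.min_points:
        raise ProfileSkipped(f"{norm.n} points (need > {cfg.min_points - 1})")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    tau1_init = float(np.clip(context.z_m * context.kd, 0.05, np.nanmax(norm.tau)))
    x0 = np.array([cfg.p1_init, tau1_init])
    lo = np.array([cfg.p1_bounds[0], 1e-6])
    hi = np.array([cfg.p1_bounds[1], np.inf])

    def fit_once(tau, b_star):
        res = optimize.least_squares(
            lambda x: community1(tau, x[0], x[1]) - b_star,
            x0, bounds=(lo, hi), xtol=1e-8, ftol=1e-8,
        )
        if not res.success:
            raise FitFailure(res.message)
        return {"p1": res.x[0], "tau1": res.x[1], "_rss": float(2 * res.cost)}

    direct = fit_once(norm.tau, norm.b_star)
    fitted = community1(norm.tau, direct["p1"], direct["tau1"])
    r2 = _r_squared(norm.b_star, fitted)
    aic = _aic(direct["_rss"], norm.n, k=2)
    if cfg.bootstrap_n > 0:
        samples = _bootstrap(
            fit_once, norm.tau, norm.b_star, cfg.bootstrap_n,
            cfg.max_bootstrap_failures, rng, ("p1", "tau1"),
        )
        medians, ci = _summarize(samples)
    else:
        medians = {"p1": direct["p1"], "tau1": direct["tau1"]}
        ci = {}
    return StepFit(
        params={"p1": direct["p1"], "tau1": direct["tau1"]},
        medians=medians, ci=ci, r2=r2, aic=aic, rss=direct["_rss"], n=norm.n,
    )


def fit_step2(
    norm: NormalizedProfile,
    p1: float,
    tau1: float,
    config: ChlFitConfig | None = None,
    rng: np.random.Generator | None = None,
) -> StepFit:
    """Step 2: bounded least squares of the full model with P1, τ1 fixed.

    Free parameters are B2m* ∈ [0, 100], σ > 0 and τ2, with the surface-
    suppression constraint τ2 ≥ 3σ enforced exactly by the
    reparameterization τ2 = 3σ + δ, δ ≥ 0.
    """
    cfg = config or ChlFitConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    base = community1(norm.tau, p1, tau1)
    resid = norm.b_star - base
    j = int(np.argmax(resid))
    b2m0 = float(np.clip(resid[j], 0.1, cfg.b2m_bounds[1]))
    tau2_0 = float(max(norm.tau[j], 0.3))
    sigma0 = min(max(0.3, tau2_0 / 6.0), tau2_0 / 3.0)
    delta0 = max(tau2_0 - 3.0 * sigma0, 0.0)
    x0 = np.array([b2m0, sigma0, delta0])
    lo = np.array([cfg.b2m_bounds[0], 1e-6, 0.0])
    hi = np.array([cfg.b2m_bounds[1], np.inf, np.inf])

    def fit_once(tau, b_star):
        b1 = community1(tau, p1, tau1)
        res = optimize.least_squares(
            lambda x: b1 + community2(tau, x[0], 3.0 * x[1] + x[2], x[1]) - b_star,
            x0, bounds=(lo, hi), xtol=1e-8, ftol=1e-8,
        )
        if not res.success:
            raise FitFailure(res.message)
        b2m, sigma, delta = res.x
        return {
            "b2m_star": b2m, "sigma": sigma, "tau2": 3.0 * sigma + delta,
            "_rss": float(2 * res.cost),
        }

    direct = fit_once(norm.tau, norm.b_star)
    fitted = base + community2(norm.tau, direct["b2m_star"], direct["tau2"], direct["sigma"])
    r2 = _r_squared(norm.b_star, fitted)
    aic = _aic(direct["_rss"], norm.n, k=3)
    if cfg.bootstrap_n > 0:
        samples = _bootstrap(
            fit_once, norm.tau, norm.b_star, cfg.bootstrap_n,
            cfg.max_bootstrap_failures, rng, ("b2m_star", "tau2", "sigma"),
        )
        medians, ci = _summarize(samples)
    else:
        medians = {k: direct[k] for k in ("b2m_star", "tau2", "sigma")}
        ci = {}
    return StepFit(
        params={k: direct[k] for k in ("b2m_star", "tau2", "sigma")},
        medians=medians, ci=ci, r2=r2, aic=aic, rss=direct["_rss"], n=norm.n,
    )


def partition_profile(
    profile: ProfileRecord,
    context: OpticalContext,
    config: ChlFitConfig | None = None,
    rng: np.random.Generator | None = None,
) -> ChlPartitionResult:
    """Run the full two-step tuning on one profile.

    Step 1 first; r² > 0.9 selects the one-community model with the step-1
    parameters.  Otherwise P1 and τ1 are fixed from the empirical
    relations and step 2 fits the Gaussian; the two-community model is
    kept only when its AIC is lower than step 1's.
    """
    cfg = config or ChlFitConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    norm = normalize_chl(profile, context, cfg)
    step1 = fit_step1(norm, context, cfg, rng)
    base = dict(
        r2_step1=step1.r2, aic_step1=step1.aic, n_points=norm.n,
        b_s=norm.b_s, kd=context.kd, cycle_id=profile.cycle_id,
    )
    if step1.r2 > cfg.r2_gate:
        return ChlPartitionResult(
            mode="one_community",
            p1=step1.medians["p1"], tau1=step1.medians["tau1"],
            b2m_star=None, tau2=None, sigma=None, ci=step1.ci, **base,
        )
    zm_kd = context.z_m * context.kd
    tau1_fix = empirical_tau1(zm_kd, cfg)
    p1_fix = empirical_p1(tau1_fix, cfg)
    step2 = fit_step2(norm, p1_fix, tau1_fix, cfg, rng)
    if step2.aic < step1.aic:
        b2m = step2.medians["b2m_star"]
        tau2 = step2.medians["tau2"]
        sigma = step2.medians["sigma"]
        reproj = False
        # per-parameter medians can violate the joint constraint τ2 ≥ 3σ
        if tau2 < 3.0 * sigma:
            tau2 = 3.0 * sigma
            reproj = True
            warnings.warn(
                f"cycle {profile.cycle_id}: bootstrap medians violated τ2 ≥ 3σ; "
                "τ2 re-projected onto the constraint", stacklevel=2,
            )
        return ChlPartitionResult(
            mode="two_community", p1=p1_fix, tau1=tau1_fix,
            b2m_star=b2m, tau2=tau2, sigma=sigma, ci=step2.ci,
            aic_step2=step2.aic, medians_reprojected=reproj, **base,
        )
    return ChlPartitionResult(
        mode="one_community",
        p1=step1.medians["p1"], tau1=step1.medians["tau1"],
        b2m_star=None, tau2=None, sigma=None, ci=step1.ci,
        aic_step2=step2.aic, **base,
    )


def integrate_column(values, depth, z_limit: float) -> float:
    """Trapezoid column integral of a depth-resolved variable over
    [shallowest sample, z_limit], linearly interpolating to z_limit.

    z_limit above the shallowest sample is an error; a z_limit beyond the
    deepest sample integrates to the deepest sample.
    """
    z = np.asarray(depth, dtype=float)
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(z) & np.isfinite(v)
    z, v = z[ok], v[ok]
    if z.size < 2:
        raise ValueError("need at least 2 samples to integrate")
    if z_limit < z[0]:
        raise ValueError(f"z_limit {z_limit} m is above the shallowest sample {z[0]} m")
    if z_limit >= z[-1]:
        return float(np.trapezoid(v, z))
    inside = z <= z_limit
    z_in = np.append(z[inside], z_limit)
    v_in = np.append(v[inside], np.interp(z_limit, z, v))
    return float(np.trapezoid(v_in, z_in))
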