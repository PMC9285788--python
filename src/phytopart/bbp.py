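"""Extension of the two-community partition to particle backscattering.

The normalized backscattering profile b_bp*(τ) = b_bp/b_bp,s is modelled
as community contributions proportional to the fitted dimensionless
chlorophyll communities plus a constant non-algal background:

    b_bp*(τ) = (1 − b*_bp,k)·B1*(τ) + ω2·B2*(τ) + b*_bp,k

(one-community profiles drop the ω2 term).  The surface closure
ω1 + b*_bp,k = 1 is built in, so ω1 is never a free parameter.  From the
two fitted parameters (ω2, b*_bp,k), chlorophyll-specific backscattering
coefficients per community and the background coefficient in physical
units follow:

    b^B_bp,1 = (1 − b*_bp,k)·b_bp,s/B_s,   b^B_bp,2 = ω2·b_bp,s/B_s,
    b^k_bp   = b*_bp,k·b_bp,s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .chl import ChlPartitionResult, FitFailure, ProfileSkipped, _summarize, community1, community2
from .config import BbpFitConfig
from .environment import OpticalContext, optical_depth
from .profiles import ProfileRecord

__all__ = [
    "NormalizedBbpProfile",
    "BbpPartitionResult",
    "normalize_bbp",
    "fit_bbp",
    "derive_coefficients",
    "partition_bbp",
    "reconstruct_bbp",
    "despike_bbp",
]


@dataclass
class NormalizedBbpProfile:
    tau: np.ndarray
    bbp_star: np.ndarray
    b_bp_s: float

    @property
    def n(self) -> int:
        return self.tau.size


@dataclass
class BbpPartitionResult:
    """Fitted backscattering partition for one profile."""

    mode: str                      # inherited from the chl partition
    omega2: float | None           # absent in one-community mode
    bbpk_star: float
    bbp1B: float                   # m^-1 per mg m^-3, community 1
    bbp2B: float | None            # community 2
    bbpk: float                    # m^-1, non-algal background
    ci: dict = field(default_factory=dict)
    n_points: int = 0
    rss: float = np.nan
    cycle_id: int | None = None

    @property
    def omega1(self) -> float:
        """Surface closure: ω1 = 1 − b*_bp,k, exact by construction."""
        return 1.0 - self.bbpk_star


def normalize_bbp(
    profile: ProfileRecord,
    context: OpticalContext,
    config: BbpFitConfig | None = None,
) -> NormalizedBbpProfile:
    """Normalize a backscattering profile by its surface value.

    b_bp,s is the median b_bp over the first optical depth; only samples
    shallower than 500 m are used.  Profiles with no surface sample or
    N ≤ 6 raise :class:`ProfileSkipped`.
    """
    cfg = config or BbpFitConfig()
    tau = optical_depth(profile.depth, context.kd)
    bbp = profile.bbp700
    surf = np.isfinite(bbp) & (tau <= 1.0)
    if not surf.any():
        raise ProfileSkipped(
            f"cycle {profile.cycle_id}: no bbp sample in the first optical depth"
        )
    b_bp_s = float(np.median(bbp[surf]))
    if b_bp_s <= 0:
        raise ProfileSkipped(f"cycle {profile.cycle_id}: non-positive surface bbp")
    keep = np.isfinite(bbp) & (profile.depth < cfg.bbp_fit_max_depth)
    if keep.sum() < cfg.min_points:
        raise ProfileSkipped(
            f"cycle {profile.cycle_id}: {int(keep.sum())} usable bbp samples "
            f"(need > {cfg.min_points - 1})"
        )
    return NormalizedBbpProfile(tau=tau[keep], bbp_star=bbp[keep] / b_bp_s, b_bp_s=b_bp_s)


def fit_bbp(
    bbp_star,
    tau,
    b1_star,
    b2_star,
    mode: str,
    config: BbpFitConfig | None = None,
    rng: np.random.Generator | None = None,
):
    """Bounded least squares for (ω2, b*_bp,k) given the chlorophyll
    community shapes evaluated on the same τ grid.

    Initial guesses 0.3 / 0.2; both bounded below by 0.01 and b*_bp,k
    above by 0.95 (the background may not exceed 95% of surface b_bp).
    Returns ``(params, ci, rss)`` where params has keys ``omega2`` (absent
    in one-community mode) and ``bbpk_star``.
    """
    cfg = config or BbpFitConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    bbp_star = np.asarray(bbp_star, dtype=float)
    tau = np.asarray(tau, dtype=float)
    b1 = np.asarray(b1_star, dtype=float)
    b2 = np.asarray(b2_star, dtype=float) if mode == "two_community" else None

    if mode == "two_community":
        x0 = np.array([cfg.init_omega2, cfg.init_bbpk_star])
        lo = np.array([cfg.omega2_lower, cfg.bbpk_star_bounds[0]])
        hi = np.array([np.inf, cfg.bbpk_star_bounds[1]])
        names = ("omega2", "bbpk_star")

        def model(x, b1v, b2v):
            return (1.0 - x[1]) * b1v + x[0] * b2v + x[1]
    elif mode == "one_community":
        x0 = np.array([cfg.init_bbpk_star])
        lo = np.array([cfg.bbpk_star_bounds[0]])
        hi = np.array([cfg.bbpk_star_bounds[1]])
        names = ("bbpk_star",)

        def model(x, b1v, b2v):
            return (1.0 - x[0]) * b1v + x[0]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    def fit_once(idx_tau, idx_bbp, b1v=None, b2v=None):
        res = optimize.least_squares(
            lambda x: model(x, b1v, b2v) - idx_bbp,
            x0, bounds=(lo, hi), xtol=1e-10, ftol=1e-10,
        )
        if not res.success:
            raise FitFailure(res.message)
        out = dict(zip(names, res.x))
        out["_rss"] = float(2 * res.cost)
        return out

    direct = fit_once(tau, bbp_star, b1, b2)
    if cfg.bootstrap_n > 0:
        # resample indices so the community shapes follow the same draw
        n = tau.size
        samples = {p: [] for p in names}
        failed = 0
        for _ in range(cfg.bootstrap_n):
            idx = rng.integers(0, n, size=n)
            try:
                est = fit_once(tau[idx], bbp_star[idx], b1[idx],
                               b2[idx] if b2 is not None else None)
            except Exception:
                failed += 1
                continue
            for p in names:
                samples[p].append(est[p])
        if failed > cfg.max_bootstrap_failures * cfg.bootstrap_n:
            raise FitFailure(f"{failed}/{cfg.bootstrap_n} bootstrap replicates failed")
        samples = {p: np.asarray(v) for p, v in samples.items()}
        medians, ci = _summarize(samples)
    else:
        medians = {p: direct[p] for p in names}
        ci = {}
    params = dict(medians)
    if mode == "one_community":
        params["omega2"] = None
    return params, ci, direct["_rss"]


def derive_coefficients(
    omega2: float | None, bbpk_star: float, b_s: float, b_bp_s: float
) -> tuple[float, float | None, float]:
    """Physical-unit coefficients from the dimensionless fit:
    (b^B_bp,1, b^B_bp,2, b^k_bp)."""
    if b_s <= 0 or b_bp_s <= 0:
        raise ValueError("B_s and b_bp,s must be positive")
    bbp1B = (1.0 - bbpk_star) * b_bp_s / b_s
    bbp2B = None if omega2 is None else omega2 * b_bp_s / b_s
    bbpk = bbpk_star * b_bp_s
    return bbp1B, bbp2B, bbpk


def partition_bbp(
    profile: ProfileRecord,
    context: OpticalContext,
    chl_fit: ChlPartitionResult,
    config: BbpFitConfig | None = None,
    rng: np.random.Generator | None = None,
) -> BbpPartitionResult:
    """Fit the backscattering partition for one profile, using the
    chlorophyll fit's median parameters for the community shapes."""
    cfg = config or BbpFitConfig()
    norm = normalize_bbp(profile, context, cfg)
    b1 = community1(norm.tau, chl_fit.p1, chl_fit.tau1)
    if chl_fit.mode == "two_community":
        b2 = community2(norm.tau, chl_fit.b2m_star, chl_fit.tau2, chl_fit.sigma)
    else:
        b2 = np.zeros_like(norm.tau)
    params, ci, rss = fit_bbp(
        norm.bbp_star, norm.tau, b1, b2, chl_fit.mode, cfg, rng
    )
    bbp1B, bbp2B, bbpk = derive_coefficients(
        params.get("omega2"), params["bbpk_star"], chl_fit.b_s, norm.b_bp_s
    )
    return BbpPartitionResult(
        mode=chl_fit.mode,
        omega2=params.get("omega2"),
        bbpk_star=params["bbpk_star"],
        bbp1B=bbp1B, bbp2B=bbp2B, bbpk=bbpk,
        ci=ci, n_points=norm.n, rss=rss, cycle_id=profile.cycle_id,
    )


def reconstruct_bbp(
    depth,
    chl_fit: ChlPartitionResult,
    bbp_fit: BbpPartitionResult,
    context: OpticalContext,
) -> np.ndarray:
    """Total b_bp(z) = b^B_bp,1·B1(z) + b^B_bp,2·B2(z) + b^k_bp (m^-1)."""
    b1 = chl_fit.community_profile(depth, 1)
    out = bbp_fit.bbp1B * b1 + bbp_fit.bbpk
    if bbp_fit.mode == "two_community" and bbp_fit.bbp2B is not None:
        out = out + bbp_fit.bbp2B * chl_fit.community_profile(depth, 2)
    return out


def despike_bbp(bbp, window: int = 11) -> np.ndarray:
    """Running-median despiking (window 11, nearest-edge padding), used for
    reporting and plots only — fits always see the raw normalized data."""
    bbp = np.asarray(bbp, dtype=float)
    n = bbp.size
    if n == 0:
        return bbp.copy()
    size = min(window, n if n % 2 == 1 else n - 1)
    size = max(size, 1)
    return ndimage.median_filter(bbp, size=size, mode="nearest")
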