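"""End-to-end orchestration: read → context → partitions → series → phenology.

A profile failing any precondition (night PAR, too few points, no surface
samples) is logged with its reason and skipped; no profile-level failure
aborts a run.  Results are deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import phenology as phen
from .bbp import partition_bbp
from .chl import ProfileSkipped, partition_profile
from .config import Config
from .environment import compute_context
from .profiles import ProfileRecord, read_profiles, write_results

__all__ = ["RunConfig", "RunSummary", "run_pipeline", "fit_profiles", "correlate_series"]

log = logging.getLogger("phytopart")


@dataclass
class RunConfig:
    """One pipeline run: inputs, output directory, module configs, seed."""

    inputs: list = field(default_factory=list)       # paths or ProfileRecords
    out_dir: str | Path = "phytopart_out"
    config: Config = field(default_factory=Config)
    seed: int = 0
    #: annual phenology windows per community: {community: (start, end)}
    phenology_windows: dict = field(default_factory=dict)
    log_level: str = "INFO"


@dataclass
class RunSummary:
    n_profiles: int = 0
    n_fitted: int = 0
    n_skipped: int = 0
    n_one_community: int = 0
    n_two_community: int = 0
    skipped_reasons: dict = field(default_factory=dict)
    output_files: dict = field(default_factory=dict)
    phenology: list = field(default_factory=list)


def _load_records(inputs) -> list[ProfileRecord]:
    records: list[ProfileRecord] = []
    for item in inputs:
        if isinstance(item, ProfileRecord):
            records.append(item)
        else:
            records.extend(read_profiles(item))
    records.sort(key=lambda r: r.time)
    return records


def fit_profiles(records, config: Config | None = None, seed: int = 0):
    """Context + chlorophyll + backscattering fits for a record sequence.

    Returns ``(contexts, chl_fits, bbp_fits, reasons)`` aligned to the
    records; a skipped profile holds None and its reason is recorded.
    """
    cfg = config or Config()
    rng = np.random.default_rng(seed)
    contexts, chl_fits, bbp_fits = [], [], []
    reasons: dict[int, str] = {}
    for rec in records:
        try:
            ctx = compute_context(rec, cfg.environment)
            fit = partition_profile(rec, ctx, cfg.chl, rng)
        except (ProfileSkipped, ValueError) as exc:
            log.info("cycle %s skipped: %s", rec.cycle_id, exc)
            reasons[rec.cycle_id] = str(exc)
            contexts.append(None)
            chl_fits.append(None)
            bbp_fits.append(None)
            continue
        log.info(
            "cycle %s: mode=%s r2=%.3f aic1=%.1f aic2=%s",
            rec.cycle_id, fit.mode, fit.r2_step1, fit.aic_step1,
            "-" if np.isnan(fit.aic_step2) else f"{fit.aic_step2:.1f}",
        )
        try:
            bfit = partition_bbp(rec, ctx, fit, cfg.bbp, rng)
        except (ProfileSkipped, ValueError) as exc:
            log.info("cycle %s bbp skipped: %s", rec.cycle_id, exc)
            bfit = None
        contexts.append(ctx)
        chl_fits.append(fit)
        bbp_fits.append(bfit)
    return contexts, chl_fits, bbp_fits, reasons


def _fit_row(rec, ctx, fit, bfit) -> dict:
    row = {
        "cycle_id": rec.cycle_id,
        "mode": fit.mode,
        "kd": ctx.kd, "kd_source": ctx.kd_source,
        "b_s": fit.b_s, "b_s10": ctx.b_s10, "b_bp_s": ctx.b_bp_s,
        "z_p": ctx.z_p, "z_m": ctx.z_m, "strat_index": ctx.strat_index,
        "par_ml": ctx.par_ml, "par_below_ml": ctx.par_below_ml,
        "p1": fit.p1, "tau1": fit.tau1,
        "b2m_star": fit.b2m_star, "tau2": fit.tau2, "sigma": fit.sigma,
        "r2_step1": fit.r2_step1, "aic_step1": fit.aic_step1,
        "aic_step2": fit.aic_step2, "n_points": fit.n_points,
    }
    for p, (lo, hi) in fit.ci.items():
        row[f"{p}_ci_low"] = lo
        row[f"{p}_ci_high"] = hi
    if bfit is not None:
        row.update(
            omega2=bfit.omega2, bbpk_star=bfit.bbpk_star, omega1=bfit.omega1,
            bbp1B=bfit.bbp1B, bbp2B=bfit.bbp2B, bbpk=bfit.bbpk,
        )
        for p, (lo, hi) in bfit.ci.items():
            row[f"{p}_ci_low"] = lo
            row[f"{p}_ci_high"] = hi
    return row


def run_pipeline(run: RunConfig) -> RunSummary:
    """Execute the full workflow and write tabular outputs.

    Outputs: per-profile parameter table, per-community integrated
    chlorophyll series, and phenology metrics for each configured annual
    window.
    """
    logging.basicConfig(level=getattr(logging, run.log_level.upper(), logging.INFO))
    records = _load_records(run.inputs)
    if not records:
        raise FileNotFoundError("no input profiles found")
    cfg = run.config
    contexts, chl_fits, bbp_fits, reasons = fit_profiles(records, cfg, run.seed)

    summary = RunSummary(n_profiles=len(records), skipped_reasons=reasons)
    summary.n_fitted = sum(f is not None for f in chl_fits)
    summary.n_skipped = len(records) - summary.n_fitted
    summary.n_one_community = sum(
        f is not None and f.mode == "one_community" for f in chl_fits
    )
    summary.n_two_community = sum(
        f is not None and f.mode == "two_community" for f in chl_fits
    )

    out_dir = Path(run.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    series_frames = []
    metrics = []
    for community in (1, 2):
        times, values = phen.community_series(
            records, chl_fits, contexts, community,
            tau_limit=cfg.environment.strat_tau_limit,
        )
        if times.size:
            series_frames.append(pd.DataFrame({
                "time": [pd.Timestamp(t) for t in times],
                "community": community,
                "integrated_chl": values,
            }))
        window = run.phenology_windows.get(community)
        if window is not None and times.size >= 2:
            daily = phen.to_daily(times, values)
            smoothed = phen.smooth_series(
                daily, cfg.phenology.sg_window, cfg.phenology.sg_order
            )
            metrics.append(
                phen.detect_bloom(smoothed, window[0], window[1],
                                  community=community, config=cfg.phenology)
            )
    summary.phenology = metrics

    fits_rows = [
        None if f is None else _fit_row(rec, ctx, f, b)
        for rec, ctx, f, b in zip(records, contexts, chl_fits, bbp_fits)
    ]
    summary.output_files = write_results(records, fits_rows, metrics, out_dir)
    if series_frames:
        series_path = out_dir / "community_series.csv"
        pd.concat(series_frames, ignore_index=True).to_csv(
            series_path, index=False, float_format="%.10g"
        )
        summary.output_files["series"] = series_path
    return summary


def correlate_series(x, y, log10: bool = False) -> tuple[float, float]:
    """Pearson correlation (r, p) between paired series, optionally after
    log10-transforming both.  Requires at least 3 finite pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if log10:
        ok &= (x > 0) & (y > 0)
    if ok.sum() < 3:
        raise ValueError(f"need at least 3 finite pairs, got {int(ok.sum())}")
    xv, yv = x[ok], y[ok]
    if log10:
        xv, yv = np.log10(xv), np.log10(yv)
    r, p = stats.pearsonr(xv, yv)
    return float(r), float(p)
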