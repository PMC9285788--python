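"""Profile containers and Argo-dialect NetCDF / CSV input-output.

A :class:`ProfileRecord` holds one float cycle: position and time plus the
depth-resolved physical (T, S, pressure), optical (bbp, PAR) and biological
(chlorophyll-a) arrays.  Missing values are carried explicitly as NaN; they
are never silently zeroed.

The NetCDF reader/writer follow the Argo single/multi-profile layout
(dimensions ``N_PROF`` x ``N_LEVELS``; variables ``PRES``, ``TEMP``,
``PSAL``, ``CHLA_ADJUSTED``, ``BBP700_ADJUSTED``, ``DOWNWELLING_PAR``,
``JULD``, ``LATITUDE``, ``LONGITUDE``, ``CYCLE_NUMBER``) so that files
written here are structurally interchangeable with delayed-mode Argo
b-files at the variable level.  A long-format CSV dialect (one row per
cycle-depth pair) is provided as a fallback that needs no NetCDF tooling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seawater import depth_from_pressure

__all__ = [
    "ProfileRecord",
    "read_argo_profiles",
    "write_argo_profiles",
    "read_csv_profiles",
    "write_csv_profiles",
    "read_profiles",
    "write_results",
]

ARGO_FILL = 99999.0
#: Argo QC flags accepted on adjusted variables (good / probably good /
#: changed in delayed mode / interpolated); all others are masked.
ACCEPTED_QC = frozenset({1, 2, 5, 8})
_JULD_EPOCH = np.datetime64("1950-01-01T00:00:00")


@dataclass
class ProfileRecord:
    """One float cycle with aligned depth-resolved arrays.

    Invariants (checked on construction): depth strictly increasing and
    non-negative; every depth-resolved array has the same length.
    """

    cycle_id: int
    time: np.datetime64
    latitude: float
    longitude: float
    depth: np.ndarray
    pressure: np.ndarray
    temperature: np.ndarray
    salinity: np.ndarray
    chl: np.ndarray
    bbp700: np.ndarray
    par: np.ndarray | None = None
    oxygen: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        n = self.depth.size
        for name in ("pressure", "temperature", "salinity", "chl", "bbp700", "par", "oxygen"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            if arr.size != n:
                raise ValueError(
                    f"array {name!r} has length {arr.size}, expected {n} (depth grid)"
                )
            setattr(self, name, arr)
        if n and self.depth.min() < 0:
            raise ValueError("depth must be non-negative")
        if n > 1 and not np.all(np.diff(self.depth) > 0):
            raise ValueError("depth must be strictly increasing")
        self.time = np.datetime64(self.time)

    @property
    def n_levels(self) -> int:
        return self.depth.size

    def mask(self, name: str) -> np.ndarray:
        """Boolean missing-value mask for a depth-resolved variable."""
        arr = getattr(self, name)
        if arr is None:
            return np.ones(self.n_levels, dtype=bool)
        return np.isnan(arr)


_NC_VARS = {
    "pressure": "PRES",
    "temperature": "TEMP",
    "salinity": "PSAL",
    "chl": "CHLA",
    "bbp700": "BBP700",
    "par": "DOWNWELLING_PAR",
    "oxygen": "DOXY",
}
_ADJUSTED = {"chl", "bbp700", "oxygen"}
_MANDATORY = ("pressure", "temperature", "salinity", "chl", "bbp700")


def _clean(values: np.ndarray) -> np.ndarray:
    out = np.asarray(values, dtype=float).copy()
    out[np.abs(out) >= ARGO_FILL - 1.0] = np.nan
    return out


def _qc_mask(ds, var: str, n: int) -> np.ndarray:
    """True where the QC flag rejects the sample; all-False if no QC var."""
    qc_name = var + "_QC"
    if qc_name not in ds:
        return np.zeros(n, dtype=bool)
    raw = np.asarray(ds[qc_name].values).ravel()[:n]
    flags = np.full(n, -1, dtype=int)
    for i, item in enumerate(raw):
        if isinstance(item, bytes):
            item = item.decode(errors="ignore")
        text = str(item).strip()
        if text.isdigit():
            flags[i] = int(text)
        else:
            try:
                flags[i] = int(float(text))
            except (TypeError, ValueError):
                flags[i] = -1
    return ~np.isin(flags, list(ACCEPTED_QC))


def read_argo_profiles(
    path: str | Path, variable_policy: str = "adjusted"
) -> list[ProfileRecord]:
    """Read an Argo-dialect NetCDF file into profile records.

    Parameters
    ----------
    path
        Single- or multi-profile Argo NetCDF file.
    variable_policy
        ``"adjusted"`` reads ``*_ADJUSTED`` biogeochemical variables
        (falling back to raw only if no adjusted variable exists at all);
        ``"raw"`` reads the unadjusted names.

    Returns
    -------
    Records sorted by time, one per cycle, pressure converted to depth.
    Cycles with non-monotonic pressure are rejected with a warning.
    """
    import xarray as xr

    if variable_policy not in ("adjusted", "raw"):
        raise ValueError(f"unknown variable_policy {variable_policy!r}")
    with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
        n_prof = ds.sizes.get("N_PROF", 1)
        records: list[ProfileRecord] = []
        for var in _MANDATORY:
            base = _NC_VARS[var]
            if base not in ds and base + "_ADJUSTED" not in ds:
                raise KeyError(f"mandatory variable {base!r} missing from {path}")
        for ip in range(n_prof):
            arrays = {}
            for var, base in _NC_VARS.items():
                name = base
                if variable_policy == "adjusted" and var in _ADJUSTED:
                    if base + "_ADJUSTED" in ds:
                        name = base + "_ADJUSTED"
                if name not in ds:
                    arrays[var] = None
                    continue
                vals = _clean(np.atleast_2d(ds[name].values)[ip])
                vals[_qc_mask(ds, name, vals.size)] = np.nan
                arrays[var] = vals
            lat = float(np.atleast_1d(ds["LATITUDE"].values)[ip])
            lon = float(np.atleast_1d(ds["LONGITUDE"].values)[ip])
            juld = float(np.atleast_1d(ds["JULD"].values)[ip])
            time = _JULD_EPOCH + np.timedelta64(round(juld * 86400), "s")
            cycle = int(np.atleast_1d(ds["CYCLE_NUMBER"].values)[ip])
            pres = arrays["pressure"]
            ok = ~np.isnan(pres)
            if ok.sum() < 2 or not np.all(np.diff(pres[ok]) > 0):
                warnings.warn(
                    f"cycle {cycle}: non-monotonic or insufficient pressure; rejected",
                    stacklevel=2,
                )
                continue
            arrays = {k: (v[ok] if v is not None else None) for k, v in arrays.items()}
            records.append(
                ProfileRecord(
                    cycle_id=cycle,
                    time=time,
                    latitude=lat,
                    longitude=lon,
                    depth=depth_from_pressure(arrays["pressure"], lat),
                    **arrays,
                )
            )
    records.sort(key=lambda r: r.time)
    return records


def write_argo_profiles(records: Sequence[ProfileRecord], path: str | Path) -> None:
    """Write records as a multi-profile Argo-dialect NetCDF (classic format).

    Adjusted variable names are used for chl / bbp / oxygen and QC flags are
    written as '1' wherever a value is present.
    """
    import xarray as xr

    if not records:
        raise ValueError("no records to write")
    n_prof = len(records)
    n_lev = max(r.n_levels for r in records)

    def pad(getter):
        out = np.full((n_prof, n_lev), np.nan)
        for i, r in enumerate(records):
            arr = getter(r)
            if arr is not None:
                out[i, : arr.size] = arr
        return out

    data = {}
    for var, base in _NC_VARS.items():
        vals = pad(lambda r, v=var: getattr(r, v))
        if np.all(np.isnan(vals)):
            continue
        name = base + "_ADJUSTED" if var in _ADJUSTED else base
        filled = np.where(np.isnan(vals), ARGO_FILL, vals)
        data[name] = (("N_PROF", "N_LEVELS"), filled)
        qc = np.where(np.isnan(vals), b"9", b"1").astype("S1")
        data[name + "_QC"] = (("N_PROF", "N_LEVELS"), qc)
    juld = np.array(
        [(r.time - _JULD_EPOCH) / np.timedelta64(1, "D") for r in records], dtype=float
    )
    data["JULD"] = (("N_PROF",), juld)
    data["LATITUDE"] = (("N_PROF",), np.array([r.latitude for r in records]))
    data["LONGITUDE"] = (("N_PROF",), np.array([r.longitude for r in records]))
    data["CYCLE_NUMBER"] = (("N_PROF",), np.array([r.cycle_id for r in records], dtype="i4"))
    ds = xr.Dataset(data)
    for base in _NC_VARS.values():
        for name in (base, base + "_ADJUSTED"):
            if name in ds:
                ds[name].attrs["_FillValue_convention"] = ARGO_FILL
    ds.to_netcdf(path, engine="scipy")


_CSV_COLUMNS = [
    "cycle_id", "time", "latitude", "longitude", "pressure", "depth",
    "temperature", "salinity", "chl", "bbp700", "par", "oxygen",
]


def write_csv_profiles(records: Sequence[ProfileRecord], path: str | Path) -> None:
    """Long-format CSV: one row per (cycle, depth)."""
    rows = []
    for r in records:
        for j in range(r.n_levels):
            rows.append(
                {
                    "cycle_id": r.cycle_id,
                    "time": pd.Timestamp(r.time).isoformat(),
                    "latitude": r.latitude,
                    "longitude": r.longitude,
                    "pressure": r.pressure[j],
                    "depth": r.depth[j],
                    "temperature": r.temperature[j],
                    "salinity": r.salinity[j],
                    "chl": r.chl[j],
                    "bbp700": r.bbp700[j],
                    "par": r.par[j] if r.par is not None else np.nan,
                    "oxygen": r.oxygen[j] if r.oxygen is not None else np.nan,
                }
            )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False, float_format="%.10g")


def read_csv_profiles(path: str | Path) -> list[ProfileRecord]:
    """Read the long-format CSV dialect written by :func:`write_csv_profiles`."""
    df = pd.read_csv(path)
    missing = {"cycle_id", "time", "latitude", "depth"} - set(df.columns)
    if missing:
        raise KeyError(f"mandatory CSV columns missing: {sorted(missing)}")
    records = []
    for cycle, grp in df.groupby("cycle_id", sort=False):
        grp = grp.reset_index(drop=True)
        depth = grp["depth"].to_numpy(float)
        if depth.size > 1 and not np.all(np.diff(depth) > 0):
            warnings.warn(f"cycle {cycle}: non-monotonic depth; rejected", stacklevel=2)
            continue

        def col(name):
            if name not in grp:
                return None
            vals = grp[name].to_numpy(float)
            return None if np.all(np.isnan(vals)) else vals

        records.append(
            ProfileRecord(
                cycle_id=int(cycle),
                time=np.datetime64(pd.Timestamp(grp["time"].iloc[0]).to_datetime64()),
                latitude=float(grp["latitude"].iloc[0]),
                longitude=float(grp["longitude"].iloc[0]) if "longitude" in grp else np.nan,
                depth=depth,
                pressure=grp["pressure"].to_numpy(float) if "pressure" in grp else depth,
                temperature=grp["temperature"].to_numpy(float),
                salinity=grp["salinity"].to_numpy(float),
                chl=grp["chl"].to_numpy(float),
                bbp700=grp["bbp700"].to_numpy(float),
                par=col("par"),
                oxygen=col("oxygen"),
            )
        )
    records.sort(key=lambda r: r.time)
    return records


def read_profiles(path: str | Path, variable_policy: str = "adjusted") -> list[ProfileRecord]:
    """Dispatch on file suffix: ``.nc`` -> Argo NetCDF, ``.csv`` -> CSV."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return read_csv_profiles(path)
    return read_argo_profiles(path, variable_policy=variable_policy)


def write_results(records, fits, phenology, out_dir: str | Path) -> dict[str, Path]:
    """Write the per-profile parameter table and phenology table.

    ``fits`` is a sequence aligned to ``records`` by ``cycle_id`` (a fit of
    None marks a skipped profile); ``phenology`` is a sequence of
    :class:`~phytopart.phenology.PhenologyMetrics` (possibly empty).  Values
    round-trip losslessly to at least 6 significant digits.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fit_list = list(fits)
    rec_list = list(records)
    if len(fit_list) != len(rec_list):
        raise ValueError(
            f"{len(fit_list)} fits for {len(rec_list)} records; inputs misaligned"
        )
    rows = []
    for rec, fit in zip(rec_list, fit_list):
        if fit is not None and fit.get("cycle_id") != rec.cycle_id:
            raise ValueError(
                f"fit cycle {fit.get('cycle_id')} does not match record {rec.cycle_id}"
            )
        row = {"cycle_id": rec.cycle_id, "time": pd.Timestamp(rec.time).isoformat()}
        row.update(fit or {"cycle_id": rec.cycle_id})
        rows.append(row)
    params_path = out_dir / "profile_parameters.csv"
    cols = list(dict.fromkeys(k for row in rows for k in row))
    pd.DataFrame(rows, columns=cols).to_csv(params_path, index=False, float_format="%.10g")

    phen_rows = [
        {
            "community": m.community,
            "initiation": "" if m.initiation is None else str(m.initiation),
            "termination": "" if m.termination is None else str(m.termination),
            "duration_days": "" if m.duration is None else m.duration,
            "window_start": str(m.window_start),
            "window_end": str(m.window_end),
        }
        for m in phenology
    ]
    phen_path = out_dir / "phenology.csv"
    pd.DataFrame(
        phen_rows,
        columns=["community", "initiation", "termination", "duration_days",
                 "window_start", "window_end"],
    ).to_csv(phen_path, index=False)
    return {"parameters": params_path, "phenology": phen_path}
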