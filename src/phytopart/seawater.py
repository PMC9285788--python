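"""EOS-80 seawater properties.

Implements the UNESCO 1983 (Fofonoff & Millard) equation of state,
adiabatic lapse rate / potential temperature, and the pressure-to-depth
conversion with latitude-dependent gravity.  These are the classic EOS-80
formulations used throughout the older oceanographic literature; TEOS-10
is deliberately out of scope.

All functions are vectorised over numpy arrays.  Units follow Argo
conventions: temperature in °C (ITS-90 treated as IPTS-68 compatible at
the accuracy needed here), practical salinity (PSU), pressure in dBar.
"""

from __future__ import annotations

import numpy as np

__all__ = ["density", "potential_temperature", "potential_density", "depth_from_pressure"]


def _smow(t: np.ndarray) -> np.ndarray:
    """Density of Standard Mean Ocean Water (pure water), kg m^-3."""
    a0 = 999.842594
    a1 = 6.793952e-2
    a2 = -9.095290e-3
    a3 = 1.001685e-4
    a4 = -1.120083e-6
    a5 = 6.536332e-9
    return a0 + (a1 + (a2 + (a3 + (a4 + a5 * t) * t) * t) * t) * t


def _density_p0(s: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Density at atmospheric pressure (p=0), kg m^-3."""
    b0 = 8.24493e-1
    b1 = -4.0899e-3
    b2 = 7.6438e-5
    b3 = -8.2467e-7
    b4 = 5.3875e-9
    c0 = -5.72466e-3
    c1 = 1.0227e-4
    c2 = -1.6546e-6
    d0 = 4.8314e-4
    b = b0 + (b1 + (b2 + (b3 + b4 * t) * t) * t) * t
    c = c0 + (c1 + c2 * t) * t
    return _smow(t) + b * s + c * s * np.sqrt(s) + d0 * s**2


def _secant_bulk_modulus(s: np.ndarray, t: np.ndarray, p_bar: np.ndarray) -> np.ndarray:
    """Secant bulk modulus K(S, T, p); p in bar."""
    # pure-water terms
    e = (19652.21, 148.4206, -2.327105, 1.360477e-2, -5.155288e-5)
    kw = e[0] + (e[1] + (e[2] + (e[3] + e[4] * t) * t) * t) * t
    f = (54.6746, -0.603459, 1.09987e-2, -6.1670e-5)
    g = (7.944e-2, 1.6483e-2, -5.3009e-4)
    k0 = (
        kw
        + (f[0] + (f[1] + (f[2] + f[3] * t) * t) * t) * s
        + (g[0] + (g[1] + g[2] * t) * t) * s * np.sqrt(s)
    )
    h = (3.239908, 1.43713e-3, 1.16092e-4, -5.77905e-7)
    i = (2.2838e-3, -1.0981e-5, -1.6078e-6)
    j0 = 1.91075e-4
    aw = h[0] + (h[1] + (h[2] + h[3] * t) * t) * t
    a = aw + (i[0] + (i[1] + i[2] * t) * t) * s + j0 * s * np.sqrt(s)
    k = (8.50935e-5, -6.12293e-6, 5.2787e-8)
    m = (-9.9348e-7, 2.0816e-8, 9.1697e-10)
    bw = k[0] + (k[1] + k[2] * t) * t
    b = bw + (m[0] + (m[1] + m[2] * t) * t) * s
    return k0 + (a + b * p_bar) * p_bar


def density(s, t, p=0.0):
    """In-situ density ρ(S, T, p) per EOS-80, kg m^-3.

    Parameters
    ----------
    s : practical salinity (PSU)
    t : temperature (°C, IPTS-68)
    p : pressure (dBar); 0 for surface

    UNESCO check value: density(35, 5, 0) ≈ 1027.67547.
    """
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    p_bar = np.asarray(p, dtype=float) / 10.0  # dBar -> bar
    rho0 = _density_p0(s, t)
    out = np.where(
        p_bar == 0.0,
        rho0,
        rho0 / (1.0 - p_bar / _secant_bulk_modulus(s, t, p_bar)),
    )
    return out if out.ndim else float(out)


def _adiabatic_lapse(s, t, p):
    """Adiabatic temperature gradient (°C per dBar), Bryden (1973)."""
    ds = s - 35.0
    a = (3.5803e-5, 8.5258e-6, -6.836e-8, 6.6228e-10)
    b = (1.8932e-6, -4.2393e-8)
    c = (1.8741e-8, -6.7795e-10, 8.733e-12, -5.4481e-14)
    d = (-1.1351e-10, 2.7759e-12)
    e = (-4.6206e-13, 1.8676e-14, -2.1687e-16)
    return (
        a[0] + (a[1] + (a[2] + a[3] * t) * t) * t
        + (b[0] + b[1] * t) * ds
        + ((c[0] + (c[1] + (c[2] + c[3] * t) * t) * t) + (d[0] + d[1] * t) * ds) * p
        + (e[0] + (e[1] + e[2] * t) * t) * p * p
    )


def potential_temperature(s, t, p, p_ref=0.0):
    """Potential temperature θ via 4th-order Runge-Kutta integration of the
    adiabatic lapse rate (Fofonoff & Millard, 1983).

    Check value: potential_temperature(40, 40, 10000, 0) ≈ 36.89073.
    """
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    dp = np.asarray(p_ref, dtype=float) - p
    h = dp
    xk = h * _adiabatic_lapse(s, t, p)
    t1 = t + 0.5 * xk
    q = xk
    p1 = p + 0.5 * h
    xk = h * _adiabatic_lapse(s, t1, p1)
    t2 = t1 + 0.29289322 * (xk - q)
    q = 0.58578644 * xk + 0.121320344 * q
    xk = h * _adiabatic_lapse(s, t2, p1)
    t3 = t2 + 1.707106781 * (xk - q)
    q = 3.414213562 * xk - 4.121320344 * q
    p2 = p + h
    xk = h * _adiabatic_lapse(s, t3, p2)
    theta = t3 + (xk - 2.0 * q) / 6.0
    return theta if theta.ndim else float(theta)


def potential_density(s, t, p, p_ref=0.0):
    """Potential density σ referenced to ``p_ref`` (default surface), kg m^-3."""
    theta = potential_temperature(s, t, p, p_ref)
    return density(s, theta, p_ref)


def depth_from_pressure(p, latitude):
    """Depth (m, positive down) from pressure (dBar), UNESCO formula with
    latitude-dependent gravity.

    depth_from_pressure(0, lat) == 0 exactly;
    check value: depth_from_pressure(10000, 30) ≈ 9712.653.
    """
    p = np.asarray(p, dtype=float)
    x = np.sin(np.deg2rad(latitude)) ** 2
    g = 9.780318 * (1.0 + (5.2788e-3 + 2.36e-5 * x) * x) + 1.092e-6 * p
    z = (((-1.82e-15 * p + 2.279e-10) * p - 2.2512e-5) * p + 9.72659) * p / g
    return z if z.ndim else float(z)
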