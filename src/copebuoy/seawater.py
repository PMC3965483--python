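"""Seawater density from the international EOS-80 equation of state.

Implements the UNESCO 1983 (Millero & Poisson 1981 one-atmosphere
polynomial plus the Fofonoff & Millard secant-bulk-modulus pressure
correction) formulation:

    rho(S, T, p) = rho(S, T, 0) / (1 - p / K(S, T, p))

with practical salinity S (PSS-78), temperature T in °C (IPTS-68), and
pressure p in bar internally (the public API takes dbar).  Densities are
returned in g/cm³ to match the body-density model; the kg/m³ → g/cm³
conversion happens here and nowhere else.

The coefficient transcription is verified in the test suite against the
published check values (e.g. rho(S=0, T=5, p=0) = 999.96675 kg/m³ and
rho(S=35, T=25, p=10000 dbar) = 1062.53817 kg/m³).
"""

from __future__ import annotations

import numpy as np

__all__ = ["seawater_density", "pressure_at_depth"]


def pressure_at_depth(z) -> float | np.ndarray:
    """Hydrostatic pressure (dbar) at depth z (m) using the 1 dbar/m rule.

    The approximation errs by well under 1% over the photic-layer depths
    (≤ ~100 m) this package targets.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth must be non-negative")
    out = z.copy()
    return float(out) if out.ndim == 0 else out


def _rho_smow(t):
    """Density of Standard Mean Ocean Water (pure water), kg/m³."""
    return (
        999.842594
        + 6.793952e-2 * t
        - 9.095290e-3 * t**2
        + 1.001685e-4 * t**3
        - 1.120083e-6 * t**4
        + 6.536332e-9 * t**5
    )


def _rho_p0(s, t):
    """One-atmosphere density rho(S, T, 0), kg/m³ (Millero & Poisson 1981)."""
    a = (
        0.824493
        - 4.0899e-3 * t
        + 7.6438e-5 * t**2
        - 8.2467e-7 * t**3
        + 5.3875e-9 * t**4
    )
    b = -5.72466e-3 + 1.0227e-4 * t - 1.6546e-6 * t**2
    c = 4.8314e-4
    return _rho_smow(t) + a * s + b * s**1.5 + c * s**2


def _bulk_modulus(s, t, p_bar):
    """Secant bulk modulus K(S, T, p), bar."""
    kw = (
        19652.21
        + 148.4206 * t
        - 2.327105 * t**2
        + 1.360477e-2 * t**3
        - 5.155288e-5 * t**4
    )
    k0 = (
        kw
        + s * (54.6746 - 0.603459 * t + 1.09987e-2 * t**2 - 6.1670e-5 * t**3)
        + s**1.5 * (7.944e-2 + 1.6483e-2 * t - 5.3009e-4 * t**2)
    )
    aw = 3.239908 + 1.43713e-3 * t + 1.16092e-4 * t**2 - 5.77905e-7 * t**3
    a = (
        aw
        + s * (2.2838e-3 - 1.0981e-5 * t - 1.6078e-6 * t**2)
        + 1.91075e-4 * s**1.5
    )
    bw = 8.50935e-5 - 6.12293e-6 * t + 5.2787e-8 * t**2
    b = bw + s * (-9.9348e-7 + 2.0816e-8 * t + 9.1697e-10 * t**2)
    return k0 + a * p_bar + b * p_bar**2


def seawater_density(T, S, P) -> float | np.ndarray:
    """Seawater density in g/cm³ at temperature T (°C), salinity S (PSU)
    and pressure P (dbar) via EOS-80.

    Accepts scalars or broadcastable arrays.  Inputs outside the oceanic
    validity range (T in [-2, 40] °C, S in [0, 45], P >= 0) raise.
    """
    t = np.asarray(T, dtype=float)
    s = np.asarray(S, dtype=float)
    p = np.asarray(P, dtype=float)
    if np.any(t < -2.0) or np.any(t > 40.0):
        raise ValueError("temperature outside [-2, 40] degC")
    if np.any(s < 0.0) or np.any(s > 45.0):
        raise ValueError("salinity outside [0, 45] PSU")
    if np.any(p < 0.0):
        raise ValueError("pressure must be non-negative")
    p_bar = p / 10.0
    rho0 = _rho_p0(s, t)
    rho = np.where(
        p_bar > 0, rho0 / (1.0 - p_bar / _bulk_modulus(s, t, p_bar)), rho0
    )
    out = rho / 1000.0  # kg/m^3 -> g/cm^3
    return float(out) if out.ndim == 0 else out
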