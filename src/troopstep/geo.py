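"""Minimal WGS84 transverse-Mercator (UTM) projection.

Implements the 6th-order Krueger series (Karney 2011 formulation) for the
forward and inverse UTM mappings. Accuracy is far below the GPS noise floor
(round-trip error < 1e-6 m); this keeps trajectory ingestion self-contained
when positions arrive as lon/lat with a declared UTM zone.
"""

from __future__ import annotations

import numpy as np

_A = 6378137.0  # WGS84 semi-major axis (m)
_F = 1.0 / 298.257223563
_K0 = 0.9996
_E0 = 500000.0  # false easting
_N0_SOUTH = 10000000.0

_N = _F / (2.0 - _F)
_E2 = _F * (2.0 - _F)
_E = np.sqrt(_E2)

n = _N
_A_BAR = _A / (1 + n) * (1 + n**2 / 4 + n**4 / 64 + n**6 / 256)

_ALPHA = np.array(
    [
        n / 2 - 2 * n**2 / 3 + 5 * n**3 / 16 + 41 * n**4 / 180
        - 127 * n**5 / 288 + 7891 * n**6 / 37800,
        13 * n**2 / 48 - 3 * n**3 / 5 + 557 * n**4 / 1440 + 281 * n**5 / 630
        - 1983433 * n**6 / 1935360,
        61 * n**3 / 240 - 103 * n**4 / 140 + 15061 * n**5 / 26880
        + 167603 * n**6 / 181440,
        49561 * n**4 / 161280 - 179 * n**5 / 168 + 6601661 * n**6 / 7257600,
        34729 * n**5 / 80640 - 3418889 * n**6 / 1995840,
        212378941 * n**6 / 319334400,
    ]
)
_BETA = np.array(
    [
        n / 2 - 2 * n**2 / 3 + 37 * n**3 / 96 - n**4 / 360
        - 81 * n**5 / 512 + 96199 * n**6 / 604800,
        n**2 / 48 + n**3 / 15 - 437 * n**4 / 1440 + 46 * n**5 / 105
        - 1118711 * n**6 / 3870720,
        17 * n**3 / 480 - 37 * n**4 / 840 - 209 * n**5 / 4480
        + 5569 * n**6 / 90720,
        4397 * n**4 / 161280 - 11 * n**5 / 504 - 830251 * n**6 / 7257600,
        4583 * n**5 / 161280 - 108847 * n**6 / 3991680,
        20648693 * n**6 / 638668800,
    ]
)
del n


def _central_meridian(zone: int) -> float:
    if not 1 <= zone <= 60:
        raise ValueError(f"UTM zone must be in 1..60, got {zone}")
    return np.deg2rad(zone * 6.0 - 183.0)


def lonlat_to_utm(lon, lat, zone: int, northern: bool = True):
    """Project geographic coordinates (degrees) to UTM easting/northing (m)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lam = np.deg2rad(lon) - _central_meridian(zone)
    phi = np.deg2rad(lat)

    s = np.sin(phi)
    t = np.sinh(
        np.arctanh(s) - (2 * np.sqrt(_N) / (1 + _N)) * np.arctanh(
            (2 * np.sqrt(_N) / (1 + _N)) * s
        )
    )
    xi_p = np.arctan2(t, np.cos(lam))
    eta_p = np.arctanh(np.sin(lam) / np.sqrt(1 + t * t))

    xi = xi_p.copy()
    eta = eta_p.copy()
    for j in range(6):
        k = 2.0 * (j + 1)
        xi = xi + _ALPHA[j] * np.sin(k * xi_p) * np.cosh(k * eta_p)
        eta = eta + _ALPHA[j] * np.cos(k * xi_p) * np.sinh(k * eta_p)

    easting = _E0 + _K0 * _A_BAR * eta
    northing = _K0 * _A_BAR * xi
    if not northern:
        northing = northing + _N0_SOUTH
    return easting, northing


def utm_to_lonlat(easting, northing, zone: int, northern: bool = True):
    """Inverse UTM projection; returns (lon, lat) in degrees."""
    easting = np.asarray(easting, dtype=float)
    northing = np.asarray(northing, dtype=float)
    if not northern:
        northing = northing - _N0_SOUTH
    xi = northing / (_K0 * _A_BAR)
    eta = (easting - _E0) / (_K0 * _A_BAR)

    xi_p = xi.copy()
    eta_p = eta.copy()
    for j in range(6):
        k = 2.0 * (j + 1)
        xi_p = xi_p - _BETA[j] * np.sin(k * xi) * np.cosh(k * eta)
        eta_p = eta_p - _BETA[j] * np.cos(k * xi) * np.sinh(k * eta)

    # conformal latitude tangent
    tau_p = np.sin(xi_p) / np.sqrt(np.sinh(eta_p) ** 2 + np.cos(xi_p) ** 2)
    lam = np.arctan2(np.sinh(eta_p), np.cos(xi_p))

    # Newton-solve tau from tau' (Karney eq. 19-21)
    tau = tau_p / (1.0 - _E2)
    for _ in range(6):
        sigma = np.sinh(_E * np.arctanh(_E * tau / np.sqrt(1 + tau * tau)))
        f_tau = tau * np.sqrt(1 + sigma * sigma) - sigma * np.sqrt(1 + tau * tau)
        dtau = (
            (tau_p - f_tau)
            * (1 + (1 - _E2) * tau * tau)
            / ((1 - _E2) * np.sqrt((1 + f_tau * f_tau) * (1 + tau * tau)))
        )
        tau = tau + dtau

    lat = np.rad2deg(np.arctan(tau))
    lon = np.rad2deg(lam + _central_meridian(zone))
    return lon, lat


def parse_crs(declaration: str):
    """Parse a CRS declaration of the form ``'utm:37N'`` -> (zone, northern)."""
    decl = declaration.strip().lower()
    if not decl.startswith("utm:"):
        raise ValueError(
            f"unsupported CRS declaration {declaration!r}; expected 'utm:<zone><N|S>'"
        )
    body = decl[4:]
    hemi = body[-1]
    if hemi not in "ns":
        raise ValueError(f"CRS declaration {declaration!r} missing hemisphere")
    return int(body[:-1]), hemi == "n"
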