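"""WGS84 geographic -> UTM forward projection.

Implements the Karney/Krueger transverse-Mercator series (6th order in the
third flattening), accurate to well under a millimetre within a UTM zone.
Only the forward direction is needed: tracking tables arrive in lon/lat and
all downstream geometry is Euclidean in projected metres.
"""
from __future__ import annotations

import math

import numpy as np

# WGS84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_K0 = 0.9996
_E0 = 500000.0  # false easting
_N0_SOUTH = 10000000.0

_n = _F / (2.0 - _F)
# rectifying radius
_AR = _A / (1.0 + _n) * (1.0 + _n**2 / 4.0 + _n**4 / 64.0 + _n**6 / 256.0)
# Krueger alpha coefficients, 6th order in n
_ALPHA = (
    _n / 2 - 2 * _n**2 / 3 + 5 * _n**3 / 16 + 41 * _n**4 / 180
    - 127 * _n**5 / 288 + 7891 * _n**6 / 37800,
    13 * _n**2 / 48 - 3 * _n**3 / 5 + 557 * _n**4 / 1440 + 281 * _n**5 / 630
    - 1983433 * _n**6 / 1935360,
    61 * _n**3 / 240 - 103 * _n**4 / 140 + 15061 * _n**5 / 26880
    + 167603 * _n**6 / 181440,
    49561 * _n**4 / 161280 - 179 * _n**5 / 168 + 6601661 * _n**6 / 7257600,
    34729 * _n**5 / 80640 - 3418889 * _n**6 / 1995840,
    212378941 * _n**6 / 319334400,
)


def utm_zone(lon: float) -> int:
    """UTM zone number (1-60) for a longitude in degrees."""
    return int((math.floor((lon + 180.0) / 6.0) % 60) + 1)


def zone_central_meridian(zone: int) -> float:
    return -183.0 + 6.0 * zone


def geographic_to_utm(
    lon: np.ndarray,
    lat: np.ndarray,
    zone: int | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Project lon/lat (degrees) to UTM easting/northing (metres).

    If ``zone`` is None the zone of the mean longitude is used for every
    point, so a track straddling a zone edge stays in one planar frame.
    Returns ``(easting, northing, zone)``.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if zone is None:
        zone = utm_zone(float(np.mean(lon)))
    lam0 = math.radians(zone_central_meridian(zone))

    phi = np.radians(lat)
    dlam = np.radians(lon) - lam0

    sphi = np.sin(phi)
    e2sqrt = 2.0 * math.sqrt(_n) / (1.0 + _n)
    t = np.sinh(np.arctanh(sphi) - e2sqrt * np.arctanh(e2sqrt * sphi))
    xi = np.arctan2(t, np.cos(dlam))
    eta = np.arctanh(np.sin(dlam) / np.sqrt(1.0 + t * t))

    xi_s = xi.copy()
    eta_s = eta.copy()
    for j, a in enumerate(_ALPHA, start=1):
        xi_s += a * np.sin(2 * j * xi) * np.cosh(2 * j * eta)
        eta_s += a * np.cos(2 * j * xi) * np.sinh(2 * j * eta)

    easting = _E0 + _K0 * _AR * eta_s
    northing = _K0 * _AR * xi_s
    northing = np.where(lat < 0.0, northing + _N0_SOUTH, northing)
    return easting, northing, zone
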