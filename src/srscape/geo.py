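"""Coordinate handling: UTM <-> WGS84 conversion and the raster grid spec.

The transverse Mercator conversion uses the Krüger series (4th order in
the third flattening, sub-millimetre truncation error inside a UTM
zone); the inverse recovers geodetic latitude from conformal latitude
by Newton iteration, so forward∘inverse round-trips to machine
precision.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

# WGS84
_A = 6378137.0
_F = 1.0 / 298.257223563
_E = math.sqrt(_F * (2.0 - _F))
_N = _F / (2.0 - _F)
_K0 = 0.9996
_FALSE_EASTING = 500000.0

# Krüger series coefficients in the third flattening n (order 4)
_n = _N
_ALPHA = (
    _n / 2 - 2 * _n**2 / 3 + 5 * _n**3 / 16 + 41 * _n**4 / 180,
    13 * _n**2 / 48 - 3 * _n**3 / 5 + 557 * _n**4 / 1440,
    61 * _n**3 / 240 - 103 * _n**4 / 140,
    49561 * _n**4 / 161280,
)
_BETA = (
    _n / 2 - 2 * _n**2 / 3 + 37 * _n**3 / 96 - _n**4 / 360,
    _n**2 / 48 + _n**3 / 15 - 437 * _n**4 / 1440,
    17 * _n**3 / 480 - 37 * _n**4 / 840,
    4397 * _n**4 / 161280,
)
# rectifying radius
_RECT_A = _A / (1 + _n) * (1 + _n**2 / 4 + _n**4 / 64)


def _parse_zone(zone: str) -> tuple[int, str]:
    m = re.fullmatch(r"(\d{1,2})([NSns])", str(zone).strip())
    if not m:
        raise ValueError(f"invalid UTM zone {zone!r} (expected e.g. '14N')")
    num = int(m.group(1))
    if not 1 <= num <= 60:
        raise ValueError(f"invalid UTM zone number {num} (must be 1-60)")
    return num, m.group(2).upper()


def _tau_prime(tau: float) -> float:
    sigma = math.sinh(_E * math.atanh(_E * tau / math.hypot(1.0, tau)))
    return tau * math.hypot(1.0, sigma) - sigma * math.hypot(1.0, tau)


def geographic_to_utm(lon: float, lat: float, zone: str) -> tuple[float, float]:
    """Project WGS84 lon/lat (degrees) to UTM easting/northing (metres)."""
    num, hemi = _parse_zone(zone)
    lam0 = math.radians(-183.0 + 6.0 * num)
    phi = math.radians(lat)
    dlam = math.radians(lon) - lam0

    tau = math.tan(phi)
    taup = _tau_prime(tau)
    xi_p = math.atan2(taup, math.cos(dlam))
    eta_p = math.asinh(math.sin(dlam) / math.hypot(taup, math.cos(dlam)))

    xi, eta = xi_p, eta_p
    for j, a in enumerate(_ALPHA, start=1):
        xi += a * math.sin(2 * j * xi_p) * math.cosh(2 * j * eta_p)
        eta += a * math.cos(2 * j * xi_p) * math.sinh(2 * j * eta_p)

    easting = _FALSE_EASTING + _K0 * _RECT_A * eta
    northing = _K0 * _RECT_A * xi + (10_000_000.0 if hemi == "S" else 0.0)
    return easting, northing


def utm_to_geographic(easting: float, northing: float, zone: str) -> tuple[float, float]:
    """Convert UTM easting/northing (metres) in a zone to WGS84 (lon, lat) degrees."""
    num, hemi = _parse_zone(zone)
    if not (0.0 <= easting <= 1_000_000.0):
        raise ValueError(f"easting {easting} outside the valid UTM span [0, 1e6] m")
    if not (0.0 <= northing <= 10_000_000.0):
        raise ValueError(f"northing {northing} outside the valid UTM span [0, 1e7] m")

    lam0 = math.radians(-183.0 + 6.0 * num)
    xi = (northing - (10_000_000.0 if hemi == "S" else 0.0)) / (_K0 * _RECT_A)
    eta = (easting - _FALSE_EASTING) / (_K0 * _RECT_A)

    xi_p, eta_p = xi, eta
    for j, b in enumerate(_BETA, start=1):
        xi_p -= b * math.sin(2 * j * xi) * math.cosh(2 * j * eta)
        eta_p -= b * math.cos(2 * j * xi) * math.sinh(2 * j * eta)

    taup = math.sin(xi_p) / math.hypot(math.sinh(eta_p), math.cos(xi_p))
    lam = math.atan2(math.sinh(eta_p), math.cos(xi_p))

    # Newton-solve tan(phi) from the conformal tangent
    tau = taup / (1.0 - _E * _E)
    for _ in range(8):
        ftau = _tau_prime(tau) - taup
        sigma = math.sinh(_E * math.atanh(_E * tau / math.hypot(1.0, tau)))
        dtaup = (
            (math.hypot(1.0, sigma) * math.hypot(1.0, tau) - sigma * tau)
            * (1.0 - _E * _E) * math.hypot(1.0, tau)
            / (1.0 + (1.0 - _E * _E) * tau * tau)
        )
        step = ftau / dtaup
        tau -= step
        if abs(step) < 1e-15 * max(1.0, abs(tau)):
            break

    lat = math.degrees(math.atan(tau))
    lon = math.degrees(lam0 + lam)
    return lon, lat


@dataclass(frozen=True)
class GridSpec:
    """A north-up, row-major raster grid.

    ``origin_lon``/``origin_lat`` give the grid's upper-left *corner*.
    Cell (row, col) covers the half-open box
    [origin_lon + col*cell, origin_lon + (col+1)*cell) x
    (origin_lat - (row+1)*cell, origin_lat - row*cell].
    """

    origin_lon: float
    origin_lat: float
    cell_size: float
    n_rows: int
    n_cols: int
    crs_id: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_index(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point (half-open convention)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.origin_lon) / self.cell_size).astype(int)
        row = np.floor((self.origin_lat - lat) / self.cell_size).astype(int)
        return row, col

    def contains(self, lon, lat) -> np.ndarray:
        row, col = self.cell_index(lon, lat)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        lon = self.origin_lon + (col + 0.5) * self.cell_size
        lat = self.origin_lat - (row + 0.5) * self.cell_size
        return lon, lat

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Lon/lat arrays (each shaped n_rows x n_cols) of all cell centres."""
        rows, cols = np.meshgrid(np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij")
        return self.cell_center(rows, cols)
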