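"""Gridded environmental layers and derived habitat predictors.

Grids are ``xarray.DataArray`` objects with dims ``(time, lat, lon)`` (or
``(lat, lon)`` for static/aggregate layers), cell-center coordinates in
degrees, missing values as NaN, and a ``units`` attribute — the in-memory
counterpart of the CF-style NetCDF files this module reads and writes.

The transformation chain mirrors a benthic habitat analysis: fill coastal
gaps, refine the grid by factor-2 bilinear resampling, convert oxygen
concentration to partial pressure, project the calibrated metabolic index
phi through the temperature/pO2 stacks, and aggregate months to min / mean
/ max predictor layers over a multi-year period.

Seawater formulas are pinned published standards:

* depth -> pressure: Saunders (1981, J. Phys. Oceanogr. 11:573) with
  latitude-dependent gravity;
* O2 solubility: Garcia & Gordon (1992, Limnol. Oceanogr. 37:1307),
  Benson & Krause coefficient set, umol kg^-1;
* water vapour pressure: Weiss & Price (1980) via :mod:`metidx.respirometry`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .calibration import PhiParameters, phi as _phi_scalar
from .respirometry import X_O2, BAROMETRIC_KPA, water_vapour_pressure

__all__ = [
    "AerobicScopeCurves",
    "pressure_at_depth",
    "o2_solubility",
    "o2_conc_to_po2",
    "fill_coastal_gaps",
    "resample_bilinear",
    "compute_phi_layers",
    "aggregate_monthly",
    "clip_depth_domain",
    "aerobic_scope_layers",
    "open_stack",
    "write_stack",
]

#: reference seawater density for umol kg^-1 <-> mmol m^-3, kg m^-3
RHO_SW = 1025.0
#: molar volume of O2 dissolved in seawater, m^3 mol^-1 (hydrostatic correction)
V_M_O2 = 32e-6
#: gas constant, J mol^-1 K^-1
R_GAS = 8.31446


def pressure_at_depth(depth, lat):
    """Sea pressure (dbar) at ``depth`` (m below sea level) and latitude.

    Saunders (1981): p = ((1-c1) - sqrt((1-c1)^2 - 8.84e-6 z)) / 4.42e-6
    with c1 = (5.92 + 5.25 sin^2(lat)) * 1e-3.
    """
    z = np.asarray(depth, float)
    if np.any(z[np.isfinite(z)] < 0):
        raise ValueError("depth must be >= 0 (m below sea level)")
    c1 = (5.92 + 5.25 * np.sin(np.deg2rad(np.asarray(lat, float))) ** 2) * 1e-3
    out = ((1.0 - c1) - np.sqrt((1.0 - c1) ** 2 - 8.84e-6 * z)) / 4.42e-6
    return float(out) if out.ndim == 0 else out


# Garcia & Gordon (1992) "combined fit" coefficients (Benson & Krause data),
# oxygen saturation concentration in umol kg^-1.
_GG_A = (5.80871, 3.20291, 4.17887, 5.10006, -9.86643e-2, 3.80369)
_GG_B = (-7.01577e-3, -7.70028e-3, -1.13864e-2, -9.51519e-3)
_GG_C0 = -2.75915e-7


def o2_solubility(temp, salinity, units: str = "mmol/m3"):
    """Air-saturated O2 concentration at ``temp`` (degC), ``salinity`` (psu).

    Garcia & Gordon (1992).  ``units``: ``"umol/kg"`` as published, or
    ``"mmol/m3"`` using the reference density :data:`RHO_SW`.
    """
    t = np.asarray(temp, float)
    s = np.asarray(salinity, float)
    if np.any(t[np.isfinite(t)] < -2) or np.any(t[np.isfinite(t)] > 40):
        raise ValueError("temperature outside the -2..40 degC fit range")
    if np.any(s[np.isfinite(s)] < 0) or np.any(s[np.isfinite(s)] > 42):
        raise ValueError("salinity outside the 0..42 psu fit range")
    ts = np.log((298.15 - t) / (273.15 + t))
    ln_c = np.polynomial.polynomial.polyval(ts, _GG_A) \
        + s * np.polynomial.polynomial.polyval(ts, _GG_B) \
        + _GG_C0 * s ** 2
    c = np.exp(ln_c)  # umol/kg
    if units == "umol/kg":
        out = c
    elif units == "mmol/m3":
        out = c * RHO_SW / 1000.0
    else:
        raise ValueError(f"unknown units {units!r}")
    return float(out) if out.ndim == 0 else out


def o2_conc_to_po2(conc, temp, salinity, pressure_dbar=0.0,
                   barometric_kpa=BAROMETRIC_KPA):
    """Oxygen concentration (mmol m^-3) to partial pressure (kPa).

    The saturation fraction conc / c_sat(T, S) scales the air-equilibrium
    partial pressure x_O2 * (P_baro - p_vapour); a hydrostatic enhancement
    exp(V_m p / (R T)) accounts for pressure at depth.  Linear in ``conc``.
    """
    conc = np.asarray(conc, float)
    if np.any(conc[np.isfinite(conc)] < 0):
        raise ValueError("concentration must be >= 0")
    c_sat = o2_solubility(temp, salinity, units="mmol/m3")
    po2_air = X_O2 * (barometric_kpa - water_vapour_pressure(temp, salinity))
    t_k = np.asarray(temp, float) + 273.15
    press_pa = np.asarray(pressure_dbar, float) * 1e4
    enhance = np.exp(V_M_O2 * press_pa / (R_GAS * t_k))
    out = conc / c_sat * po2_air * enhance
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# grid operations


def _as_3d(values: np.ndarray):
    """View (lat, lon) or (time, lat, lon) data as 3-D."""
    if values.ndim == 2:
        return values[None, ...], True
    if values.ndim == 3:
        return values, False
    raise ValueError("expected 2-D or 3-D grid")


def fill_coastal_gaps(stack: xr.DataArray, max_iter: int = 50) -> xr.DataArray:
    """Fill NaN cells from the mean of their valid 8-neighbors, iteratively.

    Each pass replaces every masked cell having at least one valid neighbor
    by the mean of its valid neighbors; passes repeat until no fillable cell
    remains or ``max_iter`` is reached.  Original valid cells are untouched.
    Idempotent once converged.
    """
    values, squeeze = _as_3d(stack.values.astype(float).copy())
    if np.all(np.isnan(values)):
        warnings.warn("all cells masked; nothing to fill", stacklevel=2)
        return stack.copy()
    shifts = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
              if (di, dj) != (0, 0)]
    for layer in values:
        for _ in range(max_iter):
            mask = np.isnan(layer)
            if not mask.any():
                break
            acc = np.zeros_like(layer)
            cnt = np.zeros_like(layer)
            for di, dj in shifts:
                shifted = np.full_like(layer, np.nan)
                src = layer[max(di, 0) or None: min(di, 0) or None,
                            max(dj, 0) or None: min(dj, 0) or None]
                shifted[max(-di, 0) or None: min(-di, 0) or None,
                        max(-dj, 0) or None: min(-dj, 0) or None] = src
                ok = ~np.isnan(shifted)
                acc[ok] += shifted[ok]
                cnt[ok] += 1
            fillable = mask & (cnt > 0)
            if not fillable.any():
                break
            layer[fillable] = acc[fillable] / cnt[fillable]
    out = values[0] if squeeze else values
    return stack.copy(data=out)


def _refined_centers(coords: np.ndarray, factor: int) -> np.ndarray:
    d = np.diff(coords)
    if len(d) and not np.allclose(d, d[0], rtol=1e-6):
        raise ValueError("irregular coordinate spacing")
    step = d[0] if len(d) else 1.0
    # split each cell into `factor` children; child centers stay inside the
    # parent cell, so refinement is pure interpolation (no extrapolation)
    offsets = (np.arange(factor) + 0.5) / factor - 0.5
    return (coords[:, None] + step * offsets[None, :]).ravel()


def resample_bilinear(stack: xr.DataArray, factor: int = 2) -> xr.DataArray:
    """Refine the lon/lat grid by ``factor`` using bilinear interpolation.

    New cell centers subdivide each parent cell, so constant fields and
    linear ramps are reproduced exactly and interior values lie within the
    hull of their 4 surrounding parent centers; the outermost half-cells
    (beyond the first/last parent centers) are linearly extrapolated.
    """
    from scipy.interpolate import RegularGridInterpolator

    lat = stack["lat"].values.astype(float)
    lon = stack["lon"].values.astype(float)
    new_lat = _refined_centers(lat, factor)
    new_lon = _refined_centers(lon, factor)
    pts_lat, pts_lon = np.meshgrid(new_lat, new_lon, indexing="ij")
    pts = np.column_stack([pts_lat.ravel(), pts_lon.ravel()])
    values, squeeze = _as_3d(stack.values.astype(float))
    out = np.empty((values.shape[0], len(new_lat), len(new_lon)))
    for i, layer in enumerate(values):
        rgi = RegularGridInterpolator((lat, lon), layer, method="linear",
                                      bounds_error=False, fill_value=None)
        out[i] = rgi(pts).reshape(len(new_lat), len(new_lon))
    coords = dict(stack.coords)
    coords["lat"] = new_lat
    coords["lon"] = new_lon
    data = out[0] if squeeze else out
    result = xr.DataArray(data, coords=coords, dims=stack.dims,
                          name=stack.name)
    result.attrs.update(stack.attrs)
    return result


def compute_phi_layers(params: PhiParameters, temp_stack: xr.DataArray,
                       po2_stack: xr.DataArray, mass: float = 1.0) -> xr.DataArray:
    """Cell-wise metabolic index phi = pO2 / pO2crit(T, mass).

    Layers are computed at a reference mass (default 1 kg); the B**n factor
    is spatially constant so the choice only rescales phi.  NaN propagates.
    """
    for dim in ("lat", "lon"):
        if not np.array_equal(temp_stack[dim].values, po2_stack[dim].values):
            raise ValueError(f"temperature and pO2 stacks disagree on {dim!r}")
    values = _phi_scalar(params, temp_stack.values, mass, po2_stack.values)
    out = temp_stack.copy(data=values)
    out.attrs = {"units": "dimensionless", "long_name": "metabolic index"}
    out.name = "phi"
    return out


def aggregate_monthly(stack: xr.DataArray, name: str | None = None) -> xr.Dataset:
    """Cell-wise min / mean / max over the time dimension of a monthly stack."""
    if "time" not in stack.dims or stack.sizes["time"] == 0:
        raise ValueError("stack has no time slices to aggregate")
    base = name or stack.name or "var"
    out = xr.Dataset({
        f"min_{base}": stack.min("time"),
        f"mean_{base}": stack.mean("time"),
        f"max_{base}": stack.max("time"),
    })
    for v in out.data_vars:
        out[v].attrs.update(stack.attrs)
    return out


def clip_depth_domain(bathy: xr.DataArray,
                      depth_range: tuple = (0.0, 100.0)) -> xr.DataArray:
    """Boolean domain mask: cells whose depth (m below sea level) lies in
    ``depth_range``, inclusive.  Depth stacks are mean-aggregated first."""
    if "time" in bathy.dims:
        bathy = bathy.mean("time")
    lo, hi = depth_range
    mask = (bathy >= lo) & (bathy <= hi) & bathy.notnull()
    if not bool(mask.any()):
        warnings.warn(f"no cells with depth in {depth_range}; empty domain",
                      stacklevel=2)
    mask.attrs = {"long_name": f"depth in [{lo}, {hi}] m"}
    return mask


@dataclass
class AerobicScopeCurves:
    """Quadratic thermal performance curves of mass-standardized SMR and MMR.

    Coefficients are ascending (c0, c1, c2): rate = c0 + c1*T + c2*T^2 in
    mg O2 min^-1 kg^-1 with T in degC.
    """

    smr_coeffs: tuple
    mmr_coeffs: tuple

    def smr(self, temp):
        return np.polynomial.polynomial.polyval(np.asarray(temp, float),
                                                self.smr_coeffs)

    def mmr(self, temp):
        return np.polynomial.polynomial.polyval(np.asarray(temp, float),
                                                self.mmr_coeffs)

    @classmethod
    def fit(cls, temps, smr_values, mmr_values) -> "AerobicScopeCurves":
        """Least-squares quadratics of SMR and MMR against temperature."""
        smr_c = np.polynomial.polynomial.polyfit(temps, smr_values, 2)
        mmr_c = np.polynomial.polynomial.polyfit(temps, mmr_values, 2)
        return cls(smr_coeffs=tuple(smr_c), mmr_coeffs=tuple(mmr_c))


def aerobic_scope_layers(curves: AerobicScopeCurves,
                         temp_stack: xr.DataArray):
    """Absolute (MMR - SMR) and factorial (MMR / SMR) aerobic scope layers.

    Cells where SMR <= 0 or MMR <= SMR are masked (outside the curves'
    validity), matching the treatment of temperatures beyond the calibrated
    thermal range.
    """
    t = temp_stack.values.astype(float)
    smr = curves.smr(t)
    mmr = curves.mmr(t)
    bad = ~np.isfinite(t) | (smr <= 0) | (mmr <= smr)
    if bad.all():
        raise ValueError("aerobic scope curves invalid over the whole stack")
    smr = np.where(bad, np.nan, smr)
    mmr = np.where(bad, np.nan, mmr)
    aas = temp_stack.copy(data=mmr - smr)
    aas.attrs = {"units": "mg O2 min-1 kg-1", "long_name": "absolute aerobic scope"}
    aas.name = "aas"
    fas = temp_stack.copy(data=mmr / smr)
    fas.attrs = {"units": "dimensionless", "long_name": "factorial aerobic scope"}
    fas.name = "fas"
    return aas, fas


# ---------------------------------------------------------------------------
# NetCDF IO (scipy engine -> classic NetCDF3, dependency-light)


def write_stack(ds: xr.Dataset | xr.DataArray, path) -> None:
    if isinstance(ds, xr.DataArray):
        ds = ds.to_dataset(name=ds.name or "var")
    ds = ds.copy()
    for v in ds.variables:  # NetCDF3 cannot store bools
        if ds[v].dtype == bool:
            ds[v] = ds[v].astype("i1")
    ds.to_netcdf(path, engine="scipy")


def open_stack(path) -> xr.Dataset:
    return xr.open_dataset(path, engine="scipy").load()
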