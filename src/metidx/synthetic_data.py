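"""Planted-truth synthetic data: respirometry cohorts, ocean grids, occurrences.

Every downstream stage of the package is testable by parameter recovery:
the generator plants a known piecewise Arrhenius pO2crit law with a mass
power law, known thermal performance curves, a known critical metabolic
index phi_crit and a known suitable-depth window, and emits data with the
statistical structure the estimators assume.

The emulated system is a coastal shelf with a warm, well-oxygenated edge on
one side and a cool hypoxic (upwelling-analogue) edge on the other, a
sinusoidal seasonal cycle, and a bathymetry ramp — monotone gradients only,
no attempt at real regional oceanography.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import calibration, env_layers
from .calibration import PhiParameters, BranchFit, arrhenius_coordinate
from .respirometry import RespirometryTrial, po2_to_saturation

__all__ = [
    "PlantedTruth",
    "SyntheticConfig",
    "generate_respirometry_cohort",
    "generate_environment",
    "generate_occurrences",
]


@dataclass
class PlantedTruth:
    """Ground truth the generators embed and the estimators must recover.

    Defaults are the calibrated roman seabream (Chrysoblephus laticeps)
    values: bidirectional hypoxia tolerance around 12 degC with E_o =
    -0.4885 eV above and +1.01 eV below, mass exponent 0.17.  A_o of the
    lower branch is derived from branch continuity at the breakpoint unless
    given explicitly.
    """

    A_o_upper: float = 1.55951e9
    E_o_upper: float = -0.4885  # eV
    E_o_lower: float = 1.01  # eV
    A_o_lower: float | None = None  # derived for continuity when None
    breakpoint_temp: float = 12.0  # degC
    mass_exponent_n: float = 0.17
    #: ascending quadratic coefficients, mg O2 min^-1 kg^-1 vs degC
    smr_curve: tuple = (0.5, 0.04, 0.001)
    mmr_curve: tuple = (2.0, 0.45, -0.01)
    phi_crit_true: float = 3.0
    depth_window: tuple = (13.0, 75.0)  # m below sea level
    noise_sd_mr: float = 0.05  # relative sd of multiplicative MR noise
    seed: int = 0

    def __post_init__(self):
        if self.A_o_lower is None:
            # continuity: both branches equal at the breakpoint
            x_bp = arrhenius_coordinate(self.breakpoint_temp)
            self.A_o_lower = float(
                self.A_o_upper * np.exp((self.E_o_upper - self.E_o_lower) * x_bp))
        self.validate()

    def validate(self) -> None:
        params = self.phi_parameters()
        temps = np.linspace(5.0, 30.0, 101)
        if np.any(calibration.po2crit_predict(params, temps, 1.0) <= 0):
            raise ValueError("planted pO2crit not positive over 5-30 degC")
        gap = params.continuity_gap()
        at_bp = calibration.po2crit_predict(params, self.breakpoint_temp, 1.0)
        if gap > 0.01 * at_bp:
            raise ValueError("planted branches discontinuous at the breakpoint")
        smr = np.polynomial.polynomial.polyval(temps, self.smr_curve)
        mmr = np.polynomial.polynomial.polyval(temps, self.mmr_curve)
        if np.any(smr <= 0) or np.any(mmr <= smr):
            raise ValueError("need 0 < SMR(T) < MMR(T) over 5-30 degC")
        if self.phi_crit_true <= 1:
            raise ValueError("phi_crit_true must exceed 1")

    def phi_parameters(self) -> PhiParameters:
        """The planted law as a :class:`PhiParameters` (the recovery target)."""
        return PhiParameters(
            upper=BranchFit(A_o=self.A_o_upper, E_o=self.E_o_upper),
            lower=BranchFit(A_o=self.A_o_lower, E_o=self.E_o_lower),
            mass_exponent=self.mass_exponent_n,
            breakpoint_temp=self.breakpoint_temp)

    def smr_at(self, temp):
        return np.polynomial.polynomial.polyval(np.asarray(temp, float),
                                                self.smr_curve)

    def mmr_at(self, temp):
        return np.polynomial.polynomial.polyval(np.asarray(temp, float),
                                                self.mmr_curve)


@dataclass
class SyntheticConfig:
    """Study-design knobs: cohort layout, grid extent, sampling effort."""

    n_individuals: int = 8  # per temperature treatment
    treatment_temps: tuple = (8.0, 12.0, 16.0, 20.0, 24.0)
    mass_range: tuple = (0.32, 1.55)  # kg
    # respirometry trace layout
    n_routine: int = 60  # ~20 h of 20-min cycles
    resting_fraction: float = 0.3  # routine cycles at true SMR
    activity_sd: float = 0.4  # half-normal multiplier sd on active cycles
    n_post_chase: int = 6
    n_hypoxia: int = 60  # max 5-min depletion cycles
    hypoxia_step: float = 2.5  # % saturation consumed per cycle at SMR
    salinity: float = 35.0
    # grid
    lon_bounds: tuple = (15.0, 25.0)
    lat_bounds: tuple = (-36.0, -26.0)
    resolution: float = 0.25  # degrees
    contemporary_years: tuple = (2005, 2009)
    future_years: tuple = (2095, 2099)
    seasonal_amp_temp: float = 1.5  # degC
    temp_range: tuple = (11.0, 27.0)  # annual-mean west -> east
    o2_sat_edge: float = 0.35  # saturation fraction at the hypoxic edge
    o2_sat_ramp: float = 0.3  # lon fraction over which saturation recovers
    warming_trend: float = 2.0  # degC added in the future block
    deox_trend: float = -0.10  # saturation-fraction change in the future block
    depth_max: float = 100.0  # bathymetry ramp, m
    # occurrences
    n_occurrences: int = 150
    label_noise: float = 0.02

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if not (0 < self.mass_range[0] <= self.mass_range[1]):
            raise ValueError("mass_range must be positive and ordered")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.items()})
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# respirometry cohorts


def _one_trial(trial_id: str, mass: float, temp: float, truth: PlantedTruth,
               config: SyntheticConfig, rng: np.random.Generator):
    smr = float(truth.smr_at(temp))
    mmr = float(truth.mmr_at(temp))
    po2crit = float(calibration.po2crit_predict(truth.phi_parameters(),
                                                temp, mass))
    sat_crit = po2_to_saturation(po2crit, temp, config.salinity)
    if not 0.0 < sat_crit < 100.0:
        raise ValueError(
            f"planted critical saturation {sat_crit:.1f}% at {temp} degC is "
            "outside (0, 100)%; adjust the planted law or treatments")
    noise = truth.noise_sd_mr

    def jitter(n):
        return 1.0 + noise * rng.standard_normal(n) if noise > 0 else np.ones(n)

    # routine: a fixed count of resting cycles pins the 0.2 quantile at SMR;
    # the rest carry one-sided (half-normal) activity elevation
    n_rout = config.n_routine
    n_rest = int(round(config.resting_fraction * n_rout))
    activity = np.ones(n_rout)
    activity[n_rest:] += np.abs(rng.standard_normal(n_rout - n_rest)) \
        * config.activity_sd
    rng.shuffle(activity)
    rows = [pd.DataFrame({
        "time_min": 20.0 * np.arange(n_rout),
        "mr": smr * activity * jitter(n_rout),
        "o2_sat": np.full(n_rout, 95.0),
        "phase": "routine"})]
    t0 = 20.0 * n_rout

    # post-chase: exponential decay from MMR
    n_pc = config.n_post_chase
    decay = np.exp(-0.15 * np.arange(n_pc))
    rows.append(pd.DataFrame({
        "time_min": t0 + 5.0 * np.arange(n_pc),
        "mr": mmr * decay * jitter(n_pc),
        "o2_sat": np.full(n_pc, 95.0),
        "phase": "post_chase"}))
    t0 += 5.0 * n_pc + 240.0  # recovery gap

    # progressive hypoxia in a closed respirometer: the fish depletes the
    # chamber, so the saturation drop per cycle tracks its metabolic rate —
    # constant above sat_crit (oxyregulation at SMR), slowing below it
    # (oxyconforming, a line through the origin hitting SMR at sat_crit).
    # Sampling therefore densifies below sat_crit, as in real trials.
    sats = []
    s = 90.0
    while len(sats) < config.n_hypoxia and s > 1.0:
        sats.append(s)
        s -= config.hypoxia_step * min(1.0, s / sat_crit)
    sats = np.asarray(sats)
    n_hyp = len(sats)
    base = np.where(sats >= sat_crit, smr, smr * sats / sat_crit)
    rows.append(pd.DataFrame({
        "time_min": t0 + 5.0 * np.arange(n_hyp),
        "mr": np.maximum(base * jitter(n_hyp), 0.0),
        "o2_sat": sats,
        "phase": "hypoxia"}))

    trial = RespirometryTrial(
        trial_id=trial_id, mass=mass, test_temp=temp,
        measurements=pd.concat(rows, ignore_index=True),
        area=str(rng.choice(["TNP", "PE"])),
        sex_stage=str(rng.choice(["F", "M", "F/I", "M/I", "unknown"],
                                 p=[0.2, 0.26, 0.41, 0.08, 0.05])),
        salinity=config.salinity)
    true_row = {"trial_id": trial_id, "mass": mass, "test_temp": temp,
                "smr_true": smr, "mmr_true": mmr,
                "o2crit_sat_true": sat_crit, "po2crit_true": po2crit}
    return trial, true_row


def generate_respirometry_cohort(config: SyntheticConfig, truth: PlantedTruth):
    """Simulate one respirometry cohort.

    Returns ``(trials, truth_table)``: a list of
    :class:`~metidx.respirometry.RespirometryTrial` (``n_individuals`` per
    treatment temperature, masses uniform over ``mass_range``) and a
    DataFrame of the per-trial planted SMR/MMR/O2crit values.
    """
    config.validate()
    rng = np.random.default_rng(truth.seed)
    trials, truths = [], []
    i = 0
    for temp in config.treatment_temps:
        for _ in range(config.n_individuals):
            mass = float(rng.uniform(*config.mass_range))
            trial, row = _one_trial(f"T{temp:g}_{i:03d}", mass, temp, truth,
                                    config, rng)
            trials.append(trial)
            truths.append(row)
            i += 1
    return trials, pd.DataFrame(truths)


# ---------------------------------------------------------------------------
# ocean grids


def _grid_coords(config: SyntheticConfig):
    res = config.resolution
    lon = np.arange(config.lon_bounds[0] + res / 2, config.lon_bounds[1], res)
    lat = np.arange(config.lat_bounds[0] + res / 2, config.lat_bounds[1], res)
    return lat, lon


def _months(years: tuple) -> pd.DatetimeIndex:
    return pd.date_range(f"{years[0]}-01-01", f"{years[1]}-12-01", freq="MS")


def generate_environment(config: SyntheticConfig, truth: PlantedTruth) -> dict:
    """Monthly gridded temperature, oxygen, salinity and depth fields.

    Annual-mean temperature ramps from cool at the western edge to warm at
    the eastern edge; the oxygen saturation fraction ramps up from a hypoxic
    western (upwelling-analogue) edge, so oxygen concentration tracks
    saturation times the temperature-dependent solubility.  A sinusoidal
    seasonal cycle rides on temperature; bathymetry ramps from 0 m at the
    northern edge to ``depth_max`` at the southern edge.  The future block
    adds the configured warming and deoxygenation trends.  The construction
    is deterministic given the config.

    Returns ``{"contemporary": Dataset, "future": Dataset}``, each with
    data variables ``temp`` (degC), ``o2`` (mmol m-3), ``sal`` (psu) over
    (time, lat, lon) and static ``depth`` (m) over (lat, lon).
    """
    config.validate()
    lat, lon = _grid_coords(config)
    fl = (lon - config.lon_bounds[0]) / (config.lon_bounds[1] - config.lon_bounds[0])
    fa = (lat - config.lat_bounds[0]) / (config.lat_bounds[1] - config.lat_bounds[0])
    t_lo, t_hi = config.temp_range
    temp_base = t_lo + (t_hi - t_lo) * fl[None, :] + 0.5 * fa[:, None]
    sat_frac = np.clip(
        config.o2_sat_edge + (1 - config.o2_sat_edge)
        * fl[None, :] / max(config.o2_sat_ramp, 1e-9), None, 1.0) \
        + 0.0 * fa[:, None]
    sal = 35.0 + 0.5 * fl[None, :] + 0.0 * fa[:, None]
    depth = (config.depth_max * (config.lat_bounds[1] - lat)
             / (config.lat_bounds[1] - config.lat_bounds[0]))[:, None] \
        + 0.0 * fl[None, :]

    out = {}
    for period, years, dtemp, dsat in (
            ("contemporary", config.contemporary_years, 0.0, 0.0),
            ("future", config.future_years, config.warming_trend,
             config.deox_trend)):
        times = _months(years)
        season = config.seasonal_amp_temp * np.sin(
            2 * np.pi * (times.month.to_numpy() - 1) / 12.0)
        temp = temp_base[None, :, :] + season[:, None, None] + dtemp
        sat3 = np.clip(sat_frac[None, :, :] + dsat, 0.02, 1.0) \
            + 0.0 * season[:, None, None]
        o2 = sat3 * env_layers.o2_solubility(temp, sal[None, :, :])
        coords = {"time": times, "lat": lat, "lon": lon}
        ds = xr.Dataset(
            {"temp": xr.DataArray(temp, coords=coords, dims=("time", "lat", "lon"),
                                  attrs={"units": "degC"}),
             "o2": xr.DataArray(o2, coords=coords, dims=("time", "lat", "lon"),
                                attrs={"units": "mmol m-3"}),
             "sal": xr.DataArray(np.broadcast_to(sal, temp.shape).copy(),
                                 coords=coords, dims=("time", "lat", "lon"),
                                 attrs={"units": "psu"}),
             "depth": xr.DataArray(np.broadcast_to(depth, (len(lat), len(lon))).copy(),
                                   coords={"lat": lat, "lon": lon},
                                   dims=("lat", "lon"),
                                   attrs={"units": "m below sea level"})})
        out[period] = ds
    return out


def phi_stack_from_env(env: xr.Dataset, params: PhiParameters,
                       mass: float = 1.0) -> xr.DataArray:
    """Monthly phi stack from an environment Dataset (conversion chain:
    depth -> pressure, O2 concentration -> pO2, then phi)."""
    lat2 = env["lat"].values[:, None] + 0.0 * env["lon"].values[None, :]
    press = env_layers.pressure_at_depth(env["depth"].values, lat2)
    po2 = env_layers.o2_conc_to_po2(env["o2"].values, env["temp"].values,
                                    env["sal"].values, press[None, :, :])
    po2_da = env["temp"].copy(data=po2)
    po2_da.attrs = {"units": "kPa"}
    return env_layers.compute_phi_layers(params, env["temp"], po2_da, mass=mass)


def generate_occurrences(env: dict | xr.Dataset, truth: PlantedTruth,
                         config: SyntheticConfig) -> pd.DataFrame:
    """Sample occurrence points from the planted suitability rule.

    A cell is suitable when its minimum monthly phi (1 kg reference mass,
    contemporary period) is >= ``truth.phi_crit_true`` and its depth lies in
    ``truth.depth_window``.  ``n_occurrences`` points are drawn uniformly
    over suitable cells (with replacement, to exercise deduplication) and
    jittered uniformly within their cell; a ``label_noise`` fraction is
    redrawn from unsuitable cells instead.

    Returns a DataFrame with columns lon, lat, and bookkeeping columns
    cell_ilat, cell_ilon, suitable_truth.
    """
    ds = env["contemporary"] if isinstance(env, dict) else env
    config.validate()
    phi_min = phi_stack_from_env(ds, truth.phi_parameters()).min("time")
    depth = ds["depth"]
    lo, hi = truth.depth_window
    suitable = (phi_min >= truth.phi_crit_true) & (depth >= lo) & (depth <= hi)
    suit = suitable.values
    if not suit.any():
        raise ValueError("no cell satisfies the planted suitability rule")

    rng = np.random.default_rng(truth.seed + 1)
    n = config.n_occurrences
    n_noise = int(round(config.label_noise * n))
    good = np.flatnonzero(suit)
    bad = np.flatnonzero(~suit)
    picks = rng.choice(good, size=n - n_noise, replace=True)
    if n_noise:
        picks = np.concatenate([picks, rng.choice(bad, size=n_noise,
                                                  replace=True)])
    ilat, ilon = np.divmod(picks, suit.shape[1])
    res = config.resolution
    lat_pts = ds["lat"].values[ilat] + rng.uniform(-res / 2, res / 2, size=n)
    lon_pts = ds["lon"].values[ilon] + rng.uniform(-res / 2, res / 2, size=n)
    return pd.DataFrame({
        "lon": lon_pts, "lat": lat_pts,
        "cell_ilat": ilat, "cell_ilon": ilon,
        "suitable_truth": suit.ravel()[picks]})
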