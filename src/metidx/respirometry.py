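"""Standard/maximum metabolic rate and critical oxygen level estimation.

Works on per-individual intermittent-flow respirometry traces in which each
measurement cycle has already been reduced to a mass-specific metabolic rate
(mg O2 min^-1 kg^-1) paired with the mean chamber oxygen saturation (% air
saturation) of that cycle.  Three phases are distinguished:

``routine``
    undisturbed normoxic measurements; the standard metabolic rate (SMR) is
    a lower quantile of these.
``post_chase``
    measurements immediately after a chase-to-exhaustion protocol; the
    maximum metabolic rate (MMR) is their maximum.
``hypoxia``
    progressive-hypoxia measurements used to locate the critical oxygen
    saturation (O2crit), the saturation below which SMR can no longer be
    met and the metabolic rate declines with ambient oxygen.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RespirometryTrial",
    "O2critResult",
    "estimate_smr",
    "estimate_mmr",
    "estimate_o2crit",
    "saturation_to_po2",
    "po2_to_saturation",
    "water_vapour_pressure",
    "process_trials",
    "read_trials_csv",
    "write_trials_csv",
]

PHASES = ("routine", "post_chase", "hypoxia")

#: mole fraction of O2 in dry air
X_O2 = 0.20946
#: default barometric pressure, kPa (laboratory pressure unreported; sea level standard)
BAROMETRIC_KPA = 101.325

ATM_KPA = 101.325


class TraceError(ValueError):
    """A respirometry trace does not support the requested estimate."""


@dataclass
class RespirometryTrial:
    """One individual's trace plus metadata.

    ``measurements`` is a DataFrame with columns ``time_min``, ``mr``,
    ``o2_sat`` and ``phase`` (one of :data:`PHASES`), ordered in time.
    """

    trial_id: str
    mass: float  # kg
    test_temp: float  # degC
    measurements: pd.DataFrame
    area: str = "unknown"
    sex_stage: str = "unknown"
    salinity: float = 35.0  # psu, chamber water
    barometric_kpa: float = BAROMETRIC_KPA

    def phase(self, name: str) -> pd.DataFrame:
        if name not in PHASES:
            raise ValueError(f"unknown phase {name!r}")
        return self.measurements[self.measurements["phase"] == name]

    def validate(self) -> None:
        m = self.measurements
        if (m["mr"] < 0).any():
            raise TraceError(f"{self.trial_id}: negative metabolic rate")
        if ((m["o2_sat"] < 0) | (m["o2_sat"] > 102)).any():
            raise TraceError(f"{self.trial_id}: saturation outside [0, 102]%")
        hyp = self.phase("hypoxia")
        if len(hyp) and (np.diff(hyp["o2_sat"].to_numpy()) > 1e-9).any():
            raise TraceError(f"{self.trial_id}: hypoxia saturations increase in time")
        if len(self.phase("routine")) < 10:
            raise TraceError(f"{self.trial_id}: fewer than 10 routine measurements")


@dataclass
class O2critResult:
    """Critical oxygen level of one trial, with the regression behind it."""

    trial_id: str
    smr: float
    o2crit_sat: float  # % air saturation
    po2crit: float  # kPa
    n_regression_points: int
    slope: float
    intercept: float
    r_squared: float
    adjusted_flag: bool = False
    notes: str = ""


def estimate_smr(trial: RespirometryTrial, quantile: float = 0.2,
                 method: str = "linear") -> float:
    """Standard metabolic rate: the ``quantile`` (default 0.2) of routine-phase
    rates, using linear interpolation between order statistics.
    """
    mr = trial.phase("routine")["mr"].to_numpy(float)
    if len(mr) < 10:
        raise TraceError(
            f"{trial.trial_id}: need >= 10 routine measurements, got {len(mr)}")
    return float(np.quantile(mr, quantile, method=method))


def estimate_mmr(trial: RespirometryTrial) -> float:
    """Maximum metabolic rate: the largest post-chase rate."""
    mr = trial.phase("post_chase")["mr"].to_numpy(float)
    if len(mr) == 0:
        raise TraceError(f"{trial.trial_id}: no post-chase measurements")
    return float(mr.max())


def _sub_smr_regression(sat: np.ndarray, mr: np.ndarray, n_points: int):
    """OLS of mr on saturation through the ``n_points`` lowest-saturation points."""
    order = np.argsort(sat, kind="stable")
    take = order[:n_points]
    res = stats.linregress(sat[take], mr[take])
    return res, len(take)


def estimate_o2crit(trial: RespirometryTrial, smr: float, max_points: int = 15,
                    alpha: float = 0.05, min_r_squared: float = 0.5,
                    force_adjust: bool | None = None) -> O2critResult:
    """Critical oxygen saturation as the intersection of the SMR line with the
    oxyconforming decline.

    Up to ``max_points`` of the lowest-saturation hypoxia measurements with
    mr < smr are regressed (OLS, mr = a + b*sat); O2crit is where the fitted
    line meets SMR.  If the regression slope is not significantly positive at
    ``alpha`` (one-sided) or R^2 < ``min_r_squared`` the fit is deemed
    contaminated by points above the true O2crit and is repeated with only
    the 4 lowest-saturation points (one more than the minimum for a
    regression), setting ``adjusted_flag``.  ``force_adjust`` overrides the
    heuristic per trial (True forces the 4-point refit, False disables it).
    """
    if smr <= 0:
        raise TraceError(f"{trial.trial_id}: non-positive SMR")
    hyp = trial.phase("hypoxia")
    if len(hyp) == 0:
        raise TraceError(f"{trial.trial_id}: no hypoxia phase")
    sub = hyp[hyp["mr"] < smr]
    if len(sub) < 3:
        raise TraceError(
            f"{trial.trial_id}: only {len(sub)} sub-SMR points (need >= 3)")
    sat = sub["o2_sat"].to_numpy(float)
    mr = sub["mr"].to_numpy(float)

    res, n_used = _sub_smr_regression(sat, mr, min(max_points, len(sat)))
    adjusted = False
    notes = ""

    def _flagged(r) -> bool:
        if r.slope <= 0:
            return True
        one_sided_p = r.pvalue / 2.0  # linregress p is two-sided
        return one_sided_p > alpha or r.rvalue ** 2 < min_r_squared

    trigger = _flagged(res) if force_adjust is None else force_adjust
    if trigger and n_used > 4:
        res, n_used = _sub_smr_regression(sat, mr, 4)
        adjusted = True
        notes = "overestimate heuristic triggered; refit with 4 points"
    elif trigger:
        notes = "heuristic triggered but <= 4 points available"

    if res.slope <= 0:
        raise TraceError(
            f"{trial.trial_id}: non-positive slope ({res.slope:.3g}) after "
            "adjustment; trace does not show an oxyconforming decline")

    o2crit_sat = (smr - res.intercept) / res.slope
    po2crit = saturation_to_po2(o2crit_sat, trial.test_temp, trial.salinity,
                                trial.barometric_kpa)
    return O2critResult(
        trial_id=trial.trial_id, smr=smr, o2crit_sat=float(o2crit_sat),
        po2crit=float(po2crit), n_regression_points=n_used,
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2), adjusted_flag=adjusted, notes=notes)


def water_vapour_pressure(temp: float | np.ndarray,
                          salinity: float | np.ndarray = 35.0):
    """Saturation water-vapour pressure over seawater, kPa.

    Weiss & Price (1980, Mar. Chem. 8:347) empirical fit:
    ln p[atm] = 24.4543 - 67.4509*(100/T) - 4.8489*ln(T/100) - 0.000544*S.
    """
    t = np.asarray(temp, float)
    if np.any(t < -2) or np.any(t > 40):
        raise ValueError("temperature outside -2..40 degC")
    T = t + 273.15
    ln_p = 24.4543 - 67.4509 * (100.0 / T) - 4.8489 * np.log(T / 100.0) \
        - 0.000544 * np.asarray(salinity, float)
    out = np.exp(ln_p) * ATM_KPA
    return float(out) if np.isscalar(temp) or np.ndim(temp) == 0 else out


def saturation_to_po2(sat, temp, salinity=35.0, barometric_kpa=BAROMETRIC_KPA):
    """Convert % air saturation to oxygen partial pressure (kPa).

    pO2 = (sat/100) * x_O2 * (P_baro - p_vapour(T, S)), i.e. the fraction of
    the partial pressure that air-equilibrated water holds at temperature
    ``temp`` under barometric pressure ``barometric_kpa``.
    """
    sat = np.asarray(sat, float)
    if np.any(sat < 0):
        raise ValueError("saturation must be >= 0")
    pv = water_vapour_pressure(temp, salinity)
    out = (sat / 100.0) * X_O2 * (np.asarray(barometric_kpa, float) - pv)
    return float(out) if out.ndim == 0 else out


def po2_to_saturation(po2, temp, salinity=35.0, barometric_kpa=BAROMETRIC_KPA):
    """Inverse of :func:`saturation_to_po2`."""
    po2 = np.asarray(po2, float)
    pv = water_vapour_pressure(temp, salinity)
    out = 100.0 * po2 / (X_O2 * (np.asarray(barometric_kpa, float) - pv))
    return float(out) if out.ndim == 0 else out


def process_trials(trials, max_points: int = 15,
                   overrides: dict[str, bool] | None = None) -> pd.DataFrame:
    """Run SMR/MMR/O2crit estimation over a collection of trials.

    ``overrides`` maps trial_id -> force_adjust for manual per-trial control
    of the overestimate heuristic.  Returns one row per trial.
    """
    overrides = overrides or {}
    rows = []
    for trial in trials:
        trial.validate()
        smr = estimate_smr(trial)
        try:
            mmr = estimate_mmr(trial)
        except TraceError:
            mmr = math.nan
        res = estimate_o2crit(trial, smr, max_points=max_points,
                              force_adjust=overrides.get(trial.trial_id))
        rows.append({
            "trial_id": trial.trial_id, "mass": trial.mass,
            "test_temp": trial.test_temp, "area": trial.area,
            "sex_stage": trial.sex_stage, "smr": smr, "mmr": mmr,
            "o2crit_sat": res.o2crit_sat, "po2crit": res.po2crit,
            "n_regression_points": res.n_regression_points,
            "slope": res.slope, "intercept": res.intercept,
            "r_squared": res.r_squared, "adjusted_flag": res.adjusted_flag,
        })
    return pd.DataFrame(rows)


def write_trials_csv(trials, path) -> None:
    """Tidy CSV: one row per measurement with trial metadata repeated."""
    frames = []
    for t in trials:
        df = t.measurements.copy()
        df.insert(0, "trial_id", t.trial_id)
        df["mass"] = t.mass
        df["test_temp"] = t.test_temp
        df["area"] = t.area
        df["sex_stage"] = t.sex_stage
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trials_csv(path) -> list[RespirometryTrial]:
    """Read the tidy per-measurement CSV written by :func:`write_trials_csv`."""
    df = pd.read_csv(path)
    trials = []
    for tid, g in df.groupby("trial_id", sort=False):
        g = g.reset_index(drop=True)
        trials.append(RespirometryTrial(
            trial_id=str(tid), mass=float(g["mass"].iloc[0]),
            test_temp=float(g["test_temp"].iloc[0]),
            area=str(g["area"].iloc[0]) if "area" in g else "unknown",
            sex_stage=str(g["sex_stage"].iloc[0]) if "sex_stage" in g else "unknown",
            measurements=g[["time_min", "mr", "o2_sat", "phase"]].copy()))
    return trials
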