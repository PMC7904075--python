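"""Piecewise Arrhenius calibration of the metabolic index.

The metabolic index phi is the ratio of environmental oxygen supply (ambient
pO2, kPa) to resting oxygen demand, where demand is the critical oxygen
partial pressure pO2crit — the minimum pO2 that sustains a standard
metabolic rate.  Demand depends on body mass B (kg) through a power law and
on temperature through an Arrhenius term evaluated on the coordinate
x = 1/(k_B * T) with k_B the Boltzmann constant in eV K^-1:

    pO2crit(T, B) = B**n * A_o * exp(E_o * x(T))
    phi(T, B, pO2) = pO2 / pO2crit(T, B)

Hypoxia tolerance can be *bidirectional*: pO2crit minimal at an intermediate
temperature and rising both above and below it.  The model is therefore fit
piecewise around a breakpoint temperature (default 12 degC), one (A_o, E_o)
pair per branch, by ordinary least squares of ln(pO2crit / B**n) on x.  The
branch above the breakpoint has E_o < 0 (demand rises with warming); the
branch below has E_o > 0 (tolerance worsens on cooling).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
import yaml
from scipy import stats

__all__ = [
    "K_B",
    "PhiParameters",
    "arrhenius_coordinate",
    "fit_mass_exponent",
    "fit_piecewise_arrhenius",
    "po2crit_predict",
    "phi",
    "test_group_effects",
    "published_parameters",
]

#: Boltzmann constant, eV K^-1
K_B = 8.617333e-5

CELSIUS_OFFSET = 273.15


def arrhenius_coordinate(temp):
    """Inverse thermal energy 1/(k_B T), in 1/eV, with T = temp + 273.15 K."""
    t = np.asarray(temp, float)
    if np.any(t <= -CELSIUS_OFFSET):
        raise ValueError("temperature at or below absolute zero")
    out = 1.0 / (K_B * (t + CELSIUS_OFFSET))
    return float(out) if out.ndim == 0 else out


@dataclass
class BranchFit:
    A_o: float
    E_o: float  # eV
    r_squared: float = float("nan")
    resid_sd: float = float("nan")
    n_obs: int = 0

    @property
    def ln_A_o(self) -> float:
        return float(np.log(self.A_o))


@dataclass
class PhiParameters:
    """Calibrated piecewise metabolic-index parameters.

    ``upper`` applies at temperatures >= ``breakpoint_temp`` (the breakpoint
    itself belongs to the upper branch for prediction), ``lower`` below it.
    """

    upper: BranchFit
    lower: BranchFit
    mass_exponent: float = 0.0
    breakpoint_temp: float = 12.0
    continuity_tol: float = 0.05  # relative branch disagreement tolerated at breakpoint

    def __post_init__(self):
        if isinstance(self.upper, dict):
            self.upper = BranchFit(**self.upper)
        if isinstance(self.lower, dict):
            self.lower = BranchFit(**self.lower)
        self.check()

    def branch(self, temp: float) -> BranchFit:
        return self.upper if temp >= self.breakpoint_temp else self.lower

    def continuity_gap(self) -> float:
        """Absolute difference between branch pO2crit values at the breakpoint (kPa)."""
        x = arrhenius_coordinate(self.breakpoint_temp)
        up = self.upper.A_o * np.exp(self.upper.E_o * x)
        lo = self.lower.A_o * np.exp(self.lower.E_o * x)
        return float(abs(up - lo))

    def check(self) -> None:
        temps = np.linspace(5.0, 30.0, 101)
        pred = po2crit_predict(self, temps, 1.0)
        if np.any(~np.isfinite(pred)) or np.any(pred <= 0):
            raise ValueError("predicted pO2crit not positive over 5-30 degC")
        x = arrhenius_coordinate(self.breakpoint_temp)
        up = self.upper.A_o * np.exp(self.upper.E_o * x)
        if self.continuity_gap() > self.continuity_tol * up:
            warnings.warn(
                f"branch pO2crit disagree by {self.continuity_gap():.3g} kPa "
                f"at {self.breakpoint_temp} degC (> {self.continuity_tol:.0%})",
                stacklevel=3)

    # -- exchange format -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PhiParameters":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def published_parameters() -> PhiParameters:
    """The calibrated parameters for Chrysoblephus laticeps (roman seabream):
    breakpoint 12 degC, upper branch A_o = 1.55951e9, E_o = -0.4885 eV, lower
    branch A_o = 5.109275e-18, E_o = 1.01 eV, mass exponent n = 0.17.
    """
    return PhiParameters(
        upper=BranchFit(A_o=1.55951e9, E_o=-0.4885),
        lower=BranchFit(A_o=5.109275e-18, E_o=1.01),
        mass_exponent=0.17, breakpoint_temp=12.0)


def po2crit_predict(params: PhiParameters, temp, mass=1.0):
    """Predicted critical oxygen partial pressure (kPa) at ``temp`` (degC)
    for a fish of ``mass`` (kg): B**n * A_o * exp(E_o / (k_B T)), branch
    selected by temperature (breakpoint -> upper branch)."""
    t = np.asarray(temp, float)
    x = arrhenius_coordinate(t)
    upper = t >= params.breakpoint_temp
    ln_a = np.where(upper, params.upper.ln_A_o, params.lower.ln_A_o)
    e_o = np.where(upper, params.upper.E_o, params.lower.E_o)
    out = np.asarray(mass, float) ** params.mass_exponent * np.exp(ln_a + e_o * x)
    return float(out) if out.ndim == 0 else out


def phi(params: PhiParameters, temp, mass, po2):
    """Metabolic index: ambient pO2 (kPa) over predicted pO2crit."""
    po2 = np.asarray(po2, float)
    if np.any(po2[np.isfinite(po2)] < 0):
        raise ValueError("pO2 must be >= 0")
    out = po2 / po2crit_predict(params, temp, mass)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# fitting


def _check_dataset(data: pd.DataFrame) -> pd.DataFrame:
    required = {"po2crit", "mass", "test_temp"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"calibration dataset missing columns {sorted(missing)}")
    if (data["po2crit"] <= 0).any():
        raise ValueError("po2crit must be positive")
    return data


def _branch_masks(temps: np.ndarray, breakpoint: float):
    # data at exactly the breakpoint enter both branch fits
    return temps >= breakpoint, temps <= breakpoint


def _fit_branch(x: np.ndarray, y: np.ndarray, label: str) -> BranchFit:
    if len(np.unique(np.round(x, 12))) < 2:
        raise ValueError(f"{label} branch: zero variance in Arrhenius coordinate")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    dof = max(len(x) - 2, 1)
    return BranchFit(A_o=float(np.exp(res.intercept)), E_o=float(res.slope),
                     r_squared=float(res.rvalue ** 2),
                     resid_sd=float(np.sqrt(np.sum(resid ** 2) / dof)),
                     n_obs=len(x))


def fit_piecewise_arrhenius(data: pd.DataFrame, mass_exponent: float,
                            breakpoint: float = 12.0,
                            min_temps_per_branch: int = 2) -> PhiParameters:
    """Fit (A_o, E_o) per branch by OLS of ln(po2crit / B**n) on 1/(k_B T).

    ``data`` needs columns po2crit (kPa), mass (kg), test_temp (degC).
    Rows at exactly the breakpoint temperature contribute to both branches.
    At least ``min_temps_per_branch`` distinct temperatures are required per
    branch (two identify a line; a warning is issued below three).
    """
    data = _check_dataset(data)
    temps = data["test_temp"].to_numpy(float)
    x = arrhenius_coordinate(temps)
    y = np.log(data["po2crit"].to_numpy(float)
               / data["mass"].to_numpy(float) ** mass_exponent)

    fits = {}
    for label, mask in zip(("upper", "lower"), _branch_masks(temps, breakpoint)):
        n_temps = len(np.unique(temps[mask]))
        if n_temps < min_temps_per_branch:
            raise ValueError(
                f"{label} branch has {n_temps} distinct temperatures "
                f"(need >= {min_temps_per_branch})")
        if n_temps < 3:
            warnings.warn(f"{label} branch fit rests on only {n_temps} "
                          "distinct temperatures", stacklevel=2)
        fits[label] = _fit_branch(x[mask], y[mask], label)

    return PhiParameters(upper=fits["upper"], lower=fits["lower"],
                         mass_exponent=float(mass_exponent),
                         breakpoint_temp=float(breakpoint))


@dataclass
class MassExponentFit:
    n: float
    n_se: float
    iterations: int
    converged: bool
    history: list = field(default_factory=list)


def fit_mass_exponent(data: pd.DataFrame, breakpoint: float = 12.0,
                      tol: float = 1e-4, max_iter: int = 20) -> MassExponentFit:
    """Best-fit mass scaling exponent n of the pO2crit ~ B**n power law.

    Alternates (a) branch-specific Arrhenius fits of the mass-standardized
    pO2crit at the current n with (b) an OLS fit of the temperature-
    standardized log residual on ln B, whose slope is the updated n, until
    |delta n| < ``tol``.
    """
    data = _check_dataset(data)
    if len(data) < 10:
        raise ValueError(f"need >= 10 rows, got {len(data)}")
    mass = data["mass"].to_numpy(float)
    ratio = mass.max() / mass.min()
    if ratio < 1.1:
        raise ValueError(
            f"degenerate mass range ({ratio:.3f}-fold); cannot identify n")
    if ratio < 2.0:
        warnings.warn(f"mass range spans only {ratio:.2f}-fold; "
                      "n is weakly identified", stacklevel=2)

    temps = data["test_temp"].to_numpy(float)
    x = arrhenius_coordinate(temps)
    ln_po2 = np.log(data["po2crit"].to_numpy(float))
    ln_b = np.log(mass)
    upper_mask, _ = _branch_masks(temps, breakpoint)

    n = 0.0
    history = []
    converged = False
    n_se = float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # branch-count warnings handled by caller
        for it in range(1, max_iter + 1):
            params = fit_piecewise_arrhenius(data, mass_exponent=n,
                                             breakpoint=breakpoint)
            ln_a = np.where(upper_mask, params.upper.ln_A_o, params.lower.ln_A_o)
            e_o = np.where(upper_mask, params.upper.E_o, params.lower.E_o)
            # temperature-standardized log pO2crit = const + n*lnB + noise
            z = ln_po2 - (ln_a + e_o * x)
            res = stats.linregress(ln_b, z)
            new_n = float(res.slope)
            history.append(new_n)
            delta, n = abs(new_n - n), new_n
            if delta < tol:
                converged = True
                n_se = float(res.stderr)
                break
    if not converged:
        raise RuntimeError(f"mass-exponent fit did not converge in {max_iter} "
                           f"iterations (last n = {n:.4f})")
    return MassExponentFit(n=n, n_se=n_se, iterations=it, converged=True,
                           history=history)


def calibrate(data: pd.DataFrame, breakpoint: float = 12.0) -> PhiParameters:
    """Full calibration: fit n, then the piecewise Arrhenius branches."""
    nfit = fit_mass_exponent(data, breakpoint=breakpoint)
    return fit_piecewise_arrhenius(data, nfit.n, breakpoint=breakpoint)


# ---------------------------------------------------------------------------
# pooling checks


@dataclass
class GroupEffectReport:
    factor: str
    temp_range: tuple
    n_obs: int
    levels: list
    additive_F: float
    additive_p: float
    interaction_F: float
    interaction_p: float

    @property
    def pooling_justified(self) -> bool:
        """Neither the additive nor the interaction term significant at 0.05."""
        return self.additive_p > 0.05 and self.interaction_p > 0.05


def test_group_effects(data: pd.DataFrame, factor: str,
                       temp_range: tuple = (12.0, 24.0)) -> GroupEffectReport:
    """Linear model po2crit ~ temp * factor on the restricted temperature
    range; F tests (type II) for the additive factor effect and its
    interaction with temperature, to decide whether groups can be pooled.
    """
    data = _check_dataset(data)
    if factor not in data.columns:
        raise ValueError(f"factor column {factor!r} not in dataset")
    lo, hi = temp_range
    sub = data[(data["test_temp"] >= lo) & (data["test_temp"] <= hi)].copy()
    levels = sorted(sub[factor].astype(str).unique())
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has {len(levels)} level(s) within "
                         f"{temp_range}; need >= 2")
    sub["_factor"] = sub[factor].astype(str)
    model = smf.ols("po2crit ~ test_temp * C(_factor)", data=sub).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    add = anova.loc["C(_factor)"]
    inter = anova.loc["test_temp:C(_factor)"]
    return GroupEffectReport(
        factor=factor, temp_range=tuple(temp_range), n_obs=len(sub),
        levels=levels,
        additive_F=float(add["F"]), additive_p=float(add["PR(>F)"]),
        interaction_F=float(inter["F"]), interaction_p=float(inter["PR(>F)"]))
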