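"""Mechanics observables of a tensile test.

Works on the time series produced by :func:`fibrilsim.engine.tensile_test`:
engineering stress-strain curve, peak stress, work to failure
``W_f = integral(sigma d eps)``, the stiffened-regime stress gain
``delta_sigma = sigma_peak - sigma(eps_0)`` with ``eps_0`` the end of the
initial linear regime (0.15 by default), per-class mean bond forces, the
cumulative failure census per bond class, and the decomposition of global
strain into molecular stretching (mean TC-bond strain ``eps_TC``) and
inter-molecular sliding (``delta_eps = eps - eps_TC``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .engine import TensileResult
from .units import KCAL_PER_MOL_A3_TO_MPA

#: Default end of the initial linear elastic regime (engineering strain).
DEFAULT_EPS0 = 0.15


@dataclass
class StressStrainCurve:
    """Engineering stress-strain record (stress in kcal/mol/A^3 and MPa)."""

    strain: np.ndarray
    stress: np.ndarray
    smoothing_window: int = 0  # records; 0 = raw

    @property
    def stress_mpa(self) -> np.ndarray:
        return self.stress * KCAL_PER_MOL_A3_TO_MPA

    def interpolate(self, strain):
        return np.interp(strain, self.strain, self.stress)


@dataclass
class MechanicalSummary:
    sigma_peak: float
    strain_at_peak: float
    work_to_failure: float
    eps0: float
    sigma0: Optional[float]
    delta_sigma: Optional[float]
    failure_strain: float

    def to_dict(self) -> dict:
        return {
            "sigma_peak": self.sigma_peak,
            "sigma_peak_mpa": self.sigma_peak * KCAL_PER_MOL_A3_TO_MPA,
            "strain_at_peak": self.strain_at_peak,
            "work_to_failure": self.work_to_failure,
            "eps0": self.eps0,
            "sigma0": self.sigma0,
            "delta_sigma": self.delta_sigma,
            "delta_sigma_mpa": (
                self.delta_sigma * KCAL_PER_MOL_A3_TO_MPA
                if self.delta_sigma is not None
                else None
            ),
            "failure_strain": self.failure_strain,
        }


def stress_strain(
    ts: pd.DataFrame,
    area: Optional[float] = None,
    smoothing_window: int = 0,
) -> StressStrainCurve:
    """Stress-strain curve from a tensile time series.

    If ``area`` is given the stress is recomputed as force/area; otherwise
    the engine's stress column is used.  ``smoothing_window`` applies a
    centered moving average over that many records (recorded in the output
    metadata; 0 disables smoothing).
    """
    strain = ts["strain"].to_numpy()
    if area is not None:
        if area <= 0:
            raise ValueError("cross-section area must be positive")
        stress = ts["force"].to_numpy() / area
    else:
        stress = ts["stress"].to_numpy()
    if smoothing_window and smoothing_window > 1:
        stress = (
            pd.Series(stress)
            .rolling(smoothing_window, center=True, min_periods=1)
            .mean()
            .to_numpy()
        )
    return StressStrainCurve(strain, stress, smoothing_window)


def summarize(curve: StressStrainCurve, eps0: float = DEFAULT_EPS0) -> MechanicalSummary:
    """Peak stress, work to failure and the stiffened-regime stress gain."""
    strain, stress = curve.strain, curve.stress
    ipk = int(np.argmax(stress))
    sigma_peak = float(stress[ipk])
    wf = float(np.trapezoid(stress, strain))
    if strain[-1] >= eps0 and strain[0] <= eps0:
        sigma0 = float(np.interp(eps0, strain, stress))
        delta = sigma_peak - sigma0
    else:
        sigma0 = None
        delta = None
    return MechanicalSummary(
        sigma_peak=sigma_peak,
        strain_at_peak=float(strain[ipk]),
        work_to_failure=wf,
        eps0=eps0,
        sigma0=sigma0,
        delta_sigma=delta,
        failure_strain=float(strain[-1]),
    )


def bond_class_mean_forces(ts: pd.DataFrame) -> pd.DataFrame:
    """Mean tension per intact bond of each class versus strain.

    Classes absent from the system are NaN throughout.  TC means cover
    helical-domain bonds only (extension bonds are excluded by the engine).
    """
    cols = {"strain": ts["strain"]}
    for key in ("tc", "ecl", "age"):
        col = f"f_{key}"
        cols[col] = ts[col] if col in ts else np.nan
    return pd.DataFrame(cols)


def failure_census(result: TensileResult) -> pd.DataFrame:
    """Cumulative broken fraction per bond class versus strain (in [0, 1])."""
    ts = result.timeseries
    out = {"strain": ts["strain"].to_numpy()}
    for key in ("tc", "ecl", "age"):
        n0 = result.initial_counts.get(key, 0)
        if n0 > 0:
            out[f"frac_{key}"] = ts[f"broken_{key}"].to_numpy() / n0
        else:
            out[f"frac_{key}"] = np.full(len(ts), np.nan)
    return pd.DataFrame(out)


def strain_decomposition(ts: pd.DataFrame) -> pd.DataFrame:
    """Split global strain into TC stretching and inter-molecular sliding.

    ``eps_tc`` is the mean strain of intact helical-domain bonds; the sliding
    contribution is ``delta_eps = eps - eps_tc`` identically.
    """
    eps = ts["strain"].to_numpy()
    eps_tc = ts["eps_tc"].to_numpy()
    return pd.DataFrame({"strain": eps, "eps_tc": eps_tc, "delta_eps": eps - eps_tc})


def stiffening_onset(
    curve: StressStrainCurve,
    fit_max_strain: float = 0.08,
    deviation: float = 0.10,
    min_strain: float = 0.0,
) -> float:
    """Strain at which the response departs from the initial linear regime.

    The initial stiffness E0 is a zero-intercept least-squares fit over
    ``[min_strain, fit_max_strain]``; the onset is the first strain beyond the
    fit range where the secant stiffness sigma/eps deviates from E0 by more
    than ``deviation`` (fractional).  Returns NaN when no departure occurs.
    """
    strain, stress = curve.strain, curve.stress
    fit = (strain >= min_strain) & (strain <= fit_max_strain) & (strain > 0)
    if fit.sum() < 3:
        raise ValueError("curve does not cover the linear fit range")
    e0 = float(np.sum(stress[fit] * strain[fit]) / np.sum(strain[fit] ** 2))
    if e0 <= 0:
        return float("nan")
    beyond = strain > fit_max_strain
    secant = np.full_like(strain, np.nan)
    secant[beyond] = stress[beyond] / strain[beyond]
    dev = np.abs(secant / e0 - 1.0)
    hit = np.nonzero(beyond & (dev > deviation))[0]
    return float(strain[hit[0]]) if len(hit) else float("nan")
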