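"""Health-related quality of life, mortality and QALY accrual.

Utility per cycle comes from a published linear regression on age, age
squared, autism symptom severity (ADOS), log cognitive ability and adaptive
behaviour.  By default the IQ and ADOS terms are held at their baseline
values (they entered the source algorithm as baseline predictors) while VABS
and age vary over time; a flag lets the IQ term track the cohort mean
instead.

Mortality applies a relative risk for autistic people to general-population
annual death probabilities on the hazard scale; it is identical in both
arms.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cohort
from .parameters import ModelSettings, ParameterError, ParameterSet

__all__ = [
    "UtilityModel",
    "MortalityModel",
    "utility",
    "utility_model",
    "mortality_model",
    "read_life_table",
    "survival_curve",
    "total_qalys",
]


@dataclass(frozen=True)
class UtilityModel:
    constant: float
    b_age: float
    b_age2: float
    b_ados: float
    b_log_iq: float
    b_vabs: float
    cap_at_one: bool = True
    time_varying_iq: bool = False


def utility_model(params: ParameterSet) -> UtilityModel:
    g = "utility_model"
    flags = params.utility_flags
    return UtilityModel(
        constant=params.value(f"{g}.constant"),
        b_age=params.value(f"{g}.b_age"),
        b_age2=params.value(f"{g}.b_age2"),
        b_ados=params.value(f"{g}.b_ados"),
        b_log_iq=params.value(f"{g}.b_log_iq"),
        b_vabs=params.value(f"{g}.b_vabs"),
        cap_at_one=bool(flags.get("cap_at_one", True)),
        time_varying_iq=bool(flags.get("time_varying_iq", False)),
    )


def utility(model: UtilityModel, age_years, ados, iq, vabs):
    """Predicted utility at the given state (vectorised; capped at 1)."""
    iq = np.asarray(iq, dtype=float)
    if np.any(iq <= 0):
        raise ParameterError("utility model requires IQ > 0 (log term)")
    age = np.asarray(age_years, dtype=float)
    u = (
        model.constant
        + model.b_age * age
        + model.b_age2 * age ** 2
        + model.b_ados * np.asarray(ados, dtype=float)
        + model.b_log_iq * np.log(iq)
        + model.b_vabs * np.asarray(vabs, dtype=float)
    )
    if model.cap_at_one:
        u = np.minimum(u, 1.0)
    return u if u.ndim else float(u)


@dataclass
class MortalityModel:
    """Life table (age in whole years -> annual death probability) + RR."""

    life_table: pd.Series
    relative_risk: float = 1.0

    def __post_init__(self) -> None:
        qx = self.life_table.to_numpy(dtype=float)
        if np.any((qx < 0) | (qx > 1)):
            raise ParameterError("life-table qx values must lie in [0, 1]")
        if self.relative_risk < 0:
            raise ParameterError("relative risk must be non-negative")

    def qx(self, age_years: int) -> float:
        try:
            return float(self.life_table.loc[int(age_years)])
        except KeyError as exc:
            raise ParameterError(
                f"life table has no entry for age {age_years}"
            ) from exc


def read_life_table(path) -> pd.Series:
    """Read a life-table CSV with columns ``age,qx`` (header required)."""
    df = pd.read_csv(path)
    if not {"age", "qx"} <= set(df.columns):
        raise ParameterError("life table must have columns 'age' and 'qx'")
    return df.set_index(df["age"].astype(int))["qx"].astype(float)


def mortality_model(params: ParameterSet) -> MortalityModel:
    """Build the configured mortality model (file-based or synthetic table)."""
    from .synthetic import SyntheticLifeTable  # avoid import cycle

    m = params.mortality
    if m.get("life_table"):
        table = read_life_table(m["life_table"])
    else:
        table = SyntheticLifeTable(
            makeham=m["makeham"],
            gompertz_a=m["gompertz_a"],
            gompertz_b=m["gompertz_b"],
        ).table()
    return MortalityModel(life_table=table, relative_risk=m["relative_risk"])


def survival_curve(
    model: MortalityModel, start_age_years: float, horizon_months: int
) -> np.ndarray:
    """Survivor fractions at months 0..horizon from ``start_age_years``.

    The annual probability ``qx`` converts to a monthly hazard
    ``-ln(1 - qx)/12``; the relative risk multiplies on the hazard scale, so
    the per-month survival factor is ``exp(-RR * (-ln(1 - qx)) / 12)``.
    """
    ages = np.floor(start_age_years + np.arange(horizon_months) / 12.0).astype(int)
    qx = np.array([model.qx(a) for a in ages])
    monthly_factor = np.exp(-model.relative_risk * (-np.log1p(-qx)) / 12.0)
    surv = np.ones(horizon_months + 1)
    surv[1:] = np.cumprod(monthly_factor)
    return surv


def total_qalys(
    traj: cohort.TrajectoryResult,
    umodel: UtilityModel,
    settings: ModelSettings,
    iq0: float | None = None,
) -> float:
    """Discounted QALYs for one arm's trajectory.

    Flows are evaluated per cycle as the mean of the endpoint utilities
    (trapezoid) weighted by mid-cycle survival, then discounted at cycle
    midpoints.  ``iq0`` is the baseline IQ used when the IQ term is frozen;
    defaults to the trajectory's starting IQ.
    """
    iq = traj.iq if umodel.time_varying_iq else (
        iq0 if iq0 is not None else float(traj.iq[0])
    )
    u = utility(umodel, traj.age_months / 12.0, traj.ados, iq, traj.vabs)
    u = np.broadcast_to(np.asarray(u, dtype=float), traj.month.shape)
    flow = 0.5 * (u[:-1] + u[1:]) * 0.5 * (traj.survival[:-1] + traj.survival[1:])
    return cohort.accumulate(
        flow / 12.0, settings.discount_rate_annual, settings.discounting_mode
    )
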