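"""Cohort trajectories and discounted accumulation.

The model tracks cohort-mean IQ and adaptive-behaviour (VABS) scores in
monthly cycles from age 3 to 18.5 years.  Under treatment-as-usual both
scores drift linearly (small annual declines); the intervention arm adds a
piecewise-linear treatment effect that ramps from zero to the one-year and
two-year effect estimates and then either persists (optimistic durability)
or washes out linearly to zero by the configured washout month, seven years
into the model by default (pessimistic durability).

All downstream accruals use mid-cycle discounting (half-cycle correction):
each cycle's flow is discounted at the midpoint of the cycle.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .parameters import ParameterError, ParameterSet

__all__ = [
    "CohortState",
    "TrajectoryResult",
    "tau_score",
    "treatment_effect",
    "build_trajectory",
    "discount_factor",
    "accumulate",
]

BASELINE_AGE_MONTHS = 36


class CohortState(NamedTuple):
    month: int
    age_months: float
    iq: float
    vabs: float
    ados: float
    survival: float


def tau_score(t, score0: float, annual_change: float):
    """Linear natural-history score at month ``t`` (vectorised)."""
    t = np.asarray(t, dtype=float)
    out = score0 + annual_change * t / 12.0
    return out if out.ndim else float(out)


def treatment_effect(
    t,
    effect_y1: float,
    effect_y2: float,
    durability: str,
    washout_end: float = 84,
):
    """Piecewise-linear additive treatment effect at month ``t``.

    Ramps 0 -> ``effect_y1`` over the first 12 months and on to ``effect_y2``
    at 24 months.  Beyond the treatment period the effect either persists
    (``optimistic``) or decays linearly to zero at ``washout_end``
    (``pessimistic``).
    """
    if durability not in ("optimistic", "pessimistic"):
        raise ParameterError(f"unknown durability {durability!r}")
    if durability == "pessimistic" and washout_end <= 24:
        raise ParameterError("washout must end after the 24-month effect point")
    t = np.asarray(t, dtype=float)
    ramp1 = effect_y1 * t / 12.0
    ramp2 = effect_y1 + (effect_y2 - effect_y1) * (t - 12.0) / 12.0
    eff = np.where(t <= 12.0, ramp1, np.where(t <= 24.0, ramp2, effect_y2))
    if durability == "pessimistic":
        decay = effect_y2 * (washout_end - t) / (washout_end - 24.0)
        eff = np.where(t > 24.0, np.maximum(decay, 0.0), eff)
    return eff if eff.ndim else float(eff)


@dataclass
class TrajectoryResult:
    """Monthly cohort states for one arm under one durability scenario."""

    arm: str
    durability: str
    month: np.ndarray
    iq: np.ndarray
    vabs: np.ndarray
    ados: float
    survival: np.ndarray

    @property
    def age_months(self) -> np.ndarray:
        return BASELINE_AGE_MONTHS + self.month

    def state(self, t: int) -> CohortState:
        return CohortState(
            month=int(self.month[t]),
            age_months=float(self.age_months[t]),
            iq=float(self.iq[t]),
            vabs=float(self.vabs[t]),
            ados=self.ados,
            survival=float(self.survival[t]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "month": self.month,
                "arm": self.arm,
                "age_months": self.age_months,
                "iq": self.iq,
                "vabs": self.vabs,
                "ados": self.ados,
                "survival": self.survival,
            }
        )


def build_trajectory(
    params: ParameterSet,
    arm: str,
    durability: str,
    survival: np.ndarray | None = None,
) -> TrajectoryResult:
    """Evolve cohort-mean scores over the childhood horizon for one arm."""
    if arm not in ("TAU", "ABA"):
        raise ParameterError(f"unknown arm {arm!r}")
    st = params.settings
    months = np.arange(st.horizon_months + 1)
    iq = tau_score(months, params.value("baseline.iq0"),
                   params.value("natural_history.d_iq_per_year"))
    vabs = tau_score(months, params.value("baseline.vabs0"),
                     params.value("natural_history.d_vabs_per_year"))
    if arm == "ABA":
        wash = st.pessimistic_washout_end_months
        iq = iq + treatment_effect(
            months, params.value("effect_y1.iq"), params.value("effect_y2.iq"),
            durability, wash)
        vabs = vabs + treatment_effect(
            months, params.value("effect_y1.vabs"),
            params.value("effect_y2.vabs"), durability, wash)
    if np.any(iq <= 0):
        raise ParameterError("cohort IQ fell to zero or below over the horizon")
    if survival is None:
        survival = np.ones_like(iq)
    return TrajectoryResult(
        arm=arm,
        durability=durability,
        month=months,
        iq=iq,
        vabs=vabs,
        ados=params.value("baseline.ados0"),
        survival=np.asarray(survival, dtype=float),
    )


def discount_factor(t, rate: float, mode: str = "monthly"):
    """Discount factor at model month ``t`` for an annual ``rate``.

    ``monthly`` discounts continuously in months, ``(1+r)**(-t/12)``;
    ``annual`` steps the factor once per completed model year.
    """
    if rate <= -1:
        raise ParameterError("discount rate must exceed -100%")
    t = np.asarray(t, dtype=float)
    if mode == "monthly":
        out = (1.0 + rate) ** (-t / 12.0)
    elif mode == "annual":
        out = (1.0 + rate) ** (-np.floor(t / 12.0))
    else:
        raise ParameterError(f"unknown discounting mode {mode!r}")
    return out if out.ndim else float(out)


def accumulate(
    values, rate: float, mode: str = "monthly", start_month: int = 0
) -> float:
    """Discounted total of per-cycle flows with half-cycle correction.

    ``values[t]`` is the flow accruing during cycle ``start_month + t``; it
    is discounted at the cycle midpoint (``start_month + t + 0.5``), always
    relative to model start.
    """
    values = np.asarray(values, dtype=float)
    mid = start_month + np.arange(values.shape[-1]) + 0.5
    return float(np.sum(values * discount_factor(mid, rate, mode), axis=-1))
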