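"""Cost flows and discounted totals by category and perspective.

Childhood costs fall into three categories: intervention provision (the
intensive programme in one arm, nursery-style usual provision in the other),
schooling (unit cost per education setting weighted by the placement mix)
and social-care/medical costs predicted from cohort scores by a linear
regression.  The NHS & social-services perspective counts intervention and
social/medical costs; the public-sector perspective adds schooling.  Adult
care costs only arise in the lifetime scenario.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import cohort
from .education import EducationMix
from .parameters import ModelSettings, ParameterError, ParameterSet

__all__ = [
    "CostParameters",
    "CostBreakdown",
    "cost_parameters",
    "intervention_cost_flow",
    "socmed_annual",
    "schooling_cost_flow",
    "total_costs",
]

PERSPECTIVES = ("nhs_social", "public_sector")


@dataclass(frozen=True)
class CostParameters:
    aba_annual: float
    tau_annual: float
    school_mainstream: float
    school_supported: float
    school_special: float
    socmed_intercept: float
    socmed_b_vabs: float
    socmed_b_iq: float

    def school_units(self) -> np.ndarray:
        return np.array(
            [self.school_mainstream, self.school_supported, self.school_special]
        )


def cost_parameters(params: ParameterSet) -> CostParameters:
    c = params.groups["costs"]
    return CostParameters(**{name: spec.mean for name, spec in c.items()})


@dataclass
class CostBreakdown:
    """Discounted cost totals by category for one arm."""

    intervention: float = 0.0
    schooling: float = 0.0
    social_medical: float = 0.0
    adult_care: float = 0.0

    def total(self, perspective: str, include_adult: bool = False) -> float:
        if perspective not in PERSPECTIVES:
            raise ParameterError(f"unknown perspective {perspective!r}")
        total = self.intervention + self.social_medical
        if perspective == "public_sector":
            total += self.schooling
        if include_adult:
            total += self.adult_care
        return total


def intervention_cost_flow(
    arm: str, settings: ModelSettings, costs: CostParameters
) -> np.ndarray:
    """Per-cycle intervention/provision cost (undiscounted, GBP)."""
    flow = np.zeros(settings.horizon_months)
    if arm == "ABA":
        flow[: settings.treatment_duration_months] = costs.aba_annual / 12.0
    elif arm == "TAU":
        flow[: settings.tau_cost_window_months] = costs.tau_annual / 12.0
    else:
        raise ParameterError(f"unknown arm {arm!r}")
    return flow


def socmed_annual(iq, vabs, costs: CostParameters):
    """Annual social-care/medical cost predicted from scores, floored at 0."""
    pred = (
        costs.socmed_intercept
        + costs.socmed_b_vabs * np.asarray(vabs, dtype=float)
        + costs.socmed_b_iq * np.asarray(iq, dtype=float)
    )
    out = np.maximum(pred, 0.0)
    return out if out.ndim else float(out)


def schooling_cost_flow(
    mix_primary: EducationMix,
    mix_secondary: EducationMix,
    settings: ModelSettings,
    costs: CostParameters,
) -> np.ndarray:
    """Per-cycle schooling cost: zero pre-school, then the mix-weighted
    annual unit cost of each phase spread over its months."""
    units = costs.school_units()
    flow = np.zeros(settings.horizon_months)
    flow[settings.preschool_end_months: settings.primary_end_months] = (
        float(mix_primary.as_array() @ units) / 12.0
    )
    flow[settings.primary_end_months:] = (
        float(mix_secondary.as_array() @ units) / 12.0
    )
    return flow


def _mid_survival(traj: cohort.TrajectoryResult) -> np.ndarray:
    return 0.5 * (traj.survival[:-1] + traj.survival[1:])


def total_costs(
    traj: cohort.TrajectoryResult,
    mix_primary: EducationMix,
    mix_secondary: EducationMix,
    params: ParameterSet,
    schooling_flow: np.ndarray | None = None,
) -> CostBreakdown:
    """Accumulate discounted childhood costs for one arm.

    All flows are survival-weighted (costs cease at death) and discounted at
    cycle midpoints.  ``schooling_flow`` overrides the phase-frozen mix flow
    (used when placement is re-evaluated every cycle).
    """
    st = params.settings
    costs = cost_parameters(params)
    surv = _mid_survival(traj)
    rate, mode = st.discount_rate_annual, st.discounting_mode

    interv = intervention_cost_flow(traj.arm, st, costs) * surv

    socmed_mid = socmed_annual(
        0.5 * (traj.iq[:-1] + traj.iq[1:]),
        0.5 * (traj.vabs[:-1] + traj.vabs[1:]),
        costs,
    )
    socmed = socmed_mid / 12.0 * surv

    if schooling_flow is None:
        schooling_flow = schooling_cost_flow(mix_primary, mix_secondary, st, costs)
    school = schooling_flow * surv

    return CostBreakdown(
        intervention=cohort.accumulate(interv, rate, mode),
        schooling=cohort.accumulate(school, rate, mode),
        social_medical=cohort.accumulate(socmed, rate, mode),
    )
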