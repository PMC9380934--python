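"""Full deterministic pipeline: trajectories -> placement -> QALYs -> costs
-> incremental cost-effectiveness.

``evaluate`` runs the whole model for one set of numeric inputs (means or a
probabilistic draw) and is the single code path shared by the base case,
the scenario analyses and both sensitivity analyses.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.special import expit

from . import adult as adult_mod
from . import cohort, costs as costs_mod, education, qaly
from .parameters import ParameterError, ParameterSet

__all__ = [
    "ICERResult",
    "EconomicResult",
    "icer",
    "evaluate",
    "run_basecase",
    "run_scenario",
    "required_additional_benefit",
    "independence_model_from_config",
]

SCENARIOS = ("base", "placement", "adult")


@dataclass(frozen=True)
class ICERResult:
    """Incremental cost-effectiveness ratio with a dominance flag.

    ``flag`` is one of ``"icer"`` (ratio meaningful), ``"dominant"`` (more
    QALYs, lower cost), ``"dominated"`` (fewer QALYs, higher cost),
    ``"undefined"`` (zero QALY difference).
    """

    value: float
    flag: str


def icer(inc_cost: float, inc_qaly: float) -> ICERResult:
    if inc_qaly == 0:
        return ICERResult(value=math.nan, flag="undefined")
    value = inc_cost / inc_qaly
    if inc_qaly > 0 and inc_cost < 0:
        return ICERResult(value=value, flag="dominant")
    if inc_qaly < 0 and inc_cost > 0:
        return ICERResult(value=value, flag="dominated")
    return ICERResult(value=value, flag="icer")


@dataclass
class EconomicResult:
    """Per-arm discounted totals plus incrementals for one comparison."""

    perspective: str
    durability: str
    scenario: str
    cost_aba: float
    cost_tau: float
    qaly_aba: float
    qaly_tau: float
    breakdown_aba: costs_mod.CostBreakdown
    breakdown_tau: costs_mod.CostBreakdown

    @property
    def inc_cost(self) -> float:
        return self.cost_aba - self.cost_tau

    @property
    def inc_qaly(self) -> float:
        return self.qaly_aba - self.qaly_tau

    @property
    def icer(self) -> ICERResult:
        return icer(self.inc_cost, self.inc_qaly)

    def as_dict(self) -> dict:
        res = self.icer
        return {
            "scenario": self.scenario,
            "perspective": self.perspective,
            "durability": self.durability,
            "cost_aba": self.cost_aba,
            "cost_tau": self.cost_tau,
            "qaly_aba": self.qaly_aba,
            "qaly_tau": self.qaly_tau,
            "inc_cost": self.inc_cost,
            "inc_qaly": self.inc_qaly,
            "icer": res.value,
            "icer_flag": res.flag,
        }


def _utility_model_from(v: Mapping[str, float], flags: Mapping) -> qaly.UtilityModel:
    return qaly.UtilityModel(
        constant=v["utility_model.constant"],
        b_age=v["utility_model.b_age"],
        b_age2=v["utility_model.b_age2"],
        b_ados=v["utility_model.b_ados"],
        b_log_iq=v["utility_model.b_log_iq"],
        b_vabs=v["utility_model.b_vabs"],
        cap_at_one=bool(flags.get("cap_at_one", True)),
        time_varying_iq=bool(flags.get("time_varying_iq", False)),
    )


def _cost_parameters_from(v: Mapping[str, float]) -> costs_mod.CostParameters:
    return costs_mod.CostParameters(
        aba_annual=v["costs.aba_annual"],
        tau_annual=v["costs.tau_annual"],
        school_mainstream=v["costs.school_mainstream"],
        school_supported=v["costs.school_supported"],
        school_special=v["costs.school_special"],
        socmed_intercept=v["costs.socmed_intercept"],
        socmed_b_vabs=v["costs.socmed_b_vabs"],
        socmed_b_iq=v["costs.socmed_b_iq"],
    )


def _education_model_from(v: Mapping[str, float], phase: str) -> education.OrderedLogitModel:
    g = f"education_{phase}"
    return education.OrderedLogitModel(
        beta_vabs=v[f"{g}.beta_vabs"], beta_iq=v[f"{g}.beta_iq"],
        cut1=v[f"{g}.cut1"], cut2=v[f"{g}.cut2"],
    )


def _scores(v, months, arm, durability, washout):
    iq = v["baseline.iq0"] + v["natural_history.d_iq_per_year"] * months / 12.0
    vb = v["baseline.vabs0"] + v["natural_history.d_vabs_per_year"] * months / 12.0
    if arm == "ABA":
        iq = iq + cohort.treatment_effect(
            months, v["effect_y1.iq"], v["effect_y2.iq"], durability, washout)
        vb = vb + cohort.treatment_effect(
            months, v["effect_y1.vabs"], v["effect_y2.vabs"], durability, washout)
    return iq, vb


def evaluate(
    params: ParameterSet,
    durability: str | None = None,
    scenario: str = "base",
    values: Mapping[str, float] | None = None,
    survival: np.ndarray | None = None,
    imodel: adult_mod.IndependenceModel | None = None,
) -> EconomicResult:
    """Run the deterministic model once.

    ``values`` overrides the flat map of parameter means (used by the
    sensitivity analyses); ``survival`` overrides the childhood survivor
    curve (precomputed once in loops).  The returned result carries both
    arms' totals under the configured perspective.
    """
    st = params.settings
    durability = durability or st.durability
    if scenario not in SCENARIOS:
        raise ParameterError(f"unknown scenario {scenario!r}")
    v = params.values() if values is None else values
    flags = params.utility_flags
    wash = st.pessimistic_washout_end_months
    months = np.arange(st.horizon_months + 1, dtype=float)

    if survival is None:
        mort = qaly.mortality_model(params)
        survival = qaly.survival_curve(mort, 3.0, st.horizon_months)
    surv_mid = 0.5 * (survival[:-1] + survival[1:])

    umodel = _utility_model_from(v, flags)
    cpar = _cost_parameters_from(v)
    edu_primary = _education_model_from(v, "primary")
    edu_secondary = _education_model_from(v, "secondary")
    rate, mode = st.discount_rate_annual, st.discounting_mode

    if imodel is None and scenario == "adult":
        imodel = independence_model_from_config(params)

    out: dict[str, tuple[float, costs_mod.CostBreakdown]] = {}
    for arm in ("TAU", "ABA"):
        iq, vb = _scores(v, months, arm, durability, wash)
        if np.any(iq <= 0):
            raise ParameterError("cohort IQ fell to zero or below")
        iq_mid = 0.5 * (iq[:-1] + iq[1:])
        vb_mid = 0.5 * (vb[:-1] + vb[1:])
        age_mid = (36.0 + months[:-1] + 0.5) / 12.0

        # QALYs
        u_iq = iq_mid if umodel.time_varying_iq else v["baseline.iq0"]
        u = qaly.utility(umodel, age_mid, v["baseline.ados0"], u_iq, vb_mid)
        qalys = cohort.accumulate(
            np.asarray(u) / 12.0 * surv_mid, rate, mode)

        # schooling placement
        if scenario == "placement":
            mix = education.observed_placement(params, arm).as_array()
            school_flow = np.zeros(st.horizon_months)
            school_flow[st.preschool_end_months:] = (
                float(mix @ cpar.school_units()) / 12.0)
        elif st.reevaluate_placement_monthly:
            school_flow = np.zeros(st.horizon_months)
            units = cpar.school_units()
            for lo, hi, model in (
                (st.preschool_end_months, st.primary_end_months, edu_primary),
                (st.primary_end_months, st.horizon_months, edu_secondary),
            ):
                eta = model.beta_vabs * vb_mid[lo:hi] + model.beta_iq * iq_mid[lo:hi]
                p1 = expit(model.cut1 - eta)
                p2 = expit(model.cut2 - eta)
                school_flow[lo:hi] = (
                    p1 * units[0] + (p2 - p1) * units[1] + (1 - p2) * units[2]
                ) / 12.0
        else:
            mix_p = education.placement_probs(
                edu_primary,
                iq[st.preschool_end_months], vb[st.preschool_end_months])
            mix_s = education.placement_probs(
                edu_secondary,
                iq[st.primary_end_months], vb[st.primary_end_months])
            school_flow = costs_mod.schooling_cost_flow(mix_p, mix_s, st, cpar)

        # costs
        interv = costs_mod.intervention_cost_flow(arm, st, cpar) * surv_mid
        socmed = costs_mod.socmed_annual(iq_mid, vb_mid, cpar) / 12.0 * surv_mid
        breakdown = costs_mod.CostBreakdown(
            intervention=cohort.accumulate(interv, rate, mode),
            schooling=cohort.accumulate(school_flow * surv_mid, rate, mode),
            social_medical=cohort.accumulate(socmed, rate, mode),
        )

        if scenario == "adult":
            ext = adult_mod.lifetime_extension(
                float(vb[-1]), imodel, params,
                iq0=v["baseline.iq0"], ados0=v["baseline.ados0"])
            breakdown.adult_care = ext["adult_care"]
            qalys += ext["adult_qalys"]

        out[arm] = (qalys, breakdown)

    include_adult = scenario == "adult"
    return EconomicResult(
        perspective=st.perspective,
        durability=durability,
        scenario=scenario,
        cost_aba=out["ABA"][1].total(st.perspective, include_adult),
        cost_tau=out["TAU"][1].total(st.perspective, include_adult),
        qaly_aba=out["ABA"][0],
        qaly_tau=out["TAU"][0],
        breakdown_aba=out["ABA"][1],
        breakdown_tau=out["TAU"][1],
    )


def independence_model_from_config(params: ParameterSet) -> adult_mod.IndependenceModel:
    """Fit the adult-independence model to the configured simulated records."""
    from .synthetic import IPDGeneratorSpec, simulate_adult_ipd

    spec = IPDGeneratorSpec.from_config(params)
    return adult_mod.fit_independence_model(simulate_adult_ipd(spec))


def run_basecase(
    params: ParameterSet,
    perspective: str | None = None,
    durability: str | None = None,
) -> EconomicResult:
    """Deterministic base-case comparison under one perspective/durability."""
    p = params
    if perspective is not None and perspective != params.settings.perspective:
        p = params.copy()
        p.settings.perspective = perspective
    return evaluate(p, durability=durability, scenario="base")


def run_scenario(
    params: ParameterSet,
    scenario: str,
    perspective: str | None = None,
    durability: str | None = None,
    imodel: adult_mod.IndependenceModel | None = None,
) -> EconomicResult:
    """One of the scenario analyses: ``placement`` (observed school mixes)
    or ``adult`` (lifetime horizon); ``base`` is allowed for symmetry."""
    p = params
    if perspective is not None and perspective != params.settings.perspective:
        p = params.copy()
        p.settings.perspective = perspective
    return evaluate(p, durability=durability, scenario=scenario, imodel=imodel)


def required_additional_benefit(
    result: EconomicResult | tuple[float, float], threshold: float
) -> tuple[float, float]:
    """QALY shortfall and cost-saving shortfall against a WTP threshold.

    For incremental cost ``dC`` and QALYs ``dQ``: the comparison would need
    ``dC/threshold - dQ`` further QALYs, or ``dC - threshold*dQ`` further
    savings, for its ICER to meet the threshold.
    """
    if threshold <= 0:
        raise ParameterError("threshold must be positive")
    if isinstance(result, EconomicResult):
        dc, dq = result.inc_cost, result.inc_qaly
    else:
        dc, dq = result
    return (dc / threshold - dq, dc - threshold * dq)
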