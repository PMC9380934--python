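"""Lifetime-horizon scenario: adult independence, care costs and QALYs.

At the end of childhood (age 18.5) the cohort's adaptive-behaviour score
maps to five ordered levels of adult independence through a cumulative-logit
model fitted by maximum likelihood to simulated individual records.  The
independence mix is then held constant through adulthood: each level carries
an annual care-cost bundle, adult utility comes from the childhood utility
model with the age term frozen at 18 plus an additive per-decade decrement
schedule, and survival continues from the mortality model.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from statsmodels.miscmodels.ordinal_model import OrderedModel

from . import cohort, qaly
from .parameters import ParameterError, ParameterSet

__all__ = [
    "INDEPENDENCE_LEVELS",
    "IndependenceModel",
    "FitError",
    "fit_independence_model",
    "independence_mix",
    "adult_cost_bundles",
    "lifetime_extension",
]

INDEPENDENCE_LEVELS = (
    "completely_independent",
    "mostly_independent",
    "some_independence",
    "mostly_dependent",
    "completely_dependent",
)


class FitError(RuntimeError):
    """Ordered-logit fit failed to converge or the data are degenerate."""


@dataclass(frozen=True)
class IndependenceModel:
    """Cumulative logit of independence level on VABS.

    Levels are ordered from most to least independent.  ``beta_vabs`` is
    the slope on the latent *dependence* scale and ``cuts`` the four
    ascending thresholds: ``P(level <= k) = logistic(cuts[k] - beta_vabs *
    vabs)`` counting levels from ``completely_independent``, so a negative
    ``beta_vabs`` means higher adaptive behaviour favours independence.
    """

    beta_vabs: float
    cuts: tuple[float, float, float, float]
    provenance: str = "supplied"

    def __post_init__(self) -> None:
        if not all(a < b for a, b in zip(self.cuts, self.cuts[1:])):
            raise ParameterError("independence cuts must be strictly ascending")


def _penalised_fit(vabs: np.ndarray, level: np.ndarray, ridge: float = 1e-3):
    """L2-penalised ordered-logit fallback for (quasi-)separated data."""
    k = len(INDEPENDENCE_LEVELS)

    def unpack(theta):
        beta = theta[0]
        cuts = np.concatenate([[theta[1]], theta[1] + np.cumsum(np.exp(theta[2:]))])
        return beta, cuts

    def nll(theta):
        beta, cuts = unpack(theta)
        eta = beta * vabs
        cum = expit(cuts[None, :] - eta[:, None])
        probs = np.diff(np.concatenate(
            [np.zeros((len(vabs), 1)), cum, np.ones((len(vabs), 1))], axis=1
        ), axis=1)
        p = np.clip(probs[np.arange(len(vabs)), level], 1e-12, 1.0)
        return -np.sum(np.log(p)) + ridge * (theta[0] ** 2)

    x0 = np.concatenate([[-0.1], [-10.0], np.log(np.full(k - 2, 2.0))])
    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"maxiter": 20000, "xatol": 1e-8, "fatol": 1e-8})
    beta, cuts = unpack(res.x)
    return beta, cuts


def fit_independence_model(ipd: pd.DataFrame) -> IndependenceModel:
    """Maximum-likelihood cumulative-logit fit of ``level`` on ``vabs``.

    ``ipd`` needs columns ``vabs`` (score) and ``level`` (integer 0..4 in
    the order of :data:`INDEPENDENCE_LEVELS`).  Deterministic given the
    data.  Raises :class:`FitError` for degenerate inputs; falls back to a
    lightly penalised fit when the unpenalised likelihood does not converge
    (e.g. complete separation).
    """
    if len(ipd) < 50:
        raise FitError("need at least 50 records to fit the independence model")
    observed = np.unique(ipd["level"])
    if len(observed) < 2:
        raise FitError("independence fit needs at least two observed levels")

    level = pd.Categorical(ipd["level"], categories=range(len(INDEPENDENCE_LEVELS)),
                           ordered=True)
    # statsmodels parameterises P(y <= k) = F(threshold_k - x beta), the
    # same orientation as IndependenceModel, so parameters map directly
    try:
        model = OrderedModel(level.codes, ipd[["vabs"]], distr="logit")
        fit = model.fit(method="bfgs", disp=False, maxiter=500)
        if not fit.mle_retvals.get("converged", False):
            raise FitError("did not converge")
        beta = float(fit.params.iloc[0])
        cuts = model.transform_threshold_params(fit.params.iloc[1:].to_numpy())[1:-1]
        cuts = tuple(float(c) for c in cuts)
    except (FitError, np.linalg.LinAlgError, ValueError):
        beta, c = _penalised_fit(
            ipd["vabs"].to_numpy(float), np.asarray(level.codes)
        )
        cuts = tuple(float(x) for x in c)
    if len(cuts) != len(INDEPENDENCE_LEVELS) - 1:
        raise FitError("unexpected number of thresholds")
    return IndependenceModel(beta_vabs=beta, cuts=cuts, provenance="fitted")


def independence_mix(model: IndependenceModel, vabs_at_18_5: float) -> np.ndarray:
    """Per-level probabilities (ordered as :data:`INDEPENDENCE_LEVELS`)."""
    cum = expit(np.asarray(model.cuts) - model.beta_vabs * vabs_at_18_5)
    probs = np.diff(np.concatenate([[0.0], cum, [1.0]]))
    return probs


def _decade_decrement(params: ParameterSet, ages: np.ndarray) -> np.ndarray:
    """Cumulative additive utility decrement reached by each age."""
    schedule = params.adult_phase.get("age_decrements_per_decade", {})
    dec = np.zeros_like(ages, dtype=float)
    for decade, value in schedule.items():
        dec += np.where(ages >= float(decade), float(value), 0.0)
    return dec


def lifetime_extension(
    vabs_at_18_5: float,
    imodel: IndependenceModel,
    params: ParameterSet,
    iq0: float | None = None,
    ados0: float | None = None,
) -> dict:
    """Discounted adult-phase costs and QALYs for one arm.

    The independence mix fixed at age 18.5 drives a constant annual care
    cost; utility uses the childhood model with the age term frozen (18 by
    default) plus the configured per-decade decrements; survival continues
    from the mortality model; all flows are discounted from model start.
    Returns ``{"adult_care": ..., "adult_qalys": ..., "mix": ...}``.
    """
    st = params.settings
    max_age = float(params.adult_phase.get("max_age_years", 80))
    start = st.horizon_months
    end = int(round((max_age - 3.0) * 12))
    if end <= start:
        return {"adult_care": 0.0, "adult_qalys": 0.0,
                "mix": independence_mix(imodel, vabs_at_18_5)}

    mix = independence_mix(imodel, vabs_at_18_5)
    annual_cost = float(mix @ adult_cost_bundles(params))

    mort = qaly.mortality_model(params)
    surv = qaly.survival_curve(mort, 3.0, end)
    surv_mid = 0.5 * (surv[start:end] + surv[start + 1: end + 1])

    umodel = qaly.utility_model(params)
    frozen_age = float(params.adult_phase.get("utility_age_years", 18.0))
    u_base = qaly.utility(
        umodel,
        frozen_age,
        params.value("baseline.ados0") if ados0 is None else ados0,
        params.value("baseline.iq0") if iq0 is None else iq0,
        vabs_at_18_5,
    )
    ages = 3.0 + (start + np.arange(end - start) + 0.5) / 12.0
    u = u_base + _decade_decrement(params, ages)
    if umodel.cap_at_one:
        u = np.minimum(u, 1.0)

    rate, mode = st.discount_rate_annual, st.discounting_mode
    return {
        "adult_care": cohort.accumulate(
            np.full(end - start, annual_cost / 12.0) * surv_mid,
            rate, mode, start_month=start,
        ),
        "adult_qalys": cohort.accumulate(
            u / 12.0 * surv_mid, rate, mode, start_month=start
        ),
        "mix": mix,
    }


def adult_cost_bundles(params: ParameterSet) -> np.ndarray:
    """Annual care cost per independence level from the configured bundles."""
    unit_costs = {name: spec.mean for name, spec in params.groups["adult_costs"].items()}
    bundles = params.adult_phase["bundles"]
    out = []
    for lvl in INDEPENDENCE_LEVELS:
        comp = bundles.get(lvl, {})
        out.append(sum(unit_costs[u] * w for u, w in comp.items()))
    costs = np.array(out)
    if np.any(np.diff(costs) < 0):
        raise ParameterError(
            "adult bundle costs must be non-decreasing with dependence"
        )
    return costs
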