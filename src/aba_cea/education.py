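"""School-placement prediction from cohort ability scores.

Placement across three settings (mainstream, mainstream with support,
special education) is predicted by a cumulative-logit (ordered logistic)
model on cohort-mean VABS and IQ, evaluated at entry to primary and
secondary school.  A scenario analysis replaces the regression link with
observed placement proportions held constant through childhood.

Orientation convention: with the negative score coefficients,
``P(setting <= k) = logistic(cut_k - eta)`` where ``eta = b_vabs*vabs +
b_iq*iq``, so that higher-functioning cohorts are more likely to attend
mainstream school.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .parameters import ParameterError, ParameterSet

__all__ = ["OrderedLogitModel", "EducationMix", "placement_probs",
           "observed_placement", "education_model"]


@dataclass(frozen=True)
class OrderedLogitModel:
    """Two-predictor cumulative-logit model with two cut-points."""

    beta_vabs: float
    beta_iq: float
    cut1: float
    cut2: float

    def __post_init__(self) -> None:
        if not self.cut1 < self.cut2:
            raise ParameterError("ordered-logit cuts must be ascending")


@dataclass(frozen=True)
class EducationMix:
    p_mainstream: float
    p_supported: float
    p_special: float

    def __post_init__(self) -> None:
        probs = self.as_array()
        if np.any(probs < -1e-12) or abs(probs.sum() - 1.0) > 1e-9:
            raise ParameterError(f"invalid education mix {tuple(probs)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_mainstream, self.p_supported, self.p_special])


def education_model(params: ParameterSet, phase: str) -> OrderedLogitModel:
    """The configured placement model for ``phase`` in {primary, secondary}."""
    group = f"education_{phase}"
    return OrderedLogitModel(
        beta_vabs=params.value(f"{group}.beta_vabs"),
        beta_iq=params.value(f"{group}.beta_iq"),
        cut1=params.value(f"{group}.cut1"),
        cut2=params.value(f"{group}.cut2"),
    )


def placement_probs(model: OrderedLogitModel, iq: float, vabs: float) -> EducationMix:
    """Predicted placement mix at the given cohort-mean scores."""
    eta = model.beta_vabs * vabs + model.beta_iq * iq
    p_le_1 = expit(model.cut1 - eta)
    p_le_2 = expit(model.cut2 - eta)
    return EducationMix(
        p_mainstream=float(p_le_1),
        p_supported=float(p_le_2 - p_le_1),
        p_special=float(1.0 - p_le_2),
    )


def observed_placement(params: ParameterSet, arm: str) -> EducationMix:
    """Observed placement mix for one arm (scenario analysis).

    The same mix applies through primary and secondary school.
    """
    key = arm.lower()
    if key not in params.placement_observed:
        raise ParameterError(f"unknown arm {arm!r}")
    mix = params.placement_observed[key]
    return EducationMix(
        p_mainstream=mix["mainstream"],
        p_supported=mix["supported"],
        p_special=mix["special"],
    )
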