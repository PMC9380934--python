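"""Deterministic and probabilistic sensitivity analysis and the CEAC.

One-way analysis re-runs the full model at each parameter's range limits
with everything else at its mean (tornado ranking).  Probabilistic analysis
draws every uncertain parameter from its distribution per iteration (simple
Monte Carlo, default 10,000 samples) and summarises with the ratio of mean
incrementals — the convention robust to sign changes across iterations.
The cost-effectiveness acceptability curve reports, per willingness-to-pay
value, the fraction of iterations with positive incremental net monetary
benefit (an alternative literal-ICER rule is available).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import qaly
from .parameters import ParameterError, ParameterSet
from .pipeline import ICERResult, icer, evaluate

__all__ = ["DSARow", "PSAOutput", "CEACPoint", "run_dsa", "run_psa", "ceac",
           "icer", "ICERResult"]


@dataclass(frozen=True)
class DSARow:
    parameter: str
    lower: float
    upper: float
    icer_at_lower: float
    icer_at_upper: float

    @property
    def range(self) -> float:
        return abs(self.icer_at_upper - self.icer_at_lower)


@dataclass
class PSAOutput:
    """Per-iteration arm totals plus summary for one perspective/durability."""

    iterations: pd.DataFrame  # columns cost_aba, qaly_aba, cost_tau, qaly_tau
    seed: int
    perspective: str
    durability: str
    n_redraws: int = 0

    @property
    def inc_cost(self) -> np.ndarray:
        return (self.iterations["cost_aba"] - self.iterations["cost_tau"]).to_numpy()

    @property
    def inc_qaly(self) -> np.ndarray:
        return (self.iterations["qaly_aba"] - self.iterations["qaly_tau"]).to_numpy()

    def summary(self) -> dict:
        means = self.iterations.mean()
        res = icer(float(means["cost_aba"] - means["cost_tau"]),
                   float(means["qaly_aba"] - means["qaly_tau"]))
        return {
            "n": len(self.iterations),
            "seed": self.seed,
            "perspective": self.perspective,
            "durability": self.durability,
            **{k: float(v) for k, v in means.items()},
            "inc_cost": float(means["cost_aba"] - means["cost_tau"]),
            "inc_qaly": float(means["qaly_aba"] - means["qaly_tau"]),
            "icer_of_means": res.value,
            "icer_flag": res.flag,
        }


@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    p_cost_effective: float


def run_dsa(
    params: ParameterSet,
    durability: str | None = None,
    top: int | None = 10,
) -> list[DSARow]:
    """One-way sensitivity analysis over every non-fixed parameter.

    Each parameter is set to the limits of its stated range (or its 95%
    normal interval when no usable range is published) with all others held
    at their means; rows are sorted by descending ICER range.
    """
    base = params.values()
    mort = qaly.mortality_model(params)
    survival = qaly.survival_curve(mort, 3.0, params.settings.horizon_months)
    rows = []
    for path, spec in params.iter_specs():
        bounds = spec.dsa_bounds()
        if bounds is None:
            continue
        icers = []
        for bound in bounds:
            v = dict(base)
            v[path] = bound
            try:
                res = evaluate(params, durability=durability, values=v,
                               survival=survival)
                icers.append(res.icer.value)
            except ParameterError:
                # a one-way excursion can be structurally invalid (e.g. a
                # cut-point crossing its neighbour); mark it undefined
                icers.append(float("nan"))
        rows.append(DSARow(parameter=path, lower=bounds[0], upper=bounds[1],
                           icer_at_lower=icers[0], icer_at_upper=icers[1]))
    rows.sort(key=lambda r: (not np.isnan(r.range), r.range), reverse=True)
    return rows if top is None else rows[:top]


def run_psa(
    params: ParameterSet,
    n: int = 10_000,
    seed: int = 0,
    durability: str | None = None,
    max_redraws: int = 10_000,
) -> PSAOutput:
    """Simple Monte Carlo over all parameter distributions.

    Reproducible given ``seed``.  Iterations whose draw is structurally
    invalid (cohort IQ driven to zero or below, so the log-IQ utility term
    is undefined) are redrawn, up to ``max_redraws`` in total.
    """
    if n < 1:
        raise ParameterError("need at least one PSA iteration")
    rng = np.random.default_rng(seed)
    st = params.settings
    mort = qaly.mortality_model(params)
    survival = qaly.survival_curve(mort, 3.0, st.horizon_months)

    sampled = [(path, spec) for path, spec in params.iter_specs()
               if spec.dist != "fixed"]
    draws = {path: np.asarray(spec.sample(rng, n)) for path, spec in sampled}
    base = params.values()

    records = np.empty((n, 4))
    redraws = 0
    for i in range(n):
        v = dict(base)
        for path in draws:
            v[path] = float(draws[path][i])
        while True:
            try:
                res = evaluate(params, durability=durability, values=v,
                               survival=survival)
                break
            except ParameterError:
                redraws += 1
                if redraws > max_redraws:
                    raise ParameterError(
                        "too many invalid PSA draws; check the distributions"
                    )
                v = dict(base)
                for path, spec in sampled:
                    v[path] = float(spec.sample(rng))
        records[i] = (res.cost_aba, res.qaly_aba, res.cost_tau, res.qaly_tau)

    return PSAOutput(
        iterations=pd.DataFrame(
            records, columns=["cost_aba", "qaly_aba", "cost_tau", "qaly_tau"]
        ),
        seed=seed,
        perspective=st.perspective,
        durability=durability or st.durability,
        n_redraws=redraws,
    )


def ceac(
    psa: PSAOutput,
    wtp_grid,
    rule: str = "nmb",
) -> list[CEACPoint]:
    """Probability the intervention is cost-effective across WTP values.

    ``nmb``: fraction of iterations with ``wtp * dQALY - dCost > 0`` (the
    standard net-monetary-benefit criterion).  ``icer``: fraction whose
    literal ICER falls below the threshold, counting dominant iterations as
    cost-effective and dominated ones as not.
    """
    if len(psa.iterations) == 0:
        raise ParameterError("empty PSA output")
    dc, dq = psa.inc_cost, psa.inc_qaly
    points = []
    for wtp in wtp_grid:
        if rule == "nmb":
            p = np.mean(wtp * dq - dc > 0)
        elif rule == "icer":
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = dc / dq
            ok = np.where(
                (dq > 0) & (dc <= 0), True,
                np.where((dq <= 0) & (dc >= 0), False,
                         np.where(dq > 0, ratio < wtp, ratio > wtp)),
            )
            p = np.mean(ok)
        else:
            raise ParameterError(f"unknown CEAC rule {rule!r}")
        points.append(CEACPoint(wtp=float(wtp), p_cost_effective=float(p)))
    return points
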