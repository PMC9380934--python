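"""Synthetic inputs: life tables, simulated adult records, perturbed configs.

The pipeline needs three external-style inputs that cannot be redistributed:
a general-population life table, individual-level adaptive-behaviour data
grouped by adult independence level (to exercise the ordered-logit fitting
step of the lifetime scenario), and jittered parameter files for testing.
Everything here is a pure function of its spec and seed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ParameterError, ParameterSet

__all__ = [
    "SyntheticLifeTable",
    "IPDGeneratorSpec",
    "make_life_table",
    "simulate_adult_ipd",
    "simulate_ordered_logit_ipd",
    "make_fixture",
]

VABS_RANGE = (20.0, 140.0)


@dataclass(frozen=True)
class SyntheticLifeTable:
    """Gompertz-Makeham annual death probabilities.

    ``qx(age) = makeham + gompertz_a * exp(gompertz_b * age)``, capped at 1.
    Defaults keep cumulative childhood mortality below 0.5% over 15.5 years
    while producing a realistic old-age ramp.
    """

    makeham: float = 2.0e-4
    gompertz_a: float = 2.5e-5
    gompertz_b: float = 0.10
    age_min: int = 0
    age_max: int = 100

    def __post_init__(self) -> None:
        if self.makeham < 0 or self.gompertz_a < 0 or self.gompertz_b < 0:
            raise ParameterError("life-table parameters must be non-negative")

    def qx(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        return np.minimum(
            self.makeham + self.gompertz_a * np.exp(self.gompertz_b * age), 1.0
        )

    def table(self) -> pd.Series:
        ages = np.arange(self.age_min, self.age_max + 1)
        return pd.Series(self.qx(ages), index=ages, name="qx")


def make_life_table(spec: SyntheticLifeTable, path=None) -> pd.DataFrame:
    """Tabulate the life table; optionally write the ``age,qx`` CSV."""
    table = spec.table()
    df = pd.DataFrame({"age": table.index, "qx": table.to_numpy()})
    if path is not None:
        df.to_csv(path, index=False)
    return df


@dataclass(frozen=True)
class IPDGeneratorSpec:
    """Per-independence-level VABS summary used to simulate records."""

    level_means: tuple[float, ...] = (95.0, 80.0, 68.0, 55.0, 42.0)
    sd: float = 8.0
    prevalences: tuple[float, ...] = (0.10, 0.15, 0.25, 0.25, 0.25)
    n: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.level_means) != len(self.prevalences):
            raise ParameterError("one prevalence per level mean required")
        if abs(sum(self.prevalences) - 1.0) > 1e-9:
            raise ParameterError("prevalences must sum to 1")
        if self.n < 1:
            raise ParameterError("n must be >= 1")

    @classmethod
    def from_config(cls, params: ParameterSet) -> "IPDGeneratorSpec":
        ipd = params.adult_phase["ipd"]
        return cls(
            level_means=tuple(ipd["level_means"]),
            sd=float(ipd["sd"]),
            prevalences=tuple(ipd["prevalences"]),
            n=int(ipd["n"]),
            seed=int(ipd["seed"]),
        )


def simulate_adult_ipd(spec: IPDGeneratorSpec, path=None) -> pd.DataFrame:
    """Simulate ``(vabs, level)`` records: level by prevalence, VABS normal
    around the level mean, truncated to the instrument range."""
    rng = np.random.default_rng(spec.seed)
    levels = rng.choice(len(spec.level_means), size=spec.n, p=spec.prevalences)
    means = np.asarray(spec.level_means)[levels]
    vabs = rng.normal(means, spec.sd)
    vabs = np.clip(vabs, *VABS_RANGE)
    df = pd.DataFrame({"vabs": vabs, "level": levels})
    if path is not None:
        df.to_csv(path, index=False)
    return df


def simulate_ordered_logit_ipd(
    beta_vabs: float,
    cuts: tuple[float, ...],
    n: int,
    seed: int = 0,
    vabs_mean: float = 65.0,
    vabs_sd: float = 18.0,
) -> pd.DataFrame:
    """Simulate ``(vabs, level)`` records from a known cumulative-logit law.

    VABS is drawn normal (truncated to the instrument range) and the level
    from ``P(level <= k) = logistic(cuts[k] - beta_vabs * vabs)`` — the
    ground truth for parameter-recovery checks of the independence fit.
    """
    rng = np.random.default_rng(seed)
    vabs = np.clip(rng.normal(vabs_mean, vabs_sd, n), *VABS_RANGE)
    cum = 1.0 / (1.0 + np.exp(-(np.asarray(cuts)[None, :] - beta_vabs * vabs[:, None])))
    probs = np.diff(
        np.concatenate([np.zeros((n, 1)), cum, np.ones((n, 1))], axis=1), axis=1
    )
    u = rng.random(n)
    level = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
    return pd.DataFrame({"vabs": vabs, "level": level})


def make_fixture(
    params: ParameterSet, perturbation: float, seed: int = 0
) -> ParameterSet:
    """Jitter every uncertain mean by ``perturbation`` standard errors
    (clipped to any bounds); the result still validates."""
    rng = np.random.default_rng(seed)
    out = params.copy()
    for _, spec in out.iter_specs():
        if spec.dist == "fixed":
            continue
        shift = perturbation * spec.se * rng.standard_normal()
        new = spec.mean + shift
        if spec.lower is not None:
            new = min(max(new, spec.lower), spec.upper)
        spec.mean = new
    out.validate()
    return out
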