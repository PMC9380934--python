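"""Model parameterisation: specs, validation, config I/O and sampling.

Every uncertain input is a :class:`ParameterSpec` carrying a mean, a standard
error, a distribution family for probabilistic analysis and (optionally)
bounds for one-way sensitivity analysis.  A :class:`ParameterSet` bundles the
full configuration of the cohort model, including deterministic settings.
"""
from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Iterator, Mapping

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "ParameterSpec",
    "ModelSettings",
    "ParameterSet",
    "ParameterError",
    "load_parameters",
    "default_parameters",
    "save_parameters",
    "gamma_moments",
]

DIST_FAMILIES = ("fixed", "normal", "gamma", "beta_like")

# groups whose members are ParameterSpecs (order defines the sampling order)
SPEC_GROUPS = (
    "baseline",
    "natural_history",
    "effect_y1",
    "effect_y2",
    "education_primary",
    "education_secondary",
    "utility_model",
    "costs",
    "adult_costs",
)

# non-spec keys allowed inside spec groups
_GROUP_FLAGS = {"utility_model": ("cap_at_one", "time_varying_iq")}


class ParameterError(ValueError):
    """Raised for schema, range or distribution violations in a config."""


def gamma_moments(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments gamma parameterisation ``(shape, scale)``.

    ``shape = (mean/se)**2`` and ``scale = se**2/mean`` so the resulting
    distribution has exactly the requested mean and standard error.
    """
    if mean <= 0 or se <= 0:
        raise ParameterError(
            f"gamma moments need positive mean and se, got ({mean}, {se})"
        )
    return (mean / se) ** 2, se ** 2 / mean


@dataclass
class ParameterSpec:
    """One uncertain model input with its sampling distribution."""

    name: str
    mean: float
    se: float = 0.0
    dist: str = "fixed"
    lower: float | None = None
    upper: float | None = None
    units: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.dist not in DIST_FAMILIES:
            raise ParameterError(
                f"{self.name}: unknown distribution family {self.dist!r}"
            )
        if self.se < 0:
            raise ParameterError(f"{self.name}: se must be >= 0, got {self.se}")
        if (self.se == 0) != (self.dist == "fixed"):
            raise ParameterError(
                f"{self.name}: se == 0 exactly when dist == 'fixed' "
                f"(se={self.se}, dist={self.dist})"
            )
        if (self.lower is None) != (self.upper is None):
            raise ParameterError(f"{self.name}: bounds must come as a pair")
        if self.lower is not None:
            if not self.lower <= self.mean <= self.upper:
                raise ParameterError(
                    f"{self.name}: bounds [{self.lower}, {self.upper}] do not "
                    f"bracket the mean {self.mean}"
                )

    # -- sensitivity-analysis range -------------------------------------
    def dsa_bounds(self) -> tuple[float, float] | None:
        """Range for one-way sensitivity analysis.

        Uses the stated bounds when present, otherwise the 95% normal
        interval ``mean +/- 1.96 se``.  ``None`` for fixed parameters.
        """
        if self.dist == "fixed":
            return None
        if self.lower is not None:
            return (self.lower, self.upper)
        return (self.mean - 1.96 * self.se, self.mean + 1.96 * self.se)

    # -- probabilistic sampling -----------------------------------------
    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw from the parameter's distribution (vectorised over ``size``)."""
        if self.dist == "fixed":
            return self.mean if size is None else np.full(size, self.mean)
        if self.dist == "normal":
            return rng.normal(self.mean, self.se, size)
        if self.dist == "gamma":
            shape, scale = gamma_moments(self.mean, self.se)
            return rng.gamma(shape, scale, size)
        # beta_like: beta for proportions, truncated normal for scores
        if 0.0 <= self.mean <= 1.0 and (self.upper is None or self.upper <= 1.0):
            var = self.se ** 2
            m = self.mean
            nu = m * (1 - m) / var - 1.0
            if nu <= 0:
                raise ParameterError(
                    f"{self.name}: se too large for a beta distribution"
                )
            return rng.beta(m * nu, (1 - m) * nu, size)
        if self.lower is None:
            return rng.normal(self.mean, self.se, size)
        a = (self.lower - self.mean) / self.se
        b = (self.upper - self.mean) / self.se
        return stats.truncnorm.rvs(
            a, b, loc=self.mean, scale=self.se, size=size, random_state=rng
        )


@dataclass
class ModelSettings:
    """Deterministic run settings (horizon, discounting, phase boundaries)."""

    horizon_months: int = 186
    cycle_length_months: int = 1
    discount_rate_annual: float = 0.035
    discounting_mode: str = "monthly"
    treatment_duration_months: int = 24
    tau_cost_window_months: int = 24
    preschool_end_months: int = 18
    primary_end_months: int = 102
    pessimistic_washout_end_months: int = 84
    reevaluate_placement_monthly: bool = False
    perspective: str = "public_sector"
    durability: str = "pessimistic"
    wtp_grid: tuple[float, ...] = tuple(
        [0, 1000, 2000, 5000, 10000, 15000, 20000, 25000, 30000, 40000, 50000,
         60000, 70000, 80000, 90000, 100000, 125000, 150000, 175000, 200000,
         250000, 300000]
    )

    def __post_init__(self) -> None:
        self.wtp_grid = tuple(float(w) for w in self.wtp_grid)
        if not 0 < self.treatment_duration_months <= self.horizon_months:
            raise ParameterError(
                "treatment duration must lie in (0, horizon]"
            )
        if not (
            self.preschool_end_months
            < self.primary_end_months
            < self.horizon_months
        ):
            raise ParameterError(
                "phase boundaries must satisfy preschool < primary < horizon"
            )
        if self.discounting_mode not in ("monthly", "annual"):
            raise ParameterError(
                f"unknown discounting mode {self.discounting_mode!r}"
            )
        if self.perspective not in ("nhs_social", "public_sector"):
            raise ParameterError(f"unknown perspective {self.perspective!r}")
        if self.durability not in ("optimistic", "pessimistic"):
            raise ParameterError(f"unknown durability {self.durability!r}")
        if self.pessimistic_washout_end_months <= self.treatment_duration_months:
            raise ParameterError(
                "pessimistic washout must end after the treatment period"
            )


@dataclass
class ParameterSet:
    """The complete model configuration.

    ``groups`` maps each parameter block to ``{name: ParameterSpec}``;
    structured non-spec blocks (observed placement, adult phase, mortality)
    are carried verbatim, and ``settings`` holds the run settings.
    """

    groups: dict[str, dict[str, ParameterSpec]]
    placement_observed: dict[str, dict[str, float]]
    adult_phase: dict
    mortality: dict
    settings: ModelSettings = field(default_factory=ModelSettings)

    def __post_init__(self) -> None:
        self.validate()

    # -- access -----------------------------------------------------------
    def spec(self, path: str) -> ParameterSpec:
        """Look up a spec by dotted path, e.g. ``"effect_y2.iq"``."""
        group, _, name = path.partition(".")
        try:
            return self.groups[group][name]
        except KeyError as exc:
            raise KeyError(f"no parameter at {path!r}") from exc

    def value(self, path: str) -> float:
        return self.spec(path).mean

    def iter_specs(self) -> Iterator[tuple[str, ParameterSpec]]:
        for group in SPEC_GROUPS:
            for name, spec in self.groups.get(group, {}).items():
                yield f"{group}.{name}", spec

    def values(self) -> dict[str, float]:
        """Flat map of dotted path -> mean, the deterministic inputs."""
        return {path: spec.mean for path, spec in self.iter_specs()}

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        for _, spec in self.iter_specs():
            spec.validate()
        for arm, mix in self.placement_observed.items():
            total = sum(mix.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                if abs(total - 1.0) > 0.02:
                    raise ParameterError(
                        f"placement proportions for {arm} sum to {total}"
                    )
                # renormalise small rounding slack
                self.placement_observed[arm] = {
                    k: v / total for k, v in mix.items()
                }
        prev = self.adult_phase["ipd"]["prevalences"]
        if not math.isclose(sum(prev), 1.0, abs_tol=1e-9):
            raise ParameterError("independence-level prevalences must sum to 1")
        if self.mortality["relative_risk"] < 1.0:
            raise ParameterError("mortality relative risk must be >= 1")

    # -- flags piggy-backed on groups ---------------------------------------
    @property
    def utility_flags(self) -> dict:
        return dict(getattr(self, "_flags", {}).get("utility_model", {}))

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)


def _parse_spec_group(group: str, block: Mapping) -> tuple[dict, dict]:
    specs: dict[str, ParameterSpec] = {}
    flags: dict[str, object] = {}
    allowed_flags = _GROUP_FLAGS.get(group, ())
    for name, entry in block.items():
        if name in allowed_flags:
            flags[name] = entry
            continue
        if not isinstance(entry, Mapping) or "mean" not in entry:
            raise ParameterError(f"{group}.{name}: expected a mapping with 'mean'")
        unknown = set(entry) - {"mean", "se", "dist", "lower", "upper", "units"}
        if unknown:
            raise ParameterError(f"{group}.{name}: unknown fields {sorted(unknown)}")
        specs[name] = ParameterSpec(
            name=f"{group}.{name}",
            mean=float(entry["mean"]),
            se=float(entry.get("se", 0.0)),
            dist=str(entry.get("dist", "fixed")),
            lower=None if entry.get("lower") is None else float(entry["lower"]),
            upper=None if entry.get("upper") is None else float(entry["upper"]),
            units=str(entry.get("units", "")),
        )
    return specs, flags


def _build(config: Mapping) -> ParameterSet:
    default = _default_raw()
    groups: dict[str, dict[str, ParameterSpec]] = {}
    all_flags: dict[str, dict] = {}
    for group in SPEC_GROUPS:
        block = config.get(group, default[group])
        specs, flags = _parse_spec_group(group, block)
        # fall back to packaged defaults for missing optional members
        for name, entry in default[group].items():
            if name in _GROUP_FLAGS.get(group, ()):
                flags.setdefault(name, entry)
            elif name not in specs:
                dspecs, _ = _parse_spec_group(group, {name: entry})
                specs[name] = dspecs[name]
        groups[group] = specs
        if flags:
            all_flags[group] = flags
    settings_block = {**default["settings"], **config.get("settings", {})}
    pset = ParameterSet(
        groups=groups,
        placement_observed={
            arm: dict(mix)
            for arm, mix in config.get(
                "placement_observed", default["placement_observed"]
            ).items()
        },
        adult_phase=copy.deepcopy(config.get("adult_phase", default["adult_phase"])),
        mortality=copy.deepcopy(config.get("mortality", default["mortality"])),
        settings=ModelSettings(**settings_block),
    )
    pset._flags = all_flags
    return pset


def _default_raw() -> dict:
    with resources.files("aba_cea.data").joinpath("default_config.yaml").open() as fh:
        return yaml.safe_load(fh)


def default_parameters() -> ParameterSet:
    """The packaged default configuration."""
    return _build(_default_raw())


def load_parameters(path) -> ParameterSet:
    """Read and validate a YAML/JSON config; missing fields take defaults."""
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, Mapping):
        raise ParameterError(f"{path}: config root must be a mapping")
    return _build(config)


def save_parameters(pset: ParameterSet, path) -> None:
    """Serialise a ParameterSet back to YAML (round-trips with load)."""
    out: dict = {}
    for group in SPEC_GROUPS:
        block: dict = {}
        for name, spec in pset.groups[group].items():
            entry = {k: v for k, v in asdict(spec).items()
                     if k != "name" and v is not None and v != ""}
            block[name] = entry
        for fname, fval in pset._flags.get(group, {}).items():
            block[fname] = fval
        out[group] = block
    out["placement_observed"] = pset.placement_observed
    out["adult_phase"] = pset.adult_phase
    out["mortality"] = pset.mortality
    sdict = asdict(pset.settings)
    sdict["wtp_grid"] = list(sdict["wtp_grid"])
    out["settings"] = sdict
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)
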