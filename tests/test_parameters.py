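"""Config loading, validation, distributions and serialisation."""
import math

import numpy as np
import pytest
import yaml

from aba_cea.parameters import (
    ParameterError,
    ParameterSpec,
    default_parameters,
    gamma_moments,
    load_parameters,
    save_parameters,
)

# every published input row must be reachable by dotted name
TABLE_MANIFEST = [
    "baseline.prop_male", "baseline.prop_intellectual_disability",
    "baseline.age_months", "baseline.vabs0", "baseline.iq0", "baseline.ados0",
    "natural_history.d_vabs_per_year", "natural_history.d_iq_per_year",
    "effect_y1.vabs", "effect_y1.iq", "effect_y2.vabs", "effect_y2.iq",
    "education_primary.beta_vabs", "education_primary.beta_iq",
    "education_primary.cut1", "education_primary.cut2",
    "education_secondary.beta_vabs", "education_secondary.beta_iq",
    "education_secondary.cut1", "education_secondary.cut2",
    "utility_model.constant", "utility_model.b_age", "utility_model.b_age2",
    "utility_model.b_ados", "utility_model.b_log_iq", "utility_model.b_vabs",
    "costs.aba_annual", "costs.tau_annual", "costs.school_mainstream",
    "costs.school_supported", "costs.school_special",
    "costs.socmed_intercept", "costs.socmed_b_vabs", "costs.socmed_b_iq",
    "adult_costs.own_home", "adult_costs.sheltered_low",
    "adult_costs.sheltered_high", "adult_costs.residential",
    "adult_costs.day_services", "adult_costs.respite",
    "adult_costs.employment_support", "adult_costs.adult_education",
    "adult_costs.hospital", "adult_costs.other",
]


def test_default_config_has_published_means(params):
    assert params.value("baseline.iq0") == 59.43
    assert params.value("baseline.vabs0") == 63.19
    assert params.value("effect_y2.iq") == 14.13
    assert params.value("costs.aba_annual") == 36682.78
    for path in TABLE_MANIFEST:
        assert isinstance(params.value(path), float | int), path


def test_placement_proportions_normalised(params):
    for arm in ("aba", "tau"):
        assert math.isclose(sum(params.placement_observed[arm].values()), 1.0,
                            abs_tol=1e-9)


@pytest.mark.parametrize(
    "kwargs, message",
    [
        (dict(mean=1.0, se=0.1, dist="fixed"), "se == 0 exactly"),
        (dict(mean=1.0, se=0.0, dist="normal"), "se == 0 exactly"),
        (dict(mean=1.0, se=0.1, dist="normal", lower=2.0, upper=3.0), "bracket"),
        (dict(mean=1.0, se=0.1, dist="normal", lower=0.0, upper=None), "pair"),
        (dict(mean=1.0, se=0.1, dist="cauchy"), "family"),
    ],
)
def test_spec_validation_rejects_bad_entries(kwargs, message):
    with pytest.raises(ParameterError, match=message):
        ParameterSpec(name="x", **kwargs)


def test_load_rejects_bound_violation(tmp_path):
    cfg = {"effect_y1": {"iq": {"mean": 9.16, "se": 2.44, "dist": "normal",
                                "lower": 10.0, "upper": 12.0}}}
    path = tmp_path / "bad.yaml"
    path.write_text(yaml.safe_dump(cfg))
    with pytest.raises(ParameterError, match="bracket"):
        load_parameters(path)


def test_partial_config_takes_defaults(tmp_path):
    path = tmp_path / "partial.yaml"
    path.write_text(yaml.safe_dump(
        {"effect_y2": {"iq": {"mean": 10.0, "se": 2.54, "dist": "normal"}}}))
    pset = load_parameters(path)
    assert pset.value("effect_y2.iq") == 10.0
    assert pset.value("baseline.iq0") == 59.43  # default filled in


def test_roundtrip_serialisation_preserves_everything(tmp_path, params):
    out = tmp_path / "roundtrip.yaml"
    save_parameters(params, out)
    again = load_parameters(out)
    for path, spec in params.iter_specs():
        other = again.spec(path)
        assert spec == other, path
    assert again.settings == params.settings
    assert again.placement_observed == params.placement_observed
    assert again.utility_flags == params.utility_flags


def test_gamma_moments_matches_method_of_moments():
    shape, scale = gamma_moments(36682.78, 7336.0)
    assert shape == pytest.approx((36682.78 / 7336.0) ** 2)
    assert shape == pytest.approx(25.004, rel=1e-4)
    assert scale == pytest.approx(1467.089, rel=1e-4)
    # mean = se implies an exponential
    assert gamma_moments(5.0, 5.0)[0] == pytest.approx(1.0)
    with pytest.raises(ParameterError):
        gamma_moments(-1.0, 2.0)


def test_gamma_sampling_recovers_moments(rng):
    spec = ParameterSpec(name="c", mean=36682.78, se=7336.0, dist="gamma")
    draws = spec.sample(rng, 1_000_000)
    se_of_mean = 7336.0 / math.sqrt(len(draws))
    assert abs(draws.mean() - 36682.78) < 3 * se_of_mean
    assert draws.std() == pytest.approx(7336.0, rel=0.01)


def test_beta_like_respects_bounds_and_mean(rng):
    spec = ParameterSpec(name="iq0", mean=59.43, se=1.08, dist="beta_like",
                         lower=57.32, upper=61.55)
    draws = spec.sample(rng, 20_000)
    assert draws.min() >= 57.32 and draws.max() <= 61.55
    assert draws.mean() == pytest.approx(59.43, abs=0.05)
    prop = ParameterSpec(name="p", mean=0.8757, se=0.0147, dist="beta_like")
    pd_ = prop.sample(rng, 20_000)
    assert ((pd_ > 0) & (pd_ < 1)).all()
    assert pd_.mean() == pytest.approx(0.8757, abs=0.001)


def test_all_fixed_config_is_degenerate(tmp_path, params):
    out = tmp_path / "fixed.yaml"
    save_parameters(params, out)
    cfg = yaml.safe_load(out.read_text())
    for group in cfg:
        if group in ("placement_observed", "adult_phase", "mortality", "settings"):
            continue
        for name, entry in cfg[group].items():
            if isinstance(entry, dict) and "mean" in entry:
                entry["se"] = 0
                entry["dist"] = "fixed"
                entry.pop("lower", None)
                entry.pop("upper", None)
    out.write_text(yaml.safe_dump(cfg))
    pset = load_parameters(out)
    assert all(spec.dist == "fixed" for _, spec in pset.iter_specs())
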