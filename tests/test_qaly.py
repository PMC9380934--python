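"""Utility regression, mortality adjustment and QALY accrual."""
import numpy as np
import pandas as pd
import pytest

from aba_cea.cohort import build_trajectory
from aba_cea.parameters import ParameterError
from aba_cea.qaly import (
    MortalityModel,
    UtilityModel,
    mortality_model,
    survival_curve,
    total_qalys,
    utility,
    utility_model,
)

FLAT = UtilityModel(constant=1.0, b_age=0, b_age2=0, b_ados=0, b_log_iq=0,
                    b_vabs=0)


def test_utility_at_baseline(params):
    u = utility(utility_model(params), 3.0, 6.98, 59.43, 63.19)
    assert u == pytest.approx(0.52566, abs=2e-5)


def test_utility_constant_only_and_cap():
    assert utility(FLAT, 50, 10, 40, 30) == pytest.approx(1.0)
    capped = UtilityModel(constant=0.9, b_age=0.02, b_age2=0, b_ados=0,
                          b_log_iq=0, b_vabs=0, cap_at_one=True)
    assert utility(capped, 40, 0, 50, 50) == pytest.approx(1.0)
    uncapped = UtilityModel(constant=0.9, b_age=0.02, b_age2=0, b_ados=0,
                            b_log_iq=0, b_vabs=0, cap_at_one=False)
    assert utility(uncapped, 40, 0, 50, 50) == pytest.approx(1.7)


def test_utility_requires_positive_iq(params):
    with pytest.raises(ParameterError):
        utility(utility_model(params), 3.0, 6.98, 0.0, 63.19)


def test_intervention_utility_dominates(params):
    """Positive VABS/log-IQ coefficients + positive effects => the treated
    arm's utility is at least TAU's at every cycle."""
    umodel = utility_model(params)
    tau = build_trajectory(params, "TAU", "optimistic")
    aba = build_trajectory(params, "ABA", "optimistic")
    u_tau = utility(umodel, tau.age_months / 12, tau.ados, tau.iq[0], tau.vabs)
    u_aba = utility(umodel, aba.age_months / 12, aba.ados, aba.iq[0], aba.vabs)
    assert np.all(u_aba >= u_tau - 1e-12)


def test_survival_identities():
    table = pd.Series(0.0, index=range(0, 30))
    model = MortalityModel(life_table=table, relative_risk=1.0)
    assert np.allclose(survival_curve(model, 3, 24), 1.0)

    qx = 0.01
    table = pd.Series(qx, index=range(0, 30))
    model = MortalityModel(life_table=table, relative_risk=2.0)
    surv = survival_curve(model, 3, 12)
    # hazard-scale doubling: one year at RR=2 equals (1-qx)^2
    assert surv[-1] == pytest.approx((1 - qx) ** 2)


def test_survival_not_arm_specific(params):
    mort = mortality_model(params)
    surv = survival_curve(mort, 3.0, params.settings.horizon_months)
    tau = build_trajectory(params, "TAU", "pessimistic", survival=surv)
    aba = build_trajectory(params, "ABA", "pessimistic", survival=surv)
    np.testing.assert_array_equal(tau.survival, aba.survival)
    assert np.all(np.diff(surv) <= 0)


def test_missing_life_table_age_raises():
    model = MortalityModel(life_table=pd.Series(0.001, index=range(0, 10)))
    with pytest.raises(ParameterError, match="no entry"):
        survival_curve(model, 5, 120)


def test_total_qalys_conservation(params):
    traj = build_trajectory(params, "TAU", "pessimistic")
    st = params.copy().settings
    st.discount_rate_annual = 0.0
    assert total_qalys(traj, FLAT, st) == pytest.approx(15.5)


def test_total_qalys_decreasing_in_discount_rate(params, fresh_params):
    traj = build_trajectory(params, "TAU", "pessimistic")
    umodel = utility_model(params)
    lo = fresh_params.settings
    hi = fresh_params.copy().settings
    hi.discount_rate_annual = 0.07
    assert total_qalys(traj, umodel, hi) < total_qalys(traj, umodel, lo)


def test_childhood_mortality_is_negligible(params):
    """Default synthetic life table + RR: < 1% effect on childhood QALYs."""
    umodel = utility_model(params)
    mort = mortality_model(params)
    surv = survival_curve(mort, 3.0, params.settings.horizon_months)
    with_mort = total_qalys(
        build_trajectory(params, "TAU", "pessimistic", survival=surv),
        umodel, params.settings)
    without = total_qalys(
        build_trajectory(params, "TAU", "pessimistic"), umodel, params.settings)
    assert abs(with_mort - without) / without < 0.01


def test_incremental_qalys_positive_and_ordered(best_params):
    from aba_cea.pipeline import run_basecase

    pess = run_basecase(best_params, "public_sector", "pessimistic")
    opt = run_basecase(best_params, "public_sector", "optimistic")
    assert 0 < pess.inc_qaly < opt.inc_qaly
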