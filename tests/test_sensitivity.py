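"""One-way sensitivity analysis, PSA behaviour and the CEAC."""
import math

import numpy as np
import pandas as pd
import pytest

from aba_cea.pipeline import icer, run_basecase
from aba_cea.sensitivity import PSAOutput, ceac, run_dsa, run_psa


@pytest.mark.parametrize(
    "dc, dq, value, flag",
    [
        (43940.0, 0.2444, 179787.0, "icer"),
        (-50294.0, 1.86, -27039.8, "dominant"),
        (50000.0, -0.5, -100000.0, "dominated"),
        (0.0, 0.5, 0.0, "icer"),
    ],
)
def test_icer_values_and_dominance_flags(dc, dq, value, flag):
    res = icer(dc, dq)
    assert res.flag == flag
    assert res.value == pytest.approx(value, rel=1e-3)


def test_icer_undefined_at_zero_qaly_difference():
    assert icer(100.0, 0.0).flag == "undefined"
    assert math.isnan(icer(100.0, 0.0).value)


@pytest.fixture(scope="module")
def dsa_rows(best_params):
    p = best_params.copy()
    p.settings.perspective = "public_sector"
    return run_dsa(p, durability="pessimistic", top=None)


def test_dsa_covers_all_uncertain_parameters(best_params, dsa_rows):
    uncertain = [path for path, spec in best_params.iter_specs()
                 if spec.dist != "fixed"]
    assert {r.parameter for r in dsa_rows} == set(uncertain)


def test_dsa_fixed_parameter_excluded_and_ranking_sorted(dsa_rows):
    finite = [r.range for r in dsa_rows if not math.isnan(r.range)]
    assert finite == sorted(finite, reverse=True)
    assert all("age_months" != r.parameter.split(".")[-1] for r in dsa_rows)


def test_treatment_effect_among_top_drivers(dsa_rows):
    top5 = {r.parameter for r in dsa_rows[:5]}
    assert "effect_y2.vabs" in top5 or "effect_y2.iq" in top5
    assert any(p.startswith("costs.") for p in top5)


def test_psa_reproducible_and_seed_sensitive(best_params):
    a = run_psa(best_params, n=40, seed=11)
    b = run_psa(best_params, n=40, seed=11)
    c = run_psa(best_params, n=40, seed=12)
    pd.testing.assert_frame_equal(a.iterations, b.iterations)
    assert not a.iterations.equals(c.iterations)


def test_degenerate_psa_equals_deterministic(fresh_params):
    """All distributions fixed -> every iteration is the deterministic run."""
    for _, spec in fresh_params.iter_specs():
        spec.se = 0.0
        spec.dist = "fixed"
        spec.lower = spec.upper = None
    det = run_basecase(fresh_params, "public_sector", "pessimistic")
    out = run_psa(fresh_params, n=5, seed=0, durability="pessimistic")
    assert np.allclose(out.iterations["cost_aba"], det.cost_aba)
    assert np.allclose(out.iterations["qaly_tau"], det.qaly_tau)
    assert out.summary()["icer_of_means"] == pytest.approx(det.icer.value)


def test_psa_converges_to_deterministic_as_se_shrinks(fresh_params):
    for _, spec in fresh_params.iter_specs():
        if spec.dist != "fixed":
            spec.se *= 1e-6
            spec.lower = spec.upper = None
    det = run_basecase(fresh_params, "public_sector", "pessimistic")
    out = run_psa(fresh_params, n=25, seed=5, durability="pessimistic")
    s = out.summary()
    assert s["inc_cost"] == pytest.approx(det.inc_cost, rel=1e-4)
    assert s["inc_qaly"] == pytest.approx(det.inc_qaly, rel=1e-4)


def _toy_psa(dc, dq):
    n = len(dc)
    frame = pd.DataFrame({
        "cost_aba": dc, "qaly_aba": dq,
        "cost_tau": np.zeros(n), "qaly_tau": np.zeros(n)})
    return PSAOutput(iterations=frame, seed=0, perspective="public_sector",
                     durability="pessimistic")


def test_ceac_limits_and_monotonicity():
    rng = np.random.default_rng(4)
    dc = rng.normal(30000, 20000, 500)
    dq = rng.normal(0.5, 0.2, 500)
    psa = _toy_psa(dc, dq)
    grid = [0, 10000, 30000, 60000, 120000, 1e7]
    points = ceac(psa, grid)
    probs = [p.p_cost_effective for p in points]
    # lambda = 0: only cost-saving iterations count
    assert probs[0] == pytest.approx(np.mean(dc < 0))
    # lambda -> infinity: fraction with positive QALY gain
    assert probs[-1] == pytest.approx(np.mean(dq > 0))
    # monotone when all QALY increments share a sign
    pos = _toy_psa(np.abs(dc), np.abs(dq) + 0.01)
    probs_pos = [p.p_cost_effective for p in ceac(pos, grid)]
    assert probs_pos == sorted(probs_pos)


def test_ceac_icer_rule_counts_dominance_correctly():
    psa = _toy_psa(np.array([-100.0, 100.0, 100.0]),
                   np.array([0.5, -0.5, 0.001]))
    point = ceac(psa, [50000], rule="icer")[0]
    # dominant counts, dominated does not, the third has ICER 100000 > 50000
    assert point.p_cost_effective == pytest.approx(1 / 3)
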