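import math
from types import SimpleNamespace

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thyrokin.selection as sel
from thyrokin.nlme import PopulationParams, RetentionNLME
from thyrokin.selection import (GateThresholds, NoAdmissibleModelError,
                                SmallSampleError, aicc, akaike_weights,
                                goodness_of_fit_gate, run_pbms)
from thyrokin.simulate import GeneratingParams


def test_aicc_published_rows():
    """AICc arithmetic reproduces the published integer-rounded values."""
    assert round(aicc(-1676, 9, 364)) == -1657
    assert round(aicc(-1810, 11, 364)) == -1787
    assert round(aicc(-1456, 219, 364)) == -349


def test_aicc_zero_parameters_identity():
    assert aicc(0.0, 0, 100) == 0.0


def test_aicc_small_sample_guard():
    with pytest.raises(SmallSampleError):
        aicc(0.0, 99, 100)
    with pytest.raises(SmallSampleError):
        aicc(0.0, 100, 100)


def test_aicc_increasing_in_k():
    vals = [aicc(-100.0, k, 50) for k in range(0, 30)]
    assert all(b > a for a, b in zip(vals, vals[1:]))


def test_akaike_weights_basic_algebra():
    assert akaike_weights({"m": 3.0}) == {"m": 1.0}
    w = akaike_weights({"a": 5.0, "b": 5.0})
    assert w["a"] == pytest.approx(0.5) and w["b"] == pytest.approx(0.5)
    w = akaike_weights({"a": 0.0, "b": 2.0})
    assert w["a"] == pytest.approx(1 / (1 + math.exp(-1)), rel=1e-12)
    assert w["b"] == pytest.approx(math.exp(-1) / (1 + math.exp(-1)), rel=1e-12)
    with pytest.raises(ValueError):
        akaike_weights({})


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(-2000, 2000), min_size=1, max_size=9),
       st.floats(-1e6, 1e6))
def test_akaike_weights_shift_invariant_and_normalized(vals, shift):
    a = {f"m{i}": v for i, v in enumerate(vals)}
    w = akaike_weights(a)
    assert sum(w.values()) == pytest.approx(1.0, abs=1e-12)
    w2 = akaike_weights({k: v + shift for k, v in a.items()})
    for k in w:
        assert w2[k] == pytest.approx(w[k], abs=1e-9)


def _fake_results(max_fixed=0.1, max_random=0.2, corr=0.5, converged=True,
                  usable=True, model_id="a4c"):
    rse = {"tvp_a1": max_fixed, "tvp_lambda1": max_fixed / 2,
           "omega2_a1": max_random, "sigma2": max_random / 2}
    return SimpleNamespace(model_id=model_id, converged=converged,
                           has_usable_covariance=usable, rse=rse,
                           correlation_offdiag_max=corr, of=-1000.0,
                           nlme_K=9)


def test_gate_published_examples():
    th = GateThresholds(check_residual_trend=False)
    # imprecise fixed effect (max RSE 0.44) is gated out
    g = goodness_of_fit_gate(_fake_results(max_fixed=0.44, max_random=0.22,
                                           corr=0.77), th)
    assert not g.passed and g.reasons == ["fixed_rse"]
    # the selected model's precision profile passes
    g = goodness_of_fit_gate(_fake_results(max_fixed=0.15, max_random=0.28,
                                           corr=0.51), th)
    assert g.passed and g.reasons == []
    # perfect precision passes
    g = goodness_of_fit_gate(_fake_results(0.0, 0.0, 0.0), th)
    assert g.passed


def test_gate_boundary_values_fail():
    th = GateThresholds(check_residual_trend=False)
    assert goodness_of_fit_gate(_fake_results(max_fixed=0.3), th).reasons == \
        ["fixed_rse"]
    assert goodness_of_fit_gate(_fake_results(max_random=0.5), th).reasons == \
        ["random_rse"]
    assert goodness_of_fit_gate(_fake_results(corr=0.8), th).reasons == \
        ["correlation"]


def test_gate_missing_diagnostics_is_convergence_failure():
    th = GateThresholds(check_residual_trend=False)
    g = goodness_of_fit_gate(_fake_results(usable=False), th)
    assert g.reasons == ["convergence"]
    g = goodness_of_fit_gate(_fake_results(converged=False), th)
    assert g.reasons == ["convergence"]


def test_residual_trend_accepts_correct_model(small_population):
    gen = GeneratingParams()
    truth = PopulationParams(tvp=dict(gen.tvp),
                             omega2={k: v ** 2 for k, v in gen.omega().items()},
                             sigma2=gen.sigma ** 2)
    res = RetentionNLME(small_population, "a4c").results_at(truth)
    ok, table = sel.residual_trend_check(res)
    assert ok
    assert set(table["time_h"]) == {2.0, 6.0, 24.0, 48.0, 96.0, 120.0}


def _stub_fit_factory(ofs):
    def stub(model_id, data, error_model="proportional", n_starts=0,
             seed=None, **kw):
        r = _fake_results(model_id=model_id)
        r.of = ofs[model_id]
        r.nlme_K = 2 * int(model_id[1]) + 1
        return r
    return stub


def test_run_pbms_gate_restricts_weights(small_population, monkeypatch):
    """A gated-out model gets no weight even with the best AICc."""
    ofs = {"a4c": -1000.0, "a3b": -2000.0}
    monkeypatch.setattr(sel, "fit_nlme", _stub_fit_factory(ofs))

    def gate(results, th):
        if results.model_id == "a3b":
            return sel.GateResult(model_id="a3b", passed=False,
                                  reasons=["fixed_rse"])
        return sel.GateResult(model_id=results.model_id, passed=True)

    monkeypatch.setattr(sel, "goodness_of_fit_gate", gate)
    rep = run_pbms(small_population, model_ids=["a3b", "a4c"], n_starts=1)
    assert rep.selected_model_id == "a4c"
    assert rep.weights == {"a4c": 1.0}
    assert rep.entries["a3b"]["weight"] is None
    assert rep.entries["a3b"]["gate_reasons"] == ["fixed_rse"]
    assert rep.entries["a4c"]["delta"] == 0.0


def test_run_pbms_single_model_weight_one(small_population, monkeypatch):
    monkeypatch.setattr(sel, "fit_nlme", _stub_fit_factory({"a4c": -500.0}))
    monkeypatch.setattr(sel, "goodness_of_fit_gate",
                        lambda r, th: sel.GateResult(model_id=r.model_id,
                                                     passed=True))
    rep = run_pbms(small_population, model_ids=["a4c"], n_starts=1)
    assert rep.weights["a4c"] == 1.0
    assert rep.selected_model_id == "a4c"


def test_run_pbms_no_admissible_model(small_population, monkeypatch):
    monkeypatch.setattr(sel, "fit_nlme", _stub_fit_factory({"a4c": -500.0}))
    monkeypatch.setattr(
        sel, "goodness_of_fit_gate",
        lambda r, th: sel.GateResult(model_id=r.model_id, passed=False,
                                     reasons=["correlation"]))
    with pytest.raises(NoAdmissibleModelError):
        run_pbms(small_population, model_ids=["a4c"], n_starts=1)


def test_run_pbms_weights_sum_to_one(small_population, monkeypatch):
    ofs = {"a4c": -1000.0, "a5b": -995.0, "a3b": -990.0}
    monkeypatch.setattr(sel, "fit_nlme", _stub_fit_factory(ofs))
    monkeypatch.setattr(sel, "goodness_of_fit_gate",
                        lambda r, th: sel.GateResult(model_id=r.model_id,
                                                     passed=True))
    rep = run_pbms(small_population, model_ids=list(ofs), n_starts=1)
    assert sum(rep.weights.values()) == pytest.approx(1.0, abs=1e-12)
    assert rep.selected_model_id == "a4c"
    frame = rep.to_frame()
    assert len(frame) == 3
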