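import math
from types import SimpleNamespace

import numpy as np
import pytest

from thyrokin.data import RetentionDataset
from thyrokin.models import evaluate_soef
from thyrokin.nlme import (PopulationParams, RetentionNLME,
                           empirical_bayes, fit_nlme, marginal_neg2ll,
                           posterior_eta, sir_uncertainty)
from thyrokin.simulate import GeneratingParams

from _oracles import gh_marginal_neg2ll, grid_posterior_eta


def _direct_fixed_effects_neg2ll(model_id, pop, data):
    total = 0.0
    for _, g in data.by_patient().items():
        t = g["time_h"].to_numpy()
        y = g["fraction"].to_numpy()
        f = evaluate_soef(model_id, pop.tvp, t)
        v = pop.sigma2 * f * f
        total += float(np.sum(np.log(2 * np.pi * v) + (y - f) ** 2 / v))
    return total


def test_zero_iiv_reduces_to_fixed_effects_likelihood(tiny_one_effect):
    data, pop = tiny_one_effect()
    pop0 = PopulationParams(tvp=pop.tvp,
                            omega2={k: 0.0 for k in pop.omega2},
                            sigma2=pop.sigma2)
    assert marginal_neg2ll("a3a", pop0, data) == pytest.approx(
        _direct_fixed_effects_neg2ll("a3a", pop0, data), rel=1e-12)


def test_patient_permutation_invariance(tiny_one_effect):
    data, pop = tiny_one_effect()
    df = data.frame
    swapped = RetentionDataset(
        df.sort_values(["patient_id", "time_h"],
                       ascending=[False, True]).reset_index(drop=True))
    assert marginal_neg2ll("a3a", pop, data) == pytest.approx(
        marginal_neg2ll("a3a", pop, swapped), rel=1e-12)


def test_objective_decomposes_additively_by_patient(tiny_one_effect):
    data, pop = tiny_one_effect()
    parts = 0.0
    for pid, g in data.by_patient().items():
        sub = RetentionDataset(g)
        parts += marginal_neg2ll("a3a", pop, sub)
    assert marginal_neg2ll("a3a", pop, data) == pytest.approx(parts, rel=1e-10)


@pytest.mark.parametrize("error_model", ["proportional", "additive",
                                         "combined", "exponential"])
def test_laplace_matches_quadrature_oracle(tiny_one_effect, error_model):
    sigma2 = (0.0005, 0.005) if error_model == "combined" else 0.01
    data, pop = tiny_one_effect(error_model=error_model, sigma2=sigma2)
    lap = marginal_neg2ll("a3a", pop, data)
    ghq = gh_marginal_neg2ll("a3a", pop, data, n_nodes=96)
    assert abs(lap - ghq) < 0.5


def test_amplitude_and_data_rescaling_shifts_objective_by_constant(
        tiny_one_effect):
    """Under proportional error, scaling data and amplitudes by c leaves the
    standardized residuals unchanged: of shifts by exactly 2 N log c."""
    data, pop = tiny_one_effect()
    c = 1.7
    scaled_pop = PopulationParams(
        tvp={**pop.tvp, "a1": c * pop.tvp["a1"]},
        omega2=pop.omega2, sigma2=pop.sigma2)
    df = data.frame.copy()
    df["fraction"] = c * df["fraction"]
    scaled = RetentionDataset(df)
    of0 = marginal_neg2ll("a3a", pop, data)
    of1 = marginal_neg2ll("a3a", scaled_pop, scaled)
    assert of1 - of0 == pytest.approx(2 * data.n_obs * math.log(c), abs=1e-6)


def _noise_free_dataset(model_id, tvp, n_patients=10,
                        times=(2.0, 6.0, 24.0, 48.0, 96.0)):
    recs = []
    f = evaluate_soef(model_id, tvp, list(times))
    for i in range(n_patients):
        recs += [(f"P{i}", t, float(v)) for t, v in zip(times, f)]
    return RetentionDataset.from_records(recs)


def test_noise_free_self_consistency():
    """Noise-free homogeneous data: typical values recovered to 1e-4."""
    tvp = dict(a1=0.4, lambda1=0.08, lambda2=0.4)
    data = _noise_free_dataset("a3a", tvp)
    start = PopulationParams(
        tvp=dict(a1=0.2, lambda1=0.05, lambda2=0.2),
        omega2=dict(a1=0.04, lambda1=0.04, lambda2=0.04), sigma2=0.01)
    res = fit_nlme("a3a", data, n_starts=12, seed=0, start_params=start,
                   explore_maxiter=40, n_polish=4, polish_maxiter=600)
    for k, v in tvp.items():
        assert res.params.tvp[k] == pytest.approx(v, rel=1e-4)


def test_fit_optimum_not_worse_than_truth(small_population):
    gen = GeneratingParams()
    truth = PopulationParams(tvp=dict(gen.tvp),
                             omega2={k: v ** 2 for k, v in gen.omega().items()},
                             sigma2=gen.sigma ** 2)
    res = fit_nlme("a4c", small_population, n_starts=2, seed=0,
                   start_params=truth, explore_maxiter=15, n_polish=2)
    assert res.of <= marginal_neg2ll("a4c", truth, small_population) + 1e-6
    assert res.converged
    assert res.n_starts_used == 2


def test_fit_deterministic_under_seed(small_population):
    kw = dict(n_starts=3, seed=11, explore_maxiter=8, n_polish=1,
              polish_maxiter=60)
    a = RetentionNLME(small_population, "a3b").fit(**kw)
    b = RetentionNLME(small_population, "a3b").fit(**kw)
    assert a.of == b.of
    assert np.array_equal(a.x, b.x)


def test_empirical_bayes_zero_variance_pins_eta(tiny_one_effect):
    data, pop = tiny_one_effect()
    ebe = empirical_bayes("a3a", pop, data)
    for pid, eta in ebe.items():
        assert eta["a1"] == 0.0 and eta["lambda2"] == 0.0
        assert abs(eta["lambda1"]) > 0


def test_empirical_bayes_matches_grid_search(tiny_one_effect):
    data, pop = tiny_one_effect()
    ebe = empirical_bayes("a3a", pop, data)
    for pid, g in data.by_patient().items():
        grid = grid_posterior_eta("a3a", pop, g["time_h"], g["fraction"],
                                  "lambda1")
        assert ebe[pid]["lambda1"] == pytest.approx(grid, abs=1e-3)


def test_posterior_eta_no_observations_is_prior_mode(tiny_one_effect):
    _, pop = tiny_one_effect()
    eta = posterior_eta("a3a", pop, [], [])
    assert eta == {"a1": 0.0, "lambda1": 0.0, "lambda2": 0.0}


def test_unknown_patient_lookup(small_population):
    gen = GeneratingParams()
    truth = PopulationParams(tvp=dict(gen.tvp),
                             omega2={k: v ** 2 for k, v in gen.omega().items()},
                             sigma2=gen.sigma ** 2)
    res = RetentionNLME(small_population, "a4c").results_at(truth)
    with pytest.raises(KeyError):
        res.patient_params("no-such-patient")


def test_fd_hessian_quadratic_closed_form(tiny_one_effect):
    """of/2 = (theta - theta_hat)^2 / (2 v)  =>  SE = sqrt(v)."""
    data, _ = tiny_one_effect()
    m = RetentionNLME(data, "a3a")
    v = 0.03
    x_hat = np.zeros(7)
    m._objective = lambda x: float(np.sum((x - x_hat) ** 2) / v)
    H = m.fd_hessian(x_hat)
    cov = np.linalg.inv(0.5 * H)
    assert np.sqrt(cov[0, 0]) == pytest.approx(math.sqrt(v), rel=1e-4)
    off = cov.copy()
    np.fill_diagonal(off, 0.0)
    assert np.abs(off).max() < 1e-6 * v


class _QuadraticModel:
    """Stand-in model whose objective is exactly quadratic (synthetic)."""

    def __init__(self, x_hat, cov):
        self.x_hat = x_hat
        self.prec = np.linalg.inv(cov)
        self._eta_cache = None

    def _objective(self, x):
        d = x - self.x_hat
        return float(d @ self.prec @ d)


def _quadratic_results(d=3, seed=0):
    rng = np.random.default_rng(seed)
    x_hat = rng.uniform(-1.0, 0.0, size=d)
    A = rng.standard_normal((d, d))
    cov = 0.02 * (A @ A.T + d * np.eye(d))
    res = SimpleNamespace(
        x=x_hat, of=0.0, eta=np.zeros((1, 1)),
        model=_QuadraticModel(x_hat, cov),
        has_usable_covariance=True,
        estimates=np.exp(x_hat),
        param_labels=[f"p{i}" for i in range(d)],
    )
    res.cov_params = lambda natural=True: cov
    return res, cov


def test_sir_matches_wald_on_quadratic_objective():
    res, cov = _quadratic_results()
    out = sir_uncertainty(res, n_samples=2000, n_resamples=1500, seed=4)
    assert not out["degenerate_weights"]
    for k, name in enumerate(res.param_labels):
        lo, hi = out["parameters"][name]["ci95"]
        se = math.sqrt(cov[k, k])
        wald_lo = res.x[k] - 1.959964 * se
        wald_hi = res.x[k] + 1.959964 * se
        width = wald_hi - wald_lo
        assert math.log(lo) == pytest.approx(wald_lo, abs=0.05 * width)
        assert math.log(hi) == pytest.approx(wald_hi, abs=0.05 * width)


def test_sir_deterministic_under_seed():
    res, _ = _quadratic_results(seed=1)
    a = sir_uncertainty(res, n_samples=400, n_resamples=200, seed=9)
    b = sir_uncertainty(res, n_samples=400, n_resamples=200, seed=9)
    assert a == b
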