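import math

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")

from thyrokin.data import RetentionDataset
from thyrokin.models import evaluate_soef, get_model
from thyrokin.nlme import PopulationParams
from thyrokin.simulate import (GeneratingParams, StudyDesign,
                               generate_population)


def admissible_params(model_id, rng, lam_range=(1e-3, 0.5),
                      amp_range=(0.01, 1.0)):
    """Random admissible parameter set for a structural model.

    Rates are ordered so the a3b/a4c denominator lambda1 + lambda2 - lambda3
    stays positive and the leading amplitude stays non-negative.
    """
    m = get_model(model_id)
    params = {}
    for name in m.param_names:
        lo, hi = lam_range if name.startswith("lambda") else amp_range
        params[name] = float(np.exp(rng.uniform(math.log(lo), math.log(hi))))
    if model_id in ("a3b", "a4c"):
        # keep the amplitude denominator safely positive
        params["lambda3"] = 0.3 * min(params["lambda1"], params["lambda2"])
    return params


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_population():
    """A reduced cohort (14 patients) from the default generative model."""
    design = StudyDesign(n_schedule_a=10, n_schedule_b=4,
                         missing_6h_patient=0)
    return generate_population(design, GeneratingParams(), seed=5)


@pytest.fixture
def tiny_one_effect():
    """2 patients x 3 observations with one random effect, for oracles."""
    rng = np.random.default_rng(3)
    tvp = dict(a1=0.5, lambda1=0.05, lambda2=0.3)
    om2 = dict(a1=0.0, lambda1=0.3, lambda2=0.0)
    times = [2.0, 24.0, 96.0]

    def build(error_model="proportional", sigma2=0.01):
        recs = []
        for pid in ("A", "B"):
            eta = rng.standard_normal() * math.sqrt(om2["lambda1"])
            pars = dict(tvp)
            pars["lambda1"] *= math.exp(eta)
            f = evaluate_soef("a3a", pars, times)
            if error_model == "combined":
                s = np.sqrt(sigma2[0] + sigma2[1] * f * f)
                y = f + s * rng.standard_normal(3)
            elif error_model == "additive":
                y = f + math.sqrt(sigma2) * rng.standard_normal(3)
            elif error_model == "exponential":
                y = f * np.exp(math.sqrt(sigma2) * rng.standard_normal(3))
            else:
                y = f * (1 + math.sqrt(sigma2) * rng.standard_normal(3))
            y = np.abs(y) + 1e-4
            recs += [(pid, t, float(v)) for t, v in zip(times, y)]
        data = RetentionDataset.from_records(recs)
        pop = PopulationParams(tvp=dict(tvp), omega2=dict(om2),
                               sigma2=sigma2, error_model=error_model)
        return data, pop

    return build
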