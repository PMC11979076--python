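"""Independent oracles used by the tests.

Everything here is deliberately written from scratch against the published
formulas (plain ``math`` transcriptions, brute-force quadrature, grid search)
and never calls the package's own evaluation/fitting code paths it is used to
check.
"""

import math

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import roots_hermite

LAMBDA_PHYS = math.log(2.0) / (8.022 * 24.0)


def soef_direct(model_id, p, t):
    """Literal transcription of the nine retention functions at scalar t."""
    lp = LAMBDA_PHYS
    e = math.exp
    if model_id == "a3a":
        return (p["a1"] * e(-(p["lambda1"] + lp) * t)
                - p["a1"] * e(-(p["lambda2"] + lp) * t))
    if model_id == "a3b":
        c = p["lambda1"] / (p["lambda2"] + p["lambda1"] - p["lambda3"])
        return c * (e(-(p["lambda3"] + lp) * t)
                    - e(-(p["lambda1"] + p["lambda2"] + lp) * t))
    if model_id == "a4a":
        return (p["a1"] * e(-(p["lambda1"] + lp) * t)
                + p["a2"] * e(-lp * t)
                - (p["a1"] + p["a2"]) * e(-(p["lambda2"] + lp) * t))
    if model_id == "a4b":
        return ((p["a1"] + p["a2"]) * e(-lp * t)
                - p["a1"] * e(-(p["lambda1"] + lp) * t)
                - p["a2"] * e(-(p["lambda2"] + lp) * t))
    if model_id == "a4c":
        c = p["lambda1"] / (p["lambda2"] + p["lambda1"] - p["lambda3"])
        return (c * (e(-(p["lambda3"] + lp) * t)
                     - e(-(p["lambda1"] + p["lambda2"] + lp) * t))
                + p["a1"] * e(-(p["lambda1"] + p["lambda2"] + lp) * t))
    if model_id == "a5a":
        return (p["a1"] * e(-(p["lambda1"] + lp) * t)
                + p["a2"] * e(-(p["lambda2"] + lp) * t)
                - (p["a1"] + p["a2"]) * e(-(p["lambda3"] + lp) * t))
    if model_id == "a5b":
        return ((p["a1"] + p["a2"]) * e(-(p["lambda1"] + lp) * t)
                - p["a1"] * e(-(p["lambda2"] + lp) * t)
                - p["a2"] * e(-(p["lambda3"] + lp) * t))
    if model_id == "a6a":
        return (p["a1"] * e(-(p["lambda1"] + lp) * t)
                + p["a2"] * e(-(p["lambda2"] + lp) * t)
                + p["a3"] * e(-lp * t)
                - (p["a1"] + p["a2"] + p["a3"]) * e(-(p["lambda3"] + lp) * t))
    if model_id == "a6b":
        return (p["a1"] * e(-(p["lambda1"] + lp) * t)
                + p["a2"] * e(-lp * t)
                - p["a3"] * e(-(p["lambda2"] + lp) * t)
                - (p["a1"] + p["a2"] - p["a3"]) * e(-(p["lambda3"] + lp) * t))
    raise KeyError(model_id)


def _patient_nll_factory(model_id, pop, t, y, rname):
    """-log joint density of one patient as a function of a scalar eta."""
    sig = pop.sigma2
    w2 = pop.omega2[rname]

    def nll(eta):
        pars = dict(pop.tvp)
        pars[rname] = pars[rname] * math.exp(eta)
        f = np.array([soef_direct(model_id, pars, tj) for tj in t])
        if pop.error_model == "proportional":
            v = sig * f * f
            r = y - f
        elif pop.error_model == "additive":
            v = np.full_like(f, sig)
            r = y - f
        elif pop.error_model == "combined":
            v = sig[0] + sig[1] * f * f
            r = y - f
        else:  # exponential (log-normal density in y)
            v = np.full_like(f, sig)
            r = np.log(y) - np.log(np.maximum(f, 1e-300))
        ll = -0.5 * np.sum(np.log(2 * np.pi * v) + r * r / v)
        if pop.error_model == "exponential":
            ll -= np.sum(np.log(y))
        ll += -0.5 * (math.log(2 * np.pi * w2) + eta * eta / w2)
        return -ll

    return nll


def gh_marginal_neg2ll(model_id, pop, data, n_nodes=96):
    """Adaptive Gauss-Hermite quadrature of the exact marginal -2 log L.

    Supports exactly one non-zero inter-individual variance.
    """
    active = [k for k, v in pop.omega2.items() if v > 0]
    assert len(active) == 1, "oracle handles one random effect"
    rname = active[0]
    nodes, wts = roots_hermite(n_nodes)
    total = 0.0
    for _, g in data.by_patient().items():
        t = g["time_h"].to_numpy()
        y = g["fraction"].to_numpy()
        nll = _patient_nll_factory(model_id, pop, t, y, rname)
        res = minimize_scalar(nll, bounds=(-10, 10), method="bounded",
                              options=dict(xatol=1e-10))
        mu = res.x
        h = 1e-4
        hess = (nll(mu + h) - 2 * nll(mu) + nll(mu - h)) / h ** 2
        s = 1.0 / math.sqrt(max(hess, 1e-8))
        pts = mu + math.sqrt(2.0) * s * nodes
        vals = np.array([-nll(x) for x in pts])
        m0 = vals.max()
        integral = math.sqrt(2.0) * s * np.sum(wts * np.exp(vals - m0 + nodes ** 2))
        total += -2.0 * (m0 + math.log(integral))
    return total


def grid_posterior_eta(model_id, pop, t, y, rname, half_width=4.0, n=8001):
    """Dense grid search for one patient's posterior mode of a scalar eta."""
    nll = _patient_nll_factory(model_id, pop, np.asarray(t), np.asarray(y),
                               rname)
    grid = np.linspace(-half_width, half_width, n)
    vals = np.array([nll(g) for g in grid])
    return float(grid[np.argmin(vals)])
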