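"""Non-linear mixed-effects estimation for retention kinetics.

The population model for patient ``i`` with structural parameter vector
``P_i`` is

    P_i = TVP * exp(eta_i),        eta_i ~ N(0, diag(omega^2)),
    y_ij = h(f(t_ij; P_i), eps_ij),  eps_ij ~ N(0, sigma^2),

where ``TVP`` are the fixed effects (typical values), ``omega^2`` the
inter-individual variances and ``sigma^2`` the residual variance.  Four
residual models are supported: proportional ``y = f (1 + eps)`` (residual
variance sigma^2 f^2), additive, combined (variance sigma_add^2 +
sigma_prop^2 f^2) and exponential (additive-normal on log observations,
including the log-normal Jacobian so objective values remain comparable
across residual models on the same data).

Estimation maximizes the Laplace-approximate marginal likelihood.  The inner
step optimizes each patient's ``eta`` by damped Newton iterations (batched
across patients); the outer step searches over ``log TVP``, ``log omega^2``
and ``log sigma^2`` with L-BFGS-B from many randomized starting values.  The
reported objective value ``of`` is -2 log L-hat including all Gaussian
normalization constants (each observation contributes its log(2 pi v) term),
a convention that is identical across models so that information-criterion
differences are unaffected by it.

The user-facing surface follows the Model/Results pattern:
``RetentionNLME(data, model_id).fit()`` returns a
:class:`RetentionNLMEResults` carrying estimates, uncertainties, empirical
Bayes estimates and diagnostics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import cached_property
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from .data import RetentionDataset
from .models import SOEF, get_model, tia_closed_form

__all__ = [
    "PopulationParams", "RetentionNLME", "RetentionNLMEResults",
    "NonConvergenceError", "fit_nlme", "marginal_neg2ll", "empirical_bayes",
    "posterior_eta", "sir_uncertainty", "ERROR_MODELS",
]

ERROR_MODELS = ("proportional", "additive", "combined", "exponential")

_LOG2PI = math.log(2.0 * math.pi)
_F_FLOOR = 1e-12          # prediction floor for error models requiring f > 0
_PENALTY = 1e10           # objective value for structurally infeasible points
_OF_CAP = 1e9             # objective values above this are log-compressed


def _soft_cap(v: float) -> float:
    """Monotone compression of huge objective values.

    Keeps infeasible-region values finite and on a moderate scale so that
    line searches can interpolate through them, while preserving ordering
    (the search is still pushed toward feasible regions).
    """
    if v <= _OF_CAP:
        return v
    return _OF_CAP + 1e6 * math.log10(v - _OF_CAP + 10.0)


_OMEGA2_ACTIVE = 1e-12    # below this an inter-individual variance is treated as 0
_DENOM_EPS = 1e-8         # guard on the a3b/a4c amplitude denominator during search


class NonConvergenceError(RuntimeError):
    """No optimization start converged; carries the best diagnostics found."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


@dataclass
class PopulationParams:
    """Population parameters of one structural model.

    ``sigma2`` is the residual variance; for the combined error model it is a
    pair ``(sigma2_additive, sigma2_proportional)``.
    """

    tvp: Dict[str, float]
    omega2: Dict[str, float]
    sigma2: float | Tuple[float, float]
    error_model: str = "proportional"

    def validate(self, model: SOEF) -> None:
        names = set(model.param_names)
        if set(self.tvp) != names or set(self.omega2) != names:
            raise ValueError(
                f"tvp/omega2 keys must equal {list(model.param_names)}")
        if self.error_model not in ERROR_MODELS:
            raise ValueError(f"unknown error model {self.error_model!r}")
        sig = np.atleast_1d(np.asarray(self.sigma2, dtype=float))
        n_sig = 2 if self.error_model == "combined" else 1
        if sig.size != n_sig or np.any(sig < 0):
            raise ValueError(
                f"sigma2 must be {n_sig} non-negative value(s) for "
                f"{self.error_model} error")


def _obs_nll(error_model: str, f: np.ndarray, y: np.ndarray, sig: np.ndarray,
             logy: np.ndarray):
    """Per-observation -2 log density and its first/second derivative in f."""
    if error_model == "proportional":
        s = sig[0]
        fc = np.maximum(f, _F_FLOOR)
        r = y - fc
        ell = _LOG2PI + np.log(s) + 2.0 * np.log(fc) + r * r / (s * fc * fc)
        lp = 2.0 / fc - 2.0 * r / (s * fc ** 2) - 2.0 * r * r / (s * fc ** 3)
        lpp = (-2.0 / fc ** 2 + 2.0 / (s * fc ** 2) + 8.0 * r / (s * fc ** 3)
               + 6.0 * r * r / (s * fc ** 4))
    elif error_model == "additive":
        s = sig[0]
        r = y - f
        ell = _LOG2PI + np.log(s) + r * r / s
        lp = np.broadcast_to(-2.0 * r / s, f.shape)
        lpp = np.full_like(f, 2.0 / s)
    elif error_model == "combined":
        sa, sp_ = sig
        v = sa + sp_ * f * f
        dv = 2.0 * sp_ * f
        ddv = 2.0 * sp_
        r = y - f
        ell = _LOG2PI + np.log(v) + r * r / v
        lp = dv / v - 2.0 * r / v - r * r * dv / (v * v)
        lpp = (ddv / v - dv * dv / (v * v) + 2.0 / v + 4.0 * r * dv / (v * v)
               - r * r * ddv / (v * v) + 2.0 * r * r * dv * dv / (v ** 3))
    elif error_model == "exponential":
        s = sig[0]
        fc = np.maximum(f, _F_FLOOR)
        u = logy - np.log(fc)
        ell = _LOG2PI + np.log(s) + u * u / s + 2.0 * logy
        lp = -2.0 * u / (s * fc)
        lpp = 2.0 * (1.0 + u) / (s * fc * fc)
    else:  # pragma: no cover
        raise ValueError(f"unknown error model {error_model!r}")
    return ell, lp, lpp


class _LaplaceEngine:
    """Batched Laplace objective for one model on one dataset."""

    def __init__(self, model: SOEF, data: RetentionDataset, error_model: str):
        if error_model not in ERROR_MODELS:
            raise ValueError(f"unknown error model {error_model!r}")
        self.model = model
        self.error_model = error_model
        self.T, self.Y, self.mask, self.patient_ids = data.padded_arrays()
        self.logY = np.log(self.Y)
        self.n, self.m = self.T.shape
        self.p = model.n_structural
        # map dataset rows -> (patient index, obs slot) for simulation
        counts: Dict[str, int] = {}
        idx = {pid: i for i, pid in enumerate(self.patient_ids)}
        rows = []
        for pid in data.frame["patient_id"]:
            i = idx[pid]
            rows.append((i, counts.get(pid, 0)))
            counts[pid] = counts.get(pid, 0) + 1
        self.row_map = np.array(rows)

    # ---- inner (per-patient eta) problem ----

    def _values(self, tvp, om2_act, active, sig, eta):
        P = tvp[None, :] * np.exp(eta)
        f = self.model.predict(P, self.T)
        ell, _, _ = _obs_nll(self.error_model, f, self.Y, sig, self.logY)
        ell = np.where(self.mask, ell, 0.0).sum(axis=1)
        if active.size:
            ea = eta[:, active]
            ell = ell + np.sum(np.log(2.0 * np.pi * om2_act)
                               + ea * ea / om2_act, axis=1)
        return ell

    def _derivs(self, tvp, om2_act, active, sig, eta, exact_hess=True):
        """Value, gradient and Hessian of the inner objective in eta.

        With ``exact_hess=False`` the Hessian is the Gauss-Newton surrogate
        (second derivatives of the prediction dropped) used for the inner
        search direction; the exact Hessian is used for the Laplace
        determinant.
        """
        P = tvp[None, :] * np.exp(eta)
        if exact_hess:
            f, jac, hess = self.model.predict_jac_hess(P, self.T)
        else:
            f, jac = self.model.predict_jac(P, self.T)
        ell, lp, lpp = _obs_nll(self.error_model, f, self.Y, sig, self.logY)
        w = self.mask
        ell = np.where(w, ell, 0.0).sum(axis=1)
        qa = active.size
        Pa = P[:, active]
        fj = jac[:, :, active] * Pa[:, None, :]                  # df/deta_a
        di = np.arange(qa)
        lp_m = np.where(w, lp, 0.0)
        lpp_m = np.where(w, lpp, 0.0)
        g = np.einsum("nm,nmk->nk", lp_m, fj)
        H = np.einsum("nm,nmk,nml->nkl", lpp_m, fj, fj)
        if exact_hess:
            fh = hess[:, :, active][:, :, :, active] \
                * Pa[:, None, :, None] * Pa[:, None, None, :]
            fh[:, :, di, di] += fj
            H = H + np.einsum("nm,nmkl->nkl", lp_m, fh)
        if qa:
            ea = eta[:, active]
            ell = ell + np.sum(np.log(2.0 * np.pi * om2_act)
                               + ea * ea / om2_act, axis=1)
            g = g + 2.0 * ea / om2_act
            H[:, di, di] += 2.0 / om2_act
        return ell, g, H

    def inner_solve(self, tvp, om2, sig, eta0, gtol=1e-7, max_iter=50):
        """Optimize eta per patient; return (eta_hat, ell, H) at the optimum.

        Inter-individual variances below a tiny floor are treated as exactly
        zero: the corresponding eta components stay at 0 and drop out of the
        Laplace integral.  Patients whose joint deviance at the starting eta
        is astronomically large (structurally hopeless parameter regions) are
        not optimized: their raw deviance is returned, which keeps the outer
        objective finite, cheap and decreasing toward feasible regions.
        """
        active = np.flatnonzero(om2 > _OMEGA2_ACTIVE)
        om2_act = om2[active]
        eta = eta0.copy()
        eta[:, np.setdiff1d(np.arange(self.p), active)] = 0.0
        qa = active.size
        if qa == 0:
            ell = self._values(tvp, om2_act, active, sig, eta)
            return eta, ell, np.zeros((self.n, 0, 0))
        eye = np.eye(qa)
        # a stale warm start can be worse than the prior mode: take the
        # better of the two per patient so the objective is path-independent
        if np.any(eta):
            eta = np.clip(eta, -12.0, 12.0)
            ell_warm = self._values(tvp, om2_act, active, sig, eta)
            ell_zero = self._values(tvp, om2_act, active, sig,
                                    np.zeros_like(eta))
            use_zero = ~(ell_warm < ell_zero)
            eta[use_zero] = 0.0
            ell0 = np.where(use_zero, ell_zero, ell_warm)
        else:
            ell0 = self._values(tvp, om2_act, active, sig, eta)
        hopeless = ~np.isfinite(ell0) | (ell0 > 1e6)
        if hopeless.all():
            return eta, ell0, np.broadcast_to(eye, (self.n, qa, qa)).copy()
        lam = np.full(self.n, 1e-6)
        ell, g, H = self._derivs(tvp, om2_act, active, sig, eta)
        ell = np.where(hopeless, ell0, ell)
        for _ in range(max_iter):
            gmax = np.abs(g).max(axis=1)
            todo = (gmax > gtol) & ~hopeless
            if not todo.any():
                break
            accepted = ~todo
            for _attempt in range(8):
                Hd = H + lam[:, None, None] * eye
                try:
                    step = -np.linalg.solve(Hd, g[..., None])[..., 0]
                except np.linalg.LinAlgError:
                    lam = lam * 10.0 + 1e-6
                    continue
                trial = eta.copy()
                upd = ~accepted
                trial[np.ix_(upd, active)] = np.clip(
                    eta[np.ix_(upd, active)] + step[upd], -12.0, 12.0)
                ell_new = self._values(tvp, om2_act, active, sig, trial)
                better = upd & (ell_new <= ell + 1e-12)
                if better.any():
                    eta[np.ix_(better, active)] = trial[np.ix_(better, active)]
                    ell[better] = ell_new[better]
                    lam[better] = np.maximum(lam[better] * 0.25, 1e-8)
                    accepted |= better
                worse = upd & ~better
                if not worse.any():
                    break
                lam[worse] *= 10.0
            ell, g, H = self._derivs(tvp, om2_act, active, sig, eta)
            ell = np.where(hopeless, ell0, ell)
        if hopeless.any():
            H = H.copy()
            H[hopeless] = eye
        return eta, ell, H

    def neg2ll(self, tvp, om2, sig, eta0=None, return_eta=False):
        """Laplace -2 log marginal likelihood (sum over patients)."""
        if eta0 is None:
            eta0 = np.zeros((self.n, self.p))
        eta, ell, H = self.inner_solve(tvp, om2, sig, eta0)
        qa = H.shape[-1]
        if qa == 0:
            of = float(ell.sum())
        else:
            Hs = 0.5 * H
            sign, logdet = np.linalg.slogdet(Hs)
            if np.any(sign <= 0):
                bad = sign <= 0
                ridge = np.eye(qa) * 1e-6
                for _ in range(12):
                    s2, l2 = np.linalg.slogdet(Hs[bad] + ridge)
                    if np.all(s2 > 0):
                        logdet[bad] = l2
                        break
                    ridge *= 10.0
                else:
                    return (np.inf, eta) if return_eta else np.inf
            of = float(np.sum(ell - qa * _LOG2PI + logdet))
        return (of, eta) if return_eta else of

    # ---- simulation under given population parameters ----

    def simulate(self, tvp, om2, sig, n_rep, rng) -> np.ndarray:
        """Simulate replicate datasets; returns (n_rep, n_obs) in row order."""
        om = np.sqrt(np.maximum(om2, 0.0))
        eta = rng.standard_normal((n_rep, self.n, self.p)) * om
        P = tvp * np.exp(eta)                              # (r, n, p)
        f = self.model.predict(P, self.T[None, :, :])      # (r, n, m)
        if self.error_model == "proportional":
            y = f * (1.0 + math.sqrt(sig[0])
                     * rng.standard_normal(f.shape))
        elif self.error_model == "additive":
            y = f + math.sqrt(sig[0]) * rng.standard_normal(f.shape)
        elif self.error_model == "combined":
            v = sig[0] + sig[1] * f * f
            y = f + np.sqrt(v) * rng.standard_normal(f.shape)
        else:  # exponential
            y = np.maximum(f, _F_FLOOR) * np.exp(
                math.sqrt(sig[0]) * rng.standard_normal(f.shape))
        i, j = self.row_map[:, 0], self.row_map[:, 1]
        return y[:, i, j]

    def population_prediction(self, tvp) -> np.ndarray:
        """Typical-value prediction per dataset row."""
        f = self.model.predict(np.asarray(tvp)[None, :], self.T)
        i, j = self.row_map[:, 0], self.row_map[:, 1]
        return f[i, j]


class RetentionNLME:
    """Non-linear mixed-effects model of thyroid retention data.

    Parameters
    ----------
    data : RetentionDataset
        Per-patient retention observations.
    model_id : str
        Structural model identifier (``a3a`` ... ``a6b``).
    error_model : str
        Residual model: ``proportional`` (default), ``additive``,
        ``combined`` or ``exponential``.
    """

    def __init__(self, data: RetentionDataset, model_id: str = "a4c",
                 error_model: str = "proportional"):
        self.data = data
        self.model_id = model_id
        self.soef = get_model(model_id)
        self.error_model = error_model
        self.engine = _LaplaceEngine(self.soef, data, error_model)
        self._eta_cache = np.zeros((self.engine.n, self.engine.p))
        p = self.soef.n_structural
        self.n_sigma = 2 if error_model == "combined" else 1
        self.k_params = 2 * p + self.n_sigma
        self.param_labels = (
            [f"tvp_{n}" for n in self.soef.param_names]
            + [f"omega2_{n}" for n in self.soef.param_names]
            + (["sigma2_add", "sigma2_prop"] if self.n_sigma == 2
               else ["sigma2"])
        )

    # ---- packing between the search scale and natural parameters ----

    def _unpack(self, x):
        p = self.soef.n_structural
        tvp = np.exp(x[:p])
        om2 = np.exp(x[p:2 * p])
        sig = np.exp(x[2 * p:])
        return tvp, om2, sig

    def _pack(self, pop: PopulationParams) -> np.ndarray:
        names = self.soef.param_names
        sig = np.atleast_1d(np.asarray(pop.sigma2, dtype=float))
        return np.log(np.concatenate([
            [pop.tvp[n] for n in names],
            [max(pop.omega2[n], _OMEGA2_ACTIVE / 10) for n in names],
            sig,
        ]))

    def _to_population_params(self, x) -> PopulationParams:
        tvp, om2, sig = self._unpack(x)
        names = self.soef.param_names
        return PopulationParams(
            tvp=dict(zip(names, map(float, tvp))),
            omega2=dict(zip(names, map(float, om2))),
            sigma2=float(sig[0]) if self.n_sigma == 1 else tuple(map(float, sig)),
            error_model=self.error_model,
        )

    @cached_property
    def _bounds(self):
        lo_amp, hi_amp = math.log(1e-6), math.log(3.0)
        lo_rate, hi_rate = math.log(1e-6), math.log(10.0)
        b = []
        for n in self.soef.param_names:
            b.append((lo_rate, hi_rate) if n.startswith("lambda")
                     else (lo_amp, hi_amp))
        b += [(math.log(1e-8), math.log(25.0))] * self.soef.n_structural
        b += [(math.log(1e-10), math.log(4.0))] * self.n_sigma
        return b

    # ---- objective ----

    def _objective(self, x) -> float:
        tvp, om2, sig = self._unpack(x)
        den = self.soef.denominator(tvp[None, :])
        if den is not None and abs(float(den[0])) < _DENOM_EPS:
            return _soft_cap(_PENALTY)
        if not np.all(np.isfinite(tvp)):
            return _soft_cap(_PENALTY)
        of, eta = self.engine.neg2ll(tvp, om2, sig, eta0=self._eta_cache,
                                     return_eta=True)
        if not np.isfinite(of):
            return _soft_cap(_PENALTY)
        self._eta_cache = eta
        return _soft_cap(of)

    def neg2ll(self, pop: PopulationParams) -> float:
        """Laplace -2 log marginal likelihood at given population parameters."""
        pop.validate(self.soef)
        if pop.error_model != self.error_model:
            raise ValueError("error_model mismatch between model and parameters")
        names = self.soef.param_names
        tvp = np.array([pop.tvp[n] for n in names], dtype=float)
        om2 = np.array([pop.omega2[n] for n in names], dtype=float)
        sig = np.atleast_1d(np.asarray(pop.sigma2, dtype=float))
        return self.engine.neg2ll(tvp, om2, sig)

    # ---- multi-start fitting ----

    def _random_start(self, rng) -> np.ndarray:
        x = []
        for n in self.soef.param_names:
            if n.startswith("lambda"):
                x.append(rng.uniform(math.log(1e-4), math.log(1.0)))
            else:
                x.append(rng.uniform(math.log(1e-3), math.log(1.0)))
        x += [math.log(0.25)] * self.soef.n_structural   # omega start 0.5
        x += [math.log(0.01)] * self.n_sigma             # sigma start 0.1
        return np.array(x)

    def fit(self, n_starts: int = 1000, seed: Optional[int] = None,
            start_params: Optional[PopulationParams] = None,
            explore_maxiter: int = 20, n_polish: int = 5,
            polish_maxiter: int = 400, gtol_converged: float = 0.1,
            ) -> "RetentionNLMEResults":
        """Maximize the Laplace marginal likelihood from randomized starts.

        Each of the ``n_starts`` local searches runs a short L-BFGS-B budget
        (``explore_maxiter`` iterations); the ``n_polish`` most promising
        candidates are then polished to full convergence and the best
        converged objective wins (ties broken by lowest start index).
        """
        if n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        rng = np.random.default_rng(seed)
        starts = []
        if start_params is not None:
            start_params.validate(self.soef)
            starts.append(self._pack(start_params))
        while len(starts) < n_starts:
            starts.append(self._random_start(rng))

        stage1 = []
        for idx, x0 in enumerate(starts):
            self._eta_cache = np.zeros((self.engine.n, self.engine.p))
            res = minimize(self._objective, x0, method="L-BFGS-B",
                           bounds=self._bounds,
                           options=dict(maxiter=explore_maxiter,
                                        maxfun=40 * explore_maxiter,
                                        ftol=1e-11, gtol=1e-7))
            stage1.append((float(res.fun), idx, res.x))
        stage1.sort(key=lambda t: (t[0], t[1]))

        best = None
        n_polish = max(1, min(n_polish, len(stage1)))
        for fun1, idx, x1 in stage1[:n_polish]:
            if fun1 >= _OF_CAP:
                continue
            # repeated L-BFGS restarts: resetting the quasi-Newton memory
            # reliably escapes premature small-step terminations
            prev = np.inf
            for _restart in range(4):
                self._eta_cache = np.zeros((self.engine.n, self.engine.p))
                res = minimize(self._objective, x1, method="L-BFGS-B",
                               bounds=self._bounds,
                               options=dict(maxiter=polish_maxiter,
                                            maxfun=40 * polish_maxiter,
                                            ftol=1e-13, gtol=1e-8))
                x1 = res.x
                if prev - res.fun < 1e-8:
                    break
                prev = res.fun
            if res.jac is not None:
                # projected gradient: components blocked by an active bound
                # do not count against convergence
                pg = np.asarray(res.jac, dtype=float).copy()
                for i, (lo, hi) in enumerate(self._bounds):
                    if res.x[i] <= lo + 1e-10 and pg[i] > 0:
                        pg[i] = 0.0
                    if res.x[i] >= hi - 1e-10 and pg[i] < 0:
                        pg[i] = 0.0
                gmax = float(np.abs(pg).max())
            else:
                gmax = np.inf
            conv = bool((res.success or gmax < gtol_converged)
                        and res.fun < _OF_CAP)
            cand = dict(of=float(res.fun), x=res.x, start_index=idx,
                        converged=conv, grad_max=gmax)
            if best is None or (cand["converged"], ) > (best["converged"], ) or (
                    cand["converged"] == best["converged"]
                    and (cand["of"], cand["start_index"])
                    < (best["of"], best["start_index"])):
                best = cand
        if best is None or not best["converged"]:
            raise NonConvergenceError(
                f"no start converged for model {self.model_id}", best=best)

        self._eta_cache = np.zeros((self.engine.n, self.engine.p))
        tvp, om2, sig = self._unpack(best["x"])
        of, eta = self.engine.neg2ll(tvp, om2, sig, eta0=self._eta_cache,
                                     return_eta=True)
        return RetentionNLMEResults(
            model=self, x=np.asarray(best["x"], dtype=float), of=float(of),
            converged=True, n_starts_used=len(starts),
            best_start_index=best["start_index"], seed=seed, eta=eta,
        )

    def results_at(self, pop: PopulationParams,
                   seed: Optional[int] = None) -> "RetentionNLMEResults":
        """Build a results object at fixed population parameters (no fitting)."""
        pop.validate(self.soef)
        x = self._pack(pop)
        tvp, om2, sig = self._unpack(x)
        of, eta = self.engine.neg2ll(tvp, om2, sig,
                                     eta0=np.zeros((self.engine.n,
                                                    self.engine.p)),
                                     return_eta=True)
        return RetentionNLMEResults(
            model=self, x=x, of=float(of), converged=True, n_starts_used=0,
            best_start_index=-1, seed=seed, eta=eta)

    # ---- curvature ----

    def fd_hessian(self, x, h: float = 1e-3) -> np.ndarray:
        """Central finite-difference Hessian of the objective at ``x``."""
        x = np.asarray(x, dtype=float)
        d = x.size
        H = np.empty((d, d))
        f0 = self._objective(x)
        steps = np.full(d, h)
        fp = np.empty(d)
        fm = np.empty(d)
        for i in range(d):
            e = np.zeros(d)
            e[i] = steps[i]
            fp[i] = self._objective(x + e)
            fm[i] = self._objective(x - e)
            H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / steps[i] ** 2
        for i in range(d):
            for j in range(i + 1, d):
                ei = np.zeros(d); ei[i] = steps[i]
                ej = np.zeros(d); ej[j] = steps[j]
                H[i, j] = H[j, i] = (
                    self._objective(x + ei + ej) - self._objective(x + ei - ej)
                    - self._objective(x - ei + ej) + self._objective(x - ei - ej)
                ) / (4.0 * steps[i] * steps[j])
        return H


@dataclass
class RetentionNLMEResults:
    """Fitted population model: estimates, uncertainty and diagnostics."""

    model: RetentionNLME
    x: np.ndarray            # estimates on the search (log) scale
    of: float                # -2 log Laplace marginal likelihood
    converged: bool
    n_starts_used: int
    best_start_index: int
    seed: Optional[int]
    eta: np.ndarray          # empirical Bayes eta per patient (n, p)

    @property
    def model_id(self) -> str:
        return self.model.model_id

    @property
    def params(self) -> PopulationParams:
        return self.model._to_population_params(self.x)

    @property
    def nlme_K(self) -> int:
        """Parameter count for information criteria (2p + residual terms)."""
        return 2 * self.model.soef.n_structural + self.model.n_sigma

    @property
    def n_obs(self) -> int:
        return self.model.data.n_obs

    @property
    def param_labels(self):
        return list(self.model.param_labels)

    @property
    def estimates(self) -> np.ndarray:
        """Estimates on the natural scale, ordered as ``param_labels``."""
        return np.exp(self.x)

    # ---- uncertainty from the objective curvature ----

    @cached_property
    def _curvature(self):
        H = self.model.fd_hessian(self.x)
        ok = np.all(np.isfinite(H))
        cov_x = None
        if ok:
            try:
                # cov of search-scale params: inverse Hessian of -log L = of/2
                cov_x = np.linalg.inv(0.5 * H)
                ok = np.all(np.isfinite(cov_x)) and np.all(np.diag(cov_x) > 0)
            except np.linalg.LinAlgError:
                ok = False
        return dict(hessian=H, cov_x=cov_x, ok=bool(ok))

    @property
    def has_usable_covariance(self) -> bool:
        return self._curvature["ok"]

    def cov_params(self, natural: bool = True) -> np.ndarray:
        """Covariance of the estimates (natural scale via the delta method)."""
        c = self._curvature
        if not c["ok"]:
            raise np.linalg.LinAlgError(
                "singular or indefinite objective Hessian; no usable covariance")
        if not natural:
            return c["cov_x"]
        d = self.estimates
        return c["cov_x"] * np.outer(d, d)

    @cached_property
    def rse(self) -> Dict[str, float]:
        """Relative standard error of each estimate (SE / estimate)."""
        cov_x = self.cov_params(natural=False)
        se_log = np.sqrt(np.diag(cov_x))
        return dict(zip(self.param_labels, map(float, se_log)))

    @cached_property
    def correlation_matrix(self) -> np.ndarray:
        cov = self.cov_params(natural=False)
        d = np.sqrt(np.diag(cov))
        return cov / np.outer(d, d)

    @property
    def correlation_offdiag_max(self) -> float:
        c = np.abs(self.correlation_matrix.copy())
        np.fill_diagonal(c, 0.0)
        return float(min(c.max(), 1.0))

    # ---- empirical Bayes / individual quantities ----

    def empirical_bayes(self) -> Dict[str, Dict[str, float]]:
        """Per-patient posterior modes of eta at the population estimates."""
        names = self.model.soef.param_names
        return {pid: dict(zip(names, map(float, self.eta[i])))
                for i, pid in enumerate(self.model.engine.patient_ids)}

    def patient_params(self, patient_id: str) -> Dict[str, float]:
        """EBE-adjusted structural parameters P_i = TVP * exp(eta_i)."""
        pids = self.model.engine.patient_ids
        if patient_id not in pids:
            raise KeyError(f"unknown patient {patient_id!r}")
        i = pids.index(patient_id)
        p = self.model.soef.n_structural
        tvp = self.estimates[:p]
        return dict(zip(self.model.soef.param_names,
                        map(float, tvp * np.exp(self.eta[i]))))

    def patient_tia(self, patient_id: str) -> float:
        """Time-integrated activity (hours) for one patient from its EBEs."""
        return tia_closed_form(self.model_id, self.patient_params(patient_id))

    def tia_typical(self) -> float:
        """TIA of the typical (eta = 0) subject."""
        p = self.model.soef.n_structural
        params = dict(zip(self.model.soef.param_names, self.estimates[:p]))
        return tia_closed_form(self.model_id, params)

    def all_tias(self) -> Dict[str, float]:
        return {pid: self.patient_tia(pid)
                for pid in self.model.engine.patient_ids}

    # ---- simulation ----

    def simulate_replicates(self, n_rep: int, seed: Optional[int] = None
                            ) -> np.ndarray:
        """Simulate replicate observation vectors under the fitted model.

        Returns an (n_rep, n_obs) array aligned with the dataset's row order.
        """
        p = self.model.soef.n_structural
        tvp, om2, sig = self.model._unpack(self.x)
        rng = np.random.default_rng(seed)
        return self.model.engine.simulate(tvp, om2, sig, n_rep, rng)

    def population_prediction(self) -> np.ndarray:
        p = self.model.soef.n_structural
        return self.model.engine.population_prediction(self.estimates[:p])

    # ---- reporting ----

    def summary(self) -> str:
        lines = [
            f"Retention NLME results — model {self.model_id} "
            f"({self.model.error_model} error)",
            f"patients: {self.model.data.n_patients}   "
            f"observations: {self.n_obs}   K: {self.nlme_K}",
            f"-2 log L (Laplace): {self.of:.3f}   "
            f"starts: {self.n_starts_used} (best: #{self.best_start_index})",
            "-" * 58,
            f"{'parameter':<16}{'estimate':>12}{'RSE':>8}",
        ]
        try:
            rse = self.rse
        except np.linalg.LinAlgError:
            rse = {}
        for name, est in zip(self.param_labels, self.estimates):
            r = f"{rse[name]:.3f}" if name in rse else "n/a"
            lines.append(f"{name:<16}{est:>12.4g}{r:>8}")
        if rse:
            lines.append(f"max |off-diagonal correlation|: "
                         f"{self.correlation_offdiag_max:.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        pop = self.params
        out = dict(
            model_id=self.model_id, error_model=self.model.error_model,
            of=self.of, K=self.nlme_K, n_obs=self.n_obs,
            converged=self.converged, n_starts_used=self.n_starts_used,
            best_start_index=self.best_start_index, seed=self.seed,
            tvp=pop.tvp, omega2=pop.omega2, sigma2=pop.sigma2,
            ebe=self.empirical_bayes(),
        )
        try:
            out["rse"] = self.rse
            out["correlation_offdiag_max"] = self.correlation_offdiag_max
            out["covariance"] = self.cov_params().tolist()
        except np.linalg.LinAlgError:
            out["rse"] = None
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---- spec-level functional surface ----

def fit_nlme(model_id: str, data: RetentionDataset,
             error_model: str = "proportional", n_starts: int = 1000,
             seed: Optional[int] = None, **fit_kwargs) -> RetentionNLMEResults:
    """Fit one structural model by multi-start Laplace NLME estimation."""
    return RetentionNLME(data, model_id, error_model).fit(
        n_starts=n_starts, seed=seed, **fit_kwargs)


def marginal_neg2ll(model_id: str, pop: PopulationParams,
                    data: RetentionDataset) -> float:
    """Laplace -2 log marginal likelihood of ``pop`` on ``data``."""
    return RetentionNLME(data, model_id, pop.error_model).neg2ll(pop)


def empirical_bayes(model_id: str, pop: PopulationParams,
                    data: RetentionDataset) -> Dict[str, Dict[str, float]]:
    """Posterior modes of eta per patient at fixed population parameters."""
    m = RetentionNLME(data, model_id, pop.error_model)
    pop.validate(m.soef)
    names = m.soef.param_names
    tvp = np.array([pop.tvp[n] for n in names])
    om2 = np.array([pop.omega2[n] for n in names])
    sig = np.atleast_1d(np.asarray(pop.sigma2, dtype=float))
    eta, _, _ = m.engine.inner_solve(tvp, om2, sig,
                                     np.zeros((m.engine.n, m.engine.p)))
    return {pid: dict(zip(names, map(float, eta[i])))
            for i, pid in enumerate(m.engine.patient_ids)}


def posterior_eta(model_id: str, pop: PopulationParams,
                  times: Sequence[float], fractions: Sequence[float]
                  ) -> Dict[str, float]:
    """Posterior mode of eta for a single (possibly new) patient.

    With no observations the posterior equals the prior and the mode is the
    zero vector.
    """
    m = get_model(model_id)
    times = list(times)
    if len(times) == 0:
        return {n: 0.0 for n in m.param_names}
    data = RetentionDataset.from_records(
        [("_new", float(t), float(y)) for t, y in zip(times, fractions)])
    return empirical_bayes(model_id, pop, data)["_new"]


def sir_uncertainty(results: RetentionNLMEResults, n_samples: int = 2000,
                    n_resamples: int = 500, seed: Optional[int] = None,
                    proposal_inflation: float = 1.0) -> dict:
    """Sampling-importance-resampling parameter uncertainty.

    Draws ``n_samples`` parameter vectors from a multivariate-normal proposal
    centered at the estimate (covariance from the objective curvature, on the
    log search scale), weights each draw by the importance ratio between
    exp(-(of(theta) - of(theta_hat))/2) and the proposal density, and
    resamples ``n_resamples`` draws without replacement.  Reports per
    parameter the 2.5/97.5 percentile interval and RSE (resample SD divided
    by the point estimate) on the natural scale.
    """
    if not results.has_usable_covariance:
        raise np.linalg.LinAlgError("SIR requires a usable covariance proposal")
    rng = np.random.default_rng(seed)
    x_hat = results.x
    cov = results.cov_params(natural=False) * proposal_inflation
    d = x_hat.size
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(d))
    z = rng.standard_normal((n_samples, d))
    xs = x_hat + z @ L.T
    of_hat = results.of
    model = results.model
    log_w = np.empty(n_samples)
    for i in range(n_samples):
        model._eta_cache = results.eta.copy()
        of_i = model._objective(xs[i])
        # importance ratio: posterior kernel / proposal kernel (log scale)
        log_w[i] = -0.5 * (of_i - of_hat) + 0.5 * np.sum(z[i] ** 2)
    log_w -= log_w.max()
    w = np.exp(log_w)
    w_sum = w.sum()
    ess = w_sum ** 2 / np.sum(w ** 2)
    degenerate = ess < 0.1 * n_samples
    n_res = min(n_resamples, n_samples)
    idx = rng.choice(n_samples, size=n_res, replace=False, p=w / w_sum)
    nat = np.exp(xs[idx])
    est = results.estimates
    out = {}
    for k, name in enumerate(results.param_labels):
        lo, hi = np.percentile(nat[:, k], [2.5, 97.5])
        out[name] = dict(ci95=(float(lo), float(hi)),
                         rse=float(np.std(nat[:, k], ddof=1) / est[k]))
    return dict(parameters=out, ess=float(ess),
                degenerate_weights=bool(degenerate),
                n_samples=n_samples, n_resamples=n_res)
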