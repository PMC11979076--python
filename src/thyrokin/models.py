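"""Bank of sum-of-exponential structural models for thyroid radioiodine retention.

Each candidate model ``a_px`` describes the fraction of administered activity
retained in the thyroid as a sum of exponential terms,

    a_px(t) = sum_k A_k(theta) * exp(-(r_k(theta) + lambda_phys) * t),

where the amplitudes ``A_k`` are dimensionless fractions of the administered
activity, the biological rates ``r_k`` are in 1/h, and ``lambda_phys`` is the
physical decay constant of I-131.  The bank contains nine such functions with
three to six adjustable parameters, including the bi-exponential uptake and
clearance function used by the EANM standard operational procedure (``a3b``)
and its extension with a residual blood-pool amplitude (``a4c``).

All functions except ``a4c`` vanish at t = 0; ``a4c`` starts at its blood-pool
amplitude ``a1``.  The closed-form time-integrated activity (TIA) of every
model is ``sum_k A_k / (r_k + lambda_phys)`` in hours per unit administered
activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property
from typing import Dict, List, Sequence, Tuple

import numpy as np
import sympy as sp

__all__ = [
    "LAMBDA_PHYS",
    "T_HALF_PHYS_DAYS",
    "SOEF",
    "MODEL_IDS",
    "ParameterMismatchError",
    "SingularModelError",
    "DivergentIntegralError",
    "get_model",
    "model_bank",
    "evaluate_soef",
    "tia_closed_form",
]

#: Physical half-life of I-131 in days.
T_HALF_PHYS_DAYS = 8.022

#: Physical decay constant of I-131 in 1/h (single source of truth).
LAMBDA_PHYS = math.log(2.0) / (T_HALF_PHYS_DAYS * 24.0)

#: Guard on the a3b/a4c amplitude denominator lambda1 + lambda2 - lambda3.
SINGULAR_EPS = 1e-10


class ParameterMismatchError(ValueError):
    """Supplied parameter names do not match the model's parameter set."""


class SingularModelError(ValueError):
    """Model is numerically singular at the supplied parameters."""


class DivergentIntegralError(ValueError):
    """The time-integrated activity does not converge."""


_a1, _a2, _a3, _l1, _l2, _l3 = sp.symbols(
    "a1 a2 a3 lambda1 lambda2 lambda3", positive=True
)

_SYMBOLS = {"a1": _a1, "a2": _a2, "a3": _a3,
            "lambda1": _l1, "lambda2": _l2, "lambda3": _l3}


def _vec(fn):
    """Wrap a lambdified scalar function so the result broadcasts to full shape."""

    def wrapped(*args):
        shape = np.broadcast_shapes(*(np.shape(a) for a in args))
        out = fn(*args)
        return np.broadcast_to(np.asarray(out, dtype=float), shape)

    return wrapped


def _compile(expr, syms):
    """Compile a sympy expression to a float constant or a numpy callable."""
    if not expr.free_symbols:
        return float(expr)
    return sp.lambdify(syms, expr, "numpy")


def _ev(entry, cols):
    """Evaluate a compiled entry; returns a float or an array over the batch."""
    if callable(entry):
        return entry(*cols)
    return entry


@dataclass(frozen=True)
class SOEF:
    """Descriptor of one sum-of-exponentials structural model.

    Attributes
    ----------
    model_id
        Identifier used throughout reports and the CLI (``a3a`` ... ``a6b``).
    param_names
        Ordered adjustable parameters (amplitudes then rates).
    terms
        Sympy ``(amplitude, biological_rate)`` pairs defining the model.
    """

    model_id: str
    param_names: Tuple[str, ...]
    terms: Tuple[Tuple[sp.Expr, sp.Expr], ...]
    #: denominator expression that must stay away from zero, if any
    singular_denominator: sp.Expr | None = None

    @property
    def n_structural(self) -> int:
        return len(self.param_names)

    @property
    def nlme_K(self) -> int:
        # fixed effects + one variance per random effect + residual variance
        return 2 * self.n_structural + 1

    @property
    def symbols(self) -> Tuple[sp.Symbol, ...]:
        return tuple(_SYMBOLS[n] for n in self.param_names)

    # ---- compiled numeric kernels (built lazily, cached per instance) ----

    @cached_property
    def _kernel(self):
        """Per-term compiled (A, dA, d2A, r, dr).

        Structural zeros are dropped: ``dA`` holds (index, entry) pairs for
        non-zero first derivatives of the amplitude, ``d2A`` holds
        (i, j, entry) pairs over the upper triangle, and ``dr`` holds
        (index, coefficient) pairs of the rate (linear in the parameters for
        every model in the bank).
        """
        syms = self.symbols
        q = len(syms)
        compiled = []
        for amp, rate in self.terms:
            A = _compile(amp, syms)
            d1 = [sp.diff(amp, s) for s in syms]
            dA = [(k, _compile(d1[k], syms)) for k in range(q) if d1[k] != 0]
            d2A = []
            for i in range(q):
                if d1[i] == 0:
                    continue
                for j in range(i, q):
                    dd = sp.diff(d1[i], syms[j])
                    if dd != 0:
                        d2A.append((i, j, _compile(dd, syms)))
            r = _compile(rate, syms)
            dr = [(k, float(sp.diff(rate, s))) for k, s in enumerate(syms)
                  if sp.diff(rate, s) != 0]
            compiled.append((A, dA, d2A, r, dr))
        return compiled

    @cached_property
    def _denom_func(self):
        if self.singular_denominator is None:
            return None
        return _vec(sp.lambdify(self.symbols, self.singular_denominator, "numpy"))

    # ---- batched evaluation ----

    def _cols(self, P: np.ndarray) -> list:
        P = np.asarray(P, dtype=float)
        return [P[..., k] for k in range(self.n_structural)]

    @staticmethod
    def _bc(v):
        """Append a broadcast time axis to per-batch values."""
        return v[..., None] if isinstance(v, np.ndarray) else v

    def _out_shape(self, P, t):
        return np.broadcast_shapes(np.shape(P)[:-1] + (1,), np.shape(t))

    def predict(self, P: np.ndarray, t: np.ndarray) -> np.ndarray:
        """Evaluate a_px(t) for a batch of parameter vectors.

        ``P`` has shape (..., q) and ``t`` broadcasts against ``P[..., 0]``
        with a trailing time axis: typical shapes are P (n, q), t (n, m).
        """
        cols = self._cols(P)
        t = np.asarray(t, dtype=float)
        f = np.zeros(self._out_shape(P, t))
        for A, _, _, r, _ in self._kernel:
            e = np.exp(-(self._bc(_ev(r, cols)) + LAMBDA_PHYS) * t)
            f += self._bc(_ev(A, cols)) * e
        return f

    def predict_jac(self, P: np.ndarray, t: np.ndarray):
        """Return (f, df/dP) with shapes (n, m) and (n, m, q)."""
        cols = self._cols(P)
        t = np.asarray(t, dtype=float)
        q = self.n_structural
        shape = self._out_shape(P, t)
        f = np.zeros(shape)
        jac = np.zeros(shape + (q,))
        for A, dA, _, r, dr in self._kernel:
            e = np.exp(-(self._bc(_ev(r, cols)) + LAMBDA_PHYS) * t)
            aE = self._bc(_ev(A, cols)) * e
            f += aE
            for k, entry in dA:
                jac[..., k] += self._bc(_ev(entry, cols)) * e
            if dr:
                taE = t * aE
                for k, c in dr:
                    jac[..., k] -= c * taE
        return f, jac

    def predict_jac_hess(self, P: np.ndarray, t: np.ndarray):
        """Return (f, df/dP, d2f/dP2) with shapes (n,m), (n,m,q), (n,m,q,q)."""
        cols = self._cols(P)
        t = np.asarray(t, dtype=float)
        q = self.n_structural
        shape = self._out_shape(P, t)
        f = np.zeros(shape)
        jac = np.zeros(shape + (q,))
        hess = np.zeros(shape + (q, q))
        for A, dA, d2A, r, dr in self._kernel:
            e = np.exp(-(self._bc(_ev(r, cols)) + LAMBDA_PHYS) * t)
            aE = self._bc(_ev(A, cols)) * e
            f += aE
            dA_vals = {k: self._bc(_ev(entry, cols)) for k, entry in dA}
            for k, v in dA_vals.items():
                jac[..., k] += v * e
            if dr:
                taE = t * aE
                te = t * e
                t2aE = t * taE
                for k, c in dr:
                    jac[..., k] -= c * taE
                # cross amplitude x rate second derivatives
                for i, v in dA_vals.items():
                    vte = v * te
                    for j, c in dr:
                        hess[..., i, j] -= c * vte
                        hess[..., j, i] -= c * vte
                # rate x rate
                for i, ci in dr:
                    for j, cj in dr:
                        hess[..., i, j] += ci * cj * t2aE
            for i, j, entry in d2A:
                v = self._bc(_ev(entry, cols)) * e
                hess[..., i, j] += v
                if i != j:
                    hess[..., j, i] += v
        return f, jac, hess

    def denominator(self, P: np.ndarray):
        """a3b/a4c amplitude denominator, or None when the model has none."""
        fn = self._denom_func
        if fn is None:
            return None
        return fn(*self._cols(P))

    # ---- scalar conveniences ----

    def params_to_vector(self, params: Dict[str, float]) -> np.ndarray:
        got = set(params)
        expected = set(self.param_names)
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise ParameterMismatchError(
                f"model {self.model_id} expects parameters {list(self.param_names)}; "
                f"missing {missing}, unexpected {extra}"
            )
        vec = np.array([float(params[n]) for n in self.param_names])
        if np.any(vec < 0):
            raise ValueError(f"model {self.model_id}: parameters must be >= 0")
        return vec

    def term_values(self, params: Dict[str, float]) -> List[Tuple[float, float]]:
        """Numeric (amplitude, biological rate) pairs at a parameter point."""
        vec = self.params_to_vector(params)
        cols = list(vec)
        self._check_singularity(vec)
        return [(float(_ev(A, cols)), float(_ev(r, cols)))
                for A, _, _, r, _ in self._kernel]

    def _check_singularity(self, vec: np.ndarray) -> None:
        if self.singular_denominator is not None:
            den = float(self._denom_func(*list(vec)))
            if abs(den) < SINGULAR_EPS:
                raise SingularModelError(
                    f"model {self.model_id}: |lambda1 + lambda2 - lambda3| = "
                    f"{abs(den):.3e} below {SINGULAR_EPS:.0e}"
                )


def _make_bank() -> Dict[str, SOEF]:
    c3b = _l1 / (_l2 + _l1 - _l3)
    bank = [
        SOEF("a3a", ("a1", "lambda1", "lambda2"),
             (( _a1, _l1), (-_a1, _l2))),
        SOEF("a3b", ("lambda1", "lambda2", "lambda3"),
             ((c3b, _l3), (-c3b, _l1 + _l2)),
             singular_denominator=_l2 + _l1 - _l3),
        SOEF("a4a", ("a1", "a2", "lambda1", "lambda2"),
             ((_a1, _l1), (_a2, sp.Integer(0)), (-(_a1 + _a2), _l2))),
        SOEF("a4b", ("a1", "a2", "lambda1", "lambda2"),
             ((_a1 + _a2, sp.Integer(0)), (-_a1, _l1), (-_a2, _l2))),
        SOEF("a4c", ("a1", "lambda1", "lambda2", "lambda3"),
             ((c3b, _l3), (_a1 - c3b, _l1 + _l2)),
             singular_denominator=_l2 + _l1 - _l3),
        SOEF("a5a", ("a1", "a2", "lambda1", "lambda2", "lambda3"),
             ((_a1, _l1), (_a2, _l2), (-(_a1 + _a2), _l3))),
        SOEF("a5b", ("a1", "a2", "lambda1", "lambda2", "lambda3"),
             ((_a1 + _a2, _l1), (-_a1, _l2), (-_a2, _l3))),
        SOEF("a6a", ("a1", "a2", "a3", "lambda1", "lambda2", "lambda3"),
             ((_a1, _l1), (_a2, _l2), (_a3, sp.Integer(0)),
              (-(_a1 + _a2 + _a3), _l3))),
        SOEF("a6b", ("a1", "a2", "a3", "lambda1", "lambda2", "lambda3"),
             ((_a1, _l1), (_a2, sp.Integer(0)), (-_a3, _l2),
              (-(_a1 + _a2 - _a3), _l3))),
    ]
    return {m.model_id: m for m in bank}


_BANK = _make_bank()

#: Model identifiers in bank order (matching increasing complexity).
MODEL_IDS: Tuple[str, ...] = tuple(_BANK)


def get_model(model_id: str) -> SOEF:
    try:
        return _BANK[model_id]
    except KeyError:
        raise KeyError(f"unknown model id {model_id!r}; known: {list(_BANK)}") from None


def model_bank() -> List[SOEF]:
    """All nine structural model descriptors, in order of complexity."""
    return list(_BANK.values())


def evaluate_soef(model_id: str, params: Dict[str, float],
                  times: Sequence[float]) -> np.ndarray:
    """Evaluate the retention fraction a_px(t) at the given times (hours)."""
    m = get_model(model_id)
    vec = m.params_to_vector(params)
    m._check_singularity(vec)
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    out = m.predict(vec[None, :], t[None, :])[0]
    if not np.all(np.isfinite(out)):
        raise SingularModelError(f"model {model_id}: non-finite prediction")
    return out


def tia_closed_form(model_id: str, params: Dict[str, float]) -> float:
    """Analytic time-integrated activity, in hours per unit administered activity.

    Integrates each exponential term over [0, inf):
    TIA = sum_k A_k / (r_k + lambda_phys).
    """
    m = get_model(model_id)
    total = 0.0
    for amp, rate in m.term_values(params):
        eff = rate + LAMBDA_PHYS
        if eff <= 0:
            raise DivergentIntegralError(
                f"model {model_id}: effective decay rate {eff:.3e} <= 0"
            )
        total += amp / eff
    return float(total)
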