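"""Differentiable fuzzification and defuzzification operators.

A zero-order Takagi-Sugeno-Kang rule bank assigns each input ``x_i`` a
Gaussian membership degree per rule,

    mu_ij(x_i) = exp(-(x_i - m_ij)^2 / (2 sigma_ij^2)),

and aggregates the per-input memberships into a firing strength per rule.
The raw product of hundreds of memberships underflows, so the default
aggregation is the geometric mean in the exponent domain:

    e_j = sum_i (x_i - m_ij)^2 / (2 sigma_ij^2)
    strength_j = exp(-e_j / n_inputs)              (geometric-mean)
    strength_j = exp(-(e_j - min_k e_k))           (product-log)

Both keep strengths in (0, 1], preserve the ordering of rules and are
differentiable in x, m and sigma (product-log almost everywhere).
Defuzzification maps nonnegative rule activations back to crisp values by a
centre-of-gravity weighted average over learned centres.

All operators come with closed-form gradients; :func:`grad_check` verifies
them against central finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .io_deap import ValidationError

__all__ = [
    "SIGMA_MIN",
    "FuzzyRuleBank",
    "DefuzzParams",
    "gaussian_membership",
    "fuzzify",
    "fuzzify_backward",
    "defuzzify",
    "defuzzify_backward",
    "grad_check",
]

#: Floor on membership widths; sigmas below this are rejected (and, in the
#: network layer, prevented by softplus reparameterization).
SIGMA_MIN: float = 1e-3

Aggregation = Literal["geometric-mean", "product-log"]


@dataclass
class FuzzyRuleBank:
    """Gaussian membership parameters of a rule bank.

    ``means`` and ``sigmas`` have shape (n_inputs, n_rules); column j holds
    the antecedent of rule j. ``consequent_weights`` optionally carries
    zero-order TSK consequent constants (one per rule); the network realises
    consequents through its dense layer and defuzzification centres instead,
    so the field is informational.
    """

    means: np.ndarray
    sigmas: np.ndarray
    consequent_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=np.float64)
        self.sigmas = np.asarray(self.sigmas, dtype=np.float64)
        if self.means.ndim != 2:
            raise ValidationError("means must be 2-D (n_inputs x n_rules)")
        if self.sigmas.shape != self.means.shape:
            raise ValidationError(
                f"sigmas shape {self.sigmas.shape} must match means shape "
                f"{self.means.shape}"
            )
        if np.any(self.sigmas < SIGMA_MIN):
            raise ValidationError(f"all sigmas must be >= {SIGMA_MIN}")
        if self.consequent_weights is not None:
            w = np.asarray(self.consequent_weights, dtype=np.float64)
            if w.shape != (self.n_rules,):
                raise ValidationError(
                    f"consequent_weights must have shape ({self.n_rules},)"
                )
            self.consequent_weights = w

    @property
    def n_inputs(self) -> int:
        return self.means.shape[0]

    @property
    def n_rules(self) -> int:
        return self.means.shape[1]


@dataclass
class DefuzzParams:
    """Centres C of shape (n_outputs, n_rules) for centre-of-gravity defuzzification."""

    centers: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64)
        if self.centers.ndim != 2:
            raise ValidationError("centers must be 2-D (n_outputs x n_rules)")
        if not np.all(np.isfinite(self.centers)):
            raise ValidationError("centers must be finite")

    @property
    def n_outputs(self) -> int:
        return self.centers.shape[0]

    @property
    def n_rules(self) -> int:
        return self.centers.shape[1]


def gaussian_membership(u: float, m: float, sigma: float) -> float:
    """Gaussian membership degree exp(-(u - m)^2 / (2 sigma^2)) in (0, 1]."""
    if sigma < SIGMA_MIN:
        raise ValidationError(f"sigma must be >= {SIGMA_MIN}; got {sigma}")
    u, m = float(u), float(m)
    return float(np.exp(-((u - m) ** 2) / (2.0 * sigma**2)))


def _exponents(x: np.ndarray, bank: FuzzyRuleBank) -> np.ndarray:
    """e_j = sum_i (x_i - m_ij)^2 / (2 sigma_ij^2), shape (n_rules,)."""
    diff = x[:, None] - bank.means
    return (diff**2 / (2.0 * bank.sigmas**2)).sum(axis=0)


def fuzzify(
    x: np.ndarray,
    bank: FuzzyRuleBank,
    aggregation: Aggregation = "geometric-mean",
) -> np.ndarray:
    """Firing strength of each rule for a crisp input vector.

    The crisp input is treated as a singleton fuzzifier: each membership
    function is evaluated at the observed value. Strengths lie in (0, 1]
    and equal 1 exactly when x matches the rule's mean vector.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (bank.n_inputs,):
        raise ValidationError(
            f"x must have shape ({bank.n_inputs},); got {x.shape}"
        )
    e = _exponents(x, bank)
    if aggregation == "geometric-mean":
        return np.exp(-e / bank.n_inputs)
    if aggregation == "product-log":
        return np.exp(-(e - e.min()))
    raise ValidationError(f"unknown aggregation '{aggregation}'")


def fuzzify_backward(
    x: np.ndarray,
    bank: FuzzyRuleBank,
    grad_out: np.ndarray,
    aggregation: Aggregation = "geometric-mean",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of ``sum(grad_out * fuzzify(x))`` w.r.t. (x, means, sigmas).

    For product-log the min-shift term is differentiated through the argmin
    rule (locally constant almost everywhere).
    """
    x = np.asarray(x, dtype=np.float64)
    grad_out = np.asarray(grad_out, dtype=np.float64)
    e = _exponents(x, bank)
    diff = x[:, None] - bank.means  # (n_inputs, n_rules)
    de_dx = diff / bank.sigmas**2  # d e_j / d x_i
    de_dm = -de_dx
    de_dsigma = -(diff**2) / bank.sigmas**3

    if aggregation == "geometric-mean":
        s = np.exp(-e / bank.n_inputs)
        g = -grad_out * s / bank.n_inputs  # d loss / d e_j
    elif aggregation == "product-log":
        jstar = int(np.argmin(e))
        s = np.exp(-(e - e[jstar]))
        g = -grad_out * s
        g[jstar] += np.sum(grad_out * s)  # de_{j*} enters every strength
    else:
        raise ValidationError(f"unknown aggregation '{aggregation}'")

    grad_x = (de_dx * g[None, :]).sum(axis=1)
    grad_m = de_dm * g[None, :]
    grad_sigma = de_dsigma * g[None, :]
    return grad_x, grad_m, grad_sigma


def defuzzify(
    x: np.ndarray, params: DefuzzParams, eps: float = 1e-9
) -> np.ndarray:
    """Centre-of-gravity crisp output nu_k = sum_j C_kj x_j / (sum_j x_j + eps).

    For nonnegative activations with sum(x) >> eps the output lies in
    [min_j C_kj, max_j C_kj]; an all-zero activation vector maps to zero
    (the eps guard avoids a division error).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (params.n_rules,):
        raise ValidationError(
            f"x must have shape ({params.n_rules},); got {x.shape}"
        )
    if not np.all(np.isfinite(x)):
        raise ValidationError("x must be finite")
    if eps <= 0:
        raise ValidationError("eps must be positive")
    return params.centers @ x / (x.sum() + eps)


def defuzzify_backward(
    x: np.ndarray,
    params: DefuzzParams,
    grad_out: np.ndarray,
    eps: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of ``sum(grad_out * defuzzify(x))`` w.r.t. (x, centers)."""
    x = np.asarray(x, dtype=np.float64)
    grad_out = np.asarray(grad_out, dtype=np.float64)
    denom = x.sum() + eps
    nu = params.centers @ x / denom
    # d nu_k / d x_j = (C_kj - nu_k) / denom
    grad_x = ((params.centers - nu[:, None]) * grad_out[:, None]).sum(axis=0) / denom
    grad_c = grad_out[:, None] * x[None, :] / denom
    return grad_x, grad_c


def grad_check(
    operator: str,
    n_inputs: int = 5,
    n_rules: int = 3,
    n_outputs: int = 2,
    h: float = 1e-5,
    seed: int = 0,
    aggregation: Aggregation = "geometric-mean",
    corruption: float = 0.0,
) -> float:
    """Compare analytic gradients with central finite differences.

    Builds a random small instance, evaluates a random linear functional of
    the operator's output, and returns the maximum relative deviation
    between the analytic gradient and the central difference
    ``(f(p + h) - f(p - h)) / (2h)`` over every input and parameter.
    ``corruption`` is added to the analytic gradients to verify the harness
    detects faulty gradients.
    """
    if not (1e-7 <= h <= 1e-3):
        raise ValidationError("h must lie in [1e-7, 1e-3]")
    rng = np.random.default_rng(seed)

    def rel_dev(analytic: np.ndarray, numeric: np.ndarray) -> float:
        scale = np.maximum(np.maximum(np.abs(analytic), np.abs(numeric)), 1e-2)
        return float(np.max(np.abs(analytic - numeric) / scale))

    if operator == "fuzzify":
        x = rng.standard_normal(n_inputs)
        bank = FuzzyRuleBank(
            means=rng.standard_normal((n_inputs, n_rules)),
            sigmas=0.5 + rng.uniform(0, 1, (n_inputs, n_rules)),
        )
        w = rng.standard_normal(n_rules)  # random linear functional

        def f(xv: np.ndarray, m: np.ndarray, s: np.ndarray) -> float:
            b = FuzzyRuleBank(means=m, sigmas=s)
            return float(w @ fuzzify(xv, b, aggregation))

        gx, gm, gs = fuzzify_backward(x, bank, w, aggregation)
        devs = []
        for arr, grad, idx_of in (
            (x, gx + corruption, lambda a, i: (a, bank.means, bank.sigmas)),
            (bank.means, gm + corruption, lambda a, i: (x, a, bank.sigmas)),
            (bank.sigmas, gs + corruption, lambda a, i: (x, bank.means, a)),
        ):
            numeric = np.empty_like(arr, dtype=np.float64)
            flat = arr.reshape(-1)
            for i in range(flat.size):
                orig = flat[i]
                flat[i] = orig + h
                fp = f(*idx_of(arr, i))
                flat[i] = orig - h
                fm = f(*idx_of(arr, i))
                flat[i] = orig
                numeric.reshape(-1)[i] = (fp - fm) / (2 * h)
            devs.append(rel_dev(np.asarray(grad), numeric))
        return max(devs)

    if operator == "defuzzify":
        x = rng.uniform(0.1, 1.0, n_rules)
        params = DefuzzParams(centers=rng.standard_normal((n_outputs, n_rules)))
        w = rng.standard_normal(n_outputs)

        def g(xv: np.ndarray, c: np.ndarray) -> float:
            return float(w @ defuzzify(xv, DefuzzParams(centers=c)))

        gx, gc = defuzzify_backward(x, params, w)
        devs = []
        for arr, grad, call in (
            (x, gx + corruption, lambda a: g(a, params.centers)),
            (params.centers, gc + corruption, lambda a: g(x, a)),
        ):
            numeric = np.empty_like(arr, dtype=np.float64)
            flat = arr.reshape(-1)
            for i in range(flat.size):
                orig = flat[i]
                flat[i] = orig + h
                fp = call(arr)
                flat[i] = orig - h
                fm = call(arr)
                flat[i] = orig
                numeric.reshape(-1)[i] = (fp - fm) / (2 * h)
            devs.append(rel_dev(np.asarray(grad), numeric))
        return max(devs)

    raise ValidationError(f"unknown operator '{operator}'")
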