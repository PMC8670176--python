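"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's quadrature and likelihood code:
plain dense trapezoid integration and direct log-density arithmetic.
"""

import numpy as np


def trapezoid_expectation(f, sd: float = 1.0, lo: float = -10.0, hi: float = 10.0, n: int = 20001) -> float:
    """E[f(b)] for b ~ N(0, sd^2) by dense trapezoid integration."""
    b = np.linspace(lo, hi, n)
    phi = np.exp(-0.5 * (b / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
    return float(np.trapezoid(f(b) * phi, b))


def trapezoid_raw(g, lo: float, hi: float, n: int = 20001) -> float:
    """int g(b) db by dense trapezoid integration."""
    b = np.linspace(lo, hi, n)
    return float(np.trapezoid(g(b), b))


def logistic_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    """Sum of Bernoulli-logit log-likelihood terms, computed directly."""
    eta = np.asarray(eta, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


def multinomial_loglik(eta3: np.ndarray, y: np.ndarray) -> float:
    """Multinomial-logit log-likelihood with reference category 0.

    eta3: (n, 3) linear predictors for categories 1..3; y in {0,1,2,3}.
    """
    eta3 = np.asarray(eta3, dtype=float)
    full = np.column_stack([np.zeros(len(eta3)), eta3])
    lse = np.log(np.exp(full).sum(axis=1))
    picked = full[np.arange(len(y)), np.asarray(y, dtype=int)]
    return float(np.sum(picked - lse))
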