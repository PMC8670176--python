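"""Gauss-Hermite quadrature for normal random-effects integrals.

Rules are built against the *probabilist* weight: a base rule with ``Q``
points integrates ``E[f(Z)]`` for ``Z ~ N(0, 1)`` exactly for polynomials of
degree <= 2Q - 1.  Tensor-product rules extend this to ``N(0, D)`` in up to
three dimensions, and :func:`adapt_rule` recentres and rescales a rule at a
cluster's posterior mode so that sharply peaked integrands (per-mother
likelihood contributions) are integrated accurately with few nodes.

Every rule also carries log "raw" weights for integrating an unnormalised
integrand ``g`` directly, ``int g(b) db ~= sum_q exp(lw_q) g(b_q)``; the raw
weights fold in the reciprocal of the Gaussian kernel, the Jacobian of the
affine node transform, and stay in log space so that likelihood accumulation
over large clusters does not underflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import roots_hermitenorm

_LOG_2PI = float(np.log(2.0 * np.pi))

__all__ = ["QuadratureRule", "gh_rule", "tensor_rule", "adapt_rule"]


@dataclass(frozen=True)
class QuadratureRule:
    """A (possibly tensorised, possibly adapted) Gauss-Hermite rule.

    Attributes
    ----------
    nodes : (n_nodes, dim) array
        Abscissae in the space of the random effect ``b``.
    weights : (n_nodes,) array
        Probabilist weights: ``sum(weights) == 1`` and
        ``sum(w_q f(b_q)) ~= E[f(b)]`` under the rule's Gaussian measure.
    log_raw_weights : (n_nodes,) array
        Log-weights for raw integration, ``int g(b) db``.
    std_nodes : (n_nodes, dim) array
        The untransformed standard-normal tensor abscissae the rule was
        built from.
    """

    nodes: np.ndarray
    weights: np.ndarray
    log_raw_weights: np.ndarray
    std_nodes: np.ndarray
    dim: int
    points_per_dim: int
    adaptive: bool = False
    shift: np.ndarray | None = None
    scale: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def integrate_gauss(self, f) -> float:
        """Approximate ``E[f(b)]`` under the rule's Gaussian measure."""
        vals = np.asarray([f(x) for x in self.nodes], dtype=float)
        return float(self.weights @ vals)

    def integrate_raw(self, g) -> float:
        """Approximate ``int g(b) db`` for a non-negative integrand ``g``."""
        vals = np.asarray([g(x) for x in self.nodes], dtype=float)
        return float(np.exp(self.log_raw_weights) @ vals)


def gh_rule(q: int) -> QuadratureRule:
    """One-dimensional probabilist Gauss-Hermite rule with ``q`` points."""
    if q < 1:
        raise ValueError(f"need at least one quadrature point, got q={q}")
    x, w = roots_hermitenorm(int(q))
    w = w / np.sqrt(2.0 * np.pi)  # normalise against the N(0,1) kernel
    nodes = x[:, None]
    log_raw = np.log(w) + 0.5 * x**2 + 0.5 * _LOG_2PI
    return QuadratureRule(
        nodes=nodes,
        weights=w,
        log_raw_weights=log_raw,
        std_nodes=nodes,
        dim=1,
        points_per_dim=int(q),
    )


def tensor_rule(base: QuadratureRule, d: int, chol_d: np.ndarray | None = None) -> QuadratureRule:
    """Tensor-product rule over ``d`` dimensions against ``N(0, L L^T)``.

    Parameters
    ----------
    base : QuadratureRule
        A one-dimensional rule from :func:`gh_rule`.
    d : int
        Target dimension (1, 2 or 3).
    chol_d : (d, d) array, optional
        Lower-triangular Cholesky factor ``L`` of the covariance ``D``.
        Identity when omitted.
    """
    if base.dim != 1:
        raise ValueError("tensor_rule requires a one-dimensional base rule")
    if d not in (1, 2, 3):
        raise ValueError(f"dimension must be 1, 2 or 3, got {d}")
    z1 = base.std_nodes[:, 0]
    grids = np.meshgrid(*([z1] * d), indexing="ij")
    z = np.column_stack([g.ravel() for g in grids])  # (q^d, d)
    wgrids = np.meshgrid(*([base.weights] * d), indexing="ij")
    w = np.prod(np.column_stack([g.ravel() for g in wgrids]), axis=1)
    if chol_d is None:
        chol_d = np.eye(d)
    chol_d = np.asarray(chol_d, dtype=float)
    if chol_d.shape != (d, d):
        raise ValueError(f"chol_d must be {d}x{d}, got {chol_d.shape}")
    diag = np.diag(chol_d)
    if np.any(diag < 0):
        raise ValueError("Cholesky factor must have non-negative diagonal (D not PSD)")
    nodes = z @ chol_d.T
    # raw weights: int g(b) db = int g(Lz) |det L| dz
    logdet = float(np.sum(np.log(np.maximum(diag, 1e-300))))
    log_raw = np.log(w) + 0.5 * np.sum(z**2, axis=1) + 0.5 * d * _LOG_2PI + logdet
    return QuadratureRule(
        nodes=nodes,
        weights=w,
        log_raw_weights=log_raw,
        std_nodes=z,
        dim=d,
        points_per_dim=base.points_per_dim,
        scale=chol_d,
    )


def adapt_rule(base: QuadratureRule, mode: np.ndarray, curvature: np.ndarray) -> QuadratureRule:
    """Recentre a standard rule at a posterior mode with matching curvature.

    ``mode`` is the maximiser of the cluster log-integrand ``log g`` and
    ``curvature`` the negative Hessian of ``log g`` there.  Nodes become
    ``mode + S z`` with ``S S^T = curvature^{-1}``; the raw weights pick up
    the Jacobian ``|det S|`` and the reciprocal standard-normal kernel so
    that ``sum exp(lw_q) g(b_q) ~= int g(b) db`` -- exact in the Laplace
    limit where ``g`` is proportional to the matching Gaussian.

    A non-positive-definite curvature falls back to the unadapted rule with
    a warning rather than failing the whole likelihood evaluation.
    """
    d = base.dim
    mode = np.atleast_1d(np.asarray(mode, dtype=float))
    curvature = np.atleast_2d(np.asarray(curvature, dtype=float))
    if mode.shape != (d,) or curvature.shape != (d, d):
        raise ValueError("mode/curvature not conformable with the base rule dimension")
    try:
        r = np.linalg.cholesky(curvature)
    except np.linalg.LinAlgError:
        warnings.warn(
            "cluster curvature not positive definite; using non-adaptive rule",
            RuntimeWarning,
            stacklevel=2,
        )
        return base
    # S = (R^T)^{-1} with curvature = R R^T  =>  S S^T = curvature^{-1}
    s = np.linalg.inv(r).T
    z = base.std_nodes
    nodes = mode[None, :] + z @ s.T
    logdet_s = float(-np.sum(np.log(np.diag(r))))
    log_raw = np.log(base.weights) + 0.5 * np.sum(z**2, axis=1) + 0.5 * d * _LOG_2PI + logdet_s
    return QuadratureRule(
        nodes=nodes,
        weights=base.weights,
        log_raw_weights=log_raw,
        std_nodes=z,
        dim=d,
        points_per_dim=base.points_per_dim,
        adaptive=True,
        shift=mode,
        scale=s,
    )
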