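"""Joint random-effects models for preterm birth and perinatal death.

Four model variants over mother-clustered deliveries:

* bivariate logit with a **shared** random intercept ``b_i`` entering both
  outcome predictors (the shared-parameter model);
* bivariate logit with **separate but correlated** random intercepts
  ``(b_i1, b_i2) ~ N(0, D)``, one per outcome;
* multinomial logit for the four-category co-occurrence outcome with one
  shared random intercept across the three non-reference logits;
* multinomial logit with separate correlated random intercepts
  ``b_i ~ N(0, D_3x3)``, one per non-reference category.

The marginal likelihood integrates each mother's product of conditional
Bernoulli (or multinomial) factors over the random-effects distribution in
a single per-mother integral -- outcomes are conditionally independent given
``b_i``, and their marginal dependence arises purely through it.  Integrals
use Gauss-Hermite quadrature, by default adaptively recentred at each
cluster's posterior mode with scale from the curvature there (refreshed at
every likelihood evaluation), and all weights are carried in log space.

Variance parameters are encoded unconstrained: log standard deviations and
free Cholesky off-diagonals (log-Cholesky parameterisation), so quasi-Newton
maximisation is unconstrained.  Deliveries missing one outcome contribute
the observed outcome's factor only, which reconciles unequal per-outcome
denominators inside one joint fit; ``complete_case=True`` restricts to
deliveries with both outcomes observed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy.special import expit, logsumexp

from .quadrature import gh_rule, tensor_rule, QuadratureRule
from .schema import CODEBOOKS

__all__ = [
    "ModelSpec",
    "ModelFrame",
    "FitResult",
    "build_design",
    "encode_psi",
    "decode_psi",
    "loglik_bivariate",
    "loglik_multinomial",
    "fit_model",
    "score_and_information",
]

_LOG_2PI = float(np.log(2.0 * np.pi))
#: below this random-effect variance the integral is collapsed to b = 0
_DEGENERATE_VAR = 1e-12
#: |beta| beyond this triggers a separation warning
_SEPARATION_BOUND = 15.0


# ---------------------------------------------------------------------------
# model specification and design matrices
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """Which outcomes, which covariates per linear predictor, and the
    random-effects structure.

    ``kind`` is ``"bivariate"`` (outcomes preterm + perinatal death, possibly
    different covariate lists) or ``"multinomial"`` (co-occurrence outcome,
    one covariate list common to the three non-reference categories, with
    "neither event" as reference).  ``random_structure`` is ``"shared"``
    (scalar) or ``"correlated"`` (vector of dimension 2 or 3).
    """

    kind: str = "bivariate"
    covariates_preterm: list = field(default_factory=list)
    covariates_death: list = field(default_factory=list)
    covariates: list = field(default_factory=list)  # multinomial
    random_structure: str = "shared"
    equal_variances: bool = False  # bivariate correlated: D = s^2 [[1, r], [r, 1]]
    references: dict = field(default_factory=dict)
    year_origin: int | None = None
    complete_case: bool = False

    def __post_init__(self):
        if self.kind not in ("bivariate", "multinomial"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.random_structure not in ("shared", "correlated"):
            raise ValueError(f"unknown random_structure {self.random_structure!r}")

    @property
    def dim(self) -> int:
        if self.random_structure == "shared":
            return 1
        return 2 if self.kind == "bivariate" else 3

    @property
    def n_psi(self) -> int:
        if self.random_structure == "shared":
            return 1
        if self.kind == "bivariate" and self.equal_variances:
            return 2
        d = self.dim
        return d * (d + 1) // 2


def build_design(
    df: pd.DataFrame,
    covariates: list,
    references: dict | None = None,
    year_origin: int | None = None,
) -> tuple[np.ndarray, list, np.ndarray]:
    """Treatment-coded design matrix with intercept.

    ``"year"`` enters as calendar year minus ``year_origin`` (default: the
    minimum year present).  Categorical covariates use the registry code
    books where available (first category = reference unless overridden);
    numeric columns enter as-is.  Returns ``(X, term_names, complete_mask)``
    where the mask flags rows with all covariates non-missing -- X holds only
    those rows.
    """
    references = references or {}
    n = len(df)
    mask = np.ones(n, dtype=bool)
    for cov in covariates:
        if cov == "year":
            mask &= pd.to_numeric(df["year"], errors="coerce").notna().to_numpy()
        else:
            col = df[cov]
            if pd.api.types.is_numeric_dtype(col):
                mask &= col.notna().to_numpy()
            else:
                mask &= (col.notna() & (col.astype(str) != "")).to_numpy()
    sub = df.loc[mask]
    cols, names = [np.ones(mask.sum())], ["intercept"]
    for cov in covariates:
        if cov == "year":
            origin = year_origin if year_origin is not None else int(df["year"].min())
            cols.append(sub["year"].to_numpy(float) - origin)
            names.append("year")
            continue
        col = sub[cov]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(float))
            names.append(cov)
            continue
        observed = set(col.unique())
        categories = [c for c in CODEBOOKS.get(cov, tuple(sorted(observed))) if c in observed]
        if not categories:
            raise ValueError(f"covariate {cov!r} has no recognised categories")
        ref = references.get(cov, categories[0])
        if ref not in categories:
            raise ValueError(f"reference {ref!r} not among observed categories of {cov!r}")
        vals = col.to_numpy()
        for cat in categories:
            if cat == ref:
                continue
            cols.append((vals == cat).astype(float))
            names.append(f"{cov}[{cat}]")
    return np.column_stack(cols), names, mask


# ---------------------------------------------------------------------------
# variance-parameter encoding (log-Cholesky)
# ---------------------------------------------------------------------------


def decode_psi(psi: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Unconstrained psi -> random-effects covariance matrix D (d x d)."""
    psi = np.asarray(psi, dtype=float)
    if spec.random_structure == "shared":
        return np.array([[np.exp(2.0 * psi[0])]])
    if spec.kind == "bivariate" and spec.equal_variances:
        s2 = np.exp(2.0 * psi[0])
        rho = np.tanh(psi[1])
        return s2 * np.array([[1.0, rho], [rho, 1.0]])
    d = spec.dim
    L = np.zeros((d, d))
    k = 0
    for i in range(d):
        for j in range(i + 1):
            L[i, j] = np.exp(psi[k]) if i == j else psi[k]
            k += 1
    return L @ L.T


def encode_psi(D: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Covariance matrix (or scalar variance) -> unconstrained psi."""
    if spec.random_structure == "shared":
        s2 = float(np.atleast_2d(D)[0, 0])
        return np.array([0.5 * np.log(max(s2, 1e-300))])
    D = np.atleast_2d(np.asarray(D, dtype=float))
    if spec.kind == "bivariate" and spec.equal_variances:
        s2 = D[0, 0]
        rho = np.clip(D[0, 1] / s2, -1 + 1e-12, 1 - 1e-12)
        return np.array([0.5 * np.log(s2), np.arctanh(rho)])
    L = np.linalg.cholesky(D)
    out = []
    for i in range(spec.dim):
        for j in range(i + 1):
            out.append(np.log(L[i, j]) if i == j else L[i, j])
    return np.asarray(out)


# ---------------------------------------------------------------------------
# prepared data
# ---------------------------------------------------------------------------


class ModelFrame:
    """Design matrices, stacked responses and cluster indexing for one spec."""

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        if "preterm" not in data.columns or "perinatal_death" not in data.columns:
            raise ValueError("data must carry derived outcome columns (see schema.derive_outcomes)")
        if spec.kind == "bivariate":
            self._init_bivariate(data)
        else:
            self._init_multinomial(data)
        if self.n_clusters == 0:
            raise ValueError("empty cluster set: no usable observations")
        self._mode_cache: np.ndarray | None = None

    # -- construction -----------------------------------------------------
    def _init_bivariate(self, data: pd.DataFrame) -> None:
        spec = self.spec
        pt = pd.to_numeric(data["preterm"], errors="coerce").to_numpy(float)
        dt = pd.to_numeric(data["perinatal_death"], errors="coerce").to_numpy(float)
        if spec.complete_case:
            cc = np.isfinite(pt) & np.isfinite(dt)
            pt = np.where(cc, pt, np.nan)
            dt = np.where(cc, dt, np.nan)
        xs, ys, masks, self.term_names = [], [], [], []
        for label, covs, yv in (
            ("preterm", spec.covariates_preterm, pt),
            ("death", spec.covariates_death, dt),
        ):
            X, names, cmask = build_design(data, covs, spec.references, spec.year_origin)
            omask = np.isfinite(yv) & cmask
            xs.append(X[omask[cmask]])
            ys.append(yv[omask])
            masks.append(omask)
            self.term_names.append([f"{label}:{t}" for t in names])
        self.X = xs
        mothers = data["mother_id"].to_numpy()
        used = masks[0] | masks[1]
        codes, uniques = pd.factorize(mothers[used])
        lookup = pd.Series(np.arange(len(uniques)), index=uniques)
        cl = np.concatenate([lookup[mothers[m]].to_numpy() for m in masks])
        comp0 = np.zeros(masks[0].sum(), dtype=np.intp)
        comp1 = np.ones(masks[1].sum(), dtype=np.intp)
        y = np.concatenate(ys)
        comp = np.concatenate([comp0, comp1])
        order = np.argsort(cl, kind="stable")
        self.y = y[order]
        self.cl = cl[order]
        self.comp = comp[order]
        self._perm = order
        self.n_clusters = len(uniques)
        self.starts = np.flatnonzero(np.r_[True, np.diff(self.cl) > 0])
        self.n_obs = {"preterm": int(masks[0].sum()), "death": int(masks[1].sum())}
        self.n_records = int(used.sum())
        self.n_beta = [x.shape[1] for x in self.X]

    def _init_multinomial(self, data: pd.DataFrame) -> None:
        spec = self.spec
        co = pd.to_numeric(data["cooccurrence"], errors="coerce").to_numpy(float)
        X, names, cmask = build_design(data, spec.covariates, spec.references, spec.year_origin)
        omask = np.isfinite(co) & cmask
        self.X = [X[omask[cmask]]]
        labels = {1: "both", 2: "death_only", 3: "preterm_only"}
        self.term_names = [[f"{labels[c]}:{t}" for t in names] for c in (1, 2, 3)]
        y = co[omask].astype(np.intp)
        mothers = data["mother_id"].to_numpy()[omask]
        codes, uniques = pd.factorize(mothers)
        order = np.argsort(codes, kind="stable")
        self.y = y[order]
        self.cl = codes[order]
        self.comp = np.zeros(0, dtype=np.intp)
        self._perm = order
        self.n_clusters = len(uniques)
        self.starts = np.flatnonzero(np.r_[True, np.diff(self.cl) > 0])
        self.n_obs = {"cooccurrence": int(omask.sum())}
        self.n_records = int(omask.sum())
        self.n_beta = [self.X[0].shape[1]] * 3

    # -- parameter layout -------------------------------------------------
    @property
    def param_names(self) -> list:
        names = [t for block in self.term_names for t in block]
        spec = self.spec
        if spec.random_structure == "shared":
            return names + ["log_sd"]
        if spec.kind == "bivariate" and spec.equal_variances:
            return names + ["log_sd", "atanh_rho"]
        extra = []
        for i in range(spec.dim):
            for j in range(i + 1):
                extra.append(f"chol[{i},{j}]" if i != j else f"log_chol[{i},{i}]")
        return names + extra

    @property
    def n_params(self) -> int:
        return sum(self.n_beta) + self.spec.n_psi

    def split_theta(self, theta: np.ndarray):
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ValueError(f"theta must have length {self.n_params}, got {theta.shape}")
        if self.spec.kind == "bivariate":
            p1, p2 = self.n_beta
            betas = [theta[:p1], theta[p1 : p1 + p2]]
            psi = theta[p1 + p2 :]
        else:
            p = self.n_beta[0]
            betas = [theta[c * p : (c + 1) * p] for c in range(3)]
            psi = theta[3 * p :]
        return betas, psi

    # -- linear predictors ------------------------------------------------
    def _offsets_bivariate(self, betas) -> np.ndarray:
        off = np.concatenate([self.X[0] @ betas[0], self.X[1] @ betas[1]])[self._perm]
        if not np.all(np.isfinite(off)):
            bad = int(self.cl[np.flatnonzero(~np.isfinite(off))[0]])
            raise ValueError(f"non-finite linear predictor in cluster {bad}")
        return off

    def _offsets_multinomial(self, betas) -> np.ndarray:
        off = (self.X[0] @ np.column_stack(betas))[self._perm]
        if not np.all(np.isfinite(off)):
            bad = int(self.cl[np.flatnonzero(~np.isfinite(off.sum(axis=1)))[0]])
            raise ValueError(f"non-finite linear predictor in cluster {bad}")
        return off


@lru_cache(maxsize=32)
def _std_tensor(q: int, d: int) -> tuple[np.ndarray, np.ndarray]:
    """Standard-normal tensor nodes (M, d) and log prob-weights (M,)."""
    rule = tensor_rule(gh_rule(q), d)
    return rule.std_nodes, np.log(rule.weights)


def _segment_sum(values: np.ndarray, starts: np.ndarray) -> np.ndarray:
    return np.add.reduceat(values, starts, axis=0)


def _chol_batched(H: np.ndarray) -> np.ndarray:
    """Batched Cholesky with escalating jitter for near-singular curvatures."""
    try:
        return np.linalg.cholesky(H)
    except np.linalg.LinAlgError:
        d = H.shape[-1]
        scale = np.maximum(np.einsum("...ii->...", H) / d, 1.0)
        eye = np.eye(d)
        for k in range(7):
            jitter = 10.0 ** (-10 + 2 * k) * scale
            try:
                return np.linalg.cholesky(H + jitter[..., None, None] * eye)
            except np.linalg.LinAlgError:
                continue
        raise


def _sym_inv(A: np.ndarray) -> np.ndarray:
    out = np.linalg.inv(A)
    return 0.5 * (out + out.T)


def _bincount(cl, weights, g):
    return np.bincount(cl, weights=weights, minlength=g)


# ---------------------------------------------------------------------------
# Bernoulli (bivariate) engine
# ---------------------------------------------------------------------------


def _bivariate_modes(frame: ModelFrame, off, Dinv, d, comp, tol=1e-8, max_iter=50):
    g = frame.n_clusters
    y, cl = frame.y, frame.cl
    b = np.zeros((g, d))
    if frame._mode_cache is not None and frame._mode_cache.shape == b.shape:
        b = frame._mode_cache.copy()

    def logpost(bm):
        eta = off + bm[cl, comp]
        ll = -np.logaddexp(0.0, np.where(y == 1, -eta, eta))
        return _bincount(cl, ll, g) - 0.5 * np.einsum("gi,ij,gj->g", bm, Dinv, bm)

    lp = logpost(b)
    H = np.tile(Dinv, (g, 1, 1))
    for _ in range(max_iter):
        eta = off + b[cl, comp]
        p = expit(eta)
        r = y - p
        w = p * (1.0 - p)
        grad = -b @ Dinv
        H = np.tile(Dinv, (g, 1, 1))
        for j in range(d):
            m = comp == j
            grad[:, j] += _bincount(cl[m], r[m], g)
            H[:, j, j] += _bincount(cl[m], w[m], g)
        step = np.linalg.solve(H + 1e-10 * np.eye(d), grad[..., None])[..., 0]
        # affine-invariant Newton decrement: robust to the huge curvature
        # scales a near-singular D induces, where an absolute gradient
        # tolerance is unattainable in floating point
        decrement = np.einsum("gi,gi->g", grad, step)
        if decrement.max() < tol:
            break
        t = np.ones(g)
        bn, lpn = b + step, None
        for _ in range(20):
            bn = b + t[:, None] * step
            lpn = logpost(bn)
            bad = lpn < lp - 1e-10
            if not bad.any():
                break
            t[bad] *= 0.5
        b, lp = bn, lpn
    frame._mode_cache = b
    return b, H


def _cluster_logliks_bivariate(theta, frame: ModelFrame, q: int, adaptive: bool) -> np.ndarray:
    spec = frame.spec
    betas, psi = frame.split_theta(theta)
    D = decode_psi(psi, spec)
    d = spec.dim
    off = frame._offsets_bivariate(betas)
    y, cl, starts, g = frame.y, frame.cl, frame.starts, frame.n_clusters
    # shared structure: both outcomes load on the single component
    comp = frame.comp if d > 1 else np.zeros_like(frame.comp)

    if np.max(np.diag(D)) < _DEGENERATE_VAR:
        ll = -np.logaddexp(0.0, np.where(y == 1, -off, off))
        return _bincount(cl, ll, g)

    z, logw = _std_tensor(q, d)
    if not adaptive:
        chol = np.linalg.cholesky(D + 1e-14 * np.eye(d))
        B = z @ chol.T  # (M, d)
        eta = off[:, None] + B[:, comp].T
        ll = -np.logaddexp(0.0, np.where(y[:, None] == 1, -eta, eta))
        lc = _segment_sum(ll, starts)
        return logsumexp(logw[None, :] + lc, axis=1)

    # one consistent jittered matrix for the inverse and the normalising
    # determinant -- mismatched jitters make the prior density integrate to
    # more than 1 when D is near-singular
    d_jit = D + 1e-10 * np.eye(d)
    Dinv = _sym_inv(d_jit)
    _, logdet_D = np.linalg.slogdet(d_jit)
    modes, H = _bivariate_modes(frame, off, Dinv, d, comp)
    R = _chol_batched(H)  # (g, d, d)
    S = np.linalg.inv(R).transpose(0, 2, 1)
    logdet_S = -np.log(np.diagonal(R, axis1=1, axis2=2)).sum(axis=1)
    b_all = modes[:, None, :] + z @ S.transpose(0, 2, 1)  # (g, M, d)
    b_sel = b_all[cl, :, comp]  # (n, M)
    eta = off[:, None] + b_sel
    ll = -np.logaddexp(0.0, np.where(y[:, None] == 1, -eta, eta))
    lc = _segment_sum(ll, starts)
    c_dinv = np.linalg.cholesky(Dinv)  # quad form b' Dinv b = ||C^T b||^2
    t = b_all @ c_dinv
    quad = np.ascontiguousarray(t * t).sum(axis=2)
    log_phi = -0.5 * quad - 0.5 * (d * _LOG_2PI + logdet_D)
    base = logw[None, :] + 0.5 * np.sum(z**2, axis=1)[None, :] + 0.5 * d * _LOG_2PI
    return logsumexp(base + logdet_S[:, None] + lc + log_phi, axis=1)


# ---------------------------------------------------------------------------
# multinomial engine
# ---------------------------------------------------------------------------


def _multinomial_probs(eta3: np.ndarray) -> np.ndarray:
    """Category probabilities (ref 0 has linear predictor 0). eta3: (..., 3)."""
    full = np.concatenate([np.zeros(eta3.shape[:-1] + (1,)), eta3], axis=-1)
    full = full - full.max(axis=-1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=-1, keepdims=True)


def _multinomial_ll_obs(eta3: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-observation log category probability; eta3 (n, M, 3), y (n,).

    The reference category has linear predictor 0, folded in without
    materialising a fourth column: lse = m + log(e^{-m} + sum_c e^{eta_c-m}).
    """
    m = np.maximum(eta3.max(axis=2), 0.0)  # (n, M)
    sumexp = np.exp(-m)
    for c in range(3):
        sumexp += np.exp(eta3[:, :, c] - m)
    lse = m + np.log(sumexp)
    nz = y > 0
    pick = np.zeros_like(lse)
    idx = np.maximum(y - 1, 0)
    pick[nz] = np.take_along_axis(eta3[nz], idx[nz, None, None], axis=2)[:, :, 0]
    return pick - lse


def _multinomial_modes(frame: ModelFrame, off3, Dinv, d, shared, tol=1e-8, max_iter=50):
    g = frame.n_clusters
    y, cl = frame.y, frame.cl
    ind = np.zeros((len(y), 3))
    for c in range(3):
        ind[:, c] = y == c + 1
    b = np.zeros((g, d))
    if frame._mode_cache is not None and frame._mode_cache.shape == b.shape:
        b = frame._mode_cache.copy()

    def eta_at(bm):
        if shared:
            return off3 + bm[cl, 0][:, None]
        return off3 + bm[cl]

    def logpost(bm):
        eta = eta_at(bm)
        full = np.concatenate([np.zeros((len(y), 1)), eta], axis=1)
        lse = logsumexp(full, axis=1)
        picked = np.take_along_axis(full, y[:, None], axis=1)[:, 0]
        return _bincount(cl, picked - lse, g) - 0.5 * np.einsum("gi,ij,gj->g", bm, Dinv, bm)

    lp = logpost(b)
    H = np.tile(Dinv, (g, 1, 1))
    for _ in range(max_iter):
        eta = eta_at(b)
        P = _multinomial_probs(eta)[:, 1:]  # (n, 3) for categories 1..3
        grad = -b @ Dinv
        H = np.tile(Dinv, (g, 1, 1))
        if shared:
            pp = P.sum(axis=1)
            grad[:, 0] += _bincount(cl, ind.sum(axis=1) - pp, g)
            H[:, 0, 0] += _bincount(cl, pp * (1.0 - pp), g)
        else:
            for c in range(3):
                grad[:, c] += _bincount(cl, ind[:, c] - P[:, c], g)
                for c2 in range(c, 3):
                    # Fisher block of the category probabilities: diag(P) - P P^T
                    w = P[:, c] * ((1.0 if c == c2 else 0.0) - P[:, c2])
                    acc = _bincount(cl, w, g)
                    H[:, c, c2] += acc
                    if c2 != c:
                        H[:, c2, c] += acc
        step = np.linalg.solve(H + 1e-10 * np.eye(d), grad[..., None])[..., 0]
        # affine-invariant Newton decrement: robust to the huge curvature
        # scales a near-singular D induces, where an absolute gradient
        # tolerance is unattainable in floating point
        decrement = np.einsum("gi,gi->g", grad, step)
        if decrement.max() < tol:
            break
        t = np.ones(g)
        bn, lpn = b + step, None
        for _ in range(20):
            bn = b + t[:, None] * step
            lpn = logpost(bn)
            bad = lpn < lp - 1e-10
            if not bad.any():
                break
            t[bad] *= 0.5
        b, lp = bn, lpn
    frame._mode_cache = b
    return b, H


def _cluster_logliks_multinomial(theta, frame: ModelFrame, q: int, adaptive: bool) -> np.ndarray:
    spec = frame.spec
    betas, psi = frame.split_theta(theta)
    D = decode_psi(psi, spec)
    d = spec.dim
    shared = spec.random_structure == "shared"
    off3 = frame._offsets_multinomial(betas)  # (n, 3)
    y, cl, starts, g = frame.y, frame.cl, frame.starts, frame.n_clusters

    if np.max(np.diag(D)) < _DEGENERATE_VAR:
        ll = _multinomial_ll_obs(off3[:, None, :], y)[:, 0]
        return _bincount(cl, ll, g)

    z, logw = _std_tensor(q, d)
    m = z.shape[0]
    if not adaptive:
        chol = np.linalg.cholesky(D + 1e-14 * np.eye(d))
        B = z @ chol.T  # (M, d)
        if shared:
            eta = off3[:, None, :] + B[None, :, 0, None]
        else:
            eta = off3[:, None, :] + B[None, :, :]
        ll = _multinomial_ll_obs(eta, y)
        lc = _segment_sum(ll, starts)
        return logsumexp(logw[None, :] + lc, axis=1)

    # one consistent jittered matrix for the inverse and the normalising
    # determinant -- mismatched jitters make the prior density integrate to
    # more than 1 when D is near-singular
    d_jit = D + 1e-10 * np.eye(d)
    Dinv = _sym_inv(d_jit)
    _, logdet_D = np.linalg.slogdet(d_jit)
    modes, H = _multinomial_modes(frame, off3, Dinv, d, shared)
    R = _chol_batched(H)
    S = np.linalg.inv(R).transpose(0, 2, 1)
    logdet_S = -np.log(np.diagonal(R, axis1=1, axis2=2)).sum(axis=1)
    b_all = modes[:, None, :] + z @ S.transpose(0, 2, 1)  # (g, M, d)
    if shared:
        eta = off3[:, None, :] + b_all[cl, :, 0][:, :, None]
    else:
        eta = off3[:, None, :] + b_all[cl]
    ll = _multinomial_ll_obs(eta, y)
    lc = _segment_sum(ll, starts)
    c_dinv = np.linalg.cholesky(Dinv)
    t = b_all @ c_dinv
    quad = np.ascontiguousarray(t * t).sum(axis=2)
    log_phi = -0.5 * quad - 0.5 * (d * _LOG_2PI + logdet_D)
    base = logw[None, :] + 0.5 * np.sum(z**2, axis=1)[None, :] + 0.5 * d * _LOG_2PI
    return logsumexp(base + logdet_S[:, None] + lc + log_phi, axis=1)


# ---------------------------------------------------------------------------
# public likelihood API
# ---------------------------------------------------------------------------


def _resolve_q(rule) -> int:
    if isinstance(rule, QuadratureRule):
        return rule.points_per_dim
    return int(rule)


def cluster_logliks(theta, frame: ModelFrame, rule=10, adaptive: bool = True) -> np.ndarray:
    """Per-mother log marginal likelihood contributions."""
    q = _resolve_q(rule)
    if frame.spec.kind == "bivariate":
        return _cluster_logliks_bivariate(theta, frame, q, adaptive)
    return _cluster_logliks_multinomial(theta, frame, q, adaptive)


def loglik_bivariate(theta, data, spec: ModelSpec, rule=10, adaptive: bool = True) -> float:
    """Marginal log-likelihood of a bivariate joint logit model.

    ``rule`` is a base one-dimensional rule (or a point count); it is
    tensorised internally for the correlated structure.
    """
    if spec.kind != "bivariate":
        raise ValueError("spec must be bivariate")
    frame = data if isinstance(data, ModelFrame) else ModelFrame(data, spec)
    return float(cluster_logliks(theta, frame, rule, adaptive).sum())


def loglik_multinomial(theta, data, spec: ModelSpec, rule=10, adaptive: bool = True) -> float:
    """Marginal log-likelihood of a random-effects multinomial logit model."""
    if spec.kind != "multinomial":
        raise ValueError("spec must be multinomial")
    frame = data if isinstance(data, ModelFrame) else ModelFrame(data, spec)
    return float(cluster_logliks(theta, frame, rule, adaptive).sum())


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Estimates, variances and diagnostics from one maximum-likelihood fit."""

    model: str
    random_structure: str
    param_names: list
    theta: np.ndarray
    D: np.ndarray
    loglik: float
    n_params: int
    bic: float
    n_mothers: int
    n_records: int
    n_obs: dict
    converged: bool
    n_iter: int
    grad_norm: float
    vcov_model: np.ndarray | None = None
    vcov_robust: np.ndarray | None = None
    quad_points: int = 10
    adaptive: bool = True

    @property
    def sigma2(self) -> float:
        return float(self.D[0, 0])

    @property
    def estimates(self) -> dict:
        return dict(zip(self.param_names, self.theta))

    def se(self, vcov: str = "model") -> np.ndarray:
        v = self.vcov_model if vcov == "model" else self.vcov_robust
        if v is None:
            raise ValueError(f"{vcov} covariance was not computed for this fit")
        return np.sqrt(np.clip(np.diag(v), 0.0, None))

    def to_json(self, path) -> None:
        payload = {
            "model": self.model,
            "random_structure": self.random_structure,
            "param_names": list(self.param_names),
            "theta": self.theta.tolist(),
            "D": self.D.tolist(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "bic": self.bic,
            "n_mothers": self.n_mothers,
            "n_records": self.n_records,
            "n_obs": self.n_obs,
            "converged": bool(self.converged),
            "n_iter": self.n_iter,
            "grad_norm": self.grad_norm,
            "vcov_model": None if self.vcov_model is None else self.vcov_model.tolist(),
            "vcov_robust": None if self.vcov_robust is None else self.vcov_robust.tolist(),
            "quad_points": self.quad_points,
            "adaptive": self.adaptive,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            p = json.load(fh)
        for key in ("theta", "D", "vcov_model", "vcov_robust"):
            if p.get(key) is not None:
                p[key] = np.asarray(p[key])
        return cls(**p)


def _initial_beta(frame: ModelFrame) -> list:
    """Outcome-wise non-random-effects fits; zero-ish fallback on failure."""
    betas = []
    if frame.spec.kind == "bivariate":
        # recover per-outcome y in design order via the stored permutation
        inv = np.empty_like(frame._perm)
        inv[frame._perm] = np.arange(len(frame._perm))
        y_stacked = frame.y[inv]
        n1 = frame.X[0].shape[0]
        ys = [y_stacked[:n1], y_stacked[n1:]]
        for X, yv in zip(frame.X, ys):
            betas.append(_safe_logit_fit(X, yv))
    else:
        inv = np.empty_like(frame._perm)
        inv[frame._perm] = np.arange(len(frame._perm))
        y = frame.y[inv]
        X = frame.X[0]
        betas = _safe_mnlogit_fit(X, y)
    return betas


def _safe_logit_fit(X, y):
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if np.all(np.isfinite(res.params)):
            return np.asarray(res.params)
    except Exception:
        pass
    beta = np.zeros(X.shape[1])
    pbar = float(np.clip(np.mean(y), 1e-4, 1 - 1e-4))
    beta[0] = np.log(pbar / (1.0 - pbar))
    return beta


def _safe_mnlogit_fit(X, y):
    p = X.shape[1]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MNLogit(y, X).fit(disp=0, maxiter=200)
        params = np.asarray(res.params)  # (p, n_cats - 1)
        if params.shape == (p, 3) and np.all(np.isfinite(params)):
            return [params[:, c] for c in range(3)]
    except Exception:
        pass
    out = []
    n = len(y)
    for c in (1, 2, 3):
        beta = np.zeros(p)
        frac = float(np.clip(np.mean(y == c), 1e-4, 1 - 1e-4))
        ref = float(np.clip(np.mean(y == 0), 1e-4, 1 - 1e-4))
        beta[0] = np.log(frac / ref)
        out.append(beta)
    return out


def fit_model(
    spec: ModelSpec,
    data,
    quad_points: int = 10,
    adaptive: bool = True,
    compute_vcov: bool = True,
    robust: bool = True,
    start: np.ndarray | None = None,
    maxiter: int = 300,
    ftol: float = 1e-9,
) -> FitResult:
    """Maximum-likelihood fit by quasi-Newton (L-BFGS-B) over encoded theta.

    Deterministic: fixed-effects starting values come from outcome-wise
    logistic / multinomial fits and variance parameters start at
    log-SD = log 0.3, so refitting identical data reproduces the result
    bit-for-bit.  A non-converged optimum is flagged, not raised.
    """
    frame = data if isinstance(data, ModelFrame) else ModelFrame(data, spec)
    if frame.n_clusters < 2:
        raise ValueError("need at least 2 clusters (mothers) to fit")
    if start is None:
        betas = _initial_beta(frame)
        psi0 = np.full(spec.n_psi, 0.0)
        psi_init = np.log(0.3)
        if spec.random_structure == "shared":
            psi0[:] = psi_init
        elif spec.kind == "bivariate" and spec.equal_variances:
            psi0[0] = psi_init
        else:
            k = 0
            for i in range(spec.dim):
                for j in range(i + 1):
                    psi0[k] = psi_init if i == j else 0.0
                    k += 1
        theta0 = np.concatenate([*betas, psi0])
    else:
        theta0 = np.asarray(start, dtype=float)

    def negll(theta):
        return -float(cluster_logliks(theta, frame, quad_points, adaptive).sum())

    # box bounds keep the optimizer inside a numerically safe region:
    # |beta| <= 30 (separation beyond that is flagged anyway), random-effect
    # SDs in [e^-8, e^1.5] ~ [3e-4, 4.5] -- an order of magnitude above any
    # plausible mother-level heterogeneity, but short of the huge-variance
    # regime where fixed-order quadrature degrades.
    bounds = []
    for name in frame.param_names:
        if name.startswith(("log_sd", "log_chol[")):
            bounds.append((-8.0, 1.5))
        elif name.startswith(("chol[", "atanh_rho")):
            bounds.append((-5.0, 5.0))
        else:
            bounds.append((-30.0, 30.0))

    frame._mode_cache = None
    res = optimize.minimize(
        negll,
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": ftol, "gtol": 1e-5, "eps": 1e-6},
    )
    theta_hat = res.x
    loglik = -float(res.fun)
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else float("nan")
    converged = bool(res.success)

    n_beta_total = sum(frame.n_beta)
    big = np.abs(theta_hat[:n_beta_total]) > _SEPARATION_BOUND
    if big.any():
        bad = [frame.param_names[i] for i in np.flatnonzero(big)]
        warnings.warn(f"possible separation: coefficient(s) {bad} escaped |beta| > "
                      f"{_SEPARATION_BOUND}", RuntimeWarning, stacklevel=2)

    p = frame.n_params
    n_bic = frame.n_records
    bic = -2.0 * loglik + p * np.log(n_bic)

    vcov_model = vcov_robust = None
    if compute_vcov:
        _, info = score_and_information(theta_hat, frame, spec, quad_points, adaptive)
        vcov_model = _robust_pinv(info)
        if robust:
            scores = _cluster_scores(theta_hat, frame, quad_points, adaptive)
            b_mat = scores.T @ scores
            g = frame.n_clusters
            vcov_robust = vcov_model @ b_mat @ vcov_model * (g / (g - 1.0))
            vcov_robust = 0.5 * (vcov_robust + vcov_robust.T)

    return FitResult(
        model=spec.kind,
        random_structure=spec.random_structure,
        param_names=frame.param_names,
        theta=theta_hat,
        D=decode_psi(frame.split_theta(theta_hat)[1], spec),
        loglik=loglik,
        n_params=p,
        bic=float(bic),
        n_mothers=frame.n_clusters,
        n_records=frame.n_records,
        n_obs=dict(frame.n_obs),
        converged=converged,
        n_iter=int(res.nit),
        grad_norm=grad_norm,
        vcov_model=vcov_model,
        vcov_robust=vcov_robust,
        quad_points=quad_points,
        adaptive=adaptive,
    )


def _robust_pinv(info: np.ndarray) -> np.ndarray:
    try:
        v = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        v = np.linalg.pinv(info)
    return 0.5 * (v + v.T)


def _fd_steps(theta: np.ndarray, rel: float = 1e-5) -> np.ndarray:
    return rel * np.maximum(1.0, np.abs(theta))


def score_and_information(theta, data, spec: ModelSpec, rule=10, adaptive: bool = True):
    """Central finite-difference score vector and observed information.

    Information is the negative Hessian of the log-likelihood, symmetrised.
    """
    frame = data if isinstance(data, ModelFrame) else ModelFrame(data, spec)
    theta = np.asarray(theta, dtype=float)
    q = _resolve_q(rule)

    def ll(t):
        return float(cluster_logliks(t, frame, q, adaptive).sum())

    p = len(theta)
    h = _fd_steps(theta)
    f0 = ll(theta)
    fp = np.empty(p)
    fm = np.empty(p)
    for i in range(p):
        e = np.zeros(p)
        e[i] = h[i]
        fp[i] = ll(theta + e)
        fm[i] = ll(theta - e)
    grad = (fp - fm) / (2.0 * h)
    if not np.all(np.isfinite(grad)):
        raise ValueError("non-finite score entries")
    hess = np.zeros((p, p))
    for i in range(p):
        hess[i, i] = (fp[i] + fm[i] - 2.0 * f0) / h[i] ** 2
        for j in range(i + 1, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = ll(theta + ei + ej)
            fpm = ll(theta + ei - ej)
            fmp = ll(theta - ei + ej)
            fmm = ll(theta - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    if not np.all(np.isfinite(hess)):
        raise ValueError("non-finite information entries")
    info = -0.5 * (hess + hess.T)
    return grad, info


def _cluster_scores(theta, frame: ModelFrame, q: int, adaptive: bool) -> np.ndarray:
    """Per-mother score vectors by central differences of cluster contributions."""
    theta = np.asarray(theta, dtype=float)
    p = len(theta)
    h = _fd_steps(theta)
    s = np.zeros((frame.n_clusters, p))
    for i in range(p):
        e = np.zeros(p)
        e[i] = h[i]
        lp = cluster_logliks(theta + e, frame, q, adaptive)
        lm = cluster_logliks(theta - e, frame, q, adaptive)
        s[:, i] = (lp - lm) / (2.0 * h[i])
    return s
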