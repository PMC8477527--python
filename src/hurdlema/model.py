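"""Multilevel hurdle-gamma (two-part) model for semicontinuous outcomes.

The observation model treats energy intake y_ij (time point i, person j) as
generated by a dual process:

* a **zero part** — multilevel logistic regression on the log-odds of *no*
  eating, pi_ij = P(y_ij = 0) = logit^-1(eta0_ij);
* a **gamma part** — multilevel gamma regression with log link on the
  conditional mean mu_ij = exp(eta1_ij) of intake given that eating occurred,
  with shape alpha (variance mu^2 / alpha).

Person-level random effects of both parts (intercepts, and optionally slopes
of momentary covariates) are jointly multivariate normal with covariance
Sigma = diag(sd) * R * diag(sd); the off-block entries of the correlation
matrix R are the *cross-part correlations* (e.g. rho between the random
intercepts u_0j and u_1j) that tie eating propensity to eating amount.

This module provides the likelihood pieces on the natural (constrained)
scale, plus an unconstrained joint log posterior with an analytic gradient
for Hamiltonian-type samplers (non-centered random effects, log-transformed
scale parameters, tanh-transformed canonical partial correlations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.special import digamma, expit, gammaln

from .data import EmaDataset

__all__ = [
    "ModelSpec",
    "ParameterSet",
    "linear_predictor_zero",
    "linear_predictor_gamma",
    "hurdle_loglik",
    "random_effects_cov",
    "log_posterior",
    "HurdleGammaPosterior",
]


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Which covariates enter each part, and which get person-specific slopes.

    Random intercepts are always present in both parts.  Random-effect order
    is fixed as (zero intercept, zero slopes..., gamma intercept, gamma
    slopes...) so correlation-matrix indices are stable.
    ``cross_part_correlated=True`` models one joint correlation matrix over
    all random effects (the ``|x|`` construct); ``False`` keeps the two parts'
    random effects independent (block-diagonal covariance).
    """

    zero_fixed: list[str] = field(default_factory=list)
    gamma_fixed: list[str] = field(default_factory=list)
    zero_random: list[str] = field(default_factory=list)
    gamma_random: list[str] = field(default_factory=list)
    cross_part_correlated: bool = True

    def __post_init__(self) -> None:
        for r, f, part in (
            (self.zero_random, self.zero_fixed, "zero"),
            (self.gamma_random, self.gamma_fixed, "gamma"),
        ):
            missing = [c for c in r if c not in f]
            if missing:
                raise ValueError(
                    f"random-slope covariates {missing} must also be fixed "
                    f"effects of the {part} part"
                )

    # -- dimensions ---------------------------------------------------------
    @property
    def n_random_zero(self) -> int:
        return 1 + len(self.zero_random)

    @property
    def n_random_gamma(self) -> int:
        return 1 + len(self.gamma_random)

    @property
    def n_random(self) -> int:
        return self.n_random_zero + self.n_random_gamma

    def random_effect_names(self) -> list[str]:
        return (
            ["zero_Intercept"] + [f"zero_{c}" for c in self.zero_random]
            + ["gamma_Intercept"] + [f"gamma_{c}" for c in self.gamma_random]
        )

    def parameter_names(self) -> list[str]:
        """Reporting order: fixed effects, random-effect SDs, correlations, shape."""
        names = ["b_zero_Intercept"] + [f"b_zero_{c}" for c in self.zero_fixed]
        names += ["b_gamma_Intercept"] + [f"b_gamma_{c}" for c in self.gamma_fixed]
        re = self.random_effect_names()
        names += [f"sd_{r}" for r in re]
        for a, b in self.correlation_pairs():
            names.append(f"cor_{re[a]}_{re[b]}")
        names.append("shape")
        return names

    def correlation_pairs(self) -> list[tuple[int, int]]:
        """Index pairs (i < j) of modelled correlations among random effects."""
        q0 = self.n_random_zero
        pairs = []
        for j in range(1, self.n_random):
            for i in range(j):
                same_part = (i < q0) == (j < q0)
                if same_part or self.cross_part_correlated:
                    pairs.append((i, j))
        return pairs

    def validate_against(self, data: EmaDataset) -> None:
        cols = set(data.table.columns)
        missing = [
            c
            for c in set(self.zero_fixed) | set(self.gamma_fixed)
            if c not in cols
        ]
        if missing:
            raise ValueError(f"covariate(s) not in dataset: {sorted(missing)}")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "zero_fixed": list(self.zero_fixed),
            "gamma_fixed": list(self.gamma_fixed),
            "zero_random": list(self.zero_random),
            "gamma_random": list(self.gamma_random),
            "cross_part_correlated": self.cross_part_correlated,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class ParameterSet:
    """Full parameter vector of the two-part model on the link scales.

    ``beta_zero`` — zero-part coefficients (intercept first) on the logit
    scale of *no eating*; ``beta_gamma`` — gamma-part coefficients (intercept
    first) on the log-kcal scale; ``re_sd`` — random-effect SDs in the fixed
    ordering (zero intercept, zero slopes, gamma intercept, gamma slopes);
    ``re_corr`` — correlation matrix over all random effects; ``shape`` —
    gamma shape alpha > 0 (the Level-1 dispersion of the positive part:
    conditional variance mu^2 / alpha).
    """

    beta_zero: np.ndarray
    beta_gamma: np.ndarray
    re_sd: np.ndarray
    re_corr: np.ndarray
    shape: float

    def __post_init__(self) -> None:
        self.beta_zero = np.atleast_1d(np.asarray(self.beta_zero, dtype=float))
        self.beta_gamma = np.atleast_1d(np.asarray(self.beta_gamma, dtype=float))
        self.re_sd = np.atleast_1d(np.asarray(self.re_sd, dtype=float))
        self.re_corr = np.asarray(self.re_corr, dtype=float)
        self.validate()

    def validate(self) -> None:
        if not self.shape > 0:
            raise ValueError(f"gamma shape must be > 0, got {self.shape}")
        if np.any(self.re_sd < 0):
            raise ValueError("random-effect SDs must be >= 0")
        R = self.re_corr
        q = len(self.re_sd)
        if R.shape != (q, q):
            raise ValueError(f"re_corr must be {q}x{q}, got {R.shape}")
        if not np.allclose(R, R.T, atol=1e-10):
            raise ValueError("re_corr must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-10):
            raise ValueError("re_corr must have unit diagonal")
        if np.min(np.linalg.eigvalsh(R)) < -1e-10:
            raise ValueError("re_corr must be positive semidefinite")


def random_effects_cov(re_sd, re_corr) -> np.ndarray:
    """Sigma = diag(sd) R diag(sd), the random-effects covariance matrix."""
    sd = np.atleast_1d(np.asarray(re_sd, dtype=float))
    R = np.asarray(re_corr, dtype=float)
    if np.min(np.linalg.eigvalsh(R)) < -1e-10:
        raise ValueError("correlation matrix is not positive semidefinite")
    return sd[:, None] * R * sd[None, :]


# ---------------------------------------------------------------------------
# Design matrices and linear predictors
# ---------------------------------------------------------------------------

def _design(table, covariates) -> np.ndarray:
    cols = [np.ones(len(table))]
    for c in covariates:
        v = table[c].to_numpy(dtype=float)
        if np.any(~np.isfinite(v)):
            bad = int(np.flatnonzero(~np.isfinite(v))[0])
            raise ValueError(f"missing/non-finite covariate {c!r} at row {bad}")
        cols.append(v)
    return np.column_stack(cols)


def build_design(data: EmaDataset, spec: ModelSpec):
    """Design matrices for both parts plus participant index codes.

    Returns ``(X0, X1, W0, W1, pid, y, labels)`` with X the fixed-effect and
    W the random-effect design (intercept column first in each).
    """
    spec.validate_against(data)
    t = data.table
    X0 = _design(t, spec.zero_fixed)
    X1 = _design(t, spec.gamma_fixed)
    W0 = _design(t, spec.zero_random)
    W1 = _design(t, spec.gamma_random)
    pid, labels = data.participant_codes()
    return X0, X1, W0, W1, pid, data.outcome, labels


def linear_predictor_zero(row, params: ParameterSet, u_j, spec: ModelSpec) -> float:
    """eta0 = b00 + sum_k b0k x_k + u_0j + sum_r u_0rj x_r (logit of no eating)."""
    x = np.concatenate([[1.0], [float(row[c]) for c in spec.zero_fixed]])
    w = np.concatenate([[1.0], [float(row[c]) for c in spec.zero_random]])
    u = np.asarray(u_j, dtype=float)[: spec.n_random_zero]
    return float(x @ params.beta_zero + w @ u)


def linear_predictor_gamma(row, params: ParameterSet, u_j, spec: ModelSpec) -> float:
    """eta1 = b10 + sum_k b1k x_k + u_1j + sum_r u_1rj x_r (log kcal given eating)."""
    x = np.concatenate([[1.0], [float(row[c]) for c in spec.gamma_fixed]])
    w = np.concatenate([[1.0], [float(row[c]) for c in spec.gamma_random]])
    u = np.asarray(u_j, dtype=float)[spec.n_random_zero:]
    return float(x @ params.beta_gamma + w @ u)


def _softplus(x):
    return np.logaddexp(0.0, x)


def hurdle_loglik(y, eta0, eta1, shape) -> np.ndarray:
    """Observation-level log likelihood of the hurdle-gamma model.

    ``y = 0`` contributes log pi with pi = logit^-1(eta0); ``y > 0``
    contributes log(1 - pi) plus the log gamma density with shape alpha and
    mean mu = exp(eta1) (shape–mean parameterization, rate = alpha / mu).
    """
    y = np.asarray(y, dtype=float)
    eta0 = np.broadcast_to(np.asarray(eta0, dtype=float), y.shape)
    eta1 = np.broadcast_to(np.asarray(eta1, dtype=float), y.shape)
    if not shape > 0:
        raise ValueError(f"shape must be > 0, got {shape}")
    if np.any(y < 0) or not np.all(np.isfinite(y)):
        raise ValueError("y must be finite and >= 0")
    if not (np.all(np.isfinite(eta0)) and np.all(np.isfinite(eta1))):
        raise ValueError("linear predictors must be finite")
    zero = y == 0
    out = np.empty_like(y)
    out[zero] = -_softplus(-eta0[zero])  # log pi
    yp, e1 = y[~zero], eta1[~zero]
    out[~zero] = (
        -_softplus(eta0[~zero])  # log(1 - pi)
        + shape * (np.log(shape) - e1)
        + (shape - 1.0) * np.log(yp)
        - shape * yp * np.exp(-e1)
        - gammaln(shape)
    )
    return out


# ---------------------------------------------------------------------------
# Priors (weakly informative defaults)
# ---------------------------------------------------------------------------
# Coefficients: Student-t(3, 0, 5) intercepts, Student-t(3, 0, 2.5) slopes —
# broad and heavy-tailed on the link scales.  Random-effect SDs and the gamma
# shape: half-Student-t(3, 0, 2.5).  Correlations: uniform canonical partial
# correlations (exactly a uniform marginal on rho when there are two random
# effects; near-uniform marginals otherwise).

_T_DF = 3.0
_SCALE_INTERCEPT = 5.0
_SCALE_SLOPE = 2.5
_SCALE_SD = 2.5


def _t_logpdf(x, scale):
    # log density of Student-t(3, 0, scale) up to a constant
    return -2.0 * np.log1p(x * x / (_T_DF * scale * scale))


def _t_grad(x, scale):
    return -4.0 * x / (_T_DF * scale * scale + x * x)


def _coef_prior_logpdf(beta):
    beta = np.atleast_1d(beta)
    lp = _t_logpdf(beta[0], _SCALE_INTERCEPT)
    if len(beta) > 1:
        lp += _t_logpdf(beta[1:], _SCALE_SLOPE).sum()
    return lp


def _coef_prior_grad(beta):
    g = np.empty_like(beta)
    g[0] = _t_grad(beta[0], _SCALE_INTERCEPT)
    if len(beta) > 1:
        g[1:] = _t_grad(beta[1:], _SCALE_SLOPE)
    return g


# ---------------------------------------------------------------------------
# Correlation Cholesky from canonical partial correlations
# ---------------------------------------------------------------------------

def corr_chol_from_cpc(z: np.ndarray, q: int) -> np.ndarray:
    """Lower-triangular Cholesky factor of a correlation matrix from CPCs.

    ``z`` holds tanh-scale canonical partial correlations in row-major order
    of the strictly lower triangle; supports leading batch dimensions.
    """
    batch = z.shape[:-1]
    L = np.zeros(batch + (q, q))
    L[..., 0, 0] = 1.0
    k = 0
    for i in range(1, q):
        rem = np.ones(batch)
        for j in range(i):
            L[..., i, j] = z[..., k] * np.sqrt(rem)
            rem = rem - L[..., i, j] ** 2
            k += 1
        L[..., i, i] = np.sqrt(np.maximum(rem, 0.0))
    return L


def _corr_chol_backprop(z: np.ndarray, dL: np.ndarray, q: int) -> np.ndarray:
    """Reverse-mode gradient of ``corr_chol_from_cpc`` (single instance)."""
    # forward, recording remainders r_j per row
    L = np.zeros((q, q))
    L[0, 0] = 1.0
    rems = {}
    k = 0
    for i in range(1, q):
        r = 1.0
        for j in range(i):
            rems[(i, j)] = r
            L[i, j] = z[k] * np.sqrt(r)
            r -= L[i, j] ** 2
            k += 1
        rems[(i, i)] = r
        L[i, i] = np.sqrt(max(r, 0.0))
    dz = np.zeros_like(z)
    k = len(z)
    for i in range(q - 1, 0, -1):
        r_i = rems[(i, i)]
        dr = dL[i, i] * (0.5 / np.sqrt(r_i)) if r_i > 1e-300 else 0.0
        for j in range(i - 1, -1, -1):
            k -= 1
            s = np.sqrt(rems[(i, j)])
            dLij = dL[i, j] - 2.0 * L[i, j] * dr
            dz[k] = dLij * s
            if s > 1e-150:
                dr = dr + dLij * z[k] * 0.5 / s
    return dz


def cpc_from_corr(R: np.ndarray) -> np.ndarray:
    """Canonical partial correlations (tanh scale) of a correlation matrix."""
    L = np.linalg.cholesky(R)
    q = R.shape[0]
    z = []
    for i in range(1, q):
        rem = 1.0
        for j in range(i):
            z.append(L[i, j] / np.sqrt(rem))
            rem -= L[i, j] ** 2
    return np.asarray(z)


# ---------------------------------------------------------------------------
# Public joint log posterior on the constrained scale
# ---------------------------------------------------------------------------

def log_posterior(
    params: ParameterSet,
    u: np.ndarray,
    data: EmaDataset,
    spec: ModelSpec,
) -> float:
    """Joint log posterior density (up to a constant) on the natural scale.

    Sums the hurdle-gamma log likelihood over rows, the multivariate-normal
    log density of the per-person random-effect vectors ``u`` (J x q) under
    Sigma = diag(sd) R diag(sd), and the weakly informative log priors over
    (beta, sd, R, shape).
    """
    X0, X1, W0, W1, pid, y, labels = build_design(data, spec)
    q0, q = spec.n_random_zero, spec.n_random
    u = np.asarray(u, dtype=float)
    J = len(labels)
    if u.shape != (J, q):
        raise ValueError(f"u must have shape {(J, q)}, got {u.shape}")
    if len(params.beta_zero) != X0.shape[1] or len(params.beta_gamma) != X1.shape[1]:
        raise ValueError("coefficient vectors inconsistent with ModelSpec")
    if len(params.re_sd) != q:
        raise ValueError("re_sd length inconsistent with ModelSpec")

    lp = 0.0
    if len(y):
        eta0 = X0 @ params.beta_zero + np.sum(W0 * u[pid, :q0], axis=1)
        eta1 = X1 @ params.beta_gamma + np.sum(W1 * u[pid, q0:], axis=1)
        lp += hurdle_loglik(y, eta0, eta1, params.shape).sum()

    R = params.re_corr if spec.cross_part_correlated else _block_diag_corr(params, spec)
    Sigma = random_effects_cov(params.re_sd, R)
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        raise ValueError("random-effects covariance is singular")
    sol = np.linalg.solve(Sigma, u.T)
    lp += -0.5 * J * (logdet + q * np.log(2 * np.pi)) - 0.5 * np.sum(u.T * sol)

    lp += _coef_prior_logpdf(params.beta_zero) + _coef_prior_logpdf(params.beta_gamma)
    lp += _t_logpdf(params.re_sd, _SCALE_SD).sum()
    lp += _t_logpdf(params.shape, _SCALE_SD)
    # correlation prior: uniform CPCs -> flat in z; constant on this scale
    return float(lp)


def _block_diag_corr(params: ParameterSet, spec: ModelSpec) -> np.ndarray:
    R = params.re_corr.copy()
    q0 = spec.n_random_zero
    R[:q0, q0:] = 0.0
    R[q0:, :q0] = 0.0
    return R


# ---------------------------------------------------------------------------
# Unconstrained posterior with analytic gradient (sampler target)
# ---------------------------------------------------------------------------

class HurdleGammaPosterior:
    """Unconstrained-scale joint log posterior and gradient for NUTS/HMC.

    Parameter packing (dimension ``n_free``):

    ========  ============================================================
    block     contents
    ========  ============================================================
    beta0     zero-part fixed effects (p0)
    beta1     gamma-part fixed effects (p1)
    log_sd    log random-effect SDs (q)
    cpc       unconstrained correlation parameters, z = tanh(.) (n_pairs)
    log_a     log gamma shape (1)
    zmat      non-centered standardized random effects, J x q (flattened)
    ========  ============================================================

    Random effects are non-centered: u_j = diag(sd) L z_j with L the
    correlation Cholesky built from canonical partial correlations, z_j
    standard normal.  Cross-part-uncorrelated models zero the off-block CPCs.
    """

    def __init__(self, data: EmaDataset, spec: ModelSpec):
        self.spec = spec
        X0, X1, W0, W1, pid, y, labels = build_design(data, spec)
        self.X0, self.X1, self.W0, self.W1 = X0, X1, W0, W1
        self.pid, self.y, self.labels = pid, y, labels
        self.J = len(labels)
        self.q0, self.q1 = spec.n_random_zero, spec.n_random_gamma
        self.q = self.q0 + self.q1
        self.p0, self.p1 = X0.shape[1], X1.shape[1]
        # all strictly-lower-triangle pairs, row-major (matches corr_chol_from_cpc)
        self._all_pairs = [(j, i) for i in range(1, self.q) for j in range(i)]
        self._free_cpc = [
            k
            for k, (a, b) in enumerate(self._all_pairs)
            if spec.cross_part_correlated or ((a < self.q0) == (b < self.q0))
        ]
        self.n_pairs = len(self._free_cpc)
        self.n_global = self.p0 + self.p1 + self.q + self.n_pairs + 1
        self.n_free = self.n_global + self.J * self.q
        self._zero = y == 0
        self._logy_pos = np.log(y[~self._zero])
        names = spec.parameter_names()
        #: names of the derived (constrained) parameters, reporting order
        self.parameter_names = names

    # -- packing ------------------------------------------------------------
    def split(self, theta):
        p0, p1, q, npair = self.p0, self.p1, self.q, self.n_pairs
        i = 0
        beta0 = theta[i:i + p0]; i += p0
        beta1 = theta[i:i + p1]; i += p1
        log_sd = theta[i:i + q]; i += q
        cpc = theta[i:i + npair]; i += npair
        log_a = theta[i]; i += 1
        zmat = theta[i:].reshape(self.J, q)
        return beta0, beta1, log_sd, cpc, log_a, zmat

    def _full_cpc_z(self, cpc):
        """tanh-transformed CPCs for *all* lower-triangle slots."""
        n_all = self.q * (self.q - 1) // 2
        z = np.zeros(cpc.shape[:-1] + (n_all,))
        z[..., self._free_cpc] = np.tanh(cpc)
        return z

    # -- evaluation ----------------------------------------------------------
    def logp_grad(self, theta):
        """Log posterior density and gradient on the unconstrained scale."""
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return self._logp_grad_impl(theta)

    def _logp_grad_impl(self, theta):
        beta0, beta1, log_sd, cpc, log_a, zmat = self.split(theta)
        sd = np.exp(log_sd)
        alpha = np.exp(log_a)
        zfull = self._full_cpc_z(cpc)
        L = corr_chol_from_cpc(zfull, self.q)
        A = sd[:, None] * L
        U = zmat @ A.T  # J x q person random effects

        q0 = self.q0
        eta0 = self.X0 @ beta0 + np.sum(self.W0 * U[self.pid, :q0], axis=1)
        eta1 = self.X1 @ beta1 + np.sum(self.W1 * U[self.pid, q0:], axis=1)
        zero = self._zero
        pos = ~zero
        e1p = eta1[pos]
        inv_mu = np.exp(-e1p)
        ypos = self.y[pos]

        lp = -_softplus(-eta0[zero]).sum()
        lp += (
            -_softplus(eta0[pos]).sum()
            + pos.sum() * (alpha * np.log(alpha) - gammaln(alpha))
            - alpha * e1p.sum()
            + (alpha - 1.0) * self._logy_pos.sum()
            - alpha * (ypos * inv_mu).sum()
        )

        # gradients wrt linear predictors
        g0 = np.where(zero, expit(-eta0), -expit(eta0))
        g1 = np.zeros_like(eta1)
        g1[pos] = alpha * (ypos * inv_mu - 1.0)

        gbeta0 = self.X0.T @ g0 + _coef_prior_grad(beta0)
        gbeta1 = self.X1.T @ g1 + _coef_prior_grad(beta1)
        lp += _coef_prior_logpdf(beta0) + _coef_prior_logpdf(beta1)

        # accumulate per-person gradient wrt U
        dU = np.empty((self.J, self.q))
        for k in range(q0):
            dU[:, k] = np.bincount(self.pid, weights=g0 * self.W0[:, k],
                                   minlength=self.J)
        for k in range(self.q1):
            dU[:, q0 + k] = np.bincount(self.pid, weights=g1 * self.W1[:, k],
                                        minlength=self.J)

        # z prior (standard normal) and chain rule through U = Z A^T
        lp += -0.5 * np.sum(zmat * zmat)
        dZ = dU @ A - zmat
        dA = dU.T @ zmat  # q x q

        # A = diag(sd) L
        dL = sd[:, None] * dA
        dsd = np.sum(dA * L, axis=1)

        # SD prior: half-t on sd, log-scale Jacobian
        lp += _t_logpdf(sd, _SCALE_SD).sum() + log_sd.sum()
        glog_sd = dsd * sd + _t_grad(sd, _SCALE_SD) * sd + 1.0

        # correlation block: backprop dL -> CPC z -> unconstrained cpc
        if self.n_pairs:
            dzfull = _corr_chol_backprop(zfull, dL, self.q)
            zt = np.tanh(cpc)
            gcpc = dzfull[self._free_cpc] * (1.0 - zt * zt)
            # uniform-CPC prior: z ~ U(-1,1) <=> density sech^2(c)/2 in c
            abs_c = np.abs(cpc)
            log_cosh = abs_c + np.log1p(np.exp(-2.0 * abs_c)) - np.log(2.0)
            lp += -2.0 * log_cosh.sum()
            gcpc = gcpc - 2.0 * np.tanh(cpc)
        else:
            gcpc = np.zeros(0)

        # shape: dl/dalpha over positive rows, half-t prior, log Jacobian
        npos = int(pos.sum())
        dl_dalpha = (
            npos * (np.log(alpha) + 1.0 - digamma(alpha))
            - e1p.sum() + self._logy_pos.sum() - (ypos * inv_mu).sum()
        )
        lp += _t_logpdf(alpha, _SCALE_SD) + log_a
        glog_a = (dl_dalpha + _t_grad(alpha, _SCALE_SD)) * alpha + 1.0

        grad = np.concatenate([
            gbeta0, gbeta1, glog_sd, gcpc, [glog_a], dZ.ravel()
        ])
        return float(lp), grad

    def logp(self, theta) -> float:
        return self.logp_grad(theta)[0]

    # -- initialization ------------------------------------------------------
    def initial_point(self, rng: np.random.Generator, jitter: float = 0.1):
        """Moment-based start: data logit/log means, small SDs, jittered."""
        theta = np.zeros(self.n_free)
        y = self.y
        prop_zero = np.clip(np.mean(y == 0), 0.02, 0.98)
        mean_pos = np.mean(y[y > 0]) if np.any(y > 0) else 1.0
        theta[0] = np.log(prop_zero / (1 - prop_zero))
        theta[self.p0] = np.log(mean_pos)
        i = self.p0 + self.p1
        theta[i:i + self.q] = np.log(0.2)
        theta[self.p0 + self.p1 + self.q + self.n_pairs] = 0.0  # alpha = 1
        theta += jitter * rng.standard_normal(self.n_free)
        return theta

    # -- constrained view ----------------------------------------------------
    def constrain(self, thetas: np.ndarray) -> np.ndarray:
        """Map unconstrained draws to the reported (Table-1 scale) parameters.

        ``thetas`` has shape (..., n_free); returns (..., n_reported) in the
        order of :attr:`parameter_names` (fixed effects, SDs, correlations,
        shape).
        """
        thetas = np.asarray(thetas)
        p0, p1, q = self.p0, self.p1, self.q
        i = 0
        beta0 = thetas[..., i:i + p0]; i += p0
        beta1 = thetas[..., i:i + p1]; i += p1
        sd = np.exp(thetas[..., i:i + q]); i += q
        cpc = thetas[..., i:i + self.n_pairs]; i += self.n_pairs
        alpha = np.exp(thetas[..., i:i + 1])
        zfull = self._full_cpc_z(cpc)
        L = corr_chol_from_cpc(zfull, q)
        R = L @ np.swapaxes(L, -1, -2)
        cors = [R[..., b, a] for a, b in self.spec.correlation_pairs()]
        cors = np.stack(cors, axis=-1) if cors else np.zeros(thetas.shape[:-1] + (0,))
        return np.concatenate([beta0, beta1, sd, cors, alpha], axis=-1)

    def random_effects(self, theta: np.ndarray) -> np.ndarray:
        """Person random effects u_j (J x q) implied by one unconstrained draw."""
        _, _, log_sd, cpc, _, zmat = self.split(theta)
        L = corr_chol_from_cpc(self._full_cpc_z(cpc), self.q)
        return zmat @ (np.exp(log_sd)[:, None] * L).T
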