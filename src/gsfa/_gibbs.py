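"""Gibbs update kernels for the guided sparse factor model.

Model (N cells, P genes, M perturbations, K factors):

    Y = Z W' + E,    E_ij ~ N(0, psi_j)
    Z = G beta + Phi, phi_ik ~ N(0, 1)
    beta_mk ~ p_m N(0, d_m^2) + (1 - p_m) delta_0            (indicator gamma)
    W_jk   ~ pi_k N(0, sigma_k^2) + (1 - pi_k) N(0, sigma_k^2 c_k^2)   (indicator F)

With a "spike_slab" loading prior the background component is replaced by
the point mass at zero.  All conditionals are conjugate; each kernel is a
pure function of (rng, state, data) so it can be checked against closed-form
posteriors in isolation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.special import expit

logger = logging.getLogger(__name__)

VAR_FLOOR = 1e-12
PROB_EPS = 1e-9


@dataclass
class GibbsState:
    """Current values of all latent variables and hyperparameters.

    ``beta``/``gamma``/``p``/``d2`` carry a leading group axis (size 1 in the
    single-group model) so the two-group extension reuses every kernel.
    """

    Z: np.ndarray  # N x K
    W: np.ndarray  # P x K
    F: np.ndarray  # P x K, {0,1}
    beta: np.ndarray  # n_groups x M x K
    gamma: np.ndarray  # n_groups x M x K, {0,1}
    psi: np.ndarray  # P
    pi: np.ndarray  # K in (0,1)
    sigma2: np.ndarray  # K
    p: np.ndarray  # n_groups x M in (0,1)
    d2: np.ndarray  # n_groups x M
    log_joint: float = np.nan

    def copy(self) -> "GibbsState":
        return GibbsState(
            **{
                k: (v.copy() if isinstance(v, np.ndarray) else v)
                for k, v in self.__dict__.items()
            }
        )

    def validate(self) -> None:
        assert np.isin(self.F, (0, 1)).all() and np.isin(self.gamma, (0, 1)).all()
        assert (self.psi > 0).all() and (self.sigma2 > 0).all() and (self.d2 > 0).all()
        assert ((self.pi > 0) & (self.pi < 1)).all()
        assert ((self.p > 0) & (self.p < 1)).all()


@dataclass
class Hyperpriors:
    """Conjugate hyperprior constants.

    Beta(a, b) on the foreground proportions (defaults favor sparsity with
    b = K), inverse-gamma (shape, rate) on all variances.
    """

    pi_beta: tuple[float, float]
    p_beta: tuple[float, float]
    sigma2_ig: tuple[float, float] = (2.0, 1.0)
    d2_ig: tuple[float, float] = (2.0, 1.0)
    psi_ig: tuple[float, float] = (2.0, 1.0)

    @classmethod
    def default(cls, K: int) -> "Hyperpriors":
        return cls(pi_beta=(1.0, float(K)), p_beta=(1.0, float(K)))


# ---------------------------------------------------------------------------
# conditional parameters (exposed for oracle tests)


def z_posterior_params(
    W: np.ndarray, psi: np.ndarray, Y: np.ndarray, prior_mean: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean matrix and shared precision of the Z conditional.

    Rows of Z are conditionally independent K-variate normals with common
    precision W' Psi^-1 W + I and mean solving precision @ mean_i =
    W' Psi^-1 Y_i + prior_mean_i (the prior mean is G_i beta).
    """
    Wp = W / psi[:, None]
    prec = W.T @ Wp + np.eye(W.shape[1])
    rhs = Y @ Wp + prior_mean
    L = scipy.linalg.cholesky(prec, lower=True)
    mean = scipy.linalg.cho_solve((L, True), rhs.T).T
    return mean, prec


def slab_log_marginal(s: np.ndarray, b: np.ndarray, v: float | np.ndarray):
    """Log marginal likelihood of a scalar regression coefficient with prior
    N(0, v), relative to the coefficient-equals-zero baseline.

    ``s`` is the precision-scaled design norm (x'x / noise_var), ``b`` the
    scaled cross-product (x'r / noise_var).  Returns (log-marginal, posterior
    mean, posterior variance).
    """
    q = s + 1.0 / v
    mu = b / q
    lm = -0.5 * np.log1p(v * s) + 0.5 * b * b / q
    return lm, mu, 1.0 / q


# ---------------------------------------------------------------------------
# kernels


def sample_z(
    rng: np.random.Generator, state: GibbsState, Y: np.ndarray, prior_mean: np.ndarray
) -> None:
    mean, prec = z_posterior_params(state.W, state.psi, Y, prior_mean)
    L = scipy.linalg.cholesky(prec, lower=True)
    eps = rng.standard_normal(mean.shape)
    # row-vector draw: cov = (L L')^{-1}  via  eps @ L^{-1}
    state.Z = mean + scipy.linalg.solve_triangular(L, eps.T, lower=True, trans="T").T


def sample_loadings(
    rng: np.random.Generator,
    state: GibbsState,
    Y: np.ndarray,
    c: float,
    prior_type: str,
) -> None:
    """Single-site update of (F_jk, W_jk), vectorized over genes per factor."""
    Z = state.Z
    A = Z.T @ Z  # K x K
    B = Z.T @ Y  # K x P
    K = A.shape[0]
    W = state.W
    F = state.F
    for k in range(K):
        resid_xr = B[k] - W @ A[:, k] + A[k, k] * W[:, k]  # P, = z_k' r_j
        s = A[k, k] / state.psi
        b = resid_xr / state.psi
        v1 = max(state.sigma2[k], VAR_FLOOR)
        logit_pi = np.log(state.pi[k]) - np.log1p(-state.pi[k])
        l1, mu1, var1 = slab_log_marginal(s, b, v1)
        if prior_type == "normal_mixture":
            v0 = max(v1 * c * c, VAR_FLOOR)
            l0, mu0, var0 = slab_log_marginal(s, b, v0)
        else:  # spike_slab: baseline is the point mass, log-marginal 0
            l0, mu0, var0 = 0.0, 0.0, 0.0
        fk = rng.random(len(b)) < expit(logit_pi + l1 - l0)
        noise = rng.standard_normal(len(b))
        w1 = mu1 + noise * np.sqrt(var1)
        if prior_type == "normal_mixture":
            w0 = mu0 + noise * np.sqrt(var0)
        else:
            w0 = np.zeros_like(w1)
        W[:, k] = np.where(fk, w1, w0)
        F[:, k] = fk.astype(np.int8)


def sample_effects(
    rng: np.random.Generator,
    state: GibbsState,
    G: np.ndarray,
    group_rows: list[np.ndarray],
) -> None:
    """Single-site spike-and-slab update of (gamma_mk, beta_mk) per group.

    The regression Z = G beta + Phi has unit residual variance, so the
    sufficient statistics are G'G and G'Z on the group's rows.
    """
    for g, rows in enumerate(group_rows):
        Gg = G[rows]
        Zg = state.Z[rows]
        GtG = Gg.T.astype(float) @ Gg
        GtZ = Gg.T.astype(float) @ Zg
        beta = state.beta[g]
        gamma = state.gamma[g]
        M, K = beta.shape
        for m in range(M):
            s = GtG[m, m]
            if s == 0:
                logger.warning(
                    "perturbation %d has no carrier cells in group %d; skipped", m, g
                )
                continue
            b = GtZ[m] - GtG[m] @ beta + s * beta[m]  # K
            v = max(state.d2[g, m], VAR_FLOOR)
            logit_p = np.log(state.p[g, m]) - np.log1p(-state.p[g, m])
            l1, mu, var = slab_log_marginal(s, b, v)
            gm = rng.random(K) < expit(logit_p + l1)
            draws = mu + rng.standard_normal(K) * np.sqrt(var)
            beta[m] = np.where(gm, draws, 0.0)
            gamma[m] = gm.astype(np.int8)


def sample_psi(
    rng: np.random.Generator,
    state: GibbsState,
    Y: np.ndarray,
    hp: Hyperpriors,
) -> np.ndarray:
    """Inverse-gamma update of the per-gene residual variances.

    Returns the per-gene residual sums of squares (reused by the log-joint).
    """
    R = Y - state.Z @ state.W.T
    ss = np.einsum("ij,ij->j", R, R)
    a, b = hp.psi_ig
    shape = a + 0.5 * Y.shape[0]
    rate = b + 0.5 * ss
    state.psi = np.maximum(1.0 / rng.gamma(shape, 1.0 / rate), VAR_FLOOR)
    return ss


def sample_hyperparams(
    rng: np.random.Generator,
    state: GibbsState,
    hp: Hyperpriors,
    c: float,
    prior_type: str,
) -> None:
    P, K = state.W.shape
    a0, b0 = hp.pi_beta
    nf = state.F.sum(axis=0)
    state.pi = np.clip(rng.beta(a0 + nf, b0 + P - nf), PROB_EPS, 1 - PROB_EPS)

    a_s, b_s = hp.sigma2_ig
    if prior_type == "normal_mixture":
        scale = state.F + (1 - state.F) * c * c  # per-entry variance factor
        ssw = (state.W**2 / scale).sum(axis=0)
        shape = a_s + 0.5 * P
    else:
        ssw = (state.W**2 * state.F).sum(axis=0)
        shape = a_s + 0.5 * nf
    state.sigma2 = np.maximum(
        1.0 / rng.gamma(shape, 1.0 / (b_s + 0.5 * ssw)), VAR_FLOOR
    )

    a0p, b0p = hp.p_beta
    a_d, b_d = hp.d2_ig
    n_groups, M, _ = state.beta.shape
    ng = state.gamma.sum(axis=2)  # n_groups x M
    state.p = np.clip(
        rng.beta(a0p + ng, b0p + K - ng), PROB_EPS, 1 - PROB_EPS
    )
    ssb = (state.beta**2).sum(axis=2)
    state.d2 = np.maximum(
        1.0 / rng.gamma(a_d + 0.5 * ng, 1.0 / (b_d + 0.5 * ssb)), VAR_FLOOR
    )


def log_joint(
    state: GibbsState,
    Y: np.ndarray,
    prior_mean: np.ndarray,
    resid_ss: np.ndarray,
    c: float,
    prior_type: str,
) -> float:
    """Unnormalized log joint density (likelihood + main-parameter priors).

    Used as a mixing diagnostic; hyperprior terms of the scalar variances are
    omitted (constant order, irrelevant to trace stabilization checks).
    """
    N, P = Y.shape
    ll = -0.5 * float(np.sum(N * np.log(2 * np.pi * state.psi) + resid_ss / state.psi))
    dz = state.Z - prior_mean
    lz = -0.5 * float(np.sum(dz * dz)) - 0.5 * dz.size * np.log(2 * np.pi)
    var_w = state.sigma2 * np.where(
        state.F == 1, 1.0, c * c if prior_type == "normal_mixture" else 1.0
    )
    if prior_type == "spike_slab":
        mask = state.F == 1
        lw = -0.5 * float(
            np.sum(
                np.where(mask, state.W**2 / var_w + np.log(2 * np.pi * var_w), 0.0)
            )
        )
    else:
        lw = -0.5 * float(np.sum(state.W**2 / var_w + np.log(2 * np.pi * var_w)))
    lw += float(
        np.sum(state.F * np.log(state.pi) + (1 - state.F) * np.log1p(-state.pi))
    )
    lb = 0.0
    for g in range(state.beta.shape[0]):
        gm = state.gamma[g] == 1
        v = np.broadcast_to(state.d2[g][:, None], state.beta[g].shape)
        lb += -0.5 * float(
            np.sum(
                np.where(
                    gm, state.beta[g] ** 2 / v + np.log(2 * np.pi * v), 0.0
                )
            )
        )
        pg = state.p[g][:, None]
        lb += float(np.sum(state.gamma[g] * np.log(pg) + (1 - state.gamma[g]) * np.log1p(-pg)))
    return ll + lz + lw + lb


def gibbs_step(
    rng: np.random.Generator,
    state: GibbsState,
    Y: np.ndarray,
    G: np.ndarray,
    group_rows: list[np.ndarray],
    hp: Hyperpriors,
    c: float,
    prior_type: str,
    guided: bool = True,
) -> None:
    """One full scan: Z -> (W,F) -> (beta,gamma) -> psi -> hyperparameters."""
    prior_mean = np.zeros_like(state.Z)
    if guided:
        for g, rows in enumerate(group_rows):
            prior_mean[rows] = G[rows] @ state.beta[g]
    sample_z(rng, state, Y, prior_mean)
    sample_loadings(rng, state, Y, c, prior_type)
    if guided:
        sample_effects(rng, state, G, group_rows)
        prior_mean = np.zeros_like(state.Z)
        for g, rows in enumerate(group_rows):
            prior_mean[rows] = G[rows] @ state.beta[g]
    resid_ss = sample_psi(rng, state, Y, hp)
    sample_hyperparams(rng, state, hp, c, prior_type)
    state.log_joint = log_joint(state, Y, prior_mean, resid_ss, c, prior_type)
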