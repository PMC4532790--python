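"""Independent brute-force oracles for small state-space instances.

The joint distribution of (s_1..s_K, y_1..y_K) under the linear-Gaussian model
is assembled explicitly and conditioned by Schur complement; nothing here
shares code with the package's recursive filters.
"""

import numpy as np
from scipy import stats

from ndfkit.lds import LDSParams


def joint_moments(params: LDSParams, K: int):
    """Mean and covariance of the stacked vector [s_1..s_K, y_1..y_K]."""
    d, n = params.d, params.n_channels
    M, P, Nc, R, pi1, S1 = (params.M, params.P, params.Ncov, params.R,
                            params.pi1, params.S1)
    ms = np.zeros((K, d))
    ms[0] = pi1
    for k in range(1, K):
        ms[k] = M @ ms[k - 1]

    Css = np.zeros((K, K, d, d))
    Css[0, 0] = S1
    for k in range(1, K):
        Css[k, k] = M @ Css[k - 1, k - 1] @ M.T + Nc
    for j in range(K):
        for k in range(j + 1, K):
            Css[j, k] = Css[j, k - 1] @ M.T
            Css[k, j] = Css[j, k].T

    mean = np.concatenate([ms.ravel(), (ms @ P.T).ravel()])
    dim = K * (d + n)
    cov = np.zeros((dim, dim))
    for j in range(K):
        for k in range(K):
            cov[j * d:(j + 1) * d, k * d:(k + 1) * d] = Css[j, k]
            cov[j * d:(j + 1) * d, K * d + k * n:K * d + (k + 1) * n] = Css[j, k] @ P.T
            cov[K * d + k * n:K * d + (k + 1) * n, j * d:(j + 1) * d] = P @ Css[k, j]
            blk = P @ Css[j, k] @ P.T
            if j == k:
                blk = blk + R
            cov[K * d + j * n:K * d + (j + 1) * n,
                K * d + k * n:K * d + (k + 1) * n] = blk
    return mean, cov


def _condition(mean, cov, obs_idx, obs_val, query_idx):
    """Conditional mean/cov of query indices given observed indices."""
    A = cov[np.ix_(query_idx, query_idx)]
    B = cov[np.ix_(query_idx, obs_idx)]
    C = cov[np.ix_(obs_idx, obs_idx)]
    sol = np.linalg.solve(C, (obs_val - mean[obs_idx]))
    m = mean[query_idx] + B @ sol
    V = A - B @ np.linalg.solve(C, B.T)
    return m, V


def filtered_moments(params: LDSParams, y: np.ndarray):
    """Exact filtered means/covs: s_k | y_1..y_k for every k."""
    d, n = params.d, params.n_channels
    K = y.shape[1]
    mean, cov = joint_moments(params, K)
    means = np.zeros((d, K))
    covs = np.zeros((d, d, K))
    for k in range(K):
        obs = np.arange(K * d, K * d + (k + 1) * n)
        q = np.arange(k * d, (k + 1) * d)
        m, V = _condition(mean, cov, obs, y[:, :k + 1].T.ravel(), q)
        means[:, k] = m
        covs[:, :, k] = V
    return means, covs


def smoothed_moments(params: LDSParams, y: np.ndarray):
    """Exact smoothed means/covs and lag-one cross-covs: s | y_1..y_K."""
    d, n = params.d, params.n_channels
    K = y.shape[1]
    mean, cov = joint_moments(params, K)
    obs = np.arange(K * d, K * d + K * n)
    q = np.arange(K * d)
    m, V = _condition(mean, cov, obs, y.T.ravel(), q)
    means = m.reshape(K, d).T
    covs = np.stack([V[k * d:(k + 1) * d, k * d:(k + 1) * d]
                     for k in range(K)], axis=2)
    cross = np.stack([V[(k + 1) * d:(k + 2) * d, k * d:(k + 1) * d]
                      for k in range(K - 1)], axis=2) if K > 1 else np.zeros((d, d, 0))
    return means, covs, cross


def marginal_loglik(params: LDSParams, y: np.ndarray) -> float:
    """Log-density of the stacked observations under their joint Gaussian."""
    d, n = params.d, params.n_channels
    K = y.shape[1]
    mean, cov = joint_moments(params, K)
    oy = np.arange(K * d, K * d + K * n)
    return float(stats.multivariate_normal.logpdf(
        y.T.ravel(), mean[oy], cov[np.ix_(oy, oy)], allow_singular=False))


def predictive_obs_mean(params: LDSParams, y: np.ndarray, k: int) -> np.ndarray:
    """E[y_k | y_1..y_{k-1}] from the joint Gaussian (k is 0-based)."""
    d, n = params.d, params.n_channels
    K = y.shape[1]
    mean, cov = joint_moments(params, K)
    obs = np.arange(K * d, K * d + k * n)
    q = np.arange(K * d + k * n, K * d + (k + 1) * n)
    m, _ = _condition(mean, cov, obs, y[:, :k].T.ravel(), q)
    return m


def random_params(rng, d=2, n=3, radius=0.85, bin_width=0.015) -> LDSParams:
    """A random, stable, well-conditioned small LDS instance."""
    M = rng.standard_normal((d, d))
    M *= radius / max(np.abs(np.linalg.eigvals(M)).max(), 1e-6)
    P = rng.standard_normal((n, d))
    Ncov = np.diag(rng.uniform(0.2, 1.0, size=d))
    R = np.diag(rng.uniform(0.3, 1.2, size=n))
    pi1 = 0.5 * rng.standard_normal(d)
    A = rng.standard_normal((d, d))
    S1 = A @ A.T / d + 0.1 * np.eye(d)
    return LDSParams(M=M, P=P, Ncov=Ncov, R=R, pi1=pi1, S1=S1,
                     bin_width=bin_width)
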