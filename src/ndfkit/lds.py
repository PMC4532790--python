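"""Latent-state linear dynamical system: model containers, Kalman inference, EM.

The generative model over binned spike counts ``y_k`` (N channels) is

    s_k = M s_{k-1} + n_k,        n_k ~ N(0, Ncov)
    y_k = P s_k     + r_k,        r_k ~ N(0, R)

with a d-dimensional latent neural state ``s_k``, diagonal noise covariances,
and initial state s_1 ~ N(pi1, S1).  Bins are 1-based in documentation; arrays
are 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import FactorAnalysis

from .errors import ConvergenceError, InputError, NumericalError

__all__ = [
    "SpikeCounts",
    "LDSParams",
    "FilterResult",
    "SmootherResult",
    "EMTrace",
    "kalman_filter",
    "kalman_smoother",
    "steady_state_gain",
    "log_likelihood",
    "em_fit",
    "fa_init",
    "predict_next_observation",
    "eigen_summary",
    "permute_dynamics",
    "permute_columns",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SpikeCounts:
    """Channels x bins matrix of binned spike counts on a contiguous time base.

    ``counts`` is stored as float64 so that model-generated (Gaussian) count
    matrices and integer threshold-crossing counts share one container; file
    readers enforce integer non-negativity where the on-disk format declares it.
    """

    counts: np.ndarray
    bin_width: float = 0.015
    channel_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.atleast_2d(np.asarray(self.counts, dtype=float))
        if self.counts.ndim != 2:
            raise InputError("counts must be a 2-D channels x bins matrix")
        if not np.isfinite(self.counts).all():
            raise InputError("counts contain non-finite entries")
        if self.bin_width <= 0:
            raise InputError(f"bin_width must be positive, got {self.bin_width}")
        if self.channel_ids is not None:
            self.channel_ids = [str(c) for c in self.channel_ids]
            if len(self.channel_ids) != self.counts.shape[0]:
                raise InputError(
                    f"{len(self.channel_ids)} channel_ids for "
                    f"{self.counts.shape[0]} channels"
                )

    @property
    def n_channels(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]


def _as_counts(Y: "SpikeCounts | np.ndarray", bin_width: float = 0.015) -> SpikeCounts:
    if isinstance(Y, SpikeCounts):
        return Y
    return SpikeCounts(np.asarray(Y, dtype=float), bin_width=bin_width)


@dataclass
class LDSParams:
    """Parameters (M, P, Ncov, R, pi1, S1) of the latent linear dynamical system.

    ``Ncov``/``R`` are kept as full matrices; EM projects them to diagonal at
    every M-step, but inference routines accept arbitrary PSD covariances (used
    e.g. by the similarity-invariance checks).
    """

    M: np.ndarray
    P: np.ndarray
    Ncov: np.ndarray
    R: np.ndarray
    pi1: np.ndarray
    S1: np.ndarray
    bin_width: float = 0.015

    def __post_init__(self) -> None:
        self.M = np.atleast_2d(np.asarray(self.M, dtype=float))
        self.P = np.atleast_2d(np.asarray(self.P, dtype=float))
        self.Ncov = np.atleast_2d(np.asarray(self.Ncov, dtype=float))
        self.R = np.atleast_2d(np.asarray(self.R, dtype=float))
        self.pi1 = np.atleast_1d(np.asarray(self.pi1, dtype=float))
        self.S1 = np.atleast_2d(np.asarray(self.S1, dtype=float))
        d = self.M.shape[0]
        n = self.P.shape[0]
        if self.M.shape != (d, d):
            raise InputError(f"M must be square, got {self.M.shape}")
        if self.P.shape != (n, d):
            raise InputError(f"P has shape {self.P.shape}, expected ({n}, {d})")
        if self.Ncov.shape != (d, d):
            raise InputError(f"Ncov has shape {self.Ncov.shape}, expected ({d}, {d})")
        if self.R.shape != (n, n):
            raise InputError(f"R has shape {self.R.shape}, expected ({n}, {n})")
        if self.pi1.shape != (d,):
            raise InputError(f"pi1 has shape {self.pi1.shape}, expected ({d},)")
        if self.S1.shape != (d, d):
            raise InputError(f"S1 has shape {self.S1.shape}, expected ({d}, {d})")
        if not np.allclose(self.S1, self.S1.T, atol=1e-10):
            raise InputError("S1 must be symmetric")
        if self.bin_width <= 0:
            raise InputError("bin_width must be positive")

    @property
    def d(self) -> int:
        return self.M.shape[0]

    @property
    def n_channels(self) -> int:
        return self.P.shape[0]

    @property
    def spectral_radius(self) -> float:
        return float(np.abs(np.linalg.eigvals(self.M)).max())

    def copy(self) -> "LDSParams":
        return LDSParams(
            self.M.copy(), self.P.copy(), self.Ncov.copy(), self.R.copy(),
            self.pi1.copy(), self.S1.copy(), self.bin_width,
        )


@dataclass
class FilterResult:
    """Output of the causal Kalman filter over a session."""

    shat: np.ndarray          # d x K filtered means
    prior_shat: np.ndarray    # d x K one-step predictions (pi1 at k=1)
    gains: np.ndarray         # d x N x K per-bin gains (frozen after steady state)
    innovations: np.ndarray   # N x K
    loglik: float
    state_cov: np.ndarray | None = None   # d x d x K posterior covs (exact mode)
    prior_cov: np.ndarray | None = None   # d x d x K prior covs (exact mode)
    steady_from: int | None = None        # 0-based bin at which the gain froze


@dataclass
class SmootherResult:
    """Output of the RTS smoother: moments sufficient for the EM M-step."""

    means: np.ndarray        # d x K
    covs: np.ndarray         # d x d x K
    cross_covs: np.ndarray   # d x d x (K-1); [:, :, i] = Cov(s_{i+2}, s_{i+1})
    loglik: float


@dataclass
class EMTrace:
    logliks: np.ndarray
    n_iter: int
    converged: bool
    init_method: str


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def _check_dims(params: LDSParams, Y: SpikeCounts) -> None:
    if params.n_channels != Y.n_channels:
        raise InputError(
            f"model has {params.n_channels} channels but data has {Y.n_channels}"
        )


def _forward(params: LDSParams, y: np.ndarray, steady: bool, steady_tol: float):
    """Forward Kalman recursion seeded at (pi1, S1).

    In steady mode the covariance recursion (and hence the gain, the innovation
    covariance factor, and its log-determinant) is frozen once successive prior
    covariances agree to ``steady_tol`` in Frobenius norm.
    """
    M, P, Nc, R = params.M, params.P, params.Ncov, params.R
    d, n = params.d, params.n_channels
    K = y.shape[1]

    shat = np.empty((d, K))
    prior = np.empty((d, K))
    gains = np.empty((d, n, K))
    innov = np.empty((n, K))
    prior_cov = np.empty((d, d, K))
    post_cov = np.empty((d, d, K))

    loglik = 0.0
    cst = n * np.log(2.0 * np.pi)
    frozen = False
    steady_from = None
    Kg = Schol = logdet = None
    Vprior = Vpost = None

    for k in range(K):
        if k == 0:
            m_pred = params.pi1.copy()
            V_pred = params.S1.copy()
        else:
            m_pred = M @ shat[:, k - 1]
            if not frozen:
                V_pred = M @ Vpost @ M.T + Nc
                V_pred = 0.5 * (V_pred + V_pred.T)
                if steady and Vprior is not None and np.linalg.norm(
                    V_pred - Vprior, "fro"
                ) < steady_tol:
                    frozen = True
                    steady_from = k

        if not frozen or Kg is None:
            S = P @ V_pred @ P.T + R
            S = 0.5 * (S + S.T)
            try:
                Schol = np.linalg.cholesky(S)
            except np.linalg.LinAlgError:
                raise NumericalError(
                    f"innovation covariance not positive definite at bin {k + 1}"
                ) from None
            logdet = 2.0 * np.log(np.diag(Schol)).sum()
            # gain = V_pred P^T S^{-1}
            Kg = np.linalg.solve(S, P @ V_pred).T
            Vpost = V_pred - Kg @ P @ V_pred
            Vpost = 0.5 * (Vpost + Vpost.T)
            Vprior = V_pred

        nu = y[:, k] - P @ m_pred
        z = np.linalg.solve(Schol, nu)
        loglik += -0.5 * (cst + logdet + z @ z)

        prior[:, k] = m_pred
        innov[:, k] = nu
        gains[:, :, k] = Kg
        shat[:, k] = m_pred + Kg @ nu
        prior_cov[:, :, k] = Vprior
        post_cov[:, :, k] = Vpost

    return dict(
        shat=shat, prior=prior, gains=gains, innov=innov, loglik=float(loglik),
        prior_cov=prior_cov, post_cov=post_cov, steady_from=steady_from,
    )


def kalman_filter(
    params: LDSParams,
    Y: SpikeCounts | np.ndarray,
    mode: str = "exact",
    steady_tol: float = 1e-8,
) -> FilterResult:
    """Causal Kalman filter for the latent neural state.

    Parameters
    ----------
    mode:
        ``"exact"`` runs the full per-bin covariance recursion and returns the
        exact innovations-form log-likelihood.  ``"steady_state"`` freezes the
        gain once the prior state covariance converges (Frobenius tolerance
        ``steady_tol``); the log-likelihood is then an approximation that uses
        the frozen innovation covariance past the freeze point.
    """
    if mode not in ("exact", "steady_state"):
        raise InputError(f"unknown filter mode {mode!r}")
    Y = _as_counts(Y)
    _check_dims(params, Y)
    fw = _forward(params, Y.counts, steady=(mode == "steady_state"),
                  steady_tol=steady_tol)
    exact = mode == "exact"
    return FilterResult(
        shat=fw["shat"],
        prior_shat=fw["prior"],
        gains=fw["gains"],
        innovations=fw["innov"],
        loglik=fw["loglik"],
        state_cov=fw["post_cov"] if exact else None,
        prior_cov=fw["prior_cov"] if exact else None,
        steady_from=fw["steady_from"],
    )


def kalman_smoother(
    params: LDSParams,
    Y: SpikeCounts | np.ndarray,
    steady_tol: float | None = None,
) -> SmootherResult:
    """RTS smoother over the Kalman filter output.

    ``steady_tol`` activates the steady-state approximation in the forward pass
    (covariance recursion frozen after convergence); ``None`` runs exact.
    Returns smoothed means/covariances and the lag-one cross-covariances needed
    by the EM M-step.
    """
    Y = _as_counts(Y)
    _check_dims(params, Y)
    fw = _forward(params, Y.counts, steady=steady_tol is not None,
                  steady_tol=steady_tol or 0.0)
    M, P = params.M, params.P
    d = params.d
    K = Y.n_bins
    shat, Vpost, Vprior = fw["shat"], fw["post_cov"], fw["prior_cov"]

    means = np.empty((d, K))
    covs = np.empty((d, d, K))
    means[:, -1] = shat[:, -1]
    covs[:, :, -1] = Vpost[:, :, -1]

    J = np.empty((d, d, K - 1)) if K > 1 else np.empty((d, d, 0))
    for k in range(K - 2, -1, -1):
        Jk = np.linalg.solve(Vprior[:, :, k + 1], M @ Vpost[:, :, k]).T
        J[:, :, k] = Jk
        means[:, k] = shat[:, k] + Jk @ (means[:, k + 1] - M @ shat[:, k])
        Vk = Vpost[:, :, k] + Jk @ (covs[:, :, k + 1] - Vprior[:, :, k + 1]) @ Jk.T
        covs[:, :, k] = 0.5 * (Vk + Vk.T)

    cross = np.empty((d, d, K - 1)) if K > 1 else np.empty((d, d, 0))
    if K > 1:
        KK = fw["gains"][:, :, -1]
        cross[:, :, -1] = (np.eye(d) - KK @ P) @ M @ Vpost[:, :, -2]
        for k in range(K - 2, 0, -1):
            # Cov(s_{k+1}, s_k) given all data (0-based bins k, k-1 below)
            cross[:, :, k - 1] = (
                Vpost[:, :, k] @ J[:, :, k - 1].T
                + J[:, :, k] @ (cross[:, :, k] - M @ Vpost[:, :, k]) @ J[:, :, k - 1].T
            )

    return SmootherResult(means=means, covs=covs, cross_covs=cross,
                          loglik=fw["loglik"])


def steady_state_gain(
    params: LDSParams,
    tol: float = 1e-12,
    max_iter: int = 200_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed point of the discrete Riccati recursion: (gain d x N, prior cov d x d).

    Iterates the filter covariance recursion from S1 until successive prior
    covariances agree to ``tol`` (Frobenius).  Raises :class:`ConvergenceError`
    with the residual norm if the budget is exhausted.
    """
    M, P, Nc, R = params.M, params.P, params.Ncov, params.R
    Vprior = params.S1.copy()
    Kg = None
    for _ in range(max_iter):
        S = P @ Vprior @ P.T + R
        S = 0.5 * (S + S.T)
        try:
            Kg = np.linalg.solve(S, P @ Vprior).T
        except np.linalg.LinAlgError:
            raise NumericalError("singular innovation covariance in Riccati "
                                 "iteration") from None
        Vpost = Vprior - Kg @ P @ Vprior
        Vnext = M @ (0.5 * (Vpost + Vpost.T)) @ M.T + Nc
        Vnext = 0.5 * (Vnext + Vnext.T)
        if not np.isfinite(Vnext).all() or np.abs(Vnext).max() > 1e100:
            raise ConvergenceError("Riccati iteration diverged (prior "
                                   "covariance blew up)")
        resid = np.linalg.norm(Vnext - Vprior, "fro")
        Vprior = Vnext
        if resid < tol:
            S = P @ Vprior @ P.T + R
            Kg = np.linalg.solve(0.5 * (S + S.T), P @ Vprior).T
            return Kg, Vprior
    raise ConvergenceError(
        f"Riccati iteration did not converge in {max_iter} iterations "
        f"(residual {resid:.3e})"
    )


def log_likelihood(params: LDSParams, Y: SpikeCounts | np.ndarray) -> float:
    """Exact innovations-form marginal log-likelihood of the observations."""
    Y = _as_counts(Y)
    _check_dims(params, Y)
    return _forward(params, Y.counts, steady=False, steady_tol=0.0)["loglik"]


def predict_next_observation(params: LDSParams, shat_prev: np.ndarray) -> np.ndarray:
    """One-step observation prediction P @ M @ shat_prev (vector or d x K)."""
    return params.P @ (params.M @ np.asarray(shat_prev, dtype=float))


# ---------------------------------------------------------------------------
# learning
# ---------------------------------------------------------------------------

def fa_init(Y: SpikeCounts | np.ndarray, d: int, seed: int = 0) -> LDSParams:
    """Factor-analysis initialization of the LDS parameters.

    P <- FA loadings, R <- FA uniquenesses; M <- lag-1 least-squares regression
    of the FA scores; Ncov <- diagonalized residual covariance of that
    regression; pi1 = 0; S1 = score covariance.
    """
    Y = _as_counts(Y)
    n, K = Y.counts.shape
    if d > n:
        raise InputError(f"latent dimension d={d} exceeds channel count {n}")
    if K <= d + 1:
        raise InputError(f"need more than d+1={d + 1} bins, got {K}")
    var = Y.counts.var(axis=1)
    dead = np.flatnonzero(var <= 0)
    if dead.size:
        raise InputError(
            "zero-variance channels cannot be factor-analysed: "
            + ", ".join(map(str, dead.tolist()))
        )
    fa = FactorAnalysis(n_components=d, random_state=seed)
    Z = fa.fit_transform(Y.counts.T).T          # d x K scores
    P = fa.components_.T                        # n x d
    R = np.diag(np.maximum(fa.noise_variance_, 1e-10))

    Z0, Z1 = Z[:, :-1], Z[:, 1:]
    M = np.linalg.lstsq(Z0.T, Z1.T, rcond=None)[0].T
    resid = Z1 - M @ Z0
    Ncov = np.diag(np.maximum(np.diag(resid @ resid.T / max(K - 1, 1)), 1e-10))
    S1 = np.cov(Z) if d > 1 else np.atleast_2d(np.var(Z))
    S1 = 0.5 * (S1 + S1.T) + 1e-10 * np.eye(d)
    return LDSParams(M=M, P=P, Ncov=Ncov, R=R, pi1=np.zeros(d), S1=S1,
                     bin_width=Y.bin_width)


def _random_init(Y: SpikeCounts, d: int, seed: int) -> LDSParams:
    rng = np.random.default_rng(seed)
    n = Y.n_channels
    M = 0.5 * rng.standard_normal((d, d)) / np.sqrt(d)
    P = rng.standard_normal((n, d)) / np.sqrt(d)
    R = np.diag(np.maximum(Y.counts.var(axis=1), 1e-6))
    return LDSParams(M=M, P=P, Ncov=np.eye(d), R=R, pi1=np.zeros(d),
                     S1=np.eye(d), bin_width=Y.bin_width)


def em_fit(
    Y: SpikeCounts | np.ndarray,
    d: int,
    init: "str | LDSParams" = "factor_analysis",
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
    steady_e_step: bool = False,
    steady_tol: float = 1e-8,
    var_floor: float = 1e-10,
    diagonal_noise: bool = True,
) -> tuple[LDSParams, EMTrace]:
    """Learn (M, P, Ncov, R, pi1, S1) by expectation maximization.

    The E-step is the RTS smoother (exactly, or with the steady-state
    approximation when ``steady_e_step`` is set: smoothing covariances are
    computed from the frozen filter covariance recursion).  The M-step is the
    standard closed form; ``Ncov`` and ``R`` are projected to diagonal, with
    variances floored at ``var_floor``.  pi1/S1 are re-estimated each
    iteration.  Stops when the relative log-likelihood improvement drops below
    ``tol`` or after ``max_iter`` iterations.

    With the exact E-step a log-likelihood decrease beyond numerical tolerance
    raises :class:`NumericalError` naming the iteration.
    """
    Y = _as_counts(Y)
    n, K = Y.counts.shape
    if d > n:
        raise InputError(f"latent dimension d={d} exceeds channel count {n}")

    if isinstance(init, LDSParams):
        params, init_method = init.copy(), "warm_start"
    elif init == "factor_analysis":
        params, init_method = fa_init(Y, d, seed=seed), "factor_analysis"
    elif init == "random":
        params, init_method = _random_init(Y, d, seed), "random"
    else:
        raise InputError(f"unknown init {init!r}")

    y = Y.counts
    yyT = y @ y.T
    logliks: list[float] = []
    converged = False
    stol = steady_tol if steady_e_step else None

    for it in range(max_iter):
        sm = kalman_smoother(params, Y, steady_tol=stol)
        ll = sm.loglik
        if logliks:
            prev = logliks[-1]
            if ll < prev - max(tol * abs(prev), 1e-9):
                if not steady_e_step:
                    raise NumericalError(
                        f"log-likelihood decreased at EM iteration {it + 1}: "
                        f"{prev:.6f} -> {ll:.6f}"
                    )
            if abs(ll - prev) <= tol * abs(prev):
                logliks.append(ll)
                converged = True
                break
        logliks.append(ll)

        m, V, C = sm.means, sm.covs, sm.cross_covs
        EssT = V + np.einsum("ik,jk->ijk", m, m)     # d x d x K
        S_all = EssT.sum(axis=2)
        S00 = S_all - EssT[:, :, -1]
        S11 = S_all - EssT[:, :, 0]
        S10 = C.sum(axis=2) + m[:, 1:] @ m[:, :-1].T

        Mnew = np.linalg.solve(S00.T, S10.T).T
        Ncov = (S11 - Mnew @ S10.T) / max(K - 1, 1)
        Ncov = 0.5 * (Ncov + Ncov.T)
        ymT = y @ m.T
        Pnew = np.linalg.solve(S_all.T, ymT.T).T
        Rnew = (yyT - Pnew @ ymT.T) / K
        Rnew = 0.5 * (Rnew + Rnew.T)
        if diagonal_noise:
            Ncov = np.diag(np.diag(Ncov))
            Rnew = np.diag(np.diag(Rnew))
        Ncov[np.diag_indices(d)] = np.maximum(np.diag(Ncov), var_floor)
        Rnew[np.diag_indices(n)] = np.maximum(np.diag(Rnew), var_floor)

        S1 = 0.5 * (V[:, :, 0] + V[:, :, 0].T) + var_floor * np.eye(d)
        params = LDSParams(M=Mnew, P=Pnew, Ncov=Ncov, R=Rnew,
                           pi1=m[:, 0].copy(), S1=S1, bin_width=Y.bin_width)

    trace = EMTrace(logliks=np.asarray(logliks), n_iter=len(logliks),
                    converged=converged, init_method=init_method)
    return params, trace


# ---------------------------------------------------------------------------
# summaries and controls
# ---------------------------------------------------------------------------

def eigen_summary(params: LDSParams) -> pd.DataFrame:
    """Eigenvalues of M with per-mode time constants and rotation frequencies.

    time constant tau = -dt / ln|lambda| seconds (inf when |lambda| = 1),
    frequency = |arg lambda| / (2 pi dt) Hz; rows sorted by |lambda| descending.
    """
    lam = np.linalg.eigvals(params.M)
    mod = np.abs(lam)
    dt = params.bin_width
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.where(np.isclose(mod, 1.0), np.inf, -dt / np.log(mod))
    freq = np.abs(np.angle(lam)) / (2.0 * np.pi * dt)
    order = np.argsort(-mod)
    return pd.DataFrame(
        {
            "eigenvalue": lam[order],
            "modulus": mod[order],
            "time_constant_s": tau[order],
            "frequency_hz": freq[order],
        }
    ).reset_index(drop=True)


def permute_columns(params: LDSParams, permutation: Sequence[int]) -> LDSParams:
    """Copy of ``params`` with the columns of M reordered by ``permutation``."""
    perm = np.asarray(permutation, dtype=int)
    if sorted(perm.tolist()) != list(range(params.d)):
        raise InputError(f"not a permutation of 0..{params.d - 1}: {perm}")
    out = params.copy()
    out.M = params.M[:, perm].copy()
    return out


def permute_dynamics(params: LDSParams, seed: int = 0) -> LDSParams:
    """Perturbed-dynamics control: permute the columns of M.

    Draws a uniformly random non-identity column permutation; every other
    parameter is untouched.  Requires d >= 2.
    """
    if params.d < 2:
        raise InputError("permute_dynamics requires d >= 2 (no non-identity "
                         "permutation exists for d = 1)")
    rng = np.random.default_rng(seed)
    ident = np.arange(params.d)
    perm = ident
    while np.array_equal(perm, ident):
        perm = rng.permutation(params.d)
    return permute_columns(params, perm)
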