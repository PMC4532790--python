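"""Cursor decoders: NDF, OLE, Wiener filter, kinematic Kalman filter, PC-smooth.

All decoders are strictly causal, share the least-squares readout with a bias
row of ones, and share the position blending rule

    p_k = (1 - alpha) * p_hat_k + alpha * (p_{k-1} + dt * v_hat_k)

with alpha = 0.975 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as _signal
from sklearn.decomposition import PCA

from .errors import InputError, NumericalError
from .lds import (
    LDSParams,
    SpikeCounts,
    _as_counts,
    em_fit,
    kalman_filter,
    EMTrace,
)

__all__ = [
    "KinematicsSeries",
    "NDFModel",
    "OLEModel",
    "WFModel",
    "KKFModel",
    "PCSmoothModel",
    "causal_gaussian_smooth",
    "fit_readout",
    "fit_ndf",
    "fit_ole",
    "fit_wf",
    "fit_kkf",
    "fit_pcsmooth",
    "decode",
    "blend_position",
    "OLE_KERNEL_GRID",
]

#: kernel grid (seconds) over which OLE smoothing is selected, mirroring the
#: 0/25/50/100/150/200-ms variants.
OLE_KERNEL_GRID = (0.0, 0.025, 0.050, 0.100, 0.150, 0.200)


@dataclass
class KinematicsSeries:
    """Per-bin 2-D cursor position (cm) and velocity (cm/s) with labels."""

    pos: np.ndarray                      # 2 x K
    vel: np.ndarray                      # 2 x K
    bin_width: float = 0.015
    epoch_labels: np.ndarray | None = None   # per-bin {"reach","hold","other"}
    trial_ids: np.ndarray | None = None
    condition_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pos = np.atleast_2d(np.asarray(self.pos, dtype=float))
        self.vel = np.atleast_2d(np.asarray(self.vel, dtype=float))
        if self.pos.shape[0] != 2 or self.vel.shape[0] != 2:
            raise InputError("pos and vel must be 2 x K")
        if self.pos.shape != self.vel.shape:
            raise InputError("pos and vel must have matching shapes")
        K = self.pos.shape[1]
        for name in ("epoch_labels", "trial_ids", "condition_ids"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                if v.shape != (K,):
                    raise InputError(f"{name} must have length {K}")
                setattr(self, name, v)
        if self.bin_width <= 0:
            raise InputError("bin_width must be positive")

    @property
    def n_bins(self) -> int:
        return self.pos.shape[1]

    def stacked(self) -> np.ndarray:
        """4 x K array [pos_x; pos_y; vel_x; vel_y]."""
        return np.vstack([self.pos, self.vel])


# ---------------------------------------------------------------------------
# shared primitives
# ---------------------------------------------------------------------------

def causal_gaussian_smooth(
    Y: SpikeCounts | np.ndarray,
    kernel_sd: float,
    bin_width: float | None = None,
) -> np.ndarray:
    """Causally smooth each row with a truncated Gaussian kernel.

    The kernel has weight exp(-(j*dt)^2 / (2*sd^2)) at lag j >= 0, truncated at
    4 standard deviations in the past and normalized to sum to 1.  Near the
    start of the sequence the available weights are renormalized, so a constant
    input maps to the same constant everywhere.  ``kernel_sd = 0`` is the
    identity.
    """
    if kernel_sd < 0:
        raise InputError("kernel_sd must be non-negative")
    if isinstance(Y, SpikeCounts):
        x, dt = Y.counts, Y.bin_width
    else:
        x = np.atleast_2d(np.asarray(Y, dtype=float))
        dt = bin_width if bin_width is not None else 0.015
    if kernel_sd == 0:
        return x.copy()
    lags = np.arange(int(np.floor(4.0 * kernel_sd / dt)) + 1)
    w = np.exp(-((lags * dt) ** 2) / (2.0 * kernel_sd**2))
    w /= w.sum()
    num = _signal.lfilter(w, [1.0], x, axis=1)
    den = _signal.lfilter(w, [1.0], np.ones(x.shape[1]))
    return num / den[None, :]


def fit_readout(features: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares readout X ~ L @ features + b via the ones-row augmentation.

    Rank-deficient feature matrices are resolved by the minimum-norm
    least-squares solution (so an all-zero feature matrix yields L = 0 and the
    bias equal to the row-means of X).
    """
    F = np.atleast_2d(np.asarray(features, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if F.shape[1] != X.shape[1]:
        raise InputError(
            f"features have {F.shape[1]} bins but targets have {X.shape[1]}"
        )
    A = np.vstack([F, np.ones(F.shape[1])])
    coef, *_ = np.linalg.lstsq(A.T, X.T, rcond=None)
    L = coef[:-1].T
    bias = coef[-1]
    return L, bias


def blend_position(
    p_hat: np.ndarray,
    v_hat: np.ndarray,
    p_prev: np.ndarray,
    alpha: float = 0.975,
    dt: float = 0.015,
) -> np.ndarray:
    """Blend decoded position with integrated velocity.

    Returns (1 - alpha) * p_hat + alpha * (p_prev + dt * v_hat): with the
    default alpha the output takes a 2.5% contribution from the decoded
    position and 97.5% from the integrated velocity.
    """
    if not 0.0 <= alpha <= 1.0:
        raise InputError(f"alpha must be in [0, 1], got {alpha}")
    p_hat = np.asarray(p_hat, dtype=float)
    v_hat = np.asarray(v_hat, dtype=float)
    p_prev = np.asarray(p_prev, dtype=float)
    return (1.0 - alpha) * p_hat + alpha * (p_prev + dt * v_hat)


def _blend_series(
    raw: np.ndarray, init_pos: np.ndarray, alpha: float, dt: float
) -> np.ndarray:
    """Apply the blending recursion along a 4 x K raw readout [pos; vel]."""
    K = raw.shape[1]
    pos = np.empty((2, K))
    p_prev = np.asarray(init_pos, dtype=float)
    for k in range(K):
        p_prev = blend_position(raw[:2, k], raw[2:, k], p_prev, alpha, dt)
        pos[:, k] = p_prev
    return pos


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

@dataclass
class NDFModel:
    """Neural dynamical filter: steady-state Kalman latent state + linear readout."""

    lds: LDSParams
    L: np.ndarray                 # 4 x d
    bias: np.ndarray              # 4
    steady_gain: np.ndarray | None = None
    em_trace: EMTrace | None = None
    decoder_type: str = field(default="ndf", init=False)

    def features(self, Y: SpikeCounts) -> np.ndarray:
        fr = kalman_filter(self.lds, Y, mode="steady_state")
        return fr.shat


@dataclass
class OLEModel:
    """Optimal linear estimator on causally smoothed spike counts."""

    L: np.ndarray                 # 4 x N
    bias: np.ndarray
    kernel_sd: float = 0.0
    decoder_type: str = field(default="ole", init=False)

    def features(self, Y: SpikeCounts) -> np.ndarray:
        return causal_gaussian_smooth(Y, self.kernel_sd)


@dataclass
class WFModel:
    """Wiener filter over a zero-padded history of p bins of spike counts."""

    L_blocks: np.ndarray          # p x 4 x N, block j applies to y_{k-j}
    bias: np.ndarray
    lam: float = 0.0
    decoder_type: str = field(default="wf", init=False)

    @property
    def p(self) -> int:
        return self.L_blocks.shape[0]

    def features(self, Y: SpikeCounts) -> np.ndarray:
        return _history_stack(Y.counts, self.p)

    @property
    def L(self) -> np.ndarray:
        """Flattened 4 x (p*N) readout matching :meth:`features` ordering."""
        return np.concatenate(list(self.L_blocks), axis=1)


@dataclass
class KKFModel:
    """Kinematic-state Kalman filter (position+velocity state by default)."""

    A: np.ndarray                 # 4 x 4 (2 x 2 when velocity_only)
    C: np.ndarray                 # N x 4
    W: np.ndarray
    Q: np.ndarray
    velocity_only: bool = False
    decoder_type: str = field(default="kkf", init=False)

    def __post_init__(self) -> None:
        for name in ("W", "Q"):
            v = getattr(self, name)
            if not np.allclose(v, v.T, atol=1e-8):
                raise InputError(f"{name} must be symmetric")


@dataclass
class PCSmoothModel:
    """Control decoder: 20 principal components, causally smoothed, linear readout."""

    components: np.ndarray        # N x n_components, orthonormal columns
    mean: np.ndarray              # N
    L: np.ndarray
    bias: np.ndarray
    kernel_sd: float = 0.100
    decoder_type: str = field(default="pcsmooth", init=False)

    def features(self, Y: SpikeCounts) -> np.ndarray:
        Z = self.components.T @ (Y.counts - self.mean[:, None])
        return causal_gaussian_smooth(Z, self.kernel_sd, bin_width=Y.bin_width)


DecoderModel = NDFModel | OLEModel | WFModel | KKFModel | PCSmoothModel


def _history_stack(y: np.ndarray, p: int) -> np.ndarray:
    """(p*N) x K design where rows [j*N:(j+1)*N] hold y_{k-j}, zero-padded."""
    n, K = y.shape
    out = np.zeros((p * n, K))
    for j in range(p):
        out[j * n : (j + 1) * n, j:] = y[:, : K - j]
    return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _stacked_kin(X: "KinematicsSeries | np.ndarray") -> np.ndarray:
    if isinstance(X, KinematicsSeries):
        return X.stacked()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != 4:
        raise InputError("kinematics must be 4 x K [pos_x; pos_y; vel_x; vel_y]")
    return X


def fit_ndf(
    Y: SpikeCounts | np.ndarray,
    X: "KinematicsSeries | np.ndarray",
    d: int = 20,
    lds: LDSParams | None = None,
    **em_opts,
) -> NDFModel:
    """Fit the neural dynamical filter.

    Learns the latent LDS by EM (unless pre-learned ``lds`` is supplied, e.g.
    the permuted-dynamics control), runs the steady-state Kalman filter over
    the training counts, and fits the least-squares readout from filtered
    states to kinematics.
    """
    Y = _as_counts(Y)
    Xs = _stacked_kin(X)
    trace = None
    if lds is None:
        lds, trace = em_fit(Y, d, **em_opts)
    fr = kalman_filter(lds, Y, mode="steady_state")
    L, bias = fit_readout(fr.shat, Xs)
    return NDFModel(lds=lds, L=L, bias=bias, steady_gain=fr.gains[:, :, -1],
                    em_trace=trace)


def fit_ole(
    Y: SpikeCounts | np.ndarray,
    X: "KinematicsSeries | np.ndarray",
    kernel_sd: float = 0.0,
) -> OLEModel:
    """Fit the optimal linear estimator on causally smoothed counts."""
    Y = _as_counts(Y)
    Ys = causal_gaussian_smooth(Y, kernel_sd)
    L, bias = fit_readout(Ys, _stacked_kin(X))
    return OLEModel(L=L, bias=bias, kernel_sd=kernel_sd)


def fit_wf(
    Y: SpikeCounts | np.ndarray,
    X: "KinematicsSeries | np.ndarray",
    p: int = 17,
    lam: float = 0.0,
) -> WFModel:
    """Fit the Wiener filter over p bins of history with ridge weight lam.

    Solves the regularized normal equations over the zero-padded history stack;
    the bias row is not penalized.
    """
    if p < 1:
        raise InputError("history length p must be >= 1")
    if lam < 0:
        raise InputError("ridge weight lam must be >= 0")
    Y = _as_counts(Y)
    Xs = _stacked_kin(X)
    F = _history_stack(Y.counts, p)
    n = Y.n_channels
    A = np.vstack([F, np.ones(F.shape[1])])
    G = A @ A.T
    pen = lam * np.eye(p * n + 1)
    pen[-1, -1] = 0.0
    try:
        coef = np.linalg.solve(G + pen, A @ Xs.T)
    except np.linalg.LinAlgError:
        raise NumericalError(
            "singular Wiener-filter normal equations; increase lam > 0"
        ) from None
    if lam == 0.0 and np.linalg.cond(G) > 1e12:
        raise NumericalError(
            "ill-conditioned Wiener-filter normal equations; increase lam > 0"
        )
    Lw = coef[:-1].T                       # 4 x (p*n)
    bias = coef[-1]
    blocks = np.stack([Lw[:, j * n : (j + 1) * n] for j in range(p)])
    return WFModel(L_blocks=blocks, bias=bias, lam=lam)


def fit_kkf(
    Y: SpikeCounts | np.ndarray,
    X: "KinematicsSeries | np.ndarray",
    velocity_only: bool = False,
) -> KKFModel:
    """Fit the kinematic-state Kalman filter.

    A comes from lag-1 least squares on the kinematics, C from regressing
    counts on kinematics; W and Q are the (centered, 1/n) sample covariances of
    the corresponding residuals.
    """
    Y = _as_counts(Y)
    Xs = _stacked_kin(X)
    if velocity_only:
        Xs = Xs[2:]
    K = Xs.shape[1]
    if K < 2:
        raise InputError("need at least 2 bins to fit kinematic dynamics")
    X0, X1 = Xs[:, :-1], Xs[:, 1:]
    gram = X0 @ X0.T
    if np.linalg.cond(gram) > 1e12:
        raise InputError("degenerate (near-constant) kinematics; cannot fit A")
    A = np.linalg.solve(gram.T, (X1 @ X0.T).T).T
    C = np.linalg.solve((Xs @ Xs.T).T, (Y.counts @ Xs.T).T).T
    W = np.cov(X1 - A @ X0, bias=True)
    W = np.atleast_2d(W)
    Q = np.atleast_2d(np.cov(Y.counts - C @ Xs, bias=True))
    return KKFModel(A=A, C=C, W=0.5 * (W + W.T), Q=0.5 * (Q + Q.T),
                    velocity_only=velocity_only)


def fit_pcsmooth(
    Y: SpikeCounts | np.ndarray,
    X: "KinematicsSeries | np.ndarray",
    n_components: int = 20,
    kernel_sd: float = 0.100,
) -> PCSmoothModel:
    """Fit the PC-smooth control decoder."""
    Y = _as_counts(Y)
    if Y.n_channels < n_components:
        raise InputError(
            f"{n_components} components requested but only {Y.n_channels} channels"
        )
    pca = PCA(n_components=n_components)
    pca.fit(Y.counts.T)
    comps = pca.components_.T              # N x n_components
    mean = pca.mean_
    model = PCSmoothModel(components=comps, mean=mean, L=np.zeros((4, n_components)),
                          bias=np.zeros(4), kernel_sd=kernel_sd)
    feats = model.features(Y)
    L, bias = fit_readout(feats, _stacked_kin(X))
    model.L = L
    model.bias = bias
    return model


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def _kkf_filter(model: KKFModel, y: np.ndarray, x0: np.ndarray) -> np.ndarray:
    """Causal Kalman filter on the kinematic state; returns state means."""
    A, C, W, Q = model.A, model.C, model.W, model.Q
    dx = A.shape[0]
    K = y.shape[1]
    xhat = np.empty((dx, K))
    m = np.asarray(x0, dtype=float)
    V = W.copy()
    for k in range(K):
        m_pred = A @ m
        V_pred = A @ V @ A.T + W
        S = C @ V_pred @ C.T + Q
        S = 0.5 * (S + S.T) + 1e-12 * np.eye(S.shape[0])
        try:
            Kg = np.linalg.solve(S, C @ V_pred).T
        except np.linalg.LinAlgError:
            raise NumericalError(
                f"singular KKF innovation covariance at bin {k + 1}"
            ) from None
        m = m_pred + Kg @ (y[:, k] - C @ m_pred)
        V = V_pred - Kg @ C @ V_pred
        V = 0.5 * (V + V.T)
        xhat[:, k] = m
    return xhat


def decode(
    model: DecoderModel,
    Y: SpikeCounts | np.ndarray,
    init_pos: Sequence[float] = (0.0, 0.0),
    alpha: float = 0.975,
) -> KinematicsSeries:
    """Run a fitted decoder causally over spike counts.

    Per bin the decoder computes its causal features (filtered latent state for
    NDF, smoothed counts for OLE, zero-padded history stack for WF, filtered
    kinematic state for KKF, smoothed principal components for PC-smooth),
    applies the linear readout to obtain raw (p_hat, v_hat), and blends the
    position with the integrated velocity.
    """
    Y = _as_counts(Y)
    n_expected = _model_n_channels(model)
    if n_expected != Y.n_channels:
        raise InputError(
            f"model was trained on {n_expected} channels but data has "
            f"{Y.n_channels}"
        )
    if isinstance(model, KKFModel):
        if model.velocity_only:
            x0 = np.zeros(2)
            vel = _kkf_filter(model, Y.counts, x0)
            raw = np.vstack([np.zeros((2, Y.n_bins)), vel])
            pos = np.cumsum(vel * Y.bin_width, axis=1) + np.asarray(
                init_pos, dtype=float
            )[:, None]
            return KinematicsSeries(pos=pos, vel=vel, bin_width=Y.bin_width)
        x0 = np.concatenate([np.asarray(init_pos, dtype=float), np.zeros(2)])
        raw = _kkf_filter(model, Y.counts, x0)
    else:
        feats = model.features(Y)
        raw = model.L @ feats + model.bias[:, None]
    pos = _blend_series(raw, np.asarray(init_pos, dtype=float), alpha, Y.bin_width)
    return KinematicsSeries(pos=pos, vel=raw[2:], bin_width=Y.bin_width)


def _model_n_channels(model: DecoderModel) -> int:
    if isinstance(model, NDFModel):
        return model.lds.n_channels
    if isinstance(model, OLEModel):
        return model.L.shape[1]
    if isinstance(model, WFModel):
        return model.L_blocks.shape[2]
    if isinstance(model, KKFModel):
        return model.C.shape[0]
    if isinstance(model, PCSmoothModel):
        return model.components.shape[0]
    raise InputError(f"unknown decoder model {type(model).__name__}")


def select_ole(
    Y_train: SpikeCounts,
    X_train: "KinematicsSeries | np.ndarray",
    Y_val: SpikeCounts,
    X_val: "KinematicsSeries | np.ndarray",
    kernel_grid: Sequence[float] = OLE_KERNEL_GRID,
    init_pos: Sequence[float] = (0.0, 0.0),
) -> tuple[OLEModel, float]:
    """Pick the OLE smoothing kernel by decoded-trajectory MSE on a validation split."""
    best = None
    best_mse = np.inf
    Xv = _stacked_kin(X_val)
    for sd in kernel_grid:
        model = fit_ole(Y_train, X_train, kernel_sd=sd)
        dec = decode(model, Y_val, init_pos=init_pos)
        mse = float(np.mean((dec.stacked() - Xv) ** 2))
        if mse < best_mse:
            best, best_mse = model, mse
    return best, best_mse
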