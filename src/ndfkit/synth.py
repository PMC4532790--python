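"""Ground-truth systems and synthetic sessions for end-to-end testing.

The generator builds a stable, non-normal latent LDS whose state space contains
a slow "hold" subspace (dims 0-1, carrying cursor position), a faster
velocity subspace (dims 2-3), and noise-driven background rotational modes.
Center-out-and-back sessions steer a deterministic latent template through
condition-dependent reach transients and slow holds, superimpose an autonomous
LDS noise process, and emit counts through the observation process and
kinematics through a linear readout of the latent state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from .decoders import KinematicsSeries
from .errors import InputError
from .lds import LDSParams, SpikeCounts
from .metrics import SelectionLog

__all__ = [
    "GroundTruth",
    "DEFAULT_SPEC",
    "make_ground_truth_lds",
    "simulate_lds",
    "simulate_reach_session",
    "simulate_grid_session",
    "make_fixtures",
]

#: Generator defaults.  Noise scales are calibrated so that raw counts are
#: visibly noisier than the latent trajectory (single-channel SNR well below 1)
#: while EM at matched latent dimension still recovers the generating spectrum.
DEFAULT_SPEC = {
    "decay_range": (0.90, 0.97),        # |lambda| of background modes
    "rot_freq_range": (0.5, 2.5),       # Hz, background modes
    "hold_contraction": 0.3,            # 1 - |lambda| of hold modes = 0.01 * this
    "vel_decay": 0.92,
    "vel_freq_hz": 0.8,
    "skew_range": (1.2, 1.6),           # within-block skew (non-normality)
    "process_noise": {"hold": 0.03, "vel": 0.05, "background": 0.30},
    "obs_noise": 1.2,                   # s.d. of observation noise per channel
    "p_scale": 1.0,
    "pos_gain_cm": 12.0,                # latent hold-mode unit -> cm
    "vel_gain": 12.0,                   # latent vel-mode unit -> cm/s
    "vel_amplitude": 3.0,               # peak latent velocity-mode excursion
    "bin_width": 0.015,
}

GEOMETRY = {
    "n_targets": 8,
    "radius_cm": 12.0,
    "hold_s": 0.5,
    "reach_bins": 13,
    "hold_bins": 34,
    "return_bins": 13,
    "hold_label_skip_start": 7,         # 100 ms after hold initiation
    "hold_label_skip_end": 10,          # 150 ms before hold completion
}


@dataclass
class GroundTruth:
    """A generating LDS plus the kinematic readout and task geometry."""

    lds: LDSParams
    kin_readout: np.ndarray             # 4 x d
    slow_dims: tuple[int, ...] = (0, 1)
    vel_dims: tuple[int, ...] = (2, 3)
    geometry: dict = field(default_factory=lambda: dict(GEOMETRY))
    spec: dict = field(default_factory=lambda: dict(DEFAULT_SPEC))


def _rotation_block(mod: float, freq_hz: float, dt: float, skew: float) -> np.ndarray:
    """2x2 block with eigenvalues mod * exp(+-i * 2*pi*freq*dt), skewed to be
    non-normal without changing the spectrum."""
    th = 2.0 * np.pi * freq_hz * dt
    return mod * np.array(
        [[np.cos(th), np.sin(th) * skew], [-np.sin(th) / skew, np.cos(th)]]
    )


def make_ground_truth_lds(
    d: int = 8,
    n_channels: int = 24,
    seed: int = 0,
    spec: dict | None = None,
) -> GroundTruth:
    """Build a stable ground-truth LDS with hold/velocity/background structure.

    Requires d >= 4 (two hold dims + two velocity dims); remaining dims are
    background damped rotations (plus one real mode when d is odd) with moduli
    in ``decay_range`` and frequencies in ``rot_freq_range``.
    """
    sp = dict(DEFAULT_SPEC)
    if spec:
        sp.update(spec)
    if d < 4:
        raise InputError("ground-truth LDS needs d >= 4 (hold + velocity modes)")
    if n_channels < d:
        raise InputError(f"need n_channels >= d, got {n_channels} < {d}")
    rng = np.random.default_rng(seed)
    dt = sp["bin_width"]

    M = np.zeros((d, d))
    lam_hold = 1.0 - 0.01 * sp["hold_contraction"]
    if not 0 < lam_hold < 1:
        raise InputError(f"infeasible hold_contraction {sp['hold_contraction']}")
    M[0, 0] = M[1, 1] = lam_hold
    # mild triangular coupling for non-normality; scaled by (1 - lambda) so the
    # near-integrator hold modes do not amplify cross-fed noise
    M[0, 1] = 0.3 * (1.0 - lam_hold)
    M[2:4, 2:4] = _rotation_block(sp["vel_decay"], sp["vel_freq_hz"], dt,
                                  rng.uniform(*sp["skew_range"]))
    i = 4
    while i + 1 < d:
        M[i : i + 2, i : i + 2] = _rotation_block(
            rng.uniform(*sp["decay_range"]),
            rng.uniform(*sp["rot_freq_range"]),
            dt,
            rng.uniform(*sp["skew_range"]),
        )
        i += 2
    if i < d:
        M[i, i] = rng.uniform(*sp["decay_range"])

    if np.abs(np.linalg.eigvals(M)).max() >= 1.0:
        raise InputError("infeasible spec: constructed dynamics are unstable")

    P = rng.standard_normal((n_channels, d)) * sp["p_scale"] / np.sqrt(d)
    nz = sp["process_noise"]
    diag = np.full(d, nz["background"])
    diag[[0, 1]] = nz["hold"]
    diag[[2, 3]] = nz["vel"]
    Ncov = np.diag(diag**2)
    R = sp["obs_noise"] ** 2 * np.eye(n_channels)
    S1 = sla.solve_discrete_lyapunov(M, Ncov)
    S1 = 0.5 * (S1 + S1.T)
    lds = LDSParams(M=M, P=P, Ncov=Ncov, R=R, pi1=np.zeros(d), S1=S1,
                    bin_width=dt)

    C = np.zeros((4, d))
    C[0, 0] = C[1, 1] = sp["pos_gain_cm"]
    C[2, 2] = C[3, 3] = sp["vel_gain"]
    return GroundTruth(lds=lds, kin_readout=C, spec=sp)


def _psd_sqrt(S: np.ndarray) -> np.ndarray:
    S = np.atleast_2d(np.asarray(S, dtype=float))
    try:
        return np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(0.5 * (S + S.T))
        return V * np.sqrt(np.clip(w, 0.0, None))


def simulate_lds(
    params: LDSParams,
    K: int,
    seed: int = 0,
    emission: str = "gaussian",
    poisson_offset: float = 0.5,
) -> tuple[np.ndarray, SpikeCounts]:
    """Ancestral sampling from the LDS: returns (latents d x K, counts N x K).

    ``gaussian`` emission follows the observation process exactly (real-valued
    counts).  ``poisson`` (robustness testing only) draws counts from
    Poisson(softplus(P s_k + poisson_offset)).
    """
    if K < 1:
        raise InputError("K must be >= 1")
    rng = np.random.default_rng(seed)
    d, n = params.d, params.n_channels
    Ls1 = _psd_sqrt(params.S1)
    Ln = _psd_sqrt(params.Ncov)
    s = np.empty((d, K))
    s[:, 0] = params.pi1 + Ls1 @ rng.standard_normal(d)
    noise = Ln @ rng.standard_normal((d, K))
    for k in range(1, K):
        s[:, k] = params.M @ s[:, k - 1] + noise[:, k]
    drive = params.P @ s
    if emission == "gaussian":
        y = drive + _psd_sqrt(params.R) @ rng.standard_normal((n, K))
    elif emission == "poisson":
        rate = np.log1p(np.exp(np.clip(drive + poisson_offset, -30, 30)))
        y = rng.poisson(rate).astype(float)
    else:
        raise InputError(f"unknown emission {emission!r}")
    return s, SpikeCounts(y, bin_width=params.bin_width)


def _minjerk(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-jerk position (0 -> 1) and unit-peak speed profiles over n bins."""
    t = (np.arange(n) + 1) / n
    pos = 10 * t**3 - 15 * t**4 + 6 * t**5
    spd = 30 * t**2 * (1 - t) ** 2
    peak = spd.max()
    return pos, (spd / peak if peak > 0 else np.ones(n))


def simulate_reach_session(
    gt: GroundTruth,
    n_trials: int = 500,
    seed: int = 0,
    kin_noise: float = 0.25,
) -> tuple[SpikeCounts, KinematicsSeries]:
    """Simulate a center-out-and-back session (~60 bins/trial).

    Each trial reaches to one of 8 targets on a 12-cm circle (min-jerk position
    profile on the hold dims, a bell-shaped transient on the velocity dims),
    holds for 500 ms, and returns to center.  An autonomous LDS noise process
    is superimposed on the template; counts come from the observation process
    and kinematics from ``kin_readout @ s_k`` plus ``kin_noise``-s.d. noise.
    Epoch labels mark center-out reach bins and the interior hold window.
    """
    if n_trials < 1:
        raise InputError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    g = gt.geometry
    lds = gt.lds
    d = lds.d
    nb_reach, nb_hold, nb_back = g["reach_bins"], g["hold_bins"], g["return_bins"]
    bins_per_trial = nb_reach + nb_hold + nb_back
    K = n_trials * bins_per_trial
    amp_v = gt.spec["vel_amplitude"]

    pos_prof, spd_prof = _minjerk(nb_reach)
    back_pos, back_spd = _minjerk(nb_back)

    z = np.zeros((d, K))
    labels = np.full(K, "other", dtype=object)
    trial_ids = np.empty(K, dtype=int)
    cond_ids = np.empty(K, dtype=int)
    pdims = list(gt.slow_dims)
    vdims = list(gt.vel_dims)

    k = 0
    for tr in range(n_trials):
        c = int(rng.integers(g["n_targets"]))
        ang = 2.0 * np.pi * c / g["n_targets"]
        u = np.array([np.cos(ang), np.sin(ang)])
        sl = slice(k, k + bins_per_trial)
        trial_ids[sl] = tr
        cond_ids[sl] = c
        # center-out reach
        z[np.ix_(pdims, range(k, k + nb_reach))] = np.outer(u, pos_prof)
        z[np.ix_(vdims, range(k, k + nb_reach))] = np.outer(u, amp_v * spd_prof)
        labels[k : k + nb_reach] = "reach"
        k += nb_reach
        # hold at target
        z[np.ix_(pdims, range(k, k + nb_hold))] = u[:, None]
        labels[k + g["hold_label_skip_start"] : k + nb_hold - g["hold_label_skip_end"]] = "hold"
        k += nb_hold
        # return to center
        z[np.ix_(pdims, range(k, k + nb_back))] = np.outer(u, 1.0 - back_pos)
        z[np.ix_(vdims, range(k, k + nb_back))] = np.outer(-u, amp_v * back_spd)
        k += nb_back

    # autonomous noise process superimposed on the template
    e = np.zeros((d, K))
    Ln = _psd_sqrt(lds.Ncov)
    e[:, 0] = _psd_sqrt(lds.S1) @ rng.standard_normal(d)
    noise = Ln @ rng.standard_normal((d, K))
    for kk in range(1, K):
        e[:, kk] = lds.M @ e[:, kk - 1] + noise[:, kk]
    s = z + e

    y = lds.P @ s + _psd_sqrt(lds.R) @ rng.standard_normal((lds.n_channels, K))
    kin = gt.kin_readout @ s + kin_noise * rng.standard_normal((4, K))

    counts = SpikeCounts(y, bin_width=lds.bin_width,
                         channel_ids=[f"ch{i:03d}" for i in range(lds.n_channels)])
    series = KinematicsSeries(
        pos=kin[:2], vel=kin[2:], bin_width=lds.bin_width,
        epoch_labels=np.asarray(labels, dtype=object),
        trial_ids=trial_ids, condition_ids=cond_ids,
    )
    return counts, series


def simulate_grid_session(
    success_rate: float,
    n_selections: int = 100,
    mean_acquire_s: float = 1.5,
    dwell: float = 0.450,
    lockout: float = 0.200,
    timeout: float = 5.0,
    timeout_rate: float = 0.0,
    seed: int = 0,
    n_targets: int = 36,
) -> SelectionLog:
    """Simulate a grid-task selection stream.

    Non-timeout selections are Bernoulli(``success_rate``) with acquire times
    of ``dwell`` plus an exponential tail (mean ``mean_acquire_s - dwell``),
    truncated below the timeout; every event is followed by the lockout.
    Timeouts (probability ``timeout_rate``) consume ``timeout`` seconds.
    """
    if not 0.0 <= success_rate <= 1.0:
        raise InputError("success_rate must be in [0, 1]")
    if mean_acquire_s <= dwell:
        raise InputError("mean_acquire_s must exceed the dwell time")
    rng = np.random.default_rng(seed)
    t = 0.0
    events: list[tuple[float, str]] = []
    for _ in range(n_selections):
        if rng.random() < timeout_rate:
            t += timeout
            events.append((t, "timeout"))
            continue
        acq = dwell + rng.exponential(mean_acquire_s - dwell)
        acq = min(acq, timeout - 1e-3)
        t += acq + lockout
        outcome = "correct" if rng.random() < success_rate else "incorrect"
        events.append((t, outcome))
    return SelectionLog(events=events, duration=t, n_targets=n_targets)


def make_fixtures(outdir, n_trials: int = 50, seed: int = 7,
                  d: int = 8, n_channels: int = 24) -> dict:
    """Write a complete small session (counts, kinematics, ground-truth LDS,
    grid log) under ``outdir``; returns the generator report."""
    from . import io as _io  # local import: io depends on the type modules only

    gt = make_ground_truth_lds(d=d, n_channels=n_channels, seed=seed)
    Y, X = simulate_reach_session(gt, n_trials=n_trials, seed=seed)
    log = simulate_grid_session(0.9, n_selections=60, seed=seed)
    _io.write_session(outdir, Y, X)
    _io.save_lds_params(gt.lds, f"{outdir}/ground_truth_lds.json")
    _io.write_selection_log(log, f"{outdir}/grid_log.tsv")
    return {"n_channels": Y.n_channels, "n_bins": Y.n_bins,
            "n_trials": n_trials, "seed": seed}
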