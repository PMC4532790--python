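"""Diagnostic statistics: dynamics-vs-innovations contribution, forward
prediction captured variance, hold/reach speed ratios, condition averaging,
and grid-task selection metrics (achieved bitrate, success rate, acquire times).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .decoders import causal_gaussian_smooth
from .errors import InputError, NumericalError
from .lds import LDSParams, SpikeCounts, _as_counts, kalman_filter

__all__ = [
    "SelectionLog",
    "EpochMask",
    "dynamics_contribution",
    "captured_variance",
    "forward_prediction_study",
    "condition_average",
    "speed_ratio",
    "grid_bitrate",
    "success_rate",
    "acquire_time_stats",
]

OUTCOMES = ("correct", "incorrect", "timeout")


@dataclass
class SelectionLog:
    """Timestamped grid-task selection events over a session of duration T."""

    events: list[tuple[float, str]]
    duration: float
    n_targets: int = 36

    def __post_init__(self) -> None:
        events = [(float(t), str(o)) for t, o in self.events]
        times = [t for t, _ in events]
        if any(o not in OUTCOMES for _, o in events):
            bad = sorted({o for _, o in events} - set(OUTCOMES))
            raise InputError(f"unknown outcomes {bad}; expected {OUTCOMES}")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise InputError("event times must be strictly increasing")
        if times and (times[0] <= 0 or times[-1] > self.duration + 1e-9):
            raise InputError("event times must lie in (0, duration]")
        if self.n_targets < 2:
            raise InputError("n_targets must be >= 2")
        self.events = events

    def outcome_counts(self) -> dict[str, int]:
        c = {o: 0 for o in OUTCOMES}
        for _, o in self.events:
            c[o] += 1
        return c


@dataclass
class EpochMask:
    """Disjoint hold/reach bin-index sets (0-based)."""

    hold_bins: np.ndarray
    reach_bins: np.ndarray

    def __post_init__(self) -> None:
        self.hold_bins = np.asarray(self.hold_bins, dtype=int)
        self.reach_bins = np.asarray(self.reach_bins, dtype=int)
        if np.intersect1d(self.hold_bins, self.reach_bins).size:
            raise InputError("hold and reach bin sets must be disjoint")

    @classmethod
    def from_labels(cls, epoch_labels: Sequence[str]) -> "EpochMask":
        lab = np.asarray(epoch_labels)
        return cls(np.flatnonzero(lab == "hold"), np.flatnonzero(lab == "reach"))


# ---------------------------------------------------------------------------
# dynamics vs innovations
# ---------------------------------------------------------------------------

def dynamics_contribution(
    params: LDSParams, Y: SpikeCounts | np.ndarray
) -> tuple[float, np.ndarray]:
    """Average contribution of the dynamics process to the state update.

    Runs the exact Kalman filter; for each bin k >= 2 forms the first-order
    dynamics term a = ||(M - I) shat_{k-1}|| and the innovations term
    b = ||K_k (y_k - P M shat_{k-1})||, and the ratio rho_k = a / (a + b).
    Returns (mean over non-degenerate bins, per-bin sequence).
    """
    Y = _as_counts(Y)
    if Y.n_bins < 2:
        raise InputError("need at least 2 bins")
    fr = kalman_filter(params, Y, mode="exact")
    MI = params.M - np.eye(params.d)
    a = np.linalg.norm(MI @ fr.shat[:, :-1], axis=0)
    upd = np.einsum("dnk,nk->dk", fr.gains[:, :, 1:], fr.innovations[:, 1:])
    b = np.linalg.norm(upd, axis=0)
    tot = a + b
    valid = tot > 0
    if not valid.any():
        raise NumericalError("all bins degenerate (zero dynamics and innovation "
                             "contributions)")
    rho = np.full(a.shape, np.nan)
    rho[valid] = a[valid] / tot[valid]
    return float(np.nanmean(rho)), rho


# ---------------------------------------------------------------------------
# forward prediction
# ---------------------------------------------------------------------------

def captured_variance(Y_true: np.ndarray, Y_pred: np.ndarray) -> float:
    """Fraction of variance captured: 1 - SSE / SST, pooled over channels and time.

    SST is taken around the per-channel temporal mean; the result may be
    negative for predictors worse than the channel means.
    """
    Yt = np.atleast_2d(np.asarray(Y_true, dtype=float))
    Yp = np.atleast_2d(np.asarray(Y_pred, dtype=float))
    if Yt.shape != Yp.shape:
        raise InputError(f"shape mismatch {Yt.shape} vs {Yp.shape}")
    sse = float(np.sum((Yt - Yp) ** 2))
    sst = float(np.sum((Yt - Yt.mean(axis=1, keepdims=True)) ** 2))
    if sst == 0.0:
        raise NumericalError("total variance is zero; captured variance undefined")
    return 1.0 - sse / sst


def forward_prediction_study(
    Y: SpikeCounts | np.ndarray,
    params_single: LDSParams,
    params_condavg: LDSParams | None = None,
    kernel_sd: float = 0.100,
) -> dict[str, float]:
    """Captured variance of y_k under three one-step-ahead predictors.

    ``smoothing``: the causally smoothed counts at bin k-1;
    ``lds_single``: P M shat_{k-1} with the single-trial LDS filtered on Y;
    ``lds_condavg``: the same using dynamics learned from condition-averaged
    data (omitted when ``params_condavg`` is None).  All predictors are scored
    on bins 2..K.
    """
    Y = _as_counts(Y)
    if Y.n_bins < 2:
        raise InputError("need at least 2 bins")
    truth = Y.counts[:, 1:]
    out: dict[str, float] = {}

    smoothed = causal_gaussian_smooth(Y, kernel_sd)
    out["smoothing"] = captured_variance(truth, smoothed[:, :-1])

    for name, par in (("lds_single", params_single), ("lds_condavg", params_condavg)):
        if par is None:
            continue
        fr = kalman_filter(par, Y, mode="exact")
        pred = par.P @ (par.M @ fr.shat[:, :-1])
        out[name] = captured_variance(truth, pred)
    return out


def condition_average(
    Y: SpikeCounts | np.ndarray,
    condition_ids: Sequence,
    trial_ids: Sequence,
) -> SpikeCounts:
    """Average counts across trials of each condition at trial-aligned bins.

    Trials of a condition are truncated to the shortest trial before averaging;
    the per-condition averages are concatenated in sorted condition order.
    """
    Y = _as_counts(Y)
    cond = np.asarray(condition_ids)
    trial = np.asarray(trial_ids)
    if cond.shape != (Y.n_bins,) or trial.shape != (Y.n_bins,):
        raise InputError("condition_ids and trial_ids must have one entry per bin")
    pieces = []
    for c in np.unique(cond):
        sel = cond == c
        tids = np.unique(trial[sel])
        segs = []
        for t in tids:
            idx = np.flatnonzero(sel & (trial == t))
            if idx.size:
                segs.append(Y.counts[:, idx])
        if not segs:
            raise InputError(f"condition {c!r} has no trials")
        kmin = min(s.shape[1] for s in segs)
        pieces.append(np.mean([s[:, :kmin] for s in segs], axis=0))
    return SpikeCounts(np.concatenate(pieces, axis=1), bin_width=Y.bin_width,
                       channel_ids=Y.channel_ids)


# ---------------------------------------------------------------------------
# epoch speed ratios
# ---------------------------------------------------------------------------

def speed_ratio(
    signal: np.ndarray,
    mask: EpochMask,
    mode: str = "observed_diff",
    M: np.ndarray | None = None,
) -> float:
    """Hold-to-reach ratio of mean per-bin speeds.

    ``observed_diff``: speed at bin k is ||signal_{k+1} - signal_k|| (bins whose
    successor falls outside the series are dropped).  ``model_state``: the
    first-order model-predicted speed ||(M - I) signal_k|| on filtered states;
    requires ``M``.
    """
    sig = np.atleast_2d(np.asarray(signal, dtype=float))
    K = sig.shape[1]
    if mask.hold_bins.size == 0 or mask.reach_bins.size == 0:
        raise InputError("both hold and reach epochs must be non-empty")
    if mode == "observed_diff":
        speeds = np.linalg.norm(np.diff(sig, axis=1), axis=0)  # speed at bin k
        valid = K - 1
        hold = mask.hold_bins[mask.hold_bins < valid]
        reach = mask.reach_bins[mask.reach_bins < valid]
        if hold.size == 0 or reach.size == 0:
            raise InputError("epoch bins have no valid successors")
    elif mode == "model_state":
        if M is None:
            raise InputError("model_state mode requires the dynamics matrix M")
        MI = np.asarray(M, dtype=float) - np.eye(sig.shape[0])
        speeds = np.linalg.norm(MI @ sig, axis=0)
        hold, reach = mask.hold_bins, mask.reach_bins
    else:
        raise InputError(f"unknown mode {mode!r}")
    denom = float(speeds[reach].mean())
    if denom == 0.0:
        raise NumericalError("mean reach-epoch speed is zero; ratio undefined")
    return float(speeds[hold].mean()) / denom


# ---------------------------------------------------------------------------
# grid-task selection metrics
# ---------------------------------------------------------------------------

def grid_bitrate(log: SelectionLog) -> float:
    """Achieved bitrate max(0, c - l) * log2(n_targets) / T in bits per second.

    Timeouts contribute to T only; a session with c <= l conveys 0 b.p.s.
    """
    if log.duration <= 0:
        raise InputError("session duration must be positive")
    counts = log.outcome_counts()
    net = counts["correct"] - counts["incorrect"]
    return max(0, net) * float(np.log2(log.n_targets)) / log.duration


def success_rate(log: SelectionLog) -> float:
    """Fraction of events that were correct selections (timeouts count against)."""
    counts = log.outcome_counts()
    total = sum(counts.values())
    if total == 0:
        raise InputError("empty selection log")
    return counts["correct"] / total


def acquire_time_stats(log: SelectionLog, lockout: float = 0.200) -> dict[str, float]:
    """Summary of target acquire times: inter-event intervals minus the lockout.

    Timeout events are excluded from the acquire-time distribution (no target
    was selected); the first interval is measured from time 0.
    """
    if not log.events:
        raise InputError("empty selection log")
    times = np.asarray([t for t, _ in log.events])
    outcomes = [o for _, o in log.events]
    intervals = np.diff(np.concatenate([[0.0], times]))
    acq = np.asarray(
        [iv - lockout for iv, o in zip(intervals, outcomes) if o != "timeout"]
    )
    if acq.size == 0:
        raise InputError("no non-timeout events in selection log")
    return {
        "n": int(acq.size),
        "mean_s": float(acq.mean()),
        "median_s": float(np.median(acq)),
        "min_s": float(acq.min()),
        "max_s": float(acq.max()),
    }
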