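"""Delimited-text and JSON serialization for sessions, models and logs.

A session directory holds ``counts.tsv`` (rows = channels, columns = bins,
'#'-prefixed header with bin_width/dtype/channel_ids) and ``kinematics.tsv``
(one row per bin).  Decoder models and LDS parameters are JSON documents with
a ``format_version`` string and, for decoders, a ``decoder_type`` tag.
"""

from __future__ import annotations

import json
import os
from typing import Any

import numpy as np

from .decoders import (
    KinematicsSeries,
    KKFModel,
    NDFModel,
    OLEModel,
    PCSmoothModel,
    WFModel,
)
from .errors import InputError
from .lds import LDSParams, SpikeCounts
from .metrics import OUTCOMES, SelectionLog

__all__ = [
    "read_session",
    "write_session",
    "read_counts",
    "write_counts",
    "read_kinematics",
    "write_kinematics",
    "save_model",
    "load_model",
    "save_lds_params",
    "load_lds_params",
    "write_selection_log",
    "read_selection_log",
]

FORMAT_VERSION = "1"


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def write_counts(Y: SpikeCounts, path: str, dtype: str = "auto") -> None:
    """Write a counts table.  ``dtype`` 'int' writes integers (and requires
    integer-valued counts); 'float' writes full precision; 'auto' picks."""
    c = Y.counts
    if dtype == "auto":
        dtype = "int" if np.all(c == np.round(c)) else "float"
    if dtype not in ("int", "float"):
        raise InputError(f"unknown dtype {dtype!r}")
    if dtype == "int" and not np.all(c == np.round(c)):
        raise InputError("cannot write non-integer counts with dtype=int")
    ids = Y.channel_ids or [f"ch{i:03d}" for i in range(Y.n_channels)]
    with open(path, "w") as fh:
        fh.write(f"# ndfkit-counts v{FORMAT_VERSION}\n")
        fh.write(f"# bin_width\t{Y.bin_width!r}\n")
        fh.write(f"# dtype\t{dtype}\n")
        fh.write("# channel_ids\t" + "\t".join(ids) + "\n")
        fmt = "%d" if dtype == "int" else "%.17g"
        np.savetxt(fh, c, fmt=fmt, delimiter="\t")


def read_counts(path: str) -> SpikeCounts:
    """Read a counts table; validates the header and, for integer files,
    integer-valued non-negative entries (errors name the offending line)."""
    header: dict[str, Any] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if len(parts) >= 2:
                    header[parts[0]] = parts[1:]
                continue
            try:
                rows.append(np.asarray([float(v) for v in line.split("\t")]))
            except ValueError:
                raise InputError(f"{path}:{lineno}: unparseable counts row") from None
            if header.get("dtype", ["float"])[0] == "int":
                r = rows[-1]
                if not np.all(r == np.round(r)):
                    raise InputError(f"{path}:{lineno}: non-integer count in "
                                     "integer-typed counts file")
                if (r < 0).any():
                    raise InputError(f"{path}:{lineno}: negative count")
    if "bin_width" not in header:
        raise InputError(f"{path}: missing bin_width header")
    if not rows:
        raise InputError(f"{path}: no count rows")
    widths = {r.size for r in rows}
    if len(widths) != 1:
        raise InputError(f"{path}: ragged rows (bin counts {sorted(widths)})")
    ids = header.get("channel_ids")
    if ids is not None and len(ids) != len(rows):
        raise InputError(f"{path}: {len(ids)} channel_ids for {len(rows)} rows")
    return SpikeCounts(np.vstack(rows), bin_width=float(header["bin_width"][0]),
                       channel_ids=ids)


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

_KIN_COLS = ("bin", "pos_x", "pos_y", "vel_x", "vel_y",
             "epoch", "trial_id", "condition_id")


def write_kinematics(X: KinematicsSeries, path: str) -> None:
    K = X.n_bins
    epochs = X.epoch_labels if X.epoch_labels is not None else ["other"] * K
    trials = X.trial_ids if X.trial_ids is not None else [-1] * K
    conds = X.condition_ids if X.condition_ids is not None else [-1] * K
    with open(path, "w") as fh:
        fh.write(f"# ndfkit-kinematics v{FORMAT_VERSION}\n")
        fh.write(f"# bin_width\t{X.bin_width!r}\n")
        fh.write("\t".join(_KIN_COLS) + "\n")
        for k in range(K):
            fh.write(
                f"{k + 1}\t{X.pos[0, k]:.9g}\t{X.pos[1, k]:.9g}"
                f"\t{X.vel[0, k]:.9g}\t{X.vel[1, k]:.9g}"
                f"\t{epochs[k]}\t{trials[k]}\t{conds[k]}\n"
            )


def read_kinematics(path: str) -> KinematicsSeries:
    header: dict[str, Any] = {}
    data: list[list[str]] = []
    saw_cols = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if len(parts) >= 2:
                    header[parts[0]] = parts[1]
                continue
            cells = line.split("\t")
            if not saw_cols:
                if tuple(cells) != _KIN_COLS:
                    raise InputError(f"{path}:{lineno}: unexpected column header")
                saw_cols = True
                continue
            if len(cells) != len(_KIN_COLS):
                raise InputError(f"{path}:{lineno}: expected {len(_KIN_COLS)} "
                                 f"columns, got {len(cells)}")
            data.append(cells)
    if "bin_width" not in header:
        raise InputError(f"{path}: missing bin_width header")
    if not data:
        raise InputError(f"{path}: no kinematics rows")
    arr = np.asarray([[float(r[i]) for i in range(1, 5)] for r in data]).T
    return KinematicsSeries(
        pos=arr[:2], vel=arr[2:], bin_width=float(header["bin_width"]),
        epoch_labels=np.asarray([r[5] for r in data], dtype=object),
        trial_ids=np.asarray([int(r[6]) for r in data]),
        condition_ids=np.asarray([int(r[7]) for r in data]),
    )


def write_session(outdir: str, Y: SpikeCounts, X: KinematicsSeries | None = None,
                  dtype: str = "auto") -> None:
    os.makedirs(outdir, exist_ok=True)
    write_counts(Y, os.path.join(outdir, "counts.tsv"), dtype=dtype)
    if X is not None:
        write_kinematics(X, os.path.join(outdir, "kinematics.tsv"))


def read_session(path: str) -> tuple[SpikeCounts, KinematicsSeries | None]:
    Y = read_counts(os.path.join(path, "counts.tsv"))
    kin_path = os.path.join(path, "kinematics.tsv")
    X = read_kinematics(kin_path) if os.path.exists(kin_path) else None
    if X is not None and X.n_bins != Y.n_bins:
        raise InputError(
            f"{path}: counts have {Y.n_bins} bins but kinematics {X.n_bins}"
        )
    return Y, X


# ---------------------------------------------------------------------------
# model serialization
# ---------------------------------------------------------------------------

def _arr(a: np.ndarray) -> list:
    return np.asarray(a, dtype=float).tolist()


def _lds_to_dict(p: LDSParams) -> dict:
    return {
        "M": _arr(p.M), "P": _arr(p.P), "Ncov": _arr(p.Ncov), "R": _arr(p.R),
        "pi1": _arr(p.pi1), "S1": _arr(p.S1), "bin_width": p.bin_width,
    }


def _lds_from_dict(d: dict) -> LDSParams:
    try:
        return LDSParams(
            M=np.asarray(d["M"]), P=np.asarray(d["P"]), Ncov=np.asarray(d["Ncov"]),
            R=np.asarray(d["R"]), pi1=np.asarray(d["pi1"]), S1=np.asarray(d["S1"]),
            bin_width=float(d["bin_width"]),
        )
    except KeyError as e:
        raise InputError(f"LDS document missing field {e.args[0]!r}") from None


def save_lds_params(params: LDSParams, path: str) -> None:
    doc = {"format_version": FORMAT_VERSION, "kind": "lds_params",
           **_lds_to_dict(params)}
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_lds_params(path: str) -> LDSParams:
    with open(path) as fh:
        doc = json.load(fh)
    _check_version(doc, path)
    return _lds_from_dict(doc)


def save_model(model, path: str) -> None:
    """Serialize any fitted decoder model to a JSON document."""
    doc: dict[str, Any] = {"format_version": FORMAT_VERSION,
                           "decoder_type": model.decoder_type}
    if isinstance(model, NDFModel):
        doc.update(lds=_lds_to_dict(model.lds), L=_arr(model.L),
                   bias=_arr(model.bias))
    elif isinstance(model, OLEModel):
        doc.update(L=_arr(model.L), bias=_arr(model.bias),
                   kernel_sd=model.kernel_sd)
    elif isinstance(model, WFModel):
        doc.update(L_blocks=_arr(model.L_blocks), bias=_arr(model.bias),
                   lam=model.lam)
    elif isinstance(model, KKFModel):
        doc.update(A=_arr(model.A), C=_arr(model.C), W=_arr(model.W),
                   Q=_arr(model.Q), velocity_only=model.velocity_only)
    elif isinstance(model, PCSmoothModel):
        doc.update(components=_arr(model.components), mean=_arr(model.mean),
                   L=_arr(model.L), bias=_arr(model.bias),
                   kernel_sd=model.kernel_sd)
    else:
        raise InputError(f"cannot serialize {type(model).__name__}")
    with open(path, "w") as fh:
        json.dump(doc, fh)


def _check_version(doc: dict, path: str) -> None:
    v = doc.get("format_version")
    if v != FORMAT_VERSION:
        raise InputError(f"{path}: unsupported format_version {v!r} "
                         f"(expected {FORMAT_VERSION!r})")


def load_model(path: str):
    """Load a decoder model, dispatching on its decoder_type tag."""
    with open(path) as fh:
        doc = json.load(fh)
    _check_version(doc, path)
    kind = doc.get("decoder_type")
    try:
        if kind == "ndf":
            return NDFModel(lds=_lds_from_dict(doc["lds"]),
                            L=np.asarray(doc["L"]), bias=np.asarray(doc["bias"]))
        if kind == "ole":
            return OLEModel(L=np.asarray(doc["L"]), bias=np.asarray(doc["bias"]),
                            kernel_sd=float(doc["kernel_sd"]))
        if kind == "wf":
            return WFModel(L_blocks=np.asarray(doc["L_blocks"]),
                           bias=np.asarray(doc["bias"]), lam=float(doc["lam"]))
        if kind == "kkf":
            return KKFModel(A=np.asarray(doc["A"]), C=np.asarray(doc["C"]),
                            W=np.asarray(doc["W"]), Q=np.asarray(doc["Q"]),
                            velocity_only=bool(doc["velocity_only"]))
        if kind == "pcsmooth":
            return PCSmoothModel(components=np.asarray(doc["components"]),
                                 mean=np.asarray(doc["mean"]),
                                 L=np.asarray(doc["L"]),
                                 bias=np.asarray(doc["bias"]),
                                 kernel_sd=float(doc["kernel_sd"]))
    except KeyError as e:
        raise InputError(f"{path}: model document missing field "
                         f"{e.args[0]!r}") from None
    raise InputError(f"{path}: unknown decoder_type {kind!r}")


# ---------------------------------------------------------------------------
# selection logs
# ---------------------------------------------------------------------------

def write_selection_log(log: SelectionLog, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# ndfkit-selection-log v{FORMAT_VERSION}\n")
        fh.write(f"# duration\t{log.duration!r}\n")
        fh.write(f"# n_targets\t{log.n_targets}\n")
        fh.write("time_s\toutcome\n")
        for t, o in log.events:
            fh.write(f"{t!r}\t{o}\n")


def read_selection_log(path: str) -> SelectionLog:
    header: dict[str, str] = {}
    events: list[tuple[float, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if len(parts) >= 2:
                    header[parts[0]] = parts[1]
                continue
            cells = line.split("\t")
            if cells[0] == "time_s":
                continue
            if len(cells) != 2 or cells[1] not in OUTCOMES:
                raise InputError(f"{path}:{lineno}: malformed event row")
            events.append((float(cells[0]), cells[1]))
    if "duration" not in header:
        raise InputError(f"{path}: missing duration header")
    return SelectionLog(events=events, duration=float(header["duration"]),
                        n_targets=int(header.get("n_targets", 36)))
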