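"""Shared data model and on-disk artifacts.

Containers for microelectrode-array recordings and the derived event/fit
tables, plus HDF5/CSV round-trip IO.  Conventions used throughout the
package:

* electrode coordinates are 0-based ``(row, col)`` with ``x = col * pitch``
  and ``y = row * pitch`` in millimetres; angles are counter-clockwise from
  the +x axis and stored in radians on ``[0, 2*pi)``
* times are seconds (64-bit floats on disk); plane-fit gradients are
  ms/mm, so a gradient norm ``g`` maps to speed ``100 / g`` cm/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from enum import Enum
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ArrayGeometry",
    "Recording",
    "IEDEvent",
    "WaveFit",
    "VonMisesMixtureFit",
    "SeizureCharacterization",
    "FormatError",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "wrap_angle",
]

TWO_PI = 2.0 * np.pi


def wrap_angle(theta):
    """Map angles (radians) onto the half-open interval [0, 2*pi)."""
    wrapped = np.mod(theta, TWO_PI)
    # mod can return 2*pi for tiny negative inputs due to rounding
    return np.where(wrapped >= TWO_PI, 0.0, wrapped) if np.ndim(theta) else (
        0.0 if wrapped >= TWO_PI else float(wrapped)
    )


class FormatError(ValueError):
    """A file is missing a required dataset or has an inconsistent layout."""


@dataclass(frozen=True)
class ArrayGeometry:
    """Regular electrode grid (default Utah-style 10x10, 400 um pitch)."""

    n_rows: int = 10
    n_cols: int = 10
    pitch_mm: float = 0.4
    bad_channels: frozenset[int] = frozenset()

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols

    def positions(self) -> np.ndarray:
        """(n_channels, 2) array of (x_mm, y_mm); channel = row * n_cols + col."""
        rows, cols = np.divmod(np.arange(self.n_channels), self.n_cols)
        return np.column_stack([cols * self.pitch_mm, rows * self.pitch_mm]).astype(float)

    def good_channels(self) -> np.ndarray:
        mask = np.ones(self.n_channels, dtype=bool)
        for ch in self.bad_channels:
            mask[ch] = False
        return np.flatnonzero(mask)


@dataclass
class Recording:
    """Multichannel LFP + per-channel multiunit event times.

    ``lfp`` is channels x samples in microvolts; ``mua_times`` holds one
    sorted array of event times (seconds) per channel; ``annotations`` is a
    list of ``(label, t0, t1)`` labelled intervals (e.g. seizure bounds,
    ``secondary_generalization`` onset).
    """

    lfp: np.ndarray
    fs_hz: float
    geometry: ArrayGeometry
    mua_times: list[np.ndarray] = field(default_factory=list)
    annotations: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self):
        self.lfp = np.asarray(self.lfp)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.lfp.shape[0] != self.geometry.n_channels:
            raise ValueError(
                f"lfp has {self.lfp.shape[0]} rows but geometry defines "
                f"{self.geometry.n_channels} channels"
            )
        if not self.mua_times:
            self.mua_times = [np.empty(0) for _ in range(self.geometry.n_channels)]
        self.mua_times = [np.sort(np.asarray(t, dtype=float)) for t in self.mua_times]
        dur = self.duration_s
        for ch, t in enumerate(self.mua_times):
            if t.size and (t[0] < 0 or t[-1] > dur):
                raise ValueError(f"mua_times on channel {ch} outside [0, {dur:.3f}] s")

    @property
    def duration_s(self) -> float:
        return self.lfp.shape[1] / self.fs_hz

    def annotation(self, label: str) -> tuple[float, float] | None:
        for lab, t0, t1 in self.annotations:
            if lab == label:
                return (t0, t1)
        return None


class QAReason(str, Enum):
    ok = "ok"
    amplitude_outlier = "amplitude_outlier"
    too_few_channels = "too_few_channels"


@dataclass
class IEDEvent:
    """One detected interictal discharge (array-wide consensus event)."""

    event_time_s: float
    channel_peak_times_s: dict[int, float]
    channel_amplitudes_uv: dict[int, float]
    n_detecting_channels: int
    qa_pass: bool = True
    qa_reason: str = QAReason.ok.value


@dataclass
class WaveFit:
    """Plane fit to per-channel event timings.

    ``beta_x/beta_y`` are the delay-gradient components in ms/mm; the wave
    travels along the gradient at ``speed_cm_s = 100 / ||(bx, by)||``.
    """

    beta_x_ms_per_mm: float
    beta_y_ms_per_mm: float
    intercept_ms: float
    speed_cm_s: float
    direction_rad: float
    p_value: float = np.nan
    n_permutations: int = 0
    is_traveling: bool = False
    n_points: int = 0
    fit_kind: str = "ied_lfp"
    r_squared: float = np.nan
    event_time_s: float = np.nan

    @property
    def speed_mm_s(self) -> float:
        """Speed in mm/s (the natural unit for the slow ictal wavefront)."""
        return self.speed_cm_s * 10.0


@dataclass
class VonMisesMixtureFit:
    """Fitted one- or two-component von Mises mixture over directions."""

    h: int
    mu_h: list[float]
    kappa_h: list[float]
    theta_h: list[float]
    assignments: np.ndarray
    log_likelihood: float
    converged: bool = True
    bimodality_index: float | None = None
    is_bimodal: bool | None = None


@dataclass
class SeizureCharacterization:
    """Recruited/penumbral classification with its supporting fits."""

    iw_fit: WaveFit | None
    sd_fits: list[WaveFit]
    phase_lock_p: float
    seizure_class: str
    analysis_end_s: float


# ---------------------------------------------------------------------------
# HDF5 recording IO
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, path) -> None:
    """Write a Recording to HDF5 (layout: /lfp, /fs_hz, /geometry, /mua, /annotations)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("lfp", data=rec.lfp.astype(np.float32))
        f.create_dataset("fs_hz", data=float(rec.fs_hz))
        geo = f.create_group("geometry")
        geo.create_dataset("positions", data=rec.geometry.positions())
        geo.create_dataset(
            "bad_channels", data=np.array(sorted(rec.geometry.bad_channels), dtype=np.int64)
        )
        geo.attrs["n_rows"] = rec.geometry.n_rows
        geo.attrs["n_cols"] = rec.geometry.n_cols
        geo.attrs["pitch_mm"] = rec.geometry.pitch_mm
        mua = f.create_group("mua")
        for ch, t in enumerate(rec.mua_times):
            mua.create_dataset(f"ch{ch}", data=np.asarray(t, dtype=np.float64))
        ann = f.create_group("annotations")
        labels = [a[0] for a in rec.annotations]
        ann.create_dataset("label", data=np.array(labels, dtype=h5py.string_dtype()))
        ann.create_dataset("t0", data=np.array([a[1] for a in rec.annotations], dtype=np.float64))
        ann.create_dataset("t1", data=np.array([a[2] for a in rec.annotations], dtype=np.float64))


def read_recording(path) -> Recording:
    """Read a Recording written by :func:`write_recording`."""
    with h5py.File(path, "r") as f:
        for name in ("lfp", "fs_hz", "geometry"):
            if name not in f:
                raise FormatError(f"recording file {path} is missing dataset '/{name}'")
        lfp = f["lfp"][()]
        fs = float(f["fs_hz"][()])
        geo = f["geometry"]
        geometry = ArrayGeometry(
            n_rows=int(geo.attrs["n_rows"]),
            n_cols=int(geo.attrs["n_cols"]),
            pitch_mm=float(geo.attrs["pitch_mm"]),
            bad_channels=frozenset(int(c) for c in geo["bad_channels"][()]),
        )
        n_ch = geometry.n_channels
        mua = [np.empty(0)] * n_ch
        if "mua" in f:
            for ch in range(n_ch):
                key = f"ch{ch}"
                if key in f["mua"]:
                    mua[ch] = f["mua"][key][()]
        annotations = []
        if "annotations" in f and "label" in f["annotations"]:
            labels = [s.decode() if isinstance(s, bytes) else str(s)
                      for s in f["annotations"]["label"][()]]
            t0 = f["annotations"]["t0"][()]
            t1 = f["annotations"]["t1"][()]
            annotations = [(lab, float(a), float(b)) for lab, a, b in zip(labels, t0, t1)]
    return Recording(lfp=lfp, fs_hz=fs, geometry=geometry, mua_times=mua,
                     annotations=annotations)


# ---------------------------------------------------------------------------
# CSV event/fit tables
# ---------------------------------------------------------------------------

_IED_COLUMNS = [
    "event_time_s", "n_detecting_channels", "qa_pass", "qa_reason",
    "channel_peak_times_s", "channel_amplitudes_uv",
]
_WAVE_COLUMNS = [
    "event_time_s", "fit_kind", "beta_x_ms_per_mm", "beta_y_ms_per_mm",
    "intercept_ms", "speed_cm_s", "direction_rad", "p_value",
    "n_permutations", "is_traveling", "n_points", "r_squared",
]


def _encode_map(d: dict[int, float]) -> str:
    return ";".join(f"{k}:{v!r}" for k, v in sorted(d.items()))


def _decode_map(s: str) -> dict[int, float]:
    if not isinstance(s, str) or not s:
        return {}
    out = {}
    for item in s.split(";"):
        k, v = item.split(":")
        out[int(k)] = float(v)
    return out


def write_events(events: Sequence, path) -> None:
    """Write a homogeneous list of IEDEvent or WaveFit records to CSV."""
    kinds = {type(e).__name__ for e in events}
    if len(kinds) > 1:
        raise ValueError(f"mixed record kinds in write_events: {sorted(kinds)}")
    kind = kinds.pop() if kinds else "IEDEvent"
    if kind == "IEDEvent":
        rows = [{
            "event_time_s": e.event_time_s,
            "n_detecting_channels": e.n_detecting_channels,
            "qa_pass": e.qa_pass,
            "qa_reason": e.qa_reason,
            "channel_peak_times_s": _encode_map(e.channel_peak_times_s),
            "channel_amplitudes_uv": _encode_map(e.channel_amplitudes_uv),
        } for e in events]
        df = pd.DataFrame(rows, columns=_IED_COLUMNS)
    elif kind == "WaveFit":
        df = pd.DataFrame(
            [{c: getattr(e, c) for c in _WAVE_COLUMNS} for e in events],
            columns=_WAVE_COLUMNS,
        )
    else:
        raise ValueError(f"unsupported record kind {kind}")
    df.to_csv(path, index=False, float_format="%.17g")


def read_events(path, kind: str = "auto") -> list:
    """Read an event/fit CSV back into IEDEvent or WaveFit records."""
    df = pd.read_csv(path)
    if kind == "auto":
        kind = "WaveFit" if "beta_x_ms_per_mm" in df.columns else "IEDEvent"
    out = []
    if kind == "IEDEvent":
        for _, r in df.iterrows():
            out.append(IEDEvent(
                event_time_s=float(r["event_time_s"]),
                channel_peak_times_s=_decode_map(r.get("channel_peak_times_s", "")),
                channel_amplitudes_uv=_decode_map(r.get("channel_amplitudes_uv", "")),
                n_detecting_channels=int(r["n_detecting_channels"]),
                qa_pass=bool(r["qa_pass"]),
                qa_reason=str(r["qa_reason"]),
            ))
    else:
        for _, r in df.iterrows():
            out.append(WaveFit(
                beta_x_ms_per_mm=float(r["beta_x_ms_per_mm"]),
                beta_y_ms_per_mm=float(r["beta_y_ms_per_mm"]),
                intercept_ms=float(r["intercept_ms"]),
                speed_cm_s=float(r["speed_cm_s"]),
                direction_rad=float(r["direction_rad"]),
                p_value=float(r["p_value"]),
                n_permutations=int(r["n_permutations"]),
                is_traveling=bool(r["is_traveling"]),
                n_points=int(r["n_points"]),
                fit_kind=str(r["fit_kind"]),
                r_squared=float(r["r_squared"]),
                event_time_s=float(r["event_time_s"]),
            ))
    return out
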