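"""Synthetic microelectrode-array recordings with known ground truth.

Generates the statistical structure the analysis assumes so every stage can
be validated: interictal discharges as planar traveling LFP deflections
whose directions follow a one- or two-component von Mises mixture and whose
speeds are log-normal (tens of cm/s); trough-locked Poisson multiunit
spiking; band-limited Gaussian background noise (per-channel plus a
common-mode term); and seizures that are either 'recruited' (slow planar
ictal wavefront of tonic firing followed by fast, phase-locked seizure
discharges) or 'penumbral' (seizure-like field rhythm with unmodulated
firing).

Everything is deterministic given (spec, seed); every planted event is
listed in the returned ground-truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .core_io import ArrayGeometry, Recording, wrap_angle

__all__ = [
    "DirectionModel",
    "IEDSimSpec",
    "SeizureSimSpec",
    "sample_vmm",
    "synth_ied_recording",
    "synth_seizure_recording",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class DirectionModel:
    """Von Mises mixture over propagation directions (h <= 2 components)."""

    mu: tuple[float, ...] = (np.pi,)
    kappa: tuple[float, ...] = (4.0,)
    weights: tuple[float, ...] = (1.0,)

    def __post_init__(self):
        if len(self.mu) != len(self.kappa) or len(self.mu) != len(self.weights):
            raise ValueError("mu, kappa, weights must have equal length")
        if any(k < 0 for k in self.kappa):
            raise ValueError("kappa must be >= 0")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    @staticmethod
    def antipodal(mu_deg: float = 180.0, separation_deg: float = 177.9,
                  kappa: float = 4.0, dominant_weight: float = 0.7
                  ) -> "DirectionModel":
        """Antipodally bimodal model (dominant + auxiliary mode)."""
        mu1 = np.deg2rad(mu_deg)
        mu2 = wrap_angle(mu1 + np.deg2rad(separation_deg))
        return DirectionModel(mu=(mu1, mu2), kappa=(kappa, kappa),
                              weights=(dominant_weight, 1.0 - dominant_weight))


def sample_vmm(model: DirectionModel, n: int, seed=None) -> np.ndarray:
    """Draw n angles in [0, 2*pi) from a von Mises mixture."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(model.weights), size=n, p=np.asarray(model.weights))
    out = np.empty(n)
    for k in range(len(model.weights)):
        m = comp == k
        if m.any():
            out[m] = rng.vonmises(model.mu[k], model.kappa[k], size=int(m.sum()))
    return np.asarray(wrap_angle(out))


@dataclass(frozen=True)
class IEDSimSpec:
    """Simulation parameters for an interictal recording segment.

    Inter-event spacing is compressed relative to clinical IED rates
    (~0.4/min) so that desk-scale segments carry enough events; per-event
    statistics are unaffected as long as events stay separated by much
    more than the 250 ms consensus window.
    """

    n_ieds: int = 100
    rate_per_min: float = 10.0
    direction_model: DirectionModel = field(default_factory=DirectionModel.antipodal)
    speed_median_cm_s: float = 50.0
    speed_sigma: float = 0.4
    trough_width_ms: float = 20.0
    slow_wave_width_ms: float = 150.0
    slow_wave_rel_amp: float = 0.4
    snr: float = 12.0              # band-limited trough amplitude / noise band SD
    noise_sd_uv: float = 30.0
    common_mode_weight: float = 0.2
    trough_amp_uv: float = 500.0   # used directly when noise_sd_uv == 0
    mua_per_ied: float = 3.0       # expected locked spikes per channel per IED
    mua_jitter_ms: float = 5.0
    mua_background_hz: float = 0.5
    fs_hz: float = 500.0

    def __post_init__(self):
        if self.snr <= 0:
            raise ValueError("snr must be positive")


def _template(t_s: np.ndarray, trough_amp: float, trough_w_s: float,
              slow_w_s: float, slow_rel: float) -> np.ndarray:
    """Biphasic IED waveform: sharp negative trough then a slow positive wave.

    Widths are FWHM of the Gaussian lobes; the sharp 20 ms trough puts the
    dominant power in the 20-40 Hz band the detector filters for.
    """
    s1 = trough_w_s / 2.355
    s2 = slow_w_s / 2.355
    delay = trough_w_s + slow_w_s / 2.0
    return (-trough_amp * np.exp(-0.5 * (t_s / s1) ** 2)
            + slow_rel * trough_amp * np.exp(-0.5 * ((t_s - delay) / s2) ** 2))


def _band_gain(spec: IEDSimSpec, fs: float = 400.0) -> float:
    """Peak 20-40 Hz band amplitude of the unit-trough template."""
    t = np.arange(-1.0, 1.0, 1.0 / fs)
    y = _template(t, 1.0, spec.trough_width_ms / 1e3,
                  spec.slow_wave_width_ms / 1e3, spec.slow_wave_rel_amp)
    sos = signal.butter(4, [20.0, 40.0], btype="bandpass", fs=fs, output="sos")
    return float(np.max(np.abs(signal.sosfiltfilt(sos, y))))


def _background_noise(rng, n_channels: int, n_samples: int, fs: float,
                      sd_uv: float, common_weight: float) -> np.ndarray:
    """Low-passed (100 Hz) Gaussian noise, per channel plus common mode."""
    lfp = np.zeros((n_channels, n_samples), dtype=np.float32)
    if sd_uv <= 0:
        return lfp
    sos = signal.butter(4, min(100.0, 0.45 * fs), btype="low", fs=fs, output="sos")
    common = signal.sosfiltfilt(sos, rng.standard_normal(n_samples))
    common /= np.std(common)
    for ch in range(n_channels):
        x = signal.sosfiltfilt(sos, rng.standard_normal(n_samples))
        x /= np.std(x)
        lfp[ch] = sd_uv * (x + common_weight * common) / np.sqrt(1 + common_weight**2)
    return lfp


def _planar_delays(positions: np.ndarray, direction_rad: float,
                   speed_cm_s: float) -> np.ndarray:
    """Per-channel delay (s) of a plane wave crossing the array center."""
    if speed_cm_s <= 0:
        raise ValueError("planted speed must be positive")
    center = positions.mean(axis=0)
    proj_mm = ((positions - center)
               @ np.array([np.cos(direction_rad), np.sin(direction_rad)]))
    return proj_mm / (10.0 * speed_cm_s)  # mm / (mm/s)


def synth_ied_recording(geometry: ArrayGeometry, spec: IEDSimSpec,
                        duration_s: float | None = None, seed=None
                        ) -> tuple[Recording, pd.DataFrame]:
    """Simulate an interictal segment with planted traveling IEDs.

    Each IED places the biphasic template on every channel with trough at
    ``t0 + (x cos(phi) + y sin(phi)) / v`` and plants trough-locked Poisson
    MUA.  Returns the recording and a ground-truth table with one row
    (t0, direction_rad, speed_cm_s) per planted event.
    """
    rng = np.random.default_rng(seed)
    if duration_s is None:
        duration_s = max(20.0, 60.0 * spec.n_ieds / spec.rate_per_min)
    if spec.n_ieds > 0 and duration_s < 60.0 * spec.n_ieds / spec.rate_per_min:
        raise ValueError("duration too short for n_ieds at rate_per_min")
    fs = spec.fs_hz
    n_samples = int(round(duration_s * fs))
    positions = geometry.positions()
    n_ch = geometry.n_channels

    lfp = _background_noise(rng, n_ch, n_samples, fs, spec.noise_sd_uv,
                            spec.common_mode_weight)

    # trough amplitude: snr is expressed in the detector's 20-40 Hz band
    if spec.noise_sd_uv > 0:
        sos = signal.butter(4, [20.0, 40.0], btype="bandpass", fs=fs, output="sos")
        band = signal.sosfiltfilt(sos, lfp[: min(3, n_ch)].astype(float), axis=1)
        band_sd = float(np.mean(1.4826 * np.median(np.abs(band), axis=1)))
        amp = spec.snr * band_sd / _band_gain(spec)
    else:
        amp = spec.trough_amp_uv

    # evenly spaced event times with jitter (keeps events non-overlapping)
    margin = 1.0
    truth_rows = []
    mua = [list() for _ in range(n_ch)]
    if spec.n_ieds > 0:
        gap = (duration_s - 2 * margin) / spec.n_ieds
        if gap < 0.8:
            raise ValueError("events would overlap; increase duration")
        t0s = margin + gap * (np.arange(spec.n_ieds) + 0.5) \
            + rng.uniform(-0.3, 0.3, spec.n_ieds) * min(gap, 1.0)
        dirs = sample_vmm(spec.direction_model, spec.n_ieds, rng.integers(2**31))
        speeds = spec.speed_median_cm_s * np.exp(
            spec.speed_sigma * rng.standard_normal(spec.n_ieds))
        half_w = 0.45
        tw_s = spec.trough_width_ms / 1e3
        sw_s = spec.slow_wave_width_ms / 1e3
        for t0, phi, v in zip(t0s, dirs, speeds):
            delays = _planar_delays(positions, phi, v)
            for ch in range(n_ch):
                t_tr = t0 + delays[ch]
                i0 = max(0, int((t_tr - half_w) * fs))
                i1 = min(n_samples, int((t_tr + half_w) * fs) + 1)
                tt = np.arange(i0, i1) / fs - t_tr
                lfp[ch, i0:i1] += _template(tt, amp, tw_s, sw_s,
                                            spec.slow_wave_rel_amp).astype(np.float32)
                n_sp = rng.poisson(spec.mua_per_ied)
                if n_sp:
                    mua[ch].extend(t_tr + 1e-3 * spec.mua_jitter_ms
                                   * rng.standard_normal(n_sp))
            truth_rows.append({"t0": float(t0), "direction_rad": float(phi),
                               "speed_cm_s": float(v)})

    if spec.mua_background_hz > 0:
        for ch in range(n_ch):
            n_bg = rng.poisson(spec.mua_background_hz * duration_s)
            mua[ch].extend(rng.uniform(0, duration_s, n_bg))
    t_max = n_samples / fs
    mua_times = [np.sort(np.clip(np.asarray(m), 0, t_max)) for m in mua]

    rec = Recording(lfp=lfp, fs_hz=fs, geometry=geometry, mua_times=mua_times)
    truth = pd.DataFrame(truth_rows, columns=["t0", "direction_rad", "speed_cm_s"])
    return rec, truth


# ---------------------------------------------------------------------------
# seizures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeizureSimSpec:
    """Simulation parameters for one seizure epoch on the array.

    ``recruited`` plants a slow planar ictal wavefront (order 0.1-1 mm/s)
    of tonic firing followed by a train of fast seizure discharges with
    phase-locked multiunit bursts; ``penumbral`` plants the seizure-like
    field rhythm with unmodulated background firing.
    """

    seizure_class: str = "recruited"
    iw_speed_mm_s: float = 0.5
    iw_direction_rad: float = 0.0
    tonic_rate_hz: float = 5.0
    recruit_burst_hz: float = 100.0
    recruit_burst_s: float = 0.5
    n_sd: int = 250
    sd_rate_hz: float = 2.0
    # SDs share the IED axis but are more stereotyped (tighter, more
    # dominant-skewed) than interictal events
    sd_direction_model: DirectionModel = field(
        default_factory=lambda: DirectionModel.antipodal(
            kappa=10.0, dominant_weight=0.8))
    sd_speed_median_cm_s: float = 40.0
    sd_speed_sigma: float = 0.3
    sd_mua_per_channel: float = 4.0
    sd_mua_jitter_ms: float = 5.0
    sd_amp_uv: float = 400.0
    baseline_rate_hz: float = 0.5
    rhythm_hz: float = 3.0
    rhythm_amp_uv: float = 150.0
    noise_sd_uv: float = 20.0
    fs_hz: float = 500.0
    pre_s: float = 10.0
    post_s: float = 10.0

    def __post_init__(self):
        if self.seizure_class not in ("recruited", "penumbral"):
            raise ValueError("seizure_class must be 'recruited' or 'penumbral'")


def synth_seizure_recording(geometry: ArrayGeometry, spec: SeizureSimSpec,
                            seed=None) -> tuple[Recording, dict]:
    """Simulate a seizure epoch; returns (Recording, ground-truth dict)."""
    rng = np.random.default_rng(seed)
    positions = geometry.positions()
    n_ch = geometry.n_channels
    fs = spec.fs_hz

    t_onset = spec.pre_s
    if spec.seizure_class == "recruited":
        u = np.array([np.cos(spec.iw_direction_rad), np.sin(spec.iw_direction_rad)])
        proj = positions @ u
        recruit = t_onset + 2.0 + (proj - proj.min()) / spec.iw_speed_mm_s
        sd_start = float(recruit.max()) + 1.0
        sd_times = sd_start + np.arange(spec.n_sd) / spec.sd_rate_hz \
            + rng.uniform(-0.05, 0.05, spec.n_sd)
        t_end = float(sd_times.max()) + 2.0
    else:
        recruit = None
        sd_times = np.empty(0)
        t_end = t_onset + 40.0
    duration = t_end + spec.post_s
    n_samples = int(round(duration * fs))

    lfp = _background_noise(rng, n_ch, n_samples, fs, spec.noise_sd_uv, 0.2)
    tgrid = np.arange(n_samples) / fs
    in_sz = (tgrid >= t_onset) & (tgrid <= t_end)

    mua = [list() for _ in range(n_ch)]
    for ch in range(n_ch):
        n_bg = rng.poisson(spec.baseline_rate_hz * duration)
        mua[ch].extend(rng.uniform(0, duration, n_bg))

    truth: dict = {"class": spec.seizure_class, "t_onset": t_onset, "t_end": t_end}

    if spec.seizure_class == "penumbral":
        # seizure-like rhythm without firing modulation; the sinusoid plus
        # harmonic is a synthetic stand-in, not a fitted ictal field model
        rhythm = (np.sin(TWO_PI * spec.rhythm_hz * tgrid)
                  + 0.3 * np.sin(TWO_PI * 2 * spec.rhythm_hz * tgrid))
        lfp += (spec.rhythm_amp_uv * rhythm * in_sz).astype(np.float32)[None, :]
        mua_times = [np.sort(np.clip(np.asarray(m), 0, n_samples / fs)) for m in mua]
        rec = Recording(lfp=lfp, fs_hz=fs, geometry=geometry, mua_times=mua_times,
                        annotations=[("seizure", t_onset, t_end)])
        truth["sd"] = pd.DataFrame(columns=["t", "direction_rad", "speed_cm_s"])
        return rec, truth

    # recruited: tonic firing with a burst at recruitment (the IW passage)
    for ch in range(n_ch):
        r = recruit[ch]
        n_b = rng.poisson(spec.recruit_burst_hz * spec.recruit_burst_s)
        mua[ch].extend(r + rng.uniform(0, spec.recruit_burst_s, n_b))
        span = max(t_end - r, 0.0)
        n_t = rng.poisson(spec.tonic_rate_hz * span)
        mua[ch].extend(r + rng.uniform(0, span, n_t) if span > 0 else [])

    # seizure discharges: planar LFP deflection + locked MUA burst per channel
    sd_rows = []
    dirs = sample_vmm(spec.sd_direction_model, spec.n_sd, rng.integers(2**31))
    speeds = spec.sd_speed_median_cm_s * np.exp(
        spec.sd_speed_sigma * rng.standard_normal(spec.n_sd))
    for t_sd, phi, v in zip(sd_times, dirs, speeds):
        delays = _planar_delays(positions, phi, v)
        for ch in range(n_ch):
            t_pass = t_sd + delays[ch]
            i0 = max(0, int((t_pass - 0.15) * fs))
            i1 = min(n_samples, int((t_pass + 0.15) * fs) + 1)
            tt = np.arange(i0, i1) / fs - t_pass
            lfp[ch, i0:i1] += _template(tt, spec.sd_amp_uv, 0.03, 0.12, 0.3
                                        ).astype(np.float32)
            n_sp = rng.poisson(spec.sd_mua_per_channel)
            if n_sp:
                mua[ch].extend(t_pass + 1e-3 * spec.sd_mua_jitter_ms
                               * rng.standard_normal(n_sp))
        sd_rows.append({"t": float(t_sd), "direction_rad": float(phi),
                        "speed_cm_s": float(v)})

    mua_times = [np.sort(np.clip(np.asarray(m), 0, n_samples / fs)) for m in mua]
    rec = Recording(lfp=lfp, fs_hz=fs, geometry=geometry, mua_times=mua_times,
                    annotations=[("seizure", t_onset, t_end)])
    truth["iw_direction_rad"] = spec.iw_direction_rad
    truth["iw_speed_mm_s"] = spec.iw_speed_mm_s
    truth["recruitment_times_s"] = recruit
    truth["sd"] = pd.DataFrame(sd_rows, columns=["t", "direction_rad", "speed_cm_s"])
    return rec, truth
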