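"""Seizure characterization: ictal wavefront, seizure discharges, recruitment.

The ictal wavefront (IW) is the slowly expanding edge of tonic multiunit
firing that marks recruitment of the tissue under each electrode into the
seizure core.  It is detected by smoothing per-channel firing rates with a
250 ms Gaussian kernel and plane-fitting the rate-peak times (speed
naturally in mm/s).  Seizure discharges (SDs) are peaks of the array-mean
25 ms-kernel rate, each given its own plane fit (cm/s).  A recording is
'recruited' when the IW fit is significant AND multiunit firing is
phase-locked to the mean LFP (Hermans-Rasson test on spike phases);
otherwise 'penumbral'.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .circular import hermans_rasson_test, wrap_angle
from .core_io import Recording, SeizureCharacterization, WaveFit
from .waves import fit_plane, fit_wave, permutation_test_wave

__all__ = [
    "firing_rate",
    "fit_ictal_wavefront",
    "detect_seizure_discharges",
    "phase_lock_test",
    "classify_recruitment",
    "characterize_seizure",
]


def firing_rate(mua_times, kernel_sd_s: float, t_grid: np.ndarray) -> np.ndarray:
    """Gaussian-kernel firing rate (Hz) on a regular time grid.

    Each spike contributes a Gaussian of standard deviation kernel_sd_s
    integrating to one, so the series integrates to the spike count.
    """
    if kernel_sd_s <= 0:
        raise ValueError("kernel_sd_s must be positive")
    t_grid = np.asarray(t_grid, dtype=float)
    spikes = np.asarray(mua_times, dtype=float)
    if spikes.size == 0 or t_grid.size < 2:
        return np.zeros_like(t_grid)
    dt = t_grid[1] - t_grid[0]
    # histogram on the grid then convolve: exact enough for dt << kernel_sd
    edges = np.concatenate([t_grid - dt / 2, [t_grid[-1] + dt / 2]])
    counts, _ = np.histogram(spikes, bins=edges)
    half = int(np.ceil(4 * kernel_sd_s / dt))
    k_t = np.arange(-half, half + 1) * dt
    kernel = np.exp(-0.5 * (k_t / kernel_sd_s) ** 2)
    kernel /= kernel.sum() * dt  # unit area in Hz units
    return signal.fftconvolve(counts.astype(float), kernel, mode="same")


def _rate_grid(window: tuple[float, float], dt: float = 0.005) -> np.ndarray:
    return np.arange(window[0], window[1], dt)


def fit_ictal_wavefront(rec: Recording, window: tuple[float, float],
                        kernel_sd_s: float = 0.25, n_perm: int = 1000,
                        seed=None, min_channels: int = 10) -> WaveFit | None:
    """Plane fit to per-channel times of maximum slow (250 ms) firing rate.

    Returns None when fewer than min_channels have spikes in the window.
    The WaveFit's ``speed_mm_s`` property is the natural unit for the IW.
    """
    t_grid = _rate_grid(window)
    times: dict[int, float] = {}
    for ch in rec.geometry.good_channels():
        sp = rec.mua_times[ch]
        sp = sp[(sp >= window[0]) & (sp <= window[1])]
        if sp.size < 3:
            continue
        rate = firing_rate(sp, kernel_sd_s, t_grid)
        times[int(ch)] = float(t_grid[np.argmax(rate)])
    if len(times) < min_channels:
        return None
    try:
        fit = fit_wave(times, rec.geometry, method="lad", fit_kind="iw",
                       n_perm=n_perm, seed=seed, min_points=min_channels)
    except ValueError:
        return None
    return fit


def detect_seizure_discharges(rec: Recording, window: tuple[float, float],
                              kernel_sd_s: float = 0.025,
                              prominence_mult: float = 2.0,
                              min_interval_s: float = 0.1,
                              per_channel: str = "rate_peak",
                              n_perm: int = 1000, seed=None,
                              min_channels: int = 10) -> list[WaveFit]:
    """Detect SDs as array-mean fast-rate peaks and plane-fit each one.

    Peaks must have prominence >= prominence_mult times the window's median
    rate and be separated by min_interval_s.  Per-channel SD timing is the
    local 25 ms rate peak within +/- 50 ms (``per_channel="rate_peak"``) or
    raw spike times (``per_channel="spikes"``).  Discharges after an
    annotated ``secondary_generalization`` time are excluded.
    """
    rng = np.random.default_rng(seed)
    sec_gen = rec.annotation("secondary_generalization")
    t_stop = sec_gen[0] if sec_gen else window[1]

    t_grid = _rate_grid(window, dt=0.002)
    good = rec.geometry.good_channels()
    rates = np.stack([firing_rate(rec.mua_times[ch], kernel_sd_s, t_grid)
                      for ch in good])
    mean_rate = rates.mean(axis=0)
    med = np.median(mean_rate)
    dt = t_grid[1] - t_grid[0]
    peaks, _ = signal.find_peaks(mean_rate,
                                 prominence=max(prominence_mult * med, 1e-9),
                                 distance=max(int(min_interval_s / dt), 1))
    positions = rec.geometry.positions()
    fits: list[WaveFit] = []
    for pk in peaks:
        t_sd = float(t_grid[pk])
        if t_sd > t_stop:
            continue
        if per_channel == "rate_peak":
            sel = (t_grid >= t_sd - 0.05) & (t_grid <= t_sd + 0.05)
            tt = t_grid[sel]
            times = {}
            for i, ch in enumerate(good):
                seg = rates[i, sel]
                if seg.size and seg.max() > 0:
                    times[int(ch)] = float(tt[np.argmax(seg)])
            pts, xy = None, None
        else:
            xy, pts = [], []
            for ch in good:
                sp = rec.mua_times[ch]
                sp = sp[(sp >= t_sd - 0.05) & (sp <= t_sd + 0.05)]
                for t in sp:
                    xy.append(positions[ch])
                    pts.append(t)
            times = None
        try:
            if times is not None:
                if len(times) < min_channels:
                    continue
                fit = fit_wave(times, rec.geometry, method="lad", fit_kind="sd",
                               n_perm=n_perm, seed=rng.integers(2**31),
                               min_points=min_channels)
            else:
                if len(pts) < min_channels:
                    continue
                fit = fit_plane(np.asarray(pts), np.asarray(xy), method="lad",
                                fit_kind="sd", min_points=min_channels)
                p = permutation_test_wave(np.asarray(pts), np.asarray(xy),
                                          n_perm=n_perm, seed=rng.integers(2**31))
                fit.p_value, fit.n_permutations = p, n_perm
                fit.is_traveling = bool(p < 0.05)
        except ValueError:
            continue
        fit.event_time_s = t_sd
        fits.append(fit)
    return fits


def phase_lock_test(rec: Recording, window: tuple[float, float],
                    band: tuple[float, float] = (1.0, 30.0),
                    n_perm: int = 1000, seed=None, min_spikes: int = 50,
                    max_spikes: int = 500) -> float | None:
    """Hermans-Rasson test of spike phases relative to the mean-LFP phase.

    Phase is the analytic-signal angle of the band-passed (default 1-30 Hz)
    array-mean LFP.  Returns None for too few spikes or a degenerate
    (effectively flat) field where phase is ill-defined.  Spike counts are
    capped at max_spikes by random subsampling to bound the O(n^2)
    statistic.
    """
    rng = np.random.default_rng(seed)
    fs = rec.fs_hz
    i0, i1 = int(window[0] * fs), min(int(window[1] * fs), rec.lfp.shape[1])
    mean_lfp = rec.lfp[rec.geometry.good_channels(), i0:i1].astype(float).mean(axis=0)
    if mean_lfp.size < 10:
        return None
    sos = signal.butter(4, [band[0], min(band[1], 0.45 * fs)], btype="bandpass",
                        fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, mean_lfp)
    analytic = signal.hilbert(filt)
    if np.median(np.abs(analytic)) < 1e-9:
        return None  # flat field: phase ill-defined
    phase = np.angle(analytic)

    spikes = np.concatenate([rec.mua_times[ch] for ch in rec.geometry.good_channels()])
    spikes = spikes[(spikes >= window[0]) & (spikes < i1 / fs)]
    if spikes.size < min_spikes:
        return None
    if spikes.size > max_spikes:
        spikes = rng.choice(spikes, size=max_spikes, replace=False)
    idx = np.clip(((spikes - window[0]) * fs).astype(int), 0, filt.size - 1)
    spike_phases = wrap_angle(phase[idx])
    return hermans_rasson_test(spike_phases, n_perm=n_perm, seed=rng.integers(2**31))


def classify_recruitment(iw_fit: WaveFit | None, phase_lock_p: float | None,
                         alpha: float = 0.05) -> str:
    """'recruited' iff a significant IW fit AND significant phase-locked firing."""
    if (iw_fit is not None and iw_fit.p_value < alpha
            and phase_lock_p is not None and phase_lock_p < alpha):
        return "recruited"
    return "penumbral"


def characterize_seizure(rec: Recording, n_perm: int = 1000, seed=None,
                         iw_max_s: float = 120.0) -> SeizureCharacterization:
    """Full seizure characterization from an annotated recording.

    Uses the ``seizure`` annotation for the analysis window (IW window
    capped at onset + iw_max_s), clipped at any annotated secondary
    generalization.
    """
    rng = np.random.default_rng(seed)
    ann = rec.annotation("seizure")
    if ann is None:
        raise ValueError("recording has no 'seizure' annotation")
    t0, t1 = ann
    sec = rec.annotation("secondary_generalization")
    analysis_end = min(t1, sec[0]) if sec else t1

    iw_window = (t0, min(t0 + iw_max_s, analysis_end))
    iw_fit = fit_ictal_wavefront(rec, iw_window, n_perm=n_perm,
                                 seed=rng.integers(2**31))
    sd_fits = detect_seizure_discharges(rec, (t0, analysis_end), n_perm=n_perm,
                                        seed=rng.integers(2**31))
    p_lock = phase_lock_test(rec, (t0, analysis_end), n_perm=n_perm,
                             seed=rng.integers(2**31))
    cls = classify_recruitment(iw_fit, p_lock)
    return SeizureCharacterization(
        iw_fit=iw_fit, sd_fits=sd_fits,
        phase_lock_p=p_lock if p_lock is not None else np.nan,
        seizure_class=cls, analysis_end_s=analysis_end,
    )
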