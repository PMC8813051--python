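"""Array-wide interictal discharge detection, QA, and MUA event detection.

The IED detector resamples each channel to 400 Hz, zero-phase band-passes
20-40 Hz (4th-order Butterworth), thresholds the absolute filtered trace at
8 robust standard deviations, de-duplicates within channel (250 ms), and
keeps only events co-detected on at least 10 electrodes within a 250 ms
consensus window.  Post-detection QA drops temporally outlying channel
extrema and flags events with outlying across-array voltage ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal

from .core_io import IEDEvent, QAReason, Recording

__all__ = [
    "DetectionConfig",
    "bandpass_zero_phase",
    "resample_recording",
    "detect_ied_candidates",
    "qa_filter",
    "detect_mua",
    "rater_agreement",
]


@dataclass(frozen=True)
class DetectionConfig:
    resample_hz: float = 400.0
    band: tuple[float, float] = (20.0, 40.0)
    filter_order: int = 4
    threshold_sd: float = 8.0
    dedup_window_s: float = 0.25
    consensus_window_s: float = 0.25
    min_channels: int = 10
    extrema_window_s: float = 0.05
    extraction_window_s: float = 0.25
    amplitude_outlier_iqr_mult: float = 2.0
    # robust: SD estimated as 1.4826 * MAD so large events do not inflate
    # the threshold; "plain" uses np.std of the filtered trace
    sd_mode: str = "robust"
    segment_s: float = 7200.0

    def __post_init__(self):
        if self.threshold_sd <= 0 or self.min_channels < 1:
            raise ValueError("invalid detection config")


def bandpass_zero_phase(x: np.ndarray, fs: float, low: float, high: float,
                        order: int = 4) -> np.ndarray:
    """Forward-backward Butterworth band-pass (zero phase, same length)."""
    if not (0 < low < high < fs / 2):
        raise ValueError(f"band ({low}, {high}) Hz infeasible at fs={fs} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def resample_recording(rec: Recording, target_hz: float) -> Recording:
    """Polyphase anti-aliased resample of the LFP to target_hz."""
    if rec.fs_hz == target_hz:
        return rec
    frac = Fraction(target_hz / rec.fs_hz).limit_denominator(1000)
    lfp = signal.resample_poly(rec.lfp.astype(float), frac.numerator,
                               frac.denominator, axis=1).astype(np.float32)
    return Recording(lfp=lfp, fs_hz=rec.fs_hz * frac.numerator / frac.denominator,
                     geometry=rec.geometry, mua_times=list(rec.mua_times),
                     annotations=list(rec.annotations))


def _robust_sd(x: np.ndarray) -> float:
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def _channel_detections(filtered: np.ndarray, fs: float, cfg: DetectionConfig) -> np.ndarray:
    """Threshold crossings of |filtered|, de-duplicated (earliest kept)."""
    sd = _robust_sd(filtered) if cfg.sd_mode == "robust" else float(np.std(filtered))
    if sd == 0:
        return np.empty(0)
    thr = cfg.threshold_sd * sd
    peaks, _ = signal.find_peaks(np.abs(filtered), height=thr)
    if peaks.size == 0:
        return np.empty(0)
    times = peaks / fs
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= cfg.dedup_window_s:
            kept.append(t)
    return np.asarray(kept)


def detect_ied_candidates(rec: Recording, cfg: DetectionConfig = DetectionConfig()
                          ) -> list[IEDEvent]:
    """Run the array-consensus IED detector on a recording.

    Returns consensus events (median detection time across contributing
    channels) with per-channel LFP-minimum times and peak-to-trough
    amplitudes extracted from a +/- extraction_window around each event.
    """
    if cfg.min_channels > rec.geometry.n_channels:
        raise ValueError("min_channels exceeds channel count")
    rs = resample_recording(rec, cfg.resample_hz)
    fs = rs.fs_hz
    good = rs.geometry.good_channels()
    n_samples = rs.lfp.shape[1]
    seg_len = max(int(cfg.segment_s * fs), 1)

    detections: list[tuple[float, int]] = []
    for start in range(0, n_samples, seg_len):
        stop = min(start + seg_len, n_samples)
        if stop - start < 3 * cfg.filter_order * 4:
            continue
        filt = bandpass_zero_phase(rs.lfp[:, start:stop].astype(float), fs,
                                   cfg.band[0], cfg.band[1], cfg.filter_order)
        for ch in good:
            for t in _channel_detections(filt[ch], fs, cfg):
                detections.append((t + start / fs, int(ch)))

    if not detections:
        return []
    detections.sort()
    # transitive merge: successive detections within the consensus window
    groups: list[list[tuple[float, int]]] = [[detections[0]]]
    for det in detections[1:]:
        if det[0] - groups[-1][-1][0] <= cfg.consensus_window_s:
            groups[-1].append(det)
        else:
            groups.append([det])

    events = []
    half = cfg.extraction_window_s / 2.0
    for grp in groups:
        chans = {c for _, c in grp}
        if len(chans) < cfg.min_channels:
            continue
        t_event = float(np.median([t for t, _ in grp]))
        i0 = max(0, int((t_event - half) * fs))
        i1 = min(n_samples, int((t_event + half) * fs) + 1)
        peak_times, amps = {}, {}
        for ch in good:
            seg = rs.lfp[ch, i0:i1].astype(float)
            if seg.size < 3 or np.ptp(seg) == 0:
                continue
            peak_times[int(ch)] = (i0 + int(np.argmin(seg))) / fs
            amps[int(ch)] = float(np.ptp(seg))
        events.append(IEDEvent(
            event_time_s=t_event, channel_peak_times_s=peak_times,
            channel_amplitudes_uv=amps, n_detecting_channels=len(chans),
        ))
    return events


def qa_filter(events: list[IEDEvent], rec: Recording,
              cfg: DetectionConfig = DetectionConfig()) -> list[IEDEvent]:
    """Post-detection QA: trim outlying channel extrema, flag outlying amplitudes.

    Channel extremum times outside the focused window (median +/- half the
    extrema window) are dropped from the event (the channel, not the
    event).  Events whose across-array voltage range exceeds
    Q3 + mult * IQR of the session's event-range distribution are flagged
    ``amplitude_outlier``; the IQR = 0 degenerate case flags nothing.
    Never adds channels or events.
    """
    out = []
    half = cfg.extrema_window_s / 2.0
    for ev in events:
        times = ev.channel_peak_times_s
        if times:
            med = float(np.median(list(times.values())))
            keep = {ch: t for ch, t in times.items() if abs(t - med) <= half}
        else:
            keep = {}
        amps = {ch: a for ch, a in ev.channel_amplitudes_uv.items() if ch in keep}
        qa_pass, reason = True, QAReason.ok.value
        if len(keep) < cfg.min_channels:
            qa_pass, reason = False, QAReason.too_few_channels.value
        out.append(IEDEvent(
            event_time_s=ev.event_time_s, channel_peak_times_s=keep,
            channel_amplitudes_uv=amps, n_detecting_channels=ev.n_detecting_channels,
            qa_pass=qa_pass, qa_reason=reason,
        ))

    ranges = np.array([max(ev.channel_amplitudes_uv.values()) if ev.channel_amplitudes_uv
                       else 0.0 for ev in out])
    if ranges.size:
        q1, q3 = np.percentile(ranges, [25, 75])
        iqr = q3 - q1
        if iqr > 0:
            cut = q3 + cfg.amplitude_outlier_iqr_mult * iqr
            for ev, r in zip(out, ranges):
                if ev.qa_pass and r > cut:
                    ev.qa_pass = False
                    ev.qa_reason = QAReason.amplitude_outlier.value
    return out


def detect_mua(broadband: np.ndarray, fs: float, mode: str = "mad",
               band: tuple[float, float] = (300.0, 3000.0),
               threshold_mult: float = 4.0) -> np.ndarray:
    """Multiunit event times from a broadband trace.

    Band-passes 0.3-3 kHz and returns times of negative peaks below
    -threshold_mult times the noise scale: the RMS of the filtered trace
    (``mode="rms"``) or the robust estimate median(|x|)/0.6745
    (``mode="mad"``, default).
    """
    required = 2.5 * band[1]
    if fs < required:
        raise ValueError(
            f"sampling rate {fs} Hz too low for the {band[1]} Hz corner; "
            f"need >= {required} Hz")
    x = bandpass_zero_phase(np.asarray(broadband, dtype=float), fs,
                            band[0], band[1], order=4)
    if mode == "rms":
        scale = float(np.sqrt(np.mean(x**2)))
    elif mode == "mad":
        scale = float(np.median(np.abs(x)) / 0.6745)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if scale == 0:
        return np.empty(0)
    peaks, _ = signal.find_peaks(-x, height=threshold_mult * scale)
    return peaks / fs


def rater_agreement(algorithm_labels, rater_labels) -> dict:
    """Precision and Cohen's kappa between algorithm and rater binary labels."""
    a = np.asarray(algorithm_labels, dtype=int)
    r = np.asarray(rater_labels, dtype=int)
    if a.size == 0 or a.shape != r.shape:
        raise ValueError("labels must be equal-length nonempty binary vectors")
    tp = int(np.sum((a == 1) & (r == 1)))
    fp = int(np.sum((a == 1) & (r == 0)))
    precision = tp / (tp + fp) if (tp + fp) else np.nan
    p_o = float(np.mean(a == r))
    p_yes_a, p_yes_r = float(np.mean(a)), float(np.mean(r))
    p_e = p_yes_a * p_yes_r + (1 - p_yes_a) * (1 - p_yes_r)
    kappa = (p_o - p_e) / (1 - p_e) if p_e < 1 else 1.0
    return {"precision": precision, "kappa": kappa}
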