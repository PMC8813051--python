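"""Plane fitting of per-channel event timings: the operational traveling wave.

An event is a traveling wave if the plane ``t = b0 + bx*x + by*y`` fitted to
its per-channel timings has a slope significantly different from zero under
spatial permutation of the electrode coordinates.  With positions in mm and
times in ms, speed is ``100 / ||(bx, by)||`` cm/s and direction is
``atan2(by, bx)`` (the wave moves up the delay gradient).
"""

from __future__ import annotations

import numpy as np

from .core_io import ArrayGeometry, IEDEvent, Recording, WaveFit, wrap_angle

__all__ = [
    "fit_plane",
    "permutation_test_wave",
    "extract_extrema_times",
    "collect_mua_times",
    "classify_events",
    "fit_wave",
]

TWO_PI = 2.0 * np.pi


def _design(xy_mm: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(xy_mm)), xy_mm])


def _ols(X, t):
    beta, *_ = np.linalg.lstsq(X, t, rcond=None)
    return beta


def _lad_irls(X, t, n_iter: int = 60, eps: float = 1e-8):
    """Least-absolute-deviation plane via iteratively reweighted least squares."""
    beta = _ols(X, t)
    for _ in range(n_iter):
        r = np.abs(t - X @ beta)
        w = 1.0 / np.maximum(r, eps)
        Xw = X * w[:, None]
        new, *_ = np.linalg.lstsq(Xw.T @ X, Xw.T @ t, rcond=None)
        if np.max(np.abs(new - beta)) < 1e-12 * (1 + np.max(np.abs(beta))):
            beta = new
            break
        beta = new
    return beta


def _r_squared(X, t):
    beta = _ols(X, t)
    resid = t - X @ beta
    ss_tot = np.sum((t - t.mean()) ** 2)
    if ss_tot <= 0:
        return 0.0
    return float(1.0 - np.sum(resid**2) / ss_tot)


def fit_plane(times: dict[int, float] | np.ndarray, geometry: ArrayGeometry | np.ndarray,
              method: str = "lad", fit_kind: str = "ied_lfp",
              min_points: int = 10) -> WaveFit:
    """Fit the delay plane to per-channel times (seconds in, ms/mm out).

    ``times`` is a map channel -> time (s), or an array aligned with the
    coordinate rows when ``geometry`` is given directly as an (n, 2) array
    of positions in mm.  ``method`` is ``"lad"`` (default, robust to
    outlying channel timings) or ``"ols"``.
    """
    if isinstance(times, dict):
        chans = np.array(sorted(times))
        t_s = np.array([times[c] for c in chans], dtype=float)
        xy = geometry.positions()[chans] if isinstance(geometry, ArrayGeometry) else \
            np.asarray(geometry, dtype=float)[chans]
    else:
        t_s = np.asarray(times, dtype=float)
        xy = np.asarray(geometry.positions() if isinstance(geometry, ArrayGeometry)
                        else geometry, dtype=float)
    if t_s.size < min_points:
        raise ValueError(f"need >= {min_points} points, got {t_s.size}")
    if len(np.unique(xy[:, 0])) < 2 or len(np.unique(xy[:, 1])) < 2:
        raise ValueError("rank-deficient design: points must span 2 x and 2 y values")

    t_ms = (t_s - t_s.mean()) * 1000.0  # center for conditioning; intercept restored below
    X = _design(xy)
    beta = _lad_irls(X, t_ms) if method == "lad" else _ols(X, t_ms)
    b0, bx, by = beta
    b0 += t_s.mean() * 1000.0
    grad = float(np.hypot(bx, by))
    if grad > 0:
        speed = 100.0 / grad
        direction = wrap_angle(np.arctan2(by, bx))
    else:
        speed = np.nan
        direction = 0.0
    return WaveFit(
        beta_x_ms_per_mm=float(bx), beta_y_ms_per_mm=float(by), intercept_ms=float(b0),
        speed_cm_s=speed, direction_rad=float(direction), n_points=int(t_s.size),
        fit_kind=fit_kind, r_squared=_r_squared(X, t_ms),
    )


def permutation_test_wave(times: dict[int, float] | np.ndarray,
                          geometry: ArrayGeometry | np.ndarray,
                          n_perm: int = 1000, seed=None) -> float:
    """Spatial-permutation p-value for the plane fit.

    The statistic is the OLS explained variance R^2 (invariant to time
    units); the null re-fits with electrode positions randomly permuted.
    p uses the add-one estimator: (1 + #{R2_perm >= R2_obs}) / (n_perm + 1).
    """
    if isinstance(times, dict):
        chans = np.array(sorted(times))
        t = np.array([times[c] for c in chans], dtype=float)
        xy = geometry.positions()[chans] if isinstance(geometry, ArrayGeometry) else \
            np.asarray(geometry, dtype=float)[chans]
    else:
        t = np.asarray(times, dtype=float)
        xy = np.asarray(geometry.positions() if isinstance(geometry, ArrayGeometry)
                        else geometry, dtype=float)
    rng = np.random.default_rng(seed)
    t = (t - t.mean()) * 1000.0
    X = _design(xy)
    obs = _r_squared(X, t)

    # permuting positions against fixed times == permuting times against
    # fixed positions; batch-solve all permutations with the normal equations
    n = t.size
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    T = t[perms].T  # (n, n_perm)
    beta = np.linalg.lstsq(X, T, rcond=None)[0]
    resid = T - X @ beta
    ss_tot = np.sum(t**2) - n * (t.mean() ** 2)
    if ss_tot <= 0:
        return 1.0
    r2 = 1.0 - np.sum(resid**2, axis=0) / ss_tot
    return float((1.0 + np.sum(r2 >= obs)) / (n_perm + 1.0))


def fit_wave(times, geometry, method: str = "lad", fit_kind: str = "ied_lfp",
             n_perm: int = 1000, seed=None, alpha: float = 0.05,
             min_points: int = 10) -> WaveFit:
    """Plane fit plus permutation test, returning a complete WaveFit."""
    fit = fit_plane(times, geometry, method=method, fit_kind=fit_kind,
                    min_points=min_points)
    p = permutation_test_wave(times, geometry, n_perm=n_perm, seed=seed)
    fit.p_value = p
    fit.n_permutations = n_perm
    fit.is_traveling = bool(p < alpha)
    return fit


# ---------------------------------------------------------------------------
# per-event timing extraction
# ---------------------------------------------------------------------------

def _parabolic_refine(y: np.ndarray, i: int) -> float:
    """Sub-sample refinement of an extremum index by parabolic interpolation."""
    if i <= 0 or i >= len(y) - 1:
        return float(i)
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return float(i)
    return float(i + 0.5 * (y[i - 1] - y[i + 1]) / denom)


def extract_extrema_times(rec: Recording, event: IEDEvent, window_s: float = 0.05,
                          min_channels: int = 10) -> dict[int, float]:
    """Per-channel LFP minimum times within the focused event window.

    The window is the across-channel median peak time +/- window_s / 2;
    when two samples tie, the earlier (more negative first) minimum wins.
    Flat channels and channels whose minimum falls on the window edge
    without a true local minimum are excluded.
    """
    if not event.channel_peak_times_s:
        raise ValueError("event has no per-channel peak times; run detection first")
    med = float(np.median(list(event.channel_peak_times_s.values())))
    half = window_s / 2.0
    fs = rec.fs_hz
    i0 = max(0, int(np.floor((med - half) * fs)))
    i1 = min(rec.lfp.shape[1], int(np.ceil((med + half) * fs)) + 1)
    out: dict[int, float] = {}
    for ch in rec.geometry.good_channels():
        seg = rec.lfp[ch, i0:i1].astype(float)
        if seg.size < 3 or np.ptp(seg) == 0:
            continue
        i_min = int(np.argmin(seg))  # argmin takes the earliest of ties
        t = (i0 + _parabolic_refine(seg, i_min)) / fs
        out[int(ch)] = t
    if len(out) < min_channels:
        raise ValueError(
            f"only {len(out)} channels retained (< {min_channels}); event excluded")
    return out


def collect_mua_times(rec: Recording, event: IEDEvent,
                      window_s: float = 0.05) -> dict[int, np.ndarray]:
    """Per-channel MUA spike times within +/- window_s of the median LFP trough."""
    med = float(np.median(list(event.channel_peak_times_s.values())))
    out: dict[int, np.ndarray] = {}
    for ch in rec.geometry.good_channels():
        t = rec.mua_times[ch]
        sel = t[(t >= med - window_s) & (t <= med + window_s)]
        if sel.size:
            out[int(ch)] = sel
    return out


def classify_events(events: list[IEDEvent], rec: Recording, method: str = "lad",
                    n_perm: int = 1000, seed=None, min_points: int = 10,
                    signals: tuple[str, ...] = ("ied_lfp", "ied_mua")) -> dict:
    """Fit waves to every QA-passing event for each signal kind.

    Returns ``{"fits": {signal: [WaveFit or None per event]}, "summary": ...}``
    with per-signal traveling counts/fractions.  MUA fits use every spike in
    the +/-50 ms window as a separate (x, y, t) point.
    """
    rng = np.random.default_rng(seed)
    positions = rec.geometry.positions()
    fits: dict[str, list] = {s: [] for s in signals}
    for ev in events:
        if not ev.qa_pass:
            for s in signals:
                fits[s].append(None)
            continue
        if "ied_lfp" in signals:
            try:
                times = extract_extrema_times(rec, ev, min_channels=min_points)
                fit = fit_wave(times, rec.geometry, method=method, fit_kind="ied_lfp",
                               n_perm=n_perm, seed=rng.integers(2**31))
                fit.event_time_s = ev.event_time_s
            except ValueError:
                fit = None
            fits["ied_lfp"].append(fit)
        if "ied_mua" in signals:
            spike_map = collect_mua_times(rec, ev)
            xy, ts = [], []
            for ch, spikes in spike_map.items():
                for t in spikes:
                    xy.append(positions[ch])
                    ts.append(t)
            fit = None
            if len(ts) >= min_points:
                xy_arr, t_arr = np.asarray(xy), np.asarray(ts)
                try:
                    fit = fit_plane(t_arr, xy_arr, method=method, fit_kind="ied_mua",
                                    min_points=min_points)
                    p = permutation_test_wave(t_arr, xy_arr, n_perm=n_perm,
                                              seed=rng.integers(2**31))
                    fit.p_value = p
                    fit.n_permutations = n_perm
                    fit.is_traveling = bool(p < 0.05)
                    fit.event_time_s = ev.event_time_s
                except ValueError:
                    fit = None
            fits["ied_mua"].append(fit)
    summary = {}
    for s in signals:
        done = [f for f in fits[s] if f is not None]
        n_trav = sum(f.is_traveling for f in done)
        summary[s] = {
            "n_events": len(events),
            "n_fit": len(done),
            "n_traveling": int(n_trav),
            "fraction_traveling": (n_trav / len(done)) if done else np.nan,
        }
    return {"fits": fits, "summary": summary}
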