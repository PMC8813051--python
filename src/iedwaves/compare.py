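"""IED vs seizure-discharge comparisons and the end-to-end pipeline.

Statistical machinery for comparing interictal discharge (IED) and seizure
discharge (SD) traveling-wave populations: cluster-based permutation tests
on time series, rank tests on speeds, proportion and McNemar tests on
counts/paired flags, a rank-based two-way analysis (Scheirer-Ray-Hare with
Kruskal-Wallis cross-checks and Dunn's post-hoc), and the full
IED<->SD comparison report (medians, bimodality, KLD).  ``run_pipeline``
chains simulate -> detect -> waves -> stats -> seizure -> compare and
writes every intermediate artifact.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar
from statsmodels.stats.proportion import proportions_chisquare

from . import circular as circ
from .core_io import ArrayGeometry, WaveFit, write_events, write_recording
from .detection import DetectionConfig, detect_ied_candidates, qa_filter
from .seizure import characterize_seizure
from .synthetic import DirectionModel, IEDSimSpec, SeizureSimSpec, \
    synth_ied_recording, synth_seizure_recording
from .waves import classify_events

__all__ = [
    "cluster_permutation_test",
    "compare_speeds",
    "proportion_test",
    "mcnemar_test",
    "speed_anova",
    "compare_ied_sd",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# cluster-based permutation test on time series
# ---------------------------------------------------------------------------

def _per_bin_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t statistic per column."""
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (ma - mb) / denom, 0.0)
    return t


def _clusters(sig: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) of runs of True (stop exclusive)."""
    out = []
    i = 0
    n = sig.size
    while i < n:
        if sig[i]:
            j = i
            while j < n and sig[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def cluster_permutation_test(group_a, group_b, alpha: float = 0.05,
                             n_perm: int = 1000, seed=None) -> dict:
    """Cluster-corrected comparison of two sets of time series.

    Per-bin t-tests are thresholded at alpha; adjacent significant bins
    form temporal clusters scored by their mass (summed |t|, the
    continuous cluster statistic that keeps the permutation test
    calibrated).  The null is the maximum cluster mass over random
    relabelings of the series; each observed cluster gets an add-one
    permutation p-value.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("series length mismatch between groups")
    if a.shape[0] < 5 or b.shape[0] < 5:
        raise ValueError("need at least 5 series per group")
    rng = np.random.default_rng(seed)
    na = a.shape[0]
    df = na + b.shape[0] - 2
    t_crit = stats.t.ppf(1 - alpha / 2, df)

    obs_t = _per_bin_t(a, b)
    obs_clusters = _clusters(np.abs(obs_t) > t_crit)
    masses = [float(np.abs(obs_t[i:j]).sum()) for i, j in obs_clusters]

    pooled = np.vstack([a, b])
    n_tot = pooled.shape[0]
    null_max = np.zeros(n_perm)
    for k in range(n_perm):
        idx = rng.permutation(n_tot)
        t = _per_bin_t(pooled[idx[:na]], pooled[idx[na:]])
        cl = _clusters(np.abs(t) > t_crit)
        null_max[k] = max((np.abs(t[i:j]).sum() for i, j in cl), default=0.0)

    cluster_p = [(1.0 + np.sum(null_max >= m)) / (n_perm + 1.0) for m in masses]
    return {"clusters": obs_clusters, "cluster_p": cluster_p,
            "t_per_bin": obs_t, "null_max": null_max}


# ---------------------------------------------------------------------------
# scalar tests
# ---------------------------------------------------------------------------

def compare_speeds(speeds_a, speeds_b) -> float:
    """Two-sided Mann-Whitney U p-value between two speed samples."""
    a = np.asarray(speeds_a, dtype=float)
    b = np.asarray(speeds_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs >= 3 observations")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def proportion_test(k1: int, n1: int, k2: int, n2: int) -> dict:
    """Two-sample proportion chi-square test."""
    chi2, p, _ = proportions_chisquare([k1, k2], [n1, n2])
    if not np.isfinite(chi2):
        chi2, p = 0.0, 1.0
    return {"chi2": float(chi2), "p": float(p)}


def mcnemar_test(flags_a, flags_b) -> dict:
    """McNemar chi-square on paired binary flags (no continuity correction)."""
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("paired flag vectors must match in length")
    n01 = int(np.sum(a & ~b))
    n10 = int(np.sum(~a & b))
    if n01 + n10 == 0:
        return {"chi2": 0.0, "p": 1.0}
    table = [[int(np.sum(a & b)), n01], [n10, int(np.sum(~a & ~b))]]
    res = sm_mcnemar(table, exact=False, correction=False)
    return {"chi2": float(res.statistic), "p": float(res.pvalue)}


def speed_anova(speeds, participant_labels, signal_labels) -> dict:
    """Rank-based two-way analysis of speeds (participant x signal).

    The two-way analysis is the Scheirer-Ray-Hare extension of
    Kruskal-Wallis (H = SS_factor on ranks / MS_total, chi-square
    reference); one-way Kruskal-Wallis per factor is reported as a
    cross-check, and Dunn's test (Holm-adjusted) gives pairwise
    participant contrasts.
    """
    df = pd.DataFrame({"speed": np.asarray(speeds, dtype=float),
                       "participant": np.asarray(participant_labels),
                       "signal": np.asarray(signal_labels)})
    for col in ("participant", "signal"):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col!r} has a single level")
    n = len(df)
    df["rank"] = stats.rankdata(df["speed"])
    grand = df["rank"].mean()
    ss_total = float(((df["rank"] - grand) ** 2).sum())
    ms_total = ss_total / (n - 1)

    def srh_factor(col):
        dof = df[col].nunique() - 1
        if ms_total == 0:  # all speeds tied: nothing to explain
            return {"H": 0.0, "df": dof, "p": 1.0}
        groups = df.groupby(col, observed=True)["rank"]
        ss = float(sum(g.size * (g.mean() - grand) ** 2 for _, g in groups))
        h = ss / ms_total
        return {"H": h, "df": dof, "p": float(stats.chi2.sf(h, dof))}

    out = {"srh_participant": srh_factor("participant"),
           "srh_signal": srh_factor("signal")}

    for col in ("participant", "signal"):
        gs = [g["speed"].to_numpy() for _, g in df.groupby(col, observed=True)]
        if ms_total == 0:
            out[f"kw_{col}"] = {"H": 0.0, "p": 1.0}
        else:
            kw = stats.kruskal(*gs)
            out[f"kw_{col}"] = {"H": float(kw.statistic), "p": float(kw.pvalue)}

    out["dunn_participant"] = _dunn(df, "participant")
    return out


def _dunn(df: pd.DataFrame, col: str) -> dict:
    """Dunn's pairwise rank-sum z tests with Holm adjustment."""
    n = len(df)
    ranks = df.groupby(col, observed=True)["rank"]
    means = ranks.mean()
    sizes = ranks.size()
    # tie correction for the rank variance
    _, counts = np.unique(df["speed"], return_counts=True)
    ties = float(np.sum(counts**3 - counts))
    var_base = n * (n + 1) / 12.0 - ties / (12.0 * (n - 1))
    levels = list(means.index)
    pairs, pvals = [], []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            a, b = levels[i], levels[j]
            se = np.sqrt(var_base * (1 / sizes[a] + 1 / sizes[b]))
            z = (means[a] - means[b]) / se if se > 0 else 0.0
            pairs.append((a, b))
            pvals.append(2 * stats.norm.sf(abs(z)))
    # Holm step-down
    order = np.argsort(pvals)
    adj = np.empty(len(pvals))
    running = 0.0
    m = len(pvals)
    for rank_i, idx in enumerate(order):
        running = max(running, (m - rank_i) * pvals[idx])
        adj[idx] = min(running, 1.0)
    return {f"{a}|{b}": float(p) for (a, b), p in zip(pairs, adj)}


# ---------------------------------------------------------------------------
# IED <-> SD comparison report
# ---------------------------------------------------------------------------

def _directions(fits, traveling_only=True) -> np.ndarray:
    if len(fits) and isinstance(fits[0], WaveFit):
        return np.array([f.direction_rad for f in fits
                         if f is not None and (f.is_traveling or not traveling_only)])
    return np.asarray(fits, dtype=float)


def _speeds(fits) -> np.ndarray:
    return np.array([f.speed_cm_s for f in fits
                     if f is not None and f.is_traveling])


def compare_ied_sd(ied_fits, sd_fits, iw_fit=None, seed=None,
                   n_perm: int = 1000) -> dict:
    """Full comparison of IED and SD traveling-wave populations.

    Accepts lists of WaveFit (traveling fits are used) or raw direction
    arrays.  Reports circular medians +/- circular SD, differences to the
    IW direction (absent on the penumbral pathway), bimodality of both
    distributions, per-sub-distribution speed and proportion comparisons,
    KLD(SD||IED) with its permutation null, and Watson-Williams /
    circular-median tests between the two direction sets.
    """
    rng = np.random.default_rng(seed)
    ied_dirs = _directions(ied_fits)
    sd_dirs = _directions(sd_fits)
    if ied_dirs.size < 60:
        raise ValueError("need >= 60 IED direction fits for bimodality analysis")
    if sd_dirs.size < 5:
        raise ValueError("need >= 5 SD direction fits")

    med_ied = circ.circular_median(ied_dirs)
    med_sd = circ.circular_median(sd_dirs)
    report: dict = {
        "n_ied": int(ied_dirs.size), "n_sd": int(sd_dirs.size),
        "ied_median_rad": med_ied, "ied_circ_sd_rad": circ.circular_sd(ied_dirs),
        "sd_median_rad": med_sd, "sd_circ_sd_rad": circ.circular_sd(sd_dirs),
        "ied_sd_median_diff_rad": circ.angle_difference(med_ied, med_sd),
    }
    if iw_fit is not None:
        iw_dir = iw_fit.direction_rad if isinstance(iw_fit, WaveFit) else float(iw_fit)
        report["iw_direction_rad"] = iw_dir
        report["ied_iw_median_diff_rad"] = circ.angle_difference(med_ied, iw_dir)

    bi_ied = circ.bimodality_index(ied_dirs, seed=rng.integers(2**31))
    bi_sd = circ.bimodality_index(sd_dirs, n_draw=min(60, sd_dirs.size),
                                  seed=rng.integers(2**31))
    report["ied_bimodal"] = bi_ied["is_bimodal"]
    report["ied_bimodality_index"] = bi_ied["index"]
    report["sd_bimodal"] = bi_sd["is_bimodal"]
    report["sd_bimodality_index"] = bi_sd["index"]
    mix_ied, mix_sd = bi_ied["mixture"], bi_sd["mixture"]
    report["ied_subdist_separation_rad"] = circ.angle_difference(
        mix_ied.mu_h[0], mix_ied.mu_h[1])
    report["sd_subdist_separation_rad"] = circ.angle_difference(
        mix_sd.mu_h[0], mix_sd.mu_h[1])

    # per-sub-distribution speed comparison (IED components) when speeds exist
    if len(ied_fits) and isinstance(ied_fits[0], WaveFit):
        trav = [f for f in ied_fits if f is not None and f.is_traveling]
        sp = np.array([f.speed_cm_s for f in trav])
        lab = mix_ied.assignments
        if lab.size == sp.size and min(np.sum(lab == 0), np.sum(lab == 1)) >= 3:
            report["ied_subdist_speed_p"] = compare_speeds(sp[lab == 0], sp[lab == 1])

    # proportion of dominant-mode events, IED vs SD (SD components aligned
    # to IED components by nearest mean direction)
    d00 = circ.angle_difference(mix_ied.mu_h[0], mix_sd.mu_h[0])
    d01 = circ.angle_difference(mix_ied.mu_h[0], mix_sd.mu_h[1])
    sd_dom = int(np.sum(mix_sd.assignments == (0 if d00 <= d01 else 1)))
    ied_dom = int(np.sum(mix_ied.assignments == 0))
    report["subdist_proportion_test"] = proportion_test(
        ied_dom, int(ied_dirs.size), sd_dom, int(sd_dirs.size))

    kld = circ.kld_permutation_test(sd_dirs, ied_dirs, n_perm=n_perm,
                                    seed=rng.integers(2**31))
    report["kld_bits"] = kld["kld_bits"]
    report["kld_p"] = kld["p"]

    report["watson_williams_p"] = circ.watson_williams([ied_dirs, sd_dirs])["p"]
    report["median_test_p"] = circ.circular_median_test(
        ied_dirs, sd_dirs, n_perm=n_perm, seed=rng.integers(2**31))
    return report


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def run_pipeline(config: dict, outdir) -> Path:
    """Run simulate -> detect -> waves -> stats -> seizure -> compare.

    ``config`` keys (all optional): ``seed``, ``n_perm``, ``ied`` (IEDSimSpec
    fields; ``direction_model`` given as mu/kappa/weights lists), ``seizure``
    (SeizureSimSpec fields, same convention), ``detection`` (DetectionConfig
    fields).  Writes the recording (HDF5), ground truth and fit tables
    (CSV), and a deterministic ``summary.json``; returns the run directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    n_perm = int(config.get("n_perm", 1000))
    rng = np.random.default_rng(seed)

    def build_dm(d):
        if isinstance(d, DirectionModel):
            return d
        return DirectionModel(mu=tuple(d["mu"]), kappa=tuple(d["kappa"]),
                              weights=tuple(d["weights"]))

    ied_cfg = dict(config.get("ied", {}))
    if "direction_model" in ied_cfg:
        ied_cfg["direction_model"] = build_dm(ied_cfg["direction_model"])
    ied_spec = IEDSimSpec(**ied_cfg)
    sz_cfg = dict(config.get("seizure", {}))
    if "sd_direction_model" in sz_cfg:
        sz_cfg["sd_direction_model"] = build_dm(sz_cfg["sd_direction_model"])
    sz_spec = SeizureSimSpec(**sz_cfg)
    det_cfg = DetectionConfig(**config.get("detection", {}))
    geometry = ArrayGeometry()

    # 1. simulate
    rec, truth = synth_ied_recording(geometry, ied_spec, seed=rng.integers(2**31))
    write_recording(rec, outdir / "interictal.h5")
    truth.to_csv(outdir / "ied_ground_truth.csv", index=False)

    # 2. detect + QA
    events = qa_filter(detect_ied_candidates(rec, det_cfg), rec, det_cfg)
    write_events(events, outdir / "ied_events.csv")

    # 3. traveling waves
    waves = classify_events(events, rec, n_perm=n_perm, seed=rng.integers(2**31))
    lfp_fits = [f for f in waves["fits"]["ied_lfp"] if f is not None]
    write_events(lfp_fits, outdir / "ied_wavefits_lfp.csv")
    mua_fits = [f for f in waves["fits"]["ied_mua"] if f is not None]
    write_events(mua_fits, outdir / "ied_wavefits_mua.csv")
    ied_dirs = np.array([f.direction_rad for f in lfp_fits if f.is_traveling])

    summary: dict = {"seed": seed, "n_events_detected": len(events),
                     "n_events_qa_pass": sum(e.qa_pass for e in events),
                     "wave_summary": waves["summary"]}

    # 4. directional statistics on traveling IEDs
    if ied_dirs.size >= 60:
        summary["hr_p"] = circ.hermans_rasson_test(ied_dirs, n_perm=n_perm,
                                                   seed=rng.integers(2**31))
        bi = circ.bimodality_index(ied_dirs, seed=rng.integers(2**31))
        summary["ied_bimodal"] = bi["is_bimodal"]
        summary["ied_bimodality_index"] = bi["index"]

    # 5. seizure
    sz_rec, sz_truth = synth_seizure_recording(geometry, sz_spec,
                                               seed=rng.integers(2**31))
    write_recording(sz_rec, outdir / "seizure.h5")
    char = characterize_seizure(sz_rec, n_perm=n_perm, seed=rng.integers(2**31))
    write_events(char.sd_fits, outdir / "sd_wavefits.csv")
    summary["seizure"] = {
        "true_class": sz_truth["class"],
        "classified": char.seizure_class,
        "phase_lock_p": char.phase_lock_p,
        "iw_p": char.iw_fit.p_value if char.iw_fit else None,
        "iw_direction_rad": char.iw_fit.direction_rad if char.iw_fit else None,
        "iw_speed_mm_s": char.iw_fit.speed_mm_s if char.iw_fit else None,
        "n_sd": len(char.sd_fits),
    }

    # 6. compare (IW-relative fields absent on the penumbral pathway)
    sd_trav = [f for f in char.sd_fits if f.is_traveling]
    if ied_dirs.size >= 60 and len(sd_trav) >= 5:
        iw = char.iw_fit if char.seizure_class == "recruited" else None
        summary["comparison"] = compare_ied_sd(
            lfp_fits, sd_trav, iw_fit=iw, seed=rng.integers(2**31), n_perm=n_perm)

    payload = _jsonable(summary)
    payload["config_hash"] = hashlib.sha256(
        json.dumps(_jsonable(config), sort_keys=True).encode()).hexdigest()[:16]
    with open(outdir / "summary.json", "w") as f:
        json.dump(payload, f, sort_keys=True, indent=2)
        f.write("\n")
    return outdir
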