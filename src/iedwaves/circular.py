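"""Directional statistics for traveling-wave direction distributions.

Implements the circular inference used throughout the pipeline: the
Hermans–Rasson permutation test of non-uniformity, von Mises mixture
fitting by EM, the permutation-Kuiper bimodality index, multi-sample
circular tests (Watson–Williams, common-median), and discrete circular
Kullback–Leibler divergence with a permutation null.

All angles are radians on [0, 2*pi); every statistic here is invariant to
a global rotation of the sample (exactly where the math is exact,
statistically for the permutation tests).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import special, stats

from .core_io import VonMisesMixtureFit, wrap_angle

__all__ = [
    "resultant_length",
    "circular_mean",
    "circular_sd",
    "circular_median",
    "angle_difference",
    "hermans_rasson_statistic",
    "hermans_rasson_test",
    "fit_vmm",
    "kuiper_statistic",
    "bimodality_index",
    "watson_williams",
    "circular_median_test",
    "kld_directions",
    "kld_permutation_test",
]

TWO_PI = 2.0 * np.pi

# weighting constant of the combined Hermans-Rasson statistic
# (Landler, Ruxton & Malkemper 2019 form)
HR_BETA = 2.895

KAPPA_MAX = 1e3


# ---------------------------------------------------------------------------
# descriptive circular statistics
# ---------------------------------------------------------------------------

def resultant_length(angles) -> float:
    """Mean resultant length R-bar of a circular sample."""
    a = np.asarray(angles, dtype=float)
    return float(np.hypot(np.cos(a).mean(), np.sin(a).mean()))


def circular_mean(angles) -> float:
    a = np.asarray(angles, dtype=float)
    return wrap_angle(np.arctan2(np.sin(a).mean(), np.cos(a).mean()))


def circular_sd(angles) -> float:
    """Circular standard deviation sqrt(-2 ln R-bar), radians."""
    r = resultant_length(angles)
    r = min(max(r, 1e-12), 1.0)
    return float(np.sqrt(-2.0 * np.log(r)))


def circular_median(angles) -> float:
    """Sample circular median: the direction minimizing mean angular deviation.

    Candidates are the data points themselves and their antipodes (the
    minimizer of the mean arc-distance lies at a data point or antipode).
    """
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ValueError("empty sample")
    cand = np.concatenate([a, a + np.pi])
    # arc distance pi - |pi - |theta - m||
    d = np.abs(a[None, :] - cand[:, None]) % TWO_PI
    dev = np.mean(np.pi - np.abs(np.pi - d), axis=1)
    return wrap_angle(cand[int(np.argmin(dev))])


def angle_difference(a: float, b: float) -> float:
    """Absolute angular difference in [0, pi]."""
    d = np.abs(a - b) % TWO_PI
    return float(min(d, TWO_PI - d))


# ---------------------------------------------------------------------------
# Hermans-Rasson test of circular non-uniformity
# ---------------------------------------------------------------------------

def hermans_rasson_statistic(angles) -> float:
    """Combined Hermans-Rasson statistic (pairwise form).

    Large values indicate departure from circular uniformity; the second
    (|sin|) term keeps power against antipodally bimodal alternatives where
    the resultant vector vanishes.
    """
    a = np.asarray(angles, dtype=float)
    return float(_hr_batch(a[None, :])[0])


def _hr_batch(samples: np.ndarray) -> np.ndarray:
    """HR statistic for each row of a (B, n) array of angles."""
    d = samples[:, :, None] - samples[:, None, :]
    ad = np.abs(d) % TWO_PI
    term1 = np.abs(ad - np.pi) - np.pi / 2.0
    term2 = np.abs(np.sin(d)) - 2.0 / np.pi
    n = samples.shape[1]
    return (term1 - HR_BETA * term2).sum(axis=(1, 2)) / n


def hermans_rasson_test(angles, n_perm: int = 1000, seed=None) -> float:
    """Permutation Hermans-Rasson test against circular uniformity.

    The null distribution is the statistic on ``n_perm`` uniform samples of
    the same size; the p-value uses the add-one estimator so it is never 0.
    """
    a = np.asarray(angles, dtype=float)
    n = a.size
    if n < 4:
        raise ValueError("Hermans-Rasson test needs at least 4 angles")
    rng = np.random.default_rng(seed)
    obs = hermans_rasson_statistic(a)
    n_ge = 0
    # chunk the uniform resamples to bound the (B, n, n) intermediate
    chunk = max(1, int(2_000_000 // max(n * n, 1)))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        null = _hr_batch(rng.uniform(0.0, TWO_PI, size=(b, n)))
        n_ge += int(np.sum(null >= obs))
        done += b
    return (1.0 + n_ge) / (n_perm + 1.0)


# ---------------------------------------------------------------------------
# von Mises mixture EM
# ---------------------------------------------------------------------------

def _a1(kappa):
    """Ratio I1(kappa)/I0(kappa), stable for large kappa."""
    return special.i1e(kappa) / special.i0e(kappa)


def _a1_inv(r: float) -> float:
    """Invert the Bessel ratio: find kappa with I1(k)/I0(k) = r.

    Best-Fisher series start, then Newton refinement; capped at KAPPA_MAX.
    """
    r = float(min(max(r, 0.0), 1.0 - 1e-12))
    if r < 1e-9:
        return 0.0
    if r < 0.53:
        k = 2 * r + r**3 + 5 * r**5 / 6
    elif r < 0.85:
        k = -0.4 + 1.39 * r + 0.43 / (1 - r)
    else:
        k = 1.0 / (r**3 - 4 * r**2 + 3 * r)
    for _ in range(25):
        a = _a1(k)
        # d/dk A(k) = 1 - A^2 - A/k
        da = 1.0 - a * a - (a / k if k > 0 else 0.5)
        if da <= 0:
            break
        step = (a - r) / da
        k -= step
        if k <= 0:
            k = 1e-8
        if abs(step) < 1e-12 * (1 + k):
            break
    return float(min(k, KAPPA_MAX))


def _vm_logpdf(angles, mu, kappa):
    # log I0(k) = log(i0e(k)) + k keeps large kappa finite
    return kappa * np.cos(angles - mu) - (np.log(2 * np.pi) + np.log(special.i0e(kappa)) + kappa)


def _em_once(a, h, mu0, kappa0, w0, max_iter, tol):
    n = a.size
    mu, kappa, w = np.array(mu0, float), np.array(kappa0, float), np.array(w0, float)
    prev_ll = -np.inf
    ll_path = []
    for _ in range(max_iter):
        logp = np.stack([np.log(w[k] + 1e-300) + _vm_logpdf(a, mu[k], kappa[k])
                         for k in range(h)])
        m = logp.max(axis=0)
        lse = m + np.log(np.exp(logp - m).sum(axis=0))
        ll = float(lse.sum())
        ll_path.append(ll)
        gamma = np.exp(logp - lse)  # (h, n) responsibilities
        nk = gamma.sum(axis=1)
        w = nk / n
        c = gamma @ np.cos(a)
        s = gamma @ np.sin(a)
        mu = np.arctan2(s, c) % TWO_PI
        rbar = np.hypot(c, s) / np.maximum(nk, 1e-300)
        kappa = np.array([_a1_inv(r) for r in rbar])
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            return mu, kappa, w, ll, ll_path, True
        prev_ll = ll
    return mu, kappa, w, prev_ll, ll_path, False


def fit_vmm(angles, h: int, seed=None, max_iter: int = 300, tol: float = 1e-8,
            n_restarts: int = 10) -> VonMisesMixtureFit:
    """Fit an h-component von Mises mixture (h in {1, 2}) by EM.

    Initialisation for h=2 uses the doubled-angle axis (robust for
    antipodal modes) plus random restarts; returns hard posterior-argmax
    assignments and the best log-likelihood fit.
    """
    a = wrap_angle(np.asarray(angles, dtype=float))
    a = np.atleast_1d(a)
    if h not in (1, 2):
        raise ValueError("h must be 1 or 2")
    if a.size < 10 * h:
        raise ValueError(f"need at least {10 * h} angles for h={h}")
    rng = np.random.default_rng(seed)

    if h == 1:
        mu = circular_mean(a)
        kappa = _a1_inv(resultant_length(a))
        mu_, ka_, w_, ll, path, conv = _em_once(a, 1, [mu], [kappa], [1.0], max_iter, tol)
        gamma = np.zeros(a.size, dtype=int)
        return VonMisesMixtureFit(h=1, mu_h=[float(mu_[0])], kappa_h=[float(ka_[0])],
                                  theta_h=[1.0], assignments=gamma,
                                  log_likelihood=ll, converged=conv)

    # h == 2: axis-based init + random restarts
    inits = []
    psi = 0.5 * np.arctan2(np.sin(2 * a).mean(), np.cos(2 * a).mean())
    inits.append(([psi % TWO_PI, (psi + np.pi) % TWO_PI], [2.0, 2.0], [0.5, 0.5]))
    for _ in range(max(0, n_restarts - 1)):
        mus = rng.choice(a, size=2, replace=False)
        wr = rng.uniform(0.3, 0.7)
        inits.append((list(mus), [1.0, 1.0], [wr, 1 - wr]))

    best = None
    for mu0, k0, w0 in inits:
        mu_, ka_, w_, ll, path, conv = _em_once(a, 2, mu0, k0, w0, max_iter, tol)
        if best is None or ll > best[3]:
            best = (mu_, ka_, w_, ll, conv)
    mu_, ka_, w_, ll, conv = best
    if not conv:
        warnings.warn("von Mises mixture EM did not converge; returning best fit so far")
    # hard assignments, component 0 = larger weight
    order = np.argsort(-w_)
    mu_, ka_, w_ = mu_[order], ka_[order], w_[order]
    logp = np.stack([np.log(w_[k] + 1e-300) + _vm_logpdf(a, mu_[k], ka_[k]) for k in range(2)])
    gamma = np.argmax(logp, axis=0)
    return VonMisesMixtureFit(h=2, mu_h=[float(m) for m in mu_],
                              kappa_h=[float(k) for k in ka_],
                              theta_h=[float(x) for x in w_],
                              assignments=gamma, log_likelihood=ll, converged=conv)


# ---------------------------------------------------------------------------
# Kuiper goodness of fit and bimodality index
# ---------------------------------------------------------------------------

def _vm_cdf_unit(angles, mu, kappa):
    """Probability-integral transform of angles under vM(mu, kappa) -> [0, 1]."""
    a = np.asarray(angles, dtype=float)
    if kappa == 0:
        return (a % TWO_PI) / TWO_PI
    centered = np.angle(np.exp(1j * (a - mu)))  # (-pi, pi]
    return stats.vonmises.cdf(centered, kappa)


def _kuiper_from_u(u: np.ndarray) -> np.ndarray:
    """Kuiper V = D+ + D- for each row of a (B, n) array of unit values."""
    u = np.sort(np.atleast_2d(u), axis=1)
    n = u.shape[1]
    i = np.arange(1, n + 1)
    d_plus = (i / n - u).max(axis=1)
    d_minus = (u - (i - 1) / n).max(axis=1)
    return d_plus + d_minus


def kuiper_statistic(angles, mu: float, kappa: float) -> float:
    """Kuiper V between the empirical sample and a vM(mu, kappa) model.

    V is invariant to the choice of circular origin, which makes it the
    appropriate two-sided statistic on the circle.
    """
    return float(_kuiper_from_u(_vm_cdf_unit(angles, mu, kappa))[0])


def bimodality_index(angles, n_draw: int = 60, n_rep: int = 1000, seed=None,
                     overall: VonMisesMixtureFit | None = None,
                     mixture: VonMisesMixtureFit | None = None) -> dict:
    """Permutation-Kuiper bimodality classification of a direction sample.

    Fits a single von Mises (overall) and a two-component mixture, then
    repeatedly draws ``n_draw`` directions and scores them with the Kuiper
    statistic against the corresponding fitted model (overall model draws
    from all angles; each sub-model draws from its assigned angles).  The
    index is the minimum over sub-models of (mean V overall - mean V sub):
    positive means two modes model the data better than one.
    """
    a = wrap_angle(np.asarray(angles, dtype=float))
    a = np.atleast_1d(a)
    if a.size < n_draw:
        raise ValueError(f"need at least n_draw={n_draw} angles, got {a.size}")
    rng = np.random.default_rng(seed)
    if overall is None:
        overall = fit_vmm(a, h=1, seed=rng.integers(2**31))
    if mixture is None:
        mixture = fit_vmm(a, h=2, seed=rng.integers(2**31))

    def mean_kuiper(pool, mu, kappa):
        replace = pool.size < n_draw
        if replace:
            warnings.warn("sub-distribution smaller than n_draw; sampling with replacement")
        draws = np.stack([rng.choice(pool, size=n_draw, replace=replace)
                          for _ in range(n_rep)])
        return float(_kuiper_from_u(_vm_cdf_unit(draws, mu, kappa)).mean())

    v_overall = mean_kuiper(a, overall.mu_h[0], overall.kappa_h[0])
    diffs = []
    for k in range(2):
        pool = a[mixture.assignments == k]
        if pool.size == 0:
            pool = a  # degenerate empty cluster: fall back to full sample
        diffs.append(v_overall - mean_kuiper(pool, mixture.mu_h[k], mixture.kappa_h[k]))
    index = float(min(diffs))
    return {"index": index, "is_bimodal": bool(index > 0),
            "v_overall": v_overall, "overall": overall, "mixture": mixture}


# ---------------------------------------------------------------------------
# multi-sample circular tests
# ---------------------------------------------------------------------------

def watson_williams(groups) -> dict:
    """Watson-Williams F test for equal mean directions across groups.

    Assumes comparable, reasonably large concentrations (kappa >~ 1); the
    standard correction factor 1 + 3/(8 kappa-hat) is applied.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 5 for g in gs):
        raise ValueError("need >= 2 groups of >= 5 angles each")
    p = len(gs)
    n_total = sum(g.size for g in gs)
    r_i = [g.size * resultant_length(g) for g in gs]
    pooled = np.concatenate(gs)
    r_all = n_total * resultant_length(pooled)
    rw = sum(r_i) / n_total
    kappa = _a1_inv(rw)
    corr = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0
    num = (n_total - p) * (sum(r_i) - r_all)
    den = (p - 1) * (n_total - sum(r_i))
    if den <= 0:
        return {"F": np.inf, "p": 0.0, "kappa": kappa}
    f_stat = corr * num / den
    p_val = float(stats.f.sf(f_stat, p - 1, n_total - p))
    return {"F": float(f_stat), "p": p_val, "kappa": kappa}


def _median_test_statistic(a, b):
    """Fisher common-median statistic: chi-square of side-of-median counts."""
    pooled = np.concatenate([a, b])
    m = circular_median(pooled)
    # side of the diameter through the pooled median
    side_a = np.sin(a - m) > 0
    side_b = np.sin(b - m) > 0
    table = np.array([[side_a.sum(), a.size - side_a.sum()],
                      [side_b.sum(), b.size - side_b.sum()]], dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    exp = row * col / table.sum()
    if np.any(exp == 0):
        return 0.0
    return float(((table - exp) ** 2 / exp).sum())


def circular_median_test(group_a, group_b, n_perm: int = 1000, seed=None) -> float:
    """Permutation test for a common circular median between two groups."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("need >= 5 angles per group")
    rng = np.random.default_rng(seed)
    obs = _median_test_statistic(a, b)
    pooled = np.concatenate([a, b])
    n_a = a.size
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if _median_test_statistic(perm[:n_a], perm[n_a:]) >= obs:
            count += 1
    return (1.0 + count) / (n_perm + 1.0)


# ---------------------------------------------------------------------------
# discrete circular Kullback-Leibler divergence
# ---------------------------------------------------------------------------

def _direction_hist(angles, n_bins, pseudocount):
    counts, _ = np.histogram(wrap_angle(np.asarray(angles, dtype=float)),
                             bins=n_bins, range=(0.0, TWO_PI))
    counts = counts.astype(float) + pseudocount
    return counts / counts.sum()


def kld_directions(angles_p, angles_q, n_bins: int = 18, pseudocount: float = 0.5,
                   base: float = 2.0) -> float:
    """KLD D(P || Q) between binned direction distributions, in bits.

    P is conventionally the seizure-discharge sample and Q the IED sample:
    the divergence is the extra information needed to encode SD directions
    with the IED direction code.  A Jeffreys pseudocount (default 0.5 per
    bin) avoids log 0; set pseudocount=0 for the raw plug-in estimate.
    """
    p = _direction_hist(angles_p, n_bins, pseudocount)
    q = _direction_hist(angles_q, n_bins, pseudocount)
    mask = p > 0
    if pseudocount == 0 and np.any(q[mask] == 0):
        return float(np.inf)
    return float(np.sum(p[mask] * (np.log(p[mask] / q[mask]) / np.log(base))))


def kld_permutation_test(angles_p, angles_q, n_bins: int = 18, n_perm: int = 1000,
                         seed=None, pseudocount: float = 0.5) -> dict:
    """Permutation test of the observed KLD against a pooled-resampling null.

    Null divergences come from randomly relabelling the pooled directions
    into pseudo-P/pseudo-Q sets of the original sizes; p is the add-one
    fraction of null KLDs at least as large as the observed one.
    """
    p_ang = np.asarray(angles_p, dtype=float)
    q_ang = np.asarray(angles_q, dtype=float)
    if p_ang.size == 0 or q_ang.size == 0:
        raise ValueError("both samples must be nonempty")
    rng = np.random.default_rng(seed)
    obs = kld_directions(p_ang, q_ang, n_bins=n_bins, pseudocount=pseudocount)
    pooled = np.concatenate([p_ang, q_ang])
    n_p = p_ang.size
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        null = kld_directions(perm[:n_p], perm[n_p:], n_bins=n_bins,
                              pseudocount=pseudocount)
        if null >= obs:
            count += 1
    p_val = (1.0 + count) / (n_perm + 1.0)
    return {"kld_bits": obs, "p": p_val}
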