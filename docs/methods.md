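# Methods

`iedwaves` implements the spatiotemporal analysis of interictal
epileptiform discharges (IEDs) and seizures recorded on Utah-style
microelectrode arrays (UEA; 10x10 penetrating electrodes, 400 µm pitch,
4x4 mm footprint), together with a synthetic-data generator that emulates
the statistical structure of such recordings so every stage can be
validated against ground truth.

## Coordinate and unit conventions

Electrodes live on a 0-based (row, col) grid with `x = col * pitch_mm`,
`y = row * pitch_mm`. Angles are counter-clockwise from +x, stored in
radians on `[0, 2π)` (reports render degrees). Times are seconds; plane-fit
gradients are ms/mm, so a delay-gradient norm `g` gives speed
`100 / g` cm/s (the ictal wavefront is additionally reported in mm/s,
`1000 / g`). Bad channels stay in the geometry and are excluded from fits,
so channel indices remain stable.

## IED detection

Each channel is resampled to 400 Hz (polyphase, anti-aliased), zero-phase
band-passed 20–40 Hz (4th-order Butterworth), and thresholded at 8
standard deviations of the filtered trace. Within-channel detections
closer than 250 ms collapse to the earliest; detections co-occurring
within a 250 ms consensus window (merged transitively) on ≥ 10 electrodes
become one array event timed at the median contributing-channel time.

Two readings of "standard deviation of the recording segment" are
supported: the default is the robust estimate `1.4826 × MAD` of the full
filtered trace, so that the events themselves do not inflate the
threshold; plain `np.std` is available via `DetectionConfig(sd_mode="plain")`.
Because the threshold is relative to the trace's own spread, the detector
presumes genuine background noise (segments ≥ 10 s); a literally
noise-free trace is outside its operating range and is exercised in tests
through the extraction and fitting stages directly.

Post-detection QA (a) drops channel extremum times outside ±25 ms of the
across-channel median (the channel is dropped, not the event; an event
left with < 10 channels fails QA), and (b) flags events whose across-array
voltage range exceeds `Q3 + 2×IQR` of the session's event-range
distribution; the degenerate `IQR = 0` case flags nothing.

Multiunit events are negative peaks of the 0.3–3 kHz band below −4× a
noise scale: `median(|x|)/0.6745` (default) or RMS — both conventions
appear in practice and are interchangeable on Gaussian-dominated traces.
The 3 kHz corner requires `fs ≥ 7.5 kHz`.

## Traveling-wave measurement

For each event, per-channel LFP-minimum times (parabolically interpolated
between samples) inside a focused ±25 ms window are fit with a plane
`t = β₀ + βₓx + βᵧy`. The default loss is least absolute deviation
(IRLS), robust to outlying channel timings, with OLS available; the two
agree on clean data. Direction is `atan2(βᵧ, βₓ)`, speed `100/‖β‖` cm/s.
MUA-based fits use every spike within ±50 ms of the median LFP trough as
its own (x, y, t) point.

Significance comes from a spatial permutation test: the plane's OLS R² is
compared with R² over `n_perm = 1000` random permutations of electrode
positions; `p = (1 + #{R²_perm ≥ R²_obs}) / (n_perm + 1)` (the add-one
estimator, so p is never 0 and respects the `1/(n_perm+1)` floor). R² was
chosen over the raw gradient norm because it is invariant to time units
and directly expresses "slope significantly different from zero"; events
with `p < 0.05` are traveling waves.

## Directional statistics

* **Non-uniformity** — the combined Hermans–Rasson statistic (pairwise
  form, weighting constant 2.895), which keeps power against antipodally
  bimodal alternatives where the Rayleigh test fails; p-values from 1000
  uniform resamples of the same n.
* **Mixtures** — one- or two-component von Mises mixtures by EM
  (log-domain responsibilities; κ by Bessel-ratio inversion with Newton
  refinement, capped at 10³; initialisation from the doubled-angle axis
  plus random restarts; tolerance 1e-8 on the log-likelihood, which is
  monotone). Hard assignments are posterior argmax.
* **Bimodality index** — for the overall (h=1) and each mixture
  sub-distribution, 1000 draws of 60 directions are scored with the
  rotation-invariant Kuiper statistic V against the corresponding fitted
  von Mises; V is averaged per model and the index is the minimum of
  (mean V overall − mean V sub). Positive ⇒ bimodal. Sub-distribution
  draws come from the cluster-assigned angles (not the fitted model); a
  cluster smaller than 60 is drawn with replacement and flagged.
* **Between-sample tests** — Watson–Williams F (with the standard
  `1 + 3/8κ` correction; requires comparable, reasonably concentrated
  groups), and a permutation common-median test (chi-square of
  side-of-pooled-median counts, labels permuted).
* **KLD** — directions are binned into 18 equal bins on `[0, 2π)` (bin 0
  starts at angle 0, half-open bins); `D(SD‖IED)` in bits with a Jeffreys
  pseudocount of 0.5 per bin (direction, log base, and pseudocount are all
  configurable; the closed-form checks use pseudocount 0). The permutation
  null relabels the pooled directions into pseudo-SD/pseudo-IED sets of
  the original sizes.

## Seizure characterization

Per-channel firing rates are Gaussian-kernel estimates (kernel widths read
as standard deviations: 250 ms for the slow ictal-wavefront estimate,
25 ms for discharge detection; each spike integrates to 1, so units are
Hz). The ictal wavefront (IW) is the plane fit to per-channel times of
maximum slow rate within the seizure window (onset to onset + 120 s);
seizure discharges (SDs) are array-mean fast-rate peaks with prominence
≥ 2× the window's median rate and ≥ 100 ms separation, each plane-fit from
local per-channel rate peaks (raw spike times optional). Discharges after
an annotated secondary generalization are excluded. Phase-locked firing is
a Hermans–Rasson test on spike phases relative to the analytic-signal
phase of the 1–30 Hz array-mean LFP (the band is configurable; spike
counts are capped at 500 by random subsampling to bound the O(n²)
statistic). A recording is **recruited** iff the IW fit and the
phase-locking are both significant at 0.05, else **penumbral**.

## Synthetic data: what it emulates, and what it does not

IEDs are biphasic templates (sharp 20 ms FWHM negative trough, then a
150 ms slow wave at 0.4 relative amplitude — the sharp trough carries the
20–40 Hz power the detector filters for) placed on every channel with
trough at `t₀ + (x cosφ + y sinφ)/v`. Directions follow a von Mises
mixture (default antipodal: separation 177.9°, κ = 4, weights 0.7/0.3);
speeds are log-normal (median 50 cm/s, σ = 0.4, spanning the observed
~20–135 cm/s range). Noise is Gaussian, low-passed at 100 Hz, per-channel
independent plus a 0.2-weight common mode; SNR is defined as the
band-limited (20–40 Hz) trough amplitude in multiples of the band-limited
noise SD, so the 8×SD threshold is directly interpretable. MUA is planted
as event times (Poisson counts locked to troughs with 5 ms jitter over a
0.5 Hz background); no spike waveforms are synthesized.

Recruited seizures plant planar recruitment times at a slow IW speed
(default 0.5 mm/s) marked by a firing burst then a tonic plateau, followed
— once the array is recruited — by a train of fast SDs (default 250 at
2 Hz) with planar LFP deflections and phase-locked multiunit bursts. The
SD direction model shares the IED antipodal axis (dominant mode opposite
the IW) but is more stereotyped: tighter (κ = 10) and more
dominant-skewed (0.8/0.2). This mirrors the empirical picture in which
IED and SD distributions share an axis while differing significantly in
sub-distribution proportions, and it is what makes the between-
distribution KLD detectably above its pooled-permutation null. Penumbral
recordings carry a seizure-like rhythm (sinusoid + harmonic — an
explicitly synthetic stand-in, since penumbral fields are not modeled
quantitatively) with unmodulated background firing.

Simulated segments compress inter-event spacing relative to clinical IED
rates (~0.4/min) so that desk-scale segments carry enough events;
per-event statistics are unaffected while events stay separated by much
more than the consensus window. Default problem sizes (300 IEDs, one
seizure with 250 SDs, 500–1000 permutations) were chosen so a full run
completes in about a minute on one CPU. What passing tests show is that
the pipeline recovers planted planar waves, mixture structure, and
recruitment classes under realistic noise; they do not certify behavior
under artifacts the generator omits (electrode drift, line noise, EMG,
non-planar or curved wavefronts, non-stationary noise).

## Numerical choices and degenerate inputs

* Ties in trough location break to the earliest sample; sub-sample trough
  times come from parabolic interpolation.
* Zero delay gradient ⇒ speed undefined (NaN), never traveling; constant
  times ⇒ R² = 0 and p ≈ 1.
* A flat channel is excluded from extraction; a flat mean LFP makes spike
  phase ill-defined and the phase-lock test returns an absent result.
* All-tied speeds make the rank ANOVA return p = 1 throughout rather than
  0/0.
* κ estimates cap at 10³ (point-mass samples); mixture EM that exhausts
  iterations returns the best fit with a warning flag.
* The two-way rank analysis is the Scheirer–Ray–Hare extension of
  Kruskal–Wallis (there is no standard "two-way Kruskal–Wallis"), reported
  alongside per-factor one-way Kruskal–Wallis and Holm-adjusted Dunn
  post-hoc contrasts.
* Cluster-based permutation tests score clusters by mass (summed |t|), the
  continuous cluster statistic; integer cluster extent makes the null
  distribution too discrete to calibrate at α = 0.05.
* Multiple comparisons across simulated participants/seizures are not
  globally corrected; each test uses α = 0.05.

## Known limitations

Plane fits ignore wavefront curvature and acceleration; the IW model
assumes a single linear front. The bimodality index depends on the 60-draw
/ 1000-repetition design and loses power below ~100 directions. The
Watson–Williams test assumes comparable concentrations; for strongly
bimodal samples only the sub-distribution comparisons are meaningful.
Vendor raw formats (NSx/NEV), EDF and NWB are out of scope — recordings
enter through the package's HDF5 layout.
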