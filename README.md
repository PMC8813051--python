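# iedwaves

Traveling-wave analysis of interictal epileptiform discharges (IEDs) on
microelectrode arrays.

IEDs — the brief, large field-potential events that punctuate the EEG of
people with epilepsy between seizures — are not just local blips: on a
10×10 Utah-style microelectrode array (4×4 mm) they sweep across the
cortical surface as planar traveling waves, typically bidirectionally
along a fixed axis that echoes the propagation of seizure discharges (SDs)
and opposes the slow expansion of the seizure core (the ictal wavefront,
IW). `iedwaves` provides the complete measurement chain for that analysis,
for electrophysiologists working with array recordings and for
methodologists who need a tested reference implementation:

* **Detection** — array-consensus IED detection (400 Hz resample, 20–40 Hz
  zero-phase Butterworth, 8×SD threshold, ≥10-electrode consensus within
  250 ms) with amplitude/timing QA, plus multiunit (MUA) event detection.
* **Wave measurement** — for each event, a plane fit to per-channel LFP
  minimum times (or MUA times), `t = β₀ + βₓx + βᵧy`, with direction
  `atan2(βᵧ, βₓ)`, speed `100/‖(βₓ,βᵧ)‖` cm/s (β in ms/mm), and a spatial
  permutation test on R²: an event is a *traveling wave* when its slope
  beats 1000 electrode-position permutations (p < 0.05).
* **Directional statistics** — Hermans–Rasson permutation tests of circular
  non-uniformity, von Mises mixture fitting by EM (μ_h, κ_h, θ_h; h ≤ 2),
  a permutation-Kuiper bimodality index, Watson–Williams and circular
  median tests, and the discrete circular Kullback–Leibler divergence
  D(SD‖IED) in bits with a pooled-permutation null.
* **Seizure characterization** — ictal-wavefront plane fits on slow
  (250 ms kernel) firing-rate peaks, SD detection on fast (25 ms kernel)
  rate peaks, spike–LFP phase-locking tests, and the recruited/penumbral
  classification.
* **Synthetic data** — a generator that plants planar traveling IEDs,
  trough-locked Poisson MUA, and recruited or penumbral seizures with full
  ground truth, so every stage above is testable without patient data.

See `docs/methods.md` for the underlying models, parameter choices and
limitations.

## Worked example

```python
import numpy as np
from iedwaves import (ArrayGeometry, IEDSimSpec, synth_ied_recording,
                      detect_ied_candidates, qa_filter, classify_events,
                      hermans_rasson_test, fit_vmm, bimodality_index)

geometry = ArrayGeometry()                      # 10x10 grid, 0.4 mm pitch
spec = IEDSimSpec(n_ieds=100)                   # antipodal directions, snr 12
rec, truth = synth_ied_recording(geometry, spec, seed=0)

events = qa_filter(detect_ied_candidates(rec), rec)
print(f"detected {len(events)} events ({sum(e.qa_pass for e in events)} pass QA)")

res = classify_events(events, rec, n_perm=1000, seed=1)
s = res["summary"]["ied_lfp"]
print(f"traveling waves: {s['n_traveling']}/{s['n_fit']} "
      f"({100*s['fraction_traveling']:.1f}%)")

dirs = np.array([f.direction_rad for f in res["fits"]["ied_lfp"]
                 if f is not None and f.is_traveling])
print(f"non-uniform directions: HR p = {hermans_rasson_test(dirs, seed=2):.4g}")

mix = fit_vmm(dirs, h=2, seed=3)
mu = np.rad2deg(mix.mu_h)
print(f"mixture modes at {mu[0]:.1f} and {mu[1]:.1f} deg, "
      f"weights {mix.theta_h[0]:.2f}/{mix.theta_h[1]:.2f}")

bi = bimodality_index(dirs, seed=4)
print(f"bimodality index = {bi['index']:.3f} -> "
      f"{'bimodal' if bi['is_bimodal'] else 'unimodal'}")
```

Output:

```
detected 100 events (97 pass QA)
traveling waves: 97/97 (100.0%)
non-uniform directions: HR p = 0.000999
mixture modes at 187.0 and 351.5 deg, weights 0.66/0.34
bimodality index = 0.004 -> bimodal
```

All 100 planted discharges are recovered (three fail amplitude QA), every
fitted event beats its spatial-permutation null, and the direction
distribution is detected as non-uniform and antipodally bimodal: the two
mixture modes sit 164.5° apart with the planted 0.7/0.3 weight split
recovered as 0.66/0.34. The positive bimodality index says two von Mises
sub-distributions out-predict a single one on held-out draws.

The same stages are scriptable from the shell:

```bash
iedwaves simulate --kind interictal --seed 0 --out rec.h5
iedwaves detect rec.h5 --out events.csv
iedwaves waves rec.h5 events.csv --out fits.csv
iedwaves stats fits.csv --out stats.json
iedwaves run --seed 11 --out rundir     # full end-to-end pipeline
```

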