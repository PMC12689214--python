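# tagshift

SSVEP frequency-tagging analysis of covert attention shifts in a
four-arc probabilistic spatial-cueing experiment.

Four arcs around fixation flicker at 18/21/24/27 Hz, each driving a
steady-state visual evoked potential (SSVEP) whose amplitude tracks
attentional facilitation of that arc. A central cue points at one arc
while the display switches to a color configuration in which an uncued
arc may share the cued arc's color. `tagshift` implements the complete
analysis chain needed to ask whether attention to the cued location
spreads to same-colored objects, and when:

* deterministic trial-schedule construction with exact class counts
  (360/640 event/no-event, 120 late-event, 168 pre-cue-event trials on
  the default 1000-trial session);
* a synthetic-data generator producing 64+4-channel epoched EEG
  (−1500…+2200 ms, 256 Hz) with known per-condition amplitude dynamics,
  1/f background noise, ocular artifacts, and per-trial behavior;
* epoch cleaning: linear detrending, 25 µV EOG rejection, per-trial
  bad-channel detection with spherical-spline interpolation, and the
  surface-Laplacian (CSD) transform;
* FFT spectra at 1/3 Hz resolution with per-subject/per-frequency
  electrode selection (best posterior-cluster channel + 4 neighbors)
  and peak-vs-sideband SNR;
* Gabor-energy amplitude envelopes (spectral half-FWHM 1 Hz ⇒ temporal
  half-FWHM 220.636 ms) expressed as percent change from the
  −720…−220 ms baseline, collapsed across tag frequencies per
  condition;
* statistics: cluster-sum permutation running t-tests (sign-flip,
  max-cluster null), JZS Bayes-factor time courses (Cauchy r = 0.71,
  null acceptance at BF₁₀ < 0.33), jackknife onset latencies (85 %
  base-to-peak criterion, Smulders back-transform), window-averaged
  contrasts, Greenhouse-Geisser rm-ANOVA with Holm correction, and
  noncentral-t power analysis.

The generator is first-class, tested code: every downstream stage is
validated against its known ground truth. See `docs/methods.md` for
the model, parameter defaults, and numerical choices.

## Worked example

```python
from tagshift.design import DesignParams, build_schedule
from tagshift.inference import apriori_n
from tagshift.envelope import GaborKernel
from tagshift.pipeline import run_subject

print("planned sample size:", apriori_n(0.66, power=0.9))
k = GaborKernel(center_hz=18.0)
print(f"Gabor temporal half-FWHM: {k.temporal_half_fwhm_ms:.3f} ms")

schedule = build_schedule(DesignParams(seed=0))
t = schedule.trials
print(f"trials: {len(t)}, with events: {t.has_postcue_event.sum()}, "
      f"late events: {t.has_late_event.sum()}, "
      f"pre-cue events: {t.has_precue_event.sum()}")

tc, behavior = run_subject(seed=42, design_params=DesignParams(n_trials=250))
window = (tc.times >= 0.75) & (tc.times <= 1.25)
for cond, trace in tc.traces.items():
    print(f"{cond:>18s}: {trace[window].mean():+6.1f} % plateau modulation")
```

prints

```
planned sample size: 27
Gabor temporal half-FWHM: 220.636 ms
trials: 1000, with events: 360, late events: 120, pre-cue events: 168
        cued_match:  +30.8 % plateau modulation
              cued:  +35.0 % plateau modulation
      uncued_match:  +20.7 % plateau modulation
  uncued_non_match:   +2.9 % plateau modulation
            uncued:  +13.1 % plateau modulation
```

The sample size is the noncentral-t inversion at d = 0.66, α = 0.05
(two-tailed), power 0.90. The plateau numbers are one simulated
subject's percent SSVEP modulation averaged over 750–1250 ms: the cued
arc and the same-colored uncued arc are strongly enhanced, the
non-matching uncued arcs much less — the generator's feature-spread
pattern, recovered through cleaning, CSD, electrode selection and
Gabor filtering. Single-subject estimates scatter by a few percentage
points around the generating truth (30/30/18/10/14 %); group means are
unbiased.

A thin CLI mirrors the library: `tagshift design`, `tagshift simulate`,
`tagshift study`, `tagshift behavior` (see `--help`).

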