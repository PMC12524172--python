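# opmpipe

Analysis pipeline for wearable OPM-MEG (optically pumped magnetometer
magnetoencephalography) studies of movement and rest — built around the
markers used to compare people with multiple sclerosis against controls:
the rise gradient of the post-movement beta rebound, the visual gamma
response, resting-state relative beta power, and orthogonalised
amplitude-envelope-correlation (AEC) connectomes.  A forward simulator
generates complete synthetic cohorts (triaxial sensor arrays, task and
resting recordings, motion-capture traces, parcellations) with known
planted effects, so every stage of the pipeline is testable without any
data download.

## What it computes

From a continuous 375-Hz triaxial magnetometer recording with sensor
geometry, trigger events and a 120-Hz motion trace:

1. **Preprocessing** — powerline notches (50/100/150 Hz), 1–150 Hz
   band-pass (4th-order Butterworth, zero phase), Welch-power bad-channel
   rejection, homogeneous field correction
   `M = I − N(NᵀN)⁻¹Nᵀ` over the channel orientation matrix N.
2. **Movement events** — finger speed `|d(x,y,z)/dt|` from the
   motion trace (7-Hz low-passed); per trial, the first local minimum after
   the second speed peak defines movement offset (t = 0).
3. **Beamforming** — LCMV with unit gain, `w = C⁻¹l/(lᵀC⁻¹l)`, covariance
   Tikhonov-regularised by 5 % of λ_max, orientation = leading generalised
   eigenvector of `(LᵀC⁻¹L, LᵀC⁻²L)` in the tangential plane of a
   spherical-conductor forward model (Sarvas closed form).  Pseudo-T
   contrast images on a 4-mm grid; virtual electrodes from broadband
   weights.
4. **Spectral** — 26-band Hilbert-envelope time-frequency spectrograms
   `R(t,f) = (A(t,f) − B(f))/B(f)`, single-band envelope curves, Welch
   relative beta power.
5. **Connectivity** — pairwise time-domain orthogonalisation, Hilbert
   envelopes downsampled 375→75 Hz, Pearson correlation over all
   n(n−1)/2 region pairs (3321 for 82 regions); 266-edge thresholding and
   network connectivity strength.
6. **Statistics** — rebound-gradient fit between the 0 % and 75 % crossings
   of the group-average envelope, label-permutation group tests (empirical
   p = (1 + #{null ≥ obs})/(n+1)), Wilcoxon signed-rank / rank-sum tests,
   Bonferroni correction (α/4).

See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example

One synthetic control subject, end to end (the output block below is what
this script actually printed):

```python
import numpy as np
import opmpipe as op
from opmpipe import beamform, motion, preprocess, spectral, stats

array = op.make_sensor_array(n_sensors=32, seed=0)
truth = op.default_ground_truth(seed=0, n_regions=14)
rec, trace = op.simulate_visuomotor_dataset(array, truth, n_trials=60,
                                            seed=7, group="control", snr=5.0)

rec = preprocess.notch_filter(rec)
rec = preprocess.bandpass_filter(rec, 1.0, 150.0)
rec.bad_channels |= preprocess.detect_bad_channels(rec)
rec, _ = preprocess.homogeneous_field_correction(rec)

speed = motion.finger_speed(motion.upsample_trace(trace, rec.sampling_rate))
onsets = rec.event_times("stimulus_onset")
offsets, _ = motion.detect_movement_offsets(
    speed, [(t + 1.7, t + 3.3) for t in onsets])

trials = preprocess.reject_bad_trials(
    preprocess.segment_trials(rec, offsets, (-1.0, 4.0)))
grid = beamform.make_grid(array, spacing=0.008)
image = beamform.pseudo_t_image(trials, (13, 30), (-1, 0), (0.5, 1.5),
                                grid=grid, spacing=0.008, mode="noise")
peak = beamform.find_peak_location(image, sign="min")

ve = beamform.extract_virtual_electrode(trials, peak, band=(13, 30))
curve = spectral.trial_envelope_curve(ve.data, rec.sampling_rate,
                                      trials.times, (13, 30), (3.0, 4.0))
fit = stats.rebound_gradient(curve, (0.0, 2.0))
```

Output:

```
recording: 96 channels, 300 s at 375 Hz
movement offsets detected: 60 (0 undetected)
trials kept: 54 of 59
beta ERD peak at [-0.032 -0.008  0.048] m (3.6 mm from the planted motor source)
rebound rise gradient: 0.715 /s (planted: 0.60 /s), fit window 0.35-0.80 s, rebound peak 0.48
```

The beta power-decrease image localises the planted motor source to within
half a grid step, and the single-subject rebound gradient recovers the
planted 0.6 s⁻¹ up to envelope sampling noise (the group statistics average
this noise away; see the power suites).

Cohort-level runs are driven by a single config:

```python
from opmpipe.pipeline import PipelineConfig, run_visuomotor, run_resting
results = run_visuomotor(PipelineConfig(seed=1))
print(results["tests"]["rebound_gradient_sitting"].p)
```

or from the shell: `opmpipe run-all --seed 1 --out results/`
(`opmpipe simulate` writes a cohort to disk in a BIDS-like layout;
`opmpipe motion-events` annotates a dataset with detected offsets).

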