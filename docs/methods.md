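# Methods

`opmpipe` analyses wearable (optically pumped magnetometer, OPM) MEG
recordings from a visuomotor task and from rest, and ships a forward
simulator that generates complete synthetic cohorts with known planted
effects.  This note documents the models, the numerical choices, and what
the synthetic data do and do not establish.

## Forward model

The magnetic field of a current dipole inside a spherically symmetric
volume conductor is computed with the closed-form solution (Sarvas
formula): with the conductor centred at the origin, a dipole **Q** (A·m) at
**r₀** and field point **r**,

    a = r − r₀,  F = a (r a + r² − r₀·r)
    ∇F = (a²/r + a·r/a + 2a + 2r) r − (a + 2r + a·r/a) r₀
    B(r) = μ₀ / (4π F²) [ F (Q × r₀) − ((Q × r₀)·r) ∇F ]

This replaces the realistic single-shell boundary-element model used in
practice for real anatomy.  The spherical form was chosen deliberately: it
is exact for the geometry the simulator generates, and it is checkable
against a fully independent oracle (the test suite reconstructs **B** from
the magnetic scalar potential, obtained by quadrature of the Biot–Savart
radial field along an outward ray, and agrees to ~1e-10 relative).  Two
properties follow analytically and are enforced in tests: radial dipoles
are externally silent, and the field is independent of the conductor
radius.  Consequence: all source models in the package are tangential, and
the beamformer's orientation search is restricted to the tangential plane.

Triaxial sensors are modelled as three orthonormal measurement axes
(radial + two tangential) per sensor position; a 64-sensor helmet gives
192 channels.  Sensors are laid out on a Fibonacci lattice covering the
upper 57.5 % of the scalp sphere (radius 0.095 m by default).

## Synthetic cohorts

The generator plants, per cohort:

- a **motor source** whose beta-band (13–30 Hz) envelope drops by the ERD
  depth during the finger movement and then rises linearly at the planted
  *rebound gradient* (relative amplitude per second) to a rebound peak,
  holding briefly and decaying back to baseline before the 3–4 s baseline
  window;
- a **visual source** whose gamma-band (35–70 Hz) envelope is raised by the
  planted *gamma gain* during the 2-s visual stimulation;
- 1/f background sources (spectrally shaped white noise, exponent 1) at
  random interior locations, white sensor noise, and optional spatially
  uniform interference;
- a five-marker **motion trace** at 120 Hz in which the index-finger marker
  performs one abduction–adduction per trial as two raised-cosine velocity
  bumps, with speed exactly zero from the planted movement offset;
- **resting-state regional sources** at parcellation centroids whose
  spectral beta fraction matches a per-region target and whose beta
  envelopes are log-normally modulated; planted pairs share a slow latent
  factor.

Task sources are amplitude-modulated band-limited noise (stochastic
carrier × deterministic envelope), matching the induced, non-phase-locked
character of beta/gamma responses.  A `carrier="constant_envelope"` option
(narrowband FM with exactly unit Hilbert amplitude) exists for
envelope-recovery oracles, where the Rayleigh fluctuation of a Gaussian
carrier would dominate the comparison.

### Default effect sizes (generator design choices)

The emulated study reports its group effects only qualitatively, so the
planted magnitudes are this package's own choices, fixed once:

| parameter | default | rationale |
|---|---|---|
| rebound gradient, control / patient | 0.6 / 0.3 s⁻¹ | ratio 0.5, "slower rise" in patients |
| ERD depth | 0.20 | movement-locked beta drop |
| rebound peak | 0.35 | a taller rebound lengthens the 0–75 % fit window, stabilising the gradient statistic at 60 trials |
| gamma gain, control / patient | 0.30 / 0.15 | halved visual gamma response |
| beta fractions | 0.35–0.45 sensorimotor, 0.15–0.30 elsewhere | sensorimotor beta dominance |
| envelope modulation depth | 0.85, clipped at 3× | see below |
| standing beta-fraction factor (patients) | 0.8 | posture-dependent beta drop |
| sensor SNR (strongest channel RMS / noise RMS) | 5 task, 2 rest | clearly detectable single-subject responses |

The resting envelope modulation is log-normal, `exp(m z − m²/2)` with a
slow (≤ 2.5 Hz) Gaussian latent `z`.  Two numerical points: (i) the latent
correlation of a planted pair is corrected for the log-normal transform
(`ρ_z = log(1 + ρ(e^{m²} − 1))/m²`) so the *envelope* correlation equals
the planted ρ; (ii) the envelope is clipped at 3× baseline because
unclipped log-normal tails make sample correlations of *independent* pairs
unstable (a single burst can fabricate |r| ≈ 0.3 over minutes of data).

## Preprocessing

IIR notch filters (2-Hz bandwidth) at 50/100/150 Hz, then a 4th-order
Butterworth band-pass (1–150 Hz).  All filters run forward–backward
(zero phase, doubling the effective order): the headline statistic compares
envelope *timing* across groups, which group delay must not bias.

Bad channels: total Welch power below 0.01× or above 100× the channel
median.  These loose ratios replace per-spectrum visual inspection; they
catch dead sensors and broken connections, not borderline cases.

Homogeneous field correction (HFC): with N the channels × 3 matrix of
orientation axes, data are premultiplied by `M = I − N(NᵀN)⁻¹Nᵀ`,
annihilating exactly the 3-dimensional uniform-field subspace.  A dipolar
signal loses its own small uniform component (~5 % RMS for the 64-sensor
cap; more for sparser test arrays).

Epoching follows the half-open convention `[t₀+w₀, t₀+w₁)` on the sample
grid, so a (−1, 4) s window at 375 Hz is exactly 1875 samples.  Bad trials:
a trial is rejected when, at any channel, its variance exceeds the
across-trial `mean + 3·std` of variance at that channel.  The source text
for this rule lacks a reference point ("exceeds three times the standard
deviation"); both the `mean + 3σ` reading (default) and the absolute `3σ`
reading are implemented.  Note a structural property of the default rule:
because a lone outlier inflates its own threshold, it is only detectable
among more than ~10 trials/segments; with the study's 60 trials or 60
segments this is immaterial.  Resting recordings are cut into 10-s
segments and the same rule applied.

Stereotyped-artifact removal replaces manual ICA inspection with a
reproducible rule: FastICA (fixed seed), remove every component whose time
course correlates at |r| ≥ 0.6 with a provided ECG/EOG reference trace,
reconstruct the rest.  Without a reference the stage is an identity
transform with a warning.

## Movement events

Marker trajectories are linearly upsampled to 375 Hz; the index-finger
velocity components are combined in quadrature into a scalar speed, 7-Hz
low-pass filtered (4th order, zero phase).  Per trial the two largest speed
peaks above 10 % of the window maximum are found in temporal order; the
movement offset (t = 0 for the beta analysis) is the first local minimum
after the second peak, with a documented fallback (first sample below 5 %
of the second peak) for monotone decays.  Windows with fewer than two peaks
are excluded and logged.  Under realistic noise the first-local-minimum
rule resolves the stop to a few samples, not to one: the stop region is
flat, so its minimum position carries noise jitter of order the filter's
correlation time (~10–20 ms).

## Beamforming

LCMV with unit gain: `w = C⁻¹l / (lᵀC⁻¹l)`.  The data covariance is
computed from all good data of the experiment in the analysis band and
Tikhonov-regularised by 5 % of its largest eigenvalue.  Source orientation
maximises projected SNR: the leading generalised eigenvector of
`(LᵀC⁻¹L, LᵀC⁻²L)` over the tangential plane, with a fall-back to the
leading eigenvector of `LᵀC⁻¹L` when the pencil is degenerate (isotropic
noise), and a deterministic sign.

Pseudo-T images contrast trial-summed projected variance between an active
and a control window.  Two normalisations are implemented:

- `contrast`: `(P_a − P_c)/(P_a + P_c)`, bounded in [−1, 1] — used for
  group-averaged display (each subject image divided by its largest
  absolute deflection before averaging);
- `noise`: `(P_a − P_c)/(2 P_n)` with `P_n = n_trials · σ² wᵀw` and
  σ² taken as the Tikhonov floor (5 % of λ_max) — used for peak finding.

The choice matters: once a strong source dominates, beamformer leakage
makes the bounded ratio nearly constant within ~1 cm of the source, so its
argmin localises poorly (7–15 of 20 planted sources found at 4 mm); the
noise-normalised image recovers 20/20 with median error 1.6 mm.  The
band-filtered covariance is rank-deficient, which is why σ² must come from
the regularisation floor and not from the smallest eigenvalue.

Virtual electrodes use weights from the broadband (1–150 Hz) covariance,
reused for every analysis band; the projected data are band-filtered
before projection.  The beta VE location is each subject's own image
extremum; the gamma VE uses the group-mean image peak (computed from
normalised subject images), since not every subject shows a clear gamma
response.

## Spectral analysis

Filter bank: 1–4, 2–6, 4–8, 6–10, 8–13, 10–20 Hz, then 10-Hz bands every
5 Hz up to 110–120 (26 bands).  Per band: zero-phase band-pass, Hilbert
envelope (trials reflection-padded by 1 s because the rebound sits near the
epoch edge), trial average A(t, f), baseline scalar B(f) (3–4 s after
movement offset for beta; 4–5 s after stimulus onset for gamma/alpha), and
R(t, f) = (A − B)/B.  R is dimensionless and invariant to any rescaling of
the VE, and its baseline-window mean is zero by construction.  Bands with
zero baseline are flagged, not divided.

Welch spectra use 2-s Hann segments at 50 % overlap (the emulated analysis
states no parameters; these are conventional).  Relative beta power is the
area under the PSD of the beta-filtered VE divided by the area under the
PSD of the broadband (1–150 Hz) VE.  Because both numerator and
denominator pass through the same 4th-order filters, the measured fraction
underestimates the planted variance share by a roughly constant factor;
rankings and contrasts, which is all the statistics use, are preserved.

## Connectivity

Beta-band regional time courses at the parcellation centroids are
pairwise-orthogonalised in the time domain (`y⊥ = y − x(x·y)/(x·x)`),
then Hilbert envelopes are computed per retained 10-s segment (avoiding
bridges across removed segments), concatenated, block-averaged 375→75 Hz
(5-sample means act as the anti-alias for slow envelopes), and Pearson
correlated.  Orthogonalisation is asymmetric, so the reported AEC is the
mean of both directions.  A pair that is a pure multiple of itself has no
residual after orthogonalisation; its AEC is defined as 0 (leakage fully
removed) rather than an error.  Connectomes are symmetric with zero
diagonal; thresholding keeps the k = 266 strongest edges (negative values
rank below positive); strength is the row sum, and network strength sums
over the labelled sensorimotor (12 regions) or dorsomedial sensorimotor
(4 regions) subsets.

The synthetic parcellation stands in for an 82-region anatomical atlas:
the 12 sensorimotor regions carry their conventional names and sit near
the vertex; the rest are placed quasi-uniformly on an upper cortical shell
(filenames and docstrings label it synthetic).

## Group statistics

**Rebound gradient.**  On the group-average relative envelope, find the
post-movement maximum M, the last up-crossing of zero before the peak and
the first crossing of 0.75 M after it (both linearly interpolated), and fit
an ordinary least-squares slope between them.  Subjects (or permutation
draws) on which the fit is undefined are excluded (draws are redrawn up to
10 times; the test aborts if more than 20 % of draws fail).

**Permutation tests.**  Group labels are shuffled preserving group sizes
(uniform draws, not enumeration), the statistic recomputed on each draw
(gradient difference on group-mean curves, or window-mean amplitude
difference), and the empirical p is `(1 + #{null ≥ observed})/(n + 1)` —
never zero, floored at 1/(n+1).  Default 20 000 permutations in the
pipeline configuration; the validation suites use 1000.  Sidedness is
configurable; the two directional planted effects (slower patient rebound,
smaller patient gamma) default to one-sided, the post-hoc alpha contrast to
two-sided.  The 0 %/75 % anchors are recomputed on each draw's own mean
curve (fully permutation-consistent), not frozen at the observed anchors.

**Rank tests.**  Wilcoxon signed-rank (sitting vs standing within group)
and rank-sum (patients vs controls within posture), two-sided, exact
distributions for small tie-free samples and the normal approximation with
continuity correction otherwise; all-zero paired differences return p = 1
by convention.  The four tests per measure are Bonferroni-corrected
(threshold α/4 = 0.0125).

## Validation suites and problem sizes

`opmpipe.validation` re-runs each guarantee on freshly simulated data; the
acceptance script reports the numbers.  Chosen sizes: forward oracle at 10
random locations; localization over 20 simulations (32-sensor array, 60
trials, SNR 5, 4-mm grid on a ±16 mm box randomly offset around the
source); null calibration over 200 runs × 1000 permutations (10 + 10
subjects, 20 trials each); rebound power over 50 cohorts of 17 + 17
subjects × 60 trials (the motion-usable cohort size); gamma power over 50
cohorts of 20 + 20; posture recovery over 25 cohorts of 20 paired subjects
with 90-s resting runs.  The effect-recovery suites run at the
virtual-electrode level (planted source + projected noise feeding the real
spectral and statistics code); the sensor-to-source chain is exercised
separately by the localization suite and the end-to-end pipeline tests.

## What the synthetic data do not show

Passing these suites demonstrates internal correctness — the statistics
detect exactly the effects the generator plants, at calibrated false-alarm
rates — not performance on real recordings.  The simulator omits: realistic
cortical geometry and the single-shell/BEM forward model, head movement and
movement artifacts beyond uniform fields, correlated bilateral sources
(which bias LCMV), non-stationary background spectra, real ocular/cardiac
topographies, and co-registration error.  Group statistics on the real
instrument additionally face inter-subject anatomical and SNR variability
that the cohort generator only caricatures with independent noise.

## Known limitations

- The bounded pseudo-T contrast is kept for display compatibility but is a
  poor localiser at high SNR (see above); peak finding uses the
  noise-normalised image.
- The `mean + 3σ` rejection rule cannot flag a single outlier among ≤ 10
  trials/segments (it inflates its own threshold).
- Movement offsets are resolved to a few samples under noise, not to one.
- Relative beta power carries a constant multiplicative bias from double
  filtering; only contrasts are interpreted.
- FastICA component selection needs a reference trace; no automatic
  ECG/EOG template learning is attempted.
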