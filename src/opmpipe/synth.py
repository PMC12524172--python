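"""Synthetic OPM-MEG cohorts with planted, recoverable effects.

This module builds everything the analysis stages consume — a triaxial
sensor array on a spherical scalp, visuomotor recordings with a planted
movement-locked beta ERD/rebound and a stimulus-locked gamma response,
resting-state recordings with planted regional beta-power fractions and
envelope-correlated source pairs, and motion-capture traces with a
two-bump finger-speed profile — all driven by a single seed so cohorts
are bit-reproducible.

Source dynamics are amplitude-modulated band-limited noise: a stochastic
band-passed carrier multiplied by a deterministic task envelope.  This
matches the induced (non-phase-locked) character of beta and gamma
responses; nothing in the generated data is phase-locked to the events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .data import Recording
from .exceptions import GeometryError, ParadigmError
from .forward import SensorArray, check_inside, dipole_field, tangential_basis

FS_MEG = 375.0     # Hz, magnetometer sampling rate
FS_MOTION = 120.0  # Hz, motion-capture sampling rate
TRIAL_LENGTH = 5.0  # s: 2 s visual stimulation + 3 s rest


# ---------------------------------------------------------------------------
# geometry

def make_sensor_array(n_sensors: int = 64, scalp_radius: float = 0.095,
                      seed: int = 0, cap_fraction: float = 0.575,
                      origin: np.ndarray | None = None) -> SensorArray:
    """Quasi-uniform triaxial array on the upper scalp cap.

    Sensors sit on a Fibonacci lattice covering the upper ``cap_fraction``
    of the sphere (the helmet does not cover the face/neck).  Each sensor
    carries a radial axis plus two tangential axes, giving ``3 * n_sensors``
    channels.  ``seed`` only rotates the lattice in azimuth, so arrays with
    different seeds are distinct but statistically equivalent.
    """
    if n_sensors < 4:
        raise GeometryError("need at least 4 sensors")
    if scalp_radius <= 0:
        raise GeometryError("scalp radius must be positive")
    origin = np.zeros(3) if origin is None else np.asarray(origin, float)

    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = np.arange(n_sensors)
    # z from the pole down to 1 - 2*cap_fraction (in units of the radius)
    z = 1.0 - (i + 0.5) / n_sensors * 2.0 * cap_fraction
    phi = i * golden + 0.1 * seed
    rho = np.sqrt(1.0 - z ** 2)
    pos = scalp_radius * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])

    orientations = np.empty((n_sensors, 3, 3))
    names = []
    for s in range(n_sensors):
        t1, t2, rad = tangential_basis(origin + pos[s], origin)
        orientations[s] = np.stack([rad, t1, t2])
        for ax in ("RAD", "TAN1", "TAN2"):
            names.append(f"OPM{s:03d}-{ax}")
    return SensorArray(sensor_positions=pos + origin, sensor_orientations=orientations,
                       channel_names=names, sphere_origin=origin,
                       scalp_radius=scalp_radius)


# ---------------------------------------------------------------------------
# parcellation

@dataclass
class Parcellation:
    """Cortical parcellation by region centroid, with network labels."""

    names: list[str]
    centroids: np.ndarray              # (n_regions, 3), m
    hemispheres: list[str]             # "L" / "R"
    sensorimotor: np.ndarray           # bool flags
    dorsomedial: np.ndarray            # bool flags (subset of sensorimotor)

    @property
    def n_regions(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


_SM_REGIONS = [
    ("Ventral Somatosensory Cortex", (0.040, -0.028, 0.030), False),
    ("Dorsolateral Somatosensory Cortex", (0.032, -0.022, 0.045), False),
    ("Dorsomedial Somatosensory Cortex", (0.012, -0.018, 0.056), True),
    ("Ventral Motor Cortex", (0.040, -0.004, 0.030), False),
    ("Dorsolateral Motor Cortex", (0.032, 0.002, 0.045), False),
    ("Dorsomedial Motor Cortex", (0.012, 0.006, 0.056), True),
]


def make_parcellation(n_regions: int = 82, seed: int = 0,
                      shell_radius: float = 0.060) -> Parcellation:
    """Synthetic centroid table standing in for an 82-region atlas.

    The 12 sensorimotor regions (6 per hemisphere, with the two dorsomedial
    ones flagged as the leg/foot representation) carry their standard atlas
    names and sit near the vertex; the remaining regions are placed
    quasi-uniformly on an upper cortical shell.
    """
    if n_regions < 14:
        raise ValueError("parcellation needs at least 14 regions")
    names, cents, hemis, sm, dm = [], [], [], [], []
    for hemi, sign in (("L", -1.0), ("R", 1.0)):
        for base, (x, y, z), is_dm in _SM_REGIONS:
            names.append(f"{base} {hemi}")
            cents.append([sign * x, y, z])
            hemis.append(hemi)
            sm.append(True)
            dm.append(is_dm)

    n_other = n_regions - 12
    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = np.arange(n_other)
    z = 0.92 - (i + 0.5) / n_other * 0.9   # upper shell, avoid the vertex
    phi = i * golden + 0.05 * seed
    rho = np.sqrt(np.clip(1.0 - z ** 2, 0.0, None))
    other = shell_radius * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    for k in range(n_other):
        hemi = "L" if other[k, 0] < 0 else "R"
        names.append(f"Cortical Region {k + 1:02d} {hemi}")
        cents.append(other[k])
        hemis.append(hemi)
        sm.append(False)
        dm.append(False)
    return Parcellation(names=names, centroids=np.array(cents), hemispheres=hemis,
                        sensorimotor=np.array(sm), dorsomedial=np.array(dm))


# ---------------------------------------------------------------------------
# ground truth

@dataclass
class GroundTruth:
    """Planted effect sizes and geometry for one synthetic cohort.

    The per-group values are artifact choices (the study this emulates
    reports its group effects only qualitatively): the planted patient
    rebound gradient is half the control one, and the planted patient gamma
    gain is half the control one.
    """

    motor_location: np.ndarray = field(default_factory=lambda: np.array([-0.032, -0.010, 0.045]))
    visual_location: np.ndarray = field(default_factory=lambda: np.array([0.005, -0.052, 0.020]))
    rebound_gradient: dict = field(default_factory=lambda: {"control": 0.6, "patient": 0.3})
    gamma_gain: dict = field(default_factory=lambda: {"control": 0.30, "patient": 0.15})
    erd_depth: float = 0.20       # fractional beta drop during movement
    rebound_peak: float = 0.35   # fractional beta overshoot at rebound peak
    parcellation: Parcellation | None = None
    beta_fractions: np.ndarray | None = None      # per region, in (0, 1)
    envelope_pairs: list = field(default_factory=list)  # (i, j, rho)
    movement_offset_times: np.ndarray | None = None
    rng_seed: int = 0

    def validate(self, array: SensorArray | None = None) -> None:
        for _, _, rho in self.envelope_pairs:
            if not 0.0 <= rho < 1.0:
                raise ValueError("planted correlations must lie in [0, 1)")
        if array is not None:
            check_inside(self.motor_location, array)
            check_inside(self.visual_location, array)
            if self.parcellation is not None:
                for c in self.parcellation.centroids:
                    check_inside(c, array)


def default_ground_truth(seed: int = 0, n_regions: int = 82) -> GroundTruth:
    """Cohort ground truth with the default planted effects.

    Beta fractions are highest over the sensorimotor regions (0.35-0.45)
    and taper elsewhere (0.15-0.30); one dorsomedial pair is planted with
    envelope correlation 0.5.
    """
    rng = np.random.default_rng(seed)
    parc = make_parcellation(n_regions=n_regions, seed=seed)
    frac = np.where(parc.sensorimotor,
                    0.35 + 0.10 * rng.random(parc.n_regions),
                    0.15 + 0.15 * rng.random(parc.n_regions))
    i = parc.index("Dorsomedial Motor Cortex L")
    j = parc.index("Dorsomedial Motor Cortex R")
    return GroundTruth(parcellation=parc, beta_fractions=frac,
                       envelope_pairs=[(i, j, 0.5)], rng_seed=seed)


# ---------------------------------------------------------------------------
# noise primitives

def bandlimited_noise(n: int, fs: float, low: float, high: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to (low, high) Hz."""
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def constant_envelope_carrier(n: int, fs: float, low: float, high: float,
                              rng: np.random.Generator) -> np.ndarray:
    """Narrowband FM carrier with an exactly constant Hilbert envelope.

    The instantaneous frequency wanders slowly inside the middle 70 % of the
    band, so the signal is band-limited but its analytic amplitude is
    constant.  Used for envelope-recovery oracles where the stochastic
    amplitude fluctuation of a Gaussian carrier would dominate.
    """
    sos = signal.butter(2, 0.5, btype="lowpass", fs=fs, output="sos")
    drift = signal.sosfiltfilt(sos, rng.standard_normal(n))
    drift = drift / (np.abs(drift).max() + 1e-30)
    f_inst = 0.5 * (low + high) + 0.35 * (high - low) * drift
    phase = 2 * np.pi * np.cumsum(f_inst) / fs + rng.uniform(0, 2 * np.pi)
    return np.sqrt(2.0) * np.cos(phase)


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with a 1/f power spectrum (spectral shaping)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * scale, n)
    return x / x.std()


def _project_source(array: SensorArray, location: np.ndarray,
                    orientation: np.ndarray, timecourse: np.ndarray,
                    amplitude_ft: float) -> np.ndarray:
    """Sensor-space field of one source, scaled so the strongest channel has
    RMS ``amplitude_ft`` for a unit-variance timecourse."""
    g = dipole_field(location, orientation, array)
    g = g / np.max(np.abs(g)) * amplitude_ft
    return g[:, None] * timecourse[None, :]


# ---------------------------------------------------------------------------
# visuomotor task

def _movement_envelope(t: np.ndarray, offsets: np.ndarray, erd: float,
                       peak: float, gradient: float) -> np.ndarray:
    """Deterministic beta-envelope template: baseline 1, ERD during movement,
    then a linear rebound rise at the planted gradient (relative units/s)."""
    env = np.ones_like(t)
    t_rise = (erd + peak) / gradient
    for T in offsets:
        env[(t >= T - 0.5) & (t < T)] = 1.0 - erd
        ramp = (t >= T) & (t < T + t_rise)
        env[ramp] = (1.0 - erd) + gradient * (t[ramp] - T)
        hold = (t >= T + t_rise) & (t < T + t_rise + 0.15)
        env[hold] = 1.0 + peak
        decay = (t >= T + t_rise + 0.15) & (t < T + t_rise + 0.55)
        env[decay] = 1.0 + peak * (1.0 - (t[decay] - T - t_rise - 0.15) / 0.4)
    return env


def _stimulus_envelope(t: np.ndarray, onsets: np.ndarray, gain: float) -> np.ndarray:
    env = np.ones_like(t)
    for T in onsets:
        env[(t >= T) & (t < T + 2.0)] = 1.0 + gain
    return env


def _speed_profile(t: np.ndarray, offset: float, peak_speed: float) -> np.ndarray:
    """Signed finger velocity: raised-cosine abduction then adduction bumps,
    with speed exactly zero from the movement offset onwards."""
    v = np.zeros_like(t)
    for t0, sgn in ((offset - 0.5, 1.0), (offset - 0.25, -1.0)):
        m = (t >= t0) & (t < t0 + 0.25)
        v[m] += sgn * peak_speed * 0.5 * (1.0 - np.cos(2 * np.pi * (t[m] - t0) / 0.25))
    return v


@dataclass
class MotionTrace:
    """Motion-capture marker trajectories (markers x 3 x time, metres)."""

    positions: np.ndarray
    sampling_rate: float = FS_MOTION
    start_time: float = 0.0
    offset_times: np.ndarray | None = None   # planted movement offsets (ground truth)

    @property
    def n_markers(self) -> int:
        return self.positions.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.positions.shape[2]) / self.sampling_rate


def make_motion_trace(offsets: np.ndarray, duration: float,
                      rng: np.random.Generator, peak_speed: float = 0.5,
                      noise_m: float = 0.0) -> MotionTrace:
    """Five-marker glove trace; marker 0 (index fingertip) performs one
    abduction-adduction per trial ending exactly at the planted offset."""
    n = int(round(duration * FS_MOTION))
    t = np.arange(n) / FS_MOTION
    v = np.zeros(n)
    for T in offsets:
        v += _speed_profile(t, T, peak_speed)
    y = np.cumsum(v) / FS_MOTION
    pos = np.zeros((5, 3, n))
    base = rng.uniform(-0.05, 0.05, size=(5, 3))
    pos += base[:, :, None]
    pos[0, 1] += y
    if noise_m > 0:
        pos += noise_m * rng.standard_normal(pos.shape)
    return MotionTrace(positions=pos, offset_times=np.asarray(offsets, float))


def simulate_visuomotor_dataset(array: SensorArray, truth: GroundTruth,
                                n_trials: int = 60, seed: int = 0,
                                group: str = "control", snr: float = 5.0,
                                sensor_noise_ft: float = 30.0,
                                n_background: int = 8,
                                background_snr: float = 0.5,
                                uniform_interference_ft: float = 0.0,
                                offset_jitter: float = 0.05,
                                motion_noise_m: float = 0.0,
                                carrier: str = "am_noise",
                                ) -> tuple[Recording, MotionTrace]:
    """Continuous visuomotor recording plus the paired motion trace.

    Each 5-s trial is 2 s of visual stimulation followed by a 3-s rest; the
    finger abduction-adduction ends (planted movement offset) about 0.5 s
    after stimulus offset.  The motor source carries the beta ERD/rebound
    with the group's planted rise gradient, the visual source carries the
    group's planted gamma gain, and 1/f background sources plus white
    sensor noise complete the scene.  ``snr`` is the ratio of the strongest
    channel's source RMS to the sensor-noise RMS.
    """
    if n_trials < 1:
        raise ParadigmError("need at least one trial")
    truth.validate(array)
    rng = np.random.default_rng(seed)
    fs = FS_MEG
    duration = n_trials * TRIAL_LENGTH
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    onsets = TRIAL_LENGTH * np.arange(n_trials)
    if truth.movement_offset_times is not None:
        offsets = np.asarray(truth.movement_offset_times, float)
    else:
        jit = rng.uniform(-offset_jitter, offset_jitter, n_trials)
        # snap planted offsets to the motion-capture grid so the speed
        # profile's zero is exactly representable at 120 Hz
        offsets = np.round((onsets + 2.5 + jit) * FS_MOTION) / FS_MOTION
    if offsets.min() < 1.0 or offsets.max() > duration - 0.1:
        raise ParadigmError("planted movement offsets outside the recording span")

    g = truth.rebound_gradient[group]
    beta_env = _movement_envelope(t, offsets, truth.erd_depth, truth.rebound_peak, g)
    gamma_env = _stimulus_envelope(t, onsets, truth.gamma_gain[group])

    amp = snr * sensor_noise_ft
    data = np.zeros((array.n_channels, n))
    mt1, _, _ = tangential_basis(truth.motor_location, array.sphere_origin)
    vt1, _, _ = tangential_basis(truth.visual_location, array.sphere_origin)
    if carrier == "am_noise":
        gen = bandlimited_noise
    elif carrier == "constant_envelope":
        gen = constant_envelope_carrier
    else:
        raise ValueError(f"unknown carrier '{carrier}'")
    motor = gen(n, fs, 13.0, 30.0, rng) * beta_env
    visual = gen(n, fs, 35.0, 70.0, rng) * gamma_env
    data += _project_source(array, truth.motor_location, mt1, motor, amp)
    data += _project_source(array, truth.visual_location, vt1, visual, amp)

    for _ in range(n_background):
        loc = _random_interior_point(array, rng)
        b1, b2, _ = tangential_basis(loc, array.sphere_origin)
        ori = np.cos(a := rng.uniform(0, 2 * np.pi)) * b1 + np.sin(a) * b2
        data += _project_source(array, loc, ori, pink_noise(n, rng),
                                background_snr * sensor_noise_ft)

    if uniform_interference_ft > 0:
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        b = pink_noise(n, rng) * uniform_interference_ft
        data += (array.channel_orientations @ d)[:, None] * b[None, :]

    data += sensor_noise_ft * rng.standard_normal(data.shape)

    events = [(float(T), "stimulus_onset") for T in onsets]
    events += [(float(T + 2.0), "stimulus_offset") for T in onsets]
    rec = Recording(data=data, sampling_rate=fs, array=array, events=events)
    motion = make_motion_trace(offsets, duration, rng, noise_m=motion_noise_m)
    return rec, motion


def _random_interior_point(array: SensorArray, rng: np.random.Generator,
                           r_lo: float = 0.02, r_hi: float = 0.075) -> np.ndarray:
    """Random point in the upper half of the conductor, off the origin."""
    while True:
        p = rng.uniform(-r_hi, r_hi, 3)
        r = np.linalg.norm(p)
        if r_lo < r < min(r_hi, 0.9 * array.scalp_radius) and p[2] > 0.005:
            return array.sphere_origin + p


def simulate_ve_trials(kind: str, effect: float, n_trials: int, seed: int,
                       snr: float = 5.0, erd_depth: float = 0.20,
                       rebound_peak: float = 0.35,
                       carrier: str = "am_noise") -> tuple[np.ndarray, np.ndarray]:
    """Epoched virtual-electrode trials with one planted task effect.

    A source-level shortcut past the sensor array: the planted band-limited
    source plus broadband noise at the virtual-electrode output, already
    epoched.  ``kind`` is ``"beta"`` (``effect`` = rebound rise gradient,
    trials epoched -1..4 s around movement offset) or ``"gamma"``
    (``effect`` = stimulus gain, trials epoched 0..5 s around stimulus
    onset).  ``snr`` is the source-to-noise RMS ratio on the trace.
    Used by the statistical power and calibration suites, where simulating
    full sensor arrays for hundreds of cohorts would add nothing but cost.

    Returns ``(trials, times)``.
    """
    rng = np.random.default_rng(seed)
    fs = FS_MEG
    duration = (n_trials + 1) * TRIAL_LENGTH
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    gen = bandlimited_noise if carrier == "am_noise" else constant_envelope_carrier
    if kind == "beta":
        offsets = TRIAL_LENGTH * np.arange(n_trials) + 2.5
        env = _movement_envelope(t, offsets, erd_depth, rebound_peak, effect)
        x = gen(n, fs, 13.0, 30.0, rng) * env
        window = (-1.0, 4.0)
        events = offsets
    elif kind == "gamma":
        onsets = TRIAL_LENGTH * np.arange(n_trials) + 1.0
        env = _stimulus_envelope(t, onsets, effect)
        x = gen(n, fs, 35.0, 70.0, rng) * env
        window = (0.0, 5.0)
        events = onsets
    else:
        raise ValueError(f"unknown kind '{kind}'")
    if snr < np.inf:
        x = x + (1.0 / snr) * rng.standard_normal(n)
    n_samp = int(round((window[1] - window[0]) * fs))
    trials = np.stack([x[int(round((T + window[0]) * fs)):][:n_samp] for T in events])
    times = window[0] + np.arange(n_samp) / fs
    return trials, times


# ---------------------------------------------------------------------------
# resting state

def simulate_regional_sources(truth: GroundTruth, duration: float, seed: int,
                              fs: float = FS_MEG,
                              modulation: float = 0.85,
                              envelope_clip: float = 3.0) -> np.ndarray:
    """Unit-variance regional source time courses (n_regions x samples).

    Each region mixes a beta-band component against beta-free (1-13 and
    30-150 Hz) background so its spectral beta fraction matches the planted
    target.  Beta components are amplitude-modulated by slow log-normal
    envelopes (clipped at ``envelope_clip`` x baseline: unclipped log-normal
    tails make sample correlations of independent pairs unstable); planted
    pairs share a latent factor, with the latent correlation corrected for
    the log-normal transform so the envelopes correlate at the planted rho.
    """
    parc = truth.parcellation
    if parc is None or truth.beta_fractions is None:
        raise ValueError("ground truth carries no parcellation / beta fractions")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    nreg = parc.n_regions

    # slow latent factors behind the envelope correlations; the 2.5-Hz
    # cutoff keeps the modulation well below the beta band's lower edge
    # while leaving enough degrees of freedom for stable correlations
    sos_slow = signal.butter(4, 2.5, btype="lowpass", fs=fs, output="sos")

    def slow(rng):
        z = signal.sosfiltfilt(sos_slow, rng.standard_normal(n))
        return z / z.std()

    latents = np.stack([slow(rng) for _ in range(nreg)])
    m = modulation
    for i, j, rho in truth.envelope_pairs:
        # the log-normal transform e^(m z) attenuates correlation; plant the
        # latent correlation rho_z that makes corr(env_i, env_j) = rho exactly
        rho_z = np.log1p(rho * np.expm1(m * m)) / (m * m)
        shared = slow(rng)
        latents[i] = np.sqrt(rho_z) * shared + np.sqrt(1 - rho_z) * latents[i]
        latents[j] = np.sqrt(rho_z) * shared + np.sqrt(1 - rho_z) * latents[j]

    out = np.empty((nreg, n))
    for r in range(nreg):
        env = np.clip(np.exp(m * latents[r] - 0.5 * m * m), None, envelope_clip)
        beta = bandlimited_noise(n, fs, 13.0, 30.0, rng) * env
        beta /= beta.std()
        rest = (bandlimited_noise(n, fs, 1.0, 13.0, rng)
                + bandlimited_noise(n, fs, 30.0, min(150.0, 0.45 * fs), rng))
        rest /= rest.std()
        phi = truth.beta_fractions[r]
        x = np.sqrt(phi) * beta + np.sqrt(1.0 - phi) * rest
        out[r] = x / x.std()
    return out


def cardiac_trace(duration: float, seed: int, fs: float = FS_MEG,
                  rate_hz: float = 1.17) -> np.ndarray:
    """Stereotyped cardiac reference: a biphasic pulse train (unit variance)."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    beat = 0.0
    while beat < duration:
        tau = (t - beat) / 0.03
        x += tau * np.exp(-0.5 * tau ** 2)   # derivative-of-Gaussian spike
        beat += 1.0 / rate_hz * (1.0 + 0.05 * rng.standard_normal())
    return x / x.std()


def simulate_resting_dataset(array: SensorArray, truth: GroundTruth,
                             duration: float = 600.0, seed: int = 0,
                             snr: float = 2.0, sensor_noise_ft: float = 30.0,
                             artifact_traces: dict | None = None,
                             artifact_amp_ft: float = 150.0) -> Recording:
    """Continuous resting recording with planted regional spectra.

    Every parcellation region radiates from its centroid with a fixed
    tangential orientation; ``snr`` scales each region's strongest channel
    RMS against the sensor noise.  ``artifact_traces`` (name -> unit-variance
    trace) plants stereotyped interference with a spatially smooth
    topography, for exercising the artifact-removal stage.
    """
    if duration <= 0:
        raise ParadigmError("duration must be positive")
    truth.validate(array)
    sources = simulate_regional_sources(truth, duration, seed)
    n = sources.shape[1]
    rng = np.random.default_rng(seed + 1)
    data = np.zeros((array.n_channels, n))
    amp = snr * sensor_noise_ft
    for r, centroid in enumerate(truth.parcellation.centroids):
        t1, t2, _ = tangential_basis(centroid, array.sphere_origin)
        a = rng.uniform(0, 2 * np.pi)
        ori = np.cos(a) * t1 + np.sin(a) * t2
        data += _project_source(array, centroid, ori, sources[r], amp)

    if artifact_traces:
        for name, trace in artifact_traces.items():
            if trace.shape[0] != n:
                raise ParadigmError(f"artifact trace '{name}' length mismatch")
            d = rng.standard_normal(3)
            d /= np.linalg.norm(d)
            topo = array.channel_orientations @ d
            data += artifact_amp_ft * topo[:, None] * trace[None, :]

    data += sensor_noise_ft * rng.standard_normal(data.shape)
    return Recording(data=data, sampling_rate=FS_MEG, array=array, events=[])
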