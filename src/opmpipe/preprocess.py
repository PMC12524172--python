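"""Cleaning and epoching of continuous magnetometer recordings.

All filters are applied forward-backward (zero phase), so envelope timing
downstream (the rebound-gradient statistic compares latencies across
groups) is not biased by group delay.  Rejection operations return masks
and never modify data in place.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import linalg, signal

from .data import Recording, TrialSet
from .exceptions import DegenerateArrayError, EmptySetError, FilterDesignError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# filtering

def notch_filter(rec: Recording, freqs=(50.0, 100.0, 150.0),
                 bandwidth: float = 2.0) -> Recording:
    """Zero-phase IIR notches at the powerline frequency and harmonics."""
    nyq = rec.sampling_rate / 2.0
    out = rec.data.copy()
    for f0 in freqs:
        if f0 >= nyq:
            raise FilterDesignError(f"notch frequency {f0} Hz >= Nyquist {nyq} Hz")
        b, a = signal.iirnotch(f0, f0 / bandwidth, fs=rec.sampling_rate)
        out = signal.filtfilt(b, a, out, axis=-1)
    return rec.with_data(out)


def bandpass_filter(rec: Recording, low: float = 1.0, high: float = 150.0,
                    order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass (effective order doubled)."""
    return rec.with_data(bandpass_array(rec.data, rec.sampling_rate, low, high, order))


def bandpass_array(x: np.ndarray, fs: float, low: float, high: float,
                   order: int = 4) -> np.ndarray:
    nyq = fs / 2.0
    if not 0.0 < low < high < nyq:
        raise FilterDesignError(f"invalid band ({low}, {high}) Hz for fs={fs}")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


# ---------------------------------------------------------------------------
# channel rejection

def detect_bad_channels(rec: Recording, floor_ratio: float = 0.01,
                        ceil_ratio: float = 100.0,
                        segment_seconds: float = 2.0) -> np.ndarray:
    """Flag dead or noisy channels from their broadband Welch power.

    A channel is bad when its total Welch power falls below ``floor_ratio``
    times, or above ``ceil_ratio`` times, the median across channels.  The
    ratio thresholds replace per-spectrum visual inspection and are
    deliberately loose: they catch sensors that dropped out or lost their
    connection, not borderline cases.
    """
    nper = int(segment_seconds * rec.sampling_rate)
    _, psd = signal.welch(rec.data, fs=rec.sampling_rate, nperseg=min(nper, rec.n_samples))
    power = psd.sum(axis=1)
    med = np.median(power)
    if med <= 0:
        return power <= 0
    return (power < floor_ratio * med) | (power > ceil_ratio * med)


# ---------------------------------------------------------------------------
# homogeneous field correction

def hfc_projector(orientations: np.ndarray) -> np.ndarray:
    """Projector M = I - N (N^T N)^-1 N^T removing the uniform-field subspace.

    ``orientations`` stacks each channel's unit orientation axis (rows).  A
    spatially uniform field b is read by channel i as b·o_i, i.e. it lies in
    the column space of N; M annihilates exactly that 3-dimensional subspace.
    """
    N = np.asarray(orientations, float)
    if np.linalg.matrix_rank(N) < 3:
        raise DegenerateArrayError("channel orientations span fewer than 3 dimensions")
    M = np.eye(N.shape[0]) - N @ linalg.solve(N.T @ N, N.T)
    return M


def homogeneous_field_correction(rec: Recording) -> tuple[Recording, np.ndarray]:
    """Remove the spatially uniform field component across the array.

    Applied on the good channels only; bad channels are passed through
    untouched.  Returns the corrected recording and the projector (sized to
    the good-channel subset).
    """
    good = rec.good_channels
    if good.sum() < 4:
        raise DegenerateArrayError("need at least 4 good channels for HFC")
    M = hfc_projector(rec.array.channel_orientations[good])
    out = rec.data.copy()
    out[good] = M @ rec.data[good]
    return rec.with_data(out), M


# ---------------------------------------------------------------------------
# epoching and rejection

def segment_trials(rec: Recording, event_times, window=(-1.0, 4.0),
                   t0_definition: str = "movement offset") -> TrialSet:
    """Epoch the recording around events, half-open [t0+w0, t0+w1).

    Events whose window extends beyond the recording are dropped (and
    counted in the log); an empty usable set is an error.
    """
    event_times = np.sort(np.asarray(event_times, float))
    if event_times.size == 0:
        raise EmptySetError("no events to segment on")
    fs = rec.sampling_rate
    n_samp = int(round((window[1] - window[0]) * fs))
    trials, kept = [], []
    for t0 in event_times:
        i0 = int(round((t0 + window[0]) * fs))
        if i0 < 0 or i0 + n_samp > rec.n_samples:
            continue
        trials.append(rec.data[:, i0:i0 + n_samp])
        kept.append(t0)
    dropped = event_times.size - len(kept)
    if dropped:
        logger.info("segment_trials: dropped %d events at recording edges", dropped)
    if not trials:
        raise EmptySetError("no events with a full window inside the recording")
    return TrialSet(data=np.stack(trials), sampling_rate=fs, array=rec.array,
                    window=tuple(window), t0_definition=t0_definition,
                    event_times=np.array(kept), bad_channels=rec.bad_channels.copy())


def reject_bad_trials(ts: TrialSet, n_std: float = 3.0,
                      rule: str = "mean_plus") -> TrialSet:
    """Variance-based bad-trial rule.

    A trial is flagged when, at any channel, its signal variance exceeds the
    across-trial spread of variance at that channel: ``mean + n_std * std``
    (default reading) or ``n_std * std`` absolute (``rule='absolute'``).
    Returns a new TrialSet with the mask set; data are untouched.
    """
    if ts.n_trials < 3:
        raise EmptySetError("need at least 3 trials for the variance rule")
    v = ts.data.var(axis=2)                       # (trials, channels)
    std = v.std(axis=0)
    if rule == "mean_plus":
        thresh = v.mean(axis=0) + n_std * std
    elif rule == "absolute":
        thresh = n_std * std
    else:
        raise ValueError(f"unknown rule '{rule}'")
    flagged = (v > thresh[None, :]).any(axis=1)
    if flagged.any():
        logger.info("reject_bad_trials: flagged %d of %d trials",
                    int(flagged.sum()), ts.n_trials)
    out = TrialSet(data=ts.data, sampling_rate=ts.sampling_rate, array=ts.array,
                   window=ts.window, t0_definition=ts.t0_definition,
                   event_times=ts.event_times, bad_channels=ts.bad_channels.copy(),
                   bad_trials=ts.bad_trials | flagged)
    return out


def segment_resting(rec: Recording, segment_length: float = 10.0) -> TrialSet:
    """Cut a resting recording into consecutive fixed-length segments."""
    fs = rec.sampling_rate
    n_per = int(round(segment_length * fs))
    n_seg = rec.n_samples // n_per
    if n_seg == 0:
        raise EmptySetError("recording shorter than one segment")
    data = rec.data[:, :n_seg * n_per].reshape(rec.n_channels, n_seg, n_per)
    return TrialSet(data=np.moveaxis(data, 1, 0), sampling_rate=fs, array=rec.array,
                    window=(0.0, segment_length), t0_definition="segment start",
                    event_times=segment_length * np.arange(n_seg),
                    bad_channels=rec.bad_channels.copy())


def reject_bad_segments(rec: Recording, segment_length: float = 10.0,
                        n_std: float = 3.0) -> tuple[TrialSet, np.ndarray]:
    """Variance rule applied to fixed resting segments; returns the mask too."""
    segs = reject_bad_trials(segment_resting(rec, segment_length), n_std=n_std)
    return segs, segs.bad_trials.copy()


# ---------------------------------------------------------------------------
# stereotyped-artifact removal

def remove_stereotyped_artifacts(rec: Recording, references: dict | None,
                                 n_components: int = 20, threshold: float = 0.6,
                                 seed: int = 0) -> Recording:
    """Remove components whose time course tracks a stereotyped reference.

    Data are decomposed into statistically independent components (FastICA,
    deterministic seed); any component correlating with a provided reference
    trace (synthetic ECG/EOG) at |r| >= ``threshold`` is projected out.
    With no reference the stage is an identity transform (with a warning),
    mirroring the fact that manual component selection is not reproducible.
    """
    if not references:
        warnings.warn("no artifact references provided; artifact removal skipped")
        return rec.with_data(rec.data.copy())
    from sklearn.decomposition import FastICA

    good = rec.good_channels
    X = rec.data[good]
    rank = np.linalg.matrix_rank(X @ X.T / X.shape[1])
    k = int(min(n_components, rank))
    ica = FastICA(n_components=k, random_state=seed, whiten="unit-variance",
                  max_iter=500, tol=1e-3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # convergence warnings on hard mixtures
        S = ica.fit_transform(X.T)        # (samples, k)
    A = ica.mixing_                        # (channels, k)
    remove = np.zeros(k, dtype=bool)
    for name, ref in references.items():
        ref = (ref - ref.mean()) / ref.std()
        Sc = S - S.mean(axis=0)   # Pearson correlation per component
        r = np.abs(Sc.T @ ref) / (np.linalg.norm(Sc, axis=0) * np.linalg.norm(ref))
        hits = r >= threshold
        if hits.any():
            logger.info("artifact removal: %d component(s) matched '%s'",
                        int(hits.sum()), name)
        remove |= hits
    if not remove.any():
        return rec.with_data(rec.data.copy())
    # subtract only the flagged components' reconstruction; channel means
    # (FastICA's additive offset) are preserved
    cleaned = X - (S[:, remove] @ A[:, remove].T).T
    out = rec.data.copy()
    out[good] = cleaned
    return rec.with_data(out)
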