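"""Hilbert-envelope spectral machinery.

Per frequency band: filter, Hilbert-transform, take the magnitude of the
analytic signal (the instantaneous band-limited amplitude), average over
trials to get A(t, f), and express task modulation relative to a baseline
scalar B(f) as R(t, f) = (A - B) / B.  R is dimensionless and invariant to
any rescaling of the source time course, so arbitrary beamformer units
cancel.  Trials are reflection-padded (1 s each side) before the Hilbert
transform because the rebound sits close to the trial edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .exceptions import EmptySetError, UndefinedStatisticError
from .preprocess import bandpass_array


def build_filter_bank() -> list[tuple[float, float]]:
    """Overlapping analysis bands from 1 to 120 Hz (26 bands).

    Six narrow low-frequency bands, then 10-Hz-wide bands stepping by 5 Hz
    from 15-25 up to 110-120.
    """
    bands = [(1, 4), (2, 6), (4, 8), (6, 10), (8, 13), (10, 20)]
    lo = 15
    while lo + 10 <= 120:
        bands.append((lo, lo + 10))
        lo += 5
    return [(float(a), float(b)) for a, b in bands]


def hilbert_envelope(x: np.ndarray, sampling_rate: float,
                     pad_seconds: float = 1.0) -> np.ndarray:
    """|analytic signal| along the last axis, with reflection padding."""
    x = np.asarray(x, float)
    if x.shape[-1] < 64:
        raise ValueError("signal too short for a stable envelope")
    npad = int(round(pad_seconds * sampling_rate))
    npad = min(npad, x.shape[-1] - 1)
    if npad > 0:
        pad = [(0, 0)] * (x.ndim - 1) + [(npad, npad)]
        xp = np.pad(x, pad, mode="reflect")
    else:
        xp = x
    env = np.abs(signal.hilbert(xp, axis=-1))
    if npad > 0:
        env = env[..., npad:-npad]
    return env


@dataclass
class TFS:
    """Time-frequency spectrogram of relative amplitude change.

    ``R[b, t] = (A[b, t] - B[b]) / B[b]`` where A is the trial-averaged
    Hilbert envelope in band b and B its mean over the baseline window.
    A and B are retained for audit; bands with zero baseline are flagged
    rather than divided.
    """

    bands: list[tuple[float, float]]
    times: np.ndarray
    R: np.ndarray
    A: np.ndarray
    B: np.ndarray
    baseline_window: tuple[float, float]
    undefined_bands: np.ndarray = field(default=None)


@dataclass
class EnvelopeCurve:
    """Single-band trial-averaged relative-amplitude envelope."""

    band: tuple[float, float]
    times: np.ndarray
    curve: np.ndarray
    baseline_window: tuple[float, float]


def _baseline_slice(times: np.ndarray, window: tuple[float, float]) -> slice:
    i = np.searchsorted(times, window[0], side="left")
    j = np.searchsorted(times, window[1], side="left")
    if j <= i:
        raise EmptySetError(f"baseline window {window} outside the trial span")
    return slice(i, j)


def _band_relative_curve(ve_trials, fs, band, times, baseline_window, pad_seconds):
    X = bandpass_array(np.atleast_2d(ve_trials), fs, band[0], band[1])
    A = hilbert_envelope(X, fs, pad_seconds).mean(axis=0)
    B = A[_baseline_slice(times, baseline_window)].mean()
    return A, B


def compute_tfs(ve_trials: np.ndarray, sampling_rate: float, times: np.ndarray,
                baseline_window: tuple[float, float],
                bands: list | None = None, pad_seconds: float = 1.0) -> TFS:
    """Filter-bank TFS of relative amplitude change from epoched VE data.

    ``ve_trials`` is (n_trials, n_samples); ``times`` is the trial time axis
    relative to the epoching event, and the baseline window is expressed on
    that axis (e.g. 3-4 s after movement offset for the beta analysis, 4-5 s
    after stimulus onset for gamma).
    """
    bands = build_filter_bank() if bands is None else bands
    ve_trials = np.atleast_2d(np.asarray(ve_trials, float))
    A = np.empty((len(bands), ve_trials.shape[1]))
    B = np.empty(len(bands))
    for k, band in enumerate(bands):
        A[k], B[k] = _band_relative_curve(ve_trials, sampling_rate, band, times,
                                          baseline_window, pad_seconds)
    undefined = B <= 0
    R = np.zeros_like(A)
    ok = ~undefined
    R[ok] = (A[ok] - B[ok, None]) / B[ok, None]
    return TFS(bands=list(bands), times=times, R=R, A=A, B=B,
               baseline_window=tuple(baseline_window), undefined_bands=undefined)


def trial_envelope_curve(ve_trials: np.ndarray, sampling_rate: float,
                         times: np.ndarray, band: tuple[float, float],
                         baseline_window: tuple[float, float],
                         pad_seconds: float = 1.0) -> EnvelopeCurve:
    """Single-band relative-change envelope; equals the matching TFS row."""
    ve_trials = np.atleast_2d(np.asarray(ve_trials, float))
    A, B = _band_relative_curve(ve_trials, sampling_rate, band, times,
                                baseline_window, pad_seconds)
    if B <= 0:
        raise UndefinedStatisticError(f"zero baseline amplitude in band {band}")
    return EnvelopeCurve(band=tuple(band), times=times, curve=(A - B) / B,
                         baseline_window=tuple(baseline_window))


def group_envelope(curves: list[EnvelopeCurve]):
    """Group mean +/- standard error across subjects' envelope curves."""
    if not curves:
        raise EmptySetError("no curves")
    M = np.stack([c.curve for c in curves])
    mean = M.mean(axis=0)
    sem = M.std(axis=0, ddof=1) / np.sqrt(M.shape[0]) if M.shape[0] > 1 else np.zeros_like(mean)
    return EnvelopeCurve(band=curves[0].band, times=curves[0].times, curve=mean,
                         baseline_window=curves[0].baseline_window), sem


# ---------------------------------------------------------------------------
# Welch spectra and relative band power

def welch_psd(x: np.ndarray, sampling_rate: float, segment_seconds: float = 2.0,
              overlap: float = 0.5):
    """One-sided Welch PSD with Hann taper (density units, x^2/Hz)."""
    nper = int(round(segment_seconds * sampling_rate))
    if x.shape[-1] < nper:
        raise ValueError("signal shorter than one Welch segment")
    return signal.welch(x, fs=sampling_rate, nperseg=nper,
                        noverlap=int(round(overlap * nper)), window="hann")


def relative_band_power(ve: np.ndarray, sampling_rate: float,
                        band=(13.0, 30.0), broadband=(1.0, 150.0),
                        segment_seconds: float = 2.0) -> float:
    """Fraction of broadband spectral area carried by one band.

    Filters the source time course to the band and to the broadband
    reference, takes the Welch PSD of each, and returns the ratio of the
    areas under the two spectra.  Invariant to global amplitude scaling.
    """
    if not (broadband[0] <= band[0] < band[1] <= broadband[1]):
        raise ValueError("band must lie inside the broadband reference")
    ve = np.asarray(ve, float)
    xb = bandpass_array(ve, sampling_rate, *band)
    xw = bandpass_array(ve, sampling_rate, *broadband)
    f, pb = welch_psd(xb, sampling_rate, segment_seconds)
    _, pw = welch_psd(xw, sampling_rate, segment_seconds)
    denom = np.trapezoid(pw, f)
    if denom <= 0:
        raise UndefinedStatisticError("zero broadband power")
    return float(np.trapezoid(pb, f) / denom)
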