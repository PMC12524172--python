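"""Finger kinematics from motion capture: speed traces and movement offsets.

The movement offset (the moment the finger stops after the abduction-
adduction) defines t = 0 for the beta-band analysis: per trial the two
largest speed peaks are found in temporal order and the first local
minimum after the second peak is taken as the offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .exceptions import OpmPipeError
from .synth import MotionTrace

logger = logging.getLogger(__name__)


@dataclass
class SpeedTrace:
    """Scalar finger speed (m/s) on the magnetometer clock."""

    speed: np.ndarray
    sampling_rate: float
    start_time: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.speed.size) / self.sampling_rate


def upsample_trace(mt: MotionTrace, target_rate: float = 375.0) -> MotionTrace:
    """Linear interpolation of marker trajectories onto a faster clock."""
    if target_rate < mt.sampling_rate:
        raise OpmPipeError("target rate below the native motion rate")
    told = mt.times
    if np.any(np.diff(told) <= 0):
        raise OpmPipeError("non-monotone motion timestamps")
    tnew = mt.start_time + np.arange(int(np.floor((told[-1] - mt.start_time) * target_rate)) + 1) / target_rate
    n_m = mt.n_markers
    out = np.empty((n_m, 3, tnew.size))
    for m in range(n_m):
        for c in range(3):
            out[m, c] = np.interp(tnew, told, mt.positions[m, c])
    return MotionTrace(positions=out, sampling_rate=target_rate,
                       start_time=mt.start_time, offset_times=mt.offset_times)


def finger_speed(mt: MotionTrace, marker: int = 0, lowpass_hz: float = 7.0,
                 order: int = 4) -> SpeedTrace:
    """Speed = |d(x,y,z)/dt| of one marker, 7-Hz low-passed (zero phase).

    The three velocity components are combined in quadrature before the
    low-pass, so the result is a single non-negative speed trace; zero-phase
    filtering can introduce small negative excursions near sharp stops,
    which are clipped.
    """
    if not 0 <= marker < mt.n_markers:
        raise OpmPipeError(f"marker {marker} does not exist")
    fs = mt.sampling_rate
    vel = np.gradient(mt.positions[marker], 1.0 / fs, axis=1)
    speed = np.sqrt((vel ** 2).sum(axis=0))
    if speed.max() > 0:
        sos = signal.butter(order, lowpass_hz, btype="lowpass", fs=fs, output="sos")
        speed = signal.sosfiltfilt(sos, speed)
    return SpeedTrace(speed=np.clip(speed, 0.0, None), sampling_rate=fs,
                      start_time=mt.start_time)


def detect_movement_offsets(st: SpeedTrace, trial_windows,
                            peak_floor_frac: float = 0.10,
                            fallback_frac: float = 0.05):
    """Per-trial movement-offset times from the two-peak speed profile.

    In each search window the two largest strict local maxima above a floor
    of ``peak_floor_frac`` x the window maximum are taken (in temporal
    order); the offset is the first local minimum after the second peak.
    If the trace decays monotonically to the window end, the first sample
    below ``fallback_frac`` x the second-peak height is used.  Windows with
    fewer than two qualifying peaks are reported as undetected.

    Returns ``(offset_times, undetected_window_indices)``.
    """
    t = st.times
    s = st.speed
    offsets, undetected = [], []
    for w, (t0, t1) in enumerate(trial_windows):
        m = (t >= t0) & (t < t1)
        idx = np.nonzero(m)[0]
        if idx.size < 5:
            undetected.append(w)
            continue
        seg = s[idx]
        floor = peak_floor_frac * seg.max()
        peaks, _ = signal.find_peaks(seg, height=floor)
        if peaks.size < 2:
            undetected.append(w)
            continue
        two = np.sort(peaks[np.argsort(seg[peaks])[-2:]])   # temporal order
        p2 = two[1]
        off = None
        for i in range(p2 + 1, seg.size - 1):
            if seg[i] <= seg[i - 1] and seg[i] <= seg[i + 1]:
                off = i
                break
        if off is None:
            below = np.nonzero(seg[p2:] < fallback_frac * seg[p2])[0]
            if below.size:
                off = p2 + below[0]
        if off is None:
            undetected.append(w)
            continue
        offsets.append(t[idx[off]])
    if undetected:
        logger.info("movement offsets undetected in %d window(s)", len(undetected))
    return np.array(offsets), undetected
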