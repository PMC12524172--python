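"""Resting-state amplitude-envelope-correlation (AEC) connectomics.

For each pair of regional source time courses, one signal is regressed out
of the other in the time domain (pairwise orthogonalisation, suppressing
the spurious zero-lag correlation produced by beamformer source leakage),
then the Hilbert envelopes are computed, down-sampled from 375 Hz to 75 Hz,
and Pearson-correlated.  Because orthogonalisation is asymmetric, the AEC
reported for a pair is the mean over both directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import EmptySetError, UndefinedStatisticError
from .spectral import hilbert_envelope
from .synth import Parcellation

logger = logging.getLogger(__name__)


def orthogonalize_pair(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Remove from y its projection on x: y_perp = y - x (x·y)/(x·x)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xx = x @ x
    if xx == 0:
        raise UndefinedStatisticError("cannot orthogonalize against a zero signal")
    return y - x * (x @ y / xx)


def downsample_envelope(env: np.ndarray, factor: int) -> np.ndarray:
    """Non-overlapping block means (anti-aliases the slow envelope)."""
    n = env.shape[-1] // factor
    return env[..., :n * factor].reshape(*env.shape[:-1], n, factor).mean(axis=-1)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    # relative tolerance: an FFT-based envelope of a constant signal is
    # constant only to machine precision
    if (a.std() <= 1e-12 * max(np.abs(a).mean(), 1e-300)
            or b.std() <= 1e-12 * max(np.abs(b).mean(), 1e-300)):
        raise UndefinedStatisticError("constant envelope: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def _segmented_envelope(sig: np.ndarray, sampling_rate: float, factor: int,
                        segment_samples: int | None = None) -> np.ndarray:
    """Downsampled Hilbert envelope; per-segment transforms when the data
    are concatenated cleaned segments (avoids bridging artifacts across the
    joins where bad segments were removed)."""
    if segment_samples:
        n_seg = sig.shape[-1] // segment_samples
        parts = [hilbert_envelope(sig[..., k * segment_samples:(k + 1) * segment_samples],
                                  sampling_rate) for k in range(n_seg)]
        env = np.concatenate(parts, axis=-1)
    else:
        env = hilbert_envelope(sig, sampling_rate)
    return downsample_envelope(env, factor)


def aec(x: np.ndarray, y: np.ndarray, sampling_rate: float = 375.0,
        downsampled_rate: float = 75.0, symmetric: bool = True,
        env_x: np.ndarray | None = None, env_y: np.ndarray | None = None,
        segment_samples: int | None = None) -> float:
    """Orthogonalised amplitude envelope correlation of two band-limited signals.

    ``env_x`` / ``env_y`` may carry the precomputed (downsampled) envelopes
    of the raw signals to avoid recomputation across the n(n-1)/2 pairs.
    With ``symmetric`` the two orthogonalisation directions are averaged.
    """
    factor = int(round(sampling_rate / downsampled_rate))
    if factor < 1 or abs(sampling_rate / downsampled_rate - factor) > 1e-9:
        raise ValueError("downsampled rate must divide the sampling rate")

    def env(sig):
        return _segmented_envelope(sig, sampling_rate, factor, segment_samples)

    def one_direction(a, env_a, b):
        b_perp = orthogonalize_pair(a, b)
        # a pair that is pure leakage (b a multiple of a) has no independent
        # signal left after orthogonalisation: its AEC is zero by convention
        if b_perp.std() <= 1e-12 * b.std():
            return 0.0
        return _pearson(env_a, env(b_perp))

    if env_x is None:
        env_x = env(x)
    r1 = one_direction(x, env_x, y)
    if not symmetric:
        return r1
    if env_y is None:
        env_y = env(y)
    r2 = one_direction(y, env_y, x)
    return 0.5 * (r1 + r2)


@dataclass
class Connectome:
    """Symmetric n_regions x n_regions AEC matrix with zero diagonal."""

    matrix: np.ndarray
    region_names: list[str]

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_pairs(self) -> int:
        n = self.n_regions
        return n * (n - 1) // 2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.region_names,
                            columns=self.region_names)


def build_connectome(sources: np.ndarray, region_names: list[str] | None = None,
                     sampling_rate: float = 375.0,
                     downsampled_rate: float = 75.0,
                     symmetric: bool = True,
                     segment_samples: int | None = None) -> Connectome:
    """AEC for every unordered pair of regional time courses.

    ``sources`` is (n_regions, n_samples) of band-limited (beta) source
    data.  Undefined pairs (a zero or constant signal) propagate as NaN
    with a log entry rather than aborting the connectome.
    """
    S = np.atleast_2d(np.asarray(sources, float))
    n = S.shape[0]
    if n < 2:
        raise EmptySetError("need at least 2 regions")
    if region_names is None:
        region_names = [f"region_{i}" for i in range(n)]
    factor = int(round(sampling_rate / downsampled_rate))
    envs = [_segmented_envelope(S[i], sampling_rate, factor, segment_samples)
            for i in range(n)]
    M = np.zeros((n, n))
    n_undefined = 0
    for i in range(n):
        for j in range(i + 1, n):
            try:
                M[i, j] = M[j, i] = aec(S[i], S[j], sampling_rate,
                                        downsampled_rate, symmetric,
                                        env_x=envs[i], env_y=envs[j],
                                        segment_samples=segment_samples)
            except UndefinedStatisticError:
                M[i, j] = M[j, i] = np.nan
                n_undefined += 1
    if n_undefined:
        logger.warning("connectome: %d undefined pair(s) set to NaN", n_undefined)
    return Connectome(matrix=M, region_names=list(region_names))


def threshold_edges(cm: Connectome, k: int = 266) -> pd.DataFrame:
    """The k strongest connections, descending; ties break by (row, col).

    Negative AEC values are kept in the matrix but rank below positives
    here, since edge strength is compared on the raw value.
    """
    n = cm.n_regions
    if k > cm.n_pairs:
        raise ValueError(f"k={k} exceeds the {cm.n_pairs} available pairs")
    iu, ju = np.triu_indices(n, k=1)
    w = cm.matrix[iu, ju]
    order = np.lexsort((ju, iu, -w))[:k]
    return pd.DataFrame({
        "region_a": [cm.region_names[i] for i in iu[order]],
        "region_b": [cm.region_names[j] for j in ju[order]],
        "weight": w[order],
    })


def connectivity_strength(cm: Connectome, subset: list[str] | None = None):
    """Per-region strength (row sums) and, optionally, a subset total.

    Strength_i = sum_j M[i, j]; the subset sum aggregates strength over a
    labelled network (e.g. the sensorimotor regions).
    """
    strength = np.nansum(cm.matrix, axis=1)
    per_region = pd.Series(strength, index=cm.region_names)
    if subset is None:
        return per_region
    for name in subset:
        if name not in cm.region_names:
            raise KeyError(f"unknown region '{name}'")
    return per_region, float(per_region.loc[list(subset)].sum())


def network_strength(cm: Connectome, parc: Parcellation,
                     network: str = "sensorimotor") -> float:
    """Summed connectivity strength over a labelled network."""
    flags = parc.sensorimotor if network == "sensorimotor" else parc.dorsomedial
    subset = [n for n, f in zip(parc.names, flags) if f]
    return connectivity_strength(cm, subset)[1]
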