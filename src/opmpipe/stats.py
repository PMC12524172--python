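"""Group inference: rebound-gradient fits, permutation tests, Wilcoxon tests.

The motor biomarker is the rise gradient of the post-movement beta rebound,
fitted on the group-average relative envelope between the time points where
the curve shows 0 % and 75 % of the rebound's maximum amplitude.  Group
differences are assessed by permuting participant labels (sham groups of
the same sizes), recomputing the statistic on each draw, and comparing the
observed value against the resulting null distribution; the empirical p is
(1 + #{null at least as extreme}) / (n_permutations + 1), so it is never
zero and never below 1/(n_permutations + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import UndefinedStatisticError
from .spectral import EnvelopeCurve


# ---------------------------------------------------------------------------
# rebound gradient

@dataclass
class GradientFit:
    """OLS fit of the rebound rise (relative amplitude per second)."""

    gradient: float
    t_lo: float           # last up-crossing of 0 before the rebound peak
    t_hi: float           # first crossing of 75 % of the peak after t_lo
    peak_value: float
    peak_time: float
    residual_rms: float


def _unpack_curve(curve):
    if isinstance(curve, EnvelopeCurve):
        return curve.times, curve.curve
    times, values = curve
    return np.asarray(times, float), np.asarray(values, float)


def rebound_gradient(curve, search_window=(0.0, 2.0)) -> GradientFit:
    """Rise gradient of the rebound in a post-movement search window.

    Finds the curve maximum M in the window, the last up-crossing of zero
    before the peak (t_lo) and the first crossing of 0.75 M after it (t_hi),
    both linearly interpolated, then fits an ordinary least-squares slope to
    the curve samples in [t_lo, t_hi].  Raises if the curve never crosses
    zero before the peak or never reaches 75 % — such subjects are excluded
    upstream.
    """
    times, values = _unpack_curve(curve)
    m = (times >= search_window[0]) & (times <= search_window[1])
    if m.sum() < 3:
        raise UndefinedStatisticError("search window contains too few samples")
    tt, vv = times[m], values[m]
    ip = int(np.argmax(vv))
    M = vv[ip]
    if M <= 0:
        raise UndefinedStatisticError("no positive rebound in the search window")
    pre = vv[:ip + 1]
    ups = np.nonzero((pre[:-1] <= 0) & (pre[1:] > 0))[0]
    if ups.size == 0:
        raise UndefinedStatisticError("curve never crosses zero before the peak")
    i0 = int(ups[-1])
    t_lo = _interp_crossing(tt, vv, i0, 0.0)
    thr = 0.75 * M
    post = np.nonzero((vv[i0:-1] < thr) & (vv[i0 + 1:] >= thr))[0]
    if post.size == 0:
        raise UndefinedStatisticError("curve never reaches 75 % of the peak")
    j0 = i0 + int(post[0])
    t_hi = _interp_crossing(tt, vv, j0, thr)
    fit = (tt >= t_lo) & (tt <= t_hi)
    if fit.sum() < 2:
        raise UndefinedStatisticError("fit interval shorter than two samples")
    slope, intercept = np.polyfit(tt[fit], vv[fit], 1)
    resid = vv[fit] - (slope * tt[fit] + intercept)
    return GradientFit(gradient=float(slope), t_lo=float(t_lo), t_hi=float(t_hi),
                       peak_value=float(M), peak_time=float(tt[ip]),
                       residual_rms=float(np.sqrt(np.mean(resid ** 2))))


def _interp_crossing(t, v, i, level):
    """Linear-interpolated time where v crosses ``level`` in [t_i, t_i+1]."""
    dv = v[i + 1] - v[i]
    if dv == 0:
        return t[i]
    return t[i] + (level - v[i]) / dv * (t[i + 1] - t[i])


def window_mean_amplitude(curve, window) -> float:
    """Mean of a relative-change curve over a half-open time window [w0, w1)."""
    times, values = _unpack_curve(curve)
    m = (times >= window[0]) & (times < window[1])
    if not m.any():
        raise UndefinedStatisticError(f"empty window {window}")
    return float(values[m].mean())


# ---------------------------------------------------------------------------
# permutation tests

@dataclass
class PermutationResult:
    """Observed group statistic against its label-shuffled null."""

    observed: float
    null: np.ndarray
    p: float
    n_permutations: int
    seed: int
    sidedness: str
    statistic: str

    def __post_init__(self):
        assert self.null.shape == (self.n_permutations,)


def _empirical_p(observed, null, sidedness):
    n = null.size
    if sidedness == "greater":
        hits = np.sum(null >= observed)
    elif sidedness == "less":
        hits = np.sum(null <= observed)
    elif sidedness == "two-sided":
        hits = np.sum(np.abs(null) >= abs(observed))
    else:
        raise ValueError(f"unknown sidedness '{sidedness}'")
    return float((1 + hits) / (n + 1))


def permutation_group_test(group_a, group_b, statistic: str = "gradient_difference",
                           n_permutations: int = 20000, seed: int = 0,
                           sidedness: str = "two-sided",
                           times: np.ndarray | None = None,
                           search_window=(0.0, 2.0), window=(0.0, 2.0),
                           max_redraw: int = 10) -> PermutationResult:
    """Group-difference permutation test on per-subject envelope curves.

    ``group_a`` and ``group_b`` are (n_subjects, n_times) stacks of relative
    envelope curves (``times`` gives their axis; EnvelopeCurve lists are
    accepted too).  The statistic is computed on group-averaged curves —
    either the difference of rebound-rise gradients or the difference of
    window-mean amplitudes (A minus B) — then labels are permuted preserving
    group sizes.  Draws on which the gradient is undefined are redrawn up to
    ``max_redraw`` times; if more than 20 % of draws fail the test aborts.
    """
    A, times = _as_matrix(group_a, times)
    B, _ = _as_matrix(group_b, times)
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise UndefinedStatisticError("each group needs at least 2 subjects")
    nA = A.shape[0]
    pool = np.vstack([A, B])
    n = pool.shape[0]
    rng = np.random.default_rng(seed)

    if statistic == "window_mean_difference":
        s = np.array([window_mean_amplitude((times, c), window) for c in pool])
        observed = s[:nA].mean() - s[nA:].mean()
        idx = np.argsort(rng.random((n_permutations, n)), axis=1)
        null = s[idx[:, :nA]].mean(axis=1) - s[idx[:, nA:]].mean(axis=1)
    elif statistic == "gradient_difference":
        def stat(ia, ib):
            ga = rebound_gradient((times, pool[ia].mean(axis=0)), search_window)
            gb = rebound_gradient((times, pool[ib].mean(axis=0)), search_window)
            return ga.gradient - gb.gradient

        observed = stat(np.arange(nA), np.arange(nA, n))
        null = np.empty(n_permutations)
        failures = 0
        for k in range(n_permutations):
            for _ in range(max_redraw):
                perm = rng.permutation(n)
                try:
                    null[k] = stat(perm[:nA], perm[nA:])
                    break
                except UndefinedStatisticError:
                    continue
            else:
                failures += 1
                null[k] = 0.0
            if failures > 0.2 * n_permutations:
                raise UndefinedStatisticError(
                    "gradient undefined on more than 20 % of permutation draws")
    else:
        raise ValueError(f"unknown statistic '{statistic}'")

    return PermutationResult(observed=float(observed), null=null,
                             p=_empirical_p(observed, null, sidedness),
                             n_permutations=n_permutations, seed=seed,
                             sidedness=sidedness, statistic=statistic)


def _as_matrix(group, times):
    if isinstance(group, np.ndarray):
        if times is None:
            raise ValueError("times required with raw curve matrices")
        return np.atleast_2d(group), np.asarray(times, float)
    curves = list(group)
    M = np.stack([c.curve for c in curves])
    return M, curves[0].times


# ---------------------------------------------------------------------------
# rank tests and correction

def wilcoxon_test(a, b, mode: str = "signed_rank_paired") -> float:
    """Two-sided Wilcoxon test p-value.

    Paired signed-rank (sitting vs standing within a group) or unpaired
    rank-sum (patients vs controls).  Exact distributions for small
    tie-free samples, normal approximation with continuity correction
    otherwise.  All-zero paired differences return p = 1 by convention.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if mode == "signed_rank_paired":
        if a.shape != b.shape:
            raise ValueError("paired test needs equal-length samples")
        if a.size < 5:
            raise ValueError("paired test needs n >= 5")
        d = a - b
        if np.all(d == 0):
            return 1.0
        d = d[d != 0]
        exact = d.size <= 25 and np.unique(np.abs(d)).size == d.size
        res = sps.wilcoxon(d, alternative="two-sided",
                           method="exact" if exact else "approx",
                           correction=not exact)
        return float(res.pvalue)
    if mode == "rank_sum_unpaired":
        pooled = np.concatenate([a, b])
        exact = max(a.size, b.size) <= 25 and np.unique(pooled).size == pooled.size
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="exact" if exact else "asymptotic",
                               use_continuity=True)
        return float(res.pvalue)
    raise ValueError(f"unknown mode '{mode}'")


def bonferroni_threshold(alpha: float, m_tests: int) -> float:
    """Corrected per-test significance threshold alpha / m."""
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    return alpha / m_tests
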