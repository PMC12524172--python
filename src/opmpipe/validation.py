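"""Recovery, calibration and analytic self-checks for the whole pipeline.

Each function here re-runs one slice of the package under controlled
synthetic conditions and reports a scalar summary: forward-model agreement
with an externally supplied oracle, beamformer localization hit rates,
projector algebra, envelope analytics, permutation-test calibration and
power, AEC behaviour.  They are used by the test suite and by the
reproduction script; problem sizes default to the scaled-down study
conditions documented in the methods note.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import beamform, connectivity, forward, preprocess, spectral, stats, synth

FS = synth.FS_MEG


def _seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# analytic / combinatorial reproductions

def combinatorial_checks() -> dict:
    """Fixed design arithmetic: pair, edge, segment and trial counts."""
    parc = synth.make_parcellation(82)
    cm = connectivity.Connectome(
        matrix=np.random.default_rng(0).uniform(0, 1, (82, 82)),
        region_names=parc.names)
    cm.matrix = (cm.matrix + cm.matrix.T) / 2
    np.fill_diagonal(cm.matrix, 0.0)
    edges = connectivity.threshold_edges(cm, k=266)
    n_segments = int(600.0 // 10.0)        # the 600-s resting run, 10-s pieces
    return {
        "n_region_pairs": cm.n_pairs,
        "n_thresholded_edges": len(edges),
        "n_resting_segments": n_segments,
        "visuomotor_duration_s": 60 * synth.TRIAL_LENGTH,
        "bonferroni_threshold": stats.bonferroni_threshold(0.05, 4),
    }


# ---------------------------------------------------------------------------
# forward model

def radial_silence(seed: int = 0) -> float:
    """Worst ratio of radial-dipole to tangential-dipole field strength."""
    rng = np.random.default_rng(seed)
    array = synth.make_sensor_array(16, seed=seed)
    worst = 0.0
    for _ in range(5):
        loc = synth._random_interior_point(array, rng)
        t1, _, rhat_basis = forward.tangential_basis(loc, array.sphere_origin)
        rhat = (loc - array.sphere_origin)
        rhat = rhat / np.linalg.norm(rhat)
        b_rad = forward.dipole_field(loc, rhat, array)
        b_tan = forward.dipole_field(loc, t1, array)
        worst = max(worst, np.abs(b_rad).max() / np.abs(b_tan).max())
    return worst


def leadfield_oracle_error(oracle_field_fn, n_locations: int = 10,
                           seed: int = 0) -> float:
    """Max relative deviation between the closed-form field and an
    independently supplied oracle, over random tangential dipoles."""
    rng = np.random.default_rng(seed)
    array = synth.make_sensor_array(16, seed=seed)
    worst = 0.0
    for _ in range(n_locations):
        loc = rng.uniform(-0.04, 0.04, 3)
        loc[2] = rng.uniform(0.02, 0.055)
        t1, t2, _ = forward.tangential_basis(loc, array.sphere_origin)
        q = rng.standard_normal() * t1 + rng.standard_normal() * t2
        B = forward.dipole_field_at(array.sensor_positions, loc, q,
                                    array.sphere_origin)
        scale = np.abs(B).max()
        s = int(rng.integers(0, array.n_sensors))
        B_oracle = oracle_field_fn(array.sensor_positions[s], q, loc)
        worst = max(worst, np.abs(B_oracle - B[s]).max() / scale)
    return worst


# ---------------------------------------------------------------------------
# beamformer

def localization_suite(n_sims: int = 20, seed: int = 0, n_sensors: int = 32,
                       n_trials: int = 60, snr: float = 5.0,
                       spacing: float = 0.004) -> dict:
    """Planted-ERD localization on a 4-mm grid, random cortical sources.

    A hit is a peak within one grid step (per axis) of the planted source.
    """
    hits = 0
    errs = []
    for k, s in enumerate(_seeds(seed, n_sims)):
        rng = np.random.default_rng(s)
        array = synth.make_sensor_array(n_sensors, seed=k)
        u = rng.standard_normal(3)
        u[2] = abs(u[2]) + 0.3
        u /= np.linalg.norm(u)
        loc = u * rng.uniform(0.045, 0.065)
        truth = replace(synth.default_ground_truth(0, 14), motor_location=loc)
        rec, mt = synth.simulate_visuomotor_dataset(
            array, truth, n_trials=n_trials, seed=s, group="control", snr=snr)
        rec = preprocess.bandpass_filter(rec, 1, 150)
        ts = preprocess.segment_trials(rec, mt.offset_times, (-1, 4))
        center = loc + rng.uniform(-0.006, 0.006, 3)
        grid = beamform.make_grid(array, spacing=spacing,
                                  bounds=np.array([center - 0.016,
                                                   center + 0.016]).T)
        img = beamform.pseudo_t_image(ts, (13, 30), (-1, 0), (0.5, 1.5),
                                      grid=grid, spacing=spacing, mode="noise")
        peak = beamform.find_peak_location(img, "min")
        cheb = np.abs(peak - loc).max()
        errs.append(cheb)
        hits += cheb <= spacing + 1e-9
    return {"hits": hits, "n_sims": n_sims,
            "median_error_mm": float(np.median(errs) * 1000)}


def unit_gain_deviation(seed: int = 0, n_voxels: int = 200) -> float:
    """Max |w'l - 1| of LCMV weights across a grid, random covariance."""
    rng = np.random.default_rng(seed)
    array = synth.make_sensor_array(16, seed=0)
    A = rng.standard_normal((array.n_channels, 4 * array.n_channels))
    cov = beamform.Covariance(matrix=A @ A.T / A.shape[1], band=(1, 150),
                              n_samples=A.shape[1],
                              channel_mask=np.ones(array.n_channels, bool))
    C = beamform.regularize(cov).matrix
    grid = beamform.make_grid(array, spacing=0.012)[:n_voxels]
    worst = 0.0
    for p in grid:
        L = forward.leadfield(p, array)
        t1, t2, _ = forward.tangential_basis(p, array.sphere_origin)
        eta = beamform.optimal_orientation(C, L, (t1, t2))
        l = L[:, :2] @ np.array([t1 @ eta, t2 @ eta])
        w = beamform.lcmv_weights(C, l)
        worst = max(worst, abs(w @ l - 1.0))
    return worst


# ---------------------------------------------------------------------------
# homogeneous field correction

def hfc_checks(seed: int = 0) -> dict:
    array = synth.make_sensor_array(16, seed=0)
    rng = np.random.default_rng(seed)
    M = preprocess.hfc_projector(array.channel_orientations)
    b = rng.standard_normal(3)
    reading = array.channel_orientations @ b
    uniform_residual = (np.abs(M @ reading).max()
                        / max(np.abs(reading).max(), 1e-300))
    return {
        "uniform_residual_rel": float(uniform_residual),
        "idempotency_dev": float(np.abs(M @ M - M).max()),
        "removed_rank": int(np.linalg.matrix_rank(np.eye(M.shape[0]) - M)),
    }


# ---------------------------------------------------------------------------
# envelope analytics

def envelope_checks() -> dict:
    t = np.arange(int(10 * FS)) / FS
    true_env = 1 + 0.5 * np.cos(2 * np.pi * 2 * t)
    x = true_env * np.cos(2 * np.pi * 20 * t)
    env = spectral.hilbert_envelope(x, FS)
    k = int(0.2 * FS)
    am_rms = (np.sqrt(np.mean((env[k:-k] - true_env[k:-k]) ** 2))
              / np.sqrt(np.mean(true_env[k:-k] ** 2)))

    # R must vanish identically when the envelope equals its baseline
    times = np.arange(1875) / FS - 1.0
    rng = np.random.default_rng(0)
    trials = np.stack([synth.bandlimited_noise(1875, FS, 13, 30, rng)
                       for _ in range(5)])
    tfs = spectral.compute_tfs(trials, FS, times, (3.0, 4.0), bands=[(13, 30)])
    m = (times >= 3.0) & (times < 4.0)
    tfs_baseline_dev = float(np.abs(tfs.R[0, m].mean()))

    # analytic linear rebound: exact gradient up to the sample grid
    v = np.zeros_like(times)
    rise = (times >= 0.2) & (times <= 1.2)
    v[rise] = 0.4 * (times[rise] - 0.2)
    v[times > 1.2] = 0.4
    fit = stats.rebound_gradient((times, v), (0.0, 2.0))
    return {
        "am_tone_rms_rel": float(am_rms),
        "tfs_baseline_dev": tfs_baseline_dev,
        "ramp_gradient_rel_err": float(abs(fit.gradient - 0.4) / 0.4),
    }


# ---------------------------------------------------------------------------
# permutation statistics

def _sub(seed: int, k: int) -> int:
    return (seed + k) % (2 ** 31)


def _subject_curve(kind, effect, seed, n_trials=60, snr=5.0):
    trials, times = synth.simulate_ve_trials(kind, effect, n_trials, seed, snr)
    band = (13, 30) if kind == "beta" else (35, 70)
    base = (3, 4) if kind == "beta" else (4, 5)
    return spectral.trial_envelope_curve(trials, FS, times, band, base)


def permutation_calibration(n_runs: int = 200, n_permutations: int = 1000,
                            seed: int = 0, n_per_group: int = 10,
                            n_trials: int = 20, alpha: float = 0.05) -> dict:
    """Type-I error of the group test when both groups are drawn identically."""
    rej = 0
    p_floor_ok = True
    seeds = _seeds(seed + 1000, n_runs)
    for r, s in enumerate(seeds):
        A = [_subject_curve("gamma", 0.2, _sub(s, 2 * k), n_trials=n_trials)
             for k in range(n_per_group)]
        B = [_subject_curve("gamma", 0.2, _sub(s, 2 * k + 1), n_trials=n_trials)
             for k in range(n_per_group)]
        res = stats.permutation_group_test(
            A, B, "window_mean_difference", n_permutations=n_permutations,
            seed=s, sidedness="less", window=(0, 2))
        rej += res.p < alpha
        p_floor_ok &= res.p >= 1.0 / (n_permutations + 1)
    return {"rejection_rate": rej / n_runs, "p_floor_respected": bool(p_floor_ok)}


def rebound_power(n_cohorts: int = 50, n_per_group: int = 17, seed: int = 0,
                  n_permutations: int = 1000, gradient_ratio: float = 0.5,
                  alpha: float = 0.05) -> float:
    """Power to detect the planted slower rebound rise in the patient group."""
    g_control = 0.6
    g_patient = gradient_ratio * g_control
    hits = 0
    for c, s in enumerate(_seeds(seed + 2000, n_cohorts)):
        A = [_subject_curve("beta", g_patient, _sub(s, 2 * k)) for k in range(n_per_group)]
        B = [_subject_curve("beta", g_control, _sub(s, 2 * k + 1)) for k in range(n_per_group)]
        res = stats.permutation_group_test(
            A, B, "gradient_difference", n_permutations=n_permutations,
            seed=s, sidedness="less", search_window=(0.0, 2.0))
        hits += res.p < alpha
    return hits / n_cohorts


def gamma_power(n_cohorts: int = 50, n_per_group: int = 20, seed: int = 0,
                n_permutations: int = 1000, alpha: float = 0.05) -> float:
    """Power to detect the planted gamma deficit (gain 0.15 vs 0.30)."""
    hits = 0
    for c, s in enumerate(_seeds(seed + 3000, n_cohorts)):
        A = [_subject_curve("gamma", 0.15, _sub(s, 2 * k)) for k in range(n_per_group)]
        B = [_subject_curve("gamma", 0.30, _sub(s, 2 * k + 1)) for k in range(n_per_group)]
        res = stats.permutation_group_test(
            A, B, "window_mean_difference", n_permutations=n_permutations,
            seed=s, sidedness="less", window=(0, 2))
        hits += res.p < alpha
    return hits / n_cohorts


def posture_power(n_cohorts: int = 25, n_subjects: int = 20, seed: int = 0,
                  duration: float = 90.0, drop_factor: float = 0.8,
                  alpha: float = 0.0125) -> float:
    """Power of the signed-rank test to recover the standing beta-power drop."""
    base = synth.default_ground_truth(seed=0, n_regions=14)
    standing_truth = replace(base, beta_fractions=base.beta_fractions * drop_factor)
    sm = base.parcellation.sensorimotor

    def subj_power(truth, s):
        S = synth.simulate_regional_sources(truth, duration, s)
        return np.mean([spectral.relative_band_power(S[i], FS)
                        for i in range(S.shape[0]) if sm[i]])

    hits = 0
    for c, s in enumerate(_seeds(seed + 4000, n_cohorts)):
        sit = np.array([subj_power(base, _sub(s, 2 * k)) for k in range(n_subjects)])
        stand = np.array([subj_power(standing_truth, _sub(s, 2 * k + 1))
                          for k in range(n_subjects)])
        p = stats.wilcoxon_test(sit, stand, "signed_rank_paired")
        hits += p < alpha
    return hits / n_cohorts


# ---------------------------------------------------------------------------
# amplitude envelope correlation

def aec_checks(seed: int = 0, duration: float = 200.0,
               n_seeds: int = 3) -> dict:
    """Leakage suppression and monotonicity in the planted correlation."""
    rng = np.random.default_rng(seed)
    n = int(duration * FS)
    x = synth.bandlimited_noise(n, FS, 13, 30, rng)
    eps = 0.1 * synth.bandlimited_noise(n, FS, 13, 30, rng)
    leakage = abs(connectivity.aec(x, 0.8 * x + eps))

    base = synth.default_ground_truth(seed=0, n_regions=14)
    means = {}
    for rho in (0.2, 0.4, 0.6):
        vals = []
        for s in _seeds(seed + 5000 + int(10 * rho), n_seeds):
            truth = replace(base, envelope_pairs=[(0, 1, rho)])
            S = preprocess.bandpass_array(
                synth.simulate_regional_sources(truth, duration, s), FS, 13, 30)
            vals.append(connectivity.aec(S[0], S[1]))
        means[rho] = float(np.mean(vals))
    return {
        "leakage_pair_aec": float(leakage),
        "aec_rho_02": means[0.2], "aec_rho_04": means[0.4],
        "aec_rho_06": means[0.6],
        "monotone": bool(means[0.2] < means[0.4] < means[0.6]),
    }


def wilcoxon_enumeration_error(signed_rank_oracle, rank_sum_oracle,
                               n_cases: int = 6, seed: int = 0) -> float:
    """Max |p - p_enumerated| over random small samples (n <= 8)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cases):
        n = int(rng.integers(5, 9))
        a = rng.standard_normal(n)
        b = a - rng.standard_normal(n) * 0.8 - 0.3
        worst = max(worst, abs(stats.wilcoxon_test(a, b, "signed_rank_paired")
                               - signed_rank_oracle(a - b)))
        x = rng.standard_normal(int(rng.integers(4, 8)))
        y = rng.standard_normal(int(rng.integers(4, 8))) + 0.5
        worst = max(worst, abs(stats.wilcoxon_test(x, y, "rank_sum_unpaired")
                               - rank_sum_oracle(x, y)))
    return worst
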