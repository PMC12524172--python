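"""End-to-end orchestration: simulate -> preprocess -> events -> beamform ->
spectral / connectivity -> group statistics.

The pipeline consumes a single :class:`PipelineConfig`; every window, band,
threshold and seed lives there, so an alpha-band re-run of the visuomotor
analysis, or a different rejection rule, is a config change and not a code
change.  Results bundles are plain dicts (JSON-serialisable apart from the
curve arrays) stamped with the master seed and a config hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from . import beamform, connectivity, motion as motion_mod, preprocess, spectral, stats, synth


@dataclass
class PipelineConfig:
    """Everything an end-to-end run needs, with desk-scale defaults.

    The full study design is 2 groups x 2 postures x 20 subjects, 60 trials
    and 600-s resting runs on a 64-sensor array; the defaults here are a
    scaled-down cohort that exercises every stage in minutes on one CPU.
    """

    seed: int = 0
    groups: tuple = ("patient", "control")
    postures: tuple = ("sitting", "standing")
    n_subjects_per_group: int = 5
    n_sensors: int = 16
    n_trials: int = 30
    rest_duration: float = 60.0
    n_regions: int = 14
    snr: float = 5.0
    rest_snr: float = 2.0

    notch: tuple = (50.0, 100.0, 150.0)
    broadband: tuple = (1.0, 150.0)
    beta_band: tuple = (13.0, 30.0)
    gamma_band: tuple = (35.0, 70.0)
    alpha_band: tuple = (8.0, 13.0)

    beta_window: tuple = (-1.0, 4.0)       # s, relative to movement offset
    beta_active: tuple = (-1.0, 0.0)
    beta_control: tuple = (0.5, 1.5)
    beta_baseline: tuple = (3.0, 4.0)
    gamma_window: tuple = (0.0, 5.0)       # s, relative to stimulus onset
    gamma_active: tuple = (0.0, 2.0)
    gamma_control: tuple = (3.0, 5.0)
    gamma_baseline: tuple = (4.0, 5.0)
    rebound_search: tuple = (0.0, 2.0)

    grid_spacing: float = 0.010
    reg_fraction: float = 0.05
    # noise-normalised images localize far more sharply than the bounded
    # ratio once a strong source dominates the leakage pattern
    pseudo_t_mode: str = "noise"
    bad_trial_nstd: float = 3.0
    bad_trial_rule: str = "mean_plus"
    segment_length: float = 10.0
    skip_artifact_removal: bool = True

    n_permutations: int = 1000
    rebound_sidedness: str = "less"        # planted: patients rise more slowly
    gamma_sidedness: str = "less"          # planted: patients respond less
    alpha_sidedness: str = "two-sided"
    alpha_level: float = 0.05

    # planted posture effect: multiplier on beta fractions when standing
    standing_beta_factor: dict = field(default_factory=lambda: {"patient": 0.8,
                                                                "control": 1.0})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(open(path))
        return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(asdict(self))), fh)

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True,
                                         default=list).encode()).hexdigest()[:12]


def _subject_seeds(master: int, n: int) -> list[int]:
    """Documented per-subject substreams of the master seed (all < 2**31)."""
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def _preprocess(rec, config):
    rec = preprocess.notch_filter(rec, config.notch)
    rec = preprocess.bandpass_filter(rec, *config.broadband)
    rec.bad_channels = rec.bad_channels | preprocess.detect_bad_channels(rec)
    rec, _ = preprocess.homogeneous_field_correction(rec)
    return rec


# ---------------------------------------------------------------------------
# visuomotor task

def _visuomotor_subject(config, truth, group, subj_seed):
    """Simulate and analyse one subject's visuomotor run."""
    array = synth.make_sensor_array(config.n_sensors, seed=subj_seed % 97)
    rec, mtrace = synth.simulate_visuomotor_dataset(
        array, truth, n_trials=config.n_trials, seed=subj_seed, group=group,
        snr=config.snr)
    rec = _preprocess(rec, config)

    st = motion_mod.finger_speed(motion_mod.upsample_trace(mtrace, rec.sampling_rate))
    onsets = rec.event_times("stimulus_onset")
    windows = [(t + 1.7, t + 3.3) for t in onsets]
    offsets, undetected = motion_mod.detect_movement_offsets(st, windows)

    out = {"n_undetected_movements": len(undetected)}
    grid = beamform.make_grid(array, spacing=config.grid_spacing)

    ts_beta = preprocess.reject_bad_trials(
        preprocess.segment_trials(rec, offsets, config.beta_window),
        n_std=config.bad_trial_nstd, rule=config.bad_trial_rule)
    img_beta = beamform.pseudo_t_image(ts_beta, config.beta_band,
                                       config.beta_active, config.beta_control,
                                       grid=grid, spacing=config.grid_spacing,
                                       reg_fraction=config.reg_fraction,
                                       mode=config.pseudo_t_mode)
    peak = beamform.find_peak_location(img_beta, sign="min")
    ve = beamform.extract_virtual_electrode(ts_beta, peak, band=config.beta_band,
                                            cov_band=config.broadband,
                                            reg_fraction=config.reg_fraction)
    out["beta_image"] = img_beta
    out["beta_peak"] = peak
    out["beta_curve"] = spectral.trial_envelope_curve(
        ve.data, rec.sampling_rate, ts_beta.times, config.beta_band,
        config.beta_baseline)
    out["n_bad_trials"] = int(ts_beta.bad_trials.sum())

    ts_gamma = preprocess.reject_bad_trials(
        preprocess.segment_trials(rec, onsets, config.gamma_window,
                                  t0_definition="stimulus onset"),
        n_std=config.bad_trial_nstd, rule=config.bad_trial_rule)
    out["gamma_image"] = beamform.pseudo_t_image(
        ts_gamma, config.gamma_band, config.gamma_active, config.gamma_control,
        grid=grid, spacing=config.grid_spacing, reg_fraction=config.reg_fraction,
        mode=config.pseudo_t_mode)
    out["ts_gamma"] = ts_gamma
    return out


def run_visuomotor(config: PipelineConfig) -> dict:
    """Full visuomotor analysis of a synthetic cohort.

    Per subject: pseudo-T images (beta at the subject's own peak, gamma at
    the posture's group-mean peak), relative envelope curves; per posture:
    rebound-gradient and gamma-amplitude permutation tests; plus the pooled
    (posture-averaged) gamma test.
    """
    truth = synth.default_ground_truth(seed=config.seed, n_regions=config.n_regions)
    seeds = _subject_seeds(config.seed, 2 * len(config.postures) * config.n_subjects_per_group)
    subjects = {}
    k = 0
    for group in config.groups:
        for posture in config.postures:
            for s in range(config.n_subjects_per_group):
                subjects[(group, posture, s)] = _visuomotor_subject(
                    config, truth, group, seeds[k])
                k += 1

    results = {"seed": config.seed, "config_hash": config.hash(), "tests": {},
               "curves": {}, "drop_log": {}}
    for posture in config.postures:
        # group-mean gamma peak for this posture, across both groups
        imgs = [subjects[(g, posture, s)]["gamma_image"]
                for g in config.groups for s in range(config.n_subjects_per_group)]
        gpeak = beamform.group_peak_location(imgs, sign="max")
        for key in [k for k in subjects if k[1] == posture]:
            sub = subjects[key]
            ve = beamform.extract_virtual_electrode(
                sub["ts_gamma"], gpeak, band=config.gamma_band,
                cov_band=config.broadband, reg_fraction=config.reg_fraction)
            times = sub["ts_gamma"].times
            sub["gamma_curve"] = spectral.trial_envelope_curve(
                ve.data, 375.0, times, config.gamma_band, config.gamma_baseline)
            ve_a = beamform.extract_virtual_electrode(
                sub["ts_gamma"], gpeak, band=config.alpha_band,
                cov_band=config.broadband, reg_fraction=config.reg_fraction)
            sub["alpha_curve"] = spectral.trial_envelope_curve(
                ve_a.data, 375.0, times, config.alpha_band, config.gamma_baseline)

        def curves(group, name):
            return [subjects[(group, posture, s)][name]
                    for s in range(config.n_subjects_per_group)]

        pa, co = config.groups[0], config.groups[1]
        results["tests"][f"rebound_gradient_{posture}"] = stats.permutation_group_test(
            curves(pa, "beta_curve"), curves(co, "beta_curve"),
            statistic="gradient_difference", n_permutations=config.n_permutations,
            seed=config.seed, sidedness=config.rebound_sidedness,
            search_window=config.rebound_search)
        results["tests"][f"gamma_amplitude_{posture}"] = stats.permutation_group_test(
            curves(pa, "gamma_curve"), curves(co, "gamma_curve"),
            statistic="window_mean_difference", n_permutations=config.n_permutations,
            seed=config.seed, sidedness=config.gamma_sidedness,
            window=config.gamma_active)
        results["tests"][f"alpha_amplitude_{posture}"] = stats.permutation_group_test(
            curves(pa, "alpha_curve"), curves(co, "alpha_curve"),
            statistic="window_mean_difference", n_permutations=config.n_permutations,
            seed=config.seed, sidedness=config.alpha_sidedness,
            window=config.gamma_active)
        for g in config.groups:
            mean, sem = spectral.group_envelope(curves(g, "beta_curve"))
            results["curves"][f"beta_{g}_{posture}"] = (mean, sem)
            mean, sem = spectral.group_envelope(curves(g, "gamma_curve"))
            results["curves"][f"gamma_{g}_{posture}"] = (mean, sem)

    # pooled gamma: average each subject's two postures, single test
    def pooled(group):
        out = []
        for s in range(config.n_subjects_per_group):
            cs = [subjects[(group, p, s)]["gamma_curve"] for p in config.postures]
            out.append(replace(cs[0], curve=np.mean([c.curve for c in cs], axis=0)))
        return out

    results["tests"]["gamma_amplitude_pooled"] = stats.permutation_group_test(
        pooled(config.groups[0]), pooled(config.groups[1]),
        statistic="window_mean_difference", n_permutations=config.n_permutations,
        seed=config.seed, sidedness=config.gamma_sidedness, window=config.gamma_active)
    results["drop_log"] = {
        f"{g}_{p}_{s}": {"bad_trials": subjects[(g, p, s)]["n_bad_trials"],
                         "undetected": subjects[(g, p, s)]["n_undetected_movements"]}
        for (g, p, s) in subjects}
    return results


# ---------------------------------------------------------------------------
# resting state

def _resting_subject(config, truth, subj_seed):
    array = synth.make_sensor_array(config.n_sensors, seed=subj_seed % 97)
    rec = synth.simulate_resting_dataset(array, truth,
                                         duration=config.rest_duration,
                                         seed=subj_seed, snr=config.rest_snr)
    rec = _preprocess(rec, config)
    segs, _ = preprocess.reject_bad_segments(rec, config.segment_length)
    if not config.skip_artifact_removal:
        rec = preprocess.remove_stereotyped_artifacts(rec, references=None)
    centroids = truth.parcellation.centroids
    n_per = segs.data.shape[2]

    ves_broad = beamform.extract_virtual_electrodes(
        segs, centroids, band=None, cov_band=config.broadband,
        reg_fraction=config.reg_fraction)
    ves_beta = beamform.extract_virtual_electrodes(
        segs, centroids, band=config.beta_band, cov_band=config.broadband,
        reg_fraction=config.reg_fraction)

    power = np.array([spectral.relative_band_power(
        v.data.reshape(-1), 375.0, band=config.beta_band,
        broadband=config.broadband) for v in ves_broad])
    beta_sources = np.stack([v.data.reshape(-1) for v in ves_beta])
    cm = connectivity.build_connectome(beta_sources, truth.parcellation.names,
                                       segment_samples=n_per)
    return {"power": power, "connectome": cm,
            "n_bad_segments": int(segs.bad_trials.sum())}


def run_resting(config: PipelineConfig) -> dict:
    """Resting-state analysis: regional beta power, connectomes, group tests.

    Four Wilcoxon tests per measure and network (sit-vs-stand within each
    group, patients-vs-controls within each posture), with the Bonferroni
    threshold alpha / 4.
    """
    base_truth = synth.default_ground_truth(seed=config.seed, n_regions=config.n_regions)
    parc = base_truth.parcellation
    seeds = _subject_seeds(config.seed + 1, 2 * len(config.postures) * config.n_subjects_per_group)
    measures = {}
    k = 0
    for group in config.groups:
        for posture in config.postures:
            factor = (config.standing_beta_factor.get(group, 1.0)
                      if posture == "standing" else 1.0)
            truth = replace(base_truth,
                            beta_fractions=base_truth.beta_fractions * factor)
            for s in range(config.n_subjects_per_group):
                measures[(group, posture, s)] = _resting_subject(config, truth, seeds[k])
                k += 1

    sm = parc.sensorimotor
    dm = parc.dorsomedial
    sm_names = [n for n, f in zip(parc.names, sm) if f]
    dm_names = [n for n, f in zip(parc.names, dm) if f]

    def network_power(key, flags):
        return measures[key]["power"][flags].mean()

    def network_conn(key, names):
        return connectivity.connectivity_strength(measures[key]["connectome"], names)[1]

    results = {"seed": config.seed, "config_hash": config.hash(), "tests": {},
               "bonferroni_threshold": stats.bonferroni_threshold(config.alpha_level, 4),
               "power": measures}
    pa, co = config.groups[0], config.groups[1]
    n_s = config.n_subjects_per_group
    for label, flags, names in (("sensorimotor", sm, sm_names),
                                ("dorsomedial", dm, dm_names)):
        for measure, fn in (("beta_power", lambda key: network_power(key, flags)),
                            ("connectivity", lambda key: network_conn(key, names))):
            vals = {(g, p): np.array([fn((g, p, s)) for s in range(n_s)])
                    for g in config.groups for p in config.postures}
            t = {}
            for g in config.groups:
                t[f"{g}_sit_vs_stand"] = stats.wilcoxon_test(
                    vals[(g, "sitting")], vals[(g, "standing")],
                    mode="signed_rank_paired")
            for p in config.postures:
                t[f"{pa}_vs_{co}_{p}"] = stats.wilcoxon_test(
                    vals[(pa, p)], vals[(co, p)], mode="rank_sum_unpaired")
            results["tests"][f"{measure}_{label}"] = t
            results[f"{measure}_{label}_means"] = {f"{g}_{p}": float(v.mean())
                                                   for (g, p), v in vals.items()}
    return results
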