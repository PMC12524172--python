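"""BIDS-like on-disk layout for synthetic cohorts and derived outputs.

Layout per subject / session (posture) / task::

    <root>/sub-<label>/ses-<posture>/meg/
        sub-..._task-<task>_meg.npy        channel data (channels x samples, fT)
        sub-..._task-<task>_meg.json       sampling rate, units, sphere geometry
        sub-..._task-<task>_channels.tsv   name, position, orientation, status
        sub-..._task-<task>_events.tsv     onset (s), trial_type
        sub-..._task-<task>_motion.tsv     time, marker, x, y, z  (120 Hz)

Ground truth is stored next to the dataset as JSON; derived images,
connectomes and masks are written as TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import Recording
from .forward import SensorArray
from .synth import GroundTruth, MotionTrace, Parcellation


def _base(root, subject: str, posture: str, task: str) -> Path:
    d = Path(root) / f"sub-{subject}" / f"ses-{posture}" / "meg"
    d.mkdir(parents=True, exist_ok=True)
    return d / f"sub-{subject}_ses-{posture}_task-{task}"


def write_recording(root, subject: str, posture: str, task: str,
                    rec: Recording, motion: MotionTrace | None = None) -> Path:
    base = _base(root, subject, posture, task)
    np.save(base.with_name(base.name + "_meg.npy"), rec.data)
    arr = rec.array
    meta = {
        "SamplingFrequency": rec.sampling_rate,
        "Units": "fT",
        "SphereOrigin": list(map(float, arr.sphere_origin)),
        "ScalpRadius": float(arr.scalp_radius),
    }
    base.with_name(base.name + "_meg.json").write_text(json.dumps(meta, indent=1))
    ch = pd.DataFrame({
        "name": arr.channel_names,
        "x": arr.channel_positions[:, 0], "y": arr.channel_positions[:, 1],
        "z": arr.channel_positions[:, 2],
        "ox": arr.channel_orientations[:, 0], "oy": arr.channel_orientations[:, 1],
        "oz": arr.channel_orientations[:, 2],
        "status": np.where(rec.bad_channels, "bad", "good"),
    })
    ch.to_csv(base.with_name(base.name + "_channels.tsv"), sep="\t", index=False)
    ev = pd.DataFrame(rec.events, columns=["onset", "trial_type"])
    ev.to_csv(base.with_name(base.name + "_events.tsv"), sep="\t", index=False)
    if motion is not None:
        rows = []
        t = motion.times
        for m in range(motion.n_markers):
            rows.append(pd.DataFrame({
                "time": t, "marker": m,
                "x": motion.positions[m, 0], "y": motion.positions[m, 1],
                "z": motion.positions[m, 2]}))
        pd.concat(rows).to_csv(base.with_name(base.name + "_motion.tsv"),
                               sep="\t", index=False)
    return base


def read_recording(root, subject: str, posture: str, task: str) -> Recording:
    base = _base(root, subject, posture, task)
    data = np.load(base.with_name(base.name + "_meg.npy"))
    if np.isnan(data).any():
        raise ValueError("channel data contain NaN")
    meta = json.loads(base.with_name(base.name + "_meg.json").read_text())
    ch = pd.read_csv(base.with_name(base.name + "_channels.tsv"), sep="\t")
    pos = ch[["x", "y", "z"]].to_numpy()[::3]
    ori = ch[["ox", "oy", "oz"]].to_numpy().reshape(-1, 3, 3)
    array = SensorArray(sensor_positions=pos, sensor_orientations=ori,
                        channel_names=list(ch["name"]),
                        sphere_origin=np.array(meta["SphereOrigin"]),
                        scalp_radius=meta["ScalpRadius"])
    ev = pd.read_csv(base.with_name(base.name + "_events.tsv"), sep="\t")
    events = [(float(t), str(lab)) for t, lab in zip(ev["onset"], ev["trial_type"])]
    return Recording(data=data, sampling_rate=meta["SamplingFrequency"],
                     array=array, events=events,
                     bad_channels=(ch["status"] == "bad").to_numpy())


def read_motion(root, subject: str, posture: str, task: str) -> MotionTrace:
    base = _base(root, subject, posture, task)
    df = pd.read_csv(base.with_name(base.name + "_motion.tsv"), sep="\t")
    markers = sorted(df["marker"].unique())
    n_t = (df["marker"] == markers[0]).sum()
    pos = np.empty((len(markers), 3, n_t))
    for k, m in enumerate(markers):
        sub = df[df["marker"] == m]
        pos[k] = sub[["x", "y", "z"]].to_numpy().T
    rate = 1.0 / np.median(np.diff(df[df["marker"] == markers[0]]["time"]))
    return MotionTrace(positions=pos, sampling_rate=float(round(rate)))


def write_events(root, subject, posture, task, times, label="movement_offset"):
    """Append detected events to the dataset's events TSV."""
    base = _base(root, subject, posture, task)
    p = base.with_name(base.name + "_events.tsv")
    ev = pd.read_csv(p, sep="\t") if p.exists() else pd.DataFrame(columns=["onset", "trial_type"])
    new = pd.DataFrame({"onset": times, "trial_type": label})
    pd.concat([ev, new]).sort_values("onset").to_csv(p, sep="\t", index=False)


def write_ground_truth(path, truth: GroundTruth) -> None:
    d = {
        "motor_location": list(map(float, truth.motor_location)),
        "visual_location": list(map(float, truth.visual_location)),
        "rebound_gradient": truth.rebound_gradient,
        "gamma_gain": truth.gamma_gain,
        "erd_depth": truth.erd_depth,
        "rebound_peak": truth.rebound_peak,
        "beta_fractions": None if truth.beta_fractions is None
        else list(map(float, truth.beta_fractions)),
        "envelope_pairs": [[int(i), int(j), float(r)] for i, j, r in truth.envelope_pairs],
        "movement_offset_times": None if truth.movement_offset_times is None
        else list(map(float, truth.movement_offset_times)),
        "rng_seed": truth.rng_seed,
    }
    if truth.parcellation is not None:
        p = truth.parcellation
        d["parcellation"] = {
            "names": p.names, "centroids": p.centroids.tolist(),
            "hemispheres": p.hemispheres,
            "sensorimotor": p.sensorimotor.tolist(),
            "dorsomedial": p.dorsomedial.tolist(),
        }
    Path(path).write_text(json.dumps(d, indent=1))


def read_ground_truth(path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    parc = None
    if "parcellation" in d:
        q = d["parcellation"]
        parc = Parcellation(names=q["names"], centroids=np.array(q["centroids"]),
                            hemispheres=q["hemispheres"],
                            sensorimotor=np.array(q["sensorimotor"]),
                            dorsomedial=np.array(q["dorsomedial"]))
    return GroundTruth(
        motor_location=np.array(d["motor_location"]),
        visual_location=np.array(d["visual_location"]),
        rebound_gradient=d["rebound_gradient"], gamma_gain=d["gamma_gain"],
        erd_depth=d["erd_depth"], rebound_peak=d["rebound_peak"],
        parcellation=parc,
        beta_fractions=None if d["beta_fractions"] is None else np.array(d["beta_fractions"]),
        envelope_pairs=[tuple(p) for p in d["envelope_pairs"]],
        movement_offset_times=None if d["movement_offset_times"] is None
        else np.array(d["movement_offset_times"]),
        rng_seed=d["rng_seed"])


def parcellation_to_tsv(parc: Parcellation, path) -> None:
    pd.DataFrame({
        "name": parc.names,
        "x": parc.centroids[:, 0], "y": parc.centroids[:, 1], "z": parc.centroids[:, 2],
        "hemisphere": parc.hemispheres,
        "sensorimotor": parc.sensorimotor.astype(int),
        "dorsomedial": parc.dorsomedial.astype(int),
    }).to_csv(path, sep="\t", index=False)


def parcellation_from_tsv(path) -> Parcellation:
    df = pd.read_csv(path, sep="\t")
    return Parcellation(names=list(df["name"]),
                        centroids=df[["x", "y", "z"]].to_numpy(),
                        hemispheres=list(df["hemisphere"]),
                        sensorimotor=df["sensorimotor"].astype(bool).to_numpy(),
                        dorsomedial=df["dorsomedial"].astype(bool).to_numpy())


def image_to_tsv(img, path) -> None:
    pd.DataFrame({"x": img.points[:, 0], "y": img.points[:, 1],
                  "z": img.points[:, 2], "value": img.values}).to_csv(
        path, sep="\t", index=False)
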