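"""Shared fixtures: small synthetic datasets, one per protocol.

Session-scoped because simulation is the expensive part; tests must not
mutate the returned datasets.
"""

import numpy as np
import pytest

from comfeedback.dataset import (
    GaitEvents,
    Perturbation,
    SubjectConstants,
    Trial,
)
from comfeedback.simulate import (
    GainSchedule,
    SimParams,
    default_standing_schedule,
    default_walking_schedule,
    simulate_standing,
    simulate_walking,
)

STANDING_SCHEDULE = default_standing_schedule(
    magnitudes=(0.5, 0.8, 1.1, 1.4), durations=(0.45, 0.35, 0.28, 0.22)
)

LOW_NOISE = {"com_pos": 1e-4, "com_vel": 1e-3, "ankle_moment": 0.1, "emg": 0.002}


@pytest.fixture(scope="session")
def standing_noiseless():
    params = SimParams(protocol="standing_translation", seed=11,
                       schedule=STANDING_SCHEDULE)
    dataset, truth = simulate_standing(params)
    return dataset, truth


@pytest.fixture(scope="session")
def standing_noisy():
    params = SimParams(protocol="standing_translation", seed=12,
                       schedule=STANDING_SCHEDULE,
                       noise=dict(LOW_NOISE), ankle_angle_noise=0.01)
    dataset, truth = simulate_standing(params)
    return dataset, truth


@pytest.fixture(scope="session")
def pelvis_noiseless():
    params = SimParams(protocol="pelvis_push", seed=13,
                       gains=GainSchedule(kp=2.5, kv=0.8, kind="raised_cosine"),
                       n_strides=6)
    dataset, truth = simulate_walking(params)
    return dataset, truth


@pytest.fixture(scope="session")
def belt_discrete_noiseless():
    params = SimParams(
        protocol="belt_discrete", seed=14,
        gains=GainSchedule(kp=2.5, kv=0.8, kind="raised_cosine"),
        schedule=default_walking_schedule(magnitudes=(0.10, 0.16, 0.22)),
        n_strides=6,
    )
    dataset, truth = simulate_walking(params)
    return dataset, truth


@pytest.fixture(scope="session")
def continuous_binned_noiseless():
    params = SimParams(
        protocol="belt_continuous", seed=15,
        gains=GainSchedule(kp=2.5, kv=0.8, kind="binned_raised_cosine"),
        n_strides=40, n_unperturbed=1,
    )
    dataset, truth = simulate_walking(params)
    return dataset, truth


@pytest.fixture(scope="session")
def continuous_smooth_noisy():
    params = SimParams(
        protocol="belt_continuous", seed=16,
        gains=GainSchedule(kp=2.5, kv=0.8, kind="raised_cosine"),
        noise={"com_pos": 1e-4, "com_vel": 1e-3, "ankle_moment": 0.2},
        n_strides=60, n_unperturbed=1,
    )
    dataset, truth = simulate_walking(params)
    return dataset, truth


def write_mat_dataset(path, trials):
    """Write trials as a .mat archive in the canonical mapping layout."""
    from scipy.io import savemat

    entries = []
    for tr in trials:
        entry = {
            "subject_id": tr.subject.subject_id,
            "mass": tr.subject.mass,
            "com_height": tr.subject.com_height,
            "condition": tr.condition,
            "walking_speed": tr.walking_speed,
            "fs": tr.fs,
            "analyzed_leg": tr.analyzed_leg,
            "time": tr.time,
            "com_pos": tr.com_pos,
            "com_vel": tr.com_vel,
            "ankle_angle": tr.ankle_angle,
            "ankle_vel": tr.ankle_vel,
            "ankle_moment": tr.ankle_moment,
            "grf_vertical": tr.grf_vertical,
            "cop_ap": tr.cop_ap,
            "events_left_hs": np.asarray(tr.gait_events.left_hs),
            "events_left_to": np.asarray(tr.gait_events.left_to),
            "events_right_hs": np.asarray(tr.gait_events.right_hs),
            "events_right_to": np.asarray(tr.gait_events.right_to),
        }
        for muscle, arr in tr.emg.items():
            entry[f"emg_{muscle}"] = arr
        for muscle, val in tr.emg_norm.items():
            entry[f"emg_norm_{muscle}"] = val
        if tr.perturbation is not None:
            entry["perturb_onset"] = tr.perturbation.onset
            entry["perturb_direction"] = tr.perturbation.direction
            entry["perturb_magnitude"] = tr.perturbation.magnitude
        if tr.foot_heel_ap is not None:
            entry["foot_heel_ap"] = tr.foot_heel_ap
            entry["foot_toe_ap"] = tr.foot_toe_ap
        entries.append(entry)
    keys = sorted(set().union(*[e.keys() for e in entries]))
    rec = np.zeros((len(entries),), dtype=[(k, object) for k in keys])
    for i, e in enumerate(entries):
        for k in keys:
            rec[i][k] = e.get(k, np.array([]))
    savemat(path, {"trials": rec})


def make_trial(n=500, fs=100.0, seed=0, perturbed=False, protocol="standing_translation",
               walking_speed=0.0, events=None, **overrides):
    """Small hand-built trial for IO/validation tests."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs

    def sig():
        return rng.standard_normal(n) * 0.01

    fields = dict(
        subject=SubjectConstants(f"T{seed}", 70.0, 0.95),
        condition="perturbed" if perturbed else "unperturbed",
        protocol=protocol,
        walking_speed=walking_speed,
        fs=fs,
        time=t,
        com_pos=sig(),
        com_vel=sig(),
        ankle_angle=sig(),
        ankle_vel=sig(),
        ankle_moment=sig() * 10,
        grf_vertical=686.7 + sig(),
        cop_ap=sig(),
        emg={"soleus": np.abs(sig()), "tibialis_anterior": np.abs(sig())},
        emg_norm={"soleus": 0.5, "tibialis_anterior": 0.4},
        perturbation=Perturbation(onset=t[n // 2], direction="forward",
                                  magnitude=1.0) if perturbed else None,
        gait_events=events or GaitEvents(),
    )
    fields.update(overrides)
    return Trial(**fields)
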