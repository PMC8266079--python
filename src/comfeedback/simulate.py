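"""Synthetic perturbed-balance data from a known generative law.

The generator embeds the delayed linear feedback law that the identification
stage estimates (delayed proportional-derivative feedback of COM position
and velocity to ankle moment, direction-gated for EMG) in a linearized
inverted pendulum, so every identification stage can be verified by
parameter recovery. Realism knobs (noise amplitudes, a nuisance component on
the ankle angle that breaks joint-level fits) are explicit parameters.

Exactness choices:

* the generative delay is an integer step shift of the 1 kHz integration
  history (delays exact to 1 ms);
* the default stride time (2.0 s at fs = 100 Hz) makes one stride exactly
  200 samples, so the 200-point reference phase grid coincides with sample
  phases and noiseless identification is exact to floating precision;
* perturbation schedules vary the pulse duration across magnitudes — with a
  single pulse shape all rows of a noiseless linear system are collinear and
  the two gains are not separately identifiable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataset import (
    Dataset,
    GaitEvents,
    Perturbation,
    SubjectConstants,
    Trial,
    write_dataset,
)
from .errors import InstabilityError

SIGNAL_STREAMS = (
    "com_pos", "com_vel", "ankle_moment", "ankle_angle", "grf", "cop",
    "emg_tibialis_anterior", "emg_soleus", "emg_gastrocnemius", "perturb",
)

MUSCLE_SIGNS = {"soleus": +1.0, "gastrocnemius": +1.0, "tibialis_anterior": -1.0}


def _raised_cosine(x, center, width):
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    inside = np.abs(x - center) < width / 2
    out[inside] = 0.5 * (1 + np.cos(2 * np.pi * (x[inside] - center) / width))
    return out


@dataclass(frozen=True)
class GainSchedule:
    """True gain profile over the stance sub-phase (zero in swing).

    kinds: ``constant`` (kp/kv throughout stance), ``raised_cosine``
    (smooth window centered at ``peak_phase`` with full width ``width``,
    both as fractions of stance), ``binned_raised_cosine`` (the raised
    cosine sampled at the centers of ``n_bins`` stance bins and held
    constant inside each bin — makes binned identification exact).
    """

    kp: float
    kv: float
    kind: str = "constant"
    peak_phase: float = 0.5
    width: float = 0.9
    n_bins: int = 16

    def __post_init__(self):
        if self.kind not in ("constant", "raised_cosine", "binned_raised_cosine"):
            raise ValueError(f"unknown gain schedule kind {self.kind!r}")
        if self.kind != "constant":
            lo = self.peak_phase - self.width / 2
            hi = self.peak_phase + self.width / 2
            if lo < -1e-9 or hi > 1 + 1e-9:
                raise ValueError("raised-cosine window must lie inside stance")

    def _shape(self, u):
        u = np.asarray(u, dtype=float)
        if self.kind == "constant":
            return np.where((u >= 0) & (u <= 1), 1.0, 0.0)
        if self.kind == "raised_cosine":
            return _raised_cosine(u, self.peak_phase, self.width)
        from .preprocessing import phase_bin_index

        centers = (np.arange(self.n_bins) + 0.5) / self.n_bins
        values = _raised_cosine(centers, self.peak_phase, self.width)
        out = values[phase_bin_index(np.nan_to_num(u), self.n_bins)]
        return np.where((u >= 0) & (u < 1), out, 0.0)

    def kp_at(self, u):
        return self.kp * self._shape(u)

    def kv_at(self, u):
        return self.kv * self._shape(u)


PULSE_SHAPES = ("rcos", "rect", "doublet")


@dataclass(frozen=True)
class PerturbationSpec:
    """One scheduled discrete perturbation (one trial).

    ``shape``: ``rcos`` (raised-cosine acceleration pulse, net velocity
    change), ``rect`` (rectangular pulse), ``doublet`` (accelerate then
    decelerate — net displacement with near-zero net velocity). Mixing
    shapes decorrelates position and velocity deviations across trials;
    with one self-similar shape the two gains are not separately
    identifiable.
    """

    direction: str  # forward | backward
    magnitude: float  # platform m/s^2 | push N | belt m/s
    duration: float  # pulse duration, s
    shape: str = "rcos"
    onset_phase: float = 0.1  # stride fraction (walking)
    onset_stride: int = 2  # stride index of the onset (walking)
    onset_time: float = 2.0  # s (standing)

    def __post_init__(self):
        if self.shape not in PULSE_SHAPES:
            raise ValueError(f"unknown pulse shape {self.shape!r}")


def _pulse(t, onset, duration, magnitude, shape):
    """Acceleration profile of one pulse on the time grid ``t``."""
    a = np.zeros_like(t)
    inside = (t >= onset) & (t < onset + duration)
    ph = (t[inside] - onset) / duration
    if shape == "rcos":
        a[inside] = magnitude * 0.5 * (1 - np.cos(2 * np.pi * ph))
    elif shape == "rect":
        a[inside] = magnitude
    else:  # doublet
        a[inside] = magnitude * np.sin(2 * np.pi * ph)
    return a


def default_standing_schedule(magnitudes=(0.6, 1.0, 1.4),
                              durations=(0.40, 0.30, 0.22),
                              onset_time: float = 2.0):
    """Forward+backward platform pulses of mixed shape; faster profiles are
    briefer (the fast/medium/slow acceleration profiles)."""
    specs = []
    for i, (mag, dur) in enumerate(zip(magnitudes, durations)):
        shape = PULSE_SHAPES[i % len(PULSE_SHAPES)]
        for direction in ("forward", "backward"):
            specs.append(PerturbationSpec(direction=direction, magnitude=mag,
                                          duration=dur, shape=shape,
                                          onset_time=onset_time))
    return tuple(specs)


def default_walking_schedule(magnitudes=(40.0, 70.0, 100.0),
                             durations=(0.30, 0.22, 0.16),
                             onset_phase: float = 0.1,
                             onset_stride: int = 2):
    specs = []
    for i, (mag, dur) in enumerate(zip(magnitudes, durations)):
        shape = PULSE_SHAPES[i % len(PULSE_SHAPES)]
        for direction in ("forward", "backward"):
            specs.append(PerturbationSpec(direction=direction, magnitude=mag,
                                          duration=dur, shape=shape,
                                          onset_phase=onset_phase,
                                          onset_stride=onset_stride))
    return tuple(specs)


@dataclass
class SimParams:
    """Full generative description of one synthetic dataset."""

    protocol: str = "standing_translation"
    subject: SubjectConstants = field(
        default_factory=lambda: SubjectConstants("S01", 70.0, 0.95)
    )
    gains: GainSchedule = field(default_factory=lambda: GainSchedule(kp=1.5, kv=0.6))
    tau_T: float = 0.100
    tau_m: float = 0.060
    emg_gains: dict = field(default_factory=lambda: {
        "soleus": (0.8, 0.4), "gastrocnemius": (0.6, 0.3),
        "tibialis_anterior": (0.7, 0.35),
    })
    emg_baseline: float = 0.05
    noise: dict = field(default_factory=dict)  # signal name -> sigma (SI units)
    ankle_angle_noise: float = 0.0  # rad, independent nuisance on ankle angle
    schedule: tuple | None = None  # None -> protocol default; () -> none
    n_unperturbed: int = 2
    trial_duration: float = 5.0  # standing trials, s
    stride_time: float = 2.0
    stance_fraction: float = 0.6
    n_strides: int = 8  # per walking trial
    walking_speed: float = 1.1
    continuous_cutoff_hz: float = 1.0
    continuous_rms: float = 0.05  # belt-speed RMS, m/s
    n_continuous_trials: int = 1
    #: extra stabilizing (kp, kv) acting on the COM dynamics only (stands in
    #: for hip/stepping mechanisms); never part of the recorded ankle moment,
    #: keeps the loop stable where the stance gain profiles dip near zero.
    background_gains: tuple = (1.2, 0.5)
    fs: float = 100.0
    sim_rate: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        if self.schedule is None:
            if self.protocol == "standing_translation":
                self.schedule = default_standing_schedule()
            elif self.protocol in ("pelvis_push", "belt_discrete"):
                self.schedule = default_walking_schedule()
            else:
                self.schedule = ()
        step = self.sim_rate / self.fs
        if abs(step - round(step)) > 1e-9:
            raise ValueError("sim_rate must be an integer multiple of fs")
        for name, sigma in self.noise.items():
            if sigma < 0:
                raise ValueError(f"noise sigma for {name!r} must be >= 0")


@dataclass
class GroundTruth:
    """Noiseless deviations and true gains of a simulated dataset."""

    params: SimParams
    deviations: list  # per trial: dict name -> noiseless array at fs
    phase_grid: np.ndarray | None = None  # stride phase, walking
    kp_grid: np.ndarray | None = None
    kv_grid: np.ndarray | None = None

    @property
    def tau_T(self) -> float:
        return self.params.tau_T

    def gain_at_stance_phase(self, u):
        return (float(self.params.gains.kp_at(u)),
                float(self.params.gains.kv_at(u)))

    def gain_at_stance_bins(self, n_bins: int = 16):
        centers = (np.arange(n_bins) + 0.5) / n_bins
        return self.params.gains.kp_at(centers), self.params.gains.kv_at(centers)

    def sidecar_csv(self, path) -> None:
        import pandas as pd

        if self.phase_grid is None:
            df = pd.DataFrame({"phase": [float("nan")],
                               "kp": [self.params.gains.kp],
                               "kv": [self.params.gains.kv]})
        else:
            df = pd.DataFrame({"phase": self.phase_grid, "kp": self.kp_grid,
                               "kv": self.kv_grid})
        df["tau_T"] = self.params.tau_T
        df["tau_m"] = self.params.tau_m
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# RNG streams
# ---------------------------------------------------------------------------


def _trial_streams(seed: int, trial_index: int) -> dict:
    """One named RNG stream per signal, derived from the single seed."""
    root = np.random.SeedSequence(entropy=seed, spawn_key=(trial_index,))
    children = root.spawn(len(SIGNAL_STREAMS))
    return {name: np.random.default_rng(c)
            for name, c in zip(SIGNAL_STREAMS, children)}


def _noise(streams, name, sigma, n):
    if sigma == 0:
        return np.zeros(n)
    return sigma * streams[name].standard_normal(n)


def _smooth_noise(rng, sigma, n, fs, cutoff=4.0):
    """Low-pass filtered Gaussian nuisance with std sigma (and its derivative)."""
    if sigma == 0:
        return np.zeros(n), np.zeros(n)
    from scipy.signal import butter, filtfilt

    raw = rng.standard_normal(n + 200)
    b, a = butter(2, cutoff / (fs / 2))
    smooth = filtfilt(b, a, raw)[100:100 + n]
    std = np.std(smooth)
    if std > 0:
        smooth = smooth * (sigma / std)
    return smooth, np.gradient(smooth) * fs


# ---------------------------------------------------------------------------
# closed-loop integration (shared by standing and walking)
# ---------------------------------------------------------------------------


def _integrate(params: SimParams, a_ext: np.ndarray,
               kp_tot: np.ndarray, kv_tot: np.ndarray,
               kp_rec: np.ndarray, kv_rec: np.ndarray):
    """Semi-implicit Euler at sim_rate with a ring-history delay.

    ``kp_tot``/``kv_tot`` drive the COM dynamics (all stabilizing moments);
    ``kp_rec``/``kv_rec`` generate the recorded reactive moment of the
    analyzed ankle. Returns (x, v, T_rec) downsampled to fs.
    """
    sub = params.subject
    g, l, m = sub.gravity, sub.com_height, sub.mass
    rate = params.sim_rate
    dt = 1.0 / rate
    kdel = round(params.tau_T * rate)
    n_steps = len(a_ext)
    c_g = g / l
    inv_ml = 1.0 / (m * l)
    mgl = m * g * l
    inv_l = 1.0 / l
    inv_vs = 1.0 / math.sqrt(g * l)
    x_lim = 0.5 * l

    a_list = a_ext.tolist()
    kpt = kp_tot.tolist()
    kvt = kv_tot.tolist()
    kpr = kp_rec.tolist()
    kvr = kv_rec.tolist()

    xs = [0.0] * n_steps
    vs = [0.0] * n_steps
    Ts = [0.0] * n_steps
    x = 0.0
    v = 0.0
    for i in range(n_steps):
        xs[i] = x
        vs[i] = v
        if i >= kdel:
            xd = xs[i - kdel]
            vd = vs[i - kdel]
        else:
            xd = 0.0
            vd = 0.0
        drive = xd * inv_l
        dvel = vd * inv_vs
        Ts[i] = mgl * (kpr[i] * drive + kvr[i] * dvel)
        T_tot = mgl * (kpt[i] * drive + kvt[i] * dvel)
        a = c_g * x - T_tot * inv_ml + a_list[i]
        v += a * dt
        x += v * dt
        if abs(x) > x_lim:
            raise InstabilityError(
                f"closed loop unstable at t={i * dt:.2f} s with gains "
                f"kp={params.gains.kp}, kv={params.gains.kv}"
            )
    step = round(rate / params.fs)
    return (np.asarray(xs)[::step], np.asarray(vs)[::step], np.asarray(Ts)[::step])


def _emg_envelopes(params: SimParams, x: np.ndarray, v: np.ndarray,
                   shape_u: np.ndarray, streams) -> tuple[dict, dict]:
    """Direction-gated EMG from delayed nondim COM deviations (at fs)."""
    sub = params.subject
    l, g = sub.com_height, sub.gravity
    km = round(params.tau_m * params.fs)
    n = len(x)
    xd = np.zeros(n)
    vd = np.zeros(n)
    xd[km:] = x[:n - km] / l
    vd[km:] = v[:n - km] / math.sqrt(g * l)
    emg = {}
    noiseless = {}
    for muscle, (kp_e, kv_e) in params.emg_gains.items():
        sign = MUSCLE_SIGNS[muscle]
        drive = sign * shape_u * (kp_e * xd + kv_e * vd)
        clean = params.emg_baseline + np.maximum(0.0, drive)
        noiseless[muscle] = clean
        emg[muscle] = clean + _noise(
            streams, f"emg_{muscle}", params.noise.get("emg", 0.0), n
        )
    return emg, noiseless


# ---------------------------------------------------------------------------
# standing
# ---------------------------------------------------------------------------


def _platform_pulse(spec: PerturbationSpec, n_steps: int, rate: float) -> np.ndarray:
    """Base-acceleration pulse of the scheduled shape."""
    t = np.arange(n_steps) / rate
    sign = 1.0 if spec.direction == "forward" else -1.0
    return _pulse(t, spec.onset_time, spec.duration, sign * spec.magnitude,
                  spec.shape)


def simulate_standing(params: SimParams):
    """Simulate perturbed standing; returns (Dataset, GroundTruth).

    The platform translation enters as base acceleration; ankle moment is
    the delayed PD feedback law of nondimensional COM deviations.
    """
    if params.protocol != "standing_translation":
        raise ValueError("simulate_standing requires protocol='standing_translation'")
    sub = params.subject
    g, l, m = sub.gravity, sub.com_height, sub.mass
    rate, fs = params.sim_rate, params.fs
    n_samples = int(round(params.trial_duration * fs)) + 1
    n_steps = (n_samples - 1) * round(rate / fs) + 1

    kp = np.full(n_steps, params.gains.kp)
    kv = np.full(n_steps, params.gains.kv)
    trials = []
    truths = []
    specs = list(params.schedule) + [None] * params.n_unperturbed
    for idx, spec in enumerate(specs):
        streams = _trial_streams(params.seed, idx)
        if spec is None:
            a_ext = np.zeros(n_steps)
        else:
            a_ext = _platform_pulse(spec, n_steps, rate)
        x, v, T = _integrate(params, a_ext, kp, kv, kp, kv)
        n = len(x)
        t100 = np.arange(n) / fs
        nz_q, nz_qd = _smooth_noise(streams["ankle_angle"],
                                    params.ankle_angle_noise, n, fs)
        emg, emg_clean = _emg_envelopes(params, x, v, np.ones(n), streams)
        fy = m * g + _noise(streams, "grf", params.noise.get("grf", 0.0), n)
        trial = Trial(
            subject=sub,
            condition="unperturbed" if spec is None else "perturbed",
            protocol=params.protocol,
            walking_speed=0.0,
            fs=fs,
            time=t100,
            com_pos=x + _noise(streams, "com_pos", params.noise.get("com_pos", 0.0), n),
            com_vel=v + _noise(streams, "com_vel", params.noise.get("com_vel", 0.0), n),
            ankle_angle=x / l + nz_q,
            ankle_vel=v / l + nz_qd,
            ankle_moment=T + _noise(streams, "ankle_moment",
                                    params.noise.get("ankle_moment", 0.0), n),
            grf_vertical=fy,
            cop_ap=T / (m * g) + _noise(streams, "cop", params.noise.get("cop", 0.0), n),
            emg=emg,
            emg_norm={mu: 1.0 for mu in emg},
            perturbation=None if spec is None else Perturbation(
                onset=spec.onset_time, direction=spec.direction,
                magnitude=spec.magnitude,
            ),
            foot_heel_ap=np.full(n, -0.10),
            foot_toe_ap=np.full(n, 0.20),
        ).validate()
        trials.append(trial)
        truths.append({"d_com_pos": x, "d_com_vel": v, "d_ankle_moment": T,
                       "d_emg": {mu: arr - params.emg_baseline
                                 for mu, arr in emg_clean.items()}})
    dataset = Dataset(trials, provenance="synthetic").validate()
    truth = GroundTruth(params=params, deviations=truths)
    return dataset, truth


# ---------------------------------------------------------------------------
# walking
# ---------------------------------------------------------------------------


def _nominal_templates(params: SimParams, s: np.ndarray) -> dict:
    """Smooth periodic templates as functions of stride phase."""
    sub = params.subject
    m, g = sub.mass, sub.gravity
    sf = params.stance_fraction
    st = params.stride_time
    u = np.where(s < sf, s / sf, np.nan)
    in_stance = s < sf
    uz = np.where(in_stance, s / sf, 0.0)

    com_pos = 0.04 * np.sin(2 * np.pi * s)
    com_vel = 0.04 * 2 * np.pi * np.cos(2 * np.pi * s) / st
    ankle_angle = 0.10 * np.sin(2 * np.pi * s + 0.8)
    ankle_vel = 0.10 * 2 * np.pi * np.cos(2 * np.pi * s + 0.8) / st
    ankle_moment = np.where(in_stance, 1.0 * m * _raised_cosine(uz, 0.65, 0.7), 0.0)
    fy = np.where(in_stance,
                  1.1 * m * g * np.maximum(0.0, np.sin(np.pi * uz)) ** 0.7, 0.0)
    cop = np.where(in_stance, -0.05 + 0.25 * uz, 0.0)
    emg = {
        "soleus": 0.30 * np.where(in_stance, _raised_cosine(uz, 0.70, 0.6), 0.0),
        "gastrocnemius": 0.25 * np.where(in_stance, _raised_cosine(uz, 0.65, 0.6), 0.0),
        "tibialis_anterior": 0.20 * np.where(in_stance, _raised_cosine(uz, 0.15, 0.5), 0.0),
    }
    return dict(com_pos=com_pos, com_vel=com_vel, ankle_angle=ankle_angle,
                ankle_vel=ankle_vel, ankle_moment=ankle_moment, grf_vertical=fy,
                cop_ap=cop, emg=emg, u=u, in_stance=in_stance)


def _walking_gain_arrays(params: SimParams, s: np.ndarray):
    """Analyzed-leg and two-leg-total gain arrays over stride phase.

    The contralateral leg runs the same profile half a stride out of phase;
    both stabilize the COM, but only the analyzed leg's share is recorded.
    """
    sf = params.stance_fraction
    sched = params.gains

    def leg(su):
        u = su / sf
        kp = np.where(su < sf, sched.kp_at(np.clip(u, 0.0, 1.0 - 1e-12)), 0.0)
        kv = np.where(su < sf, sched.kv_at(np.clip(u, 0.0, 1.0 - 1e-12)), 0.0)
        return kp, kv

    kp_a, kv_a = leg(np.mod(s, 1.0))
    kp_o, kv_o = leg(np.mod(s + 0.5, 1.0))
    bg_p, bg_v = params.background_gains
    return kp_a, kv_a, kp_a + kp_o + bg_p, kv_a + kv_o + bg_v


def _walking_events(params: SimParams) -> GaitEvents:
    st = params.stride_time
    sf = params.stance_fraction
    T = params.n_strides * st
    hs_a = [k * st for k in range(params.n_strides + 1)]
    to_a = [k * st + sf * st for k in range(params.n_strides)]
    hs_o = [(k + 0.5) * st for k in range(params.n_strides)]
    to_o = [(k - 0.5) * st + sf * st for k in range(params.n_strides + 1)]
    to_o = [t for t in to_o if 0 <= t <= T]
    hs_o = [t for t in hs_o if 0 <= t <= T]
    return GaitEvents(left_hs=tuple(hs_a), left_to=tuple(to_a),
                      right_hs=tuple(hs_o), right_to=tuple(to_o))


def _walking_drive(params: SimParams, spec, n_steps: int, streams) -> np.ndarray:
    """External COM acceleration input for one walking trial."""
    rate = params.sim_rate
    if params.protocol == "belt_continuous":
        from scipy.signal import butter, filtfilt

        raw = streams["perturb"].standard_normal(n_steps + 2000)
        b, a = butter(2, params.continuous_cutoff_hz / (rate / 2))
        belt = filtfilt(b, a, raw)[1000:1000 + n_steps]
        std = np.std(belt)
        if std > 0:
            belt = belt * (params.continuous_rms / std)
        return np.gradient(belt) * rate
    t = np.arange(n_steps) / rate
    onset = (spec.onset_stride + spec.onset_phase) * params.stride_time
    sign = 1.0 if spec.direction == "forward" else -1.0
    if params.protocol == "pelvis_push":
        amp = spec.magnitude / params.subject.mass  # push force -> acceleration
        return _pulse(t, onset, spec.duration, sign * amp, spec.shape)
    if params.protocol == "belt_discrete":
        # belt speed change dv over a ramp; doublet = speed up then back down
        amp = spec.magnitude / spec.duration
        shape = "rect" if spec.shape == "rcos" else spec.shape
        return _pulse(t, onset, spec.duration, sign * amp, shape)
    raise ValueError(f"unknown walking protocol {params.protocol!r}")


def simulate_walking(params: SimParams):
    """Simulate perturbed walking; returns (Dataset, GroundTruth).

    Nominal periodic templates plus deviation dynamics with phase-dependent
    gains; perturbations are pelvis-push pulses, discrete belt-speed steps,
    or continuous low-pass-filtered random belt drive. Gait events come
    exactly from the template.
    """
    if params.protocol not in ("pelvis_push", "belt_discrete", "belt_continuous"):
        raise ValueError("simulate_walking requires a walking protocol")
    sub = params.subject
    g, l, m = sub.gravity, sub.com_height, sub.mass
    rate, fs = params.sim_rate, params.fs
    step = round(rate / fs)
    n_samples = int(round(params.n_strides * params.stride_time * fs)) + 1
    n_steps = (n_samples - 1) * step + 1

    t_hi = np.arange(n_steps) / rate
    s_hi = np.mod(t_hi / params.stride_time, 1.0)
    kp_a, kv_a, kp_tot, kv_tot = _walking_gain_arrays(params, s_hi)

    t100 = np.arange(n_samples) / fs
    s100 = np.mod(t100 / params.stride_time, 1.0)
    nom = _nominal_templates(params, s100)
    events = _walking_events(params)
    emg_shape = params.gains._shape(np.where(nom["in_stance"],
                                             np.nan_to_num(nom["u"]), 2.0))

    if params.protocol == "belt_continuous":
        specs = [("continuous", i) for i in range(params.n_continuous_trials)]
    else:
        specs = list(params.schedule)
    specs += [None] * params.n_unperturbed

    emg_norm = {mu: float(np.max(arr) + params.emg_baseline)
                for mu, arr in nom["emg"].items()}

    trials = []
    truths = []
    for idx, spec in enumerate(specs):
        streams = _trial_streams(params.seed, idx)
        if spec is None:
            a_ext = np.zeros(n_steps)
        elif isinstance(spec, tuple):  # continuous
            a_ext = _walking_drive(params, None, n_steps, streams)
        else:
            a_ext = _walking_drive(params, spec, n_steps, streams)
        x, v, T_dev = _integrate(params, a_ext, kp_tot, kv_tot, kp_a, kv_a)
        n = len(x)
        nz_q, nz_qd = _smooth_noise(streams["ankle_angle"],
                                    params.ankle_angle_noise, n, fs)
        emg_dev, emg_clean = _emg_envelopes(params, x, v, emg_shape, streams)
        # _emg_envelopes already includes the baseline
        emg = {mu: nom["emg"][mu] + emg_dev[mu] for mu in emg_dev}
        fy = nom["grf_vertical"] + _noise(streams, "grf",
                                          params.noise.get("grf", 0.0), n)
        cop_shift = np.where(nom["in_stance"],
                             T_dev / (m * g), 0.0)
        perturbation = None
        if spec is not None and not isinstance(spec, tuple):
            onset = (spec.onset_stride + spec.onset_phase) * params.stride_time
            perturbation = Perturbation(onset=onset, direction=spec.direction,
                                        magnitude=spec.magnitude)
        trial = Trial(
            subject=sub,
            condition="unperturbed" if spec is None else "perturbed",
            protocol=params.protocol,
            walking_speed=params.walking_speed,
            fs=fs,
            time=t100,
            com_pos=nom["com_pos"] + x + _noise(streams, "com_pos",
                                                params.noise.get("com_pos", 0.0), n),
            com_vel=nom["com_vel"] + v + _noise(streams, "com_vel",
                                                params.noise.get("com_vel", 0.0), n),
            ankle_angle=nom["ankle_angle"] + x / l + nz_q,
            ankle_vel=nom["ankle_vel"] + v / l + nz_qd,
            ankle_moment=nom["ankle_moment"] + T_dev + _noise(
                streams, "ankle_moment", params.noise.get("ankle_moment", 0.0), n),
            grf_vertical=fy,
            cop_ap=nom["cop_ap"] + cop_shift + _noise(
                streams, "cop", params.noise.get("cop", 0.0), n),
            emg=emg,
            emg_norm=emg_norm,
            perturbation=perturbation,
            gait_events=events,
            analyzed_leg="left",
            foot_heel_ap=np.full(n, -0.05),
            foot_toe_ap=np.full(n, 0.20),
        ).validate()
        trials.append(trial)
        truths.append({"d_com_pos": x, "d_com_vel": v, "d_ankle_moment": T_dev,
                       "d_emg": {mu: arr - params.emg_baseline
                                 for mu, arr in emg_clean.items()}})

    grid = np.arange(200) / 200.0
    sf = params.stance_fraction
    u_grid = np.clip(grid / sf, 0.0, 1.0 - 1e-12)
    kp_grid = np.where(grid < sf, params.gains.kp_at(u_grid), 0.0)
    kv_grid = np.where(grid < sf, params.gains.kv_at(u_grid), 0.0)
    dataset = Dataset(trials, provenance="synthetic").validate()
    truth = GroundTruth(params=params, deviations=truths, phase_grid=grid,
                        kp_grid=kp_grid, kv_grid=kv_grid)
    return dataset, truth


def simulate(params: SimParams):
    """Dispatch on protocol."""
    if params.protocol == "standing_translation":
        return simulate_standing(params)
    return simulate_walking(params)


# ---------------------------------------------------------------------------
# fixture suite
# ---------------------------------------------------------------------------


def make_fixture_suite(seed: int, out_dir) -> dict:
    """Write one small deterministic dataset per protocol; returns paths."""
    out_dir = Path(out_dir)
    configs = {
        "standing": SimParams(
            protocol="standing_translation", seed=seed,
            noise={"com_pos": 1e-4, "com_vel": 1e-3, "ankle_moment": 0.05,
                   "emg": 0.005},
            ankle_angle_noise=0.01,
        ),
        "pelvis_push": SimParams(
            protocol="pelvis_push", seed=seed,
            gains=GainSchedule(kp=2.5, kv=0.8, kind="raised_cosine"),
            noise={"com_pos": 1e-4, "com_vel": 1e-3, "ankle_moment": 0.05,
                   "emg": 0.005},
            ankle_angle_noise=0.01, n_strides=6,
        ),
        "belt_discrete": SimParams(
            protocol="belt_discrete", seed=seed,
            gains=GainSchedule(kp=2.5, kv=0.8, kind="raised_cosine"),
            schedule=default_walking_schedule(magnitudes=(0.10, 0.16, 0.22)),
            noise={"com_pos": 1e-4, "com_vel": 1e-3, "ankle_moment": 0.05},
            ankle_angle_noise=0.01, n_strides=6,
        ),
        "belt_continuous": SimParams(
            protocol="belt_continuous", seed=seed,
            gains=GainSchedule(kp=2.5, kv=0.8, kind="raised_cosine"),
            noise={"com_pos": 1e-4, "com_vel": 1e-3, "ankle_moment": 0.05},
            ankle_angle_noise=0.01, n_strides=40, n_continuous_trials=1,
            n_unperturbed=1,
        ),
    }
    paths = {}
    for name, params in configs.items():
        dataset, truth = simulate(params)
        d = out_dir / name
        write_dataset(dataset, d)
        truth.sidecar_csv(d / "ground_truth.csv")
        paths[name] = d
    return paths
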