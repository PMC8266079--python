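"""Turn trials into regression inputs/outputs.

Stages: gait-event detection from vertical force, stride-phase
normalization, reference trajectories from unperturbed data, deviations of
perturbed data from the reference, non-dimensionalization, and delayed
signals. Invalid samples (pre-delay support, incomplete strides) are marked
NaN and excluded from regressions, never imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .dataset import Dataset, GaitEvents, SubjectConstants, Trial
from .errors import (
    DelayError,
    EventDetectionError,
    EventOrderError,
    NormalizationError,
    PhaseDomainError,
    ReferenceBuildError,
)

log = logging.getLogger(__name__)

#: number of phase samples per stride on the reference grid
PHASE_GRID_POINTS = 200

#: signals that get a reference / deviation (besides per-muscle EMG)
SIGNALS = (
    "com_pos",
    "com_vel",
    "ankle_angle",
    "ankle_vel",
    "ankle_moment",
    "grf_vertical",
    "cop_ap",
)

_DEBOUNCE_S = 0.100  # minimum inter-event gap for force-threshold events

_EDGE_EPS = 1e-9  # snap tolerance for phase values landing on a bin edge


def phase_bin_index(u, n_bins: int) -> np.ndarray:
    """Bin index for phase fractions in [0, 1).

    Values within 1e-9 x bin of an edge are snapped onto it (and belong to
    the upper bin), so that generator and identifier agree on samples whose
    phase lands exactly on a boundary up to floating rounding.
    """
    v = np.asarray(u, dtype=float) * n_bins
    r = np.round(v)
    v = np.where(np.abs(v - r) < _EDGE_EPS, r, v)
    with np.errstate(invalid="ignore"):
        return np.clip(np.floor(v), 0, n_bins - 1).astype(int)


@dataclass(frozen=True)
class DelayConfig:
    """Neural delays of one feedback model.

    ``tau_m`` applies to muscle activity, ``tau_T`` to joint moments
    (electromechanical delay included). Defaults: COM model 60/100 ms,
    joint model 40/80 ms.
    """

    tau_m: float
    tau_T: float
    model: str  # com | joint

    def __post_init__(self):
        if self.tau_m < 0 or self.tau_T < 0:
            raise DelayError("delays must be >= 0")

    @classmethod
    def com(cls) -> "DelayConfig":
        return cls(tau_m=0.060, tau_T=0.100, model="com")

    @classmethod
    def joint(cls) -> "DelayConfig":
        return cls(tau_m=0.040, tau_T=0.080, model="joint")

    @classmethod
    def for_model(cls, model: str) -> "DelayConfig":
        if model == "com":
            return cls.com()
        if model == "joint":
            return cls.joint()
        raise ValueError(f"unknown model {model!r}")


@dataclass
class GaitPhase:
    """Per-sample stride phase of one leg.

    ``s`` is the fraction of the stride (heel strike to heel strike) in
    [0, 1); ``u`` the fraction of the stance sub-phase (NaN in swing);
    ``in_stance`` flags foot-on-ground samples. Samples outside any complete
    stride are NaN.
    """

    leg: str
    s: np.ndarray
    u: np.ndarray
    in_stance: np.ndarray
    stride_starts: np.ndarray  # heel-strike times bounding complete strides
    stance_fractions: np.ndarray  # per complete stride; NaN if no toe-off found

    @property
    def n_strides(self) -> int:
        return len(self.stride_starts) - 1

    def mean_stance_fraction(self) -> float:
        vals = self.stance_fractions[np.isfinite(self.stance_fractions)]
        if len(vals) == 0:
            raise EventOrderError(f"no toe-off events found for leg {self.leg!r}")
        return float(np.mean(vals))

    def phase_at(self, t: float) -> float:
        """Stride phase at an arbitrary time (linear between heel strikes)."""
        hs = self.stride_starts
        if t < hs[0] or t > hs[-1]:
            raise PhaseDomainError(f"time {t} s outside strides [{hs[0]}, {hs[-1]}] s")
        i = int(np.searchsorted(hs, t, side="right")) - 1
        i = min(i, len(hs) - 2)
        return float((t - hs[i]) / (hs[i + 1] - hs[i]))


@dataclass
class ReferenceTrajectory:
    """Per-signal unperturbed mean: phase-indexed (walking) or scalar (standing)."""

    mode: str  # standing | walking
    signals: dict  # name -> float (standing) or (n_grid,) array (walking)
    grid: np.ndarray | None = None  # phase grid, walking only
    n_strides_used: int = 0

    def evaluate(self, name: str, s=None):
        if name not in self.signals:
            raise PhaseDomainError(f"reference has no signal {name!r}")
        if self.mode == "standing":
            return self.signals[name]
        if s is None:
            raise PhaseDomainError("walking reference needs a phase to evaluate at")
        s = np.asarray(s, dtype=float)
        out = np.full(s.shape, np.nan)
        ok = np.isfinite(s)
        out[ok] = np.interp(np.mod(s[ok], 1.0), self.grid, self.signals[name],
                            period=1.0)
        return out


@dataclass
class DeviationSeries:
    """Deviations of one trial from the unperturbed reference.

    Raw SI units until :func:`nondimensionalize_deviations` is applied
    (``nondim`` flag). Invalid samples are NaN.
    """

    time: np.ndarray
    fs: float
    subject: SubjectConstants
    d_com_pos: np.ndarray
    d_com_vel: np.ndarray
    d_ankle_angle: np.ndarray
    d_ankle_vel: np.ndarray
    d_ankle_moment: np.ndarray
    d_emg: dict = field(default_factory=dict)
    phase: GaitPhase | None = None
    nondim: bool = False


# ---------------------------------------------------------------------------
# gait events & phase
# ---------------------------------------------------------------------------


def detect_gait_events(trial: Trial, threshold_fraction: float = 0.05) -> GaitEvents:
    """Detect heel strikes / toe-offs of the analyzed leg from vertical force.

    Heel strike = upward crossing of ``threshold_fraction`` x body weight,
    toe-off = downward crossing; events closer than 100 ms to the previous
    accepted event of the same leg are debounced.
    """
    fy = np.asarray(trial.grf_vertical, dtype=float)
    t = np.asarray(trial.time, dtype=float)
    threshold = threshold_fraction * trial.subject.mass * trial.subject.gravity
    above = fy > threshold
    if above.all() or (~above).all():
        raise EventDetectionError(
            f"vertical force never crosses threshold {threshold:.1f} N"
        )
    hs, to = [], []
    last = -math.inf
    for i in range(1, len(fy)):
        if above[i] == above[i - 1]:
            continue
        # linear interpolation of the crossing instant
        f0, f1 = fy[i - 1], fy[i]
        tc = t[i - 1] + (threshold - f0) / (f1 - f0) * (t[i] - t[i - 1])
        if tc - last < _DEBOUNCE_S:
            continue
        last = tc
        (hs if above[i] else to).append(tc)
    if not hs and not to:
        raise EventDetectionError("no gait events after debouncing")
    leg = trial.analyzed_leg
    if leg == "left":
        return GaitEvents(left_hs=tuple(hs), left_to=tuple(to))
    return GaitEvents(right_hs=tuple(hs), right_to=tuple(to))


def phase_normalize(trial: Trial, events: GaitEvents | None = None,
                    leg: str | None = None) -> GaitPhase:
    """Per-sample stride phase by linear interpolation between heel strikes."""
    leg = leg or trial.analyzed_leg
    events = events or trial.gait_events
    hs, to = events.for_leg(leg)
    if len(hs) < 2:
        raise EventOrderError(
            f"need >= 2 heel strikes for leg {leg!r}, got {len(hs)}"
        )
    if list(hs) != sorted(hs) or list(to) != sorted(to):
        raise EventOrderError(f"gait events for leg {leg!r} are out of order")

    hs = np.asarray(hs, dtype=float)
    to = np.asarray(to, dtype=float)
    t = np.asarray(trial.time, dtype=float)
    n = len(t)
    s = np.full(n, np.nan)
    u = np.full(n, np.nan)
    in_stance = np.zeros(n, dtype=bool)
    stance_fractions = np.full(len(hs) - 1, np.nan)

    for i in range(len(hs) - 1):
        t0, t1 = hs[i], hs[i + 1]
        stride = t1 - t0
        inside = (t >= t0) & (t < t1)
        s[inside] = (t[inside] - t0) / stride
        to_in = to[(to > t0) & (to < t1)]
        if len(to_in) == 1:
            sf = (to_in[0] - t0) / stride
            stance_fractions[i] = sf
            # edge-tolerant: a sample exactly at toe-off belongs to swing
            stance = inside & (s < sf - _EDGE_EPS)
            in_stance |= stance
            u[stance] = s[stance] / sf
        elif len(to_in) > 1:
            raise EventOrderError(
                f"multiple toe-offs inside stride [{t0:.3f}, {t1:.3f}] s for leg {leg!r}"
            )
    return GaitPhase(leg=leg, s=s, u=u, in_stance=in_stance,
                     stride_starts=hs, stance_fractions=stance_fractions)


# ---------------------------------------------------------------------------
# references & deviations
# ---------------------------------------------------------------------------


def _trial_signal(trial: Trial, name: str) -> np.ndarray:
    if name.startswith("emg_"):
        return np.asarray(trial.emg[name[4:]], dtype=float)
    return np.asarray(getattr(trial, name), dtype=float)


def _reference_signal_names(trial: Trial) -> list:
    return list(SIGNALS) + [f"emg_{m}" for m in sorted(trial.emg)]


def compute_reference(dataset: Dataset, mode: str,
                      n_grid: int = PHASE_GRID_POINTS,
                      pre_onset_window: float = 0.5) -> ReferenceTrajectory:
    """Mean unperturbed trajectory: scalar (standing) or phase-indexed (walking).

    Standing: the mean over the 0.5 s pre-onset window of each perturbed
    trial (plus the full span of unperturbed trials), averaged over trials.
    Walking: the per-phase mean of every complete unperturbed stride on a
    fixed 200-point stride-phase grid.
    """
    if mode == "standing":
        sums: dict = {}
        counts: dict = {}
        for trial in dataset:
            t = np.asarray(trial.time, dtype=float)
            if trial.perturbation is not None:
                onset = trial.perturbation.onset
                window = (t >= onset - pre_onset_window) & (t < onset)
            else:
                window = np.ones(len(t), dtype=bool)
            if not window.any():
                continue
            for name in _reference_signal_names(trial):
                sums[name] = sums.get(name, 0.0) + float(
                    np.mean(_trial_signal(trial, name)[window])
                )
                counts[name] = counts.get(name, 0) + 1
        if not sums:
            raise ReferenceBuildError("no usable pre-onset or unperturbed data")
        signals = {name: sums[name] / counts[name] for name in sums}
        return ReferenceTrajectory(mode="standing", signals=signals,
                                   n_strides_used=0)

    if mode != "walking":
        raise ValueError(f"mode must be standing/walking, got {mode!r}")

    grid = np.arange(n_grid) / n_grid
    stacks: dict = {}
    n_strides = 0
    trials = list(dataset.unperturbed())
    if not trials:
        raise ReferenceBuildError("no unperturbed trials to build walking reference")
    for trial in trials:
        phase = phase_normalize(trial)
        t = np.asarray(trial.time, dtype=float)
        hs = phase.stride_starts
        for i in range(len(hs) - 1):
            # include the closing heel-strike sample (phase 1) so the
            # interpolation covers the full [0, 1] phase domain
            inside = (t >= hs[i]) & (t <= hs[i + 1])
            if inside.sum() < 2:
                continue
            s_local = (t[inside] - hs[i]) / (hs[i + 1] - hs[i])
            n_strides += 1
            for name in _reference_signal_names(trial):
                vals = np.interp(grid, s_local, _trial_signal(trial, name)[inside])
                stacks.setdefault(name, []).append(vals)
    if n_strides == 0:
        raise ReferenceBuildError("no complete unperturbed strides found")
    if n_strides < 5:
        log.warning("walking reference built from only %d strides (< 5)", n_strides)
    signals = {name: np.mean(np.stack(v), axis=0) for name, v in stacks.items()}
    return ReferenceTrajectory(mode="walking", signals=signals, grid=grid,
                               n_strides_used=n_strides)


def compute_deviations(trial: Trial, ref: ReferenceTrajectory,
                       phase: GaitPhase | None = None) -> DeviationSeries:
    """Measured minus reference, phase-locked for walking, scalar for standing."""
    if ref.mode == "walking" and phase is None:
        phase = phase_normalize(trial)

    def dev(name):
        sig = _trial_signal(trial, name)
        if ref.mode == "standing":
            return sig - ref.evaluate(name)
        return sig - ref.evaluate(name, phase.s)

    d_emg = {}
    for muscle in sorted(trial.emg):
        name = f"emg_{muscle}"
        if name in ref.signals:
            d_emg[muscle] = dev(name)
    return DeviationSeries(
        time=np.asarray(trial.time, dtype=float),
        fs=trial.fs,
        subject=trial.subject,
        d_com_pos=dev("com_pos"),
        d_com_vel=dev("com_vel"),
        d_ankle_angle=dev("ankle_angle"),
        d_ankle_vel=dev("ankle_vel"),
        d_ankle_moment=dev("ankle_moment"),
        d_emg=d_emg,
        phase=phase,
        nondim=False,
    )


# ---------------------------------------------------------------------------
# non-dimensionalization
# ---------------------------------------------------------------------------


def nondimensionalize(x, kind: str, const: SubjectConstants, emg_ref: float | None = None):
    """Scale a quantity to non-dimensional units.

    position / l_max, velocity / sqrt(g l_max), torque / (m g l_max),
    emg / reference (MVC or unperturbed-walking peak).
    """
    x = np.asarray(x, dtype=float) if np.ndim(x) else float(x)
    g, l, m = const.gravity, const.com_height, const.mass
    if kind == "position":
        return x / l
    if kind == "velocity":
        return x / math.sqrt(g * l)
    if kind == "torque":
        return x / (m * g * l)
    if kind == "emg":
        if emg_ref is None or emg_ref <= 0:
            raise NormalizationError("EMG normalization requires a positive MVC/peak reference")
        return x / emg_ref
    raise ValueError(f"unknown kind {kind!r}")


def nondimensionalize_deviations(dev: DeviationSeries,
                                 emg_norm: Mapping[str, float] | None = None) -> DeviationSeries:
    """Non-dimensional copy of a DeviationSeries (angles stay in rad).

    EMG channels without a normalization constant are dropped (use
    :func:`nondimensionalize` directly to get the hard error).
    """
    const = dev.subject
    d_emg = {}
    for muscle, arr in dev.d_emg.items():
        ref = None if emg_norm is None else emg_norm.get(muscle)
        if ref is None:
            continue
        d_emg[muscle] = nondimensionalize(arr, "emg", const, emg_ref=ref)
    return DeviationSeries(
        time=dev.time,
        fs=dev.fs,
        subject=const,
        d_com_pos=nondimensionalize(dev.d_com_pos, "position", const),
        d_com_vel=nondimensionalize(dev.d_com_vel, "velocity", const),
        d_ankle_angle=np.asarray(dev.d_ankle_angle, dtype=float),
        d_ankle_vel=np.asarray(dev.d_ankle_vel, dtype=float),
        d_ankle_moment=nondimensionalize(dev.d_ankle_moment, "torque", const),
        d_emg=d_emg,
        phase=dev.phase,
        nondim=True,
    )


def emg_peak_reference(dataset: Dataset) -> dict:
    """Peak of the gait-cycle-average EMG during unperturbed walking, per muscle."""
    ref = compute_reference(dataset, mode="walking")
    peaks = {}
    for name, vals in ref.signals.items():
        if name.startswith("emg_"):
            peaks[name[4:]] = float(np.max(vals))
    if not peaks:
        raise NormalizationError("no EMG signals in unperturbed walking data")
    return peaks


# ---------------------------------------------------------------------------
# delays
# ---------------------------------------------------------------------------


def apply_delay(x, tau: float, fs: float) -> np.ndarray:
    """Return y(t) = x(t - tau); the leading ``tau`` seconds become NaN.

    Integer-sample delays are exact shifts; fractional delays use linear
    interpolation on the sample grid.
    """
    x = np.asarray(x, dtype=float)
    if tau < 0:
        raise DelayError(f"delay must be >= 0, got {tau}")
    n = len(x)
    if n == 0 or tau > (n - 1) / fs:
        raise DelayError(f"delay {tau} s >= signal duration {(max(n - 1, 0)) / fs} s")
    if tau == 0:
        return x.copy()
    shift = tau * fs
    k = round(shift)
    y = np.full(n, np.nan)
    if abs(shift - k) < 1e-9:
        y[k:] = x[: n - k]
        return y
    t = np.arange(n) / fs
    tq = t - tau
    ok = tq >= 0
    y[ok] = np.interp(tq[ok], t, x)
    return y
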