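"""Delayed feedback-gain identification.

Estimates the linear mapping from delayed deviations of COM kinematics (or
ankle-joint kinematics) to reactive ankle moment / muscle activity by
ordinary least squares with exactly two parameters and no intercept, at
discrete perturbation onsets or per phase bin, pooled over subjects or per
subject, with the uncentered coefficient of determination and RMSE as fit
statistics. Model variants: phase-binned gains, constant gains, and constant
gains multiplied by a delayed modulator (vertical ground reaction force or
fore-aft COP-to-foot-bound distance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataset import Dataset, Trial
from .errors import (
    ConditioningError,
    DegenerateModulatorError,
    InsufficientDataError,
    NormalizationError,
    PhaseDomainError,
    UndefinedR2Error,
    ValidationError,
)
from .preprocessing import (
    DelayConfig,
    DeviationSeries,
    apply_delay,
    compute_deviations,
    compute_reference,
    emg_peak_reference,
    nondimensionalize_deviations,
    phase_bin_index,
    phase_normalize,
)

#: condition-number threshold for rejecting (near-)collinear regressors
COND_LIMIT = 1e8

#: input sampling instant after perturbation onset [s]
T_INPUT = 0.150

MODELS = ("com", "joint")
MODEL_TAGS = ("com", "joint", "constant", "fy_modulated", "cop_modulated")


# ---------------------------------------------------------------------------
# result types
# ---------------------------------------------------------------------------


@dataclass
class GainProfile:
    """Estimated position/velocity gains.

    ``kp``/``kv`` are scalars (discrete or constant fits), per-bin arrays
    (phase-binned fits) or ``{direction: (kp, kv)}`` dicts (direction-split
    EMG fits).
    """

    kp: object
    kv: object
    delays: DelayConfig
    output: str = "moment"
    bin_edges: np.ndarray | None = None
    direction_split: bool = False


@dataclass
class FitResult:
    """One fitted feedback model with uncentered R^2 and RMSE."""

    gains: GainProfile
    r2: float
    rmse: float
    n_rows: int
    scope: str  # pooled | subject:<id>
    model: str  # com | joint | constant | fy_modulated | cop_modulated
    r2_by_bin: np.ndarray | None = None
    rmse_by_bin: np.ndarray | None = None
    n_by_bin: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    @property
    def stance_average_r2(self) -> float:
        if self.r2_by_bin is None:
            return self.r2
        return float(np.nanmean(self.r2_by_bin))

    @property
    def stance_average_rmse(self) -> float:
        if self.rmse_by_bin is None:
            return self.rmse
        return float(np.nanmean(self.rmse_by_bin))


@dataclass
class DelaySweep:
    """R^2 of the discrete-onset fit over a grid of moment delays."""

    taus: np.ndarray
    r2: np.ndarray

    @property
    def tau_best(self) -> float:
        return float(self.taus[int(np.argmax(self.r2))])


# ---------------------------------------------------------------------------
# core regression
# ---------------------------------------------------------------------------


def uncentered_r2(y_meas, y_mod) -> float:
    """1 - sum((y - yhat)^2) / sum(y^2), without mean-centering (may be < 0)."""
    y = np.asarray(y_meas, dtype=float)
    yhat = np.asarray(y_mod, dtype=float)
    if y.shape != yhat.shape or y.size < 1:
        raise ValueError("y_meas and y_mod must be equal-length, non-empty")
    denom = float(np.sum(y * y))
    if denom <= 0.0:
        raise UndefinedR2Error("uncentered R^2 undefined: sum(y_meas^2) == 0")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / denom


def fit_gains(X, y, delays: DelayConfig | None = None, output: str = "moment",
              scope: str = "pooled", model: str = "com") -> FitResult:
    """Two-parameter, no-intercept OLS of responses on [position, velocity] rows."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2 or len(X) != len(y):
        raise ValueError("X must be (n, 2) with matching y")
    if len(y) < 4:
        raise InsufficientDataError(f"need >= 4 rows, got {len(y)}")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("rows contain non-finite values; mask them before fitting")
    cond = float(np.linalg.cond(X))
    if cond > COND_LIMIT:
        raise ConditioningError(
            f"regressors are collinear (condition number {cond:.3g})", cond
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    yhat = X @ beta
    r2 = uncentered_r2(y, yhat)
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    gains = GainProfile(kp=float(beta[0]), kv=float(beta[1]),
                        delays=delays or DelayConfig.for_model("com"),
                        output=output)
    return FitResult(gains=gains, r2=r2, rmse=rmse, n_rows=len(y),
                     scope=scope, model=model)


# ---------------------------------------------------------------------------
# row assembly
# ---------------------------------------------------------------------------


def _sample_at(time: np.ndarray, series: np.ndarray, t: float) -> float:
    """Linear interpolation at one instant; NaN if outside or masked."""
    if t < time[0] or t > time[-1]:
        return math.nan
    i = int(np.searchsorted(time, t))
    if i == 0 or math.isclose(time[i - 1], t, abs_tol=1e-12):
        return float(series[max(i - 1, 0)]) if math.isclose(
            time[max(i - 1, 0)], t, abs_tol=1e-9) else _interp(time, series, t, i)
    return _interp(time, series, t, i)


def _interp(time, series, t, i):
    if i == 0:
        return float(series[0])
    if i >= len(time):
        return float(series[-1])
    t0, t1 = time[i - 1], time[i]
    w = (t - t0) / (t1 - t0)
    return float((1 - w) * series[i - 1] + w * series[i])


def _regressor_arrays(dev: DeviationSeries, model: str):
    if model == "com":
        return dev.d_com_pos, dev.d_com_vel
    if model == "joint":
        return dev.d_ankle_angle, dev.d_ankle_vel
    raise ValueError(f"model must be com/joint, got {model!r}")


def _output_array(dev: DeviationSeries, output: str):
    if output == "moment":
        return dev.d_ankle_moment
    if output.startswith("emg:"):
        muscle = output[4:]
        if muscle not in dev.d_emg:
            raise ValidationError(f"trial lacks EMG for muscle {muscle!r}")
        return dev.d_emg[muscle]
    raise ValueError(f"output must be 'moment' or 'emg:<muscle>', got {output!r}")


def _group_key(trial: Trial):
    return (trial.subject.subject_id, round(trial.walking_speed, 6))


def _mode_of(dataset: Dataset) -> str:
    protocols = {tr.protocol for tr in dataset}
    return "standing" if protocols <= {"standing_translation"} else "walking"


def _group_references(dataset: Dataset, mode: str):
    """Per (subject, speed) reference + EMG normalization constants."""
    groups: dict = {}
    for trial in dataset:
        groups.setdefault(_group_key(trial), []).append(trial)
    refs = {}
    for key, trials in groups.items():
        sub = Dataset(trials, dataset.provenance)
        ref = compute_reference(sub, mode=mode)
        emg_norm = {}
        for trial in trials:
            emg_norm.update(trial.emg_norm)
        if not emg_norm and mode == "walking":
            try:
                emg_norm = emg_peak_reference(sub)
            except Exception:
                emg_norm = {}
        refs[key] = (ref, emg_norm, trials)
    return refs


def onset_phase(trial: Trial) -> float:
    """Stride phase (analyzed leg) at the perturbation onset."""
    if trial.perturbation is None:
        raise ValidationError("trial has no discrete perturbation onset")
    return phase_normalize(trial).phase_at(trial.perturbation.onset)


def contralateral_toeoff_phase(trial: Trial) -> float:
    """Phase of the contralateral toe-off within the analyzed leg's stride."""
    phase = phase_normalize(trial)
    other = "right" if trial.analyzed_leg == "left" else "left"
    _, to = trial.gait_events.for_leg(other)
    hs = phase.stride_starts
    for t0, t1 in zip(hs, hs[1:]):
        for t in to:
            if t0 < t < t1:
                return float((t - t0) / (t1 - t0))
    raise PhaseDomainError("no contralateral toe-off inside any analyzed stride")


def select_by_onset_phase(dataset: Dataset, target="contralateral_toe_off",
                          tol: float = 0.05) -> Dataset:
    """Keep perturbed trials whose onset phase is within ``tol`` of target."""
    kept = list(dataset.unperturbed())
    for trial in dataset.perturbed():
        tgt = (contralateral_toeoff_phase(trial) if target == "contralateral_toe_off"
               else float(target))
        if abs(onset_phase(trial) - tgt) <= tol:
            kept.append(trial)
    return Dataset(kept, dataset.provenance)


def _discrete_rows(dataset: Dataset, model: str, output: str,
                   delays: DelayConfig, tau: float,
                   include_unperturbed: bool = True):
    """One regression row per perturbed trial (+ near-zero unperturbed rows).

    Inputs are sampled at onset + 150 ms, outputs at onset + 150 ms + delay.
    Returns (X, y, subject_ids, directions).
    """
    mode = _mode_of(dataset)
    refs = _group_references(dataset, mode)
    rows_X, rows_y, subjects, directions = [], [], [], []

    onset_phases = []
    if mode == "walking":
        for trial in dataset.perturbed():
            if trial.perturbation is not None:
                try:
                    onset_phases.append(onset_phase(trial))
                except PhaseDomainError:
                    pass
    s_star = float(np.mean(onset_phases)) if onset_phases else 0.5

    for (ref, emg_norm, trials) in refs.values():
        for trial in trials:
            dev = compute_deviations(trial, ref)
            norms = dict(trial.emg_norm)
            norms.update(emg_norm or {})
            if output.startswith("emg:") and output[4:] not in norms:
                raise NormalizationError(
                    f"no EMG normalization constant for muscle {output[4:]!r}"
                )
            dev = nondimensionalize_deviations(dev, norms)
            xp, xv = _regressor_arrays(dev, model)
            yarr = _output_array(dev, output)
            t = dev.time

            if trial.condition == "perturbed" and trial.perturbation is not None:
                t_ins = [trial.perturbation.onset + T_INPUT]
                dirs = [trial.perturbation.direction]
            elif include_unperturbed and trial.condition == "unperturbed":
                if mode == "standing":
                    t_ins = [float(t[0] + (t[-1] - t[0]) / 2)]
                else:
                    phase = dev.phase
                    hs = phase.stride_starts
                    t_ins = [float(t0 + s_star * (t1 - t0))
                             for t0, t1 in zip(hs, hs[1:])]
                dirs = ["none"] * len(t_ins)
            else:
                continue

            for t_in, direction in zip(t_ins, dirs):
                t_out = t_in + tau
                row = (
                    _sample_at(t, xp, t_in),
                    _sample_at(t, xv, t_in),
                    _sample_at(t, yarr, t_out),
                )
                if all(np.isfinite(row)):
                    rows_X.append(row[:2])
                    rows_y.append(row[2])
                    subjects.append(trial.subject.subject_id)
                    directions.append(direction)
    return (np.asarray(rows_X, dtype=float), np.asarray(rows_y, dtype=float),
            np.asarray(subjects), np.asarray(directions))


# ---------------------------------------------------------------------------
# model fits
# ---------------------------------------------------------------------------


def _emg_delay(output: str, delays: DelayConfig) -> float:
    return delays.tau_m if output.startswith("emg:") else delays.tau_T


def fit_discrete_onset(dataset: Dataset, model: str = "com",
                       output: str = "moment", scope: str = "pooled",
                       delays: DelayConfig | None = None,
                       tau_T_override: float | None = None,
                       include_unperturbed: bool = True) -> FitResult:
    """Feedback-gain fit at discrete perturbation onsets.

    Moment fits pool both perturbation directions into one regression; EMG
    fits are per-subject only and direction-split (separate (Kp, Kv) per
    direction, with the combined uncentered R^2 reported).
    """
    delays = delays or DelayConfig.for_model(model)
    tau = tau_T_override if tau_T_override is not None else _emg_delay(output, delays)
    is_emg = output.startswith("emg:")
    if is_emg and scope == "pooled":
        raise ValidationError(
            "EMG fits are per-subject only (scope='subject:<id>'); "
            "pooling EMG across subjects is not supported"
        )
    X, y, subjects, directions = _discrete_rows(
        dataset, model, output, delays, tau,
        include_unperturbed=include_unperturbed and not is_emg,
    )
    if scope.startswith("subject:"):
        sid = scope[len("subject:"):]
        keep = subjects == sid
        X, y, directions = X[keep], y[keep], directions[keep]
    elif scope != "pooled":
        raise ValueError(f"scope must be 'pooled' or 'subject:<id>', got {scope!r}")
    if len(y) < 4:
        raise InsufficientDataError(f"only {len(y)} usable trials (need >= 4)")

    if not is_emg:
        res = fit_gains(X, y, delays=delays, output=output, scope=scope, model=model)
        res.gains.bin_edges = None
        return res

    # direction-split EMG fit
    gains = {}
    yhat = np.full(len(y), np.nan)
    n_used = 0
    for direction in ("forward", "backward"):
        sel = directions == direction
        if sel.sum() < 4:
            continue
        try:
            sub = fit_gains(X[sel], y[sel], delays=delays, output=output,
                            scope=scope, model=model)
        except UndefinedR2Error:
            continue  # muscle fully gated off in this direction
        gains[direction] = (sub.gains.kp, sub.gains.kv)
        yhat[sel] = X[sel] @ np.array([sub.gains.kp, sub.gains.kv])
        n_used += int(sel.sum())
    if not gains:
        raise InsufficientDataError("no direction with >= 4 EMG rows")
    ok = np.isfinite(yhat)
    r2 = uncentered_r2(y[ok], yhat[ok])
    rmse = float(np.sqrt(np.mean((y[ok] - yhat[ok]) ** 2)))
    profile = GainProfile(kp={d: g[0] for d, g in gains.items()},
                          kv={d: g[1] for d, g in gains.items()},
                          delays=delays, output=output, direction_split=True)
    return FitResult(gains=profile, r2=r2, rmse=rmse, n_rows=n_used,
                     scope=scope, model=model)


def fit_per_subject(dataset: Dataset, **kwargs) -> dict:
    """fit_discrete_onset per subject; returns {subject_id: FitResult}."""
    out = {}
    for sid in dataset.subject_ids():
        out[sid] = fit_discrete_onset(dataset, scope=f"subject:{sid}", **kwargs)
    return out


def _binned_rows(dataset: Dataset, model: str, output: str,
                 delays: DelayConfig, domain: str = "stance"):
    """Per-sample regression rows over whole perturbed walking series.

    Regressors are delayed deviations, the response is the (undelayed)
    deviation at the same instant; the bin coordinate is the stance fraction
    (domain='stance') or the stride phase (domain='stride').
    Returns (X, y, coord, subject_ids).
    """
    if domain not in ("stance", "stride"):
        raise ValueError(f"domain must be stance/stride, got {domain!r}")
    tau = _emg_delay(output, delays)
    refs = _group_references(dataset, "walking")
    Xs, ys, coords, subjects = [], [], [], []
    for (ref, emg_norm, trials) in refs.values():
        for trial in trials:
            if trial.condition != "perturbed":
                continue
            dev = compute_deviations(trial, ref)
            dev = nondimensionalize_deviations(dev, emg_norm or None)
            xp, xv = _regressor_arrays(dev, model)
            yarr = _output_array(dev, output)
            xp_d = apply_delay(xp, tau, trial.fs)
            xv_d = apply_delay(xv, tau, trial.fs)
            phase = dev.phase
            coord = phase.u if domain == "stance" else phase.s
            ok = (np.isfinite(xp_d) & np.isfinite(xv_d) & np.isfinite(yarr)
                  & np.isfinite(coord))
            Xs.append(np.column_stack([xp_d[ok], xv_d[ok]]))
            ys.append(yarr[ok])
            coords.append(coord[ok])
            subjects.append(np.repeat(trial.subject.subject_id, int(ok.sum())))
    if not Xs:
        raise InsufficientDataError("no perturbed walking rows found")
    return (np.concatenate(Xs), np.concatenate(ys), np.concatenate(coords),
            np.concatenate(subjects))


def _restrict_scope(scope, X, y, coord, subjects, extra=None):
    if scope == "pooled":
        return (X, y, coord) + ((extra,) if extra is not None else ())
    if scope.startswith("subject:"):
        keep = subjects == scope[len("subject:"):]
        out = (X[keep], y[keep], coord[keep])
        if extra is not None:
            out += (extra[keep],)
        return out
    raise ValueError(f"scope must be 'pooled' or 'subject:<id>', got {scope!r}")


def _per_bin_stats(X, y, coord, edges, beta_by_bin):
    """Per-bin uncentered R^2 / RMSE for given per-bin coefficient vectors."""
    n_bins = len(edges) - 1
    r2 = np.full(n_bins, np.nan)
    rmse = np.full(n_bins, np.nan)
    n = np.zeros(n_bins, dtype=int)
    idx = phase_bin_index(coord, n_bins)
    for b in range(n_bins):
        sel = idx == b
        n[b] = int(sel.sum())
        beta = beta_by_bin[b]
        if n[b] == 0 or beta is None or not np.all(np.isfinite(beta)):
            continue
        yhat = X[sel] @ beta
        try:
            r2[b] = uncentered_r2(y[sel], yhat)
        except UndefinedR2Error:
            r2[b] = np.nan
        rmse[b] = float(np.sqrt(np.mean((y[sel] - yhat) ** 2)))
    return r2, rmse, n


def fit_phase_binned(dataset: Dataset, n_bins: int = 16, model: str = "com",
                     output: str = "moment", scope: str = "pooled",
                     domain: str = "stance",
                     delays: DelayConfig | None = None) -> FitResult:
    """Independent two-parameter regression per phase bin (16 over stance).

    Empty / underpopulated bins are flagged absent (NaN gains), never
    zero-filled. ``r2`` is the average of the per-bin uncentered R^2.
    """
    delays = delays or DelayConfig.for_model(model)
    X, y, coord, subjects = _binned_rows(dataset, model, output, delays, domain)
    X, y, coord = _restrict_scope(scope, X, y, coord, subjects)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = phase_bin_index(coord, n_bins)
    kp = np.full(n_bins, np.nan)
    kv = np.full(n_bins, np.nan)
    betas = [None] * n_bins
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() < 4:
            continue
        try:
            sub = fit_gains(X[sel], y[sel], delays=delays, output=output,
                            scope=scope, model=model)
        except (ConditioningError, UndefinedR2Error):
            continue
        kp[b], kv[b] = sub.gains.kp, sub.gains.kv
        betas[b] = np.array([kp[b], kv[b]])
    r2_by_bin, rmse_by_bin, n_by_bin = _per_bin_stats(X, y, coord, edges, betas)
    gains = GainProfile(kp=kp, kv=kv, delays=delays, output=output, bin_edges=edges)
    return FitResult(
        gains=gains,
        r2=float(np.nanmean(r2_by_bin)) if np.isfinite(r2_by_bin).any() else math.nan,
        rmse=float(np.nanmean(rmse_by_bin)) if np.isfinite(rmse_by_bin).any() else math.nan,
        n_rows=int(len(y)),
        scope=scope,
        model=model,
        r2_by_bin=r2_by_bin,
        rmse_by_bin=rmse_by_bin,
        n_by_bin=n_by_bin,
        extras={"domain": domain},
    )


def _modulator_series(trial: Trial, modulator: str, tau: float) -> np.ndarray:
    if modulator == "none":
        return np.ones(trial.n_samples)
    if modulator == "fy":
        m = np.asarray(trial.grf_vertical, dtype=float) / (
            trial.subject.mass * trial.subject.gravity
        )
    elif modulator == "cop_bound":
        if trial.foot_heel_ap is None or trial.foot_toe_ap is None:
            raise ValidationError(
                "cop_bound modulator requires foot_heel_ap/foot_toe_ap bounds"
            )
        cop = np.asarray(trial.cop_ap, dtype=float)
        m = np.minimum(cop - np.asarray(trial.foot_heel_ap, dtype=float),
                       np.asarray(trial.foot_toe_ap, dtype=float) - cop)
        m = m / trial.subject.com_height
    else:
        raise ValueError(f"modulator must be fy/cop_bound/none, got {modulator!r}")
    return apply_delay(m, tau, trial.fs)


def fit_modulated_gain(dataset: Dataset, modulator: str = "fy",
                       n_bins: int = 16, model: str = "com",
                       scope: str = "pooled", domain: str = "stance",
                       delays: DelayConfig | None = None) -> FitResult:
    """Constant COM gains multiplied by a delayed modulator.

    Response: reactive moment deviation = M(t - tau) * (Kp dCOM(t - tau) +
    Kv dCOMdot(t - tau)); linear in (Kp, Kv) given M, solved by least
    squares on modulator-scaled regressors. ``modulator='none'`` (M == 1) is
    the constant-gain model. Per-bin R^2/RMSE are evaluated post-hoc against
    the single fitted model for comparison with the phase-binned fit.
    """
    delays = delays or DelayConfig.for_model(model)
    tau = delays.tau_T
    refs = _group_references(dataset, "walking")
    Xs, ys, coords, subjects = [], [], [], []
    for (ref, emg_norm, trials) in refs.values():
        for trial in trials:
            if trial.condition != "perturbed":
                continue
            dev = compute_deviations(trial, ref)
            dev = nondimensionalize_deviations(dev, emg_norm or None)
            xp, xv = _regressor_arrays(dev, model)
            xp_d = apply_delay(xp, tau, trial.fs)
            xv_d = apply_delay(xv, tau, trial.fs)
            m_d = _modulator_series(trial, modulator, tau)
            yarr = dev.d_ankle_moment
            phase = dev.phase
            coord = phase.u if domain == "stance" else phase.s
            ok = (np.isfinite(xp_d) & np.isfinite(xv_d) & np.isfinite(yarr)
                  & np.isfinite(coord) & np.isfinite(m_d))
            Xs.append(np.column_stack([(m_d * xp_d)[ok], (m_d * xv_d)[ok]]))
            ys.append(yarr[ok])
            coords.append(coord[ok])
            subjects.append(np.repeat(trial.subject.subject_id, int(ok.sum())))
            if m_d[ok].size and float(np.max(np.abs(m_d[ok]))) < 1e-12:
                raise DegenerateModulatorError(
                    f"modulator {modulator!r} is identically zero over stance"
                )
    if not Xs:
        raise InsufficientDataError("no perturbed walking rows found")
    X = np.concatenate(Xs)
    y = np.concatenate(ys)
    coord = np.concatenate(coords)
    subj = np.concatenate(subjects)
    X, y, coord = _restrict_scope(scope, X, y, coord, subj)
    if X.size and float(np.max(np.abs(X))) < 1e-12:
        raise DegenerateModulatorError(
            f"modulator {modulator!r} zeroes every regression row"
        )
    res = fit_gains(X, y, delays=delays, output="moment", scope=scope)
    res.model = {"none": "constant", "fy": "fy_modulated",
                 "cop_bound": "cop_modulated"}[modulator]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    beta = np.array([res.gains.kp, res.gains.kv])
    betas = [beta] * n_bins
    res.r2_by_bin, res.rmse_by_bin, res.n_by_bin = _per_bin_stats(
        X, y, coord, edges, betas
    )
    res.gains.bin_edges = edges
    res.extras = {"domain": domain, "modulator": modulator,
                  "stance_average_r2": float(np.nanmean(res.r2_by_bin))}
    return res


def fit_constant_gain(dataset: Dataset, n_bins: int = 16, model: str = "com",
                      scope: str = "pooled", domain: str = "stance",
                      delays: DelayConfig | None = None) -> FitResult:
    """Single (Kp, Kv) over all stance rows (the M == 1 modulated model)."""
    return fit_modulated_gain(dataset, modulator="none", n_bins=n_bins,
                              model=model, scope=scope, domain=domain,
                              delays=delays)


def delay_sensitivity(dataset: Dataset, tau_grid, model: str = "com",
                      output: str = "moment", scope: str = "pooled",
                      **kwargs) -> DelaySweep:
    """Rerun the discrete-onset fit with the moment delay swept over a grid."""
    taus = np.asarray(list(tau_grid), dtype=float)
    if taus.size == 0:
        raise ValueError("tau_grid is empty")
    r2 = np.empty(len(taus))
    for i, tau in enumerate(taus):
        res = fit_discrete_onset(dataset, model=model, output=output,
                                 scope=scope, tau_T_override=float(tau), **kwargs)
        r2[i] = res.r2
    return DelaySweep(taus=taus, r2=r2)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def fit_results_to_csv(results, path) -> None:
    """Flat CSV: one row per bin x model x scope (scalar fits use bin 0-1)."""
    import pandas as pd

    records = []
    for res in results:
        g = res.gains
        if g.bin_edges is not None and isinstance(g.kp, np.ndarray):
            for b in range(len(g.bin_edges) - 1):
                records.append(dict(
                    model=res.model, output=g.output, scope=res.scope,
                    bin_lo=g.bin_edges[b], bin_hi=g.bin_edges[b + 1],
                    direction="both", Kp=g.kp[b], Kv=g.kv[b],
                    r2=(res.r2_by_bin[b] if res.r2_by_bin is not None else res.r2),
                    rmse=(res.rmse_by_bin[b] if res.rmse_by_bin is not None else res.rmse),
                    n_rows=(int(res.n_by_bin[b]) if res.n_by_bin is not None else res.n_rows),
                ))
        elif g.direction_split:
            for direction in g.kp:
                records.append(dict(
                    model=res.model, output=g.output, scope=res.scope,
                    bin_lo=0.0, bin_hi=1.0, direction=direction,
                    Kp=g.kp[direction], Kv=g.kv[direction],
                    r2=res.r2, rmse=res.rmse, n_rows=res.n_rows,
                ))
        else:
            records.append(dict(
                model=res.model, output=g.output, scope=res.scope,
                bin_lo=0.0, bin_hi=1.0, direction="both",
                Kp=g.kp, Kv=g.kv, r2=res.r2, rmse=res.rmse, n_rows=res.n_rows,
            ))
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def fit_results_from_csv(path):
    import pandas as pd

    return pd.read_csv(Path(path))
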