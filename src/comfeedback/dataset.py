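"""Canonical trial/dataset data model, on-disk format, importers and validators.

The canonical on-disk format is a UTF-8 CSV per trial: a ``#``-prefixed
``key=value`` header block (subject constants, protocol, perturbation
metadata, gait-event lists, EMG normalization constants) followed by columnar
samples. Floats are written with ``repr`` so that write → read round-trips
bit-exactly.

Conventions (fixed across the package):

* SI units on disk; non-dimensionalization is a pipeline stage, never stored.
* Anterior positive for COM position, COP and perturbation direction;
  plantarflexion moment positive.
* Time is trial-local seconds starting at 0; the perturbation onset is a
  time, not an index.
* Canonical sampling rate is 100 Hz; imported data at other rates is
  resampled by linear interpolation (:func:`resample_trial`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .errors import (
    ImportFormatError,
    SamplingError,
    SchemaError,
    ValidationError,
)

log = logging.getLogger(__name__)

FORMAT_TAG = "comfeedback-trial v1"
CANONICAL_FS = 100.0
GRAVITY = 9.81

MUSCLES = ("tibialis_anterior", "soleus", "gastrocnemius")

PROTOCOLS = (
    "standing_translation",
    "pelvis_push",
    "belt_discrete",
    "belt_continuous",
)

#: protocols whose perturbed trials carry a single discrete onset
DISCRETE_PROTOCOLS = ("standing_translation", "pelvis_push", "belt_discrete")

REQUIRED_COLUMNS = (
    "time",
    "com_pos",
    "com_vel",
    "ankle_angle",
    "ankle_vel",
    "ankle_moment",
    "grf_vertical",
    "cop_ap",
)

_TIME_TOL = 1e-6  # allowed deviation of any time step from the nominal one [s]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectConstants:
    """Anthropometric constants used for non-dimensionalization."""

    subject_id: str
    mass: float  # kg
    com_height: float  # l_max, m
    gravity: float = GRAVITY  # m/s^2, fixed

    def __post_init__(self):
        if not self.mass > 0:
            raise ValidationError(f"mass must be > 0, got {self.mass}")
        if not self.com_height > 0:
            raise ValidationError(f"com_height must be > 0, got {self.com_height}")
        if abs(self.gravity - GRAVITY) > 1e-12:
            raise ValidationError(f"gravity is fixed at {GRAVITY}, got {self.gravity}")


@dataclass(frozen=True)
class Perturbation:
    """Metadata of a single discrete perturbation."""

    onset: float  # s, trial-local
    direction: str  # forward | backward
    magnitude: float  # protocol units

    def __post_init__(self):
        if self.direction not in ("forward", "backward"):
            raise ValidationError(
                f"perturbation direction must be forward/backward, got {self.direction!r}"
            )


@dataclass(frozen=True)
class GaitEvents:
    """Heel-strike and toe-off times per leg (trial-local seconds)."""

    left_hs: tuple = ()
    left_to: tuple = ()
    right_hs: tuple = ()
    right_to: tuple = ()

    def for_leg(self, leg: str) -> tuple:
        if leg == "left":
            return tuple(self.left_hs), tuple(self.left_to)
        if leg == "right":
            return tuple(self.right_hs), tuple(self.right_to)
        raise ValueError(f"leg must be left/right, got {leg!r}")

    def is_empty(self) -> bool:
        return not (self.left_hs or self.left_to or self.right_hs or self.right_to)


@dataclass
class Trial:
    """One perturbation or unperturbed recording.

    All per-sample arrays share length and sampling rate. ``emg`` maps muscle
    name to envelope (normalized units); ``emg_norm`` maps muscle name to the
    normalization constant (MVC for standing, unperturbed-walking peak for
    walking). ``foot_heel_ap`` / ``foot_toe_ap`` are optional fore-aft foot
    bounds used by the COP-bound gain modulator.
    """

    subject: SubjectConstants
    condition: str  # unperturbed | perturbed
    protocol: str
    walking_speed: float  # m/s, 0 for standing
    fs: float
    time: np.ndarray
    com_pos: np.ndarray
    com_vel: np.ndarray
    ankle_angle: np.ndarray
    ankle_vel: np.ndarray
    ankle_moment: np.ndarray
    grf_vertical: np.ndarray
    cop_ap: np.ndarray
    emg: dict = field(default_factory=dict)
    emg_norm: dict = field(default_factory=dict)
    perturbation: Perturbation | None = None
    gait_events: GaitEvents = field(default_factory=GaitEvents)
    analyzed_leg: str = "left"
    foot_heel_ap: np.ndarray | None = None
    foot_toe_ap: np.ndarray | None = None

    # -- helpers -----------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def series_items(self) -> Iterator[tuple[str, np.ndarray]]:
        """Yield (column name, array) for every per-sample series."""
        for name in REQUIRED_COLUMNS:
            yield name, getattr(self, name)
        for muscle in sorted(self.emg):
            yield f"emg_{muscle}", self.emg[muscle]
        if self.foot_heel_ap is not None:
            yield "foot_heel_ap", self.foot_heel_ap
        if self.foot_toe_ap is not None:
            yield "foot_toe_ap", self.foot_toe_ap

    # -- validation --------------------------------------------------------

    def validate(self) -> "Trial":
        """Check every Trial invariant; raise on violation, return self."""
        if self.condition not in ("unperturbed", "perturbed"):
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.protocol not in PROTOCOLS:
            raise ValidationError(f"unknown protocol {self.protocol!r}")
        if self.analyzed_leg not in ("left", "right"):
            raise ValidationError(f"analyzed_leg must be left/right, got {self.analyzed_leg!r}")
        n = self.n_samples
        if n == 0:
            raise ValidationError("trial has 0 samples")
        for name, arr in self.series_items():
            if len(arr) != n:
                raise ValidationError(
                    f"series {name!r} has length {len(arr)}, expected {n}"
                )
        self._check_sampling()
        self._check_perturbation()
        self._check_events()
        for muscle in self.emg:
            if muscle not in MUSCLES:
                raise ValidationError(f"unknown muscle {muscle!r}")
        return self

    def _check_sampling(self):
        t = np.asarray(self.time, dtype=float)
        if len(t) > 1:
            dt = np.diff(t)
            nominal = 1.0 / self.fs
            if np.any(np.abs(dt - nominal) > _TIME_TOL):
                worst = float(np.max(np.abs(dt - nominal)))
                raise SamplingError(
                    f"non-uniform time step: max deviation {worst:.3g} s from "
                    f"nominal {nominal:.6g} s exceeds {_TIME_TOL:g} s"
                )

    def _check_perturbation(self):
        if self.condition == "unperturbed":
            if self.perturbation is not None:
                raise ValidationError("unperturbed trial carries a perturbation record")
            return
        if self.protocol == "belt_continuous":
            # continuous perturbation: whole trial is perturbed, no discrete onset
            if self.perturbation is not None:
                raise ValidationError(
                    "belt_continuous trials have no discrete onset record"
                )
            return
        if self.perturbation is None:
            raise ValidationError(
                f"perturbed {self.protocol} trial requires exactly one onset"
            )
        onset = self.perturbation.onset
        if not (self.time[0] <= onset <= self.time[-1]):
            raise ValidationError(
                f"perturbation onset {onset} s outside recorded span "
                f"[{self.time[0]}, {self.time[-1]}] s"
            )

    def _check_events(self):
        for leg in ("left", "right"):
            hs, to = self.gait_events.for_leg(leg)
            for name, ev in (("heel-strike", hs), ("toe-off", to)):
                if list(ev) != sorted(ev) or len(set(ev)) != len(ev):
                    raise ValidationError(
                        f"{leg} {name} events not strictly increasing"
                    )
            # merged events must alternate hs/to (either may start the sequence)
            merged = sorted([(t, "hs") for t in hs] + [(t, "to") for t in to])
            for (t1, k1), (t2, k2) in zip(merged, merged[1:]):
                if k1 == k2:
                    raise ValidationError(
                        f"{leg} gait events do not alternate near t={t1:.3f} s"
                    )


@dataclass
class Dataset:
    """A collection of trials sharing one protocol (or 'synthetic')."""

    trials: list
    provenance: str = "synthetic"

    def __iter__(self) -> Iterator[Trial]:
        return iter(self.trials)

    def __len__(self) -> int:
        return len(self.trials)

    def subjects(self) -> list:
        seen: dict = {}
        for tr in self.trials:
            seen.setdefault(tr.subject.subject_id, tr.subject)
        return list(seen.values())

    def subject_ids(self) -> list:
        return [s.subject_id for s in self.subjects()]

    def filter(self, **conditions) -> "Dataset":
        """Return a sub-dataset; keys: condition, protocol, subject_id, walking_speed."""

        def keep(tr: Trial) -> bool:
            for key, val in conditions.items():
                if key == "subject_id":
                    if tr.subject.subject_id != val:
                        return False
                elif key == "walking_speed":
                    if abs(tr.walking_speed - val) > 1e-9:
                        return False
                else:
                    if getattr(tr, key) != val:
                        return False
            return True

        return Dataset([tr for tr in self.trials if keep(tr)], self.provenance)

    def unperturbed(self) -> "Dataset":
        return self.filter(condition="unperturbed")

    def perturbed(self) -> "Dataset":
        return self.filter(condition="perturbed")

    def validate(self) -> "Dataset":
        if not self.trials:
            raise ValidationError("dataset has no trials")
        by_protocol: dict = {}
        for tr in self.trials:
            tr.validate()
            by_protocol.setdefault(tr.protocol, set()).add(round(tr.fs, 9))
        for protocol, rates in by_protocol.items():
            if len(rates) > 1:
                raise ValidationError(
                    f"trials of protocol {protocol!r} mix sampling rates {sorted(rates)}"
                )
        return self


# ---------------------------------------------------------------------------
# canonical file IO
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return repr(float(x))


def _fmt_events(ev: Iterable[float]) -> str:
    return ",".join(_fmt(t) for t in ev)


def _parse_events(s: str) -> tuple:
    s = s.strip()
    if not s:
        return ()
    return tuple(float(tok) for tok in s.split(","))


def write_trial(trial: Trial, path) -> None:
    """Write a validated Trial to the canonical CSV format.

    Deterministic: two writes of the same Trial produce byte-identical files.
    """
    trial.validate()
    path = Path(path)
    lines = [f"# {FORMAT_TAG}"]

    def put(key, value):
        lines.append(f"# {key}={value}")

    put("subject_id", trial.subject.subject_id)
    put("mass", _fmt(trial.subject.mass))
    put("com_height", _fmt(trial.subject.com_height))
    put("gravity", _fmt(trial.subject.gravity))
    put("condition", trial.condition)
    put("protocol", trial.protocol)
    put("walking_speed", _fmt(trial.walking_speed))
    put("fs", _fmt(trial.fs))
    put("analyzed_leg", trial.analyzed_leg)
    if trial.perturbation is not None:
        put("perturb_onset", _fmt(trial.perturbation.onset))
        put("perturb_direction", trial.perturbation.direction)
        put("perturb_magnitude", _fmt(trial.perturbation.magnitude))
    ge = trial.gait_events
    put("events_left_hs", _fmt_events(ge.left_hs))
    put("events_left_to", _fmt_events(ge.left_to))
    put("events_right_hs", _fmt_events(ge.right_hs))
    put("events_right_to", _fmt_events(ge.right_to))
    for muscle in sorted(trial.emg_norm):
        put(f"emg_norm_{muscle}", _fmt(trial.emg_norm[muscle]))

    names = [name for name, _ in trial.series_items()]
    arrays = [np.asarray(arr, dtype=float) for _, arr in trial.series_items()]
    lines.append(",".join(names))
    for i in range(trial.n_samples):
        lines.append(",".join(_fmt(a[i]) for a in arrays))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_trial(path) -> Trial:
    """Read and validate a canonical trial file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header: dict = {}
    columns: list = []
    rows: list = []
    with path.open("r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    header[key.strip()] = value
                continue
            if not columns:
                columns = [c.strip() for c in line.split(",")]
                continue
            rows.append([float(tok) for tok in line.split(",")])

    for key in ("subject_id", "mass", "com_height", "condition", "protocol", "fs"):
        if key not in header:
            raise SchemaError(f"missing required header key {key!r} in {path.name}")
    for col in REQUIRED_COLUMNS:
        if col not in columns:
            raise SchemaError(f"missing required column {col!r} in {path.name}")
    if not rows:
        raise ValidationError(f"trial file {path.name} has 0 samples")

    data = np.asarray(rows, dtype=float)
    series = {name: data[:, i].copy() for i, name in enumerate(columns)}

    subject = SubjectConstants(
        subject_id=header["subject_id"],
        mass=float(header["mass"]),
        com_height=float(header["com_height"]),
        gravity=float(header.get("gravity", GRAVITY)),
    )
    perturbation = None
    if "perturb_onset" in header:
        perturbation = Perturbation(
            onset=float(header["perturb_onset"]),
            direction=header.get("perturb_direction", "forward"),
            magnitude=float(header.get("perturb_magnitude", 0.0)),
        )
    gait_events = GaitEvents(
        left_hs=_parse_events(header.get("events_left_hs", "")),
        left_to=_parse_events(header.get("events_left_to", "")),
        right_hs=_parse_events(header.get("events_right_hs", "")),
        right_to=_parse_events(header.get("events_right_to", "")),
    )
    emg = {
        name[len("emg_"):]: arr
        for name, arr in series.items()
        if name.startswith("emg_") and not name.startswith("emg_norm_")
    }
    emg_norm = {
        key[len("emg_norm_"):]: float(val)
        for key, val in header.items()
        if key.startswith("emg_norm_")
    }
    trial = Trial(
        subject=subject,
        condition=header["condition"],
        protocol=header["protocol"],
        walking_speed=float(header.get("walking_speed", 0.0)),
        fs=float(header["fs"]),
        time=series["time"],
        com_pos=series["com_pos"],
        com_vel=series["com_vel"],
        ankle_angle=series["ankle_angle"],
        ankle_vel=series["ankle_vel"],
        ankle_moment=series["ankle_moment"],
        grf_vertical=series["grf_vertical"],
        cop_ap=series["cop_ap"],
        emg=emg,
        emg_norm=emg_norm,
        perturbation=perturbation,
        gait_events=gait_events,
        analyzed_leg=header.get("analyzed_leg", "left"),
        foot_heel_ap=series.get("foot_heel_ap"),
        foot_toe_ap=series.get("foot_toe_ap"),
    )
    return trial.validate()


def write_dataset(dataset: Dataset, directory) -> list:
    """Write every trial as ``trial_XXXX.csv``; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "provenance.txt").write_text(dataset.provenance + "\n", encoding="utf-8")
    paths = []
    for i, trial in enumerate(dataset.trials):
        p = directory / f"trial_{i:04d}.csv"
        write_trial(trial, p)
        paths.append(p)
    return paths


def read_dataset(directory) -> Dataset:
    directory = Path(directory)
    prov_file = directory / "provenance.txt"
    provenance = (
        prov_file.read_text(encoding="utf-8").strip() if prov_file.exists() else "unknown"
    )
    paths = sorted(directory.glob("trial_*.csv"))
    if not paths:
        raise ValidationError(f"no trial files found in {directory}")
    return Dataset([read_trial(p) for p in paths], provenance).validate()


# ---------------------------------------------------------------------------
# resampling (canonical rate)
# ---------------------------------------------------------------------------


def resample_trial(trial: Trial, fs: float = CANONICAL_FS) -> Trial:
    """Linearly resample all series of a trial to ``fs``.

    Events and perturbation metadata are times and carry over unchanged.
    """
    if abs(trial.fs - fs) < 1e-9:
        return trial
    t_old = np.asarray(trial.time, dtype=float)
    n_new = int(math.floor((t_old[-1] - t_old[0]) * fs)) + 1
    t_new = t_old[0] + np.arange(n_new) / fs

    def resample(arr):
        return np.interp(t_new, t_old, np.asarray(arr, dtype=float))

    new = replace(
        trial,
        fs=fs,
        time=t_new,
        com_pos=resample(trial.com_pos),
        com_vel=resample(trial.com_vel),
        ankle_angle=resample(trial.ankle_angle),
        ankle_vel=resample(trial.ankle_vel),
        ankle_moment=resample(trial.ankle_moment),
        grf_vertical=resample(trial.grf_vertical),
        cop_ap=resample(trial.cop_ap),
        emg={m: resample(a) for m, a in trial.emg.items()},
        foot_heel_ap=None if trial.foot_heel_ap is None else resample(trial.foot_heel_ap),
        foot_toe_ap=None if trial.foot_toe_ap is None else resample(trial.foot_toe_ap),
    )
    return new.validate()


# ---------------------------------------------------------------------------
# supplementary .mat import
# ---------------------------------------------------------------------------

_DEFAULT_MAPPING = Path(__file__).parent / "data" / "mat_mappings.yaml"


def _load_mat(path):
    """Load a .mat file (pre-7.3 via scipy, 7.3 via h5py)."""
    from scipy.io import loadmat

    try:
        return loadmat(path, squeeze_me=True, struct_as_record=False)
    except NotImplementedError:
        import h5py

        out = {}
        with h5py.File(path, "r") as f:
            f.visititems(lambda name, obj: out.__setitem__(name, obj[()])
                         if hasattr(obj, "shape") else None)
        return out


def import_supplementary(path, protocol: str, mapping_path=None) -> Dataset:
    """Import one of a supplementary .mat archive of the source study.

    The internal variable names are declared in a versioned YAML mapping table
    (shipped with the package; override with ``mapping_path``). Unmapped
    variables are logged and ignored; an unknown layout raises
    :class:`ImportFormatError` listing the variable names found.
    """
    import yaml

    if protocol not in PROTOCOLS:
        raise ValidationError(f"unknown protocol {protocol!r}")
    mapping_file = Path(mapping_path) if mapping_path else _DEFAULT_MAPPING
    mapping = yaml.safe_load(mapping_file.read_text(encoding="utf-8"))
    try:
        pmap = mapping["protocols"][protocol]
    except KeyError as exc:
        raise ImportFormatError(
            f"mapping table {mapping_file} has no entry for protocol {protocol!r}"
        ) from exc

    raw = _load_mat(path)
    declared_protocol = pmap.get("expected_protocol", protocol)
    if declared_protocol != protocol:
        raise ImportFormatError(
            f"mapping declares protocol {declared_protocol!r}, expected {protocol!r}"
        )

    trials_var = pmap["trials_var"]
    if trials_var not in raw:
        found = sorted(k for k in raw if not k.startswith("__"))
        raise ImportFormatError(
            f"variable {trials_var!r} not found in {Path(path).name}; "
            f"found variables: {found}"
        )

    entries = np.atleast_1d(raw[trials_var])
    fields = pmap["fields"]
    trials = []
    for entry in entries:
        def get(canonical, required=True):
            mat_name = fields.get(canonical)
            if mat_name is None:
                if required:
                    raise ImportFormatError(
                        f"mapping for {protocol!r} lacks field {canonical!r}"
                    )
                return None
            try:
                return getattr(entry, mat_name)
            except AttributeError as exc:
                if required:
                    avail = [a for a in dir(entry) if not a.startswith("_")]
                    raise ImportFormatError(
                        f"trial struct lacks {mat_name!r} (mapped from {canonical!r}); "
                        f"available fields: {avail}"
                    ) from exc
                return None

        known = set(fields.values())
        extra = [a for a in dir(entry) if not a.startswith("_") and a not in known]
        if extra:
            log.info("ignoring unmapped variables: %s", extra)

        def scalar(canonical, required=True):
            v = get(canonical, required=required)
            if v is None:
                return None
            return float(np.ravel(v)[0])

        subject = SubjectConstants(
            subject_id=str(get("subject_id")),
            mass=scalar("mass"),
            com_height=scalar("com_height"),
        )
        onset = get("perturb_onset", required=False)
        perturbation = None
        if onset is not None and np.size(onset) and np.isfinite(float(np.ravel(onset)[0])):
            perturbation = Perturbation(
                onset=float(np.ravel(onset)[0]),
                direction=str(get("perturb_direction")),
                magnitude=scalar("perturb_magnitude"),
            )

        def events(canonical):
            ev = get(canonical, required=False)
            if ev is None:
                return ()
            return tuple(float(x) for x in np.ravel(ev))

        def series(canonical, required=True):
            arr = get(canonical, required=required)
            if arr is None:
                return None
            return np.asarray(np.ravel(arr), dtype=float)

        emg = {}
        for muscle in MUSCLES:
            arr = series(f"emg_{muscle}", required=False)
            if arr is not None and arr.size:
                emg[muscle] = arr
        emg_norm = {}
        for muscle in MUSCLES:
            val = get(f"emg_norm_{muscle}", required=False)
            if val is not None and np.size(val):
                emg_norm[muscle] = float(np.ravel(val)[0])

        trial = Trial(
            subject=subject,
            condition=str(get("condition")),
            protocol=protocol,
            walking_speed=scalar("walking_speed"),
            fs=scalar("fs"),
            time=series("time"),
            com_pos=series("com_pos"),
            com_vel=series("com_vel"),
            ankle_angle=series("ankle_angle"),
            ankle_vel=series("ankle_vel"),
            ankle_moment=series("ankle_moment"),
            grf_vertical=series("grf_vertical"),
            cop_ap=series("cop_ap"),
            emg=emg,
            emg_norm=emg_norm,
            perturbation=perturbation,
            gait_events=GaitEvents(
                left_hs=events("events_left_hs"),
                left_to=events("events_left_to"),
                right_hs=events("events_right_hs"),
                right_to=events("events_right_to"),
            ),
            analyzed_leg=str(get("analyzed_leg", required=False) or "left"),
            foot_heel_ap=series("foot_heel_ap", required=False),
            foot_toe_ap=series("foot_toe_ap", required=False),
        )
        trial = resample_trial(trial.validate())
        trials.append(trial)

    return Dataset(trials, provenance=protocol).validate()
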