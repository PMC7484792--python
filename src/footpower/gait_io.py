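"""Trial-level I/O: marker trajectories, force-plate records, subject metadata.

On-disk layout of a dataset::

    root/
      subjects.yaml                 # one entry per subject (Table-1-style columns)
      segments.yaml                 # segment definitions (local marker coordinates)
      <subject_id>/<condition>/<trial>/
          markers.csv               # header: time, <label>_X, <label>_Y, <label>_Z
          forces.csv                # header: time, Fx, Fy, Fz, Mx, My, Mz (or COP dialect)
          trial.yaml                # measured_speed, sample rates, units, plate origin
          ground_truth.json         # optional sidecar (synthetic trials only)

All positions are metres in a right-handed lab frame with Z vertical up; this
convention is declared here once and never inferred from data.  Readers never
filter or resample: they return raw arrays with gaps flagged, leaving all
signal conditioning to :mod:`footpower.preprocess`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError, LookupError_, ParseError, SyncError

#: Declared lab-frame convention (documentation constant, not configuration).
LAB_FRAME = "right-handed, X forward, Y left, Z vertical up, metres"

YOUNG_AGE_RANGE = (18.0, 40.0)
OLDER_AGE_MIN = 55.0

CONDITIONS = ("slow", "comfortable", "fast")


@dataclass
class SubjectInfo:
    """Demographic / anthropometric record for one subject."""

    subject_id: str
    age: float                  # years
    age_group: int              # 0 = Young, 1 = Older
    height: float               # m
    mass: float                 # kg
    leg_length: float           # m
    comfortable_speed: float    # m/s

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.height <= 0:
            raise ConfigError(
                f"subject {self.subject_id}: mass and height must be positive"
            )
        if self.age_group not in (0, 1):
            raise ConfigError(f"subject {self.subject_id}: age_group must be 0 or 1")
        if self.age_group == 0 and not (
            YOUNG_AGE_RANGE[0] <= self.age <= YOUNG_AGE_RANGE[1]
        ):
            raise ConfigError(
                f"subject {self.subject_id}: age {self.age} inconsistent with Young group"
            )
        if self.age_group == 1 and self.age < OLDER_AGE_MIN:
            raise ConfigError(
                f"subject {self.subject_id}: age {self.age} inconsistent with Older group"
            )

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "age": float(self.age),
            "age_group": int(self.age_group),
            "height": float(self.height),
            "mass": float(self.mass),
            "leg_length": float(self.leg_length),
            "comfortable_speed": float(self.comfortable_speed),
        }


@dataclass
class MarkerTrajectories:
    """Raw marker positions on the motion-capture clock.

    ``positions`` is (n_samples, n_markers, 3) in metres, lab frame; samples
    where a marker was not visible are NaN in ``positions`` and True in
    ``gap_mask``.  No interpolation is ever performed here.
    """

    sample_rate: float
    labels: list
    positions: np.ndarray       # (T, M, 3) m
    time: np.ndarray            # (T,) s
    gap_mask: np.ndarray = None  # (T, M) bool

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.gap_mask is None:
            self.gap_mask = np.isnan(self.positions).any(axis=2)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.positions.shape[0]

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ConfigError(f"unknown marker label {label!r}; have {self.labels}")


@dataclass
class ForcePlateRecord:
    """Raw force-plate channels on the analog clock.

    ``moment_about_origin`` is the plate moment about ``plate_origin`` (a lab
    frame point on the plate surface unless stated otherwise).
    """

    sample_rate: float
    force: np.ndarray                 # (T, 3) N, ground reaction force on the foot
    moment_about_origin: np.ndarray   # (T, 3) N*m
    plate_origin: np.ndarray          # (3,) m
    time: np.ndarray = None           # (T,) s

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        self.moment_about_origin = np.asarray(self.moment_about_origin, dtype=float)
        self.plate_origin = np.asarray(self.plate_origin, dtype=float)
        if self.force.shape != self.moment_about_origin.shape:
            raise ParseError("force and moment arrays must have identical shape")
        if self.time is None:
            self.time = np.arange(self.force.shape[0]) / self.sample_rate
        self.time = np.asarray(self.time, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.force.shape[0]


@dataclass
class Trial:
    """One walking pass: markers + force plate + metadata."""

    subject: SubjectInfo
    condition: str
    measured_speed: float
    markers: MarkerTrajectories
    forceplate: ForcePlateRecord
    trial_id: str = "trial01"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ConfigError(
                f"condition {self.condition!r} not one of {CONDITIONS}"
            )


# ---------------------------------------------------------------------------
# delimited-text readers / writers


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        head = fh.readline()
    if not head.strip():
        raise ParseError(f"{path}: empty file")
    return "\t" if "\t" in head else ","


def _read_table(path: Path) -> tuple[list, np.ndarray]:
    """Read a delimited numeric table; NaN for blank/'nan' cells."""
    path = Path(path)
    delim = _sniff_delimiter(path)
    with open(path) as fh:
        reader = csv.reader(fh, delimiter=delim)
        header = next(reader)
        header = [h.strip() for h in header]
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(row)} cells, expected {len(header)})"
                )
            try:
                rows.append(
                    [float(c) if c.strip() not in ("", "nan", "NaN") else np.nan
                     for c in row]
                )
            except ValueError as exc:
                raise ParseError(f"{path}: non-numeric cell at line {lineno}: {exc}")
    if not rows:
        raise ParseError(f"{path}: no data rows")
    return header, np.asarray(rows, dtype=float)


def read_marker_file(path, config: dict | None = None) -> MarkerTrajectories:
    """Read a delimited marker file with ``<label>_X/_Y/_Z`` columns.

    ``config`` keys: ``units`` ("m" or "mm", default "m"), ``sample_rate``
    (default 150), ``rename`` (file label -> canonical label),
    ``required_labels`` (error listing any that are absent).
    """
    cfg = dict(config or {})
    units = cfg.get("units", "m")
    if units not in ("m", "mm"):
        raise ConfigError(f"unknown marker units {units!r}")
    scale = 1e-3 if units == "mm" else 1.0
    rename = cfg.get("rename", {})

    header, data = _read_table(Path(path))
    cols = {name: i for i, name in enumerate(header)}

    labels = []
    for name in header:
        if name.endswith("_X"):
            lab = name[:-2]
            if {f"{lab}_Y", f"{lab}_Z"} <= set(header):
                labels.append(rename.get(lab, lab))
    if not labels:
        raise ParseError(f"{path}: no <label>_X/_Y/_Z column triplets found")

    required = cfg.get("required_labels")
    if required:
        missing = sorted(set(required) - set(labels))
        if missing:
            raise ConfigError(f"{path}: missing marker labels {missing}")

    inv_rename = {v: k for k, v in rename.items()}
    T = data.shape[0]
    positions = np.empty((T, len(labels), 3))
    for j, lab in enumerate(labels):
        raw = inv_rename.get(lab, lab)
        for k, ax in enumerate(("X", "Y", "Z")):
            positions[:, j, k] = data[:, cols[f"{raw}_{ax}"]]
    positions *= scale

    sample_rate = float(cfg.get("sample_rate", 150.0))
    if "time" in cols:
        time = data[:, cols["time"]]
    else:
        time = np.arange(T) / sample_rate
    return MarkerTrajectories(sample_rate=sample_rate, labels=labels,
                              positions=positions, time=time)


def write_marker_file(path, markers: MarkerTrajectories) -> None:
    path = Path(path)
    header = ["time"]
    for lab in markers.labels:
        header += [f"{lab}_X", f"{lab}_Y", f"{lab}_Z"]
    T = markers.n_samples
    out = np.empty((T, 1 + 3 * len(markers.labels)))
    out[:, 0] = markers.time
    out[:, 1:] = markers.positions.reshape(T, -1)
    _write_table(path, header, out)


def _write_table(path: Path, header: list, data: np.ndarray) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(",".join(header) + "\n")
        for row in data:
            fh.write(",".join(f"{v:.10g}" if np.isfinite(v) else "nan" for v in row))
            fh.write("\n")


FORCE_CHANNELS = ("Fx", "Fy", "Fz", "Mx", "My", "Mz")
COP_CHANNELS = ("Fx", "Fy", "Fz", "COPx", "COPy", "Tz")


def read_force_file(path, config: dict | None = None) -> ForcePlateRecord:
    """Read a delimited force-plate file.

    Two dialects: moment channels (Fx..Mz about the plate origin) or COP
    channels (Fx, Fy, Fz, COPx, COPy, Tz) from which the origin moment is
    reconstructed as ``M = (cop - origin) x F + Tz ez`` with the COP on the
    plate surface plane.
    """
    cfg = dict(config or {})
    sample_rate = float(cfg.get("sample_rate", 300.0))
    if sample_rate <= 0:
        raise ConfigError(f"sample rate must be positive, got {sample_rate}")
    origin = np.asarray(cfg.get("plate_origin", (0.0, 0.0, 0.0)), dtype=float)
    dialect = cfg.get("dialect", "moment")

    header, data = _read_table(Path(path))
    cols = {name: i for i, name in enumerate(header)}
    want = FORCE_CHANNELS if dialect == "moment" else COP_CHANNELS
    missing = sorted(set(want) - set(cols))
    if missing:
        raise ParseError(f"{path}: missing force channels {missing}")

    force = np.column_stack([data[:, cols[c]] for c in ("Fx", "Fy", "Fz")])
    if dialect == "moment":
        moment = np.column_stack([data[:, cols[c]] for c in ("Mx", "My", "Mz")])
    elif dialect == "cop":
        cop = np.column_stack([
            data[:, cols["COPx"]],
            data[:, cols["COPy"]],
            np.full(data.shape[0], origin[2]),
        ])
        tz = data[:, cols["Tz"]]
        moment = np.cross(cop - origin, force)
        moment[:, 2] += tz
    else:
        raise ConfigError(f"unknown force-file dialect {dialect!r}")

    time = data[:, cols["time"]] if "time" in cols else None
    return ForcePlateRecord(sample_rate=sample_rate, force=force,
                            moment_about_origin=moment, plate_origin=origin,
                            time=time)


def write_force_file(path, record: ForcePlateRecord) -> None:
    header = ["time", "Fx", "Fy", "Fz", "Mx", "My", "Mz"]
    out = np.column_stack([record.time, record.force, record.moment_about_origin])
    _write_table(Path(path), header, out)


# ---------------------------------------------------------------------------
# dataset assembly


def read_subjects(root) -> dict:
    path = Path(root) / "subjects.yaml"
    if not path.exists():
        raise LookupError_(f"no subjects.yaml under {root}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or []
    return {d["subject_id"]: SubjectInfo(**d) for d in raw}


def write_subjects(root, subjects: list) -> None:
    path = Path(root) / "subjects.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump([s.to_dict() for s in subjects], fh, sort_keys=False)


def load_trial(root, subject_id: str, condition: str,
               trial: str = "trial01", sync_tol_s: float = 0.05) -> Trial:
    """Assemble a :class:`Trial` from the documented dataset layout.

    Markers and forces are required to share t=0 and to agree in duration
    within ``sync_tol_s``; no resampling happens here.
    """
    root = Path(root)
    subjects = read_subjects(root)
    if subject_id not in subjects:
        raise LookupError_(
            f"unknown subject {subject_id!r}; dataset has {sorted(subjects)}"
        )
    tdir = root / subject_id / condition / trial
    if not tdir.is_dir():
        raise LookupError_(f"no trial directory {tdir}")
    with open(tdir / "trial.yaml") as fh:
        meta = yaml.safe_load(fh)

    markers = read_marker_file(
        tdir / "markers.csv",
        {"units": meta.get("marker_units", "m"),
         "sample_rate": meta.get("marker_rate", 150.0)},
    )
    record = read_force_file(
        tdir / "forces.csv",
        {"sample_rate": meta.get("force_rate", 300.0),
         "plate_origin": meta.get("plate_origin", (0.0, 0.0, 0.0)),
         "dialect": meta.get("force_dialect", "moment")},
    )
    dur_m = markers.time[-1] - markers.time[0]
    dur_f = record.time[-1] - record.time[0]
    if abs(dur_m - dur_f) > sync_tol_s:
        raise SyncError(
            f"marker ({dur_m:.3f} s) and force ({dur_f:.3f} s) durations "
            f"differ by more than {sync_tol_s} s"
        )
    return Trial(subject=subjects[subject_id], condition=condition,
                 measured_speed=float(meta["measured_speed"]),
                 markers=markers, forceplate=record, trial_id=trial)
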