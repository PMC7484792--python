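"""Segment kinematics, contact kinetics, and inertial parameters.

This module turns filtered marker clouds into rigid-body segment states
(rotation, centre-of-mass position/velocity, angular velocity, joint point),
resolves the centre of pressure and free moment from plate channels, and
provides foot/shank inertial parameters from a published anthropometric table.

Conventions
-----------
* All vector quantities are carried in the lab frame; the per-sample inertia
  tensor is rotated into the lab frame where needed.
* Segment definitions live in a local frame with origin at the segment centre
  of mass: marker coordinates, the joint (ankle) point and the COM itself are
  expressed there, so a least-squares rigid fit of the markers recovers the
  lab-from-segment rotation and the COM trajectory in one step.
* The COP is always on the plate surface plane; the free moment is the
  vertical-axis residual moment about the COP and has zero horizontal
  components by construction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import ConfigError, GeometryError, LengthError, NoContactError
from .gait_io import ForcePlateRecord, MarkerTrajectories

GRAVITY = np.array([0.0, 0.0, -9.80665])  # m/s^2, lab frame


@dataclass
class SegmentDefinition:
    """Rigid-segment model: marker and landmark coordinates in a COM-origin
    local frame.

    ``joint_markers`` (e.g. the medial/lateral malleoli) takes precedence for
    the joint point when given: the joint is then the midpoint of those two
    measured markers, the standard ankle-centre convention for lower-limb
    marker sets.  Otherwise ``joint_local`` is mapped through the fitted pose.
    """

    name: str
    local_positions: dict            # label -> (3,) m, COM-origin local frame
    com_local: np.ndarray = field(default_factory=lambda: np.zeros(3))
    joint_local: np.ndarray | None = None
    joint_markers: tuple | None = None

    def __post_init__(self) -> None:
        self.local_positions = {
            k: np.asarray(v, dtype=float) for k, v in self.local_positions.items()
        }
        self.com_local = np.asarray(self.com_local, dtype=float)
        if self.joint_local is not None:
            self.joint_local = np.asarray(self.joint_local, dtype=float)
        if len(self.local_positions) < 3:
            raise ConfigError(
                f"segment {self.name!r} needs >= 3 markers, has "
                f"{len(self.local_positions)}"
            )

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "local_positions": {k: [float(x) for x in v]
                                for k, v in self.local_positions.items()},
            "com_local": [float(x) for x in self.com_local],
        }
        if self.joint_local is not None:
            d["joint_local"] = [float(x) for x in self.joint_local]
        if self.joint_markers is not None:
            d["joint_markers"] = list(self.joint_markers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentDefinition":
        jm = d.get("joint_markers")
        return cls(
            name=d["name"],
            local_positions=d["local_positions"],
            com_local=d.get("com_local", (0.0, 0.0, 0.0)),
            joint_local=d.get("joint_local"),
            joint_markers=tuple(jm) if jm else None,
        )


@dataclass
class SegmentKinematics:
    """Time-resolved rigid state of one segment, lab frame."""

    segment: str
    sample_rate: float
    rotation: np.ndarray          # (T, 3, 3) lab-from-segment
    com_position: np.ndarray      # (T, 3) m
    com_velocity: np.ndarray      # (T, 3) m/s
    angular_velocity: np.ndarray  # (T, 3) rad/s, lab frame
    joint_point: np.ndarray       # (T, 3) m (ankle centre)

    @property
    def n_samples(self) -> int:
        return self.rotation.shape[0]


@dataclass
class ContactKinetics:
    """Centre of pressure, free moment and GRF over one record."""

    cop: np.ndarray               # (T, 3) m, on the plate surface plane
    free_moment: np.ndarray       # (T, 3) N*m, vertical component only
    grf: np.ndarray               # (T, 3) N
    valid: np.ndarray             # (T,) bool, Fz >= threshold
    threshold: float
    r_cop_from_com: np.ndarray | None = None  # filled once foot kinematics known


@dataclass
class InertialParams:
    mass: float                   # kg
    com_offset: float             # fraction of segment length from proximal end
    moi: np.ndarray               # (3, 3) kg*m^2 about COM, segment frame
    table: str = ""
    segment: str = ""

    def __post_init__(self) -> None:
        self.moi = np.asarray(self.moi, dtype=float)
        if self.mass <= 0:
            raise ConfigError("segment mass must be positive")
        if not np.allclose(self.moi, self.moi.T):
            raise ConfigError("inertia tensor must be symmetric")
        if (np.linalg.eigvalsh(self.moi) < -1e-12).any():
            raise ConfigError("inertia tensor must be positive semi-definite")


# ---------------------------------------------------------------------------
# differentiation and angular velocity


def differentiate(series, fs: float) -> np.ndarray:
    """d/dt by central differences (one-sided at the ends)."""
    y = np.asarray(series, dtype=float)
    if y.shape[0] < 3:
        raise LengthError("need at least 3 samples to differentiate")
    return np.gradient(y, 1.0 / fs, axis=0, edge_order=2)


def angular_velocity(rotation, fs: float) -> np.ndarray:
    """Angular velocity from a rotation-matrix time series, lab frame.

    omega is read off the skew-symmetric part of ``Rdot R^T`` with Rdot from
    central differences; the symmetric part (pure discretization error) is
    discarded by averaging the off-diagonal pairs.
    """
    R = np.asarray(rotation, dtype=float)
    if R.ndim != 3 or R.shape[1:] != (3, 3):
        raise ConfigError("rotation must be a (T, 3, 3) array")
    if R.shape[0] < 3:
        raise LengthError("need at least 3 rotation samples")
    Rdot = np.gradient(R, 1.0 / fs, axis=0, edge_order=2)
    W = np.einsum("tij,tkj->tik", Rdot, R)
    omega = np.empty((R.shape[0], 3))
    omega[:, 0] = 0.5 * (W[:, 2, 1] - W[:, 1, 2])
    omega[:, 1] = 0.5 * (W[:, 0, 2] - W[:, 2, 0])
    omega[:, 2] = 0.5 * (W[:, 1, 0] - W[:, 0, 1])
    return omega


# ---------------------------------------------------------------------------
# rigid pose from markers


def _kabsch(local: np.ndarray, observed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation/translation mapping local -> observed (least squares)."""
    p0 = local.mean(axis=0)
    q0 = observed.mean(axis=0)
    H = (local - p0).T @ (observed - q0)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = q0 - R @ p0
    return R, t


def segment_pose(markers: MarkerTrajectories, segdef: SegmentDefinition,
                 fs: float | None = None) -> SegmentKinematics:
    """Least-squares rigid pose of one segment over a (gap-free) window.

    Equivariant under rigid transforms of the marker cloud; raises
    :class:`GeometryError` for collinear marker sets, where the rotation about
    the marker line would be unobservable.
    """
    fs = fs or markers.sample_rate
    labels = list(segdef.local_positions)
    missing = [lab for lab in labels if lab not in markers.labels]
    if missing:
        raise ConfigError(
            f"segment {segdef.name!r}: markers {missing} absent from trajectories"
        )
    idx = [markers.index_of(lab) for lab in labels]
    local = np.stack([segdef.local_positions[lab] for lab in labels])

    sv = np.linalg.svd(local - local.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1e-12):
        raise GeometryError(
            f"segment {segdef.name!r}: marker set is collinear/degenerate"
        )

    obs = markers.positions[:, idx, :]
    if np.isnan(obs).any():
        raise GeometryError(
            f"segment {segdef.name!r}: gap inside the pose-estimation window"
        )
    T = obs.shape[0]
    R = np.empty((T, 3, 3))
    trans = np.empty((T, 3))
    for t in range(T):
        R[t], trans[t] = _kabsch(local, obs[t])

    com = trans + np.einsum("tij,j->ti", R, segdef.com_local)
    if segdef.joint_markers is not None:
        a, b = segdef.joint_markers
        joint = 0.5 * (markers.positions[:, markers.index_of(a), :]
                       + markers.positions[:, markers.index_of(b), :])
    elif segdef.joint_local is not None:
        joint = trans + np.einsum("tij,j->ti", R, segdef.joint_local)
    else:
        raise ConfigError(f"segment {segdef.name!r}: no joint rule configured")

    return SegmentKinematics(
        segment=segdef.name, sample_rate=fs, rotation=R,
        com_position=com, com_velocity=differentiate(com, fs),
        angular_velocity=angular_velocity(R, fs), joint_point=joint,
    )


# ---------------------------------------------------------------------------
# centre of pressure / free moment


def cop_and_free_moment(record: ForcePlateRecord, threshold: float = 50.0,
                        surface_z: float | None = None) -> ContactKinetics:
    """Resolve COP and free moment from plate force/moment channels.

    With moments referred to a point ``s`` on the surface plane and r = cop - s:
    COPx = s_x - My/Fz, COPy = s_y + Mx/Fz, and the free moment is the vertical
    residual Mz - (x*Fy - y*Fx).  Samples with Fz below ``threshold`` carry the
    last valid COP (power contributions are zeroed downstream), so near-zero
    forces at the stance edges never poison work integrals with NaNs.
    """
    F = record.force
    fz = F[:, 2]
    valid = fz >= threshold
    if not valid.any():
        raise NoContactError(
            f"vertical force never reaches {threshold} N; no COP defined"
        )
    origin = record.plate_origin
    if surface_z is None:
        surface_z = origin[2]
    s = np.array([origin[0], origin[1], surface_z])
    # translate moments from the plate origin to the surface point s
    M_s = record.moment_about_origin - np.cross(s - origin, F)

    T = F.shape[0]
    cop = np.full((T, 3), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        x_rel = -M_s[:, 1] / fz
        y_rel = M_s[:, 0] / fz
    cop[valid, 0] = s[0] + x_rel[valid]
    cop[valid, 1] = s[1] + y_rel[valid]
    cop[valid, 2] = surface_z

    free = np.zeros((T, 3))
    free[valid, 2] = (M_s[valid, 2]
                      - (x_rel[valid] * F[valid, 1] - y_rel[valid] * F[valid, 0]))

    # forward/backward fill the held COP outside contact
    idx = np.arange(T)
    good = np.flatnonzero(valid)
    prev = np.searchsorted(good, idx, side="right") - 1
    hold = good[np.clip(prev, 0, good.size - 1)]
    cop = cop[hold]

    return ContactKinetics(cop=cop, free_moment=free, grf=F.copy(),
                           valid=valid, threshold=threshold)


# ---------------------------------------------------------------------------
# anthropometric inertial parameters


def _load_anthropometry() -> dict:
    out = {}
    with resources.files("footpower.data").joinpath("anthropometry.csv").open() as fh:
        for row in csv.DictReader(fh):
            out[(row["table"], row["segment"])] = {
                k: float(v) for k, v in row.items() if k not in ("table", "segment")
            }
    return out


_ANTHRO = None


def anthropometric_entry(table: str, segment: str) -> dict:
    global _ANTHRO
    if _ANTHRO is None:
        _ANTHRO = _load_anthropometry()
    key = (table, segment)
    if key not in _ANTHRO:
        tables = sorted({t for t, _ in _ANTHRO})
        raise ConfigError(f"unknown anthropometric entry {key}; tables: {tables}")
    return _ANTHRO[key]


def segment_inertial(segment: str, mass_body: float, length: float,
                     table: str = "de_leva_male") -> InertialParams:
    """Segment mass, COM offset and inertia from the configured table.

    The principal radii of gyration are mapped onto a segment frame with x
    longitudinal, y transverse and z along the remaining (sagittal-moment)
    axis: Ixx uses the longitudinal radius, Iyy the sagittal, Izz the
    transverse.  Inertia scales linearly in body mass and quadratically in
    segment length.
    """
    if mass_body <= 0 or length <= 0:
        raise GeometryError("body mass and segment length must be positive")
    e = anthropometric_entry(table, segment)
    m = e["mass_fraction"] * mass_body
    moi = np.diag([
        m * (e["rg_longitudinal"] * length) ** 2,
        m * (e["rg_sagittal"] * length) ** 2,
        m * (e["rg_transverse"] * length) ** 2,
    ])
    return InertialParams(mass=m, com_offset=e["com_fraction"], moi=moi,
                          table=table, segment=segment)


def foot_inertial(mass_body: float, foot_length: float,
                  table: str = "de_leva_male") -> InertialParams:
    """Foot inertial parameters (see :func:`segment_inertial`)."""
    return segment_inertial("foot", mass_body, foot_length, table)
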