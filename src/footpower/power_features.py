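"""Ankle, foot and summed mechanical power, and the nine outcome features.

Three power series are computed over stance:

* ``P_ankle`` — six-DOF ankle joint power, the net rate of work done by the
  ankle joint structures on the two adjacent segments:

      P_ankle = F_ankle . dV_ankle + M_ankle . w_ankle

  with ``dV_ankle`` the difference of the ankle-centre material-point
  velocities of foot and shank (distal minus proximal) and
  ``w_ankle = w_foot - w_shank``.  Positive power is generation: the late
  stance push-off burst is positive under this convention.

* ``P_foot`` — distal (deformable) foot power, the rate of energy exchange of
  everything distal to the foot's proximal boundary, from the ground loads
  acting on the rigidly modelled foot:

      P_foot = GRF . [V_cm_foot + w_foot x R_cop/cm] + M_free . w_foot

* ``P_sum = P_ankle + P_foot`` — total ankle-foot power (exact samplewise
  identity).

The nine scalar features are the propulsion-phase peaks of the three series
(the foot peak is the magnitude of its propulsion-phase minimum, reported
positive so that speed effects on all peak features share a sign) and the
positive/negative works (W+ >= 0, W- <= 0), with ankle and sum works taken
over the full stance and foot works over the sub-intervals where P_foot is
positive/negative (the foot absorption phase).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateDataError, SyncError, UsageError
from .foot_mechanics import ContactKinetics, SegmentKinematics
from .inverse_dynamics import JointLoads

FEATURE_NAMES = (
    "P_ankle", "P_foot", "P_sum",
    "Wpos_ankle", "Wpos_foot", "Wpos_sum",
    "Wneg_ankle", "Wneg_foot", "Wneg_sum",
)


@dataclass
class PowerSeries:
    """P_ankle / P_foot / P_sum over one stance, in W (or W/kg if normalized)."""

    time: np.ndarray
    p_ankle: np.ndarray
    p_foot: np.ndarray
    p_sum: np.ndarray
    normalized_by_mass: bool = False

    def __post_init__(self) -> None:
        if not (len(self.time) == len(self.p_ankle) == len(self.p_foot)
                == len(self.p_sum)):
            raise SyncError("power series components differ in length")

    def per_kg(self, mass: float) -> "PowerSeries":
        if self.normalized_by_mass:
            return self
        return PowerSeries(self.time, self.p_ankle / mass, self.p_foot / mass,
                           self.p_sum / mass, normalized_by_mass=True)


@dataclass
class FeatureRecord:
    subject_id: str
    condition: str
    speed: float
    features: dict = field(default_factory=dict)   # name -> value (W or J)


def _material_point_velocity(kin: SegmentKinematics) -> np.ndarray:
    """Velocity of the segment's material point at its joint (ankle) centre."""
    return kin.com_velocity + np.cross(
        kin.angular_velocity, kin.joint_point - kin.com_position
    )


def ankle_power(loads: JointLoads, foot_kin: SegmentKinematics,
                shank_kin: SegmentKinematics) -> np.ndarray:
    """Six-DOF ankle joint power (translational + rotational terms)."""
    n = foot_kin.n_samples
    if shank_kin.n_samples != n or loads.force.shape[0] != n:
        raise SyncError("loads, foot and shank kinematics must share one clock")
    dv = _material_point_velocity(foot_kin) - _material_point_velocity(shank_kin)
    w_rel = foot_kin.angular_velocity - shank_kin.angular_velocity
    return (np.einsum("ti,ti->t", loads.force, dv)
            + np.einsum("ti,ti->t", loads.moment, w_rel))


def foot_power(contact: ContactKinetics, foot_kin: SegmentKinematics) -> np.ndarray:
    """Distal foot power; samples without valid contact are forced to zero."""
    if contact.grf.shape[0] != foot_kin.n_samples:
        raise SyncError("contact kinetics and foot kinematics differ in length")
    r = contact.cop - foot_kin.com_position
    contact.r_cop_from_com = r
    v_pt = foot_kin.com_velocity + np.cross(foot_kin.angular_velocity, r)
    p = (np.einsum("ti,ti->t", contact.grf, v_pt)
         + np.einsum("ti,ti->t", contact.free_moment, foot_kin.angular_velocity))
    p = np.where(contact.valid, p, 0.0)
    return p


def sum_power(p_ankle, p_foot) -> np.ndarray:
    p_ankle = np.asarray(p_ankle, dtype=float)
    p_foot = np.asarray(p_foot, dtype=float)
    if p_ankle.shape != p_foot.shape:
        raise SyncError("p_ankle and p_foot differ in shape")
    return p_ankle + p_foot


def compute_power_series(time, loads: JointLoads, foot_kin: SegmentKinematics,
                         shank_kin: SegmentKinematics,
                         contact: ContactKinetics) -> PowerSeries:
    pa = ankle_power(loads, foot_kin, shank_kin)
    pf = foot_power(contact, foot_kin)
    return PowerSeries(np.asarray(time, dtype=float), pa, pf, sum_power(pa, pf))


# ---------------------------------------------------------------------------
# propulsion window, work, features


def propulsion_window(p_sum) -> slice:
    """Index window of the propulsion phase of stance.

    The window runs from the last negative-to-positive zero crossing of
    ``P_sum`` to toe off.  A series that never crosses (e.g. strictly
    positive) falls back to the final 50% of stance with a warning.
    """
    p = np.asarray(p_sum, dtype=float)
    if p.size == 0 or not np.any(p != 0.0):
        raise DegenerateDataError("all-zero power series has no propulsion phase")
    neg_to_pos = np.flatnonzero((p[:-1] < 0) & (p[1:] >= 0))
    if neg_to_pos.size:
        return slice(int(neg_to_pos[-1]) + 1, p.size)
    warnings.warn(
        "no negative-to-positive crossing of P_sum; "
        "falling back to the final 50% of stance", stacklevel=2,
    )
    return slice(p.size // 2, p.size)


def work(series, time, window: slice | None = None, sign: str = "net") -> float:
    """Trapezoidal work integral of a power series over a window, in J."""
    p = np.asarray(series, dtype=float)
    t = np.asarray(time, dtype=float)
    if window is not None:
        p = p[window]
        t = t[window]
    if p.size == 0:
        warnings.warn("empty work window; returning 0", stacklevel=2)
        return 0.0
    if p.size != t.size:
        raise UsageError("power and time windows differ in length")
    if sign == "positive":
        p = np.clip(p, 0.0, None)
    elif sign == "negative":
        p = np.clip(p, None, 0.0)
    elif sign != "net":
        raise UsageError(f"unknown work sign {sign!r}")
    return float(np.trapezoid(p, t))


def stance_features(powers: PowerSeries) -> dict:
    """The nine features of one stance (peaks in W, works in J).

    Peaks are taken inside the propulsion window: maxima for P_ankle and
    P_sum, the magnitude of the P_foot minimum (reported positive).
    """
    win = propulsion_window(powers.p_sum)
    t = powers.time
    feats = {
        "P_ankle": float(np.max(powers.p_ankle[win])),
        "P_foot": float(-np.min(powers.p_foot[win])),
        "P_sum": float(np.max(powers.p_sum[win])),
    }
    for name, series in (("ankle", powers.p_ankle), ("foot", powers.p_foot),
                         ("sum", powers.p_sum)):
        feats[f"Wpos_{name}"] = work(series, t, sign="positive")
        feats[f"Wneg_{name}"] = work(series, t, sign="negative")
    return feats


def extract_features(trial_powers: list, subject_id: str, condition: str,
                     speed: float, min_trials: int = 3) -> FeatureRecord:
    """Average per-trial features across trials of one subject x condition.

    Mirrors the study's procedure of computing the outcome variables per
    stance and averaging across the representative trials of each condition;
    fewer than ``min_trials`` stances raises :class:`DegenerateDataError`
    (the trial-count rule is a data-quality gate, configurable here).
    """
    if len(trial_powers) < min_trials:
        raise DegenerateDataError(
            f"{subject_id}/{condition}: only {len(trial_powers)} trials, "
            f"minimum is {min_trials}"
        )
    per_trial = [stance_features(p) for p in trial_powers]
    mean_feats = {
        name: float(np.mean([f[name] for f in per_trial]))
        for name in FEATURE_NAMES
    }
    return FeatureRecord(subject_id=subject_id, condition=condition,
                         speed=speed, features=mean_feats)
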