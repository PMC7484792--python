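"""Newton-Euler inverse dynamics of the foot segment.

The foot is modelled as a single rigid body acted on by gravity, the ground
(GRF at the COP plus the vertical free moment) and the shank through the ankle
joint.  Solving the Newton and Euler equations for the unknown joint load
gives the ankle force and moment used by the six-DOF ankle power equation.

Sign convention: ``F_ankle``/``M_ankle`` are the loads applied BY the shank ON
the foot, with the moment expressed about the (moving) ankle centre so it
plugs directly into the joint-power formula.  The convention is pinned by the
rigid-body energy balance: the total power of all external loads on the foot
must equal the rate of change of its kinetic energy (see
:func:`energy_balance`), which any sign error breaks immediately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SyncError
from .foot_mechanics import (
    GRAVITY,
    ContactKinetics,
    InertialParams,
    SegmentKinematics,
    differentiate,
)


@dataclass
class JointLoads:
    """Ankle load on the foot from the shank, lab frame."""

    force: np.ndarray    # (T, 3) N
    moment: np.ndarray   # (T, 3) N*m, about the ankle centre


def _check_clocks(*lengths) -> None:
    if len(set(lengths)) != 1:
        raise SyncError(f"inputs are on different clocks: lengths {lengths}")


def _lab_inertia(kin: SegmentKinematics, inertia: InertialParams) -> np.ndarray:
    return np.einsum("tij,jk,tlk->til", kin.rotation, inertia.moi, kin.rotation)


def newton_euler_foot(kin: SegmentKinematics, contact: ContactKinetics,
                      inertia: InertialParams,
                      g: np.ndarray = GRAVITY) -> JointLoads:
    """Solve the foot's Newton-Euler equations for the ankle load.

    Newton:  m a_com = F_ankle + GRF + m g
    Euler (about COM):  I w' + w x (I w) = M_ankle
        + (r_ankle - r_com) x F_ankle + (r_cop - r_com) x GRF + M_free

    Accelerations come from :func:`differentiate` applied to the kinematic
    velocities; the inertia tensor is rotated per sample into the lab frame.
    """
    _check_clocks(kin.n_samples, contact.grf.shape[0])
    m = inertia.mass
    fs = kin.sample_rate
    a_com = differentiate(kin.com_velocity, fs)
    omega = kin.angular_velocity
    omega_dot = differentiate(omega, fs)
    I_lab = _lab_inertia(kin, inertia)

    F_ankle = m * a_com - m * g - contact.grf

    Iw = np.einsum("tij,tj->ti", I_lab, omega)
    M_inertial = np.einsum("tij,tj->ti", I_lab, omega_dot) + np.cross(omega, Iw)
    r_ankle = kin.joint_point - kin.com_position
    r_cop = contact.cop - kin.com_position
    M_ankle = (M_inertial
               - np.cross(r_ankle, F_ankle)
               - np.cross(r_cop, contact.grf)
               - contact.free_moment)
    return JointLoads(force=F_ankle, moment=M_ankle)


# ---------------------------------------------------------------------------
# residual diagnostics (the module's oracles)


def newton_residual(loads: JointLoads, kin: SegmentKinematics,
                    contact: ContactKinetics, inertia: InertialParams,
                    g: np.ndarray = GRAVITY) -> np.ndarray:
    """m a - (F_ankle + GRF + m g); zero by construction for our own solver."""
    m = inertia.mass
    a_com = differentiate(kin.com_velocity, kin.sample_rate)
    return m * a_com - (loads.force + contact.grf + m * g)


def euler_residual(loads: JointLoads, kin: SegmentKinematics,
                   contact: ContactKinetics, inertia: InertialParams) -> np.ndarray:
    """Euler equation residual about the COM (should vanish)."""
    fs = kin.sample_rate
    omega = kin.angular_velocity
    I_lab = _lab_inertia(kin, inertia)
    Iw = np.einsum("tij,tj->ti", I_lab, omega)
    lhs = np.einsum("tij,tj->ti", I_lab, differentiate(omega, fs)) \
        + np.cross(omega, Iw)
    rhs = (loads.moment
           + np.cross(kin.joint_point - kin.com_position, loads.force)
           + np.cross(contact.cop - kin.com_position, contact.grf)
           + contact.free_moment)
    return lhs - rhs


def energy_balance(loads: JointLoads, kin: SegmentKinematics,
                   contact: ContactKinetics, inertia: InertialParams,
                   g: np.ndarray = GRAVITY) -> tuple[np.ndarray, np.ndarray]:
    """External power on the foot vs. rate of change of its kinetic energy.

    Returns ``(power_in, dE_dt)`` where

        power_in = F_ankle . v_ankle + M_ankle . w + GRF . v_cop
                   + M_free . w + m g . v_com

    with v_ankle and v_cop the material-point velocities of the foot at the
    ankle centre and the COP, and E = 1/2 m |v_com|^2 + 1/2 w . I_lab w.
    For a rigid body the two sides agree up to numerical differentiation
    error; the identity pins every sign convention in this module.
    """
    m = inertia.mass
    fs = kin.sample_rate
    v = kin.com_velocity
    w = kin.angular_velocity
    I_lab = _lab_inertia(kin, inertia)
    Iw = np.einsum("tij,tj->ti", I_lab, w)

    v_ankle = v + np.cross(w, kin.joint_point - kin.com_position)
    v_cop = v + np.cross(w, contact.cop - kin.com_position)
    power_in = (np.einsum("ti,ti->t", loads.force, v_ankle)
                + np.einsum("ti,ti->t", loads.moment, w)
                + np.einsum("ti,ti->t", contact.grf, v_cop)
                + np.einsum("ti,ti->t", contact.free_moment, w)
                + m * v @ g)
    E = 0.5 * m * np.einsum("ti,ti->t", v, v) + 0.5 * np.einsum("ti,ti->t", w, Iw)
    dE_dt = differentiate(E, fs)
    return power_in, dE_dt
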