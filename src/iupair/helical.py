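"""Helicoidal base-pair and base-pair-step parameters.

All parameters use one internally consistent mid-frame scheme (the
CEHS/3DNA construction): the relative rotation between two frames is
split symmetrically about the hinge axis, the twist-like angle is
measured about the shared z-axis of the symmetrized frames, and the
translational parameters are the components of the origin difference in
the mid-frame.  Pair parameters (shear, stretch, stagger, buckle,
propeller, opening) are obtained from the same decomposition applied
from the flipped strand-2 base frame to the strand-1 base frame, so a
purine on strand 1 sliding its partner toward the major groove gives
the negative shear characteristic of wobble pairs.

Distances are in Angstrom, angles in degrees.  The local bend of a step
is ``sqrt(roll**2 + tilt**2)``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .basegeom import ReferenceFrame

__all__ = [
    "PairParams", "StepParams", "BendSummary",
    "pair_params", "step_params", "compose_step", "compose_pair",
    "pair_mid_frame", "flip_frame",
    "trajectory_profile", "total_bend",
]

_FLIP = np.diag([1.0, -1.0, -1.0])  # 180 deg about the frame's own x

#: Idealized straight A-form step means (shift, slide, rise, tilt, roll,
#: twist): the characteristic backward slide of A-RNA with zero roll, so
#: a noise-free duplex is perfectly straight.  Angstrom / degrees.
A_RNA_STEP = (0.0, -1.5, 3.3, 0.0, 0.0, 32.7)


@dataclass(frozen=True)
class PairParams:
    pair_index: int
    shear: float
    stretch: float
    stagger: float
    buckle: float
    propeller: float
    opening: float

    def as_array(self) -> np.ndarray:
        return np.array([self.shear, self.stretch, self.stagger,
                         self.buckle, self.propeller, self.opening])


@dataclass(frozen=True)
class StepParams:
    step_index: int
    shift: float
    slide: float
    rise: float
    tilt: float
    roll: float
    twist: float

    @property
    def local_bend(self) -> float:
        return float(np.hypot(self.roll, self.tilt))

    def as_array(self) -> np.ndarray:
        return np.array([self.shift, self.slide, self.rise,
                         self.tilt, self.roll, self.twist])


@dataclass(frozen=True)
class BendSummary:
    total_bend: float               # degrees, >= 0
    local_bends: np.ndarray         # mean per-step local bend, degrees


def _rot(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about a unit axis (Rodrigues)."""
    x, y, z = axis
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * K @ K


def _decompose(frame_from: ReferenceFrame,
               frame_to: ReferenceFrame) -> np.ndarray:
    """Mid-frame decomposition -> (dx, dy, dz, tilt, roll, twist-like).

    Angles returned in radians; the caller converts.
    """
    R1, R2 = frame_from.axes, frame_to.axes
    z1, z2 = R1[:, 2], R2[:, 2]
    cosg = np.clip(z1 @ z2, -1.0, 1.0)
    gamma = np.arccos(cosg)
    if gamma < 1e-12:
        hinge = R1[:, 1]          # arbitrary in-plane axis; gamma is zero
    else:
        hinge = np.cross(z1, z2)
        hinge /= np.linalg.norm(hinge)
    A = _rot(hinge, 0.5 * gamma)
    R1p = A @ R1
    R2p = _rot(hinge, -0.5 * gamma) @ R2
    zm = R1p[:, 2]
    x1, x2 = R1p[:, 0], R2p[:, 0]
    y1, y2 = R1p[:, 1], R2p[:, 1]
    # twist about the common z, averaged over x- and y-axis estimates
    omega = np.arctan2(np.cross(x1, x2) @ zm + np.cross(y1, y2) @ zm,
                       x1 @ x2 + y1 @ y2)
    xm = x1 + x2
    xm /= np.linalg.norm(xm)
    ym = np.cross(zm, xm)
    phi = np.arctan2(np.cross(ym, hinge) @ zm, ym @ hinge)
    tilt = gamma * np.sin(phi)
    roll = gamma * np.cos(phi)
    Rm = np.column_stack([xm, ym, zm])
    disp = Rm.T @ (frame_to.origin - frame_from.origin)
    return np.array([disp[0], disp[1], disp[2], tilt, roll, omega])


def _mid_frame(frame_from: ReferenceFrame,
               frame_to: ReferenceFrame) -> ReferenceFrame:
    """Mid frame of the symmetric decomposition, origin at the midpoint."""
    R1, R2 = frame_from.axes, frame_to.axes
    z1, z2 = R1[:, 2], R2[:, 2]
    cosg = np.clip(z1 @ z2, -1.0, 1.0)
    gamma = np.arccos(cosg)
    if gamma < 1e-12:
        hinge = R1[:, 1]
    else:
        hinge = np.cross(z1, z2)
        hinge /= np.linalg.norm(hinge)
    R1p = _rot(hinge, 0.5 * gamma) @ R1
    R2p = _rot(hinge, -0.5 * gamma) @ R2
    xm = R1p[:, 0] + R2p[:, 0]
    xm /= np.linalg.norm(xm)
    zm = R1p[:, 2]
    ym = np.cross(zm, xm)
    return ReferenceFrame(0.5 * (frame_from.origin + frame_to.origin),
                          np.column_stack([xm, ym, zm]))


def _compose(frame_from: ReferenceFrame, params: np.ndarray) -> ReferenceFrame:
    """Inverse of :func:`_decompose` (angles in radians)."""
    dx, dy, dz, tilt, roll, omega = params
    gamma = float(np.hypot(tilt, roll))
    phi = float(np.arctan2(tilt, roll))
    # hinge axis in the from-frame, at phi + omega/2 from the mid y-axis
    alpha = phi + 0.5 * omega + 0.5 * np.pi
    h_local = np.array([np.cos(alpha), np.sin(alpha), 0.0])
    R1 = frame_from.axes
    hinge = R1 @ h_local
    R2 = _rot(hinge, gamma) @ R1 @ _rot_z(omega)
    Rm_axes = _rot(hinge, 0.5 * gamma) @ R1 @ _rot_z(0.5 * omega)
    origin_to = frame_from.origin + Rm_axes @ np.array([dx, dy, dz])
    return ReferenceFrame(origin_to, R2)


def _rot_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def flip_frame(frame: ReferenceFrame) -> ReferenceFrame:
    """Rotate a frame 180 degrees about its own x-axis (strand-2 bases)."""
    return ReferenceFrame(frame.origin, frame.axes @ _FLIP)


def pair_params(frame_b1: ReferenceFrame, frame_b2: ReferenceFrame,
                pair_index: int = 0, flipped: bool = False) -> PairParams:
    """Six base-pair parameters of base 1 relative to its partner.

    ``frame_b2`` is the partner base's own frame; it is flipped about
    its x-axis internally unless ``flipped`` says the caller already
    did so.
    """
    f2 = frame_b2 if flipped else flip_frame(frame_b2)
    d = _decompose(f2, frame_b1)
    deg = np.degrees(d[3:])
    return PairParams(pair_index, d[0], d[1], d[2], deg[0], deg[1], deg[2])


def pair_mid_frame(frame_b1: ReferenceFrame, frame_b2: ReferenceFrame,
                   flipped: bool = False) -> ReferenceFrame:
    """The base-pair frame: mid frame between base 1 and the flipped base 2."""
    f2 = frame_b2 if flipped else flip_frame(frame_b2)
    return _mid_frame(f2, frame_b1)


def step_params(pair_frame_i: ReferenceFrame, pair_frame_i1: ReferenceFrame,
                step_index: int = 0) -> StepParams:
    """Six step parameters between consecutive base-pair frames."""
    d = _decompose(pair_frame_i, pair_frame_i1)
    deg = np.degrees(d[3:])
    return StepParams(step_index, d[0], d[1], d[2], deg[0], deg[1], deg[2])


def compose_step(pair_frame_i: ReferenceFrame,
                 params: StepParams) -> ReferenceFrame:
    """Build the next pair frame from step parameters (inverse of
    :func:`step_params`)."""
    p = np.array([params.shift, params.slide, params.rise,
                  np.radians(params.tilt), np.radians(params.roll),
                  np.radians(params.twist)])
    return _compose(pair_frame_i, p)


def compose_pair(mid_frame: ReferenceFrame,
                 params: PairParams) -> Tuple[ReferenceFrame, ReferenceFrame]:
    """Place the two base frames of a pair from its mid frame and
    parameters; returns ``(frame_b1, frame_b2)`` with ``frame_b2`` the
    partner base's own (unflipped) frame."""
    p = np.array([params.shear, params.stretch, params.stagger,
                  np.radians(params.buckle), np.radians(params.propeller),
                  np.radians(params.opening)])
    # mid frame M relates to the 'from' (flipped b2) frame by the half
    # transform Q; invert it, then run the full transform forward.
    gamma = float(np.hypot(p[3], p[4]))
    phi = float(np.arctan2(p[3], p[4]))
    alpha = phi + 0.5 * p[5] + 0.5 * np.pi
    h_local = np.array([np.cos(alpha), np.sin(alpha), 0.0])
    Q = _rot_from_local(h_local, 0.5 * gamma) @ _rot_z(0.5 * p[5])
    R_from = mid_frame.axes @ np.linalg.inv(Q)
    o_from = mid_frame.origin - 0.5 * (mid_frame.axes @ p[:3])
    frame_from = ReferenceFrame(o_from, R_from)
    frame_b1 = _compose(frame_from, p)
    frame_b2 = flip_frame(frame_from)
    return frame_b1, frame_b2


def _rot_from_local(h_local: np.ndarray, angle: float) -> np.ndarray:
    """Rotation about an axis given in local coordinates, as applied on
    the right of a frame matrix: R' = R @ Rot_local."""
    return _rot(h_local, angle)


def trajectory_profile(values: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Per-position means and standard deviations over frames.

    ``values`` has shape (n_frames, n_positions); angles are averaged
    arithmetically (valid away from the +-180 degree wrap).
    """
    values = np.asarray(values, float)
    if values.size == 0 or values.shape[0] == 0:
        raise ValueError("empty ensemble")
    return values.mean(axis=0), values.std(axis=0, ddof=0)


def total_bend(pair_frames: Sequence[Sequence[ReferenceFrame]]) -> BendSummary:
    """Global duplex bend from mid-pair frame z-vectors.

    For each frame of the ensemble, the helical-axis direction of each
    terminal half of the duplex is taken as the mean z-vector of its
    mid-pair frames, excluding the terminal pair at each end; the bend
    is the angle between the two half-axis directions, averaged over
    frames.

    Parameters
    ----------
    pair_frames
        Ensemble of per-frame lists of mid-pair frames (>=4 pairs).
    """
    angles = []
    bends = []
    for frames in pair_frames:
        n = len(frames)
        if n < 4:
            raise ValueError("total bend needs a duplex of >=4 pairs")
        zs = np.array([f.axes[:, 2] for f in frames[1:-1]])
        half = len(zs) // 2
        a1 = zs[:half].mean(axis=0)
        a2 = zs[-half:].mean(axis=0)
        a1 /= np.linalg.norm(a1)
        a2 /= np.linalg.norm(a2)
        angles.append(np.degrees(np.arccos(np.clip(a1 @ a2, -1.0, 1.0))))
        local = [step_params(frames[i], frames[i + 1], i).local_bend
                 for i in range(n - 1)]
        bends.append(local)
    return BendSummary(float(np.mean(angles)), np.mean(np.array(bends), axis=0))
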