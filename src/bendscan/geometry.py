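"""Rigid superposition and inter-helical Euler-angle decomposition.

The bend/twist analysis rests on three primitives:

* least-squares rigid superposition (Kabsch) of an ideal 3-bp helix onto an
  observed duplex segment, which carries the ideal helix's central-pair frame
  onto the segment;
* the relative rotation between two such frames;
* its active ZYZ Euler decomposition R = Rz(alpha) Ry(beta_h) Rz(gamma), from
  which the bend magnitude beta_h (the exact inter-axis angle), the bending
  direction gamma_h = alpha and the inter-helical twist zeta_h = alpha + gamma
  are read off. beta_h is computed in the numerically stable atan2 form so an
  undistorted helix yields beta_h at machine precision rather than the
  sqrt(eps) noise floor of arccos.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    BasePair,
    DegenerateGeometryError,
    Duplex,
    HelixFrame,
    UsageError,
    ValidationError,
    frame_atom_names,
    step_count,
    wrap_angle,
)
from .ideal_helix import FiberParams, build_ideal_duplex, pair_frame

__all__ = [
    "EulerAngles",
    "SuperpositionResult",
    "compose_euler",
    "euler_decompose",
    "fit_helix_frame",
    "kabsch_superpose",
    "relative_rotation",
    "underwinding",
]

#: sin(beta) below which the ZYZ decomposition is treated as gimbal-locked
GIMBAL_TOL = 1e-12


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid motion x -> R x + t of a moving set onto a fixed set."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


@dataclass(frozen=True)
class EulerAngles:
    """ZYZ inter-helical angles, degrees.

    beta_h in [0, 180] is the bend magnitude (angle between helical axes),
    gamma_h in (-180, 180] the bending direction, zeta_h in (-180, 180] the
    inter-helical twist. When beta_h is at a gimbal singularity (0 or 180) the
    direction is undefined and reported as 0.
    """

    beta_h: float
    gamma_h: float
    zeta_h: float
    gimbal: bool = False


def kabsch_superpose(
    moving: Sequence[Sequence[float]] | np.ndarray,
    fixed: Sequence[Sequence[float]] | np.ndarray,
) -> SuperpositionResult:
    """Least-squares proper-rotation superposition of point sets.

    Returns the rigid transform minimizing the RMSD of ``moving`` onto
    ``fixed``; reflections are excluded even for near-planar sets.
    """
    P = np.asarray(moving, dtype=float)
    Q = np.asarray(fixed, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise UsageError("moving and fixed must be equal-shape (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise DegenerateGeometryError("need at least 3 points for superposition")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    for name, X in (("moving", P0), ("fixed", Q0)):
        s = np.linalg.svd(X, compute_uv=False)
        if s[1] <= 1e-8 * max(s[0], 1.0):
            raise DegenerateGeometryError(f"{name} points are collinear")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cq - R @ cp
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    return SuperpositionResult(R, t, rmsd)


def fit_helix_frame(
    segment: Sequence[BasePair],
    reference: Duplex | None = None,
    params: FiberParams | None = None,
) -> tuple[HelixFrame, float]:
    """Fit an ideal 3-bp B-form helix to an observed segment.

    The ideal helix is built with the segment's target-strand sequence (or
    taken from ``reference``), its base-ring + C1' atoms of both strands are
    superposed onto the observed segment, and the ideal helix's central-pair
    frame is carried through the fitted transform. Returns (frame, fit RMSD).
    """
    segment = list(segment)
    if len(segment) != 3:
        raise UsageError("a helix segment must contain exactly 3 base pairs")
    steps = [step_count(a.pam_index, b.pam_index) for a, b in zip(segment, segment[1:])]
    if steps != [1, 1]:
        raise UsageError(
            f"segment pairs must be consecutive (pam_index {[p.pam_index for p in segment]})"
        )
    p = params or FiberParams()
    seq = "".join(bp.ts.base for bp in segment)
    if reference is None:
        reference = build_ideal_duplex(seq, p, first_index=1)
    elif reference.ts_sequence() != seq:
        raise UsageError(
            f"reference sequence {reference.ts_sequence()!r} does not match segment {seq!r}"
        )
    ideal_xyz, obs_xyz = [], []
    for ref_bp, obs_bp in zip(reference.pairs, segment):
        for ref_nt, obs_nt in ((ref_bp.ts, obs_bp.ts), (ref_bp.nts, obs_bp.nts)):
            names = frame_atom_names(ref_nt.base)
            ideal_xyz.append(ref_nt.coords(names))
            obs_xyz.append(obs_nt.coords(names))
    sup = kabsch_superpose(np.vstack(ideal_xyz), np.vstack(obs_xyz))
    frame = pair_frame(1, p).transformed(sup.rotation, sup.translation)
    return frame, sup.rmsd


def relative_rotation(h1: HelixFrame, h2: HelixFrame) -> np.ndarray:
    """Rotation of h2's axes expressed in h1's frame: R = A1^T A2."""
    h1.validate()
    h2.validate()
    return h1.axes.T @ h2.axes


def _check_rotation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValidationError("rotation must be a 3x3 matrix")
    if np.abs(R.T @ R - np.eye(3)).max() > 1e-6 or abs(np.linalg.det(R) - 1.0) > 1e-6:
        raise ValidationError("matrix is not a proper rotation (orthonormal, det +1)")
    return R


def euler_decompose(R: np.ndarray) -> EulerAngles:
    """Active ZYZ decomposition R = Rz(alpha) Ry(beta) Rz(gamma).

    Reports beta_h = beta in [0, 180], gamma_h = wrap(alpha) and
    zeta_h = wrap(alpha + gamma). At gimbal lock (beta = 0 or 180) only
    alpha + gamma (resp. alpha - gamma) is determined; gamma_h is reported as
    0 by convention and the result is flagged.
    """
    R = _check_rotation(R)
    sin_beta = float(np.hypot(R[2, 0], R[2, 1]))
    beta = float(np.degrees(np.arctan2(sin_beta, R[2, 2])))
    if sin_beta < GIMBAL_TOL:
        if R[2, 2] > 0:  # beta ~ 0: R ~ Rz(alpha + gamma)
            zeta = float(np.degrees(np.arctan2(R[1, 0], R[0, 0])))
            return EulerAngles(beta, 0.0, wrap_angle(zeta), gimbal=True)
        # beta ~ 180: only alpha - gamma is determined; twist undefined.
        return EulerAngles(beta, 0.0, 0.0, gimbal=True)
    alpha = float(np.degrees(np.arctan2(R[1, 2], R[0, 2])))
    gamma = float(np.degrees(np.arctan2(R[2, 1], -R[2, 0])))
    return EulerAngles(beta, wrap_angle(alpha), wrap_angle(alpha + gamma))


def compose_euler(beta_h: float, gamma_h: float, zeta_h: float) -> np.ndarray:
    """Inverse of :func:`euler_decompose`: rebuild R from the three angles."""

    def rz(d: float) -> np.ndarray:
        c, s = np.cos(np.deg2rad(d)), np.sin(np.deg2rad(d))
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    b = np.deg2rad(beta_h)
    ry = np.array(
        [
            [np.cos(b), 0.0, np.sin(b)],
            [0.0, 1.0, 0.0],
            [-np.sin(b), 0.0, np.cos(b)],
        ]
    )
    return rz(gamma_h) @ ry @ rz(zeta_h - gamma_h)


def underwinding(n_junction: int, zeta_h: float, twist_per_step: float = 36.0) -> float:
    """Underwinding across an N-bp junction: N * twist - zeta_h (degrees).

    The sign is preserved and no re-wrapping is applied: positive values mean
    the junction is underwound relative to ideal B-form.
    """
    if not isinstance(n_junction, (int, np.integer)) or n_junction < 1:
        raise UsageError("n_junction must be an integer >= 1")
    return n_junction * twist_per_step - zeta_h
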