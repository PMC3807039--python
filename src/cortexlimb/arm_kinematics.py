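"""Forward/inverse kinematics of the 4-DOF shoulder-elbow arm model.

The arm is modeled as two rigid segments: upper arm (length ``l1``) from the
shoulder to the elbow and forearm (length ``l2``) from the elbow to the
wrist.  Four joint angles are tracked:

======  ==============================  ==========================
angle   motion                          rotation
======  ==============================  ==========================
theta1  shoulder adduction/abduction    about x
theta2  shoulder extension/flexion      about y
theta3  shoulder medial/lateral rot.    about z (upper-arm axis)
theta4  elbow extension/flexion         interior elbow angle
======  ==============================  ==========================

The shoulder sits at the origin and the arm hangs along -z at zero shoulder
angles.  ``theta4`` is the interior angle at the elbow, so ``theta4 = pi``
is the fully extended (straight) arm and small values are deep flexion;
this makes the law-of-cosines inversion
``cos(theta4) = (l1^2 + l2^2 - R^2) / (2 l1 l2)`` (with ``R`` the
shoulder-wrist distance) hold with the principal arccos branch.  The full
transform chain is ``Ax(t1) Ay(t2) Az(t3) Lz(l1) Ax(pi - t4) Lz(l2)``.

Closed-form positions used throughout (``ci = cos(theta_i)``, etc.)::

    elbow = -l1 * [s2, -s1 c2, c1 c2]
    wrist = elbow + l2 * [ s2 c4 - c2 s3 s4,
                           (c1 c3 - s1 s2 s3) s4 - s1 c2 c4,
                           (s1 c3 + c1 s2 s3) s4 + c1 c2 c4 ]

The closed-form inverse uses principal branches, valid on the restricted
workspace ``theta2, theta3 in (-pi/2, pi/2)``, ``theta4 in (0, pi)``:
``theta1 = atan2(yE, -zE)`` (the branch of ``tan(theta1) = -yE/zE`` that
round-trips with the forward model), ``theta2 = asin(-xE/l1)``, ``theta4``
by the law of cosines, and
``theta3 = asin(((xE - xW)/l2 + s2 c4) / (c2 s4))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cortexlimb.exceptions import (
    InvalidInputError,
    SingularConfigurationError,
    UnreachablePostureError,
)

#: absolute tolerance for clamping |sin(theta2)|, |cos(theta4)| to 1 before
#: declaring a posture unreachable (guards against marker noise)
CLAMP_TOL = 1e-6

#: |sin(theta4)| below this is treated as a singular configuration for theta3
SINGULAR_TOL = 1e-8


@dataclass(frozen=True)
class ArmGeometry:
    """Segment lengths of the arm model, in meters."""

    l1: float
    l2: float

    def __post_init__(self):
        if not (self.l1 > 0 and self.l2 > 0):
            raise InvalidInputError("segment lengths must be positive")


@dataclass
class JointAngleTrajectory:
    """Joint angles theta1..theta4 (radians) sampled uniformly at ``rate`` Hz.

    ``theta`` has shape (4, T).  ``t_start`` is the time of the first sample
    relative to movement onset (seconds); trajectories cut to include a
    pre-movement baseline have negative ``t_start``.
    """

    theta: np.ndarray
    rate: float
    t_start: float = 0.0

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 2 or self.theta.shape[0] != 4:
            raise InvalidInputError(
                f"theta must have shape (4, T), got {self.theta.shape}"
            )
        if self.rate <= 0:
            raise InvalidInputError("rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.theta.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.n_samples) / self.rate


@dataclass
class MarkerTrajectory:
    """3-D positions of shoulder, elbow and wrist markers, each (3, T), meters."""

    shoulder: np.ndarray
    elbow: np.ndarray
    wrist: np.ndarray
    rate: float = 120.0
    t_start: float = 0.0

    def __post_init__(self):
        for name in ("shoulder", "elbow", "wrist"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[0] != 3:
                raise InvalidInputError(f"{name} must have shape (3, T)")
            setattr(self, name, arr)
        if not (
            self.shoulder.shape == self.elbow.shape == self.wrist.shape
        ):
            raise InvalidInputError("marker arrays must share one shape")
        if self.rate <= 0:
            raise InvalidInputError("rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.shoulder.shape[1]


def estimate_geometry(markers: MarkerTrajectory) -> ArmGeometry:
    """Estimate segment lengths as median marker distances.

    Subject-specific segment lengths are measured per recording in practice;
    when they are not supplied, the median shoulder-elbow and elbow-wrist
    distances over the trajectory are a robust stand-in.
    """
    l1 = float(np.median(np.linalg.norm(markers.elbow - markers.shoulder, axis=0)))
    l2 = float(np.median(np.linalg.norm(markers.wrist - markers.elbow, axis=0)))
    return ArmGeometry(l1=l1, l2=l2)


def forward_kinematics(
    angles: JointAngleTrajectory, geom: ArmGeometry
) -> MarkerTrajectory:
    """Map joint angles to shoulder/elbow/wrist marker positions.

    The shoulder is fixed at the origin.  Elbow and wrist follow the
    closed-form expressions in the module docstring.
    """
    th = angles.theta
    if not np.all(np.isfinite(th)):
        raise InvalidInputError("non-finite joint angles")
    s1, c1 = np.sin(th[0]), np.cos(th[0])
    s2, c2 = np.sin(th[1]), np.cos(th[1])
    s3, c3 = np.sin(th[2]), np.cos(th[2])
    s4, c4 = np.sin(th[3]), np.cos(th[3])
    l1, l2 = geom.l1, geom.l2

    elbow = -l1 * np.stack([s2, -s1 * c2, c1 * c2])
    wrist = elbow + l2 * np.stack(
        [
            s2 * c4 - c2 * s3 * s4,
            (c1 * c3 - s1 * s2 * s3) * s4 - s1 * c2 * c4,
            (s1 * c3 + c1 * s2 * s3) * s4 + c1 * c2 * c4,
        ]
    )
    shoulder = np.zeros_like(elbow)
    return MarkerTrajectory(
        shoulder=shoulder,
        elbow=elbow,
        wrist=wrist,
        rate=angles.rate,
        t_start=angles.t_start,
    )


def _clamped(x: np.ndarray, what: str) -> np.ndarray:
    """Clamp |x| <= 1 within CLAMP_TOL, else raise UnreachablePostureError."""
    over = np.abs(x) - 1.0
    if np.any(over > CLAMP_TOL):
        raise UnreachablePostureError(
            f"|{what}| exceeds 1 by more than {CLAMP_TOL:g} "
            f"(max excess {float(np.max(over)):.3g})"
        )
    return np.clip(x, -1.0, 1.0)


def inverse_kinematics(
    markers: MarkerTrajectory, geom: ArmGeometry | None = None
) -> JointAngleTrajectory:
    """Recover the four joint angles from marker positions.

    Markers are translated so the shoulder sits at the origin.  When
    ``geom`` is omitted, segment lengths are estimated from the markers
    themselves (median segment distances).

    Raises
    ------
    UnreachablePostureError
        If ``|sin(theta2)|`` or ``|cos(theta4)|`` exceeds 1 beyond the
        clamping tolerance (markers inconsistent with the segment lengths).
    SingularConfigurationError
        If ``sin(theta4)`` is (numerically) zero, where theta3 is undefined.
    """
    if geom is None:
        geom = estimate_geometry(markers)
    E = markers.elbow - markers.shoulder
    W = markers.wrist - markers.shoulder
    if not (np.all(np.isfinite(E)) and np.all(np.isfinite(W))):
        raise InvalidInputError("non-finite marker positions")
    l1, l2 = geom.l1, geom.l2

    xE, yE, zE = E
    xW = W[0]
    R2 = np.sum(W * W, axis=0)

    c4 = _clamped((l1**2 + l2**2 - R2) / (2 * l1 * l2), "cos(theta4)")
    theta4 = np.arccos(c4)
    s4 = np.sin(theta4)

    s2 = _clamped(-xE / l1, "sin(theta2)")
    theta2 = np.arcsin(s2)
    c2 = np.cos(theta2)

    theta1 = np.arctan2(yE, -zE)

    if np.any(np.abs(s4) < SINGULAR_TOL):
        raise SingularConfigurationError(
            "sin(theta4) ~ 0: theta3 is undefined at a straight or folded elbow"
        )
    s3 = _clamped(((xE - xW) / l2 + s2 * c4) / (c2 * s4), "sin(theta3)")
    theta3 = np.arcsin(s3)

    return JointAngleTrajectory(
        theta=np.stack([theta1, theta2, theta3, theta4]),
        rate=markers.rate,
        t_start=markers.t_start,
    )


def summed_squared_velocity(angles: JointAngleTrajectory) -> np.ndarray:
    """Sum over joints of the squared angular velocity, per time step.

    Velocities are central differences at the trajectory's rate (one-sided
    at the ends).  Units rad^2/s^2.  This scalar is the gating feature of
    the mixture-of-experts decoder: near zero during stationary postures,
    large during reaches.
    """
    if angles.n_samples < 2:
        raise InvalidInputError("need at least 2 samples to differentiate")
    dtheta = np.gradient(angles.theta, 1.0 / angles.rate, axis=1)
    return np.sum(dtheta**2, axis=0)


def resample_trajectory(
    series: np.ndarray, rate: float, target_rate: float
) -> np.ndarray:
    """Interpolate a uniformly sampled series onto a new rate.

    ``series`` is (..., T) sampled at ``rate`` Hz.  Output has
    ``floor(duration * target_rate) + 1`` samples with both endpoints
    preserved, where ``duration = (T - 1)/rate``.  Interpolation is a
    cubic spline (exact on straight lines; down/up round trips of slow
    kinematic signals through a 120 Hz grid stay below 1e-3 error, which
    plain linear interpolation cannot achieve); inputs shorter than four
    samples fall back to linear interpolation.
    """
    if rate <= 0 or target_rate <= 0:
        raise InvalidInputError("rates must be positive")
    series = np.asarray(series, dtype=float)
    T = series.shape[-1]
    if T < 1:
        raise InvalidInputError("empty series")
    if rate == target_rate:
        return series.copy()
    duration = (T - 1) / rate
    n_out = int(np.floor(duration * target_rate)) + 1
    t_out = np.arange(n_out) / target_rate
    t_in = np.arange(T) / rate
    if T >= 4:
        from scipy.interpolate import CubicSpline

        out = CubicSpline(t_in, series, axis=-1)(np.clip(t_out, 0, t_in[-1]))
    else:
        flat = series.reshape(-1, T)
        out = np.stack([np.interp(t_out, t_in, row) for row in flat])
        out = out.reshape(series.shape[:-1] + (n_out,))
    return out


# ---------------------------------------------------------------------------
# CSV interfaces


def write_markers_csv(markers: MarkerTrajectory, path) -> None:
    """Write markers as tidy CSV: time_s, marker, x_m, y_m, z_m."""
    t = markers.t_start + np.arange(markers.n_samples) / markers.rate
    frames = []
    for name in ("shoulder", "elbow", "wrist"):
        arr = getattr(markers, name)
        frames.append(
            pd.DataFrame(
                {"time_s": t, "marker": name, "x_m": arr[0], "y_m": arr[1], "z_m": arr[2]}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_markers_csv(path) -> MarkerTrajectory:
    df = pd.read_csv(path)
    required = {"time_s", "marker", "x_m", "y_m", "z_m"}
    if not required.issubset(df.columns):
        raise InvalidInputError(f"marker CSV must have columns {sorted(required)}")
    parts = {}
    t = None
    for name in ("shoulder", "elbow", "wrist"):
        sub = df[df["marker"] == name].sort_values("time_s")
        if sub.empty:
            raise InvalidInputError(f"marker CSV missing '{name}' rows")
        parts[name] = sub[["x_m", "y_m", "z_m"]].to_numpy().T
        t = sub["time_s"].to_numpy()
    dt = np.diff(t)
    if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise InvalidInputError("non-uniform marker timeline")
    rate = 1.0 / dt[0] if len(dt) else 120.0
    return MarkerTrajectory(rate=rate, t_start=float(t[0]), **parts)


def write_angles_csv(angles: JointAngleTrajectory, path) -> None:
    """Write joint angles as CSV: time_s, theta1..theta4 (radians)."""
    df = pd.DataFrame(
        {"time_s": angles.times}
        | {f"theta{k + 1}": angles.theta[k] for k in range(4)}
    )
    df.to_csv(path, index=False)


def read_angles_csv(path) -> JointAngleTrajectory:
    df = pd.read_csv(path)
    cols = [f"theta{k + 1}" for k in range(4)]
    if "time_s" not in df.columns or any(c not in df.columns for c in cols):
        raise InvalidInputError("angle CSV must have columns time_s, theta1..theta4")
    t = df["time_s"].to_numpy()
    dt = np.diff(t)
    if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise InvalidInputError("non-uniform angle timeline")
    rate = 1.0 / dt[0] if len(dt) else 1000.0
    return JointAngleTrajectory(
        theta=df[cols].to_numpy().T, rate=rate, t_start=float(t[0])
    )
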