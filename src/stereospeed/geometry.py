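"""Perspective kinematics of motion in depth.

The scene is the classic stereoscope setup: an observer views a screen at
distance ``D`` along the midline (the z axis); a pair of vertical lines sits
at fixed lateral world positions ``±x_w`` and approaches the observer at
constant world speed, so the depth coordinate ``z_w`` shrinks linearly in
time.  The visual direction of a line is

    theta = arctan(x_w / z_w)

and the screen position that renders that direction is ``x_s = D tan(theta)
= D x_w / z_w``.  Because theta is an arctangent of a linearly shrinking
denominator, constant world speed maps to *accelerating* retinal speed: the
instantaneous angular speed is

    dtheta/dt = x_w v / (x_w^2 + z_w^2)        (v = -dz/dt > 0, approach)

which grows without bound as ``z_w`` falls.  Constant-retinal-speed stimuli
(the ``Retina`` family) instead hold dtheta/dt fixed, which corresponds to a
decelerating object in the world.

All angles are stored in arcmin and angular speeds in arcmin/s; the
radian→arcmin constant is applied once at this module's boundary.
Coordinates: x lateral (rightward positive, in cm), z distance from the
cyclopean eye along the midline (cm); the screen lives at ``z = D``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "ARCMIN_PER_RAD",
    "ViewingGeometry",
    "SpeedChangeInterval",
    "WorldTrajectory",
    "RetinalTrace",
    "world_to_angle",
    "angle_to_screen",
    "world_to_screen",
    "angular_speed",
    "build_world_interval",
    "trace_retinal",
    "build_retina_interval",
    "derive_retina_speed",
    "render_stereo",
    "recover_geometry",
]

#: arcminutes per radian (60 * 180 / pi)
ARCMIN_PER_RAD = 60.0 * 180.0 / math.pi

#: channel order used in every per-channel array
CHANNELS = ("left", "right", "cyclopean")


@dataclass(frozen=True)
class ViewingGeometry:
    """Fixed scene parameters of the stereoscope setup.

    Parameters
    ----------
    viewing_distance_cm:
        Distance ``D`` from the cyclopean eye to the screen, cm.
    ipd_cm:
        Interpupillary distance; the eyes sit at lateral ``±ipd/2``.
    refresh_hz:
        Display refresh rate; frames are sampled at ``i / refresh_hz``.
    half_separation_cm:
        Lateral world position ``x_w`` of each line (one at ``+x``, one at
        ``-x``).  The default 3.0 cm is the value recovered by inverting the
        Fast-standard retinal-speed endpoints (see :func:`recover_geometry`).
    """

    viewing_distance_cm: float = 97.0
    ipd_cm: float = 6.5
    refresh_hz: float = 85.0
    half_separation_cm: float = 3.0

    def __post_init__(self) -> None:
        if self.viewing_distance_cm <= 0:
            raise ValueError("viewing_distance_cm must be positive")
        if self.refresh_hz <= 0:
            raise ValueError("refresh_hz must be positive")
        if self.half_separation_cm <= 0:
            raise ValueError("half_separation_cm must be positive")
        if self.ipd_cm < 0:
            raise ValueError("ipd_cm must be non-negative")

    @property
    def eye_offsets(self) -> tuple[float, float, float]:
        """Lateral eye positions (cm) for the (left, right, cyclopean) channels."""
        return (-self.ipd_cm / 2.0, +self.ipd_cm / 2.0, 0.0)


@dataclass(frozen=True)
class SpeedChangeInterval:
    """One 2IFC interval: world speeds before/after an instantaneous change.

    A *standard* interval has ``v_before == v_after`` (no change); a
    *variable* interval steps from ``v_before`` to ``v_after`` at
    ``change_time_s`` after motion onset.  The static lead is the period the
    first frame is shown before motion starts.
    """

    v_before: float
    v_after: float
    change_time_s: float = 0.5
    duration_s: float = 1.0
    static_lead_s: float = 0.25
    direction: str = "approaching"

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not 0 < self.change_time_s < self.duration_s:
            raise ValueError("change_time_s must lie strictly inside the interval")
        if self.static_lead_s < 0:
            raise ValueError("static_lead_s must be non-negative")
        if self.direction not in ("approaching", "receding", "lateral"):
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def total_distance(self) -> float:
        """World distance travelled over the interval (cm)."""
        return (
            self.v_before * self.change_time_s
            + self.v_after * (self.duration_s - self.change_time_s)
        )

    @property
    def is_standard(self) -> bool:
        return self.v_before == self.v_after


def _check_positive_depth(z_w) -> None:
    if np.any(np.asarray(z_w) <= 0):
        raise ValueError("z_w must be positive (object in front of the eye)")


def world_to_angle(x_w, z_w):
    """Visual angle (radians) of world point ``(x_w, z_w)`` from the origin eye.

    ``theta = arctan(x_w / z_w)``; antisymmetric in ``x_w``.
    """
    _check_positive_depth(z_w)
    return np.arctan(np.asarray(x_w, dtype=float) / np.asarray(z_w, dtype=float))


def angle_to_screen(angle, viewing_distance_cm):
    """Screen position (cm) rendering visual angle ``angle``: ``x_s = D tan(theta)``."""
    angle = np.asarray(angle, dtype=float)
    if np.any(np.abs(angle) >= math.pi / 2):
        raise ValueError("angle must lie strictly within (-pi/2, pi/2)")
    return viewing_distance_cm * np.tan(angle)


def world_to_screen(x_w, z_w, viewing_distance_cm):
    """Screen position (cm) of world point ``(x_w, z_w)``: ``x_s = D x_w / z_w``.

    Algebraically identical to composing :func:`world_to_angle` with
    :func:`angle_to_screen`.
    """
    _check_positive_depth(z_w)
    return viewing_distance_cm * np.asarray(x_w, dtype=float) / np.asarray(z_w, dtype=float)


def angular_speed(x_w, z_w, v):
    """Instantaneous retinal angular speed (arcmin/s) of an approaching point.

    Exact time derivative of the visual angle for ``dz/dt = -v``:
    ``dtheta/dt = x_w v / (x_w^2 + z_w^2)``, converted to arcmin/s.
    """
    _check_positive_depth(z_w)
    x_w = np.asarray(x_w, dtype=float)
    z_w = np.asarray(z_w, dtype=float)
    return x_w * np.asarray(v, dtype=float) / (x_w**2 + z_w**2) * ARCMIN_PER_RAD


@dataclass(frozen=True)
class WorldTrajectory:
    """Piecewise-linear approach along the midline.

    ``z(t) = z0 - v_before * min(t, t_c) - v_after * max(t - t_c, 0)``;
    the two lines keep fixed lateral world coordinates ``±x_w``.
    """

    z0: float
    v_before: float
    v_after: float
    change_time_s: float
    duration_s: float
    x_w: float

    @property
    def total_distance(self) -> float:
        return (
            self.v_before * self.change_time_s
            + self.v_after * (self.duration_s - self.change_time_s)
        )

    @property
    def z1(self) -> float:
        return self.z0 - self.total_distance

    @property
    def z_change(self) -> float:
        """Depth at the moment of the speed change."""
        return self.z0 - self.v_before * self.change_time_s

    @property
    def x_w_left_line(self) -> float:
        return -self.x_w

    @property
    def x_w_right_line(self) -> float:
        return +self.x_w

    def z_of_t(self, t):
        """Depth (cm) at time(s) ``t`` seconds from motion onset."""
        t = np.asarray(t, dtype=float)
        z = (
            self.z0
            - self.v_before * np.minimum(t, self.change_time_s)
            - self.v_after * np.maximum(t - self.change_time_s, 0.0)
        )
        return z

    def v_of_t(self, t):
        """World speed (cm/s) at time(s) ``t`` (right-continuous at the change)."""
        t = np.asarray(t, dtype=float)
        return np.where(t < self.change_time_s, self.v_before, self.v_after)


def build_world_interval(
    interval: SpeedChangeInterval, geom: ViewingGeometry
) -> WorldTrajectory:
    """Place a constant-world-speed interval in depth.

    The trajectory is symmetric about the screen plane: it starts at
    ``D + total_distance/2`` and ends at ``D - total_distance/2``, so the
    Fast ladder (40 cm/s over 1 s) runs 117→77 cm and the Slow ladder
    (20 cm/s) runs 107→87 cm for ``D = 97``.
    """
    if interval.direction != "approaching":
        raise ValueError("only approaching world trajectories are supported")
    if interval.v_before <= 0 or interval.v_after <= 0:
        raise ValueError("world speeds must be positive")
    total = interval.total_distance
    if total >= 2 * geom.viewing_distance_cm:
        raise ValueError(
            "total distance ≥ 2·viewing distance: object would pass the eye"
        )
    z0 = geom.viewing_distance_cm + total / 2.0
    return WorldTrajectory(
        z0=z0,
        v_before=interval.v_before,
        v_after=interval.v_after,
        change_time_s=interval.change_time_s,
        duration_s=interval.duration_s,
        x_w=geom.half_separation_cm,
    )


@dataclass(frozen=True)
class RetinalTrace:
    """Per-frame retinal angles/speeds of the two lines in three channels.

    ``angle_arcmin`` and ``speed_arcmin_per_s`` have shape
    ``(n_frames, 2 lines, 3 channels)`` with lines ordered (left, right) and
    channels ordered ``(left eye, right eye, cyclopean)``.  ``a, b, c, d``
    are the cyclopean instantaneous speeds of the right line at interval
    onset, just before the change, just after the change, and at interval
    end — the four symbols of the speed-time profile.
    """

    frame_times_s: np.ndarray
    angle_arcmin: np.ndarray
    speed_arcmin_per_s: np.ndarray
    a: float
    b: float
    c: float
    d: float
    change_time_s: float
    duration_s: float
    channels: tuple[str, ...] = field(default=CHANNELS)

    @property
    def cyclopean_angle(self) -> np.ndarray:
        """Cyclopean angles (arcmin) of the two lines, shape (n_frames, 2)."""
        return self.angle_arcmin[:, :, 2]

    @property
    def cyclopean_speed(self) -> np.ndarray:
        return self.speed_arcmin_per_s[:, :, 2]


def _frame_times(duration_s: float, refresh_hz: float) -> np.ndarray:
    n = int(math.floor(duration_s * refresh_hz))
    return np.arange(n + 1, dtype=float) / refresh_hz


def trace_retinal(traj: WorldTrajectory, geom: ViewingGeometry) -> RetinalTrace:
    """Sample the retinal view of a world trajectory at frame times.

    Positions are defined in continuous time and sampled at frame onsets
    ``i / refresh_hz``; speeds are the exact instantaneous derivative of the
    visual angle, not frame differences.  The eye channels place the eye at
    lateral ``±ipd/2`` (angle ``arctan((x_line - e)/z)``); the cyclopean
    channel uses ``e = 0``.
    """
    t = _frame_times(traj.duration_s, geom.refresh_hz)
    z = traj.z_of_t(t)  # (n,)
    v = traj.v_of_t(t)
    lines = np.array([traj.x_w_left_line, traj.x_w_right_line])  # (2,)
    eyes = np.array(geom.eye_offsets)  # (3,)
    # broadcast to (n, 2, 2->3)
    rel = lines[None, :, None] - eyes[None, None, :]  # (1, 2, 3)
    zz = z[:, None, None]
    angle = np.arctan(rel / zz) * ARCMIN_PER_RAD
    speed = rel * v[:, None, None] / (rel**2 + zz**2) * ARCMIN_PER_RAD

    x = traj.x_w_right_line
    a = float(angular_speed(x, traj.z0, traj.v_before))
    b = float(angular_speed(x, traj.z_change, traj.v_before))
    c = float(angular_speed(x, traj.z_change, traj.v_after))
    d = float(angular_speed(x, traj.z1, traj.v_after))
    return RetinalTrace(
        frame_times_s=t,
        angle_arcmin=angle,
        speed_arcmin_per_s=speed,
        a=a,
        b=b,
        c=c,
        d=d,
        change_time_s=traj.change_time_s,
        duration_s=traj.duration_s,
    )


def build_retina_interval(
    speed_before: float,
    speed_after: float,
    duration_s: float = 1.0,
    change_time_s: float = 0.5,
    geom: ViewingGeometry | None = None,
    start_angle_arcmin: float | None = None,
    control: bool = False,
) -> RetinalTrace:
    """Build a constant-retinal-speed interval (piecewise constant if changing).

    ``Retina`` family (``control=False``): the two lines separate
    symmetrically — the right line's angle grows at ``speed`` while the left
    line's shrinks — giving a linearly growing separation (the size-change
    cue) and, per eye, opposite-signed lateral motion.  ``Retina Control``
    (``control=True``): both lines translate together at ``speed`` with the
    separation frozen, removing every motion-in-depth cue.

    The starting angle defaults to the cyclopean angle of a line at the Fast
    trajectory start (``arctan(x_w / (D + 20))``) and only shifts the traces;
    speeds and displacements are unaffected.
    """
    if speed_before <= 0 or speed_after <= 0:
        raise ValueError("retinal speeds must be positive")
    if not 0 < change_time_s < duration_s:
        raise ValueError("change_time_s must lie strictly inside the interval")
    geom = geom or ViewingGeometry()
    if start_angle_arcmin is None:
        start_angle_arcmin = float(
            world_to_angle(geom.half_separation_cm, geom.viewing_distance_cm + 20.0)
            * ARCMIN_PER_RAD
        )
    t = _frame_times(duration_s, geom.refresh_hz)
    disp = speed_before * np.minimum(t, change_time_s) + speed_after * np.maximum(
        t - change_time_s, 0.0
    )  # arcmin
    spd = np.where(t < change_time_s, speed_before, speed_after)
    n = t.size
    angle = np.empty((n, 2, 3))
    speed = np.empty((n, 2, 3))
    if control:
        # common translation, fixed separation
        angle[:, 0, :] = (-start_angle_arcmin + disp)[:, None]
        angle[:, 1, :] = (+start_angle_arcmin + disp)[:, None]
        speed[:, 0, :] = spd[:, None]
        speed[:, 1, :] = spd[:, None]
    else:
        # symmetric separation: opposite-signed motion of the two lines
        angle[:, 0, :] = (-start_angle_arcmin - disp)[:, None]
        angle[:, 1, :] = (+start_angle_arcmin + disp)[:, None]
        speed[:, 0, :] = -spd[:, None]
        speed[:, 1, :] = +spd[:, None]
    return RetinalTrace(
        frame_times_s=t,
        angle_arcmin=angle,
        speed_arcmin_per_s=speed,
        a=float(speed_before),
        b=float(speed_before),
        c=float(speed_after),
        d=float(speed_after),
        change_time_s=change_time_s,
        duration_s=duration_s,
    )


def derive_retina_speed(trace: RetinalTrace) -> float:
    """Time-averaged cyclopean angular speed (arcmin/s) of the right line.

    Total cyclopean angular displacement divided by duration — the natural
    reading of matching the ``Retina`` conditions to "the mean of the speeds
    presented" in the constant-world-speed conditions.  Note the stimulus
    tables' printed constants (47.6 and 22.3 arcmin/s for the Fast/Slow
    standards) are slightly above this time average (45.75 / 22.13); the
    printed values are available as configuration overrides.
    """
    ang = trace.angle_arcmin[:, 1, 2]
    t = trace.frame_times_s
    return float((ang[-1] - ang[0]) / (t[-1] - t[0]))


def render_stereo(
    traj: WorldTrajectory, geom: ViewingGeometry, world_control: bool = False
) -> np.ndarray:
    """Per-eye, per-frame screen positions (cm), shape (n_frames, 2 lines, 2 eyes).

    For an eye at lateral offset ``e``, a line at ``(x_w, z_w)`` is drawn at
    ``x_s = e + D (x_w - e) / z_w`` so that the drawn point lies on the
    eye–object ray where it pierces the screen.  With ``world_control=True``
    the left-eye half image is duplicated into both eyes (looming without
    binocular cues).
    """
    t = _frame_times(traj.duration_s, geom.refresh_hz)
    z = traj.z_of_t(t)
    _check_positive_depth(z)
    lines = np.array([traj.x_w_left_line, traj.x_w_right_line])
    eyes = np.array(geom.eye_offsets[:2])  # (left, right)
    rel = lines[None, :, None] - eyes[None, None, :]
    xs = eyes[None, None, :] + geom.viewing_distance_cm * rel / z[:, None, None]
    if world_control:
        xs = np.repeat(xs[:, :, :1], 2, axis=2)
    return xs


def recover_geometry(
    a: float, d: float, v: float, duration_s: float
) -> tuple[float, float]:
    """Invert interval endpoint speeds to the start distance and line offset.

    Given the onset and end cyclopean angular speeds ``a < d`` (arcmin/s) of
    a constant-world-speed approach at ``v`` cm/s lasting ``duration_s``,
    solve

        a = x v K / (x^2 + z0^2),   d = x v K / (x^2 + z1^2),
        z1 = z0 - v * duration_s,   K = arcmin per radian

    for ``(z0, x)``.  For small ``x`` the speed ratio reduces to
    ``(z0/z1)^2``, which yields a closed-form first estimate that is then
    refined by a Newton root solve on the full system.
    """
    if not d > a > 0:
        raise ValueError("require d > a > 0 (accelerating approach)")
    if v <= 0 or duration_s <= 0:
        raise ValueError("v and duration_s must be positive")
    travel = v * duration_s
    r = math.sqrt(d / a)
    z1_est = travel / (r - 1.0)
    z0_est = r * z1_est
    if z1_est <= 0:
        raise ValueError("inconsistent inputs: no positive start distance")
    # x from the onset-speed quadratic  a x^2 - (vK) x + a z0^2 = 0
    vk = v * ARCMIN_PER_RAD
    disc = vk**2 - 4.0 * a**2 * z0_est**2
    if disc <= 0:
        raise ValueError("inconsistent inputs: onset speed too large for geometry")
    x_est = (vk - math.sqrt(disc)) / (2.0 * a)  # near-axis root

    def residual(p):
        z0, x = p
        z1 = z0 - travel
        return [
            x * vk / (x**2 + z0**2) - a,
            x * vk / (x**2 + z1**2) - d,
        ]

    sol = optimize.root(residual, x0=[z0_est, x_est])
    z0, x = sol.x
    if not sol.success or z0 - travel <= 0 or x <= 0:
        raise ValueError("geometry recovery failed: no positive root")
    return float(z0), float(x)
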