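"""Planar geometry helpers shared by the generator and the preprocessor.

Ground-plane convention: 2-D (x, y) in metres, right-handed, angles in
radians, counter-clockwise positive.  The vertical axis is stored separately
in tracking data and never enters the model.
"""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def ccw_angle(u, v) -> float:
    """Counter-clockwise angle from direction ``u`` to direction ``v``, in [0, 2*pi)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    ang = np.arctan2(u[0] * v[1] - u[1] * v[0], u[0] * v[0] + u[1] * v[1])
    return float(ang % TWO_PI)


def rotate(vec, angle):
    """Rotate a 2-D vector counter-clockwise by ``angle``."""
    c, s = np.cos(angle), np.sin(angle)
    vec = np.asarray(vec, dtype=float)
    return np.array([c * vec[0] - s * vec[1], s * vec[0] + c * vec[1]])


def turn_sign(c1, c2, c3) -> float:
    """+1 for a left (counter-clockwise) outbound turn, -1 for a right turn."""
    a = np.asarray(c2, float) - np.asarray(c1, float)
    b = np.asarray(c3, float) - np.asarray(c2, float)
    cross = a[0] * b[1] - a[1] * b[0]
    return 1.0 if cross >= 0 else -1.0


def triangle_geometry(c1, c2, c3):
    """Leg lengths and unsigned turn magnitude of an outbound path.

    Returns ``(l1, l2, theta2, sign)`` where ``theta2`` in [0, pi] is the
    magnitude of the heading change at the second cone and ``sign`` is +1 for
    a left turn, -1 for a right turn.
    """
    c1 = np.asarray(c1, float)
    c2 = np.asarray(c2, float)
    c3 = np.asarray(c3, float)
    leg1 = c2 - c1
    leg2 = c3 - c2
    l1 = float(np.hypot(*leg1))
    l2 = float(np.hypot(*leg2))
    if l1 < 1e-9 or l2 < 1e-9:
        raise ValueError("degenerate geometry: coincident cones")
    sign = turn_sign(c1, c2, c3)
    ang = ccw_angle(leg1, leg2)
    theta2 = ang if sign > 0 else TWO_PI - ang
    if theta2 > np.pi:  # numerical guard at exactly pi
        theta2 = TWO_PI - theta2
    return l1, l2, theta2, sign


def egocentric_turn(c2, c3, endpoint, sign) -> float:
    """Turn from the final outbound heading to the response direction.

    Measured in the left-turn canonical frame: for right-turn (mirrored)
    trials the sense of rotation is flipped, so the result is always the
    counter-clockwise angle after canonicalization, wrapped to [0, 2*pi).
    """
    c2 = np.asarray(c2, float)
    c3 = np.asarray(c3, float)
    endpoint = np.asarray(endpoint, float)
    heading = c3 - c2
    resp = endpoint - c3
    if np.hypot(*resp) < 1e-12:
        raise ValueError("endpoint coincident with the third cone")
    ang = ccw_angle(heading, resp)
    if sign < 0:
        ang = (TWO_PI - ang) % TWO_PI
    return ang


def ray_exit_distance(origin, direction, side) -> float:
    """Distance from ``origin`` along unit ``direction`` to the arena boundary.

    The arena is the axis-aligned square [0, side] x [0, side]; returns +inf
    if the ray never leaves (cannot happen for a unit direction).
    """
    origin = np.asarray(origin, float)
    direction = np.asarray(direction, float)
    t_exit = np.inf
    for dim in range(2):
        d = direction[dim]
        if abs(d) < 1e-12:
            continue
        for bound in (0.0, side):
            t = (bound - origin[dim]) / d
            if t > 0:
                t_exit = min(t_exit, t)
    return float(t_exit)
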