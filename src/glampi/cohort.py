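"""Synthetic triangle-completion cohorts.

Generates raw-format datasets with the statistical structure the analysis
assumes: pseudo-random triangles inside a square tracking arena, constant
per-trial outbound walking speed with across-trial variability, inbound
responses produced by the generative linear-angular model with group-level
parameter presets, and out-of-bound truncation of the inbound path at the
arena boundary (plus the 0.3 m overshoot at which the in-task warning stops
the participant).

Every run is reproducible from a single seed: the cohort seed is expanded
into independent per-participant streams with ``numpy.random.SeedSequence``
spawning, so regenerating any one participant yields identical data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from ._geometry import egocentric_turn, ray_exit_distance, rotate, triangle_geometry
from .model import (
    GlampiParams,
    PARAM_NAMES,
    calculate_inbound,
    encode_angle,
    encode_distances,
    produce_inbound,
)

__all__ = [
    "CONDITIONS",
    "GROUP_PRESETS",
    "TriangleLayout",
    "CohortSpec",
    "generate_triangle",
    "simulate_outbound",
    "simulate_inbound",
    "generate_cohort",
    "save_cohort",
]

CONDITIONS = ("no_change", "reduced_flow", "reduced_cues")

#: Validity bounds for per-participant parameter draws (truncation limits).
PARAM_DRAW_BOUNDS = {
    "k": (1e-3, 3.0),
    "g2": (1e-3, 3.0),
    "beta": (-0.5, 1.0),
    "g3": (-0.5, 2.0),
    "m3": (-0.5, 2.0),
    "sigma": (1e-3, 2.0),
    "nu": (1e-3, np.pi),
}

#: Common between-participant spread of the seven parameters.
_DEFAULT_SDS = GlampiParams(k=0.15, g2=0.15, beta=0.08, g3=0.15, m3=0.12, sigma=0.08, nu=0.10)

#: Group-level presets.  Parameter means encode the qualitative group profile:
#: elderly show a speed gain k>1, a small angular encoding gain and angular
#: regression to the mean; the amyloid-positive MCI profile is dominated by a
#: large angular encoding gain g2 and increased angular noise nu, which under
#: the model jointly produce under-walking and over-turning.  Arena sides and
#: trial counts follow the study setup (young tested in a 3.5 m arena with 12
#: trials per condition, elderly in 4.5 m, MCI groups in 4.0 m, 9 per
#: condition).
GROUP_PRESETS = {
    "young": dict(
        arena_side=3.5,
        trials_per_condition=12,
        speed_mean=0.65,
        speed_sd=0.10,
        param_means=GlampiParams(k=1.00, g2=1.00, beta=0.01, g3=0.85, m3=1.00, sigma=0.18, nu=0.20),
    ),
    "elderly": dict(
        arena_side=4.5,
        trials_per_condition=9,
        speed_mean=0.75,
        speed_sd=0.10,
        param_means=GlampiParams(k=1.25, g2=1.05, beta=0.10, g3=0.80, m3=1.00, sigma=0.30, nu=0.40),
    ),
    "mci_unknown": dict(
        arena_side=4.0,
        trials_per_condition=9,
        speed_mean=0.80,
        speed_sd=0.10,
        param_means=GlampiParams(k=1.20, g2=1.25, beta=0.12, g3=0.80, m3=0.95, sigma=0.40, nu=0.55),
    ),
    "mci_neg": dict(
        arena_side=4.0,
        trials_per_condition=9,
        speed_mean=0.80,
        speed_sd=0.10,
        param_means=GlampiParams(k=1.20, g2=1.15, beta=0.10, g3=0.80, m3=0.95, sigma=0.38, nu=0.50),
    ),
    "mci_pos": dict(
        arena_side=4.0,
        trials_per_condition=9,
        speed_mean=0.80,
        speed_sd=0.10,
        param_means=GlampiParams(k=1.20, g2=1.45, beta=0.12, g3=0.75, m3=0.90, sigma=0.45, nu=0.75),
    ),
}


@dataclass(frozen=True)
class TriangleLayout:
    """Ground-plane cone positions of one trial, metres."""

    cone1: np.ndarray
    cone2: np.ndarray
    cone3: np.ndarray

    def geometry(self):
        """(l1, l2, theta2, turn_sign) of the outbound path."""
        return triangle_geometry(self.cone1, self.cone2, self.cone3)

    def correct_return(self):
        """Correct inbound distance and egocentric turn (to cone 1)."""
        *_, sign = self.geometry()
        dist = float(np.hypot(*(self.cone1 - self.cone3)))
        ang = egocentric_turn(self.cone2, self.cone3, self.cone1, sign)
        return dist, ang


@dataclass
class CohortSpec:
    """Definition of one synthetic group."""

    group_label: str
    n_participants: int
    trials_per_condition: int = 9
    arena_side: float = 4.0
    param_means: GlampiParams = field(default_factory=GlampiParams)
    param_sds: GlampiParams = field(default_factory=lambda: _DEFAULT_SDS)
    speed_mean: float = 0.8
    speed_sd: float = 0.1
    sample_rate: float = 10.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.group_label not in GROUP_PRESETS:
            raise ValueError(f"unknown group label {self.group_label!r}")
        if self.arena_side <= 0:
            raise ValueError("arena_side must be positive")
        if self.trials_per_condition < 7:
            raise ValueError("trials_per_condition must be >= 7")
        if self.speed_mean <= 0:
            raise ValueError("speed_mean must be positive")
        if self.param_means.sigma < 0 or self.param_means.nu < 0:
            raise ValueError("noise SD means must be >= 0")

    @classmethod
    def from_preset(cls, group_label: str, n_participants: int, rng_seed: int = 0, **overrides) -> "CohortSpec":
        preset = GROUP_PRESETS[group_label]
        kwargs = dict(preset)
        kwargs.update(overrides)
        return cls(group_label=group_label, n_participants=n_participants, rng_seed=rng_seed, **kwargs)


def generate_triangle(arena_side, rng, prev_end=None, max_attempts=1000) -> TriangleLayout:
    """Pseudo-randomly place the three cones inside the square arena.

    Cone 1 goes near the arena corner farthest from ``prev_end`` (a random
    corner on the first trial); cones 2 and 3 go near the two sides opposite
    that corner, in random order.  "Near" means within 25% of the arena side.
    Rejection sampling enforces: cones 2-3 at least 1 m apart, legs at least
    0.5 m, a non-degenerate turn, and an acute return-vertex angle (the
    regime in which the model's trigonometric branch is exact).

    Raises ``RuntimeError`` after ``max_attempts`` rejections.
    """
    if arena_side < 2.0:
        raise ValueError("arena_side must be at least 2 m")
    s = float(arena_side)
    band = 0.25 * s
    corners = np.array([[0, 0], [0, s], [s, 0], [s, s]], dtype=float)
    if prev_end is None:
        corner = corners[rng.integers(4)]
    else:
        prev_end = np.asarray(prev_end, dtype=float)
        corner = corners[np.argmax(np.hypot(*(corners - prev_end).T))]
    # The two sides opposite the chosen corner, each as (fixed_dim, fixed_val).
    opp = [(0, s - corner[0]), (1, s - corner[1])]

    def near_corner():
        # 10-30% of the side away from each of the corner's walls, keeping a
        # clearance margin so the return target is not flush with the boundary
        offsets = rng.uniform(0.1 * s, 0.3 * s, size=2)
        return np.abs(corner - offsets)

    def near_side(dim, val):
        p = np.empty(2)
        p[dim] = rng.uniform(min(val, abs(val - band)), max(val, abs(val - band)))
        p[1 - dim] = rng.uniform(0, s)
        return p

    for _ in range(max_attempts):
        c1 = near_corner()
        sides = opp if rng.random() < 0.5 else opp[::-1]
        c2 = near_side(*sides[0])
        c3 = near_side(*sides[1])
        if np.hypot(*(c3 - c2)) < 1.0:
            continue
        try:
            l1, l2, theta2, _ = triangle_geometry(c1, c2, c3)
        except ValueError:
            continue
        if l1 < 0.5 or l2 < 0.5:
            continue
        if not 0.15 <= theta2 <= np.pi - 0.15:
            continue
        if l2 + l1 * np.cos(theta2) <= 0.05:  # keep the return vertex acute
            continue
        return TriangleLayout(c1, c2, c3)
    raise RuntimeError("triangle generation failed: arena/constraint combination too restrictive")


def _heading_quaternions(directions, pitch_deg):
    """Quaternions facing along 2-D ``directions``, tilted down by ``pitch_deg``.

    Reference pose: forward +x, up +z.  Yaw about the world z axis, then
    pitch about the body y axis (positive = looking down).
    """
    yaw = np.arctan2(directions[:, 1], directions[:, 0])
    pitch = np.full_like(yaw, np.deg2rad(pitch_deg))
    rot = Rotation.from_euler("ZY", np.column_stack([yaw, pitch]))
    q = rot.as_quat()  # x, y, z, w
    return np.column_stack([q[:, 3], q[:, 0], q[:, 1], q[:, 2]])


def simulate_outbound(layout: TriangleLayout, speed, sample_rate, rng, pitch_deg=10.0, jitter_sd=0.002, head_height=1.7):
    """Tracking samples of a constant-speed outbound walk along the two legs.

    Returns ``(samples, T1, T2)``: a DataFrame of 10 Hz-style samples
    (t, x, y, z, qw, qx, qy, qz) and the times at which cones 2 and 3 are
    reached (``T1 = l1/speed``, ``T1 + T2``...).  Positions get a small
    Gaussian jitter emulating tracker noise; orientations face the walking
    direction with a configurable downward head pitch.
    """
    if speed <= 0:
        raise ValueError("speed must be positive")
    l1, l2, _, _ = layout.geometry()
    T1, T2 = l1 / speed, l2 / speed
    dt = 1.0 / sample_rate
    t = np.arange(0.0, T1 + T2 + 0.5 * dt, dt)
    d1 = (layout.cone2 - layout.cone1) / l1
    d2 = (layout.cone3 - layout.cone2) / l2
    on_leg1 = t <= T1
    pos = np.where(
        on_leg1[:, None],
        layout.cone1 + speed * t[:, None] * d1,
        layout.cone2 + speed * np.clip(t - T1, 0, None)[:, None] * d2,
    )
    pos = pos + rng.normal(0.0, jitter_sd, size=pos.shape)
    dirs = np.where(on_leg1[:, None], d1, d2)
    quat = _heading_quaternions(dirs, pitch_deg)
    samples = pd.DataFrame(
        {
            "t": t,
            "x": pos[:, 0],
            "y": pos[:, 1],
            "z": head_height,
            "qw": quat[:, 0],
            "qx": quat[:, 1],
            "qy": quat[:, 2],
            "qz": quat[:, 3],
        }
    )
    return samples, T1, T2


def simulate_inbound(layout: TriangleLayout, params: GlampiParams, T1, T2, session_means, rng, arena_side):
    """Generate one inbound response from the model's generative process.

    Draws the produced turn and distance from Gaussians centred on the model
    prediction, converts them to a ground-plane endpoint from cone 3 (the
    turn is applied in the trial's own turn sense, i.e. mirrored trials turn
    clockwise), and truncates the path at the arena boundary plus the 0.3 m
    warning overshoot, marking the trial out-of-bound.

    Returns a dict with ``response``, ``oob``, ``oob_point``, ``theta3``
    (produced turn actually realised) and ``l3`` (intended distance drawn).
    """
    l1, l2, theta2, sign = layout.geometry()
    l1p, l2p = encode_distances(l1, l2, T1, T2, params.k, params.beta)
    th2p = encode_angle(theta2, params.g2)
    h, alpha = calculate_inbound(l1p, l2p, th2p)
    lbar, thbar = session_means
    l3p, th3p = produce_inbound(h, alpha, params.g3, params.m3, lbar, thbar)
    theta3 = th3p + (params.nu * rng.standard_normal() if params.nu > 0 else 0.0)
    l3 = l3p + (params.sigma * rng.standard_normal() if params.sigma > 0 else 0.0)
    l3 = max(l3, 0.01)

    heading = (layout.cone3 - layout.cone2) / l2
    direction = rotate(heading, sign * theta3)
    t_exit = ray_exit_distance(layout.cone3, direction, arena_side)
    if l3 > t_exit:
        stop = min(l3, t_exit + 0.3)
        point = layout.cone3 + stop * direction
        return dict(response=point, oob=True, oob_point=point, theta3=theta3, l3=l3)
    endpoint = layout.cone3 + l3 * direction
    return dict(response=endpoint, oob=False, oob_point=None, theta3=theta3, l3=l3)


def _draw_params(means: GlampiParams, sds: GlampiParams, rng) -> GlampiParams:
    """Truncated-normal per-participant parameter draw (zero SD = fixed)."""
    values = {}
    for name in PARAM_NAMES:
        mu = getattr(means, name)
        sd = getattr(sds, name)
        if sd == 0:
            values[name] = mu
            continue
        lo, hi = PARAM_DRAW_BOUNDS[name]
        for _ in range(1000):
            v = rng.normal(mu, sd)
            if lo <= v <= hi:
                values[name] = v
                break
        else:
            raise RuntimeError(f"parameter draw for {name} never fell inside {lo, hi}")
    return GlampiParams(**values)


def _lognormal_speed(mean, sd, rng):
    if sd == 0:
        return mean
    var = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - 0.5 * var
    return float(rng.lognormal(mu, np.sqrt(var)))


def generate_cohort(spec: CohortSpec, include_tracking: bool = True):
    """Generate a full raw-format cohort.

    Returns ``(trials, tracking, truth)``: the per-trial table, the tracking
    sample table (or ``None``), and the per-participant table of true
    generating parameters.  Fully reproducible from ``spec.rng_seed``.
    """
    root = np.random.SeedSequence(spec.rng_seed)
    trial_rows = []
    tracking_parts = []
    truth_rows = []
    for pidx, child in enumerate(root.spawn(spec.n_participants)):
        rng = np.random.default_rng(child)
        pid = f"{spec.group_label}_{pidx:03d}"
        params = _draw_params(spec.param_means, spec.param_sds, rng)
        truth_rows.append({"participant": pid, "group": spec.group_label, **{n: getattr(params, n) for n in PARAM_NAMES}})
        for cond in CONDITIONS:
            layouts, speeds = [], []
            prev_end = None
            for _ in range(spec.trials_per_condition):
                layout = generate_triangle(spec.arena_side, rng, prev_end=prev_end)
                layouts.append(layout)
                speeds.append(_lognormal_speed(spec.speed_mean, spec.speed_sd, rng))
                prev_end = layout.cone1  # responses terminate near the goal
            correct = [lay.correct_return() for lay in layouts]
            session_means = (
                float(np.mean([c[0] for c in correct])),
                float(np.mean([c[1] for c in correct])),
            )
            for tidx, (layout, speed) in enumerate(zip(layouts, speeds)):
                if include_tracking:
                    samples, T1, T2 = simulate_outbound(layout, speed, spec.sample_rate, rng)
                else:
                    l1, l2, _, _ = layout.geometry()
                    T1, T2 = l1 / speed, l2 / speed
                inb = simulate_inbound(layout, params, T1, T2, session_means, rng, spec.arena_side)
                t_c3 = T1 + T2
                inbound_dist = float(np.hypot(*(inb["response"] - layout.cone3)))
                t_end = t_c3 + 2.0 + inbound_dist / speed  # 2 s turn pause
                row = {
                    "participant": pid,
                    "group": spec.group_label,
                    "condition": cond,
                    "environment": tidx % 3 + 1,
                    "trial": tidx,
                    "c1x": layout.cone1[0],
                    "c1y": layout.cone1[1],
                    "c2x": layout.cone2[0],
                    "c2y": layout.cone2[1],
                    "c3x": layout.cone3[0],
                    "c3y": layout.cone3[1],
                    "t_start": 0.0,
                    "t_c2": T1,
                    "t_c3": t_c3,
                    "t_end": t_end,
                    "resp_x": inb["response"][0],
                    "resp_y": inb["response"][1],
                    "oob": inb["oob"],
                    "oob_x": inb["oob_point"][0] if inb["oob"] else np.nan,
                    "oob_y": inb["oob_point"][1] if inb["oob"] else np.nan,
                    "speed": speed,
                }
                trial_rows.append(row)
                if include_tracking:
                    inb_samples = _inbound_tracking(layout, inb["response"], speed, spec.sample_rate, t_c3 + 2.0, rng)
                    part = pd.concat([samples, inb_samples], ignore_index=True)
                    part.insert(0, "trial", tidx)
                    part.insert(0, "condition", cond)
                    part.insert(0, "participant", pid)
                    tracking_parts.append(part)
    trials = pd.DataFrame(trial_rows)
    tracking = pd.concat(tracking_parts, ignore_index=True) if include_tracking else None
    truth = pd.DataFrame(truth_rows)
    return trials, tracking, truth


def _inbound_tracking(layout, endpoint, speed, sample_rate, t_start, rng, jitter_sd=0.002, head_height=1.7):
    """Straight-line inbound tracking samples from cone 3 to the endpoint."""
    vec = np.asarray(endpoint, float) - layout.cone3
    dist = float(np.hypot(*vec))
    if dist < 1e-9:
        return pd.DataFrame(columns=["t", "x", "y", "z", "qw", "qx", "qy", "qz"])
    direction = vec / dist
    dt = 1.0 / sample_rate
    t = np.arange(0.0, dist / speed + 0.5 * dt, dt)
    pos = layout.cone3 + speed * t[:, None] * direction
    pos = pos + rng.normal(0.0, jitter_sd, size=pos.shape)
    quat = _heading_quaternions(np.tile(direction, (len(t), 1)), 10.0)
    return pd.DataFrame(
        {
            "t": t_start + t,
            "x": pos[:, 0],
            "y": pos[:, 1],
            "z": head_height,
            "qw": quat[:, 0],
            "qx": quat[:, 1],
            "qy": quat[:, 2],
            "qz": quat[:, 3],
        }
    )


def save_cohort(out_dir, trials, tracking=None, truth=None) -> None:
    """Write ``trials.csv``, ``tracking.csv`` and the true-parameter sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials.to_csv(out / "trials.csv", index=False)
    if tracking is not None:
        tracking.to_csv(out / "tracking.csv", index=False)
    if truth is not None:
        sidecar = {
            row["participant"]: {n: row[n] for n in PARAM_NAMES}
            for row in truth.to_dict("records")
        }
        (out / "params_true.json").write_text(json.dumps(sidecar, indent=2))
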