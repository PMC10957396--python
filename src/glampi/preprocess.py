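"""Raw-trial loading, geometric standardization, exclusions, and tracking-derived measures.

Standardization canonicalizes each trial: cone 1 to the origin, the first
outbound leg along +x, and right-turn trials mirrored so every outbound turn
is a left (counter-clockwise) turn.  All model inputs (l1, l2, theta2, T1,
T2, theta3, l3) are read off in that frame, which makes them invariant to
the arena's absolute coordinates.

Exclusion rules: trials whose inbound path terminates within 0.5 m of the
start of the inbound path are dropped (no clear movement intention); trials
whose inbound trajectory re-enters the neighbourhood of cone 2 are dropped
as instruction violations (a configurable proxy for retracing, applied when
inbound tracking is available); out-of-bound trials with no recorded
boundary-hit point are dropped as tracking faults; finally any
participant-condition cell left with fewer usable trials than the model has
parameters (7) is dropped entirely.  Out-of-bound trials are otherwise
retained: they contribute an angle and never a distance downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.spatial.transform import Rotation

from ._geometry import egocentric_turn, triangle_geometry

__all__ = [
    "RawTrial",
    "StandardizedTrial",
    "ExclusionReport",
    "standardize_trial",
    "produced_turn",
    "oob_angle",
    "standardize_dataset",
    "apply_exclusions",
    "reconstruct_speed",
    "head_pitch",
    "load_cohort",
]

N_MODEL_PARAMS = 7
SHORT_RESPONSE_M = 0.5
RETRACE_RADIUS_M = 0.3


@dataclass
class RawTrial:
    """One trial as recorded: cones, timestamps, response, out-of-bound info."""

    cone1: np.ndarray
    cone2: np.ndarray
    cone3: np.ndarray
    t_start: float
    t_c2: float
    t_c3: float
    response: Optional[np.ndarray] = None
    oob: bool = False
    oob_point: Optional[np.ndarray] = None

    @classmethod
    def from_row(cls, row) -> "RawTrial":
        def pt(xc, yc):
            x, y = row[xc], row[yc]
            if np.isnan(x) or np.isnan(y):
                return None
            return np.array([x, y], dtype=float)

        return cls(
            cone1=np.array([row["c1x"], row["c1y"]], dtype=float),
            cone2=np.array([row["c2x"], row["c2y"]], dtype=float),
            cone3=np.array([row["c3x"], row["c3y"]], dtype=float),
            t_start=float(row["t_start"]),
            t_c2=float(row["t_c2"]),
            t_c3=float(row["t_c3"]),
            response=pt("resp_x", "resp_y"),
            oob=bool(row["oob"]),
            oob_point=pt("oob_x", "oob_y") if bool(row["oob"]) else None,
        )

    def endpoint(self) -> Optional[np.ndarray]:
        """Inbound termination point: boundary hit for out-of-bound trials."""
        return self.oob_point if self.oob else self.response


@dataclass
class StandardizedTrial:
    """Canonicalized trial geometry (left-turn frame, cone 1 at origin)."""

    l1: float
    l2: float
    theta2: float
    T1: float
    T2: float
    theta3: float
    l3: Optional[float]
    oob: bool
    endpoint: np.ndarray  # canonical-frame termination point
    correct_l3: float
    correct_angle: float


def produced_turn(raw: RawTrial) -> float:
    """Egocentric produced turn theta3 in [0, 2*pi).

    Counter-clockwise angle (in the left-turn canonical frame) from the final
    outbound heading (cone2 -> cone3) to the direction of the inbound
    termination point from cone 3, under the convention that the intended
    response uses the short anticlockwise turn.
    """
    end = raw.endpoint()
    if end is None:
        raise ValueError("trial has no endpoint")
    _, _, _, sign = triangle_geometry(raw.cone1, raw.cone2, raw.cone3)
    return egocentric_turn(raw.cone2, raw.cone3, end, sign)


def oob_angle(raw: RawTrial) -> float:
    """Produced turn of an out-of-bound trial, from the boundary-hit point.

    Distance information of such trials is absent (not zero) downstream.
    """
    if not raw.oob:
        raise ValueError("not an out-of-bound trial")
    if raw.oob_point is None:
        raise ValueError("out-of-bound trial without boundary-hit point (tracking fault)")
    return produced_turn(raw)


def standardize_trial(raw: RawTrial) -> StandardizedTrial:
    """Canonicalize one trial's geometry.

    Maps cone 1 to the origin and the first leg onto +x; mirrors the trial if
    the outbound turn was rightward, so the second leg always points leftward
    (left-turn canonical frame).  The response / boundary-hit point is
    transformed identically.  Idempotent, and invariant under any rigid
    motion or mirroring of the raw trial.
    """
    l1, l2, theta2, sign = triangle_geometry(raw.cone1, raw.cone2, raw.cone3)
    T1 = raw.t_c2 - raw.t_start
    T2 = raw.t_c3 - raw.t_c2
    if T1 <= 0 or T2 <= 0:
        raise ValueError("cone timestamps must be strictly increasing")
    leg1 = raw.cone2 - raw.cone1
    phi = np.arctan2(leg1[1], leg1[0])
    c, s = np.cos(-phi), np.sin(-phi)
    rot = np.array([[c, -s], [s, c]])

    def canon(p):
        q = rot @ (np.asarray(p, float) - raw.cone1)
        if sign < 0:
            q = q * np.array([1.0, -1.0])
        return q

    end = raw.endpoint()
    if end is None:
        raise ValueError("trial has no endpoint")
    end_c = canon(end)
    c3_c = canon(raw.cone3)
    theta3 = produced_turn(raw)
    l3 = None if raw.oob else float(np.hypot(*(end_c - c3_c)))
    correct_l3 = float(np.hypot(*(raw.cone1 - raw.cone3)))
    correct_angle = egocentric_turn(raw.cone2, raw.cone3, raw.cone1, sign)
    return StandardizedTrial(
        l1=l1,
        l2=l2,
        theta2=theta2,
        T1=T1,
        T2=T2,
        theta3=theta3,
        l3=l3,
        oob=raw.oob,
        endpoint=end_c,
        correct_l3=correct_l3,
        correct_angle=correct_angle,
    )


@dataclass
class ExclusionReport:
    """Per-trial and per-cell keep/drop decisions with reasons."""

    trials: pd.DataFrame  # participant, condition, trial, keep, reason
    cells: pd.DataFrame  # participant, condition, n_usable, keep
    counts: pd.DataFrame  # group x reason counts

    def summary(self) -> str:
        lines = ["Exclusions by group and reason:"]
        for _, row in self.counts.iterrows():
            lines.append(f"  {row['group']}: {row['reason']} = {row['n']}")
        return "\n".join(lines)


_META_COLS = ("participant", "group", "condition", "environment", "trial")


def standardize_dataset(trials: pd.DataFrame, tracking: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Standardize every trial of a raw trial table.

    Returns one row per trial with the canonical geometry, the produced turn,
    the correct return distance/turn and, when ``tracking`` is given, the
    reconstructed outbound walking speed and mean head pitch between cones 2
    and 3.  Trials whose geometry cannot be standardized (missing endpoint,
    coincident cones) get ``valid = False`` with a reason.
    """
    by_trial = None
    if tracking is not None:
        by_trial = dict(tuple(tracking.groupby(["participant", "condition", "trial"], sort=False)))
    rows = []
    for _, row in trials.iterrows():
        raw = RawTrial.from_row(row)
        out = {k: row[k] for k in _META_COLS if k in row}
        # raw-frame fields needed by tracking-based exclusion rules
        for k in ("c2x", "c2y", "t_c3"):
            if k in row:
                out[k] = row[k]
        out["valid"] = True
        out["invalid_reason"] = ""
        try:
            std = standardize_trial(raw)
        except ValueError as exc:
            out["valid"] = False
            out["invalid_reason"] = "tracking_fault" if raw.oob and raw.oob_point is None else str(exc)
            rows.append(out)
            continue
        out.update(
            l1=std.l1,
            l2=std.l2,
            theta2=std.theta2,
            T1=std.T1,
            T2=std.T2,
            theta3=std.theta3,
            l3=np.nan if std.l3 is None else std.l3,
            oob=std.oob,
            end_x=std.endpoint[0],
            end_y=std.endpoint[1],
            correct_l3=std.correct_l3,
            correct_angle=std.correct_angle,
        )
        if by_trial is not None:
            key = (row["participant"], row["condition"], row["trial"])
            tr = by_trial.get(key)
            if tr is not None:
                out["outbound_speed"] = reconstruct_speed(tr, t_start=row["t_start"], t_end=row["t_c3"])
                leg2 = tr[(tr["t"] >= row["t_c2"]) & (tr["t"] <= row["t_c3"])]
                if len(leg2):
                    out["head_pitch_deg"] = head_pitch(leg2[["qw", "qx", "qy", "qz"]].to_numpy())
        rows.append(out)
    return pd.DataFrame(rows)


def apply_exclusions(
    std: pd.DataFrame,
    tracking: Optional[pd.DataFrame] = None,
    short_response_m: float = SHORT_RESPONSE_M,
    retrace_radius_m: float = RETRACE_RADIUS_M,
    min_trials: int = N_MODEL_PARAMS,
):
    """Apply the trial- and cell-level exclusion rules.

    Returns ``(kept, report)``.  Reasons are exhaustive and mutually
    exclusive per trial: ``tracking_fault`` (no usable endpoint),
    ``short_response`` (inbound termination within ``short_response_m`` of
    cone 3), ``instruction_violation`` (inbound trajectory re-enters within
    ``retrace_radius_m`` of cone 2; needs tracking).  Cells with fewer than
    ``min_trials`` usable trials are dropped from fitting and summaries.
    """
    std = std.copy()
    reasons = np.full(len(std), "", dtype=object)
    invalid = ~std["valid"].to_numpy(bool) if "valid" in std else np.zeros(len(std), bool)
    reasons[invalid] = "tracking_fault"
    # distance from cone 3 to the inbound termination point, canonical frame
    ok = ~invalid if "l1" in std.columns else np.zeros(len(std), bool)
    short = np.zeros(len(std), bool)
    if ok.any():
        c3x = std.loc[ok, "l1"] + std.loc[ok, "l2"] * np.cos(std.loc[ok, "theta2"])
        c3y = std.loc[ok, "l2"] * np.sin(std.loc[ok, "theta2"])
        inbound_len = np.hypot(std.loc[ok, "end_x"] - c3x, std.loc[ok, "end_y"] - c3y)
        short[np.flatnonzero(ok)[inbound_len.to_numpy() < short_response_m]] = True
    reasons[short & ~invalid] = "short_response"

    if tracking is not None:
        violation = _retrace_violations(std, tracking, retrace_radius_m)
        reasons[violation & ~invalid & ~short] = "instruction_violation"

    std["keep"] = reasons == ""
    std["reason"] = reasons

    usable = std[std["keep"]]
    cell_sizes = usable.groupby(["participant", "condition"]).size().rename("n_usable").reset_index()
    # cells absent from `usable` entirely have 0 usable trials
    all_cells = std[["participant", "condition"]].drop_duplicates()
    cells = all_cells.merge(cell_sizes, how="left", on=["participant", "condition"])
    cells["n_usable"] = cells["n_usable"].fillna(0).astype(int)
    cells["keep"] = cells["n_usable"] >= min_trials

    kept_cells = cells[cells["keep"]][["participant", "condition"]]
    kept = usable.merge(kept_cells, on=["participant", "condition"], how="inner")

    trial_report = std[[c for c in _META_COLS if c in std] + ["keep", "reason"]].copy()
    dropped = std[~std["keep"]]
    if "group" in std.columns and len(dropped):
        counts = dropped.groupby(["group", "reason"]).size().rename("n").reset_index()
    else:
        counts = pd.DataFrame(columns=["group", "reason", "n"])
    return kept, ExclusionReport(trials=trial_report, cells=cells, counts=counts)


def _retrace_violations(std: pd.DataFrame, tracking: pd.DataFrame, radius: float) -> np.ndarray:
    """Trials whose inbound trajectory re-enters the cone-2 neighbourhood."""
    flags = np.zeros(len(std), bool)
    grouped = dict(tuple(tracking.groupby(["participant", "condition", "trial"], sort=False)))
    if not {"c2x", "c2y", "t_c3"}.issubset(std.columns):
        return flags
    for i, row in enumerate(std.itertuples(index=False)):
        key = (row.participant, row.condition, row.trial)
        tr = grouped.get(key)
        if tr is None:
            continue
        inbound = tr[tr["t"] > row.t_c3 + 1.0]  # ignore the turn at cone 3
        if not len(inbound):
            continue
        d = np.hypot(inbound["x"] - row.c2x, inbound["y"] - row.c2y)
        flags[i] = bool((d < radius).any())
    return flags


def reconstruct_speed(
    tracking: pd.DataFrame,
    t_start: Optional[float] = None,
    t_end: Optional[float] = None,
    ema_alpha: float = 0.9,
    kernel_sd_s: float = 1.0,
    stationary_threshold: float = 0.2,
    burn_in_s: float = 1.0,
) -> float:
    """Mean moving speed of a tracked interval, m/s.

    Instantaneous ground-plane speeds are smoothed by an exponential moving
    average ``s_i = alpha*s_{i-1} + (1-alpha)*|x_i - x_{i-1}|/(t_i-t_{i-1})``
    with ``alpha = 0.9`` (initialized at the first finite instantaneous
    speed), then convolved with a Gaussian kernel of 1 s width (sigma = 1 s,
    truncated at 3 sigma, reflected edges).  The mean is taken over samples
    faster than the 0.2 m/s stationary threshold, excluding a 1 s burn-in.
    Returns NaN if every sample is stationary (never 0/0).
    """
    tr = tracking
    if t_start is not None:
        tr = tr[tr["t"] >= t_start]
    if t_end is not None:
        tr = tr[tr["t"] <= t_end]
    t = tr["t"].to_numpy(float)
    if len(t) < 2:
        raise ValueError("need at least two tracking samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    xy = tr[["x", "y"]].to_numpy(float)
    inst = np.hypot(*np.diff(xy, axis=0).T) / np.diff(t)
    ema = np.empty_like(inst)
    ema[0] = inst[0]
    for i in range(1, len(inst)):
        ema[i] = ema_alpha * ema[i - 1] + (1.0 - ema_alpha) * inst[i]
    dt = np.median(np.diff(t))
    smooth = gaussian_filter1d(ema, sigma=kernel_sd_s / dt, mode="reflect", truncate=3.0)
    ts = t[1:]
    keep = (smooth > stationary_threshold) & (ts >= t[0] + burn_in_s)
    if not keep.any():
        return float("nan")
    return float(smooth[keep].mean())


def head_pitch(quaternions) -> float:
    """Mean head pitch in degrees: angle of the face direction from world up.

    Quaternions are (qw, qx, qy, qz) rows; non-unit quaternions are
    normalized, zero-norm rejected.  A level forward gaze gives 90 degrees;
    looking down gives more than 90.
    """
    q = np.atleast_2d(np.asarray(quaternions, dtype=float))
    norms = np.linalg.norm(q, axis=1)
    if np.any(norms < 1e-9):
        raise ValueError("zero-norm quaternion")
    q = q / norms[:, None]
    rot = Rotation.from_quat(q[:, [1, 2, 3, 0]])  # to (x, y, z, w)
    forward = rot.apply(np.array([1.0, 0.0, 0.0]))
    cosang = np.clip(forward @ np.array([0.0, 0.0, 1.0]), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)).mean())


def load_cohort(path):
    """Read a ``trials.csv`` (+ optional ``tracking.csv``) cohort directory.

    External datasets with a different on-disk schema are adapted by renaming
    columns to this dialect before calling the pipeline.
    """
    path = Path(path)
    trials = pd.read_csv(path / "trials.csv")
    tracking_file = path / "tracking.csv"
    tracking = pd.read_csv(tracking_file) if tracking_file.exists() else None
    return trials, tracking
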