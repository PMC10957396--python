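"""Generative linear-angular model of triangle-completion path integration.

The model predicts the unguided return (inbound) leg of a triangle-completion
trial from the guided outbound legs.  Three error stages are modelled:

1. *Encoding* — walked distances are accumulated by a leaky integrator of
   walking speed (decay rate ``beta``, speed gain ``k``); the outbound turn is
   scaled by an angular gain ``g2``.
2. *Calculation* — the intended return distance ``h`` and turn ``alpha`` are
   computed by vector addition of the encoded legs.
3. *Production* — the executed return regresses toward the session-mean
   correct return (slopes ``m3`` for distance, ``g3`` for angle), and
   independent Gaussian noise (SDs ``sigma``, ``nu``) corrupts the outcome.

All angles are radians, distances metres, times seconds.  The produced turn
``theta3`` is the counter-clockwise angle from the final outbound heading to
the response direction, wrapped to [0, 2*pi) in the left-turn canonical frame.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

__all__ = [
    "GlampiParams",
    "NOMINAL",
    "PARAM_NAMES",
    "TrialSet",
    "leak_factor",
    "encode_distances",
    "encode_angle",
    "calculate_inbound",
    "produce_inbound",
    "predict_inbound",
    "trial_nll",
    "dataset_nll",
    "desktop_encoded_distance",
]

PARAM_NAMES = ("k", "g2", "beta", "g3", "m3", "sigma", "nu")

LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class GlampiParams:
    """The seven model parameters.

    ``k``     speed gain (dimensionless; 1 = veridical speed percept)
    ``g2``    outbound-turn encoding gain (1 = veridical)
    ``beta``  leak rate of the distance integrator, 1/s (0 = perfect memory,
              negative values represent growth)
    ``g3``    angular production slope (1 = no regression to the mean)
    ``m3``    distance production slope (1 = no regression to the mean)
    ``sigma`` distance noise SD, m
    ``nu``    angular noise SD, rad
    """

    k: float = 1.0
    g2: float = 1.0
    beta: float = 0.0
    g3: float = 1.0
    m3: float = 1.0
    sigma: float = 0.0
    nu: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.nu < 0:
            raise ValueError("noise SDs sigma and nu must be >= 0")
        for name in PARAM_NAMES:
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"parameter {name} must be finite")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values) -> "GlampiParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, values))))

    def replace(self, **changes) -> "GlampiParams":
        d = asdict(self)
        d.update(changes)
        return GlampiParams(**d)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "GlampiParams":
        return cls(**json.loads(text))


#: Error-free ("nominal") parameter values used for one-sample comparisons.
NOMINAL = GlampiParams(k=1.0, g2=1.0, beta=0.0, g3=1.0, m3=1.0, sigma=0.0, nu=0.0)


def leak_factor(beta, T):
    """Fractional distance retained by a leaky integrator run for time ``T``.

    Returns ``(1 - exp(-beta*T)) / (beta*T)`` with the removable singularity
    at ``beta*T = 0`` evaluated analytically (limit 1), never as 0/0.
    """
    bT = np.asarray(beta * np.asarray(T, dtype=float), dtype=float)
    small = np.abs(bT) < 1e-10
    safe = np.where(small, 1.0, bT)
    out = np.where(small, 1.0 - bT / 2.0, -np.expm1(-safe) / safe)
    return out if out.ndim else float(out)


def encode_distances(l1, l2, T1, T2, k, beta):
    """Encoded lengths of the two outbound legs.

    A leaky integrator of walking speed (``dl'/dt = -beta*l' + k*v``) run at
    constant speed over each leg gives ``l' = l*k*(1-exp(-beta*T))/(beta*T)``;
    the first leg's trace keeps decaying during the second leg, contributing a
    further factor ``exp(-beta*T2)``.
    """
    l1p = l1 * k * leak_factor(beta, T1) * np.exp(-beta * np.asarray(T2, dtype=float))
    l2p = l2 * k * leak_factor(beta, T2)
    return l1p, l2p


def encode_angle(theta2, g2):
    """Encoded outbound turn: gain-scaled physical turn ``g2 * theta2``."""
    return g2 * theta2


def calculate_inbound(l1p, l2p, theta2p, *, return_flag=False):
    """Intended return distance ``h`` and turn ``alpha`` from the encoded path.

    ``h = sqrt((l1' + l2'*cos(theta2'))^2 + (l2'*sin(theta2'))^2)`` and
    ``alpha = pi - asin(l1'*sin(theta2')/h)``.  The asin form is used
    deliberately: it departs from exact planar geometry whenever the encoded
    triangle's return-vertex angle is obtuse (``l2' + l1'*cos(theta2') < 0``,
    reachable when a large angular gain inflates the encoded turn), and that
    branch is what lets an angular over-encoding produce large over-turns.
    With ``return_flag=True`` also returns a boolean mask marking where the
    asin form disagrees with exact geometry.

    Raises ``ValueError`` if the encoded path closes on itself (``h = 0``).
    """
    l1p = np.asarray(l1p, dtype=float)
    l2p = np.asarray(l2p, dtype=float)
    theta2p = np.asarray(theta2p, dtype=float)
    x = l1p + l2p * np.cos(theta2p)
    y = l2p * np.sin(theta2p)
    h = np.hypot(x, y)
    if np.any(h < 1e-12):
        raise ValueError("degenerate trial: encoded path closes on itself (h = 0)")
    arg = np.clip(l1p * np.sin(theta2p) / h, -1.0, 1.0)
    alpha = np.pi - np.arcsin(arg)
    if h.ndim == 0:
        h, alpha = float(h), float(alpha)
    if return_flag:
        ambiguous = (l2p + l1p * np.cos(theta2p)) < 0
        return h, alpha, ambiguous
    return h, alpha


def produce_inbound(h, alpha, g3, m3, lbar, thbar):
    """Produced return distance and turn after regression to the session mean.

    ``l3' = m3*h + (1-m3)*lbar`` and ``theta3' = g3*alpha + (1-g3)*thbar``,
    where ``lbar``/``thbar`` are the session means of the *correct* return
    distance and egocentric turn for that participant and condition.
    """
    l3p = m3 * np.asarray(h, dtype=float) + (1.0 - m3) * lbar
    th3p = g3 * np.asarray(alpha, dtype=float) + (1.0 - g3) * thbar
    if np.ndim(h) == 0:
        return float(l3p), float(th3p)
    return l3p, th3p


def predict_inbound(params: GlampiParams, l1, l2, theta2, T1, T2, lbar, thbar):
    """Noise-free model prediction ``(l3', theta3')`` for one or more trials."""
    l1p, l2p = encode_distances(l1, l2, T1, T2, params.k, params.beta)
    th2p = encode_angle(theta2, params.g2)
    h, alpha = calculate_inbound(l1p, l2p, th2p)
    return produce_inbound(h, alpha, params.g3, params.m3, lbar, thbar)


@dataclass
class TrialSet:
    """Vectorised container for one participant-condition cell's trials.

    ``l3`` is NaN on out-of-bound trials (distance unobserved, angle valid).
    ``lbar``/``thbar`` are the session means of the correct return distance
    and correct egocentric turn across the cell's usable trials.
    """

    l1: np.ndarray
    l2: np.ndarray
    theta2: np.ndarray
    T1: np.ndarray
    T2: np.ndarray
    theta3: np.ndarray
    l3: np.ndarray
    oob: np.ndarray
    lbar: float
    thbar: float

    def __post_init__(self) -> None:
        arrays = ("l1", "l2", "theta2", "T1", "T2", "theta3", "l3", "oob")
        for name in arrays:
            setattr(self, name, np.asarray(getattr(self, name)))
        n = len(self.l1)
        if any(len(getattr(self, a)) != n for a in arrays):
            raise ValueError("all trial arrays must have equal length")
        if not (-2 * np.pi <= self.thbar <= 2 * np.pi):
            raise ValueError("session mean turn out of [-2pi, 2pi]")

    def __len__(self) -> int:
        return len(self.l1)

    @classmethod
    def from_frame(cls, df) -> "TrialSet":
        """Build from a standardized-trials DataFrame (one cell)."""
        usable = df
        lbar = float(usable["correct_l3"].mean())
        thbar = float(usable["correct_angle"].mean())
        return cls(
            l1=usable["l1"].to_numpy(float),
            l2=usable["l2"].to_numpy(float),
            theta2=usable["theta2"].to_numpy(float),
            T1=usable["T1"].to_numpy(float),
            T2=usable["T2"].to_numpy(float),
            theta3=usable["theta3"].to_numpy(float),
            l3=usable["l3"].to_numpy(float),
            oob=usable["oob"].to_numpy(bool),
            lbar=lbar,
            thbar=thbar,
        )


def trial_nll(l3, theta3, l3p, theta3p, sigma, nu, oob=False):
    """Negative log-likelihood contribution of a single trial.

    Complete trials contribute two independent Gaussian negative log-densities
    (distance around ``l3'`` with SD ``sigma``; turn around ``theta3'`` with SD
    ``nu``).  Out-of-bound trials contribute the angle term only.
    """
    if sigma <= 0 or nu <= 0:
        return math.inf
    nll = (theta3 - theta3p) ** 2 / (2.0 * nu**2) + math.log(nu) + 0.5 * LOG_2PI
    if not oob:
        nll += (l3 - l3p) ** 2 / (2.0 * sigma**2) + math.log(sigma) + 0.5 * LOG_2PI
    return float(nll)


def dataset_nll(trials: TrialSet, params: GlampiParams) -> float:
    """Total negative log-likelihood of a trial set under ``params``.

    Sum over trials of the per-trial Gaussian contributions; out-of-bound
    trials enter with their angle term only.  ``sigma`` or ``nu`` at zero
    yields +inf (a fit-reject signal), never NaN.
    """
    if len(trials) == 0:
        raise ValueError("empty trial set")
    if params.sigma <= 0 or params.nu <= 0:
        return math.inf
    l3p, th3p = predict_inbound(
        params,
        trials.l1,
        trials.l2,
        trials.theta2,
        trials.T1,
        trials.T2,
        trials.lbar,
        trials.thbar,
    )
    n = len(trials)
    ang = (trials.theta3 - th3p) ** 2 / (2.0 * params.nu**2)
    nll = float(np.sum(ang)) + n * (math.log(params.nu) + 0.5 * LOG_2PI)
    complete = ~trials.oob
    n_c = int(np.count_nonzero(complete))
    if n_c:
        res = trials.l3[complete] - l3p[complete]
        nll += float(np.sum(res**2)) / (2.0 * params.sigma**2)
        nll += n_c * (math.log(params.sigma) + 0.5 * LOG_2PI)
    return nll


def desktop_encoded_distance(l, alpha_rate, k=1.0):
    """Distance-domain leaky integrator used by desktop (joystick) tasks.

    ``l' = k/alpha * (1 - exp(-alpha*l))``.  For constant walking speed ``v``
    this coincides with the time-domain encoder at ``alpha = beta / v`` — the
    documented equivalence between the two formulations.
    """
    l = np.asarray(l, dtype=float)
    out = k * l * leak_factor(alpha_rate, l)
    return float(out) if out.ndim == 0 else out
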