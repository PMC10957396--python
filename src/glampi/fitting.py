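"""Maximum-likelihood fitting, the candidate-model lattice, and AIC/BIC selection.

Each participant-condition cell is fitted independently by minimizing the
trial-set negative log-likelihood with seeded multi-start bounded local
optimization (L-BFGS-B from Latin-hypercube starting points).  Candidate
models are the 32 combinations of freeing the five structural parameters
{k, g2, beta, m3, g3} (the noise SDs sigma and nu are always free); masked
parameters are fixed at their error-free values.  Models are compared by
mean AIC across fitted cells (BIC reported as a secondary score).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .model import GlampiParams, PARAM_NAMES, TrialSet, dataset_nll

__all__ = [
    "CandidateModel",
    "FULL_MODEL",
    "FitSettings",
    "FitResult",
    "enumerate_candidates",
    "fit",
    "fit_cohort",
    "condition_average",
    "select_model",
]

STRUCTURAL = ("k", "g2", "beta", "m3", "g3")
FIXED_VALUES = {"k": 1.0, "g2": 1.0, "beta": 0.0, "m3": 1.0, "g3": 1.0}

#: Optimizer box bounds; sigma and nu are searched on a log scale.
FIT_BOUNDS = {
    "k": (1e-3, 3.0),
    "g2": (1e-3, 3.0),
    "beta": (-0.5, 1.0),
    "g3": (-1.0, 2.0),
    "m3": (-1.0, 2.0),
    "log_sigma": (math.log(1e-4), math.log(3.0)),
    "log_nu": (math.log(1e-4), math.log(math.pi)),
}

MIN_TRIALS = 7


@dataclass(frozen=True)
class CandidateModel:
    """A free-parameter mask over the five structural parameters."""

    mask: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = set(self.mask) - set(STRUCTURAL)
        if bad:
            raise ValueError(f"unknown structural parameters: {bad}")
        ordered = tuple(p for p in STRUCTURAL if p in self.mask)
        object.__setattr__(self, "mask", ordered)

    @property
    def n_free(self) -> int:
        return 2 + len(self.mask)

    @property
    def label(self) -> str:
        return "+".join(self.mask) if self.mask else "noise_only"

    def build_params(self, structural_values, sigma, nu) -> GlampiParams:
        values = dict(FIXED_VALUES)
        values.update(dict(zip(self.mask, structural_values)))
        return GlampiParams(sigma=sigma, nu=nu, **values)


FULL_MODEL = CandidateModel(mask=STRUCTURAL)


def enumerate_candidates() -> list[CandidateModel]:
    """All 2^5 = 32 masks, ordered by increasing free-parameter count."""
    models = [
        CandidateModel(mask=combo)
        for r in range(len(STRUCTURAL) + 1)
        for combo in itertools.combinations(STRUCTURAL, r)
    ]
    return models


@dataclass
class FitSettings:
    n_starts: int = 20
    seed: int = 0
    maxiter: int = 300


@dataclass
class FitResult:
    params: GlampiParams  # raw maximum-likelihood estimate
    nll: float
    n_trials: int
    n_free: int
    aic: float
    bic: float
    n_restarts: int
    converged: bool
    best_start: int
    model: CandidateModel
    #: MLE with degrees-of-freedom-corrected noise SDs (the reported estimate):
    #: the raw Gaussian-SD MLE is biased low by ~sqrt((n-p)/n) when p mean
    #: parameters are estimated from n observations, so sigma is rescaled by
    #: sqrt(n_dist/(n_dist - p_dist)) (distance observations exclude
    #: out-of-bound trials) and nu by sqrt(n/(n - p_ang)).
    params_corrected: GlampiParams | None = None


def _start_points(model: CandidateModel, trials: TrialSet, settings: FitSettings) -> np.ndarray:
    names = list(model.mask) + ["log_sigma", "log_nu"]
    lo = np.array([FIT_BOUNDS[n][0] for n in names])
    hi = np.array([FIT_BOUNDS[n][1] for n in names])
    # heuristic start: error-free structural values, moment-based noise SDs
    complete = ~trials.oob
    sig0 = float(np.std(trials.l3[complete] - trials.lbar)) if complete.any() else 0.3
    nu0 = float(np.std(trials.theta3 - trials.thbar))
    heur = np.array(
        [FIXED_VALUES[n] for n in model.mask]
        + [math.log(min(max(sig0, 0.05), 2.0)), math.log(min(max(nu0, 0.05), 2.0))]
    )
    heur = np.clip(heur, lo, hi)
    n_lhs = max(settings.n_starts - 1, 1)
    sampler = qmc.LatinHypercube(d=len(names), seed=settings.seed)
    pts = qmc.scale(sampler.random(n_lhs), lo, hi)
    return np.vstack([heur, pts])


def _fast_objective(trials: TrialSet, model: CandidateModel):
    """Inlined negative log-likelihood for the optimizer hot path.

    Numerically identical to ``dataset_nll`` (checked in the test suite) but
    avoids per-call dataclass construction.
    """
    l1 = trials.l1.astype(float)
    l2 = trials.l2.astype(float)
    th2 = trials.theta2.astype(float)
    T1 = trials.T1.astype(float)
    T2 = trials.T2.astype(float)
    th3 = trials.theta3.astype(float)
    complete = ~trials.oob.astype(bool)
    l3c = trials.l3.astype(float)[complete]
    n = len(l1)
    n_c = int(complete.sum())
    lbar, thbar = trials.lbar, trials.thbar
    mask = model.mask
    base = dict(FIXED_VALUES)
    n_struct = len(mask)
    half_log_2pi = 0.5 * math.log(2.0 * math.pi)

    def objective(x):
        vals = base.copy()
        for i, name in enumerate(mask):
            vals[name] = x[i]
        sigma = math.exp(x[n_struct])
        nu = math.exp(x[n_struct + 1])
        k, g2, beta, m3, g3 = vals["k"], vals["g2"], vals["beta"], vals["m3"], vals["g3"]
        bT1 = beta * T1
        bT2 = beta * T2
        lf1 = np.where(np.abs(bT1) < 1e-10, 1.0 - bT1 / 2.0, -np.expm1(-bT1) / np.where(np.abs(bT1) < 1e-10, 1.0, bT1))
        lf2 = np.where(np.abs(bT2) < 1e-10, 1.0 - bT2 / 2.0, -np.expm1(-bT2) / np.where(np.abs(bT2) < 1e-10, 1.0, bT2))
        l1p = l1 * k * lf1 * np.exp(-bT2)
        l2p = l2 * k * lf2
        th2p = g2 * th2
        xx = l1p + l2p * np.cos(th2p)
        yy = l2p * np.sin(th2p)
        h = np.hypot(xx, yy)
        if np.any(h < 1e-12):
            return math.inf
        alpha = np.pi - np.arcsin(np.clip(l1p * np.sin(th2p) / h, -1.0, 1.0))
        l3p = m3 * h + (1.0 - m3) * lbar
        th3p = g3 * alpha + (1.0 - g3) * thbar
        nll = float(np.sum((th3 - th3p) ** 2)) / (2.0 * nu * nu) + n * (math.log(nu) + half_log_2pi)
        if n_c:
            res = l3c - l3p[complete]
            nll += float(np.sum(res * res)) / (2.0 * sigma * sigma) + n_c * (math.log(sigma) + half_log_2pi)
        return nll

    return objective


def fit(trials: TrialSet, model: CandidateModel = FULL_MODEL, settings: FitSettings | None = None) -> FitResult:
    """Fit one participant-condition cell by multi-start bounded MLE.

    Refuses cells with fewer than 7 trials (overfitting guard) or fewer
    trials than free parameters.  Deterministic given ``settings.seed``.
    """
    settings = settings or FitSettings()
    n = len(trials)
    if n < MIN_TRIALS:
        raise ValueError(f"refusing to fit {n} trials: fewer than {MIN_TRIALS}")
    if n < model.n_free:
        raise ValueError(f"refusing to fit {n} trials with {model.n_free} free parameters")
    names = list(model.mask) + ["log_sigma", "log_nu"]
    bounds = [FIT_BOUNDS[name] for name in names]
    n_struct = len(model.mask)
    objective = _fast_objective(trials, model)
    n_dim = n_struct + 2
    fd_step = 1e-7

    def fun_and_grad(x):
        f0 = objective(x)
        grad = np.empty(n_dim)
        for j in range(n_dim):
            xp = x.copy()
            xp[j] += fd_step
            grad[j] = (objective(xp) - f0) / fd_step
        return f0, grad

    best = None
    best_idx = -1
    any_converged = False
    starts = _start_points(model, trials, settings)
    for i, x0 in enumerate(starts):
        res = minimize(
            fun_and_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": settings.maxiter},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best, best_idx = res, i
    params = model.build_params(best.x[:n_struct], math.exp(best.x[-2]), math.exp(best.x[-1]))
    nll = float(best.fun)
    aic = 2.0 * model.n_free + 2.0 * nll
    bic = model.n_free * math.log(n) + 2.0 * nll
    n_dist = int(np.count_nonzero(~trials.oob))
    p_dist = len(set(model.mask) & {"k", "g2", "beta", "m3"})
    p_ang = len(set(model.mask) & {"k", "g2", "beta", "g3"})
    sigma_c = params.sigma * math.sqrt(n_dist / (n_dist - p_dist)) if n_dist > p_dist else params.sigma
    nu_c = params.nu * math.sqrt(n / (n - p_ang)) if n > p_ang else params.nu
    return FitResult(
        params_corrected=params.replace(sigma=sigma_c, nu=nu_c),
        params=params,
        nll=nll,
        n_trials=n,
        n_free=model.n_free,
        aic=aic,
        bic=bic,
        n_restarts=len(starts),
        converged=any_converged,
        best_start=best_idx,
        model=model,
    )


def fit_cohort(
    std: pd.DataFrame,
    candidates: list[CandidateModel] | None = None,
    settings: FitSettings | None = None,
) -> pd.DataFrame:
    """Fit every participant-condition cell, one row per cell per candidate.

    Cells refused by :func:`fit` (too few usable trials) are skipped and do
    not appear in the output.
    """
    candidates = candidates if candidates is not None else [FULL_MODEL]
    settings = settings or FitSettings()
    rows = []
    for (pid, cond), cell in std.groupby(["participant", "condition"], sort=True):
        trials = TrialSet.from_frame(cell)
        group = cell["group"].iloc[0] if "group" in cell else ""
        for cand in candidates:
            try:
                result = fit(trials, cand, settings)
            except ValueError:
                continue
            rows.append(
                {
                    "participant": pid,
                    "group": group,
                    "condition": cond,
                    "candidate": cand.label,
                    "n_free": cand.n_free,
                    # reported sigma/nu carry the df correction; raw MLEs kept alongside
                    **{name: getattr(result.params_corrected, name) for name in PARAM_NAMES},
                    "sigma_mle": result.params.sigma,
                    "nu_mle": result.params.nu,
                    "nll": result.nll,
                    "aic": result.aic,
                    "bic": result.bic,
                    "n_trials": result.n_trials,
                    "converged": result.converged,
                }
            )
    return pd.DataFrame(rows)


def condition_average(fits: pd.DataFrame) -> pd.DataFrame:
    """Condition-averaged parameters per participant (one candidate at a time)."""
    value_cols = list(PARAM_NAMES)
    return (
        fits.groupby(["participant", "group", "candidate"], sort=True)[value_cols]
        .mean()
        .reset_index()
    )


def select_model(fits: pd.DataFrame):
    """Rank candidates by mean AIC across cells (SEM reported, BIC secondary).

    Cells lacking a fit for any candidate are dropped pairwise so every
    candidate is scored on the same cells.  Ties in mean AIC are broken in
    favour of fewer free parameters.  Returns ``(table, winner_label)``.
    """
    wide = fits.pivot_table(
        index=["participant", "condition"], columns="candidate", values="aic"
    ).dropna(axis=0, how="any")
    if wide.empty:
        raise ValueError("no cells fitted for every candidate")
    n_free = fits.groupby("candidate")["n_free"].first()
    bic_wide = fits.pivot_table(
        index=["participant", "condition"], columns="candidate", values="bic"
    ).loc[wide.index]
    table = pd.DataFrame(
        {
            "candidate": wide.columns,
            "n_free": n_free.loc[wide.columns].to_numpy(),
            "mean_aic": wide.mean(axis=0).to_numpy(),
            "sem_aic": wide.sem(axis=0).to_numpy(),
            "mean_bic": bic_wide.mean(axis=0).to_numpy(),
            "n_cells": len(wide),
        }
    ).sort_values(["mean_aic", "n_free"], kind="mergesort").reset_index(drop=True)
    winner = table.iloc[0]["candidate"]
    return table, winner
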