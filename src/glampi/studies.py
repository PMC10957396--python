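"""Self-generated validation studies: parameter recovery, group-difference
detection, and model selection under known ground truth.

Each study generates synthetic cohorts with the generator's group presets (or
a stated truth), runs the full pipeline (standardization, exclusions,
fitting), and measures how well the known generating structure is recovered.
Recovery fits pool each participant's three condition cells (the generator
shares the truth across conditions); the pipeline's per-condition fits are
used where conditions matter (the group-difference ANOVA).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CohortSpec, generate_cohort
from .fitting import FitSettings, FULL_MODEL, enumerate_candidates, fit, fit_cohort, select_model
from .inference import two_way_anova
from .model import GlampiParams, PARAM_NAMES, TrialSet
from .preprocess import apply_exclusions, standardize_dataset

__all__ = [
    "SELECTION_TRUTH_MEANS",
    "SELECTION_TRUTH_SDS",
    "NOISE_ONLY_MEANS",
    "recovery_study",
    "group_difference_study",
    "selection_study",
]

#: Ground truth for the model-selection study: every structural error source
#: clearly present, so each parameter should earn its AIC penalty.
SELECTION_TRUTH_MEANS = GlampiParams(k=1.3, g2=1.15, beta=0.15, g3=0.6, m3=0.7, sigma=0.30, nu=0.30)
SELECTION_TRUTH_SDS = GlampiParams(k=0.05, g2=0.05, beta=0.05, g3=0.05, m3=0.05, sigma=0.03, nu=0.03)

#: Ground truth with no structural error sources at all (noise only).
NOISE_ONLY_MEANS = GlampiParams(sigma=0.30, nu=0.30)
NOISE_ONLY_SDS = GlampiParams(k=0, g2=0, beta=0, g3=0, m3=0, sigma=0.03, nu=0.03)


def _pipeline(spec: CohortSpec):
    trials, _, truth = generate_cohort(spec, include_tracking=False)
    std = standardize_dataset(trials)
    kept, _ = apply_exclusions(std)
    return kept, truth


def recovery_study(n_participants: int = 100, seed: int = 42, n_starts: int = 20):
    """Fit elderly-preset participants and compare estimates with the truth.

    Returns ``(estimates, summary)``: per-participant estimated vs true
    parameters, and a per-parameter summary with the median estimation error
    and its size relative to the preset mean (percent).
    """
    spec = CohortSpec.from_preset("elderly", n_participants, rng_seed=seed)
    kept, truth = _pipeline(spec)
    rows = []
    for pid, sub in kept.groupby("participant"):
        res = fit(TrialSet.from_frame(sub), FULL_MODEL, FitSettings(n_starts=n_starts, seed=0))
        rows.append({"participant": pid, **{n: getattr(res.params_corrected, n) for n in PARAM_NAMES}})
    est = pd.DataFrame(rows).merge(truth, on="participant", suffixes=("_est", "_true"))
    summary_rows = []
    for name in PARAM_NAMES:
        err = est[f"{name}_est"] - est[f"{name}_true"]
        ref = getattr(spec.param_means, name)
        summary_rows.append(
            {
                "param": name,
                "preset_mean": ref,
                "median_bias": float(np.median(err)),
                "median_bias_pct": float(100.0 * np.median(err) / ref),
                "iqr": float(np.subtract(*np.percentile(err, [75, 25])) * -1),
            }
        )
    return est, pd.DataFrame(summary_rows)


def group_difference_study(
    n_replicates: int = 20,
    n_per_group: int = 20,
    seed: int = 0,
    n_starts: int = 4,
    params=("g2", "nu"),
    alpha: float = 0.05,
):
    """Detection rate of the MCI+-like vs MCI--like preset difference.

    Per replicate: generate both cohorts, fit the full model per
    participant-condition cell, and run the group x condition ANOVA on each
    requested parameter.  Returns the fraction of replicates with a
    significant group effect, per parameter.
    """
    detections = {p: 0 for p in params}
    for rep in range(n_replicates):
        frames = []
        for grp in ("mci_pos", "mci_neg"):
            spec = CohortSpec.from_preset(grp, n_per_group, rng_seed=seed + 1000 * (rep + 1) + (grp == "mci_pos"))
            kept, _ = _pipeline(spec)
            frames.append(kept)
        fits = fit_cohort(pd.concat(frames, ignore_index=True), settings=FitSettings(n_starts=n_starts, seed=0))
        for p in params:
            effect = [e for e in two_way_anova(fits, p) if e.effect == "group"][0]
            detections[p] += effect.p < alpha
    return {p: detections[p] / n_replicates for p in params}


def selection_study(truth: str = "full", n_participants: int = 14, seed: int = 7, n_starts: int = 8):
    """Fit the 32-candidate lattice on data of known generative complexity.

    ``truth='full'`` generates from the seven-parameter model (all error
    sources present); ``truth='noise_only'`` from the veridical-plus-noise
    model.  Fits pool each participant's conditions.  Returns a dict with the
    ranked AIC table, the winning candidate, and the AIC gap between the
    noise-only candidate and the minimum.
    """
    if truth == "full":
        means, sds = SELECTION_TRUTH_MEANS, SELECTION_TRUTH_SDS
    elif truth == "noise_only":
        means, sds = NOISE_ONLY_MEANS, NOISE_ONLY_SDS
    else:
        raise ValueError("truth must be 'full' or 'noise_only'")
    spec = CohortSpec.from_preset("elderly", n_participants, rng_seed=seed, param_means=means, param_sds=sds)
    kept, _ = _pipeline(spec)
    kept = kept.assign(condition="pooled")
    fits = fit_cohort(kept, enumerate_candidates(), FitSettings(n_starts=n_starts, seed=0))
    table, winner = select_model(fits)
    noise_aic = float(table.loc[table["candidate"] == "noise_only", "mean_aic"].iloc[0])
    winner_structural_free = int(table.iloc[0]["n_free"]) - 2
    return {
        "table": table,
        "winner": winner,
        "noise_only_gap": noise_aic - float(table["mean_aic"].min()),
        "winner_structural_free": winner_structural_free,
    }
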