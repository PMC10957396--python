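"""Per-trial proportional errors and group/condition summaries.

The proportional linear error is the length of the performed inbound path
(cone 3 to the response) divided by the length of the correct inbound path
(cone 3 to cone 1); the proportional angular error is the produced
egocentric turn divided by the correct turn, both wrapped to [0, 2*pi) under
the anticlockwise short-turn convention.  A value of 1 is perfect; below 1
is under-walking / under-turning, above 1 over-walking / over-turning.
Out-of-bound trials have no linear error (the distance is unobserved) but a
valid angular error.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["trial_errors", "summarize"]


def trial_errors(std: pd.DataFrame) -> pd.DataFrame:
    """Add ``ple`` and ``pae`` columns to a standardized-trials table.

    ``ple`` is NaN on out-of-bound trials; ``pae`` is defined for every trial
    with a produced turn.  Missing values are propagated, never imputed.
    """
    out = std.copy()
    ple = out["l3"] / out["correct_l3"]
    out["ple"] = ple.where(~out["oob"].astype(bool))
    out["pae"] = out["theta3"] / out["correct_angle"]
    return out


def summarize(errors: pd.DataFrame, young_first_n: int | None = None):
    """Participant-condition, participant and group summary tables.

    Averaging proceeds trial -> participant-condition cell -> participant
    (unweighted across conditions) -> group mean/SD.  Out-of-bound trials are
    excluded from linear-error means (the denominator is the count of defined
    values) and counted into each participant's out-of-bound ratio.

    ``young_first_n`` optionally restricts young participants to their first
    N trials per condition, for parity with groups that completed fewer
    trials.
    """
    df = errors
    if young_first_n is not None:
        mask = (df["group"] != "young") | (df["trial"] < young_first_n)
        df = df[mask]
    cell = (
        df.groupby(["participant", "group", "condition"])
        .agg(
            ple=("ple", "mean"),
            pae=("pae", "mean"),
            oob_ratio=("oob", "mean"),
            n_trials=("pae", "size"),
        )
        .reset_index()
    )
    participant = (
        cell.groupby(["participant", "group"])
        .agg(ple=("ple", "mean"), pae=("pae", "mean"), oob_ratio=("oob_ratio", "mean"))
        .reset_index()
    )
    group = (
        participant.groupby("group")
        .agg(
            ple_mean=("ple", "mean"),
            ple_sd=("ple", "std"),
            pae_mean=("pae", "mean"),
            pae_sd=("pae", "std"),
            oob_ratio_mean=("oob_ratio", "mean"),
            n=("participant", "size"),
        )
        .reset_index()
    )
    return cell, participant, group
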