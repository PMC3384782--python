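"""Per-cycle analysis dataset construction.

Raw within-cycle assessments (typically three per 21-day cycle) are reduced
to one observation per subject-cycle: the arithmetic mean of the scores and
the mean number of days from randomization to the assessments, converted to
months.  Records after the observed survival time and after cycle 6 are
excluded; termination of the series at progression makes the longitudinal
missingness informative, which is precisely what the joint model addresses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["cycle_average", "apply_exclusions", "completion_table"]


def cycle_average(raw: pd.DataFrame, item: str | None = None,
                  days_per_month: float = 30.0) -> pd.DataFrame:
    """Collapse raw assessments of one item to per-cycle means.

    Parameters
    ----------
    raw : DataFrame
        Columns ``subject_id, day, cycle, item, score``; scores in [0, 100].
    item : str, optional
        Item to extract; rows for other items are ignored.  If omitted, the
        table must contain a single item - averaging scores across items
        would be meaningless, so mixed input is rejected.
    days_per_month : float
        Divisor converting days to months (default 30, so a 21-day cycle is
        exactly 0.7 month).

    Returns
    -------
    DataFrame with one row per (subject, observed cycle): columns
    ``subject_id, cycle, y`` (cycle-mean score) and ``t`` (mean day / divisor,
    months).  Cycles with no assessments emit nothing.
    """
    required = {"subject_id", "day", "cycle", "item", "score"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"raw table lacks columns {sorted(missing)}")
    if item is None:
        items = raw["item"].unique()
        if len(items) > 1:
            raise ValueError(
                f"mixed items {sorted(items)} passed to cycle_average; "
                "select one with the item argument")
        sub = raw
    else:
        sub = raw[raw["item"] == item]
        if sub.empty and not raw.empty:
            raise ValueError(f"no rows for item {item!r}")
    out = (sub.groupby(["subject_id", "cycle"], sort=True)
           .agg(y=("score", "mean"), mean_day=("day", "mean"))
           .reset_index())
    out["t"] = out["mean_day"] / days_per_month
    return out.drop(columns="mean_day")


def apply_exclusions(observations: pd.DataFrame, survival: pd.DataFrame,
                     max_cycle: int = 6):
    """Drop post-survival-time and post-cycle-``max_cycle`` records.

    All subjects are truncated at their observed time ``T_i`` (for censored
    subjects as well: the model describes no post-``T`` data).  An exact tie
    ``t == T_i`` is retained - a measurement "at" progression precedes the
    event administratively.

    Returns ``(filtered, drops)`` where ``drops`` counts removals by reason
    (``post_cycle{max_cycle}``, ``post_event_time``).  Idempotent, and
    retained + dropped = input count.
    """
    surv = survival.set_index("subject_id")
    orphans = sorted(set(observations["subject_id"]) - set(surv.index))
    if orphans:
        raise KeyError(f"observations without survival record: {orphans}")
    T = surv["time_months"].reindex(observations["subject_id"]).to_numpy()
    post_cycle = observations["cycle"].to_numpy() > max_cycle
    post_event = (observations["t"].to_numpy() > T) & ~post_cycle
    keep = ~(post_cycle | post_event)
    drops = {f"post_cycle{max_cycle}": int(post_cycle.sum()),
             "post_event_time": int(post_event.sum())}
    return observations[keep].reset_index(drop=True), drops


def completion_table(observations: pd.DataFrame, survival: pd.DataFrame,
                     cycle_length: float = 0.7, max_cycle: int = 6) -> pd.DataFrame:
    """Fraction of at-risk, on-schedule subjects with an observation per cycle.

    The denominator for cycle c counts subjects whose follow-up
    ``min(T_i, max_cycle * cycle_length)`` extends beyond that cycle's
    scheduled window (i.e. is at least ``c * cycle_length``); the numerator
    counts those with an observed cycle-c record.
    """
    horizon = np.minimum(survival["time_months"].to_numpy(),
                         max_cycle * cycle_length)
    ids = survival["subject_id"].to_numpy()
    rows = []
    for c in range(1, max_cycle + 1):
        at_risk = set(ids[horizon >= c * cycle_length])
        if not at_risk:
            rows.append((c, 0, 0, np.nan))
            continue
        observed = set(observations.loc[observations["cycle"] == c,
                                        "subject_id"]) & at_risk
        rows.append((c, len(at_risk), len(observed),
                     len(observed) / len(at_risk)))
    return pd.DataFrame(rows, columns=["cycle", "n_at_risk", "n_observed",
                                       "fraction"])
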