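"""Trial classification, exclusion rules, and update/memory scoring.

All ratings of negative trait adjectives are reverse-coded (r -> 9 - r on
the 1-8 scale) so that higher always means more socially desirable; a trial
is *desirable* when the reverse-coded feedback exceeds the reverse-coded
first rating and *undesirable* when it falls below it.  Per trial,

    feedback discrepancy   = |feedback - first rating|
    update                 = second rating - first rating   (reverse-coded)
    absolute memory error  = |feedback - recollection|      (raw scale)

and per participant and (target x desirability) cell,

    relative absolute mean update = |mean update| / mean feedback discrepancy

i.e. the ratio of means, not the mean of per-trial ratios: a value of 0.3
means ratings moved on average 30% of the way toward the feedback.  Trials
with a missing first or second rating are excluded from update scoring
(they are kept for memory scoring when the recollection is present), and
trials with zero feedback discrepancy are excluded because they cannot be
classified as desirable or undesirable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .task import Valence

__all__ = [
    "reverse_code",
    "classify_desirability",
    "feedback_discrepancy",
    "update",
    "memory_error",
    "aggregate_condition_scores",
    "overall_update",
]

#: Columns of the per-participant-per-cell score table, in output order.
SCORE_COLUMNS = [
    "participant_id",
    "target",
    "desirability",
    "relative_absolute_mean_update",
    "signed_relative_mean_update",
    "mean_absolute_update",
    "mean_feedback_discrepancy",
    "mean_absolute_memory_error",
    "n_trials_final",
    "n_missing_excluded",
    "n_zero_excluded",
    "n_memory_trials",
]


def reverse_code(rating, valence):
    """Mirror ratings of negative traits onto the desirability scale.

    Positive valence is the identity; negative valence maps r -> 9 - r.
    Works element-wise on arrays (with an array-valued ``valence``) and on
    scalars; values must lie within [1, 8].
    """
    r = np.asarray(rating, dtype=float)
    if np.any((r[~np.isnan(r)] < 1) | (r[~np.isnan(r)] > 8)):
        raise ValueError("ratings must lie within [1, 8]")
    neg = np.asarray(valence) == Valence.negative.value
    out = np.where(neg, 9.0 - r, r)
    return float(out) if np.isscalar(rating) else out


def classify_desirability(first_recoded, feedback_recoded) -> str:
    """Classify one trial from reverse-coded first rating and feedback.

    Returns ``"missing"`` when either input is absent (such trials are
    flagged rather than classified), ``"neutral"`` on equality (these are
    the zero-discrepancy trials, excluded downstream)."""
    if (
        first_recoded is None
        or feedback_recoded is None
        or np.isnan(first_recoded)
        or np.isnan(feedback_recoded)
    ):
        return "missing"
    if feedback_recoded > first_recoded:
        return "desirable"
    if feedback_recoded < first_recoded:
        return "undesirable"
    return "neutral"


def feedback_discrepancy(first, feedback):
    """|feedback - first|; invariant under joint reverse coding."""
    return abs(feedback - first)


def update(first, second):
    """second - first on the reverse-coded scale; positive updates move in
    the socially desirable direction."""
    return second - first


def memory_error(feedback, recollection):
    """|feedback - recollection| on the raw display scale."""
    return abs(feedback - recollection)


def _classified(trials: pd.DataFrame) -> pd.DataFrame:
    """Annotate a trial table with reverse-coded values, desirability and
    per-trial scores (vectorised)."""
    t = trials.copy()
    val = t["valence"].to_numpy()
    t["first_rc"] = reverse_code(t["first_rating"].to_numpy(float), val)
    t["second_rc"] = reverse_code(t["second_rating"].to_numpy(float), val)
    t["feedback_rc"] = reverse_code(t["feedback"].to_numpy(float), val)
    t["discrepancy"] = np.abs(t["feedback_rc"] - t["first_rc"])
    with np.errstate(invalid="ignore"):
        t["desirability"] = np.select(
            [t["feedback_rc"] > t["first_rc"], t["feedback_rc"] < t["first_rc"]],
            ["desirable", "undesirable"],
            default="neutral",
        )
    t.loc[t["first_rc"].isna(), "desirability"] = "missing"
    t["update"] = t["second_rc"] - t["first_rc"]
    t["memory_err"] = np.abs(
        t["feedback"].to_numpy(float) - t["recollection"].to_numpy(float)
    )
    return t


def aggregate_condition_scores(
    trials: pd.DataFrame, extra_keys: tuple[str, ...] = ()
) -> pd.DataFrame:
    """Per-participant condition scores for each (target x desirability) cell.

    Update scoring uses trials with both ratings present and a nonzero
    feedback discrepancy; the relative absolute mean update is the absolute
    value of (mean update / mean discrepancy) within the cell.  Memory
    scoring uses trials with a first rating, nonzero discrepancy, and a
    recollection present (the second rating may be missing).  Cells with no
    update-scorable trials get NaN scores.

    ``extra_keys`` adds grouping columns (e.g. ``("valence",)`` for the
    valence-split analysis).  Exclusion counts are reported per cell for the
    classifiable trials plus, under ``desirability == "all"`` pseudo-cells,
    the per-target totals of missing-response trials (which cannot be
    assigned a desirability).
    """
    required = {
        "participant_id",
        "target",
        "valence",
        "first_rating",
        "feedback",
        "second_rating",
        "recollection",
    }
    missing_cols = required - set(trials.columns)
    if missing_cols:
        raise ValueError(f"trial table lacks columns: {sorted(missing_cols)}")

    t = _classified(trials)
    keys = ["participant_id", "target", *extra_keys]

    # Exclusion order: missing-response trials first, then zero-discrepancy
    # among the complete trials (so the two counts never overlap).
    t["missing_resp"] = t["first_rc"].isna() | t["second_rc"].isna()
    t["zero_disc"] = ~t["missing_resp"] & (t["discrepancy"] == 0)

    scorable = t[~t["missing_resp"] & ~t["zero_disc"]]
    mem = t[
        ~t["first_rc"].isna()
        & ~t["zero_disc"]
        & (t["desirability"] != "missing")
        & ~t["memory_err"].isna()
    ]

    cell_keys = keys + ["desirability"]
    grouped = scorable.groupby(cell_keys, observed=True)
    agg = grouped.agg(
        mean_update=("update", "mean"),
        mean_feedback_discrepancy=("discrepancy", "mean"),
        mean_absolute_update=("update", lambda u: np.mean(np.abs(u))),
        n_trials_final=("update", "size"),
    )
    agg["signed_relative_mean_update"] = (
        agg["mean_update"] / agg["mean_feedback_discrepancy"]
    )
    agg["relative_absolute_mean_update"] = agg["signed_relative_mean_update"].abs()

    mem_agg = mem.groupby(cell_keys, observed=True).agg(
        mean_absolute_memory_error=("memory_err", "mean"),
        n_memory_trials=("memory_err", "size"),
    )

    zero_counts = (
        t[t["zero_disc"]].groupby(keys, observed=True).size().rename("n_zero_excluded")
    )
    missing_counts = (
        t[t["missing_resp"]]
        .groupby(keys, observed=True)
        .size()
        .rename("n_missing_excluded")
    )

    # complete cell index: every participant x target x desirability level
    participants = t["participant_id"].unique()
    targets = t["target"].unique()
    extra_levels = [t[k].unique() for k in extra_keys]
    idx = pd.MultiIndex.from_product(
        [participants, targets, *extra_levels, ["desirable", "undesirable"]],
        names=cell_keys,
    )
    out = agg.join(mem_agg, how="outer").reindex(idx)
    out = out.join(zero_counts, on=keys).join(missing_counts, on=keys)
    for c in ("n_trials_final", "n_memory_trials", "n_zero_excluded", "n_missing_excluded"):
        out[c] = out[c].fillna(0).astype(int)
    out = out.reset_index()
    cols = SCORE_COLUMNS.copy()
    for k in extra_keys:
        cols.insert(2, k)
    return out[cols]


def overall_update(scores: pd.DataFrame) -> pd.Series:
    """Overall relative absolute mean update per participant: the unweighted
    mean across the four (target x desirability) cells."""
    return scores.groupby("participant_id", observed=True)[
        "relative_absolute_mean_update"
    ].mean()
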