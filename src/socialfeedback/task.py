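"""Trait-feedback paradigm: stimuli, trial schedules, and the feedback engine.

The paradigm presents a participant with trait adjectives (half positive,
half negative in valence).  On each trial the participant rates how much a
trait applies to a target (themselves or one other person) on an integer
Likert scale from 1 to 8, then sees a "peer feedback" rating — a decimal
value on a fixed grid from 1.0 to 8.0 in steps of 0.3.  The absolute
difference between the first rating and the feedback is the *feedback
discrepancy*, the experimentally manipulated independent variable.

This module generates the stimulus set, the run-by-run trial schedule
(each adjective appears exactly once per target, spread over runs with
balanced valence), and the feedback values themselves via a seeded engine
that controls the discrepancy magnitude, the direction of the feedback on
the desirability scale, and the rate of zero-discrepancy trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "Valence",
    "Target",
    "FEEDBACK_GRID",
    "GRID_STEP",
    "TraitAdjective",
    "FeedbackEngineParams",
    "build_stimulus_set",
    "build_schedule",
    "generate_feedback",
    "snap_to_grid",
]


class Valence(str, Enum):
    positive = "positive"
    negative = "negative"


class Target(str, Enum):
    self = "self"
    other = "other"


GRID_STEP = 0.3

#: The feedback display grid: 1.0, 1.3, ..., 7.9 plus the 8.0 endpoint.
#: 1.0 + 0.3k stops at 7.9 for k = 23; the scale endpoint 8.0 is appended so
#: that both printed endpoints of the rating scale are reachable.
FEEDBACK_GRID = np.round(np.append(1.0 + GRID_STEP * np.arange(24), 8.0), 1)


def snap_to_grid(values):
    """Snap value(s) to the nearest point of the feedback grid.

    Ties (exactly halfway between two grid points) go to the lower point.
    Accepts scalars or arrays; always returns values inside [1.0, 8.0].
    """
    arr = np.asarray(values, dtype=float)
    idx = np.searchsorted(FEEDBACK_GRID, arr)
    idx = np.clip(idx, 1, len(FEEDBACK_GRID) - 1)
    lo = FEEDBACK_GRID[idx - 1]
    hi = FEEDBACK_GRID[idx]
    out = np.where(arr - lo <= hi - arr, lo, hi)
    return float(out) if np.isscalar(values) else out


@dataclass(frozen=True)
class TraitAdjective:
    """A trait word stimulus with a predefined social valence."""

    label: str
    valence: Valence


@dataclass
class FeedbackEngineParams:
    """Parameters of the feedback-generation engine.

    discrepancy_magnitude_range : (low, high) in rating units; magnitudes
        are drawn uniformly over multiples of the 0.3 grid step inside this
        range.  The default (0.3, 3.6) yields realized mean absolute
        discrepancies near 1.9 rating points.
    zero_discrepancy_probability : probability of a feedback value placed as
        close to the first rating as the grid allows (a "confirmation"
        trial; such trials cannot be classified as desirable or undesirable
        and are excluded from update scoring).
    desirable_probability : probability that the drawn discrepancy points in
        the desirable direction on the reverse-coded scale.
    """

    discrepancy_magnitude_range: tuple[float, float] = (0.3, 3.6)
    zero_discrepancy_probability: float = 0.07
    desirable_probability: float = 0.5
    rng_seed: int = 0

    def __post_init__(self):
        lo, hi = self.discrepancy_magnitude_range
        if not (0 <= lo <= hi):
            raise ValueError(
                "discrepancy_magnitude_range must satisfy 0 <= low <= high, "
                f"got {self.discrepancy_magnitude_range}"
            )
        for name in ("zero_discrepancy_probability", "desirable_probability"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")

    def magnitude_choices(self) -> np.ndarray:
        """Grid-step multiples inside the configured magnitude range."""
        lo, hi = self.discrepancy_magnitude_range
        kmin = int(np.ceil(round(lo / GRID_STEP, 9)))
        kmax = int(np.floor(round(hi / GRID_STEP, 9)))
        kmin = max(kmin, 1)
        if kmax < kmin:
            raise ValueError(
                "discrepancy_magnitude_range contains no positive grid multiple"
            )
        return np.round(GRID_STEP * np.arange(kmin, kmax + 1), 1)


def build_stimulus_set(
    n_positive: int = 40,
    n_negative: int = 40,
    labels: list[str] | None = None,
) -> list[TraitAdjective]:
    """Build a stimulus set of trait adjectives with fixed valence counts.

    With no explicit labels, deterministic placeholder labels ``pos_01`` ...
    ``neg_40`` are generated.  Labels must be unique.
    """
    if n_positive < 1 or n_negative < 1:
        raise ValueError("need at least one adjective of each valence")
    n = n_positive + n_negative
    if labels is None:
        width = len(str(max(n_positive, n_negative)))
        labels = [f"pos_{i + 1:0{width}d}" for i in range(n_positive)] + [
            f"neg_{i + 1:0{width}d}" for i in range(n_negative)
        ]
    if len(labels) != n:
        raise ValueError(f"expected {n} labels, got {len(labels)}")
    if len(set(labels)) != n:
        raise ValueError("stimulus labels must be unique")
    valences = [Valence.positive] * n_positive + [Valence.negative] * n_negative
    return [TraitAdjective(lab, val) for lab, val in zip(labels, valences)]


def build_schedule(
    stimuli: list[TraitAdjective],
    n_runs: int = 4,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Allocate adjectives to runs and interleave self/other trials.

    Each run uses ``len(stimuli) / n_runs`` distinct adjectives with equal
    valence counts; every adjective is shown twice within its run, once per
    target, and the self/other trials are randomly intermixed.  Adjectives
    are assigned to runs at random under the seed.

    Returns a tidy frame with columns ``run`` (1-based), ``order_index``
    (position within run), ``target``, ``adjective`` and ``valence``.
    """
    n = len(stimuli)
    if n == 0 or n % n_runs != 0:
        raise ValueError(f"{n} stimuli cannot be split evenly into {n_runs} runs")
    pos = [s for s in stimuli if s.valence == Valence.positive]
    neg = [s for s in stimuli if s.valence == Valence.negative]
    if len(pos) != len(neg):
        raise ValueError("stimulus set must have equal valence counts")
    per_run_half = len(pos) // n_runs
    if per_run_half * n_runs != len(pos):
        raise ValueError("valence counts must divide evenly into runs")

    rng = np.random.default_rng(rng_seed)
    pos = [pos[i] for i in rng.permutation(len(pos))]
    neg = [neg[i] for i in rng.permutation(len(neg))]

    rows = []
    for run in range(1, n_runs + 1):
        chunk = (
            pos[(run - 1) * per_run_half : run * per_run_half]
            + neg[(run - 1) * per_run_half : run * per_run_half]
        )
        slots = [(adj, tgt) for adj in chunk for tgt in (Target.self, Target.other)]
        order = rng.permutation(len(slots))
        for order_index, j in enumerate(order):
            adj, tgt = slots[j]
            rows.append(
                {
                    "run": run,
                    "order_index": order_index,
                    "target": tgt.value,
                    "adjective": adj.label,
                    "valence": adj.valence.value,
                }
            )
    return pd.DataFrame(rows)


def _generate_feedback_array(
    first_ratings: np.ndarray,
    valences: np.ndarray,
    params: FeedbackEngineParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized feedback draw; see :func:`generate_feedback`."""
    first = np.asarray(first_ratings, dtype=float)
    if np.any((first < 1) | (first > 8)):
        raise ValueError("first ratings must lie in 1..8")
    negative = np.asarray(valences) == Valence.negative.value

    n = first.shape[0]
    zero = rng.random(n) < params.zero_discrepancy_probability
    desirable = rng.random(n) < params.desirable_probability
    mags = rng.choice(params.magnitude_choices(), size=n)

    # Desirable feedback exceeds the first rating on the reverse-coded scale,
    # which on the raw scale means "up" for positive traits and "down" for
    # negative ones.
    sign = np.where(desirable, 1.0, -1.0) * np.where(negative, -1.0, 1.0)
    target = np.clip(first + sign * mags, 1.0, 8.0)
    fb = snap_to_grid(np.where(zero, first, target))
    return fb


def generate_feedback(
    first_rating: int,
    valence: Valence | str,
    params: FeedbackEngineParams,
    rng: np.random.Generator,
) -> float:
    """Draw one feedback value for a trial.

    With probability ``zero_discrepancy_probability`` the feedback is the
    grid value nearest the first rating.  Otherwise a discrepancy magnitude
    is drawn uniformly over grid multiples in the configured range, pointed
    in the desirable direction (on the reverse-coded scale) with probability
    ``desirable_probability``, added to the first rating, clamped to
    [1.0, 8.0] and snapped to the grid.  Snapping never crosses the first
    rating, so the drawn direction is preserved; clamping at the scale
    endpoints can collapse the discrepancy to zero (e.g. a desirable draw on
    a trait already rated 8).
    """
    if not 1 <= first_rating <= 8:
        raise ValueError(f"first rating must lie in 1..8, got {first_rating}")
    valence = Valence(valence)
    out = _generate_feedback_array(
        np.array([first_rating]), np.array([valence.value]), params, rng
    )
    return float(out[0])
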