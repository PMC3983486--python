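"""Synthetic cohort generator for the trait-feedback paradigm.

Produces participant tables (two cultural groups tested in two places, with
questionnaire covariates) and trial-level logs with the behavioural
structure the downstream analysis assumes:

* integer first ratings 1..8 on the reverse-coded scale, self rated more
  positively than the other person;
* partial updating of the second rating toward the feedback, stronger for
  desirable than undesirable feedback and stronger in the more
  interdependent cultural group;
* noisy recollection of the feedback value, more accurate for self- than
  other-related feedback;
* occasional missing responses.

The update model is linear partial adjustment: on the reverse-coded scale

    second = round(first + alpha * (feedback - first) + eps),  eps ~ N(0, sd)

clamped to 1..8, with a per-cell update fraction ``alpha`` in [0, 1].  The
per-condition relative absolute mean update computed by the scoring layer
is then an (approximately unbiased) estimate of ``alpha``, which makes
parameter recovery a direct validation of the whole pipeline.  Participant
heterogeneity and the interdependence link act additively on the logit of
alpha so alpha stays inside [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .task import (
    FeedbackEngineParams,
    Target,
    Valence,
    _generate_feedback_array,
    build_schedule,
    build_stimulus_set,
    snap_to_grid,
)

__all__ = [
    "Participant",
    "AgentParams",
    "CohortConfig",
    "simulate_participants",
    "simulate_first_rating",
    "simulate_update",
    "simulate_recollection",
    "simulate_cohort_trials",
    "recovery_config",
]

CULTURES = ("German", "Chinese")
PLACES = ("Berlin", "Beijing")
GROUPS = [(c, p) for c in CULTURES for p in PLACES]

#: Questionnaire covariate calibration per (culture, place) group:
#: (mean, sd) for each score, plus the admissible scale range.
#: Interdependence/independence are 1-7 scale means (24-item self-construal
#: scale), self-esteem is the 10-40 Rosenberg sum score, perceived
#: similarity is a single 1-8 Likert item.
COVARIATE_CALIBRATION = {
    "interdependence": {
        ("German", "Berlin"): (3.10, 0.53),
        ("German", "Beijing"): (3.58, 0.38),
        ("Chinese", "Berlin"): (3.71, 0.38),
        ("Chinese", "Beijing"): (3.89, 0.41),
        "range": (1.0, 7.0),
    },
    "independence": {
        ("German", "Berlin"): (3.72, 0.30),
        ("German", "Beijing"): (3.85, 0.32),
        ("Chinese", "Berlin"): (3.58, 0.36),
        ("Chinese", "Beijing"): (3.47, 0.43),
        "range": (1.0, 7.0),
    },
    "self_esteem": {
        ("German", "Berlin"): (23.0, 5.35),
        ("German", "Beijing"): (23.6, 3.57),
        ("Chinese", "Berlin"): (20.6, 5.40),
        ("Chinese", "Beijing"): (21.7, 4.36),
        "range": (10.0, 40.0),
    },
    "perceived_similarity": {
        ("German", "Berlin"): (3.67, 1.47),
        ("German", "Beijing"): (4.06, 1.63),
        ("Chinese", "Berlin"): (3.79, 1.77),
        ("Chinese", "Beijing"): (4.24, 1.13),
        "range": (1.0, 8.0),
    },
}

#: Grand mean interdependence across the four calibrated groups; the
#: interdependence -> alpha slope is applied to deviations from this value.
INTERDEPENDENCE_CENTER = 3.57


@dataclass(frozen=True)
class Participant:
    id: str
    culture: str
    place: str
    interdependence: float
    independence: float
    self_esteem: float
    perceived_similarity: float


@dataclass
class AgentParams:
    """Generative parameters of one simulated participant.

    ``alpha`` maps (target, desirability) to the update fraction in [0, 1].
    ``alpha_interdependence_slope`` is the logit-scale increment in alpha
    per interdependence point above the grand mean (applied when agents are
    built for a cohort).  Rating means are on the reverse-coded scale;
    ``first_rating_sd`` is the trial-to-trial spread across adjectives.
    """

    alpha: dict = field(
        default_factory=lambda: {
            ("self", "desirable"): 0.40,
            ("self", "undesirable"): 0.09,
            ("other", "desirable"): 0.40,
            ("other", "undesirable"): 0.13,
        }
    )
    alpha_interdependence_slope: float = 0.4
    update_noise_sd: float = 0.5
    first_rating_mean_self: float = 5.60
    first_rating_mean_other: float = 5.35
    first_rating_sd: float = 1.4
    memory_noise_sd_self: float = 2.3
    memory_noise_sd_other: float = 2.6
    response_missing_probability: float = 0.04

    def __post_init__(self):
        for cell, a in self.alpha.items():
            if not 0 <= a <= 1:
                raise ValueError(f"alpha{cell} must lie in [0, 1], got {a}")
        for name in (
            "update_noise_sd",
            "first_rating_sd",
            "memory_noise_sd_self",
            "memory_noise_sd_other",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.response_missing_probability <= 1:
            raise ValueError("response_missing_probability must lie in [0, 1]")


@dataclass
class CohortConfig:
    """Cohort-level configuration.

    Defaults reproduce the calibrated study conditions: group sizes
    27/24/28/25, covariates per ``COVARIATE_CALIBRATION``, a +-0.12
    logit-scale culture offset on the update fraction (Chinese higher), a
    logit-sd of 0.8 for participant-level alpha heterogeneity, and a 0.5
    between-participant sd on first-rating means.
    """

    group_sizes: dict = field(
        default_factory=lambda: {
            ("German", "Berlin"): 27,
            ("German", "Beijing"): 24,
            ("Chinese", "Berlin"): 28,
            ("Chinese", "Beijing"): 25,
        }
    )
    group_alpha_offsets: dict = field(
        default_factory=lambda: {"German": -0.12, "Chinese": 0.12}
    )
    alpha_logit_sd: float = 0.5
    alpha_cell_logit_sd: float = 1.0
    first_rating_between_sd: float = 0.5
    agent: AgentParams = field(default_factory=AgentParams)
    rng_seed: int = 0

    def __post_init__(self):
        for g, n in self.group_sizes.items():
            if n < 0:
                raise ValueError(f"group size for {g} must be >= 0")
        if (
            self.alpha_logit_sd < 0
            or self.alpha_cell_logit_sd < 0
            or self.first_rating_between_sd < 0
        ):
            raise ValueError("between-participant sds must be non-negative")


def _truncnorm(mean, sd, lo, hi, size, rng):
    if sd == 0:
        return np.full(size, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_participants(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw the participant table from truncated-normal covariate models."""
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    frames = []
    counter = 0
    for culture, place in GROUPS:
        n = config.group_sizes.get((culture, place), 0)
        if n == 0:
            continue
        cols = {"culture": culture, "place": place}
        for cov, calib in COVARIATE_CALIBRATION.items():
            mean, sd = calib[(culture, place)]
            lo, hi = calib["range"]
            cols[cov] = _truncnorm(mean, sd, lo, hi, n, rng)
        ids = [f"p{counter + i:04d}" for i in range(n)]
        counter += n
        frames.append(pd.DataFrame({"participant_id": ids, **cols}))
    if not frames:
        raise ValueError("all group sizes are zero")
    return pd.concat(frames, ignore_index=True)


def simulate_first_rating(
    agent: AgentParams, target: Target | str, rng: np.random.Generator
) -> int:
    """One integer first rating on the reverse-coded scale: round(N(mu, sd))
    clamped to 1..8."""
    mu = (
        agent.first_rating_mean_self
        if Target(target) == Target.self
        else agent.first_rating_mean_other
    )
    draw = rng.normal(mu, agent.first_rating_sd)
    return int(np.clip(np.rint(draw), 1, 8))


def simulate_update(
    agent: AgentParams,
    first: int,
    feedback: float,
    target: Target | str,
    desirability: str,
    rng: np.random.Generator,
) -> int:
    """Second rating on the reverse-coded scale under partial adjustment."""
    a = agent.alpha[(Target(target).value, desirability)]
    raw = first + a * (feedback - first) + rng.normal(0, agent.update_noise_sd)
    return int(np.clip(np.rint(raw), 1, 8))


def simulate_recollection(
    agent: AgentParams,
    feedback: float,
    target: Target | str,
    rng: np.random.Generator,
) -> float:
    """Noisy recollection of the raw feedback value, snapped to the grid."""
    sd = (
        agent.memory_noise_sd_self
        if Target(target) == Target.self
        else agent.memory_noise_sd_other
    )
    return float(snap_to_grid(np.clip(feedback + rng.normal(0, sd), 1.0, 8.0)))


def _logit(p):
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return np.log(p / (1 - p))


def _build_agent_alphas(
    participants: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-participant alpha for each (target, desirability) cell.

    logit(alpha_cell) = logit(base_cell) + culture offset
                        + slope * (interdependence - center)
                        + eps_participant + eps_participant_cell

    ``eps_participant`` (sd ``alpha_logit_sd``) is a general conformity
    disposition shared across cells; ``eps_participant_cell``
    (sd ``alpha_cell_logit_sd``) is cell-specific, reflecting that a
    person's receptiveness to desirable and undesirable feedback are only
    weakly coupled.
    """
    n = len(participants)
    eps = rng.normal(0, config.alpha_logit_sd, size=n)
    offs = participants["culture"].map(config.group_alpha_offsets).to_numpy(float)
    slope_term = config.agent.alpha_interdependence_slope * (
        participants["interdependence"].to_numpy(float) - INTERDEPENDENCE_CENTER
    )
    out = {}
    for cell, base in config.agent.alpha.items():
        eps_cell = rng.normal(0, config.alpha_cell_logit_sd, size=n)
        logit = _logit(base) + offs + slope_term + eps + eps_cell
        out[cell] = 1.0 / (1.0 + np.exp(-logit))
    return pd.DataFrame(out, index=participants.index)


def implied_alpha_table(
    config: CohortConfig, n_per_group: int = 10_000, rng_seed: int = 12345
) -> pd.DataFrame:
    """Monte-Carlo table of participant-level alphas implied by the config.

    Used as an analytic oracle for what the scoring layer should recover:
    it samples the alpha-generation process alone, without simulating any
    trials, ratings or rounding.
    """
    cfg = replace(
        config,
        group_sizes={g: n_per_group for g in GROUPS},
        rng_seed=rng_seed,
    )
    rng = np.random.default_rng(rng_seed)
    parts = simulate_participants(cfg, rng)
    alphas = _build_agent_alphas(parts, cfg, rng)
    alphas.columns = [f"alpha_{t}_{d}" for t, d in alphas.columns]
    return pd.concat([parts, alphas], axis=1)


def simulate_cohort_trials(
    config: CohortConfig,
    engine_params: FeedbackEngineParams | None = None,
    schedule: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full cohort: participant table plus trial log.

    Each participant gets their own random adjective-to-run allocation
    unless an explicit shared ``schedule`` is passed.  The returned trial
    log has one row per scheduled trial (160 at defaults) with raw-scale
    values; missing responses appear as empty (NaN) first/second ratings or
    recollections.  Fully deterministic under ``config.rng_seed``.
    """
    engine_params = engine_params or FeedbackEngineParams()
    rng = np.random.default_rng(config.rng_seed)
    participants = simulate_participants(config, rng)
    alphas = _build_agent_alphas(participants, config, rng)
    agent = config.agent

    stimuli = build_stimulus_set()
    # per-participant deviations of mean first ratings (shared self/other)
    mean_shift = rng.normal(0, config.first_rating_between_sd, len(participants))

    frames = []
    for i, row in participants.iterrows():
        sched = (
            schedule
            if schedule is not None
            else build_schedule(stimuli, 4, rng_seed=int(rng.integers(2**31)))
        )
        sched = sched.reset_index(drop=True)
        nt = len(sched)
        is_self = (sched["target"] == Target.self.value).to_numpy()
        negative = (sched["valence"] == Valence.negative.value).to_numpy()

        # first ratings on the reverse-coded scale
        mu = np.where(
            is_self,
            agent.first_rating_mean_self,
            agent.first_rating_mean_other,
        ) + mean_shift[i]
        first_rc = np.clip(
            np.rint(rng.normal(mu, agent.first_rating_sd)), 1, 8
        ).astype(int)
        first_raw = np.where(negative, 9 - first_rc, first_rc)

        feedback = _generate_feedback_array(
            first_raw, sched["valence"].to_numpy(), engine_params, rng
        )
        fb_rc = np.where(negative, 9.0 - feedback, feedback)

        desirable = fb_rc > first_rc
        a_cell = np.empty(nt)
        for tgt in ("self", "other"):
            for des, mask_des in (("desirable", desirable), ("undesirable", ~desirable)):
                m = (is_self == (tgt == "self")) & mask_des
                a_cell[m] = alphas.at[i, (tgt, des)]

        second_rc = np.clip(
            np.rint(
                first_rc
                + a_cell * (fb_rc - first_rc)
                + rng.normal(0, agent.update_noise_sd, nt)
            ),
            1,
            8,
        ).astype(int)
        second_raw = np.where(negative, 9 - second_rc, second_rc)

        mem_sd = np.where(is_self, agent.memory_noise_sd_self, agent.memory_noise_sd_other)
        recollection = snap_to_grid(
            np.clip(feedback + rng.normal(0, mem_sd), 1.0, 8.0)
        )

        p_half = agent.response_missing_probability / 2.0
        first_out = first_raw.astype(float)
        second_out = second_raw.astype(float)
        rec_out = recollection.astype(float)
        first_out[rng.random(nt) < p_half] = np.nan
        second_out[rng.random(nt) < p_half] = np.nan
        rec_out[rng.random(nt) < p_half] = np.nan

        frames.append(
            pd.DataFrame(
                {
                    "participant_id": row["participant_id"],
                    "run": sched["run"],
                    "order_index": sched["order_index"],
                    "target": sched["target"],
                    "adjective": sched["adjective"],
                    "valence": sched["valence"],
                    "first_rating": first_out,
                    "feedback": feedback,
                    "second_rating": second_out,
                    "recollection": rec_out,
                }
            )
        )
    trials = pd.concat(frames, ignore_index=True)
    return trials, participants


def recovery_config(
    alpha: float,
    n_participants: int = 100,
    update_noise_sd: float = 0.5,
    rng_seed: int = 0,
) -> CohortConfig:
    """Config for parameter-recovery runs: one known update fraction in all
    cells, no culture offsets, no interdependence link, no participant
    heterogeneity."""
    agent = AgentParams(
        alpha={
            ("self", "desirable"): alpha,
            ("self", "undesirable"): alpha,
            ("other", "desirable"): alpha,
            ("other", "undesirable"): alpha,
        },
        alpha_interdependence_slope=0.0,
        update_noise_sd=update_noise_sd,
    )
    quarter = n_participants // 4
    sizes = dict(
        zip(GROUPS, [quarter, quarter, quarter, n_participants - 3 * quarter])
    )
    return CohortConfig(
        group_sizes=sizes,
        group_alpha_offsets={"German": 0.0, "Chinese": 0.0},
        alpha_logit_sd=0.0,
        alpha_cell_logit_sd=0.0,
        agent=agent,
        rng_seed=rng_seed,
    )
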