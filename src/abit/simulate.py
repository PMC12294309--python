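"""Seeded generator of synthetic ABIT cohorts with known ground truth.

Each child carries a scalar latent awake-bruxism propensity ``theta`` — the
mean number of AB events per day.  The three behaviors share it through fixed
multipliers (clenching most perceived, then bracing/thrusting, then
grinding).  Daily event counts are Poisson(theta) truncated at the 6 slots
the paper sheet offers; a child paints each occurring event with probability
``adherence``.  Likert answers are derived from the behavior-specific rate
through fixed ordinal thresholds, then perturbed one category up or down with
probability ``report_noise``.  Clinical findings are per-finding Bernoulli
draws whose probability depends on the child's active/inactive status and,
being physical signs, are stable across the 15-day test-retest interval.

Test and retest administrations are coupled two ways: the latent propensity
is paired through a Gaussian copula with correlation ``retest_rho``, and all
behavioral draws use common random numbers (one uniform stream per child,
shared across stages, consumed through inverse CDFs).  With ``retest_rho=1``
and ``report_noise=0`` the paired records are therefore identical; only the
report-noise draws are stage-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    BehaviorTriplet,
    ClinicalExam,
    EMADiary,
    LikertResponse,
    ParticipantRecord,
    Source,
    Stage,
    ECA_FINDINGS,
    ICA_FINDINGS,
)

__all__ = ["SimulationParams", "simulate_participant", "simulate_cohort"]

#: Per-behavior multipliers on the latent rate (grinding, clenching, bracing).
BEHAVIOR_MULTIPLIERS = (0.5, 1.0, 0.9)

#: Ordinal thresholds (events/day) separating the five Likert categories.
LIKERT_RATE_CUTS = (0.05, 0.35, 1.0, 2.5)

#: Log-normal dispersion of theta around its group mean.
THETA_SIGMA = 0.5

#: FDI identifiers of the index teeth inspected for wear.
WEAR_TEETH = ("16", "26", "36", "46", "11", "21", "31", "41")

_LIKERT_BY_SCORE = [
    LikertResponse.NEVER,
    LikertResponse.ALMOST_NEVER,
    LikertResponse.SOMETIMES,
    LikertResponse.MOST_OF_TIME,
    LikertResponse.ALWAYS,
]


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for one simulated cohort.

    Defaults emulate a pilot-scale clinic sample: 10 children, 40% with a
    latent AB propensity averaging 1.5 events/day against a 0.05 background,
    moderate reporting noise, imperfect diary adherence, and a strong but
    imperfect 15-day retest correlation.
    """

    n_participants: int = 10
    prevalence: float = 0.4
    theta_active: float = 1.5
    theta_inactive: float = 0.05
    report_noise: float = 0.1
    clinical_prob_active: float = 0.15
    clinical_prob_inactive: float = 0.03
    retest_rho: float = 0.9
    adherence: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "prevalence",
            "report_noise",
            "clinical_prob_active",
            "clinical_prob_inactive",
            "retest_rho",
            "adherence",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("theta_active", "theta_inactive"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name}={v} must be finite and non-negative")
        if self.n_participants < 0:
            raise ValueError("n_participants must be non-negative")


def _shared_draws(params: SimulationParams, index: int) -> dict:
    """The child-level uniform block shared between test and retest."""
    rng = np.random.default_rng([params.seed, index])
    return {
        "u_active": rng.random(),
        "z_pair": rng.standard_normal(2),
        "age": int(rng.integers(8, 13)),
        "u_events": rng.random(7),
        "u_paint": rng.random(7),
        "slot_order": np.stack([rng.permutation(6) for _ in range(7)]),
        "u_clinical": rng.random(len(ICA_FINDINGS) + len(ECA_FINDINGS)),
        "u_wear": rng.random(len(WEAR_TEETH)),
        "u_sb": rng.random(),
    }


def _likert_base(rate: float) -> int:
    return int(np.searchsorted(LIKERT_RATE_CUTS, rate, side="right"))


def _triplet(
    source: Source, theta: float, noise: float, rng_noise: np.random.Generator
) -> BehaviorTriplet:
    answers = []
    for mult in BEHAVIOR_MULTIPLIERS:
        cat = _likert_base(theta * mult)
        if rng_noise.random() < noise:
            cat += 1 if rng_noise.random() < 0.5 else -1
            cat = int(np.clip(cat, 0, 4))
        answers.append(_LIKERT_BY_SCORE[cat])
    return BehaviorTriplet(source, *answers)


def _diary(theta: float, adherence: float, draws: dict) -> EMADiary:
    grid = np.zeros((7, 6), dtype=bool)
    for day in range(7):
        if theta > 0:
            events = max(0, int(stats.poisson.ppf(draws["u_events"][day], theta)))
        else:
            events = 0
        events = min(events, 6)  # the sheet offers 6 slots per day
        painted = (
            max(0, int(stats.binom.ppf(draws["u_paint"][day], events, adherence)))
            if events and adherence > 0
            else 0
        )
        for slot in draws["slot_order"][day][:painted]:
            grid[day, slot] = True
    return EMADiary(grid)


def _exam(active: bool, params: SimulationParams, draws: dict) -> ClinicalExam:
    p = params.clinical_prob_active if active else params.clinical_prob_inactive
    flags = draws["u_clinical"] < p
    findings = dict(zip(ICA_FINDINGS + ECA_FINDINGS, (bool(f) for f in flags)))
    wear: dict[str, int] = {}
    for tooth, u in zip(WEAR_TEETH, draws["u_wear"]):
        if u < p:  # worn at all; deeper wear is half as likely again
            wear[tooth] = 2 if u < p / 2 else 1
    return ClinicalExam(tooth_wear=wear, **findings)


def simulate_participant(
    params: SimulationParams,
    latent_theta: float,
    *,
    index: int = 0,
    stage: Stage = Stage.TEST,
    participant_id: str | None = None,
    active: bool | None = None,
) -> tuple[ParticipantRecord, dict]:
    """Simulate one participant-stage record at a given latent propensity.

    ``index`` selects the child's shared random stream, so calling twice with
    the same params, index and theta reproduces the record exactly, and
    calling with different stages couples them through common random numbers.
    Returns the record and a ground-truth dict.
    """
    draws = _shared_draws(params, index)
    if active is None:
        active = draws["u_active"] < params.prevalence
    rng_noise = np.random.default_rng(
        [params.seed, index, 1 if stage is Stage.TEST else 2]
    )
    pid = participant_id or f"P{index + 1:03d}"
    record = ParticipantRecord(
        participant_id=pid,
        age_years=draws["age"],
        stage=stage,
        r1=_triplet(Source.R1, latent_theta, params.report_noise, rng_noise),
        sr=_triplet(Source.SR, latent_theta, params.report_noise, rng_noise),
        r2=_triplet(Source.R2, latent_theta, params.report_noise, rng_noise),
        ema=_diary(latent_theta, params.adherence, draws),
        exam=_exam(active, params, draws),
        sb_reported=bool(draws["u_sb"] < 0.2),
    )
    truth = {
        "participant_id": pid,
        "latent_theta": float(latent_theta),
        "true_label": "AB" if active else "not_AB",
    }
    return record, truth


def _stage_thetas(params: SimulationParams, draws: dict) -> tuple[float, float, bool]:
    """Paired latent propensities via a Gaussian copula on the shared z-draws."""
    active = draws["u_active"] < params.prevalence
    mean = params.theta_active if active else params.theta_inactive
    z1, z2 = draws["z_pair"]
    z_test = z1
    z_retest = params.retest_rho * z1 + np.sqrt(1 - params.retest_rho**2) * z2
    # log-normal with mean equal to the group mean rate
    shift = THETA_SIGMA**2 / 2
    theta_test = mean * np.exp(THETA_SIGMA * z_test - shift)
    theta_retest = mean * np.exp(THETA_SIGMA * z_retest - shift)
    return float(theta_test), float(theta_retest), bool(active)


def simulate_cohort(
    params: SimulationParams,
) -> tuple[list[ParticipantRecord], list[ParticipantRecord], pd.DataFrame]:
    """Simulate paired test/retest cohorts plus a ground-truth table.

    Returns ``(test_cohort, retest_cohort, truth)`` where ``truth`` has one
    row per child: id, active status, both latent propensities and the label.
    """
    test, retest, truth_rows = [], [], []
    for i in range(params.n_participants):
        draws = _shared_draws(params, i)
        theta_t, theta_r, active = _stage_thetas(params, draws)
        rec_t, _ = simulate_participant(
            params, theta_t, index=i, stage=Stage.TEST, active=active
        )
        rec_r, _ = simulate_participant(
            params, theta_r, index=i, stage=Stage.RETEST, active=active
        )
        test.append(rec_t)
        retest.append(rec_r)
        truth_rows.append(
            {
                "participant_id": rec_t.participant_id,
                "latent_theta_test": theta_t,
                "latent_theta_retest": theta_r,
                "true_label": "AB" if active else "not_AB",
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "participant_id",
            "latent_theta_test",
            "latent_theta_retest",
            "true_label",
        ],
    )
    return test, retest, truth
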