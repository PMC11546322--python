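"""Dose-finding engine: TITE-BOIN escalation with backfill cohorts.

Escalation decisions follow the BOIN rule: the estimated DLT probability at
the current dose is compared with two fixed boundaries ``lambda_e < lambda_d``
derived from the target rate; estimates at or below ``lambda_e`` escalate,
above ``lambda_d`` de-escalate, in between retain.  While some patients'
toxicity assessments are still pending, the time-to-event extension imputes
each pending patient's expected DLT indicator as

    p * (1 - t/T) / (1 - p)

where ``t`` is the follow-up time so far, ``T`` the assessment window and
``p`` a plug-in estimate of the dose's DLT probability, assuming toxicity
times are uniform over the window.

Backfilling assigns newly arriving patients to lower doses that have been
tried and look safe, acceptable on QoL, and not futile, subject to a per-dose
sample-size cap and a pending-fraction guard.  Several allocation strategies
are provided, from equal randomization to QoL-adaptive weighting.

This module is deliberately free of simulation concerns: given a trial state
it answers "what should happen next", and :mod:`backfill_qol.simulator` drives
it through simulated time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from .monitoring import DoseStatus, MonitoringConfig, qol_predictive_prob

__all__ = [
    "TrialConfig",
    "PendingRecord",
    "BoinBoundaries",
    "DoseAccrual",
    "TrialState",
    "Move",
    "StopReason",
    "boin_boundaries",
    "impute_dlt_estimate",
    "escalation_decision",
    "escalation_target",
    "backfill_eligible",
    "allocate_backfill",
    "stopping_check",
]

ALLOCATION_STRATEGIES = ("equal", "highest", "qol_adaptive", "pick_winner")
DECISION_VARIANTS = ("standard", "conservative")


class Move(str, Enum):
    ESCALATE = "escalate"
    STAY = "stay"
    DEESCALATE = "deescalate"
    SUSPEND = "suspend"


class StopReason(str, Enum):
    MAX_N = "max_n"
    N_STOP_RETAIN = "n_stop_retain"
    LOWEST_TOXIC = "lowest_toxic"
    EXTERNAL = "external"


@dataclass(frozen=True)
class TrialConfig:
    """Structural parameters of the trial.

    Defaults are a six-dose trial with escalation cohorts of 3 up to 36
    escalation patients, early stop after 9 consecutive patients retained at
    one dose, a 12-patient backfill cap per dose, toxicity/QoL windows of 4
    weeks and an efficacy window of 8 weeks, and an accrual rate of 3
    patients per 4 weeks.
    """

    n_doses: int = 6
    n_escalation_max: int = 36
    cohort_size: int = 3
    n_stop: int = 9
    n_cap: int = 12
    window_tox: float = 4.0
    window_eff: float = 8.0
    window_qol: float = 4.0
    accrual_rate: float = 0.75  # patients per week
    allocation_strategy: str = "equal"
    decision_variant: str = "standard"
    start_dose: int = 1

    def __post_init__(self) -> None:
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be >= 1")
        if self.n_escalation_max < self.cohort_size:
            raise ValueError("n_escalation_max must be >= cohort_size")
        if self.n_stop > self.n_cap:
            raise ValueError("n_stop must be <= n_cap")
        if min(self.window_tox, self.window_eff, self.window_qol) <= 0:
            raise ValueError("assessment windows must be positive")
        if self.accrual_rate <= 0:
            raise ValueError("accrual_rate must be positive")
        if self.allocation_strategy not in ALLOCATION_STRATEGIES:
            raise ValueError(
                f"unknown allocation_strategy {self.allocation_strategy!r}; "
                f"expected one of {ALLOCATION_STRATEGIES}"
            )
        if self.decision_variant not in DECISION_VARIANTS:
            raise ValueError(
                f"unknown decision_variant {self.decision_variant!r}; "
                f"expected one of {DECISION_VARIANTS}"
            )
        if not (1 <= self.start_dose <= self.n_doses):
            raise ValueError("start_dose must be a valid dose index")


@dataclass
class PendingRecord:
    """A patient whose DLT assessment window has not yet elapsed."""

    patient_id: int
    dose_index: int
    follow_up_time: float
    window: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.follow_up_time <= self.window):
            raise ValueError("follow-up time must lie in [0, window]")


@dataclass(frozen=True)
class BoinBoundaries:
    lambda_e: float
    lambda_d: float

    def __post_init__(self) -> None:
        if not (0.0 < self.lambda_e < self.lambda_d < 1.0):
            raise ValueError("need 0 < lambda_e < lambda_d < 1")


@dataclass
class DoseAccrual:
    """Running per-dose tallies kept by the trial state.

    Toxicity, efficacy and QoL have separate observation counts because their
    assessment windows differ; ``n_enrolled`` counts everyone assigned.
    """

    dose_index: int
    n_enrolled: int = 0
    backfill_enrolled: int = 0
    n_tox_assessed: int = 0
    dlt_count: int = 0
    n_eff_assessed: int = 0
    response_count: int = 0
    qol_scores: list[float] = field(default_factory=list)
    pending: list[PendingRecord] = field(default_factory=list)

    @property
    def tried(self) -> bool:
        return self.n_enrolled > 0

    @property
    def n_pending(self) -> int:
        return len(self.pending)

    @property
    def observed_dlt_fraction(self) -> Optional[float]:
        if self.n_tox_assessed == 0:
            return None
        return self.dlt_count / self.n_tox_assessed

    def qol_mean(self) -> Optional[float]:
        if not self.qol_scores:
            return None
        return float(np.mean(self.qol_scores))


@dataclass
class TrialState:
    """Snapshot of an ongoing trial, sufficient for every engine decision."""

    config: TrialConfig
    clock: float = 0.0
    doses: list[DoseAccrual] = field(default_factory=list)
    statuses: list[DoseStatus] = field(default_factory=list)
    current_dose: int = 1
    escalation_enrolled: int = 0
    stop_reason: Optional[StopReason] = None

    def __post_init__(self) -> None:
        if not self.doses:
            self.doses = [DoseAccrual(j + 1) for j in range(self.config.n_doses)]
        if not self.statuses:
            self.statuses = [DoseStatus() for _ in range(self.config.n_doses)]
        self.current_dose = self.config.start_dose

    def dose(self, j: int) -> DoseAccrual:
        return self.doses[j - 1]

    def status(self, j: int) -> DoseStatus:
        return self.statuses[j - 1]

    @property
    def total_enrolled(self) -> int:
        return sum(d.n_enrolled for d in self.doses)


def boin_boundaries(
    phi_dlt: float,
    phi1: Optional[float] = None,
    phi2: Optional[float] = None,
) -> BoinBoundaries:
    """BOIN escalation/de-escalation boundaries for a target DLT rate.

    ``phi1`` and ``phi2`` bracket the target: they are the highest DLT rate
    still considered subtherapeutic and the lowest considered overly toxic,
    defaulting to ``0.6 * phi`` and ``1.4 * phi``.  The boundaries are the
    likelihood-ratio crossings

        lambda_e = log((1-phi1)/(1-phi)) / log(phi (1-phi1) / (phi1 (1-phi)))
        lambda_d = log((1-phi)/(1-phi2)) / log(phi2 (1-phi) / (phi (1-phi2)))
    """
    if not (0.0 < phi_dlt < 1.0):
        raise ValueError("phi_dlt must lie in (0, 1)")
    phi1 = 0.6 * phi_dlt if phi1 is None else phi1
    phi2 = 1.4 * phi_dlt if phi2 is None else phi2
    if not (0.0 <= phi1 < phi_dlt < phi2 <= 1.0):
        raise ValueError("need phi1 < phi_dlt < phi2 (degenerate interval forbidden)")
    lambda_e = math.log((1 - phi1) / (1 - phi_dlt)) / math.log(
        phi_dlt * (1 - phi1) / (phi1 * (1 - phi_dlt))
    )
    lambda_d = math.log((1 - phi_dlt) / (1 - phi2)) / math.log(
        phi2 * (1 - phi_dlt) / (phi_dlt * (1 - phi2))
    )
    return BoinBoundaries(lambda_e=lambda_e, lambda_d=lambda_d)


def impute_dlt_estimate(
    observed_dlt_count: int,
    n_tox_assessed: int,
    pending: list[PendingRecord],
    plug_in_p: float,
) -> float:
    """DLT-probability estimate with pending outcomes imputed.

    Pending patients contribute ``plug_in_p * (1 - t/T) / (1 - plug_in_p)``
    each — the approximate conditional expectation of an unobserved DLT
    indicator after follow-up ``t`` of window ``T`` under uniform toxicity
    times; the denominator counts assessed plus pending patients.  The result
    is clipped to [0, 1].
    """
    if not (0.0 <= plug_in_p < 1.0):
        raise ValueError("plug_in_p must lie in [0, 1)")
    n_total = n_tox_assessed + len(pending)
    if n_total == 0:
        raise ValueError("no patients to estimate from")
    imputed = sum(
        plug_in_p * (1.0 - rec.follow_up_time / rec.window) / (1.0 - plug_in_p)
        for rec in pending
    )
    return min(1.0, (observed_dlt_count + imputed) / n_total)


# Plug-in p_j is clipped away from 1 so the imputation weight stays finite; a
# dose whose every assessed patient had a DLT is being flagged by the safety
# monitor regardless.
_PLUG_IN_CAP = 0.95


def _plug_in_p(acc: DoseAccrual, phi_dlt: float) -> float:
    frac = acc.observed_dlt_fraction
    if frac is None:
        return phi_dlt / 2.0
    return min(frac, _PLUG_IN_CAP)


def _interval_move(p_hat: float, boundaries: BoinBoundaries) -> Move:
    if p_hat <= boundaries.lambda_e:
        return Move.ESCALATE
    if p_hat > boundaries.lambda_d:
        return Move.DEESCALATE
    return Move.STAY


def _dose_p_hat(acc: DoseAccrual, phi_dlt: float) -> float:
    return impute_dlt_estimate(
        acc.dlt_count, acc.n_tox_assessed, acc.pending, _plug_in_p(acc, phi_dlt)
    )


def escalation_decision(
    state: TrialState,
    boundaries: BoinBoundaries,
    config: TrialConfig,
    monitoring: MonitoringConfig,
) -> Move:
    """Escalation move for the next cohort, without resolving the target dose.

    Suspends when more than half of the current dose's patients are pending
    (too little information for a TITE decision).  Under the conservative
    variant the move is taken from the lowest tried dose with a stay or
    de-escalate interval decision, when one exists.
    """
    move, _ = escalation_target(state, boundaries, config, monitoring)
    return move


def escalation_target(
    state: TrialState,
    boundaries: BoinBoundaries,
    config: TrialConfig,
    monitoring: MonitoringConfig,
) -> tuple[Move, int]:
    """Escalation move and the dose the next escalation cohort should receive.

    The move is interpreted against a reference dose: the current dose under
    the standard variant, or — under the conservative variant — the lowest
    tried dose with a stay/de-escalate interval decision when one exists.
    Escalation never skips an untried dose, never enters a dose flagged
    overly toxic, and de-escalation stops at dose 1.
    """
    c = state.current_dose
    acc = state.dose(c)
    if acc.n_enrolled == 0:
        raise ValueError("no patients at the current dose yet")
    if 2 * acc.n_tox_assessed < acc.n_enrolled:
        return Move.SUSPEND, c

    reference = c
    if state.status(c).overly_toxic:
        move = Move.DEESCALATE
    else:
        move = _interval_move(_dose_p_hat(acc, monitoring.phi_dlt), boundaries)
        if config.decision_variant == "conservative":
            for j in range(1, c + 1):
                other = state.dose(j)
                if other.n_enrolled == 0 or other.n_tox_assessed == 0:
                    continue
                if state.status(j).overly_toxic:
                    other_move = Move.DEESCALATE
                else:
                    other_move = _interval_move(
                        _dose_p_hat(other, monitoring.phi_dlt), boundaries
                    )
                if other_move in (Move.STAY, Move.DEESCALATE):
                    reference, move = j, other_move
                    break

    if move is Move.ESCALATE:
        if reference >= config.n_doses or state.status(reference + 1).overly_toxic:
            return Move.STAY, reference
        return Move.ESCALATE, reference + 1
    if move is Move.DEESCALATE:
        if reference <= 1:
            return Move.STAY, 1
        return Move.DEESCALATE, reference - 1
    return Move.STAY, reference


def backfill_eligible(state: TrialState, config: TrialConfig) -> set[int]:
    """Doses currently eligible to receive a backfill patient.

    A dose qualifies when it (i) sits strictly below the current escalation
    dose and has been tried, (ii) carries no monitoring flag, (iii) has not
    reached the per-dose cap ``n_cap``, and (iv) has at most half of its
    patients with pending toxicity assessments.
    """
    eligible: set[int] = set()
    for j in range(1, state.current_dose):
        acc = state.dose(j)
        if not acc.tried:
            continue
        if state.status(j).any_flag:
            continue
        if acc.n_enrolled >= config.n_cap:
            continue
        if acc.n_pending > acc.n_enrolled / 2.0:
            continue
        eligible.add(j)
    return eligible


def allocate_backfill(
    eligible: set[int],
    strategy: str,
    state: TrialState,
    monitoring: MonitoringConfig,
    rng: np.random.Generator,
) -> Optional[int]:
    """Pick the backfill dose for a newly arrived patient.

    * ``equal`` — uniform randomization over the eligible doses;
    * ``highest`` — the highest eligible dose;
    * ``qol_adaptive`` — randomization weighted by the predictive probability
      that a future patient's QoL change stays above the tolerable
      deterioration (doses without two observed scores get the neutral
      weight 0.5);
    * ``pick_winner`` — the eligible dose with the best observed mean QoL
      change, favouring higher doses on ties and unexplored doses outright.
    """
    if strategy not in ALLOCATION_STRATEGIES:
        raise ValueError(f"unknown allocation strategy {strategy!r}")
    if not eligible:
        return None
    doses = sorted(eligible)
    if strategy == "highest":
        return doses[-1]
    if strategy == "equal":
        return int(rng.choice(doses))
    if strategy == "qol_adaptive":
        weights = []
        for j in doses:
            acc = state.dose(j)
            if len(acc.qol_scores) >= 2:
                prob_bad = qol_predictive_prob(
                    float(np.mean(acc.qol_scores)),
                    float(np.std(acc.qol_scores, ddof=1)),
                    len(acc.qol_scores),
                    monitoring.phi_qol,
                )
            else:
                prob_bad = 0.5
            weights.append(1.0 - prob_bad)
        total = sum(weights)
        if total <= 0:
            return int(rng.choice(doses))
        probs = [w / total for w in weights]
        return int(rng.choice(doses, p=probs))
    # pick_winner: unexplored doses rank above any observed mean
    def key(j: int) -> tuple[float, int]:
        mean = state.dose(j).qol_mean()
        return (math.inf if mean is None else mean, j)

    return max(doses, key=key)


def stopping_check(
    state: TrialState,
    config: TrialConfig,
    decision: Optional[Move] = None,
) -> Optional[StopReason]:
    """Evaluate the trial stopping conditions.

    Stops when the escalation sample size reaches its maximum, when the
    current dose has accumulated ``n_stop`` patients and the latest decision
    is still to retain it, or when the lowest dose is flagged overly toxic.
    External stops are injected by the caller.
    """
    if state.stop_reason is not None:
        return state.stop_reason
    if state.status(1).overly_toxic:
        return StopReason.LOWEST_TOXIC
    if state.escalation_enrolled >= config.n_escalation_max:
        return StopReason.MAX_N
    if (
        decision is Move.STAY
        and state.dose(state.current_dose).n_enrolled >= config.n_stop
    ):
        return StopReason.N_STOP_RETAIN
    return None
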