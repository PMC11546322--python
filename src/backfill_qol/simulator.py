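"""Discrete-event simulation of whole dose-optimization trials.

A simulated trial draws patient arrivals from a Poisson process (exponential
inter-arrival times), generates each patient's toxicity, response and QoL
outcomes from the scenario's true curves at enrollment, and reveals them to
the trial engine only as the respective assessment windows elapse.  Every
arrival and assessment completion is an event at which monitoring flags are
refreshed and enrollment decisions made.

Four designs share the engine:

* ``backfill_qol`` — escalation with backfilling, safety/efficacy/QoL
  monitoring, and QoL-aware RP2D selection;
* ``backfill``     — the same with all QoL components disabled;
* ``de_qol``       — BOIN escalation without backfilling, followed by a
  dose-expansion phase randomizing ``6 x |promising doses|`` patients equally
  across the promising doses, with continued monitoring;
* ``boin``         — plain BOIN escalation only (MTD finding), used as a
  reference design.

All randomness flows from one seed, split into independent streams for
arrivals, patient outcomes, allocation and selection, so that replicates are
reproducible and results do not depend on execution order.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .dose_finding import (
    BoinBoundaries,
    Move,
    PendingRecord,
    StopReason,
    TrialConfig,
    TrialState,
    allocate_backfill,
    backfill_eligible,
    boin_boundaries,
    escalation_target,
    stopping_check,
)
from .monitoring import (
    DoseData,
    MonitoringConfig,
    futility_boundary,
    overdosing_boundary,
    qol_predictive_prob,
)
from .selection import isotonic_dlt_estimates, promising_set, select_mtd, select_rp2d

__all__ = [
    "Scenario",
    "PatientOutcome",
    "TrialResult",
    "OCSummary",
    "generate_outcomes",
    "run_trial",
    "operating_characteristics",
    "fixture_scenarios",
    "DESIGNS",
]

DESIGNS = ("backfill_qol", "backfill", "de_qol", "boin")


@dataclass(frozen=True)
class Scenario:
    """True per-dose outcome curves plus truth labels for scoring.

    ``optimal_dose`` is the dose a perfectly informed committee would pick as
    RP2D (``None`` when no dose should be recommended); ``mtd_truth`` is the
    dose whose true DLT rate is closest to the target.
    """

    name: str
    dlt_probs: tuple[float, ...]
    response_probs: tuple[float, ...]
    qol_means: tuple[float, ...]
    qol_sds: tuple[float, ...]
    corr: Optional[np.ndarray] = None
    optimal_dose: Optional[int] = None
    mtd_truth: Optional[int] = None

    def __post_init__(self) -> None:
        lengths = {
            len(self.dlt_probs),
            len(self.response_probs),
            len(self.qol_means),
            len(self.qol_sds),
        }
        if len(lengths) != 1:
            raise ValueError("all per-dose curves must have equal length")
        if any(not (0.0 <= p <= 1.0) for p in self.dlt_probs + self.response_probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if any(sd <= 0 for sd in self.qol_sds):
            raise ValueError("QoL standard deviations must be positive")
        if self.corr is not None:
            corr = np.asarray(self.corr, dtype=float)
            if corr.shape != (3, 3):
                raise ValueError("correlation matrix must be 3x3")
            if not np.allclose(corr, corr.T):
                raise ValueError("correlation matrix must be symmetric")
            if not np.allclose(np.diag(corr), 1.0):
                raise ValueError("correlation matrix must have unit diagonal")
            if np.linalg.eigvalsh(corr).min() <= 0:
                raise ValueError("correlation matrix must be positive definite")
            object.__setattr__(self, "corr", corr)

    @property
    def n_doses(self) -> int:
        return len(self.dlt_probs)


@dataclass(frozen=True)
class PatientOutcome:
    dlt: bool
    dlt_time: Optional[int]  # integer weeks in 1..window when dlt
    response: bool
    qol_change: int


@dataclass
class TrialResult:
    """Outcome of one simulated trial."""

    design: str
    seed: int
    mtd: Optional[int]
    rp2d: Optional[int]
    stop_reason: Optional[str]
    n_total: int
    n_escalation: int
    n_backfill: int
    duration: float
    per_dose_n: list[int]
    per_dose_backfill: list[int]
    promising: list[int] = field(default_factory=list)
    safety_violations: int = 0


@dataclass
class OCSummary:
    """Operating characteristics aggregated over simulated trials."""

    design: str
    scenario: str
    n_trials: int
    pcs_mtd: float  # percent
    pcs_rp2d: float  # percent
    expected_n: float
    avg_duration: float
    mtd_selection_freq: list[float]  # percent per dose; no-selection excluded
    rp2d_selection_freq: list[float]
    mean_allocation: list[float]
    pct_no_rp2d: float = 0.0


def generate_outcomes(
    scenario: Scenario,
    dose: int,
    rng: np.random.Generator,
    window_tox: float = 4.0,
) -> PatientOutcome:
    """Draw one patient's latent outcomes at a dose.

    Independent mode draws Bernoulli DLT and response indicators and a normal
    QoL change.  Correlated mode draws a trivariate normal (two latent event
    variables plus the QoL change); a latent variable above zero marks the
    event, with thresholds set so the marginal event probabilities equal the
    scenario's, and the QoL marginal is unchanged.  DLT times are uniform
    over the toxicity window, rounded up to whole weeks; QoL changes are
    rounded to the nearest integer.  Exactly four variates are consumed per
    call in independent mode (three normals and one uniform in correlated
    mode), which keeps parallel streams aligned across designs.
    """
    j = dose - 1
    p = scenario.dlt_probs[j]
    theta = scenario.response_probs[j]
    mu, sd = scenario.qol_means[j], scenario.qol_sds[j]
    if scenario.corr is None:
        u_dlt, u_time, u_resp = rng.random(3)
        z_qol = rng.standard_normal()
        dlt = u_dlt < p
        response = u_resp < theta
        qol = mu + sd * z_qol
    else:
        z = np.linalg.cholesky(scenario.corr) @ rng.standard_normal(3)
        u_time = rng.random()
        dlt = bool(z[0] + stats.norm.ppf(p) > 0) if p > 0 else False
        response = bool(z[1] + stats.norm.ppf(theta) > 0) if theta > 0 else False
        qol = mu + sd * z[2]
    dlt_time = int(math.ceil(u_time * window_tox)) if dlt else None
    if dlt and dlt_time == 0:  # u_time == 0 exactly
        dlt_time = 1
    return PatientOutcome(
        dlt=bool(dlt),
        dlt_time=dlt_time,
        response=bool(response),
        qol_change=int(round(qol)),
    )


class _Engine:
    """One trial's mutable machinery; ``run`` executes it to completion."""

    def __init__(
        self,
        scenario: Scenario,
        trial_config: TrialConfig,
        monitoring: MonitoringConfig,
        design: str,
        seed: int,
        qol_mc_draws: int = 10_000,
    ) -> None:
        if design not in DESIGNS:
            raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")
        if scenario.n_doses != trial_config.n_doses:
            raise ValueError("scenario and trial config disagree on dose count")
        self.scenario = scenario
        self.cfg = trial_config
        self.mon = monitoring
        self.design = design
        self.seed = seed
        self.qol_mc_draws = qol_mc_draws
        self.use_qol = design in ("backfill_qol", "de_qol")
        self.backfilling = design in ("backfill_qol", "backfill")
        # plain BOIN (and the escalation phase of the expansion design) makes
        # decisions only on fully assessed data
        self.full_assessment = design in ("de_qol", "boin")

        ss = np.random.SeedSequence(seed)
        kids = ss.spawn(4)
        self.rng_arrival = np.random.default_rng(kids[0])
        self.rng_outcome = np.random.default_rng(kids[1])
        self.rng_alloc = np.random.default_rng(kids[2])
        self.rng_select = np.random.default_rng(kids[3])

        self.boundaries: BoinBoundaries = boin_boundaries(monitoring.phi_dlt)
        self.state = TrialState(config=trial_config)
        # boundary lookup tables make per-event flag refreshes cheap
        n_max = trial_config.n_escalation_max + trial_config.n_cap + trial_config.cohort_size
        self._tox_bound = [None] + [
            overdosing_boundary(monitoring.varphi_T, n, monitoring)
            for n in range(1, n_max + 1)
        ]
        self._fut_bound = [None] + [
            futility_boundary(monitoring.varphi_E, n, monitoring)
            for n in range(1, n_max + 1)
        ]

        self.cohort_count = 0
        self.events: list[tuple[float, int, str, int]] = []  # (time, seq, kind, pid)
        self._seq = 0
        self.patients: list[dict] = []  # per-patient records
        self.enroll_time: dict[int, float] = {}
        self.violations = 0
        self.max_tried = 0

    # -- bookkeeping -------------------------------------------------------

    def _push(self, time: float, kind: str, pid: int) -> None:
        heapq.heappush(self.events, (time, self._seq, kind, pid))
        self._seq += 1

    def _enroll(self, dose: int, time: float, backfill: bool) -> None:
        pid = len(self.patients)
        outcome = generate_outcomes(
            self.scenario, dose, self.rng_outcome, self.cfg.window_tox
        )
        self.patients.append(
            {"id": pid, "dose": dose, "time": time, "outcome": outcome, "backfill": backfill}
        )
        self.enroll_time[pid] = time
        acc = self.state.dose(dose)
        acc.n_enrolled += 1
        if backfill:
            acc.backfill_enrolled += 1
        else:
            self.state.escalation_enrolled += 1
        acc.pending.append(
            PendingRecord(
                patient_id=pid, dose_index=dose, follow_up_time=0.0, window=self.cfg.window_tox
            )
        )
        tox_at = time + (outcome.dlt_time if outcome.dlt else self.cfg.window_tox)
        self._push(tox_at, "tox", pid)
        self._push(time + self.cfg.window_eff, "eff", pid)
        self._push(time + self.cfg.window_qol, "qol", pid)
        self.max_tried = max(self.max_tried, dose)

    def _apply_event(self, kind: str, pid: int) -> None:
        rec = self.patients[pid]
        acc = self.state.dose(rec["dose"])
        outcome: PatientOutcome = rec["outcome"]
        if kind == "tox":
            acc.pending = [p for p in acc.pending if p.patient_id != pid]
            acc.n_tox_assessed += 1
            acc.dlt_count += int(outcome.dlt)
        elif kind == "eff":
            acc.n_eff_assessed += 1
            acc.response_count += int(outcome.response)
        else:
            acc.qol_scores.append(float(outcome.qol_change))
        self._refresh_status(rec["dose"])

    def _refresh_status(self, dose: int) -> None:
        acc = self.state.dose(dose)
        status = self.state.status(dose)
        if acc.n_tox_assessed >= 1:
            bound = self._tox_bound[acc.n_tox_assessed]
            if bound is not None and acc.dlt_count >= bound:
                status.overly_toxic = True  # elimination is permanent
        if acc.n_eff_assessed >= 1:
            fbound = self._fut_bound[acc.n_eff_assessed]
            status.futile = fbound is not None and acc.response_count <= fbound
        else:
            status.futile = False
        if self.use_qol and len(acc.qol_scores) >= 2:
            sd = float(np.std(acc.qol_scores, ddof=1))
            prob = qol_predictive_prob(
                float(np.mean(acc.qol_scores)), sd, len(acc.qol_scores), self.mon.phi_qol
            )
            status.qol_unacceptable = prob > self.mon.varphi_Q
        # propagate safety elimination upward
        if status.overly_toxic:
            for k in range(dose + 1, self.cfg.n_doses + 1):
                self.state.status(k).overly_toxic = True

    def _refresh_follow_up(self, dose: int, clock: float) -> None:
        for rec in self.state.dose(dose).pending:
            rec.follow_up_time = min(
                clock - self.enroll_time[rec.patient_id], rec.window
            )

    # -- safety re-verification at assignment time -------------------------

    def _verify_escalation(self, dose: int) -> None:
        acc = self.state.dose(dose)
        if acc.n_tox_assessed >= 1:
            bound = self._tox_bound[acc.n_tox_assessed]
            if bound is not None and acc.dlt_count >= bound:
                self.violations += 1
        if dose > self.max_tried + 1:
            self.violations += 1

    def _verify_backfill(self, dose: int) -> None:
        acc = self.state.dose(dose)
        ok = (
            dose < self.state.current_dose
            and acc.n_enrolled > 0
            and acc.n_enrolled < self.cfg.n_cap
            and len(acc.pending) <= acc.n_enrolled / 2.0
            and not self.state.status(dose).any_flag
        )
        if not ok:
            self.violations += 1

    # -- enrollment logic ---------------------------------------------------

    def _decision_ready(self) -> bool:
        acc = self.state.dose(self.state.current_dose)
        if self.full_assessment:
            return not acc.pending
        return 2 * acc.n_tox_assessed >= acc.n_enrolled

    def _try_escalation(self, clock: float) -> Optional[int]:
        state, cfg = self.state, self.cfg
        if state.escalation_enrolled >= cfg.n_escalation_max:
            return None
        needs_decision = (
            self.cohort_count >= cfg.cohort_size
            or state.status(state.current_dose).overly_toxic
        )
        if needs_decision:
            if not self._decision_ready():
                return None
            self._refresh_follow_up(state.current_dose, clock)
            move, target = escalation_target(state, self.boundaries, cfg, self.mon)
            if move is Move.SUSPEND:
                return None
            state.current_dose = target
            self.cohort_count = 0
            reason = stopping_check(state, cfg, decision=move)
            if reason in (StopReason.N_STOP_RETAIN, StopReason.LOWEST_TOXIC):
                state.stop_reason = reason
                return None
            if state.status(target).overly_toxic:
                return None
        dose = state.current_dose
        self._verify_escalation(dose)
        self._enroll(dose, clock, backfill=False)
        self.cohort_count += 1
        if state.escalation_enrolled >= cfg.n_escalation_max:
            state.stop_reason = StopReason.MAX_N
        return dose

    def _try_backfill(self, clock: float) -> Optional[int]:
        if not self.backfilling:
            return None
        eligible = backfill_eligible(self.state, self.cfg)
        dose = allocate_backfill(
            eligible, self.cfg.allocation_strategy, self.state, self.mon, self.rng_alloc
        )
        if dose is None:
            return None
        self._verify_backfill(dose)
        self._enroll(dose, clock, backfill=True)
        return dose

    # -- phases -------------------------------------------------------------

    def _process_events_until(self, time: float) -> None:
        while self.events and self.events[0][0] <= time:
            _t, _s, kind, pid = heapq.heappop(self.events)
            self._apply_event(kind, pid)
            if self.state.stop_reason is None and self.state.status(1).overly_toxic:
                self.state.stop_reason = StopReason.LOWEST_TOXIC

    def _drain_events(self) -> None:
        while self.events:
            _t, _s, kind, pid = heapq.heappop(self.events)
            self._apply_event(kind, pid)

    def _last_assessment_time(self) -> float:
        """Trial duration endpoint: the last patient's last assessment completion."""
        last = 0.0
        tail = max(self.cfg.window_eff, self.cfg.window_qol)
        for rec in self.patients:
            outcome: PatientOutcome = rec["outcome"]
            tox_done = outcome.dlt_time if outcome.dlt else self.cfg.window_tox
            last = max(last, rec["time"] + max(tail, tox_done))
        return last

    def _run_escalation_phase(self) -> None:
        clock = self.rng_arrival.exponential(1.0 / self.cfg.accrual_rate)
        # first cohort opens at the starting dose with the first arrival
        while True:
            self._process_events_until(clock)
            if self.state.stop_reason is not None:
                break
            self.state.clock = clock
            if self._try_escalation(clock) is None and self.state.stop_reason is None:
                self._try_backfill(clock)
            if self.state.stop_reason is not None:
                break
            clock += self.rng_arrival.exponential(1.0 / self.cfg.accrual_rate)

    def _run_expansion_phase(self) -> None:
        """Dose-expansion for the ``de_qol`` design, after escalation completes."""
        if self.state.stop_reason is StopReason.LOWEST_TOXIC:
            return
        self._drain_events()
        self.state.clock = max(self.state.clock, self._last_assessment_time())
        data = self._final_dose_data()
        estimates = isotonic_dlt_estimates(
            [d.dlt_count for d in data],
            [d.n for d in data],
            (self.mon.prior_a, self.mon.prior_b),
        )
        mtd = select_mtd(estimates, self.state.statuses, self.mon.phi_dlt)
        if mtd is None:
            return
        pset = promising_set(data, mtd, self.mon, use_qol=True)
        if not pset.doses:
            return
        target_n = 6 * len(pset.doses)
        active = list(pset.doses)
        enrolled = 0
        clock = self.state.clock
        while enrolled < target_n and active:
            clock += self.rng_arrival.exponential(1.0 / self.cfg.accrual_rate)
            self._process_events_until(clock)
            active = [j for j in active if not self.state.status(j).any_flag]
            if not active:
                break
            self.state.clock = clock
            dose = int(self.rng_alloc.choice(active))
            self._enroll(dose, clock, backfill=True)
            enrolled += 1

    def _final_dose_data(self) -> list[DoseData]:
        """Per-dose data once all assessments are in (call after draining events)."""
        return [
            DoseData(
                dose_index=acc.dose_index,
                n=acc.n_enrolled,
                dlt_count=acc.dlt_count,
                response_count=acc.response_count,
                qol_scores=list(acc.qol_scores),
            )
            for acc in self.state.doses
        ]

    def run(self) -> TrialResult:
        self._run_escalation_phase()
        if self.design == "de_qol":
            self._run_expansion_phase()
        self._drain_events()
        duration = self._last_assessment_time()
        data = self._final_dose_data()

        mtd = None
        rp2d = None
        promising: list[int] = []
        stopped_toxic = self.state.stop_reason is StopReason.LOWEST_TOXIC
        tried = any(d.n > 0 for d in data)
        if tried and not stopped_toxic:
            estimates = isotonic_dlt_estimates(
                [d.dlt_count for d in data],
                [d.n for d in data],
                (self.mon.prior_a, self.mon.prior_b),
            )
            mtd = select_mtd(estimates, self.state.statuses, self.mon.phi_dlt)
            if self.design != "boin" and mtd is not None:
                sel = select_rp2d(
                    data,
                    mtd,
                    self.mon,
                    rng=self.rng_select,
                    mc_draws=self.qol_mc_draws,
                    use_qol=self.use_qol,
                )
                rp2d = sel.rp2d
                if sel.promising is not None:
                    promising = sel.promising.doses

        per_dose_n = [acc.n_enrolled for acc in self.state.doses]
        per_dose_bf = [acc.backfill_enrolled for acc in self.state.doses]
        return TrialResult(
            design=self.design,
            seed=self.seed,
            mtd=mtd,
            rp2d=rp2d,
            stop_reason=self.state.stop_reason.value if self.state.stop_reason else None,
            n_total=sum(per_dose_n),
            n_escalation=self.state.escalation_enrolled,
            n_backfill=sum(per_dose_bf),
            duration=float(duration) if self.patients else 0.0,
            per_dose_n=per_dose_n,
            per_dose_backfill=per_dose_bf,
            promising=promising,
            safety_violations=self.violations,
        )


def run_trial(
    scenario: Scenario,
    trial_config: Optional[TrialConfig] = None,
    monitoring_config: Optional[MonitoringConfig] = None,
    design: str = "backfill_qol",
    seed: int = 0,
    qol_mc_draws: int = 10_000,
) -> TrialResult:
    """Simulate one trial under a design and return its outcome.

    The result is a pure function of (scenario, configs, design, seed).
    """
    trial_config = trial_config or TrialConfig(n_doses=scenario.n_doses)
    monitoring_config = monitoring_config or MonitoringConfig()
    engine = _Engine(
        scenario, trial_config, monitoring_config, design, seed, qol_mc_draws
    )
    return engine.run()


def run_trials(
    scenario: Scenario,
    n_trials: int,
    trial_config: Optional[TrialConfig] = None,
    monitoring_config: Optional[MonitoringConfig] = None,
    design: str = "backfill_qol",
    seed: int = 0,
    qol_mc_draws: int = 10_000,
) -> list[TrialResult]:
    """Run independent replicates with per-replicate seeds derived from ``seed``."""
    child_seeds = np.random.SeedSequence(seed).generate_state(n_trials) % (2**31)
    return [
        run_trial(
            scenario,
            trial_config,
            monitoring_config,
            design=design,
            seed=int(s),
            qol_mc_draws=qol_mc_draws,
        )
        for s in child_seeds
    ]


def operating_characteristics(
    results: Sequence[TrialResult], scenario: Scenario
) -> OCSummary:
    """Aggregate simulated trials into operating characteristics.

    PCS-MTD is the percentage of trials selecting the true MTD (or selecting
    none when the scenario has no admissible MTD); PCS-RP2D analogously scores
    the optimal dose, counting "no dose selected" as correct in null
    scenarios.
    """
    if not results:
        raise ValueError("no trial results to aggregate")
    n = len(results)
    n_doses = scenario.n_doses

    def pct(hits: int) -> float:
        return 100.0 * hits / n

    if scenario.mtd_truth is None:
        pcs_mtd = pct(sum(r.mtd is None for r in results))
    else:
        pcs_mtd = pct(sum(r.mtd == scenario.mtd_truth for r in results))
    if scenario.optimal_dose is None:
        pcs_rp2d = pct(sum(r.rp2d is None for r in results))
    else:
        pcs_rp2d = pct(sum(r.rp2d == scenario.optimal_dose for r in results))
    mtd_freq = [pct(sum(r.mtd == j for r in results)) for j in range(1, n_doses + 1)]
    rp2d_freq = [pct(sum(r.rp2d == j for r in results)) for j in range(1, n_doses + 1)]
    alloc = [
        float(np.mean([r.per_dose_n[j] for r in results])) for j in range(n_doses)
    ]
    return OCSummary(
        design=results[0].design,
        scenario=scenario.name,
        n_trials=n,
        pcs_mtd=pcs_mtd,
        pcs_rp2d=pcs_rp2d,
        expected_n=float(np.mean([r.n_total for r in results])),
        avg_duration=float(np.mean([r.duration for r in results])),
        mtd_selection_freq=mtd_freq,
        rp2d_selection_freq=rp2d_freq,
        mean_allocation=alloc,
        pct_no_rp2d=pct(sum(r.rp2d is None for r in results)),
    )


def fixture_scenarios() -> list[Scenario]:
    """Labeled six-dose scenarios spanning the qualitative dose-curve shapes.

    The shapes cover: response plateauing at a low dose while QoL declines;
    response and QoL moving together; unacceptable QoL exactly at the
    effective doses (no dose should be recommended); the MTD at a middle or
    low dose; an all-too-toxic drug; and a QoL cliff just above the optimal
    dose.  Truth labels are by construction.
    """
    sd8 = (8.0,) * 6
    return [
        Scenario(
            name="plateau_response_declining_qol",
            dlt_probs=(0.02, 0.04, 0.07, 0.11, 0.17, 0.25),
            response_probs=(0.30, 0.45, 0.48, 0.50, 0.50, 0.50),
            qol_means=(-2.0, -5.0, -9.0, -15.0, -19.0, -23.0),
            qol_sds=sd8,
            optimal_dose=2,
            mtd_truth=6,
        ),
        Scenario(
            name="concordant_response_qol",
            dlt_probs=(0.02, 0.05, 0.08, 0.12, 0.18, 0.25),
            response_probs=(0.10, 0.20, 0.30, 0.40, 0.50, 0.60),
            qol_means=(-1.0, -2.0, -3.0, -4.0, -5.0, -6.0),
            qol_sds=sd8,
            optimal_dose=6,
            mtd_truth=6,
        ),
        Scenario(
            name="poor_qol_low_doses",
            dlt_probs=(0.03, 0.06, 0.10, 0.15, 0.20, 0.25),
            response_probs=(0.25, 0.35, 0.45, 0.50, 0.55, 0.60),
            qol_means=(-22.0, -18.0, -14.0, -6.0, -4.0, -2.0),
            qol_sds=sd8,
            optimal_dose=6,
            mtd_truth=6,
        ),
        Scenario(
            name="effective_doses_unacceptable_qol",
            dlt_probs=(0.02, 0.05, 0.08, 0.12, 0.18, 0.25),
            response_probs=(0.05, 0.10, 0.15, 0.40, 0.50, 0.55),
            qol_means=(-6.0, -8.0, -12.0, -19.0, -21.0, -23.0),
            qol_sds=sd8,
            optimal_dose=None,
            mtd_truth=6,
        ),
        Scenario(
            name="mtd_mid_concordant",
            dlt_probs=(0.05, 0.10, 0.16, 0.25, 0.40, 0.55),
            response_probs=(0.15, 0.25, 0.35, 0.45, 0.50, 0.50),
            qol_means=(-3.0, -5.0, -7.0, -8.0, -12.0, -15.0),
            qol_sds=sd8,
            optimal_dose=4,
            mtd_truth=4,
        ),
        Scenario(
            name="mtd_low",
            dlt_probs=(0.12, 0.25, 0.40, 0.52, 0.60, 0.68),
            response_probs=(0.25, 0.40, 0.45, 0.50, 0.50, 0.50),
            qol_means=(-4.0, -7.0, -12.0, -16.0, -20.0, -24.0),
            qol_sds=sd8,
            optimal_dose=2,
            mtd_truth=2,
        ),
        Scenario(
            name="all_toxic",
            dlt_probs=(0.30, 0.42, 0.50, 0.58, 0.65, 0.72),
            response_probs=(0.30, 0.40, 0.45, 0.50, 0.50, 0.50),
            qol_means=(-14.0, -18.0, -21.0, -24.0, -26.0, -28.0),
            qol_sds=sd8,
            optimal_dose=None,
            mtd_truth=1,
        ),
        Scenario(
            name="qol_cliff_above_optimal",
            dlt_probs=(0.02, 0.04, 0.06, 0.10, 0.15, 0.22),
            response_probs=(0.15, 0.30, 0.50, 0.52, 0.54, 0.55),
            qol_means=(-2.0, -4.0, -6.0, -17.0, -20.0, -23.0),
            qol_sds=sd8,
            optimal_dose=3,
            mtd_truth=6,
        ),
    ]
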