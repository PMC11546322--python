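import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from backfill_qol import (
    Move,
    PendingRecord,
    StopReason,
    TrialConfig,
    TrialState,
    allocate_backfill,
    backfill_eligible,
    boin_boundaries,
    escalation_decision,
    escalation_target,
    impute_dlt_estimate,
    stopping_check,
)
from backfill_qol.monitoring import MonitoringConfig


def make_state(
    config=None,
    current_dose=1,
    tallies=(),
    escalation_enrolled=None,
):
    """Build a TrialState from per-dose (n_enrolled, n_assessed, dlt, pending_times)."""
    config = config or TrialConfig()
    state = TrialState(config=config)
    state.current_dose = current_dose
    total = 0
    for j, (n_enr, n_ass, dlt, pend) in enumerate(tallies, start=1):
        acc = state.dose(j)
        acc.n_enrolled = n_enr
        acc.n_tox_assessed = n_ass
        acc.dlt_count = dlt
        acc.pending = [
            PendingRecord(patient_id=100 * j + i, dose_index=j, follow_up_time=t, window=config.window_tox)
            for i, t in enumerate(pend)
        ]
        total += n_enr
    state.escalation_enrolled = total if escalation_enrolled is None else escalation_enrolled
    return state


class TestBoinBoundaries:
    def test_default_boundaries_for_quarter_target(self):
        b = boin_boundaries(0.25)
        assert b.lambda_e == pytest.approx(0.1968, abs=5e-4)
        assert b.lambda_d == pytest.approx(0.2984, abs=5e-4)

    def test_ordering_invariant(self):
        b = boin_boundaries(0.30)
        assert b.lambda_e < 0.30 < b.lambda_d

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            boin_boundaries(0.25, phi1=0.25, phi2=0.25)


class TestImputation:
    def test_no_pending_reduces_to_observed_fraction(self):
        assert impute_dlt_estimate(1, 3, [], 0.2) == pytest.approx(1 / 3)

    def test_completed_follow_up_contributes_nothing(self):
        pend = [PendingRecord(patient_id=1, dose_index=1, follow_up_time=4.0, window=4.0)]
        assert impute_dlt_estimate(0, 2, pend, 0.2) == 0.0

    def test_half_window_example(self):
        pend = [PendingRecord(patient_id=1, dose_index=1, follow_up_time=2.0, window=4.0)]
        assert impute_dlt_estimate(0, 2, pend, 0.2) == pytest.approx(
            (0.2 * 0.5 / 0.8) / 3
        )

    def test_certain_toxicity_plug_in_rejected(self):
        with pytest.raises(ValueError):
            impute_dlt_estimate(0, 1, [], 1.0)

    def test_estimate_clipped_to_unit_interval(self):
        pend = [
            PendingRecord(patient_id=i, dose_index=1, follow_up_time=0.1, window=4.0)
            for i in range(3)
        ]
        assert impute_dlt_estimate(2, 2, pend, 0.9) <= 1.0


class TestEscalationDecision:
    def setup_method(self):
        self.bounds = boin_boundaries(0.25)
        self.cfg = TrialConfig()
        self.mon = MonitoringConfig()

    def decide(self, state):
        return escalation_target(state, self.bounds, state.config, self.mon)

    def test_low_rate_escalates(self):
        state = make_state(current_dose=2, tallies=[(3, 3, 0, []), (10, 10, 1, [])])
        move, target = self.decide(state)
        assert move is Move.ESCALATE and target == 3

    def test_interval_membership(self):
        stay = make_state(current_dose=1, tallies=[(4, 4, 1, [])])  # 0.25
        assert self.decide(stay)[0] is Move.STAY
        down = make_state(current_dose=2, tallies=[(3, 3, 0, []), (5, 5, 2, [])])  # 0.4
        move, target = self.decide(down)
        assert move is Move.DEESCALATE and target == 1

    def test_escalation_blocked_by_toxic_dose_above(self):
        state = make_state(current_dose=2, tallies=[(3, 3, 0, []), (6, 6, 0, [])])
        state.status(3).overly_toxic = True
        move, target = self.decide(state)
        assert move is Move.STAY and target == 2

    def test_suspends_when_majority_pending(self):
        state = make_state(
            current_dose=1, tallies=[(3, 1, 0, [1.0, 2.0])]
        )
        assert escalation_decision(state, self.bounds, self.cfg, self.mon) is Move.SUSPEND

    def test_deescalation_stops_at_lowest_dose(self):
        state = make_state(current_dose=1, tallies=[(5, 5, 2, [])])  # 0.4 at dose 1
        move, target = self.decide(state)
        assert move is Move.STAY and target == 1

    @given(n=st.integers(1, 12), data=st.data())
    @settings(max_examples=120, deadline=None)
    def test_matches_plain_boin_with_no_pending(self, n, data):
        """Zero pending: decision equals the plain BOIN interval rule on x/n."""
        x = data.draw(st.integers(0, n))
        state = make_state(current_dose=1, tallies=[(n, n, x, [])])
        # keep the safety monitor out of it: compare raw interval decisions
        state.statuses[0].overly_toxic = False
        p_hat = x / n
        if p_hat <= self.bounds.lambda_e:
            expected = Move.ESCALATE
        elif p_hat > self.bounds.lambda_d:
            expected = Move.DEESCALATE
        else:
            expected = Move.STAY
        move, _ = self.decide(state)
        if expected is Move.ESCALATE:
            assert move is Move.ESCALATE
        elif expected is Move.DEESCALATE:
            assert move is Move.STAY  # dose 1 cannot de-escalate further
        else:
            assert move is Move.STAY

    def test_conservative_variant_acts_on_lowest_retaining_dose(self):
        cfg = TrialConfig(decision_variant="conservative")
        # dose 1 sits in the retention interval, dose 2 would escalate
        state = make_state(
            config=cfg,
            current_dose=2,
            tallies=[(4, 4, 1, []), (6, 6, 0, [])],
        )
        move, target = escalation_target(state, boin_boundaries(0.25), cfg, self.mon)
        assert move is Move.STAY and target == 1


class TestBackfillEligibility:
    def test_no_lower_dose_tried(self, trial_config):
        state = make_state(current_dose=1, tallies=[(3, 3, 0, [])])
        assert backfill_eligible(state, trial_config) == set()

    def test_cap_excludes_dose(self, trial_config):
        state = make_state(
            current_dose=3,
            tallies=[(12, 12, 1, []), (3, 3, 0, []), (3, 1, 0, [])],
        )
        assert backfill_eligible(state, trial_config) == {2}

    def test_pending_majority_excludes_dose(self, trial_config):
        state = make_state(
            current_dose=2,
            tallies=[(3, 1, 0, [1.0, 0.5]), (3, 0, 0, [])],
        )
        assert backfill_eligible(state, trial_config) == set()

    def test_monitoring_flags_exclude_dose(self, trial_config):
        state = make_state(
            current_dose=3,
            tallies=[(4, 4, 0, []), (4, 4, 0, []), (3, 0, 0, [])],
        )
        state.status(1).qol_unacceptable = True
        state.status(2).futile = True
        assert backfill_eligible(state, trial_config) == set()


class TestAllocation:
    def setup_method(self):
        self.mon = MonitoringConfig()

    def test_equal_randomization_is_uniform(self):
        state = make_state(current_dose=3, tallies=[(3, 3, 0, []), (3, 3, 0, [])])
        rng = np.random.default_rng(11)
        picks = [
            allocate_backfill({1, 2}, "equal", state, self.mon, rng) for _ in range(10_000)
        ]
        freq = picks.count(1) / len(picks)
        assert abs(freq - 0.5) < 3 * 0.005

    def test_highest_and_empty(self):
        state = make_state(current_dose=4, tallies=[(3, 3, 0, [])] * 3)
        rng = np.random.default_rng(0)
        assert allocate_backfill({1, 2, 3}, "highest", state, self.mon, rng) == 3
        assert allocate_backfill(set(), "highest", state, self.mon, rng) is None

    def test_pick_winner_prefers_best_mean_qol(self):
        state = make_state(current_dose=3, tallies=[(3, 3, 0, []), (3, 3, 0, [])])
        state.dose(1).qol_scores = [-20.0, -18.0]
        state.dose(2).qol_scores = [-2.0, -4.0]
        rng = np.random.default_rng(0)
        assert allocate_backfill({1, 2}, "pick_winner", state, self.mon, rng) == 2

    def test_qol_adaptive_downweights_poor_qol(self):
        state = make_state(current_dose=3, tallies=[(6, 6, 0, []), (6, 6, 0, [])])
        state.dose(1).qol_scores = [-25.0, -22.0, -28.0, -24.0]
        state.dose(2).qol_scores = [-1.0, -3.0, -2.0, -4.0]
        rng = np.random.default_rng(5)
        picks = [
            allocate_backfill({1, 2}, "qol_adaptive", state, self.mon, rng)
            for _ in range(2000)
        ]
        assert picks.count(2) > picks.count(1)

    def test_unknown_strategy_rejected(self):
        state = make_state(current_dose=2, tallies=[(3, 3, 0, [])])
        with pytest.raises(ValueError):
            allocate_backfill({1}, "fanciest", state, self.mon, np.random.default_rng(0))


class TestStopping:
    def test_max_escalation_sample_size(self, trial_config):
        state = make_state(tallies=[(36, 30, 2, [])], escalation_enrolled=36)
        assert stopping_check(state, trial_config) is StopReason.MAX_N

    def test_retention_at_n_stop(self, trial_config):
        state = make_state(current_dose=1, tallies=[(9, 9, 2, [])])
        assert (
            stopping_check(state, trial_config, decision=Move.STAY)
            is StopReason.N_STOP_RETAIN
        )
        assert stopping_check(state, trial_config, decision=Move.ESCALATE) is None

    def test_lowest_dose_toxic(self, trial_config):
        state = make_state(current_dose=1, tallies=[(3, 3, 3, [])])
        state.status(1).overly_toxic = True
        assert stopping_check(state, trial_config) is StopReason.LOWEST_TOXIC

    def test_no_stop(self, trial_config):
        state = make_state(current_dose=1, tallies=[(3, 3, 0, [])])
        assert stopping_check(state, trial_config) is None


class TestTrialConfigValidation:
    def test_invariants(self):
        with pytest.raises(ValueError):
            TrialConfig(n_stop=15, n_cap=12)
        with pytest.raises(ValueError):
            TrialConfig(cohort_size=0)
        with pytest.raises(ValueError):
            TrialConfig(allocation_strategy="nope")
        with pytest.raises(ValueError):
            TrialConfig(window_tox=0.0)
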