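"""Five-moments inference: detection, linking, compliance and evaluation."""

from fractions import Fraction

import numpy as np
import pytest

from wardwatch import SimConfig, simulate_shift
from wardwatch.event_processing import (
    HYGIENE_STATION_VISIT,
    ZONE_ENTER,
    ZONE_EXIT,
    LocationEvent,
)
from wardwatch.moments import (
    HHAction,
    HHOpportunity,
    Moment,
    actions_from_events,
    compliance_rate,
    detect_opportunities,
    evaluate_against_truth,
    link_actions,
    summarize_shift,
)
from wardwatch.pipeline import process_messages
from wardwatch.simulator import NoiseConfig, sense_messages
from wardwatch.ward_layout import Facility, FacilityKind

BED_A = Facility(id="A", kind=FacilityKind.BED, room_id="R", position=(1, 1))
BED_B = Facility(id="B", kind=FacilityKind.BED, room_id="R", position=(3, 1))


def _enter(t, bed=BED_A, tag="pink"):
    return LocationEvent(tag, bed, t, ZONE_ENTER, 0.0)


def _exit(t, bed=BED_A, tag="pink"):
    return LocationEvent(tag, bed, t, ZONE_EXIT, 0.0)


def _rub(t, tag="pink"):
    return HHAction(tag, "RUB", t, 25.0, "D")


class TestDetectOpportunities:
    def test_single_visit_yields_entry_and_exit_moments(self):
        opps = detect_opportunities([_enter(100), _exit(400)])
        assert [(o.moment, o.time) for o in opps] == [(Moment.M1, 100),
                                                      (Moment.M45, 400)]

    def test_two_visits_yield_four_opportunities(self):
        opps = detect_opportunities(
            [_enter(0), _exit(100), _enter(300, BED_B), _exit(400, BED_B)]
        )
        assert len(opps) == 4
        assert [o.zone_id for o in opps] == ["A", "A", "B", "B"]

    def test_reentry_within_grace_is_one_visit(self):
        opps = detect_opportunities(
            [_enter(0), _exit(100), _enter(105), _exit(400)], reentry_grace_s=10
        )
        assert [(o.moment, o.time) for o in opps] == [(Moment.M1, 0),
                                                      (Moment.M45, 400)]

    def test_reentry_after_grace_is_a_new_visit(self):
        opps = detect_opportunities(
            [_enter(0), _exit(100), _enter(150), _exit(400)], reentry_grace_s=10
        )
        assert len(opps) == 4

    def test_orphan_exit_still_emits_exit_moment(self):
        counters = {}
        opps = detect_opportunities([_exit(50)], counters=counters)
        assert [o.moment for o in opps] == [Moment.M45]
        assert counters["orphan_exits"] == 1

    def test_out_of_order_events_rejected(self):
        with pytest.raises(ValueError, match="order"):
            detect_opportunities([_enter(100), _exit(50)])

    def test_central_zone_events_do_not_create_opportunities(self):
        central = Facility(id="C", kind=FacilityKind.CENTRAL, room_id="R",
                           position=(2, 2))
        events = [LocationEvent("pink", central, 10, ZONE_ENTER, 0.0),
                  LocationEvent("pink", central, 500, ZONE_EXIT, 0.0)]
        assert detect_opportunities(events) == []


class TestLinkActions:
    def test_action_before_entry_complies_entry_moment(self):
        opps = detect_opportunities([_enter(60), _exit(400)])
        out = link_actions(opps, [_rub(50)])
        m1 = next(o for o in out if o.moment == Moment.M1)
        assert m1.complied and m1.linked_action.time == 50

    def test_one_gap_action_satisfies_both_exit_and_next_entry(self):
        opps = detect_opportunities(
            [_enter(0), _exit(300), _enter(330, BED_B), _exit(600, BED_B)]
        )
        out = link_actions(opps, [_rub(310)])
        by = {(o.moment, o.zone_id): o for o in out}
        assert by[(Moment.M45, "A")].complied
        assert by[(Moment.M1, "B")].complied
        assert by[(Moment.M45, "A")].linked_action is by[(Moment.M1, "B")].linked_action

    def test_no_action_in_gap_leaves_both_uncomplied(self):
        opps = detect_opportunities(
            [_enter(0), _exit(300), _enter(320, BED_B), _exit(600, BED_B)]
        )
        out = link_actions(opps, [])
        assert not any(o.complied for o in out)

    def test_exit_window_is_left_open_right_closed(self):
        opps = detect_opportunities([_enter(0), _exit(300)])
        assert not link_actions(opps, [_rub(300)])[1].complied  # exactly at exit: no
        assert link_actions(opps, [_rub(420)])[1].complied      # exactly at +120: yes
        assert not link_actions(opps, [_rub(421)])[1].complied

    def test_action_after_next_entry_cannot_serve_previous_exit(self):
        opps = detect_opportunities(
            [_enter(0), _exit(300), _enter(310, BED_B), _exit(600, BED_B)]
        )
        out = link_actions(opps, [_rub(315)])  # inside visit B
        by = {(o.moment, o.zone_id): o for o in out}
        assert not by[(Moment.M45, "A")].complied
        assert not by[(Moment.M1, "B")].complied  # after entry, outside its window

    def test_pre_entry_window_bounds_the_lookback(self):
        opps = detect_opportunities([_enter(1000), _exit(1300)])
        assert link_actions(opps, [_rub(10)])[0].complied
        assert not link_actions(opps, [_rub(10)], pre_entry_window_s=120)[0].complied


# ---------------------------------------------------------------------------
# Independent brute-force oracle
# ---------------------------------------------------------------------------


def _oracle(events, actions, grace=10.0, post=120.0):
    """Naive re-implementation: visits -> windows -> existence checks."""
    by_tag = {}
    for e in events:
        if e.facility.kind == FacilityKind.BED:
            by_tag.setdefault(e.tag_id, []).append(e)
    result = []
    for tag, evs in by_tag.items():
        raw_visits = []
        stack = None
        for e in evs:
            if e.kind == ZONE_ENTER:
                stack = (e.facility.id, e.time)
            elif stack is not None and stack[0] == e.facility.id:
                raw_visits.append([stack[0], stack[1], e.time])
                stack = None
        visits = []
        for v in raw_visits:
            if visits and visits[-1][0] == v[0] and v[1] - visits[-1][2] < grace:
                visits[-1][2] = v[2]
            else:
                visits.append(v)
        acts = sorted(a.time for a in actions if a.tag_id == tag)
        for i, (zone, entry, exit_) in enumerate(visits):
            prev_exit = visits[i - 1][2] if i > 0 else float("-inf")
            m1_ok = any(prev_exit < t <= entry for t in acts)
            hi = exit_ + post
            if i + 1 < len(visits):
                hi = min(hi, visits[i + 1][1])
            m45_ok = any(exit_ < t <= hi for t in acts)
            result.append((tag, zone, entry, "M1", m1_ok))
            result.append((tag, zone, exit_, "M45", m45_ok))
    return sorted(result)


class TestOracleEquivalence:
    def test_random_well_formed_streams_match_brute_force(self):
        """Detection + linking agree with an independent enumeration (300 cases)."""
        rng = np.random.default_rng(11)
        beds = [BED_A, BED_B]
        for _ in range(300):
            events, t = [], 0.0
            for _ in range(int(rng.integers(1, 12))):
                t += float(rng.uniform(1, 200))
                bed = beds[int(rng.integers(2))]
                entry = t
                t += float(rng.uniform(1, 300))
                events += [_enter(entry, bed), _exit(t, bed)]
            actions = [_rub(float(rng.uniform(0, t + 200)))
                       for _ in range(int(rng.integers(0, 6)))]
            actions.sort(key=lambda a: a.time)
            opps = link_actions(detect_opportunities(events), actions)
            got = sorted((o.tag_id, o.zone_id, o.time,
                          "M1" if o.moment == Moment.M1 else "M45", o.complied)
                         for o in opps)
            assert got == _oracle(events, actions)


class TestComplianceRate:
    @pytest.mark.parametrize(
        "complied, total, expected",
        [(7, 10, Fraction(7, 10)), (0, 5, Fraction(0)), (698, 1000, Fraction(698, 1000))],
    )
    def test_exact_ratio(self, complied, total, expected):
        assert compliance_rate(complied, total) == expected

    def test_empty_shift_is_undefined_not_zero(self):
        assert compliance_rate(0, 0) is None

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            compliance_rate(3, 2)
        with pytest.raises(ValueError):
            compliance_rate(-1, 2)


class TestSummarize:
    def test_empty_shift_summary(self):
        s = summarize_shift([], [])
        assert s.n_opportunities == 0 and s.compliance_rate is None
        assert s.last_position is None

    def test_hourly_buckets_conserve_totals(self):
        rng = np.random.default_rng(5)
        opps = [
            HHOpportunity("pink", Moment.M1, float(rng.uniform(0, 7200)), "A",
                          complied=bool(rng.random() < 0.7))
            for _ in range(40)
        ]
        s = summarize_shift(opps, [], shift_hours=2)
        assert sum(n for n, _ in s.per_hour) == 40
        assert sum(c for _, c in s.per_hour) == sum(o.complied for o in opps)
        assert len(s.per_hour) == 2

    def test_totals_equal_recount(self):
        rng = np.random.default_rng(8)
        opps = [
            HHOpportunity("pink", Moment.M45, float(rng.uniform(0, 3600)), "A",
                          complied=bool(rng.random() < 0.5))
            for _ in range(rng.integers(1, 60))
        ]
        s = summarize_shift(opps, [])
        assert s.n_opportunities == len(opps)
        assert s.n_complied == sum(1 for o in opps if o.complied)
        assert s.compliance_rate == pytest.approx(s.n_complied / s.n_opportunities)

    def test_last_position_is_latest_event_facility(self):
        events = [_enter(10), _exit(500, BED_B)]
        assert summarize_shift([], events).last_position == "B"

    def test_multiple_tags_rejected(self):
        with pytest.raises(ValueError):
            summarize_shift([], [_enter(1, tag="pink"), _enter(2, tag="green")])


class TestEvaluation:
    def test_noiseless_pipeline_has_unit_sensitivity_and_zero_bias(
        self, layout, noiseless_cfg
    ):
        truths = simulate_shift(layout, noiseless_cfg)
        msgs = sense_messages(truths, layout, NoiseConfig.off(), seed=0)
        _, opps, _ = process_messages(msgs, layout, noiseless_cfg.shift_s)
        for t in truths:
            rep = evaluate_against_truth(
                [o for o in opps if o.tag_id == t.tag_id], t
            )
            assert rep.sensitivity == 1.0
            assert rep.n_spurious == 0
            assert rep.compliance_bias == 0.0

    def test_truth_with_only_inzone_moments_is_invisible(self):
        truth = [
            HHOpportunity("pink", Moment.M2, 100, "A", detectable=False),
            HHOpportunity("pink", Moment.M3, 200, "A", detectable=False),
        ]
        rep = evaluate_against_truth([], truth)
        assert rep.n_truth_detectable == 0
        assert rep.n_detected == 0 and rep.n_spurious == 0

    def test_deletion_noise_degrades_sensitivity_without_negatives(self, layout):
        cfg = SimConfig(n_nurses_per_shift=2, shift_hours=4.0, seed=9,
                        noise=NoiseConfig(p_missed_msg=0.5, p_duplicate_msg=0.0,
                                          p_ghost_msg_per_hour=0.0,
                                          msg_rate_multiplier=1.0))
        truths = simulate_shift(layout, cfg)
        msgs = sense_messages(truths, layout, cfg.noise, seed=9)
        _, opps, _ = process_messages(msgs, layout, cfg.shift_s)
        rep = evaluate_against_truth(
            [o for o in opps if o.tag_id == truths[0].tag_id], truths[0]
        )
        assert rep.sensitivity < 1.0
        assert rep.n_spurious >= 0 and rep.n_missed > 0

    def test_inference_never_emits_inzone_moments(self, layout, noiseless_cfg):
        truths = simulate_shift(layout, noiseless_cfg)
        msgs = sense_messages(truths, layout, NoiseConfig.off(), seed=0)
        _, opps, _ = process_messages(msgs, layout, noiseless_cfg.shift_s)
        assert all(o.moment in (Moment.M1, Moment.M45) for o in opps)


class TestActionsFromEvents:
    def test_station_visits_become_typed_actions(self, layout):
        sink = next(f for f in layout.facilities if f.kind == FacilityKind.SINK)
        disp = next(f for f in layout.facilities if f.kind == FacilityKind.DISPENSER)
        events = [
            LocationEvent("pink", sink, 100, HYGIENE_STATION_VISIT, 45.0),
            LocationEvent("pink", disp, 200, HYGIENE_STATION_VISIT, 5.0),
        ]
        acts = actions_from_events(events)
        assert [a.kind for a in acts] == ["WASH", "RUB"]
        assert acts[0].duration_s == 45.0
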