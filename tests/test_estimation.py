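import pytest

from stoptask.estimation import (
    EstimationError,
    ExclusionCriteria,
    apply_exclusions,
    independence_check,
    inhibition_function,
    integration_ssrt,
    mean_method_ssrt,
    mean_ssd,
    nth_rt_index,
    p_respond_signal,
)

from conftest import make_session


class TestPRespondSignal:
    def test_counts_any_response_including_premature(self):
        stops = [(200, 150.0)] * 2 + [(200, 450.0)] * 21 + [(200, None)] * 27
        session = make_session(go_rts=[500] * 10, stops=stops)
        assert p_respond_signal(session) == pytest.approx(23 / 50)

    def test_all_responded_is_one(self):
        session = make_session(go_rts=[500], stops=[(200, 400.0)] * 5)
        assert p_respond_signal(session) == 1.0

    def test_zero_ssd_probes_excluded_from_both_sides(self):
        session = make_session(
            go_rts=[500] * 10,
            stops=[(200, 450.0)] * 23 + [(200, None)] * 27,
            probes=[300.0] * 10,  # all probes responded
        )
        assert p_respond_signal(session) == pytest.approx(0.46)

    def test_no_stop_trials_is_an_error(self):
        with pytest.raises(EstimationError):
            p_respond_signal(make_session(go_rts=[500]))


class TestMeanSSD:
    def test_arithmetic_mean(self):
        session = make_session(
            go_rts=[500], stops=[(200, None), (250, 400.0), (300, None)]
        )
        assert mean_ssd(session) == 250.0

    def test_probes_excluded(self):
        session = make_session(
            go_rts=[500], stops=[(200, None), (300, None)], probes=[None]
        )
        assert mean_ssd(session) == 250.0

    def test_single_stop_trial(self):
        session = make_session(go_rts=[500], stops=[(150, None)])
        assert mean_ssd(session) == 150.0


class TestNthRtIndex:
    @pytest.mark.parametrize(
        "n_go, p, expected",
        [
            (200, 0.45, 90),  # the canonical worked example
            (200, 0.50, 100),
            (37, 0.43, 16),  # 15.91 rounds half-up to 16
            (10, 1.0, 10),
            (10, 0.01, 1),  # clamped to the fastest RT
        ],
    )
    def test_half_up_rounding(self, n_go, p, expected):
        assert nth_rt_index(n_go, p) == expected

    def test_ceiling_rule_option(self):
        assert nth_rt_index(37, 0.43, rounding="ceiling") == 16
        assert nth_rt_index(10, 0.41, rounding="ceiling") == 5
        assert nth_rt_index(10, 0.41, rounding="half_up") == 4

    def test_zero_p_respond_undefined(self):
        with pytest.raises(EstimationError):
            nth_rt_index(100, 0.0)


class TestIntegrationMethod:
    def test_toy_session_by_hand(self, toy_session):
        # 10 go RTs, p = 0.40 -> rank 4 -> 460; 460 - 200 = 260
        est = integration_ssrt(toy_session)
        assert est.rank_n == 4
        assert est.value == pytest.approx(260.0)
        assert est.p_respond_signal == pytest.approx(0.40)
        assert est.mean_ssd == pytest.approx(200.0)

    def test_replacement_of_go_omissions_with_deadline(self):
        go_rts = [400, 420, 440, 460, 480, 500, 520, 540, 560, 580]
        stops = [(200, 430.0)] * 4 + [(200, None)] * 6
        session = make_session(
            go_rts=go_rts, n_go_omissions=2, stops=stops, max_rt=800
        )
        est = integration_ssrt(session, replacement="deadline")
        # distribution 10 RTs + two 800s -> length 12, 12 * 0.4 = 4.8 -> rank 5
        assert est.n_go_distribution == 12
        assert est.n_omissions_replaced == 2
        assert est.rank_n == 5
        assert est.value == pytest.approx(480.0 - 200.0)

    def test_replacement_with_observed_max(self):
        session = make_session(
            go_rts=[400, 500, 600], n_go_omissions=1, stops=[(200, 450.0), (200, None)]
        )
        est = integration_ssrt(session, replacement="observed_max")
        # distribution [400, 500, 600, 600], p = 0.5 -> rank 2
        assert est.n_go_distribution == 4
        assert est.value == pytest.approx(500.0 - 200.0)

    def test_all_stops_responded_takes_slowest_go_rt(self, toy_session):
        for t in toy_session.trials:
            if t.is_stop and not t.responded:
                t.response, t.rt = "choice-1", 420.0
        est = integration_ssrt(toy_session)
        assert est.rank_n == est.n_go_distribution == 10
        assert est.value == pytest.approx(580.0 - 200.0)

    def test_without_replacement_omissions_ignored(self):
        go_rts = [400, 420, 440, 460, 480, 500, 520, 540, 560, 580]
        stops = [(200, 430.0)] * 4 + [(200, None)] * 6
        session = make_session(go_rts=go_rts, n_go_omissions=2, stops=stops)
        est = integration_ssrt(session, replace_omissions=False)
        assert est.method == "integration_noreplace"
        assert est.n_go_distribution == 10
        assert est.value == pytest.approx(460.0 - 200.0)

    def test_no_responded_stop_trials_is_an_error(self):
        session = make_session(go_rts=[500] * 4, stops=[(200, None)] * 4)
        with pytest.raises(EstimationError):
            integration_ssrt(session)


class TestMeanMethod:
    def test_toy_session(self, toy_session):
        est = mean_method_ssrt(toy_session)
        assert est.value == pytest.approx(290.0)  # mean 490 - mean SSD 200
        assert est.rank_n is None

    def test_identity_when_mean_rt_equals_mean_ssd(self):
        session = make_session(go_rts=[300, 500], stops=[(400, 350.0), (400, None)])
        assert mean_method_ssrt(session).value == pytest.approx(0.0)

    def test_no_go_responses_is_an_error(self):
        session = make_session(n_go_omissions=3, stops=[(200, 300.0)])
        with pytest.raises(EstimationError):
            mean_method_ssrt(session)


class TestIndependenceCheck:
    def test_faster_stop_responses_pass(self):
        session = make_session(go_rts=[520, 520], stops=[(200, 480.0), (200, None)])
        result = independence_check(session)
        assert result.applicable and not result.violation

    def test_numerically_longer_stop_rt_violates(self):
        session = make_session(go_rts=[520, 520], stops=[(200, 530.0), (200, None)])
        assert independence_check(session).violation

    def test_equal_means_pass(self):
        session = make_session(go_rts=[520], stops=[(200, 520.0)])
        assert not independence_check(session).violation

    def test_no_responded_stop_trials_inapplicable(self):
        session = make_session(go_rts=[520], stops=[(200, None)])
        result = independence_check(session)
        assert not result.applicable and not result.violation


class TestApplyExclusions:
    def test_p_respond_above_range_excludes(self):
        stops = [(200, 450.0)] * 8 + [(200, None)] * 2
        session = make_session(go_rts=[500] * 10, stops=stops)
        decision = apply_exclusions(session)
        assert decision.excluded
        assert decision.reasons == ["p_respond_out_of_range"]

    def test_inclusive_bounds_keep_boundary_subjects(self):
        stops = [(200, 450.0)] * 25 + [(200, None)] * 75  # exactly 0.25
        session = make_session(go_rts=[500] * 10, stops=stops)
        assert not apply_exclusions(session).excluded

    def test_clean_session_not_excluded(self):
        stops = [(200, 450.0)] * 5 + [(200, None)] * 5
        session = make_session(go_rts=[500] * 10, stops=stops)
        decision = apply_exclusions(session)
        assert not decision.excluded and decision.reasons == []

    def test_multiple_reasons_accumulate(self):
        stops = [(200, 530.0)] * 2 + [(200, None)] * 8  # slow stop RTs, p = 0.2
        session = make_session(go_rts=[500] * 10, stops=stops)
        decision = apply_exclusions(session)
        assert set(decision.reasons) == {
            "independence_violation",
            "p_respond_out_of_range",
        }

    def test_go_omission_ceiling(self):
        stops = [(200, 450.0)] * 5 + [(200, None)] * 5
        session = make_session(go_rts=[500] * 8, n_go_omissions=2, stops=stops)
        criteria = ExclusionCriteria(max_go_omission_rate=0.1)
        assert apply_exclusions(session, criteria).reasons == ["go_omission_rate"]

    def test_decision_is_idempotent(self):
        session = make_session(go_rts=[500] * 10, stops=[(200, 450.0)] * 10)
        a = apply_exclusions(session)
        b = apply_exclusions(session)
        assert a == b


class TestInhibitionFunction:
    def test_counting_per_ssd(self):
        stops = [(100, 400.0)] * 2 + [(100, None)] * 8
        stops += [(300, 400.0)] * 8 + [(300, None)] * 2
        session = make_session(go_rts=[500], stops=stops)
        assert inhibition_function(session) == {100.0: 0.2, 300.0: 0.8}

    def test_single_ssd(self):
        session = make_session(go_rts=[500], stops=[(250, None), (250, 400.0)])
        assert inhibition_function(session) == {250.0: 0.5}
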