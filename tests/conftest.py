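import pytest

from stoptask.trial_data import NO_RESPONSE, SessionData, TrialRecord


def make_session(
    go_rts=(),
    n_go_omissions=0,
    stops=(),
    probes=(),
    max_rt=1500.0,
    subject_id="s1",
    condition="c1",
    go_choice_errors=0,
    go_premature=0,
):
    """Construct a synthetic session from plain numbers.

    ``stops`` is a sequence of ``(ssd, rt_or_None)`` pairs; ``probes`` a
    sequence of ``rt_or_None`` for zero-SSD diagnostic trials.  The first
    ``go_choice_errors`` responded go trials are marked as choice errors,
    the first ``go_premature`` as premature.
    """
    trials = []
    idx = 0

    def add(**kw):
        nonlocal idx
        trials.append(
            TrialRecord(
                subject_id=subject_id, condition=condition, block=0,
                trial_index=idx, **kw,
            )
        )
        idx += 1

    for k, rt in enumerate(go_rts):
        add(
            trial_type="go",
            response="choice-2" if k < go_choice_errors else "choice-1",
            rt=float(rt),
            choice_correct=k >= go_choice_errors,
            premature=k < go_premature,
        )
    for _ in range(n_go_omissions):
        add(trial_type="go", response=NO_RESPONSE, rt=None)
    for ssd, rt in stops:
        add(
            trial_type="stop",
            ssd_requested=float(ssd),
            ssd_real=float(ssd),
            response="choice-1" if rt is not None else NO_RESPONSE,
            rt=float(rt) if rt is not None else None,
            choice_correct=True if rt is not None else None,
            premature=(rt is not None and rt < ssd),
        )
    for rt in probes:
        add(
            trial_type="stop",
            ssd_requested=0.0,
            ssd_real=0.0,
            response="choice-1" if rt is not None else NO_RESPONSE,
            rt=float(rt) if rt is not None else None,
            choice_correct=True if rt is not None else None,
            zero_ssd_probe=True,
        )
    return SessionData(trials=trials, max_rt=max_rt)


@pytest.fixture
def toy_session():
    """Ten go RTs 400..580, ten stop trials (4 responded), mean SSD 200.

    p(respond|signal) = 0.40; hand-executing the integration method gives
    rank 4 → 460 ms → SSRT = 260; the mean method gives 490 − 200 = 290.
    """
    go_rts = [400, 420, 440, 460, 480, 500, 520, 540, 560, 580]
    stops = [(150, 430), (200, 450), (250, 410), (200, 470)] + [(200, None)] * 6
    return make_session(go_rts=go_rts, stops=stops)
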