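"""Non-parametric SSRT estimation and validity checks.

Two consensus estimators are provided, both assuming the independent race
model and (for the mean method) an adaptive tracking design:

* **Integration method** — the stop process is assumed to finish at the go-RT
  quantile where the cumulative go-RT distribution equals p(respond|signal);
  SSRT = nth fastest go RT − mean SSD, with n = number of go-distribution RTs
  × p(respond|signal).  The recommended variant replaces each go omission
  with the maximum RT so the missing slow responses do not deflate the
  quantile.
* **Mean method** — assumes the tracking procedure converged on
  p(respond|signal) = 0.50, so that mean go RT = SSRT + mean SSD;
  SSRT = mean go RT − mean SSD.

Validity checks implement the consensus exclusion rules: the race-model
independence check (mean RT on unsuccessful stop trials must not exceed mean
go RT), the p(respond|signal) ∈ [0.25, 0.75] range, and a study-set go
omission ceiling.  Sessions are always evaluated per subject × condition.

Zero-SSD probe trials (trigger-failure diagnostics) are excluded from
p(respond|signal), mean SSD, and both estimators throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import fmean

from .trial_data import SessionData, TrialRecord

__all__ = [
    "SSRTEstimate",
    "ExclusionCriteria",
    "ExclusionDecision",
    "IndependenceResult",
    "EstimationError",
    "p_respond_signal",
    "mean_ssd",
    "nth_rt_index",
    "integration_ssrt",
    "mean_method_ssrt",
    "independence_check",
    "apply_exclusions",
    "inhibition_function",
    "ESTIMATORS",
]


class EstimationError(ValueError):
    """Estimation is undefined for this session (e.g. no stop trials)."""


@dataclass(frozen=True)
class SSRTEstimate:
    """An SSRT estimate with its intermediate quantities (all ms)."""

    method: str  # "integration_replace" | "integration_noreplace" | "mean"
    value: float
    p_respond_signal: float
    mean_ssd: float
    n_go_distribution: int
    rank_n: int | None = None
    n_omissions_replaced: int = 0


@dataclass(frozen=True)
class ExclusionCriteria:
    """Pre-registered validity rules applied before estimation.

    ``max_go_omission_rate`` is a study-level choice and defaults to no
    ceiling (``None``); set it per your design analysis.
    """

    p_low: float = 0.25
    p_high: float = 0.75
    max_go_omission_rate: float | None = None
    require_independence: bool = True

    def __post_init__(self):
        if not 0.0 <= self.p_low < self.p_high <= 1.0:
            raise ValueError(
                f"need 0 <= p_low < p_high <= 1, got [{self.p_low}, {self.p_high}]"
            )


@dataclass(frozen=True)
class IndependenceResult:
    applicable: bool
    violation: bool
    mean_usrt: float | None  # mean RT on unsuccessful (responded) stop trials
    mean_go_rt: float | None


@dataclass
class ExclusionDecision:
    excluded: bool
    reasons: list[str] = field(default_factory=list)
    mean_usrt: float | None = None
    mean_go_rt: float | None = None


def _stops(session: SessionData) -> list[TrialRecord]:
    return session.stop_trials(include_probes=False)


def p_respond_signal(session: SessionData) -> float:
    """Fraction of non-probe stop trials with *any* response.

    Premature and choice-error responses count as responses; zero-SSD probe
    trials are excluded from numerator and denominator.
    """
    stops = _stops(session)
    if not stops:
        raise EstimationError("no non-probe stop trials")
    return sum(t.responded for t in stops) / len(stops)


def mean_ssd(session: SessionData) -> float:
    """Mean SSD over non-probe stop trials (real SSD, falling back to requested)."""
    stops = _stops(session)
    if not stops:
        raise EstimationError("no non-probe stop trials")
    ssds = [t.ssd for t in stops if t.ssd is not None]
    if not ssds:
        raise EstimationError("stop trials carry no SSD values")
    return fmean(ssds)


def nth_rt_index(n_go: int, p_respond: float, rounding: str = "half_up") -> int:
    """Rank of the go-RT order statistic used by the integration method.

    rank = ``n_go × p_respond``, rounded (half-up by default, ``"ceiling"``
    as an alternative), clamped to ``[1, n_go]``.  E.g. 200 go RTs with
    p(respond|signal) = 0.45 → the 90th fastest go RT.
    """
    if n_go < 1:
        raise EstimationError(f"n_go must be >= 1, got {n_go}")
    if not 0.0 < p_respond <= 1.0:
        raise EstimationError(
            f"p_respond must be in (0, 1], got {p_respond}; "
            "no quantile is defined when no stop trial was responded"
        )
    x = n_go * p_respond
    if rounding == "half_up":
        rank = math.floor(x + 0.5)
    elif rounding == "ceiling":
        rank = math.ceil(x)
    else:
        raise ValueError(f"unknown rounding rule {rounding!r}")
    return min(max(rank, 1), n_go)


def _go_rt_distribution(
    session: SessionData, replace_omissions: bool, replacement: str
) -> tuple[list[float], int]:
    """Sorted go-RT distribution and the number of replaced omissions.

    All responded go trials enter at their recorded RT, choice errors and
    premature responses included.  With replacement, each go omission
    contributes one value: the maximum observed go RT (default) or the
    response deadline (``replacement="deadline"``).
    """
    responded = [t.rt for t in session.go_trials() if t.rt is not None]
    n_omissions = sum(1 for t in session.go_trials() if not t.responded)
    rts = list(responded)
    n_replaced = 0
    if replace_omissions and n_omissions:
        if replacement == "observed_max":
            if not responded:
                raise EstimationError(
                    "cannot replace omissions: no responded go trial to take "
                    "the maximum from"
                )
            fill = max(responded)
        elif replacement == "deadline":
            fill = float(session.max_rt)
        else:
            raise ValueError(f"unknown replacement rule {replacement!r}")
        rts.extend([fill] * n_omissions)
        n_replaced = n_omissions
    rts.sort()
    return rts, n_replaced


def integration_ssrt(
    session: SessionData,
    replace_omissions: bool = True,
    replacement: str = "observed_max",
    rounding: str = "half_up",
) -> SSRTEstimate:
    """Integration-method SSRT: nth fastest go RT minus mean SSD.

    ``replace_omissions`` assigns the maximum RT to every go omission before
    the quantile is taken (the recommended variant).
    """
    p = p_respond_signal(session)
    if p == 0.0:
        raise EstimationError("p(respond|signal) = 0: integration rank undefined")
    rts, n_replaced = _go_rt_distribution(session, replace_omissions, replacement)
    if not rts:
        raise EstimationError("empty go-RT distribution")
    ssd_bar = mean_ssd(session)
    rank = nth_rt_index(len(rts), p, rounding=rounding)
    method = "integration_replace" if replace_omissions else "integration_noreplace"
    return SSRTEstimate(
        method=method,
        value=rts[rank - 1] - ssd_bar,
        p_respond_signal=p,
        mean_ssd=ssd_bar,
        n_go_distribution=len(rts),
        rank_n=rank,
        n_omissions_replaced=n_replaced,
    )


def mean_method_ssrt(session: SessionData) -> SSRTEstimate:
    """Mean-method SSRT: mean responded go RT minus mean SSD (tracking designs)."""
    go_rts = [t.rt for t in session.go_trials() if t.rt is not None]
    if not go_rts:
        raise EstimationError("no responded go trials")
    ssd_bar = mean_ssd(session)
    return SSRTEstimate(
        method="mean",
        value=fmean(go_rts) - ssd_bar,
        p_respond_signal=p_respond_signal(session),
        mean_ssd=ssd_bar,
        n_go_distribution=len(go_rts),
        rank_n=None,
    )


def independence_check(session: SessionData) -> IndependenceResult:
    """Race-model independence check on the RT ordering.

    Under the race, responses that escape inhibition are the fast tail of the
    go distribution, so mean RT on unsuccessful stop trials must not be
    numerically longer than mean go RT.  All responded trials enter, choice
    errors and premature responses included.  Equality passes; a violation
    requires a strictly longer stop-trial mean.  With no responded stop trial
    the check is inapplicable (not a violation).
    """
    usrt = [t.rt for t in _stops(session) if t.rt is not None]
    go_rts = [t.rt for t in session.go_trials() if t.rt is not None]
    if not usrt or not go_rts:
        return IndependenceResult(
            applicable=False,
            violation=False,
            mean_usrt=fmean(usrt) if usrt else None,
            mean_go_rt=fmean(go_rts) if go_rts else None,
        )
    m_usrt, m_go = fmean(usrt), fmean(go_rts)
    return IndependenceResult(True, m_usrt > m_go, m_usrt, m_go)


def apply_exclusions(
    session: SessionData, criteria: ExclusionCriteria | None = None
) -> ExclusionDecision:
    """Evaluate every exclusion rule; callers must skip excluded sessions.

    Checks, in order: the independence check, the p(respond|signal) range
    (inclusive bounds), and the go-omission ceiling.  All failing reasons are
    listed; the decision never raises and is idempotent.
    """
    criteria = criteria or ExclusionCriteria()
    reasons: list[str] = []

    indep = independence_check(session)
    if criteria.require_independence and indep.violation:
        reasons.append("independence_violation")

    stops = _stops(session)
    if not stops:
        reasons.append("no_stop_trials")
    else:
        p = p_respond_signal(session)
        if p < criteria.p_low or p > criteria.p_high:
            reasons.append("p_respond_out_of_range")

    if criteria.max_go_omission_rate is not None:
        gos = session.go_trials()
        if gos:
            omission_rate = sum(1 for t in gos if not t.responded) / len(gos)
            if omission_rate > criteria.max_go_omission_rate:
                reasons.append("go_omission_rate")

    return ExclusionDecision(
        excluded=bool(reasons),
        reasons=reasons,
        mean_usrt=indep.mean_usrt,
        mean_go_rt=indep.mean_go_rt,
    )


def inhibition_function(
    session: SessionData, include_probes: bool = False
) -> dict[float, float]:
    """p(respond|signal) per distinct SSD, for fixed-delay designs.

    Returns a mapping SSD (ms) → responded fraction, sorted by SSD.  Under
    the race model the function is non-decreasing in SSD.  Also usable on
    staircase data (many sparse SSD levels).
    """
    counts: dict[float, list[int]] = {}
    for t in session.stop_trials(include_probes=include_probes):
        if t.ssd is None:
            continue
        bucket = counts.setdefault(float(t.ssd), [0, 0])
        bucket[0] += int(t.responded)
        bucket[1] += 1
    return {ssd: r / n for ssd, (r, n) in sorted(counts.items())}


def _integration_replace(session: SessionData) -> SSRTEstimate:
    return integration_ssrt(session, replace_omissions=True)


def _integration_noreplace(session: SessionData) -> SSRTEstimate:
    return integration_ssrt(session, replace_omissions=False)


#: Estimator registry used by the study runner and the CLI.
ESTIMATORS = {
    "integration_replace": _integration_replace,
    "integration_noreplace": _integration_noreplace,
    "mean": mean_method_ssrt,
}
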