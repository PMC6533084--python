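"""Consensus descriptive report for stop-signal sessions.

One summary per subject × condition, covering the fields every stop-signal
study should report: go omission and choice-error probabilities, go RT
central tendency and intra-subject variability, p(respond|signal), mean SSD,
SSRT, and mean RT on unsuccessful stop trials.  Directly observable fields
are reported even for subjects whose SSRT was not estimated; only the SSRT
itself is withheld, with the exclusion reasons recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean, median, stdev

import pandas as pd

from .estimation import (
    ExclusionDecision,
    SSRTEstimate,
    inhibition_function,
    mean_ssd,
    p_respond_signal,
)
from .trial_data import SessionData

__all__ = ["Box3Summary", "summarize_session", "summarize_group"]


@dataclass
class Box3Summary:
    """Per-subject × condition descriptive statistics (the reporting checklist)."""

    subject_id: str
    condition: str
    n_go: int
    n_stop: int
    p_go_omission: float | None
    p_choice_error_go: float | None
    go_rt_mean: float | None
    go_rt_median: float | None
    go_rt_sd: float | None  # intra-subject variability of responded go RTs
    p_respond_signal: float | None
    p_respond_per_ssd: dict[float, float] | None  # fixed-delay designs
    mean_ssd: float | None
    ssrt: float | None  # absent when the subject is excluded
    ssrt_method: str | None
    usrt_mean: float | None  # mean RT of responses on unsuccessful stop trials
    p_respond_zero_ssd: float | None  # probe trials, reported separately
    excluded: bool = False
    exclusion_reasons: list[str] = field(default_factory=list)


def summarize_session(
    session: SessionData,
    estimate: SSRTEstimate | None = None,
    decision: ExclusionDecision | None = None,
    *,
    per_ssd: bool = False,
    variability: str = "sd",
) -> Box3Summary:
    """Compute the descriptive summary of one session.

    Uses the same inclusion rules as estimation: responded trials include
    choice errors and premature responses; zero-SSD probes are excluded from
    stop-trial statistics and reported separately.  ``variability`` selects
    the intra-subject go-RT spread measure (``"sd"`` or ``"iqr"``).

    ``ssrt`` is taken from ``estimate`` only when ``decision`` does not
    exclude the subject; everything observable is reported regardless.
    """
    gos = session.go_trials()
    go_rts = [t.rt for t in gos if t.rt is not None]
    n_go_responded = len(go_rts)

    if variability == "sd":
        spread = stdev(go_rts) if len(go_rts) > 1 else 0.0 if go_rts else None
    elif variability == "iqr":
        if go_rts:
            s = pd.Series(go_rts)
            spread = float(s.quantile(0.75) - s.quantile(0.25))
        else:
            spread = None
    else:
        raise ValueError(f"unknown variability measure {variability!r}")

    stops = session.stop_trials(include_probes=False)
    probes = session.probe_trials()
    usrt = [t.rt for t in stops if t.rt is not None]

    excluded = bool(decision.excluded) if decision is not None else False
    subject_id = session.trials[0].subject_id if session.trials else "unknown"
    condition = session.trials[0].condition if session.trials else "default"

    return Box3Summary(
        subject_id=subject_id,
        condition=condition,
        n_go=len(gos),
        n_stop=len(stops),
        p_go_omission=(
            sum(1 for t in gos if not t.responded) / len(gos) if gos else None
        ),
        p_choice_error_go=(
            sum(1 for t in gos if t.choice_correct is False) / n_go_responded
            if n_go_responded
            else None
        ),
        go_rt_mean=fmean(go_rts) if go_rts else None,
        go_rt_median=median(go_rts) if go_rts else None,
        go_rt_sd=spread,
        p_respond_signal=p_respond_signal(session) if stops else None,
        p_respond_per_ssd=inhibition_function(session) if (per_ssd and stops) else None,
        mean_ssd=mean_ssd(session) if stops else None,
        ssrt=(estimate.value if (estimate is not None and not excluded) else None),
        ssrt_method=(estimate.method if (estimate is not None and not excluded) else None),
        usrt_mean=fmean(usrt) if usrt else None,
        p_respond_zero_ssd=(
            sum(t.responded for t in probes) / len(probes) if probes else None
        ),
        excluded=excluded,
        exclusion_reasons=list(decision.reasons) if decision is not None else [],
    )


_NUMERIC_FIELDS = [
    "p_go_omission",
    "p_choice_error_go",
    "go_rt_mean",
    "go_rt_median",
    "go_rt_sd",
    "p_respond_signal",
    "mean_ssd",
    "ssrt",
    "usrt_mean",
    "p_respond_zero_ssd",
]


def summarize_group(summaries: list[Box3Summary]) -> pd.DataFrame:
    """Group-level table: per-condition means/SDs plus exclusion accounting.

    One row per condition, columns ``<field>_mean`` / ``<field>_sd`` for each
    descriptive field (SSRT aggregated over included subjects only, the
    observable fields over everyone), the number of subjects, excluded count,
    and a tally of exclusion reasons.
    """
    if not summaries:
        raise ValueError("need at least one summary")
    frame = pd.DataFrame([vars(s) for s in summaries])
    rows = []
    for condition, grp in frame.groupby("condition", sort=True):
        row: dict = {"condition": condition, "n_subjects": len(grp)}
        for f in _NUMERIC_FIELDS:
            vals = grp[f].dropna()
            row[f"{f}_mean"] = float(vals.mean()) if len(vals) else None
            row[f"{f}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else (
                0.0 if len(vals) == 1 else None
            )
        row["n_excluded"] = int(grp["excluded"].sum())
        tally: dict[str, int] = {}
        for reasons in grp["exclusion_reasons"]:
            for r in reasons:
                tally[r] = tally.get(r, 0) + 1
        row["exclusion_reasons"] = (
            ";".join(f"{k}={v}" for k, v in sorted(tally.items())) or ""
        )
        rows.append(row)
    return pd.DataFrame(rows)


def format_report(summaries: list[Box3Summary]) -> str:
    """Human-readable plain-text report mirroring the checklist order."""
    lines: list[str] = []
    for s in summaries:
        lines.append(f"subject {s.subject_id} | condition {s.condition}")
        lines.append(f"  go trials: {s.n_go}   stop trials: {s.n_stop}")

        def fmt(label, value, unit=""):
            if value is None:
                lines.append(f"  {label}: n/a")
            else:
                lines.append(f"  {label}: {value:.3f}{unit}")

        fmt("P(go omission)", s.p_go_omission)
        fmt("P(choice error | go response)", s.p_choice_error_go)
        fmt("go RT mean", s.go_rt_mean, " ms")
        fmt("go RT median", s.go_rt_median, " ms")
        fmt("go RT intra-subject spread", s.go_rt_sd, " ms")
        fmt("P(respond | signal)", s.p_respond_signal)
        fmt("mean SSD", s.mean_ssd, " ms")
        fmt("SSRT", s.ssrt, " ms")
        fmt("mean RT on unsuccessful stops", s.usrt_mean, " ms")
        if s.p_respond_zero_ssd is not None:
            fmt("P(respond | zero-SSD probe)", s.p_respond_zero_ssd)
        if s.excluded:
            lines.append(
                "  EXCLUDED from SSRT estimation: " + ", ".join(s.exclusion_reasons)
            )
        lines.append("")
    return "\n".join(lines)
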