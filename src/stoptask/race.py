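"""Independent race-model simulator for stop-signal sessions.

The generative model: on every trial a *go runner* is started by the go
stimulus with an ex-Gaussian finishing time; on stop trials a *stop runner*
is started at the stop-signal delay (SSD) with its own ex-Gaussian latency
(the stop-signal reaction time, SSRT).  A response is emitted iff the go
runner finishes before the stop runner and before the response deadline.
The two finishing times are independent.

Imperfections of real data are modelled explicitly:

* **trigger failures** — with probability ``p_trigger_failure`` the stop
  runner is never started on a stop trial, so the go response escapes
  regardless of SSD;
* **go failures** — with probability ``p_go_failure`` the go runner is never
  started, producing a go omission (and, on stop trials, a guaranteed
  "successful" stop);
* **choice errors** — an emitted response is the wrong choice with
  probability ``p_choice_error``, independent of its latency.

SSD is managed either by the standard one-up/one-down staircase (up after a
successful stop, down after *any* response on a stop trial, premature and
choice-error responses included) or drawn from a fixed set of delays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .trial_data import NO_RESPONSE, SessionData, TrialRecord

__all__ = [
    "ExGaussianParams",
    "SubjectParams",
    "StaircaseConfig",
    "DesignConfig",
    "ParamDist",
    "PopulationParams",
    "ParameterError",
    "DesignError",
    "sample_exgaussian",
    "build_trial_sequence",
    "staircase_update",
    "default_staircase",
    "simulate_session",
    "sample_population",
]


class ParameterError(ValueError):
    """Invalid distribution or subject parameters."""


class DesignError(ValueError):
    """Invalid session design configuration."""


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class ExGaussianParams:
    """Ex-Gaussian latency distribution: Normal(mu, sigma) + Exponential(tau).

    ``tau`` controls the right skew; the distribution mean is ``mu + tau``
    and the variance ``sigma**2 + tau**2``.  ``tau = 0`` degenerates to a
    Gaussian.  All parameters in milliseconds.
    """

    mu: float
    sigma: float
    tau: float

    def __post_init__(self):
        if self.sigma < 0:
            raise ParameterError(f"sigma must be >= 0, got {self.sigma}")
        if self.tau < 0:
            raise ParameterError(f"tau must be >= 0, got {self.tau}")

    @property
    def mean(self) -> float:
        return self.mu + self.tau

    @property
    def variance(self) -> float:
        return self.sigma**2 + self.tau**2


@dataclass(frozen=True)
class SubjectParams:
    """Generative parameters of one simulated participant."""

    go: ExGaussianParams = ExGaussianParams(500.0, 50.0, 50.0)
    stop: ExGaussianParams = ExGaussianParams(200.0, 30.0, 20.0)
    p_trigger_failure: float = 0.0
    p_go_failure: float = 0.0
    p_choice_error: float = 0.0

    def __post_init__(self):
        for name in ("p_trigger_failure", "p_go_failure", "p_choice_error"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {p}")

    @property
    def true_ssrt(self) -> float:
        """Mean of the stop-latency distribution: stop.mu + stop.tau."""
        return self.stop.mean


@dataclass(frozen=True)
class StaircaseConfig:
    """One-up/one-down SSD tracker. Milliseconds throughout."""

    start: float = 200.0
    step: float = 50.0
    min: float = 0.0
    max: float = 1450.0

    def __post_init__(self):
        if self.step <= 0:
            raise ParameterError(f"staircase step must be > 0, got {self.step}")
        if not self.min <= self.start <= self.max:
            raise ParameterError(
                f"staircase start {self.start} outside [{self.min}, {self.max}]"
            )


@dataclass(frozen=True)
class DesignConfig:
    """Session design: trial counts, stop proportion, deadline, SSD regime.

    The 25% stop-signal proportion is the recommended default for standard
    designs; ``n_zero_ssd_probes`` extra flagged stop trials at SSD = 0 can
    be interleaved as a trigger-failure diagnostic.  The intertrial interval
    exists for design completeness only (the simulator has no anticipation
    model, so the ITI has no behavioural effect).
    """

    n_trials: int = 200
    p_stop: float = 0.25
    max_rt: float = 1500.0
    ssd_mode: str = "staircase"  # "staircase" | "fixed-set"
    fixed_ssds: tuple[float, ...] = ()
    n_zero_ssd_probes: int = 0
    iti_mode: str = "fixed"  # "fixed" | "exponential"
    iti_mean: float = 500.0
    iti_offset: float = 250.0
    iti_max: float = 2000.0

    def __post_init__(self):
        if not 0.0 <= self.p_stop < 1.0:
            raise DesignError(f"p_stop must be in [0, 1), got {self.p_stop}")
        if self.n_trials < 0:
            raise DesignError(f"n_trials must be >= 0, got {self.n_trials}")
        if self.max_rt <= 0:
            raise DesignError(f"max_rt must be > 0, got {self.max_rt}")
        if self.ssd_mode not in ("staircase", "fixed-set"):
            raise DesignError(f"unknown ssd_mode {self.ssd_mode!r}")
        if self.ssd_mode == "fixed-set" and not self.fixed_ssds:
            raise DesignError("fixed-set mode requires a non-empty fixed_ssds")
        if self.iti_mode not in ("fixed", "exponential"):
            raise DesignError(f"unknown iti_mode {self.iti_mode!r}")

    @property
    def n_stop(self) -> int:
        return round(self.n_trials * self.p_stop)

    @property
    def n_go(self) -> int:
        return self.n_trials - self.n_stop


def sample_exgaussian(
    params: ExGaussianParams, n: int, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Draw ``n`` ex-Gaussian finishing times (ms)."""
    if n < 0:
        raise ParameterError(f"n must be >= 0, got {n}")
    rng = _as_rng(rng)
    out = rng.normal(params.mu, params.sigma, size=n)
    if params.tau > 0:
        out = out + rng.exponential(params.tau, size=n)
    return out


@dataclass(frozen=True)
class TrialSlot:
    trial_type: str  # "go" | "stop"
    zero_ssd_probe: bool = False


def build_trial_sequence(
    design: DesignConfig, rng: np.random.Generator | int | None = None
) -> list[TrialSlot]:
    """Randomised trial order: exactly ``round(n_trials * p_stop)`` stop trials.

    Zero-SSD probes are extra flagged stop trials interleaved uniformly at
    random; they do not count toward ``n_trials``.
    """
    rng = _as_rng(rng)
    slots = [TrialSlot("stop")] * design.n_stop + [TrialSlot("go")] * design.n_go
    order = rng.permutation(len(slots))
    seq = [slots[i] for i in order]
    for _ in range(design.n_zero_ssd_probes):
        pos = int(rng.integers(0, len(seq) + 1))
        seq.insert(pos, TrialSlot("stop", zero_ssd_probe=True))
    return seq


def staircase_update(
    ssd: float, responded: bool, cfg: StaircaseConfig
) -> float:
    """Next SSD after a stop trial.

    Any response — including premature responses and choice errors — counts
    as an unsuccessful stop and lowers the SSD; a successful stop raises it.
    The result is clamped to ``[cfg.min, cfg.max]``.
    """
    if responded:
        return max(ssd - cfg.step, cfg.min)
    return min(ssd + cfg.step, cfg.max)


def default_staircase(design: DesignConfig) -> StaircaseConfig:
    """Staircase defaults: start 200 ms, step 50 ms, range [0, max_rt − step]."""
    return StaircaseConfig(start=200.0, step=50.0, min=0.0,
                           max=design.max_rt - 50.0)


def simulate_session(
    subject: SubjectParams,
    design: DesignConfig | None = None,
    stair: StaircaseConfig | None = None,
    rng: np.random.Generator | int | None = None,
    *,
    subject_id: str = "sim",
    condition: str = "default",
    go_failures_on_stop_trials: bool = True,
) -> SessionData:
    """Simulate one stop-signal session under the independent race model.

    Per trial: a go finishing time is drawn (or the go runner is never
    started, with ``p_go_failure``); on stop trials a stop finishing time
    ``SSD + SSRT draw`` is drawn (or the stop runner is never started, with
    ``p_trigger_failure``).  A response is recorded iff the go runner
    finishes first and before ``max_rt``.  The SSD staircase is advanced on
    every non-probe stop trial; zero-SSD probes are flagged and bypass the
    tracker.

    ``go_failures_on_stop_trials=False`` restricts go failures to go trials.
    """
    design = design or DesignConfig()
    stair = stair or default_staircase(design)
    rng = _as_rng(rng)

    seq = build_trial_sequence(design, rng)
    n = len(seq)
    go_rts = sample_exgaussian(subject.go, n, rng)
    stop_lat = sample_exgaussian(subject.stop, n, rng)
    u_gofail = rng.random(n)
    u_trigfail = rng.random(n)
    u_choice = rng.random(n)

    ssd = float(stair.start)
    trials: list[TrialRecord] = []
    for i, slot in enumerate(seq):
        is_stop = slot.trial_type == "stop"
        go_started = u_gofail[i] >= subject.p_go_failure
        if is_stop and not go_failures_on_stop_trials:
            go_started = True
        go_rt = go_rts[i] if go_started else math.inf

        if is_stop:
            if slot.zero_ssd_probe:
                trial_ssd = 0.0
            elif design.ssd_mode == "staircase":
                trial_ssd = ssd
            else:
                trial_ssd = float(
                    design.fixed_ssds[int(rng.integers(0, len(design.fixed_ssds)))]
                )
            triggered = u_trigfail[i] >= subject.p_trigger_failure
            stop_finish = trial_ssd + stop_lat[i] if triggered else math.inf
            responded = go_rt < stop_finish and go_rt <= design.max_rt
        else:
            trial_ssd = None
            responded = go_rt <= design.max_rt

        if responded:
            correct = u_choice[i] >= subject.p_choice_error
            response = "choice-1" if correct else "choice-2"
            rt: float | None = float(go_rt)
            choice_correct: bool | None = bool(correct)
        else:
            response, rt, choice_correct = NO_RESPONSE, None, None

        premature = bool(
            is_stop and rt is not None and trial_ssd is not None and rt < trial_ssd
        )

        trials.append(
            TrialRecord(
                subject_id=subject_id,
                condition=condition,
                block=0,
                trial_index=i,
                trial_type=slot.trial_type,
                ssd_requested=trial_ssd,
                ssd_real=trial_ssd,
                response=response,
                rt=rt,
                choice_correct=choice_correct,
                premature=premature,
                zero_ssd_probe=slot.zero_ssd_probe,
            )
        )

        if is_stop and not slot.zero_ssd_probe and design.ssd_mode == "staircase":
            ssd = staircase_update(ssd, responded, stair)

    return SessionData(
        trials=trials,
        max_rt=design.max_rt,
        metadata={"generator": "stoptask.race", "ssd_mode": design.ssd_mode},
    )


# --------------------------------------------------------------------------
# Populations of subjects

@dataclass(frozen=True)
class ParamDist:
    """Truncated-Gaussian between-subject distribution of one parameter."""

    mean: float
    sd: float = 0.0
    lower: float = -math.inf
    upper: float = math.inf

    def __post_init__(self):
        if self.sd < 0:
            raise ParameterError(f"sd must be >= 0, got {self.sd}")
        if not self.lower <= self.mean <= self.upper:
            raise ParameterError(
                f"mean {self.mean} outside truncation bounds "
                f"[{self.lower}, {self.upper}]"
            )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0:
            return np.full(n, self.mean)
        out = np.empty(n)
        todo = np.arange(n)
        # rejection sampling; bounds always contain the mean, so this terminates
        while todo.size:
            draw = rng.normal(self.mean, self.sd, size=todo.size)
            ok = (draw >= self.lower) & (draw <= self.upper)
            out[todo[ok]] = draw[ok]
            todo = todo[~ok]
        return out


@dataclass(frozen=True)
class PopulationParams:
    """Between-subject parameter distributions.

    Defaults describe a healthy adult population performing a standard
    two-choice stop-signal task: mean go RT ≈ 550 ms with moderate skew,
    mean SSRT ≈ 220 ms, and low failure rates.
    """

    go_mu: ParamDist = ParamDist(500.0, 50.0, 200.0, 1000.0)
    go_sigma: ParamDist = ParamDist(50.0, 10.0, 5.0, 200.0)
    go_tau: ParamDist = ParamDist(50.0, 20.0, 1.0, 400.0)
    stop_mu: ParamDist = ParamDist(200.0, 30.0, 50.0, 500.0)
    stop_sigma: ParamDist = ParamDist(30.0, 8.0, 2.0, 100.0)
    stop_tau: ParamDist = ParamDist(20.0, 8.0, 1.0, 150.0)
    p_trigger_failure: ParamDist = ParamDist(0.0, 0.0, 0.0, 1.0)
    p_go_failure: ParamDist = ParamDist(0.0, 0.0, 0.0, 1.0)
    p_choice_error: ParamDist = ParamDist(0.0, 0.0, 0.0, 1.0)

    def with_overrides(self, **dists: ParamDist) -> "PopulationParams":
        return replace(self, **dists)


def sample_population(
    pop: PopulationParams,
    n_subjects: int,
    rng: np.random.Generator | int | None = None,
) -> list[SubjectParams]:
    """Draw a roster of subjects; independent truncated-Gaussian fields."""
    if n_subjects < 1:
        raise ParameterError(f"n_subjects must be >= 1, got {n_subjects}")
    rng = _as_rng(rng)
    cols = {
        name: getattr(pop, name).sample(n_subjects, rng)
        for name in (
            "go_mu", "go_sigma", "go_tau",
            "stop_mu", "stop_sigma", "stop_tau",
            "p_trigger_failure", "p_go_failure", "p_choice_error",
        )
    }
    return [
        SubjectParams(
            go=ExGaussianParams(cols["go_mu"][i], cols["go_sigma"][i],
                                cols["go_tau"][i]),
            stop=ExGaussianParams(cols["stop_mu"][i], cols["stop_sigma"][i],
                                  cols["stop_tau"][i]),
            p_trigger_failure=float(np.clip(cols["p_trigger_failure"][i], 0, 1)),
            p_go_failure=float(np.clip(cols["p_go_failure"][i], 0, 1)),
            p_choice_error=float(np.clip(cols["p_choice_error"][i], 0, 1)),
        )
        for i in range(n_subjects)
    ]
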