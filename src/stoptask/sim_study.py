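"""Factorial Monte-Carlo studies of SSRT estimator bias, reliability and power.

A *cell* is one combination of design and population factors (number of stop
trials, go-failure rate, go-RT skew, ...).  For each replication the runner
samples a roster of subjects, simulates a full staircase session per subject,
applies the consensus exclusion rules *before* estimation, and estimates SSRT
per included subject with each requested estimator.  Reported per cell:

* bias — mean(estimated − true SSRT), where true SSRT is the mean of the
  generating stop-latency distribution (stop.mu + stop.tau);
* SD of the bias scores;
* Pearson correlation between estimated and true SSRT across included
  subjects (reliability), averaged over replications;
* exclusion counts, shared across estimators (the validity checks are
  estimator-independent).

The power planner simulates two groups whose true mean SSRT differs by a
target amount, runs a Welch two-sample t-test on the per-subject estimates,
and reports the rejection rate with its binomial standard error — the tool
for trading off trial numbers against sample size at the design stage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import ESTIMATORS, ExclusionCriteria, apply_exclusions
from .race import (
    DesignConfig,
    ParamDist,
    PopulationParams,
    default_staircase,
    sample_population,
    simulate_session,
)

__all__ = [
    "CellSpec",
    "CellResult",
    "PowerSpec",
    "PowerResult",
    "run_cell",
    "run_factorial",
    "make_grid",
    "estimate_power",
]


@dataclass(frozen=True)
class CellSpec:
    """One cell of the factorial simulation design."""

    n_stop_trials: int = 50
    p_stop: float = 0.25
    n_subjects: int = 25
    n_replications: int = 1
    tau_go: float | None = None  # overrides the population mean go-RT skew
    p_go_failure: float | None = None  # overrides the go-omission rate (point value)
    p_trigger_failure: float | None = None
    population: PopulationParams = field(default_factory=PopulationParams)
    estimators: tuple[str, ...] = ("integration_replace", "mean")
    criteria: ExclusionCriteria = field(default_factory=ExclusionCriteria)
    max_rt: float = 1500.0
    master_seed: int = 12345

    def __post_init__(self):
        if self.n_stop_trials < 1 or self.n_subjects < 1 or self.n_replications < 1:
            raise ValueError("counts and replications must be >= 1")
        unknown = set(self.estimators) - set(ESTIMATORS)
        if unknown:
            raise ValueError(f"unknown estimator(s): {sorted(unknown)}")

    @property
    def n_trials(self) -> int:
        return round(self.n_stop_trials / self.p_stop)

    def effective_population(self) -> PopulationParams:
        pop = self.population
        if self.tau_go is not None:
            pop = pop.with_overrides(
                go_tau=replace(pop.go_tau, mean=self.tau_go,
                               upper=max(pop.go_tau.upper, self.tau_go))
            )
        if self.p_go_failure is not None:
            pop = pop.with_overrides(
                p_go_failure=ParamDist(self.p_go_failure, 0.0, 0.0, 1.0)
            )
        if self.p_trigger_failure is not None:
            pop = pop.with_overrides(
                p_trigger_failure=ParamDist(self.p_trigger_failure, 0.0, 0.0, 1.0)
            )
        return pop


@dataclass
class CellResult:
    """Aggregated outcome of one simulation cell."""

    spec: CellSpec
    n_included: int
    n_excluded: int
    frac_excluded: float
    exclusion_reasons: dict[str, int]
    bias_mean: dict[str, float]  # per estimator, ms
    bias_sd: dict[str, float]
    correlation_true: dict[str, float | None]  # None when < 3 included subjects
    n_flagged_replications: int  # replications with every subject excluded


def _simulate_roster(spec: CellSpec, seed: np.random.SeedSequence):
    """One replication: (true_ssrt, session, decision) per subject."""
    rng_pop = np.random.default_rng(seed.spawn(1)[0])
    subjects = sample_population(spec.effective_population(), spec.n_subjects, rng_pop)
    design = DesignConfig(
        n_trials=spec.n_trials, p_stop=spec.p_stop, max_rt=spec.max_rt
    )
    stair = default_staircase(design)
    out = []
    for subj, child in zip(subjects, seed.spawn(spec.n_subjects)):
        session = simulate_session(
            subj, design, stair, np.random.default_rng(child)
        )
        decision = apply_exclusions(session, spec.criteria)
        out.append((subj.true_ssrt, session, decision))
    return out


def run_cell(spec: CellSpec) -> CellResult:
    """Run every replication of one cell and aggregate.

    Exclusions are decided once per simulated subject, before estimation, and
    shared across estimators.  A replication in which every subject is
    excluded is flagged and omitted from the aggregates, never silently
    dropped.
    """
    root = np.random.SeedSequence(spec.master_seed)
    errors: dict[str, list[float]] = {e: [] for e in spec.estimators}
    per_rep_corr: dict[str, list[float]] = {e: [] for e in spec.estimators}
    n_excluded = 0
    n_total = 0
    n_flagged = 0
    reason_tally: dict[str, int] = {}

    for rep_seed in root.spawn(spec.n_replications):
        roster = _simulate_roster(spec, rep_seed)
        n_total += len(roster)
        included = [(t, s) for t, s, d in roster if not d.excluded]
        for _, _, d in roster:
            if d.excluded:
                n_excluded += 1
                for r in d.reasons:
                    reason_tally[r] = reason_tally.get(r, 0) + 1
        if not included:
            n_flagged += 1
            continue
        truths = np.array([t for t, _ in included])
        for name in spec.estimators:
            est = np.array([ESTIMATORS[name](s).value for _, s in included])
            errors[name].extend(est - truths)
            if len(included) >= 3 and truths.std() > 0 and est.std() > 0:
                per_rep_corr[name].append(float(np.corrcoef(est, truths)[0, 1]))

    return CellResult(
        spec=spec,
        n_included=n_total - n_excluded,
        n_excluded=n_excluded,
        frac_excluded=n_excluded / n_total if n_total else float("nan"),
        exclusion_reasons=reason_tally,
        bias_mean={e: float(np.mean(v)) if v else float("nan")
                   for e, v in errors.items()},
        bias_sd={e: float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
                 for e, v in errors.items()},
        correlation_true={
            e: (float(np.mean(c)) if c else None) for e, c in per_rep_corr.items()
        },
        n_flagged_replications=n_flagged,
    )


_FACTOR_FIELDS = (
    "n_stop_trials", "p_stop", "n_subjects", "tau_go",
    "p_go_failure", "p_trigger_failure",
)


def make_grid(base: CellSpec, factors: dict[str, Sequence]) -> list[CellSpec]:
    """Expand a factor dictionary into the full crossing of cells."""
    names = list(factors)
    cells = [
        replace(base, **dict(zip(names, combo)))
        for combo in itertools.product(*(factors[n] for n in names))
    ]
    return cells


def run_factorial(
    grid: list[CellSpec], master_seed: int | None = None
) -> tuple[pd.DataFrame, list[CellResult]]:
    """Run every cell of a factorial grid; one table row per cell.

    With ``master_seed`` given, per-cell seeds are derived from it so the
    whole study is reproducible from one integer; otherwise each cell uses
    its own ``master_seed``.  Duplicate factor combinations are rejected.
    """
    if not grid:
        raise ValueError("empty factor grid")
    keys = [tuple(getattr(c, f) for f in _FACTOR_FIELDS) for c in grid]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate factor combinations in grid")

    if master_seed is not None:
        seeds = np.random.SeedSequence(master_seed).generate_state(len(grid)) % (2**31)
        grid = [replace(c, master_seed=int(s)) for c, s in zip(grid, seeds)]

    results = [run_cell(c) for c in grid]
    rows = []
    for res in results:
        row: dict = {f: getattr(res.spec, f) for f in _FACTOR_FIELDS}
        row.update(
            n_included=res.n_included,
            n_excluded=res.n_excluded,
            frac_excluded=res.frac_excluded,
            n_flagged_replications=res.n_flagged_replications,
        )
        for e in res.spec.estimators:
            row[f"bias_{e}"] = res.bias_mean[e]
            row[f"bias_sd_{e}"] = res.bias_sd[e]
            row[f"r_true_{e}"] = res.correlation_true[e]
        rows.append(row)
    return pd.DataFrame(rows), results


@dataclass(frozen=True)
class PowerSpec:
    """Two-group power study: groups differ in true mean SSRT by ``delta_ssrt``."""

    delta_ssrt: float
    n_subjects_per_group: int
    n_stop_trials: int = 50
    p_stop: float = 0.25
    population: PopulationParams = field(default_factory=PopulationParams)
    estimator: str = "integration_replace"
    criteria: ExclusionCriteria = field(default_factory=ExclusionCriteria)
    alpha: float = 0.05
    n_replications: int = 200
    max_rt: float = 1500.0
    master_seed: int = 12345

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_subjects_per_group < 2 or self.n_replications < 1:
            raise ValueError("need >= 2 subjects per group and >= 1 replication")


@dataclass
class PowerResult:
    power: float
    se: float  # binomial Monte-Carlo standard error
    alpha: float
    n_effective_replications: int
    n_flagged_replications: int  # < 2 included subjects in a group


def _group_estimates(spec: PowerSpec, pop, seed) -> np.ndarray:
    cell = CellSpec(
        n_stop_trials=spec.n_stop_trials,
        p_stop=spec.p_stop,
        n_subjects=spec.n_subjects_per_group,
        population=pop,
        estimators=(spec.estimator,),
        criteria=spec.criteria,
        max_rt=spec.max_rt,
    )
    roster = _simulate_roster(cell, seed)
    est = ESTIMATORS[spec.estimator]
    return np.array([est(s).value for _, s, d in roster if not d.excluded])


def estimate_power(spec: PowerSpec) -> PowerResult:
    """Monte-Carlo power of a Welch two-sample comparison of estimated SSRT.

    Group 2's population mean stop latency is shifted by ``delta_ssrt``;
    each replication simulates both groups end to end (session simulation,
    exclusions, estimation) and tests group means at ``alpha`` (two-sided).
    """
    pop_a = spec.population
    shifted = replace(
        pop_a.stop_mu,
        mean=pop_a.stop_mu.mean + spec.delta_ssrt,
        upper=max(pop_a.stop_mu.upper, pop_a.stop_mu.mean + spec.delta_ssrt),
        lower=min(pop_a.stop_mu.lower, pop_a.stop_mu.mean + spec.delta_ssrt),
    )
    pop_b = pop_a.with_overrides(stop_mu=shifted)

    root = np.random.SeedSequence(spec.master_seed)
    rejections = 0
    effective = 0
    flagged = 0
    for rep_seed in root.spawn(spec.n_replications):
        seed_a, seed_b = rep_seed.spawn(2)
        a = _group_estimates(spec, pop_a, seed_a)
        b = _group_estimates(spec, pop_b, seed_b)
        if len(a) < 2 or len(b) < 2:
            flagged += 1
            continue
        effective += 1
        pval = stats.ttest_ind(a, b, equal_var=False).pvalue
        rejections += pval < spec.alpha

    power = rejections / effective if effective else float("nan")
    se = (
        float(np.sqrt(power * (1 - power) / effective)) if effective else float("nan")
    )
    return PowerResult(
        power=power,
        se=se,
        alpha=spec.alpha,
        n_effective_replications=effective,
        n_flagged_replications=flagged,
    )


def plot_factorial(table: pd.DataFrame, path, estimators=("integration_replace", "mean")):
    """Panel plot of bias and reliability against the number of stop trials."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for e in estimators:
        sub = table.sort_values("n_stop_trials")
        axes[0].plot(sub["n_stop_trials"], sub[f"bias_{e}"], marker="o", label=e)
        axes[1].plot(sub["n_stop_trials"], sub[f"r_true_{e}"], marker="o", label=e)
    axes[0].axhline(0, color="grey", lw=0.5)
    axes[0].set_xlabel("stop trials")
    axes[0].set_ylabel("bias (ms)")
    axes[1].set_xlabel("stop trials")
    axes[1].set_ylabel("r(estimated, true)")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
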