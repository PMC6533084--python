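# Methods

## Generative model

Each simulated trial is an independent race.  The go runner's finishing time
is ex-Gaussian, `Normal(mu_go, sigma_go) + Exp(tau_go)` (milliseconds from go
onset); on stop trials the stop runner finishes at `SSD + Normal(mu_stop,
sigma_stop) + Exp(tau_stop)`.  A response is emitted iff the go runner
finishes first and within the deadline `max_rt`.  The model's auxiliary
failure processes are Bernoulli and independent of the latencies:

* `p_trigger_failure` — the stop runner is never started on a stop trial, so
  the go response escapes at any SSD.  This is what zero-SSD probe trials
  diagnose: at SSD = 0 a triggered stop process virtually always wins, so the
  probe response rate approximates the trigger-failure rate.
* `p_go_failure` — the go runner is never started, producing a go omission.
  By default this applies on stop trials too (a non-started go runner cannot
  respond, so such trials register as successful stops); switchable with
  `go_failures_on_stop_trials=False` since the behavior of go failures on
  stop trials is not observable in real data.
* `p_choice_error` — an emitted response is the wrong choice, drawn
  independently of its latency (default 0).  The toolkit needs such trials
  only so the estimators can be shown to include them; no RT–accuracy
  dependency is modelled.

The true mean SSRT of a simulated subject is `mu_stop + tau_stop`, the mean of
the generating stop-latency distribution; bias and reliability in the study
runner are measured against it.

### SSD management

The default staircase starts at 200 ms and moves in 50 ms steps, clamped to
`[0, max_rt − step]`: up after a successful stop, down after *any* response on
a stop trial — premature responses (RT < SSD) and choice errors included.
One global tracker per session (the simplest standard arrangement; per-hand
trackers are out of scope).  This converges on p(respond|signal) ≈ 0.50; in a
1600-trial session the overall responded-stop fraction lands within ±0.01 of
0.50 across seeds.  Fixed-delay designs draw each stop trial's SSD uniformly
from a user-given set.  Zero-SSD probe trials are interleaved uniformly at
random, flagged, and bypass the tracker.

Requested and real SSD are distinct columns in the data schema because on real
hardware they differ (screen-refresh quantization); the simulator writes the
same value to both, and estimation prefers `ssd_real`, falling back to
`ssd_requested`.

### Intertrial interval

`DesignConfig` accepts a fixed or shifted-truncated-exponential ITI for design
completeness, but the simulator has no anticipation model, so the ITI has no
behavioral effect on generated data.

## Estimators

* **Integration with replacement** (default): the go-RT distribution is every
  responded go trial at its recorded RT (choice errors and premature responses
  included — a premature go response with negative RT enters as recorded),
  plus one value per go omission equal to the maximum observed go RT within
  the subject × condition (configurable to the deadline `max_rt`; the
  "maximum RT" convention is ambiguous between the two and observed-max is
  the default).  SSRT = nth fastest value − mean SSD, with rank
  n = length × p(respond|signal), rounded half-up and clamped to
  `[1, length]`.  The rounding rule is configurable (`ceiling` available);
  half-up reproduces the canonical example (200 × 0.45 → rank 90) and behaves
  symmetrically for fractional ranks.
* **Integration without replacement**: same, omissions simply dropped; kept
  for comparison since it is common in older work.
* **Mean method**: mean responded go RT − mean SSD.  Valid only for tracking
  designs, and biased upward by go-RT skew and omissions.

p(respond|signal) and mean SSD count every non-probe stop trial; any response
(premature, choice error) makes a stop trial unsuccessful.  Zero-SSD probes
are excluded from p(respond|signal), mean SSD, and both estimators, and their
response rate is reported separately.

## Validity and exclusion rules

Applied per subject × condition, before estimation, in a fixed order:

1. **Independence check** — mean RT over all responded stop trials strictly
   greater than mean RT over all responded go trials flags a race-model
   violation (equality passes: the criterion is "numerically longer").
   Inapplicable (and not a violation) when no stop trial was responded.
2. **p(respond|signal) window** — outside `[0.25, 0.75]` (inclusive bounds:
   only strict deviations exclude).
3. **Go-omission ceiling** — optional, study-set; off by default.

All failing reasons are listed, the decision is idempotent, and exclusion is
estimator-independent, so excluded counts are shared across estimators in the
study runner.  Directly observable statistics are always reported for excluded
subjects; only SSRT is withheld.

## Descriptive report

One summary per subject × condition: go-omission probability (denominator:
all go trials), choice-error probability (denominator: responded go trials —
the two denominators deliberately differ), mean and median go RT (both, to
avoid choosing), intra-subject go-RT variability (SD by default, IQR
optional), p(respond|signal) (per SSD for fixed-delay designs), mean SSD,
SSRT, mean RT on unsuccessful stop trials, and the probe response rate.
Group tables add per-condition means/SDs, excluded counts and reason tallies.

## Monte-Carlo studies

A factorial **cell** fixes the number of stop trials (total trials =
`n_stop_trials / p_stop`), the go-omission rate, the go skew `tau_go`, and a
population; each replication samples subjects (independent truncated-Gaussian
parameters), simulates full staircase sessions, applies the exclusion rules,
then estimates SSRT per included subject with each estimator.  Reported:
mean and SD of (estimated − true) SSRT, the per-replication Pearson
correlation between estimated and true SSRT averaged over replications
(Spearman is a one-line change via the estimate arrays), and exclusion
counts.  Replications where every subject is excluded are flagged and
excluded from aggregates, never silently dropped.

Power planning simulates two groups whose population mean stop latency
differs by `delta_ssrt`, applies the same pipeline, and runs a two-sided
Welch (unequal-variance) two-sample t-test on the per-subject estimates at
`alpha` (default 0.05).  The test is a deliberate choice — no canonical test
exists for this comparison — and the estimator is configurable.  Power is
the rejection fraction with its binomial standard error; at `delta_ssrt = 0`
the procedure is calibrated (rejection rate within Monte-Carlo error of
alpha).

### Default population

Healthy-adult-like values, chosen once: go `mu ~ N(500, 50)`, `sigma ~
N(50, 10)`, `tau ~ N(50, 20)`; stop `mu ~ N(200, 30)`, `sigma ~ N(30, 8)`,
`tau ~ N(20, 8)` (all ms, truncated to positive plausible ranges so every
sampled subject is valid); failure probabilities default to point masses at
0.  These give mean go RT ≈ 550 ms, true SSRT ≈ 220 ms, and a staircase
operating range comfortably inside `[0, max_rt]`.

### Problem sizes

The shipped tests and the acceptance script use: 1600-trial sessions (400
stop trials) for staircase-convergence checks; 12 000-trial fixed-SSD
sessions per delay for the race-integral comparison; 200 subjects × 200 stop
trials for the unbiasedness check of the integration estimator (observed
bias ≈ −2.5 ms, well inside the ±10 ms criterion); 100–200 subjects per cell
for directional comparisons; 400 replications for type-I calibration.  These
sizes put Monte-Carlo error well below the effects being checked while
keeping a full run in a few minutes on one core.

## Numerical choices

* RTs and SSDs are real-valued ms internally; file output preserves full
  precision by default (`round_ms=True` rounds on write).
* Rank rounding: half-up; ties in sorted RTs resolved by position (stable
  sort), which cannot change the selected value.
* Randomness: `numpy.random.Generator` throughout; factorial cells and
  subjects get independent child streams spawned from one master seed
  (`SeedSequence`), so every study is reproducible from a single integer and
  cells are mutually independent.
* Degenerate inputs raise typed errors (`EstimationError`, `ParameterError`,
  `DesignError`) with messages naming the offending quantity; validation and
  exclusion functions report rather than raise.

## What the simulator does and does not emulate

It emulates: ex-Gaussian go and stop latencies, staircase or fixed SSDs,
trigger/go failures, choice errors, deadline censoring, zero-SSD probes, and
between-subject parameter variation.  It does **not** emulate proactive
slowing or waiting strategies, sequential effects (post-stop slowing,
learning, fatigue), RT–accuracy dependence, context-dependent (non-independent)
races, or SSD quantization to screen refreshes.  Tests passing on simulated
data therefore validate the estimators *under the race model's assumptions*;
they cannot certify behavior on real data that violates those assumptions —
that is exactly what the independence check and exclusion rules are for.

## Known limitations

* The mean method is implemented in its simple tracked-design form only.
* No parametric or Bayesian SSRT estimation, and no estimation of the
  trigger-failure probability; the zero-SSD probe response rate is exposed as
  a diagnostic instead.
* Between-subject parameters are sampled independently; real populations show
  correlated parameters (e.g. go mean with go skew).
* The power planner compares two independent groups; within-subject and
  factorial inference designs are out of scope.
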