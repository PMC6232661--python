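# Methods

## The model

`hfacsbn` models the 3-month risk of a needlestick or sharps injury (NSI)
among hospital nurses as a discrete Bayesian network whose topology is fixed
by the Human Factors Analysis and Classification System (HFACS). Twelve
questionnaire-measured variables occupy four causal levels:

| level | role | variables (states) |
|---|---|---|
| 4 | organizational influences | management commitment (poor/moderate/good), staffing (poor/moderate/good), availability of safe work procedures (yes/no) |
| 3 | unsafe supervision | night shifts per month (normal ≤8 / high 9–11 / very high ≥12), working hours per week (normal <45 / high 45–55 / very high >55), supervisors' attitude toward safety, safety training (both poor/moderate/good) |
| 2 | preconditions for unsafe acts | fatigue (low/moderate/high), teamwork, physical environment, safety motivation (poor/moderate/good) |
| 1 | outcome | NSI in the last 3 months (yes/no) |

Two structural assumptions define the DAG: variables within a level are
mutually independent given the level above (no within-level edges), and
every variable of a level is a direct parent of every variable in the level
immediately below. This yields 32 edges and 1,358 CPT entries; the largest
table (a level-2 node with four ternary parents) has 3^5 = 243 entries,
which also sets the minimum number of training cases the design calls for.
The joint distribution factorizes as P(x₁…x₁₂) = Π P(xᵢ | pa(xᵢ)); parent
configurations are indexed mixed-radix over the ordered parent list with the
last parent fastest, and that canonical order is used everywhere (JSON and
XMLBIF serialization, learning counts, fixtures).

## Measurement and discretization

Eight constructs are measured with 5-point Likert scales (5 items for
management commitment, 4 each for the rest; 33 items). A scale's score is
the mean of its answered items, accepted when at least half the items were
answered, missing otherwise; residual missingness is handled by EM rather
than imputation. Scores in [1, 5] are cut into three equal intervals,
left-closed ([1, 7/3), [7/3, 11/3), [11/3, 5]), so every legal score maps to
exactly one state; re-discretizing a state label is an error by design, not
a no-op. Working hours and night shifts use the interval definitions in the
table above; the two binary questions pass through.

Respondents whose Likert items are all answered with one identical value
across the entire questionnaire (zero-variance straight-lining) are
discarded before any scoring; this is the only quality filter, and it never
modifies retained records. Reliability is reported per scale as Cronbach's
alpha with sample variances and listwise deletion; zero total variance is
signalled as an explicit error rather than returned as NaN.

Train/test splitting mirrors the study design of 343 training and 50 test
cases out of 393 usable: with ≥ 393 retained records the exact sizes are
used (excess records left unassigned), otherwise sizes scale proportionally
(test = round(n·50/393)). Test cases are drawn only from records with an
observed outcome, since held-out scoring needs the label; records missing
the outcome remain usable by EM in training.

## Inference

All posteriors are exact. Two independent routes exist: a full-joint
enumeration engine that materializes the 236,196-cell joint table (the
oracle, also the EM E-step engine — at 12 variables the dense table is
cheaper than per-record elimination), and variable elimination with a
min-fill ordering, ties broken by canonical variable order. The two are
required to agree to 1e-9 and the elimination result is invariant to the
elimination order. Evidence with probability zero raises a dedicated
`ImpossibleEvidenceError` so that callers can distinguish impossible
observations from bugs.

## Learning

Complete-data estimation is the smoothed relative frequency
P(x | pa) = (N(x, pa) + c)/(N(pa) + cK) with pseudocount c (default 1,
a uniform Dirichlet prior; it keeps every CPT entry positive, which the
logarithmic loss requires). Unseen parent configurations fall back to the
smoothed uniform row. EM alternates an exact E-step (expected family counts
from the joint conditioned on each record's observed values; duplicate
observation patterns are collapsed first) with that M-step. Convergence is
declared when the relative change of the objective falls below 1e-6, with a
cap of 500 iterations; initialization is uniform, with optional seeded
Dirichlet jitter for multi-start.

Because a positive pseudocount makes each M-step a MAP update, the
monotonically non-decreasing quantity is the penalized objective
log-likelihood + c·Σ log θ, and that is what the fit's trace records (it
equals the raw log-likelihood at c = 0); the raw observed-data
log-likelihood is reported separately.

## Validation

Held-out cases are scored by entering each record's non-missing predictor
states as evidence and reading the outcome posterior. Four indices, all
means over cases: error rate in percent under argmax classification (ties
classified "yes" — the conservative call for an injury outcome);
logarithmic loss −ln P_c (natural log by default, base configurable);
quadratic (Brier) loss 1 − 2P_c + Σ P_j², range 0–2; spherical payoff
P_c / √(Σ P_j²), range 0–1, higher better.

## Sensitivity and interventions

Predictive reasoning scans each predictor's states and records the worst
and best posterior of P(NSI = no); the sensitivity index is the relative
percent gain 100·(best − worst)/worst, reported to one decimal. Mutual
information I(X; NSI) in bits is computed from the exact pairwise joint and
also expressed as a percent of the outcome entropy H(NSI). Predictors are
reported grouped by HFACS level (preconditions, unsafe supervision,
organizational influences), strongest first within each group.

An intervention is an evidence set; its effect is the conditional NSI rate
100 − P(NSI = no | evidence) in percent, compared to the no-evidence
baseline. This is observational conditioning — what predictive reasoning on
this network means — not graph surgery; a truncated-product do-operator
mode exists behind a flag for comparison (the two coincide for root
variables).

## Synthetic study generator

The generator emulates the study conditions so the pipeline is testable
without the undeposited hospital data: 408 respondents per study, of which
14 are straight-liners; ~2% missingness per item and per direct answer;
item noise s.d. 0.6 around state-specific Likert centers (2/3/4 for the
first/second/third state), which places per-scale alphas around 0.78–0.86
and lets the re-discretized item means recover the latent state ≥ 90% of
the time. Working-hour and night-shift answers are integers drawn uniformly
inside the latent state's interval (capped at 84 h/week and 16
nights/month).

Ground-truth CPTs are monotone by construction: a child's favorable-state
propensity is θ = clip(b + β·(ḡ − ½)), where ḡ is the mean "goodness" of
the parents' states; three-state children receive a binomial(2, θ)
distribution over their goodness-ranked states, binary children put θ on
the favorable state. Effect strengths β default to 0.5 per inter-level
bundle and 0.4 into the outcome — moderate dependencies of the size
survey-based safety-climate studies typically report. Four marginals are
calibrated by bisection against exact inference (no sampling error): NSI
yes 27.9%, staffing moderate-or-good 55.4%, procedures available 75.8%,
safety motivation good 43.2%. The four level-2 variables are structurally
symmetric apart from the motivation calibration, so their sensitivities
and mutual informations are near-ties by design.

What the generator does not emulate: hospital-level clustering (a
hospital-ID column is emitted but unused), respondent demographics,
non-straight-lining careless response styles, informative missingness, and
any real-world deviation from the layered-complete topology. Passing tests
therefore demonstrate the pipeline's correctness and calibration under the
model's own assumptions, not the field validity of those assumptions.

## Numerical choices and problem sizes

CPT rows must sum to 1 within 1e-9; VE must match enumeration within 1e-9;
bisection calibrates bases to ~1e-5. The default test suite runs EM at up
to n = 5,000 with 20% missingness and reliability checks at n = 10,000 —
sizes at which parameter-recovery noise for the well-populated tables is a
few percentage points while the whole suite stays fast on a single CPU.
A caveat on recovery accuracy: a parent configuration with an expected
count of ~50 has a per-entry sampling s.d. of ≈ √(0.25/50) ≈ 0.07 even with
complete data, so the maximum entry error across the ~900 such entries is
typically 0.15–0.25 regardless of estimator; the mean absolute error
(~0.04–0.05 at n = 5,000) is the informative recovery summary at this
scale.

## Known limitations

- The layered-complete topology is assumed, not learned; the package
  deliberately offers no structure learning.
- With ~343 training cases and 243-row tables, the pseudocount prior
  noticeably shrinks sparsely populated rows toward uniform; fitted-model
  marginals are therefore pulled toward 0.5 relative to the generator
  (e.g. the fitted NSI marginal sits several points above the calibrated
  27.9%). This is the honest small-sample behavior of the design, matching
  its own "243 cases minimum" arithmetic.
- Intervention evaluation is observational conditioning; causal claims
  inherit the network's assumptions wholesale.
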