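# Methods

`backfill_qol` implements a Bayesian phase I dose-optimization design in
which patient-reported quality of life (QoL) is monitored alongside toxicity
and efficacy, and is used both to steer backfill enrollment away from doses
with poor QoL profiles and to select the recommended phase II dose (RP2D).

## Monitoring model

For each dose `j` with `n_j` patients, `x_j` dose-limiting toxicities (DLTs)
and `r_j` tumor responses, both event counts are binomial and carry a shared
conjugate `Beta(a, b)` prior (default `Beta(1, 1)`). The three continuous
monitoring rules are

* overly toxic:      `Pr(p_j > phi_DLT | data) > varphi_T`   (defaults 0.25, 0.95)
* futile:            `Pr(theta_j > theta_0 | data) < varphi_E` (defaults 0.20, 0.50)
* QoL-unacceptable:  `Pr(y_tilde_j < phi_QoL | data) > varphi_Q` (defaults -10, 0.50)

where `y_tilde_j` is the QoL change from baseline of a *future* patient.
Scores are modeled as i.i.d. normal; under a uniform prior on
`(mu_j, log sigma_j)` the posterior predictive is the location-scale t

    y_tilde_j | data ~ t_{n_j - 1}( ybar_j, sqrt(1 + 1/n_j) * s_j ).

The predictive probability is preferred to `Pr(mu_j < phi_QoL | data)`
because it estimates the *fraction of patients* who will deteriorate past the
floor: a dose with `mu = -9, sigma = 10` harms nearly half its patients even
though the posterior for `mu` eventually concentrates above -10.

Beta and t tail probabilities use `scipy.special` incomplete-beta and
Student-t CDFs (absolute accuracy far below the 1e-10 we require); no Monte
Carlo appears in production monitoring paths. The inequalities are strict, so
ties at a cutoff do not trigger a flag. Boundary tables (smallest flagging
DLT count, largest flagging response count per `n`) are exposed for protocol
appendices and are byte-stable across runs.

### Calibration of the QoL cutoff

The probability of declaring a dose unacceptable depends on the true outcome
distribution only through `q = Pr(y < phi_QoL)`, not through `(mu, sigma)`
individually: writing `delta = Phi^{-1}(q)`, the declaration event is
equivalent to a noncentral-t event, giving the closed form

    P(declare) = F_nct( -sqrt(n+1) * t^{-1}_{n-1}(varphi_Q); df = n-1,
                        nc = -sqrt(n) * delta ).

`declare_probability` evaluates this; it is strictly increasing in `q` and
decreasing in `varphi_Q`, so cutoffs can be calibrated from a small grid
(`calibrate-qol` subcommand) without specifying means or variances.

### Degenerate and small samples

QoL monitoring activates once a dose has two observed scores (the sample SD
needs `n >= 2`; the predictive t has `n - 1` degrees of freedom). With fewer
scores a dose is never declared QoL-unacceptable. Trialists who prefer a
floor of 3 can simply treat the flag as advisory below that. A zero sample
SD yields the continuity limit of the t family: a point mass at the sample
mean (probability 1/0 on either side of the floor, 0.5 at equality).

## Dose-finding engine

Escalation follows BOIN: the DLT estimate at the current dose is compared
with fixed boundaries `lambda_e < lambda_d` derived from the target rate
`phi` and the bracketing rates `phi_1 = 0.6 phi`, `phi_2 = 1.4 phi`
(`lambda_e ≈ 0.197`, `lambda_d ≈ 0.298` at `phi = 0.25`). While toxicity
assessments are pending, the time-to-event extension imputes a pending
patient's expected DLT indicator as `p (1 - t/T) / (1 - p)` (uniform
toxicity-time assumption), with plug-in `p` equal to the observed DLT
fraction among assessed patients at that dose (`phi/2` before any
assessment, clipped at 0.95 so the weight stays finite). A decision for the
escalation cohort is made only when at least half of the current dose's
patients have a known DLT outcome; otherwise escalation accrual suspends and
arrivals are offered backfill. Escalation never skips an untried dose and
never enters a dose flagged overly toxic; safety elimination is permanent
and propagates to all higher doses. Futility and QoL flags do not redirect
escalation (which is safety-driven); they gate backfilling and selection.

A dose is backfill-eligible iff it is strictly below the current escalation
dose and already tried, carries no monitoring flag, has fewer than `n_cap`
patients, and has at most half of its patients pending. Allocation
strategies: equal randomization (default), highest eligible dose,
QoL-adaptive randomization with weights `1 - Pr(y_tilde_j < phi_QoL | data)`
(neutral weight 0.5 for doses without two scores), and pick-the-winner by
observed mean QoL (ties to the higher dose; unexplored doses win outright).
The adaptive weights and the pick-winner criterion are this package's
conventions; both sit behind the strategy enum.

The trial stops when escalation enrollment reaches `N_esc`, when the current
dose holds `n_stop` patients and the decision is still to retain it (a stay
forced by a blocked escalation counts as retention), or when the lowest dose
is flagged overly toxic. Arrivals that can be neither escalated nor
backfilled are not enrolled and do not count toward the sample size.

A conservative decision variant acts on the lowest tried dose with a
stay/de-escalate interval decision when one exists, instead of the current
dose.

## MTD and RP2D selection

At study end the per-dose posterior-mean DLT estimates
`(a + x_j)/(a + b + n_j)` are smoothed by pool-adjacent-violators with
weights `n_j + a + b` (untried doses excluded); the MTD is the non-eliminated
dose closest to the target, distance ties going to the lower dose when a
tied estimate exceeds the target and to the higher dose otherwise. A trial
stopped for lowest-dose toxicity selects no MTD.

The promising set `P` holds tried doses at or below the MTD with
`Pr(theta_j > theta_0 | data) > varphi_E2` and
`Pr(y_tilde_j < phi_QoL | data) < varphi_Q2` (selection cutoffs default to
the monitoring cutoffs and may be tightened). A dose without two QoL scores
cannot demonstrate an acceptable profile and is excluded. `d_Q` is the
member with the smallest predictive deterioration probability (ties: higher
observed mean, then lower dose). Doses in `P` are walked in decreasing
posterior-mean response rate; the first dose whose QoL is not meaningfully
worse than `d_Q` — `Pr(y_tilde_j < y_tilde_{d_Q} | data) < varphi_C`,
estimated by seeded Monte Carlo from the two predictive t distributions — is
the RP2D. The self-comparison of `d_Q` sits near 0.5 < `varphi_C`, so the
walk always terminates. Response ranking uses posterior means for
consistency with the monitoring prior. Discretionary overrides (PK/PD,
recommended dose ranges) are out of scope: the function returns the
algorithmic answer.

## Simulator

Arrivals are a Poisson process (default 3 patients per 4 weeks; exponential
inter-arrival mean 4/3 weeks). Outcomes are drawn at enrollment — Bernoulli
DLT and response, DLT times uniform over the 4-week toxicity window rounded
up to whole weeks, QoL change normal rounded to the nearest integer — and
revealed at the end of each assessment window (toxicity 4, efficacy 8, QoL 4
weeks). An optional trivariate-normal mode draws two latent event variables
and the QoL score from a user-supplied correlation matrix with thresholds
chosen to preserve every marginal. Trial duration runs from first enrollment
to the last patient's last assessment completion (the efficacy window of the
final patient in practice); the paper-style defaults are `J = 6`,
`N_esc = 36`, cohorts of 3, `n_stop = 9`, `n_cap = 12`,
`varphi_T = 0.95`, `varphi_E = varphi_Q = 0.5`, `varphi_C = 0.75`, equal
randomization.

Comparator designs: `backfill` is the same engine with every QoL component
disabled (its RP2D is the highest-response promising dose); `de_qol` runs a
plain BOIN escalation (decisions on fully assessed data, no backfill), then
determines the promising set once and randomizes `6 x |P|` expansion
patients equally across it with continued monitoring (flagged doses drop
out); `boin` is the escalation phase alone, as an MTD-finding reference.

Replicates derive per-trial seeds from one master seed via
`numpy.random.SeedSequence`, with independent child streams for arrivals,
outcomes, allocation and selection, so results are order-independent and
exactly reproducible. Safety coherence (no assignment to a flagged dose, cap
and pending rules, backfill strictly below the escalation dose) is
re-verified from raw tallies at every assignment and surfaced per trial.

### What the fixtures do and do not show

The bundled scenarios are shape-faithful stand-ins spanning the qualitative
regimes of interest — response plateau with declining QoL, concordant
response/QoL, effective doses with unacceptable QoL (no dose should be
recommended), MTD at middle/low doses, an all-too-toxic drug, and a QoL
cliff directly above the optimal dose — with truth labels by construction.
They emulate independent (optionally latent-correlated) outcomes with
normal, homoscedastic QoL and stationary accrual; they do not emulate
longitudinal or skewed QoL measurements, informative dropout, or
between-patient heterogeneity in assessment timing. Passing tests therefore
demonstrate the design's internal correctness and its comparative behavior
under the stated generative model, not its performance on any particular
real trial.

### Numerical and testing choices

Tail probabilities are exact special-function evaluations (tolerance 1e-10);
the only Monte Carlo in production code is the end-of-trial predictive QoL
comparison (10^5 default draws in the standalone function, 10^4 inside the
simulator, standard error at most 0.005). Simulation-based checks in the
test suite use 400–1,000 replicates per design cell and a 10,000-trial
safety sweep; Monte-Carlo assertions use three-standard-error bands. The
engine's equivalence to an independently coded plain-BOIN simulator is
checked per-seed in a slow-accrual configuration in which arrivals never
overlap assessment windows, which makes the event timing of the two
implementations comparable without altering any decision logic.

## Known limitations

* The TITE plug-in estimator of `p_j` is a simple observed-fraction rule;
  the original time-to-event formulation uses a posterior-based estimate
  that can differ in very small samples.
* QoL monitoring assumes approximately normal change scores; heavily skewed
  instruments would need a transformed or quantile-based rule.
* The pending-half rule counts each dose's own patients, and arrivals that
  cannot be enrolled are turned away rather than queued.
* Backfill allocation strategies beyond equal/highest are conventions, not
  published rules, and should be re-examined per trial.
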