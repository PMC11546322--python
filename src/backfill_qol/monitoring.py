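"""Continuous Bayesian monitoring of safety, efficacy and quality of life.

Safety and efficacy are monitored with a conjugate beta-binomial model: with a
``Beta(a, b)`` prior on the per-dose DLT probability ``p_j`` (and, separately,
on the response probability ``theta_j``), the posterior after ``x`` events in
``n`` patients is ``Beta(a + x, b + n - x)`` and tail probabilities are exact.

Quality of life is monitored through the posterior predictive distribution of
the change-from-baseline score of a *future* patient.  Under a noninformative
uniform prior on ``(mu_j, log sigma_j)`` for normally distributed scores, that
predictive distribution is a location-scale t:

    y_tilde | data  ~  t_{n-1}( ybar,  sqrt(1 + 1/n) * s )

where ``ybar`` and ``s`` are the sample mean and sample standard deviation at
the dose.  A dose is declared QoL-unacceptable when the predictive probability
of a future score falling below the tolerable deterioration ``phi_qol``
exceeds the cutoff ``varphi_Q``.

The predictive-probability rule has a useful calibration property: the chance
of declaring a dose unacceptable depends on the true outcome distribution only
through ``q = Pr(y < phi_qol)``, the population fraction of patients with an
undesired score, never through the individual values of ``mu`` and ``sigma``.
:func:`declare_probability` evaluates that chance in closed form via a
noncentral t distribution, which makes cutoff calibration a small table
exercise rather than a simulation study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from scipy import special, stats

__all__ = [
    "MonitoringConfig",
    "DoseData",
    "DoseStatus",
    "posterior_prob_exceeds",
    "overdosing_boundary",
    "futility_boundary",
    "qol_predictive_prob",
    "declare_probability",
    "monitor_dose",
    "overdosing_boundary_table",
    "futility_boundary_table",
    "declare_probability_table",
]


def _check_prob(value: float, name: str) -> None:
    if not (0.0 < value < 1.0):
        raise ValueError(f"{name} must lie strictly in (0, 1); got {value!r}")


@dataclass(frozen=True)
class MonitoringConfig:
    """Thresholds, cutoffs and priors for trial monitoring and selection.

    Defaults correspond to a target DLT rate of 25%, a lowest acceptable
    response rate of 20%, a tolerable mean QoL deterioration of -10 points
    (FACT-G change from baseline) and uniform ``Beta(1, 1)`` priors.

    Parameters
    ----------
    phi_dlt
        Target DLT rate, in (0, 1).
    theta0
        Lowest acceptable response rate, in (0, 1).
    phi_qol
        Maximum acceptable mean QoL deterioration, in score units (negative
        means deterioration).
    varphi_T, varphi_E, varphi_Q
        Monitoring cutoffs for toxicity, efficacy (futility) and QoL.
    varphi_E2, varphi_Q2
        Selection cutoffs for the promising-dose criteria; default to the
        monitoring cutoffs when omitted and may be set more stringent.
    varphi_C
        Cutoff for the predictive QoL comparison used in RP2D selection.
    prior_a, prior_b
        Beta prior parameters, shared for ``p_j`` and ``theta_j``.
    """

    phi_dlt: float = 0.25
    theta0: float = 0.20
    phi_qol: float = -10.0
    varphi_T: float = 0.95
    varphi_E: float = 0.50
    varphi_Q: float = 0.50
    varphi_E2: Optional[float] = None
    varphi_Q2: Optional[float] = None
    varphi_C: float = 0.75
    prior_a: float = 1.0
    prior_b: float = 1.0

    def __post_init__(self) -> None:
        _check_prob(self.phi_dlt, "phi_dlt")
        _check_prob(self.theta0, "theta0")
        for name in ("varphi_T", "varphi_E", "varphi_Q", "varphi_C"):
            _check_prob(getattr(self, name), name)
        for name in ("varphi_E2", "varphi_Q2"):
            value = getattr(self, name)
            if value is not None:
                _check_prob(value, name)
        if self.prior_a <= 0 or self.prior_b <= 0:
            raise ValueError("prior_a and prior_b must be positive")

    @property
    def efficacy_selection_cutoff(self) -> float:
        return self.varphi_E if self.varphi_E2 is None else self.varphi_E2

    @property
    def qol_selection_cutoff(self) -> float:
        return self.varphi_Q if self.varphi_Q2 is None else self.varphi_Q2


@dataclass
class DoseData:
    """Accumulated outcome data at a single dose level.

    ``n`` counts patients with observed outcomes; ``qol_scores`` holds the
    observed change-from-baseline QoL scores, which may be fewer than ``n``
    (QoL is assessed over its own window).
    """

    dose_index: int
    n: int = 0
    dlt_count: int = 0
    response_count: int = 0
    qol_scores: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dose_index < 1:
            raise ValueError("dose_index is 1-based and must be >= 1")
        if not (0 <= self.dlt_count <= self.n):
            raise ValueError("need 0 <= dlt_count <= n")
        if not (0 <= self.response_count <= self.n):
            raise ValueError("need 0 <= response_count <= n")
        if len(self.qol_scores) > self.n:
            raise ValueError("cannot have more QoL scores than patients")

    @property
    def qol_n(self) -> int:
        return len(self.qol_scores)

    @property
    def qol_mean(self) -> float:
        if not self.qol_scores:
            raise ValueError("no QoL scores observed")
        return float(sum(self.qol_scores)) / len(self.qol_scores)

    @property
    def qol_sd(self) -> float:
        """Sample standard deviation (divisor n-1); needs >= 2 scores."""
        k = len(self.qol_scores)
        if k < 2:
            raise ValueError("sample SD requires at least 2 QoL scores")
        m = self.qol_mean
        return math.sqrt(sum((y - m) ** 2 for y in self.qol_scores) / (k - 1))


@dataclass
class DoseStatus:
    """Monitoring verdicts for one dose; any combination of flags may hold."""

    overly_toxic: bool = False
    futile: bool = False
    qol_unacceptable: bool = False

    @property
    def any_flag(self) -> bool:
        return self.overly_toxic or self.futile or self.qol_unacceptable


def posterior_prob_exceeds(
    events: int, n: int, prior_a: float, prior_b: float, threshold: float
) -> float:
    """Posterior probability that a binomial rate exceeds ``threshold``.

    Under a ``Beta(prior_a, prior_b)`` prior and ``events`` successes in ``n``
    trials, returns ``Pr(rate > threshold)`` from the exact
    ``Beta(prior_a + events, prior_b + n - events)`` posterior.
    """
    if events < 0 or n < 0 or events > n:
        raise ValueError(f"need 0 <= events <= n; got events={events}, n={n}")
    if prior_a <= 0 or prior_b <= 0:
        raise ValueError("prior parameters must be positive")
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    return float(special.betaincc(prior_a + events, prior_b + n - events, threshold))


def overdosing_boundary(
    cutoff: float, n: int, config: MonitoringConfig
) -> Optional[int]:
    """Smallest DLT count that declares a dose overly toxic at sample size ``n``.

    Returns the smallest ``d`` in ``0..n`` with
    ``Pr(p > phi_dlt | d, n) > cutoff``, or ``None`` when even ``d = n`` does
    not cross the cutoff.  Nondecreasing in ``n`` for a fixed cutoff.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for d in range(n + 1):
        if (
            posterior_prob_exceeds(d, n, config.prior_a, config.prior_b, config.phi_dlt)
            > cutoff
        ):
            return d
    return None


def futility_boundary(cutoff: float, n: int, config: MonitoringConfig) -> Optional[int]:
    """Largest response count that declares a dose futile at sample size ``n``.

    Returns the largest ``r`` in ``0..n`` with
    ``Pr(theta > theta0 | r, n) < cutoff``, or ``None`` when even ``r = 0``
    leaves the posterior probability at or above the cutoff.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    boundary = None
    for r in range(n + 1):
        if (
            posterior_prob_exceeds(r, n, config.prior_a, config.prior_b, config.theta0)
            < cutoff
        ):
            boundary = r
        else:
            break
    return boundary


def qol_predictive_prob(qol_mean: float, qol_sd: float, n: int, phi_qol: float) -> float:
    """Predictive probability that a future patient's QoL change falls below ``phi_qol``.

    Evaluates ``Pr(y_tilde < phi_qol | data)`` from the location-scale t
    predictive distribution with location ``qol_mean``, scale
    ``sqrt(1 + 1/n) * qol_sd`` and ``n - 1`` degrees of freedom.  A degenerate
    sample (``qol_sd == 0``) yields a point mass: 1 if the mean is below the
    threshold, 0 if above, 0.5 at equality.
    """
    if n < 2:
        raise ValueError("predictive t needs n >= 2 (sample SD undefined otherwise)")
    if qol_sd < 0:
        raise ValueError("qol_sd must be nonnegative")
    if qol_sd == 0.0:
        if qol_mean < phi_qol:
            return 1.0
        if qol_mean > phi_qol:
            return 0.0
        return 0.5
    z = (phi_qol - qol_mean) / (math.sqrt(1.0 + 1.0 / n) * qol_sd)
    return float(special.stdtr(n - 1, z))


def declare_probability(q: float, n: int, varphi_q: float) -> float:
    """Probability of declaring a dose QoL-unacceptable at true undesired fraction ``q``.

    ``q`` is the population proportion of patients whose QoL change falls
    below the tolerable deterioration.  The declaration event
    ``Pr(y_tilde < phi_qol | data) > varphi_q`` depends on the true normal
    outcome distribution only through ``q``, so this probability is free of
    the individual ``(mu, sigma)``.  In closed form it equals

        P( T' < -sqrt(n+1) * t_{n-1}^{-1}(varphi_q) )

    with ``T'`` noncentral t, ``n - 1`` degrees of freedom and noncentrality
    ``-sqrt(n) * Phi^{-1}(q)``.  Strictly increasing in ``q`` and decreasing
    in ``varphi_q``.
    """
    if n < 2:
        raise ValueError("declaration needs n >= 2")
    _check_prob(q, "q")
    _check_prob(varphi_q, "varphi_q")
    t_quantile = stats.t.ppf(varphi_q, n - 1)
    noncentrality = -math.sqrt(n) * stats.norm.ppf(q)
    return float(stats.nct.cdf(-math.sqrt(n + 1) * t_quantile, n - 1, noncentrality))


def monitor_dose(data: DoseData, config: MonitoringConfig) -> DoseStatus:
    """Apply the three monitoring rules to one dose's accumulated data.

    * overly toxic:   Pr(p_j > phi_dlt | data)   >  varphi_T
    * futile:         Pr(theta_j > theta0 | data) < varphi_E
    * QoL unacceptable: Pr(y_tilde < phi_qol | data) > varphi_Q, evaluated
      only once at least two QoL scores are observed.
    """
    status = DoseStatus()
    a, b = config.prior_a, config.prior_b
    if data.n > 0:
        status.overly_toxic = (
            posterior_prob_exceeds(data.dlt_count, data.n, a, b, config.phi_dlt)
            > config.varphi_T
        )
        status.futile = (
            posterior_prob_exceeds(data.response_count, data.n, a, b, config.theta0)
            < config.varphi_E
        )
    if data.qol_n >= 2:
        status.qol_unacceptable = (
            qol_predictive_prob(data.qol_mean, data.qol_sd, data.qol_n, config.phi_qol)
            > config.varphi_Q
        )
    return status


def overdosing_boundary_table(
    cutoffs: Sequence[float],
    n_values: Sequence[int],
    config: Optional[MonitoringConfig] = None,
):
    """Overdosing boundaries as a DataFrame (rows: cutoffs, columns: n)."""
    import pandas as pd

    config = config or MonitoringConfig()
    rows = {
        cutoff: [overdosing_boundary(cutoff, n, config) for n in n_values]
        for cutoff in cutoffs
    }
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(n_values))
    table.index.name = "cutoff"
    table.columns.name = "n_patients"
    return table


def futility_boundary_table(
    cutoffs: Sequence[float],
    n_values: Sequence[int],
    config: Optional[MonitoringConfig] = None,
):
    """Futility boundaries as a DataFrame (rows: cutoffs, columns: n)."""
    import pandas as pd

    config = config or MonitoringConfig()
    rows = {
        cutoff: [futility_boundary(cutoff, n, config) for n in n_values]
        for cutoff in cutoffs
    }
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(n_values))
    table.index.name = "cutoff"
    table.columns.name = "n_patients"
    return table


def declare_probability_table(
    cutoffs: Sequence[float],
    proportions: Sequence[float],
    n_values: Sequence[int],
):
    """Calibration grid of QoL declaration probabilities.

    Rows are (cutoff, true undesired proportion) pairs; one column per sample
    size.  Used to pick ``varphi_Q`` so that doses with poor QoL profiles are
    detected with high probability while good doses are rarely stopped.
    """
    import pandas as pd

    records = []
    for cutoff in cutoffs:
        for q in proportions:
            row = {"cutoff": cutoff, "proportion_undesired": q}
            for n in n_values:
                row[f"declare_prob_n{n}"] = declare_probability(q, n, cutoff)
            records.append(row)
    return pd.DataFrame.from_records(records)
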