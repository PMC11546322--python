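"""End-of-trial MTD and RP2D selection.

The MTD is the tried dose whose isotonically smoothed DLT estimate is closest
to the target rate.  The RP2D is chosen from the promising set — doses at or
below the MTD that clear the efficacy and QoL selection criteria — by walking
doses in decreasing order of estimated response rate and returning the first
whose QoL profile is not meaningfully worse than that of the best-QoL
promising dose, judged by the predictive probability
``Pr(y_tilde_j < y_tilde_ref | data) < varphi_C``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .monitoring import (
    DoseData,
    DoseStatus,
    MonitoringConfig,
    posterior_prob_exceeds,
    qol_predictive_prob,
)

__all__ = [
    "PromisingSet",
    "SelectionResult",
    "isotonic_dlt_estimates",
    "select_mtd",
    "promising_set",
    "qol_compare_prob",
    "select_rp2d",
]


@dataclass
class PromisingSet:
    """Doses satisfying the RP2D efficacy and QoL criteria, at or below the MTD."""

    doses: list[int]
    best_qol_dose: Optional[int]

    def __post_init__(self) -> None:
        if self.doses and self.best_qol_dose not in self.doses:
            raise ValueError("best_qol_dose must belong to the promising set")


@dataclass
class SelectionResult:
    mtd: Optional[int]
    rp2d: Optional[int]
    isotonic_estimates: list[float] = field(default_factory=list)
    promising: Optional[PromisingSet] = None
    efficacy_probs: dict[int, float] = field(default_factory=dict)
    qol_probs: dict[int, float] = field(default_factory=dict)


def _pava_nondecreasing(values: Sequence[float], weights: Sequence[float]) -> list[float]:
    """Weighted least-squares isotonic (nondecreasing) fit via pool adjacent violators."""
    blocks: list[list[float]] = []  # [mean, weight, count]
    for v, w in zip(values, weights):
        blocks.append([float(v), float(w), 1])
        while len(blocks) > 1 and blocks[-2][0] > blocks[-1][0]:
            m2, w2, c2 = blocks.pop()
            m1, w1, c1 = blocks.pop()
            blocks.append([(m1 * w1 + m2 * w2) / (w1 + w2), w1 + w2, c1 + c2])
    out: list[float] = []
    for mean, _w, count in blocks:
        out.extend([mean] * count)
    return out


def isotonic_dlt_estimates(
    dlt_counts: Sequence[int],
    n_patients: Sequence[int],
    prior: tuple[float, float] = (1.0, 1.0),
) -> list[float]:
    """Isotonically smoothed per-dose DLT estimates.

    Posterior means ``(a + x_j) / (a + b + n_j)`` at tried doses are made
    nondecreasing by pool-adjacent-violators with weights ``n_j + a + b``.
    Untried doses (``n_j == 0``) are excluded and reported as NaN.
    """
    if len(dlt_counts) != len(n_patients):
        raise ValueError("dlt_counts and n_patients must have equal length")
    a, b = prior
    if a <= 0 or b <= 0:
        raise ValueError("prior parameters must be positive")
    tried = [j for j, n in enumerate(n_patients) if n > 0]
    if not tried:
        raise ValueError("no dose has been tried; nothing to estimate")
    means = [(a + dlt_counts[j]) / (a + b + n_patients[j]) for j in tried]
    weights = [n_patients[j] + a + b for j in tried]
    smoothed = _pava_nondecreasing(means, weights)
    out = [math.nan] * len(n_patients)
    for j, value in zip(tried, smoothed):
        out[j] = value
    return out


def select_mtd(
    estimates: Sequence[float],
    statuses: Optional[Sequence[DoseStatus]],
    phi_dlt: float,
    stopped_lowest_toxic: bool = False,
) -> Optional[int]:
    """MTD: the admissible dose whose smoothed DLT estimate is closest to target.

    Doses flagged overly toxic are excluded; a trial stopped because the
    lowest dose was too toxic selects no MTD.  Among distance ties the lower
    dose wins when a tied estimate exceeds the target (conservative), the
    higher dose otherwise.
    """
    if stopped_lowest_toxic:
        return None
    candidates = []
    for j, est in enumerate(estimates, start=1):
        if math.isnan(est):
            continue
        if statuses is not None and statuses[j - 1].overly_toxic:
            continue
        candidates.append((j, est))
    if not candidates:
        return None
    best = min(abs(est - phi_dlt) for _, est in candidates)
    tied = [(j, est) for j, est in candidates if abs(est - phi_dlt) <= best + 1e-12]
    if any(est > phi_dlt for _, est in tied):
        return min(j for j, _ in tied)
    return max(j for j, _ in tied)


def _qol_prob(data: DoseData, config: MonitoringConfig) -> Optional[float]:
    if data.qol_n < 2:
        return None
    return qol_predictive_prob(data.qol_mean, data.qol_sd, data.qol_n, config.phi_qol)


def promising_set(
    final_data: Sequence[DoseData],
    mtd: int,
    config: MonitoringConfig,
    use_qol: bool = True,
) -> PromisingSet:
    """Doses at or below the MTD meeting the efficacy and QoL selection criteria.

    Efficacy: ``Pr(theta_j > theta0 | data) > varphi_E2``.  QoL:
    ``Pr(y_tilde_j < phi_qol | data) < varphi_Q2``; a dose without at least
    two observed QoL scores cannot demonstrate an acceptable profile and is
    excluded.  With ``use_qol=False`` (the QoL-blind comparator design) the
    QoL criterion is skipped and the best-QoL member is instead the member
    with the highest observed mean QoL, defaulting to the lowest dose.
    """
    members: list[int] = []
    qol_probs: dict[int, float] = {}
    for data in final_data:
        j = data.dose_index
        if j > mtd or data.n == 0:
            continue
        eff_ok = (
            posterior_prob_exceeds(
                data.response_count, data.n, config.prior_a, config.prior_b, config.theta0
            )
            > config.efficacy_selection_cutoff
        )
        if not eff_ok:
            continue
        if use_qol:
            prob = _qol_prob(data, config)
            if prob is None or prob >= config.qol_selection_cutoff:
                continue
            qol_probs[j] = prob
        members.append(j)
    if not members:
        return PromisingSet(doses=[], best_qol_dose=None)
    by_index = {d.dose_index: d for d in final_data}
    if use_qol:
        # ties: higher observed mean, then lower dose
        best = min(
            members,
            key=lambda j: (qol_probs[j], -by_index[j].qol_mean, j),
        )
    else:
        def mean_or_low(j: int) -> float:
            d = by_index[j]
            return d.qol_mean if d.qol_n else -math.inf

        best = max(members, key=lambda j: (mean_or_low(j), -j))
    return PromisingSet(doses=sorted(members), best_qol_dose=best)


def qol_compare_prob(
    data_j: DoseData,
    data_ref: DoseData,
    mc_draws: int = 100_000,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Monte-Carlo ``Pr(y_tilde_j < y_tilde_ref | data)`` for two doses.

    Each predictive draw comes from the dose's own location-scale t
    distribution; the draws are independent across doses.  At the default
    100,000 draws the Monte-Carlo standard error is at most 0.0016.
    """
    for data in (data_j, data_ref):
        if data.qol_n < 2:
            raise ValueError(
                f"dose {data.dose_index} has fewer than 2 QoL scores; "
                "predictive comparison undefined"
            )
    rng = np.random.default_rng() if rng is None else rng

    def draws(data: DoseData) -> np.ndarray:
        scale = math.sqrt(1.0 + 1.0 / data.qol_n) * data.qol_sd
        t = rng.standard_t(data.qol_n - 1, size=mc_draws)
        return data.qol_mean + scale * t

    return float(np.mean(draws(data_j) < draws(data_ref)))


def select_rp2d(
    final_data: Sequence[DoseData],
    mtd: Optional[int],
    config: MonitoringConfig,
    rng: Optional[np.random.Generator] = None,
    mc_draws: int = 100_000,
    use_qol: bool = True,
) -> SelectionResult:
    """Full RP2D selection given final per-dose data and the MTD.

    Walks the promising set by posterior-mean response rate (descending; ties
    prefer the better QoL profile, then the lower dose) and returns the first
    dose whose QoL is not meaningfully worse than the best-QoL promising dose.
    The best-QoL dose itself always terminates the walk, since its
    self-comparison sits near 0.5.
    """
    a, b = config.prior_a, config.prior_b
    result = SelectionResult(mtd=mtd, rp2d=None)
    for data in final_data:
        if data.n > 0:
            result.efficacy_probs[data.dose_index] = posterior_prob_exceeds(
                data.response_count, data.n, a, b, config.theta0
            )
            prob = _qol_prob(data, config)
            if prob is not None:
                result.qol_probs[data.dose_index] = prob
    if mtd is None:
        return result
    pset = promising_set(final_data, mtd, config, use_qol=use_qol)
    result.promising = pset
    if not pset.doses:
        return result
    by_index = {d.dose_index: d for d in final_data}
    response_mean = {
        j: (a + by_index[j].response_count) / (a + b + by_index[j].n)
        for j in pset.doses
    }
    if not use_qol:
        result.rp2d = max(pset.doses, key=lambda j: (response_mean[j], -j))
        return result
    qol_prob = {j: result.qol_probs.get(j, 1.0) for j in pset.doses}
    order = sorted(pset.doses, key=lambda j: (-response_mean[j], qol_prob[j], j))
    rng = np.random.default_rng() if rng is None else rng
    ref = by_index[pset.best_qol_dose]
    for j in order:
        if j == pset.best_qol_dose:
            result.rp2d = j
            break
        if qol_compare_prob(by_index[j], ref, mc_draws=mc_draws, rng=rng) < config.varphi_C:
            result.rp2d = j
            break
    return result
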