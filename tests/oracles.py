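"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths for the quantity they
check: a sequential plain-BOIN trial simulator (scikit-learn isotonic fit,
direct beta tail probabilities), a vectorized Monte-Carlo implementation of
the QoL declaration frequency, a brute-force isotonic least-squares search,
and a quadrature evaluation of the two-dose predictive comparison.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import integrate, special, stats
from sklearn.isotonic import IsotonicRegression

from backfill_qol import generate_outcomes

PHI = 0.25
_LAMBDA_E = math.log(0.85 / 0.75) / math.log(0.25 * 0.85 / (0.15 * 0.75))
_LAMBDA_D = math.log(0.75 / 0.65) / math.log(0.35 * 0.75 / (0.25 * 0.65))


def plain_boin_mtd(scenario, seed, n_doses=6, n_max=36, cohort=3, n_stop=9):
    """Sequential plain-BOIN trial: observed DLT fractions only, no imputation.

    Patients enroll one at a time with all previous assessments complete;
    escalation/de-escalation happens at cohort completion, safety elimination
    is checked before every enrollment.  Consumes the same outcome stream as
    the trial engine (stream index 1 of the seed's spawned children).
    """

    def eliminated(x, n):
        return n > 0 and special.betaincc(1 + x, 1 + n - x, PHI) > 0.95

    rng_out = np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[1])
    n = [0] * n_doses
    x = [0] * n_doses
    elim = [False] * n_doses
    current, total, cohort_count = 1, 0, 0
    while True:
        for j in range(n_doses):
            if eliminated(x[j], n[j]):
                for k in range(j, n_doses):
                    elim[k] = True
                break
        if elim[0] or total >= n_max:
            break
        if cohort_count >= cohort or elim[current - 1]:
            if elim[current - 1]:
                move = "deescalate"
            else:
                p_hat = x[current - 1] / n[current - 1]
                if p_hat <= _LAMBDA_E:
                    move = "escalate"
                elif p_hat > _LAMBDA_D:
                    move = "deescalate"
                else:
                    move = "stay"
            if move == "escalate":
                target = current + 1 if (current < n_doses and not elim[current]) else current
            elif move == "deescalate":
                target = max(current - 1, 1)
            else:
                target = current
            if target == current and n[current - 1] >= n_stop:
                break
            current = target
            cohort_count = 0
        outcome = generate_outcomes(scenario, current, rng_out, 4.0)
        n[current - 1] += 1
        x[current - 1] += int(outcome.dlt)
        total += 1
        cohort_count += 1

    if elim[0] or all(v == 0 for v in n):
        return None
    tried = [j for j in range(n_doses) if n[j] > 0]
    means = [(1 + x[j]) / (2 + n[j]) for j in tried]
    weights = [n[j] + 2 for j in tried]
    iso = IsotonicRegression().fit_transform(np.arange(len(tried)), means, sample_weight=weights)
    candidates = [(tried[i] + 1, iso[i]) for i in range(len(tried)) if not elim[tried[i]]]
    if not candidates:
        return None
    best = min(abs(e - PHI) for _, e in candidates)
    tied = [(j, e) for j, e in candidates if abs(e - PHI) <= best + 1e-12]
    if any(e > PHI for _, e in tied):
        return min(j for j, _ in tied)
    return max(j for j, _ in tied)


def mc_declare_frequency(mu, sigma, n, varphi_q, phi_qol, draws, rng):
    """Monte-Carlo frequency of declaring a dose QoL-unacceptable.

    Draws ``draws`` samples of ``n`` normal QoL scores, applies the
    predictive-t rule to each sample, and returns the declaration frequency.
    """
    y = rng.normal(mu, sigma, size=(draws, n))
    mean = y.mean(axis=1)
    sd = y.std(axis=1, ddof=1)
    z = (phi_qol - mean) / (np.sqrt(1.0 + 1.0 / n) * sd)
    prob = special.stdtr(n - 1, z)
    return float(np.mean(prob > varphi_q)), mean, sd, prob


def brute_force_isotonic(values, weights):
    """Exhaustive weighted isotonic least squares over ordered block partitions."""
    k = len(values)
    best, best_sse = None, math.inf
    for cuts in itertools.product([0, 1], repeat=k - 1):
        bounds = [0] + [i + 1 for i, c in enumerate(cuts) if c] + [k]
        fit = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            w = sum(weights[lo:hi])
            m = sum(v * wt for v, wt in zip(values[lo:hi], weights[lo:hi])) / w
            fit.extend([m] * (hi - lo))
        if any(fit[i] > fit[i + 1] + 1e-12 for i in range(k - 1)):
            continue
        sse = sum(wt * (v - f) ** 2 for v, f, wt in zip(values, fit, weights))
        if sse < best_sse - 1e-12:
            best, best_sse = fit, sse
    return best


def quadrature_prob_less(mean1, sd1, n1, mean2, sd2, n2):
    """P(X1 < X2) for two independent location-scale t predictive draws."""
    scale1 = math.sqrt(1 + 1 / n1) * sd1
    scale2 = math.sqrt(1 + 1 / n2) * sd2
    d1 = stats.t(df=n1 - 1, loc=mean1, scale=scale1)
    d2 = stats.t(df=n2 - 1, loc=mean2, scale=scale2)
    val, _err = integrate.quad(
        lambda u: d1.pdf(u) * d2.sf(u), -np.inf, np.inf, limit=200
    )
    return val
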