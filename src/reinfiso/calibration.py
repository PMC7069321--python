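"""Monte-Carlo calibration and power analysis for the context contrast.

These routines simulate dichotomous trials under the beta-share model
(see :mod:`reinfiso.synthetic`), compute the per-trial preference
statistic, and test for a sympatry-allopatry difference with either the
Mann-Whitney U test or the context F test from the linear model.  They
answer two questions about the study design:

* Is the nominal 5% test calibrated at the study's group sizes?
* How does power depend on the standardized effect size (Cohen's d) of
  the context difference?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import DomainError
from .synthetic import sop_sd

__all__ = [
    "NullCalibration",
    "null_rejection_rates",
    "beta_for_cohens_d",
    "power_context_effect",
]


def _draw_sop(
    rng: np.random.Generator, beta: float, kappa: float, n: int
) -> np.ndarray:
    """Per-trial preference values 2c - 1 with c beta-distributed around
    (1 + beta)/2 at precision kappa (activity cancels out of the ratio)."""
    m = (1.0 + beta) / 2.0
    c = rng.beta(m * kappa, (1.0 - m) * kappa, size=n)
    return 2.0 * c - 1.0


def _mw_reject(a: np.ndarray, b: np.ndarray, alpha: float) -> bool:
    from .inference import mann_whitney

    res = mann_whitney(a, b)
    return (res.p_value is not None) and (res.p_value < alpha)


def _context_f_reject(a: np.ndarray, b: np.ndarray, alpha: float) -> bool:
    # one-way F for the two-context design, equivalent to the context row
    # of the linear model when context is the only term
    n1, n2 = a.size, b.size
    grand = np.concatenate([a, b]).mean()
    ss_between = n1 * (a.mean() - grand) ** 2 + n2 * (b.mean() - grand) ** 2
    ss_within = float(np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2))
    df2 = n1 + n2 - 2
    if ss_within <= 0:
        return False
    f = ss_between / (ss_within / df2)
    return float(stats.f.sf(f, 1, df2)) < alpha


@dataclass(frozen=True)
class NullCalibration:
    mann_whitney_rate: float
    context_f_rate: float
    n_sims: int
    n_per_group: int
    alpha: float


def null_rejection_rates(
    n_per_group: int = 18,
    n_sims: int = 1000,
    alpha: float = 0.05,
    beta: float = 0.3,
    kappa: float = 5.0,
    seed: int = 0,
) -> NullCalibration:
    """Type-I error of the Mann-Whitney and context-F tests under a null
    with equal preference bias in both contexts."""
    rng = np.random.default_rng(seed)
    mw = 0
    cf = 0
    for _ in range(n_sims):
        a = _draw_sop(rng, beta, kappa, n_per_group)
        b = _draw_sop(rng, beta, kappa, n_per_group)
        mw += _mw_reject(a, b, alpha)
        cf += _context_f_reject(a, b, alpha)
    return NullCalibration(mw / n_sims, cf / n_sims, n_sims, n_per_group, alpha)


def beta_for_cohens_d(d: float, beta_base: float = 0.0, kappa: float = 5.0) -> float:
    """Preference bias whose contrast with ``beta_base`` has standardized
    effect size ``d`` under the beta-share model (pooled SD of the two
    per-trial distributions)."""
    if d < 0:
        raise DomainError("d must be >= 0")
    if d == 0:
        return beta_base

    def gap(b: float) -> float:
        sd_pool = np.sqrt((sop_sd(beta_base, kappa) ** 2 + sop_sd(b, kappa) ** 2) / 2.0)
        return (b - beta_base) - d * sd_pool

    hi = 1.0 - 1e-9
    if gap(hi) < 0:
        raise DomainError(f"effect size d={d} not reachable from beta={beta_base}")
    return float(optimize.brentq(gap, beta_base, hi, xtol=1e-12))


def power_context_effect(
    d: float,
    n_per_group: int = 36,
    n_sims: int = 500,
    alpha: float = 0.05,
    beta_base: float = 0.0,
    kappa: float = 5.0,
    test: str = "mann_whitney",
    seed: int = 0,
) -> float:
    """Simulated power to detect a context effect of standardized size
    ``d`` between two groups of ``n_per_group`` trials."""
    if test not in ("mann_whitney", "context_f"):
        raise DomainError("test must be 'mann_whitney' or 'context_f'")
    beta_alt = beta_for_cohens_d(d, beta_base=beta_base, kappa=kappa)
    rng = np.random.default_rng(seed)
    reject = _mw_reject if test == "mann_whitney" else _context_f_reject
    hits = 0
    for _ in range(n_sims):
        a = _draw_sop(rng, beta_alt, kappa, n_per_group)
        b = _draw_sop(rng, beta_base, kappa, n_per_group)
        hits += reject(a, b, alpha)
    return hits / n_sims
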