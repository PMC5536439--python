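"""Inverse-variance-weighted fixed-effects meta-analysis with Cochran's Q,
I-squared and a per-study direction string — the combiner applied to
study-level log-odds-ratio estimates from each cohort's scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2, norm

Z975 = 1.959964


@dataclass(frozen=True)
class StudyEstimate:
    study: str
    beta: float  # log odds ratio
    se: float

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("standard error must be > 0")


@dataclass
class MetaResult:
    beta: float
    se: float
    z: float
    p: float
    q: float  # Cochran's heterogeneity statistic (nan for a single study)
    het_p: float
    i2: float  # percent, floored at 0
    direction: str  # one +/- per study, in input order

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci(self) -> tuple[float, float]:
        return float(np.exp(self.beta - Z975 * self.se)), float(np.exp(self.beta + Z975 * self.se))


def se_from_or_ci(or_: float, ci_low: float, ci_high: float, study: str = "") -> StudyEstimate:
    """Invert the OR (95% CI) reporting convention: beta = ln(OR),
    se = (ln(hi) - ln(lo)) / (2 * 1.959964)."""
    if min(or_, ci_low, ci_high) <= 0:
        raise ValueError("odds ratio and CI bounds must be positive")
    if not ci_low <= or_ <= ci_high:
        raise ValueError("CI does not bracket the odds ratio")
    return StudyEstimate(study, float(np.log(or_)), float((np.log(ci_high) - np.log(ci_low)) / (2 * Z975)))


def ivw_meta(estimates: Sequence[StudyEstimate]) -> MetaResult:
    """Fixed-effects combination: weights 1/se^2, pooled beta the weighted
    mean, pooled se = sqrt(1/sum(w)); two-sided normal p."""
    if len(estimates) == 0:
        raise ValueError("no study estimates")
    betas = np.array([e.beta for e in estimates])
    w = np.array([1.0 / e.se**2 for e in estimates])
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    z = beta / se
    p = 2.0 * float(norm.sf(abs(z)))
    direction = "".join("+" if b >= 0 else "-" for b in betas)
    q, het_p, i2 = heterogeneity_stats(betas, w, beta)
    return MetaResult(beta, se, z, p, q, het_p, i2, direction)


def heterogeneity_stats(betas: np.ndarray, weights: np.ndarray, beta_meta: float):
    """Cochran's Q = sum w_i (beta_i - beta_meta)^2, chi-square(k-1) upper
    tail, and I^2 = max(0, (Q - (k-1)) / Q) * 100.  Undefined (nan) for a
    single study."""
    k = len(betas)
    if k < 2:
        return float("nan"), float("nan"), float("nan")
    q = float(np.sum(weights * (betas - beta_meta) ** 2))
    het_p = float(chi2.sf(q, k - 1))
    i2 = 0.0 if q == 0 else max(0.0, (q - (k - 1)) / q) * 100.0
    return q, het_p, i2


def heterogeneity(estimates: Sequence[StudyEstimate], result: MetaResult):
    """Q, het_p and I^2 for a set of study estimates around a pooled beta."""
    if len(estimates) < 2:
        raise ValueError("heterogeneity requires at least two studies")
    betas = np.array([e.beta for e in estimates])
    w = np.array([1.0 / e.se**2 for e in estimates])
    return heterogeneity_stats(betas, w, result.beta)
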