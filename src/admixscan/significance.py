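"""Empirical genome-wide significance for interaction scans.

Two routes are implemented:

* a paired min-p permutation — per iteration the (case status, PC1) row
  pairs are shuffled together within each cohort (preserving the
  correlation between global ancestry and outcome), the full interaction
  scan is re-run per cohort, estimates are combined across cohorts by
  fixed-effects meta-analysis, and the smallest interaction p-value over
  markers is stored; the threshold is the lower alpha-quantile of the
  stored minima; and

* an effective-number-of-tests (simpleM-style) Bonferroni threshold from
  the eigenvalues of the marker correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .assoc import fit_logistic
from .meta import StudyEstimate, ivw_meta
from scipy.stats import norm


@dataclass(frozen=True)
class PermutationConfig:
    n_perm: int = 1000  # desk-scale default; production analyses use 10,000
    alpha: float = 0.05
    seed: int = 0
    suggestive_alpha: float = 5e-4

    def __post_init__(self) -> None:
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100 for a usable threshold")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class ThresholdResult:
    threshold: float
    minp_samples: np.ndarray
    meff: Optional[list] = None
    bonferroni: Optional[float] = None


@dataclass
class ScanDataset:
    """Row-aligned inputs for one cohort's interaction scan."""

    la_calls: np.ndarray  # n x M 0/1/2 European-copy dosages
    bmi: np.ndarray
    age: np.ndarray
    pcs: np.ndarray  # n x k, PC1 in the first column
    outcome: np.ndarray


def _scan_beta_se(ds: ScanDataset, outcome: np.ndarray, pc1: np.ndarray):
    """Interaction beta/se per marker for one (possibly permuted) outcome.

    Returns (betas, ses) with NaN for untestable or non-converged markers.
    """
    la = np.asarray(ds.la_calls, float)
    n, m = la.shape
    pcs = np.asarray(ds.pcs, float)
    X = np.column_stack([np.ones(n), np.zeros(n), ds.bmi, np.zeros(n), ds.age, pc1, pcs[:, 1:]])
    betas = np.full(m, np.nan)
    ses = np.full(m, np.nan)
    bmi = np.asarray(ds.bmi, float)
    for j in range(m):
        col = la[:, j]
        if np.ptp(col) == 0:
            continue
        X[:, 1] = col
        X[:, 3] = col * bmi
        fit = fit_logistic(X, outcome)
        if not fit.converged or 3 in fit.dropped:
            continue
        betas[j] = fit.beta[3]
        ses[j] = fit.se()[3]
    return betas, ses


def _meta_min_p(per_study: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """Minimum meta-analysis interaction p over markers; markers untestable
    in every study are excluded."""
    betas = np.array([b for b, _ in per_study])
    ses = np.array([s for _, s in per_study])
    with np.errstate(divide="ignore", invalid="ignore"):
        w = 1.0 / ses**2
    w = np.where(np.isfinite(w), w, 0.0)
    b = np.where(np.isfinite(betas), betas, 0.0)
    wsum = w.sum(axis=0)
    testable = wsum > 0
    beta_meta = np.where(testable, (w * b).sum(axis=0) / np.where(testable, wsum, 1.0), np.nan)
    z = beta_meta * np.sqrt(wsum)
    p = 2.0 * norm.sf(np.abs(z[testable]))
    if p.size == 0:
        return np.nan
    return float(p.min())


def minp_permutation_threshold(
    datasets: Sequence[ScanDataset],
    config: PermutationConfig,
) -> ThresholdResult:
    """Paired (outcome, PC1) min-p permutation threshold.

    Per iteration and per cohort a single permutation of rows is applied
    jointly to the outcome and the first principal component, leaving local
    ancestry, BMI, age and the remaining PCs fixed to individuals; the
    interaction scan is re-run, studies are meta-analyzed per marker, and
    the smallest p is stored.  The threshold is the ``alpha`` empirical
    quantile (linear interpolation) of the stored minima.  Identical seeds
    give bit-identical minima sequences.
    """
    if len(datasets) == 0:
        raise ValueError("need at least one dataset")
    n_markers = {np.asarray(ds.la_calls).shape[1] for ds in datasets}
    if len(n_markers) > 1:
        raise ValueError("datasets must be aligned on the same marker set")
    rng = np.random.default_rng(config.seed)
    minima = np.empty(config.n_perm)
    n_redrawn = 0
    i = 0
    while i < config.n_perm:
        per_study = []
        for ds in datasets:
            n = len(ds.outcome)
            perm = rng.permutation(n)
            y = np.asarray(ds.outcome, float)[perm]
            pc1 = np.asarray(ds.pcs, float)[perm, 0]
            per_study.append(_scan_beta_se(ds, y, pc1))
        mp = _meta_min_p(per_study)
        if not np.isfinite(mp):
            n_redrawn += 1  # no testable marker this iteration; redraw
            if n_redrawn > 10 * config.n_perm:
                raise RuntimeError("permutation stalled: no testable markers")
            continue
        minima[i] = mp
        i += 1
    threshold = float(np.quantile(minima, config.alpha, method="linear"))
    return ThresholdResult(threshold=threshold, minp_samples=minima)


def simple_m(genotypes: np.ndarray, var_explained: float = 0.995) -> int:
    """Effective number of independent tests from the eigenvalues of the
    marker-marker Pearson correlation matrix (missing entries mean-imputed,
    constant markers dropped): the smallest k whose top-k eigenvalue sum
    reaches ``var_explained`` of the trace."""
    g = np.asarray(genotypes, float)
    col_mean = np.nanmean(g, axis=0)
    g = np.where(np.isnan(g), col_mean[None, :], g)
    sd = g.std(axis=0)
    g = g[:, sd > 0]
    if g.shape[1] < 2:
        raise ValueError("need at least 2 variable markers")
    corr = np.corrcoef(g, rowvar=False)
    eig = np.linalg.eigvalsh(corr)[::-1]
    eig = np.clip(eig, 0, None)
    cum = np.cumsum(eig)
    return int(np.searchsorted(cum, var_explained * eig.sum()) + 1)


def bonferroni_threshold(alpha: float, meff_values: Sequence[float]) -> float:
    """alpha divided by the most conservative (largest) effective-test count."""
    meff = [m for m in meff_values if m >= 1]
    if not meff:
        raise ValueError("need at least one meff >= 1")
    return alpha / max(meff)
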