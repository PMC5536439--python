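"""Logistic association models for admixture-mapping G x E analyses.

All scans reduce to a Newton/IRLS logistic fit with Wald inference:

* genome-wide local-ancestry x BMI interaction scans
  (logit Y ~ LA + BMI + LA*BMI + age + PC1..PC10),
* local-ancestry main-effect scans stratified by BMI category,
* a 3-df likelihood-ratio test for group x BMI-category interaction,
* four SNP x BMI interaction parameterizations (continuous, category
  trend, per-SD, stratified), and
* conditional models adjusting for local ancestry at a named marker.

The IRLS core is written directly in numpy so that permutation loops with
~1e5 refits stay cheap; its estimates and standard errors are validated
against an independent maximum-likelihood implementation in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, norm

# Separation guard: fitted log-odds beyond this are treated as divergence.
BETA_MAX = 15.0
Z975 = 1.959964


def bmi_category_3level(bmi: np.ndarray) -> np.ndarray:
    """0 = normal (<25), 1 = overweight [25, 30), 2 = obese (>= 30).
    Interior boundaries are left-closed."""
    b = np.asarray(bmi, float)
    return (b >= 25).astype(int) + (b >= 30).astype(int)


def bmi_category_4level(bmi: np.ndarray) -> np.ndarray:
    """0 = <25, 1 = [25, 30), 2 = [30, 35), 3 = >= 35."""
    b = np.asarray(bmi, float)
    return (b >= 25).astype(int) + (b >= 30).astype(int) + (b >= 35).astype(int)


@dataclass
class LogisticFit:
    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    n: int
    converged: bool
    n_iter: int
    dropped: list = field(default_factory=list)  # aliased column indices

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by Newton/IRLS.

    Iterates to gradient infinity-norm < ``tol``; the covariance is the
    inverse observed information at the optimum.  Rank-deficient designs
    have aliased columns dropped (recorded in ``dropped`` with zero rows in
    beta/cov).  Quasi-separation (any |beta| > 15 on the logit scale) or
    failure to converge within ``max_iter`` yields ``converged = False``.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("design/outcome dimensions disagree")
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        if len(classes) < 2:
            raise ValueError("outcome has a single class")
        raise ValueError("outcome must be coded 0/1")

    n, p = X.shape
    dropped = _aliased_columns(X)
    active = [j for j in range(p) if j not in dropped]
    Xa = X[:, active]

    beta = np.zeros(len(active))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xa @ beta
        mu = expit(eta)
        grad = Xa.T @ (y - mu)
        w = mu * (1.0 - mu)
        H = (Xa * w[:, None]).T @ Xa
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(beta)) > BETA_MAX:
            break
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
    mu = expit(Xa @ beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    cov_a = np.full((len(active), len(active)), np.nan)
    if converged:
        w = mu * (1.0 - mu)
        H = (Xa * w[:, None]).T @ Xa
        cov_a = np.linalg.inv(H)

    full_beta = np.zeros(p)
    full_cov = np.zeros((p, p))
    ia = np.array(active)
    full_beta[ia] = beta
    full_cov[np.ix_(ia, ia)] = cov_a
    return LogisticFit(full_beta, full_cov, ll, n, converged, it, dropped)


def _aliased_columns(X: np.ndarray) -> list:
    """Columns linearly dependent on earlier ones (Gram-Schmidt sweep,
    keep-earliest convention so results are deterministic)."""
    n, p = X.shape
    basis = np.empty((n, 0))
    dropped = []
    for j in range(p):
        col = X[:, j]
        norm0 = np.linalg.norm(col)
        if norm0 == 0:
            dropped.append(j)
            continue
        resid = col - basis @ (basis.T @ col) if basis.shape[1] else col.copy()
        if np.linalg.norm(resid) <= 1e-8 * norm0:
            dropped.append(j)
        else:
            basis = np.column_stack([basis, resid / np.linalg.norm(resid)])
    return dropped


def wald_record(marker_id, term, beta, se, n, converged, stratum=None, reason="") -> dict:
    """One tidy association record: OR, 95% CI and two-sided Wald p."""
    if converged and se > 0:
        z = beta / se
        p = 2.0 * norm.sf(abs(z))
    else:
        z = p = np.nan
    return {
        "marker_id": marker_id,
        "term": term,
        "stratum": stratum,
        "beta": beta if converged else np.nan,
        "se": se if converged else np.nan,
        "or": np.exp(beta) if converged else np.nan,
        "ci_low": np.exp(beta - Z975 * se) if converged else np.nan,
        "ci_high": np.exp(beta + Z975 * se) if converged else np.nan,
        "z": z,
        "p": p,
        "n": n,
        "converged": bool(converged),
        "reason": reason,
    }


def _fit_and_record(X, y, term_idx, marker_id, term, stratum=None) -> dict:
    try:
        fit = fit_logistic(X, y)
    except ValueError as exc:
        return wald_record(marker_id, term, np.nan, np.nan, len(y), False, stratum, str(exc))
    aliased = term_idx in fit.dropped
    # a dropped column perfectly collinear with the reported term makes the
    # term's coefficient uninterpretable even though the term itself was kept
    for j in fit.dropped:
        if j == term_idx:
            continue
        sd_t, sd_j = np.std(X[:, term_idx]), np.std(X[:, j])
        if sd_t > 0 and sd_j > 0:
            r = np.corrcoef(X[:, term_idx], X[:, j])[0, 1]
            if abs(r) > 1 - 1e-10:
                aliased = True
    if aliased:
        return wald_record(marker_id, term, np.nan, np.nan, fit.n, False, stratum, "aliased")
    if not fit.converged:
        return wald_record(marker_id, term, np.nan, np.nan, fit.n, False, stratum, "nonconvergence")
    se = fit.se()[term_idx]
    return wald_record(marker_id, term, fit.beta[term_idx], se, fit.n, True, stratum)


def interaction_scan(
    la_calls: np.ndarray,
    bmi: np.ndarray,
    age: np.ndarray,
    pcs: np.ndarray,
    outcome: np.ndarray,
    marker_ids: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Per-marker Wald test of the LA x BMI product term in
    logit(Y) ~ LA + BMI + LA*BMI + age + PCs.

    Markers whose local-ancestry column has zero variance are flagged
    ``untestable`` and excluded from downstream min-p statistics.
    """
    la = np.asarray(la_calls, float)
    n, m = la.shape
    if marker_ids is None:
        marker_ids = [f"m{j}" for j in range(m)]
    base = np.column_stack([np.ones(n), np.zeros(n), bmi, np.zeros(n), age, pcs])
    y = np.asarray(outcome, float)
    rows = []
    for j in range(m):
        col = la[:, j]
        if np.ptp(col) == 0:
            rows.append(
                wald_record(marker_ids[j], "LAxBMI", np.nan, np.nan, n, False, None, "untestable")
            )
            continue
        base[:, 1] = col
        base[:, 3] = col * np.asarray(bmi, float)
        rows.append(_fit_and_record(base, y, 3, marker_ids[j], "LAxBMI"))
    return pd.DataFrame(rows)


def stratified_scan(
    la_calls: np.ndarray,
    outcome: np.ndarray,
    age: np.ndarray,
    pcs: np.ndarray,
    bmi: np.ndarray,
    marker_ids: Optional[Sequence] = None,
    min_cases: int = 10,
) -> pd.DataFrame:
    """Local-ancestry main effect (logit Y ~ LA + age + PCs) within each
    3-level BMI category.  Strata lacking both outcome classes or with
    fewer than ``min_cases`` cases yield missing records with a reason."""
    la = np.asarray(la_calls, float)
    n, m = la.shape
    if marker_ids is None:
        marker_ids = [f"m{j}" for j in range(m)]
    cat = bmi_category_3level(bmi)
    y = np.asarray(outcome, float)
    labels = {0: "<25", 1: "25-30", 2: ">30"}
    rows = []
    for c, label in labels.items():
        sel = cat == c
        ys = y[sel]
        reason = ""
        if sel.sum() == 0:
            reason = "empty stratum"
        elif len(np.unique(ys)) < 2:
            reason = "single outcome class"
        elif int(ys.sum()) < min_cases:
            reason = f"fewer than {min_cases} cases"
        if reason:
            for j in range(m):
                rows.append(wald_record(marker_ids[j], "LA", np.nan, np.nan, int(sel.sum()), False, label, reason))
            continue
        Xs = np.column_stack([np.ones(sel.sum()), la[sel, 0], age[sel], np.asarray(pcs)[sel]])
        for j in range(m):
            Xs[:, 1] = la[sel, j]
            if np.ptp(Xs[:, 1]) == 0:
                rows.append(wald_record(marker_ids[j], "LA", np.nan, np.nan, int(sel.sum()), False, label, "untestable"))
                continue
            rows.append(_fit_and_record(Xs, ys, 1, marker_ids[j], "LA", label))
    return pd.DataFrame(rows)


def overall_scan(
    la_calls: np.ndarray,
    outcome: np.ndarray,
    age: np.ndarray,
    pcs: np.ndarray,
    marker_ids: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Local-ancestry main effect across all individuals (no interaction)."""
    la = np.asarray(la_calls, float)
    n, m = la.shape
    if marker_ids is None:
        marker_ids = [f"m{j}" for j in range(m)]
    X = np.column_stack([np.ones(n), la[:, 0], age, np.asarray(pcs)])
    y = np.asarray(outcome, float)
    rows = []
    for j in range(m):
        X[:, 1] = la[:, j]
        if np.ptp(X[:, 1]) == 0:
            rows.append(wald_record(marker_ids[j], "LA", np.nan, np.nan, n, False, "overall", "untestable"))
            continue
        rows.append(_fit_and_record(X, y, 1, marker_ids[j], "LA", "overall"))
    return pd.DataFrame(rows)


@dataclass
class LrtResult:
    statistic: float
    df: int
    p: float
    stratum_or: pd.DataFrame  # group OR within each BMI category, from the full model


def categorical_interaction_lrt(
    outcome: np.ndarray,
    group: np.ndarray,
    bmi: np.ndarray,
    age: np.ndarray,
) -> LrtResult:
    """3-df likelihood-ratio test for group x BMI-category interaction.

    Reduced: logit Y ~ cat1 + cat2 + cat3 + group + age
    Full:    reduced + group*cat1 + group*cat2 + group*cat3
    with 4-level BMI categories (<25 reference).  Stratum-specific group
    ORs are linear combinations of full-model coefficients with
    delta-method standard errors.  Empty group x category cells alias the
    corresponding interaction column; it is dropped and the df reduced.
    """
    y = np.asarray(outcome, float)
    grp = np.asarray(group, float)
    cat = bmi_category_4level(bmi)
    n = len(y)
    d = np.column_stack([(cat == c).astype(float) for c in (1, 2, 3)])
    X_red = np.column_stack([np.ones(n), d, grp, np.asarray(age, float)])
    inter = d * grp[:, None]
    X_full = np.column_stack([X_red, inter])
    fit_red = fit_logistic(X_red, y)
    fit_full = fit_logistic(X_full, y)
    df = 3 - sum(1 for j in fit_full.dropped if j >= X_red.shape[1])
    stat = max(0.0, 2.0 * (fit_full.loglik - fit_red.loglik))
    p = float(chi2.sf(stat, df)) if df > 0 else np.nan

    labels = ["<25", "25-30", "30-35", ">=35"]
    g_idx = 4  # group column in the full design
    rows = []
    for c, label in enumerate(labels):
        contrast = np.zeros(X_full.shape[1])
        contrast[g_idx] = 1.0
        if c > 0:
            contrast[X_red.shape[1] + c - 1] = 1.0
        beta = float(contrast @ fit_full.beta)
        se = float(np.sqrt(contrast @ fit_full.cov @ contrast))
        rows.append(wald_record(None, "group", beta, se, n, fit_full.converged, label))
    return LrtResult(stat, df, p, pd.DataFrame(rows))


def snp_interaction_tests(
    snp: np.ndarray,
    bmi: np.ndarray,
    age: np.ndarray,
    pcs: np.ndarray,
    outcome: np.ndarray,
    marker_id: str = "snp",
    maf_min: float = 0.05,
    conditioning_la: Optional[np.ndarray] = None,
    min_cases: int = 10,
) -> pd.DataFrame:
    """The four SNP x BMI interaction parameterizations for one variant.

    1. BMI continuous x SNP, 2. 3-level BMI category (0/1/2 trend) x SNP,
    3. per-SD standardized BMI x SNP, 4. SNP main effect by BMI stratum.
    Variants at MAF <= 5% are skipped.  ``conditioning_la`` optionally adds
    local-ancestry dosage at a named marker as a covariate (conditional
    analysis); the SNP-related term is still the one reported.
    """
    g = np.asarray(snp, float)
    y = np.asarray(outcome, float)
    n = len(y)
    maf = min(np.nanmean(g) / 2.0, 1 - np.nanmean(g) / 2.0)
    if maf <= maf_min:
        return pd.DataFrame(
            [wald_record(marker_id, t, np.nan, np.nan, n, False, None, f"MAF {maf:.3f} <= {maf_min}")
             for t in ("SNPxBMI", "SNPxBMIcat", "SNPxBMIsd", "SNP")]
        )
    bmi = np.asarray(bmi, float)
    cond = [] if conditioning_la is None else [np.asarray(conditioning_la, float)]
    rows = []
    encodings = {
        "SNPxBMI": bmi,
        "SNPxBMIcat": bmi_category_3level(bmi).astype(float),
        "SNPxBMIsd": (bmi - bmi.mean()) / bmi.std(ddof=1),
    }
    for term, enc in encodings.items():
        X = np.column_stack([np.ones(n), g, enc, g * enc, age, np.asarray(pcs)] + cond)
        rows.append(_fit_and_record(X, y, 3, marker_id, term))
    cat = bmi_category_3level(bmi)
    for c, label in {0: "<25", 1: "25-30", 2: ">30"}.items():
        sel = cat == c
        ys = y[sel]
        if sel.sum() == 0 or len(np.unique(ys)) < 2 or int(ys.sum()) < min_cases:
            rows.append(wald_record(marker_id, "SNP", np.nan, np.nan, int(sel.sum()), False, label, "stratum unusable"))
            continue
        Xs = np.column_stack(
            [np.ones(sel.sum()), g[sel], age[sel], np.asarray(pcs)[sel]] + [c_[sel] for c_ in cond]
        )
        rows.append(_fit_and_record(Xs, ys, 1, marker_id, "SNP", label))
    return pd.DataFrame(rows)


def conditional_scan(
    snp: np.ndarray,
    bmi: np.ndarray,
    age: np.ndarray,
    pcs: np.ndarray,
    outcome: np.ndarray,
    conditioning_la: np.ndarray,
    marker_id: str = "snp",
) -> pd.DataFrame:
    """SNP x BMI tests conditioned on local-ancestry dosage at a marker."""
    if conditioning_la is None or len(conditioning_la) != len(outcome):
        raise ValueError("conditioning local-ancestry vector missing or misaligned")
    return snp_interaction_tests(
        snp, bmi, age, pcs, outcome, marker_id=marker_id, conditioning_la=conditioning_la
    )
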