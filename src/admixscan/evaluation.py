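"""Property-based evaluation harnesses for the synthetic pipeline.

The study-scale results of an admixture-mapping interaction analysis depend
on private individual-level cohorts, so the pipeline is validated instead
on properties a correct implementation must exhibit on synthetic data:
parameter recovery of a planted local-ancestry x BMI interaction, type-I
calibration of the interaction test, agreement of the min-p permutation
threshold with the Sidak closed form on independent markers, local-ancestry
decoding accuracy against simulator truth, and the PC1 / global-ancestry
correlation.  Each harness is seeded and returns plain numbers; the test
suite and the acceptance script both call these.
"""

from __future__ import annotations

import numpy as np

from . import ancestry, assoc, simulate
from .significance import PermutationConfig, ScanDataset, minp_permutation_threshold

Z975 = 1.959964


def _child_seeds(seed: int, n: int) -> list[int]:
    """Independent 31-bit child seeds derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n, np.uint32)]


def interaction_coverage(
    n_reps: int = 100,
    n_individuals: int = 1500,
    n_markers: int = 500,
    beta_int: float = float(np.log(0.95)),
    seed: int = 0,
    use_inferred_la: bool = True,
) -> dict:
    """Replicate-level 95% CI coverage of the causal-marker interaction.

    Each replicate simulates a cohort with the planted interaction, infers
    local ancestry with the HMM, computes principal components, fits
    logit(Y) ~ LA + BMI + LA*BMI + age + PC1..PC10 at the causal marker and
    records whether the Wald 95% CI covers the generative coefficient.
    """
    seeds = _child_seeds(seed, 3 * n_reps)
    causal = f"rs{n_markers // 2:06d}"
    covered = 0
    used = 0
    for r in range(n_reps):
        panel = simulate.make_aim_panel(n_markers, seed=seeds[3 * r], n_chrom=4)
        acfg = simulate.AdmixtureConfig(seed=seeds[3 * r + 1])
        pcfg = simulate.PhenotypeConfig(
            n_individuals=n_individuals,
            causal_marker=causal,
            beta_int=beta_int,
            seed=seeds[3 * r + 2],
        )
        cohort = simulate.simulate_cohort(panel, acfg, pcfg)
        if use_inferred_la:
            la = ancestry.infer_local_ancestry(
                cohort.genotypes, cohort.panel, acfg, keep_posterior=False
            ).calls
        else:
            la = cohort.true_local_ancestry
        pcs = ancestry.compute_pcs(cohort.genotypes, k=10)
        j = int(cohort.panel.index[cohort.panel["marker_id"] == causal][0])
        n = cohort.n_individuals
        bmi = cohort.covariates["bmi"].to_numpy()
        X = np.column_stack(
            [np.ones(n), la[:, j], bmi, la[:, j] * bmi, cohort.covariates["age"], pcs]
        )
        fit = assoc.fit_logistic(X, cohort.phenotype.astype(float))
        if not fit.converged:
            continue
        used += 1
        b, se = fit.beta[3], fit.se()[3]
        if b - Z975 * se <= beta_int <= b + Z975 * se:
            covered += 1
    return {"covered": covered, "n_reps": used, "coverage": covered / max(used, 1)}


def null_interaction_type1(
    n_tests: int = 1000,
    n_individuals: int = 800,
    markers_per_cohort: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Empirical type-I error of the LA x BMI interaction Wald test.

    Cohorts carry BMI and age effects but no ancestry effect anywhere, so
    every marker is null for the interaction; markers sit one per
    chromosome so tests are independent.  Returns the rejection rate at
    ``alpha`` and the vector of p-values (for uniformity checks).
    """
    n_cohorts = int(np.ceil(n_tests / markers_per_cohort))
    seeds = _child_seeds(seed, 3 * n_cohorts)
    pvals = []
    for c in range(n_cohorts):
        panel = simulate.make_aim_panel(
            markers_per_cohort, seed=seeds[3 * c], n_chrom=markers_per_cohort
        )
        # homogeneous admixture proportion: one marker per chromosome then
        # gives mutually independent local-ancestry columns, so the tests
        # are independent draws for the calibration check
        acfg = simulate.AdmixtureConfig(seed=seeds[3 * c + 1], lambda_sd=0.0)
        pcfg = simulate.PhenotypeConfig(
            n_individuals=n_individuals,
            causal_marker=None,
            beta_la=0.0,
            beta_int=0.0,
            seed=seeds[3 * c + 2],
        )
        cohort = simulate.simulate_cohort(panel, acfg, pcfg)
        pcs = ancestry.compute_pcs(cohort.genotypes, k=10)
        res = assoc.interaction_scan(
            cohort.true_local_ancestry,
            cohort.covariates["bmi"].to_numpy(),
            cohort.covariates["age"].to_numpy(),
            pcs,
            cohort.phenotype,
        )
        pvals.extend(res.loc[res["converged"], "p"].tolist())
    pvals = np.array(pvals[:n_tests])
    return {
        "type1": float(np.mean(pvals < alpha)),
        "n_tests": len(pvals),
        "pvals": pvals,
    }


def sidak_permutation_check(
    n_markers: int = 50,
    n_individuals: int = 1200,
    n_perm: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Min-p permutation threshold on independent null markers vs the
    Sidak closed form 1 - (1 - alpha)^(1/M).

    One marker per chromosome and a homogeneous admixture proportion make
    local-ancestry columns mutually independent, the regime in which the
    Sidak value is exact.
    """
    seeds = _child_seeds(seed, 4)
    panel = simulate.make_aim_panel(n_markers, seed=seeds[0], n_chrom=n_markers)
    acfg = simulate.AdmixtureConfig(seed=seeds[1], lambda_sd=0.0)
    pcfg = simulate.PhenotypeConfig(
        n_individuals=n_individuals, causal_marker=None, beta_la=0.0, beta_int=0.0, seed=seeds[2]
    )
    cohort = simulate.simulate_cohort(panel, acfg, pcfg)
    pcs = ancestry.compute_pcs(cohort.genotypes, k=10)
    ds = ScanDataset(
        la_calls=cohort.true_local_ancestry,
        bmi=cohort.covariates["bmi"].to_numpy(),
        age=cohort.covariates["age"].to_numpy(),
        pcs=pcs,
        outcome=cohort.phenotype,
    )
    cfg = PermutationConfig(n_perm=n_perm, alpha=alpha, seed=seeds[3])
    thr = minp_permutation_threshold([ds], cfg)
    sidak = 1.0 - (1.0 - alpha) ** (1.0 / n_markers)
    return {"threshold": thr.threshold, "sidak": sidak, "ratio": thr.threshold / sidak}


def local_ancestry_accuracy(
    n_markers: int = 2000,
    n_individuals: int = 300,
    seed: int = 0,
) -> dict:
    """Per-marker HMM call accuracy against simulator truth on a dense AIM
    panel (delta > 0.2)."""
    seeds = _child_seeds(seed, 3)
    panel = simulate.make_aim_panel(n_markers, seed=seeds[0], n_chrom=8)
    acfg = simulate.AdmixtureConfig(seed=seeds[1])
    pcfg = simulate.PhenotypeConfig(n_individuals=n_individuals, causal_marker=None, seed=seeds[2])
    cohort = simulate.simulate_cohort(panel, acfg, pcfg)
    la = ancestry.infer_local_ancestry(cohort.genotypes, cohort.panel, acfg, keep_posterior=False)
    acc = float(np.mean(la.calls == cohort.true_local_ancestry))
    return {"accuracy": acc, "n": n_individuals * n_markers}


def pc1_theta_correlation(
    n_markers: int = 500,
    n_individuals: int = 500,
    seed: int = 0,
) -> dict:
    """|corr| between the first genotype principal component and the
    HMM-derived global European ancestry proportion."""
    seeds = _child_seeds(seed, 3)
    panel = simulate.make_aim_panel(n_markers, seed=seeds[0], n_chrom=4)
    acfg = simulate.AdmixtureConfig(seed=seeds[1])
    pcfg = simulate.PhenotypeConfig(n_individuals=n_individuals, causal_marker=None, seed=seeds[2])
    cohort = simulate.simulate_cohort(panel, acfg, pcfg)
    la = ancestry.infer_local_ancestry(cohort.genotypes, cohort.panel, acfg, keep_posterior=False)
    theta = ancestry.global_ancestry(la)
    pcs = ancestry.compute_pcs(cohort.genotypes, k=10)
    corr = float(abs(np.corrcoef(pcs[:, 0], theta)[0, 1]))
    return {"correlation": corr, "n": n_individuals}
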