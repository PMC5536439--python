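"""Synthetic admixed case-control cohorts with known local-ancestry tracts.

The generator emulates a two-way (African/European) admixed population of
the kind studied in admixture-mapping designs: haplotype ancestry follows a
Markov tract model along each chromosome, genotypes are drawn from
ancestry-specific allele frequencies, and a binary disease outcome carries a
local-ancestry x BMI interaction at a designated causal marker.  Every
downstream stage (QC, ancestry inference, association scans, permutation
thresholds) is testable against the simulator's recorded truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

PANEL_COLUMNS = ["marker_id", "chrom", "pos", "ref", "alt", "freq_afr", "freq_eur"]

# BMI is centered at the normal-weight boundary inside the generative
# interaction term so the baseline log-odds stays interpretable when the
# interaction coefficient is non-zero.  Fitted models are invariant to this
# choice up to reparameterization of the main effects.
BMI_CENTER = 25.0


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Check an ancestral allele-frequency panel and return it unchanged.

    Required columns: marker_id, chrom, pos, ref, alt, freq_afr, freq_eur.
    Positions must be strictly increasing within each chromosome and
    frequencies must lie in [0, 1].
    """
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel missing columns: {missing}")
    if len(panel) == 0:
        raise ValueError("panel is empty")
    if panel["marker_id"].duplicated().any():
        raise ValueError("duplicate marker_id in panel")
    for col in ("freq_afr", "freq_eur"):
        f = panel[col].to_numpy(float)
        if np.any((f < 0) | (f > 1)) or np.any(~np.isfinite(f)):
            raise ValueError(f"{col} outside [0, 1]")
    for chrom, sub in panel.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"positions not strictly increasing on chrom {chrom}")
    return panel


@dataclass(frozen=True)
class AdmixtureConfig:
    """Demographic parameters of the two-way admixture event.

    lambda_eur : expected European ancestry proportion (stationary weight).
    generations: generations since the single-pulse admixture event.
    recomb_rate: per-bp per-generation recombination rate.
    lambda_sd  : between-individual SD of the admixture proportion.  Real
                 admixed cohorts show sizeable spread in global ancestry
                 (roughly 10 percentage points around a 17-20% mean);
                 individual proportions are drawn from a Beta with mean
                 ``lambda_eur`` and this SD, shared by the two haplotypes
                 of an individual.  0 gives a homogeneous population.
    """

    lambda_eur: float = 0.2
    generations: int = 7
    recomb_rate: float = 1e-8
    lambda_sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.lambda_eur < 1.0:
            raise ValueError("lambda_eur must be in (0, 1)")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.recomb_rate <= 0:
            raise ValueError("recomb_rate must be > 0")
        if self.lambda_sd < 0:
            raise ValueError("lambda_sd must be >= 0")
        if self.lambda_sd**2 >= self.lambda_eur * (1 - self.lambda_eur):
            raise ValueError("lambda_sd too large for a Beta distribution")

    def draw_lambdas(self, n_individuals: int, rng: np.random.Generator) -> np.ndarray:
        """Per-individual admixture proportions: Beta with mean lambda_eur
        and SD lambda_sd (degenerate at lambda_eur when lambda_sd = 0)."""
        if self.lambda_sd == 0:
            return np.full(n_individuals, self.lambda_eur)
        mu, s2 = self.lambda_eur, self.lambda_sd**2
        nu = mu * (1 - mu) / s2 - 1.0
        return rng.beta(mu * nu, (1 - mu) * nu, n_individuals)


@dataclass(frozen=True)
class PhenotypeConfig:
    """Generative logistic model for the binary outcome.

    P(case) = expit(beta0 + beta_la * a + beta_bmi * BMI
                    + beta_int * a * (BMI - 25) + beta_age * age)

    where ``a`` is the number of European-ancestry copies at the causal
    marker.  Covariate moments default to an EMR-style fibroid cohort of
    admixed African American women (BMI ~ 32.5 (8.7) kg/m^2, age ~ 41 (13) y),
    truncated at physically plausible lower bounds.
    """

    beta0: float = -1.2
    beta_la: float = 0.15
    beta_bmi: float = 0.02
    beta_int: float = float(np.log(0.95))
    beta_age: float = 0.01
    causal_marker: Optional[str] = None
    bmi_mean: float = 32.5
    bmi_sd: float = 8.7
    age_mean: float = 41.0
    age_sd: float = 13.0
    n_individuals: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bmi_sd <= 0 or self.age_sd <= 0:
            raise ValueError("bmi_sd and age_sd must be > 0")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")


@dataclass
class CohortData:
    """Genotypes, covariates, outcome and (if simulated) true local ancestry.

    genotypes           : n x M array of 0/1/2 alt-allele copies, NaN = missing.
    true_local_ancestry : n x M array of 0/1/2 European copies, or None.
    covariates          : DataFrame indexed like individual_id with columns
                          age, bmi, bmi_category.
    phenotype           : length-n 0/1 array.
    """

    individual_id: np.ndarray
    genotypes: np.ndarray
    covariates: pd.DataFrame
    phenotype: np.ndarray
    panel: pd.DataFrame
    true_local_ancestry: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n, m = self.genotypes.shape
        if len(self.individual_id) != n or len(self.phenotype) != n:
            raise ValueError("row dimensions disagree")
        if len(self.covariates) != n:
            raise ValueError("covariate rows disagree with genotypes")
        if len(self.panel) != m:
            raise ValueError("panel rows disagree with genotype columns")
        if self.true_local_ancestry is not None:
            if self.true_local_ancestry.shape != (n, m):
                raise ValueError("true_local_ancestry shape disagrees")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]


def make_aim_panel(
    n_markers: int,
    delta_min: float = 0.2,
    spacing_bp: int = 140_000,
    n_chrom: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a synthetic panel of ancestry-informative markers (AIMs).

    Allele frequencies in the two ancestral populations are drawn uniformly
    and resampled until |freq_afr - freq_eur| > delta_min, mimicking an AIM
    panel pre-screened on allele-frequency differentiation.  The default
    140 kb spacing matches roughly 20,000 markers spread over an autosomal
    genome.
    """
    rng = np.random.default_rng(seed)
    freq_afr = np.empty(n_markers)
    freq_eur = np.empty(n_markers)
    todo = np.arange(n_markers)
    while todo.size:
        fa = rng.uniform(0.02, 0.98, todo.size)
        fe = rng.uniform(0.02, 0.98, todo.size)
        ok = np.abs(fa - fe) > delta_min
        freq_afr[todo[ok]] = fa[ok]
        freq_eur[todo[ok]] = fe[ok]
        todo = todo[~ok]
    per = int(np.ceil(n_markers / n_chrom))
    chroms, pos = [], []
    for i in range(n_markers):
        c = i // per
        chroms.append(str(c + 1))
        pos.append((i - c * per + 1) * spacing_bp)
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, n_markers)
    alt = np.array([rng.choice(bases[bases != r]) for r in ref])
    return pd.DataFrame(
        {
            "marker_id": [f"rs{i + 1:06d}" for i in range(n_markers)],
            "chrom": chroms,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "freq_afr": freq_afr,
            "freq_eur": freq_eur,
        }
    )


def haplotype_switch_prob(distance_bp: np.ndarray, config: AdmixtureConfig) -> np.ndarray:
    """Probability that ancestry is re-drawn from the stationary distribution
    between two markers ``distance_bp`` apart: 1 - exp(-G * r * d)."""
    return -np.expm1(-config.generations * config.recomb_rate * np.asarray(distance_bp, float))


def simulate_haplotype_tracts(
    panel: pd.DataFrame,
    config: AdmixtureConfig,
    n_haplotypes: int,
    rng: Optional[np.random.Generator] = None,
    return_redraws: bool = False,
):
    """Simulate ancestry labels (1 = EUR, 0 = AFR) along each haplotype.

    Along each chromosome the label is a Markov chain: the first marker is
    EUR with the haplotype's admixture proportion; between adjacent markers
    the label is re-drawn from the stationary distribution with probability
    1 - exp(-G*r*d).  Haplotypes 2i and 2i+1 share individual i's
    proportion.  Chromosomes are independent; latent re-draw segments are
    Exponential(G) in Morgans.

    With ``return_redraws`` also returns a boolean array marking markers at
    which a stationary re-draw occurred (chromosome starts included), the
    bookkeeping needed to audit tract lengths without censoring by label
    coincidence.
    """
    validate_panel(panel)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lam_ind = config.draw_lambdas((n_haplotypes + 1) // 2, rng)
    lam = np.repeat(lam_ind, 2)[:n_haplotypes]
    m = len(panel)
    labels = np.empty((n_haplotypes, m), dtype=np.int8)
    redraws = np.zeros((n_haplotypes, m), dtype=bool)
    col = 0
    for _, sub in panel.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(float)
        k = len(pos)
        state = (rng.random(n_haplotypes) < lam).astype(np.int8)
        labels[:, col] = state
        redraws[:, col] = True
        switch_p = haplotype_switch_prob(np.diff(pos), config)
        for j in range(1, k):
            redraw = rng.random(n_haplotypes) < switch_p[j - 1]
            fresh = (rng.random(n_haplotypes) < lam).astype(np.int8)
            state = np.where(redraw, fresh, state)
            labels[:, col + j] = state
            redraws[:, col + j] = redraw
        col += k
    if return_redraws:
        return labels, redraws
    return labels


def simulate_genotypes(
    tracts: np.ndarray,
    panel: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw genotypes given haplotype ancestry labels.

    ``tracts`` has shape (2n, M) with haplotypes 2i, 2i+1 belonging to
    individual i.  An allele on a haplotype is the alternate allele with
    probability freq_eur if the haplotype is European at that marker and
    freq_afr otherwise.  Returns (genotypes, true_local_ancestry), both
    n x M arrays; local ancestry counts European haplotype labels.
    """
    validate_panel(panel)
    n2, m = tracts.shape
    if n2 % 2:
        raise ValueError("tracts must hold two haplotypes per individual")
    fa = panel["freq_afr"].to_numpy(float)
    fe = panel["freq_eur"].to_numpy(float)
    p_alt = np.where(tracts == 1, fe[None, :], fa[None, :])
    alleles = (rng.random((n2, m)) < p_alt).astype(np.int8)
    genotypes = (alleles[0::2] + alleles[1::2]).astype(float)
    true_la = (tracts[0::2] + tracts[1::2]).astype(np.int8)
    return genotypes, true_la


def _truncated_normal(rng, mean, sd, lower, size):
    a = (lower - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def draw_covariates(pcfg: PhenotypeConfig, rng: np.random.Generator) -> pd.DataFrame:
    """BMI ~ Normal truncated at 15 kg/m^2, age ~ Normal truncated at 18 y,
    drawn independently (the joint distribution is not modelled)."""
    n = pcfg.n_individuals
    bmi = _truncated_normal(rng, pcfg.bmi_mean, pcfg.bmi_sd, 15.0, n)
    age = _truncated_normal(rng, pcfg.age_mean, pcfg.age_sd, 18.0, n)
    from .assoc import bmi_category_3level  # derived label, shared encoding

    return pd.DataFrame({"age": age, "bmi": bmi, "bmi_category": bmi_category_3level(bmi)})


def simulate_phenotype(
    true_la_causal: np.ndarray,
    covariates: pd.DataFrame,
    pcfg: PhenotypeConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bernoulli outcome from the logistic model with an LA x BMI product term."""
    bmi = covariates["bmi"].to_numpy(float)
    age = covariates["age"].to_numpy(float)
    a = np.asarray(true_la_causal, float)
    eta = (
        pcfg.beta0
        + pcfg.beta_la * a
        + pcfg.beta_bmi * bmi
        + pcfg.beta_int * a * (bmi - BMI_CENTER)
        + pcfg.beta_age * age
    )
    return (rng.random(len(eta)) < expit(eta)).astype(np.int8)


def simulate_cohort(
    panel: pd.DataFrame,
    acfg: AdmixtureConfig,
    pcfg: PhenotypeConfig,
    missing_rate: float = 0.0,
    out_dir=None,
) -> CohortData:
    """Compose tract, genotype, covariate and phenotype simulation.

    Ancestry/genotype randomness flows from ``acfg.seed`` and
    covariate/outcome randomness from ``pcfg.seed``, so identical configs
    give bit-identical cohorts.  ``missing_rate`` optionally masks genotype
    entries at random to exercise QC.  With ``out_dir`` set, the cohort is
    also written to disk (VCF + covariate TSV + truth TSV + panel TSV) and
    the seeds are echoed to the log.
    """
    validate_panel(panel)
    rng_g = np.random.default_rng(acfg.seed)
    rng_p = np.random.default_rng(pcfg.seed)
    n = pcfg.n_individuals
    tracts = simulate_haplotype_tracts(panel, acfg, 2 * n, rng=rng_g)
    genotypes, true_la = simulate_genotypes(tracts, panel, rng_g)
    if missing_rate > 0:
        mask = rng_g.random(genotypes.shape) < missing_rate
        genotypes = genotypes.copy()
        genotypes[mask] = np.nan
    covariates = draw_covariates(pcfg, rng_p)
    if pcfg.causal_marker is not None:
        idx = panel.index[panel["marker_id"] == pcfg.causal_marker]
        if len(idx) == 0:
            raise ValueError(f"causal_marker {pcfg.causal_marker!r} not in panel")
        a = true_la[:, panel.index.get_loc(idx[0])]
    else:
        a = np.zeros(n)
    phenotype = simulate_phenotype(a, covariates, pcfg, rng_p)
    ids = np.array([f"ind{i + 1:05d}" for i in range(n)])
    cohort = CohortData(
        individual_id=ids,
        genotypes=genotypes,
        covariates=covariates,
        phenotype=phenotype,
        panel=panel.reset_index(drop=True),
        true_local_ancestry=true_la,
    )
    if out_dir is not None:
        from pathlib import Path

        from . import io as _io

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _io.write_vcf(cohort, out / "genotypes.vcf")
        _io.write_covariates(cohort, out / "covariates.tsv")
        _io.write_truth(cohort, out / "truth.tsv")
        _io.write_panel(cohort.panel, out / "panel.tsv")
        import logging

        logging.getLogger(__name__).info(
            "cohort written to %s (ancestry seed %d, phenotype seed %d)",
            out, acfg.seed, pcfg.seed,
        )
    return cohort


def mean_tract_length_morgans(
    redraws: np.ndarray, panel: pd.DataFrame, recomb_rate: float
) -> float:
    """Average latent ancestry-segment length in Morgans from the
    simulator's own re-draw bookkeeping (segments run between consecutive
    re-draw points; the last, end-censored segment of each chromosome is
    excluded).  For dense maps this should sit near 1/G."""
    validate_panel(panel)
    lengths = []
    col = 0
    for _, sub in panel.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(float)
        k = len(pos)
        red = redraws[:, col : col + k]
        for h in range(red.shape[0]):
            starts = np.flatnonzero(red[h])
            for s, e in zip(starts[:-1], starts[1:]):
                lengths.append((pos[e] - pos[s]) * recomb_rate)
        col += k
    return float(np.mean(lengths)) if lengths else float("nan")
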