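"""Genotype and sample quality control.

Standard array-style filters applied in a fixed order: sample call rate,
then marker call rate, then minor allele frequency, then Hardy-Weinberg
equilibrium tested in controls only.  Thresholds are strict inequalities
(a sample at exactly the call-rate threshold is retained).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .simulate import CohortData


@dataclass(frozen=True)
class QcThresholds:
    min_sample_call_rate: float = 0.95
    min_snp_call_rate: float = 0.95
    min_maf: float = 0.01
    hwe_p_min: float = 1e-6
    hwe_in_controls_only: bool = True

    def __post_init__(self) -> None:
        for v in (self.min_sample_call_rate, self.min_snp_call_rate, self.min_maf):
            if not 0.0 < v <= 1.0:
                raise ValueError("call-rate/MAF thresholds must be in (0, 1]")
        if not 0.0 < self.hwe_p_min < 1.0:
            raise ValueError("hwe_p_min must be in (0, 1)")


@dataclass
class QcReport:
    """Per-filter removal counts, in application order, plus retained ids."""

    n_samples_in: int = 0
    n_markers_in: int = 0
    samples_removed_call_rate: int = 0
    markers_removed_call_rate: int = 0
    markers_removed_maf: int = 0
    markers_removed_no_data: int = 0
    markers_removed_hwe: int = 0
    retained_individuals: list = field(default_factory=list)
    retained_markers: list = field(default_factory=list)

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - self.samples_removed_call_rate

    @property
    def n_markers_out(self) -> int:
        return (
            self.n_markers_in
            - self.markers_removed_call_rate
            - self.markers_removed_no_data
            - self.markers_removed_maf
            - self.markers_removed_hwe
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("samples_in", self.n_samples_in),
            ("samples_removed_call_rate", self.samples_removed_call_rate),
            ("samples_out", self.n_samples_out),
            ("markers_in", self.n_markers_in),
            ("markers_removed_call_rate", self.markers_removed_call_rate),
            ("markers_removed_no_data", self.markers_removed_no_data),
            ("markers_removed_maf", self.markers_removed_maf),
            ("markers_removed_hwe", self.markers_removed_hwe),
            ("markers_out", self.n_markers_out),
        ]
        return pd.DataFrame(rows, columns=["step", "count"])


def call_rate(genotypes: np.ndarray, axis: int) -> np.ndarray:
    """Non-missing fraction per sample (axis=1) or per marker (axis=0)."""
    g = np.asarray(genotypes, float)
    if g.size == 0:
        raise ValueError("empty genotype matrix")
    return 1.0 - np.mean(np.isnan(g), axis=axis)


def minor_allele_frequency(column: np.ndarray) -> float:
    """MAF = min(f, 1-f) with f the alt-allele frequency over non-missing
    genotypes.  NaN if the column has no data."""
    g = np.asarray(column, float)
    g = g[~np.isnan(g)]
    if g.size == 0:
        return float("nan")
    f = np.mean(g) / 2.0
    return float(min(f, 1.0 - f))


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """One-degree-of-freedom chi-square goodness-of-fit test of
    Hardy-Weinberg proportions, expected counts from the observed allele
    frequency.  Monomorphic markers return p = 1 (no test possible)."""
    n = n_aa + n_ab + n_bb
    if n <= 0:
        raise ValueError("no genotypes")
    f = (2 * n_aa + n_ab) / (2.0 * n)
    if f in (0.0, 1.0):
        return 1.0
    exp = np.array([n * f * f, 2 * n * f * (1 - f), n * (1 - f) * (1 - f)])
    obs = np.array([n_aa, n_ab, n_bb], float)
    stat = np.sum((obs - exp) ** 2 / exp)
    return float(chi2.sf(stat, df=1))


def hwe_pvalues(genotypes: np.ndarray) -> np.ndarray:
    """Column-wise HWE p-values, missing genotypes excluded per marker."""
    g = np.asarray(genotypes, float)
    out = np.empty(g.shape[1])
    for j in range(g.shape[1]):
        col = g[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            out[j] = np.nan
            continue
        # counts keyed by alt copies: 2 -> homozygous alt
        out[j] = hwe_test(int(np.sum(col == 2)), int(np.sum(col == 1)), int(np.sum(col == 0)))
    return out


def run_qc(cohort: CohortData, thresholds: QcThresholds = QcThresholds()) -> tuple[CohortData, QcReport]:
    """Apply sample call-rate, marker call-rate, MAF and HWE-in-controls
    filters in that order; returns the filtered cohort and a report whose
    per-step removals reconcile exactly with the dimension change."""
    g = np.asarray(cohort.genotypes, float)
    report = QcReport(n_samples_in=g.shape[0], n_markers_in=g.shape[1])

    keep_i = call_rate(g, axis=1) >= thresholds.min_sample_call_rate
    report.samples_removed_call_rate = int(np.sum(~keep_i))
    if not keep_i.any():
        raise RuntimeError("QC removed every individual (sample call-rate filter)")
    g = g[keep_i]
    pheno = np.asarray(cohort.phenotype)[keep_i]

    keep_m = call_rate(g, axis=0) >= thresholds.min_snp_call_rate
    report.markers_removed_call_rate = int(np.sum(~keep_m))

    no_data = np.all(np.isnan(g), axis=0)
    newly = no_data & keep_m
    report.markers_removed_no_data = int(np.sum(newly))
    keep_m &= ~no_data

    maf = np.array([minor_allele_frequency(g[:, j]) if keep_m[j] else np.nan for j in range(g.shape[1])])
    low_maf = keep_m & (maf < thresholds.min_maf)
    report.markers_removed_maf = int(np.sum(low_maf))
    keep_m &= ~low_maf

    hwe_rows = (pheno == 0) if thresholds.hwe_in_controls_only else np.ones(len(pheno), bool)
    hwe_g = g[hwe_rows] if hwe_rows.any() else g
    hwe_p = hwe_pvalues(hwe_g)
    hwe_bad = keep_m & (np.nan_to_num(hwe_p, nan=1.0) < thresholds.hwe_p_min)
    report.markers_removed_hwe = int(np.sum(hwe_bad))
    keep_m &= ~hwe_bad

    filtered = CohortData(
        individual_id=np.asarray(cohort.individual_id)[keep_i],
        genotypes=g[:, keep_m],
        covariates=cohort.covariates.loc[keep_i].reset_index(drop=True),
        phenotype=pheno,
        panel=cohort.panel.loc[keep_m].reset_index(drop=True),
        true_local_ancestry=(
            None
            if cohort.true_local_ancestry is None
            else cohort.true_local_ancestry[keep_i][:, keep_m]
        ),
    )
    report.retained_individuals = list(filtered.individual_id)
    report.retained_markers = list(filtered.panel["marker_id"])
    return filtered, report
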