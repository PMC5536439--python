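"""Readers and writers for the pipeline's on-disk formats, plus the
end-to-end pipeline runner.

Formats: VCF 4.2 (diploid, unphased GT) for genotypes; tab-separated
tables for the ancestral allele-frequency panel, covariates, simulation
truth, local/global ancestry, principal components and association
results.  "NA" is the missing sentinel in every TSV; VCF positions are
1-based and preserved unchanged.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .simulate import (
    CohortData,
    make_aim_panel,
    simulate_cohort,
    validate_panel,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_vcf(cohort: CohortData, path) -> None:
    """Write genotypes as a plain-text VCF 4.2 with unphased diploid GT."""
    path = Path(path)
    g = np.asarray(cohort.genotypes, float)
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for chrom in pd.unique(cohort.panel["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.individual_id)
            + "\n"
        )
        for j, row in enumerate(cohort.panel.itertuples(index=False)):
            gts = [gt_map.get(v, "./.") for v in g[:, j]]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.marker_id}\t{row.ref}\t{row.alt}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_vcf(path):
    """Read a diploid VCF into (genotype matrix, site table, sample ids).

    Unphased or phased GT is mapped to alternate-allele copy counts;
    "./." becomes NaN.  Multi-allelic records and non-diploid calls are
    rejected with the offending record named.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    rows, sites = [], []
    for i, v in enumerate(vcf):
        if len(v.ALT) != 1:
            raise ValueError(f"multi-allelic record at {v.CHROM}:{v.POS} (record {i + 1})")
        gts = v.genotypes  # [[a0, a1, phased], ...]
        dose = np.empty(len(samples))
        for s, gt in enumerate(gts):
            if len(gt) != 3:
                raise ValueError(f"non-diploid call at {v.CHROM}:{v.POS} sample {samples[s]}")
            a, b = gt[0], gt[1]
            dose[s] = np.nan if (a < 0 or b < 0) else float(a + b)
        rows.append(dose)
        sites.append((v.ID, v.CHROM, v.POS, v.REF, v.ALT[0]))
    if not rows:
        raise ValueError(f"no records in {path}")
    site_table = pd.DataFrame(sites, columns=["marker_id", "chrom", "pos", "ref", "alt"])
    return np.column_stack(rows).astype(float), site_table, samples


def write_panel(panel: pd.DataFrame, path) -> None:
    validate_panel(panel)
    panel.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_panel(path) -> pd.DataFrame:
    panel = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return validate_panel(panel)


def write_covariates(cohort: CohortData, path) -> None:
    out = pd.DataFrame(
        {
            "individual_id": cohort.individual_id,
            "case": cohort.phenotype,
            "age": cohort.covariates["age"],
            "bmi": cohort.covariates["bmi"],
        }
    )
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_covariates(path) -> pd.DataFrame:
    """Covariate table keyed by individual_id; duplicates rejected."""
    tab = pd.read_csv(path, sep="\t")
    required = {"individual_id", "case", "age", "bmi"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"covariate table missing columns: {sorted(missing)}")
    if tab["individual_id"].duplicated().any():
        raise ValueError("duplicate individual_id in covariate table")
    return tab


def write_truth(cohort: CohortData, path) -> None:
    """Long-format true local ancestry (simulation bookkeeping)."""
    if cohort.true_local_ancestry is None:
        raise ValueError("cohort has no recorded truth")
    n, m = cohort.true_local_ancestry.shape
    out = pd.DataFrame(
        {
            "individual_id": np.repeat(cohort.individual_id, m),
            "marker_id": np.tile(cohort.panel["marker_id"].to_numpy(), n),
            "true_la": cohort.true_local_ancestry.ravel(),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def align_by_id(genotypes: np.ndarray, sample_ids: list, covariates: pd.DataFrame):
    """Row-align a genotype matrix with a covariate table on individual_id.

    Unmatched ids on either side are dropped; the drop counts are returned
    so callers can log them.
    """
    cov = covariates.set_index("individual_id")
    keep = [i for i, s in enumerate(sample_ids) if s in cov.index]
    dropped_geno = len(sample_ids) - len(keep)
    ids = [sample_ids[i] for i in keep]
    dropped_cov = len(cov) - len(ids)
    return genotypes[keep], cov.loc[ids].reset_index(), ids, {"genotypes": dropped_geno, "covariates": dropped_cov}


def write_local_ancestry(la, individual_ids, path) -> None:
    """Long-format calls with posterior columns p0/p1/p2."""
    n, m = la.calls.shape
    out = pd.DataFrame(
        {
            "individual_id": np.repeat(np.asarray(individual_ids), m),
            "marker_id": np.tile(np.asarray(la.marker_id), n),
            "call": la.calls.ravel(),
        }
    )
    if la.posterior is not None:
        for k in range(3):
            out[f"p{k}"] = la.posterior[:, :, k].ravel()
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class RunConfig:
    """Every knob of the end-to-end synthetic run; all seeds explicit."""

    out_dir: str
    n_markers: int = 300
    panel_seed: int = 11
    delta_min: float = 0.2
    r2_max: float = 0.1
    k_pcs: int = 10
    n_perm: int = 200
    perm_seed: int = 17
    missing_rate: float = 0.0
    cohorts: list = field(default_factory=list)  # (name, AdmixtureConfig, PhenotypeConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(
        {k: (str(v) if k == "cohorts" else v) for k, v in asdict(cfg).items()}, sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(cfg: RunConfig) -> dict:
    """Simulate -> QC -> ancestry -> per-cohort interaction scan -> meta ->
    permutation threshold, persisting every artifact under ``out_dir``.

    Returns a dict of the in-memory results keyed by stage.  A stage
    failure raises with the stage name; artifacts written so far remain.
    """
    from . import ancestry, assoc, qc, significance
    from .meta import StudyEstimate, ivw_meta

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        panel = make_aim_panel(cfg.n_markers, delta_min=cfg.delta_min, seed=cfg.panel_seed)
        write_panel(panel, out / "panel.tsv")
        cohorts = {}
        for name, acfg, pcfg in cfg.cohorts:
            cdir = out / name
            cdir.mkdir(exist_ok=True)
            cohort = simulate_cohort(panel, acfg, pcfg, missing_rate=cfg.missing_rate)
            write_vcf(cohort, cdir / "genotypes.vcf")
            write_covariates(cohort, cdir / "covariates.tsv")
            cohorts[name] = cohort

        stage = "qc"
        for name, cohort in cohorts.items():
            filtered, report = qc.run_qc(cohort)
            report.to_frame().to_csv(out / name / "qc_report.tsv", sep="\t", index=False)
            cohorts[name] = filtered

        stage = "ancestry"
        # consensus marker set: markers retained by QC in every cohort, then
        # AIM selection and LD pruning decided once (on the first cohort) so
        # downstream scans and the meta-analysis are marker-aligned
        shared = set.intersection(*(set(c.panel["marker_id"]) for c in cohorts.values()))
        consensus_keep = None
        datasets = {}
        for name, cohort in cohorts.items():
            in_shared = cohort.panel["marker_id"].isin(shared).to_numpy()
            cohort = CohortData(
                individual_id=cohort.individual_id,
                genotypes=cohort.genotypes[:, in_shared],
                covariates=cohort.covariates,
                phenotype=cohort.phenotype,
                panel=cohort.panel.loc[in_shared].reset_index(drop=True),
                true_local_ancestry=(
                    None
                    if cohort.true_local_ancestry is None
                    else cohort.true_local_ancestry[:, in_shared]
                ),
            )
            cohorts[name] = cohort
            aims = ancestry.select_aims(cohort.panel, cfg.delta_min)
            cols = cohort.panel.index.get_indexer(aims.index)
            if consensus_keep is None:
                consensus_keep = ancestry.ld_prune(cohort.genotypes[:, cols], r2_max=cfg.r2_max)
            keep = consensus_keep
            aims = aims.loc[aims.index[keep]].reset_index(drop=True)
            g_aims = cohort.genotypes[:, cols[keep]]
            la = ancestry.infer_local_ancestry(g_aims, aims, cfg.cohorts[0][1], keep_posterior=False)
            theta = ancestry.global_ancestry(la)
            pcs = ancestry.compute_pcs(cohort.genotypes, k=cfg.k_pcs)
            write_local_ancestry(la, cohort.individual_id, out / name / "local_ancestry.tsv")
            pd.DataFrame({"individual_id": cohort.individual_id, "theta": theta}).to_csv(
                out / name / "global_ancestry.tsv", sep="\t", index=False
            )
            pd.DataFrame(pcs, columns=[f"PC{i + 1}" for i in range(pcs.shape[1])]).assign(
                individual_id=cohort.individual_id
            ).to_csv(out / name / "pcs.tsv", sep="\t", index=False)
            datasets[name] = significance.ScanDataset(
                la_calls=la.calls,
                bmi=cohort.covariates["bmi"].to_numpy(),
                age=cohort.covariates["age"].to_numpy(),
                pcs=pcs,
                outcome=cohort.phenotype,
            )
            cohorts[name] = (cohort, la, aims)

        stage = "scan"
        scans = {}
        for name, ds in datasets.items():
            cohort, la, aims = cohorts[name]
            res = assoc.interaction_scan(
                ds.la_calls, ds.bmi, ds.age, ds.pcs, ds.outcome, marker_ids=la.marker_id
            )
            res.to_csv(out / name / "interaction_scan.tsv", sep="\t", index=False, na_rep="NA")
            scans[name] = res

        stage = "meta"
        names = list(scans)
        merged = None
        if len(names) >= 2:
            common = set.intersection(*(set(s["marker_id"]) for s in scans.values()))
            rows = []
            for mid in sorted(common):
                ests = []
                for name in names:
                    r = scans[name].set_index("marker_id").loc[mid]
                    if r["converged"] and np.isfinite(r["se"]):
                        ests.append(StudyEstimate(name, r["beta"], r["se"]))
                if len(ests) < 1:
                    continue
                mr = ivw_meta(ests)
                rows.append(
                    {
                        "marker_id": mid,
                        "beta": mr.beta,
                        "se": mr.se,
                        "or": mr.odds_ratio,
                        "z": mr.z,
                        "p": mr.p,
                        "het_p": mr.het_p,
                        "i2": mr.i2,
                        "direction": mr.direction,
                        "k": len(ests),
                    }
                )
            merged = pd.DataFrame(rows)
            merged.to_csv(out / "meta_interaction.tsv", sep="\t", index=False, na_rep="NA")

        stage = "permute"
        pcfg = significance.PermutationConfig(n_perm=cfg.n_perm, seed=cfg.perm_seed)
        thr = significance.minp_permutation_threshold(list(datasets.values()), pcfg)
        with open(out / "threshold.json", "w") as fh:
            json.dump(
                {
                    "threshold": thr.threshold,
                    "n_perm": cfg.n_perm,
                    "alpha": pcfg.alpha,
                    "seed": cfg.perm_seed,
                    "config_hash": config_hash(cfg),
                },
                fh,
                indent=2,
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "run_manifest.json", "w") as fh:
        json.dump({"config_hash": config_hash(cfg), "stages": "simulate,qc,ancestry,scan,meta,permute"}, fh)
    return {"scans": scans, "meta": merged, "threshold": thr}
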