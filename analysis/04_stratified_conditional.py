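#!/usr/bin/env python
"""Stratified and conditional follow-up at the top interaction marker.

For the planted causal marker: the local-ancestry main effect overall and
within BMI categories (<25, 25-30, >30 kg/m^2), each cohort then combined
by fixed effects; and a SNP x BMI analysis at the causal marker's genotype
conditioned on local ancestry there, to show how much of the genotype
association is carried by ancestry.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from admixscan import assoc
from admixscan.meta import StudyEstimate, ivw_meta

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "analysis" / "data"
DERIVED = ROOT / "scratch" / "analysis" / "derived"
RESULTS = ROOT / "results"
CAUSAL = "rs000200"


def main() -> None:
    if not DERIVED.exists():
        raise SystemExit("run 02_infer_ancestry.py first")
    strat_rows = []
    per_study = {}
    for d in sorted(DERIVED.iterdir()):
        la = np.load(d / "la_calls.npy")
        pcs = np.load(d / "pcs.npy")
        aims = pd.read_csv(d / "aims.tsv", sep="\t")
        pheno = pd.read_csv(d / "pheno.tsv", sep="\t")
        j = aims.index[aims["marker_id"] == CAUSAL]
        if len(j) == 0:
            print(f"{d.name}: causal marker pruned, skipping")
            continue
        j = int(j[0])
        args = (pheno["case"].to_numpy(), pheno["age"].to_numpy(), pcs, pheno["bmi"].to_numpy())
        overall = assoc.overall_scan(la[:, [j]], args[0], args[1], args[2], marker_ids=[CAUSAL])
        strata = assoc.stratified_scan(la[:, [j]], *args, marker_ids=[CAUSAL])
        both = pd.concat([overall, strata]).assign(cohort=d.name)
        strat_rows.append(both)
        per_study[d.name] = both.set_index("stratum")

    strat = pd.concat(strat_rows)
    meta_rows = []
    for stratum in ["overall", "<25", "25-30", ">30"]:
        ests = [
            StudyEstimate(n, t.loc[stratum, "beta"], t.loc[stratum, "se"])
            for n, t in per_study.items()
            if stratum in t.index and t.loc[stratum, "converged"]
        ]
        if not ests:
            meta_rows.append({"stratum": stratum, "or": np.nan, "note": "no usable stratum"})
            continue
        r = ivw_meta(ests)
        meta_rows.append(
            {"stratum": stratum, "or": round(r.odds_ratio, 3),
             "ci_low": round(r.ci[0], 3), "ci_high": round(r.ci[1], 3),
             "p": f"{r.p:.3g}", "k": len(ests)}
        )
        print(f"LA main effect, {stratum}: meta OR {r.odds_ratio:.3f} "
              f"({r.ci[0]:.2f}-{r.ci[1]:.2f}), p = {r.p:.3g}")
    strat.to_csv(RESULTS / "04_stratified_by_cohort.tsv", sep="\t", index=False, na_rep="NA")
    pd.DataFrame(meta_rows).to_csv(RESULTS / "04_stratified_meta.tsv", sep="\t", index=False)

    # conditional analysis: genotype at the causal marker, with/without LA
    from admixscan.io import read_vcf

    cond_rows = []
    for d in sorted(DERIVED.iterdir()):
        aims = pd.read_csv(d / "aims.tsv", sep="\t")
        if CAUSAL not in set(aims["marker_id"]):
            continue
        g, sites, samples = read_vcf(DATA / d.name / "genotypes.vcf")
        pheno = pd.read_csv(d / "pheno.tsv", sep="\t")
        keep = [samples.index(s) for s in pheno["individual_id"]]
        snp = g[keep, int(sites.index[sites["marker_id"] == CAUSAL][0])]
        la = np.load(d / "la_calls.npy")[:, int(aims.index[aims["marker_id"] == CAUSAL][0])]
        pcs = np.load(d / "pcs.npy")
        args = (pheno["bmi"].to_numpy(), pheno["age"].to_numpy(), pcs, pheno["case"].to_numpy())
        plain = assoc.snp_interaction_tests(snp, *args, marker_id=CAUSAL)
        cond = assoc.conditional_scan(snp, *args, conditioning_la=la, marker_id=CAUSAL)
        obese_plain = plain.query("term == 'SNP' and stratum == '>30'")["or"].iloc[0]
        obese_cond = cond.query("term == 'SNP' and stratum == '>30'")["or"].iloc[0]
        cond_rows.append(
            {"cohort": d.name, "snp_or_obese": round(obese_plain, 3),
             "snp_or_obese_given_la": round(obese_cond, 3)}
        )
        print(f"{d.name}: obese-stratum SNP OR {obese_plain:.3f} -> "
              f"{obese_cond:.3f} after conditioning on local ancestry")
    pd.DataFrame(cond_rows).to_csv(RESULTS / "04_conditional.tsv", sep="\t", index=False)
    print(f"wrote {RESULTS}/04_*.tsv")


if __name__ == "__main__":
    main()
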