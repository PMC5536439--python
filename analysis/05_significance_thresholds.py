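#!/usr/bin/env python
"""Empirical and effective-tests significance thresholds for the scan.

Runs the paired (case status, PC1) min-p permutation across both cohorts
(meta-analyzed per iteration) at desk scale (500 iterations), and the
simpleM-style effective-number-of-tests Bonferroni threshold from each
cohort's AIM genotype correlation matrix.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from admixscan import significance
from admixscan.io import read_vcf
from admixscan.significance import PermutationConfig, ScanDataset

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "analysis" / "data"
DERIVED = ROOT / "scratch" / "analysis" / "derived"
RESULTS = ROOT / "results"

N_PERM = 500  # desk scale; production analyses use 10,000
SEED = 2718


def main() -> None:
    if not DERIVED.exists():
        raise SystemExit("run 02_infer_ancestry.py first")
    datasets, meffs = [], {}
    marker_sets = []
    for d in sorted(DERIVED.iterdir()):
        aims = pd.read_csv(d / "aims.tsv", sep="\t")
        marker_sets.append(list(aims["marker_id"]))
    shared = [m for m in marker_sets[0] if all(m in s for s in marker_sets)]
    for d in sorted(DERIVED.iterdir()):
        la = np.load(d / "la_calls.npy")
        pcs = np.load(d / "pcs.npy")
        aims = pd.read_csv(d / "aims.tsv", sep="\t")
        pheno = pd.read_csv(d / "pheno.tsv", sep="\t")
        cols = [int(aims.index[aims["marker_id"] == m][0]) for m in shared]
        datasets.append(
            ScanDataset(
                la_calls=la[:, cols],
                bmi=pheno["bmi"].to_numpy(),
                age=pheno["age"].to_numpy(),
                pcs=pcs,
                outcome=pheno["case"].to_numpy(),
            )
        )
        g, sites, _ = read_vcf(DATA / d.name / "genotypes.vcf")
        aim_idx = sites.index[sites["marker_id"].isin(shared)]
        meffs[d.name] = significance.simple_m(g[:, aim_idx])
        print(f"{d.name}: effective tests {meffs[d.name]} of {len(shared)} markers")

    bonf = significance.bonferroni_threshold(0.05, list(meffs.values()))
    thr = significance.minp_permutation_threshold(
        datasets, PermutationConfig(n_perm=N_PERM, seed=SEED)
    )
    out = {
        "n_markers": len(shared),
        "n_perm": N_PERM,
        "seed": SEED,
        "minp_threshold": thr.threshold,
        "meff": meffs,
        "bonferroni_threshold": bonf,
    }
    with open(RESULTS / "05_thresholds.json", "w") as fh:
        json.dump(out, fh, indent=2)
    print(f"min-p permutation threshold ({N_PERM} iterations): {thr.threshold:.3e}")
    print(f"simpleM Bonferroni threshold: {bonf:.3e}")
    print(f"wrote {RESULTS / '05_thresholds.json'}")


if __name__ == "__main__":
    main()
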