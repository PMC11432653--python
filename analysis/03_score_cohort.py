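#!/usr/bin/env python
"""Score the cohort: aPRS and wPRS per individual, wPRS Z score,
percentile rank and decile, plus per-group medians.

Reads results/cohort/, writes results/scores/scored.csv and prints the
group-level score summary (the frequency-table analog).
"""
import argparse
from pathlib import Path

from ldlprs.io import read_genotype_csv, read_phenotype_csv
from ldlprs.phenotype import assign_groups, dlcn_score_frame
from ldlprs.score import ScoreDefinition, scored_cohort

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
parser.add_argument("--out", type=Path, default=Path("results/scores"))
args = parser.parse_args()

genotypes = read_genotype_csv(args.cohort / "genotypes.csv")
phenotypes = read_phenotype_csv(args.cohort / "phenotypes.csv")
scored = scored_cohort(genotypes, ScoreDefinition.default())

dl = dlcn_score_frame(phenotypes)
phenotypes["dlcn_points"] = dl["dlcn_points"]
subgroup = assign_groups(phenotypes)

args.out.mkdir(parents=True, exist_ok=True)
scored.join(phenotypes[["group"]]).to_csv(args.out / "scored.csv")

print(f"scored {len(scored)} individuals "
      f"({int((~scored['complete']).sum())} incomplete)")
for g in ("HC", "nFH", "dFH"):
    sel = subgroup == g
    if sel.any():
        w = scored.loc[sel.to_numpy(), "wPRS"]
        a = scored.loc[sel.to_numpy(), "aPRS"]
        print(f"{g:4s} n={int(sel.sum()):5d}  median aPRS {a.median():.1f} "
              f"(IQR {a.quantile(0.25):.1f}-{a.quantile(0.75):.1f})  "
              f"median wPRS {w.median():.3f} "
              f"(IQR {w.quantile(0.25):.3f}-{w.quantile(0.75):.3f})")
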