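#!/usr/bin/env python
"""Clinical-FH discrimination: wPRS across DLCN probability categories,
the DLCN >= 3 contrast with its ROC operating point, and the
100%-sensitivity screening threshold for definite FH (DLCN > 8).
"""
import argparse
from pathlib import Path

from ldlprs.io import read_genotype_csv, read_phenotype_csv
from ldlprs.phenotype import assign_groups, dlcn_score_frame
from ldlprs.score import ScoreDefinition, scored_cohort
from ldlprs.stats import jonckheere_terpstra, mann_whitney, roc_analysis

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
parser.add_argument("--seed", type=int, default=7)
args = parser.parse_args()

genotypes = read_genotype_csv(args.cohort / "genotypes.csv")
df = read_phenotype_csv(args.cohort / "phenotypes.csv")
scored = scored_cohort(genotypes, ScoreDefinition.default())
df["wPRS"] = scored["wPRS"]
dl = dlcn_score_frame(df)
df["dlcn_points"] = dl["dlcn_points"]
df["dlcn_category"] = dl["dlcn_category"]
df["subgroup"] = assign_groups(df)

order = ["unlikely", "possible", "probable", "definite"]
groups = [df.loc[df.dlcn_category == c, "wPRS"].to_numpy()
          for c in order if (df.dlcn_category == c).any()]
jt = jonckheere_terpstra(groups, alternative="increasing", seed=args.seed)
print("wPRS across DLCN categories "
      f"({', '.join(f'{c}: n={int((df.dlcn_category == c).sum())}' for c in order)})")
print(f"  Jonckheere-Terpstra JT={jt.estimate:.0f}, one-sided p={jt.p_value:.2e}")

ge3 = (df["dlcn_points"] >= 3).astype(int)
mw = mann_whitney(df.loc[ge3 == 1, "wPRS"], df.loc[ge3 == 0, "wPRS"])
roc = roc_analysis(df["wPRS"].to_numpy(), ge3.to_numpy(), criterion="youden")
print(f"DLCN >= 3 vs < 3: Mann-Whitney p={mw.p_value:.2e}; "
      f"AUC {roc.auc:.3f} [{roc.auc_ci[0]:.3f}, {roc.auc_ci[1]:.3f}]; "
      f"Youden threshold wPRS > {roc.operating_threshold:.3f} "
      f"(sens {100 * roc.operating_sensitivity:.1f}%, "
      f"spec {100 * roc.operating_specificity:.1f}%)")

dfh = (df["subgroup"] == "dFH").astype(int)
if dfh.sum() >= 3:
    screen = roc_analysis(df["wPRS"].to_numpy(), dfh.to_numpy(),
                          criterion="sensitivity", target_sensitivity=1.0)
    pct = float((df["wPRS"] <= screen.operating_threshold).mean() * 100)
    print(f"definite-FH screening (n={int(dfh.sum())} dFH): "
          f"wPRS > {screen.operating_threshold:.3f} (~{pct:.0f}th percentile) "
          f"gives sens {100 * screen.operating_sensitivity:.0f}%, "
          f"spec {100 * screen.operating_specificity:.1f}%, "
          f"AUC {screen.auc:.3f}")
else:
    print("too few definite-FH individuals in this cohort for the screening ROC")
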