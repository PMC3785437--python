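#!/usr/bin/env python
"""Diet composition statistics from the pipeline's diet matrix.

Computes the frequency of occurrence of each prey species over positive
samples, the amplicon share per species, mean prey richness with its
standard error, a one-way ANOVA of richness across age classes and a
Jaccard PERMANOVA of composition. Writes results/diet_summary.tsv.
Run 03_run_pipeline.py first.
"""

import argparse
from pathlib import Path

import pandas as pd

from preydiet.dietstats import (
    DietMatrix,
    amplicon_proportions,
    anova_richness,
    occurrence,
    permanova,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--matrix", type=Path, default=Path("results/pipeline/diet_matrix.tsv"))
parser.add_argument("--out", type=Path, default=Path("results/diet_summary.tsv"))
args = parser.parse_args()

df = pd.read_csv(args.matrix, sep="\t", index_col=0)
matrix = DietMatrix(df.drop(columns=["age_class"]).astype(int),
                    df["age_class"].astype(str))

occ = occurrence(matrix)
props = amplicon_proportions(matrix)
summary = pd.DataFrame(
    {"occurrence": occ.occurrence.round(4), "amplicon_share": props.round(4)}
).sort_values("occurrence", ascending=False)
args.out.parent.mkdir(parents=True, exist_ok=True)
summary.to_csv(args.out, sep="\t")

print(f"positive samples: {occ.n_positive} of {len(matrix.counts)}")
print(f"mean prey richness: {occ.mean_richness:.2f} +- {occ.richness_se:.2f} (SE)")
top = summary.index[0]
print(f"most frequent prey: {top} in {summary.occurrence.iloc[0]:.0%} of positive "
      f"samples, {props[top]:.0%} of all amplicons")
an = anova_richness(matrix)
print(f"richness ~ age class: F({an.df1},{an.df2}) = {an.f:.4f}, p = {an.p:.4f}")
pm = permanova(matrix, distance="jaccard", permutations=999, seed=args.seed)
print(f"composition ~ age class (Jaccard PERMANOVA, P=999): "
      f"pseudo-F = {pm.pseudo_f:.4f}, p = {pm.p:.4f}")
print(f"per-species table written to {args.out}")
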