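"""Summary outputs across models.

Combines the per-model heritability decompositions into one table with
recomputed totals, computes per-subject genetic (G) and G-by-ethnicity (GE)
values and effect-carrier percentages for the base-model loci, and draws
the genetic-architecture dot/line chart across models.
"""

import os

import pandas as pd

from condgwas import io_qc
from condgwas.encoding import build_design, code_locus, code_pair
from condgwas.estimation import effect_carrier_percentages, individual_genetic_values
from condgwas.report import plot_architecture

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")
DATA = os.path.join(RESULTS, "data")

if __name__ == "__main__":
    models = {}
    for name in ["base", "cond_trans", "cond_smoke"]:
        path = os.path.join(RESULTS, name, "heritability.tsv")
        if os.path.exists(path):
            models[name] = pd.read_csv(path, sep="\t", index_col=0)
    if models:
        combined = pd.concat(models.values())
        combined.to_csv(os.path.join(RESULTS, "heritability_all_models.tsv"), sep="\t")
        print("total heritability by model:",
              {m: float(df["hT2"].iloc[0]) for m, df in models.items()})

    g = io_qc.read_genotypes(os.path.join(DATA, "genotypes_qc.tsv"))
    cohort = io_qc.read_cohort(os.path.join(DATA, "phenotype_qc.csv"))
    effects = pd.read_csv(os.path.join(RESULTS, "base", "effects.tsv"), sep="\t")
    loci = sorted({s for u in effects["unit"] for s in str(u).split(":")})
    cods = {s: code_locus(g, s) for s in loci}
    pair_units = sorted({u for u in effects["unit"] if ":" in str(u)})
    all_c = list(cods.values()) + [
        code_pair(cods[i], cods[j]) for u in pair_units for i, j in [u.split(":")]
    ]
    design = build_design(cohort, all_c)

    vals = individual_genetic_values(effects, design, cohort, pca_sort=True)
    vals.insert(0, "subject_id", cohort["subject_id"])
    vals["ethnicity"] = cohort["ethnicity"]
    vals.to_csv(os.path.join(RESULTS, "genetic_values.tsv"), sep="\t", index=False)
    by_group = vals.groupby("ethnicity")[["G", "GE"]].mean().round(4)
    print("mean G / GE by ethnic group:")
    print(by_group.to_string())

    pct = effect_carrier_percentages(effects, design, cohort)
    pct.to_csv(os.path.join(RESULTS, "carrier_percentages.tsv"), sep="\t", index=False)

    frames = {}
    for name in ["base", "cond_trans", "cond_smoke"]:
        path = os.path.join(RESULTS, name, "scan.tsv")
        if os.path.exists(path):
            frames[name] = pd.read_csv(path, sep="\t")
    if frames:
        # significance on the -log10 P_EW scale; at 500 permutations the
        # resolvable floor is log10(501), so gate at the alpha level instead
        import numpy as np

        _, n_lines = plot_architecture(frames, threshold=float(-np.log10(0.05)),
                                       path=os.path.join(RESULTS, "architecture.png"))
        print(f"architecture plot written ({n_lines} epistasis lines)")
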