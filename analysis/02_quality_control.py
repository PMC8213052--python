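"""Quality control.

SNP filters (MAF >= 0.05, call rate >= 90%), quartile-fence phenotype
outlier removal, then a one-pass standardized-residual filter (|z| > 3)
under the null design (mean + sex + ethnicity).  Missing genotypes are
mean-imputed within ethnic group.  Writes the filtered data and a QC report
whose drop counts conserve the input totals.
"""

import os

import numpy as np

from condgwas import io_qc
from condgwas.encoding import build_design

DATA = os.path.join(os.path.dirname(__file__), "..", "results", "data")

if __name__ == "__main__":
    g = io_qc.read_genotypes(os.path.join(DATA, "genotypes.tsv"))
    cohort = io_qc.read_cohort(os.path.join(DATA, "phenotype.csv"))

    g, rep = io_qc.filter_snps(g)
    rep.n_subjects_in = len(cohort)
    mask_iqr = io_qc.filter_phenotype_outliers_iqr(cohort["bsa"].to_numpy(float))
    rep.subjects_dropped_iqr = int((~mask_iqr).sum())
    cohort = cohort.loc[mask_iqr].reset_index(drop=True)
    g = io_qc.impute_missing(g.subset_subjects(mask_iqr), cohort["ethnicity"].to_numpy())

    mask_res = io_qc.filter_residual_outliers(
        cohort["bsa"].to_numpy(float), build_design(cohort, [])
    )
    rep.subjects_dropped_residual = int((~mask_res).sum())
    cohort = cohort.loc[mask_res].reset_index(drop=True)
    g = g.subset_subjects(mask_res)
    rep.n_subjects_out = len(cohort)
    rep.validate()

    io_qc.write_genotypes(g, os.path.join(DATA, "genotypes_qc.tsv"))
    cohort.to_csv(os.path.join(DATA, "phenotype_qc.csv"), index=False)
    rep.to_tsv(os.path.join(DATA, "qc_report.tsv"))
    print(f"QC kept {rep.n_snps_out}/{rep.n_snps_in} SNPs and "
          f"{rep.n_subjects_out}/{rep.n_subjects_in} subjects "
          f"(IQR fence dropped {rep.subjects_dropped_iqr}, "
          f"residual filter dropped {rep.subjects_dropped_residual})")
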