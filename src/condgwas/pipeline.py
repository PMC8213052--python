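"""End-to-end scan -> permutation -> estimation pipeline for one model.

One call runs the full association workflow the way the study describes it:
single-locus scan, permutation experiment-wise threshold, liberal
preselection feeding the pairwise epistasis scan, Gibbs refit of the
selected multi-locus model, and the component heritability decomposition.
The same function serves the unconditional (base) model and every
cofactor-conditional model; the only difference is the fixed covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import estimation, scan as scan_mod
from .encoding import build_design, code_locus, code_pair
from .estimation import GibbsConfig, HeritabilityTable
from .io_qc import GenotypeMatrix
from .scan import PermutationNull, ScanResult

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    n_perm: int = scan_mod.DEFAULT_N_PERM
    alpha: float = scan_mod.DEFAULT_ALPHA
    seed: int = 0
    preselect_alpha: float = 1e-3
    max_candidates: int = 200
    sig_threshold: float = 5.0      # -log10 P_EW scale for reporting
    run_2d: bool = True
    heritability_mode: str = "empirical"
    gibbs: GibbsConfig = field(default_factory=GibbsConfig)


@dataclass
class PipelineResult:
    model: str
    scan1: list[ScanResult]
    scan2: list[ScanResult]
    null: PermutationNull
    effect_table: pd.DataFrame
    heritability: HeritabilityTable | None
    selected_loci: list[str]
    selected_pairs: list[tuple[str, str]]

    def scan_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.scan1 + self.scan2:
            rows.append(
                {
                    "unit": r.unit,
                    "f_value": r.f.f_value,
                    "df1": r.f.df1,
                    "df2": r.f.df2,
                    "p_nominal": r.f.p_nominal,
                    "neg_log10_p_ew": r.neg_log10_p_ew,
                    "selected": r.selected,
                }
            )
        return pd.DataFrame(rows)


def run_pipeline(
    g: GenotypeMatrix,
    cohort: pd.DataFrame,
    cofactor: str | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    cfg = config or PipelineConfig()
    model = "BSA" if cofactor is None else f"BSA|{cofactor}"
    y = cohort["bsa"].to_numpy(dtype=float)

    results1 = scan_mod.scan_1d(g, cohort, cofactor=cofactor)
    null = scan_mod.permutation_threshold(
        g, cohort, n_perm=cfg.n_perm, alpha=cfg.alpha, seed=cfg.seed, cofactor=cofactor
    )
    scan_mod.assign_experimentwise(results1, null)
    selected_loci = [r.unit for r in results1 if r.selected]

    results2: list[ScanResult] = []
    selected_pairs: list[tuple[str, str]] = []
    if cfg.run_2d:
        candidates = scan_mod.preselect_candidates(
            results1, cfg.preselect_alpha, cfg.max_candidates
        ) if results1 else []
        if len(candidates) >= 2:
            results2 = scan_mod.scan_2d(g, cohort, candidates, cofactor=cofactor)
            scan_mod.assign_experimentwise(results2, null)
            selected_pairs = [tuple(r.unit.split(":")) for r in results2 if r.selected]

    # final multi-locus model: selected loci + marginals of selected pairs
    final_loci = list(dict.fromkeys(selected_loci + [s for p in selected_pairs for s in p]))
    effect_table = pd.DataFrame(
        columns=["unit", "effect", "estimate", "se", "neg_log10_p_ew", "h2_percent"]
    )
    herit = None
    if final_loci:
        codings = [code_locus(g, s) for s in final_loci]
        locus_coding = {c.snp_id: c for c in codings}
        codings += [code_pair(locus_coding[i], locus_coding[j]) for i, j in selected_pairs]
        design = build_design(cohort, codings, cofactor=cofactor)
        effect_table, draws = estimation.gibbs_fit(y, design, cfg.gibbs, null=null)
        comps = estimation.component_variances(draws, design, mode=cfg.heritability_mode)
        comps = {k: max(v, 0.0) for k, v in comps.items()}
        # V_P per the model decomposition: genetic + G-by-ethnicity + residual
        vp_model = sum(comps.values()) + float(draws.sigma2["sigma2_eps"].mean())
        est = draws.theta.mean(axis=0)
        W = design.full_matrix()
        lab_idx = {lab: j for j, lab in enumerate(design.full_labels)}
        h2 = []
        for r in effect_table.itertuples(index=False):
            eff = r.effect
            lab = (
                f"{eff.rsplit('_', 1)[0]}[{r.unit}]_{eff.rsplit('_', 1)[1]}"
                if "_" in eff and eff.rsplit("_", 1)[1].isdigit()
                else f"{eff}[{r.unit}]"
            )
            j = lab_idx[lab]
            h2.append(100.0 * est[j] ** 2 * float(np.var(W[:, j])) / vp_model)
        effect_table = effect_table.assign(h2_percent=h2)
        # per-effect experiment-wise significance: the unit's joint-F P_EW,
        # gated by a pointwise |t| >= 2 filter (the per-coefficient squared-t
        # referred to the max-joint-F null is far too conservative)
        unit_pew = {r.unit: r.neg_log10_p_ew for r in results1 + results2}
        pew = [
            unit_pew.get(r.unit, np.nan) if r.se > 0 and abs(r.estimate) >= 2 * r.se else np.nan
            for r in effect_table.itertuples(index=False)
        ]
        effect_table = effect_table.assign(neg_log10_p_ew=pew)
        # an experiment-wise-selected unit always carries its significance on
        # at least one effect: when coding collinearity (e.g. a vs d at low
        # MAF) pushes every per-coefficient |t| below 2, keep the strongest
        selected_units = set(selected_loci) | {f"{i}:{j}" for i, j in selected_pairs}
        for unit in selected_units:
            rows = effect_table.index[effect_table["unit"] == unit]
            if len(rows) and effect_table.loc[rows, "neg_log10_p_ew"].isna().all():
                tstat = (effect_table.loc[rows, "estimate"].abs()
                         / effect_table.loc[rows, "se"].replace(0, np.nan))
                effect_table.loc[tstat.idxmax(), "neg_log10_p_ew"] = unit_pew.get(unit, np.nan)
        herit = estimation.heritability_table(comps, vp_model)
    else:
        log.info("%s: no units passed the experiment-wise threshold", model)

    return PipelineResult(
        model=model,
        scan1=results1,
        scan2=results2,
        null=null,
        effect_table=effect_table,
        heritability=herit,
        selected_loci=selected_loci,
        selected_pairs=selected_pairs,
    )
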