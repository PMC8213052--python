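"""Cofactor-conditional analyses and base-vs-conditional classification.

The conditional model adds one lifestyle cofactor (walk, exer, read, smoke,
trans) as a fixed covariate to the otherwise identical pipeline; the
remaining genetic effects are those net of that cofactor.  Comparing each
effect between the base and a conditional model yields a verdict per the
study's symbol scheme:

    'x' (not affected)  significant in both, estimate unchanged;
    '+' / '-'           significant in both, |estimate| grew / shrank by
                        more than k pooled standard errors (default k=2);
    'sqrt' caused_by    significant in the base model only — the effect is
                        attributable to the cofactor;
    'sqrt' suppressed   significant in the conditional model only — the
                        cofactor was masking it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_qc import COFACTORS, GenotypeMatrix
from .pipeline import PipelineConfig, PipelineResult, run_pipeline

SYMBOLS = {
    "not_affected": "×",
    "increased": "+",
    "decreased": "−",
    "caused_by": "√",
    "suppressed": "√",
}


def run_conditional(
    g: GenotypeMatrix,
    cohort: pd.DataFrame,
    cofactor: str,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full pipeline with ``cofactor`` as a fixed covariate.

    Subjects with a missing cofactor value are dropped listwise for this
    run only (the base model keeps them).
    """
    if cofactor not in COFACTORS:
        raise ValueError(f"cofactor must be one of {COFACTORS}")
    c = cohort[cofactor].to_numpy(dtype=float)
    keep = ~np.isnan(c)
    if np.ptp(c[keep]) == 0:
        raise ValueError(f"cofactor {cofactor!r} is constant")
    sub_cohort = cohort.loc[keep].reset_index(drop=True)
    sub_g = g.subset_subjects(keep)
    return run_pipeline(sub_g, sub_cohort, cofactor=cofactor, config=config)


@dataclass
class CofactorComparison:
    unit: str
    effect: str
    cofactor: str
    base_estimate: float
    base_significant: bool
    conditional_estimate: float
    conditional_significant: bool
    verdict: str     # not_affected | increased | decreased | caused_by | suppressed
    symbol: str


def classify_cofactor_impacts(
    base: pd.DataFrame,
    conditional: pd.DataFrame,
    cofactor: str,
    sig_threshold: float = 5.0,
    k: float = 2.0,
) -> list[CofactorComparison]:
    """Classify every effect significant in either model.

    ``base`` and ``conditional`` are EffectTables (unit, effect, estimate,
    se, neg_log10_p_ew).  Significance is -log10 P_EW > ``sig_threshold``.
    """
    def keyed(df):
        out = {}
        for r in df.itertuples(index=False):
            sig = bool(np.nan_to_num(r.neg_log10_p_ew) > sig_threshold)
            out[(r.unit, r.effect)] = (float(r.estimate), float(r.se), sig)
        return out

    b, c = keyed(base), keyed(conditional)
    comparisons = []
    for key in sorted(set(b) | set(c), key=str):
        be, bse, bsig = b.get(key, (0.0, 0.0, False))
        ce, cse, csig = c.get(key, (0.0, 0.0, False))
        if not bsig and not csig:
            continue
        if bsig and not csig:
            verdict = "caused_by"
        elif csig and not bsig:
            verdict = "suppressed"
        else:
            pooled = np.sqrt(bse**2 + cse**2)
            if pooled > 0 and abs(abs(ce) - abs(be)) > k * pooled:
                verdict = "increased" if abs(ce) > abs(be) else "decreased"
            else:
                verdict = "not_affected"
        comparisons.append(
            CofactorComparison(
                unit=key[0],
                effect=key[1],
                cofactor=cofactor,
                base_estimate=be,
                base_significant=bsig,
                conditional_estimate=ce,
                conditional_significant=csig,
                verdict=verdict,
                symbol=SYMBOLS[verdict],
            )
        )
    return comparisons


def comparisons_to_frame(comparisons: list[CofactorComparison]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in comparisons])
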