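"""Published MESA BSA heritability decomposition, used as reference input.

The original multi-ethnic BSA study reports, for the base model and the five
lifestyle-cofactor models, the percent-of-V_P heritability of each of the 12
genetic/G-by-ethnicity components together with aggregate totals.  The raw
MESA genotypes are controlled-access, but the printed component values are
public numbers; feeding them through the package's aggregation code checks
the arithmetic identities (total, dominance-related, G-by-ethnicity,
additive-related sums) the study states.

Component order: A, D, AA, AD, DA, DD, AE, DE, AAE, ADE, DAE, DDE.
"""

from .estimation import COMPONENTS, HeritabilityTable

_ROWS = {
    "BSA":       (7.06, 4.24, 2.27, 8.33, 2.43, 5.21, 4.23, 3.38, 2.37, 18.76, 5.83, 10.74),
    "BSA|Walk":  (7.23, 4.61, 2.43, 8.82, 2.85, 5.67, 4.09, 3.37, 2.27, 18.10, 5.62, 10.52),
    "BSA|Exer":  (5.12, 5.97, 4.02, 3.36, 5.74, 12.71, 1.73, 9.95, 1.78, 9.34, 3.43, 14.58),
    "BSA|Read":  (7.24, 4.57, 2.43, 8.78, 2.84, 5.60, 4.10, 3.39, 2.26, 18.18, 5.63, 10.52),
    "BSA|Smoke": (5.54, 7.14, 6.68, 6.82, 8.02, 9.09, 4.27, 7.74, 9.40, 0.54, 7.22, 4.43),
    "BSA|Trans": (6.28, 4.34, 5.40, 3.53, 6.61, 3.42, 3.08, 11.79, 7.53, 9.92, 5.52, 12.45),
}

#: Published per-model component heritabilities (percent of V_P).
PUBLISHED_COMPONENT_H2 = {
    model: dict(zip(COMPONENTS, vals)) for model, vals in _ROWS.items()
}

#: Published per-effect heritabilities (percent) of the COL25A1 x RP11-81H3.2
#: epistasis pair in the base model (da, E-A-specific dae, E-A-specific dde).
COL25A1_PAIR_EFFECT_H2 = {"da": 1.17, "dae_1": 3.24, "dde_1": 1.11}


def published_heritability_table(model: str) -> HeritabilityTable:
    """The published components of ``model`` as a HeritabilityTable (vp=100)."""
    return HeritabilityTable(h2=dict(PUBLISHED_COMPONENT_H2[model]), vp=100.0)
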