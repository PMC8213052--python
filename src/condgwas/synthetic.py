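"""Synthetic multi-ethnic cohort generator with planted genetic architecture.

Emulates the study conditions of a four-group US cohort: ethnic proportions
38/12/28/22% (E-A, C-A, A-A, H-A), a sex block, common SNPs (MAF >= 0.05)
with Balding-Nichols between-group frequency divergence, Hardy-Weinberg
genotypes within group, lifestyle cofactors, and a continuous body-surface-
area-like phenotype assembled term by term from the full genetic model:

    y = mu + sex + cofactors + sum a_i xA_i + sum d_i xD_i
        + epistasis terms + e_h + ethnicity-interaction terms + eps

Planted effects are recorded in a TruthLedger so downstream stages can be
scored for recovery.  Effect sizes are specified as target shares of the
phenotypic variance and converted to coefficients through the realized
coding-column variances, so the realized architecture tracks the target.

No linkage disequilibrium, relatedness, or recombination maps are modelled.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .encoding import ETHNIC_GROUPS, code_locus, code_pair
from .io_qc import COFACTORS, GenotypeMatrix, SnpMeta, _annotate_freq

DEFAULT_PROPORTIONS = (0.38, 0.12, 0.28, 0.22)  # E-A, C-A, A-A, H-A
DEFAULT_MU = 1.85          # population mean on the BSA scale (m^2)
DEFAULT_SEX_EFFECT = 0.1   # male-female block contrast (m^2)
DEFAULT_VP = 0.04          # phenotypic variance on the BSA scale
_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("G", "C"), ("T", "A"))


@dataclass
class CofactorRule:
    """Generation rule for one lifestyle cofactor.

    kind 'independent': pure noise, unrelated to genotype and phenotype.
    kind 'mediator':    cofactor = snp_coef * xA(snp) + noise, and the
                        phenotype receives y_coef * cofactor (SNP -> cofactor
                        -> phenotype; conditioning shrinks the SNP effect).
    kind 'masker':      a latent residual share m enters the phenotype and
                        the cofactor observes it (cofactor = m + noise);
                        conditioning removes that residual variance and
                        unmasks weak planted effects.
    """

    kind: str = "independent"
    snp: str | None = None
    snp_coef: float = 0.0
    y_coef: float = 0.0
    noise_sd: float = 1.0
    latent_sd: float = 0.0


@dataclass
class TruthLedger:
    """Record of everything planted, sufficient to regenerate given the seed."""

    seed: int
    mu: float = DEFAULT_MU
    sex_effect: float = DEFAULT_SEX_EFFECT
    sigma_eps: float = np.sqrt(DEFAULT_VP)
    ethnic_intercepts: dict[int, float] = field(default_factory=dict)
    single_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    pair_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    cofactor_rules: dict[str, CofactorRule] = field(default_factory=dict)
    realized: dict[str, float] = field(default_factory=dict)

    def planted_units(self) -> list[str]:
        return list(self.single_effects) + list(self.pair_effects)

    def planted_effect_items(self):
        for snp, effs in self.single_effects.items():
            for lab, val in effs.items():
                yield snp, lab, val
        for pair, effs in self.pair_effects.items():
            for lab, val in effs.items():
                yield pair, lab, val

    def to_json(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, default=float)

    @classmethod
    def from_json(cls, path) -> "TruthLedger":
        with open(path) as fh:
            d = json.load(fh)
        d["cofactor_rules"] = {k: CofactorRule(**v) for k, v in d["cofactor_rules"].items()}
        d["ethnic_intercepts"] = {int(k): v for k, v in d["ethnic_intercepts"].items()}
        return cls(**d)


def generate_cohort(
    n: int, proportions=DEFAULT_PROPORTIONS, seed: int = 0
) -> pd.DataFrame:
    """Cohort skeleton: ids, sex (Bernoulli 0.5), ethnicity (multinomial)."""
    if n < 8:
        raise ValueError("need n >= 8 to populate all sex x ethnicity strata")
    proportions = np.asarray(proportions, dtype=float)
    if abs(proportions.sum() - 1.0) > 1e-8:
        raise ValueError("ethnic proportions must sum to 1")
    rng = np.random.default_rng(seed)
    eth = rng.choice(np.array(ETHNIC_GROUPS), size=n, p=proportions)
    sex = rng.integers(0, 2, size=n)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:06d}" for i in range(1, n + 1)],
            "sex": sex,
            "ethnicity": eth,
        }
    )


def generate_genotypes(
    cohort: pd.DataFrame,
    n_snps: int,
    maf_range=(0.05, 0.5),
    fst: float = 0.05,
    seed: int = 0,
) -> GenotypeMatrix:
    """HW genotypes with Balding-Nichols group divergence.

    Ancestral Q-allele frequencies are uniform on ``maf_range``; each group's
    frequency is a Beta(p(1-F)/F, (1-p)(1-F)/F) draw around the ancestral p.
    SNP columns whose realized pooled MAF falls below the range floor are
    redrawn so the output emulates a post-QC panel.
    """
    lo, hi = maf_range
    if not (0.05 <= lo < hi <= 0.5):
        raise ValueError("maf_range must sit inside [0.05, 0.5]")
    rng = np.random.default_rng(seed)
    eth = cohort["ethnicity"].to_numpy()
    n = len(cohort)
    calls = np.empty((n, n_snps))
    group_rows = {h: eth == h for h in ETHNIC_GROUPS}

    def draw(cols: np.ndarray) -> None:
        m = cols.size
        p_anc = rng.uniform(lo, hi, size=m)
        for h, rows in group_rows.items():
            if fst > 0:
                a = p_anc * (1 - fst) / fst
                b = (1 - p_anc) * (1 - fst) / fst
                p_h = np.clip(rng.beta(a, b), lo, 1 - lo)
            else:
                p_h = p_anc
            k = int(rows.sum())
            calls[np.ix_(rows, cols)] = rng.binomial(2, np.tile(p_h, (k, 1)))

    draw(np.arange(n_snps))
    for _ in range(20):
        freq = calls.mean(axis=0) / 2.0
        bad = np.flatnonzero(np.minimum(freq, 1 - freq) < lo)
        if bad.size == 0:
            break
        draw(bad)

    snps = []
    for i in range(n_snps):
        aQ, aq = _ALLELE_PAIRS[i % len(_ALLELE_PAIRS)]
        snps.append(SnpMeta(f"rs{i + 1:06d}", i % 22 + 1, 10_000 + 1_000 * i, aQ, aq))
    g = GenotypeMatrix(list(cohort["subject_id"]), snps, calls)
    _annotate_freq(g)
    return g


def _interaction_column(base: np.ndarray, eth: np.ndarray, h: int) -> np.ndarray:
    return base * (eth == h)


def effect_for_share(column: np.ndarray, share: float, vp: float) -> float:
    """Coefficient size so the column's contribution variance is share * vp."""
    v = float(np.var(column))
    if v == 0:
        raise ValueError("constant coding column cannot carry an effect")
    return float(np.sqrt(share * vp / v))


def generate_phenotype(
    cohort: pd.DataFrame,
    g: GenotypeMatrix,
    ledger: TruthLedger,
    sigma_eps: float | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Assemble the phenotype and cofactor columns from the ledger.

    Returns a full cohort table (adds ``bsa`` and the five cofactor columns)
    and records realized component variances back into ``ledger.realized``.
    """
    rng = np.random.default_rng(ledger.seed if seed is None else seed)
    sigma_eps = ledger.sigma_eps if sigma_eps is None else sigma_eps
    n = len(cohort)
    eth = cohort["ethnicity"].to_numpy()
    out = cohort.copy()

    y = np.full(n, ledger.mu)
    y = y + ledger.sex_effect * cohort["sex"].to_numpy(dtype=float)
    for h, val in ledger.ethnic_intercepts.items():
        y = y + val * (eth == int(h))

    comp_sums: dict[str, np.ndarray] = {}

    def add_term(comp: str, contrib: np.ndarray) -> None:
        comp_sums[comp] = comp_sums.get(comp, np.zeros(n)) + contrib

    codings = {}

    def coding(snp: str):
        if snp not in codings:
            codings[snp] = code_locus(g, snp)
        return codings[snp]

    for snp, effs in ledger.single_effects.items():
        c = coding(snp)
        for lab, val in effs.items():
            if lab == "a":
                add_term("A", val * c.xA)
            elif lab == "d":
                add_term("D", val * c.xD)
            elif lab.startswith(("ae_", "de_")):
                base, h = lab.split("_")
                col = _interaction_column(c.xA if base == "ae" else c.xD, eth, int(h))
                add_term(base.upper(), val * col)
            else:
                raise ValueError(f"unknown single-locus effect label: {lab}")
    for pair, effs in ledger.pair_effects.items():
        si, sj = pair.split(":")
        pc = code_pair(coding(si), coding(sj))
        marg = {"aa": pc.xAA, "ad": pc.xAD, "da": pc.xDA, "dd": pc.xDD}
        for lab, val in effs.items():
            if lab in marg:
                add_term(lab.upper(), val * marg[lab])
            elif "_" in lab:
                base, h = lab.split("_")
                if base not in ("aae", "ade", "dae", "dde"):
                    raise ValueError(f"unknown pair effect label: {lab}")
                key = base[:-1]
                col = _interaction_column(marg[key], eth, int(h))
                add_term(base.upper(), val * col)
            else:
                raise ValueError(f"unknown pair effect label: {lab}")

    genetic = np.zeros(n)
    for contrib in comp_sums.values():
        genetic = genetic + contrib
    y = y + genetic

    eps = rng.normal(0.0, sigma_eps, size=n)
    masker_part = np.zeros(n)
    for name in COFACTORS:
        rule = ledger.cofactor_rules.get(name, CofactorRule())
        if rule.kind == "independent":
            out[name] = rng.normal(0.0, rule.noise_sd, size=n)
        elif rule.kind == "mediator":
            c = rule.snp_coef * coding(rule.snp).xA + rng.normal(0.0, rule.noise_sd, size=n)
            out[name] = c
            y = y + rule.y_coef * c
        elif rule.kind == "masker":
            m = rng.normal(0.0, rule.latent_sd, size=n)
            masker_part = masker_part + rule.y_coef * m
            out[name] = m + rng.normal(0.0, rule.noise_sd, size=n)
        else:
            raise ValueError(f"unknown cofactor rule kind: {rule.kind}")
    y = y + eps + masker_part
    out["bsa"] = y

    resid = eps + masker_part
    realized = {comp: float(np.var(v)) for comp, v in comp_sums.items()}
    vp = float(np.var(genetic + resid))
    realized["V_eps"] = float(np.var(resid))
    realized["V_P"] = vp
    realized["hT2"] = 100.0 * float(np.var(genetic)) / vp
    ledger.realized = realized
    cols = ["subject_id", "sex", "ethnicity", "bsa"] + COFACTORS
    return out[[c for c in cols if c in out.columns]]


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

def _pooled_interaction_shares(share: float) -> float:
    # one group carries the effect; share refers to that single column
    return share


def scenario_ledger(
    scenario: str,
    g: GenotypeMatrix,
    cohort: pd.DataFrame,
    seed: int,
    vp: float = DEFAULT_VP,
) -> TruthLedger:
    """Build the TruthLedger for a named study scenario.

    ``null``              no genetic effects (type-I calibration input);
    ``additive``          one additive locus at 2% of V_P;
    ``epistasis``         one dd pair (no marginal effects) at 2% of V_P;
    ``gxe``               group-specific ae/de effects;
    ``cofactor-independent`` a well-powered additive SNP plus a cofactor
                          unrelated to genotype and phenotype;
    ``cofactor-mediated`` an additive SNP acting partly through a cofactor;
    ``cofactor-masked``   a weak SNP plus a cofactor sharing residual noise;
    ``full``              additive + dominance + epistasis + GxE loci, each
                          term >= 1-2% of V_P;
    ``paper_scale``       many loci with component shares proportioned like
                          the published decomposition, total ~= 75%.
    """
    eth = cohort["ethnicity"].to_numpy()
    ids = [s.snp_id for s in g.snps]
    led = TruthLedger(seed=seed, sigma_eps=np.sqrt(vp))

    def cod(snp):
        return code_locus(g, snp)

    def size(col, share):
        return effect_for_share(col, share, vp)

    residual_share = 1.0

    def plant_single(snp, lab, share, sign=1.0):
        nonlocal residual_share
        c = cod(snp)
        if lab == "a":
            col = c.xA
        elif lab == "d":
            col = c.xD
        else:
            base, h = lab.split("_")
            col = _interaction_column(c.xA if base == "ae" else c.xD, eth, int(h))
        led.single_effects.setdefault(snp, {})[lab] = sign * size(col, share)
        residual_share -= share

    def plant_pair(si, sj, lab, share, sign=1.0):
        nonlocal residual_share
        pc = code_pair(cod(si), cod(sj))
        marg = {"aa": pc.xAA, "ad": pc.xAD, "da": pc.xDA, "dd": pc.xDD}
        if "_" in lab:
            base, h = lab.split("_")
            col = _interaction_column(marg[base[:-1]], eth, int(h))
        else:
            col = marg[lab]
        led.pair_effects.setdefault(f"{si}:{sj}", {})[lab] = sign * size(col, share)
        residual_share -= share

    if scenario == "null":
        pass
    elif scenario == "additive":
        plant_single(ids[0], "a", 0.02)
    elif scenario == "epistasis":
        plant_pair(ids[0], ids[1], "dd", 0.02)
    elif scenario == "gxe":
        plant_single(ids[0], "ae_1", 0.02)
        plant_single(ids[1], "de_3", 0.02, sign=-1.0)
    elif scenario == "cofactor-independent":
        plant_single(ids[0], "a", 0.04)
        led.cofactor_rules["trans"] = CofactorRule(kind="independent")
    elif scenario == "cofactor-mediated":
        plant_single(ids[0], "a", 0.002)
        led.cofactor_rules["trans"] = CofactorRule(
            kind="mediator", snp=ids[0], snp_coef=1.0, y_coef=0.4 * np.sqrt(vp), noise_sd=1.0
        )
        # the mediated path adds roughly (y_coef^2 * var(xA)) of phenotype variance
    elif scenario == "cofactor-masked":
        plant_single(ids[0], "a", 0.05)
        led.cofactor_rules["trans"] = CofactorRule(
            kind="masker", y_coef=1.0, latent_sd=np.sqrt(12.0 * vp), noise_sd=0.05 * np.sqrt(vp)
        )
    elif scenario == "full":
        plant_single(ids[0], "a", 0.03)
        plant_single(ids[1], "a", 0.02, sign=-1.0)
        plant_single(ids[2], "d", 0.03)
        plant_single(ids[3], "a", 0.015)
        plant_single(ids[3], "d", 0.015)
        plant_single(ids[4], "ae_1", 0.02)
        plant_single(ids[4], "ae_3", 0.02, sign=-1.0)
        plant_single(ids[5], "de_4", 0.02)
        plant_pair(ids[6], ids[7], "aa", 0.02)
        plant_pair(ids[6], ids[7], "dd", 0.02, sign=-1.0)
        plant_pair(ids[8], ids[9], "dae_1", 0.02)
    elif scenario == "paper_scale":
        # component shares roughly proportioned like the published base-model
        # decomposition (additive-related small, dominance-related dominant),
        # summing to ~0.75
        plan = [
            ("a", 0.030), ("a", 0.030), ("d", 0.017), ("d", 0.017),
            ("ae_1", 0.017), ("ae_3", 0.017), ("de_1", 0.052), ("de_3", 0.052),
            ("de_4", 0.043),
        ]
        for k, (lab, share) in enumerate(plan):
            plant_single(ids[k], lab, share, sign=1.0 if k % 2 == 0 else -1.0)
        pair_plan = [
            ("aa", 0.020), ("ad", 0.069), ("da", 0.022), ("dd", 0.043),
            ("aae_2", 0.021), ("ade_1", 0.078), ("ade_3", 0.078),
            ("dae_1", 0.050), ("dde_1", 0.047), ("dde_4", 0.047),
        ]
        for k, (lab, share) in enumerate(pair_plan):
            si, sj = ids[10 + 2 * k], ids[11 + 2 * k]
            plant_pair(si, sj, lab, share, sign=1.0 if k % 2 == 0 else -1.0)
    else:
        raise ValueError(f"unknown scenario: {scenario}")

    if residual_share <= 0.05:
        raise ValueError("planted shares leave too little residual variance")
    led.sigma_eps = float(np.sqrt(residual_share * vp))
    return led


def generate_dataset(
    n: int,
    n_snps: int,
    seed: int,
    scenario: str = "null",
    proportions=DEFAULT_PROPORTIONS,
    fst: float = 0.05,
    vp: float = DEFAULT_VP,
):
    """One-call generation: (cohort-with-phenotype, genotypes, truth ledger)."""
    cohort = generate_cohort(n, proportions, seed=seed)
    g = generate_genotypes(cohort, n_snps, fst=fst, seed=seed + 1)
    ledger = scenario_ledger(scenario, g, cohort, seed=seed + 2, vp=vp)
    full = generate_phenotype(cohort, g, ledger)
    return full, g, ledger
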