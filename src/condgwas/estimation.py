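"""Gibbs-sampling effect estimation and component heritability decomposition.

The final multi-locus model is refit by MCMC: the full coefficient vector
(fixed genetic effects with flat priors; ethnicity and interaction effects
with group-variance shrinkage) is drawn as one Gaussian block, followed by
conjugate inverse-gamma updates of each group variance and the residual
variance.  Point estimates are posterior means, standard errors posterior
standard deviations, over the post-burn-in draws.

Heritability components follow the 12-term decomposition

    V_P = (V_A + V_D + V_AA + V_AD + V_DA + V_DD)
        + (V_AE + V_DE + V_AAE + V_ADE + V_DAE + V_DDE) + V_eps

with h^2 = 100 * V_component / V_P.  Two variance modes are available:
``empirical`` (variance across subjects of the component's fitted
contribution, averaged over posterior draws — the default) and
``alpha_formula`` (alpha * sigma^2_g / V_P with alpha = 2, 1, 4, 2, 2, 1 for
a, d, aa, ad/da, dd and sigma^2_g the squared posterior-mean effect times
its coding-column variance over alpha; the alpha cancels by construction).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import DesignBundle

COMPONENTS = ("A", "D", "AA", "AD", "DA", "DD", "AE", "DE", "AAE", "ADE", "DAE", "DDE")
DOMINANCE_RELATED = ("D", "AD", "DA", "DD", "DE", "ADE", "DAE", "DDE")
GXE_COMPONENTS = ("AE", "DE", "AAE", "ADE", "DAE", "DDE")
ADDITIVE_RELATED = ("A", "AA", "AE", "AAE")
ETHNIC_DOMINANCE_RELATED = ("DE", "ADE", "DAE", "DDE")
ALPHA_MULTIPLIER = {"a": 2.0, "d": 1.0, "aa": 4.0, "ad": 2.0, "da": 2.0, "dd": 1.0}

_LABEL_RE = re.compile(r"^(a|d|aa|ad|da|dd|ae|de|aae|ade|dae|dde)\[(.+?)\](?:_(\d))?$")


def parse_term_label(label: str):
    """Split a genetic term label into (effect, unit, group-or-None)."""
    m = _LABEL_RE.match(label)
    if not m:
        return None
    eff, unit, grp = m.groups()
    return eff, unit, (int(grp) if grp else None)


def component_of_label(label: str) -> str | None:
    parsed = parse_term_label(label)
    if parsed is None:
        return None
    return parsed[0].upper()


@dataclass
class GibbsConfig:
    """Sampler settings.

    The group-variance prior is inverse-gamma(``ig_shape``,
    ``ig_scale_frac`` x var(y)).  The default (2, 0.005) is weakly
    informative with a small finite prior mean: it pins down the direction
    left unidentified by the exact collinearity between each fixed genetic
    coding and the sum of its group incidences, while a genuine interaction
    variance in the data easily dominates it.  The residual variance keeps a
    near-flat inverse-gamma(0.001, 0.001) prior.
    """

    n_iter: int = 20_000
    burn_in: int = 4_000
    thin: int = 1
    seed: int = 0
    ig_shape: float = 2.0
    ig_scale_frac: float = 0.005

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must be below n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class GibbsDraws:
    """Post-burn-in, thinned posterior draws."""

    labels: list[str]
    theta: np.ndarray                 # (n_draws, p)
    sigma2: pd.DataFrame              # per-group + residual variance draws
    converged: bool = True
    rhat: dict[str, float] = field(default_factory=dict)


def _split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction from one chain's draws."""
    m = x.size // 2
    if m < 2:
        return 1.0
    halves = np.stack([x[:m], x[m : 2 * m]])
    within = halves.var(axis=1, ddof=1).mean()
    if within == 0:
        return 1.0
    between = m * halves.mean(axis=1).var(ddof=1)
    var_plus = (m - 1) / m * within + between / m
    return float(np.sqrt(var_plus / within))


def gibbs_fit(
    y: np.ndarray,
    design: DesignBundle,
    cfg: GibbsConfig | None = None,
    null=None,
    vp: float | None = None,
    variance_granularity: str = "unit",
) -> tuple[pd.DataFrame, GibbsDraws]:
    """Fit the final model by Gibbs sampling; returns (EffectTable, draws).

    ``null`` is an optional PermutationNull: each effect's squared
    t-equivalent is referred to it to attach a -log10 P_EW per effect (an
    approximation; the permutation null was built for the joint scan
    statistic).  ``vp`` defaults to the sample phenotypic variance.

    ``variance_granularity`` controls the shrinkage pools for the random
    interaction effects: ``"unit"`` (default) gives every locus/pair its own
    variance per interaction type, so a single locus with a real
    group-specific effect is not shrunk toward the many null loci;
    ``"type"`` pools one variance per interaction type across loci, matching
    the Method III component structure.
    """
    cfg = cfg or GibbsConfig()
    y = np.asarray(y, dtype=float)
    n = y.size
    W = design.full_matrix()
    labels = design.full_labels
    p = W.shape[1]
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)
    vp = float(np.var(y)) if vp is None else float(vp)

    n_fixed = design.fixed.shape[1]
    if variance_granularity == "type":
        groups = {g: [n_fixed + i for i in idx] for g, idx in design.random_groups.items()}
    elif variance_granularity == "unit":
        groups = {}
        for i, lab in enumerate(design.random_labels):
            parsed = parse_term_label(lab)
            key = "e" if parsed is None else f"{parsed[0]}[{parsed[1]}]"
            groups.setdefault(key, []).append(n_fixed + i)
    else:
        raise ValueError(f"unknown variance_granularity: {variance_granularity}")
    rng = np.random.default_rng(cfg.seed)
    a0 = b0 = 1e-3  # residual-variance prior
    ag = cfg.ig_shape
    bg = cfg.ig_scale_frac * float(np.var(y))

    sigma2_eps = max(np.var(y), 1e-12)
    sigma2_g = {g: sigma2_eps / 10.0 for g in groups}
    theta = np.zeros(p)

    kept = []
    kept_s2 = []
    prior_prec = np.zeros(p)
    for it in range(cfg.n_iter):
        for g, idx in groups.items():
            prior_prec[idx] = 1.0 / sigma2_g[g]
        A = WtW / sigma2_eps + np.diag(prior_prec)
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, Wty / sigma2_eps)
        z = rng.standard_normal(p)
        theta = mean + np.linalg.solve(L.T, z)
        for g, idx in groups.items():
            u = theta[idx]
            sigma2_g[g] = 1.0 / rng.gamma(ag + len(idx) / 2.0, 1.0 / (bg + u @ u / 2.0))
        sse = yty - 2.0 * theta @ Wty + theta @ WtW @ theta
        sse = max(sse, 1e-12)
        sigma2_eps = 1.0 / rng.gamma(a0 + n / 2.0, 1.0 / (b0 + sse / 2.0))
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            kept.append(theta.copy())
            kept_s2.append([sigma2_g[g] for g in groups] + [sigma2_eps])

    theta_draws = np.array(kept)
    s2 = pd.DataFrame(kept_s2, columns=[f"sigma2_{g}" for g in groups] + ["sigma2_eps"])
    rhat = {lab: _split_rhat(theta_draws[:, j]) for j, lab in enumerate(labels)}
    converged = all(r <= 1.1 for r in rhat.values())
    if not converged:
        warnings.warn("Gibbs convergence heuristic failed (split-chain PSR > 1.1)")
    draws = GibbsDraws(labels, theta_draws, s2, converged, rhat)

    rows = []
    est = theta_draws.mean(axis=0)
    se = theta_draws.std(axis=0, ddof=1)
    for j, lab in enumerate(labels):
        parsed = parse_term_label(lab)
        if parsed is None:
            continue  # mu / sex / c / e_h are not genetic effect rows
        eff, unit, grp = parsed
        col = W[:, j]
        h2 = 100.0 * (est[j] ** 2) * np.var(col) / vp
        pew = np.nan
        if null is not None and se[j] > 0:
            pew = null.neg_log10_p_ew((est[j] / se[j]) ** 2)
        rows.append(
            {
                "unit": unit,
                "effect": eff if grp is None else f"{eff}_{grp}",
                "estimate": est[j],
                "se": se[j],
                "neg_log10_p_ew": pew,
                "h2_percent": h2,
            }
        )
    return pd.DataFrame(rows), draws


def component_variances(
    draws: GibbsDraws,
    design: DesignBundle,
    mode: str = "empirical",
    max_draws: int = 200,
) -> dict[str, float]:
    """Per-component variance estimates from posterior draws.

    ``empirical``: across-subject variance of each component's fitted
    contribution, averaged over (a subsample of) posterior draws.
    ``alpha_formula``: sum over the component's columns of
    (posterior-mean effect)^2 x column variance.
    """
    W = design.full_matrix()
    comp_cols: dict[str, list[int]] = {c: [] for c in COMPONENTS}
    for j, lab in enumerate(design.full_labels):
        comp = component_of_label(lab)
        if comp in comp_cols:
            comp_cols[comp].append(j)

    if mode == "empirical":
        td = draws.theta
        if td.shape[0] > max_draws:
            step = td.shape[0] // max_draws
            td = td[::step][:max_draws]
        out = {}
        for comp, idx in comp_cols.items():
            if not idx:
                out[comp] = 0.0
                continue
            contrib = W[:, idx] @ td[:, idx].T  # (n, n_draws)
            out[comp] = float(contrib.var(axis=0).mean())
        return out
    if mode == "alpha_formula":
        est = draws.theta.mean(axis=0)
        out = {}
        for comp, idx in comp_cols.items():
            out[comp] = float(sum(est[j] ** 2 * np.var(W[:, j]) for j in idx))
        return out
    raise ValueError(f"unknown heritability mode: {mode}")


@dataclass
class HeritabilityTable:
    """Percent-of-V_P heritability for the 12 components plus the totals."""

    h2: dict[str, float]
    vp: float

    def __post_init__(self) -> None:
        missing = [c for c in COMPONENTS if c not in self.h2]
        if missing:
            raise ValueError(f"missing components: {missing}")
        neg = {c: v for c, v in self.h2.items() if v < 0}
        if neg:
            raise ValueError(f"negative components: {neg}")

    @property
    def hT2(self) -> float:
        return float(sum(self.h2[c] for c in COMPONENTS))

    @property
    def hD_plus2(self) -> float:
        return float(sum(self.h2[c] for c in DOMINANCE_RELATED))

    @property
    def hGE2(self) -> float:
        return float(sum(self.h2[c] for c in GXE_COMPONENTS))

    @property
    def additive_related2(self) -> float:
        """Additive, additive epistasis, and their ethnic-specific parts."""
        return float(sum(self.h2[c] for c in ADDITIVE_RELATED))

    @property
    def additive_plus_ae2(self) -> float:
        """Additive plus ethnic-specific additive only (A + AE)."""
        return float(self.h2["A"] + self.h2["AE"])

    @property
    def ethnic_dominance_related2(self) -> float:
        return float(sum(self.h2[c] for c in ETHNIC_DOMINANCE_RELATED))

    def to_series(self) -> pd.Series:
        s = pd.Series({c: self.h2[c] for c in COMPONENTS})
        s["hT2"] = self.hT2
        s["hD+2"] = self.hD_plus2
        s["hGE2"] = self.hGE2
        return s


def heritability_table(components: dict[str, float], vp: float) -> HeritabilityTable:
    """Convert component variances to percent heritabilities of ``vp``."""
    if vp <= 0:
        raise ValueError("phenotypic variance must be positive")
    h2 = {c: 100.0 * components.get(c, 0.0) / vp for c in COMPONENTS}
    return HeritabilityTable(h2=h2, vp=vp)


def _unit_columns(effect_table: pd.DataFrame, design: DesignBundle):
    """Map (unit, design column index, estimate, is_interaction) triples."""
    reg = design.term_registry
    W = design.full_matrix()
    labels = design.full_labels
    for row in effect_table.itertuples(index=False):
        eff = row.effect
        if "_" in eff and eff.split("_")[-1].isdigit():
            base, grp = eff.rsplit("_", 1)
            lab = f"{base}[{row.unit}]_{grp}"
            inter = True
        else:
            lab = f"{eff}[{row.unit}]"
            inter = False
        if lab in reg:
            yield row.unit, labels.index(lab), float(row.estimate), inter
    del W


def individual_genetic_values(
    effect_table: pd.DataFrame, design: DesignBundle, cohort=None, pca_sort: bool = False
) -> pd.DataFrame:
    """Per-subject total genetic (G) and ethnicity-interaction (GE) values.

    G sums the fixed genetic contributions; GE sums the group-incidence
    contributions (already zero outside the subject's ethnic group).  With
    ``pca_sort`` and a cohort, adds a display order sorting subjects within
    each ethnic group by their first principal component of the per-unit
    contribution matrix.
    """
    W = design.full_matrix()
    n = design.n
    G = np.zeros(n)
    GE = np.zeros(n)
    per_unit: dict[str, np.ndarray] = {}
    for unit, j, est, inter in _unit_columns(effect_table, design):
        contrib = est * W[:, j]
        per_unit[unit] = per_unit.get(unit, np.zeros(n)) + contrib
        if inter:
            GE += contrib
        else:
            G += contrib
    out = pd.DataFrame({"G": G, "GE": GE})
    if pca_sort and cohort is not None and per_unit:
        M = np.column_stack(list(per_unit.values()))
        M = M - M.mean(axis=0)
        u, _, _ = np.linalg.svd(M, full_matrices=False)
        pc1 = u[:, 0]
        eth = cohort["ethnicity"].to_numpy()
        order = np.lexsort((pc1, eth))
        out["display_order"] = np.argsort(order)
    return out


def effect_carrier_percentages(
    effect_table: pd.DataFrame, design: DesignBundle, cohort, tol: float = 1e-12
) -> pd.DataFrame:
    """Percent of subjects per ethnic group carrying +/-/zero total effects.

    Per locus/pair, a subject's contribution is the fixed genetic part plus
    their own group's interaction part; signs are classified with ``tol``.
    """
    n = design.n
    eth = cohort["ethnicity"].to_numpy()
    per_unit: dict[str, np.ndarray] = {}
    for unit, j, est, _ in _unit_columns(effect_table, design):
        contrib = est * design.full_matrix()[:, j]
        per_unit[unit] = per_unit.get(unit, np.zeros(n)) + contrib
    rows = []
    for unit, contrib in per_unit.items():
        for h in sorted(np.unique(eth)):
            sub = contrib[eth == h]
            m = len(sub)
            pos = float(np.sum(sub > tol)) / m * 100.0
            negv = float(np.sum(sub < -tol)) / m * 100.0
            rows.append(
                {
                    "unit": unit,
                    "ethnicity": int(h),
                    "pct_positive": pos,
                    "pct_negative": negv,
                    "pct_zero": 100.0 - pos - negv,
                }
            )
    return pd.DataFrame(rows)
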