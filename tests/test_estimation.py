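"""Gibbs estimation, heritability decomposition, and per-subject effects."""

import numpy as np
import pandas as pd
import pytest

from condgwas.encoding import DesignBundle, build_design, code_locus, code_pair
from condgwas.estimation import (
    COMPONENTS,
    GibbsConfig,
    component_variances,
    effect_carrier_percentages,
    gibbs_fit,
    heritability_table,
    individual_genetic_values,
)
from condgwas.synthetic import generate_dataset

from conftest import make_cohort, make_genotypes


def _fixed_only(X, labels):
    return DesignBundle(
        fixed=X, fixed_labels=labels, random=np.empty((X.shape[0], 0)),
        random_labels=[], random_groups={},
    )


def test_default_iterations():
    assert GibbsConfig().n_iter == 20_000


def test_gibbs_config_validation():
    with pytest.raises(ValueError):
        GibbsConfig(n_iter=100, burn_in=100)
    with pytest.raises(ValueError):
        GibbsConfig(thin=0)


def test_intercept_only_posterior_mean(rng):
    n = 200
    y = rng.normal(5.0, 1.0, n)
    db = _fixed_only(np.ones((n, 1)), ["mu"])
    _, draws = gibbs_fit(y, db, GibbsConfig(n_iter=2000, burn_in=500, seed=1))
    mu_draws = draws.theta[:, 0]
    assert abs(mu_draws.mean() - 5.0) < 3 * mu_draws.std()


def test_posterior_means_converge_to_ols(rng):
    # fixed-effects-only design: Gibbs posterior means ~ OLS estimates
    n, p = 500, 4
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
    beta_true = np.array([1.0, 0.5, -0.3, 0.2, 0.0])
    y = X @ beta_true + rng.normal(0, 0.5, n)
    db = _fixed_only(X, ["mu"] + [f"x{i}" for i in range(p)])
    _, draws = gibbs_fit(y, db, GibbsConfig(n_iter=20_000, burn_in=4000, seed=2))
    ols = np.linalg.lstsq(X, y, rcond=None)[0]
    np.testing.assert_allclose(draws.theta.mean(axis=0), ols, rtol=0.01, atol=1e-3)


def test_planted_a_d_recovery():
    # a = 0.03, d = 0.045 at n = 2000, sigma_eps = 0.1
    n = 2000
    zs = []
    for rep in range(5):
        rng = np.random.default_rng(100 + rep)
        cohort = make_cohort(n=n, seed=rep)
        g = make_genotypes(rng.binomial(2, 0.4, (n, 1)).astype(float))
        design = build_design(cohort, [code_locus(g, "snp0")])
        y = (0.03 * design.column("a[snp0]") + 0.045 * design.column("d[snp0]")
             + rng.normal(0, 0.1, n))
        table, _ = gibbs_fit(y, design, GibbsConfig(n_iter=3000, burn_in=600, seed=rep))
        t = table.set_index("effect")
        for eff, truth in (("a", 0.03), ("d", 0.045)):
            zs.append(abs(t.loc[eff, "estimate"] - truth) / t.loc[eff, "se"])
    assert max(zs) < 3


class TestComponentVariances:
    def test_zero_effects_zero_variances(self, rng):
        cohort = make_cohort(n=100, seed=0)
        g = make_genotypes(rng.binomial(2, 0.3, (100, 1)).astype(float))
        design = build_design(cohort, [code_locus(g, "snp0")])
        from condgwas.estimation import GibbsDraws

        theta = np.zeros((10, design.full_matrix().shape[1]))
        draws = GibbsDraws(design.full_labels, theta, pd.DataFrame({"sigma2_eps": np.ones(10)}))
        comps = component_variances(draws, design)
        assert all(v == 0 for v in comps.values())

    def test_single_locus_va_converges_to_half_a_squared(self):
        # Var(xA) = 2pq = 0.5 under HW(0.5), so V_A -> a^2/2
        rng = np.random.default_rng(3)
        n = 10_000
        a = 0.2
        cohort = make_cohort(n=n, seed=3)
        g = make_genotypes(rng.binomial(2, 0.5, (n, 1)).astype(float))
        design = build_design(cohort, [code_locus(g, "snp0")])
        from condgwas.estimation import GibbsDraws

        theta = np.zeros((5, design.full_matrix().shape[1]))
        theta[:, design.full_labels.index("a[snp0]")] = a
        draws = GibbsDraws(design.full_labels, theta, pd.DataFrame({"sigma2_eps": np.ones(5)}))
        comps = component_variances(draws, design)
        assert comps["A"] == pytest.approx(a**2 / 2, rel=0.05)

    def test_two_loci_additivity(self):
        rng = np.random.default_rng(4)
        n = 10_000
        cohort = make_cohort(n=n, seed=4)
        g = make_genotypes(rng.binomial(2, 0.5, (n, 2)).astype(float))
        design = build_design(cohort, [code_locus(g, "snp0"), code_locus(g, "snp1")])
        from condgwas.estimation import GibbsDraws

        p = design.full_matrix().shape[1]
        th = np.zeros((5, p))
        th[:, design.full_labels.index("a[snp0]")] = 0.1
        th[:, design.full_labels.index("a[snp1]")] = 0.15
        draws = GibbsDraws(design.full_labels, th, pd.DataFrame({"sigma2_eps": np.ones(5)}))
        both = component_variances(draws, design)["A"]
        assert both == pytest.approx(0.1**2 / 2 + 0.15**2 / 2, rel=0.05)

    def test_unknown_mode_rejected(self, rng):
        cohort = make_cohort(n=50, seed=0)
        g = make_genotypes(rng.binomial(2, 0.3, (50, 1)).astype(float))
        design = build_design(cohort, [code_locus(g, "snp0")])
        from condgwas.estimation import GibbsDraws

        draws = GibbsDraws(design.full_labels,
                           np.zeros((3, design.full_matrix().shape[1])),
                           pd.DataFrame({"sigma2_eps": np.ones(3)}))
        with pytest.raises(ValueError, match="mode"):
            component_variances(draws, design, mode="bogus")


class TestHeritabilityTable:
    def test_identity_sums(self, rng):
        comps = {c: float(v) for c, v in zip(COMPONENTS, rng.uniform(0, 2, 12))}
        t = heritability_table(comps, vp=sum(comps.values()) + 1.0)
        assert t.hT2 == pytest.approx(sum(t.h2.values()))
        assert t.hD_plus2 == pytest.approx(
            sum(t.h2[c] for c in ("D", "AD", "DA", "DD", "DE", "ADE", "DAE", "DDE"))
        )
        assert t.hGE2 == pytest.approx(
            sum(t.h2[c] for c in ("AE", "DE", "AAE", "ADE", "DAE", "DDE"))
        )
        # complementary split: dominance-related + additive-related = total
        assert t.hD_plus2 + t.additive_related2 == pytest.approx(t.hT2)

    def test_zero_components(self):
        t = heritability_table({c: 0.0 for c in COMPONENTS}, vp=1.0)
        assert t.hT2 == 0.0

    def test_vp_guard(self):
        with pytest.raises(ValueError):
            heritability_table({c: 0.0 for c in COMPONENTS}, vp=0.0)

    def test_negative_component_rejected(self):
        comps = {c: 0.0 for c in COMPONENTS}
        comps["A"] = -0.1
        with pytest.raises(ValueError):
            heritability_table(comps, vp=1.0)


class TestIndividualValues:
    def _toy(self):
        rng = np.random.default_rng(5)
        n = 60
        cohort = make_cohort(n=n, seed=5)
        g = make_genotypes(rng.binomial(2, 0.5, (n, 2)).astype(float))
        design = build_design(cohort, [code_locus(g, "snp0"), code_locus(g, "snp1")])
        return cohort, g, design

    def test_all_heterozygous_additive_only_gives_zero(self):
        cohort = make_cohort(n=20, seed=6)
        g = make_genotypes(np.ones((20, 1)))  # everyone Qq -> xA = 0
        design = build_design(cohort, [code_locus(g, "snp0")])
        et = pd.DataFrame(
            [{"unit": "snp0", "effect": "a", "estimate": 0.5, "se": 0.1,
              "neg_log10_p_ew": 9.0, "h2_percent": 1.0}]
        )
        vals = individual_genetic_values(et, design)
        np.testing.assert_array_equal(vals["G"], 0.0)

    def test_two_locus_hand_dot_product(self):
        cohort, g, design = self._toy()
        et = pd.DataFrame(
            [
                {"unit": "snp0", "effect": "a", "estimate": 0.03, "se": 0.01,
                 "neg_log10_p_ew": 9.0, "h2_percent": 1.0},
                {"unit": "snp1", "effect": "d", "estimate": -0.02, "se": 0.01,
                 "neg_log10_p_ew": 9.0, "h2_percent": 1.0},
            ]
        )
        vals = individual_genetic_values(et, design)
        expected = 0.03 * design.column("a[snp0]") - 0.02 * design.column("d[snp1]")
        np.testing.assert_allclose(vals["G"], expected)
        np.testing.assert_array_equal(vals["GE"], 0.0)

    def test_interaction_shifts_group_means(self):
        cohort, g, design = self._toy()
        et = pd.DataFrame(
            [{"unit": "snp0", "effect": "de_1", "estimate": 0.4, "se": 0.1,
              "neg_log10_p_ew": 9.0, "h2_percent": 1.0}]
        )
        vals = individual_genetic_values(et, design)
        eth = cohort["ethnicity"].to_numpy()
        in1 = vals["GE"][eth == 1]
        out1 = vals["GE"][eth != 1]
        assert in1.abs().sum() > 0
        np.testing.assert_array_equal(out1, 0.0)


class TestCarrierPercentages:
    def test_zero_effect_all_zero_class(self, rng):
        cohort = make_cohort(n=40, seed=7)
        g = make_genotypes(rng.binomial(2, 0.5, (40, 1)).astype(float))
        design = build_design(cohort, [code_locus(g, "snp0")])
        et = pd.DataFrame(
            [{"unit": "snp0", "effect": "a", "estimate": 0.0, "se": 0.1,
              "neg_log10_p_ew": 0.0, "h2_percent": 0.0}]
        )
        pct = effect_carrier_percentages(et, design, cohort)
        assert (pct["pct_zero"] == 100.0).all()

    def test_hw_half_additive_quarters(self):
        # HW(0.5), positive a: ~25% QQ positive, ~25% qq negative, ~50% zero
        rng = np.random.default_rng(8)
        n = 20_000
        cohort = make_cohort(n=n, seed=8)
        g = make_genotypes(rng.binomial(2, 0.5, (n, 1)).astype(float))
        design = build_design(cohort, [code_locus(g, "snp0")])
        et = pd.DataFrame(
            [{"unit": "snp0", "effect": "a", "estimate": 0.05, "se": 0.01,
              "neg_log10_p_ew": 9.0, "h2_percent": 1.0}]
        )
        pct = effect_carrier_percentages(et, design, cohort)
        overall = pct.groupby("unit")[["pct_positive", "pct_negative", "pct_zero"]].mean()
        assert overall.loc["snp0", "pct_positive"] == pytest.approx(25, abs=3)
        assert overall.loc["snp0", "pct_negative"] == pytest.approx(25, abs=3)
        assert overall.loc["snp0", "pct_zero"] == pytest.approx(50, abs=3)

    def test_percentages_sum_to_100(self, rng):
        cohort = make_cohort(n=300, seed=9)
        g = make_genotypes(rng.binomial(2, 0.4, (300, 2)).astype(float))
        c0, c1 = code_locus(g, "snp0"), code_locus(g, "snp1")
        design = build_design(cohort, [c0, c1, code_pair(c0, c1)])
        et = pd.DataFrame(
            [
                {"unit": "snp0", "effect": "a", "estimate": 0.1, "se": 0.01,
                 "neg_log10_p_ew": 9.0, "h2_percent": 1.0},
                {"unit": "snp0:snp1", "effect": "dd", "estimate": -0.2, "se": 0.01,
                 "neg_log10_p_ew": 9.0, "h2_percent": 1.0},
            ]
        )
        pct = effect_carrier_percentages(et, design, cohort)
        sums = pct["pct_positive"] + pct["pct_negative"] + pct["pct_zero"]
        np.testing.assert_allclose(sums, 100.0, atol=0.01)

    def test_group_specific_sign_flip(self):
        rng = np.random.default_rng(10)
        n = 400
        cohort = make_cohort(n=n, seed=10)
        g = make_genotypes(rng.binomial(2, 0.5, (n, 1)).astype(float))
        design = build_design(cohort, [code_locus(g, "snp0")])
        et = pd.DataFrame(
            [
                {"unit": "snp0", "effect": "de_1", "estimate": 0.3, "se": 0.01,
                 "neg_log10_p_ew": 9.0, "h2_percent": 1.0},
                {"unit": "snp0", "effect": "de_2", "estimate": -0.3, "se": 0.01,
                 "neg_log10_p_ew": 9.0, "h2_percent": 1.0},
            ]
        )
        pct = effect_carrier_percentages(et, design, cohort).set_index("ethnicity")
        assert pct.loc[1, "pct_positive"] > 0 and pct.loc[1, "pct_negative"] == 0
        assert pct.loc[2, "pct_negative"] > 0 and pct.loc[2, "pct_positive"] == 0


def test_full_recovery_correlation():
    # planted architecture at n = 5000: correlation between true and
    # estimated effect vectors across all planted terms >= 0.9
    cohort, g, led = generate_dataset(5000, 30, seed=77, scenario="full")
    loci = list(dict.fromkeys(
        list(led.single_effects) + [s for p in led.pair_effects for s in p.split(":")]
    ))
    cods = {s: code_locus(g, s) for s in loci}
    all_c = list(cods.values()) + [
        code_pair(cods[i], cods[j]) for pr in led.pair_effects for i, j in [pr.split(":")]
    ]
    design = build_design(cohort, all_c)
    y = cohort["bsa"].to_numpy()
    table, _ = gibbs_fit(y, design, GibbsConfig(n_iter=4000, burn_in=1000, seed=77))
    t = table.set_index(["unit", "effect"])
    true_v, est_v = [], []
    for unit, lab, val in led.planted_effect_items():
        true_v.append(val)
        est_v.append(t.loc[(unit, lab), "estimate"])
    r = np.corrcoef(true_v, est_v)[0, 1]
    assert r >= 0.9
    assert all(np.sign(a) == np.sign(b) for a, b in zip(true_v, est_v))
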