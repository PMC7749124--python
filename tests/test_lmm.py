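"""Mixed-model estimation and Type II Wald tests against independent oracles."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import pinegrowth as pg
from pinegrowth.errors import SingularDesignError, ValidationError


def _sim(eff, seed, **design_kw):
    cfg = pg.DesignConfig(seed=seed, **design_kw)
    return pg.simulate_growth(pg.design_experiment(cfg), eff, seed=seed + 1)


@pytest.fixture(scope="module")
def fitted_2017(field_sim_table):
    return pg.GrowthModel(field_sim_table, "R02", 2017).fit(seed=0)


def test_zero_variance_limit_matches_ols():
    """With no stand/block variance and homoscedastic noise the REML fixed
    effects coincide with ordinary least squares."""
    eff = pg.EffectConfig.null(baseline=10.0, resid_sd=1.0)
    tab = _sim(eff, seed=100)
    m = pg.GrowthModel(tab, "R02", 2017, het_variance=False)
    res = m.profile_results(0.0, 0.0, 1.0)
    beta_ols, *_ = np.linalg.lstsq(m.exog, m.endog, rcond=None)
    assert np.abs(res.params.to_numpy() - beta_ols).max() < 1e-6
    # and the free REML fit lands near the boundary on such data
    fit = m.fit(seed=0)
    assert fit.stand_sd < 0.5 and fit.block_sd < 0.5


def test_matches_statsmodels_mixedlm_homoscedastic():
    """Homoscedastic submodel agrees with statsmodels MixedLM (REML) on
    estimates and log-likelihood."""
    sm = pytest.importorskip("statsmodels.api")
    eff = pg.EffectConfig.null(baseline=12.0, resid_sd=1.5, stand_sd=0.5, block_sd=1.0)
    tab = _sim(eff, seed=200, n_full_controls=0)
    m = pg.GrowthModel(tab, "H", 2017, het_variance=False)
    res = m.fit(seed=0)

    sub = tab[(tab["trait"] == "H") & (tab["year"] == 2017)].copy()
    sub["groups"] = 1  # fully crossed-at-top: both factors as variance components
    vcf = {"stand": "0 + C(stand)", "block": "0 + C(block)"}
    md = sm.MixedLM.from_formula(
        "increment ~ start_size + C(browsing_y2, Treatment('none')) * "
        "C(insects, Treatment('once'))",
        groups="groups", vc_formula=vcf, data=sub,
    )
    mf = md.fit(reml=True, method="lbfgs", maxiter=500)
    assert np.allclose(
        np.sort(res.params.to_numpy()), np.sort(mf.fe_params.to_numpy()), atol=1e-4
    )
    assert res.llf == pytest.approx(mf.llf, abs=1e-4)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_matches_nlme_varident_oracle(tmp_path):
    """Full heteroscedastic model agrees with nlme::lme + varIdent and the
    Type II chi-squares agree with car::Anova on the same data."""
    eff = pg.EffectConfig.field_calibrated()
    cfg = pg.DesignConfig(seed=5, n_full_controls=0)
    wide = pg.simulate_measurements(pg.design_experiment(cfg), eff, seed=6)
    data_path = tmp_path / "data.csv"
    pg.write_measurements(wide, data_path)
    tab = pg.compute_increments(wide)
    res = pg.GrowthModel(tab, "R02", 2017).fit(seed=0)

    rscript = f'''
    suppressMessages({{library(nlme); library(car)}})
    w <- read.csv("{data_path}")
    w$inc <- w$d02_2017_mm - w$d02_2016_mm
    w$browsing <- factor(w$browsing_y2, levels=c("none","b2016","b2016_2017","b2017"))
    w$insects <- factor(w$insects, levels=c("once","twice"))
    fit <- lme(inc ~ start_diam02_mm + browsing*insects, random=~1|stand/block,
               weights=varIdent(form=~1|browsing), data=w, method="REML",
               control=lmeControl(maxIter=200, msMaxIter=200, opt="optim"))
    a <- Anova(fit, type="II")
    cat(fixef(fit)["browsingb2016"], fixef(fit)["insectstwice"], logLik(fit),
        a["browsing","Chisq"], a["browsing:insects","Chisq"], sep=",")
    '''
    out = subprocess.run(["Rscript", "-"], input=rscript, capture_output=True,
                         text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    b2016, twice, llf, chi_b, chi_bi = map(float, out.stdout.strip().split(","))
    assert res.params["browsing[T.b2016]"] == pytest.approx(b2016, abs=2e-3)
    assert res.params["insects[T.twice]"] == pytest.approx(twice, abs=2e-3)
    assert res.llf == pytest.approx(llf, abs=5e-3)
    an = res.anova().set_index("term")
    assert an.loc["Browsing", "chisq"] == pytest.approx(chi_b, rel=5e-3)
    assert an.loc["Browsing:Insects", "chisq"] == pytest.approx(chi_bi, rel=5e-3)


def test_heteroscedastic_sd_ratio_recovered():
    """A 2:1 clipped:control residual-SD truth is estimated within [1.7, 2.3]."""
    eff = pg.EffectConfig.null(baseline=10.0, resid_sd=1.0)
    eff[("R02", 2016)].resid_sd_by_browsing = {"control": 1.0, "clipped": 2.0}
    tab = _sim(eff, seed=300, blocks_per_stand=100)  # 800 trees
    res = pg.GrowthModel(tab, "R02", 2016).fit(seed=0)
    ratio = res.resid_sds["clipped"] / res.resid_sds["control"]
    assert 1.7 <= ratio <= 2.3


def test_nesting_property(fitted_2017, field_sim_table):
    """Group-wise variance REML log-likelihood >= homoscedastic submodel's."""
    assert fitted_2017.llf >= fitted_2017.llf_homoscedastic - 1e-6
    homo = pg.GrowthModel(field_sim_table, "R02", 2017, het_variance=False).fit(seed=0)
    assert fitted_2017.llf >= homo.llf - 1e-6


def test_wald_1df_equals_squared_z(fitted_2017):
    """For a term with no higher-order relatives the 1-df chi-square equals
    (estimate/SE)^2."""
    an = fitted_2017.anova().set_index("term")
    z = fitted_2017.params["start_size"] / fitted_2017.bse["start_size"]
    assert an.loc["Starting size", "chisq"] == pytest.approx(z**2, abs=1e-8)


def test_anova_df_structure(fitted_2017, field_sim_table):
    an17 = fitted_2017.anova().set_index("term")
    assert an17.loc["Browsing", "df"] == 3
    assert an17.loc["Insects", "df"] == 1
    assert an17.loc["Browsing:Insects", "df"] == 3
    an16 = pg.GrowthModel(field_sim_table, "R02", 2016).fit(seed=0).anova().set_index("term")
    assert an16.loc["Browsing", "df"] == 1
    assert an16.loc["Browsing:Insects", "df"] == 1
    assert ((an17["p"] >= 0) & (an17["p"] <= 1)).all()


def test_interaction_test_is_type3_equivalent(fitted_2017):
    """The interaction has no relatives, so its Type II test equals the raw
    Wald test of its coefficients."""
    names = [n for n in fitted_2017.params.index if ":" in n]
    L = np.zeros((len(names), len(fitted_2017.params)))
    for k, n in enumerate(names):
        L[k, list(fitted_2017.params.index).index(n)] = 1.0
    stat, df, _ = fitted_2017.wald_test(L)
    an = fitted_2017.anova().set_index("term")
    assert an.loc["Browsing:Insects", "chisq"] == pytest.approx(stat, rel=1e-10)
    assert an.loc["Browsing:Insects", "df"] == df


def test_estimates_invariant_to_row_order_and_block_labels(field_sim_table):
    res_a = pg.GrowthModel(field_sim_table, "R075", 2017).fit(seed=0)
    shuffled = field_sim_table.sample(frac=1.0, random_state=9).reset_index(drop=True)
    relabel = {b: f"grp-{k}" for k, b in enumerate(pd.unique(shuffled["block"]))}
    shuffled["block"] = shuffled["block"].map(relabel)
    res_b = pg.GrowthModel(shuffled, "R075", 2017).fit(seed=0)
    assert np.allclose(res_a.params.to_numpy(), res_b.params.to_numpy(), atol=1e-5)
    assert res_a.llf == pytest.approx(res_b.llf, abs=1e-5)


def test_pure_interaction_detected():
    """Zero mains plus a large interaction shift: interaction p < 0.01 and its
    chi-square dominates the main effects'."""
    eff = pg.EffectConfig.null(baseline=15.0, resid_sd=1.0, stand_sd=0.3, block_sd=0.5)
    e = eff[("R02", 2017)]
    # zero row/column margins: a pure interaction in the marginal sense too
    e.interaction = {("b2017", "once"): -1.5, ("b2017", "twice"): 1.5,
                     ("b2016_2017", "once"): 1.5, ("b2016_2017", "twice"): -1.5}
    tab = _sim(eff, seed=400, blocks_per_stand=50)  # 400 trees
    an = pg.GrowthModel(tab, "R02", 2017).fit(seed=0).anova().set_index("term")
    assert an.loc["Browsing:Insects", "p"] < 0.01
    assert an.loc["Browsing:Insects", "chisq"] > an.loc["Browsing", "chisq"]
    assert an.loc["Browsing:Insects", "chisq"] > an.loc["Insects", "chisq"]


def test_empty_cell_raises_named_error(field_sim_table):
    broken = field_sim_table[
        ~((field_sim_table["browsing_y2"] == "b2017")
          & (field_sim_table["insects"] == "twice"))
    ]
    with pytest.raises(SingularDesignError, match="b2017"):
        pg.GrowthModel(broken, "R02", 2017)


def test_convergence_status_reported(fitted_2017):
    assert fitted_2017.converged is True
    txt = fitted_2017.summary()
    assert "converged: True" in txt
    assert "Type II Wald" in txt


# -- percentage differences -------------------------------------------------

def test_percent_difference_insects_2016():
    """Observed cell means give the published ~12% year-1 defoliation loss."""
    fx = pg.observed_cell_means()
    res = pg.percent_difference(fx, "R075", 2016, "insects")
    # oracle: (mean(9.99, 8.42) - mean(8.19, 7.96)) / mean(9.99, 8.42)
    assert res.percent == pytest.approx(100 * (9.205 - 8.075) / 9.205, abs=1e-9)
    assert res.absolute == pytest.approx(1.13, abs=1e-9)


def test_percent_difference_browsing_2017_height():
    fx = pg.observed_cell_means()
    res = pg.percent_difference(fx, "H", 2017, "browsing")
    ref = (114.7 + 110.1) / 2
    exposed = (98.5 + 98.4 + 97.3 + 108.2 + 107.3 + 104.1) / 6
    assert res.percent == pytest.approx(100 * (ref - exposed) / ref, abs=1e-9)


def test_percent_difference_zero_when_equal():
    means = pd.DataFrame({
        "year": 2016, "trait": "R02",
        "browsing": ["control", "control", "clipped", "clipped"],
        "insects": ["no", "yes", "no", "yes"], "mean": [5.0] * 4,
    })
    assert pg.percent_difference(means, "R02", 2016, "browsing").percent == 0.0


def test_percent_difference_nonpositive_reference_rejected():
    means = pd.DataFrame({
        "year": 2016, "trait": "R02",
        "browsing": ["control", "clipped"], "insects": ["no", "no"],
        "mean": [-1.0, 2.0],
    })
    with pytest.raises(ValidationError, match="undefined"):
        pg.percent_difference(means, "R02", 2016, "browsing")


def test_adjusted_cell_means_recover_noise_free_truth():
    eff = pg.EffectConfig.null(baseline=10.0, resid_sd=0.0)
    eff[("R02", 2017)].browsing = {
        "none": 0.0, "b2016": -2.0, "b2017": -1.0, "b2016_2017": -3.0}
    tab = _sim(eff, seed=500)
    m = pg.GrowthModel(tab, "R02", 2017, het_variance=False)
    # noise-free data make the REML criterion unbounded; evaluate the GLS
    # (exact interpolation here) at fixed unit variance instead
    res = m.profile_results(0.0, 0.0, 1.0)
    adj = pg.adjusted_cell_means(res).set_index(["browsing", "insects"])
    assert adj.loc[("b2016", "once"), "mean"] == pytest.approx(8.0, abs=1e-3)
    assert adj.loc[("none", "twice"), "mean"] == pytest.approx(10.0, abs=1e-3)


# -- Levene diagnostic ------------------------------------------------------

def test_levene_equal_spread_large_p():
    rng = np.random.default_rng(0)
    resid = rng.normal(0, 1, 400)
    groups = np.repeat(["a", "b"], 200)
    stat, p = pg.levene_diagnostic(resid, groups)
    assert p > 0.05


def test_levene_detects_5x_spread():
    rng = np.random.default_rng(1)
    resid = np.concatenate([rng.normal(0, 1, 100), rng.normal(0, 5, 100)])
    groups = np.repeat(["a", "b"], 100)
    _, p = pg.levene_diagnostic(resid, groups)
    assert p < 0.01


def test_levene_single_group_rejected():
    with pytest.raises(ValidationError):
        pg.levene_diagnostic(np.ones(10), np.repeat("a", 10))
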