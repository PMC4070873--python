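"""Statistical core: variance moderation, BH, designs, blocked ANOVA, SVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from stablemeth import (BlockedAnovaModel, DesignSpec, ModeratedLinearModel,
                        bh_adjust, estimate_surrogates, group_delta_beta)
from stablemeth.models import (fit_variance_prior, squeeze_variances,
                               trigamma_inverse)
from conftest import toy_m_matrix


# ------------------------------------------------------------- moderation

def test_trigamma_inverse_inverts_trigamma():
    for x in (1e-5, 0.01, 0.5, 1.0, 5.0, 100.0, 1e8):
        y = trigamma_inverse(x)
        assert polygamma(1, y) == pytest.approx(x, rel=1e-6)


def test_equal_variances_give_infinite_prior_df():
    s2 = np.full(50, 0.3)
    d0, s0 = fit_variance_prior(s2, df=4.0)
    assert np.isinf(d0)
    # the moment estimator corrects for the chi-square bias of log s^2, so
    # the prior scale sits above the constant observed value by that factor
    assert s0 == pytest.approx(0.3 * np.exp(np.log(2.0) - digamma(2.0)))
    post, d0_out, s0_out = squeeze_variances(s2, df=4.0)
    assert np.isinf(d0_out)
    np.testing.assert_allclose(post, s0_out, rtol=1e-12)


def test_prior_recovery_from_scaled_inv_chi2():
    # simulate s^2 ~ s0^2 * d0/chi2(d0) * chi2(d)/d with known d0, s0
    rng = np.random.default_rng(0)
    d0_true, s0_true, df = 8.0, 0.5, 6.0
    true_var = s0_true * d0_true / rng.chisquare(d0_true, size=20_000)
    s2 = true_var * rng.chisquare(df, size=20_000) / df
    d0, s0 = fit_variance_prior(s2, df=df)
    assert d0 == pytest.approx(d0_true, rel=0.15)
    assert s0 == pytest.approx(s0_true, rel=0.1)


def test_squeeze_formula_and_overrides():
    rng = np.random.default_rng(1)
    # heterogeneous true variances, so the fitted prior df is finite
    true_var = np.exp(rng.normal(0.0, 1.0, size=200))
    s2 = true_var * rng.chisquare(5, size=200) / 5
    post, d0, s0 = squeeze_variances(s2, df=5.0)
    assert 0 < d0 < np.inf
    np.testing.assert_allclose(post, (d0 * s0 + 5.0 * s2) / (d0 + 5.0),
                               rtol=1e-12)
    raw, d0_raw, _ = squeeze_variances(s2, df=5.0, prior_df=0)
    assert d0_raw == 0.0
    np.testing.assert_allclose(raw, s2, rtol=0, atol=0)
    inf_post, d0_inf, s0_inf = squeeze_variances(s2, df=5.0, prior_df=np.inf)
    np.testing.assert_allclose(inf_post, s0_inf, rtol=1e-12)


def test_trended_prior_tracks_the_covariate():
    # variance rises with the covariate; the trended prior should follow it
    rng = np.random.default_rng(2)
    n = 4000
    cov = np.linspace(-3, 3, n)
    true_s2 = np.exp(0.8 * cov)
    df = 10.0
    s2 = true_s2 * rng.chisquare(df, size=n) / df
    _, s0 = fit_variance_prior(s2, df=df, covariate=cov)
    assert np.ndim(s0) == 1
    mid = (cov > -2) & (cov < 2)        # away from the running-mean edges
    ratio = s0[mid] / true_s2[mid]
    assert np.median(np.abs(np.log(ratio))) < 0.25


# ---------------------------------------------------------------------- BH

def test_bh_hand_case():
    p = np.array([0.01, 0.04, 0.03, 0.002])
    # sorted: 0.002,0.01,0.03,0.04 -> *n/i: 0.008,0.02,0.04,0.04 -> cummin ok
    np.testing.assert_allclose(bh_adjust(p), [0.02, 0.04, 0.04, 0.008])


def test_bh_matches_statsmodels_on_random_vectors():
    rng = np.random.default_rng(3)
    for _ in range(200):
        n = int(rng.integers(1, 60))
        p = rng.random(n) ** rng.uniform(0.5, 3.0)
        ours = bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)


def test_bh_preserves_series_index_and_validates():
    s = pd.Series([0.5, 0.01], index=["b", "a"])
    out = bh_adjust(s)
    assert list(out.index) == ["b", "a"]
    with pytest.raises(ValueError):
        bh_adjust(np.array([0.5, 1.5]))
    with pytest.raises(ValueError):
        bh_adjust(np.array([[0.1, 0.2]]))


# ------------------------------------------------------------------ design

def test_design_spec_selects_and_builds(small_sim):
    sheet = small_sim["sheet"]
    spec = DesignSpec(timepoint="T4")
    sub = spec.select_samples(sheet)
    assert (sub["timepoint"] == "T4").all()
    assert (sub["fraction"] == "").all()
    X = spec.build(sheet)
    assert list(X.columns) == ["intercept", "treatment_effect",
                               "cell_line_lineB"]
    assert set(X["treatment_effect"].unique()) == {0.0, 1.0}
    assert spec.effect_name() == "treatment_effect"


def test_design_spec_joint_timepoints(small_sim):
    sheet = small_sim["sheet"]
    spec = DesignSpec(per_timepoint_effects=True)
    X = spec.build(sheet)
    assert list(X.columns) == ["intercept", "timepoint_T8",
                               "treatment_effect_T4", "treatment_effect_T8",
                               "cell_line_lineB"]
    sub = spec.select_samples(sheet)
    is_t4_tgfb = ((sub["timepoint"] == "T4") & (sub["treatment"] == "TGFB"))
    assert (X["treatment_effect_T4"] == is_t4_tgfb.astype(float)).all()
    assert spec.effect_name("T8") == "treatment_effect_T8"
    with pytest.raises(ValueError):
        spec.effect_name()
    with pytest.raises(ValueError):
        DesignSpec(per_timepoint_effects=True, timepoint="T4").build(sheet)


def test_design_spec_errors(small_sim):
    sheet = small_sim["sheet"]
    with pytest.raises(ValueError, match="fewer than 2"):
        DesignSpec(contrast=("TGFB", "nosuch")).build(sheet)
    # duplicating the factor as a covariate makes the design rank deficient
    with pytest.raises(ValueError, match="rank deficient"):
        DesignSpec(covariates=("cell_line", "treatment")).build(sheet)


# --------------------------------------------------- moderated linear model

def _ols_oracle(m, X, j):
    """Per-probe OLS t statistics from explicit normal equations."""
    Xn = X.to_numpy(dtype=float)
    n, p = Xn.shape
    xtx_inv = np.linalg.inv(Xn.T @ Xn)
    effects, ts, ps = [], [], []
    for _, row in m.iterrows():
        y = row.to_numpy(dtype=float)
        b = xtx_inv @ (Xn.T @ y)
        rss = float(np.sum((y - Xn @ b) ** 2))
        s2 = rss / (n - p)
        se = np.sqrt(s2 * xtx_inv[j, j])
        t = b[j] / se
        effects.append(b[j])
        ts.append(t)
        ps.append(2 * stats.t.sf(abs(t), n - p))
    return np.array(effects), np.array(ts), np.array(ps)


def test_unmoderated_fit_matches_ols_oracle():
    m, sheet = toy_m_matrix(n_probes=60, seed=4)
    spec = DesignSpec(timepoint="T4")
    model = ModeratedLinearModel.from_sample_sheet(m, sheet, spec)
    res = model.fit(prior_df=0)
    X = model.design
    j = list(X.columns).index("treatment_effect")
    effect, t, p = _ols_oracle(m[X.index], X, j)
    np.testing.assert_allclose(res.effect, effect, atol=1e-10)
    np.testing.assert_allclose(res.t, t, atol=1e-10)
    np.testing.assert_allclose(res.p, p, atol=1e-10)
    np.testing.assert_allclose(res.q, bh_adjust(p), atol=1e-10)


def test_moderated_t_shrinks_toward_prior():
    m, sheet = toy_m_matrix(n_probes=200, seed=5)
    model = ModeratedLinearModel.from_sample_sheet(m, sheet, DesignSpec(
        timepoint="T4"))
    raw = model.fit(prior_df=0)
    mod = model.fit()
    assert mod.df_prior > 0
    # posterior variances lie between the raw variance and the prior scale
    lo = np.minimum(raw.s2, mod.s2_prior)
    hi = np.maximum(raw.s2, mod.s2_prior)
    assert ((mod.s2_post >= lo - 1e-12) & (mod.s2_post <= hi + 1e-12)).all()
    # extreme raw t statistics are pulled in, not pushed out, on average
    assert np.abs(mod.t).max() <= np.abs(raw.t).max() + 1e-9


def test_trend_fit_gives_per_probe_prior():
    m, sheet = toy_m_matrix(n_probes=150, seed=6)
    model = ModeratedLinearModel.from_sample_sheet(m, sheet, DesignSpec(
        timepoint="T4"))
    res = model.fit(trend=True)
    assert np.ndim(res.s2_prior) == 1
    assert len(res.s2_prior) == 150
    assert "trended mean" in res.summary()


def test_joint_model_pools_residual_df(small_sim):
    beta, sheet = small_sim["beta"], small_sim["sheet"]
    from stablemeth import beta_to_m
    m = beta_to_m(beta)
    joint_spec = DesignSpec(per_timepoint_effects=True)
    joint = ModeratedLinearModel.from_sample_sheet(m, sheet, joint_spec,
                                                   timepoint="T4").fit()
    single = ModeratedLinearModel.from_sample_sheet(
        m, sheet, DesignSpec(timepoint="T4")).fit()
    # 24 bulk samples, 5 columns vs 12 samples, 3 columns
    assert joint.df_resid == 19
    assert single.df_resid == 9
    assert joint.model.coef == "treatment_effect_T4"


def test_model_input_validation():
    m, sheet = toy_m_matrix(n_probes=10, seed=7)
    X = DesignSpec(timepoint="T4").build(sheet)
    with pytest.raises(ValueError, match="not in design"):
        ModeratedLinearModel(m, X, coef="nosuch")
    bad = X.copy()
    bad.index = [f"zz{i}" for i in range(len(bad))]
    with pytest.raises(ValueError, match="absent from matrix"):
        ModeratedLinearModel(m, bad)
    # saturated design: as many columns as samples
    sat = pd.DataFrame(np.eye(len(X)), index=X.index)
    sat.columns = [str(c) for c in sat.columns]
    with pytest.raises(ValueError, match="degrees of freedom"):
        ModeratedLinearModel(m, sat, coef="0").fit()


def test_results_frame_and_significant():
    m, sheet = toy_m_matrix(n_probes=30, seed=8)
    res = ModeratedLinearModel.from_sample_sheet(
        m, sheet, DesignSpec(timepoint="T4")).fit()
    df = res.to_frame()
    assert list(df.columns) == ["effect", "stderr", "s2", "s2_post", "t",
                                "p", "q"]
    assert df.index.equals(m.index)
    assert set(res.significant(1.0)) == set(m.index)
    assert "Moderated linear model" in res.summary()


# ------------------------------------------------------------ blocked ANOVA

def _blocked_inputs(n_probes=50, seed=9):
    g = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(12)]
    classes = pd.Series(["neg", "pos"] * 6, index=ids)
    blocks = pd.Series(np.repeat(["lineA", "lineB"], 6), index=ids)
    m = pd.DataFrame(g.normal(size=(n_probes, 12)),
                     index=[f"cg{i}" for i in range(n_probes)], columns=ids)
    return m, classes, blocks


def test_blocked_f_matches_normal_equations_oracle():
    m, classes, blocks = _blocked_inputs()
    res = BlockedAnovaModel(m, classes, blocks).fit()
    # explicit normal-equations oracle for both nested models
    def rss_of(X, y):
        b = np.linalg.solve(X.T @ X, X.T @ y)
        return float(np.sum((y - X @ b) ** 2))
    ones = np.ones((12, 1))
    bd = pd.get_dummies(blocks, drop_first=True).to_numpy(float)
    cd = pd.get_dummies(classes, drop_first=True).to_numpy(float)
    X_full = np.hstack([ones, bd, cd])
    X_red = np.hstack([ones, bd])
    df_full = 12 - X_full.shape[1]
    for i, (_, row) in enumerate(m.iterrows()):
        y = row.to_numpy(float)
        rss_f, rss_r = rss_of(X_full, y), rss_of(X_red, y)
        F = (rss_r - rss_f) / (rss_f / df_full)
        p = stats.f.sf(F, 1, df_full)
        assert res.F[i] == pytest.approx(F, abs=1e-10)
        assert abs(res.p[i] - p) < 1e-12
        lrt = 12 * np.log(rss_r / rss_f)
        assert res.lrt[i] == pytest.approx(lrt, abs=1e-10)


def test_blocked_f_equals_t_squared():
    m, classes, blocks = _blocked_inputs(seed=10)
    fres = BlockedAnovaModel(m, classes, blocks).fit()
    sheet = pd.DataFrame({"fraction": classes, "cell_line": blocks})
    spec = DesignSpec(factor="fraction", contrast=("pos", "neg"),
                      covariates=("cell_line",))
    tres = ModeratedLinearModel.from_sample_sheet(m, sheet, spec).fit(prior_df=0)
    np.testing.assert_allclose(fres.F, tres.t ** 2, atol=1e-10)
    np.testing.assert_allclose(fres.p, tres.p, atol=1e-10)


def test_blocked_anova_requires_both_classes_per_block():
    m, classes, blocks = _blocked_inputs()
    classes.iloc[:6] = "neg"     # block lineA loses the 'pos' class
    with pytest.raises(ValueError, match="both classes"):
        BlockedAnovaModel(m, classes, blocks)


def test_blocked_results_frame():
    m, classes, blocks = _blocked_inputs(n_probes=5)
    res = BlockedAnovaModel(m, classes, blocks).fit()
    df = res.to_frame()
    assert list(df.columns) == ["F", "p", "lrt"]
    assert "Randomized-block" in res.summary()


# --------------------------------------------------------------------- SVA

def test_sva_disabled_and_null_behaviour():
    m, sheet = toy_m_matrix(n_probes=400, seed=11)
    X = DesignSpec().build(sheet)
    assert estimate_surrogates(m, X, max_k=0).shape == (len(X), 0)
    # pure iid noise: parallel analysis should keep nothing (or almost)
    sv = estimate_surrogates(m, X, seed=0)
    assert sv.shape[1] <= 1


def test_sva_recovers_planted_batch():
    m, sheet = toy_m_matrix(n_probes=500, seed=12)
    g = np.random.default_rng(99)
    batch = (sheet["batch"] == "batch2").to_numpy(float)
    loadings = g.normal(0.0, 1.0, size=len(m))
    m_batched = m + np.outer(loadings, batch - batch.mean())
    X = DesignSpec(per_timepoint_effects=True).build(sheet)
    sv = estimate_surrogates(m_batched, X, seed=0)
    assert sv.shape[1] >= 1
    corr = np.corrcoef(sv["sv1"].to_numpy(), batch)[0, 1]
    assert abs(corr) > 0.9


def test_sva_is_deterministic():
    m, sheet = toy_m_matrix(n_probes=300, seed=13)
    X = DesignSpec().build(sheet)
    sv1 = estimate_surrogates(m, X, seed=7)
    sv2 = estimate_surrogates(m, X, seed=7)
    pd.testing.assert_frame_equal(sv1, sv2)


def test_sva_zero_residuals_warns():
    m, sheet = toy_m_matrix(n_probes=20, seed=14)
    X = DesignSpec().build(sheet)
    fitted = pd.DataFrame(np.ones((20, len(X))), index=m.index,
                          columns=X.index)
    with pytest.warns(UserWarning, match="numerically zero"):
        sv = estimate_surrogates(fitted, X)
    assert sv.shape[1] == 0


# ------------------------------------------------------------- delta-beta

def test_group_delta_beta_hand_check():
    ids = ["a_c", "a_t", "b_c", "b_t"]
    sheet = pd.DataFrame({
        "cell_line": ["lineA", "lineA", "lineB", "lineB"],
        "treatment": ["control", "TGFB", "control", "TGFB"],
        "timepoint": ["T4"] * 4, "fraction": [""] * 4}, index=ids)
    beta = pd.DataFrame([[0.2, 0.5, 0.4, 0.3]], index=["cg1"], columns=ids)
    out = group_delta_beta(beta, sheet)
    assert out.loc["cg1", "lineA_T4"] == pytest.approx(0.3)
    assert out.loc["cg1", "lineB_T4"] == pytest.approx(-0.1)
    assert out.loc["cg1", "overall"] == pytest.approx((0.5 + 0.3) / 2
                                                      - (0.2 + 0.4) / 2)


def test_group_delta_beta_excludes_fraction_samples(small_sim):
    out = group_delta_beta(small_sim["beta"], small_sim["sheet"])
    assert set(out.columns) == {"lineA_T4", "lineA_T8", "lineB_T4",
                                "lineB_T8", "overall"}


def test_group_delta_beta_missing_stratum_errors():
    ids = ["a_c", "a_t"]
    sheet = pd.DataFrame({"cell_line": ["lineA", "lineA"],
                          "treatment": ["control", "control"],
                          "timepoint": ["T4", "T4"], "fraction": ["", ""]},
                         index=ids)
    beta = pd.DataFrame([[0.2, 0.5]], index=["cg1"], columns=ids)
    with pytest.raises(ValueError, match="lacks samples"):
        group_delta_beta(beta, sheet)
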