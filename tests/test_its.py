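"""Interrupted time-series design coding and GLMM estimation."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest

from resilnet import (GeneratorConfig, ITSDesign, build_design, fit_its,
                      generate_panel, trend_change_report)
from resilnet.panel import SymptomPanel
from resilnet.simulate import OutcomeModel


def _its_panel(seed=301, n=1500, sigma_u=1.0, t_post=-0.31, years=None):
    models = {"medication_use": OutcomeModel(intercept=-2.0, t=0.0,
                                             t_post=t_post, confounder=-0.1,
                                             sigma_u=sigma_u),
              "healthcare_use": OutcomeModel(intercept=-2.2, sigma_u=sigma_u)}
    kwargs = {}
    if years is not None:
        kwargs["years"] = years
    cfg = GeneratorConfig(seed=seed, n_target=n, outcome_models=models,
                          **kwargs)
    return generate_panel(cfg)


@pytest.fixture(scope="module")
def its_panel():
    return _its_panel()


def test_time_coding(its_panel):
    panel, truth = its_panel
    frame = build_design(panel, ITSDesign(outcome="medication_use",
                                          confounder=truth["confounder"]))
    X = frame.X
    by_year = {}
    years = panel.df["year"]
    # reconstruct year from t coding
    for t, tp in zip(X["t"], X["t_post"]):
        by_year[int(t) + 2016] = (t, tp)
    assert by_year[2012] == (-4.0, 0.0)
    assert by_year[2019] == (3.0, 3.0)
    assert by_year[2015] == (-1.0, 0.0)
    assert by_year[2016] == (0.0, 0.0)
    assert "post" not in X.columns          # level change off by default
    assert "bct" in X.columns


def test_level_change_term_is_optional(its_panel):
    panel, truth = its_panel
    frame = build_design(panel, ITSDesign(outcome="medication_use",
                                          confounder=truth["confounder"],
                                          include_level_change=True))
    assert "post" in frame.X.columns


def test_subgroup_contrast_columns(its_panel):
    panel, truth = its_panel
    frame = build_design(panel, ITSDesign(outcome="medication_use",
                                          confounder=truth["confounder"],
                                          subgroup="social_support"))
    cols = list(frame.X.columns)
    # 3 levels -> 2 reference-coded contrasts, each with main, x t, x t x post
    for lvl in ("middle", "high"):
        assert f"social_support[{lvl}]" in cols
        assert f"social_support[{lvl}]:t" in cols
        assert f"social_support[{lvl}]:t_post" in cols
    assert "social_support[low]" not in cols


def test_missing_confounder_year_is_an_error(its_panel):
    panel, truth = its_panel
    conf = {k: v for k, v in truth["confounder"].items() if k != 2017}
    with pytest.raises(ValueError, match="2017"):
        build_design(panel, ITSDesign(outcome="medication_use",
                                      confounder=conf))


def test_constant_outcome_is_an_error(its_panel):
    panel, truth = its_panel
    df = panel.df.copy()
    df["healthcare_use"] = 0
    broken = SymptomPanel(df, panel.study_window, panel.missing_years)
    with pytest.raises(ValueError, match="healthcare_use"):
        build_design(broken, ITSDesign(outcome="healthcare_use",
                                       confounder=truth["confounder"]))


def test_recovers_generated_trend_change(its_panel):
    panel, truth = its_panel
    frame = build_design(panel, ITSDesign(outcome="medication_use",
                                          confounder=truth["confounder"]))
    res = fit_its(frame)
    assert res.converged
    c = res.coef("t_post")
    assert abs(c["beta"] - (-0.31)) < 2 * c["se"]
    assert abs(res.sigma_u - 1.0) < 0.3


def test_sigma_zero_matches_plain_logistic_oracle():
    import statsmodels.api as sm
    panel, truth = _its_panel(seed=302, n=3000, sigma_u=0.0)
    frame = build_design(panel, ITSDesign(outcome="medication_use",
                                          confounder=truth["confounder"]))
    res = fit_its(frame)
    oracle = sm.Logit(frame.y, frame.X.to_numpy()).fit(disp=0, tol=1e-12)
    np.testing.assert_allclose(res.table["beta"].to_numpy(), oracle.params,
                               atol=1e-3)
    assert res.sigma_u < 0.05


def test_time_coding_invariance_under_calendar_shift(its_panel):
    """Shifting all years and the campaign start by the same amount
    leaves every coefficient unchanged."""
    panel, truth = its_panel
    shift = 7
    frame = build_design(panel, ITSDesign(outcome="medication_use",
                                          confounder=truth["confounder"]))
    res = fit_its(frame)
    df = panel.df.copy()
    df["year"] = df["year"] + shift
    moved = SymptomPanel(df, (panel.study_window[0] + shift,
                              panel.study_window[1] + shift),
                         tuple(y + shift for y in panel.missing_years))
    conf = {k + shift: v for k, v in truth["confounder"].items()}
    frame2 = build_design(moved, ITSDesign(
        outcome="medication_use", window=(2012 + shift, 2019 + shift),
        campaign_start=2016 + shift, confounder=conf))
    res2 = fit_its(frame2)
    np.testing.assert_allclose(res2.table["beta"].to_numpy(),
                               res.table["beta"].to_numpy(), atol=1e-8)


def test_constant_confounder_changes_nothing(its_panel):
    panel, truth = its_panel
    base = fit_its(build_design(panel, ITSDesign(outcome="medication_use")))
    const = fit_its(build_design(panel, ITSDesign(
        outcome="medication_use",
        confounder={y: 3.14 for y in range(2012, 2020)})))
    np.testing.assert_allclose(const.table["beta"].to_numpy(),
                               base.table["beta"].to_numpy(), atol=1e-8)


def test_missing_survey_year_handled_by_calendar_coding():
    """Dropping the 2014 wave must not re-index time: t for the remaining
    years is unchanged and estimates move only slightly."""
    years_full = (2012, 2013, 2014, 2015, 2016, 2017, 2018, 2019)
    params = {y: (-3.4, 14.0) for y in years_full}
    cfg = GeneratorConfig(seed=88, n_target=1200, years=years_full,
                          year_params=params)
    panel_full, truth = generate_panel(cfg)
    df_drop = panel_full.df[panel_full.df["year"] != 2014].reset_index(drop=True)
    panel_drop = SymptomPanel(df_drop, panel_full.study_window, (2014,))

    design = ITSDesign(outcome="medication_use", confounder=truth["confounder"])
    f_full = build_design(panel_full, design)
    f_drop = build_design(panel_drop, design)

    def year_to_t(frame):
        return dict(zip((frame.X["t"] + 2016).astype(int), frame.X["t"]))

    t_full, t_drop = year_to_t(f_full), year_to_t(f_drop)
    for year, t in t_drop.items():
        assert t_full[year] == t
    r_full, r_drop = fit_its(f_full), fit_its(f_drop)
    c_full, c_drop = r_full.coef("t_post"), r_drop.coef("t_post")
    assert abs(c_full["beta"] - c_drop["beta"]) < 4 * c_full["se"]


def test_trend_change_report_row_counts(its_panel):
    panel, truth = its_panel
    report = trend_change_report(
        panel, outcomes=("healthcare_use", "medication_use"),
        subgroups=(), confounder=truth["confounder"])
    assert len(report) == 2
    assert set(report["contrast"]) == {"trend_change"}

    report_sub = trend_change_report(
        panel, outcomes=("medication_use",), subgroups=("social_support",),
        confounder=truth["confounder"])
    contrasts = set(report_sub["contrast"])
    assert contrasts == {"trend_change", "social_support[middle]:t_post",
                         "social_support[high]:t_post"}


def test_glmm_agrees_with_lme4_oracle(tmp_path):
    """Cross-check the quadrature GLMM against glmer (lme4, adaptive
    Gauss-Hermite) on a small panel."""
    panel, truth = _its_panel(seed=303, n=250, sigma_u=1.0,
                              years=(2013, 2015, 2016, 2017, 2018))
    frame = build_design(panel, ITSDesign(outcome="medication_use",
                                          confounder=truth["confounder"],
                                          window=(2013, 2018)))
    res = fit_its(frame)
    data = frame.X.copy()
    data["y"] = frame.y
    data["pid"] = frame.groups
    csv = tmp_path / "glmm.csv"
    data.to_csv(csv, index=False)
    rscript = textwrap.dedent(f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- glmer(y ~ t + t_post + bct + (1 | pid), data = d,
                   family = binomial, nAGQ = 15)
        cat(fixef(m), sigma <- sqrt(unlist(VarCorr(m))), sep = "\\n")
    """)
    out = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                         text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    vals = [float(v) for v in out.stdout.split()]
    beta_r, sigma_r = np.array(vals[:4]), vals[4]
    ours = res.table.set_index("term")["beta"]
    np.testing.assert_allclose(
        [ours["const"], ours["t"], ours["t_post"], ours["bct"]],
        beta_r, atol=2e-2)
    assert abs(res.sigma_u - sigma_r) < 0.05
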