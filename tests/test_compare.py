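"""Yearly resilience summaries and BCa bootstrap machinery."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.stats import norm

from resilnet import (GeneratorConfig, bca_interval,
                      bootstrap_stability_difference_test, generate_panel,
                      pvalue_from_bca, sample_ising_exact, summaries_to_frame,
                      yearly_summary)

# ---------------------------------------------------------------------------
# independent brute-force BCa oracle (explicit formulas, own quantile code)

TOY_DATA = np.array([2.1, -0.4, 1.3, 0.0, 3.7, 1.1, -1.2, 0.8, 2.6, 0.5])


def _oracle_quantile(sorted_x, q):
    """Hand-coded type-7 (linear interpolation) quantile."""
    h = (len(sorted_x) - 1) * q
    lo = int(math.floor(h))
    hi = min(lo + 1, len(sorted_x) - 1)
    return sorted_x[lo] + (h - lo) * (sorted_x[hi] - sorted_x[lo])


def _oracle_bca(boot, observed, jack, alpha):
    boot = np.sort(np.asarray(boot, dtype=float))
    B = len(boot)
    frac = (np.sum(boot < observed) + 0.5 * np.sum(boot == observed)) / B
    frac = min(max(frac, 0.5 / B), 1 - 0.5 / B)
    z0 = norm.ppf(frac)
    jbar = np.mean(jack)
    num = np.sum((jbar - jack) ** 3)
    den = 6.0 * np.sum((jbar - jack) ** 2) ** 1.5
    a = num / den if den > 0 else 0.0
    out = []
    for z in (norm.ppf(alpha / 2), norm.ppf(1 - alpha / 2)):
        adj = norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z)))
        out.append(_oracle_quantile(boot, adj))
    return tuple(out)


def _toy_replicates(B=2000, seed=2024):
    rng = np.random.default_rng(seed)
    n = len(TOY_DATA)
    idx = rng.integers(0, n, size=(B, n))
    boot = TOY_DATA[idx].mean(axis=1)
    jack = (TOY_DATA.sum() - TOY_DATA) / (n - 1)   # leave-one-out means
    return boot, TOY_DATA.mean(), jack


def test_bca_matches_brute_force_oracle():
    boot, observed, jack = _toy_replicates()
    ours = bca_interval(boot, observed, jack, alpha=0.05)
    oracle = _oracle_bca(boot, observed, jack, alpha=0.05)
    assert ours[0] == pytest.approx(oracle[0], abs=1e-9)
    assert ours[1] == pytest.approx(oracle[1], abs=1e-9)


def test_pvalue_matches_oracle_inversion():
    boot, observed, jack = _toy_replicates()
    p = pvalue_from_bca(boot, observed, jack)

    lo_a, hi_a = 1e-6, 1 - 1e-6

    def excl(alpha):
        lo, hi = _oracle_bca(boot, observed, jack, alpha)
        return lo > 0 or hi < 0

    while hi_a - lo_a > 1e-5:
        mid = 0.5 * (lo_a + hi_a)
        if excl(mid):
            hi_a = mid
        else:
            lo_a = mid
    assert p == pytest.approx(0.5 * (lo_a + hi_a), abs=1e-3)


def test_bca_reduces_to_percentile_when_unbiased_symmetric():
    """z0 = 0 and a = 0 collapse the BCa interval to plain percentile."""
    rng = np.random.default_rng(5)
    spread = np.abs(rng.normal(1.0, 0.3, 500))
    observed = 2.0
    boot = np.concatenate([observed + spread, observed - spread])
    jack = np.concatenate([spread, -spread])  # symmetric -> a = 0
    lo, hi = bca_interval(boot, observed, jack, alpha=0.05)
    assert lo == pytest.approx(np.quantile(boot, 0.025), abs=1e-12)
    assert hi == pytest.approx(np.quantile(boot, 0.975), abs=1e-12)


def test_bca_full_coverage_limit_is_range():
    boot, observed, jack = _toy_replicates(B=500)
    lo, hi = bca_interval(boot, observed, jack, alpha=1e-9)
    assert lo == pytest.approx(boot.min())
    assert hi == pytest.approx(boot.max())


def test_pvalue_near_alpha_when_interval_touches_zero():
    rng = np.random.default_rng(8)
    spread = np.abs(rng.normal(1.0, 0.3, 2000))
    sym = np.concatenate([spread, -spread])
    # shift so the 2.5% quantile sits at ~0: interval endpoint touches 0
    shift = -np.quantile(sym, 0.025)
    boot = sym + shift
    jack = np.concatenate([spread, -spread])
    p = pvalue_from_bca(boot, shift, jack)
    assert p == pytest.approx(0.05, abs=0.01)


def test_pvalue_is_one_for_central_null():
    rng = np.random.default_rng(9)
    spread = np.abs(rng.normal(1.0, 0.3, 1000))
    boot = np.concatenate([spread, -spread])
    jack = boot.copy()
    assert pvalue_from_bca(boot, 0.0, jack) > 0.9


def test_degenerate_bootstrap_yields_point_interval():
    with pytest.warns(RuntimeWarning):
        lo, hi = bca_interval(np.full(300, 1.7), 1.7, np.full(20, 1.7))
    assert lo == hi == 1.7


# ---------------------------------------------------------------------------
# full-pipeline bootstrap


def _year_matrices(default_config, n=1500, seed=0):
    net_a = default_config.network_for(2012, "middle")
    net_b = default_config.network_for(2019, "middle")
    return (sample_ising_exact(net_a, n, seed=seed),
            sample_ising_exact(net_b, n, seed=seed + 1))


def test_bootstrap_comparison_deterministic_given_seed(default_config):
    Xa, Xb = _year_matrices(default_config)
    r1 = bootstrap_stability_difference_test(Xa, Xb, B=200, seed=11)
    r2 = bootstrap_stability_difference_test(Xa, Xb, B=200, seed=11)
    assert dataclasses.asdict(r1) == dataclasses.asdict(r2)
    r3 = bootstrap_stability_difference_test(Xa, Xb, B=200, seed=12)
    assert r3.ci_low != r1.ci_low


def test_bootstrap_comparison_basic_contract(default_config):
    Xa, Xb = _year_matrices(default_config)
    res = bootstrap_stability_difference_test(Xa, Xb, B=200, seed=4)
    assert res.ci_low <= res.ci_high
    assert 0.0 < res.p_value <= 1.0
    assert res.B == 200
    assert res.year_a == 2012 and res.year_b == 2019


def test_bootstrap_requires_minimum_replicates(default_config):
    Xa, Xb = _year_matrices(default_config, n=500)
    with pytest.raises(ValueError):
        bootstrap_stability_difference_test(Xa, Xb, B=100, seed=1)


def test_null_contrast_interval_contains_zero(default_config):
    """Two samples from the same network: the 95% interval should cover 0."""
    net = default_config.network_for(2012, "middle")
    Xa = sample_ising_exact(net, 2000, seed=21)
    Xb = sample_ising_exact(net, 2000, seed=22)
    res = bootstrap_stability_difference_test(Xa, Xb, B=300, seed=23)
    assert res.ci_low <= 0.0 <= res.ci_high


def test_shifted_thresholds_detected(default_config):
    """Raising all thresholds by 1.5 flips the landscape enough that the
    interval excludes zero."""
    net_a = default_config.network_for(2012, "middle")
    tau_b = net_a.tau + 1.5
    import resilnet
    net_b = resilnet.IsingNetwork(net_a.labels, net_a.W, tau_b)
    Xa = sample_ising_exact(net_a, 2000, seed=31)
    Xb = sample_ising_exact(net_b, 2000, seed=32)
    res = bootstrap_stability_difference_test(Xa, Xb, B=300, seed=33)
    assert res.ci_high < 0.0     # S drops when thresholds rise
    assert res.p_value < 0.05


# ---------------------------------------------------------------------------
# yearly summaries


def test_yearly_summary_schema_and_consistency(small_panel):
    panel, _ = small_panel
    rows = yearly_summary(panel, years=[2012, 2019])
    assert [r.year for r in rows] == [2012, 2019]
    for r in rows:
        assert r.n > 0
        assert r.unhealthy_percent == pytest.approx(
            100.0 * r.unhealthy_count / r.n, abs=1e-9)
        assert r.threshold_mean == pytest.approx(r.threshold_total / 5, abs=1e-9)
        assert r.stability_difference > 0
    frame = summaries_to_frame(rows)
    assert list(frame.columns) == [
        "year", "n", "threshold_total", "threshold_mean", "threshold_sd",
        "connectivity", "stability_difference", "unhealthy_count",
        "unhealthy_percent"]


def test_yearly_summary_skips_empty_years(small_panel):
    panel, _ = small_panel
    rows = yearly_summary(panel, years=[2012, 2014])
    assert [r.year for r in rows] == [2012]


def test_lower_thresholds_reduce_stability_difference():
    """A panel whose later years have thresholds raised by 1.0 must show a
    clearly lower stability difference there."""
    params = {2012: (-3.25, 13.0), 2013: (-3.25, 13.0),
              2015: (-2.25, 13.0), 2016: (-2.25, 13.0)}
    cfg = GeneratorConfig(seed=77, n_target=2500,
                          years=tuple(params), year_params=params)
    panel, _ = generate_panel(cfg)
    rows = {r.year: r for r in yearly_summary(panel)}
    assert rows[2015].stability_difference < rows[2012].stability_difference
    assert rows[2016].stability_difference < rows[2013].stability_difference


def test_subgroup_pipeline_reuses_same_code_path(small_panel):
    panel, _ = small_panel
    sub = panel.subset(panel.df["social_support"] == "low")
    rows = yearly_summary(sub, years=[2012])
    assert len(rows) == 1
    assert rows[0].n < len(panel.df[panel.df["year"] == 2012])
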