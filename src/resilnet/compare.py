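"""Per-year resilience summaries and BCa bootstrap contrasts.

The yearly summary reproduces, for each survey year, the resilience
proxies derived from the group-level network: node-threshold total / mean
/ SD, connectivity (sum of edge weights), the stability difference S, and
the point prevalence of mental ill-health.

Change in S between two years is tested with a bias-corrected and
accelerated (BCa) bootstrap: participants are resampled with replacement
independently within each year, the entire pipeline (eLasso fit ->
landscape -> S) is refit per replicate, and the interval for
theta = S_b - S_a is the BCa-adjusted percentile interval. The p-value is
the smallest alpha at which the 1-alpha interval excludes zero
(interval inversion, found by bisection).

Quantiles are computed with linear interpolation (Hyndman-Fan type 7,
numpy's default), so the BCa interval with z0 = 0 and a = 0 reduces
exactly to the percentile interval.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from . import _fast
from .ising import DegenerateNodeError, connectivity, fit_elasso, threshold_summary
from .landscape import activation_landscape, stability_difference
from .panel import (BinarySymptomMatrix, EmptyYearError, FilterRules,
                    SymptomPanel, filter_eligible, prevalence_unhealthy)

log = logging.getLogger(__name__)


@dataclass
class ResilienceSummary:
    """One row of the per-year resilience table."""

    year: int
    n: int
    threshold_total: float
    threshold_mean: float
    threshold_sd: float
    connectivity: float
    stability_difference: float
    unhealthy_count: int
    unhealthy_percent: float


@dataclass
class BootstrapComparison:
    """BCa contrast of stability differences between two years."""

    year_a: int
    year_b: int
    observed_diff: float
    B: int
    z0: float
    accel: float
    ci_low: float
    ci_high: float
    alpha: float
    p_value: float
    seed: int
    n_redraws: int = 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "year_a", "year_b", "observed_diff", "B", "z0", "accel",
            "ci_low", "ci_high", "alpha", "p_value", "seed", "n_redraws")}


def yearly_summary(panel: SymptomPanel, years=None,
                   rules: FilterRules | None = None, gamma: float = 0.25,
                   rule: str = "AND", healthy_max: int = 2) -> list[ResilienceSummary]:
    """Per-year pipeline: filter -> binarize -> eLasso -> landscape -> proxies.

    Years that are empty or have a degenerate (constant) symptom column
    are skipped with a logged warning.
    """
    rules = rules or FilterRules()
    out = []
    for year in (years if years is not None else panel.years):
        try:
            mat = filter_eligible(panel, year, rules)
            net = fit_elasso(mat, gamma=gamma, rule=rule)
            land = activation_landscape(net, healthy_max=healthy_max)
            total, mean, sd = threshold_summary(net)
            count, pct = prevalence_unhealthy(panel, year, rules)
        except (EmptyYearError, DegenerateNodeError) as exc:
            log.warning("skipping year %s: %s", year, exc)
            continue
        out.append(ResilienceSummary(
            year=year, n=mat.n, threshold_total=total, threshold_mean=mean,
            threshold_sd=sd, connectivity=connectivity(net),
            stability_difference=stability_difference(land),
            unhealthy_count=count, unhealthy_percent=pct))
    return out


def summaries_to_frame(summaries):
    """Summary rows as a DataFrame in the reporting column order."""
    import pandas as pd
    cols = ["year", "n", "threshold_total", "threshold_mean", "threshold_sd",
            "connectivity", "stability_difference", "unhealthy_count",
            "unhealthy_percent"]
    return pd.DataFrame([{c: getattr(s, c) for c in cols} for s in summaries],
                        columns=cols)


# ---------------------------------------------------------------------------
# BCa machinery


def _bca_adjusted_levels(boot_stats, observed, jackknife_stats, alpha):
    boot = np.asarray(boot_stats, dtype=float)
    B = boot.size
    below = np.sum(boot < observed) + 0.5 * np.sum(boot == observed)
    frac = below / B
    frac = min(max(frac, 0.5 / B), 1.0 - 0.5 / B)  # keep z0 finite
    z0 = norm.ppf(frac)
    jack = np.asarray(jackknife_stats, dtype=float)
    d = jack.mean() - jack
    denom = np.sum(d * d) ** 1.5
    a = float(np.sum(d ** 3) / (6.0 * denom)) if denom > 0 else 0.0
    levels = []
    for z in (norm.ppf(alpha / 2.0), norm.ppf(1.0 - alpha / 2.0)):
        adj = z0 + (z0 + z) / (1.0 - a * (z0 + z))
        levels.append(float(norm.cdf(adj)))
    return float(z0), a, levels[0], levels[1]


def bca_interval(boot_stats, observed, jackknife_stats,
                 alpha: float = 0.05) -> tuple[float, float]:
    """BCa (1 - alpha) interval from bootstrap and jackknife replicates.

    z0 from the fraction of bootstrap replicates below the observed value
    (ties counted half); acceleration a from the jackknife skewness
    formula; the interval is the empirical type-7 quantile of the
    bootstrap distribution at the adjusted levels.
    """
    boot = np.asarray(boot_stats, dtype=float)
    if boot.size < 2 or np.all(boot == boot[0]):
        warnings.warn("degenerate bootstrap distribution; returning a "
                      "point interval at the observed value", RuntimeWarning,
                      stacklevel=2)
        return float(observed), float(observed)
    _, _, a1, a2 = _bca_adjusted_levels(boot, observed, jackknife_stats, alpha)
    lo = float(np.quantile(boot, a1, method="linear"))
    hi = float(np.quantile(boot, a2, method="linear"))
    return lo, hi


def pvalue_from_bca(boot_stats, observed, jackknife_stats) -> float:
    """Smallest alpha whose (1 - alpha) BCa interval excludes zero.

    Found by bisection on alpha to a resolution of 1e-4; capped at 1.0.
    """
    boot = np.asarray(boot_stats, dtype=float)
    if boot.size < 2 or np.all(boot == boot[0]):
        return 1.0 if observed == 0 else 1e-4

    def excludes_zero(alpha):
        lo, hi = bca_interval(boot, observed, jackknife_stats, alpha)
        return lo > 0.0 or hi < 0.0

    hi_alpha = 1.0 - 1e-6
    if not excludes_zero(hi_alpha):
        return 1.0
    lo_alpha = 1e-6
    if excludes_zero(lo_alpha):
        return 1e-4
    while hi_alpha - lo_alpha > 1e-4:
        mid = 0.5 * (lo_alpha + hi_alpha)
        if excludes_zero(mid):
            hi_alpha = mid
        else:
            lo_alpha = mid
    return min(1.0, 0.5 * (lo_alpha + hi_alpha))


# ---------------------------------------------------------------------------
# Full-pipeline bootstrap for the stability difference


def _as_matrix(x):
    if isinstance(x, BinarySymptomMatrix):
        return x.X, x.year
    arr = np.asarray(x, dtype=np.int8)
    return arr, -1


def _bit_counts(K):
    states = np.arange(1 << K)
    return np.array([[(s >> j) & 1 for j in range(K)] for s in states],
                    dtype=np.int64)


def _degenerate(counts, bits, n):
    active = bits.T @ counts
    return bool(np.any(active == 0) or np.any(active == n))


def _stat_from_counts(counts, K, gamma, rule_and, healthy_max,
                      tol=1e-7, maxiter=50):
    return _fast.stability_difference_counts(
        counts, K, gamma, rule_and, 100, 0.01, tol, maxiter, healthy_max)


def _jackknife_groups(counts, n_groups, rng):
    """Delete-d jackknife: randomly partition participants into groups and
    return the pattern-count vector of each group."""
    n = int(counts.sum())
    n_groups = min(n_groups, n)
    labels = np.repeat(np.arange(counts.size), counts)
    rng.shuffle(labels)
    splits = np.array_split(labels, n_groups)
    return [np.bincount(chunk, minlength=counts.size).astype(np.int64)
            for chunk in splits]


def bootstrap_stability_difference_test(
        panel_a, panel_b, B: int = 1000, alpha: float = 0.05,
        seed: int = 0, gamma: float = 0.25, rule: str = "AND",
        healthy_max: int = 2, n_jackknife_groups: int = 100) -> BootstrapComparison:
    """BCa bootstrap test for a change in stability difference.

    ``panel_a`` / ``panel_b`` are the binary symptom matrices of the two
    years. Participants are resampled with replacement independently
    within each year and the full pipeline is refit per replicate;
    theta* = S_b* - S_a*. A replicate producing a constant symptom column
    is redrawn (counted; more than 10% redraws aborts). Deterministic for
    a fixed seed.

    Resampling participant rows i.i.d. is implemented as a multinomial
    draw over the 2^K pattern counts, which has exactly the same
    distribution and is what makes B in the thousands affordable.
    """
    if B < 200:
        raise ValueError("B must be at least 200")
    Xa, year_a = _as_matrix(panel_a)
    Xb, year_b = _as_matrix(panel_b)
    K = Xa.shape[1]
    if Xb.shape[1] != K:
        raise ValueError("both years must have the same symptom set")
    rule_and = rule == "AND"
    counts_a = _fast.counts_from_matrix(Xa)
    counts_b = _fast.counts_from_matrix(Xb)
    bits = _bit_counts(K)
    n_a, n_b = int(counts_a.sum()), int(counts_b.sum())
    for counts, n, year in ((counts_a, n_a, year_a), (counts_b, n_b, year_b)):
        if _degenerate(counts, bits, n):
            raise DegenerateNodeError(f"year {year} has a constant symptom column")

    s_a = _stat_from_counts(counts_a, K, gamma, rule_and, healthy_max)
    s_b = _stat_from_counts(counts_b, K, gamma, rule_and, healthy_max)
    observed = s_b - s_a

    rng = np.random.default_rng(seed)
    p_a = counts_a / n_a
    p_b = counts_b / n_b
    max_redraws = int(0.10 * B)
    redraws = 0

    def draw(p, n):
        nonlocal redraws
        while True:
            c = rng.multinomial(n, p).astype(np.int64)
            if not _degenerate(c, bits, n):
                return c
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError(
                    "more than 10% of bootstrap replicates had a constant "
                    "symptom column; sample too small for this resolution")

    boot = np.empty(B)
    for b in range(B):
        ca = draw(p_a, n_a)
        cb = draw(p_b, n_b)
        boot[b] = (_stat_from_counts(cb, K, gamma, rule_and, healthy_max)
                   - _stat_from_counts(ca, K, gamma, rule_and, healthy_max))

    # grouped (delete-d) jackknife; groups drawn per year, the other year
    # kept at its full sample when a group is deleted
    jack = []
    for counts, is_year_a in ((counts_a, True), (counts_b, False)):
        for gcounts in _jackknife_groups(counts, n_jackknife_groups, rng):
            reduced = counts - gcounts
            if _degenerate(reduced, bits, int(reduced.sum())):
                continue
            s_red = _stat_from_counts(reduced, K, gamma, rule_and, healthy_max)
            jack.append(s_b - s_red if is_year_a else s_red - s_a)
    jack = np.asarray(jack)

    z0, accel, _, _ = _bca_adjusted_levels(boot, observed, jack, alpha)
    lo, hi = bca_interval(boot, observed, jack, alpha)
    p = pvalue_from_bca(boot, observed, jack)
    return BootstrapComparison(
        year_a=year_a, year_b=year_b, observed_diff=float(observed), B=B,
        z0=float(z0), accel=float(accel), ci_low=lo, ci_high=hi, alpha=alpha,
        p_value=float(p), seed=seed, n_redraws=redraws)
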