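"""Interrupted time-series analysis with logistic random-intercept models.

Binary outcomes (mentally unhealthy, mental healthcare use, medication
use) are modelled on the logit scale as

    logit P(y_it = 1) = x_it' beta + u_i,   u_i ~ Normal(0, sigma^2)

with a participant random intercept u_i. Time is coded t = year -
campaign_start, a post indicator marks years from the campaign start
onward, and the trend change is the t x post interaction (the post main
effect is off by default: the design is a single trend line whose slope
may change at the interruption). A yearly macro-economic confounder
(business-cycle indicator) enters as a standardized covariate. Subgroup
analyses add main effects, subgroup x t, and the differential
trend-change terms subgroup x t x post under reference coding.

The marginal likelihood integrates the random intercept by Gauss-Hermite
quadrature (15 nodes by default, exact for practical purposes at one
random effect), maximized with L-BFGS-B using the analytic gradient;
inference is Wald (z) per coefficient, matching the mixed-model summary
convention. At sigma = 0 the model collapses to ordinary logistic
regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import norm

from .panel import ITEM_COLUMNS, SymptomPanel, UNHEALTHY_CUTOFF

log = logging.getLogger(__name__)

#: canonical reference-first level orders for subgroup factors
SUBGROUP_LEVELS = {
    "gender": ("male", "female"),
    "social_support": ("low", "middle", "high"),
    "urbanicity": ("low", "middle", "high"),
    "migration": ("dutch", "non_dutch_hic", "non_dutch_lmic"),
    "education": (1, 2, 3, 4, 5, 6),
}

OUTCOMES = ("unhealthy", "healthcare_use", "medication_use")


@dataclass
class ITSDesign:
    """Specification of one interrupted time-series model."""

    outcome: str
    window: tuple[int, int] = (2012, 2019)
    campaign_start: int = 2016
    confounder: dict | None = None          # year -> business-cycle value
    subgroup: str | None = None
    include_level_change: bool = False      # adds a post main effect
    min_age: int = 18
    genders: tuple[str, ...] = ("male", "female")


@dataclass
class ModelFrame:
    y: np.ndarray
    X: pd.DataFrame
    groups: np.ndarray          # participant index per row (contiguous blocks)
    n_participants: int
    design: ITSDesign


@dataclass
class ITSResult:
    table: pd.DataFrame         # term, beta, se, z, p
    sigma_u: float
    n_obs: int
    n_participants: int
    converged: bool
    loglik: float

    def coef(self, term: str) -> dict:
        row = self.table.loc[self.table["term"] == term]
        if row.empty:
            raise KeyError(term)
        return row.iloc[0].to_dict()


def _outcome_series(df: pd.DataFrame, outcome: str) -> pd.Series:
    if outcome == "unhealthy":
        items = df[ITEM_COLUMNS]
        complete = items.notna().all(axis=1)
        score = items.sum(axis=1).astype(float) * 4
        out = pd.Series(np.where(score < UNHEALTHY_CUTOFF, 1.0, 0.0),
                        index=df.index)
        out[~complete] = np.nan
        return out
    if outcome not in df.columns:
        raise KeyError(f"unknown outcome {outcome!r}")
    return df[outcome].astype(float)


def build_design(panel: SymptomPanel, design: ITSDesign) -> ModelFrame:
    """Model frame for one ITS fit.

    Keeps eligible adults in the window with a non-missing outcome;
    requires the outcome in at least 2 pre- and 2 post-campaign years and
    a confounder value for every year in the window.
    """
    lo, hi = design.window
    df = panel.df
    mask = (df["year"].between(lo, hi)
            & (df["age"] >= design.min_age)
            & df["gender"].isin(design.genders))
    df = df.loc[mask].copy()
    y = _outcome_series(df, design.outcome)
    df = df.loc[y.notna()]
    y = y.loc[df.index].to_numpy()
    if len(df) == 0:
        raise ValueError(f"no usable observations for {design.outcome!r}")
    if y.min() == y.max():
        raise ValueError(f"outcome {design.outcome!r} is constant "
                         f"({'all 1' if y.min() == 1 else 'all 0'})")
    years = df["year"].to_numpy()
    pre = np.unique(years[years < design.campaign_start])
    post_years = np.unique(years[years >= design.campaign_start])
    if len(pre) < 2 or len(post_years) < 2:
        raise ValueError("need the outcome observed in >= 2 pre and >= 2 "
                         "post campaign years")

    t = (years - design.campaign_start).astype(float)
    post = (years >= design.campaign_start).astype(float)
    X = pd.DataFrame({"const": np.ones(len(df)), "t": t}, index=df.index)
    if design.include_level_change:
        X["post"] = post
    X["t_post"] = t * post
    if design.confounder is not None:
        missing = sorted(set(np.unique(years)) - set(design.confounder))
        if missing:
            raise ValueError(f"confounder missing for years {missing}")
        vals = {yr: design.confounder[yr] for yr in range(lo, hi + 1)
                if yr in design.confounder}
        series = np.array(list(vals.values()), dtype=float)
        sd = series.std()
        if sd > 0:
            mean = series.mean()
            z = {yr: (v - mean) / sd for yr, v in vals.items()}
            X["bct"] = [z[yr] for yr in years]
        else:
            # a constant macro-economic series carries no information;
            # keeping it would only duplicate the intercept
            log.info("confounder is constant over the window; dropped")
    if design.subgroup is not None:
        var = design.subgroup
        levels = SUBGROUP_LEVELS.get(var)
        if levels is None:
            raise KeyError(f"unknown subgroup factor {var!r}")
        obs = df[var]
        keep = obs.isin(levels)
        if not keep.all():
            df = df.loc[keep]
            X = X.loc[keep]
            y = y[keep.to_numpy()]
            obs = obs.loc[keep]
            t = X["t"].to_numpy()
        tp = X["t_post"].to_numpy()
        tt = X["t"].to_numpy()
        for lvl in levels[1:]:
            ind = (obs == lvl).astype(float).to_numpy()
            X[f"{var}[{lvl}]"] = ind
            X[f"{var}[{lvl}]:t"] = ind * tt
            X[f"{var}[{lvl}]:t_post"] = ind * tp

    # contiguous participant blocks for the quadrature
    order = df["participant_id"].to_numpy().argsort(kind="stable")
    X = X.iloc[order].reset_index(drop=True)
    y = y[order]
    pid = df["participant_id"].to_numpy()[order]
    groups = np.unique(pid, return_inverse=True)[1]
    return ModelFrame(y=y, X=X, groups=groups,
                      n_participants=int(groups.max()) + 1, design=design)


# ---------------------------------------------------------------------------
# Gauss-Hermite marginal likelihood


def _prepare_quadrature(n_quad: int):
    zq, wq = hermgauss(n_quad)
    return np.sqrt(2.0) * zq, np.log(wq) - 0.5 * np.log(np.pi)


def _loglik_and_grad(theta, y, X, starts, row_group, zq_s, logw):
    p = X.shape[1]
    beta, sigma = theta[:p], theta[p]
    eta0 = X @ beta
    Eta = eta0[:, None] + sigma * zq_s[None, :]
    ll_rows = y[:, None] * Eta - np.logaddexp(0.0, Eta)
    ll_grp = np.add.reduceat(ll_rows, starts, axis=0) + logw[None, :]
    Li = logsumexp(ll_grp, axis=1)
    loglik = float(Li.sum())
    # posterior weights over quadrature nodes, mapped back to rows
    Wg = np.exp(ll_grp - Li[:, None])
    Wrow = Wg[row_group]
    R = (y[:, None] - expit(Eta)) * Wrow
    grad_beta = X.T @ R.sum(axis=1)
    grad_sigma = float((R * zq_s[None, :]).sum())
    return loglik, np.concatenate([grad_beta, [grad_sigma]])


def fit_its(frame: ModelFrame, n_quad: int = 15,
            start_sigma: float = 0.75) -> ITSResult:
    """Maximum (marginal) likelihood fit of the random-intercept logit model.

    Returns Wald z and two-sided p per fixed-effect term; sigma_u is
    reported in the metadata. A non-converged optimization is flagged,
    never silently returned as converged.
    """
    y = frame.y.astype(float)
    Xdf = frame.X
    X = Xdf.to_numpy(dtype=float)
    groups = frame.groups
    starts = np.flatnonzero(np.r_[1, np.diff(groups)])
    zq_s, logw = _prepare_quadrature(n_quad)

    # ordinary logistic starting values
    import statsmodels.api as sm
    try:
        start_beta = sm.Logit(y, X).fit(disp=0, maxiter=200).params
    except Exception:  # separation etc.; start from zero
        start_beta = np.zeros(X.shape[1])
    theta0 = np.concatenate([start_beta, [start_sigma]])

    def negloglik(theta):
        ll, g = _loglik_and_grad(theta, y, X, starts, groups, zq_s, logw)
        return -ll, -g

    p = X.shape[1]
    bounds = [(None, None)] * p + [(0.0, 25.0)]
    opt = minimize(negloglik, theta0, jac=True, method="L-BFGS-B",
                   bounds=bounds, options={"maxiter": 500, "ftol": 1e-12,
                                           "gtol": 1e-8})
    theta = opt.x
    sigma = float(theta[p])

    # observed information by central differences of the analytic gradient
    at_boundary = sigma < 1e-6
    dim = p if at_boundary else p + 1
    H = np.zeros((dim, dim))
    for j in range(dim):
        h = 1e-5 * (1.0 + abs(theta[j]))
        tp_ = theta.copy(); tp_[j] += h
        tm = theta.copy(); tm[j] -= h
        _, gp = _loglik_and_grad(tp_, y, X, starts, groups, zq_s, logw)
        _, gm = _loglik_and_grad(tm, y, X, starts, groups, zq_s, logw)
        H[j] = (-(gp - gm) / (2.0 * h))[:dim]
    H = 0.5 * (H + H.T)
    converged = bool(opt.success)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.diag(cov)[:p])
        if not np.all(np.isfinite(se)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    beta = theta[:p]
    zstat = beta / se
    pval = 2.0 * norm.sf(np.abs(zstat))
    table = pd.DataFrame({"term": list(Xdf.columns), "beta": beta,
                          "se": se, "z": zstat, "p": pval})
    ll, _ = _loglik_and_grad(theta, y, X, starts, groups, zq_s, logw)
    if not converged:
        log.warning("ITS fit for %r did not converge", frame.design.outcome)
    return ITSResult(table=table, sigma_u=sigma, n_obs=len(y),
                     n_participants=frame.n_participants,
                     converged=converged, loglik=ll)


def trend_change_report(panel: SymptomPanel, outcomes=OUTCOMES,
                        subgroups=("gender", "social_support", "urbanicity",
                                   "education", "migration"),
                        window: tuple[int, int] = (2012, 2019),
                        campaign_start: int = 2016,
                        confounder: dict | None = None,
                        include_level_change: bool = False) -> pd.DataFrame:
    """Trend-change coefficient table across outcomes and subgroup contrasts.

    One row per (outcome, contrast): the overall t x post term of the
    base model, plus every differential subgroup x t x post contrast.
    """
    rows = []
    for outcome in outcomes:
        specs = [None, *subgroups]
        for sub in specs:
            design = ITSDesign(outcome=outcome, window=window,
                               campaign_start=campaign_start,
                               confounder=confounder, subgroup=sub,
                               include_level_change=include_level_change)
            try:
                frame = build_design(panel, design)
                res = fit_its(frame)
            except (ValueError, KeyError) as exc:
                log.warning("skipping %s / %s: %s", outcome, sub, exc)
                continue
            terms = (["t_post"] if sub is None else
                     [c for c in res.table["term"]
                      if c.endswith(":t_post")])
            for term in terms:
                c = res.coef(term)
                rows.append({
                    "outcome": outcome,
                    "contrast": "trend_change" if sub is None else term,
                    "beta": c["beta"], "se": c["se"], "p": c["p"],
                    "window": f"{window[0]}-{window[1]}",
                    "n": res.n_obs, "converged": res.converged,
                })
    return pd.DataFrame(rows, columns=["outcome", "contrast", "beta", "se",
                                       "p", "window", "n", "converged"])
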