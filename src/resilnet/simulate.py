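"""Rotating-panel generator with known truth.

Emulates the structure of a LISS-like yearly internet panel: an Ising
model over five binary anxiety/depression symptoms per survey year
(parameters follow the published yearly trajectory of mean node threshold
and connectivity), ordinal MHI-5 items recovered from the binary states,
~10% yearly attrition with refreshment back to the target size, a survey
year with no questionnaire (2014), sociodemographic covariates with
realistic marginals, and binary healthcare outcomes from logistic models
with configurable trend / trend-change coefficients and participant
random intercepts.

Everything is driven by one master seed; the generating parameters are
returned as a separate truth record so recovery tests can compare
estimates against them.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from . import _fast
from .ising import IsingNetwork
from .landscape import state_distribution
from .panel import (DEFAULT_LABELS, ITEM_COLUMNS, PANEL_COLUMNS,
                    BinarySymptomMatrix, SymptomPanel)

#: yearly (mean node threshold, connectivity) describing the study-period
#: trajectory the generator emulates; 2014 had no questionnaire
DEFAULT_YEAR_PARAMS = {
    2012: (-3.25, 12.9361),
    2013: (-3.37, 13.2731),
    2015: (-3.92, 16.0506),
    2016: (-3.73, 14.7956),
    2017: (-3.72, 14.9121),
    2018: (-3.72, 14.8091),
    2019: (-3.79, 15.3089),
    2020: (-3.79, 15.3687),
    2021: (-3.78, 14.9628),
    2022: (-3.78, 15.2941),
}

#: fixed node-heterogeneity pattern, zero-sum, sample SD 0.97 (the
#: observed between-node threshold spread in the first study year)
TAU_HETEROGENEITY = tuple(0.97 / np.sqrt(2.5) * np.array([-2, -1, 0, 1, 2]))


@dataclass
class OutcomeModel:
    """Logit-scale coefficients of one binary outcome process."""

    intercept: float
    t: float = 0.0
    t_post: float = 0.0
    confounder: float = 0.0
    sigma_u: float = 1.0
    #: differential trend change: (covariate, level) -> extra t x post coef
    contrasts: dict = field(default_factory=dict)


def default_outcome_models() -> dict:
    return {
        "healthcare_use": OutcomeModel(
            intercept=-2.2, t=-0.02, t_post=0.0, confounder=-0.10,
            sigma_u=1.2,
            contrasts={("social_support", "middle"): -0.31,
                       ("migration", "non_dutch_lmic"): 0.67}),
        "medication_use": OutcomeModel(
            intercept=-2.6, t=0.0, t_post=-0.31, confounder=-0.10,
            sigma_u=1.2),
    }


@dataclass
class GeneratorConfig:
    """All generating parameters of the synthetic rotating panel."""

    seed: int | None = None
    years: tuple[int, ...] = tuple(sorted(DEFAULT_YEAR_PARAMS))
    n_target: int = 5000
    attrition: float = 0.10
    year_params: dict = field(default_factory=lambda: dict(DEFAULT_YEAR_PARAMS))
    tau_heterogeneity: tuple[float, ...] = TAU_HETEROGENEITY
    #: additive threshold shift by experienced social support
    support_tau_shift: dict = field(default_factory=lambda: {
        "low": 0.5, "middle": 0.0, "high": -0.5})
    active_threshold: int = 2
    record_missing_rate: float = 0.05
    item_missing_rate: float = 0.005
    minor_age_rate: float = 0.02      # 16-17 year olds, filtered downstream
    gender_probs: dict = field(default_factory=lambda: {
        "male": 0.454, "female": 0.546})
    other_gender_rate_2022: float = 0.0035
    education_probs: dict = field(default_factory=lambda: {
        1: 0.076, 2: 0.201, 3: 0.134, 4: 0.234, 5: 0.238, 6: 0.117})
    support_probs: dict = field(default_factory=lambda: {
        "low": 0.233, "middle": 0.591, "high": 0.176})
    urbanicity_probs: dict = field(default_factory=lambda: {
        "low": 0.347, "middle": 0.216, "high": 0.437})
    migration_probs: dict = field(default_factory=lambda: {
        "dutch": 0.820, "non_dutch_hic": 0.088, "non_dutch_lmic": 0.092})
    campaign_start: int = 2016
    outcome_models: dict = field(default_factory=default_outcome_models)
    confounder_phi: float = 0.7
    confounder_sigma: float = 1.0

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("an explicit master seed is required")
        if not 0.0 <= self.attrition < 1.0:
            raise ValueError("attrition must lie in [0, 1)")
        if self.n_target < 1:
            raise ValueError("n_target must be >= 1")
        missing = [y for y in self.years if y not in self.year_params]
        if missing:
            raise ValueError(f"no Ising parameters for years {missing}")
        for probs in (self.gender_probs, self.education_probs,
                      self.support_probs, self.urbanicity_probs,
                      self.migration_probs):
            if abs(sum(probs.values()) - 1.0) > 1e-8:
                raise ValueError("covariate probabilities must sum to 1")

    def network_for(self, year: int, support: str | None = None) -> IsingNetwork:
        """Generating network of a year (optionally support-shifted)."""
        mean_tau, conn = self.year_params[year]
        tau = mean_tau + np.asarray(self.tau_heterogeneity, dtype=float)
        if support is not None:
            tau = tau + self.support_tau_shift[support]
        K = tau.size
        w = conn / (K * (K - 1) / 2)
        W = np.full((K, K), w) - w * np.eye(K)
        return IsingNetwork(labels=DEFAULT_LABELS, W=W, tau=tau,
                            meta={"year": year, "support": support,
                                  "generator": True})


def generate_business_cycle(years, phi: float = 0.7, sigma: float = 1.0,
                            seed=None) -> dict:
    """Stationary zero-mean AR(1) business-cycle stand-in, one value per year.

    The first value is drawn from the stationary distribution, so the
    long-run variance is sigma^2 / (1 - phi^2).
    """
    if not abs(phi) < 1:
        raise ValueError("require |phi| < 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    years = list(years)
    if sigma == 0.0:
        return {int(y): 0.0 for y in years}
    x = rng.normal(0.0, sigma / np.sqrt(1.0 - phi * phi))
    out = {}
    for y in years:
        out[int(y)] = float(x)
        x = phi * x + rng.normal(0.0, sigma)
    return out


def sample_ising_exact(net: IsingNetwork, n: int, seed=None) -> BinarySymptomMatrix:
    """n i.i.d. draws from the exact Boltzmann distribution (no burn-in)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = state_distribution(net)
    states = rng.choice(probs.size, size=n, p=probs)
    X = (states[:, None] >> np.arange(net.K)[None, :]) & 1
    return BinarySymptomMatrix(year=int(net.meta.get("year", 0)),
                               labels=net.labels, X=X.astype(np.int8))


def sample_ising_gibbs(net: IsingNetwork, n: int, burn_in: int = 1000,
                       thin: int = 10, seed=None) -> BinarySymptomMatrix:
    """Single-site Gibbs sampler with conditional
    P(x_i = 1 | rest) = sigmoid(tau_i + sum_j W_ij x_j)."""
    if burn_in < 0 or thin < 1:
        raise ValueError("require burn_in >= 0 and thin >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random((burn_in + n * thin) * net.K)
    X = _fast.gibbs_sample(net.tau, net.W, n, burn_in, thin, u)
    return BinarySymptomMatrix(year=int(net.meta.get("year", 0)),
                               labels=net.labels, X=X)


def actives_to_items(flags, seed=None) -> np.ndarray:
    """Ordinal MHI-5 items consistent with symptom-activity flags.

    Active symptoms draw an item score uniformly from {0, 1, 2}, inactive
    from {3, 4, 5}; binarizing at the default threshold of 2 recovers the
    flags exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flags = np.asarray(flags, dtype=np.int8)
    low = rng.integers(0, 3, size=flags.shape)
    high = rng.integers(3, 6, size=flags.shape)
    return np.where(flags == 1, low, high).astype(np.int64)


def _item_sum_pmf(k: int, K: int = 5) -> np.ndarray:
    """Exact pmf of the MHI-5 item sum given k active symptoms under the
    band mapping (active ~ U{0,1,2}, inactive ~ U{3,4,5})."""
    pmf = np.array([1.0])
    for _ in range(k):
        pmf = np.convolve(pmf, np.ones(3) / 3.0)          # support 0..2
    for _ in range(K - k):
        block = np.zeros(6)
        block[3:] = 1.0 / 3.0                             # support 3..5
        pmf = np.convolve(pmf, block)
    return pmf


def exact_unhealthy_probability(config: GeneratorConfig, year: int) -> float:
    """Marginal P(MHI-5 score < 60) implied by the generator for a year,
    by exact enumeration over the support-level mixture of Ising models
    and the item-band mapping (score < 60 <=> item sum < 15)."""
    from . import _fast
    total = 0.0
    for lvl, pi in config.support_probs.items():
        net = config.network_for(year, lvl)
        Pn = _fast.activation_probabilities(net.tau, net.W)
        for k, pk in enumerate(Pn):
            q_unhealthy = _item_sum_pmf(k)[:15].sum()
            total += pi * pk * q_unhealthy
    return float(total)


def _draw_categorical(rng, probs: dict, size: int):
    keys = list(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    idx = rng.choice(len(keys), size=size, p=p / p.sum())
    return np.array(keys, dtype=object)[idx]


def generate_panel(config: GeneratorConfig) -> tuple[SymptomPanel, dict]:
    """Simulate the rotating panel and return (panel, truth record).

    Participants enter with baseline covariates and per-outcome random
    intercepts; each calendar year they survive with probability
    1 - attrition (applied per elapsed year, also across the missing
    survey year); refreshment restores the target size. Symptoms are
    drawn from that year's (support-shifted) Ising model, items from the
    band mapping, outcomes from the configured logistic models.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    years = sorted(config.years)
    cal_years = range(min(years), max(years) + 1)
    confounder = generate_business_cycle(
        cal_years, config.confounder_phi, config.confounder_sigma, rng)

    outcome_names = list(config.outcome_models)
    # per-participant storage, appended as participants enter
    pid, hid, entry_year, age_at_entry = [], [], [], []
    gender, education, support, urban, migration = [], [], [], [], []
    rand_intercepts = {o: [] for o in outcome_names}

    def recruit(m: int, year: int) -> np.ndarray:
        start = len(pid)
        for i in range(m):
            k = start + i
            pid.append(f"P{k + 1:06d}")
            hid.append(f"H{k + 1:06d}")
            entry_year.append(year)
        minor = rng.random(m) < config.minor_age_rate
        ages = np.clip(np.round(rng.normal(46, 18, size=m)), 18, 94)
        ages[minor] = rng.integers(16, 18, size=int(minor.sum()))
        age_at_entry.extend(int(a) for a in ages)
        g = _draw_categorical(rng, config.gender_probs, m)
        if year == 2022 and config.other_gender_rate_2022 > 0:
            g[rng.random(m) < config.other_gender_rate_2022] = "other"
        gender.extend(g)
        education.extend(_draw_categorical(rng, config.education_probs, m))
        support.extend(_draw_categorical(rng, config.support_probs, m))
        urban.extend(_draw_categorical(rng, config.urbanicity_probs, m))
        migration.extend(_draw_categorical(rng, config.migration_probs, m))
        for o in outcome_names:
            s = config.outcome_models[o].sigma_u
            rand_intercepts[o].extend(rng.normal(0.0, s, size=m))
        return np.arange(start, start + m)

    rows = []
    active = np.array([], dtype=int)
    prev_year = None
    support_levels = list(config.support_tau_shift)
    for year in years:
        if prev_year is None:
            active = recruit(config.n_target, year)
        else:
            gap = year - prev_year
            keep = rng.random(active.size) < (1.0 - config.attrition) ** gap
            active = active[keep]
            deficit = config.n_target - active.size
            if deficit > 0:
                active = np.concatenate([active, recruit(deficit, year)])
        prev_year = year

        m = active.size
        sup = np.array([support[i] for i in active], dtype=object)
        states = np.zeros(m, dtype=np.int64)
        for lvl in support_levels:
            sel = np.flatnonzero(sup == lvl)
            if sel.size == 0:
                continue
            probs = state_distribution(config.network_for(year, lvl))
            states[sel] = rng.choice(probs.size, size=sel.size, p=probs)
        flags = ((states[:, None] >> np.arange(5)[None, :]) & 1).astype(np.int8)
        items = actives_to_items(flags, rng).astype(float)
        # missingness: whole questionnaire, then stray single items
        rec_miss = rng.random(m) < config.record_missing_rate
        items[rec_miss] = np.nan
        item_miss = rng.random(items.shape) < config.item_missing_rate
        items[item_miss] = np.nan

        t = float(year - config.campaign_start)
        post = 1.0 if year >= config.campaign_start else 0.0
        conf = confounder[year]
        outs = {}
        for o in outcome_names:
            mdl = config.outcome_models[o]
            eta = (mdl.intercept + mdl.t * t + mdl.t_post * t * post
                   + mdl.confounder * conf
                   + np.array([rand_intercepts[o][i] for i in active]))
            for (var, lvl), coef in mdl.contrasts.items():
                vals = {"social_support": support, "urbanicity": urban,
                        "migration": migration, "gender": gender,
                        "education": education}[var]
                ind = np.array([1.0 if vals[i] == lvl else 0.0 for i in active])
                eta = eta + coef * ind * t * post
            outs[o] = (rng.random(m) < expit(eta)).astype(int)

        year_cols = {
            "participant_id": np.array([pid[i] for i in active], dtype=object),
            "household_id": np.array([hid[i] for i in active], dtype=object),
            "year": np.full(m, year),
            "gender": np.array([gender[i] for i in active], dtype=object),
            "age": np.array([age_at_entry[i] + (year - entry_year[i])
                             for i in active]),
            "education": np.array([education[i] for i in active], dtype=object),
            "social_support": sup,
            "urbanicity": np.array([urban[i] for i in active], dtype=object),
            "migration": np.array([migration[i] for i in active], dtype=object),
        }
        for c, col in enumerate(ITEM_COLUMNS):
            year_cols[col] = items[:, c]
        for o in ("healthcare_use", "medication_use"):
            year_cols[o] = (outs[o].astype(float) if o in outs
                            else np.full(m, np.nan))
        rows.append(pd.DataFrame(year_cols))

    df = pd.concat(rows, ignore_index=True)[PANEL_COLUMNS]
    for col in [*ITEM_COLUMNS, "healthcare_use", "medication_use"]:
        df[col] = df[col].round().astype("Int64")
    df["education"] = df["education"].astype(int)
    df["age"] = df["age"].astype(int)
    df["year"] = df["year"].astype(int)
    window = (min(years), max(years))
    missing = tuple(y for y in cal_years if y not in years)
    panel = SymptomPanel(df, study_window=window, missing_years=missing)

    truth = {
        "seed": config.seed,
        "years": years,
        "year_params": {int(y): list(config.year_params[y]) for y in years},
        "tau_by_year": {int(y): config.network_for(y).tau.tolist() for y in years},
        "W_first_year": config.network_for(years[0]).W.tolist(),
        "tau_heterogeneity": list(config.tau_heterogeneity),
        "support_tau_shift": dict(config.support_tau_shift),
        "attrition": config.attrition,
        "n_target": config.n_target,
        "campaign_start": config.campaign_start,
        "confounder": {int(k): v for k, v in confounder.items()},
        "confounder_phi": config.confounder_phi,
        "confounder_sigma": config.confounder_sigma,
        "outcome_models": {
            o: {**{k: v for k, v in asdict(m).items() if k != "contrasts"},
                "contrasts": {f"{var}:{lvl}": c
                              for (var, lvl), c in m.contrasts.items()}}
            for o, m in config.outcome_models.items()},
    }
    return panel, copy.deepcopy(truth)
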