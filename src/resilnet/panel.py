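"""MHI-5 panel data model: scoring, binarization and eligibility filtering.

The panel is a long-format table with one row per participant-year. The
five MHI-5 items are scored 0-5 in the favourable direction (higher =
better mental health; positively-worded items are assumed already
reverse-coded). The sum score is rescaled to 0-100 and a score below 60
classifies a record as mentally unhealthy. Missing items are never
imputed; records with incomplete items are dropped listwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ITEM_COLUMNS = ["mhi1", "mhi2", "mhi3", "mhi4", "mhi5"]
DEFAULT_LABELS = tuple(ITEM_COLUMNS)

#: columns of the long-format panel CSV, in canonical order
PANEL_COLUMNS = [
    "participant_id", "household_id", "year",
    *ITEM_COLUMNS,
    "gender", "age", "education", "social_support", "urbanicity",
    "migration", "healthcare_use", "medication_use",
]

GENDER_LEVELS = ("male", "female", "other")
SUPPORT_LEVELS = ("low", "middle", "high")
URBANICITY_LEVELS = ("low", "middle", "high")
MIGRATION_LEVELS = ("dutch", "non_dutch_hic", "non_dutch_lmic")

#: number of active symptoms from which a state counts as unhealthy is
#: handled in :mod:`resilnet.landscape`; here the item-level rule:
DEFAULT_ACTIVE_THRESHOLD = 2
UNHEALTHY_CUTOFF = 60


class EmptyYearError(ValueError):
    """Raised when a survey year has no eligible records."""


@dataclass
class SymptomPanel:
    """Long-format participant-year panel.

    Parameters
    ----------
    df : DataFrame with :data:`PANEL_COLUMNS`.
    study_window : (first, last) calendar year covered by the study.
    missing_years : survey years in the window with no questionnaire
        (by default 2014, which was not administered).
    """

    df: pd.DataFrame
    study_window: tuple[int, int] = (2012, 2022)
    missing_years: tuple[int, ...] = (2014,)

    def __post_init__(self) -> None:
        missing_cols = [c for c in PANEL_COLUMNS if c not in self.df.columns]
        if missing_cols:
            raise ValueError(f"panel is missing columns {missing_cols}")
        dup = self.df.duplicated(subset=["participant_id", "year"])
        if dup.any():
            raise ValueError("duplicate (participant_id, year) records")
        years = self.df["year"].to_numpy()
        lo, hi = self.study_window
        if len(years) and (years.min() < lo or years.max() > hi):
            raise ValueError("records outside the study window")
        if np.isin(years, self.missing_years).any():
            raise ValueError(
                f"records present in missing survey years {self.missing_years}")
        items = self.df[ITEM_COLUMNS].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = np.nan_to_num(items, nan=0.0)
            if ((bad < 0) | (bad > 5)).any():
                raise ValueError("MHI-5 items must lie in 0..5")
        if (self.df["age"].to_numpy() < 0).any():
            raise ValueError("age must be nonnegative")

    @property
    def years(self) -> list[int]:
        """Survey years present in the data, sorted."""
        return sorted(self.df["year"].unique().tolist())

    def subset(self, mask: pd.Series) -> "SymptomPanel":
        """New panel restricted to rows where ``mask`` is True."""
        return SymptomPanel(self.df.loc[mask].reset_index(drop=True),
                            self.study_window, self.missing_years)


@dataclass
class BinarySymptomMatrix:
    """Complete-case binary symptom data for one survey year.

    ``X[i, j] = 1`` means symptom j is active for participant i.
    """

    year: int
    labels: tuple[str, ...]
    X: np.ndarray
    ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.X = np.ascontiguousarray(np.asarray(self.X, dtype=np.int8))
        if self.X.ndim != 2 or self.X.shape[1] != len(self.labels):
            raise ValueError("X must be n x K with K == len(labels)")
        if self.X.size and not np.isin(self.X, (0, 1)).all():
            raise ValueError("X entries must be 0/1")
        if self.X.shape[0] < 1:
            raise EmptyYearError(f"no records in year {self.year}")

    @property
    def n(self) -> int:
        return self.X.shape[0]


def score_mhi5(items: Sequence[float]) -> float:
    """MHI-5 sum score rescaled to 0-100 (sum of five 0-5 items times 4).

    Returns NaN when any item is missing; such records are excluded
    downstream rather than imputed.
    """
    arr = np.asarray(items, dtype=float)
    if arr.shape != (5,):
        raise ValueError("expected exactly five items")
    if np.isnan(arr).any():
        return float("nan")
    if ((arr < 0) | (arr > 5)).any():
        raise ValueError("items must lie in 0..5")
    return float(arr.sum() * 4)


def classify_unhealthy(score: float) -> int:
    """1 (mentally unhealthy) iff the 0-100 score is strictly below 60."""
    if not 0 <= score <= 100:
        raise ValueError("score must lie in [0, 100]")
    return int(score < UNHEALTHY_CUTOFF)


def binarize_items(items: Sequence[float],
                   active_threshold: int = DEFAULT_ACTIVE_THRESHOLD) -> np.ndarray:
    """Symptom-activity flags: active iff favourable item score <= threshold.

    The default threshold of 2 mirrors the 60% sum-score convention (a
    favourable score below 3/5 of the item scale marks the symptom as
    present).
    """
    arr = np.asarray(items, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("cannot binarize incomplete items; exclude the record")
    return (arr <= active_threshold).astype(np.int8)


@dataclass
class FilterRules:
    """Eligibility rules applied before network estimation."""

    min_age: int = 18
    genders: tuple[str, ...] = ("male", "female")
    active_threshold: int = DEFAULT_ACTIVE_THRESHOLD


def _eligible_mask(df: pd.DataFrame, rules: FilterRules) -> tuple[pd.Series, dict]:
    age_ok = df["age"] >= rules.min_age
    gender_ok = df["gender"].isin(rules.genders)
    complete = df[ITEM_COLUMNS].notna().all(axis=1)
    exclusions = {
        "age_below_minimum": int((~age_ok).sum()),
        "gender_excluded": int((age_ok & ~gender_ok).sum()),
        "incomplete_items": int((age_ok & gender_ok & ~complete).sum()),
    }
    return age_ok & gender_ok & complete, exclusions


def filter_eligible(panel: SymptomPanel, year: int,
                    rules: FilterRules | None = None) -> BinarySymptomMatrix:
    """Eligible complete cases for one year, binarized to symptom activity.

    Applies age >= 18, the configured gender set, and listwise deletion of
    records with any missing MHI-5 item; logs counts excluded per rule.
    """
    rules = rules or FilterRules()
    sub = panel.df[panel.df["year"] == year]
    if sub.empty:
        raise EmptyYearError(f"no records for year {year}")
    mask, exclusions = _eligible_mask(sub, rules)
    log.info("year %d eligibility: kept %d of %d, excluded %s",
             year, int(mask.sum()), len(sub), exclusions)
    kept = sub.loc[mask]
    if kept.empty:
        raise EmptyYearError(f"no eligible records for year {year}")
    items = kept[ITEM_COLUMNS].to_numpy(dtype=float)
    X = (items <= rules.active_threshold).astype(np.int8)
    return BinarySymptomMatrix(year=year, labels=DEFAULT_LABELS, X=X,
                               ids=tuple(kept["participant_id"].astype(str)))


def prevalence_unhealthy(panel: SymptomPanel, year: int,
                         rules: FilterRules | None = None) -> tuple[int, float]:
    """(count, percent) mentally unhealthy (score < 60) among eligible
    completers in the given year."""
    rules = rules or FilterRules()
    sub = panel.df[panel.df["year"] == year]
    if sub.empty:
        raise EmptyYearError(f"no records for year {year}")
    mask, _ = _eligible_mask(sub, rules)
    kept = sub.loc[mask]
    if kept.empty:
        raise EmptyYearError(f"no eligible records for year {year}")
    scores = kept[ITEM_COLUMNS].to_numpy(dtype=float).sum(axis=1) * 4
    count = int((scores < UNHEALTHY_CUTOFF).sum())
    return count, 100.0 * count / len(kept)


_INT_COLUMNS = [*ITEM_COLUMNS, "healthcare_use", "medication_use"]


def read_panel_csv(path, study_window: tuple[int, int] = (2012, 2022),
                   missing_years: tuple[int, ...] = (2014,)) -> SymptomPanel:
    """Read a long-format panel CSV (UTF-8, header row, empty cell =
    missing, ``#`` comment lines allowed)."""
    df = pd.read_csv(path, comment="#", dtype={
        "participant_id": str, "household_id": str})
    for col in _INT_COLUMNS:
        df[col] = df[col].astype("Int64")
    df["year"] = df["year"].astype(int)
    df["age"] = df["age"].astype(int)
    df["education"] = df["education"].astype(int)
    return SymptomPanel(df[PANEL_COLUMNS], study_window, missing_years)


def write_binary_matrix_csv(mat: BinarySymptomMatrix, path,
                            header_lines: Iterable[str] = ()) -> None:
    """Write one year's filtered binary symptom matrix (id + 0/1 flags)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("participant_id," + ",".join(mat.labels) + "\n")
        ids = mat.ids or [str(i) for i in range(mat.n)]
        for pid, row in zip(ids, mat.X):
            fh.write(pid + "," + ",".join(str(int(v)) for v in row) + "\n")


def write_panel_csv(panel: SymptomPanel, path, header_lines: Iterable[str] = ()) -> None:
    """Write a panel in the same dialect `read_panel_csv` expects."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        panel.df.to_csv(fh, index=False)
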