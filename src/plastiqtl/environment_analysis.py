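"""Grain-filling weather summaries, trait-weather correlations, and grading.

Meteorological factors are summarised over the first ``window_days`` days
after full heading (default 15): means of daily minimum / maximum / average
temperature, diurnal range and solar radiation, plus accumulated rainfall and
the count of rainy days — a rainy day being one with strictly more than 1 mm
of rainfall.  Quality traits are related to the factors with Spearman's rank
correlation (mid-ranks for ties, two-sided t approximation).  Records are
graded against a user-supplied rule table; no national-standard thresholds
are built in — a documented toy rule ships for tests and examples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError, ParameterError

logger = logging.getLogger(__name__)

RAINY_DAY_MM = 1.0      # strictly more than this much rain makes a rainy day

FACTOR_NAMES = ("tmin_mean", "tmax_mean", "tavg_mean", "diurnal_mean",
                "solar_mean", "rain_total", "rainy_days")

#: default significance tiers for correlation heat-map stars
#: (two-tier convention: ** below 1e-3, *** below 1e-4)
STAR_TIERS = ((1e-4, "***"), (1e-3, "**"))


# ---------------------------------------------------------------------------
# window summaries
# ---------------------------------------------------------------------------

def window_factors(met: pd.DataFrame, headings: pd.DataFrame,
                   window_days: int = 15) -> pd.DataFrame:
    """Summarise weather over [heading, heading + window_days) per record.

    ``headings`` needs columns location_id, sowing_index, heading_date (one
    row per location x sowing).  Missing days inside a window raise
    :class:`DataError` listing the gaps.
    """
    if window_days < 1:
        raise ParameterError("window_days must be >= 1")
    met = met.copy()
    met["date"] = pd.to_datetime(met["date"])
    out = []
    for _, row in headings.iterrows():
        loc = row["location_id"]
        start = pd.to_datetime(row["heading_date"])
        days = pd.date_range(start, periods=window_days, freq="D")
        sub = met[(met["location_id"] == loc) & met["date"].isin(days)]
        if len(sub) < window_days:
            missing = sorted(set(days) - set(sub["date"]))
            raise DataError(
                f"meteorology gaps for {loc} window starting {start.date()}: "
                f"{[d.date().isoformat() for d in missing[:5]]}")
        out.append({
            "location_id": loc, "sowing_index": row["sowing_index"],
            "tmin_mean": sub["tmin"].mean(), "tmax_mean": sub["tmax"].mean(),
            "tavg_mean": sub["tavg"].mean(),
            "diurnal_mean": sub["diurnal_range"].mean(),
            "solar_mean": sub["solar"].mean(),
            "rain_total": sub["rainfall"].sum(),
            "rainy_days": int((sub["rainfall"] > RAINY_DAY_MM).sum()),
        })
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def spearman(x, y) -> tuple[float, float]:
    """Spearman's rho with mid-ranks and the two-sided t approximation.

    Pairs with a missing value on either side are dropped; fewer than three
    complete pairs is an error; zero rank variance returns (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise DataError(f"need >= 3 complete pairs, got {x.size}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return float("nan"), float("nan")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, p


def correlate_traits_factors(pheno: pd.DataFrame, factors: pd.DataFrame,
                             star_tiers=STAR_TIERS) -> pd.DataFrame:
    """Per-location Spearman correlations of each trait with each factor.

    Factor values are shared by every hybrid of a (location, sowing); the
    correlation runs across all records of the location.
    """
    merged = pheno.merge(factors, on=["location_id", "sowing_index"],
                         how="inner")
    rows = []
    for (loc, trait), grp in merged.groupby(["location_id", "trait_name"]):
        for fac in FACTOR_NAMES:
            try:
                rho, p = spearman(grp["value"], grp[fac])
            except DataError:
                rho, p = np.nan, np.nan
            star = ""
            for cut, sym in sorted(star_tiers):
                if np.isfinite(p) and p < cut:
                    star = sym
                    break
            rows.append({"location_id": loc, "trait_name": trait,
                         "factor": fac, "rho": rho, "p": p, "star": star})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# grading
# ---------------------------------------------------------------------------

@dataclass
class GradeRule:
    """Per-trait graded thresholds.

    ``thresholds[trait] = (direction, [t1, t2, t3, ...])`` assigns grade k
    (1 = best) when ``value <= t_k`` (direction "le") or ``value >= t_k``
    (direction "ge"); thresholds must be monotone along the grade ordering.
    A value passing no band gets ``worst_grade`` = len(thresholds) + 1.
    The overall record grade is the worst per-trait grade.
    """

    thresholds: dict[str, tuple[str, list[float]]]

    def __post_init__(self):
        for trait, (direction, cuts) in self.thresholds.items():
            if direction not in ("le", "ge"):
                raise ParameterError(f"{trait}: direction must be 'le' or 'ge'")
            diffs = np.diff(cuts)
            if direction == "le" and (diffs < 0).any():
                raise ParameterError(f"{trait}: 'le' thresholds must be "
                                     "non-decreasing from best to worst grade")
            if direction == "ge" and (diffs > 0).any():
                raise ParameterError(f"{trait}: 'ge' thresholds must be "
                                     "non-increasing from best to worst grade")

    def trait_grade(self, trait: str, value: float) -> int:
        direction, cuts = self.thresholds[trait]
        for k, cut in enumerate(cuts, start=1):
            if (direction == "le" and value <= cut) or \
               (direction == "ge" and value >= cut):
                return k
        return len(cuts) + 1

    @classmethod
    def from_dict(cls, d: dict) -> "GradeRule":
        return cls(thresholds={t: (v["direction"], list(v["thresholds"]))
                               for t, v in d.items()})


#: synthetic example rule for tests and demos (not a national standard)
TOY_GRADE_RULE = GradeRule(thresholds={
    "CD": ("le", [2.0, 5.0, 8.0]),
    "PGWC": ("le", [10.0, 20.0, 30.0]),
    "MRR": ("ge", [68.0, 64.0, 60.0]),
})


def grade_records(pheno: pd.DataFrame, rule: GradeRule,
                  good_grade: int = 3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Grade every (hybrid, location, sowing) record; count good records.

    Returns ``(grades, counts)`` where ``grades`` holds one row per record
    with its per-rule worst grade (NaN + flag when a referenced trait is
    missing), and ``counts`` aggregates records at grade <= ``good_grade``
    per location x sowing.
    """
    traits = list(rule.thresholds)
    wide = pheno.pivot_table(index=["hybrid_id", "location_id", "sowing_index"],
                             columns="trait_name", values="value",
                             aggfunc="first")
    rows = []
    for key, rec in wide.iterrows():
        missing = [t for t in traits if t not in rec.index or pd.isna(rec.get(t))]
        if missing:
            rows.append({"hybrid_id": key[0], "location_id": key[1],
                         "sowing_index": key[2], "grade": np.nan,
                         "ungraded": True})
            continue
        grade = max(rule.trait_grade(t, float(rec[t])) for t in traits)
        rows.append({"hybrid_id": key[0], "location_id": key[1],
                     "sowing_index": key[2], "grade": grade,
                     "ungraded": False})
    grades = pd.DataFrame(
        rows, columns=["hybrid_id", "location_id", "sowing_index",
                       "grade", "ungraded"])
    if grades.empty:
        counts = pd.DataFrame(columns=["location_id", "sowing_index", "n_good"])
    else:
        good = grades.assign(n_good=(grades["grade"] <= good_grade)
                             .fillna(False).astype(int))
        counts = good.groupby(["location_id", "sowing_index"], as_index=False)[
            "n_good"].sum()
    n_ungraded = int(grades["ungraded"].sum()) if not grades.empty else 0
    if n_ungraded:
        logger.warning("grade_records: %d records lacked a referenced trait",
                       n_ungraded)
    return grades, counts
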