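"""Longitudinal measurement handling and derived obesity traits.

Traits handled here: body weight (BW, kg), crown-to-rump length (CRL, cm),
waist circumference (WC, cm) and BMI (kg/m^2, computed per visit as
BW / (CRL/100)^2).  Obesity is defined on WC (upper 20th percentile of colony
measures, or a fixed 40.5 cm threshold), chronic obesity as three or more
consecutive obese measures after excluding visits flagged as pregnant.  Adult
traits are the means of all measures from the age of stable adult size
(5 years) onward.  Diet-exposure cohorts are assigned from the calendar
overlap between an intervention-diet era and each individual's gestation
(165 days pre-birth) or postnatal windows (PN1 birth-2 y, PN2 2-5 y, adult
5 y+).  Pre-analysis transforms (rank-based inverse-normal, age adjustment)
live here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .pedigree import Pedigree

__all__ = [
    "ADULT_AGE",
    "OBESITY_WC_CM",
    "GESTATION_DAYS",
    "compute_bmi",
    "obesity_threshold",
    "flag_chronic_obesity",
    "adult_trait_means",
    "assign_diet_exposure",
    "inverse_normal_transform",
    "regress_out_age",
    "adult_trait_table",
]

ADULT_AGE = 5.0  # years; age of stable adult size
OBESITY_WC_CM = 40.5  # fixed waist-circumference obesity cut-off
OBESITY_PERCENTILE = 80.0
GESTATION_DAYS = 165

MEASUREMENT_COLUMNS = ["id", "date", "age", "bw", "crl", "wc", "pregnant"]


def compute_bmi(bw, crl):
    """BMI in kg/m^2 from body weight (kg) and crown-to-rump length (cm)."""
    bw = np.asarray(bw, dtype=float)
    crl = np.asarray(crl, dtype=float)
    if np.any(bw <= 0) or np.any(crl <= 0):
        raise ValueError("bw and crl must be strictly positive")
    return bw / (crl / 100.0) ** 2


def obesity_threshold(wc_values, percentile: float = OBESITY_PERCENTILE, fixed: bool = False) -> float:
    """Waist-circumference obesity cut-off (cm).

    Empirical ``percentile`` (default 80th, i.e. the upper 20th percentile)
    of the supplied adult non-pregnant WC values, using the linear-
    interpolation ("type 7") quantile convention.  With ``fixed=True`` the
    canonical 40.5 cm cut-off is returned regardless of the data.  A warning
    is emitted when the empirical value strays more than 10% from 40.5 cm.
    """
    if fixed:
        return OBESITY_WC_CM
    vals = np.asarray(pd.Series(wc_values).dropna(), dtype=float)
    if vals.size < 5:
        raise ValueError(f"need >= 5 WC values to estimate a threshold, got {vals.size}")
    thr = float(np.percentile(vals, percentile))  # numpy default = linear/type 7
    if abs(thr - OBESITY_WC_CM) > 0.10 * OBESITY_WC_CM:
        warnings.warn(
            f"empirical WC threshold {thr:.1f} cm differs >10% from the fixed 40.5 cm cut-off",
            stacklevel=2,
        )
    return thr


def flag_chronic_obesity(series: pd.DataFrame, threshold: float, min_run: int = 3) -> bool:
    """True iff some run of >= min_run consecutive retained measures has wc > threshold.

    ``series`` is a per-individual measurement frame sorted by date with
    columns ``wc`` and ``pregnant``; pregnant-flagged visits are removed
    before runs are counted, so a pregnancy interrupting an obese streak does
    not reset it.  Comparison is strict (> threshold).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if "date" in series.columns:
        d = pd.to_datetime(series["date"])
        if not d.is_monotonic_increasing:
            raise ValueError("measurement series must be sorted by date")
    retained = series.loc[~series["pregnant"].astype(bool), "wc"].to_numpy(dtype=float)
    run = 0
    for v in retained:
        if np.isfinite(v) and v > threshold:
            run += 1
            if run >= min_run:
                return True
        else:
            run = 0
    return False


@dataclass(frozen=True)
class AdultTraitRecord:
    id: str
    mean_age: float
    mean_bw: float
    mean_crl: float
    mean_wc: float
    mean_bmi: float
    n_measures: int
    chronic_obese: bool


def adult_trait_means(
    series: pd.DataFrame,
    adult_age: float = ADULT_AGE,
    wc_threshold: float = OBESITY_WC_CM,
    exclude_pregnant: bool = True,
    bmi_per_visit: bool = True,
) -> AdultTraitRecord:
    """Average adult (age >= adult_age) traits for one individual.

    Pregnant-flagged visits are excluded from the WC and BW means (CRL, a
    skeletal measure, is retained).  BMI is by default computed per visit
    where BW and CRL co-occur and then averaged; ``bmi_per_visit=False``
    instead forms it from the averaged BW and CRL.
    """
    adult = series.loc[np.asarray(series["age"], dtype=float) >= adult_age]
    if adult.empty:
        raise ValueError("no measures at or beyond the adult age threshold")
    preg = adult["pregnant"].astype(bool) if exclude_pregnant else pd.Series(False, index=adult.index)
    nonpreg = adult.loc[~preg]
    bw = nonpreg["bw"].astype(float)
    wc = nonpreg["wc"].astype(float)
    crl = adult["crl"].astype(float)
    bmi_rows = nonpreg.loc[nonpreg["bw"].notna() & nonpreg["crl"].notna()]
    if bmi_per_visit:
        mean_bmi = float(np.mean(compute_bmi(bmi_rows["bw"], bmi_rows["crl"]))) if len(bmi_rows) else np.nan
    else:
        mean_bmi = float(compute_bmi(bw.mean(), crl.mean())) if bw.notna().any() and crl.notna().any() else np.nan
    return AdultTraitRecord(
        id=str(adult["id"].iloc[0]),
        mean_age=float(adult["age"].astype(float).mean()),
        mean_bw=float(bw.mean()),
        mean_crl=float(crl.mean()),
        mean_wc=float(wc.mean()),
        mean_bmi=mean_bmi,
        n_measures=int(len(adult)),
        chronic_obese=flag_chronic_obesity(adult.sort_values("age"), wc_threshold)
        if "wc" in adult
        else False,
    )


@dataclass(frozen=True)
class DietExposure:
    id: str
    maternal_diet_gestation: str  # "Standard" or "ID"
    id_intro_period: str  # gestation | PN1 | PN2 | adult | never


def assign_diet_exposure(
    ped: Pedigree,
    id_interval: tuple[date, date],
    gestation_days: int = GESTATION_DAYS,
    as_of: date | None = None,
) -> dict[str, DietExposure]:
    """Assign each pedigree member a single diet-exposure cohort.

    The first window (gestation = [birth-165 d, birth], then PN1 = [birth,
    birth+2 y), PN2 = [birth+2 y, birth+5 y), adult = [birth+5 y, inf)) that
    overlaps the intervention-diet interval defines the cohort; individuals
    whose windows never overlap it are "never".
    """
    start, end = id_interval
    if start >= end:
        raise ValueError("id_interval must satisfy start < end")
    out: dict[str, DietExposure] = {}
    for ind in ped.individuals:
        if ind.birth_date is None:
            raise ValueError(f"individual {ind.id!r} has no birth date")
        b = ind.birth_date
        windows = [
            ("gestation", b - timedelta(days=gestation_days), b),
            ("PN1", b, _add_years(b, 2)),
            ("PN2", _add_years(b, 2), _add_years(b, 5)),
            ("adult", _add_years(b, 5), as_of or date.max),
        ]
        period = "never"
        for name, w0, w1 in windows:
            if w0 <= end and w1 >= start and w0 < w1:
                period = name
                break
        out[ind.id] = DietExposure(
            id=ind.id,
            maternal_diet_gestation="ID" if period == "gestation" else "Standard",
            id_intro_period=period,
        )
    return out


def _add_years(d: date, years: int) -> date:
    return d + timedelta(days=round(years * 365.25))


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse-normal transform, z_i = Probit((r_i - 0.5)/n).

    Average ranks on ties; NaNs are passed through.  Used to correct residual
    kurtosis in traits before variance-component analysis.
    """
    x = np.asarray(values, dtype=float)
    out = np.full_like(x, np.nan)
    mask = np.isfinite(x)
    v = x[mask]
    if v.size < 3:
        raise ValueError("need >= 3 non-missing values")
    if np.ptp(v) == 0:
        raise ValueError("all values identical; transform undefined")
    ranks = stats.rankdata(v, method="average")
    out[mask] = stats.norm.ppf((ranks - 0.5) / v.size)
    return out


def regress_out_age(trait, age) -> np.ndarray:
    """OLS residuals of trait on intercept + age (pairwise non-missing)."""
    y = np.asarray(trait, dtype=float)
    a = np.asarray(age, dtype=float)
    mask = np.isfinite(y) & np.isfinite(a)
    if mask.sum() < 3:
        raise ValueError("need >= 3 matched non-missing pairs")
    if np.ptp(a[mask]) == 0:
        raise ValueError("age is constant; cannot adjust")
    res = sm.OLS(y[mask], sm.add_constant(a[mask])).fit()
    out = np.full_like(y, np.nan)
    out[mask] = res.resid
    return out


def adult_trait_table(
    measurements: pd.DataFrame,
    adult_age: float = ADULT_AGE,
    wc_threshold: float | None = None,
    min_measures: int = 1,
) -> pd.DataFrame:
    """Per-individual adult trait means for a long-format measurement table.

    If ``wc_threshold`` is None, the empirical upper-20th-percentile
    threshold is computed from all adult non-pregnant WC measures.
    """
    m = measurements.copy()
    m["age"] = m["age"].astype(float)
    adult = m[m["age"] >= adult_age]
    if wc_threshold is None:
        pool = adult.loc[~adult["pregnant"].astype(bool), "wc"].dropna()
        wc_threshold = obesity_threshold(pool) if len(pool) >= 5 else OBESITY_WC_CM
    rows = []
    for _, grp in adult.groupby("id", sort=True):
        if len(grp) < min_measures:
            continue
        grp = grp.sort_values("age")
        rec = adult_trait_means(grp, adult_age=adult_age, wc_threshold=wc_threshold)
        rows.append(rec.__dict__)
    return pd.DataFrame(rows)
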