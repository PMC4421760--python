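"""Monthly multi-site panel construction.

Long-term exposure at a monitor-month is the average of daily PM2.5 over the
365 days ending the day before the month's first day.  Exposures are then
centered within location (x*_ij = x_ij - x̄_i), so the level-1 slope measures
the association of month-to-month mortality variation with month-to-month
variation in previous-year exposure, and x̄_i is carried as a site-level
covariate.  Site-level explanatory variables (constituents, community
confounders, x̄_i) are standardized across locations to mean 0, SD 1 so
second-level coefficients read as effects per 1-SD increase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONSTITUENTS = ["ec", "ocm", "so4", "si", "no3", "na"]
CONFOUNDERS = ["income", "hs", "urban", "white", "black"]


@dataclass
class PanelRecord:
    """One monitor-month: deaths, population at risk, previous-year exposure."""

    location_id: str
    month_index: int
    deaths: int
    at_risk: int
    exposure: float
    exposure_centered: float = float("nan")


@dataclass
class CovariateProfile:
    """Site-level covariates: six constituents, five confounders, mean exposure.

    ``observed`` flags mark which constituent entries are measured rather than
    imputed.  Standardized copies (``constituents_std`` etc.) are filled by
    :func:`standardize_covariates`.
    """

    location_id: str
    constituents: np.ndarray  # (6,) μg/m³
    confounders: np.ndarray  # (5,) mixed units
    exposure_mean: float  # μg/m³
    observed: np.ndarray = field(default_factory=lambda: np.ones(6, dtype=bool))
    constituents_std: np.ndarray | None = None
    confounders_std: np.ndarray | None = None
    exposure_mean_std: float | None = None


def previous_year_average(
    daily_series: pd.Series,
    month_starts: list | pd.DatetimeIndex,
    min_coverage: float = 0.5,
) -> list[tuple[pd.Timestamp, float]]:
    """Previous-1-year average exposure at each month start.

    ``daily_series`` is indexed by date.  For month start ``m`` the window is
    the 365 calendar days ending the day before ``m``; the month is emitted
    only when at least ``min_coverage`` of those days have values.
    """
    if not isinstance(daily_series.index, pd.DatetimeIndex):
        daily_series = pd.Series(
            daily_series.to_numpy(), index=pd.to_datetime(daily_series.index)
        )
    if daily_series.index.has_duplicates:
        raise ValueError("daily series has duplicate dates")
    daily_series = daily_series.sort_index().dropna()
    out = []
    for m in pd.to_datetime(pd.Index(month_starts)):
        lo = m - pd.Timedelta(days=365)
        window = daily_series.loc[lo : m - pd.Timedelta(days=1)]
        if len(window) / 365.0 >= min_coverage and len(window) > 0:
            out.append((m, float(window.mean())))
    return out


def center_within_location(panel: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Fill ``exposure_centered`` = exposure − location mean; return the means x̄_i.

    Raises on any location with fewer than two records (slope unidentifiable).
    """
    counts = panel.groupby("location_id").size()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"locations with < 2 records cannot be centered: {bad}")
    panel = panel.copy()
    means = panel.groupby("location_id")["exposure"].mean()
    panel["exposure_centered"] = panel["exposure"] - panel["location_id"].map(means)
    return panel, means.rename("exposure_mean")


def standardize_covariates(
    profiles: list[CovariateProfile],
) -> tuple[list[CovariateProfile], pd.DataFrame]:
    """Standardize constituent, confounder and x̄ columns across locations.

    Each column becomes mean 0, SD 1 (denominator n−1).  Returns the profiles
    with standardized fields filled plus a constants table (column, mean, sd)
    for back-transformation of effects onto the per-1-SD scale.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 locations to standardize")
    z = np.array([p.constituents for p in profiles], dtype=float)
    w = np.array([p.confounders for p in profiles], dtype=float)
    xb = np.array([p.exposure_mean for p in profiles], dtype=float)
    cols = CONSTITUENTS + CONFOUNDERS + ["exposure_mean"]
    mat = np.column_stack([z, w, xb])
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    for name, s in zip(cols, sd):
        if s == 0 or not np.isfinite(s):
            raise ValueError(f"column {name!r} is constant; cannot standardize")
    std = (mat - mu) / sd
    for i, p in enumerate(profiles):
        p.constituents_std = std[i, :6].copy()
        p.confounders_std = std[i, 6:11].copy()
        p.exposure_mean_std = float(std[i, 11])
    constants = pd.DataFrame({"column": cols, "mean": mu, "sd": sd})
    return profiles, constants


def profiles_to_frame(profiles: list[CovariateProfile]) -> pd.DataFrame:
    """Covariate profiles as a flat DataFrame (raw columns plus observed mask)."""
    rows = []
    for p in profiles:
        row = {"location_id": p.location_id}
        row.update(dict(zip(CONSTITUENTS, p.constituents)))
        row.update(dict(zip(CONFOUNDERS, p.confounders)))
        row["exposure_mean"] = p.exposure_mean
        row["observed_mask"] = "".join("1" if o else "0" for o in p.observed)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_profiles(df: pd.DataFrame) -> list[CovariateProfile]:
    """Inverse of :func:`profiles_to_frame`."""
    profiles = []
    for _, r in df.iterrows():
        # CSV round-trips may coerce the mask to int and drop leading zeros
        mask = str(r.get("observed_mask", "1" * len(CONSTITUENTS))).zfill(len(CONSTITUENTS))
        profiles.append(
            CovariateProfile(
                location_id=str(r["location_id"]),
                constituents=np.array([r[c] for c in CONSTITUENTS], dtype=float),
                confounders=np.array([r[c] for c in CONFOUNDERS], dtype=float),
                exposure_mean=float(r["exposure_mean"]),
                observed=np.array([ch == "1" for ch in str(mask)], dtype=bool),
            )
        )
    return profiles
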