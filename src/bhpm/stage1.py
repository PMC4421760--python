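"""Level-1 estimation: per-location Poisson regression of monthly deaths.

For each monitoring location i the model is

    Y_ij ~ Poisson(lambda_ij),  log(lambda_ij) = log(N_ij) + a_i0 + a_i1 x*_ij,

with Y deaths, N population at risk (offset with fixed coefficient 1) and
x* the within-location-centered previous-year exposure.  a_i0 is the log
baseline mortality rate at the location's average exposure; a_i1 the log
rate ratio per 1 μg/m³.  The MLE is found by Newton iteration; the inverse
observed information supplies the 2x2 sampling covariance that the second
stage treats as known.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)


@dataclass
class Stage1Estimate:
    """Per-location (a0_hat, a1_hat) with sampling covariance."""

    location_id: str
    alpha0_hat: float
    alpha1_hat: float
    vcov: np.ndarray  # (2, 2)
    n_months: int
    converged: bool


def poisson_loglik(alpha0: float, alpha1: float, records: pd.DataFrame) -> float:
    """Poisson log-likelihood of one location's monthly records.

    ``records`` needs columns deaths, at_risk, exposure_centered.
    """
    y = records["deaths"].to_numpy(dtype=float)
    n = records["at_risk"].to_numpy(dtype=float)
    x = records["exposure_centered"].to_numpy(dtype=float)
    eta = np.log(n) + alpha0 + alpha1 * x
    return float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1.0)))


def fit_location(
    records: pd.DataFrame,
    *,
    max_iter: int = 60,
    grad_tol: float = 1e-10,
    location_id: str | None = None,
) -> Stage1Estimate:
    """Maximum-likelihood (a0, a1) for one location by safeguarded Newton steps.

    Degenerate locations (all-zero deaths, or centered exposure with no
    variation) are returned with ``converged=False`` and an infinite-variance
    covariance so downstream stages can exclude them.
    """
    loc = location_id or str(records["location_id"].iloc[0])
    y = records["deaths"].to_numpy(dtype=float)
    n = records["at_risk"].to_numpy(dtype=float)
    x = records["exposure_centered"].to_numpy(dtype=float)
    m = len(y)
    bad = np.full((2, 2), np.inf)
    if m < 2 or y.sum() == 0 or np.ptp(x) < 1e-12:
        return Stage1Estimate(loc, float("nan"), float("nan"), bad, m, False)

    a = np.array([np.log(y.sum() / n.sum()), 0.0])
    logn = np.log(n)

    def loglik(a_):
        eta = logn + a_[0] + a_[1] * x
        return np.sum(y * eta - np.exp(eta))

    ll = loglik(a)
    converged = False
    for _ in range(max_iter):
        mu = np.exp(logn + a[0] + a[1] * x)
        g = np.array([np.sum(y - mu), np.sum((y - mu) * x)])
        if np.linalg.norm(g) < grad_tol * max(1.0, y.sum()):
            converged = True
            break
        s0, s1, s2 = mu.sum(), (mu * x).sum(), (mu * x * x).sum()
        H = np.array([[s0, s1], [s1, s2]])
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        # halve the Newton step until the log-likelihood does not decrease
        # (tolerance relative to |loglik| so float noise cannot stall the search)
        tol = 1e-9 * max(1.0, abs(ll))
        t = 1.0
        for _ in range(40):
            a_new = a + t * step
            ll_new = loglik(a_new)
            if ll_new >= ll - tol:
                break
            t *= 0.5
        else:
            break
        a, ll = a_new, ll_new
    mu = np.exp(logn + a[0] + a[1] * x)
    g = np.array([np.sum(y - mu), np.sum((y - mu) * x)])
    converged = bool(np.linalg.norm(g) < 1e-8 * max(1.0, y.sum()))
    s0, s1, s2 = mu.sum(), (mu * x).sum(), (mu * x * x).sum()
    H = np.array([[s0, s1], [s1, s2]])
    det = s0 * s2 - s1 * s1
    vcov = np.array([[s2, -s1], [-s1, s0]]) / det if det > 0 else bad
    return Stage1Estimate(loc, float(a[0]), float(a[1]), vcov, m, converged)


def fit_all_locations(panel: pd.DataFrame, *, min_months: int = 6) -> list[Stage1Estimate]:
    """Fit every location in a centered panel, ordered by location_id.

    Locations with fewer than ``min_months`` records are flagged unconverged
    rather than fitted; failures never abort the batch.
    """
    out = []
    for loc, grp in sorted(panel.groupby("location_id"), key=lambda kv: kv[0]):
        if len(grp) < min_months:
            out.append(
                Stage1Estimate(str(loc), float("nan"), float("nan"), np.full((2, 2), np.inf), len(grp), False)
            )
            logger.warning("location %s has %d < %d months; skipped", loc, len(grp), min_months)
            continue
        est = fit_location(grp, location_id=str(loc))
        if not est.converged:
            logger.warning("location %s did not converge", loc)
        out.append(est)
    return out


def estimates_to_frame(estimates: list[Stage1Estimate]) -> pd.DataFrame:
    """Stage-1 estimates as a DataFrame (var00, var01, var11 flatten the vcov)."""
    return pd.DataFrame(
        {
            "location_id": [e.location_id for e in estimates],
            "alpha0_hat": [e.alpha0_hat for e in estimates],
            "alpha1_hat": [e.alpha1_hat for e in estimates],
            "var00": [e.vcov[0, 0] for e in estimates],
            "var01": [e.vcov[0, 1] for e in estimates],
            "var11": [e.vcov[1, 1] for e in estimates],
            "n_months": [e.n_months for e in estimates],
            "converged": [e.converged for e in estimates],
        }
    )


def frame_to_estimates(df: pd.DataFrame) -> list[Stage1Estimate]:
    """Inverse of :func:`estimates_to_frame`."""
    return [
        Stage1Estimate(
            str(r.location_id),
            float(r.alpha0_hat),
            float(r.alpha1_hat),
            np.array([[r.var00, r.var01], [r.var01, r.var11]]),
            int(r.n_months),
            bool(r.converged),
        )
        for r in df.itertuples()
    ]
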