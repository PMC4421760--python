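"""Synthetic multi-site mortality studies with known truth.

Generates complete studies with the statistical structure the hierarchical
analysis assumes: monitor locations in a geographic box, spatially
correlated constituent surfaces (exponential-covariance Gaussian processes
calibrated so correlation at ~40 miles matches values typical of eastern-US
speciation networks), correlated community confounders, slowly varying
previous-year exposure series, and Poisson death counts driven by the
two-level model run forward.  Defaults mirror an eastern-US Medicare
monitoring study: 518 sites, 33-70 monthly records each, ~14,500 people at
risk and ~4.5 deaths/month/1,000 per site.

The default bounding box is sized so that a uniform draw reproduces the
linkage geometry of the real networks (about half of 518 mass monitors
within 6 miles of one of 174 speciation monitors), i.e. the network's
effective density rather than its full geographic extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geo import pairwise_distances
from .gp import exponential_covariance
from .panel import CONSTITUENTS, CONFOUNDERS, CovariateProfile, center_within_location, standardize_covariates
from .stage2 import ModelSpec, build_design

#: lon_min, lon_max, lat_min, lat_max — mid-Atlantic box of ~31,500 sq miles
DEFAULT_BBOX = (-80.0, -76.8, 36.0, 38.56)

#: (mean, total SD, correlation at 40 miles) per constituent, μg/m³
CONSTITUENT_FIELDS = {
    "ec": (0.68, 0.24, 0.05),
    "ocm": (4.05, 0.90, 0.20),
    "so4": (4.14, 0.80, 0.21),
    "si": (0.09, 0.03, 0.19),
    "no3": (1.68, 0.85, 0.21),
    "na": (0.17, 0.07, 0.20),
}

CONFOUNDER_MEANS = np.array([40305.0, 0.79, 0.86, 0.70, 0.19])
CONFOUNDER_SDS = np.array([12461.0, 0.08, 0.23, 0.20, 0.17])
# pairwise correlations reported for the real community covariates
CONFOUNDER_CORR_PAIRS = {("income", "hs"): 0.62, ("hs", "white"): 0.50, ("white", "black"): -0.84}


@dataclass(frozen=True)
class GPHyperparams:
    """Exponential-covariance field parameters: mean, sill, decay (1/mile), nugget."""

    mean: float
    sill: float
    decay: float
    nugget: float = 0.0

    def __post_init__(self) -> None:
        if self.sill < 0 or self.nugget < 0 or self.decay <= 0:
            raise ValueError("require sill >= 0, nugget >= 0, decay > 0")

    def correlation_at(self, d: float) -> float:
        """Implied correlation between two sites at distance d miles."""
        return self.sill * np.exp(-self.decay * d) / (self.sill + self.nugget)


def calibrated_gp_params(
    mean: float, total_sd: float, corr_at_40: float, nugget_fraction: float = 0.05
) -> GPHyperparams:
    """Field params with a given total SD and 40-mile correlation.

    The nugget takes ``nugget_fraction`` of the total variance and the decay
    solves sill/(sill+nugget) * exp(-40 phi) = corr_at_40.
    """
    var = total_sd**2
    nugget = nugget_fraction * var
    sill = var - nugget
    ratio = corr_at_40 * var / sill
    if not 0 < ratio < 1:
        raise ValueError("corr_at_40 incompatible with nugget fraction")
    decay = -np.log(ratio) / 40.0
    return GPHyperparams(mean=mean, sill=sill, decay=decay, nugget=nugget)


def _default_gp_params() -> dict[str, GPHyperparams]:
    return {
        name: calibrated_gp_params(m, sd, c40)
        for name, (m, sd, c40) in CONSTITUENT_FIELDS.items()
    }


def _default_beta() -> np.ndarray:
    # const, ec, ocm, so4, si, no3, na, income, hs, urban, white, black, exposure_mean
    return np.array(
        [np.log(0.0045), 0.013, 0.0, 0.0, 0.014, 0.012, 0.0,
         -0.03, -0.02, 0.01, -0.02, 0.015, 0.02]
    )


def _default_gamma() -> np.ndarray:
    # const, ec, ocm, so4, si, no3, na, income, hs, urban, white, black
    return np.array(
        [0.008, 0.0, 0.0, 0.004, 0.0, 0.0, 0.003, 0.0, 0.0, 0.0, 0.0, 0.0]
    )


@dataclass
class SimulationTruth:
    """Known parameter values driving a synthetic study.

    ``beta`` (13) and ``gamma`` (12) are on the standardized-covariate scale
    of the second-level equations; the standardization is taken over the
    realized sample so the generative model matches the fitted one exactly.
    """

    beta: np.ndarray = field(default_factory=_default_beta)
    gamma: np.ndarray = field(default_factory=_default_gamma)
    sigma_eps0: float = 0.05
    sigma_eps1: float = 0.004
    gp_params: dict = field(default_factory=_default_gp_params)
    n_locations: int = 518
    months_range: tuple[int, int] = (33, 70)
    bbox: tuple[float, float, float, float] = DEFAULT_BBOX
    exposure_mean: float = 13.7
    exposure_sd: float = 2.13
    exposure_month_sd: float = 1.0
    exposure_ar1: float = 0.9
    population_log_mean: float = 9.207  # lognormal: mean ~14,500, SD ~15,500
    population_log_sd: float = 0.868
    seed: int = 0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.beta.shape != (13,) or self.gamma.shape != (12,):
            raise ValueError("beta must have 13 entries and gamma 12")
        if self.sigma_eps0 <= 0 or self.sigma_eps1 <= 0:
            raise ValueError("error SDs must be positive")
        lo, hi = self.months_range
        if not (2 <= lo <= hi):
            raise ValueError("invalid months_range")


@dataclass
class SimulatedStudy:
    """A complete synthetic study with its generating truth attached."""

    panel: pd.DataFrame  # location_id, month_index, deaths, at_risk, exposure, exposure_centered
    profiles: list[CovariateProfile]  # standardized, all observed
    coords: pd.DataFrame  # location_id, lon, lat
    truth: SimulationTruth
    alpha0: np.ndarray  # true SV intercepts
    alpha1: np.ndarray  # true SV slopes
    scaling: pd.DataFrame  # standardization constants used in generation


def simulate_locations(
    n: int, bbox: tuple[float, float, float, float] = DEFAULT_BBOX, seed: int = 0
) -> pd.DataFrame:
    """Uniform monitor locations in a lon/lat box; ids loc0001, loc0002, ..."""
    if n < 2:
        raise ValueError("need at least 2 locations")
    lon_min, lon_max, lat_min, lat_max = bbox
    if lon_min >= lon_max or lat_min >= lat_max:
        raise ValueError(f"degenerate bbox {bbox}")
    rng = np.random.default_rng(seed)
    lon = rng.uniform(lon_min, lon_max, size=n)
    lat = rng.uniform(lat_min, lat_max, size=n)
    width = max(4, len(str(n)))
    ids = [f"loc{str(i + 1).zfill(width)}" for i in range(n)]
    return pd.DataFrame({"location_id": ids, "lon": lon, "lat": lat})


def simulate_gp_field(
    coords: np.ndarray, params: GPHyperparams, seed: int = 0, *, planar: bool = False
) -> np.ndarray:
    """One draw of a GP with covariance sill*exp(-decay d) + nugget*I."""
    coords = np.asarray(coords, dtype=float)
    rng = np.random.default_rng(seed)
    n = coords.shape[0]
    if params.sill == 0.0 and params.nugget == 0.0:
        return np.full(n, params.mean)
    dist = pairwise_distances(coords, planar=planar)
    cov = exponential_covariance(dist, params.sill, params.decay, params.nugget)
    cov[np.diag_indices_from(cov)] += 1e-10 * max(params.sill + params.nugget, 1.0)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "field covariance not positive definite even after jitter"
        ) from exc
    return params.mean + L @ rng.standard_normal(n)


def _confounder_correlation() -> np.ndarray:
    corr = np.eye(5)
    idx = {name: k for k, name in enumerate(CONFOUNDERS)}
    for (a, b), r in CONFOUNDER_CORR_PAIRS.items():
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    # project to the nearest positive-definite correlation matrix
    w, v = np.linalg.eigh(corr)
    w = np.maximum(w, 1e-6)
    corr = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(corr))
    return corr / np.outer(d, d)


def simulate_study(truth: SimulationTruth | None = None) -> SimulatedStudy:
    """Run the two-level generative model forward with known truth.

    Constituent surfaces are GP draws; confounders a correlated multivariate
    normal; exposures a site mean plus AR(1) monthly deviations; site
    effects follow the second-level regressions with Gaussian errors; deaths
    are Poisson with the population-at-risk offset.
    """
    truth = truth or SimulationTruth()
    root = np.random.SeedSequence(truth.seed)
    keys = root.spawn(8)
    n = truth.n_locations

    coords = simulate_locations(n, truth.bbox, seed=keys[0])
    xy = coords[["lon", "lat"]].to_numpy()

    field_keys = keys[1].spawn(len(CONSTITUENTS))
    z = np.column_stack(
        [
            simulate_gp_field(xy, truth.gp_params[name], seed=field_keys[k])
            for k, name in enumerate(CONSTITUENTS)
        ]
    )

    rng_conf = np.random.default_rng(keys[2])
    corr = _confounder_correlation()
    Lc = np.linalg.cholesky(corr)
    w = CONFOUNDER_MEANS + (rng_conf.standard_normal((n, 5)) @ Lc.T) * CONFOUNDER_SDS
    # proportions clipped to [0.01, 0.99]; income floored at a nominal minimum
    w[:, 1:] = np.clip(w[:, 1:], 0.01, 0.99)
    w[:, 0] = np.maximum(w[:, 0], 5000.0)

    rng_exp = np.random.default_rng(keys[3])
    rng_months = np.random.default_rng(keys[4])
    rng_pop = np.random.default_rng(keys[5])
    rng_eps = np.random.default_rng(keys[6])
    rng_y = np.random.default_rng(keys[7])

    lo, hi = truth.months_range
    n_months = rng_months.integers(lo, hi + 1, size=n)
    site_mean = rng_exp.normal(truth.exposure_mean, truth.exposure_sd, size=n)
    site_mean = np.maximum(site_mean, 2.0)
    pop = np.maximum(
        np.round(rng_pop.lognormal(truth.population_log_mean, truth.population_log_sd, size=n)),
        500.0,
    )

    rows = []
    exposures = []
    rho = truth.exposure_ar1
    innov_sd = truth.exposure_month_sd * np.sqrt(1.0 - rho**2)
    for i in range(n):
        m = int(n_months[i])
        dev = np.empty(m)
        dev[0] = rng_exp.normal(0.0, truth.exposure_month_sd)
        for j in range(1, m):
            dev[j] = rho * dev[j - 1] + rng_exp.normal(0.0, innov_sd)
        x = np.maximum(site_mean[i] + dev, 0.5)
        exposures.append(x)
        for j in range(m):
            rows.append((coords["location_id"].iloc[i], j + 1, int(pop[i]), x[j]))
    panel = pd.DataFrame(rows, columns=["location_id", "month_index", "at_risk", "exposure"])
    panel, xbar = center_within_location(panel)

    profiles = [
        CovariateProfile(
            location_id=coords["location_id"].iloc[i],
            constituents=z[i].copy(),
            confounders=w[i].copy(),
            exposure_mean=float(xbar[coords["location_id"].iloc[i]]),
        )
        for i in range(n)
    ]
    profiles, scaling = standardize_covariates(profiles)

    X0, X1, _, _ = build_design(profiles, ModelSpec("both", False))
    eps0 = rng_eps.normal(0.0, truth.sigma_eps0, size=n)
    eps1 = rng_eps.normal(0.0, truth.sigma_eps1, size=n)
    alpha0 = X0 @ truth.beta + eps0
    alpha1 = X1 @ truth.gamma + eps1

    a0 = panel["location_id"].map(dict(zip(coords["location_id"], alpha0))).to_numpy()
    a1 = panel["location_id"].map(dict(zip(coords["location_id"], alpha1))).to_numpy()
    log_lam = np.log(panel["at_risk"].to_numpy(dtype=float)) + a0 + a1 * panel[
        "exposure_centered"
    ].to_numpy()
    if np.any(log_lam > 25.0):
        raise ValueError(
            "Poisson mean overflow: expected counts exceed e^25; use smaller coefficients"
        )
    panel["deaths"] = rng_y.poisson(np.exp(log_lam))
    panel = panel[
        ["location_id", "month_index", "deaths", "at_risk", "exposure", "exposure_centered"]
    ]
    return SimulatedStudy(panel, profiles, coords, truth, alpha0, alpha1, scaling)


def mask_constituents(
    profiles: list[CovariateProfile], fraction: float, seed: int = 0
) -> tuple[list[CovariateProfile], np.ndarray]:
    """Clear observed flags (and values) at round(fraction*n) random locations.

    Emulates a speciation network sparser than the mass network: a masked
    monitor loses all six constituents.  Returns the masked copies and the
    index array of masked locations.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    n = len(profiles)
    k = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    masked_idx = np.sort(rng.choice(n, size=k, replace=False))
    masked = set(masked_idx.tolist())
    out = []
    for i, p in enumerate(profiles):
        q = CovariateProfile(
            location_id=p.location_id,
            constituents=p.constituents.copy(),
            confounders=p.confounders.copy(),
            exposure_mean=p.exposure_mean,
            observed=p.observed.copy(),
        )
        if i in masked:
            q.constituents[:] = np.nan
            q.observed[:] = False
        out.append(q)
    return out, masked_idx


def truth_to_dict(truth: SimulationTruth) -> dict:
    """JSON-serializable dump of a truth object."""
    return {
        "beta": truth.beta.tolist(),
        "gamma": truth.gamma.tolist(),
        "sigma_eps0": truth.sigma_eps0,
        "sigma_eps1": truth.sigma_eps1,
        "gp_params": {
            k: {"mean": v.mean, "sill": v.sill, "decay": v.decay, "nugget": v.nugget}
            for k, v in truth.gp_params.items()
        },
        "n_locations": truth.n_locations,
        "months_range": list(truth.months_range),
        "bbox": list(truth.bbox),
        "seed": truth.seed,
    }
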