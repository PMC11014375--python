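"""Semi-variogram estimation, model fitting and the range-selection rules.

The empirical semi-variogram is computed with the Matheron estimator

    γ̂(h) = Σ_{(i,j) in bin(h)} (z_i − z_j)² / (2 N(h)),

over equal-width lag bins; bins with fewer than ``min_pairs`` point pairs
(default 30) are dropped as unreliable. Three model families — spherical,
exponential and Gaussian — are fitted by weighted least squares on
(nugget, partial sill, range), and two selection rules turn twelve monthly
fits into a single spatial admissibility threshold: per month keep the fit
with the lowest nugget, then across months take the smallest range. Pairs
farther apart than that range are treated as spatially uncorrelated, so the
range is the minimum distance a new training sample must keep from the
labeled set to be spatially informative.

All families use the *effective range* parameterization (factor 3 inside the
exponential/Gaussian), so ``range_m`` is the distance at which the model
reaches ~95% of the sill for every family and ranges are comparable across
families.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist

FAMILIES = ("spherical", "exponential", "gaussian")


class EstimationError(ValueError):
    """Raised when an empirical variogram cannot support model fitting."""


class FittingError(RuntimeError):
    """Raised when no optimizer start converges."""


@dataclass(frozen=True)
class VariogramEstimate:
    """Empirical semi-variance per retained lag bin."""

    lag_centers: tuple  # m, strictly increasing
    gamma: tuple  # semi-variance per lag (dimensionless²)
    pair_counts: tuple  # pairs per lag, each ≥ min_pairs
    max_lag: float
    min_pairs: int = 30

    def __post_init__(self):
        object.__setattr__(self, "lag_centers", tuple(float(v) for v in self.lag_centers))
        object.__setattr__(self, "gamma", tuple(float(v) for v in self.gamma))
        object.__setattr__(self, "pair_counts", tuple(int(v) for v in self.pair_counts))
        lags = np.asarray(self.lag_centers)
        if np.any(np.diff(lags) <= 0):
            raise ValueError("lag_centers must be strictly increasing")
        if any(g < 0 for g in self.gamma):
            raise ValueError("semi-variance must be non-negative")
        if any(c < self.min_pairs for c in self.pair_counts):
            raise ValueError("retained bins must satisfy the pair-count minimum")

    def __len__(self) -> int:
        return len(self.lag_centers)


@dataclass(frozen=True)
class VariogramModel:
    """A fitted (or specified) semi-variogram model.

    ``sill = nugget + partial_sill``; γ(0⁺) → nugget; γ(h) → sill as h → ∞
    (reached exactly at h = range for the spherical family).
    """

    family: str
    nugget: float
    partial_sill: float
    range_m: float
    sserr: float = 0.0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.nugget < 0 or self.partial_sill < 0 or self.sserr < 0:
            raise ValueError("nugget, partial_sill and sserr must be non-negative")
        if self.range_m <= 0:
            raise ValueError("range_m must be positive")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def __call__(self, h):
        return model_semivariance(self, h)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "nugget": self.nugget,
            "partial_sill": self.partial_sill,
            "range_m": self.range_m,
            "sserr": self.sserr,
        }


def model_semivariance(model: VariogramModel, h):
    """Model semi-variance γ(h) for scalar or array lag distance h ≥ 0.

    γ(0) is reported as the nugget (limit-from-above convention: zero-distance
    pairs are excluded from estimation, so the discontinuity at the origin is
    resolved toward the nugget).
    """
    h_arr = np.asarray(h, dtype=float)
    if np.any(h_arr < 0):
        raise ValueError("lag distance must be non-negative")
    a, ps, n0 = model.range_m, model.partial_sill, model.nugget
    r = h_arr / a
    if model.family == "spherical":
        struct = np.where(r <= 1.0, 1.5 * r - 0.5 * r**3, 1.0)
    elif model.family == "exponential":
        struct = 1.0 - np.exp(-3.0 * r)
    else:  # gaussian
        struct = 1.0 - np.exp(-3.0 * r**2)
    out = n0 + ps * struct
    return float(out) if out.ndim == 0 else out


def empirical_variogram_xy(
    coords: np.ndarray,
    values: np.ndarray,
    n_lags: int = 15,
    max_lag: float | None = None,
    min_pairs: int = 30,
) -> VariogramEstimate:
    """Matheron estimator on raw coordinates/values (see module docstring).

    ``max_lag`` defaults to half the maximum pairwise distance. Bins with
    fewer than ``min_pairs`` pairs are dropped (not merged). Raises
    :class:`EstimationError` when no bin survives; model fitting additionally
    requires at least 3 surviving bins (one per parameter).
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    values = np.asarray(values, dtype=float).ravel()
    if len(coords) < 2:
        raise EstimationError("need at least 2 samples")
    d = pdist(coords)
    if max_lag is None:
        max_lag = float(d.max()) / 2.0
    if max_lag <= 0:
        raise EstimationError("max_lag must be positive")
    sq = 0.5 * pdist(values[:, None], metric="sqeuclidean")

    edges = np.linspace(0.0, max_lag, n_lags + 1)
    # right-closed bins (e_b, e_{b+1}]; zero-distance pairs are excluded
    idx = np.searchsorted(edges, d, side="left") - 1
    valid = (d > 0) & (d <= max_lag)

    lags, gammas, counts = [], [], []
    for b in range(n_lags):
        m = valid & (idx == b)
        n = int(m.sum())
        if n < min_pairs:
            continue
        lags.append(0.5 * (edges[b] + edges[b + 1]))
        gammas.append(float(sq[m].mean()))
        counts.append(n)
    if not lags:
        raise EstimationError(
            f"insufficient pairs: no lag bin reached {min_pairs} pairs"
        )
    return VariogramEstimate(tuple(lags), tuple(gammas), tuple(counts), max_lag, min_pairs)


def empirical_variogram(
    sample_set,
    month: int,
    n_lags: int = 15,
    max_lag: float | None = None,
    min_pairs: int = 30,
) -> VariogramEstimate:
    """Empirical semi-variogram of one month's NDVI values of a SampleSet."""
    p = sample_set.n_features
    if not (1 <= month <= p):
        raise ValueError(f"month must lie in 1..{p}")
    values = sample_set.feature_matrix()[:, month - 1]
    return empirical_variogram_xy(
        sample_set.coords(), values, n_lags=n_lags, max_lag=max_lag, min_pairs=min_pairs
    )


def _sserr(params, family, lags, gamma, weights):
    n0, ps, a = params
    model = VariogramModel(family, max(n0, 0.0), max(ps, 0.0), max(a, 1e-12))
    resid = gamma - model_semivariance(model, lags)
    return float(np.sum(weights * resid**2))


def fit_variogram(
    est: VariogramEstimate,
    family: str = "spherical",
    weights: str = "pair_counts",
) -> VariogramModel:
    """Weighted least-squares fit of one model family to an estimate.

    The objective is SSErr = Σ_j w_j (γ̂_j − γ_model(h_j))² with w_j the
    pair count of bin j (``weights="uniform"`` for unweighted). Bounded
    optimization (all parameters ≥ 0, range ≤ 2·max_lag) from five
    deterministic starts; the best converged fit is returned with its SSErr.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if len(est) < 3:
        raise EstimationError(
            "insufficient pairs for fitting: need at least 3 retained lag bins"
        )
    lags = np.asarray(est.lag_centers)
    gamma = np.asarray(est.gamma)
    w = (
        np.asarray(est.pair_counts, dtype=float)
        if weights == "pair_counts"
        else np.ones_like(gamma)
    )

    sill0 = max(float(gamma.max()), 1e-10)
    hmax = float(est.max_lag)
    starts = [
        (0.0, sill0, hmax / 2),
        (0.1 * sill0, 0.9 * sill0, hmax / 3),
        (0.5 * sill0, 0.5 * sill0, hmax),
        (0.0, sill0, float(lags[len(lags) // 2])),
        (0.25 * sill0, 0.75 * sill0, 1.5 * hmax),
    ]
    sqrt_w = np.sqrt(w)

    def residuals(params):
        n0, ps, a = params
        model = VariogramModel(family, max(n0, 0.0), max(ps, 0.0), max(a, 1e-12))
        return sqrt_w * (gamma - model_semivariance(model, lags))

    lower = np.array([0.0, 0.0, 1e-9])
    upper = np.array([np.inf, np.inf, 2 * hmax])
    best_x, best_cost = None, np.inf
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float), lower, upper)
        try:
            res = least_squares(residuals, x0=x0, bounds=(lower, upper))
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        cost = _sserr(res.x, family, lags, gamma, w)
        if cost < best_cost:
            best_x, best_cost = res.x, cost
    if best_x is None:
        raise FittingError(f"no optimizer start converged for family {family!r}")
    n0, ps, a = best_x
    return VariogramModel(family, max(n0, 0.0), max(ps, 0.0), max(a, 1e-9), float(best_cost))


def fit_all_families(est: VariogramEstimate, weights: str = "pair_counts") -> list:
    """Fit all three families to one estimate."""
    return [fit_variogram(est, fam, weights=weights) for fam in FAMILIES]


def select_model_per_month(fits: Sequence[VariogramModel]) -> VariogramModel:
    """The per-month rule: keep the fitted model with the lowest nugget.

    Ties break by smaller SSErr, then by family order
    spherical < exponential < gaussian. (An alternative global rule —
    smallest SSErr across families — is available via ``min(fits, key=...)``
    by the caller; lowest nugget is the default selection rule here.)
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits supplied")
    return min(fits, key=lambda m: (m.nugget, m.sserr, FAMILIES.index(m.family)))


def select_range(monthly_models: Iterable[VariogramModel]) -> float:
    """The cross-month rule: the smallest range among the monthly models.

    This range is the minimum distance above which sample pairs are treated
    as spatially uncorrelated; larger choices would discard potentially
    informative samples.
    """
    models = list(monthly_models)
    if not models:
        raise ValueError("no monthly models supplied")
    return min(m.range_m for m in models)


def select_threshold(
    sample_set,
    n_lags: int = 15,
    max_lag: float | None = None,
    min_pairs: int = 30,
    weights: str = "pair_counts",
) -> tuple:
    """Full pipeline: monthly variograms → per-month lowest-nugget fit →
    smallest range. Returns (threshold_m, list of 12 selected monthly models).

    Months whose empirical variogram has too few reliable bins are skipped;
    raises :class:`EstimationError` if no month is estimable.
    """
    monthly = []
    for month in range(1, sample_set.n_features + 1):
        try:
            est = empirical_variogram(
                sample_set, month, n_lags=n_lags, max_lag=max_lag, min_pairs=min_pairs
            )
        except EstimationError:
            continue
        monthly.append(select_model_per_month(fit_all_families(est, weights=weights)))
    if not monthly:
        raise EstimationError("no month had enough pairs to estimate a variogram")
    return select_range(monthly), monthly
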