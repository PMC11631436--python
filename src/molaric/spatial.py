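"""Spatial lag (SAR) regression over geographic populations.

Populations that are geographically close tend to be more similar
(through drift, gene flow, migration and shared environment), so an
ordinary regression across populations overstates its effective sample
size.  The spatial simultaneous autoregressive lag model

    y = rho * W y + X beta + eps,   eps ~ iid N(0, sigma^2)

absorbs that dependence through a spatial weight matrix W (here the
inverse of the great-circle distance between populations, optionally
row-standardized) and a lag coefficient rho, fitted by maximum
likelihood via the profile log-likelihood in rho.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_tables import GeoLocation, ValidationError
from .phylo import RegressionResult

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


def haversine(p: GeoLocation, q: GeoLocation) -> float:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    lat1, lon1 = math.radians(p.lat), math.radians(p.lon)
    lat2, lon2 = math.radians(q.lat), math.radians(q.lon)
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def _locations(locs) -> list[GeoLocation]:
    if isinstance(locs, pd.DataFrame):
        return [
            GeoLocation(
                group_id=str(r.group_id),
                lat=float(r.lat),
                lon=float(r.lon),
                continent=getattr(r, "continent", None),
            )
            for r in locs.itertuples()
        ]
    return list(locs)


def distance_matrix_km(locs) -> tuple[list[str], np.ndarray]:
    """Pairwise great-circle distances (km) between locations."""
    points = _locations(locs)
    labels = [p.group_id for p in points]
    n = len(points)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = haversine(points[i], points[j])
    return labels, D


@dataclass(frozen=True)
class SpatialWeights:
    """Spatial weight matrix with zero diagonal.

    ``style="row_standardized"`` rescales every nonzero row to sum to 1
    (the usual default of spatial-lag software); ``"raw"`` keeps plain
    inverse distances.
    """

    labels: tuple[str, ...]
    W: np.ndarray
    style: str = "row_standardized"
    raw: np.ndarray | None = None  # pre-standardization symmetric matrix

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1] or W.shape[0] != len(self.labels):
            raise ValidationError("weight matrix shape does not match labels")
        if np.any(np.diag(W) != 0):
            raise ValidationError("weight matrix diagonal must be zero")
        if np.any(W < 0):
            raise ValidationError("weights must be non-negative")
        object.__setattr__(self, "W", W)
        if self.raw is not None:
            object.__setattr__(self, "raw", np.asarray(self.raw, dtype=float))

    @property
    def n(self) -> int:
        return len(self.labels)

    def eigenvalues(self) -> np.ndarray:
        """Real eigenvalues of W (for the admissible interval of rho).

        A row-standardized matrix built from a symmetric raw matrix S is
        D^-1 S, similar to the symmetric D^-1/2 S D^-1/2, so its
        spectrum is real; it is computed through that symmetric form.
        """
        cached = getattr(self, "_lam", None)
        if cached is not None:
            return cached
        lam = self._eigenvalues()
        object.__setattr__(self, "_lam", lam)
        return lam

    def _eigenvalues(self) -> np.ndarray:
        W = self.W
        if not np.any(W):
            return np.zeros(self.n)
        if np.allclose(W, W.T, atol=1e-12):
            return np.linalg.eigvalsh(W)
        S = self.raw
        if S is not None and np.allclose(S, S.T, atol=1e-12):
            rs = S.sum(axis=1)
            if np.all(rs > 0):
                d = 1.0 / np.sqrt(rs)
                return np.linalg.eigvalsh(d[:, None] * S * d[None, :])
        lam = np.linalg.eigvals(W)
        if np.abs(lam.imag).max() > 1e-9 * max(1.0, np.abs(lam.real).max()):
            raise ValidationError(
                "asymmetric weight matrix has complex eigenvalues; supply the "
                "symmetric raw matrix or use the row-standardized form"
            )
        return np.sort(lam.real)

    def rho_bounds(self) -> tuple[float, float]:
        lam = self.eigenvalues()
        lam_min, lam_max = float(lam.min()), float(lam.max())
        lo = 1.0 / lam_min if lam_min < 0 else -np.inf
        hi = 1.0 / lam_max if lam_max > 0 else np.inf
        return lo, hi


def inverse_distance_weights(
    locs, style: str = "row_standardized", epsilon_km: float = 1.0
) -> SpatialWeights:
    """Inverse great-circle-distance weights, W[i][j] = 1/max(d_ij, epsilon).

    ``epsilon_km`` floors the distance so co-located populations do not
    produce infinite weights; with ``epsilon_km=0`` duplicates raise.
    """
    if style not in ("raw", "row_standardized"):
        raise ValueError(f"unknown weight style: {style!r}")
    labels, D = distance_matrix_km(locs)
    n = len(labels)
    if n < 3:
        raise ValidationError(f"need >= 3 locations, got {n}")
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = max(D[i, j], epsilon_km)
            if d == 0:
                raise ValidationError(
                    f"infinite weight: {labels[i]!r} and {labels[j]!r} are "
                    "co-located and epsilon_km = 0"
                )
            W[i, j] = 1.0 / d
    raw = W.copy()
    if style == "row_standardized":
        rs = W.sum(axis=1)
        nz = rs > 0
        W[nz] = W[nz] / rs[nz, None]
    return SpatialWeights(tuple(labels), W, style, raw=raw)


@dataclass(frozen=True)
class SARResult:
    """Maximum-likelihood fit of the spatial lag model."""

    rho: float
    slope: float
    intercept: float
    se_rho: float
    se_slope: float
    se_intercept: float
    ci95_rho: tuple[float, float]
    ci95_slope: tuple[float, float]
    ci95_intercept: tuple[float, float]
    sigma2: float
    loglik: float
    r2: float
    n: int
    boundary: bool = False
    method: str = "lagSAR"

    def as_regression_result(self) -> RegressionResult:
        return RegressionResult(
            slope=self.slope,
            intercept=self.intercept,
            se_slope=self.se_slope,
            se_intercept=self.se_intercept,
            ci95_slope=self.ci95_slope,
            ci95_intercept=self.ci95_intercept,
            r2=self.r2,
            sigma2=self.sigma2,
            method="lagSAR",
            n=self.n,
            df=self.n - 3,
        )


def _sar_design(x: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(x.size), x])


def sar_loglik(rho: float, x, y, weights: SpatialWeights, eigenvalues=None) -> float:
    """Profile log-likelihood of the lag model in rho.

    beta and sigma^2 are concentrated out:
    l(rho) = sum_i ln(1 - rho*lam_i) - (n/2) ln(SSE(rho)/n) + const,
    with SSE(rho) the residual sum of squares of the OLS fit of
    (I - rho W) y on X.  The additive constant -(n/2)(ln(2 pi) + 1) is
    included so the value matches the full log-likelihood at the optimum.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    lam = weights.eigenvalues() if eigenvalues is None else eigenvalues
    n = y.size
    X = _sar_design(x)
    z = y - rho * (weights.W @ y)
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ beta
    sse = float(resid @ resid)
    logdet = float(np.sum(np.log(1.0 - rho * lam)))
    return logdet - 0.5 * n * np.log(sse / n) - 0.5 * n * (np.log(2 * np.pi) + 1.0)


def sar_full_loglik(rho, beta, sigma2, x, y, weights: SpatialWeights) -> float:
    """Full log-likelihood l(rho, beta, sigma^2) of the lag model."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = y.size
    lam = weights.eigenvalues()
    X = _sar_design(x)
    resid = y - rho * (weights.W @ y) - X @ np.asarray(beta, float)
    logdet = float(np.sum(np.log(1.0 - rho * lam)))
    return (
        -0.5 * n * np.log(2 * np.pi * sigma2)
        + logdet
        - 0.5 * float(resid @ resid) / sigma2
    )


def lag_sar_fit(x, y, weights: SpatialWeights) -> SARResult:
    """Fit y = rho W y + X beta + eps by maximum likelihood.

    rho is found by bounded scalar maximization of the profile
    log-likelihood on the open eigenvalue interval (shrunk by 1e-6);
    beta and sigma^2 are recovered at rho_hat.  Standard errors come
    from the observed information (negative Hessian of the full
    log-likelihood, central finite differences); 95% CIs are
    normal-based.  A W of all zeros makes the likelihood flat in rho;
    by convention rho_hat = 0 and the fit reduces exactly to OLS.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 5:
        raise ValidationError(f"lagSAR needs >= 5 observations, got {n}")
    if weights.n != n:
        raise ValidationError("weight matrix does not match data length")
    lam = weights.eigenvalues()
    X = _sar_design(x)

    if not np.any(weights.W):
        rho_hat, boundary = 0.0, False
        lo = hi = 0.0
    else:
        lo, hi = weights.rho_bounds()
        lo = lo + 1e-6 if np.isfinite(lo) else -0.999999
        hi = hi - 1e-6 if np.isfinite(hi) else 0.999999
        res = optimize.minimize_scalar(
            lambda r: -sar_loglik(r, x, y, weights, eigenvalues=lam),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        rho_hat = float(res.x)
        boundary = min(rho_hat - lo, hi - rho_hat) < 1e-4 * (hi - lo)
        if boundary:
            logger.warning("lagSAR: rho estimate %.6f at interval boundary", rho_hat)

    z = y - rho_hat * (weights.W @ y)
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ beta
    sigma2 = float(resid @ resid) / n
    ll = sar_full_loglik(rho_hat, beta, sigma2, x, y, weights)

    theta = np.array([rho_hat, beta[0], beta[1], sigma2])

    def nll(t):
        if t[3] <= 0:
            return np.inf
        if np.any(1.0 - t[0] * lam <= 0):
            return np.inf
        return -sar_full_loglik(t[0], t[1:3], t[3], x, y, weights)

    H = _numerical_hessian(nll, theta)
    se = np.full(4, np.nan)
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        if np.all(d[:3] > 0):
            se[:3] = np.sqrt(d[:3])
            se[3] = np.sqrt(d[3]) if d[3] > 0 else np.nan
    except np.linalg.LinAlgError:
        pass
    if not np.all(np.isfinite(se[:3])):
        # fall back: rho from profile curvature, beta from GLS-at-rho formula
        se = _fallback_se(rho_hat, x, y, weights, lam, sigma2, se)

    zc = stats.norm.ppf(0.975)
    # pseudo-R^2: squared correlation of observed y with fitted values
    fitted = np.linalg.solve(np.eye(n) - rho_hat * weights.W, X @ beta)
    r2 = float(np.corrcoef(y, fitted)[0, 1] ** 2) if np.ptp(fitted) > 0 else 0.0

    return SARResult(
        rho=rho_hat,
        slope=float(beta[1]),
        intercept=float(beta[0]),
        se_rho=float(se[0]),
        se_slope=float(se[2]),
        se_intercept=float(se[1]),
        ci95_rho=(rho_hat - zc * se[0], rho_hat + zc * se[0]),
        ci95_slope=(float(beta[1] - zc * se[2]), float(beta[1] + zc * se[2])),
        ci95_intercept=(float(beta[0] - zc * se[1]), float(beta[0] + zc * se[1])),
        sigma2=sigma2,
        loglik=float(ll),
        r2=r2,
        n=n,
        boundary=boundary,
    )


def _numerical_hessian(f, theta: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian of f at theta."""
    k = theta.size
    h = rel_step * np.maximum(np.abs(theta), 1.0)
    H = np.zeros((k, k))
    f0 = f(theta)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                tp = theta.copy(); tp[i] += h[i]
                tm = theta.copy(); tm[i] -= h[i]
                vals = (f(tp), f0, f(tm))
                H[i, i] = (
                    (vals[0] - 2 * vals[1] + vals[2]) / h[i] ** 2
                    if np.all(np.isfinite(vals))
                    else np.nan
                )
            else:
                tpp = theta.copy(); tpp[i] += h[i]; tpp[j] += h[j]
                tpm = theta.copy(); tpm[i] += h[i]; tpm[j] -= h[j]
                tmp = theta.copy(); tmp[i] -= h[i]; tmp[j] += h[j]
                tmm = theta.copy(); tmm[i] -= h[i]; tmm[j] -= h[j]
                vals = (f(tpp), f(tpm), f(tmp), f(tmm))
                H[i, j] = H[j, i] = (
                    (vals[0] - vals[1] - vals[2] + vals[3]) / (4 * h[i] * h[j])
                    if np.all(np.isfinite(vals))
                    else np.nan
                )
    return H


def _fallback_se(rho_hat, x, y, weights, lam, sigma2, se):
    """SEs when the joint Hessian is ill-conditioned (e.g. W = 0):
    conditional-on-rho OLS standard errors for beta, profile curvature
    for rho."""
    n = y.size
    X = _sar_design(np.asarray(x, float))
    XtX_inv = np.linalg.inv(X.T @ X)
    cov_beta = sigma2 * n / (n - 2) * XtX_inv
    out = se.copy()
    if not np.isfinite(out[1]):
        out[1] = np.sqrt(cov_beta[0, 0])
    if not np.isfinite(out[2]):
        out[2] = np.sqrt(cov_beta[1, 1])
    if not np.isfinite(out[0]):
        if np.any(weights.W):
            h = 1e-5
            c = (
                sar_loglik(rho_hat + h, x, y, weights, lam)
                - 2 * sar_loglik(rho_hat, x, y, weights, lam)
                + sar_loglik(rho_hat - h, x, y, weights, lam)
            ) / h**2
            out[0] = np.sqrt(-1.0 / c) if c < 0 else np.nan
        else:
            out[0] = 0.0
    return out


def simulate_sar(
    locs_or_weights,
    rho: float,
    beta: tuple[float, float],
    sigma2: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate (x, y) from the lag model y = (I - rho W)^-1 (X beta + eps).

    ``x`` is standard normal, ``eps ~ N(0, sigma2)``; ``beta`` is
    (intercept, slope).  ``rho`` must lie strictly inside the
    eigenvalue-bounded interval of W.
    """
    if isinstance(locs_or_weights, SpatialWeights):
        weights = locs_or_weights
    else:
        weights = inverse_distance_weights(locs_or_weights)
    lo, hi = weights.rho_bounds()
    if not (lo < rho < hi):
        raise ValidationError(f"rho={rho} outside admissible interval ({lo:.4g}, {hi:.4g})")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = weights.n
    x = rng.normal(size=n)
    eps = rng.normal(0.0, np.sqrt(sigma2), size=n)
    X = _sar_design(x)
    y = np.linalg.solve(np.eye(n) - rho * weights.W, X @ np.asarray(beta, float) + eps)
    return x, y
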