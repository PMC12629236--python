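"""Gaussian model-X knockoff copies of the CLR design matrix.

The CLR transform maps compositions close to a multivariate normal, so
knockoffs are built under a Gaussian model N(mu, Sigma): a decorrelation
vector ``s`` with 0 <= diag(s) and 2*Sigma - diag(s) PSD is chosen, and
each knockoff row is drawn from the conditional

    Z~_i | Z_i ~ N( Z_i - diag(s) Sigma^-1 (Z_i - mu),
                    2 diag(s) - diag(s) Sigma^-1 diag(s) ),

the closed form of the sequential conditional independent pairs
construction for multivariate normals.  Because CLR rows sum to zero the
empirical covariance is exactly singular; shrinkage toward a scaled
identity is therefore mandatory before the construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.covariance import LedoitWolf

from .data_io import ClrMatrix

__all__ = ["GaussianModel", "KnockoffSet", "fit_gaussian", "solve_s", "sample_knockoffs"]

_PD_FLOOR_FACTOR = 1e-8  # min eigenvalue floor, relative to mean diagonal


@dataclass
class GaussianModel:
    """Fitted multivariate-normal approximation of the CLR rows."""

    mu: np.ndarray
    sigma: np.ndarray
    shrinkage_intensity: float

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma, dtype=float)
        if np.max(np.abs(s - s.T)) > 1e-10:
            raise ValueError("sigma must be symmetric")
        eigmin = float(np.linalg.eigvalsh(s)[0])
        if eigmin <= 0:
            raise ValueError("sigma must be positive definite after shrinkage")
        self.sigma = (s + s.T) / 2.0


@dataclass
class KnockoffSet:
    """Knockoff matrix with the construction's provenance."""

    z_tilde: np.ndarray
    s: np.ndarray
    method: str
    seed: int


def _as_matrix(Z: ClrMatrix | np.ndarray) -> np.ndarray:
    return Z.values if isinstance(Z, ClrMatrix) else np.asarray(Z, dtype=float)


def fit_gaussian(Z: ClrMatrix | np.ndarray, shrinkage: str | float = "auto") -> GaussianModel:
    """Fit N(mu, Sigma) with shrinkage guaranteeing positive definiteness.

    ``shrinkage="auto"`` uses Ledoit-Wolf analytic shrinkage toward the
    scaled identity; a float in [0, 1] fixes the intensity.  Either way
    the minimum eigenvalue is floored at 1e-8 times the mean diagonal, the
    amount needed because exact CLR data have a zero eigenvalue along the
    all-ones direction.
    """
    X = _as_matrix(Z)
    n, p = X.shape
    if n < 2:
        raise ValueError("at least two samples are required to estimate a covariance")
    mu = X.mean(axis=0)
    Xc = X - mu
    emp = Xc.T @ Xc / n
    target_scale = float(np.trace(emp)) / p
    if shrinkage == "auto":
        lw = LedoitWolf(assume_centered=True).fit(Xc)
        intensity = float(lw.shrinkage_)
        sigma = np.asarray(lw.covariance_)
    else:
        intensity = float(shrinkage)
        if not 0.0 <= intensity <= 1.0:
            raise ValueError("shrinkage intensity must lie in [0, 1]")
        sigma = (1 - intensity) * emp + intensity * target_scale * np.eye(p)
    diag = np.diag(sigma)
    if np.any(diag <= 0):
        warnings.warn("constant column detected; variance floored by shrinkage")
    floor = _PD_FLOOR_FACTOR * max(float(diag.mean()), np.finfo(float).tiny)
    eigmin = float(np.linalg.eigvalsh(sigma)[0])
    if eigmin < floor:
        # push further toward the scaled identity until the floor holds
        bump = (floor - eigmin) / max(target_scale - eigmin, floor)
        bump = min(max(bump, 0.0), 1.0)
        sigma = (1 - bump) * sigma + bump * target_scale * np.eye(p)
        intensity = intensity + (1 - intensity) * bump
    return GaussianModel(mu=mu, sigma=sigma, shrinkage_intensity=intensity)


def _equicorrelated_s(corr: np.ndarray) -> np.ndarray:
    lam_min = float(np.linalg.eigvalsh(corr)[0])
    return np.full(corr.shape[0], min(2.0 * lam_min, 1.0))


def _sdp_s(corr: np.ndarray, max_cycles: int = 50, tol: float = 1e-8) -> np.ndarray:
    """Maximize sum(s) s.t. 0 <= s <= 1, 2*corr - diag(s) PSD, by cyclic
    coordinate ascent with exact Schur-complement bounds per coordinate."""
    p = corr.shape[0]
    s = _equicorrelated_s(corr).copy()  # feasible start
    A = 2.0 * corr - np.diag(s)
    for _ in range(max_cycles):
        delta = 0.0
        for j in range(p):
            idx = np.r_[0:j, j + 1 : p]
            Ajj_full = 2.0 * corr[j, j]
            q = A[np.ix_(idx, [j])].ravel()
            sub = A[np.ix_(idx, idx)]
            try:
                sol = np.linalg.solve(sub + 1e-12 * np.eye(p - 1), q)
            except np.linalg.LinAlgError:
                continue
            # s_j can rise until the Schur complement A_jj - q' sub^-1 q hits 0
            bound = Ajj_full - float(q @ sol)
            new_sj = float(np.clip(bound - 1e-9, 0.0, 1.0))
            if new_sj > s[j]:
                delta = max(delta, new_sj - s[j])
                A[j, j] = 2.0 * corr[j, j] - new_sj
                s[j] = new_sj
        if delta < tol:
            break
    return s


def solve_s(model: GaussianModel, method: str = "equicorrelated") -> np.ndarray:
    """Compute the decorrelation vector s (on the covariance scale).

    Solved on the correlation scale, then mapped back by the variances.
    The returned s always satisfies eigmin(2*Sigma - diag(s)) >= -1e-10.
    """
    sigma = model.sigma
    d = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(d, d)
    corr = (corr + corr.T) / 2.0
    if method == "equicorrelated":
        s_corr = _equicorrelated_s(corr)
    elif method == "sdp":
        try:
            s_corr = _sdp_s(corr)
        except Exception:  # numerical failure: keep the guaranteed-feasible choice
            warnings.warn("SDP coordinate ascent failed; falling back to equicorrelated")
            s_corr = _equicorrelated_s(corr)
    else:
        raise ValueError(f"unknown method {method!r}")
    s = s_corr * d**2
    # feasibility contract, with a conservative backoff if roundoff bites
    for _ in range(60):
        if float(np.linalg.eigvalsh(2.0 * sigma - np.diag(s))[0]) >= -1e-10:
            break
        s *= 1.0 - 1e-6
    return s


def sample_knockoffs(
    Z: ClrMatrix | np.ndarray,
    model: GaussianModel,
    s: np.ndarray,
    seed: int,
    method: str = "equicorrelated",
) -> KnockoffSet:
    """Draw knockoff rows from the Gaussian conditional; deterministic in seed."""
    X = _as_matrix(Z)
    n, p = X.shape
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("s must be non-negative")
    sigma_inv = np.linalg.inv(model.sigma)
    D = np.diag(s)
    cond_mean = X - (X - model.mu) @ sigma_inv @ D
    cond_cov = 2.0 * D - D @ sigma_inv @ D
    cond_cov = (cond_cov + cond_cov.T) / 2.0
    w, V = np.linalg.eigh(cond_cov)
    if np.any(w < -1e-10):
        warnings.warn("conditional covariance has negative eigenvalues; clipping at 0")
    w = np.clip(w, 0.0, None)
    chol_like = V * np.sqrt(w)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n, p))
    z_tilde = cond_mean + noise @ chol_like.T
    return KnockoffSet(z_tilde=z_tilde, s=s, method=method, seed=seed)
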