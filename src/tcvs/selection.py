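"""Knockoff filter statistics, threshold, BIC tuning, and the TCVS pipeline.

After fitting the augmented model, each taxon gets an importance contrast
W_j = |b_j| - |b~_j|: a genuine signal inflates the original coefficient
relative to its knockoff, while nulls are symmetric.  The data-dependent
threshold T is the smallest candidate magnitude t at which the count of
strongly negative statistics, a proxy for false positives, stays within a
fraction q of the selections; the selected set is {j : W_j >= T}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_io import CountTable, ResponseData, close_counts, clr_transform
from .knockoffs import fit_gaussian, sample_knockoffs, solve_s
from .solver import PenaltySpec, TcvsFit, fit, lambda_max
from .tree_groups import GroupStructure, TaxonomicTree, augment_groups, build_groups

__all__ = [
    "KnockoffStatistics",
    "SelectionResult",
    "TcvsConfig",
    "knockoff_statistics",
    "knockoff_threshold",
    "bic_score",
    "default_lambda_grid",
    "tune_lambda",
    "run_tcvs",
]

VARIANTS = ("tcvs", "tlasso", "classo", "classokf")


@dataclass
class KnockoffStatistics:
    w: np.ndarray
    nonzero_abs: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        mags = np.unique(np.abs(self.w))
        self.nonzero_abs = mags[mags > 0]


@dataclass
class SelectionResult:
    selected: np.ndarray
    threshold: float
    q: float | None
    w: np.ndarray | None
    lambda_opt: float
    bic_table: "list[dict]"
    fit: TcvsFit
    taxa: list[str] | None = None
    variant: str = "tcvs"
    seed: int | None = None


@dataclass
class TcvsConfig:
    """Pipeline options: selection level q, pseudo-count, seed, grid, variant."""

    q: float = 0.05
    pseudo_count: float = 0.5
    seed: int = 0
    n_lambda: int = 50
    lambda_min_ratio: float = 0.001
    lambda_grid: np.ndarray | None = None
    variant: str = "tcvs"
    knockoff_method: str = "equicorrelated"
    include_root: bool = True
    weight_mode: str = "size"
    plus: bool = False  # knockoff+ variant of the threshold (off by default)

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0, 1)")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")


def knockoff_statistics(fit_result: TcvsFit) -> KnockoffStatistics:
    """W_j = |b_j| - |b~_j| from a single augmented fit."""
    if fit_result.beta_tilde is None:
        raise ValueError("fit has no knockoff coefficients; run an augmented variant")
    return KnockoffStatistics(w=np.abs(fit_result.beta) - np.abs(fit_result.beta_tilde))


def knockoff_threshold(stats: KnockoffStatistics, q: float, plus: bool = False) -> float:
    """Smallest t among the distinct nonzero |W_j| with estimated FDP <= q.

    The estimate is #{j : W_j <= -t} / max(1, #{j : W_j >= t}); ``plus``
    adds 1 to the numerator (the FDR-controlling variant).  Returns
    +infinity when no candidate qualifies (empty selection).
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    w = stats.w
    offset = 1.0 if plus else 0.0
    for t in stats.nonzero_abs:  # ascending: first feasible t is the minimum
        num = offset + np.count_nonzero(w <= -t)
        den = max(1, np.count_nonzero(w >= t))
        if num / den <= q:
            return float(t)
    return float("inf")


def bic_score(y: np.ndarray, design_star: np.ndarray, coeffs_star: np.ndarray,
              n: int | None = None) -> float:
    """n*log(RSS/n) + K*log(n), K counting nonzeros of the augmented coefficients."""
    y = np.asarray(y, dtype=float).ravel()
    D = np.asarray(design_star, dtype=float)
    c = np.asarray(coeffs_star, dtype=float).ravel()
    if n is None:
        n = y.size
    resid = y - D @ c
    rss = float(resid @ resid)
    k = int(np.count_nonzero(c))
    if rss <= 0:
        warnings.warn("zero residual sum of squares: saturated fit, BIC = -inf")
        return float("-inf")
    return n * float(np.log(rss / n)) + k * float(np.log(n))


def default_lambda_grid(y: np.ndarray, design: np.ndarray,
                        l1_mask: np.ndarray | None = None,
                        n_lambda: int = 50,
                        min_ratio: float = 0.001) -> np.ndarray:
    """Log-spaced grid from the data-derived lambda_max down to min_ratio*lambda_max."""
    lmax = lambda_max(y, design, l1_mask)
    if lmax <= 0:
        lmax = 1.0
    return np.geomspace(lmax, min_ratio * lmax, n_lambda)


def tune_lambda(
    y: np.ndarray,
    Z: np.ndarray,
    Z_tilde: np.ndarray | None,
    groups: GroupStructure | None,
    grid: np.ndarray,
    covariates: np.ndarray | None = None,
    weight_mode: str = "size",
    **fit_kwargs,
) -> tuple[float, list[dict], TcvsFit]:
    """Fit the path (warm-started, descending) and pick the BIC minimizer.

    Ties break toward the larger lambda (sparser model); the grid is
    sorted internally so permuting it cannot change the answer.
    """
    grid = np.sort(np.asarray(grid, dtype=float))[::-1]
    if grid.size == 0 or np.any(grid <= 0):
        raise ValueError("lambda grid must be nonempty and positive")
    n = y.size
    design_parts = [Z] if Z_tilde is None else [Z, Z_tilde]
    D = np.hstack(design_parts)
    n_pen = D.shape[1]
    yc = np.asarray(y, float) - float(np.mean(y))
    Dc = D - D.mean(axis=0)

    table: list[dict] = []
    best: tuple[float, float, TcvsFit] | None = None
    warm = None
    any_converged = False
    for lam in grid:
        spec = PenaltySpec(lam=float(lam), groups=groups, weight_mode=weight_mode)
        f = fit(y, Z, Z_tilde, spec, covariates=covariates, warm_start=warm, **fit_kwargs)
        coeffs = f.beta if f.beta_tilde is None else np.concatenate([f.beta, f.beta_tilde])
        if covariates is not None:
            full = np.concatenate([coeffs, f.covariate_coefs])
            warm = full
        else:
            warm = coeffs
        any_converged = any_converged or f.converged
        # BIC on the penalized (augmented) design after removing covariate effects
        if covariates is not None:
            C = np.atleast_2d(np.asarray(covariates, float))
            if C.shape[0] != n:
                C = C.T
            y_adj = yc - (C - C.mean(axis=0)) @ f.covariate_coefs
        else:
            y_adj = yc
        score = bic_score(y_adj, Dc, coeffs[:n_pen], n)
        khat = int(np.count_nonzero(coeffs[:n_pen]))
        table.append({"lambda": float(lam), "bic": score, "support_size": khat,
                      "converged": bool(f.converged)})
        if f.converged and (best is None or score < best[0] - 1e-12):
            best = (score, float(lam), f)
    if not any_converged or best is None:
        raise RuntimeError("no lambda in the grid produced a converged fit")
    return best[1], table, best[2]


def run_tcvs(
    counts: CountTable | np.ndarray,
    taxonomy: TaxonomicTree | None,
    y: ResponseData | np.ndarray,
    covariates: np.ndarray | None = None,
    config: TcvsConfig | None = None,
) -> SelectionResult:
    """End-to-end pipeline: CLR, knockoffs, augmented fit, W statistics, threshold.

    Variants: ``tcvs`` (tree groups + knockoffs), ``tlasso`` (tree groups,
    no knockoffs), ``classokf`` (knockoffs, no groups), ``classo``
    (neither).  Non-knockoff variants return the BIC-selected support
    directly with threshold NaN.
    """
    config = config or TcvsConfig()
    taxa: list[str] | None = None
    if isinstance(counts, CountTable):
        taxa = counts.taxa
        Z = clr_transform(close_counts(counts, config.pseudo_count)).values
    else:
        Z = np.asarray(counts, dtype=float)  # pre-transformed CLR matrix accepted
    if isinstance(y, ResponseData):
        if covariates is None:
            covariates = y.covariates
        y_vec = y.y
    else:
        y_vec = np.asarray(y, dtype=float).ravel()
    if y_vec.size != Z.shape[0]:
        raise ValueError("response length does not match sample count")

    use_tree = config.variant in ("tcvs", "tlasso")
    use_knockoffs = config.variant in ("tcvs", "classokf")

    groups = None
    if use_tree:
        if taxonomy is None:
            raise ValueError(f"variant {config.variant!r} requires a taxonomic tree")
        groups = build_groups(taxonomy, include_root=config.include_root)

    Z_tilde = None
    if use_knockoffs:
        model = fit_gaussian(Z)
        s = solve_s(model, method=config.knockoff_method)
        Z_tilde = sample_knockoffs(Z, model, s, seed=config.seed,
                                   method=config.knockoff_method).z_tilde
        if groups is not None:
            groups = augment_groups(groups)

    design = Z if Z_tilde is None else np.hstack([Z, Z_tilde])
    grid = config.lambda_grid
    if grid is None:
        grid = default_lambda_grid(y_vec, design, n_lambda=config.n_lambda,
                                   min_ratio=config.lambda_min_ratio)
    lam_opt, table, best_fit = tune_lambda(
        y_vec, Z, Z_tilde, groups, grid, covariates=covariates,
        weight_mode=config.weight_mode,
    )

    if use_knockoffs:
        stats = knockoff_statistics(best_fit)
        T = knockoff_threshold(stats, config.q, plus=config.plus)
        selected = np.flatnonzero(stats.w >= T) if np.isfinite(T) else np.array([], dtype=int)
        w = stats.w
    else:
        T = float("nan")
        w = None
        selected = np.flatnonzero(best_fit.beta)

    return SelectionResult(
        selected=selected,
        threshold=T,
        q=config.q if use_knockoffs else None,
        w=w,
        lambda_opt=lam_opt,
        bic_table=table,
        fit=best_fit,
        taxa=taxa,
        variant=config.variant,
        seed=config.seed,
    )
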